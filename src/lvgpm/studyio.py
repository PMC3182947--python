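"""JSON study-file format: schema, validation, read/write.

Lengths are always millimetres in files. The plane model (origin + two
in-plane direction cosines) is DICOM-orientation-compatible to ease future
adapters, but DICOM parsing itself is out of scope.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import List, Literal, Optional

import numpy as np
from pydantic import BaseModel, Field
from pydantic import ValidationError as PydanticValidationError

from .errors import SchemaError
from .geometry import SlicePlane
from .study import CineStudy, StudySlice

SCHEMA_VERSION = "1"


class PlaneModel(BaseModel):
    origin: List[float] = Field(..., min_length=3, max_length=3)
    normal: List[float] = Field(..., min_length=3, max_length=3)
    axis_u: List[float] = Field(..., min_length=3, max_length=3)
    axis_v: List[float] = Field(..., min_length=3, max_length=3)


class FrameContours(BaseModel):
    endo_points: List[List[float]]
    epi_points: List[List[float]]


class SliceModel(BaseModel):
    label: Literal["SAX", "LAX_2CH", "LAX_4CH"]
    sax_index: Optional[int] = None
    plane: PlaneModel
    frames: List[FrameContours]


class MetadataModel(BaseModel):
    animal_id: str = "unknown"
    group: Literal["control", "infarct", "unknown"] = "unknown"
    slice_thickness_mm: float = Field(..., gt=0)
    pixel_size_mm: float = Field(..., gt=0)
    n_frames: int = Field(..., ge=1)
    rng_seed: Optional[int] = None
    noise_sd_mm: Optional[float] = None


class StudyFileModel(BaseModel):
    schema_version: str
    metadata: MetadataModel
    slices: List[SliceModel]
    mv_points: List[List[List[float]]]


def _pointer(loc) -> str:
    return "/" + "/".join(str(p) for p in loc)


def write_study(study: CineStudy, path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "metadata": {
            "animal_id": str(study.metadata.get("animal_id", "unknown")),
            "group": study.metadata.get("group", "unknown"),
            "slice_thickness_mm": study.slice_thickness_mm,
            "pixel_size_mm": study.pixel_size_mm,
            "n_frames": study.n_frames,
            "rng_seed": study.metadata.get("rng_seed"),
            "noise_sd_mm": study.metadata.get("noise_sd_mm"),
        },
        "slices": [
            {
                "label": s.label,
                "sax_index": s.plane.sax_index,
                "plane": {
                    "origin": s.plane.origin.tolist(),
                    "normal": s.plane.normal.tolist(),
                    "axis_u": s.plane.axis_u.tolist(),
                    "axis_v": s.plane.axis_v.tolist(),
                },
                "frames": [
                    {"endo_points": s.endo[f].tolist(),
                     "epi_points": s.epi[f].tolist()}
                    for f in range(study.n_frames)
                ],
            }
            for s in study.slices
        ],
        "mv_points": study.mv_points.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def read_study(path) -> CineStudy:
    """Load and validate a study file; schema errors carry JSON pointers."""
    try:
        raw = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise SchemaError(f"cannot parse study file {path}: {exc}") from exc
    version = raw.get("schema_version") if isinstance(raw, dict) else None
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema_version {version!r} (expected "
            f"{SCHEMA_VERSION!r}) in {path}")
    try:
        doc = StudyFileModel.model_validate(raw)
    except PydanticValidationError as exc:
        msgs = "; ".join(f"{_pointer(e['loc'])}: {e['msg']}"
                         for e in exc.errors()[:10])
        raise SchemaError(f"study file {path} invalid: {msgs}") from exc

    n_frames = doc.metadata.n_frames
    slices = []
    for i, sm in enumerate(doc.slices):
        if len(sm.frames) != n_frames:
            raise SchemaError(
                f"study file {path} invalid: /slices/{i}/frames: expected "
                f"{n_frames} frames, got {len(sm.frames)}")
        try:
            plane = SlicePlane(origin=np.array(sm.plane.origin),
                               normal=np.array(sm.plane.normal),
                               axis_u=np.array(sm.plane.axis_u),
                               axis_v=np.array(sm.plane.axis_v),
                               slice_label=sm.label, sax_index=sm.sax_index)
        except Exception as exc:
            raise SchemaError(
                f"study file {path} invalid: /slices/{i}/plane: {exc}"
            ) from exc

        def contour(arr, where):
            try:
                a = np.asarray(arr, dtype=float)
            except ValueError as exc:
                raise SchemaError(
                    f"study file {path} invalid: {where}: ragged contour "
                    f"({exc})") from exc
            if a.size == 0:
                return np.zeros((0, 2))
            if a.ndim != 2 or a.shape[1] != 2:
                raise SchemaError(
                    f"study file {path} invalid: {where}: ragged or "
                    f"non-(n,2) contour of shape {a.shape}")
            return a

        endo = [contour(fr.endo_points,
                        f"/slices/{i}/frames/{f}/endo_points")
                for f, fr in enumerate(sm.frames)]
        epi = [contour(fr.epi_points,
                       f"/slices/{i}/frames/{f}/epi_points")
               for f, fr in enumerate(sm.frames)]
        slices.append(StudySlice(plane=plane, endo=endo, epi=epi))

    mv = np.asarray(doc.mv_points, dtype=float)
    if mv.shape != (n_frames, 4, 3):
        raise SchemaError(
            f"study file {path} invalid: /mv_points: shape {mv.shape} != "
            f"({n_frames}, 4, 3)")
    meta = {"animal_id": doc.metadata.animal_id,
            "group": doc.metadata.group}
    if doc.metadata.rng_seed is not None:
        meta["rng_seed"] = doc.metadata.rng_seed
    if doc.metadata.noise_sd_mm is not None:
        meta["noise_sd_mm"] = doc.metadata.noise_sd_mm
    return CineStudy(slices=slices, mv_points=mv, n_frames=n_frames,
                     slice_thickness_mm=doc.metadata.slice_thickness_mm,
                     pixel_size_mm=doc.metadata.pixel_size_mm,
                     metadata=meta)
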