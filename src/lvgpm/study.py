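"""In-memory container for one animal's cine study.

A :class:`CineStudy` is the pipeline's exchange format: an ordered stack of
short-axis (SAX) slice planes plus one two-chamber and one four-chamber
long-axis (LAX) plane, each carrying per-frame endocardial and epicardial
contours in plane coordinates, together with the four mitral-valve landmark
points per frame.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .geometry import SlicePlane

SAX = "SAX"
LAX_2CH = "LAX_2CH"
LAX_4CH = "LAX_4CH"


@dataclass
class StudySlice:
    """One imaging plane with its per-frame contours (plane coordinates, mm)."""

    plane: SlicePlane
    endo: list[np.ndarray]          # per frame, (n_i, 2); may be empty
    epi: list[np.ndarray]

    @property
    def label(self) -> str:
        return self.plane.slice_label

    def endo_nonempty(self, frame: int) -> bool:
        return len(self.endo[frame]) > 0


@dataclass
class CineStudy:
    slices: list[StudySlice]
    mv_points: np.ndarray           # (n_frames, 4, 3)
    n_frames: int
    slice_thickness_mm: float
    pixel_size_mm: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mv_points = np.asarray(self.mv_points, dtype=float)
        labels = [s.label for s in self.slices]
        if labels.count(LAX_2CH) != 1 or labels.count(LAX_4CH) != 1:
            raise ConfigurationError(
                "study must contain exactly one LAX_2CH and one LAX_4CH slice")
        if self.mv_points.shape != (self.n_frames, 4, 3):
            raise ConfigurationError(
                f"mv_points shape {self.mv_points.shape} != "
                f"({self.n_frames}, 4, 3)")
        for s in self.slices:
            if len(s.endo) != self.n_frames or len(s.epi) != self.n_frames:
                raise ConfigurationError(
                    f"slice {s.label}/{s.plane.sax_index} does not carry "
                    f"{self.n_frames} frames")

    # -- accessors ----------------------------------------------------------
    def sax_slices(self) -> list[StudySlice]:
        out = [s for s in self.slices if s.label == SAX]
        return sorted(out, key=lambda s: s.plane.sax_index)

    def lax_slices(self) -> list[StudySlice]:
        return [s for s in self.slices if s.label != SAX]

    def slice_by_id(self, label: str, sax_index: int | None = None
                    ) -> StudySlice:
        for s in self.slices:
            if s.label == label and (label != SAX or
                                     s.plane.sax_index == sax_index):
                return s
        raise ConfigurationError(f"no slice {label}/{sax_index} in study")

    # -- transforms (used by equivariance checks) ----------------------------
    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "CineStudy":
        """Rigidly transform every plane and landmark; contours unchanged."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new_slices = []
        for s in self.slices:
            p = s.plane
            new_plane = SlicePlane(origin=R @ p.origin + t,
                                   normal=R @ p.normal,
                                   axis_u=R @ p.axis_u,
                                   axis_v=R @ p.axis_v,
                                   slice_label=p.slice_label,
                                   sax_index=p.sax_index)
            new_slices.append(StudySlice(plane=new_plane,
                                         endo=[c.copy() for c in s.endo],
                                         epi=[c.copy() for c in s.epi]))
        mv = self.mv_points @ R.T + t
        return replace(self, slices=new_slices, mv_points=mv)


def studies_equal(a: CineStudy, b: CineStudy) -> bool:
    """Value equality of two studies (bit-identical arrays)."""
    if (a.n_frames != b.n_frames
            or a.slice_thickness_mm != b.slice_thickness_mm
            or a.pixel_size_mm != b.pixel_size_mm
            or len(a.slices) != len(b.slices)):
        return False
    if not np.array_equal(a.mv_points, b.mv_points):
        return False
    for sa, sb in zip(a.slices, b.slices):
        pa, pb = sa.plane, sb.plane
        for attr in ("origin", "normal", "axis_u", "axis_v"):
            if not np.array_equal(getattr(pa, attr), getattr(pb, attr)):
                return False
        if pa.slice_label != pb.slice_label or pa.sax_index != pb.sax_index:
            return False
        for ca, cb in zip(sa.endo + sa.epi, sb.endo + sb.epi):
            if not np.array_equal(ca, cb):
                return False
    return True
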