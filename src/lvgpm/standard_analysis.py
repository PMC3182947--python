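"""Slice-summation reference method (manual-segmentation surrogate).

Per-slice cavity and myocardial areas are measured by voxel counting:
pixel centers inside the contour polygon times the pixel area, emulating
manual segmentation on the reconstructed image grid. End-diastolic and
end-systolic frames are selected per slice (maximal / minimal cavity
area); volumes are the sum of per-slice areas times slice thickness over
the contiguous SAX stack, and mass is 1.05 x the ED/ES-averaged
myocardial volume.
"""
from __future__ import annotations

import logging

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import ConfigurationError, ContourTopologyError
from .geometry import LVSurfaceModel, MitralValvePlane
from .metrics import FunctionReport, derive
from .phantom import AKINESIA_THRESHOLD_MM, TruthModel
from .study import CineStudy, StudySlice

logger = logging.getLogger(__name__)


def _polygon(points: np.ndarray, where: str) -> Polygon | None:
    if len(points) < 3:
        return None
    poly = Polygon(points)
    if not poly.is_valid:
        # noise-level micro-loops are repaired; a genuine bow-tie whose
        # repair changes the area materially is a data error
        repaired = poly.buffer(0)
        if repaired.geom_type == "MultiPolygon":
            parts = list(repaired.geoms)
            repaired = max(parts, key=lambda g: g.area)
        area_ref = abs(poly.area)
        tol = max(0.005 * area_ref, 0.01)     # mm^2; floor covers noise blobs
        if (not repaired.is_valid or repaired.is_empty
                or abs(repaired.area - area_ref) > tol):
            raise ContourTopologyError(
                f"self-intersecting contour at {where}")
        logger.debug("repaired micro self-intersection at %s", where)
        poly = repaired
    return poly


def _pixel_count(poly: Polygon | None, pixel_size_mm: float) -> int:
    """Pixel centers inside the polygon, on a lattice anchored at the origin."""
    if poly is None:
        return 0
    minx, miny, maxx, maxy = poly.bounds
    i0 = int(np.floor(minx / pixel_size_mm)) - 1
    i1 = int(np.ceil(maxx / pixel_size_mm)) + 1
    j0 = int(np.floor(miny / pixel_size_mm)) - 1
    j1 = int(np.ceil(maxy / pixel_size_mm)) + 1
    xs = (np.arange(i0, i1) + 0.5) * pixel_size_mm
    ys = (np.arange(j0, j1) + 0.5) * pixel_size_mm
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    inside = shapely.contains_xy(poly, X.ravel(), Y.ravel())
    return int(inside.sum())


def rasterized_slice_areas(study: CineStudy, slice_obj: StudySlice | int,
                           frame: int, pixel_size_mm: float | None = None
                           ) -> dict:
    """Cavity and myocardial areas (mm^2) of one SAX slice at one frame."""
    if isinstance(slice_obj, int):
        slice_obj = study.sax_slices()[slice_obj]
    px = pixel_size_mm if pixel_size_mm is not None else study.pixel_size_mm
    where = f"slice {slice_obj.label}/{slice_obj.plane.sax_index} frame {frame}"
    endo = _polygon(slice_obj.endo[frame], where + " (endo)")
    epi = _polygon(slice_obj.epi[frame], where + " (epi)")
    n_endo = _pixel_count(endo, px)
    n_epi = _pixel_count(epi, px)
    return {"cavity_area": n_endo * px ** 2,
            "myocardial_area": max(n_epi - n_endo, 0) * px ** 2}


def select_ed_es_per_slice(cavity_areas) -> dict:
    """ED = argmax, ES = argmin of per-frame cavity area (earliest on ties)."""
    areas = np.asarray(cavity_areas, dtype=float)
    if areas.size < 2:
        raise ConfigurationError("per-slice frame selection needs >= 2 frames")
    return {"ed_frame": int(np.argmax(areas)), "es_frame": int(np.argmin(areas))}


def slice_summation(study: CineStudy, pixel_size_mm: float | None = None,
                    global_frames: bool = False) -> FunctionReport:
    """Simpson-style slice-summation function report from the SAX stack.

    ``global_frames=True`` switches from the per-slice ED/ES rule to a
    single globally selected frame pair (sensitivity analysis).
    """
    px = pixel_size_mm if pixel_size_mm is not None else study.pixel_size_mm
    sax = study.sax_slices()
    if not sax:
        raise ConfigurationError("slice summation needs a SAX stack")
    # contiguity check (a single slice is trivially contiguous)
    origins = np.array([s.plane.origin for s in sax])
    steps = np.linalg.norm(np.diff(origins, axis=0), axis=1)
    if np.any(np.abs(steps - study.slice_thickness_mm) > 1e-6):
        raise ConfigurationError(
            "standard analysis requires a contiguous SAX stack with uniform "
            f"spacing {study.slice_thickness_mm} mm; got steps {steps}")

    thick = study.slice_thickness_mm
    cav = np.zeros((len(sax), study.n_frames))
    myo = np.zeros_like(cav)
    used = []
    for i, s in enumerate(sax):
        if not any(len(c) >= 3 for c in s.endo):
            logger.warning("slice SAX/%s has no usable contours in any "
                           "frame; excluded", s.plane.sax_index)
            continue
        for f in range(study.n_frames):
            areas = rasterized_slice_areas(study, s, f, px)
            cav[i, f] = areas["cavity_area"]
            myo[i, f] = areas["myocardial_area"]
        used.append(i)
    if not used:
        raise ConfigurationError("no usable SAX slices")

    if global_frames:
        total = cav[used].sum(axis=0)
        ed = int(np.argmax(total))
        es = int(np.argmin(total))
        frames = [(ed, es)] * len(used)
    else:
        frames = [tuple(select_ed_es_per_slice(cav[i]).values()) for i in used]

    edv = sum(cav[i, ed] for i, (ed, _) in zip(used, frames)) * thick
    esv = sum(cav[i, es] for i, (_, es) in zip(used, frames)) * thick
    myo_ed = sum(myo[i, ed] for i, (ed, _) in zip(used, frames)) * thick
    myo_es = sum(myo[i, es] for i, (_, es) in zip(used, frames)) * thick
    return derive(edv, esv, 0.5 * (myo_ed + myo_es), method_label="standard")


def akinetic_fraction(model_ed: LVSurfaceModel, model_es: LVSurfaceModel,
                      base: MitralValvePlane,
                      tau_mm: float = AKINESIA_THRESHOLD_MM,
                      grid: tuple[int, int] = (64, 64)) -> float:
    """Percent of mid-wall area whose endocardial ED->ES excursion < tau.

    The two models must share the axis frame (the pipeline fits all frames
    with one frame geometry, so this holds by construction).
    """
    n_mu, n_th = grid
    mu = (np.arange(n_mu) + 0.5) / n_mu
    th = np.arange(n_th) * 2 * np.pi / n_th
    M, T = np.meshgrid(mu, th, indexing="ij")

    lam_ed = model_ed.radial_field("endo", M, T)
    lam_es = model_es.radial_field("endo", M, T)
    d, _, _ = model_ed.direction_field(M.ravel(), T.ravel())
    dnorm = np.linalg.norm(d, axis=-1).reshape(M.shape)
    excursion = np.abs(lam_es - lam_ed) * dnorm

    # mid-wall area element at ED
    lam_mid = 0.5 * (lam_ed + model_ed.radial_field("epi", M, T))
    mid = LVSurfaceModel(
        axis_origin=model_ed.axis_origin,
        axis_direction=model_ed.axis_direction,
        transverse_u=model_ed.transverse_u,
        transverse_v=model_ed.transverse_v,
        elongation=model_ed.elongation,
        coeffs_endo=0.5 * (model_ed.coeffs_endo + model_ed.coeffs_epi),
        coeffs_epi=model_ed.coeffs_epi,
        basis_order=model_ed.basis_order, _basis=model_ed._basis)
    S, S_m, S_t = mid.surface_derivatives("endo", M.ravel(), T.ravel())
    dA = np.linalg.norm(np.cross(S_m, S_t), axis=-1).reshape(M.shape)
    below = ((S - base.origin) @ base.normal).reshape(M.shape) >= 0

    denom = dA[below].sum()
    if denom == 0:
        raise ConfigurationError("base plane excludes the whole mid-wall")
    akin = below & (excursion < tau_mm)
    return float(100.0 * dA[akin].sum() / denom)


def infarct_size(source, tau_mm: float = AKINESIA_THRESHOLD_MM,
                 grid: tuple[int, int] = (64, 64)) -> float:
    """Infarct size (% of LV myocardium akinetic) from truth or fitted models.

    ``source`` is either a :class:`TruthModel` or a tuple
    ``(model_ed, model_es, base_plane)``.
    """
    if isinstance(source, TruthModel):
        return akinetic_fraction(source.frames[source.ed_frame],
                                 source.frames[source.es_frame],
                                 source.base_plane, tau_mm, grid)
    model_ed, model_es, base = source
    if model_es is None:
        raise ConfigurationError("end-systolic geometry is required")
    return akinetic_fraction(model_ed, model_es, base, tau_mm, grid)
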