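"""Deterministic slice-selection rules for the reduced acquisition protocols.

``reduce_six``: four SAX + two LAX — drop the extreme basal and apical LV
slices, keep alternate slices starting from the second-most-basal; if more
than four remain drop from the apical end, if fewer remain fill from the
apical end of the unselected interior slices.

``reduce_four``: two SAX + two LAX — one slice in the middle of the basal
half (position round(N/4)) and one in the middle of the apical half
(round(3N/4)), 1-based base->apex, ties rounded toward the base.

A slice counts as "within the LV" when its endocardial contour at
end-diastole is non-empty. Retained slices keep their planes and contour
data unchanged.
"""
from __future__ import annotations

from dataclasses import replace

from .errors import InsufficientSlicesError
from .study import SAX, CineStudy, StudySlice


def _lv_sax(study: CineStudy) -> list[StudySlice]:
    return [s for s in study.sax_slices() if len(s.endo[0]) >= 3]


def _subset(study: CineStudy, keep_sax: list[StudySlice]) -> CineStudy:
    keep_ids = {id(s) for s in keep_sax}
    slices = [s for s in study.slices
              if s.label != SAX or id(s) in keep_ids]
    return replace(study, slices=slices)


def six_slice_sax_positions(n: int) -> list[int]:
    """1-based LV-stack positions kept by the six-slice rule (4 of n)."""
    if n < 6:
        raise InsufficientSlicesError(
            f"six-slice protocol needs >= 6 LV SAX slices, got {n}")
    interior = list(range(2, n))             # drop most basal (1), apical (n)
    selected = interior[0::2]
    while len(selected) > 4:
        selected = selected[:-1]              # drop from the apical end
    if len(selected) < 4:
        remaining = [i for i in interior if i not in selected]
        # fill from the apical end of the remaining interior slices
        for idx in reversed(remaining):
            selected.append(idx)
            if len(selected) == 4:
                break
    return sorted(selected)


def four_slice_sax_positions(n: int) -> list[int]:
    """1-based LV-stack positions kept by the four-slice rule (2 of n)."""
    if n < 4:
        raise InsufficientSlicesError(
            f"four-slice protocol needs >= 4 LV SAX slices, got {n}")

    def round_toward_base(x: float) -> int:
        import math
        return int(math.ceil(x - 0.5))        # .5 rounds down (toward base)

    i1 = round_toward_base(n / 4)
    i2 = round_toward_base(3 * n / 4)
    return [max(i1, 1), min(i2, n)]


def reduce_six(study: CineStudy) -> CineStudy:
    """Six-slice protocol: 4 SAX + 2 LAX."""
    lv = _lv_sax(study)
    keep = six_slice_sax_positions(len(lv))
    return _subset(study, [lv[i - 1] for i in keep])


def reduce_four(study: CineStudy) -> CineStudy:
    """Four-slice protocol: 2 SAX + 2 LAX."""
    lv = _lv_sax(study)
    keep = four_slice_sax_positions(len(lv))
    return _subset(study, [lv[i - 1] for i in keep])


def slice_saving_fraction(n_standard_sax: int, protocol: str = "six") -> float:
    """Fractional reduction in acquired slices vs an n-slice SAX standard."""
    n_reduced = {"six": 6, "four": 4}[protocol]
    return (n_standard_sax - n_reduced) / n_standard_sax
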