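"""Global LV function parameters shared by both analysis paths.

Volumes in ul, mass in mg (myocardial density 1.05 mg/ul). The ejection
fraction is stored as a fraction and rendered as percent in reports.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

from .errors import ValidationError

DENSITY_G_PER_ML = 1.05


@dataclass(frozen=True)
class FunctionReport:
    edv_ul: float
    esv_ul: float
    sv_ul: float
    ef_fraction: float
    lvm_mg: float
    method_label: str
    infarct_pct: float | None = None
    density_g_per_ml: float = DENSITY_G_PER_ML

    def __post_init__(self):
        if abs(self.sv_ul - (self.edv_ul - self.esv_ul)) > 1e-9:
            raise ValidationError("SV must equal EDV - ESV")
        if not (0.0 <= self.ef_fraction <= 1.0):
            raise ValidationError(f"EF {self.ef_fraction} outside [0, 1]")
        if self.lvm_mg < 0:
            raise ValidationError("mass must be non-negative")

    @property
    def ef_pct(self) -> float:
        return 100.0 * self.ef_fraction

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ef_pct"] = self.ef_pct
        return d


def derive(edv_ul: float, esv_ul: float, myo_volume_ul: float,
           method_label: str = "", infarct_pct: float | None = None
           ) -> FunctionReport:
    """SV = EDV - ESV, EF = SV/EDV, LVM = 1.05 x myocardial volume."""
    if esv_ul < 0 or edv_ul < esv_ul:
        raise ValidationError(
            f"need EDV >= ESV >= 0, got EDV={edv_ul}, ESV={esv_ul} "
            "(caller must pass frame-selected values)")
    sv = edv_ul - esv_ul
    ef = sv / edv_ul if edv_ul > 0 else 0.0
    return FunctionReport(edv_ul=edv_ul, esv_ul=esv_ul, sv_ul=sv,
                          ef_fraction=ef,
                          lvm_mg=DENSITY_G_PER_ML * myo_volume_ul,
                          method_label=method_label, infarct_pct=infarct_pct)
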