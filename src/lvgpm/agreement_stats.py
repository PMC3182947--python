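"""Agreement and within-subject comparison statistics.

Bland-Altman agreement with limits defined literally as bias +- 2 SD of the
paired differences (not 1.96 SD), and one-way repeated-measures ANOVA from
explicit sums of squares with Bonferroni-corrected paired post-hoc tests.
Sphericity is assumed by default; a Greenhouse-Geisser correction is
available behind a flag.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import PairingError, ValidationError
from .metrics import FunctionReport

PARAMETERS = ("edv_ul", "esv_ul", "sv_ul", "ef_pct", "lvm_mg")


@dataclass(frozen=True)
class AgreementResult:
    bias: float
    sd_diff: float
    n: int

    @property
    def loa_low(self) -> float:
        return self.bias - 2.0 * self.sd_diff

    @property
    def loa_high(self) -> float:
        return self.bias + 2.0 * self.sd_diff

    def to_dict(self) -> dict:
        return {"bias": self.bias, "sd_diff": self.sd_diff, "n": self.n,
                "loa_low": self.loa_low, "loa_high": self.loa_high}


@dataclass
class RMAnovaResult:
    f_stat: float
    df_between: int
    df_error: int
    p_value: float
    posthoc: list[dict] = field(default_factory=list)


def bland_altman(method_a, method_b) -> AgreementResult:
    """Bias and +-2 SD limits of agreement of paired per-subject values."""
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise PairingError(
            f"paired vectors must have equal length, got {a.shape} vs "
            f"{b.shape}")
    if len(a) < 2:
        raise PairingError("agreement analysis needs >= 2 paired subjects")
    d = a - b
    return AgreementResult(bias=float(d.mean()),
                           sd_diff=float(d.std(ddof=1)), n=len(d))


def rm_anova(data, greenhouse_geisser: bool = False,
             method_names=None) -> RMAnovaResult:
    """One-way within-subject ANOVA on a subjects x methods matrix.

    Explicit sums of squares; for two methods F equals the squared paired-t
    statistic. Post-hoc: Bonferroni-corrected paired t-tests over all
    method pairs.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("need a complete (>=2 subjects) x (>=2 "
                              "methods) matrix")
    if not np.all(np.isfinite(X)):
        raise ValidationError("missing cells are not allowed (no imputation)")
    n, k = X.shape
    grand = X.mean()
    ss_methods = n * np.sum((X.mean(axis=0) - grand) ** 2)
    ss_subjects = k * np.sum((X.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_error = ss_total - ss_methods - ss_subjects
    df_b = k - 1
    df_e = (n - 1) * (k - 1)
    ms_methods = ss_methods / df_b
    ms_error = ss_error / df_e
    if ms_error <= 0:
        f = 0.0 if ms_methods <= 0 else np.inf
    else:
        f = ms_methods / ms_error

    eps = 1.0
    if greenhouse_geisser and k > 2:
        # Greenhouse-Geisser epsilon from the double-centered covariance
        S = np.cov(X, rowvar=False, ddof=1)
        Sc = S - S.mean(axis=0, keepdims=True) - \
            S.mean(axis=1, keepdims=True) + S.mean()
        eps = float(np.trace(Sc) ** 2 / ((k - 1) * np.sum(Sc ** 2)))
        eps = min(max(eps, 1.0 / (k - 1)), 1.0)
    p = float(sps.f.sf(f, df_b * eps, df_e * eps)) if np.isfinite(f) else 0.0
    if f == 0.0:
        p = 1.0

    names = list(method_names) if method_names is not None \
        else [f"m{j}" for j in range(k)]
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    posthoc = []
    for i, j in pairs:
        d = X[:, i] - X[:, j]
        if np.allclose(d, 0):
            p_raw = 1.0
        else:
            p_raw = float(sps.ttest_rel(X[:, i], X[:, j]).pvalue)
        posthoc.append({"method_pair": (names[i], names[j]),
                        "p_raw": p_raw,
                        "p_adjusted": min(1.0, p_raw * len(pairs))})
    return RMAnovaResult(f_stat=float(f), df_between=df_b, df_error=df_e,
                         p_value=p, posthoc=posthoc)


@dataclass
class ProtocolComparison:
    table: pd.DataFrame
    agreement: dict            # {(parameter, method): AgreementResult}
    anova: dict                # {parameter: RMAnovaResult}
    single_subject: bool = False


def compare_protocols(reports: dict[str, list[FunctionReport]],
                      reference: str = "standard") -> ProtocolComparison:
    """Study-level comparison table across methods.

    ``reports`` maps method label -> per-animal FunctionReports, aligned by
    animal across methods. Emits mean +- SD per method and reference-minus-
    method difference columns, Bland-Altman agreement vs the reference, and
    a repeated-measures ANOVA per parameter.
    """
    if reference not in reports:
        raise ValidationError(f"reference method {reference!r} missing")
    methods = list(reports)
    n_animals = {m: len(v) for m, v in reports.items()}
    if len(set(n_animals.values())) != 1:
        incomplete = sorted(set(n_animals.values()))
        raise ValidationError(
            f"methods carry different animal counts {n_animals}; "
            f"animal sets must align (counts seen: {incomplete})")
    n = next(iter(n_animals.values()))
    single = n == 1

    rows = []
    agreement: dict = {}
    anova: dict = {}
    for param in PARAMETERS:
        vals = {m: np.array([getattr(r, param) for r in reports[m]])
                for m in methods}
        row: dict = {"parameter": param}
        for m in methods:
            row[f"{m}_mean"] = vals[m].mean()
            row[f"{m}_sd"] = vals[m].std(ddof=1) if not single else np.nan
        for m in methods:
            if m == reference:
                continue
            d = vals[reference] - vals[m]
            row[f"{reference}-{m}_mean"] = d.mean()
            row[f"{reference}-{m}_sd"] = d.std(ddof=1) if not single \
                else np.nan
            if not single:
                agreement[(param, m)] = bland_altman(vals[reference],
                                                     vals[m])
        if not single:
            X = np.stack([vals[m] for m in methods], axis=1)
            anova[param] = rm_anova(X, method_names=methods)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("parameter")
    return ProtocolComparison(table=table, agreement=agreement, anova=anova,
                              single_subject=single)


def bland_altman_plot(method_a, method_b, ax=None, label_a: str = "A",
                      label_b: str = "B"):
    """Bland-Altman plot: solid bias line, dashed +-2 SD limits."""
    import matplotlib.pyplot as plt

    res = bland_altman(method_a, method_b)
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((a + b) / 2, a - b, color="k")
    ax.axhline(res.bias, color="k")
    for y in (res.loa_low, res.loa_high):
        ax.axhline(y, color="k", linestyle="--")
    ax.set_xlabel(f"mean of {label_a} and {label_b}")
    ax.set_ylabel(f"{label_a} - {label_b}")
    return ax, res
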