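"""Paired-comparison statistics for two-assay method agreement.

Implements the classic battery for comparing a candidate assay (CLIA) against
a reference (LC-MS/MS) on the same subjects:

* intraclass correlation from one-way ANOVA mean squares,
  ``ICC = (MSB - MSW) / (MSB + (k - 1) * MSW)`` with k = 2 methods;
* Bland–Altman limits of agreement, ``mean difference ± 1.96 × SD``;
* paired t-test on the differences;
* ordinary least squares of the reference on the candidate with 95%
  coefficient intervals;
* threshold cross-classification at a clinical cutoff (e.g. 20 ng/mL
  deficiency threshold) with agreement rate, Cohen's kappa, and a Wilson
  score interval on the discordant proportion;
* multi-threshold reclassification: how many subjects change diagnostic
  category depending on the method used.

Conventions: sample statistics use the n−1 denominator; values exactly at a
threshold classify as "≥" (sufficient); p-values are two-sided; the 1.96 in
the limits of agreement is a fixed constant while the Wilson z is a normal
quantile at a configurable level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .exceptions import (
    DegenerateStatisticError,
    InsufficientDataError,
    SingularDesignError,
)
from .io_model import Dataset, register_report


@dataclass(frozen=True)
class AnovaComponents:
    """One-way ANOVA mean squares behind the ICC: subjects are groups, the
    k methods are the repeated measures within each subject."""

    msb: float
    msw: float
    k: int = 2

    def __post_init__(self) -> None:
        if self.msb < 0 or self.msw < 0 or self.k < 2:
            raise DegenerateStatisticError(
                f"invalid ANOVA components msb={self.msb} msw={self.msw} k={self.k}"
            )


@register_report("bland_altman")
@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BlandAltmanResult":
        return cls(**d)


@register_report("regression")
@dataclass(frozen=True)
class RegressionFit:
    """OLS of the reference method on the candidate: lcms = slope·clia + intercept."""

    slope: float
    intercept: float
    r2: float
    adj_r2: float
    sse: float
    rmse: float
    slope_ci95: tuple[float, float]
    intercept_ci95: tuple[float, float]
    n: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["slope_ci95"] = list(self.slope_ci95)
        d["intercept_ci95"] = list(self.intercept_ci95)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionFit":
        d = dict(d)
        d["slope_ci95"] = tuple(d["slope_ci95"])
        d["intercept_ci95"] = tuple(d["intercept_ci95"])
        return cls(**d)

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


@register_report("crosstab")
@dataclass(frozen=True)
class CrossTabResult:
    """2×2 cross-classification at a threshold.

    First index: candidate (CLIA) ≥ / < threshold; second: reference
    (LC-MS/MS) ≥ / < threshold.  ``n_pn`` is CLIA ≥ t but LC-MS/MS < t.
    """

    threshold: float
    n_pp: int
    n_pn: int
    n_np: int
    n_nn: int
    agreement_rate: float
    kappa: float
    discordant: int
    discordant_wilson_ci: tuple[float, float]

    @property
    def n(self) -> int:
        return self.n_pp + self.n_pn + self.n_np + self.n_nn

    def to_dict(self) -> dict:
        d = asdict(self)
        d["discordant_wilson_ci"] = list(self.discordant_wilson_ci)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CrossTabResult":
        d = dict(d)
        d["discordant_wilson_ci"] = tuple(d["discordant_wilson_ci"])
        return cls(**d)


@register_report("reclassification")
@dataclass(frozen=True)
class ReclassificationResult:
    """Per-threshold cross-tabs plus the pooled any-threshold discordance."""

    per_threshold: tuple[CrossTabResult, ...]
    pooled_discordant: int
    n: int
    pooled_proportion: float
    pooled_wilson_ci: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "per_threshold": [c.to_dict() for c in self.per_threshold],
            "pooled_discordant": self.pooled_discordant,
            "n": self.n,
            "pooled_proportion": self.pooled_proportion,
            "pooled_wilson_ci": list(self.pooled_wilson_ci),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReclassificationResult":
        return cls(
            per_threshold=tuple(
                CrossTabResult.from_dict(c) for c in d["per_threshold"]
            ),
            pooled_discordant=d["pooled_discordant"],
            n=d["n"],
            pooled_proportion=d["pooled_proportion"],
            pooled_wilson_ci=tuple(d["pooled_wilson_ci"]),
        )


# ---------------------------------------------------------------------------


def icc_from_components(comp: AnovaComponents) -> float:
    """ICC = (MSB − MSW) / (MSB + (k−1)·MSW)."""
    denom = comp.msb + (comp.k - 1) * comp.msw
    if denom <= 0:
        raise DegenerateStatisticError("ICC undefined: MSB + (k-1)*MSW <= 0")
    return (comp.msb - comp.msw) / denom


def icc(data: Dataset) -> tuple[AnovaComponents, float]:
    """Intraclass correlation treating each subject's (clia, lcms) pair as
    k = 2 repeated measures of one quantity (one-way random-effects model)."""
    n = len(data)
    if n < 3:
        raise InsufficientDataError(f"ICC needs n >= 3, got {n}")
    x = np.array([[s.clia, s.lcms] for s in data], dtype=float)
    k = x.shape[1]
    subject_means = x.mean(axis=1)
    grand = x.mean()
    msb = k * np.sum((subject_means - grand) ** 2) / (n - 1)
    msw = np.sum((x - subject_means[:, None]) ** 2) / (n * (k - 1))
    comp = AnovaComponents(msb=float(msb), msw=float(msw), k=k)
    return comp, icc_from_components(comp)


def bland_altman(data: Dataset) -> BlandAltmanResult:
    n = len(data)
    if n < 2:
        raise InsufficientDataError(f"Bland-Altman needs n >= 2, got {n}")
    d = np.asarray(data.diffs, dtype=float)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_lower=mean - 1.96 * sd,
        loa_upper=mean + 1.96 * sd,
        n=n,
    )


def paired_t(data: Dataset) -> tuple[float, float]:
    """Two-sided paired t-test on lcms − clia (df = n − 1)."""
    n = len(data)
    if n < 2:
        raise InsufficientDataError(f"paired t-test needs n >= 2, got {n}")
    d = np.asarray(data.diffs, dtype=float)
    if d.std(ddof=1) == 0:
        raise DegenerateStatisticError("paired t-test undefined: zero variance")
    lcms = np.array([s.lcms for s in data])
    clia = np.array([s.clia for s in data])
    res = stats.ttest_rel(lcms, clia)
    return float(res.statistic), float(res.pvalue)


def comparison_regression(data: Dataset) -> RegressionFit:
    """OLS of the reference (lcms) on the candidate (clia), with intercept."""
    n = len(data)
    if n < 3:
        raise InsufficientDataError(f"regression needs n >= 3, got {n}")
    x = np.array([s.clia for s in data], dtype=float)
    y = np.array([s.lcms for s in data], dtype=float)
    if np.ptp(x) == 0:
        raise SingularDesignError("constant predictor: clia has zero range")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)  # rows: const, slope
    sse = float(fit.ssr)
    return RegressionFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        sse=sse,
        rmse=math.sqrt(sse / (n - 2)),
        slope_ci95=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci95=(float(ci[0][0]), float(ci[0][1])),
        n=n,
    )


def cohen_kappa(n_pp: int, n_pn: int, n_np: int, n_nn: int) -> float:
    """Chance-corrected agreement on a 2×2 table.

    κ = (p_o − p_e)/(1 − p_e) with p_e from the row×column marginal products.
    Degenerate marginals (p_e = 1) yield NaN with a warning so batch runs on
    extreme synthetic draws survive.
    """
    n = n_pp + n_pn + n_np + n_nn
    if n <= 0:
        raise DegenerateStatisticError("kappa undefined on an empty table")
    p_o = (n_pp + n_nn) / n
    row_p = (n_pp + n_pn) / n
    col_p = (n_pp + n_np) / n
    p_e = row_p * col_p + (1 - row_p) * (1 - col_p)
    if p_e == 1.0:
        warnings.warn("degenerate marginals: kappa undefined, returning NaN",
                      RuntimeWarning, stacklevel=2)
        return math.nan
    return (p_o - p_e) / (1 - p_e)


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise DegenerateStatisticError("Wilson interval undefined for n = 0")
    if not 0 <= successes <= n:
        raise DegenerateStatisticError(f"successes {successes} outside [0, {n}]")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    # the score interval's bounds are exactly 0 (resp. 1) at the extremes;
    # clamp away the round-off the closed-form evaluation leaves behind
    lo = 0.0 if successes == 0 else max(float(lo), 0.0)
    hi = 1.0 if successes == n else min(float(hi), 1.0)
    return float(lo), float(hi)


def threshold_crosstab(data: Dataset, threshold: float) -> CrossTabResult:
    """Cross-classify both assays at a clinical cutoff; ≥ threshold counts
    as positive (sufficient)."""
    n = len(data)
    if n < 1:
        raise InsufficientDataError("crosstab needs at least one sample")
    clia_pos = np.array([s.clia >= threshold for s in data])
    lcms_pos = np.array([s.lcms >= threshold for s in data])
    n_pp = int(np.sum(clia_pos & lcms_pos))
    n_pn = int(np.sum(clia_pos & ~lcms_pos))
    n_np = int(np.sum(~clia_pos & lcms_pos))
    n_nn = int(np.sum(~clia_pos & ~lcms_pos))
    discordant = n_pn + n_np
    return CrossTabResult(
        threshold=threshold,
        n_pp=n_pp, n_pn=n_pn, n_np=n_np, n_nn=n_nn,
        agreement_rate=(n_pp + n_nn) / n,
        kappa=cohen_kappa(n_pp, n_pn, n_np, n_nn),
        discordant=discordant,
        discordant_wilson_ci=wilson_ci(discordant, n),
    )


def reclassification(data: Dataset,
                     thresholds: tuple[float, ...] = (20.0, 30.0),
                     ) -> ReclassificationResult:
    """Per-threshold cross-tabs plus the pooled proportion of subjects that
    fall on different sides of ANY threshold under the two methods."""
    if not thresholds:
        raise DegenerateStatisticError("reclassification needs >= 1 threshold")
    if any(t <= 0 for t in thresholds):
        raise DegenerateStatisticError("thresholds must be positive")
    tabs = tuple(threshold_crosstab(data, t) for t in thresholds)
    n = len(data)
    pooled = sum(
        1 for s in data
        if any((s.clia >= t) != (s.lcms >= t) for t in thresholds)
    )
    return ReclassificationResult(
        per_threshold=tabs,
        pooled_discordant=pooled,
        n=n,
        pooled_proportion=pooled / n,
        pooled_wilson_ci=wilson_ci(pooled, n),
    )


@register_report("agreement_battery")
@dataclass(frozen=True)
class AgreementBattery:
    """The full agreement report emitted by the CLI in one shot."""

    anova: AnovaComponents
    icc: float
    bland_altman: BlandAltmanResult
    t_stat: float
    t_pvalue: float
    regression: RegressionFit
    reclassification: ReclassificationResult

    def to_dict(self) -> dict:
        return {
            "anova": asdict(self.anova),
            "icc": self.icc,
            "bland_altman": self.bland_altman.to_dict(),
            "t_stat": self.t_stat,
            "t_pvalue": self.t_pvalue,
            "regression": self.regression.to_dict(),
            "reclassification": self.reclassification.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgreementBattery":
        return cls(
            anova=AnovaComponents(**d["anova"]),
            icc=d["icc"],
            bland_altman=BlandAltmanResult.from_dict(d["bland_altman"]),
            t_stat=d["t_stat"],
            t_pvalue=d["t_pvalue"],
            regression=RegressionFit.from_dict(d["regression"]),
            reclassification=ReclassificationResult.from_dict(d["reclassification"]),
        )


def agreement_battery(data: Dataset,
                      thresholds: tuple[float, ...] = (20.0, 30.0),
                      ) -> AgreementBattery:
    """Run every agreement statistic on one dataset."""
    comp, icc_val = icc(data)
    t_stat, p = paired_t(data)
    return AgreementBattery(
        anova=comp,
        icc=icc_val,
        bland_altman=bland_altman(data),
        t_stat=t_stat,
        t_pvalue=p,
        regression=comparison_regression(data),
        reclassification=reclassification(data, thresholds),
    )
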