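"""Verification of a demographic difference pattern by relative risk.

The fuzzy model's hypothesis — that women aged 30–40 show larger
inter-method differences — is checked on an independent cohort: differences
are dichotomized into high/low at a threshold (the cohort mean by default),
subjects are split into an experimental group (women aged 30–40, boundaries
inclusive) and a control group (everyone else), and the relative risk of a
high difference is computed with a 95% CI from the log-RR normal
approximation

    exp( ln RR ± 1.96 * sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)) ).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import Callable

from .exceptions import DegenerateStatisticError, ValidationError
from .io_model import Dataset, PairedSample, Sex, register_report

HIGH = "high"
LOW = "low"


@register_report("relative_risk")
@dataclass(frozen=True)
class RRResult:
    """2×2 high/low-difference contingency by group, with RR and 95% CI."""

    n_exp_high: int
    n_exp_low: int
    n_ctrl_high: int
    n_ctrl_low: int
    p_exp: float
    p_ctrl: float
    rr: float
    ci95: tuple[float, float]
    threshold: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ci95"] = list(self.ci95)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RRResult":
        d = dict(d)
        d["ci95"] = tuple(d["ci95"])
        return cls(**d)

    def ci_excludes_one(self) -> bool:
        lo, hi = self.ci95
        return lo > 1.0 or hi < 1.0


def dichotomize_difference(data: Dataset,
                           threshold: float | str = "mean") -> list[str]:
    """Label each sample's difference high (diff ≥ threshold) or low.

    ``threshold="mean"`` resolves to the dataset's mean difference; the
    boundary value itself is high.
    """
    if len(data) == 0:
        raise ValidationError("cannot dichotomize an empty dataset")
    if isinstance(threshold, str):
        if threshold != "mean":
            raise ValidationError(f"unknown threshold policy {threshold!r}")
        threshold = sum(data.diffs) / len(data)
    return [HIGH if s.diff >= threshold else LOW for s in data]


def resolve_threshold(data: Dataset, threshold: float | str) -> float:
    if isinstance(threshold, str):
        return sum(data.diffs) / len(data)
    return float(threshold)


def default_experimental_predicate(sample: PairedSample) -> bool:
    """Women aged 30–40, both boundaries inclusive."""
    return sample.sex is Sex.female and 30.0 <= sample.age <= 40.0


def group_membership(sample: PairedSample,
                     rule: Callable[[PairedSample], bool] | None = None) -> str:
    """Assign a sample to the experimental or control group."""
    rule = rule or default_experimental_predicate
    return "experimental" if rule(sample) else "control"


def relative_risk(n_exp_high: int, n_exp_low: int,
                  n_ctrl_high: int, n_ctrl_low: int,
                  threshold: float = math.nan,
                  continuity_correction: bool = False) -> RRResult:
    """Relative risk of a high difference, experimental vs control.

    A zero cell makes the log-RR variance undefined; ``continuity_correction``
    adds 0.5 to every cell for the CI in that case (Haldane–Anscombe).
    """
    a, b, c, d = n_exp_high, n_exp_low, n_ctrl_high, n_ctrl_low
    if min(a, b, c, d) < 0:
        raise ValidationError("counts must be non-negative")
    n_exp, n_ctrl = a + b, c + d
    if n_exp == 0 or n_ctrl == 0:
        raise DegenerateStatisticError("both group totals must be positive")
    p_exp, p_ctrl = a / n_exp, c / n_ctrl

    if continuity_correction and (a == 0 or c == 0):
        a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a_, b_, c_, d_ = float(a), float(b), float(c), float(d)

    if c_ == 0:
        warnings.warn("zero high-count in control: RR infinite, CI undefined",
                      RuntimeWarning, stacklevel=2)
        return RRResult(a, b, c, d, p_exp, p_ctrl, math.inf,
                        (math.nan, math.nan), threshold)
    rr = (a_ / (a_ + b_)) / (c_ / (c_ + d_))
    if a_ == 0:
        warnings.warn("zero high-count in experimental group: CI undefined",
                      RuntimeWarning, stacklevel=2)
        return RRResult(a, b, c, d, p_exp, p_ctrl, rr,
                        (math.nan, math.nan), threshold)
    se = math.sqrt(1 / a_ - 1 / (a_ + b_) + 1 / c_ - 1 / (c_ + d_))
    log_rr = math.log(rr)
    ci = (math.exp(log_rr - 1.96 * se), math.exp(log_rr + 1.96 * se))
    return RRResult(a, b, c, d, p_exp, p_ctrl, rr, ci, threshold)


def verify_cohort(data: Dataset,
                  threshold: float | str = "mean",
                  rule: Callable[[PairedSample], bool] | None = None,
                  continuity_correction: bool = False) -> RRResult:
    """Full verification stage: dichotomize, group, compute relative risk."""
    thr = resolve_threshold(data, threshold)
    labels = dichotomize_difference(data, thr)
    counts = {"experimental": [0, 0], "control": [0, 0]}
    for sample, label in zip(data, labels):
        grp = group_membership(sample, rule)
        counts[grp][0 if label == HIGH else 1] += 1
    (a, b), (c, d) = counts["experimental"], counts["control"]
    return relative_risk(a, b, c, d, threshold=thr,
                         continuity_correction=continuity_correction)
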