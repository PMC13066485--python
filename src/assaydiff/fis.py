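"""Cluster-generated Takagi–Sugeno fuzzy inference system.

The model maps four inputs — candidate assay result (CLIA, ng/mL), reference
assay result (LC-MS/MS, ng/mL), sex (numerically encoded) and age (years) —
to the inter-method difference (ng/mL).  It is generated from data, not
hand-written:

1. the joint input–output matrix ``[clia, lcms, sex, age, diff]`` is min–max
   scaled to [0, 1] per dimension (years and ng/mL are incommensurate, so
   unscaled Euclidean distance would be dominated by one axis);
2. fuzzy C-means partitions the scaled joint space into ``n_clusters``
   clusters, each becoming one IF–THEN rule;
3. each rule's antecedent is a Gaussian membership function per input, with
   center the cluster-center projection and sigma the membership-weighted
   standard deviation of that input (floored at 0.05 of the scaled range so
   tight clusters cannot produce spike functions that kill firing strengths);
4. rule consequents are first-order (linear in the scaled inputs) and fitted
   by one global least-squares problem weighted by normalized firing
   strengths; a rank-deficient system falls back to constant consequents
   with a warning;
5. the observed difference range is stored so outputs can be reported on the
   normalized [0, 1] scale ``(value - min)/(max - min)``.

Inference: a query's firing strength per rule is the product of its Gaussian
memberships (computed in the log domain, so simultaneous underflow of all
rules can never divide by zero); the prediction is the firing-strength-
weighted convex combination of the rule consequent outputs.

Rule labels (low / medium / high) come from ranking cluster centers on each
input, which reproduces the usual human-readable rule phrasing
("IF clia is low AND ... THEN difference is ...") deterministically.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InfeasibleError, ValidationError
from .fcm import FCMConfig, MinMaxTransform, fcm_fit, scale_minmax
from .io_model import Dataset, Sex, SexEncoding, register_report

INPUT_NAMES = ("clia", "lcms", "sex", "age")
N_INPUTS = 4


@dataclass(frozen=True)
class GaussianMF:
    """Gaussian membership function exp(-(x-center)^2 / (2 sigma^2))."""

    center: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValidationError(f"sigma must be > 0, got {self.sigma}")

    def __call__(self, x: float) -> float:
        z = (x - self.center) / self.sigma
        return float(np.exp(-0.5 * z * z))

    def log_membership(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.center) / self.sigma
        return -0.5 * z * z


@dataclass(frozen=True)
class FuzzyRule:
    """One rule: an antecedent Gaussian per input plus a linear consequent
    ``a . x_scaled + b`` (coeffs ordered as the inputs, constant last)."""

    antecedents: tuple[GaussianMF, ...]
    consequent_coeffs: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.antecedents) != N_INPUTS:
            raise ValidationError(
                f"expected {N_INPUTS} antecedents, got {len(self.antecedents)}"
            )
        if len(self.consequent_coeffs) != N_INPUTS + 1:
            raise ValidationError("consequent needs one coeff per input plus a constant")


@register_report("sugeno_fis")
@dataclass
class SugenoFIS:
    """A fitted fuzzy inference system, self-contained and serializable."""

    input_names: tuple[str, ...]
    rules: tuple[FuzzyRule, ...]
    scaling: MinMaxTransform  # over the 5 joint dims (inputs + diff)
    output_norm: tuple[float, float]
    sex_encoding: SexEncoding
    training_meta: dict = field(default_factory=dict)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "input_names": list(self.input_names),
            "rules": [
                {
                    "antecedents": [
                        {"center": mf.center, "sigma": mf.sigma}
                        for mf in r.antecedents
                    ],
                    "consequent_coeffs": list(r.consequent_coeffs),
                    "labels": list(r.labels),
                }
                for r in self.rules
            ],
            "scaling": self.scaling.to_dict(),
            "output_norm": list(self.output_norm),
            "sex_encoding": {"male_code": self.sex_encoding.male_code,
                             "female_code": self.sex_encoding.female_code},
            "training_meta": self.training_meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SugenoFIS":
        rules = tuple(
            FuzzyRule(
                antecedents=tuple(GaussianMF(**mf) for mf in r["antecedents"]),
                consequent_coeffs=tuple(r["consequent_coeffs"]),
                labels=tuple(r["labels"]),
            )
            for r in d["rules"]
        )
        return cls(
            input_names=tuple(d["input_names"]),
            rules=rules,
            scaling=MinMaxTransform.from_dict(d["scaling"]),
            output_norm=tuple(d["output_norm"]),
            sex_encoding=SexEncoding(**d["sex_encoding"]),
            training_meta=d.get("training_meta", {}),
        )


@register_report("rule_weights")
@dataclass(frozen=True)
class RuleWeightSummary:
    """Per-rule normalized mean firing strength over a dataset (sums to 1)."""

    weights: tuple[float, ...]
    labels: tuple[tuple[str, ...], ...]

    def to_dict(self) -> dict:
        return {"weights": list(self.weights),
                "labels": [list(l) for l in self.labels]}

    @classmethod
    def from_dict(cls, d: dict) -> "RuleWeightSummary":
        return cls(weights=tuple(d["weights"]),
                   labels=tuple(tuple(l) for l in d["labels"]))


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

_SIGMA_FLOOR = 0.05  # fraction of the scaled (unit) range

_LEVELS3 = ("low", "medium", "high")


def _rank_labels(centers_dim: np.ndarray) -> list[str]:
    # rank cluster centers on one input; ties broken by cluster index
    order = np.argsort(centers_dim, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(order))
    k = len(centers_dim)
    if k == 1:
        return ["medium"]
    if k <= 3:
        names = _LEVELS3[:k] if k == 3 else ("low", "high")
        return [names[r] for r in ranks]
    return [f"level{r + 1}" for r in ranks]


def _joint_matrix(data: Dataset, enc: SexEncoding) -> np.ndarray:
    return np.array(
        [[s.clia, s.lcms, enc.encode(s.sex), s.age, s.diff] for s in data],
        dtype=float,
    )


def build_fis(data: Dataset,
              sex_encoding: SexEncoding = SexEncoding(),
              config: FCMConfig = FCMConfig(),
              linear: bool = True) -> SugenoFIS:
    """Generate a Sugeno FIS from paired-assay data via FCM clustering.

    ``linear=True`` fits first-order (linear) consequents; ``linear=False``
    fits a zero-order system whose consequents are constants.  The
    first-order system fits the training output better, but because the
    difference is arithmetically determined by the two assay inputs it
    reduces to that identity and carries no demographic information at the
    assay-consistency locus; the zero-order system is the one that exposes
    rule-level output levels (the low/medium/high reading of the rule
    table), so demographic profile analyses use it.
    """
    n = len(data)
    if n < 2 * config.n_clusters:
        raise InfeasibleError(
            f"need at least {2 * config.n_clusters} samples to generate "
            f"{config.n_clusters} rules, got {n}"
        )
    joint = _joint_matrix(data, sex_encoding)
    joint01, scaling = scale_minmax(joint)
    result = fcm_fit(joint01, config)

    u = result.memberships          # (n, K)
    centers = result.centers        # (K, 5)
    m = config.fuzzifier
    K = config.n_clusters

    # antecedents: per-input Gaussians around the cluster-center projections
    w_m = u ** m
    rules_mf: list[tuple[GaussianMF, ...]] = []
    for j in range(K):
        mfs = []
        for d in range(N_INPUTS):
            var = np.sum(w_m[:, j] * (joint01[:, d] - centers[j, d]) ** 2)
            var /= np.sum(w_m[:, j])
            sigma = max(float(np.sqrt(var)), _SIGMA_FLOOR)
            mfs.append(GaussianMF(center=float(centers[j, d]), sigma=sigma))
        rules_mf.append(tuple(mfs))

    labels_per_rule = _assign_labels(centers[:, :N_INPUTS])

    # consequents: one global least-squares over all rules simultaneously,
    # weighted by normalized firing strengths
    X01 = joint01[:, :N_INPUTS]
    y = joint[:, 4]
    wbar = _normalized_firing(rules_mf, X01)            # (n, K)
    if linear:
        phi = np.hstack([
            wbar[:, [j]] * np.hstack([X01, np.ones((n, 1))]) for j in range(K)
        ])                                              # (n, K*(d+1))
        # minimum-norm least squares: rank-deficient systems are generic here
        # (e.g. a single-sex cluster makes its sex column equal its constant
        # column), and the pseudo-inverse solution still minimizes the residual
        theta, _, _, _ = np.linalg.lstsq(phi, y, rcond=None)
    else:
        theta = None
    if theta is None or not np.all(np.isfinite(theta)):
        if linear:
            warnings.warn(
                "unusable consequent solution: falling back to constant consequents",
                RuntimeWarning, stacklevel=2,
            )
        theta_c, *_ = np.linalg.lstsq(wbar, y, rcond=None)
        coeffs = [
            (0.0,) * N_INPUTS + (float(theta_c[j]),) for j in range(K)
        ]
    else:
        coeffs = [
            tuple(float(v) for v in theta[j * (N_INPUTS + 1):(j + 1) * (N_INPUTS + 1)])
            for j in range(K)
        ]

    rules = tuple(
        FuzzyRule(antecedents=rules_mf[j],
                  consequent_coeffs=coeffs[j],
                  labels=labels_per_rule[j])
        for j in range(K)
    )
    diffs = joint[:, 4]
    meta = {
        "seed": config.seed,
        "n": n,
        "config_hash": hashlib.sha256(repr(config).encode()).hexdigest()[:16],
        "fcm_objective": result.objective,
        "fcm_converged": bool(result.converged),
    }
    return SugenoFIS(
        input_names=INPUT_NAMES,
        rules=rules,
        scaling=scaling,
        output_norm=(float(diffs.min()), float(diffs.max())),
        sex_encoding=sex_encoding,
        training_meta=meta,
    )


def _assign_labels(input_centers: np.ndarray) -> list[tuple[str, ...]]:
    K = input_centers.shape[0]
    per_dim = [_rank_labels(input_centers[:, d]) for d in range(N_INPUTS)]
    return [tuple(per_dim[d][j] for d in range(N_INPUTS)) for j in range(K)]


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _normalized_firing(rules_mf, X01: np.ndarray) -> np.ndarray:
    """Normalized firing strengths, computed in the log domain so that a
    query far from every rule still yields valid weights."""
    logs = np.stack(
        [
            sum(mfs[d].log_membership(X01[:, d]) for d in range(N_INPUTS))
            for mfs in rules_mf
        ],
        axis=1,
    )                                                   # (n, K)
    logs = logs - logs.max(axis=1, keepdims=True)
    w = np.exp(logs)
    return w / w.sum(axis=1, keepdims=True)


def _firing_strengths(fis: SugenoFIS, X01: np.ndarray) -> np.ndarray:
    """Raw firing strengths (products of memberships, in (0, 1])."""
    logs = np.stack(
        [
            sum(r.antecedents[d].log_membership(X01[:, d])
                for d in range(N_INPUTS))
            for r in fis.rules
        ],
        axis=1,
    )
    return np.exp(logs)


def _scale_inputs(fis: SugenoFIS, X: np.ndarray) -> np.ndarray:
    tf = fis.scaling
    return (np.asarray(X, dtype=float) - tf.mins[:N_INPUTS]) / tf.ranges[:N_INPUTS]


def predict_batch(fis: SugenoFIS, X: np.ndarray) -> np.ndarray:
    """Predict differences (ng/mL) for rows of ``[clia, lcms, sex_code, age]``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != N_INPUTS:
        raise ValidationError(f"expected {N_INPUTS} input columns, got {X.shape[1]}")
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite inputs")
    X01 = _scale_inputs(fis, X)
    wbar = _normalized_firing([r.antecedents for r in fis.rules], X01)
    design = np.hstack([X01, np.ones((X.shape[0], 1))])
    outputs = np.stack(
        [design @ np.asarray(r.consequent_coeffs) for r in fis.rules], axis=1
    )
    return np.sum(wbar * outputs, axis=1)


def fis_predict(fis: SugenoFIS, clia: float, lcms: float,
                sex: Sex | float, age: float) -> float:
    """Predict the inter-method difference (ng/mL) for one subject."""
    code = fis.sex_encoding.encode(sex) if isinstance(sex, Sex) else float(sex)
    return float(predict_batch(fis, np.array([[clia, lcms, code, age]]))[0])


def normalize_output(value: float, norm: tuple[float, float]) -> float:
    """Map an output onto [0, 1] over the observed difference range;
    out-of-range values clamp with a warning."""
    lo, hi = norm
    if not hi > lo:
        raise ValidationError(f"degenerate normalization range ({lo}, {hi})")
    z = (value - lo) / (hi - lo)
    if z < 0 or z > 1:
        warnings.warn(
            f"output {value} outside training range [{lo}, {hi}]; clamping",
            RuntimeWarning, stacklevel=2,
        )
        z = min(max(z, 0.0), 1.0)
    return float(z)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def rule_weight_summary(fis: SugenoFIS, data: Dataset) -> RuleWeightSummary:
    """Mean firing strength per rule over a dataset, normalized to sum to 1."""
    if len(data) == 0:
        raise ValidationError("rule_weight_summary needs a non-empty dataset")
    X = _joint_matrix(data, fis.sex_encoding)[:, :N_INPUTS]
    w = _firing_strengths(fis, _scale_inputs(fis, X))
    means = w.mean(axis=0)
    total = means.sum()
    if total == 0:  # all strengths underflowed; fall back to uniform
        means = np.ones_like(means)
        total = means.sum()
    return RuleWeightSummary(
        weights=tuple(float(v) for v in means / total),
        labels=tuple(r.labels for r in fis.rules),
    )


def _resolve_dim(fis: SugenoFIS, dim) -> int:
    if isinstance(dim, str):
        return fis.input_names.index(dim)
    return int(dim)


def rule_surface(fis: SugenoFIS, dim_a, dim_b, fixed: dict,
                 grid: int = 50) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized output over a 2-D grid spanning the observed ranges of two
    inputs, remaining inputs held at ``fixed`` (natural units).

    Returns ``(axis_a, axis_b, matrix)``; ``matrix[i, j]`` is the prediction
    at ``axis_a[i], axis_b[j]`` (rows = dim_a ascending).
    """
    ia, ib = _resolve_dim(fis, dim_a), _resolve_dim(fis, dim_b)
    if ia == ib:
        raise ValidationError("dim_a and dim_b must differ")
    if grid < 2:
        raise ValidationError("grid must be >= 2 per axis")
    fixed_idx = {}
    for key, val in fixed.items():
        idx = _resolve_dim(fis, key)
        if isinstance(val, Sex):
            val = fis.sex_encoding.encode(val)
        fixed_idx[idx] = float(val)
    missing = set(range(N_INPUTS)) - {ia, ib} - set(fixed_idx)
    if missing:
        names = [fis.input_names[i] for i in sorted(missing)]
        raise ValidationError(f"fixed values missing for inputs {names}")
    tf = fis.scaling
    axis_a = np.linspace(tf.mins[ia], tf.maxs[ia], grid)
    axis_b = np.linspace(tf.mins[ib], tf.maxs[ib], grid)
    A, B = np.meshgrid(axis_a, axis_b, indexing="ij")
    X = np.empty((grid * grid, N_INPUTS))
    for idx, val in fixed_idx.items():
        X[:, idx] = val
    X[:, ia] = A.ravel()
    X[:, ib] = B.ravel()
    preds = predict_batch(fis, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        normed = np.array([normalize_output(p, fis.output_norm) for p in preds])
    return axis_a, axis_b, normed.reshape(grid, grid)


def age_profile(fis: SugenoFIS, sex: Sex, ages,
                assay_reference: tuple[float, float] = (20.0, 20.0)
                ) -> list[float]:
    """Normalized FIS output along age at fixed sex.

    The two assay inputs sit on their consistency locus by default — both
    methods reading the 20 ng/mL deficiency threshold — so the profile
    isolates the demographic contribution to the predicted difference.
    """
    ages = list(ages)
    if not ages:
        raise ValidationError("ages must be non-empty")
    clia_ref, lcms_ref = assay_reference
    code = fis.sex_encoding.encode(sex)
    X = np.array([[clia_ref, lcms_ref, code, a] for a in ages], dtype=float)
    preds = predict_batch(fis, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return [normalize_output(p, fis.output_norm) for p in preds]
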