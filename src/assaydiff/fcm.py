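"""Fuzzy C-means clustering.

Minimizes the weighted within-cluster scatter

    J_m = sum_i sum_j mu_ij^m * ||x_i - c_j||^2

by alternating the closed-form updates

    mu_ij = 1 / sum_k (||x_i - c_j|| / ||x_i - c_k||)^(2/(m-1))
    c_j   = sum_i mu_ij^m x_i / sum_i mu_ij^m

until the objective change drops below ``tol`` or ``max_iter`` is reached.
The fuzzifier m > 1 controls cluster overlap (m -> 1 approaches hard k-means
assignments).  Initialization is a seeded random membership matrix with
normalized rows; ``n_restarts`` independent starts are run and the best
objective kept, guarding against local minima.

This optimizer is unit-agnostic: it clusters whatever matrix it is given.
Callers mixing incommensurate axes (years vs ng/mL) should min–max scale
first — see :func:`scale_minmax` — as the fuzzy-model builder does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InfeasibleError, ValidationError


@dataclass(frozen=True)
class FCMConfig:
    """Clustering controls; defaults follow common biomedical practice
    (3 clusters, fuzzifier 2)."""

    n_clusters: int = 3
    fuzzifier: float = 2.0
    tol: float = 1e-6
    max_iter: int = 300
    seed: int = 0
    n_restarts: int = 5

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be >= 1")
        if self.fuzzifier <= 1:
            raise ValidationError("fuzzifier must be > 1")
        if self.tol <= 0 or self.max_iter < 1 or self.n_restarts < 1:
            raise ValidationError("tol, max_iter, n_restarts must be positive")


@dataclass(frozen=True)
class FCMResult:
    """Fitted clusters: centers (N×d), memberships (D×N, rows sum to 1),
    and the per-iteration objective trace of the winning restart."""

    centers: np.ndarray
    memberships: np.ndarray
    objective_trace: tuple[float, ...]
    converged: bool
    iterations: int

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]


@dataclass
class MinMaxTransform:
    """Per-dimension affine map of observed data onto [0, 1], invertible.

    Zero-range dimensions map to a constant 0 (offset only), so degenerate
    axes — e.g. a single-sex cohort — cannot blow up the scaling.
    """

    mins: np.ndarray
    maxs: np.ndarray
    ranges: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        r = self.maxs - self.mins
        self.ranges = np.where(r > 0, r, 1.0)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mins) / self.ranges

    def inverse(self, X01: np.ndarray) -> np.ndarray:
        return np.asarray(X01, dtype=float) * self.ranges + self.mins

    def to_dict(self) -> dict:
        return {"mins": self.mins.tolist(), "maxs": self.maxs.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxTransform":
        return cls(mins=np.array(d["mins"]), maxs=np.array(d["maxs"]))


def scale_minmax(X: np.ndarray) -> tuple[np.ndarray, MinMaxTransform]:
    """Min–max scale each column of X to [0, 1]; returns the scaled matrix
    and the stored transform for later inversion."""
    X = np.asarray(X, dtype=float)
    tf = MinMaxTransform(mins=X.min(axis=0), maxs=X.max(axis=0))
    return tf.transform(X), tf


def fcm_objective(X: np.ndarray, centers: np.ndarray,
                  memberships: np.ndarray, m: float) -> float:
    """The clustering objective J_m, exactly as the double sum; pure function
    usable as an audit of any fitted state."""
    X = np.asarray(X, dtype=float)
    centers = np.asarray(centers, dtype=float)
    memberships = np.asarray(memberships, dtype=float)
    if X.ndim != 2 or centers.ndim != 2 or memberships.ndim != 2:
        raise ValidationError("X, centers, memberships must be 2-D")
    if (memberships.shape != (X.shape[0], centers.shape[0])
            or X.shape[1] != centers.shape[1]):
        raise ValidationError(
            f"shape mismatch: X {X.shape}, centers {centers.shape}, "
            f"memberships {memberships.shape}"
        )
    d2 = _sq_dists(X, centers)
    return float(np.sum(memberships ** m * d2))


def _sq_dists(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - centers[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def _memberships_from_centers(X: np.ndarray, centers: np.ndarray,
                              m: float) -> np.ndarray:
    d2 = _sq_dists(X, centers)
    coincident = d2 <= 0
    power = 1.0 / (m - 1.0)
    # normalize by each point's nearest center before exponentiating:
    # ratios are >= 1 so small fuzzifiers cannot overflow
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = d2 / d2.min(axis=1, keepdims=True)
        inv = ratio ** -power
        u = inv / inv.sum(axis=1, keepdims=True)
    # a point sitting exactly on a center gets full membership there
    # (split evenly across coincident centers)
    hit = coincident.any(axis=1)
    if hit.any():
        u[hit] = coincident[hit] / coincident[hit].sum(axis=1, keepdims=True)
    return u


def _centers_from_memberships(X: np.ndarray, u: np.ndarray,
                              m: float) -> np.ndarray:
    w = u ** m
    return (w.T @ X) / w.sum(axis=0)[:, None]


def fcm_fit(X: np.ndarray, config: FCMConfig) -> FCMResult:
    """Cluster the rows of X; returns the best of ``config.n_restarts``
    seeded alternating-optimization runs."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValidationError("fcm_fit: input contains non-finite values")
    D = X.shape[0]
    if D < config.n_clusters:
        raise InfeasibleError(
            f"cannot form {config.n_clusters} clusters from {D} points"
        )
    rng = np.random.default_rng(config.seed)
    best: FCMResult | None = None
    for _ in range(config.n_restarts):
        result = _fcm_single(X, config, rng)
        if best is None or result.objective < best.objective:
            best = result
    assert best is not None
    return best


def _fcm_single(X: np.ndarray, config: FCMConfig,
                rng: np.random.Generator) -> FCMResult:
    D = X.shape[0]
    m = config.fuzzifier
    u = rng.random((D, config.n_clusters))
    u /= u.sum(axis=1, keepdims=True)
    trace: list[float] = []
    converged = False
    for it in range(1, config.max_iter + 1):
        centers = _centers_from_memberships(X, u, m)
        u = _memberships_from_centers(X, centers, m)
        trace.append(fcm_objective(X, centers, u, m))
        if len(trace) > 1 and abs(trace[-2] - trace[-1]) < config.tol:
            converged = True
            break
    return FCMResult(
        centers=centers,
        memberships=u,
        objective_trace=tuple(trace),
        converged=converged,
        iterations=len(trace),
    )
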