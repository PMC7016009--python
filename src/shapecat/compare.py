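"""Comparing RDMs: Spearman and partial Spearman rank correlation with
label-permutation significance testing.

RDMs are compared on their vectorised upper triangles by Spearman rank
correlation (second-order isomorphism: shared similarity structure, not
linear correspondence). When two model RDMs are themselves correlated —
e.g. behavioural shape and category models built from the same stimuli —
partial Spearman correlation removes the shared part: all vectors are
rank-transformed, the controls are regressed out of both sides (with an
intercept), and the residuals are correlated.

Significance is assessed non-parametrically by permuting the condition
labels of the second RDM (rows and columns jointly) and recomputing the
statistic, giving a one-sided p-value with +1 smoothing,
``p = (1 + #{null ≥ observed}) / (1 + n_perm)``, and an empirical
(1 − alpha) null quantile as the significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .exceptions import (
    DegeneratePartialError,
    UndefinedCorrelationError,
    ValidationError,
)
from .rdm import RDM, vectorize

RESIDUAL_VAR_TOL = 1e-12


@dataclass(frozen=True)
class RDMComparison:
    """A (partial) Spearman rank correlation between two RDMs."""

    rho: float
    method: str  # "plain" | "partial"
    control_tags: tuple[str, ...] = ()
    n_pairs: int = 0

    def __post_init__(self):
        if not (-1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12):
            raise ValidationError(f"|rho| must be ≤ 1, got {self.rho}")
        if self.method == "partial" and not self.control_tags:
            raise ValidationError("partial comparison requires control tags")


@dataclass(frozen=True)
class PermutationResult:
    """Observed rho, its permutation null, p-value and alpha-level threshold."""

    observed_rho: float
    null_rhos: np.ndarray
    p_value: float
    alpha: float
    threshold_rho: float
    seed: int
    method: str = "plain"

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    @property
    def n_perm(self) -> int:
        return len(self.null_rhos)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0.0 or ny == 0.0:
        raise UndefinedCorrelationError("correlation of a constant vector is undefined")
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def _ranked_triu(rdm: RDM) -> np.ndarray:
    return rankdata(vectorize(rdm).values)


def _spearman_vec(ra: np.ndarray, rb: np.ndarray) -> float:
    return _pearson(ra, rb)


def _partial_vec(ra: np.ndarray, rb: np.ndarray, rcs: np.ndarray) -> float:
    """Partial Pearson of pre-ranked vectors given pre-ranked controls.

    Residualises ``ra`` and ``rb`` on [1, controls] by least squares and
    correlates the residuals.
    """
    n = len(ra)
    X = np.column_stack([np.ones(n), rcs.T])
    coef_a, *_ = np.linalg.lstsq(X, ra, rcond=None)
    coef_b, *_ = np.linalg.lstsq(X, rb, rcond=None)
    res_a = ra - X @ coef_a
    res_b = rb - X @ coef_b
    va = res_a @ res_a / n
    vb = res_b @ res_b / n
    if va < RESIDUAL_VAR_TOL or vb < RESIDUAL_VAR_TOL:
        raise DegeneratePartialError(
            "control RDM is (near-)collinear with a compared RDM: residual "
            f"variance {min(va, vb):.3g} below {RESIDUAL_VAR_TOL:g}"
        )
    return float(np.clip(res_a @ res_b / np.sqrt((res_a @ res_a) * (res_b @ res_b)),
                         -1.0, 1.0))


def spearman_rdm(a: RDM, b: RDM) -> RDMComparison:
    """Spearman rank correlation between the upper triangles of two RDMs.

    Ties receive average ranks. The RDMs must share condition ids and order.
    """
    a.require_aligned(b)
    ra, rb = _ranked_triu(a), _ranked_triu(b)
    return RDMComparison(rho=_spearman_vec(ra, rb), method="plain", n_pairs=len(ra))


def partial_spearman_rdm(a: RDM, b: RDM, controls: list[RDM] | tuple[RDM, ...],
                         control_tags: tuple[str, ...] | None = None) -> RDMComparison:
    """Partial Spearman correlation of ``a`` and ``b`` given control RDMs.

    Rank-transform first, then partial out the controls (rank-then-partial,
    the common RSA order of operations).
    """
    if len(controls) < 1:
        raise ValidationError("partial correlation needs at least one control RDM")
    for c in controls:
        a.require_aligned(c)
    a.require_aligned(b)
    ra, rb = _ranked_triu(a), _ranked_triu(b)
    rcs = np.vstack([_ranked_triu(c) for c in controls])
    if control_tags is None:
        control_tags = tuple(c.metric_tag for c in controls)
    rho = _partial_vec(ra, rb, rcs)
    return RDMComparison(rho=rho, method="partial",
                         control_tags=tuple(control_tags), n_pairs=len(ra))


def _rho(a: RDM, b: RDM, controls) -> float:
    if controls:
        return partial_spearman_rdm(a, b, controls).rho
    return spearman_rdm(a, b).rho


def permutation_test(a: RDM, b: RDM, n_perm: int = 1000, seed: int = 0,
                     controls: list[RDM] | None = None,
                     alpha: float = 0.05) -> PermutationResult:
    """One-sided label-permutation test of (partial) Spearman correspondence.

    Each permutation jointly relabels the rows and columns of ``b`` by a
    uniformly random permutation of its conditions, then recomputes the
    (partial) Spearman rho against the unpermuted ``a`` (controls, if any,
    stay fixed). Identical seeds yield identical null distributions.
    """
    if n_perm < 1:
        raise ValidationError(f"n_perm must be ≥ 1, got {n_perm}")
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    a.require_aligned(b)
    controls = list(controls) if controls else []
    observed = _rho(a, b, controls)
    rng = np.random.default_rng(seed)
    n = a.n_conditions
    ra = _ranked_triu(a)
    rcs = np.vstack([_ranked_triu(c) for c in controls]) if controls else None
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        bp = b.values[np.ix_(perm, perm)]
        iu, ju = np.triu_indices(n, k=1)
        rbp = rankdata(bp[iu, ju])
        null[k] = (_partial_vec(ra, rbp, rcs) if rcs is not None
                   else _spearman_vec(ra, rbp))
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    threshold = float(np.quantile(null, 1.0 - alpha))
    return PermutationResult(
        observed_rho=observed, null_rhos=null, p_value=float(p),
        alpha=alpha, threshold_rho=threshold, seed=seed,
        method="partial" if controls else "plain",
    )


def comparison_record(result: PermutationResult, *, controls: tuple[str, ...] = (),
                      extra: dict | None = None) -> dict:
    """Flat JSON-serialisable record for a permutation-tested comparison."""
    rec = {
        "rho": result.observed_rho,
        "method": result.method,
        "controls": list(controls),
        "p_value": result.p_value,
        "alpha": result.alpha,
        "threshold_rho": result.threshold_rho,
        "n_perm": result.n_perm,
        "seed": result.seed,
        "significant": bool(result.significant),
    }
    if extra:
        rec.update(extra)
    return rec
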