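"""Representational dissimilarity matrices (RDMs).

An RDM summarises a representation — a conditions × units activation or voxel
pattern matrix — as the matrix of pairwise pattern dissimilarities, here
1 − Pearson correlation across units. Binary design-model RDMs (0 = same
factor level, 1 = different) provide the shape and category reference models
that measured RDMs are compared against.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .design import StimulusDesign
from .exceptions import (
    AlignmentError,
    DegenerateModelError,
    UndefinedCorrelationError,
    ValidationError,
)

SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class PatternMatrix:
    """Conditions × units activation patterns for one layer or one subject/ROI.

    ``values[i]`` is the response pattern of condition ``conditions[i]``
    across measurement units (network nodes or voxels). ``source_tag``
    records provenance (layer name, subject+ROI) verbatim.
    """

    conditions: tuple[str, ...]
    values: np.ndarray
    source_tag: str = ""

    def __init__(self, conditions: Sequence[str], values: np.ndarray, source_tag: str = ""):
        values = np.asarray(values, dtype=float)
        object.__setattr__(self, "conditions", tuple(str(c) for c in conditions))
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "source_tag", str(source_tag))
        if values.ndim != 2:
            raise ValidationError(f"pattern values must be 2-D, got shape {values.shape}")
        if values.shape[0] != len(self.conditions):
            raise ValidationError(
                f"{len(self.conditions)} condition labels for {values.shape[0]} rows"
            )
        if len(set(self.conditions)) != len(self.conditions):
            raise ValidationError("duplicate condition ids in pattern matrix")
        if values.shape[1] < 2:
            raise ValidationError(
                f"need at least 2 units per pattern, got {values.shape[1]}"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError("pattern matrix contains non-finite values")

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def zero_variance_rows(self) -> list[str]:
        """Condition ids whose pattern is constant (Pearson undefined)."""
        sd = self.values.std(axis=1)
        return [c for c, s in zip(self.conditions, sd) if s == 0.0]


@dataclass(frozen=True)
class RDM:
    """A symmetric N × N dissimilarity matrix with a zero diagonal."""

    conditions: tuple[str, ...]
    values: np.ndarray
    metric_tag: str = "external"

    def __init__(self, conditions: Sequence[str], values: np.ndarray,
                 metric_tag: str = "external"):
        values = np.asarray(values, dtype=float)
        object.__setattr__(self, "conditions", tuple(str(c) for c in conditions))
        object.__setattr__(self, "metric_tag", str(metric_tag))
        n = len(self.conditions)
        if values.shape != (n, n):
            raise ValidationError(
                f"RDM values must be {n}×{n} to match conditions, got {values.shape}"
            )
        asym = np.abs(values - values.T).max(initial=0.0)
        if asym > SYMMETRY_TOL:
            raise ValidationError(
                f"RDM asymmetric beyond tolerance ({asym:.3g} > {SYMMETRY_TOL:g})"
            )
        values = (values + values.T) / 2.0
        if np.abs(np.diag(values)).max(initial=0.0) > SYMMETRY_TOL:
            raise ValidationError("RDM diagonal must be zero")
        np.fill_diagonal(values, 0.0)
        values.flags.writeable = False
        object.__setattr__(self, "values", values)
        if metric_tag == "one_minus_pearson":
            lo, hi = values.min(), values.max()
            if lo < -1e-9 or hi > 2 + 1e-9:
                raise ValidationError(
                    f"1−Pearson dissimilarities must lie in [0, 2], got [{lo}, {hi}]"
                )

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def aligned_with(self, other: "RDM") -> bool:
        return self.conditions == other.conditions

    def require_aligned(self, other: "RDM") -> None:
        if not self.aligned_with(other):
            raise AlignmentError(
                "RDMs are not aligned: condition sets/order differ "
                f"({self.conditions[:3]}... vs {other.conditions[:3]}...)"
            )

    def permuted(self, order: Sequence[int]) -> "RDM":
        """RDM with conditions (rows and columns jointly) reordered by ``order``."""
        idx = np.asarray(order)
        return RDM(
            [self.conditions[i] for i in idx],
            self.values[np.ix_(idx, idx)],
            metric_tag=self.metric_tag,
        )

    def relabelled(self, conditions: Sequence[str]) -> "RDM":
        return dataclasses.replace(self, conditions=tuple(conditions))


@dataclass(frozen=True)
class RDMVector:
    """Strict upper triangle of an RDM in row-major pair order."""

    pair_index: tuple[tuple[int, int], ...]
    values: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.values)


def _pearson_rows(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    r = (xc @ xc.T) / np.outer(norms, norms)
    return np.clip(r, -1.0, 1.0)


def compute_rdm(patterns: PatternMatrix) -> RDM:
    """Correlation-distance RDM: entry (i, j) = 1 − Pearson r(row i, row j).

    Raises
    ------
    UndefinedCorrelationError
        If any condition's pattern has zero variance across units.
    """
    bad = patterns.zero_variance_rows()
    if bad:
        raise UndefinedCorrelationError(
            f"zero-variance pattern rows (Pearson undefined) for conditions: {bad}"
        )
    d = 1.0 - _pearson_rows(patterns.values)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return RDM(patterns.conditions, d, metric_tag="one_minus_pearson")


def compute_rdm_spearman(patterns: PatternMatrix) -> RDM:
    """Variant dissimilarity 1 − Spearman r; off the default path."""
    from scipy.stats import rankdata

    bad = patterns.zero_variance_rows()
    if bad:
        raise UndefinedCorrelationError(
            f"zero-variance pattern rows for conditions: {bad}"
        )
    ranked = np.apply_along_axis(rankdata, 1, patterns.values)
    d = 1.0 - _pearson_rows(ranked)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return RDM(patterns.conditions, d, metric_tag="one_minus_pearson")


def model_rdm(design: StimulusDesign, factor: str) -> RDM:
    """Binary design-model RDM: 0 where two conditions share the level of
    ``factor``, 1 otherwise."""
    labels = design.labels(factor)
    if len(set(labels)) < 2:
        raise DegenerateModelError(f"factor {factor!r} has a single level")
    lab = np.asarray(labels)
    d = (lab[:, None] != lab[None, :]).astype(float)
    return RDM(design.condition_ids, d, metric_tag="model_binary")


def triu_pairs(n: int) -> tuple[tuple[int, int], ...]:
    iu, ju = np.triu_indices(n, k=1)
    return tuple(zip(iu.tolist(), ju.tolist()))


def vectorize(rdm: RDM) -> RDMVector:
    """Extract the strict upper triangle, row-major, length N(N−1)/2."""
    n = rdm.n_conditions
    iu, ju = np.triu_indices(n, k=1)
    return RDMVector(pair_index=triu_pairs(n), values=rdm.values[iu, ju].copy())


def devectorize(vec: RDMVector | np.ndarray, conditions: Sequence[str],
                metric_tag: str = "external") -> RDM:
    """Inverse of :func:`vectorize` given the condition labels."""
    v = vec.values if isinstance(vec, RDMVector) else np.asarray(vec, dtype=float)
    n = len(conditions)
    if len(v) != n * (n - 1) // 2:
        raise ValidationError(
            f"vector length {len(v)} does not match {n} conditions "
            f"(expected {n * (n - 1) // 2})"
        )
    m = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    m[iu, ju] = v
    m = m + m.T
    return RDM(conditions, m, metric_tag=metric_tag)


class RDMTransformer(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer from pattern matrices to RDM values.

    ``transform`` maps a conditions × units array to its N × N correlation-
    distance matrix; :meth:`transform_rdm` maps a :class:`PatternMatrix`
    to an :class:`RDM` object carrying labels. The transformer is stateless
    (``fit`` only records dimensions) but follows the estimator API so it
    composes with sklearn pipelines.

    Parameters
    ----------
    dissimilarity : {'pearson', 'spearman'}
        Correlation used in ``1 − r``. Pearson is the RSA convention.
    """

    def __init__(self, dissimilarity: str = "pearson"):
        self.dissimilarity = dissimilarity

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValidationError("X must be conditions × units with ≥ 2 units")
        self.n_conditions_ = X.shape[0]
        self.n_units_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        if self.dissimilarity not in ("pearson", "spearman"):
            raise ValidationError(
                f"unknown dissimilarity {self.dissimilarity!r}"
            )
        pm = PatternMatrix([f"c{i}" for i in range(np.asarray(X).shape[0])], X)
        fn = compute_rdm if self.dissimilarity == "pearson" else compute_rdm_spearman
        return fn(pm).values

    def transform_rdm(self, patterns: PatternMatrix) -> RDM:
        fn = compute_rdm if self.dissimilarity == "pearson" else compute_rdm_spearman
        return fn(patterns)
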