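"""Stimulus-set orthogonality audit: GIST descriptors + LDA cross-decoding.

A stimulus set that claims to dissociate shape from category must not leak
category information through low-level image statistics. The audit computes
GIST descriptors — energies of a bank of oriented band-pass (Gabor-type)
filters pooled over a coarse spatial grid — and asks a linear discriminant
classifier to predict shape or category from them under leave-one-level-out
cross-validation: to predict category, the classifier must generalise across
held-out shape levels (and vice versa), so any accuracy above chance reflects
genuine low-level covariation rather than memorised exemplars.

The filter bank is built directly in the frequency domain: each filter is the
product of a log-Gaussian radial profile centred on one of ``n_scales``
spatial frequencies and a Gaussian angular profile centred on one of
``n_orientations`` directions, restricted to a half-plane so the complex
modulus of the filtered image is a local-energy (quadrature) measure. Filters
have no DC response, so a constant image yields an all-zero descriptor.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import binomtest
from skimage.transform import resize
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .design import StimulusDesign
from .exceptions import DesignError, InsufficientDataError, ValidationError

#: highest filter centre frequency (cycles/pixel); scales descend by sqrt(2)
_F_MAX = 0.32
_SCALE_STEP = math.sqrt(2.0)


@dataclass(frozen=True)
class GistConfig:
    """Parameters of the GIST descriptor.

    The descriptor length is ``n_scales * n_orientations * grid**2``
    (default 8 × 8 × 16 = 1024).
    """

    n_scales: int = 8
    n_orientations: int = 8
    grid: int = 4
    image_side: int = 256
    prefilter: bool = False

    def __post_init__(self):
        for name in ("n_scales", "n_orientations", "grid", "image_side"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")

    @property
    def descriptor_length(self) -> int:
        return self.n_scales * self.n_orientations * self.grid ** 2


@lru_cache(maxsize=8)
def _filter_bank(n_scales: int, n_orientations: int, side: int) -> np.ndarray:
    """Frequency-domain transfer functions, shape (n_scales, n_orient, side, side)."""
    fy = np.fft.fftfreq(side)[:, None]
    fx = np.fft.fftfreq(side)[None, :]
    f = np.hypot(fx, fy)
    theta = np.arctan2(fy, fx)
    # the unpaired Nyquist row/column of an even-size grid breaks exact
    # rotation covariance of the bank; exclude it from every filter
    nyquist = (np.abs(fx) >= 0.5 - 1e-12) | (np.abs(fy) >= 0.5 - 1e-12)
    logf = np.log(np.where(f > 0, f, 1.0))
    sigma_r = 0.55  # radial bandwidth in log-frequency units (~0.8 octave)
    sigma_t = math.pi / n_orientations  # angular bandwidth, overlapping lobes
    bank = np.empty((n_scales, n_orientations, side, side))
    for s in range(n_scales):
        f0 = _F_MAX / _SCALE_STEP ** s
        radial = np.exp(-((logf - math.log(f0)) ** 2) / (2 * sigma_r ** 2))
        radial[f == 0] = 0.0  # zero-mean filters: no DC response
        radial[nyquist] = 0.0
        for o in range(n_orientations):
            theta0 = o * math.pi / n_orientations
            dt = np.angle(np.exp(1j * (theta - theta0)))  # wrapped to (−π, π]
            angular = np.exp(-(dt ** 2) / (2 * sigma_t ** 2))  # one-sided lobe
            bank[s, o] = radial * angular
    return bank


def _prepare_image(image: np.ndarray, config: GistConfig) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValidationError(
            f"expected a non-empty single-channel 2-D image, got shape {img.shape}"
        )
    side = config.image_side
    if img.shape != (side, side):
        img = resize(img, (side, side), anti_aliasing=True, mode="reflect")
    if config.prefilter:
        # local contrast normalisation: subtract a heavy low-pass, divide by
        # local energy (Oliva–Torralba style whitening)
        from scipy.ndimage import gaussian_filter

        low = gaussian_filter(img, sigma=side / 32)
        img = img - low
        local = np.sqrt(gaussian_filter(img ** 2, sigma=side / 32))
        img = img / (local.mean() + local + 1e-12)
    return img


def _pool_grid(energy: np.ndarray, grid: int) -> np.ndarray:
    """Average within each cell of a grid × grid partition, row-major."""
    side = energy.shape[0]
    edges = np.linspace(0, side, grid + 1).astype(int)
    out = np.empty(grid * grid)
    k = 0
    for i in range(grid):
        for j in range(grid):
            out[k] = energy[edges[i]:edges[i + 1], edges[j]:edges[j + 1]].mean()
            k += 1
    return out


def gist_descriptor(image: np.ndarray, config: GistConfig | None = None) -> np.ndarray:
    """GIST descriptor of a grayscale image.

    Concatenates, in (scale, orientation, cell) order, the grid-pooled
    local-energy responses of the oriented band-pass filter bank.
    """
    config = config or GistConfig()
    img = _prepare_image(image, config)
    bank = _filter_bank(config.n_scales, config.n_orientations, config.image_side)
    F = np.fft.fft2(img)
    desc = np.empty(config.descriptor_length)
    cells = config.grid ** 2
    k = 0
    for s in range(config.n_scales):
        for o in range(config.n_orientations):
            energy = np.abs(np.fft.ifft2(F * bank[s, o]))
            desc[k:k + cells] = _pool_grid(energy, config.grid)
            k += cells
    return desc


class GistDescriptor(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: stack of grayscale images → GIST features.

    ``transform`` accepts an (n_images, H, W) array or a sequence of 2-D
    arrays and returns an (n_images, n_scales·n_orientations·grid²) matrix.
    """

    def __init__(self, n_scales: int = 8, n_orientations: int = 8, grid: int = 4,
                 image_side: int = 256, prefilter: bool = False):
        self.n_scales = n_scales
        self.n_orientations = n_orientations
        self.grid = grid
        self.image_side = image_side
        self.prefilter = prefilter

    def _config(self) -> GistConfig:
        return GistConfig(self.n_scales, self.n_orientations, self.grid,
                          self.image_side, self.prefilter)

    def fit(self, X, y=None):
        self.config_ = self._config()
        self.n_features_out_ = self.config_.descriptor_length
        return self

    def transform(self, X) -> np.ndarray:
        config = self._config()
        return np.vstack([gist_descriptor(np.asarray(img), config) for img in X])


@dataclass(frozen=True)
class CVFoldPlan:
    """Leave-one-level-out cross-validation plan.

    Each fold is a (train condition ids, test condition ids) pair. The
    classifier predicts ``target_factor`` while entire levels of
    ``generalization_factor`` are held out, forcing generalisation across
    that factor.
    """

    scheme: str  # "two_way_A" | "six_way_B"
    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    target_factor: str
    generalization_factor: str

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def _check_balanced_crossing(design: StimulusDesign) -> None:
    counts: dict[tuple[str, str], int] = {}
    for s, c in zip(design.shape_labels, design.category_labels):
        counts[(s, c)] = counts.get((s, c), 0) + 1
    n_shape = len(design.levels("shape"))
    n_cat = len(design.levels("category"))
    if len(counts) != n_shape * n_cat or len(set(counts.values())) != 1:
        raise DesignError(
            "six-way scheme requires shape fully crossed with category with "
            "equal cell counts"
        )


def build_folds(design: StimulusDesign, scheme: str,
                target_factor: str = "category") -> CVFoldPlan:
    """Build the leave-one-level-out plan for a stimulus design.

    two_way_A
        One fold per level of the generalisation factor (which must have
        exactly 2 levels): train on the other level, test on the held-out one.
    six_way_B
        For every 6-subset of the shape levels and every choice of one
        held-out element: when the target is category, train on the other
        five shape levels of the subset and test on the held-out shape level;
        when the target is shape, the 6-subset defines the six classes and
        one category level is held out for testing instead. Either way each
        fold of a 9-shape × 6-category design trains on 30 conditions and
        tests on 6, and the plan has C(9, 6) × 6 = 504 folds.
    """
    gen_factor = design.other_factor(target_factor)
    ids = np.asarray(design.condition_ids)
    tlab = np.asarray(design.labels(target_factor))
    glab = np.asarray(design.labels(gen_factor))

    if scheme == "two_way_A":
        gen_levels = design.levels(gen_factor)
        if len(gen_levels) != 2:
            raise DesignError(
                f"two_way_A needs a 2-level generalisation factor, "
                f"{gen_factor!r} has {len(gen_levels)} levels"
            )
        folds = tuple(
            (tuple(ids[glab != lev]), tuple(ids[glab == lev]))
            for lev in gen_levels
        )
        return CVFoldPlan("two_way_A", folds, target_factor, gen_factor)

    if scheme == "six_way_B":
        shape_levels = design.levels("shape")
        if len(shape_levels) < 7:
            raise DesignError(
                f"six_way_B needs ≥ 7 shape levels, got {len(shape_levels)}"
            )
        _check_balanced_crossing(design)
        slab = np.asarray(design.shape_labels)
        folds = []
        if target_factor == "category":
            for subset in itertools.combinations(shape_levels, 6):
                for held in subset:
                    train_levels = set(subset) - {held}
                    folds.append((
                        tuple(ids[np.isin(slab, sorted(train_levels))]),
                        tuple(ids[slab == held]),
                    ))
        elif target_factor == "shape":
            cat_levels = design.levels("category")
            if len(cat_levels) != 6:
                raise DesignError(
                    "six-way shape decoding expects 6 category levels, got "
                    f"{len(cat_levels)}"
                )
            clab = np.asarray(design.category_labels)
            for subset in itertools.combinations(shape_levels, 6):
                in_subset = np.isin(slab, subset)
                for held in cat_levels:
                    folds.append((
                        tuple(ids[in_subset & (clab != held)]),
                        tuple(ids[in_subset & (clab == held)]),
                    ))
        else:  # pragma: no cover - factor validated above
            raise DesignError(f"unknown target factor {target_factor!r}")
        return CVFoldPlan("six_way_B", tuple(folds), target_factor, gen_factor)

    raise DesignError(f"unknown scheme {scheme!r}; expected two_way_A or six_way_B")


@dataclass(frozen=True)
class DecodingResult:
    """Cross-decoding accuracy for one target factor."""

    target_factor: str
    accuracy: float
    per_fold_accuracies: np.ndarray
    chance_level: float
    n_correct: int
    n_trials: int
    p_value: float  # binomial test (greater than chance) over pooled test trials


@dataclass(frozen=True)
class AuditReport:
    """Joint shape + category orthogonality audit of one stimulus set."""

    shape: DecodingResult
    category: DecodingResult

    @property
    def shape_accuracy(self) -> float:
        return self.shape.accuracy

    @property
    def category_accuracy(self) -> float:
        return self.category.accuracy

    def to_dict(self) -> dict:
        out = {}
        for res in (self.shape, self.category):
            out[res.target_factor] = {
                "accuracy": res.accuracy,
                "chance_level": res.chance_level,
                "n_folds": len(res.per_fold_accuracies),
                "n_correct": res.n_correct,
                "n_trials": res.n_trials,
                "p_value_above_chance": res.p_value,
            }
        return out


def _make_lda() -> LinearDiscriminantAnalysis:
    # high-dimensional descriptors with tiny training folds make the
    # within-class scatter singular; Ledoit–Wolf shrinkage is deterministic
    # and needs no tuning fold
    return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")


def lda_cross_decode(features: np.ndarray, design: StimulusDesign,
                     plan: CVFoldPlan) -> DecodingResult:
    """Fit LDA per fold on the training conditions, score the held-out ones.

    ``features`` rows must align with ``design.condition_ids``. Accuracy is
    the unweighted mean of per-fold accuracies; a pooled binomial test
    against the chance level 1/(number of target levels) is reported.
    """
    features = np.asarray(features, dtype=float)
    if features.shape[0] != design.n_conditions:
        raise ValidationError(
            f"{features.shape[0]} feature rows for {design.n_conditions} conditions"
        )
    index = {c: i for i, c in enumerate(design.condition_ids)}
    labels = np.asarray(design.labels(plan.target_factor))
    n_levels = len(design.levels(plan.target_factor))
    fold_acc = np.empty(plan.n_folds)
    n_correct = 0
    n_trials = 0
    for k, (train_ids, test_ids) in enumerate(plan.folds):
        tr = np.asarray([index[c] for c in train_ids])
        te = np.asarray([index[c] for c in test_ids])
        if len(te) == 0:
            raise DesignError(f"fold {k} has an empty test partition")
        train_classes = set(labels[tr])
        if len(train_classes) < 2:
            raise InsufficientDataError(
                f"fold {k}: fewer than 2 target classes in training partition"
            )
        missing = set(labels[te]) - train_classes
        if missing:
            raise DesignError(
                f"fold {k}: test classes absent from training partition: "
                f"{sorted(missing)}"
            )
        clf = _make_lda()
        clf.fit(features[tr], labels[tr])
        pred = clf.predict(features[te])
        correct = int(np.sum(pred == labels[te]))
        fold_acc[k] = correct / len(te)
        n_correct += correct
        n_trials += len(te)
    p = binomtest(n_correct, n_trials, p=1.0 / n_levels,
                  alternative="greater").pvalue
    return DecodingResult(
        target_factor=plan.target_factor,
        accuracy=float(fold_acc.mean()),
        per_fold_accuracies=fold_acc,
        chance_level=1.0 / n_levels,
        n_correct=n_correct,
        n_trials=n_trials,
        p_value=float(p),
    )


def audit_stimulus_set(images, design: StimulusDesign, scheme: str,
                       config: GistConfig | None = None) -> AuditReport:
    """Run the full orthogonality audit: GIST features, then shape and
    category leave-one-level-out LDA decoding."""
    config = config or GistConfig()
    feats = np.vstack([gist_descriptor(np.asarray(img), config) for img in images])
    results = {}
    for target in ("shape", "category"):
        plan = build_folds(design, scheme, target_factor=target)
        results[target] = lda_cross_decode(feats, design, plan)
    return AuditReport(shape=results["shape"], category=results["category"])
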