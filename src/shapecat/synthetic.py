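"""Synthetic designs, images, activations, and subject patterns.

Everything the analysis pipeline consumes can be generated here with planted,
known structure: balanced shape × category factorial designs; bar/blob
grayscale images whose low-level statistics carry shape but not category;
layer activation stacks whose shape/category signal mixture varies with
depth (shape early, category peaking at the final layer); multi-subject ROI
patterns with a V1-shape → anterior-VTC-category gradient; and continuous
behavioural-style model RDMs with a controllable shape–category dependency.

The model is deliberately minimal: each shape level and each category level
is embedded once as a fixed random unit-feature vector, and a layer (or ROI)
pattern is a weighted mixture of its condition's two embedding vectors, a
fixed exemplar-unique component (features idiosyncratic to each stimulus,
preserved across depth), and independent Gaussian noise. Depth (or ROI
identity) changes only the mixture weights — exactly the structure the
layer-profile analysis assumes.
All generators are bit-reproducible given (spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import rankdata

from .design import StimulusDesign
from .exceptions import DesignError, ValidationError
from .rdm import RDM, PatternMatrix, model_rdm, vectorize


@dataclass(frozen=True)
class SynthSpec:
    """Conditions of a synthetic study.

    Defaults describe the bundled "paper-like" regime: a balanced 2 × 2
    design with 8 stimuli per cell (32 conditions), an 8-layer network whose
    shape signal decays with depth while category signal rises to peak at
    the final layer, 16 subjects, and three ROIs forming a V1-shape →
    VTC-ant-category gradient.
    """

    n_shape_levels: int = 2
    n_category_levels: int = 2
    n_per_cell: int = 8
    n_layers: int = 8
    shape_schedule: tuple[float, ...] = ()
    category_schedule: tuple[float, ...] = ()
    noise_sd: float = 0.3
    exemplar_weight: float = 1.0
    n_units: int = 60
    n_subjects: int = 16
    subject_noise_sd: float = 0.4
    roi_weights: tuple[tuple[str, float, float], ...] = (
        ("V1", 1.0, 0.05),
        ("VTC_post", 0.55, 0.45),
        ("VTC_ant", 0.08, 1.0),
    )
    model_dependency: float = 0.48
    seed: int = 0

    def __post_init__(self):
        if min(self.n_shape_levels, self.n_category_levels, self.n_per_cell) < 1:
            raise ValidationError("design cell structure must be positive")
        if not self.shape_schedule:
            object.__setattr__(self, "shape_schedule",
                               tuple(np.linspace(1.0, 0.35, self.n_layers)))
        if not self.category_schedule:
            object.__setattr__(self, "category_schedule",
                               tuple(np.geomspace(0.05, 1.0, self.n_layers)))
        for name in ("shape_schedule", "category_schedule"):
            sched = getattr(self, name)
            if len(sched) != self.n_layers:
                raise ValidationError(
                    f"{name} has length {len(sched)}, expected n_layers = {self.n_layers}")
            if any(w < 0 for w in sched):
                raise ValidationError(f"{name} weights must be non-negative")
        if self.noise_sd < 0 or self.subject_noise_sd < 0:
            raise ValidationError("noise standard deviations must be non-negative")

    @classmethod
    def paper_like(cls, seed: int = 0) -> "SynthSpec":
        """The default regime (see class docstring) with a chosen seed."""
        return cls(seed=seed)

    @property
    def roi_names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.roi_weights)


def make_design(n_shape_levels: int, n_category_levels: int,
                n_per_cell: int = 1) -> StimulusDesign:
    """Fully crossed balanced factorial design, deterministic given its sizes.

    A (2, 2, 8) design has 32 conditions; (9, 6, 1) has 54.
    """
    if min(n_shape_levels, n_category_levels, n_per_cell) < 1:
        raise ValidationError("all design sizes must be positive")
    if n_shape_levels < 2 or n_category_levels < 2:
        raise DesignError("both factors need ≥ 2 levels")
    ids, shapes, cats = [], [], []
    for s in range(n_shape_levels):
        for c in range(n_category_levels):
            for k in range(n_per_cell):
                ids.append(f"s{s + 1}c{c + 1}e{k + 1}")
                shapes.append(f"shape{s + 1}")
                cats.append(f"cat{c + 1}")
    return StimulusDesign(ids, shapes, cats)


# ---------------------------------------------------------------------------
# images


def _render_blob(side: int, a: float, b: float, angle: float,
                 cx: float, cy: float, texture: np.ndarray) -> np.ndarray:
    """One smooth textured ellipse on a uniform light background."""
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    x = xx - cx
    y = yy - cy
    ca, sa = np.cos(angle), np.sin(angle)
    u = (x * ca + y * sa) / a
    v = (-x * sa + y * ca) / b
    mask = (u ** 2 + v ** 2 <= 1.0).astype(float)
    mask = gaussian_filter(mask, sigma=side / 128)  # smooth boundary
    img = np.full((side, side), 0.92)
    interior = 0.25 + 0.3 * texture  # mid-gray with texture, darker than bg
    return img * (1 - mask) + interior * mask


def make_images(design: StimulusDesign, seed: int = 0,
                side: int = 256) -> list[np.ndarray]:
    """Bar/blob grayscale stimuli whose aspect ratio follows the shape factor.

    The first shape level renders as elongated bars (bounding-box aspect
    ratio > 2.5), the second as compact blobs (< 1.5). Position, size and
    orientation jitter and the interior texture are drawn independently of
    the category label, so category is unpredictable from low-level
    statistics by construction.
    """
    shape_levels = design.levels("shape")
    if len(shape_levels) != 2:
        raise DesignError(
            f"bar/blob rendering needs a 2-level shape factor, got "
            f"{len(shape_levels)} levels")
    bar_level = shape_levels[0]
    rng = np.random.default_rng(seed)
    images = []
    for cond, s in zip(design.condition_ids, design.shape_labels):
        cx = side / 2 + rng.uniform(-side / 20, side / 20)
        cy = side / 2 + rng.uniform(-side / 20, side / 20)
        if s == bar_level:
            a = side * rng.uniform(0.36, 0.42)
            b = side * rng.uniform(0.055, 0.07)
            angle = rng.uniform(-np.pi / 16, np.pi / 16)  # near-horizontal
        else:
            a = side * rng.uniform(0.20, 0.24)
            b = side * rng.uniform(0.17, 0.20)
            angle = rng.uniform(0, np.pi)
        texture = gaussian_filter(rng.standard_normal((side, side)), sigma=side / 40)
        texture = texture / (np.abs(texture).max() + 1e-12)
        images.append(_render_blob(side, a, b, angle, cx, cy, texture))
    return images


# ---------------------------------------------------------------------------
# activations and subject patterns


def _level_embeddings(levels: tuple[str, ...], n_units: int,
                      rng: np.random.Generator) -> dict[str, np.ndarray]:
    # one fixed standard-normal embedding vector per factor level
    return {lev: rng.standard_normal(n_units) for lev in levels}


def _mixture_patterns(design: StimulusDesign, w_shape: float, w_cat: float,
                      S: dict[str, np.ndarray], C: dict[str, np.ndarray],
                      E: np.ndarray, w_exemplar: float, noise_sd: float,
                      rng: np.random.Generator, n_units: int,
                      tag: str) -> PatternMatrix:
    rows = np.empty((design.n_conditions, n_units))
    for i, (s, c) in enumerate(zip(design.shape_labels, design.category_labels)):
        rows[i] = (w_shape * S[s] + w_cat * C[c] + w_exemplar * E[i]
                   + noise_sd * rng.standard_normal(n_units))
    return PatternMatrix(design.condition_ids, rows, source_tag=tag)


def make_layer_activations(design: StimulusDesign, spec: SynthSpec,
                           ) -> list[PatternMatrix]:
    """Layer activation stack: layer l = shape_schedule[l]·S + category_schedule[l]·C + noise.

    S and C map each factor level to a fixed random embedding drawn once per
    run, so depth changes only the mixture weights.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    S = _level_embeddings(design.levels("shape"), spec.n_units, rng)
    C = _level_embeddings(design.levels("category"), spec.n_units, rng)
    E = rng.standard_normal((design.n_conditions, spec.n_units))
    return [
        _mixture_patterns(design, ws, wc, S, C, E, spec.exemplar_weight,
                          spec.noise_sd, rng, spec.n_units, tag=f"layer{l}")
        for l, (ws, wc) in enumerate(zip(spec.shape_schedule,
                                         spec.category_schedule))
    ]


def make_subject_patterns(design: StimulusDesign, spec: SynthSpec,
                          ) -> dict[str, dict[str, PatternMatrix]]:
    """Per-subject, per-ROI patterns sharing ROI-level signal mixtures.

    Every subject sees the same ROI mixture of the shape/category embeddings
    but with independent Gaussian noise, yielding a complete
    subject × ROI grid.
    """
    if not spec.roi_weights:
        raise ValidationError("spec.roi_weights must name at least one ROI")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    S = _level_embeddings(design.levels("shape"), spec.n_units, rng)
    C = _level_embeddings(design.levels("category"), spec.n_units, rng)
    E = rng.standard_normal((design.n_conditions, spec.n_units))
    out: dict[str, dict[str, PatternMatrix]] = {}
    for si in range(spec.n_subjects):
        sub = f"sub{si + 1:02d}"
        out[sub] = {}
        for roi, ws, wc in spec.roi_weights:
            out[sub][roi] = _mixture_patterns(
                design, ws, wc, S, C, E, spec.exemplar_weight,
                spec.subject_noise_sd, rng, spec.n_units,
                tag=f"{sub}:{roi}")
    return out


# ---------------------------------------------------------------------------
# behavioural-style model RDMs


def _rank_corr(v: np.ndarray, w: np.ndarray) -> float:
    rv, rw = rankdata(v), rankdata(w)
    rv = rv - rv.mean()
    rw = rw - rw.mean()
    return float(rv @ rw / np.sqrt((rv @ rv) * (rw @ rw)))


def make_behavioural_rdm(design: StimulusDesign, factor: str,
                         model_dependency: float = 0.0,
                         noise_sd: float = 0.1, seed: int = 0) -> RDM:
    """Continuous behavioural-style model RDM for one factor with a planted
    rank-correlation dependency on the other factor's model.

    The RDM is ``binary factor model + w·(other-factor model) + symmetric
    noise`` rescaled to [0, 2]; the mixing weight ``w`` is calibrated so the
    achieved upper-triangle Spearman correlation with the other factor's
    binary model is within ±0.1 of ``model_dependency``. If the target is
    unreachable a warning reports the achieved value.
    """
    if not -0.5 <= model_dependency <= 0.9:
        raise ValidationError(
            f"model_dependency must lie in [−0.5, 0.9], got {model_dependency}")
    base = vectorize(model_rdm(design, factor)).values
    other = vectorize(model_rdm(design, design.other_factor(factor))).values
    rng = np.random.default_rng(seed)
    noise = noise_sd * rng.standard_normal(len(base))

    def achieved(w: float) -> float:
        return _rank_corr(base + w * other + noise, other)

    # achieved(w) is monotone in w but piecewise constant when noise is small
    # (ranks only change at crossings), so bisection alone can overshoot a
    # step: refine with a candidate grid and keep the best mixing weight
    lo, hi = -50.0, 50.0
    if model_dependency <= achieved(lo):
        w = lo
    elif model_dependency >= achieved(hi):
        w = hi
    else:
        for _ in range(60):
            mid = (lo + hi) / 2
            if achieved(mid) < model_dependency:
                lo = mid
            else:
                hi = mid
        w = (lo + hi) / 2
    candidates = np.concatenate([[0.0, w], np.linspace(-2.0, 5.0, 141)])
    w = float(min(candidates, key=lambda c: abs(achieved(c) - model_dependency)))

    v = base + w * other + noise
    vmin, vmax = v.min(), v.max()
    if vmax > vmin:
        v = 2.0 * (v - vmin) / (vmax - vmin)
    got = _rank_corr(v, other)
    if abs(got - model_dependency) > 0.1:
        warnings.warn(
            f"dependency target {model_dependency:.3f} unreachable; achieved "
            f"{got:.3f}", stacklevel=2)
    n = design.n_conditions
    m = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    m[iu, ju] = v
    return RDM(design.condition_ids, m + m.T, metric_tag="external")
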