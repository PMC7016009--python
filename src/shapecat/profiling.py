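"""Layer-wise and ROI-wise shape/category information profiles.

The central question — is category information represented independently of
shape? — is answered by correlating each representation's RDM (one per CNN
layer, or one per subject × ROI) with a shape model RDM and a category model
RDM. When the two models are themselves dependent, the other model is
partialled out. The resulting correlation profiles are then submitted to the
study's inferential battery:

* a 2 × 2 fixed-effects ANOVA over layers with Layer (modelled linearly,
  intercept + slope) and Condition (shape vs category) as factors;
* a fully within-subject two-factor repeated-measures ANOVA over ROI ×
  Condition;
* a repeated-measures ANOVA of brain–layer correlations with Layer as a
  linear within-subject trend and ROI as a within-subject factor;
* post-hoc paired t, one-sample t, and Tukey HSD tests.

Repeated-measures sums of squares are partitioned explicitly from cell and
marginal means, with each effect tested against its own subject-by-effect
interaction term; degenerate zero-variance effects yield F = 0 rather than
0/0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .compare import partial_spearman_rdm, permutation_test, spearman_rdm
from .exceptions import InsufficientDataError, ValidationError
from .rdm import RDM

_TINY_P = np.finfo(float).tiny


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class LayerProfile:
    """Per-layer (partial) Spearman correlations with the two model RDMs."""

    network_tag: str
    layer_index: tuple[int, ...]
    rho_shape: np.ndarray
    rho_category: np.ndarray
    significant_shape: np.ndarray  # bool flags at alpha
    significant_category: np.ndarray
    threshold_shape: np.ndarray  # per-comparison permutation thresholds
    threshold_category: np.ndarray
    method: str  # "plain" | "partial"
    alpha: float = 0.05

    @property
    def n_layers(self) -> int:
        return len(self.layer_index)

    def argmax_layer(self, which: str = "category") -> int:
        rho = self.rho_category if which == "category" else self.rho_shape
        return int(self.layer_index[int(np.argmax(rho))])


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    F: float
    df_num: float
    df_den: float
    p_value: float


@dataclass(frozen=True)
class AnovaTable:
    effects: tuple[AnovaEffect, ...]
    design_tag: str

    def __getitem__(self, name: str) -> AnovaEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_records(self) -> list[dict]:
        return [
            {"effect": e.name, "F": e.F, "df_num": e.df_num,
             "df_den": e.df_den, "p_value": e.p_value}
            for e in self.effects
        ]


@dataclass(frozen=True)
class SubjectRoiProfile:
    """Per-subject, per-ROI correlation measures on a complete grid.

    ``values[s, r, m]`` is subject ``subjects[s]``'s correlation in ROI
    ``rois[r]`` for measure ``measure_names[m]`` — measures are either the
    two model conditions ('shape', 'category') or layer tags.
    """

    subjects: tuple[str, ...]
    rois: tuple[str, ...]
    measure_names: tuple[str, ...]
    values: np.ndarray
    method: str = "plain"

    def __post_init__(self):
        expected = (len(self.subjects), len(self.rois), len(self.measure_names))
        if self.values.shape != expected:
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"(subjects, rois, measures) = {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("profile contains non-finite values; "
                                  "the subject × roi grid must be complete")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def group_mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def sem(self) -> np.ndarray:
        """Standard error of the mean across subjects (sd/√n); NaN for n = 1."""
        n = self.n_subjects
        if n < 2:
            return np.full(self.values.shape[1:], np.nan)
        return self.values.std(axis=0, ddof=1) / np.sqrt(n)


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: float
    p_value: float


# ---------------------------------------------------------------------------
# layer profiles


def models_are_dependent(shape_model: RDM, category_model: RDM,
                         n_perm: int = 1000, seed: int = 0,
                         alpha: float = 0.05) -> bool:
    """Permutation test of shape–category model dependency at ``alpha``."""
    return permutation_test(shape_model, category_model, n_perm=n_perm,
                            seed=seed, alpha=alpha).significant


def _profile_one(rdm: RDM, model: RDM, control: RDM | None,
                 n_perm: int, seed: int, alpha: float):
    controls = [control] if control is not None else None
    res = permutation_test(rdm, model, n_perm=n_perm, seed=seed,
                           controls=controls, alpha=alpha)
    return res.observed_rho, res.significant, res.threshold_rho


def layer_profile(layer_rdms: Sequence[RDM], shape_model: RDM,
                  category_model: RDM, partial_when_dependent: bool = True,
                  n_perm: int = 1000, seed: int = 0, alpha: float = 0.05,
                  network_tag: str = "", layer_index: Sequence[int] | None = None,
                  ) -> LayerProfile:
    """Layer-by-layer RSA of an ordered stack of layer RDMs against the
    shape and category model RDMs.

    If ``partial_when_dependent`` and the two models are significantly
    correlated (label-permutation test at ``alpha``), each model correlation
    partials out the other model; otherwise plain Spearman is used. Every
    layer × model comparison carries its own permutation significance flag
    and threshold. Seeds for the per-comparison permutations are spawned
    deterministically from ``seed``.
    """
    if layer_index is None:
        layer_index = tuple(range(len(layer_rdms)))
    layer_index = tuple(int(i) for i in layer_index)
    if len(layer_index) != len(layer_rdms):
        raise ValidationError("layer_index length must match layer_rdms")
    if len(set(layer_index)) != len(layer_index) or list(layer_index) != sorted(layer_index):
        raise ValidationError("layer indices must be strictly increasing and unique")
    for r in layer_rdms:
        r.require_aligned(shape_model)
    shape_model.require_aligned(category_model)

    dependent = partial_when_dependent and models_are_dependent(
        shape_model, category_model, n_perm=n_perm, seed=seed, alpha=alpha)
    method = "partial" if dependent else "plain"

    ss = np.random.SeedSequence(seed)
    sub_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2 * len(layer_rdms))]
    rho_s, sig_s, thr_s = [], [], []
    rho_c, sig_c, thr_c = [], [], []
    for i, rdm in enumerate(layer_rdms):
        ctrl_for_shape = category_model if dependent else None
        ctrl_for_cat = shape_model if dependent else None
        r, s, t = _profile_one(rdm, shape_model, ctrl_for_shape,
                               n_perm, sub_seeds[2 * i], alpha)
        rho_s.append(r); sig_s.append(s); thr_s.append(t)
        r, s, t = _profile_one(rdm, category_model, ctrl_for_cat,
                               n_perm, sub_seeds[2 * i + 1], alpha)
        rho_c.append(r); sig_c.append(s); thr_c.append(t)
    return LayerProfile(
        network_tag=network_tag, layer_index=layer_index,
        rho_shape=np.asarray(rho_s), rho_category=np.asarray(rho_c),
        significant_shape=np.asarray(sig_s, dtype=bool),
        significant_category=np.asarray(sig_c, dtype=bool),
        threshold_shape=np.asarray(thr_s), threshold_category=np.asarray(thr_c),
        method=method, alpha=alpha,
    )


# ---------------------------------------------------------------------------
# ANOVAs


def _f_p(ss_eff: float, df_eff: float, ss_err: float, df_err: float,
         scale: float = 0.0) -> tuple[float, float]:
    """F and p from effect/error sums of squares.

    ``scale`` is the total sum of squares of the response; sums of squares
    below 1e-12 × scale are rounding residue of a degenerate (constant)
    effect and are treated as exactly zero: a zero effect gives F = 0,
    p = 1, and a zero error term under a real effect gives F = ∞.
    """
    if df_err <= 0:
        raise InsufficientDataError("no error degrees of freedom")
    zero_tol = 1e-12 * scale + 1e-300
    if ss_eff <= zero_tol:
        return 0.0, 1.0
    ms_err = ss_err / df_err
    if ss_err <= zero_tol:
        return float("inf"), _TINY_P
    F = (ss_eff / df_eff) / ms_err
    return float(F), float(max(stats.f.sf(F, df_eff, df_err), _TINY_P))


def layer_condition_anova(profile: LayerProfile) -> AnovaTable:
    """2 × 2 ANOVA over layers: Layer (linear, intercept + slope) × Condition.

    The shape and category correlation series are stacked into one response
    vector and a fixed-effects regression
    ``rho ~ 1 + layer + condition + layer:condition`` is fitted with layer as
    a centred continuous covariate and condition effect-coded ±1/2. Each
    effect's F comes from the nested residual-sum-of-squares comparison of
    the full model against the model without that term, on error df
    ``n_points − 4``.
    """
    L = profile.n_layers
    if L < 3:
        raise InsufficientDataError(f"need ≥ 3 layers for the ANOVA, got {L}")
    x = np.asarray(profile.layer_index, dtype=float)
    x = x - x.mean()
    layer = np.concatenate([x, x])
    cond = np.concatenate([np.full(L, 0.5), np.full(L, -0.5)])  # shape +, category −
    y = np.concatenate([profile.rho_shape, profile.rho_category])
    X_full = np.column_stack([np.ones(2 * L), layer, cond, layer * cond])

    def rss(X):
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r)

    rss_full = rss(X_full)
    df_err = 2 * L - 4
    scale = float(y @ y)
    effects = []
    for name, col in (("Layer", 1), ("Condition", 2), ("Interaction", 3)):
        X_red = np.delete(X_full, col, axis=1)
        F, p = _f_p(rss(X_red) - rss_full, 1, rss_full, df_err, scale=scale)
        effects.append(AnovaEffect(name, F, 1, df_err, p))
    return AnovaTable(tuple(effects), design_tag="layer_condition_2x2")


def roi_condition_anova(data: SubjectRoiProfile) -> AnovaTable:
    """Two-factor fully within-subject repeated-measures ANOVA.

    Factors are Condition (the profile's measures, e.g. shape vs category)
    and ROI; each effect is tested against its own subject-by-effect
    interaction error term. Requires a complete subject × ROI × condition
    grid with ≥ 3 subjects.
    """
    y = data.values  # (n, q_roi, p_cond)
    n, q, p = y.shape
    if n < 3:
        raise InsufficientDataError(f"repeated-measures ANOVA needs ≥ 3 subjects, got {n}")
    if q < 2 or p < 2:
        raise InsufficientDataError("both factors need ≥ 2 levels")
    m = y.mean()
    m_s = y.mean(axis=(1, 2))          # subject means
    m_r = y.mean(axis=(0, 2))          # roi means
    m_c = y.mean(axis=(0, 1))          # condition means
    m_sr = y.mean(axis=2)              # subject × roi
    m_sc = y.mean(axis=1)              # subject × condition
    m_rc = y.mean(axis=0)              # roi × condition

    ss_c = n * q * float(np.sum((m_c - m) ** 2))
    ss_r = n * p * float(np.sum((m_r - m) ** 2))
    ss_rc = n * float(np.sum((m_rc - m_r[:, None] - m_c[None, :] + m) ** 2))
    ss_cs = q * float(np.sum((m_sc - m_s[:, None] - m_c[None, :] + m) ** 2))
    ss_rs = p * float(np.sum((m_sr - m_s[:, None] - m_r[None, :] + m) ** 2))
    resid = (y - m_rc[None, :, :] - m_sr[:, :, None] - m_sc[:, None, :]
             + m_r[None, :, None] + m_c[None, None, :] + m_s[:, None, None] - m)
    ss_rcs = float(np.sum(resid ** 2))

    scale = float(np.sum(y * y))
    effects = []
    for name, ss_eff, df_eff, ss_err, df_err in (
        ("Condition", ss_c, p - 1, ss_cs, (p - 1) * (n - 1)),
        ("ROI", ss_r, q - 1, ss_rs, (q - 1) * (n - 1)),
        ("Interaction", ss_rc, (p - 1) * (q - 1), ss_rcs, (p - 1) * (q - 1) * (n - 1)),
    ):
        F, pv = _f_p(ss_eff, df_eff, ss_err, df_err, scale=scale)
        effects.append(AnovaEffect(name, F, df_eff, df_err, pv))
    return AnovaTable(tuple(effects), design_tag="roi_condition_rm")


def _rm_oneway(values: np.ndarray) -> tuple[float, float, float, float]:
    """One-way repeated-measures SS partition for (n_subjects, k_levels)."""
    n, k = values.shape
    m = values.mean()
    m_l = values.mean(axis=0)
    m_s = values.mean(axis=1)
    ss_eff = n * float(np.sum((m_l - m) ** 2))
    ss_err = float(np.sum((values - m_l[None, :] - m_s[:, None] + m) ** 2))
    return ss_eff, k - 1.0, ss_err, (k - 1.0) * (n - 1.0)


def layer_trend_roi_anova(data: SubjectRoiProfile,
                          layer_index: Sequence[int] | None = None) -> AnovaTable:
    """Repeated-measures ANOVA with Layer as a linear within-subject trend
    and ROI as a within-subject factor.

    Layer is modelled linearly (intercept + slope over the centred layer
    index): the Layer main effect tests the mean per-subject slope against
    zero on (1, n−1) df; the ROI effect is a one-way repeated-measures ANOVA
    on layer-averaged ROI means; the interaction is the same ANOVA on the
    per-subject, per-ROI slopes.
    """
    n = data.n_subjects
    if n < 2:
        raise InsufficientDataError("ANOVA requires ≥ 2 subjects")
    L = len(data.measure_names)
    if L < 2:
        raise InsufficientDataError("need ≥ 2 layers for a linear trend")
    x = (np.arange(L, dtype=float) if layer_index is None
         else np.asarray(layer_index, dtype=float))
    x = x - x.mean()
    denom = float(x @ x)
    # centering across layers first makes the slope of a layer-constant
    # series exactly zero (no BLAS rounding residue)
    vc = data.values - data.values.mean(axis=2, keepdims=True)
    slopes = vc @ x / denom                   # (n, q)
    means = data.values.mean(axis=2)          # (n, q)

    # Layer: one-sample test of the roi-averaged subject slopes
    sbar = slopes.mean(axis=1)
    ss_layer = n * float(sbar.mean() ** 2)
    ss_layer_err = float(np.sum((sbar - sbar.mean()) ** 2))
    F_l, p_l = _f_p(ss_layer, 1, ss_layer_err, n - 1,
                    scale=float(np.sum(sbar * sbar)))
    ss_r, df_r, ss_re, df_re = _rm_oneway(means)
    F_r, p_r = _f_p(ss_r, df_r, ss_re, df_re,
                    scale=float(np.sum(means * means)))
    ss_i, df_i, ss_ie, df_ie = _rm_oneway(slopes)
    F_i, p_i = _f_p(ss_i, df_i, ss_ie, df_ie,
                    scale=float(np.sum(slopes * slopes)))
    return AnovaTable((
        AnovaEffect("Layer", F_l, 1, n - 1, p_l),
        AnovaEffect("ROI", F_r, df_r, df_re, p_r),
        AnovaEffect("Interaction", F_i, df_i, df_ie, p_i),
    ), design_tag="layer_roi_2x3")


# ---------------------------------------------------------------------------
# brain–layer profiles


def _grid_from_mapping(subject_rdms: Mapping[str, Mapping[str, RDM]]):
    subjects = tuple(subject_rdms)
    if not subjects:
        raise ValidationError("no subjects supplied")
    rois = tuple(subject_rdms[subjects[0]])
    for s in subjects:
        if tuple(subject_rdms[s]) != rois:
            raise ValidationError(
                f"incomplete subject × ROI grid: subject {s!r} has ROIs "
                f"{tuple(subject_rdms[s])}, expected {rois}"
            )
    return subjects, rois


@dataclass(frozen=True)
class BrainLayerResult:
    profile: SubjectRoiProfile
    anova: AnovaTable | None
    peak_layer: dict[str, int]  # per-ROI argmax layer of the group mean


def brain_layer_profile(subject_rdms: Mapping[str, Mapping[str, RDM]],
                        layer_rdms: Sequence[RDM],
                        layer_index: Sequence[int] | None = None,
                        layer_tags: Sequence[str] | None = None,
                        ) -> BrainLayerResult:
    """Correlate each subject's ROI RDMs with every layer RDM.

    Returns per-subject/ROI/layer Spearman rho on a complete grid, the
    group mean peak layer per ROI, and the Layer-trend × ROI
    repeated-measures ANOVA. With a single subject the SEM is undefined and
    the ANOVA is refused (returned as None, with a warning).
    """
    subjects, rois = _grid_from_mapping(subject_rdms)
    L = len(layer_rdms)
    if layer_index is None:
        layer_index = tuple(range(L))
    if layer_tags is None:
        layer_tags = tuple(f"layer{i}" for i in layer_index)
    vals = np.empty((len(subjects), len(rois), L))
    for si, s in enumerate(subjects):
        for ri, r in enumerate(rois):
            brdm = subject_rdms[s][r]
            for li, lrdm in enumerate(layer_rdms):
                vals[si, ri, li] = spearman_rdm(brdm, lrdm).rho
    profile = SubjectRoiProfile(subjects, rois, tuple(layer_tags), vals)
    gm = profile.group_mean()
    peaks = {r: int(layer_index[int(np.argmax(gm[ri]))]) for ri, r in enumerate(rois)}
    if len(subjects) < 2:
        warnings.warn("single subject: SEM undefined and ANOVA refused",
                      stacklevel=2)
        anova = None
    else:
        anova = layer_trend_roi_anova(profile, layer_index=layer_index)
    return BrainLayerResult(profile=profile, anova=anova, peak_layer=peaks)


def partialled_brain_layer_profile(subject_rdms: Mapping[str, Mapping[str, RDM]],
                                   layer_rdms: Sequence[RDM], control: RDM,
                                   layer_tags: Sequence[str] | None = None,
                                   ) -> SubjectRoiProfile:
    """Brain–layer correlations with a model RDM partialled out of both sides."""
    subjects, rois = _grid_from_mapping(subject_rdms)
    L = len(layer_rdms)
    if layer_tags is None:
        layer_tags = tuple(f"layer{i}" for i in range(L))
    vals = np.empty((len(subjects), len(rois), L))
    for si, s in enumerate(subjects):
        for ri, r in enumerate(rois):
            brdm = subject_rdms[s][r]
            for li, lrdm in enumerate(layer_rdms):
                vals[si, ri, li] = partial_spearman_rdm(brdm, lrdm, [control]).rho
    return SubjectRoiProfile(subjects, rois, tuple(layer_tags), vals,
                             method="partial")


# ---------------------------------------------------------------------------
# post-hoc tests


def paired_t(x: Sequence[float], y: Sequence[float], name: str = "paired_t") -> TestResult:
    """Two-sided paired t-test; identical samples give t = 0, p = 1."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = len(d)
    if n < 2:
        raise InsufficientDataError("paired t-test needs n ≥ 2")
    sd = d.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if d.mean() == 0.0 else float("inf") * np.sign(d.mean())
        p = 1.0 if d.mean() == 0.0 else _TINY_P
    else:
        t = float(d.mean() / (sd / np.sqrt(n)))
        p = float(2 * stats.t.sf(abs(t), n - 1))
    return TestResult(name, t, n - 1, p)


def one_sample_t(x: Sequence[float], popmean: float = 0.0,
                 name: str = "one_sample_t") -> TestResult:
    """Two-sided one-sample t-test against ``popmean``."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise InsufficientDataError("one-sample t-test needs n ≥ 2")
    sd = x.std(ddof=1)
    mean_dev = x.mean() - popmean
    if sd == 0.0:
        t = 0.0 if mean_dev == 0.0 else float("inf") * np.sign(mean_dev)
        p = 1.0 if mean_dev == 0.0 else _TINY_P
    else:
        t = float(mean_dev / (sd / np.sqrt(n)))
        p = float(2 * stats.t.sf(abs(t), n - 1))
    return TestResult(name, t, n - 1, p)


def tukey_hsd_rm(values: np.ndarray, level_names: Sequence[str],
                 prefix: str = "tukey") -> list[TestResult]:
    """Tukey HSD over repeated-measures level means.

    ``values`` is (n_subjects, k_levels); the error term is the
    subject-by-level interaction mean square of the one-way repeated-measures
    ANOVA, and p-values come from the studentized range distribution with
    k means and (k−1)(n−1) df.
    """
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    if n < 2 or k < 2:
        raise InsufficientDataError("Tukey HSD needs ≥ 2 subjects and ≥ 2 levels")
    _, _, ss_err, df_err = _rm_oneway(values)
    ms_err = ss_err / df_err
    means = values.mean(axis=0)
    se = np.sqrt(ms_err / n)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            if se == 0.0:
                q = 0.0 if means[i] == means[j] else float("inf")
                p = 1.0 if means[i] == means[j] else _TINY_P
            else:
                q = float(abs(means[i] - means[j]) / se)
                p = float(max(stats.studentized_range.sf(q, k, df_err), _TINY_P))
            out.append(TestResult(f"{prefix}:{level_names[i]}-{level_names[j]}",
                                  q, df_err, p))
    return out


def posthoc_tests(data: SubjectRoiProfile, tests: Sequence[tuple]) -> list[TestResult]:
    """Run a battery of post-hoc tests on a subject × ROI profile.

    Each entry of ``tests`` is a tuple:

    * ``("paired_t", roi, measure_a, measure_b)`` — paired t across subjects
      between two measures within one ROI;
    * ``("one_sample_t", roi, measure)`` — one-sample t of one measure in one
      ROI against zero;
    * ``("tukey_rois",)`` or ``("tukey_rois", measure)`` — Tukey HSD over ROI
      means (averaged over measures, or for one named measure), using the
      repeated-measures error term.
    """
    ri = {r: i for i, r in enumerate(data.rois)}
    mi = {m: i for i, m in enumerate(data.measure_names)}
    out: list[TestResult] = []
    for spec in tests:
        kind = spec[0]
        if kind == "paired_t":
            _, roi, ma, mb = spec
            x = data.values[:, ri[roi], mi[ma]]
            y = data.values[:, ri[roi], mi[mb]]
            out.append(paired_t(x, y, name=f"paired_t:{roi}:{ma}-{mb}"))
        elif kind == "one_sample_t":
            _, roi, m = spec
            out.append(one_sample_t(data.values[:, ri[roi], mi[m]],
                                    name=f"one_sample_t:{roi}:{m}"))
        elif kind == "tukey_rois":
            if len(spec) > 1:
                vals = data.values[:, :, mi[spec[1]]]
                prefix = f"tukey:{spec[1]}"
            else:
                vals = data.values.mean(axis=2)
                prefix = "tukey"
            out.extend(tukey_hsd_rm(vals, data.rois, prefix=prefix))
        else:
            raise ValidationError(f"unknown post-hoc test kind {kind!r}")
    return out
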