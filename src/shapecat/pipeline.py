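"""End-to-end orchestration: fixture tree in, result tree out.

A fixture tree is the on-disk layout written by ``shapecat simulate`` (and
the adapter point for real data — any source of conditions × units matrices
can populate it)::

    design.csv                 condition_id, shape, category
    models/shape.csv           continuous or binary model RDMs (optional;
    models/category.csv        binary design models are built if absent)
    layers/layer00.csv ...     one pattern matrix per layer, depth-ordered
    subjects/sub01__V1.csv ... one pattern matrix per subject × ROI
    images/<condition>.png     grayscale stimuli (optional; GIST audit)

``run_pipeline`` executes model construction → layer and ROI profiling →
ANOVAs → post-hoc tests → MDS and writes delimited tables plus a JSON
summary carrying the config, seed and package version.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compare import permutation_test
from .design import StimulusDesign
from .exceptions import ShapecatError
from .io import (
    align_patterns_to_design,
    align_to_design,
    read_design,
    read_pattern_matrix,
    read_rdm,
    write_rdm,
)
from .mds import classical_mds
from .profiling import (
    SubjectRoiProfile,
    brain_layer_profile,
    layer_condition_anova,
    layer_profile,
    models_are_dependent,
    partialled_brain_layer_profile,
    posthoc_tests,
    roi_condition_anova,
)
from .rdm import RDM, compute_rdm, model_rdm
from .compare import partial_spearman_rdm, spearman_rdm

log = logging.getLogger("shapecat")


@dataclass(frozen=True)
class RunConfig:
    fixture_dir: str
    out_dir: str
    alpha: float = 0.05
    n_perm: int = 1000
    seed: int = 0
    network_tag: str = "synthetic"

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ShapecatError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_perm < 1:
            raise ShapecatError(f"n_perm must be ≥ 1, got {self.n_perm}")


def _load_models(fixture: Path, design: StimulusDesign) -> dict[str, RDM]:
    models = {}
    for factor in ("shape", "category"):
        path = fixture / "models" / f"{factor}.csv"
        if path.exists():
            models[factor] = align_to_design(read_rdm(path), design)
            log.info("loaded %s model RDM from %s", factor, path)
        else:
            models[factor] = model_rdm(design, factor)
            log.info("built binary %s model RDM from the design", factor)
    return models


def _load_layers(fixture: Path, design: StimulusDesign):
    layer_dir = fixture / "layers"
    paths = sorted(layer_dir.glob("*.csv"))
    if not paths:
        raise ShapecatError(f"stage layers: no layer matrices under {layer_dir}")
    rdms = []
    for p in paths:
        pm = align_patterns_to_design(read_pattern_matrix(p), design)
        rdms.append(compute_rdm(pm))
    return [p.stem for p in paths], rdms


def _load_subjects(fixture: Path, design: StimulusDesign):
    sub_dir = fixture / "subjects"
    grid: dict[str, dict[str, RDM]] = {}
    for p in sorted(sub_dir.glob("*.csv")):
        stem = p.stem
        if "__" not in stem:
            raise ShapecatError(
                f"stage subjects: cannot parse subject/ROI from {p.name}; "
                "expected <subject>__<roi>.csv")
        sub, roi = stem.split("__", 1)
        pm = align_patterns_to_design(read_pattern_matrix(p), design)
        grid.setdefault(sub, {})[roi] = compute_rdm(pm)
    return grid


def _roi_model_profile(grid, models, dependent: bool) -> SubjectRoiProfile:
    subjects = tuple(grid)
    rois = tuple(grid[subjects[0]])
    vals = np.empty((len(subjects), len(rois), 2))
    for si, s in enumerate(subjects):
        for ri, r in enumerate(rois):
            brdm = grid[s][r]
            if dependent:
                vals[si, ri, 0] = partial_spearman_rdm(
                    brdm, models["shape"], [models["category"]]).rho
                vals[si, ri, 1] = partial_spearman_rdm(
                    brdm, models["category"], [models["shape"]]).rho
            else:
                vals[si, ri, 0] = spearman_rdm(brdm, models["shape"]).rho
                vals[si, ri, 1] = spearman_rdm(brdm, models["category"]).rho
    return SubjectRoiProfile(subjects, rois, ("shape", "category"), vals,
                             method="partial" if dependent else "plain")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis on a fixture tree; returns the summary dict."""
    fixture = Path(config.fixture_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config": dataclasses.asdict(config),
        "version": __version__,
    }

    log.info("stage design: reading %s", fixture / "design.csv")
    design = read_design(fixture / "design.csv")
    models = _load_models(fixture, design)

    dep = models_are_dependent(models["shape"], models["category"],
                               n_perm=config.n_perm, seed=config.seed,
                               alpha=config.alpha)
    summary["models_dependent"] = bool(dep)
    dep_rho = spearman_rdm(models["shape"], models["category"]).rho
    summary["model_dependency_rho"] = dep_rho
    log.info("stage models: shape–category rho = %.4f (dependent: %s)", dep_rho, dep)

    # --- layer profiling -------------------------------------------------
    layer_tags, layer_rdms = _load_layers(fixture, design)
    log.info("stage layers: %d layer RDMs (n_perm=%d, alpha=%g)",
             len(layer_rdms), config.n_perm, config.alpha)
    prof = layer_profile(layer_rdms, models["shape"], models["category"],
                         n_perm=config.n_perm, seed=config.seed,
                         alpha=config.alpha, network_tag=config.network_tag)
    pd.DataFrame({
        "layer": layer_tags,
        "layer_index": prof.layer_index,
        "rho_shape": prof.rho_shape,
        "rho_category": prof.rho_category,
        "significant_shape": prof.significant_shape,
        "significant_category": prof.significant_category,
        "threshold_shape": prof.threshold_shape,
        "threshold_category": prof.threshold_category,
    }).to_csv(out / "layer_profile.csv", index=False)
    anova_layers = layer_condition_anova(prof)
    pd.DataFrame(anova_layers.to_records()).to_csv(
        out / "layer_condition_anova.csv", index=False)
    summary["layer_profile"] = {
        "method": prof.method,
        "peak_layer_category": prof.argmax_layer("category"),
        "peak_layer_shape": prof.argmax_layer("shape"),
        "category_peaks_at_final_layer":
            prof.argmax_layer("category") == prof.layer_index[-1],
        "anova": anova_layers.to_records(),
    }

    # --- subject / ROI profiling -----------------------------------------
    grid = _load_subjects(fixture, design)
    if grid:
        log.info("stage subjects: %d subjects × %d ROIs",
                 len(grid), len(next(iter(grid.values()))))
        roi_prof = _roi_model_profile(grid, models, dep)
        mean = roi_prof.group_mean()
        sem = roi_prof.sem()
        pd.DataFrame({
            "roi": np.repeat(roi_prof.rois, 2),
            "condition": list(roi_prof.measure_names) * len(roi_prof.rois),
            "mean_rho": mean.ravel(),
            "sem": sem.ravel(),
        }).to_csv(out / "roi_profile.csv", index=False)
        roi_anova = roi_condition_anova(roi_prof)
        pd.DataFrame(roi_anova.to_records()).to_csv(
            out / "roi_condition_anova.csv", index=False)
        tests = [("paired_t", roi_prof.rois[0], "shape", "category"),
                 ("paired_t", roi_prof.rois[-1], "shape", "category"),
                 ("tukey_rois",)]
        post = posthoc_tests(roi_prof, tests)
        pd.DataFrame([dataclasses.asdict(t) for t in post]).to_csv(
            out / "posthoc_tests.csv", index=False)
        summary["roi_profile"] = {
            "rois": list(roi_prof.rois),
            "anova": roi_anova.to_records(),
        }

        bl = brain_layer_profile(grid, layer_rdms,
                                 layer_tags=tuple(layer_tags))
        gm = bl.profile.group_mean()
        sem = bl.profile.sem()
        rows = []
        for ri, roi in enumerate(bl.profile.rois):
            for li, tag in enumerate(bl.profile.measure_names):
                rows.append({"roi": roi, "layer": tag,
                             "mean_rho": gm[ri, li], "sem": sem[ri, li]})
        pd.DataFrame(rows).to_csv(out / "brain_layer_profile.csv", index=False)
        if bl.anova is not None:
            pd.DataFrame(bl.anova.to_records()).to_csv(
                out / "brain_layer_anova.csv", index=False)
        summary["brain_layer"] = {
            "peak_layer": bl.peak_layer,
            "anova": bl.anova.to_records() if bl.anova else None,
        }

        for control_name in ("shape", "category"):
            pprof = partialled_brain_layer_profile(
                grid, layer_rdms, models[control_name],
                layer_tags=tuple(layer_tags))
            gm = pprof.group_mean()
            sem = pprof.sem()
            rows = []
            for ri, roi in enumerate(pprof.rois):
                for li, tag in enumerate(pprof.measure_names):
                    rows.append({"roi": roi, "layer": tag,
                                 "mean_rho": gm[ri, li], "sem": sem[ri, li]})
            pd.DataFrame(rows).to_csv(
                out / f"brain_layer_partial_{control_name}.csv", index=False)

    # --- MDS at the peak layers ------------------------------------------
    peak = int(np.argmax(prof.rho_category))
    emb = classical_mds(layer_rdms[peak], d=2)
    pd.DataFrame({
        "condition": emb.conditions,
        "shape": design.shape_labels,
        "category": design.category_labels,
        "dim1": emb.coordinates[:, 0],
        "dim2": emb.coordinates[:, 1],
    }).to_csv(out / "mds_peak_category_layer.csv", index=False)
    summary["mds"] = {
        "layer": layer_tags[peak],
        "stress": emb.stress,
        "negative_eigenvalue_mass": emb.negative_eigenvalue_mass,
    }
    for factor in ("shape", "category"):
        write_rdm(models[factor], out / f"model_{factor}_rdm.csv")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonify)
    log.info("pipeline complete; results under %s", out)
    return summary


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
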