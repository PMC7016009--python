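"""Delimited-text readers/writers for designs, pattern matrices and RDMs.

All on-disk formats are plain delimited text (comma or tab, auto-detected)
for inspectability — the matrices are small (N ≤ 54 conditions).

* Design table: columns ``condition_id, shape, category``.
* Pattern matrix: header row of condition ids; one data row per measurement
  unit (the file stores units × conditions; reading transposes back).
* RDM: header row of condition ids and the same ids as a first column;
  symmetrised on read when asymmetry is within tolerance, rejected otherwise.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .design import StimulusDesign
from .exceptions import ParseError, ValidationError
from .rdm import RDM, SYMMETRY_TOL, PatternMatrix


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    try:
        return pd.read_csv(path, sep=_sniff_sep(path), **kwargs)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_design(path: str | Path) -> StimulusDesign:
    df = _read_table(path)
    required = {"condition_id", "shape", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return StimulusDesign(df["condition_id"].astype(str).tolist(),
                          df["shape"].astype(str).tolist(),
                          df["category"].astype(str).tolist())


def write_design(design: StimulusDesign, path: str | Path) -> None:
    pd.DataFrame({
        "condition_id": design.condition_ids,
        "shape": design.shape_labels,
        "category": design.category_labels,
    }).to_csv(path, index=False)


def _numeric_values(df: pd.DataFrame, path) -> np.ndarray:
    """Coerce a frame to floats; name the first offending cell on failure."""
    coerced = df.apply(pd.to_numeric, errors="coerce")
    values = coerced.to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ParseError(
            f"{path}: non-numeric or missing cell at data row {i + 1}, "
            f"column {df.columns[j]!r}")
    return values


def _check_unique_header(path: Path) -> None:
    # pandas mangles duplicate column names on read; inspect the raw header
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    sep = "\t" if "\t" in header else ","
    cols = header.split(sep)
    if len(set(cols)) != len(cols):
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        raise ParseError(f"{path}: duplicate condition ids in header: {dupes}")


def read_pattern_matrix(path: str | Path, source_tag: str | None = None) -> PatternMatrix:
    _check_unique_header(Path(path))
    df = _read_table(path)
    conditions = [str(c) for c in df.columns]
    values = _numeric_values(df, path).T  # conditions × units
    tag = source_tag if source_tag is not None else Path(path).stem
    try:
        return PatternMatrix(conditions, values, source_tag=tag)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_pattern_matrix(pm: PatternMatrix, path: str | Path) -> None:
    pd.DataFrame(pm.values.T, columns=list(pm.conditions)).to_csv(path, index=False)


def read_rdm(path: str | Path, metric_tag: str = "external") -> RDM:
    df = _read_table(path, index_col=0)
    conditions = [str(c) for c in df.columns]
    row_ids = [str(r) for r in df.index]
    if row_ids != conditions:
        raise ParseError(
            f"{path}: RDM row ids must equal column ids in the same order")
    values = _numeric_values(df, path)
    asym = np.abs(values - values.T).max(initial=0.0)
    if asym > max(SYMMETRY_TOL, 1e-9):
        raise ParseError(
            f"{path}: RDM asymmetric beyond tolerance (max |M−Mᵀ| = {asym:.3g})")
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    try:
        return RDM(conditions, values, metric_tag=metric_tag)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_rdm(rdm: RDM, path: str | Path) -> None:
    pd.DataFrame(rdm.values, index=list(rdm.conditions),
                 columns=list(rdm.conditions)).to_csv(path)


def align_to_design(rdm: RDM, design: StimulusDesign) -> RDM:
    """Canonicalise an RDM's condition order to the design's order."""
    if set(rdm.conditions) != set(design.condition_ids):
        extra = sorted(set(rdm.conditions) - set(design.condition_ids))
        missing = sorted(set(design.condition_ids) - set(rdm.conditions))
        raise ValidationError(
            f"RDM conditions do not match design (extra: {extra[:3]}, "
            f"missing: {missing[:3]})")
    pos = {c: i for i, c in enumerate(rdm.conditions)}
    order = [pos[c] for c in design.condition_ids]
    return rdm.permuted(order)


def align_patterns_to_design(pm: PatternMatrix, design: StimulusDesign) -> PatternMatrix:
    """Canonicalise a pattern matrix's row order to the design's order."""
    if set(pm.conditions) != set(design.condition_ids):
        raise ValidationError(
            f"pattern conditions do not match design for {pm.source_tag!r}")
    pos = {c: i for i, c in enumerate(pm.conditions)}
    order = [pos[c] for c in design.condition_ids]
    return PatternMatrix(design.condition_ids, pm.values[order],
                         source_tag=pm.source_tag)
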