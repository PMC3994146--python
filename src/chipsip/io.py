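"""Readers and writers for probe-spot tables, Newick trees and result files.

The probe-spot table is the central external format: one row per microarray
spot with probe id, taxon (OTU) id, treatment level (H/M/L), fluorescence,
and either a delta 15N value (permil) or raw 12C14N-/12C15N- ion counts.
Column names are mapped, not hard-coded, so externally deposited matrices can
be adapted via the ``columns`` argument rather than by editing code.
"""

from __future__ import annotations

import os
from typing import Mapping, Optional, Sequence

import dendropy
import pandas as pd

from .config import TREATMENTS
from .errors import FormatError, ValidationError

#: Default column-name mapping: internal field -> column name in the file.
DEFAULT_COLUMNS = {
    "probe_id": "probe",
    "taxon_id": "taxon",
    "treatment": "treatment",
    "fluorescence": "fluor",
    "delta_permil": "delta",
    "count_14N": "c14n",
    "count_15N": "c15n",
}

REQUIRED_FIELDS = ("probe_id", "taxon_id", "treatment", "fluorescence")
OPTIONAL_FIELDS = ("delta_permil", "count_14N", "count_15N")


def _infer_sep(path: str, sep: Optional[str]) -> str:
    if sep is not None:
        return sep
    ext = os.path.splitext(str(path))[1].lower()
    return "," if ext == ".csv" else "\t"


def read_probe_table(
    path: str,
    columns: Optional[Mapping[str, str]] = None,
    sep: Optional[str] = None,
) -> pd.DataFrame:
    """Read and validate a probe-spot table.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    columns
        Mapping from internal field names (``probe_id``, ``taxon_id``,
        ``treatment``, ``fluorescence``, ``delta_permil``, ``count_14N``,
        ``count_15N``) to the column names used in the file. Unspecified
        fields fall back to :data:`DEFAULT_COLUMNS`.
    sep
        Field delimiter; inferred from the extension when omitted
        (``.csv`` -> comma, otherwise tab).

    Returns
    -------
    DataFrame with internal column names, ``treatment`` as an ordered
    categorical H > M > L, validated row by row.

    Raises
    ------
    FormatError
        If a required column is missing.
    ValidationError
        If any row violates a schema invariant; the message lists the
        offending row numbers (1-based, excluding the header).
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        unknown = set(columns) - set(DEFAULT_COLUMNS)
        if unknown:
            raise FormatError(f"unknown field names in column mapping: {sorted(unknown)}")
        colmap.update(columns)

    try:
        raw = pd.read_csv(path, sep=_infer_sep(path, sep))
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc

    missing = [colmap[f] for f in REQUIRED_FIELDS if colmap[f] not in raw.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; present: {list(raw.columns)}"
        )

    rename = {colmap[f]: f for f in REQUIRED_FIELDS + OPTIONAL_FIELDS if colmap[f] in raw.columns}
    df = raw.rename(columns=rename)[list(rename.values())].copy()
    for f in OPTIONAL_FIELDS:
        if f not in df.columns:
            df[f] = pd.NA
    return validate_probe_table(df, source=str(path))


def validate_probe_table(df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    """Validate a probe-spot DataFrame in internal column layout.

    Checks every schema invariant and reports all offending rows at once:
    treatment in {H,M,L}; fluorescence finite and nonnegative; each row has
    a delta value or both ion counts; counts nonnegative; probe ids unique
    within (taxon, treatment).
    """
    problems: list[str] = []
    df = df.copy()

    bad_treat = ~df["treatment"].astype(str).isin(TREATMENTS)
    if bad_treat.any():
        rows = (df.index[bad_treat] + 1).tolist()
        problems.append(f"treatment not in {{H,M,L}} at row(s) {rows}")

    fluor = pd.to_numeric(df["fluorescence"], errors="coerce")
    bad_fluor = fluor.isna() | (fluor < 0)
    if bad_fluor.any():
        rows = (df.index[bad_fluor] + 1).tolist()
        problems.append(f"fluorescence missing or negative at row(s) {rows}")
    df["fluorescence"] = fluor

    delta = pd.to_numeric(df["delta_permil"], errors="coerce")
    c14 = pd.to_numeric(df["count_14N"], errors="coerce")
    c15 = pd.to_numeric(df["count_15N"], errors="coerce")
    no_measurement = delta.isna() & (c14.isna() | c15.isna())
    if no_measurement.any():
        rows = (df.index[no_measurement] + 1).tolist()
        problems.append(
            f"neither delta_permil nor both ion counts present at row(s) {rows}"
        )
    bad_counts = (c14 < 0) | (c15 < 0)
    if bad_counts.any():
        rows = (df.index[bad_counts] + 1).tolist()
        problems.append(f"negative ion count at row(s) {rows}")
    df["delta_permil"] = delta
    df["count_14N"] = c14
    df["count_15N"] = c15

    dup = df.duplicated(subset=["taxon_id", "treatment", "probe_id"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 1).tolist()
        problems.append(
            f"duplicate probe_id within (taxon, treatment) at row(s) {rows}"
        )

    if problems:
        raise ValidationError(f"{source}: " + "; ".join(problems))

    df["treatment"] = pd.Categorical(df["treatment"], categories=list(TREATMENTS), ordered=True)
    df["probe_id"] = df["probe_id"].astype(str)
    df["taxon_id"] = df["taxon_id"].astype(str)
    return df.reset_index(drop=True)


def write_probe_table(df: pd.DataFrame, path: str, sep: str = "\t") -> None:
    """Write a probe table in the default column layout (lossless TSV)."""
    out = df.rename(columns=DEFAULT_COLUMNS)
    out.to_csv(path, sep=sep, index=False)


def read_tree(path_or_string: str) -> dendropy.Tree:
    """Read a Newick tree of the targeted OTUs.

    The tree is treated as unrooted downstream; branch lengths are ignored
    by the parsimony machinery. Accepts a file path or a raw Newick string.

    Raises
    ------
    FormatError
        On unparseable Newick.
    ValidationError
        On duplicate or missing leaf labels.
    """
    s = str(path_or_string)
    try:
        if os.path.exists(s):
            tree = dendropy.Tree.get(path=s, schema="newick",
                                     suppress_internal_node_taxa=True)
        else:
            tree = dendropy.Tree.get(data=s, schema="newick",
                                     suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parse error types
        if "uplicate taxon label" in str(exc):
            raise ValidationError(f"duplicate leaf labels in tree: {exc}") from exc
        raise FormatError(f"could not parse Newick input: {exc}") from exc

    labels = [lf.taxon.label if lf.taxon else None for lf in tree.leaf_node_iter()]
    if any(l is None for l in labels):
        raise ValidationError("tree has unlabeled leaves")
    seen: set[str] = set()
    dups = sorted({l for l in labels if l in seen or seen.add(l)})
    if dups:
        raise ValidationError(f"duplicate leaf labels in tree: {dups}")
    tree.is_rooted = False
    return tree


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    """Labels of all leaves, in tree traversal order."""
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


RESULT_COLUMNS = [
    "taxon_id",
    "hce_H", "se_H", "enriched_H",
    "hce_M", "se_M", "enriched_M",
    "hce_L", "se_L", "enriched_L",
    "activity", "guild", "ancova_p",
    "w_H", "w_M", "w_L",
]


def write_results(results_table: pd.DataFrame, path: str) -> None:
    """Write the per-taxon results table (one row per taxon) as UTF-8 TSV.

    Columns follow :data:`RESULT_COLUMNS`; absent columns are emitted empty
    so the file schema is stable across degraded runs.
    """
    out = results_table.copy()
    for col in RESULT_COLUMNS:
        if col not in out.columns:
            out[col] = pd.NA
    out = out[RESULT_COLUMNS]
    out.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_results(path: str) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
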