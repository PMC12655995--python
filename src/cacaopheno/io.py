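"""Readers and writers for trial tables, panels and result bundles.

All formats are plain text: CSV/TSV for tables, JSON for the trait catalog,
Newick for dendrograms.  Quantitative values round-trip at full float
precision (`repr` serialization); report-shaped tables are additionally
rounded to two decimals for display parity with conventional germplasm
reports.
"""

from __future__ import annotations

import logging
import os
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import to_tree

from .catalog import TraitCatalog, default_catalog
from .tables import (
    TRIAL_COLUMNS,
    PhytochemPanel,
    TrialTable,
    ValidationError,
)

log = logging.getLogger(__name__)


def _read_delim(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    kw = dict(dtype={"value": object}, float_precision="round_trip")
    df = pd.read_csv(path, sep=sep, **kw)
    if df.shape[1] == 1 and sep == ",":  # tab-delimited despite .csv suffix
        df = pd.read_csv(path, sep="\t", **kw)
    return df


def read_trial(path, catalog: Optional[TraitCatalog] = None) -> TrialTable:
    """Read a long-format trial CSV/TSV and validate it against the catalog.

    Required columns: accession, replicate, season, descriptor, value.
    Quantitative values are parsed as floats; rows whose value fails to parse
    are dropped with a logged report.
    """
    catalog = catalog or default_catalog()
    if os.path.getsize(path) == 0:
        raise ValidationError(f"empty file: {path}")
    df = _read_delim(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    unknown = sorted(set(df["descriptor"]) - set(catalog.acronyms))
    if unknown:
        raise ValidationError(f"{path}: unknown descriptors {unknown}")

    quant = {t.acronym for t in catalog.quantitative()}
    is_quant = df["descriptor"].isin(quant)

    def _float(v):  # exact round-trip parsing (python float, not fast-path)
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    parsed = df.loc[is_quant, "value"].map(_float)
    bad = parsed.index[parsed.isna()]
    if len(bad):
        log.warning("%s: dropped %d unparseable quantitative rows", path, len(bad))
        df = df.drop(index=bad)
        parsed = parsed.drop(index=bad)
    df = df.copy()
    df.loc[parsed.index, "value"] = parsed.astype(float)
    df["season"] = df["season"].astype(int)
    df["accession"] = df["accession"].astype(str)
    df["replicate"] = df["replicate"].astype(str)
    return TrialTable(df[TRIAL_COLUMNS], catalog=catalog)


def write_trial(trial: TrialTable, path) -> None:
    """Write a trial table; floats serialized at full precision."""
    df = trial.data.copy()
    df["value"] = df["value"].astype(object)
    quant = {t.acronym for t in trial.catalog.quantitative()}
    is_quant = df["descriptor"].isin(quant)
    df.loc[is_quant, "value"] = df.loc[is_quant, "value"].map(
        lambda v: repr(float(v))
    )
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index=False)


def read_panel(path) -> PhytochemPanel:
    df = _read_delim(path)
    for c in df.columns:
        if c not in ("accession", "replicate"):
            df[c] = pd.to_numeric(df[c], errors="coerce")
    return PhytochemPanel(df)


def write_panel(panel: PhytochemPanel, path) -> None:
    panel.data.to_csv(path, index=False)


# -- dendrogram export -----------------------------------------------------


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string.

    Branch lengths are differences of merge heights, so the root-to-leaf path
    length of every leaf equals the root merge height (ultrametric tree).
    """
    tree = to_tree(Z)

    def build(node, parent_height):
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height - 0.0:.10g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    left = build(tree.left, tree.dist)
    right = build(tree.right, tree.dist)
    return f"({left},{right});"


def write_outputs(tables: dict, outdir, newick: Optional[str] = None) -> list[str]:
    """Write named result DataFrames as CSVs (plus an optional Newick tree).

    Returns the list of file paths written.  An empty ``tables`` dict writes
    nothing and logs a warning.
    """
    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []
    if not tables and newick is None:
        log.warning("write_outputs called with no result tables")
        return written
    for name, df in tables.items():
        path = os.path.join(outdir, f"{name}.csv")
        if isinstance(df, pd.Series):
            df = df.to_frame()
        df.to_csv(path, index=not isinstance(df.index, pd.RangeIndex))
        written.append(path)
    if newick is not None:
        path = os.path.join(outdir, "dendrogram.nwk")
        with open(path, "w") as fh:
            fh.write(newick + "\n")
        written.append(path)
    return written
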