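"""Protein/mRNA differential-table integration and translational-target classes.

The operational signature of codon-dependent translational regulation is a
gene whose protein level changes significantly while its mRNA does not.  Each
gene present in both layers is assigned exactly one class:

==================  =========================================================
translational_down  protein significantly down, mRNA not significant
translational_up    protein significantly up, mRNA not significant
concordant          both layers significant with the same log2FC sign
mrna_only           mRNA significant, protein not
unchanged           neither layer significant
unclassified        both significant with opposite signs
==================  =========================================================

Significance means BH-adjusted p < alpha and \\|log2FC\\| > fc_threshold
(defaults alpha=0.05, fc_threshold=0).  Treating "mRNA did not change" as
non-significance is a convenience, not an equivalence test — see the methods
note for the limitation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

Layer = Literal["protein", "mrna"]

CLASSES = (
    "translational_down",
    "translational_up",
    "concordant",
    "mrna_only",
    "unchanged",
    "unclassified",
)

DEFAULT_COLUMNS = {"gene": "gene_id", "log2fc": "log2fc", "p": "p_value"}


@dataclass(frozen=True)
class DifferentialRecord:
    """One gene's differential statistics in one layer."""

    gene_id: str
    layer: Layer
    log2fc: float
    p_value: float
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"{self.gene_id}: p_value {self.p_value} outside [0,1]")
        if self.p_adjusted is not None and not 0.0 <= self.p_adjusted <= 1.0:
            raise ValueError(f"{self.gene_id}: p_adjusted outside [0,1]")


class DuplicateGeneError(ValueError):
    """A layer table contains the same gene more than once."""


def read_differential_table(
    path: str | Path,
    layer: Layer,
    columns: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a tab-delimited differential table into a validated DataFrame.

    ``columns`` maps the logical names ``gene``/``log2fc``/``p`` to the file's
    header names.  Duplicate gene ids are fatal and named; rows with missing
    or non-numeric statistics are dropped with a logged count.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df.rename(
        columns={colmap["gene"]: "gene_id", colmap["log2fc"]: "log2fc",
                 colmap["p"]: "p_value"}
    )[["gene_id", "log2fc", "p_value"]]
    df["log2fc"] = pd.to_numeric(df["log2fc"], errors="coerce")
    df["p_value"] = pd.to_numeric(df["p_value"], errors="coerce")
    n_before = len(df)
    df = df.dropna()
    if n_before - len(df):
        logger.info("%s: dropped %d rows with missing/non-numeric values",
                    path, n_before - len(df))
    dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].unique()
    if len(dupes):
        raise DuplicateGeneError(
            f"{path}: duplicated gene_ids in {layer} layer: {sorted(dupes)}"
        )
    if ((df["p_value"] < 0) | (df["p_value"] > 1)).any():
        raise ValueError(f"{path}: p_value outside [0,1]")
    df["layer"] = layer
    return df.reset_index(drop=True)


def write_differential_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def adjust_pvalues(
    df: pd.DataFrame, method: Literal["bh", "none"] = "bh"
) -> pd.DataFrame:
    """Add a ``p_adjusted`` column (Benjamini–Hochberg step-up, or a copy)."""
    out = df.copy()
    if method == "bh":
        out["p_adjusted"] = multipletests(out["p_value"].to_numpy(),
                                          method="fdr_bh")[1]
    elif method == "none":
        out["p_adjusted"] = out["p_value"]
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return out


def _significant(df: pd.DataFrame, alpha: float, fc_threshold: float) -> pd.Series:
    return (df["p_adjusted"] < alpha) & (df["log2fc"].abs() > fc_threshold)


def classify_translational_targets(
    protein: pd.DataFrame,
    mrna: pd.DataFrame,
    sig_alpha: float = 0.05,
    fc_threshold: float = 0.0,
    adjust: Literal["bh", "none"] = "bh",
) -> pd.DataFrame:
    """Join the two layers on gene_id and assign one class per gene.

    Input frames need columns gene_id/log2fc/p_value (``p_adjusted`` is
    computed per layer if absent).  The join is inner on exact gene_id;
    unmatched genes are reported via the logger.  Returns a frame sorted by
    gene_id with per-layer statistics and a ``cls`` column.
    """
    frames = {}
    for name, df in (("protein", protein), ("mrna", mrna)):
        if "p_adjusted" not in df.columns:
            df = adjust_pvalues(df, adjust)
        frames[name] = df[["gene_id", "log2fc", "p_value", "p_adjusted"]].rename(
            columns={c: f"{name}_{c}" for c in ("log2fc", "p_value", "p_adjusted")}
        )
    joined = frames["protein"].merge(frames["mrna"], on="gene_id", how="inner")
    if joined.empty:
        raise ValueError("no genes shared between protein and mRNA layers")
    n_unmatched = len(protein) + len(mrna) - 2 * len(joined)
    if n_unmatched:
        logger.info("classify: %d unmatched rows dropped by inner join", n_unmatched)

    prot_sig = (joined["protein_p_adjusted"] < sig_alpha) & (
        joined["protein_log2fc"].abs() > fc_threshold
    )
    mrna_sig = (joined["mrna_p_adjusted"] < sig_alpha) & (
        joined["mrna_log2fc"].abs() > fc_threshold
    )
    prot_down = joined["protein_log2fc"] < 0
    same_sign = np.sign(joined["protein_log2fc"]) == np.sign(joined["mrna_log2fc"])

    cls = np.select(
        [
            prot_sig & ~mrna_sig & prot_down,
            prot_sig & ~mrna_sig & ~prot_down,
            prot_sig & mrna_sig & same_sign,
            prot_sig & mrna_sig & ~same_sign,
            ~prot_sig & mrna_sig,
        ],
        [
            "translational_down",
            "translational_up",
            "concordant",
            "unclassified",
            "mrna_only",
        ],
        default="unchanged",
    )
    joined["cls"] = pd.Categorical(cls, categories=CLASSES)
    return joined.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def class_counts(results: pd.DataFrame) -> pd.Series:
    """Per-class gene counts (all classes present, zero-filled)."""
    return results["cls"].value_counts().reindex(CLASSES, fill_value=0)


def intersect_signatures(
    set_a: Iterable[str], set_b: Iterable[str]
) -> dict[str, object]:
    """Exact set algebra for a two-way Venn: A∩B, A\\B, B\\A with sizes."""
    a, b = set(set_a), set(set_b)
    both, only_a, only_b = a & b, a - b, b - a
    return {
        "intersection": both,
        "a_only": only_a,
        "b_only": only_b,
        "sizes": (len(both), len(only_a), len(only_b)),
    }


def read_gene_set(path: str | Path) -> set[str]:
    """Gene-set list file: one id per line, blanks ignored."""
    return {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    }


def correlation_table(results: pd.DataFrame) -> dict[str, object]:
    """Summary of an integration run: class counts, Pearson r, volcano table.

    ``r`` is the Pearson correlation of protein vs mRNA log2FC over all joined
    genes; with fewer than 3 genes it is reported as NaN.  The volcano table
    carries gene, both log2FCs, −log10 adjusted p per layer and the class.
    """
    counts = class_counts(results)
    if len(results) >= 3:
        r = float(
            stats.pearsonr(results["protein_log2fc"], results["mrna_log2fc"])[0]
        )
    else:
        r = float("nan")
    with np.errstate(divide="ignore"):
        volcano = pd.DataFrame(
            {
                "gene_id": results["gene_id"],
                "protein_log2fc": results["protein_log2fc"],
                "mrna_log2fc": results["mrna_log2fc"],
                "protein_neglog10_padj": -np.log10(results["protein_p_adjusted"]),
                "mrna_neglog10_padj": -np.log10(results["mrna_p_adjusted"]),
                "cls": results["cls"],
            }
        )
    return {"class_counts": counts, "pearson_r": r, "volcano": volcano}
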