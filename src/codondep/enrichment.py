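"""Corpus-wide background model and per-gene codon-set enrichment z-scores.

The background is the distribution of per-gene codon-set frequency over an
entire CDS corpus, each gene weighted equally regardless of CDS length.  A
gene's enrichment is its frequency standardised against that background.

Two z modes are provided because the source formula standardises by the
*variance* of the background rather than its standard deviation — unusual for
a quantity called a z-score, and likely a slip for the SD, but we reproduce it
verbatim on request:

* ``sd`` (default):        z = (f_g − μ) / σ
* ``variance`` (verbatim): z = (f_g − μ) / σ²

The two are related exactly by z_var = z_sd / σ.  Because the transform is
positive monotone, rankings (and hence any top-N selection) are identical
between modes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

ZMode = Literal["sd", "variance"]
VarianceConvention = Literal["sample", "population"]


class DegenerateBackgroundError(ValueError):
    """The background has zero variance; z-scores are undefined."""


@dataclass(frozen=True)
class BackgroundModel:
    """Mean/variance/SD of per-gene codon-set frequency over a corpus."""

    codon_set: frozenset[str]
    n_genes: int
    mean_freq: float
    variance: float
    sd: float
    policy_tag: str = ""

    def __post_init__(self) -> None:
        if not math.isclose(self.sd**2, self.variance, rel_tol=1e-9, abs_tol=1e-15):
            raise ValueError("sd**2 does not equal variance")


@dataclass(frozen=True)
class CodonSetProfile:
    """One gene's codon-set frequency and its enrichment z-score."""

    gene_id: str
    freq: float
    z: float
    z_mode: ZMode = "sd"


def build_background(
    frequencies: Iterable[float] | Mapping[str, float],
    codon_set: Iterable[str] = (),
    variance_convention: VarianceConvention = "sample",
    policy_tag: str = "",
) -> BackgroundModel:
    """Summarise per-gene frequencies into a :class:`BackgroundModel`.

    Each gene contributes one value, weighted equally.  Requires at least two
    genes (variance undefined otherwise).  The variance convention (``sample``
    = n−1 denominator, ``population`` = n) is recorded in ``policy_tag``.
    """
    if isinstance(frequencies, Mapping):
        values = np.asarray(list(frequencies.values()), dtype=float)
    else:
        values = np.asarray(list(frequencies), dtype=float)
    if values.size < 2:
        raise ValueError("background requires at least 2 genes")
    ddof = 1 if variance_convention == "sample" else 0
    var = float(values.var(ddof=ddof))
    tag = f"variance={variance_convention};{policy_tag}" if policy_tag else (
        f"variance={variance_convention}"
    )
    return BackgroundModel(
        codon_set=frozenset(codon_set),
        n_genes=int(values.size),
        mean_freq=float(values.mean()),
        variance=var,
        sd=math.sqrt(var),
        policy_tag=tag,
    )


def zscore(freq: float, bg: BackgroundModel, z_mode: ZMode = "sd") -> float:
    """Standardise one frequency against the background.

    ``sd`` mode divides the centred frequency by σ (the standard z-score);
    ``variance`` mode divides by σ², reproducing the source formula verbatim.
    """
    if bg.variance <= 0.0:
        raise DegenerateBackgroundError(
            f"background over {bg.n_genes} genes has zero variance "
            f"(all frequencies identical); z-score undefined"
        )
    centred = freq - bg.mean_freq
    if z_mode == "sd":
        return centred / bg.sd
    if z_mode == "variance":
        return centred / bg.variance
    raise ValueError(f"unknown z mode {z_mode!r}")


def profile_table(
    freq_table: pd.DataFrame, bg: BackgroundModel
) -> pd.DataFrame:
    """Per-gene profile table with both z modes.

    ``freq_table`` needs columns ``gene_id`` and ``freq``.  Returns columns
    gene_id, freq, z_sd, z_var.
    """
    if bg.variance <= 0.0:
        raise DegenerateBackgroundError("zero-variance background")
    out = freq_table[["gene_id", "freq"]].copy()
    out["z_sd"] = (out["freq"] - bg.mean_freq) / bg.sd
    out["z_var"] = (out["freq"] - bg.mean_freq) / bg.variance
    return out


def background_frame(bg: BackgroundModel) -> pd.DataFrame:
    """Single-row summary table of a background model."""
    return pd.DataFrame(
        [
            {
                "codon_set": ",".join(sorted(bg.codon_set)),
                "n_genes": bg.n_genes,
                "mean_freq": bg.mean_freq,
                "variance": bg.variance,
                "sd": bg.sd,
                "policy_tag": bg.policy_tag,
            }
        ]
    )


def rank_top_n(
    profiles: pd.DataFrame | Sequence[CodonSetProfile],
    n: int,
    z_column: str = "z_sd",
) -> tuple[list[str], pd.DataFrame]:
    """Top-``n`` genes by enrichment z, with a heatmap-ready matrix.

    Sort order: z descending, frequency descending, then gene_id ascending —
    fully deterministic.  Returns the ordered gene ids and the corresponding
    gene × {freq, z} matrix.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(profiles, pd.DataFrame):
        profiles = pd.DataFrame(
            [{"gene_id": p.gene_id, "freq": p.freq, z_column: p.z} for p in profiles]
        )
    if profiles.empty:
        raise ValueError("no profiles to rank")
    ordered = profiles.sort_values(
        by=[z_column, "freq", "gene_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).head(n)
    matrix = ordered.set_index("gene_id")[["freq", z_column]]
    return list(ordered["gene_id"]), matrix
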