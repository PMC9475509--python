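"""Pipeline orchestration: count → enrich → integrate → rank, reproducibly.

A run consumes a flat config (YAML file and/or keyword overrides), executes
the four stages, writes every intermediate table as UTF-8 tab-delimited text,
and freezes a machine-readable manifest (resolved config, input checksums,
package version, per-stage row counts).  Identical inputs and config produce
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from codondep import codon_core, enrichment, omics_integration

logger = logging.getLogger(__name__)

STAGES = ("count", "enrich", "integrate", "rank")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception | str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Resolved, validated configuration of one pipeline run."""

    cds_fasta: str = ""
    protein_table: str = ""
    mrna_table: str = ""
    output_dir: str = "codondep_out"
    codon_set: list[str] = field(
        default_factory=lambda: sorted(codon_core.DEFAULT_U34_CODON_SET)
    )
    z_mode: str = "sd"
    variance_convention: str = "sample"
    transcript_policy: str = "longest"
    alpha: float = 0.05
    fc_threshold: float = 0.0
    adjust_method: str = "bh"
    top_n: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.z_mode not in ("sd", "variance"):
            raise ValueError(f"invalid z_mode {self.z_mode!r}")
        if self.variance_convention not in ("sample", "population"):
            raise ValueError(f"invalid variance_convention")
        if self.adjust_method not in ("bh", "none"):
            raise ValueError(f"invalid adjust_method {self.adjust_method!r}")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha outside (0,1]")
        if self.fc_threshold < 0 or self.top_n < 1:
            raise ValueError("fc_threshold must be >=0 and top_n >=1")
        self.codon_set = sorted(str(c).upper() for c in self.codon_set)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


@dataclass
class PipelineResult:
    """In-memory results of a run plus the paths of everything written."""

    config: PipelineConfig
    background: enrichment.BackgroundModel
    profiles: pd.DataFrame
    integration: pd.DataFrame
    top_genes: list[str]
    top_matrix: pd.DataFrame
    manifest: dict[str, Any]
    output_dir: Path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute count → enrich → integrate → rank and write the report bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": dataclasses.asdict(config),
        "version": _package_version(),
        "stages": {},
        "inputs": {},
        "complete": False,
    }
    codon_set = frozenset(config.codon_set)

    # -- count ---------------------------------------------------------------
    try:
        records, report = codon_core.read_cds_fasta(
            config.cds_fasta, transcript_policy=config.transcript_policy
        )
        manifest["inputs"]["cds_fasta"] = _sha256(Path(config.cds_fasta))
        tables = [codon_core.codon_counts(r) for r in records]
        freq = codon_core.frequency_table(tables, codon_set)
        _write_tsv(codon_core.counts_matrix(tables), out / "codon_counts.tsv",
                   index=True)
        _write_tsv(freq, out / "codon_set_frequency.tsv")
        (out / "validation_report.txt").write_text(report.to_text())
        manifest["stages"]["count"] = {"n_in": report.n_input, "n_out": len(freq)}
        logger.info("stage count: %d records in, %d genes out",
                    report.n_input, len(freq))
    except PipelineError:
        raise
    except Exception as exc:
        _abort(out, manifest, "count", exc)

    # -- enrich --------------------------------------------------------------
    try:
        bg = enrichment.build_background(
            dict(zip(freq["gene_id"], freq["freq"])),
            codon_set=codon_set,
            variance_convention=config.variance_convention,
            policy_tag=f"transcripts={config.transcript_policy}",
        )
        profiles = enrichment.profile_table(freq, bg)
        _write_tsv(enrichment.background_frame(bg), out / "background.tsv")
        _write_tsv(profiles, out / "profiles.tsv")
        manifest["stages"]["enrich"] = {"n_in": len(freq), "n_out": len(profiles)}
        logger.info("stage enrich: %d genes in, %d profiles out",
                    len(freq), len(profiles))
    except Exception as exc:
        _abort(out, manifest, "enrich", exc)

    # -- integrate -----------------------------------------------------------
    try:
        protein = omics_integration.read_differential_table(
            config.protein_table, "protein"
        )
        mrna = omics_integration.read_differential_table(config.mrna_table, "mrna")
        manifest["inputs"]["protein_table"] = _sha256(Path(config.protein_table))
        manifest["inputs"]["mrna_table"] = _sha256(Path(config.mrna_table))
        integration = omics_integration.classify_translational_targets(
            protein,
            mrna,
            sig_alpha=config.alpha,
            fc_threshold=config.fc_threshold,
            adjust=config.adjust_method,
        )
        _write_tsv(integration, out / "integration.tsv")
        manifest["stages"]["integrate"] = {
            "n_in": len(protein) + len(mrna),
            "n_out": len(integration),
        }
        logger.info("stage integrate: %d+%d rows in, %d joined genes out",
                    len(protein), len(mrna), len(integration))
    except Exception as exc:
        _abort(out, manifest, "integrate", exc)

    # -- rank ----------------------------------------------------------------
    try:
        z_col = "z_sd" if config.z_mode == "sd" else "z_var"
        down = integration.loc[
            integration["cls"] == "translational_down", "gene_id"
        ]
        candidate_profiles = profiles[profiles["gene_id"].isin(down)]
        if candidate_profiles.empty:
            top_genes: list[str] = []
            top_matrix = pd.DataFrame(columns=["freq", z_col]).rename_axis(
                "gene_id"
            )
        else:
            top_genes, top_matrix = enrichment.rank_top_n(
                candidate_profiles, config.top_n, z_column=z_col
            )
        _write_tsv(top_matrix, out / "top_genes.tsv", index=True)
        manifest["stages"]["rank"] = {
            "n_in": len(candidate_profiles),
            "n_out": len(top_genes),
        }
        logger.info("stage rank: %d candidates in, top %d out",
                    len(candidate_profiles), len(top_genes))
    except Exception as exc:
        _abort(out, manifest, "rank", exc)

    manifest["complete"] = True
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    result = PipelineResult(
        config=config,
        background=bg,
        profiles=profiles,
        integration=integration,
        top_genes=top_genes,
        top_matrix=top_matrix,
        manifest=manifest,
        output_dir=out,
    )
    (out / "summary.txt").write_text(write_report(result))
    return result


def _abort(out: Path, manifest: dict[str, Any], stage: str, exc: Exception):
    manifest["failed_stage"] = stage
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    raise PipelineError(stage, exc) from exc


def _package_version() -> str:
    from codondep import __version__

    return __version__


def write_report(result: PipelineResult) -> str:
    """Plain-text run summary: background, class counts, top-N listing."""
    counts = omics_integration.class_counts(result.integration)
    corr = omics_integration.correlation_table(result.integration)
    bg = result.background
    lines = [
        "codondep pipeline summary",
        "=========================",
        f"codon set            : {','.join(sorted(bg.codon_set))}",
        f"background genes     : {bg.n_genes}",
        f"background mean freq : {bg.mean_freq:.6f}",
        f"background SD        : {bg.sd:.6f}  (variance {bg.variance:.3e})",
        f"policy               : {bg.policy_tag}",
        "",
        "translational classes:",
    ]
    for cls, n in counts.items():
        lines.append(f"  {cls:<20s}: {n}")
    r = corr["pearson_r"]
    lines.append("")
    lines.append(f"protein~mRNA log2FC Pearson r: "
                 f"{'undefined' if pd.isna(r) else format(r, '.4f')}")
    lines.append("")
    lines.append(f"top {len(result.top_genes)} codon-enriched translational_down "
                 f"genes (z {result.config.z_mode} mode):")
    z_col = result.top_matrix.columns[-1] if len(result.top_matrix.columns) else ""
    for gid, row in result.top_matrix.iterrows():
        lines.append(f"  {gid:<12s} freq={row['freq']:.4f}  z={row[z_col]:+.3f}")
    if not result.top_genes:
        lines.append("  (none)")
    return "\n".join(lines) + "\n"
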