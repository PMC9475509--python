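"""CDS parsing, codon counting, codon-set frequencies, translation and recoding.

The unit of analysis is a coding sequence (CDS) as exported by Ensembl: frame 0
from the first base, ideally start codon through a single terminal stop.  Real
CDS dumps are imperfect — trailing partial codons, internal stops, ambiguous
bases — so parsing validates every record, flags recoverable defects and
reports hard rejections instead of silently dropping them.

Conventions (applied uniformly across the package):

* frame is always 0; no ORF scanning
* a trailing partial codon is trimmed, not fatal (``had_partial_tail``)
* the terminal stop codon is not a sense codon: stops are not decoded by an
  elongator tRNA, so they are excluded from ``total_sense``
* codons containing ``N`` are excluded from both the numerator and the
  denominator of any frequency (``ambiguous_codons``)
* input is case-insensitive and ``U`` is normalised to ``T``
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
BASES = "ACGT"
ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)
SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

#: the three codons whose decoding requires the mcm5s2 modification of U34
DEFAULT_U34_CODON_SET = frozenset({"AAA", "CAA", "GAA"})

_VALID_CHARS = re.compile(r"^[ACGTN]*$")


class CdsValidationError(ValueError):
    """A record failed hard CDS validation."""


@dataclass(frozen=True)
class CdsRecord:
    """One validated coding sequence.

    ``sequence`` is the retained, normalised sequence (uppercase, T not U,
    length a multiple of 3, trailing partial codon already trimmed).
    ``n_codons`` counts sense codons: the terminal stop, when present, is not
    one of them; N-containing codons are (they are subtracted later via
    ``ambiguous_codons``).
    """

    gene_id: str
    transcript_id: str
    sequence: str
    n_codons: int
    has_terminal_stop: bool = False
    had_partial_tail: bool = False
    internal_stop: bool = False
    ambiguous_codons: int = 0

    def sense_codons(self) -> list[str]:
        """In-frame codons excluding the terminal stop (N-codons included)."""
        end = len(self.sequence) - (3 if self.has_terminal_stop else 0)
        return [self.sequence[i : i + 3] for i in range(0, end, 3)]


@dataclass(frozen=True)
class CodonCountTable:
    """Per-gene codon counts over sense codons.

    ``counts`` covers the 64 standard codons; N-containing codons are excluded
    from both ``counts`` and ``total_sense``.  Internal stop codons, if the
    record carries any, are counted (and flagged upstream).
    """

    gene_id: str
    counts: Mapping[str, int]
    total_sense: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total_sense:
            raise ValueError(
                f"{self.gene_id}: counts sum {sum(self.counts.values())} "
                f"!= total_sense {self.total_sense}"
            )


class UndefinedFrequencyError(ZeroDivisionError):
    """Codon-set frequency requested for a gene with no countable codons."""


@dataclass(frozen=True)
class RecodingMap:
    """Synonymous codon replacement map, e.g. AAA→AAG, CAA→CAG, GAA→GAG.

    Every source→target pair must encode the same amino acid under the
    standard genetic code, and no target may itself be a source (acyclic), so
    applying the map twice equals applying it once.
    """

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        tbl = standard_dna_table.forward_table
        for src, dst in self.mapping.items():
            if src in STOP_CODONS or dst in STOP_CODONS:
                raise ValueError(f"stop codon in recoding pair {src}->{dst}")
            if src not in tbl or dst not in tbl:
                raise ValueError(f"invalid codon in recoding pair {src}->{dst}")
            if tbl[src] != tbl[dst]:
                raise ValueError(
                    f"non-synonymous recoding {src}({tbl[src]})->{dst}({tbl[dst]})"
                )
        sources = set(self.mapping)
        if sources & set(self.mapping.values()):
            raise ValueError("recoding map is cyclic: a target codon is also a source")


#: the construct-design map: replace U34-dependent codons by their G-ending
#: synonyms, which are decoded without the mcm5s2 U34 modification
DEFAULT_U34_RECODING = RecodingMap(
    mapping={"AAA": "AAG", "CAA": "CAG", "GAA": "GAG"}
)


@dataclass
class ValidationReport:
    """Per-file tally of what parsing retained, repaired and rejected."""

    n_input: int = 0
    n_retained: int = 0
    n_partial_tail: int = 0
    n_internal_stop: int = 0
    n_ambiguous_codons: int = 0
    rejected: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def to_text(self) -> str:
        lines = [
            "CDS validation report",
            f"  records in file        : {self.n_input}",
            f"  records retained       : {self.n_retained}",
            f"  records rejected       : {self.n_rejected}",
            f"  trailing partial tails : {self.n_partial_tail}",
            f"  internal stop codons   : {self.n_internal_stop}",
            f"  ambiguous (N) codons   : {self.n_ambiguous_codons}",
        ]
        for ident, reason in self.rejected:
            lines.append(f"  rejected {ident}: {reason}")
        return "\n".join(lines) + "\n"


def normalize_sequence(raw: str) -> str:
    """Uppercase, RNA→DNA.  Raises :class:`CdsValidationError` on other chars."""
    seq = raw.strip().upper().replace("U", "T")
    if not _VALID_CHARS.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise CdsValidationError(f"invalid characters {bad}")
    return seq


def build_record(
    gene_id: str,
    transcript_id: str,
    raw_sequence: str,
    strict: bool = False,
) -> CdsRecord:
    """Validate one sequence into a :class:`CdsRecord`.

    Raises :class:`CdsValidationError` for hard failures: invalid characters,
    fewer than one sense codon, or (in strict mode) internal stop codons.
    """
    seq = normalize_sequence(raw_sequence)
    tail = len(seq) % 3
    had_partial_tail = tail != 0
    if had_partial_tail:
        seq = seq[: len(seq) - tail]
    if len(seq) < 3:
        raise CdsValidationError("fewer than 3 nt after trimming")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    has_terminal_stop = codons[-1] in STOP_CODONS
    sense = codons[:-1] if has_terminal_stop else codons
    if not sense:
        raise CdsValidationError("no sense codons (stop-only sequence)")
    internal_stop = any(c in STOP_CODONS for c in sense)
    if strict and internal_stop:
        raise CdsValidationError("internal stop codon (strict mode)")
    ambiguous = sum("N" in c for c in sense)
    return CdsRecord(
        gene_id=gene_id,
        transcript_id=transcript_id,
        sequence=seq,
        n_codons=len(sense),
        has_terminal_stop=has_terminal_stop,
        had_partial_tail=had_partial_tail,
        internal_stop=internal_stop,
        ambiguous_codons=ambiguous,
    )


def default_header_policy(record_id: str, description: str) -> tuple[str, str]:
    """Parse ``(gene_id, transcript_id)`` from a FASTA header.

    The first whitespace-delimited token is the transcript id.  A ``gene:TAG``
    field anywhere in the description supplies the gene id; ``GENE|TRANSCRIPT``
    pipe headers are split; otherwise gene id falls back to the transcript id.
    """
    token = record_id
    m = re.search(r"gene:(\S+)", description)
    if m:
        return m.group(1), token
    if "|" in token:
        gene, _, transcript = token.partition("|")
        return gene, transcript or token
    return token, token


HeaderPolicy = Callable[[str, str], tuple[str, str]]


def regex_header_policy(pattern: str) -> HeaderPolicy:
    """Build a header policy from a regex with ``gene`` / ``transcript`` groups."""
    compiled = re.compile(pattern)

    def policy(record_id: str, description: str) -> tuple[str, str]:
        m = compiled.search(description) or compiled.search(record_id)
        if not m:
            raise CdsValidationError(f"header {record_id!r} does not match pattern")
        groups = m.groupdict()
        transcript = groups.get("transcript") or record_id
        gene = groups.get("gene") or transcript
        return gene, transcript

    return policy


def apply_transcript_policy(
    records: Sequence[CdsRecord], policy: str = "longest"
) -> list[CdsRecord]:
    """Collapse multiple transcripts per gene.

    ``longest`` keeps the longest CDS per gene (ties broken by transcript id,
    deterministic); ``all`` keeps everything; ``list:<path>`` keeps transcripts
    whose ids appear in the file (one per line).
    """
    if policy == "all":
        return list(records)
    if policy == "longest":
        best: dict[str, CdsRecord] = {}
        for rec in records:
            cur = best.get(rec.gene_id)
            if (
                cur is None
                or len(rec.sequence) > len(cur.sequence)
                or (len(rec.sequence) == len(cur.sequence)
                    and rec.transcript_id < cur.transcript_id)
            ):
                best[rec.gene_id] = rec
        return [best[g] for g in sorted(best)]
    if policy.startswith("list:"):
        keep = {
            line.strip()
            for line in Path(policy[5:]).read_text().splitlines()
            if line.strip()
        }
        return [r for r in records if r.transcript_id in keep]
    raise ValueError(f"unknown transcript policy {policy!r}")


def read_cds_fasta(
    path: str | Path,
    id_policy: HeaderPolicy | str | None = None,
    transcript_policy: str = "all",
    strict: bool = False,
) -> tuple[list[CdsRecord], ValidationReport]:
    """Read and validate a CDS FASTA file.

    Returns the retained records (after the transcript policy) and a
    :class:`ValidationReport`.  An unreadable or empty file is fatal; records
    failing hard validation are listed in the report with the reason.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if id_policy is None:
        policy: HeaderPolicy = default_header_policy
    elif isinstance(id_policy, str):
        policy = regex_header_policy(id_policy)
    else:
        policy = id_policy

    report = ValidationReport()
    records: list[CdsRecord] = []
    for seq_record in SeqIO.parse(str(path), "fasta"):
        report.n_input += 1
        gene_id, transcript_id = policy(seq_record.id, seq_record.description)
        try:
            rec = build_record(gene_id, transcript_id, str(seq_record.seq), strict)
        except CdsValidationError as exc:
            report.rejected.append((seq_record.id, str(exc)))
            continue
        records.append(rec)
        report.n_partial_tail += rec.had_partial_tail
        report.n_internal_stop += rec.internal_stop
        report.n_ambiguous_codons += rec.ambiguous_codons
    if report.n_input == 0:
        raise CdsValidationError(f"{path}: empty FASTA file")
    records = apply_transcript_policy(records, transcript_policy)
    report.n_retained = len(records)
    return records, report


def write_cds_fasta(records: Iterable[CdsRecord], path: str | Path) -> None:
    """Write records as FASTA with ``gene|transcript`` headers."""
    seq_records = [
        SeqRecord(
            Seq(rec.sequence),
            id=f"{rec.gene_id}|{rec.transcript_id}",
            description="",
        )
        for rec in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def codon_counts(record: CdsRecord) -> CodonCountTable:
    """Count in-frame sense codons; N-containing codons are excluded."""
    counts: Counter[str] = Counter(
        c for c in record.sense_codons() if "N" not in c
    )
    return CodonCountTable(
        gene_id=record.gene_id,
        counts=dict(counts),
        total_sense=record.n_codons - record.ambiguous_codons,
    )


def codon_set_frequency(table: CodonCountTable, codon_set: Iterable[str]) -> float:
    """Fraction of a gene's countable sense codons that belong to ``codon_set``."""
    codon_set = frozenset(codon_set)
    for c in codon_set:
        if c not in ALL_CODONS:
            raise ValueError(f"not a codon: {c!r}")
    if table.total_sense == 0:
        raise UndefinedFrequencyError(
            f"{table.gene_id}: no countable sense codons"
        )
    return sum(table.counts.get(c, 0) for c in codon_set) / table.total_sense


def translate(record: CdsRecord, include_stop: bool = False) -> str:
    """Standard-genetic-code translation, one letter per sense codon.

    N-containing codons become ``X``; stop codons (internal or, when
    ``include_stop`` is set, terminal) become ``*``.
    """
    end = len(record.sequence) if include_stop else (
        len(record.sequence) - (3 if record.has_terminal_stop else 0)
    )
    return str(Seq(record.sequence[:end]).translate())


def recode_synonymous(
    record: CdsRecord, rmap: RecodingMap = DEFAULT_U34_RECODING
) -> tuple[CdsRecord, dict[str, int]]:
    """Replace every source codon of ``rmap`` by its synonymous target.

    The terminal stop is untouched.  Returns the recoded record and a
    per-codon replacement count report.  The map is re-validated (fatal before
    any replacement if non-synonymous or cyclic — enforced by RecodingMap
    construction).
    """
    replaced: dict[str, int] = {src: 0 for src in rmap.mapping}
    new_codons = []
    for codon in record.sense_codons():
        if codon in rmap.mapping:
            replaced[codon] += 1
            codon = rmap.mapping[codon]
        new_codons.append(codon)
    seq = "".join(new_codons)
    if record.has_terminal_stop:
        seq += record.sequence[-3:]
    new_record = replace(record, sequence=seq)
    return new_record, replaced


def counts_matrix(tables: Sequence[CodonCountTable]) -> pd.DataFrame:
    """Gene × 64-codon count matrix (genes as rows, codons as columns)."""
    data = {
        t.gene_id: [t.counts.get(c, 0) for c in ALL_CODONS] for t in tables
    }
    return pd.DataFrame.from_dict(
        data, orient="index", columns=list(ALL_CODONS)
    ).rename_axis("gene_id")


def frequency_table(
    tables: Sequence[CodonCountTable], codon_set: Iterable[str]
) -> pd.DataFrame:
    """Per-gene codon-set frequency table with columns gene_id/total_sense/freq."""
    codon_set = frozenset(codon_set)
    rows = [
        {
            "gene_id": t.gene_id,
            "total_sense": t.total_sense,
            "freq": codon_set_frequency(t, codon_set),
        }
        for t in tables
    ]
    return pd.DataFrame(rows)
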