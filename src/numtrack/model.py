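"""Domain types and compilation I/O for NumtS annotation.

NumtS (Nuclear MiTochondrial Sequences) are fragments of the mitochondrial
genome that have integrated into nuclear chromosomes.  A *compilation* is the
annotated catalogue of NumtS loci for one species/genome build; each record
traces back to one or more High Scoring Pairs (HSPs) from the in silico
hybridization of the mitochondrial reference against the nuclear assembly.

Coordinate convention: all intervals are 0-based half-open (BED style);
SAM output uses the standard 1-based positions.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

__all__ = [
    "GenomicInterval",
    "ScoringScheme",
    "EValueParams",
    "HSP",
    "NumtSRecord",
    "Compilation",
    "CompilationError",
    "chrom_sort_key",
    "read_compilation",
    "write_compilation",
]

NUMTS_ID_RE = re.compile(r"^([A-Z][a-z]{2})_NumtS_(\d{3,})(?:_b(\d+))?$")

SPECIES_PREFIXES = ("Hsa", "Ptr", "Rhm", "Mms")


class CompilationError(ValueError):
    """Raised when a compilation file or record violates the format contract."""


def chrom_sort_key(chrom: str) -> tuple:
    """Natural chromosome order: chr1..chrN numeric, then X, Y, M, then others.

    Used for compilation sorting and sequential ID assignment.
    """
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    special = {"X": 1, "Y": 2, "M": 3, "MT": 3}
    if name.upper() in special:
        return (1, special[name.upper()], "")
    return (2, 0, name)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class ScoringScheme:
    """BlastN-style nucleotide scoring used for the in silico hybridization.

    Defaults are the protocol constants: +2 match, -3 mismatch, -5 gap open,
    -2 gap extension, with HSPs retained at E-value <= 1e-3.  A gap of
    length L scores ``gap_open + L * gap_extend`` (NCBI convention).
    """

    match_reward: int = 2
    mismatch_penalty: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    evalue_threshold: float = 1e-3

    def __post_init__(self) -> None:
        if self.match_reward <= 0:
            raise ValueError("match_reward must be positive")
        if self.mismatch_penalty >= 0:
            raise ValueError("mismatch_penalty must be negative")
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be positive")


@dataclass(frozen=True)
class EValueParams:
    """Karlin-Altschul parameters for E = K * m * n * exp(-lambda * S).

    lambda_ is in nats per score unit; K is the dimensionless search-space
    correction constant; m and n are the query and subject search-space
    lengths in bp.
    """

    lambda_: float
    K: float
    m: int = 1
    n: int = 1

    def __post_init__(self) -> None:
        if not (self.lambda_ > 0 and math.isfinite(self.lambda_)):
            raise ValueError("lambda_ must be finite and positive")
        if not (self.K > 0 and math.isfinite(self.K)):
            raise ValueError("K must be finite and positive")
        if self.m < 1 or self.n < 1:
            raise ValueError("search-space lengths m, n must be >= 1")

    def with_search_space(self, m: int, n: int) -> "EValueParams":
        return replace(self, m=m, n=n)


@dataclass(frozen=True)
class HSP:
    """One High Scoring Pair: a significant local alignment between the
    mitochondrial genome (query, coordinates always on its forward strand)
    and a nuclear chromosome.

    ``strand`` is the orientation of the nuclear hit relative to the mtDNA;
    nuclear coordinates are always on the chromosome forward strand.
    """

    mito: GenomicInterval
    nuclear: GenomicInterval
    strand: str
    raw_score: float
    percent_identity: float
    aln_length: int
    evalue: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 < self.percent_identity <= 100):
            raise ValueError(
                f"percent_identity must be in (0, 100], got {self.percent_identity}"
            )
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if self.aln_length < max(len(self.mito), len(self.nuclear)) - _GAP_SLACK:
            raise ValueError(
                "aln_length inconsistent with aligned interval lengths"
            )


# Alignment columns can never be fewer than the longer aligned span; a small
# slack is tolerated for records reconstructed from files that round lengths.
_GAP_SLACK = 0


def _weighted_identity(members: list[HSP]) -> float:
    total = sum(h.aln_length for h in members)
    return sum(h.percent_identity * h.aln_length for h in members) / total


@dataclass
class NumtSRecord:
    """One compilation entry: a NumtS locus, possibly assembled from several
    HSPs chained under the 2000 bp rule.

    ``numts_id`` follows the ``<prefix>_NumtS_<3 digits>`` convention; the
    browser track name appends ``_b<block_count>``.
    """

    numts_id: str
    species_prefix: str
    nuclear: GenomicInterval
    mito: GenomicInterval
    strand: str
    percent_identity: float
    bed_score: int
    members: list[HSP] = field(default_factory=list)
    block_count: int = 1
    via_repeat: bool = False

    def __post_init__(self) -> None:
        m = NUMTS_ID_RE.match(self.numts_id)
        if m is None:
            raise ValueError(f"malformed NumtS ID {self.numts_id!r}")
        if m.group(1) != self.species_prefix:
            raise ValueError(
                f"ID prefix {m.group(1)!r} != species prefix {self.species_prefix!r}"
            )
        if m.group(3) is not None and int(m.group(3)) != self.block_count:
            raise ValueError(
                f"ID suffix _b{m.group(3)} inconsistent with block_count "
                f"{self.block_count}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.bed_score <= 1000):
            raise ValueError("bed_score must be in [0, 1000]")
        if self.members:
            if len(self.members) != self.block_count:
                raise ValueError("block_count must equal number of member HSPs")
            for h in self.members:
                if h.nuclear.chrom != self.nuclear.chrom or h.strand != self.strand:
                    raise ValueError(
                        "members must share the record's chromosome and strand"
                    )
                if not (
                    self.nuclear.start <= h.nuclear.start
                    and h.nuclear.end <= self.nuclear.end
                ):
                    raise ValueError("nuclear span must cover every member")
                if not (
                    self.mito.start <= h.mito.start and h.mito.end <= self.mito.end
                ):
                    raise ValueError("mito span must cover every member")

    @property
    def base_id(self) -> str:
        """ID without any _b suffix."""
        m = NUMTS_ID_RE.match(self.numts_id)
        return f"{m.group(1)}_NumtS_{m.group(2)}"

    @property
    def track_name(self) -> str:
        """Browser track name: ID with explicit block-count suffix."""
        return f"{self.base_id}_b{self.block_count}"


@dataclass
class Compilation:
    """The annotated NumtS catalogue for one species and genome build."""

    species: str
    genome_build: str
    records: list[NumtSRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.numts_id in seen:
                raise CompilationError(f"duplicate NumtS ID {rec.numts_id}")
            seen.add(rec.numts_id)
        keys = [
            (chrom_sort_key(r.nuclear.chrom), r.nuclear.start) for r in self.records
        ]
        if keys != sorted(keys):
            raise CompilationError(
                "records must be sorted by (chromosome, nuclear start)"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


# ---------------------------------------------------------------------------
# Compilation TSV I/O
#
# Dialect: tab-separated, UTF-8, '#'-prefixed header, no quoting.  Metadata
# lines '##species=' and '##genome_build=' precede the column header.  The
# fragments column serializes every member HSP as
# nuclear_start-nuclear_end/mito_start-mito_end/percent_identity, ';'-joined,
# so assembled records round-trip with full per-fragment detail.
# ---------------------------------------------------------------------------

_COLUMNS = (
    "NumtS_ID",
    "HSP_NumtS_ID",
    "chrom",
    "strand",
    "nuclear_start",
    "nuclear_end",
    "mito_start",
    "mito_end",
    "percent_identity",
    "fragments",
)


def _format_fragments(rec: NumtSRecord) -> str:
    if not rec.members:
        return (
            f"{rec.nuclear.start}-{rec.nuclear.end}/"
            f"{rec.mito.start}-{rec.mito.end}/{rec.percent_identity:.2f}"
        )
    return ";".join(
        f"{h.nuclear.start}-{h.nuclear.end}/{h.mito.start}-{h.mito.end}/"
        f"{h.percent_identity:.2f}"
        for h in rec.members
    )


def _parse_fragments(text: str, chrom: str, strand: str, lineno: int) -> list[HSP]:
    members = []
    for part in text.split(";"):
        m = re.match(r"^(\d+)-(\d+)/(\d+)-(\d+)/([\d.]+)$", part)
        if m is None:
            raise CompilationError(f"line {lineno}: malformed fragment {part!r}")
        ns, ne, ms, me, pid = (
            int(m.group(1)),
            int(m.group(2)),
            int(m.group(3)),
            int(m.group(4)),
            float(m.group(5)),
        )
        members.append(
            HSP(
                mito=GenomicInterval("chrM", ms, me),
                nuclear=GenomicInterval(chrom, ns, ne),
                strand=strand,
                raw_score=float("nan"),
                percent_identity=pid,
                aln_length=max(ne - ns, me - ms),
            )
        )
    return members


def write_compilation(comp: Compilation, path) -> None:
    """Write a compilation TSV with deterministic column and sort order."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"##species={comp.species}\n")
        fh.write(f"##genome_build={comp.genome_build}\n")
        fh.write("#" + "\t".join(_COLUMNS) + "\n")
        for rec in comp.records:
            fh.write(
                "\t".join(
                    (
                        rec.numts_id,
                        rec.track_name,
                        rec.nuclear.chrom,
                        rec.strand,
                        str(rec.nuclear.start),
                        str(rec.nuclear.end),
                        str(rec.mito.start),
                        str(rec.mito.end),
                        f"{rec.percent_identity:.2f}",
                        _format_fragments(rec),
                    )
                )
                + "\n"
            )


def read_compilation(path) -> Compilation:
    """Read a compilation TSV written by :func:`write_compilation`.

    Raises :class:`CompilationError` naming the offending line on malformed
    rows, and on duplicate IDs or unsorted records.
    """
    species = ""
    build = ""
    records: list[NumtSRecord] = []
    header_seen = False
    from .tracks import bed_score  # local import avoids a cycle

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##species="):
                species = line.split("=", 1)[1]
                continue
            if line.startswith("##genome_build="):
                build = line.split("=", 1)[1]
                continue
            if line.startswith("#"):
                cols = tuple(line[1:].split("\t"))
                if cols != _COLUMNS:
                    raise CompilationError(
                        f"line {lineno}: unexpected header columns {cols}"
                    )
                header_seen = True
                continue
            if not header_seen:
                raise CompilationError(f"line {lineno}: missing header row")
            fields = line.split("\t")
            if len(fields) != len(_COLUMNS):
                raise CompilationError(
                    f"line {lineno}: expected {len(_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            (numts_id, _hsp_id, chrom, strand, ns, ne, ms, me, pid, frags) = fields
            if strand not in ("+", "-"):
                raise CompilationError(f"line {lineno}: invalid strand {strand!r}")
            m = NUMTS_ID_RE.match(numts_id)
            if m is None:
                raise CompilationError(
                    f"line {lineno}: malformed NumtS ID {numts_id!r}"
                )
            try:
                members = _parse_fragments(frags, chrom, strand, lineno)
                pid_f = float(pid)
                rec = NumtSRecord(
                    numts_id=numts_id,
                    species_prefix=m.group(1),
                    nuclear=GenomicInterval(chrom, int(ns), int(ne)),
                    mito=GenomicInterval("chrM", int(ms), int(me)),
                    strand=strand,
                    percent_identity=pid_f,
                    bed_score=bed_score(pid_f),
                    members=members,
                    block_count=len(members),
                )
            except (ValueError, CompilationError) as exc:
                raise CompilationError(f"line {lineno}: {exc}") from exc
            records.append(rec)
    return Compilation(species=species, genome_build=build, records=records)
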