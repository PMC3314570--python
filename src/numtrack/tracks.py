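"""Genome-browser track generation from a NumtS compilation.

Four track types are produced:

* "NumtS" — one BED6 line per HSP on its nuclear locus;
* "NumtS assembled" — one BED6 line per (possibly multi-block) record;
* "NumtS on mitochondrion" — every record projected onto the mtDNA (chrM);
* "NumtS on mitochondrion with mismatches" — a SAM file realigning each
  NumtS sequence to the mitochondrial reference, with CIGAR, NM and MD.

BED scores encode percent identity as ``round(10 * identity)`` capped at
1000 (the 0-1000 browser convention); SAM positions are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Compilation, GenomicInterval, NumtSRecord, ScoringScheme

__all__ = [
    "TrackRecord",
    "AlignmentDetail",
    "SuspectRecordError",
    "bed_score",
    "nuclear_track",
    "mito_track",
    "read_bed",
    "write_bed",
    "realign_to_mito",
    "mismatch_track_details",
    "write_sam",
]


class SuspectRecordError(ValueError):
    """Raised when a NumtS realigns to its mitochondrial window too poorly."""


@dataclass(frozen=True)
class TrackRecord:
    """One BED6 line (0-based half-open, score 0-1000)."""

    chrom: str
    start: int
    end: int
    name: str
    score: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid BED interval {self.start}-{self.end}")
        if not (0 <= self.score <= 1000):
            raise ValueError(f"BED score {self.score} outside [0, 1000]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def to_line(self) -> str:
        return (
            f"{self.chrom}\t{self.start}\t{self.end}\t{self.name}"
            f"\t{self.score}\t{self.strand}"
        )


@dataclass(frozen=True)
class AlignmentDetail:
    """Realignment of one NumtS to the mitochondrial reference (SAM fields).

    ``mito_pos`` is the 1-based leftmost reference position; minus-strand
    records carry flag 16 and ``seq`` in reference orientation.
    """

    numts_id: str
    mito_pos: int
    flag: int
    cigar: str
    nm: int
    md: str
    seq: str

    def __post_init__(self) -> None:
        if self.flag not in (0, 16):
            raise ValueError("flag must be 0 or 16")
        if self.mito_pos < 1:
            raise ValueError("mito_pos is 1-based")
        consumed = sum(n for n, op in _cigar_ops(self.cigar) if op in "MIS")
        if consumed != len(self.seq):
            raise ValueError("CIGAR M/I/S lengths must sum to sequence length")

    @property
    def reference_span(self) -> int:
        """Reference bases consumed (M + D)."""
        return sum(n for n, op in _cigar_ops(self.cigar) if op in "MD")


def _cigar_ops(cigar: str) -> list[tuple[int, str]]:
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if not num or ch not in "MIDNSHP=X":
                raise ValueError(f"malformed CIGAR {cigar!r}")
            ops.append((int(num), ch))
            num = ""
    if num:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


def bed_score(percent_identity: float) -> int:
    """Map percent identity to the BED 0-1000 score: round(10 x identity)."""
    if not (0 < percent_identity <= 100):
        raise ValueError(
            f"percent_identity must be in (0, 100], got {percent_identity}"
        )
    return min(1000, round(10 * percent_identity))


def nuclear_track(comp: Compilation, assembled_only: bool = False) -> list[TrackRecord]:
    """Nuclear-coordinate BED track.

    With ``assembled_only`` one line per record (the assembled compilation);
    otherwise one line per member HSP, named ``<id>.<ordinal>``.  For
    compilations whose records are all single-block the two have the same
    cardinality.
    """
    out: list[TrackRecord] = []
    for rec in comp.records:
        if assembled_only or not rec.members:
            out.append(
                TrackRecord(
                    chrom=rec.nuclear.chrom,
                    start=rec.nuclear.start,
                    end=rec.nuclear.end,
                    name=rec.track_name,
                    score=rec.bed_score,
                    strand=rec.strand,
                )
            )
        else:
            for i, h in enumerate(rec.members, start=1):
                name = rec.track_name if len(rec.members) == 1 else (
                    f"{rec.base_id}.{i}"
                )
                out.append(
                    TrackRecord(
                        chrom=h.nuclear.chrom,
                        start=h.nuclear.start,
                        end=h.nuclear.end,
                        name=name,
                        score=bed_score(h.percent_identity),
                        strand=h.strand,
                    )
                )
    return out


def mito_track(
    comp: Compilation,
    mtdna_length: int | None = None,
    mito_name: str = "chrM",
) -> list[TrackRecord]:
    """Project every record onto the mitochondrial genome (BED6 on chrM)."""
    out = []
    for rec in comp.records:
        if mtdna_length is not None and rec.mito.end > mtdna_length:
            raise ValueError(
                f"{rec.numts_id}: mito span {rec.mito.end} exceeds "
                f"mtDNA length {mtdna_length}"
            )
        out.append(
            TrackRecord(
                chrom=mito_name,
                start=rec.mito.start,
                end=rec.mito.end,
                name=rec.track_name,
                score=rec.bed_score,
                strand=rec.strand,
            )
        )
    return out


def write_bed(records: list[TrackRecord], path, track_line: str | None = None) -> None:
    """Write BED6; ``track_line`` may hold a UCSC 'track name=...' header."""
    with open(path, "w", encoding="utf-8") as fh:
        if track_line:
            fh.write(track_line.rstrip("\n") + "\n")
        for rec in records:
            fh.write(rec.to_line() + "\n")


def read_bed(path) -> list[TrackRecord]:
    """Read BED6 (skips 'track', 'browser' and '#' lines)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if (
                not line
                or line.startswith("#")
                or line.startswith("track")
                or line.startswith("browser")
            ):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"line {lineno}: expected >= 6 BED columns")
            out.append(
                TrackRecord(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=fields[3],
                    score=int(fields[4]),
                    strand=fields[5],
                )
            )
    return out


# ---------------------------------------------------------------------------
# Realignment to the mitochondrial reference (mismatch track)
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp_str(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def realign_to_mito(
    numts_seq: str,
    mtdna: str,
    mito_hint: GenomicInterval,
    numts_id: str = "NumtS",
    scheme: ScoringScheme | None = None,
    slack: int = 500,
    min_score_floor: float | None = 0.0,
) -> AlignmentDetail:
    """Globally align a NumtS sequence to its hinted mtDNA window.

    The window is the hint extended by ``slack`` bp on each side; the whole
    NumtS sequence is aligned (free end-gaps on the window).  Minus-strand
    hints are aligned as the reverse complement with SAM flag 16.  An
    alignment scoring below ``min_score_floor`` raises
    :class:`SuspectRecordError`.
    """
    from .aligner import _fit_kernel, encode  # deferred: numba import cost

    scheme = scheme or ScoringScheme()
    if mito_hint.end > len(mtdna):
        raise ValueError("hint exceeds mtDNA length")
    lo = max(0, mito_hint.start - slack)
    hi = min(len(mtdna), mito_hint.end + slack)
    window = mtdna[lo:hi]
    flag = 0
    seq = numts_seq.upper()
    if mito_hint.strand == "-":
        seq = _revcomp_str(seq)
        flag = 16
    score, ws, _we, ops = _fit_kernel(
        encode(seq),
        encode(window),
        scheme.match_reward,
        scheme.mismatch_penalty,
        scheme.gap_open,
        scheme.gap_extend,
    )
    if min_score_floor is not None and score < min_score_floor:
        raise SuspectRecordError(
            f"{numts_id}: realignment score {score} below floor "
            f"{min_score_floor}; record is suspect"
        )
    cigar, nm, md = _ops_to_sam(np.asarray(ops), seq, mtdna, lo + ws)
    return AlignmentDetail(
        numts_id=numts_id,
        mito_pos=lo + ws + 1,
        flag=flag,
        cigar=cigar,
        nm=nm,
        md=md,
        seq=seq,
    )


def _ops_to_sam(ops: np.ndarray, seq: str, ref: str, ref_start: int):
    """CIGAR / NM / MD from traceback ops (0 match, 1 mismatch, 2 del, 3 ins).

    Op code 2 consumes reference only (deletion in the read), 3 consumes the
    read only (insertion).
    """
    cigar_parts: list[str] = []
    run_op = ""
    run_len = 0
    nm = 0
    md_parts: list[str] = []
    md_matches = 0
    ri = ref_start
    qi = 0
    in_del = False
    for op in ops:
        sam_op = "M" if op in (0, 1) else ("D" if op == 2 else "I")
        if sam_op == run_op:
            run_len += 1
        else:
            if run_len:
                cigar_parts.append(f"{run_len}{run_op}")
            run_op = sam_op
            run_len = 1
        if op == 0:
            md_matches += 1
            in_del = False
            ri += 1
            qi += 1
        elif op == 1:
            nm += 1
            md_parts.append(str(md_matches))
            md_matches = 0
            md_parts.append(ref[ri].upper())
            in_del = False
            ri += 1
            qi += 1
        elif op == 2:  # deletion: reference base absent from the read
            nm += 1
            if not in_del:
                md_parts.append(str(md_matches))
                md_matches = 0
                md_parts.append("^")
                in_del = True
            md_parts.append(ref[ri].upper())
            ri += 1
        else:  # insertion: read base absent from the reference
            nm += 1
            in_del = False
            qi += 1
    if run_len:
        cigar_parts.append(f"{run_len}{run_op}")
    md_parts.append(str(md_matches))
    return "".join(cigar_parts), nm, "".join(md_parts)


def mismatch_track_details(
    comp: Compilation,
    mtdna: str,
    chromosomes: dict[str, str],
    scheme: ScoringScheme | None = None,
    slack: int = 500,
) -> list[AlignmentDetail]:
    """Realign every NumtS of a compilation for the mismatch track.

    Single-block records are realigned whole; assembled records are
    realigned fragment by fragment (the spacer between blocks is nuclear
    sequence with no mitochondrial counterpart), with fragment lines named
    ``<track name>.<ordinal>``.
    """
    details = []
    for rec in comp.records:
        chrom = chromosomes[rec.nuclear.chrom]
        if rec.block_count <= 1 or not rec.members:
            pieces = [(rec.track_name, rec.nuclear, rec.mito)]
        else:
            pieces = [
                (f"{rec.track_name}.{i}", h.nuclear, h.mito)
                for i, h in enumerate(rec.members, start=1)
            ]
        for name, nuc, mito in pieces:
            details.append(
                realign_to_mito(
                    chrom[nuc.start : nuc.end],
                    mtdna,
                    GenomicInterval(mito.chrom, mito.start, mito.end, rec.strand),
                    numts_id=name,
                    scheme=scheme,
                    slack=slack,
                )
            )
    return details


def write_sam(
    details: list[AlignmentDetail],
    mtdna_name: str = "chrM",
    mtdna_length: int = 16569,
    path=None,
) -> str:
    """Render the mismatch track as SAM text (and optionally write it).

    Records are emitted sorted by position; the header declares the
    mitochondrial reference.  Binary (BAM) conversion is left to external
    tooling such as samtools.
    """
    lines = [
        "@HD\tVN:1.6\tSO:coordinate",
        f"@SQ\tSN:{mtdna_name}\tLN:{mtdna_length}",
        "@PG\tID:numtrack\tPN:numtrack",
    ]
    for d in sorted(details, key=lambda d: (d.mito_pos, d.numts_id)):
        if d.mito_pos - 1 + d.reference_span > mtdna_length:
            raise ValueError(
                f"{d.numts_id}: alignment extends past the {mtdna_length} bp "
                "reference"
            )
        lines.append(
            "\t".join(
                (
                    d.numts_id,
                    str(d.flag),
                    mtdna_name,
                    str(d.mito_pos),
                    "255",
                    d.cigar,
                    "*",
                    "0",
                    "0",
                    d.seq,
                    "*",
                    f"NM:i:{d.nm}",
                    f"MD:Z:{d.md}",
                )
            )
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
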