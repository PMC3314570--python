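"""Synthetic genomes with implanted mitochondrial fragments.

The generator builds a random mitochondrial reference and a random nuclear
chromosome, then implants mutated copies of mtDNA windows, emulating the
observed properties of real NumtS catalogues: fragment lengths from tens of
bp up to ~9 kb, sequence identity from ~64% to 100%, occasional split
insertions (two fragments separated by a short spacer) and duplicated
insertions.  A truth table records every implant so detection, assembly and
track generation can be scored exactly.

The mutational model is deliberately simple: uniform base composition,
uniform substitutions, with 10% of divergence events realized as 1 bp
indels.  All randomness flows from one seeded generator, so outputs are
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Compilation, GenomicInterval

__all__ = [
    "SyntheticTruth",
    "SyntheticGenome",
    "DetectionScore",
    "generate",
    "score_detection",
    "write_truth_tsv",
    "read_truth_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one implant.

    ``nuclear`` spans the whole insertion including any spacer;
    ``fragments`` lists the mtDNA-derived pieces (one, or two when split).
    """

    implant_id: str
    nuclear: GenomicInterval
    mito_source: GenomicInterval
    strand: str
    divergence: float
    is_split: bool
    spacer: int
    is_duplicate_of: str | None
    fragments: tuple[GenomicInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (0 <= self.divergence < 0.4):
            raise ValueError("divergence must be in [0, 0.4)")


@dataclass
class SyntheticGenome:
    """Generator output: sequences plus the implant truth table."""

    nuclear: dict[str, str]
    mtdna: str
    truth: list[SyntheticTruth]


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def _to_str(codes: np.ndarray) -> str:
    return codes.tobytes().decode("ascii")


_COMP_TABLE = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGT", b"TGCA"):
    _COMP_TABLE[a] = b


def _revcomp(codes: np.ndarray) -> np.ndarray:
    return _COMP_TABLE[codes][::-1].copy()


def _mutate(
    rng: np.random.Generator, codes: np.ndarray, divergence: float,
    indel_fraction: float = 0.1,
) -> np.ndarray:
    """Apply substitutions and 1 bp indels totalling ``divergence`` events/bp."""
    seq = list(codes)
    n_events = int(round(divergence * len(seq)))
    if n_events == 0:
        return codes.copy()
    n_indels = int(round(indel_fraction * n_events))
    n_subs = n_events - n_indels
    positions = rng.choice(len(seq), size=min(n_events, len(seq)), replace=False)
    sub_pos = positions[:n_subs]
    indel_pos = positions[n_subs:]
    alphabet = list(_BASES)
    for p in sub_pos:
        current = seq[p]
        choices = [b for b in alphabet if b != current]
        seq[p] = choices[rng.integers(0, 3)]
    # apply indels right-to-left so earlier positions stay valid
    for p in sorted(indel_pos, reverse=True):
        if rng.random() < 0.5 and len(seq) > 1:
            del seq[p]
        else:
            seq.insert(p, alphabet[rng.integers(0, 4)])
    return np.array(seq, dtype=np.uint8)


def generate(
    genome_size: int = 1_000_000,
    n_implants: int = 30,
    length_range: tuple[int, int] = (28, 8984),
    divergence_range: tuple[float, float] = (0.0, 0.36),
    duplication_rate: float = 0.1,
    split_rate: float = 0.15,
    spacer_range: tuple[int, int] = (100, 1900),
    seed: int = 0,
    mtdna_length: int = 16_500,
    chrom_name: str = "chr1",
    min_spacing: int = 2001,
    max_retries: int = 1000,
) -> SyntheticGenome:
    """Build a nuclear chromosome carrying implanted mtDNA fragments.

    Implants never overlap and are separated by at least ``min_spacing`` bp
    of background so that independent implants cannot be chained by the
    2000 bp assembly rule, keeping the truth bookkeeping unambiguous.
    Fully reproducible from ``seed``.
    """
    if length_range[0] < 1 or length_range[0] > length_range[1]:
        raise ValueError("invalid length_range")
    if not (0 <= divergence_range[0] <= divergence_range[1] < 0.4):
        raise ValueError("invalid divergence_range")
    if length_range[1] >= mtdna_length:
        raise ValueError("implant length must be below the mtDNA length")
    rng = np.random.default_rng(seed)
    mt = _random_seq(rng, mtdna_length)
    background = _random_seq(rng, genome_size)

    # draw implant descriptions first, then pack them onto the chromosome
    drawn = []
    for i in range(n_implants):
        dup_of = None
        if drawn and rng.random() < duplication_rate:
            dup_of = int(rng.integers(0, len(drawn)))
            src = drawn[dup_of]
            piece = src["piece"].copy()
            mito_iv = src["mito"]
            divergence = src["div"]
            strand = src["strand"]
        else:
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            m0 = int(rng.integers(0, mtdna_length - length))
            divergence = float(rng.uniform(*divergence_range))
            piece = _mutate(rng, mt[m0 : m0 + length], divergence)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                piece = _revcomp(piece)
            mito_iv = GenomicInterval("chrM", m0, m0 + length)
        is_split = bool(rng.random() < split_rate) and piece.shape[0] >= 2
        spacer = 0
        if is_split:
            spacer = int(rng.integers(spacer_range[0], spacer_range[1] + 1))
        drawn.append(
            {
                "piece": piece,
                "mito": mito_iv,
                "div": divergence,
                "strand": strand,
                "split": is_split,
                "spacer": spacer,
                "dup_of": dup_of,
            }
        )

    # greedy non-overlapping placement with bounded retries
    placements: list[tuple[int, int, int]] = []  # (background pos, span, idx)
    occupied: list[tuple[int, int]] = []
    for idx, d in enumerate(drawn):
        span = d["piece"].shape[0] + d["spacer"]
        if span + 2 * min_spacing >= genome_size:
            raise ValueError("genome_size too small to host implants")
        placed = False
        for _ in range(max_retries):
            pos = int(rng.integers(min_spacing, genome_size - span - min_spacing))
            if all(
                pos + span + min_spacing <= lo or hi + min_spacing <= pos
                for lo, hi in occupied
            ):
                occupied.append((pos, pos + span))
                placements.append((pos, span, idx))
                placed = True
                break
        if not placed:
            raise ValueError(
                "could not place implants without overlap; increase genome_size"
            )

    placements.sort()
    parts: list[np.ndarray] = []
    truth: list[SyntheticTruth] = []
    prev = 0
    shift = 0  # inserted bases so far: background pos -> chromosome pos offset
    for pos, span, idx in placements:
        d = drawn[idx]
        parts.append(background[prev:pos])
        start = pos + shift
        piece = d["piece"]
        if d["split"]:
            cut = int(rng.integers(1, piece.shape[0]))
            spacer_seq = _random_seq(rng, d["spacer"])
            parts.extend((piece[:cut], spacer_seq, piece[cut:]))
            fragments = (
                GenomicInterval(chrom_name, start, start + cut),
                GenomicInterval(
                    chrom_name,
                    start + cut + d["spacer"],
                    start + piece.shape[0] + d["spacer"],
                ),
            )
        else:
            parts.append(piece)
            fragments = (
                GenomicInterval(chrom_name, start, start + piece.shape[0]),
            )
        truth.append(
            SyntheticTruth(
                implant_id=f"implant_{idx:03d}",
                nuclear=GenomicInterval(chrom_name, start, start + span),
                mito_source=d["mito"],
                strand=d["strand"],
                divergence=d["div"],
                is_split=d["split"],
                spacer=d["spacer"],
                is_duplicate_of=(
                    f"implant_{d['dup_of']:03d}" if d["dup_of"] is not None else None
                ),
                fragments=fragments,
            )
        )
        prev = pos
        shift += span
    parts.append(background[prev:])
    chrom = _to_str(np.concatenate(parts)) if parts else ""
    truth.sort(key=lambda t: t.nuclear.start)
    return SyntheticGenome(
        nuclear={chrom_name: chrom}, mtdna=_to_str(mt), truth=truth
    )


# ---------------------------------------------------------------------------
# Truth table I/O
# ---------------------------------------------------------------------------

_TRUTH_COLUMNS = (
    "implant_id",
    "chrom",
    "start",
    "end",
    "mito_start",
    "mito_end",
    "strand",
    "divergence",
    "is_split",
    "spacer",
    "is_duplicate_of",
    "fragments",
)


def write_truth_tsv(truth: list[SyntheticTruth], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(_TRUTH_COLUMNS) + "\n")
        for t in truth:
            frags = ";".join(f"{f.start}-{f.end}" for f in t.fragments)
            fh.write(
                "\t".join(
                    (
                        t.implant_id,
                        t.nuclear.chrom,
                        str(t.nuclear.start),
                        str(t.nuclear.end),
                        str(t.mito_source.start),
                        str(t.mito_source.end),
                        t.strand,
                        repr(t.divergence),  # full precision round-trips
                        "1" if t.is_split else "0",
                        str(t.spacer),
                        t.is_duplicate_of or ".",
                        frags,
                    )
                )
                + "\n"
            )


def read_truth_tsv(path) -> list[SyntheticTruth]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            (iid, chrom, s, e, ms, me, strand, div, split, spacer, dup,
             frags) = line.split("\t")
            fragments = tuple(
                GenomicInterval(chrom, int(p.split("-")[0]), int(p.split("-")[1]))
                for p in frags.split(";")
                if p
            )
            out.append(
                SyntheticTruth(
                    implant_id=iid,
                    nuclear=GenomicInterval(chrom, int(s), int(e)),
                    mito_source=GenomicInterval("chrM", int(ms), int(me)),
                    strand=strand,
                    divergence=float(div),
                    is_split=split == "1",
                    spacer=int(spacer),
                    is_duplicate_of=None if dup == "." else dup,
                    fragments=fragments,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Detection scoring
# ---------------------------------------------------------------------------


@dataclass
class DetectionScore:
    """Locus- and base-level recall/precision of a detection run.

    ``locus_precision`` is None (missing) when nothing was detected.
    ``assignments`` maps implant_id -> list of matched NumtS IDs.
    """

    locus_recall: float
    locus_precision: float | None
    bp_recall: float
    bp_precision: float | None
    n_truth: int
    n_detected: int
    assignments: dict[str, list[str]]


def score_detection(
    detected: Compilation,
    truth: list[SyntheticTruth],
    bp_tolerance: int = 20,
) -> DetectionScore:
    """Score a detected compilation against the generator's truth table.

    Each detected record is assigned to the truth implant whose span it
    overlaps most.  A truth locus counts as recalled when the assigned
    records cover at least 50% of its fragment bases; a detected record
    counts as correct when at least 50% of its bases fall inside its
    implant's span.  Split implants assembled into one record therefore
    count as a single matched locus.  For base-level recall the truth
    fragments are trimmed by ``bp_tolerance`` at each end (terminal bases an
    aligner may legitimately miss); precision uses untrimmed intervals.
    """
    n_truth = len(truth)
    n_det = len(detected.records)
    assignments: dict[str, list[str]] = {t.implant_id: [] for t in truth}
    covered_by: dict[str, int] = {t.implant_id: 0 for t in truth}
    tp_records = 0
    det_bp = 0
    det_in_truth_bp = 0
    for rec in detected.records:
        iv = rec.nuclear
        det_bp += len(iv)
        best_t = None
        best_ov = 0
        for t in truth:
            ov = iv.intersection_length(t.nuclear)
            if ov > best_ov:
                best_ov = ov
                best_t = t
        if best_t is None:
            continue
        frag_ov = sum(iv.intersection_length(f) for f in best_t.fragments)
        covered_by[best_t.implant_id] += frag_ov
        assignments[best_t.implant_id].append(rec.numts_id)
        det_in_truth_bp += best_ov
        if best_ov >= 0.5 * len(iv):
            tp_records += 1
    matched = 0
    truth_bp = 0
    truth_recovered_bp = 0
    for t in truth:
        frag_bp = sum(len(f) for f in t.fragments)
        if covered_by[t.implant_id] >= 0.5 * frag_bp:
            matched += 1
        for f in t.fragments:
            lo = min(f.start + bp_tolerance, f.end)
            hi = max(f.end - bp_tolerance, lo)
            if hi <= lo:
                continue
            trimmed = GenomicInterval(f.chrom, lo, hi)
            truth_bp += len(trimmed)
            truth_recovered_bp += sum(
                min(trimmed.intersection_length(r.nuclear), len(trimmed))
                for r in detected.records
            )
    bp_recall = (
        min(1.0, truth_recovered_bp / truth_bp) if truth_bp else 0.0
    )
    return DetectionScore(
        locus_recall=matched / n_truth if n_truth else 0.0,
        locus_precision=tp_records / n_det if n_det else None,
        bp_recall=bp_recall,
        bp_precision=det_in_truth_bp / det_bp if det_bp else None,
        n_truth=n_truth,
        n_detected=n_det,
        assignments=assignments,
    )
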