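"""Chaining of HSPs into NumtS records and compilation ID assignment.

Two HSPs on the same chromosome and strand are combined into one *assembled
NumtS* when their nuclear loci lie less than ``max_nuclear_gap`` bp apart
(strict), the corresponding mitochondrial fragments are at most
``max_mito_gap`` bp apart (inclusive), and the mitochondrial order is
colinear with the nuclear order ('+' records: mito coordinates increase
along the chromosome; '-' records: decrease).  Chaining is greedy and
transitive along a run of consecutive HSPs.

A relaxation admits larger nuclear gaps when the gap is essentially one long
repetitive element: at least ``repeat_gap_cover_fraction`` of the gap bases
covered by annotated repeats each at least ``repeat_min_length`` bp long.
Records merged this way are flagged (``via_repeat``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .model import (
    HSP,
    Compilation,
    GenomicInterval,
    NumtSRecord,
    chrom_sort_key,
)
from .tracks import bed_score

__all__ = ["AssemblyParams", "assemble", "repeat_aware_assemble", "assign_ids"]


@dataclass(frozen=True)
class AssemblyParams:
    """Thresholds of the fragment-joining rule.

    The nuclear threshold is strict ("less than 2000 bp"), the mitochondrial
    threshold inclusive ("at most distant 2000 bp"); the asymmetry is part
    of the protocol definition.
    """

    max_nuclear_gap: int = 2000
    max_mito_gap: int = 2000
    repeat_gap_cover_fraction: float = 0.9
    repeat_min_length: int = 500

    def __post_init__(self) -> None:
        if self.max_nuclear_gap < 0 or self.max_mito_gap < 0:
            raise ValueError("gap thresholds must be non-negative")
        if not (0 < self.repeat_gap_cover_fraction <= 1):
            raise ValueError("repeat_gap_cover_fraction must be in (0, 1]")
        if self.repeat_min_length < 0:
            raise ValueError("repeat_min_length must be non-negative")


def _mito_gap(prev: HSP, nxt: HSP) -> int:
    """Signed distance between consecutive mito fragments along the chain.

    For '+' chains the next fragment should lie downstream on the mtDNA,
    for '-' chains upstream; negative values indicate overlap.
    """
    if prev.strand == "+":
        return nxt.mito.start - prev.mito.end
    return prev.mito.start - nxt.mito.end


def _colinear(prev: HSP, nxt: HSP) -> bool:
    if prev.strand == "+":
        return nxt.mito.start >= prev.mito.start
    return nxt.mito.start <= prev.mito.start


def _gap_repeat_covered(
    gap_start: int,
    gap_end: int,
    chrom: str,
    repeats_by_chrom: dict[str, list[tuple[int, int]]],
    params: AssemblyParams,
) -> bool:
    """True when >= cover_fraction of [gap_start, gap_end) lies in long repeats."""
    gap_len = gap_end - gap_start
    if gap_len <= 0:
        return False
    covered = 0
    last = gap_start
    for start, end in repeats_by_chrom.get(chrom, ()):
        if end - start < params.repeat_min_length:
            continue
        lo = max(start, gap_start, last)
        hi = min(end, gap_end)
        if hi > lo:
            covered += hi - lo
            last = hi
        if start >= gap_end:
            break
    return covered >= params.repeat_gap_cover_fraction * gap_len


def _chainable(
    prev: HSP,
    nxt: HSP,
    params: AssemblyParams,
    repeats_by_chrom: dict | None,
) -> tuple[bool, bool]:
    """(chainable, via_repeat) for two nuclear-sorted consecutive HSPs."""
    if prev.nuclear.chrom != nxt.nuclear.chrom or prev.strand != nxt.strand:
        return False, False
    if not _colinear(prev, nxt):
        return False, False
    if _mito_gap(prev, nxt) > params.max_mito_gap:
        return False, False
    nuclear_gap = nxt.nuclear.start - prev.nuclear.end
    if nuclear_gap < params.max_nuclear_gap:
        return True, False
    if repeats_by_chrom is not None and _gap_repeat_covered(
        prev.nuclear.end, nxt.nuclear.start, prev.nuclear.chrom,
        repeats_by_chrom, params,
    ):
        return True, True
    return False, False


def _build_record(members: list[HSP], via_repeat: bool) -> NumtSRecord:
    chrom = members[0].nuclear.chrom
    strand = members[0].strand
    n_lo = min(h.nuclear.start for h in members)
    n_hi = max(h.nuclear.end for h in members)
    m_lo = min(h.mito.start for h in members)
    m_hi = max(h.mito.end for h in members)
    total = sum(h.aln_length for h in members)
    pid = sum(h.percent_identity * h.aln_length for h in members) / total
    return NumtSRecord(
        numts_id="Hsa_NumtS_000",  # provisional; assign_ids names records
        species_prefix="Hsa",
        nuclear=GenomicInterval(chrom, n_lo, n_hi),
        mito=GenomicInterval(members[0].mito.chrom, m_lo, m_hi),
        strand=strand,
        percent_identity=pid,
        bed_score=bed_score(pid),
        members=list(members),
        block_count=len(members),
        via_repeat=via_repeat,
    )


def assemble(hsps: list[HSP], params: AssemblyParams | None = None) -> list[NumtSRecord]:
    """Chain HSPs into NumtS records under the 2000 bp joining rule.

    HSPs are sorted by (chromosome, nuclear start); consecutive HSPs are
    merged greedily whenever the rule admits it, so chaining is transitive
    along a run.  Unchained HSPs become single-block records.  The returned
    records carry provisional IDs; :func:`assign_ids` names them.
    """
    return _assemble_impl(hsps, params or AssemblyParams(), None)


def repeat_aware_assemble(
    hsps: list[HSP],
    params: AssemblyParams | None = None,
    repeats: list[GenomicInterval] | None = None,
) -> list[NumtSRecord]:
    """As :func:`assemble`, additionally joining across repeat-filled gaps.

    ``repeats`` must be sorted by (chrom, start); with no repeats the result
    reduces to :func:`assemble`.
    """
    params = params or AssemblyParams()
    if not repeats:
        return _assemble_impl(hsps, params, None)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in repeats:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, ivs in by_chrom.items():
        if ivs != sorted(ivs):
            raise ValueError(f"repeat intervals on {chrom} must be sorted")
    return _assemble_impl(hsps, params, by_chrom)


def _assemble_impl(hsps, params, repeats_by_chrom):
    ordered = sorted(
        hsps,
        key=lambda h: (
            chrom_sort_key(h.nuclear.chrom),
            h.nuclear.start,
            h.nuclear.end,
        ),
    )
    records: list[NumtSRecord] = []
    run: list[HSP] = []
    run_via_repeat = False
    for h in ordered:
        if run:
            ok, via_rep = _chainable(run[-1], h, params, repeats_by_chrom)
            if ok:
                run.append(h)
                run_via_repeat = run_via_repeat or via_rep
                continue
            records.append(_build_record(run, run_via_repeat))
            run_via_repeat = False
        run = [h]
    if run:
        records.append(_build_record(run, run_via_repeat))
    return records


def assign_ids(
    records: list[NumtSRecord],
    species_prefix: str,
    species: str = "",
    genome_build: str = "",
) -> Compilation:
    """Assign sequential compilation IDs (<prefix>_NumtS_001 ...).

    Records are sorted by (chromosome order, nuclear start) first, so the
    numbering is invariant to the input order.  Beyond 999 records the codes
    widen to four digits (with a warning).
    """
    if not (len(species_prefix) == 3 and species_prefix[0].isupper()
            and species_prefix.isalpha()):
        raise ValueError(
            "species_prefix must be a three-letter code like Ptr or Mms"
        )
    ordered = sorted(
        records,
        key=lambda r: (chrom_sort_key(r.nuclear.chrom), r.nuclear.start, r.nuclear.end),
    )
    if len(ordered) > 999:
        warnings.warn(
            f"{len(ordered)} records: widening NumtS codes to 4 digits",
            stacklevel=2,
        )
    width = max(3, len(str(len(ordered))))
    out = []
    for i, rec in enumerate(ordered, start=1):
        out.append(
            NumtSRecord(
                numts_id=f"{species_prefix}_NumtS_{i:0{width}d}",
                species_prefix=species_prefix,
                nuclear=rec.nuclear,
                mito=rec.mito,
                strand=rec.strand,
                percent_identity=rec.percent_identity,
                bed_score=rec.bed_score,
                members=rec.members,
                block_count=rec.block_count,
                via_repeat=rec.via_repeat,
            )
        )
    return Compilation(species=species, genome_build=genome_build, records=out)
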