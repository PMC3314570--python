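"""Mitochondrial co-amplification risk screening.

Primers designed against a mitochondrial target may also amplify a NumtS —
the nuclear copy acts as an unintended template and can masquerade as
heteroplasmy.  Two screens are provided: a positional query of the
mitochondrion-projected track against a target region, and a simplified
primer-site check over the NumtS sequences (a stand-in for a full
thermodynamic primer search: Hamming-distance sites with an exact 3' anchor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Compilation
from .tracks import TrackRecord, _revcomp_str

__all__ = ["PrimerHit", "query_mito_region", "primer_site_check"]


def query_mito_region(
    mito_track: list[TrackRecord],
    start: int,
    end: int,
    mtdna_length: int,
) -> list[TrackRecord]:
    """NumtS whose mitochondrial projection overlaps [start, end) by >= 1 bp.

    Returned sorted by score descending (the co-amplification risk ranking);
    ties broken by start ascending, then name.
    """
    if start >= end:
        raise ValueError("require start < end")
    if not (0 <= start and end <= mtdna_length):
        raise ValueError(
            f"region [{start}, {end}) outside the {mtdna_length} bp mtDNA"
        )
    hits = [r for r in mito_track if r.start < end and start < r.end]
    hits.sort(key=lambda r: (-r.score, r.start, r.name))
    return hits


@dataclass(frozen=True)
class PrimerHit:
    """One NumtS predicted to yield a PCR product from the primer pair."""

    numts_id: str
    product_length: int
    forward_mismatches: int
    reverse_mismatches: int
    forward_pos: int
    reverse_pos: int
    orientation: str  # '+' product as given, '-' product on the complement

    @property
    def total_mismatches(self) -> int:
        return self.forward_mismatches + self.reverse_mismatches


def _validate_primer(primer: str, label: str) -> str:
    primer = primer.upper()
    if not (15 <= len(primer) <= 35):
        raise ValueError(f"{label} primer must be 15-35 bp, got {len(primer)}")
    if set(primer) - set("ACGT"):
        raise ValueError(f"{label} primer contains non-ACGT characters")
    return primer


def _site_scan(seq: np.ndarray, primer: np.ndarray, max_mm: int, anchor: int,
               anchor_at_start: bool) -> list[tuple[int, int]]:
    """(position, mismatches) of primer sites in seq.

    The 3'-terminal ``anchor`` bases must match exactly; for a plus-strand
    forward primer those are the last bases of the site, for the
    reverse-complemented reverse primer the first bases.
    """
    L = primer.shape[0]
    n = seq.shape[0]
    if n < L:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(seq, L)
    mism = np.sum(windows != primer, axis=1)
    if anchor_at_start:
        exact = np.all(windows[:, :anchor] == primer[:anchor], axis=1)
    else:
        exact = np.all(windows[:, L - anchor :] == primer[L - anchor :], axis=1)
    ok = np.nonzero((mism <= max_mm) & exact)[0]
    return [(int(p), int(mism[p])) for p in ok]


def primer_site_check(
    forward: str,
    reverse: str,
    comp: Compilation,
    numts_sequences: dict[str, str],
    max_mismatches: int = 2,
    max_product: int = 4000,
    anchor: int = 5,
    both_orientations: bool = True,
) -> list[PrimerHit]:
    """Screen NumtS sequences for potential co-amplification products.

    A NumtS is reported when its sequence contains a forward-primer site and,
    downstream, the reverse complement of the reverse primer, each within
    ``max_mismatches`` (3'-terminal ``anchor`` bases exact), with product
    length <= ``max_product``.  With ``both_orientations`` the complementary
    template orientation is screened too.  One best (fewest-mismatch,
    leftmost) product is reported per record, sorted by total mismatches.
    """
    from .aligner import encode

    fwd = _validate_primer(forward, "forward")
    rev = _validate_primer(reverse, "reverse")
    fwd_c = encode(fwd)
    rev_rc_c = encode(_revcomp_str(rev))
    hits: list[PrimerHit] = []
    for rec in comp.records:
        if rec.numts_id not in numts_sequences:
            raise KeyError(f"no sequence supplied for {rec.numts_id}")
        seq = numts_sequences[rec.numts_id].upper()
        best: PrimerHit | None = None
        orientations = ("+", "-") if both_orientations else ("+",)
        for orient in orientations:
            s = seq if orient == "+" else _revcomp_str(seq)
            codes = encode(s)
            f_sites = _site_scan(
                codes, fwd_c, max_mismatches, anchor, anchor_at_start=False
            )
            r_sites = _site_scan(
                codes, rev_rc_c, max_mismatches, anchor, anchor_at_start=True
            )
            for fp, fm in f_sites:
                for rp, rm in r_sites:
                    if rp < fp + len(fwd):
                        continue
                    product = rp + len(rev) - fp
                    if product > max_product:
                        continue
                    cand = PrimerHit(
                        numts_id=rec.numts_id,
                        product_length=product,
                        forward_mismatches=fm,
                        reverse_mismatches=rm,
                        forward_pos=fp,
                        reverse_pos=rp,
                        orientation=orient,
                    )
                    if best is None or (
                        cand.total_mismatches,
                        cand.forward_pos,
                    ) < (best.total_mismatches, best.forward_pos):
                        best = cand
        if best is not None:
            hits.append(best)
    hits.sort(key=lambda h: (h.total_mismatches, h.product_length, h.numts_id))
    return hits
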