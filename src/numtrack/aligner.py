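"""Affine-gap local alignment and genome scanning (in silico hybridization).

The hybridization step finds every significant local alignment (HSP) between
the mitochondrial reference (query) and a nuclear chromosome (subject), on
both strands, under the BlastN-style scheme (+2/-3, gap open -5, extend -2)
with Karlin-Altschul E-value filtering.

Two search paths share one dynamic-programming core:

* :func:`local_align` — full Smith-Waterman over the whole sequence pair;
  exact, used directly for small inputs and as the extension engine.
* :func:`scan_genome` — exact k-mer seeding (default k=12) followed by
  windowed Smith-Waterman extension; dispatches to the full DP whenever the
  problem is small enough, so the two paths agree there by construction.

Overlapping HSPs are resolved greedily by score, masking accepted subject
regions (ties to the leftmost nuclear start), mirroring BLAST behaviour.
A gap of length L scores ``gap_open + L * gap_extend``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .model import HSP, EValueParams, GenomicInterval, ScoringScheme
from .karlin import evalue as _evalue
from .karlin import min_score_for_evalue, solve_karlin_altschul

__all__ = [
    "encode",
    "decode",
    "revcomp",
    "local_align",
    "scan_genome",
    "parse_blast_tabular",
    "write_blast_tabular",
    "read_hsp_tsv",
    "write_hsp_tsv",
]

_LUT = np.full(256, 255, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _LUT[ord(base)] = i
    _LUT[ord(base.lower())] = i
_LUT[ord("N")] = 4
_LUT[ord("n")] = 4

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

NEG = -(1 << 40)


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A0 C1 G2 T3 N4); rejects non-IUPAC-core."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _LUT[raw]
    if np.any(codes == 255):
        bad = chr(raw[int(np.argmax(codes == 255))])
        raise ValueError(f"non-IUPAC character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement on the code alphabet (N maps to N)."""
    comp = np.where(codes < 4, 3 - codes.astype(np.int8), 4).astype(np.uint8)
    return comp[::-1].copy()


# ---------------------------------------------------------------------------
# DP kernels.  seq1 indexes rows, seq2 columns.  Traceback op codes:
# 0 = match, 1 = mismatch, 2 = gap in seq1 (consumes seq2),
# 3 = gap in seq2 (consumes seq1).  N aligned to anything scores as mismatch.
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sw_kernel(q, s, match, mism, go, ge, mask):
    """Smith-Waterman with affine gaps and masked subject columns.

    Returns (best_score, q_start, q_end, s_start, s_end, ops) for the single
    best local alignment; ops is empty when best_score is 0.
    """
    m = q.shape[0]
    n = s.shape[0]
    ptr_h = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptr_e = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptr_f = np.zeros((m + 1, n + 1), dtype=np.uint8)
    h_prev = np.zeros(n + 1, dtype=np.int64)
    h_cur = np.zeros(n + 1, dtype=np.int64)
    f_row = np.full(n + 1, NEG, dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qc = q[i - 1]
        e = NEG
        h_cur[0] = 0
        for j in range(1, n + 1):
            if mask[j - 1]:
                h_cur[j] = 0
                e = NEG
                f_row[j] = NEG
                ptr_h[i, j] = 0
                continue
            # E: gap in seq1, consumes seq2
            e_open = h_cur[j - 1] + go + ge
            e_ext = e + ge
            if e_ext >= e_open:
                e = e_ext
                ptr_e[i, j] = 1
            else:
                e = e_open
                ptr_e[i, j] = 0
            # F: gap in seq2, consumes seq1
            f_open = h_prev[j] + go + ge
            f_ext = f_row[j] + ge
            if f_ext >= f_open:
                f_row[j] = f_ext
                ptr_f[i, j] = 1
            else:
                f_row[j] = f_open
                ptr_f[i, j] = 0
            sc = s[j - 1]
            if qc == sc and qc < 4:
                diag = h_prev[j - 1] + match
            else:
                diag = h_prev[j - 1] + mism
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if e > h:
                h = e
                p = 2
            if f_row[j] > h:
                h = f_row[j]
                p = 3
            h_cur[j] = h
            ptr_h[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
    # traceback
    ops = np.empty(m + n, dtype=np.uint8)
    nops = 0
    i = bi
    j = bj
    while i > 0 and j > 0 and ptr_h[i, j] != 0:
        p = ptr_h[i, j]
        if p == 1:
            if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                ops[nops] = 0
            else:
                ops[nops] = 1
            nops += 1
            i -= 1
            j -= 1
        elif p == 2:
            while True:
                ops[nops] = 2
                nops += 1
                was_open = ptr_e[i, j] == 0
                j -= 1
                if was_open:
                    break
        else:
            while True:
                ops[nops] = 3
                nops += 1
                was_open = ptr_f[i, j] == 0
                i -= 1
                if was_open:
                    break
    return best, i, bi, j, bj, ops[:nops][::-1].copy()


@njit(cache=True)
def _fit_kernel(q, s, match, mism, go, ge):
    """Glocal (fit) alignment: all of seq1 aligned, free end-gaps on seq2.

    Returns (score, s_start, s_end, ops).
    """
    m = q.shape[0]
    n = s.shape[0]
    ptr_h = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptr_e = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptr_f = np.zeros((m + 1, n + 1), dtype=np.uint8)
    h_prev = np.zeros(n + 1, dtype=np.int64)
    h_cur = np.zeros(n + 1, dtype=np.int64)
    f_row = np.full(n + 1, NEG, dtype=np.int64)
    # column 0: leading seq1 residues are gaps in seq2 (op F)
    col0 = np.empty(m + 1, dtype=np.int64)
    col0[0] = 0
    for i in range(1, m + 1):
        col0[i] = go + ge * i
    for i in range(1, m + 1):
        qc = q[i - 1]
        e = NEG
        h_cur[0] = col0[i]
        for j in range(1, n + 1):
            e_open = h_cur[j - 1] + go + ge
            e_ext = e + ge
            if e_ext >= e_open:
                e = e_ext
                ptr_e[i, j] = 1
            else:
                e = e_open
                ptr_e[i, j] = 0
            f_open = h_prev[j] + go + ge
            f_ext = f_row[j] + ge
            if f_ext >= f_open:
                f_row[j] = f_ext
                ptr_f[i, j] = 1
            else:
                f_row[j] = f_open
                ptr_f[i, j] = 0
            sc = s[j - 1]
            if qc == sc and qc < 4:
                diag = h_prev[j - 1] + match
            else:
                diag = h_prev[j - 1] + mism
            h = diag
            p = 1
            if e > h:
                h = e
                p = 2
            if f_row[j] > h:
                h = f_row[j]
                p = 3
            h_cur[j] = h
            ptr_h[i, j] = p
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
    # best end over the last row (free trailing seq2)
    best = h_prev[0]
    bj = 0
    for j in range(1, n + 1):
        if h_prev[j] > best:
            best = h_prev[j]
            bj = j
    ops = np.empty(m + n, dtype=np.uint8)
    nops = 0
    i = m
    j = bj
    while i > 0:
        if j == 0:
            ops[nops] = 3
            nops += 1
            i -= 1
            continue
        p = ptr_h[i, j]
        if p == 1:
            if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                ops[nops] = 0
            else:
                ops[nops] = 1
            nops += 1
            i -= 1
            j -= 1
        elif p == 2:
            while True:
                ops[nops] = 2
                nops += 1
                was_open = ptr_e[i, j] == 0
                j -= 1
                if was_open:
                    break
        else:
            while True:
                ops[nops] = 3
                nops += 1
                was_open = ptr_f[i, j] == 0
                i -= 1
                if was_open:
                    break
    return best, j, bj, ops[:nops][::-1].copy()


def _ops_stats(ops: np.ndarray) -> tuple[int, int, int]:
    """(matches, alignment columns, NM-style difference count)."""
    matches = int(np.sum(ops == 0))
    cols = int(ops.size)
    nm = cols - matches
    return matches, cols, nm


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        if seq.size == 0:
            raise ValueError("empty sequence")
        return seq.astype(np.uint8)
    return encode(str(seq))


def _split_ops_at_long_gaps(ops: np.ndarray, threshold: int):
    """Split a traceback at gap runs >= threshold columns.

    Long interior gaps mark two distinct local matches bridged only because
    the flanking segments outscore the gap penalty; BLAST-style extension
    would have terminated there (X-drop), so the alignment is decomposed and
    each piece reported as its own HSP.  Returns (start, end) column ranges.
    """
    if threshold <= 0 or ops.size == 0:
        return [(0, int(ops.size))]
    is_gap = ops >= 2
    ranges = []
    seg_start = 0
    idx = 0
    n = int(ops.size)
    while idx < n:
        if is_gap[idx]:
            run_start = idx
            while idx < n and is_gap[idx]:
                idx += 1
            if idx - run_start >= threshold:
                if run_start > seg_start:
                    ranges.append((seg_start, run_start))
                seg_start = idx
        else:
            idx += 1
    if seg_start < n:
        ranges.append((seg_start, n))
    return ranges


def _segment_score(ops: np.ndarray, scheme) -> int:
    score = 0
    run = 0
    for op in ops:
        if op == 0:
            score += scheme.match_reward
            run = 0
        elif op == 1:
            score += scheme.mismatch_penalty
            run = 0
        else:
            if run == 0:
                score += scheme.gap_open
            score += scheme.gap_extend
            run = 1
    return score


def _hsp_candidates_on_strand(q, s, scheme, mask, strand, q_len,
                              gap_split_threshold=50):
    """Best-alignment candidates from one kernel run, split at long gaps.

    Returns (best_raw_score, subject_span, [candidate dicts]); candidates
    carry window coordinates that the caller offsets into global space.
    """
    best, qs, qe, ss, se, ops = _sw_kernel(
        q,
        s,
        scheme.match_reward,
        scheme.mismatch_penalty,
        scheme.gap_open,
        scheme.gap_extend,
        mask,
    )
    if best <= 0 or ops.size == 0:
        return 0, (0, 0), []
    ranges = _split_ops_at_long_gaps(ops, gap_split_threshold)
    # per-column cumulative query/subject consumption along the traceback
    q_step = np.where(ops != 2, 1, 0)
    s_step = np.where(ops != 3, 1, 0)
    q_pos = qs + np.concatenate(([0], np.cumsum(q_step)))
    s_pos = ss + np.concatenate(([0], np.cumsum(s_step)))
    cands = []
    for lo, hi in ranges:
        piece = ops[lo:hi]
        matches = int(np.sum(piece == 0))
        cols = int(piece.size)
        if cols == 0 or matches == 0:
            continue
        q_lo, q_hi = int(q_pos[lo]), int(q_pos[hi])
        s_lo, s_hi = int(s_pos[lo]), int(s_pos[hi])
        if q_hi <= q_lo or s_hi <= s_lo:
            continue
        score = _segment_score(piece, scheme) if len(ranges) > 1 else int(best)
        if strand == "-":
            mito_lo, mito_hi = q_len - q_hi, q_len - q_lo
        else:
            mito_lo, mito_hi = q_lo, q_hi
        cands.append(
            {
                "score": int(score),
                "mito": (mito_lo, mito_hi),
                "sub": (s_lo, s_hi),
                "strand": strand,
                "pid": 100.0 * matches / cols,
                "cols": cols,
            }
        )
    return int(best), (ss, se), cands


def local_align(
    query,
    subject,
    scheme: ScoringScheme | None = None,
    min_score: int = 1,
    *,
    subject_name: str = "subject",
    mito_name: str = "chrM",
    evalue_params: EValueParams | None = None,
    max_hsps: int | None = None,
    gap_split_threshold: int = 50,
) -> list[HSP]:
    """All maximal non-overlapping local alignments with score >= min_score.

    Both strands are searched (the query is reverse-complemented for '-'
    hits); every HSP carries coordinates on the forward strands of both
    sequences.  HSPs are extracted greedily by score; each accepted hit
    masks its subject interval for subsequent rounds.  Alignments bridging
    two matches across a gap run of >= ``gap_split_threshold`` columns are
    decomposed into separate HSPs (BLAST-style extension would terminate in
    such a gap).
    """
    scheme = scheme or ScoringScheme()
    q = _as_codes(query)
    s = _as_codes(subject)
    q_rc = revcomp(q)
    mask = np.zeros(s.shape[0], dtype=np.bool_)
    hsps: list[HSP] = []
    while max_hsps is None or len(hsps) < max_hsps:
        runs = []
        for strand, qq in (("+", q), ("-", q_rc)):
            best, span, cands = _hsp_candidates_on_strand(
                qq, s, scheme, mask, strand, q.shape[0], gap_split_threshold
            )
            runs.append((best, span, cands, strand))
        runs.sort(key=lambda t: (-t[0], t[1][0], t[3]))
        best, span, cands, strand = runs[0]
        if best < min_score:
            break
        accepted = [c for c in cands if c["score"] >= min_score]
        for c in accepted:
            ev = _evalue(c["score"], evalue_params) if evalue_params else None
            hsps.append(
                HSP(
                    mito=GenomicInterval(mito_name, c["mito"][0], c["mito"][1]),
                    nuclear=GenomicInterval(
                        subject_name, c["sub"][0], c["sub"][1]
                    ),
                    strand=c["strand"],
                    raw_score=float(c["score"]),
                    percent_identity=c["pid"],
                    aln_length=c["cols"],
                    evalue=ev,
                )
            )
            mask[c["sub"][0] : c["sub"][1]] = True
        if not accepted:
            # best alignment decomposed into sub-threshold pieces only:
            # mask its whole span so the search makes progress
            mask[span[0] : span[1]] = True
    hsps.sort(key=lambda h: (h.nuclear.start, h.nuclear.end, h.strand))
    return hsps


# ---------------------------------------------------------------------------
# Seed-and-extend scan
# ---------------------------------------------------------------------------


def _kmer_index(codes: np.ndarray, k: int) -> dict[int, list[int]]:
    """Exact k-mer -> positions map; windows containing N are skipped."""
    index: dict[int, list[int]] = {}
    n = codes.shape[0]
    if n < k:
        return index
    vals = codes.astype(np.int64)
    bad = np.cumsum(np.concatenate(([0], (vals >= 4).astype(np.int64))))
    powers = 4 ** np.arange(k, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(vals, k)
    kmers = windows @ powers
    valid = (bad[k:] - bad[:-k]) == 0
    for pos in np.nonzero(valid)[0]:
        index.setdefault(int(kmers[pos]), []).append(int(pos))
    return index


def _seed_hits(index: dict[int, list[int]], s_codes: np.ndarray, k: int):
    """(query_pos, subject_pos) pairs of exact k-mer matches."""
    n = s_codes.shape[0]
    if n < k or not index:
        return []
    vals = s_codes.astype(np.int64)
    bad = np.cumsum(np.concatenate(([0], (vals >= 4).astype(np.int64))))
    powers = 4 ** np.arange(k, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(vals, k)
    kmers = windows @ powers
    valid = (bad[k:] - bad[:-k]) == 0
    keys = np.fromiter(index.keys(), dtype=np.int64, count=len(index))
    hit_mask = valid & np.isin(kmers, keys)
    hits = []
    for spos in np.nonzero(hit_mask)[0]:
        positions = index[int(kmers[spos])]
        # highly repetitive k-mers are uninformative as seeds
        if len(positions) > 100:
            continue
        for qpos in positions:
            hits.append((qpos, int(spos)))
    return hits


def _cluster_seeds(hits, k, max_seed_gap=1500, diag_tol=150):
    """Group seed hits into extension windows by diagonal and proximity."""
    hits = sorted(hits, key=lambda t: t[1])
    clusters: list[dict] = []
    open_clusters: list[dict] = []
    for qpos, spos in hits:
        diag = spos - qpos
        open_clusters = [
            c for c in open_clusters if spos - c["smax"] <= max_seed_gap
        ]
        placed = False
        for c in open_clusters:
            if c["dmin"] - diag_tol <= diag <= c["dmax"] + diag_tol:
                c["smax"] = max(c["smax"], spos + k)
                c["smin"] = min(c["smin"], spos)
                c["qmin"] = min(c["qmin"], qpos)
                c["qmax"] = max(c["qmax"], qpos + k)
                c["dmin"] = min(c["dmin"], diag)
                c["dmax"] = max(c["dmax"], diag)
                c["diags"].append(diag)
                placed = True
                break
        if not placed:
            c = {
                "smin": spos,
                "smax": spos + k,
                "qmin": qpos,
                "qmax": qpos + k,
                "dmin": diag,
                "dmax": diag,
                "diags": [diag],
            }
            clusters.append(c)
            open_clusters.append(c)
    return clusters


def _ungapped_trigger_score(qq, s_codes, cluster, scheme, pad):
    """Best ungapped segment score along the cluster's median seed diagonal.

    Cheap filter that discards chance seed clusters before any gapped DP
    (the two stages mirror BLAST's ungapped-then-gapped extension).
    """
    diags = sorted(cluster["diags"])
    d = diags[len(diags) // 2]
    lo = max(cluster["smin"] - pad, d, 0)
    hi = min(cluster["smax"] + pad, qq.shape[0] + d, s_codes.shape[0])
    if hi <= lo:
        return 0
    sseg = s_codes[lo:hi]
    qseg = qq[lo - d : hi - d]
    is_match = (sseg == qseg) & (sseg < 4)
    col = np.where(is_match, scheme.match_reward, scheme.mismatch_penalty)
    # maximum-subarray score via running prefix minimum
    prefix = np.concatenate(([0], np.cumsum(col)))
    return int(np.max(prefix[1:] - np.minimum.accumulate(prefix[:-1])))


def _merge_windows(windows):
    """Merge overlapping (subject) extension windows to avoid duplicate DP."""
    if not windows:
        return []
    windows.sort()
    merged = [list(windows[0])]
    for w in windows[1:]:
        if w[0] <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], w[1])
            merged[-1][2] = min(merged[-1][2], w[2])
            merged[-1][3] = max(merged[-1][3], w[3])
        else:
            merged.append(list(w))
    return merged


def _scan_one_strand(q_codes, s_codes, scheme, strand, min_score, *,
                     k, pad, max_seed_gap, diag_tol, subject_name, mito_name,
                     gap_split_threshold=50):
    q_len = q_codes.shape[0]
    qq = q_codes if strand == "+" else revcomp(q_codes)
    index = _kmer_index(qq, k)
    hits = _seed_hits(index, s_codes, k)
    clusters = _cluster_seeds(hits, k, max_seed_gap, diag_tol)
    n = s_codes.shape[0]
    trigger = max(20, int(0.8 * min_score))
    windows = []
    for c in clusters:
        if _ungapped_trigger_score(qq, s_codes, c, scheme, pad) < trigger:
            continue
        ss = max(0, c["smin"] - pad)
        se = min(n, c["smax"] + pad)
        qs = max(0, c["qmin"] - pad)
        qe = min(q_len, c["qmax"] + pad)
        windows.append((ss, se, qs, qe))
    candidates = []
    for ss, se, qs, qe in _merge_windows(windows):
        sub = s_codes[ss:se]
        mask = np.zeros(sub.shape[0], dtype=np.bool_)
        # window [qs, qe) lives on qq; on '-' qq is the reverse complement,
        # so the window's forward-strand mito offset is q_len - qe
        mito_offset = qs if strand == "+" else q_len - qe
        while True:
            best, span, cands = _hsp_candidates_on_strand(
                qq[qs:qe], sub, scheme, mask, strand, qe - qs,
                gap_split_threshold,
            )
            if best < min_score:
                break
            accepted = [c for c in cands if c["score"] >= min_score]
            for c in accepted:
                mask[c["sub"][0] : c["sub"][1]] = True
                mlo, mhi = c["mito"]
                candidates.append(
                    {
                        **c,
                        "mito": (mito_offset + mlo, mito_offset + mhi),
                        "sub": (ss + c["sub"][0], ss + c["sub"][1]),
                    }
                )
            if not accepted:
                mask[span[0] : span[1]] = True
    return candidates


def scan_genome(
    mtdna,
    chromosomes: dict,
    scheme: ScoringScheme | None = None,
    *,
    k: int = 12,
    evalue_params: EValueParams | None = None,
    full_dp_max_cells: int = 1_000_000,
    pad: int = 500,
    max_seed_gap: int = 1500,
    diag_tol: int = 150,
    gap_split_threshold: int = 50,
    mito_name: str = "chrM",
) -> list[HSP]:
    """Scan nuclear chromosomes for HSPs against the mitochondrial genome.

    Parameters
    ----------
    mtdna : str or array of codes
        The mitochondrial reference (single sequence, treated linearly).
    chromosomes : dict
        Mapping of chromosome name to sequence.
    scheme : ScoringScheme
        Scoring constants; the E-value threshold drives the score cutoff with
        m = mtDNA length and n = chromosome length.
    evalue_params : EValueParams, optional
        Override lambda and K (e.g. to match an external BLAST run); the
        search-space lengths are always set per chromosome.

    Returns the retained HSPs sorted by (chromosome, nuclear start).  A
    chromosome containing only Ns yields no HSPs.
    """
    scheme = scheme or ScoringScheme()
    q = _as_codes(mtdna)
    base_params = evalue_params or solve_karlin_altschul(scheme)
    out: list[HSP] = []
    for name, seq in chromosomes.items():
        s = _as_codes(seq)
        params = base_params.with_search_space(m=q.shape[0], n=s.shape[0])
        min_score = min_score_for_evalue(scheme.evalue_threshold, params)
        if q.shape[0] * s.shape[0] <= full_dp_max_cells:
            hsps = local_align(
                q,
                s,
                scheme,
                min_score,
                subject_name=name,
                mito_name=mito_name,
                evalue_params=params,
                gap_split_threshold=gap_split_threshold,
            )
            out.extend(h for h in hsps if h.evalue <= scheme.evalue_threshold)
            continue
        candidates = []
        for strand in ("+", "-"):
            candidates.extend(
                _scan_one_strand(
                    q,
                    s,
                    scheme,
                    strand,
                    min_score,
                    k=k,
                    pad=pad,
                    max_seed_gap=max_seed_gap,
                    diag_tol=diag_tol,
                    subject_name=name,
                    mito_name=mito_name,
                    gap_split_threshold=gap_split_threshold,
                )
            )
        # greedy non-overlap resolution by score, ties to leftmost start
        candidates.sort(key=lambda c: (-c["score"], c["sub"][0], c["strand"]))
        accepted: list[tuple[int, int]] = []
        for c in candidates:
            lo, hi = c["sub"]
            if any(lo < b and a < hi for a, b in accepted):
                continue
            accepted.append((lo, hi))
            ev = _evalue(c["score"], params)
            if ev > scheme.evalue_threshold:
                continue
            out.append(
                HSP(
                    mito=GenomicInterval(mito_name, c["mito"][0], c["mito"][1]),
                    nuclear=GenomicInterval(name, lo, hi),
                    strand=c["strand"],
                    raw_score=float(c["score"]),
                    percent_identity=c["pid"],
                    aln_length=c["cols"],
                    evalue=ev,
                )
            )
    out.sort(key=lambda h: (h.nuclear.chrom, h.nuclear.start, h.nuclear.end))
    return out


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6) interchange
# ---------------------------------------------------------------------------


def parse_blast_tabular(path, mito_as_query: bool = True) -> list[HSP]:
    """Read 12-column BLAST tabular output into HSPs.

    BLAST coordinates are 1-based inclusive; subject start > end marks a
    minus-strand hit.  With ``mito_as_query`` the query columns map to the
    mitochondrial genome and the subject columns to the nuclear chromosome.
    """
    hsps = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            (qid, sid, pid, alen, _mm, _gaps, qs, qe, ss, se, ev, bits) = fields
            qs, qe, ss, se = int(qs), int(qe), int(ss), int(se)
            if not mito_as_query:
                qid, sid = sid, qid
                qs, qe, ss, se = ss, se, qs, qe
            strand = "+"
            if ss > se:
                strand = "-"
                ss, se = se, ss
            if qs > qe:  # minus encoded on the query side instead
                strand = "-"
                qs, qe = qe, qs
            hsps.append(
                HSP(
                    mito=GenomicInterval(qid, qs - 1, qe),
                    nuclear=GenomicInterval(sid, ss - 1, se),
                    strand=strand,
                    raw_score=float(bits),
                    percent_identity=float(pid),
                    aln_length=int(alen),
                    evalue=float(ev),
                )
            )
    return hsps


def write_blast_tabular(hsps: list[HSP], path) -> None:
    """Write HSPs as 12-column BLAST-style tabular (1-based inclusive)."""
    with open(path, "w", encoding="utf-8") as fh:
        for h in hsps:
            mismatches = round(
                h.aln_length * (1 - h.percent_identity / 100.0)
            )
            ss, se = h.nuclear.start + 1, h.nuclear.end
            if h.strand == "-":
                ss, se = se, ss
            fh.write(
                "\t".join(
                    (
                        h.mito.chrom,
                        h.nuclear.chrom,
                        f"{h.percent_identity:.2f}",
                        str(h.aln_length),
                        str(mismatches),
                        "0",
                        str(h.mito.start + 1),
                        str(h.mito.end),
                        str(ss),
                        str(se),
                        f"{h.evalue:.2e}" if h.evalue is not None else "0.0",
                        f"{h.raw_score:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Internal HSP TSV (full-fidelity interchange between scan and assemble)
# ---------------------------------------------------------------------------

_HSP_COLUMNS = (
    "chrom",
    "nuclear_start",
    "nuclear_end",
    "mito_start",
    "mito_end",
    "strand",
    "raw_score",
    "evalue",
    "percent_identity",
    "aln_length",
)


def write_hsp_tsv(hsps: list[HSP], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(_HSP_COLUMNS) + "\n")
        for h in hsps:
            fh.write(
                "\t".join(
                    (
                        h.nuclear.chrom,
                        str(h.nuclear.start),
                        str(h.nuclear.end),
                        str(h.mito.start),
                        str(h.mito.end),
                        h.strand,
                        f"{h.raw_score:.1f}",
                        f"{h.evalue:.6e}" if h.evalue is not None else ".",
                        f"{h.percent_identity:.4f}",
                        str(h.aln_length),
                    )
                )
                + "\n"
            )


def read_hsp_tsv(path) -> list[HSP]:
    hsps = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(_HSP_COLUMNS):
                raise ValueError(f"line {lineno}: malformed HSP row")
            chrom, ns, ne, ms, me, strand, score, ev, pid, alen = fields
            hsps.append(
                HSP(
                    mito=GenomicInterval("chrM", int(ms), int(me)),
                    nuclear=GenomicInterval(chrom, int(ns), int(ne)),
                    strand=strand,
                    raw_score=float(score),
                    evalue=None if ev == "." else float(ev),
                    percent_identity=float(pid),
                    aln_length=int(alen),
                )
            )
    return hsps
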