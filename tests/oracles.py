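"""Independent reference implementations used only to check the package.

These deliberately use the plain textbook formulations (row-by-row affine
DP recurrences, per-base bitmaps, the direct Pearson sum formula) rather
than any code path from the package under test.
"""

import numpy as np


def sw_best_score(
    query: str,
    subject: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> int:
    """Best local alignment score, affine gaps (length-L gap = open + L*ext).

    Straight Smith-Waterman-Gotoh recurrences; the E (horizontal) state is
    filled sequentially per row, D and F vectorized.
    """
    qa = np.frombuffer(query.encode(), dtype=np.uint8)
    sa = np.frombuffer(subject.encode(), dtype=np.uint8)
    n = sa.size
    NEG = -1e18
    h_prev = np.zeros(n + 1)
    f_prev = np.full(n + 1, NEG)
    best = 0.0
    for i in range(qa.size):
        sub = np.where(sa == qa[i], float(match), float(mismatch))
        diag = h_prev[:-1] + sub
        f_row = np.maximum(h_prev + gap_open + gap_extend, f_prev + gap_extend)
        h_row = np.zeros(n + 1)
        e = NEG
        for j in range(1, n + 1):
            e = max(h_row[j - 1] + gap_open + gap_extend, e + gap_extend)
            h_row[j] = max(0.0, diag[j - 1], e, f_row[j])
        best = max(best, h_row.max())
        h_prev = h_row
        f_prev = f_row
    return int(best)


def sw_best_score_both_strands(query, subject, **kw) -> int:
    comp = str.maketrans("ACGT", "TGCA")
    rc = query.translate(comp)[::-1]
    return max(sw_best_score(query, subject, **kw), sw_best_score(rc, subject, **kw))


def bitmap_re_summary(numts, flanked, repeats, genome_sizes):
    """Per-base bitmap computation of all repeat-content statistics.

    ``numts``/``flanked``/``repeats`` are lists of (chrom, start, end).
    Returns the six RESummary fields as a dict.
    """
    masks = {c: np.zeros(size, dtype=bool) for c, size in genome_sizes.items()}
    fmasks = {c: np.zeros(size, dtype=bool) for c, size in genome_sizes.items()}
    rmasks = {c: np.zeros(size, dtype=bool) for c, size in genome_sizes.items()}
    for c, s, e in numts:
        masks[c][s:e] = True
    for c, s, e in flanked:
        fmasks[c][s:e] = True
    for c, s, e in repeats:
        rmasks[c][s:e] = True
    count_in = sum(1 for c, s, e in repeats if masks[c][s:e].any())
    count_fl = sum(1 for c, s, e in repeats if fmasks[c][s:e].any())
    re_bp = sum(int((masks[c] & rmasks[c]).sum()) for c in masks)
    numts_bp = sum(int(m.sum()) for m in masks.values())
    genome_re_bp = sum(int(m.sum()) for m in rmasks.values())
    n_records = len(numts)
    return {
        "re_count_in_numts": count_in,
        "re_count_with_flanks": count_fl,
        "re_bp_in_numts": re_bp,
        "pct_re_bp_of_numts_bp": 100.0 * re_bp / numts_bp if numts_bp else 0.0,
        "pct_re_count_of_numts_count": (
            100.0 * count_in / n_records if n_records else 0.0
        ),
        "pct_re_bp_of_genome_re_bp": (
            100.0 * re_bp / genome_re_bp if genome_re_bp else 0.0
        ),
    }


def pearson_r(x, y) -> float:
    """Direct sum-formula Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    den = np.sqrt(n * np.sum(x * x) - np.sum(x) ** 2) * np.sqrt(
        n * np.sum(y * y) - np.sum(y) ** 2
    )
    return float(num / den)
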