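"""Independent brute-force oracles used to check the pipeline's fast paths.

These deliberately share no code with the package: the trim oracle scans
every trim point, the alignment oracle is a plain O(mn) Gotoh local
aligner, and the mapping oracle slides the read over every offset of the
reference with NumPy.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def brute_trim_point(seq: str, adapter: str, max_error_rate: float, min_overlap: int):
    """Best adapter start: lowest error fraction, ties to the earliest
    position; None when no occurrence qualifies."""
    best = None
    for pos in range(len(seq) + 1):
        overlap = min(len(seq) - pos, len(adapter))
        if overlap < min_overlap:
            continue
        mismatches = sum(
            1 for a, b in zip(seq[pos : pos + overlap], adapter[:overlap]) if a != b
        )
        frac = mismatches / overlap
        if frac <= max_error_rate and (best is None or frac < best[0]):
            best = (frac, pos)
    return None if best is None else best[1]


def gotoh_local_score(a: str, b: str, match=1, mismatch=-2, gap_open=-5, gap_extend=-2):
    """Exact local alignment score under BLAST's affine convention
    (a length-L gap scores gap_open + L * gap_extend)."""
    first = gap_open + gap_extend
    n, m = len(a), len(b)
    neg = float("-inf")
    h_prev = [0.0] * (m + 1)
    e_prev = [neg] * (m + 1)
    best = 0.0
    for i in range(1, n + 1):
        h_cur = [0.0] * (m + 1)
        e_cur = [neg] * (m + 1)
        f = neg
        for j in range(1, m + 1):
            e_cur[j] = max(h_prev[j] + first, e_prev[j] + gap_extend)
            f = max(h_cur[j - 1] + first, f + gap_extend)
            sub = match if a[i - 1] == b[j - 1] else mismatch
            h_cur[j] = max(0.0, h_prev[j - 1] + sub, e_cur[j], f)
            if h_cur[j] > best:
                best = h_cur[j]
        h_prev, e_prev = h_cur, e_cur
    return int(best)


def brute_force_placements(seq: str, ref: str, max_mismatches: int):
    """All (start0, strand, mismatches) ungapped placements, N never matches."""
    out = []
    ref_arr = np.frombuffer(ref.encode(), dtype="S1")
    n_mask = ref_arr == b"N"
    read_len = len(seq)
    if read_len > len(ref):
        return out
    windows = np.lib.stride_tricks.sliding_window_view(ref_arr, read_len)
    win_n = np.lib.stride_tricks.sliding_window_view(n_mask, read_len)
    for strand, pattern in (("+", seq), ("-", rc(seq))):
        pat = np.frombuffer(pattern.encode(), dtype="S1")
        mism = ((windows != pat) | win_n | (pat == b"N")).sum(axis=1)
        for start in np.nonzero(mism <= max_mismatches)[0]:
            out.append((int(start), strand, int(mism[start])))
    out.sort(key=lambda p: (p[0], p[1]))
    return out


def pair_distance_histogram(alignments, size_class, max_distance, weights):
    """O(n^2) enumeration of overlapping sense/antisense 5'-5' distances."""
    lo, hi = size_class
    counts = np.zeros(max_distance + 1)
    subset = [a for a in alignments if lo <= a.read_len <= hi]
    for a1 in subset:
        if a1.strand != "+":
            continue
        for a2 in subset:
            if a2.strand != "-":
                continue
            d = a2.five_prime - a1.five_prime
            if not 1 <= d <= max_distance:
                continue
            overlap_start = max(a1.start, a2.start)
            overlap_end = min(a1.end, a2.end)
            if overlap_end - overlap_start + 1 >= 1:
                counts[d] += weights[id(a1)] * weights[id(a2)]
    return counts


def tile_reads(source: str, read_len: int, stride: int, prefix: str = "t"):
    """Error-free plus-strand tiling reads over a source sequence."""
    starts = list(range(0, len(source) - read_len + 1, stride))
    if starts and starts[-1] != len(source) - read_len:
        starts.append(len(source) - read_len)  # always cover the 3' tail
    return [
        (f"{prefix}{idx}", source[start : start + read_len])
        for idx, start in enumerate(starts)
    ]
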