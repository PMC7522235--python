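"""Independent reference implementations used only by the tests.

These are deliberately simple, full (unbanded) dynamic programs against
which the package's edlib-backed motif search and the numba-backed banded
aligner are checked.  They share no code with the implementations they
verify; the only shared input is the IUPAC equality list, which is part of
the contract under test.
"""

from __future__ import annotations

import math

import numpy as np

from holopore.demux import IUPAC_EQUALITIES
from holopore.io import revcomp

_EQ = set(IUPAC_EQUALITIES)

# character-level match table (identity plus the IUPAC equalities)
_MATCH = np.zeros((256, 256), dtype=bool)
for _i in range(256):
    _MATCH[_i, _i] = True
for _a, _b in _EQ:
    _MATCH[ord(_a), ord(_b)] = True
    _MATCH[ord(_b), ord(_a)] = True


def chars_match(a: str, b: str) -> bool:
    return bool(_MATCH[ord(a), ord(b)])


def _enc(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype=np.uint8)


def _infix_final_row(mcodes: np.ndarray, tcodes: np.ndarray) -> np.ndarray:
    """Final DP row of the semi-global (infix) edit-distance matrix.

    Row 0 is all zeros (free start anywhere in the target); column j of the
    returned row is the best distance of the whole motif against a target
    substring ending at j.
    """
    n = tcodes.size
    prev = np.zeros(n + 1, dtype=np.int64)
    arange = np.arange(n + 1)
    t = np.empty(n + 1, dtype=np.int64)
    for i in range(1, mcodes.size + 1):
        sub = (~_MATCH[mcodes[i - 1], tcodes]).astype(np.int64)
        t[0] = i
        np.minimum(prev[:-1] + sub, prev[1:] + 1, out=t[1:])
        # close the horizontal recurrence: D[i][j] = min_{k<=j} t[k] + (j-k)
        prev = np.minimum.accumulate(t - arange) + arange
    return prev


def infix_edit_distance(motif: str, target: str) -> int:
    """Minimum edit distance of motif against any substring of target.

    Semi-global DP (target flanks free, motif fully aligned), IUPAC codes
    in either sequence matched at zero cost per the shared equality list.
    """
    if len(target) == 0:
        return len(motif)
    return int(_infix_final_row(_enc(motif), _enc(target)).min())


def infix_hit_span(motif: str, target: str) -> tuple[int, int, int]:
    """(distance, end, start) of the leftmost-ending best infix occurrence."""
    mcodes, tcodes = _enc(motif), _enc(target)
    row = _infix_final_row(mcodes, tcodes)
    d = int(row.min())
    end = int(np.argmin(row))
    # start position via the reversed problem on the prefix ending at `end`
    rev_row = _infix_final_row(mcodes[::-1].copy(), tcodes[:end][::-1].copy())
    assert int(rev_row.min()) == d
    start = end - int(np.argmin(rev_row))
    return d, end, start


def full_affine_overlap_score(query: str, ref: str, match=2, mismatch=-4,
                              gap_open=-4, gap_extend=-2) -> int:
    """Unbanded ends-free affine-gap alignment score, plain row loops."""
    m, n = len(query), len(ref)
    NEG = -(10**9)
    go = gap_open + gap_extend
    h_prev = [0] * (n + 1)
    f_prev = [NEG] * (n + 1)
    best = 0
    for i in range(1, m + 1):
        h_row = [0] + [NEG] * n
        e_row = [NEG] * (n + 1)
        f_row = [NEG] * (n + 1)
        qc = query[i - 1]
        for j in range(1, n + 1):
            s = match if qc == ref[j - 1] else mismatch
            f = max(h_prev[j] + go, f_prev[j] + gap_extend)
            e = max(h_row[j - 1] + go, e_row[j - 1] + gap_extend)
            h = max(h_prev[j - 1] + s, e, f)
            h_row[j], e_row[j], f_row[j] = h, e, f
        best = max(best, h_row[n])
        h_prev, f_prev = h_row, f_row
    best = max(best, max(h_prev))
    return best


# ---------------------------------------------------------------------------
# Demultiplexing decision oracle
# ---------------------------------------------------------------------------


def oracle_demux_decision(seq: str, scheme, end_window=150, max_error_rate=0.25,
                          min_length=100) -> tuple[str, str | None, str | None]:
    """(status, sample, strand) by exhaustive full-DP over every
    (barcode, orientation, end) combination, replicating the published
    decision rules independently of the package's search code."""
    start_blocks = {}
    end_blocks = {}
    for idx, bc in enumerate(scheme.barcodes):
        start_blocks[("+", idx)] = scheme.fwd_tail + bc
        end_blocks[("+", idx)] = revcomp(scheme.rev_tail + bc)
        start_blocks[("-", idx)] = scheme.rev_tail + bc
        end_blocks[("-", idx)] = revcomp(scheme.fwd_tail + bc)
    all_blocks = list(start_blocks.values()) + list(end_blocks.values())

    w = min(end_window, len(seq))
    interior = seq[w : len(seq) - w]
    if len(interior) >= 10:
        for motif in all_blocks:
            if infix_edit_distance(motif, interior) <= math.ceil(max_error_rate * len(motif)):
                return "DISCARDED_MIDDLE", None, None

    def best_end(blocks, region):
        best = None
        for (strand, idx), motif in blocks.items():
            d = infix_edit_distance(motif, region)
            if d > math.ceil(max_error_rate * len(motif)):
                continue
            key = (d, idx, strand)
            if best is None or key < best[:3]:
                best = (d, idx, strand, motif)
        return best

    hit1 = best_end(start_blocks, seq[:w])
    hit2 = best_end(end_blocks, seq[len(seq) - w :])
    if hit1 is None and hit2 is None:
        return "UNASSIGNED", None, None
    if hit1 is not None and hit2 is not None and hit1[1:3] != hit2[1:3]:
        return "UNASSIGNED", None, None
    chosen = hit1 if (hit2 is None or (hit1 is not None and hit1[0] <= hit2[0])) else hit2
    barcode_to_sample = {idx: s for s, idx in scheme.sample_to_barcode.items()}
    sample = barcode_to_sample.get(chosen[1])
    if sample is None:
        return "UNASSIGNED", None, None
    # approximate trimmed length from block spans (primer refinement only
    # shortens further; disagreement possible in a narrow length window)
    lo = 0
    if hit1 is not None:
        _, end, _ = infix_hit_span(hit1[3], seq[:w])
        lo = end
    hi = len(seq)
    if hit2 is not None:
        _, _, start = infix_hit_span(hit2[3], seq[len(seq) - w :])
        hi = len(seq) - w + start
    if hi - lo < min_length:
        return "UNASSIGNED", None, chosen[2]
    return "ASSIGNED", sample, chosen[2]
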