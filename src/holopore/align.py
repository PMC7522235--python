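"""Noisy long-read to reference alignment at amplicon scale.

Seeding uses canonical-k-mer minimizers; candidate references are ranked by
the longest colinear seed chain, then scored with a banded semi-global
(ends-free / overlap) affine-gap dynamic program re-centered on the chain
diagonal.  Read overhangs and reference flanks are unpenalized, which suits
amplicon reads that may carry residual adapter or primer bases.

Scoring is minimap2 map-ont-like: match +2, mismatch -4, gap open -4,
gap extend -2 (a gap of length L costs 4 + 2L).  Every reported alignment
carries an explicit =/X/I/D edit string from which the score is exactly
recomputable.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from numba import njit

from .io import Marker, MarkerDatabase, Read, revcomp

NEG = -(1 << 29)

_CODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_TABLE[_b] = _i
    _CODE_TABLE[_b + 32] = _i  # lowercase


def encode(seq: str) -> np.ndarray:
    """2-bit encode; anything outside ACGT becomes code 4 (never matches)."""
    return _CODE_TABLE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class AlignParams:
    k: int = 15
    w: int = 10
    match: int = 2
    mismatch: int = -4
    gap_open: int = -4
    gap_extend: int = -2
    min_identity: float = 0.70
    min_query_coverage: float = 0.50
    band_min: int = 50
    band_frac: float = 0.2
    max_seeds: int = 5000
    max_candidates: int = 5


def default_align_params(marker: Marker) -> AlignParams:
    """k=15/w=10 for the ~1.3-1.8 kb markers; denser k=11/w=5 for ITS2."""
    if marker == Marker.ITS2:
        return AlignParams(k=11, w=5)
    return AlignParams()


# ---------------------------------------------------------------------------
# Minimizer index
# ---------------------------------------------------------------------------


def _mix64(x: np.ndarray) -> np.ndarray:
    # 64-bit finalizer; decorrelates k-mer rank from sequence content
    x = x.astype(np.uint64, copy=True)
    x ^= x >> np.uint64(33)
    x *= np.uint64(0xFF51AFD7ED558CCD)
    x ^= x >> np.uint64(33)
    x *= np.uint64(0xC4CEB9FE1A85EC53)
    x ^= x >> np.uint64(33)
    return x


def minimizers(seq: str, k: int, w: int) -> list[tuple[int, int, int]]:
    """(hash, position, strand) minimizers of a sequence.

    The minimizer of each w-window of canonical k-mer hashes is kept;
    strand is 0 when the forward k-mer is the canonical one.  k-mers
    containing non-ACGT bases are skipped.
    """
    codes = encode(seq)
    n = codes.size
    if n < k:
        return []
    m = n - k + 1
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    for t in range(k):
        fwd = (fwd << np.uint64(2)) | codes[t : t + m].astype(np.uint64)
        rev = (rev << np.uint64(2)) | (
            np.uint64(3) - codes[k - 1 - t : k - 1 - t + m].astype(np.uint64)
        )
    valid = (
        np.convolve((codes < 4).astype(np.int32), np.ones(k, dtype=np.int32), "valid") == k
    )
    strand = (rev < fwd).astype(np.uint8)
    canonical = np.where(strand == 0, fwd, rev)
    hashes = _mix64(canonical)
    hashes[~valid] = np.uint64(0xFFFFFFFFFFFFFFFF)
    if m <= w:
        pos_set = {int(np.argmin(hashes))} if valid.any() else set()
    else:
        windows = np.lib.stride_tricks.sliding_window_view(hashes, w)
        pos_set = set((windows.argmin(axis=1) + np.arange(m - w + 1)).tolist())
    out = []
    for pos in sorted(pos_set):
        if valid[pos]:
            out.append((int(hashes[pos]), pos, int(strand[pos])))
    return out


@dataclass
class MinimizerIndex:
    k: int
    w: int
    ref_ids: list[str]
    postings: dict[int, list[tuple[int, int, int]]]  # hash -> (ref_idx, pos, strand)


def build_index(db: MarkerDatabase, k: int, w: int) -> MinimizerIndex:
    """Minimizer index over all references of a database (cached on the db)."""
    if not 8 <= k <= 21:
        raise ValueError(f"k={k} outside [8, 21]")
    if w < 1:
        raise ValueError(f"w={w} must be >= 1")
    cached = db._index_cache.get((k, w))
    if cached is not None:
        return cached
    shortest = min((len(r.bases) for r in db.refs), default=0)
    if db.refs and k > shortest:
        raise ValueError(f"k={k} exceeds shortest reference length {shortest}")
    postings: dict[int, list[tuple[int, int, int]]] = {}
    for ref_idx, ref in enumerate(db.refs):
        for h, pos, strand in minimizers(ref.bases, k, w):
            postings.setdefault(h, []).append((ref_idx, pos, strand))
    index = MinimizerIndex(k, w, [r.ref_id for r in db.refs], postings)
    db._index_cache[(k, w)] = index
    return index


# ---------------------------------------------------------------------------
# Banded affine semi-global DP
# ---------------------------------------------------------------------------


@njit(cache=False)
def _fill_banded(q, r, match, mismatch, gap_open, gap_ext, d0, band):  # pragma: no cover
    m = q.shape[0]
    n = r.shape[0]
    H = np.full((m + 1, n + 1), NEG, np.int32)
    E = np.full((m + 1, n + 1), NEG, np.int32)
    F = np.full((m + 1, n + 1), NEG, np.int32)
    for j in range(n + 1):
        H[0, j] = 0
    for i in range(m + 1):
        H[i, 0] = 0
    go = gap_open + gap_ext
    for i in range(1, m + 1):
        lo = i + d0 - band
        hi = i + d0 + band
        if lo < 1:
            lo = 1
        if hi > n:
            hi = n
        if lo > hi:
            continue
        qi = q[i - 1]
        for j in range(lo, hi + 1):
            best = NEG
            h_diag = H[i - 1, j - 1]
            if h_diag > NEG:
                s = match if (qi == r[j - 1] and qi < 4) else mismatch
                best = h_diag + s
            f = NEG
            if H[i - 1, j] > NEG:
                f = H[i - 1, j] + go
            if F[i - 1, j] > NEG and F[i - 1, j] + gap_ext > f:
                f = F[i - 1, j] + gap_ext
            F[i, j] = f
            if f > best:
                best = f
            e = NEG
            if H[i, j - 1] > NEG:
                e = H[i, j - 1] + go
            if E[i, j - 1] > NEG and E[i, j - 1] + gap_ext > e:
                e = E[i, j - 1] + gap_ext
            E[i, j] = e
            if e > best:
                best = e
            H[i, j] = best
    return H, E, F


@dataclass
class Alignment:
    """One read-to-reference alignment with an exact edit string.

    ``q_start/q_end`` are on the strand-oriented query (the read as
    aligned, i.e. reverse-complemented first when ``strand == '-'``);
    ``cigar`` runs over =/X/I/D where I consumes query and D consumes
    reference.  ``score`` is exactly recomputable from the cigar.
    """

    read_id: str
    ref_id: str
    score: int
    identity: float
    q_start: int
    q_end: int
    r_start: int
    r_end: int
    strand: str
    cigar: str
    matches: int
    columns: int
    query_length: int

    def oriented_query(self, read: Read) -> str:
        return read.bases if self.strand == "+" else revcomp(read.bases)

    @property
    def query_coverage(self) -> float:
        return (self.q_end - self.q_start) / self.query_length if self.query_length else 0.0


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops = []
    count = ""
    for ch in cigar:
        if ch.isdigit():
            count += ch
        else:
            ops.append((ch, int(count)))
            count = ""
    return ops


def score_from_cigar(cigar: str, params: AlignParams) -> int:
    """Re-score an edit string under the scoring scheme (exact)."""
    score = 0
    for op, length in parse_cigar(cigar):
        if op == "=":
            score += params.match * length
        elif op == "X":
            score += params.mismatch * length
        elif op in "ID":
            score += params.gap_open + params.gap_extend * length
        else:
            raise ValueError(f"unknown cigar op {op!r}")
    return score


def banded_align(
    query: str,
    ref: str,
    params: AlignParams,
    diagonal: int = 0,
    band: int | None = None,
) -> Alignment | None:
    """Ends-free banded alignment of ``query`` against ``ref``.

    The band is centered on ``diagonal`` (ref position minus query
    position); ``band`` defaults to max(band_min, band_frac * len(query)).
    Equals the unbanded optimum whenever the optimal path stays in band.
    """
    if not query or not ref:
        return None
    if band is None:
        band = max(params.band_min, int(params.band_frac * len(query)))
    q = encode(query)
    r = encode(ref)
    H, E, F = _fill_banded(
        q, r, params.match, params.mismatch, params.gap_open, params.gap_extend,
        int(diagonal), int(band),
    )
    m, n = len(query), len(ref)
    # best cell over last row and last column (free trailing clips)
    last_row_j = int(np.argmax(H[m, :]))
    last_col_i = int(np.argmax(H[:, n]))
    if H[m, last_row_j] >= H[last_col_i, n]:
        bi, bj = m, last_row_j
    else:
        bi, bj = last_col_i, n
    score = int(H[bi, bj])
    if score <= NEG // 2 or score <= 0:
        return None
    ops: list[str] = []
    i, j = bi, bj
    go = params.gap_open + params.gap_extend
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0 and (i == 0 or j == 0):
                break
            if H[i - 1, j - 1] > NEG and (
                h == H[i - 1, j - 1]
                + (params.match if (q[i - 1] == r[j - 1] and q[i - 1] < 4) else params.mismatch)
            ):
                ops.append("=" if (q[i - 1] == r[j - 1] and q[i - 1] < 4) else "X")
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = "F"
            elif h == E[i, j]:
                state = "E"
            else:  # free end (score 0 at boundary-reachable cell)
                break
        elif state == "F":
            ops.append("I")
            if H[i - 1, j] > NEG and F[i, j] == H[i - 1, j] + go:
                state = "H"
            i -= 1
        else:  # E
            ops.append("D")
            if H[i, j - 1] > NEG and E[i, j] == H[i, j - 1] + go:
                state = "H"
            j -= 1
    ops.reverse()
    q_start, r_start = i, j
    matches = sum(1 for op in ops if op == "=")
    columns = len(ops)
    if columns == 0:
        return None
    runs: list[str] = []
    prev, count = ops[0], 0
    for op in ops:
        if op == prev:
            count += 1
        else:
            runs.append(f"{count}{prev}")
            prev, count = op, 1
    runs.append(f"{count}{prev}")
    return Alignment(
        read_id="",
        ref_id="",
        score=score,
        identity=matches / columns,
        q_start=q_start,
        q_end=bi,
        r_start=r_start,
        r_end=bj,
        strand="+",
        cigar="".join(runs),
        matches=matches,
        columns=columns,
        query_length=m,
    )


# ---------------------------------------------------------------------------
# Seeding, chaining, mapping
# ---------------------------------------------------------------------------


def _longest_increasing_chain(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest strictly colinear subset of (qpos, rpos) anchor pairs."""
    pairs = sorted(pairs)
    tails: list[int] = []  # rpos tails
    tails_idx: list[int] = []
    parent = [-1] * len(pairs)
    for idx, (_, rpos) in enumerate(pairs):
        at = bisect.bisect_left(tails, rpos)
        if at == len(tails):
            tails.append(rpos)
            tails_idx.append(idx)
        else:
            tails[at] = rpos
            tails_idx[at] = idx
        parent[idx] = tails_idx[at - 1] if at > 0 else -1
    chain = []
    cursor = tails_idx[-1] if tails_idx else -1
    while cursor >= 0:
        chain.append(pairs[cursor])
        cursor = parent[cursor]
    chain.reverse()
    return chain


def map_read(read: Read, db: MarkerDatabase, params: AlignParams) -> Alignment | None:
    """Best alignment of one read against one marker database, or None.

    Candidates are ranked by colinear seed-chain length; the top candidates
    are aligned with the banded DP re-centered on the chain diagonal.  The
    winner is the highest score passing the identity/coverage filters,
    ties broken by higher identity then lexicographically smaller ref_id.
    """
    index = build_index(db, params.k, params.w)
    read_mins = minimizers(read.bases, params.k, params.w)
    if not read_mins:
        return None
    hits: dict[tuple[int, int], list[tuple[int, int]]] = {}
    n_hits = 0
    for h, qpos, qstrand in read_mins:
        for ref_idx, rpos, rstrand in index.postings.get(h, ()):
            rel = qstrand ^ rstrand
            opos = qpos if rel == 0 else len(read.bases) - params.k - qpos
            hits.setdefault((ref_idx, rel), []).append((opos, rpos))
            n_hits += 1
    if not hits:
        return None
    if n_hits > params.max_seeds:
        stride = (n_hits + params.max_seeds - 1) // params.max_seeds
        hits = {key: pairs[::stride] for key, pairs in hits.items()}
    chains = []
    for (ref_idx, rel), pairs in hits.items():
        chain = _longest_increasing_chain(pairs)
        chains.append((len(chain), ref_idx, rel, chain))
    chains.sort(key=lambda c: (-c[0], index.ref_ids[c[1]], c[2]))
    best: Alignment | None = None
    for chain_len, ref_idx, rel, chain in chains[: params.max_candidates]:
        ref = db.refs[ref_idx]
        query = read.bases if rel == 0 else revcomp(read.bases)
        diags = [rpos - qpos for qpos, rpos in chain]
        d0 = int(np.median(diags))
        band = max(
            params.band_min,
            int(params.band_frac * len(query)),
            (max(diags) - min(diags)) // 2 + 20,
        )
        aln = banded_align(query, ref.bases, params, d0, band)
        if aln is None:
            continue
        if aln.identity < params.min_identity or aln.query_coverage < params.min_query_coverage:
            continue
        aln = replace(aln, read_id=read.read_id, ref_id=ref.ref_id,
                      strand="+" if rel == 0 else "-")
        if best is None or (-aln.score, -aln.identity, aln.ref_id) < (
            -best.score, -best.identity, best.ref_id
        ):
            best = aln
    return best


def map_all(
    reads: Iterable[Read],
    dbs: dict[Marker, MarkerDatabase],
    params_by_marker: dict[Marker, AlignParams] | None = None,
) -> dict[str, tuple[Marker, Alignment] | None]:
    """Map each read against all marker databases; best score wins.

    A read whose best alignment fails the filters in every database maps to
    None (counted as unmapped by callers).
    """
    if params_by_marker is None:
        params_by_marker = {m: default_align_params(m) for m in dbs}
    results: dict[str, tuple[Marker, Alignment] | None] = {}
    for read in reads:
        best: tuple[Marker, Alignment] | None = None
        for marker, db in dbs.items():
            if not db.refs:
                continue
            aln = map_read(read, db, params_by_marker[marker])
            if aln is None:
                continue
            if best is None or (-aln.score, -aln.identity, aln.ref_id) < (
                -best[1].score, -best[1].identity, best[1].ref_id
            ):
                best = (marker, aln)
        results[read.read_id] = best
    return results
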