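"""Reference-guided haploid consensus from supporting reads.

Base counts are accumulated per reference position directly from each
alignment's edit string (no realignment; base qualities are never
weighted).  The call is a plurality vote per position over {A, C, G, T,
deletion} with ties broken toward the reference symbol; an insertion after
a position is emitted when its most common inserted sequence is supported
by more than half of the reads spanning that junction.  Positions with no
coverage emit the reference base, so a shallow pileup still yields a
full-length sequence (configurable to emit N instead).

The plurality vote stands in for a haploid genotype-likelihood caller: on
deep amplicon pileups with qualities ignored the two coincide, and the
plurality rule is fully specifiable.  The consensus is finally labelled
with its closest database reference by edit distance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np

from .align import Alignment, parse_cigar
from .io import MarkerDatabase, Read, ReferenceSeq

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_SYMBOLS = "ACGT-"
DELETION = 4


@dataclass
class Pileup:
    """Per-reference-position tallies from a set of supporting alignments."""

    ref_id: str
    counts: np.ndarray  # (ref_len, 5): A C G T deletion
    insertions: dict[int, Counter]  # junction after position -> {seq: count}
    junction_depth: np.ndarray  # reads spanning (pos, pos+1)
    n_reads: int

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class ConsensusParams:
    insertion_threshold: float = 0.5  # fraction of spanning depth
    zero_depth_emits: str = "ref"  # "ref" or "N"


@dataclass
class ConsensusSequence:
    ref_id: str
    bases: str
    n_support: int
    depth: np.ndarray
    label: tuple[str, int] | None = None  # (closest ref, edit distance)


def build_pileup(
    alignments: list[Alignment],
    reads: dict[str, Read],
    ref: ReferenceSeq,
) -> Pileup:
    """Accumulate base/deletion/insertion counts from the edit strings.

    Every alignment must target ``ref``; an edit string that does not
    exactly consume its stated query and reference spans raises an error
    naming the read.
    """
    ref_len = len(ref.bases)
    counts = np.zeros((ref_len, 5), dtype=np.int64)
    insertions: dict[int, Counter] = {}
    junction_cover = np.zeros(ref_len + 1, dtype=np.int64)
    for aln in alignments:
        if aln.ref_id != ref.ref_id:
            raise ValueError(f"alignment of {aln.read_id!r} targets {aln.ref_id!r}, not {ref.ref_id!r}")
        read = reads[aln.read_id]
        query = aln.oriented_query(read)
        qpos, rpos = aln.q_start, aln.r_start
        for op, length in parse_cigar(aln.cigar):
            if op in "=X":
                for t in range(length):
                    idx = _BASE_INDEX.get(query[qpos + t])
                    if idx is not None:  # N contributes nothing
                        counts[rpos + t, idx] += 1
                qpos += length
                rpos += length
            elif op == "D":  # gap in query: reference bases deleted
                counts[rpos : rpos + length, DELETION] += 1
                rpos += length
            elif op == "I":  # inserted query bases after reference position rpos-1
                insertions.setdefault(rpos - 1, Counter())[query[qpos : qpos + length]] += 1
                qpos += length
            else:
                raise ValueError(f"read {aln.read_id!r}: unknown cigar op {op!r}")
        if qpos != aln.q_end or rpos != aln.r_end:
            raise ValueError(
                f"read {aln.read_id!r}: edit string inconsistent with spans "
                f"(ended at q={qpos}/{aln.q_end}, r={rpos}/{aln.r_end})"
            )
        # junctions strictly inside the aligned reference span are covered
        if aln.r_end - aln.r_start >= 2:
            junction_cover[aln.r_start] += 1
            junction_cover[aln.r_end - 1] -= 1
    junction_depth = np.cumsum(junction_cover)[:ref_len]
    return Pileup(ref.ref_id, counts, insertions, junction_depth, len(alignments))


def call_consensus(
    pileup: Pileup,
    ref: ReferenceSeq,
    params: ConsensusParams | None = None,
) -> ConsensusSequence:
    """Plurality call per position; haploid, quality-blind.

    Ties go to the reference symbol when it is among the leaders, else to
    the lexicographically smallest symbol (deletion last).  Deletion wins
    emit nothing.  Insertions are emitted after a position when the most
    common inserted sequence is carried by more than
    ``insertion_threshold`` of the reads spanning the junction.
    """
    params = params or ConsensusParams()
    depth = pileup.depth
    if not depth.any():
        raise ValueError(f"empty pileup for {pileup.ref_id!r}")
    out: list[str] = []
    for pos in range(len(ref.bases)):
        if depth[pos] == 0:
            out.append(ref.bases[pos] if params.zero_depth_emits == "ref" else "N")
        else:
            col = pileup.counts[pos]
            top = col.max()
            leaders = [sym for sym in range(5) if col[sym] == top]
            ref_sym = _BASE_INDEX.get(ref.bases[pos], None)
            if ref_sym is not None and ref_sym in leaders:
                winner = ref_sym
            else:
                winner = leaders[0]  # A < C < G < T < deletion
            if winner != DELETION:
                out.append(_SYMBOLS[winner])
        ins = pileup.insertions.get(pos)
        if ins:
            seq, count = ins.most_common(1)[0]
            span = pileup.junction_depth[pos]
            if span > 0 and count > params.insertion_threshold * span:
                out.append(seq)
    return ConsensusSequence(pileup.ref_id, "".join(out), pileup.n_reads, depth)


def label_consensus(seq: ConsensusSequence, db: MarkerDatabase) -> tuple[str, int]:
    """Closest database reference to the consensus, by global edit distance.

    Ties break to the lexicographically smaller ref_id.  Deterministic.
    """
    if not db.refs:
        raise ValueError("cannot label against an empty database")
    best: tuple[int, str] | None = None
    for ref in sorted(db.refs, key=lambda r: r.ref_id):
        d = edlib.align(seq.bases, ref.bases, mode="NW")["editDistance"]
        if best is None or d < best[0]:
            best = (d, ref.ref_id)
    return best[1], best[0]


def consensus_for_reference(
    ref: ReferenceSeq,
    alignments: list[Alignment],
    reads: dict[str, Read],
    db: MarkerDatabase,
    params: ConsensusParams | None = None,
) -> ConsensusSequence:
    """Pileup -> plurality call -> closest-reference label, in one step."""
    pileup = build_pileup(alignments, reads, ref)
    cons = call_consensus(pileup, ref, params)
    cons.label = label_consensus(cons, db)
    return cons
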