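"""Pileup accumulation, plurality calling, and closest-reference labeling."""

from collections import Counter

import numpy as np
import pytest
from scipy import stats

from holopore.align import Alignment, AlignParams, banded_align
from holopore.consensus import (
    ConsensusParams,
    build_pileup,
    call_consensus,
    consensus_for_reference,
    label_consensus,
)
from holopore.io import Marker, MarkerDatabase, Read, ReferenceSeq
from holopore.simulate import ErrorModel, corrupt, make_variant_family

BASES = "ACGT"


def random_seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


def perfect_alignment(read_id, seq, ref, r_start=0):
    """Alignment of an indel-free read against ref starting at r_start."""
    ops = []
    for i, base in enumerate(seq):
        ops.append("=" if base == ref.bases[r_start + i] else "X")
    runs = []
    prev, count = ops[0], 0
    for op in ops:
        if op == prev:
            count += 1
        else:
            runs.append(f"{count}{prev}")
            prev, count = op, 1
    runs.append(f"{count}{prev}")
    matches = ops.count("=")
    params = AlignParams()
    score = params.match * matches + params.mismatch * (len(ops) - matches)
    return Alignment(
        read_id, ref.ref_id, score, matches / len(ops), 0, len(seq),
        r_start, r_start + len(seq), "+", "".join(runs), matches, len(ops), len(seq),
    )


@pytest.fixture()
def ref100():
    rng = np.random.default_rng(0)
    return ReferenceSeq("ref", random_seq(rng, 100), ["t"], Marker.ITS2)


class TestPileup:
    def test_single_perfect_read_depth(self, ref100):
        read = Read("r1", ref100.bases)
        pileup = build_pileup([perfect_alignment("r1", read.bases, ref100)], {"r1": read}, ref100)
        assert (pileup.depth == 1).all()

    def test_partial_coverage(self, ref100):
        seq = ref100.bases[20:60]
        read = Read("r1", seq)
        pileup = build_pileup([perfect_alignment("r1", seq, ref100, 20)], {"r1": read}, ref100)
        assert (pileup.depth[20:60] == 1).all()
        assert pileup.depth[:20].sum() == 0 and pileup.depth[60:].sum() == 0

    def test_disagreeing_column(self, ref100):
        a = ref100.bases
        b = a[:50] + ("A" if a[50] != "A" else "C") + a[51:]
        reads = {"r1": Read("r1", a), "r2": Read("r2", b)}
        pileup = build_pileup(
            [perfect_alignment("r1", a, ref100), perfect_alignment("r2", b, ref100)],
            reads, ref100,
        )
        col = pileup.counts[50]
        assert col.sum() == 2
        assert (col > 0).sum() == 2

    def test_counts_match_brute_force_recount(self):
        # random noisy reads aligned by the real aligner; recount by
        # expanding every alignment column by hand
        rng = np.random.default_rng(4)
        params = AlignParams()
        for _ in range(50):
            ref = ReferenceSeq("ref", random_seq(rng, 150), ["t"], Marker.ITS2)
            alignments, reads = [], {}
            for i in range(int(rng.integers(2, 6))):
                seq, _ = corrupt(ref.bases, ErrorModel(0.05, 0.02, 0.02), rng)
                aln = banded_align(seq, ref.bases, params, 0, 60)
                aln.read_id, aln.ref_id = f"r{i}", "ref"
                alignments.append(aln)
                reads[f"r{i}"] = Read(f"r{i}", seq)
            pileup = build_pileup(alignments, reads, ref)
            expected = np.zeros((150, 5), dtype=int)
            from holopore.align import parse_cigar

            for aln in alignments:
                q, qpos, rpos = reads[aln.read_id].bases, aln.q_start, aln.r_start
                for op, length in parse_cigar(aln.cigar):
                    if op in "=X":
                        for t in range(length):
                            expected[rpos + t, "ACGT".index(q[qpos + t])] += 1
                        qpos += length
                        rpos += length
                    elif op == "D":
                        expected[rpos : rpos + length, 4] += 1
                        rpos += length
                    else:
                        qpos += length
            assert (pileup.counts == expected).all()

    def test_inconsistent_edit_string_names_read(self, ref100):
        aln = perfect_alignment("bad", ref100.bases, ref100)
        aln.r_end = 99  # corrupt the span
        with pytest.raises(ValueError, match="bad"):
            build_pileup([aln], {"bad": Read("bad", ref100.bases)}, ref100)


class TestCallConsensus:
    def test_identical_reads_reproduce_reference(self, ref100):
        reads = {f"r{i}": Read(f"r{i}", ref100.bases) for i in range(5)}
        alignments = [perfect_alignment(rid, ref100.bases, ref100) for rid in reads]
        pileup = build_pileup(alignments, reads, ref100)
        cons = call_consensus(pileup, ref100)
        assert cons.bases == ref100.bases
        assert cons.n_support == 5

    def test_plurality_wins_sixty_forty(self, ref100):
        alt = "A" if ref100.bases[10] != "A" else "C"
        variant = ref100.bases[:10] + alt + ref100.bases[11:]
        reads, alignments = {}, []
        for i in range(10):
            seq = variant if i < 6 else ref100.bases
            reads[f"r{i}"] = Read(f"r{i}", seq)
            alignments.append(perfect_alignment(f"r{i}", seq, ref100))
        cons = call_consensus(build_pileup(alignments, reads, ref100), ref100)
        assert cons.bases[10] == alt

    def test_tie_goes_to_reference_base(self, ref100):
        alt = "A" if ref100.bases[10] != "A" else "C"
        variant = ref100.bases[:10] + alt + ref100.bases[11:]
        reads, alignments = {}, []
        for i in range(10):
            seq = variant if i < 5 else ref100.bases
            reads[f"r{i}"] = Read(f"r{i}", seq)
            alignments.append(perfect_alignment(f"r{i}", seq, ref100))
        cons = call_consensus(build_pileup(alignments, reads, ref100), ref100)
        assert cons.bases == ref100.bases

    def test_zero_depth_emits_reference_or_n(self, ref100):
        seq = ref100.bases[:40]
        reads = {"r": Read("r", seq)}
        alignments = [perfect_alignment("r", seq, ref100)]
        pileup = build_pileup(alignments, reads, ref100)
        cons = call_consensus(pileup, ref100)
        assert cons.bases == ref100.bases
        cons_n = call_consensus(pileup, ref100, ConsensusParams(zero_depth_emits="N"))
        assert cons_n.bases == ref100.bases[:40] + "N" * 60

    def test_majority_deletion_removes_base(self, ref100):
        # 3 reads skip position 30, 1 read covers it
        with_del = ref100.bases[:30] + ref100.bases[31:]
        reads, alignments = {}, []
        params = AlignParams()
        for i in range(4):
            seq = with_del if i < 3 else ref100.bases
            aln = banded_align(seq, ref100.bases, params, 0, 50)
            aln.read_id, aln.ref_id = f"r{i}", "ref"
            reads[f"r{i}"] = Read(f"r{i}", seq)
            alignments.append(aln)
        cons = call_consensus(build_pileup(alignments, reads, ref100), ref100)
        assert cons.bases == with_del

    def test_majority_insertion_emitted(self, ref100):
        with_ins = ref100.bases[:30] + "GGG" + ref100.bases[30:]
        reads, alignments = {}, []
        params = AlignParams()
        for i in range(4):
            seq = with_ins if i < 3 else ref100.bases
            aln = banded_align(seq, ref100.bases, params, 0, 50)
            aln.read_id, aln.ref_id = f"r{i}", "ref"
            reads[f"r{i}"] = Read(f"r{i}", seq)
            alignments.append(aln)
        cons = call_consensus(build_pileup(alignments, reads, ref100), ref100)
        assert cons.bases == with_ins

    def test_empty_pileup_rejected(self, ref100):
        pileup = build_pileup([], {}, ref100)
        with pytest.raises(ValueError):
            call_consensus(pileup, ref100)


class TestSiteRecovery:
    def test_depth_30_recovers_single_site_difference(self):
        """Truth differs from the reference at one site; depth-30 pileups at
        5% iid substitution noise recover it essentially always (binomial
        cross-check below)."""
        rng = np.random.default_rng(8)
        n_rep, depth, L = 120, 30, 120
        successes = 0
        for _ in range(n_rep):
            ref_seq = random_seq(rng, L)
            site = int(rng.integers(0, L))
            alt = BASES[(BASES.index(ref_seq[site]) + 1 + int(rng.integers(0, 3))) % 4]
            truth = ref_seq[:site] + alt + ref_seq[site + 1 :]
            ref = ReferenceSeq("ref", ref_seq, ["t"], Marker.ITS2)
            reads, alignments = {}, []
            for i in range(depth):
                noisy = list(truth)
                errs = rng.random(L) < 0.05
                for pos in np.flatnonzero(errs):
                    noisy[pos] = BASES[(BASES.index(noisy[pos]) + 1 + int(rng.integers(0, 3))) % 4]
                seq = "".join(noisy)
                reads[f"r{i}"] = Read(f"r{i}", seq)
                alignments.append(perfect_alignment(f"r{i}", seq, ref))
            cons = call_consensus(build_pileup(alignments, reads, ref), ref)
            if cons.bases[site] == alt:
                successes += 1
        # binomial cross-check: per-read correct w.p. 0.95; a wrong call
        # needs the truth base to lose the column plurality
        p_lower = stats.binom.cdf(depth // 2, depth, 0.95)
        assert p_lower < 1e-6
        assert successes / n_rep >= 0.99


class TestLabel:
    def test_exact_database_entry_distance_zero(self):
        fam = make_variant_family(200, 3, 3, seed=6, prefix="L")
        db = MarkerDatabase(Marker.ITS2, fam)
        from holopore.consensus import ConsensusSequence

        seq = ConsensusSequence("L1", fam[1].bases, 12, np.ones(200))
        assert label_consensus(seq, db) == ("L1", 0)

    def test_one_substitution_from_source(self):
        fam = make_variant_family(200, 2, 5, seed=7, prefix="L")
        db = MarkerDatabase(Marker.ITS2, fam)
        mutated = ("A" if fam[0].bases[0] != "A" else "C") + fam[0].bases[1:]
        from holopore.consensus import ConsensusSequence

        seq = ConsensusSequence("x", mutated, 12, np.ones(200))
        assert label_consensus(seq, db) == ("L0", 1)
        # deterministic across calls
        assert label_consensus(seq, db) == label_consensus(seq, db)

    def test_empty_db_rejected(self):
        from holopore.consensus import ConsensusSequence

        seq = ConsensusSequence("x", "ACGT", 12, np.ones(4))
        with pytest.raises(ValueError):
            label_consensus(seq, MarkerDatabase(Marker.ITS2, []))
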