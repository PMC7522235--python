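"""Synthetic nanopore amplicon reads with known truth.

The simulator emulates the multiplexed tri-marker assay: each molecule is a
marker amplicon (host 18S ~1.8 kb, Symbiodiniaceae ITS2 ~250 bp, bacterial
16S ~1.3 kb) carrying, on both ends, the ONT four-primer-PCR tail, a
sample barcode, and the marker primer.  Reads are corrupted with a
configurable substitution/insertion/deletion model, reverse-complemented
with probability 0.5, and mixed with optional junk reads and chimeras
(two amplicons concatenated, the middle-adapter case).  A truth table
records sample, marker, source reference, strand and class per read, so
every downstream stage is verifiable offline.

Reference fixtures (``make_*_db``) generate small marker databases with
near-identical variant families — the situation that drives read
mis-assignment between database neighbours at high error rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .io import (
    Marker,
    MarkerDatabase,
    Read,
    ReferenceSeq,
    RefFlag,
    atomic_write,
    revcomp,
    write_fastq,
    write_tsv,
)

# ---------------------------------------------------------------------------
# Published scheme constants (tails and marker primers of the assay)
# ---------------------------------------------------------------------------

#: ONT four-primer-PCR tails added 5' of barcode+primer on each strand.
FWD_TAIL = "TTTCTGTTGGTGCTGATATTGC"
REV_TAIL = "ACTTGCCTGTCGCTCTATCTTC"

#: Marker primer pairs (5'->3' on their own strand; IUPAC degeneracies kept).
MARKER_PRIMERS: dict[Marker, tuple[str, str]] = {
    Marker.HOST_18S: ("AACCTGGTTGATCCTGCCAGT", "TGATCCTTCTGCAGGTTCACCTAC"),
    Marker.BACT_16S: ("AGAGTTTGATCMTGGCTCAG", "TACGGYTACCTTGTTACGACTT"),
    Marker.ITS2: ("GAATTGCAGAACTCCGTGAACC", "CGGGTTCWCTTGTYTGACTTCATGC"),
}

#: Default amplicon (insert) lengths per marker, bp.
AMPLICON_LENGTHS: dict[Marker, int] = {
    Marker.HOST_18S: 1800,
    Marker.ITS2: 250,
    Marker.BACT_16S: 1300,
}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

BASES = "ACGT"
N_BARCODES = 12
BARCODE_LENGTH = 24
BARCODE_MIN_DIST = 8
DEFAULT_FLAT_QUALITY = 12


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


# ---------------------------------------------------------------------------
# Error model
# ---------------------------------------------------------------------------


@dataclass
class ErrorModel:
    """Per-base substitution/insertion/deletion probabilities.

    Defaults approximate an early (R7.9-era) nanopore error profile of about
    15% total error, split 6% substitution / 4% insertion / 5% deletion.
    """

    sub_rate: float = 0.06
    ins_rate: float = 0.04
    del_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name}={rate} outside [0, 1)")
        if self.sub_rate + self.ins_rate + self.del_rate >= 1.0:
            raise ValueError("total error rate must be < 1")

    @property
    def total(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate

    @classmethod
    def with_total(cls, total: float, seed: int = 0) -> "ErrorModel":
        """Scale the default 6/4/5 split to a given total error rate."""
        if total == 0:
            return cls(0.0, 0.0, 0.0, seed)
        return cls(0.06 / 0.15 * total, 0.04 / 0.15 * total, 0.05 / 0.15 * total, seed)


def corrupt(
    seq: str, model: ErrorModel, rng: np.random.Generator
) -> tuple[str, list[tuple[str, int]]]:
    """Apply the error model to a sequence; return (mutated, edit trace).

    Per input base: deletion with probability ``del_rate``; otherwise
    substitution with probability ``sub_rate`` (uniform over the three
    alternative bases); after each emitted base an insertion of a uniform
    random base with probability ``ins_rate``.  The trace lists
    ``(op, input_position)`` with op in {M, S, D, I}; insertions carry the
    input position after which they were emitted.
    """
    if not seq:
        return "", []
    n = len(seq)
    u = rng.random((n, 3))
    subs_choice = rng.integers(0, 3, size=n)
    out: list[str] = []
    trace: list[tuple[str, int]] = []
    for i, base in enumerate(seq):
        if u[i, 0] < model.del_rate:
            trace.append(("D", i))
            continue
        if u[i, 1] < model.sub_rate:
            alternatives = [b for b in BASES if b != base]
            base = alternatives[subs_choice[i]]
            trace.append(("S", i))
        else:
            trace.append(("M", i))
        out.append(base)
        if u[i, 2] < model.ins_rate:
            out.append(BASES[rng.integers(0, 4)])
            trace.append(("I", i))
    return "".join(out), trace


# ---------------------------------------------------------------------------
# Primer scheme
# ---------------------------------------------------------------------------


@dataclass
class PrimerScheme:
    """Tails, the 12 sample barcodes, and the marker primer pairs."""

    fwd_tail: str = FWD_TAIL
    rev_tail: str = REV_TAIL
    barcodes: list[str] = field(default_factory=list)
    primers: dict[Marker, tuple[str, str]] = field(default_factory=lambda: dict(MARKER_PRIMERS))
    sample_to_barcode: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.barcodes) != N_BARCODES:
            raise ValueError(f"expected {N_BARCODES} barcodes, got {len(self.barcodes)}")
        import edlib

        for i in range(len(self.barcodes)):
            for j in range(i + 1, len(self.barcodes)):
                d = edlib.align(self.barcodes[i], self.barcodes[j], mode="NW")["editDistance"]
                if d < BARCODE_MIN_DIST:
                    raise ValueError(
                        f"barcodes {i} and {j} are only {d} edits apart "
                        f"(minimum {BARCODE_MIN_DIST})"
                    )
        for sample, idx in self.sample_to_barcode.items():
            if not 0 <= idx < len(self.barcodes):
                raise ValueError(f"sample {sample!r} maps to invalid barcode index {idx}")

    @property
    def samples(self) -> list[str]:
        return sorted(self.sample_to_barcode)

    def barcode_of(self, sample_id: str) -> str:
        if sample_id not in self.sample_to_barcode:
            raise KeyError(f"unknown sample {sample_id!r}")
        return self.barcodes[self.sample_to_barcode[sample_id]]


def random_barcodes(
    rng: np.random.Generator,
    n: int = N_BARCODES,
    length: int = BARCODE_LENGTH,
    min_dist: int = BARCODE_MIN_DIST,
) -> list[str]:
    """Draw n random barcodes with pairwise edit distance >= min_dist."""
    import edlib

    barcodes: list[str] = []
    attempts = 0
    while len(barcodes) < n:
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("could not place barcodes at the requested distance")
        candidate = _random_seq(rng, length)
        if all(
            edlib.align(candidate, b, mode="NW")["editDistance"] >= min_dist for b in barcodes
        ):
            barcodes.append(candidate)
    return barcodes


def default_scheme(seed: int = 0, sample_ids: Sequence[str] | None = None) -> PrimerScheme:
    """The published tails/primers plus 12 deterministic synthetic barcodes.

    The real barcode sequences of the kit are not public, so fixture
    barcodes are random 24-mers at pairwise edit distance >= 8.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(101,)))
    barcodes = random_barcodes(rng)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:02d}" for i in range(N_BARCODES)]
    if len(sample_ids) > N_BARCODES:
        raise ValueError("at most 12 samples per scheme")
    return PrimerScheme(
        barcodes=barcodes,
        sample_to_barcode={s: i for i, s in enumerate(sample_ids)},
    )


def save_scheme(scheme: PrimerScheme, path: str | Path) -> None:
    payload = {
        "fwd_tail": scheme.fwd_tail,
        "rev_tail": scheme.rev_tail,
        "barcodes": list(scheme.barcodes),
        "primers": {m.value: list(p) for m, p in scheme.primers.items()},
        "sample_to_barcode": dict(scheme.sample_to_barcode),
    }
    with atomic_write(path) as handle:
        yaml.safe_dump(payload, handle, sort_keys=True)


def load_scheme(path: str | Path) -> PrimerScheme:
    with open(path) as handle:
        payload = yaml.safe_load(handle)
    return PrimerScheme(
        fwd_tail=payload["fwd_tail"],
        rev_tail=payload["rev_tail"],
        barcodes=list(payload["barcodes"]),
        primers={Marker(m): (p[0], p[1]) for m, p in payload["primers"].items()},
        sample_to_barcode=dict(payload["sample_to_barcode"]),
    )


# ---------------------------------------------------------------------------
# Amplicon construction
# ---------------------------------------------------------------------------


def realize_primer(primer: str, rng: np.random.Generator) -> str:
    """Resolve IUPAC degeneracies uniformly at random (the PCR analogy)."""
    out = []
    for ch in primer:
        options = IUPAC.get(ch)
        if options is None:
            raise ValueError(f"invalid primer base {ch!r}")
        out.append(options if len(options) == 1 else options[rng.integers(0, len(options))])
    return "".join(out)


def build_amplicon(
    ref: ReferenceSeq,
    scheme: PrimerScheme,
    sample_id: str,
    rng: np.random.Generator | None = None,
) -> str:
    """Error-free amplicon: tail+barcode+primer on both ends of the insert.

    Layout (forward strand):
    ``fwd_tail  barcode  fwd_primer  insert  rc(rev_primer)  rc(barcode)  rc(rev_tail)``
    Degenerate primer positions are realized at construction time.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    barcode = scheme.barcode_of(sample_id)
    fwd_primer, rev_primer = scheme.primers[ref.marker]
    fwd = realize_primer(fwd_primer, rng)
    rev = realize_primer(rev_primer, rng)
    return (
        scheme.fwd_tail
        + barcode
        + fwd
        + ref.bases
        + revcomp(rev)
        + revcomp(barcode)
        + revcomp(scheme.rev_tail)
    )


# ---------------------------------------------------------------------------
# Community truth and full-run simulation
# ---------------------------------------------------------------------------


@dataclass
class CommunityTruth:
    """Known composition of one sample: per-marker (ref_id, weight) plus counts."""

    sample_id: str
    composition: dict[Marker, list[tuple[str, float]]]
    n_reads: dict[Marker, int]

    def __post_init__(self) -> None:
        for marker, entries in self.composition.items():
            weights = [w for _, w in entries]
            if any(w < 0 for w in weights):
                raise ValueError(f"{self.sample_id}/{marker}: negative weight")
            if entries and not math.isclose(sum(weights), 1.0, abs_tol=1e-9):
                raise ValueError(f"{self.sample_id}/{marker}: weights sum to {sum(weights)}")


TRUTH_COLUMNS = ("read_id", "sample", "marker", "ref_id", "strand", "class")


def simulate_run(
    truths: Sequence[CommunityTruth],
    dbs: dict[Marker, MarkerDatabase],
    scheme: PrimerScheme,
    model: ErrorModel,
    seed: int,
    junk_fraction: float = 0.0,
    chimera_fraction: float = 0.0,
    fastq_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> tuple[list[Read], list[tuple]]:
    """Simulate one pooled multiplexed MinION run.

    Reads are drawn per marker per sample according to the truth weights;
    each is a corrupted amplicon, reverse-complemented with probability 0.5.
    ``junk_fraction`` of additional reads are random sequence and
    ``chimera_fraction`` are two concatenated amplicons (the internal
    junction retains a full tail+barcode block, porechop's middle-adapter
    case).  Deterministic given the seed.  Returns the reads and the truth
    rows (and writes them when paths are given).
    """
    for truth in truths:
        for marker, entries in truth.composition.items():
            known = dbs[marker].by_id
            for ref_id, _ in entries:
                if ref_id not in known:
                    raise ValueError(
                        f"truth for {truth.sample_id}/{marker.value} references "
                        f"unknown ref {ref_id!r}"
                    )
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    reads: list[Read] = []
    truth_rows: list[tuple] = []
    counter = 0

    def emit(bases: str, sample: str, marker: str, ref_id: str, strand: str, cls: str) -> None:
        nonlocal counter
        counter += 1
        read_id = f"sim{counter:07d}"
        reads.append(
            Read(
                read_id,
                bases,
                [DEFAULT_FLAT_QUALITY] * len(bases),
                source_tags={
                    "sample": sample,
                    "marker": marker,
                    "ref_id": ref_id,
                    "strand": strand,
                    "class": cls,
                },
            )
        )
        truth_rows.append((read_id, sample, marker, ref_id, strand, cls))

    def one_amplicon(truth: CommunityTruth, marker: Marker) -> tuple[str, str]:
        entries = truth.composition[marker]
        weights = np.array([w for _, w in entries])
        idx = rng.choice(len(entries), p=weights / weights.sum())
        ref_id = entries[idx][0]
        ref = dbs[marker].by_id[ref_id]
        return ref_id, build_amplicon(ref, scheme, truth.sample_id, rng)

    n_amplicon_total = 0
    for truth in truths:
        for marker, n in truth.n_reads.items():
            n_amplicon_total += n
            for _ in range(n):
                ref_id, amplicon = one_amplicon(truth, marker)
                mutated, _ = corrupt(amplicon, model, rng)
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    mutated = revcomp(mutated)
                if not mutated:
                    mutated = "N"
                emit(mutated, truth.sample_id, marker.value, ref_id, strand, "amplicon")

    n_junk = int(round(junk_fraction * n_amplicon_total))
    for _ in range(n_junk):
        length = int(rng.integers(200, 1200))
        emit(_random_seq(rng, length), "", "", "", "+", "junk")

    n_chimera = int(round(chimera_fraction * n_amplicon_total))
    markered = [t for t in truths if t.n_reads]
    for _ in range(n_chimera):
        parts = []
        sample = ""
        for _ in range(2):
            truth = markered[rng.integers(0, len(markered))]
            marker = list(truth.n_reads)[rng.integers(0, len(truth.n_reads))]
            _, amplicon = one_amplicon(truth, marker)
            parts.append(amplicon)
            sample = truth.sample_id
        mutated, _ = corrupt("".join(parts), model, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            mutated = revcomp(mutated)
        if not mutated:
            mutated = "N"
        emit(mutated, sample, "", "", strand, "chimera")

    if fastq_path is not None:
        write_fastq(reads, fastq_path)
    if truth_path is not None:
        write_tsv(truth_rows, TRUTH_COLUMNS, truth_path)
    return reads, truth_rows


# ---------------------------------------------------------------------------
# Reference fixtures
# ---------------------------------------------------------------------------


def make_variant_family(
    base_length: int,
    n_variants: int,
    substitutions_per_variant: int,
    seed: int,
    marker: Marker = Marker.ITS2,
    prefix: str = "V",
    taxonomy: Sequence[str] | None = None,
) -> list[ReferenceSeq]:
    """A base sequence plus near-identical variants.

    Returns one random sequence of ``base_length`` plus ``n_variants - 1``
    derived sequences, each exactly ``substitutions_per_variant``
    substitutions away from the base (at distinct positions, so any two
    derived variants are <= 2x that many substitutions apart).  Mimics the
    single-substitution database neighbours that inflate observed richness
    at high read error rates.
    """
    if base_length < 50:
        raise ValueError("base_length must be >= 50")
    if substitutions_per_variant < 1:
        raise ValueError("substitutions_per_variant must be >= 1")
    if substitutions_per_variant >= base_length:
        raise ValueError("substitutions_per_variant must be < base_length")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(11,)))
    base = _random_seq(rng, base_length)
    tax = list(taxonomy) if taxonomy else ["Symbiodiniaceae"]
    refs = [ReferenceSeq(f"{prefix}0", base, tax, marker)]
    for v in range(1, n_variants):
        positions = rng.choice(base_length, size=substitutions_per_variant, replace=False)
        bases = list(base)
        for pos in positions:
            alternatives = [b for b in BASES if b != bases[pos]]
            bases[pos] = alternatives[rng.integers(0, 3)]
        refs.append(ReferenceSeq(f"{prefix}{v}", "".join(bases), tax, marker))
    return refs


def make_host_db(
    seed: int,
    n_corals: int = 20,
    n_sym_decoys: int = 5,
    length: int | None = None,
) -> tuple[MarkerDatabase, list[str]]:
    """Synthetic host 18S database plus the Symbiodiniaceae decoy ID list."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(21,)))
    length = length or AMPLICON_LENGTHS[Marker.HOST_18S]
    families = ["Acroporidae", "Poritidae", "Pocilloporidae", "Fungiidae", "Milleporidae"]
    refs = []
    for i in range(n_corals):
        family = families[i % len(families)]
        refs.append(
            ReferenceSeq(
                f"coral18S_{i:03d}",
                _random_seq(rng, length),
                ["Eukaryota", "Cnidaria", family, f"Genus{i:03d}"],
                Marker.HOST_18S,
            )
        )
    decoy_ids = []
    for i in range(n_sym_decoys):
        rid = f"sym18S_{i:03d}"
        decoy_ids.append(rid)
        refs.append(
            ReferenceSeq(
                rid,
                _random_seq(rng, length),
                ["Eukaryota", "Dinoflagellata", "Symbiodiniaceae"],
                Marker.HOST_18S,
                {RefFlag.SYMBIODINIACEAE_18S},
            )
        )
    return MarkerDatabase(Marker.HOST_18S, refs), decoy_ids


def make_its2_db(
    seed: int,
    n_backbone: int = 10,
    family_kwargs: dict | None = None,
) -> MarkerDatabase:
    """Synthetic Symbiodiniaceae ITS2 database (~250 bp entries).

    Contains a variant family of near-identical sequences (default: one
    base plus neighbours 1 substitution away) on top of random backbone
    entries, mirroring the C66/C57/C74-style neighbourhoods of the real
    database.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(22,)))
    kwargs = {
        "base_length": AMPLICON_LENGTHS[Marker.ITS2],
        "n_variants": 3,
        "substitutions_per_variant": 1,
        "seed": seed,
        "prefix": "C",
        "taxonomy": ["Symbiodiniaceae", "Cladocopium"],
    }
    kwargs.update(family_kwargs or {})
    refs = make_variant_family(marker=Marker.ITS2, **kwargs)
    for i in range(n_backbone):
        genus = "Durusdinium" if i % 2 else "Cladocopium"
        refs.append(
            ReferenceSeq(
                f"ITS2_{i:03d}",
                _random_seq(rng, AMPLICON_LENGTHS[Marker.ITS2]),
                ["Symbiodiniaceae", genus],
                Marker.ITS2,
            )
        )
    return MarkerDatabase(Marker.ITS2, refs)


def make_16s_db(
    seed: int,
    n_bacteria: int = 20,
    n_chloroplast: int = 2,
    length: int | None = None,
) -> MarkerDatabase:
    """Synthetic bacterial 16S database with Greengenes-style taxonomy.

    A fraction of entries are eukaryote chloroplast 16S, labelled with the
    "Chloroplast" class rank the way Greengenes does.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(23,)))
    length = length or AMPLICON_LENGTHS[Marker.BACT_16S]
    lineages = [
        ["Bacteria", "Proteobacteria", "Gammaproteobacteria", "Oceanospirillales",
         "Endozoicomonadaceae", "Endozoicomonas"],
        ["Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rhizobiales",
         "Rhizobiaceae", "Rhizobium"],
        ["Bacteria", "Proteobacteria", "Gammaproteobacteria", "Chromatiales",
         "Ectothiorhodospiraceae", "Thioalkalivibrio"],
        ["Bacteria", "Proteobacteria", "Gammaproteobacteria", "Alteromonadales",
         "Pseudoalteromonadaceae", "Pseudoalteromonas"],
        ["Bacteria", "Spirochaetes", "Spirochaetia", "Spirochaetales",
         "Spirochaetaceae", "Spirochaeta"],
    ]
    refs = []
    for i in range(n_bacteria):
        refs.append(
            ReferenceSeq(
                f"bact16S_{i:03d}",
                _random_seq(rng, length),
                list(lineages[i % len(lineages)]),
                Marker.BACT_16S,
            )
        )
    for i in range(n_chloroplast):
        refs.append(
            ReferenceSeq(
                f"chloro16S_{i:03d}",
                _random_seq(rng, length),
                ["Bacteria", "Cyanobacteria", "Chloroplast", "Streptophyta"],
                Marker.BACT_16S,
                {RefFlag.CHLOROPLAST},
            )
        )
    return MarkerDatabase(Marker.BACT_16S, refs)


def default_databases(seed: int = 0) -> tuple[dict[Marker, MarkerDatabase], list[str]]:
    """All three fixture databases plus the host decoy exclusion-ID list."""
    host, decoys = make_host_db(seed)
    return (
        {
            Marker.HOST_18S: host,
            Marker.ITS2: make_its2_db(seed),
            Marker.BACT_16S: make_16s_db(seed),
        },
        decoys,
    )


def default_truths(
    dbs: dict[Marker, MarkerDatabase],
    sample_ids: Sequence[str],
    n_reads: dict[Marker, int] | None = None,
    seed: int = 0,
    include_chimerogenic_refs: bool = False,
) -> list[CommunityTruth]:
    """A plausible 12-sample community: one host, 1-2 symbionts, 2-4 bacteria."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(31,)))
    if n_reads is None:
        n_reads = {Marker.HOST_18S: 15, Marker.ITS2: 25, Marker.BACT_16S: 20}
    host_ids = [r.ref_id for r in dbs[Marker.HOST_18S].refs if RefFlag.SYMBIODINIACEAE_18S not in r.flags]
    its2_ids = [r.ref_id for r in dbs[Marker.ITS2].refs]
    bact_ids = [r.ref_id for r in dbs[Marker.BACT_16S].refs if RefFlag.CHLOROPLAST not in r.flags]
    truths = []
    for s, sample in enumerate(sample_ids):
        host = host_ids[s % len(host_ids)]
        n_sym = 1 + int(rng.integers(0, 2))
        sym = list(rng.choice(its2_ids, size=n_sym, replace=False))
        sym_w = _round_weights(rng.dirichlet(np.ones(n_sym) * 5.0))
        n_bact = 2 + int(rng.integers(0, 3))
        bact = list(rng.choice(bact_ids, size=n_bact, replace=False))
        bact_w = _round_weights(rng.dirichlet(np.ones(n_bact) * 5.0))
        truths.append(
            CommunityTruth(
                sample,
                {
                    Marker.HOST_18S: [(host, 1.0)],
                    Marker.ITS2: list(zip(sym, sym_w)),
                    Marker.BACT_16S: list(zip(bact, bact_w)),
                },
                dict(n_reads),
            )
        )
    return truths


def _round_weights(weights: np.ndarray) -> list[float]:
    rounded = np.round(weights, 6)
    rounded[-1] = 1.0 - rounded[:-1].sum()
    return [float(w) for w in rounded]
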