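"""Core record types and on-disk formats.

Every pipeline stage consumes the types defined here: :class:`Read` for
nanopore reads, :class:`ReferenceSeq` / :class:`MarkerDatabase` for the three
marker reference sets (coral host 18S, Symbiodiniaceae ITS2, bacterial 16S),
plus atomic writers for FASTA/TSV/GraphML/JSON outputs.

Coordinates are 0-based, half-open throughout the package.  Quality scores
are carried through demultiplexing and trimming but never enter any scoring
decision (the consensus step deliberately ignores base qualities).
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from contextlib import contextmanager
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger("holopore")

PHRED_OFFSET = 33

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


class Marker(str, Enum):
    """The three marker genes of the tri-marker assay."""

    HOST_18S = "HOST_18S"
    ITS2 = "ITS2"
    BACT_16S = "BACT_16S"


class RefFlag(str, Enum):
    CHLOROPLAST = "CHLOROPLAST"
    SYMBIODINIACEAE_18S = "SYMBIODINIACEAE_18S"


class ParseError(ValueError):
    """Malformed input file (FASTQ/FASTA/scheme/config)."""


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass
class Read:
    """One basecalled nanopore read.

    ``source_tags`` holds free-form annotations, e.g. truth labels attached
    by the simulator (sample of origin, source reference, strand, class).
    """

    read_id: str
    bases: str
    quals: list[int] | None = None
    source_tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.quals)} quality values "
                f"for {len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ReferenceSeq:
    """A reference marker sequence with parsed taxonomy.

    ``taxonomy`` is an ordered rank list (domain..species for 16S under the
    Greengenes dialect; marker-appropriate labels otherwise).  ``flags``
    mark chloroplast 16S entries and the Symbiodiniaceae 18S decoys carried
    in the host database solely to absorb (and then discard) symbiont reads.
    """

    ref_id: str
    bases: str
    taxonomy: list[str]
    marker: Marker
    flags: set[RefFlag] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.taxonomy:
            raise ValueError(f"reference {self.ref_id!r}: empty taxonomy")


@dataclass
class MarkerDatabase:
    """All references for one marker; the minimizer index is built lazily."""

    marker: Marker
    refs: list[ReferenceSeq]
    # (k, w) -> index; populated by align.build_index
    _index_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ref in self.refs:
            if ref.ref_id in seen:
                raise ValueError(f"duplicate ref_id {ref.ref_id!r}")
            seen.add(ref.ref_id)
            if ref.marker != self.marker:
                raise ValueError(
                    f"reference {ref.ref_id!r} has marker {ref.marker}, "
                    f"database is {self.marker}"
                )

    @property
    def by_id(self) -> dict[str, ReferenceSeq]:
        return {r.ref_id: r for r in self.refs}

    def __len__(self) -> int:
        return len(self.refs)

    def subset(self, ref_ids: Iterable[str]) -> "MarkerDatabase":
        wanted = set(ref_ids)
        return MarkerDatabase(self.marker, [r for r in self.refs if r.ref_id in wanted])


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream reads from a Sanger Phred+33 FASTQ file, in file order.

    Raises :class:`ParseError` naming the (0-based) record index on a
    malformed record or a base/quality length mismatch.
    """
    with open(path) as handle:
        parser = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise ParseError(f"{path}: malformed FASTQ record {index}: {exc}") from exc
            if len(seq) != len(qual):
                raise ParseError(
                    f"{path}: record {index}: {len(seq)} bases but {len(qual)} qualities"
                )
            if not seq:
                raise ParseError(f"{path}: record {index}: empty sequence")
            read_id = title.split()[0]
            yield Read(read_id, seq, [ord(c) - PHRED_OFFSET for c in qual])
            index += 1


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads as FASTQ (flat Q12 when a read carries no qualities)."""
    n = 0
    with atomic_write(path) as handle:
        for read in reads:
            quals = read.quals if read.quals is not None else [12] * len(read.bases)
            qline = "".join(chr(q + PHRED_OFFSET) for q in quals)
            handle.write(f"@{read.read_id}\n{read.bases}\n+\n{qline}\n")
            n += 1
    return n


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> int:
    n = 0
    with atomic_write(path) as handle:
        for header, seq in records:
            handle.write(f">{header}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Reference databases and taxonomy dialects
# ---------------------------------------------------------------------------

GREENGENES_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

#: Rank names by position, shared across dialects for roll-ups.
RANK_ORDER = ("domain", "phylum", "class", "order", "family", "genus", "species")


def parse_taxonomy(text: str, dialect: str, strict: bool = True) -> list[str]:
    """Parse a header taxonomy string under the named dialect.

    ``greengenes``: semicolon-separated with k__/p__/.../s__ rank prefixes
    (prefixes stripped; empty ranks kept as "").  ``plain``: semicolon
    separated, no prefixes.  Under lenient mode an unparseable string yields
    ``["unknown"]`` with a logged warning.
    """
    text = text.strip()
    if dialect not in ("greengenes", "plain"):
        raise ValueError(f"unknown taxonomy dialect {dialect!r}")
    parts = [p.strip() for p in text.split(";")] if text else []
    if dialect == "greengenes":
        ranks = []
        ok = bool(parts)
        for i, part in enumerate(parts):
            prefix = GREENGENES_PREFIXES[i] if i < len(GREENGENES_PREFIXES) else None
            if prefix is not None and part.startswith(prefix):
                ranks.append(part[len(prefix) :])
            else:
                ok = False
                break
        if not ok:
            if strict:
                raise ParseError(f"taxonomy not in greengenes dialect: {text!r}")
            logger.warning("unparseable taxonomy %r; using 'unknown'", text)
            return ["unknown"]
        return ranks
    # plain
    if not parts:
        if strict:
            raise ParseError(f"empty taxonomy string: {text!r}")
        logger.warning("empty taxonomy; using 'unknown'")
        return ["unknown"]
    return parts


def read_reference_db(
    path: str | Path,
    marker: Marker,
    taxonomy_dialect: str = "greengenes",
    exclusion_ids: Iterable[str] | None = None,
    strict: bool = True,
) -> MarkerDatabase:
    """Load a marker reference FASTA into a :class:`MarkerDatabase`.

    The CHLOROPLAST flag is set when any taxonomy rank equals "Chloroplast"
    (case-insensitive), following the Greengenes convention for plastid 16S.
    ``exclusion_ids`` lists the reference IDs to flag SYMBIODINIACEAE_18S —
    the decoy symbiont 18S entries added to the host database.
    """
    excluded = set(exclusion_ids or ())
    refs: list[ReferenceSeq] = []
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            fields = header.split(None, 1)
            ref_id = fields[0]
            tax_text = fields[1] if len(fields) > 1 else ""
            if tax_text:
                taxonomy = parse_taxonomy(tax_text, taxonomy_dialect, strict=strict)
            else:
                if strict:
                    raise ParseError(f"{path}: reference {ref_id!r} has no taxonomy")
                logger.warning("reference %r has no taxonomy; using 'unknown'", ref_id)
                taxonomy = ["unknown"]
            flags: set[RefFlag] = set()
            if any(rank.lower() == "chloroplast" for rank in taxonomy):
                flags.add(RefFlag.CHLOROPLAST)
            if ref_id in excluded:
                flags.add(RefFlag.SYMBIODINIACEAE_18S)
            refs.append(ReferenceSeq(ref_id, seq.upper(), taxonomy, marker, flags))
    return MarkerDatabase(marker, refs)


def write_reference_db(db: MarkerDatabase, path: str | Path, dialect: str = "plain") -> int:
    """Serialize a database back to FASTA with taxonomy-bearing headers."""

    def fmt(ref: ReferenceSeq) -> str:
        if dialect == "greengenes":
            tax = ";".join(
                f"{GREENGENES_PREFIXES[i]}{rank}" if i < len(GREENGENES_PREFIXES) else rank
                for i, rank in enumerate(ref.taxonomy)
            )
        else:
            tax = ";".join(ref.taxonomy)
        return f"{ref.ref_id} {tax}"

    return write_fasta(((fmt(r), r.bases) for r in db.refs), path)


# ---------------------------------------------------------------------------
# Atomic output writers
# ---------------------------------------------------------------------------


@contextmanager
def atomic_write(path: str | Path, mode: str = "w"):
    """Write to a temp file in the target directory, then rename.

    No partial file is ever left at the destination path.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, mode) as handle:
            yield handle
        os.replace(tmp, path)
    except BaseException:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise


def write_tsv(
    rows: Iterable[Sequence], header: Sequence[str], path: str | Path, float_fmt: str = "%.6f"
) -> int:
    """Tab-delimited UTF-8 with a header row; floats formatted to 6 decimals."""
    n = 0
    with atomic_write(path) as handle:
        handle.write("\t".join(header) + "\n")
        for row in rows:
            cells = []
            for value in row:
                if isinstance(value, float):
                    cells.append(float_fmt % value)
                elif value is None:
                    cells.append("")
                else:
                    cells.append(str(value))
            handle.write("\t".join(cells) + "\n")
            n += 1
    return n


def write_json(obj, path: str | Path) -> None:
    with atomic_write(path) as handle:
        json.dump(obj, handle, indent=2, sort_keys=True)
        handle.write("\n")


def write_outputs(
    out_dir: str | Path,
    consensus_fastas: dict[str, list[tuple[str, str]]] | None = None,
    tables: dict[str, tuple[Sequence[str], list[Sequence]]] | None = None,
    graph=None,
    metadata: dict | None = None,
) -> list[str]:
    """Write a result bundle: consensus FASTAs, TSV tables, GraphML, metadata.

    Returns the list of files written (relative to ``out_dir``).  Each file
    is written atomically; an unwritable path raises before any partial
    table is left behind.
    """
    import networkx as nx

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    for name, records in (consensus_fastas or {}).items():
        write_fasta(records, out_dir / name)
        written.append(name)
    for name, (header, rows) in (tables or {}).items():
        write_tsv(rows, header, out_dir / name)
        written.append(name)
    if graph is not None:
        target = out_dir / "network.graphml"
        fd, tmp = tempfile.mkstemp(dir=out_dir, suffix=".tmp")
        os.close(fd)
        try:
            nx.write_graphml(graph, tmp)
            os.replace(tmp, target)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise
        written.append("network.graphml")
    if metadata is not None:
        write_json(metadata, out_dir / "run_metadata.json")
        written.append("run_metadata.json")
    return written
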