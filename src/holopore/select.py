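"""Marker-specific reference retention and the second mapping round.

After the first mapping round, each marker keeps references by its own
rule: the coral host keeps the single most-covered 18S reference (after
discarding reads whose best hit is a Symbiodiniaceae 18S decoy); ITS2
keeps references covering at least 1% of mapped reads; 16S first removes
reads on chloroplast references, then keeps references covering at least
0.01% of the remaining mapped reads.  All of the sample's reads for the
marker — including previously unmapped ones — are then re-mapped against
the reduced database to aggregate reads mis-assigned among similar
references in round 1.  Consensus is only built for references supported
by strictly more than ``min_reads_consensus`` (default 10) reads.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .align import Alignment, AlignParams, map_read
from .io import Marker, MarkerDatabase, Read, RefFlag

logger = logging.getLogger("holopore")


@dataclass
class AssignmentRow:
    read_id: str
    ref_id: str | None  # None = unmapped
    score: int | None = None
    identity: float | None = None


@dataclass
class AssignmentTable:
    """Per-sample per-marker read-to-reference assignments for one round."""

    sample_id: str
    marker: Marker
    rows: list[AssignmentRow]
    round: int = 1

    def __post_init__(self) -> None:
        seen = set()
        for row in self.rows:
            if row.read_id in seen:
                raise ValueError(f"duplicate read {row.read_id!r} in assignment table")
            seen.add(row.read_id)

    @property
    def total_mapped(self) -> int:
        return sum(1 for row in self.rows if row.ref_id is not None)

    def counts(self) -> Counter:
        return Counter(row.ref_id for row in self.rows if row.ref_id is not None)


@dataclass
class RetentionRules:
    """The published retention thresholds.

    Fractions are of mapped reads for that marker in that sample, after any
    stated removals (chloroplast reads leave the 16S denominator before the
    0.01% rule is applied).  ``min_reads_consensus`` is a strictly-greater
    gate: consensus requires more than 10 supporting reads, i.e. >= 11.
    """

    its2_min_fraction: float = 0.01
    bact16s_min_fraction: float = 0.0001
    drop_chloroplast: bool = True
    min_reads_consensus: int = 10

    def __post_init__(self) -> None:
        for name in ("its2_min_fraction", "bact16s_min_fraction"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name}={value} outside (0, 1)")


@dataclass
class RetentionDetails:
    """What was kept and why; recorded in run metadata."""

    kept: dict[str, int] = field(default_factory=dict)  # ref_id -> round-1 read count
    fractions: dict[str, float] = field(default_factory=dict)
    denominator: int = 0
    removed_chloroplast_reads: int = 0
    excluded_sym18s_reads: int = 0
    note: str = ""


def retain_references(
    table: AssignmentTable,
    db: MarkerDatabase,
    rules: RetentionRules,
    return_details: bool = False,
):
    """Apply the marker's retention rule to a round-1 table.

    Returns the reduced database (and the :class:`RetentionDetails` when
    ``return_details`` is set).  Zero mapped reads give an empty database,
    flagged in the log, not an exception.
    """
    if table.round != 1:
        raise ValueError("retention operates on round-1 tables")
    if table.marker != db.marker:
        raise ValueError(f"table marker {table.marker} != database marker {db.marker}")
    by_id = db.by_id
    details = RetentionDetails()
    counts = table.counts()

    if table.marker == Marker.HOST_18S:
        for ref_id in list(counts):
            if RefFlag.SYMBIODINIACEAE_18S in by_id[ref_id].flags:
                details.excluded_sym18s_reads += counts.pop(ref_id)
        details.denominator = sum(counts.values())
        if counts:
            top = max(counts.values())
            tied = sorted(ref_id for ref_id, c in counts.items() if c == top)
            if len(tied) > 1:
                logger.warning(
                    "%s: host argmax tie between %s; keeping %s",
                    table.sample_id, tied, tied[0],
                )
                details.note = f"argmax tie among {tied}"
            winner = tied[0]
            details.kept = {winner: counts[winner]}
            details.fractions = {winner: counts[winner] / details.denominator}
    elif table.marker == Marker.ITS2:
        details.denominator = sum(counts.values())
        for ref_id, c in counts.items():
            frac = c / details.denominator
            if frac >= rules.its2_min_fraction:
                details.kept[ref_id] = c
                details.fractions[ref_id] = frac
    else:  # BACT_16S
        if rules.drop_chloroplast:
            for ref_id in list(counts):
                if RefFlag.CHLOROPLAST in by_id[ref_id].flags:
                    details.removed_chloroplast_reads += counts.pop(ref_id)
        details.denominator = sum(counts.values())
        for ref_id, c in counts.items():
            frac = c / details.denominator
            if frac >= rules.bact16s_min_fraction:
                details.kept[ref_id] = c
                details.fractions[ref_id] = frac

    if not details.kept:
        logger.warning(
            "%s/%s: no references retained (%d mapped reads)",
            table.sample_id, table.marker.value, table.total_mapped,
        )
        details.note = details.note or "no references retained"
    reduced = db.subset(details.kept)
    if return_details:
        return reduced, details
    return reduced


def second_round(
    reads: Sequence[Read],
    reduced_db: MarkerDatabase,
    params: AlignParams,
    sample_id: str = "",
) -> tuple[AssignmentTable, dict[str, Alignment]]:
    """Re-map all of a sample's reads for one marker against the reduced db.

    Uses identical alignment parameters to round 1.  Includes reads that
    were unmapped in round 1, since the purpose of the second round is to
    aggregate reads potentially mis-assigned the first time.  Returns the
    round-2 table plus the alignments (needed for consensus pileups).
    """
    if not reduced_db.refs:
        raise ValueError("second round requires a non-empty reduced database")
    rows: list[AssignmentRow] = []
    alignments: dict[str, Alignment] = {}
    for read in reads:
        aln = map_read(read, reduced_db, params)
        if aln is None:
            rows.append(AssignmentRow(read.read_id, None))
        else:
            rows.append(AssignmentRow(read.read_id, aln.ref_id, aln.score, aln.identity))
            alignments[read.read_id] = aln
    return AssignmentTable(sample_id, reduced_db.marker, rows, round=2), alignments


def consensus_gate(
    table: AssignmentTable, rules: RetentionRules
) -> list[tuple[str, list[str]]]:
    """References with strictly more than ``min_reads_consensus`` reads.

    Returns (ref_id, supporting read ids) sorted by ref_id; a reference
    with exactly ``min_reads_consensus`` reads is not emitted.
    """
    supporters: dict[str, list[str]] = {}
    for row in table.rows:
        if row.ref_id is not None:
            supporters.setdefault(row.ref_id, []).append(row.read_id)
    return sorted(
        (ref_id, ids)
        for ref_id, ids in supporters.items()
        if len(ids) > rules.min_reads_consensus
    )


ASSIGNMENT_COLUMNS = ("sample", "marker", "round", "read_id", "ref_id", "score", "identity")


def table_rows(table: AssignmentTable) -> list[tuple]:
    return [
        (
            table.sample_id,
            table.marker.value,
            table.round,
            row.read_id,
            row.ref_id if row.ref_id is not None else "UNMAPPED",
            row.score,
            row.identity,
        )
        for row in table.rows
    ]
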