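"""Relative-abundance profiles and the colony-taxon co-occurrence network.

Profiles are per (sample, marker) relative abundances over the round-2
assignments.  The holobiont network is bipartite: one colony node per
sample (attributed with its host family, or "morphology-only" when no host
call was possible) and one taxon node per retained sequence, with an edge
when the taxon's fraction in that colony meets the marker's display filter
(default 5% for ITS2 sequences, 1% for bacterial 16S sequences).  Layout is
force-directed (Fruchterman-Reingold), seeded for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .io import Marker, MarkerDatabase, RANK_ORDER
from .select import AssignmentTable


@dataclass
class ProfileEntry:
    ref_id: str
    count: int
    fraction: float
    taxonomy: list[str] = field(default_factory=list)


@dataclass
class AbundanceProfile:
    sample_id: str
    marker: Marker
    entries: list[ProfileEntry]

    @property
    def total_mapped(self) -> int:
        return sum(e.count for e in self.entries)


def make_profile(table: AssignmentTable, db: MarkerDatabase | None = None) -> AbundanceProfile:
    """Relative abundances from a round-2 table, sorted by descending fraction.

    Zero mapped reads yield an empty profile; otherwise fractions sum to 1.
    """
    counts = table.counts()
    total = sum(counts.values())
    by_id = db.by_id if db is not None else {}
    entries = [
        ProfileEntry(
            ref_id,
            count,
            count / total,
            list(by_id[ref_id].taxonomy) if ref_id in by_id else [],
        )
        for ref_id, count in counts.items()
    ]
    entries.sort(key=lambda e: (-e.fraction, e.ref_id))
    return AbundanceProfile(table.sample_id, table.marker, entries)


def aggregate_taxa(profile: AbundanceProfile, rank: str) -> dict[str, float]:
    """Roll fractions up to a taxonomy rank; missing ranks bucket as "unclassified".

    Rank names follow the Greengenes order (domain..species); totals are
    conserved.
    """
    if rank not in RANK_ORDER:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANK_ORDER}")
    idx = RANK_ORDER.index(rank)
    out: dict[str, float] = {}
    for entry in profile.entries:
        value = (
            entry.taxonomy[idx]
            if idx < len(entry.taxonomy) and entry.taxonomy[idx]
            else "unclassified"
        )
        out[value] = out.get(value, 0.0) + entry.fraction
    return out


@dataclass
class NetworkFilters:
    """Display filters: taxa below their marker's fraction are not drawn."""

    its2_display: float = 0.05
    bact16s_display: float = 0.01

    def threshold(self, marker: Marker) -> float:
        if marker == Marker.ITS2:
            return self.its2_display
        if marker == Marker.BACT_16S:
            return self.bact16s_display
        raise ValueError(f"no display filter for marker {marker}")


def build_network(
    profiles: list[AbundanceProfile],
    host_calls: dict[str, str | None],
    filters: NetworkFilters | None = None,
) -> nx.Graph:
    """Bipartite colony-taxon graph over all samples.

    Colony nodes carry ``kind='colony'`` and ``host_family``; taxon nodes
    carry ``kind='taxon'``, ``marker`` and ``ref_id`` and are shared across
    samples.  Edge weight is the taxon's fraction in that colony.
    """
    filters = filters or NetworkFilters()
    graph = nx.Graph()
    for sample_id in sorted(host_calls):
        family = host_calls[sample_id]
        graph.add_node(
            f"colony:{sample_id}",
            kind="colony",
            sample=sample_id,
            host_family=family if family is not None else "morphology-only",
            bipartite=0,
        )
    for profile in profiles:
        if profile.marker == Marker.HOST_18S:
            continue
        threshold = filters.threshold(profile.marker)
        colony = f"colony:{profile.sample_id}"
        if colony not in graph:
            graph.add_node(colony, kind="colony", sample=profile.sample_id,
                           host_family="morphology-only", bipartite=0)
        for entry in profile.entries:
            if entry.fraction < threshold:
                continue
            node = f"{profile.marker.value}:{entry.ref_id}"
            if node not in graph:
                family = ""
                if profile.marker == Marker.BACT_16S and len(entry.taxonomy) > 4:
                    family = entry.taxonomy[4]
                elif entry.taxonomy:
                    family = entry.taxonomy[-1]
                graph.add_node(
                    node, kind="taxon", marker=profile.marker.value,
                    ref_id=entry.ref_id, family=family, bipartite=1,
                )
            graph.add_edge(colony, node, weight=entry.fraction)
    return graph


def layout_network(
    net: nx.Graph, seed: int, iterations: int = 200
) -> dict[str, tuple[float, float]]:
    """Seeded Fruchterman-Reingold coordinates; attached to the nodes."""
    if net.number_of_nodes() == 0:
        return {}
    if net.number_of_nodes() == 1:
        node = next(iter(net.nodes))
        coords = {node: (0.0, 0.0)}
    else:
        raw = nx.spring_layout(net, seed=seed, iterations=iterations)
        coords = {node: (float(xy[0]), float(xy[1])) for node, xy in raw.items()}
    for node, (x, y) in coords.items():
        net.nodes[node]["x"] = x
        net.nodes[node]["y"] = y
    return coords


EDGE_COLUMNS = ("colony", "taxon", "marker", "weight")


def edge_rows(net: nx.Graph) -> list[tuple]:
    rows = []
    for u, v, data in sorted(net.edges(data=True)):
        colony, taxon = (u, v) if net.nodes[u]["kind"] == "colony" else (v, u)
        rows.append((colony, taxon, net.nodes[taxon]["marker"], data["weight"]))
    return rows


PROFILE_COLUMNS = ("sample", "marker", "ref_id", "count", "fraction", "taxonomy")


def profile_rows(profiles: list[AbundanceProfile]) -> list[tuple]:
    rows = []
    for profile in profiles:
        for entry in profile.entries:
            rows.append(
                (
                    profile.sample_id,
                    profile.marker.value,
                    entry.ref_id,
                    entry.count,
                    entry.fraction,
                    ";".join(entry.taxonomy),
                )
            )
    return rows
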