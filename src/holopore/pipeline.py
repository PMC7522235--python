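"""Run orchestration: simulate/demux/map/select/consensus/profile/network.

A single YAML config drives the whole run; one global seed fans out to
per-stage seeds through a fixed derivation so each stage is independently
reproducible.  Everything is offline: databases and reads are local files
(or generated fixtures), outputs land atomically under ``out_dir``.
Timestamps appear only in the log, never in result files, so two runs with
the same config and seed produce byte-identical bundles.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import align, consensus as cons, demux as dmx, profile_network as pn, select as sel
from . import simulate as sim
from .io import Marker, read_fastq, read_reference_db, write_json, write_outputs

logger = logging.getLogger("holopore")

MARKER_KEYS = {"host_18s": Marker.HOST_18S, "its2": Marker.ITS2, "bact_16s": Marker.BACT_16S}


def derive_seed(seed: int, stage: int) -> int:
    """Stage seed from the global seed; stable across runs and platforms."""
    return int(np.random.SeedSequence(seed, spawn_key=(stage,)).generate_state(1)[0] % (2**31))


@dataclass
class SimulateBlock:
    n_samples: int = 12
    reads_per_marker: dict[str, int] = field(
        default_factory=lambda: {"HOST_18S": 15, "ITS2": 25, "BACT_16S": 20}
    )
    junk_fraction: float = 0.0
    chimera_fraction: float = 0.0


@dataclass
class RunConfig:
    """Validated, fully-defaulted run configuration.

    Either ``fastq`` (plus database and scheme paths) or ``simulate`` must
    be set.  The full config is echoed into the run metadata.
    """

    seed: int = 0
    out_dir: str = "holopore_out"
    fastq: str | None = None
    simulate: SimulateBlock | None = None
    databases: dict[str, str] = field(default_factory=dict)  # marker key -> FASTA path
    dialects: dict[str, str] = field(
        default_factory=lambda: {"host_18s": "plain", "its2": "plain", "bact_16s": "greengenes"}
    )
    host_exclusion_ids: str | None = None
    scheme: str | None = None
    error_model: dict[str, float] = field(
        default_factory=lambda: {"sub_rate": 0.06, "ins_rate": 0.04, "del_rate": 0.05}
    )
    demux: dict[str, Any] = field(
        default_factory=lambda: {"end_window": 150, "max_error_rate": 0.25, "min_length": 100}
    )
    align: dict[str, Any] = field(
        default_factory=lambda: {"min_identity": 0.70, "min_query_coverage": 0.50}
    )
    retention: dict[str, Any] = field(
        default_factory=lambda: {
            "its2_min_fraction": 0.01,
            "bact16s_min_fraction": 0.0001,
            "drop_chloroplast": True,
            "min_reads_consensus": 10,
        }
    )
    consensus: dict[str, Any] = field(
        default_factory=lambda: {"insertion_threshold": 0.5, "zero_depth_emits": "ref"}
    )
    network: dict[str, Any] = field(
        default_factory=lambda: {
            "its2_display": 0.05,
            "bact16s_display": 0.01,
            "layout_iterations": 200,
        }
    )

    def to_dict(self) -> dict:
        data = asdict(self)
        if self.simulate is not None:
            data["simulate"] = asdict(self.simulate)
        return data


_TOP_KEYS = {
    "seed", "out_dir", "fastq", "simulate", "databases", "dialects",
    "host_exclusion_ids", "scheme", "error_model", "demux", "align",
    "retention", "consensus", "network",
}


def validate_config(source: str | Path | dict) -> tuple[RunConfig | None, list[str]]:
    """Normalize a YAML file or dict into a RunConfig, collecting all errors."""
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            raw = yaml.safe_load(handle) or {}
    else:
        raw = dict(source)
    errors: list[str] = []
    if not isinstance(raw, dict):
        return None, ["config must be a mapping"]
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    config = RunConfig()

    def merge(section: str) -> None:
        incoming = raw.get(section)
        if incoming is None:
            return
        if not isinstance(incoming, dict):
            errors.append(f"{section}: expected a mapping")
            return
        defaults = getattr(config, section)
        bad = set(incoming) - set(defaults)
        if bad:
            errors.append(f"{section}: unknown keys {sorted(bad)}")
        defaults.update({k: v for k, v in incoming.items() if k in defaults})

    for section in ("error_model", "demux", "align", "retention", "consensus", "network", "dialects"):
        merge(section)
    config.seed = int(raw.get("seed", config.seed))
    config.out_dir = str(raw.get("out_dir", config.out_dir))
    config.fastq = raw.get("fastq")
    config.scheme = raw.get("scheme")
    config.host_exclusion_ids = raw.get("host_exclusion_ids")
    if "databases" in raw:
        dbs = raw["databases"] or {}
        bad = set(dbs) - set(MARKER_KEYS)
        if bad:
            errors.append(f"databases: unknown keys {sorted(bad)}")
        config.databases = {k: str(v) for k, v in dbs.items() if k in MARKER_KEYS}
    if "simulate" in raw and raw["simulate"] is not None:
        block = raw["simulate"] if isinstance(raw["simulate"], dict) else {}
        if not isinstance(raw["simulate"], dict):
            errors.append("simulate: expected a mapping")
        sim_block = SimulateBlock()
        bad = set(block) - {"n_samples", "reads_per_marker", "junk_fraction", "chimera_fraction"}
        if bad:
            errors.append(f"simulate: unknown keys {sorted(bad)}")
        sim_block.n_samples = int(block.get("n_samples", sim_block.n_samples))
        if not 1 <= sim_block.n_samples <= 12:
            errors.append("simulate.n_samples must be in [1, 12] (12 barcodes per scheme)")
        if "reads_per_marker" in block:
            sim_block.reads_per_marker = {
                str(k): int(v) for k, v in block["reads_per_marker"].items()
            }
            bad_markers = set(sim_block.reads_per_marker) - {m.value for m in Marker}
            if bad_markers:
                errors.append(f"simulate.reads_per_marker: unknown markers {sorted(bad_markers)}")
        for key in ("junk_fraction", "chimera_fraction"):
            value = float(block.get(key, getattr(sim_block, key)))
            setattr(sim_block, key, value)
            if not 0.0 <= value < 1.0:
                errors.append(f"simulate.{key}={value} outside [0, 1)")
        config.simulate = sim_block

    if config.fastq is None and config.simulate is None:
        errors.append("config needs either 'fastq' or a 'simulate' block")
    if config.fastq is not None:
        if not Path(config.fastq).exists():
            errors.append(f"fastq path does not exist: {config.fastq}")
        missing = [k for k in MARKER_KEYS if k not in config.databases]
        if missing:
            errors.append(f"databases missing for markers: {missing}")
        if config.scheme is None:
            errors.append("a scheme file is required with a real fastq input")
    for key, path in config.databases.items():
        if not Path(path).exists():
            errors.append(f"database path does not exist: {key}: {path}")
    for rate_key in ("sub_rate", "ins_rate", "del_rate"):
        rate = float(config.error_model[rate_key])
        if not 0.0 <= rate < 1.0:
            errors.append(f"error_model.{rate_key}={rate} outside [0, 1)")
    for frac_key in ("its2_min_fraction", "bact16s_min_fraction"):
        value = float(config.retention[frac_key])
        if not 0.0 < value < 1.0:
            errors.append(f"retention.{frac_key}={value} outside (0, 1)")
    for disp_key in ("its2_display", "bact16s_display"):
        value = float(config.network[disp_key])
        if not 0.0 <= value <= 1.0:
            errors.append(f"network.{disp_key}={value} outside [0, 1]")
    if not 0.0 < float(config.demux["max_error_rate"]) < 1.0:
        errors.append("demux.max_error_rate outside (0, 1)")
    if errors:
        return None, errors
    return config, []


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs have been removed."""


@dataclass
class RunResult:
    out_dir: Path
    counts: dict[str, int]
    host_calls: dict[str, str | None]
    retained: dict[str, dict[str, list[str]]]  # sample -> marker -> ref ids
    consensus_count: int
    files: list[str]


def _load_inputs(config: RunConfig):
    """Stage 0: reads + databases + scheme, simulated or from disk."""
    if config.simulate is not None:
        dbs, _exclusion = sim.default_databases(derive_seed(config.seed, 10))
        sample_ids = [f"S{i + 1:02d}" for i in range(config.simulate.n_samples)]
        scheme = sim.default_scheme(derive_seed(config.seed, 11), sample_ids=sample_ids)
        n_reads = {Marker(k): v for k, v in config.simulate.reads_per_marker.items()}
        truths = sim.default_truths(dbs, sample_ids, n_reads, seed=derive_seed(config.seed, 12))
        model = sim.ErrorModel(**{k: float(v) for k, v in config.error_model.items()})
        reads, truth_rows = sim.simulate_run(
            truths, dbs, scheme, model, derive_seed(config.seed, 13),
            junk_fraction=config.simulate.junk_fraction,
            chimera_fraction=config.simulate.chimera_fraction,
        )
        return reads, dbs, scheme, truth_rows, truths
    reads = list(read_fastq(config.fastq))
    exclusion = []
    if config.host_exclusion_ids:
        exclusion = [
            line.strip()
            for line in Path(config.host_exclusion_ids).read_text().splitlines()
            if line.strip()
        ]
    dbs = {
        marker: read_reference_db(
            config.databases[key], marker,
            taxonomy_dialect=config.dialects.get(key, "plain"),
            exclusion_ids=exclusion if marker == Marker.HOST_18S else None,
            strict=False,
        )
        for key, marker in MARKER_KEYS.items()
    }
    scheme = sim.load_scheme(config.scheme)
    return reads, dbs, scheme, None, None


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages in order and write the report bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def abort(stage: str, exc: Exception):
        for name in written:
            target = out_dir / name
            if target.exists():
                target.unlink()
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    try:
        reads, dbs, scheme, truth_rows, _ = _load_inputs(config)
    except Exception as exc:  # noqa: BLE001
        abort("input", exc)
    logger.info("input: %d reads, %d samples in scheme", len(reads), len(scheme.samples))

    try:
        params = dmx.DemuxParams(
            end_window=int(config.demux["end_window"]),
            max_error_rate=float(config.demux["max_error_rate"]),
            min_length=int(config.demux["min_length"]),
        )
        by_sample, demux_report, status_counts = dmx.demux_run(reads, scheme, params)
    except Exception as exc:  # noqa: BLE001
        abort("demux", exc)
    logger.info("demux: %s", status_counts)

    align_params = {m: align.default_align_params(m) for m in dbs}
    for p in align_params.values():
        p.min_identity = float(config.align["min_identity"])
        p.min_query_coverage = float(config.align["min_query_coverage"])
    rules = sel.RetentionRules(
        its2_min_fraction=float(config.retention["its2_min_fraction"]),
        bact16s_min_fraction=float(config.retention["bact16s_min_fraction"]),
        drop_chloroplast=bool(config.retention["drop_chloroplast"]),
        min_reads_consensus=int(config.retention["min_reads_consensus"]),
    )
    cons_params = cons.ConsensusParams(
        insertion_threshold=float(config.consensus["insertion_threshold"]),
        zero_depth_emits=str(config.consensus["zero_depth_emits"]),
    )

    round1_rows: list[tuple] = []
    round2_rows: list[tuple] = []
    consensus_records: list[tuple[str, str]] = []
    profiles: list[pn.AbundanceProfile] = []
    host_calls: dict[str, str | None] = {}
    host_families: dict[str, str | None] = {}
    retained_all: dict[str, dict[str, list[str]]] = {}
    retention_meta: dict[str, dict] = {}
    mapped_counts = {"mapped": 0, "unmapped": 0}
    consensus_count = 0

    try:
        for sample_id in scheme.samples:
            sample_reads = by_sample.get(sample_id, [])
            winners = align.map_all(sample_reads, dbs, align_params)
            retained_all[sample_id] = {}
            retention_meta[sample_id] = {}
            host_calls[sample_id] = None
            host_families[sample_id] = None
            tables1: dict[Marker, sel.AssignmentTable] = {}
            for marker in dbs:
                rows = [
                    sel.AssignmentRow(rid, result[1].ref_id, result[1].score, result[1].identity)
                    for rid, result in winners.items()
                    if result is not None and result[0] == marker
                ]
                tables1[marker] = sel.AssignmentTable(sample_id, marker, rows, round=1)
            n_unmapped = sum(1 for r in winners.values() if r is None)
            mapped_counts["mapped"] += len(sample_reads) - n_unmapped
            mapped_counts["unmapped"] += n_unmapped
            for marker, table in tables1.items():
                round1_rows.extend(sel.table_rows(table))
                reduced, details = sel.retain_references(table, dbs[marker], rules, return_details=True)
                retained_all[sample_id][marker.value] = sorted(details.kept)
                retention_meta[sample_id][marker.value] = {
                    "kept": details.kept,
                    "fractions": details.fractions,
                    "denominator": details.denominator,
                    "removed_chloroplast_reads": details.removed_chloroplast_reads,
                    "excluded_sym18s_reads": details.excluded_sym18s_reads,
                    "note": details.note,
                }
                if not reduced.refs:
                    continue
                table2, alignments = sel.second_round(
                    sample_reads, reduced, align_params[marker], sample_id
                )
                round2_rows.extend(sel.table_rows(table2))
                if marker == Marker.HOST_18S:
                    top = table2.counts().most_common(1)
                    if top:
                        host_calls[sample_id] = top[0][0]
                        taxonomy = dbs[marker].by_id[top[0][0]].taxonomy
                        host_families[sample_id] = (
                            taxonomy[-2] if len(taxonomy) >= 2 else taxonomy[-1]
                        )
                else:
                    profiles.append(pn.make_profile(table2, dbs[marker]))
                reads_by_id = {r.read_id: r for r in sample_reads}
                for ref_id, supporter_ids in sel.consensus_gate(table2, rules):
                    ref = dbs[marker].by_id[ref_id]
                    support = [alignments[rid] for rid in supporter_ids]
                    result = cons.consensus_for_reference(
                        ref, support, reads_by_id, dbs[marker], cons_params
                    )
                    label_ref, label_dist = result.label
                    consensus_records.append(
                        (
                            f"{sample_id}|{marker.value}|{ref_id} n_support={result.n_support} "
                            f"label={label_ref} distance={label_dist}",
                            result.bases,
                        )
                    )
                    consensus_count += 1
    except Exception as exc:  # noqa: BLE001
        abort("assignment", exc)

    try:
        filters = pn.NetworkFilters(
            its2_display=float(config.network["its2_display"]),
            bact16s_display=float(config.network["bact16s_display"]),
        )
        net = pn.build_network(profiles, host_families, filters)
        pn.layout_network(net, derive_seed(config.seed, 20),
                          int(config.network["layout_iterations"]))
    except Exception as exc:  # noqa: BLE001
        abort("network", exc)

    try:
        summary_rows = []
        for sample_id in scheme.samples:
            its2 = retained_all[sample_id].get(Marker.ITS2.value, [])
            bact = retained_all[sample_id].get(Marker.BACT_16S.value, [])
            summary_rows.append(
                (
                    sample_id,
                    host_calls[sample_id] or "",
                    host_families[sample_id] or "morphology-only",
                    ",".join(its2),
                    ",".join(bact),
                    sum(
                        1
                        for header, _ in consensus_records
                        if header.startswith(f"{sample_id}|")
                    ),
                )
            )
        tables = {
            "demux_report.tsv": (dmx.REPORT_COLUMNS, demux_report),
            "assignments_round1.tsv": (sel.ASSIGNMENT_COLUMNS, round1_rows),
            "assignments_round2.tsv": (sel.ASSIGNMENT_COLUMNS, round2_rows),
            "profiles.tsv": (pn.PROFILE_COLUMNS, pn.profile_rows(profiles)),
            "edges.tsv": (pn.EDGE_COLUMNS, pn.edge_rows(net)),
            "summary.tsv": (
                ("sample", "host_call", "host_family", "its2_refs", "bact16s_refs", "n_consensus"),
                summary_rows,
            ),
        }
        if truth_rows is not None:
            tables["truth.tsv"] = (sim.TRUTH_COLUMNS, truth_rows)
        metadata = {
            "config": config.to_dict(),
            "counts": {**status_counts, **mapped_counts, "input_reads": len(reads)},
            "retention": retention_meta,
            "retention_rules": asdict(rules),
        }
        written.extend(
            write_outputs(
                out_dir,
                consensus_fastas={"consensus.fasta": consensus_records},
                tables=tables,
                graph=net,
                metadata=metadata,
            )
        )
        write_json({"files": sorted(written)}, out_dir / "manifest.json")
        written.append("manifest.json")
    except Exception as exc:  # noqa: BLE001
        abort("write", exc)

    return RunResult(
        out_dir=out_dir,
        counts={**status_counts, **mapped_counts, "input_reads": len(reads)},
        host_calls=host_calls,
        retained=retained_all,
        consensus_count=consensus_count,
        files=sorted(written),
    )
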