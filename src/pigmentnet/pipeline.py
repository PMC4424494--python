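"""End-to-end pipeline: build -> topology -> paths -> perturbation scan.

A :class:`RunConfig` fully describes one run (input, designations, stages,
output directory); :func:`run_pipeline` executes it and writes every
artifact plus a manifest (config echo, input checksums, package version)
sufficient to reproduce the run byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

from . import __version__
from .interactions import ParserOptions, SchemaError
from .io import (
    network_to_edge_table,
    read_network,
    write_topology_report_json,
    write_topology_report_tsv,
)
from .network import SignallingNetwork, centrality
from .paths import PathSet, extract_s2t_subnetwork, source_target_paths
from .perturb import (
    alternate_path_report,
    alternate_report_tsv,
    essentiality_scan,
    shortlist_candidates,
)
from .synthetic import printed_paths_fixture, table1_fixture, table2_designations

log = logging.getLogger("pigmentnet")

FIXTURE_INPUTS = ("fixture:table1", "fixture:printed_paths")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (flat key-value YAML dialect)."""

    input: str  # path to an edge-table, or "fixture:table1"/"fixture:printed_paths"
    outdir: str = "pigmentnet_out"
    sources: list[str] | str | None = None  # ids, "fixture:table2", a file, or None
    targets: list[str] | str | None = None  # None -> designations on the input network
    topology: bool = True
    paths: bool = True
    scan: bool = False
    path_mode: str = "canonical_per_pair"
    shortlist_top_by_degree: int = 0
    shortlist_top_by_path_frequency: int = 0
    candidates: list[str] | str = "shortlist"  # ids | "shortlist" | "all_intermediates"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "input" not in data:
            raise SchemaError("config is missing the 'input' key")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class RunResult:
    network: SignallingNetwork
    artifacts: dict[str, Path] = field(default_factory=dict)
    topology_report: Any = None
    path_set: PathSet | None = None
    subnetwork: SignallingNetwork | None = None
    essentiality: Any = None
    outcomes: list = field(default_factory=list)
    manifest: dict[str, Any] = field(default_factory=dict)


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _load_input(config: RunConfig) -> tuple[SignallingNetwork, str]:
    if config.input == "fixture:table1":
        return table1_fixture(), "fixture:table1"
    if config.input == "fixture:printed_paths":
        return printed_paths_fixture(), "fixture:printed_paths"
    text = Path(config.input).read_text(encoding="utf-8")
    net, warnings = read_network(text, ParserOptions())
    for w in warnings:
        log.warning("%s: %s", config.input, w)
    return net, _sha256(text.encode("utf-8"))


def _resolve_designations(
    config: RunConfig, network: SignallingNetwork
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    def one(value, fallback: Sequence[str], which: str) -> tuple[str, ...]:
        if value is None:
            return tuple(fallback)
        if isinstance(value, str):
            if value == "fixture:table2":
                src, tgt = table2_designations()
                return src if which == "sources" else tgt
            return tuple(Path(value).read_text(encoding="utf-8").split())
        return tuple(value)

    sources = one(config.sources, network.sources, "sources")
    targets = one(config.targets, network.targets, "targets")
    return sources, targets


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the configured stages and write all artifacts + manifest."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    network, input_id = _load_input(config)
    result = RunResult(network=network)

    def write(name: str, text: str) -> None:
        path = outdir / name
        path.write_text(text, encoding="utf-8")
        result.artifacts[name] = path

    write("network.tsv", network_to_edge_table(network))

    if config.topology:
        report = centrality(network)
        result.topology_report = report
        import io as _io

        buf = _io.StringIO()
        write_topology_report_tsv(report, buf)
        write("topology.tsv", buf.getvalue())
        buf = _io.StringIO()
        write_topology_report_json(report, buf)
        write("topology.json", buf.getvalue())

    sources = targets = ()
    if config.paths or config.scan:
        sources, targets = _resolve_designations(config, network)
        if not sources or not targets:
            raise ValueError(
                "source/target designations are empty; set 'sources'/'targets' "
                "or use an input with designations"
            )
        unknown = [n for n in (*sources, *targets) if n not in network]
        if unknown:
            raise KeyError(f"unknown designation id(s): {', '.join(unknown)}")

    if config.paths:
        pset = source_target_paths(network, sources, targets, config.path_mode)
        result.path_set = pset
        write("paths.tsv", pset.to_tsv())
        sub = extract_s2t_subnetwork(network, pset)
        result.subnetwork = sub
        write("s2t_subnetwork.tsv", network_to_edge_table(sub))
        log.info(
            "S2T sub-network: %d nodes, %d edges, weakly connected: %s",
            sub.node_count,
            sub.edge_count,
            sub.is_weakly_connected(),
        )

    if config.scan:
        pset = result.path_set or source_target_paths(
            network, sources, targets, config.path_mode
        )
        if isinstance(config.candidates, str):
            if config.candidates == "shortlist":
                cand = shortlist_candidates(
                    network,
                    pset,
                    {
                        "top_by_degree": config.shortlist_top_by_degree,
                        "top_by_path_frequency": config.shortlist_top_by_path_frequency,
                    },
                )
            elif config.candidates == "all_intermediates":
                # intermediates over *all tied* shortest routes, so a node on
                # a non-canonical tied route is still a candidate
                tied = source_target_paths(network, sources, targets, "all_tied")
                cand = {
                    n
                    for p in tied.paths
                    for n in p.nodes
                    if n not in sources and n not in targets
                }
            else:
                raise ValueError(f"unknown candidates rule: {config.candidates!r}")
        else:
            cand = set(config.candidates)
        table, outcomes = essentiality_scan(network, sources, targets, cand)
        result.essentiality = table
        result.outcomes = outcomes
        write("essentiality.tsv", table.to_tsv())
        write("alternates.tsv", alternate_report_tsv(alternate_path_report(outcomes)))

    manifest = {
        "config": config.to_dict(),
        "input_checksum": input_id,
        "pigmentnet_version": __version__,
        "artifacts": {
            name: _sha256(path.read_bytes()) for name, path in result.artifacts.items()
        },
    }
    result.manifest = manifest
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    result.artifacts["manifest.json"] = manifest_path
    return result
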