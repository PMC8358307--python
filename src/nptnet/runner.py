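"""Reproducible multi-stage runs: configuration, orchestration, manifest.

A run executes a subset of the stages ``simulate, features, networks,
bootstrap, variability, outcomes, export`` in dependency order, writing
every artifact under an output directory together with a JSON manifest
(config hash, seeds, per-stage timing, warning counts, output paths).  A
single master seed fans out to per-stage seeds through the same hash
derivation the synthetic module uses, so stages can be rerun independently
and a rerun with the same config and seed reproduces all CSV outputs
bit-identically.

The subject-level parameter table can come from three sources: the fast
synthetic path (default), full signal synthesis plus feature extraction
(``simulate.signals: true``), or an external CSV ingested through a column
mapping.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import StageDependencyError
from .networks import (
    bootstrap_networks,
    build_association_network,
    edge_confidence_intervals,
    export_network,
    variability_network,
)
from .outcomes import outcome_report
from .pipeline import FeatureConfig, extract_roi_features, summarize_subject
from .synthetic import (
    CohortConfig,
    emulate_parameter_table,
    sample_cohort,
    synthesize_roi_signals,
    _entity_seed,
)
from .tables import ParameterTable, assemble_parameter_table

__all__ = ["STAGES", "RunManifest", "load_config", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "features", "networks", "bootstrap", "variability",
          "outcomes", "export")
NETWORK_MODES = ("pre", "post", "changes", "prediction")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_seeds: dict[str, int]
    stages: list[str]
    outputs: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    warnings: dict[str, int] = field(default_factory=dict)
    package_version: str = __version__

    def write(self, path: Path) -> None:
        payload = {k: v for k, v in self.__dict__.items()}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_config(config_path: str | Path | None) -> dict:
    if config_path is None:
        return {}
    cfg = yaml.safe_load(Path(config_path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise StageDependencyError("config file must contain a key-value mapping")
    return cfg


def _config_hash(cfg: dict, seed: int) -> str:
    blob = json.dumps({"config": cfg, "seed": seed}, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _cohort_config(cfg: dict, seed: int) -> CohortConfig:
    params = dict(cfg.get("cohort", {}))
    params.setdefault("seed", _entity_seed(seed, "stage", "simulate"))
    return CohortConfig(**params)


class _WarnCounter(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record: logging.LogRecord) -> None:
        self.count += 1


def run_pipeline(
    config_path: str | Path | None = None,
    stages: tuple[str, ...] | list[str] = STAGES,
    seed: int | None = None,
    out_dir: str | Path = "nptnet-run",
    table_path: str | Path | None = None,
    column_map: str | Path | None = None,
) -> RunManifest:
    """Execute the requested stages and write artifacts plus a manifest.

    ``table_path`` (optionally with ``column_map``) replaces the simulate/
    features stages with an ingested external parameter table.  Unknown or
    out-of-order stage requests raise ``StageDependencyError`` naming the
    missing prerequisite.
    """
    cfg = load_config(config_path)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = sorted(set(stages) - set(STAGES))
    if unknown:
        raise StageDependencyError(f"unknown stages requested: {unknown}")
    stages = [s for s in STAGES if s in set(stages)]
    if not stages:
        raise StageDependencyError("no stages requested")

    stage_seeds = {s: _entity_seed(seed, "stage", s) for s in STAGES}
    manifest = RunManifest(
        config_hash=_config_hash(cfg, seed),
        seed=seed,
        stage_seeds={s: stage_seeds[s] for s in stages},
        stages=list(stages),
    )
    counter = _WarnCounter()
    logging.getLogger("nptnet").addHandler(counter)

    state: dict[str, object] = {}
    if table_path is not None:
        table = (
            ParameterTable.from_external(table_path, column_map)
            if column_map is not None
            else ParameterTable.from_csv(table_path)
        )
        state["table"] = table
        manifest.outputs["ingested_table"] = str(table_path)

    def _need(stage: str, key: str) -> None:
        if key not in state:
            prereq = {"table": "simulate or features (or --table)",
                      "simulate": "simulate", "bootstrap": "bootstrap",
                      "networks": "networks"}[key]
            raise StageDependencyError(
                f"stage '{stage}' requires '{prereq}' to have run first"
            )

    try:
        for stage in stages:
            t0 = time.perf_counter()
            warn0 = counter.count

            if stage == "simulate":
                cohort_cfg = _cohort_config(cfg, seed)
                records = sample_cohort(cohort_cfg)
                state["simulate"] = (cohort_cfg, records)
                if bool(cfg.get("simulate", {}).get("signals", False)):
                    state["signals_pending"] = True
                elif "table" not in state:
                    table = emulate_parameter_table(cohort_cfg)
                    state["table"] = table
                    p = out / "parameter_table.csv"
                    table.to_csv(p)
                    manifest.outputs["parameter_table"] = str(p)

            elif stage == "features":
                _need(stage, "simulate")
                cohort_cfg, records = state["simulate"]  # type: ignore[misc]
                feat_cfg = FeatureConfig(**cfg.get("features", {}))
                summaries = {}
                for rec in records:
                    for session in ("pre", "post"):
                        sig = synthesize_roi_signals(rec, session, cohort_cfg)
                        feats = extract_roi_features(sig, feat_cfg)
                        summaries[(rec.subject_id, session)] = summarize_subject(
                            feats, feat_cfg.sse
                        )
                table = assemble_parameter_table(records, summaries)
                state["table"] = table
                p = out / "parameter_table.csv"
                table.to_csv(p)
                manifest.outputs["parameter_table"] = str(p)

            elif stage == "networks":
                _need(stage, "table")
                net_cfg = cfg.get("networks", {})
                nets = {
                    mode: build_association_network(
                        state["table"],  # type: ignore[arg-type]
                        mode,
                        covariate_adjust=bool(net_cfg.get("covariate_adjust", True)),
                        alpha=float(net_cfg.get("alpha", 0.05)),
                    )
                    for mode in net_cfg.get("modes", NETWORK_MODES)
                }
                state["networks"] = nets

            elif stage == "bootstrap":
                _need(stage, "table")
                n_iter = int(cfg.get("bootstrap", {}).get("n_iterations", 2000))
                ensembles = {
                    mode: bootstrap_networks(
                        state["table"], mode, n_iterations=n_iter,  # type: ignore[arg-type]
                        seed=stage_seeds["bootstrap"],
                    )
                    for mode in ("pre", "post", "changes", "prediction")
                }
                state["bootstrap"] = ensembles
                for mode, ens in ensembles.items():
                    p = out / f"bootstrap_ci_{mode}.csv"
                    edge_confidence_intervals(ens).to_csv(
                        p, index=False, float_format="%.12g"
                    )
                    manifest.outputs[f"bootstrap_ci_{mode}"] = str(p)

            elif stage == "variability":
                _need(stage, "bootstrap")
                ensembles = state["bootstrap"]  # type: ignore[assignment]
                net = variability_network(
                    ensembles["pre"], ensembles["post"],
                    top_fraction=float(cfg.get("variability", {}).get("top_fraction", 0.05)),
                )
                state.setdefault("networks", {})["variability"] = net  # type: ignore[union-attr]

            elif stage == "outcomes":
                _need(stage, "table")
                summary = outcome_report(state["table"])  # type: ignore[arg-type]
                p = out / "outcomes.txt"
                p.write_text(str(summary) + "\n")
                manifest.outputs["outcomes"] = str(p)

            elif stage == "export":
                _need(stage, "networks")
                formats = cfg.get("export", {}).get(
                    "formats", ["gexf", "edge-csv", "node-csv"]
                )
                for mode, net in state["networks"].items():  # type: ignore[union-attr]
                    for fmt in formats:
                        suffix = {"gexf": "gexf", "edge-csv": "edges.csv",
                                  "node-csv": "nodes.csv"}[fmt]
                        p = export_network(net, out / f"network_{mode}.{suffix}", fmt)
                        manifest.outputs[f"network_{mode}_{fmt}"] = str(p)

            manifest.timings_s[stage] = round(time.perf_counter() - t0, 4)
            manifest.warnings[stage] = counter.count - warn0
    finally:
        logging.getLogger("nptnet").removeHandler(counter)

    manifest_path = out / "manifest.json"
    manifest.outputs["manifest"] = str(manifest_path)
    manifest.write(manifest_path)
    return manifest
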