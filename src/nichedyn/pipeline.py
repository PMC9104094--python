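"""End-to-end pipeline: synthesize/ingest -> preprocess -> niche -> SDM -> report.

A single YAML-style config drives every stage; one master seed expands to
fixed per-stage child seeds (synthesis: seed, niche permutations:
seed + 100, ensembles: seed + 200) so stages can be rerun independently
yet reproducibly. All tables are tidy CSV; every defaulted parameter is
logged with its value.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .containers import EnvLayerStack, OccurrenceSet
from .io import (read_env_stack, read_occurrences, write_env_stack,
                 write_occurrences)
from .models import NicheShiftModel, ReciprocalSDM
from .preprocess import filter_correlated, rarefy_occurrences
from .synthetic import make_invasion_scenario

__all__ = ["PipelineConfig", "AnalysisReport", "load_config", "run_pipeline"]

log = logging.getLogger("nichedyn")

_SECTION_KEYS = {
    "synthetic": {"n_rows", "n_cols", "k_layers", "gradient_weights",
                  "noise_scale", "correlation_pairs", "cell_size",
                  "native_centre", "native_breadth", "shift_delta",
                  "native_centre_cell", "invaded_centre_cell",
                  "invaded_breadth", "invaded_stack_offset", "n_native",
                  "n_invaded", "introduction_cell", "spread_rate", "years",
                  "seed"},
    "inputs": {"occurrences", "native_stack", "invaded_stack",
               "native_label", "invaded_label"},
    "preprocess": {"rarefy", "cell_size", "corr_threshold", "priority"},
    "envspace": {"grid_resolution", "bandwidth", "intersect_quantile"},
    "niche": {"n_perm", "quantiles", "esu_threshold", "run_tests"},
    "sdm": {"enabled", "reps", "ratio", "train_fraction", "algorithms"},
}
_TOP_KEYS = set(_SECTION_KEYS) | {"seed", "output_dir"}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    raw: dict
    seed: int
    output_dir: Path

    def section(self, name: str) -> dict:
        return dict(self.raw.get(name) or {})


@dataclass
class AnalysisReport:
    tables: dict[str, pd.DataFrame]
    provenance: dict
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {"provenance": self.provenance, "warnings": self.warnings,
                   "tables": {k: json.loads(v.to_json(orient="records"))
                              for k, v in self.tables.items()}}
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def load_config(source) -> PipelineConfig:
    """Parse and validate a config mapping or YAML file.

    Exactly one of the ``synthetic`` / ``inputs`` sections must be present;
    unknown keys anywhere are rejected (no silent defaults for misspellings).
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for name, allowed in _SECTION_KEYS.items():
        extra = set(raw.get(name) or {}) - allowed
        if extra:
            raise ValueError(f"unknown key(s) in section {name!r}: {sorted(extra)}")
    has_synth = "synthetic" in raw
    has_inputs = "inputs" in raw
    if has_synth == has_inputs:
        raise ValueError("config needs exactly one of 'synthetic' or 'inputs'")
    seed = int(raw.get("seed", 0))
    out = Path(raw.get("output_dir", "nichedyn_output"))
    return PipelineConfig(raw, seed, out)


def _config_hash(raw: dict) -> str:
    return hashlib.sha256(
        json.dumps(raw, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _load_data(cfg: PipelineConfig):
    """Stage 1: synthesize a scenario or ingest user files."""
    if "synthetic" in cfg.raw:
        scfg = cfg.section("synthetic")
        scfg.setdefault("seed", cfg.seed)
        scen = make_invasion_scenario(scfg)
        return (scen.native_stack, scen.native_occ,
                scen.invaded_stack, scen.invaded_occ)
    icfg = cfg.section("inputs")
    occ = read_occurrences(icfg["occurrences"])
    nat_label = icfg.get("native_label", "native")
    inv_label = icfg.get("invaded_label", "P1")
    return (read_env_stack(icfg["native_stack"]),
            occ.for_population(nat_label),
            read_env_stack(icfg["invaded_stack"]),
            occ.for_population(inv_label))


def _preprocess(cfg: PipelineConfig, nat_stack, nat_occ, inv_stack, inv_occ):
    """Stage 2: rarefaction per range, collinearity filter on pooled cells."""
    pcfg = cfg.section("preprocess")
    if pcfg.get("rarefy", True):
        cell = pcfg.get("cell_size")
        nat_occ = rarefy_occurrences(nat_occ, nat_stack, cell)
        inv_occ = rarefy_occurrences(inv_occ, inv_stack, cell)
    threshold = float(pcfg.get("corr_threshold", 0.70))
    pooled = pd.concat([nat_stack.table(), inv_stack.table()], ignore_index=True)
    kept = filter_correlated(pooled, threshold, pcfg.get("priority"))
    log.info("collinearity filter (|r| >= %.2f): kept %d/%d layers: %s",
             threshold, len(kept), nat_stack.k, kept)
    if len(kept) < nat_stack.k:
        nat_stack = nat_stack.subset_layers(kept)
        inv_stack = inv_stack.subset_layers(kept)
    return nat_stack, nat_occ, inv_stack, inv_occ, kept


def run_pipeline(config) -> AnalysisReport:
    """Run every stage and assemble the analysis report.

    Deterministic given the config seed; all intermediate artifacts are
    persisted under ``output_dir``. A failure inside the SDM stage is
    reported as a warning and does not discard the niche-dynamics outputs.
    """
    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []

    nat_stack, nat_occ, inv_stack, inv_occ = _load_data(cfg)
    write_env_stack(nat_stack, out / "native_stack")
    write_env_stack(inv_stack, out / "invaded_stack")
    both = OccurrenceSet(pd.concat([nat_occ.data, inv_occ.data],
                                   ignore_index=True))
    write_occurrences(both, out / "occurrences.csv")

    nat_stack, nat_occ, inv_stack, inv_occ, kept = _preprocess(
        cfg, nat_stack, nat_occ, inv_stack, inv_occ)
    (out / "kept_layers.txt").write_text("\n".join(kept) + "\n")
    both = OccurrenceSet(pd.concat([nat_occ.data, inv_occ.data],
                                   ignore_index=True))
    write_occurrences(both, out / "occurrences_rarefied.csv")

    ecfg = cfg.section("envspace")
    ncfg = cfg.section("niche")
    model = NicheShiftModel(
        nat_stack, nat_occ, inv_stack, inv_occ,
        grid_resolution=int(ecfg.get("grid_resolution", 100)),
        bandwidth=ecfg.get("bandwidth"),
        quantiles=tuple(ncfg.get("quantiles", (0.0, 0.1, 0.2))),
        occupancy_threshold=float(ncfg.get("esu_threshold", 0.0)),
        n_perm=int(ncfg.get("n_perm", 99)),
        seed=cfg.seed + 100)
    run_tests = bool(ncfg.get("run_tests", True))
    res = model.fit(equivalency=run_tests, similarity=run_tests)
    log.info("niche stage: R=%d, bandwidth=%s/%s, n_perm=%d",
             model.R, res.native_grid.occ_bandwidth,
             res.invasive_grid.occ_bandwidth, model.n_perm)

    tables: dict[str, pd.DataFrame] = {}
    tables["niche_metrics"] = res.marginality.assign(entity="invasive")
    tables["niche_metrics"].to_csv(out / "niche_metrics.csv", index=False)
    if res.temporal is not None:
        tables["temporal_dynamics"] = res.temporal
        res.temporal.to_csv(out / "temporal_dynamics.csv", index=False)
    perm_rows = []
    for t in (res.equivalency, res.similarity):
        if t is not None:
            perm_rows.append({"kind": t.kind, "observed_D": t.observed_D,
                              "p_value": t.p_value, "n_perm": t.n_perm,
                              "direction": t.direction})
    if perm_rows:
        tables["permutation_tests"] = pd.DataFrame(perm_rows)
        tables["permutation_tests"].to_csv(out / "permutation_tests.csv",
                                           index=False)
    pd.DataFrame({"mess_fraction_nonnegative": [res.mess_fraction_nonnegative]}
                 ).to_csv(out / "mess.csv", index=False)
    (out / "summary.txt").write_text(res.summary() + "\n")

    scfg = cfg.section("sdm")
    if scfg.get("enabled", True):
        try:
            rdm = ReciprocalSDM(
                nat_stack, nat_occ, inv_stack, inv_occ,
                reps=int(scfg.get("reps", 10)),
                ratio=int(scfg.get("ratio", 5)),
                train_fraction=float(scfg.get("train_fraction", 0.75)),
                algorithms=tuple(scfg.get("algorithms",
                                          ("boosted_trees", "random_forest",
                                           "maxent_like"))),
                seed=cfg.seed + 200)
            rres = rdm.fit()
            tables["sdm_runs"] = rres.run_table
            rres.run_table.to_csv(out / "sdm_runs.csv", index=False)
            shares = dict(rres.risk.shares)
            shares["coverage_native_to_invaded"] = rres.coverage_native_to_invaded
            shares["coverage_invaded_to_native"] = rres.coverage_invaded_to_native
            tables["risk_shares"] = pd.DataFrame([shares])
            tables["risk_shares"].to_csv(out / "risk_shares.csv", index=False)
            # single-band rasters: risk codes {0 neither, 1 invasive_only,
            # 2 native_only, 3 both} and the two consensus maps
            from .io import write_ascii_grid
            inv = inv_stack
            write_ascii_grid(rres.risk.categories.astype(float),
                             out / "risk_categories.asc",
                             inv.cell_size, inv.origin)
            write_ascii_grid(rres.invaded_ensemble.consensus_binary.astype(float),
                             out / "consensus_invaded.asc",
                             inv.cell_size, inv.origin)
            write_ascii_grid(rres.native_ensemble.consensus_binary.astype(float),
                             out / "consensus_native.asc",
                             nat_stack.cell_size, nat_stack.origin)
            (out / "sdm_summary.txt").write_text(rres.summary() + "\n")
        except Exception as exc:
            msg = f"SDM stage failed: {exc}"
            log.warning(msg)
            warnings_log.append(msg)

    report = AnalysisReport(
        tables=tables,
        provenance={"config_hash": _config_hash(cfg.raw), "seed": cfg.seed,
                    "version": __version__, "kept_layers": kept},
        warnings=warnings_log)
    report.to_json(out / "report.json")
    return report
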