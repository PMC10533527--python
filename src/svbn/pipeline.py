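"""End-to-end pipeline: simulate -> discretize -> learn -> query/risk/compare.

A run is driven by a YAML config validated against a lightweight schema;
every stochastic stage requires an explicit seed, every artifact is JSON or
TSV, and a manifest records inputs, seeds, the config hash, and a checksum
per written file.  Identical config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .cohort import (
    CohortTable,
    STANDARD_RULES,
    ThresholdRule,
    apply_thresholds,
    filter_complete_cases,
    read_cohort,
    write_discrete_cohort,
)
from .model import LearnerConfig, learn_network, save_network
from .risk import RiskError, RiskScenario, scenario_battery
from .stats import bonferroni_adjust, mann_whitney_u
from .synthetic import SyntheticSpec, build_preset_network, sample_discrete_cohort

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(Exception):
    """Config or stage failure; the message names the stage."""


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    out_dir: Path
    simulate: dict[str, Any] | None = None  # preset, n
    input_path: Path | None = None
    schema: dict[str, str] = field(default_factory=dict)
    rules: list[ThresholdRule] = field(default_factory=list)
    learner: LearnerConfig = LearnerConfig()
    scenarios: list[RiskScenario] = field(default_factory=list)
    n_boot: int = 0
    compare: list[dict[str, str]] = field(default_factory=list)
    raw: dict[str, Any] = field(default_factory=dict)

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _parse_scenario(d: Mapping[str, Any]) -> RiskScenario:
    return RiskScenario(
        outcome=d["outcome"],
        outcome_state=d.get("outcome_state", "true"),
        risk_variables=tuple(
            (rv["variable"], rv.get("state", "true")) for rv in d["risk_variables"]
        ),
        label=d.get("label", ""),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config."""
    raw = yaml.safe_load(Path(path).read_text())
    return config_from_dict(raw, base=Path(path).parent)


def config_from_dict(raw: Mapping[str, Any], base: Path = Path(".")) -> RunConfig:
    n_boot = int(raw.get("n_boot", 0))
    stochastic = bool(raw.get("simulate")) or n_boot > 0
    if stochastic and "seed" not in raw:
        raise PipelineError("config error: 'seed' is required for stochastic stages")
    rules = []
    for r in raw.get("rules", []):
        if isinstance(r, str):
            if r not in STANDARD_RULES:
                raise PipelineError(f"config error: unknown standard rule {r!r}")
            rules.append(STANDARD_RULES[r])
        else:
            rules.append(ThresholdRule.from_dict(r))
    learner_raw = raw.get("learner", {})
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        out_dir=base / raw.get("out_dir", "svbn_run"),
        simulate=raw.get("simulate"),
        input_path=(base / raw["input"]) if "input" in raw else None,
        schema=dict(raw.get("schema", {})),
        rules=rules,
        learner=LearnerConfig(
            max_parents=int(learner_raw.get("max_parents", 3)),
            pseudocount=float(learner_raw.get("pseudocount", 1.0)),
        ),
        scenarios=[_parse_scenario(s) for s in raw.get("scenarios", [])],
        n_boot=n_boot,
        compare=list(raw.get("compare", [])),
        raw=dict(raw),
    )


def _write_json(path: Path, obj: Any) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages in order and write the manifest.

    Returns the manifest dict.  Any stage error aborts with the stage name;
    files written before the failure are listed in the manifest with
    ``complete: false``.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    manifest: dict[str, Any] = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "complete": False,
        "artifacts": [],
    }

    def _finish(error: str | None = None) -> dict[str, Any]:
        manifest["complete"] = error is None
        if error:
            manifest["error"] = error
        manifest["artifacts"] = [
            {"path": p.name, "sha256": _checksum(p)} for p in artifacts
        ]
        _write_json(out / "manifest.json", manifest)
        return manifest

    try:
        # --- acquire a cohort ----------------------------------------
        if config.simulate:
            preset = config.simulate.get("preset", "svr_core")
            n = int(config.simulate.get("n", 500))
            truth = build_preset_network(preset)
            spec = SyntheticSpec(truth=truth, n_subjects=n, seed=config.seed)
            table = sample_discrete_cohort(spec)
            truth_path = out / "truth_net.json"
            save_network(truth, truth_path)
            artifacts.append(truth_path)
        elif config.input_path is not None:
            table = read_cohort(config.input_path, config.schema)
        else:
            raise PipelineError("stage simulate/input: no cohort source configured")

        # --- complete cases + discretize -----------------------------
        analysis_vars = list(table.kinds)
        table, n_removed = filter_complete_cases(table, analysis_vars)
        manifest["n_subjects"] = table.n_subjects
        manifest["n_removed_incomplete"] = n_removed
        disc = apply_thresholds(table, config.rules)
        disc_path = out / "cohort_discrete.tsv"
        write_discrete_cohort(disc, disc_path)
        artifacts.append(disc_path)
        artifacts.append(disc_path.with_suffix(disc_path.suffix + ".meta.json"))

        # --- learn ----------------------------------------------------
        net = learn_network(disc, config.learner)
        net_path = out / "network.json"
        save_network(net, net_path)
        artifacts.append(net_path)

        # --- risk scenarios -------------------------------------------
        if config.scenarios:
            if config.n_boot < 1:
                raise PipelineError("stage risk: n_boot must be >= 1")
            estimates = scenario_battery(
                disc, config.scenarios, n_boot=config.n_boot,
                seed=config.seed, learner=config.learner,
            )
            risk_rows = []
            forest_lines = ["label\trr\tci_lo\tci_hi"]
            for est in estimates:
                if isinstance(est, RiskError):
                    risk_rows.append({"error": str(est)})
                    continue
                risk_rows.append({
                    "label": est.scenario.describe(),
                    "outcome": est.scenario.outcome,
                    "risk_variables": [list(v) for v in est.scenario.risk_variables],
                    "rr": est.rr,
                    "ci_lo": est.ci_lo,
                    "ci_hi": est.ci_hi,
                    "n_boot": est.n_boot,
                    "n_failed": est.n_failed,
                    "seed": est.seed,
                })
                forest_lines.append(
                    f"{est.scenario.describe()}\t{est.rr:.6g}\t"
                    f"{est.ci_lo:.6g}\t{est.ci_hi:.6g}"
                )
            risk_path = out / "risk_estimates.json"
            _write_json(risk_path, risk_rows)
            artifacts.append(risk_path)
            forest_path = out / "forest.tsv"
            forest_path.write_text("\n".join(forest_lines) + "\n")
            artifacts.append(forest_path)

        # --- group comparisons ----------------------------------------
        if config.compare:
            results = []
            for spec_cmp in config.compare:
                by, value = spec_cmp["by"], spec_cmp["value"]
                if by not in table.kinds or table.kinds[by] != "binary":
                    raise PipelineError(f"stage compare: {by!r} must be binary")
                mask = table.data[by].astype(bool).to_numpy()
                vals = table.data[value].to_numpy(dtype=float)
                cmp_res = mann_whitney_u(vals[mask], vals[~mask])
                results.append({
                    "by": by, "value": value,
                    "u_statistic": cmp_res.u_statistic,
                    "n1": cmp_res.n1, "n2": cmp_res.n2,
                    "p_value": cmp_res.p_value,
                    "method": cmp_res.method,
                })
            ps = [r["p_value"] for r in results]
            for r, adj in zip(results, bonferroni_adjust(ps)):
                r["p_adjusted"] = adj
            cmp_path = out / "group_comparisons.json"
            _write_json(cmp_path, results)
            artifacts.append(cmp_path)
    except (PipelineError, Exception) as e:  # noqa: BLE001 - manifest must record it
        _finish(error=f"{type(e).__name__}: {e}")
        raise
    return _finish()
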