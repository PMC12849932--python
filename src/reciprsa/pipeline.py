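"""Run orchestration: configuration, stage execution, structured reporting.

All randomness flows from ``RunConfig.seed`` via named child streams, and a
saved config plus its seed reproduces every output.  The run report echoes
the config hash, the seed, and every analysis-switch flag in effect so
published numbers are auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, behavior, io, neural_expression, rsa, simulate
from .design import CONDITION_ORDER, EfficiencyCondition

__all__ = ["RunConfig", "run_simulation", "run_behavior",
           "run_expression", "run_rsa", "run_full"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serializable run configuration."""

    seed: int = 0
    n_participants: int = 50
    n_runs: int = 3
    endowment: int = 25
    agent: simulate.AgentParams = field(default_factory=simulate.AgentParams)
    neural: simulate.NeuralGenSpec = field(
        default_factory=simulate.NeuralGenSpec.for_expression
    )
    # analysis switches
    normalization_scope: str = "global"
    beta_method: str = "mixed"
    n_perm: int = 10_000
    alpha: float = 0.05
    rsa_models: tuple[str, ...] = tuple(rsa.COGNITIVE_MODELS)

    def to_dict(self) -> dict:
        d = asdict(self)
        for sub in ("agent", "neural"):
            d[sub] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in d[sub].items()
            }
            d[sub] = {
                k: ({m: list(p) for m, p in v.items()}
                    if isinstance(v, dict) else v)
                for k, v in d[sub].items()
            }
        d["rsa_models"] = list(d["rsa_models"])
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        agent = simulate.AgentParams(**{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in d.pop("agent", {}).items()
        })
        nd = d.pop("neural", {})
        nd = {k: (tuple(v) if isinstance(v, list) and k != "signal_parcels"
                  else v) for k, v in nd.items()}
        if "signal_parcels" in nd:
            nd["signal_parcels"] = {
                m: tuple(p) for m, p in nd["signal_parcels"].items()
            }
        neural = simulate.NeuralGenSpec(**nd)
        if "rsa_models" in d:
            d["rsa_models"] = tuple(d["rsa_models"])
        return cls(agent=agent, neural=neural, **d)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_simulation(config: RunConfig, outdir) -> Path:
    """Generate and write the full synthetic data bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss_behav, ss_neural = simulate.child_seeds(config.seed, 2)
    bundle = simulate.simulate_behavioral_dataset(
        config.agent, config.n_participants, config.n_runs,
        seed=config.seed,
    )
    io.write_trials(bundle["trials"], outdir / "trials.csv")
    io.write_ratings(bundle["ratings"], outdir / "ratings.csv")
    neural = simulate.simulate_condition_maps(
        config.neural, config.n_participants, ss_neural
    )
    io.write_neural_bundle(neural, outdir / "neural")
    manifest = {
        "seed": config.seed,
        "config_hash": config.digest(),
        "agent": simulate.agent_manifest(config.agent),
        "neural": neural.manifest,
        "version": __version__,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    log.info("simulation bundle written to %s", outdir)
    return outdir


def _stat_rows(results: dict[str, behavior.StatResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"result": key, **r.to_dict()} for key, r in results.items()]
    )


def run_behavior(trials: pd.DataFrame, ratings: pd.DataFrame,
                 config: RunConfig) -> dict:
    """Behavioral stage: choice ANOVA/trend, relative weights, self-payoff."""
    results: dict[str, behavior.StatResult] = {}

    choice_tab = behavior.choice_probability_table(trials)
    results["choice_prob_anova"] = behavior.rm_anova_gg(
        choice_tab, effect_name="P(choose altruistic) ~ condition"
    )
    results["choice_prob_linear_trend"] = behavior.linear_trend(choice_tab)
    for r in behavior.pairwise_comparisons(choice_tab):
        results[f"choice_prob_pair {r.effect_name}"] = r

    fs = behavior.factor_scores(ratings)
    weights = behavior.relative_weights(
        trials, fs.scores, method=config.beta_method
    )
    w_tab = weights.pivot_table(
        index="participant_id", columns="condition", values="relative_weight"
    )[[c.value for c in CONDITION_ORDER]]
    results["relative_weight_anova"] = behavior.rm_anova_gg(
        w_tab.dropna(), effect_name="relative weight ~ condition"
    )
    results["relative_weight_linear_trend"] = behavior.linear_trend(
        w_tab.dropna()
    )

    results["self_payoff_strategic"] = behavior.self_payoff_comparison(
        trials, "strategic",
        EfficiencyCondition.A1S3, EfficiencyCondition.A1S1,
        endowment=config.endowment,
    )
    results["self_payoff_altruistic"] = behavior.self_payoff_comparison(
        trials, "altruistic",
        EfficiencyCondition.A3S1, EfficiencyCondition.A1S1,
        endowment=config.endowment,
    )
    return {
        "stats": results,
        "factor_scores": fs,
        "relative_weights": weights,
        "choice_table": choice_tab,
        "weight_table": w_tab,
    }


def run_expression(neural: simulate.SimulatedNeuralData,
                   config: RunConfig) -> dict:
    """Pattern-expression stage with its permutation test."""
    communal = neural_expression.PatternMap("communal", neural.communal_map)
    obligation = neural_expression.PatternMap(
        "obligation", neural.obligation_map
    )
    table = neural_expression.expression_table(
        neural.maps, communal, obligation,
        participant_ids=neural.participant_ids,
    )
    table = neural_expression.minmax_normalize(
        table, group=config.normalization_scope
    )
    nrw = neural_expression.neural_relative_weight(table)
    nrw_tab = neural_expression.relative_weight_table(nrw).dropna()
    n_dropped = config.n_participants - len(nrw_tab)
    if n_dropped:
        log.info("dropped %d participants with degenerate ratios", n_dropped)
    anova = behavior.rm_anova_gg(
        nrw_tab, effect_name="neural relative weight ~ condition"
    )
    trend = behavior.linear_trend(nrw_tab)
    perm = neural_expression.permutation_test(
        nrw_tab, n_perm=config.n_perm, seed=config.seed
    )
    return {
        "expression_table": table,
        "nrw": nrw,
        "nrw_table": nrw_tab,
        "stats": {"nrw_anova": anova, "nrw_linear_trend": trend},
        "permutation": perm,
    }


def run_rsa(neural: simulate.SimulatedNeuralData, config: RunConfig) -> dict:
    """Parcel-wise RSA stage."""
    table = rsa.rsa_parcels(
        neural.maps, neural.parcellation,
        models=list(config.rsa_models), alpha=config.alpha,
    )
    return {"parcel_results": table}


def run_full(config: RunConfig, outdir) -> dict:
    """Simulate (or reuse) a bundle, run all stages, write the report."""
    outdir = Path(outdir)
    bundle_dir = outdir / "bundle"
    if not (bundle_dir / "manifest.json").exists():
        run_simulation(config, bundle_dir)
    else:
        log.info("reusing existing bundle at %s", bundle_dir)
    trials = io.read_trials(bundle_dir / "trials.csv")
    ratings = io.read_ratings(bundle_dir / "ratings.csv")
    neural = io.read_neural_bundle(bundle_dir / "neural")

    behav = run_behavior(trials, ratings, config)
    expr = run_expression(neural, config)
    rsa_out = run_rsa(neural, config)

    resdir = outdir / "results"
    resdir.mkdir(parents=True, exist_ok=True)
    _stat_rows(behav["stats"]).to_csv(resdir / "behavior_stats.csv",
                                      index=False)
    behav["relative_weights"].to_csv(resdir / "relative_weights.csv",
                                     index=False)
    _stat_rows(expr["stats"]).to_csv(resdir / "expression_stats.csv",
                                     index=False)
    expr["expression_table"].to_csv(resdir / "expression_values.csv",
                                    index=False)
    rsa_out["parcel_results"].to_csv(resdir / "rsa_parcels.csv", index=False)

    report = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "config": config.to_dict(),
        "flags": {
            "normalization_scope": config.normalization_scope,
            "beta_method": config.beta_method,
            "n_perm": config.n_perm,
            "alpha": config.alpha,
        },
        "behavior": {k: r.to_dict() for k, r in behav["stats"].items()},
        "neural_expression": {
            **{k: r.to_dict() for k, r in expr["stats"].items()},
            "permutation_p_f": expr["permutation"].p_f,
            "permutation_p_beta": expr["permutation"].p_beta,
        },
        "rsa_significant_parcels": {
            model: sorted(
                int(p) for p in rsa_out["parcel_results"].query(
                    "model == @model and significant"
                )["parcel_id"]
            )
            for model in config.rsa_models
        },
    }
    (resdir / "report.json").write_text(
        json.dumps(_jsonify(report), indent=2, sort_keys=True)
    )
    return {"behavior": behav, "expression": expr, "rsa": rsa_out,
            "report": report, "outdir": outdir}


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj
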