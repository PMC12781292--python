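"""End-to-end orchestration: cohort -> scoring -> spline -> network -> NIRA.

A PipelineConfig (typically loaded from YAML) toggles stages and carries
every stage parameter, including an explicit seed for each stochastic stage;
run_pipeline executes the enabled stages in order, writes per-stage
artifacts (CSV/JSON/PNG) into the output directory, and returns the
in-memory results.  All randomness flows through the configured seeds, so
two runs of the same config produce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import plots
from .bridges import bridge_indices, rank_bridge_nodes
from .dose_response import describe_continuous, fit_rcs_model, predict_curve
from .instruments import assemble_network_matrix, score_table
from .ising import EstimationConfig, estimate_ising
from .nira import identify_core_targets, run_scenarios
from .stability import case_drop_bootstrap, cs_coefficient, default_index_pipeline
from .synthetic import (
    CohortSpec,
    NetworkTruthSpec,
    make_ground_truth_ising,
    simulate_binary_cohort,
    simulate_dose_response_cohort,
    synthesize_item_responses,
)

logger = logging.getLogger(__name__)

STAGES = ("cohort", "dose_response", "network", "bridges", "stability", "nira")
RANDOM_STAGES = ("cohort", "network", "stability", "nira")


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    cohort: dict = field(default_factory=lambda: {"n": 645, "seed": None})
    dose_response: dict = field(default_factory=lambda: {"covariates": ["gender"]})
    network: dict = field(
        default_factory=lambda: {
            "n": 1000, "seed": None, "gamma": 0.25, "rule": "AND",
            "method": "ebic_lasso", "sweeps": 100, "path_length": 100,
        }
    )
    stability: dict = field(
        default_factory=lambda: {
            "n_boot": 100, "seed": None,
            "drop_fractions": [0.1, 0.2, 0.3, 0.4, 0.5],
        }
    )
    nira: dict = field(
        default_factory=lambda: {
            "n_sim": 5000, "k": 2.0, "seed": None,
            "directions": ["alleviating", "aggravating"], "sweeps": 100,
        }
    )

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        for stage in RANDOM_STAGES:
            if self.stages.get(stage) and getattr(self, stage).get("seed") is None:
                raise ValueError(f"enabled stochastic stage {stage!r} requires a seed")
        deps = {"bridges": "network", "stability": "network", "nira": "network"}
        for stage, dep in deps.items():
            if self.stages.get(stage) and not self.stages.get(dep):
                raise ValueError(f"stage {stage!r} requires stage {dep!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        merged = {}
        for f in dataclasses.fields(cls):
            default = f.default_factory() if f.default_factory is not dataclasses.MISSING else f.default
            value = raw.get(f.name, default)
            if isinstance(default, dict) and f.name in raw:
                extra = set(raw[f.name]) - set(default)
                if extra and f.name != "stages":
                    raise ValueError(f"unknown key(s) in {f.name!r}: {sorted(extra)}")
                value = {**default, **raw[f.name]}
            merged[f.name] = value
        return cls(**merged)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages, writing artifacts under config.outdir."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": dataclasses.asdict(config)}
    with open(out / "pipeline_config.json", "w") as fh:
        json.dump(results["config"], fh, indent=1, default=str)

    current = "setup"
    try:
        if config.stages.get("cohort"):
            current = "cohort"
            spec = CohortSpec(
                n=config.cohort.get("n", 645), seed=config.cohort["seed"]
            )
            cohort = simulate_dose_response_cohort(spec)
            cohort.to_csv(out / "cohort.csv", index=False)
            desc = pd.DataFrame(
                [
                    describe_continuous(cohort["md_total"], "md_total"),
                    describe_continuous(cohort["cf_total"], "cf_total"),
                ]
            )
            desc.to_csv(out / "descriptives.csv", index=False)
            results["cohort"] = cohort

        if config.stages.get("dose_response"):
            current = "dose_response"
            cohort = results["cohort"]
            covs = config.dose_response.get("covariates") or []
            fit1 = fit_rcs_model(cohort["md_total"], cohort["cf_total"])
            fit2 = fit_rcs_model(
                cohort["md_total"], cohort["cf_total"], cohort[covs] if covs else None
            )
            with open(out / "dose_response.json", "w") as fh:
                json.dump(
                    {"model1": fit1.summary_dict(), "model2": fit2.summary_dict()},
                    fh, indent=1,
                )
            grid = np.linspace(cohort["cf_total"].min(), cohort["cf_total"].max(), 120)
            curve = predict_curve(fit1, grid)
            curve.to_csv(out / "dose_response_curve.csv", index=False)
            plots.plot_dose_response_curve(curve, out / "dose_response_curve.png")
            results["dose_response"] = {"model1": fit1, "model2": fit2}

        if config.stages.get("network"):
            current = "network"
            ncfg = config.network
            truth, partition = make_ground_truth_ising(
                NetworkTruthSpec(seed=ncfg["seed"])
            )
            binary = simulate_binary_cohort(
                truth, ncfg.get("n", 1000), seed=ncfg["seed"],
                sweeps=ncfg.get("sweeps", 100),
            )
            items = synthesize_item_responses(binary, seed=ncfg["seed"])
            scored = score_table(items)
            scored.to_csv(out / "scored.csv", index=False)
            assembled = assemble_network_matrix(items)
            assembled.to_frame().to_csv(out / "binary_matrix.csv", index=False)
            est_cfg = EstimationConfig(
                method=ncfg.get("method", "ebic_lasso"),
                gamma=ncfg.get("gamma", 0.25),
                rule=ncfg.get("rule", "AND"),
                path_length=ncfg.get("path_length", 100),
            )
            model = estimate_ising(assembled, est_cfg)
            model.to_json(out / "model.json", partition=partition)
            plots.plot_network(model, partition, out / "network.png")
            results["network"] = {
                "truth": truth, "model": model,
                "partition": partition, "binary": assembled,
                "estimation_config": est_cfg,
            }

        if config.stages.get("bridges"):
            current = "bridges"
            net = results["network"]
            indices = bridge_indices(net["model"], net["partition"])
            indices.to_csv(out / "bridge_indices.csv")
            results["bridges"] = {
                "indices": indices,
                "ranking": rank_bridge_nodes(indices, "bridge_expected_influence"),
            }

        if config.stages.get("stability"):
            current = "stability"
            scfg = config.stability
            net = results["network"]
            boot = case_drop_bootstrap(
                net["binary"],
                default_index_pipeline(net["estimation_config"]),
                drop_fractions=tuple(scfg.get("drop_fractions")),
                n_boot=scfg.get("n_boot", 100),
                seed=scfg["seed"],
            )
            cs = cs_coefficient(boot)
            boot.summary().to_csv(out / "stability.csv", index=False)
            with open(out / "stability_cs.json", "w") as fh:
                json.dump({"cs": cs, "labels": boot.labels}, fh, indent=1)
            plots.plot_stability(boot, out / "stability.png")
            results["stability"] = boot

        if config.stages.get("nira"):
            current = "nira"
            ncfg = config.nira
            net = results["network"]
            root = np.random.SeedSequence(ncfg["seed"])
            nira_results = {}
            for direction, ss in zip(
                ncfg.get("directions"), root.spawn(len(ncfg.get("directions")))
            ):
                res = run_scenarios(
                    net["model"], net["partition"], direction,
                    n_sim=ncfg.get("n_sim", 5000), k=ncfg.get("k", 2.0),
                    seed=ss.generate_state(1)[0],
                    sweeps=ncfg.get("sweeps", 100),
                )
                res.table.to_csv(out / f"nira_{direction}.csv", index=False)
                identify_core_targets(res).to_csv(
                    out / f"nira_{direction}_targets.csv", index=False
                )
                plots.plot_interventions(res, out / f"nira_{direction}.png")
                nira_results[direction] = res
            results["nira"] = nira_results
    except Exception as err:
        raise RuntimeError(f"pipeline stage {current!r} failed: {err}") from err
    return results
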