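"""In-silico network interventions on CF nodes (threshold perturbation).

Each scenario takes the fitted Ising model and shifts one CF node's
threshold by k standard deviations of all estimated thresholds — downward
for an alleviating intervention, upward for an aggravating one — then
simulates a fresh cohort and records every observation's MD-community sum
score.  Scenarios are compared with the unperturbed baseline by Welch
t-tests with Benjamini-Hochberg correction within each direction; the
significant scenarios ranked by |change in mean MD| are the candidate core
intervention targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ising import IsingModel, sample_ising

ALLEVIATING = "alleviating"
AGGRAVATING = "aggravating"
BASELINE = "baseline"


def perturb_threshold(
    model: IsingModel, node: str, direction: str, k: float = 2.0
) -> IsingModel:
    """Shift one node's threshold by k * SD of all thresholds.

    The spread s is the sample standard deviation (n-1 denominator) of the
    model's threshold vector; alleviating subtracts k*s, aggravating adds it.
    """
    if direction not in (ALLEVIATING, AGGRAVATING):
        raise ValueError(f"direction must be '{ALLEVIATING}' or '{AGGRAVATING}'")
    if model.n_nodes < 2:
        raise ValueError("perturbation needs at least 2 nodes")
    i = model.index(node)
    s = float(np.std(model.tau, ddof=1))
    if k != 0 and s == 0:
        raise ValueError("all thresholds identical; perturbation scale is degenerate")
    out = model.copy()
    out.tau[i] += k * s if direction == AGGRAVATING else -k * s
    return out


@dataclass
class InterventionResult:
    """Per-scenario outcomes of one intervention direction."""

    direction: str
    table: pd.DataFrame  # scenario, mean_md, delta, t, p, p_fdr, significant
    md_sums: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def significant_nodes(self) -> list[str]:
        sig = self.table[(self.table.scenario != BASELINE) & self.table.significant]
        return list(sig.scenario)


def _md_sum_scores(samples, md_labels: list[str]) -> np.ndarray:
    cols = [samples.node_labels.index(lab) for lab in md_labels]
    return samples.values[:, cols].sum(axis=1).astype(float)


def run_scenarios(
    model: IsingModel,
    partition: dict[str, str],
    direction: str,
    n_sim: int = 5000,
    k: float = 2.0,
    seed: int | None = None,
    sweeps: int = 100,
) -> InterventionResult:
    """Baseline plus one scenario per CF node, each freshly simulated.

    For a 30-node CF community this yields 31 simulations per direction.
    Every scenario draws ``n_sim`` independent observations with its own
    sub-seed; the outcome is each observation's MD-community sum score.
    """
    if n_sim < 2:
        raise ValueError("n_sim must be >= 2")
    md_labels = [lab for lab in model.labels if partition.get(lab) == "MD"]
    cf_labels = [lab for lab in model.labels if partition.get(lab) == "CF"]
    if not md_labels or not cf_labels:
        raise ValueError("partition must define nonempty MD and CF communities")
    root = np.random.SeedSequence(seed)
    subseeds = root.spawn(len(cf_labels) + 1)
    md_sums: dict[str, np.ndarray] = {}
    base = sample_ising(model, n_sim, sweeps=sweeps, seed=subseeds[0])
    md_sums[BASELINE] = _md_sum_scores(base, md_labels)
    for node, ss in zip(cf_labels, subseeds[1:]):
        perturbed = perturb_threshold(model, node, direction, k)
        samples = sample_ising(perturbed, n_sim, sweeps=sweeps, seed=ss)
        md_sums[node] = _md_sum_scores(samples, md_labels)
    return compare_to_baseline(md_sums, direction)


def compare_to_baseline(
    md_sums: dict[str, np.ndarray], direction: str, alpha: float = 0.05
) -> InterventionResult:
    """Welch t-tests of every scenario vs baseline, BH-FDR within direction."""
    if BASELINE not in md_sums:
        raise ValueError("md_sums must contain the baseline scenario")
    base = np.asarray(md_sums[BASELINE], dtype=float)
    scenarios = [s for s in md_sums if s != BASELINE]
    rows = [
        {
            "scenario": BASELINE,
            "direction": direction,
            "mean_md": base.mean(),
            "delta": 0.0,
            "t": np.nan,
            "p": np.nan,
        }
    ]
    pvals = []
    for s in scenarios:
        x = np.asarray(md_sums[s], dtype=float)
        t, p = stats.ttest_ind(x, base, equal_var=False)
        rows.append(
            {
                "scenario": s,
                "direction": direction,
                "mean_md": x.mean(),
                "delta": x.mean() - base.mean(),
                "t": float(t),
                "p": float(p),
            }
        )
        pvals.append(float(p))
    table = pd.DataFrame(rows)
    p_fdr = np.full(len(table), np.nan)
    sig = np.zeros(len(table), dtype=bool)
    if pvals:
        reject, adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        p_fdr[1:] = adj
        sig[1:] = reject
    table["p_fdr"] = p_fdr
    table["significant"] = sig
    return InterventionResult(direction, table, md_sums)


def identify_core_targets(result: InterventionResult) -> pd.DataFrame:
    """Significant scenarios ranked by |delta| descending (ties by label)."""
    sig = result.table[
        (result.table.scenario != BASELINE) & result.table.significant
    ].copy()
    sig = sig.sort_values(
        by=["delta", "scenario"],
        key=lambda col: -col.abs() if col.name == "delta" else col,
    )
    return sig.reset_index(drop=True)
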