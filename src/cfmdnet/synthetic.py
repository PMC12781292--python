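"""Synthetic cohorts with the statistical structure the analyses assume.

No public record of the survey exists, so this module generates stand-in
cohorts: (a) dose-response cohorts in which moral distress follows a
saturating (or, optionally, linear) curve in compassion fatigue plus
covariate shifts and Gaussian noise, with covariates drawn from the reported
marginal distributions of the study population; and (b) two-community Ising
ground truths with explicitly planted bridge edges, from which binary
symptom data and full item-level responses can be synthesised.  Everything
is deterministic under a seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from . import instruments
from .instruments import BinarySymptomMatrix, ItemResponseTable
from .ising import IsingModel, sample_ising

logger = logging.getLogger(__name__)

# Category counts observed in the study population (n = 645); used as
# sampling weights so the synthetic marginals match the published ones.
DEFAULT_COVARIATE_COUNTS: dict[str, dict[str, int]] = {
    "gender": {"male": 75, "female": 570},
    "age_band": {"18-29": 300, "30-39": 295, "40-49": 46, "50-59": 4},
    "marital_status": {"married": 392, "unmarried": 246, "divorced": 6, "other": 1},
    "icu_tenure": {"<=5y": 329, "6-10y": 178, "11-15y": 104, "16-20y": 22, ">=21y": 12},
    "education": {"college": 134, "undergraduate": 493, "postgraduate": 16, "doctorate": 2},
    "title": {
        "nurse": 130,
        "nurse_practitioner": 289,
        "nurse_in_charge": 206,
        "associate_chief_nurse": 17,
        "chief_nurse": 3,
    },
    "income_band": {
        "<=4000": 91,
        "4001-8000": 338,
        "8001-12000": 183,
        "12001-16000": 27,
        "16001-20000": 5,
        ">=20001": 1,
    },
    "income_satisfaction": {"satisfied": 284, "unsatisfied": 361},
}


def default_covariate_marginals() -> dict[str, dict[str, float]]:
    return {
        cov: {cat: cnt / sum(counts.values()) for cat, cnt in counts.items()}
        for cov, counts in DEFAULT_COVARIATE_COUNTS.items()
    }


@dataclass
class CurveSpec:
    """Dose-response curve of mean MD given CF.

    ``saturating``: 4-parameter logistic — lower plateau, upper plateau,
    midpoint and scale chosen so the rise is steepest around CF 60-90 and
    flattens at both extremes.  ``linear``: straight line (the null of the
    nonlinearity test), parameterised by intercept and slope.
    """

    kind: str = "saturating"
    lower: float = 25.0
    upper: float = 110.0
    midpoint: float = 75.0
    scale: float = 8.0
    intercept: float = 60.0
    slope: float = 0.8

    def __call__(self, cf: np.ndarray) -> np.ndarray:
        cf = np.asarray(cf, dtype=float)
        if self.kind == "saturating":
            return self.lower + (self.upper - self.lower) * expit(
                (cf - self.midpoint) / self.scale
            )
        if self.kind == "linear":
            return self.intercept + self.slope * cf
        raise ValueError(f"unknown curve kind {self.kind!r}")


@dataclass
class CohortSpec:
    """Conditions for a synthetic dose-response cohort.

    CF totals are drawn from a normal truncated to the observed range 35-139
    (location 82, scale 17.8, matching the reported median and IQR); MD is
    the curve value plus additive covariate shifts plus Gaussian noise,
    truncated to the scale range [0, 352].  Only the gender effect is
    nonzero by default, mirroring the covariate-adjusted finding that gender
    was the sole significant covariate.
    """

    n: int = 645
    covariate_marginals: dict[str, dict[str, float]] = field(
        default_factory=default_covariate_marginals
    )
    curve: CurveSpec = field(default_factory=CurveSpec)
    noise_sd: float = 30.0
    covariate_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"gender": {"female": 8.0}}
    )
    cf_loc: float = 82.0
    cf_scale: float = 17.8
    cf_range: tuple[float, float] = (35.0, 139.0)
    truncation_tolerance: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for cov, probs in self.covariate_marginals.items():
            total = sum(probs.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"marginals for {cov!r} sum to {total}, not 1")


def draw_covariates(
    marginals: dict[str, dict[str, float]], n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Sample categorical covariates independently from their marginals."""
    cols = {}
    for cov, probs in marginals.items():
        cats = list(probs)
        p = np.array([probs[c] for c in cats])
        cols[cov] = pd.Categorical.from_codes(
            rng.choice(len(cats), size=n, p=p / p.sum()), categories=cats
        )
    return pd.DataFrame(cols)


def simulate_dose_response_cohort(
    spec: CohortSpec | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Generate a (cf_total, md_total, covariates) table from a CohortSpec."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    lo, hi = spec.cf_range
    a, b = (lo - spec.cf_loc) / spec.cf_scale, (hi - spec.cf_loc) / spec.cf_scale
    cf = truncnorm.rvs(a, b, loc=spec.cf_loc, scale=spec.cf_scale, size=spec.n, random_state=rng)
    cf = np.round(cf)
    covariates = draw_covariates(spec.covariate_marginals, spec.n, rng)
    shift = np.zeros(spec.n)
    for cov, effects in spec.covariate_effects.items():
        if cov not in covariates.columns:
            raise ValueError(f"covariate effect refers to unknown covariate {cov!r}")
        for cat, eff in effects.items():
            shift += np.where(covariates[cov] == cat, eff, 0.0)
    md_raw = spec.curve(cf) + shift + rng.normal(0.0, spec.noise_sd, size=spec.n)
    out_of_range = np.mean((md_raw < 0) | (md_raw > 352))
    if out_of_range > spec.truncation_tolerance:
        logger.warning(
            "%.1f%% of raw MD values fall outside [0, 352] before truncation",
            100 * out_of_range,
        )
    md = np.clip(md_raw, 0.0, 352.0)
    out = pd.DataFrame({"cf_total": cf.astype(int), "md_total": md})
    return pd.concat([out, covariates], axis=1)


@dataclass
class NetworkTruthSpec:
    """Ground-truth two-community Ising structure with planted bridges.

    Intra-community edges are sprinkled at ``intra_density`` with positive
    weights in ``weight_range``; cross-community couplings are exactly the
    ``bridge_edges`` list, nothing else.  The default plants CF26 as the
    dominant bridge with secondary bridges at CF25/CF28/CF29, echoing the
    qualitative structure the downstream analyses should recover.
    """

    n_md: int = 22
    n_cf: int = 30
    intra_density: float = 0.15
    weight_range: tuple[float, float] = (0.3, 0.9)
    bridge_edges: list[tuple[str, str, float]] = field(
        default_factory=lambda: [
            ("CF26", "MD10", 1.8),
            ("CF26", "MD5", 1.2),
            ("CF28", "MD10", 0.9),
            ("CF25", "MD14", 0.8),
            ("CF29", "MD3", 0.6),
        ]
    )
    threshold_range: tuple[float, float] = (-3.5, -0.5)
    seed: int | None = None

    @property
    def labels(self) -> list[str]:
        return [f"MD{i}" for i in range(1, self.n_md + 1)] + [
            f"CF{i}" for i in range(1, self.n_cf + 1)
        ]

    @property
    def partition(self) -> dict[str, str]:
        return {lab: ("MD" if lab.startswith("MD") else "CF") for lab in self.labels}


def make_ground_truth_ising(
    spec: NetworkTruthSpec | None = None, seed: int | None = None
) -> tuple[IsingModel, dict[str, str]]:
    """Construct the planted Ising model described by a NetworkTruthSpec."""
    spec = spec or NetworkTruthSpec()
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    labels = spec.labels
    index = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    omega = np.zeros((n, n))
    lo_w, hi_w = spec.weight_range

    def sprinkle(members):
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                if rng.random() < spec.intra_density:
                    w = rng.uniform(lo_w, hi_w)
                    i, j = index[members[a]], index[members[b]]
                    omega[i, j] = omega[j, i] = w

    md_nodes = [lab for lab in labels if lab.startswith("MD")]
    cf_nodes = [lab for lab in labels if lab.startswith("CF")]
    sprinkle(md_nodes)
    sprinkle(cf_nodes)
    for cf_node, md_node, w in spec.bridge_edges:
        if cf_node not in index or md_node not in index:
            raise ValueError(f"bridge edge ({cf_node}, {md_node}) references unknown node")
        if not np.isfinite(w):
            raise ValueError("bridge weights must be finite")
        i, j = index[cf_node], index[md_node]
        omega[i, j] = omega[j, i] = w
    tau = rng.uniform(*spec.threshold_range, size=n)
    return IsingModel(labels, tau, omega), spec.partition


def simulate_binary_cohort(
    model: IsingModel, n: int, seed: int | None = None, sweeps: int = 100
) -> BinarySymptomMatrix:
    """Sample n observations from an Ising ground truth (delegates to MCMC)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return sample_ising(model, n, sweeps=sweeps, seed=seed)


def synthesize_item_responses(
    binary: BinarySymptomMatrix,
    seed: int | None = None,
    covariate_marginals: dict[str, dict[str, float]] | None = None,
) -> ItemResponseTable:
    """Lift a 52-node binary matrix back to plausible item-level responses.

    Inactive CF nodes map to response 1 ("never"); active ones draw uniformly
    from 2-5.  Inactive MD nodes get frequency 0 (intensity uniform 0-4, so
    the product is 0); active ones draw frequency and intensity uniformly
    from 1-4.  Dichotomizing the result reproduces the input exactly, so the
    full scoring pipeline can be exercised end-to-end.
    """
    if binary.n_nodes != instruments.N_NODES:
        raise ValueError(f"expected {instruments.N_NODES} nodes, got {binary.n_nodes}")
    rng = np.random.default_rng(seed)
    n = binary.n
    md_cols = [binary.node_labels.index(lab) for lab in instruments.MD_LABELS]
    cf_cols = [binary.node_labels.index(lab) for lab in instruments.CF_LABELS]
    md_active = binary.values[:, md_cols]
    cf_active = binary.values[:, cf_cols]

    proqol = np.where(cf_active == 1, rng.integers(2, 6, size=cf_active.shape), 1)
    freq = np.where(md_active == 1, rng.integers(1, 5, size=md_active.shape), 0)
    intensity = np.where(
        md_active == 1,
        rng.integers(1, 5, size=md_active.shape),
        rng.integers(0, 5, size=md_active.shape),
    )
    covariates = draw_covariates(
        covariate_marginals or default_covariate_marginals(), n, rng
    )
    return ItemResponseTable(proqol, freq, intensity, covariates)
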