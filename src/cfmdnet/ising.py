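"""Ising model on {0,1}^n: exact inference, sampling, and nodewise estimation.

The model places probability P(x) proportional to exp(sum_i tau_i x_i +
sum_{i<j} omega_ij x_i x_j) on binary symptom vectors.  tau_i is the
threshold (logistic intercept) controlling node i's autonomous activation;
omega is the symmetric coupling matrix.  The full conditional of one node
given the rest is logistic(tau_i + sum_j omega_ij x_j), which is both the
Gibbs update and the basis of pseudo-likelihood estimation.

Estimation follows the eLasso recipe: per node an L1-regularised logistic
regression on all other nodes, penalty chosen by the extended BIC, and the
directed coefficient pairs symmetrised by the AND rule (edge present only if
both directions select it; value = mean of the two estimates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .instruments import BinarySymptomMatrix

EXACT_ENUMERATION_LIMIT = 20


@dataclass
class IsingModel:
    """Thresholds tau and symmetric zero-diagonal couplings omega on {0,1}."""

    labels: list[str]
    tau: np.ndarray
    omega: np.ndarray

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        n = len(self.labels)
        if self.tau.shape != (n,):
            raise ValueError(f"tau must have length {n}")
        if self.omega.shape != (n, n):
            raise ValueError(f"omega must be {n} x {n}")
        if not (np.isfinite(self.tau).all() and np.isfinite(self.omega).all()):
            raise ValueError("parameters must be finite")
        if not np.allclose(self.omega, self.omega.T):
            raise ValueError("omega must be symmetric")
        if not np.allclose(np.diag(self.omega), 0):
            raise ValueError("omega must have zero diagonal")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def index(self, node: str) -> int:
        try:
            return self.labels.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None

    def copy(self) -> "IsingModel":
        return IsingModel(list(self.labels), self.tau.copy(), self.omega.copy())

    def to_json(self, path=None, partition: dict[str, str] | None = None) -> str:
        payload = {
            "labels": list(self.labels),
            "tau": self.tau.tolist(),
            "omega": self.omega.tolist(),
        }
        if partition is not None:
            payload["partition"] = partition
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "IsingModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(payload["labels"], np.array(payload["tau"]), np.array(payload["omega"]))


def conditional_probability(model: IsingModel, node: int | str, others: np.ndarray) -> float:
    """P(x_i = 1 | rest) = logistic(tau_i + sum_j omega_ij x_j).

    ``others`` gives the states of the remaining n-1 nodes in label order
    with node i removed.
    """
    i = model.index(node) if isinstance(node, str) else int(node)
    if not 0 <= i < model.n_nodes:
        raise IndexError(f"node index {i} out of range")
    others = np.asarray(others)
    if others.shape != (model.n_nodes - 1,):
        raise ValueError(f"expected {model.n_nodes - 1} neighbour states")
    x = np.insert(others.astype(float), i, 0.0)
    return float(expit(model.tau[i] + model.omega[i] @ x))


def _all_states(n: int) -> np.ndarray:
    # 2^n x n array of binary states, row s = bits of s (node 0 = LSB)
    s = np.arange(2**n)[:, None]
    return (s >> np.arange(n)) & 1


def exact_distribution(model: IsingModel) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate all 2^n states and their probabilities (n <= 20 only)."""
    n = model.n_nodes
    if n > EXACT_ENUMERATION_LIMIT:
        raise ValueError(
            f"exact enumeration limited to {EXACT_ENUMERATION_LIMIT} nodes; use sample_ising"
        )
    states = _all_states(n).astype(float)
    energy = states @ model.tau + 0.5 * np.einsum("si,ij,sj->s", states, model.omega, states)
    w = np.exp(energy - energy.max())
    return states.astype(int), w / w.sum()


def expected_sum_score(model: IsingModel, subset) -> float:
    """Exact expectation of the number of active nodes among ``subset``."""
    idx = [model.index(s) if isinstance(s, str) else int(s) for s in subset]
    if len(idx) == 0:
        return 0.0
    states, probs = exact_distribution(model)
    return float(probs @ states[:, idx].sum(axis=1))


def sample_ising(
    model: IsingModel,
    n_samples: int,
    sweeps: int = 100,
    seed: int | np.random.SeedSequence | None = None,
) -> BinarySymptomMatrix:
    """Draw ``n_samples`` independent observations by single-site MCMC.

    Each observation starts from a uniform-random 0/1 state and receives
    ``sweeps`` sequential passes in which every node is redrawn from its full
    conditional.  Chains never interact, so observations are independent;
    the whole batch is advanced with vectorised per-node updates.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if sweeps < 1:
        raise ValueError("sweeps must be >= 1")
    rng = np.random.default_rng(seed)
    n = model.n_nodes
    x = (rng.random((n_samples, n)) < 0.5).astype(float)
    for _ in range(sweeps):
        u = rng.random((n_samples, n))
        for i in range(n):
            p = expit(model.tau[i] + x @ model.omega[:, i])
            x[:, i] = u[:, i] < p
    return BinarySymptomMatrix(
        x.astype(int),
        list(model.labels),
        {lab: ("MD" if lab.startswith("MD") else "CF") for lab in model.labels}
        if all(lab.startswith(("MD", "CF")) for lab in model.labels)
        else {lab: "all" for lab in model.labels},
    )


@dataclass
class EstimationConfig:
    """Settings for nodewise Ising estimation.

    ``gamma`` is the EBIC hyperparameter (0 = plain BIC); ``rule`` is the
    symmetrisation rule for the two directed coefficients of an edge;
    ``method`` switches between the L1/EBIC path and plain (unpenalised)
    maximum pseudo-likelihood.
    """

    method: str = "ebic_lasso"  # or "pseudolikelihood"
    gamma: float = 0.25
    path_length: int = 100
    lambda_min_ratio: float = 0.01
    rule: str = "AND"
    max_iter: int = 1000
    tol: float = 1e-6

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.rule not in ("AND", "OR"):
            raise ValueError("rule must be 'AND' or 'OR'")
        if self.method not in ("ebic_lasso", "pseudolikelihood"):
            raise ValueError("method must be 'ebic_lasso' or 'pseudolikelihood'")


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # Bernoulli log-likelihood with logit eta, numerically safe
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _nodewise_ebic_path(y, X, config: EstimationConfig):
    """L1 logistic path for one node; returns (intercept, coefs) at min-EBIC."""
    n, p = X.shape
    ybar = y.mean()
    # max |score| of the slopes at the intercept-only fit sets lambda_max
    lam_max = np.abs(X.T @ (y - ybar)).max() / n
    lam_max = max(lam_max, 1e-10)
    lams = np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.path_length)
    best = (np.inf, 0.0, np.zeros(p))
    for lam in lams:
        clf = LogisticRegression(
            l1_ratio=1.0,
            C=1.0 / (n * lam),
            solver="liblinear",
            # liblinear regularises the intercept; a large intercept_scaling
            # makes that penalty negligible
            intercept_scaling=100.0,
            max_iter=config.max_iter,
            tol=config.tol,
            random_state=0,  # liblinear shuffles internally
        )
        clf.fit(X, y)
        coef = clf.coef_[0]
        eta = clf.intercept_[0] + X @ coef
        k = int(np.count_nonzero(coef))
        ebic = -2 * _log_likelihood(y, eta) + k * np.log(n) + 2 * config.gamma * k * np.log(p)
        if ebic < best[0]:
            best = (ebic, float(clf.intercept_[0]), coef.copy())
    return best[1], best[2]


def _nodewise_mple(y, X, config: EstimationConfig):
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=config.max_iter)
    clf.fit(X, y)
    return float(clf.intercept_[0]), clf.coef_[0].copy()


def estimate_ising(
    data: BinarySymptomMatrix | np.ndarray,
    config: EstimationConfig | None = None,
    labels: list[str] | None = None,
) -> IsingModel:
    """Fit an Ising model by nodewise logistic regression.

    Default: L1 path per node with EBIC selection and AND-rule
    symmetrisation (edge value = mean of the two directed coefficients when
    both are nonzero, else 0).  ``method='pseudolikelihood'`` fits the
    unpenalised nodewise model instead (for small, dense problems).
    """
    config = config or EstimationConfig()
    if isinstance(data, BinarySymptomMatrix):
        X = data.values.astype(float)
        labels = labels or list(data.node_labels)
    else:
        X = np.asarray(data, dtype=float)
        labels = labels or [f"V{i + 1}" for i in range(X.shape[1])]
    if not np.isin(X, (0, 1)).all():
        raise ValueError("data must be binary 0/1")
    n, p = X.shape
    if n < 2 or np.unique(X, axis=0).shape[0] < 2:
        raise ValueError("need at least 2 distinct observations")
    col_means = X.mean(axis=0)
    degenerate = np.where((col_means == 0) | (col_means == 1))[0]
    if degenerate.size:
        raise ValueError(
            f"zero-variance column(s): {[labels[j] for j in degenerate]}; "
            "every node needs both 0s and 1s"
        )
    fit_one = _nodewise_ebic_path if config.method == "ebic_lasso" else _nodewise_mple
    tau = np.zeros(p)
    directed = np.zeros((p, p))
    for i in range(p):
        others = np.delete(np.arange(p), i)
        intercept, coefs = fit_one(X[:, i], X[:, others], config)
        tau[i] = intercept
        directed[i, others] = coefs
    both = (directed != 0) & (directed.T != 0)
    either = (directed != 0) | (directed.T != 0)
    mean_dir = (directed + directed.T) / 2.0
    if config.rule == "AND":
        omega = np.where(both, mean_dir, 0.0)
    else:
        omega = np.where(either, mean_dir, 0.0)
    np.fill_diagonal(omega, 0.0)
    return IsingModel(labels, tau, omega)
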