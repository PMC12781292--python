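"""Scoring and dichotomization of the ProQOL and MDS-R instruments.

The compassion-fatigue (CF) composite is built from the 30-item Professional
Quality of Life scale (ProQOL): the burnout (BO) and secondary traumatic
stress (STS) subscales are summed as administered, while the compassion
satisfaction (CS) subscale is reverse-scored (6 - response) so that a higher
value means lower satisfaction.  The composite therefore ranges 30-150 with
higher values indicating more severe compassion fatigue.

Moral distress (MD) comes from the 22-item Moral Distress Scale-Revised
(MDS-R): each item carries a frequency (0-4) and an intensity (0-4) rating,
the per-item product is summed into a 0-352 composite.

For network analysis every item becomes a binary symptom node: an MDS-R item
is active when its frequency x intensity product is nonzero, and a ProQOL
item is active when the raw administered response exceeds 1 ("never").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_PROQOL = 30
N_MDSR = 22
N_NODES = N_MDSR + N_PROQOL

MD_LABELS = [f"MD{i}" for i in range(1, N_MDSR + 1)]
CF_LABELS = [f"CF{i}" for i in range(1, N_PROQOL + 1)]
NODE_LABELS = MD_LABELS + CF_LABELS

MD_COMMUNITY = "MD"
CF_COMMUNITY = "CF"

# Default composite ordering of ProQOL items: CS occupies positions 1-10,
# BO 11-20, STS 21-30.  The ordering is configurable because published
# network figures index items by their position in the composite.
DEFAULT_SUBSCALE_MAP: dict[str, tuple[int, ...]] = {
    "CS": tuple(range(1, 11)),
    "BO": tuple(range(11, 21)),
    "STS": tuple(range(21, 31)),
}


def _validate_subscale_map(subscale_map: dict[str, tuple[int, ...]]) -> None:
    keys = set(subscale_map)
    if keys != {"CS", "BO", "STS"}:
        raise ValueError(f"subscale map must have keys CS/BO/STS, got {sorted(keys)}")
    all_items = [i for items in subscale_map.values() for i in items]
    if sorted(all_items) != list(range(1, N_PROQOL + 1)):
        raise ValueError("subscale map must assign items 1..30 to exactly one subscale")
    for name, items in subscale_map.items():
        if len(items) != 10:
            raise ValueError(f"subscale {name} must contain exactly 10 items, got {len(items)}")


def _check_range(values, lo: int, hi: int, what: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind not in "iu":
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValueError(f"{what}: responses must be integers")
        arr = arr.astype(int)
    bad = np.where((arr < lo) | (arr > hi))[0]
    if bad.size:
        raise ValueError(
            f"{what}: item {bad[0] + 1} has value {arr[bad[0]]}, outside [{lo}, {hi}]"
        )
    return arr


def reverse_score(response):
    """Reverse a 1-5 Likert response (6 - x); an involution on 1..5."""
    return 6 - np.asarray(response)


def score_proqol_cf(
    responses, subscale_map: dict[str, tuple[int, ...]] | None = None
) -> dict[str, int]:
    """Score the 30 ProQOL responses into the CF composite and subscale sums.

    CS items are reverse-scored (6 - x) before summing; BO and STS are summed
    raw.  Returns ``bo_sum``, ``sts_sum``, ``cs_reversed_sum`` (each 10-50)
    and ``cf_total`` (30-150).
    """
    subscale_map = subscale_map or DEFAULT_SUBSCALE_MAP
    _validate_subscale_map(subscale_map)
    arr = _check_range(responses, 1, 5, "ProQOL")
    if arr.shape != (N_PROQOL,):
        raise ValueError(f"ProQOL requires exactly {N_PROQOL} responses, got {arr.shape}")
    idx = {k: np.array(v) - 1 for k, v in subscale_map.items()}
    bo = int(arr[idx["BO"]].sum())
    sts = int(arr[idx["STS"]].sum())
    cs_rev = int(reverse_score(arr[idx["CS"]]).sum())
    return {
        "bo_sum": bo,
        "sts_sum": sts,
        "cs_reversed_sum": cs_rev,
        "cf_total": bo + sts + cs_rev,
    }


def score_mdsr(freq, intensity) -> int:
    """MDS-R composite: sum over the 22 items of frequency x intensity."""
    f = _check_range(freq, 0, 4, "MDS-R frequency")
    i = _check_range(intensity, 0, 4, "MDS-R intensity")
    if f.shape != (N_MDSR,) or i.shape != (N_MDSR,):
        raise ValueError(
            f"MDS-R requires paired vectors of length {N_MDSR}, got {f.shape} and {i.shape}"
        )
    return int((f * i).sum())


def dichotomize_md(freq, intensity):
    """MD node activation: 0 iff the frequency x intensity product is 0."""
    f = _check_range(freq, 0, 4, "MDS-R frequency")
    i = _check_range(intensity, 0, 4, "MDS-R intensity")
    return ((f * i) != 0).astype(int)


def dichotomize_cf(response, reverse_first: bool = False):
    """CF node activation: 1 ("never") -> 0, 2-5 -> 1.

    Applied to the RAW administered response by default; ``reverse_first``
    reverses (6 - x) before applying the rule, for callers who prefer
    reversed-CS activation semantics.
    """
    r = _check_range(response, 1, 5, "ProQOL")
    if reverse_first:
        r = reverse_score(r)
    return (r != 1).astype(int)


@dataclass
class ItemResponseTable:
    """Per-respondent item-level data: ProQOL, MDS-R pairs, and covariates.

    ``proqol`` is n x 30 (values 1-5, composite ordering), ``mdsr_freq`` and
    ``mdsr_intensity`` are n x 22 (values 0-4), ``covariates`` is an n-row
    DataFrame of categorical fields (may be empty).
    """

    proqol: np.ndarray
    mdsr_freq: np.ndarray
    mdsr_intensity: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        self.proqol = np.asarray(self.proqol, dtype=int)
        self.mdsr_freq = np.asarray(self.mdsr_freq, dtype=int)
        self.mdsr_intensity = np.asarray(self.mdsr_intensity, dtype=int)
        n = self.proqol.shape[0]
        if self.proqol.shape != (n, N_PROQOL):
            raise ValueError(f"proqol must be n x {N_PROQOL}, got {self.proqol.shape}")
        if self.mdsr_freq.shape != (n, N_MDSR) or self.mdsr_intensity.shape != (n, N_MDSR):
            raise ValueError(f"mdsr arrays must be n x {N_MDSR}")
        if np.any((self.proqol < 1) | (self.proqol > 5)):
            raise ValueError("ProQOL responses must be in 1..5 with no missing cells")
        for name, a in [("freq", self.mdsr_freq), ("intensity", self.mdsr_intensity)]:
            if np.any((a < 0) | (a > 4)):
                raise ValueError(f"MDS-R {name} must be in 0..4 with no missing cells")
        if len(self.covariates) not in (0, n):
            raise ValueError("covariates must have one row per respondent")

    @property
    def n(self) -> int:
        return self.proqol.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"proqol_{i + 1}": self.proqol[:, i] for i in range(N_PROQOL)}
        cols.update({f"mdsr_freq_{i + 1}": self.mdsr_freq[:, i] for i in range(N_MDSR)})
        cols.update(
            {f"mdsr_intensity_{i + 1}": self.mdsr_intensity[:, i] for i in range(N_MDSR)}
        )
        df = pd.DataFrame(cols)
        if len(self.covariates):
            df = pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ItemResponseTable":
        proqol_cols = [f"proqol_{i + 1}" for i in range(N_PROQOL)]
        freq_cols = [f"mdsr_freq_{i + 1}" for i in range(N_MDSR)]
        int_cols = [f"mdsr_intensity_{i + 1}" for i in range(N_MDSR)]
        missing = [c for c in proqol_cols + freq_cols + int_cols if c not in df.columns]
        if missing:
            raise ValueError(f"missing item columns: {missing[:5]}...")
        if df[proqol_cols + freq_cols + int_cols].isna().any().any():
            raise ValueError("missing item responses are not supported")
        cov_cols = [c for c in df.columns if c not in proqol_cols + freq_cols + int_cols]
        return cls(
            proqol=df[proqol_cols].to_numpy(),
            mdsr_freq=df[freq_cols].to_numpy(),
            mdsr_intensity=df[int_cols].to_numpy(),
            covariates=df[cov_cols].copy(),
        )


@dataclass
class BinarySymptomMatrix:
    """n x 52 binary symptom matrix with node labels and community partition."""

    values: np.ndarray
    node_labels: list[str] = field(default_factory=lambda: list(NODE_LABELS))
    partition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[1] != len(self.node_labels):
            raise ValueError("one column per node label required")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("entries must be 0/1")
        if not self.partition:
            self.partition = {
                lab: MD_COMMUNITY if lab.startswith("MD") else CF_COMMUNITY
                for lab in self.node_labels
            }
        if set(self.partition) != set(self.node_labels):
            raise ValueError("partition must cover every node exactly once")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def community_columns(self, community: str) -> np.ndarray:
        return np.array(
            [j for j, lab in enumerate(self.node_labels) if self.partition[lab] == community]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.node_labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, partition: dict[str, str] | None = None):
        return cls(df.to_numpy(), list(df.columns), partition or {})


def score_table(table: ItemResponseTable, subscale_map=None) -> pd.DataFrame:
    """Score every respondent: subscale sums, cf_total, md_total + covariates."""
    rows = [score_proqol_cf(r, subscale_map) for r in table.proqol]
    scored = pd.DataFrame(rows)
    scored["md_total"] = [
        score_mdsr(f, i) for f, i in zip(table.mdsr_freq, table.mdsr_intensity)
    ]
    if len(table.covariates):
        scored = pd.concat([scored, table.covariates.reset_index(drop=True)], axis=1)
    return scored


def assemble_network_matrix(
    table: ItemResponseTable,
    reverse_cs_before_dichotomizing: bool = False,
    subscale_map: dict[str, tuple[int, ...]] | None = None,
) -> BinarySymptomMatrix:
    """Dichotomize all items into the 52-node MD-CF binary matrix.

    Column order is MD1..MD22 then CF1..CF30; rows preserve respondent order.
    By default CS items are dichotomized on the raw administered response
    like every other ProQOL item; the switch applies the 6 - x reversal to
    the CS columns first.  Zero-variance columns are passed through —
    estimation rejects them later.
    """
    md = (table.mdsr_freq * table.mdsr_intensity != 0).astype(int)
    proqol = table.proqol
    if reverse_cs_before_dichotomizing:
        smap = subscale_map or DEFAULT_SUBSCALE_MAP
        _validate_subscale_map(smap)
        proqol = proqol.copy()
        cs_idx = np.array(smap["CS"]) - 1
        proqol[:, cs_idx] = 6 - proqol[:, cs_idx]
    cf = (proqol != 1).astype(int)
    return BinarySymptomMatrix(np.hstack([md, cf]))
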