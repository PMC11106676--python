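"""Cartesian drug-NP pairing, label-ranked ordering, stratified resampling
and the 3/4-1/4 training/validation split.

A *paired case* is one drug assay crossed with one NP assay, denormalized
so all labels and descriptors of both sides sit on one row. The full
universe has ``|NDD| x |NP|`` cases and is only materialized per sampled
subset; working samples of a fixed size are drawn without replacement,
stratified on the fused activity-parameter pair ``(c_d0, c_n0)`` with
proportional allocation and largest-remainder rounding, so sample and
split sizes are exact for any N and fraction. All tie-breaks use stable
identifiers, never hash order, for cross-platform determinism.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import NDD_LABEL_KEYS, NP_LABEL_KEYS

log = logging.getLogger(__name__)

#: Label preference order for ranking paired cases (A-to-Z within each key,
#: alternating drug- and NP-side labels).
DEFAULT_LABEL_ORDER = ("c_d0", "c_n0", "c_d1", "c_n1",
                       "c_d2", "c_n2", "c_d3", "c_n3")


@dataclass
class SamplingPlan:
    """How working samples are drawn from the paired universe."""

    n_samples: int = 3
    cases_per_sample: int = 500_000
    train_fraction: float = 0.75
    label_order: tuple[str, ...] = DEFAULT_LABEL_ORDER
    base_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.cases_per_sample < 1 or self.n_samples < 1:
            raise ValueError("sample counts must be >= 1")
        self.label_order = tuple(self.label_order)

    def seed_for(self, sample_index: int) -> int:
        """Per-sample seed: base + sample index (samples are numbered 1..n)."""
        return self.base_seed + sample_index


def _prepare_side(df: pd.DataFrame, side: str) -> pd.DataFrame:
    if len(df) == 0:
        raise ValueError(f"{side} table is empty; cannot pair")
    rename = ({"assay_id": "ndd_assay_id", "value": "value_d",
               "f_obs": "f_obs_d"} if side == "ndd" else
              {"assay_id": "np_assay_id", "value": "value_n",
               "f_obs": "f_obs_n"})
    return df.rename(columns=rename).reset_index(drop=True)


@dataclass
class PairUniverse:
    """The lazily-enumerable cartesian product of the two assay tables.

    Enumeration order is ndd-major: case ``k`` pairs drug row ``k // n_np``
    with NP row ``k % n_np``. Rows are denormalized only on demand.
    """

    ndd: pd.DataFrame
    np_side: pd.DataFrame

    def __len__(self) -> int:
        return len(self.ndd) * len(self.np_side)

    @property
    def n_pairs(self) -> int:
        return len(self)

    def materialize(self, flat_indices: np.ndarray) -> pd.DataFrame:
        """Denormalize the cases at the given flat (ndd-major) indices."""
        flat = np.asarray(flat_indices, dtype=np.int64)
        i = flat // len(self.np_side)
        j = flat % len(self.np_side)
        left = self.ndd.iloc[i].reset_index(drop=True)
        right = self.np_side.iloc[j].reset_index(drop=True)
        out = pd.concat([left, right], axis=1)
        out.insert(0, "case_id",
                   out["ndd_assay_id"].astype(str) + "|"
                   + out["np_assay_id"].astype(str))
        # labels as categoricals: halves the memory of large working samples
        for key in (*NDD_LABEL_KEYS, *NP_LABEL_KEYS):
            if key in out.columns:
                out[key] = out[key].astype("category")
        return out

    def to_frame(self) -> pd.DataFrame:
        return self.materialize(np.arange(len(self)))

    def stratum_sizes(self) -> pd.Series:
        """Cases per (c_d0, c_n0) stratum, computed without materializing."""
        nd = self.ndd["c_d0"].value_counts()
        nn = self.np_side["c_n0"].value_counts()
        sizes = {(a, b): int(ca) * int(cb)
                 for a, ca in nd.items() for b, cb in nn.items()}
        return pd.Series(sizes).sort_index()


def pair_assays(ndd_df: pd.DataFrame, np_df: pd.DataFrame) -> PairUniverse:
    """Form the paired-case universe from the two (annotated) assay tables."""
    return PairUniverse(_prepare_side(ndd_df, "ndd"), _prepare_side(np_df, "np"))


def rank_cases(pairs: pd.DataFrame,
               label_order: tuple[str, ...] = DEFAULT_LABEL_ORDER) -> pd.DataFrame:
    """Stable lexicographic A-to-Z sort on the ordered label tuple, ties
    broken by (ndd_assay_id, np_assay_id). A reproducible pre-sort only —
    it does not alter sampling probabilities."""
    missing = [k for k in label_order if k not in pairs.columns]
    if missing:
        raise KeyError(f"label keys {missing} not in paired table")
    by = [*label_order, "ndd_assay_id", "np_assay_id"]
    sort_frame = pairs[by].astype(str)
    order = sort_frame.sort_values(by, kind="mergesort").index
    return pairs.loc[order].reset_index(drop=True)


def largest_remainder(weights: np.ndarray, total: int,
                      caps: np.ndarray | None = None) -> np.ndarray:
    """Integer allocation proportional to ``weights`` summing exactly to
    ``total``; optional per-cell caps. Deterministic: ties go to the lower
    index after sorting by remainder."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    quota = w / w.sum() * total
    alloc = np.floor(quota).astype(np.int64)
    if caps is not None:
        alloc = np.minimum(alloc, caps)
    shortfall = total - int(alloc.sum())
    remainders = quota - np.floor(quota)
    # stable order: largest remainder first, index ascending on ties
    order = np.lexsort((np.arange(len(w)), -remainders))
    k = 0
    while shortfall > 0:
        idx = order[k % len(order)]
        if caps is None or alloc[idx] < caps[idx]:
            alloc[idx] += 1
            shortfall -= 1
        k += 1
        if k > 10 * len(order) * (1 + shortfall):
            raise RuntimeError("allocation cannot satisfy caps")
    return alloc


def resample(universe: PairUniverse, plan: SamplingPlan,
             sample_index: int) -> pd.DataFrame:
    """Draw one working sample of exactly ``plan.cases_per_sample`` cases.

    Stratified on (c_d0, c_n0) with proportional largest-remainder
    allocation; without replacement when the universe is large enough,
    with replacement otherwise (logged). Seeded per sample index.
    """
    rng = np.random.default_rng(plan.seed_for(sample_index))
    n_univ = len(universe)
    target = plan.cases_per_sample
    replace = n_univ < target
    if replace:
        log.warning("universe (%d) smaller than sample size (%d): sampling "
                    "with replacement", n_univ, target)

    nd_groups = {a: np.flatnonzero(universe.ndd["c_d0"].to_numpy(object) == a)
                 for a in sorted(universe.ndd["c_d0"].unique())}
    nn_groups = {b: np.flatnonzero(universe.np_side["c_n0"].to_numpy(object) == b)
                 for b in sorted(universe.np_side["c_n0"].unique())}
    strata = [(a, b) for a in nd_groups for b in nn_groups]
    sizes = np.array([len(nd_groups[a]) * len(nn_groups[b]) for a, b in strata],
                     dtype=np.int64)
    alloc = largest_remainder(sizes, target,
                              caps=None if replace else sizes)

    n_np = len(universe.np_side)
    chunks = []
    for (a, b), n_st, k in zip(strata, sizes, alloc):
        if k == 0:
            continue
        local = rng.choice(n_st, size=int(k), replace=replace, shuffle=False)
        local = np.sort(local)
        rows_d = nd_groups[a][local // len(nn_groups[b])]
        rows_n = nn_groups[b][local % len(nn_groups[b])]
        chunks.append(rows_d.astype(np.int64) * n_np + rows_n)
    flat = np.concatenate(chunks)
    sample = universe.materialize(flat)
    order = tuple(k for k in plan.label_order if k in sample.columns)
    sample = rank_cases(sample, order)
    sample["sample_index"] = sample_index
    log.info("sample %d: %d cases from a universe of %d (%s replacement)",
             sample_index, len(sample), n_univ,
             "with" if replace else "without")
    return sample


def split_train_valid(sample: pd.DataFrame, train_fraction: float = 0.75,
                      seed: int = 0) -> pd.DataFrame:
    """Assign subset 't' or 'v' per case: within each (c_d0, c_n0) stratum
    a largest-remainder share of ``train_fraction`` goes to training, with
    the global total exactly ``round(fraction * N)``."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = len(sample)
    target_t = int(math.floor(train_fraction * n + 0.5))
    strata = sample.groupby(
        [sample["c_d0"].astype(object), sample["c_n0"].astype(object)],
        sort=True).indices
    keys = sorted(strata)
    sizes = np.array([len(strata[k]) for k in keys], dtype=np.int64)
    alloc = largest_remainder(sizes, target_t, caps=sizes)

    rng = np.random.default_rng(seed)
    subset = np.full(n, "v", dtype=object)
    for k, n_st, k_t in zip(keys, sizes, alloc):
        rows = np.asarray(strata[k])
        picked = rng.choice(n_st, size=int(k_t), replace=False, shuffle=False)
        subset[rows[picked]] = "t"
    out = sample.copy()
    out["subset"] = subset
    n_t = int((out["subset"] == "t").sum())
    log.info("split: %d training / %d validation (fraction %.3f)",
             n_t, n - n_t, train_fraction)
    return out
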