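"""Desirability-based binarization and information-fusion of assay outcomes.

Every assay reports a value ``v`` whose meaning depends on its activity
parameter (IC50, EC50, activity %, ...). A *desirability* ``d = +1`` marks
parameters where larger is better, ``d = -1`` where smaller is better. A
per-parameter cutoff then turns each value into a Boolean objective::

    f_obs = 1  iff  (v > cutoff and d = +1) or (v < cutoff and d = -1)

with the boundary ``v == cutoff`` classified 0 (strict inequalities). The
drug-side and NP-side Booleans are fused as a product, so a paired case is
positive only when both subsystems are favorable. The *reference* function
is the per-stratum probability ``p(f_obs = 1)`` estimated on training rows
only; fused references multiply the two subsystem probabilities.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Parameter-name patterns giving default desirability (case-insensitive).
#: Concentration-like endpoints (lower is better) -> -1; response-like
#: endpoints (higher is better) -> +1. Anything else needs an explicit entry.
_DESIRABILITY_PATTERNS = (
    (re.compile(r"ic50|ec50|cc50|lc50|tc50|\bki\b|imax", re.I), -1),
    (re.compile(r"activity|inhibition|bmax|\bcp\b", re.I), +1),
)


@dataclass
class DesirabilityTable:
    """Map activity-parameter label -> d in {-1, +1}.

    Explicit entries win; otherwise the name-pattern defaults above apply.
    A parameter matching neither is an error at lookup time — there is no
    silent default.
    """

    entries: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        bad = {k: v for k, v in self.entries.items() if v not in (-1, 1)}
        if bad:
            raise ValueError(f"desirability must be -1 or +1, got {bad}")

    def __getitem__(self, parameter: str) -> int:
        if parameter in self.entries:
            return self.entries[parameter]
        for pattern, d in _DESIRABILITY_PATTERNS:
            if pattern.search(parameter):
                return d
        raise KeyError(
            f"no desirability entry or name-pattern default for activity "
            f"parameter {parameter!r}")

    def __contains__(self, parameter: str) -> bool:
        try:
            self[parameter]
        except KeyError:
            return False
        return True

    @classmethod
    def read_csv(cls, path) -> "DesirabilityTable":
        df = pd.read_csv(path)
        return cls(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int))))

    def write_csv(self, path) -> Path:
        path = Path(path)
        pd.DataFrame(sorted(self.entries.items()),
                     columns=["parameter", "desirability"]).to_csv(path, index=False)
        return path


@dataclass
class CutoffTable:
    """Map activity-parameter label -> (cutoff in native units, provenance)."""

    entries: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        bad = [k for k, v in self.entries.items() if not math.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite cutoffs for {bad}")

    def __getitem__(self, parameter: str) -> float:
        try:
            return self.entries[parameter]
        except KeyError:
            raise KeyError(f"no cutoff for activity parameter {parameter!r}") from None

    def __contains__(self, parameter: str) -> bool:
        return parameter in self.entries

    @classmethod
    def read_csv(cls, path) -> "CutoffTable":
        df = pd.read_csv(path)
        entries = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))
        return cls(entries, {k: "user" for k in entries})

    def write_csv(self, path) -> Path:
        path = Path(path)
        rows = [(k, v, self.provenance.get(k, "user"))
                for k, v in sorted(self.entries.items())]
        pd.DataFrame(rows, columns=["parameter", "cutoff", "provenance"]).to_csv(
            path, index=False)
        return path


def binarize_value(v: float, cutoff: float, d: int) -> int:
    """Apply the desirability-directed cutoff rule to one value."""
    if not math.isfinite(v):
        raise ValueError(f"observed value must be finite, got {v!r}")
    if not math.isfinite(cutoff):
        raise ValueError(f"cutoff must be finite, got {cutoff!r}")
    if d not in (-1, 1):
        raise ValueError(f"desirability must be -1 or +1, got {d!r}")
    if (v > cutoff and d == 1) or (v < cutoff and d == -1):
        return 1
    return 0


def derive_cutoffs(
    values: pd.Series,
    parameters: pd.Series,
    user_table: CutoffTable | None = None,
) -> CutoffTable:
    """Per-parameter cutoffs: user entries win, otherwise the within-stratum
    median of the observed values (the only dataset-agnostic, reproducible
    default). A parameter with a single observation uses that value, with a
    warning."""
    entries: dict[str, float] = {}
    provenance: dict[str, str] = {}
    grouped = pd.Series(np.asarray(values, dtype=float)).groupby(
        pd.Series(np.asarray(parameters, dtype=object)))
    for param, vals in grouped:
        if user_table is not None and param in user_table:
            entries[param] = user_table[param]
            provenance[param] = "user"
            continue
        if len(vals) < 2:
            log.warning("cutoff for %r derived from a single observation", param)
        entries[param] = float(vals.median())
        provenance[param] = "derived-median"
    if user_table is not None:
        for param, cut in user_table.entries.items():
            if param not in entries:
                entries[param] = cut
                provenance[param] = "user"
    log.info("derived cutoffs for %d activity parameters (%d from user table)",
             len(entries), sum(p == "user" for p in provenance.values()))
    return CutoffTable(entries, provenance)


def apply_objective(
    df: pd.DataFrame,
    desirability: DesirabilityTable,
    cutoffs: CutoffTable,
    param_key: str,
    out_col: str = "f_obs",
) -> pd.DataFrame:
    """Annotate an assay table with the Boolean objective ``f_obs``.

    Every activity parameter present must have desirability and cutoff
    entries; a missing entry raises, naming the parameter — no silent
    defaulting.
    """
    params = df[param_key].astype(object)
    missing_d = sorted({p for p in params.unique() if p not in desirability})
    if missing_d:
        raise KeyError(f"no desirability for activity parameter(s) {missing_d}")
    missing_c = sorted({p for p in params.unique() if p not in cutoffs})
    if missing_c:
        raise KeyError(f"no cutoff for activity parameter(s) {missing_c}")

    d_vec = params.map(lambda p: desirability[p]).to_numpy(dtype=float)
    cut_vec = params.map(lambda p: cutoffs[p]).to_numpy(dtype=float)
    v = df["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("observed values must be finite")
    f = ((v > cut_vec) & (d_vec == 1)) | ((v < cut_vec) & (d_vec == -1))
    out = df.copy()
    out[out_col] = f.astype(np.int8)
    n1 = int(out[out_col].sum())
    log.info("objective %s: %d positive / %d negative of %d assays",
             out_col, n1, len(out) - n1, len(out))
    return out


def fuse_objective(f_d, f_n):
    """Fused Boolean objective: the product of the two subsystem Booleans."""
    f_d = np.asarray(f_d)
    f_n = np.asarray(f_n)
    if not (np.isin(f_d, (0, 1)).all() and np.isin(f_n, (0, 1)).all()):
        raise ValueError("objective inputs must be Boolean 0/1")
    out = f_d * f_n
    return out if out.ndim else int(out)


@dataclass
class ReferenceTable:
    """Per-stratum positive-rate estimates ``p = numerator / denominator``.

    Estimated on training rows only. An unseen stratum at lookup falls back
    to the side's global positive rate (logged).
    """

    numerators: dict[str, int]
    denominators: dict[str, int]
    global_rate: float

    def __post_init__(self):
        for k, num in self.numerators.items():
            den = self.denominators[k]
            if not (0 <= num <= den):
                raise ValueError(f"stratum {k!r}: numerator {num} not in [0, {den}]")
        if not 0.0 <= self.global_rate <= 1.0:
            raise ValueError("global rate must lie in [0, 1]")

    @property
    def probabilities(self) -> dict[str, float]:
        return {k: self.numerators[k] / self.denominators[k]
                for k in self.numerators}

    def __getitem__(self, stratum: str) -> float:
        if stratum in self.numerators:
            return self.numerators[stratum] / self.denominators[stratum]
        log.warning("unseen stratum %r: falling back to global rate %.4f",
                    stratum, self.global_rate)
        return self.global_rate

    def lookup(self, strata: pd.Series) -> np.ndarray:
        probs = self.probabilities
        out = strata.map(probs)
        unseen = out.isna()
        if unseen.any():
            log.warning("%d rows in %d unseen strata: global-rate fallback %.4f",
                        int(unseen.sum()),
                        strata[unseen].nunique(), self.global_rate)
            out = out.fillna(self.global_rate)
        return out.to_numpy(dtype=float)

    def write_csv(self, path) -> Path:
        path = Path(path)
        rows = [(k, self.numerators[k], self.denominators[k],
                 self.numerators[k] / self.denominators[k])
                for k in sorted(self.numerators)]
        df = pd.DataFrame(rows, columns=["stratum", "n_positive", "n", "p"])
        df.to_csv(path, index=False)
        with open(path, "a") as fh:
            fh.write(f"__global__,,{0},{self.global_rate}\n")
        return path

    @classmethod
    def read_csv(cls, path) -> "ReferenceTable":
        df = pd.read_csv(path)
        body = df[df["stratum"] != "__global__"]
        tail = df[df["stratum"] == "__global__"]
        global_rate = float(tail["p"].iloc[0]) if len(tail) else \
            float(body["n_positive"].sum() / body["n"].sum())
        return cls(dict(zip(body["stratum"], body["n_positive"].astype(int))),
                   dict(zip(body["stratum"], body["n"].astype(int))),
                   global_rate)


def compute_reference(
    df: pd.DataFrame,
    stratum_key: str,
    training_mask=None,
    f_obs_col: str = "f_obs",
) -> ReferenceTable:
    """Estimate ``p(f_obs = 1)`` per stratum of ``stratum_key`` from training
    rows only (validation rows never leak into the denominators)."""
    if stratum_key not in df.columns:
        raise KeyError(f"stratum key {stratum_key!r} not in table")
    sub = df if training_mask is None else df.loc[np.asarray(training_mask, bool)]
    if len(sub) == 0:
        raise ValueError("no training rows to estimate references from")
    grp = sub.groupby(sub[stratum_key].astype(object))[f_obs_col]
    numerators = grp.sum().astype(int).to_dict()
    denominators = grp.size().astype(int).to_dict()
    global_rate = float(sub[f_obs_col].mean())
    return ReferenceTable(numerators, denominators, global_rate)


def fuse_reference(p_d, p_n):
    """Fused reference probability: product of the subsystem probabilities."""
    p_d = np.asarray(p_d, dtype=float)
    p_n = np.asarray(p_n, dtype=float)
    if (p_d < 0).any() or (p_d > 1).any() or (p_n < 0).any() or (p_n > 1).any():
        raise ValueError("reference probabilities must lie in [0, 1]")
    out = p_d * p_n
    return out if out.ndim else float(out)
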