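"""Probability simulation over candidate drug x nanoparticle grids.

A fitted model's affine score maps to a probability through the logistic
function ``p = 1 / (1 + exp(-f_calc))``. Probabilities over a candidate
grid are banded high / mid / low for triage (boundaries 0.61 and 0.17,
half-open so every p has exactly one band), and summarized as a binned
mean-probability surface over two chosen deviation axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binned_statistic_2d

from .fusion import ReferenceTable, fuse_reference
from .operators import FeatureMatrix
from .records import NA_LEVEL, NDD_LABEL_KEYS, NP_LABEL_KEYS

log = logging.getLogger(__name__)

#: Band boundaries: p >= 0.61 high, 0.17 <= p < 0.61 mid, p < 0.17 low.
BAND_HIGH = 0.61
BAND_LOW = 0.17


def score_to_probability(f_calc):
    """Logistic map of the model score; strictly increasing, saturating."""
    f = np.asarray(f_calc, dtype=float)
    if not np.isfinite(f).all():
        raise ValueError("scores must be finite")
    out = 1.0 / (1.0 + np.exp(-f))
    return out if out.ndim else float(out)


def band_probability(p):
    """Assign each probability to exactly one of high / mid / low."""
    arr = np.asarray(p, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    bands = np.where(arr >= BAND_HIGH, "high",
                     np.where(arr >= BAND_LOW, "mid", "low"))
    return bands if arr.ndim else str(bands)


@dataclass
class ProbabilityMatrix:
    """Long-format predictions over a compounds x NP-conditions grid."""

    predictions: pd.DataFrame  # compound_id, np_condition, score, p, band
    n_rows: int
    n_cols: int
    n_masked: int

    def __post_init__(self):
        if len(self.predictions) + self.n_masked != self.n_rows * self.n_cols:
            raise ValueError("computed + masked cells must equal rows x columns")

    @property
    def n_computed(self) -> int:
        return len(self.predictions)

    def to_wide(self, value: str = "p") -> pd.DataFrame:
        return self.predictions.pivot(index="compound_id",
                                      columns="np_condition", values=value)


def predict_grid(
    model,
    feature_matrix: FeatureMatrix,
    ref_d: ReferenceTable,
    ref_n: ReferenceTable,
    compounds: pd.DataFrame,
    np_conditions: pd.DataFrame,
    fixed_context: dict[str, str] | None = None,
    mask: np.ndarray | None = None,
) -> ProbabilityMatrix:
    """One probability per (compound, NP-condition) cell.

    ``compounds`` carries drug descriptors (and any drug-side labels);
    ``np_conditions`` carries the NP labels and descriptors. Label keys
    provided by neither are filled from ``fixed_context`` and otherwise
    default to the missing-category level (logged). ``mask`` is an
    optional (n_compounds, n_conditions) Boolean array marking cells as
    not-applicable; masked cells are skipped, not predicted.
    """
    if len(compounds) == 0 or len(np_conditions) == 0:
        raise ValueError("compound and NP-condition lists must be non-empty")
    n_r, n_c = len(compounds), len(np_conditions)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (n_r, n_c):
            raise ValueError(f"mask shape {mask.shape} != ({n_r}, {n_c})")

    i, j = np.meshgrid(np.arange(n_r), np.arange(n_c), indexing="ij")
    keep = ~mask.ravel() if mask is not None else np.ones(n_r * n_c, bool)
    left = compounds.iloc[i.ravel()[keep]].reset_index(drop=True)
    right = np_conditions.iloc[j.ravel()[keep]].reset_index(drop=True)
    grid = pd.concat([left, right], axis=1)
    grid = grid.loc[:, ~grid.columns.duplicated()]

    fixed_context = fixed_context or {}
    for key in (*NDD_LABEL_KEYS, *NP_LABEL_KEYS):
        if key not in grid.columns:
            level = fixed_context.get(key, NA_LEVEL)
            log.info("grid context: label %s fixed to %r", key, level)
            grid[key] = level

    if "np_condition" not in grid.columns:
        grid["np_condition"] = (
            np_conditions.index.astype(str)[j.ravel()[keep]]
            if "np_id" not in np_conditions.columns
            else right["np_id"].astype(str))

    f_ref = fuse_reference(ref_d.lookup(grid["c_d0"]),
                           ref_n.lookup(grid["c_n0"]))
    X = feature_matrix.transform(grid, f_ref)
    scores = model.score(X)
    p = score_to_probability(scores)
    predictions = pd.DataFrame({
        "compound_id": grid["compound_id"].to_numpy()
        if "compound_id" in grid.columns else left.index.astype(str),
        "np_condition": grid["np_condition"].to_numpy(),
        "score": scores,
        "p": p,
        "band": band_probability(p),
    })
    return ProbabilityMatrix(predictions=predictions, n_rows=n_r, n_cols=n_c,
                             n_masked=int((~keep).sum()))


def binned_surface(p, x, y, n_bins: int = 10) -> pd.DataFrame:
    """Mean probability and count on an equal-width 2-D binning of the
    observed (x, y) ranges. Returns one row per bin with bin edges, the
    per-bin mean (NaN for empty bins) and the count; ``empty`` flags bins
    with no points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    mean, xe, ye, _ = binned_statistic_2d(x, y, p, statistic="mean",
                                          bins=n_bins)
    count, _, _, _ = binned_statistic_2d(x, y, p, statistic="count",
                                         bins=[xe, ye])
    rows = []
    for a in range(n_bins):
        for b in range(n_bins):
            rows.append({
                "x_lo": xe[a], "x_hi": xe[a + 1],
                "y_lo": ye[b], "y_hi": ye[b + 1],
                "mean_p": mean[a, b], "count": int(count[a, b]),
                "empty": count[a, b] == 0,
            })
    return pd.DataFrame(rows)
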