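"""End-to-end orchestration: fusion -> pairing -> resampling -> PTOs ->
model fitting -> metrics -> robustness.

The stages follow the information-fusion workflow: each side's assays are
binarized with desirability-directed cutoffs, the cartesian paired-case
universe is formed, fixed-size working samples are drawn and split 3/4
training / 1/4 validation, per-stratum reference probabilities and group
means are estimated on training rows only, PTO features are assembled,
and the requested model families are fitted and scored per subset. All
randomness is seeded through the sampling plan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fusion import (
    CutoffTable,
    DesirabilityTable,
    ReferenceTable,
    apply_objective,
    compute_reference,
    derive_cutoffs,
    fuse_objective,
    fuse_reference,
)
from .models import (
    MetricsRecord,
    RobustnessSummary,
    confusion_metrics,
    fit_linear,
    fit_network,
    forward_stepwise,
    robustness,
)
from .operators import (
    FeatureMatrix,
    FeatureSpec,
    assemble_features,
    default_feature_spec,
    standardize,
)
from .pairing import SamplingPlan, pair_assays, resample, split_train_valid
from .records import NDD_LABEL_KEYS, NP_LABEL_KEYS

log = logging.getLogger(__name__)

#: architecture per network family
ARCHITECTURES = {"lnn": (), "mlp": (11,), "dln": (10, 10)}

DEFAULT_FAMILIES = ("lda", "lnn", "mlp", "dln")


@dataclass
class SampleResult:
    """Fitted artifacts and metrics for one working sample."""

    sample_index: int
    metrics: dict[tuple[str, str], MetricsRecord]  # (family, subset) -> record
    models: dict[str, object]
    features: FeatureMatrix           # raw features (linear model input)
    features_std: FeatureMatrix       # standardized (network input)
    ref_d: ReferenceTable
    ref_n: ReferenceTable
    label_modes: dict[str, str]
    n_train: int
    n_valid: int
    sample: pd.DataFrame | None = None


@dataclass
class StudyResult:
    """All samples plus cross-sample robustness summaries."""

    samples: list[SampleResult]
    robustness: dict[tuple[str, str], RobustnessSummary]
    cutoffs: CutoffTable
    n_pairs: int

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            for (family, subset), rec in s.metrics.items():
                rows.append({"sample": s.sample_index, "model": family,
                             **rec.to_dict()})
        return pd.DataFrame(rows)


def prepare_fused_tables(
    ndd_df: pd.DataFrame,
    np_df: pd.DataFrame,
    desirability: DesirabilityTable,
    cutoffs: CutoffTable | None = None,
):
    """Binarize both sides (deriving median cutoffs when none are given)
    and return the annotated tables plus the cutoff table used."""
    if cutoffs is None:
        cut_d = derive_cutoffs(ndd_df["value"], ndd_df["c_d0"])
        cut_n = derive_cutoffs(np_df["value"], np_df["c_n0"])
        cutoffs = CutoffTable({**cut_d.entries, **cut_n.entries},
                              {**cut_d.provenance, **cut_n.provenance})
    ndd_df = apply_objective(ndd_df, desirability, cutoffs, "c_d0")
    np_df = apply_objective(np_df, desirability, cutoffs, "c_n0")
    return ndd_df, np_df, cutoffs


def _annotate_sample(sample: pd.DataFrame, tmask: np.ndarray):
    ref_d = compute_reference(sample, "c_d0", tmask, "f_obs_d")
    ref_n = compute_reference(sample, "c_n0", tmask, "f_obs_n")
    sample["f_obs_fused"] = fuse_objective(sample["f_obs_d"].to_numpy(),
                                           sample["f_obs_n"].to_numpy())
    sample["f_ref_fused"] = fuse_reference(ref_d.lookup(sample["c_d0"]),
                                           ref_n.lookup(sample["c_n0"]))
    return ref_d, ref_n


def run_sample(
    sample: pd.DataFrame,
    plan: SamplingPlan,
    sample_index: int,
    feature_spec: FeatureSpec,
    families=DEFAULT_FAMILIES,
    use_fsw: bool = False,
    keep_sample: bool = False,
) -> SampleResult:
    """Split one working sample, build features and fit/score the models."""
    sample = split_train_valid(sample, plan.train_fraction,
                               seed=plan.seed_for(sample_index) + 1000)
    tmask = (sample["subset"] == "t").to_numpy()
    vmask = ~tmask
    ref_d, ref_n = _annotate_sample(sample, tmask)
    y = sample["f_obs_fused"].to_numpy()

    features = assemble_features(sample, feature_spec, tmask)
    features_std = standardize(features, tmask)

    models: dict[str, object] = {}
    metrics: dict[tuple[str, str], MetricsRecord] = {}
    for family in families:
        if family == "lda":
            selected = None
            if use_fsw:
                selected = forward_stepwise(features.X, y, tmask)
                if not selected:  # nothing passed the entry test
                    selected = tuple(features.X.columns)
            model = fit_linear(features.X, y, tmask, features=selected)
            X = features.X
        else:
            model = fit_network(features_std.X, y, tmask,
                                architecture=ARCHITECTURES[family],
                                seed=plan.seed_for(sample_index))
            X = features_std.X
        models[family] = model
        scores = model.score(X)
        pred = model.predict(X)
        for subset, mask in (("t", tmask), ("v", vmask)):
            metrics[(family, subset)] = confusion_metrics(
                pred[mask], y[mask], subset=subset, scores=scores[mask])

    label_modes = {
        key: sample.loc[tmask, key].astype(object).mode().iloc[0]
        for key in (*NDD_LABEL_KEYS, *NP_LABEL_KEYS) if key in sample.columns
    }
    return SampleResult(
        sample_index=sample_index, metrics=metrics, models=models,
        features=features, features_std=features_std,
        ref_d=ref_d, ref_n=ref_n, label_modes=label_modes,
        n_train=int(tmask.sum()), n_valid=int(vmask.sum()),
        sample=sample if keep_sample else None)


def run_study(
    ndd_df: pd.DataFrame,
    np_df: pd.DataFrame,
    desirability: DesirabilityTable,
    cutoffs: CutoffTable | None = None,
    plan: SamplingPlan | None = None,
    feature_spec: FeatureSpec | None = None,
    families=DEFAULT_FAMILIES,
    use_fsw: bool = False,
    keep_samples: bool = False,
) -> StudyResult:
    """Run the full pipeline on a pair of assay tables."""
    plan = plan or SamplingPlan()
    feature_spec = feature_spec or default_feature_spec()
    ndd_df, np_df, cutoffs = prepare_fused_tables(ndd_df, np_df,
                                                  desirability, cutoffs)
    universe = pair_assays(ndd_df, np_df)
    log.info("paired universe: %d x %d = %d cases",
             len(universe.ndd), len(universe.np_side), len(universe))

    results = []
    for k in range(1, plan.n_samples + 1):
        sample = resample(universe, plan, k)
        results.append(run_sample(sample, plan, k, feature_spec, families,
                                  use_fsw, keep_sample=keep_samples))

    rob: dict[tuple[str, str], RobustnessSummary] = {}
    if len(results) >= 2:
        for family in families:
            for subset in ("t", "v"):
                rob[(family, subset)] = robustness(
                    [r.metrics[(family, subset)] for r in results])
    return StudyResult(samples=results, robustness=rob, cutoffs=cutoffs,
                       n_pairs=len(universe))
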