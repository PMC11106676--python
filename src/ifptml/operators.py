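"""Perturbation-theory operators (PTOs) and feature-matrix assembly.

The moving-average (MA) operator measures how far a structural descriptor
deviates from its expected value under a set of assay conditions::

    dD = D - <D | c>

where ``<D | c>`` is the mean of ``D`` over all *training* cases sharing
the same joint combination of condition labels ``c`` (a partition of the
label keys). Cross PTOs condition a descriptor of one subsystem on the
other subsystem's partition (only meaningful on the paired table). The
moving-average-balance (MAB) operator balances a drug-descriptor deviation
against the mean of two homologous coating-agent descriptor deviations::

    ddD(D_ca1, D_ca2, D_dk) = dD(D_dk | c_I) - (dD(D_ca1 | c_III)
                                               + dD(D_ca2 | c_III)) / 2

Group means are always estimated on training rows only; a label
combination unseen in training falls back to the descriptor's global
training mean (logged), with no partial-tuple backoff — exact tuple or
global, for determinism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .records import PartitionSpec, resolve_descriptor

log = logging.getLogger(__name__)

#: MAB default pairing: each drug descriptor is balanced against its two
#: homologous coating-agent descriptors.
MAB_DEFAULT_PAIRING = {
    "logp": ("d_n12", "d_n13"),   # ALOGPcoat, ALOGP2coat
    "psa": ("d_n10", "d_n11"),    # TPSA(NO)coat, TPSA(Tot)coat
}


@dataclass
class MeanTable:
    """Per-group training means of one descriptor within one partition."""

    descriptor: str
    partition: tuple[str, ...]
    means: dict[tuple, float]
    global_mean: float

    def __post_init__(self):
        if not np.isfinite(self.global_mean):
            raise ValueError("global mean must be finite")
        bad = [k for k, v in self.means.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite group means for {bad}")

    def lookup(self, df: pd.DataFrame) -> np.ndarray:
        """Group mean per row of ``df`` (global-mean fallback, logged)."""
        keys = pd.MultiIndex.from_frame(df[list(self.partition)].astype(object))
        out = np.fromiter(
            (self.means.get(k, np.nan) for k in keys), dtype=float, count=len(df))
        unseen = np.isnan(out)
        if unseen.any():
            log.warning(
                "%s | %s: %d rows in unseen label combinations, using global "
                "mean %.6g", self.descriptor, "x".join(self.partition),
                int(unseen.sum()), self.global_mean)
            out[unseen] = self.global_mean
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(*k, v) for k, v in sorted(self.means.items())]
        return pd.DataFrame(rows, columns=[*self.partition, "mean"])

    def to_dict(self) -> dict:
        return {"descriptor": self.descriptor, "partition": list(self.partition),
                "means": [[list(k), v] for k, v in sorted(self.means.items())],
                "global_mean": self.global_mean}

    @classmethod
    def from_dict(cls, d: dict) -> "MeanTable":
        return cls(d["descriptor"], tuple(d["partition"]),
                   {tuple(k): v for k, v in d["means"]}, d["global_mean"])


def group_means(
    df: pd.DataFrame,
    descriptor: str,
    partition: tuple[str, ...],
    training_mask=None,
) -> MeanTable:
    """Mean of ``descriptor`` per observed joint combination of the
    partition's label values, computed from training rows only."""
    if descriptor not in df.columns:
        raise KeyError(f"descriptor {descriptor!r} not in table")
    missing = [k for k in partition if k not in df.columns]
    if missing:
        raise KeyError(f"partition keys {missing} not in table")
    sub = df if training_mask is None else df.loc[np.asarray(training_mask, bool)]
    if len(sub) == 0:
        raise ValueError("no training rows to compute group means from")
    grp = sub.groupby([sub[k].astype(object) for k in partition],
                      sort=False)[descriptor].mean()
    means = {k if isinstance(k, tuple) else (k,): float(v)
             for k, v in grp.items()}
    return MeanTable(descriptor=descriptor, partition=tuple(partition),
                     means=means, global_mean=float(sub[descriptor].mean()))


def ma_deviation(df: pd.DataFrame, means: MeanTable) -> np.ndarray:
    """dD = D - <D | c> per row, with global-mean fallback for unseen groups."""
    return df[means.descriptor].to_numpy(dtype=float) - means.lookup(df)


def cross_deviation(
    paired_df: pd.DataFrame,
    descriptor: str,
    partition: tuple[str, ...],
    training_mask=None,
) -> tuple[np.ndarray, MeanTable]:
    """Deviation of one side's descriptor within the *other* side's label
    partition. Groups only exist after pairing, so this is computed on the
    paired table; when the partition is the descriptor's own side this
    coincides with the plain MA operator."""
    means = group_means(paired_df, descriptor, partition, training_mask)
    return ma_deviation(paired_df, means), means


def mab_operator(
    paired_df: pd.DataFrame,
    drug_descriptor: str,
    coating_descriptor_1: str,
    coating_descriptor_2: str,
    partitions: PartitionSpec,
    training_mask=None,
) -> tuple[np.ndarray, list[MeanTable]]:
    """Moving-average-balance PTO: the drug deviation within c_I balanced
    against the mean of the two homologous coating deviations within c_III."""
    d_dk = resolve_descriptor(drug_descriptor, "ndd")
    ca1 = resolve_descriptor(coating_descriptor_1, "np")
    ca2 = resolve_descriptor(coating_descriptor_2, "np")
    m_d = group_means(paired_df, d_dk, partitions.c_I, training_mask)
    m_1 = group_means(paired_df, ca1, partitions.c_III, training_mask)
    m_2 = group_means(paired_df, ca2, partitions.c_III, training_mask)
    col = (ma_deviation(paired_df, m_d)
           - 0.5 * (ma_deviation(paired_df, m_1) + ma_deviation(paired_df, m_2)))
    return col, [m_d, m_1, m_2]


# Feature specification ------------------------------------------------------

@dataclass(frozen=True)
class FeatureDef:
    """One feature: its kind, descriptor(s) and conditioning partition.

    kind: ``reference`` (the fused reference probability), ``ma`` (own-side
    moving-average deviation), ``cross_ma`` (other-side partition), or
    ``mab`` (drug-vs-coating balance; ``descriptor`` is the drug descriptor
    and ``coating_pair`` the two homologous coating descriptors).
    """

    kind: str
    name: str
    descriptor: str | None = None
    partition: tuple[str, ...] | str | None = None
    coating_pair: tuple[str, str] | None = None

    def __post_init__(self):
        if self.kind not in ("reference", "ma", "cross_ma", "mab"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind != "reference" and self.descriptor is None:
            raise ValueError(f"feature {self.name!r}: descriptor required")

    def resolve_partition(self, partitions: PartitionSpec) -> tuple[str, ...]:
        if isinstance(self.partition, str):
            return partitions[self.partition]
        return tuple(self.partition)


def default_feature_spec() -> "FeatureSpec":
    """The seven-variable input set of the reference linear/ANN models:
    the fused reference plus six moving-average deviations."""
    return FeatureSpec(features=(
        FeatureDef("reference", "f(cd0,cn0)_ref"),
        FeatureDef("ma", "dD_psa(c_I)", "psa", "c_I"),
        FeatureDef("ma", "dD_t(c_III)", "assay_time", "c_III"),
        FeatureDef("ma", "dD_lnp(c_III)", "d_n02", "c_III"),
        FeatureDef("ma", "dD_vnu(c_III)", "d_n03", "c_III"),
        FeatureDef("ma", "dD_vxcoat(c_III)", "d_n17", "c_III"),
        FeatureDef("ma", "dD_vvdwmgcoat(c_III)", "d_n18", "c_III"),
    ))


@dataclass
class FeatureSpec:
    """Ordered feature definitions plus the label-partition layout."""

    features: tuple[FeatureDef, ...]
    partitions: PartitionSpec = field(default_factory=PartitionSpec)

    def __post_init__(self):
        self.features = tuple(self.features)
        if not self.features:
            raise ValueError("feature spec is empty")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def to_yaml(self, path) -> None:
        data = [{k: v for k, v in {
            "kind": f.kind, "name": f.name, "descriptor": f.descriptor,
            "partition": list(f.partition) if isinstance(f.partition, tuple)
            else f.partition,
            "coating_pair": list(f.coating_pair) if f.coating_pair else None,
        }.items() if v is not None} for f in self.features]
        with open(path, "w") as fh:
            yaml.safe_dump({"features": data}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path, partitions: PartitionSpec | None = None):
        with open(path) as fh:
            data = yaml.safe_load(fh)
        feats = []
        for d in data["features"]:
            part = d.get("partition")
            if isinstance(part, list):
                part = tuple(part)
            pair = d.get("coating_pair")
            feats.append(FeatureDef(d["kind"], d["name"], d.get("descriptor"),
                                    part,
                                    tuple(pair) if pair else None))
        return cls(tuple(feats), partitions or PartitionSpec())


@dataclass
class FeatureMatrix:
    """Assembled feature columns with the fitted state needed to transform
    new cases: per-feature mean tables and (after ``standardize``) the
    training standardization stats."""

    X: pd.DataFrame
    spec: FeatureSpec
    mean_tables: dict[str, list[MeanTable]]
    train_mean: pd.Series | None = None
    train_sd: pd.Series | None = None
    constant_features: tuple[str, ...] = ()

    def transform(self, df: pd.DataFrame, f_ref: np.ndarray) -> pd.DataFrame:
        """Build the same feature columns for new (e.g. grid) cases using
        the stored training mean tables and standardization stats."""
        cols = {}
        for feat in self.spec.features:
            if feat.kind == "reference":
                cols[feat.name] = np.asarray(f_ref, dtype=float)
                continue
            tables = self.mean_tables[feat.name]
            if tables is None:  # absent optional descriptor -> zero column
                cols[feat.name] = np.zeros(len(df))
            elif feat.kind == "mab":
                m_d, m_1, m_2 = tables
                cols[feat.name] = (ma_deviation(df, m_d)
                                   - 0.5 * (ma_deviation(df, m_1)
                                            + ma_deviation(df, m_2)))
            else:
                cols[feat.name] = ma_deviation(df, tables[0])
        out = pd.DataFrame(cols, index=df.index)[self.spec.names]
        if self.train_mean is not None:
            out = (out - self.train_mean) / self.train_sd.replace(0.0, 1.0)
            for name in self.constant_features:
                out[name] = 0.0
        return out

    def state_to_json(self, path) -> None:
        """Persist the fitted transform state (not the feature values)."""
        import json
        spec = [{"kind": f.kind, "name": f.name, "descriptor": f.descriptor,
                 "partition": (list(f.partition)
                               if isinstance(f.partition, tuple) else f.partition),
                 "coating_pair": list(f.coating_pair) if f.coating_pair else None}
                for f in self.spec.features]
        state = {
            "spec": spec,
            "partitions": {"c_I": list(self.spec.partitions.c_I),
                           "c_II": list(self.spec.partitions.c_II),
                           "c_III": list(self.spec.partitions.c_III)},
            "mean_tables": {
                name: ([t.to_dict() for t in tables] if tables else None)
                for name, tables in self.mean_tables.items()},
            "train_mean": (self.train_mean.to_dict()
                           if self.train_mean is not None else None),
            "train_sd": (self.train_sd.to_dict()
                         if self.train_sd is not None else None),
            "constant_features": list(self.constant_features),
        }
        with open(path, "w") as fh:
            json.dump(state, fh)

    @classmethod
    def state_from_json(cls, path) -> "FeatureMatrix":
        """Rebuild a transform-only FeatureMatrix (empty X) from JSON."""
        import json
        with open(path) as fh:
            d = json.load(fh)
        feats = tuple(
            FeatureDef(f["kind"], f["name"], f["descriptor"],
                       tuple(f["partition"]) if isinstance(f["partition"], list)
                       else f["partition"],
                       tuple(f["coating_pair"]) if f["coating_pair"] else None)
            for f in d["spec"])
        spec = FeatureSpec(feats, PartitionSpec(**{
            k: tuple(v) for k, v in d["partitions"].items()}))
        tables = {name: ([MeanTable.from_dict(t) for t in ts] if ts else None)
                  for name, ts in d["mean_tables"].items()}
        tm = pd.Series(d["train_mean"]) if d["train_mean"] else None
        ts = pd.Series(d["train_sd"]) if d["train_sd"] else None
        return cls(X=pd.DataFrame(columns=spec.names), spec=spec,
                   mean_tables=tables, train_mean=tm, train_sd=ts,
                   constant_features=tuple(d["constant_features"]))


def assemble_features(
    paired_df: pd.DataFrame,
    spec: FeatureSpec,
    training_mask=None,
    f_ref_col: str = "f_ref_fused",
) -> FeatureMatrix:
    """Assemble the ordered feature columns of ``spec`` on the paired table.

    Mean tables are fitted on training rows only and retained so the same
    pipeline can score unseen cases. An ``ma`` feature whose descriptor
    column is absent (the optional assay-time column) yields an all-zero
    column and is flagged.
    """
    cols: dict[str, np.ndarray] = {}
    mean_tables: dict[str, list[MeanTable] | None] = {}
    constant: list[str] = []
    for feat in spec.features:
        if feat.kind == "reference":
            if f_ref_col not in paired_df.columns:
                raise KeyError(f"fused reference column {f_ref_col!r} missing")
            cols[feat.name] = paired_df[f_ref_col].to_numpy(dtype=float)
            mean_tables[feat.name] = None
            continue
        if feat.kind == "mab":
            pair = feat.coating_pair or MAB_DEFAULT_PAIRING.get(
                resolve_descriptor(feat.descriptor, "ndd"))
            if pair is None:
                raise KeyError(
                    f"feature {feat.name!r}: no coating pair configured for "
                    f"drug descriptor {feat.descriptor!r}")
            col, tables = mab_operator(paired_df, feat.descriptor, pair[0],
                                       pair[1], spec.partitions, training_mask)
            cols[feat.name] = col
            mean_tables[feat.name] = tables
            continue
        # ma / cross_ma share the mechanics; they differ in which side's
        # partition conditions the mean
        partition = feat.resolve_partition(spec.partitions)
        descriptor = feat.descriptor
        if descriptor not in paired_df.columns:
            if descriptor == "assay_time":
                log.warning("feature %s: assay_time column absent, "
                            "emitting zeros", feat.name)
                cols[feat.name] = np.zeros(len(paired_df))
                mean_tables[feat.name] = None
                constant.append(feat.name)
                continue
            raise KeyError(f"feature {feat.name!r}: descriptor "
                           f"{descriptor!r} not in paired table")
        dev, table = cross_deviation(paired_df, descriptor, partition,
                                     training_mask)
        cols[feat.name] = dev
        mean_tables[feat.name] = [table]
    X = pd.DataFrame(cols, index=paired_df.index)[spec.names]
    return FeatureMatrix(X=X, spec=spec, mean_tables=mean_tables,
                         constant_features=tuple(constant))


def standardize(matrix: FeatureMatrix, training_mask) -> FeatureMatrix:
    """Z-score all columns with training-row mean and sample (n-1) sd.

    Constant training columns are zeroed and flagged rather than divided
    by zero. Returns a new FeatureMatrix carrying the stats; validation
    rows are standardized with training statistics only.
    """
    mask = np.asarray(training_mask, bool)
    if mask.sum() < 2:
        raise ValueError("need at least 2 training rows to standardize")
    train = matrix.X.loc[mask]
    mean = train.mean()
    sd = train.std(ddof=1)
    constant = tuple(sd.index[sd == 0.0]) + matrix.constant_features
    X = (matrix.X - mean) / sd.replace(0.0, 1.0)
    for name in constant:
        X[name] = 0.0
    if constant:
        log.warning("constant feature column(s) zeroed: %s", sorted(set(constant)))
    return FeatureMatrix(X=X, spec=matrix.spec, mean_tables=matrix.mean_tables,
                         train_mean=mean, train_sd=sd,
                         constant_features=tuple(sorted(set(constant))))
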