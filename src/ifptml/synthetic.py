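"""Synthetic assay-table generator with a configurable planted signal.

Emulates the two heterogeneous input tables of the screening problem — a
drug-side (NDD) preclinical-assay table and an NP cytotoxicity table — at
their real label cardinalities, so every downstream stage is testable
without any external download.

What the generator emulates
---------------------------
* Label vocabularies at the study cardinalities (46 drug activity
  parameters, 21 targets, ... 53 NP cell lines, 16 coating agents), with
  Zipf(1) rank-frequency — real assay metadata is long-tailed, which
  stresses stratified sampling. Leading vocabulary tokens are real names
  ("IC50 (nM)", "spherical", ...) so desirability tables written against
  real names also work; the tail is synthesized as readable tokens.
* Per-entity descriptors: all assays of one compound share its LOGP/PSA
  (Gaussian per entity, not per assay), which is what makes moving-average
  deviations meaningful.
* A planted activity signal: observed values are overwritten so that after
  binarization the positive class follows a known logistic model in
  standardized descriptor deviations, with the ground-truth per-assay
  probabilities returned for oracle tests.

One global seed expands into independent per-stream sub-seeds (drug labels,
drug descriptors, NP labels, NP descriptors, outcomes) so that, e.g.,
regenerating outcomes never perturbs the label stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fusion import CutoffTable, DesirabilityTable
from .records import (
    NDD_DESCRIPTOR_KEYS,
    NDD_LABEL_KEYS,
    NP_ASSAY_TIME_KEY,
    NP_DESCRIPTOR_KEYS,
    NP_LABEL_KEYS,
    resolve_descriptor,
)

#: Study-scale label cardinalities (drug side then NP side).
DEFAULT_CARDINALITIES = {
    "c_d0": 46, "c_d1": 21, "c_d2": 7, "c_d3": 7,
    "c_d4": 6, "c_d5": 3, "c_d6": 3, "c_d7": 4, "c_d8": 3,
    "c_n0": 5, "c_n1": 53, "c_n2": 10, "c_n3": 8, "c_n4": 16,
}

#: Real leading tokens per label vocabulary; the tail is synthesized.
REAL_LEVEL_NAMES = {
    "c_d0": ["IC50 (nM)", "EC50 (nM)", "Ki (nM)", "Activity (%)",
             "Inhibition (%)", "Bmax (fmol/mg)", "Cp (nM)", "Imax (%)"],
    "c_d2": ["SH-SY5Y", "CHO-K1", "HEK293", "PC-12", "CHO", "HEK-293T",
             "HuT78"],
    "c_d3": ["Homo sapiens", "Rattus norvegicus", "Mus musculus",
             "Cavia porcellus", "Canis lupus familiaris",
             "Macaca fascicularis", "Caenorhabditis elegans"],
    "c_d4": ["single protein", "protein complex", "organism", "tissue",
             "non-molecular target", "ADMET"],
    "c_d5": ["binding", "functional", "ADMET"],
    "c_d6": ["auto-curation", "expert", "intermediate"],
    "c_d7": ["9", "1", "0", "8"],
    "c_d8": ["protein", "non-molecular target", "homologous protein"],
    "c_n0": ["CC50 (nM)", "EC50 (nM)", "IC50 (nM)", "LC50 (nM)", "TC50 (nM)"],
    "c_n1": ["A549 (H)", "RAW 264.7", "Neuro-2A (M)"],
    "c_n2": ["spherical", "irregular", "slice-shaped", "needles", "rods",
             "elliptical", "pseudo-spherical", "polyhedral", "pyramidal",
             "strips"],
    "c_n3": ["dry", "H2O", "DMEM", "RPMI", "1% Triton X-100/H2O",
             "H2O/TMAOH", "egg/H2O", "H2O/HMT"],
    "c_n4": ["UC", "PEG-Si(OMe)3", "PVA", "sodium citrate",
             "11-mercaptoundecanoic acid", "PVP", "propylammonium fragment",
             "undecylazide fragment", "CTAB",
             "N,N,N-trimethyl-3(1-propene) ammonium fragment",
             "potato starch", "N-acetylcysteine", "CMC-90",
             "2,3-dimercaptopropanesulfonate", "3-mercaptopropanesulfonate",
             "thioglycolic acid"],
}

#: Per-descriptor (mean, sd) of the per-entity Gaussians. Magnitudes are
#: plausible for each unit but chemical realism is out of scope.
DEFAULT_DESCRIPTOR_MODEL = {
    "logp": (2.5, 1.5),     # log units
    "psa": (75.0, 30.0),    # A^2
    "d_n01": (500.0, 200.0), "d_n02": (60.0, 30.0), "d_n03": (8e3, 3e3),
    "d_n04": (2.5, 0.6), "d_n05": (12.0, 4.0), "d_n06": (2.0, 1.0),
    "d_n07": (0.5, 0.2), "d_n08": (0.4, 0.2), "d_n09": (45.0, 15.0),
    "d_n10": (60.0, 25.0), "d_n11": (70.0, 28.0), "d_n12": (1.5, 1.2),
    "d_n13": (4.0, 2.5), "d_n14": (180.0, 60.0), "d_n15": (40.0, 15.0),
    "d_n16": (20.0, 8.0), "d_n17": (1.4, 0.5), "d_n18": (150.0, 50.0),
    "d_n19": (140.0, 45.0), "d_n20": (0.7, 0.15),
}

#: All planted cutoffs sit at this value; planted observed values are drawn
#: on the favorable/unfavorable side of it according to desirability.
PLANTED_CUTOFF = 100.0

# sub-seed stream indices (fixed offsets from the global seed)
_STREAMS = {"ndd_labels": 0, "ndd_desc": 1, "np_labels": 2, "np_desc": 3,
            "outcomes": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class SignalSpec:
    """Planted-signal description.

    ``linear_weights`` maps ``"side:descriptor"`` (e.g. ``"ndd:psa"``,
    ``"np:Lnp"``) to a weight on the *standardized* moving-average deviation
    of that descriptor within its activity-parameter stratum.
    ``interaction_weights`` maps pairs of such keys (same side only — a
    cross-side interaction cannot be expressed through per-assay values) to
    a weight on the product of standardized deviations. ``noise_sd`` is
    Gaussian noise on the latent log-odds; ``base_positive_rate`` is the
    fused positive rate when all weights are zero.
    """

    linear_weights: dict[str, float] = field(default_factory=dict)
    interaction_weights: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = 0.0
    base_positive_rate: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.base_positive_rate < 1.0:
            raise ValueError("base_positive_rate must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for key in self.linear_weights:
            _parse_key(key)
        for pair in self.interaction_weights:
            s1, _ = _parse_key(pair[0])
            s2, _ = _parse_key(pair[1])
            if s1 != s2:
                raise ValueError(
                    f"interaction {pair} crosses sides; planted interactions "
                    "must pair descriptors of the same subsystem")

    def sides_with_signal(self) -> set[str]:
        sides = {_parse_key(k)[0] for k in self.linear_weights
                 if self.linear_weights[k] != 0}
        sides |= {_parse_key(p[0])[0] for p, w in self.interaction_weights.items()
                  if w != 0}
        return sides


def _parse_key(key: str) -> tuple[str, str]:
    try:
        side, name = key.split(":", 1)
    except ValueError:
        raise ValueError(f"signal key {key!r} must look like 'side:descriptor'") \
            from None
    if side not in ("ndd", "np"):
        raise ValueError(f"signal key {key!r}: side must be 'ndd' or 'np'")
    return side, resolve_descriptor(name, side)


@dataclass
class SynthConfig:
    """Generator configuration; defaults are the study-scale conditions."""

    n_ndd_assays: int = 4403
    n_np_assays: int = 260
    n_unique_compounds: int = 2566
    n_unique_nps: int = 31
    cardinalities: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CARDINALITIES))
    descriptor_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DESCRIPTOR_MODEL))
    signal_spec: SignalSpec = field(default_factory=SignalSpec)
    seed: int = 0

    def __post_init__(self):
        card = dict(DEFAULT_CARDINALITIES)
        card.update(self.cardinalities)
        self.cardinalities = card
        model = dict(DEFAULT_DESCRIPTOR_MODEL)
        model.update(self.descriptor_model)
        self.descriptor_model = model
        for name, n in (("n_ndd_assays", self.n_ndd_assays),
                        ("n_np_assays", self.n_np_assays),
                        ("n_unique_compounds", self.n_unique_compounds),
                        ("n_unique_nps", self.n_unique_nps)):
            if n < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_unique_compounds > self.n_ndd_assays:
            raise ValueError("n_unique_compounds cannot exceed n_ndd_assays")
        if self.n_unique_nps > self.n_np_assays:
            raise ValueError("n_unique_nps cannot exceed n_np_assays")
        bad = {k: v for k, v in self.cardinalities.items() if v < 1}
        if bad:
            raise ValueError(f"cardinalities must be >= 1, got {bad}")


def vocabulary(key: str, cardinality: int) -> list[str]:
    """Level names for one label key: real leading tokens, synthesized tail."""
    real = REAL_LEVEL_NAMES.get(key, [])[:cardinality]
    tail = [f"{key}_L{r:02d}" for r in range(len(real) + 1, cardinality + 1)]
    return real + tail


def zipf_probs(k: int) -> np.ndarray:
    """Zipf rank-frequency weights with exponent 1, normalized."""
    w = 1.0 / np.arange(1, k + 1)
    return w / w.sum()


def _draw_labels(rng, keys, cardinalities, n) -> dict[str, np.ndarray]:
    out = {}
    for key in keys:
        vocab = np.array(vocabulary(key, cardinalities[key]), dtype=object)
        out[key] = rng.choice(vocab, size=n, p=zipf_probs(len(vocab)))
    return out


def _assign_entities(rng, n_assays: int, n_unique: int, prefix: str) -> np.ndarray:
    """Every entity appears at least once; the remaining assays reuse
    entities with Zipf(1) popularity, then the assignment is shuffled."""
    width = len(str(n_unique))
    ids = np.array([f"{prefix}{i + 1:0{width}d}" for i in range(n_unique)],
                   dtype=object)
    assignment = np.concatenate([
        np.arange(n_unique),
        rng.choice(n_unique, size=n_assays - n_unique, p=zipf_probs(n_unique)),
    ])
    rng.shuffle(assignment)
    return ids[assignment]


def _entity_descriptors(rng, entity_ids, names, model) -> pd.DataFrame:
    uniq = pd.unique(entity_ids)
    cols = {}
    for name in names:
        mean, sd = model[name]
        per_entity = dict(zip(uniq, rng.normal(mean, sd, size=len(uniq))))
        cols[name] = np.array([per_entity[e] for e in entity_ids])
    return pd.DataFrame(cols)


def _baseline_values(rng, n) -> np.ndarray:
    # log-normal, median at the planted cutoff, before any planting
    return 10 ** rng.normal(math.log10(PLANTED_CUTOFF), 0.5, size=n)


def generate_ndd_assays(config: SynthConfig) -> pd.DataFrame:
    """Drug-side table with canonical columns; seeded and reproducible."""
    n = config.n_ndd_assays
    rng_l = _rng(config.seed, "ndd_labels")
    rng_d = _rng(config.seed, "ndd_desc")
    df = pd.DataFrame({"assay_id": [f"NDDA{i + 1:06d}" for i in range(n)]})
    df["compound_id"] = _assign_entities(rng_l, n, config.n_unique_compounds, "D")
    df["value"] = _baseline_values(rng_l, n)
    for key, col in _draw_labels(rng_l, NDD_LABEL_KEYS,
                                 config.cardinalities, n).items():
        df[key] = col
    desc = _entity_descriptors(rng_d, df["compound_id"].to_numpy(),
                               NDD_DESCRIPTOR_KEYS, config.descriptor_model)
    return pd.concat([df, desc], axis=1)


def generate_np_assays(config: SynthConfig) -> pd.DataFrame:
    """NP cytotoxicity table: 20 descriptors plus an assay-time column."""
    n = config.n_np_assays
    rng_l = _rng(config.seed, "np_labels")
    rng_d = _rng(config.seed, "np_desc")
    df = pd.DataFrame({"assay_id": [f"NPA{i + 1:06d}" for i in range(n)]})
    df["np_id"] = _assign_entities(rng_l, n, config.n_unique_nps, "NP")
    df["value"] = _baseline_values(rng_l, n)
    for key, col in _draw_labels(rng_l, NP_LABEL_KEYS,
                                 config.cardinalities, n).items():
        df[key] = col
    df[NP_ASSAY_TIME_KEY] = rng_l.choice([4.0, 24.0, 48.0, 72.0], size=n)
    desc = _entity_descriptors(rng_d, df["np_id"].to_numpy(),
                               NP_DESCRIPTOR_KEYS, config.descriptor_model)
    return pd.concat([df, desc], axis=1)


def default_desirability(config: SynthConfig) -> DesirabilityTable:
    """Explicit desirability entries covering the generated vocabularies.

    Real parameter names follow the concentration-vs-response convention
    (IC50-like lower-is-better -> -1; activity-like -> +1); synthesized
    tail tokens are treated as concentration-like (-1), the majority class
    in curated bioactivity data.
    """
    entries = {}
    base = DesirabilityTable()
    for key in ("c_d0", "c_n0"):
        for token in vocabulary(key, config.cardinalities[key]):
            entries[token] = base[token] if token in base else -1
    return DesirabilityTable(entries)


def planted_cutoffs(config: SynthConfig) -> CutoffTable:
    """The cutoff table the planting step encodes the signal against."""
    entries = {}
    for key in ("c_d0", "c_n0"):
        for token in vocabulary(key, config.cardinalities[key]):
            entries[token] = PLANTED_CUTOFF
    return CutoffTable(entries, {k: "user" for k in entries})


@dataclass
class PlantedTruth:
    """Ground truth returned by :func:`plant_outcomes`.

    ``ndd`` / ``np`` hold per-assay positive probabilities and latent
    log-odds (log-odds is ``inf`` on a side made deterministically
    favorable). Fused per-pair truth is the product of the two sides'
    probabilities.
    """

    ndd: pd.DataFrame
    np: pd.DataFrame
    cutoffs: CutoffTable

    def fused_p(self, ndd_assay_ids, np_assay_ids) -> np.ndarray:
        p_d = self.ndd.set_index("assay_id")["p"]
        p_n = self.np.set_index("assay_id")["p"]
        return (p_d.loc[np.asarray(ndd_assay_ids, dtype=object)].to_numpy()
                * p_n.loc[np.asarray(np_assay_ids, dtype=object)].to_numpy())


def _standardized_deviation(df, column, group_key) -> np.ndarray:
    x = df[column].to_numpy(dtype=float)
    dev = x - df.groupby(group_key)[column].transform("mean").to_numpy()
    sd = dev.std()
    if sd == 0:
        return np.zeros_like(dev)
    return dev / sd


def _side_logit(df, side, signal: SignalSpec, base_logit, rng, noise_sd):
    group_key = "c_d0" if side == "ndd" else "c_n0"
    z = {}

    def zcol(key):
        s, col = _parse_key(key)
        if col not in df.columns:
            raise KeyError(f"signal references unknown descriptor {key!r}")
        if col not in z:
            z[col] = _standardized_deviation(df, col, group_key)
        return z[col]

    logit = np.full(len(df), base_logit)
    for key, w in signal.linear_weights.items():
        if _parse_key(key)[0] == side and w != 0:
            logit = logit + w * zcol(key)
    for (k1, k2), w in signal.interaction_weights.items():
        if _parse_key(k1)[0] == side and w != 0:
            logit = logit + w * zcol(k1) * zcol(k2)
    if noise_sd > 0:
        logit = logit + rng.normal(0.0, noise_sd, size=len(df))
    return logit


def _write_values(df, f_target, desirability, rng) -> np.ndarray:
    """Observed values consistent with the Boolean targets: strictly on the
    favorable side of the planted cutoff when f=1, unfavorable when f=0."""
    param_key = "c_d0" if "c_d0" in df.columns else "c_n0"
    d = df[param_key].map(lambda p: desirability[p]).to_numpy(dtype=float)
    margin = 0.05 * PLANTED_CUTOFF
    u = np.abs(rng.normal(0.0, 0.3 * PLANTED_CUTOFF, size=len(df))) + margin
    sign = np.where(f_target == 1, d, -d)
    return PLANTED_CUTOFF + sign * u


def plant_outcomes(
    ndd_table: pd.DataFrame,
    np_table: pd.DataFrame,
    signal: SignalSpec,
    desirability: DesirabilityTable,
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Overwrite observed values so the fused positive class follows the
    planted logistic model; labels and table shapes are untouched.

    When only one side carries signal weights, the full base rate is
    assigned to that side and the other side is made deterministically
    favorable — the fused log-odds then equals the planted logit exactly.
    When both (or neither) side carries weights, the base rate is split as
    the square root per side, and noise is divided accordingly.
    """
    rng = _rng(config.seed, "outcomes")
    base = signal.base_positive_rate
    sides = signal.sides_with_signal()

    def logit(p):
        return math.log(p / (1.0 - p))

    if len(sides) == 1:
        bases = {s: (logit(base) if s in sides else None) for s in ("ndd", "np")}
        noise = {s: signal.noise_sd for s in ("ndd", "np")}
    else:
        bases = {s: logit(math.sqrt(base)) for s in ("ndd", "np")}
        noise = {s: signal.noise_sd / math.sqrt(2) for s in ("ndd", "np")}

    out_tables, truths = {}, {}
    for side, df in (("ndd", ndd_table), ("np", np_table)):
        df = df.copy()
        if bases[side] is None:  # deterministically favorable side
            p = np.ones(len(df))
            lg = np.full(len(df), np.inf)
            f_target = np.ones(len(df), dtype=int)
        else:
            lg = _side_logit(df, side, signal, bases[side], rng, noise[side])
            p = 1.0 / (1.0 + np.exp(-lg))
            f_target = (rng.random(len(df)) < p).astype(int)
        df["value"] = _write_values(df, f_target, desirability, rng)
        out_tables[side] = df
        truths[side] = pd.DataFrame(
            {"assay_id": df["assay_id"], "p": p, "logit": lg})

    truth = PlantedTruth(ndd=truths["ndd"], np=truths["np"],
                         cutoffs=planted_cutoffs(config))
    return out_tables["ndd"], out_tables["np"], truth


def generate_study(config: SynthConfig):
    """Convenience wrapper: generate both tables, plant the configured
    signal, and return (ndd_df, np_df, desirability, truth)."""
    ndd = generate_ndd_assays(config)
    npt = generate_np_assays(config)
    desirability = default_desirability(config)
    ndd, npt, truth = plant_outcomes(ndd, npt, config.signal_spec,
                                     desirability, config)
    return ndd, npt, desirability, truth
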