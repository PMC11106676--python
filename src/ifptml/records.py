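"""Typed data model for drug (NDD) and nanoparticle (NP) preclinical assays.

An *assay record* is one preclinical measurement: an observed value ``v``
(in the units implied by its activity parameter), a vector of categorical
condition labels ``c_j`` (what was measured, on which cell line, etc.) and a
vector of real-valued structural descriptors ``D_k`` of the compound or
nanoparticle. Missing categories are stored as the literal level ``"NA"``
and treated as a valid stratum, never imputed: the perturbation-theory
operators condition on label combinations, so missingness must be a level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

#: Sentinel level for a missing category. A valid stratum, never imputed.
NA_LEVEL = "NA"

# Drug-side (NDD) schema ----------------------------------------------------

#: c_d0 activity parameter; c_d1 target protein; c_d2 cell line; c_d3
#: organism; c_d4 target type; c_d5 assay type; c_d6 curation; c_d7
#: confidence score; c_d8 target mapping.
NDD_LABEL_KEYS = tuple(f"c_d{j}" for j in range(9))

#: LOGP (octanol/water partition, log units) and PSA (topological polar
#: surface area, Å²). Extra drug descriptors may be configured per table.
NDD_DESCRIPTOR_KEYS = ("logp", "psa")

# NP-side schema ------------------------------------------------------------

#: c_n0 activity parameter; c_n1 cell line; c_n2 shape; c_n3
#: medium/measurement condition; c_n4 coating agent.
NP_LABEL_KEYS = tuple(f"c_n{j}" for j in range(5))

#: Canonical column -> field-standard descriptor name.
NP_DESCRIPTOR_NAMES = {
    "d_n01": "NMUn",          # number of monomer units
    "d_n02": "Lnp",           # NP length
    "d_n03": "Vnu",           # NP volume
    "d_n04": "Enu",           # NP electronegativity
    "d_n05": "Pnu",           # NP polarizability
    "d_n06": "Uccoat",        # unsaturation count of the coating
    "d_n07": "Uicoat",        # unsaturation index
    "d_n08": "Hycoat",        # hydrophilic factor
    "d_n09": "AMRcoat",       # Ghose-Crippen molar refractivity
    "d_n10": "TPSA(NO)coat",  # TPSA, N/O contributions
    "d_n11": "TPSA(Tot)coat", # TPSA, N/O/S/P contributions
    "d_n12": "ALOGPcoat",     # Ghose-Crippen logP of the coating
    "d_n13": "ALOGP2coat",    # squared ALOGP
    "d_n14": "SAtotcoat",     # total P_VSA-like surface area
    "d_n15": "SAacccoat",     # acceptor-atom surface area
    "d_n16": "SAdoncoat",     # donor-atom surface area
    "d_n17": "Vxcoat",        # McGowan volume
    "d_n18": "VvdwMGcoat",    # van der Waals volume (McGowan)
    "d_n19": "VvdwZAZcoat",   # van der Waals volume (Zhao-Abraham-Zissimos)
    "d_n20": "PDIcoat",       # packing density index
}

NP_DESCRIPTOR_KEYS = tuple(NP_DESCRIPTOR_NAMES)

#: Reverse lookup: field-standard name (case-insensitive) -> canonical column.
NP_DESCRIPTOR_COLUMNS = {v.lower(): k for k, v in NP_DESCRIPTOR_NAMES.items()}

#: Optional NP-side numeric column (assay duration, hours). Carried so the
#: "deviation of assay time" feature can be formed; all-zero when absent.
NP_ASSAY_TIME_KEY = "assay_time"

ENTITY_KEYS = {"ndd": "compound_id", "np": "np_id"}


def resolve_descriptor(name: str, side: str) -> str:
    """Map a descriptor name (canonical column or field-standard alias,
    e.g. ``"Lnp"`` -> ``"d_n02"``) to its canonical column name."""
    low = name.lower()
    if side == "ndd":
        if low in NDD_DESCRIPTOR_KEYS:
            return low
    else:
        if low in NP_DESCRIPTOR_KEYS or low == NP_ASSAY_TIME_KEY:
            return low
        if low in NP_DESCRIPTOR_COLUMNS:
            return NP_DESCRIPTOR_COLUMNS[low]
    raise KeyError(f"unknown {side!r} descriptor: {name!r}")


def _check_record(kind, assay_id, value, labels, descriptors,
                  label_keys, descriptor_keys):
    if not (isinstance(value, (int, float)) and math.isfinite(value)):
        raise ValueError(f"{kind} {assay_id!r}: value must be finite, got {value!r}")
    missing = [k for k in label_keys if k not in labels]
    if missing:
        raise ValueError(f"{kind} {assay_id!r}: missing label keys {missing}")
    extra = [k for k in labels if k not in label_keys]
    if extra:
        raise ValueError(f"{kind} {assay_id!r}: unexpected label keys {extra}")
    if set(descriptors) != set(descriptor_keys):
        raise ValueError(
            f"{kind} {assay_id!r}: descriptor keys {sorted(descriptors)} != "
            f"configured {sorted(descriptor_keys)}")
    bad = [k for k, v in descriptors.items() if not math.isfinite(v)]
    if bad:
        raise ValueError(f"{kind} {assay_id!r}: non-finite descriptors {bad}")


@dataclass
class NDDAssayRecord:
    """One drug-side preclinical assay."""

    assay_id: str
    compound_id: str
    value: float
    labels: dict[str, str]
    descriptors: dict[str, float]
    descriptor_keys: tuple[str, ...] = NDD_DESCRIPTOR_KEYS

    side = "ndd"
    label_keys = NDD_LABEL_KEYS

    def __post_init__(self):
        self.value = float(self.value)
        self.descriptors = {k: float(v) for k, v in self.descriptors.items()}
        _check_record("NDD assay", self.assay_id, self.value, self.labels,
                      self.descriptors, self.label_keys, self.descriptor_keys)


@dataclass
class NPAssayRecord:
    """One nanoparticle cytotoxicity assay."""

    assay_id: str
    np_id: str
    value: float
    labels: dict[str, str]
    descriptors: dict[str, float]
    descriptor_keys: tuple[str, ...] = NP_DESCRIPTOR_KEYS
    assay_time: float | None = None

    side = "np"
    label_keys = NP_LABEL_KEYS

    def __post_init__(self):
        self.value = float(self.value)
        self.descriptors = {k: float(v) for k, v in self.descriptors.items()}
        _check_record("NP assay", self.assay_id, self.value, self.labels,
                      self.descriptors, self.label_keys, self.descriptor_keys)
        if self.assay_time is not None:
            self.assay_time = float(self.assay_time)
            if not math.isfinite(self.assay_time):
                raise ValueError(f"NP assay {self.assay_id!r}: non-finite assay_time")

    @property
    def entity_id(self) -> str:
        return self.np_id


# PartitionSpec -------------------------------------------------------------

@dataclass(frozen=True)
class PartitionSpec:
    """Grouping of condition labels over which descriptor means are taken.

    ``c_I`` — drug-side biological labels; ``c_II`` — drug-side data-quality
    labels; ``c_III`` — the single NP-side partition. The three lists are
    disjoint and jointly cover every configured label key.
    """

    c_I: tuple[str, ...] = ("c_d0", "c_d1", "c_d2", "c_d3")
    c_II: tuple[str, ...] = ("c_d4", "c_d5", "c_d6", "c_d7", "c_d8")
    c_III: tuple[str, ...] = NP_LABEL_KEYS

    def __post_init__(self):
        object.__setattr__(self, "c_I", tuple(self.c_I))
        object.__setattr__(self, "c_II", tuple(self.c_II))
        object.__setattr__(self, "c_III", tuple(self.c_III))
        parts = [self.c_I, self.c_II, self.c_III]
        flat = [k for p in parts for k in p]
        if len(set(flat)) != len(flat):
            raise ValueError("partitions c_I, c_II, c_III must be disjoint")
        covered = set(flat)
        expected = set(NDD_LABEL_KEYS) | set(NP_LABEL_KEYS)
        if not covered <= expected:
            raise ValueError(f"unknown label keys in partitions: {covered - expected}")
        if covered != expected:
            raise ValueError(f"partitions must cover all label keys; missing {expected - covered}")

    def __getitem__(self, name: str) -> tuple[str, ...]:
        try:
            return {"c_I": self.c_I, "c_II": self.c_II, "c_III": self.c_III}[name]
        except KeyError:
            raise KeyError(f"unknown partition {name!r}; expected c_I/c_II/c_III") from None


@dataclass
class DatasetSummary:
    """Counts describing one assay table: how many assays, how many unique
    compounds/NPs, the assays-per-entity ratio and per-label cardinalities."""

    n_assays: int
    n_unique_entities: int
    assays_per_entity: float = field(init=False)
    label_cardinalities: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_assays < 1 or self.n_unique_entities < 1:
            raise ValueError("counts must be >= 1")
        if any(c < 1 for c in self.label_cardinalities.values()):
            raise ValueError("label cardinalities must be >= 1")
        self.assays_per_entity = self.n_assays / self.n_unique_entities

    def to_dict(self) -> dict:
        return {
            "n_assays": self.n_assays,
            "n_unique_entities": self.n_unique_entities,
            # reported to 2 decimals
            "assays_per_entity": round(self.assays_per_entity, 2),
            "label_cardinalities": dict(self.label_cardinalities),
        }


def side_schema(side: str) -> tuple[tuple[str, ...], tuple[str, ...], str]:
    """Return (label_keys, descriptor_keys, entity_key) for a side."""
    if side == "ndd":
        return NDD_LABEL_KEYS, NDD_DESCRIPTOR_KEYS, ENTITY_KEYS["ndd"]
    if side == "np":
        return NP_LABEL_KEYS, NP_DESCRIPTOR_KEYS, ENTITY_KEYS["np"]
    raise ValueError(f"side must be 'ndd' or 'np', got {side!r}")
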