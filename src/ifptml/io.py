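"""Validated CSV/TSV readers and writers for assay tables.

Canonical headers are snake-case (``c_d0``…``c_d8``, ``c_n0``…``c_n4``,
``value``, ``logp``, ``psa``, ``d_n01``…``d_n20``); foreign files with
free-text headers are accommodated through a user-supplied rename map.
The delimiter is auto-detected from the extension (``.tsv`` -> tab) and
can be overridden. Round-trip stability (``read(write(x)) == x``) is part
of the contract and covered by tests.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .records import (
    NA_LEVEL,
    NP_ASSAY_TIME_KEY,
    DatasetSummary,
    NDDAssayRecord,
    NPAssayRecord,
    side_schema,
)


class SchemaError(ValueError):
    """The file's columns do not match the configured schema."""


class ParseError(ValueError):
    """A row failed validation; the message names the offending row."""


def _delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_assay_table(
    path,
    side: str,
    rename: dict[str, str] | None = None,
    delimiter: str | None = None,
    extra_descriptors: tuple[str, ...] = (),
) -> list:
    """Read one side's assay table into validated records, preserving row order.

    Parameters
    ----------
    path : path to a CSV/TSV file with canonical (or renamed) headers.
    side : ``"ndd"`` or ``"np"``.
    rename : optional map from the file's headers to canonical names.
    extra_descriptors : additional descriptor columns beyond the fixed schema
        (the drug side fixes LOGP and PSA; extras are configuration).
    """
    path = Path(path)
    label_keys, descriptor_keys, entity_key = side_schema(side)
    descriptor_keys = tuple(descriptor_keys) + tuple(extra_descriptors)

    df = pd.read_csv(path, sep=_delimiter(path, delimiter), dtype=str,
                     keep_default_na=False)
    if rename:
        df = df.rename(columns=rename)

    required = ["assay_id", entity_key, "value", *label_keys, *descriptor_keys]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing mandatory column(s) {missing} for side {side!r}")

    cls = NDDAssayRecord if side == "ndd" else NPAssayRecord
    has_time = side == "np" and NP_ASSAY_TIME_KEY in df.columns

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        kwargs = {}
        try:
            value = float(row["value"])
        except ValueError:
            raise ParseError(
                f"{path.name} row {i}: non-numeric value {row['value']!r}") from None
        descriptors = {}
        for k in descriptor_keys:
            try:
                descriptors[k] = float(row[k])
            except ValueError:
                raise ParseError(
                    f"{path.name} row {i}: non-numeric descriptor "
                    f"{k}={row[k]!r}") from None
        if has_time and row[NP_ASSAY_TIME_KEY] != "":
            try:
                kwargs["assay_time"] = float(row[NP_ASSAY_TIME_KEY])
            except ValueError:
                raise ParseError(
                    f"{path.name} row {i}: non-numeric {NP_ASSAY_TIME_KEY}="
                    f"{row[NP_ASSAY_TIME_KEY]!r}") from None
        labels = {k: (row[k] if row[k] != "" else NA_LEVEL) for k in label_keys}
        try:
            rec = cls(
                assay_id=row["assay_id"],
                **{entity_key: row[entity_key]},
                value=value,
                labels=labels,
                descriptors=descriptors,
                descriptor_keys=descriptor_keys,
                **kwargs,
            )
        except ValueError as exc:
            raise ParseError(f"{path.name} row {i}: {exc}") from None
        records.append(rec)
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Denormalize records into a flat DataFrame with canonical columns."""
    if not records:
        raise ValueError("record list is empty")
    side = records[0].side
    if any(r.side != side for r in records):
        raise ValueError("records must all be from the same side")
    label_keys, _, entity_key = side_schema(side)
    descriptor_keys = records[0].descriptor_keys
    rows = []
    for r in records:
        row = {"assay_id": r.assay_id, entity_key: getattr(r, entity_key),
               "value": r.value}
        row.update({k: r.labels[k] for k in label_keys})
        row.update({k: r.descriptors[k] for k in descriptor_keys})
        if side == "np" and r.assay_time is not None:
            row[NP_ASSAY_TIME_KEY] = r.assay_time
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame, side: str,
                     extra_descriptors: tuple[str, ...] = ()) -> list:
    """Inverse of :func:`records_to_frame` (used by the generators)."""
    label_keys, descriptor_keys, entity_key = side_schema(side)
    descriptor_keys = tuple(descriptor_keys) + tuple(extra_descriptors)
    cls = NDDAssayRecord if side == "ndd" else NPAssayRecord
    has_time = side == "np" and NP_ASSAY_TIME_KEY in df.columns
    out = []
    for row in df.itertuples(index=False):
        row = row._asdict()
        kwargs = {"assay_time": float(row[NP_ASSAY_TIME_KEY])} if has_time else {}
        out.append(cls(
            assay_id=str(row["assay_id"]),
            **{entity_key: str(row[entity_key])},
            value=float(row["value"]),
            labels={k: str(row[k]) for k in label_keys},
            descriptors={k: float(row[k]) for k in descriptor_keys},
            descriptor_keys=descriptor_keys,
            **kwargs,
        ))
    return out


def write_assay_table(records, path, delimiter: str | None = None) -> Path:
    """Write records to CSV/TSV so that ``read_assay_table`` round-trips them."""
    path = Path(path)
    df = records_to_frame(records)  # raises on empty/mixed input
    df.to_csv(path, sep=_delimiter(path, delimiter), index=False)
    return path


def summarize_dataset(records, entity_key: str | None = None) -> DatasetSummary:
    """Exact counts: assays, unique entities, assays/entity, label cardinalities."""
    if not records:
        raise ValueError("cannot summarize an empty record list")
    side = records[0].side
    label_keys, _, default_entity = side_schema(side)
    entity_key = entity_key or default_entity
    entities = {getattr(r, entity_key) for r in records}
    cardinalities = {
        k: len({r.labels[k] for r in records}) for k in label_keys
    }
    return DatasetSummary(
        n_assays=len(records),
        n_unique_entities=len(entities),
        label_cardinalities=cardinalities,
    )


def write_summary(summary: DatasetSummary, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(summary.to_dict(), indent=2) + "\n")
    return path
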