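"""Block-structured descriptor tables for nano-QSPR modeling.

A modeling table holds one row per polymeric nanoparticle (PNP):
descriptor values grouped into *core* (continuous physicochemical
properties of the polymer core), *coating* (small-integer counts
describing the surface functionalization) and *corona* (binary
protein-corona fingerprint bits), an endpoint column (zeta potential
in mV) and a train/validation split label.

The 20-PNP, 5-descriptor dataset used to develop the reference model
ships as a packaged CSV fixture (:func:`load_fixture_table1`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

BLOCKS = ("core", "coating", "corona")
KINDS = ("continuous", "count", "binary")
SPLITS = ("T", "V", "unassigned")


class TableValidationError(ValueError):
    """A modeling-table invariant is violated; message carries row/column coordinates."""


@dataclass(frozen=True)
class DescriptorColumn:
    """A single descriptor: its name, structural block and value kind."""

    name: str
    block: str
    kind: str

    def __post_init__(self) -> None:
        if self.block not in BLOCKS:
            raise TableValidationError(
                f"column {self.name!r}: unknown block {self.block!r} (expected one of {BLOCKS})"
            )
        if self.kind not in KINDS:
            raise TableValidationError(
                f"column {self.name!r}: unknown kind {self.kind!r} (expected one of {KINDS})"
            )


@dataclass
class PNPSample:
    """One nanoparticle: identifiers, descriptor values, endpoint and split label.

    ``predicted_mV`` is reference metadata (e.g. a previously published
    prediction); it is never used for fitting.
    """

    structure_id: str
    core_name: str
    coating_name: str
    descriptor_values: tuple[float, ...]
    zeta_mV: float
    split: str = "unassigned"
    predicted_mV: float | None = None


@dataclass
class ModelingTable:
    """An ordered collection of :class:`PNPSample` rows sharing one descriptor schema."""

    columns: list[DescriptorColumn]
    samples: list[PNPSample]

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise TableValidationError(f"duplicate descriptor names: {dupes}")
        ids = [s.structure_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise TableValidationError(f"duplicate structure_id: {dupes}")
        p = len(self.columns)
        for s in self.samples:
            if len(s.descriptor_values) != p:
                raise TableValidationError(
                    f"sample {s.structure_id!r}: {len(s.descriptor_values)} descriptor "
                    f"values for {p} columns"
                )
            if not math.isfinite(s.zeta_mV):
                raise TableValidationError(f"sample {s.structure_id!r}: non-finite endpoint")
            if s.split not in SPLITS:
                raise TableValidationError(
                    f"sample {s.structure_id!r}: unknown split label {s.split!r}"
                )
        if not self.samples:
            return
        X = self.X
        bad = ~np.isfinite(X)
        binary = np.array([c.kind == "binary" for c in self.columns])
        count = np.array([c.kind == "count" for c in self.columns])
        if binary.any():
            bad |= binary & ~np.isin(X, (0.0, 1.0))
        if count.any():
            bad |= count & ((X < 0) | (X != np.floor(X)))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            col = self.columns[j]
            raise TableValidationError(
                f"sample {self.samples[i].structure_id!r}, column {col.name!r}: "
                f"invalid value {X[i, j]!r} for {col.kind} descriptor"
            )

    # -- array views -----------------------------------------------------

    @property
    def descriptor_names(self) -> list[str]:
        return [c.name for c in self.columns]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def X(self) -> np.ndarray:
        """Descriptor matrix, shape (n_samples, n_descriptors)."""
        return np.array([s.descriptor_values for s in self.samples], dtype=float).reshape(
            len(self.samples), len(self.columns)
        )

    @property
    def y(self) -> np.ndarray:
        """Endpoint vector (zeta potential, mV)."""
        return np.array([s.zeta_mV for s in self.samples], dtype=float)

    @property
    def split_labels(self) -> np.ndarray:
        return np.array([s.split for s in self.samples])

    @property
    def train_mask(self) -> np.ndarray:
        return self.split_labels == "T"

    @property
    def validation_mask(self) -> np.ndarray:
        return self.split_labels == "V"

    @property
    def structure_ids(self) -> list[str]:
        return [s.structure_id for s in self.samples]

    # -- derived tables --------------------------------------------------

    def subset_descriptors(self, names: Sequence[str]) -> "ModelingTable":
        """Restrict to the given descriptor columns, preserving their table order."""
        missing = [n for n in names if n not in self.descriptor_names]
        if missing:
            raise KeyError(f"descriptors not in table: {missing}")
        keep = [j for j, c in enumerate(self.columns) if c.name in set(names)]
        cols = [self.columns[j] for j in keep]
        samples = [
            replace(s, descriptor_values=tuple(s.descriptor_values[j] for j in keep))
            for s in self.samples
        ]
        return ModelingTable(cols, samples)

    def subset_blocks(self, blocks: Iterable[str]) -> "ModelingTable":
        blocks = set(blocks)
        return self.subset_descriptors([c.name for c in self.columns if c.block in blocks])

    def subset_rows(self, mask: np.ndarray) -> "ModelingTable":
        samples = [s for s, m in zip(self.samples, mask) if m]
        return ModelingTable(list(self.columns), samples)

    def training(self) -> "ModelingTable":
        return self.subset_rows(self.train_mask)

    def validation(self) -> "ModelingTable":
        return self.subset_rows(self.validation_mask)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "structure_id": self.structure_ids,
                "core": [s.core_name for s in self.samples],
                "coating": [s.coating_name for s in self.samples],
            }
        )
        X = self.X
        for j, c in enumerate(self.columns):
            df[c.name] = X[:, j]
        df["zeta_mV"] = self.y
        preds = [s.predicted_mV for s in self.samples]
        if any(p is not None for p in preds):
            df["zeta_pred_mV"] = [np.nan if p is None else p for p in preds]
        df["split"] = self.split_labels
        return df


# -- schema-driven CSV I/O ----------------------------------------------


@dataclass
class TableSchema:
    """Maps CSV columns to table roles and descriptor blocks/kinds."""

    endpoint_column: str
    descriptors: dict[str, DescriptorColumn]
    id_column: str = "structure_id"
    core_name_column: str | None = "core"
    coating_name_column: str | None = "coating"
    split_column: str | None = "split"
    predicted_column: str | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "TableSchema":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "TableSchema":
        desc = {
            name: DescriptorColumn(name, spec["block"], spec["kind"])
            for name, spec in raw["descriptors"].items()
        }
        return cls(
            endpoint_column=raw["endpoint_column"],
            descriptors=desc,
            id_column=raw.get("id_column", "structure_id"),
            core_name_column=raw.get("core_name_column"),
            coating_name_column=raw.get("coating_name_column"),
            split_column=raw.get("split_column"),
            predicted_column=raw.get("predicted_column"),
        )

    def to_dict(self) -> dict:
        d: dict = {
            "id_column": self.id_column,
            "endpoint_column": self.endpoint_column,
            "descriptors": {
                name: {"block": c.block, "kind": c.kind} for name, c in self.descriptors.items()
            },
        }
        for key in ("core_name_column", "coating_name_column", "split_column", "predicted_column"):
            if getattr(self, key) is not None:
                d[key] = getattr(self, key)
        return d

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _parse_cell(raw: str, row_id: str, colname: str) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise TableValidationError(
            f"row {row_id!r}, column {colname!r}: non-numeric descriptor cell {raw!r}"
        ) from None


def read_table(path: str | Path, schema: TableSchema | str | Path) -> ModelingTable:
    """Read a modeling table from CSV according to a schema config.

    All invariants (binary columns in {0,1}, finite endpoints, unique ids)
    are enforced; violations raise :class:`TableValidationError` naming the
    offending row and column.
    """
    if not isinstance(schema, TableSchema):
        schema = TableSchema.from_file(schema)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in [schema.id_column, schema.endpoint_column, *schema.descriptors]:
        if col not in df.columns:
            raise TableValidationError(f"required column {col!r} missing from {path}")
    columns = list(schema.descriptors.values())
    samples = []
    for _, row in df.iterrows():
        sid = str(row[schema.id_column])
        values = tuple(_parse_cell(row[name], sid, name) for name in schema.descriptors)
        zeta = _parse_cell(row[schema.endpoint_column], sid, schema.endpoint_column)
        split = "unassigned"
        if schema.split_column and schema.split_column in df.columns:
            split = row[schema.split_column] or "unassigned"
        pred = None
        if schema.predicted_column and schema.predicted_column in df.columns:
            raw = row[schema.predicted_column]
            pred = None if raw in ("", "NA") else _parse_cell(raw, sid, schema.predicted_column)
        samples.append(
            PNPSample(
                structure_id=sid,
                core_name=str(row[schema.core_name_column]) if schema.core_name_column else "",
                coating_name=(
                    str(row[schema.coating_name_column]) if schema.coating_name_column else ""
                ),
                descriptor_values=values,
                zeta_mV=zeta,
                split=split,
                predicted_mV=pred,
            )
        )
    return ModelingTable(columns, samples)


def _fmt(v: float) -> str:
    """Shortest decimal text that round-trips the float exactly."""
    v = float(v)
    if v == int(v) and abs(v) < 1e16:
        return str(int(v))
    return repr(v)


def write_table(table: ModelingTable, path: str | Path, schema: TableSchema | None = None) -> None:
    """Write a modeling table as CSV; values are rendered as round-trippable decimal text."""
    if schema is None:
        schema = default_schema(table)
    rows = []
    for s in table.samples:
        row: dict[str, str] = {schema.id_column: s.structure_id}
        if schema.core_name_column:
            row[schema.core_name_column] = s.core_name
        if schema.coating_name_column:
            row[schema.coating_name_column] = s.coating_name
        for name, v in zip(schema.descriptors, s.descriptor_values):
            row[name] = _fmt(v)
        row[schema.endpoint_column] = _fmt(s.zeta_mV)
        if schema.predicted_column:
            row[schema.predicted_column] = "" if s.predicted_mV is None else _fmt(s.predicted_mV)
        if schema.split_column:
            row[schema.split_column] = s.split
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def default_schema(table: ModelingTable) -> TableSchema:
    has_pred = any(s.predicted_mV is not None for s in table.samples)
    return TableSchema(
        endpoint_column="zeta_mV",
        descriptors={c.name: c for c in table.columns},
        predicted_column="zeta_pred_mV" if has_pred else None,
    )


# -- packaged fixture ----------------------------------------------------


def load_fixture_table1() -> ModelingTable:
    """The packaged 20-PNP, 5-descriptor zeta-potential dataset.

    Descriptors: AMW-P (core, average molecular weight of the polymer),
    nCsp2-C (coating, count of sp2-hybridized carbons), and three binary
    protein-corona fingerprint bits (CC1rs = complement C1r subcomponent,
    AA-I = alpha-amylase inhibitor / Apo A-I, kininogen-1).  The published
    train/validation labels and the published per-sample predictions are
    carried along; the predictions are reference metadata only.
    """
    pkg = resources.files("nanoqspr.data")
    with resources.as_file(pkg / "table1.csv") as csv_path, resources.as_file(
        pkg / "table1_schema.yaml"
    ) as schema_path:
        return read_table(csv_path, TableSchema.from_file(schema_path))


def fixture_schema() -> TableSchema:
    pkg = resources.files("nanoqspr.data")
    with resources.as_file(pkg / "table1_schema.yaml") as schema_path:
        return TableSchema.from_file(schema_path)


# -- endpoint-sorted every-third split -----------------------------------


def split_every_third(
    table: ModelingTable, tie_break_order: Sequence[str] | None = None
) -> ModelingTable:
    """Assign train/validation labels by the sorted every-third rule.

    Samples are sorted by ascending endpoint (ties broken by
    ``tie_break_order``, a sequence of structure_ids; default = current
    table order); every third sample in the sorted sequence (positions
    3, 6, 9, ...) goes to the validation set V, the rest to T.  Returns a
    relabeled copy in sorted order.  The endpoint distribution of V thus
    spans the endpoint range of T ("balanced" split).
    """
    if table.n_samples < 3:
        raise ValueError("every-third split needs at least 3 samples")
    if tie_break_order is None:
        tie_rank = {s.structure_id: i for i, s in enumerate(table.samples)}
    else:
        tie_rank = {sid: i for i, sid in enumerate(tie_break_order)}
        missing = [s.structure_id for s in table.samples if s.structure_id not in tie_rank]
        if missing:
            raise ValueError(f"tie_break_order missing structure_ids: {missing}")
    ordered = sorted(table.samples, key=lambda s: (s.zeta_mV, tie_rank[s.structure_id]))
    relabeled = [
        replace(s, split="V" if (i + 1) % 3 == 0 else "T") for i, s in enumerate(ordered)
    ]
    return ModelingTable(list(table.columns), relabeled)
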