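"""Curated microbial trait database: reading, validation, encoding, derived quantities.

A trait database records, for each validly described taxon (species- or
genus-rank), a mixture of continuous traits (e.g. optimal growth temperature),
categorical traits (e.g. oxygen requirement with levels aerobe / anaerobe /
facultative) and binary activity traits (e.g. growth on glucose, hydrogen
sulfide production).  Binary traits follow the curation convention that an
activity is coded 0 when it is not reported, so binary cells are never
missing; continuous and categorical cells may be.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraitKind",
    "TraitCategory",
    "TraitDef",
    "TraitSchema",
    "TraitTable",
    "EncodedTraitMatrix",
    "SchemaError",
    "ValidationError",
    "normalize_taxon_id",
    "read_trait_schema",
    "read_trait_table",
    "genus_consensus",
    "encode_traits",
    "metabolic_breadth",
]

LINEAGE_COLUMNS = ("phylum", "class", "order", "family")
RESERVED_COLUMNS = ("taxon", "rank", *LINEAGE_COLUMNS)

TRAIT_KINDS = ("continuous", "categorical", "binary")
TRAIT_CATEGORIES = (
    "carbon_substrate",
    "enzyme_assay",
    "gas_production",
    "morphology",
    "growth_condition",
    "genomic",
    "other",
)

#: markers normalized to "missing" on read (case-insensitive)
MISSING_MARKERS = frozenset({"", "na", "nan"})

TraitKind = str
TraitCategory = str


class SchemaError(ValueError):
    """A trait column or schema row violates the schema contract."""


class ValidationError(ValueError):
    """A data cell violates its trait's type constraints."""


def normalize_taxon_id(name: str) -> str:
    """Normalize a taxon identifier for cross-file matching.

    Underscores become spaces, runs of whitespace collapse, and the result is
    case-folded.  Abundance-file lineage strings and database names differ in
    exactly these cosmetic ways.
    """
    return re.sub(r"\s+", " ", str(name).replace("_", " ").strip()).casefold()


@dataclass(frozen=True)
class TraitDef:
    """Definition of a single trait."""

    name: str
    kind: TraitKind
    category: TraitCategory = "other"
    levels: tuple[str, ...] = ()
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in TRAIT_KINDS:
            raise SchemaError(f"trait {self.name!r}: unknown kind {self.kind!r}")
        if self.category not in TRAIT_CATEGORIES:
            raise SchemaError(
                f"trait {self.name!r}: unknown category {self.category!r}"
            )
        if self.kind == "categorical" and not self.levels:
            raise SchemaError(f"categorical trait {self.name!r} has no levels")
        if self.kind != "categorical" and self.levels:
            raise SchemaError(f"non-categorical trait {self.name!r} has levels")


@dataclass(frozen=True)
class TraitSchema:
    """Ordered collection of trait definitions; each trait appears once."""

    traits: tuple[TraitDef, ...]
    _by_name: Mapping[str, TraitDef] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        by_name = {t.name: t for t in self.traits}
        if len(by_name) != len(self.traits):
            raise SchemaError("duplicate trait names in schema")
        object.__setattr__(self, "_by_name", by_name)

    def __len__(self) -> int:
        return len(self.traits)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> TraitDef:
        return self._by_name[name]

    def names(self, kind: TraitKind | None = None,
              category: TraitCategory | None = None) -> list[str]:
        return [
            t.name
            for t in self.traits
            if (kind is None or t.kind == kind)
            and (category is None or t.category == category)
        ]

    @property
    def carbon_substrates(self) -> list[str]:
        return self.names(kind="binary", category="carbon_substrate")

    def kind_counts(self) -> dict[str, int]:
        return {k: len(self.names(kind=k)) for k in TRAIT_KINDS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait": [t.name for t in self.traits],
                "kind": [t.kind for t in self.traits],
                "category": [t.category for t in self.traits],
                "levels": ["|".join(t.levels) for t in self.traits],
                "units": [t.units for t in self.traits],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class TraitTable:
    """Trait database in memory: one row per taxon, mixed-type trait columns.

    ``data`` is indexed by taxon_id and carries the columns ``rank``,
    ``phylum``, ``class``, ``order``, ``family`` followed by one column per
    schema trait.  Continuous traits are float (NaN = missing), categorical
    traits are object (NaN = missing), binary traits are int 0/1 and never
    missing.
    """

    data: pd.DataFrame
    schema: TraitSchema

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dups[:5]}")
        for trait in self.schema.names(kind="binary"):
            if self.data[trait].isna().any():
                raise ValidationError(f"binary trait {trait!r} has missing values")

    @property
    def taxa(self) -> pd.Index:
        return self.data.index

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.schema.traits]

    def traits_only(self) -> pd.DataFrame:
        return self.data[self.trait_names]

    def composition(self) -> dict[str, int]:
        """Structural counts: entries by rank and traits by kind."""
        rank = self.data["rank"]
        return {
            "n_species": int((rank == "species").sum()),
            "n_genera": int((rank == "genus").sum()),
            "n_traits": len(self.schema),
            **{f"n_{k}": v for k, v in self.schema.kind_counts().items()},
        }

    def subset(self, taxa: Iterable[str]) -> "TraitTable":
        keep = [t for t in taxa if t in self.data.index]
        return TraitTable(self.data.loc[keep], self.schema)

    def write(self, path: str | Path) -> None:
        out = self.data.reset_index(names="taxon")
        out.to_csv(path, sep="\t", index=False)


def _detect_sep(path: Path) -> str:
    with open(path, "rt") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_trait_schema(path: str | Path) -> TraitSchema:
    """Read a sidecar schema table (columns trait, kind, category, levels, units)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str).fillna("")
    required = {"trait", "kind"}
    if not required.issubset(df.columns):
        raise SchemaError(f"schema file missing columns {required - set(df.columns)}")
    defs = []
    for _, row in df.iterrows():
        levels = tuple(s for s in str(row.get("levels", "")).split("|") if s)
        defs.append(
            TraitDef(
                name=row["trait"],
                kind=row["kind"],
                category=row.get("category", "other") or "other",
                levels=levels,
                units=row.get("units", "") or "",
            )
        )
    return TraitSchema(tuple(defs))


def _is_missing(value: object) -> bool:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return True
    return str(value).strip().casefold() in MISSING_MARKERS


def read_trait_table(path: str | Path, schema: TraitSchema) -> TraitTable:
    """Read and validate a delimited trait database against ``schema``.

    Missing markers (empty cell, "NA", "NaN", any case) are normalized;
    binary cells that are missing are coded 0 per the not-reported convention.
    Rows violating type constraints raise :class:`ValidationError` naming the
    taxon and trait.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_detect_sep(path), dtype=str, keep_default_na=False)
    if "taxon" not in raw.columns:
        raise SchemaError("trait table missing 'taxon' column")
    unknown = [
        c for c in raw.columns if c not in RESERVED_COLUMNS and c not in schema
    ]
    if unknown:
        raise SchemaError(f"trait columns absent from schema: {unknown}")
    absent = [t.name for t in schema.traits if t.name not in raw.columns]
    if absent:
        raise SchemaError(f"schema traits absent from table: {absent}")

    raw = raw.copy()
    raw["taxon"] = raw["taxon"].map(normalize_taxon_id)
    data = raw.set_index("taxon")
    for col in RESERVED_COLUMNS[1:]:
        if col not in data.columns:
            data[col] = ""

    cols: dict[str, pd.Series] = {"rank": data["rank"].replace("", "species")}
    cols.update({c: data[c] for c in RESERVED_COLUMNS[2:]})
    for tdef in schema.traits:
        col = data[tdef.name]
        missing = col.map(_is_missing)
        if tdef.kind == "binary":
            values = pd.Series(0, index=col.index, dtype=int)
            present = col[~missing]
            for taxon, v in present.items():
                sv = str(v).strip()
                if sv not in {"0", "1", "0.0", "1.0"}:
                    raise ValidationError(
                        f"taxon {taxon!r}, binary trait {tdef.name!r}: "
                        f"invalid value {v!r}"
                    )
                values.loc[taxon] = int(float(sv))
            cols[tdef.name] = values
        elif tdef.kind == "continuous":
            values = pd.Series(np.nan, index=col.index, dtype=float)
            for taxon, v in col[~missing].items():
                try:
                    values.loc[taxon] = float(v)
                except ValueError as exc:
                    raise ValidationError(
                        f"taxon {taxon!r}, continuous trait {tdef.name!r}: "
                        f"non-numeric value {v!r}"
                    ) from exc
            cols[tdef.name] = values
        else:  # categorical
            values = pd.Series(np.nan, index=col.index, dtype=object)
            for taxon, v in col[~missing].items():
                sv = str(v).strip()
                if sv not in tdef.levels:
                    raise ValidationError(
                        f"taxon {taxon!r}, categorical trait {tdef.name!r}: "
                        f"value {sv!r} not in levels {tdef.levels}"
                    )
                values.loc[taxon] = sv
            cols[tdef.name] = values

    out = pd.DataFrame(cols, index=data.index)
    return TraitTable(out, schema)


def genus_name(taxon_id: str) -> str:
    """Genus of a binomial taxon id: its first whitespace-delimited token."""
    return normalize_taxon_id(taxon_id).split(" ")[0]


def genus_consensus(
    table: TraitTable, *, ignore_missing: bool = True
) -> TraitTable:
    """Derive genus-rank consensus records from species-rank rows.

    A genus trait value is the value shared by all species in the genus,
    coded missing when species disagree.  Under the default ``ignore_missing``
    rule, agreement is evaluated over species with a non-missing value only
    (a missing species value neither supports nor breaks consensus); with
    ``ignore_missing=False`` any missing species value makes the genus value
    missing.  Binary traits, which cannot be missing, fall back to 0 on
    disagreement, consistent with the not-reported-means-0 convention.
    """
    species = table.data[table.data["rank"] == "species"]
    if species.empty:
        return TraitTable(table.data.iloc[0:0].copy(), table.schema)

    genera = species.index.map(genus_name)
    rows: dict[str, dict[str, object]] = {}
    for genus, grp in species.groupby(genera):
        row: dict[str, object] = {"rank": "genus"}
        for col in LINEAGE_COLUMNS:
            vals = grp[col][grp[col] != ""].unique()
            row[col] = vals[0] if len(vals) == 1 else ""
        row["family"] = row.get("family", "")
        for tdef in table.schema.traits:
            vals = grp[tdef.name]
            nonmiss = vals.dropna()
            if tdef.kind == "binary":
                uniq = set(int(v) for v in vals)
                row[tdef.name] = uniq.pop() if len(uniq) == 1 else 0
                continue
            if not ignore_missing and len(nonmiss) < len(vals):
                row[tdef.name] = np.nan
                continue
            uniq = set(nonmiss)
            row[tdef.name] = uniq.pop() if len(uniq) == 1 else np.nan
        rows[genus] = row

    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "taxon"
    out = out[["rank", *LINEAGE_COLUMNS, *table.trait_names]]
    for trait in table.schema.names(kind="binary"):
        out[trait] = out[trait].astype(int)
    for trait in table.schema.names(kind="continuous"):
        out[trait] = out[trait].astype(float)
    return TraitTable(out, table.schema)


@dataclass
class EncodedTraitMatrix:
    """Numeric taxa x expanded-trait matrix with missingness mask.

    Categorical traits with k levels expand to k one-hot 0/1 columns named
    ``trait=level``; continuous and binary traits pass through.  ``mask`` is
    True where the original value was missing; all dummies of a missing
    categorical value are jointly masked.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    expansion: dict[str, list[str]]
    schema: TraitSchema

    @property
    def taxa(self) -> pd.Index:
        return self.values.index

    @property
    def columns(self) -> pd.Index:
        return self.values.columns

    def column_trait(self, column: str) -> str:
        """Original trait a (possibly dummy) column belongs to."""
        for trait, cols in self.expansion.items():
            if column in cols:
                return trait
        raise KeyError(column)

    def collapse_categorical(self, trait: str) -> pd.Series:
        """Recover the categorical assignment from its dummy columns."""
        tdef = self.schema[trait]
        if tdef.kind != "categorical":
            raise ValueError(f"{trait!r} is not categorical")
        cols = self.expansion[trait]
        sub = self.values[cols]
        masked = self.mask[cols].any(axis=1)
        levels = [c.split("=", 1)[1] for c in cols]
        idx = np.nan_to_num(sub.to_numpy(dtype=float)).argmax(axis=1)
        out = pd.Series([levels[i] for i in idx], index=sub.index, dtype=object)
        out[masked] = np.nan
        return out

    def subset(self, taxa: Sequence[str]) -> "EncodedTraitMatrix":
        keep = [t for t in taxa if t in self.values.index]
        return EncodedTraitMatrix(
            self.values.loc[keep], self.mask.loc[keep], self.expansion, self.schema
        )


def encode_traits(table: TraitTable, schema: TraitSchema | None = None) -> EncodedTraitMatrix:
    """Expand a TraitTable to a numeric matrix with one-hot categorical dummies."""
    schema = schema or table.schema
    values: dict[str, pd.Series] = {}
    mask: dict[str, pd.Series] = {}
    expansion: dict[str, list[str]] = {}
    for tdef in schema.traits:
        col = table.data[tdef.name]
        if tdef.kind == "categorical":
            miss = col.isna()
            names = []
            for level in tdef.levels:
                name = f"{tdef.name}={level}"
                names.append(name)
                values[name] = (col == level).astype(float)
                mask[name] = miss
            expansion[tdef.name] = names
        else:
            values[tdef.name] = col.astype(float)
            mask[tdef.name] = col.isna()
            expansion[tdef.name] = [tdef.name]
    vdf = pd.DataFrame(values, index=table.data.index)
    mdf = pd.DataFrame(mask, index=table.data.index)
    vdf[mdf] = np.nan
    return EncodedTraitMatrix(vdf, mdf, expansion, schema)


def metabolic_breadth(table: TraitTable, schema: TraitSchema | None = None) -> pd.Series:
    """Number of carbon substrates each taxon is recorded to grow on."""
    schema = schema or table.schema
    substrates = schema.carbon_substrates
    if not substrates:
        return pd.Series(0, index=table.data.index, dtype=int)
    return table.data[substrates].astype(int).sum(axis=1).rename("metabolic_breadth")
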