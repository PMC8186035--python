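"""Abundance tables, sample metadata, and abundance-weighted trait profiles.

The central object is the trait profile: for every sample, the mean value of
each (expanded) trait over the resident, trait-annotated taxa, weighted by
relative abundance.  When a taxon is missing a trait value, the abundances of
the remaining taxa are renormalized so the mean is taken over known values
only.  Profiles can be restricted to one phylum ("phyla-samples") for
leave-one-phylum-out prediction.
"""

from __future__ import annotations

import bz2
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .trait_db import (
    EncodedTraitMatrix,
    TraitSchema,
    TraitTable,
    genus_name,
    normalize_taxon_id,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BODY_AREAS",
    "SampleMetadata",
    "AbundanceTable",
    "TraitProfileMatrix",
    "GeneralismLabels",
    "DiversityStats",
    "read_abundance",
    "match_taxa",
    "weighted_trait_profile",
    "generalism_labels",
    "sample_diversity",
    "substrate_overlap",
]

BODY_AREAS = ("gut", "vagina", "mouth", "skin", "airways")


@dataclass
class SampleMetadata:
    """Per-sample subject, body site and body area labels.

    Each body site maps to exactly one body area (e.g. stool -> gut,
    posterior fornix -> vagina, tongue dorsum -> mouth).
    """

    data: pd.DataFrame  # index sample_id; columns subject_id, body_site, body_area

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        site_area = self.data.groupby("body_site")["body_area"].nunique()
        bad = site_area[site_area > 1]
        if not bad.empty:
            raise ValueError(f"body sites mapping to multiple areas: {list(bad.index)}")

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    @property
    def sites(self) -> list[str]:
        return sorted(self.data["body_site"].unique())

    def site_of(self) -> pd.Series:
        return self.data["body_site"]

    def area_of(self) -> pd.Series:
        return self.data["body_area"]

    def samples_from_site(self, site: str) -> pd.Index:
        return self.data.index[self.data["body_site"] == site]

    def subset(self, samples: Sequence[str]) -> "SampleMetadata":
        keep = [s for s in samples if s in self.data.index]
        return SampleMetadata(self.data.loc[keep])

    def write(self, path: str | Path) -> None:
        self.data.reset_index(names="sample_id").to_csv(path, sep="\t", index=False)


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a taxon lineage string into rank names plus the terminal taxon.

    Accepts pipe- or semicolon-delimited rank lists, with or without
    greengenes-style ``p__`` prefixes.  The last field is the taxon name;
    ranks are assigned positionally as kingdom, phylum, class, order, family
    when unprefixed.
    """
    sep = "|" if "|" in lineage else ";"
    fields = [f.strip() for f in lineage.split(sep) if f.strip()]
    prefixes = {"k": "kingdom", "p": "phylum", "c": "class", "o": "order",
                "f": "family", "g": "genus", "s": "species"}
    out: dict[str, str] = {}
    plain: list[str] = []
    for f in fields:
        if len(f) > 3 and f[1:3] == "__" and f[0].lower() in prefixes:
            out[prefixes[f[0].lower()]] = f[3:].replace("_", " ")
        else:
            plain.append(f)
    if plain:
        ranks = ("kingdom", "phylum", "class", "order", "family")
        for rank, value in zip(ranks, plain[:-1]):
            out.setdefault(rank, value)
        out.setdefault("taxon", plain[-1])
    if "taxon" not in out:
        out["taxon"] = out.get("species") or fields[-1]
    return out


@dataclass
class AbundanceTable:
    """Relative abundances, taxa x samples, with per-taxon lineage fields."""

    abundances: pd.DataFrame  # index taxon_id (normalized), columns sample ids
    lineages: pd.DataFrame  # index taxon_id; columns phylum, class, order, family

    def __post_init__(self) -> None:
        if (self.abundances.to_numpy() < 0).any():
            raise ValueError("negative abundance entries")
        totals = self.abundances.sum(axis=0)
        if (totals > 1 + 1e-6).any():
            bad = totals[totals > 1 + 1e-6]
            raise ValueError(f"per-sample abundance totals exceed 1: {dict(bad.head())}")

    @property
    def taxa(self) -> pd.Index:
        return self.abundances.index

    @property
    def samples(self) -> pd.Index:
        return self.abundances.columns

    def phylum_of(self) -> pd.Series:
        return self.lineages["phylum"]

    def subset_samples(self, samples: Sequence[str]) -> "AbundanceTable":
        keep = [s for s in samples if s in self.abundances.columns]
        return AbundanceTable(self.abundances[keep], self.lineages)

    def subset_taxa(self, taxa: Sequence[str]) -> "AbundanceTable":
        keep = [t for t in taxa if t in self.abundances.index]
        return AbundanceTable(self.abundances.loc[keep], self.lineages.loc[keep])


def read_abundance(
    path: str | Path, metadata_path: str | Path
) -> tuple[AbundanceTable, SampleMetadata]:
    """Read an HMP-style abundance matrix and its sample metadata.

    The matrix is TSV (optionally bz2-compressed) with a lineage string in
    the first column and one numeric column per sample.  Samples without a
    metadata row are dropped with a logged count.
    """
    path = Path(path)
    opener = bz2.open if path.suffix == ".bz2" else open
    with opener(path, "rt") as fh:
        raw = pd.read_csv(fh, sep="\t", index_col=0, float_precision="round_trip")
    for col in raw.columns:
        if not pd.api.types.is_numeric_dtype(raw[col]):
            bad = raw[col][pd.to_numeric(raw[col], errors="coerce").isna()]
            where = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric abundance cell in sample {col!r}, row {where!r}"
            )

    parsed = [parse_lineage(str(ix)) for ix in raw.index]
    taxon_ids = [normalize_taxon_id(p["taxon"]) for p in parsed]
    lineages = pd.DataFrame(
        {
            rank: [p.get(rank, "") for p in parsed]
            for rank in ("phylum", "class", "order", "family")
        },
        index=taxon_ids,
    )
    ab = raw.copy()
    ab.index = pd.Index(taxon_ids, name="taxon")
    # collapse duplicate taxon rows (same terminal name from different lineages)
    if ab.index.has_duplicates:
        ab = ab.groupby(level=0).sum()
        lineages = lineages[~lineages.index.duplicated()]
        lineages = lineages.loc[ab.index]

    meta_df = pd.read_csv(metadata_path, sep="\t", dtype=str).set_index("sample_id")
    meta = SampleMetadata(meta_df)
    known = [s for s in ab.columns if s in meta.samples]
    dropped = len(ab.columns) - len(known)
    if dropped:
        logger.warning("dropped %d samples absent from metadata", dropped)
    meta = meta.subset(known)
    return AbundanceTable(ab[known], lineages), meta


@dataclass
class TaxonMatch:
    """Result of matching abundance-table taxa against the trait database."""

    matches: pd.DataFrame  # index abundance taxon; columns db_taxon, rank_used
    unmatched: list[str]

    @property
    def matched_taxa(self) -> pd.Index:
        return self.matches.index

    def db_taxon_of(self) -> pd.Series:
        return self.matches["db_taxon"]


def match_taxa(ab: AbundanceTable, db: TraitTable) -> TaxonMatch:
    """Match abundance taxa to trait-database records.

    Species-level matches are preferred; when absent, a genus-rank consensus
    record matching the taxon's genus is used; otherwise the taxon is
    reported unmatched.
    """
    species_ids = set(db.data.index[db.data["rank"] == "species"])
    genus_ids = set(db.data.index[db.data["rank"] == "genus"])
    rows = {}
    unmatched = []
    for taxon in ab.taxa:
        if taxon in species_ids:
            rows[taxon] = {"db_taxon": taxon, "rank_used": "species"}
            continue
        genus = genus_name(taxon)
        if genus in genus_ids:
            rows[taxon] = {"db_taxon": genus, "rank_used": "genus"}
        else:
            unmatched.append(taxon)
    matches = pd.DataFrame.from_dict(rows, orient="index")
    if matches.empty:
        matches = pd.DataFrame(columns=["db_taxon", "rank_used"])
    return TaxonMatch(matches, unmatched)


@dataclass
class TraitProfileMatrix:
    """Expanded traits x samples matrix of abundance-weighted mean trait values.

    ``support`` carries, per cell, the summed (unrenormalized) relative
    abundance of taxa that informed the mean; a cell is NaN when support is 0.
    """

    values: pd.DataFrame
    support: pd.DataFrame
    phylum: str | None = None
    empty_samples: list[str] = field(default_factory=list)

    @property
    def traits(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, samples: Sequence[str]) -> "TraitProfileMatrix":
        keep = [s for s in samples if s in self.values.columns]
        return TraitProfileMatrix(
            self.values[keep], self.support[keep], self.phylum,
            [s for s in self.empty_samples if s in keep],
        )


def weighted_trait_profile(
    ab: AbundanceTable,
    enc: EncodedTraitMatrix,
    match: TaxonMatch | None = None,
    db: TraitTable | None = None,
    restrict_phylum: str | None = None,
) -> TraitProfileMatrix:
    """Abundance-weighted mean trait values per sample.

    For expanded trait t and sample s the profile cell is sum_i w_i x_i(t)
    over matched taxa i with a non-missing value of t, where w_i are the
    taxa's relative abundances renormalized over exactly those taxa.  With
    ``restrict_phylum`` only taxa from that phylum contribute, yielding the
    per-phylum "phyla-sample" profiles.
    """
    if match is None:
        if db is None:
            raise ValueError("provide either a TaxonMatch or the TraitTable")
        match = match_taxa(ab, db)

    matched = [t for t in match.matched_taxa if t in ab.taxa]
    if restrict_phylum is not None:
        phyla = ab.phylum_of()
        matched = [t for t in matched if phyla.get(t, "") == restrict_phylum]

    db_ids = [match.matches.loc[t, "db_taxon"] for t in matched]
    X = enc.values.loc[db_ids].to_numpy(dtype=float)  # taxa x exp-traits
    known = ~enc.mask.loc[db_ids].to_numpy(dtype=bool)
    X = np.nan_to_num(X)
    W = ab.abundances.loc[matched].to_numpy(dtype=float)  # taxa x samples

    # support[t, s] = sum of abundances of taxa knowing trait t
    support = known.T @ W  # exp-traits x samples
    weighted = (X * known).T @ W
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(support > 0, weighted / np.where(support > 0, support, 1.0), np.nan)

    values = pd.DataFrame(profile, index=enc.columns, columns=ab.samples)
    supp = pd.DataFrame(support, index=enc.columns, columns=ab.samples)
    total_w = W.sum(axis=0) if len(matched) else np.zeros(len(ab.samples))
    empty = [s for s, tw in zip(ab.samples, total_w) if tw == 0]
    if empty:
        logger.warning(
            "%d samples with no matched taxa%s", len(empty),
            f" in phylum {restrict_phylum}" if restrict_phylum else "",
        )
    return TraitProfileMatrix(values, supp, restrict_phylum, empty)


@dataclass
class GeneralismLabels:
    """Habitat-breadth labels per taxon.

    A body area counts for a taxon when the taxon is present (abundance > 0)
    in at least ``min_appearances`` samples from that area.  Specialists
    qualify in exactly one area, generalists in two or more; taxa found in a
    single sample overall, or qualifying nowhere, are excluded.
    """

    data: pd.DataFrame  # index taxon; columns n_areas, n_samples_present, label

    @property
    def labels(self) -> pd.Series:
        return self.data["label"]

    def of(self, label: str) -> pd.Index:
        return self.data.index[self.data["label"] == label]


def generalism_labels(
    ab: AbundanceTable,
    meta: SampleMetadata,
    min_appearances: int = 2,
) -> GeneralismLabels:
    present = ab.abundances > 0
    areas = meta.area_of().reindex(ab.samples)
    per_area = present.T.groupby(areas).sum().T  # taxa x areas, counts
    qualifying = (per_area >= min_appearances).sum(axis=1)
    n_present = present.sum(axis=1)

    label = pd.Series("excluded", index=ab.taxa, dtype=object)
    label[(qualifying == 1)] = "specialist"
    label[(qualifying >= 2)] = "generalist"
    label[n_present <= 1] = "excluded"
    data = pd.DataFrame(
        {"n_areas": qualifying, "n_samples_present": n_present, "label": label}
    )
    return GeneralismLabels(data)


@dataclass
class DiversityStats:
    """Per-sample taxonomic and carbon-source Shannon diversity (nats)."""

    data: pd.DataFrame  # index sample; columns taxonomic_entropy,
    # carbon_entropy, carbon_richness


def shannon(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        return float("nan")
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def sample_diversity(
    ab: AbundanceTable,
    db: TraitTable,
    schema: TraitSchema | None = None,
    match: TaxonMatch | None = None,
    allocation: str = "equal",
) -> DiversityStats:
    """Taxonomic and carbon-source diversity per sample.

    Taxonomic entropy is the Shannon entropy of renormalized abundances of
    matched taxa.  The carbon-source distribution allocates each taxon's
    abundance over the substrates it uses — split equally (``allocation=
    'equal'``, default) or full weight to every substrate then renormalized
    (``allocation='full'``) — and sums over taxa.  Samples with no substrate
    users get NaN carbon entropy.
    """
    schema = schema or db.schema
    if match is None:
        match = match_taxa(ab, db)
    substrates = schema.carbon_substrates
    matched = [t for t in match.matched_taxa if t in ab.taxa]
    db_ids = [match.matches.loc[t, "db_taxon"] for t in matched]
    usage = db.data.loc[db_ids, substrates].to_numpy(dtype=float)  # taxa x subs
    W = ab.abundances.loc[matched].to_numpy(dtype=float)  # taxa x samples

    n_subs_per_taxon = usage.sum(axis=1)
    if allocation == "equal":
        alloc = np.divide(
            usage, np.where(n_subs_per_taxon > 0, n_subs_per_taxon, 1)[:, None]
        )
    elif allocation == "full":
        alloc = usage
    else:
        raise ValueError(f"unknown allocation rule {allocation!r}")

    carbon_mass = alloc.T @ W  # substrates x samples
    rows = {}
    for j, s in enumerate(ab.samples):
        w = W[:, j]
        tax_ent = shannon(w) if w.sum() > 0 else float("nan")
        cm = carbon_mass[:, j]
        carb_ent = shannon(cm) if cm.sum() > 0 else float("nan")
        rows[s] = {
            "taxonomic_entropy": tax_ent,
            "carbon_entropy": carb_ent,
            "carbon_richness": int((cm > 0).sum()),
        }
    return DiversityStats(pd.DataFrame.from_dict(rows, orient="index"))


def substrate_overlap(
    db: TraitTable,
    taxa: Sequence[str],
    schema: TraitSchema | None = None,
) -> tuple[pd.Series, float]:
    """Distribution of pairwise shared-substrate counts among ``taxa``.

    Returns the per-pair counts (index "a|b") and their mean; empty when
    fewer than two of the taxa are in the database.
    """
    schema = schema or db.schema
    substrates = schema.carbon_substrates
    keep = [t for t in taxa if t in db.data.index]
    if len(keep) < 2:
        return pd.Series(dtype=int), float("nan")
    U = db.data.loc[keep, substrates].to_numpy(dtype=int)
    shared = U @ U.T
    counts = {}
    for i in range(len(keep)):
        for j in range(i + 1, len(keep)):
            counts[f"{keep[i]}|{keep[j]}"] = int(shared[i, j])
    ser = pd.Series(counts, dtype=int)
    return ser, float(ser.mean())
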