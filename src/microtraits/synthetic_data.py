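"""Synthetic worlds with known ground truth for every pipeline stage.

A world emulates the three inputs the pipeline consumes — a curated trait
database, an abundance matrix with sample metadata, and per-phylum
phylogenies — with planted structure that downstream analyses should
recover:

* continuous traits drawn from a multivariate normal whose precision matrix
  is block-diagonal (the blocks are the "true" trait suites);
* binary traits evolved on the phylum trees through a distance-decaying
  Gaussian copula, so they carry phylogenetic signal;
* categorical traits drawn from per-phylum multinomials;
* per-sample abundances from site-specific Dirichlet draws whose
  concentrations favor taxa whose trait values match the site's planted
  effect;
* habitat generalists planted by giving a subset of taxa home ranges
  spanning two or more body areas (optionally tied to a designated binary
  trait), plus a small presence "leak" that creates the single-sample
  noise the generalism filter is meant to remove;
* optionally, carbon-substrate usage driven by a continuous trait so that
  metabolic breadth is predictable from it.

Everything is deterministic given the config seed, and the emitted files
re-parse (through the package's own readers) to the in-memory truth.
"""

from __future__ import annotations

import bz2 as bz2lib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .community_profiles import SampleMetadata, AbundanceTable
from .phylo_logit import Phylogeny, read_newick, simulate_binary_on_tree
from .trait_db import TraitDef, TraitSchema, TraitTable

__all__ = ["WorldConfig", "SyntheticWorld", "simulate_world", "write_world"]

DEFAULT_SITES = {
    "stool": "gut",
    "posterior_fornix": "vagina",
    "buccal_mucosa": "mouth",
    "supragingival_plaque": "mouth",
    "tongue_dorsum": "mouth",
    "anterior_nares": "airways",
    "retroauricular_crease": "skin",
}


@dataclass
class WorldConfig:
    """Generator settings; defaults give a desk-scale but fully featured world."""

    seed: int = 0
    n_phyla: int = 4
    classes_per_phylum: int = 3
    families_per_class: int = 2
    taxa_per_phylum: int = 75
    n_subjects: int = 40
    sites: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SITES))
    site_visit_prob: float = 0.8  # chance a subject is sampled at a site
    repeat_visit_prob: float = 0.15  # chance of a second sample (same subject+site)
    n_continuous: int = 12  # divisible by n_trait_blocks
    n_trait_blocks: int = 4
    block_partial_corr: float = 0.35
    n_categorical: int = 5
    categorical_levels: int = 3
    n_binary: int = 45
    n_carbon: int = 30  # leading n_carbon binary traits are carbon substrates
    binary_alpha_phy: float = 1.0  # copula decay rate on tree distance
    missing_rate: float = 0.10  # continuous & categorical only
    generalist_fraction: float = 0.30
    generalism_trait: str | None = None  # binary trait that forces generalism
    breadth_driver: str | None = None  # continuous trait driving substrate use
    breadth_slope: float = 2.0
    effect_size: float = 2.0  # planted site-trait effect, SD units
    n_effect_sites: int = 4  # sites that get one planted trait effect each
    auto_effects: bool = True
    effects: dict | None = None  # {(site, trait): effect}; overrides auto
    site_neutral: bool = False  # composition carries no site signal: every
    # taxon ranges over all areas and there are no noise occurrences; combine
    # with auto_effects=False / effects={} for a global null world, or with
    # explicit effects so a planted trait is the only site signal
    presence_prob: float = 0.6  # chance a home-area taxon occurs in a sample
    leak_prob: float = 0.002  # chance of an out-of-range (noise) occurrence
    dirichlet_theta: float = 0.8  # concentration multiplier
    genus_only_fraction: float = 0.08  # abundance taxa matchable only at genus

    def phylum_names(self) -> list[str]:
        return [f"phylum {i + 1}" for i in range(self.n_phyla)]


@dataclass
class SyntheticWorld:
    """A generated world plus the ground-truth ledger that scores recovery."""

    config: WorldConfig
    schema: TraitSchema
    trait_table: TraitTable
    abundance: AbundanceTable
    metadata: SampleMetadata
    trees: dict[str, Phylogeny]  # phylum -> tree over its species tips
    newicks: dict[str, str]
    truth: dict


def _make_schema(cfg: WorldConfig) -> TraitSchema:
    defs: list[TraitDef] = []
    for i in range(cfg.n_continuous):
        defs.append(
            TraitDef(f"cont trait {i + 1:02d}", "continuous",
                     "genomic" if i == 0 else "growth_condition", units="au")
        )
    levels = tuple(f"level{j + 1}" for j in range(cfg.categorical_levels))
    for i in range(cfg.n_categorical):
        defs.append(
            TraitDef(f"cat trait {i + 1:02d}", "categorical", "morphology",
                     levels=levels)
        )
    for i in range(cfg.n_binary):
        cat = "carbon_substrate" if i < cfg.n_carbon else "enzyme_assay"
        defs.append(TraitDef(f"bin trait {i + 1:02d}", "binary", cat))
    return TraitSchema(tuple(defs))


def _make_taxonomy(cfg: WorldConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign taxa to phylum/class/family/genus; index is the taxon id."""
    rows = {}
    for p, phylum in enumerate(cfg.phylum_names()):
        classes = [f"p{p + 1}c{c + 1}" for c in range(cfg.classes_per_phylum)]
        for t in range(cfg.taxa_per_phylum):
            cls = classes[t % len(classes)]
            fam_i = (t // len(classes)) % cfg.families_per_class
            family = f"{cls}f{fam_i + 1}"
            genus = f"{family}g{t % 3 + 1}"
            taxon = f"{genus} sp{t + 1}"
            rows[taxon] = {
                "rank": "species", "phylum": phylum, "class": cls,
                "order": f"{cls} ord", "family": family, "genus": genus,
            }
    return pd.DataFrame.from_dict(rows, orient="index")


def _build_newick(cfg: WorldConfig, taxonomy: pd.DataFrame, phylum: str,
                  rng: np.random.Generator) -> str:
    """Random clade-structured newick: families within classes within the root.

    Within a family, tips join a caterpillar with exponential branch lengths;
    internal nodes carry class=/family= labels so the reader can annotate
    tips.  The clade nesting guarantees classes and families are monophyletic.
    """

    def bl() -> float:
        return float(np.round(rng.exponential(0.3) + 0.02, 6))

    def join(children: list[str], label: str = "") -> str:
        qlabel = f"'{label}'" if label else ""
        while len(children) > 2:
            a = children.pop(int(rng.integers(len(children))))
            b = children.pop(int(rng.integers(len(children))))
            children.append(f"({a}:{bl()},{b}:{bl()})")
        if len(children) == 1:
            return children[0] if not label else f"({children[0]}:{bl()}){qlabel}"
        return f"({children[0]}:{bl()},{children[1]}:{bl()}){qlabel}"

    sub = taxonomy[(taxonomy["phylum"] == phylum)]
    class_trees = []
    for cls, cgrp in sub.groupby("class", sort=True):
        fam_trees = []
        for fam, fgrp in cgrp.groupby("family", sort=True):
            tips = [t.replace(" ", "_") for t in sorted(fgrp.index)]
            fam_trees.append(join(list(tips), f"family={fam}"))
        class_trees.append(join(fam_trees, f"class={cls}"))
    return join(class_trees) + ";"


def _planted_effects(cfg: WorldConfig, schema: TraitSchema,
                     rng: np.random.Generator) -> dict[tuple[str, str], float]:
    if cfg.effects is not None:
        return {tuple(k) if not isinstance(k, tuple) else k: float(v)
                for k, v in cfg.effects.items()}
    if not cfg.auto_effects:
        return {}
    sites = sorted(cfg.sites)[: cfg.n_effect_sites]
    # one continuous trait per precision block: effect traits are mutually
    # uncorrelated, so each planted site signature is identifiable, and
    # continuous traits (drawn iid over taxa) carry no phylogenetic
    # confounding that would shift per-phylum profile baselines
    cont = schema.names(kind="continuous")
    block = max(1, cfg.n_continuous // cfg.n_trait_blocks)
    candidates = [cont[i] for i in range(0, len(cont), block)]
    while len(candidates) < len(sites):  # more effect sites than blocks
        candidates += [t for t in cont if t not in candidates]
    return {
        (site, candidates[i]): cfg.effect_size for i, site in enumerate(sites)
    }


def simulate_world(config: WorldConfig | None = None, seed: int | None = None) -> SyntheticWorld:
    """Generate a complete synthetic world; deterministic given the seed."""
    cfg = config or WorldConfig()
    if seed is not None:
        cfg = WorldConfig(**{**asdict(cfg), "seed": seed})
    if cfg.n_trait_blocks > cfg.n_continuous:
        raise ValueError("more precision blocks than continuous traits")
    if cfg.n_carbon > cfg.n_binary:
        raise ValueError("more carbon substrates than binary traits")
    if len(set(cfg.sites.values())) < 2:
        raise ValueError("need sites from at least 2 body areas")

    rng = np.random.default_rng(cfg.seed)
    schema = _make_schema(cfg)
    taxonomy = _make_taxonomy(cfg, rng)
    taxa = list(taxonomy.index)
    n_taxa = len(taxa)

    # --- phylogenies -------------------------------------------------------
    newicks: dict[str, str] = {}
    trees: dict[str, Phylogeny] = {}
    import os
    import tempfile

    for phylum in cfg.phylum_names():
        nwk = _build_newick(cfg, taxonomy, phylum, rng)
        newicks[phylum] = nwk
        with tempfile.NamedTemporaryFile("w", suffix=".nwk", delete=False) as fh:
            fh.write(nwk)
            tmp = fh.name
        trees[phylum] = read_newick(tmp)
        os.unlink(tmp)

    # --- continuous traits: block-structured MVN ---------------------------
    cont_names = schema.names(kind="continuous")
    block_size = cfg.n_continuous // cfg.n_trait_blocks
    blocks = {
        name: i // block_size if i // block_size < cfg.n_trait_blocks
        else cfg.n_trait_blocks - 1
        for i, name in enumerate(cont_names)
    }
    precision = np.eye(cfg.n_continuous)
    for i in range(cfg.n_continuous):
        for j in range(i + 1, cfg.n_continuous):
            if blocks[cont_names[i]] == blocks[cont_names[j]]:
                precision[i, j] = precision[j, i] = -cfg.block_partial_corr
    # guarantee positive definiteness
    w, _ = np.linalg.eigh(precision)
    if w.min() <= 1e-6:
        precision += (1e-6 - w.min() + 0.05) * np.eye(cfg.n_continuous)
    cov = np.linalg.inv(precision)
    cont_values = rng.multivariate_normal(
        np.zeros(cfg.n_continuous), cov, size=n_taxa, method="cholesky"
    )
    cont = pd.DataFrame(cont_values, index=taxa, columns=cont_names)

    # --- binary traits evolved on the trees --------------------------------
    bin_names = schema.names(kind="binary")
    binary = pd.DataFrame(0, index=taxa, columns=bin_names, dtype=int)
    trait_prevalence = rng.uniform(0.25, 0.75, size=len(bin_names))
    for phylum, tree in trees.items():
        tip_order = tree.tips
        zeros = pd.Series(0.0, index=tip_order)
        for t_i, name in enumerate(bin_names):
            beta0 = float(np.log(trait_prevalence[t_i] / (1 - trait_prevalence[t_i])))
            y = simulate_binary_on_tree(
                tree, beta0, 0.0, zeros, cfg.binary_alpha_phy,
                seed=int(rng.integers(2**31 - 1)),
            )
            binary.loc[tip_order, name] = y.astype(int)

    # --- optionally drive carbon-substrate use from a continuous trait -----
    carbon_names = schema.carbon_substrates
    if cfg.breadth_driver is not None:
        driver = cont[cfg.breadth_driver]
        z = (driver - driver.mean()) / driver.std(ddof=0)
        from scipy.special import expit

        p_use = expit(cfg.breadth_slope * z.to_numpy())[:, None]
        binary.loc[:, carbon_names] = (
            rng.random((n_taxa, len(carbon_names))) < p_use
        ).astype(int)

    # --- categorical traits: per-phylum multinomials ------------------------
    cat_names = schema.names(kind="categorical")
    levels = schema[cat_names[0]].levels if cat_names else ()
    cat = pd.DataFrame(index=taxa, columns=cat_names, dtype=object)
    for phylum in cfg.phylum_names():
        members = taxonomy.index[taxonomy["phylum"] == phylum]
        for name in cat_names:
            probs = rng.dirichlet(np.ones(len(levels)) * 2.0)
            draws = rng.choice(len(levels), size=len(members), p=probs)
            cat.loc[members, name] = [levels[d] for d in draws]

    # --- missingness (never on binary traits) ------------------------------
    for name in cont_names:
        mask = rng.random(n_taxa) < cfg.missing_rate
        cont.loc[mask, name] = np.nan
    for name in cat_names:
        mask = rng.random(n_taxa) < cfg.missing_rate
        cat.loc[mask, name] = np.nan

    table_df = pd.concat(
        [taxonomy[["rank", "phylum", "class", "order", "family"]],
         cont, cat, binary],
        axis=1,
    )
    table_df.index.name = "taxon"
    trait_table = TraitTable(table_df, schema)

    # --- home areas and generalists ----------------------------------------
    areas = sorted(set(cfg.sites.values()))
    if cfg.site_neutral:
        cfg = WorldConfig(**{**asdict(cfg), "leak_prob": 0.0})
    if cfg.generalism_trait is not None:
        is_generalist = binary[cfg.generalism_trait].astype(bool).to_numpy()
    else:
        is_generalist = rng.random(n_taxa) < cfg.generalist_fraction
    home: dict[str, list[str]] = {}
    for i, taxon in enumerate(taxa):
        if cfg.site_neutral:
            home[taxon] = list(areas)
        elif is_generalist[i]:
            k = int(rng.integers(2, len(areas) + 1))
            home[taxon] = sorted(
                rng.choice(areas, size=k, replace=False).tolist()
            )
        else:
            home[taxon] = [str(rng.choice(areas))]

    # --- samples and metadata ----------------------------------------------
    site_list = sorted(cfg.sites)
    meta_rows = {}
    for s in range(cfg.n_subjects):
        subject = f"subj{s + 1:03d}"
        for site in site_list:
            if rng.random() >= cfg.site_visit_prob:
                continue
            n_rep = 2 if rng.random() < cfg.repeat_visit_prob else 1
            for r in range(n_rep):
                sid = f"{subject}.{site}.{r + 1}"
                meta_rows[sid] = {
                    "subject_id": subject,
                    "body_site": site,
                    "body_area": cfg.sites[site],
                }
    meta_df = pd.DataFrame.from_dict(meta_rows, orient="index")
    meta_df.index.name = "sample_id"
    metadata = SampleMetadata(meta_df)

    # --- planted site-trait effects and abundances -------------------------
    effects = _planted_effects(cfg, schema, rng)
    # encoded z-scores of the effect traits (binary as +-, continuous scaled)
    zscores: dict[str, np.ndarray] = {}
    for (_, trait) in effects:
        if trait in zscores:
            continue
        if trait in binary.columns:
            v = binary[trait].to_numpy(dtype=float)
        else:
            v = np.nan_to_num(cont[trait].to_numpy(dtype=float))
        sd = v.std() or 1.0
        zscores[trait] = (v - v.mean()) / sd

    home_mask = pd.DataFrame(
        {a: [a in home[t] for t in taxa] for a in areas}, index=taxa
    )
    ab = np.zeros((n_taxa, len(meta_df)))
    sample_ids = list(meta_df.index)
    for j, sid in enumerate(sample_ids):
        site = meta_df.loc[sid, "body_site"]
        area = meta_df.loc[sid, "body_area"]
        in_home = home_mask[area].to_numpy()
        present = np.where(
            in_home,
            rng.random(n_taxa) < cfg.presence_prob,
            rng.random(n_taxa) < cfg.leak_prob,
        )
        if not present.any():
            present[int(rng.integers(n_taxa))] = True
        conc = np.full(n_taxa, cfg.dirichlet_theta)
        log_boost = np.zeros(n_taxa)
        for (e_site, trait), size in effects.items():
            if e_site == site:
                log_boost += size * zscores[trait]
        conc = conc * np.exp(np.clip(log_boost, -6, 6))
        draw = rng.gamma(conc[present], 1.0)
        if draw.sum() <= 0:
            draw = np.ones(present.sum())
        ab[present, j] = draw / draw.sum()

    # a slice of abundance taxa is reported at genus level only
    display_names = {}
    n_genus_only = int(round(cfg.genus_only_fraction * n_taxa))
    genus_only = set(
        rng.choice(n_taxa, size=n_genus_only, replace=False).tolist()
    )
    for i, taxon in enumerate(taxa):
        if i in genus_only:
            display_names[taxon] = f"{taxonomy.loc[taxon, 'genus']} unclassified{i}"
        else:
            display_names[taxon] = taxon

    ab_index = [display_names[t] for t in taxa]
    lineages = pd.DataFrame(
        {
            "phylum": taxonomy["phylum"].to_numpy(),
            "class": taxonomy["class"].to_numpy(),
            "order": taxonomy["order"].to_numpy(),
            "family": taxonomy["family"].to_numpy(),
        },
        index=ab_index,
    )
    abundance = AbundanceTable(
        pd.DataFrame(ab, index=pd.Index(ab_index, name="taxon"),
                     columns=sample_ids),
        lineages,
    )

    truth = {
        "seed": cfg.seed,
        "site_trait_effects": {f"{s}|{t}": e for (s, t), e in effects.items()},
        "trait_blocks": blocks,
        "home_areas": home,
        "planted_generalists": sorted(
            t for i, t in enumerate(taxa) if is_generalist[i]
        ),
        "generalism_trait": cfg.generalism_trait,
        "breadth_driver": cfg.breadth_driver,
        "genus_only_taxa": sorted(
            display_names[taxa[i]] for i in genus_only
        ),
        "n_taxa": n_taxa,
        "n_samples": len(sample_ids),
    }
    return SyntheticWorld(cfg, schema, trait_table, abundance, metadata,
                          trees, newicks, truth)


def write_world(world: SyntheticWorld, directory: str | Path,
                bz2: bool = False) -> dict[str, Path]:
    """Write the world in exactly the dialects the package readers consume."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["schema"] = directory / "trait_schema.tsv"
    world.schema.write(paths["schema"])
    paths["traits"] = directory / "trait_table.tsv"
    world.trait_table.write(paths["traits"])
    paths["metadata"] = directory / "sample_metadata.tsv"
    world.metadata.write(paths["metadata"])

    # abundance with lineage strings in the first column
    lin = world.abundance.lineages
    lineage_strings = [
        "|".join(
            ["Bacteria", lin.loc[t, "phylum"], lin.loc[t, "class"],
             lin.loc[t, "order"], lin.loc[t, "family"], t]
        )
        for t in world.abundance.taxa
    ]
    ab_out = world.abundance.abundances.copy()
    ab_out.index = pd.Index(lineage_strings, name="lineage")
    name = "abundance.tsv.bz2" if bz2 else "abundance.tsv"
    paths["abundance"] = directory / name
    text = ab_out.to_csv(sep="\t")
    if bz2:
        with bz2lib.open(paths["abundance"], "wt") as fh:
            fh.write(text)
    else:
        paths["abundance"].write_text(text)

    for phylum, nwk in world.newicks.items():
        key = f"tree_{phylum.replace(' ', '_')}"
        paths[key] = directory / f"{key}.nwk"
        paths[key].write_text(nwk + "\n")

    paths["truth"] = directory / "ground_truth.json"
    paths["truth"].write_text(json.dumps(world.truth, indent=2, sort_keys=True))
    return paths
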