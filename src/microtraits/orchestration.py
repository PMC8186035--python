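"""End-to-end study pipelines and their configuration.

Three pipelines mirror the study design:

* ``run_site_analysis`` — abundance-weighted trait profiles, per-phylum
  permutation contrasts between body sites with the >=2-phyla replication
  filter, leave-one-phylum-out random-forest site classifiers, and the trait
  network (graphical lasso -> spin-glass clusters -> bipartite cluster-site
  graph).
* ``run_generalism_analysis`` — generalist/specialist labeling, within- and
  cross-phylum blocked random forests, top-trait selection, and phylogenetic
  logistic regression with BH correction over all phylum x trait tests.
* ``run_metabolism_analysis`` — per-sample taxonomic and carbon-source
  diversity, per-taxon metabolic breadth, blocked random-forest regression
  of breadth on the non-substrate traits, and per-site substrate overlap.

Every stochastic stage derives its seed from the master seed; the config is
serialized into each output directory so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import blocked_learn, community_profiles, phylo_logit, site_contrasts
from . import trait_db, trait_network
from .blocked_learn import FoldSpec, LearnConfig
from .community_profiles import AbundanceTable, SampleMetadata
from .phylo_logit import Phylogeny
from .trait_db import TraitSchema, TraitTable

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineData", "run_site_analysis",
           "run_generalism_analysis", "run_metabolism_analysis", "CI_PROFILE"]


@dataclass
class RunConfig:
    """All pipeline knobs in one place.

    Defaults mirror the analysis conventions: 10,000 permutations,
    BH alpha 0.05, 5000-tree forests, 10,000 bootstrap replicates, 10-fold
    lasso CV, sites with >= 10 subjects, replication in >= 2 phyla and the
    >= 2-appearances-per-area generalism rule.
    """

    seed: int = 0
    n_perm: int = 10_000
    alpha: float = 0.05
    min_phyla: int = 2
    min_subjects_per_site: int = 10
    n_trees: int = 5000
    gamma_ebic: float = 0.5
    n_lambda: int = 100
    spin_glass_gamma: float = 1.0
    lasso_cv_folds: int = 10
    nboot: int = 10_000
    min_appearances: int = 2
    top_k_traits: int = 5
    focal_phyla: list[str] | None = None  # None = phyla with >= 50 matched taxa
    min_focal_taxa: int = 50
    singleton_filter: bool = True
    importance_repeats: int = 5

    def stage_seed(self, stage: str) -> int:
        h = zlib.crc32(stage.encode()) % (2**16)
        return int(np.random.default_rng([self.seed, h]).integers(2**31 - 1))

    def learn_config(self, stage: str) -> LearnConfig:
        return LearnConfig(
            n_trees=self.n_trees,
            seed=self.stage_seed(stage),
            importance_repeats=self.importance_repeats,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**(yaml.safe_load(text) or {}))


#: reduced settings for fast, repeated runs
CI_PROFILE = dict(n_perm=1000, n_trees=500, nboot=500, n_lambda=30,
                  importance_repeats=1)


@dataclass
class PipelineData:
    """Validated inputs shared by all pipelines."""

    schema: TraitSchema
    db: TraitTable  # species + genus-consensus rows
    abundance: AbundanceTable
    metadata: SampleMetadata
    trees: Mapping[str, Phylogeny] = field(default_factory=dict)

    @classmethod
    def load(cls, trait_path, schema_path, abundance_path, metadata_path,
             tree_paths: Mapping[str, str] | None = None) -> "PipelineData":
        schema = trait_db.read_trait_schema(schema_path)
        table = trait_db.read_trait_table(trait_path, schema)
        species = TraitTable(table.data[table.data["rank"] == "species"], schema)
        genus = trait_db.genus_consensus(species)
        merged = TraitTable(
            pd.concat([species.data, genus.data.loc[
                [g for g in genus.data.index if g not in species.data.index]
            ]]),
            schema,
        )
        ab, meta = community_profiles.read_abundance(abundance_path, metadata_path)
        trees = {
            phylum: phylo_logit.read_newick(p)
            for phylum, p in (tree_paths or {}).items()
        }
        return cls(schema, merged, ab, meta, trees)

    def focal_phyla(self, config: RunConfig) -> list[str]:
        if config.focal_phyla is not None:
            return list(config.focal_phyla)
        match = community_profiles.match_taxa(self.abundance, self.db)
        phyla = self.abundance.phylum_of().loc[match.matched_taxa]
        counts = phyla.value_counts()
        return sorted(counts.index[counts >= config.min_focal_taxa])


def _write(df: pd.DataFrame, out_dir: Path, name: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_dir / name, sep="\t", index=False)


def _finish(out_dir: Path | None, config: RunConfig, outputs: dict) -> dict:
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "config.yaml").write_text(config.to_yaml())
    return outputs


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.time()


def run_site_analysis(data: PipelineData, config: RunConfig | None = None,
                      out_dir: str | Path | None = None) -> dict:
    """Profiles -> per-phylum contrasts -> site classifiers -> trait network."""
    config = config or RunConfig()
    out = Path(out_dir) if out_dir is not None else None
    match = community_profiles.match_taxa(data.abundance, data.db)
    enc = trait_db.encode_traits(data.db)
    focal = data.focal_phyla(config)

    # one sample per subject x site
    t0 = _stage("dedup+profiles")
    keep = site_contrasts.subsample_one_per_subject(
        data.metadata, config.stage_seed("dedup")
    )
    ab = data.abundance.subset_samples(keep)
    meta = data.metadata.subset(keep)

    profiles_all = community_profiles.weighted_trait_profile(ab, enc, match)
    per_phylum_profiles = {
        ph: community_profiles.weighted_trait_profile(
            ab, enc, match, restrict_phylum=ph
        )
        for ph in focal
    }

    t0 = _stage("contrasts")
    contrast_seed = config.stage_seed("contrasts")
    per_phylum = {
        ph: site_contrasts.all_site_contrasts(
            prof, meta, n_perm=config.n_perm, seed=contrast_seed + i,
            alpha=config.alpha,
        )
        for i, (ph, prof) in enumerate(per_phylum_profiles.items())
    }
    pooled = site_contrasts.all_site_contrasts(
        profiles_all, meta, n_perm=config.n_perm,
        seed=contrast_seed - 1, alpha=config.alpha,
    )
    replicated = site_contrasts.replicate_across_phyla(
        per_phylum, alpha=config.alpha, min_phyla=config.min_phyla
    )

    t0 = _stage("site classifiers")
    site_metrics, site_importances = _site_classifiers(
        data, config, per_phylum_profiles, meta
    )

    t0 = _stage("trait network")
    net = trait_network.fit_glasso_ebic(
        profiles_all, gamma_ebic=config.gamma_ebic, n_lambda=config.n_lambda
    )
    clusters = trait_network.spin_glass_communities(
        net, gamma_sg=config.spin_glass_gamma, seed=config.stage_seed("spinglass")
    )
    bipartite = trait_network.site_cluster_network(
        profiles_all, meta, clusters, cv_folds=config.lasso_cv_folds,
        seed=config.stage_seed("lasso"),
    )

    outputs = {
        "profiles": profiles_all,
        "per_phylum_profiles": per_phylum_profiles,
        "contrasts_per_phylum": per_phylum,
        "contrasts_pooled": pooled,
        "replicated": replicated,
        "site_metrics": site_metrics,
        "site_importances": site_importances,
        "network": net,
        "clusters": clusters,
        "bipartite": bipartite,
    }
    if out is not None:
        frames = [
            site_contrasts.contrasts_to_frame(res, ph)
            for ph, res in per_phylum.items()
        ] + [site_contrasts.contrasts_to_frame(pooled, "all")]
        _write(pd.concat(frames, ignore_index=True), out, "contrasts.tsv")
        _write(
            pd.DataFrame(
                [
                    {"trait": r.trait, "siteA": r.site_a, "siteB": r.site_b,
                     "phyla": ",".join(r.phyla), "sign": r.consensus_sign,
                     "conflict": r.sign_conflict}
                    for r in replicated
                ],
                columns=["trait", "siteA", "siteB", "phyla", "sign", "conflict"],
            ),
            out, "replicated_contrasts.tsv",
        )
        _write(site_metrics.reset_index(names="site"), out, "site_kappa.tsv")
        _write(net.edges(), out, "trait_network_edges.tsv")
        _write(clusters.to_frame(), out, "trait_clusters.tsv")
        _write(bipartite.edges, out, "cluster_site_network.tsv")
        import networkx as nx

        nx.write_graphml(net.to_networkx(), out / "trait_network.graphml")
        nx.write_graphml(bipartite.to_networkx(), out / "cluster_site.graphml")
    return _finish(out, config, outputs)


def _site_classifiers(data: PipelineData, config: RunConfig,
                      per_phylum_profiles: Mapping[str, object],
                      meta: SampleMetadata) -> tuple[pd.DataFrame, dict]:
    """One-vs-rest site classifiers on phyla-samples with phylum folds."""
    # assemble phyla-sample feature rows: unit = (phylum, sample)
    rows = []
    for ph, prof in per_phylum_profiles.items():
        df = prof.values.T  # samples x traits
        df = df.loc[[s for s in df.index if s not in prof.empty_samples]]
        df = df.fillna(df.mean())
        df = df.fillna(0.0)
        df.index = [f"{ph}::{s}" for s in df.index]
        rows.append(df)
    features = pd.concat(rows).dropna(axis=1, how="any")
    unit_phylum = pd.Series(
        [u.split("::")[0] for u in features.index], index=features.index
    )
    unit_sample = pd.Series(
        [u.split("::")[1] for u in features.index], index=features.index
    )
    site_of = meta.site_of()
    unit_site = unit_sample.map(site_of)

    subj_counts = meta.data.groupby("body_site")["subject_id"].nunique()
    eligible = sorted(subj_counts.index[subj_counts >= config.min_subjects_per_site])
    mouth_sites = sorted(
        meta.data.loc[meta.data["body_area"] == "mouth", "body_site"].unique()
    )

    folds = FoldSpec(
        {
            ph: tuple(features.index[unit_phylum == ph])
            for ph in sorted(unit_phylum.unique())
        },
        "phylum",
    )
    tasks: dict[str, pd.Series] = {
        site: (unit_site == site).astype(int) for site in eligible
    }
    if len(mouth_sites) > 1:
        tasks["mouth (all)"] = unit_site.isin(mouth_sites).astype(int)

    metric_rows = {}
    importances = {}
    lc = config.learn_config("site-classify")
    for task, labels in tasks.items():
        if labels.nunique() < 2:
            continue
        preds, metrics, imp = blocked_learn.blocked_classify(
            features, labels, folds, lc
        )
        row = {"mean_kappa": metrics.mean_kappa, "mean_auprc": metrics.mean_auprc,
               "pooled_kappa": metrics.pooled_kappa}
        for fold_id, r in metrics.per_fold.iterrows():
            row[f"kappa[{fold_id}]"] = r["kappa"]
        metric_rows[task] = row
        importances[task] = imp
    return pd.DataFrame.from_dict(metric_rows, orient="index"), importances


def run_generalism_analysis(data: PipelineData,
                            config: RunConfig | None = None,
                            out_dir: str | Path | None = None) -> dict:
    """Blocked generalism classifiers plus phylogenetic logistic regression."""
    config = config or RunConfig()
    out = Path(out_dir) if out_dir is not None else None
    match = community_profiles.match_taxa(data.abundance, data.db)
    labels_all = community_profiles.generalism_labels(
        data.abundance, data.metadata, min_appearances=config.min_appearances
    )
    if not config.singleton_filter:
        # degradation check: keep single-occurrence taxa, one area counted
        # per single appearance
        present = data.abundance.abundances > 0
        areas = data.metadata.area_of().reindex(data.abundance.samples)
        per_area = (present.T.groupby(areas).sum().T >= 1).sum(axis=1)
        lab = pd.Series("excluded", index=data.abundance.taxa, dtype=object)
        lab[per_area == 1] = "specialist"
        lab[per_area >= 2] = "generalist"
        labels_all = community_profiles.GeneralismLabels(
            pd.DataFrame({"n_areas": per_area,
                          "n_samples_present": present.sum(axis=1),
                          "label": lab})
        )

    usable = labels_all.data[labels_all.data["label"] != "excluded"]
    matched = match.matches.loc[
        [t for t in usable.index if t in match.matches.index]
    ]
    db_ids = matched["db_taxon"]
    y = (usable.loc[matched.index, "label"] == "generalist").astype(int)
    y.index = db_ids.to_numpy()
    y = y[~y.index.duplicated()]

    enc = trait_db.encode_traits(data.db)
    features = blocked_learn.mean_impute(
        enc.values.loc[[t for t in y.index if t in enc.values.index]]
    )
    y = y.loc[features.index]
    lineage = data.db.data[["phylum", "class", "family"]]

    focal = data.focal_phyla(config)
    phylum_of = lineage["phylum"]
    lc = config.learn_config("generalism")

    results: dict[str, object] = {"labels": labels_all}
    metric_rows = {}
    importances: dict[str, pd.DataFrame] = {}

    # cross-phylum: phyla as folds
    in_focal = features.index[phylum_of.loc[features.index].isin(focal)]
    if len(focal) >= 2 and y.loc[in_focal].nunique() == 2:
        folds = FoldSpec(
            {ph: tuple(t for t in in_focal if phylum_of[t] == ph)
             for ph in focal},
            "phylum",
        )
        _, metrics, imp = blocked_learn.blocked_classify(
            features.loc[in_focal], y.loc[in_focal], folds, lc
        )
        metric_rows["all"] = {
            "mean_kappa": metrics.mean_kappa, "mean_auprc": metrics.mean_auprc,
            "pooled_kappa": metrics.pooled_kappa,
        }
        importances["all"] = imp

    # within-phylum: classes (or families) as folds
    phylo_tests = []
    for ph in focal:
        members = [t for t in features.index if phylum_of[t] == ph]
        if len(members) < 10 or y.loc[members].nunique() < 2:
            logger.warning("phylum %s: too few labeled taxa, skipped", ph)
            continue
        try:
            folds = blocked_learn.make_clade_folds(members, lineage, "class")
        except ValueError as exc:
            logger.warning("phylum %s: %s", ph, exc)
            continue
        _, metrics, imp = blocked_learn.blocked_classify(
            features.loc[members], y.loc[members], folds, lc
        )
        metric_rows[ph] = {
            "mean_kappa": metrics.mean_kappa, "mean_auprc": metrics.mean_auprc,
            "pooled_kappa": metrics.pooled_kappa, "fold_level": folds.level,
        }
        importances[ph] = imp

        # top-k traits into phylogenetic logistic regression
        if ph not in data.trees:
            continue
        tree = data.trees[ph]
        tips = [t for t in members if t in tree.distances.index]
        if len(tips) < 8 or y.loc[tips].nunique() < 2:
            continue
        top = phylo_logit.select_top_traits(
            imp.drop(columns=["rank"]), k=config.top_k_traits
        )
        for trait in top:
            x = features.loc[tips, trait]
            if x.nunique() < 2:
                continue
            fit = phylo_logit.phylo_logistic(
                tree.prune_to(tips), y.loc[tips], x,
                nboot=config.nboot,
                seed=config.stage_seed(f"phylolog-{ph}-{trait}"),
            )
            phylo_tests.append(
                {"phylum": ph, "trait": trait, "coefficient": fit.coefficient,
                 "alpha": fit.alpha_phy, "p_boot": fit.p_boot,
                 "nboot": fit.n_boot, "converged": fit.converged}
            )

    phylo_df = pd.DataFrame(
        phylo_tests, columns=["phylum", "trait", "coefficient", "alpha",
                              "p_boot", "nboot", "converged"],
    )
    if len(phylo_df):
        q, reject = site_contrasts.bh_adjust(
            phylo_df["p_boot"].tolist(), alpha=config.alpha
        )
        phylo_df["q"] = q
        phylo_df["significant"] = reject

    results["metrics"] = pd.DataFrame.from_dict(metric_rows, orient="index")
    results["importances"] = importances
    results["phylo_logit"] = phylo_df
    if out is not None:
        _write(results["metrics"].reset_index(names="model"), out,
               "generalism_kappa.tsv")
        _write(phylo_df, out, "phylo_logit.tsv")
        _write(labels_all.data.reset_index(names="taxon"), out,
               "generalism_labels.tsv")
    return _finish(out, config, results)


def run_metabolism_analysis(data: PipelineData,
                            config: RunConfig | None = None,
                            out_dir: str | Path | None = None) -> dict:
    """Diversity decomposition and blocked regression of metabolic breadth."""
    config = config or RunConfig()
    out = Path(out_dir) if out_dir is not None else None
    match = community_profiles.match_taxa(data.abundance, data.db)
    diversity = community_profiles.sample_diversity(
        data.abundance, data.db, match=match
    )
    div = diversity.data.join(data.metadata.data[["body_site", "body_area"]])

    breadth = trait_db.metabolic_breadth(data.db)
    enc = trait_db.encode_traits(data.db)
    substrate_cols = [
        c for c in enc.values.columns
        if enc.column_trait(c) in data.schema.carbon_substrates
    ]
    features = blocked_learn.mean_impute(
        enc.values.drop(columns=substrate_cols)
    )

    focal = data.focal_phyla(config)
    phylum_of = data.db.data["phylum"]
    members = [t for t in features.index if phylum_of[t] in focal]
    folds = FoldSpec(
        {ph: tuple(t for t in members if phylum_of[t] == ph) for ph in focal},
        "phylum",
    )
    preds, metrics, imp = blocked_learn.blocked_regress(
        features.loc[members], breadth.loc[members], folds,
        config.learn_config("metabolism"),
    )

    overlap_by_site = {}
    site_of = data.metadata.site_of()
    for site in sorted(site_of.unique()):
        samples = data.metadata.samples_from_site(site)
        sub = data.abundance.abundances[
            [s for s in samples if s in data.abundance.samples]
        ]
        resident = sub.index[(sub > 0).any(axis=1)]
        db_resident = sorted(
            {match.matches.loc[t, "db_taxon"]
             for t in resident if t in match.matches.index}
        )
        _, mean_shared = community_profiles.substrate_overlap(
            data.db, db_resident, data.schema
        )
        overlap_by_site[site] = mean_shared

    outputs = {
        "diversity": div,
        "breadth": breadth,
        "regression_metrics": metrics,
        "regression_predictions": preds,
        "importances": imp,
        "substrate_overlap_by_site": pd.Series(overlap_by_site),
    }
    if out is not None:
        _write(div.reset_index(names="sample"), out, "sample_diversity.tsv")
        _write(metrics.per_fold.reset_index(names="fold"), out,
               "breadth_regression.tsv")
        _write(preds, out, "breadth_predictions.tsv")
        _write(
            pd.Series(overlap_by_site, name="mean_shared_substrates")
            .rename_axis("site").reset_index(),
            out, "substrate_overlap.tsv",
        )
    return _finish(out, config, outputs)
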