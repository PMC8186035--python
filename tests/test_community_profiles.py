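"""Abundance parsing, taxon matching, trait profiles, generalism, diversity."""

import itertools

import numpy as np
import pandas as pd
import pytest

from microtraits import community_profiles as cp
from microtraits import trait_db
from microtraits.community_profiles import (
    AbundanceTable,
    SampleMetadata,
    generalism_labels,
    match_taxa,
    read_abundance,
    sample_diversity,
    substrate_overlap,
    weighted_trait_profile,
)


def _write_abundance(tmp_path, matrix, meta_rows):
    ab_path = tmp_path / "ab.tsv"
    lines = ["lineage\t" + "\t".join(matrix.columns)]
    for taxon, row in matrix.iterrows():
        lines.append(taxon + "\t" + "\t".join(str(v) for v in row))
    ab_path.write_text("\n".join(lines) + "\n")
    meta_path = tmp_path / "meta.tsv"
    meta = pd.DataFrame(meta_rows)
    meta.to_csv(meta_path, sep="\t", index=False)
    return ab_path, meta_path


@pytest.fixture
def four_taxon_files(tmp_path):
    matrix = pd.DataFrame(
        [[0.5, 0.2, 0.0], [0.5, 0.0, 0.3], [0.0, 0.8, 0.3], [0.0, 0.0, 0.4]],
        index=[
            "Bacteria|P1|C1|O1|F1|alpha one",
            "Bacteria|P1|C1|O1|F1|alpha two",
            "Bacteria|P2|C2|O2|F2|beta one",
            "Bacteria|P2|C2|O2|F2|beta two",
        ],
        columns=["s1", "s2", "s3"],
    )
    meta_rows = {
        "sample_id": ["s1", "s2", "s3"],
        "subject_id": ["u1", "u1", "u2"],
        "body_site": ["stool", "tongue_dorsum", "stool"],
        "body_area": ["gut", "mouth", "gut"],
    }
    return _write_abundance(tmp_path, matrix, meta_rows)


class TestReadAbundance:
    def test_fixture_shapes_and_lineage(self, four_taxon_files):
        ab, meta = read_abundance(*four_taxon_files)
        assert ab.abundances.shape == (4, 3)
        assert ab.lineages.loc["alpha one", "phylum"] == "P1"
        assert ab.lineages.loc["beta two", "family"] == "F2"
        assert list(meta.samples) == ["s1", "s2", "s3"]

    def test_sample_without_metadata_dropped(self, tmp_path):
        matrix = pd.DataFrame(
            [[0.4, 0.6]], index=["Bacteria|P1|C1|O1|F1|a b"],
            columns=["s1", "orphan"],
        )
        ab, meta = read_abundance(*_write_abundance(
            tmp_path, matrix,
            {"sample_id": ["s1"], "subject_id": ["u"], "body_site": ["stool"],
             "body_area": ["gut"]},
        ))
        assert list(ab.samples) == ["s1"]

    def test_non_numeric_cell_raises_with_location(self, tmp_path):
        matrix = pd.DataFrame(
            [["0.4"], ["oops"]],
            index=["Bacteria|P1|C1|O1|F1|a b", "Bacteria|P1|C1|O1|F1|c d"],
            columns=["s1"],
        )
        paths = _write_abundance(
            tmp_path, matrix,
            {"sample_id": ["s1"], "subject_id": ["u"], "body_site": ["stool"],
             "body_area": ["gut"]},
        )
        with pytest.raises(ValueError, match="s1"):
            read_abundance(*paths)

    def test_generator_round_trip(self, small_world, small_world_dir):
        _, paths = small_world_dir
        ab, meta = read_abundance(paths["abundance"], paths["metadata"])
        assert (
            ab.abundances.to_numpy() == small_world.abundance.abundances.to_numpy()
        ).all()
        assert list(ab.taxa) == list(small_world.abundance.taxa)
        pd.testing.assert_frame_equal(meta.data, small_world.metadata.data)

    def test_site_to_area_mapping_must_be_unique(self):
        df = pd.DataFrame(
            {"subject_id": ["u", "u"], "body_site": ["stool", "stool"],
             "body_area": ["gut", "mouth"]},
            index=["s1", "s2"],
        )
        with pytest.raises(ValueError, match="stool"):
            SampleMetadata(df)


class TestMatchTaxa:
    def test_species_preferred_then_genus_then_unmatched(
        self, four_taxon_files, mini_schema
    ):
        ab, _ = read_abundance(*four_taxon_files)
        df = pd.DataFrame(
            {
                "rank": ["species", "genus"],
                "phylum": ["P1", "P2"], "class": ["C1", "C2"],
                "order": ["O1", "O2"], "family": ["F1", "F2"],
                "optimal temp": [30.0, 25.0],
                "oxygen": ["aerobe", "anaerobe"],
                "glucose": [1, 0], "xylose": [0, 1], "catalase": [1, 1],
            },
            index=["alpha one", "beta"],
        )
        match = match_taxa(ab, trait_db.TraitTable(df, mini_schema))
        assert match.matches.loc["alpha one", "rank_used"] == "species"
        assert match.matches.loc["beta one", "rank_used"] == "genus"
        assert match.matches.loc["beta one", "db_taxon"] == "beta"
        assert "alpha two" in match.unmatched


class TestWeightedProfile:
    def _world(self, abundances, trait_values, mask=None):
        taxa = [f"t{i} sp" for i in range(len(abundances))]
        ab = AbundanceTable(
            pd.DataFrame({"s": abundances}, index=taxa).rename_axis("taxon"),
            pd.DataFrame({"phylum": "P", "class": "C", "order": "O",
                          "family": "F"}, index=taxa),
        )
        schema = trait_db.TraitSchema(
            (trait_db.TraitDef("v", "continuous", "growth_condition"),)
        )
        df = pd.DataFrame({"v": trait_values}, index=taxa)
        df.insert(0, "rank", "species")
        for c in ("phylum", "class", "order", "family"):
            df[c] = "P"
        enc = trait_db.encode_traits(trait_db.TraitTable(df, schema))
        match = match_taxa(ab, trait_db.TraitTable(df, schema))
        return ab, enc, match

    def test_direct_weighted_mean(self):
        ab, enc, match = self._world([0.6, 0.4], [10.0, 20.0])
        prof = weighted_trait_profile(ab, enc, match)
        assert prof.values.loc["v", "s"] == pytest.approx(14.0)

    def test_missing_value_renormalizes_weights(self):
        ab, enc, match = self._world([0.6, 0.4], [10.0, np.nan])
        prof = weighted_trait_profile(ab, enc, match)
        assert prof.values.loc["v", "s"] == pytest.approx(10.0)
        assert prof.support.loc["v", "s"] == pytest.approx(0.6)

    def test_shared_value_invariant_to_abundances(self):
        for w in ([0.9, 0.1], [0.5, 0.5], [0.01, 0.99]):
            ab, enc, match = self._world(w, [7.0, 7.0])
            prof = weighted_trait_profile(ab, enc, match)
            assert prof.values.loc["v", "s"] == pytest.approx(7.0)

    def test_all_missing_cell_is_nan_with_zero_support(self):
        ab, enc, match = self._world([0.6, 0.4], [np.nan, np.nan])
        prof = weighted_trait_profile(ab, enc, match)
        assert np.isnan(prof.values.loc["v", "s"])
        assert prof.support.loc["v", "s"] == 0

    def test_split_taxon_aggregation_consistency(self, small_world):
        """Duplicating a taxon row while splitting its abundance leaves
        profile cells unchanged."""
        world = small_world
        ab = world.abundance
        enc = trait_db.encode_traits(world.trait_table)
        match = match_taxa(ab, world.trait_table)
        prof = weighted_trait_profile(ab, enc, match)

        # split the most abundant matched taxon's mass across two rows
        matched_mass = ab.abundances.loc[
            [t for t in match.matched_taxa if t in ab.taxa]
        ]
        target = matched_mass.sum(axis=1).idxmax()
        split = ab.abundances.copy()
        split.loc[target] /= 2.0
        clone = split.loc[target].copy()
        clone.name = f"{target} clone"
        split = pd.concat([split, clone.to_frame().T])
        lin = pd.concat([ab.lineages, ab.lineages.loc[[target]].rename(
            index={target: clone.name})])
        ab2 = AbundanceTable(split, lin)
        m2 = match.matches.copy()
        m2.loc[clone.name] = m2.loc[target]
        prof2 = weighted_trait_profile(ab2, enc, cp.TaxonMatch(m2, []))
        pd.testing.assert_frame_equal(prof.values, prof2.values, atol=1e-12)

    def test_phylum_restriction_drops_other_taxa(self, small_world):
        world = small_world
        enc = trait_db.encode_traits(world.trait_table)
        match = match_taxa(world.abundance, world.trait_table)
        prof = weighted_trait_profile(
            world.abundance, enc, match, restrict_phylum="phylum 1"
        )
        # support never exceeds the summed abundance of phylum-1 taxa
        in_ph = world.abundance.phylum_of() == "phylum 1"
        cap = world.abundance.abundances.loc[in_ph].sum(axis=0)
        assert (prof.support.max(axis=0) <= cap + 1e-12).all()


class TestGeneralism:
    def _ab(self, presence, samples, sites, areas):
        taxa = list(presence.keys())
        mat = pd.DataFrame(0.0, index=taxa, columns=samples)
        for t, cols in presence.items():
            for c in cols:
                mat.loc[t, c] = 0.1
        ab = AbundanceTable(
            mat, pd.DataFrame({"phylum": "P", "class": "C", "order": "O",
                               "family": "F"}, index=taxa),
        )
        meta = SampleMetadata(pd.DataFrame(
            {"subject_id": [f"u{i}" for i in range(len(samples))],
             "body_site": sites, "body_area": areas}, index=samples,
        ))
        return ab, meta

    def test_rule_enumeration(self):
        samples = [f"g{i}" for i in range(5)] + ["m1", "m2", "n1"]
        sites = ["stool"] * 5 + ["tongue_dorsum"] * 2 + ["anterior_nares"]
        areas = ["gut"] * 5 + ["mouth"] * 2 + ["airways"]
        ab, meta = self._ab(
            {
                "only gut": ["g0", "g1", "g2", "g3", "g4"],
                "gut and mouth": ["g0", "g1", "g2", "m1", "m2"],
                "two singles": ["g0", "n1"],
                "one sample": ["g0"],
            },
            samples, sites, areas,
        )
        labels = generalism_labels(ab, meta)
        assert labels.data.loc["only gut", "label"] == "specialist"
        assert labels.data.loc["gut and mouth", "label"] == "generalist"
        # present twice overall but no single area reaches two appearances
        assert labels.data.loc["two singles", "label"] == "excluded"
        assert labels.data.loc["one sample", "label"] == "excluded"

    def test_monotone_in_min_appearances(self, small_world):
        l2 = generalism_labels(small_world.abundance, small_world.metadata, 2)
        l4 = generalism_labels(small_world.abundance, small_world.metadata, 4)
        was_specialist = l2.of("specialist")
        assert not set(l4.of("generalist")) & set(was_specialist)


class TestDiversity:
    def _world(self, abundances, usage):
        taxa = [f"t{i} sp" for i in range(len(abundances))]
        subs = [f"c{j}" for j in range(usage.shape[1])]
        schema = trait_db.TraitSchema(
            tuple(trait_db.TraitDef(s, "binary", "carbon_substrate")
                  for s in subs)
        )
        df = pd.DataFrame(usage, index=taxa, columns=subs)
        df.insert(0, "rank", "species")
        for c in ("phylum", "class", "order", "family"):
            df[c] = "P"
        db = trait_db.TraitTable(df, schema)
        ab = AbundanceTable(
            pd.DataFrame({"s": abundances}, index=taxa),
            pd.DataFrame({"phylum": "P", "class": "C", "order": "O",
                          "family": "F"}, index=taxa),
        )
        return ab, db

    def test_single_taxon_single_substrate_zero_entropy(self):
        ab, db = self._world([1.0], np.array([[1, 0]]))
        d = sample_diversity(ab, db).data
        assert d.loc["s", "taxonomic_entropy"] == pytest.approx(0.0)
        assert d.loc["s", "carbon_entropy"] == pytest.approx(0.0)

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_uniform_disjoint_closed_form(self, k):
        ab, db = self._world([1.0 / k] * k, np.eye(k, dtype=int))
        d = sample_diversity(ab, db).data
        assert d.loc["s", "taxonomic_entropy"] == pytest.approx(np.log(k))
        assert d.loc["s", "carbon_entropy"] == pytest.approx(np.log(k))
        assert d.loc["s", "carbon_richness"] == k

    def test_skewed_disjoint_closed_form(self):
        # H(0.5, 0.25, 0.25) = 1.5 ln 2 = 1.0397 nats
        ab, db = self._world([0.5, 0.25, 0.25], np.eye(3, dtype=int))
        d = sample_diversity(ab, db).data
        assert d.loc["s", "carbon_entropy"] == pytest.approx(1.0397, abs=1e-4)

    def test_no_substrate_users_gives_nan_carbon_entropy(self):
        ab, db = self._world([0.6, 0.4], np.zeros((2, 2), dtype=int))
        d = sample_diversity(ab, db).data
        assert np.isnan(d.loc["s", "carbon_entropy"])

    def test_entropy_upper_bounds(self, small_world):
        world = small_world
        d = sample_diversity(world.abundance, world.trait_table).data
        n_subs = len(world.schema.carbon_substrates)
        n_taxa = len(world.abundance.taxa)
        assert (d["carbon_entropy"].dropna() <= np.log(n_subs) + 1e-9).all()
        assert (d["taxonomic_entropy"] <= np.log(n_taxa) + 1e-9).all()


class TestSubstrateOverlap:
    def test_identical_and_disjoint_sets(self):
        schema = trait_db.TraitSchema(
            tuple(trait_db.TraitDef(f"c{j}", "binary", "carbon_substrate")
                  for j in range(5))
        )
        df = pd.DataFrame(
            [[1, 1, 1, 1, 1], [1, 1, 1, 1, 1], [0, 0, 0, 0, 0]],
            index=["a sp", "b sp", "c sp"], columns=[f"c{j}" for j in range(5)],
        )
        df.insert(0, "rank", "species")
        for c in ("phylum", "class", "order", "family"):
            df[c] = "P"
        db = trait_db.TraitTable(df, schema)
        counts, mean = substrate_overlap(db, ["a sp", "b sp", "c sp"])
        assert counts["a sp|b sp"] == 5
        assert counts["a sp|c sp"] == 0
        assert mean == pytest.approx(5 / 3)

    def test_matches_brute_force_oracle(self, small_world):
        db = small_world.trait_table
        taxa = list(db.data.index[:12])
        counts, _ = substrate_overlap(db, taxa)
        subs = db.schema.carbon_substrates
        for a, b in itertools.combinations(taxa, 2):
            expected = int(
                ((db.data.loc[a, subs] == 1) & (db.data.loc[b, subs] == 1)).sum()
            )
            assert counts[f"{a}|{b}"] == expected

    def test_fewer_than_two_taxa_empty(self, small_world):
        counts, mean = substrate_overlap(small_world.trait_table, ["nope"])
        assert counts.empty and np.isnan(mean)
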