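"""Shared fixtures: small trait-database fixtures and synthetic worlds."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from microtraits import synthetic_data as sd
from microtraits import trait_db

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*graphical_lasso.*")


@pytest.fixture(scope="session")
def mini_schema() -> trait_db.TraitSchema:
    """One continuous, one categorical, three binary traits (two carbon)."""
    return trait_db.TraitSchema(
        (
            trait_db.TraitDef("optimal temp", "continuous", "growth_condition",
                              units="C"),
            trait_db.TraitDef(
                "oxygen", "categorical", "growth_condition",
                levels=("aerobe", "anaerobe", "facultative"),
            ),
            trait_db.TraitDef("glucose", "binary", "carbon_substrate"),
            trait_db.TraitDef("xylose", "binary", "carbon_substrate"),
            trait_db.TraitDef("catalase", "binary", "enzyme_assay"),
        )
    )


@pytest.fixture
def mini_table_text() -> str:
    return (
        "taxon\trank\tphylum\tclass\torder\tfamily\t"
        "optimal temp\toxygen\tglucose\txylose\tcatalase\n"
        "escherichia coli\tspecies\tproteobacteria\tgamma\tenterobacterales\t"
        "enterobacteriaceae\t37.0\tfacultative\t1\t1\t1\n"
        "escherichia fergusonii\tspecies\tproteobacteria\tgamma\t"
        "enterobacterales\tenterobacteriaceae\t37.0\tfacultative\t1\t0\t\n"
        "bacteroides fragilis\tspecies\tbacteroidetes\tbacteroidia\t"
        "bacteroidales\tbacteroidaceae\tNA\tanaerobe\t1\t\t0\n"
    )


@pytest.fixture
def mini_table(tmp_path, mini_table_text, mini_schema) -> trait_db.TraitTable:
    p = tmp_path / "db.tsv"
    p.write_text(mini_table_text)
    return trait_db.read_trait_table(p, mini_schema)


@pytest.fixture(scope="session")
def small_world() -> sd.SyntheticWorld:
    """Desk-scale default-condition world shared across read-only tests."""
    return sd.simulate_world(
        sd.WorldConfig(seed=42, n_subjects=25, taxa_per_phylum=40)
    )


@pytest.fixture(scope="session")
def small_world_dir(small_world, tmp_path_factory):
    d = tmp_path_factory.mktemp("world")
    paths = sd.write_world(small_world, d)
    return d, paths
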