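import numpy as np
import pandas as pd
import pytest

import traitscan as ts


def make_traits(species, log_mass, habitat, clade=None):
    """Trait DataFrame with the schema read_trait_table produces."""
    log_mass = np.asarray(log_mass, dtype=float)
    return pd.DataFrame(
        {
            "species": list(species),
            "mass_kg": np.exp(log_mass),
            "habitat": list(habitat),
            "clade": clade if clade is not None else [pd.NA] * len(species),
            "log_mass": log_mass,
        }
    )


@pytest.fixture
def six_species_traits():
    """Three large aquatic and three small terrestrial species; the worked
    one-way ANOVA example (log masses 10,11,12 vs 1,2,3)."""
    return make_traits(
        species=list("abcdef"),
        log_mass=[10, 11, 12, 1, 2, 3],
        habitat=["aquatic"] * 3 + ["terrestrial"] * 3,
    )


@pytest.fixture
def six_species_column():
    return ts.ColumnData(column=1, species=list("abcdef"), alleles=list("TTTCCC"))


def make_alignment(rows: dict[str, str]) -> ts.AlignmentMatrix:
    ids = list(rows)
    chars = np.array([list(rows[i]) for i in ids], dtype="U1")
    return ts.AlignmentMatrix(ids=ids, chars=chars)


@pytest.fixture
def small_sim_config():
    """Desk-scale simulation config used across tests."""
    cfg = ts.default_config(
        seed=11,
        n_columns=400,
        n_scaffolds=1,
        scaffold_length=200_000,
        roh_segments=[],
    )
    cfg.plants = ts.default_plants(cfg, n_type1=2, n_type2=1)
    return cfg


def make_track(scaffold_lengths, scaffold, pos, gt, depth=None, alleles=None):
    """Build a GenotypeTrack from parallel arrays."""
    pos = np.asarray(pos, dtype=int)
    n = len(pos)
    df = pd.DataFrame(
        {
            "scaffold": [scaffold] * n if isinstance(scaffold, str) else list(scaffold),
            "pos": pos,
            "gt": list(gt),
            "depth": np.full(n, 30) if depth is None else np.asarray(depth, dtype=int),
        }
    )
    if alleles is not None:
        a1, a2 = alleles
        df["a1"] = list(a1)
        df["a2"] = list(a2)
    return ts.GenotypeTrack(sites=df, scaffold_lengths=dict(scaffold_lengths))
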