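import numpy as np
import pandas as pd
import pytest

from phyloherb.datasets import (
    Assemblage,
    HerbivoreRecord,
    InteractionTable,
    PlantRecord,
)
from phyloherb.phylo import Phylogeny


def make_table(counts, origins=None, guilds=None, plant_names=None, herb_names=None):
    counts = np.asarray(counts)
    n_p, n_h = counts.shape
    plant_names = plant_names or [f"P{i+1}" for i in range(n_p)]
    herb_names = herb_names or [f"H{j+1}" for j in range(n_h)]
    origins = origins or ["native"] * n_p
    guilds = guilds or ["endophage"] * n_h
    plants = [PlantRecord(n, origin=o) for n, o in zip(plant_names, origins)]
    herbs = [HerbivoreRecord(n, guild=g) for n, g in zip(herb_names, guilds)]
    return InteractionTable(plants, herbs, counts)


@pytest.fixture
def toy_table():
    # P1 hosts {H1,H2,H3}; P2 hosts {H2,H3,H4,H5}; P3 hosts {H1}
    counts = [
        [1, 2, 1, 0, 0],
        [0, 1, 3, 1, 1],
        [2, 0, 0, 0, 0],
    ]
    return make_table(counts, origins=["native", "native", "exotic"],
                      guilds=["endophage", "endophage", "exophage", "exophage", "endophage"])


@pytest.fixture
def toy_assemblage(toy_table):
    return Assemblage("A1", toy_table)


@pytest.fixture
def cherry_tree():
    # ((A:1,B:1):1,C:2) with taxonomy
    return Phylogeny.from_newick(
        "((A:1,B:1):1,C:2);",
        taxonomy={"A": ("GA", "F1"), "B": ("GB", "F1"), "C": ("GC", "F2")},
    )


@pytest.fixture
def genus_tree():
    # ((Qa:10,Qb:10):5,X:15)
    return Phylogeny.from_newick(
        "((Qa:10,Qb:10):5,X:15);",
        taxonomy={"Qa": ("Q", "QF"), "Qb": ("Q", "QF"), "X": ("X", "XF")},
    )


def glmm_poisson_frame(seed, b_pi=-0.5, b_po=0.3, b_int=0.0, sd_u=0.4,
                       n_groups=20, per_group=30, intercept=-3.0):
    """Simulate directly from the Poisson random-intercept model."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        u = rng.normal(0, sd_u)
        off = int(rng.integers(20, 60))
        pi = rng.normal(0, 1, per_group)
        po = rng.random(per_group) < 0.5
        eta = intercept + b_pi * pi + b_po * po + b_int * pi * po + np.log(off) + u
        y = rng.poisson(np.exp(eta))
        for i in range(per_group):
            rows.append(
                dict(
                    assemblage_id=f"g{g:02d}",
                    phylo_isolation=pi[i],
                    origin="native" if po[i] else "exotic",
                    richness=y[i],
                    assemblage_richness=off,
                )
            )
    return pd.DataFrame(rows)
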