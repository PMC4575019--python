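"""Synthetic plant-herbivore datasets with controllable phylogenetic signal.

The generator produces a dated Yule tree with clustered genus/family labels
and a set of local assemblages in which each herbivore originates on a
native host plant and attacks plant *j* with probability

    baseline * exp(-lambda_guild * d(origin, j)) * exp(u_assemblage)

clipped to (0, 1], where *d* is patristic distance.  With lambda > 0 this
yields poorer, more dissimilar, and more specialized faunas on
phylogenetically isolated plants; with lambda = 0 host use is independent
of the tree, giving a null testbed.  Exotic plants are drawn preferentially
from clades distant to the native draw (tunable), so isolation and origin
can be made correlated or orthogonal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import yaml

from .datasets import (
    Assemblage,
    HerbivoreRecord,
    InteractionTable,
    PlantRecord,
    write_herbivore_metadata,
    write_interactions,
    write_plant_metadata,
)
from .phylo import Phylogeny


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n_assemblages: int = 30
    plants_per_assemblage: int = 20
    herbivores_per_assemblage: tuple[int, int] = (5, 90)
    exotic_fraction: float = 0.25
    regional_pool_size: int = 150
    tree_model: str = "yule"
    birth_rate: float = 0.1
    decay_lambda_endophage: float = 0.06
    decay_lambda_exophage: float = 0.025
    baseline_attack_prob: float = 0.8
    between_assemblage_sd: float = 0.3
    guild_mix: float = 0.5  # endophage fraction
    clade_displacement: float = 2.0  # >0 pushes exotics away from natives
    counts_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tree_model != "yule":
            raise ConfigError(f"unknown tree model {self.tree_model!r}")
        for name in ("birth_rate", "decay_lambda_endophage", "decay_lambda_exophage",
                     "between_assemblage_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 < self.baseline_attack_prob <= 1:
            raise ConfigError("baseline_attack_prob must be in (0, 1]")
        if not 0 <= self.exotic_fraction <= 1:
            raise ConfigError("exotic_fraction must be in [0, 1]")
        if not 0 <= self.guild_mix <= 1:
            raise ConfigError("guild_mix must be in [0, 1]")
        if self.plants_per_assemblage < 5:
            raise ConfigError("plants_per_assemblage must be >= 5 (eligibility)")
        lo, hi = self.herbivores_per_assemblage
        if lo < 5 or hi < lo:
            raise ConfigError("herbivores_per_assemblage must be a range with min >= 5")
        if self.n_exotic < 3:
            raise ConfigError(
                "exotic_fraction too low to place 3 exotic plants "
                f"among {self.plants_per_assemblage} (got {self.n_exotic})"
            )
        if self.plants_per_assemblage - self.n_exotic < 2:
            raise ConfigError("need at least 2 native plants per assemblage")
        if self.plants_per_assemblage > self.regional_pool_size:
            raise ConfigError("regional pool smaller than plants per assemblage")

    @property
    def n_exotic(self) -> int:
        # round-half-up so e.g. 0.25 * 10 -> 3 (banker's rounding would give 2)
        return int(self.exotic_fraction * self.plants_per_assemblage + 0.5)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        if "herbivores_per_assemblage" in raw:
            raw["herbivores_per_assemblage"] = tuple(raw["herbivores_per_assemblage"])
        try:
            return cls(**raw)
        except TypeError as exc:  # pragma: no cover
            raise ConfigError(str(exc)) from exc

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class GroundTruth:
    config: SimulationConfig
    lambda_endophage: float
    lambda_exophage: float
    assemblage_intercepts: dict[str, float] = field(default_factory=dict)
    origin_hosts: dict[str, dict[str, str]] = field(default_factory=dict)
    expected_pi_sign_on_richness: int = 0  # -1, 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["config"] = dataclasses.asdict(self.config)
        d["config"]["herbivores_per_assemblage"] = list(
            self.config.herbivores_per_assemblage
        )
        return json.dumps(d, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Yule tree with clustered taxonomy


def simulate_tree(
    n_tips: int,
    birth_rate: float,
    seed: int | np.random.Generator = 0,
    genus_age_fraction: float = 0.15,
    family_age_fraction: float = 0.45,
) -> Phylogeny:
    """Pure-birth ultrametric tree; genera/families are age-threshold clades.

    Starting from two lineages, with k extant lineages the wait to the next
    split is Exp(k * birth_rate); a final Exp(n * birth_rate) epoch runs
    after the last split, so E[height] = sum_{k=2..n} 1/(k * birth_rate).
    """
    if n_tips < 2:
        raise ConfigError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ConfigError("birth_rate must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        active.append((root.new_child(), 0.0))
    k = 2
    while k < n_tips:
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        node, start = active.pop(i)
        node.edge.length = t - start
        active.append((node.new_child(), t))
        active.append((node.new_child(), t))
        k += 1
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    order = rng.permutation(len(active))
    for rank, i in enumerate(order):
        node, start = active[i]
        node.edge.length = t - start
        node.taxon = tns.new_taxon(label=f"P{rank + 1:04d}")

    phy = Phylogeny(tree, require_ultrametric=False)
    _assign_taxonomy(phy, genus_age_fraction, family_age_fraction)
    return phy


def _assign_taxonomy(phy: Phylogeny, genus_frac: float, family_frac: float) -> None:
    """Label tips with genera/families by cutting the tree at age thresholds."""
    h = phy.height()
    cuts = {"genus": genus_frac * h, "family": family_frac * h}
    groups: dict[str, dict] = {"genus": {}, "family": {}}
    counters = {"genus": 0, "family": 0}
    depths = phy._node_depths()

    def assign(node, inherited):
        age = h - depths[node]
        labels = dict(inherited)
        for rank, cut in cuts.items():
            if labels.get(rank) is None and age <= cut:
                counters[rank] += 1
                prefix = "G" if rank == "genus" else "F"
                labels[rank] = f"{prefix}{counters[rank]:03d}"
        if node.is_leaf():
            for rank in cuts:
                if labels.get(rank) is None:  # pendant edge crosses the cut
                    counters[rank] += 1
                    prefix = "G" if rank == "genus" else "F"
                    labels[rank] = f"{prefix}{counters[rank]:03d}"
            groups["genus"][node.taxon.label] = labels["genus"]
            groups["family"][node.taxon.label] = labels["family"]
        else:
            for child in node.child_nodes():
                assign(child, labels)

    assign(phy.tree.seed_node, {"genus": None, "family": None})
    phy.taxonomy = {
        tip: (groups["genus"][tip], groups["family"][tip]) for tip in phy.tip_labels()
    }


# ---------------------------------------------------------------------------
# assemblages


def simulate_assemblage(
    dist: np.ndarray,
    pool: list[str],
    config: SimulationConfig,
    assemblage_index: int,
    rng: np.random.Generator,
) -> tuple[Assemblage, dict]:
    """Sample one assemblage against a precomputed pool distance matrix."""
    aid = f"A{assemblage_index + 1:02d}"
    n_p = config.plants_per_assemblage
    n_ex = config.n_exotic
    n_nat = n_p - n_ex
    pool_idx = np.arange(len(pool))
    native_idx = rng.choice(pool_idx, size=n_nat, replace=False)
    remaining = np.setdiff1d(pool_idx, native_idx)
    mean_d = dist[np.ix_(remaining, native_idx)].mean(axis=1)
    href = max(dist.max() / 2.0, 1e-9)
    w = np.exp(config.clade_displacement * mean_d / href)
    w /= w.sum()
    exotic_idx = rng.choice(remaining, size=n_ex, replace=False, p=w)
    plant_idx = np.concatenate([native_idx, exotic_idx])
    origins = ["native"] * n_nat + ["exotic"] * n_ex

    lo, hi = config.herbivores_per_assemblage
    n_h = int(rng.integers(lo, hi + 1))
    guilds = np.where(rng.random(n_h) < config.guild_mix, "endophage", "exophage")
    lam = np.where(
        guilds == "endophage",
        config.decay_lambda_endophage,
        config.decay_lambda_exophage,
    )
    origin_pos = rng.integers(n_nat, size=n_h)  # index into plant_idx (natives first)
    u = float(rng.normal(0.0, config.between_assemblage_sd))

    D = dist[np.ix_(plant_idx, plant_idx)]
    p_attack = np.minimum(
        1.0,
        config.baseline_attack_prob
        * np.exp(-lam[None, :] * D[:, origin_pos])
        * np.exp(u),
    )  # plants x herbivores
    presence = rng.random(p_attack.shape) < p_attack
    # retry-then-drop: redraw all-zero herbivore columns / plant rows
    for _ in range(50):
        zero_cols = ~presence.any(axis=0)
        zero_rows = ~presence.any(axis=1)
        if not zero_cols.any() and not zero_rows.any():
            break
        if zero_cols.any():
            presence[:, zero_cols] = rng.random(p_attack[:, zero_cols].shape) < p_attack[:, zero_cols]
        zero_rows = ~presence.any(axis=1)
        if zero_rows.any():
            presence[zero_rows, :] = rng.random(p_attack[zero_rows, :].shape) < p_attack[zero_rows, :]
    counts = presence.astype(np.int64)
    if config.counts_mode:
        counts = counts * (1 + rng.poisson(2.0, size=counts.shape))

    plants = [
        PlantRecord(species=pool[i], origin=orig)
        for i, orig in zip(plant_idx, origins)
    ]
    herbs = [
        HerbivoreRecord(species=f"{aid}_H{j + 1:03d}", guild=g)
        for j, g in enumerate(guilds)
    ]
    table = InteractionTable(plants, herbs, counts)
    truth = {
        "intercept": u,
        "origin_hosts": {
            h.species: pool[plant_idx[pos]] for h, pos in zip(herbs, origin_pos)
        },
    }
    return Assemblage(assemblage_id=aid, table=table, metadata={}), truth


@dataclass
class DatasetBundle:
    phylogeny: Phylogeny
    assemblages: list[Assemblage]
    ground_truth: GroundTruth
    config: SimulationConfig


def generate_dataset(config: SimulationConfig) -> DatasetBundle:
    """Full synthetic dataset: tree + assemblages + ground truth."""
    rng = np.random.default_rng(config.seed)
    phy = simulate_tree(config.regional_pool_size, config.birth_rate, rng)
    pool = sorted(phy.tip_labels())
    dist = phy.distance_matrix(pool).to_numpy()
    truth = GroundTruth(
        config=config,
        lambda_endophage=config.decay_lambda_endophage,
        lambda_exophage=config.decay_lambda_exophage,
        expected_pi_sign_on_richness=(
            -1
            if (config.decay_lambda_endophage > 0 or config.decay_lambda_exophage > 0)
            else 0
        ),
    )
    assemblages = []
    for i in range(config.n_assemblages):
        a, t = simulate_assemblage(dist, pool, config, i, rng)
        assemblages.append(a)
        truth.assemblage_intercepts[a.assemblage_id] = t["intercept"]
        truth.origin_hosts[a.assemblage_id] = t["origin_hosts"]
    return DatasetBundle(phy, assemblages, truth, config)


def write_dataset(bundle: DatasetBundle, outdir: str | Path, dialect: str = "edges") -> Path:
    """Write a dataset in the exchange formats; returns the manifest path."""
    outdir = Path(outdir)
    (outdir / "interactions").mkdir(parents=True, exist_ok=True)
    bundle.phylogeny.write_newick(outdir / "tree.nwk")
    pool_records = [
        PlantRecord(species=s, genus=g, family=f)
        for s, (g, f) in sorted(bundle.phylogeny.taxonomy.items())
    ]
    write_plant_metadata(pool_records, outdir / "taxonomy.csv")
    all_herbs = [h for a in bundle.assemblages for h in a.table.herbivores]
    write_herbivore_metadata(all_herbs, outdir / "herbivores.csv")
    entries = []
    for a in bundle.assemblages:
        rel = f"interactions/{a.assemblage_id}.csv"
        write_interactions(a.table, outdir / rel, dialect=dialect)
        prel = f"interactions/{a.assemblage_id}_plants.csv"
        tax = bundle.phylogeny.taxonomy
        recs = [
            PlantRecord(p.species, *tax.get(p.species, ("", "")), origin=p.origin)
            for p in a.table.plants
        ]
        write_plant_metadata(recs, outdir / prel)
        entries.append(
            {"id": a.assemblage_id, "interactions": rel, "plants": prel, "dialect": dialect}
        )
    manifest = {
        "tree": "tree.nwk",
        "herbivores": "herbivores.csv",
        "assemblages": entries,
        "config_hash": bundle.config.hash(),
        "seed": bundle.config.seed,
    }
    path = outdir / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    (outdir / "ground_truth.json").write_text(bundle.ground_truth.to_json())
    return path
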