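"""Dated-phylogeny handling: polytomy grafting, patristic distances, isolation.

Species missing from the reference ultrametric tree are attached as new tips
at the most recent common ancestor of their congeners (falling back to the
family MRCA), with the new branch spanning from the attachment node to the
present — so the tree stays ultrametric.  Per-plant phylogenetic isolation
is the mean patristic distance (in the tree's time units, Myr) from a focal
plant to the native plants co-occurring in its assemblage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .datasets import Assemblage, PlantRecord, ValidationError

ULTRAMETRIC_RTOL = 1e-6


class GraftError(ValueError):
    pass


@dataclass
class GraftReport:
    species_name: str
    attachment_level: str  # "genus" | "family" | "failed"
    attachment_node_age: float
    assigned_branch_length: float


@dataclass
class IsolationRecord:
    assemblage_id: str
    focal_species: str
    phylo_isolation: float
    n_comparators: int


class Phylogeny:
    """A rooted ultrametric tree plus per-tip genus/family taxonomy."""

    def __init__(
        self,
        tree: dendropy.Tree,
        taxonomy: dict[str, tuple[str, str]] | None = None,
        require_ultrametric: bool = True,
    ) -> None:
        tree.is_rooted = True
        self.tree = tree
        self.taxonomy: dict[str, tuple[str, str]] = dict(taxonomy or {})
        self._depths: dict | None = None
        labels = self.tip_labels()
        if len(set(labels)) != len(labels):
            raise ValidationError("tip labels are not unique")
        for e in tree.preorder_edge_iter():
            if e.length is not None and e.length < 0:
                raise ValidationError("negative branch length in tree")
        if require_ultrametric and not self.is_ultrametric():
            raise ValidationError(
                f"tree is not ultrametric within relative tolerance {ULTRAMETRIC_RTOL}"
            )

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(
        cls,
        source: str | Path,
        taxonomy: dict[str, tuple[str, str]] | None = None,
        require_ultrametric: bool = True,
    ) -> "Phylogeny":
        try:
            if isinstance(source, Path) or (isinstance(source, str) and Path(source).exists()):
                tree = dendropy.Tree.get(path=str(source), schema="newick",
                                         preserve_underscores=True)
            else:
                tree = dendropy.Tree.get(data=source, schema="newick",
                                         preserve_underscores=True)
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ValidationError(f"duplicate tip labels in newick: {exc}") from exc
        return cls(tree, taxonomy=taxonomy, require_ultrametric=require_ultrametric)

    def write_newick(self, path: str | Path) -> None:
        self.tree.write(path=str(path), schema="newick", suppress_rooting=True,
                        unquoted_underscores=True)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True,
                                   unquoted_underscores=True)

    def clone(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1), taxonomy=dict(self.taxonomy),
                         require_ultrametric=False)

    # -- geometry ----------------------------------------------------------

    def _invalidate(self) -> None:
        self._depths = None

    def _node_depths(self) -> dict:
        """Root-to-node path lengths, cached until the topology changes."""
        if self._depths is None:
            depths: dict = {}
            for node in self.tree.preorder_node_iter():
                if node.parent_node is None:
                    depths[node] = 0.0
                else:
                    depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
            self._depths = depths
        return self._depths

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def height(self) -> float:
        depths = self._node_depths()
        return max(depths[leaf] for leaf in self.tree.leaf_node_iter())

    def node_age(self, node) -> float:
        return self.height() - self._node_depths()[node]

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        depths = self._node_depths()
        tip_depths = np.array([depths[leaf] for leaf in self.tree.leaf_node_iter()])
        h = tip_depths.max()
        if h == 0:
            return True
        return bool(np.max(np.abs(tip_depths - h)) / h < rtol)

    def force_ultrametric(self) -> None:
        """Extend every tip to the tree height (off by default in loaders)."""
        depths = self._node_depths()
        h = self.height()
        for leaf in self.tree.leaf_node_iter():
            leaf.edge.length = (leaf.edge.length or 0.0) + (h - depths[leaf])
        self._invalidate()

    # -- distances ---------------------------------------------------------

    def distance_matrix(self, labels: list[str] | None = None) -> pd.DataFrame:
        """Patristic distance matrix for the requested tips (all by default).

        d(i, j) = depth(i) + depth(j) - 2 * depth(mrca(i, j)), computed in a
        single post-order pass.
        """
        if labels is None:
            labels = sorted(self.tip_labels())
        idx = {n: i for i, n in enumerate(labels)}
        missing = set(labels) - set(self.tip_labels())
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        depths = self._node_depths()
        n = len(labels)
        D = np.zeros((n, n))
        rd = np.zeros(n)
        below: dict = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                lab = node.taxon.label
                if lab in idx:
                    rd[idx[lab]] = depths[node]
                    below[node] = np.array([idx[lab]], dtype=np.intp)
                else:
                    below[node] = np.empty(0, dtype=np.intp)
            else:
                child_sets = [below.pop(c) for c in node.child_nodes()]
                d_node = depths[node]
                for a in range(len(child_sets)):
                    for b in range(a + 1, len(child_sets)):
                        s1, s2 = child_sets[a], child_sets[b]
                        if len(s1) and len(s2):
                            block = rd[s1][:, None] + rd[s2][None, :] - 2.0 * d_node
                            D[np.ix_(s1, s2)] = block
                            D[np.ix_(s2, s1)] = block.T
                below[node] = np.concatenate(child_sets) if child_sets else np.empty(0, dtype=np.intp)
        return pd.DataFrame(D, index=labels, columns=labels)

    def patristic_distance(self, sp1: str, sp2: str) -> float:
        if sp1 == sp2:
            if sp1 not in set(self.tip_labels()):
                raise KeyError(f"unknown tip {sp1!r}")
            return 0.0
        d = self.distance_matrix([sp1, sp2])
        return float(d.loc[sp1, sp2])


# ---------------------------------------------------------------------------
# grafting


def _mrca(nodes: list) -> "dendropy.Node":
    """MRCA of a list of nodes (walks ancestor paths; bipartition-cache free)."""
    paths = []
    for node in nodes:
        path = []
        cur = node
        while cur is not None:
            path.append(cur)
            cur = cur.parent_node
        paths.append(path[::-1])  # root -> node
    mrca = paths[0][0]
    for depth in range(min(len(p) for p in paths)):
        candidates = {id(p[depth]) for p in paths}
        if len(candidates) == 1:
            mrca = paths[0][depth]
        else:
            break
    return mrca


def _tips_matching(phy: Phylogeny, genus: str, family: str, level: str) -> list:
    out = []
    for leaf in phy.tree.leaf_node_iter():
        tax = phy.taxonomy.get(leaf.taxon.label)
        if tax is None:
            continue
        if level == "genus" and genus and tax[0] == genus:
            out.append(leaf)
        elif level == "family" and family and tax[1] == family:
            out.append(leaf)
    return out


def graft_species(phy: Phylogeny, species: PlantRecord) -> GraftReport:
    """Attach one missing species in place; returns the graft report.

    Attachment node: MRCA of congeneric tips when two or more exist; the
    parent (stem) of the single congener otherwise; same rule at family
    rank as the fallback.  The new branch length equals the attachment
    node's age, so every root-to-tip depth is preserved.
    """
    if species.species in set(phy.tip_labels()):
        raise GraftError(f"{species.species!r} is already a tip")
    for level in ("genus", "family"):
        tips = _tips_matching(phy, species.genus, species.family, level)
        if not tips:
            continue
        if len(tips) == 1:
            attach = tips[0].parent_node
        else:
            attach = _mrca(tips)
        age = phy.node_age(attach)
        taxon = dendropy.Taxon(label=species.species)
        phy.tree.taxon_namespace.add_taxon(taxon)
        child = attach.new_child(taxon=taxon, edge_length=age)
        assert child is not None
        phy.taxonomy[species.species] = (species.genus, species.family)
        phy._invalidate()
        return GraftReport(species.species, level, age, age)
    return GraftReport(species.species, "failed", float("nan"), float("nan"))


def graft_all(
    phy: Phylogeny, assemblages: list[Assemblage] | list[PlantRecord]
) -> tuple[Phylogeny, list[GraftReport]]:
    """Graft every plant species missing from the tree; non-mutating.

    The final pairwise distance matrix does not depend on graft order
    (children of a polytomy are exchangeable), so input order is kept.
    """
    records: dict[str, PlantRecord] = {}
    for item in assemblages:
        if isinstance(item, Assemblage):
            for p in item.table.plants:
                records.setdefault(p.species, p)
        else:
            records.setdefault(item.species, item)
    out = phy.clone()
    present = set(out.tip_labels())
    reports = []
    for name, rec in records.items():
        if name in present:
            continue
        reports.append(graft_species(out, rec))
        present.add(name)
    return out, reports


# ---------------------------------------------------------------------------
# phylogenetic isolation


def phylo_isolation(
    phy: Phylogeny,
    a: Assemblage,
    focal: str,
    exclude_self: bool = True,
    dist: pd.DataFrame | None = None,
) -> IsolationRecord:
    """Mean patristic distance from ``focal`` to the assemblage's natives.

    A native focal plant is excluded from its own comparator set by default
    (distance to self is zero and would deflate native isolation).
    """
    natives = [p.species for p in a.table.plants if p.origin == "native"]
    comparators = [n for n in natives if not (exclude_self and n == focal)]
    if not comparators:
        raise ValidationError(
            f"no native comparators for {focal!r} in {a.assemblage_id!r}"
        )
    if dist is None:
        dist = phy.distance_matrix(sorted(set(comparators + [focal])))
    vals = dist.loc[focal, comparators].to_numpy(dtype=float)
    return IsolationRecord(
        assemblage_id=a.assemblage_id,
        focal_species=focal,
        phylo_isolation=float(vals.mean()),
        n_comparators=len(comparators),
    )


def isolation_table(
    phy: Phylogeny, a: Assemblage, exclude_self: bool = True
) -> list[IsolationRecord]:
    """Phylogenetic isolation of every plant in an assemblage (one matrix)."""
    labels = sorted(a.table.plant_names)
    dist = phy.distance_matrix(labels)
    return [
        phylo_isolation(phy, a, p, exclude_self=exclude_self, dist=dist)
        for p in a.table.plant_names
    ]
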