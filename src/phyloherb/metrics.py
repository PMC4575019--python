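"""Per-plant herbivore fauna metrics: richness, dissimilarity, specialization.

Dissimilarity between two plants' faunas is computed from presence/absence
shared/exclusive species counts (a, b, c):

* Jaccard dissimilarity  = (b + c) / (a + b + c)
* Simpson dissimilarity  = min(b, c) / (min(b, c) + a)

Specialization of a herbivore is the standardized Kullback-Leibler index
d' in [0, 1]: the KL divergence between the herbivore's realized host-use
frequencies and host availability, rescaled between its achievable integer
minimum and the maximum ln(m / A).  The minimum is found exactly: the
objective is separable and convex in the integer allocation, so marginal
(greedy) allocation of interactions one at a time attains the optimum.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import Assemblage, InteractionTable, ValidationError

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    pass


@dataclass(frozen=True)
class PairwiseCounts:
    a: int  # shared herbivore species
    b: int  # exclusive to plant 1
    c: int  # exclusive to plant 2

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValidationError("a, b, c must be nonnegative")


@dataclass
class DPrimeRecord:
    herbivore: str
    d_raw: float
    d_min: float
    d_max: float
    d_prime: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# richness and pairwise dissimilarity


def richness(table: InteractionTable, plant: str) -> int:
    """Number of herbivore species with count >= 1 on the plant's row."""
    row = table.counts[table.plant_index(plant)]
    r = int(np.count_nonzero(row))
    if r == 0:
        raise ValidationError(
            f"plant {plant!r} has no herbivores; filter it out before computing metrics"
        )
    return r


def pairwise_abc(table: InteractionTable, p1: str, p2: str) -> PairwiseCounts:
    if p1 == p2:
        raise ValueError("pairwise_abc requires two distinct plants")
    r1 = table.counts[table.plant_index(p1)] >= 1
    r2 = table.counts[table.plant_index(p2)] >= 1
    return PairwiseCounts(
        a=int(np.count_nonzero(r1 & r2)),
        b=int(np.count_nonzero(r1 & ~r2)),
        c=int(np.count_nonzero(~r1 & r2)),
    )


def jaccard_dissimilarity(pc: PairwiseCounts) -> float:
    denom = pc.a + pc.b + pc.c
    if denom == 0:
        raise UndefinedMetricError("Jaccard undefined: a = b = c = 0")
    return (pc.b + pc.c) / denom


def simpson_dissimilarity(pc: PairwiseCounts) -> float:
    m = min(pc.b, pc.c)
    if m + pc.a == 0:
        raise UndefinedMetricError("Simpson undefined: a = min(b, c) = 0")
    return m / (m + pc.a)


_INDEX_FN = {"jaccard": jaccard_dissimilarity, "simpson": simpson_dissimilarity}


def mean_dissimilarity(
    table: InteractionTable,
    focal: str,
    native_set: list[str],
    index: str = "jaccard",
) -> tuple[float, int]:
    """Mean pairwise dissimilarity of ``focal`` versus each native comparator.

    The focal plant never compares against itself.  Pairs with an undefined
    index are skipped (with the comparator count reduced) and logged.
    Returns ``(mean, n_comparators)``.
    """
    fn = _INDEX_FN[index]
    comparators = [n for n in native_set if n != focal]
    if not comparators:
        raise UndefinedMetricError(f"no native comparators for {focal!r}")
    vals = []
    for other in comparators:
        try:
            vals.append(fn(pairwise_abc(table, focal, other)))
        except UndefinedMetricError:
            logger.warning("undefined %s index for pair (%s, %s); skipped", index, focal, other)
    if not vals:
        raise UndefinedMetricError(f"all {index} comparisons undefined for {focal!r}")
    return float(np.mean(vals)), len(vals)


# ---------------------------------------------------------------------------
# Blüthgen-style d'


def _alloc_term(k: int, A: int, lnq: float) -> float:
    # contribution of k interactions on a plant with availability q = e^lnq
    if k == 0:
        return 0.0
    p = k / A
    return p * (math.log(p) - lnq)


def min_kl_allocation(A: int, q: np.ndarray) -> float:
    """Exact minimum of sum_j p_j ln(p_j / q_j) over integer allocations.

    ``A`` interactions are spread over plants with availabilities ``q``
    (positive entries only are usable).  Each plant's contribution
    (k/A) ln(k/(A q_j)) is convex in k, so greedily assigning one
    interaction at a time to the plant with the smallest marginal increase
    is exact for this separable convex program.
    """
    usable = np.flatnonzero(q > 0)
    if A < 1 or len(usable) == 0:
        raise ValueError("need A >= 1 and at least one plant with q > 0")
    lnq = np.log(q[usable])
    heap = [(_alloc_term(1, A, lnq[i]) - 0.0, i) for i in range(len(usable))]
    heapq.heapify(heap)
    alloc = np.zeros(len(usable), dtype=np.int64)
    total = 0.0
    for _ in range(A):
        delta, i = heapq.heappop(heap)
        total += delta
        alloc[i] += 1
        k = alloc[i]
        heapq.heappush(
            heap, (_alloc_term(k + 1, A, lnq[i]) - _alloc_term(k, A, lnq[i]), i)
        )
    return total


def dprime(table: InteractionTable, herbivore: str) -> DPrimeRecord:
    """Standardized KL specialization of one herbivore in an assemblage.

    Uses raw counts as interaction frequencies (0/1 incidence reduces to
    the binary special case).  A degenerate network (d_max == d_min, e.g. a
    single-plant table) yields d' = 0 with the ``degenerate`` flag set.
    """
    j = table.herbivore_index(herbivore)
    col = table.counts[:, j].astype(float)
    A = col.sum()
    if A < 1:
        raise UndefinedMetricError(f"herbivore {herbivore!r} has no interactions")
    row_tot = table.counts.sum(axis=1).astype(float)
    m = row_tot.sum()
    q = row_tot / m
    p = col / A
    nz = p > 0
    d_raw = float(np.sum(p[nz] * np.log(p[nz] / q[nz])))
    d_max = float(np.log(m / A))
    d_min = float(min_kl_allocation(int(A), q))
    # clip tiny numerical excursions outside [d_min, d_max]
    d_raw = min(max(d_raw, d_min), d_max)
    if d_max - d_min < 1e-12 or int(np.count_nonzero(row_tot)) == 1:
        return DPrimeRecord(herbivore, d_raw, d_min, d_max, 0.0, degenerate=True)
    d_prime = (d_raw - d_min) / (d_max - d_min)
    return DPrimeRecord(herbivore, d_raw, d_min, d_max, float(np.clip(d_prime, 0.0, 1.0)))


def dprime_table(table: InteractionTable) -> dict[str, DPrimeRecord]:
    return {h: dprime(table, h) for h in table.herbivore_names}


def mean_dprime_per_plant(
    table: InteractionTable,
    plant: str,
    records: dict[str, DPrimeRecord] | None = None,
) -> float:
    """Unweighted mean d' over the herbivores present on a plant."""
    i = table.plant_index(plant)
    present = [h for j, h in enumerate(table.herbivore_names) if table.counts[i, j] >= 1]
    if not present:
        raise ValidationError(f"plant {plant!r} hosts no herbivores")
    if records is None:
        records = {h: dprime(table, h) for h in present}
    return float(np.mean([records[h].d_prime for h in present]))


# ---------------------------------------------------------------------------
# assembly of the per-plant analysis table

PLANT_METRIC_COLUMNS = [
    "assemblage_id",
    "species",
    "origin",
    "richness",
    "mean_jaccard",
    "mean_simpson",
    "mean_dprime",
    "phylo_isolation",
    "n_native_comparators",
    "guild_scope",
]


def build_plant_metrics(
    a: Assemblage,
    phy,
    guild_scope: str = "all",
    exclude_self: bool = True,
) -> pd.DataFrame:
    """One row per plant: the four responses plus isolation and origin.

    Plants whose metrics are undefined (e.g. a native with no other native
    comparator) get NaN in the affected columns and a logged warning; the
    modeling stage drops incomplete rows.
    """
    from .phylo import phylo_isolation  # local import to avoid cycle

    t = a.table
    natives = [p.species for p in t.plants if p.origin == "native"]
    dp = dprime_table(t)
    labels = sorted(t.plant_names)
    dist = phy.distance_matrix(labels) if phy is not None else None
    rows = []
    for p in t.plants:
        row: dict = {
            "assemblage_id": a.assemblage_id,
            "species": p.species,
            "origin": p.origin,
            "guild_scope": guild_scope,
        }
        row["richness"] = richness(t, p.species)
        for index in ("jaccard", "simpson"):
            try:
                val, ncomp = mean_dissimilarity(t, p.species, natives, index)
            except UndefinedMetricError as exc:
                logger.warning("%s: %s", a.assemblage_id, exc)
                val, ncomp = float("nan"), 0
            row[f"mean_{index}"] = val
        row["n_native_comparators"] = ncomp
        row["mean_dprime"] = mean_dprime_per_plant(t, p.species, dp)
        if phy is not None:
            try:
                iso = phylo_isolation(phy, a, p.species, exclude_self=exclude_self, dist=dist)
                row["phylo_isolation"] = iso.phylo_isolation
            except ValidationError as exc:
                logger.warning("%s: %s", a.assemblage_id, exc)
                row["phylo_isolation"] = float("nan")
        else:
            row["phylo_isolation"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows, columns=PLANT_METRIC_COLUMNS)
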