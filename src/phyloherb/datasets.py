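"""Core domain types, file I/O, and assemblage filtering rules.

An :class:`Assemblage` is a local plant-herbivore community: an interaction
table (plants x herbivores, nonnegative integer counts) plus origin labels
for plants and guild labels for herbivores.  This module reads and writes
the plain-text exchange formats (edge-list / incidence-matrix CSVs, metadata
CSVs, YAML manifests) and implements the eligibility rules applied before
any metric or model is computed:

* plants of unknown origin are excluded;
* plants consumed by no herbivore are excluded (with a cascade removing
  herbivores left without hosts);
* an assemblage enters the analysis only if it has >= 5 plants, >= 5
  herbivores, >= 10 species in total, >= 3 exotic plants and >= 1 native
  plant.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

ORIGINS = ("native", "exotic", "unknown")
GUILDS = ("endophage", "exophage")

#: eligibility reason codes, in the order they are checked
REASON_MIN_PLANTS = "min_plants"
REASON_MIN_HERBIVORES = "min_herbivores"
REASON_MIN_TOTAL = "min_total"
REASON_MIN_EXOTICS = "min_exotics"
REASON_MIN_NATIVES = "min_natives"


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


class ParseError(ValueError):
    """Raised when an input file is malformed; carries the offending line."""


@dataclass(frozen=True)
class PlantRecord:
    """A host plant: species label, taxonomy for grafting, and origin."""

    species: str
    genus: str = ""
    family: str = ""
    origin: str = "unknown"

    def __post_init__(self) -> None:
        if not self.species:
            raise ValidationError("plant species name must be nonempty")
        if self.origin not in ORIGINS:
            raise ValidationError(
                f"origin {self.origin!r} for {self.species!r} not in {ORIGINS}"
            )


@dataclass(frozen=True)
class HerbivoreRecord:
    """An insect herbivore: species label and feeding guild (may be unset)."""

    species: str
    guild: str | None = None

    def __post_init__(self) -> None:
        if not self.species:
            raise ValidationError("herbivore species name must be nonempty")
        if self.guild is not None and self.guild not in GUILDS:
            raise ValidationError(
                f"guild {self.guild!r} for {self.species!r} not in {GUILDS}"
            )


class InteractionTable:
    """Plants x herbivores count matrix with typed row/column records.

    Counts are the canonical representation; presence/absence is derived as
    ``count >= 1`` everywhere downstream.
    """

    def __init__(
        self,
        plants: Sequence[PlantRecord],
        herbivores: Sequence[HerbivoreRecord],
        counts: np.ndarray,
    ) -> None:
        counts = np.asarray(counts)
        if counts.shape != (len(plants), len(herbivores)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(plants)} plants x {len(herbivores)} herbivores"
            )
        if counts.size and (not np.issubdtype(counts.dtype, np.integer)):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("interaction counts must be integers")
            counts = np.round(counts).astype(np.int64)
        counts = counts.astype(np.int64, copy=True)
        if counts.size and counts.min() < 0:
            raise ValidationError("interaction counts must be nonnegative")
        names_p = [p.species for p in plants]
        names_h = [h.species for h in herbivores]
        if len(set(names_p)) != len(names_p):
            raise ValidationError("duplicated plant labels in table")
        if len(set(names_h)) != len(names_h):
            raise ValidationError("duplicated herbivore labels in table")
        self.plants = list(plants)
        self.herbivores = list(herbivores)
        self.counts = counts
        self._plant_index = {n: i for i, n in enumerate(names_p)}
        self._herb_index = {n: j for j, n in enumerate(names_h)}

    # -- basic accessors ---------------------------------------------------

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def n_herbivores(self) -> int:
        return len(self.herbivores)

    @property
    def plant_names(self) -> list[str]:
        return [p.species for p in self.plants]

    @property
    def herbivore_names(self) -> list[str]:
        return [h.species for h in self.herbivores]

    def plant_index(self, name: str) -> int:
        try:
            return self._plant_index[name]
        except KeyError:
            raise KeyError(f"unknown plant {name!r}") from None

    def herbivore_index(self, name: str) -> int:
        try:
            return self._herb_index[name]
        except KeyError:
            raise KeyError(f"unknown herbivore {name!r}") from None

    def presence(self) -> np.ndarray:
        """Boolean plants x herbivores incidence matrix."""
        return self.counts >= 1

    def subset(self, plant_mask: np.ndarray, herb_mask: np.ndarray) -> "InteractionTable":
        plants = [p for p, k in zip(self.plants, plant_mask) if k]
        herbs = [h for h, k in zip(self.herbivores, herb_mask) if k]
        counts = self.counts[np.ix_(np.asarray(plant_mask, bool), np.asarray(herb_mask, bool))]
        return InteractionTable(plants, herbs, counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionTable):
            return NotImplemented
        return (
            self.plants == other.plants
            and self.herbivores == other.herbivores
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return f"<InteractionTable {self.n_plants} plants x {self.n_herbivores} herbivores>"


@dataclass
class Assemblage:
    """One local community: an id, its interaction table, free metadata."""

    assemblage_id: str
    table: InteractionTable
    metadata: dict = field(default_factory=dict)


@dataclass
class RemovalLogEntry:
    assemblage_id: str
    kind: str  # "plant" | "herbivore"
    name: str
    reason: str  # "origin_unknown" | "no_herbivores" | "no_hosts"


@dataclass
class EligibilityReport:
    assemblage_id: str
    passed: bool
    n_plants: int
    n_herbivores: int
    n_exotic: int
    n_native: int
    reasons: list[str]

    def __post_init__(self) -> None:
        if self.passed != (not self.reasons):
            raise ValidationError("passed must be true iff reasons is empty")


# ---------------------------------------------------------------------------
# reading / writing interaction tables


def _records_from_lookup(
    names: Iterable[str],
    lookup: Mapping[str, PlantRecord] | None,
    kind: str,
) -> list:
    out = []
    for n in names:
        if lookup is not None and n in lookup:
            out.append(lookup[n])
        elif kind == "plant":
            out.append(PlantRecord(species=n))
        else:
            out.append(HerbivoreRecord(species=n))
    return out


def read_interactions(
    path: str | Path,
    dialect: str = "edges",
    plant_lookup: Mapping[str, PlantRecord] | None = None,
    herbivore_lookup: Mapping[str, HerbivoreRecord] | None = None,
) -> InteractionTable:
    """Read an interaction table from CSV.

    ``dialect="edges"``: columns ``plant,herbivore[,count]`` (count defaults
    to 1; repeated rows sum).  ``dialect="matrix"``: first column holds plant
    labels, remaining columns are herbivore labels.  Metadata lookups, when
    given, attach origin/guild to the row/column records.
    """
    path = Path(path)
    if dialect == "edges":
        return _read_edges(path, plant_lookup, herbivore_lookup)
    if dialect == "matrix":
        return _read_matrix(path, plant_lookup, herbivore_lookup)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_edges(path, plant_lookup, herbivore_lookup) -> InteractionTable:
    try:
        df = pd.read_csv(path, dtype={"plant": str, "herbivore": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    for col in ("plant", "herbivore"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if "count" not in df.columns:
        df["count"] = 1
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        if pd.isna(row.plant) or pd.isna(row.herbivore) or pd.isna(row.count):
            raise ParseError(f"{path}: malformed row at line {lineno}")
        if float(row.count) != int(row.count):
            raise ParseError(f"{path}: non-integer count at line {lineno}")
    counts = df["count"].astype(np.int64)
    if (counts < 0).any():
        bad = int(np.argmax(counts.to_numpy() < 0)) + 2
        raise ValidationError(f"{path}: negative count at line {bad}")
    plants = list(dict.fromkeys(df["plant"]))
    herbs = list(dict.fromkeys(df["herbivore"]))
    mat = np.zeros((len(plants), len(herbs)), dtype=np.int64)
    pi = {n: i for i, n in enumerate(plants)}
    hi = {n: j for j, n in enumerate(herbs)}
    for p, h, c in zip(df["plant"], df["herbivore"], counts):
        mat[pi[p], hi[h]] += c  # duplicates sum
    return InteractionTable(
        _records_from_lookup(plants, plant_lookup, "plant"),
        _records_from_lookup(herbs, herbivore_lookup, "herbivore"),
        mat,
    )


def _read_matrix(path, plant_lookup, herbivore_lookup) -> InteractionTable:
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"{path}: {exc}") from exc
    if df.isna().any().any():
        raise ParseError(f"{path}: missing values in incidence matrix")
    mat = df.to_numpy()
    if not np.allclose(mat, np.round(mat.astype(float))):
        raise ParseError(f"{path}: non-integer entries in incidence matrix")
    mat = np.round(mat.astype(float)).astype(np.int64)
    if mat.size and mat.min() < 0:
        raise ValidationError(f"{path}: negative entry in incidence matrix")
    return InteractionTable(
        _records_from_lookup([str(x) for x in df.index], plant_lookup, "plant"),
        _records_from_lookup([str(x) for x in df.columns], herbivore_lookup, "herbivore"),
        mat,
    )


def write_interactions(table: InteractionTable, path: str | Path, dialect: str = "edges") -> None:
    """Write a table to CSV in either dialect (round-trips exactly)."""
    path = Path(path)
    if dialect == "edges":
        rows = []
        for i, p in enumerate(table.plant_names):
            for j, h in enumerate(table.herbivore_names):
                c = int(table.counts[i, j])
                if c:
                    rows.append((p, h, c))
        pd.DataFrame(rows, columns=["plant", "herbivore", "count"]).to_csv(path, index=False)
    elif dialect == "matrix":
        pd.DataFrame(
            table.counts, index=table.plant_names, columns=table.herbivore_names
        ).to_csv(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# metadata CSVs


def read_plant_metadata(path: str | Path) -> dict[str, PlantRecord]:
    df = pd.read_csv(path, dtype=str).fillna("")
    for col in ("species", "origin"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    out: dict[str, PlantRecord] = {}
    for row in df.itertuples(index=False):
        rec = PlantRecord(
            species=row.species,
            genus=getattr(row, "genus", ""),
            family=getattr(row, "family", ""),
            origin=row.origin or "unknown",
        )
        out[rec.species] = rec
    return out


def read_herbivore_metadata(path: str | Path) -> dict[str, HerbivoreRecord]:
    df = pd.read_csv(path, dtype=str).fillna("")
    for col in ("species", "guild"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    out: dict[str, HerbivoreRecord] = {}
    for row in df.itertuples(index=False):
        rec = HerbivoreRecord(species=row.species, guild=row.guild or None)
        out[rec.species] = rec
    return out


def write_plant_metadata(records: Iterable[PlantRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.species, r.genus, r.family, r.origin) for r in records],
        columns=["species", "genus", "family", "origin"],
    ).to_csv(path, index=False)


def write_herbivore_metadata(records: Iterable[HerbivoreRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.species, r.guild or "") for r in records], columns=["species", "guild"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# dataset manifest


@dataclass
class Dataset:
    assemblages: list[Assemblage]
    tree_path: Path | None = None
    manifest: dict = field(default_factory=dict)


def load_dataset(manifest_path: str | Path) -> Dataset:
    """Load a dataset described by a YAML/JSON manifest.

    The manifest lists the tree file, metadata CSVs, and one interaction
    file per assemblage; all paths are resolved relative to the manifest.
    """
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.yaml"
    text = manifest_path.read_text()
    manifest = (
        json.loads(text) if manifest_path.suffix == ".json" else yaml.safe_load(text)
    )
    base = manifest_path.parent
    plant_lookup = (
        read_plant_metadata(base / manifest["plants"]) if "plants" in manifest else None
    )
    herb_lookup = (
        read_herbivore_metadata(base / manifest["herbivores"])
        if "herbivores" in manifest
        else None
    )
    assemblages = []
    for entry in manifest.get("assemblages", []):
        # per-assemblage metadata overrides (origin is assemblage-specific)
        entry_plants = (
            read_plant_metadata(base / entry["plants"]) if "plants" in entry else plant_lookup
        )
        entry_herbs = (
            read_herbivore_metadata(base / entry["herbivores"])
            if "herbivores" in entry
            else herb_lookup
        )
        table = read_interactions(
            base / entry["interactions"],
            dialect=entry.get("dialect", "edges"),
            plant_lookup=entry_plants,
            herbivore_lookup=entry_herbs,
        )
        skip = ("id", "interactions", "dialect", "plants", "herbivores")
        assemblages.append(
            Assemblage(
                assemblage_id=str(entry["id"]),
                table=table,
                metadata={k: v for k, v in entry.items() if k not in skip},
            )
        )
    ids = [a.assemblage_id for a in assemblages]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicated assemblage ids in manifest")
    tree_path = base / manifest["tree"] if "tree" in manifest else None
    return Dataset(assemblages=assemblages, tree_path=tree_path, manifest=manifest)


# ---------------------------------------------------------------------------
# filtering


def drop_unusable_plants(a: Assemblage) -> tuple[Assemblage, list[RemovalLogEntry]]:
    """Remove unknown-origin plants, zero-herbivore plants, and cascade.

    Herbivores whose every host was removed are removed too.  Removing an
    all-zero column cannot zero any row, so one cascade pass suffices.
    """
    t = a.table
    log: list[RemovalLogEntry] = []
    rowsum = t.counts.sum(axis=1)
    keep_p = np.ones(t.n_plants, dtype=bool)
    for i, p in enumerate(t.plants):
        if p.origin == "unknown":
            keep_p[i] = False
            log.append(RemovalLogEntry(a.assemblage_id, "plant", p.species, "origin_unknown"))
        elif rowsum[i] == 0:
            keep_p[i] = False
            log.append(RemovalLogEntry(a.assemblage_id, "plant", p.species, "no_herbivores"))
    colsum = t.counts[keep_p].sum(axis=0) if keep_p.any() else np.zeros(t.n_herbivores)
    keep_h = colsum >= 1
    for j, h in enumerate(t.herbivores):
        if not keep_h[j]:
            log.append(RemovalLogEntry(a.assemblage_id, "herbivore", h.species, "no_hosts"))
    return (
        Assemblage(a.assemblage_id, t.subset(keep_p, keep_h), dict(a.metadata)),
        log,
    )


def check_eligibility(a: Assemblage) -> EligibilityReport:
    """Apply the inclusion criteria; assumes drop_unusable_plants was run."""
    t = a.table
    n_exotic = sum(p.origin == "exotic" for p in t.plants)
    n_native = sum(p.origin == "native" for p in t.plants)
    reasons = []
    if t.n_plants < 5:
        reasons.append(REASON_MIN_PLANTS)
    if t.n_herbivores < 5:
        reasons.append(REASON_MIN_HERBIVORES)
    if t.n_plants + t.n_herbivores < 10:
        reasons.append(REASON_MIN_TOTAL)
    if n_exotic < 3:
        reasons.append(REASON_MIN_EXOTICS)
    if n_native < 1:
        reasons.append(REASON_MIN_NATIVES)
    return EligibilityReport(
        assemblage_id=a.assemblage_id,
        passed=not reasons,
        n_plants=t.n_plants,
        n_herbivores=t.n_herbivores,
        n_exotic=n_exotic,
        n_native=n_native,
        reasons=reasons,
    )


def split_by_guild(
    a: Assemblage, drop: bool = True
) -> dict[str, Assemblage]:
    """Partition an assemblage into endophage-only and exophage-only tables.

    With ``drop=True`` (default) each sub-assemblage is re-passed through
    :func:`drop_unusable_plants` so plants without interactions in that
    guild disappear.  With ``drop=False`` the raw partition is returned
    (guild sub-tables sum cell-wise to the original).
    """
    t = a.table
    for h in t.herbivores:
        if h.guild is None:
            raise ValidationError(
                f"herbivore {h.species!r} in {a.assemblage_id!r} has no guild label"
            )
    out: dict[str, Assemblage] = {}
    for guild in GUILDS:
        mask = np.array([h.guild == guild for h in t.herbivores], dtype=bool)
        sub = Assemblage(
            assemblage_id=a.assemblage_id,
            table=t.subset(np.ones(t.n_plants, dtype=bool), mask),
            metadata={**a.metadata, "guild_scope": guild},
        )
        if drop:
            sub, _ = drop_unusable_plants(sub)
        out[guild] = sub
    return out


def removal_log_frame(entries: Iterable[RemovalLogEntry]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(e) for e in entries],
                        columns=["assemblage_id", "kind", "name", "reason"])
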