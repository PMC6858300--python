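"""From species presences to community trophic structures on a grid.

A cell's trophic structure is its point in "trophic space": the vector of
species counts per guild.  Cells with low human impact are classified into
structures by fuzzy clustering (with an AMD scan to pick the structure
count), remaining cells are interpolated with a random-forest classifier,
and a PCA decomposition relates structure variation to species richness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from trophoscape.fuzzy_core import (
    AMDScanResult,
    FuzzyPartition,
    SampleMatrix,
    amd_scan,
    compute_amd,
    fit_cmeans,
)
from trophoscape.guilds import GuildAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "PresenceGrid",
    "TrophicSpace",
    "ImpactTable",
    "StructureClassification",
    "build_trophic_space",
    "filter_low_impact",
    "classify_structures",
    "interpolate_structures",
    "richness_decomposition",
]


@dataclass
class PresenceGrid:
    """Per-cell species presences (long format) with cell centre coordinates."""

    presences: pd.DataFrame  # columns: cell, species
    coords: pd.DataFrame | None = None  # columns: cell, lat, lon
    cell_roster: list[str] | None = None  # full cell set incl. species-free cells

    def __post_init__(self) -> None:
        if not {"cell", "species"}.issubset(self.presences.columns):
            raise ValueError("presences needs 'cell' and 'species' columns")

    @property
    def cells(self) -> list[str]:
        if self.cell_roster is not None:
            return list(self.cell_roster)
        return list(pd.unique(self.presences["cell"]))

    @classmethod
    def from_binary_matrix(cls, df: pd.DataFrame) -> "PresenceGrid":
        """From a cells x species 0/1 matrix (cell ids in the index).

        Cells whose row is all zeros stay on the roster (they become all-zero
        trophic-space rows, i.e. real depauperate candidates)."""
        long = df.stack()
        long = long[long > 0].reset_index()
        long.columns = ["cell", "species", "_v"]
        return cls(long[["cell", "species"]], cell_roster=[str(i) for i in df.index])

    @classmethod
    def from_csv(cls, path: str | Path) -> "PresenceGrid":
        df = pd.read_csv(path, comment="#")
        if {"cell", "species"}.issubset(df.columns):
            return cls(df[["cell", "species"]])
        return cls.from_binary_matrix(pd.read_csv(path, index_col=0, comment="#"))


@dataclass
class TrophicSpace:
    """Cells x guilds species-count matrix; richness is the row sum."""

    cell_ids: list[str]
    guild_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("guild counts must be non-negative")

    @property
    def richness(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def as_samples(self) -> SampleMatrix:
        return SampleMatrix(self.counts.astype(float), list(self.cell_ids))

    def subset(self, cell_ids: list[str]) -> "TrophicSpace":
        index = {c: i for i, c in enumerate(self.cell_ids)}
        rows = [index[c] for c in cell_ids]
        return TrophicSpace(list(cell_ids), list(self.guild_ids), self.counts[rows])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.guild_ids)
        df.insert(0, "cell_id", self.cell_ids)
        return df


@dataclass
class ImpactTable:
    """Per-cell human impact indicators (land-use percentages, population density)."""

    table: pd.DataFrame  # index: cell ids; columns include the six indicators

    REQUIRED = ["cropland", "pasture", "primary", "secondary", "urban", "population"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"impact table missing columns: {missing}")
        pct = self.table[["cropland", "pasture", "primary", "secondary", "urban"]]
        if ((pct < 0) | (pct > 100)).to_numpy().any():
            raise ValueError("land-use percentages must lie in [0, 100]")
        if (self.table["population"] < 0).any():
            raise ValueError("population density must be >= 0")

    def for_cells(self, cell_ids: list[str]) -> pd.DataFrame:
        missing = [c for c in cell_ids if c not in self.table.index]
        if missing:
            raise KeyError(f"impact records missing for cells: {missing[:10]}")
        return self.table.loc[cell_ids]


@dataclass
class StructureClassification:
    """Structure label, membership degree and provenance per cell."""

    cell_ids: list[str]
    labels: np.ndarray  # structure label (str) per cell
    membership: np.ndarray  # membership degree / vote fraction in (0, 1]
    provenance: np.ndarray  # "clustered" | "interpolated"
    partition: FuzzyPartition | None = None
    scan: AMDScanResult | None = None
    structure_names: list[str] = field(default_factory=list)

    def to_frame(self, coords: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "label": self.labels,
                "membership": self.membership,
                "provenance": self.provenance,
            }
        )
        if coords is not None:
            df = df.merge(coords, left_on="cell_id", right_on="cell", how="left").drop(
                columns=["cell"], errors="ignore"
            )
        return df

    def merged_with(self, other: "StructureClassification") -> "StructureClassification":
        return StructureClassification(
            cell_ids=list(self.cell_ids) + list(other.cell_ids),
            labels=np.concatenate([self.labels, other.labels]),
            membership=np.concatenate([self.membership, other.membership]),
            provenance=np.concatenate([self.provenance, other.provenance]),
            partition=self.partition,
            scan=self.scan,
            structure_names=self.structure_names or other.structure_names,
        )


def build_trophic_space(grid: PresenceGrid, guilds: GuildAssignment) -> TrophicSpace:
    """Count species per guild in every cell.

    Cells present in the grid but holding no species keep all-zero rows.
    Raises if any present species lacks a guild label.
    """
    guild_of = guilds.guild_of()
    present = pd.unique(grid.presences["species"])
    unknown = [s for s in present if s not in guild_of]
    if unknown:
        raise ValueError(f"species without guild assignment: {sorted(unknown)[:10]}")
    guild_names = list(dict.fromkeys(guilds.guild_names))
    df = grid.presences.assign(guild=grid.presences["species"].map(guild_of))
    tab = pd.crosstab(df["cell"], df["guild"])
    tab = tab.reindex(columns=guild_names, fill_value=0)
    cell_ids = grid.cells
    tab = tab.reindex(index=cell_ids, fill_value=0)
    return TrophicSpace(list(tab.index), guild_names, tab.to_numpy())


def filter_low_impact(
    cell_ids: list[str],
    impacts: ImpactTable,
    primary_min: float = 25.0,
    urban_max: float = 0.003,
    population_max: float = 26.0,
) -> list[str]:
    """Cells with low human impact: enough primary vegetation, almost no urban
    surface, and low population density.  Logs per-criterion exclusion counts."""
    t = impacts.for_cells(list(cell_ids))
    ok_primary = t["primary"].to_numpy() >= primary_min
    ok_urban = t["urban"].to_numpy() < urban_max
    ok_pop = t["population"].to_numpy() < population_max
    keep = ok_primary & ok_urban & ok_pop
    logger.info(
        "low-impact filter: %d/%d retained (excluded: primary %d, urban %d, population %d)",
        int(keep.sum()),
        len(cell_ids),
        int((~ok_primary).sum()),
        int((~ok_urban).sum()),
        int((~ok_pop).sum()),
    )
    return [c for c, k in zip(cell_ids, keep) if k]


def classify_structures(
    space: TrophicSpace,
    cell_ids: list[str] | None = None,
    c: int | None = None,
    c_min: int = 2,
    c_max: int = 10,
    replicates: int = 200,
    fuzzifier_m: float = 2.0,
    seed: int = 0,
) -> StructureClassification:
    """Fuzzy-classify cells into trophic structures.

    With ``c=None`` the structure count is selected by an AMD scan over
    ``[c_min, c_max]``; the best-AMD partition at the selected count supplies
    labels (maximal membership) and membership degrees.  Structure names are
    ``S0..S{c-1}`` until renamed by the caller.
    """
    sub = space if cell_ids is None else space.subset(list(cell_ids))
    n = len(sub.cell_ids)
    scan = None
    if c is None:
        scan = amd_scan(
            sub.as_samples(),
            c_min=c_min,
            c_max=min(c_max, n - 1),
            replicates=replicates,
            fuzzifier_m=fuzzifier_m,
            seed=seed,
        )
        part = scan.best_partition()
    else:
        if c > n:
            raise ValueError(f"c={c} exceeds number of cells ({n})")
        best = None
        for r in range(replicates):
            p = fit_cmeans(sub.as_samples(), c, fuzzifier_m=fuzzifier_m, seed=seed + r)
            if best is None or compute_amd(p).amd > compute_amd(best).amd:
                best = p
        part = best
    hard = part.hard_labels()
    names = [f"S{k}" for k in range(part.c)]
    return StructureClassification(
        cell_ids=list(sub.cell_ids),
        labels=np.array([names[k] for k in hard], dtype=object),
        membership=part.membership[np.arange(len(hard)), hard],
        provenance=np.full(len(hard), "clustered", dtype=object),
        partition=part,
        scan=scan,
        structure_names=names,
    )


#: Random-forest settings pinned for reproducibility.
RF_PARAMS = dict(n_estimators=500, max_features="sqrt", oob_score=True, n_jobs=1)


def interpolate_structures(
    space: TrophicSpace,
    labelled: StructureClassification,
    unlabelled_cells: list[str],
    seed: int = 0,
) -> StructureClassification:
    """Assign structures to unlabelled cells with a random forest.

    The forest is trained on guild-count vectors of the labelled cells; the
    reported membership degree of an interpolated cell is the forest's vote
    fraction for the winning structure.  Out-of-bag accuracy is logged.
    """
    train = space.subset(list(labelled.cell_ids))
    test = space.subset(list(unlabelled_cells))
    y = np.asarray(labelled.labels)
    classes = np.unique(y)
    if len(classes) < 2:
        logger.warning("single-class training set; predicting %r everywhere", classes[0])
        return StructureClassification(
            cell_ids=list(unlabelled_cells),
            labels=np.full(len(unlabelled_cells), classes[0], dtype=object),
            membership=np.ones(len(unlabelled_cells)),
            provenance=np.full(len(unlabelled_cells), "interpolated", dtype=object),
            structure_names=labelled.structure_names,
        )
    rf = RandomForestClassifier(random_state=seed, **RF_PARAMS)
    rf.fit(train.counts, y)
    logger.info("random-forest out-of-bag accuracy: %.4f", rf.oob_score_)
    proba = rf.predict_proba(test.counts)
    best = np.argmax(proba, axis=1)
    return StructureClassification(
        cell_ids=list(unlabelled_cells),
        labels=rf.classes_[best].astype(object),
        membership=proba[np.arange(len(best)), best],
        provenance=np.full(len(best), "interpolated", dtype=object),
        structure_names=labelled.structure_names,
    )


def richness_decomposition(
    space: TrophicSpace,
    cell_ids: list[str] | None = None,
) -> dict:
    """PCA of the cells x guilds matrix and the richness content of axis 1.

    Columns are centred but not variance-scaled, preserving the species-count
    (richness) interpretation of the first axis.  Returns per-axis variance
    shares, axis-1 scores, and the squared correlation between axis-1 scores
    and per-cell species richness.
    """
    sub = space if cell_ids is None else space.subset(list(cell_ids))
    X = sub.counts.astype(float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 cells for a PCA")
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("constant matrix: principal axes undefined")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    shares = var / var.sum()
    scores1 = U[:, 0] * s[0]
    rich = sub.richness.astype(float)
    r = np.corrcoef(scores1, rich)[0, 1]
    return {
        "variance_shares": shares,
        "axis1_scores": scores1,
        "loadings": Vt,
        "r2_axis1_richness": float(r**2),
    }
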