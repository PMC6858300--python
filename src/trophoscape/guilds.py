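"""Trophic guild inference from diet-composition matrices.

Species are described by the estimated percentage of each trophic resource in
their diet.  Guilds — groups of species exploiting similar resources — are
recovered by fuzzy c-means clustering of the diet vectors under Euclidean
distance; each species is then hard-assigned to its maximal-membership guild.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from trophoscape.fuzzy_core import (
    AMDScanResult,
    FuzzyPartition,
    SampleMatrix,
    amd_scan,
    compute_amd,
    fit_cmeans,
)

__all__ = [
    "DietMatrix",
    "GuildAssignment",
    "infer_guilds",
    "name_guilds",
    "select_n_guilds",
    "DEFAULT_NAMING_RULES",
]


@dataclass
class DietMatrix:
    """Species x resource table of diet percentages; rows sum to 100."""

    values: np.ndarray
    species: list[str]
    resources: list[str]

    #: tolerated deviation of a raw row sum from 100 before rejection
    sum_band: float = 0.5

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        s, r = self.values.shape
        if len(self.species) != s or len(self.resources) != r:
            raise ValueError("species/resource labels do not match matrix shape")
        if np.any(self.values < 0) or np.any(self.values > 100):
            raise ValueError("diet percentages must lie in [0, 100]")
        sums = self.values.sum(axis=1)
        bad = np.abs(sums - 100.0) > self.sum_band
        if np.any(bad):
            offenders = [f"{self.species[i]} (sum={sums[i]:.2f})" for i in np.flatnonzero(bad)]
            raise ValueError(
                f"diet rows deviate from 100 beyond the +-{self.sum_band:.2f} band: "
                + ", ".join(offenders[:10])
            )
        # renormalize the small tolerated drift away
        self.values = self.values * (100.0 / sums[:, None])

    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    def as_samples(self) -> SampleMatrix:
        return SampleMatrix(self.values, list(self.species))

    @classmethod
    def from_csv(cls, path: str | Path, sum_band: float = 0.5) -> "DietMatrix":
        df = pd.read_csv(path, index_col=0, comment="#")
        return cls(
            df.to_numpy(dtype=float),
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            sum_band=sum_band,
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.species, columns=self.resources).to_csv(
            path, index_label="species"
        )


@dataclass
class GuildAssignment:
    """Hard guild labels with fuzzy membership degrees and guild centres in diet space."""

    species: list[str]
    labels: np.ndarray  # guild index per species
    membership_degree: np.ndarray  # membership to the assigned guild, in (0, 1]
    centres: np.ndarray  # n_guilds x n_resources
    resources: list[str]
    guild_names: list[str] = field(default_factory=list)
    partition: FuzzyPartition | None = None

    def __post_init__(self) -> None:
        if not self.guild_names:
            self.guild_names = [f"guild_{k}" for k in range(self.centres.shape[0])]

    @property
    def n_guilds(self) -> int:
        return self.centres.shape[0]

    def guild_of(self) -> dict[str, str]:
        """Species id -> guild display name."""
        return {
            sp: self.guild_names[g] for sp, g in zip(self.species, self.labels)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "guild": [self.guild_names[g] for g in self.labels],
                "membership": self.membership_degree,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def infer_guilds(
    diet: DietMatrix,
    n_guilds: int,
    replicates: int = 50,
    fuzzifier_m: float = 2.0,
    seed: int = 0,
) -> GuildAssignment:
    """Cluster species into trophic guilds by fuzzy c-means on diet vectors.

    Runs ``replicates`` restarts and keeps the fit with the lowest objective;
    the hard label of a species is its maximal-membership guild.
    """
    if n_guilds < 2:
        raise ValueError("n_guilds must be >= 2")
    if n_guilds > diet.n_species:
        raise ValueError("n_guilds exceeds number of species")
    samples = diet.as_samples()
    best: FuzzyPartition | None = None
    for r in range(replicates):
        part = fit_cmeans(samples, n_guilds, fuzzifier_m=fuzzifier_m, seed=seed + r)
        if best is None or part.objective < best.objective:
            best = part
    labels = best.hard_labels()
    return GuildAssignment(
        species=list(diet.species),
        labels=labels,
        membership_degree=best.membership[np.arange(diet.n_species), labels],
        centres=best.centres,
        resources=list(diet.resources),
        partition=best,
    )


# Dominant-resource naming heuristics: (set of resources, min combined share, name).
# Checked in order; the first rule whose resources jointly dominate wins.
DEFAULT_NAMING_RULES: list[tuple[tuple[str, ...], float, str]] = [
    (("fs",), 50.0, "PS"),  # piscivores
    (("inv",), 50.0, "IF"),  # invertebrate feeders
    (("mm", "lm"), 50.0, "LC"),  # large carnivores
    (("sv", "sm"), 50.0, "SC"),  # small carnivores
    (("fr",), 50.0, "FR"),  # frugivores
    (("gr",), 60.0, "Gz"),  # grazers
    (("lv",), 60.0, "FL"),  # folivores
    (("gr", "lv"), 70.0, "MF"),  # mixed feeders (grazing and browsing)
    (("fb", "fw"), 40.0, "SH"),  # selective herbivores
    (("gr", "lv", "sd", "fb", "fr"), 75.0, "PF"),  # plant material feeders
    (("inv", "sv", "fr", "gr", "lv", "sd"), 75.0, "OM"),  # omnivores
]


def name_guilds(
    assignment: GuildAssignment,
    explicit: dict[int, str] | None = None,
    rules: list[tuple[tuple[str, ...], float, str]] | None = None,
) -> GuildAssignment:
    """Attach display names to guilds from centre composition or an explicit map.

    Heuristic rules name a guild after the first resource combination that
    dominates its centre; an explicit ``{guild_index: name}`` map overrides.
    Guilds matching no rule keep ``guild_k``.
    """
    rules = DEFAULT_NAMING_RULES if rules is None else rules
    explicit = explicit or {}
    if len(set(explicit.values())) != len(explicit):
        raise ValueError("duplicate explicit guild names")
    res_idx = {r: j for j, r in enumerate(assignment.resources)}
    names: list[str] = []
    for k in range(assignment.n_guilds):
        if k in explicit:
            names.append(explicit[k])
            continue
        centre = assignment.centres[k]
        name = f"guild_{k}"
        for res, min_share, candidate in rules:
            if candidate in names:
                continue
            share = sum(centre[res_idx[r]] for r in res if r in res_idx)
            if share >= min_share:
                name = candidate
                break
        names.append(name)
    assignment.guild_names = names
    return assignment


def select_n_guilds(
    diet: DietMatrix,
    c_min: int = 2,
    c_max: int = 15,
    replicates: int = 50,
    fuzzifier_m: float = 2.0,
    seed: int = 0,
) -> AMDScanResult:
    """AMD scan over guild counts on the diet matrix (how many guilds exist?)."""
    return amd_scan(
        diet.as_samples(),
        c_min=c_min,
        c_max=c_max,
        replicates=replicates,
        fuzzifier_m=fuzzifier_m,
        seed=seed,
    )
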