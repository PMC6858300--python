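"""Bipartite energy-flow networks between trophic resources and guilds.

For a set of species, the flux of an edge resource -> guild is the summed
diet percentage of that resource over the guild's species; a guild node's
weight is its species count, and a resource node's weight is the sum of its
outgoing fluxes (its total contribution to the web).  Total flux is
conserved: it always equals 100 x the number of species.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from trophoscape.guilds import DietMatrix, GuildAssignment
from trophoscape.structures import PresenceGrid, StructureClassification

__all__ = ["EnergyNetwork", "build_energy_network", "structure_network", "export_network"]


@dataclass
class EnergyNetwork:
    """Resource -> guild flux network for a species set."""

    guild_weights: dict[str, int]  # guild -> species count
    resource_weights: dict[str, float]  # resource -> total contribution
    edges: pd.DataFrame  # columns: resource, guild, flux (zero-flux edges omitted)
    n_species: int

    def total_flux(self) -> float:
        return float(self.edges["flux"].sum())

    def as_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for r, w in self.resource_weights.items():
            g.add_node(r, kind="resource", weight=float(w))
        for gu, w in self.guild_weights.items():
            g.add_node(gu, kind="guild", weight=int(w))
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.resource, row.guild, flux=float(row.flux))
        return g


def build_energy_network(
    species: list[str] | None,
    diet: DietMatrix,
    guilds: GuildAssignment,
) -> EnergyNetwork:
    """Build the resource -> guild energy network for the given species.

    ``species=None`` uses every species in the diet matrix.  Raises if a
    requested species has no diet row or no guild label.
    """
    if species is None:
        species = list(diet.species)
    species = list(dict.fromkeys(species))  # de-duplicate, keep order
    diet_idx = {s: i for i, s in enumerate(diet.species)}
    guild_of = guilds.guild_of()
    missing = [s for s in species if s not in diet_idx or s not in guild_of]
    if missing:
        raise ValueError(f"species missing diet or guild: {sorted(missing)[:10]}")
    if not species:
        return EnergyNetwork(
            guild_weights={},
            resource_weights={},
            edges=pd.DataFrame(columns=["resource", "guild", "flux"]),
            n_species=0,
        )

    rows = np.array([diet_idx[s] for s in species])
    labels = [guild_of[s] for s in species]
    guild_names = list(dict.fromkeys(guilds.guild_names))
    flux = pd.DataFrame(diet.values[rows], columns=diet.resources).assign(guild=labels)
    flux = flux.groupby("guild", sort=False).sum()

    edges = (
        flux.reset_index()
        .melt(id_vars="guild", var_name="resource", value_name="flux")
        .loc[lambda d: d["flux"] > 0, ["resource", "guild", "flux"]]
        .reset_index(drop=True)
    )
    guild_counts = pd.Series(labels).value_counts().to_dict()
    return EnergyNetwork(
        guild_weights={g: int(guild_counts.get(g, 0)) for g in guild_names if g in guild_counts},
        resource_weights=edges.groupby("resource")["flux"].sum().to_dict(),
        edges=edges,
        n_species=len(species),
    )


def structure_network(
    classification: StructureClassification,
    structure_label: str,
    grid: PresenceGrid,
    diet: DietMatrix,
    guilds: GuildAssignment,
) -> EnergyNetwork:
    """Energy network over the union of species present in a structure's cells.

    Each species is counted once no matter how many of the structure's cells
    it occupies.
    """
    cells = [
        c for c, lab in zip(classification.cell_ids, classification.labels)
        if lab == structure_label
    ]
    if not cells:
        raise ValueError(f"no cells carry structure label {structure_label!r}")
    pres = grid.presences
    species = pd.unique(pres.loc[pres["cell"].isin(cells), "species"]).tolist()
    return build_energy_network(species, diet, guilds)


def export_network(net: EnergyNetwork, path: str | Path, fmt: str = "graphml") -> Path:
    """Write the network as GraphML/GEXF, or as a plain edge-list CSV."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net.as_graph(), path)
    elif fmt == "gexf":
        nx.write_gexf(net.as_graph(), path)
    elif fmt == "csv":
        net.edges.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r} (graphml, gexf, csv)")
    return path
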