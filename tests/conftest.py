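"""Shared fixtures: a synthetic world, its trophic space, and one full
pipeline run, built once per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from trophoscape.pipeline import PipelineConfig, run_pipeline
from trophoscape.structures import ImpactTable, TrophicSpace
from trophoscape.synthetic_data import SyntheticWorld, generate_world

WORLD_SEED = 11


@pytest.fixture(scope="session")
def world() -> SyntheticWorld:
    return generate_world(n_cells=2000, seed=WORLD_SEED)


@pytest.fixture(scope="session")
def trophic_space(world) -> TrophicSpace:
    return TrophicSpace(
        list(world.guild_counts["cell_id"]),
        world.guilds,
        world.guild_counts[world.guilds].to_numpy(),
    )


@pytest.fixture(scope="session")
def low_impact_cells(world, trophic_space) -> list[str]:
    mask = world.low_impact_mask()
    return [c for c, m in zip(trophic_space.cell_ids, mask) if m]


@pytest.fixture(scope="session")
def impact_table(world) -> ImpactTable:
    return ImpactTable(world.cells.set_index("cell_id")[ImpactTable.REQUIRED])


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One end-to-end synthetic run; returns (config, manifest, output dir)."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(
        seed=WORLD_SEED,
        out_dir=str(out),
        n_cells=2000,
        n_species=330,
        structure_replicates=25,
        guild_replicates=10,
        tree_population=150,
        tree_generations=300,
        tree_patience=50,
    )
    manifest = run_pipeline(cfg)
    return cfg, manifest, out


def read_output(out_dir, name: str) -> pd.DataFrame:
    return pd.read_csv(out_dir / name, comment="#")
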