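"""End-to-end orchestration: simulate -> guilds -> structures -> climate tree
-> transitions -> networks, with a reproducibility manifest.

A single global seed fans out to fixed per-stage offsets so each stage can be
re-run independently; every tabular output carries the generating seed and a
parameter hash in a leading comment line, and the manifest records SHA-256
checksums of all artifacts (two runs with the same config are bit-identical).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from trophoscape import climate_tree as ct
from trophoscape import synthetic_data as sd
from trophoscape.fuzzy_core import compute_amd, fit_cmeans
from trophoscape.guilds import infer_guilds, name_guilds
from trophoscape.networks import export_network, structure_network
from trophoscape.structures import (
    ImpactTable,
    PresenceGrid,
    StructureClassification,
    TrophicSpace,
    build_trophic_space,
    classify_structures,
    filter_low_impact,
    interpolate_structures,
    richness_decomposition,
)
from trophoscape.transitions import compare_structures, impact_tree, impact_ttests, kappa_agreement

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "validate_amd_benchmark"]

# fixed per-stage seed offsets off the global seed
STAGE_SEEDS = {
    "diet": 1,
    "guilds": 2,
    "world": 3,
    "presences": 4,
    "structures": 5,
    "interpolate": 6,
    "climate_tree": 7,
    "impact_tree": 8,
}


@dataclass
class PipelineConfig:
    """Parameters of a full synthetic-mode pipeline run."""

    seed: int = 0
    out_dir: str = "trophoscape_run"
    # diet / guild stage
    n_species: int = 689
    diet_noise_sd: float = 5.0
    n_guilds: int = 11
    guild_replicates: int = 50
    # world stage
    n_cells: int = 3000
    island_fraction: float = 0.05
    overdispersion: float = 0.0
    # structure stage
    structure_c: int | None = None  # None -> AMD scan
    c_min: int = 2
    c_max: int = 10
    structure_replicates: int = 60
    fuzzifier_m: float = 2.0
    # low-impact filter
    primary_min: float = 25.0
    urban_max: float = 0.003
    population_max: float = 26.0
    # tree stages
    tree_population: int = 150
    tree_generations: int = 400
    tree_patience: int = 60
    tree_max_depth: int = 5
    tree_min_leaf: int = 10
    tree_alpha: float = 0.01
    impact_tree_max_depth: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in data:
            raise ValueError("config must set a seed")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def params_hash(self) -> str:
        params = asdict(self)
        params.pop("out_dir")  # output location must not affect content hashes
        payload = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class RunManifest:
    """Per-stage record of parameters, seeds, checksums and timings."""

    config: dict
    stages: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def add_stage(self, name: str, seed: int | None, outputs: dict[str, str],
                  seconds: float, warnings: list[str] | None = None, **extra) -> None:
        self.stages.append(
            {
                "stage": name,
                "seed": seed,
                "outputs": outputs,
                "wall_time_s": round(seconds, 3),
                "warnings": warnings or [],
                **extra,
            }
        )

    def checksums(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for st in self.stages:
            out.update(st["outputs"])
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "stages": self.stages, "summary": self.summary},
            indent=2, default=str,
        ))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, seed: int, params_hash: str, **kw) -> str:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed} params={params_hash}\n")
        df.to_csv(fh, **kw)
    return _sha256(path)


def _name_structures_by_archetype(
    classification: StructureClassification,
    space: TrophicSpace,
    archetypes: dict[str, np.ndarray],
    guild_order: list[str],
) -> StructureClassification:
    """Rename fuzzy clusters to structure names by optimally matching cluster
    centres (in guild-count space) to the archetype mean vectors."""
    part = classification.partition
    # align guild columns: archetype vectors follow guild_order
    reorder = [space.guild_ids.index(g) for g in guild_order]
    centres = part.centres[:, reorder]
    names = list(archetypes.keys())
    A = np.vstack([archetypes[n] for n in names])
    cost = cdist(centres, A)
    rows, cols = linear_sum_assignment(cost)
    mapping = {f"S{r}": names[c] for r, c in zip(rows, cols)}
    classification.labels = np.array([mapping.get(l, l) for l in classification.labels], dtype=object)
    classification.structure_names = [mapping.get(n, n) for n in classification.structure_names]
    return classification


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full synthetic pipeline and write all artifacts.

    Stages: (1) simulate diets and infer/name the trophic guilds; (2) simulate
    the gridded world and expand guild counts into species presences; (3)
    build the trophic space, filter low-impact cells, fuzzy-classify them into
    structures (AMD scan unless a count is fixed) and interpolate the rest
    with a random forest; (4) fit the evolutionary climate tree on low-impact
    mainland cells and predict all cells; (5) type observed-vs-predicted
    transitions, compute kappa, run impact t tests and impact trees; (6)
    export per-structure energy networks and the richness PCA.  A failing
    stage aborts but leaves prior outputs in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "networks").mkdir(exist_ok=True)
    seed = config.seed
    phash = config.params_hash()
    manifest = RunManifest(config=asdict(config))
    config.to_yaml(out / "config.yaml")

    # -- stage 1: diets and guilds -------------------------------------------
    t0 = time.time()
    s_diet = seed + STAGE_SEEDS["diet"]
    diet, true_guilds = sd.generate_diet_matrix(
        config.n_species, noise_sd=config.diet_noise_sd, seed=s_diet
    )
    assignment = infer_guilds(
        diet, config.n_guilds, replicates=config.guild_replicates,
        seed=seed + STAGE_SEEDS["guilds"],
    )
    assignment = name_guilds(assignment)
    diet_path = out / "diet.csv"
    diet.to_csv(diet_path)
    guilds_path = out / "guild_assignment.csv"
    cks = {
        str(diet_path): _sha256(diet_path),
        str(guilds_path): _write_csv(assignment.to_frame(), guilds_path, s_diet, phash, index=False),
    }
    manifest.add_stage("guilds", s_diet, cks, time.time() - t0,
                       n_species=config.n_species, n_guilds=config.n_guilds)

    # -- stage 2: world and presences ----------------------------------------
    t0 = time.time()
    s_world = seed + STAGE_SEEDS["world"]
    world = sd.generate_world(
        n_cells=config.n_cells,
        island_fraction=config.island_fraction,
        overdispersion=config.overdispersion,
        seed=s_world,
    )
    species_guilds = {
        sp: sd.GUILD_CODES[g] for sp, g in zip(diet.species, true_guilds)
    }
    presences = sd.generate_presences(
        world, species_guilds, seed=seed + STAGE_SEEDS["presences"]
    )
    cells_path = out / "world_cells.csv"
    counts_path = out / "guild_counts.csv"
    pres_path = out / "presences.csv"
    cks = {
        str(cells_path): _write_csv(world.cells, cells_path, s_world, phash, index=False),
        str(counts_path): _write_csv(world.guild_counts, counts_path, s_world, phash, index=False),
        str(pres_path): _write_csv(presences, pres_path, s_world, phash, index=False),
    }
    manifest.add_stage("world", s_world, cks, time.time() - t0, n_cells=world.n_cells)

    # -- stage 3: trophic space, low-impact filter, structures ----------------
    t0 = time.time()
    s_struct = seed + STAGE_SEEDS["structures"]
    grid = PresenceGrid(presences, coords=world.cells[["cell_id", "lat", "lon"]]
                        .rename(columns={"cell_id": "cell"}))
    space = build_trophic_space(grid, assignment)
    # cells with zero species never enter the presence table; restore them
    missing = [c for c in world.cells["cell_id"] if c not in set(space.cell_ids)]
    if missing:
        space = TrophicSpace(
            space.cell_ids + missing,
            space.guild_ids,
            np.vstack([space.counts, np.zeros((len(missing), len(space.guild_ids)), dtype=int)]),
        )
    impacts = ImpactTable(world.cells.set_index("cell_id")[ImpactTable.REQUIRED])
    low_cells = filter_low_impact(
        space.cell_ids, impacts,
        primary_min=config.primary_min,
        urban_max=config.urban_max,
        population_max=config.population_max,
    )
    clustered = classify_structures(
        space, low_cells,
        c=config.structure_c,
        c_min=config.c_min, c_max=config.c_max,
        replicates=config.structure_replicates,
        fuzzifier_m=config.fuzzifier_m,
        seed=s_struct,
    )
    clustered = _name_structures_by_archetype(clustered, space, world.archetypes, world.guilds)
    rest = [c for c in space.cell_ids if c not in set(low_cells)]
    interpolated = interpolate_structures(
        space, clustered, rest, seed=seed + STAGE_SEEDS["interpolate"]
    )
    classification = clustered.merged_with(interpolated)
    cls_path = out / "classification.csv"
    cks = {
        str(cls_path): _write_csv(
            classification.to_frame(grid.coords), cls_path, s_struct, phash, index=False
        ),
    }
    if clustered.scan is not None:
        curve_path = out / "amd_curve.csv"
        cks[str(curve_path)] = _write_csv(clustered.scan.amd_curve, curve_path, s_struct, phash, index=False)
    pca = richness_decomposition(space, low_cells)
    pca_path = out / "pca.json"
    pca_path.write_text(json.dumps(
        {
            "variance_shares": pca["variance_shares"].tolist(),
            "r2_axis1_richness": pca["r2_axis1_richness"],
        }, indent=2))
    cks[str(pca_path)] = _sha256(pca_path)
    manifest.add_stage(
        "structures", s_struct, cks, time.time() - t0,
        n_low_impact=len(low_cells),
        selected_c=None if clustered.scan is None else clustered.scan.selected_c,
    )

    # -- stage 4: climate tree ------------------------------------------------
    t0 = time.time()
    s_tree = seed + STAGE_SEEDS["climate_tree"]
    cell_order = {c: i for i, c in enumerate(classification.cell_ids)}
    obs_labels = np.asarray(classification.labels)
    wcells = world.cells.set_index("cell_id")
    island = wcells["island"]
    calib = [c for c in low_cells if not island.loc[c]]
    calib_labels = obs_labels[[cell_order[c] for c in calib]]
    cfg_tree = ct.EvolutionConfig(
        population_size=config.tree_population,
        generations=config.tree_generations,
        patience=config.tree_patience,
        max_depth=config.tree_max_depth,
        min_samples_leaf=config.tree_min_leaf,
        alpha=config.tree_alpha,
        seed=s_tree,
    )
    climate_model = ct.evolve_tree(wcells.loc[calib, sd.BIOCLIM_VARS], calib_labels, cfg_tree)
    all_cells = list(classification.cell_ids)
    predicted = ct.predict_tree(climate_model, wcells.loc[all_cells, sd.BIOCLIM_VARS])
    model_path = out / "climate_tree.json"
    climate_model.to_json(model_path)
    thr_path = out / "climate_thresholds.csv"
    cks = {
        str(model_path): _sha256(model_path),
        str(thr_path): _write_csv(ct.extract_thresholds(climate_model), thr_path, s_tree, phash, index=False),
    }
    manifest.add_stage(
        "climate_tree", s_tree, cks, time.time() - t0,
        misclassification=climate_model.train_misclassification,
        n_leaves=climate_model.n_leaves,
    )

    # -- stage 5: transitions -------------------------------------------------
    t0 = time.time()
    s_imp = seed + STAGE_SEEDS["impact_tree"]
    tmap = compare_structures(
        obs_labels, predicted,
        island=island.loc[all_cells].to_numpy(),
        cell_ids=all_cells,
    )
    agreement = kappa_agreement(obs_labels, predicted)
    tmap_path = out / "transitions.csv"
    agree_path = out / "agreement.json"
    agree_path.write_text(json.dumps(agreement.to_dict(), indent=2))
    cks = {
        str(tmap_path): _write_csv(tmap.table, tmap_path, seed, phash, index=False),
        str(agree_path): _sha256(agree_path),
    }
    cfg_imp = ct.EvolutionConfig(
        population_size=config.tree_population,
        generations=config.tree_generations,
        patience=config.tree_patience,
        max_depth=config.impact_tree_max_depth,
        min_samples_leaf=config.tree_min_leaf,
        alpha=config.tree_alpha,
        seed=s_imp,
    )
    extra = {}
    for dtype in ("typeI", "typeII"):
        if len(tmap.cells_of_type(dtype)) >= 2:
            tt = impact_ttests(tmap, impacts, dtype)
            tt_path = out / f"ttests_{dtype}.csv"
            cks[str(tt_path)] = _write_csv(tt.table, tt_path, seed, phash, index=False)
            model = impact_tree(tmap, impacts, dtype, cfg_imp)
            ipath = out / f"impact_tree_{dtype}.json"
            model.to_json(ipath)
            cks[str(ipath)] = _sha256(ipath)
            extra[f"{dtype}_cells"] = len(tmap.cells_of_type(dtype))
    manifest.add_stage("transitions", s_imp, cks, time.time() - t0,
                       kappa=agreement.kappa, **extra)

    # -- stage 6: energy networks --------------------------------------------
    t0 = time.time()
    cks = {}
    for label in sorted(set(map(str, classification.labels))):
        net = structure_network(classification, label, grid, diet, assignment)
        gpath = out / "networks" / f"{label}.graphml"
        export_network(net, gpath, "graphml")
        epath = out / "networks" / f"{label}_edges.csv"
        export_network(net, epath, "csv")
        cks[str(gpath)] = _sha256(gpath)
        cks[str(epath)] = _sha256(epath)
    manifest.add_stage("networks", None, cks, time.time() - t0)

    manifest.summary = {
        "selected_c": None if clustered.scan is None else clustered.scan.selected_c,
        "kappa_observed_vs_predicted": agreement.kappa,
        "climate_tree_misclassification": climate_model.train_misclassification,
        "transition_counts": tmap.counts(),
        "pca_axis1_share": float(pca["variance_shares"][0]),
        "pca_r2_axis1_richness": pca["r2_axis1_richness"],
    }
    manifest.to_json(out / "manifest.json")
    return manifest


def validate_amd_benchmark(
    n: int = 8000,
    d: int = 11,
    k: int = 6,
    c_min: int = 2,
    c_max: int = 10,
    replicates: int = 200,
    sds: tuple[float, ...] = (1.0, 1.7),
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Reproduce the AMD-index validation on computer-generated samples.

    Fits c-means to structureless uniform samples (AMD should be ~0) and
    scans the cluster-count range on planted-cluster benchmarks at each sd
    in ``sds`` (the peak should sit at the planted count, lower for fuzzier
    clusters).  Returns curves and peak values; optionally writes them as CSV.
    """
    from trophoscape.fuzzy_core import amd_scan

    report: dict = {"n": n, "d": d, "k": k}
    uniform = sd.generate_random_samples(n, d, seed=seed)
    amds = [
        compute_amd(fit_cmeans(uniform, k, seed=seed + r)).amd for r in range(20)
    ]
    report["uniform_random_amd"] = float(max(amds))

    curves = {}
    for s in sds:
        bench = sd.generate_cluster_benchmark(n, d, k, sd=s, seed=seed)
        scan = amd_scan(bench.samples, c_min, c_max, replicates=replicates, seed=seed)
        curves[s] = scan.amd_curve
        report[f"selected_c_sd{s:g}"] = scan.selected_c
        report[f"peak_amd_sd{s:g}"] = float(scan.amd_curve["best_amd"].max())
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for s, curve in curves.items():
            curve.to_csv(out / f"amd_curve_sd{s:g}.csv", index=False)
        (out / "amd_validation.json").write_text(json.dumps(report, indent=2))
    report["curves"] = curves
    return report
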