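"""Trophic space construction, low-impact filtering, structure classification,
random-forest interpolation, and the richness PCA."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from trophoscape.guilds import GuildAssignment
from trophoscape.structures import (
    ImpactTable,
    PresenceGrid,
    TrophicSpace,
    build_trophic_space,
    classify_structures,
    filter_low_impact,
    interpolate_structures,
    richness_decomposition,
)
from trophoscape.synthetic_data import default_structure_archetypes


def tiny_assignment() -> GuildAssignment:
    species = ["A", "B", "C", "D"]
    labels = np.array([0, 0, 1, 2])
    return GuildAssignment(
        species=species,
        labels=labels,
        membership_degree=np.ones(4),
        centres=np.zeros((3, 2)),
        resources=["gr", "fs"],
        guild_names=["OM", "LC", "PS"],
    )


class TestBuildTrophicSpace:
    def test_counts_per_guild(self):
        grid = PresenceGrid(pd.DataFrame({"cell": ["c1", "c1", "c1"], "species": ["A", "B", "C"]}))
        space = build_trophic_space(grid, tiny_assignment())
        assert space.guild_ids == ["OM", "LC", "PS"]
        np.testing.assert_array_equal(space.counts, [[2, 1, 0]])

    def test_empty_cell_kept_as_zero_row(self):
        matrix = pd.DataFrame(
            [[1, 0], [0, 0]], index=["c1", "c_empty"], columns=["A", "C"]
        )
        grid = PresenceGrid.from_binary_matrix(matrix)
        space = build_trophic_space(grid, tiny_assignment())
        assert "c_empty" in space.cell_ids
        row = space.counts[space.cell_ids.index("c_empty")]
        np.testing.assert_array_equal(row, [0, 0, 0])

    def test_richness_equals_species_count(self, world, trophic_space):
        np.testing.assert_array_equal(
            trophic_space.richness,
            world.guild_counts[world.guilds].sum(axis=1).to_numpy(),
        )

    def test_unassigned_species_rejected(self):
        grid = PresenceGrid(pd.DataFrame({"cell": ["c1"], "species": ["mystery"]}))
        with pytest.raises(ValueError, match="mystery"):
            build_trophic_space(grid, tiny_assignment())


class TestFilterLowImpact:
    @staticmethod
    def impacts() -> ImpactTable:
        return ImpactTable(
            pd.DataFrame(
                {
                    "cropland": [5.0] * 4,
                    "pasture": [5.0] * 4,
                    "primary": [20.0, 30.0, 30.0, 30.0],  # cell 0 violates primary
                    "secondary": [5.0] * 4,
                    "urban": [0.001, 0.01, 0.001, 0.001],  # cell 1 violates urban
                    "population": [10.0, 10.0, 30.0, 10.0],  # cell 2 violates pop
                },
                index=["c0", "c1", "c2", "c3"],
            )
        )

    def test_one_violation_each_leaves_one_cell(self):
        kept = filter_low_impact(["c0", "c1", "c2", "c3"], self.impacts())
        assert kept == ["c3"]

    def test_idempotent_and_order_independent(self):
        imp = self.impacts()
        kept = filter_low_impact(["c2", "c0", "c3", "c1"], imp)
        assert filter_low_impact(kept, imp) == kept
        assert set(kept) == set(filter_low_impact(["c0", "c1", "c2", "c3"], imp))

    def test_missing_cell_record_rejected(self):
        with pytest.raises(KeyError):
            filter_low_impact(["c0", "nope"], self.impacts())


class TestClassifyStructures:
    def test_planted_structures_recovered(self, world, trophic_space, low_impact_cells):
        """The AMD scan finds the six planted structures on low-impact cells and
        the best partition matches the planted labels almost perfectly."""
        cls = classify_structures(
            trophic_space, low_impact_cells, replicates=15, seed=0
        )
        assert cls.scan.selected_c == 6
        truth = dict(zip(world.cells["cell_id"], world.cells["observed_label"]))
        ari = adjusted_rand_score([truth[c] for c in cls.cell_ids], cls.labels)
        assert ari >= 0.9

    def test_identical_cells_single_structure(self):
        space = TrophicSpace([f"c{i}" for i in range(8)], ["g1", "g2"], np.ones((8, 2)))
        cls = classify_structures(space, c=1, replicates=2, seed=0)
        assert np.allclose(cls.membership, 1.0)
        assert len(set(cls.labels)) == 1

    def test_labels_stable_across_seeds_up_to_permutation(self, trophic_space, low_impact_cells):
        a = classify_structures(trophic_space, low_impact_cells, c=6, replicates=8, seed=0)
        b = classify_structures(trophic_space, low_impact_cells, c=6, replicates=8, seed=123)
        assert adjusted_rand_score(a.labels, b.labels) > 0.95

    def test_more_clusters_than_cells_rejected(self):
        space = TrophicSpace(["c1", "c2"], ["g"], np.array([[1], [2]]))
        with pytest.raises(ValueError):
            classify_structures(space, c=5, replicates=1)


class TestInterpolateStructures:
    def test_holdout_accuracy(self, world, trophic_space, low_impact_cells):
        """A forest trained on 80% of the labelled cells recovers >= 95% of the
        held-out labels."""
        truth = dict(zip(world.cells["cell_id"], world.cells["observed_label"]))
        rng = np.random.default_rng(0)
        cells = list(low_impact_cells)
        rng.shuffle(cells)
        cut = int(0.8 * len(cells))
        train, test = cells[:cut], cells[cut:]
        labelled = classify_structures(trophic_space, train, c=6, replicates=8, seed=0)
        # use planted names for the clusters via majority vote per cluster
        frame = pd.DataFrame({"cell": labelled.cell_ids, "cluster": labelled.labels})
        frame["truth"] = frame["cell"].map(truth)
        mapping = frame.groupby("cluster")["truth"].agg(lambda s: s.mode()[0]).to_dict()
        labelled.labels = np.array([mapping[l] for l in labelled.labels], dtype=object)
        pred = interpolate_structures(trophic_space, labelled, test, seed=1)
        acc = np.mean([truth[c] == l for c, l in zip(pred.cell_ids, pred.labels)])
        assert acc >= 0.95
        assert set(pred.provenance) == {"interpolated"}
        assert np.all((pred.membership > 0) & (pred.membership <= 1))

    def test_archetype_mean_cell_gets_its_label(self, world, trophic_space, low_impact_cells):
        truth = dict(zip(world.cells["cell_id"], world.cells["observed_label"]))
        labelled = classify_structures(trophic_space, low_impact_cells, c=6, replicates=8, seed=0)
        frame = pd.DataFrame({"cell": labelled.cell_ids, "cluster": labelled.labels})
        frame["truth"] = frame["cell"].map(truth)
        mapping = frame.groupby("cluster")["truth"].agg(lambda s: s.mode()[0]).to_dict()
        labelled.labels = np.array([mapping[l] for l in labelled.labels], dtype=object)

        arch = default_structure_archetypes()
        probes = np.vstack([np.round(arch[k]) for k in arch])
        probe_space = TrophicSpace(
            list(trophic_space.cell_ids) + [f"probe_{k}" for k in arch],
            trophic_space.guild_ids,
            np.vstack([trophic_space.counts, probes]),
        )
        pred = interpolate_structures(
            probe_space, labelled, [f"probe_{k}" for k in arch], seed=0
        )
        for name, got in zip(arch, pred.labels):
            assert got == name

    def test_single_class_training_predicts_that_class(self, trophic_space):
        from trophoscape.structures import StructureClassification

        cells = trophic_space.cell_ids
        labelled = StructureClassification(
            cell_ids=cells[:50],
            labels=np.array(["only"] * 50, dtype=object),
            membership=np.ones(50),
            provenance=np.full(50, "clustered", dtype=object),
        )
        pred = interpolate_structures(trophic_space, labelled, cells[50:60], seed=0)
        assert set(pred.labels) == {"only"}


class TestRichnessDecomposition:
    def test_rank_one_matrix(self):
        profile = np.array([3.0, 1.0, 0.5])
        X = np.outer(np.arange(1, 7, dtype=float), profile)
        space = TrophicSpace([f"c{i}" for i in range(6)], ["a", "b", "c"], X)
        rep = richness_decomposition(space)
        assert rep["variance_shares"][0] == pytest.approx(1.0)
        assert rep["r2_axis1_richness"] == pytest.approx(1.0)

    def test_shares_sum_to_one(self, trophic_space):
        rep = richness_decomposition(trophic_space)
        assert rep["variance_shares"].sum() == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.poisson(5.0, size=(100, 11)).astype(float)
        space = TrophicSpace([f"c{i}" for i in range(100)], [f"g{j}" for j in range(11)], X)
        rep = richness_decomposition(space)
        evals = np.linalg.eigvalsh(np.cov(X, rowvar=False, ddof=1))[::-1]
        np.testing.assert_allclose(rep["variance_shares"], evals / evals.sum(), atol=1e-8)

    def test_degenerate_inputs_rejected(self):
        space = TrophicSpace(["c1", "c2", "c3"], ["g"], np.ones((3, 1)))
        with pytest.raises(ValueError):
            richness_decomposition(space)
        small = TrophicSpace(["c1", "c2"], ["g"], np.array([[1], [2]]))
        with pytest.raises(ValueError):
            richness_decomposition(small)
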