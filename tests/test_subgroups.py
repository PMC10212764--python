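"""Map partitioning, subgroup labelling, profiles and prediction."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from metabotrace import (
    SOMModel,
    SubgroupBoundary,
    assign_subgroups,
    auto_partition,
    label_partition,
    predict_subgroups,
    ring_lattice,
    subgroup_profiles,
)


def quadrant_model(sep=6.0):
    """91-district map whose prototypes form four blobs by lattice quadrant."""
    pos = ring_lattice(5)
    quad = (pos[:, 0] >= 0).astype(int) * 2 + (pos[:, 1] >= 0).astype(int)
    rng = np.random.default_rng(0)
    prototypes = np.zeros((len(pos), 4))
    for q in range(4):
        prototypes[quad == q] = np.eye(4)[q] * sep
    prototypes += 0.05 * rng.normal(size=prototypes.shape)
    return SOMModel(pos, prototypes, [f"f{i}" for i in range(4)]), quad


class TestAssignSubgroups:
    def test_all_districts_one_label(self):
        model, _ = quadrant_model()
        boundary = SubgroupBoundary(
            {d: "TG-rich" for d in range(model.n_districts)}
        )
        labels = assign_subgroups(np.array([0, 5, 88]), boundary)
        assert (labels == "TG-rich").all()

    def test_counts_preserved_and_pure_function(self):
        model, quad = quadrant_model()
        names = ["TG-rich", "TG-poor", "High LDL-C", "Low lipid"]
        boundary = SubgroupBoundary({d: names[quad[d]] for d in range(91)})
        rng = np.random.default_rng(1)
        assignments = rng.integers(0, 91, 500)
        labels = assign_subgroups(assignments, boundary)
        assert len(labels) == 500
        perm = rng.permutation(500)
        labels_perm = assign_subgroups(assignments[perm], boundary)
        assert (labels_perm.to_numpy() == labels.to_numpy()[perm]).all()

    def test_unmapped_district_raises(self):
        boundary = SubgroupBoundary({0: "TG-rich"})
        with pytest.raises(KeyError, match="without a subgroup"):
            assign_subgroups(np.array([0, 3]), boundary)

    def test_boundary_json_roundtrip(self, tmp_path):
        boundary = SubgroupBoundary({0: "TG-rich", 1: "TG-poor", 2: "High LDL-C",
                                     3: "Low lipid"}, provenance="committee file")
        path = tmp_path / "b.json"
        boundary.to_json(path)
        back = SubgroupBoundary.from_json(path)
        assert back.mapping == boundary.mapping
        assert back.provenance == "committee file"


class TestAutoPartition:
    def test_k1_single_label(self):
        model, _ = quadrant_model()
        assert set(auto_partition(model, k=1)) == {0}

    def test_four_blobs_recovered_contiguously(self):
        model, quad = quadrant_model()
        clusters = auto_partition(model, k=4, seed=0)
        assert adjusted_rand_score(quad, clusters) == pytest.approx(1.0)

    def test_isolated_island_absorbed(self):
        model, quad = quadrant_model()
        clusters = auto_partition(model, k=4, seed=0)
        # corrupt one interior district into a foreign single-district island
        island = 45
        foreign = (clusters[island] + 1) % 4
        corrupted = clusters.copy()
        corrupted[island] = foreign
        model2 = SOMModel(model.positions, model.prototypes.copy(),
                          model.feature_names)
        model2.prototypes[island] = np.eye(4)[foreign] * 6.0
        repaired = auto_partition(model2, k=4, seed=0)
        assert repaired[island] == clusters[island]

    def test_regions_lattice_contiguous_after_repair(self, rng):
        # irregular prototypes: force fragmented k-means then check repair
        pos = ring_lattice(4)
        prototypes = rng.normal(size=(len(pos), 3))
        model = SOMModel(pos, prototypes, list("abc"))
        clusters = auto_partition(model, k=3, seed=0)
        neighbors = model.lattice_neighbors()
        for c in np.unique(clusters):
            nodes = set(np.flatnonzero(clusters == c))
            start = next(iter(nodes))
            seen, stack = {start}, [start]
            while stack:
                i = stack.pop()
                for j in neighbors[i]:
                    if j in nodes and j not in seen:
                        seen.add(j)
                        stack.append(j)
            assert seen == nodes, f"cluster {c} not contiguous"

    def test_k_validation(self):
        model, _ = quadrant_model()
        with pytest.raises(ValueError):
            auto_partition(model, k=0)
        with pytest.raises(ValueError):
            auto_partition(model, k=92)


class TestLabelPartition:
    def test_biochemical_rule_names_regions(self):
        model, quad = quadrant_model()
        rng = np.random.default_rng(2)
        assignments = rng.integers(0, 91, 2000)
        region = quad[assignments]
        # region 3: TG-richest; region 0: TG-poorest; of 1 and 2, region 1 has
        # the higher LDL-C
        tg = np.select([region == 3, region == 0], [1.5, -1.5], 0.0)
        ldl = np.select([region == 1, region == 2], [1.0, -1.0], 0.0)
        ref = pd.DataFrame({"tg_chol_ratio": tg + 0.01 * rng.normal(size=2000),
                            "ldl_c": ldl + 0.01 * rng.normal(size=2000)})
        boundary = label_partition(quad, assignments, ref)
        by_region = {quad[d]: lab for d, lab in boundary.mapping.items()}
        assert by_region == {3: "TG-rich", 0: "TG-poor", 1: "High LDL-C",
                             2: "Low lipid"}


class TestSubgroupProfiles:
    def test_constant_measure_zero_width_ci(self):
        values = pd.DataFrame({"m": np.full(80, 2.5)})
        labels = np.repeat(["a", "b"], 40)
        prof = subgroup_profiles(values, labels, n_boot=200, seed=0)
        assert (prof["ci_high"] - prof["ci_low"]).abs().max() < 1e-12
        assert prof["n"].sum() == 80

    def test_separated_subgroups_have_disjoint_cis(self, rng):
        values = pd.DataFrame(
            {"m": np.concatenate([rng.normal(0, 1, 500), rng.normal(1, 1, 500)])}
        )
        labels = np.repeat(["lo", "hi"], 500)
        prof = subgroup_profiles(values, labels, n_boot=500, seed=1).set_index(
            "subgroup"
        )
        assert prof.loc["lo", "ci_high"] < prof.loc["hi", "ci_low"]

    def test_bootstrap_ci_covers_true_mean(self, rng):
        """Coverage of the subject-bootstrap CI is ~95%."""
        hits = 0
        reps = 500
        for rep in range(reps):
            vals = pd.DataFrame({"m": rng.normal(0.3, 1.0, 60)})
            prof = subgroup_profiles(vals, np.full(60, "g"), n_boot=250, seed=rep)
            hits += int(prof["ci_low"][0] <= 0.3 <= prof["ci_high"][0])
        assert 0.92 <= hits / reps <= 0.98

    def test_empty_subgroup_and_min_boot(self):
        values = pd.DataFrame({"m": np.arange(10.0)})
        with pytest.raises(ValueError, match="n_boot"):
            subgroup_profiles(values, np.full(10, "g"), n_boot=10)


class TestPredictSubgroups:
    def test_separable_classes_high_accuracy(self, rng):
        n = 400
        y = np.repeat(list("abcd"), n // 4)
        x = pd.DataFrame(np.eye(4)[np.arange(n) // (n // 4)] * 4.0
                         + rng.normal(size=(n, 4)) * 0.3)
        x.columns = [f"f{i}" for i in range(4)]
        res = predict_subgroups(x, y, cv_folds=5, seed=0)
        assert res.accuracy > 0.95

    def test_permuted_labels_near_chance(self, rng):
        n = 2000
        y = rng.permutation(np.repeat(list("abcd"), n // 4))
        x = pd.DataFrame(rng.normal(size=(n, 10)),
                         columns=[f"f{i}" for i in range(10)])
        res = predict_subgroups(x, y, cv_folds=10, seed=0)
        assert abs(res.accuracy - 0.25) < 0.03

    def test_panel_compared_with_itself_not_significant(self, rng):
        n = 300
        y = np.repeat(list("ab"), n // 2)
        x = pd.DataFrame(
            {"f0": (y == "a") + rng.normal(size=n) * 1.0,
             "f1": rng.normal(size=n)}
        )
        res = predict_subgroups(x, y, panel=["f0", "f1"],
                                comparison_panel=["f0", "f1"], cv_folds=5, seed=3)
        assert res.comparison_p > 0.2

    def test_true_labels_beat_permuted_over_seeds(self, rng):
        wins = 0
        n = 240
        for s in range(10):
            r = np.random.default_rng(s)
            y = np.repeat(list("abcd"), n // 4)
            x = pd.DataFrame(
                np.eye(4)[np.arange(n) // (n // 4)] * 1.2 + r.normal(size=(n, 4))
            )
            x.columns = [f"f{i}" for i in range(4)]
            true_acc = predict_subgroups(x, y, cv_folds=4, seed=s).accuracy
            perm_acc = predict_subgroups(x, r.permutation(y), cv_folds=4,
                                         seed=s).accuracy
            wins += int(true_acc >= perm_acc)
        assert wins >= 9

    def test_fold_count_validation(self, rng):
        y = np.array(["a"] * 3 + ["b"] * 50)
        x = pd.DataFrame({"f": rng.normal(size=53)})
        with pytest.raises(ValueError, match="smallest class"):
            predict_subgroups(x, y, cv_folds=5)
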