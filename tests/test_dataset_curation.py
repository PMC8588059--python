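import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from glycofit.dataset_curation import (
    charge_statistics,
    deduplicate,
    filter_lj_outliers,
    rmsd,
    split,
)
from glycofit.forcefield_io import Conformer, ConformerSet


class TestRmsd:
    def test_identical_structures(self, chair_coords):
        assert rmsd(chair_coords, chair_coords) == pytest.approx(0.0, abs=1e-12)

    def test_translation_literal_vs_superposed(self, chair_coords):
        shifted = chair_coords + np.array([1.0, 0.0, 0.0])
        assert rmsd(chair_coords, shifted, superpose=False) == pytest.approx(1.0)
        assert rmsd(chair_coords, shifted, superpose=True) == pytest.approx(0.0, abs=1e-9)

    def test_two_atom_literal_value(self):
        x = np.zeros((2, 3))
        y = np.array([[0.3, 0.3, 0.3], [0.4, 0.4, 0.4]])
        expected = np.sqrt((3 * 0.3**2 + 3 * 0.4**2) / 2)
        assert rmsd(x, y, superpose=False) == pytest.approx(expected)

    def test_rotation_invisible_when_superposed(self, chair_coords):
        rot = chair_coords @ Rotation.random(random_state=1).as_matrix().T
        assert rmsd(chair_coords, rot, superpose=True) == pytest.approx(0.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmsd(np.zeros((0, 3)), np.zeros((0, 3)))


class TestDeduplicate:
    def _set(self, topology, coords_list):
        return ConformerSet(
            [Conformer(f"s{i}", c) for i, c in enumerate(coords_list)], topology
        )

    def test_exact_copies_collapse_to_one(self, topology, chair_coords):
        cs = self._set(topology, [chair_coords] * 3)
        kept, rep = deduplicate(cs)
        assert kept.ids == ["s0"]
        assert rep.removed_duplicates == [("s1", "s0"), ("s2", "s0")]

    def test_threshold_is_inclusive(self, topology, chair_coords):
        # a uniform displacement of every atom by d gives superposed RMSD 0;
        # instead displace one atom so the RMSD is exactly computable
        other = chair_coords.copy()
        n = chair_coords.shape[0]
        bumped = rmsd(chair_coords, other)  # 0
        other[0] += np.array([0.05 * np.sqrt(n), 0, 0])
        r = rmsd(chair_coords, other, superpose=False)
        assert r == pytest.approx(0.05, abs=1e-12)
        kept, rep = deduplicate(self._set(topology, [chair_coords, other]), threshold=r, superpose=False)
        assert kept.ids == ["s0"]

    def test_distinct_structures_all_retained(self, small_dataset):
        kept, rep = deduplicate(small_dataset)
        assert rep.removed_duplicate_count == 0
        assert kept.ids == small_dataset.ids

    def test_idempotent(self, topology, chair_coords, small_dataset):
        cs = ConformerSet(
            small_dataset.conformers + [Conformer("dup", small_dataset[0].coordinates.copy())],
            topology,
        )
        once, rep1 = deduplicate(cs)
        assert rep1.removed_duplicate_count == 1
        twice, rep2 = deduplicate(once)
        assert rep2.removed_duplicate_count == 0

    def test_frame_independent_with_superposition(self, topology, small_dataset, rng):
        rotated = [
            Conformer(
                c.id,
                c.coordinates @ Rotation.random(random_state=i).as_matrix().T
                + rng.normal(0, 3.0, 3),
            )
            for i, c in enumerate(small_dataset.conformers)
        ]
        cs = ConformerSet(small_dataset.conformers + rotated, topology)
        kept, rep = deduplicate(cs)
        assert rep.removed_duplicate_count == len(small_dataset)


class TestLjOutliers:
    def test_identical_structures_none_removed(self, topology, chair_coords, start_params):
        cs = ConformerSet([Conformer(f"s{i}", chair_coords) for i in range(5)], topology)
        kept, rep = filter_lj_outliers(cs, start_params)
        assert rep.removed_outlier_count == 0

    def test_steric_clash_removed_under_default_rule(
        self, topology, small_dataset, start_params
    ):
        clash = small_dataset[0].coordinates.copy()
        i, j = topology.index("O2"), topology.index("O4")
        clash[j] = clash[i] + np.array([0.5, 0.0, 0.0])  # r^-12 blow-up
        cs = ConformerSet(
            small_dataset.conformers + [Conformer("clash", clash)], topology
        )
        kept, rep = filter_lj_outliers(cs, start_params)
        assert [i for i, _ in rep.removed_outliers] == ["clash"]
        assert rep.removed_outliers[0][1] > 1e3

    def test_disabled_rule_removes_nothing(self, small_dataset, start_params):
        _, rep = filter_lj_outliers(small_dataset, start_params, iqr_factor=None)
        assert rep.removed_outlier_count == 0


class TestSplit:
    def test_seven_three_sizes(self, small_dataset):
        train, test = split(small_dataset, 0.7, seed=1)
        assert len(train) == 42 and len(test) == 18
        assert sorted(train + test) == list(range(60))

    def test_same_seed_reproducible(self, small_dataset):
        assert split(small_dataset, seed=3) == split(small_dataset, seed=3)

    @pytest.mark.parametrize("seed", range(8))
    def test_reference_always_in_train(self, small_dataset, seed):
        train, _ = split(small_dataset, seed=seed)
        assert small_dataset.reference_index in train


class TestChargeStatistics:
    def test_identical_sets_have_zero_sd(self, topology, chair_coords, truth_params):
        q = truth_params.charge_vector(topology)
        cs = ConformerSet(
            [Conformer(f"s{i}", chair_coords, None, q.copy()) for i in range(4)], topology
        )
        stats = charge_statistics(cs)
        assert all(v == 0.0 for v in stats.sd.values())
        assert stats.mean["O5"] == pytest.approx(truth_params.charges["O5"])
        assert stats.sample_count == 4

    def test_two_point_statistics(self, topology, chair_coords):
        q1 = np.zeros(24)
        q2 = np.zeros(24)
        i = topology.index("O5")
        q1[i], q2[i] = 0.1, 0.3
        cs = ConformerSet(
            [Conformer("a", chair_coords, None, q1), Conformer("b", chair_coords, None, q2)],
            topology,
        )
        stats = charge_statistics(cs)
        assert stats.mean["O5"] == pytest.approx(0.2)
        assert stats.sd["O5"] == pytest.approx(0.1)  # population SD

    def test_nonzero_aliphatic_hydrogen_rejected(self, topology, chair_coords):
        q = np.zeros(24)
        q[topology.index("H1")] = 0.01
        cs = ConformerSet(
            [Conformer("a", chair_coords, None, q), Conformer("b", chair_coords, None, q)],
            topology,
        )
        with pytest.raises(ValueError, match="H1"):
            charge_statistics(cs)

    def test_recovers_generating_distribution(self, topology):
        from glycofit.synthetic_data import (
            GeneratorConfig,
            emulate_resp_sets,
            generate_conformers,
            ground_truth_parameters,
        )

        cs = generate_conformers(GeneratorConfig(n_structures=1000, seed=5, jitter_sigma=0.0))
        truth = ground_truth_parameters()
        cs = emulate_resp_sets(cs, truth.charges, 0.03, seed=6)
        stats = charge_statistics(cs)
        se_mean = 0.03 / np.sqrt(1000)
        for label, mu in stats.mean.items():
            assert abs(mu - truth.charges[label]) < 3 * se_mean
            assert abs(stats.sd[label] - 0.03) < 3 * 0.03 / np.sqrt(2 * 1000)
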