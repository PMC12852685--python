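"""Cohort generation, preprocessing and splitting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qheart.cohort import (
    CONTINUOUS_FEATURES,
    COLUMN_ORDER,
    CohortSpec,
    encode_dataset,
    encode_labels,
    generate_cohort,
    one_hot,
    read_cohort_csv,
    scale_to_angle,
    split_train_test,
    standardize,
    subsample_fraction,
    write_cohort_csv,
)


class TestGeneration:
    def test_default_size_and_schema(self, default_cohort):
        _, table = default_cohort
        assert len(table) == 918
        assert list(table.columns) == COLUMN_ORDER
        assert not table.isna().any().any()
        assert not table.duplicated().any()

    def test_prevalence_near_55_percent(self, default_cohort):
        # binomial 99% interval around 0.55 at n=918 is roughly +/- 0.042
        _, table = default_cohort
        prev = table.HeartDisease.mean()
        half = 2.576 * math.sqrt(0.55 * 0.45 / 918)
        assert abs(prev - 0.55) < half

    def test_continuous_means_within_four_se(self, default_cohort):
        spec, table = default_cohort
        for name in CONTINUOUS_FEATURES:
            m = spec.continuous_marginals[name]
            se = m.sd / math.sqrt(len(table))
            # clipping to [min, max] shifts the mean slightly; 4 SE still holds
            assert abs(table[name].mean() - m.mean) < 4 * se, name

    def test_ranges_respected(self, default_cohort):
        spec, table = default_cohort
        for name in CONTINUOUS_FEATURES:
            m = spec.continuous_marginals[name]
            assert table[name].min() >= m.min
            assert table[name].max() <= m.max

    def test_correlation_signs(self, default_cohort):
        _, table = default_cohort
        assert np.corrcoef(table.Age, table.MaxHR)[0, 1] < 0
        assert np.corrcoef(table.Age, table.Oldpeak)[0, 1] > 0

    def test_correlation_signs_across_seeds(self):
        # sign fidelity in at least 95 of 100 seeded cohorts (small n for speed)
        spec = CohortSpec(n_records=300)
        hits = 0
        for seed in range(100):
            t = generate_cohort(spec, seed=seed)
            if (np.corrcoef(t.Age, t.MaxHR)[0, 1] < 0
                    and np.corrcoef(t.Age, t.Oldpeak)[0, 1] > 0):
                hits += 1
        assert hits >= 95

    def test_determinism(self):
        spec = CohortSpec(n_records=100)
        pd.testing.assert_frame_equal(
            generate_cohort(spec, seed=3), generate_cohort(spec, seed=3)
        )

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(CohortSpec(n_records=0))
        with pytest.raises(ValueError):
            generate_cohort(CohortSpec(target_prevalence=1.5))
        bad = CohortSpec()
        bad.categorical_levels["Sex"] = {"M": 0.6, "F": 0.5}
        with pytest.raises(ValueError):
            generate_cohort(bad)

    def test_config_roundtrip(self, tmp_path):
        spec = CohortSpec(n_records=200, target_prevalence=0.6, seed=9)
        path = tmp_path / "cohort.yaml"
        spec.to_yaml(path)
        again = CohortSpec.from_yaml(path)
        assert again == spec

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            CohortSpec.from_dict({"n_records": 10, "typo_key": 1})


class TestStandardize:
    def test_constant_shift_to_zero(self):
        z, _ = standardize([5.0, 5.0, 7.0, 3.0])
        assert z[np.isclose([5, 5, 7, 3], 5.0)][0] == pytest.approx(0.0)

    def test_fitted_moments(self, rng):
        z, _ = standardize(rng.normal(10, 3, size=500))
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_hand_computed_example(self):
        # x = (1,2,3): mu = 2, sigma = sqrt(2/3)
        sigma = math.sqrt(2.0 / 3.0)
        z, stats = standardize([1.0, 2.0, 3.0])
        np.testing.assert_allclose(z, [-1 / sigma, 0.0, 1 / sigma])
        assert stats == (2.0, pytest.approx(sigma))

    def test_fit_stats_reused(self):
        _, stats = standardize([0.0, 10.0])
        z, _ = standardize([5.0], fit_stats=stats)
        assert z[0] == pytest.approx(0.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            standardize([4.0, 4.0, 4.0])


class TestScaleToAngle:
    def test_endpoints_and_midpoint(self):
        v, _ = scale_to_angle([0.0, 5.0, 10.0])
        np.testing.assert_allclose(v, [0.0, math.pi, 2 * math.pi])

    def test_out_of_range_clipped(self):
        _, fit = scale_to_angle([0.0, 10.0])
        v, _ = scale_to_angle([-3.0, 12.0], fit_range=fit)
        assert v[0] == pytest.approx(0.0)
        assert v[1] == pytest.approx(2 * math.pi)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            scale_to_angle([2.0, 2.0])


class TestOneHot:
    def test_full_scheme(self):
        m = one_hot(["a", "b", "c", "a"], ["a", "b", "c"], scheme="full")
        assert m.shape == (4, 3)
        np.testing.assert_array_equal(m.sum(axis=1), 1)

    def test_drop_first(self):
        m = one_hot(["a", "b", "c"], ["a", "b", "c"], scheme="drop_first")
        assert m.shape == (3, 2)
        assert m.sum(axis=1).max() <= 1

    def test_study_categoricals_give_ten_bits(self, encoded):
        # 6 categoricals under drop_first: 1+3+1+2+1+2 = 10 bit columns
        assert encoded.basis_block.shape[1] == 10

    def test_unseen_level_rejected(self):
        with pytest.raises(ValueError, match="unseen"):
            one_hot(["a", "z"], ["a", "b"])


class TestLabels:
    def test_stated_mapping(self):
        np.testing.assert_array_equal(encode_labels([0, 1, 1]), [-1, 1, 1])

    def test_roundtrip(self, rng):
        y = rng.integers(0, 2, size=50)
        np.testing.assert_array_equal((encode_labels(y) + 1) // 2, y)

    def test_empty(self):
        assert encode_labels([]).size == 0

    def test_bad_values(self):
        with pytest.raises(ValueError):
            encode_labels([0, 2])


class TestSplit:
    def test_printed_split_sizes(self, default_cohort):
        _, table = default_cohort
        tr, te = split_train_test(table, 0.7, seed=0)
        assert (tr.size, te.size) == (643, 275)

    def test_small_n(self):
        t = pd.DataFrame({"x": range(10)})
        tr, te = split_train_test(t, 0.7, seed=1)
        assert (tr.size, te.size) == (7, 3)

    def test_fraction_one_empty_test(self):
        t = pd.DataFrame({"x": range(5)})
        tr, te = split_train_test(t, 1.0, seed=0)
        assert te.size == 0 and tr.size == 5

    @given(n=st.integers(1, 1000))
    @settings(max_examples=60, deadline=None)
    def test_ceiling_rule_all_n(self, n):
        t = pd.DataFrame({"x": range(n)})
        tr, te = split_train_test(t, 0.7, seed=0)
        assert tr.size == math.ceil(0.7 * n)
        assert np.intersect1d(tr, te).size == 0
        assert tr.size + te.size == n


class TestSubsample:
    def test_ten_percent_of_643(self):
        idx = np.arange(643)
        assert subsample_fraction(idx, 0.1, seed=0).size == 64  # round(64.3)

    def test_identity_at_full_fraction(self):
        idx = np.arange(20)
        np.testing.assert_array_equal(subsample_fraction(idx, 1.0, seed=0), idx)

    def test_different_seeds_differ(self):
        idx = np.arange(643)
        a = subsample_fraction(idx, 0.1, seed=1)
        b = subsample_fraction(idx, 0.1, seed=2)
        assert not np.array_equal(a, b)

    def test_without_replacement(self):
        idx = np.arange(100)
        s = subsample_fraction(idx, 0.5, seed=3)
        assert np.unique(s).size == s.size


class TestEncodedDataset:
    def test_angle_matrix_range(self, encoded):
        assert encoded.angle_matrix.min() >= 0.0
        assert encoded.angle_matrix.max() <= 2 * math.pi + 1e-12
        assert encoded.angle_matrix.shape[1] == 11

    def test_amplitude_block_train_moments(self, encoded):
        tr = encoded.amplitude_block[encoded.train_index]
        np.testing.assert_allclose(tr.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(tr.std(axis=0, ddof=0), 1.0, atol=1e-9)

    def test_partition_disjoint_exhaustive(self, encoded):
        n = encoded.labels_01.size
        assert encoded.train_index.size + encoded.test_index.size == n
        assert np.intersect1d(encoded.train_index, encoded.test_index).size == 0

    def test_no_leakage_from_test_extremes(self, default_cohort):
        # angle scaling fitted on train: a test value outside the train range
        # must clip to an endpoint, not stretch the map
        spec, table = default_cohort
        data = encode_dataset(table, spec, split_seed=11)
        tr = data.angle_matrix[data.train_index]
        assert tr.min() == pytest.approx(0.0)
        assert tr.max() == pytest.approx(2 * math.pi)

    def test_nn_matrix_default_width(self, encoded):
        assert encoded.nn_matrix.shape[1] == 13

    def test_full_onehot_alternative(self, default_cohort):
        spec, table = default_cohort
        data = encode_dataset(table, spec, split_seed=11, nn_scheme="full_onehot")
        assert data.nn_matrix.shape[1] == 5 + 16

    def test_labels_pm(self, encoded):
        assert set(np.unique(encoded.labels_pm)) == {-1, 1}


class TestCsvIO:
    def test_roundtrip(self, default_cohort, tmp_path):
        _, table = default_cohort
        path = tmp_path / "cohort.csv"
        write_cohort_csv(table, path)
        again = read_cohort_csv(path)
        assert list(again.columns) == COLUMN_ORDER
        pd.testing.assert_frame_equal(again, table)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"Age": [50]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing"):
            read_cohort_csv(path)
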