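"""Per-signal features: spectral quantities, Hjorth parameters, sample
entropy (against a brute-force oracle), and feature-matrix assembly."""

import numpy as np
import pytest

from itdeeg.epochs import EpochSet
from itdeeg.features import (
    EntropyParams,
    FEATURE_KINDS,
    FeatureMatrix,
    PRC_SELECTIONS,
    UndefinedFeatureError,
    build_feature_matrix,
    extract_trial_features,
    hjorth_activity,
    hjorth_complexity,
    hjorth_mobility,
    mean_value,
    periodogram_psd,
    sample_entropy,
    signal_features,
    spectral_moment,
    subset_selection,
    total_power,
)


def brute_force_sampen_counts(x, m, r):
    """Independent O(N^2) pairwise oracle for the Richman-Moorman counts."""
    n = len(x)
    nt = n - m
    a = b = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                    a += 1
    return a, b


class TestBasicFeatures:
    def test_mean(self):
        assert mean_value([1, 2, 3]) == pytest.approx(2.0)
        assert mean_value(np.full(10, 4.2)) == pytest.approx(4.2)

    def test_centered_mean_is_zero(self, rng):
        x = rng.standard_normal(100)
        assert mean_value(x - x.mean()) == pytest.approx(0.0, abs=1e-12)

    def test_periodogram_impulse_is_flat(self):
        x = np.zeros(8)
        x[0] = 1.0
        sd = periodogram_psd(x)
        np.testing.assert_allclose(sd.density, 1.0 / 8.0)
        np.testing.assert_allclose(sd.frequencies, 2 * np.pi * np.arange(8) / 8)

    def test_zero_signal_spectrum(self):
        assert periodogram_psd(np.zeros(16)).density.sum() == 0.0
        assert total_power(np.zeros(16)) == 0.0

    def test_parseval(self, rng):
        for _ in range(10):
            x = rng.standard_normal(rng.integers(16, 400))
            assert total_power(x) == pytest.approx((x**2).sum(), rel=1e-9)

    def test_one_sided_option_preserves_total(self, rng):
        x = rng.standard_normal(128)
        two = periodogram_psd(x)
        one = periodogram_psd(x, one_sided=True)
        assert one.density.size == 65
        assert one.density.sum() == pytest.approx(two.density.sum(), rel=1e-12)

    def test_power_quadratic_scaling(self, rng):
        x = rng.standard_normal(64)
        assert total_power(3.0 * x) == pytest.approx(9.0 * total_power(x), rel=1e-9)


class TestSpectralMoments:
    def test_zero_signal(self):
        for p in range(1, 5):
            assert spectral_moment(np.zeros(32), p) == 0.0

    def test_bin_aligned_sinusoid(self):
        # energy splits between bins k0 and N-k0; M_p = S_T/2 * (w^p + (2pi-w)^p)
        n, k0 = 256, 10
        x = np.cos(2 * np.pi * k0 * np.arange(n) / n)
        st = total_power(x)
        w = 2 * np.pi * k0 / n
        for p in range(1, 5):
            expected = st / 2 * (w**p + (2 * np.pi - 2 * np.pi * k0 / n) ** p)
            assert spectral_moment(x, p) == pytest.approx(expected, rel=1e-9)

    def test_even_moments_nonnegative(self, rng):
        x = rng.standard_normal(100)
        assert spectral_moment(x, 2) >= 0.0
        assert spectral_moment(x, 4) >= 0.0

    def test_order_out_of_range(self):
        with pytest.raises(ValueError, match="1..4"):
            spectral_moment(np.ones(8), 5)


class TestHjorth:
    def test_activity_constant_zero(self):
        assert hjorth_activity(np.full(20, 3.0)) == 0.0

    def test_activity_two_point_hand_value(self):
        # variance with N-1 denominator: ((0-1)^2 + (2-1)^2)/1 = 2
        assert hjorth_activity([0.0, 2.0]) == pytest.approx(2.0)

    def test_activity_shift_invariance(self, rng):
        x = rng.standard_normal(50)
        assert hjorth_activity(x + 7.5) == pytest.approx(hjorth_activity(x))

    def test_mobility_sinusoid_closed_form(self):
        # first difference of sin(w0 n) has SD ratio 2 sin(w0/2)
        n = 1000
        for cycles in (5, 20, 50):
            w0 = 2 * np.pi * cycles / n
            x = np.sin(w0 * np.arange(n))
            assert hjorth_mobility(x) == pytest.approx(2 * np.sin(w0 / 2), rel=0.01)

    def test_mobility_scale_invariance(self, rng):
        x = rng.standard_normal(100)
        assert hjorth_mobility(5.0 * x) == pytest.approx(hjorth_mobility(x), rel=1e-12)

    def test_mobility_linear_ramp_zero(self):
        assert hjorth_mobility(np.arange(10.0)) == pytest.approx(0.0, abs=1e-9)

    def test_mobility_undefined_for_constant(self):
        with pytest.raises(UndefinedFeatureError):
            hjorth_mobility(np.ones(10))

    def test_complexity_sinusoid_near_one(self):
        n = 1000
        x = np.sin(2 * np.pi * 20 * np.arange(n) / n)
        assert hjorth_complexity(x) == pytest.approx(1.0, rel=0.02)

    def test_complexity_noise_exceeds_sinusoid(self, rng):
        n = 1000
        sine = np.sin(2 * np.pi * 20 * np.arange(n) / n)
        noise = rng.standard_normal(n)
        assert hjorth_complexity(noise) > hjorth_complexity(sine)

    def test_complexity_scale_invariance(self, rng):
        x = rng.standard_normal(100)
        assert hjorth_complexity(0.1 * x) == pytest.approx(
            hjorth_complexity(x), rel=1e-12
        )


class TestSampleEntropy:
    def test_constant_signal_zero(self):
        assert sample_entropy(np.full(50, 2.0)) == 0.0

    def test_periodic_two_cycle_zero(self):
        x = np.array([0.0, 1.0] * 50)
        assert sample_entropy(x, EntropyParams(m=2, r=0.2)) == 0.0

    @pytest.mark.parametrize("m", [1, 2])
    @pytest.mark.parametrize("r", [0.1, 0.2])
    def test_matches_brute_force_oracle(self, rng, m, r):
        from itdeeg._kernels import sampen_counts, sampen_counts_m2

        for _ in range(5):
            x = rng.standard_normal(200)
            tol = r * x.std()
            expected = brute_force_sampen_counts(x, m, tol)
            if m == 2:
                assert tuple(sampen_counts_m2(x, tol)) == expected
            assert tuple(sampen_counts(x, m, tol)) == expected
            a, b = expected
            assert sample_entropy(x, EntropyParams(m=m, r=r)) == pytest.approx(
                -np.log(a / b)
            )

    def test_no_extended_matches_gives_inf(self):
        # strictly geometric growth: nothing matches within a tiny tolerance
        x = np.array([0.0, 1.0, 3.0, 7.0, 15.0, 31.0, 63.0, 127.0])
        assert sample_entropy(x, EntropyParams(m=1, r=1e-6)) == np.inf


class TestTrialFeatures:
    @pytest.mark.parametrize("selection", sorted(PRC_SELECTIONS))
    def test_column_count_formula(self, rng, selection):
        n_ch = 4
        trial = rng.standard_normal((n_ch, 256))
        values, names, flags, _ = extract_trial_features(trial, selection)
        n_comp = len(PRC_SELECTIONS[selection])
        assert len(values) == len(names) == 10 * n_ch * n_comp
        assert len(set(names)) == len(names)

    def test_name_ordering_channel_major(self, rng):
        trial = rng.standard_normal((2, 128))
        _, names, _, _ = extract_trial_features(trial, "PRCs1-2")
        assert names[0] == "ch01|PRC1|mean"
        assert names[10] == "ch01|PRC2|mean"
        assert names[20] == "ch02|PRC1|mean"
        kinds = [n.split("|")[2] for n in names[:10]]
        assert tuple(kinds) == FEATURE_KINDS

    def test_zero_trial_flags_undefined_features(self):
        values, names, flags, _ = extract_trial_features(np.zeros((1, 64)), "EEG")
        assert not values.any()
        flagged = {n.split("|")[2] for n, f in zip(names, flags) if f}
        assert flagged == {"mobility", "complexity"}

    def test_shallow_decomposition_zero_pads_and_flags(self):
        # one full sine cycle has very few extrema: fewer than 3 PRCs
        trial = np.sin(2 * np.pi * np.arange(64) / 64)[None, :]
        values, names, _, row_flag = extract_trial_features(trial, "PRCs1-to-3")
        assert row_flag
        prc3 = [v for v, n in zip(values, names) if "|PRC3|" in n]
        assert not any(prc3)

    def test_unknown_selection_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown selection"):
            extract_trial_features(rng.standard_normal((1, 64)), "PRC9")


def tiny_epochs(rng, n_trials=12, n_channels=2, n_samples=200):
    labels = np.arange(n_trials) % 3 + 1
    return EpochSet(
        data=rng.standard_normal((n_trials, n_channels, n_samples)),
        labels=labels,
        fs=1000.0,
    )


class TestFeatureMatrix:
    def test_row_count_and_labels(self, rng):
        epochs = tiny_epochs(rng)
        fm = build_feature_matrix(epochs, "PRC1")
        assert fm.n_trials == 12
        assert fm.n_features == 10 * 2
        np.testing.assert_array_equal(fm.labels, epochs.labels)

    def test_deterministic_rebuild(self, rng):
        epochs = tiny_epochs(rng)
        a = build_feature_matrix(epochs, "PRCs1-2")
        b = build_feature_matrix(epochs, "PRCs1-2")
        assert a.values.equals(b.values)

    def test_trial_permutation_permutes_rows(self, rng):
        epochs = tiny_epochs(rng)
        fm = build_feature_matrix(epochs, "EEG")
        perm = rng.permutation(epochs.n_trials)
        fm_perm = build_feature_matrix(epochs.select_trials(perm), "EEG")
        np.testing.assert_allclose(
            fm_perm.values.to_numpy(), fm.values.to_numpy()[perm]
        )
        np.testing.assert_array_equal(fm_perm.labels, fm.labels[perm])

    def test_subset_selection_matches_direct_build(self, rng):
        epochs = tiny_epochs(rng)
        full = build_feature_matrix(epochs, "PRCs1-to-3")
        sub = subset_selection(full, "PRC2")
        direct = build_feature_matrix(epochs, "PRC2")
        np.testing.assert_allclose(sub.values.to_numpy(), direct.values.to_numpy())
        assert sub.columns == direct.columns

    def test_subset_requires_superset(self, rng):
        epochs = tiny_epochs(rng)
        fm = build_feature_matrix(epochs, "PRC1")
        with pytest.raises(ValueError, match="not a subset"):
            subset_selection(fm, "PRC2")

    def test_tsv_round_trip(self, rng, tmp_path):
        fm = build_feature_matrix(tiny_epochs(rng), "PRC1")
        path = tmp_path / "features.tsv"
        fm.to_tsv(path)
        back = FeatureMatrix.from_tsv(path)
        np.testing.assert_allclose(
            back.values.to_numpy(), fm.values.to_numpy(), rtol=1e-12
        )
        assert back.columns == fm.columns
        assert back.selection == fm.selection
        np.testing.assert_array_equal(back.labels, fm.labels)

    def test_signal_features_consistent_with_scalar_api(self, rng):
        x = rng.standard_normal(300)
        vals, flags = signal_features(x)
        assert not flags.any()
        assert vals[0] == pytest.approx(mean_value(x))
        assert vals[1] == pytest.approx(total_power(x))
        assert vals[4] == pytest.approx(spectral_moment(x, 3))
        assert vals[6] == pytest.approx(hjorth_activity(x))
        assert vals[7] == pytest.approx(hjorth_mobility(x))
        assert vals[8] == pytest.approx(hjorth_complexity(x))
        assert vals[9] == pytest.approx(sample_entropy(x))
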