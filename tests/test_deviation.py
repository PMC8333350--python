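"""Deviation scoring, effect sizes, AUC, percentile CIs, bootstrap plumbing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import neuronorm as nn
from neuronorm.cohort import N_REGIONS
from neuronorm.deviation import percentile_ci

scalar_lists = st.lists(st.floats(-100, 100, allow_nan=False), min_size=1,
                        max_size=12)


def brute_force_delta(a, b):
    greater = sum(x > y for x in a for y in b)
    less = sum(x < y for x in a for y in b)
    return (greater - less) / (len(a) * len(b))


def brute_force_auc(pos, neg):
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestObservedDeviation:
    def test_perfect_reconstruction_is_zero(self):
        x = np.random.default_rng(0).normal(size=N_REGIONS)
        assert nn.observed_deviation(x, x) == 0.0

    def test_unit_residuals_give_one(self):
        x = np.zeros(N_REGIONS)
        assert nn.observed_deviation(x, x - 1.0) == pytest.approx(1.0)

    def test_two_region_arithmetic(self):
        assert nn.observed_deviation(np.array([0.5, -0.5]),
                                     np.array([0.0, 0.0])) == pytest.approx(0.25)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nn.observed_deviation(np.zeros(3), np.zeros(4))

    def test_equals_mean_of_region_deviations(self):
        rng = np.random.default_rng(1)
        x, xhat = rng.normal(size=(2, N_REGIONS))
        assert nn.observed_deviation(x, xhat) == pytest.approx(
            float(np.mean(nn.region_deviations(x, xhat))), abs=1e-15)


class TestRegionDeviations:
    def test_zero_for_perfect_reconstruction(self):
        x = np.ones(N_REGIONS)
        np.testing.assert_array_equal(nn.region_deviations(x, x), 0.0)

    def test_single_discrepant_region(self):
        x = np.zeros(N_REGIONS)
        xhat = x.copy()
        xhat[0] -= 1.0
        d = nn.region_deviations(x, xhat)
        assert d[0] == 1.0 and np.all(d[1:] == 0.0)

    def test_signed_variant_keeps_direction(self):
        x = np.zeros(4)
        xhat = np.array([1.0, -1.0, 0.0, 2.0])
        np.testing.assert_allclose(
            nn.region_deviations(x, xhat, signed=True), [-1.0, 1.0, 0.0, -2.0])


class TestCliffsDelta:
    def test_complete_dominance(self):
        assert nn.cliffs_delta([1, 2, 3], [4, 5, 6]) == -1.0
        assert nn.cliffs_delta([4, 5, 6], [1, 2, 3]) == 1.0

    def test_identical_samples_give_zero(self):
        assert nn.cliffs_delta([2, 2, 5], [2, 2, 5]) == 0.0

    def test_small_mixed_example(self):
        # pairs: (3>2), (1<2) -> (1 - 1)/2 = 0
        assert nn.cliffs_delta([3, 1], [2]) == 0.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            nn.cliffs_delta([], [1.0])

    @given(scalar_lists, scalar_lists)
    def test_matches_brute_force_oracle(self, a, b):
        assert nn.cliffs_delta(a, b) == pytest.approx(brute_force_delta(a, b),
                                                      abs=1e-12)

    @given(scalar_lists, scalar_lists)
    def test_antisymmetry_and_bounds(self, a, b):
        d = nn.cliffs_delta(a, b)
        assert -1.0 <= d <= 1.0
        assert d == pytest.approx(-nn.cliffs_delta(b, a), abs=1e-12)


class TestAUC:
    def test_complete_separation(self):
        assert nn.auc_from_scores([5, 6], [1, 2]) == 1.0

    def test_identical_distributions_give_half(self):
        assert nn.auc_from_scores([1, 2, 3], [1, 2, 3]) == 0.5

    def test_one_discordant_pair(self):
        assert nn.auc_from_scores([0.9, 0.4], [0.5, 0.1]) == 0.75

    @given(scalar_lists, scalar_lists)
    def test_matches_brute_force_oracle(self, pos, neg):
        assert nn.auc_from_scores(pos, neg) == pytest.approx(
            brute_force_auc(pos, neg), abs=1e-12)

    @given(scalar_lists, scalar_lists)
    def test_cliffs_delta_identity(self, pos, neg):
        auc = nn.auc_from_scores(pos, neg)
        delta = nn.cliffs_delta(pos, neg)
        assert auc == pytest.approx((delta + 1.0) / 2.0, abs=1e-12)


class TestPercentileCI:
    def test_constant_samples_give_degenerate_interval(self):
        ci = percentile_ci(np.full(10, 3.25))
        assert ci.lower == ci.upper == ci.point == 3.25

    def test_linear_interpolation_on_1_to_1000(self):
        ci = percentile_ci(np.arange(1.0, 1001.0))
        assert ci.lower == pytest.approx(25.975)
        assert ci.upper == pytest.approx(975.025)
        assert ci.point == pytest.approx(500.5)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=200)
        a = percentile_ci(s)
        b = percentile_ci(rng.permutation(s))
        assert (a.lower, a.upper) == (b.lower, b.upper)
        assert a.point == pytest.approx(b.point, rel=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            percentile_ci([1.0])

    def test_excludes_zero_flag(self):
        assert percentile_ci(np.linspace(0.1, 1.0, 50)).excludes_zero
        assert not percentile_ci(np.linspace(-0.5, 0.5, 50)).excludes_zero


class TestBootstrapEvaluation:
    def test_two_iteration_plumbing(self, small_reference, graded_clinical,
                                    quick_config):
        clinical, _ = graded_clinical
        res = nn.bootstrap_normative_evaluation(
            small_reference, [clinical], quick_config, n_iterations=2, seed=5)
        assert res.n_iterations == 2
        for g in ("HC", "EMCI", "LMCI", "AD"):
            assert res.group_means[clinical.name][g].shape == (2,)
            ci = res.group_mean_ci(clinical.name, g)
            assert ci.lower <= ci.point <= ci.upper
        for g in ("EMCI", "LMCI", "AD"):
            assert res.aucs[clinical.name][g].shape == (2,)
            assert res.region_deltas[clinical.name][g].shape == (2, N_REGIONS)
        diff = res.difference_ci(clinical.name, "HC", "AD")
        assert diff.lower <= diff.upper
        assert not res.deviation_summary().empty
        assert not res.effect_size_summary().empty

    def test_deviation_scores_non_negative(self, small_reference,
                                           trained_small_model):
        table = nn.score_cohort(small_reference, trained_small_model)
        assert (table["observed_deviation"] >= 0).all()
        region_cols = [c for c in table.columns if c.startswith("dev:")]
        assert len(region_cols) == N_REGIONS
        np.testing.assert_allclose(
            table[region_cols].mean(axis=1), table["observed_deviation"],
            rtol=1e-12)

    def test_reference_must_be_hc_only(self, graded_clinical, quick_config):
        clinical, _ = graded_clinical
        with pytest.raises(ValueError, match="HC"):
            nn.bootstrap_normative_evaluation(clinical, [clinical],
                                              quick_config, n_iterations=1)

    def test_clinical_cohort_without_hc_rejected(self, small_reference,
                                                 graded_clinical, quick_config):
        clinical, _ = graded_clinical
        ad_only = clinical.subset("AD")
        with pytest.raises(ValueError, match="HC"):
            nn.bootstrap_normative_evaluation(small_reference, [ad_only],
                                              quick_config, n_iterations=1)

    def test_identity_reconstruction_gives_zero_deviation(self, atlas):
        # a perfectly fitted identity model assigns zero deviation to any
        # subject: the end-to-end null check of the scoring plumbing
        spec = nn.SimulationSpec(group_sizes={"HC": 8}, atlas=atlas, seed=41)
        cohort = nn.generate_reference_cohort(spec)
        params = nn.build_model(nn.AAEConfig(
            encoder_hidden=(101,), decoder_hidden=(101,), latent_dim=101))
        # encoder passes x through untouched; decoder returns the latent part
        eye = np.eye(101)
        params.encoder.W = [eye.copy(), eye.copy()]
        params.encoder.b = [np.full(101, 100.0), np.zeros(101)]  # keep ReLU linear
        params.encoder.W[1][:] = eye
        params.encoder.b[1][:] = -100.0
        dec_in = np.zeros((101 + 29, 101))
        dec_in[:101, :101] = eye
        params.decoder.W = [dec_in, eye.copy()]
        params.decoder.b = [np.full(101, 100.0), np.zeros(101)]
        params.decoder.b[1][:] = -100.0
        from neuronorm.preprocess import cohort_relative_volumes, fit_scaler
        params.scaler = fit_scaler(cohort_relative_volumes(cohort))
        X, Xhat = nn.reconstruct_cohort(cohort, params)
        np.testing.assert_allclose(Xhat, X, atol=1e-9)
        for i in range(len(cohort)):
            assert nn.observed_deviation(X[i], Xhat[i]) < 1e-18
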