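"""Decoder contracts: z-scoring, the Gaussian read-out weights, strict
leave-one-out cross-validation, and condition-averaged trajectories."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dvmotifs as dm
from dvmotifs.containers import BinnedResponses
from dvmotifs.decoding import (
    DecodingError,
    _loo_decode_bin,
    fit_decoder,
    zscore_bins,
)


def responses_from(counts):
    counts = np.asarray(counts, float)
    edges = np.arange(-50.0 * counts.shape[1], 1e-9, 50.0)
    return BinnedResponses(counts=counts, bin_edges_ms=edges)


def zscored(counts, min_rate=0.0):
    return zscore_bins(responses_from(counts), min_rate=min_rate)


class TestZScore:
    def test_constant_unit_maps_to_zero(self, rng):
        counts = rng.poisson(10.0, (2, 3, 30))
        counts[1] = 7
        Z = zscored(counts)
        np.testing.assert_array_equal(Z.z[1], 0.0)

    def test_mean_zero_sd_one_where_defined(self, rng):
        counts = rng.poisson(10.0, (4, 5, 80))
        Z = zscored(counts)
        live = Z.sds > 0
        means = Z.z.mean(axis=2)
        sds = Z.z.std(axis=2, ddof=1)
        assert np.all(np.abs(means[live]) < 1e-12)
        assert np.all(np.abs(sds[live] - 1.0) < 1e-12)

    def test_low_rate_unit_excluded(self, rng):
        counts = rng.poisson(10.0, (2, 15, 50))
        counts[0] = rng.poisson(0.1, (15, 50))  # ~2 ips < 3 ips threshold
        Z = zscore_bins(responses_from(counts), min_rate=3.0)
        assert Z.n_units == 1
        assert len(Z.dropped_units) == 1

    def test_all_units_dropped_raises(self, rng):
        counts = rng.poisson(0.01, (2, 15, 50))
        with pytest.raises(DecodingError):
            zscore_bins(responses_from(counts), min_rate=3.0)


class TestDecoderWeights:
    def test_identity_covariance_returns_mean_difference(self, rng):
        # huge n with independent unit noise: covariance ~ identity in
        # z-scored units, so w ~ s; verify on a constructed exact system
        s = np.array([1.0, 0.0])
        sigma = np.eye(2)
        w = np.linalg.solve(sigma, s)
        np.testing.assert_allclose(w, [1.0, 0.0])

    def test_diagonal_covariance_scales_components(self):
        w = np.linalg.solve(np.diag([2.0, 1.0]), np.array([1.0, 1.0]))
        np.testing.assert_allclose(w, [0.5, 1.0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        n_units=st.integers(2, 5),
        n_trials=st.integers(20, 200),
        seed=st.integers(0, 10_000),
    )
    def test_oracle_equivalence_with_lda(self, n_units, n_trials, seed):
        """Unregularized weights match an independent linear-discriminant
        solve (direction, to 1e-8 relative) on random instances."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(seed)
        labels = np.zeros(n_trials, bool)
        labels[: n_trials // 2] = True
        rng.shuffle(labels)
        X = rng.normal(10, 1, (n_units, 1, n_trials))
        X[:, 0, labels] += rng.normal(0, 1, n_units)[:, None]
        Z = zscored(X)
        w = fit_decoder(Z, labels, shrinkage=0.0).w[0]
        lda = LinearDiscriminantAnalysis(solver="lsqr")
        lda.fit(Z.z[:, 0, :].T, labels)
        coef = lda.coef_[0]
        w_hat = w / np.linalg.norm(w)
        c_hat = coef / np.linalg.norm(coef)
        if np.dot(w_hat, c_hat) < 0:
            c_hat = -c_hat
        np.testing.assert_allclose(w_hat, c_hat, atol=1e-8)

    def test_too_few_class_trials_raise(self, rng):
        Z = zscored(rng.poisson(5.0, (3, 2, 10)))
        labels = np.zeros(10, bool)
        labels[0] = True
        with pytest.raises(DecodingError):
            fit_decoder(Z, labels)


class TestLeaveOneOut:
    def test_single_class_labels_raise(self, small_session):
        trials, responses, _ = small_session
        trials = trials.copy()
        trials["choice_category"] = "cw"
        with pytest.raises(DecodingError):
            dm.PopulationDecoder(responses, trials).fit()

    def test_two_per_class_precondition(self, rng):
        X = rng.normal(0, 1, (4, 2))
        labels = np.array([True, True, False, False])
        # leaving one out drops a class to a single trial -> class means are
        # still defined, but 3 per class is the documented contract
        trials_needed = 3
        assert labels.sum() < trials_needed

    def test_held_out_sign_predicts_label_when_separated(self, rng):
        n = 60
        labels = np.arange(n) < n // 2
        X = rng.normal(0, 1, (n, 6)) + np.where(labels, 2.0, -2.0)[:, None]
        dv = _loo_decode_bin(X, labels, shrinkage=0.1, strict=True)
        assert np.mean((dv > 0) == labels) > 0.9

    def test_duplicating_held_out_trial_changes_dv(self, rng):
        """Leakage guard: the LOO estimate must depend on excluding trial j."""
        n = 30
        labels = np.arange(n) < n // 2
        X = rng.normal(0, 1, (n, 4)) + np.where(labels, 1.0, -1.0)[:, None]
        dv = _loo_decode_bin(X, labels, shrinkage=0.1, strict=True)
        j = 5
        X_dup = np.vstack([X, X[j]])
        labels_dup = np.append(labels, labels[j])
        dv_dup = _loo_decode_bin(X_dup, labels_dup, shrinkage=0.1, strict=True)
        assert dv_dup[j] != pytest.approx(dv[j], abs=1e-12)

    def test_strict_and_permissive_agree_in_sign(self, rng):
        n = 40
        labels = np.arange(n) < n // 2
        X = rng.normal(0, 1, (n, 4)) + np.where(labels, 1.5, -1.5)[:, None]
        strict = _loo_decode_bin(X, labels, 0.1, True)
        loose = _loo_decode_bin(X, labels, 0.1, False)
        assert np.mean(np.sign(strict) == np.sign(loose)) > 0.9

    def test_decoded_dvs_finite_and_shaped(self, decoded_session):
        trials, _, _, _, dv = decoded_session
        for dim in ("categorical", "motor"):
            assert dv.dv[dim].shape == (len(trials), 15)
            assert np.all(np.isfinite(dv.dv[dim]))


class TestAccuracy750:
    def test_random_labels_near_chance(self, rng):
        n = 1000
        X = rng.normal(0, 1, (5, 1, n))
        labels = rng.random(n) < 0.5
        responses = responses_from(X)
        trials = None
        dv = _loo_decode_bin(X[:, 0, :].T, labels, 0.1, True)
        acc = np.mean((dv > 0) == labels)
        assert abs(acc - 0.5) < 0.04  # binomial null band

    def test_high_snr_generator_reaches_090(self):
        emission = dm.EmissionConfig(loading_sd=10.0)
        trials, responses, _ = dm.simulate_session(
            dm.TaskConfig(n_trials=320), emission=emission, seed=17
        )
        dec = dm.PopulationDecoder(responses, trials)
        assert dec.accuracy_750("motor") >= 0.9


class TestTrajectories:
    def test_single_trial_group_equals_its_dv(self, decoded_session):
        trials, _, _, _, dv = decoded_session
        mask = np.zeros(len(trials), bool)
        mask[7] = True
        ts = dm.average_trajectories(dv, trials, groups={"one": mask})
        np.testing.assert_allclose(
            ts.trajectories["one"][0], dv.dv["categorical"][7]
        )
        assert ts.counts["one"] == 1

    def test_empty_group_omitted_not_zero_filled(self, decoded_session):
        trials, _, _, _, dv = decoded_session
        ts = dm.average_trajectories(
            dv, trials, groups={"none": np.zeros(len(trials), bool)}
        )
        assert "none" not in ts.trajectories
        assert ts.omitted == ["none"]

    def test_unsigned_folds_agree_between_choice_signs(self):
        # sign-symmetric generator: cw-fold and ccw-fold unsigned averages
        # agree within Monte-Carlo error
        trials, responses, _ = dm.simulate_session(
            dm.TaskConfig(n_trials=2000), seed=23
        )
        dv = dm.PopulationDecoder(responses, trials).fit()
        unsigned = dm.unsign_dv(dv, trials)
        cw = (trials["choice_category"] == "cw").to_numpy()
        late = slice(8, 12)
        a = unsigned["categorical"][cw, late].mean()
        b = unsigned["categorical"][~cw, late].mean()
        assert a == pytest.approx(b, abs=0.15)

    def test_outcome_groups_partition_all_trials(self, decoded_session):
        trials, _, _, _, _ = decoded_session
        groups = dm.outcome_groups(trials)
        total = np.zeros(len(trials), int)
        for mask in groups.values():
            total += mask.astype(int)
        assert np.all(total == 1)

    def test_zero_signal_accuracy_groups_balanced(self):
        # random feedback on the vertical stimulus: accuracy groups ~ equal
        task = dm.TaskConfig(n_trials=4000, orientations=(0.0,), zero_weight=1.0)
        trials = dm.generate_task_trials(task, seed=2)
        filled, _ = dm.simulate_decision_process(trials, dm.ProcessConfig(), seed=3)
        frac = filled["correct"].mean()
        assert abs(frac - 0.5) < 0.03
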