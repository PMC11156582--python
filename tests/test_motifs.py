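"""Motif trajectory models: evaluation identities, fitting, AIC comparison,
onset/peak estimation and the peak-time bootstrap."""

import numpy as np
import pytest
from scipy.stats import norm

import dvmotifs as dm
from dvmotifs.containers import BIN_CENTERS
from dvmotifs.motifs import (
    ABSTRACT_MIN_SEPARATION,
    MotifError,
    Z_ONSET,
    Z_PEAK,
    eval_motif,
    fit_motif,
)

ABSTRACT_PARAMS = {
    "offset_c": 0.1, "range_c": 1.0, "tau_c": 60.0, "t50_c": -430.0,
    "tau_decay": 350.0,
    "offset_m": -0.05, "range_m": 1.3, "tau_m": 55.0, "t50_m": -140.0,
}


class TestEvalMotif:
    def test_zero_range_is_flat_at_offset(self):
        params = dict(ABSTRACT_PARAMS, range_m=0.0)
        pair = eval_motif("abstract", params)
        np.testing.assert_allclose(pair[1], params["offset_m"], atol=1e-12)

    def test_half_rise_at_t50(self):
        v = eval_motif(
            "intentional",
            {"offset_m": 0.2, "range_m": 1.0, "tau_m": 50.0, "t50_m": -300.0},
            t=np.array([-300.0]),
        )
        assert v[1, 0] == pytest.approx(0.2 + 0.5)

    def test_peak_quantile_constant(self):
        # the decay is anchored where the rise reaches its 99.38th percentile
        assert Z_PEAK == pytest.approx(norm.ppf(0.9938))
        assert Z_PEAK == pytest.approx(2.50, abs=0.01)

    def test_intentional_categorical_is_structureless(self):
        pair = eval_motif(
            "intentional",
            {"offset_m": 0.0, "range_m": 1.0, "tau_m": 50.0, "t50_m": -200.0},
        )
        np.testing.assert_array_equal(pair[0], 0.0)

    def test_mixture_shares_rise_across_dimensions(self):
        params = {
            "offset_c": 0.0, "range_c": 1.0, "tau_decay": 1e9,
            "offset_m": 0.0, "range_m": 2.0, "tau": 50.0, "t50": -300.0,
        }
        pair = eval_motif("mixture", params)
        np.testing.assert_allclose(pair[1], 2.0 * pair[0], rtol=1e-6)

    def test_unknown_motif_rejected(self):
        with pytest.raises(MotifError):
            eval_motif("bayesian", {})


class TestFitMotif:
    def test_noiseless_self_consistency(self):
        clean = eval_motif("abstract", ABSTRACT_PARAMS)
        fit = fit_motif(clean, "abstract", n_starts=8, seed=0)
        assert fit.sse < 1e-10
        assert fit.params["t50_c"] == pytest.approx(ABSTRACT_PARAMS["t50_c"], abs=1.0)
        assert fit.params["t50_m"] == pytest.approx(ABSTRACT_PARAMS["t50_m"], abs=1.0)

    def test_noisy_t50_recovery_within_25ms(self):
        rng = np.random.default_rng(4)
        clean = eval_motif("abstract", ABSTRACT_PARAMS)
        errs = []
        for i in range(20):
            noisy = clean + rng.normal(0, 0.1, clean.shape)
            fit = fit_motif(noisy, "abstract", n_starts=6, seed=i)
            errs.append(abs(fit.params["t50_c"] - ABSTRACT_PARAMS["t50_c"]))
        assert np.median(errs) <= 25.0

    def test_flat_trajectories_get_near_zero_range(self):
        flat = np.zeros((2, 15))
        fit = fit_motif(flat, "unconstrained", n_starts=6, seed=0)
        assert abs(fit.params["range_c"]) < 1e-3
        assert abs(fit.params["range_m"]) < 1e-3
        assert np.isnan(fit.onset_time("categorical"))

    def test_refit_reproduces_sse_from_predictions(self):
        rng = np.random.default_rng(1)
        clean = eval_motif("abstract", ABSTRACT_PARAMS)
        noisy = clean + rng.normal(0, 0.05, clean.shape)
        fit = fit_motif(noisy, "abstract", n_starts=6, seed=0)
        sse = float(np.sum((fit.predict() - noisy) ** 2))
        assert sse == pytest.approx(fit.sse, abs=1e-10)

    def test_abstract_constraint_holds_at_optimum(self):
        rng = np.random.default_rng(2)
        for i in range(10):
            traj = rng.normal(0, 1, (2, 15))
            fit = fit_motif(traj, "abstract", n_starts=4, seed=i)
            assert (
                fit.params["t50_m"]
                >= fit.params["t50_c"] + ABSTRACT_MIN_SEPARATION - 1e-6
            )


class TestCompare:
    def test_identical_fits_have_zero_delta(self):
        clean = eval_motif("abstract", ABSTRACT_PARAMS)
        fit = fit_motif(clean + 0.05, "abstract", n_starts=4, seed=0)
        table = dm.compare_models({"a": fit, "b": fit})
        assert table["delta"][("a", "b")] == pytest.approx(0.0)

    def test_equal_sigma2_delta_is_twice_k_difference(self):
        a = dm.MotifResults(motif="abstract", params={}, k=9, n=30, sse=21.0,
                            t=BIN_CENTERS, data=np.zeros((2, 15)))
        b = dm.MotifResults(motif="intentional", params={}, k=4, n=30, sse=26.0,
                            t=BIN_CENTERS, data=np.zeros((2, 15)))
        # sse chosen so sigma2 = sse/(n-k) = 1 for both
        assert a.sigma2 == pytest.approx(b.sigma2)
        assert a.aic - b.aic == pytest.approx(10.0)

    def test_mismatched_n_raises(self):
        a = dm.MotifResults(motif="abstract", params={}, k=9, n=30, sse=1.0,
                            t=BIN_CENTERS, data=np.zeros((2, 15)))
        b = dm.MotifResults(motif="abstract", params={}, k=9, n=20, sse=1.0,
                            t=BIN_CENTERS[:10], data=np.zeros((2, 10)))
        with pytest.raises(MotifError):
            dm.compare_models({"a": a, "b": b})

    def test_aic_ordering_invariant_to_additive_constant(self):
        # the data-dependent AIC constant cancels in differences: shifting
        # all data points leaves the delta between offset-covariant models
        # unchanged (the intentional motif is excluded -- its categorical
        # dimension is pinned at zero and cannot absorb a shift)
        rng = np.random.default_rng(3)
        clean = eval_motif("abstract", ABSTRACT_PARAMS)
        noisy = clean + rng.normal(0, 0.1, clean.shape)
        deltas = []
        for c in (0.0, 5.0):
            fits = {
                m: fit_motif(noisy + c, m, n_starts=8, seed=0)
                for m in ("mixture", "abstract")
            }
            deltas.append(fits["abstract"].aic - fits["mixture"].aic)
        # the post-peak decay acts on the full categorical value, so the
        # optimum is only approximately shift-covariant; the model ordering
        # and the delta's scale must survive the shift
        assert np.sign(deltas[0]) == np.sign(deltas[1])
        assert deltas[0] == pytest.approx(deltas[1], rel=0.1)

    def test_intentional_data_prefers_intentional(self):
        rng = np.random.default_rng(5)
        wins = 0
        for i in range(10):
            params = {"offset_m": 0.0, "range_m": 1.0, "tau_m": 60.0,
                      "t50_m": -150.0}
            clean = eval_motif("intentional", params)
            noisy = clean + rng.normal(0, 0.1, clean.shape)
            best, _ = dm.select_motif(noisy, n_starts=4, seed=i)
            wins += best == "intentional"
        assert wins >= 9


class TestOnsetPeak:
    def test_onset_formula_worked_example(self):
        fit = dm.MotifResults(
            motif="unconstrained",
            params={"offset_c": 0.0, "range_c": 1.0, "tau_c": 60.8,
                    "t50_c": -300.0, "tau_decay": 300.0, "offset_m": 0.0,
                    "range_m": 1.0, "tau_m": 60.8, "t50_m": -300.0},
            k=9, n=30, sse=1.0, t=BIN_CENTERS, data=np.zeros((2, 15)),
        )
        # -300 - 1.6449 * 60.8 = -400.0
        assert fit.onset_time("categorical") == pytest.approx(-400.0, abs=0.05)
        assert Z_ONSET == pytest.approx(norm.ppf(0.95))

    def test_onset_approaches_t50_as_tau_vanishes(self):
        fit = dm.MotifResults(
            motif="unconstrained",
            params={"offset_c": 0.0, "range_c": 1.0, "tau_c": 1e-9,
                    "t50_c": -300.0, "tau_decay": 300.0, "offset_m": 0.0,
                    "range_m": 1.0, "tau_m": 1e-9, "t50_m": -300.0},
            k=9, n=30, sse=1.0, t=BIN_CENTERS, data=np.zeros((2, 15)),
        )
        assert fit.onset_time("motor") == pytest.approx(-300.0, abs=1e-6)

    def test_absolute_threshold_onset_before_relative_peak(self):
        clean = eval_motif("abstract", ABSTRACT_PARAMS)
        fit = fit_motif(clean, "abstract", n_starts=6, seed=0)
        t_abs = fit.onset_time_absolute("categorical", level=0.05)
        assert t_abs < fit.peak_time("categorical")


class TestPeakBootstrap:
    def test_single_resample_sd_flagged_nan(self, decoded_session):
        trials, _, _, _, dv = decoded_session
        boot = dm.peak_time_bootstrap(trials, dv, n_boot=1, seed=0,
                                      n_starts_point=6, n_starts_boot=1)
        assert all(np.isnan(v) for v in boot.sd.values())

    def test_fixed_seed_reproduces_bootstrap(self, decoded_session):
        trials, _, _, _, dv = decoded_session
        a = dm.peak_time_bootstrap(trials, dv, n_boot=5, seed=9,
                                   n_starts_point=6, n_starts_boot=1)
        b = dm.peak_time_bootstrap(trials, dv, n_boot=5, seed=9,
                                   n_starts_point=6, n_starts_boot=1)
        assert a.point == b.point
        for k in a.samples:
            np.testing.assert_allclose(a.samples[k], b.samples[k])
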