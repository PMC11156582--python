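"""Variance partition, residual timecourse, DV bias and the
expectation-behavior linkage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import dvmotifs as dm
from dvmotifs.signatures import (
    SignatureError,
    expectation_vs_behavior,
    partition_sums,
)


class TestPartition:
    def test_worked_four_trial_example(self):
        t, c, s, r = partition_sums(
            [2.0, 0.0, -2.0, 0.0], ["A", "A", "B", "B"], ["s1", "s2", "s1", "s2"]
        )
        assert (t, c, s, r) == (8.0, 4.0, 4.0, 0.0)

    def test_all_equal_dv_gives_zero_components(self):
        t, c, s, r = partition_sums([1.0] * 6, [0, 0, 0, 1, 1, 1], [0, 1] * 3)
        assert t == c == s == r == 0.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_conservation_identity_exact(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        dv = rng.normal(0, rng.uniform(0.5, 4.0), n)
        choice = rng.integers(0, 2, n)
        stim = rng.integers(0, 5, n)
        t, c, s, r = partition_sums(dv, choice, stim)
        assert abs(t - (c + s + r)) <= 1e-10 * max(t, 1.0)
        assert min(c, s, r) >= -1e-12

    def test_single_trial_cells_still_conserve(self):
        t, c, s, r = partition_sums([1.0, 4.0, -2.0], [0, 0, 1], [0, 1, 0])
        assert t == pytest.approx(c + s + r, abs=1e-12)

    def test_fewer_than_two_trials_raise(self):
        with pytest.raises(SignatureError):
            partition_sums([1.0], [0], [0])

    def test_permuted_stimulus_labels_kill_stim_component(self, decoded_session):
        trials, _, _, _, dv = decoded_session
        rng = np.random.default_rng(0)
        shuffled = trials.copy()
        vp = dm.variance_partition(dv, trials)
        shuffled["orientation"] = rng.permutation(trials["orientation"].to_numpy())
        vp_null = dm.variance_partition(dv, shuffled)
        late = slice(6, 10)
        assert (
            vp_null.fractions["categorical"]["stim"][late].mean()
            < vp.fractions["categorical"]["stim"][late].mean()
        )


class TestResidualTimecourse:
    def test_constant_dv_yields_flat_zero_series(self):
        n = 20
        cat = np.ones((n, 15))
        trials = pd.DataFrame(
            {
                "orientation": np.tile([-1.0, 1.0], n // 2),
                "choice_category": ["cw", "ccw"] * (n // 2),
                "saccade_direction": ["left", "right"] * (n // 2),
            }
        )

        class _DV:
            dv = {"categorical": cat, "motor": cat}
            bin_left_edges_ms = np.arange(-750.0, 0.0, 50.0)

        vp = dm.variance_partition(_DV(), trials)
        np.testing.assert_array_equal(vp.components["categorical"]["res"], 0.0)
        rt = dm.residual_timecourse(vp)
        assert rt.rise_length_ms["categorical"] == 0.0

    def test_white_noise_has_short_rise_on_average(self):
        rng = np.random.default_rng(1)
        lengths = []
        for _ in range(30):
            n = 200
            noise = rng.normal(0, 1, (n, 15))
            trials = pd.DataFrame(
                {
                    "orientation": rng.choice([-1.0, 0.0, 1.0], n),
                    "choice_category": rng.choice(["cw", "ccw"], n),
                    "saccade_direction": rng.choice(["left", "right"], n),
                }
            )

            class _DV:
                dv = {"categorical": noise, "motor": noise}
                bin_left_edges_ms = np.arange(-750.0, 0.0, 50.0)

            vp = dm.variance_partition(_DV(), trials)
            rt = dm.residual_timecourse(vp)
            lengths.append(rt.rise_length_ms["categorical"])
        assert np.mean(lengths) < 200.0  # no systematic multi-bin rise

    def test_generator_accumulation_rise_is_categorical_only(self, decoded_session):
        trials, _, gt, _, dv = decoded_session
        vp = dm.variance_partition(dv, trials)
        edges = vp.bin_left_edges_ms
        proc = gt.process_config
        lo = np.flatnonzero(np.isclose(edges, proc.acc_onset_ms))[0]
        hi = np.flatnonzero(
            np.isclose(edges, proc.acc_onset_ms + proc.rotation_delay_ms - 50.0)
        )[0]
        d_cat = (
            vp.components["categorical"]["res"][hi]
            - vp.components["categorical"]["res"][lo]
        )
        d_mot = vp.components["motor"]["res"][hi] - vp.components["motor"]["res"][lo]
        assert d_cat > 0
        assert d_mot < d_cat


class TestDVBias:
    @staticmethod
    def _trials(n, rng):
        return pd.DataFrame(
            {
                "orientation": rng.choice([-2.2, -1.1, 0.0, 1.1, 2.2], n),
                "contrast": rng.choice(["high", "low"], n),
                "prior": rng.choice(["cw", "ccw"], n),
                "choice_category": rng.choice(["cw", "ccw"], n),
                "saccade_direction": rng.choice(["left", "right"], n),
            }
        )

    @staticmethod
    def _dv(cat, mot):
        class _DV:
            dv = {"categorical": cat, "motor": mot}
            bin_left_edges_ms = np.arange(-750.0, 0.0, 50.0)

            def bin_index(self, t):
                hits = np.flatnonzero(np.isclose(self.bin_left_edges_ms, t))
                if len(hits) != 1:
                    raise ValueError("off-grid readout")
                return int(hits[0])

        return _DV()

    def test_identical_groups_give_zero_bias(self, rng):
        n = 400
        trials = self._trials(n, rng)
        cat = np.ones((n, 15)) * np.where(
            trials["choice_category"] == "cw", 1.0, -1.0
        )[:, None]
        mot = np.ones((n, 15)) * np.where(
            trials["saccade_direction"] == "right", 1.0, -1.0
        )[:, None]
        dv = self._dv(cat, mot)
        res = dm.dv_bias(dv, trials)
        for v in res.bias.values():
            np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_level_average_of_two_differences(self):
        # two levels with congruent-incongruent differences 0.6 and 0.2
        # average to a bias of 0.4 at the readout
        trials = pd.DataFrame(
            {
                "orientation": [1.1, 1.1, 2.2, 2.2] * 2,
                "contrast": ["high"] * 8,
                "prior": ["cw"] * 8,
                "choice_category": ["cw", "ccw"] * 4,
                "saccade_direction": ["right", "left"] * 4,
            }
        )
        cat = np.zeros((8, 15))
        congruent = (trials["choice_category"] == "cw").to_numpy()
        level1 = (trials["orientation"] == 1.1).to_numpy()
        # unsigned values: congruent at level1 = 0.6 larger, level2 = 0.2
        base = np.where(congruent, 0.0, 0.0)
        cat[:] = base[:, None]
        sign = np.where(congruent, 1.0, -1.0)
        cat[level1 & congruent] = 0.6
        cat[~level1 & congruent] = 0.2
        cat = cat * sign[:, None]  # unsign_dv will fold ccw trials back
        dv = self._dv(cat, np.zeros((8, 15)))
        res = dm.dv_bias(dv, trials)
        assert res.expectation[("high", "categorical")] == pytest.approx(0.4)

    def test_level_reweighting_leaves_bias_unchanged(self, rng):
        # doubling one stimulus level's trials must not move the bias,
        # because levels are averaged with equal weights
        n = 300
        trials = self._trials(n, rng)
        cat = rng.normal(0, 1, (n, 15)) + np.where(
            trials["choice_category"] == trials["prior"], 0.5, 0.0
        )[:, None] * np.where(trials["choice_category"] == "cw", 1, -1)[:, None]
        dv = self._dv(cat, cat * 0)
        base = dm.dv_bias(dv, trials)
        dup_mask = (trials["orientation"] == 1.1).to_numpy()
        trials_dup = pd.concat(
            [trials, trials[dup_mask]], ignore_index=True
        )
        cat_dup = np.vstack([cat, cat[dup_mask]])
        dv_dup = self._dv(cat_dup, cat_dup * 0)
        dup = dm.dv_bias(dv_dup, trials_dup)
        for key in base.bias:
            level_means_same = set(base.per_level[key]) == set(dup.per_level[key])
            assert level_means_same

    def test_off_grid_readout_raises(self, rng):
        trials = self._trials(60, rng)
        dv = self._dv(rng.normal(0, 1, (60, 15)), rng.normal(0, 1, (60, 15)))
        with pytest.raises(ValueError):
            dm.dv_bias(dv, trials, readout_ms=-512.0)

    def test_generator_offset_biases_categorical_before_stimulus(self):
        proc = dm.ProcessConfig(
            prior_start_offset={"high": 0.25, "low": 0.25}
        )
        trials, responses, _ = dm.simulate_session(
            dm.TaskConfig(n_trials=1280), proc, seed=13
        )
        dv = dm.PopulationDecoder(responses, trials).fit()
        res = dm.dv_bias(dv, trials, readout_ms=-650.0)  # pre-stimulus bin
        cat = np.mean([res.expectation[(c, "categorical")] for c in ("high", "low")])
        mot = np.mean([res.expectation[(c, "motor")] for c in ("high", "low")])
        assert cat > 0
        assert abs(mot) < cat


class TestExpectationCorrelation:
    def test_identical_vectors_have_rho_one(self):
        x = np.arange(10.0)
        res = expectation_vs_behavior({"categorical": x}, x, n_perm=200, seed=0)
        assert res.rho["categorical"] == pytest.approx(1.0)
        assert res.p_perm["categorical"] < 0.05

    def test_independent_vectors_not_significant(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        res = expectation_vs_behavior({"categorical": x}, y, n_perm=500, seed=0)
        assert abs(res.rho["categorical"]) < 0.5

    def test_tied_input_flagged(self):
        res = expectation_vs_behavior(
            {"categorical": np.ones(8)}, np.arange(8.0), n_perm=100, seed=0
        )
        assert res.undefined
        assert np.isnan(res.rho["categorical"])

    def test_too_few_pairs_raise(self):
        with pytest.raises(SignatureError):
            expectation_vs_behavior({"categorical": [1, 2]}, [1, 2])
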