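"""Simulation experiments: recovery, calibration and signature checks.

Each experiment regenerates synthetic data with known ground truth, runs
the corresponding analysis stage, and returns plain-number summaries.
They double as the package's simulation-based calibration suite: decoder
self-consistency, variance-partition conservation, motif parameter
recovery and model-selection calibration, onset-order recovery, the
deliberation signatures, DV geometry, the prior-expectation linkage, and
psychometric parameter recovery.

All functions take a single integer ``seed``; derived seeds stay below
2**31.
"""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .behavior import PriorBiasModel, PsychometricModel
from .decoding import PopulationDecoder, average_trajectories
from .geometry import angle_series, xcorr_trialwise
from .motifs import MotifModel, eval_motif, fit_motif, peak_time_bootstrap
from .pipeline import run_pipeline
from .signatures import (
    dv_bias,
    partition_sums,
    variance_partition,
)
from .synthetic import (
    EmissionConfig,
    ProcessConfig,
    TaskConfig,
    simulate_session,
)

__all__ = [
    "partition_conservation",
    "motif_t50_recovery",
    "model_selection_calibration",
    "onset_order_experiment",
    "signature_experiment",
    "geometry_experiment",
    "expectation_linkage_experiment",
    "psychometric_recovery",
    "pipeline_determinism",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# variance partition conservation


def partition_conservation(n_instances: int = 1000, seed: int = 0) -> dict:
    """Max relative violation of S_total = S_choice + S_stim + S_res over
    random instances (random trial counts, label structures, DV values),
    plus the 4-trial worked example."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(2, 60))
        dv = rng.normal(0, rng.uniform(0.1, 5.0), n)
        choice = rng.integers(0, 2, n)
        stim = rng.choice(rng.integers(1, 8), n)
        t, c, s, r = partition_sums(dv, choice, stim)
        denom = max(t, 1e-30)
        worst = max(worst, abs(t - (c + s + r)) / denom)
    t, c, s, r = partition_sums(
        [2.0, 0.0, -2.0, 0.0], ["A", "A", "B", "B"], ["s1", "s2", "s1", "s2"]
    )
    return {
        "max_rel_error": worst,
        "worked_example": {"total": t, "choice": c, "stim": s, "res": r},
    }


# ---------------------------------------------------------------------------
# motif recovery and model selection


_TRUE_ABSTRACT = {
    "offset_c": 0.0, "range_c": 1.0, "tau_c": 60.0, "t50_c": -450.0,
    "tau_decay": 300.0,
    "offset_m": 0.0, "range_m": 1.2, "tau_m": 50.0, "t50_m": -150.0,
}


def motif_t50_recovery(
    n_reps: int = 100, seed: int = 0, noise_frac: float = 0.1,
    n_starts: int = 8,
) -> dict:
    """Recover the half-rise times of a known abstract-motif trajectory pair
    under Gaussian noise of s.d. ``noise_frac`` x dynamic range."""
    rng = np.random.default_rng(seed)
    clean = eval_motif("abstract", _TRUE_ABSTRACT)
    sd = np.array(
        [noise_frac * abs(_TRUE_ABSTRACT["range_c"]),
         noise_frac * abs(_TRUE_ABSTRACT["range_m"])]
    )
    err_c, err_m = [], []
    for i in range(n_reps):
        noisy = clean + rng.normal(0.0, sd[:, None], clean.shape)
        fit = fit_motif(noisy, "abstract", n_starts=n_starts, seed=seed + i)
        err_c.append(abs(fit.params["t50_c"] - _TRUE_ABSTRACT["t50_c"]))
        err_m.append(abs(fit.params["t50_m"] - _TRUE_ABSTRACT["t50_m"]))
    return {
        "median_t50_error_categorical_ms": float(np.median(err_c)),
        "median_t50_error_motor_ms": float(np.median(err_m)),
        "n_reps": n_reps,
    }


def _draw_true_params(motif: str, rng) -> dict:
    base = {
        "offset_c": rng.uniform(-0.1, 0.1),
        "offset_m": rng.uniform(-0.1, 0.1),
        "range_m": rng.uniform(0.8, 1.5),
        "tau_m": rng.uniform(40.0, 90.0),
    }
    if motif == "intentional":
        base["t50_m"] = rng.uniform(-250.0, -100.0)
        base["offset_c"] = 0.0
        return base
    base["range_c"] = rng.uniform(0.8, 1.5)
    base["tau_decay"] = rng.uniform(200.0, 600.0)
    if motif == "abstract":
        base["tau_c"] = rng.uniform(40.0, 90.0)
        base["t50_c"] = rng.uniform(-500.0, -420.0)
        base["t50_m"] = base["t50_c"] + rng.uniform(260.0, 380.0)
        return base
    if motif == "mixture":
        base["tau"] = rng.uniform(40.0, 90.0)
        base["t50"] = rng.uniform(-400.0, -200.0)
        base.pop("tau_m")
        return base
    raise ValueError(motif)


def model_selection_calibration(
    n_sessions: int = 100, seed: int = 0, noise_frac: float = 0.1,
    n_starts: int = 4,
) -> dict:
    """Fraction of simulated sessions whose generating motif wins the AIC
    comparison, per generating class."""
    rng = np.random.default_rng(seed)
    hits = {}
    for gen in ("intentional", "abstract", "mixture"):
        n_hit = 0
        for i in range(n_sessions):
            params = _draw_true_params(gen, rng)
            clean = eval_motif(gen, params)
            span = max(float(np.ptp(clean)), 1.0)
            noisy = clean + rng.normal(0.0, noise_frac * span, clean.shape)
            aics = {}
            for m in ("intentional", "abstract", "mixture"):
                aics[m] = fit_motif(
                    noisy, m, n_starts=n_starts, seed=seed + i
                ).aic
            if min(aics, key=aics.get) == gen:
                n_hit += 1
        hits[gen] = n_hit
    return {"n_correct": hits, "n_sessions": n_sessions}


# ---------------------------------------------------------------------------
# full-pipeline experiments


def _simulate_and_decode(task, process, emission, seed):
    trials, responses, gt = simulate_session(task, process, emission, seed)
    dec = PopulationDecoder(responses, trials)
    return trials, gt, dec.fit()


def onset_order_experiment(
    n_sessions: int = 50, seed: int = 0, rotation_delay_ms: float = 200.0,
    n_trials: int = 320, n_starts: int = 12,
) -> dict:
    """Recover the categorical-to-motor onset lag from decoded sessions.

    Each session's unsigned all-trials trajectory pair is fit with the
    unconstrained motif model; onsets are the 5th-percentile times.
    """
    task = TaskConfig(n_trials=n_trials)
    process = ProcessConfig(rotation_delay_ms=rotation_delay_ms)
    emission = EmissionConfig()
    delays, n_correct = [], 0
    for s in _child_seeds(seed, n_sessions):
        trials, _, dv = _simulate_and_decode(task, process, emission, s)
        ts = average_trajectories(
            dv, trials, groups={"all": np.ones(len(trials), bool)}, unsigned=True
        )
        fit = fit_motif(ts.trajectories["all"], "unconstrained",
                        n_starts=n_starts, seed=s)
        on_c = fit.onset_time("categorical")
        on_m = fit.onset_time("motor")
        if np.isfinite(on_c) and np.isfinite(on_m):
            if on_c < on_m:
                n_correct += 1
            delays.append(on_m - on_c)
        else:
            delays.append(np.nan)
    return {
        "n_sessions": n_sessions,
        "n_categorical_first": n_correct,
        "median_delay_ms": float(np.nanmedian(delays)),
        "true_delay_ms": rotation_delay_ms,
    }


def signature_experiment(
    n_sessions: int = 20, seed: int = 0, n_trials: int = 1600,
    n_boot: int = 60,
) -> dict:
    """Deliberation signatures on generator data, per session:

    (a) graded evidence -- the regression slope of the unsigned categorical
        DV (averaged over the late-stimulus window, when evidence has
        accumulated but commitment is not yet universal) on stimulus
        strength is positive on correct and negative on error trials;
    (b) diffusion -- the categorical residual variance rises across the
        accumulation window while the motor residual variance does not;
    (c) bound -- the bootstrap categorical peak time is later on error than
        correct trials while motor peaks are indistinguishable.
    """
    task = TaskConfig(n_trials=n_trials)
    process = ProcessConfig()
    emission = EmissionConfig()
    win_lo = process.acc_onset_ms
    # late-stimulus readout: from 100 ms after accumulation onset through
    # the last pre-rotation bin
    read_lo = process.acc_onset_ms + 100.0
    read_hi = process.acc_onset_ms + process.rotation_delay_ms - 50.0
    graded_corr_pos = graded_err_neg = 0
    cat_rise_pos = mot_rise_pos = mot_rise_ge_cat = 0
    cat_peak_later_err = mot_peak_later_err = 0
    d_cat_rise, d_mot_rise, d_cat_peak, d_mot_peak = [], [], [], []
    slope_cor, slope_err = [], []

    def slope(x, y):
        x = x - x.mean()
        return float(np.dot(x, y) / np.dot(x, x))

    for s in _child_seeds(seed, n_sessions):
        trials, _, dv = _simulate_and_decode(task, process, emission, s)
        # (a) graded evidence in the late-stimulus window
        b_lo, b_hi = dv.bin_index(read_lo), dv.bin_index(read_hi)
        sign = np.where(trials["choice_category"] == "cw", 1.0, -1.0)
        u = dv.dv["categorical"][:, b_lo:b_hi + 1].mean(axis=1) * sign
        strength = np.abs(trials["orientation"].to_numpy())
        cor = trials["correct"].to_numpy().astype(bool)
        s_c = slope(strength[cor], u[cor])
        s_e = slope(strength[~cor], u[~cor])
        slope_cor.append(s_c)
        slope_err.append(s_e)
        graded_corr_pos += s_c > 0
        graded_err_neg += s_e < 0
        # (b) residual variance across the accumulation window
        vp = variance_partition(dv, trials)
        edges = vp.bin_left_edges_ms
        lo = int(np.flatnonzero(np.isclose(edges, win_lo))[0])
        hi = b_hi
        dc = vp.components["categorical"]["res"][hi] - \
            vp.components["categorical"]["res"][lo]
        dm = vp.components["motor"]["res"][hi] - vp.components["motor"]["res"][lo]
        d_cat_rise.append(dc / vp.n_trials)
        d_mot_rise.append(dm / vp.n_trials)
        cat_rise_pos += dc > 0
        mot_rise_pos += dm > 0
        mot_rise_ge_cat += dm >= dc
        # (c) peak times by accuracy
        boot = peak_time_bootstrap(
            trials, dv, group_column="correct", n_boot=n_boot, seed=s,
            n_starts_point=12, n_starts_boot=1,
        )
        # bootstrap-median peak estimates: stabler than the single point fit
        med = {k: float(np.nanmedian(v)) for k, v in boot.samples.items()}
        dcp = med[(0, "categorical")] - med[(1, "categorical")]
        dmp = med[(0, "motor")] - med[(1, "motor")]
        d_cat_peak.append(dcp)
        d_mot_peak.append(dmp)
        cat_peak_later_err += dcp > 0
        mot_peak_later_err += dmp > 0
    return {
        "n_sessions": n_sessions,
        "graded_correct_positive": int(graded_corr_pos),
        "graded_error_negative": int(graded_err_neg),
        "median_slope_correct": float(np.median(slope_cor)),
        "median_slope_error": float(np.median(slope_err)),
        "categorical_residual_rise_positive": int(cat_rise_pos),
        "motor_residual_rise_positive": int(mot_rise_pos),
        "motor_rise_at_least_categorical": int(mot_rise_ge_cat),
        "median_categorical_residual_rise": float(np.median(d_cat_rise)),
        "median_motor_residual_rise": float(np.median(d_mot_rise)),
        "categorical_peak_later_on_error": int(cat_peak_later_err),
        "motor_peak_later_on_error": int(mot_peak_later_err),
        "median_categorical_peak_delay_ms": float(np.median(d_cat_peak)),
        "median_motor_peak_delay_ms": float(np.median(d_mot_peak)),
    }


def geometry_experiment(
    n_sessions: int = 20, seed: int = 0, n_trials: int = 320,
    motor_lag_ms: float = 100.0,
) -> dict:
    """DV geometry on generator data.

    Part 1 (default generator, independent loadings): circular-mean angle
    between the categorical and motor decoder weights.  Part 2 (motor
    latent = rule-signed categorical latent delayed by ``motor_lag_ms``):
    peak lag of the shuffle-corrected cross-correlation and the sign
    relation between the two mapping rules.
    """
    task = TaskConfig(n_trials=n_trials)
    emission = EmissionConfig()
    seeds = _child_seeds(seed, 2 * n_sessions)
    dv_list = []
    for s in seeds[:n_sessions]:
        _, _, dv = _simulate_and_decode(task, ProcessConfig(), emission, s)
        dv_list.append(dv)
    ang = angle_series(dv_list, ci_boot=0)
    mean_angle = float(np.nanmean(ang.angles_deg))

    lag_proc = ProcessConfig(motor_lag_ms=motor_lag_ms)
    peak_lags, sign_flips = [], 0
    for s in seeds[n_sessions:]:
        trials, _, dv = _simulate_and_decode(task, lag_proc, emission, s)
        xc = xcorr_trialwise(dv, trials, seed=s)
        rules = sorted(xc.corrected_by_rule)
        c1, c2 = (xc.corrected_by_rule[r] for r in rules[:2])
        k = int(np.nanargmax(np.abs(c1) + np.abs(c2)))
        peak_lags.append(float(xc.lags_ms[k]))
        sign_flips += c1[k] * c2[k] < 0
    return {
        "n_sessions": n_sessions,
        "mean_angle_deg": mean_angle,
        "median_xcorr_peak_lag_ms": float(np.median(peak_lags)),
        "embedded_lag_ms": motor_lag_ms,
        "rule_sign_flips": int(sign_flips),
    }


def expectation_linkage_experiment(
    n_sessions: int = 30, seed: int = 0, n_trials: int = 640,
    n_perm: int = 2000,
) -> dict:
    """Across sessions with varying prior starting-point offsets, correlate
    the neural expectation (categorical and motor DV bias at -500 ms, per
    contrast) with the behaviorally fitted decision bias."""
    task = TaskConfig(n_trials=n_trials)
    emission = EmissionConfig()
    rng = np.random.default_rng(seed)
    neural_c, neural_m, behavioral = [], [], []
    for s in _child_seeds(seed, n_sessions):
        z_low = float(rng.uniform(0.02, 0.30))
        proc = ProcessConfig(
            prior_start_offset={"high": z_low / 2.0, "low": z_low}
        )
        trials, _, dv = _simulate_and_decode(task, proc, emission, s)
        bias_neural = dv_bias(dv, trials, readout_ms=-500.0)
        for contrast in ("high", "low"):
            fit = PriorBiasModel.from_trials(
                trials[trials["contrast"] == contrast]
            ).fit()
            behavioral.append(fit.decision_bias)
            neural_c.append(bias_neural.expectation[(contrast, "categorical")])
            neural_m.append(bias_neural.expectation[(contrast, "motor")])
    rng_p = np.random.default_rng(seed + 1)
    out = {"n_pairs": len(behavioral), "n_sessions": n_sessions}
    for name, x in (("categorical", neural_c), ("motor", neural_m)):
        r = spearmanr(x, behavioral).statistic
        null = np.empty(n_perm)
        b = np.asarray(behavioral)
        for i in range(n_perm):
            null[i] = spearmanr(x, rng_p.permutation(b)).statistic
        out[f"rho_{name}"] = float(r)
        out[f"p_{name}"] = float((1 + np.sum(np.abs(null) >= abs(r))) / (n_perm + 1))
    return out


# ---------------------------------------------------------------------------
# psychometric recovery


def psychometric_recovery(
    n_sessions: int = 100, seed: int = 0, n_trials: int = 2000,
    sigma: float = 2.0, lapse: float = 0.02, bias_deg: float = 0.8,
) -> dict:
    """Simulate Bernoulli choices from known psychometric parameters and
    recover sigma and the prior decision bias."""
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    orientations = np.array([-3.3, -2.2, -1.1, 0.0, 1.1, 2.2, 3.3])
    rel_sigma_err, bias_err = [], []
    for _ in range(n_sessions):
        theta = rng.choice(orientations, n_trials)
        prior = np.where(rng.random(n_trials) < 0.5, "cw", "ccw")
        mu = np.where(prior == "cw", -bias_deg / 2.0, bias_deg / 2.0)
        p = lapse / 2.0 + (1 - lapse) * norm.cdf((theta - mu) / sigma)
        y = (rng.random(n_trials) < p).astype(int)
        choice = np.where(y == 1, "cw", "ccw")
        trials = pd.DataFrame(
            {"orientation": theta, "prior": prior, "choice_category": choice}
        )
        psy = PsychometricModel.from_trials(trials).fit()
        bias_fit = PriorBiasModel.from_trials(trials).fit()
        rel_sigma_err.append(abs(psy.sigma - sigma) / sigma)
        bias_err.append(abs(bias_fit.decision_bias - bias_deg))
    return {
        "n_sessions": n_sessions,
        "median_rel_sigma_error": float(np.median(rel_sigma_err)),
        "median_bias_error_deg": float(np.median(bias_err)),
    }


# ---------------------------------------------------------------------------
# determinism


def pipeline_determinism(seed: int = 0, workdir=None, config: dict | None = None
                         ) -> dict:
    """Run the default pipeline twice with one seed and compare every output
    file bitwise."""
    import tempfile

    cfg = config or {
        "n_sessions": 2,
        "task": {"n_trials": 160},
        "motifs": {"n_starts": 6},
    }
    base = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="dvmotifs_"))
    out_a, out_b = base / "run_a", base / "run_b"
    run_pipeline(cfg, seed=seed, outdir=out_a)
    run_pipeline(cfg, seed=seed, outdir=out_b)
    files_a = sorted(p.relative_to(out_a) for p in out_a.rglob("*") if p.is_file())
    files_b = sorted(p.relative_to(out_b) for p in out_b.rglob("*") if p.is_file())
    identical = files_a == files_b and all(
        filecmp.cmp(out_a / f, out_b / f, shallow=False) for f in files_a
    )
    return {"identical": bool(identical), "n_files": len(files_a)}
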