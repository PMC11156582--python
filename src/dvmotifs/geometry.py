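"""Geometry of the two decoder dimensions.

Vector angle between the categorical and motor weight vectors per bin
(arc-cosine of the normalized inner product), temporal stability of each
projection plane, and the shuffle-corrected trial-wise cross-correlation
between the two DV time series.

Lag convention: ``corr(lag)`` pairs the categorical DV at t + lag with the
motor DV at t, so a categorical signal that leads the motor signal produces
a peak at negative lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BIN_MS


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# vector angles


def vector_angle(w_c: np.ndarray, w_m: np.ndarray) -> np.ndarray:
    """Angle (deg, in [0, 180]) between weight vectors, per bin.

    Inputs are (n_bins, n_units) or (n_units,).  Zero-norm vectors yield
    NaN (undefined angle) rather than an arbitrary value.
    """
    w_c = np.atleast_2d(np.asarray(w_c, float))
    w_m = np.atleast_2d(np.asarray(w_m, float))
    if w_c.shape != w_m.shape:
        raise GeometryError("weight arrays must share a unit set and bin grid")
    nc = np.linalg.norm(w_c, axis=1)
    nm = np.linalg.norm(w_m, axis=1)
    dot = np.einsum("bi,bi->b", w_c, w_m)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = dot / (nc * nm)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ang[(nc == 0) | (nm == 0)] = np.nan
    return ang if ang.size > 1 else ang


def circular_mean_deg(angles, axis=None) -> float | np.ndarray:
    """Circular mean of angles in degrees (NaNs ignored)."""
    a = np.radians(np.asarray(angles, float))
    s = np.nanmean(np.sin(a), axis=axis)
    c = np.nanmean(np.cos(a), axis=axis)
    return np.degrees(np.arctan2(s, c)) % 360.0


@dataclass
class AngleSeries:
    angles_deg: np.ndarray        # (n_sessions, n_bins) or (n_bins,)
    bin_left_edges_ms: np.ndarray
    mean_deg: np.ndarray | None = None   # circular mean across sessions
    ci95_deg: np.ndarray | None = None   # (2, n_bins)


def angle_series(dv_list, ci_boot: int = 200, seed: int = 0) -> AngleSeries:
    """Per-bin angle between the categorical and motor decoder weights,
    aggregated across sessions with a bootstrap 95% CI of the circular
    mean."""
    dv_list = dv_list if isinstance(dv_list, (list, tuple)) else [dv_list]
    rows = []
    for dv in dv_list:
        rows.append(
            vector_angle(dv.weights["categorical"].w, dv.weights["motor"].w)
        )
    angles = np.vstack(rows)
    mean = circular_mean_deg(angles, axis=0)
    ci = None
    if len(rows) > 1 and ci_boot:
        rng = np.random.default_rng(seed)
        boots = np.empty((ci_boot, angles.shape[1]))
        for i in range(ci_boot):
            idx = rng.integers(0, len(rows), len(rows))
            boots[i] = circular_mean_deg(angles[idx], axis=0)
        ci = np.percentile(boots, [2.5, 97.5], axis=0)
    return AngleSeries(
        angles_deg=angles,
        bin_left_edges_ms=dv_list[0].bin_left_edges_ms,
        mean_deg=mean,
        ci95_deg=ci,
    )


def plane_stability(weights: np.ndarray, reference_bin: int = -1) -> np.ndarray:
    """Angle of each bin's weight vector to a reference bin's vector.

    Default reference is the final pre-saccadic bin.  Requires >= 2 bins.
    """
    W = np.asarray(weights, float)
    if W.ndim != 2 or W.shape[0] < 2:
        raise GeometryError("need a (n_bins >= 2, n_units) weight array")
    ref = np.broadcast_to(W[reference_bin], W.shape)
    return vector_angle(W, ref.copy())


# ---------------------------------------------------------------------------
# trial-wise cross-correlation


def _xcorr_matrix(xc: np.ndarray, xm: np.ndarray, max_lag: int, min_overlap: int):
    """Normalized cross-correlation per trial for lags -max_lag..max_lag.

    Series are mean-subtracted per trial; normalization is by the product
    of the full-series norms (biased estimator).  Trials with a constant
    series are returned as NaN rows.
    """
    n, T = xc.shape
    xc = xc - xc.mean(axis=1, keepdims=True)
    xm = xm - xm.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(xc, axis=1) * np.linalg.norm(xm, axis=1)
    lags = np.arange(-max_lag, max_lag + 1)
    out = np.full((n, len(lags)), np.nan)
    for i, lag in enumerate(lags):
        if lag >= 0:
            a, b = xc[:, lag:], xm[:, : T - lag]
        else:
            a, b = xc[:, :T + lag], xm[:, -lag:]
        if a.shape[1] < min_overlap:
            continue
        num = np.einsum("nt,nt->n", a, b)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, i] = num / denom
    out[denom == 0] = np.nan
    return lags, out


@dataclass
class XCorrResult:
    lags_ms: np.ndarray
    raw_by_rule: dict             # rule -> mean raw cross-correlation curve
    corrected_by_rule: dict       # rule -> rule mean minus global mean
    global_mean: np.ndarray
    null_band: dict               # rule -> (2, n_lags) 2.5/97.5 percentiles
    n_trials: dict
    n_skipped: int = 0


def xcorr_trialwise(
    dv,
    trials: pd.DataFrame,
    subset: np.ndarray | None = None,
    max_lag_bins: int = 10,
    min_overlap: int = 5,
    n_null: int = 40,
    seed: int = 0,
) -> XCorrResult:
    """Trial-wise categorical/motor cross-correlation, split by mapping rule.

    Each trial's normalized cross-correlation function is averaged within
    mapping rule; the session's global average is subtracted from each rule
    average (removing rule-independent autocorrelation structure).  The
    null band re-pairs each trial's categorical DV with the motor DV of a
    circularly shifted trial within the same rule (the next trial and
    further shifts), which preserves autocorrelation but severs trial
    identity.
    """
    trials = trials.reset_index(drop=True)
    mask = np.ones(len(trials), bool) if subset is None else np.asarray(subset, bool)
    xc_all = dv.dv["categorical"]
    xm_all = dv.dv["motor"]
    rules = trials["mapping_rule"].to_numpy()
    lags = None
    raw_by_rule, n_trials, per_rule_curves = {}, {}, {}
    skipped = 0
    rule_names = [r for r in np.unique(rules[mask])]
    for rule in rule_names:
        m = mask & (rules == rule)
        if m.sum() < 2:
            raise GeometryError(f"need >=2 trials for mapping rule {rule!r}")
        lags, mat = _xcorr_matrix(xc_all[m], xm_all[m], max_lag_bins, min_overlap)
        ok = ~np.all(np.isnan(mat), axis=1)
        skipped += int((~ok).sum())
        per_rule_curves[rule] = (m, mat)
        raw_by_rule[rule] = np.nanmean(mat[ok], axis=0)
        n_trials[rule] = int(ok.sum())
    weights = np.array([n_trials[r] for r in rule_names], float)
    global_mean = (
        np.vstack([raw_by_rule[r] for r in rule_names]).T @ weights / weights.sum()
    )
    corrected = {r: raw_by_rule[r] - global_mean for r in rule_names}

    # shuffle null: circular within-rule shifts of the motor series
    null_band = {}
    rng = np.random.default_rng(seed)
    null_curves = {r: [] for r in rule_names}
    for k in range(1, n_null + 1):
        shuffled_raw = {}
        for rule in rule_names:
            m, _ = per_rule_curves[rule]
            xm_r = xm_all[m]
            shift = k if k < m.sum() else int(rng.integers(1, m.sum()))
            xm_shift = np.roll(xm_r, -shift, axis=0)
            _, mat = _xcorr_matrix(xc_all[m], xm_shift, max_lag_bins, min_overlap)
            ok = ~np.all(np.isnan(mat), axis=1)
            shuffled_raw[rule] = np.nanmean(mat[ok], axis=0)
        g = (
            np.vstack([shuffled_raw[r] for r in rule_names]).T
            @ weights / weights.sum()
        )
        for rule in rule_names:
            null_curves[rule].append(shuffled_raw[rule] - g)
    for rule in rule_names:
        null_band[rule] = np.percentile(
            np.vstack(null_curves[rule]), [2.5, 97.5], axis=0
        )
    return XCorrResult(
        lags_ms=lags * BIN_MS,
        raw_by_rule=raw_by_rule,
        corrected_by_rule=corrected,
        global_mean=global_mean,
        null_band=null_band,
        n_trials=n_trials,
        n_skipped=skipped,
    )
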