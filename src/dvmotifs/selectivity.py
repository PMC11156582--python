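"""Single-unit choice selectivity and the memory-guided-saccade
response-field test.

Selectivity is a signal-to-noise ratio: the difference of the two
choice-conditioned mean responses in a bin, normalized by the pooled
response standard deviation (square root of the unweighted mean of the two
group variances).  Each unit's trace is signed so that its maximal value is
positive, making categorical and motor traces comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np

from .containers import BIN_CENTERS, BinnedResponses


class SelectivityError(ValueError):
    pass


@dataclass
class SNRTrace:
    values: np.ndarray           # (n_units, n_bins) signed SNR
    peak_time_ms: np.ndarray     # (n_units,) bin center of the maximum
    flipped: np.ndarray          # (n_units,) bool, sign convention applied
    zero_sd_bins: int = 0        # count of (unit, bin) cells with zero pooled sd
    bin_centers_ms: np.ndarray = field(default_factory=lambda: BIN_CENTERS.copy())
    labeling: str = ""


def snr_timecourse(
    responses: BinnedResponses, labels: np.ndarray, labeling: str = ""
) -> SNRTrace:
    """Choice-selectivity (SNR) timecourse per unit.

    ``labels`` is boolean per trial.  Bins where the pooled sd is zero get
    SNR 0 (counted in ``zero_sd_bins``).  Traces are sign-flipped when their
    maximum is not positive, so max(trace) > 0 unless the trace is all-zero.
    """
    labels = np.asarray(labels, bool)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise SelectivityError("both label values need at least 2 trials")
    counts = responses.counts.astype(float)
    a, b = counts[:, :, labels], counts[:, :, ~labels]
    diff = a.mean(axis=2) - b.mean(axis=2)
    pooled = np.sqrt((a.var(axis=2, ddof=1) + b.var(axis=2, ddof=1)) / 2.0)
    zero = pooled == 0
    snr = np.zeros_like(diff)
    snr[~zero] = diff[~zero] / pooled[~zero]
    flip = snr.max(axis=1) <= 0
    nonzero = np.any(snr != 0, axis=1)
    flip &= nonzero
    snr[flip] *= -1.0
    centers = responses.bin_edges_ms[:-1] + np.diff(responses.bin_edges_ms) / 2.0
    peak = centers[np.argmax(snr, axis=1)]
    peak = np.where(nonzero, peak, np.nan)
    return SNRTrace(
        values=snr,
        peak_time_ms=peak,
        flipped=flip,
        zero_sd_bins=int(zero.sum()),
        bin_centers_ms=centers,
        labeling=labeling,
    )


@dataclass
class PeakOrderSummary:
    n_units: int
    n_excluded: int
    n_cat_before_go: int
    n_mot_after_go: int
    n_cat_before_and_mot_after: int
    go_cue_ms: float


def peak_order_summary(
    categorical: SNRTrace, motor: SNRTrace, go_cue_ms: float = -150.0
) -> PeakOrderSummary:
    """Count units whose categorical selectivity peaks before the go cue and
    whose motor selectivity peaks after it.

    Units with an all-zero trace in either labeling (undefined peak) are
    excluded and reported.
    """
    cat_peak = categorical.peak_time_ms
    mot_peak = motor.peak_time_ms
    valid = ~np.isnan(cat_peak) & ~np.isnan(mot_peak)
    cat_before = valid & (cat_peak < go_cue_ms)
    mot_after = valid & (mot_peak >= go_cue_ms)
    return PeakOrderSummary(
        n_units=int(valid.sum()),
        n_excluded=int((~valid).sum()),
        n_cat_before_go=int(cat_before.sum()),
        n_mot_after_go=int(mot_after.sum()),
        n_cat_before_and_mot_after=int((cat_before & mot_after).sum()),
        go_cue_ms=go_cue_ms,
    )


def peak_selectivity_table(categorical: SNRTrace, motor: SNRTrace,
                           unit_ids=None):
    """Per-unit peak selectivity and timing for both labelings, as a
    DataFrame ready for CSV export."""
    import pandas as pd

    n = categorical.values.shape[0]
    ids = unit_ids if unit_ids is not None else [f"u{i:03d}" for i in range(n)]
    return pd.DataFrame(
        {
            "unit_id": list(ids),
            "peak_snr_categorical": categorical.values.max(axis=1),
            "peak_time_categorical_ms": categorical.peak_time_ms,
            "peak_snr_motor": motor.values.max(axis=1),
            "peak_time_motor_ms": motor.peak_time_ms,
        }
    )


@dataclass
class ResponseFieldResult:
    has_field: bool
    preferred_location: int
    observed_diff: float
    null_interval: tuple
    alpha: float
    flagged: str = ""


def response_field_test(
    counts_by_location: list,
    alpha: float = 0.05,
    n_null: int = 1000,
    seed: int = 0,
) -> ResponseFieldResult:
    """Poisson parametric-bootstrap test for a motor response field.

    ``counts_by_location`` is a sequence (one entry per saccade target
    location, typically 24 = 3 radii x 8 directions) of per-trial
    pre-saccadic spike counts.  The statistic is the preferred (maximal)
    location's mean minus the grand mean of the remaining locations; it is
    compared with the central (1 - alpha) interval of the same statistic
    under a null in which every location fires Poisson at the pooled mean.
    """
    arrays = [np.asarray(c, float) for c in counts_by_location]
    if len(arrays) < 2:
        raise SelectivityError("need at least 2 locations")
    for i, arr in enumerate(arrays):
        if len(arr) < 2:
            raise SelectivityError(f"location {i} has fewer than 2 trials")
    means = np.array([a.mean() for a in arrays])
    pooled = np.concatenate(arrays)
    if pooled.sum() == 0:
        return ResponseFieldResult(
            has_field=False,
            preferred_location=0,
            observed_diff=0.0,
            null_interval=(0.0, 0.0),
            alpha=alpha,
            flagged="all-zero counts",
        )

    def statistic(ms):
        pref = int(np.argmax(ms))
        others = np.delete(ms, pref)
        return ms[pref] - others.mean(), pref

    obs, pref = statistic(means)
    rng = np.random.default_rng(seed)
    lam = pooled.mean()
    ns = [len(a) for a in arrays]
    null = np.empty(n_null)
    for i in range(n_null):
        sim_means = np.array([rng.poisson(lam, n).mean() for n in ns])
        null[i], _ = statistic(sim_means)
    lo, hi = np.percentile(null, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return ResponseFieldResult(
        has_field=bool(obs < lo or obs > hi),
        preferred_location=pref,
        observed_diff=float(obs),
        null_interval=(float(lo), float(hi)),
        alpha=alpha,
    )
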