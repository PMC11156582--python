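"""Deliberation signatures carried by the decision variables.

* Variance partition: for each bin and DV dimension, the total sum of
  squares splits exactly into choice, stimulus and residual components,

      sum_k (DV_k - m)^2 = sum_k (m_choice(k) - m)^2
                         + sum_k (m_cell(k) - m_choice(k))^2
                         + sum_k (DV_k - m_cell(k))^2,

  where m_choice(k) averages trials sharing trial k's choice and m_cell(k)
  averages trials sharing both its choice and its stimulus.
* Residual timecourse: the residual fraction over time; under temporal
  integration of noisy evidence its categorical component rises during
  accumulation (diffusion) while the motor component does not.
* DV bias: congruent-minus-incongruent unsigned DV difference computed per
  stimulus-strength level and then averaged with equal level weights, so
  that stimulus strength itself cannot masquerade as bias.  Its value at a
  fixed pre-saccadic readout time (default -500 ms) is the session's
  "neural expectation".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .decoding import DIMENSIONS, LABEL_COLUMNS, unsign_dv


class SignatureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# variance partition


def partition_sums(dv: np.ndarray, choice: np.ndarray, stim: np.ndarray):
    """Exact three-way sum-of-squares partition for one vector of DV values.

    Returns (S_total, S_choice, S_stim, S_res)."""
    dv = np.asarray(dv, float)
    if len(dv) < 2:
        raise SignatureError("need at least 2 trials")
    df = pd.DataFrame({"dv": dv, "choice": choice, "stim": stim})
    grand = dv.mean()
    m_choice = df.groupby("choice")["dv"].transform("mean").to_numpy()
    m_cell = df.groupby(["choice", "stim"])["dv"].transform("mean").to_numpy()
    s_choice = np.sum((m_choice - grand) ** 2)
    s_stim = np.sum((m_cell - m_choice) ** 2)
    s_res = np.sum((dv - m_cell) ** 2)
    s_total = np.sum((dv - grand) ** 2)
    return float(s_total), float(s_choice), float(s_stim), float(s_res)


@dataclass
class VariancePartition:
    components: dict   # dimension -> {"total","choice","stim","res"}: (n_bins,)
    fractions: dict    # dimension -> {"stim","res"}: (n_bins,)
    bin_left_edges_ms: np.ndarray
    n_trials: int


def variance_partition(dv, trials: pd.DataFrame) -> VariancePartition:
    """Per-bin, per-dimension variance partition of the DV.

    The choice factor is each dimension's own labeling (category for the
    categorical DV, saccade direction for the motor DV); the stimulus
    factor is the orientation.
    """
    trials = trials.reset_index(drop=True)
    if len(trials) < 2:
        raise SignatureError("need at least 2 trials")
    stim = trials["orientation"].to_numpy()
    components, fractions = {}, {}
    for dim in DIMENSIONS:
        choice = trials[LABEL_COLUMNS[dim]].to_numpy()
        series = dv.dv[dim]
        n_bins = series.shape[1]
        comp = {k: np.empty(n_bins) for k in ("total", "choice", "stim", "res")}
        for b in range(n_bins):
            t, c, s, r = partition_sums(series[:, b], choice, stim)
            comp["total"][b], comp["choice"][b] = t, c
            comp["stim"][b], comp["res"][b] = s, r
        with np.errstate(invalid="ignore", divide="ignore"):
            fractions[dim] = {
                "stim": comp["stim"] / comp["total"],
                "res": comp["res"] / comp["total"],
            }
        components[dim] = comp
    return VariancePartition(
        components=components,
        fractions=fractions,
        bin_left_edges_ms=dv.bin_left_edges_ms,
        n_trials=len(trials),
    )


@dataclass
class ResidualRise:
    fraction: dict               # dimension -> (n_bins,) residual fraction
    rise_interval_ms: dict       # dimension -> (start, end) or None
    rise_length_ms: dict
    bin_left_edges_ms: np.ndarray


def residual_timecourse(
    vp: VariancePartition, window_start_ms: float = -600.0
) -> ResidualRise:
    """Residual-fraction series plus the largest contiguous rise interval
    at or after `window_start_ms` (default: around stimulus onset)."""
    edges = vp.bin_left_edges_ms
    out_frac, out_int, out_len = {}, {}, {}
    for dim, frac in vp.fractions.items():
        series = frac["res"]
        out_frac[dim] = series
        eligible = np.flatnonzero(edges >= window_start_ms)
        best = (0, None)
        run_start = None
        for i in eligible:
            if i == 0:
                continue
            if series[i] > series[i - 1]:
                if run_start is None:
                    run_start = i - 1
                length = edges[i] - edges[run_start]
                if length > best[0]:
                    best = (length, (float(edges[run_start]), float(edges[i])))
            else:
                run_start = None
        out_len[dim] = float(best[0])
        out_int[dim] = best[1]
    return ResidualRise(
        fraction=out_frac,
        rise_interval_ms=out_int,
        rise_length_ms=out_len,
        bin_left_edges_ms=edges,
    )


# ---------------------------------------------------------------------------
# DV bias and neural expectation


@dataclass
class DVBiasResult:
    bias: dict            # (contrast, dimension) -> (n_bins,) level-avg difference
    per_level: dict       # (contrast, dimension) -> {level: (n_bins,) difference}
    expectation: dict     # (contrast, dimension) -> bias at the readout bin
    readout_ms: float
    excluded_levels: dict # contrast -> levels lacking one congruency group
    bin_left_edges_ms: np.ndarray


def congruency_labels(trials: pd.DataFrame) -> np.ndarray:
    """True where the chosen category matches the block's over-represented
    category (defined on choices, not on the presented stimulus)."""
    return (trials["choice_category"] == trials["prior"]).to_numpy()


def dv_bias(dv, trials: pd.DataFrame, readout_ms: float = -500.0) -> DVBiasResult:
    """Prior-induced bias of the unsigned DV, per contrast and dimension.

    For each stimulus-strength level (|orientation|) the congruent and
    incongruent unsigned trajectories are averaged and differenced; level
    differences are then averaged with equal weights.  Levels missing a
    congruency group are excluded and reported.  The neural expectation is
    the bias at `readout_ms` (must lie on the bin grid).
    """
    trials = trials.reset_index(drop=True)
    readout_bin = dv.bin_index(readout_ms)  # raises off-grid
    unsigned = unsign_dv(dv, trials)
    congruent = congruency_labels(trials)
    strength = np.abs(trials["orientation"].to_numpy())
    contrast = trials["contrast"].to_numpy()
    bias, per_level, expectation, excluded = {}, {}, {}, {}
    for c in np.unique(contrast):
        cm = contrast == c
        levels = np.unique(strength[cm])
        excluded[c] = []
        diffs_by_level = {}
        for lv in levels:
            m = cm & (strength == lv)
            gcon, ginc = m & congruent, m & ~congruent
            if not gcon.any() or not ginc.any():
                excluded[c].append(float(lv))
                continue
            for dim in DIMENSIONS:
                d = unsigned[dim][gcon].mean(axis=0) - unsigned[dim][ginc].mean(axis=0)
                diffs_by_level.setdefault(dim, {})[float(lv)] = d
        if not diffs_by_level:
            raise SignatureError(
                f"no stimulus level under contrast {c!r} has both congruency groups"
            )
        for dim in DIMENSIONS:
            stack = np.vstack(list(diffs_by_level[dim].values()))
            bias[(c, dim)] = stack.mean(axis=0)
            per_level[(c, dim)] = diffs_by_level[dim]
            expectation[(c, dim)] = float(bias[(c, dim)][readout_bin])
    return DVBiasResult(
        bias=bias,
        per_level=per_level,
        expectation=expectation,
        readout_ms=readout_ms,
        excluded_levels=excluded,
        bin_left_edges_ms=dv.bin_left_edges_ms,
    )


def readout_sensitivity(dv, trials: pd.DataFrame, readout_ms: float = -500.0,
                        n_bins_around: int = 2) -> dict:
    """Neural expectation recomputed at readout times +/- `n_bins_around`
    bins -- the robustness check that nearby readout moments agree."""
    step = float(dv.bin_left_edges_ms[1] - dv.bin_left_edges_ms[0])
    out = {}
    for k in range(-n_bins_around, n_bins_around + 1):
        t = readout_ms + k * step
        if t < dv.bin_left_edges_ms[0] or t > dv.bin_left_edges_ms[-1]:
            continue
        out[t] = dv_bias(dv, trials, readout_ms=t).expectation
    return out


# ---------------------------------------------------------------------------
# expectation vs behavioral bias


@dataclass
class ExpectationCorrelation:
    rho: dict       # dimension -> Spearman rho
    p_perm: dict    # dimension -> permutation p-value
    n_pairs: int
    n_perm: int
    undefined: bool = False


def expectation_vs_behavior(
    neural: dict, behavioral: np.ndarray, n_perm: int = 2000, seed: int = 0
) -> ExpectationCorrelation:
    """Rank correlation between neural expectation and behavioral bias.

    ``neural`` maps dimension -> array of per-session (or per session x
    contrast) expectations; ``behavioral`` is the matching vector of
    behavioral decision biases.  Significance is assessed by permutation.
    """
    behavioral = np.asarray(behavioral, float)
    if len(behavioral) < 5:
        raise SignatureError("need at least 5 paired observations")
    rng = np.random.default_rng(seed)
    rho, p_perm = {}, {}
    undefined = False
    for dim, x in neural.items():
        x = np.asarray(x, float)
        if len(x) != len(behavioral):
            raise SignatureError("neural and behavioral vectors differ in length")
        if np.all(x == x[0]) or np.all(behavioral == behavioral[0]):
            rho[dim], p_perm[dim] = float("nan"), float("nan")
            undefined = True
            continue
        r_obs = spearmanr(x, behavioral).statistic
        null = np.empty(n_perm)
        for i in range(n_perm):
            null[i] = spearmanr(x, rng.permutation(behavioral)).statistic
        p = (1 + np.sum(np.abs(null) >= abs(r_obs))) / (n_perm + 1)
        rho[dim], p_perm[dim] = float(r_obs), float(p)
    return ExpectationCorrelation(
        rho=rho, p_perm=p_perm, n_pairs=len(behavioral), n_perm=n_perm,
        undefined=undefined,
    )
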