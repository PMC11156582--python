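"""Synthetic session generator with known ground truth.

Emulates a flexible orientation-categorization task: seven orientations
around vertical, two randomly interleaved stimulus-response mapping rules,
alternating 80-trial blocks of two skewed stimulus priors and of two
contrast levels.  The latent decision process is a bounded drift-diffusion
accumulation of orientation evidence on a "categorical" axis, followed --
a fixed delay after evidence onset -- by transfer of the accumulated state
onto an orthogonal "motor" axis whose sign is set by the trial's mapping
rule.  Population spike counts are Poisson emissions with mixed (and
mutually independent) categorical/motor loadings, so the two axes are
orthogonal in expectation at the population level.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` children, one per stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import (
    BIN_EDGES,
    BIN_MS,
    EPOCH_MS,
    N_BINS,
    BinnedResponses,
    saccade_direction_for,
)


class ConfigError(ValueError):
    """Invalid generator configuration."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class TaskConfig:
    """Task design: stimuli, block structure, event timing.

    Orientations are degrees from vertical (positive = clockwise).  Event
    times are means relative to fixation onset; each event receives an
    independent uniform jitter of 0-65 ms, as in the task it emulates.
    """

    orientations: tuple = (-3.3, -2.2, -1.1, 0.0, 1.1, 2.2, 3.3)
    contrasts: tuple = ("high", "low")
    contrast_block: int = 100
    prior_block: int = 80
    prior_skew: float = 0.75      # mass on the over-represented side
    zero_weight: float = 1.0 / 7  # mass on the vertical (0 deg) stimulus
    n_trials: int = 320
    # event timing (ms from fixation onset)
    t_targets_mean: float = 500.0
    t_stimulus_after_targets: float = 250.0
    stimulus_duration: float = 500.0
    event_jitter: float = 65.0

    def validate(self) -> None:
        ori = np.asarray(self.orientations, float)
        if not np.allclose(np.sort(ori), np.sort(-ori)):
            raise ConfigError("orientations must be symmetric about 0")
        if self.prior_block <= 0 or self.contrast_block <= 0:
            raise ConfigError("block lengths must be positive")
        if not 0.0 <= self.prior_skew <= 1.0:
            raise ConfigError("prior_skew must lie in [0, 1]")
        if (EPOCH_MS[1] - EPOCH_MS[0]) % BIN_MS:
            raise ConfigError("bin width must divide the epoch length")

    def prior_weights(self, prior: str) -> np.ndarray:
        """Sampling weights over `orientations` under one prior context.

        The vertical stimulus keeps a fixed mass; the remainder is split
        `prior_skew` / (1 - prior_skew) between the over- and
        under-represented sides.
        """
        ori = np.asarray(self.orientations, float)
        w = np.zeros_like(ori)
        zero = ori == 0
        n_zero = zero.sum()
        rest = 1.0 - (self.zero_weight * n_zero if n_zero else 0.0)
        if n_zero:
            w[zero] = self.zero_weight
        side = 1.0 if prior == "cw" else -1.0
        over = ori * side > 0
        under = ori * side < 0
        w[over] = rest * self.prior_skew / max(over.sum(), 1)
        w[under] = rest * (1.0 - self.prior_skew) / max(under.sum(), 1)
        return w / w.sum()


@dataclass
class ProcessConfig:
    """Latent bounded-accumulation / rotation decision process.

    Evidence units are scaled so the absorbing bound sits at
    ``bound_height``.  ``drift_gain`` maps stimulus orientation (deg) to
    drift (evidence/s); ``accumulation_noise`` is the diffusion s.d. per
    sqrt(second).  The prior context offsets the accumulator's starting
    point (not its drift), separately per contrast.

    Commitment happens at the per-trial bound-hit time, or at the
    deliberation deadline ``rotation_delay_ms`` after accumulation onset if
    the bound is never reached; the categorical latent decays exponentially
    from commitment onward.  The transfer onto the motor axis is gated at
    the fixed ``rotation_delay_ms`` (deliberation must fill the stimulus
    epoch before the response can be released), so the motor latent ramps
    -- over ``90 / rotation_angular_speed`` seconds -- to a largely
    stereotyped amplitude that only weakly echoes the committed categorical
    state through ``motor_gain``.  This makes the categorical trajectory's
    peak accuracy- and strength-dependent (early bound hits on easy correct
    trials) while the motor trajectory stays stereotyped.

    Setting ``motor_lag_ms`` switches the motor latent to a rule-signed
    delayed copy of the categorical latent (a pure constant-lag link,
    useful for calibrating lag-recovery analyses).
    """

    drift_gain: dict = field(default_factory=lambda: {"high": 1.0, "low": 0.45})
    accumulation_noise: float = 1.0
    bound_height: float = 0.5
    prior_start_offset: dict = field(default_factory=lambda: {"high": 0.08, "low": 0.16})
    rotation_delay_ms: float = 300.0
    rotation_angular_speed: float = 600.0   # deg of plane rotation per s
    categorical_decay_ms: float = 300.0
    motor_amplitude: float = 1.0
    motor_gain: float = 0.3
    non_decision_delay_ms: float = 50.0     # sensory latency to accumulation onset
    acc_onset_ms: float = -600.0            # mean accumulation onset, saccade-aligned
    onset_jitter_ms: float = 30.0
    lapse_rate: float = 0.02
    motor_lag_ms: float | None = None
    euler_step_ms: float = 5.0

    def validate(self) -> None:
        if self.bound_height <= 0:
            raise ConfigError("bound_height must be positive")
        if self.accumulation_noise <= 0:
            raise ConfigError("accumulation_noise must be positive")
        for c, z in self.prior_start_offset.items():
            if abs(z) >= self.bound_height:
                raise ConfigError(
                    f"|prior_start_offset[{c!r}]| must be below the bound"
                )
        if self.rotation_angular_speed <= 0:
            raise ConfigError("rotation_angular_speed must be positive")

    @property
    def rotation_ramp_ms(self) -> float:
        return 90.0 / self.rotation_angular_speed * 1000.0


@dataclass
class EmissionConfig:
    """Poisson population-emission model.

    Per-unit rate: ``max(0, baseline + a_i * x_c(t) + m_i * x_m(t))`` with
    counts drawn per 50-ms bin.  Loadings a (categorical) and m (motor) are
    drawn independently, giving mixed selectivity with no systematic
    relationship between preferred category and preferred direction.
    """

    n_units: int = 30
    baseline_mean: float = 10.0
    baseline_shape: float = 4.0
    baseline_min: float = 3.0
    loading_sd: float = 6.0

    def validate(self) -> None:
        if self.n_units < 2:
            raise ConfigError("need at least 2 units for population decoding")
        if self.baseline_min < 0:
            raise ConfigError("baseline_min must be nonnegative")


@dataclass
class SyntheticGroundTruth:
    """Latent trajectories and generator internals for recovery tests."""

    times_ms: np.ndarray              # (n_steps,) Euler grid, saccade-aligned
    x_categorical: np.ndarray         # (n_trials, n_steps)
    x_motor: np.ndarray               # (n_trials, n_steps)
    bound_hit_ms: np.ndarray          # nan where the bound was never reached
    acc_onset_ms: np.ndarray          # per-trial accumulation onset
    rotation_onset_ms: np.ndarray
    process_config: ProcessConfig | None = None
    task_config: TaskConfig | None = None
    emission_config: EmissionConfig | None = None
    loadings_categorical: np.ndarray | None = None
    loadings_motor: np.ndarray | None = None
    baselines: np.ndarray | None = None

    def binned_latents(self) -> tuple[np.ndarray, np.ndarray]:
        """Average the Euler-grid latents into the 50-ms analysis bins.

        Returns (x_c, x_m), each (n_trials, n_bins).
        """
        idx = np.digitize(self.times_ms, BIN_EDGES) - 1
        keep = (idx >= 0) & (idx < N_BINS)
        xc = np.stack(
            [self.x_categorical[:, keep & (idx == b)].mean(axis=1) for b in range(N_BINS)],
            axis=1,
        )
        xm = np.stack(
            [self.x_motor[:, keep & (idx == b)].mean(axis=1) for b in range(N_BINS)],
            axis=1,
        )
        return xc, xm


# ---------------------------------------------------------------------------
# stage 1: task trials


def _alternating_blocks(n_trials: int, block: int, options: tuple, rng) -> np.ndarray:
    """Blocks of `block` trials alternating between two options, random
    starting option.

    Prior and contrast use different block lengths (80 vs 100 by default),
    so the two blocked factors stay unconfounded.
    """
    first = rng.integers(2)
    n_blocks = math.ceil(n_trials / block)
    seq = [options[(first + b) % 2] for b in range(n_blocks)]
    return np.repeat(seq, block)[:n_trials]


def generate_task_trials(cfg: TaskConfig, seed: int) -> pd.DataFrame:
    """Generate the per-trial task variables (no outcomes yet).

    Prior context and contrast alternate in independent blocks; the mapping
    rule is drawn per trial with probability 1/2; orientation is drawn from
    the active prior's skewed distribution.  Outcome columns are filled by
    :func:`simulate_decision_process`.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = cfg.n_trials
    prior = _alternating_blocks(n, cfg.prior_block, ("cw", "ccw"), rng)
    contrast = _alternating_blocks(n, cfg.contrast_block, ("high", "low"), rng)
    rule = np.where(rng.random(n) < 0.5, "rule1", "rule2")
    ori = np.empty(n)
    orientations = np.asarray(cfg.orientations, float)
    for p in ("cw", "ccw"):
        mask = prior == p
        ori[mask] = rng.choice(orientations, size=mask.sum(), p=cfg.prior_weights(p))
    jit = lambda: rng.uniform(0.0, cfg.event_jitter, n)  # noqa: E731
    t_targets = cfg.t_targets_mean + jit()
    t_stim = t_targets + cfg.t_stimulus_after_targets + jit()
    t_stim_off = t_stim + cfg.stimulus_duration + jit()
    trials = pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "orientation": ori,
            "contrast": contrast,
            "prior": prior,
            "mapping_rule": rule,
            "choice_category": "",
            "saccade_direction": "",
            "correct": np.zeros(n, dtype=int),
            "saccade_time_ms": np.nan,
            "t_targets_ms": t_targets,
            "t_stimulus_ms": t_stim,
            "t_stimulus_off_ms": t_stim_off,
        }
    )
    return trials


# ---------------------------------------------------------------------------
# stage 2: latent decision process


def simulate_decision_process(
    trials: pd.DataFrame, cfg: ProcessConfig, seed: int
) -> tuple[pd.DataFrame, SyntheticGroundTruth]:
    """Simulate the bounded-accumulation / rotation latent process.

    Euler-discretized (5-ms steps) accumulation starts at the prior- and
    contrast-specific offset, drifts at ``drift_gain * orientation``, and is
    absorbed at the bound; unabsorbed trials are truncated at the
    deliberation deadline.  The categorical choice is the accumulator's
    sign at commitment; a lapse flips the reported choice (and hence the
    saccade) with probability ``lapse_rate``.  Returns the trial table with
    outcome columns filled plus the ground truth.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = len(trials)
    dt = cfg.euler_step_ms / 1000.0
    times = np.arange(EPOCH_MS[0], EPOCH_MS[1], cfg.euler_step_ms) + cfg.euler_step_ms / 2
    n_steps = len(times)

    ori = trials["orientation"].to_numpy(float)
    contrast = trials["contrast"].to_numpy()
    prior_sign = np.where(trials["prior"].to_numpy() == "cw", 1.0, -1.0)
    drift = np.array([cfg.drift_gain[c] for c in contrast]) * ori
    z0 = prior_sign * np.array([cfg.prior_start_offset[c] for c in contrast])

    acc_onset = cfg.acc_onset_ms + rng.uniform(0.0, cfg.onset_jitter_ms, n)
    t_rot = acc_onset + cfg.rotation_delay_ms

    x_c = np.tile(z0[:, None], (1, n_steps))
    bound_hit = np.full(n, np.nan)
    absorbed = np.zeros(n, dtype=bool)
    sign_at_bound = np.zeros(n)
    x = z0.copy()
    B = cfg.bound_height
    noise = rng.standard_normal((n, n_steps))
    for k in range(n_steps):
        t = times[k]
        active = (t >= acc_onset) & (t < t_rot) & ~absorbed
        if active.any():
            x[active] = (
                x[active]
                + drift[active] * dt
                + cfg.accumulation_noise * math.sqrt(dt) * noise[active, k]
            )
            hit = active & (np.abs(x) >= B)
            if hit.any():
                sign_at_bound[hit] = np.sign(x[hit])
                x[hit] = np.sign(x[hit]) * B
                absorbed[hit] = True
                bound_hit[hit] = t
        started = t >= acc_onset
        x_c[started, k] = x[started]

    # commitment: bound hit, or the deadline for unabsorbed trials
    t_commit = np.where(np.isnan(bound_hit), t_rot, bound_hit)
    # choice = sign of the accumulator at commitment
    x_term = x.copy()
    term_sign = np.sign(x_term)
    zero = term_sign == 0
    if zero.any():
        term_sign[zero] = rng.choice([-1.0, 1.0], size=zero.sum())
    lapse = rng.random(n) < cfg.lapse_rate
    choice_sign = np.where(lapse, -term_sign, term_sign)
    choice = np.where(choice_sign > 0, "cw", "ccw")

    correct = np.where(
        ori == 0,
        rng.random(n) < 0.5,  # random feedback on the vertical stimulus
        np.sign(ori) == choice_sign,
    ).astype(int)

    rule = trials["mapping_rule"].to_numpy()
    direction = np.array(
        [saccade_direction_for(r, c) for r, c in zip(rule, choice)]
    )
    dir_sign = np.where(direction == "right", 1.0, -1.0)
    rule_sign = np.where(rule == "rule1", 1.0, -1.0)

    # motor latent + categorical decay after transfer begins
    x_m = np.zeros((n, n_steps))
    if cfg.motor_lag_ms is not None:
        lag_steps = int(round(cfg.motor_lag_ms / cfg.euler_step_ms))
        if lag_steps > 0:
            x_m[:, lag_steps:] = x_c[:, :-lag_steps]
        else:
            x_m[:] = x_c
        x_m *= rule_sign[:, None]
    else:
        ramp_ms = cfg.rotation_ramp_ms
        m_target = dir_sign * (cfg.motor_amplitude + cfg.motor_gain * np.abs(x_term))
        rel = times[None, :] - t_rot[:, None]
        ramp = np.clip(rel / ramp_ms, 0.0, 1.0)
        x_m = m_target[:, None] * ramp
        # categorical decay starts at the per-trial commitment time
        rel_commit = times[None, :] - t_commit[:, None]
        decay = np.exp(-np.clip(rel_commit, 0.0, None) / cfg.categorical_decay_ms)
        x_c = np.where(rel_commit > 0, x_term[:, None] * decay, x_c)

    out = trials.copy()
    out["choice_category"] = choice
    out["saccade_direction"] = direction
    out["correct"] = correct
    # saccade initiation relative to stimulus onset (stimulus precedes
    # accumulation onset by the non-decision sensory latency)
    out["saccade_time_ms"] = -(acc_onset - cfg.non_decision_delay_ms)

    gt = SyntheticGroundTruth(
        times_ms=times,
        x_categorical=x_c,
        x_motor=x_m,
        bound_hit_ms=bound_hit,
        acc_onset_ms=acc_onset,
        rotation_onset_ms=t_rot,
        process_config=cfg,
        task_config=None,
    )
    return out, gt


# ---------------------------------------------------------------------------
# stage 3: Poisson emissions


def emit_population_spikes(
    gt: SyntheticGroundTruth, cfg: EmissionConfig, seed: int
) -> BinnedResponses:
    """Emit Poisson spike counts from the binned latent trajectories.

    Rate link is rectified-linear: ``max(0, baseline + a*x_c + m*x_m)``
    ips, integrated over the 50-ms bin.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    base = np.maximum(
        rng.gamma(cfg.baseline_shape, cfg.baseline_mean / cfg.baseline_shape, cfg.n_units),
        cfg.baseline_min,
    )
    a = rng.normal(0.0, cfg.loading_sd, cfg.n_units)
    m = rng.normal(0.0, cfg.loading_sd, cfg.n_units)
    xc, xm = gt.binned_latents()  # (n_trials, n_bins)
    rate = np.maximum(
        0.0,
        base[:, None, None]
        + a[:, None, None] * xc.T[None, :, :]
        + m[:, None, None] * xm.T[None, :, :],
    )
    counts = rng.poisson(rate * (BIN_MS / 1000.0))
    gt.loadings_categorical = a
    gt.loadings_motor = m
    gt.baselines = base
    gt.emission_config = cfg
    return BinnedResponses(counts=counts, bin_edges_ms=BIN_EDGES.copy())


# ---------------------------------------------------------------------------
# one-call session


def simulate_session(
    task: TaskConfig | None = None,
    process: ProcessConfig | None = None,
    emission: EmissionConfig | None = None,
    seed: int = 0,
):
    """Generate a complete synthetic session.

    Returns ``(trials, responses, ground_truth)``.  The single seed is
    expanded into independent per-stage child seeds.
    """
    task = task or TaskConfig()
    process = process or ProcessConfig()
    emission = emission or EmissionConfig()
    children = np.random.SeedSequence(seed).spawn(3)
    stage_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    trials = generate_task_trials(task, stage_seeds[0])
    trials, gt = simulate_decision_process(trials, process, stage_seeds[1])
    gt.task_config = task
    responses = emit_population_spikes(gt, emission, stage_seeds[2])
    responses.trial_ids = trials["trial_id"].to_numpy().copy()
    return trials, responses, gt


def config_dicts(task: TaskConfig, process: ProcessConfig, emission: EmissionConfig):
    """JSON-serializable copies of the three generator configs."""
    return {
        "task": asdict(task),
        "process": asdict(process),
        "emission": asdict(emission),
    }
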