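"""Descriptive trajectory models of the deliberation hypotheses.

Each hypothesis predicts the joint average evolution of the categorical and
motor DV for one choice-conditioned trajectory pair.  Rises are cumulative
Gaussians, value(t) = offset + range * Phi((t - t50) / tau):

* intentional -- the categorical DV is structureless (fixed at 0); only the
  motor DV rises.  4 free parameters.
* abstract -- both DVs rise; the categorical rise must lead (the motor
  half-rise is bounded to come >= 250 ms after the categorical half-rise)
  and the categorical DV decays exponentially after its peak, defined as
  the time the cumulative Gaussian reaches its 99.38th percentile.
  9 free parameters.
* mixture -- both DVs rise with a shared speed (tau) and half-rise time
  (t50); the categorical DV may decay after its peak.  7 free parameters.
* unconstrained -- the abstract equations with no ordering bound; used to
  estimate onset and peak times without presupposing a temporal order.

Models are compared by AIC = 2k + n ln(sigma_hat^2) (the data-dependent
constant cancels in differences), with sigma_hat^2 = SSE / (n - k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import norm, qmc

from .containers import BIN_CENTERS

#: Phi^{-1}(0.9938): the rise is complete, the decay begins
Z_PEAK = float(norm.ppf(0.9938))
#: Phi^{-1}(0.95): onset is the 5th percentile of the rise
Z_ONSET = float(norm.ppf(0.95))
#: minimum categorical-to-motor half-rise separation in the abstract model (ms)
ABSTRACT_MIN_SEPARATION = 250.0

MOTIFS = ("intentional", "abstract", "mixture", "unconstrained")
N_PARAMS = {"intentional": 4, "abstract": 9, "mixture": 7, "unconstrained": 9}

_RANGE_FLOOR = 1e-4  # below this dynamic range, onset/peak are unresolvable


class MotifError(ValueError):
    pass


def _rise(t, offset, rng_, tau, t50):
    return offset + rng_ * norm.cdf((t - t50) / tau)


def _decayed_rise(t, offset, rng_, tau, t50, tau_decay):
    """Cumulative-Gaussian rise multiplied, past its peak, by an exponential
    decay toward zero."""
    v = _rise(t, offset, rng_, tau, t50)
    t_peak = t50 + Z_PEAK * tau
    decay = np.exp(-np.clip(t - t_peak, 0.0, None) / tau_decay)
    return v * decay


def eval_motif(motif: str, params: dict, t: np.ndarray | None = None) -> np.ndarray:
    """Predicted (categorical, motor) trajectory pair, shape (2, len(t)).

    Parameter names: categorical ``offset_c, range_c, tau_c, t50_c,
    tau_decay``; motor ``offset_m, range_m, tau_m, t50_m``.  The mixture
    motif shares ``tau``/``t50`` across dimensions.
    """
    t = BIN_CENTERS if t is None else np.asarray(t, float)
    p = params
    if motif == "intentional":
        cat = np.zeros_like(t)
        mot = _rise(t, p["offset_m"], p["range_m"], p["tau_m"], p["t50_m"])
    elif motif in ("abstract", "unconstrained"):
        cat = _decayed_rise(
            t, p["offset_c"], p["range_c"], p["tau_c"], p["t50_c"], p["tau_decay"]
        )
        mot = _rise(t, p["offset_m"], p["range_m"], p["tau_m"], p["t50_m"])
    elif motif == "mixture":
        cat = _decayed_rise(
            t, p["offset_c"], p["range_c"], p["tau"], p["t50"], p["tau_decay"]
        )
        mot = _rise(t, p["offset_m"], p["range_m"], p["tau"], p["t50"])
    else:
        raise MotifError(f"unknown motif {motif!r}; expected one of {MOTIFS}")
    return np.stack([cat, mot])


# ---------------------------------------------------------------------------
# parameter vector <-> dict mappings, with bounds

_TAU_BOUNDS = (5.0, 500.0)
_DECAY_BOUNDS = (10.0, 2000.0)
_T50_BOUNDS = (-750.0, 0.0)


def _param_spec(motif, lo_off, hi_off, lo_r, hi_r):
    """(names, lower, upper) for the optimizer's parameter vector."""
    if motif == "intentional":
        names = ["offset_m", "range_m", "tau_m", "t50_m"]
        lo = [lo_off, lo_r, _TAU_BOUNDS[0], _T50_BOUNDS[0]]
        hi = [hi_off, hi_r, _TAU_BOUNDS[1], _T50_BOUNDS[1]]
    elif motif == "unconstrained":
        names = [
            "offset_c", "range_c", "tau_c", "t50_c", "tau_decay",
            "offset_m", "range_m", "tau_m", "t50_m",
        ]
        lo = [lo_off, lo_r, _TAU_BOUNDS[0], _T50_BOUNDS[0], _DECAY_BOUNDS[0],
              lo_off, lo_r, _TAU_BOUNDS[0], _T50_BOUNDS[0]]
        hi = [hi_off, hi_r, _TAU_BOUNDS[1], _T50_BOUNDS[1], _DECAY_BOUNDS[1],
              hi_off, hi_r, _TAU_BOUNDS[1], _T50_BOUNDS[1]]
    elif motif == "abstract":
        # t50_m is parameterized as t50_c + 250 + sep, sep >= 0, which makes
        # the ordering constraint a simple box bound
        names = [
            "offset_c", "range_c", "tau_c", "t50_c", "tau_decay",
            "offset_m", "range_m", "tau_m", "sep",
        ]
        lo = [lo_off, lo_r, _TAU_BOUNDS[0], _T50_BOUNDS[0], _DECAY_BOUNDS[0],
              lo_off, lo_r, _TAU_BOUNDS[0], 0.0]
        hi = [hi_off, hi_r, _TAU_BOUNDS[1], -ABSTRACT_MIN_SEPARATION,
              _DECAY_BOUNDS[1], hi_off, hi_r, _TAU_BOUNDS[1], 500.0]
    elif motif == "mixture":
        names = [
            "offset_c", "range_c", "tau_decay", "offset_m", "range_m",
            "tau", "t50",
        ]
        lo = [lo_off, lo_r, _DECAY_BOUNDS[0], lo_off, lo_r,
              _TAU_BOUNDS[0], _T50_BOUNDS[0]]
        hi = [hi_off, hi_r, _DECAY_BOUNDS[1], hi_off, hi_r,
              _TAU_BOUNDS[1], _T50_BOUNDS[1]]
    else:
        raise MotifError(f"unknown motif {motif!r}")
    return names, np.array(lo), np.array(hi)


def _vec_to_params(motif, names, x):
    p = dict(zip(names, x))
    if motif == "abstract":
        p["t50_m"] = p["t50_c"] + ABSTRACT_MIN_SEPARATION + p.pop("sep")
    return p


# ---------------------------------------------------------------------------
# results object


@dataclass
class MotifResults:
    """One fitted motif on one choice-conditioned trajectory pair."""

    motif: str
    params: dict
    k: int
    n: int
    sse: float
    t: np.ndarray
    data: np.ndarray
    n_starts: int = 0
    field_names: tuple = ()

    @property
    def sigma2(self) -> float:
        """ML residual-variance estimate, SSE over degrees of freedom."""
        return self.sse / (self.n - self.k)

    @property
    def aic(self) -> float:
        """AIC up to the shared data constant: 2k + n ln(sigma_hat^2)."""
        return 2.0 * self.k + self.n * np.log(max(self.sigma2, 1e-300))

    def predict(self, t=None) -> np.ndarray:
        return eval_motif(self.motif, self.params, self.t if t is None else t)

    def _rise_params(self, dimension: str):
        p = self.params
        if self.motif == "intentional":
            if dimension == "categorical":
                return None
            return p["range_m"], p["tau_m"], p["t50_m"]
        if self.motif == "mixture":
            r = p["range_c"] if dimension == "categorical" else p["range_m"]
            return r, p["tau"], p["t50"]
        if dimension == "categorical":
            return p["range_c"], p["tau_c"], p["t50_c"]
        return p["range_m"], p["tau_m"], p["t50_m"]

    def onset_time(self, dimension: str) -> float:
        """Onset = t50 - Phi^{-1}(0.95) * tau, the 5th percentile of the
        rise.  NaN when the dimension has no resolvable rise."""
        rp = self._rise_params(dimension)
        if rp is None:
            return float("nan")
        r, tau, t50 = rp
        if abs(r) < _RANGE_FLOOR:
            return float("nan")
        return t50 - Z_ONSET * tau

    def onset_time_absolute(self, dimension: str, level: float = 0.05) -> float:
        """Absolute-threshold onset: first time the fitted rise exceeds its
        starting value by `level` DV units (range-independent variant)."""
        rp = self._rise_params(dimension)
        if rp is None:
            return float("nan")
        r, tau, t50 = rp
        if abs(r) < _RANGE_FLOOR:
            return float("nan")
        grid = np.arange(self.t[0] - 200.0, self.t[-1] + 200.0, 1.0)
        v = np.abs(r) * norm.cdf((grid - t50) / tau)
        above = np.flatnonzero(v >= level)
        return float(grid[above[0]]) if len(above) else float("nan")

    def peak_time(self, dimension: str) -> float:
        """Peak = t50 + Phi^{-1}(0.9938) * tau, where the decay begins."""
        rp = self._rise_params(dimension)
        if rp is None:
            return float("nan")
        r, tau, t50 = rp
        if abs(r) < _RANGE_FLOOR:
            return float("nan")
        return t50 + Z_PEAK * tau

    def summary(self) -> str:
        lines = [
            f"Motif fit: {self.motif} (k={self.k}, n={self.n})",
            f"  SSE      : {self.sse:.6g}",
            f"  sigma^2  : {self.sigma2:.6g}",
            f"  AIC - 2C : {self.aic:.3f}",
        ]
        for name in sorted(self.params):
            lines.append(f"  {name:<9}: {self.params[name]:+.4g}")
        for dim in ("categorical", "motor"):
            lines.append(
                f"  {dim} onset {self.onset_time(dim):.1f} ms, "
                f"peak {self.peak_time(dim):.1f} ms"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# fitting


class MotifModel:
    """Bounded least-squares motif fit for one trajectory pair.

    Parameters
    ----------
    trajectory : ndarray, shape (2, n_bins)
        Rows are the (categorical, motor) condition-averaged DV.
    t : ndarray
        Bin centers in ms (defaults to the standard 15-bin grid).
    motif : str
        One of ``intentional | abstract | mixture | unconstrained``.
    """

    def __init__(self, trajectory, t=None, motif: str = "abstract"):
        self.data = np.asarray(trajectory, float)
        if self.data.ndim != 2 or self.data.shape[0] != 2:
            raise MotifError("trajectory must have shape (2, n_bins)")
        self.t = BIN_CENTERS.copy() if t is None else np.asarray(t, float)
        if self.data.shape[1] != len(self.t):
            raise MotifError("trajectory length does not match the time grid")
        if motif not in MOTIFS:
            raise MotifError(f"unknown motif {motif!r}")
        self.motif = motif

    def _residuals(self, x, names):
        pred = eval_motif(self.motif, _vec_to_params(self.motif, names, x), self.t)
        return (pred - self.data).ravel()

    def _data_driven_start(self, names, lo, hi):
        """Half-rise crossing heuristic initialization."""
        x0 = (lo + hi) / 2.0
        x0 = np.where(np.isfinite(x0), x0, 0.0)
        p = dict(zip(names, x0))
        for dim, (okey, rkey, tkey) in {
            0: ("offset_c", "range_c", "t50_c"),
            1: ("offset_m", "range_m", "t50_m"),
        }.items():
            y = self.data[dim]
            if okey in p:
                p[okey] = float(y[0])
            if rkey in p:
                p[rkey] = float(y.max() - y[0]) or 0.1
            half = y[0] + 0.5 * (y.max() - y[0])
            above = np.flatnonzero(y >= half)
            t50 = float(self.t[above[0]]) if len(above) else float(self.t[len(y) // 2])
            if tkey in p:
                p[tkey] = t50
            elif "t50" in p and dim == 0:
                p["t50"] = t50
        if "sep" in p:
            p["sep"] = 50.0
            p["t50_c"] = min(p.get("t50_c", -400.0), -ABSTRACT_MIN_SEPARATION - 5)
        for key in ("tau", "tau_c", "tau_m"):
            if key in p:
                p[key] = 60.0
        if "tau_decay" in p:
            p["tau_decay"] = 300.0
        return np.clip(np.array([p[nm] for nm in names]), lo, hi)

    def fit(self, n_starts: int = 20, seed: int = 0, x0: np.ndarray | None = None
            ) -> MotifResults:
        """Multi-start bounded least squares.

        Starts are Latin-hypercube samples within the bounds plus one
        data-driven initialization (half-rise heuristic); pass ``x0`` to
        warm-start (used by bootstrap refits).
        """
        span = float(np.ptp(self.data)) or 1.0
        lo_off, hi_off = self.data.min() - span, self.data.max() + span
        lo_r, hi_r = -3.0 * span, 3.0 * span
        names, lo, hi = _param_spec(self.motif, lo_off, hi_off, lo_r, hi_r)
        starts = [(self._data_driven_start(names, lo, hi), None)]
        if x0 is not None:
            starts.insert(0, (np.clip(np.asarray(x0, float), lo, hi), None))
        extra = max(n_starts - len(starts), 0)
        if extra:
            sampler = qmc.LatinHypercube(d=len(names), seed=seed)
            u = sampler.random(extra)
            # random escape starts get a capped iteration budget; the best
            # of them is polished below
            starts.extend((x, 60) for x in lo + u * (hi - lo))
        best = None
        for s, max_nfev in starts:
            try:
                res = least_squares(
                    self._residuals, s, args=(names,), bounds=(lo, hi),
                    method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10,
                    max_nfev=max_nfev,
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is not None and best.nfev >= 60:
            res = least_squares(
                self._residuals, best.x, args=(names,), bounds=(lo, hi),
                method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10,
            )
            if res.cost < best.cost:
                best = res
        if best is None:
            raise MotifError(
                f"{self.motif} fit failed to converge from any of "
                f"{len(starts)} starts"
            )
        params = _vec_to_params(self.motif, names, best.x)
        sse = float(np.sum(best.fun**2))
        return MotifResults(
            motif=self.motif,
            params=params,
            k=N_PARAMS[self.motif],
            n=self.data.size,
            sse=sse,
            t=self.t,
            data=self.data,
            n_starts=len(starts),
            field_names=tuple(names),
        )


def fit_motif(trajectory, motif: str, t=None, n_starts: int = 20, seed: int = 0
              ) -> MotifResults:
    """Functional wrapper around :class:`MotifModel`."""
    return MotifModel(trajectory, t=t, motif=motif).fit(n_starts=n_starts, seed=seed)


# ---------------------------------------------------------------------------
# model comparison


def compare_models(fits: dict) -> dict:
    """Pairwise delta-AIC over motif fits of the same data.

    ``fits`` maps motif name -> MotifResults (one trajectory pair) or
    -> list of MotifResults (a session's trajectory pairs).  Returns
    ``{"aic": {...}, "delta": {(a, b): mean AIC_a - AIC_b}, "delta_sd":
    spread across a session's trajectories}``.
    """
    names = list(fits)
    as_lists = {
        m: (v if isinstance(v, (list, tuple)) else [v]) for m, v in fits.items()
    }
    n_points = {m: tuple(f.n for f in v) for m, v in as_lists.items()}
    if len(set(n_points.values())) > 1:
        raise MotifError(f"fits cover different data sizes: {n_points}")
    aics = {m: np.array([f.aic for f in v]) for m, v in as_lists.items()}
    delta, delta_sd = {}, {}
    for a in names:
        for b in names:
            if a == b:
                continue
            d = aics[a] - aics[b]
            delta[(a, b)] = float(d.mean())
            delta_sd[(a, b)] = float(d.std(ddof=1)) if len(d) > 1 else float("nan")
    return {
        "aic": {m: v.tolist() for m, v in aics.items()},
        "delta": delta,
        "delta_sd": delta_sd,
    }


def select_motif(trajectory, candidates=("intentional", "abstract", "mixture"),
                 t=None, n_starts: int = 12, seed: int = 0):
    """Fit all candidate motifs and return (best name, {name: fit})."""
    fits = {
        m: fit_motif(trajectory, m, t=t, n_starts=n_starts, seed=seed)
        for m in candidates
    }
    best = min(fits, key=lambda m: fits[m].aic)
    return best, fits


# ---------------------------------------------------------------------------
# peak-time bootstrap


@dataclass
class PeakTimeBootstrap:
    point: dict          # (group, dimension) -> peak time (ms)
    sd: dict             # (group, dimension) -> bootstrap s.d. (NaN if n_boot < 2)
    n_boot: int
    n_redrawn: int = 0
    samples: dict = field(default_factory=dict)


def peak_time_bootstrap(
    trials,
    dv,
    group_column: str = "correct",
    n_boot: int = 1000,
    seed: int = 0,
    n_starts_point: int = 20,
    n_starts_boot: int = 2,
) -> PeakTimeBootstrap:
    """Bootstrap uncertainty of the DV peak time per accuracy group.

    The full pipeline -- unsigned condition averaging followed by an
    unconstrained motif fit -- is repeated on trial resamples drawn with
    replacement.  Resamples in which a group vanishes are redrawn and
    counted.  Bootstrap refits warm-start at the point estimate.
    """
    from .decoding import average_trajectories  # local: avoid cycle at import

    trials = trials.reset_index(drop=True)
    values = sorted(trials[group_column].unique())
    if len(values) < 2:
        raise MotifError(f"both {group_column} groups must be nonempty")
    rng = np.random.default_rng(seed)

    def peaks_for(index):
        sub = trials.iloc[index].reset_index(drop=True)
        sub_dv = DVSubset(dv, np.asarray(index))
        groups = {v: (sub[group_column] == v).to_numpy() for v in values}
        ts = average_trajectories(sub_dv, sub, groups=groups, unsigned=True)
        out = {}
        for v in values:
            if v not in ts.trajectories:
                return None
            out[v] = ts.trajectories[v]
        return out

    n = len(trials)
    base = peaks_for(np.arange(n))
    point, sd, samples, warm = {}, {}, {}, {}
    for v, traj in base.items():
        fit = fit_motif(traj, "unconstrained", n_starts=n_starts_point, seed=seed)
        warm[v] = np.array([fit.params.get(nm, 0.0) for nm in fit.field_names])
        for dim in ("categorical", "motor"):
            point[(v, dim)] = fit.peak_time(dim)
            samples[(v, dim)] = []
    redrawn = 0
    draws = 0
    while draws < n_boot:
        idx = rng.integers(0, n, n)
        groups = peaks_for(idx)
        if groups is None:
            redrawn += 1
            if redrawn > 10 * max(n_boot, 1):
                raise MotifError("bootstrap groups keep vanishing")
            continue
        draws += 1
        for v, traj in groups.items():
            model = MotifModel(traj, motif="unconstrained")
            fit = model.fit(n_starts=n_starts_boot, seed=seed + draws, x0=warm[v])
            for dim in ("categorical", "motor"):
                samples[(v, dim)].append(fit.peak_time(dim))
    for key, vals in samples.items():
        arr = np.asarray(vals, float)
        sd[key] = float(np.nanstd(arr, ddof=1)) if len(arr) > 1 else float("nan")
        samples[key] = arr
    return PeakTimeBootstrap(
        point=point, sd=sd, n_boot=n_boot, n_redrawn=redrawn, samples=samples
    )


class DVSubset:
    """Light view of a DVSeries restricted/reindexed to a trial index."""

    def __init__(self, dv, index):
        self.dv = {k: v[index] for k, v in dv.dv.items()}
        self.weights = dv.weights
        self.bin_left_edges_ms = dv.bin_left_edges_ms
        self.trial_ids = dv.trial_ids[index]
        self.protocol = dv.protocol

    def bin_index(self, time_ms):
        hits = np.flatnonzero(np.isclose(self.bin_left_edges_ms, time_ms))
        if len(hits) != 1:
            raise ValueError(f"time {time_ms} ms is not on the bin grid")
        return int(hits[0])
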