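"""Pipeline orchestration: simulate -> decode -> fit-motifs -> geometry ->
signatures -> behavior, with every stage seeded from one master seed and a
JSON run report recording configs, seeds and stage outputs."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .behavior import fit_bias_model, fit_psychometric
from .decoding import PopulationDecoder, average_trajectories, outcome_groups
from .geometry import angle_series, xcorr_trialwise
from .motifs import compare_models, fit_motif
from .session_io import SessionBundle, savez_deterministic, write_session
from .signatures import dv_bias, residual_timecourse, variance_partition
from .synthetic import (
    EmissionConfig,
    ProcessConfig,
    TaskConfig,
    config_dicts,
    simulate_session,
)

log = logging.getLogger("dvmotifs")

ALL_STAGES = ("simulate", "decode", "behavior", "fit_motifs", "geometry", "signatures")

DEFAULT_CONFIG = {
    "n_sessions": 10,
    "stages": list(ALL_STAGES),
    "task": {},
    "process": {},
    "emission": {},
    "decode": {"shrinkage": 0.1, "min_rate": 3.0, "strict_zscore": True},
    "motifs": {"n_starts": 12},
    "write_sessions": True,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _merge_config(user: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (user or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def build_configs(cfg: dict):
    task = TaskConfig(**{
        k: (tuple(v) if isinstance(v, list) else v) for k, v in cfg["task"].items()
    })
    process = ProcessConfig(**cfg["process"])
    emission = EmissionConfig(**cfg["emission"])
    return task, process, emission


def _session_seeds(seed: int, n_sessions: int) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n_sessions)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def run_pipeline(config: dict | None = None, seed: int = 0, outdir=None) -> dict:
    """Execute the configured stages over ``n_sessions`` synthetic sessions.

    Returns the run report (also written to ``outdir`` as JSON plus a
    human-readable summary when ``outdir`` is given).  A stage failure
    aborts the run with the stage named; artifacts of completed stages
    remain on disk.
    """
    cfg = _merge_config(config)
    stages = list(cfg["stages"])
    skipped = [s for s in ALL_STAGES if s not in stages]
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    task, process, emission = build_configs(cfg)
    seeds = _session_seeds(seed, int(cfg["n_sessions"]))
    report = {
        "seed": seed,
        "session_seeds": seeds,
        "software_version": __version__,
        "config": cfg,
        "stages_run": stages,
        "stages_skipped": skipped,
        "sessions": [],
    }

    for i, s_seed in enumerate(seeds):
        entry: dict = {"session": i, "seed": s_seed}
        dv = None
        trials = None
        if "simulate" in stages:
            try:
                trials, responses, gt = simulate_session(task, process, emission, s_seed)
            except Exception as err:  # noqa: BLE001
                raise StageError("simulate", err) from err
            entry["n_trials"] = len(trials)
            entry["n_units"] = responses.n_units
            if outdir is not None and cfg.get("write_sessions", True):
                bundle = SessionBundle(
                    trials=trials,
                    responses=responses,
                    ground_truth=gt,
                    provenance={
                        "seed": s_seed,
                        "master_seed": seed,
                        "configs": config_dicts(task, process, emission),
                        "stage": "simulate",
                    },
                )
                write_session(bundle, outdir / f"session_{i:03d}")
        else:
            entry["note"] = "simulate skipped; downstream stages skipped too"
            report["sessions"].append(entry)
            continue

        if "decode" in stages:
            try:
                dec = PopulationDecoder(
                    responses,
                    trials,
                    shrinkage=cfg["decode"]["shrinkage"],
                    min_rate=cfg["decode"]["min_rate"],
                    strict_zscore=cfg["decode"]["strict_zscore"],
                )
                dv = dec.fit()
                entry["accuracy_750"] = {
                    dim: dec.accuracy_750(dim) for dim in ("categorical", "motor")
                }
                entry["dropped_units"] = dec.Z.dropped_units
            except Exception as err:  # noqa: BLE001
                raise StageError("decode", err) from err
            if outdir is not None and cfg.get("write_sessions", True):
                savez_deterministic(
                    outdir / f"session_{i:03d}" / "dv.npz",
                    categorical=dv.dv["categorical"],
                    motor=dv.dv["motor"],
                    bin_left_edges_ms=dv.bin_left_edges_ms,
                )

        if "behavior" in stages:
            try:
                from .behavior import DegenerateFitError

                psy = fit_psychometric(trials, by=("contrast",))
                bias, degenerate = {}, []
                for c in sorted(trials["contrast"].unique()):
                    sub = trials[trials["contrast"] == c]
                    try:
                        bias[c] = fit_bias_model(sub, by=("contrast",))[(c,)]
                    except DegenerateFitError:
                        # short sessions can miss a prior context within one
                        # contrast block; note it rather than abort
                        degenerate.append(c)
                entry["behavior"] = {
                    "sensitivity": {k[0]: v.sensitivity for k, v in psy.items()},
                    "sigma": {k[0]: v.sigma for k, v in psy.items()},
                    "decision_bias": {c: v.decision_bias for c, v in bias.items()},
                    "degenerate_bias_groups": degenerate,
                }
            except Exception as err:  # noqa: BLE001
                raise StageError("behavior", err) from err

        if "fit_motifs" in stages and dv is not None:
            try:
                traj = average_trajectories(
                    dv, trials, groups=outcome_groups(trials), unsigned=False
                )
                n_starts = cfg["motifs"]["n_starts"]
                fits = {
                    m: [
                        fit_motif(pair, m, n_starts=n_starts, seed=s_seed)
                        for pair in traj.trajectories.values()
                    ]
                    for m in ("intentional", "abstract", "mixture")
                }
                cmp_ = compare_models(fits)
                entry["delta_aic"] = {
                    "abstract_minus_intentional": cmp_["delta"][("abstract", "intentional")],
                    "abstract_minus_mixture": cmp_["delta"][("abstract", "mixture")],
                    "sd_abstract_minus_intentional": cmp_["delta_sd"][
                        ("abstract", "intentional")
                    ],
                }
            except Exception as err:  # noqa: BLE001
                raise StageError("fit_motifs", err) from err

        if "geometry" in stages and dv is not None:
            try:
                ang = angle_series(dv, ci_boot=0)
                xc = xcorr_trialwise(dv, trials, n_null=20, seed=s_seed)
                peak_lag = {}
                for rule, curve in xc.corrected_by_rule.items():
                    k = int(np.nanargmax(np.abs(curve)))
                    peak_lag[rule] = float(xc.lags_ms[k])
                entry["geometry"] = {
                    "mean_angle_deg": float(
                        np.nanmean(ang.angles_deg)
                    ),
                    "xcorr_peak_lag_ms": peak_lag,
                }
            except Exception as err:  # noqa: BLE001
                raise StageError("geometry", err) from err

        if "signatures" in stages and dv is not None:
            try:
                vp = variance_partition(dv, trials)
                rt = residual_timecourse(vp)
                bias_res = dv_bias(dv, trials)
                entry["signatures"] = {
                    "residual_rise_ms": rt.rise_length_ms,
                    "expectation": {
                        f"{c}/{dim}": v for (c, dim), v in bias_res.expectation.items()
                    },
                }
            except Exception as err:  # noqa: BLE001
                raise StageError("signatures", err) from err

        report["sessions"].append(entry)
        log.info("session %d finished", i)

    if outdir is not None:
        (outdir / "report.json").write_text(
            json.dumps(report, indent=1, default=_default)
        )
        (outdir / "summary.txt").write_text(_summarize(report))
    return report


def _default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _summarize(report: dict) -> str:
    lines = [
        f"dvmotifs {report['software_version']} pipeline run",
        f"master seed: {report['seed']}",
        f"stages: {', '.join(report['stages_run'])}"
        + (f" (skipped: {', '.join(report['stages_skipped'])})"
           if report["stages_skipped"] else ""),
        f"sessions: {len(report['sessions'])}",
        "",
    ]
    for s in report["sessions"]:
        parts = [f"session {s['session']:3d} (seed {s['seed']})"]
        if "accuracy_750" in s:
            acc = s["accuracy_750"]
            parts.append(
                f"acc750 cat={acc['categorical']:.2f} mot={acc['motor']:.2f}"
            )
        if "delta_aic" in s:
            parts.append(
                "dAIC(abs-int)="
                f"{s['delta_aic']['abstract_minus_intentional']:.1f}"
            )
        if "geometry" in s:
            parts.append(f"angle={s['geometry']['mean_angle_deg']:.1f}deg")
        lines.append("  ".join(parts))
    return "\n".join(lines) + "\n"
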