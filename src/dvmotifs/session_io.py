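"""Session persistence: trial table as CSV, spike counts as a zipped array
container with a JSON sidecar, ground truth and provenance as JSON +
arrays.  Round trips are lossless (bitwise for counts)."""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import BinnedResponses, SchemaError, validate_trials
from .synthetic import SyntheticGroundTruth


@dataclass
class SessionBundle:
    trials: pd.DataFrame
    responses: BinnedResponses
    ground_truth: SyntheticGroundTruth | None = None
    provenance: dict | None = None

    def validate(self) -> None:
        validate_trials(self.trials)
        if len(self.trials) != self.responses.n_trials:
            raise SchemaError(
                f"trial table has {len(self.trials)} rows, counts have "
                f"{self.responses.n_trials} trials"
            )
        tids = self.trials["trial_id"].to_numpy()
        if not np.array_equal(tids, np.asarray(self.responses.trial_ids)):
            raise SchemaError("trial ids differ between table and counts")


def savez_deterministic(path, **arrays) -> None:
    """Write arrays to an npz-compatible zip with fixed member timestamps,
    so identical arrays produce bitwise-identical files across runs."""
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name, arr in arrays.items():
            buf = io.BytesIO()
            np.lib.format.write_array(buf, np.asarray(arr))
            info = zipfile.ZipInfo(f"{name}.npy", date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, buf.getvalue())


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_session(bundle: SessionBundle, path) -> list:
    """Write a session to `path` (a directory). Returns the files written."""
    bundle.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []

    trials_path = path / "trials.csv"
    bundle.trials.to_csv(trials_path, index=False)
    written.append(trials_path)

    counts_path = path / "counts.npz"
    savez_deterministic(counts_path, counts=bundle.responses.counts)
    written.append(counts_path)
    sidecar = {
        "bin_edges_ms": bundle.responses.bin_edges_ms.tolist(),
        "alignment": bundle.responses.alignment,
        "unit_ids": [str(u) for u in bundle.responses.unit_ids],
        "trial_ids": [int(t) for t in bundle.responses.trial_ids],
    }
    sidecar_path = path / "counts.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    written.append(sidecar_path)

    if bundle.ground_truth is not None:
        gt = bundle.ground_truth
        gt_path = path / "ground_truth.npz"
        savez_deterministic(
            gt_path,
            times_ms=gt.times_ms,
            x_categorical=gt.x_categorical,
            x_motor=gt.x_motor,
            bound_hit_ms=gt.bound_hit_ms,
            acc_onset_ms=gt.acc_onset_ms,
            rotation_onset_ms=gt.rotation_onset_ms,
            loadings_categorical=gt.loadings_categorical
            if gt.loadings_categorical is not None else np.array([]),
            loadings_motor=gt.loadings_motor
            if gt.loadings_motor is not None else np.array([]),
            baselines=gt.baselines if gt.baselines is not None else np.array([]),
        )
        written.append(gt_path)
        meta = {
            "task": asdict(gt.task_config) if gt.task_config else None,
            "process": asdict(gt.process_config) if gt.process_config else None,
            "emission": asdict(gt.emission_config) if gt.emission_config else None,
        }
        meta_path = path / "ground_truth.json"
        meta_path.write_text(json.dumps(meta, indent=1, default=_json_default))
        written.append(meta_path)

    prov = dict(bundle.provenance or {})
    prov.setdefault("software_version", __version__)
    prov_path = path / "provenance.json"
    prov_path.write_text(json.dumps(prov, indent=1, default=_json_default))
    written.append(prov_path)
    return written


def read_session(path) -> SessionBundle:
    """Read a session directory written by :func:`write_session`.

    Schema violations are reported with the offending row/field; grid
    mismatches between the declared sidecar and the count array raise."""
    path = Path(path)
    trials = pd.read_csv(path / "trials.csv")
    validate_trials(trials)
    with np.load(path / "counts.npz") as z:
        counts = z["counts"]
    sidecar = json.loads((path / "counts.json").read_text())
    edges = np.asarray(sidecar["bin_edges_ms"], float)
    if counts.shape[1] != len(edges) - 1:
        raise SchemaError(
            f"counts have {counts.shape[1]} bins but the sidecar declares "
            f"{len(edges) - 1}"
        )
    responses = BinnedResponses(
        counts=counts,
        bin_edges_ms=edges,
        unit_ids=np.asarray(sidecar["unit_ids"]),
        trial_ids=np.asarray(sidecar["trial_ids"]),
        alignment=sidecar.get("alignment", "saccade"),
    )
    ground_truth = None
    gt_npz = path / "ground_truth.npz"
    if gt_npz.exists():
        with np.load(gt_npz) as z:
            ground_truth = SyntheticGroundTruth(
                times_ms=z["times_ms"],
                x_categorical=z["x_categorical"],
                x_motor=z["x_motor"],
                bound_hit_ms=z["bound_hit_ms"],
                acc_onset_ms=z["acc_onset_ms"],
                rotation_onset_ms=z["rotation_onset_ms"],
                loadings_categorical=z["loadings_categorical"]
                if z["loadings_categorical"].size else None,
                loadings_motor=z["loadings_motor"]
                if z["loadings_motor"].size else None,
                baselines=z["baselines"] if z["baselines"].size else None,
            )
    prov_path = path / "provenance.json"
    provenance = json.loads(prov_path.read_text()) if prov_path.exists() else None
    bundle = SessionBundle(
        trials=trials,
        responses=responses,
        ground_truth=ground_truth,
        provenance=provenance,
    )
    bundle.validate()
    return bundle
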