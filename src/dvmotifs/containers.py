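"""Core data containers shared by every analysis stage.

Time conventions: all times are in milliseconds relative to saccade
initiation at t = 0.  The analysis epoch is [-750, 0) ms, divided into 15
nonoverlapping 50-ms bins labeled by their left edge (half-open
[left, left + 50)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIN_MS = 50.0
EPOCH_MS = (-750.0, 0.0)
N_BINS = 15

#: left edges of the analysis bins, ms relative to saccade initiation
BIN_LEFT_EDGES = np.arange(EPOCH_MS[0], EPOCH_MS[1], BIN_MS)
BIN_EDGES = np.arange(EPOCH_MS[0], EPOCH_MS[1] + BIN_MS, BIN_MS)
BIN_CENTERS = BIN_LEFT_EDGES + BIN_MS / 2.0

CHOICE_CATEGORIES = ("cw", "ccw")
SACCADE_DIRECTIONS = ("right", "left")
MAPPING_RULES = ("rule1", "rule2")
PRIORS = ("cw", "ccw")
CONTRASTS = ("high", "low")

#: saccade direction communicated for each (mapping rule, choice category)
RULE_MAP = {
    ("rule1", "cw"): "right",
    ("rule1", "ccw"): "left",
    ("rule2", "cw"): "left",
    ("rule2", "ccw"): "right",
}

TRIAL_COLUMNS = (
    "trial_id",
    "orientation",
    "contrast",
    "prior",
    "mapping_rule",
    "choice_category",
    "saccade_direction",
    "correct",
    "saccade_time_ms",
    "t_targets_ms",
    "t_stimulus_ms",
    "t_stimulus_off_ms",
)


class SchemaError(ValueError):
    """A trial table or response container violates the expected schema."""


def validate_trials(trials: pd.DataFrame, require_outcomes: bool = True) -> None:
    """Check the trial-table schema, raising :class:`SchemaError` on the
    first violation (with the offending row/field named)."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table missing required columns: {missing}")
    checks = {
        "contrast": CONTRASTS,
        "prior": PRIORS,
        "mapping_rule": MAPPING_RULES,
    }
    if require_outcomes:
        checks["choice_category"] = CHOICE_CATEGORIES
        checks["saccade_direction"] = SACCADE_DIRECTIONS
    for col, allowed in checks.items():
        bad = ~trials[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"column {col!r}, row {row}: value {trials[col].iloc[row]!r} "
                f"not in {allowed}"
            )
    if trials["trial_id"].duplicated().any():
        raise SchemaError("duplicate trial ids")


@dataclass
class BinnedResponses:
    """Spike counts per unit, time bin and trial, aligned to saccade
    initiation.

    Attributes
    ----------
    counts : ndarray, shape (n_units, n_bins, n_trials)
        Nonnegative integer spike counts in 50-ms bins.
    bin_edges_ms : ndarray, shape (n_bins + 1,)
        Bin edges in ms relative to the alignment event.
    unit_ids : ndarray of str
    trial_ids : ndarray of int
        Must match the ``trial_id`` column of the companion trial table.
    alignment : str
        Name of the alignment event (``"saccade"``).
    """

    counts: np.ndarray
    bin_edges_ms: np.ndarray = field(default_factory=lambda: BIN_EDGES.copy())
    unit_ids: np.ndarray | None = None
    trial_ids: np.ndarray | None = None
    alignment: str = "saccade"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise SchemaError("counts must have shape (n_units, n_bins, n_trials)")
        if self.counts.shape[1] != len(self.bin_edges_ms) - 1:
            raise SchemaError(
                f"counts declare {self.counts.shape[1]} bins but the edge grid "
                f"has {len(self.bin_edges_ms) - 1}"
            )
        if self.unit_ids is None:
            self.unit_ids = np.array([f"u{i:03d}" for i in range(self.n_units)])
        if self.trial_ids is None:
            self.trial_ids = np.arange(self.n_trials)

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[2]

    @property
    def bin_width_s(self) -> float:
        return float(self.bin_edges_ms[1] - self.bin_edges_ms[0]) / 1000.0

    def mean_rates(self) -> np.ndarray:
        """Mean firing rate (ips) per unit across all bins and trials."""
        return self.counts.mean(axis=(1, 2)) / self.bin_width_s


def saccade_direction_for(rule: str, category: str) -> str:
    """Saccade direction that reports `category` under `rule`."""
    return RULE_MAP[(rule, category)]
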