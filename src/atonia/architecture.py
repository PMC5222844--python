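"""Hypnogram-level sleep architecture metrics.

State proportions per time bin (2-h bins by default, matching how rodent
sleep is usually summarized over the 12 h/12 h light cycle), bout extraction
with empirical cumulative bout-length distributions, the five permitted state
transitions (WAKE→REMS is behaviorally absent and counted as an anomaly),
and REMS latency from a reference time.

A bout or transition belongs to the circadian period (inactive = lights on,
active = lights off) containing its first epoch; bouts spanning the
light/dark boundary are not split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ARTIFACT, NREMS, REMS, STATES, WAKE, Hypnogram
from .errors import IntegrityError, UndefinedResultError

PERIODS = ("inactive", "active")

#: the five behaviorally possible transitions, in reporting order
TRANSITIONS = (
    (WAKE, NREMS),
    (NREMS, WAKE),
    (NREMS, REMS),
    (REMS, WAKE),
    (REMS, NREMS),
)
ANOMALY = (WAKE, REMS)


def transition_key(src: str, dst: str) -> str:
    return f"{src}->{dst}"


def epoch_periods(h: Hypnogram, lights_off_at: float) -> np.ndarray:
    """Period label per epoch: 'inactive' before lights-off, 'active' after."""
    return np.where(h.start_times < lights_off_at, "inactive", "active")


def state_proportions(h: Hypnogram, bin_s: float = 7200.0) -> pd.DataFrame:
    """Percentage of scored (non-artifact) epochs per state, per time bin.

    Returns one row per bin (index = bin start time in seconds) with columns
    WAKE/NREMS/REMS and ``n_scored``. A partial final bin uses the epochs it
    has. Per-bin percentages sum to 100 whenever the bin holds scored epochs.
    """
    if bin_s <= 0 or abs(bin_s / h.epoch_len - round(bin_s / h.epoch_len)) > 1e-9:
        raise IntegrityError("bin_s must be a positive multiple of epoch_len")
    n = h.n_epochs
    if n == 0:
        return pd.DataFrame(columns=[*STATES, "n_scored"])
    per_bin = int(round(bin_s / h.epoch_len))
    bin_idx = np.arange(n) // per_bin
    scored = ~h.flags[ARTIFACT]
    rows = []
    for b in range(int(bin_idx[-1]) + 1):
        sel = (bin_idx == b) & scored
        n_scored = int(sel.sum())
        row = {"bin_start_s": b * bin_s + h.epoch0_time, "n_scored": n_scored}
        for s in STATES:
            row[s] = 100.0 * np.sum(h.states[sel] == s) / n_scored if n_scored else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("bin_start_s")


def extract_bouts(h: Hypnogram, lights_off_at: float = 0.0) -> pd.DataFrame:
    """Maximal runs of equal state, tiling the hypnogram.

    Columns: state, start_epoch, length (epochs), period (by start epoch).
    """
    periods = epoch_periods(h, lights_off_at)
    rows = [
        {
            "state": r.state,
            "start_epoch": r.start,
            "length": r.length,
            "period": periods[r.start],
        }
        for r in h.runs()
    ]
    return pd.DataFrame(rows, columns=["state", "start_epoch", "length", "period"])


def bout_cdf(
    bouts: pd.DataFrame, state: str, period: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of bout length for one state (optionally one period).

    Returns ``(lengths, cdf)`` where ``lengths`` are the sorted unique bout
    lengths and ``cdf[i] = P(L <= lengths[i])``; nondecreasing, ends at 1.
    """
    sel = bouts["state"] == state
    if period is not None:
        sel &= bouts["period"] == period
    lengths = bouts.loc[sel, "length"].to_numpy()
    if lengths.size == 0:
        raise UndefinedResultError(
            f"no {state} bouts in period {period!r}: distribution undefined"
        )
    uniq, counts = np.unique(lengths, return_counts=True)
    return uniq, np.cumsum(counts) / lengths.size


@dataclass
class TransitionProfile:
    """Counts of the five permitted transitions plus the WAKE→REMS anomaly."""

    counts: dict[str, int] = field(
        default_factory=lambda: {transition_key(a, b): 0 for a, b in TRANSITIONS}
    )
    anomalies: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def probabilities(self) -> dict[str, float]:
        """The five counts normalized to sum to 1 (anomalies excluded)."""
        t = self.total
        return {k: (v / t if t else 0.0) for k, v in self.counts.items()}


def transition_profile(
    h: Hypnogram, period: str | None = None, lights_off_at: float = 0.0
) -> TransitionProfile:
    """Count state changes between consecutive bouts.

    A transition is assigned to the period containing its first epoch, i.e.
    the last epoch of the bout being left. WAKE→REMS is tallied as an anomaly
    and excluded from the five-way normalization.
    """
    runs = h.runs()
    periods = epoch_periods(h, lights_off_at)
    profile = TransitionProfile()
    for prev, nxt in zip(runs, runs[1:]):
        if period is not None:
            p = periods[prev.start + prev.length - 1]
            if p != period:
                continue
        if (prev.state, nxt.state) == ANOMALY:
            profile.anomalies += 1
        else:
            profile.counts[transition_key(prev.state, nxt.state)] += 1
    return profile


def rems_latency(
    h: Hypnogram, from_time: float, min_bout_epochs: int = 3
) -> int | None:
    """Epochs from ``from_time`` to the first coherent REMS bout at/after it.

    Coherent means at least ``min_bout_epochs`` consecutive REMS epochs (the
    same persistence constant the staging uses for a state change). Returns
    None when no such bout follows ``from_time``.
    """
    if not h.epoch0_time <= from_time <= h.epoch0_time + h.n_epochs * h.epoch_len:
        raise IntegrityError("from_time outside the session")
    from_epoch = int(np.ceil((from_time - h.epoch0_time) / h.epoch_len - 1e-9))
    for run in h.runs():
        if run.state == REMS and run.length >= min_bout_epochs and run.start >= from_epoch:
            return run.start - from_epoch
    return None
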