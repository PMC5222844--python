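"""Synthetic mouse EEG/EMG cohorts with ground-truth hypnograms.

Vigilance is simulated as a discrete-time Markov chain on {WAKE, NREMS,
REMS} at the 4-s epoch resolution, with separate transition matrices for the
inactive (lights-on) and active (lights-off) halves of the 12 h/12 h cycle
and a structurally forbidden WAKE→REMS transition. Signals are then drawn
per epoch: EEG = 1/f-shaped background noise plus a state-typical
oscillation (slow δ waves in NREMS, ~7 Hz θ in REMS, low-amplitude mixed
activity in WAKE); EMG = 50–90 Hz band-limited noise at a state-dependent
tone (WAKE > NREMS > atonic REMS), elevated during REM-A epochs.

Phenotypes mirror a transgenic α-synucleinopathy (MSA) mouse model against
wildtype controls at two ages. The configurable disease effects are: more
REMS in the inactive period (young MSA), a broadband EEG power increase with
the REMS θ peak shifted toward 8–10 Hz (young MSA), slow-wave activity
redistributed from 1–2 Hz toward 3–5 Hz (young MSA), and an age-dependent
probability of REM-A episodes (highest in adult MSA). REM-A is injected as
contiguous bursts of 1–3 REMS epochs; burst EMG sits between the NREM and
WAKE tones (phasic twitches rather than full postural tone), with a small
configurable fraction of WAKE-level bursts that the staging will initially
call WAKE — exercising the flanked-WAKE rescoring route.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import signal

from . import io_formats
from .core import NREMS, REM_A, REMS, STATES, WAKE, Hypnogram, Recording
from .errors import IntegrityError

#: canonical group labels, in the order cohorts are generated
GROUPS = ("control_young", "control_adult", "msa_young", "msa_adult")


@dataclass
class EEGStateTemplate:
    """Spectral recipe for one vigilance state."""

    background_rms: float  # µV, 1/f-shaped noise floor
    slope: float  # 1/f exponent of the background
    osc_amp: float  # µV, amplitude of the state oscillation
    osc_freq: tuple[float, float]  # Hz, uniform draw per epoch


@dataclass
class PhenotypeParams:
    """Generator parameters for one experimental group."""

    transitions: dict[str, np.ndarray]  # period -> 3x3 row-stochastic (W,N,R)
    eeg: dict[str, EEGStateTemplate]
    emg_tone: dict[str, float]  # µV RMS per state
    emg_tone_rema: float = 15.0
    emg_tone_rema_wakelike: float = 30.0
    p_rema: float = 0.02  # per-REMS-epoch REM-A probability
    rema_wakelike_fraction: float = 0.05  # bursts drawn at WAKE-level EMG
    broadband_gain: float = 1.0
    theta_alpha_shift: float = 0.0  # Hz added to the REMS θ peak
    swa_fast_fraction: float = 0.35  # weight of 3–5 Hz vs 1–2 Hz δ waves
    rems_inactive_boost: float = 1.0  # multiplier on NREMS→REMS entry, lights on

    def __post_init__(self) -> None:
        for period, m in self.transitions.items():
            m = np.asarray(m, dtype=float)
            if m.shape != (3, 3) or np.any(m < 0):
                raise IntegrityError(f"bad transition matrix for {period!r}")
            if abs(m[0, 2]) > 1e-12:
                raise IntegrityError("WAKE→REMS must be structurally zero")
            if not np.allclose(m.sum(axis=1), 1.0):
                raise IntegrityError("transition rows must sum to 1")
            self.transitions[period] = m
        if not (
            self.emg_tone[WAKE] > self.emg_tone[NREMS] > self.emg_tone[REMS]
        ):
            raise IntegrityError("EMG tone must order WAKE > NREMS > REMS")
        if not 0.0 <= self.p_rema <= 1.0:
            raise IntegrityError("p_rema must be a probability")


def _base_transitions() -> dict[str, np.ndarray]:
    # Dwell times and occupancies typical of C57BL/6 mice: long consolidated
    # WAKE in the dark phase, NREMS-dominated light phase, REMS bouts of
    # roughly 40-80 s mostly during lights-on. Rows/cols ordered W, N, R.
    inactive = np.array(
        [
            [0.917, 0.083, 0.0],
            [0.023, 0.950, 0.027],
            [0.083, 0.017, 0.900],
        ]
    )
    active = np.array(
        [
            [0.960, 0.040, 0.0],
            [0.057, 0.917, 0.026],
            [0.075, 0.050, 0.875],
        ]
    )
    return {"inactive": inactive, "active": active}


def _base_eeg() -> dict[str, EEGStateTemplate]:
    return {
        WAKE: EEGStateTemplate(20.0, 1.0, 15.0, (2.0, 4.5)),
        NREMS: EEGStateTemplate(25.0, 1.2, 60.0, (1.0, 2.0)),  # δ freq via SWA mix
        REMS: EEGStateTemplate(12.0, 0.8, 40.0, (6.5, 7.5)),
    }


def _base_emg() -> dict[str, float]:
    return {WAKE: 30.0, NREMS: 8.0, REMS: 2.0}


def phenotype_for_group(group: str) -> PhenotypeParams:
    """Default PhenotypeParams for one of the four study groups."""
    p = PhenotypeParams(
        transitions=_base_transitions(),
        eeg=_base_eeg(),
        emg_tone=_base_emg(),
    )
    if group == "control_young":
        return replace(p, p_rema=0.03)
    if group == "control_adult":
        # seniors spend more of the active period in NREMS
        t = {k: v.copy() for k, v in p.transitions.items()}
        t["active"][0] = [0.950, 0.050, 0.0]
        return replace(p, transitions=t, p_rema=0.02)
    if group == "msa_young":
        return replace(
            p,
            p_rema=0.10,
            rems_inactive_boost=1.8,
            broadband_gain=1.3,
            theta_alpha_shift=1.5,
            swa_fast_fraction=0.65,
        )
    if group == "msa_adult":
        return replace(p, p_rema=0.45)
    raise IntegrityError(f"unknown group {group!r}; expected one of {GROUPS}")


def _effective_matrix(p: PhenotypeParams, period: str) -> np.ndarray:
    m = p.transitions[period].copy()
    if period == "inactive" and p.rems_inactive_boost != 1.0:
        entry = min(m[1, 2] * p.rems_inactive_boost, 0.5)
        m[1, 1] -= entry - m[1, 2]
        m[1, 2] = entry
    return m


def stationary_distribution(m: np.ndarray) -> np.ndarray:
    """Stationary occupancy of a row-stochastic matrix (left eigenvector)."""
    w, v = np.linalg.eig(m.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    return pi / pi.sum()


def simulate_hypnogram(
    params: PhenotypeParams,
    n_epochs: int,
    lights_off_epoch: int,
    seed: int | np.random.Generator | None = None,
    epoch_len: float = 4.0,
) -> Hypnogram:
    """Ground-truth hypnogram: period-dependent Markov chain + REM-A bursts.

    REM-A flags are drawn so that the expected flagged fraction of REMS
    epochs is ``p_rema``, in contiguous bursts of 1–3 epochs (truncated at
    the end of the REMS bout).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mats = {
        "inactive": _effective_matrix(params, "inactive"),
        "active": _effective_matrix(params, "active"),
    }
    cum = {k: np.cumsum(m, axis=1) for k, m in mats.items()}
    states_idx = np.empty(n_epochs, dtype=np.int64)
    # start from the inactive-period stationary distribution
    pi0 = stationary_distribution(mats["inactive"])
    s = int(np.searchsorted(np.cumsum(pi0), rng.random()))
    u = rng.random(n_epochs)
    for i in range(n_epochs):
        period = "inactive" if i < lights_off_epoch else "active"
        s = int(np.searchsorted(cum[period][s], u[i], side="right"))
        states_idx[i] = s
    states = np.array(STATES, dtype="<U5")[states_idx]

    rema = np.zeros(n_epochs, dtype=bool)
    if params.p_rema > 0:
        start_p = params.p_rema / (2.0 - params.p_rema)  # mean burst length 2
        i = 0
        while i < n_epochs:
            if states[i] == REMS and not rema[i] and rng.random() < start_p:
                burst = int(rng.integers(1, 4))
                j = i
                while j < n_epochs and j < i + burst and states[j] == REMS:
                    rema[j] = True
                    j += 1
                i = j
            else:
                i += 1
    return Hypnogram(states=states, flags={REM_A: rema}, epoch_len=epoch_len)


_EMG_FILTER_CACHE: dict[float, tuple[np.ndarray, float]] = {}


def _emg_filter(fs: float) -> tuple[np.ndarray, float]:
    """8th-order Butterworth 50–90 Hz band-pass and its broadband-noise gain
    correction so filtered white noise keeps the requested RMS."""
    if fs not in _EMG_FILTER_CACHE:
        sos = signal.butter(8, [50.0, 90.0], btype="bandpass", fs=fs, output="sos")
        _, h = signal.sosfreqz(sos, worN=8192, fs=fs)
        gain = float(np.sqrt(np.mean(np.abs(h) ** 4)))  # forward-backward
        _EMG_FILTER_CACHE[fs] = (sos, gain)
    return _EMG_FILTER_CACHE[fs]


def synthesize_signals(
    truth: Hypnogram,
    params: PhenotypeParams,
    seed: int | np.random.Generator | None = None,
    fs: float = 250.0,
    animal_id: str = "animal",
    group: str = "unlabeled",
) -> Recording:
    """Render a Recording (one EEG channel + EMG, µV, 250 Hz) from a truth
    hypnogram."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_ep = truth.n_epochs
    spe = int(round(fs * truth.epoch_len))
    states = truth.states
    freqs = np.fft.rfftfreq(spe, d=1.0 / fs)

    # --- EEG: 1/f background, vectorized per state ---------------------------
    white = rng.standard_normal((n_ep, spe))
    spec = np.fft.rfft(white, axis=-1)
    shaped = np.empty_like(white)
    for st in STATES:
        mask = states == st
        if not mask.any():
            continue
        tpl = params.eeg[st]
        scale = np.maximum(freqs, 0.5) ** (-tpl.slope / 2.0)
        scale[0] = 0.0
        x = np.fft.irfft(spec[mask] * scale, n=spe, axis=-1)
        rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
        shaped[mask] = x / np.where(rms > 0, rms, 1.0) * tpl.background_rms

    # --- state oscillations ---------------------------------------------------
    lo = np.empty(n_ep)
    hi = np.empty(n_ep)
    amp = np.empty(n_ep)
    for st in STATES:
        mask = states == st
        tpl = params.eeg[st]
        lo[mask], hi[mask] = tpl.osc_freq
        amp[mask] = tpl.osc_amp
    f = rng.uniform(lo, hi)
    # NREMS δ frequency: mixture of slow (1–2 Hz) and fast (3–5 Hz) waves;
    # the fast fraction implements the SWA redistribution phenotype
    nrem = states == NREMS
    fast = nrem & (rng.random(n_ep) < params.swa_fast_fraction)
    f[fast] = rng.uniform(3.0, 5.0, size=int(fast.sum()))
    f[states == REMS] += params.theta_alpha_shift
    amp = amp * rng.uniform(0.8, 1.2, size=n_ep)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=n_ep)
    t = np.arange(spe) / fs
    osc = amp[:, None] * np.sin(2.0 * np.pi * f[:, None] * t[None, :] + phase[:, None])

    eeg = ((shaped + osc) * params.broadband_gain).reshape(-1)

    # --- EMG: band-limited noise at state-dependent tone ----------------------
    tone = np.empty(n_ep)
    for st in STATES:
        tone[states == st] = params.emg_tone[st]
    rema_idx = np.flatnonzero(truth.flags[REM_A])
    if rema_idx.size:
        # per-burst EMG level: phasic (sub-WAKE) by default, a configurable
        # fraction at WAKE-like level (those epochs will stage as WAKE)
        bursts = np.split(rema_idx, np.flatnonzero(np.diff(rema_idx) > 1) + 1)
        for burst in bursts:
            wakelike = rng.random() < params.rema_wakelike_fraction
            tone[burst] = (
                params.emg_tone_rema_wakelike if wakelike else params.emg_tone_rema
            )
    sos, gain = _emg_filter(fs)
    emg_white = rng.standard_normal(n_ep * spe) * np.repeat(tone, spe)
    emg = signal.sosfiltfilt(sos, emg_white) / gain

    return Recording(
        eeg=eeg[None, :],
        emg=emg,
        fs=fs,
        lights_off_at=0.0,  # set by the caller below
        animal_id=animal_id,
        group=group,
    )


@dataclass
class CohortConfig:
    """A full synthetic study: group sizes, session geometry, master seed.

    Group sizes default to the analyzed study design (8 young controls,
    6 adult controls, 8 young MSA, 10 adult MSA). Sessions default to 2 h
    for tractable testing; 23-h sessions with lights-off at 12 h reproduce
    the full recording geometry.
    """

    groups: dict[str, int] = field(
        default_factory=lambda: {
            "control_young": 8,
            "control_adult": 6,
            "msa_young": 8,
            "msa_adult": 10,
        }
    )
    session_length: float = 7200.0  # s
    lights_off_at: float | None = None  # default: mid-session
    fs: float = 250.0
    epoch_len: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.groups.values()):
            raise IntegrityError("group sizes must be >= 1")
        if self.lights_off_at is None:
            self.lights_off_at = self.session_length / 2.0


@dataclass
class CohortAnimal:
    animal_id: str
    group: str
    seed_entropy: int
    recording: Recording
    truth: Hypnogram


def generate_cohort(cfg: CohortConfig) -> Iterator[CohortAnimal]:
    """Yield one synthesized animal at a time (recordings are large).

    Per-animal RNG streams are spawned from the master seed by counter, so
    a fixed seed reproduces the cohort exactly, animal by animal.
    """
    n_epochs = int(cfg.session_length // cfg.epoch_len)
    lights_off_epoch = int(cfg.lights_off_at // cfg.epoch_len)
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(sum(cfg.groups.values()))
    k = 0
    for group, size in cfg.groups.items():
        params = phenotype_for_group(group)
        for i in range(size):
            rng = np.random.default_rng(children[k])
            animal_id = f"{group}_{i + 1:02d}"
            truth = simulate_hypnogram(
                params, n_epochs, lights_off_epoch, rng, cfg.epoch_len
            )
            rec = synthesize_signals(
                truth, params, rng, cfg.fs, animal_id=animal_id, group=group
            )
            rec.lights_off_at = float(cfg.lights_off_at)
            yield CohortAnimal(
                animal_id=animal_id,
                group=group,
                seed_entropy=k,
                recording=rec,
                truth=truth,
            )
            k += 1


def write_cohort(cfg: CohortConfig, outdir) -> pd.DataFrame:
    """Materialize a cohort: EDF per animal, truth-hypnogram CSV, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for animal in generate_cohort(cfg):
        edf = outdir / f"{animal.animal_id}.edf"
        truth_csv = outdir / f"{animal.animal_id}_truth.csv"
        io_formats.write_recording_edf(animal.recording, edf)
        io_formats.write_hypnogram(animal.truth, truth_csv)
        rows.append(
            {
                "animal_id": animal.animal_id,
                "group": animal.group,
                "seed": cfg.seed,
                "animal_index": animal.seed_entropy,
                "recording": edf.name,
                "truth": truth_csv.name,
                "lights_off_at": cfg.lights_off_at,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
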