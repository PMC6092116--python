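"""Voxelwise phase-encoded analysis.

Preprocessing chain (in order): discard the first half cycle (8 volumes),
linear detrend, high-pass filter at 0.01 Hz, divide by the mean (percent
change), shift back 3 volumes (4.5 s) to compensate hemodynamic lag, and
time-reverse clockwise runs so every run follows the counterclockwise
orientation sequence. A voxel's preferred orientation is then read from the
phase of the best-fitting cosine at the stimulus fundamental; response
reliability is summarized by coherence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import detrend as _linear_detrend

from .circular import circular_correlation  # re-exported for convenience
from .synth import RunTimeSeries, SyntheticSession

__all__ = [
    "VoxelPreference",
    "preprocess_run",
    "fit_phase_encoded",
    "phase_to_orientation",
    "estimate_preferences",
    "average_runs",
    "circular_correlation",
    "DEFAULT_COHERENCE_THRESHOLD",
]

DEFAULT_COHERENCE_THRESHOLD = 0.2


@dataclass
class VoxelPreference:
    preferred_deg: float  # [0, 180); NaN when below threshold / undefined
    amplitude: float  # percent signal at the fundamental
    coherence: float  # [0, 1]
    phase_rad: float  # fitted cosine phase, [0, 2*pi)


def preprocess_run(
    run: RunTimeSeries,
    discard_volumes: int = 8,
    highpass_hz: float = 0.01,
    lag_volumes: int = 3,
    protect_task_frequencies: bool = True,
) -> RunTimeSeries:
    """Apply the preprocessing chain to a raw run.

    The lag compensation is a circular shift over the retained volumes (the
    design is periodic after the discarded half cycle). Raises if the run is
    already preprocessed.

    By default the linear trend is estimated after projecting out the
    task-periodic component (the tiled cycle average), so that a purely
    periodic response contributes no spurious slope and the later circular
    shift/time-reversal is exact for noiseless data; set
    ``protect_task_frequencies=False`` for a plain least-squares line fit.
    """
    if run.preprocessed:
        raise ValueError("run is already preprocessed")
    vpc = run.design.volumes_per_cycle
    if run.values.shape[1] < discard_volumes + int(1.5 * vpc):
        raise ValueError("run too short: need at least 1.5 cycles after discard")
    ts = np.asarray(run.values, dtype=float)[:, discard_volumes:]
    n = ts.shape[1]

    if protect_task_frequencies and n % vpc == 0:
        cycles = ts.reshape(ts.shape[0], n // vpc, vpc)
        periodic = np.tile(cycles.mean(axis=1), (1, n // vpc))
        resid = ts - periodic  # zero-mean over complete cycles
        line = resid - _linear_detrend(resid, axis=1, type="linear")
        ts = ts - line  # removes the trend, keeps the original mean
    else:
        means = ts.mean(axis=1, keepdims=True)
        # plain detrend removes the mean; keep it for percent-change
        ts = _linear_detrend(ts, axis=1, type="linear") + means

    # high-pass: zero Fourier bins strictly below the cutoff (keep DC)
    spec = np.fft.rfft(ts, axis=1)
    freqs = np.fft.rfftfreq(n, d=run.design.tr_s)
    kill = (freqs > 0) & (freqs < highpass_hz)
    spec[:, kill] = 0
    ts = np.fft.irfft(spec, n, axis=1)

    ts = ts / ts.mean(axis=1, keepdims=True)  # percent change (unit mean)
    ts = np.roll(ts, -lag_volumes, axis=1)  # shift back in time
    if run.design.direction == "cw":
        ts = ts[:, ::-1]
    return RunTimeSeries(
        values=ts,
        design=run.design,
        preprocessed=True,
        n_discarded=discard_volumes,
        meta=dict(run.meta),
    )


def fit_phase_encoded(ts: np.ndarray, n_cycles: int) -> VoxelPreference:
    """Fundamental cosine fit of one voxel's (preprocessed) time series.

    The series is modeled as ``a * cos(2*pi*n_cycles*t/T - phase)``;
    coherence is the fundamental amplitude divided by the root-sum-square of
    amplitudes at all nonzero frequencies.
    """
    ts = np.asarray(ts, dtype=float)
    n = ts.size
    if n_cycles < 1 or n_cycles >= n / 2:
        raise ValueError("n_cycles must satisfy 1 <= n_cycles < n/2")
    if n % n_cycles:
        raise ValueError("series length must be divisible by n_cycles")
    spec = np.fft.fft(ts)
    fund = spec[n_cycles]
    amplitude = 2.0 * np.abs(fund) / n
    total = 0.5 * np.sum(np.abs(spec[1:]) ** 2)
    coherence = float(np.abs(fund) / np.sqrt(total)) if total > 0 else 0.0
    if amplitude <= 1e-12 * max(1.0, np.abs(ts).max()):
        return VoxelPreference(preferred_deg=float("nan"), amplitude=0.0,
                               coherence=0.0, phase_rad=0.0)
    phase = float(-np.angle(fund) % (2 * np.pi))
    return VoxelPreference(preferred_deg=float("nan"), amplitude=float(amplitude),
                           coherence=coherence, phase_rad=phase)


def phase_to_orientation(phase_rad: float, offset_deg: float = 0.0) -> float:
    """Map a fitted cosine phase to orientation degrees in [0, 180).

    With no offset, phase 0 corresponds to the first orientation of the
    counterclockwise sequence (0 deg) and phase pi to 90 deg. ``offset_deg``
    accounts for where in the cycle the retained series starts (the
    discarded half cycle advances the sequence by 8 steps = 90 deg).
    """
    ori = (offset_deg + phase_rad / (2 * np.pi) * 180.0) % 180.0
    if ori >= 180.0 - 1e-9:
        ori = 0.0
    return float(ori)


def average_runs(runs: list[RunTimeSeries]) -> np.ndarray:
    """Average preprocessed runs (voxels x volumes)."""
    if not runs:
        raise ValueError("no runs to average")
    if not all(r.preprocessed for r in runs):
        raise ValueError("runs must be preprocessed before averaging")
    return np.mean([r.values for r in runs], axis=0)


def estimate_preferences(
    runs: list[RunTimeSeries],
    coherence_threshold: float = 0.0,
) -> list[VoxelPreference]:
    """Per-voxel preferred orientation from (averaged) preprocessed runs.

    ``runs`` should all come from one modulator axis; cw/ccw and
    sine/cosine-phase runs are averaged together after preprocessing, as in
    the study. Preferences with coherence below ``coherence_threshold`` are
    flagged NaN but keep their amplitude/coherence values.
    """
    prepped = [r if r.preprocessed else preprocess_run(r) for r in runs]
    mean_ts = average_runs(prepped)
    design = prepped[0].design
    n_cycles = int(mean_ts.shape[1] / design.volumes_per_cycle)
    step_deg = 180.0 / design.n_orientations
    offset_deg = (prepped[0].n_discarded % design.volumes_per_cycle) * step_deg
    out = []
    for ts in mean_ts:
        pref = fit_phase_encoded(ts, n_cycles)
        if pref.amplitude > 0 and pref.coherence >= coherence_threshold:
            pref = replace(
                pref,
                preferred_deg=phase_to_orientation(pref.phase_rad, offset_deg),
            )
        out.append(pref)
    return out


def runs_by_modulator(session: SyntheticSession) -> dict[str, list[RunTimeSeries]]:
    """Split a session's runs by modulator axis."""
    out: dict[str, list[RunTimeSeries]] = {}
    for run in session.runs:
        out.setdefault(run.design.modulator.axis, []).append(run)
    return out
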