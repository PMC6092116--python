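"""Synthetic phase-encoded fMRI sessions.

Emulates the study design: the carrier orientation cycles through 16 evenly
spaced angles at 1.5 s per orientation (one volume per step at TR = 1.5 s),
completing 10.5 cycles per 252 s run. A session fully crosses carrier
direction (cw/ccw) x modulator axis (radial/angular) x modulator phase
(sine/cosine), two runs per condition: 16 runs.

Each synthetic voxel has a ground-truth orientation tuning per modulator
(either taken from the energy-model simulation or synthesized analytically),
a hemodynamic delay (pure 3-volume lag by default, optional gamma IRF),
low-frequency drift, and white noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.stats import gamma as gamma_dist

from .simulation import ORIENTATIONS_16, PRF, TuningPrediction
from .stimuli import ModulatorSpec

__all__ = [
    "RunDesign",
    "SessionDesign",
    "GroundTruthVoxel",
    "NoiseModel",
    "RunTimeSeries",
    "SyntheticSession",
    "make_prf_grid",
    "generate_run",
    "generate_session",
    "cosine_tuning_truths",
    "orientation_index_sequence",
]

Direction = Literal["cw", "ccw"]


@dataclass(frozen=True)
class RunDesign:
    """Timing and condition of one phase-encoded run."""

    modulator: ModulatorSpec = field(default_factory=ModulatorSpec)
    direction: Direction = "ccw"
    tr_s: float = 1.5
    s_per_orientation: float = 1.5
    n_orientations: int = 16
    n_cycles: float = 10.5

    def __post_init__(self) -> None:
        if self.direction not in ("cw", "ccw"):
            raise ValueError("direction must be 'cw' or 'ccw'")
        run_s = self.n_cycles * self.cycle_s
        if abs(run_s / self.tr_s - round(run_s / self.tr_s)) > 1e-9:
            raise ValueError("run duration must be an integer number of volumes")

    @property
    def cycle_s(self) -> float:
        return self.n_orientations * self.s_per_orientation

    @property
    def run_s(self) -> float:
        return self.n_cycles * self.cycle_s

    @property
    def n_volumes(self) -> int:
        return int(round(self.run_s / self.tr_s))

    @property
    def volumes_per_cycle(self) -> int:
        return int(round(self.cycle_s / self.tr_s))


@dataclass(frozen=True)
class SessionDesign:
    """Full 2 x 2 x 2 crossing, ``runs_per_condition`` repeats each."""

    runs_per_condition: int = 2
    radial: ModulatorSpec = field(
        default_factory=lambda: ModulatorSpec("radial", "sine", "cosine", 0.5)
    )
    angular: ModulatorSpec = field(
        default_factory=lambda: ModulatorSpec("angular", "sine", "cosine", 12)
    )
    base: RunDesign = field(default_factory=RunDesign)

    def run_designs(self) -> list[RunDesign]:
        out = []
        for axis in ("radial", "angular"):
            for direction in ("ccw", "cw"):
                for mod_phase in ("cosine", "sine"):
                    spec = self.radial if axis == "radial" else self.angular
                    spec = replace(spec, phase=mod_phase)
                    for _ in range(self.runs_per_condition):
                        out.append(
                            replace(self.base, modulator=spec, direction=direction)
                        )
        return out

    @property
    def n_runs(self) -> int:
        return 8 * self.runs_per_condition


@dataclass
class GroundTruthVoxel:
    """Links one synthetic voxel's pRF to its tuning under each modulator."""

    prf: PRF
    tuning: dict  # modulator axis -> TuningPrediction (16 responses)
    baseline: float = 100.0
    amplitude_scale: float = 2.0  # percent signal, peak-to-mean of the drive


@dataclass(frozen=True)
class NoiseModel:
    white_sd: float = 0.5  # percent signal per volume
    drift_linear: float = 0.0  # percent signal over the run
    drift_quadratic: float = 0.0
    drift_pink: float = 0.0  # SD of the 1/f component, percent signal
    hemo_lag_s: float = 4.5
    irf: Literal["delay", "gamma"] = "delay"
    gamma_shape: float = 6.0
    gamma_scale_s: float = 0.9

    def __post_init__(self) -> None:
        if self.white_sd < 0:
            raise ValueError("white_sd must be >= 0")


@dataclass
class RunTimeSeries:
    """One run: voxels x volumes plus design metadata and state flags."""

    values: np.ndarray  # (V, T)
    design: RunDesign
    preprocessed: bool = False
    n_discarded: int = 0  # volumes dropped from the start by preprocessing
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.preprocessed and self.values.shape[1] != self.design.n_volumes:
            raise ValueError(
                f"{self.values.shape[1]} volumes inconsistent with design "
                f"({self.design.n_volumes})"
            )

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]


@dataclass
class SyntheticSession:
    runs: list
    truths: list
    design: SessionDesign
    noise: NoiseModel
    seed: int | None = None


def orientation_index_sequence(design: RunDesign) -> np.ndarray:
    """Orientation index shown at each volume (before hemodynamic lag).

    ccw runs step 0, 1, ..., 15, 0, ...; cw runs present the reversed
    sequence 15, 14, ..., 0, 15, ...
    """
    v = np.arange(design.n_volumes)
    n = design.n_orientations
    if design.direction == "ccw":
        return v % n
    return (n - 1 - v) % n


def make_prf_grid(
    ecc_range: tuple[float, float],
    n_ecc: int,
    n_polar: int,
    sigma_rule: Callable[[float], float] = lambda ecc: 0.5 + 0.1 * ecc,
) -> list[PRF]:
    """Deterministic polar grid of pRFs; sigma follows ``sigma_rule(ecc)``."""
    if n_ecc < 1 or n_polar < 1:
        raise ValueError("empty pRF grid")
    eccs = np.linspace(ecc_range[0], ecc_range[1], n_ecc)
    polars = np.arange(n_polar) / n_polar * 2 * np.pi
    out = []
    for ecc in eccs:
        for beta in polars:
            out.append(
                PRF(
                    x0=float(ecc * np.cos(beta)),
                    y0=float(ecc * np.sin(beta)),
                    sigma=float(sigma_rule(float(ecc))),
                )
            )
    return out


def cosine_tuning_truths(
    prfs: Sequence[PRF],
    rng: np.random.Generator,
    tuning_amplitude: float = 1.0,
    flip_exact: bool = True,
) -> list[GroundTruthVoxel]:
    """Analytic stand-in truths: each voxel prefers its pRF's polar angle
    under the radial modulator and the orthogonal orientation under the
    angular modulator (the model's prediction), with cosine tuning curves.

    Fast path for tests that exercise the measurement pipeline without
    re-running the image-computable model.
    """
    out = []
    for prf in prfs:
        beta = np.degrees(np.arctan2(prf.y0, prf.x0)) % 180.0
        jitter = 0.0 if flip_exact else float(rng.normal(scale=5.0))
        prefs = {"radial": beta, "angular": (beta + 90.0 + jitter) % 180.0}
        tuning = {}
        for axis, pref in prefs.items():
            resp = 1.0 + tuning_amplitude * np.cos(
                2 * np.pi * (ORIENTATIONS_16 - pref) / 180.0
            )
            tuning[axis] = TuningPrediction(
                responses=resp, preferred_deg=pref, amplitude=tuning_amplitude
            )
        out.append(GroundTruthVoxel(prf=prf, tuning=tuning))
    return out


def _gamma_irf(noise: NoiseModel, tr_s: float, n: int) -> np.ndarray:
    t = np.arange(n) * tr_s
    h = gamma_dist.pdf(t, a=noise.gamma_shape, scale=noise.gamma_scale_s)
    return h / h.sum()


def _drift(noise: NoiseModel, n: int, rng: np.random.Generator) -> np.ndarray:
    t = np.linspace(-1.0, 1.0, n)
    d = noise.drift_linear * t + noise.drift_quadratic * t**2
    if noise.drift_pink > 0:
        freqs = np.fft.rfftfreq(n)
        amp = np.zeros_like(freqs)
        amp[1:] = 1.0 / freqs[1:]
        spec = amp * np.exp(2j * np.pi * rng.random(freqs.size))
        pink = np.fft.irfft(spec, n)
        pink = pink / pink.std()
        d = d + noise.drift_pink * pink
    return d


def generate_run(
    design: RunDesign,
    truths: Sequence[GroundTruthVoxel],
    noise: NoiseModel,
    rng: np.random.Generator | int | None = None,
) -> RunTimeSeries:
    """Synthesize one run (voxels x volumes, image-intensity units).

    The neural drive per volume is the voxel's ground-truth tuning at the
    currently shown orientation; hemodynamics delay it (circularly, the
    drive being periodic); drift and white noise are in percent signal.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    axis = design.modulator.axis
    for tv in truths:
        if axis not in tv.tuning:
            raise ValueError(
                f"ground-truth voxel lacks tuning for modulator {axis!r}"
            )
    idx = orientation_index_sequence(design)
    n = design.n_volumes
    lag_volumes = int(round(noise.hemo_lag_s / design.tr_s))
    values = np.empty((len(truths), n))
    for i, tv in enumerate(truths):
        resp = np.asarray(tv.tuning[axis].responses, dtype=float)
        # center/scale by the single-period tuning (the run holds 10.5
        # cycles; a run-mean would bias cw and ccw differently)
        span = resp.max() - resp.min()
        drive = (resp[idx] - resp.mean()) / (span if span > 0 else 1.0)
        if noise.irf == "delay":
            bold = np.roll(drive, lag_volumes)
        else:
            h = _gamma_irf(noise, design.tr_s, min(n, 24))
            bold = np.convolve(np.tile(drive, 2), h, mode="full")[n : 2 * n]
        pct = tv.amplitude_scale * bold + _drift(noise, n, rng)
        pct = pct + rng.normal(scale=noise.white_sd, size=n)
        values[i] = tv.baseline * (1.0 + pct / 100.0)
    return RunTimeSeries(values=values, design=design,
                         meta={"modulator_axis": axis,
                               "direction": design.direction,
                               "modulator_phase": design.modulator.phase})


def generate_session(
    sdesign: SessionDesign,
    truths: Sequence[GroundTruthVoxel],
    noise: NoiseModel,
    seed: int | None = None,
) -> SyntheticSession:
    """All 16 runs of one session; identical ``seed`` -> identical data."""
    root = np.random.default_rng(seed)
    children = root.spawn(len(sdesign.run_designs()))
    runs = [
        generate_run(rd, truths, noise, rng)
        for rd, rng in zip(sdesign.run_designs(), children)
    ]
    return SyntheticSession(runs=runs, truths=list(truths), design=sdesign,
                            noise=noise, seed=seed)
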