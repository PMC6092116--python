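"""Pipeline orchestration: configuration, staged execution, figures, logging.

``run_pipeline`` executes stimuli -> energy-model simulation -> synthetic
session -> phase-encoded analysis -> decoding/RSA and writes figure analogs
(bias maps, pRF-ring preferences, model-vs-recovered scatter, decoding bars,
MDS rings) plus CSV tables and a run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import __version__
from .analysis import estimate_preferences, preprocess_run, runs_by_modulator
from .circular import axial_difference_deg, median_absolute_axial_difference
from .decoding import (
    decoding_summary,
    dissimilarity_matrix,
    mds_embed,
    session_population_responses,
)
from .io import preferences_table, save_session_h5, tuning_table
from .simulation import (
    ORIENTATIONS_16,
    PRF,
    TuningPrediction,
    predict_prf_tuning,
    simulate_orientation_maps,
)
from .stimuli import AnnulusSpec, CarrierSpec, ModulatorSpec, simulation_geometry
from .synth import (
    GroundTruthVoxel,
    NoiseModel,
    SessionDesign,
    generate_session,
    make_prf_grid,
)

__all__ = ["ExperimentConfig", "RunLog", "run_pipeline", "config_from_toml"]


@dataclass(frozen=True)
class ExperimentConfig:
    """All pipeline parameters, defaulting to the conventional 3T design;
    ``preset="7t"`` switches carrier/annulus to the high-field variant."""

    seed: int = 0
    out_dir: str = "results/pipeline"
    # geometry / simulation resolution
    image_size: int = 128
    field_deg: float = 24.0
    # pyramid
    n_orientation_bands: int = 6
    sf_bandwidth_octaves: float = 0.5
    # stimulus
    carrier_sf_cpd: float = 0.5
    carrier_contrast: float = 1.0
    annulus_inner_deg: float = 0.5
    annulus_outer_deg: float = 9.5
    annulus_transition_deg: float = 1.0
    # modulators must be coarser than the carrier for the vignetting
    # geometry to dominate
    radial_modulator_freq: float = 0.25
    radial_log_scaled: bool = False
    angular_modulator_freq: int = 8
    modulator_waveform: str = "sine"
    n_carrier_phases: int = 8
    # synthetic session
    n_ecc: int = 3
    n_polar: int = 16
    prf_sigma_deg: float = 1.0
    noise_white_sd: float = 1.0
    drift_linear: float = 1.0
    drift_pink: float = 0.5
    # analysis / decoding
    coherence_threshold: float = 0.2
    mds_seed: int = 0

    @classmethod
    def preset(cls, name: str, **overrides) -> "ExperimentConfig":
        if name == "3t":
            base = {}
        elif name == "7t":
            base = {
                "carrier_sf_cpd": 1.4,
                "annulus_inner_deg": 0.75,
                "annulus_outer_deg": 9.0,
                "radial_log_scaled": True,
                "radial_modulator_freq": 1.0,
            }
        else:
            raise ValueError(f"unknown preset {name!r}")
        base.update(overrides)
        return cls(**base)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def config_from_toml(path: str | Path) -> ExperimentConfig:
    """Read a flat or block-structured TOML config."""
    with open(path, "rb") as f:
        raw = tomllib.load(f)
    preset = raw.pop("preset", None)
    flat: dict = {}
    for key, value in raw.items():
        if isinstance(value, dict):
            flat.update(value)
        else:
            flat[key] = value
    if preset:
        return ExperimentConfig.preset(preset, **flat)
    return ExperimentConfig(**flat)


@dataclass
class RunLog:
    config_hash: str
    version: str
    stages: list = field(default_factory=list)

    def record(self, stage: str, seconds: float, **info) -> None:
        self.stages.append({"stage": stage, "wall_s": round(seconds, 3), **info})

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "version": self.version,
                    "stages": self.stages,
                },
                indent=1,
            )
        )


def _modulators(config: ExperimentConfig) -> dict[str, ModulatorSpec]:
    return {
        "radial": ModulatorSpec(
            "radial",
            config.modulator_waveform,
            "cosine",
            config.radial_modulator_freq,
            log_scaled=config.radial_log_scaled,
        ),
        "angular": ModulatorSpec(
            "angular", config.modulator_waveform, "cosine",
            config.angular_modulator_freq,
        ),
    }


def run_pipeline(config: ExperimentConfig) -> dict:
    """Execute the full synthetic pipeline; returns a report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog(config_hash=config.hash(), version=__version__)
    report: dict = {"out_dir": str(out), "config_hash": config.hash()}

    geom = simulation_geometry(config.image_size, config.field_deg)
    annulus = AnnulusSpec(
        config.annulus_inner_deg, config.annulus_outer_deg,
        config.annulus_transition_deg,
    )
    carrier = CarrierSpec(sf_cpd=config.carrier_sf_cpd,
                          contrast=config.carrier_contrast)
    phases = np.arange(config.n_carrier_phases) / config.n_carrier_phases * 2 * np.pi
    mods = _modulators(config)

    # -- stage 1: energy-model simulation ---------------------------------
    t0 = time.perf_counter()
    maps = {}
    for axis, mod in mods.items():
        maps[axis], scale = simulate_orientation_maps(
            geom, mod, annulus, carrier, carrier_phases=phases,
            n_orientations_bank=config.n_orientation_bands,
            bandwidth=config.sf_bandwidth_octaves,
        )
    # unmodulated maps for the plain bias figure
    plain, _ = simulate_orientation_maps(
        geom, None, annulus, carrier, carrier_phases=phases,
        orientations_deg=np.array([90.0, 0.0]),
        n_orientations_bank=config.n_orientation_bands,
        bandwidth=config.sf_bandwidth_octaves,
    )
    log.record("model_simulation", time.perf_counter() - t0, scale=scale)

    _bias_figure(plain[0] - plain[1], geom, out / "fig_bias_annulus.png",
                 "vertical - horizontal, annulus vignette")
    for axis in mods:
        v = maps[axis][np.argmin(np.abs(ORIENTATIONS_16 - 90.0))]
        h = maps[axis][0]
        _bias_figure(v - h, geom, out / f"fig_bias_{axis}.png",
                     f"vertical - horizontal, {axis} modulator")

    # -- stage 2: pRF sampling -> ground truth ----------------------------
    t0 = time.perf_counter()
    # keep pRFs near mid-annulus: voxels toward the annulus edges see the
    # radial aperture edge shared by both modulators and are not expected
    # to flip
    mid = 0.5 * (config.annulus_inner_deg + config.annulus_outer_deg)
    lo, hi = mid - 0.5, mid + 0.5
    prfs = make_prf_grid((lo, hi), config.n_ecc, config.n_polar,
                         sigma_rule=lambda e: config.prf_sigma_deg)
    truths = []
    for prf in prfs:
        tuning = {
            axis: predict_prf_tuning(maps[axis], prf, geom) for axis in mods
        }
        truths.append(GroundTruthVoxel(prf=prf, tuning=tuning))
    table = tuning_table(prfs, [t.tuning["radial"] for t in truths])
    table.to_csv(out / "tuning_radial.csv", index=False)
    tuning_table(prfs, [t.tuning["angular"] for t in truths]).to_csv(
        out / "tuning_angular.csv", index=False
    )
    log.record("prf_sampling", time.perf_counter() - t0, n_prfs=len(prfs))
    _ring_figure(truths, out / "fig_prf_ring.png")

    # -- stage 3: synthetic session ---------------------------------------
    t0 = time.perf_counter()
    sdesign = SessionDesign(radial=mods["radial"], angular=mods["angular"])
    noise = NoiseModel(
        white_sd=config.noise_white_sd,
        drift_linear=config.drift_linear,
        drift_pink=config.drift_pink,
    )
    session = generate_session(sdesign, truths, noise, seed=config.seed)
    save_session_h5(out / "session.h5", session)
    log.record("synthetic_session", time.perf_counter() - t0,
               n_runs=len(session.runs))

    # -- stage 4: phase-encoded analysis ----------------------------------
    t0 = time.perf_counter()
    recovered = {}
    frames = []
    for axis, runs in runs_by_modulator(session).items():
        prefs = estimate_preferences(runs)
        recovered[axis] = prefs
        frames.append(preferences_table(prefs, axis))
    import pandas as pd

    pd.concat(frames, ignore_index=True).to_csv(out / "preferences.csv",
                                                index=False)
    rec_r = np.array([p.preferred_deg for p in recovered["radial"]])
    rec_a = np.array([p.preferred_deg for p in recovered["angular"]])
    flip = median_absolute_axial_difference(rec_r, rec_a)
    report["recovered_flip_deg"] = flip
    log.record("phase_encoded_analysis", time.perf_counter() - t0,
               median_flip_deg=round(flip, 2))
    _scatter_figure(truths, recovered, out / "fig_model_vs_recovered.png")

    # -- stage 5: decoding + RSA ------------------------------------------
    t0 = time.perf_counter()
    responses = session_population_responses(session)
    summary = decoding_summary(responses)
    report["decoding"] = summary
    pd.DataFrame([summary]).to_csv(out / "decoding.csv", index=False)

    cond = np.vstack(
        [np.mean([r.matrix for r in responses[ax]], axis=0)
         for ax in ("radial", "angular")]
    )
    dmat = dissimilarity_matrix(cond)
    pd.DataFrame(dmat).to_csv(out / "dissimilarity.csv", index=False)
    points, stress = mds_embed(dmat, seed=config.mds_seed)
    pd.DataFrame(points, columns=["x", "y"]).to_csv(out / "mds.csv", index=False)
    report["mds_stress"] = stress
    log.record("decoding_rsa", time.perf_counter() - t0, **summary)
    _decoding_figure(summary, out / "fig_decoding.png")
    _mds_figure(points, out / "fig_mds.png")

    log.write(out / "runlog.json")
    report["figures"] = sorted(str(p.name) for p in out.glob("fig_*.png"))
    return report


def _bias_figure(bias: np.ndarray, geom, path: Path, title: str) -> None:
    lim = np.abs(bias).max() or 1.0
    half = geom.shape[0] / 2 * geom.deg_per_pixel
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(bias, cmap="RdBu_r", vmin=-lim, vmax=lim,
                   extent=[-half, half, -half, half])
    ax.set_title(title, fontsize=9)
    ax.set_xlabel("deg")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _ring_figure(truths: list[GroundTruthVoxel], path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for axis, color in (("radial", "tab:blue"), ("angular", "tab:orange")):
        beta = [np.degrees(np.arctan2(t.prf.y0, t.prf.x0)) % 360 for t in truths]
        pref = [t.tuning[axis].preferred_deg for t in truths]
        ax.scatter(beta, pref, s=12, color=color, label=axis)
    ax.set_xlabel("pRF polar angle (deg)")
    ax.set_ylabel("predicted preferred orientation (deg)")
    ax.legend()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _scatter_figure(truths, recovered, path: Path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(8, 4), sharey=True)
    for ax, axis in zip(axes, ("radial", "angular")):
        true = [t.tuning[axis].preferred_deg for t in truths]
        rec = [p.preferred_deg for p in recovered[axis]]
        ax.scatter(true, rec, s=10)
        ax.plot([0, 180], [0, 180], "k--", lw=0.8)
        ax.set_title(axis)
        ax.set_xlabel("model-predicted (deg)")
    axes[0].set_ylabel("recovered (deg)")
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _decoding_figure(summary: dict, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    keys = ["within", "across", "across_shifted"]
    ax.bar(range(3), [summary[k] for k in keys], color="gray")
    ax.axhline(1 / 16, color="k", ls="--", lw=0.8, label="chance")
    ax.set_xticks(range(3), keys, rotation=20)
    ax.set_ylabel("decoding accuracy")
    ax.legend()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _mds_figure(points: np.ndarray, path: Path) -> None:
    n = points.shape[0] // 2
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    cmap = plt.get_cmap("hsv")
    for i in range(points.shape[0]):
        ori = (i % n) / n
        style = "o" if i < n else "s"
        ax.plot(points[i, 0], points[i, 1], style, color=cmap(ori))
    ax.set_title("MDS: circles=radial, squares=angular; hue=orientation",
                 fontsize=8)
    fig.savefig(path, dpi=110)
    plt.close(fig)
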