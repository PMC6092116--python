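"""Reference evaluation protocols.

Self-contained, seeded procedures that recompute the package's headline
quantities from scratch: the modulator-flip prediction of the energy model,
noisy parameter recovery through the phase-encoded pipeline, the
within/across/shifted decoding pattern, and the calibration of the
phase-randomization permutation test. Used by the acceptance script and the
acceptance test suite.
"""

from __future__ import annotations

import numpy as np

from .analysis import estimate_preferences, fit_phase_encoded, preprocess_run, runs_by_modulator
from .circular import circular_correlation, median_absolute_axial_difference
from .decoding import (
    decode_within,
    decoding_summary,
    dissimilarity_matrix,
    mds_embed,
    permutation_test,
    session_population_responses,
)
from .simulation import PRF, predict_prf_tuning, simulate_orientation_maps
from .stimuli import AnnulusSpec, CarrierSpec, ModulatorSpec, simulation_geometry
from .synth import (
    GroundTruthVoxel,
    NoiseModel,
    RunDesign,
    SessionDesign,
    SyntheticSession,
    cosine_tuning_truths,
    generate_run,
    generate_session,
    make_prf_grid,
)

__all__ = [
    "SINUSOIDAL_ANNULUS",
    "SINUSOIDAL_CARRIER",
    "SINUSOIDAL_MODULATORS",
    "modulator_flip_protocol",
    "model_truths_on_ring",
    "qualitative_pattern_protocol",
    "recovery_protocol",
    "permutation_calibration_protocol",
]

# the sinusoidal-modulator experiment: carrier annulus 0.75-9 deg,
# 1.4 cpd carrier, eccentricity-scaled rings, 12-cycle wedges
SINUSOIDAL_ANNULUS = AnnulusSpec(inner_deg=0.75, outer_deg=9.0, transition_deg=1.0)
SINUSOIDAL_CARRIER = CarrierSpec(sf_cpd=1.4)
SINUSOIDAL_MODULATORS = {
    "radial": ModulatorSpec("radial", "sine", "cosine", 1.0, log_scaled=True),
    "angular": ModulatorSpec("angular", "sine", "cosine", 12),
}


def _model_maps(size: int, field_deg: float, n_phases: int) -> tuple[dict, object]:
    geom = simulation_geometry(size, field_deg)
    phases = np.arange(n_phases) / n_phases * 2 * np.pi
    maps = {}
    for axis, mod in SINUSOIDAL_MODULATORS.items():
        maps[axis], _ = simulate_orientation_maps(
            geom, mod, SINUSOIDAL_ANNULUS, SINUSOIDAL_CARRIER,
            carrier_phases=phases,
        )
    return maps, geom


def modulator_flip_protocol(
    size: int = 256,
    field_deg: float = 24.0,
    n_phases: int = 16,
    n_polar: int = 16,
    prf_sigma: float = 1.0,
) -> dict:
    """Model-predicted preferred orientations under radial vs angular
    sinusoidal modulators, sampled by Gaussian pRFs on the mid-annulus
    ring; returns the circular median absolute difference (deg)."""
    maps, geom = _model_maps(size, field_deg, n_phases)
    mid = 0.5 * (SINUSOIDAL_ANNULUS.inner_deg + SINUSOIDAL_ANNULUS.outer_deg)
    prefs: dict[str, list[float]] = {"radial": [], "angular": []}
    for beta in np.arange(n_polar) / n_polar * 2 * np.pi:
        prf = PRF(mid * np.cos(beta), mid * np.sin(beta), prf_sigma)
        for axis in prefs:
            prefs[axis].append(
                predict_prf_tuning(maps[axis], prf, geom).preferred_deg
            )
    flip = median_absolute_axial_difference(
        np.array(prefs["radial"]), np.array(prefs["angular"])
    )
    return {"flip_deg": flip, "preferred": prefs, "n": n_polar}


def model_truths_on_ring(
    size: int = 128,
    field_deg: float = 24.0,
    n_phases: int = 4,
    n_polar: int = 16,
    n_ecc: int = 2,
    prf_sigma: float = 1.0,
) -> list[GroundTruthVoxel]:
    """Ground-truth voxels with energy-model tuning, pRFs near mid-annulus."""
    maps, geom = _model_maps(size, field_deg, n_phases)
    mid = 0.5 * (SINUSOIDAL_ANNULUS.inner_deg + SINUSOIDAL_ANNULUS.outer_deg)
    prfs = make_prf_grid((mid - 0.4, mid + 0.4), n_ecc, n_polar,
                         sigma_rule=lambda e: prf_sigma)
    truths = []
    for prf in prfs:
        tuning = {
            axis: predict_prf_tuning(maps[axis], prf, geom)
            for axis in SINUSOIDAL_MODULATORS
        }
        truths.append(GroundTruthVoxel(prf=prf, tuning=tuning))
    return truths


def qualitative_pattern_protocol(
    truths: list[GroundTruthVoxel],
    n_seeds: int = 10,
    white_sd: float = 1.0,
    seed: int = 0,
) -> list[dict]:
    """Within / across / across-shifted decoding plus the MDS label-rotation
    alignment, over ``n_seeds`` model-faithful synthetic sessions."""
    sdesign = SessionDesign(
        radial=SINUSOIDAL_MODULATORS["radial"],
        angular=SINUSOIDAL_MODULATORS["angular"],
    )
    noise = NoiseModel(white_sd=white_sd, drift_linear=1.0)
    out = []
    for s in range(n_seeds):
        session = generate_session(sdesign, truths, noise, seed=seed + s)
        responses = session_population_responses(session)
        summary = decoding_summary(responses)
        mean = {
            ax: np.mean([r.matrix for r in responses[ax]], axis=0)
            for ax in ("radial", "angular")
        }

        def identical_label_distance(shift: int) -> float:
            cond = np.vstack(
                [mean["radial"], np.roll(mean["angular"], -shift, axis=0)]
            )
            emb, _ = mds_embed(dissimilarity_matrix(cond), seed=seed + s)
            return float(np.mean(np.linalg.norm(emb[:16] - emb[16:], axis=1)))

        summary["mds_distance_unshifted"] = identical_label_distance(0)
        summary["mds_distance_shifted"] = identical_label_distance(8)
        out.append(summary)
    return out


def recovery_protocol(
    n_voxels: int = 200,
    white_sd: float = 2.4,
    n_seeds: int = 10,
    seed: int = 0,
) -> dict:
    """Preferred-orientation recovery at single-run coherence ~0.3.

    Analytic (cosine-tuned) ground truth; returns per-seed circular
    correlations between recovered and true preferences, the mean
    single-run coherence, and the per-seed median radial-vs-angular
    recovered flip.
    """
    n_polar = max(8, n_voxels // 5)
    prfs = make_prf_grid((3.0, 7.0), int(np.ceil(n_voxels / n_polar)), n_polar)
    prfs = prfs[:n_voxels]
    noise = NoiseModel(white_sd=white_sd)
    corr, flips, cohs = [], [], []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        truths = cosine_tuning_truths(prfs, rng)
        session = generate_session(SessionDesign(), truths, noise,
                                   seed=seed + 1000 + s)
        by_mod = runs_by_modulator(session)
        rec = {}
        for axis, runs in by_mod.items():
            prefs = estimate_preferences(runs)
            rec[axis] = np.array([p.preferred_deg for p in prefs])
            true = np.array([t.tuning[axis].preferred_deg for t in truths])
            corr.append(circular_correlation(rec[axis], true))
        flips.append(
            median_absolute_axial_difference(rec["radial"], rec["angular"])
        )
        single = preprocess_run(by_mod["radial"][0])
        cohs.append(
            np.mean([fit_phase_encoded(ts, 10).coherence for ts in single.values])
        )
    return {
        "circular_correlations": corr,
        "median_flips_deg": flips,
        "mean_single_run_coherence": float(np.mean(cohs)),
        "n_voxels": n_voxels,
    }


def permutation_calibration_protocol(
    n_null: int = 200,
    n_perm: int = 99,
    n_voxels: int = 6,
    white_sd: float = 1.0,
    seed: int = 0,
) -> dict:
    """False-positive rate of the permutation test under pure-noise nulls."""
    rng = np.random.default_rng(seed)
    prfs = make_prf_grid((5.0, 5.0), 1, n_voxels)
    flat = [
        GroundTruthVoxel(prf=p, tuning={"radial": t.tuning["radial"]},
                         amplitude_scale=0.0)
        for p, t in zip(prfs, cosine_tuning_truths(prfs, rng))
    ]
    sdesign = SessionDesign()
    rdesigns = [d for d in sdesign.run_designs() if d.modulator.axis == "radial"]
    noise = NoiseModel(white_sd=white_sd)
    pvals = np.empty(n_null)
    for i in range(n_null):
        root = np.random.default_rng(seed + 10_000 + i)
        runs = [
            generate_run(d, flat, noise, r)
            for d, r in zip(rdesigns, root.spawn(len(rdesigns)))
        ]
        session = SyntheticSession(runs=runs, truths=flat, design=sdesign,
                                   noise=noise)
        _, pvals[i], _ = permutation_test(
            session, decode_within, n_perm=n_perm, seed=seed + 20_000 + i
        )
    return {
        "false_positive_rate": float(np.mean(pvals < 0.05)),
        "p_values": pvals.tolist(),
        "n_null": n_null,
        "n_perm": n_perm,
    }
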