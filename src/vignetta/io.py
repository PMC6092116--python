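"""Format adapters: HDF5 sessions and energy maps, NIfTI interchange,
CSV tables, JSON design sidecars."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .simulation import PRF, TuningPrediction
from .stimuli import ModulatorSpec
from .synth import (
    GroundTruthVoxel,
    NoiseModel,
    RunDesign,
    RunTimeSeries,
    SessionDesign,
    SyntheticSession,
)

__all__ = [
    "save_session_h5",
    "load_session_h5",
    "save_energy_maps_h5",
    "export_session_nifti",
    "import_real_session",
    "tuning_table",
    "preferences_table",
]


def _design_dict(design: RunDesign) -> dict:
    d = dataclasses.asdict(design)
    return d


def _design_from_dict(d: dict) -> RunDesign:
    mod = ModulatorSpec(**d.pop("modulator"))
    return RunDesign(modulator=mod, **d)


def save_session_h5(path: str | Path, session: SyntheticSession) -> None:
    """runs x voxels x volumes plus JSON-encoded designs and truths."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        data = np.stack([r.values for r in session.runs])
        f.create_dataset("bold", data=data)
        f.attrs["designs"] = json.dumps(
            [_design_dict(r.design) for r in session.runs]
        )
        f.attrs["noise"] = json.dumps(dataclasses.asdict(session.noise))
        if session.seed is not None:
            f.attrs["seed"] = session.seed
        truths = [
            {
                "prf": dataclasses.asdict(t.prf),
                "baseline": t.baseline,
                "amplitude_scale": t.amplitude_scale,
                "tuning": {
                    k: {
                        "responses": list(map(float, v.responses)),
                        "preferred_deg": v.preferred_deg,
                        "amplitude": v.amplitude,
                    }
                    for k, v in t.tuning.items()
                },
            }
            for t in session.truths
        ]
        f.attrs["truths"] = json.dumps(truths)


def load_session_h5(path: str | Path) -> SyntheticSession:
    with h5py.File(path, "r") as f:
        bold = f["bold"][()]
        designs = [_design_from_dict(d) for d in json.loads(f.attrs["designs"])]
        noise = NoiseModel(**json.loads(f.attrs["noise"]))
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
        truths = []
        for t in json.loads(f.attrs["truths"]):
            tuning = {
                k: TuningPrediction(
                    responses=np.asarray(v["responses"]),
                    preferred_deg=v["preferred_deg"],
                    amplitude=v["amplitude"],
                )
                for k, v in t["tuning"].items()
            }
            truths.append(
                GroundTruthVoxel(
                    prf=PRF(**t["prf"]),
                    tuning=tuning,
                    baseline=t["baseline"],
                    amplitude_scale=t["amplitude_scale"],
                )
            )
    runs = [RunTimeSeries(values=v, design=d) for v, d in zip(bold, designs)]
    # session design is reconstructed loosely; runs carry the authority
    return SyntheticSession(
        runs=runs, truths=truths, design=SessionDesign(), noise=noise, seed=seed
    )


def save_energy_maps_h5(
    path: str | Path,
    energy: np.ndarray,
    peak_frequencies: np.ndarray,
    config: dict,
) -> None:
    """Energy maps with dimensions (scale, orientation, row, col)."""
    with h5py.File(Path(path), "w") as f:
        ds = f.create_dataset("energy", data=energy)
        ds.attrs["dimensions"] = "scale,orientation,row,col"
        ds.attrs["peak_frequencies_cpp"] = np.asarray(peak_frequencies)
        f.attrs["config"] = json.dumps(config)


def export_session_nifti(
    session: SyntheticSession, out_dir: str | Path
) -> tuple[list[Path], Path]:
    """One 4D NIfTI per run (voxels laid out along x) plus a design sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, run in enumerate(session.runs):
        vol = run.values[:, None, None, :].astype(np.float64)  # (V,1,1,T)
        img = nib.Nifti1Image(vol, affine=np.eye(4))
        img.header.set_zooms((1.0, 1.0, 1.0, run.design.tr_s))
        p = out_dir / f"run-{i:02d}.nii"
        nib.save(img, p)
        paths.append(p)
    sidecar = out_dir / "design.json"
    sidecar.write_text(
        json.dumps([_design_dict(r.design) for r in session.runs], indent=1)
    )
    return paths, sidecar


def import_real_session(
    nifti_paths: Sequence[str | Path],
    design_sidecar: str | Path,
    roi_mask: np.ndarray | None = None,
) -> SyntheticSession:
    """Load 4D BOLD runs + a JSON design sidecar into a session object.

    ``roi_mask`` is a boolean array over the volume's spatial grid; voxels
    outside it are dropped.
    """
    design_sidecar = Path(design_sidecar)
    if not design_sidecar.exists():
        raise FileNotFoundError(f"design sidecar not found: {design_sidecar}")
    designs = [_design_from_dict(d) for d in json.loads(design_sidecar.read_text())]
    if len(designs) != len(nifti_paths):
        raise ValueError(
            f"{len(nifti_paths)} volumes but {len(designs)} run designs in sidecar"
        )
    runs = []
    for p, d in zip(nifti_paths, designs):
        img = nib.load(str(p))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"{p}: expected a 4D volume")
        if roi_mask is not None:
            values = data[np.asarray(roi_mask, dtype=bool)]
        else:
            values = data.reshape(-1, data.shape[-1])
        runs.append(RunTimeSeries(values=values, design=d))
    n_vox = {r.values.shape[0] for r in runs}
    if len(n_vox) > 1:
        raise ValueError(f"runs disagree on voxel count: {sorted(n_vox)}")
    return SyntheticSession(
        runs=runs, truths=[], design=SessionDesign(), noise=NoiseModel()
    )


def tuning_table(
    prfs: Sequence[PRF], tunings: Sequence[TuningPrediction]
) -> pd.DataFrame:
    """CSV-ready table: prf_x, prf_y, sigma, 16 responses, preferred, amp."""
    rows = []
    for prf, t in zip(prfs, tunings):
        row = {"prf_x": prf.x0, "prf_y": prf.y0, "sigma": prf.sigma}
        row.update({f"resp_{i:02d}": r for i, r in enumerate(t.responses)})
        row["preferred_deg"] = t.preferred_deg
        row["amplitude"] = t.amplitude
        rows.append(row)
    return pd.DataFrame(rows)


def preferences_table(preferences, modulator: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "preferred_deg": [p.preferred_deg for p in preferences],
            "amplitude": [p.amplitude for p in preferences],
            "coherence": [p.coherence for p in preferences],
            "modulator": modulator,
        }
    )
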