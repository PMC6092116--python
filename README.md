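# vignetta

An image-computable V1 energy model plus a phase-encoded fMRI analysis
suite for studying **stimulus vignetting**: any contrast envelope
("vignette") bounding a grating spreads Fourier energy across orientations,
so population responses that carry no explicit orientation tuning still
depend on grating orientation near the vignette. The package demonstrates,
on synthetic data emulating a 16-orientation phase-encoded design, that
swapping a radial modulator (rings) for an angular one (wedges) flips
measured orientation preference by 90 degrees.

## What is in the box

| module | contents |
| --- | --- |
| `vignetta.pyramid` | frequency-domain steerable pyramid: quadrature-pair filter bank, exact tiling (sum of squared amplitudes = 1), decomposition, energy channels |
| `vignetta.stimuli` | calibrated display geometry, oriented sinusoidal carriers, raised-cosine annulus vignettes, radial/angular square/sine modulators, stimulus composition |
| `vignetta.simulation` | simulated voxel maps (orientation-summed energy at the dominant scale, carrier-phase averaged), orientation-bias maps, Gaussian-pRF sampling, cosine tuning fits |
| `vignetta.synth` | synthetic phase-encoded sessions: 16 orientations x 1.5 s, 10.5 cycles per 252-s run, cw/ccw x radial/angular x sine/cosine crossing (16 runs), hemodynamic lag, drift, noise |
| `vignetta.analysis` | preprocessing chain (discard half cycle, detrend, 0.01-Hz high-pass, percent change, 3-volume lag shift, cw time reversal), fundamental cosine fit with coherence, phase-to-orientation mapping, Fisher-Lee circular correlation |
| `vignetta.decoding` | cycle-averaged population responses, pooled-diagonal-covariance naive Bayes decoding (within / across / 90-deg-shifted), Fourier phase-randomization permutation test, 1-r dissimilarity matrices, metric MDS |
| `vignetta.workflow` / `vignetta.io` / `vignetta.cli` | TOML-configured pipeline with figures and run logs, HDF5/NIfTI/CSV/JSON adapters, `vignetta` CLI |
| `vignetta.protocols` | seeded end-to-end evaluation protocols used by the acceptance suite |

## Quick start

```python
import numpy as np
from vignetta.pyramid import PyramidConfig, build_filter_bank, tiling_error
from vignetta.protocols import modulator_flip_protocol

bank = build_filter_bank(PyramidConfig(image_shape=(768, 1024)))
print(bank.n_scales)              # 15 spatial-frequency channels
print(tiling_error(bank))         # ~1e-15

flip = modulator_flip_protocol(size=256)
print(flip["flip_deg"])           # ~90 deg radial-vs-angular preference flip
```

## Command line

```bash
vignetta report --preset 7t --seed 0 --out results/pipeline   # full pipeline + figures
vignetta stimuli --condition radial-sine --orientation 90 --out results/stims
vignetta model --image stim.npy --orientations 6 --bandwidth 0.5 --out energy.h5
vignetta synth --n-voxels 64 --out session.h5                  # synthetic session
vignetta analyze --session session.h5 --coherence-threshold 0.2 --out results/an
vignetta decode --session session.h5 --scheme within --n-perm 1000 --seed 7
vignetta rsa --session session.h5 --out results/rsa
```

## Conventions

Orientation 0 deg means horizontal stripes; angles increase
counterclockwise and are reported mod 180 deg. Carrier phase 0 puts a
luminance maximum at fixation. The filter bank's "bandwidth" is the full
width at half maximum of the squared radial transfer, in octaves.
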