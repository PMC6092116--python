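"""MVPA suite: population responses, diagonal-Gaussian decoding, Fourier
phase-randomization permutation testing, and representational similarity
analysis with multidimensional scaling.

The decoder is a naive Bayes classifier with a shared diagonal covariance
(linear boundaries): per-class feature means, one pooled per-feature
variance, equal priors. Dissimilarity between condition mean response
vectors is 1 - Pearson r.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.manifold import MDS

from .analysis import preprocess_run, runs_by_modulator
from .synth import RunTimeSeries, SyntheticSession

__all__ = [
    "PopulationResponse",
    "DecoderModel",
    "cycle_average",
    "decode_within",
    "decode_across",
    "phase_randomize",
    "permutation_test",
    "dissimilarity_matrix",
    "mds_embed",
    "session_population_responses",
    "decoding_summary",
]

VARIANCE_FLOOR = 1e-12


@dataclass
class PopulationResponse:
    """16 orientation-labelled response vectors of one run.

    Row ``i`` holds the cycle-averaged response to orientation
    ``i * 11.25`` deg (rows are aligned to the counterclockwise orientation
    sequence during construction).
    """

    matrix: np.ndarray  # (16, V)
    labels_deg: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.labels_deg):
            raise ValueError("one label per row required")


def cycle_average(run: RunTimeSeries) -> PopulationResponse:
    """Average a preprocessed run across its cycles: (16, V) matrix.

    Rows are rolled so that row ``i`` corresponds to orientation
    ``i * (180/n)`` deg of the counterclockwise sequence, undoing the
    half-cycle discard offset.

    Raises
    ------
    ValueError
        If the run is not preprocessed or does not hold an integer number
        of cycles.
    """
    if not run.preprocessed:
        raise ValueError("cycle_average expects a preprocessed run")
    vpc = run.design.volumes_per_cycle
    v, t = run.values.shape
    if t % vpc:
        raise ValueError(f"{t} volumes is not an integer number of {vpc}-volume cycles")
    mat = run.values.reshape(v, t // vpc, vpc).mean(axis=1).T  # (vpc, V)
    offset = run.n_discarded % vpc
    mat = np.roll(mat, offset, axis=0)  # row i <- cycle position (i - offset)
    n = run.design.n_orientations
    labels = np.arange(n) * (180.0 / n)
    return PopulationResponse(matrix=mat, labels_deg=labels, meta=dict(run.meta))


@dataclass
class DecoderModel:
    """Gaussian naive Bayes with pooled diagonal covariance, equal priors."""

    class_means: np.ndarray  # (C, V)
    pooled_variance: np.ndarray  # (V,)

    @classmethod
    def fit(cls, rows: np.ndarray, labels: np.ndarray) -> "DecoderModel":
        """``rows`` (N, V) with integer class ``labels`` (N,)."""
        classes = np.unique(labels)
        means = np.vstack([rows[labels == c].mean(axis=0) for c in classes])
        resid = rows - means[np.searchsorted(classes, labels)]
        dof = max(rows.shape[0] - classes.size, 1)
        var = (resid**2).sum(axis=0) / dof
        var = np.maximum(var, VARIANCE_FLOOR)
        return cls(class_means=means, pooled_variance=var)

    def log_likelihood(self, rows: np.ndarray) -> np.ndarray:
        """(N, C) class-conditional Gaussian log likelihoods."""
        d = rows[:, None, :] - self.class_means[None, :, :]
        return -0.5 * np.sum(
            d**2 / self.pooled_variance + np.log(2 * np.pi * self.pooled_variance),
            axis=2,
        )

    def predict(self, rows: np.ndarray) -> np.ndarray:
        """Max-likelihood class per row; ties go to the lowest class index."""
        return np.argmax(self.log_likelihood(rows), axis=1)


def _stack_runs(responses: Sequence[PopulationResponse]) -> tuple[np.ndarray, np.ndarray]:
    rows = np.vstack([r.matrix for r in responses])
    n = responses[0].matrix.shape[0]
    labels = np.tile(np.arange(n), len(responses))
    return rows, labels


def decode_within(
    responses: Sequence[PopulationResponse] | dict,
) -> float:
    """Leave-one-run-out decoding accuracy.

    ``responses`` is either a list of runs from one modulator, or a dict
    ``{modulator: [runs]}`` in which case accuracies are averaged across
    modulators.
    """
    if isinstance(responses, dict):
        return float(np.mean([decode_within(v) for v in responses.values()]))
    if len(responses) < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    accs = []
    for held in range(len(responses)):
        train = [r for i, r in enumerate(responses) if i != held]
        rows, labels = _stack_runs(train)
        model = DecoderModel.fit(rows, labels)
        test = responses[held].matrix
        pred = model.predict(test)
        accs.append(np.mean(pred == np.arange(test.shape[0])))
    return float(np.mean(accs))


def decode_across(
    responses_a: Sequence[PopulationResponse],
    responses_b: Sequence[PopulationResponse],
    label_shift_deg: float = 0.0,
) -> float:
    """Across-modulator decoding, averaged over both train/test directions.

    ``label_shift_deg`` rotates the test-set orientation labels before
    scoring (90 deg = 8 of 16 positions); it must be a multiple of the
    orientation step.
    """
    n = responses_a[0].matrix.shape[0]
    step = 180.0 / n
    shift = label_shift_deg / step
    if abs(shift - round(shift)) > 1e-9:
        raise ValueError(
            f"label shift {label_shift_deg} deg is not a multiple of the "
            f"orientation step {step} deg"
        )
    shift = int(round(shift)) % n
    accs = []
    for train_set, test_set in ((responses_a, responses_b), (responses_b, responses_a)):
        rows, labels = _stack_runs(train_set)
        model = DecoderModel.fit(rows, labels)
        for resp in test_set:
            pred = model.predict(resp.matrix)
            truth = (np.arange(n) + shift) % n
            accs.append(np.mean(pred == truth))
    return float(np.mean(accs))


def phase_randomize(ts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Surrogate series with the same amplitude spectrum, randomized phases.

    Phases are drawn independently per voxel; DC and Nyquist components
    keep their (real) values so the output is real.
    """
    ts = np.asarray(ts, dtype=float)
    n = ts.shape[-1]
    spec = np.fft.rfft(ts, axis=-1)
    k = spec.shape[-1]
    hi = k - 1 if n % 2 == 0 else k  # exclude the Nyquist bin when present
    phases = rng.uniform(0, 2 * np.pi, size=spec.shape[:-1] + (hi - 1,))
    spec[..., 1:hi] = np.abs(spec[..., 1:hi]) * np.exp(1j * phases)
    return np.fft.irfft(spec, n, axis=-1)


def session_population_responses(
    session: SyntheticSession,
) -> dict[str, list[PopulationResponse]]:
    """Preprocess every run of a session and cycle-average, per modulator."""
    out: dict[str, list[PopulationResponse]] = {}
    for axis, runs in runs_by_modulator(session).items():
        out[axis] = [cycle_average(preprocess_run(r)) for r in runs]
    return out


def permutation_test(
    session: SyntheticSession,
    statistic: Callable[[dict[str, list[PopulationResponse]]], float],
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Fourier phase-randomization permutation test on raw time courses.

    Each permutation randomizes the Fourier phases of every voxel's raw
    series (preserving amplitude spectra), reruns preprocessing and the
    ``statistic``, and the p-value is the fraction of permutations with a
    statistic >= the observed one.

    Returns ``(observed, p_value, null_distribution)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = statistic(session_population_responses(session))
    null = np.empty(n_perm)
    for p in range(n_perm):
        surrogate = SyntheticSession(
            runs=[
                RunTimeSeries(
                    values=phase_randomize(r.values, rng),
                    design=r.design,
                    meta=dict(r.meta),
                )
                for r in session.runs
            ],
            truths=session.truths,
            design=session.design,
            noise=session.noise,
        )
        null[p] = statistic(session_population_responses(surrogate))
    p_value = float(np.mean(null >= observed))
    return float(observed), p_value, null


def within_modulator_statistic(
    responses: dict[str, list[PopulationResponse]],
) -> float:
    """Default permutation-test statistic: within-modulator accuracy."""
    return decode_within(responses)


def dissimilarity_matrix(conditions: np.ndarray) -> np.ndarray:
    """1 - Pearson r between condition mean response vectors.

    ``conditions`` is (C, V); returns a symmetric (C, C) matrix with zero
    diagonal and entries in [0, 2].
    """
    conditions = np.asarray(conditions, dtype=float)
    if conditions.shape[1] < 2:
        raise ValueError("need at least 2 voxels per condition vector")
    sd = conditions.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance condition vector")
    d = 1.0 - np.corrcoef(conditions)
    np.fill_diagonal(d, 0.0)
    return d


def mds_embed(
    d: np.ndarray, dim: int = 2, seed: int | None = 0
) -> tuple[np.ndarray, float]:
    """Metric MDS (stress-majorization, 10 restarts, seeded).

    Returns ``(points, stress)`` with ``points`` of shape (C, dim).
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    mds = MDS(
        n_components=dim,
        metric="precomputed",
        metric_mds=True,
        n_init=10,
        init="random",
        max_iter=3000,
        eps=1e-14,
        random_state=seed,
        normalized_stress=False,
    )
    points = mds.fit_transform(d)
    return points, float(mds.stress_)


def decoding_summary(
    responses: dict[str, list[PopulationResponse]],
) -> dict[str, float]:
    """Within, across, and 90 deg-shifted across accuracies for a session."""
    axes = sorted(responses)
    if len(axes) != 2:
        raise ValueError("expected exactly two modulator axes")
    a, b = (responses[ax] for ax in axes)
    return {
        "within": decode_within(responses),
        "across": decode_across(a, b, 0.0),
        "across_shifted": decode_across(a, b, 90.0),
    }
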