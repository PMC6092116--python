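import itertools

import numpy as np
import pytest

from vignetta.analysis import preprocess_run
from vignetta.decoding import (
    DecoderModel,
    PopulationResponse,
    cycle_average,
    decode_across,
    decode_within,
    dissimilarity_matrix,
    mds_embed,
    permutation_test,
    phase_randomize,
    session_population_responses,
)
from vignetta.synth import (
    NoiseModel,
    RunDesign,
    RunTimeSeries,
    SessionDesign,
    generate_session,
)


def brute_force_predict(train_rows, train_labels, test_rows):
    """Independent oracle: per-class Gaussian posteriors, enumerated."""
    classes = sorted(set(train_labels))
    means = {c: np.mean([x for x, l in zip(train_rows, train_labels) if l == c],
                        axis=0) for c in classes}
    sq = []
    for x, l in zip(train_rows, train_labels):
        sq.append((np.asarray(x) - means[l]) ** 2)
    var = np.sum(sq, axis=0) / max(len(train_rows) - len(classes), 1)
    var = np.maximum(var, 1e-12)
    preds = []
    for x in test_rows:
        best, best_ll = None, -np.inf
        for c in classes:  # lowest class wins ties (strict >)
            ll = float(np.sum(-0.5 * ((x - means[c]) ** 2 / var
                                      + np.log(2 * np.pi * var))))
            if ll > best_ll:
                best, best_ll = c, ll
        preds.append(best)
    return np.array(preds)


def make_response(matrix, **meta):
    n = matrix.shape[0]
    return PopulationResponse(matrix=matrix,
                              labels_deg=np.arange(n) * 180.0 / n, meta=meta)


class TestCycleAverage:
    def test_shape_and_alignment(self, faithful_session):
        run = preprocess_run(faithful_session.runs[0])
        pr = cycle_average(run)
        assert pr.matrix.shape == (16, run.values.shape[0])
        assert pr.labels_deg[1] == pytest.approx(11.25)

    def test_requires_preprocessed(self, faithful_session):
        with pytest.raises(ValueError, match="preprocessed"):
            cycle_average(faithful_session.runs[0])

    def test_noiseless_rows_equal_single_cycle(self):
        vals = np.tile(np.arange(16.0), (2, 10))
        run = RunTimeSeries(values=vals, design=RunDesign(), preprocessed=True,
                            n_discarded=0)
        pr = cycle_average(run)
        np.testing.assert_allclose(pr.matrix[:, 0], np.arange(16.0))

    def test_alignment_undoes_discard_offset(self):
        base = np.arange(16.0)
        shifted = np.tile(np.roll(base, -8), 10)  # starts at position 8
        run = RunTimeSeries(values=shifted[None, :], design=RunDesign(),
                            preprocessed=True, n_discarded=8)
        pr = cycle_average(run)
        np.testing.assert_allclose(pr.matrix[:, 0], base)

    def test_white_noise_variance_reduction(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(200, 160))
        run = RunTimeSeries(values=vals, design=RunDesign(), preprocessed=True,
                            n_discarded=0)
        pr = cycle_average(run)
        ratio = pr.matrix.var() / vals.var()
        assert ratio == pytest.approx(0.1, rel=0.15)

    def test_non_integer_cycles(self):
        run = RunTimeSeries(values=np.zeros((2, 150)), design=RunDesign(),
                            preprocessed=True, n_discarded=0)
        with pytest.raises(ValueError, match="integer"):
            cycle_average(run)


class TestDecoderOracle:
    def test_matches_brute_force_toy_instances(self):
        rng = np.random.default_rng(3)
        for n_classes, n_vox in itertools.product((2, 3, 4, 5), (1, 3, 5)):
            for rep in range(5):
                n_train_per = 3
                rows = rng.normal(size=(n_classes * n_train_per, n_vox))
                labels = np.repeat(np.arange(n_classes), n_train_per)
                test = rng.normal(size=(7, n_vox))
                model = DecoderModel.fit(rows, labels)
                np.testing.assert_array_equal(
                    model.predict(test),
                    brute_force_predict(rows, labels, test),
                )

    def test_tie_breaks_to_lowest_class(self):
        rows = np.array([[0.0], [0.0], [1.0], [1.0]])
        labels = np.array([0, 0, 1, 1])
        model = DecoderModel.fit(rows, labels)
        assert model.predict(np.array([[0.5]]))[0] == 0


class TestDecodeWithin:
    def test_perfect_separation(self):
        rng = np.random.default_rng(0)
        centers = rng.normal(size=(16, 8)) * 10
        runs = [make_response(centers + rng.normal(size=(16, 8)) * 1e-3)
                for _ in range(8)]
        assert decode_within(runs) == 1.0

    def test_needs_two_runs(self):
        with pytest.raises(ValueError):
            decode_within([make_response(np.zeros((16, 4)))])

    def test_permuted_labels_chance(self):
        rng = np.random.default_rng(1)
        centers = rng.normal(size=(16, 6))
        accs = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            runs = [
                make_response(r.permutation(centers + r.normal(size=(16, 6)) * 0.5))
                for _ in range(4)
            ]
            accs.append(decode_within(runs))
        mean = np.mean(accs)
        se = np.std(accs) / np.sqrt(len(accs))
        assert abs(mean - 1 / 16) < 3 * max(se, 1e-3)


class TestDecodeAcross:
    @pytest.fixture()
    def orthogonal_pair(self):
        """Modulator B's responses are modulator A's rolled by 90 deg."""
        rng = np.random.default_rng(2)
        centers = rng.normal(size=(16, 10)) * 5
        noise = 0.05
        runs_a = [make_response(centers + rng.normal(size=(16, 10)) * noise)
                  for _ in range(4)]
        rolled = np.roll(centers, 8, axis=0)
        runs_b = [make_response(rolled + rng.normal(size=(16, 10)) * noise)
                  for _ in range(4)]
        return runs_a, runs_b

    def test_shift_90_restores(self, orthogonal_pair):
        runs_a, runs_b = orthogonal_pair
        assert decode_across(runs_a, runs_b, 0.0) <= 1 / 16
        assert decode_across(runs_a, runs_b, 90.0) == 1.0

    def test_double_shift_identity(self, orthogonal_pair):
        runs_a, runs_b = orthogonal_pair
        a0 = decode_across(runs_a, runs_b, 0.0)
        a180 = decode_across(runs_a, runs_b, 180.0)
        assert a0 == a180

    def test_invalid_shift(self, orthogonal_pair):
        runs_a, runs_b = orthogonal_pair
        with pytest.raises(ValueError, match="multiple"):
            decode_across(runs_a, runs_b, 17.0)


class TestPhaseRandomization:
    def test_amplitude_spectrum_preserved(self):
        rng = np.random.default_rng(4)
        ts = rng.normal(size=(5, 168))
        surr = phase_randomize(ts, rng)
        amp0 = np.abs(np.fft.rfft(ts, axis=-1))
        amp1 = np.abs(np.fft.rfft(surr, axis=-1))
        assert np.abs(amp0 - amp1).max() < 1e-9
        assert (surr != ts).any()

    def test_output_real_and_mean_preserved(self):
        rng = np.random.default_rng(5)
        ts = rng.normal(size=(3, 167)) + 7.0  # odd length: no Nyquist bin
        surr = phase_randomize(ts, rng)
        assert np.isrealobj(surr)
        np.testing.assert_allclose(surr.mean(axis=1), ts.mean(axis=1))

    def test_permutation_chance_level(self, analytic_truths):
        noise = NoiseModel(white_sd=1.0)
        sess = generate_session(SessionDesign(), analytic_truths[:8], noise,
                                seed=6)
        obs, p, null = permutation_test(sess, decode_within, n_perm=30, seed=0)
        assert obs > 0.5
        assert p == 0.0
        se = null.std() / np.sqrt(null.size)
        assert abs(null.mean() - 1 / 16) < max(3 * se, 0.02)

    def test_n_perm_validation(self, faithful_session):
        with pytest.raises(ValueError):
            permutation_test(faithful_session, decode_within, n_perm=0)


class TestDissimilarity:
    def test_self_zero_and_symmetry(self):
        rng = np.random.default_rng(6)
        cond = rng.normal(size=(32, 20))
        d = dissimilarity_matrix(cond)
        assert np.allclose(np.diag(d), 0.0)
        assert np.allclose(d, d.T)
        assert d.min() >= 0.0 and d.max() <= 2.0

    def test_anticorrelated_is_two(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        d = dissimilarity_matrix(np.vstack([v, -v]))
        assert d[0, 1] == pytest.approx(2.0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            dissimilarity_matrix(np.vstack([np.ones(4), np.arange(4.0)]))


class TestMDS:
    def test_exact_metric_configuration(self):
        pts = np.array([[0, 0], [2, 0], [2, 1], [0, 1]], float)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        emb, stress = mds_embed(d, seed=0)
        de = np.linalg.norm(emb[:, None] - emb[None, :], axis=2)
        assert np.abs(de - d).max() < 1e-6

    def test_ring_order(self):
        # shifted-cosine similarity over 16 conditions embeds as a ring in
        # label order
        n = 16
        i = np.arange(n)
        d = 1.0 - np.cos(2 * np.pi * (i[:, None] - i[None, :]) / n)
        emb, _ = mds_embed(d, seed=1)
        ang = np.unwrap(np.arctan2(emb[:, 1], emb[:, 0]))
        steps = np.diff(ang)
        assert np.all(steps > 0) or np.all(steps < 0)

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            mds_embed(np.arange(16.0).reshape(4, 4))


class TestSessionLevel:
    def test_fig7_pattern_on_faithful_session(self, faithful_session):
        responses = session_population_responses(faithful_session)
        within = decode_within(responses)
        across = decode_across(responses["radial"], responses["angular"], 0.0)
        shifted = decode_across(responses["radial"], responses["angular"], 90.0)
        assert within > 0.5
        assert across <= 1 / 16
        assert shifted > within - 0.2

    def test_mds_label_rotation_aligns(self, faithful_session):
        responses = session_population_responses(faithful_session)
        mean = {
            ax: np.mean([r.matrix for r in responses[ax]], axis=0)
            for ax in ("radial", "angular")
        }

        def identical_label_distance(shift):
            cond = np.vstack([mean["radial"],
                              np.roll(mean["angular"], -shift, axis=0)])
            emb, _ = mds_embed(dissimilarity_matrix(cond), seed=0)
            return np.mean(
                np.linalg.norm(emb[:16] - emb[16:], axis=1)
            )

        assert identical_label_distance(8) < identical_label_distance(0)
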