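import numpy as np
import pytest

from smtrace.finetune import (
    DwellTimeSummary,
    _fit_exponential_rate,
    _mask_to_intervals,
    classify_and_segment,
    count_photobleach_steps,
    dwell_times_and_rates,
    extract_dwells,
    fit_logistic_head,
    idealize,
    kinetic_fingerprint_classify,
)
from smtrace.model import EmbeddingSet, Encoder, HeadSpec, embed_traces
from smtrace.simulate import (
    NO_BLEACH,
    NoiseConfig,
    PhotophysicsConfig,
    SimulatorConfig,
    generate_dataset,
)


def _emb_set(z, frames=None):
    if frames is None:
        frames = np.tile(z, (10, 1))
    return EmbeddingSet(np.asarray(z, float), np.asarray(frames, float))


class TestFitLogisticHead:
    def test_separable_two_class(self, rng):
        z0 = rng.normal(size=(50, 8)) + 10
        z1 = rng.normal(size=(50, 8)) - 10
        embs = [_emb_set(z) for z in np.vstack([z0, z1])]
        y = np.array([0] * 50 + [1] * 50)
        head = fit_logistic_head(embs, y, seed=0)
        assert head.training_accuracy == 1.0
        assert head.n_labeled == 100

    def test_random_labels_chance_level(self, rng):
        Z = rng.normal(size=(200, 8))
        y = rng.integers(0, 2, size=200)
        head = fit_logistic_head(Z[:100], y[:100], seed=0)
        from smtrace.model import head_predict

        preds = np.argmax(head_predict(Z[100:], head.head), axis=1)
        acc = np.mean(head.classes[preds] == y[100:])
        assert 0.3 < acc < 0.7

    def test_single_class_errors(self, rng):
        embs = [_emb_set(z) for z in rng.normal(size=(10, 4))]
        with pytest.raises(ValueError, match="single class"):
            fit_logistic_head(embs, np.zeros(10, dtype=int))

    def test_frame_level_fit(self, rng):
        frames = rng.normal(size=(5, 20, 6))
        labels = (frames[..., 0] > 0).astype(int)
        embs = [_emb_set(np.zeros(6), f) for f in frames]
        head = fit_logistic_head(embs, labels, level="frame", seed=1)
        assert head.head.level == "frame"
        assert head.training_accuracy > 0.9

    def test_determinism(self, rng):
        Z = rng.normal(size=(60, 6))
        y = (Z[:, 0] > 0).astype(int)
        h1 = fit_logistic_head(Z, y, seed=3)
        h2 = fit_logistic_head(Z, y, seed=3)
        assert np.array_equal(h1.head.W, h2.head.W)

    def test_frozen_encoder_unchanged(self, tiny_model_cfg, rng):
        encoder = Encoder(tiny_model_cfg, seed=7)
        before = encoder.fingerprint()
        traces = [rng.normal(size=(500, 2)) for _ in range(20)]
        embs = embed_traces(traces, encoder)
        y = np.arange(20) % 2
        fit_logistic_head(embs, y, seed=0)
        assert encoder.fingerprint() == before
        embs2 = embed_traces(traces, encoder)
        for a, b in zip(embs, embs2):
            assert np.array_equal(a.trace_embedding, b.trace_embedding)


class TestSegmentation:
    def test_mask_to_intervals(self):
        assert _mask_to_intervals(np.ones(10, bool)) == [(0, 10)]
        assert _mask_to_intervals(np.zeros(5, bool)) == []
        m = np.array([0, 1, 1, 0, 1], dtype=bool)
        assert _mask_to_intervals(m) == [(1, 3), (4, 5)]

    def test_all_usable_single_interval(self, rng):
        Z = np.vstack([rng.normal(size=(20, 6)) + 5,
                       rng.normal(size=(20, 6)) - 5])
        y = np.array([1] * 20 + [0] * 20)
        head = fit_logistic_head(Z, y, seed=0)
        embs = [_emb_set(Z[0], np.tile(Z[0], (30, 1)))]
        res = classify_and_segment(embs, head)
        assert res[0]["accepted"]
        assert res[0]["intervals"] == [(0, 30)]

    def test_rejected_trace_empty_intervals(self, rng):
        Z = np.vstack([rng.normal(size=(20, 6)) + 5,
                       rng.normal(size=(20, 6)) - 5])
        y = np.array([1] * 20 + [0] * 20)
        head = fit_logistic_head(Z, y, seed=0)
        embs = [_emb_set(Z[-1])]
        res = classify_and_segment(embs, head)
        assert not res[0]["accepted"]
        assert res[0]["intervals"] == []

    def test_segment_end_near_bleach(self, trained_toy):
        # simulator oracle at unit-test scale: with the briefly pre-trained
        # conftest encoder, usable intervals must not overrun the first
        # bleach frame by more than one 50-frame patch (the strict 5-frame
        # bound is asserted on the fully trained acceptance encoder)
        cfg = SimulatorConfig(
            n_frames=500,
            one_color_fraction=0.0,
            noise=NoiseConfig(snr_range=(5.0, 6.0)),
            photophysics=PhotophysicsConfig(tau_bleach_range=(100.0, 400.0)),
        )
        traces = generate_dataset(120, cfg, seed=41)
        encoder = trained_toy.encoder
        embs = embed_traces(traces, encoder)
        frame_labels = [t.ground_truth.active_mask.astype(int) for t in traces]
        head = fit_logistic_head(embs[:80], frame_labels[:80], level="frame",
                                 seed=0)
        trace_head = fit_logistic_head(
            embs[:80], np.ones(80, dtype=int) - np.arange(80) % 2, seed=0
        )  # dummy accept head; force acceptance via threshold 0
        res = classify_and_segment(embs[80:], trace_head, head, threshold=0.0,
                                   frame_threshold=0.5)
        checked = 0
        overruns = []
        for r, t in zip(res, traces[80:]):
            gt = t.ground_truth
            first = [b for b in gt.bleach_frame if b != NO_BLEACH]
            if not first or not r["intervals"]:
                continue
            end = max(e for _, e in r["intervals"])
            overruns.append(end - min(first))
            checked += 1
        assert checked >= 10
        overruns = np.asarray(overruns)
        assert np.median(overruns) <= 50
        assert np.mean(overruns <= 50) >= 0.8


class TestIdealize:
    def test_constant_trace_single_state(self):
        D, K = 6, 6
        head = HeadSpec("fret", "frame", K, np.eye(D), np.zeros(K))
        frames = np.tile(np.eye(D)[3] * 10, (40, 1))
        out = idealize([_emb_set(np.zeros(D), frames)], head)
        assert np.all(out[0]["classes"] == 3)
        centers = 0.5 * (np.linspace(0, 1, 7)[:-1] + np.linspace(0, 1, 7)[1:])
        assert np.allclose(out[0]["fret"], centers[3])

    def test_two_state_known_head(self):
        D = 10
        head = HeadSpec("fret", "frame", 10, np.eye(D), np.zeros(10))
        seq = np.array([2] * 5 + [7] * 5)
        frames = np.eye(D)[seq] * 10
        out = idealize([_emb_set(np.zeros(D), frames)], head)
        assert np.array_equal(out[0]["classes"], seq)


class TestDwellTimes:
    def test_extract_dwells_censoring(self):
        states = np.array([0, 0, 1, 1, 1, 0, 0, 2, 2, 0])
        d = extract_dwells(states)
        assert d == {1: [3], 0: [2], 2: [2]}
        d_all = extract_dwells(states, drop_censored=False)
        assert d_all[0] == [2, 2, 1]

    def test_single_dwell_cdf_step(self):
        k = _fit_exponential_rate(np.array([10.0, 10.0, 10.0, 10.0]))
        # survival steps at 10; only t=10 points with S>0 contribute
        assert k > 0

    def test_exponential_fit_recovery(self, rng):
        dwells = rng.geometric(0.02, size=3000).astype(float)
        k = _fit_exponential_rate(dwells)
        assert abs(k - 0.02) / 0.02 < 0.15

    def test_two_state_rate_recovery(self, rng):
        k12, k21 = 0.02, 0.05
        seqs = []
        for _ in range(200):
            s, path = 0, []
            for _ in range(500):
                path.append(s)
                u = rng.uniform()
                s = 1 - s if u < (k12 if s == 0 else k21) else s
            seqs.append(np.array(path))
        summary = dwell_times_and_rates(seqs, frame_period=0.5)
        assert abs(summary.rates["k12"] - k12) / k12 < 0.15
        assert abs(summary.rates["k21"] - k21) / k21 < 0.15
        assert np.allclose(summary.rates_per_second["k12"],
                           summary.rates["k12"] / 0.5)

    def test_low_confidence_flag(self):
        seqs = [np.array([0, 0, 1, 1, 0])]
        summary = dwell_times_and_rates(seqs)
        assert summary.low_confidence["k12"] or summary.low_confidence["k21"]

    def test_single_state_errors(self):
        with pytest.raises(ValueError, match="2 observed states"):
            dwell_times_and_rates([np.zeros(10, dtype=int)])


class TestPhotobleachCounting:
    def test_known_head_counts(self):
        D = 7
        head = HeadSpec("pb", "trace", 7, np.eye(D), np.zeros(7))
        embs = [_emb_set(np.eye(D)[3] * 10), _emb_set(np.eye(D)[0] * 10)]
        res = count_photobleach_steps(embs, head)
        assert res["counts"].tolist() == [3, 0]
        assert res["mean"] == 1.5


class TestKineticFingerprint:
    def test_empty_field(self, rng):
        Z = rng.normal(size=(20, 4))
        y = (Z[:, 0] > 0).astype(int)
        head = fit_logistic_head(Z, y, seed=0)
        res = kinetic_fingerprint_classify([], head)
        assert res["accepted"].size == 0 and res["per_fov"] == {}

    def test_separated_classes(self, rng):
        pos = rng.normal(size=(100, 6)) + 4
        neg = rng.normal(size=(100, 6)) - 4
        Z = np.vstack([pos, neg])
        y = np.array([1] * 100 + [0] * 100)
        head = fit_logistic_head(Z[::2], y[::2], seed=0)
        embs = [_emb_set(z) for z in Z[1::2]]
        res = kinetic_fingerprint_classify(
            embs, head, fields_of_view=["f1"] * 50 + ["f2"] * 50
        )
        yy = y[1::2]
        sens = res["accepted"][yy == 1].mean()
        spec = 1 - res["accepted"][yy == 0].mean()
        assert sens >= 0.9 and spec >= 0.9
        assert sum(res["per_fov"].values()) == int(res["accepted"].sum())

    def test_shuffled_labels_chance(self, rng):
        Z = rng.normal(size=(200, 6))
        Z[:100] += 4
        y_true = np.array([1] * 100 + [0] * 100)
        y_shuf = rng.permutation(y_true)
        head = fit_logistic_head(Z, y_shuf, seed=0)
        embs = [_emb_set(z) for z in Z]
        res = kinetic_fingerprint_classify(embs, head)
        rate_pos = res["accepted"][y_true == 1].mean()
        rate_neg = res["accepted"][y_true == 0].mean()
        assert abs(rate_pos - rate_neg) < 0.25
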