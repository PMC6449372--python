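"""Bag-of-features classifier: descriptors, vocabulary, encoding, training."""

from itertools import combinations

import numpy as np
import pytest

from wakewatch import bof_classifier as B
from wakewatch.bof_classifier import (DescriptorSpec, build_vocabulary,
                                      compute_descriptors, encode,
                                      encode_chips, evaluate, train_classifier)

SPEC = DescriptorSpec()


class TestDescriptors:
    def test_constant_chip_yields_zero_descriptors(self):
        descs = compute_descriptors(np.full((32, 32), 0.5), SPEC)
        assert not descs.any()

    def test_half_turn_permutes_orientation_bins(self):
        rng = np.random.default_rng(3)
        chip = rng.uniform(0, 1, (32, 32))
        d1 = compute_descriptors(chip, SPEC)
        d2 = compute_descriptors(np.rot90(chip, 2), SPEC)
        n = SPEC.n_orientations
        # permute orientation bins of the original by half a turn; the
        # energy channel is invariant.  Compare as multisets (cell order
        # reverses under rotation).
        perm = np.r_[(np.arange(n) + n // 2) % n, [n]]
        d1p = d1[:, perm]
        assert np.allclose(np.sort(d1p, axis=0), np.sort(d2, axis=0),
                           atol=1e-9)

    def test_vertical_step_edge_concentrates_horizontal_gradient(self):
        chip = np.zeros((32, 32))
        chip[:, 16:] = 1.0
        descs = compute_descriptors(chip, SPEC)
        live = descs[descs[:, :SPEC.n_orientations].sum(axis=1) > 0]
        # gradient of a vertical edge points along +x -> orientation bin 0
        assert np.all(live[:, 0] > 0.99)

    def test_chip_smaller_than_cell_rejected(self):
        with pytest.raises(ValueError):
            compute_descriptors(np.zeros((2, 2)), SPEC)


class TestVocabulary:
    def test_two_cluster_centroids_match_brute_force_partition(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 0.05, (6, 3))
        b = rng.normal(5.0, 0.05, (6, 3))
        pts = np.vstack([a, b])
        vocab = build_vocabulary([pts], k=2, seed=0)

        # exhaustive search over all 2-partitions of <= 12 points
        best, best_sse = None, np.inf
        idx = range(len(pts))
        for r in range(1, len(pts)):
            for subset in combinations(idx, r):
                m = np.zeros(len(pts), dtype=bool)
                m[list(subset)] = True
                c1, c2 = pts[m].mean(axis=0), pts[~m].mean(axis=0)
                sse = (np.sum((pts[m] - c1) ** 2)
                       + np.sum((pts[~m] - c2) ** 2))
                if sse < best_sse:
                    best_sse, best = sse, (c1, c2)
        got = sorted(map(tuple, vocab.centroids))
        expect = sorted(map(tuple, best))
        assert np.allclose(got, expect, atol=1e-6)

    def test_duplicate_descriptors_do_not_crash(self):
        pts = np.tile([1.0, 2.0, 3.0], (20, 1))
        vocab = build_vocabulary([pts], k=2, seed=0)
        assert vocab.centroids.shape == (2, 3)

    def test_same_seed_identical_centroids(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 1, (100, 9))
        v1 = build_vocabulary([pts], k=5, seed=3)
        v2 = build_vocabulary([pts], k=5, seed=3)
        assert np.array_equal(v1.centroids, v2.centroids)

    def test_too_few_descriptors_suggests_smaller_k(self):
        with pytest.raises(ValueError, match="smaller k"):
            build_vocabulary([np.zeros((3, 9))], k=10, seed=0)


class TestEncode:
    def _vocab(self):
        centroids = np.zeros((4, SPEC.n_dims))
        centroids[1, 0] = 1.0
        centroids[2, 1] = 1.0
        centroids[3, 2] = 1.0
        return B.Vocabulary(centroids=centroids, k=4, descriptor_spec=SPEC,
                            seed=0)

    def test_single_word_histogram(self):
        vocab = self._vocab()
        descs = np.tile(vocab.centroids[1], (7, 1))
        enc = encode(descs, vocab)
        assert np.allclose(enc.histogram, [0, 1, 0, 0])

    def test_histogram_always_sums_to_one(self, rng):
        vocab = self._vocab()
        for _ in range(10):
            descs = rng.uniform(0.1, 1.0, (rng.integers(1, 30), SPEC.n_dims))
            assert np.isclose(encode(descs, vocab).histogram.sum(), 1.0)

    def test_degenerate_chip_encodes_uniform_and_flagged(self):
        enc = encode(np.zeros((5, SPEC.n_dims)), self._vocab())
        assert enc.degenerate
        assert np.allclose(enc.histogram, 0.25)

    def test_assignment_equals_exhaustive_search(self, rng):
        vocab = self._vocab()
        descs = rng.uniform(0.1, 1.0, (25, SPEC.n_dims))
        enc = encode(descs, vocab)
        counts = np.zeros(4)
        for d in descs:  # exhaustive nearest-centroid search
            counts[np.argmin([np.linalg.norm(d - c)
                              for c in vocab.centroids])] += 1
        assert np.allclose(enc.histogram, counts / counts.sum())

    def test_spec_mismatch_rejected(self):
        with pytest.raises(ValueError, match="spec"):
            encode(np.zeros((3, SPEC.n_dims)), self._vocab(),
                   spec=DescriptorSpec(cell_px=8))


class TestTrainEvaluate:
    def _encoded(self, X):
        return [B.EncodedChip(histogram=h) for h in X]

    def _vocab(self, k=4):
        return B.Vocabulary(centroids=np.eye(k, SPEC.n_dims), k=k,
                            descriptor_spec=SPEC, seed=0)

    def test_separable_histograms_reach_perfect_training_accuracy(self):
        X = np.zeros((40, 4))
        X[:20, 0] = 1.0
        X[20:, 1] = 1.0
        y = np.r_[np.ones(20, dtype=int), np.zeros(20, dtype=int)]
        model = train_classifier(self._encoded(X), y, self._vocab(), seed=0)
        rep = evaluate(model, self._encoded(X), y)
        assert rep.average_accuracy == 100.0

    def test_shuffled_labels_give_chance_level_heldout_accuracy(self, rng):
        n = 2000
        X = rng.dirichlet(np.ones(4), size=2 * n)
        y = rng.integers(0, 2, 2 * n)
        model = train_classifier(self._encoded(X[:n]), y[:n], self._vocab(),
                                 seed=0)
        rep = evaluate(model, self._encoded(X[n:]), y[n:])
        assert abs(rep.average_accuracy - 50.0) < 5.0

    def test_single_class_training_rejected(self):
        X = np.eye(4)
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(self._encoded(X), [1, 1, 1, 1], self._vocab())

    def test_all_tern_predictions_on_balanced_set_give_half(self):
        X = np.zeros((10, 4)); X[:, 0] = 1.0
        y = np.r_[np.ones(5, dtype=int), np.zeros(5, dtype=int)]
        Xtr = np.zeros((4, 4)); Xtr[:2, 0] = 1.0; Xtr[2:, 0] = 1.0
        Xtr[2:, 1] = 5.0
        model = train_classifier(self._encoded(Xtr), [1, 1, 0, 0],
                                 self._vocab(), seed=0)
        # validation set designed so the model predicts tern throughout
        rep = evaluate(model, self._encoded(X), y)
        assert np.isclose(rep.average_accuracy, 50.0)

    def test_confusion_matches_pairwise_enumeration(self, rng):
        X = rng.dirichlet(np.ones(4), size=60)
        y = rng.integers(0, 2, 60)
        model = train_classifier(self._encoded(X), y, self._vocab(), seed=0)
        rep = evaluate(model, self._encoded(X), y)
        pred = model.predict(X)
        for t in (0, 1):
            for p in (0, 1):
                assert rep.confusion[t, p] == int(np.sum((y == t) & (pred == p)))
        assert rep.confusion.sum() == 60

    def test_macro_accuracy_invariant_to_validation_duplication(self, rng):
        X = rng.dirichlet(np.ones(4), size=40)
        y = rng.integers(0, 2, 40)
        model = train_classifier(self._encoded(X), y, self._vocab(), seed=0)
        r1 = evaluate(model, self._encoded(X), y)
        X2, y2 = np.vstack([X, X]), np.r_[y, y]
        r2 = evaluate(model, self._encoded(X2), y2)
        assert np.isclose(r1.average_accuracy, r2.average_accuracy)

    def test_empty_validation_rejected(self):
        model = train_classifier(
            self._encoded(np.eye(4)), [1, 1, 0, 0], self._vocab(), seed=0)
        with pytest.raises(ValueError):
            evaluate(model, [], [])


class TestEndToEnd:
    def test_pipeline_deterministic_and_better_than_chance(self, small_chip_sets):
        (train_chips, ytr), (val_chips, yva) = small_chip_sets

        def run():
            descs = [compute_descriptors(c, SPEC) for c in train_chips]
            vocab = build_vocabulary(descs, k=50, seed=5)
            model = train_classifier(
                [encode(d, vocab) for d in descs], ytr, vocab, seed=5)
            rep = evaluate(model, encode_chips(val_chips, vocab), yva)
            return rep

        r1, r2 = run(), run()
        assert r1.average_accuracy == r2.average_accuracy  # determinism
        assert r1.average_accuracy > 90.0

    def test_accuracy_non_decreasing_in_chip_contrast(self):
        from wakewatch.synthetic_data import SceneConfig, generate_chip_dataset
        accs = []
        for contrast in (15.0, 40.0, 90.0):
            vals = []
            for seed in (1, 2, 3):
                cfg = SceneConfig(bird_contrast=contrast,
                                  foam_contrast=contrast * 0.8)
                tr_c, tr_y = generate_chip_dataset(80, cfg, seed=seed)
                va_c, va_y = generate_chip_dataset(80, cfg, seed=seed + 100)
                descs = [compute_descriptors(c, SPEC) for c in tr_c]
                vocab = build_vocabulary(descs, k=40, seed=seed)
                model = train_classifier(
                    [encode(d, vocab) for d in descs], tr_y, vocab, seed=seed)
                rep = evaluate(model, encode_chips(va_c, vocab), va_y)
                vals.append(rep.average_accuracy)
            accs.append(np.mean(vals))
        assert accs[0] <= accs[1] + 2.0 and accs[1] <= accs[2] + 2.0
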