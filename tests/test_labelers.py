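"""Jump/duration labeling, filterbank preprocessing and cosine k-means."""

import numpy as np
import pytest

from usvsyntax.corpus import Corpus, LabelAlphabet, Syllable, SyllableSequence
from usvsyntax.labelers import (
    CentroidSet,
    FilterbankConfig,
    assign_by_centroid,
    assign_unclassified,
    cosine_assign,
    fit_duration_split,
    jump_label,
    label_by_jumps,
    preprocess_spectral,
    train_centroids,
)


def _syl(duration, jumps=0, dirs=()):
    return Syllable(0.0, duration, jump_count=jumps, jump_directions=tuple(dirs))


class TestJumpLabel:
    @pytest.mark.parametrize(
        "jumps, dirs, expected",
        [
            (0, (), "Simple"),
            (1, ("up",), "Up"),
            (1, ("down",), "Down"),
            (2, ("up", "down"), "Multiple"),
            (3, ("up", "down", "up"), "Multiple"),
        ],
    )
    def test_base_labels(self, jumps, dirs, expected):
        assert jump_label(_syl(0.05, jumps, dirs)) == expected

    def test_rejects_missing_features(self):
        with pytest.raises(ValueError, match="jump"):
            jump_label(Syllable(0.0, 0.05))


class TestDurationSplit:
    def _corpus(self, durations, label):
        t = 0.0
        syls = []
        for d in durations:
            syls.append(Syllable(t, t + d, label=label))
            t += d + 0.02
        return Corpus([SyllableSequence(syls)])

    def test_median_split_rule(self):
        base = {"Simple": [0.010, 0.020, 0.030, 0.040]}
        corpus = self._corpus(base["Simple"], "Simple")
        # pad the other base classes minimally
        for lab in ("Up", "Down", "Multiple"):
            corpus.sequences.append(self._corpus([0.05], lab).sequences[0])
        scheme = fit_duration_split(corpus)
        assert scheme.split_medians["Simple"] == pytest.approx(0.025)
        assert scheme.split("Simple", 0.020) == "Simple-short"
        assert scheme.split("Simple", 0.030) == "Simple-long"
        # tie rule: exactly the median goes short
        assert scheme.split("Simple", 0.025) == "Simple-short"

    def test_externally_supplied_medians(self):
        from usvsyntax.labelers import JumpLabelScheme

        scheme = JumpLabelScheme(
            split_medians={"Simple": 0.0276, "Down": 0.0481, "Up": 0.0507, "Multiple": 0.0963},
            global_median=0.0353,
        )
        assert scheme.split("Down", 0.0480) == "Down-short"
        assert scheme.split("Up", 0.0510) == "Up-long"
        assert assign_unclassified(Syllable(0, 0.020), scheme) == "Simple"
        assert assign_unclassified(Syllable(0, 0.090), scheme) == "Multiple"
        # exactly the global median is not "shorter"
        assert assign_unclassified(Syllable(0, 0.0353), scheme) == "Multiple"

    def test_rejects_empty_base_class(self):
        corpus = self._corpus([0.02, 0.03], "Simple")
        with pytest.raises(ValueError, match="Up"):
            fit_duration_split(corpus)

    def test_split_halves_each_class(self, rng):
        t = 0.0
        syls = []
        for _ in range(101):
            d = float(rng.uniform(0.01, 0.1))
            jumps = int(rng.integers(0, 3))
            dirs = tuple(rng.choice(["up", "down"], size=jumps))
            syls.append(Syllable(t, t + d, jump_count=jumps, jump_directions=dirs))
            t += d + 0.02
        corpus = Corpus([SyllableSequence(syls)])
        labeled, scheme = label_by_jumps(corpus)
        assert labeled.alphabet.size == 8
        counts = {}
        for s in labeled.iter_syllables():
            counts[s.label] = counts.get(s.label, 0) + 1
        for base in ("Simple", "Up", "Down", "Multiple"):
            short = counts.get(f"{base}-short", 0)
            long_ = counts.get(f"{base}-long", 0)
            assert abs(short - long_) <= 1


class TestPreprocessSpectral:
    def _spec(self, n_frames=40, value=1.0):
        freqs = np.linspace(0, 125_000, 129)
        return np.full((129, n_frames), value), freqs

    def test_output_length_2016(self):
        spec, freqs = self._spec()
        vec = preprocess_spectral(spec, freqs)
        assert vec.shape == (2016,)
        assert vec.sum() == pytest.approx(1.0, abs=1e-12)

    def test_flat_spectrum_equal_channels(self):
        spec, freqs = self._spec()
        vec = preprocess_spectral(spec, freqs).reshape(16, 126)
        assert np.allclose(vec, vec[0, 0], atol=1e-9)

    def test_power_scale_invariance(self):
        spec, freqs = self._spec()
        a = preprocess_spectral(spec, freqs)
        b = preprocess_spectral(spec * 10.0, freqs)
        assert np.allclose(a, b, atol=1e-12)

    def test_rejects_single_frame(self):
        freqs = np.linspace(0, 125_000, 129)
        with pytest.raises(ValueError, match="frames"):
            preprocess_spectral(np.ones((129, 1)), freqs)

    def test_rejects_band_not_covered(self):
        freqs = np.linspace(0, 50_000, 64)
        with pytest.raises(ValueError, match="band"):
            preprocess_spectral(np.ones((64, 10)), freqs)


class TestTrainCentroids:
    def test_k_distinct_points_recovered(self, rng):
        points = np.eye(4) + 0.01
        cs = train_centroids(points, k=4, seed=0)
        sims = (points / np.linalg.norm(points, axis=1, keepdims=True)) @ (
            cs.centroids / np.linalg.norm(cs.centroids, axis=1, keepdims=True)
        ).T
        assert np.allclose(sims.max(axis=1), 1.0, atol=1e-9)

    def test_blob_purity_and_sklearn_cross_check(self, rng):
        from sklearn.cluster import KMeans
        from sklearn.metrics import adjusted_rand_score

        k, d, n = 5, 32, 600
        centers = rng.uniform(0.5, 2.0, size=(k, d)) * (1 + 4 * np.eye(k, d))
        truth = rng.integers(0, k, size=n)
        X = centers[truth] * rng.uniform(0.95, 1.05, size=(n, d))
        cs = train_centroids(X, k=k, seed=0)
        ours = cosine_assign(X, cs.centroids)
        # purity against ground truth
        purity = sum(
            np.bincount(truth[ours == j]).max() for j in range(k) if np.any(ours == j)
        ) / n
        assert purity > 0.95
        # independent oracle: Euclidean k-means on unit-normalized vectors
        Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
        ref = KMeans(n_clusters=k, n_init=10, random_state=0).fit_predict(Xn)
        assert adjusted_rand_score(ours, ref) > 0.95

    def test_seed_determinism(self, rng):
        X = rng.uniform(0.1, 1.0, size=(100, 8))
        a = train_centroids(X, k=3, seed=5)
        b = train_centroids(X, k=3, seed=5)
        assert np.array_equal(a.centroids, b.centroids)

    def test_rejects_too_few_distinct(self):
        X = np.ones((10, 4))
        with pytest.raises(ValueError, match="distinct"):
            train_centroids(X, k=2)


class TestAssignByCentroid:
    def _set(self):
        return CentroidSet(np.array([[1.0, 0.0], [0.0, 1.0]]), LabelAlphabet(("a", "b")))

    def test_centroid_maps_to_itself(self):
        assert assign_by_centroid(np.array([0.0, 1.0]), self._set()) == "b"

    def test_tie_goes_to_lowest_index(self):
        assert assign_by_centroid(np.array([1.0, 1.0]), self._set()) == "a"

    def test_scale_invariance(self):
        cs = self._set()
        assert assign_by_centroid(np.array([0.0, 2.0]), cs) == "b"
        assert assign_by_centroid(np.array([0.0, 0.001]), cs) == "b"

    def test_rejects_zero_norm(self):
        with pytest.raises(ValueError, match="zero-norm"):
            assign_by_centroid(np.zeros(2), self._set())

    def test_round_trip_on_training_points(self, rng):
        X = rng.uniform(0.1, 1.0, size=(60, 6))
        cs = train_centroids(X, k=3, seed=1)
        codes = cosine_assign(X, cs.centroids)
        labels = [assign_by_centroid(x, cs) for x in X]
        assert all(cs.alphabet.symbols[c] == lab for c, lab in zip(codes, labels))

    def test_serialization_round_trip(self, tmp_path):
        cs = CentroidSet(
            np.array([[1.0, 2.0], [3.0, 4.0]]),
            LabelAlphabet(("a", "b")),
            preprocessing=FilterbankConfig(),
        )
        path = tmp_path / "centroids.json"
        cs.save(path)
        clone = CentroidSet.load(path)
        assert np.allclose(clone.centroids, cs.centroids)
        assert clone.preprocessing.out_dim == 2016
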