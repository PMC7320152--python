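"""Syllable-labeling algorithms.

Two families are provided:

* a **pitch-jump / duration labeler**: syllables are first assigned one of
  four base labels from their frequency-jump features — Simple (no jump),
  Up (one upward jump), Down (one downward jump), Multiple (two or more
  jumps) — and each base class is then split at its median duration into
  -short / -long for eight labels in total.  Syllables without jump
  features fall back to Simple/Multiple by the global median duration.

* a **centroid labeler**: syllable spectrograms are reduced to a
  fixed-length filterbank representation (16 channels x 126 time-
  normalized frames = 2016 values, energy-normalized per syllable),
  centroids are learned by k-means under the cosine metric on a training
  subsample, and syllables are labeled by their nearest centroid in
  cosine distance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import Corpus, LabelAlphabet, Syllable, SyllableSequence

BASE_LABELS = ("Simple", "Up", "Down", "Multiple")


# ---------------------------------------------------------------------------
# pitch-jump / duration labeling
# ---------------------------------------------------------------------------

def jump_label(syllable: Syllable) -> str:
    """Base label from pitch-jump features: Simple / Up / Down / Multiple."""
    if syllable.jump_count is None:
        raise ValueError("syllable has no jump_count; cannot jump-label it")
    k = syllable.jump_count
    if k == 0:
        return "Simple"
    if k >= 2:
        return "Multiple"
    if not syllable.jump_directions:
        raise ValueError("single-jump syllable lacks jump_directions")
    return "Up" if syllable.jump_directions[0] == "up" else "Down"


@dataclass(frozen=True)
class JumpLabelScheme:
    """Duration-split thresholds for the eight-label jump scheme.

    ``split_medians`` maps each base label to its median duration
    (seconds); a syllable at or below the median becomes ``<base>-short``,
    above it ``<base>-long``.  ``global_median`` is the all-syllable
    median used to resolve syllables without jump features (shorter ->
    Simple, otherwise Multiple).
    """

    split_medians: Mapping[str, float]
    global_median: float

    @property
    def alphabet(self) -> LabelAlphabet:
        return LabelAlphabet(
            tuple(f"{base}-{half}" for base in BASE_LABELS for half in ("short", "long"))
        )

    def split(self, base: str, duration: float) -> str:
        median = self.split_medians[base]
        return f"{base}-{'short' if duration <= median else 'long'}"


def fit_duration_split(corpus: Corpus) -> JumpLabelScheme:
    """Fit per-base-label median durations on a base-labeled corpus."""
    durations: dict[str, list[float]] = {b: [] for b in BASE_LABELS}
    all_durations: list[float] = []
    for s in corpus.iter_syllables():
        all_durations.append(s.duration)
        if s.label in durations:
            durations[s.label].append(s.duration)
    for base, vals in durations.items():
        if not vals:
            raise ValueError(f"no syllables with base label {base!r}; cannot fit its median")
    return JumpLabelScheme(
        split_medians={b: float(np.median(v)) for b, v in durations.items()},
        global_median=float(np.median(all_durations)),
    )


def assign_unclassified(syllable: Syllable, scheme: JumpLabelScheme) -> str:
    """Base label for a syllable without jump features: Simple if shorter
    than the global median duration, else Multiple."""
    return "Simple" if syllable.duration < scheme.global_median else "Multiple"


def apply_jump_scheme(corpus: Corpus, scheme: JumpLabelScheme) -> Corpus:
    """Label every syllable with one of the eight jump/duration labels."""
    sequences = []
    for seq in corpus.sequences:
        syls = []
        for s in seq:
            base = jump_label(s) if s.jump_count is not None else assign_unclassified(s, scheme)
            syls.append(replace(s, label=scheme.split(base, s.duration)))
        sequences.append(SyllableSequence(syls))
    return Corpus(sequences=sequences, alphabet=scheme.alphabet, provenance=corpus.provenance)


def label_by_jumps(corpus: Corpus) -> tuple[Corpus, JumpLabelScheme]:
    """End-to-end jump labeling: base labels, median fit, eight-label split."""
    base_seqs = []
    for seq in corpus.sequences:
        syls = []
        for s in seq:
            base = jump_label(s) if s.jump_count is not None else None
            syls.append(replace(s, label=base))
        base_seqs.append(SyllableSequence(syls))
    base_corpus = Corpus(sequences=base_seqs, alphabet=LabelAlphabet(BASE_LABELS))
    scheme = fit_duration_split(base_corpus)
    return apply_jump_scheme(corpus, scheme), scheme


# ---------------------------------------------------------------------------
# filterbank preprocessing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterbankConfig:
    """Spectral preprocessing into a fixed-length feature vector.

    ``n_filters`` log-spaced triangular bandpass filters over ``band``
    approximate a gammatone-style auditory filterbank; per-filter energies
    are resampled to ``n_frames`` frames so every syllable, regardless of
    duration, maps to a vector of length ``out_dim = n_filters *
    n_frames`` with total energy 1.
    """

    n_filters: int = 16
    n_frames: int = 126
    band: tuple[float, float] = (25_000.0, 125_000.0)

    @property
    def out_dim(self) -> int:
        return self.n_filters * self.n_frames

    def to_json(self) -> dict:
        return {
            "n_filters": self.n_filters,
            "n_frames": self.n_frames,
            "band": list(self.band),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "FilterbankConfig":
        return cls(obj["n_filters"], obj["n_frames"], tuple(obj["band"]))


def _triangular_filterbank(freqs: np.ndarray, config: FilterbankConfig) -> np.ndarray:
    """(n_filters, n_freq) matrix of log-spaced triangular responses."""
    lo, hi = config.band
    edges = np.geomspace(lo, hi, config.n_filters + 2)
    fb = np.zeros((config.n_filters, freqs.size))
    for i in range(config.n_filters):
        left, center, right = edges[i], edges[i + 1], edges[i + 2]
        up = (freqs - left) / (center - left)
        down = (right - freqs) / (right - center)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
        total = fb[i].sum()
        if total > 0:
            fb[i] /= total  # unit-gain channels: flat spectra excite all equally
    return fb


def preprocess_spectral(
    spec_power: np.ndarray,
    freqs: np.ndarray,
    config: FilterbankConfig = FilterbankConfig(),
) -> np.ndarray:
    """Reduce one syllable's power spectrogram to the filterbank vector.

    ``spec_power`` is (n_freq, n_frames_in) non-negative power;
    ``freqs`` the frequency axis in Hz.  The output is scale invariant:
    multiplying the input power by a constant leaves it unchanged.
    """
    spec_power = np.asarray(spec_power, dtype=float)
    if spec_power.ndim != 2 or spec_power.size == 0:
        raise ValueError("spectrogram must be a non-empty 2-D array")
    if spec_power.shape[1] < 2:
        raise ValueError("syllable spectrogram must span at least 2 frames")
    freqs = np.asarray(freqs, dtype=float)
    if freqs[0] > config.band[0] or freqs[-1] < config.band[1]:
        raise ValueError(
            f"spectrogram frequency axis [{freqs[0]}, {freqs[-1]}] does not "
            f"cover the filterbank band {config.band}"
        )
    fb = _triangular_filterbank(freqs, config)
    channels = fb @ spec_power  # (n_filters, n_frames_in)
    t_in = np.linspace(0.0, 1.0, channels.shape[1])
    t_out = np.linspace(0.0, 1.0, config.n_frames)
    resampled = np.empty((config.n_filters, config.n_frames))
    for i in range(config.n_filters):
        resampled[i] = np.interp(t_out, t_in, channels[i])
    vec = resampled.reshape(-1)
    total = vec.sum()
    if total <= 0:
        raise ValueError("syllable has no energy in the filterbank band")
    return vec / total


# ---------------------------------------------------------------------------
# centroid labeling (cosine k-means)
# ---------------------------------------------------------------------------

@dataclass
class CentroidSet:
    """k labeled centroids assigned by minimum cosine distance."""

    centroids: np.ndarray  # (k, dim)
    alphabet: LabelAlphabet
    metric: str = "cosine"
    preprocessing: FilterbankConfig | None = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2:
            raise ValueError("centroids must be a (k, dim) array")
        if self.centroids.shape[0] != self.alphabet.size:
            raise ValueError("number of centroids must equal alphabet size")
        norms = np.linalg.norm(self.centroids, axis=1)
        if not np.all(np.isfinite(self.centroids)) or np.any(norms == 0):
            raise ValueError("centroids must be finite with non-zero norm")
        if self.metric != "cosine":
            raise ValueError("only the cosine metric is supported")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def to_json(self) -> dict:
        return {
            "schema": 1,
            "k": self.k,
            "metric": self.metric,
            "alphabet": list(self.alphabet.symbols),
            "preprocessing": self.preprocessing.to_json() if self.preprocessing else None,
            "centroids": self.centroids.tolist(),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "CentroidSet":
        return cls(
            centroids=np.asarray(obj["centroids"]),
            alphabet=LabelAlphabet(tuple(obj["alphabet"])),
            metric=obj.get("metric", "cosine"),
            preprocessing=FilterbankConfig.from_json(obj["preprocessing"])
            if obj.get("preprocessing")
            else None,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json()))

    @classmethod
    def load(cls, path: str | Path) -> "CentroidSet":
        return cls.from_json(json.loads(Path(path).read_text()))


def _unit_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm feature vector has no cosine direction")
    return X / norms


def cosine_assign(features: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Index of the nearest centroid in cosine distance for each row.

    Ties resolve to the lowest centroid index.  Cosine distance ignores
    vector magnitude, so assignments are scale invariant in the feature.
    """
    F = _unit_rows(np.atleast_2d(np.asarray(features, dtype=float)))
    C = _unit_rows(np.asarray(centroids, dtype=float))
    sims = F @ C.T
    return np.argmax(sims, axis=1)


def assign_by_centroid(feature: np.ndarray, centroid_set: CentroidSet) -> str:
    """Label of the centroid closest to ``feature`` in cosine distance."""
    idx = cosine_assign(np.atleast_2d(feature), centroid_set.centroids)[0]
    return centroid_set.alphabet.symbols[int(idx)]


def _spherical_kmeans_once(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 200
) -> tuple[np.ndarray, np.ndarray, float]:
    n = X.shape[0]
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    assign = np.full(n, -1)
    for _ in range(max_iter):
        sims = _unit_rows(X) @ _unit_rows(centroids).T
        new_assign = np.argmax(sims, axis=1)
        # reseed empty clusters from the worst-represented point
        for j in range(k):
            if not np.any(new_assign == j):
                worst = int(np.argmin(sims.max(axis=1)))
                centroids[j] = X[worst]
                new_assign[worst] = j
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            centroids[j] = X[assign == j].mean(axis=0)
    sims = _unit_rows(X) @ _unit_rows(centroids).T
    inertia = float(np.sum(1.0 - sims[np.arange(n), assign]))
    return centroids, assign, inertia


def train_centroids(
    features: np.ndarray,
    k: int = 8,
    n_train: int = 5000,
    seed: int | None = None,
    n_restarts: int = 10,
    preprocessing: FilterbankConfig | None = None,
    labels: Sequence[str] | None = None,
) -> CentroidSet:
    """k-means under the cosine metric on a training subsample.

    At most ``n_train`` feature vectors (sampled without replacement) are
    clustered; each centroid is the mean of its members and assignment
    minimizes cosine distance.  The best of ``n_restarts`` random
    initializations (by total cosine-distance inertia) is kept.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a (n, dim) array")
    distinct = np.unique(X, axis=0).shape[0]
    if distinct < k:
        raise ValueError(f"need at least k={k} distinct feature vectors, got {distinct}")
    rng = np.random.default_rng(seed)
    if X.shape[0] > n_train:
        X = X[rng.choice(X.shape[0], size=n_train, replace=False)]
    best = None
    for _ in range(n_restarts):
        centroids, _, inertia = _spherical_kmeans_once(X, k, rng)
        if best is None or inertia < best[1]:
            best = (centroids, inertia)
    symbols = tuple(labels) if labels is not None else tuple(f"C{i}" for i in range(k))
    return CentroidSet(
        centroids=best[0],
        alphabet=LabelAlphabet(symbols),
        preprocessing=preprocessing,
    )


def label_by_centroids(corpus: Corpus, centroid_set: CentroidSet) -> Corpus:
    """Label every syllable of a feature-bearing corpus by nearest centroid."""
    feats = []
    for s in corpus.iter_syllables():
        if s.features is None:
            raise ValueError("corpus syllables lack feature vectors")
        feats.append(s.features)
    idx = cosine_assign(np.asarray(feats), centroid_set.centroids)
    symbols = centroid_set.alphabet.symbols
    sequences = []
    pos = 0
    for seq in corpus.sequences:
        syls = []
        for s in seq:
            syls.append(replace(s, label=symbols[int(idx[pos])]))
            pos += 1
        sequences.append(SyllableSequence(syls))
    return Corpus(sequences=sequences, alphabet=centroid_set.alphabet, provenance=corpus.provenance)
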