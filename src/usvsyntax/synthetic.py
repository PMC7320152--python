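"""Synthetic corpora with known ground truth.

Every other module is exercised against data whose generating process is
fully specified here: Markov-structured label sequences, realistic timing
statistics (truncated-exponential syllable durations with a controlled
lag-1 correlation, bimodal ISIs, power-law sequence lengths),
cluster-structured feature vectors with multiplicative noise, and
synthetic chirp audio for the parser.

Timing defaults mirror the statistics of a large laboratory mouse USV
corpus: the normalized duration density 0.51*exp(-0.41 x) in 4 ms bin
units, the sequence-length pmf ~ 0.6*x^-1.88, ISI modes near 20 ms and
70 ms, and a lag-1 correlation of 0.44 between adjacent syllable
durations.  The duration marginal is realized exactly as the truncated
exponential x0 + Exp(0.41) in bin units with x0 = ln(0.51/0.41)/0.41,
the unique shifted exponential whose normalized density has the stated
(a, b).  The lag-1 correlation uses a mixing construction: with
probability rho a syllable copies its predecessor's duration, otherwise
it draws fresh — giving Pearson lag-1 correlation exactly rho while
preserving the marginal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus, LabelAlphabet, Syllable, SyllableSequence
from .ground_truth import MarkovGroundTruth, generate_sequences, power_law_length_sampler
from .labelers import CentroidSet

DURATION_A = 0.51          # normalized density a*exp(b*x), x in bin units
DURATION_B = -0.41
DURATION_BIN_MS = 4.0
LENGTH_A = 0.6             # pmf ~ a*x^b on the truncated integer support
LENGTH_B = -1.88
ISI_MODES = (0.020, 0.070)  # seconds
ISI_SDS = (0.008, 0.020)
ISI_WEIGHTS = (0.4, 0.6)
DURATION_LAG1_RHO = 0.44
SEQUENCE_GAP = 0.5         # silent seconds between generated sequences


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions."""

    markov_model: MarkovGroundTruth = field(
        default_factory=lambda: MarkovGroundTruth.sticky(8, 0.4)
    )
    length_params: tuple[float, float] = (LENGTH_A, LENGTH_B)
    duration_params: tuple[float, float] = (DURATION_A, DURATION_B)
    isi_modes: tuple[float, float] = ISI_MODES
    duration_lag1_corr: float = DURATION_LAG1_RHO
    feature_dim: int = 2016
    feature_noise: tuple[float, float] = (0.9, 1.1)
    bump_width: float = 20.0
    bump_spacing: float = 2.0
    bump_baseline: float = 0.01
    corruption: float | None = None
    seed: int | None = None


def sample_durations(
    n: int,
    rng: np.random.Generator,
    a: float = DURATION_A,
    b: float = DURATION_B,
    bin_ms: float = DURATION_BIN_MS,
) -> np.ndarray:
    """Durations (seconds) from the truncated exponential whose normalized
    density is a*exp(b*x) with x in ``bin_ms`` histogram-bin units."""
    rate = -b
    x0 = math.log(a / rate) / rate
    x = x0 + rng.exponential(1.0 / rate, size=n)
    return x * bin_ms / 1000.0


def sample_isis(n: int, rng: np.random.Generator, max_isi: float = 0.160) -> np.ndarray:
    """ISIs (seconds) from a two-mode truncated Gaussian mixture on
    (0, max_isi] — the bimodal gap structure of natural USV sequences."""
    out = np.empty(n)
    comp = rng.choice(2, size=n, p=ISI_WEIGHTS)
    remaining = np.arange(n)
    while remaining.size:
        c = comp[remaining]
        draw = rng.normal(np.take(ISI_MODES, c), np.take(ISI_SDS, c))
        ok = (draw > 0) & (draw <= max_isi)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def correlated_durations(
    lengths: Sequence[int],
    rng: np.random.Generator,
    rho: float = DURATION_LAG1_RHO,
    duration_params: tuple[float, float] = (DURATION_A, DURATION_B),
) -> list[np.ndarray]:
    """Per-sequence durations with lag-1 Pearson correlation ``rho``.

    With probability rho each syllable copies its predecessor's duration,
    otherwise it draws a fresh value from the marginal; the marginal is
    untouched and the lag-1 correlation equals rho in expectation.
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"lag-1 correlation must be in [0, 1), got {rho}")
    a, b = duration_params
    out = []
    for L in lengths:
        fresh = sample_durations(int(L), rng, a=a, b=b)
        copy = rng.random(int(L)) < rho
        copy[0] = False
        d = fresh.copy()
        for i in range(1, int(L)):
            if copy[i]:
                d[i] = d[i - 1]
        out.append(d)
    return out


def make_label_corpus(
    spec: SyntheticSpec,
    n_sequences: int,
    seed: int | None = None,
) -> Corpus:
    """Markov-labeled corpus with realistic duration/ISI statistics."""
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    a_len, b_len = spec.length_params
    sampler = power_law_length_sampler(b=b_len, min_length=max(1, spec.markov_model.depth + 1))
    skeleton = generate_sequences(
        spec.markov_model, n_sequences, sampler, seed=int(rng.integers(2**31))
    )
    lengths = [len(s) for s in skeleton.sequences]
    durations = correlated_durations(
        lengths, rng, rho=spec.duration_lag1_corr, duration_params=spec.duration_params
    )
    sequences = []
    t = 0.0
    for seq, durs in zip(skeleton.sequences, durations):
        isis = sample_isis(len(seq) - 1, rng)
        syls = []
        for i, s in enumerate(seq):
            jumps = int(rng.choice(3, p=[0.5, 0.3, 0.2]))
            dirs = tuple(rng.choice(["up", "down"], size=jumps))
            syls.append(
                Syllable(
                    start_time=t,
                    end_time=t + durs[i],
                    mean_frequency=float(rng.uniform(50_000, 90_000)),
                    jump_count=jumps,
                    jump_directions=dirs,
                    label=s.label,
                )
            )
            t += durs[i] + (isis[i] if i < len(seq) - 1 else 0.0)
        sequences.append(SyllableSequence(syls))
        t += SEQUENCE_GAP
    return Corpus(
        sequences=sequences,
        alphabet=spec.markov_model.alphabet,
        provenance="synthetic label corpus",
    )


@dataclass
class FeatureCorpusResult:
    """Feature-bearing corpus plus the centroids that generated it.

    ``corpus`` carries both the feature vectors and the hidden
    ground-truth labels; ``true_centroids`` generated the features;
    ``corrupted_centroids`` (if requested) is the degraded copy handed to
    the optimizer as a starting point.
    """

    corpus: Corpus
    true_centroids: CentroidSet
    corrupted_centroids: CentroidSet | None


def make_feature_corpus(
    spec: SyntheticSpec,
    n_sequences: int,
    seed: int | None = None,
) -> FeatureCorpusResult:
    """Cluster-structured features whose hidden labels follow the chain.

    Ground-truth centroids are overlapping Gaussian spectral bumps: the
    profile of cluster l is ``baseline + exp(-(i - p_l)^2 / (2 w^2))``
    over the feature index i, with bump centers ``p_l`` spaced
    ``spec.bump_spacing`` dimensions apart and width ``spec.bump_width``
    — syllable classes as slightly shifted spectral peaks, the shape of
    overlap that filterbank features of graded call types produce.  Each
    syllable's feature vector is its label's centroid times elementwise
    multiplicative noise uniform on ``spec.feature_noise``.  When
    ``spec.corruption`` = c is set, a corrupted centroid copy (true
    centroid times uniform noise on [1-c, 1+c]) is returned for recovery
    experiments; with the default geometry the corruption misassigns a
    fraction of syllables while the true centroids still classify
    near-perfectly.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    model = spec.markov_model
    k, d = model.n_labels, spec.feature_dim
    centers = d // 2 + spec.bump_spacing * (np.arange(k) - (k - 1) / 2.0)
    grid = np.arange(d)
    true_centroids = spec.bump_baseline + np.exp(
        -0.5 * ((grid[None, :] - centers[:, None]) / spec.bump_width) ** 2
    )
    base = make_label_corpus(spec, n_sequences, seed=int(rng.integers(2**31)))
    lo, hi = spec.feature_noise
    index = {s: i for i, s in enumerate(model.alphabet.symbols)}
    sequences = []
    for seq in base.sequences:
        syls = []
        for s in seq:
            noise = rng.uniform(lo, hi, size=d)
            s2 = Syllable(
                start_time=s.start_time,
                end_time=s.end_time,
                mean_frequency=s.mean_frequency,
                features=true_centroids[index[s.label]] * noise,
                label=s.label,
            )
            syls.append(s2)
        sequences.append(SyllableSequence(syls))
    corpus = Corpus(sequences=sequences, alphabet=model.alphabet,
                    provenance="synthetic feature corpus")
    true_set = CentroidSet(true_centroids, model.alphabet)
    corrupted = None
    if spec.corruption:
        c = spec.corruption
        corrupted = CentroidSet(
            true_centroids * rng.uniform(1 - c, 1 + c, size=(k, d)),
            model.alphabet,
        )
    return FeatureCorpusResult(corpus=corpus, true_centroids=true_set,
                               corrupted_centroids=corrupted)


def make_sim_recovery_fixture(
    n_sequences: int = 500,
    seed: int | None = None,
    p_stay: float = 0.6,
    corruption: float = 0.2,
) -> FeatureCorpusResult:
    """The centroid-recovery study conditions for the SIM optimizer.

    Eight clusters of 2016-dimensional spectral-bump features, hidden
    labels from a first-order repetition-biased chain (probability
    ``p_stay`` of repeating the previous label), and starting centroids
    corrupted by +/-``corruption`` multiplicative noise.  From the true
    centroids assignment is near-perfect; from the corrupted ones a
    fraction of syllables is mislabeled, which depresses the SIS and
    leaves headroom the optimizer can recover.
    """
    spec = SyntheticSpec(
        markov_model=MarkovGroundTruth.sticky(8, p_stay),
        corruption=corruption,
        seed=seed,
    )
    return make_feature_corpus(spec, n_sequences, seed=seed)


# ---------------------------------------------------------------------------
# synthetic audio
# ---------------------------------------------------------------------------

def make_audio_fixture(
    corpus: Corpus,
    fs: int = 250_000,
    seed: int | None = None,
    snr_db: float = 20.0,
    freq_range: tuple[float, float] = (40_000.0, 90_000.0),
    sweep_hz: float = 10_000.0,
    jump_hz: float = 30_000.0,
    amplitude: float = 0.5,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Synthesize chirp audio matching the corpus timing.

    Each syllable becomes a linear frequency-modulated tone starting at a
    random carrier in ``freq_range`` and sweeping ``sweep_hz``; syllables
    with ``jump_count`` set get instantaneous carrier steps of
    ``jump_hz`` (well above any jump-detection threshold).  Broadband
    Gaussian noise is added at ``snr_db`` relative to tone power.
    Returns the waveform and an exact ground-truth syllable table.
    """
    rng = np.random.default_rng(seed)
    syllables = [s for seq in corpus.sequences for s in seq]
    for i in range(1, len(syllables)):
        if syllables[i].start_time < syllables[i - 1].end_time:
            raise ValueError(f"overlapping syllables at positions {i - 1},{i}")
    end = syllables[-1].end_time if syllables else 0.1
    n = int(round((end + 0.05) * fs))
    wave = np.zeros(n)
    rows = []
    for s in syllables:
        i0, i1 = int(round(s.start_time * fs)), int(round(s.end_time * fs))
        m = i1 - i0
        if m < 8:
            continue
        t = np.arange(m) / fs
        f0 = rng.uniform(*freq_range)
        freq = f0 + sweep_hz * t / t[-1] * rng.choice([-1.0, 1.0])
        dirs = list(s.jump_directions or [])
        if s.jump_count:
            # place jumps at evenly spaced interior points
            pts = np.linspace(0, m, s.jump_count + 2).astype(int)[1:-1]
            step = np.zeros(m)
            for j, p in enumerate(pts):
                direction = dirs[j] if j < len(dirs) else ("up" if j % 2 == 0 else "down")
                step[p:] += jump_hz if direction == "up" else -jump_hz
            freq = np.clip(freq + step, 30_000.0, 110_000.0)
        phase = 2.0 * np.pi * np.cumsum(freq) / fs
        tone = amplitude * np.sin(phase)
        ramp = min(int(0.001 * fs), m // 4)
        if ramp > 0:
            env = np.ones(m)
            env[:ramp] = np.linspace(0, 1, ramp)
            env[-ramp:] = np.linspace(1, 0, ramp)
            tone *= env
        wave[i0:i1] += tone
        rows.append(
            {
                "start_s": s.start_time,
                "end_s": s.end_time,
                "mean_freq_hz": float(freq.mean()),
                "jump_count": int(s.jump_count or 0),
            }
        )
    tone_power = amplitude**2 / 2.0
    noise_sigma = math.sqrt(tone_power / 10 ** (snr_db / 10.0))
    wave += rng.normal(0.0, noise_sigma, size=n)
    return wave, pd.DataFrame(rows)
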