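"""Domain types for ultrasonic-vocalization (USV) corpora.

A *syllable* is one continuous stretch of ultrasonic power bounded by
silence; syllables separated by an inter-syllable interval (ISI) longer
than a threshold (160 ms by default) belong to different *sequences*.
Sequences are the unit over which syllable syntax is modeled.

This module also carries the descriptive-statistics battery used to
characterize a corpus before any labeling: adjacent-syllable correlations
and parametric fits (exponential / power law) of duration and
sequence-length distributions with Kolmogorov-Smirnov goodness checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

DEFAULT_ISI_THRESHOLD = 0.160  # seconds


@dataclass(frozen=True)
class LabelAlphabet:
    """Ordered set of distinct syllable labels; ``size`` is N_c."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be distinct")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def __contains__(self, label: str) -> bool:
        return label in self.symbols

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def index(self, label: str) -> int:
        return self.symbols.index(label)


@dataclass
class Syllable:
    """One USV with its timing, spectral summary and optional label.

    Times are in seconds.  ``features`` is an optional fixed-length
    non-negative vector (e.g. a filterbank representation) used by
    centroid-based labelers.
    """

    start_time: float
    end_time: float
    mean_frequency: float | None = None
    jump_count: int | None = None
    jump_directions: tuple[str, ...] | None = None
    features: np.ndarray | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.end_time > self.start_time:
            raise ValueError(
                f"syllable end_time ({self.end_time}) must exceed start_time "
                f"({self.start_time})"
            )
        if self.jump_count is not None and self.jump_count < 0:
            raise ValueError("jump_count must be non-negative")
        if self.jump_directions is not None:
            bad = set(self.jump_directions) - {"up", "down"}
            if bad:
                raise ValueError(f"jump directions must be 'up'/'down', got {bad}")
            if self.jump_count is not None and len(self.jump_directions) != self.jump_count:
                raise ValueError(
                    "jump_directions length must equal jump_count "
                    f"({len(self.jump_directions)} != {self.jump_count})"
                )
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=float)

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass
class SyllableSequence:
    """A time-ordered run of syllables with all internal ISIs below threshold."""

    syllables: list[Syllable]

    def __post_init__(self) -> None:
        _check_ordering(self.syllables)

    @property
    def isis(self) -> np.ndarray:
        """Silent gaps between consecutive syllables, seconds."""
        starts = np.array([s.start_time for s in self.syllables[1:]])
        ends = np.array([s.end_time for s in self.syllables[:-1]])
        return starts - ends

    def __len__(self) -> int:
        return len(self.syllables)

    def __iter__(self) -> Iterator[Syllable]:
        return iter(self.syllables)

    @property
    def labels(self) -> list[str | None]:
        return [s.label for s in self.syllables]


@dataclass
class Corpus:
    """A collection of syllable sequences with an optional label alphabet."""

    sequences: list[SyllableSequence]
    alphabet: LabelAlphabet | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.alphabet is not None:
            for seq in self.sequences:
                for s in seq:
                    if s.label is not None and s.label not in self.alphabet:
                        raise ValueError(
                            f"label {s.label!r} not in corpus alphabet"
                        )

    @property
    def n_syllables(self) -> int:
        return sum(len(seq) for seq in self.sequences)

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def iter_syllables(self) -> Iterator[Syllable]:
        for seq in self.sequences:
            yield from seq

    def label_sequences(self) -> list[list[str]]:
        """Label strings per sequence; raises if any syllable is unlabeled."""
        out = []
        for seq in self.sequences:
            labels = []
            for s in seq:
                if s.label is None:
                    raise ValueError("corpus contains unlabeled syllables")
                labels.append(s.label)
            out.append(labels)
        return out

    def infer_alphabet(self) -> LabelAlphabet:
        """Alphabet of labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.iter_syllables():
            if s.label is not None and s.label not in seen:
                seen[s.label] = None
        return LabelAlphabet(tuple(seen))


def _check_ordering(syllables: Sequence[Syllable]) -> None:
    for i in range(1, len(syllables)):
        prev, cur = syllables[i - 1], syllables[i]
        if cur.start_time < prev.start_time:
            raise ValueError(
                f"syllables not sorted by start_time at positions {i - 1},{i} "
                f"({prev.start_time} then {cur.start_time})"
            )
        if cur.start_time < prev.end_time:
            raise ValueError(
                f"overlapping syllables at positions {i - 1},{i} "
                f"(previous ends {prev.end_time}, next starts {cur.start_time})"
            )


def segment_into_sequences(
    syllables: Sequence[Syllable],
    isi_threshold: float = DEFAULT_ISI_THRESHOLD,
) -> list[SyllableSequence]:
    """Split a time-ordered syllable list into sequences at long ISIs.

    A gap *strictly greater* than ``isi_threshold`` ends the current
    sequence; a gap exactly equal to the threshold keeps it.  The
    concatenation of the output reproduces the input exactly.
    """
    syllables = list(syllables)
    if not syllables:
        return []
    _check_ordering(syllables)
    sequences: list[SyllableSequence] = []
    current = [syllables[0]]
    for s in syllables[1:]:
        isi = s.start_time - current[-1].end_time
        if isi > isi_threshold:
            sequences.append(SyllableSequence(current))
            current = [s]
        else:
            current.append(s)
    sequences.append(SyllableSequence(current))
    return sequences


def flatten(sequences: Iterable[SyllableSequence]) -> list[Syllable]:
    """Concatenate sequences back into a single syllable list."""
    return [s for seq in sequences for s in seq]


def relabel(corpus: Corpus, mapping: Mapping[str, str]) -> Corpus:
    """Merge or rename labels; the new alphabet is the image of ``mapping``.

    Used e.g. to collapse an eight-label scheme into jump (J) / no-jump (N)
    or into the five merged base classes.  Sequence structure and timing
    are untouched.
    """
    alphabet = corpus.alphabet or corpus.infer_alphabet()
    missing = [sym for sym in alphabet if sym not in mapping]
    if missing:
        raise ValueError(f"mapping does not cover label {missing[0]!r}")
    new_symbols: dict[str, None] = {}
    for sym in alphabet:
        new_symbols.setdefault(mapping[sym], None)
    new_sequences = []
    for seq in corpus.sequences:
        new_syl = []
        for s in seq:
            if s.label is not None and s.label not in mapping:
                raise ValueError(f"unmapped label {s.label!r}")
            new_syl.append(
                replace(s, label=None if s.label is None else mapping[s.label])
            )
        new_sequences.append(SyllableSequence(new_syl))
    return Corpus(
        sequences=new_sequences,
        alphabet=LabelAlphabet(tuple(new_symbols)),
        provenance=corpus.provenance,
    )


def adjacent_pair_correlation(
    corpus: Corpus, which: str = "duration"
) -> tuple[float, float, int]:
    """Pearson correlation between adjacent values within sequences.

    ``which`` is ``"duration"`` (consecutive syllable durations) or
    ``"isi"`` (consecutive inter-syllable intervals).  Pairs never span a
    sequence boundary.  Returns ``(r, p, n_pairs)``.
    """
    if which not in ("duration", "isi"):
        raise ValueError("which must be 'duration' or 'isi'")
    first, second = [], []
    for seq in corpus.sequences:
        if which == "duration":
            vals = [s.duration for s in seq]
        else:
            vals = list(seq.isis)
        first.extend(vals[:-1])
        second.extend(vals[1:])
    n_pairs = len(first)
    if n_pairs < 3:
        raise ValueError(
            f"need at least 3 adjacent pairs for a correlation, got {n_pairs}"
        )
    r, p = stats.pearsonr(first, second)
    return float(r), float(p), n_pairs


@dataclass(frozen=True)
class PdfFit:
    """Least-squares density fit with a resampled two-sample KS check.

    ``family`` is ``"exponential"`` (a*exp(b*x)) or ``"power"`` (a*x**b);
    ``x`` is measured in histogram-bin units so the parameters are on the
    same scale as binned-density fits reported for real corpora.
    """

    family: str
    a: float
    b: float
    ks_D: float
    ks_p: float
    bin_width: float = 1.0


def _sample_from_fit(
    fit_family: str, a: float, b: float, lo: float, hi: float,
    n: int, rng: np.random.Generator, discrete: bool = False,
) -> np.ndarray:
    """Draws from the fitted density truncated to the observed support."""
    if fit_family == "exponential":
        rate = -b
        # truncated exponential on [lo, hi]
        u = rng.random(n)
        cdf_hi = 1.0 - math.exp(-rate * (hi - lo))
        return lo - np.log1p(-u * cdf_hi) / rate
    if discrete:
        support = np.arange(max(1, int(round(lo))), int(round(hi)) + 1)
        pmf = support.astype(float) ** b
        pmf /= pmf.sum()
        return rng.choice(support, size=n, p=pmf).astype(float)
    grid = np.linspace(lo, hi, 4096)
    cdf = np.cumsum(a * grid ** b)
    cdf /= cdf[-1]
    u = rng.random(n)
    return grid[np.searchsorted(cdf, u)]


def fit_pdf_with_ks(
    values: np.ndarray,
    family: str,
    bin_width: float = 1.0,
    n_sample: int = 1000,
    reps: int = 1000,
    seed: int | None = None,
) -> PdfFit:
    """Fit a parametric density to binned data and score it by repeated KS.

    The empirical density is a unit-bin histogram of ``values / bin_width``
    (so for 4 ms duration bins, pass durations in ms and ``bin_width=4``).
    The family is fit by least squares on the bin centers.  The fit is then
    scored by drawing ``n_sample`` values from the data and ``n_sample``
    from the fitted density, running a two-sample Kolmogorov-Smirnov test,
    and averaging D and p over ``reps`` repetitions.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 100:
        raise ValueError(f"need at least 100 values to fit, got {values.size}")
    if family not in ("exponential", "power"):
        raise ValueError("family must be 'exponential' or 'power'")
    x = values / bin_width
    if family == "power" and np.any(x <= 0):
        raise ValueError("power-law fit requires strictly positive values")

    discrete = bool(np.allclose(x, np.round(x)))
    if discrete:
        # unit bins centered on the integers, so density == pmf at each value
        lo, hi = int(round(x.min())), int(round(x.max()))
        edges = np.arange(lo - 0.5, hi + 1.5)
    else:
        # unit bins anchored at the observed minimum: a distribution with a
        # lower support bound then fills its first bin completely
        n_bins = int(math.ceil(x.max() - x.min())) + 1
        edges = x.min() + np.arange(n_bins + 1)
    dens, _ = np.histogram(x, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = dens > 0
    centers, dens = centers[keep], dens[keep]

    if family == "exponential":
        def model(t, a, b):
            return a * np.exp(b * t)
        p0 = (dens[0], -0.5)
    else:
        def model(t, a, b):
            return a * t ** b
        p0 = (dens[0], -1.5)
    (a_fit, b_fit), _ = optimize.curve_fit(model, centers, dens, p0=p0, maxfev=20000)

    rng = np.random.default_rng(seed)
    ds = np.empty(reps)
    ps = np.empty(reps)
    for i in range(reps):
        emp = rng.choice(x, size=n_sample, replace=True)
        fit_draws = _sample_from_fit(
            family, a_fit, b_fit, x.min(), x.max(), n_sample, rng, discrete=discrete
        )
        res = stats.ks_2samp(emp, fit_draws)
        ds[i] = res.statistic
        ps[i] = res.pvalue
    return PdfFit(
        family=family,
        a=float(a_fit),
        b=float(b_fit),
        ks_D=float(ds.mean()),
        ks_p=float(ps.mean()),
        bin_width=bin_width,
    )
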