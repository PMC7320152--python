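"""Synthetic Markov chains with analytic entropy rate and SIS.

The plug-in estimators in :mod:`usvsyntax.markov` are validated against
chains whose information measures are known exactly.  A D-order chain over
N_c labels is specified by its conditional distributions
p(x_n | x_{n-1}, ..., x_{n-D}); it is equivalent to a 1st-order chain over
the N_c^D suffix states (a suffix state advances by dropping its oldest
label and appending the emitted one).  The stationary distribution mu is
the eigenvalue-1 eigenvector of that suffix-state transition matrix,
normalized to sum 1, and

    H = -sum_s mu_s sum_x p(x|s) log2 p(x|s)
    SIS = H(label marginal) - H

are the analytic entropy rate and syntax information score.  Realizations
are generated sequence by sequence, starting each sequence from the
stationary suffix distribution so that the generated ensemble is itself
stationary.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.sparse import csgraph, csr_matrix

from .corpus import Corpus, LabelAlphabet, Syllable, SyllableSequence
from .markov import SuffixTree, build_suffix_tree, entropy_rate, sis, validity_check

# power-law sequence-length defaults (pmf ~ x**b on a truncated range)
LENGTH_POWER_B = -1.88
LENGTH_MAX = 100


@dataclass
class MarkovGroundTruth:
    """A stationary, irreducible D-order Markov chain over syllable labels.

    ``cond`` holds the conditional next-label distributions as an
    (N_c^D, N_c) row-stochastic array; row order enumerates suffixes
    oldest-label-first in lexicographic order of the alphabet.
    """

    depth: int
    alphabet: LabelAlphabet
    cond: np.ndarray

    def __post_init__(self) -> None:
        n = self.alphabet.size
        self.cond = np.asarray(self.cond, dtype=float)
        expected = (n ** self.depth, n)
        if self.cond.shape != expected:
            raise ValueError(f"cond shape {self.cond.shape} != {expected}")
        if np.any(self.cond < 0):
            raise ValueError("conditional probabilities must be non-negative")
        if not np.allclose(self.cond.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each conditional distribution must sum to 1")

    # -- constructors --------------------------------------------------
    @classmethod
    def iid(cls, probs: Sequence[float], labels: Sequence[str] | None = None) -> "MarkovGroundTruth":
        """0-order chain: labels drawn independently from ``probs``."""
        probs = np.asarray(probs, dtype=float)
        labels = labels or [f"L{i}" for i in range(probs.size)]
        return cls(0, LabelAlphabet(tuple(labels)), probs.reshape(1, -1))

    @classmethod
    def from_transition(
        cls, P: np.ndarray, labels: Sequence[str] | None = None
    ) -> "MarkovGroundTruth":
        """1st-order chain from an N_c x N_c transition matrix."""
        P = np.asarray(P, dtype=float)
        labels = labels or [f"L{i}" for i in range(P.shape[0])]
        return cls(1, LabelAlphabet(tuple(labels)), P)

    @classmethod
    def sticky(
        cls, n_labels: int, p_stay: float, labels: Sequence[str] | None = None
    ) -> "MarkovGroundTruth":
        """1st-order chain that repeats its last label with probability
        ``p_stay`` and otherwise moves uniformly — a simple model of the
        syllable-repetition motifs that dominate real USV syntax."""
        off = (1.0 - p_stay) / (n_labels - 1)
        P = np.full((n_labels, n_labels), off)
        np.fill_diagonal(P, p_stay)
        return cls.from_transition(P, labels)

    @classmethod
    def from_cond_probs(
        cls,
        depth: int,
        alphabet: Sequence[str],
        cond_probs: Mapping[tuple[tuple[str, ...], str], float],
    ) -> "MarkovGroundTruth":
        alpha = LabelAlphabet(tuple(alphabet))
        n = alpha.size
        cond = np.zeros((n ** depth, n))
        suffixes = list(itertools.product(alpha.symbols, repeat=depth))
        row_of = {s: i for i, s in enumerate(suffixes)}
        col_of = {s: j for j, s in enumerate(alpha.symbols)}
        for (suf, sym), p in cond_probs.items():
            cond[row_of[tuple(suf)], col_of[sym]] = p
        return cls(depth, alpha, cond)

    # -- derived structure ---------------------------------------------
    @property
    def n_labels(self) -> int:
        return self.alphabet.size

    @property
    def n_states(self) -> int:
        return self.n_labels ** self.depth

    def suffix_states(self) -> list[tuple[str, ...]]:
        return list(itertools.product(self.alphabet.symbols, repeat=self.depth))

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic matrix over the N_c^D suffix states.

        From suffix (s_1..s_D), emitting x moves to (s_2..s_D, x) with
        probability p(x | s_1..s_D); this is the 1st-order representation
        of the D-order chain."""
        n, S = self.n_labels, self.n_states
        if self.depth == 0:
            return np.ones((1, 1))
        T = np.zeros((S, S))
        for s in range(S):
            tail = (s % (n ** (self.depth - 1))) * n if self.depth > 0 else 0
            for x in range(n):
                T[s, tail + x] += self.cond[s, x]
        return T

    def to_json(self) -> dict:
        return {
            "schema": 1,
            "depth": self.depth,
            "alphabet": list(self.alphabet.symbols),
            "cond_probs": {
                "|".join(suf) + "->" + sym: float(self.cond[i, j])
                for i, suf in enumerate(self.suffix_states())
                for j, sym in enumerate(self.alphabet.symbols)
                if self.cond[i, j] > 0
            },
        }

    @classmethod
    def from_json(cls, obj: dict) -> "MarkovGroundTruth":
        depth = int(obj["depth"])
        cond_probs = {}
        for key, p in obj["cond_probs"].items():
            suf_s, sym = key.split("->")
            suf = tuple(suf_s.split("|")) if depth > 0 else ()
            cond_probs[(suf, sym)] = p
        return cls.from_cond_probs(depth, obj["alphabet"], cond_probs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json()))

    @classmethod
    def load(cls, path: str | Path) -> "MarkovGroundTruth":
        return cls.from_json(json.loads(Path(path).read_text()))


def _assert_irreducible(T: np.ndarray) -> None:
    if T.shape[0] == 1:
        return
    graph = csr_matrix((T > 0).astype(np.int8))
    n_comp, _ = csgraph.connected_components(graph, directed=True, connection="strong")
    if n_comp != 1:
        raise ValueError(
            "chain is reducible: the positive-transition graph is not "
            "strongly connected, so no unique stationary distribution exists"
        )


def analytic_stationary(model: MarkovGroundTruth) -> np.ndarray:
    """Stationary distribution over suffix states.

    mu = e / sum(e) where e is the eigenvalue-1 left eigenvector of the
    suffix-state transition matrix; requires irreducibility.
    """
    T = model.transition_matrix()
    _assert_irreducible(T)
    if T.shape[0] == 1:
        return np.ones(1)
    vals, vecs = np.linalg.eig(T.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    if abs(vals[idx] - 1.0) > 1e-8:
        raise ValueError("no eigenvalue-1 eigenvector found")
    e = np.real(vecs[:, idx])
    e = np.abs(e)
    mu = e / e.sum()
    if not np.allclose(mu @ T, mu, atol=1e-9):
        raise ValueError("stationary check mu P == mu failed")
    return mu


def analytic_entropy_rate(model: MarkovGroundTruth) -> float:
    """Exact entropy rate -sum_s mu_s sum_x p(x|s) log2 p(x|s), bits/symbol."""
    if model.depth == 0:
        p = model.cond[0]
        nz = p > 0
        return float(-(p[nz] * np.log2(p[nz])).sum())
    mu = analytic_stationary(model)
    P = model.cond
    nz = P > 0
    plogp = np.zeros_like(P)
    plogp[nz] = P[nz] * np.log2(P[nz])
    return float(-(mu @ plogp.sum(axis=1)))


def label_marginal(model: MarkovGroundTruth) -> np.ndarray:
    """Stationary distribution of a single label, p(x)."""
    if model.depth == 0:
        return model.cond[0].copy()
    mu = analytic_stationary(model)
    return mu @ model.cond


def analytic_sis(model: MarkovGroundTruth) -> float:
    """Exact SIS: H(label marginal) minus the entropy rate; >= 0."""
    p = label_marginal(model)
    nz = p > 0
    h0 = float(-(p[nz] * np.log2(p[nz])).sum())
    return h0 - analytic_entropy_rate(model)


# ---------------------------------------------------------------------------
# realization generation
# ---------------------------------------------------------------------------

def power_law_length_sampler(
    b: float = LENGTH_POWER_B,
    min_length: int = 1,
    max_length: int = LENGTH_MAX,
) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Sampler of sequence lengths with pmf proportional to x**b on
    {min_length..max_length} (shorter sequences are more common)."""
    support = np.arange(min_length, max_length + 1)
    pmf = support.astype(float) ** b
    pmf /= pmf.sum()

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(support, size=n, p=pmf)

    return sample


def generate_sequences(
    model: MarkovGroundTruth,
    n_sequences: int,
    length_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int | None = None,
    syllable_duration: float = 0.030,
    isi: float = 0.050,
) -> Corpus:
    """Sample a labeled corpus from the chain.

    Each sequence is initialized from the stationary suffix distribution
    (its first D labels are one stationary suffix draw) and extended one
    label at a time from the conditional distributions.  Syllable timing
    is filled with fixed placeholder durations/ISIs; use the synthetic
    corpus generator for realistic timing statistics.
    """
    rng = np.random.default_rng(seed)
    if length_sampler is None:
        length_sampler = power_law_length_sampler(min_length=model.depth + 1)
    lengths = np.asarray(length_sampler(rng, n_sequences), dtype=int)
    if np.any(lengths < 1):
        raise ValueError("length_sampler must yield lengths >= 1")

    n, D = model.n_labels, model.depth
    if D == 0:
        mu_states = np.ones(1)
    else:
        mu_states = analytic_stationary(model)
    cond_cdf = np.cumsum(model.cond, axis=1)
    cond_cdf[:, -1] = 1.0  # guard against rounding
    tail_mod = n ** max(D - 1, 0)

    # initial suffix state per sequence
    states = rng.choice(mu_states.size, size=n_sequences, p=mu_states)
    labels = [np.empty(L, dtype=np.int64) for L in lengths]
    # unpack initial suffix labels (oldest first)
    for i, (st, L) in enumerate(zip(states, lengths)):
        suffix = []
        s = int(st)
        for _ in range(D):
            suffix.append(s % n)
            s //= n
        suffix.reverse()
        labels[i][: min(D, L)] = suffix[: min(D, L)]

    max_len = int(lengths.max()) if n_sequences else 0
    # advance all still-active sequences one position at a time
    for pos in range(D, max_len):
        active = np.nonzero(lengths > pos)[0]
        if active.size == 0:
            break
        st = states[active]
        u = rng.random(active.size)
        nxt = (cond_cdf[st] > u[:, None]).argmax(axis=1)
        for k, i in enumerate(active):
            labels[i][pos] = nxt[k]
        states[active] = (st % tail_mod) * n + nxt if D > 0 else 0

    symbols = model.alphabet.symbols
    sequences = []
    t = 0.0
    for codes in labels:
        syls = []
        for c in codes:
            syls.append(Syllable(start_time=t, end_time=t + syllable_duration, label=symbols[int(c)]))
            t += syllable_duration + isi
        sequences.append(SyllableSequence(syls))
        t += 0.5  # silent gap between sequences, beyond any ISI threshold
    return Corpus(sequences=sequences, alphabet=model.alphabet, provenance="synthetic Markov realization")


@dataclass(frozen=True)
class EstimationError:
    """Absolute plug-in estimation errors against the analytic values."""

    entropy_rate_error: float
    sis_error: float
    valid: bool
    n_syllables: int


def estimation_error(
    model: MarkovGroundTruth,
    n_syllables: int,
    depth: int | None = None,
    seed: int | None = None,
) -> EstimationError:
    """Generate ~n_syllables of realizations, re-estimate, and compare.

    The difference between the estimated and analytic entropy rate / SIS
    is the estimation error of the plug-in procedure at this data volume.
    ``valid`` flags whether the estimated tree passes the 10%-zeros
    criterion.
    """
    depth = model.depth if depth is None else depth
    if depth != model.depth:
        raise ValueError("estimation depth must equal the model depth")
    sampler = power_law_length_sampler(min_length=model.depth + 1)
    # mean sequence length fixes how many sequences we need
    support = np.arange(model.depth + 1, LENGTH_MAX + 1)
    pmf = support.astype(float) ** LENGTH_POWER_B
    pmf /= pmf.sum()
    mean_len = float((support * pmf).sum())
    n_seq = max(2, int(math.ceil(n_syllables / mean_len)))
    corpus = generate_sequences(model, n_seq, sampler, seed=seed)
    tree = build_suffix_tree(corpus, depth)
    h_err = abs(entropy_rate(tree) - analytic_entropy_rate(model))
    s_err = abs(sis(tree) - analytic_sis(model)) if depth >= 1 else 0.0
    return EstimationError(
        entropy_rate_error=float(h_err),
        sis_error=float(s_err),
        valid=validity_check(tree),
        n_syllables=corpus.n_syllables,
    )
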