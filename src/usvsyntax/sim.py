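"""Syntax Information Maximization (SIM).

SIM refines a set of cluster centroids so that the labeling they induce
carries more sequential structure, measured by the syntax information
score (SIS) of a depth-D suffix tree built from the relabeled training
sequences.  Each iteration draws one random vector V with entries uniform
on [0.9, 1.1] and perturbs every centroid in turn by the elementwise
product centroid * V; every candidate relabels the whole training set and
is scored.  The best candidate is applied if it beats the current SIS;
otherwise a failure counter increments, and after 5 consecutive failures
the best candidate is applied regardless (an escape from local optima).
After the training SIS converges, the recorded perturbation chain is
replayed on a held-out test set to check that the refined centroids
generalize.

The multiplicative (Hadamard) form of the perturbation keeps non-negative
features non-negative and is scale-free per feature dimension.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import Corpus, LabelAlphabet
from .labelers import CentroidSet, _unit_rows
from .markov import build_from_coded, sis

FAILURE_LIMIT = 5
PERTURBATION_RANGE = (0.9, 1.1)


@dataclass
class FeatureSet:
    """Features of one corpus flattened for fast relabeling.

    ``features`` is (n_syllables, dim); ``seq_lengths`` gives the number
    of syllables per sequence, in order, so any labeling of the rows can
    be split back into sequences.
    """

    features: np.ndarray
    seq_lengths: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.seq_lengths = np.asarray(self.seq_lengths, dtype=int)
        if self.seq_lengths.sum() != self.features.shape[0]:
            raise ValueError("sequence lengths do not sum to the number of rows")

    @classmethod
    def from_corpus(cls, corpus: Corpus) -> "FeatureSet":
        feats = []
        lengths = []
        for seq in corpus.sequences:
            lengths.append(len(seq))
            for s in seq:
                if s.features is None:
                    raise ValueError("corpus syllables lack feature vectors")
                feats.append(s.features)
        return cls(np.asarray(feats), np.asarray(lengths))

    def split_labels(self, codes: np.ndarray) -> list[np.ndarray]:
        return np.split(codes, np.cumsum(self.seq_lengths)[:-1])


def split_train_test(corpus: Corpus, seed: int | None = None) -> tuple[FeatureSet, FeatureSet]:
    """Shuffle sequences and split them 50/50 into training and test sets
    (odd counts give the extra sequence to training)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(corpus.n_sequences)
    n_train = (corpus.n_sequences + 1) // 2
    train_idx, test_idx = order[:n_train], order[n_train:]
    def subset(idx):
        return FeatureSet.from_corpus(
            Corpus([corpus.sequences[i] for i in idx], alphabet=corpus.alphabet)
        )
    return subset(train_idx), subset(test_idx)


@dataclass
class AppliedPerturbation:
    centroid_index: int
    vector: np.ndarray
    forced: bool
    sis_after: float


@dataclass
class SimState:
    """Full state of one SIM run (training loop plus test replay)."""

    centroids: np.ndarray  # current (k, dim)
    initial_centroids: np.ndarray
    alphabet: LabelAlphabet
    train: FeatureSet
    test: FeatureSet
    depth: int
    rng: np.random.Generator
    sis_train_history: list[float] = field(default_factory=list)
    sis_test_history: list[float] = field(default_factory=list)
    failure_counter: int = 0
    applied_perturbations: list[AppliedPerturbation] = field(default_factory=list)
    iterations: int = 0

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def current_sis(self) -> float:
        return self.sis_train_history[-1]


def init_state(
    corpus: Corpus,
    centroid_set: CentroidSet,
    depth: int = 1,
    seed: int | None = None,
) -> SimState:
    """Split the corpus, score the initial labeling, and set up the run."""
    if depth < 1:
        raise ValueError("SIS optimization requires depth >= 1")
    train, test = split_train_test(corpus, seed=seed)
    state = SimState(
        centroids=centroid_set.centroids.copy(),
        initial_centroids=centroid_set.centroids.copy(),
        alphabet=centroid_set.alphabet,
        train=train,
        test=test,
        depth=depth,
        rng=np.random.default_rng(seed),
    )
    state.sis_train_history.append(_labeling_sis(train, state.centroids, state.alphabet, depth))
    return state


def _labeling_sis(
    feats: FeatureSet, centroids: np.ndarray, alphabet: LabelAlphabet, depth: int
) -> float:
    codes = _assign_codes(feats.features, centroids)
    tree = build_from_coded(feats.split_labels(codes), alphabet, depth)
    value = sis(tree)
    if not math.isfinite(value):
        raise RuntimeError("non-finite SIS during optimization; labeling degenerate")
    return value


def _assign_codes(features: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    sims = _unit_rows(features) @ _unit_rows(centroids).T
    return np.argmax(sims, axis=1)


def perturbation_vector(dim: int, rng: np.random.Generator) -> np.ndarray:
    """One multiplicative perturbation: entries iid uniform on [0.9, 1.1]."""
    lo, hi = PERTURBATION_RANGE
    return rng.uniform(lo, hi, size=dim)


def evaluate_perturbation(
    state: SimState, centroid_index: int, V: np.ndarray
) -> tuple[float, np.ndarray]:
    """SIS change from multiplying one centroid by V; state is not mutated.

    The candidate centroid is the elementwise product ``centroid * V``;
    all training syllables are re-assigned against the candidate set and
    the training SIS recomputed.  Returns (delta_SIS, candidate labeling).
    """
    if V.shape != (state.centroids.shape[1],):
        raise ValueError(
            f"perturbation dimension {V.shape} does not match centroid "
            f"dimension ({state.centroids.shape[1]},)"
        )
    candidate = state.centroids.copy()
    candidate[centroid_index] = candidate[centroid_index] * V
    codes = _assign_codes(state.train.features, candidate)
    tree = build_from_coded(state.train.split_labels(codes), state.alphabet, state.depth)
    value = sis(tree)
    return value - state.current_sis, codes


def sim_step(state: SimState) -> SimState:
    """One SIM iteration: draw V, try it on every centroid, accept or fail.

    The same V perturbs each centroid in turn.  If the best candidate SIS
    beats the current SIS it is applied and the failure counter resets;
    otherwise the counter increments, and on reaching 5 the best candidate
    is applied anyway (forced) and the counter resets.
    """
    V = perturbation_vector(state.centroids.shape[1], state.rng)
    deltas = np.empty(state.k)
    for i in range(state.k):
        deltas[i], _ = evaluate_perturbation(state, i, V)
    best = int(np.argmax(deltas))
    state.iterations += 1
    if deltas[best] > 0:
        _apply(state, best, V, forced=False)
    else:
        state.failure_counter += 1
        if state.failure_counter >= FAILURE_LIMIT:
            _apply(state, best, V, forced=True)
    return state


def _apply(state: SimState, index: int, V: np.ndarray, forced: bool) -> None:
    state.centroids[index] = state.centroids[index] * V
    new_sis = _labeling_sis(state.train, state.centroids, state.alphabet, state.depth)
    state.sis_train_history.append(new_sis)
    state.applied_perturbations.append(
        AppliedPerturbation(centroid_index=index, vector=V.copy(), forced=forced, sis_after=new_sis)
    )
    state.failure_counter = 0


def replay_on_test(state: SimState) -> list[float]:
    """Apply the recorded perturbation chain to the test set.

    Starting from the initial centroids, each applied perturbation is
    replayed in order and the test-set SIS logged after each; index 0 is
    the initial test SIS.  The replay is deterministic."""
    centroids = state.initial_centroids.copy()
    history = [_labeling_sis(state.test, centroids, state.alphabet, state.depth)]
    for ap in state.applied_perturbations:
        centroids[ap.centroid_index] = centroids[ap.centroid_index] * ap.vector
        history.append(_labeling_sis(state.test, centroids, state.alphabet, state.depth))
    return history


def run_sim(
    state: SimState,
    max_iters: int = 500,
    tol: float = 1e-4,
    window: int = 20,
) -> SimState:
    """Run the training loop to convergence, then replay on the test set.

    Convergence: at least ``window`` perturbations have been applied and
    the best-so-far training SIS improved by no more than ``tol`` bits
    over the last ``window`` applied perturbations; or ``max_iters``
    iterations elapse.
    """
    while state.iterations < max_iters:
        sim_step(state)
        applied = len(state.applied_perturbations)
        if applied > window:
            hist = np.array(state.sis_train_history)
            best_now = hist.max()
            best_before = hist[: -window].max()
            if best_now - best_before <= tol:
                break
    state.sis_test_history = replay_on_test(state)
    return state


def save_run_log(state: SimState, path: str | Path, seed: int | None = None) -> None:
    """JSON artifact of a finished run (histories, perturbations, centroids)."""
    log = {
        "schema": 1,
        "seed": seed,
        "depth": state.depth,
        "iterations": state.iterations,
        "n_train_sequences": int(state.train.seq_lengths.size),
        "n_test_sequences": int(state.test.seq_lengths.size),
        "sis_train_history": state.sis_train_history,
        "sis_test_history": state.sis_test_history,
        "applied_perturbations": [
            {
                "centroid_index": ap.centroid_index,
                "forced": ap.forced,
                "sis_after": ap.sis_after,
                "vector": ap.vector.tolist(),
            }
            for ap in state.applied_perturbations
        ],
        "final_centroids": state.centroids.tolist(),
    }
    Path(path).write_text(json.dumps(log))
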