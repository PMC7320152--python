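"""Suffix-tree Markov models of labeled syllable sequences.

A depth-D suffix tree is the tabular form of a D-order Markov chain over
syllable labels: for every length-D label tuple (the *suffix*, the D most
recent labels) it stores how often that suffix occurred, and how often
each label followed it.  Counts are accumulated from (D+1)-windows that
lie entirely inside a single sequence; windows never span sequence
boundaries.

From these counts the module computes

* the plug-in **entropy rate** H = -sum_i mu_i sum_j P_ij log2 P_ij, the
  residual uncertainty (bits/symbol) about the next label given the
  suffix, where mu is the empirical suffix distribution and P the
  conditional next-label distribution;
* the **syntax information score (SIS)**, the mutual information between
  the next label and its suffix, I(X;Y) = sum p(x,y) log2 p(x,y)/(p(x)p(y)),
  computed on the (D+1)-tuple ensemble;
* per-tuple SIS contributions p(x,y) log2 p(x,y)/(p(x)p(y)), which sum to
  the SIS and expose over/under-represented motifs;
* a validity criterion (< 10% of potential (D+1)-tuples unobserved),
  resampled uncertainty, and the SIS normalized by log2(N_c).

Internally counts live in a dense (N_c^D, N_c) integer array, which keeps
scoring vectorizable; dict views keyed by label tuples are derived on
demand.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import Corpus, LabelAlphabet

DEFAULT_CELL_CAP = 2 ** 24
VALIDITY_MAX_ZERO_FRACTION = 0.10


@dataclass
class SuffixTree:
    """Depth-D Markov model: suffix counts and conditional next-label counts."""

    depth: int
    alphabet: LabelAlphabet
    counts: np.ndarray  # shape (N_c**depth, N_c), integer

    def __post_init__(self) -> None:
        n = self.alphabet.size
        expected = (n ** self.depth, n)
        if self.counts.shape != expected:
            raise ValueError(
                f"counts shape {self.counts.shape} != expected {expected}"
            )

    # -- derived views -------------------------------------------------
    @property
    def n_labels(self) -> int:
        return self.alphabet.size

    @property
    def total_tuples(self) -> int:
        return int(self.counts.sum())

    def suffix_tuples(self) -> list[tuple[str, ...]]:
        """All N_c^D suffixes, oldest label first, in row order."""
        return list(itertools.product(self.alphabet.symbols, repeat=self.depth))

    @property
    def suffix_counts(self) -> dict[tuple[str, ...], int]:
        rows = self.counts.sum(axis=1)
        return {
            suf: int(rows[i])
            for i, suf in enumerate(self.suffix_tuples())
            if rows[i] > 0
        }

    @property
    def cond_counts(self) -> dict[tuple[tuple[str, ...], str], int]:
        out = {}
        for i, suf in enumerate(self.suffix_tuples()):
            for j, sym in enumerate(self.alphabet.symbols):
                c = int(self.counts[i, j])
                if c > 0:
                    out[(suf, sym)] = c
        return out

    @staticmethod
    def display_suffix(suffix: tuple[str, ...]) -> str:
        """Suffix printed newest label first (read right-to-left in time)."""
        return "".join(reversed(suffix))

    # -- serialization -------------------------------------------------
    def to_json(self) -> dict:
        return {
            "schema": 1,
            "depth": self.depth,
            "alphabet": list(self.alphabet.symbols),
            "suffix_counts": {"|".join(k): v for k, v in self.suffix_counts.items()},
            "cond_counts": {
                "|".join(suf) + "->" + sym: v
                for (suf, sym), v in self.cond_counts.items()
            },
            "total_tuples": self.total_tuples,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "SuffixTree":
        alphabet = LabelAlphabet(tuple(obj["alphabet"]))
        depth = int(obj["depth"])
        tree = cls(depth, alphabet, np.zeros((alphabet.size ** depth, alphabet.size), dtype=np.int64))
        index = {s: i for i, s in enumerate(alphabet.symbols)}
        for key, v in obj["cond_counts"].items():
            suf_s, sym = key.split("->")
            suf = tuple(suf_s.split("|")) if depth > 0 else ()
            row = _suffix_row(tuple(index[t] for t in suf), alphabet.size)
            tree.counts[row, index[sym]] = v
        return tree

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json()))

    @classmethod
    def load(cls, path: str | Path) -> "SuffixTree":
        return cls.from_json(json.loads(Path(path).read_text()))


def _suffix_row(codes: tuple[int, ...], n_labels: int) -> int:
    row = 0
    for c in codes:
        row = row * n_labels + c
    return row


def _encode_sequences(
    corpus: Corpus, alphabet: LabelAlphabet
) -> list[np.ndarray]:
    index = {s: i for i, s in enumerate(alphabet.symbols)}
    coded = []
    for seq in corpus.sequences:
        codes = np.empty(len(seq), dtype=np.int64)
        for i, s in enumerate(seq):
            if s.label is None:
                raise ValueError("cannot build a suffix tree from unlabeled syllables")
            codes[i] = index[s.label]
        coded.append(codes)
    return coded


def build_from_coded(
    coded_sequences: Iterable[np.ndarray],
    alphabet: LabelAlphabet,
    depth: int,
    cell_cap: int = DEFAULT_CELL_CAP,
) -> SuffixTree:
    """Accumulate (depth+1)-window counts from integer-coded sequences.

    Fast path used by the SIM optimizer, which rebuilds trees thousands of
    times from candidate labelings.
    """
    n = alphabet.size
    if depth < 0:
        raise ValueError("depth must be non-negative")
    n_cells = n ** (depth + 1)
    if n_cells > cell_cap:
        raise ValueError(
            f"alphabet size {n} at depth {depth} needs {n_cells} cells "
            f"(> cap {cell_cap}); reduce the depth or the number of labels"
        )
    flat = np.zeros(n_cells, dtype=np.int64)
    powers = n ** np.arange(depth, -1, -1)
    for codes in coded_sequences:
        if len(codes) < depth + 1:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, depth + 1)
        cells = windows @ powers
        flat += np.bincount(cells, minlength=n_cells)
    return SuffixTree(depth, alphabet, flat.reshape(n ** depth, n))


def build_suffix_tree(
    corpus: Corpus, depth: int, cell_cap: int = DEFAULT_CELL_CAP
) -> SuffixTree:
    """Build the depth-D suffix tree of a fully labeled corpus."""
    alphabet = corpus.alphabet or corpus.infer_alphabet()
    coded = _encode_sequences(corpus, alphabet)
    return build_from_coded(coded, alphabet, depth, cell_cap=cell_cap)


# ---------------------------------------------------------------------------
# information measures (log base 2; 0 * log 0 := 0 throughout)
# ---------------------------------------------------------------------------

def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def entropy_rate(tree: SuffixTree) -> float:
    """Plug-in entropy rate H = -sum_i mu_i P_ij log2 P_ij, bits/symbol."""
    total = tree.total_tuples
    if total == 0:
        raise ValueError("empty suffix tree: no (D+1)-tuples observed")
    row_sums = tree.counts.sum(axis=1, keepdims=True)
    mu = row_sums[:, 0] / total
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(row_sums > 0, tree.counts / np.maximum(row_sums, 1), 0.0)
    h_rows = -_xlog2x(P).sum(axis=1)
    return float(np.dot(mu, h_rows))


def distribution_set(tree: SuffixTree, marginal_px: bool = True) -> dict[str, np.ndarray]:
    """The three pmfs used by the SIS: p(x,y), p(y), p(x).

    ``p_xy`` is the empirical (D+1)-tuple distribution (suffix rows by
    next-label columns); ``p_y`` and ``p_x`` are its marginals.  With
    ``marginal_px=False`` p(x) is instead the 0th-order label frequency
    over *all* syllables of the tuple ensemble's windows; the marginal
    form (default) uses one consistent ensemble and guarantees a
    non-negative mutual information.
    """
    total = tree.total_tuples
    if total == 0:
        raise ValueError("empty suffix tree")
    p_xy = tree.counts / total
    p_y = p_xy.sum(axis=1)
    p_x = p_xy.sum(axis=0)
    if not marginal_px:
        # suffix-position mass also counts toward the label frequencies
        p_all = p_x * 1.0
        if tree.depth > 0:
            suf_label_mass = np.zeros(tree.n_labels)
            n = tree.n_labels
            grid = p_y.reshape((n,) * tree.depth)
            for axis in range(tree.depth):
                marg = grid.sum(axis=tuple(a for a in range(tree.depth) if a != axis))
                suf_label_mass += marg
            p_all = (p_x + suf_label_mass) / (tree.depth + 1)
        p_x = p_all
    return {"p_xy": p_xy, "p_y": p_y, "p_x": p_x}


def sis(tree: SuffixTree, marginal_px: bool = True) -> float:
    """Syntax information score: MI between the next label and its suffix."""
    if tree.depth < 1:
        raise ValueError("SIS requires depth >= 1 (a non-empty suffix)")
    d = distribution_set(tree, marginal_px=marginal_px)
    p_xy, p_y, p_x = d["p_xy"], d["p_y"], d["p_x"]
    q = np.outer(p_y, p_x)
    nz = p_xy > 0
    return float(np.sum(p_xy[nz] * np.log2(p_xy[nz] / q[nz])))


def sis_contributions(
    tree: SuffixTree, marginal_px: bool = True
) -> dict[tuple[str, ...], float]:
    """Per-(D+1)-tuple contribution p(x,y) log2 p(x,y)/(p(x)p(y)) to the SIS.

    Keys are full (D+1)-tuples, suffix oldest-first then the next label.
    Contributions of unobserved tuples are 0 and omitted; the returned
    values sum to ``sis(tree)``.  Individual contributions can be negative
    (under-represented motifs).
    """
    if tree.depth < 1:
        raise ValueError("SIS contributions require depth >= 1")
    d = distribution_set(tree, marginal_px=marginal_px)
    p_xy, p_y, p_x = d["p_xy"], d["p_y"], d["p_x"]
    q = np.outer(p_y, p_x)
    suffixes = tree.suffix_tuples()
    out: dict[tuple[str, ...], float] = {}
    rows, cols = np.nonzero(p_xy)
    for i, j in zip(rows, cols):
        key = suffixes[i] + (tree.alphabet.symbols[j],)
        out[key] = float(p_xy[i, j] * np.log2(p_xy[i, j] / q[i, j]))
    return out


def validity_check(
    tree: SuffixTree, max_zero_fraction: float = VALIDITY_MAX_ZERO_FRACTION
) -> bool:
    """True iff fewer than ``max_zero_fraction`` of the N_c^(D+1) potential
    (D+1)-tuples are unobserved.

    Entropy-rate and SIS estimates from trees failing this criterion are
    unreliable (too many conditional probabilities are zero only for lack
    of data)."""
    zero_fraction = float(np.count_nonzero(tree.counts == 0)) / tree.counts.size
    return zero_fraction < max_zero_fraction


def normalized_sis(tree: SuffixTree) -> float:
    """SIS divided by log2(N_c): information gain per bit of label code."""
    if tree.n_labels < 2:
        raise ValueError("normalized SIS requires at least 2 labels")
    return sis(tree) / math.log2(tree.n_labels)


@dataclass(frozen=True)
class SyntaxScore:
    """Summary of a tree's predictability measures."""

    entropy_rate: float
    sis: float | None
    depth: int
    n_tuples: int
    valid: bool


def score(tree: SuffixTree) -> SyntaxScore:
    return SyntaxScore(
        entropy_rate=entropy_rate(tree),
        sis=sis(tree) if tree.depth >= 1 else None,
        depth=tree.depth,
        n_tuples=tree.total_tuples,
        valid=validity_check(tree),
    )


@dataclass(frozen=True)
class ResampledScores:
    mean_entropy_rate: float
    sd2_entropy_rate: float
    mean_sis: float
    sd2_sis: float
    reps: int
    frac: float


def resampled_scores(
    corpus: Corpus,
    depth: int,
    reps: int = 25,
    frac: float = 0.6,
    seed: int | None = None,
) -> ResampledScores:
    """Mean and 2 s.d. of entropy rate and SIS over sequence subsamples.

    Each repetition draws ``ceil(frac * n_sequences)`` sequences without
    replacement and rebuilds the suffix tree from that subset, giving a
    resampling estimate of the scores' uncertainty.
    """
    if not (0 < frac <= 1):
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    if corpus.n_sequences < 2:
        raise ValueError("resampling needs at least 2 sequences")
    alphabet = corpus.alphabet or corpus.infer_alphabet()
    coded = _encode_sequences(corpus, alphabet)
    rng = np.random.default_rng(seed)
    n_take = math.ceil(frac * len(coded))
    hs = np.empty(reps)
    ss = np.empty(reps)
    for r in range(reps):
        idx = rng.choice(len(coded), size=n_take, replace=False)
        tree = build_from_coded([coded[i] for i in idx], alphabet, depth)
        hs[r] = entropy_rate(tree)
        ss[r] = sis(tree) if depth >= 1 else np.nan
    return ResampledScores(
        mean_entropy_rate=float(hs.mean()),
        sd2_entropy_rate=float(2.0 * hs.std(ddof=0)),
        mean_sis=float(np.nanmean(ss)) if depth >= 1 else float("nan"),
        sd2_sis=float(2.0 * np.nanstd(ss, ddof=0)) if depth >= 1 else float("nan"),
        reps=reps,
        frac=frac,
    )


def entropy_rate_curve(corpus: Corpus, max_depth: int) -> list[float]:
    """Entropy rate at depths 0..max_depth (the depth-saturation curve)."""
    return [entropy_rate(build_suffix_tree(corpus, d)) for d in range(max_depth + 1)]
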