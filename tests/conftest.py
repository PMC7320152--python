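import numpy as np
import pytest

from usvsyntax.corpus import Corpus, LabelAlphabet, Syllable, SyllableSequence


def corpus_from_labels(label_sequences, alphabet=None, duration=0.03, gap=0.05):
    """Build a corpus with given label strings and synthetic timing."""
    t = 0.0
    sequences = []
    for labels in label_sequences:
        syls = []
        for lab in labels:
            syls.append(Syllable(start_time=t, end_time=t + duration, label=lab))
            t += duration + gap
        sequences.append(SyllableSequence(syls))
        t += 0.5
    if alphabet is None:
        seen = {}
        for labels in label_sequences:
            for lab in labels:
                seen.setdefault(lab, None)
        alphabet = LabelAlphabet(tuple(seen))
    return Corpus(sequences=sequences, alphabet=alphabet)


def syllables_with_gaps(gaps, duration=0.01):
    """Syllable list whose consecutive ISIs equal ``gaps``."""
    syls = [Syllable(0.0, duration)]
    t = duration
    for g in gaps:
        syls.append(Syllable(t + g, t + g + duration))
        t += g + duration
    return syls


@pytest.fixture
def two_state_chain():
    """The J/N repetition-biased chain: p(J|J)=0.64, p(N|N)=0.67."""
    from usvsyntax.ground_truth import MarkovGroundTruth

    return MarkovGroundTruth.from_transition(
        [[0.64, 0.36], [0.33, 0.67]], labels=["J", "N"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
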