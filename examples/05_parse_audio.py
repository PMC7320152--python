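"""Detect syllables in synthetic ultrasonic audio and label them by jumps.

Synthesizes chirp audio at 250 kHz with known syllable boundaries and
pitch jumps, runs the spectrogram parser, and applies the
jump/duration labeler to the detected syllables.
"""

import numpy as np

from usvsyntax.corpus import Corpus, Syllable, SyllableSequence, segment_into_sequences
from usvsyntax.labelers import label_by_jumps
from usvsyntax.parsing import ParserConfig, parse_wav
from usvsyntax.synthetic import make_audio_fixture

rng = np.random.default_rng(0)
syls, t = [], 0.1
for i in range(40):
    d = rng.uniform(0.02, 0.07)
    jumps = int(rng.integers(0, 3))
    dirs = tuple(rng.choice(["up", "down"], size=jumps))
    syls.append(Syllable(t, t + d, jump_count=jumps, jump_directions=dirs))
    t += d + rng.uniform(0.04, 0.3)
truth_corpus = Corpus([SyllableSequence(syls)])

wave, truth = make_audio_fixture(truth_corpus, seed=0, snr_db=20.0)
print(f"synthesized {len(truth)} syllables in {wave.size / 250_000:.2f} s of audio")

detected = parse_wav(wave, ParserConfig())
print(f"parser detected {len(detected)} syllables")

sequences = segment_into_sequences(detected, isi_threshold=0.160)
labeled, scheme = label_by_jumps(Corpus(sequences))
counts: dict[str, int] = {}
for s in labeled.iter_syllables():
    counts[s.label] = counts.get(s.label, 0) + 1
print("label distribution (base class x short/long at the class median):")
for lab in sorted(counts):
    print(f"  {lab:>15}: {counts[lab]}")
# Detection boundaries are accurate to about one STFT hop (0.5 ms);
# jump counts come from discontinuities > 20 kHz in the peak track.
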