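"""Segment a synthetic syllable stream and reproduce its timing statistics.

Builds a corpus with the package's default study conditions (exponential
durations, bimodal ISIs, power-law sequence lengths, correlated adjacent
durations), then recovers those parameters with the statistics battery.
"""

import numpy as np

from usvsyntax import MarkovGroundTruth, SyntheticSpec, adjacent_pair_correlation, fit_pdf_with_ks
from usvsyntax.synthetic import make_label_corpus

spec = SyntheticSpec(markov_model=MarkovGroundTruth.iid([0.5, 0.5]))
corpus = make_label_corpus(spec, 5000, seed=0)
print(f"corpus: {corpus.n_syllables} syllables in {corpus.n_sequences} sequences")

r, p, n = adjacent_pair_correlation(corpus, "duration")
print(f"lag-1 duration correlation r = {r:.3f} over {n} adjacent pairs (target 0.44)")

durations_ms = np.array([s.duration for s in corpus.iter_syllables()]) * 1000.0
fit = fit_pdf_with_ks(durations_ms, "exponential", bin_width=4.0, reps=200, seed=0)
print(
    f"duration density ~ {fit.a:.2f} * exp({fit.b:.2f} x) in 4 ms bins "
    f"(generator: 0.51 * exp(-0.41 x)); mean KS p = {fit.ks_p:.2f}"
)

lengths = np.array([len(s) for s in corpus.sequences], dtype=float)
fit_len = fit_pdf_with_ks(lengths, "power", reps=200, seed=0)
print(
    f"sequence-length pmf ~ {fit_len.a:.2f} * x^{fit_len.b:.2f} "
    f"(generator exponent -1.88)"
)
# A KS p-value above 0.05 means the fitted family is statistically
# indistinguishable from the data at the 1000-sample scale.
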