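"""Recover corrupted cluster centroids by syntax information maximization.

A synthetic corpus of 8 spectral clusters with first-order Markov syntax
is labeled from centroids corrupted by +/-20% multiplicative noise; SIM
perturbs the centroids, keeping changes that raise the training-set SIS,
and replays the accepted chain on a held-out test set.
"""

import numpy as np

from usvsyntax.labelers import cosine_assign
from usvsyntax.sim import init_state, run_sim
from usvsyntax.synthetic import make_sim_recovery_fixture

res = make_sim_recovery_fixture(n_sequences=500, seed=0)
feats = np.array([s.features for s in res.corpus.iter_syllables()])
hidden = np.array([res.corpus.alphabet.index(s.label) for s in res.corpus.iter_syllables()])

acc0 = (cosine_assign(feats, res.corrupted_centroids.centroids) == hidden).mean()
print(f"assignment accuracy from corrupted centroids: {acc0:.3f}")

state = init_state(res.corpus, res.corrupted_centroids, depth=1, seed=0)
run_sim(state, max_iters=200)

accF = (cosine_assign(feats, state.centroids) == hidden).mean()
print(
    f"train SIS: {state.sis_train_history[0]:.3f} -> {state.sis_train_history[-1]:.3f} bits "
    f"({len(state.applied_perturbations)} applied perturbations)"
)
print(f"test SIS:  {state.sis_test_history[0]:.3f} -> {state.sis_test_history[-1]:.3f} bits")
print(f"assignment accuracy after optimization: {accF:.3f}")
# The held-out SIS rises alongside the training SIS: the refined
# centroids capture more of the hidden syntax, not noise in the
# training split, and the labeling moves toward the ground truth.
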