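# Methods

## Sequence model

Labeled syllable sequences are modeled as stationary, irreducible
discrete Markov chains of order D over an alphabet of N_c labels.  The
chain is stored as a full depth-D suffix tree: for every length-D label
tuple (the *suffix*, the D most recent labels, stored oldest-first and
printed newest-first) it holds the count N(suffix) of windows ending in
that suffix and the counts N(x | suffix) of each following label.  Counts
are accumulated only from (D+1)-windows lying entirely inside one
sequence; windows never span the silent gaps that separate sequences,
because the inter-sequence interval carries no within-sequence syntax.
Sequences shorter than D+1 syllables contribute nothing at depth D.

All probabilities are plug-in (maximum-likelihood) estimates — counts
over totals — with no smoothing or bias correction.  Instead of
correcting, estimates are *gated*: a depth-D tree is considered valid
only if fewer than 10% of all N_c^(D+1) potential (D+1)-tuples are
unobserved.  Beyond that point the zero cells reflect missing data rather
than structure and both the entropy rate and the SIS are unreliable.

Logarithms are base 2 throughout and 0·log 0 := 0.

## Entropy rate and syntax information score

The entropy rate of the depth-D model is

    H_D = − Σ_i μ_i Σ_j P_ij log2 P_ij,

with μ the empirical suffix distribution and P_ij the conditional
next-label probabilities.  It is bounded by log2(N_c), with equality only
for uniform independent labels.

The syntax information score is the mutual information between the next
label X and its suffix Y on the empirical (D+1)-tuple ensemble:

    SIS = Σ_{x,y} p(x,y) log2 [ p(x,y) / (p(x) p(y)) ].

By default p(x) and p(y) are both taken as marginals of p(x,y) — one
consistent ensemble — which guarantees SIS ≥ 0 and the exact identity
SIS = H(p_x) − H_D on that ensemble.  A literal "0th-order p(x) over all
syllables" differs slightly at sequence boundaries (suffix-position
syllables are counted too); that variant is available behind the
`marginal_px=False` flag but is not the default precisely because it can
break non-negativity on short sequences.

Per-tuple contributions p(x,y) log2 p(x,y)/(p(x)p(y)) sum to the SIS
(within 1e-9 in the tests); positive terms are over-represented motifs,
negative terms under-represented ones.  Normalized SIS divides by
log2(N_c), the number of bits needed to encode one label, making scores
comparable across alphabet sizes.

Uncertainty is estimated by resampling: 25 repetitions, each rebuilding
the tree from a 60% sample of sequences drawn without replacement, with
the mean and 2 standard deviations reported.

## Analytic ground truth

A D-order chain is equivalent to a first-order chain over the N_c^D
suffix states (drop the oldest label, append the emitted one).  The
stationary distribution μ is the eigenvalue-1 eigenvector of that
transition matrix, normalized to sum to one; irreducibility is verified
as strong connectivity of the positive-transition graph, and μP = μ is
checked to 1e-9.  Entropy rate and SIS then have closed forms (the label
marginal is μ·P_cond), which serve as the oracle for estimator
validation: realizations are generated (each sequence initialized from
the stationary suffix distribution, so the ensemble itself is
stationary), a tree is re-estimated, and |estimated − analytic| is the
estimation error.  Errors shrink roughly as n^(−1/2); the acceptance
checks use a fixed 4-label chain at n = 10^3..10^5.

## Labelers

**Jump/duration labeling.**  Syllables with pitch-jump features map to
four base labels — Simple (0 jumps), Up (1 upward), Down (1 downward),
Multiple (≥ 2) — and each base class splits at its median duration into
-short/-long (eight labels).  A duration exactly at the median goes to
-short (tie rule; the choice is arbitrary but fixed).  Syllables without
jump features fall back to Simple when shorter than the global median
duration, else Multiple.  Externally supplied medians (e.g. 27.6 / 48.1 /
50.7 / 96.3 ms with a 35.3 ms global median, values fitted on a large
laboratory corpus) are accepted for compatibility runs.

**Centroid labeling.**  Syllable spectrograms pass through a bank of 16
log-spaced triangular filters over 25–125 kHz (unit-gain per channel);
channel energies are linearly resampled to 126 frames and flattened to a
length-2016 vector normalized to unit total energy, making the
representation invariant to recording gain and syllable duration.  The
triangular bank is a configurable stand-in for gammatone-style auditory
filterbanks — exact filter shapes matter little here because every
comparison is within one preprocessing.  Centroids come from k-means
under the cosine metric on up to 5000 training vectors (10 restarts,
empty clusters reseeded from the worst-represented point, centroid =
cluster mean); assignment minimizes cosine distance with ties to the
lowest index.

## Syntax information maximization

SIM splits the corpus 50/50 by sequences (training gets the odd one).
Each iteration draws one vector V with entries uniform on [0.9, 1.1] and
applies it elementwise to each centroid in turn — "multiplying the
centroid by V" is implemented as the Hadamard product, since a true inner
product would collapse the centroid to a scalar.  Every candidate
relabels the whole training set and is scored by the depth-D SIS; the
best candidate is applied if it beats the current score, otherwise a
failure counter increments, and at 5 consecutive failures the best
candidate is applied regardless (resetting the counter) — an escape from
local optima.  Convergence is declared when at least 20 perturbations
have been applied and the best-so-far training SIS improved ≤ 1e-4 bits
over the last 20 applied; the run also stops at `max_iters` (default
500; the bundled experiments use 200, which the fixture runs reach
well after their improvement plateaus).  The recorded chain is then
replayed on the test set, logging the held-out SIS after each applied
perturbation (index 0 = initial).  With the seed fixed the whole run,
including the replay, is bit-reproducible.

## Synthetic study conditions

The generators emulate the statistics of large laboratory USV corpora:

* **Durations** (ms): the truncated exponential x0 + Exp(0.41) in 4 ms
  bin units with x0 = ln(0.51/0.41)/0.41 — the unique shifted exponential
  whose normalized density is 0.51·e^(−0.41x).  Adjacent durations are
  correlated by a mixing construction: with probability ρ = 0.44 a
  syllable copies its predecessor's duration, else it draws fresh; this
  leaves the marginal untouched and gives lag-1 Pearson correlation
  exactly ρ in expectation.  All labels share one duration marginal (a
  per-label mixture would no longer be exponential and would break the
  recovery checks).
* **ISIs**: a two-component truncated Gaussian mixture with modes at
  20 ms (weight 0.4, sd 8 ms) and 70 ms (weight 0.6, sd 20 ms), resampled
  into (0, 160 ms] so segmentation at the 160 ms threshold reproduces the
  generated sequences exactly.  The mixture family is a modeling choice;
  only the bimodality and mode locations are empirically motivated.
* **Sequence lengths**: pmf ∝ x^(−1.88) on a truncated integer range
  (lower bound D+1 so every sequence contributes windows); the
  normalization constant on {1..100} is ≈ 0.60.
* **Feature corpora**: ground-truth centroids are overlapping Gaussian
  spectral bumps (baseline 0.01, width 20 dims, centers 2 dims apart in
  the 2016-dim feature space) — syllable classes as slightly shifted
  spectral peaks.  Features are the label's centroid times elementwise
  uniform noise on [0.9, 1.1].  This geometry was chosen so that the
  corruption experiment is informative: nearest-centroid assignment from
  the true centroids is essentially perfect, while ±20% multiplicative
  corruption of the centroids misassigns a 10–30% fraction.  Geometries
  with iid-random centroid entries are degenerate for this purpose — the
  energy spreads over thousands of equally-weighted dimensions, where
  either the corruption is harmless or every [0.9, 1.1] perturbation
  destroys a centroid outright, leaving the optimizer nothing to accept.
* **Hidden syntax**: a first-order repetition-biased chain (probability
  0.6 of repeating the previous label in the recovery fixture, uniform
  otherwise; analytic SIS ≈ 0.69 bits), mirroring the dominance of
  repetition motifs in real USV sequences.
* **Audio**: linear-FM chirps at the corpus timings, carriers in
  40–90 kHz, pitch jumps as instantaneous ≥ 25 kHz carrier steps, 1 ms
  amplitude ramps, white noise at a configurable SNR, 250 kHz sampling.

What passing these tests does *not* show: real syllables are not
multiplicative perturbations of eight fixed spectral templates, real
duration dependence is not a copy mixture, and real recordings contain
broadband cage noise, overlapping callers and amplitude variation the
chirp fixture omits.  The synthetic results validate the estimators and
the optimizer's mechanics, not any biological claim.

## Parser

The parser is a deliberately simple spectrogram thresholder (256-point
FFT, half-window hop, Hann window): the per-bin noise floor is the median
frame power over the file (robust because vocal activity is temporally
sparse), frames whose 25–110 kHz in-band power exceeds the floor by
10 dB are active, events closer than 10 ms merge, events shorter than
5 ms are dropped, and boundaries are reported at hop resolution
(≈ 0.5 ms at 250 kHz).  Mean frequency is the mean of the per-frame peak
frequency within the band; a pitch jump is a between-frame peak step
> 20 kHz, its direction the sign of the step.  Threshold, gaps and the
jump criterion are configuration, not claims — the defaults are set for
the synthetic fixtures and clean laboratory recordings, and detection is
amplitude-scale invariant by construction.

## Sizes, tolerances, numerical choices

* Probability cells are capped at 2^24 per tree (alphabet^depth guard).
* Validity threshold 0.10 (strict: exactly 10% zeros is invalid).
* Analytic checks: stationary residual ≤ 1e-9; oracle equivalence and
  entropy identities at 1e-12; contribution decomposition at 1e-9.
* Bundled experiment sizes: estimator validation at 10^3–10^5 syllables
  over 10 seeds; the SIM recovery fixture uses 500 sequences (≈ 4000
  syllables, ≈ 2000 per split) — large enough that depth-1 trees over 8
  labels pass validity while single runs complete in tens of seconds.
* The two-label worked example prints H(0.43, 0.57) = 0.9858 bits; coarser
  reports of ~0.98 for this distribution reflect rounding of the
  underlying percentages, and comparisons are made at ±0.01.

## Known limitations

* No entropy-estimator bias correction; scores near the validity
  boundary are biased downward (H) / upward (SIS) in the usual plug-in
  way.
* The SIS depth must be chosen a priori; the package computes
  depth curves but does not select an order automatically.
* The parser has no overlapping-caller separation and no per-animal
  adaptation; hierarchical or similarity-graph clusterers are out of
  scope.
* SIM optimizes a fixed k; it will not merge or split clusters except
  implicitly through assignment shifts.
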