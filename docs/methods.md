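# Methods

This note documents the models and procedures implemented in `phrasetag`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not establish.

## Paradigm arithmetic

Everything derives from two primitives: the 320 ms monosyllabic word and
the 52-word stream whose first 4 words are discarded as an onset
transient.  Hence streams last 16.64 s, the analysed epoch is
48 × 0.32 s = 15.36 s (15360 samples at 1 kHz), the DFT resolution is
1/15.36 ≈ 0.0651 Hz, and the two tag rates fall exactly on bins 24
(1.5625 Hz, two-word rate) and 48 (3.125 Hz, word rate).
`design.assert_tag_bins_on_grid()` guards this at configuration time;
frequencies are addressed internally by bin index so no floating-point
drift can push a request off-bin.

## Stream construction

*AN / AV.*  Cross-category pairs are retained when their embedding cosine
similarity lies in a window (default [0.75, 1]; a tunable band, not a
constant, since suitable values depend on the embedding set).  Streams are
chained greedily: after an initial seeded pair (A1, N1), each next word is
the unused candidate — restricted to words forming a retained pair with
the previous word — whose similarity to the previous word is closest to
the similarity of the preceding link.  Ties break to the lexicographically
smaller word form, making the chain a deterministic function of (pair set,
seed) and invariant to input ordering.  "No pair appears twice" is
strengthened to "no word form appears twice per stream" (a 52-word stream
from a 52-word pool).  Stuck chains restart from the next seeded initial
pair, default budget 100 attempts, then fail with per-constraint
diagnostics.

*MP.*  26 contiguous two-word phrases drawn from the six mixed-phrase
types (verb–noun, verb–adjective, adverb–adjective, determiner–noun,
preposition–noun, verb–adverb) by seeded rejection sampling, under two
constraints: adjacent phrases may not share a phrase type (the stricter of
the two readings of "no category repetition in adjacent phrases"), and the
category pair straddling each phrase boundary must not itself be a
grammatical phrase.  The boundary check uses the full phrase grammar
*including* adjective–noun — an adjective-final phrase followed by a
noun-initial one would create a spurious noun phrase — even though
adjective–noun is not itself a mixed-phrase construction type.

*RR.*  52 words sampled without replacement from adjectives, verbs,
prepositions and determiners (nouns excluded: they form phrases with too
many categories), such that no adjacent category bigram is in the phrase
grammar and, by default, no category repeats in adjacent positions.  The
simulator's random reference condition (SHUF) is a uniform shuffle of an
RR stream, which destroys exactly that residual structure.

## Fictive EEG

Component e of the simulated voltage during word i is
η·ξ_e(t) before the word's onset delay τ_i and w_e^i + η·ξ_e(t) after it,
with η = 0.5, τ_i drawn independently per word presentation, uniform on
integer milliseconds in [20, 60], and time discretised to 1 ms.  Points
the defining equation leaves open are resolved as follows:

* the noise-only branch applies to every word's pre-τ interval, not only
  the first word;
* ξ_e is one continuous unit-variance pink-noise stream per component per
  trial (no word-locked noise structure), independent across components;
* pink noise is generated by spectral shaping of white Gaussian noise with
  a 1/√f amplitude envelope, DC bin zeroed, then standardised to exactly
  zero mean and unit variance;
* onset delays are redrawn for every (participant, stream) presentation —
  a simulated participant is defined by its random 32-of-300 electrode
  subset and fresh noise, and is explicitly not a model of real
  between-participant variability;
* noise is generated only for the 32 selected components, which is
  mathematically identical to generating all 300 and subsetting because
  the noise is component-independent.

A useful exact identity: at the two-word bin of the untrimmed noise-free
signal, the DFT factorises as (alternating word-vector sum) × (a window
factor common to all components), so the component-summed DFT magnitude is
exactly proportional to the regularity statistic φ below.  This is the
module-level cross-check between the simulator and the φ statistic.

## ITPC and grouping

R = |Σ_k e^{iθ_k}|/K is implemented literally as the mean resultant
length (the label "square(d) mean resultant" found in some descriptions is
treated as a naming slip; the formula itself is unsquared).  The DFT uses
a rectangular window, no zero-padding and no detrending: the tag
frequencies are exactly bin-centred so leakage control is unnecessary, and
tapering would bias phase.  Per-participant grouping computes R over the
K = 24 streams of one condition per electrode, then averages over
electrodes; per-item grouping uses participants as trials.

For small-K locking-strength recovery the package also provides the
standard bias-corrected squared estimator (K·R² − 1)/(K − 1), whose
expectation is exactly the squared population mean resultant length; the
raw R is biased upward at small K (E[R] ≈ ½√(π/K) > 0 under uniform
phases), which makes raw-R comparisons against analytic locking values
meaningless near zero locking.

## Preprocessing

25 Hz sixth-order Butterworth low-pass applied forward and backward:
with order and cutoff fixed by the recording protocol, zero-phase
(bidirectional) application is chosen because the downstream measure is
phase coherence.  Common-average referencing commutes with the filter (both are
linear and channel-symmetric; asserted in tests), so their order is
immaterial.  The blink rule consumes an externally computed ICA component
topography and rejects it iff the mean squared weight over the four
frontal channels (Fp1, Fp2, F7, F8) strictly exceeds 10× the mean squared
weight over all other channels; "power" is defined as squared weight, and
the boundary ratio of exactly 10 keeps the component.  ICA itself and PCA
reduction are intentionally out of scope.

## Significance machinery

The random-phase null mimics the data pipeline: one replicate = the mean
over 32 "electrodes" of R over K = 24 uniform phases; 5000 replicates per
null.  The chance band drawn on per-participant figures uses the
fixed order-statistic rank convention — the 250th and
4750th sorted entries of 5000 — which is numerically a 5th/95th-percentile
pair (90% central coverage) even though it is conventionally labelled a
95% interval; calibration tests that need true 95% coverage use the
2.5%/97.5% quantiles instead.  Peak tests are one-sided Mann–Whitney U
(observed per-participant ITPCs vs the 5000 replicates; unpaired by
construction), asymptotic with tie correction.  Condition comparisons:
Kruskal–Wallis across conditions, pairwise Wilcoxon signed-rank with
configured sidedness, no multiplicity correction anywhere.  Behavioural
2×2 tables use the exact one-sided hypergeometric tail; reported p-values
round half-up to 3 decimals.

## Synthetic data

*Lexicon.*  One Gaussian cluster per grammatical category in 300
dimensions, centre norm 3 (per-component scale ≈ 0.17, comparable to real
distributional vectors against the η = 0.5 noise).  The designated pairs
(ADJ–NOUN, ADJ–VERB) have centre cosine 0.93 and content-cluster spread
0.35 (relative to centre norm), which places ~100% of cross-pair cosines
near 0.83, inside the [0.75, 1] retention window; the spread anneals
geometrically if a different target window demands it.  Function-word
categories (DET, PREP, ADV, PRON) get spread 1.2: real function words are
far more word-specific than content clusters, and this word-level
variation matters — with all categories equally tight the 300 simulation
components are nearly rank-4 for shuffled streams, electrode averaging
cannot self-average, and the shuffled condition's peak test degenerates to
a stream-set coin flip.  What the generator does not emulate: embedding
anisotropy, frequency effects, polysemy, and any fitted relationship to
recorded EEG.

*Locked EEG.*  Sinusoids at chosen DFT bins whose per-trial phase is von
Mises about a fixed phase, with concentration κ parameterised by a locking
strength s ∈ [0, 1] through s = I₁(κ)/I₀(κ) — so the strength *is* the
population mean resultant length and every injected bin has an exact
expected coherence.  Optional uniform onset jitter and per-channel pink
noise; the sinusoid is common to all channels (a single source), so
channel averaging does not shrink its phase variance.

## Problem sizes and determinism

The full simulated experiment runs at the design scale — 24 streams × 4
simulated conditions (AN, AV, MP, SHUF) × 20 participants, 32 electrodes
from 300 components, 5000 null replicates — in well under a minute on one
CPU; unit tests use reduced dimensions (40–60) for stream and container
checks.  Every stage seeds its RNG from a spawned child of one global
seed; a run is reproducible byte-for-byte from its config, whose hash is
echoed into every output file.

## Known limitations

* With a single stream set shared by all participants (as in the real
  design), per-participant ITPCs at untagged bins are correlated across
  participants; the Mann–Whitney peak test then partly reflects the
  particular stream draw rather than participant-level evidence, so the
  shuffled-condition "no peak" outcome retains stream-set-level
  variability across global seeds.  This is a property of the design, not
  of the implementation.
* The von Mises locking model and the category-cluster lexicon are test
  scaffolding with known ground truth, not fitted models of cortical
  dynamics or of real embedding geometry; passing tests establish
  correctness of the machinery, not claims about recorded EEG.
* φ is a stimulus-regularity diagnostic only; its condition ordering under
  the synthetic lexicon differs from what real distributional embeddings
  produce (function-word variance inflates the shuffled reference), and no
  claim is made that φ predicts human coherence values.
* The behavioural analysis consumes printed count tables; raw behavioural
  data handling is out of scope.
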