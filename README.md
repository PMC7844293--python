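# phrasetag

Frequency-tagged EEG analysis of two-word phrase processing.

When monosyllabic words are played isochronously (one word every 320 ms,
i.e. 3.125 Hz), any neural process that tracks a *two-word* linguistic unit
shows up as spectral phase coherence at half the word rate, 1.5625 Hz.
`phrasetag` implements the complete computational machinery of such a
study for four stream conditions:

* **AN** — strict adjective–noun alternation (grammatical phrases *and*
  category regularity: *cold food loud room …*),
* **AV** — strict adjective–verb alternation (category regularity, no
  grammatical phrases),
* **MP** — mixed grammatical two-word phrases with no category regularity,
* **RR** — random non-noun words with no phrases and (for the simulator's
  reference) a shuffled variant, **SHUF**.

The package is aimed at researchers who want to rebuild, test, or extend
the pipeline at desk scale: every input it needs — embedding lexicons and
multichannel EEG — can be generated synthetically with known ground truth.

## What it computes

**Inter-trial phase coherence.** For DFT phases θ_k of trials
k = 1…K at one frequency and channel,

    R = | Σ_k exp(i θ_k) | / K

(the mean resultant length; 1 = perfect phase locking, chance level
≈ ½√(π/K) for K random phases).  Epochs are low-pass filtered (25 Hz,
zero-phase Butterworth), common-average referenced, and trimmed to the
15.36 s analysed window, so the tag rates 1.5625 / 3.125 Hz sit exactly on
DFT bins 24 / 48 (resolution 1/15.36 ≈ 0.0651 Hz).  R is grouped per
participant × condition (trials = streams) or per item (trials =
participants) and averaged over electrodes.

**Fictive EEG.** A stream's simulated signal tiles each word's
300-dimensional embedding vector w over its 320 ms window, gated by a
per-word onset delay τ ~ U{20…60} ms, plus unit-variance pink noise
scaled by η = 0.5:

    v_e(t) = η ξ_e(t)          (t < τ, within each word window)
    v_e(t) = w_e + η ξ_e(t)    (t ≥ τ)

A simulated participant is a random subset of 32 "electrodes" from the
300 components with fresh noise.

**Significance.** Chance level comes from a Monte-Carlo null: each of
5000 replicates averages 32 single-electrode ITPCs of K = 24 uniform
phases; peaks are tested with a one-sided Mann–Whitney U against the
replicates.  Condition effects use Kruskal–Wallis and pairwise Wilcoxon
signed-rank tests (uncorrected); behavioural 2×2 phrase-vs-random
judgment tables use one-sided Fisher exact tests.

**Stream regularity.** The alternating-sign statistic
φ = Σ_e |Σ_i (−1)^i w_e^i| measures a stream's two-word regularity in
embedding space, reported per condition normalised to the shuffled
reference.

## Worked example

```python
import numpy as np
from phrasetag import (SyntheticLexiconSpec, generate_category_lexicon,
                       retain_similar_pairs, build_alternating_stream, Category,
                       fisher_exact_one_sided, round_p, simulate_null_itpc,
                       phi_statistic)

lexicon = generate_category_lexicon(SyntheticLexiconSpec(seed=0))
pairs = retain_similar_pairs(lexicon, Category.ADJ, Category.NOUN, lo=0.75, hi=1.0)
print(f"retained ADJ-NOUN pairs: {len(pairs)} of {30*30}")

stream = build_alternating_stream(pairs, seed=0, stream_id="AN00")
print("first six words:", " ".join(stream.forms[:6]))
print("phi(stream) =", round(phi_statistic(stream.vectors()), 2))

null = simulate_null_itpc(K=24, n_electrodes=32, n_rep=5000, seed=0)
lo, hi = null.confidence_interval(0.95)
print(f"null ITPC mean {null.mean():.4f}, chance band [{lo:.4f}, {hi:.4f}]")

p = round_p(fisher_exact_one_sided(np.array([[32, 1], [22, 6]])))
print("Fisher one-sided p (AN vs RR phrase judgments):", p)
```

prints

```
retained ADJ-NOUN pairs: 900 of 900
first six words: adj19 noun07 adj10 noun10 adj08 noun20
phi(stream) = 410.18
null ITPC mean 0.1808, chance band [0.1542, 0.2090]
Fisher one-sided p (AN vs RR phrase judgments): 0.031
```

The retained pairs are the similarity window [0.75, 1] used to chain
adjective–noun streams; the null mean sits at the ½√(π/24) ≈ 0.181 chance
level, and any electrode-averaged ITPC above the upper band is
significant at the 5% rank criterion.  The Fisher p-value tests whether
listeners judged an AN stream as "made of phrases" more often than an RR
stream.

The full simulated experiment (streams → fictive EEG → preprocessing →
ITPC → null → peak tests → φ) runs from one config:

```python
from phrasetag import RunConfig, run_simulated_experiment
report = run_simulated_experiment(RunConfig(seed=0))
print(report.significance)   # per-condition peak tests at bins 24 and 48
```

or from the shell: `phrasetag run --seed 0 --out results/`.  A CLI
subcommand exists for every stage (`build-streams`, `simulate`,
`preprocess`, `analyze`, `null`, `stats`, `phi`, `behavior`,
`synth-lexicon`); see `phrasetag --help`.

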