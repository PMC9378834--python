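# Methods

## The model

`mirpairs` builds rank-based single-sample classifiers in the
top-scoring-pairs family. The working assumption is biological coordination:
in non-diseased serum, the relative ordering of expression between most miRNA
pairs is stable across individuals, and malignancy perturbs a subset of those
orderings. Because a within-sample ordering E_a > E_b is invariant to any
strictly increasing transform of that sample's values, classifiers built on
orderings need no cross-sample normalisation, no batch correction and no
pre-calibrated score threshold — the properties that make a *single-sample*
classifier possible.

Formally, for an M × N expression matrix E and a pair (a, b), the stability
in a cohort is P(E_a > E_b) = m/N with m the number of samples where the
strict inequality holds. The pipeline is:

1. **Stable pairs.** All M(M−1)/2 unordered pairs are scanned; a pair whose
   majority orientation has m/N *strictly greater* than the stability
   threshold (default 0.95) is kept, stored in that orientation. An optional
   retention pass re-checks the stored orientation in a second control cohort
   at the same threshold and never flips it.
2. **Reversal testing.** For each retained pair the 2×2 table
   (n₁, n₂; m₁, m₂) of E_a > E_b vs E_a < E_b counts in controls and cases is
   tested with Fisher's exact test, one-sided toward case enrichment of the
   reversed ordering. In bulk the p-value is computed as the hypergeometric
   tail P(X ≥ n₁), which is identical to the one-sided Fisher probability and
   vectorises. BH step-up q-values are computed across all tested pairs;
   candidates need q < 0.05 and a reversal rate m₂/(m₁+m₂) ≥ 0.70.
3. **Panel search.** Each candidate acts as a pivot of a greedy set-cover
   growth: at every step the candidate adding the most newly covered case
   samples joins the combination (a sample is covered when at least one
   member pair is reversed in it), stopping at the first step with zero gain.
   Pairs are then ranked by occurrence frequency across all combinations, and
   every odd panel size n ≤ max_top (default 31) is evaluated on the training
   cohorts by majority-reversed voting; the selection criterion is
   √(PPV × NPV), with the smallest maximising n preferred.
4. **Voting.** A sample is labelled case when strictly more than half of the
   usable panel pairs show E_a < E_b. The vote fraction
   votes_reversed / n_usable serves as the continuous score for ROC/AUC
   evaluation.

## Parameters

| parameter | default | meaning |
|---|---|---|
| stability threshold | 0.95 | minimum ordering proportion (strict `>`) for a stable pair, both at mining and retention |
| q threshold | 0.05 | BH-FDR cutoff for significant reversal (strict `<`) |
| reversal threshold | 0.70 | minimum case reversal rate m₂/(m₁+m₂) (inclusive `≥`) |
| max_top | 31 | largest odd panel size scanned during selection |
| sidedness | one-sided | direction of the Fisher test; two-sided available |
| missing-miRNA mode | strict | permissive mode skips affected pairs and shrinks the usable panel |

## Numerical and convention choices

- **Ties.** Exact expression ties (rare on continuous platforms) count toward
  neither orientation anywhere: stability and contingency denominators treat
  them as excluded observations, and tied pairs abstain from voting. This is
  conservative against spurious stability and against spurious votes.
- **Threshold comparisons.** Stability is strict (`m/N > threshold`); the
  stability boundary case m/N = 0.95 is therefore *not* stable. The FDR
  filter is strict, the reversal-rate filter inclusive (`≥`), matching the
  defining inequality of each filter.
- **Fisher sidedness.** The diagnostic hypothesis is directional (orderings
  *reversed* in cancer), so the test is one-sided toward reversal by default;
  only reversal-direction pairs are usable downstream. Note that for a
  perfectly balanced table the one-sided p is the tail mass at or above the
  expectation (≈ 0.62 for (10,10,10,10)), not 1.
- **Coverage semantics.** Joint coverage of a combination is the union of
  per-pair reversal sets: the growth procedure "compensates" for the pivot's
  uncovered samples, and a stopping rule phrased as "no further increase" is
  only coherent if adding pairs can increase coverage. An intersection mode
  is available behind `grow_combination(..., mode="intersection")` for
  sensitivity analysis; under it growth never proceeds past the pivot.
- **Tie-breaking.** Every ranking and greedy choice breaks ties by smaller
  q-value, then higher reversal rate, then lexicographic pair ids. The whole
  search is consequently a pure function of its inputs; repeated runs are
  byte-identical, which the pipeline manifest exploits.
- **Half-votes.** With an odd, tie-free panel an exact half-vote is
  impossible. Where it can occur (ties, or a panel shrunk in permissive
  mode), the sample resolves to control, conservative toward non-cancer.
- **Undefined metrics.** A metric with a zero denominator is reported as NaN
  and named in `ClassificationMetrics.undefined`; during panel selection an
  undefined PPV/NPV maps the evaluation index to 0 with a warning rather
  than propagating NaN into the argmax.
- **AUC.** Computed as the Mann–Whitney rank statistic with midranks, exact
  under the heavy score ties that vote fractions produce; trapezoidal ROC
  integration is deliberately not used.
- **Memory.** Pair mining accumulates an M × M strict-greater count matrix in
  sample blocks (bounded boolean workspace), so cohorts of thousands of
  samples with ~2,500 miRNAs (~3·10⁶ pairs) are feasible on one CPU without
  per-pair sample lists.

## Synthetic data generator

`SimConfig`/`generate_cohorts` emulate exactly the regime the method assumes.
Each miRNA receives a baseline on the log2 scale, consecutive baselines
separated by `baseline_spread`; per-sample log-normal noise with SD
`noise_sd` is added, and values are exponentiated to a positive expression
scale. Defaults are `baseline_spread = 0.5` and `noise_sd = 0.05` — a gap of
ten noise SDs, so neighbouring orderings are stable to ~1 in 10¹² per sample
and ordering violations are dominated by the explicit flip mechanisms below.
The feasibility check `baseline_spread ≥ 4√2·noise_sd` rejects configs where
noise alone would erode stability.

Orderings are perturbed by swapping the two realized values of a pair within
a sample, which flips that pair's ordering while preserving the marginal
value distribution (planted pairs are not detectable from mean expression):

- **Planted reversals.** `n_planted` pairs, drawn miRNA-disjoint *and
  adjacent in baseline rank*, are swapped in a Bernoulli(`reversal_rate_cases`)
  subset of case samples. Adjacency matters: swapping two rank-adjacent
  miRNAs changes no ordering involving a third miRNA, so the planted truth is
  exactly the set of perturbed pairs and recovery checks ("panel ⊆ planted")
  are well-posed. Swapping distant miRNAs would reverse every interleaved
  pair as a side effect.
- **Background flips.** Every non-planted adjacent disjoint pair is swapped
  with probability `background_flip_rate` per sample in *both* cohorts, and
  planted pairs undergo the same background flipping in controls. This
  models the low rate of ordering violations real control cohorts show and
  keeps planted pairs statistically unexceptional in controls.

Default cohort conditions (200 miRNAs, 200 controls, 100 cases, 20 planted
pairs, case reversal rate 0.9, background flip rate 0.02) are the recovery
benchmark used throughout the test suite. A consequence worth noting: a
planted pair's control stability is Binomial(N, 0.98)/N, so with 200 controls
a planted pair occasionally lands at or below the strict 0.95 mining
threshold (~1% per pair). Recovery tests therefore exercise the significance
and reversal filters on a pair pool guaranteed to include the planted truth,
while the knife-edge mining boundary has its own dedicated test.

What the generator does **not** emulate: platform-specific intensity
distributions, batch effects, correlated noise between miRNAs, multi-site
drift, or class imbalance at the published scale (2,000 controls vs 200
cases). Passing recovery tests therefore demonstrate correctness of the
algorithmics under the method's own assumptions, not expected field
performance on clinical serum profiles.

## Problem sizes

The test suite and examples run at desk scale by design: oracle-equivalence
checks use ≤ 15 miRNAs × ≤ 30 samples against exhaustive double-loop oracles;
recovery runs use the 200-miRNA benchmark (≈ 20,000 pairs), which completes
in about a second. The implementation itself is written for the full scale of
a ~2,500-miRNA, ~5,000-sample reference cohort via the blocked counting
kernel and vectorised contingency/hypergeometric paths.

## Known limitations

- The published 13-pair and 17-pair panels are bundled as classifier
  definitions; reproducing their *derivation* requires the original cohorts
  from GEO and the (unpublished) random training split, so only their
  application is covered by tests.
- The ROC score behind the published 17-pair AUC values is not specified in
  the source; the vote fraction is used as the canonical score for voting
  panels and is documented as a declared choice.
- How the published work fixed the ranked-list cutoff of 31 pairs is not
  stated; `max_top` is exposed as a free parameter defaulting to 31.
- The coefficients of one published comparator model (an 8-miRNA ovarian
  panel) are not printed in the source and it is therefore not implemented.
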