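# Methods

## Model

`boolinfer` treats a genetic network as a set of signed pairwise Boolean
relations. Expression profiles T = {T₀, …, Tₙ} are binarised to
DT = {DT₀, …, DTₙ}; a relation regulator → target holds under *activation*
when DT_target[t+1] = DT_reg[t] and under *inhibition* when
DT_target[t+1] = 1 − DT_reg[t]. The Boolean function space is deliberately
the single-regulator pair {identity, negation} with a fixed one-step delay:
it is the minimal model under the hypothesis that a target's expression
follows its regulator's with a certain delay, it makes the inference
exactly identifiable on in-degree-≤1 ground truth, and it keeps the
pairwise consistency interpretable as a fraction of explained transitions.
The delay is exposed as an integer (default 1) for sensitivity analysis.
Multi-regulator Boolean tables, probabilistic Boolean networks and
attractor analysis are out of scope.

Assumptions: expression is measured on a log2 scale at ordered timepoints;
regulation acts at the transcriptional level (self-regulation and
post-transcriptional feedback are excluded, which is also why enzymatic
genes can be barred as regulators wholesale); and one transition step of
the series corresponds to one regulatory delay.

## Binarisation panel

Five families, 24 varieties. All thresholds are strict: a value exactly at
the threshold encodes 0. The prose definitions ("greater than the mean
were encoded to 1") fix this choice; values exactly at a threshold are
measure-zero on real data, so the choice matters only for synthetic
two-level inputs.

* mean, mid-range: one variety each; invariant under translation and
  positive scaling of a profile.
* sign of log₂-ratio: one variety; positive → 1; restricted to
  log-ratio data (a positivity threshold is meaningless for intensities),
  hence the 23-variety panel for intensity datasets.
* max − x%·max: nine varieties, x = 10…90 step 10. The formula is applied
  literally even when max ≤ 0 (with a warning) since it is intended for
  positive-scale data.
* T₀/mean ± x·SD hysteresis: twelve varieties (three initial-state anchors
  × x ∈ {0, 0.1, 0.3, 0.5}). Values above mean + x·SD encode 1, below
  mean − x·SD encode 0, inside the band the previous state carries
  forward. The anchor sets DT₀: `min_t0` → 0, `max_t0` → 1, `mean_t0` →
  (T₀ > mean). SD is the population SD (÷n); a `sd_mode="sample"` switch
  provides the n−1 convention. With x = 0 and the mean anchor the rule
  reduces to the mean rule except at exact-tie positions, where the carry
  branch (not 0) applies.

The `max_t0` anchor forces DT₀ = 1 regardless of the data, so a strictly
increasing profile binarises to 1,0,…,1 rather than a single switch; this
is inherent to a forced-high anchor and the property tests exempt
position 0 accordingly.

## Function assignment and stringency

For each ordered non-self pair both candidate signs are scored by
consistency = (matching transitions)/(total transitions); the two scores
sum to 1 exactly. The better sign is assigned iff its consistency reaches
stringency/100 — compared in integer arithmetic (matches·100 ≥
percent·total) to avoid float threshold artifacts — and the signs are not
tied. Stringency s corresponds to a conflicted allowance of 100 − s
percent; 100 means zero conflicting transitions. A tie (possible only at
s ≤ 50) assigns nothing: emitting both signs is never meaningful for a
single pair. Edges whose regulator (over the transition window) or target
(over the predicted window) is constant are assigned but flagged
`degenerate`, because a constant series is explained trivially; downstream
steps can drop them (`--drop-degenerate`).

Constraints are applied by skipping barred pairs before assignment —
observationally identical to post-hoc deletion but cheaper, and it matches
the semantics of "not allowed to be a parental node". Constraint genes
absent from the data raise an error rather than silently constraining
nothing.

## Evaluation

The unit of evaluation is the ordered signed pair over the k-gene
universe, self-pairs excluded, so the five confusion cells always total
k(k−1). A predicted edge whose pair is in the reference with the opposite
sign counts once as FP-wrong (its reference edge is not additionally FN);
a predicted pair absent from the reference is FP-unidentified — kept as a
separate class because such predictions may be real regulation the
reference lacks. TP requires sign agreement by default; `ignore_sign`
relaxes to pair-level matching. Indexes with zero denominators are
reported as null, never coerced to 0 or 1.

## Master network

The N per-variety solutions are merged per signed edge (pair + sign, so a
pair can legitimately carry both signs as two entries with separate
support); consistency = support/N. Two filter conventions exist in
practice — an absolute support count (≥ 4 of 24) and a strict fraction
(> 20%, i.e. ≥ 5 of 23) — and they disagree at the margin (4/24 ≈ 16.7%),
so the interface requires the caller to pick exactly one (`min_count` xor
`min_fraction [strict]`). Both shipped protocol presets record their
convention. GraphML export carries consistency/support/sign as typed edge
attributes (consistency drives edge thickness in Cytoscape).

## Synthetic benchmark

The generator emulates the short oscillatory microarray series the method
targets. Defaults: 14 genes and 12 timepoints (the circadian-style test
set size), amplitude 1.39 log2 units (mid-range of the 1.25–3.11 spanned
by the real datasets the protocol was studied on), noise SD 0.25 (a
moderate fraction of the two-level separation), 60% of genes regulated,
activation/inhibition balanced, 30% of genes enzymatic (out-degree 0,
mirroring 4 of 14). Topology, dynamics and noise draw from sub-seeds
derived from one integer seed.

Emission is two-level (baseline ± amplitude/2 + Gaussian noise) rather
than sinusoidal: it makes the dataset amplitude equal the configured
amplitude for non-constant profiles and keeps every binarisation rule
analysable. What passing tests therefore show is correctness of the
inference machinery under its own generative model — they do not show
robustness to probe effects, normalisation artifacts, unequal sampling
intervals, multi-regulator logic or continuous-valued dynamics, none of
which the generator emulates.

The returned constraint set contains only true non-relations (the
enzymatic genes, plus a seeded sample of non-edges with non-enzymatic
sources, `n_specific` defaulting to the gene count), which guarantees the
constraint-benefit comparison is fair: true positives cannot be removed,
so precision and specificity are non-decreasing on every seed.

## Numerical choices and degenerate inputs

* Consistency fractions are float divisions of small-integer counts; the
  activation/inhibition complementarity m/d + (d−m)/d = 1.0 was verified
  exhaustively in double precision for all denominators used.
* Threshold comparisons in function assignment are exact integer
  arithmetic (see above).
* Noise-free amplitude recovery is checked at relative tolerance 1e-12:
  averaging k identical peak-to-trough distances in float64 is not
  bit-exact for arbitrary amplitudes (the sum k·a can need more than 53
  bits), so equality is asserted up to pure round-off.
* Constant profiles binarise validly under every rule (all-0 under mean /
  mid-range / max−x%; anchor-then-carry under hysteresis). Empty
  matrices, p < 2, duplicate or unknown gene ids, missing values (unless
  `drop_incomplete_rows`), malformed constraint or reference lines all
  raise informative errors.
* Problem sizes in the test and acceptance runs — e.g. 10 genes × 12
  timepoints × 20 seeds for recovery, 100 seeds at 6 × 8 for
  monotonicity, 50 randomised oracle comparisons at k ≤ 5, p ≤ 8 —
  were chosen as the smallest sizes at which each property is
  non-trivially exercised (every seed contributing planted edges,
  all three stringency levels reachable).

## Known limitations

* The single-regulator model cannot represent combinatorial regulation; a
  gene regulated by two parents is mis-specified by construction (the
  simulator rejects it rather than guessing a rule).
* Consistency is undefined information-theoretically when the regulator is
  constant; such edges are only flagged, not suppressed, since inflated
  false positives from degenerate profiles are themselves a finding the
  evaluation is meant to expose.
* The shipped galactose/clock reference networks are curator stand-ins
  (`*_synthetic.tsv`) for graphically published schemes; evaluations
  against them characterise the pipeline, not the literature networks.
* Real-data reproduction depends on external normalisation software and
  its versions; the package consumes normalised matrices only.
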