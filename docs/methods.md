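# Methods

This note documents the model implemented by `crowdcbr`, the choices
made where the method description left the design open, and what the
synthetic data generator does and does not emulate.

## Crowd knowledge from hit counts

The knowledge base starts from a frequency table: for each candidate
feature word *x*, its standalone hit count ζ(x) and its co-occurrence
count ζ(x ⊗ c_k) with each degree-qualified class term c_k ("normal
depression", "serious depression", ...). The association strength is
the Jaccard-style ratio

    α(x, c_k) = ζ(x ⊗ c_k) / (ζ(x) + ζ(c_k) − ζ(x ⊗ c_k)).

Hit counts returned by search engines do not obey set semantics: a
co-occurrence count can exceed a single-word count (the shipped
co-occurrence table contains several such rows). Counts are therefore
accepted as given, only non-negativity is enforced, and the ratio is
clipped into [0, 1]. A non-positive union denominator is a degenerate
input and raises.

**Directions.** Each feature carries a direction β ∈ {−1, +1}: +1 if
the feature rises with the class concept, −1 if it falls (well-being
vs. depression). When labelled cases exist, β is the sign of the
Pearson correlation between the feature and the binary class
indicator; otherwise it comes from configuration, defaulting to +1
(every word in the shipped table describes a burden or symptom).
A widely-circulated alternative convention multiplies positive
associations by 2 and negative ones by 1 instead of signing them; it
is available as `beta_convention="literal"` but not the default,
because only the signed form lets negatively-directed features reduce
an aggregate score.

**Concept aggregation.** A concept (severity level) may own several
degree-adverb variants; its per-feature strength is the
hit-count-weighted signed mean Σ β ζ_k α_k / Σ ζ_k over those
variants, which collapses to β·α when each concept has a single count
column (the shipped table's case). The sum runs over all K variants in
numerator and denominator, keeping the statistic a bounded weighted
mean.

**Feature partition.** Feature f joins J_con when its strength
magnitude for con is at least `margin` times its magnitude for every
other concept. `margin` defaults to 1 (argmax); margins above 1 leave
ambiguous features unassigned. Exact ties go to the more severe
concept — the partition exists to collect minority evidence, so
ambiguity should not silently drop a potential minority marker.
The published association-level table's own emphasis markings do not
follow any single ratio rule (two words contradict every candidate);
the packaged fixture records the printed emphasis verbatim and the
tests assert only the property stated in prose — the eleven
severe-level words all land in the severe set under argmax.

**Class-term counts.** The standalone hit counts of the
degree-qualified class terms are required inputs: they were never
published for the reference data, so the packaged concept
configuration (`depression_concepts_synthetic.json`) carries synthetic
stand-ins of plausible magnitude (2.0M / 8.0M), chosen large enough to
keep every union denominator positive against the shipped
co-occurrence counts. Knowledge bases built from them are structurally
faithful but numerically illustrative.

## Crowd reasoner

Both votes operate on the severe concept's member set J_SC restricted
to 7-point-scale items; nominal codes and open numeric covariates
(age, weight) have no scale extreme and are excluded even when the
partition assigns them to the severe concept.

* **Subjective average.** Score(r) = Σ_f |α_f|·v'_f / Σ_f |α_f| where
  v' = (v − 1)/6 for β ≥ 0 and 1 − (v − 1)/6 for β < 0. The vote is
  *minor* iff Score(r) strictly exceeds the mean score over the
  reference case base (the full training base, not class-conditional).
  The strict inequality keeps a record exactly at the reference in the
  majority class — the majority is the default under imbalance.
* **Absolute maximum.** *Minor* iff at least `m_min` (default 1) J_SC
  features sit at the scale extreme: v ≥ `tau` (default 6, the
  abnormality cut-off of the labelling rule) for positive direction,
  mirrored (v ≤ 8 − tau) for negative. The threshold is global with a
  per-feature override possible through the profile's strengths; the
  method description does not say whether the "specific range" is
  per-feature, and a single tau is the smaller assumption.
* The crowd decision is the OR of the two votes; if one vote is not
  computable the other decides, and only if both are impossible does
  the crowd reasoner abstain.

## CBR reasoner

The case base stores labelled records with per-feature (min, max)
normalization learned from the stored cases only. Similarity between
normalized vectors is 1 − (W_num·E + W_nom·H)/(W_num + W_nom), with E
the weighted Euclidean distance over numeric components scaled to
[0, 1] and H the weighted Hamming mismatch fraction over nominal
codes; weights default to 1 (an optional bridge weights features by
|α| from the knowledge base, off by default). k defaults to 3;
retrieval ties break deterministically by record id; label ties in the
k-vote go to the minority class. There is no revise step: reusing a
binary label needs no adaptation. The retain step returns a new case
base (optionally refitting normalization) and never mutates the old
one.

Both k-NN voting and similarity are deliberately implemented in the
package (vectorized with numpy) rather than delegated, so that the
tie-break, the mixed metric and the retain semantics are exactly as
specified; scikit-learn appears only as an independent oracle in the
test suite.

## Hybrid rule and its guarantee

decision = minor iff crowd vote = minor **or** CBR vote = minor. Two
structural consequences are asserted as theorems in the tests: the
hybrid's minority true-positive set contains each component's, and
dually its majority false-positive set contains each component's. If
the crowd reasoner abstains (empty severe profile), classification
degrades to CBR alone with a logged warning — batch classification is
total whenever the case base is non-empty.

## Evaluation conventions

The minority (abnormal/"serious") class is ROC-positive. Reports
carry: per-class TP rate, FP rate, precision, recall (each class in
turn treated as positive); "overall" rows as prevalence-weighted
means; "overall norm" rows as unweighted macro means; overall accuracy
in percent. Rounding is half-up — 3 decimals for rates, 4 decimals of
percent for accuracy — applied only at the reporting edge; the
underlying statistics stay unrounded. Undefined metrics (zero
denominators) are NaN sentinels, logged, and serialized as JSON null,
never silent zeros.

PPV/NPV are emitted in two labelled variants because both occur in the
comparison literature for this method: textbook (TP/(TP+FP),
TN/(TN+FN)) and per-class-recall (minority TP rate / majority TP
rate). The package takes no position on which is "the" definition.

AUC uses the trapezoid rule Σ TPR_i·ΔFPR + ½·ΔTPR·ΔFPR. Discrete
classifiers get the single-operating-point curve (0,0)–(FPR,TPR)–(1,1),
whose AUC equals (1 + TPR − FPR)/2; the score-emitting crowd reasoner
gets a full descending-threshold sweep with ties grouped. Constant
scores yield the degenerate two-point diagonal (AUC 0.5).

## Synthetic data generator

The generator emulates the survey's structure: every column drawn
independently from its empirical marginal in the packaged 100-record
sample (so synthetic marginals resemble printed data without external
input), minority membership assigned to round(n/(ratio+1)) records,
a planted shift of `effect_delta` Likert points (clipped at 7) on the
designated minority features, and a target item drawn from {6, 7} for
minority and from the ≤ 5 part of the empirical marginal for majority
records. Label noise flips class membership for the target draw only,
leaving features at the true class's pattern. A companion hit-count
table plants co-occurrence mass so the severe-level association
strictly dominates for exactly the planted features (and the reverse
for all others), making knowledge-base recovery checkable against
ground truth.

Defaults are the study conditions of the reference data: n = 334,
ratio 10.7:1 (the stress task's imbalance; 16.9:1, the depression
task's, is exercised in tests), delta = 3, noise = 0.05. What the
generator does **not** model: inter-feature correlation beyond the
planted class effect, ordinal response styles (acquiescence, central
tendency), or any dependence between the demographic covariates and
the class. Passing recovery tests therefore show the pipeline is
correct and minority-sensitive under known ground truth — not that it
attains any particular accuracy on real survey populations.

## Problem sizes and determinism

The recovery experiment runs 20 seeds at n = 1000 and 10:1 imbalance
with a 70/30 split — large enough for stable recall averages, small
enough that the whole suite runs in seconds. All randomness flows
through explicit `numpy.random.default_rng(seed)` streams; there is no
global RNG state, and every test and the acceptance script are
deterministic given their seeds.

## Known limitations

* Live mining (web crawling, SNS APIs, synonym discovery, sentiment
  analysis for direction) is out of scope; hit-count tables are file
  inputs.
* Only the binary normal/abnormal task is exercised; the concept
  machinery accepts more than two severity levels but multi-class
  voting is not implemented.
* Missing survey values are rejected, not imputed.
* The subjective-average vote flags roughly half of a homogeneous
  population by construction (scores above the mean); combined with
  the OR rule this buys minority recall at a substantial majority
  false-positive cost, which is intended behaviour, not a defect.
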