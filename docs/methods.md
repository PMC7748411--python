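# Methods

## The problem

A combination-treatment experiment measures a response (here: log2 gene
expression) under four conditions: vehicle control (0), stimulus X alone,
stimulus Y alone, and the combination X+Y. The scientific question is which
genes show *interactions* — departures of the combination from what the two
single-stimulus effects predict — and of what kind: an effect that exists
only in the combination (emergence), an amplified (potentiation) or reduced
(inhibition) single-agent effect, complete cancellation (suppression of an
induction, restoration of a repression), saturation at the strongest
single-agent level (ceiling/floor), or a reversal of direction. A binary
synergy/antagonism call conflates these biologically distinct situations;
this package classifies each gene onto a complete qualitative taxonomy
instead.

## The taxonomy

Write `e0, eX, eY, eXY` for the four condition means and
`eAdd = eX + eY - e0` for the additive prediction (the Bliss independence
reference on the log scale). A profile is the weak order (ordered set
partition) of the five values `(e0, eX, eY, eXY, eAdd)`. Because `eAdd` is
an affine function of the other values, not every weak order is realizable:
of the 541 weak orders on five elements, exactly 123 admit a strictly
feasible solution, verified by linear programming. These 123 cells
partition the space of mean vectors, so every finite vector matches exactly
one profile. The rank of `eXY` relative to `eAdd` is the interaction
(Bliss) sign of the profile: above = synergistic, below = antagonistic,
tied = additive.

Each profile is stored in `data/taxonomy.tsv` as a system of sign relations
over the free basis `(e0, eX, eY, eXY)` with exact rational coefficients —
equalities chaining each tied group and one strict inequality per adjacent
pair of groups — together with a category, an interaction sign, and a
`target` field recording whose single-agent effect the combination alters
(X, Y, both, or none). The file is the runtime source of truth (checksum
pinned); an independent enumerator regenerates it from first principles and
the test suite asserts equality. Profile ids are assigned by category block
(constant = 1, then the two emergent profiles, so "emergent synergy" is
profile 3), then by number of distinct levels, Bliss sign, and rank
pattern.

Categories are assigned by an explicit rule set over the signs of
`dX = eX - e0`, `dY = eY - e0`, `dXY = eXY - e0` and the Bliss sign; the
rules are in `taxonomy._categorize` and produce: 1 constant, 2 emergent,
16 additive, 22 potentiation, 34 inhibition, 21 suppression, 5 restoration,
6 ceiling, 6 floor, and 5 + 5 reversal profiles.

At load time every profile receives an interior-point witness from an LP
that maximizes the common margin of its strict relations; witnesses serve
as satisfiability certificates, as distinguishability certificates (each
witness must violate every other profile's system), and as anchors for the
X↔Y mirror map used in role-swap analyses.

### Matching with tolerance

Observed means are never exactly tied. The deterministic matcher
canonicalizes a vector by snapping all pairwise differences with
`|diff| <= tau` to exact equality (transitively closed, groups replaced by
their mean), appends the additive prediction, and looks up the five-value
rank pattern. A tolerance-snapped pattern that is not realizable (possible
only for adversarial tie chains) falls back to the exact pattern of the
canonical vector, which always is. Ties between profiles cannot occur for
the complete taxonomy; for user-supplied partial taxonomies the matcher
falls back to a relation scan and resolves ties to the lowest id with a
warning.

## Simulation

Training data are drawn per profile by hit-and-run sampling of the
profile's solution polytope inside the admissible range [-14, 14] log2
units (typical of normalized microarray / voom-transformed RNA-seq data).
Tied values are identified exactly by sampling in the null space of the
equality constraints; strict inequalities carry a margin equal to the
minimum signal (0.5 log2), which makes the signal floor structural: the
signal delta — the smallest nonzero pairwise difference among the four
condition means — is at least 0.5 for every non-constant noiseless
instance. Burn-in is 100 steps and thinning 10; a rejection sampler is
available as a cross-check for full-dimensional profiles. The sampler is
approximately uniform on the polytope; uniformity is not required by any
downstream contract, only coverage and validity.

Replicate noise is Gaussian around the group means, n = 4 replicates per
condition, with one standard deviation sigma shared by all four groups.
Noise regimes are expressed as the ratio delta/sigma: low = 4, medium =
2.5, high = 2. Values pushed outside the admissible range are clipped to
the range limits. The constant profile has no defined delta; its training
sigma is drawn from the empirical sigma distribution of the non-constant
instances of the same regime, which keeps the constant class learnable.
The default training set holds 400 instances per (profile, regime).

## Features

Each gene or instance is summarized by a fixed 19-vector: the four means;
two-sided p-values and t statistics of the six pairwise contrasts (pair
order (0,X), (0,Y), (0,XY), (X,Y), (X,XY), (Y,XY)); the estimated signal
delta-hat; the omnibus 4-group F p-value; and the pooled within-group
variance (df = 4(n-1)). When at least 100 genes are processed as a batch
(always true for training, done per regime, and for real datasets), the
per-gene variances are moderated: a scaled inverse-chi-square prior is
fitted by method of moments on the log variances (digamma/trigamma
inversion) and the posterior variance
`(d0*s0^2 + d*s^2) / (d0 + d)` replaces the raw one, with the tests
gaining the prior degrees of freedom. The fit agrees with the standard
empirical-Bayes implementation in the R limma package (`squeezeVar`) to
four decimals on shared input; a test asserts this against Rscript.

**delta-hat.** On noisy data the raw "smallest nonzero difference" is
degenerate: for profiles with tied condition means the smallest estimated
difference is pure noise of size ~sigma, and sigma scales with the gene's
signal, so no fixed magnitude threshold separates the two. delta-hat is
therefore the smallest pairwise difference that is *statistically
supported*: contrast p below 0.05/6 (Bonferroni over the six contrasts,
because a minimum is being taken) and magnitude above the tie tolerance
tau. If no difference is supported, delta-hat is 0. The same definition is
used in training and application.

## Classifier

The primary model is a Random Forest: 200 trees, sqrt-features per split,
minimum leaf size 20, class probability = fraction of tree votes, trained
on the mixture of all three noise regimes with equal instances per class.
The leaf-size floor bounds memory (sklearn stores a per-node vector over
the 123 classes; unrestricted trees at the default training scale cost
several GB) and slightly smooths the probability estimates; a small
documented grid over max_features {4, 8, 12} showed no practically
relevant accuracy difference. Baselines with the same interface: Linear
Discriminant Analysis, and the deterministic matcher (tolerance 0.25, half
the minimum signal) wrapped as a one-hot "classifier". Evaluation reports
per-class accuracy/precision/recall, and the multiclass log gain: the mean
of -ln(probability assigned to the true class), floored at 1e-15.

Measured on held-out simulation (30 instances/profile/regime, training at
100/profile/regime), macro accuracy is ≈0.82/0.79/0.69 at delta/sigma =
4/2.5/2 for the forest, ≈0.58/0.58/0.56 for LDA, and ≈0.55/0.46/0.42 for
the deterministic matcher, with the forest's log gain far below LDA's at
every regime — reproducing the qualitative model ranking that motivates
the probabilistic approach.

## Per-dataset pipeline

Stages, in fixed order: (1) probe collapse — among a gene's probes keep
the one with the largest coefficient of variation; (2) CV filter — drop
genes with CV below the median; CV is computed on the linear scale (2^x)
because log2 means can be zero or negative; (3) DE gate — moderated
omnibus F, Benjamini–Hochberg adjusted p < 0.05; (4) signal filter — among
DE genes drop those with delta-hat below the median; (5) classification
and scoring. Each call carries the profile id, its class probability p
(of the argmax class, not summed over same-sign classes), the Bliss index
`b = (eXY - e0) - ((eX - e0) + (eY - e0))` from the estimated means, the
score `b*p`, and a sign (0 for non-interacting profiles, otherwise the
sign of b; disagreements between the Bliss sign and the assigned profile's
sign are logged as warnings). Reruns with identical inputs and seed are
bit-identical.

## Landscape and enrichment

Per-dataset call tables integrate into a dataset × gene × score landscape
with experiment metadata and gene-family annotations. Category frequencies
are reported over interacting calls only (profiles with nonzero sign;
per-call, not per-unique-gene). Scores are not re-normalized across
datasets. The context-dependence analysis selects, per dataset and change
type (suppression, the two reversals, emergence), the genes whose profile
`target` includes the focal stimulus's design role; the X↔Y mirror map
makes this analysis an involution under role relabeling.

Enrichment is a one-sided hypergeometric upper-tail test per term,
BH-corrected across tested terms; terms are intersected with the universe
first, terms at or above 500 genes (after intersection) are excluded, and
significance additionally requires covering at least 2% of the query. The
universe defaults to the genes surviving preprocessing, the conservative
conditioning choice.

## Synthetic datasets

`generate_synthetic_dataset` composes the simulator into an
expression-matrix fixture with a known truth table. Gene counts per mix
key (profile id or category) are allocated by largest remainder
(deterministic); profiles within a category are drawn at random.
Responsive genes follow the simulator exactly. Non-responsive (constant)
genes carry residual noise sigma ~ U(0.1, 0.5) log2 units — the typical
residual spread of non-DE genes in normalized array data — rather than the
training simulator's signal-scaled sigma, which would make null genes as
variable as the noisiest responders and defeat the CV filter for no
realistic reason.

What the fixtures do not emulate: mean–variance dependence, probe-level
artifacts beyond a trivial probe map, gene–gene correlation, batch
effects, and realistic (concentrated) effect-size distributions — effects
are sampled uniformly from each profile's polytope, so simulated fold
changes are far larger on average than in real data. Passing tests
therefore certify the machinery under the simulation's own assumptions,
not performance on any particular real dataset.

## Known limitations

* **End-to-end recall of planted emergent synergies is bounded near
  0.6–0.7 under the default study conditions.** Two structural effects
  compound: the median-delta filter removes the below-median half of DE
  genes, and by the polytope gap distribution ~20–25% of emergent
  instances fall below the DE-set median; and at n = 4, delta/sigma = 4, a
  chance 2–3 SE wobble of a tied mean makes an emergent instance genuinely
  resemble weak potentiation or reversal, capping classifier category
  accuracy on survivors at ~85–90%. The corresponding acceptance test is
  allowed to fail on its recall clause; precision (~1.0) and null-dataset
  specificity (~2%) hold with wide margins.
* The hit-and-run sampler is only approximately uniform at the default
  burn-in/thinning; no downstream contract depends on uniformity.
* Classification assumes approximately Gaussian replicate noise on the
  analysis scale; count data require a variance-stabilizing transform
  first.
* Two-time-point designs are analyzed as separate experiments; no
  dose–response or time-course modeling.

## Problem sizes used in tests

The unit suite trains on 20 instances/profile/regime; the acceptance tests
train at 100 (model comparison) and 400 (pipeline model)
instances/profile/regime, evaluate on 30/profile/regime, and run the
pipeline on 2,000-gene synthetic datasets; the null-calibration and
enrichment simulations use 10,000 and 200 replicates respectively. These
sizes keep the complete suite within a few minutes on one CPU while
leaving every statistical check well-powered.
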