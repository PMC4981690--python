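# Methods

## Problem and model

Plant GH9 endoglucanase subclasses A, B and C share a homologous
catalytic core; the class signal lives in short termini (transmembrane
anchor, signal peptide) and, for class C, a C-terminal CBM49 module.
Generic family profiles detect all three; class discrimination requires
class-specific profiles and a statistic that quantifies *how separated*
a query's per-class evidence is.  The pipeline is: profile-HMM scoring →
class-mean reduction → β screening → k-means centroids → a small
feed-forward approximator → interval rules.

## Profile registry

For training counts (n_A, n_B, n_C) the registry holds 2 generic
profiles, 2 per class, and 2·n_X leave-one-out profiles per class X (a
1D/3D pair per excluded sequence) — 60 profiles for counts (6, 16, 4).
The 1D/3D distinction is metadata: any aligned FASTA/Stockholm input is
accepted as the "3D" member.  Leave-one-out selection for a training
sequence retains all leave-one-out profiles of the other two classes
plus its own excluding pair; the δ fraction divides the retained count
by the class-specific total (all leave-one-out profiles plus the six
class-level profiles, the only denominator consistent with the published
fractions 0.72/0.38/0.79).  Registry construction is pure arithmetic and
available metadata-only (`ProfileRegistry.from_training_counts`); model
compilation and scoring go through pyhmmer (HMMER3).

Scores are best single-region (best-domain) bit scores — the highest
scoring region of a sequence per profile — with full-sequence scores
behind a config switch.  Reporting thresholds: E ≤ 10⁻⁶ for class and
leave-one-out profiles, E ≤ 10 for the generic homolog screen ("10E−06"
read as 1e-6; the two thresholds are seven orders of magnitude apart).
A missing cell (no hit) is zeroed with a warning when its class still
has at least one real hit; a class with no hits at all makes the
sequence unclassifiable rather than silently zero — absent hits near
threshold have no meaningful bit score, and zero is the conservative
floor.

## The β statistic

Each class contributes a two-member group — its 1D-side mean and 3D-side
mean — so τ = 2 in both generic and leave-one-out modes.  With
intra-group means μ and *population* variances σ² (divide by τ; the
group is exhaustive, not a sample):

    α_ij = τ² (μ_i − μ_j)² / (100 (σ_i² + σ_j²)),    β = α₁₂ + α₂₃ + α₁₃

Group indices map 1↔A, 2↔B, 3↔C.  This α is symmetric, invariant under
affine rescaling of the raw scores, monotone in each mean gap at fixed
variances, and inversely proportional to the mean within-group variance;
β is the halved symmetric 3×3 double sum.  An alternative
parenthesization of the α formula circulates in typeset form; it is
exposed as `formula="alt"` for sensitivity checks but is not affine
invariant and is never the default.  When both variances vanish while
means differ, the denominator is floored at ε = 10⁻⁹ bits² and a
saturation flag is set; degenerate inputs must not crash the pipeline.

Screening partitions: AA (β > 2.777), AB (1.00 ≤ β ≤ 2.777), AC
(β < 1.00).  The spacing requirement median(ΔHMM) ≥ 200 bits (median =
middle order statistic of the three absolute pairwise class-mean
differences) is reported as a separate `well_spaced` boolean; both must
hold for high-confidence downstream use.  Both the median and the mean
of pooled per-sequence deltas are emitted in evaluation reports, since
either summary is a reasonable reading of "observed spacing".

## Centroids and outliers

k-means (k = 3, scikit-learn, seeded k-means++ with 100 restarts; 1-D
k-means is multi-modal under bad seeds) clusters the training β values;
quality is between_SS/total_SS.  Clusters map to classes by majority
training label — centroid ordering is an empirical outcome, not a rule —
and mapping ties raise rather than resolve silently.  Outlier exclusion
defaults to a manual accession list (mirroring curated exclusion of
atypical training members), with a programmatic alternative flagging
points more than 2.5 within-cluster SDs from their centroid; exclusion
triggers a refit.

## The network

3 inputs (α₁₂, α₂₃, α₁₃), one hidden layer of 10 logistic units,
one linear output: 51 weights.  Targets are each training sequence's
class centroid β′, so the net learns a smooth α → centroid map
(β′ ≅ Σ γ_ij α_ij in the linear reading).  Training is resilient
backpropagation (RPROP+ with weight backtracking; η⁻ = 0.5, η⁺ = 1.2,
Δ₀ = 0.1, Δ ∈ [10⁻¹⁰, 50]) on the sum-of-squares error, stopping when
the largest absolute error-gradient component drops below the threshold
(default 0.01) — the semantics of the R `neuralnet` tool ("one hidden
layer of 10 units" is likewise that tool's `hidden = 10` reading).
Initialization is seeded standard-normal; non-convergence within
`max_steps` returns the model with `converged = False` plus a warning.
Inputs are unscaled by default (matching the reference tool);
standardization is available and is the pipeline default on synthetic
runs, where α magnitudes can reach the hundreds.

Validation is leave-one-out retraining: each held-out prediction β″ is
compared with the sequence's expected centroid via χ² = Σ(β″ − β′)²/β′
with df = n − 1, plus nearest-centroid match flags.

## Rule table

Assignment intervals on β″ live in YAML (`data/rules.yaml`), loaded into
a table whose construction validates pairwise disjointness on a dense
grid.  Default bounds: A = (9.95, 10.779) with α₁₃ < 0.02; B_high =
(3.45, 5.55); B_low = [5.55, 8.2052); C = [8.2052, 9.95] ∪ ((9.95,
10.779) with α₁₃ > 0.02) ∪ [10.779, 11.371].  Bounds are implemented
exactly as stated — open/closed per the inequality symbols, α₁₃ = 0.02
matching neither A nor C — and everything unmatched is `unassigned`;
the rules are never silently extended.  Evaluation reference labels are
the max-mean-profile class, the only ground truth available for
sequences known from expression data alone.

`derive_rule_bounds` re-derives intervals from a scored reference set:
`minmax` takes the closed per-class [min, max] of β″ (the original
construction); `midpoint` additionally widens each interval to the
midpoint of the gap to its neighbour (a Voronoi partition of the β″
axis).  The pipeline uses `midpoint` on synthetic runs because the
network's outputs cluster very tightly around each centroid there, and a
new sequence can land just outside the observed min/max while still
being unambiguous.  Derived tables carry no α₁₃ conditions, and the
class-B interval maps to the high-confidence label (the derivation set
is screened).

## Synthetic data

`gen_families` emulates the family architecture: a 450-residue shared
ancestor core from which each subclass diverges at 15% of sites (the
subclasses are paralogous lineages — without core divergence the class
signal would sit entirely in the short termini and inter-class spacings
would be tens, not hundreds, of bits); class A prepends a 23-residue
hydrophobic TM-like segment, B a 20-residue signal-like segment, and C
additionally appends a 110-residue W/F/Y-enriched (45% aromatic)
CBM49-like module.  Members are per-site mutated copies (default 5%).
Alignments come free of charge because the generator introduces no
indels: segments occupy fixed column blocks, gap-filled where a class
lacks them; the "3D" alignment drops every 100th column, emulating a
structure-guided trim while keeping (1D, 3D) score pairs tight.
Defaults: 6 training and 20 test sequences per class in the end-to-end
pipeline.

What the generator does *not* emulate: indels and alignment uncertainty,
site-rate heterogeneity, real CBM49 sequence content, compositional bias
of genuine TM/signal segments, or paralog gradients between classes B
and C.  Passing synthetic end-to-end tests therefore demonstrates that
the statistics, clustering, network and rules behave as specified on
well-posed inputs — not that the published bounds transfer to arbitrary
proteomes.

`gen_score_table` skips the engine entirely, drawing each class's
(1D, 3D) pair from Normal(class mean, SD); `gen_alpha_beta` draws
class-conditional α triples (per-class means summing near the published
centroids ~8.13/3.91/6.95) with linear-plus-noise targets for network
recovery tests.  All generators are byte-deterministic per seed, and
truth tables always accompany generated data.

## Numerical and scale choices

- Problem sizes: tests run the full chain at 6 train + 20 test per class
  (44 profiles, ~1 minute of engine time); network recovery uses 24-row
  leave-one-out fits at ≤ 20 000 RPROP steps.  These sizes make every
  statistic well-conditioned while keeping the suite quick.
- Seeds propagate from a single integer through `numpy.random`
  SeedSequence spawns; identical seeds give identical artifacts
  byte-for-byte.
- Ties in the max-class reduction are flagged ambiguous, never broken
  silently — the β screen exists precisely to remove near-ties.
- χ² is reported with df = n − 1; the statistic is a closeness index
  here, not a calibrated test, and no p-value is asserted.

## Known limitations

- The published interval bounds are tied to the score scale of the
  original training profiles; applying them to profiles built from other
  alignments requires re-deriving bounds (`derive_rule_bounds`).
- β is a screening heuristic: its distribution under the null of equal
  class means is not characterized, and no multiple-testing treatment is
  applied to the diagnostic z-scores.
- Sequences whose entire class evidence is missing are unclassifiable by
  design; the pipeline reports rather than imputes them.
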