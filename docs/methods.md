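# Methods

This note documents the model implemented by `funvul`, the defaults and
the numerical conventions, and what the synthetic-data generator does and
does not emulate.

## Trait space and functional entities

Species dissimilarity is the Gower coefficient: per trait, continuous
values contribute |x_i − x_j| divided by the trait's observed range;
ordinal traits are rank-transformed first (Podani's convention) and then
treated like continuous ones; nominal and binary traits contribute 0/1.
Each pair is averaged over the traits both species have observed (pairwise
deletion), so missing values shrink the evidence for a pair rather than
discarding the species. Two hard edges: a species pair sharing no observed
trait is an error (the dissimilarity is undefined), and a trait with zero
observed range is excluded with a warning (its partial term would be 0/0).
Species whose traits are all missing are rejected at ingest.

The embedding is classical metric scaling (PCoA): double-center
−½·J·D²·J, eigendecompose, keep eigenvectors scaled by √λ for positive
eigenvalues. Negative eigenvalues — Gower matrices are generally
non-Euclidean — are dropped without Cailliez/Lingoes correction; their
count is logged. Only the first two axes feed the entity grid: with more
axes the number of grid cells grows as R^axes and entities degenerate to
one species each, which defeats the redundancy logic. Axis signs are
canonicalized (largest-magnitude coordinate positive, ties broken by
species id) so results are invariant to input row order. Coordinates are
used raw; the grid bounds absorb scale, so rescaling axes would only
change cell aspect ratios, not occupancy.

The grid is R × R (default 20, the resolution at which the index was
found to stabilize in the original sensitivity analysis), bounded by the
extreme species on each axis. Cells are half-open [low, high) with the
last cell closed above, so the extreme species stay inside. An axis with
no spread collapses to a single row/column (an R × 1 grid for a 1-D
space); a space with no spread at all is an error.

Functional distinctiveness is D_i = Σ_{j≠i} d_ij / (S − 1), the row mean
of off-diagonal dissimilarities, in [0, 1] because the dissimilarities
are.

## Virtual communities

The reference set crosses redundancy × weights × pairing. The full 3×3×2
crossing would give 18, but under homogeneous weights the
distinctiveness–weight pairing is undefined (all weights equal), so the
pairing collapses there and the canonical set has 3 × 5 = 15 members.
Occurrence data carry no weight information, leaving only the two
opposite redundancy distributions.

Redundancy rearrangement operates on the N entities occupied in the
observed community, ordered row-major. Homogeneous: each entity receives
⌊S/N⌋ species and the S mod N leftovers go one per entity from the first
— the maximally even completion of the floor rule. Heterogeneous: one
species per entity, with the S − N surplus stacked in the last occupied
entity ("last" being otherwise undefined, row-major order pins it down).
Species fill slots in stable id order.

Weight rearrangement conserves T exactly. Homogeneous: T/S each.
Heterogeneous: S − 1 species receive a unit u and one species the
remainder; u = 1 individual when the observed weights are integer counts
and T ≥ 2S (matching the "one individual each" construction for count
data), otherwise u = T/(2S), which keeps the remainder strictly above the
unit so the configuration stays extreme. Pairing sorts the weight
multiset against D_i (ascending for positive, descending for negative;
ties in D broken by species id). The observed-weight modality re-pairs
the observed multiset by sign rather than keeping the observed
species–weight association: the pairing axis is otherwise inert for that
modality.

After relocation a species' original trait vector no longer describes its
position, so D_i for virtual configurations is recomputed geometrically:
each relocated species sits at its cell's center, distances are Euclidean
in the grid plane normalized by the grid diagonal (keeping D ∈ [0, 1]),
and the observed-redundancy configurations use the species' actual
coordinates the same way. A config switch
(`recompute_distinctiveness=False`) instead reuses the trait-based D_i
for all configurations, for users who prefer the trait-space ordering to
survive relocation; recomputation is the default because the pairing is
meant to reflect the configuration being disturbed.

Virtual suitability communities may assign one species a weight above 1:
the rearrangement conserves total weight, and the [0, 1] bound is a
property of observed suitability data, not of the synthetic references.

## Disturbance simulation

All modes run until total extinction, recording after every step the
fraction disturbed (x: removed weight / initial T, or removed species / S
for occurrences) and the fraction of initially occupied entities still
occupied (y). A species is extinct when its weight falls to ≤ 1e-12
(floating-point dust absorber). The per-step abundance budget is 5% of
the *initial* total, so a series takes exactly ⌈1/f⌉ steps; tying the
budget to the current total would decay geometrically and never
terminate. Using the disturbed fraction (not the step count) as x makes
curves from communities needing different step counts comparable on
[0, 1].

Two budget-allocation rules are provided for abundance data:

* `species` (default): the budget is consumed by repeatedly drawing an
  extant species uniformly at random and removing as much of its
  abundance as the budget allows. Every step removes exactly f·T₀.
* `individual`: the budget is removed one individual at a time, drawn
  uniformly from the surviving individuals — classical rarefaction. A
  realization is equivalent to a random permutation of all individuals,
  so the expected curve is invariant to the step size by construction;
  the implementation exploits this with an O(T) vectorized schedule.
  Non-integer weights are split into unit-sized quanta with one partial
  remainder per species.

The rules differ in what "randomly hit" means: per species or per
individual. Under the `species` rule a smaller step size shifts the
expected curve on uneven communities (a small budget only nibbles at
whichever species it lands on, so dominant species are drained relatively
faster), which is why the chunk-invariance property is documented and
tested on the `individual` rule. Both rules yield the same vulnerability
ordering in practice; the default follows the simpler uniform-species
reading.

Occurrence mode removes a configurable number (default 1) of uniformly
chosen extant species per step. Suitability mode subtracts the decrement
(default 0.05, i.e. 5% of the maximal suitability) from *every* extant
species, which makes it deterministic; replication is therefore skipped
for it with a logged note. A stochastic variant can be emulated by
running suitability data in occurrence mode on thresholded values.

Replication uses one master seed with replicate-indexed child streams
(`default_rng([seed, replicate])`), so results do not depend on
scheduling, and all states of one assessment share the stream family
(common random numbers, which tightens the envelope comparison).

## The index

Each curve is integrated by the trapezoid rule; points are recorded at
every step (20 per series at the default 5% decrement), so the quadrature
choice is second-order. AUC_min/AUC_max are the min/max of
*replicate-mean* AUCs per virtual spec — the index compares communities,
not individual realizations. FV = 100 × (AUC_max − AUC_obs) /
(AUC_max − AUC_min), oriented so that 100 marks the most vulnerable
reference (low AUC) and 0 the least vulnerable; a widely reprinted form
of the formula carries the opposite orientation, available via
`printed_orientation=True` for auditing. When stochastic noise pushes
AUC_obs outside the envelope, FV is clamped to [0, 100] and the event is
logged; a degenerate envelope (AUC_max − AUC_min < 1e-9, e.g. occurrence
data with one species per entity, where both references coincide) is an
error reported per community without aborting a multi-community run.

Replicate dispersion of FV is reported as the relative SD of per-replicate
FV values (each replicate's observed AUC positioned in that replicate's
envelope). Note that relative SD inflates mechanically when mean FV is
near zero.

## Sensitivity sweeps

`sensitivity_sweep` re-runs the assessment along four axes: replicate
count and grid resolution (8 independent seeded batches each, reporting
mean FV and between-batch relative SD), random trait subsets (20 seeded
combinations per subset size; a subset of all traits reproduces the
baseline exactly; sizes below 3 warn that the trait space is unstable),
and deletion of species with any missing trait.

## Synthetic data

The generator emulates the two structural axes the framework responds to:
clustering in trait space (k latent 2-D cluster centers, Gaussian
within-cluster spread σ, continuous traits = latent coordinates plus
proportional noise, nominal traits = cluster labels with 10% flip noise)
and abundance evenness (geometric series with ratio p, p = 1 even;
integer counts by largest-remainder rounding summing exactly to
T = 20·S individuals, so the count-data rules are exercised). The extreme
pair used for directional checks holds the abundance vector fixed and
varies only clustering: every species its own tight cluster versus all
species stacked at one point plus a single outlier that fixes the grid
extent.

What the generator does not emulate: real trait covariance structures,
phylogenetic signal, detection error, spatial autocorrelation among
sites, or the heavy-tailed abundance distributions of large surveys.
Passing tests therefore demonstrate the internal correctness and the
qualitative behavior of the framework (conservation laws, oracle
agreement, direction of the redundancy effect, replicate stability), not
calibration against any particular empirical system.

## Problem sizes and defaults

Defaults: 20 × 20 grid, 5% abundance decrement, 0.05 suitability
decrement, 1 species per occurrence step, 99 replicates. The packaged
checks run at S = 12 (self-consistency, direction), S = 50 (replicate
stability), S ≤ 8 with 2000 replicates (occurrence oracle), and 200
random communities with S ∈ [5, 20) (conservation) — sizes at which every
quantity is estimated well while a full verification run completes in
about a minute. The minimum-richness filter (default 10) applies to
occurrence and suitability runs, where species-poor cells make the
two-member envelope unstable; abundance runs apply no filter by default.

## Known limitations

* Only the first two PCoA axes are used; communities whose trait
  structure needs more axes lose information (the eigenvalue spectrum is
  exposed for auditing).
* Exposure is uniform by construction — disturbances hit species (or
  individuals) at random, so the index measures intrinsic sensitivity,
  not threat-specific risk.
* The index is relative to self-derived references: FV values are
  comparable across communities in the same study design, but a
  degenerate envelope (S = N occurrence data) admits no score.
* Mean trait values per species; intraspecific variation is out of scope.
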