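# Methods

## Growth model

Tumours are grown cell-by-cell in discrete steps. A dividing cell is
chosen uniformly at random among cells able to divide; its daughter is
placed on a uniformly chosen empty neighbouring lattice site
(*structured* mode) or simply added to the population (*well-mixed*
mode). With probability μ the daughter acquires exactly one new mutation
under the infinite-allele assumption (every mutation arises once, is
never recurrent, and is lost only by cell death). After each division
one uniformly chosen extant cell — the newborn daughter included — dies
with probability d. Growth stops when the extant population reaches
`n_target`. All mutations are neutral; there is no migration,
selection, or back-mutation.

Defaults and rationale:

* **μ = 0.5** per division. With effective exome-wide mutation rates in
  neoplasms, a detectable mutation arises in roughly every other
  division; this produces early branching and a broad emergent spectrum
  of sub-clone sizes, which is exactly the regime in which the sampling
  question is interesting.
* **d = 0.1** per division, a non-aggressive tumour. Death both roughens
  the growth front and transiently perforates the interior, letting
  occasional interior divisions occur.
* **n_target = 20 000** in the full-scale configuration (so a 1% biopsy
  is 200 cells); the reduced scale used by the test suite is 5 000
  (1% biopsy = 50 cells). See "Scales" below.
* **Neighbourhood**: Moore (8 neighbours) by default, von Neumann (4)
  available. The adjacency notion is not uniquely determined by the
  biology; Moore gives denser fronts with fewer jammed cells and the
  choice is exposed for sensitivity analysis.

Implementation decisions where the procedure was genuinely open:

* In structured mode, cells with no empty neighbouring site cannot
  divide; the reproducing cell is drawn uniformly among divisible cells
  (implemented by rejection, which is distributionally equivalent per
  committed division).
* The death draw includes the newborn daughter and is skipped while only
  one cell is alive, so a nascent tumour cannot go extinct.
* The lattice is an unbounded sparse coordinate map; there are no
  boundary effects.
* Runs are bit-reproducible from the seed; the lineage table (parent id,
  birth mutation, position, alive flag) is append-only, so any cell's
  genotype can be reconstructed after the fact.

## Clone structure

All statistics are computed over extant cells at observation time. The
**truncal set** is the set of mutations at frequency 1. This is an
operational definition: a mutation fixed later by genetic drift is
indistinguishable from a founder mutation in any sampling scheme, so it
counts as truly clonal (the founder-only alternative is available behind
a flag). **First-tier branches** are equivalence classes of extant cells
by the first non-truncal mutation on their root-to-cell lineage path;
cells whose genotype is exactly the truncal set form the ancestral
class. Because the truncal set can grow by drift, branches are defined
relative to the *final* truncal set. The balancing factor is reported
two ways: `f_largest`, the highest frequency among non-truncal mutations
(used by default), and `f_first_tier`, the largest branch fraction; the
two coincide whenever any branch exists, since every branch member
carries the branch's root mutation and no nested mutation can outnumber
its branch.

## Sampling protocols

* **Single cells**: uniform without replacement. Within-sample
  frequencies are all 1, so single-cell inference is detection-threshold
  invariant.
* **Bulk biopsies** (structured): a connected patch grown by
  breadth-first expansion over occupied neighbour sites from a uniform
  seed cell with randomised visiting order. This guarantees exact target
  size (⌈s·N⌉ cells) and connectivity on ragged fronts, which a
  geometric disk would not. Biopsies are independent and may overlap.
* **Pooled samples** (well-mixed): uniform without replacement; the
  within-sample frequency of a mutation is hypergeometric around its
  population frequency.
* **Pattern samples** (structured): single cells on the tumour edge
  (cells with ≥ 1 empty neighbouring site) nearest to equidistant target
  angles about the extant-cell centroid, ties broken by larger radius
  then lower cell id. A rotation sweep evaluates the template at
  `n_steps` offsets spanning one angular period (default 64), which by
  symmetry covers the whole circumference; this yields a deterministic
  per-tumour accuracy with no sampling randomness.

## Inference and scoring

A mutation is detected in a sample when its within-sample frequency is
≥ ε (inclusive; ε mimics sequencing-depth limits). The putative clonal
set is the intersection of detected sets over all samples. A repetition
is correct iff the putative set contains no sub-clonal mutation; missed
truncal mutations are not errors (a false positive would direct therapy
at a target absent from part of the tumour; a false negative only
shortens the candidate list). A strict mode requiring exact recovery of
the truncal set exists for sensitivity analyses. Repeated-sampling
estimates use one master seed spawning per-repetition child seeds, so
repetitions are independent and individually replayable.

## Closed-form theory

With branch fractions f·(1−f)^(k−1), the probability that n random
samples do not all land in one first-tier branch is
1 − f^n·Σ_{i<M}(1−f)^(n·i) for M branches; the M→∞ geometric limit is
(1 − f^n − (1−f)^n)/(1 − (1−f)^n). Boundary values at f ∈ {0, 1} are
defined by analytic limits (the expression is 0/0 there): f=0 gives 0
for n=1 and 1 for n≥2; f=1 gives 0. The sample-number planner uses the
strict bound p > p_target, matching how the confidence statements it
reproduces are phrased. The equidistant-pattern planner returns
⌈1/(1−f)⌉ with a 1e−9 tolerance absorbing floating-point excess (e.g.
1/(1−0.9) evaluates to 10.000000000000002).

**Balancing-factor estimation.** Observed coincidence ratios — the
fraction of size-i sample subsets whose mutation intersection equals the
intersection of all n samples — estimate p_f(i)/p_f(n). `estimate_f`
minimises the squared distance between observed and predicted ratios
over f ∈ (0, 1) via a 1 000-point grid followed by bounded Brent
refinement on the bracketing interval; it is deterministic for fixed
input. When every ratio equals 1 no discordance was observed, f is not
identifiable from above, and the estimator returns the lower search
boundary (1e−4) with a `degenerate` flag. Subset enumeration is exact up
to 12 samples and switches to seeded uniform subsampling above.

**Verification oracle.** A Monte-Carlo oracle draws samples from the
categorical distribution over branch masses plus the ancestral remainder
(1−f)^M and counts a repetition as a failure iff all samples land in a
single first-tier branch; samples all in the ancestral remainder are a
success, matching the terms of the finite-branch formula. The oracle is
used in tests as an independent check of the closed form, never as the
implementation.

## What the simulations do and do not show

The generator emulates neutral, spatially coherent clonal growth with
peripheral expansion and drift — the regime in which sampling geometry
is the dominant source of misclassification. It does not model normal
cell contamination, ploidy/purity effects, read-depth noise, cell
migration, or selective sweeps; passing tests therefore demonstrate the
sampling-geometry effects in an idealised tumour, not the full error
budget of clinical sequencing. Two model properties noted during
validation:

* The closed form assumes geometrically decaying branch sizes; simulated
  branch structures deviate stochastically, so single-cell validation is
  banded (3 SE) rather than exact, with agreement improving as n grows.
* Branch shares measured along the roughened tumour edge deviate from
  area shares by a few percent per tumour, in either direction. The
  edge-random control therefore matches plain random sampling within
  3 SE for most but not necessarily all tumours at high repetition
  counts, and the control comparison is assessed batch-wise.

## Scales and numerical choices

The test suite runs the simulation checks at a reduced scale chosen to
preserve every ordering and agreement property: 5 000-cell tumours,
500–1 000 sampling repetitions, batches of 10–30 tumours (the package's
own default `ExperimentConfig`); `ExperimentConfig.full_scale()` gives
20 000-cell tumours with 10 000 repetitions. Statistical assertions use
3 standard errors with add-one smoothing of binomial SEs (so the band is
never exactly zero at observed proportions of 0 or 1). The well-mixed
threshold experiment tests the boundary ε = f_largest + 3 hypergeometric
SDs; tumours where that exceeds 1 have no valid boundary threshold and
are excluded from that specific assertion. Probabilities are evaluated
with direct floating-point formulas; the finite-branch sum uses the
closed geometric form, accurate to ~1e−15 over the tested grid
f ∈ [0.01, 0.99], n ≤ 40.

## Known limitations

* Two dimensions only; no off-lattice or 3-D geometry.
* The first-tier decomposition assumes the ancestral mutation rate is
  constant, so unequal branching intervals (bursty mutation) are not
  modelled in the theory.
* `f_hat` comes with a residual but no confidence interval.
* Pattern sampling assumes a roughly convex tumour with a well-defined
  centroid and edge; highly invasive morphologies would need a different
  placement rule.
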