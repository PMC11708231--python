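# Methods

## The statistics

At a biallelic site observed in five populations (one chromosome each, or a
population allele frequency), write `A` for the allele seen at least three
times out of five and `B` for the minority allele. No ancestral state is
called and the fifth taxon is treated like any other — the *outgroup mutation
assumption*. This leaves 15 polarized patterns: 5 singletons (one `B`) and 10
doubletons.

An *equal probability set* is a set of patterns whose probabilities coincide
under the null hypothesis of no gene flow purely by the exchangeability of
sister lineages in the species tree (ignoring recurrent and back mutation).
For the symmetric tree `S = (((1,2),(3,4)),5)` the sets are
{BABAA, BAABA, ABBAA, ABABA}, {BAAAB, ABAAB}, {AABAB, AAABB}, and the
singleton sets {BAAAA, ABAAA}, {AABAA, AAABA}; the asymmetric tree
`A = ((((1,2),3),4),5)` and quasisymmetric tree `Q = (((1,2),3),(4,5))` have
their own collections. Singleton sets are equal-probability only under the
additional *synchronization assumption* — that the mutation opportunity of a
lineage depends on the time interval alone, not the population it is in.
Ancient samples (tips that "die" before the present) violate it.

A *binomial* statistic picks one pattern from each side of a set,
`Δ = n(L) − n(R)`, mean zero under the null. Sums and differences of
binomials give composed statistics; shared patterns cancel first, the
positive-coefficient patterns form `L`, the negative `R` (always disjoint),
and the scaled value is `Δ* = (n(L) − n(R)) / (n(L) + n(R)) ∈ [−1, 1]`.
Twenty composed statistics form the preferred panels: eight for `S`, four
for `A`, eight for `Q`, with the singleton-dependent ones placed right of a
divider so they can be dropped for ancient data. The classic four-taxon D
and the DFOIL and Partitioned-D statistics are special cases; `dfoil_panel`
evaluates each DFOIL statistic through both of its equivalent compositions
and asserts their identity.

Classification: under the null and independent loci,
`Z = (n(L) − n(R)) / sqrt(n(L) + n(R))` is approximately standard normal; a
statistic is classified `+` if `Z ≥ Φ⁻¹(1 − α/2)`, `−` if
`Z ≤ −Φ⁻¹(1 − α/2)`, else `0`, with `n(L)=n(R)=0` conventionally `0`.
The default `α = 0.01` gives the threshold 2.576, which also scales the
reported Wald radius `z · sqrt(4 n(L) n(R) / (n(L)+n(R))³)`. The critical
value is computed from the normal quantile at run time, never hard-coded.
Frequency-mode (fractional) counts reuse the same formulas; this is an
approximation, as the binomial sampling story strictly applies to integer
counts. No multiple-testing correction is applied across a panel — α is
per-statistic — and no linkage correction is attempted (block-jackknife
standard errors are out of scope).

One printed formulation of the eighth `Q` statistic is internally
inconsistent (its numerator and denominator name different pattern sets);
the package uses the compositional definition ΔQ1+ΔQ2−ΔQ6+ΔQ8, which is the
only reading that is a combination of the binomial statistics and mean-zero
under the null, and which reproduces the expected classifications in
simulation.

## Prediction tables and matching

Each unidirectional gene-flow event `x->y` (a branch stemming from `x`
admixing into `y`) has a predicted tuple of `{+,−,0}` classifications over
the tree's panel — its *signature*. The tables are encoded as literal data:
32 events for `S`, 18 for `A`, 34 for `Q`; every unlisted event predicts the
all-zero signature. Collapsed (singleton-free) tables are the projection of
the full tables onto the statistics left of the divider, with events merged
when their projections coincide and dropped when the projection is zero.
Events sharing a signature form an ambiguity class, labelled by a
representative with an asterisk (`34<->2*`); the full member list is always
reported. Matching an observed signature is exact equality on signs:
all-zero maps to "Nothing", an exact row match to its ambiguity class, and
anything else to "Unknown scenario" — mixtures of events are deliberately
left to the user's interpretation under the single-event assumption.

For tree `S`, one scenario (3->12) is known to drift two nominally-zero
statistics (ΔS3−5*, ΔS4−5*) slightly off zero; the table keeps the
theoretical zeros and validation treats those two entries as unconstrained.

The DFOIL comparison table in `dfoil_prediction` was derived with this
package's simulator (2×10⁶ patterns per scenario under the default scenario
geometry below) and frozen as data; it agrees with the published anchor
facts that 1->3 yields (+++0) and that DFOIL cannot see gene flow from a
terminal branch into 5.

## The coalescent simulator

The model is a species tree of shape S/A/Q with node times (time 0 = the
present, increasing into the past; one time unit ≈ 2λNe generations),
within-population pairwise coalescence rate λ (default 1), per-leaf sampling
times (default 0; positive values model ancient samples), mutation intensity
μ per unit branch length (default 10⁻⁴), and gene-flow edges with admixture
proportion β (default 0.1). Backward in time, lineages coalesce within
their current population at rate λ per pair; at an admixture time each
lineage in the target branch independently switches to the donor side with
probability β; at species-tree nodes populations merge. A donor is the
source branch itself when the two branches coexist at the admixture time
(instantaneous edge), otherwise an intermediate ghost population that joins
the source branch at a later `ghost_join` time — matching the view that
introgression is typically ghost-mediated.

Default node times place the root at 3 and the internal nodes roughly
evenly: `S` (1, 1, 2, 3), `A` (0.75, 1.5, 2.25, 3), `Q` (t12=1, t123=2,
t45=1, root 3). Under these defaults a few events name a source terminal
branch that ends before the target branch begins (3->12 and the like); since
the predicted signatures are parameter-free, the scenario builder makes such
an event realizable by delaying the source leaf's parent node to 80% of its
allowed interval (e.g. t34 → 1.8 for 3->12) and placing the edge
instantaneously at 10% into the resulting overlap, so the introgressed
lineages enjoy a donor co-residence comparable to the unstretched events.
Unstretched instantaneous edges sit at the overlap midpoint and ghost
joins at the source-interval midpoint. β = 0 edges are accepted and are
exact no-ops (useful for regression tests).

Mutations are infinite-sites: a gene tree with total branch length `L`
below the sample MRCA carries `k ~ Poisson(μL)` mutations placed uniformly
on its branches (`drop_mutations`); each mutation is one polarized pattern,
and mutations above the MRCA are unobservable and ignored. At the default
μ a tree carries ~10⁻³ mutations, so patterns are effectively i.i.d. draws
from the single-mutation distribution. Bulk sampling
(`simulate_pattern_counts`) therefore uses the exact limit directly:
size-biased tree acceptance (probability `L/M`, with `M` set from a pilot
mean plus 25 time units, truncating a tail of probability < e⁻¹²) followed
by a single uniformly placed mutation. This makes the emitted patterns
exactly i.i.d. and about three orders of magnitude faster than literal
Poisson thinning, at a distributional cost far below Monte-Carlo noise.
The hot path is a numba kernel; a readable pure-Python walk
(`simulate_gene_tree`) is the reference implementation, and the two are
cross-checked against each other and against an independent msprime
implementation of the same demography in the test suite.

Reproducibility: every simulation takes an explicit seed; the scenario suite
derives per-scenario substreams from the master seed with
`numpy.random.SeedSequence`.

## The windowed scan

Sites sorted by (chrom, pos) are bucketed into fixed-width bins anchored at
coordinate 1 of each chromosome (bin index `(pos−1)//size`); output
coordinates are 0-based half-open. Bins are genomic, not SNP-count, bins;
trailing partial windows are kept. Each window's counts yield a panel,
signature and table match; zero-retained-site windows classify "Nothing".
Aggregation counts windows per ambiguity class plus "Nothing" and "Unknown
scenario", always summing to the window count. Windows are anchored per
chromosome. The per-window binomial Z makes no linkage correction, so short
windows in high-LD regions will have inflated |Z|; window size is the user's
trade-off between power and the single-event assumption.

## Validation suite: problem sizes and expectations

The acceptance tests exercise the whole chain at sizes chosen to keep the
default run inside a few minutes of one CPU while leaving comfortable
statistical margins:

- Sign recovery: all 84 scenarios at 10⁵ patterns must recover every
  predicted non-singleton sign; at 10⁶ patterns additionally the
  singleton-dependent signs. Predicted-zero entries fire at rate α by
  construction (~290 such entries across the suites, so ~3 false nonzeros
  are *expected*); the tests bound false nonzeros by the 99.9% Poisson
  quantile of that α-budget rather than demanding an outcome the statistic
  itself contradicts. Sign flips on predicted-nonzero entries always fail;
  at 10⁵ patterns a single scenario per tree may carry a borderline miss
  (the weakest rows sit near |Z| ≈ 4–5 there), at 10⁶ none may. The 3->12
  flagged pair is exempt (see above).
- Null calibration: 200 null runs of 10⁴ patterns; each statistic's
  classification rate must stay within 3 binomial SE of α = 0.01.
- Ancient-tip bias: 50 null runs of 10⁵ patterns with leaf 2 sampled at
  time 0.5. The singleton statistics whose patterns involve the dead tip
  (ΔS5+7*, ΔS3+4−5+7*) must classify nonzero in a majority of runs while the
  four singleton-free statistics stay 0 — the failure mode that makes
  singleton-based tests (DFOIL included) unsafe on ancient samples. The
  other two singleton statistics (ΔS6+8*, ΔS1+2−6+8*) are built from
  singletons of leaves 3 and 4 only and are genuinely unaffected by an
  ancient leaf 2, so no expectation is placed on them.

`scripts/acceptance.py` re-runs the same computations (non-singleton sign
recovery at 10⁵ patterns, calibration, ancient-tip bias) from scratch under
a caller-supplied seed and writes the headline numbers as JSON.

## What the simulator does and does not emulate

The generator reproduces the ingredients the statistics respond to: ILS,
tree-shape symmetry, admixture pulses of either polarity, ghost mediation,
and dead tips. It deliberately omits recombination and linkage (patterns are
independent, so it cannot inform window-size choice), sequencing error, DNA
damage, recurrent mutation, and population-size variation along branches
(λ is constant). Passing the suite therefore demonstrates correctness of
the statistics and their predicted signs under the model's assumptions, not
robustness to LD-inflated Z scores or data artifacts in real genomes.

## Known limitations

- Frequency-mode Z scores treat fractional pattern weights as counts.
- The genome scan's exact signature matching means a single α-level false
  positive in a window demotes it to "Unknown scenario"; users scanning many
  windows should expect this at roughly the α rate per zero statistic.
- The non-binomial tree-A statistic
  n(BAABA)+n(ABABA)+2n(AABAB)−n(BAAAB)−n(ABAAB)−2n(AABBA) is out of scope,
  as are block-jackknife errors and admixture-proportion/time inference.
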