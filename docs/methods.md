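# Methods

## Model overview

`palmbreed` is an individual-based, forward-in-time simulator. Loci are
biallelic, mapped in centimorgans, and mutation-free: every allele in any
generation descends from the founder gene pool. Meiosis follows
Haldane's model — per-chromosome crossover counts Poisson(length/100 cM),
uniform positions, no interference, random starting strand.

Two additive traits, bunch number (BN) and bunch weight (BW), are
controlled by QTLs with normal effects; a configurable fraction of QTLs
(default 70 %) is pleiotropic with a bivariate-normal effect pair of
correlation −0.9, which generates the negative BN/BW genetic correlation
observed in these populations (≈ −0.75). Yield is FFB = BN × BW exactly;
phenotypes add normal environmental noise with
σ²e = σ²a (1 − h²)/h² per trait and population. Heterosis needs no
dominance: with mirrored population profiles the hybrid mean product of
near-equal components exceeds the midparent mean of unbalanced products.

## Initial populations

Both populations descend from one finite random-mating **ancestral
population**. Its size is set from the target LD decay distance through
the Sved/Hill–Robertson expectation E(r²) ≈ 1/(1 + 4Nc) (r² = 0.1 at
d ≈ 225/N cM), and it drifts for N generations before founder sampling,
so bottleneck + drift create LD mechanically. Initial allele frequencies
are Uniform(0.05, 0.95) in linkage equilibrium.

The **QTL architecture is defined in the ancestral base**: QTL loci are
drawn among loci with MAF > 0.1 *at that point*, before drift and the
bottlenecks. By generation 0 the QTL frequency spectrum has therefore
drifted (and responded to burn-in selection) like any other locus,
fixation included. QTL homozygosity is measured over **all** QTL loci —
fixation at QTLs is precisely the signal the measure is after — while
the neutral SNP panel follows the standard convention of freezing the
loci polymorphic in the initial La Mé population at generation 0. This
is what makes the QTL-based inbreeding sit above the SNP-based one in
every generation, with selection widening the gap.

Founder histories: Deli expands from 4 founders through cohorts of
25, 75, 75, 75, 75, 75, 75, 100 with mass selection from the second
generation and selfing allowed in the last two; La Mé expands from 24
founders through 70 and 100 with mass selection throughout. Mass
selection takes the top 50 % on a weighted index of standardized BN/BW
phenotypes; the weights differ by population (Deli 0.1/0.9,
La Mé 0.9/0.1), creating the mirrored trait profiles. At generation 0
the trait scale is **anchored**: effects are rescaled so the mean
realized additive variance matches the target (BN 2.445, BW 0.315 —
the mean of the two populations' published-scale values), population
means are shifted to the target profiles (Deli 9.22/20.52, La Mé
19.73/10.07), and residual variances follow from the target
heritabilities (Deli 0.54/0.55, La Mé 0.48/0.47). Hybrid parameters are
the midparent/average of the two.

## Evaluation

Parents are evaluated for general combining ability (GCA) in hybrid
crosses with a per-trait mixed model y = 1μ + Z_D u_D + Z_L u_L + e
solved by Henderson's equations. RRS uses the tabular-method numerator
relationship matrix A (so A_ii = 1 + F_i); RRGS uses VanRaden's
G = ZZ′ / 2Σp(1−p) with base frequencies frozen at the generation-0
population and markers drawn once from the neutral SNPs. Variance
components are the simulated truth, not REML estimates: σ²GCA = σ²a/4
per population, and the residual pools the hybrid environmental variance
with the within-cross segregation variance (σ²a/4 from each side).
Estimated breeding values are reported on an absolute half-scale,
g = μ̂/2 + û, so a Deli term plus a La Mé term reconstructs the expected
hybrid trait value and products in the multiplicative formulas stay
positive and rank-meaningful. If G is not positive definite a 1e-6 ridge
is added and logged.

Kinship for mating constraints switches basis with the scheme —
pedigree kinship f = A/2 in RRS, genomic coancestry f = G/2 in RRGS —
so inbreeding is controlled on the same basis used to estimate breeding
values. The scale conversions in use: f_ii = (1 + F_i)/2 (pedigree),
F_i = G_ii − 1 (genomic), progeny inbreeding of a design
= mean f over its crosses, directly comparable with the candidate mean
F(n) used in the threshold.

## Mating designs

The conventional method gives the top 16 parents 4 mating slots each and
fills 32 distinct cells of the upper triangle + diagonal sequentially,
drawing uniformly among currently feasible cells, restarting on dead
ends (a selfing consumes two of its parent's slots, closing the
16 × 4 = 2 × 32 arithmetic). This sequential construction slightly
over-represents selfings (~13.5 % against the naive cell-uniform 11.8 %)
because end-of-process slot depletion forces selfings; exhaustive
enumeration of the 4-parent/2-slot case shows the exact uniform law over
valid designs actually sits *below* the naive value, so no exact-degree
sampler realizes 11.8 % — the distribution is a genuine design choice.
`mating.mix_design_cells` provides a verified degree-preserving swap
chain whose stationary law is uniform over valid designs, for analyses
that need it.

The five simple management rules modify this scheme: `NoSelf` forbids
the diagonal; `FS_T1`/`FS_T3` walk down the ranking skipping candidates
whose full-sib family (unordered parent pair) already reached the cap.

## Simulated-annealing mate selection

The decision variable is the 0/1 upper-triangular cross matrix over the
preselected candidates (50 of 120, or 60 of 330), constrained to
Σx = 32 and mean parent-pair kinship below F(n) + ΔF(n). The threshold
increment interpolates with the user coefficient c_ΔF ∈ {0, 0.25, 0.5}
between two simulated anchors: mean progeny inbreeding of 12 random
selection-and-mating designs (lower) and of 7 conventional designs
(upper).

The energy E is the negative mean expected hybrid FFB over all pairs of
(fixed conventional Deli cross, La Mé cross); it factorizes as
E = −(m_ab + m_a·mean(b_L) + m_b·mean(a_L) + mean(a_L b_L)) with the
three Deli statistics precomputed once, making each evaluation O(32) —
an algebraic identity verified in the tests against the explicit double
loop. The neighbourhood swaps nr set/unset cells (nr = 3 at temperature
levels 1–5, 2 up to 15, then 1 — the schedule is indexed by temperature
reductions, resolving an ambiguity between inner iterations and levels),
retrying up to 5,000 times for a constraint-satisfying alternative;
exhaustion ends the run with the current solution. Metropolis
acceptance uses P = e^(−ΔE/T) for ΔE ≥ 0 (so ΔE = 0 is accepted);
cooling is T ← 0.95 T when 50 iterations or 30 acceptances are reached
at a level (100/60 in the 330-candidate preset), stopping after a level
with zero acceptances, at 80 (100) reductions, or on neighbourhood
exhaustion. T0 is calibrated so a non-improving move is accepted with
probability ~0.5: over 10 probe alternatives to X0, T0 = d̄/ln 2 with d̄
the mean positive ΔE; all-improving probes fall back to T0 = 0.15, no
valid probe at all regenerates X0 (up to 5 times) before the restart
aborts. X0 itself (16 random individuals randomly mated) is exempt from
the kinship constraint; the best-ever solution is tracked over
constraint-satisfying solutions only, falling back to X0 when nothing
feasible was accepted. Independent restarts get counter-spawned seeds,
so the winner (lowest E, first index on ties) is identical whatever the
degree of parallelism.

## Scheme orchestration

A scenario runs 4 (desk default 2) cycles. RRS progeny-tests every
cycle; RRGS in cycles 1 and 3 only, training GBLUP on the most recent
test while new candidates enter G ungenotyped-in-y. The progeny test is
an incomplete factorial: every parent gets at least one mate, pairs are
added to a total of 2.1 × parents crosses, each with 20 (desk 10)
phenotyped hybrids. Selection/mating applies the chosen method in La Mé
and the conventional method in Deli; each of the 32 crosses contributes
⌊candidates/32⌋ or ⌈candidates/32⌉ progeny. Cycle lengths: 19 years
with a progeny test, 6 without — 76 years for four RRS cycles, 50 for
four RRGS cycles.

Genetic progress is 100 × (FFB_end − FFB_0)/FFB_0 on the mean *genetic*
FFB of a reference set of random Deli × La Mé hybrids simulated from the
current candidates (200 by default; using genetic values removes
phenotyping noise from the progress measure), annualized by the scheme
timetable. Method comparisons are paired: within a replicate every
method starts from a clone of the same generation-0 state; endpoint
tables report paired t-tests with Holm correction.

## Problem sizes

The desk preset preserves every ratio of the full design at reduced
size: 60 candidates, 8 selected, 16 crosses (4 slots each), progeny
tests of 60 parents × 2.1 mates × 10 hybrids, 1,200 loci on 16
chromosomes of 100 cM, 200 QTLs per trait, 500 markers, 2 cycles. The
`full_scale` preset restores 120/16/32, 20 hybrids per cross, 16,000
loci, 800 QTLs, 2,250 markers, 4 cycles and 96 restarts. The directional
test suites use 10 paired replicates of the desk preset; the
mate-selection acceptance statistic uses 10 synthetic single-generation
instances solved with 24 restarts each — more than the stated minimum of
10 restarts, chosen as the closest practical approximation of the
full design's 96 restarts.

## The synthetic mate-selection instance

`fixtures.ms_instance` emulates one La Mé generation without running the
whole simulator: 120 candidates in 32 full-sib families whose parents
come from a 24-member base pool (creating full- and half-sib kinship
through the pedigree), EBVs = midparent family value + within-family
deviation at half the family spread (these populations are strongly
family-structured with low within-family variation), BN/BW correlation
−0.7 at realistic half-scale means, and the adaptive threshold computed
exactly as in a simulation cycle. It reproduces the qualitative features
that matter — family clustering under truncation selection, a binding
kinship constraint — but not LD, Mendelian sampling noise in EBVs, or
drift across generations; conclusions drawn from it concern the
optimizer's behaviour, not long-term genetic trends.

## What the synthetic data do and do not show

The generator reproduces the mechanisms the methods depend on —
multiplicative heterosis from mirrored profiles, LD from drift and
bottlenecks, family structure from small founder numbers, inbreeding
accumulation under selection — at desk scale. It is not calibrated to
any real breeding population: Fst between the simulated populations
(~0.15 at desk scale against 0.54 published) and absolute inbreeding
levels depend on locus counts and ancestral depth that are scaled down
for runtime. Directional comparisons between methods are therefore
meaningful; absolute full-scale magnitudes (e.g. multi-decade inbreeding
changes or annual-gain percentages) are not reproduced at this scale.

## Numerical choices and degenerate inputs

Ties in ranking break by ascending id; positions get a nextafter nudge
to stay strictly increasing; monomorphic panels raise errors rather than
returning silent zeros; the LD decay distance comes from a decreasing
isotonic (pool-adjacent-violators) fit of adjacent-pair r² against
distance, interpolated at r² = 0.1; mixed-model solutions assert a
residual norm below 1e-8; Metropolis exponents are clamped to avoid
overflow; all stochastic operations take an explicit generator and all
replicate/restart seeds are spawned from the master seed.

## Known limitations

No dominance or epistasis, no G×E, biallelic loci only, no mutation, no
ROH-based inbreeding, no joint optimization of both parental populations
(the Deli design stays conventional inside a mate-selection run), and
fixed progeny numbers per cross. These mirror the scope of the breeding
question the package addresses; several are natural extensions.
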