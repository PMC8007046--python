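# Methods

This note records the model assumptions, parameter conventions and
numerical choices behind `metdiv`, and what the desk-scale test suite
does and does not establish.

## Spatial simulator (`metdiv.sim`)

**Process.** Cells occupy sites of a 3D integer lattice with the
26-site Moore neighborhood; the founder starts at the origin at t = 0.
Cell *i* divides at rate λ0 · mult_i · ψ_i, where ψ_i is its fraction of
empty neighbors and mult_i = Π(1+s) over inherited drivers; one daughter
keeps the site, the other fills a uniformly chosen empty neighbor. Cells
die at rate μ and vacate their site. Time is in days; λ0 = 0.25
corresponds to a four-day cell cycle, and ρ = μ/λ0 is the
death-to-birth ratio (0.72 fast growth, 0.99 slow).

**Event loop.** An exact stochastic simulation via Poisson thinning:
waiting times are drawn at the bound rate λ0·max_mult·n + μ·n; proposed
births pick a uniform alive cell and accept with probability
mult_i·ψ_i/max_mult (max_mult is the running maximum multiplier, which
never decreases, so the bound stays valid). This is equivalent in law to
a per-cell-rate Gillespie loop. Hot loops are numba-compiled; all
randomness flows through an explicit xoshiro256++ state seeded from the
run seed (metastases use child streams derived from (seed, seeding
index), so adding one metastasis never perturbs another).

**Mutations.** Each newborn daughter gains one passenger with
probability u (Bernoulli; a Poisson(u) option exists behind
`mutation_model="poisson"`) and one driver with probability u_b, with
selection coefficient drawn from Gaussian(s, s/2) truncated at zero by
resampling (a plain Gaussian has negative mass; drivers are beneficial
by definition). Variants follow the infinite-allele convention: ids are
unique; genomic coordinates (passengers uniform over 5·10⁷, drivers over
2·10⁵) are bookkeeping labels and may collide.

**Seeding.** When the primary first reaches I·N_s cells (I = 1, 2, …),
the next-born cell disseminates: it is recorded with its full genotype
and never occupies the lattice (its would-be site stays vacant and
neighbor densities update immediately). A primary of N_final = I_max·N_s
therefore yields exactly I_max seeding events. Metastases grow on fresh
lattices with ρ_met = 0.72 and all other parameters inherited; extinct
attempts (probability ≈ ρ_met per attempt) are refounded from the same
genotype with a fresh RNG stream, up to 100 retries, and the retry count
is logged.

**Lattice geometry.** The bulk of the tumor equilibrates at occupancy
≈ (1−ρ): deaths open sites at rate μ per occupied site and empty sites
refill at rate ≈ λ0 per occupied neighbor fraction. The growth front is
diffuse, so the box is sized for half that density and transparently
re-allocated (positions remapped) if the tumor ever touches a wall.
A consequence worth noting: a fixed-radius sphere contains ~(1−ρ)× as
many cells as at full packing (see Sampling below).

**Degenerate inputs.** ρ ≥ 1 without drivers is subcritical and warns at
configuration time; extinction raises a typed error carrying the partial
registry; intra-tumoral migration is fixed at zero and rejected if set.

## Genealogy (`metdiv.genealogy`)

The clonal tree is the directed graph of birth events. Descendant counts
over an *observation set* are accumulated in one reverse-birth-order
pass; a cell counts itself when observed. Detectable ancestors at
threshold *a* are cells with observed-descendant fraction ≥ *a*; with
heterozygous variants, VAF thresholds α and γ become CCF cutoffs 2α and
2γ. The MRDA of a seeding cell is the deepest detectable ancestor on its
root path (the founder, at fraction 1, guarantees existence).

Two observation sets are exposed deliberately: all cells alive at
observation (the tree-theoretic default), and the sampled population
(the sequencing-visible cells). The series produced by the pipeline
carries both (`bmd_variants` vs `bmd_variants_sampled`, etc.). For
regressions of *measured* divergence on tree quantities, the sampled
variant is the apples-to-apples choice, and it must mirror the pooled
estimator exactly: pooled VAFs average regions with equal (depth)
weight irrespective of region size, so the index weights each sampled
cell by Σ 1/(n_regions·|region|) over the regions containing it — the
descendant-weight fraction of a cell then equals the expected pooled
cancer-cell fraction of its variants. Without this, subclones
concentrated in a few large regions are tree-detectable yet pool below
threshold, leaving persistent offsets; and using the full-population
definition adds spatial-sampling mismatch outright. At desk scale these
choices matter a great deal (R² 0.45 unweighted-full vs ~0.85
weighted-sampled in the weak-selection batches); at full scale the
signal range dwarfs them.

The tree B_p is variant-weighted: the sum of per-edge variant counts
over the genealogy of detectable ancestors at 2γ, minus the
founder→MRDA(2γ) branch of the seeding cell. Variants notionally private
to the founder's own birth are excluded (the founder's clonal background
is implicit; its definition in real data is fuzzy anyway). An edge-count
(generations) version of B_md is reported alongside the variant count.

## Sampling and sequencing (`metdiv.seq`)

Regions are spheres centered on uniformly chosen occupied sites; overlap
is allowed (a disjoint flag exists). The reference condition is **~1000
cells per region**: radius 6.3 lattice units achieves that at full
packing, but this lattice equilibrates near 20% occupancy, so the
default pipeline scales the radius per tumor from the measured bulk
density (median-radius estimator) to keep the cell count at the
reference value; `sample_regions` itself takes any radius. Surface
regions naturally run smaller; no resampling is done.

Depth per (variant, region) is NegBinom with mean m_d = 100 and **size**
parameter σ_d = 10 (variance m_d + m_d²/σ_d = 1100) — "dispersion" is
read as the size parameter, the convention of the depth model the
simulator emulates. Alt reads are Binomial(D, F) with F = carrier
fraction / 2. D = 0 gives an undefined frequency, recorded as 0 (variant
not seen). Pooled frequencies are read-count pools ΣM/ΣD across regions.
B_m/B_p use strict inequalities (f > γ for presence, f < α for absence).
Hudson-style Fst sums the per-variant numerator and denominator over the
variants observed in either region before taking the ratio; pairs with
zero denominator are reported missing and skipped by the mean.

## Analytic model (`metdiv.analytic`)

Non-spatial supercritical birth–death growth, conditioned on survival;
the seeding cell's variant count *k* is the dissemination clock. The
expected population when the j-th lineage variant appears follows from
exponential inter-variant waiting times (rate uλ) and the conditioned
size N(t) = e^{rt}/ρ − (1/ρ−1)e^{−rt} with net growth rate r = λ−μ;
multiplying by u gives the order map g(j) = u·(e^{−x} + 2sinh(x)/ρ),
x = (1−ρ)j/u. The detectability of the j-th variant at frequency
threshold f is d_j = base^{g(j)} with base = u/(u − log(1+(ρ−1)f));
d_0 is pinned to exactly 1 (the founder variant is clonal), which makes
the telescoping pmf Pr[B_md = k−j] = d_j − d_{j+1} sum to 1 exactly and
the direct expectation sum agree with the pmf mean to machine precision.
Computations run in log space; g overflows harmlessly to d = 0. The
domain requires f < 1/(1−ρ) and f ∈ (0,1).

**Multi-type mixture.** Advantageous types form a nested chain (type i a
subtype of i−1), each with its own ρ_i, introduction clock T_i and final
fraction f_i. Seeding weights over extant types follow one of three
scenarios: all mass on the newest type; proportional to type birth rates
(default λ_i ∝ 1/ρ_i, i.e. advantage at a common death rate — explicit
birth rates can be supplied); or proportional to expected (exclusive)
type sizes from the conditioned growth law evaluated on the k-clock.
Conditioned on the type, the neutral expectation applies with clock
k − T_i and threshold rescaled to the sub-population (2α/f_i inside type
i; 2α/(1−f_1) for the original type). The chain generalization simply
applies the same rescaling per type — the chosen reading of an extension
the source model leaves open. When a rescaled threshold reaches 1 the
sub-population cannot host a detectable variant at all; that branch
degenerates to B_md = K exactly (with a warning) rather than erroring,
which is required to evaluate B_p-level thresholds (2γ/(1−f_1) > 1 for
large f_1). Introduction times given as population sizes convert to the
k-clock by inverting N (`size_to_k`). The reported std is the full
mixture std; `origination_variance` isolates the between-type component,
which is exactly zero under the deterministic most-advanced scenario.

The expected primary-specific branch is B_p = |M| − k + B_md(γ), with
|M| (the count of substantially present variants) supplied by the
caller; negative values are clamped to 0 with a warning.

## Series statistics (`metdiv.series`)

Running mean/std use centered windows (default 20 events) with truncated
edges. Variance-explained is plain OLS (statsmodels) with a 95% slope
CI. Heteroscedasticity along seeding order is White's test on the
squared residuals of y ~ order. Subclonal expansions are cells whose
descendants reach ≥ 5% of the final *sampled* population; nested
qualifying ancestors each count. The zigzag filter keeps reversals
exceeding 10% of the preceding extremum (both defaults configurable).
Valleys are positions where the observed running mean falls below the 5%
quantile envelope of running means of value-shuffled series (1000
shuffles); the literal alternative reading — below 0.05× the randomized
mean — is available behind a flag. The expansion/drop co-occurrence test
circularly shifts each interval independently within the size-fraction
domain above 0.2, preserving interval lengths and count, and reports the
one-sided enrichment p-value with the +1 correction.

## Scaled study conditions and what the tests show

The reference experiments (`metdiv.experiments`) run primaries of 10⁵
cells seeding every 2.5·10³ (40 events), metastases of 5·10⁴, five
replicate seeds per growth mode — a deliberate scale-down of the
full-size setting (10⁷ cells, 400 metastases) chosen so the whole suite
runs on one CPU in minutes. Consequences to keep in mind:

* Seeding-cell lineages are ~10× shorter (k ≈ 5–25 variants), so
  percent-of-variance statements are noisier and thinning noise
  (Bernoulli u per division) is relatively larger.
* Subclonal sweeps have less time to spread. The mean detectable
  fraction of seeding-cell variants under s ∈ {0.1, 0.2} comes out near
  40% at this scale, whereas at full scale — where the detectable trunk
  dominates a much longer lineage, and stronger-selection regimes also
  enter the average — a majority of the lineage is detectable. The
  acceptance suite states the majority claim as-is and the shortfall is
  a scale effect, not a measurement choice.
* The well-mixed simulation cross-check of the closed-form model agrees
  in rank and overall magnitude (ratio ~0.6–1 at N = 4000); the closed
  form is an asymptotic approximation (deterministic order map,
  infinite-population detectability) and is not expected to match small
  populations to sampling error.

The synthetic data generator *is* the spatial simulator; what passing
tests show is internal consistency of measurement, tree reconstruction
and closed-form expectations under the model's assumptions (monoclonal
seeding, heterozygous diploid variants, fair detection above α, no
purity/ploidy confounding, no intra-tumoral migration). They do not
validate those assumptions against real sequencing data.
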