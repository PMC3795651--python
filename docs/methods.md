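# Methods

## Demographic model

The unit of analysis is a single closed diploid population whose
inbreeding effective size changed exponentially from an ancestral stable
size `N_stbl` to the current size `N_crnt` over a span `Tfa`:

    N(t) = N_crnt * exp[(t / T) * ln(N_stbl / N_crnt)],   0 <= t <= T,

with `t` measured backward from the present in generations and
`N(t) = N_stbl` for `t > T`. A founder event layers an island deme on top
of this trajectory: the island is constant at its post-founding size back
to the split time (15 generations by default), spends exactly one
generation at the founder count, and the remaining lineages then transfer
to the source deme. A translocation is the same construction stacked once
more (one generation at `k` founders, instant growth to the island's
current size, sampled one generation after founding). Because every
dataset is drawn from a single deme, the demography seen by the sampled
lineages is always one piecewise-exponential trajectory, and the
time-inhomogeneous coalescent is simulated by inverting the integrated
pair-coalescence intensity epoch by epoch in closed form.

The one-generation founder bottleneck is the minimal event consistent with
a single introduction; longer bottlenecks can be built by stacking
explicit epochs.

**Time units.** The candidate-scenario builder applies the ancestral
decline span (3,155) directly in coalescent generations
(`generation_time = 1.0`). This choice reproduces the island/source
simulation statistics that anchor the scenario set (island
H_E near 0.49 with about 3.6 alleles per locus; source H_E near 0.51 with
about 4.0–4.2); converting the same span through a multi-year generation
time compresses the decline into fewer generations and leaves the demes
visibly more diverse (island H_E near 0.59–0.63 at 2–3 years per
generation). A different generation time can be supplied; it rescales only
the decline, since the founding events are specified in generations.

## Mutation model

Microsatellites evolve by the generalized stepwise model on a bounded
allele-size lattice (2 bp motif, 20–40 bp by default, 11 states).
Mutation counts are Poisson with rate `mu` per generation per gene copy
(default 3.5e-4); each mutation moves the repeat count by `k` steps with
`k ~ Geometric(1 - P)` (default `P = 0.22`; `P = 0` recovers the strict
stepwise model) and an equiprobable sign, and sizes reflect at the lattice
bounds. Reflection (rather than absorption) preserves the configured
allele range; a flag is not needed because bounds are per-locus fields.
On branches long enough that the expected mutation count exceeds 50 times
the state count, the walk has long reached its stationary distribution and
the per-branch step loop is capped at that many draws; this bounds the
cost of deep ancestral branches without changing the sampled tip
distribution.

## Summary statistics

Expected heterozygosity uses Nei's (1978) unbiased estimator
`He = n/(n-1) (1 - sum p_i^2)` with `n` in gene copies. F_IS is reported
two ways: the primary estimator `1 - Ho/Hs` with the Nei–Chesser
small-sample `Hs` (the single-population reduction of the Weir–Cockerham
machinery), and the naive `1 - Ho/He` alongside. Exact Hardy–Weinberg and
genotypic linkage-disequilibrium tests are Monte-Carlo approximations
(gene copies shuffled into diploids; genotype columns permuted across
individuals) with the (k+1)/(N+1) p-value convention; batch sizes are
desk-scale defaults (hundreds of permutations) and configurable. The
null-allele scan is a one-sided homozygote-excess test against the same
permutation null — a presence/absence signal, not a size-class
reconstruction. Raw p-values are reported without multiplicity
correction, matching how such scans are conventionally summarized
("x of 66 pairs significant").

The ABC distance space is a fixed-order 10-vector: across-locus mean and
SD of He, Ho, allele count, allele-size variance, and the M-ratio
`na / (size range / motif + 1)`.

## Size-change inference

Two parameterizations: the full-scale model `(N_crnt, N_stbl, Tfa)` with
normal log10 priors (means/variances (4, 2.25), (4, 2.25), (5, 2.5)), and
the bounded model `(theta, r, tf)` with `theta = 2 N_crnt mu`,
`r = N_crnt / N_stbl`, `tf` in generations scaled by `N_crnt`, uniform on
log10 within (−5, 2), (−5.5, 1.5), (−1, 1). `Tfa` is interpreted in
generations by default (`generation_time = 1.0`), consistent with the
scenario builder; `theta` uses N in diploids as a single constant so the
convention is isolated in one place. A decline is declared when the 95%
highest-density interval of log10 r lies entirely below zero.

**MCMC backend (reference).** Metropolis–Hastings over the demographic
parameters, per-locus log-mutation rates, and per-locus genealogies. The
data term is the stepwise-mutation likelihood of the observed repeat
counts by Felsenstein pruning; the transition kernel is a reflected
single-step walk whose rate matrix is symmetric (outward boundary steps
suppressed), so one eigendecomposition per locus serves every branch
length and the stationary distribution is uniform. Moves: log-scale
random walks on parameters and mutation rates; node-time perturbations
(uniform in the parent/child window; multiplicative for the root); a
time-respecting sibling exchange for topology; a per-locus tree-depth
rescale; a genealogy regeneration move that redraws one locus's tree from
the coalescent prior (accepted on the mutation-likelihood ratio); and a
global scaling move along the `mu x N` ridge (times and sizes by `c`,
mutation rates by `1/c`) whose likelihood and rate-integral terms cancel
exactly, leaving a prior-only acceptance. Default scale is 20,000 steps,
500 recorded points, 3 chains — orders of magnitude below the chain
lengths this model family needs for full convergence, which is why the
Gelman–Rubin report (point PSRF and its 97.5% quantile, flagged above
1.02) accompanies every estimate and non-converged results are returned
flagged rather than discarded. At this scale the posterior is visibly
multimodal (decline and expansion basins) and chains rarely cross between
basins.

**ABC backend (default for estimates).** Rejection sampling: particles
drawn from the log10 priors, datasets simulated at the observed sample
size and locus panel with the reference mutation rate, standardized
Euclidean distance on the summary vector, closest fraction retained
(default 1% of 20,000). Point summaries optionally apply the Beaumont
local-linear regression adjustment (Epanechnikov-weighted), which
substantially reduces prior pull on the mode; quartiles and HDIs come
from the same (adjusted) particle cloud. Posterior modes are KDE argmaxes
(Gaussian KDE, Silverman bandwidth, 512-point grid over the sample range
extended by three bandwidths, lowest-index tie-break) computed on the
log10 scale and transformed back; the HDI is the shortest contiguous
interval over sorted draws, leftmost among ties.

## ABC scenario choice

Four candidate demographies share the island founding (16 founders, 15
generations ago, growth to 271) and the ancestral decline from 10,522,
and differ only in the source's current size: 271, 385, 500, 918. The
reference table draws per-locus nuisance parameters — mutation rates
lognormal around 3.5e-4 (0.2 decades SD) and GSM coefficients Beta around
0.22 (concentration 20) — simulates a 63-diploid island dataset per row,
and records the summary vector. Scenario probabilities are retained-count
shares after rejection (default 0.1%); model choice by rejection counting
is the transparent baseline (a logistic-regression refinement is a
documented extension point). Retained particles of the winning scenario
yield Epanechnikov-weighted posterior summaries of the drawn nuisance
parameters. Duplicating every table row leaves the probabilities
unchanged; zero-variance summary columns are dropped from the distance
with a warning.

Between adjacent candidates the retained-count shares can run close (the
source sizes 385 and 500 produce overlapping island diversity), so the
headline selection in the reproduction script votes over three independent
reference tables rather than trusting a single one; each table is a full
rerun of the same procedure with its own seed.

## Founder forecasting

For each founder count k the forecast simulates replicate datasets from
the translocation demography above (default sample: `min(63, 2k)`
diploids, sampled one generation after founding; both choices are
configurable flags) and records per-replicate across-locus mean He, Ho
and na, plus the island baseline simulated with the same replicate count.
Expected one-generation retention follows Wright's `1 - 1/(2k)` closed
form (plus one generation at the island size), which the simulations
match within Monte-Carlo error. Standard errors use the number of loci as
the sample size (SE across per-locus means). The post-founding size
re-estimate analyzes one randomly selected replicate (seed-controlled)
with the size-change inference stage and reports the mode's relative
reduction against the island's reference size (271).

## Synthetic data

Fixtures are simulation-derived, never frequency-painted: the island-like
dataset is drawn from the strong-bottleneck scenario's coalescent
demography and seeds are resampled until the across-locus mean He lands in
a target band (0.48–0.52 by default; the accepted seed is recorded), so
downstream inference always sees internally consistent genealogical
structure. The mtDNA fixture plants exactly two haplotypes differing at 11
sites with a configurable minor-haplotype count (2 of 63 by default) in a
550 bp control-region-like alignment. The null-allele fixture recodes a
fraction of one locus's heterozygotes as homozygotes — the apparent
signature of a segregating null allele. What the generators do *not*
emulate: genotyping error and allele dropout, missing data (default rate
zero), population structure, linked loci, and selection; tests passing on
these fixtures therefore validate the estimators and the demographic
machinery, not robustness to those artifacts.

## Numerical choices and limitations

* Genepop I/O uses 3-digit coding by default (sizes in bp fit three
  digits), width auto-detected on read; "000"-style codes map to one
  missing sentinel and statistics use per-locus effective sample sizes.
  Multiple POP blocks are concatenated with labels kept.
* Monte-Carlo p-values are conservative at small permutation counts; the
  calibration tests assert the sub-nominal false-positive rate rather
  than exact uniformity.
* Desk-scale rejection-ABC remains prior-influenced for this model family:
  with 12 loci and 63 diploids the (N_crnt, N_stbl, Tfa) likelihood
  surface is ridged, absolute size estimates are wide, and interquartile
  coverage of planted truths sits near — not comfortably above — one half.
  Re-estimated current sizes for freshly founded populations carry
  additional single-replicate variance; their relative reductions are
  qualitative brackets, not point predictions.
* All randomness flows from explicit integer seeds (numpy `SeedSequence`
  spawning; numba kernels seeded per dataset); equal seeds give equal
  results on one platform, and all simulation outputs record their seed.
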