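# msatpop

Coalescent simulation, effective-population-size inference and founder
forecasting for diploid microsatellite data from small, bottlenecked
populations.

## The problem

Island or translocated wildlife populations are often founded by a handful
of animals drawn from a larger source. Managers then face two linked
questions: *how much of the source's genetic diversity did the founders
capture*, and *what happens to diversity if this population is itself used
as a translocation stock*? Summary statistics (expected heterozygosity
H<sub>E</sub>, observed heterozygosity H<sub>O</sub>, alleles per locus
n<sub>a</sub>) describe the present; answering the management questions
requires a demographic model.

`msatpop` implements the full analysis chain for a single closed
population typed at unlinked microsatellite loci:

* **Diversity and disequilibrium statistics** — Nei's unbiased
  H<sub>E</sub>, H<sub>O</sub>, n<sub>a</sub>, Weir–Cockerham-style
  F<sub>IS</sub> with permutation tests, Monte-Carlo exact Hardy–Weinberg
  and linkage-disequilibrium tests, a homozygote-excess scan for
  null-allele signals, a binomial G-test, and haplotype/nucleotide
  diversity for mtDNA alignments.
* **Coalescent simulation** under a piecewise-exponential size history
  N(t) = N_crnt · exp[(t/T) · ln(N_stbl/N_crnt)] with optional founder
  events (a one-generation bottleneck of k diploids followed by instant
  growth), and a generalized stepwise mutation model (GSM): Poisson
  mutations on branches, step sizes k ~ Geometric(1−P), reflecting
  boundaries on the allele-size lattice. The per-locus kernels are
  numba-compiled; a 63-diploid, 12-locus dataset simulates in well under a
  millisecond.
* **Bayesian inference of size change** for (N_crnt, N_stbl, Tfa) with
  normal priors on log₁₀ (means/variances (4, 2.25), (4, 2.25), (5, 2.5))
  or the bounded (θ, r, tf) parameterization with θ = 2·N_crnt·μ and
  r = N_crnt/N_stbl. Two backends share one interface: a
  Metropolis–Hastings sampler over per-locus genealogies (stepwise-mutation
  pruning likelihood) and a rejection-ABC backend with optional
  local-linear regression adjustment. Gelman–Rubin diagnostics (flagging
  97.5% PSRF quantiles above 1.02), KDE posterior modes, quartiles and
  highest-density intervals follow.
* **ABC scenario choice** among four candidate bottleneck scenarios that
  differ only in the source population's current size (271, 385, 500, 918),
  all sharing the island founding event (16 diploids, 15 generations ago,
  instant growth to 271) and the ancestral decline from N_stbl = 10,522.
* **Founder forecasting** — distributions of H<sub>E</sub>, H<sub>O</sub>
  and n<sub>a</sub> for populations founded with 8/16/32/64 individuals
  from the island deme, and re-estimation of the founded population's
  current effective size.

## Worked example

```python
import numpy as np
from msatpop import (FixtureSpec, SimSettings, build_scenarios,
                     diversity_loss_curve, make_ti_like_dataset,
                     summary_vector)

scenario_c = next(s for s in build_scenarios() if s.label == "C")

# a 63-individual, 12-locus island-like dataset
gm = make_ti_like_dataset(FixtureSpec(seed=0))
print("mean He %.3f  mean na %.2f" % tuple(summary_vector(gm)[[0, 4]]))

# founder forecast: 1000 replicates per founder count
curve = diversity_loss_curve(scenario_c.model, list(scenario_c.loci),
                             (8, 16, 32, 64), 1000, SimSettings(seed=7))
for k in curve.k_values:
    print("k=%2d  He %.4f  loss %.1f%%  na %.2f" %
          (k, curve.mean_he(k), 100 * curve.he_loss(k), curve.mean_na(k)))
```

prints

```
mean He 0.491  mean na 3.92
k= 8  He 0.4625  loss 6.3%  na 2.92
k=16  He 0.4788  loss 2.9%  na 3.24
k=32  He 0.4841  loss 1.9%  na 3.46
k=64  He 0.4897  loss 0.7%  na 3.53
```

i.e. a population founded with 16 individuals from the island loses about
3% of its expected heterozygosity (close to Wright's 1/(2k) = 3.1%), while
8 founders cost about 6% of H<sub>E</sub> and lose nearly one allele per
locus — allele loss always runs ahead of heterozygosity loss in a fresh
bottleneck.

A command-line interface mirrors the library
(`msatpop sumstats|simulate|infer|abc|forecast|compare|fixtures`); see
`msatpop --help`.

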