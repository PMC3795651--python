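"""Forecast genetic-diversity loss when founding new populations from a
bottlenecked island source.

A founding event is modeled as one generation at the founder count k
followed by instant growth to the island's current effective size; the
founded deme is sampled one generation after founding.  Per founder count
the distributions of He, Ho and allele number over replicate simulated
datasets are recorded, along with the relative loss against the island
baseline, and optionally the current effective size is re-estimated from
one randomly selected replicate with the size-change inference stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_io import GenotypeMatrix, LocusSpec
from .coalsim import (DemographicModel, SimSettings, _stack_founder_layer,
                      compile_epochs, _sim_dataset_kernel)
from .demog_infer import (FullModelPriors, IntervalSummary, McmcSettings,
                          estimate_sizes)
from .sumstats import summaries_from_tips

__all__ = ["ForecastResult", "found_population", "diversity_loss_curve",
           "ncrnt_after_founding"]


@dataclass
class ForecastResult:
    """Per-founder-count replicate distributions and their losses."""

    k_values: list[int]
    n_replicates: int
    he: dict[int, np.ndarray]          # per-replicate across-locus mean He
    ho: dict[int, np.ndarray]
    na: dict[int, np.ndarray]
    island_he: np.ndarray
    island_ho: np.ndarray
    island_na: np.ndarray
    he_se: dict[int, float]            # SE over loci (per-locus means)
    na_se: dict[int, float]

    def mean_he(self, k: int) -> float:
        return float(np.mean(self.he[k]))

    def mean_na(self, k: int) -> float:
        return float(np.mean(self.na[k]))

    def he_loss(self, k: int) -> float:
        """Relative He loss vs the island baseline, in [0, 1]."""
        base = float(np.mean(self.island_he))
        return max(0.0, 1.0 - self.mean_he(k) / base)

    def na_loss(self, k: int) -> float:
        base = float(np.mean(self.island_na))
        return max(0.0, 1.0 - self.mean_na(k) / base)


def _founded_epochs(model: DemographicModel, k: int,
                    growth_size: float | None,
                    gens_after_founding: float = 1.0):
    """Island trajectory with an extra founded-deme layer on top."""
    fe = model.founder_event
    if fe is None:
        raise ValueError("source model must carry the island founder event")
    island = compile_epochs(model, "island")
    epochs = list(zip(island[0], island[1], island[2]))
    size = growth_size if growth_size is not None else fe.post_found_size
    stacked = _stack_founder_layer(epochs, gens_after_founding, k, size)
    arr = np.asarray(stacked)
    return arr[:, 0].copy(), arr[:, 1].copy(), arr[:, 2].copy()


def _founded_tips(model, loci, k, n_sample, seed, growth_size=None,
                  gens_after_founding=1.0):
    starts, sizes, rates = _founded_epochs(model, k, growth_size,
                                           gens_after_founding)
    mus = np.array([l.mu for l in loci])
    ps = np.array([l.p_gsm for l in loci])
    n_states = np.array([l.n_states for l in loci], dtype=np.int64)
    reps = _sim_dataset_kernel(starts, sizes, rates, 2 * n_sample, mus, ps,
                               n_states, seed % (2**31 - 1) or 1)
    out = np.empty_like(reps)
    for j, locus in enumerate(loci):
        out[:, j] = locus.min_len + reps[:, j] * locus.motif_bp
    return out


def found_population(model: DemographicModel, loci: list[LocusSpec], k: int,
                     settings: SimSettings, growth_size: float | None = None,
                     sample_size: int | None = None,
                     gens_after_founding: float = 1.0) -> GenotypeMatrix:
    """Simulate a genotype dataset from a population founded with ``k``
    diploids drawn from the island deme one generation before present,
    with instant growth to the island's current size.

    The default sample size is ``min(63, 2k)`` diploids.
    """
    if k < 2:
        raise ValueError("need >= 2 founders")
    n_sample = sample_size if sample_size is not None \
        else min(settings.n_sample, 2 * k)
    tips = _founded_tips(model, loci, k, n_sample, settings.seed,
                         growth_size, gens_after_founding)
    calls = tips.reshape(n_sample, 2, len(loci)).transpose(0, 2, 1)
    inds = [f"f{k}_{i + 1}" for i in range(n_sample)]
    return GenotypeMatrix(inds, list(loci), calls,
                          meta={"seed": settings.seed, "k_founders": k})


def _tip_summaries(tips, n_loci):
    """(mean He, mean Ho, mean na, per-locus He, per-locus na) of one
    simulated dataset."""
    s = summaries_from_tips(tips)
    return s[0], s[2], s[4]


def diversity_loss_curve(model: DemographicModel, loci: list[LocusSpec],
                         k_list=(8, 16, 32, 64), n_replicates: int = 1000,
                         settings: SimSettings | None = None,
                         sample_full: bool = False) -> ForecastResult:
    """Replicate distributions of He, Ho and na per founder count.

    The island baseline is simulated with the same replicate count.
    Standard errors use the number of loci as the sample size (per-locus
    means across replicates, SE across loci).  ``sample_full=True`` samples
    the configured ``n_sample`` diploids from the founded deme regardless
    of k.
    """
    if n_replicates < 1:
        raise ValueError("need >= 1 replicate")
    settings = settings or SimSettings()
    rng = np.random.default_rng(settings.seed)
    n_loci = len(loci)
    mus = np.array([l.mu for l in loci])
    ps = np.array([l.p_gsm for l in loci])
    n_states = np.array([l.n_states for l in loci], dtype=np.int64)
    motif = loci[0].motif_bp

    def locus_stats(tips):
        two_n = tips.shape[0]
        he = np.empty(n_loci)
        na = np.empty(n_loci)
        pairs = tips.reshape(two_n // 2, 2, n_loci)
        ho = np.mean(pairs[:, 0, :] != pairs[:, 1, :], axis=0)
        for j in range(n_loci):
            _, counts = np.unique(tips[:, j], return_counts=True)
            p = counts / two_n
            he[j] = two_n / (two_n - 1) * (1.0 - np.sum(p**2))
            na[j] = len(counts)
        return he, ho, na

    # island baseline
    isl_starts, isl_sizes, isl_rates = compile_epochs(model, "island")
    base_he = np.empty(n_replicates)
    base_ho = np.empty(n_replicates)
    base_na = np.empty(n_replicates)
    for r in range(n_replicates):
        reps = _sim_dataset_kernel(isl_starts, isl_sizes, isl_rates,
                                   2 * settings.n_sample, mus, ps, n_states,
                                   int(rng.integers(1, 2**31 - 1)))
        he, ho, na = locus_stats(reps)
        base_he[r], base_ho[r], base_na[r] = he.mean(), ho.mean(), na.mean()

    he_d, ho_d, na_d, he_se, na_se = {}, {}, {}, {}, {}
    for k in k_list:
        starts, sizes, rates = _founded_epochs(model, int(k), None)
        n_sample = settings.n_sample if sample_full \
            else min(settings.n_sample, 2 * int(k))
        hes = np.empty(n_replicates)
        hos = np.empty(n_replicates)
        nas = np.empty(n_replicates)
        he_loci = np.zeros(n_loci)
        na_loci = np.zeros(n_loci)
        for r in range(n_replicates):
            reps = _sim_dataset_kernel(starts, sizes, rates, 2 * n_sample,
                                       mus, ps, n_states,
                                       int(rng.integers(1, 2**31 - 1)))
            he, ho, na = locus_stats(reps)
            hes[r], hos[r], nas[r] = he.mean(), ho.mean(), na.mean()
            he_loci += he
            na_loci += na
        he_loci /= n_replicates
        na_loci /= n_replicates
        he_d[int(k)] = hes
        ho_d[int(k)] = hos
        na_d[int(k)] = nas
        he_se[int(k)] = float(he_loci.std(ddof=1) / math.sqrt(n_loci))
        na_se[int(k)] = float(na_loci.std(ddof=1) / math.sqrt(n_loci))

    return ForecastResult(
        [int(k) for k in k_list], n_replicates, he_d, ho_d, na_d,
        base_he, base_ho, base_na, he_se, na_se,
    )


def ncrnt_after_founding(dataset: GenotypeMatrix,
                         priors: FullModelPriors | None = None,
                         settings: McmcSettings | None = None,
                         reference_n_crnt: float = 271.0):
    """Re-estimate the current effective size from a founded-population
    dataset and report its relative reduction against the island estimate.

    Returns ``(IntervalSummary for N_crnt, relative reduction in [0, 1])``.
    """
    priors = priors or FullModelPriors()
    settings = settings or McmcSettings(backend="abc")
    summaries, report, _ = estimate_sizes(dataset, priors, settings)
    ncrnt = summaries["N_crnt"]
    reduction = max(0.0, 1.0 - ncrnt.mode / reference_n_crnt)
    return ncrnt, reduction
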