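"""Diversity and disequilibrium statistics for microsatellite and mtDNA data.

Implements the classic single-population battery: Nei's unbiased expected
heterozygosity, observed heterozygosity, allele counts, F_IS (Weir &
Cockerham-style small-sample estimator with a permutation test),
Monte-Carlo exact tests for Hardy-Weinberg and pairwise linkage
disequilibrium, a homozygote-excess scan for null-allele signals, a G-test
against a binomial null, haplotype/nucleotide diversity for mtDNA
alignments, and the fixed-order summary-statistic vector used as the ABC
distance space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import MISSING, GenotypeMatrix, HaplotypeAlignment

__all__ = [
    "TestResult",
    "DiversityReport",
    "MtDnaReport",
    "expected_het",
    "observed_het",
    "fis",
    "diversity_report",
    "hwe_test",
    "ld_test",
    "ld_scan",
    "null_allele_scan",
    "gtest_binomial",
    "mtdna_stats",
    "summary_vector",
    "SUMMARY_STAT_NAMES",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_iter: int
    method: str

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < 0.05)


@dataclass
class DiversityReport:
    locus_names: list[str]
    he: np.ndarray
    ho: np.ndarray
    na: np.ndarray
    fis_wc: np.ndarray
    n_copies: np.ndarray

    def overall(self, values: np.ndarray) -> tuple[float, float]:
        v = values[~np.isnan(values)]
        return float(np.mean(v)), float(np.std(v, ddof=1)) if v.size > 1 else 0.0


@dataclass
class MtDnaReport:
    n_seqs: int
    n_haplotypes: int
    segregating_sites: int
    haplotype_diversity: float
    haplotype_diversity_sd: float
    nucleotide_diversity: float
    nucleotide_diversity_sd: float


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------


def expected_het(freqs, n_copies: int) -> float:
    """Nei's (1978) unbiased expected heterozygosity
    ``He = n/(n-1) * (1 - sum p_i^2)`` with n in gene copies."""
    if n_copies < 2:
        raise ValueError("need >= 2 gene copies")
    p = np.asarray(list(freqs.values()) if isinstance(freqs, dict) else freqs,
                   dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must sum to 1")
    return float(n_copies / (n_copies - 1) * (1.0 - np.sum(p**2)))


def _locus_het(gm: GenotypeMatrix, j: int):
    """(He, Ho, na, n_copies, n_typed_individuals) for locus j, NaN-flagged
    when everything is missing."""
    pairs = gm.calls[:, j, :]
    typed = np.all(pairs != MISSING, axis=1)
    n_ind = int(typed.sum())
    if n_ind == 0:
        return math.nan, math.nan, 0, 0, 0
    obs = pairs[typed]
    n_copies = 2 * n_ind
    _, counts = np.unique(obs, return_counts=True)
    p = counts / n_copies
    he = n_copies / (n_copies - 1) * (1.0 - float(np.sum(p**2)))
    ho = float(np.mean(obs[:, 0] != obs[:, 1]))
    return he, ho, int(len(counts)), n_copies, n_ind


def observed_het(gm: GenotypeMatrix):
    """Per-locus observed heterozygosity (fraction of non-missing
    individuals heterozygous) and the across-locus mean."""
    ho = np.array([_locus_het(gm, j)[1] for j in range(gm.n_loci)])
    valid = ho[~np.isnan(ho)]
    return ho, float(np.mean(valid)) if valid.size else math.nan


# ---------------------------------------------------------------------------
# F_IS
# ---------------------------------------------------------------------------


def _fis_components(pairs: np.ndarray):
    """Per-locus (Ho_hat, Hs_hat) with the Nei & Chesser small-sample
    correction; Hs is the within-population gene diversity Genepop's
    Weir-Cockerham F_IS reduces to for a single population."""
    typed = np.all(pairs != MISSING, axis=1)
    obs = pairs[typed]
    n = obs.shape[0]
    if n == 0:
        return math.nan, math.nan
    _, counts = np.unique(obs, return_counts=True)
    p = counts / (2 * n)
    ho = float(np.mean(obs[:, 0] != obs[:, 1]))
    hs = n / (n - 1) * (1.0 - float(np.sum(p**2)) - ho / (2 * n)) if n > 1 \
        else math.nan
    return ho, hs


def fis(gm: GenotypeMatrix, n_perm: int = 999, rng=None):
    """Per-locus and overall F_IS with permutation p-values.

    Returns ``(per_locus_wc, per_locus_naive, overall_wc, overall_naive,
    TestResult)``.  The primary estimator is the Weir-Cockerham-style
    ``1 - Ho/Hs`` with small-sample-corrected Hs; the heuristic
    ``1 - Ho/He`` is reported alongside.  The overall value is a ratio of
    across-locus averages.  Significance of the overall heterozygote
    deficit is assessed by permuting gene copies among individuals within
    each locus (one-sided, deficit direction), with the (k+1)/(N+1)
    convention.
    """
    if gm.n_individuals < 2:
        raise ValueError("need >= 2 individuals")
    rng = np.random.default_rng(rng)

    def overall_fis(calls):
        hos, hss = [], []
        for j in range(calls.shape[1]):
            ho, hs = _fis_components(calls[:, j, :])
            if not math.isnan(hs) and hs > 0:
                hos.append(ho)
                hss.append(hs)
        if not hss:
            return math.nan
        return 1.0 - np.mean(hos) / np.mean(hss)

    per_wc, per_naive = [], []
    for j in range(gm.n_loci):
        ho, hs = _fis_components(gm.calls[:, j, :])
        he = _locus_het(gm, j)[0]
        per_wc.append(1.0 - ho / hs if hs and not math.isnan(hs) and hs > 0
                      else math.nan)
        per_naive.append(1.0 - ho / he if he and not math.isnan(he) and he > 0
                         else math.nan)

    obs_fis = overall_fis(gm.calls)
    k = 0
    for _ in range(n_perm):
        perm = gm.calls.copy()
        for j in range(gm.n_loci):
            pairs = perm[:, j, :]
            typed = np.all(pairs != MISSING, axis=1)
            copies = pairs[typed].ravel()
            copies = rng.permutation(copies)
            perm[typed, j, :] = copies.reshape(-1, 2)
        if overall_fis(perm) >= obs_fis:
            k += 1
    p = (k + 1) / (n_perm + 1)
    ho_mean = np.nanmean([_fis_components(gm.calls[:, j, :])[0]
                          for j in range(gm.n_loci)])
    test = TestResult(obs_fis, p, n_perm, "permutation (heterozygote deficit)")
    he_all = np.array([_locus_het(gm, j)[0] for j in range(gm.n_loci)])
    overall_naive = 1.0 - ho_mean / np.nanmean(he_all)
    return (np.array(per_wc), np.array(per_naive), obs_fis,
            float(overall_naive), test)


def diversity_report(gm: GenotypeMatrix) -> DiversityReport:
    he, ho, na, nc = [], [], [], []
    for j in range(gm.n_loci):
        h, o, a, c, _ = _locus_het(gm, j)
        he.append(h)
        ho.append(o)
        na.append(a)
        nc.append(c)
    per_wc, _, _, _, _ = fis(gm, n_perm=0) if gm.n_individuals >= 2 else (
        np.full(gm.n_loci, np.nan),) * 5
    return DiversityReport([l.name for l in gm.loci], np.array(he),
                           np.array(ho), np.array(na, dtype=float), per_wc,
                           np.array(nc))


# ---------------------------------------------------------------------------
# Monte-Carlo exact tests
# ---------------------------------------------------------------------------


def _genotype_log_prob(pairs: np.ndarray) -> float:
    """Log conditional probability of the genotype array given its allele
    counts (Levene): the exact-test ordering statistic."""
    n = pairs.shape[0]
    a = np.sort(pairs, axis=1)
    het = int(np.sum(a[:, 0] != a[:, 1]))
    _, geno_counts = np.unique(a, axis=0, return_counts=True)
    _, allele_counts = np.unique(a.ravel(), return_counts=True)
    lg = math.lgamma(n + 1) - math.lgamma(2 * n + 1) + het * math.log(2.0)
    lg += float(np.sum([math.lgamma(c + 1) for c in allele_counts]))
    lg -= float(np.sum([math.lgamma(c + 1) for c in geno_counts]))
    return lg


def hwe_test(gm: GenotypeMatrix, locus: int, n_reps: int = 2000,
             rng=None) -> TestResult:
    """Monte-Carlo exact test of Hardy-Weinberg proportions at one locus.

    Gene copies are shuffled into diploids; the p-value is the fraction of
    shuffles whose conditional genotype probability is <= the observed one
    ((k+1)/(N+1) convention).  Monomorphic loci return p = 1.
    """
    pairs = gm.calls[:, locus, :]
    typed = np.all(pairs != MISSING, axis=1)
    obs = pairs[typed]
    if obs.size == 0 or len(np.unique(obs)) < 2:
        return TestResult(math.nan, 1.0, 0, "exact HWE (monomorphic)")
    rng = np.random.default_rng(rng)
    stat = _genotype_log_prob(obs)
    copies = obs.ravel()
    k = 0
    for _ in range(n_reps):
        perm = rng.permutation(copies).reshape(-1, 2)
        if _genotype_log_prob(perm) <= stat + 1e-12:
            k += 1
    return TestResult(stat, (k + 1) / (n_reps + 1), n_reps, "MC exact HWE")


def _g_stat(table: np.ndarray) -> float:
    """G statistic of independence for a contingency table."""
    table = table.astype(float)
    total = table.sum()
    exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    mask = table > 0
    return float(2.0 * np.sum(table[mask] * np.log(table[mask] / exp[mask])))


def ld_test(gm: GenotypeMatrix, locus_pair: tuple[int, int],
            n_perm: int = 1000, rng=None) -> TestResult:
    """Monte-Carlo test of genotypic linkage disequilibrium for one locus
    pair: G statistic on the two-locus genotype contingency table, null
    distribution by permuting one locus's genotypes across individuals.
    Pairs with fewer than 5 jointly typed individuals are flagged NA.
    """
    i, j = locus_pair
    a = np.sort(gm.calls[:, i, :], axis=1)
    b = np.sort(gm.calls[:, j, :], axis=1)
    typed = np.all(a != MISSING, axis=1) & np.all(b != MISSING, axis=1)
    a, b = a[typed], b[typed]
    if a.shape[0] < 5:
        return TestResult(math.nan, math.nan, 0, "LD (insufficient data)")
    rng = np.random.default_rng(rng)
    _, acode = np.unique(a, axis=0, return_inverse=True)
    _, bcode = np.unique(b, axis=0, return_inverse=True)
    na, nb = acode.max() + 1, bcode.max() + 1
    if na < 2 or nb < 2:
        return TestResult(0.0, 1.0, 0, "LD (monomorphic)")

    def table(x, y):
        t = np.zeros((na, nb))
        np.add.at(t, (x, y), 1)
        return t

    g_obs = _g_stat(table(acode, bcode))
    k = 0
    for _ in range(n_perm):
        if _g_stat(table(acode, rng.permutation(bcode))) >= g_obs - 1e-12:
            k += 1
    return TestResult(g_obs, (k + 1) / (n_perm + 1), n_perm, "MC genotypic LD")


def ld_scan(gm: GenotypeMatrix, n_perm: int = 500, alpha: float = 0.05,
            rng=None):
    """All pairwise LD tests; returns (results dict, n significant)."""
    rng = np.random.default_rng(rng)
    results = {}
    n_sig = 0
    for i in range(gm.n_loci):
        for j in range(i + 1, gm.n_loci):
            r = ld_test(gm, (i, j), n_perm=n_perm, rng=rng)
            results[(i, j)] = r
            if not math.isnan(r.p_value) and r.p_value < alpha:
                n_sig += 1
    return results, n_sig


def null_allele_scan(gm: GenotypeMatrix, n_reps: int = 1000, rng=None):
    """Homozygote-excess scan for null-allele signals.

    For every locus, the observed homozygote count is compared with its
    Hardy-Weinberg permutation distribution (gene copies shuffled into
    diploids).  Returns a list of dicts with a one-sided Monte-Carlo
    p-value, a z-score, and a flag at p < 0.05.  Monomorphic loci are
    never flagged.
    """
    rng = np.random.default_rng(rng)
    out = []
    for j, locus in enumerate(gm.loci):
        pairs = gm.calls[:, j, :]
        typed = np.all(pairs != MISSING, axis=1)
        obs = pairs[typed]
        if obs.size == 0 or len(np.unique(obs)) < 2:
            out.append({"locus": locus.name, "z": 0.0, "p_value": 1.0,
                        "flag": False})
            continue
        hom_obs = int(np.sum(obs[:, 0] == obs[:, 1]))
        copies = obs.ravel()
        sims = np.empty(n_reps)
        for r in range(n_reps):
            perm = rng.permutation(copies).reshape(-1, 2)
            sims[r] = np.sum(perm[:, 0] == perm[:, 1])
        p = (np.sum(sims >= hom_obs) + 1) / (n_reps + 1)
        sd = sims.std(ddof=1)
        z = (hom_obs - sims.mean()) / sd if sd > 0 else 0.0
        out.append({"locus": locus.name, "z": float(z), "p_value": float(p),
                    "flag": bool(p < 0.05)})
    return out


def gtest_binomial(k: int, n: int, p0: float) -> TestResult:
    """Likelihood-ratio G-test of a binomial proportion against p0.

    ``G = 2 [k ln(k/(n p0)) + (n-k) ln((n-k)/(n (1-p0)))]``; terms with a
    zero count contribute 0; p from chi-square with 1 df.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k outside [0, n]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    g = 0.0
    if k > 0:
        g += k * math.log(k / (n * p0))
    if n - k > 0:
        g += (n - k) * math.log((n - k) / (n * (1.0 - p0)))
    g *= 2.0
    p = float(stats.chi2.sf(g, df=1))
    return TestResult(g, p, 0, "G-test vs binomial")


# ---------------------------------------------------------------------------
# mtDNA
# ---------------------------------------------------------------------------


def mtdna_stats(aln: HaplotypeAlignment) -> MtDnaReport:
    """Haplotype and nucleotide diversity of an mtDNA alignment.

    S counts variable sites (gaps/N excluded as states); H is the unbiased
    haplotype diversity ``n/(n-1) (1 - sum q_j^2)``; pi is the mean
    pairwise difference per site, excluding gap/N positions pairwise.
    SDs follow the standard large-sample formulas (Nei 1987).
    """
    n = aln.n_seqs
    if n < 2:
        raise ValueError("need >= 2 sequences")
    arr = aln.as_array()
    valid = np.isin(arr, [b"A", b"C", b"G", b"T"])

    s_sites = 0
    for col in range(aln.length):
        states = np.unique(arr[valid[:, col], col])
        if len(states) > 1:
            s_sites += 1

    _, hap_counts = np.unique(arr.view(f"S{aln.length}").ravel(),
                              return_counts=True)
    q = hap_counts / n
    h = n / (n - 1) * (1.0 - float(np.sum(q**2)))
    # Nei (1987) eq. 8.12 variance of haplotype diversity
    var_h = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (float(np.sum(q**3)) - float(np.sum(q**2)) ** 2)
        + float(np.sum(q**2)) - float(np.sum(q**2)) ** 2
    )

    diffs = []
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            nsite = int(both.sum())
            if nsite == 0:
                continue
            d = int(np.sum(arr[i, both] != arr[j, both]))
            diffs.append(d / nsite)
    pi = float(np.mean(diffs)) if diffs else 0.0
    # Nei (1987) eq. 10.7 (no-recombination sampling variance, per site)
    var_pi = ((n + 1) / (3 * (n - 1)) * pi / aln.length
              + 2 * (n**2 + n + 3) / (9 * n * (n - 1)) * pi**2)
    return MtDnaReport(
        n_seqs=n,
        n_haplotypes=int(len(hap_counts)),
        segregating_sites=int(s_sites),
        haplotype_diversity=float(h),
        haplotype_diversity_sd=float(math.sqrt(max(var_h, 0.0))),
        nucleotide_diversity=pi,
        nucleotide_diversity_sd=float(math.sqrt(max(var_pi, 0.0))),
    )


# ---------------------------------------------------------------------------
# ABC summary vector
# ---------------------------------------------------------------------------

SUMMARY_STAT_NAMES = (
    "he_mean", "he_sd", "ho_mean", "ho_sd", "na_mean", "na_sd",
    "sizevar_mean", "sizevar_sd", "mratio_mean", "mratio_sd",
)


def summaries_from_tips(tips: np.ndarray, motif_bp: int = 2) -> np.ndarray:
    """Summary vector from a ``(2n, n_loci)`` array of allele sizes (bp),
    gene copies paired consecutively into diploids.  Fast path used when
    building ABC reference tables."""
    two_n, n_loci = tips.shape
    n = two_n // 2
    he = np.empty(n_loci)
    ho = np.empty(n_loci)
    na = np.empty(n_loci)
    var = np.empty(n_loci)
    mr = np.empty(n_loci)
    pairs = tips.reshape(n, 2, n_loci)
    for j in range(n_loci):
        col = tips[:, j]
        _, counts = np.unique(col, return_counts=True)
        p = counts / two_n
        he[j] = two_n / (two_n - 1) * (1.0 - np.sum(p**2))
        ho[j] = np.mean(pairs[:, 0, j] != pairs[:, 1, j])
        na[j] = len(counts)
        var[j] = np.var(col, ddof=1) if two_n > 1 else 0.0
        span = col.max() - col.min()
        mr[j] = na[j] / (span / motif_bp + 1.0)

    def ms(x):
        return float(np.mean(x)), float(np.std(x, ddof=1)) if n_loci > 1 else 0.0

    vals = []
    for x in (he, ho, na, var, mr):
        vals.extend(ms(x))
    return np.array(vals)


def summary_vector(gm: GenotypeMatrix) -> np.ndarray:
    """Fixed-order summary-statistic vector (see SUMMARY_STAT_NAMES):
    across-locus mean and SD of unbiased He, Ho, allele count, allele-size
    variance, and the M-ratio ``na / (size range / motif + 1)``.

    Missing calls are ignored per locus; two identical datasets always map
    to identical vectors.
    """
    he = np.empty(gm.n_loci)
    ho = np.empty(gm.n_loci)
    na = np.empty(gm.n_loci)
    var = np.empty(gm.n_loci)
    mr = np.empty(gm.n_loci)
    for j, locus in enumerate(gm.loci):
        h, o, a, _, _ = _locus_het(gm, j)
        he[j], ho[j], na[j] = h, o, a
        obs = gm.locus_calls(j)
        var[j] = np.var(obs, ddof=1) if obs.size > 1 else 0.0
        span = obs.max() - obs.min() if obs.size else 0
        mr[j] = a / (span / locus.motif_bp + 1.0) if a else math.nan
    vals = []
    for x in (he, ho, na, var, mr):
        v = x[~np.isnan(x)]
        vals.append(float(np.mean(v)))
        vals.append(float(np.std(v, ddof=1)) if v.size > 1 else 0.0)
    return np.array(vals)
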