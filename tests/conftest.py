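import numpy as np
import pytest

from msatpop import (FixtureSpec, GenotypeMatrix, LocusSpec, default_loci,
                     make_ti_like_dataset)
from msatpop.abc_model_choice import build_scenarios


@pytest.fixture(scope="session")
def ti_fixture():
    """Island-like 63 x 12 dataset (He in the 0.48-0.52 band)."""
    return make_ti_like_dataset(FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def scenario_c():
    return next(s for s in build_scenarios() if s.label == "C")


@pytest.fixture(scope="session")
def panel():
    """Default 12-locus dinucleotide panel."""
    return default_loci(12)


def make_gm(genotypes, locus=None, loci=None):
    """Small GenotypeMatrix from a list of (a, b) pairs (one locus) or a
    list of per-individual lists of pairs (multi-locus)."""
    genotypes = list(genotypes)
    if isinstance(genotypes[0][0], (int, np.integer)):
        genotypes = [[g] for g in genotypes]
    n_loci = len(genotypes[0])
    if loci is None:
        base = locus or LocusSpec("L1", motif_bp=1, min_len=10, max_len=400,
                                  mu=0.0, p_gsm=0.0)
        loci = [
            LocusSpec(f"L{j + 1}", motif_bp=base.motif_bp,
                      min_len=base.min_len, max_len=base.max_len,
                      mu=base.mu, p_gsm=base.p_gsm)
            for j in range(n_loci)
        ]
    calls = np.array(genotypes, dtype=np.int32)
    inds = [f"i{k + 1}" for k in range(len(genotypes))]
    return GenotypeMatrix(inds, loci, calls)
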