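"""Pairwise comparison of posterior size estimates between populations.

Two posterior samples of the same parameter are compared through the
distribution of their difference: draws from each sample are randomly
permuted and paired, and the mean difference with its 95% HDI is
reported.  The difference is called significant when the HDI excludes
zero — the same discrete decision rule as a Bayesian estimate of the null
value "the difference between two estimates is zero".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demog_infer import PosteriorSample, hdi

__all__ = ["ComparisonResult", "compare_posteriors"]


@dataclass
class ComparisonResult:
    param: str
    mean_difference: float
    hdi_low: float
    hdi_high: float
    significant: bool
    n_pairs: int
    hdi_mass: float = 0.95


def _draws(sample, param):
    if isinstance(sample, PosteriorSample):
        if param not in sample.draws:
            raise KeyError(f"parameter {param!r} not in posterior sample")
        return sample.pooled(param)
    return np.asarray(sample, dtype=float).ravel()


def compare_posteriors(a, b, param: str, mass: float = 0.95,
                       rng=None, min_draws: int = 1000) -> ComparisonResult:
    """Difference distribution a - b for one parameter.

    ``a`` and ``b`` are :class:`PosteriorSample` objects (sharing the
    parameter label) or plain draw arrays with >= ``min_draws`` draws each.
    """
    xa = _draws(a, param)
    xb = _draws(b, param)
    if xa.size < min_draws or xb.size < min_draws:
        raise ValueError(f"need >= {min_draws} draws per sample")
    rng = np.random.default_rng(rng)
    n = min(xa.size, xb.size)
    diff = rng.permutation(xa)[:n] - rng.permutation(xb)[:n]
    lo, hi = hdi(diff, mass)
    return ComparisonResult(
        param=param,
        mean_difference=float(diff.mean()),
        hdi_low=lo,
        hdi_high=hi,
        significant=bool(hi < 0.0 or lo > 0.0),
        n_pairs=int(n),
        hdi_mass=mass,
    )
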