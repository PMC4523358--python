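"""Independent oracles used by the test suite.

These deliberately avoid the package's own fast paths: the marginal
likelihood is recomputed by exhaustive summation over latent seed counts
(organized as a forward pass over the gut-load distribution), and the
compound-thinning law by direct enumeration.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom, poisson

from seedpassage.model import (
    ParameterSet,
    detection_probability,
    effective_excretion_probability,
    excretion_probability,
    germination_probability_curve,
    germination_sample_probability,
)


def brute_force_marginal_loglik(
    ntot, times, deltas, defec, y, g, wd, wg, params: ParameterSet, species, plant,
    cap_extra: int = 40,
) -> float:
    """Exact log P(Y, G | defec) by summing over every latent configuration.

    The sum over (nt0, nf_t, nfd_t) is organized as a forward recursion on
    the gut-load distribution; the per-interval observation factor sums the
    dissection/count/germination probabilities over nfd explicitly.
    """
    a, b, c = params.excretion[(species, plant)]
    pviz = params.pviz[(species, plant)]
    g0, g1 = params.germination[(species, plant)]
    times = np.asarray(times, dtype=float)
    pex = excretion_probability(a, b, c, times)
    pexeff = effective_excretion_probability(
        np.asarray(defec), pex, np.asarray(deltas, dtype=float), warn_on_clamp=False
    )
    lam = detection_probability(pviz)
    pgerm = germination_probability_curve(g0, g1, times)

    cap = int(ntot) + cap_extra
    n_ax = np.arange(cap + 1)
    w = poisson.pmf(n_ax, ntot)  # distribution of the initial load
    for t in range(len(times)):
        nf_grid, nfd_grid = np.meshgrid(n_ax, n_ax, indexing="ij")
        valid = nfd_grid <= nf_grid
        factor = binom.pmf(nfd_grid, nf_grid, wd[t]) * binom.pmf(y[t], nfd_grid, lam)
        if wg[t] > 0:
            pg = germination_sample_probability(pgerm[t], wg[t])
            rest = np.where(valid, nf_grid - nfd_grid, 0)
            factor = factor * binom.pmf(g[t], rest, pg)
        elif g[t] > 0:
            factor = factor * 0.0
        factor = np.where(valid, factor, 0.0)
        obs = factor.sum(axis=1)  # P(obs at t | nf)
        trans = binom.pmf(np.meshgrid(n_ax, n_ax, indexing="ij")[1],
                          np.meshgrid(n_ax, n_ax, indexing="ij")[0], pexeff[t])
        weighted = trans * obs[None, :]
        new = np.zeros(cap + 1)
        for nt_prev in range(cap + 1):
            if w[nt_prev] == 0:
                continue
            nf_r = np.arange(nt_prev + 1)
            new[nt_prev - nf_r] += w[nt_prev] * weighted[nt_prev, : nt_prev + 1]
        w = new
    total = w.sum()
    return float(np.log(total)) if total > 0 else -np.inf


def compound_thinning_pmf(nf: int, p1: float, p2: float, k: int) -> float:
    """P(K = k) for K ~ Binomial(M, p2), M ~ Binomial(nf, p1), by direct
    enumeration over M."""
    return float(sum(
        binom.pmf(m, nf, p1) * binom.pmf(k, m, p2) for m in range(nf + 1)
    ))
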