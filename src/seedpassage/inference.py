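"""Posterior sampling, convergence diagnostics and predictive checks.

The default ("marginal") backend exploits two structural facts about the
model.  First, Poisson splitting collapses every latent count, leaving a
product of Poisson likelihoods for the observed seed and seedling counts
(see :mod:`seedpassage.model`).  Second, conditional on the observed
defecation records, that marginal posterior factorizes into independent
blocks: one small block per animal species (its defecation hazard) and one
per animal species x plant (its excretion quadratic, detection probability
and germination curve).  Each block is sampled with an adaptive random-walk
Metropolis chain whose proposal covariance is tuned during burn-in and
frozen afterwards.

A "latent" backend that samples the discrete seed counts by single-site
Metropolis alongside the parameters is provided for cross-validation on
small instances; it targets the identical posterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import arviz as az
import numba
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, gammaln

from .io import FeedingDataset
from .model import (
    LatentTrajectory,
    ModelSpec,
    ParameterSet,
    complete_data_log_density,
    defecation_probability,
    excretion_probability,
    excretion_weights,
    germination_probability_curve,
)

__all__ = [
    "MCMCSettings",
    "PosteriorDraws",
    "ConvergenceReport",
    "desk_settings",
    "full_settings",
    "run_mcmc",
    "adaptive_metropolis",
    "gelman_rubin",
    "classic_rhat",
    "posterior_predictive_check",
    "InitializationError",
]


class InitializationError(RuntimeError):
    """The posterior density is not finite at the initial state."""


class InsufficientChainsError(ValueError):
    """Convergence diagnostics need at least two chains."""


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler run lengths.  ``n_iter`` counts post-burn-in iterations;
    ``n_iter // thin`` draws are retained per chain."""

    n_chains: int = 3
    n_burnin: int = 20_000
    n_iter: int = 20_000
    thin: int = 10
    seed: int = 0
    backend: str = "marginal"

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least two chains")
        if self.thin < 1 or self.n_iter < self.thin:
            raise ValueError("require thin >= 1 and n_iter >= thin")
        if self.backend not in ("marginal", "latent"):
            raise ValueError("backend must be 'marginal' or 'latent'")

    @property
    def n_draws(self) -> int:
        return self.n_iter // self.thin


def desk_settings(seed: int = 0, backend: str = "marginal") -> MCMCSettings:
    """Workstation-scale defaults: 3 chains x 20k iterations, thinned by 10."""
    return MCMCSettings(3, 20_000, 20_000, 10, seed, backend)


def full_settings(seed: int = 0, backend: str = "marginal") -> MCMCSettings:
    """The original run lengths: 3 chains, 1e6 burn-in + 1e6 iterations
    thinned by 500.  Hours of compute; prefer :func:`desk_settings`."""
    return MCMCSettings(3, 1_000_000, 1_000_000, 500, seed, backend)


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, one (n_chains, n_draws) array per parameter.

    Parameters are stored on their natural scale (hazards positive,
    probabilities in [0, 1]).  ``fixed`` carries any parameter pinned
    during fitting so that a full :class:`ParameterSet` can be rebuilt from
    one draw.
    """

    draws: dict[str, np.ndarray]
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.draws.values()}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent draw shapes: {shapes}")

    @property
    def names(self) -> list[str]:
        return list(self.draws)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated, preserving (chain, iteration) order."""
        return self.draws[name].reshape(-1)

    def parameter_set(self, index: int) -> ParameterSet:
        """Rebuild a full ParameterSet from the ``index``-th stacked draw.

        Random-effect draws (``eps_*``/pair-level scales) are not part of a
        ParameterSet and are skipped.
        """
        population = {"delta", "a", "b", "c", "pviz", "gamma0", "gamma1", "sigma_g"}
        vals = dict(self.fixed)
        vals.update({k: self.stacked(k)[index] for k in self.draws})
        kept = {}
        for name, v in vals.items():
            head = name.split("[")[0]
            if head in population:
                kept[name] = v
            elif head in ("sigma_e", "sigma_d") and "," not in name:
                kept[name] = v
        df = pd.DataFrame({"parameter": list(kept), "value": list(kept.values())})
        return ParameterSet.from_frame(df)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.draws.items():
            for c in range(arr.shape[0]):
                rows.append(pd.DataFrame({
                    "chain": c, "iter": np.arange(arr.shape[1]),
                    "parameter": name, "value": arr[c],
                }))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, fixed: dict | None = None) -> "PosteriorDraws":
        draws = {}
        for name, sub in df.groupby("parameter", sort=False):
            piv = sub.pivot(index="chain", columns="iter", values="value")
            draws[name] = piv.to_numpy()
        return cls(draws=draws, fixed=fixed or {})


@dataclass
class ConvergenceReport:
    """Per-parameter potential scale reduction factors and effective sizes."""

    table: pd.DataFrame  # parameter, rhat, ess
    threshold: float = 1.2

    @property
    def max_rhat(self) -> float:
        return float(self.table["rhat"].max())

    @property
    def passed(self) -> bool:
        return bool((self.table["rhat"] < self.threshold).all())

    @property
    def failing(self) -> list[str]:
        return self.table.loc[self.table["rhat"] >= self.threshold, "parameter"].tolist()

    def __str__(self) -> str:
        verdict = "converged" if self.passed else f"NOT converged: {self.failing}"
        return (
            f"Convergence report (threshold Rhat < {self.threshold}): {verdict}\n"
            f"max Rhat = {self.max_rhat:.4f}\n" + self.table.to_string(index=False)
        )


# ---------------------------------------------------------------------------
# Generic adaptive random-walk Metropolis


def adaptive_metropolis(
    log_post,
    x0: np.ndarray,
    n_burnin: int,
    n_iter: int,
    thin: int,
    rng: np.random.Generator,
    scale0: np.ndarray | None = None,
) -> np.ndarray:
    """Random-walk Metropolis with Haario-style covariance adaptation.

    The proposal covariance is learned from the chain's own history during
    burn-in (scaled by 2.38^2 / d) and frozen afterwards, so the retained
    draws come from a standard Markov chain.  Returns an array of shape
    (n_iter // thin, d).
    """
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    d = x.size
    lp = float(log_post(x))
    if not np.isfinite(lp):
        raise InitializationError(f"log posterior not finite at initial state {x}")
    scale0 = np.ones(d) if scale0 is None else np.asarray(scale0, dtype=float)
    s_d = 2.38**2 / d
    cov = np.diag(scale0**2)
    chol = np.linalg.cholesky(s_d * cov + 1e-12 * np.eye(d))
    mean = x.copy()
    m2 = np.zeros((d, d))
    n_seen = 0
    out = np.empty((n_iter // thin, d))
    kept = 0
    for it in range(n_burnin + n_iter):
        prop = x + chol @ rng.standard_normal(d)
        lp_prop = float(log_post(prop))
        if lp_prop - lp > math.log(rng.random() + 1e-300):
            x, lp = prop, lp_prop
        if it < n_burnin:
            n_seen += 1
            delta = x - mean
            mean += delta / n_seen
            m2 += np.outer(delta, x - mean)
            if n_seen > 2 * d and n_seen % 50 == 0:
                emp = m2 / (n_seen - 1)
                chol = np.linalg.cholesky(
                    s_d * emp + 1e-6 * np.diag(scale0**2) + 1e-12 * np.eye(d)
                )
        else:
            k = it - n_burnin
            if (k + 1) % thin == 0:
                out[kept] = x
                kept += 1
    return out[:kept]


# ---------------------------------------------------------------------------
# Data preparation for the factorized marginal posterior


@dataclass
class _SpeciesDefecData:
    """Sufficient statistics of a species' defecation record: for each
    unique interval length, the number of intervals with and without a
    defecation."""

    species: str
    u_deltas: np.ndarray
    n_defec: np.ndarray
    n_empty: np.ndarray

    @classmethod
    def from_records(cls, species: str, defec: np.ndarray, deltas: np.ndarray):
        u = np.unique(deltas)
        n1 = np.array([(defec[deltas == d] == 1).sum() for d in u], dtype=float)
        n0 = np.array([(defec[deltas == d] == 0).sum() for d in u], dtype=float)
        return cls(species, u.astype(float), n1, n0)


@dataclass
class _PairData:
    species: str
    plant: str
    ntot: np.ndarray  # (nA,)
    defec: np.ndarray  # (nA, T)
    wd: np.ndarray
    wg: np.ndarray
    y: np.ndarray
    g: np.ndarray
    times: np.ndarray  # (T,)
    deltas: np.ndarray
    log_fact_const: float = 0.0
    sum_y: float = 0.0

    def __post_init__(self) -> None:
        self.log_fact_const = -float(
            np.sum(gammaln(self.y + 1)) + np.sum(gammaln(self.g + 1))
        )
        self.sum_y = float(self.y.sum())


def _prepare_blocks(dataset: FeedingDataset):
    grid = dataset.grid
    times = np.asarray(grid.times)
    deltas = np.asarray(grid.deltas)
    species_of = dataset.species_of()

    raw_defec: dict[str, list[np.ndarray]] = {}
    for animal in dataset.animals:
        plant0 = dataset.trials.loc[dataset.trials.animal_id == animal, "plant"].iloc[0]
        cell = dataset.cell_arrays(animal, plant0)
        raw_defec.setdefault(species_of[animal], []).append(cell["defec"])
    defec_blocks = {
        s: _SpeciesDefecData.from_records(
            s, np.concatenate(recs), np.tile(deltas, len(recs))
        )
        for s, recs in raw_defec.items()
    }

    pair_blocks: dict[tuple[str, str], _PairData] = {}
    for (s, plant), sub in dataset.trials.groupby(["species", "plant"], sort=True):
        animals = list(sub["animal_id"])
        cells = [dataset.cell_arrays(a, plant) for a in animals]
        pair_blocks[(s, plant)] = _PairData(
            species=s,
            plant=plant,
            ntot=np.array([dataset.ntot(a, plant) for a in animals], dtype=float),
            defec=np.stack([c["defec"] for c in cells]).astype(float),
            wd=np.stack([c["wd"] for c in cells]),
            wg=np.stack([c["wg"] for c in cells]),
            y=np.stack([c["y"] for c in cells]).astype(float),
            g=np.stack([c["g"] for c in cells]).astype(float),
            times=times,
            deltas=deltas,
        )
    return defec_blocks, pair_blocks


@numba.njit(cache=False)
def _pair_poisson_core(a, b, c, g0, g1, fit_germ, eps, times, deltas,
                       defec, ntot, wd, wg, y, g):  # pragma: no cover - jitted
    """Detection-free part of one species x plant block's Poisson log
    likelihood.

    The counted-seed means factor as ``mu_y = C_it * pviz`` with
    ``C_it = ntot_i q_it WD_it``; this kernel returns
    ``(sum y log C + germination terms, K = sum C)`` so the caller can
    either plug in a fixed detection probability or integrate it out
    against its uniform prior in closed form.  ``eps`` holds one excretion
    deviation per animal (zeros when random effects are off).
    """
    nA, T = defec.shape
    total = 0.0
    K = 0.0
    for i in range(nA):
        surv = 1.0
        for t in range(T):
            tt = times[t]
            x = a + b * tt + c * tt * tt + eps[i]
            pex = 1.0 / (1.0 + math.exp(-x))
            pe = pex * deltas[t]
            if pe > 1.0:
                pe = 1.0
            pe *= defec[i, t]
            q = pe * surv
            surv *= 1.0 - pe
            C = ntot[i] * q * wd[i, t]
            K += C
            if y[i, t] > 0:
                if C <= 0.0:
                    return -np.inf, K
                total += y[i, t] * math.log(C)
            if fit_germ:
                pgerm = 1.0 / (1.0 + math.exp(-(g0 + g1 * tt)))
                mu_g = ntot[i] * q * (1.0 - wd[i, t]) * wg[i, t] * pgerm
                if g[i, t] > 0:
                    if mu_g <= 0.0:
                        return -np.inf, K
                    total += g[i, t] * math.log(mu_g)
                total -= mu_g
    return total, K


def _pair_log_post(theta: np.ndarray, data: _PairData, spec: ModelSpec,
                   fit_germ: bool, pviz_fixed: float | None = None) -> float:
    """Log posterior of one species x plant block.

    When ``pviz_fixed`` is None the detection probability is integrated out
    analytically: with the uniform prior,
    ``int_0^1 p^sy exp(-K p) dp = Gamma(sy+1) P(sy+1, K) / K^(sy+1)``
    (P the regularized lower incomplete gamma), which removes the strongly
    correlated pviz-excretion ridge from the sampled space.
    """
    a, b, c = theta[0], theta[1], theta[2]
    if spec.constrain_curvature and c > 0:
        return -np.inf
    n_core = 5 if fit_germ else 3
    lp = 0.0
    if spec.random_effects == "collapsed":
        # one excretion deviation per animal, scale sampled on the log scale
        log_sig = theta[n_core]
        sig = math.exp(log_sig)
        eps = np.ascontiguousarray(theta[n_core + 1:])
        lp += spec.priors["sigma"].logpdf1(sig) + log_sig
        lp += float(np.sum(-0.5 * (eps / sig) ** 2)) - eps.size * (
            log_sig + 0.5 * math.log(2 * math.pi))
    else:
        eps = np.zeros(data.defec.shape[0])
    g0 = theta[3] if fit_germ else 0.0
    g1 = theta[4] if fit_germ else 0.0
    ll, K = _pair_poisson_core(a, b, c, g0, g1, fit_germ, eps, data.times,
                               data.deltas, data.defec, data.ntot, data.wd,
                               data.wg, data.y, data.g)
    if not np.isfinite(ll):
        return -np.inf
    sy = data.sum_y
    if pviz_fixed is not None:
        if sy > 0 and pviz_fixed <= 0:
            return -np.inf
        ll += sy * math.log(pviz_fixed) - K * pviz_fixed if pviz_fixed > 0 else 0.0
    elif K > 0:
        from scipy.special import gammainc

        trunc = float(gammainc(sy + 1.0, K))
        if trunc <= 0:
            return -np.inf
        ll += math.lgamma(sy + 1.0) + math.log(trunc) - (sy + 1.0) * math.log(K)
    elif sy > 0:
        return -np.inf
    pri = spec.priors
    lp += ll + pri["a"].logpdf1(a) + pri["b"].logpdf1(b) + pri["c"].logpdf1(c)
    if fit_germ:
        lp += pri["gamma0"].logpdf1(g0) + pri["gamma1"].logpdf1(g1)
    return lp


def _recover_pviz_draws(thetas: np.ndarray, data: _PairData, spec: ModelSpec,
                        fit_germ: bool, rng: np.random.Generator) -> np.ndarray:
    """Exact posterior draws of the detection probability given retained
    draws of the excretion state: pviz | rest ~ Gamma(sum Y + 1, rate K)
    truncated to (0, 1), by inverse CDF."""
    from scipy.special import gammainc, gammaincinv

    a0 = float(data.sum_y) + 1.0
    out = np.empty(thetas.shape[0])
    for i, th in enumerate(thetas):
        K = _pair_expected_dissect_rate(th, data, spec, fit_germ)
        u = rng.random()
        if K <= 0:
            out[i] = u ** (1.0 / a0)  # plain power-law posterior on (0, 1)
            continue
        cdf1 = float(gammainc(a0, K))
        if cdf1 <= 0:
            out[i] = 1.0 - 1e-12  # mass pushed against the upper bound
            continue
        out[i] = min(max(float(gammaincinv(a0, u * cdf1)) / K, 1e-12), 1 - 1e-12)
    return out


def _delta_log_post(x: np.ndarray, data: _SpeciesDefecData, spec: ModelSpec) -> float:
    z = float(x[0])
    if z > 20:
        return -np.inf
    delta = math.exp(z)
    ll = 0.0
    for d, n1, n0 in zip(data.u_deltas, data.n_defec, data.n_empty):
        p = -math.expm1(-delta * d)
        if n1 > 0:
            if p <= 0:
                return -np.inf
            ll += n1 * math.log(p)
        ll -= n0 * delta * d
    # Jacobian of the log transform
    return ll + spec.priors["delta"].logpdf1(delta) + z


def _pair_expected_dissect_rate(theta, data: _PairData, spec: ModelSpec,
                                fit_germ: bool) -> float:
    """K = sum_it ntot_i * q_it * WD_it, the factor multiplying pviz in the
    Poisson means of the counted seeds, at the current excretion state."""
    a, b, c = theta[0], theta[1], theta[2]
    n_core = 5 if fit_germ else 3
    if spec.random_effects == "collapsed":
        eps = theta[n_core + 1:][:, None]
    else:
        eps = 0.0
    pex = expit(a + b * data.times + c * data.times**2 + eps)
    pexeff = data.defec * np.clip(pex * data.deltas, 0.0, 1.0)
    q = excretion_weights(pexeff)
    return float(np.sum(data.ntot[:, None] * q * data.wd))


def _finite_start(log_post, x0: np.ndarray, jitter: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Jittered chain start, shrinking the jitter until the density is
    finite (falls back to the unjittered point)."""
    scale = 1.0
    for _ in range(12):
        start = x0 + scale * jitter * rng.standard_normal(x0.size)
        if np.isfinite(log_post(start)):
            return start
        scale *= 0.5
    return np.asarray(x0, dtype=float)


def _map_start(log_post, x0: np.ndarray, bounds=None) -> np.ndarray:
    """Posterior mode by L-BFGS (finite fallback to the supplied start)."""
    def neg(x):
        v = log_post(x)
        return 1e12 if not np.isfinite(v) else -v

    try:
        res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
        if np.isfinite(log_post(res.x)):
            return np.asarray(res.x, dtype=float)
    except Exception:
        pass
    return np.asarray(x0, dtype=float)


def run_mcmc(
    dataset: FeedingDataset,
    spec: ModelSpec | None = None,
    settings: MCMCSettings | None = None,
) -> PosteriorDraws:
    """Sample the posterior of all free parameters.

    With the default marginal backend the posterior factorizes over species
    (defecation hazards) and species x plant blocks (excretion, detection,
    germination), each sampled by adaptive Metropolis from a jittered
    posterior-mode start.  Deterministic given ``settings.seed``.
    """
    spec = spec or ModelSpec()
    settings = settings or desk_settings()
    if settings.backend == "latent":
        return _run_latent_backend(dataset, spec, settings)

    defec_blocks, pair_blocks = _prepare_blocks(dataset)
    fit_defec = "defecation" in spec.components
    fit_counts = "dissection" in spec.components or "excretion" in spec.components
    fit_germ = "germination" in spec.components

    ss = np.random.SeedSequence(settings.seed)
    draws: dict[str, np.ndarray] = {}
    fixed = dict(spec.fixed)

    jobs = []
    if fit_defec:
        for s in sorted(defec_blocks):
            jobs.append(("delta", s))
    if fit_counts:
        for key in sorted(pair_blocks):
            jobs.append(("pair", key))

    children = ss.spawn(len(jobs) * settings.n_chains)
    ci = 0
    for kind, key in jobs:
        if kind == "delta":
            data = defec_blocks[key]
            name = f"delta[{key}]"
            if name in fixed:
                continue
            lp = lambda x, d=data: _delta_log_post(x, d, spec)
            x0 = _map_start(lp, np.array([math.log(0.3)]))
            chains = []
            for _ in range(settings.n_chains):
                rng = np.random.default_rng(children[ci]); ci += 1
                start = _finite_start(lp, x0, np.array([0.2]), rng)
                sam = adaptive_metropolis(lp, start, settings.n_burnin, settings.n_iter,
                                          settings.thin, rng, scale0=np.array([0.3]))
                chains.append(np.exp(sam[:, 0]))
            draws[name] = np.stack(chains)
        else:
            s, plant = key
            data = pair_blocks[key]
            pviz_name = f"pviz[{s},{plant}]"
            pviz_fixed = fixed.get(pviz_name)  # None -> integrated out
            pnames = [f"a[{s},{plant}]", f"b[{s},{plant}]", f"c[{s},{plant}]"]
            if fit_germ:
                pnames += [f"gamma0[{s},{plant}]", f"gamma1[{s},{plant}]"]
            n_core = len(pnames)
            if spec.random_effects == "collapsed":
                n_animals = data.defec.shape[0]
                pnames.append(f"sigma_e[{s},{plant}]")
                pnames += [f"eps_e[{s},{plant},{k}]" for k in range(n_animals)]
            dim = len(pnames)
            full0 = np.array([-7.0, 0.25, -0.004, -3.0, -0.05][:n_core])
            scale_full = np.array([0.5, 0.05, 0.002, 0.5, 0.05][:n_core])
            if spec.random_effects == "collapsed":
                full0 = np.concatenate([full0, [math.log(0.3)],
                                        np.zeros(dim - n_core - 1)])
                scale_full = np.concatenate([scale_full, [0.3],
                                             0.3 * np.ones(dim - n_core - 1)])
            # pin fixed parameters (sampling-scale values) and sample the rest
            for k, nm in enumerate(pnames):
                if nm in fixed:
                    v = fixed[nm]
                    if nm.startswith("sigma_e"):
                        v = math.log(max(v, 1e-12))
                    full0[k] = v
            free_idx = np.array([k for k, nm in enumerate(pnames) if nm not in fixed],
                                dtype=int)
            if free_idx.size == 0:
                continue

            def lp(th_free, d=data, tmpl=full0, idx=free_idx):
                full = tmpl.copy()
                full[idx] = th_free
                return _pair_log_post(full, d, spec, fit_germ, pviz_fixed)

            bounds = []
            for k in free_idx:
                if pnames[k].startswith("c[") and spec.constrain_curvature:
                    bounds.append((None, 0.0))
                else:
                    bounds.append((None, None))
            x0 = _map_start(lp, full0[free_idx], bounds=bounds)
            scale0 = scale_full[free_idx]
            c_pos = np.flatnonzero([pnames[k].startswith("c[") for k in free_idx])
            chains = []
            pviz_chains = []
            for _ in range(settings.n_chains):
                rng = np.random.default_rng(children[ci]); ci += 1
                start = _finite_start(lp, x0, 0.3 * scale0, rng)
                if spec.constrain_curvature and c_pos.size and start[c_pos[0]] > 0:
                    start[c_pos[0]] = -abs(start[c_pos[0]])
                    if not np.isfinite(lp(start)):
                        start = x0
                sam = adaptive_metropolis(lp, start, settings.n_burnin, settings.n_iter,
                                          settings.thin, rng, scale0=scale0)
                chains.append(sam)
                if pviz_fixed is None:
                    full = np.tile(full0, (sam.shape[0], 1))
                    full[:, free_idx] = sam
                    pviz_chains.append(
                        _recover_pviz_draws(full, data, spec, fit_germ, rng))
            stacked = np.stack(chains)  # (chains, draws, n_free)
            for col, k in enumerate(free_idx):
                nm = pnames[k]
                vals = stacked[:, :, col]
                if nm.startswith("sigma_e"):
                    vals = np.exp(vals)
                draws[nm] = vals
            if pviz_fixed is None:
                draws[pviz_name] = np.stack(pviz_chains)

    if not draws:
        raise ValueError("nothing to fit: no components selected or all parameters fixed")
    return PosteriorDraws(draws=draws, fixed=fixed)


# ---------------------------------------------------------------------------
# Latent-count backend (small instances; cross-validates the marginal one)


def _run_latent_backend(dataset: FeedingDataset, spec: ModelSpec,
                        settings: MCMCSettings) -> PosteriorDraws:
    """Metropolis-within-Gibbs over latent counts and parameters.

    Latent updates are single-site integer random walks (window +/- 3)
    respecting the conservation and subsampling support; parameters use the
    same blockwise random-walk moves as the marginal backend but against
    the complete-data density.  Intended for small instances.
    """
    grid = dataset.grid
    times = np.asarray(grid.times)
    deltas = np.asarray(grid.deltas)
    T = len(times)
    species_of = dataset.species_of()
    cells = []
    for _, row in dataset.trials.iterrows():
        cell = dataset.cell_arrays(row.animal_id, row.plant)
        cells.append((row.animal_id, species_of[row.animal_id], row.plant,
                      int(row.ntot), cell))
    fit_germ = "germination" in spec.components

    def make_params(vals: dict[str, float]) -> ParameterSet:
        merged = dict(spec.fixed)
        merged.update(vals)
        df = pd.DataFrame({"parameter": list(merged), "value": list(merged.values())})
        return ParameterSet.from_frame(df)

    free: list[str] = []
    for s in sorted({c[1] for c in cells}):
        free.append(f"delta[{s}]")
    for s, plant in sorted({(c[1], c[2]) for c in cells}):
        free += [f"a[{s},{plant}]", f"b[{s},{plant}]", f"c[{s},{plant}]",
                 f"pviz[{s},{plant}]"]
        if fit_germ:
            free += [f"gamma0[{s},{plant}]", f"gamma1[{s},{plant}]"]
    free = [f for f in free if f not in spec.fixed]
    defaults = {"delta": 0.3, "a": -7.0, "b": 0.25, "c": -0.004, "pviz": 0.5,
                "gamma0": -3.0, "gamma1": -0.05}
    steps = {"delta": 0.1, "a": 0.4, "b": 0.04, "c": 0.002, "pviz": 0.1,
             "gamma0": 0.4, "gamma1": 0.04}

    def total_density(params: ParameterSet, latents) -> float:
        lp = 0.0
        for (animal, s, plant, ntot, cell), lat in zip(cells, latents):
            lp += complete_data_log_density(
                ntot, times, deltas, lat, cell["y"], cell["g"], cell["wd"],
                cell["wg"], params, s, plant, spec=spec,
            )
            if not np.isfinite(lp):
                return -np.inf
        return lp

    ss = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    all_chains: dict[str, list[np.ndarray]] = {f: [] for f in free}
    for chain_seed in ss:
        rng = np.random.default_rng(chain_seed)
        vals = {f: defaults[f.split("[")[0]] * (1 + 0.1 * rng.standard_normal())
                for f in free}
        params = make_params(vals)
        latents = []
        for animal, s, plant, ntot, cell in cells:
            # smallest latent state consistent with the observations
            nf0 = (cell["y"] + cell["g"]).astype(int)
            nt0 = max(ntot, int(nf0.sum()))
            lat = LatentTrajectory(nt0=nt0, defec=cell["defec"].copy(),
                                   nf=nf0, nfd=cell["y"].astype(int).copy())
            latents.append(lat)
        lp = total_density(params, latents)
        if not np.isfinite(lp):
            raise InitializationError("latent backend: non-finite density at start")

        retained = {f: [] for f in free}
        for it in range(settings.n_burnin + settings.n_iter):
            # latent single-site updates
            for lat in latents:
                for fld in ("nt0", "nf", "nfd"):
                    if fld == "nt0":
                        old = lat.nt0
                        lat.nt0 = old + int(rng.integers(-3, 4))
                        lp_new = total_density(params, latents)
                        if lp_new - lp > math.log(rng.random() + 1e-300):
                            lp = lp_new
                        else:
                            lat.nt0 = old
                    else:
                        arr = getattr(lat, fld)
                        for k in range(T):
                            old = arr[k]
                            arr[k] = old + int(rng.integers(-3, 4))
                            lp_new = total_density(params, latents)
                            if lp_new - lp > math.log(rng.random() + 1e-300):
                                lp = lp_new
                            else:
                                arr[k] = old
            # parameter updates, one site at a time
            for f in free:
                head = f.split("[")[0]
                old = vals[f]
                vals[f] = old + steps[head] * rng.standard_normal()
                if head == "delta" and vals[f] <= 0:
                    vals[f] = old
                    continue
                if head == "pviz" and not (0 < vals[f] < 1):
                    vals[f] = old
                    continue
                params_new = make_params(vals)
                lp_new = total_density(params_new, latents)
                if lp_new - lp > math.log(rng.random() + 1e-300):
                    lp, params = lp_new, params_new
                else:
                    vals[f] = old
            if it >= settings.n_burnin and (it - settings.n_burnin + 1) % settings.thin == 0:
                for f in free:
                    retained[f].append(vals[f])
        for f in free:
            all_chains[f].append(np.asarray(retained[f]))

    return PosteriorDraws(draws={f: np.stack(v) for f, v in all_chains.items()},
                          fixed=dict(spec.fixed))


# ---------------------------------------------------------------------------
# Convergence diagnostics


def classic_rhat(chains: np.ndarray) -> float:
    """Original Gelman–Rubin potential scale reduction factor for one
    parameter, ``chains`` of shape (n_chains, n_draws)."""
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    if m < 2:
        raise InsufficientChainsError("classic Rhat needs >= 2 chains")
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b_over_n = means.var(ddof=1)
    if w == 0:
        return 1.0
    var_hat = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_hat / w))


def gelman_rubin(
    draws: PosteriorDraws,
    threshold: float = 1.2,
    method: str = "rank",
) -> ConvergenceReport:
    """Per-parameter Rhat and effective sample size.

    ``method="rank"`` (default) uses the rank-normalized split statistic,
    which is conservative relative to ``method="classic"``, the original
    between/within-variance form.
    """
    if draws.n_chains < 2:
        raise InsufficientChainsError("need >= 2 chains for Rhat")
    if draws.n_draws < 10:
        raise ValueError("need >= 10 retained draws per chain")
    rows = []
    for name, arr in draws.draws.items():
        if method == "rank":
            rhat = float(az.rhat(arr))
        elif method == "classic":
            rhat = classic_rhat(arr)
        else:
            raise ValueError("method must be 'rank' or 'classic'")
        ess = float(az.ess(arr))
        rows.append((name, rhat, ess))
    table = pd.DataFrame(rows, columns=["parameter", "rhat", "ess"])
    return ConvergenceReport(table=table, threshold=threshold)


# ---------------------------------------------------------------------------
# Posterior predictive check


def posterior_predictive_check(
    dataset: FeedingDataset,
    draws: PosteriorDraws,
    rng: np.random.Generator,
    n_rep: int = 200,
) -> pd.DataFrame:
    """Replicate (Y, G) from the fitted model and locate the observations.

    For each of ``n_rep`` posterior draws, simulates replicated counts
    conditional on the observed defecation records and sample weights, and
    reports per animal x plant the tail probability
    ``P(total rep >= total observed)`` for seeds and seedlings.  Values
    near 0 or 1 flag misfit; a correctly specified model gives tails well
    inside (0, 1) wherever counts are informative.
    """
    total = draws.n_chains * draws.n_draws
    idx = rng.choice(total, size=min(n_rep, total), replace=False)
    times = np.asarray(dataset.grid.times)
    deltas = np.asarray(dataset.grid.deltas)
    species_of = dataset.species_of()

    cells = []
    for _, row in dataset.trials.iterrows():
        cell = dataset.cell_arrays(row.animal_id, row.plant)
        cells.append((row.animal_id, species_of[row.animal_id], row.plant,
                      int(row.ntot), cell))

    rep_y = {c[0] + "|" + c[2]: [] for c in cells}
    rep_g = {c[0] + "|" + c[2]: [] for c in cells}
    for i in idx:
        params = draws.parameter_set(int(i))
        for animal, s, plant, ntot, cell in cells:
            a, b, c = params.excretion[(s, plant)]
            pex = excretion_probability(a, b, c, times)
            pexeff = cell["defec"] * np.clip(pex * deltas, 0, 1)
            nt = rng.poisson(ntot)
            y_tot = g_tot = 0
            for k in range(len(times)):
                nf = rng.binomial(nt, pexeff[k]) if nt > 0 else 0
                nt -= nf
                if nf == 0:
                    continue
                nfd = rng.binomial(nf, cell["wd"][k])
                if nfd > 0:
                    y_tot += rng.binomial(nfd, params.pviz[(s, plant)])
                rest = nf - nfd
                if rest > 0 and cell["wg"][k] > 0:
                    g0, g1 = params.germination[(s, plant)]
                    pg = cell["wg"][k] * germination_probability_curve(g0, g1, times[k])
                    g_tot += rng.binomial(rest, min(pg, 1.0))
            rep_y[animal + "|" + plant].append(y_tot)
            rep_g[animal + "|" + plant].append(g_tot)

    rows = []
    for animal, s, plant, ntot, cell in cells:
        key = animal + "|" + plant
        obs_y = int(cell["y"].sum())
        obs_g = int(cell["g"].sum())
        ry = np.asarray(rep_y[key])
        rg = np.asarray(rep_g[key])
        rows.append((animal, s, plant, obs_y, float(np.mean(ry >= obs_y)),
                     obs_g, float(np.mean(rg >= obs_g))))
    return pd.DataFrame(
        rows,
        columns=["animal_id", "species", "plant", "obs_y", "tail_y", "obs_g", "tail_g"],
    )
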