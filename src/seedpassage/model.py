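"""Generative model of seed passage through an ungulate gut.

The joint model has three submodels, chained through latent seed counts for
each animal ``i``, plant ``j`` and collection time ``t``:

* **Excretion** — the initial gut load is ``Nt_0 ~ Poisson(Ntot)``; at each
  collection time the animal defecates with probability
  ``pdef = 1 - exp(-delta_s * dt)`` (a constant per-hour hazard per animal
  species, so probabilities compose correctly over the unequal 3-h / 6-h
  intervals), and the seeds excreted in that interval are
  ``Nf ~ Binomial(Nt_{t-1}, pexeff)`` with
  ``pexeff = defec * pex * dt`` and
  ``pex = logistic(a + b t + c t^2 + eps_e)``.  With ``c < 0`` the
  excretion curve has an interior maximum whose time is the retention-time
  estimate.
* **Dissection** — a weighed subsample of each feces is dissected:
  ``Nfd ~ Binomial(Nf, WD)`` seeds land in it, of which
  ``Y ~ Binomial(Nfd, lambda)`` are actually counted under the
  stereomicroscope, ``lambda = logistic(logit(pviz) + eps_d)``.
* **Germination** — the remaining ``restNf = Nf - Nfd`` seeds may appear as
  seedlings in the germination sample:
  ``G ~ Binomial(restNf, pg)`` with
  ``pg = logistic(logit(WG * pgerm) + eps_g)`` and
  ``pgerm = logistic(gamma0 + gamma1 t)`` (logit-linear in time; a negative
  slope captures the loss of viability with retention time).

Because the initial load is Poisson and every subsequent step is a
binomial thinning, the latent counts can be collapsed exactly (Poisson
splitting): conditional on the defecation record, the counted seeds and
seedlings are independent Poissons,
``Y_t ~ Poisson(Ntot q_t WD lambda)`` and
``G_t ~ Poisson(Ntot q_t (1 - WD) pg)`` with
``q_t = pexeff_t * prod_{u<t} (1 - pexeff_u)``.
:func:`marginalized_observation_likelihood` implements that collapse and is
both the default fitting target and an analytic oracle for the
complete-data density.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterSet",
    "RandomEffects",
    "LatentTrajectory",
    "ModelSpec",
    "PriorSpec",
    "defecation_probability",
    "excretion_probability",
    "effective_excretion_probability",
    "detection_probability",
    "germination_probability_curve",
    "germination_sample_probability",
    "complete_data_log_density",
    "marginalized_observation_likelihood",
    "excretion_quadratic_from_peak",
]

PairKey = tuple[str, str]  # (animal species, plant)


# ---------------------------------------------------------------------------
# Parameters


@dataclass
class ParameterSet:
    """All population-level parameters of the joint model.

    ``excretion[(s, j)] = (a, b, c)`` are the logit-quadratic coefficients
    of the potential excretion probability; ``germination[(s, j)] =
    (gamma0, gamma1)`` the logit-linear germination curve.  All random
    effect dispersions are standard deviations.
    """

    delta: dict[str, float]  # per-hour defecation hazard per species
    excretion: dict[PairKey, tuple[float, float, float]]
    pviz: dict[PairKey, float]  # seed detection probability
    germination: dict[PairKey, tuple[float, float]]
    sigma_e: dict[str, float] = field(default_factory=dict)
    sigma_d: dict[str, float] = field(default_factory=dict)
    sigma_g: float = 0.0

    def __post_init__(self) -> None:
        for s, d in self.delta.items():
            if d < 0:
                raise ValueError(f"delta[{s}] must be >= 0")
        for k, p in self.pviz.items():
            if not (0 <= p <= 1):
                raise ValueError(f"pviz[{k}] must lie in [0, 1]")
        for s in self.sigma_e.values():
            if s < 0:
                raise ValueError("sigma_e must be >= 0")
        for s in self.sigma_d.values():
            if s < 0:
                raise ValueError("sigma_d must be >= 0")
        if self.sigma_g < 0:
            raise ValueError("sigma_g must be >= 0")

    @property
    def species(self) -> list[str]:
        return list(self.delta)

    @property
    def pairs(self) -> list[PairKey]:
        return list(self.excretion)

    # -- flat-table interchange -------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows: list[tuple[str, float]] = []
        for s, v in self.delta.items():
            rows.append((f"delta[{s}]", v))
        for s, v in self.sigma_e.items():
            rows.append((f"sigma_e[{s}]", v))
        for s, v in self.sigma_d.items():
            rows.append((f"sigma_d[{s}]", v))
        rows.append(("sigma_g", self.sigma_g))
        for (s, j), (a, b, c) in self.excretion.items():
            rows += [(f"a[{s},{j}]", a), (f"b[{s},{j}]", b), (f"c[{s},{j}]", c)]
        for (s, j), v in self.pviz.items():
            rows.append((f"pviz[{s},{j}]", v))
        for (s, j), (g0, g1) in self.germination.items():
            rows += [(f"gamma0[{s},{j}]", g0), (f"gamma1[{s},{j}]", g1)]
        return pd.DataFrame(rows, columns=["parameter", "value"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ParameterSet":
        vals = dict(zip(df["parameter"], df["value"]))
        delta, sigma_e, sigma_d = {}, {}, {}
        excretion: dict[PairKey, list[float]] = {}
        pviz: dict[PairKey, float] = {}
        germ: dict[PairKey, list[float]] = {}
        sigma_g = 0.0
        for name, v in vals.items():
            if name == "sigma_g":
                sigma_g = float(v)
                continue
            head, inner = name.split("[", 1)
            inner = inner.rstrip("]")
            if head == "delta":
                delta[inner] = float(v)
            elif head == "sigma_e":
                sigma_e[inner] = float(v)
            elif head == "sigma_d":
                sigma_d[inner] = float(v)
            else:
                s, j = inner.split(",")
                key = (s, j)
                if head in ("a", "b", "c"):
                    excretion.setdefault(key, [0.0, 0.0, 0.0])["abc".index(head)] = float(v)
                elif head == "pviz":
                    pviz[key] = float(v)
                elif head in ("gamma0", "gamma1"):
                    germ.setdefault(key, [0.0, 0.0])[int(head[-1])] = float(v)
                else:
                    raise ValueError(f"unrecognized parameter name {name!r}")
        return cls(
            delta=delta,
            excretion={k: tuple(v) for k, v in excretion.items()},
            pviz=pviz,
            germination={k: tuple(v) for k, v in germ.items()},
            sigma_e=sigma_e,
            sigma_d=sigma_d,
            sigma_g=sigma_g,
        )


@dataclass
class RandomEffects:
    """Random-effect deviations per (animal_id, plant), one value per
    collection time: ``eps_e`` shifts the excretion logit, ``eps_d`` the
    detection logit, ``eps_g`` the germination-sample logit."""

    eps_e: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    eps_d: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    eps_g: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    @classmethod
    def zeros(cls, keys: Iterable[tuple[str, str]], n_times: int) -> "RandomEffects":
        z = {k: np.zeros(n_times) for k in keys}
        return cls({k: v.copy() for k, v in z.items()},
                   {k: v.copy() for k, v in z.items()},
                   {k: v.copy() for k, v in z.items()})

    @classmethod
    def draw(
        cls,
        keys: Iterable[tuple[str, str]],
        species_of: Mapping[str, str],
        n_times: int,
        params: ParameterSet,
        rng: np.random.Generator,
    ) -> "RandomEffects":
        """Draw per-(animal, plant, time) normal deviations at the scales in
        ``params`` (zero scale gives exactly-zero deviations)."""
        re = cls()
        for animal, plant in keys:
            s = species_of[animal]
            re.eps_e[(animal, plant)] = rng.normal(0, params.sigma_e.get(s, 0.0), n_times)
            re.eps_d[(animal, plant)] = rng.normal(0, params.sigma_d.get(s, 0.0), n_times)
            re.eps_g[(animal, plant)] = rng.normal(0, params.sigma_g, n_times)
        return re


@dataclass
class LatentTrajectory:
    """Unobserved seed counts for one animal x plant.

    ``nt0`` is the realized initial gut load; ``nf[t]`` the seeds excreted
    in the whole feces of interval ``t``; ``nfd[t]`` the seeds in the
    dissected sample; ``defec[t]`` the defecation indicator.  Conservation
    ``nt[t] = nt[t-1] - nf[t] >= 0`` holds by construction.
    """

    nt0: int
    defec: np.ndarray  # (T,) int {0,1}
    nf: np.ndarray  # (T,) int
    nfd: np.ndarray  # (T,) int

    @property
    def nt(self) -> np.ndarray:
        """Gut load after each interval."""
        return self.nt0 - np.cumsum(self.nf)

    @property
    def rest_nf(self) -> np.ndarray:
        """Seeds in the non-dissected remainder of each feces."""
        return self.nf - self.nfd

    def is_valid(self) -> bool:
        nf = np.asarray(self.nf)
        nfd = np.asarray(self.nfd)
        defec = np.asarray(self.defec)
        return bool(
            self.nt0 >= 0
            and np.all(nf >= 0)
            and np.all(nfd >= 0)
            and np.all(nfd <= nf)
            and np.all(self.nt >= 0)
            and np.all(nf[defec == 0] == 0)
        )


# ---------------------------------------------------------------------------
# Priors


@dataclass(frozen=True)
class PriorSpec:
    """One prior: family in {normal, exponential, halfnormal, uniform} with
    its (loc/scale | rate | scale | lo/hi) parameters."""

    family: str
    params: tuple[float, ...]

    def logpdf(self, x: float | np.ndarray) -> float | np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.family == "normal":
            mu, sd = self.params
            return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)
        if self.family == "exponential":
            (rate,) = self.params
            return np.where(x >= 0, math.log(rate) - rate * x, -np.inf)
        if self.family == "halfnormal":
            (sd,) = self.params
            out = -0.5 * (x / sd) ** 2 - math.log(sd) + 0.5 * math.log(2 / math.pi)
            return np.where(x >= 0, out, -np.inf)
        if self.family == "uniform":
            lo, hi = self.params
            return np.where((x >= lo) & (x <= hi), -math.log(hi - lo), -np.inf)
        raise ValueError(f"unknown prior family {self.family!r}")

    def logpdf1(self, x: float) -> float:
        """Scalar fast path of :meth:`logpdf` (pure ``math``, no arrays)."""
        if self.family == "normal":
            mu, sd = self.params
            return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)
        if self.family == "exponential":
            (rate,) = self.params
            return math.log(rate) - rate * x if x >= 0 else -math.inf
        if self.family == "halfnormal":
            (sd,) = self.params
            if x < 0:
                return -math.inf
            return -0.5 * (x / sd) ** 2 - math.log(sd) + 0.5 * math.log(2 / math.pi)
        if self.family == "uniform":
            lo, hi = self.params
            return -math.log(hi - lo) if lo <= x <= hi else -math.inf
        raise ValueError(self.family)

    def median(self) -> float:
        if self.family == "normal":
            return self.params[0]
        if self.family == "exponential":
            return math.log(2) / self.params[0]
        if self.family == "halfnormal":
            return 0.6744897501960817 * self.params[0]
        if self.family == "uniform":
            return 0.5 * (self.params[0] + self.params[1])
        raise ValueError(self.family)


def _default_priors() -> dict[str, PriorSpec]:
    # "Noninformative" made concrete: wide normals on logit/quadratic
    # coefficients, unit-rate exponential on hazards, half-normal on RE
    # scales, uniform on detection.
    return {
        "delta": PriorSpec("exponential", (1.0,)),
        "a": PriorSpec("normal", (0.0, 10.0)),
        "b": PriorSpec("normal", (0.0, 10.0)),
        "c": PriorSpec("normal", (0.0, 10.0)),
        "pviz": PriorSpec("uniform", (0.0, 1.0)),
        "gamma0": PriorSpec("normal", (0.0, 10.0)),
        "gamma1": PriorSpec("normal", (0.0, 10.0)),
        "sigma": PriorSpec("halfnormal", (2.0,)),
    }


@dataclass
class ModelSpec:
    """Priors and structural switches of the model.

    ``constrain_curvature`` truncates the quadratic coefficient ``c`` to
    ``<= 0`` so the excretion curve has a maximum.  ``components`` selects
    which submodels contribute to the likelihood (a defecation-only fit
    uses ``("defecation",)``).  ``random_effects`` chooses how random
    effects enter fitting: "none" (population curves only, the desk-scale
    default), or "collapsed" (one deviation per animal x plant).
    ``fixed`` pins named parameters to values during fitting.
    """

    priors: dict[str, PriorSpec] = field(default_factory=_default_priors)
    constrain_curvature: bool = True
    components: tuple[str, ...] = ("defecation", "excretion", "dissection", "germination")
    random_effects: str = "none"
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = {"defecation", "excretion", "dissection", "germination"}
        bad = set(self.components) - known
        if bad:
            raise ValueError(f"unknown components: {sorted(bad)}")
        if self.random_effects not in ("none", "collapsed"):
            raise ValueError("random_effects must be 'none' or 'collapsed'")
        missing = {"delta", "a", "b", "c", "pviz", "gamma0", "gamma1", "sigma"} - set(self.priors)
        if missing:
            raise ValueError(f"priors missing for: {sorted(missing)}")

    def with_priors(self, **over: PriorSpec) -> "ModelSpec":
        pri = dict(self.priors)
        pri.update(over)
        return replace(self, priors=pri)

    # -- structured-config round trip -------------------------------------
    def to_dict(self) -> dict:
        return {
            "constrain_curvature": self.constrain_curvature,
            "components": list(self.components),
            "random_effects": self.random_effects,
            "fixed": dict(self.fixed),
            "priors": {k: {"family": p.family, "params": list(p.params)}
                       for k, p in self.priors.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        priors = {k: PriorSpec(v["family"], tuple(v["params"]))
                  for k, v in d.get("priors", {}).items()}
        base = _default_priors()
        base.update(priors)
        return cls(
            priors=base,
            constrain_curvature=bool(d.get("constrain_curvature", True)),
            components=tuple(d.get("components",
                                   ("defecation", "excretion", "dissection",
                                    "germination"))),
            random_effects=d.get("random_effects", "none"),
            fixed=dict(d.get("fixed", {})),
        )


# ---------------------------------------------------------------------------
# Link functions


def defecation_probability(delta: float | np.ndarray, dt: float | np.ndarray):
    """P(at least one defecation in an interval of length ``dt`` hours)
    under a constant per-hour hazard ``delta``: ``1 - exp(-delta * dt)``."""
    delta = np.asarray(delta, dtype=float)
    dt = np.asarray(dt, dtype=float)
    if np.any(delta < 0) or np.any(dt < 0):
        raise ValueError("delta and dt must be non-negative")
    out = -np.expm1(-delta * dt)
    return float(out) if out.ndim == 0 else out

def excretion_probability(a, b, c, t, eps_e=0.0):
    """Potential per-hour excretion probability at time ``t``:
    ``logistic(a + b t + c t^2 + eps_e)``.  With ``c < 0`` the curve peaks
    at ``t* = -b / (2 c)``."""
    t = np.asarray(t, dtype=float)
    out = expit(a + b * t + c * t * t + np.asarray(eps_e, dtype=float))
    return float(out) if out.ndim == 0 else out


def effective_excretion_probability(defec, pex, dt, warn_on_clamp: bool = True):
    """Per-interval excretion probability ``defec * pex * dt``, clamped to
    [0, 1].

    The product form can exceed 1 for large ``pex * dt``; realistic fitted
    excretion probabilities are far below that (maxima of order 1e-3 to
    1e-1), so the clamp is a guard rail and any activation is logged.
    """
    raw = np.asarray(defec, dtype=float) * np.asarray(pex, dtype=float) * np.asarray(dt, dtype=float)
    clamped = np.clip(raw, 0.0, 1.0)
    n_clamped = int(np.sum(raw > 1.0))
    if n_clamped and warn_on_clamp:
        logger.warning(
            "effective excretion probability clamped to 1 in %d cell(s) "
            "(max raw value %.3g); check pex * dt magnitudes",
            n_clamped,
            float(np.max(raw)),
        )
    return float(clamped) if clamped.ndim == 0 else clamped


def detection_probability(pviz, eps_d=0.0):
    """Probability a seed in the dissected sample is counted:
    ``logistic(logit(pviz) + eps_d)``."""
    pviz_arr = np.asarray(pviz, dtype=float)
    eps_arr = np.asarray(eps_d, dtype=float)
    boundary = (pviz_arr <= 0) | (pviz_arr >= 1)
    if np.any(boundary & (eps_arr != 0)):
        raise ValueError("pviz on {0,1} boundary cannot take a detection random effect")
    out = np.where(boundary, pviz_arr, expit(logit(np.clip(pviz_arr, 1e-12, 1 - 1e-12)) + eps_arr))
    return float(out) if out.ndim == 0 else out


def germination_probability_curve(gamma0, gamma1, t):
    """Germination probability of a seed excreted at time ``t``:
    ``logistic(gamma0 + gamma1 t)`` (decreasing in ``t`` when gamma1 < 0)."""
    t = np.asarray(t, dtype=float)
    out = expit(gamma0 + gamma1 * t)
    return float(out) if out.ndim == 0 else out


def germination_sample_probability(pgerm, wg, eps_g=0.0):
    """Probability a seed in the non-dissected remainder shows up as a
    seedling in the germination sample of relative weight ``wg``:
    ``logistic(logit(wg * pgerm) + eps_g)`` (exactly ``wg * pgerm`` when
    the random effect is zero)."""
    wg_arr = np.asarray(wg, dtype=float)
    if np.any(wg_arr <= 0) or np.any(wg_arr > 1):
        raise ValueError("relative germination-sample weight must lie in (0, 1]")
    base = wg_arr * np.asarray(pgerm, dtype=float)
    out = expit(logit(np.clip(base, 1e-300, 1 - 1e-16)) + np.asarray(eps_g, dtype=float))
    out = np.where(base == 0, 0.0, out)
    return float(out) if out.ndim == 0 else out


def excretion_quadratic_from_peak(
    max_pex: float, peak_time: float, curvature: float = -0.003
) -> tuple[float, float, float]:
    """Back-solve logit-quadratic coefficients from a peak value and time.

    Returns ``(a, b, c)`` with ``c = curvature < 0`` such that
    ``excretion_probability`` attains ``max_pex`` at ``t = peak_time``.
    """
    if not (0 < max_pex < 1):
        raise ValueError("max_pex must lie in (0, 1)")
    if curvature >= 0:
        raise ValueError("curvature must be negative")
    c = curvature
    b = -2.0 * c * peak_time
    a = float(logit(max_pex)) + c * peak_time**2
    return (a, b, c)


# ---------------------------------------------------------------------------
# Densities


def _log_binom(k, n, p):
    """Vectorized log Binomial(k; n, p), -inf off support, safe at p in {0,1}."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    k, n, p = np.broadcast_arrays(k, n, p)
    out = np.full(k.shape, -np.inf)
    ok = (k >= 0) & (k <= n)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.where(k > 0, k * np.log(p), 0.0)
        lq = np.where(n - k > 0, (n - k) * np.log1p(-p), 0.0)
        comb = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        val = comb + lp + lq
    out[ok] = np.where(np.isnan(val[ok]), -np.inf, val[ok])
    return out


def _log_poisson(k, mu):
    k = np.asarray(k, dtype=float)
    mu = np.asarray(mu, dtype=float)
    k, mu = np.broadcast_arrays(k, mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = k * np.log(mu) - mu - gammaln(k + 1)
    val = np.where((mu == 0) & (k == 0), 0.0, val)
    val = np.where((mu == 0) & (k > 0), -np.inf, val)
    return np.where(k < 0, -np.inf, val)


def _log_bernoulli(x, p):
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(x == 1, np.log(p), np.log1p(-p))


def _cell_params(params: ParameterSet, species: str, plant: str):
    return (
        params.delta[species],
        params.excretion[(species, plant)],
        params.pviz[(species, plant)],
        params.germination[(species, plant)],
    )


def complete_data_log_density(
    ntot: int,
    times: np.ndarray,
    deltas: np.ndarray,
    latent: LatentTrajectory,
    y: np.ndarray,
    g: np.ndarray,
    wd: np.ndarray,
    wg: np.ndarray,
    params: ParameterSet,
    species: str,
    plant: str,
    eps_e=0.0,
    eps_d=0.0,
    eps_g=0.0,
    spec: ModelSpec | None = None,
) -> float:
    """Joint log density of latents and observations for one animal x plant.

    Sums the factors of the generative chain —
    Poisson(nt0; Ntot), Bernoulli(defec; pdef), Binomial(nf; nt_{t-1},
    pexeff), Binomial(nfd; nf, WD), Binomial(Y; nfd, lambda),
    Binomial(G; restNf, pg) — and, when ``spec`` is given, adds the random
    effect and prior log densities.  Returns ``-inf`` off the latent
    support.  ``wd``/``wg`` are the relative sample weights per time.
    """
    times = np.asarray(times, dtype=float)
    deltas = np.asarray(deltas, dtype=float)
    y = np.asarray(y)
    g = np.asarray(g)
    T = times.size
    for arr, name in ((latent.defec, "defec"), (latent.nf, "nf"), (latent.nfd, "nfd"),
                      (y, "y"), (g, "g")):
        if np.asarray(arr).shape != (T,):
            raise ValueError(f"{name} misaligned with the observation grid")
    if not latent.is_valid():
        return -np.inf

    delta_s, (a, b, c), pviz, (g0, g1) = _cell_params(params, species, plant)
    if spec is not None and spec.constrain_curvature and c > 0:
        return -np.inf

    pdef = defecation_probability(delta_s, deltas)
    pex = excretion_probability(a, b, c, times, eps_e)
    pexeff = effective_excretion_probability(latent.defec, pex, deltas, warn_on_clamp=False)
    lam = detection_probability(pviz, eps_d)
    pgerm = germination_probability_curve(g0, g1, times)
    wg_arr = np.asarray(wg, dtype=float)
    pg = np.where(
        wg_arr > 0,
        germination_sample_probability(pgerm, np.where(wg_arr > 0, wg_arr, 0.5), eps_g),
        0.0,
    )

    nt_prev = np.concatenate([[latent.nt0], latent.nt[:-1]])
    lp = float(_log_poisson(latent.nt0, ntot))
    lp += float(np.sum(_log_bernoulli(latent.defec, pdef)))
    lp += float(np.sum(_log_binom(latent.nf, nt_prev, pexeff)))
    lp += float(np.sum(_log_binom(latent.nfd, latent.nf, wd)))
    lp += float(np.sum(_log_binom(y, latent.nfd, lam)))
    lp += float(np.sum(_log_binom(g, latent.rest_nf, pg)))

    if spec is not None:
        pri = spec.priors
        lp += float(pri["delta"].logpdf(delta_s))
        lp += float(pri["a"].logpdf(a) + pri["b"].logpdf(b) + pri["c"].logpdf(c))
        lp += float(pri["pviz"].logpdf(pviz))
        lp += float(pri["gamma0"].logpdf(g0) + pri["gamma1"].logpdf(g1))
        for eps, sig in ((eps_e, params.sigma_e.get(species, 0.0)),
                         (eps_d, params.sigma_d.get(species, 0.0)),
                         (eps_g, params.sigma_g)):
            eps = np.asarray(eps, dtype=float)
            if sig > 0:
                lp += float(np.sum(PriorSpec("normal", (0.0, sig)).logpdf(eps)))
            elif np.any(eps != 0):
                return -np.inf
    return lp


def excretion_weights(pexeff: np.ndarray) -> np.ndarray:
    """Fraction ``q_t`` of the initial gut load excreted in interval ``t``:
    ``pexeff_t`` times the survival probability through earlier intervals."""
    pexeff = np.atleast_1d(np.asarray(pexeff, dtype=float))
    surv = np.cumprod(1.0 - pexeff, axis=-1)
    prev = np.concatenate([np.ones(pexeff.shape[:-1] + (1,)), surv[..., :-1]], axis=-1)
    return pexeff * prev


def marginalized_observation_likelihood(
    ntot: int,
    times: np.ndarray,
    deltas: np.ndarray,
    defec: np.ndarray,
    y: np.ndarray,
    g: np.ndarray,
    wd: np.ndarray,
    wg: np.ndarray,
    params: ParameterSet,
    species: str,
    plant: str,
    eps_e=0.0,
    eps_d=0.0,
    eps_g=0.0,
) -> float:
    """Exact marginal log likelihood of (Y, G) given the defecation record.

    Collapses all latent counts by Poisson splitting; equals the sum of
    :func:`complete_data_log_density` (without priors) over every latent
    configuration.  Does not include the Bernoulli terms for ``defec``.
    """
    times = np.asarray(times, dtype=float)
    deltas = np.asarray(deltas, dtype=float)
    _, (a, b, c), pviz, (g0, g1) = _cell_params(params, species, plant)

    pex = excretion_probability(a, b, c, times, eps_e)
    pexeff = effective_excretion_probability(defec, pex, deltas, warn_on_clamp=False)
    q = excretion_weights(pexeff)
    lam = detection_probability(pviz, eps_d)
    pgerm = germination_probability_curve(g0, g1, times)
    wg_arr = np.asarray(wg, dtype=float)
    # intervals without a feces have no germination sample (wg = 0): no seeds
    # can appear there, matching q = 0
    pg = np.where(
        wg_arr > 0,
        germination_sample_probability(pgerm, np.where(wg_arr > 0, wg_arr, 0.5), eps_g),
        0.0,
    )

    mu_y = ntot * q * np.asarray(wd, dtype=float) * lam
    mu_g = ntot * q * (1.0 - np.asarray(wd, dtype=float)) * pg
    g = np.asarray(g)
    if np.any((g > 0) & (pg == 0)):
        return -np.inf
    return float(np.sum(_log_poisson(y, mu_y)) + np.sum(_log_poisson(g, mu_g)))
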