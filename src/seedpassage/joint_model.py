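"""Model/Results surface over the joint excretion–germination model.

Usage mirrors the fit-then-inspect style of statsmodels::

    from seedpassage import SeedExcretionModel, desk_settings

    model = SeedExcretionModel.from_simulation(seed=1)
    res = model.fit(desk_settings(seed=2))
    print(res.summary())
    res.retention_summary()      # Table of MRT and max pex per pair
    res.convergence()            # Rhat / ESS per parameter
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import ObservationGrid, StudyDesign
from .inference import (
    ConvergenceReport,
    MCMCSettings,
    PosteriorDraws,
    desk_settings,
    gelman_rubin,
    posterior_predictive_check,
    run_mcmc,
)
from .io import FeedingDataset, load_and_validate, write_dataset
from .model import ModelSpec, ParameterSet
from . import summaries as _summaries

__all__ = ["SeedExcretionModel", "SeedExcretionResults"]


class SeedExcretionModel:
    """Joint Bayesian model of seed excretion, dissection and germination,
    built from a feeding-experiment dataset."""

    def __init__(self, dataset: FeedingDataset, spec: ModelSpec | None = None):
        self.dataset = dataset
        self.spec = spec or ModelSpec()
        self.simulated = None  # set by from_simulation; carries latent truth

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_csv(cls, trials_path, feces_path, spec: ModelSpec | None = None):
        return cls(load_and_validate(trials_path, feces_path), spec=spec)

    @classmethod
    def from_dataframes(cls, trials: pd.DataFrame, feces: pd.DataFrame,
                        spec: ModelSpec | None = None,
                        grid: ObservationGrid | None = None):
        return cls(FeedingDataset(trials=trials, feces=feces, grid=grid), spec=spec)

    @classmethod
    def from_simulation(
        cls,
        design: StudyDesign | None = None,
        params: ParameterSet | None = None,
        seed: int = 0,
        spec: ModelSpec | None = None,
        ingestion: str = "full",
    ):
        """Build the model on a forward-simulated experiment (the latent
        truth stays available as ``model.simulated``)."""
        from .simulate import simulate_dataset

        sim = simulate_dataset(design=design, params=params, seed=seed,
                               ingestion=ingestion)
        obj = cls(sim.dataset, spec=spec)
        obj.simulated = sim
        return obj

    @property
    def grid(self) -> ObservationGrid:
        return self.dataset.grid

    def fit(self, settings: MCMCSettings | None = None) -> "SeedExcretionResults":
        settings = settings or desk_settings()
        draws = run_mcmc(self.dataset, self.spec, settings)
        return SeedExcretionResults(self, draws, settings)


class SeedExcretionResults:
    """Posterior draws plus every derived summary of a fitted model."""

    def __init__(self, model: SeedExcretionModel, draws: PosteriorDraws,
                 settings: MCMCSettings):
        self.model = model
        self.draws = draws
        self.settings = settings

    # -- diagnostics -------------------------------------------------------
    def convergence(self, threshold: float = 1.2, method: str = "rank") -> ConvergenceReport:
        return gelman_rubin(self.draws, threshold=threshold, method=method)

    def ppc(self, seed: int = 0, n_rep: int = 200) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        return posterior_predictive_check(self.model.dataset, self.draws, rng, n_rep=n_rep)

    # -- summaries ---------------------------------------------------------
    def retention_summary(self) -> pd.DataFrame:
        return _summaries.retention_time_estimates(self.draws, self.model.grid)

    def defecation_summary(self, reference_dt: float = 3.0) -> pd.DataFrame:
        return _summaries.defecation_summary(self.draws, reference_dt)

    def max_germination(self) -> pd.DataFrame:
        return _summaries.max_germination_probability(
            self.draws, self.model.grid, dataset=self.model.dataset
        )

    def percent_excreted(self) -> pd.DataFrame:
        return _summaries.percent_seeds_excreted(self.model.dataset, self.draws)

    def summary(self) -> str:
        """Human-readable report of the main posterior summaries."""
        lines = [
            "Joint seed excretion / germination model",
            "=" * 56,
            f"chains: {self.settings.n_chains}   retained draws/chain: "
            f"{self.draws.n_draws}   backend: {self.settings.backend}",
            "",
        ]
        defec = self.defecation_summary()
        if len(defec):
            lines.append("Defecation probability per 3-h interval (median [95% CrI]):")
            for _, r in defec.iterrows():
                lines.append(f"  {r.species:12s} {r.pdef_median:.2f} "
                             f"[{r.pdef_lo:.2f}; {r.pdef_hi:.2f}]")
            lines.append("")
        try:
            ret = self.retention_summary()
        except (KeyError, ValueError):
            ret = pd.DataFrame()
        if len(ret):
            lines.append("Retention time (grid argmax, h) and max excretion probability:")
            for _, r in ret.iterrows():
                flag = "  [at grid boundary]" if r.boundary_flag else ""
                lines.append(
                    f"  {r.species:10s} x {r.plant:18s} MRT {r.mrt_median:4.0f} h "
                    f"[{r.mrt_lo:.0f}; {r.mrt_hi:.0f}]  max pex {r.max_pex_median:.4f} "
                    f"[{r.max_pex_lo:.4f}; {r.max_pex_hi:.4f}]{flag}"
                )
            lines.append("")
        try:
            germ = self.max_germination()
        except (KeyError, ValueError):
            germ = pd.DataFrame()
        if len(germ):
            lines.append("Max germination probability over the window (median [95% CrI]):")
            for _, r in germ.iterrows():
                flag = "  [degenerate: no seedlings]" if r.degenerate_flag else ""
                lines.append(
                    f"  {r.species:10s} x {r.plant:18s} {r.max_pgerm_median:.3f} "
                    f"[{r.max_pgerm_lo:.3f}; {r.max_pgerm_hi:.3f}]{flag}"
                )
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, outdir) -> dict[str, Path]:
        """Write draws.csv, convergence.csv and summary tables under outdir."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["draws"] = outdir / "draws.csv"
        self.draws.to_dataframe().to_csv(paths["draws"], index=False)
        paths["convergence"] = outdir / "convergence.csv"
        conv = self.convergence()
        conv.table.to_csv(paths["convergence"], index=False)
        (outdir / "convergence.txt").write_text(str(conv) + "\n")
        try:
            ret = self.retention_summary()
            paths["summary_table2"] = outdir / "summary_table2.csv"
            ret.drop(columns=["mrt_vertex_median"]).to_csv(paths["summary_table2"], index=False)
        except (KeyError, ValueError):
            pass
        return paths

    # -- plots -------------------------------------------------------------
    def plot_excretion_curves(self, species: str | None = None, ax=None):
        """Median excretion-probability curves over time per pair."""
        import matplotlib.pyplot as plt
        from scipy.special import expit

        if ax is None:
            _, ax = plt.subplots()
        times = np.asarray(self.model.grid.times)
        tt = np.linspace(times[0], times[-1], 200)
        for s, j in _summaries._pairs_in(self.draws, "a"):
            if species is not None and s != species:
                continue
            a = np.median(self.draws.stacked(f"a[{s},{j}]"))
            b = np.median(self.draws.stacked(f"b[{s},{j}]"))
            c = np.median(self.draws.stacked(f"c[{s},{j}]"))
            ax.plot(tt, expit(a + b * tt + c * tt**2), label=f"{s} x {j}")
        ax.set_xlabel("time since ingestion (h)")
        ax.set_ylabel("excretion probability pex")
        ax.legend(fontsize=6)
        return ax

    def plot_germination_curves(self, ax=None):
        """Median germination-probability curves against retention time."""
        import matplotlib.pyplot as plt
        from scipy.special import expit

        if ax is None:
            _, ax = plt.subplots()
        times = np.asarray(self.model.grid.times)
        tt = np.linspace(times[0], times[-1], 200)
        for s, j in _summaries._pairs_in(self.draws, "gamma0"):
            g0 = np.median(self.draws.stacked(f"gamma0[{s},{j}]"))
            g1 = np.median(self.draws.stacked(f"gamma1[{s},{j}]"))
            ax.plot(tt, expit(g0 + g1 * tt), label=f"{s} x {j}")
        ax.set_xlabel("retention time (h)")
        ax.set_ylabel("germination probability pgerm")
        ax.legend(fontsize=6)
        return ax

    def plot_defecation(self, ax=None):
        """Posterior boxplots of the per-species 3-h defecation probability."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        names = [n for n in self.draws.names if n.startswith("delta[")]
        data = [-np.expm1(-self.draws.stacked(n) * 3.0) for n in names]
        ax.boxplot(data, tick_labels=[n[6:-1] for n in names])
        ax.set_ylabel("defecation probability per 3 h")
        return ax
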