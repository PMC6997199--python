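"""Trajectory fitting: nRMSE fit index and male-mating-success grid search.

The laboratory experiment records six genotype-proportion trajectories
(αα/αβ/ββ among eggs and among adults) over five generations.  The
individual-based simulator predicts those trajectories for any parameter
set, so the one parameter the experiment could not measure directly — the
relative mating success of ββ males, ``T_ββ-m`` — is estimated by grid
search: for each candidate value, simulated replicates are scored against
the observed trajectories by the normalized root-mean-squared error
(nRMSE), the six per-variable nRMSEs are averaged within each replicate,
the replicate means are averaged into a fit index, and the grid argmin is
the estimate.  The heterozygote weight is the co-dominant midpoint
``T_αβ-m = (T_αα-m + T_ββ-m) / 2`` unless a dominance variant is requested.

`InversionDynamicsModel` wraps the observed trajectories plus the fixed
scenario parameters; ``fit()`` returns an `InversionDynamicsResults` with
the fit table, per-scenario indices, the best value and a ``summary()``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .params import (GENOTYPES, MALE, DevelopmentParams, FitnessParams,
                     HabitatParams, SimulationConfig, lab_default_params)
from . import simulator

__all__ = ["nrmse", "trajectory_variables", "observed_from_count_table",
           "InversionDynamicsModel", "InversionDynamicsResults",
           "compare_scenarios"]

#: the six fitted variables, in fixed order
VARIABLES = tuple(f"{stage}_{g}" for stage in ("egg", "adult") for g in GENOTYPES)


def nrmse(observed, simulated, norm: str = "mean") -> float:
    """Normalized RMSE between two equal-length series.

    ``norm="mean"`` divides the RMSE by the mean of the observed series
    (the default; stable for short series), ``norm="range"`` by its range.
    """
    o = np.asarray(observed, dtype=float)
    s = np.asarray(simulated, dtype=float)
    if o.shape != s.shape or o.size == 0:
        raise ValueError("series must be non-empty and of equal length")
    rmse = float(np.sqrt(np.mean((o - s) ** 2)))
    if norm == "mean":
        denom = float(np.mean(o))
    elif norm == "range":
        denom = float(np.ptp(o))
    else:
        raise ValueError("norm must be 'mean' or 'range'")
    if denom == 0:
        raise ValueError(f"observed series has zero {norm}; nRMSE undefined")
    return rmse / denom


def trajectory_variables(traj) -> pd.DataFrame:
    """Six-variable wide table (generation × variable) from a trajectory.

    Accepts a stochastic ``Trajectory`` or a ``RecursionResult``; egg and
    adult genotype proportions are sex-pooled.
    """
    egg = traj.egg_props() if callable(getattr(traj, "egg_props", None)) else traj.egg_props
    adult = traj.adult_props() if callable(getattr(traj, "adult_props", None)) else traj.adult_props
    data = np.hstack([egg, adult])
    return pd.DataFrame(data, columns=list(VARIABLES),
                        index=pd.RangeIndex(len(egg), name="generation"))


def observed_from_count_table(df: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged observed trajectories from a tidy count table.

    Proportions are computed within (replicate, generation, stage) with
    sexes pooled, then averaged over replicates; returns a generation ×
    variable wide table.
    """
    frames = []
    for stage in ("egg", "adult"):
        sub = df[df["stage"] == stage]
        counts = (sub.groupby(["replicate", "generation", "genotype"])["count"]
                  .sum().unstack("genotype")
                  .reindex(columns=list(GENOTYPES), fill_value=0))
        props = counts.div(counts.sum(axis=1), axis=0)
        mean = props.groupby("generation").mean()
        mean.columns = [f"{stage}_{g}" for g in mean.columns]
        frames.append(mean)
    out = pd.concat(frames, axis=1).reindex(columns=list(VARIABLES))
    out.index.name = "generation"
    return out


def _male_T(t_bb: float, t_ab=None) -> np.ndarray:
    """Male reproductive-success weights (1, midpoint or explicit, t_bb)."""
    if t_ab is None:
        t_ab = 0.5 * (1.0 + t_bb)
    return np.array([1.0, t_ab, t_bb])


class InversionDynamicsModel:
    """Individual-based inversion-dynamics model tied to observed trajectories.

    Parameters
    ----------
    observed : DataFrame
        Generation × variable table of the six observed genotype-proportion
        trajectories (columns ``egg_AA .. adult_BB``); build it from a tidy
        count table with :func:`observed_from_count_table` or from
        simulator output with :func:`trajectory_variables`.
    config : SimulationConfig
        Demography of the simulated scenarios (K, generations, initial
        proportions, replicates).
    fitness, development, habitat : optional
        Fixed scenario parameters; laboratory defaults when omitted.  The
        male reproductive-success weights are overridden per grid point
        during fitting.
    norm : {"mean", "range"}
        nRMSE normalization.
    fit_generations : slice of generations entering the nRMSE (default 1–G;
        generation 0 is the shared founding state and carries no signal).
    """

    def __init__(self, observed: pd.DataFrame, config: SimulationConfig,
                 fitness: FitnessParams = None,
                 development: DevelopmentParams = None,
                 habitat: HabitatParams = None,
                 norm: str = "mean", fit_generations=None):
        fp0, dp0, hp0 = lab_default_params()
        self.observed = observed.reindex(columns=list(VARIABLES))
        if self.observed.isna().any().any():
            raise ValueError("observed table must cover all six variables")
        self.config = config
        self.fitness = fitness if fitness is not None else fp0
        self.development = development if development is not None else dp0
        self.habitat = habitat if habitat is not None else hp0
        self.norm = norm
        if fit_generations is None:
            fit_generations = [g for g in self.observed.index if g >= 1]
        self.fit_generations = list(fit_generations)
        missing = set(self.fit_generations) - set(self.observed.index)
        if missing:
            raise ValueError(f"observed table lacks generations {sorted(missing)}")

    @classmethod
    def from_count_table(cls, df: pd.DataFrame, config: SimulationConfig, **kw):
        """Build the model from a tidy genotype count table."""
        return cls(observed_from_count_table(df), config, **kw)

    # -- simulation ---------------------------------------------------------

    def simulate(self, t_bb_m=None, t_ab_m=None, n_replicates=None, seed=None,
                 fitness=None):
        """Run replicate simulations of one scenario; returns trajectories."""
        fp = fitness if fitness is not None else self.fitness
        if t_bb_m is not None:
            T = fp.T.copy()
            T[MALE] = _male_T(t_bb_m, t_ab_m)
            fp = fp.replace(T=T)
        return simulator.run_replicates(self.config, fp, self.development,
                                        self.habitat, n_replicates=n_replicates,
                                        seed=seed)

    # -- scoring ------------------------------------------------------------

    def score_trajectory(self, traj) -> dict:
        """Per-variable nRMSE of one simulated replicate vs the observed table."""
        sim = trajectory_variables(traj)
        gens = self.fit_generations
        if traj.extinct or not set(gens).issubset(sim.index):
            return None
        out = {}
        for var in VARIABLES:
            out[var] = nrmse(self.observed.loc[gens, var], sim.loc[gens, var],
                             norm=self.norm)
        return out

    def fit_index(self, label, t_bb_m=None, t_ab_m=None, n_replicates=None,
                  seed=None, fitness=None):
        """Score one scenario: per-replicate six-variable nRMSEs.

        Returns ``(rows, n_extinct)`` where each row carries the replicate
        index, the six per-variable nRMSEs and their mean.  Extinct
        replicates are excluded from scoring and tallied.
        """
        trajs = self.simulate(t_bb_m=t_bb_m, t_ab_m=t_ab_m,
                              n_replicates=n_replicates, seed=seed,
                              fitness=fitness)
        rows, n_extinct = [], 0
        for i, traj in enumerate(trajs):
            scores = self.score_trajectory(traj)
            if scores is None:
                n_extinct += 1
                continue
            row = {"scenario": label, "replicate": i}
            row.update(scores)
            row["mean_nrmse"] = float(np.mean(list(scores.values())))
            rows.append(row)
        return rows, n_extinct

    # -- fitting ------------------------------------------------------------

    def fit(self, grid=None, n_replicates=None, seed=None, t_ab_m=None):
        """Grid search over ββ-male relative mating success.

        Parameters
        ----------
        grid : iterable of candidate ``T_ββ-m`` values in (0, 1]
            (default 0.1, 0.2, ..., 1.0).
        n_replicates : simulated replicates per grid point (default from
            the config, 30 in the laboratory setting).
        seed : master seed; each grid point gets an independent child
            stream.
        t_ab_m : explicit heterozygote weight (default: co-dominant
            midpoint of the homozygote weights).
        """
        if grid is None:
            grid = np.round(np.arange(0.1, 1.01, 0.1), 10)
        grid = [float(v) for v in grid]
        if len(grid) == 0:
            raise ValueError("empty grid")
        if any(not 0 < v <= 1 for v in grid):
            raise ValueError("grid values must lie in (0, 1]")
        master = seed if seed is not None else self.config.seed
        streams = np.random.SeedSequence(master).spawn(len(grid))
        all_rows, extinct = [], {}
        for t_bb, stream in zip(grid, streams):
            label = f"T_bb_m={t_bb:g}"
            rows, n_ext = self.fit_index(label, t_bb_m=t_bb, t_ab_m=t_ab_m,
                                         n_replicates=n_replicates,
                                         seed=stream)
            all_rows.extend(rows)
            extinct[label] = n_ext
        table = pd.DataFrame(all_rows)
        return InversionDynamicsResults(self, grid, table, extinct)


class InversionDynamicsResults:
    """Grid-search results: fit table, per-scenario indices, best value."""

    def __init__(self, model: InversionDynamicsModel, grid, fit_table: pd.DataFrame,
                 n_extinct: dict):
        self.model = model
        self.grid = list(grid)
        self.fit_table = fit_table
        self.n_extinct = n_extinct
        by = fit_table.groupby("scenario")["mean_nrmse"]
        agg = by.agg(["mean", "std", "count"]).rename(
            columns={"mean": "fit_index", "std": "sd", "count": "n_replicates"})
        order = [f"T_bb_m={v:g}" for v in self.grid]
        self.scenario_table = agg.reindex(order)
        self.scenario_table.insert(0, "t_bb_m", self.grid)

    @property
    def params(self) -> dict:
        """Best-fit parameter (grid argmin of the fit index)."""
        i = int(np.nanargmin(self.scenario_table["fit_index"].to_numpy()))
        return {"t_bb_m": self.grid[i]}

    @property
    def best_scenario(self) -> str:
        return self.scenario_table.index[
            int(np.nanargmin(self.scenario_table["fit_index"].to_numpy()))]

    @property
    def fit_index(self) -> float:
        """Fit index (grand mean nRMSE) of the best scenario."""
        return float(np.nanmin(self.scenario_table["fit_index"].to_numpy()))

    def replicate_nrmse(self, scenario=None) -> np.ndarray:
        """Per-replicate mean nRMSE vector of one scenario (best by default)."""
        scenario = scenario or self.best_scenario
        return self.fit_table.loc[self.fit_table["scenario"] == scenario,
                                  "mean_nrmse"].to_numpy()

    def compare(self, scenarios=None) -> pd.DataFrame:
        """Pairwise Welch t-tests between scenarios with BH adjustment."""
        if scenarios is None:
            scenarios = list(self.scenario_table.index)
        vectors = {s: self.replicate_nrmse(s) for s in scenarios}
        return compare_scenarios(vectors)

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = ["Inversion dynamics trajectory fit (nRMSE grid search)",
                 "=" * 56,
                 f"variables: {', '.join(VARIABLES)}",
                 f"generations fitted: {self.model.fit_generations}",
                 f"normalization: {self.model.norm}",
                 "",
                 self.scenario_table.to_string(float_format=lambda v: f"{v:.4f}"),
                 "",
                 f"best scenario: {self.best_scenario} "
                 f"(fit index = {self.fit_index:.4f})"]
        ext = {k: v for k, v in self.n_extinct.items() if v}
        if ext:
            lines.append(f"extinct replicates excluded: {ext}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Fit index vs grid value (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.scenario_table
        ax.errorbar(t["t_bb_m"], t["fit_index"],
                    yerr=t["sd"] / np.sqrt(t["n_replicates"]), marker="o")
        ax.set_xlabel("relative mating success of ββ males (T_ββ-m)")
        ax.set_ylabel("fit index (mean nRMSE)")
        return ax


def compare_scenarios(vectors: dict) -> pd.DataFrame:
    """Pairwise Welch two-sample t-tests on replicate-level mean nRMSE.

    ``vectors`` maps scenario labels to per-replicate nRMSE arrays.
    p-values are Benjamini–Hochberg adjusted across the pairs.  Two
    identical degenerate (zero-variance, equal-mean) vectors compare with
    t = 0, p = 1.
    """
    labels = list(vectors)
    if len(labels) < 2:
        raise ValueError("need at least two scenarios to compare")
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            x, y = np.asarray(vectors[a], float), np.asarray(vectors[b], float)
            if x.size < 2 or y.size < 2:
                raise ValueError("need at least two replicates per scenario")
            if x.std() == 0 and y.std() == 0 and x.mean() == y.mean():
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(x, y, equal_var=False)
            rows.append({"scenario_a": a, "scenario_b": b,
                         "t": float(t), "pvalue": float(p)})
    table = pd.DataFrame(rows)
    table["pvalue_bh"] = multipletests(table["pvalue"], method="fdr_bh")[1]
    return table
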