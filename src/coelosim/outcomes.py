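"""Total-fitness algebra, mechanism classification and parameter sweeps.

Total fitness of a genotype within a sex is the product of its two
relative components, ``W = S · T``.  Allele-level fitnesses follow by
gamete counting: ``w_α = W_αα + W_αβ/2`` and ``w_β = W_ββ + W_αβ/2`` per
sex.  Two classical balancing-selection mechanisms are read off these
values:

* **overdominance** within a sex — the heterozygote strictly exceeds both
  homozygotes in total fitness;
* **sexual antagonism** — the sign of ``w_α − w_β`` differs between the
  sexes (strictly on both sides).

Long simulations are summarized into polymorphism outcomes (maintained /
α fixed / β fixed / extinct) with an equilibrium window average, and the
sweep driver maps these outcomes plus mechanism flags over parameter
grids (male mating success × habitat duration × habitat variability, or
the theoretical s/t/H space).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .params import (FEMALE, MALE, DevelopmentParams, FitnessParams,
                     HabitatParams, SimulationConfig, TheoreticalParams,
                     from_theoretical, lab_default_params)
from . import simulator

__all__ = ["TotalFitness", "total_fitness", "classify_overdominance",
           "classify_sexual_antagonism", "classify_polymorphism",
           "realized_relative_survival", "realized_fitness_params",
           "sweep", "summarize_sweep"]


@dataclass(frozen=True)
class TotalFitness:
    """Genotype total fitnesses W and allele fitnesses w_α, w_β per sex."""

    W: np.ndarray        # (2, 3) by (sex, genotype)
    w_alpha: np.ndarray  # (2,)
    w_beta: np.ndarray   # (2,)


def total_fitness(S, T) -> TotalFitness:
    """Elementwise ``W = S·T`` and allele fitnesses ``w_α, w_β`` per sex."""
    S = np.asarray(S, dtype=float)
    T = np.asarray(T, dtype=float)
    if S.shape != (2, 3) or T.shape != (2, 3):
        raise ValueError("S and T must be (2 sexes, 3 genotypes) arrays")
    if np.any(S < 0) or np.any(T < 0):
        raise ValueError("S and T must be non-negative")
    W = S * T
    w_alpha = W[:, 0] + 0.5 * W[:, 1]
    w_beta = W[:, 2] + 0.5 * W[:, 1]
    return TotalFitness(W=W, w_alpha=w_alpha, w_beta=w_beta)


def classify_overdominance(tf: TotalFitness) -> np.ndarray:
    """Per-sex flag: heterozygote total fitness strictly exceeds both homozygotes."""
    W = tf.W
    return (W[:, 1] > W[:, 0]) & (W[:, 1] > W[:, 2])


def classify_sexual_antagonism(tf: TotalFitness) -> bool:
    """True when opposite alleles are strictly favoured in the two sexes."""
    d = tf.w_alpha - tf.w_beta
    return bool((d[FEMALE] > 0 and d[MALE] < 0) or (d[FEMALE] < 0 and d[MALE] > 0))


def classify_polymorphism(traj, window: int = 20, tol: float = 0.0) -> dict:
    """Polymorphism outcome of one trajectory.

    Status is ``extinct`` for flagged replicates, ``alpha_fixed`` /
    ``beta_fixed`` when the final adult α frequency is within ``tol`` of
    1 / 0, else ``maintained``.  The equilibrium summary is the mean adult
    composition over the final ``window`` generations.
    """
    if traj.extinct:
        return {"status": "extinct", "p_eq": np.nan,
                "props_eq": np.full(3, np.nan)}
    p = traj.p_adult()
    props = traj.adult_props()
    w = min(window, len(p))
    out = {"p_eq": float(np.nanmean(p[-w:])),
           "props_eq": np.nanmean(props[-w:], axis=0)}
    p_final = p[-1]
    if p_final >= 1 - tol:
        out["status"] = "alpha_fixed"
    elif p_final <= tol:
        out["status"] = "beta_fixed"
    else:
        out["status"] = "maintained"
    return out


def _stage_ratio_by_generation(traj, sex: int) -> np.ndarray:
    """Mean over generations of the per-generation adult/egg proportion ratio.

    Proportions are formed within each generation and stage, so the ratio
    is invariant to the egg-pool size (the recorded egg pool is the full
    pre-census clutch while adults grow from the censused subset).
    """
    ratios = []
    for rec in traj.records:
        if rec.egg_counts is None or rec.adult_counts is None:
            continue
        eggs = rec.egg_counts[sex].astype(float)
        adults = rec.adult_counts[sex].astype(float)
        if eggs.sum() == 0 or adults.sum() == 0:
            continue
        e = eggs / eggs.sum()
        a = adults / adults.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios.append(np.where(e > 0, a / np.where(e > 0, e, 1), np.nan))
    if not ratios:
        return np.full(3, np.nan)
    return np.nanmean(np.vstack(ratios), axis=0)


def realized_relative_survival(traj, sex: int = MALE) -> np.ndarray:
    """Per-genotype realized survival from a trajectory, normalized to ββ = 1.

    Within each recorded generation, forms the per-genotype ratio of adult
    to egg proportions for the chosen sex (the estimator applied to the
    simulation's own census), averages the ratios over generations, and
    divides by the ββ value (the reference genotype).  NaN when no ββ
    individuals survived in any generation.
    """
    ratio = _stage_ratio_by_generation(traj, sex)
    if not np.isfinite(ratio[2]) or ratio[2] == 0:
        return np.full(3, np.nan)
    return ratio / ratio[2]


def realized_fitness_params(traj, fp: FitnessParams) -> "TotalFitness":
    """Total fitness using realized (habitat-censored) survival per sex.

    Survival is the generation-averaged adult/egg proportion ratio per
    sex × genotype, normalized to the best genotype within each sex;
    reproduction weights come from the configured parameters.
    """
    S = np.empty((2, 3))
    for sex in (FEMALE, MALE):
        ratio = _stage_ratio_by_generation(traj, sex)
        best = np.nanmax(ratio)
        S[sex] = ratio / best if best and np.isfinite(best) else np.nan
    return total_fitness(np.nan_to_num(S), fp.T)


# ---------------------------------------------------------------------------
# sweep driver

def _point_params(point: dict, base_fp, base_dp, base_hp):
    """Materialize one grid point into parameter sets."""
    fp, dp, hp = base_fp, base_dp, base_hp
    theoretical = {k for k in ("s_m", "s_f", "t_m", "t_f", "H_s", "H_t")
                   if k in point}
    if theoretical:
        tp = TheoreticalParams(**{k: point[k] for k in theoretical})
        fp = from_theoretical(tp, V=fp.V, E=fp.E)
    if "t_bb_m" in point:
        T = fp.T.copy()
        t_bb = point["t_bb_m"]
        t_ab = point.get("t_ab_m", 0.5 * (1.0 + t_bb))
        T[MALE] = [1.0, t_ab, t_bb]
        fp = fp.replace(T=T)
    if "S" in point:
        fp = fp.replace(S=point["S"])
    if "a_mean" in point or "a_var" in point:
        hp = HabitatParams(a_mean=point.get("a_mean", hp.a_mean),
                           a_var=point.get("a_var", hp.a_var))
    return fp, dp, hp


def sweep(grid, cfg: SimulationConfig, fitness: FitnessParams = None,
          development: DevelopmentParams = None, habitat: HabitatParams = None,
          n_replicates: int = None, seed=None, window: int = 20,
          progress=None) -> pd.DataFrame:
    """Replicated simulations over a parameter grid.

    ``grid`` is either a dict mapping parameter names (``t_bb_m``,
    ``a_mean``, ``a_var``, ``s_m`` … ``H_t``) to value lists — expanded as
    a cartesian product — or an explicit iterable of per-point dicts.
    Per-point, per-replicate seeds are spawned deterministically from the
    master seed, so the sweep table is reproducible.  Returns one row per
    grid point × replicate with the polymorphism outcome, equilibrium
    composition, realized male survival and configured mechanism flags.
    """
    base_fp, base_dp, base_hp = lab_default_params()
    fitness = fitness if fitness is not None else base_fp
    development = development if development is not None else base_dp
    habitat = habitat if habitat is not None else base_hp

    if isinstance(grid, dict):
        names = list(grid)
        points = [dict(zip(names, vals)) for vals in product(*grid.values())]
    else:
        points = [dict(p) for p in grid]

    n_rep = n_replicates if n_replicates is not None else cfg.n_replicates
    master = seed if seed is not None else cfg.seed
    ss = master if isinstance(master, np.random.SeedSequence) \
        else np.random.SeedSequence(master)
    point_streams = ss.spawn(len(points))

    rows = []
    for idx, (point, stream) in enumerate(zip(points, point_streams)):
        fp, dp, hp = _point_params(point, fitness, development, habitat)
        tf = total_fitness(fp.S, fp.T)
        od = classify_overdominance(tf)
        sa = classify_sexual_antagonism(tf)
        for rep, child in enumerate(stream.spawn(n_rep)):
            traj = simulator.run_simulation(cfg, fp, dp, hp,
                                            rng=np.random.default_rng(child))
            out = classify_polymorphism(traj, window=window)
            rs = realized_relative_survival(traj, sex=MALE)
            row = {"point": idx, **point, "replicate": rep,
                   "status": out["status"], "p_eq": out["p_eq"],
                   "f_AA": out["props_eq"][0], "f_AB": out["props_eq"][1],
                   "f_BB": out["props_eq"][2],
                   "surv_m_AA": rs[0], "surv_m_AB": rs[1], "surv_m_BB": rs[2],
                   "overdominance_f": bool(od[FEMALE]),
                   "overdominance_m": bool(od[MALE]),
                   "sexual_antagonism": sa}
            rows.append(row)
        if progress is not None:
            progress(idx + 1, len(points))
    return pd.DataFrame(rows)


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a sweep table per grid point.

    Adds the fraction of replicates maintaining polymorphism, fixing each
    allele or going extinct, and the mean equilibrium composition.
    """
    keys = [c for c in table.columns
            if c in ("point", "t_bb_m", "t_ab_m", "a_mean", "a_var",
                     "s_m", "s_f", "t_m", "t_f", "H_s", "H_t")]
    grouped = table.groupby(keys, dropna=False)
    out = grouped.agg(
        n=("status", "size"),
        frac_polymorphic=("status", lambda s: np.mean(s == "maintained")),
        frac_alpha_fixed=("status", lambda s: np.mean(s == "alpha_fixed")),
        frac_beta_fixed=("status", lambda s: np.mean(s == "beta_fixed")),
        frac_extinct=("status", lambda s: np.mean(s == "extinct")),
        p_eq=("p_eq", "mean"),
        f_AA=("f_AA", "mean"), f_AB=("f_AB", "mean"), f_BB=("f_BB", "mean"),
        overdominance_f=("overdominance_f", "first"),
        overdominance_m=("overdominance_m", "first"),
        sexual_antagonism=("sexual_antagonism", "first"),
    ).reset_index()
    return out
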