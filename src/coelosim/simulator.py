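"""Stochastic individual-based generation cycle and its deterministic oracle.

Generations are non-overlapping.  Each generation runs two phases:

* **growth** — every egg survives with probability ``V * S[sex, genotype]``
  (binomial viability), surviving larvae draw an individual development
  time ``D_i`` (cube root of the product of three uniform draws on
  ``[mu(1-c), mu(1+c)]``) and an individual habitat availability ``A_i``
  (uniform on ``[A_mean - A_var, A_mean + A_var]``), and mature into
  adults only when ``D_i < A_i``;
* **reproduction** — every adult female mates once and lays
  ``round(E * T[f, g])`` eggs; her mate's genotype is drawn from the adult
  males with weight proportional to ``N_m[g] * T[m, g]`` (males may mate
  repeatedly), optionally damped by a negative frequency-dependent factor
  ``(1 - d * f_g,m)``.  Egg genotypes follow Mendelian inheritance (one
  uniformly drawn allele per parent) and egg sex is Bernoulli(sex_ratio).

A subset of ``K`` eggs (uniform sample without replacement) initiates the
next generation, mirroring the experimental census / a carrying capacity.
Egg and adult genotype compositions are recorded every generation.

:func:`deterministic_recursion` iterates the exact expected-value map of
the same cycle for an infinite population and serves as the verification
oracle for the stochastic engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (FEMALE, GENOTYPES, MALE, SEXES, DevelopmentParams,
                     FitnessParams, HabitatParams, SimulationConfig)

__all__ = [
    "Cohort", "GenerationRecord", "Trajectory",
    "initialize_cohort", "survive_viability", "draw_development_time",
    "draw_habitat_availability", "mature", "reproduce", "census",
    "run_simulation", "run_replicates",
    "maturation_probability", "deterministic_recursion",
    "expected_development_time",
]


@dataclass
class Cohort:
    """A stage cohort: parallel arrays of genotype (0=AA,1=AB,2=BB) and sex (0=f,1=m)."""

    genotype: np.ndarray
    sex: np.ndarray
    dev_time: np.ndarray = None  # set at the larval stage

    def __len__(self):
        return self.genotype.size

    def counts(self) -> np.ndarray:
        """(2, 3) array of counts by (sex, genotype)."""
        out = np.zeros((2, 3), dtype=np.int64)
        np.add.at(out, (self.sex, self.genotype), 1)
        return out


def _props(counts):
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    return counts / total if total > 0 else np.full(counts.shape, np.nan)


def _allele_freq(counts3):
    n = np.asarray(counts3, dtype=float)
    total = n.sum()
    if total == 0:
        return np.nan
    return (2 * n[0] + n[1]) / (2 * total)


@dataclass
class GenerationRecord:
    """Egg and adult composition of one generation."""

    generation: int
    egg_counts: np.ndarray = None    # (2, 3) by (sex, genotype)
    adult_counts: np.ndarray = None  # (2, 3)

    @property
    def egg_props(self):
        """Sex-pooled egg genotype proportions (AA, AB, BB)."""
        return _props(self.egg_counts.sum(axis=0))

    @property
    def adult_props(self):
        return _props(self.adult_counts.sum(axis=0))

    def adult_props_by_sex(self, sex: int):
        return _props(self.adult_counts[sex])

    @property
    def p_egg(self):
        return _allele_freq(self.egg_counts.sum(axis=0))

    @property
    def p_adult(self):
        return _allele_freq(self.adult_counts.sum(axis=0))


@dataclass
class Trajectory:
    """Ordered per-generation records of one simulation replicate."""

    records: list
    extinct: bool = False
    extinct_generation: int = None
    seed: object = None
    config: SimulationConfig = None

    def __len__(self):
        return len(self.records)

    @property
    def n_generations(self):
        return len(self.records) - 1

    def p_adult(self) -> np.ndarray:
        return np.array([r.p_adult for r in self.records])

    def p_egg(self) -> np.ndarray:
        return np.array([r.p_egg for r in self.records])

    def adult_props(self) -> np.ndarray:
        """(G+1, 3) sex-pooled adult genotype proportions."""
        return np.vstack([r.adult_props for r in self.records])

    def egg_props(self) -> np.ndarray:
        return np.vstack([r.egg_props for r in self.records])

    def to_frame(self, replicate: int = 0) -> pd.DataFrame:
        """Tidy long table: replicate, generation, stage, sex, genotype, count, ..."""
        rows = []
        for rec in self.records:
            for stage, counts in (("egg", rec.egg_counts), ("adult", rec.adult_counts)):
                if counts is None:
                    continue
                props = _props(counts.sum(axis=0))
                p = _allele_freq(counts.sum(axis=0))
                for s in (FEMALE, MALE):
                    for g in range(3):
                        rows.append({
                            "replicate": replicate,
                            "generation": rec.generation,
                            "stage": stage,
                            "sex": SEXES[s],
                            "genotype": GENOTYPES[g],
                            "count": int(counts[s, g]),
                            "proportion": props[g],
                            "p_alpha": p,
                            "extinct": self.extinct,
                        })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stochastic steps

def initialize_cohort(cfg: SimulationConfig, rng: np.random.Generator) -> Cohort:
    """Found a cohort of ``k`` eggs: multinomial genotypes, Bernoulli sex."""
    counts = rng.multinomial(cfg.k, cfg.initial_props)
    genotype = np.repeat(np.arange(3, dtype=np.int8), counts)
    sex = (rng.random(cfg.k) >= cfg.sex_ratio).astype(np.int8)  # 0=f with prob sex_ratio
    return Cohort(genotype=genotype, sex=sex)


def survive_viability(eggs: Cohort, fp: FitnessParams, rng: np.random.Generator) -> Cohort:
    """Binomial egg-to-larva survival with probability ``V * S[sex, genotype]``."""
    p = fp.V * fp.S[eggs.sex, eggs.genotype]
    keep = rng.random(len(eggs)) < p
    return Cohort(genotype=eggs.genotype[keep], sex=eggs.sex[keep])


def draw_development_time(sex, genotype, dp: DevelopmentParams,
                          rng: np.random.Generator) -> np.ndarray:
    """Individual development times (days).

    ``D_i = (u1 u2 u3)^(1/3)`` with the ``u_j`` i.i.d. uniform on
    ``[mu(1-c), mu(1+c)]`` for the larva's sex and genotype.
    """
    mu = dp.mu[np.asarray(sex), np.asarray(genotype)]
    lo, hi = mu * (1 - dp.c), mu * (1 + dp.c)
    u = rng.uniform(lo[..., None], hi[..., None], size=(*np.shape(mu), 3))
    return np.cbrt(u.prod(axis=-1))


def draw_habitat_availability(hp: HabitatParams, rng: np.random.Generator,
                              size=None) -> np.ndarray:
    """Per-larva habitat availability ``A_i ~ U[a_mean - a_var, a_mean + a_var]``."""
    return rng.uniform(hp.a_mean - hp.a_var, hp.a_mean + hp.a_var, size=size)


def mature(larvae: Cohort, hp: HabitatParams, rng: np.random.Generator) -> Cohort:
    """Keep exactly the larvae whose development finished before habitat loss."""
    if len(larvae) == 0:
        return larvae
    a = draw_habitat_availability(hp, rng, size=len(larvae))
    keep = larvae.dev_time < a
    return Cohort(genotype=larvae.genotype[keep], sex=larvae.sex[keep])


def grow(eggs: Cohort, fp: FitnessParams, dp: DevelopmentParams,
         hp: HabitatParams, rng: np.random.Generator) -> Cohort:
    """Full growth phase: viability, development time, habitat censoring."""
    larvae = survive_viability(eggs, fp, rng)
    larvae.dev_time = draw_development_time(larvae.sex, larvae.genotype, dp, rng)
    return mature(larvae, hp, rng)


class ExtinctionError(RuntimeError):
    """Raised internally when a replicate loses one sex or all eggs."""


def _father_genotype_weights(male_counts: np.ndarray, fp: FitnessParams,
                             freq_dep: float) -> np.ndarray:
    w = male_counts.astype(float) * fp.T[MALE]
    if freq_dep > 0 and male_counts.sum() > 0:
        f = male_counts / male_counts.sum()
        w = w * np.clip(1.0 - freq_dep * f, 0.0, None)
    return w


def reproduce(adults: Cohort, fp: FitnessParams, rng: np.random.Generator,
              sex_ratio: float = 0.5, freq_dep: float = 0.0) -> Cohort:
    """Reproduction phase: fecundity, weighted mate draw, Mendelian eggs.

    Raises :class:`ExtinctionError` when either sex is absent or no eggs
    are laid.
    """
    females = adults.genotype[adults.sex == FEMALE]
    male_counts = np.bincount(adults.genotype[adults.sex == MALE], minlength=3)
    if females.size == 0 or male_counts.sum() == 0:
        raise ExtinctionError("no adults of one sex")

    w = _father_genotype_weights(male_counts, fp, freq_dep)
    if w.sum() <= 0:
        raise ExtinctionError("all male mating weights are zero")
    fathers = rng.choice(3, size=females.size, p=w / w.sum()).astype(np.int8)

    clutch = fp.eggs_per_female()[females]
    n_eggs = int(clutch.sum())
    if n_eggs == 0:
        raise ExtinctionError("no eggs laid")

    mother_g = np.repeat(females, clutch)
    father_g = np.repeat(fathers, clutch)

    def gamete(par_g):
        # allele contribution in beta-dose coding: AA->0, BB->1, AB->coin flip
        allele = (par_g // 2).astype(np.int8)
        het = par_g == 1
        n_het = int(het.sum())
        if n_het:
            allele[het] = rng.integers(0, 2, size=n_het, dtype=np.int8)
        return allele

    genotype = gamete(mother_g) + gamete(father_g)
    sex = (rng.random(n_eggs) >= sex_ratio).astype(np.int8)
    return Cohort(genotype=genotype.astype(np.int8), sex=sex)


def census(eggs: Cohort, k: int, rng: np.random.Generator) -> Cohort:
    """Uniform subsample without replacement of at most ``k`` eggs."""
    n = len(eggs)
    if n == 0:
        raise ExtinctionError("no eggs to census")
    if n <= k:
        return eggs
    idx = rng.choice(n, size=k, replace=False)
    return Cohort(genotype=eggs.genotype[idx], sex=eggs.sex[idx])


def run_simulation(cfg: SimulationConfig, fp: FitnessParams,
                   dp: DevelopmentParams, hp: HabitatParams,
                   rng=None) -> Trajectory:
    """Run one replicate of the generation cycle; reproducible from the seed.

    Eggs are recorded before the census (the full laid pool), adults after
    the growth phase.  Replicates that lose one sex or all eggs terminate
    early with ``extinct=True`` and a truncated record list.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    traj = Trajectory(records=[], seed=cfg.seed, config=cfg)
    eggs = initialize_cohort(cfg, rng)
    rec = GenerationRecord(generation=0, egg_counts=eggs.counts())
    traj.records.append(rec)
    for t in range(cfg.n_generations + 1):
        adults = grow(eggs, fp, dp, hp, rng)
        traj.records[-1].adult_counts = adults.counts()
        if t == cfg.n_generations:
            break
        try:
            laid = reproduce(adults, fp, rng, sex_ratio=cfg.sex_ratio,
                             freq_dep=cfg.freq_dep)
            traj.records.append(
                GenerationRecord(generation=t + 1, egg_counts=laid.counts()))
            eggs = census(laid, cfg.k, rng)
        except ExtinctionError:
            traj.extinct = True
            traj.extinct_generation = t
            break
    return traj


def run_replicates(cfg: SimulationConfig, fp: FitnessParams,
                   dp: DevelopmentParams, hp: HabitatParams,
                   n_replicates=None, seed=None) -> list:
    """Run independent replicates with child seeds spawned from one master seed."""
    n = cfg.n_replicates if n_replicates is None else n_replicates
    master = cfg.seed if seed is None else seed
    if not isinstance(master, np.random.SeedSequence):
        master = np.random.SeedSequence(master)
    streams = master.spawn(n)
    return [run_simulation(cfg, fp, dp, hp, rng=np.random.default_rng(s))
            for s in streams]


# ---------------------------------------------------------------------------
# deterministic infinite-population recursion (verification oracle)

_GL_NODES = 48


def _gl(lo, hi, n=_GL_NODES):
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (hi - lo) * x + 0.5 * (hi + lo), 0.5 * (hi - lo) * w / (hi - lo)


def maturation_probability(mu: float, c: float, a_mean: float, a_var: float) -> float:
    """P(D < A) for one sex-genotype class, by Gauss–Legendre quadrature.

    ``D = (u1 u2 u3)^(1/3)`` with ``u_j ~ U[mu(1-c), mu(1+c)]`` and
    ``A ~ U[a_mean - a_var, a_mean + a_var]``.  Degenerate cases (c = 0
    and/or a_var = 0) are handled exactly.
    """
    if c == 0:
        if a_var == 0:
            return float(mu < a_mean)
        lo, hi = a_mean - a_var, a_mean + a_var
        return float(np.clip((hi - mu) / (hi - lo), 0.0, 1.0))
    # D < A  <=>  v1 v2 v3 < (A/mu)^3 with v_j ~ U[1-c, 1+c]
    v, wv = _gl(1 - c, 1 + c)
    if a_var == 0:
        a_nodes, wa = np.array([a_mean]), np.array([1.0])
    else:
        a_nodes, wa = _gl(a_mean - a_var, a_mean + a_var)
    t = (a_nodes / mu) ** 3  # thresholds on the product
    v1 = v[:, None]
    v2 = v[None, :]
    prod12 = v1 * v2
    # inner CDF of v3 at t/(v1 v2), clipped to the uniform support
    cdf = np.clip((t[:, None, None] / prod12[None, :, :] - (1 - c)) / (2 * c), 0.0, 1.0)
    per_a = np.einsum("aij,i,j->a", cdf, wv, wv)
    return float(np.dot(per_a, wa))


def expected_development_time(mu: float, c: float) -> float:
    """Closed-form E[D] = mu * (E[v^(1/3)])^3 for v ~ U[1-c, 1+c]."""
    if c == 0:
        return float(mu)
    lo, hi = 1 - c, 1 + c
    m = 0.75 * (hi ** (4 / 3) - lo ** (4 / 3)) / (2 * c)
    return float(mu * m ** 3)


@dataclass
class RecursionResult:
    """Expected-value trajectory of the infinite-population recursion."""

    egg_props: np.ndarray        # (G+1, 3), sex-pooled (egg sex is independent)
    adult_props_f: np.ndarray    # (G+1, 3)
    adult_props_m: np.ndarray
    adult_props: np.ndarray      # pooled over sexes, weighted by survival mass
    p_adult: np.ndarray
    p_egg: np.ndarray
    extinct: bool = False


def deterministic_recursion(fp: FitnessParams, dp: DevelopmentParams,
                            hp: HabitatParams, initial_props,
                            n_generations: int,
                            sex_ratio: float = 0.5,
                            freq_dep: float = 0.0) -> RecursionResult:
    """Iterate the exact expected-value map of the generation cycle.

    Effective survival per (sex, genotype) class is
    ``V * S * P(D < A)``; maternal gamete α-frequency weights female adult
    proportions by the rounded clutch size ``round(E*T_f)``, paternal
    gamete frequency weights male adult proportions by ``T_m`` (optionally
    frequency-damped); next-generation egg genotype proportions are the
    products of the parental gamete frequencies.
    """
    surv = np.empty((2, 3))
    for s in (FEMALE, MALE):
        for g in range(3):
            surv[s, g] = fp.V * fp.S[s, g] * maturation_probability(
                dp.mu[s, g], dp.c, hp.a_mean, hp.a_var)

    fec = fp.eggs_per_female().astype(float)
    a_dose = np.array([1.0, 0.5, 0.0])  # alpha gametes per genotype

    G = n_generations
    egg = np.empty((G + 1, 3))
    ad_f = np.full((G + 1, 3), np.nan)
    ad_m = np.full((G + 1, 3), np.nan)
    ad = np.full((G + 1, 3), np.nan)
    egg[0] = np.asarray(initial_props, dtype=float)
    extinct = False

    for t in range(G + 1):
        mass_f = sex_ratio * egg[t] * surv[FEMALE]
        mass_m = (1 - sex_ratio) * egg[t] * surv[MALE]
        tot_f, tot_m = mass_f.sum(), mass_m.sum()
        if tot_f <= 0 or tot_m <= 0:
            extinct = True
            egg[t + 1:] = np.nan
            break
        ad_f[t] = mass_f / tot_f
        ad_m[t] = mass_m / tot_m
        ad[t] = (mass_f + mass_m) / (tot_f + tot_m)
        if t == G:
            break
        w_f = ad_f[t] * fec
        w_m = ad_m[t] * fp.T[MALE]
        if freq_dep > 0:
            w_m = w_m * np.clip(1.0 - freq_dep * ad_m[t], 0.0, None)
        if w_f.sum() <= 0 or w_m.sum() <= 0:
            extinct = True
            egg[t + 1:] = np.nan
            break
        pf = np.dot(w_f, a_dose) / w_f.sum()
        pm = np.dot(w_m, a_dose) / w_m.sum()
        egg[t + 1] = (pf * pm, pf * (1 - pm) + pm * (1 - pf), (1 - pf) * (1 - pm))

    p_egg = egg[:, 0] + 0.5 * egg[:, 1]
    p_ad = ad[:, 0] + 0.5 * ad[:, 1]
    return RecursionResult(egg_props=egg, adult_props_f=ad_f, adult_props_m=ad_m,
                           adult_props=ad, p_adult=p_ad, p_egg=p_egg,
                           extinct=extinct)
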