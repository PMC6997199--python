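"""Parameter sets for the inversion-polymorphism model.

The inversion behaves as a single Mendelian locus with two alleles, α and β.
Genotypes are written ``AA`` (αα), ``AB`` (αβ) and ``BB`` (ββ), always in
that order; sexes are ordered ``("f", "m")``.  Fitness enters the model
through four per-sex, per-genotype relative components:

* ``S`` — relative egg-to-adult survival, multiplied by a global viability
  ``V`` to give the per-egg survival probability,
* ``T`` — relative reproductive success: a fecundity weight for females and
  a mating-probability weight for males,

plus development-time means (days) and the habitat-availability window
(mean duration and half-width variability, days).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

GENOTYPES = ("AA", "AB", "BB")
SEXES = ("f", "m")
FEMALE, MALE = 0, 1


def _as_sex_genotype(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape != (2, 3):
        raise ValueError(f"{name} must have shape (2 sexes, 3 genotypes), got {a.shape}")
    return a


@dataclass(frozen=True)
class FitnessParams:
    """Relative survival/reproduction weights plus global viability and fecundity.

    Parameters
    ----------
    S : (2, 3) array
        Relative egg-to-adult survival per ``(sex, genotype)``; rows ordered
        ``(f, m)``, columns ``(AA, AB, BB)``.  Values in ``[0, 1]``.
    T : (2, 3) array
        Relative reproductive success per ``(sex, genotype)``, same layout.
    V : float
        Global egg-to-adult survival rate; the per-egg survival probability
        is ``V * S[sex, genotype]``.
    E : int
        Baseline number of eggs per female; a genotype-``g`` female lays
        ``round(E * T[f, g])`` eggs.
    """

    S: np.ndarray
    T: np.ndarray
    V: float = 0.3
    E: int = 70

    def __post_init__(self):
        object.__setattr__(self, "S", _as_sex_genotype(self.S, "S"))
        object.__setattr__(self, "T", _as_sex_genotype(self.T, "T"))
        if np.any(self.S < 0) or np.any(self.S > 1):
            raise ValueError("all relative survival values S must lie in [0, 1]")
        if np.any(self.T < 0) or np.any(self.T > 1):
            raise ValueError("all relative reproduction values T must lie in [0, 1]")
        if not 0 < self.V <= 1:
            raise ValueError("global viability V must lie in (0, 1]")
        if self.E <= 0 or int(self.E) != self.E:
            raise ValueError("fecundity E must be a positive integer")

    def eggs_per_female(self) -> np.ndarray:
        """Deterministic clutch size per female genotype: round(E * T_f)."""
        return np.rint(self.E * self.T[FEMALE]).astype(int)

    def replace(self, **kw) -> "FitnessParams":
        d = dict(S=self.S, T=self.T, V=self.V, E=self.E)
        d.update(kw)
        return FitnessParams(**d)


@dataclass(frozen=True)
class DevelopmentParams:
    """Development-time distribution parameters.

    ``mu`` holds the mean larval development time in days per
    ``(sex, genotype)``; an individual time is the cube root of the product
    of three draws from ``Uniform[mu(1-c), mu(1+c)]`` with variation
    coefficient ``c``.
    """

    mu: np.ndarray
    c: float = 0.5

    def __post_init__(self):
        object.__setattr__(self, "mu", _as_sex_genotype(self.mu, "mu"))
        if np.any(self.mu <= 0):
            raise ValueError("development means mu must be positive")
        if not 0 <= self.c < 1:
            raise ValueError("variation coefficient c must lie in [0, 1)")


@dataclass(frozen=True)
class HabitatParams:
    """Habitat (wrackbed) availability window.

    Each larva draws an individual availability ``A_i`` from
    ``Uniform[a_mean - a_var, a_mean + a_var]`` and matures only if its
    development time is shorter than ``A_i``.  ``a_var`` is the half-width
    of the window (days).
    """

    a_mean: float = 30.0
    a_var: float = 2.0

    def __post_init__(self):
        if self.a_mean <= 0:
            raise ValueError("a_mean must be positive")
        if self.a_var < 0:
            raise ValueError("a_var must be non-negative")
        if self.a_mean - self.a_var < 0:
            raise ValueError("a_mean - a_var must be non-negative")


@dataclass(frozen=True)
class TheoreticalParams:
    """Selection/dominance parameterization of the fitness components.

    ``s_m, s_f`` are survival selection coefficients against the α allele,
    ``t_m, t_f`` reproduction selection coefficients against the β allele,
    and ``H_s, H_t`` the dominance coefficients placing the heterozygote
    between the homozygotes for survival and reproduction respectively.
    All six values are dimensionless and must lie in [0, 1].
    """

    s_m: float = 0.0
    s_f: float = 0.0
    t_m: float = 0.0
    t_f: float = 0.0
    H_s: float = 0.5
    H_t: float = 0.5

    def __post_init__(self):
        for name in ("s_m", "s_f", "t_m", "t_f", "H_s", "H_t"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} = {v} outside [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Demographic/run configuration for the individual-based model.

    ``initial_props`` are the genotype proportions of the founding egg
    cohort; if ``p0`` is given instead, Hardy–Weinberg proportions
    ``(p0^2, 2 p0 (1-p0), (1-p0)^2)`` are used.  ``freq_dep`` is the
    coefficient ``d`` of the optional negative frequency-dependent male
    mating weight ``T_m[g] * (1 - d * f_g,m)``.
    """

    k: int = 1000
    n_generations: int = 5
    initial_props: tuple = None
    p0: float = None
    sex_ratio: float = 0.5
    n_replicates: int = 30
    seed: int = None
    freq_dep: float = 0.0

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("carrying capacity k must be positive")
        if self.n_generations < 0:
            raise ValueError("n_generations must be non-negative")
        if not 0 < self.sex_ratio < 1:
            raise ValueError("sex_ratio must lie in (0, 1)")
        if self.freq_dep < 0:
            raise ValueError("freq_dep coefficient must be non-negative")
        if self.initial_props is None:
            p = 0.5 if self.p0 is None else float(self.p0)
            if not 0 <= p <= 1:
                raise ValueError("p0 must lie in [0, 1]")
            props = (p * p, 2 * p * (1 - p), (1 - p) * (1 - p))
            object.__setattr__(self, "initial_props", props)
        else:
            props = tuple(float(v) for v in self.initial_props)
            if len(props) != 3 or any(v < 0 for v in props):
                raise ValueError("initial_props must be 3 non-negative values")
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError("initial_props must sum to 1 within 1e-9")
            object.__setattr__(self, "initial_props", props)

    def replace(self, **kw) -> "SimulationConfig":
        d = dict(
            k=self.k, n_generations=self.n_generations,
            initial_props=self.initial_props, sex_ratio=self.sex_ratio,
            n_replicates=self.n_replicates, seed=self.seed,
            freq_dep=self.freq_dep,
        )
        d.update(kw)
        if "p0" in kw:
            d["initial_props"] = None
        return SimulationConfig(**d)


def lab_default_params():
    """Laboratory-fitted default parameter set.

    Returns the ``(FitnessParams, DevelopmentParams, HabitatParams)`` triple
    estimated from the 5-generation laboratory evolution experiment:
    per-sex relative survival and reproductive success (the male mating
    weights 0.55/0.1 being the best-fit values from the trajectory fit),
    global viability 0.3, 70 eggs per female, sex- and genotype-specific
    development means, variation coefficient 0.5 and an effectively
    unlimited habitat window of 30 ± 2 days.
    """
    fp = FitnessParams(
        S=[[0.71, 0.90, 1.0],       # females
           [0.81, 1.00, 0.88]],     # males
        T=[[1.0, 0.97, 0.87],
           [1.0, 0.55, 0.10]],
        V=0.3,
        E=70,
    )
    dp = DevelopmentParams(
        mu=[[9.0, 8.7, 9.0],
            [12.8, 10.3, 8.8]],
        c=0.5,
    )
    hp = HabitatParams(a_mean=30.0, a_var=2.0)
    return fp, dp, hp


def from_theoretical(tp: TheoreticalParams, V: float = 0.3, E: int = 70) -> FitnessParams:
    """Build a :class:`FitnessParams` from the s/t/H parameterization.

    Survival selects against α (``S = (1-s, 1-s*H_s, 1)``) and reproduction
    against β (``T = (1, 1-t*H_t, 1-t)``), each per sex; within each sex
    the best genotype has weight 1.
    """
    S = [
        [1 - tp.s_f, 1 - tp.s_f * tp.H_s, 1.0],
        [1 - tp.s_m, 1 - tp.s_m * tp.H_s, 1.0],
    ]
    T = [
        [1.0, 1 - tp.t_f * tp.H_t, 1 - tp.t_f],
        [1.0, 1 - tp.t_m * tp.H_t, 1 - tp.t_m],
    ]
    return FitnessParams(S=S, T=T, V=V, E=E)


def to_theoretical(fp: FitnessParams) -> TheoreticalParams:
    """Invert :func:`from_theoretical` (defined when the S/T layout matches)."""
    s_f = 1 - fp.S[FEMALE, 0]
    s_m = 1 - fp.S[MALE, 0]
    t_f = 1 - fp.T[FEMALE, 2]
    t_m = 1 - fp.T[MALE, 2]
    H_s = (1 - fp.S[FEMALE, 1]) / s_f if s_f > 0 else (
        (1 - fp.S[MALE, 1]) / s_m if s_m > 0 else 0.5)
    H_t = (1 - fp.T[FEMALE, 1]) / t_f if t_f > 0 else (
        (1 - fp.T[MALE, 1]) / t_m if t_m > 0 else 0.5)
    return TheoreticalParams(s_m=s_m, s_f=s_f, t_m=t_m, t_f=t_f,
                             H_s=min(max(H_s, 0.0), 1.0),
                             H_t=min(max(H_t, 0.0), 1.0))


#: survival blocks for the larval-density presets.  "low" reproduces the
#: laboratory (low-density) estimates; medium/high-density values are not
#: published in usable form and must be supplied by the user.
_DENSITY_PRESETS = {
    "low": np.array([[0.71, 0.90, 1.0],
                     [0.81, 1.00, 0.88]]),
}


def density_preset(name: str, table=None, base: FitnessParams = None) -> FitnessParams:
    """Return a :class:`FitnessParams` with the survival block of a density preset.

    ``name`` is one of ``low``/``medium``/``high``; ``low`` is built in,
    the other two require a user-supplied ``table`` (a (2, 3) survival
    array).  Reproduction, viability and fecundity are taken from ``base``
    (laboratory defaults when omitted).
    """
    if base is None:
        base = lab_default_params()[0]
    if table is not None:
        S = _as_sex_genotype(table, f"density preset {name!r}")
    elif name in _DENSITY_PRESETS:
        S = _DENSITY_PRESETS[name]
    elif name in ("medium", "high"):
        raise KeyError(
            f"density preset {name!r} has no built-in survival values; "
            "pass them via table=")
    else:
        raise KeyError(f"unknown density preset {name!r}")
    return base.replace(S=S)


# ---------------------------------------------------------------------------
# configuration files ([fitness]/[development]/[habitat]/[simulation] TOML)

def load_config(path) -> dict:
    """Read a parameter file and return a dict of constructed parameter sets.

    The file is TOML with sections ``[fitness]``, ``[development]``,
    ``[habitat]`` and ``[simulation]``; missing sections fall back to the
    laboratory defaults.  Returns keys ``fitness``, ``development``,
    ``habitat``, ``simulation``.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return parse_config(raw)


def parse_config(raw: dict) -> dict:
    fp0, dp0, hp0 = lab_default_params()
    f = raw.get("fitness", {})
    fp = FitnessParams(
        S=[f.get("survival_female", fp0.S[FEMALE]),
           f.get("survival_male", fp0.S[MALE])],
        T=[f.get("reproduction_female", fp0.T[FEMALE]),
           f.get("reproduction_male", fp0.T[MALE])],
        V=f.get("viability", fp0.V),
        E=f.get("fecundity", fp0.E),
    )
    d = raw.get("development", {})
    dp = DevelopmentParams(
        mu=[d.get("mean_female", dp0.mu[FEMALE]),
            d.get("mean_male", dp0.mu[MALE])],
        c=d.get("variation", dp0.c),
    )
    h = raw.get("habitat", {})
    hp = HabitatParams(a_mean=h.get("a_mean", hp0.a_mean),
                       a_var=h.get("a_var", hp0.a_var))
    s = raw.get("simulation", {})
    cfg = SimulationConfig(
        k=s.get("carrying_capacity", 1000),
        n_generations=s.get("n_generations", 5),
        initial_props=s.get("initial_props"),
        p0=s.get("p0"),
        sex_ratio=s.get("sex_ratio", 0.5),
        n_replicates=s.get("n_replicates", 30),
        seed=s.get("seed"),
        freq_dep=s.get("freq_dep", 0.0),
    )
    return {"fitness": fp, "development": dp, "habitat": hp, "simulation": cfg}


def lab_default_config_path() -> Path:
    """Path of the bundled laboratory default parameter file."""
    return Path(resources.files("coelosim").joinpath("data/lab_default.toml"))
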