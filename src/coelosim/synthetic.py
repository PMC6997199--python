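"""Synthetic experiment-like genotype count tables with known ground truth.

The laboratory experiment genotyped a finite subsample of each replicate's
eggs (28–51, unsexed) and adults (40–95, sexed) at every generation.  The
generator here runs the individual-based simulator under known parameters
and applies the same finite genotyping, producing tidy count tables on
which the estimators and the trajectory fit can be validated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (FEMALE, GENOTYPES, MALE, SEXES, DevelopmentParams,
                     FitnessParams, HabitatParams, SimulationConfig,
                     lab_default_params)
from . import simulator

__all__ = ["SyntheticExperimentSpec", "sample_genotyping",
           "make_experiment_dataset"]


@dataclass
class SyntheticExperimentSpec:
    """Generating parameters and genotyping depths of a synthetic experiment."""

    fitness: FitnessParams = None
    development: DevelopmentParams = None
    habitat: HabitatParams = None
    config: SimulationConfig = None
    n_replicates: int = 4
    eggs_genotyped: tuple = (28, 51)
    adults_genotyped: tuple = (40, 95)
    seed: int = None

    def __post_init__(self):
        fp0, dp0, hp0 = lab_default_params()
        if self.fitness is None:
            self.fitness = fp0
        if self.development is None:
            self.development = dp0
        if self.habitat is None:
            self.habitat = hp0
        if self.config is None:
            self.config = SimulationConfig(k=1000, n_generations=5, p0=0.32)
        for rng_ in (self.eggs_genotyped, self.adults_genotyped):
            lo, hi = rng_
            if lo < 1 or hi < lo:
                raise ValueError("genotyping depth ranges must be >= 1 and ordered")


def sample_genotyping(true_props, n: int, rng: np.random.Generator) -> np.ndarray:
    """Multinomial genotyping of ``n`` individuals from true proportions."""
    p = np.asarray(true_props, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be non-negative and sum to 1")
    if n < 1:
        raise ValueError("genotyping depth must be >= 1")
    return rng.multinomial(n, p)


def _depth(bounds, rng):
    lo, hi = bounds
    return int(rng.integers(lo, hi + 1))


def make_experiment_dataset(spec: SyntheticExperimentSpec, rng=None):
    """Generate a tidy genotype count table plus the underlying truth.

    Per replicate, runs the simulator and genotypes a finite subsample of
    the egg pool (sex-pooled, eggs were not sexed in the experiment) and
    of the adults (split by sex proportionally to the true sex × genotype
    composition) at every recorded generation.  Returns
    ``(count_table, trajectories)``; extinct replicates contribute the
    generations they reached.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    trajectories = simulator.run_replicates(
        spec.config, spec.fitness, spec.development, spec.habitat,
        n_replicates=spec.n_replicates, seed=rng.integers(2 ** 31))
    rows = []
    for rep, traj in enumerate(trajectories):
        for rec in traj.records:
            if rec.egg_counts is not None and rec.egg_counts.sum() > 0:
                props = rec.egg_props
                counts = sample_genotyping(props, _depth(spec.eggs_genotyped, rng), rng)
                for g in range(3):
                    rows.append({"replicate": rep, "generation": rec.generation,
                                 "stage": "egg", "sex": "unknown",
                                 "genotype": GENOTYPES[g], "count": int(counts[g])})
            if rec.adult_counts is not None and rec.adult_counts.sum() > 0:
                flat = rec.adult_counts.astype(float).ravel()  # (f×3, m×3)
                n = _depth(spec.adults_genotyped, rng)
                n = min(n, int(rec.adult_counts.sum()))
                counts = rng.multinomial(n, flat / flat.sum()).reshape(2, 3)
                for s in (FEMALE, MALE):
                    for g in range(3):
                        rows.append({"replicate": rep,
                                     "generation": rec.generation,
                                     "stage": "adult", "sex": SEXES[s],
                                     "genotype": GENOTYPES[g],
                                     "count": int(counts[s, g])})
    return pd.DataFrame(rows), trajectories
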