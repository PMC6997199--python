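"""Fitness-component estimators for egg/adult genotype count tables.

Given genotype counts of eggs and of the adults they came from (and of the
parental adults that laid them), these estimators recover the two fitness
components the inversion acts on:

* **relative survival** — the ratio of a genotype's proportion among
  adults to its proportion among the eggs of the same generation; 1 for
  all genotypes means equal egg-to-adult survival;
* **deviation from random mating** — the ratio of a genotype's proportion
  among eggs to its Hardy–Weinberg expectation computed from the previous
  generation's adult allele frequency, minus 1; 0 for all genotypes means
  random mating with equal reproductive success.

A Pearson χ² goodness-of-fit test against the Hardy–Weinberg expectation,
with Fisher (or Stouffer) combination of probabilities across replicates,
tests the random-mating null.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .params import GENOTYPES

__all__ = [
    "allele_frequency", "hw_expected", "relative_survival",
    "mating_deviation", "random_mating_test", "combine_pvalues",
    "survival_table", "deviation_table", "bootstrap_counts",
]


def allele_frequency(counts) -> float:
    """α allele frequency ``(2 n_AA + n_AB) / (2 N)`` from (AA, AB, BB) counts."""
    n = np.asarray(counts, dtype=float)
    if n.shape[-1] != 3:
        raise ValueError("expected counts for the three genotypes (AA, AB, BB)")
    total = n.sum(axis=-1)
    if np.any(total == 0):
        raise ValueError("allele frequency undefined for zero total count")
    return (2 * n[..., 0] + n[..., 1]) / (2 * total)


def hw_expected(p) -> np.ndarray:
    """Hardy–Weinberg genotype proportions ``(p², 2p(1−p), (1−p)²)``."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("allele frequency must lie in [0, 1]")
    q = 1 - p
    return np.stack([p * p, 2 * p * q, q * q], axis=-1)


def relative_survival(egg_props, adult_props, normalize: bool = True) -> np.ndarray:
    """Per-genotype survival ratio ``adult_prop / egg_prop``.

    With ``normalize=True`` the ratios are rescaled so the best genotype
    is 1 (the scale relative survival is reported on).  A genotype absent
    from both stages yields NaN; absent from eggs but present in adults is
    an error (its ratio is not estimable).
    """
    e = np.asarray(egg_props, dtype=float)
    a = np.asarray(adult_props, dtype=float)
    if np.any((e == 0) & (a > 0)):
        raise ValueError("genotype present in adults but absent from eggs")
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where((e == 0) & (a == 0), np.nan, a / e)
    if normalize:
        best = np.nanmax(raw, axis=-1, keepdims=True)
        return raw / best
    return raw


def mating_deviation(parent_adult_counts, egg_counts) -> np.ndarray:
    """Fractional deviation of egg proportions from the random-mating expectation.

    ``dev[g] = egg_prop[g] / HW(p_parents)[g] - 1`` where ``p_parents`` is
    the allele frequency of the previous generation's adults.  Genotypes
    with zero Hardy–Weinberg expectation (p ∈ {0, 1}) are reported NaN.
    """
    p = allele_frequency(parent_adult_counts)
    exp = hw_expected(p)
    eggs = np.asarray(egg_counts, dtype=float)
    total = eggs.sum(axis=-1, keepdims=True)
    if np.any(total == 0):
        raise ValueError("no eggs to compare")
    obs = eggs / total
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(exp > 0, obs / exp - 1, np.nan)


def random_mating_test(egg_counts, expected_props):
    """Pearson χ² goodness-of-fit of egg counts to expected proportions.

    Categories with zero expectation must have zero observations (error
    otherwise) and are dropped; df = remaining categories − 1.  Returns
    ``(chi2, df, pvalue)``.
    """
    obs = np.asarray(egg_counts, dtype=float)
    exp = np.asarray(expected_props, dtype=float)
    if obs.sum() == 0:
        raise ValueError("all-zero observations")
    if np.any((exp == 0) & (obs > 0)):
        raise ValueError("observed counts in a zero-expectation category")
    keep = exp > 0
    obs, exp = obs[keep], exp[keep]
    exp_counts = exp / exp.sum() * obs.sum()
    chi2, p = stats.chisquare(obs, exp_counts)
    return float(chi2), int(obs.size - 1), float(p)


def combine_pvalues(pvalues, method: str = "fisher") -> float:
    """Combine independent p-values (Fisher's method by default)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        raise ValueError("no p-values to combine")
    return float(stats.combine_pvalues(pvalues, method=method).pvalue)


# ---------------------------------------------------------------------------
# tidy-table drivers

_KEY = ["replicate", "generation"]


def _cell_counts(df: pd.DataFrame, stage: str, sex=None) -> pd.DataFrame:
    """Counts per (replicate, generation, genotype) for a stage, sex-pooled or one sex."""
    sub = df[df["stage"] == stage]
    if sex is not None:
        sub = sub[sub["sex"] == sex]
    wide = (sub.groupby(_KEY + ["genotype"])["count"].sum()
            .unstack("genotype")
            .reindex(columns=list(GENOTYPES), fill_value=0)
            .fillna(0))
    return wide


def survival_table(df: pd.DataFrame, by_sex: bool = False,
                   normalize: bool = True) -> pd.DataFrame:
    """Relative survival per replicate × generation from a tidy count table.

    Egg proportions are always sex-pooled (eggs are not sexed); adult
    proportions are pooled or per sex with ``by_sex=True``.  Rows with no
    adults or no eggs in a cell are dropped.
    """
    eggs = _cell_counts(df, "egg")
    egg_props = eggs.div(eggs.sum(axis=1), axis=0)
    out = []
    sexes = ["f", "m"] if by_sex else [None]
    for sex in sexes:
        adults = _cell_counts(df, "adult", sex=sex)
        adult_props = adults.div(adults.sum(axis=1), axis=0)
        idx = egg_props.index.intersection(adult_props.index)
        for key in idx:
            e = egg_props.loc[key].to_numpy()
            a = adult_props.loc[key].to_numpy()
            if not np.isfinite(e).all() or not np.isfinite(a).all():
                continue
            ratios = relative_survival(e, a, normalize=normalize)
            rec = dict(zip(_KEY, key))
            rec["sex"] = sex if sex is not None else "pooled"
            rec.update(dict(zip(GENOTYPES, ratios)))
            out.append(rec)
    return pd.DataFrame(out)


def deviation_table(df: pd.DataFrame) -> pd.DataFrame:
    """Deviation from random mating per replicate × generation.

    Eggs of generation ``t`` are compared to the Hardy–Weinberg
    expectation from the adults of generation ``t − 1`` within the same
    replicate; generations without a parental adult record are skipped.
    """
    eggs = _cell_counts(df, "egg")
    adults = _cell_counts(df, "adult")
    out = []
    for (rep, gen) in eggs.index:
        parent_key = (rep, gen - 1)
        if parent_key not in adults.index:
            continue
        parents = adults.loc[parent_key].to_numpy()
        egg_counts = eggs.loc[(rep, gen)].to_numpy()
        if parents.sum() == 0 or egg_counts.sum() == 0:
            continue
        dev = mating_deviation(parents, egg_counts)
        rec = {"replicate": rep, "generation": gen}
        rec.update(dict(zip(GENOTYPES, dev)))
        out.append(rec)
    return pd.DataFrame(out)


def random_mating_table(df: pd.DataFrame, method: str = "fisher"):
    """χ² random-mating test per replicate × generation plus the combined p.

    Returns ``(table, combined_p)`` where the table has one row per tested
    cell (chi2, df, pvalue).
    """
    eggs = _cell_counts(df, "egg")
    adults = _cell_counts(df, "adult")
    rows = []
    for (rep, gen) in eggs.index:
        parent_key = (rep, gen - 1)
        if parent_key not in adults.index:
            continue
        parents = adults.loc[parent_key].to_numpy()
        egg_counts = eggs.loc[(rep, gen)].to_numpy()
        if parents.sum() == 0 or egg_counts.sum() == 0:
            continue
        exp = hw_expected(allele_frequency(parents))
        try:
            chi2, dof, p = random_mating_test(egg_counts, exp)
        except ValueError:
            continue
        rows.append({"replicate": rep, "generation": gen,
                     "chi2": chi2, "df": dof, "pvalue": p})
    table = pd.DataFrame(rows)
    combined = combine_pvalues(table["pvalue"], method=method) if len(table) else np.nan
    return table, combined


def bootstrap_counts(df: pd.DataFrame, statistic, n_boot: int = 200,
                     seed=None) -> np.ndarray:
    """Replicate-level bootstrap of a count-table statistic.

    Resamples replicates with replacement and re-evaluates ``statistic``
    (a callable on the tidy table) on each resample; returns the array of
    bootstrap values.
    """
    rng = np.random.default_rng(seed)
    reps = df["replicate"].unique()
    out = []
    for _ in range(n_boot):
        chosen = rng.choice(reps, size=reps.size, replace=True)
        frames = []
        for i, r in enumerate(chosen):
            sub = df[df["replicate"] == r].copy()
            sub["replicate"] = i
            frames.append(sub)
        out.append(statistic(pd.concat(frames, ignore_index=True)))
    return np.asarray(out)
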