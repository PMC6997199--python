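"""Tabular I/O, config echo and run manifests.

Count tables and trajectory tables travel as TSV with a fixed header;
lines starting with ``#`` carry a ``key = value`` config echo and are
ignored on read.  A JSON run manifest (command, resolved config, master
seed, package version, outputs) makes every output reproducible.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .params import GENOTYPES

COUNT_COLUMNS = ["replicate", "generation", "stage", "sex", "genotype", "count"]
_STAGES = {"egg", "adult"}
_SEXES = {"f", "m", "unknown"}


def read_count_table(path) -> pd.DataFrame:
    """Read and validate a tidy genotype count TSV.

    Requires the header ``replicate generation stage sex genotype count``;
    checks stage/sex/genotype vocabularies, non-negative integer counts
    and key uniqueness.  An empty table with a valid header is fine.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df[COUNT_COLUMNS]
    if len(df) == 0:
        return df
    for col, vocab in (("stage", _STAGES), ("sex", _SEXES),
                       ("genotype", set(GENOTYPES))):
        bad = set(df[col].unique()) - vocab
        if bad:
            row = df.index[df[col].isin(bad)][0]
            raise ValueError(
                f"{path}: invalid {col} value {sorted(bad)[0]!r} (row {row})")
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts < 0) | (counts != counts.round())
    if bad.any():
        row = df.index[bad][0]
        raise ValueError(
            f"{path}: count must be a non-negative integer "
            f"(row {row}: {df.loc[row, 'count']!r})")
    df["count"] = counts.astype(int)
    keys = df[COUNT_COLUMNS[:-1]]
    if keys.duplicated().any():
        row = keys.index[keys.duplicated()][0]
        raise ValueError(f"{path}: duplicate key at row {row}")
    return df


def write_table(df: pd.DataFrame, path, config_echo: dict = None):
    """Write a TSV with an optional ``# key = value`` config-echo header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (config_echo or {}).items():
            fh.write(f"# {k} = {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def trajectories_to_frame(trajectories) -> pd.DataFrame:
    """Concatenate replicate trajectories into one tidy long table."""
    return pd.concat(
        [traj.to_frame(replicate=i) for i, traj in enumerate(trajectories)],
        ignore_index=True)


def config_echo(cfg=None, fp=None, dp=None, hp=None, **extra) -> dict:
    """Flatten parameter sets into a ``key = value`` echo dict."""
    echo = {}
    if fp is not None:
        echo.update({
            "survival_female": list(fp.S[0]), "survival_male": list(fp.S[1]),
            "reproduction_female": list(fp.T[0]),
            "reproduction_male": list(fp.T[1]),
            "viability": fp.V, "fecundity": fp.E,
        })
    if dp is not None:
        echo.update({"dev_mean_female": list(dp.mu[0]),
                     "dev_mean_male": list(dp.mu[1]), "dev_variation": dp.c})
    if hp is not None:
        echo.update({"a_mean": hp.a_mean, "a_var": hp.a_var})
    if cfg is not None:
        echo.update({"carrying_capacity": cfg.k,
                     "n_generations": cfg.n_generations,
                     "initial_props": list(cfg.initial_props),
                     "sex_ratio": cfg.sex_ratio,
                     "n_replicates": cfg.n_replicates,
                     "freq_dep": cfg.freq_dep, "seed": cfg.seed})
    echo.update(extra)
    return echo


def write_manifest(path, command: str, config: dict, seed, outputs):
    """Write a JSON run manifest sufficient to regenerate every output."""
    from . import __version__

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "package": "coelosim",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": [str(p) for p in outputs],
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, default=default) + "\n")
    return manifest
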