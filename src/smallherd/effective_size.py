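"""Effective population size from LD decay and from inbreeding rate.

Historical Ne: under drift-recombination equilibrium the expected genotypic
r2 between loci c Morgans apart is E(r2) ~ 1/(alpha + 4 Ne c), with alpha=2
when mutation matters and 1 otherwise, so Ne ~ (1/(4c)) (1/r2 - alpha).
Each inter-marker distance probes the population roughly t = 1/(2c)
generations ago, so the binned decay curve yields an Ne trajectory.

Contemporary Ne: from the rate of inbreeding, Ne = 1/(2 dF), where dF is
the per-generation change of an inbreeding coefficient -- here the OLS
regression slope of F on birth year multiplied by the generation interval
in years.

Also provides Wright's pedigree inbreeding coefficient (recursive kinship)
and a percentile bootstrap for cohort means.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import UNKNOWN_PARENT

DEFAULT_GENERATION_INTERVAL_YEARS = 5.66


@dataclass
class NeLDConfig:
    alpha: int = 2           # 2 with mutation, 1 without
    cm_per_mb: float = 1.25  # genetic per physical distance
    # The distance-to-generation map t = 1/(2c) follows the convention that
    # short distances reflect ancient Ne and long distances recent Ne.
    t_numerator: float = 0.5  # t = t_numerator / c

    def __post_init__(self):
        if self.alpha not in (1, 2):
            raise ValueError("alpha must be 1 or 2")
        if self.cm_per_mb <= 0:
            raise ValueError("cm_per_mb must be positive")


@dataclass
class DeltaF:
    slope_per_year: float
    generation_interval_years: float

    @property
    def delta_f(self) -> float:
        return self.slope_per_year * self.generation_interval_years


def ne_from_r2(mean_r2: float, c_morgans: float, alpha: int = 2) -> float:
    """Ne ~ (1/(4c)) (1/r2 - alpha), truncated at 0."""
    if not 0.0 < mean_r2 <= 1.0:
        raise ValueError("mean_r2 must be in (0, 1]")
    if c_morgans <= 0:
        raise ValueError("c_morgans must be positive")
    ne = (1.0 / (4.0 * c_morgans)) * (1.0 / mean_r2 - alpha)
    return max(ne, 0.0)


def generations_ago(c_morgans: float, t_numerator: float = 0.5) -> float:
    """Generations ago probed by loci c Morgans apart (t = 1/(2c) by default)."""
    if c_morgans <= 0:
        raise ValueError("c_morgans must be positive")
    return t_numerator / c_morgans


def ne_trajectory(bins: pd.DataFrame, cfg: NeLDConfig | None = None) -> pd.DataFrame:
    """Historical Ne trajectory from binned LD decay.

    Each populated bin's midpoint distance maps to a recombination distance
    c = mid_Mb * cm_per_mb / 100 Morgans, hence a time t and an Ne estimate.
    Bins whose t rounds to the same integer generation are aggregated into
    mean +/- SD.
    """
    cfg = cfg or NeLDConfig()
    rows = []
    for _, b in bins.iterrows():
        if b["n_pairs"] < 1 or not np.isfinite(b["mean_r2"]) or b["mean_r2"] <= 0:
            continue
        mid_mb = 0.5 * (b["bin_lo_bp"] + b["bin_hi_bp"]) / 1e6
        c = mid_mb * cfg.cm_per_mb / 100.0
        t = generations_ago(c, cfg.t_numerator)
        ne = ne_from_r2(min(b["mean_r2"], 1.0), c, cfg.alpha)
        rows.append((int(round(t)), ne))
    if not rows:
        return pd.DataFrame(columns=["t_generations", "ne", "sd", "n_bins"])
    df = pd.DataFrame(rows, columns=["t_generations", "ne"])
    agg = df.groupby("t_generations")["ne"].agg(["mean", "std", "count"]).reset_index()
    agg.columns = ["t_generations", "ne", "sd", "n_bins"]
    return agg.sort_values("t_generations").reset_index(drop=True)


def delta_f_from_regression(
    f_values,
    birth_years,
    gi_years: float = DEFAULT_GENERATION_INTERVAL_YEARS,
) -> DeltaF:
    """OLS slope of an inbreeding coefficient on birth year, scaled to one
    generation by the generation interval."""
    f = np.asarray(f_values, dtype=float)
    years = np.asarray(birth_years, dtype=float)
    if len(f) != len(years) or len(f) < 2:
        raise ValueError("need matched F values and birth years (n >= 2)")
    if np.unique(years).size < 2:
        raise ValueError("all birth years identical; slope undefined")
    slope = stats.linregress(years, f).slope
    return DeltaF(slope_per_year=float(slope), generation_interval_years=gi_years)


def ne_from_delta_f(delta_f: float) -> float:
    """Inbreeding effective size Ne = 1/(2 dF); NaN when dF <= 0 (no
    detectable inbreeding accumulation)."""
    if delta_f <= 0:
        return float("nan")
    return 1.0 / (2.0 * delta_f)


def bootstrap_mean_ci(
    values,
    reps: int = 10_000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """Percentile bootstrap confidence interval for the mean."""
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise ValueError("empty sample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(reps, len(x)))
    means = x[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(x.mean()), float(lo), float(hi)


# ---------------------------------------------------------------------------
# pedigree inbreeding
# ---------------------------------------------------------------------------

def pedigree_inbreeding(samples: pd.DataFrame) -> pd.Series:
    """Wright's inbreeding coefficient per sample via recursive kinship.

    Parents outside the table (or the unknown sentinel) contribute zero
    relatedness; founders therefore have F = 0.
    """
    ids = samples["sample_id"].tolist()
    sire = dict(zip(samples["sample_id"], samples["sire_id"]))
    dam = dict(zip(samples["sample_id"], samples["dam_id"]))
    known = set(ids)

    def parents(a):
        s, d = sire.get(a, UNKNOWN_PARENT), dam.get(a, UNKNOWN_PARENT)
        return (s if s in known else None, d if d in known else None)

    # birth-order rank for "older" comparisons; fall back to table order
    order = {a: i for i, a in enumerate(ids)}
    if "birth_year" in samples.columns:
        by = dict(zip(samples["sample_id"], samples["birth_year"]))
        order = {a: (by[a], i) for i, a in enumerate(ids)}

    cache: dict[tuple, float] = {}
    sys.setrecursionlimit(max(sys.getrecursionlimit(), 10 * len(ids) + 1000))

    def kin(a, b) -> float:
        if a is None or b is None:
            return 0.0
        if a == b:
            s, d = parents(a)
            return 0.5 * (1.0 + kin_cached(s, d))
        # recurse on the younger animal
        if order[a] < order[b]:
            a, b = b, a
        s, d = parents(a)
        return 0.5 * (kin_cached(s, b) + kin_cached(d, b))

    def kin_cached(a, b) -> float:
        if a is None or b is None:
            return 0.0
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            cache[key] = kin(a, b)
        return cache[key]

    out = {}
    for a in ids:
        s, d = parents(a)
        out[a] = kin_cached(s, d)
    return pd.Series(out, name="f_ped")
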