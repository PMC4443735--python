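"""Within-chromosome linkage disequilibrium and its decay with distance.

LD between two SNPs is the squared Pearson correlation of 0/1/2 genotype
dosages (the genotypic r-squared, not the haplotype EM r-squared), computed
over individuals non-missing at both markers.  Pairs where either marker is
monomorphic in that pairwise-complete subset have undefined r2 and are
excluded from all summaries rather than set to zero.

The decay curve summarises all same-chromosome pairs closer than 10 Mb in
half-open 100 kb distance bins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

DEFAULT_MAX_DIST_BP = 10_000_000
DEFAULT_BIN_BP = 100_000

PAIR_COLUMNS = ["snp_j", "snp_m", "chromosome", "distance_bp", "r2"]


def squared_correlation(g_j: np.ndarray, g_m: np.ndarray) -> float:
    """Squared dosage correlation between two markers; NaN when undefined.

    Undefined means fewer than two pairwise-complete individuals or zero
    dosage variance at either marker within that subset.
    """
    g_j = np.asarray(g_j, dtype=np.int16)
    g_m = np.asarray(g_m, dtype=np.int16)
    if g_j.shape != g_m.shape:
        raise ValueError("dosage vectors must have equal length")
    both = (g_j != MISSING) & (g_m != MISSING)
    if both.sum() < 2:
        return float("nan")
    x = g_j[both].astype(float)
    y = g_m[both].astype(float)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        return float("nan")
    sxy = float(xc @ yc)
    return min(1.0, sxy * sxy / (sxx * syy))


def _pairwise_r2_block(calls: np.ndarray) -> np.ndarray:
    """All-pairs genotypic r2 for one chromosome, pairwise-complete, NaN
    where undefined.  calls: (n_individuals, m) with MISSING = -1."""
    x = calls.astype(float)
    mask = (calls != MISSING).astype(float)
    xz = np.where(calls == MISSING, 0.0, x)

    n = mask.T @ mask                      # pairwise-complete counts
    sx = xz.T @ mask                       # sum of x_j over joint support
    sy = sx.T
    sxy = xz.T @ xz
    sxx = (xz * xz).T @ mask
    syy = sxx.T

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        r2 = (cov * cov) / (varx * vary)
    r2[(n < 2) | (varx <= 0) | (vary <= 0)] = np.nan
    return np.minimum(r2, 1.0, where=~np.isnan(r2), out=r2)


def ld_scan(g: GenotypeMatrix, max_dist_bp: int = DEFAULT_MAX_DIST_BP) -> pd.DataFrame:
    """All same-chromosome marker pairs with 0 < distance < ``max_dist_bp``.

    Returns one row per pair (j before m in map order) with the pair's r2;
    undefined pairs carry NaN.  The map must be sorted.
    """
    g.validate()
    frames = []
    chroms = g.markers["chromosome"].to_numpy()
    positions = g.markers["position_bp"].to_numpy()
    snp_ids = g.markers["snp_id"].to_numpy()
    for chrom in np.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if len(idx) < 2:
            continue
        pos = positions[idx]
        r2 = _pairwise_r2_block(g.calls[:, idx])
        jj, mm = np.triu_indices(len(idx), k=1)
        dist = pos[mm] - pos[jj]
        sel = (dist > 0) & (dist < max_dist_bp)
        frames.append(
            pd.DataFrame(
                {
                    "snp_j": snp_ids[idx[jj[sel]]],
                    "snp_m": snp_ids[idx[mm[sel]]],
                    "chromosome": chrom,
                    "distance_bp": dist[sel],
                    "r2": r2[jj[sel], mm[sel]],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def bin_decay(
    pairs: pd.DataFrame,
    bin_bp: int = DEFAULT_BIN_BP,
    max_dist_bp: int = DEFAULT_MAX_DIST_BP,
) -> pd.DataFrame:
    """Mean/SD of r2 in half-open [lo, hi) distance bins tiling (0, max].

    Pairs with undefined r2 do not contribute; empty bins carry n_pairs = 0
    and NaN summaries.  SD is the ddof=1 standard deviation, defined only
    for bins with at least two pairs.
    """
    n_bins = int(np.ceil(max_dist_bp / bin_bp))
    lo = np.arange(n_bins, dtype=np.int64) * bin_bp
    out = pd.DataFrame(
        {
            "bin_lo_bp": lo,
            "bin_hi_bp": lo + bin_bp,
            "n_pairs": 0,
            "mean_r2": np.nan,
            "sd_r2": np.nan,
        }
    )
    if len(pairs) == 0:
        return out
    defined = pairs.dropna(subset=["r2"])
    if len(defined) == 0:
        return out
    which = (defined["distance_bp"].to_numpy() // bin_bp).astype(int)
    ok = which < n_bins
    which, r2 = which[ok], defined["r2"].to_numpy()[ok]
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=r2, minlength=n_bins)
    sums2 = np.bincount(which, weights=r2 * r2, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = (sums2 - counts * mean**2) / np.maximum(counts - 1, 1)
    out["n_pairs"] = counts
    out["mean_r2"] = mean
    out["sd_r2"] = np.where(counts >= 2, np.sqrt(np.maximum(var, 0.0)), np.nan)
    return out


def adjacent_ld_summary(g: GenotypeMatrix) -> tuple[float, float]:
    """Mean and SD of r2 over physically adjacent same-chromosome pairs."""
    g.validate()
    chroms = g.markers["chromosome"].to_numpy()
    values = []
    for chrom in np.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for a, b in zip(idx[:-1], idx[1:]):
            r2 = squared_correlation(g.calls[:, a], g.calls[:, b])
            if not np.isnan(r2):
                values.append(r2)
    if len(values) < 2:
        raise ValueError("fewer than 2 adjacent pairs with defined r2")
    arr = np.asarray(values)
    return float(arr.mean()), float(arr.std(ddof=1))
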