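"""Runs of homozygosity: detection, F_ROH, ancestor dating, islands.

A run of homozygosity (ROH) is a stretch of consecutive homozygous SNP
calls interpreted as autozygosity -- both chromosome copies inherited from
a recent common ancestor.  The detection rule keeps maximal runs of at
least ``min_snps`` consecutive homozygous SNPs whose neighbouring SNPs are
never more than ``max_gap_bp`` apart and whose average marker density is at
least one SNP per ``max_bp_per_snp``.  Heterozygous and missing calls both
break a run by default; small allowances can be configured.

The genomic inbreeding coefficient is F_ROH = L_ROH / L_AUTOSOME, the summed
length of ROH above a minimum-length threshold divided by the SNP-covered
autosome length.  Thresholds of 4, 8 and 16 Mb date the autozygosity to
roughly 12, 6 and 3 generations back (expected exchange of one recombination
per 100/(2g) cM with 1 cM ~ 1 Mb).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

#: autosome length covered by a bovine 50K chip, bp
DEFAULT_L_AUTOSOME_BP = 2_499_624_571

SEGMENT_COLUMNS = ["sample_id", "chromosome", "start_bp", "end_bp", "start_idx", "end_idx", "n_snps", "length_bp"]


@dataclass
class ROHParams:
    min_snps: int = 15
    max_gap_bp: int = 1_000_000
    max_bp_per_snp: int = 100_000
    allow_missing_in_run: int = 0
    allow_het_in_run: int = 0

    def __post_init__(self):
        if min(self.min_snps, self.max_gap_bp, self.max_bp_per_snp) <= 0:
            raise ValueError("min_snps, max_gap_bp and max_bp_per_snp must be positive")
        if min(self.allow_missing_in_run, self.allow_het_in_run) < 0:
            raise ValueError("allowances must be non-negative")


def detect_roh(
    g: GenotypeMatrix,
    params: ROHParams | None = None,
    require_qc: bool = True,
) -> pd.DataFrame:
    """Detect ROH per individual per chromosome.

    Expects a matrix that went through the ROH QC track (override with
    ``require_qc=False``).  Returns one row per segment with positions of
    the first/last SNP in the run and length = end_bp - start_bp.
    """
    params = params or ROHParams()
    g.validate()
    if require_qc and not g.roh_qc_applied:
        raise ValueError(
            "genotypes have not been through ROH QC; pass require_qc=False to override"
        )

    chroms = g.markers["chromosome"].to_numpy()
    positions = g.markers["position_bp"].to_numpy()
    sample_ids = g.samples["sample_id"].to_numpy()
    rows = []
    for chrom in np.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        pos = positions[idx]
        big_gap_after = np.zeros(len(idx), dtype=bool)
        if len(idx) > 1:
            big_gap_after[:-1] = np.diff(pos) > params.max_gap_bp
        for i in range(g.n_samples):
            calls = g.calls[i, idx]
            for s, e in _scan_runs(calls, big_gap_after, params):
                n_snps = e - s + 1
                length = int(pos[e] - pos[s])
                if n_snps >= params.min_snps and length / n_snps <= params.max_bp_per_snp:
                    rows.append(
                        (
                            sample_ids[i],
                            int(chrom),
                            int(pos[s]),
                            int(pos[e]),
                            int(idx[s]),
                            int(idx[e]),
                            int(n_snps),
                            length,
                        )
                    )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def _scan_runs(calls: np.ndarray, big_gap_after: np.ndarray, params: ROHParams):
    """Maximal candidate windows before count/density filtering.

    With zero allowances these are the maximal runs of consecutive
    homozygous calls split at oversized gaps.  With allowances, a two-
    pointer sweep yields maximal windows that start and end homozygous and
    contain at most the allowed numbers of het/missing calls.
    """
    hom = (calls == 0) | (calls == 2)
    het = calls == 1
    miss = calls == MISSING
    m = len(calls)

    if params.allow_het_in_run == 0 and params.allow_missing_in_run == 0:
        # simple segmentation: breaks at non-hom calls and big gaps
        start = None
        for k in range(m):
            if hom[k] and start is None:
                start = k
            if start is not None:
                last = k == m - 1 or not hom[k + 1] or big_gap_after[k]
                if last:
                    yield start, k
                    start = None
        return

    # generalized sweep (maximal windows, possibly overlapping)
    prev_end = -1
    for s in range(m):
        if not hom[s]:
            continue
        n_het = n_miss = 0
        e = s
        k = s
        while k + 1 < m:
            if big_gap_after[k]:
                break
            nxt = k + 1
            nh = n_het + int(het[nxt])
            nm = n_miss + int(miss[nxt])
            if nh > params.allow_het_in_run or nm > params.allow_missing_in_run:
                break
            k = nxt
            n_het, n_miss = nh, nm
            if hom[k]:
                e = k
        if e > prev_end:
            yield s, e
            prev_end = e


# ---------------------------------------------------------------------------
# F_ROH and ancestor dating
# ---------------------------------------------------------------------------

def froh(
    segments: pd.DataFrame,
    threshold_mb: float,
    sample_ids,
    l_autosome_bp: int = DEFAULT_L_AUTOSOME_BP,
) -> pd.DataFrame:
    """Per-sample F_ROH = total length of ROH longer than ``threshold_mb`` Mb
    divided by ``l_autosome_bp``.  Samples without qualifying segments get 0."""
    if threshold_mb < 0:
        raise ValueError("threshold must be non-negative")
    if l_autosome_bp <= 0:
        raise ValueError("autosome length must be positive")
    sample_ids = list(sample_ids)
    out = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "threshold_mb": float(threshold_mb),
            "n_segments": 0,
            "total_length_bp": 0,
            "f_roh": 0.0,
        }
    )
    if len(segments):
        sel = segments[segments["length_bp"] > threshold_mb * 1e6]
        agg = sel.groupby("sample_id")["length_bp"].agg(["count", "sum"])
        idx = out.set_index("sample_id").index
        common = agg.index.intersection(idx)
        out = out.set_index("sample_id")
        out.loc[common, "n_segments"] = agg.loc[common, "count"].astype(int)
        out.loc[common, "total_length_bp"] = agg.loc[common, "sum"].astype(int)
        out["f_roh"] = out["total_length_bp"] / float(l_autosome_bp)
        out = out.reset_index()
    return out


def generations_from_length(length_mb: float, cm_per_mb: float = 1.0) -> int:
    """Generations to the common ancestor implied by a minimum ROH length.

    An autozygous segment from an ancestor g generations back has expected
    length 100/(2g) cM; inverting and flooring gives g = floor(100/(2 L_cM)),
    reproducing the conventional 4/8/16 Mb -> 12/6/3 generation labels.
    """
    if length_mb <= 0:
        raise ValueError("length must be positive")
    if cm_per_mb <= 0:
        raise ValueError("cm_per_mb must be positive")
    return int(math.floor(100.0 / (2.0 * length_mb * cm_per_mb)))


# ---------------------------------------------------------------------------
# incidence and autozygosity islands
# ---------------------------------------------------------------------------

def roh_incidence(
    segments: pd.DataFrame,
    g: GenotypeMatrix,
    threshold_mb: float = 4.0,
) -> np.ndarray:
    """Per-SNP fraction of individuals with a qualifying ROH covering it."""
    n = g.n_samples
    covered = np.zeros(g.n_markers, dtype=float)
    if n == 0 or len(segments) == 0:
        return covered
    chroms = g.markers["chromosome"].to_numpy()
    positions = g.markers["position_bp"].to_numpy()
    sel = segments[segments["length_bp"] > threshold_mb * 1e6]
    for sample_id, sub in sel.groupby("sample_id"):
        hit = np.zeros(g.n_markers, dtype=bool)
        for _, seg in sub.iterrows():
            on_chrom = chroms == seg["chromosome"]
            hit |= on_chrom & (positions >= seg["start_bp"]) & (positions <= seg["end_bp"])
        covered += hit
    return covered / n


def find_islands(incidence: np.ndarray, markers: pd.DataFrame) -> pd.DataFrame:
    """Autozygosity islands: maximal runs of consecutive Tukey-outlier SNPs.

    A SNP is an outlier when its ROH incidence exceeds Q3 + 1.5 IQR of the
    genome-wide incidence distribution (quartiles by midpoint
    interpolation).  Runs are bounded by chromosome ends.
    """
    incidence = np.asarray(incidence, dtype=float)
    if len(incidence) != len(markers):
        raise ValueError("incidence vector not aligned to marker map")
    if len(incidence) < 4:
        raise ValueError("need at least 4 SNPs to form quartiles")
    q1, q3 = np.percentile(incidence, [25, 75], method="midpoint")
    cut = q3 + 1.5 * (q3 - q1)
    outlier = incidence > cut

    chroms = markers["chromosome"].to_numpy()
    snp_ids = markers["snp_id"].to_numpy()
    positions = markers["position_bp"].to_numpy()
    rows = []
    k = 0
    m = len(incidence)
    while k < m:
        if outlier[k]:
            e = k
            while e + 1 < m and outlier[e + 1] and chroms[e + 1] == chroms[k]:
                e += 1
            rows.append(
                (
                    int(chroms[k]),
                    int(positions[k]),
                    int(positions[e]),
                    snp_ids[k],
                    snp_ids[e],
                    e - k + 1,
                    float(incidence[k : e + 1].max()),
                )
            )
            k = e + 1
        else:
            k += 1
    return pd.DataFrame(
        rows,
        columns=["chromosome", "start_bp", "end_bp", "start_snp", "end_snp", "n_snps", "peak_incidence"],
    )
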