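"""Two SNP-array quality-control pipelines.

``apply_marker_qc`` / ``apply_sample_qc`` implement the standard track used
for LD, effective-size and genomic-prediction work: marker call rate, exact
Hardy-Weinberg test, minor allele frequency, duplicated physical positions,
then sample call rate.

``apply_roh_qc`` implements the stricter track used before calling runs of
homozygosity: markers are dropped on array-quality scores (GenCall <= 0.7,
GenTrain <= 0.4, both inclusive) and samples on missingness > 5%, while MAF,
HWE and LD are deliberately left unfiltered -- low-MAF and out-of-HWE
markers carry real autozygosity signal.

Boundary conventions are strict: a marker with call rate exactly at the
threshold survives the standard track, while a score exactly at the cut is
removed in the ROH track.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .genotype_io import GenotypeMatrix, QualityScores

log = logging.getLogger(__name__)


@dataclass
class QCConfig:
    """Thresholds for the standard QC track (removal is strictly below/above)."""

    marker_call_rate_min: float = 0.90
    hwe_p_min: float = 1e-6
    maf_min: float = 0.05
    sample_call_rate_min: float = 0.90
    drop_duplicate_positions: bool = True

    def __post_init__(self):
        for name in ("marker_call_rate_min", "hwe_p_min", "maf_min", "sample_call_rate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class ROHQCConfig:
    """Thresholds for the ROH QC track (score cuts are inclusive)."""

    gencall_min: float = 0.7
    gentrain_min: float = 0.4
    sample_missing_max: float = 0.05


@dataclass
class QCReport:
    """Per-step removal counts, in application order."""

    steps: list = field(default_factory=list)  # (step name, axis, n removed)
    n_markers_in: int = 0
    n_markers_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0

    def add(self, name: str, axis: str, n_removed: int) -> None:
        self.steps.append({"step": name, "axis": axis, "removed": int(n_removed)})

    def removed(self, axis: str) -> int:
        return sum(s["removed"] for s in self.steps if s["axis"] == axis)

    def to_dict(self) -> dict:
        return {
            "steps": list(self.steps),
            "markers": {"in": self.n_markers_in, "out": self.n_markers_out},
            "samples": {"in": self.n_samples_in, "out": self.n_samples_out},
        }


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-sided Hardy-Weinberg test for one biallelic marker.

    Conditional on the sample size and minor-allele count, heterozygote
    counts follow the Levene-Haldane distribution; the p-value sums the
    probabilities of all heterozygote configurations no more probable than
    the observed one (the plain exact test, no mid-p correction).
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotyped individual required")

    n_b = 2 * n_bb + n_ab
    minor = min(n_b, 2 * n - n_b)
    hets = np.arange(minor % 2, minor + 1, 2)
    hom_minor = (minor - hets) // 2
    hom_major = n - hets - hom_minor
    logp = (
        gammaln(n + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hets + 1)
        - gammaln(hom_major + 1)
        + hets * np.log(2.0)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.nonzero(hets == n_ab)[0][0]]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    """Exact HWE p-value for every marker (1.0 where no calls exist)."""
    out = np.ones(g.n_markers)
    calls = g.calls
    for k in range(g.n_markers):
        col = calls[:, k]
        n_bb = int((col == 2).sum())
        n_ab = int((col == 1).sum())
        n_aa = int((col == 0).sum())
        if n_aa + n_ab + n_bb > 0:
            out[k] = hwe_exact_test(n_aa, n_ab, n_bb)
    return out


# ---------------------------------------------------------------------------
# standard track
# ---------------------------------------------------------------------------

def apply_marker_qc(g: GenotypeMatrix, cfg: QCConfig | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Marker filters in fixed order: call rate, HWE, MAF, duplicate positions."""
    cfg = cfg or QCConfig()
    report = QCReport(n_markers_in=g.n_markers, n_samples_in=g.n_samples)

    keep = g.marker_call_rate() >= cfg.marker_call_rate_min
    report.add("marker_call_rate", "marker", (~keep).sum())
    g = g.subset_markers(np.flatnonzero(keep))

    pvals = hwe_pvalues(g)
    keep = pvals >= cfg.hwe_p_min
    report.add("hwe", "marker", (~keep).sum())
    g = g.subset_markers(np.flatnonzero(keep))

    with np.errstate(invalid="ignore"):
        maf = g.maf()
    keep = ~(maf < cfg.maf_min)  # monomorphic-with-no-calls (NaN) kept here
    keep &= ~np.isnan(maf)
    report.add("maf", "marker", (~keep).sum())
    g = g.subset_markers(np.flatnonzero(keep))

    if cfg.drop_duplicate_positions:
        keep_idx = _dedupe_positions(g)
        report.add("duplicate_position", "marker", g.n_markers - len(keep_idx))
        g = g.subset_markers(keep_idx)
    else:
        report.add("duplicate_position", "marker", 0)

    if g.n_markers == 0:
        warnings.warn("marker QC removed every marker", stacklevel=2)
    report.n_markers_out = g.n_markers
    report.n_samples_out = g.n_samples
    return g, report


def _dedupe_positions(g: GenotypeMatrix) -> np.ndarray:
    """Indices to keep: per duplicated (chrom, pos), the highest call rate wins;
    ties keep the first in map order."""
    call_rate = g.marker_call_rate()
    best: dict[tuple, int] = {}
    chrom = g.markers["chromosome"].to_numpy()
    pos = g.markers["position_bp"].to_numpy()
    for k in range(g.n_markers):
        key = (chrom[k], pos[k])
        if key not in best or call_rate[k] > call_rate[best[key]]:
            best[key] = k
    return np.array(sorted(best.values()), dtype=int)


def apply_sample_qc(g: GenotypeMatrix, cfg: QCConfig | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Drop samples with call rate strictly below the threshold (after marker QC)."""
    cfg = cfg or QCConfig()
    report = QCReport(n_markers_in=g.n_markers, n_samples_in=g.n_samples)
    keep = g.sample_call_rate() >= cfg.sample_call_rate_min
    report.add("sample_call_rate", "sample", (~keep).sum())
    g = g.subset_samples(np.flatnonzero(keep))
    if g.n_samples == 0:
        raise ValueError("sample QC removed every sample")
    report.n_markers_out = g.n_markers
    report.n_samples_out = g.n_samples
    return g, report


def apply_standard_qc(g: GenotypeMatrix, cfg: QCConfig | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Full standard track: marker QC then sample QC, one merged report."""
    cfg = cfg or QCConfig()
    g1, rep_m = apply_marker_qc(g, cfg)
    g2, rep_s = apply_sample_qc(g1, cfg)
    report = QCReport(
        steps=rep_m.steps + rep_s.steps,
        n_markers_in=rep_m.n_markers_in,
        n_markers_out=g2.n_markers,
        n_samples_in=rep_m.n_samples_in,
        n_samples_out=g2.n_samples,
    )
    return g2, report


# ---------------------------------------------------------------------------
# ROH track
# ---------------------------------------------------------------------------

def apply_roh_qc(
    g: GenotypeMatrix,
    scores: QualityScores,
    cfg: ROHQCConfig | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Score-based marker filters then sample missingness; no MAF/HWE/LD filters."""
    cfg = cfg or ROHQCConfig()
    aligned = scores.aligned_to(g.markers)
    report = QCReport(n_markers_in=g.n_markers, n_samples_in=g.n_samples)

    gencall = aligned["gencall"].to_numpy(dtype=float)
    gentrain = aligned["gentrain"].to_numpy(dtype=float)
    drop = (gencall <= cfg.gencall_min) | (gentrain <= cfg.gentrain_min)
    report.add("quality_scores", "marker", drop.sum())
    g = g.subset_markers(np.flatnonzero(~drop))

    missingness = 1.0 - g.sample_call_rate()
    keep = missingness <= cfg.sample_missing_max
    report.add("sample_missingness", "sample", (~keep).sum())
    g = g.subset_samples(np.flatnonzero(keep))

    report.n_markers_out = g.n_markers
    report.n_samples_out = g.n_samples
    g.roh_qc_applied = True
    return g, report
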