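"""Genomic prediction by GBLUP with reliability-weighted residuals.

The model is y = 1 mu + Z g + e with g ~ N(0, G sigma2_g) on a VanRaden
genomic relationship matrix and heteroscedastic residuals e ~ N(0, R
sigma2_e).  Records are pseudo-phenotypes (EBV or deregressed EBV) whose
reliability r2 sets the residual weight: record weight w = r2/(1-r2), i.e.
R_ii = (1-r2)/r2 by default.  A literal convention R_ii = r2/(1-r2) is also
available (``weights="as_printed"``) since some descriptions print the
weight itself on the R diagonal; the convention used is recorded on the
result.

Validation follows forward prediction: older animals form the reference,
young animals (born after a cutoff year) are predicted through G, and
accuracy is the Pearson correlation of GEBV with the validation pseudo-
phenotypes, bootstrapped for standard errors.  The parent-average
correlation diagnostic flags accuracies that merely recover parent
averages, the characteristic failure mode of small reference populations
with low-reliability validation proofs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, UNKNOWN_PARENT

GRM_JITTER = 0.01  # ridge added to G before inversion


@dataclass
class GRM:
    """VanRaden (method 1) genomic relationship matrix."""

    values: np.ndarray
    sample_ids: list
    allele_frequencies: np.ndarray

    def index_of(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"sample absent from GRM: {e.args[0]}") from None


@dataclass
class TraitRecords:
    """Per-animal pseudo-phenotypes with reliabilities for one trait."""

    table: pd.DataFrame  # sample_id, trait, pseudo_phenotype, reliability, kind

    def __post_init__(self):
        rel = self.table["reliability"].to_numpy(dtype=float)
        if ((rel <= 0) | (rel >= 1)).any():
            raise ValueError("reliabilities must lie strictly in (0, 1)")
        if not self.table["kind"].isin(["ebv", "debv"]).all():
            raise ValueError("kind must be 'ebv' or 'debv'")

    def for_samples(self, ids) -> pd.DataFrame:
        sub = self.table.set_index("sample_id")
        present = [s for s in ids if s in sub.index]
        return sub.loc[present].reset_index()


@dataclass
class GBLUPResult:
    gebv: pd.Series
    mu_hat: float
    variance_ratio: float
    weight_convention: str
    accuracy: float = float("nan")
    bootstrap_mean: float = float("nan")
    bootstrap_se: float = float("nan")
    bootstrap_lo: float = float("nan")
    bootstrap_hi: float = float("nan")
    pa_correlation: float = float("nan")
    meta: dict = field(default_factory=dict)


def build_grm(g: GenotypeMatrix) -> GRM:
    """G = W W' / (2 sum p(1-p)) with W the 2p-centred dosage matrix.

    Allele frequencies are observed over the full (combined) sample;
    missing dosages are imputed to 2p, i.e. contribute nothing after
    centring.  Monomorphic markers add nothing to numerator or denominator.
    """
    p = g.allele_b_frequency()
    usable = np.isfinite(p)
    p = np.where(usable, p, 0.0)
    het = p * (1.0 - p)
    denom = 2.0 * het.sum()
    if denom <= 0:
        raise ValueError("all markers monomorphic; GRM undefined")
    x = g.calls.astype(float)
    x = np.where(g.calls == MISSING, 2.0 * p[None, :], x)
    w = x - 2.0 * p[None, :]
    w[:, ~usable] = 0.0
    values = (w @ w.T) / denom
    return GRM(
        values=values,
        sample_ids=list(g.samples["sample_id"]),
        allele_frequencies=p,
    )


# ---------------------------------------------------------------------------
# reference/validation design
# ---------------------------------------------------------------------------

def forward_split(
    samples: pd.DataFrame,
    cutoff_year: int = 2003,
    scenario: str = "single",
    focal_breed: str | None = None,
    donor_breeds: tuple = (),
) -> tuple[list, list]:
    """Forward-prediction split by birth year.

    single: focal animals born <= cutoff form the reference, younger focal
    animals the validation set.  multi: the single-breed reference plus all
    donor-breed animals.  across: all focal animals are validated, donors
    alone form the reference.
    """
    if scenario not in ("single", "multi", "across"):
        raise ValueError(f"unknown scenario {scenario!r}")
    breeds = samples["breed"]
    focal_breed = focal_breed or breeds.iloc[0]
    focal = samples[breeds == focal_breed]
    donors = samples[breeds.isin(list(donor_breeds))]

    if scenario == "across":
        reference = donors["sample_id"].tolist()
        validation = focal["sample_id"].tolist()
    else:
        old = focal[focal["birth_year"] <= cutoff_year]
        young = focal[focal["birth_year"] > cutoff_year]
        reference = old["sample_id"].tolist()
        validation = young["sample_id"].tolist()
        if scenario == "multi":
            reference += donors["sample_id"].tolist()
    if not reference:
        raise ValueError("empty reference set")
    if not validation:
        raise ValueError("empty validation set")
    return reference, validation


def debv_reliability_filter(records: TraitRecords, min_rel: float = 0.3) -> TraitRecords:
    """Drop deregressed-EBV records with reliability strictly below
    ``min_rel``; EBV records pass untouched."""
    t = records.table
    keep = (t["kind"] != "debv") | (t["reliability"] >= min_rel)
    return TraitRecords(table=t[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# mixed-model solve
# ---------------------------------------------------------------------------

def solve_gblup(
    grm: GRM,
    records: TraitRecords,
    reference: list,
    variance_ratio: float,
    weights: str = "standard",
    use_weights: bool = True,
    jitter: float = GRM_JITTER,
) -> GBLUPResult:
    """Solve the mixed-model equations; GEBVs come back for every GRM sample.

    ``variance_ratio`` is lambda = sigma2_e / sigma2_g.  ``weights``:
    "standard" puts (1-r2)/r2 on the R diagonal (reliable records get small
    residual variance); "as_printed" puts r2/(1-r2) there.
    """
    if variance_ratio <= 0:
        raise ValueError("variance_ratio must be positive")
    if weights not in ("standard", "as_printed"):
        raise ValueError(f"unknown weight convention {weights!r}")

    recs = records.for_samples(reference)
    if len(recs) == 0:
        raise ValueError("no reference records")
    y = recs["pseudo_phenotype"].to_numpy(dtype=float)
    rel = recs["reliability"].to_numpy(dtype=float)
    if use_weights:
        r_diag = (1.0 - rel) / rel if weights == "standard" else rel / (1.0 - rel)
    else:
        r_diag = np.ones_like(rel)
    r_inv = 1.0 / r_diag

    n_g = len(grm.sample_ids)
    z_idx = grm.index_of(recs["sample_id"])
    g_stab = grm.values + jitter * np.eye(n_g)
    g_inv = np.linalg.inv(g_stab)

    # MME: [1'R-1 1, 1'R-1 Z; Z'R-1 1, Z'R-1 Z + lambda G-1] [mu; g] = [1'R-1 y; Z'R-1 y]
    zrz = np.zeros((n_g, n_g))
    np.add.at(zrz, (z_idx, z_idx), r_inv)
    zr1 = np.zeros(n_g)
    np.add.at(zr1, z_idx, r_inv)
    zry = np.zeros(n_g)
    np.add.at(zry, z_idx, r_inv * y)

    lhs = np.zeros((n_g + 1, n_g + 1))
    lhs[0, 0] = r_inv.sum()
    lhs[0, 1:] = zr1
    lhs[1:, 0] = zr1
    lhs[1:, 1:] = zrz + variance_ratio * g_inv
    rhs = np.concatenate(([(r_inv * y).sum()], zry))

    try:
        sol = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular mixed-model equations: {e}") from e
    mu_hat = float(sol[0])
    gebv = pd.Series(sol[1:], index=pd.Index(grm.sample_ids, name="sample_id"), name="gebv")
    return GBLUPResult(
        gebv=gebv,
        mu_hat=mu_hat,
        variance_ratio=variance_ratio,
        weight_convention=weights if use_weights else "unweighted",
        meta={"jitter": jitter, "n_reference_records": len(recs)},
    )


def variance_ratio_from_h2(h2: float) -> float:
    """lambda = (1 - h2)/h2 for a pseudo-phenotype of heritability h2."""
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must be in (0, 1)")
    return (1.0 - h2) / h2


# ---------------------------------------------------------------------------
# validation metrics
# ---------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def accuracy(gebv: pd.Series, records: TraitRecords, validation: list) -> float:
    """Pearson correlation of GEBV with validation pseudo-phenotypes."""
    recs = records.for_samples(validation)
    recs = recs[recs["sample_id"].isin(gebv.index)]
    if len(recs) < 3:
        raise ValueError("need at least 3 validation animals with records")
    pred = gebv.loc[recs["sample_id"]].to_numpy()
    obs = recs["pseudo_phenotype"].to_numpy(dtype=float)
    return _pearson(pred, obs)


def bootstrap_accuracy(
    gebv: np.ndarray,
    pseudo: np.ndarray,
    reps: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float, float, int]:
    """Bootstrap the validation correlation over animals.

    Returns (mean, SE, lower 2.5%, upper 97.5%, n_redrawn); resamples where
    either vector is constant are redrawn and counted.
    """
    x = np.asarray(gebv, dtype=float)
    y = np.asarray(pseudo, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("gebv and pseudo-phenotypes must be matched vectors")
    n = len(x)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def corr_rows(idx):
        xs, ys = x[idx], y[idx]
        xm = xs - xs.mean(axis=1, keepdims=True)
        ym = ys - ys.mean(axis=1, keepdims=True)
        sx = (xm**2).sum(axis=1)
        sy = (ym**2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xm * ym).sum(axis=1) / np.sqrt(sx * sy)
        r[(sx == 0) | (sy == 0)] = np.nan
        return r

    rs = corr_rows(rng.integers(0, n, size=(reps, n)))
    n_redrawn = 0
    while np.isnan(rs).any():
        bad = np.flatnonzero(np.isnan(rs))
        n_redrawn += len(bad)
        rs[bad] = corr_rows(rng.integers(0, n, size=(len(bad), n)))
    lo, hi = np.quantile(rs, [0.025, 0.975])
    return float(rs.mean()), float(rs.std(ddof=1)) if reps > 1 else 0.0, float(lo), float(hi), n_redrawn


def parent_average(records: TraitRecords, samples: pd.DataFrame, ids) -> pd.Series:
    """PA = 0.5 (pseudo_sire + pseudo_dam) where both parents are recorded
    and phenotyped; animals lacking either are omitted."""
    pheno = records.table.set_index("sample_id")["pseudo_phenotype"]
    ped = samples.set_index("sample_id")
    out = {}
    for a in ids:
        if a not in ped.index:
            continue
        s, d = ped.loc[a, "sire_id"], ped.loc[a, "dam_id"]
        if s == UNKNOWN_PARENT or d == UNKNOWN_PARENT:
            continue
        if s in pheno.index and d in pheno.index:
            out[a] = 0.5 * (float(pheno[s]) + float(pheno[d]))
    return pd.Series(out, name="parent_average")


def parent_average_correlation(
    records: TraitRecords,
    samples: pd.DataFrame,
    gebv: pd.Series,
    validation: list,
) -> float:
    """Correlation of GEBV with parent averages over validation animals."""
    pa = parent_average(records, samples, validation)
    pa = pa[pa.index.isin(gebv.index)]
    if len(pa) < 3:
        raise ValueError("fewer than 3 validation animals with computable parent average")
    return _pearson(gebv.loc[pa.index].to_numpy(), pa.to_numpy())


def pca_grm(grm: GRM, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Leading eigenvectors of the GRM, scaled by sqrt(eigenvalue).

    Returns per-sample coordinates and the explained-variance fractions
    (eigenvalue over the summed positive spectrum).
    """
    vals, vecs = np.linalg.eigh(grm.values)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = np.clip(vals, 0.0, None)
    total = pos.sum()
    explained = pos / total if total > 0 else np.zeros_like(pos)
    k = min(n_components, len(vals))
    coords = vecs[:, :k] * np.sqrt(pos[:k])[None, :]
    df = pd.DataFrame(
        coords,
        columns=[f"pc{i + 1}" for i in range(k)],
        index=pd.Index(grm.sample_ids, name="sample_id"),
    )
    return df, explained[:k]
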