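"""Forward-in-time simulator of a small closed breed.

Discrete non-overlapping generations of a finite diploid population with
recombination produce exactly the statistical structure the analysis
modules assume: LD generated by drift at finite Ne, runs of homozygosity
from pedigree loops, paternal half-sib families from polygynous (AI-style)
matings, and pseudo-phenotypes (EBV/dEBV) at controlled reliability.

Founders are drawn in linkage equilibrium with allele-B frequencies uniform
on (0.05, 0.95); all LD is subsequently created by drift, the regime the
LD-based Ne estimator assumes.  Gametes recombine as a Poisson crossover
process (no interference) on chromosomes of fixed genetic length; marker
positions are uniform with 1 cM = 1 Mb, so genetic and physical maps
coincide.

Two mating systems:

* ``two_sex`` (default): ``n_sires`` males and the remaining females are
  parents; each offspring draws a random sire and a random dam.  Few sires
  mimic AI-bull population structure; the variance effective size is then
  4 Nm Nf / (Nm + Nf), below the census size.
* ``wright_fisher``: the idealized monoecious model -- both gametes of an
  offspring come from parents drawn uniformly with replacement (selfing
  allowed).  This is the configuration in which the closed-form laws
  F_t = 1 - (1 - 1/(2N))^t and per-generation heterozygosity decay
  (1 - 1/(2N)) hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import SAMPLE_COLUMNS, GenotypeMatrix, QualityScores, UNKNOWN_PARENT


@dataclass
class SimConfig:
    n_chromosomes: int = 29
    chrom_length_cm: float = 100.0
    markers_per_chromosome: int = 1000
    ne: int = 100
    n_generations: int = 20
    n_sires_per_generation: int | None = None  # default: ne // 4 (polygyny)
    mating: str = "two_sex"                    # or "wright_fisher"
    mutation_rate: float = 0.0                 # per marker per meiosis
    qtl_count: int = 100
    h2: float = 0.4
    ebv_reliability_range: tuple = (0.6, 0.95)
    debv_reliability_factor: float = 0.85      # dEBV reliabilities = factor * EBV's
    cutoff_year_fraction: float = 0.2          # final fraction of generations = "young"
    base_year: int = 1990
    breed: str = "SYN"
    low_score_marker_fraction: float = 0.0     # markers given failing QC scores
    seed: int = 0

    def __post_init__(self):
        if self.markers_per_chromosome < 2:
            raise ValueError("markers_per_chromosome must be >= 2")
        if self.ne < 2:
            raise ValueError("ne must be >= 2")
        if self.mating not in ("two_sex", "wright_fisher"):
            raise ValueError(f"unknown mating system {self.mating!r}")
        n_sires = self.n_sires
        if self.mating == "two_sex" and not 1 <= n_sires < self.ne:
            raise ValueError("need 1 <= n_sires < ne")
        for name in ("mutation_rate", "cutoff_year_fraction", "h2"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def n_sires(self) -> int:
        if self.n_sires_per_generation is not None:
            return self.n_sires_per_generation
        return max(1, self.ne // 4)

    @property
    def cutoff_year(self) -> int:
        """Birth year splitting old (reference) from young (validation)."""
        young_gens = max(1, int(round(self.cutoff_year_fraction * self.n_generations)))
        return self.base_year + self.n_generations - young_gens


@dataclass
class SimOutput:
    genotypes: GenotypeMatrix          # all generations, founders first
    true_bv: pd.Series                 # indexed by sample_id
    trait_records: pd.DataFrame        # EBV + dEBV rows, TraitRecords layout
    quality_scores: QualityScores
    qtl_effects: pd.Series             # indexed by snp_id (zero off-QTL markers omitted)
    config: SimConfig

    @property
    def samples(self) -> pd.DataFrame:
        return self.genotypes.samples


# ---------------------------------------------------------------------------
# core simulation
# ---------------------------------------------------------------------------

def _marker_map(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    chrom_bp = int(cfg.chrom_length_cm * 1e6)  # 1 cM = 1 Mb
    rows = []
    for c in range(1, cfg.n_chromosomes + 1):
        want = cfg.markers_per_chromosome
        pos = np.unique(rng.integers(1, chrom_bp + 1, size=2 * want))
        while len(pos) < want:  # top up on the (rare) collision shortfall
            extra = rng.integers(1, chrom_bp + 1, size=want)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.choice(pos, size=want, replace=False))
        for k, p in enumerate(pos):
            rows.append((f"snp_c{c}_{k:05d}", c, int(p)))
    df = pd.DataFrame(rows, columns=["snp_id", "chromosome", "position_bp"])
    df["allele_a"] = "B"
    df["allele_b"] = "A"  # counted allele sorts first so text round trips are exact
    return df


def _meiosis(
    haplos: np.ndarray,          # (2, m) uint8 for one parent
    chrom_slices: list,
    marker_cm: list,             # per chromosome, marker positions in cM
    chrom_length_cm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    gamete = np.empty(haplos.shape[1], dtype=np.uint8)
    for sl, cm in zip(chrom_slices, marker_cm):
        k = rng.poisson(chrom_length_cm / 100.0)
        start = rng.integers(0, 2)
        if k == 0:
            gamete[sl] = haplos[start, sl]
            continue
        xpos = np.sort(rng.uniform(0.0, chrom_length_cm, size=k))
        source = (start + np.searchsorted(xpos, cm)) % 2
        block = haplos[:, sl]
        gamete[sl] = np.where(source == 0, block[0], block[1])
    return gamete


def simulate_breed(cfg: SimConfig | None = None) -> SimOutput:
    """Run the simulation; deterministic for a fixed config (incl. seed)."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    markers = _marker_map(cfg, rng)
    m = len(markers)
    chrom_slices, marker_cm = [], []
    chroms = markers["chromosome"].to_numpy()
    for c in range(1, cfg.n_chromosomes + 1):
        idx = np.flatnonzero(chroms == c)
        chrom_slices.append(slice(idx[0], idx[-1] + 1))
        marker_cm.append(markers["position_bp"].to_numpy()[idx] / 1e6)

    founder_freq = rng.uniform(0.05, 0.95, size=m)
    n = cfg.ne
    haplos = (rng.random((n, 2, m)) < founder_freq).astype(np.uint8)

    all_haplos = [haplos]
    pedigree = [(f"G00_{i:04d}", UNKNOWN_PARENT, UNKNOWN_PARENT, 0) for i in range(n)]
    gen_ids = [p[0] for p in pedigree]

    for gen in range(1, cfg.n_generations + 1):
        prev_ids = gen_ids
        prev_h = all_haplos[-1]
        new_h = np.empty_like(prev_h)
        gen_ids = []
        for i in range(n):
            if cfg.mating == "wright_fisher":
                si = int(rng.integers(0, n))
                di = int(rng.integers(0, n))
            else:
                si = int(rng.integers(0, cfg.n_sires))
                di = int(rng.integers(cfg.n_sires, n))
            new_h[i, 0] = _meiosis(prev_h[si], chrom_slices, marker_cm, cfg.chrom_length_cm, rng)
            new_h[i, 1] = _meiosis(prev_h[di], chrom_slices, marker_cm, cfg.chrom_length_cm, rng)
            child = f"G{gen:02d}_{i:04d}"
            pedigree.append((child, prev_ids[si], prev_ids[di], gen))
            gen_ids.append(child)
        if cfg.mutation_rate > 0:
            flips = rng.random(new_h.shape) < cfg.mutation_rate
            new_h ^= flips.astype(np.uint8)
        all_haplos.append(new_h)

    haplo_stack = np.concatenate(all_haplos, axis=0)  # (total, 2, m)
    calls = haplo_stack.sum(axis=1).astype(np.int8)

    ids = [p[0] for p in pedigree]
    gens = np.array([p[3] for p in pedigree])
    sex = np.full(len(ids), "F", dtype=object)
    if cfg.mating == "two_sex":
        sex[np.array([int(i.split("_")[1]) for i in ids]) < cfg.n_sires] = "M"
    else:
        sex[:] = "U"
    samples = pd.DataFrame(
        {
            "sample_id": ids,
            "sire_id": [p[1] for p in pedigree],
            "dam_id": [p[2] for p in pedigree],
            "birth_year": cfg.base_year + gens,
            "breed": cfg.breed,
            "sex": sex,
        }
    )[SAMPLE_COLUMNS]

    genotypes = GenotypeMatrix(calls=calls, markers=markers, samples=samples)

    # additive true breeding values from QTL inside the marker panel
    qtl_idx = rng.choice(m, size=min(cfg.qtl_count, m), replace=False)
    effects = rng.normal(0.0, 1.0, size=len(qtl_idx))
    tbv_raw = calls[:, qtl_idx].astype(float) @ effects
    sd = tbv_raw.std()
    tbv = (tbv_raw - tbv_raw.mean()) / (sd if sd > 0 else 1.0)
    true_bv = pd.Series(tbv, index=pd.Index(ids, name="sample_id"), name="true_bv")
    qtl_effects = pd.Series(
        effects / (sd if sd > 0 else 1.0),
        index=pd.Index(markers["snp_id"].to_numpy()[qtl_idx], name="snp_id"),
        name="effect",
    )

    rel = rng.uniform(*cfg.ebv_reliability_range, size=len(ids))
    ebv = assign_pseudo_phenotypes(true_bv, cfg.h2, rel, rng, kind="ebv")
    debv_rel = np.clip(rel * cfg.debv_reliability_factor, 1e-3, 1 - 1e-3)
    debv = assign_pseudo_phenotypes(true_bv, cfg.h2, debv_rel, rng, kind="debv")
    trait_records = pd.concat([ebv, debv], ignore_index=True)

    gencall = rng.uniform(0.85, 1.0, size=m)
    gentrain = rng.uniform(0.6, 1.0, size=m)
    if cfg.low_score_marker_fraction > 0:
        n_low = int(round(cfg.low_score_marker_fraction * m))
        low = rng.choice(m, size=n_low, replace=False)
        gencall[low] = rng.uniform(0.3, 0.7, size=n_low)  # <= 0.7: fails ROH QC
    scores = QualityScores(
        table=pd.DataFrame(
            {"snp_id": markers["snp_id"], "gencall": gencall, "gentrain": gentrain}
        )
    )

    return SimOutput(
        genotypes=genotypes,
        true_bv=true_bv,
        trait_records=trait_records,
        quality_scores=scores,
        qtl_effects=qtl_effects,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# pseudo-phenotypes
# ---------------------------------------------------------------------------

def assign_pseudo_phenotypes(
    true_bv: pd.Series,
    h2: float,
    reliability,
    seed: int | np.random.Generator = 0,
    kind: str = "ebv",
    trait: str = "trait",
    mode: str = "independent",
    samples: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pseudo-phenotypes at target reliability.

    ``independent`` (default): EBV = r TBV + sqrt(r (1-r)) sigma z with
    independent standard-normal z, so cor^2(EBV, TBV) -> r.

    ``parent_average``: each animal's pseudo-phenotype blends its own
    (independent-construction) value with the mean of its parents' values
    in proportion to its reliability -- value = rel * own + (1 - rel) * PA.
    Proven animals keep their own information; near-zero-reliability
    animals collapse onto the parent average, emulating how genetic
    evaluations behave for unproven young bulls.  Requires ``samples`` for
    the pedigree; animals with an unrecorded parent keep their own value.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rel = np.broadcast_to(np.asarray(reliability, dtype=float), (len(true_bv),)).copy()
    if ((rel < 0) | (rel > 1)).any():
        raise ValueError("reliabilities must be in [0, 1]")
    sigma = true_bv.std() if true_bv.std() > 0 else 1.0
    z = rng.normal(0.0, 1.0, size=len(true_bv))
    values = rel * true_bv.to_numpy() + np.sqrt(rel * (1.0 - rel)) * sigma * z

    if mode == "parent_average":
        if samples is None:
            raise ValueError("parent_average mode needs the sample/pedigree table")
        ped = samples.set_index("sample_id")
        val = dict(zip(true_bv.index, values))
        rel_by_id = dict(zip(true_bv.index, rel))
        for sid in true_bv.index:  # table is in birth order: parents resolved first
            s, d = ped.loc[sid, "sire_id"], ped.loc[sid, "dam_id"]
            if s in val and d in val:
                w = rel_by_id[sid]
                val[sid] = w * val[sid] + (1.0 - w) * 0.5 * (val[s] + val[d])
        values = np.array([val[sid] for sid in true_bv.index])
    elif mode != "independent":
        raise ValueError(f"unknown mode {mode!r}")

    rel_clipped = np.clip(rel, 1e-3, 1 - 1e-3)  # TraitRecords needs (0, 1)
    return pd.DataFrame(
        {
            "sample_id": true_bv.index,
            "trait": trait,
            "pseudo_phenotype": values,
            "reliability": rel_clipped,
            "kind": kind,
        }
    )
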