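"""Genotype containers and PLINK-dialect I/O.

The central object is :class:`GenotypeMatrix`: an individuals x markers array
of allele-B dosages (0/1/2, ``MISSING`` = -1) tied to a marker map and a
sample/pedigree table.  Markers are kept sorted by (chromosome, position);
only the 29 bovine autosomes are retained.

Supported on-disk dialects:

* text   -- PLINK PED/MAP.  The counted allele (allele_b) is the
  lexicographically smaller of the two observed alleles, so a save/load
  round trip is the identity on calls whenever ``allele_b < allele_a``.
* binary -- PLINK BED/BIM/FAM, SNP-major, bit-exact 2-bit packing.  The
  counted allele is the BIM A1 allele.

Sample metadata beyond the FAM columns (birth year, breed) live in a TSV
sidecar ``<prefix>.samples.tsv``; per-marker array-quality scores (GenCall,
GenTrain) in ``<prefix>.scores.tsv``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = np.int8(-1)
N_AUTOSOMES = 29

MARKER_COLUMNS = ["snp_id", "chromosome", "position_bp", "allele_a", "allele_b"]
SAMPLE_COLUMNS = ["sample_id", "sire_id", "dam_id", "birth_year", "breed", "sex"]
UNKNOWN_PARENT = "0"

# BED 2-bit code -> allele-B (=A1) dosage; code 0b01 is missing.
_BED_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


class GenotypeIOError(Exception):
    """Raised for malformed or inconsistent genotype file sets."""


def _empty_samples(sample_ids) -> pd.DataFrame:
    n = len(sample_ids)
    return pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "sire_id": [UNKNOWN_PARENT] * n,
            "dam_id": [UNKNOWN_PARENT] * n,
            "birth_year": [0] * n,
            "breed": ["NA"] * n,
            "sex": ["U"] * n,
        }
    )


@dataclass
class GenotypeMatrix:
    """Dosage matrix plus marker map and sample table.

    ``calls[i, k]`` counts copies of ``markers.allele_b[k]`` carried by
    ``samples.sample_id[i]`` (0, 1, 2, or ``MISSING``).
    """

    calls: np.ndarray
    markers: pd.DataFrame
    samples: pd.DataFrame
    counted_allele: str = "allele_b"
    roh_qc_applied: bool = field(default=False, compare=False)

    # -- basic structure -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def validate(self) -> None:
        if self.calls.ndim != 2:
            raise GenotypeIOError("calls must be 2-dimensional")
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise GenotypeIOError(
                f"dimension mismatch: calls {self.calls.shape}, "
                f"{len(self.samples)} samples, {len(self.markers)} markers"
            )
        vals = np.unique(self.calls)
        bad = set(vals.tolist()) - {-1, 0, 1, 2}
        if bad:
            raise GenotypeIOError(f"invalid dosage codes: {sorted(bad)}")
        if self.markers["snp_id"].duplicated().any():
            raise GenotypeIOError("duplicate snp_id in marker map")
        if self.samples["sample_id"].duplicated().any():
            raise GenotypeIOError("duplicate sample_id in sample table")
        chrom = self.markers["chromosome"].to_numpy()
        if len(chrom) and ((chrom < 1) | (chrom > N_AUTOSOMES)).any():
            raise GenotypeIOError("marker map contains non-autosomal chromosomes")
        key = self.markers[["chromosome", "position_bp"]].to_numpy()
        if len(key) > 1:
            order = np.lexsort((key[:, 1], key[:, 0]))
            if not np.array_equal(order, np.arange(len(key))):
                raise GenotypeIOError("marker map is not sorted by (chromosome, position)")

    def sort_markers(self) -> "GenotypeMatrix":
        """Return a copy with markers sorted by (chromosome, position_bp)."""
        order = np.lexsort(
            (
                self.markers["position_bp"].to_numpy(),
                self.markers["chromosome"].to_numpy(),
            )
        )
        return self.subset_markers(order)

    def subset_markers(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype != bool:
            index = index.astype(np.intp)
        return replace(
            self,
            calls=self.calls[:, index],
            markers=self.markers.iloc[index].reset_index(drop=True),
            samples=self.samples.copy(),
        )

    def subset_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype != bool:
            index = index.astype(np.intp)
        return replace(
            self,
            calls=self.calls[index, :],
            markers=self.markers.copy(),
            samples=self.samples.iloc[index].reset_index(drop=True),
        )

    # -- per-axis summaries ----------------------------------------------
    def marker_call_rate(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_markers)
        return (self.calls != MISSING).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        if self.n_markers == 0:
            return np.zeros(self.n_samples)
        return (self.calls != MISSING).mean(axis=1)

    def allele_b_frequency(self) -> np.ndarray:
        """Frequency of the counted allele over non-missing calls (NaN if none)."""
        obs = self.calls != MISSING
        n = obs.sum(axis=0)
        dose = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, dose / (2.0 * n), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_b_frequency()
        return np.minimum(p, 1.0 - p)


@dataclass
class QualityScores:
    """Per-marker array-genotyping quality scores, aligned to a marker map."""

    table: pd.DataFrame  # snp_id, gencall, gentrain

    def aligned_to(self, markers: pd.DataFrame) -> pd.DataFrame:
        idx = self.table.set_index("snp_id")
        missing = set(markers["snp_id"]) - set(idx.index)
        if missing:
            raise GenotypeIOError(
                f"quality scores missing for {len(missing)} markers, e.g. {sorted(missing)[:3]}"
            )
        out = idx.loc[markers["snp_id"], ["gencall", "gentrain"]].reset_index()
        return out


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_genotypes(path_prefix: str, fmt: str = "binary", autosomes_only: bool = True) -> GenotypeMatrix:
    """Load a PLINK file set (``text`` = PED/MAP, ``binary`` = BED/BIM/FAM).

    Markers are re-sorted by (chromosome, position); non-autosomal markers
    (chromosome outside 1..29) are dropped when ``autosomes_only``.  Sample
    order is never changed.  A ``<prefix>.samples.tsv`` sidecar, if present,
    supplies birth years and breeds.
    """
    if fmt == "text":
        g = _load_text(path_prefix)
    elif fmt == "binary":
        g = _load_binary(path_prefix)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if autosomes_only:
        chrom = g.markers["chromosome"].to_numpy()
        keep = np.flatnonzero((chrom >= 1) & (chrom <= N_AUTOSOMES))
        g = g.subset_markers(keep)
    g = g.sort_markers()

    sidecar = f"{path_prefix}.samples.tsv"
    if os.path.exists(sidecar):
        table = load_sample_table(sidecar)
        idx = table.set_index("sample_id")
        missing = set(g.samples["sample_id"]) - set(idx.index)
        if missing:
            raise GenotypeIOError(f"sample sidecar missing ids: {sorted(missing)[:3]}")
        g.samples = idx.loc[g.samples["sample_id"]].reset_index()[SAMPLE_COLUMNS]
    g.validate()
    return g


def _require(path: str) -> str:
    if not os.path.exists(path):
        raise GenotypeIOError(f"missing file: {path}")
    return path


def _read_map_like(path: str, n_cols: int) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != n_cols:
                raise GenotypeIOError(f"{path}: expected {n_cols} columns, got {len(parts)}")
            rows.append(parts)
    return pd.DataFrame(rows)


def _parse_chromosome(raw: pd.Series) -> np.ndarray:
    def one(v: str) -> int:
        try:
            return int(v)
        except ValueError:
            return -1  # X/Y/MT and unplaced markers: flagged non-autosomal

    return raw.map(one).to_numpy(dtype=np.int64)


def _load_text(prefix: str) -> GenotypeMatrix:
    map_path = _require(prefix + ".map")
    ped_path = _require(prefix + ".ped")

    raw_map = _read_map_like(map_path, 4)
    markers = pd.DataFrame(
        {
            "snp_id": raw_map[1],
            "chromosome": _parse_chromosome(raw_map[0]),
            "position_bp": raw_map[3].astype(np.int64),
            "allele_a": "0",
            "allele_b": "0",
        }
    )
    m = len(markers)

    sample_rows, allele_rows = [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise GenotypeIOError(
                    f"{ped_path}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            sample_rows.append(parts[:6])
            allele_rows.append(parts[6:])
    if not sample_rows:
        raise GenotypeIOError(f"{ped_path}: no samples")

    alleles = np.array(allele_rows, dtype="U4").reshape(len(sample_rows), m, 2)
    calls = np.full((len(sample_rows), m), MISSING, dtype=np.int8)
    allele_a = np.full(m, "0", dtype="U4")
    allele_b = np.full(m, "0", dtype="U4")
    for k in range(m):
        col = alleles[:, k, :]
        observed = col[col != "0"]
        uniq = sorted(set(observed.tolist()))
        if len(uniq) > 2:
            raise GenotypeIOError(
                f"marker {markers['snp_id'][k]} is not biallelic: alleles {uniq}"
            )
        if not uniq:
            continue  # fully missing marker: coding undefined
        b = uniq[0]  # lexicographically smaller allele is counted
        a = uniq[1] if len(uniq) == 2 else "0"
        allele_b[k], allele_a[k] = b, a
        called = (col[:, 0] != "0") & (col[:, 1] != "0")
        calls[called, k] = (col[called] == b).sum(axis=1).astype(np.int8)

    markers["allele_a"] = allele_a
    markers["allele_b"] = allele_b

    fam = pd.DataFrame(sample_rows, columns=["fid", "sample_id", "sire_id", "dam_id", "sex", "pheno"])
    samples = _samples_from_fam(fam)
    return GenotypeMatrix(calls=calls, markers=markers, samples=samples)


def _samples_from_fam(fam: pd.DataFrame) -> pd.DataFrame:
    sex = fam["sex"].map({"1": "M", "2": "F"}).fillna("U")
    out = _empty_samples(fam["sample_id"])
    out["sire_id"] = fam["sire_id"].to_numpy()
    out["dam_id"] = fam["dam_id"].to_numpy()
    out["sex"] = sex.to_numpy()
    out["breed"] = fam["fid"].to_numpy()
    return out


def _load_binary(prefix: str) -> GenotypeMatrix:
    bed_path = _require(prefix + ".bed")
    bim_path = _require(prefix + ".bim")
    fam_path = _require(prefix + ".fam")

    raw_bim = _read_map_like(bim_path, 6)
    markers = pd.DataFrame(
        {
            "snp_id": raw_bim[1],
            "chromosome": _parse_chromosome(raw_bim[0]),
            "position_bp": raw_bim[3].astype(np.int64),
            "allele_a": raw_bim[5],  # A2
            "allele_b": raw_bim[4],  # A1: the counted allele
        }
    )
    raw_fam = _read_map_like(fam_path, 6)
    raw_fam.columns = ["fid", "sample_id", "sire_id", "dam_id", "sex", "pheno"]
    samples = _samples_from_fam(raw_fam)

    n, m = len(samples), len(markers)
    with open(bed_path, "rb") as fh:
        payload = fh.read()
    if payload[:3] != _BED_MAGIC:
        raise GenotypeIOError(f"{bed_path}: bad magic bytes (not SNP-major BED)")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(payload, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise GenotypeIOError(
            f"{bed_path}: payload is {body.size} bytes, expected {bytes_per_snp * m}"
        )
    blocks = body.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, sample s in bits (2*(s%4), 2*(s%4)+1) of byte s//4
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0x3
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    calls = _BED_CODE_TO_DOSAGE[codes].T.copy()  # (n, m)
    return GenotypeMatrix(calls=calls, markers=markers, samples=samples)


# ---------------------------------------------------------------------------
# saving
# ---------------------------------------------------------------------------

def save_genotypes(g: GenotypeMatrix, path_prefix: str, fmt: str = "binary") -> list[str]:
    """Write ``g`` as a PLINK file set plus the sample-table sidecar.

    Returns the list of paths written.
    """
    g.validate()
    if g.n_markers == 0:
        raise GenotypeIOError("refusing to write an empty marker set")
    if fmt == "text":
        paths = _save_text(g, path_prefix)
    elif fmt == "binary":
        paths = _save_binary(g, path_prefix)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    sidecar = f"{path_prefix}.samples.tsv"
    save_sample_table(g.samples, sidecar)
    return paths + [sidecar]


def _fam_rows(samples: pd.DataFrame):
    sex_code = samples["sex"].map({"M": "1", "F": "2"}).fillna("0")
    for i in range(len(samples)):
        row = samples.iloc[i]
        yield [str(row["breed"]), str(row["sample_id"]), str(row["sire_id"]),
               str(row["dam_id"]), sex_code.iloc[i], "-9"]


def _save_text(g: GenotypeMatrix, prefix: str) -> list[str]:
    map_path, ped_path = prefix + ".map", prefix + ".ped"
    with open(map_path, "w") as fh:
        for _, r in g.markers.iterrows():
            fh.write(f"{r['chromosome']}\t{r['snp_id']}\t0\t{r['position_bp']}\n")
    allele_a = g.markers["allele_a"].to_numpy()
    allele_b = g.markers["allele_b"].to_numpy()
    if ((allele_a == "0") & (g.calls < 2).any(axis=0) & (g.calls >= 0).any(axis=0)).any():
        raise GenotypeIOError("cannot write text genotypes: allele_a unknown for a polymorphic marker")
    with open(ped_path, "w") as fh:
        for i, fam in enumerate(_fam_rows(g.samples)):
            fields = list(fam)
            row = g.calls[i]
            for k in range(g.n_markers):
                d = row[k]
                if d == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [allele_b[k]] * int(d) + [allele_a[k]] * int(2 - d)
            fh.write(" ".join(fields) + "\n")
    return [ped_path, map_path]


def _save_binary(g: GenotypeMatrix, prefix: str) -> list[str]:
    bed_path, bim_path, fam_path = prefix + ".bed", prefix + ".bim", prefix + ".fam"
    with open(bim_path, "w") as fh:
        for _, r in g.markers.iterrows():
            fh.write(
                f"{r['chromosome']}\t{r['snp_id']}\t0\t{r['position_bp']}"
                f"\t{r['allele_b']}\t{r['allele_a']}\n"
            )
    with open(fam_path, "w") as fh:
        for fam in _fam_rows(g.samples):
            fh.write(" ".join(fam) + "\n")

    n, m = g.n_samples, g.n_markers
    dosage_to_code = np.zeros(4, dtype=np.uint8)
    dosage_to_code[[2, 1, 0]] = [0b00, 0b10, 0b11]
    codes = np.where(g.calls == MISSING, 0b01, dosage_to_code[np.clip(g.calls, 0, 2)])
    bytes_per_snp = (n + 3) // 4
    padded = np.full((m, bytes_per_snp * 4), 0b01, dtype=np.uint8)  # pad bits read as missing
    padded[:, :n] = codes.T
    padded[:, n:] = 0  # PLINK zero-pads trailing bits
    quads = padded.reshape(m, bytes_per_snp, 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (quads << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    return [bed_path, bim_path, fam_path]


# ---------------------------------------------------------------------------
# sidecar tables
# ---------------------------------------------------------------------------

def save_sample_table(samples: pd.DataFrame, path: str) -> None:
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def load_sample_table(path: str) -> pd.DataFrame:
    table = pd.read_csv(
        path, sep="\t",
        dtype={"sample_id": str, "sire_id": str, "dam_id": str, "breed": str, "sex": str},
    )
    missing = set(SAMPLE_COLUMNS) - set(table.columns)
    if missing:
        raise GenotypeIOError(f"{path}: missing columns {sorted(missing)}")
    table["birth_year"] = table["birth_year"].astype(int)
    return table[SAMPLE_COLUMNS]


def save_quality_scores(scores: QualityScores, path: str) -> None:
    scores.table[["snp_id", "gencall", "gentrain"]].to_csv(path, sep="\t", index=False)


def load_quality_scores(path: str) -> QualityScores:
    table = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    missing = {"snp_id", "gencall", "gentrain"} - set(table.columns)
    if missing:
        raise GenotypeIOError(f"{path}: missing columns {sorted(missing)}")
    return QualityScores(table=table)
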