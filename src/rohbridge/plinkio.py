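"""SNP-array genotype I/O (PLINK text and binary dialects) and quality control.

Genotypes are held as an individuals x SNPs int8 matrix coding the count of
each SNP's first-listed allele (A1): 0, 1, 2, with -1 for a missing call.
The map carries chromosome label, SNP id, genetic position and physical
position (1-based base pairs).  Chromosome bookkeeping is species-aware:
goats have 29 autosomes (ARS1 assembly), sheep 26 (OAR4); the X chromosome
and unplaced markers are recognised either by label ("X", "0") or by the
numeric code one past the last autosome, as SNP-chip files commonly encode
them.

QC implements the standard marker/sample filters for medium-density chips:
drop unplaced and X-linked markers, drop SNPs with missing-call fraction
>= 5%, drop individuals with call rate < 95%.  A separate MAF < 0.05 filter
exists for GRM construction only — ROH calling deliberately keeps rare
alleles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SnpMap",
    "GenotypeDataset",
    "QCReport",
    "PlinkFormatError",
    "AUTOSOME_COUNTS",
    "read_plink_text",
    "write_plink_text",
    "read_plink_binary",
    "write_plink_binary",
    "qc_filter",
    "allele_freq",
    "maf_filter",
]

MISSING = np.int8(-1)

#: autosome counts per species (goat: ARS1, sheep: OAR4)
AUTOSOME_COUNTS = {"goat": 29, "sheep": 26}

_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = b"\x01"


class PlinkFormatError(ValueError):
    """Malformed PLINK file (ragged rows, bad magic bytes, truncation...)."""


def _snpmap_frame(df: pd.DataFrame) -> pd.DataFrame:
    need = ["chrom", "snp_id", "cm", "pos", "a1", "a2"]
    for c in need:
        if c not in df.columns:
            raise PlinkFormatError(f"SNP map is missing column {c!r}")
    out = df[need].copy()
    out["chrom"] = out["chrom"].astype(str)
    out["cm"] = out["cm"].astype(float)
    out["pos"] = out["pos"].astype(np.int64)
    return out.reset_index(drop=True)


@dataclass
class SnpMap:
    """Physical map of the SNP panel: one row per marker.

    Columns: chrom (string label), snp_id, cm, pos (1-based bp), a1, a2.
    A1 is the counted allele.
    """

    table: pd.DataFrame

    def __post_init__(self):
        self.table = _snpmap_frame(self.table)

    def __len__(self):
        return len(self.table)

    def is_autosomal(self, n_autosomes: int) -> np.ndarray:
        """Boolean mask of placed autosomal markers.

        Unplaced: chromosome label "0"/"" or non-positive position.
        X: label "X"/"x"/"23"-style code ``n_autosomes + 1`` or beyond.
        """
        lab = self.table["chrom"].str.strip()
        pos = self.table["pos"].to_numpy()
        unplaced = lab.isin(["0", ""]) | (pos <= 0)
        numeric = pd.to_numeric(lab, errors="coerce")
        sex_or_other = lab.str.upper().isin(["X", "Y", "XY", "MT", "M"]) | (
            numeric > n_autosomes
        )
        return (~unplaced & ~sex_or_other).to_numpy()


@dataclass
class GenotypeDataset:
    """Individuals x SNPs genotype calls with sample and map metadata.

    ``geno`` codes each call as the count of the SNP's A1 allele
    (0/1/2) with -1 for missing.  ``samples`` has columns fid, iid and
    optionally breed/species/sex.
    """

    samples: pd.DataFrame
    snps: SnpMap
    geno: np.ndarray
    species: str = "sheep"

    def __post_init__(self):
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"genotype matrix {self.geno.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.geno, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype codes outside {0,1,2,missing}")
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.geno.shape[0]

    @property
    def n_snps(self) -> int:
        return self.geno.shape[1]

    @property
    def n_autosomes(self) -> int:
        return AUTOSOME_COUNTS.get(self.species, 29)

    def subset(self, ind_mask=None, snp_mask=None) -> "GenotypeDataset":
        ind_mask = np.ones(self.n_individuals, bool) if ind_mask is None else ind_mask
        snp_mask = np.ones(self.n_snps, bool) if snp_mask is None else snp_mask
        return GenotypeDataset(
            samples=self.samples.loc[ind_mask].reset_index(drop=True),
            snps=SnpMap(self.snps.table.loc[snp_mask]),
            geno=self.geno[np.ix_(ind_mask, snp_mask)],
            species=self.species,
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            np.array_equal(self.geno, other.geno)
            and self.snps.table.equals(other.snps.table)
            and list(self.samples["iid"]) == list(other.samples["iid"])
        )


# ---------------------------------------------------------------------------
# text dialect (PED/MAP)

def read_plink_text(ped_path, map_path, species: str = "sheep") -> GenotypeDataset:
    """Read a PED/MAP pair.

    Each PED row is FID IID SIRE DAM SEX PHENO followed by two allele
    columns per SNP; "0 0" is a missing call.  Genotypes are coded as the
    count of the first-listed (A1) allele of each SNP; for a SNP first seen
    only through missing calls the allele codes fall back to the map file
    when present, else "A"/"B" placeholders.
    """
    map_rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (4, 6):
                raise PlinkFormatError(f"{map_path}:{ln}: expected 4 or 6 columns")
            try:
                pos = int(parts[3])
                cm = float(parts[2])
            except ValueError as e:
                raise PlinkFormatError(f"{map_path}:{ln}: non-numeric position") from e
            a1, a2 = (parts[4], parts[5]) if len(parts) == 6 else (None, None)
            map_rows.append((parts[0], parts[1], cm, pos, a1, a2))
    m = len(map_rows)

    sample_rows, geno_rows = [], []
    allele1 = [r[4] for r in map_rows]
    allele2 = [r[5] for r in map_rows]
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise PlinkFormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            fid, iid, sire, dam, sex, pheno = parts[:6]
            sample_rows.append({"fid": fid, "iid": iid, "sire": sire,
                                "dam": dam, "sex": sex, "pheno": pheno})
            row = np.empty(m, dtype=np.int8)
            for j in range(m):
                b1, b2 = parts[6 + 2 * j], parts[7 + 2 * j]
                if b1 == "0" or b2 == "0":
                    row[j] = MISSING
                    continue
                for b in (b1, b2):
                    if allele1[j] is None:
                        allele1[j] = b
                    elif allele2[j] is None and b != allele1[j]:
                        allele2[j] = b
                    elif b not in (allele1[j], allele2[j]):
                        raise PlinkFormatError(
                            f"{ped_path}:{ln}: SNP {j} has >2 alleles"
                        )
                row[j] = (b1 == allele1[j]) + (b2 == allele1[j])
            geno_rows.append(row)

    snp_df = pd.DataFrame(
        {
            "chrom": [r[0] for r in map_rows],
            "snp_id": [r[1] for r in map_rows],
            "cm": [r[2] for r in map_rows],
            "pos": [r[3] for r in map_rows],
            "a1": [a if a is not None else "A" for a in allele1],
            "a2": [a if a is not None else "B" for a in allele2],
        }
    )
    geno = (np.vstack(geno_rows) if geno_rows
            else np.empty((0, m), dtype=np.int8))
    return GenotypeDataset(
        samples=pd.DataFrame(sample_rows, columns=["fid", "iid", "sire", "dam", "sex", "pheno"]),
        snps=SnpMap(snp_df), geno=geno, species=species,
    )


def write_plink_text(ds: GenotypeDataset, ped_path, map_path) -> None:
    t = ds.snps.table
    with open(map_path, "w") as fh:
        for r in t.itertuples():
            fh.write(f"{r.chrom}\t{r.snp_id}\t{r.cm:.17g}\t{r.pos}\t{r.a1}\t{r.a2}\n")
    a1 = t["a1"].to_numpy()
    a2 = t["a2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i in range(ds.n_individuals):
            s = ds.samples.iloc[i]
            lead = [str(s.get("fid", "0")), str(s["iid"]), str(s.get("sire", "0")),
                    str(s.get("dam", "0")), str(s.get("sex", "0")), str(s.get("pheno", "-9"))]
            alleles = []
            for j, g in enumerate(ds.geno[i]):
                if g == MISSING:
                    alleles += ["0", "0"]
                elif g == 2:
                    alleles += [a1[j], a1[j]]
                elif g == 1:
                    alleles += [a1[j], a2[j]]
                else:
                    alleles += [a2[j], a2[j]]
            fh.write(" ".join(lead + alleles) + "\n")


# ---------------------------------------------------------------------------
# binary dialect (BED/BIM/FAM, SNP-major v1.x)

# 2-bit codes in a v1.x BED byte (per pair of bits, LSB first):
# 00 = hom A1 (count 2), 01 = missing, 10 = het, 11 = hom A2 (count 0)
_BED_DECODE = np.array([2, -1, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}


def read_plink_binary(bed_path, bim_path, fam_path, species: str = "sheep") -> GenotypeDataset:
    """Read a BED/BIM/FAM trio (SNP-major, v1.x magic bytes)."""
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "sire", "dam", "sex", "pheno"], dtype=str,
    )
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
        float_precision="round_trip",
    )
    n, m = len(fam), len(bim)
    with open(bed_path, "rb") as fh:
        header = fh.read(3)
        if len(header) < 3 or header[:2] != _BED_MAGIC:
            raise PlinkFormatError(
                f"{bed_path}: not a PLINK v1.x BED file (bad magic bytes)"
            )
        if header[2:3] != _BED_SNP_MAJOR:
            raise PlinkFormatError(f"{bed_path}: not SNP-major BED")
        body = fh.read()
    bpr = (n + 3) // 4  # bytes per SNP record
    if len(body) < bpr * m:
        raise PlinkFormatError(
            f"{bed_path}: truncated ({len(body)} bytes, need {bpr * m})"
        )
    raw = np.frombuffer(body[: bpr * m], dtype=np.uint8).reshape(m, bpr)
    # unpack 2-bit fields, sample-fastest within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (raw[:, :, None] >> shifts) & 0b11  # m x bpr x 4
    codes = codes.reshape(m, bpr * 4)[:, :n]
    geno = _BED_DECODE[codes].T.copy()  # n x m
    return GenotypeDataset(samples=fam, snps=SnpMap(bim), geno=geno, species=species)


def write_plink_binary(ds: GenotypeDataset, bed_path, bim_path, fam_path) -> None:
    t = ds.snps.table
    with open(bim_path, "w") as fh:
        for r in t.itertuples():
            fh.write(f"{r.chrom}\t{r.snp_id}\t{r.cm:.17g}\t{r.pos}\t{r.a1}\t{r.a2}\n")
    with open(fam_path, "w") as fh:
        for i in range(ds.n_individuals):
            s = ds.samples.iloc[i]
            fh.write(
                f"{s.get('fid', '0')} {s['iid']} {s.get('sire', '0')} "
                f"{s.get('dam', '0')} {s.get('sex', '0')} {s.get('pheno', '-9')}\n"
            )
    n = ds.n_individuals
    bpr = (n + 3) // 4
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + _BED_SNP_MAJOR)
        enc = np.array([_BED_ENCODE[g] for g in (-1, 0, 1, 2)], dtype=np.uint8)
        codes = enc[ds.geno + 1]  # n x m of 2-bit codes
        padded = np.zeros((bpr * 4, ds.n_snps), dtype=np.uint8)
        padded[:n] = codes
        padded = padded.T.reshape(ds.n_snps, bpr, 4)
        shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
        packed = (padded << shifts).sum(axis=2).astype(np.uint8)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# quality control

@dataclass
class QCReport:
    """Bookkeeping of what each filter removed; in - removed = out per axis."""

    n_snps_in: int
    n_ind_in: int
    n_removed_unplaced: int = 0
    n_removed_x: int = 0
    n_removed_snp_missing: int = 0
    n_removed_ind_callrate: int = 0

    @property
    def n_snps_out(self) -> int:
        return (self.n_snps_in - self.n_removed_unplaced - self.n_removed_x
                - self.n_removed_snp_missing)

    @property
    def n_ind_out(self) -> int:
        return self.n_ind_in - self.n_removed_ind_callrate

    def to_dict(self) -> dict:
        return {
            "n_snps_in": self.n_snps_in,
            "n_ind_in": self.n_ind_in,
            "n_removed_unplaced": self.n_removed_unplaced,
            "n_removed_x": self.n_removed_x,
            "n_removed_snp_missing": self.n_removed_snp_missing,
            "n_removed_ind_callrate": self.n_removed_ind_callrate,
            "n_snps_out": self.n_snps_out,
            "n_ind_out": self.n_ind_out,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def __str__(self) -> str:
        d = self.to_dict()
        lines = [f"QC: {d['n_snps_in']} SNPs x {d['n_ind_in']} individuals in"]
        lines.append(f"  removed unplaced markers : {d['n_removed_unplaced']}")
        lines.append(f"  removed X-linked markers : {d['n_removed_x']}")
        lines.append(f"  removed SNPs missing>=thr: {d['n_removed_snp_missing']}")
        lines.append(f"  removed low-call-rate ind: {d['n_removed_ind_callrate']}")
        lines.append(f"  retained {d['n_snps_out']} SNPs x {d['n_ind_out']} individuals")
        return "\n".join(lines)


def qc_filter(
    ds: GenotypeDataset,
    snp_missing_max: float = 0.05,
    ind_callrate_min: float = 0.95,
    drop_nonautosomal: bool = True,
    callrate_after_snp_filter: bool = True,
) -> tuple[GenotypeDataset, QCReport]:
    """Marker- and sample-level quality control.

    Order: marker placement (unplaced, X) -> SNP missingness (fraction
    missing >= ``snp_missing_max`` removed) -> individual call rate
    (< ``ind_callrate_min`` removed, computed over the retained SNPs by
    default; set ``callrate_after_snp_filter=False`` to use all placed
    markers).
    """
    report = QCReport(n_snps_in=ds.n_snps, n_ind_in=ds.n_individuals)

    snp_keep = np.ones(ds.n_snps, dtype=bool)
    if drop_nonautosomal:
        auto = ds.snps.is_autosomal(ds.n_autosomes)
        lab = ds.snps.table["chrom"].str.strip()
        pos = ds.snps.table["pos"].to_numpy()
        unplaced = (lab.isin(["0", ""]) | (pos <= 0)).to_numpy()
        report.n_removed_unplaced = int(unplaced.sum())
        report.n_removed_x = int((~auto & ~unplaced).sum())
        snp_keep = auto

    miss = ds.geno == MISSING
    if ds.n_individuals:
        miss_frac = miss.mean(axis=0)
        fail_missing = (miss_frac >= snp_missing_max) & snp_keep
        report.n_removed_snp_missing = int(fail_missing.sum())
        snp_keep &= ~fail_missing

    ind_keep = np.ones(ds.n_individuals, dtype=bool)
    denom_snps = snp_keep if callrate_after_snp_filter else np.ones(ds.n_snps, bool)
    if denom_snps.sum() > 0:
        callrate = 1.0 - miss[:, denom_snps].mean(axis=1)
        ind_keep = callrate >= ind_callrate_min
        report.n_removed_ind_callrate = int((~ind_keep).sum())

    out = ds.subset(ind_keep, snp_keep)
    if out.n_snps == 0 or out.n_individuals == 0:
        import warnings

        warnings.warn("QC removed every SNP or every individual", stacklevel=2)
    return out, report


def allele_freq(ds: GenotypeDataset) -> np.ndarray:
    """Per-SNP frequency of the counted (A1) allele.

    freq = mean(non-missing codes) / 2; NaN where every call is missing.
    """
    g = ds.geno.astype(float)
    g[ds.geno == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        return np.nanmean(g, axis=0) / 2.0


def maf_filter(ds: GenotypeDataset, maf_min: float = 0.05) -> GenotypeDataset:
    """Drop SNPs with minor allele frequency strictly below ``maf_min``.

    Applied before GRM construction only; ROH calling keeps all markers so
    long homozygous stretches are not fragmented by removing rare alleles.
    Monomorphic and all-missing SNPs are removed.
    """
    p = allele_freq(ds)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    keep = np.where(np.isnan(maf), False, maf >= maf_min)
    return ds.subset(snp_mask=keep)
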