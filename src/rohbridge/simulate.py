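"""Gene-dropping simulation: pedigrees, genotypes and true autozygosity.

Founder chromosomes carry unique labels; each meiosis draws a Poisson
number of crossovers (no interference, 1 cM/Mb by default) with uniform
breakpoints, so descendants inherit recombinant mosaics of founder
haplotypes.  Identity by descent is defined at the founder-haplotype
level: an individual is autozygous wherever its two homologs carry the
same founder label, and F_true is the autozygous fraction of the map
length.  This makes F_true the realized autozygosity that F_ROH estimates
and whose pedigree expectation is F_PED.

Genotypes are read off the mosaics using founder haplotype alleles drawn
from a configurable founder allele-frequency distribution (uniform on
[0.05, 0.5] by default, so a MAF filter at 0.05 is mostly inert on
truth-checking runs).  Utilities mask parent records (emulating incomplete
herd books) and inject missing genotype calls (emulating chip no-calls),
so every pipeline stage is testable without external data.

The generated herds emulate the structure of medium-density SNP-array
livestock data: a few dozen sires serving many dams per generation, with
an optional sire-overuse weighting that concentrates matings on few males,
the way artificial insemination does, and thereby elevates inbreeding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import AnimalRecord, Pedigree
from .plinkio import GenotypeDataset, SnpMap

__all__ = [
    "SimConfig",
    "TruthTrack",
    "simulate_pedigree",
    "make_snp_map",
    "gene_drop",
    "mask_pedigree",
    "inject_missing",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the synthetic herd.

    Defaults approximate a single medium-sized livestock breed genotyped on
    a ~50k chip: 10 chromosomes of 100 Mb at 2,000 SNPs each (20k autosomal
    SNPs), 5 discrete generations after the founders, a handful of sires
    serving many dams.  ``sire_overuse`` >= 1 weights sire usage
    geometrically (1 = uniform random mating; larger values concentrate
    matings on the first sires, as heavy artificial insemination does).
    """

    n_founders: int = 40
    generations: int = 5
    sires_per_generation: int = 5
    dams_per_generation: int = 20
    offspring_per_mating: int = 2
    mating_scheme: str = "random"  # {random, sire-overuse}
    sire_overuse: float = 1.0
    n_chromosomes: int = 10
    chromosome_length_mb: float = 100.0
    snps_per_chromosome: int = 2000
    founder_freq_range: tuple[float, float] = (0.05, 0.5)
    cm_per_mb: float = 1.0
    missing_rate: float = 0.0
    mask_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_founders", "generations", "sires_per_generation",
                     "dams_per_generation", "offspring_per_mating",
                     "n_chromosomes", "snps_per_chromosome"):
            if getattr(self, name) < 0 or (name != "generations" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        for name in ("missing_rate", "mask_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.sire_overuse < 1.0:
            raise ValueError("sire_overuse must be >= 1")


@dataclass
class TruthTrack:
    """Realized autozygosity per simulated individual.

    ``table`` has one row per individual (iid, f_true); ``segments`` lists
    the autozygous (IBD) intervals per chromosome.  Founders have
    f_true = 0 by construction.
    """

    table: pd.DataFrame
    segments: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["iid", "chrom", "start_bp", "end_bp"]))

    def f_true(self, iid: str) -> float:
        row = self.table.loc[self.table["iid"] == iid, "f_true"]
        return float(row.iloc[0])


def simulate_pedigree(cfg: SimConfig, seed: int | None = None) -> Pedigree:
    """Generation-structured random-mating pedigree with optional sire overuse."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    records: dict[str, AnimalRecord] = {}
    males: list[str] = []
    females: list[str] = []
    for i in range(cfg.n_founders):
        sex = "male" if i % 2 == 0 else "female"
        aid = f"F{i:04d}"
        records[aid] = AnimalRecord(id=aid, sex=sex, breed="SIM")
        (males if sex == "male" else females).append(aid)

    for g in range(1, cfg.generations + 1):
        if not males or not females:
            break
        n_sires = min(cfg.sires_per_generation, len(males))
        n_dams = min(cfg.dams_per_generation, len(females))
        sires = list(rng.choice(males, size=n_sires, replace=False))
        dams = list(rng.choice(females, size=n_dams, replace=False))
        if cfg.mating_scheme == "sire-overuse" and n_sires > 1:
            w = cfg.sire_overuse ** -np.arange(n_sires)
            w = w / w.sum()
        else:
            w = np.full(n_sires, 1.0 / n_sires)
        new_males, new_females = [], []
        k = 0
        for dam in dams:
            sire = sires[int(rng.choice(n_sires, p=w))]
            for _ in range(cfg.offspring_per_mating):
                aid = f"G{g:02d}I{k:05d}"
                k += 1
                sex = "male" if rng.random() < 0.5 else "female"
                records[aid] = AnimalRecord(id=aid, sire=sire, dam=dam,
                                            sex=sex, breed="SIM")
                (new_males if sex == "male" else new_females).append(aid)
        males, females = new_males, new_females
    return Pedigree(records=records)


def make_snp_map(cfg: SimConfig, seed: int | None = None) -> SnpMap:
    """Jittered-grid SNP positions: near-even density like a commercial chip."""
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 101)
    l_bp = int(cfg.chromosome_length_mb * 1e6)
    n = cfg.snps_per_chromosome
    rows = []
    for c in range(1, cfg.n_chromosomes + 1):
        spacing = l_bp / (n + 1)
        grid = spacing * np.arange(1, n + 1)
        jitter = rng.uniform(-0.4, 0.4, size=n) * spacing
        pos = np.clip(np.round(grid + jitter), 1, l_bp).astype(np.int64)
        pos = np.sort(pos)
        pos += np.concatenate(([0], np.cumsum(np.diff(pos) == 0)))  # dedupe
        for j, p in enumerate(pos):
            rows.append((str(c), f"snp{c}_{j}", p / 1e6 * cfg.cm_per_mb,
                         int(p), "A", "B"))
    return SnpMap(pd.DataFrame(rows, columns=["chrom", "snp_id", "cm",
                                              "pos", "a1", "a2"]))


# a gamete chromosome is (ends, labels): interval j spans
# [ends[j-1], ends[j]) in bp (ends[-1] == chromosome length)

def _meiosis(hap0, hap1, l_bp: int, l_morgan: float, rng) -> tuple[np.ndarray, np.ndarray]:
    n_cross = rng.poisson(l_morgan)
    breaks = np.sort(rng.uniform(0, l_bp, size=n_cross)) if n_cross else np.empty(0)
    cur = int(rng.integers(2))
    seg_ends, seg_labels = [], []
    start = 0.0
    sources = (hap0, hap1)
    for b in list(breaks) + [float(l_bp)]:
        if b > start:
            ends, labels = sources[cur]
            i0 = int(np.searchsorted(ends, start, side="right"))
            i1 = int(np.searchsorted(ends, b, side="left"))
            for i in range(i0, i1 + 1):
                e = min(float(ends[i]), b)
                if e > start:
                    if seg_labels and seg_labels[-1] == labels[i]:
                        seg_ends[-1] = e
                    else:
                        seg_ends.append(e)
                        seg_labels.append(labels[i])
                    start = e
        cur = 1 - cur
        start = b
    return np.asarray(seg_ends), np.asarray(seg_labels, dtype=np.int64)


def _ibd_intervals(hapA, hapB) -> list[tuple[float, float]]:
    """Intervals where the two homologs carry the same founder label."""
    endsA, labA = hapA
    endsB, labB = hapB
    out = []
    ia = ib = 0
    start = 0.0
    while ia < len(endsA) and ib < len(endsB):
        e = min(endsA[ia], endsB[ib])
        if labA[ia] == labB[ib] and e > start:
            if out and out[-1][1] == start:
                out[-1] = (out[-1][0], e)
            else:
                out.append((start, e))
        start = e
        if endsA[ia] <= e:
            ia += 1
        if endsB[ib] <= e:
            ib += 1
    return out


def _labels_at(hap, positions: np.ndarray) -> np.ndarray:
    ends, labels = hap
    return labels[np.searchsorted(ends, positions, side="right").clip(max=len(labels) - 1)]


def gene_drop(
    p: Pedigree,
    snp_map: SnpMap,
    founder_freqs: np.ndarray,
    seed: int = 0,
    cm_per_mb: float = 1.0,
    samples_meta: pd.DataFrame | None = None,
) -> tuple[GenotypeDataset, TruthTrack]:
    """Drop labeled founder genomes down the pedigree.

    Returns the genotype dataset for every animal in the pedigree (coded as
    counts of allele A) and the :class:`TruthTrack` of realized
    autozygosity.  ``founder_freqs`` gives the per-SNP frequency of allele
    A among founder haplotypes.
    """
    rng = np.random.default_rng(seed)
    t = snp_map.table
    chroms = list(dict.fromkeys(t["chrom"]))
    chrom_pos = {c: t.loc[t["chrom"] == c, "pos"].to_numpy(dtype=float) for c in chroms}
    chrom_cols = {c: np.flatnonzero((t["chrom"] == c).to_numpy()) for c in chroms}
    chrom_len = {c: float(chrom_pos[c].max()) + 1.0 for c in chroms}
    total_len = sum(chrom_len.values())
    founder_freqs = np.asarray(founder_freqs, dtype=float)
    if len(founder_freqs) != len(t):
        raise ValueError("founder_freqs length must match the SNP map")

    founders = [a for a in p.order if p.sire_idx[p.index[a]] < 0
                and p.dam_idx[p.index[a]] < 0]
    n_hap = 2 * len(founders)
    # founder haplotype alleles: 1 = counted allele A
    hap_alleles = (rng.random((n_hap, len(t))) < founder_freqs).astype(np.int8)
    label_of = {a: (2 * i, 2 * i + 1) for i, a in enumerate(founders)}

    genomes: dict[str, dict[str, tuple]] = {}  # iid -> chrom -> (hapA, hapB)
    geno = np.empty((len(p.order), len(t)), dtype=np.int8)
    truth_rows, ibd_rows = [], []
    for idx, a in enumerate(p.order):
        si, di = p.sire_idx[p.index[a]], p.dam_idx[p.index[a]]
        haps = {}
        if a in label_of:
            l0, l1 = label_of[a]
            for c in chroms:
                l_bp = chrom_len[c]
                haps[c] = (
                    (np.array([l_bp]), np.array([l0], dtype=np.int64)),
                    (np.array([l_bp]), np.array([l1], dtype=np.int64)),
                )
        else:
            sire_g = genomes[p.order[si]] if si >= 0 else None
            dam_g = genomes[p.order[di]] if di >= 0 else None
            if sire_g is None or dam_g is None:
                raise ValueError(
                    f"gene_drop needs a fully linked pedigree; {a!r} has an "
                    "unknown parent but is not a founder"
                )
            for c in chroms:
                l_bp = chrom_len[c]
                l_m = l_bp / 1e6 * cm_per_mb / 100.0
                pat = _meiosis(*sire_g[c], l_bp, l_m, rng)
                mat = _meiosis(*dam_g[c], l_bp, l_m, rng)
                haps[c] = (pat, mat)
        genomes[a] = haps

        ibd_total = 0.0
        for c in chroms:
            hA, hB = haps[c]
            pos = chrom_pos[c]
            lab1 = _labels_at(hA, pos)
            lab2 = _labels_at(hB, pos)
            cols = chrom_cols[c]
            geno[idx, cols] = hap_alleles[lab1, cols] + hap_alleles[lab2, cols]
            for s, e in _ibd_intervals(hA, hB):
                ibd_total += e - s
                ibd_rows.append((a, c, s, e))
        truth_rows.append((a, ibd_total / total_len))

    samples = pd.DataFrame({
        "fid": ["0"] * len(p.order),
        "iid": list(p.order),
        "sire": [p.records[a].sire or "0" for a in p.order],
        "dam": [p.records[a].dam or "0" for a in p.order],
        "sex": [{"male": "1", "female": "2"}.get(p.records[a].sex, "0")
                for a in p.order],
        "pheno": ["-9"] * len(p.order),
        "breed": [p.records[a].breed for a in p.order],
    })
    if samples_meta is not None:
        samples = samples.merge(samples_meta, on="iid", how="left")
    ds = GenotypeDataset(samples=samples, snps=snp_map, geno=geno)
    truth = TruthTrack(
        table=pd.DataFrame(truth_rows, columns=["iid", "f_true"]),
        segments=pd.DataFrame(ibd_rows, columns=["iid", "chrom",
                                                 "start_bp", "end_bp"]),
    )
    return ds, truth


def mask_pedigree(p: Pedigree, mask_prob: float, seed: int = 0) -> Pedigree:
    """Independently erase each parent link with probability ``mask_prob``."""
    rng = np.random.default_rng(seed)
    records = {}
    for a in p.order:
        r = p.records[a]
        sire = r.sire if (r.sire is not None and rng.random() >= mask_prob) else None
        dam = r.dam if (r.dam is not None and rng.random() >= mask_prob) else None
        records[a] = AnimalRecord(id=a, sire=sire, dam=dam, sex=r.sex,
                                  breed=r.breed, birth_order=r.birth_order)
    return Pedigree(records=records)


def inject_missing(ds: GenotypeDataset, rate: float, seed: int = 0) -> GenotypeDataset:
    """Independently set each genotype call to missing with probability ``rate``."""
    rng = np.random.default_rng(seed)
    geno = ds.geno.copy()
    if rate > 0:
        geno[rng.random(geno.shape) < rate] = -1
    return GenotypeDataset(samples=ds.samples.copy(),
                           snps=SnpMap(ds.snps.table.copy()),
                           geno=geno, species=ds.species)


def simulate_dataset(cfg: SimConfig):
    """Full synthetic bundle: pedigree, genotypes, truth, masked pedigree.

    Returns a dict with keys ``pedigree`` (unmasked), ``masked_pedigree``,
    ``dataset`` (with missing calls injected), ``truth`` and ``snp_map``.
    All randomness derives from ``cfg.seed``.
    """
    ped = simulate_pedigree(cfg)
    snp_map = make_snp_map(cfg)
    rng = np.random.default_rng(cfg.seed + 202)
    lo, hi = cfg.founder_freq_range
    freqs = rng.uniform(lo, hi, size=len(snp_map))
    ds, truth = gene_drop(ped, snp_map, freqs, seed=cfg.seed + 303,
                          cm_per_mb=cfg.cm_per_mb)
    if cfg.missing_rate > 0:
        ds = inject_missing(ds, cfg.missing_rate, seed=cfg.seed + 404)
    masked = (mask_pedigree(ped, cfg.mask_prob, seed=cfg.seed + 505)
              if cfg.mask_prob > 0 else ped)
    return {"pedigree": ped, "masked_pedigree": masked, "dataset": ds,
            "truth": truth, "snp_map": snp_map}
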