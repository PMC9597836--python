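"""Sliding-window detection of runs of homozygosity (ROH) and F_ROH.

The scanner follows the classic SNP-chip recipe: a window of 20 consecutive
SNPs is "homozygous" when it contains no heterozygous call and at most two
missing calls; each SNP's hit rate is the fraction of windows covering it
that are homozygous, and SNPs with hit rate >= 5% are eligible.  Maximal
runs of consecutive eligible SNPs are split at inter-marker gaps above
500 kb and kept as ROH when they contain >= 20 SNPs, span >= 1 Mb and
average at most 500 kb per SNP.  These deliberately stringent settings
minimise false discovery in regions of low marker density.

F_ROH of an individual is the summed ROH length divided by L_AUTO, the
total autosomal length covered by the SNP map.  Segments are also binned
into length classes ([1,2), [2,4), [4,8), [8,16), [16,inf) Mb); shorter
runs reflect older inbreeding because recombination has had more meioses
to break them up, and each class maps to an approximate age in generations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plinkio import MISSING, GenotypeDataset, SnpMap

__all__ = [
    "RohParams",
    "GENERATION_MAP",
    "LENGTH_CLASSES_MB",
    "snp_eligibility",
    "call_roh",
    "l_auto",
    "froh",
    "froh_by_class",
    "roh_summary",
    "froh_table",
]

#: length-class lower/upper bounds in Mb, half-open [lo, hi)
LENGTH_CLASSES_MB: list[tuple[float, float]] = [
    (1.0, 2.0), (2.0, 4.0), (4.0, 8.0), (8.0, 16.0), (16.0, float("inf")),
]

#: approximate age (generations ago) of the inbreeding captured by each class
GENERATION_MAP: dict[tuple[float, float], float] = {
    (1.0, 2.0): 50.0,
    (2.0, 4.0): 20.0,
    (4.0, 8.0): 12.5,
    (8.0, 16.0): 6.0,
    (16.0, float("inf")): 3.0,
}


@dataclass(frozen=True)
class RohParams:
    """Scanning-window and segment-filter parameters (kb units where named)."""

    window_snps: int = 20
    window_het_max: int = 0
    window_missing_max: int = 2
    window_hit_threshold: float = 0.05
    min_snps: int = 20
    min_length_kb: float = 1000.0
    min_density_kb_per_snp: float = 500.0
    max_gap_kb: float = 500.0

    def __post_init__(self):
        if self.window_snps < 1:
            raise ValueError("window_snps must be >= 1")
        for name in ("window_het_max", "window_missing_max", "min_snps",
                     "min_length_kb", "min_density_kb_per_snp", "max_gap_kb",
                     "window_hit_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _window_sums(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate(([0], np.cumsum(x, dtype=np.int64)))
    return c[w:] - c[:-w]


def snp_eligibility(genotypes: np.ndarray, params: RohParams = RohParams()) -> np.ndarray:
    """Per-SNP eligibility mask for one individual on one chromosome.

    A window of ``window_snps`` consecutive SNPs is homozygous when its
    heterozygote count is <= ``window_het_max`` and its missing count is
    <= ``window_missing_max``.  A SNP is eligible when the fraction of
    windows covering it that are homozygous is >= ``window_hit_threshold``.
    Chromosomes shorter than one window yield an all-False mask.
    """
    g = np.asarray(genotypes)
    n, w = len(g), params.window_snps
    if n < w:
        return np.zeros(n, dtype=bool)
    het = (g == 1).astype(np.int64)
    mis = (g == MISSING).astype(np.int64)
    hom_win = (
        (_window_sums(het, w) <= params.window_het_max)
        & (_window_sums(mis, w) <= params.window_missing_max)
    ).astype(np.int64)
    # windows covering SNP i start in [max(0, i-w+1), min(i, n-w)]
    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(idx, n - w)
    c = np.concatenate(([0], np.cumsum(hom_win)))
    hits = c[hi + 1] - c[lo]
    counts = hi - lo + 1
    return hits / counts >= params.window_hit_threshold


def _runs_of_true(mask: np.ndarray):
    """(start, end) index pairs (inclusive) of maximal True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts, ends))


def call_roh(ds: GenotypeDataset, params: RohParams = RohParams()) -> pd.DataFrame:
    """Detect ROH for every individual on every autosome.

    Candidate segments are maximal runs of eligible SNPs, split wherever
    two adjacent SNPs are more than ``max_gap_kb`` apart, then filtered on
    SNP count, physical length (end - start + 1 bp) and marker density
    (length_kb / n_snps <= ``min_density_kb_per_snp``).  Segments start and
    end on eligible SNPs.  Returns a frame with columns IID, CHR, POS1,
    POS2, NSNP, KB, sorted by individual then chromosome then start.
    """
    t = ds.snps.table
    out = []
    max_gap_bp = params.max_gap_kb * 1000.0
    for chrom, sub in t.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"SNP map not position-sorted on chromosome {chrom}")
        cols = sub.index.to_numpy()
        gap_split = np.flatnonzero(np.diff(pos) > max_gap_bp)  # split after these
        for i in range(ds.n_individuals):
            g = ds.geno[i, cols]
            elig = snp_eligibility(g, params)
            for s, e in _runs_of_true(elig):
                # split the run at oversized gaps
                cut = gap_split[(gap_split >= s) & (gap_split < e)]
                bounds = np.concatenate(([s], cut + 1, [e + 1]))
                for b0, b1 in zip(bounds[:-1], bounds[1:]):
                    b1 -= 1
                    n_snps = b1 - b0 + 1
                    length = pos[b1] - pos[b0] + 1
                    if n_snps < params.min_snps:
                        continue
                    if length < params.min_length_kb * 1000.0:
                        continue
                    if (length / 1000.0) / n_snps > params.min_density_kb_per_snp:
                        continue
                    out.append(
                        (ds.samples["iid"].iloc[i], str(chrom),
                         int(pos[b0]), int(pos[b1]), int(n_snps), length / 1000.0)
                    )
    df = pd.DataFrame(out, columns=["IID", "CHR", "POS1", "POS2", "NSNP", "KB"])
    return df.sort_values(["IID", "CHR", "POS1"], kind="stable").reset_index(drop=True)


def l_auto(snp_map: SnpMap, n_autosomes: int | None = None) -> int:
    """Total autosomal length covered by the map, in base pairs.

    Per chromosome: last position - first position + 1 (a single-SNP
    chromosome contributes 1 bp).  When ``n_autosomes`` is given, unplaced
    and sex-linked markers are excluded first.
    """
    t = snp_map.table
    if n_autosomes is not None:
        t = t.loc[snp_map.is_autosomal(n_autosomes)]
    total = 0
    for _, sub in t.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        total += int(pos.max() - pos.min() + 1)
    return total


def _seg_lengths_bp(segments: pd.DataFrame) -> np.ndarray:
    return (segments["POS2"] - segments["POS1"] + 1).to_numpy(dtype=float)


def froh(segments: pd.DataFrame, l_auto_bp: float) -> float:
    """F_ROH = total ROH length of one individual / covered autosome length."""
    if len(segments) == 0:
        return 0.0
    return float(_seg_lengths_bp(segments).sum() / l_auto_bp)


def froh_by_class(segments: pd.DataFrame, l_auto_bp: float) -> dict[tuple[float, float], float]:
    """F_ROH decomposed by segment length class; values sum to total F_ROH.

    Each segment belongs to exactly one half-open class [lo, hi) Mb.
    """
    lengths_mb = _seg_lengths_bp(segments) / 1e6 if len(segments) else np.array([])
    out = {}
    for lo, hi in LENGTH_CLASSES_MB:
        in_class = (lengths_mb >= lo) & (lengths_mb < hi)
        out[(lo, hi)] = float(lengths_mb[in_class].sum() * 1e6 / l_auto_bp)
    return out


def froh_table(ds: GenotypeDataset, segments: pd.DataFrame) -> pd.DataFrame:
    """Per-individual ROH summary: counts, lengths, F_ROH and class split."""
    la = l_auto(ds.snps, ds.n_autosomes)
    rows = []
    grouped = dict(tuple(segments.groupby("IID"))) if len(segments) else {}
    for iid in ds.samples["iid"]:
        seg = grouped.get(iid, segments.iloc[0:0])
        lengths = _seg_lengths_bp(seg)
        row = {
            "iid": iid,
            "n_segments": len(seg),
            "total_length_bp": float(lengths.sum()) if len(seg) else 0.0,
            "mean_length_bp": float(lengths.mean()) if len(seg) else np.nan,
            "f_roh": froh(seg, la),
        }
        for (lo, hi), v in froh_by_class(seg, la).items():
            hi_lab = "inf" if np.isinf(hi) else f"{hi:g}"
            row[f"f_roh_{lo:g}_{hi_lab}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def roh_summary(per_individual: pd.DataFrame, breeds: pd.Series | None = None) -> pd.DataFrame:
    """Per-breed ROH distribution statistics.

    Reports, per breed: number of individuals, number without any ROH,
    mean number of segments per individual, mean total ROH length per
    individual (Mb), mean segment length (Mb) and mean F_ROH.  With no
    breed labels a single "all" stratum is reported.
    """
    df = per_individual.copy()
    df["breed"] = breeds.to_numpy() if breeds is not None else "all"
    rows = []
    for breed, sub in df.groupby("breed", sort=True):
        has = sub["n_segments"] > 0
        rows.append({
            "breed": breed,
            "n_individuals": len(sub),
            "n_without_roh": int((~has).sum()),
            "mean_n_segments": float(sub["n_segments"].mean()),
            "mean_total_length_mb": float(sub["total_length_bp"].mean() / 1e6),
            "mean_segment_length_mb": (
                float(sub.loc[has, "mean_length_bp"].mean() / 1e6)
                if has.any() else np.nan
            ),
            "mean_f_roh": float(sub["f_roh"].mean()),
        })
    return pd.DataFrame(rows)
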