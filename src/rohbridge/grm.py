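"""Genomic relationship matrix (GRM) and GRM-based inbreeding estimators.

The GRM is built from per-SNP standardized genotype deviations,
w = (x - 2p) / sqrt(2p(1-p)) with p the sample frequency of the counted
allele, G = W W' / m.  Missing genotypes contribute nothing to the
numerator and each pair's denominator is the count of jointly non-missing
SNPs, which keeps the estimator unbiased under missingness at random.

Four per-individual inbreeding estimators are emitted:

* ``f_diag``  — G_ii - 1, the diagonal of the standardized GRM minus one;
* ``fhat1``   — variance-standardized estimator, mean of w^2 - 1
  (identical to ``f_diag`` under the missing-data handling above);
* ``fhat2``   — excess-homozygosity estimator, 1 - mean[x(2-x)/(2p(1-p))];
* ``fhat3``   — allele-frequency-corrected correlation-form estimator,
  mean[(x^2 - (1+2p)x + 2p^2) / (2p(1-p))].

All may legitimately be negative: an individual less homozygous than
expected under Hardy-Weinberg at the sample frequencies scores below zero.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .plinkio import MISSING, GenotypeDataset, allele_freq

__all__ = ["build_grm", "fgrm", "write_grm"]


def _standardize(ds: GenotypeDataset):
    """Return (W, mask, p, kept) with monomorphic/all-missing SNPs dropped."""
    p = allele_freq(ds)
    with np.errstate(invalid="ignore"):
        poly = (p > 0.0) & (p < 1.0)
    poly = np.where(np.isnan(p), False, poly)
    if (~poly).any():
        warnings.warn(
            f"excluding {int((~poly).sum())} monomorphic/all-missing SNPs "
            "from GRM construction",
            stacklevel=3,
        )
    p = p[poly]
    x = ds.geno[:, poly].astype(float)
    mask = x != MISSING
    x[~mask] = np.nan
    w = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    w = np.where(mask, w, 0.0)
    return w, mask.astype(float), p, poly


def build_grm(ds: GenotypeDataset) -> np.ndarray:
    """n x n genomic relationship matrix with pairwise-complete denominators.

    Expects a MAF-filtered dataset; allele frequencies are the sample
    frequencies of the same dataset.
    """
    w, mask, _, _ = _standardize(ds)
    counts = mask @ mask.T
    with np.errstate(invalid="ignore", divide="ignore"):
        g = (w @ w.T) / counts
    g[counts == 0] = np.nan
    return g


def fgrm(ds: GenotypeDataset) -> pd.DataFrame:
    """Per-individual GRM inbreeding estimators (f_diag, fhat1..fhat3).

    The module's headline F_GRM is ``f_diag``; all four columns are always
    returned so downstream comparisons can pick any convention.
    """
    w, mask, p, poly = _standardize(ds)
    x = ds.geno[:, poly].astype(float)
    x[mask == 0] = 0.0  # masked terms contribute 0; denominators use counts
    m_i = mask.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fhat1 = (w**2).sum(axis=1) / m_i - 1.0

        het_term = x * (2.0 - x) / (2.0 * p * (1.0 - p))
        fhat2 = 1.0 - (het_term * mask).sum(axis=1) / m_i

        corr_term = (x**2 - (1.0 + 2.0 * p) * x + 2.0 * p**2) / (
            2.0 * p * (1.0 - p)
        )
        # masked entries of corr_term are not zero at x=0, mask explicitly
        fhat3 = (corr_term * mask).sum(axis=1) / m_i

    g = build_grm(ds)
    return pd.DataFrame({
        "iid": ds.samples["iid"].to_numpy(),
        "f_diag": np.diag(g) - 1.0,
        "fhat1": fhat1,
        "fhat2": fhat2,
        "fhat3": fhat3,
    })


def write_grm(g: np.ndarray, ids, square_path=None, lower_path=None) -> None:
    """Write the GRM as a square TSV and/or lower-triangle text."""
    ids = list(ids)
    if square_path is not None:
        pd.DataFrame(g, index=ids, columns=ids).to_csv(square_path, sep="\t")
    if lower_path is not None:
        with open(lower_path, "w") as fh:
            for i in range(len(ids)):
                for j in range(i + 1):
                    fh.write(f"{i + 1}\t{j + 1}\t{g[i, j]:.10g}\n")
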