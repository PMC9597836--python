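"""Calibrating pedigree inbreeding against genomic inbreeding.

Herd-book pedigrees of small ruminants are often shallow or wrong, so
F_PED underestimates true autozygosity exactly for the animals whose
genealogy is least recorded.  The procedure implemented here estimates the
F_PED that a *complete* pedigree would have produced, from F_ROH:

1. pool both species and fit F_PED ~ F_ROH by ordinary least squares within
   increasing pedigree-depth strata (animals with FullGen >= k, k = 0..8);
2. per species, select the stratum that keeps at least ``min_n`` (600)
   individuals of that species while maximizing the fit (highest R^2,
   ties broken by higher Pearson r, then deeper stratum);
3. apply the selected line to that species' stratum, z-score the residuals
   (predicted - observed), drop animals outside the central residual
   quartiles and refit on the retained half ("refined" model);
4. use the refined line to estimate a definitive F_PED for every animal of
   the stratum, and summarise F_ROH within 0.05-wide bins of estimated
   F_PED (mean, SD, normal-approximation 95% CI, range) per breed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "BridgeModel",
    "DegenerateFitError",
    "correlate",
    "fit_lrm",
    "lrm_by_fullgen",
    "select_model",
    "standardized_residuals",
    "quartile_exclude",
    "refine",
    "estimate_fped",
    "invert_boundary",
    "class_table",
    "round3",
]

REQUIRED_COLS = ["id", "species", "breed", "f_ped", "f_roh", "fullgen"]


class DegenerateFitError(ValueError):
    """Regression impossible: too few points or constant predictor."""


@dataclass(frozen=True)
class BridgeModel:
    """A fitted line F_PED = intercept + slope * F_ROH with provenance."""

    intercept: float
    slope: float
    r: float
    r_squared: float
    n: int
    min_fullgen: int = 0
    stage: str = "per-class"  # {per-class, selected, refined}
    species: str | None = None
    n_goats: int | None = None
    n_sheep: int | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "intercept", "slope", "r", "r_squared", "n", "min_fullgen",
            "stage", "species", "n_goats", "n_sheep")}


def round3(x: float) -> float:
    """Round to 3 decimals, half away from zero (report convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.001"),
                                                  rounding=ROUND_HALF_UP))


def correlate(x, y) -> dict[str, float]:
    """Pearson correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("correlate needs two equal-length vectors, n >= 3")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p_value": float(p)}


def fit_lrm(table: pd.DataFrame, *, min_fullgen: int = 0,
            stage: str = "per-class", species: str | None = None) -> BridgeModel:
    """OLS of f_ped on f_roh over the given rows."""
    x = table["f_roh"].to_numpy(dtype=float)
    y = table["f_ped"].to_numpy(dtype=float)
    if len(x) < 3:
        raise DegenerateFitError(f"only {len(x)} rows; need >= 3")
    if np.ptp(x) == 0:
        raise DegenerateFitError("constant f_roh: design matrix is singular")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    r = float(stats.pearsonr(x, y)[0]) if np.ptp(y) > 0 else 0.0
    counts = table["species"].value_counts() if "species" in table else {}
    return BridgeModel(
        intercept=float(res.params[0]), slope=float(res.params[1]),
        r=r, r_squared=float(res.rsquared), n=len(x),
        min_fullgen=min_fullgen, stage=stage, species=species,
        n_goats=int(counts.get("goat", 0)) if len(counts) else None,
        n_sheep=int(counts.get("sheep", 0)) if len(counts) else None,
    )


def lrm_by_fullgen(table: pd.DataFrame, k_values=range(0, 9)) -> list[BridgeModel | None]:
    """Fit the pooled two-species line within each FullGen >= k stratum.

    Returns one model per k (None where the stratum is empty or the fit is
    degenerate).  Strata are nested, so n is non-increasing in k.
    """
    models: list[BridgeModel | None] = []
    for k in k_values:
        sub = table.loc[table["fullgen"] >= k]
        try:
            models.append(fit_lrm(sub, min_fullgen=int(k)))
        except DegenerateFitError:
            models.append(None)
    return models


def select_model(models, species: str, min_n: int = 600) -> BridgeModel:
    """Pick the stratum for one species: enough animals, best fit.

    Among strata whose count of ``species`` individuals is >= ``min_n``,
    select the model with the highest R^2; ties broken by higher r, then
    larger minimum FullGen.  A warning is logged when the max-r and max-R^2
    criteria point to different strata.
    """
    count_key = {"goat": "n_goats", "sheep": "n_sheep"}[species]
    eligible = [m for m in models
                if m is not None and (getattr(m, count_key) or 0) >= min_n]
    if not eligible:
        raise DegenerateFitError(
            f"no FullGen stratum keeps >= {min_n} {species} individuals"
        )
    best = max(eligible, key=lambda m: (m.r_squared, m.r, m.min_fullgen))
    best_by_r = max(eligible, key=lambda m: (m.r, m.r_squared, m.min_fullgen))
    if best_by_r.min_fullgen != best.min_fullgen:
        import logging

        logging.getLogger(__name__).warning(
            "selection criteria disagree for %s: max R^2 at FullGen>=%d, "
            "max r at FullGen>=%d; using max R^2",
            species, best.min_fullgen, best_by_r.min_fullgen,
        )
    return replace(best, stage="selected", species=species)


def standardized_residuals(model: BridgeModel, table: pd.DataFrame) -> np.ndarray:
    """Z-scores of (predicted - observed) F_PED under the given line.

    All-equal residuals (zero SD) yield all-zero z-scores.
    """
    pred = model.intercept + model.slope * table["f_roh"].to_numpy(dtype=float)
    d = pred - table["f_ped"].to_numpy(dtype=float)
    sd = d.std(ddof=1) if len(d) > 1 else 0.0
    # essentially-constant residuals (incl. float noise) standardize to 0
    if sd <= 1e-12 * max(1.0, float(np.abs(d).max(initial=0.0))):
        return np.zeros(len(d))
    return (d - d.mean()) / sd


def quartile_exclude(z: np.ndarray) -> np.ndarray:
    """Retention mask keeping Q1 <= z <= Q3 (linear-interpolation quantiles).

    Animals with standardized residuals strictly below the first or above
    the third quartile are excluded.  When Q1 == Q3 (e.g. all values tied)
    nothing is excluded.
    """
    z = np.asarray(z, dtype=float)
    q1, q3 = np.quantile(z, [0.25, 0.75])  # default linear interpolation
    return (z >= q1) & (z <= q3)


def refine(model: BridgeModel, table: pd.DataFrame) -> BridgeModel:
    """Residual-quartile refinement of a selected model.

    Applies ``model`` to its species' FullGen >= k stratum, drops animals
    with standardized residuals outside [Q1, Q3] and refits on the rest.
    """
    if model.species is None:
        raise ValueError("refine needs a species-selected model")
    sub = table.loc[
        (table["species"] == model.species)
        & (table["fullgen"] >= model.min_fullgen)
    ]
    z = standardized_residuals(model, sub)
    kept = sub.loc[quartile_exclude(z)]
    refit = fit_lrm(kept, min_fullgen=model.min_fullgen,
                    stage="refined", species=model.species)
    return refit


def estimate_fped(f_roh, model: BridgeModel, clamp_at_zero: bool = False):
    """Estimated F_PED = intercept + slope * F_ROH (optionally floored at 0)."""
    est = model.intercept + model.slope * np.asarray(f_roh, dtype=float)
    if clamp_at_zero:
        est = np.maximum(est, 0.0)
    return est if est.ndim else float(est)


def invert_boundary(f_ped_boundary: float, model: BridgeModel) -> float:
    """F_ROH at which the line predicts ``f_ped_boundary`` (3-decimal report).

    Inverse of :func:`estimate_fped`: (boundary - intercept) / slope.
    """
    if model.slope == 0:
        raise ZeroDivisionError("zero slope: boundary inversion undefined")
    return round3((f_ped_boundary - model.intercept) / model.slope)


def class_table(
    estimates: np.ndarray,
    table: pd.DataFrame,
    bin_width: float = 0.05,
    floor_negative_to_first_bin: bool = True,
) -> pd.DataFrame:
    """F_ROH summaries within bins of estimated F_PED, per breed and overall.

    Bins are [0, 0.05), [0.05, 0.10), ...  Negative estimates go to the
    first bin by default (the fitted intercepts are slightly negative).
    Reports n, F_ROH mean, SD, normal 95% CI (mean +/- 1.96 SD/sqrt(n);
    blank at n = 1) and min-max range; per-breed rows plus an "all" row
    per bin, with per-breed counts summing to the overall bin count.
    """
    est = np.asarray(estimates, dtype=float)
    df = table.copy().reset_index(drop=True)
    df["_est"] = est
    binned = est.copy()
    if floor_negative_to_first_bin:
        binned = np.maximum(binned, 0.0)
    df["_bin"] = np.floor(binned / bin_width) * bin_width

    rows = []
    for lo, sub in df.groupby("_bin", sort=True):
        strata = [("all", sub)] + [
            (b, g) for b, g in sub.groupby("breed", sort=True)
        ]
        for breed, g in strata:
            v = g["f_roh"].to_numpy(dtype=float)
            n = len(v)
            mean = float(v.mean())
            sd = float(v.std(ddof=1)) if n > 1 else float("nan")
            if n > 1:
                half = 1.96 * sd / np.sqrt(n)
                ci_lo, ci_hi = mean - half, mean + half
            else:
                ci_lo = ci_hi = float("nan")
            rows.append({
                "breed": breed,
                "fped_class_lo": round(float(lo), 10),
                "fped_class_hi": round(float(lo) + bin_width, 10),
                "n": n,
                "froh_mean": mean,
                "froh_sd": sd,
                "froh_ci_lo": ci_lo,
                "froh_ci_hi": ci_hi,
                "froh_min": float(v.min()),
                "froh_max": float(v.max()),
            })
    return pd.DataFrame(rows)
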