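"""Clone-level statistics.

Clone-initiating-cell (CIC) frequency, in vivo doubling time, mixture-based
speed classification, fate calling across passages, Shannon entropy of
clonal composition, dose-response slopes and caliper tumour volume.

The doubling-time statistic is days in vivo divided by log2(absolute clone
size): the average days per population doubling needed for one cell to
reach the observed clone size, independent of tumour size and of competing
clones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from clonetrack.mixture import MixtureFit, fit_gaussian_mixture

SPEED_LABELS = ("fast", "medium", "slow")
FATE_PROPAGATING = "propagating"
FATE_TRANSIENT = "transient"
FATE_EMERGING = "emerging"


@dataclass
class CICFrequency:
    """Clones per uniquely barcoded cell implanted, as fraction and '1 in N'."""

    fraction: float
    one_in: float  # N such that frequency = 1 in N (inf when no clones)


def cic_frequency(
    n_clones: int, cells_implanted: int, transduction_efficiency: float
) -> CICFrequency:
    """Clones detected in the primary xenograft per barcoded cell implanted.

    ``transduction_efficiency`` is the fraction of implanted cells carrying
    a barcode (GFP-positive fraction).
    """
    if cells_implanted <= 0:
        raise ValueError("cells_implanted must be positive")
    if not 0 < transduction_efficiency <= 1:
        raise ValueError("transduction_efficiency must be in (0, 1]")
    barcoded = cells_implanted * transduction_efficiency
    if n_clones > barcoded:
        raise ValueError(
            f"{n_clones} clones exceed the {barcoded:.0f} barcoded cells implanted"
        )
    if n_clones == 0:
        return CICFrequency(fraction=0.0, one_in=np.inf)
    frac = n_clones / barcoded
    return CICFrequency(fraction=frac, one_in=1.0 / frac)


def doubling_time(est_cells: float, days_in_vivo: float) -> float:
    """Days in vivo divided by log2(absolute clone size)."""
    if days_in_vivo <= 0:
        raise ValueError("days_in_vivo must be positive")
    if est_cells <= 1:
        raise ValueError("doubling time undefined for clones of <= 1 cell")
    return days_in_vivo / np.log2(est_cells)


def doubling_times(clones: pd.DataFrame) -> pd.DataFrame:
    """Vectorised doubling times; clones of <=1 cell are excluded with reason.

    Expects columns ``est_cells`` and ``days_in_vivo``; returns the input
    with a ``doubling_time`` column, rows failing the size precondition
    dropped and counted in ``df.attrs['n_excluded_size']``.
    """
    ok = clones["est_cells"] > 1
    out = clones[ok].copy()
    out["doubling_time"] = out["days_in_vivo"] / np.log2(out["est_cells"])
    out.attrs["n_excluded_size"] = int((~ok).sum())
    return out


def fit_doubling_mixture(
    times, max_k: int = 3, criterion: str = "aic", seed: int = 0, **kwargs
) -> MixtureFit:
    """Gaussian-mixture fit of the doubling-time distribution, K by AIC."""
    return fit_gaussian_mixture(
        times, max_k=max_k, criterion=criterion, seed=seed, **kwargs
    )


def classify_speed(
    time, fit: MixtureFit, method: str = "posterior"
) -> np.ndarray | str:
    """Fast/medium/slow class from the mixture fit (fast = smallest mean).

    ``method='posterior'`` assigns by maximum posterior; ``method='cutoff'``
    uses the hard density-crossing boundaries between adjacent components.
    """
    if fit.k > 3:
        raise ValueError("speed labels defined for <= 3 components")
    arr = np.atleast_1d(np.asarray(time, dtype=float))
    if (arr <= 0).any():
        raise ValueError("doubling times must be positive")
    if method == "posterior":
        idx = fit.classify(arr)
    elif method == "cutoff":
        idx = np.searchsorted(fit.cutoffs, arr)
    else:
        raise ValueError("method must be 'posterior' or 'cutoff'")
    labels = np.array(SPEED_LABELS[: fit.k])[idx]
    return labels if np.ndim(time) else str(labels[0])


def classify_fate(present_primary: bool, present_any_secondary: bool) -> str:
    """Propagating (P & S), transient (P only) or emerging (S only).

    Presence means detection above the limit of detection; clones below LOD
    count as absent.
    """
    if present_primary and present_any_secondary:
        return FATE_PROPAGATING
    if present_primary:
        return FATE_TRANSIENT
    if present_any_secondary:
        return FATE_EMERGING
    raise ValueError("clone observed in neither primary nor secondary xenografts")


def shannon_entropy(fractions, base: float = 2.0) -> float:
    """Shannon index -sum(p log p) of a composition vector.

    Accepts near-normalised vectors (renormalised within 1e-9); 0*log(0)=0.
    Base 2 (bits) by default; pass ``base=np.e`` for nats.
    """
    p = np.asarray(fractions, dtype=float)
    if (p < 0).any():
        raise ValueError("negative entries in composition vector")
    total = p.sum()
    if total <= 0:
        raise ValueError("composition sums to zero")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(base))


def tumor_volume(w: float, h: float) -> float:
    """Caliper tumour volume in mm^3: width^2 x height / 2."""
    if w < 0 or h < 0:
        raise ValueError("dimensions must be nonnegative")
    return w * w * h / 2.0


def dose_response_slope(
    doses, cic, groups=None
) -> pd.DataFrame:
    """Per-model OLS slope of log10(CIC frequency) on log10(cells implanted).

    Models with a single dose are skipped (slope undefined) and reported
    with NaN coefficients. Returns columns
    ``model, slope, intercept, slope_se, n``.
    """
    df = pd.DataFrame(
        {
            "dose": np.asarray(doses, dtype=float),
            "cic": np.asarray(cic, dtype=float),
            "model": groups if groups is not None else "all",
        }
    )
    if (df["dose"] <= 0).any() or (df["cic"] <= 0).any():
        raise ValueError("doses and CIC frequencies must be positive")
    rows = []
    for model, sub in df.groupby("model", sort=True):
        if sub["dose"].nunique() < 2:
            rows.append(
                {"model": model, "slope": np.nan, "intercept": np.nan,
                 "slope_se": np.nan, "n": len(sub)}
            )
            continue
        fit = stats.linregress(np.log10(sub["dose"]), np.log10(sub["cic"]))
        rows.append(
            {"model": model, "slope": fit.slope, "intercept": fit.intercept,
             "slope_se": fit.stderr, "n": len(sub)}
        )
    return pd.DataFrame(rows)
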