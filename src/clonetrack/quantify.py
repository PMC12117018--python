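"""Spike-in calibrated absolute clone sizes.

Spike-in control cells of known number are sequenced alongside the clones.
Each clone's fractional read value (FRV) — its reads divided by the summed
reads of all spike-ins in the sample — is converted to an absolute cell
number through a log10-log10 linear calibration fitted on the spike-in
ladder, which corrects for amplification bias. Detection thresholds and the
limit-of-detection formula (20 cells scaled by the inverse fraction of
tumour sampled) decide which clones count as present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from clonetrack.exceptions import CalibrationError
from clonetrack.extraction import BarcodeCountTable

#: Detection sensitivity anchor: clones of 20 cells are detected with 95%
#: sensitivity in a fully sampled tumour.
LOD_CELLS = 20.0


@dataclass
class CalibrationModel:
    """log10(cells) = intercept + slope * log10(FRV), from the spike-in ladder."""

    slope: float
    intercept: float
    residual_sd: float
    n_points: int
    n_excluded: int = 0

    def __post_init__(self):
        if self.n_points < 2:
            raise CalibrationError("calibration needs >= 2 points")
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise CalibrationError("non-finite calibration coefficients")


def compute_frv(clone_reads: int, spikein_total_reads: int) -> float:
    """Fractional read value: clone reads over summed spike-in reads."""
    if spikein_total_reads <= 0:
        raise CalibrationError("no spike-in reads: FRV undefined")
    if clone_reads < 0:
        raise ValueError("negative read count")
    return clone_reads / spikein_total_reads


def fit_calibration(spikeins: pd.DataFrame) -> CalibrationModel:
    """Least-squares fit of log10(known cells) on log10(FRV).

    ``spikeins`` needs columns ``known_cells`` and ``reads`` (one row per
    technical replicate). Spike-ins with zero reads cannot enter the log-log
    fit; they are excluded and reported via ``n_excluded``.
    """
    if not {"known_cells", "reads"}.issubset(spikeins.columns):
        raise ValueError("spikeins needs 'known_cells' and 'reads' columns")
    total = int(spikeins["reads"].sum())
    if total <= 0:
        raise CalibrationError("all spike-ins have zero reads")
    usable = spikeins[spikeins["reads"] > 0]
    n_excluded = len(spikeins) - len(usable)
    if usable["known_cells"].nunique() < 2:
        raise CalibrationError("need >= 2 distinct ladder levels with reads")
    x = np.log10(usable["reads"].to_numpy(dtype=float) / total)
    y = np.log10(usable["known_cells"].to_numpy(dtype=float))
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    dof = max(len(x) - 2, 1)
    return CalibrationModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        residual_sd=float(np.sqrt((resid**2).sum() / dof)),
        n_points=len(x),
        n_excluded=n_excluded,
    )


def estimate_absolute_size(frv: float, model: CalibrationModel) -> float:
    """Absolute clone size (cells) implied by an FRV under the calibration."""
    if frv <= 0:
        raise ValueError("FRV must be positive to estimate a size")
    return float(10 ** (model.intercept + model.slope * np.log10(frv)))


def apply_detection_filters(
    table: BarcodeCountTable, min_reads: int = 0
) -> BarcodeCountTable:
    """Drop barcodes below a read threshold (applied *after* collapsing).

    Removed reads are accounted under the ``below_threshold`` rejection
    reason so read conservation still holds.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    kept = {b: n for b, n in table.counts.items() if n >= min_reads}
    dropped = sum(table.counts.values()) - sum(kept.values())
    rejected = dict(table.rejected)
    if dropped:
        rejected["below_threshold"] = rejected.get("below_threshold", 0) + dropped
    return BarcodeCountTable(
        sample_id=table.sample_id,
        library_id=table.library_id,
        counts=kept,
        rejected=rejected,
        is_spikein=table.is_spikein,
    )


def limit_of_detection(percent_tumor_sampled: float) -> float:
    """Smallest detectable clone: 20 cells x (100 / percent of tumour sampled)."""
    if not 0 < percent_tumor_sampled <= 100:
        raise ValueError("percent sampled must be in (0, 100]")
    return LOD_CELLS * (100.0 / percent_tumor_sampled)


def quantify_clones(
    clone_table: BarcodeCountTable,
    spikein_table: BarcodeCountTable,
    spikein_manifest: pd.DataFrame,
    percent_tumor_sampled: float = 100.0,
    min_reads: int = 0,
) -> pd.DataFrame:
    """Clone quantification for one sample: reads -> FRV -> absolute cells.

    ``spikein_manifest`` maps spike-in barcodes to known cell numbers
    (columns ``barcode``, ``known_cells``). Returns a frame with columns
    ``sample, barcode, reads, frv, est_cells, pass_lod``.
    """
    filtered = apply_detection_filters(clone_table, min_reads=min_reads)
    spike_reads = spikein_manifest.assign(
        reads=[spikein_table.counts.get(b, 0) for b in spikein_manifest["barcode"]]
    )
    model = fit_calibration(spike_reads)
    total_spike = int(spike_reads["reads"].sum())
    lod = limit_of_detection(percent_tumor_sampled)
    rows = []
    for barcode, reads in sorted(filtered.counts.items()):
        frv = compute_frv(reads, total_spike)
        est = estimate_absolute_size(frv, model) if frv > 0 else 0.0
        rows.append(
            {
                "sample": clone_table.sample_id,
                "barcode": barcode,
                "reads": reads,
                "frv": frv,
                "est_cells": est,
                "pass_lod": est >= lod,
            }
        )
    return pd.DataFrame(
        rows, columns=["sample", "barcode", "reads", "frv", "est_cells", "pass_lod"]
    )
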