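"""Background subtraction, log2 transform and robust within-chip Z scores.

Each of the 32 chips (4 experiments x 8 time points) is processed entirely
on its own: the minimum raw reading over the genes of interest is subtracted
from every feature, values are log2 transformed (with a +1 pseudocount so
the minimum gene maps to 0 exactly), and the result is centered and scaled
robustly,

    Z_k = (b_k - median(b)) / ((p95(b) - p5(b)) / 3.29),

where the median and the 5th/95th percentiles are computed over the genes
of interest. 3.29 is the normal-distribution width of the middle 90%
(z_0.95 - z_0.05), so the denominator estimates the SD without being pulled
by outliers such as strongly responding genes. No cross-chip information is
used anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from qanet._errors import DegenerateScaleError, ParameterError, StructuralError
from qanet.synth import ChipLayout, ChipSet

#: z_0.95 - z_0.05 of the standard normal; robust SD calibration.
ROBUST_SD_DIVISOR = 3.29

#: Spike coefficient-of-variation threshold above which a chip is flagged.
SPIKE_CV_LIMIT = 0.65


@dataclass(frozen=True)
class NormalizedSet:
    """Robust Z values for every experiment, time point and feature."""

    z: np.ndarray  # (n_experiments, n_times, n_features)
    time_grid_hr: np.ndarray
    provenance: pd.DataFrame  # one row per chip: min subtracted, percentiles

    @property
    def n_features(self) -> int:
        return self.z.shape[2]


def preprocess_chip(raw_chip: np.ndarray, layout: ChipLayout) -> np.ndarray:
    """Background-subtract and log2-transform one chip.

    The minimum is taken over genes of interest only; the subtraction is
    applied to every feature (negative controls included).
    """
    raw = np.asarray(raw_chip, dtype=float)
    if raw.shape != (layout.n_features,):
        raise StructuralError("raw chip length does not match layout")
    if np.any(raw < 0):
        raise ParameterError("raw intensities must be nonnegative")
    goi = layout.gene_mask
    if not goi.any():
        raise StructuralError("layout has no genes of interest")
    # negative controls may read below the gene minimum; floor at 0 so the
    # +1 pseudocount keeps the log finite
    return np.log2(np.maximum(raw - raw[goi].min(), 0.0) + 1.0)


def robust_z(b: np.ndarray) -> np.ndarray:
    """Robust Z score of a log2 vector using its own median and p5/p95.

    Percentiles use linear interpolation between order statistics.
    """
    b = np.asarray(b, dtype=float)
    if len(np.unique(b)) < 3:
        raise DegenerateScaleError("need at least 3 distinct values")
    p5, p50, p95 = np.percentile(b, [5, 50, 95])
    scale = (p95 - p5) / ROBUST_SD_DIVISOR
    if scale == 0:
        raise DegenerateScaleError("p95 equals p5; chip rejected")
    return (b - p50) / scale


def normalize_chip(raw_chip: np.ndarray, layout: ChipLayout):
    """Full within-chip normalization of one chip.

    Center and scale statistics are computed over genes of interest and
    applied to all features. Returns ``(z, provenance dict)``.
    """
    raw = np.asarray(raw_chip, dtype=float)
    goi = layout.gene_mask
    b = preprocess_chip(raw, layout)
    bg = b[goi]
    if len(np.unique(bg)) < 3:
        raise DegenerateScaleError("need at least 3 distinct gene values")
    p5, p50, p95 = np.percentile(bg, [5, 50, 95])
    scale = (p95 - p5) / ROBUST_SD_DIVISOR
    if scale == 0:
        raise DegenerateScaleError("p95 equals p5; chip rejected")
    prov = {"min_subtracted": float(raw[goi].min()), "p5": p5, "p50": p50,
            "p95": p95, "scale": scale}
    return (b - p50) / scale, prov


def normalize_set(chipset: ChipSet, layout: ChipLayout) -> NormalizedSet:
    """Normalize every chip of a ChipSet independently."""
    n_exp, n_time, n_feat = chipset.intensities.shape
    z = np.empty_like(chipset.intensities)
    rows = []
    for i in range(n_exp):
        for j in range(n_time):
            z[i, j], prov = normalize_chip(chipset.intensities[i, j], layout)
            rows.append({"experiment": chipset.experiments[i],
                         "time_hr": chipset.time_grid_hr[j], **prov})
    return NormalizedSet(z, chipset.time_grid_hr.copy(), pd.DataFrame(rows))


def qc_metrics(raw_chip: np.ndarray, layout: ChipLayout):
    """Chip quality metrics from control features.

    Returns ``(fraction_above_background, spike_cv, flagged)`` where the
    fraction counts gene features exceeding the median of the negative
    controls, and the chip is flagged when the spike CV exceeds 0.65.
    """
    raw = np.asarray(raw_chip, dtype=float)
    if raw.shape != (layout.n_features,):
        raise StructuralError("raw chip length does not match layout")
    neg = layout.negative_control_flags
    if not neg.any():
        raise StructuralError("no negative controls: background undefined")
    if not layout.spike_flags.any():
        raise StructuralError("no spike features: CV undefined")
    bg_median = np.median(raw[neg])
    frac = float(np.mean(raw[layout.gene_mask] > bg_median))
    spikes = raw[layout.spike_flags]
    mean = spikes.mean()
    cv = float(spikes.std(ddof=1) / mean) if mean > 0 else np.inf
    return frac, cv, cv > SPIKE_CV_LIMIT


def qc_report(chipset: ChipSet, layout: ChipLayout) -> pd.DataFrame:
    """Per-chip QC table (one row per experiment x time point)."""
    rows = []
    for i, exp in enumerate(chipset.experiments):
        for j, t in enumerate(chipset.time_grid_hr):
            frac, cv, flag = qc_metrics(chipset.intensities[i, j], layout)
            rows.append({"experiment": exp, "time_hr": t,
                         "fraction_above_background": frac,
                         "spike_cv": cv, "flagged": flag})
    return pd.DataFrame(rows)
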