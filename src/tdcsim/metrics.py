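"""Dosimetry metrics: per-tissue field statistics, focality volumes, CV in dB.

Focality is summarised by V70 and V50: the percentage of a tissue's volume
where the field amplitude exceeds 70% (about a 3 dB amplitude reduction) or
50% (about 6 dB) of its within-tissue peak.  Interindividual variability is
the coefficient of variability (standard deviation over mean) of a statistic
across the phantom family, expressed in decibels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TissueStats",
    "FocalityResult",
    "tissue_descriptive_stats",
    "focality_volume_fraction",
    "focality_result",
    "cv_db",
    "db_reduction",
]


@dataclass(frozen=True)
class TissueStats:
    """Order statistics of the amplitude distribution within one tissue mask."""

    tissue: str
    median: float
    q25: float
    q75: float
    min: float
    max: float
    peak: float
    voxel_count: int


@dataclass(frozen=True)
class FocalityResult:
    tissue: str
    v70: float  # % of tissue volume above 70% of peak
    v50: float


def _masked(amp: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vals = np.asarray(amp)[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty tissue mask")
    if np.any(vals < 0):
        raise ValueError("amplitudes must be non-negative")
    return vals


def tissue_descriptive_stats(amp: np.ndarray, mask: np.ndarray, tissue: str = "",
                             robust_peak: bool = False) -> TissueStats:
    """Median, quartiles, min, max and peak of the amplitudes under a mask.

    Percentiles use linear interpolation.  ``robust_peak`` reports the 99.9th
    percentile instead of the literal maximum, guarding against single-voxel
    numerical artifacts; off by default.
    """
    vals = _masked(amp, mask)
    q25, med, q75 = np.percentile(vals, [25, 50, 75])
    mx = float(vals.max())
    peak = float(np.percentile(vals, 99.9)) if robust_peak else mx
    return TissueStats(tissue, float(med), float(q25), float(q75),
                       float(vals.min()), mx, peak, int(vals.size))


def focality_volume_fraction(amp: np.ndarray, mask: np.ndarray,
                             threshold_fraction: float,
                             robust_peak: bool = False) -> float:
    """Percentage of masked voxels with amplitude strictly above
    ``threshold_fraction`` times the within-mask peak."""
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold fraction must be in (0, 1)")
    vals = _masked(amp, mask)
    peak = np.percentile(vals, 99.9) if robust_peak else vals.max()
    return 100.0 * float(np.count_nonzero(vals > threshold_fraction * peak)) / vals.size


def focality_result(amp: np.ndarray, mask: np.ndarray, tissue: str = "",
                    robust_peak: bool = False) -> FocalityResult:
    """V70 and V50 for one tissue."""
    return FocalityResult(
        tissue,
        focality_volume_fraction(amp, mask, 0.7, robust_peak),
        focality_volume_fraction(amp, mask, 0.5, robust_peak),
    )


def cv_db(values, convention: str = "one_plus", ddof: int = 1) -> float:
    """Coefficient of variability across models, in dB.

    CV = sample standard deviation / mean.  The default dB convention is
    ``20*log10(1 + CV)``, which maps CV = 1 (sd equal to the mean) to about
    6 dB, matching the amplitude-dB scale on which a factor 0.5 is 6 dB; the
    alternative ``"ratio"`` convention ``20*log10(CV)`` is also available.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("CV requires a positive mean")
    cv = vals.std(ddof=ddof) / mean
    if convention == "one_plus":
        return 20.0 * math.log10(1.0 + cv)
    if convention == "ratio":
        return 20.0 * math.log10(cv) if cv > 0 else -math.inf
    raise ValueError(f"unknown CV-dB convention {convention!r}")


def db_reduction(fraction: float) -> float:
    """Amplitude reduction in dB of a fractional threshold (0.7 -> ~3 dB)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return 20.0 * math.log10(1.0 / fraction)
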