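"""First-order intensity statistics over the in-mask HU distribution.

Conventions (fixed, documented):

* variance / standard deviation use the population convention (``ddof=0``);
* skewness is the Fisher-Pearson population coefficient, kurtosis is the
  population excess kurtosis; both are defined as 0 for a constant VOI;
* entropy and uniformity are computed on the equal-width quantized levels
  (same binning rule as the texture stage); entropy uses log base 2;
* coefficient-of-variation and quartile-coefficient-of-dispersion fall back
  to 0 when their denominator is 0 so every feature is always finite.
"""

from __future__ import annotations

import numpy as np

from immunorad.volumes import CTVolume, ROIMask

INTENSITY_FEATURE_NAMES = (
    "fo_mean",
    "fo_median",
    "fo_minimum",
    "fo_maximum",
    "fo_range",
    "fo_percentile10",
    "fo_percentile25",
    "fo_percentile75",
    "fo_percentile90",
    "fo_interquartile_range",
    "fo_variance",
    "fo_standard_deviation",
    "fo_skewness",
    "fo_kurtosis",
    "fo_energy",
    "fo_total_energy",
    "fo_root_mean_square",
    "fo_mean_absolute_deviation",
    "fo_robust_mean_absolute_deviation",
    "fo_median_absolute_deviation",
    "fo_entropy",
    "fo_uniformity",
    "fo_coefficient_of_variation",
    "fo_quartile_coefficient_of_dispersion",
)


def _histogram_probabilities(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width histogram over the in-mask range, as probabilities."""
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return np.array([1.0])
    counts, _ = np.histogram(values, bins=n_bins, range=(lo, hi))
    return counts[counts > 0] / values.size


def intensity_features(
    voi: CTVolume, mask: ROIMask, n_bins: int = 64
) -> dict[str, float]:
    """Compute the 24 first-order features of the in-mask intensities."""
    x = voi.intensities[mask.foreground].astype(np.float64)
    n = x.size
    mean = float(x.mean())
    median = float(np.median(x))
    p10, p25, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 75, 90))
    var = float(x.var())
    sd = float(np.sqrt(var))
    centered = x - mean
    if sd > 0:
        skew = float(np.mean(centered**3) / sd**3)
        kurt = float(np.mean(centered**4) / sd**4 - 3.0)
    else:
        skew = kurt = 0.0
    energy = float(np.sum(x**2))
    # robust MAD: mean absolute deviation of the 10th-90th percentile subset
    robust = x[(x >= p10) & (x <= p90)]
    robust_mad = float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0
    probs = _histogram_probabilities(x, n_bins)
    entropy = float(-np.sum(probs * np.log2(probs)))
    uniformity = float(np.sum(probs**2))
    cv = sd / abs(mean) if mean != 0 else 0.0
    qcd = (p75 - p25) / (p75 + p25) if (p75 + p25) != 0 else 0.0
    return {
        "fo_mean": mean,
        "fo_median": median,
        "fo_minimum": float(x.min()),
        "fo_maximum": float(x.max()),
        "fo_range": float(x.max() - x.min()),
        "fo_percentile10": p10,
        "fo_percentile25": p25,
        "fo_percentile75": p75,
        "fo_percentile90": p90,
        "fo_interquartile_range": p75 - p25,
        "fo_variance": var,
        "fo_standard_deviation": sd,
        "fo_skewness": skew,
        "fo_kurtosis": kurt,
        "fo_energy": energy,
        "fo_total_energy": voi.voxel_volume_mm3 * energy,
        "fo_root_mean_square": float(np.sqrt(energy / n)),
        "fo_mean_absolute_deviation": float(np.mean(np.abs(centered))),
        "fo_robust_mean_absolute_deviation": robust_mad,
        "fo_median_absolute_deviation": float(np.median(np.abs(x - median))),
        "fo_entropy": entropy,
        "fo_uniformity": uniformity,
        "fo_coefficient_of_variation": float(cv),
        "fo_quartile_coefficient_of_dispersion": float(qcd),
    }
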