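"""Spatial Shannon entropy (SSE) of a parameter's distribution over ROIs.

A local-activation parameter evaluated on the 68 cortical regions of
interest yields a map of 68 values.  Its SSE is the normalized Shannon
entropy of the histogram of those values: a parameter that is uniform
across the cortex (delta-like value distribution) gives SSE near 0, while a
parameter with a wide, evenly spread range of values (uniform distribution)
gives SSE near 1.  Two maps with identical means can therefore have very
different SSEs — the measure captures spatial heterogeneity, not level.

Bin edges are equal-width over the per-map min-max (affine-equivariant, so
the SSE is invariant to adding a constant to, or positively rescaling, the
map).  The bin count (default 8) is a reporting-relevant choice and should
accompany any SSE value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError

__all__ = ["SpatialEntropyConfig", "spatial_shannon_entropy", "sse_name"]


@dataclass(frozen=True)
class SpatialEntropyConfig:
    """Histogram settings for the SSE.

    n_bins:
        number of equal-width bins over the map's min-max range (default 8,
        roughly the square root of 68 rounded to a power of two).
    """

    n_bins: int = 8

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ConfigurationError("n_bins must be >= 2")


def sse_name(parameter: str) -> str:
    """Column name for the SSE of a parameter, e.g. ``S(IAF)``."""
    return f"S({parameter})"


def spatial_shannon_entropy(
    roi_values: np.ndarray, config: SpatialEntropyConfig = SpatialEntropyConfig()
) -> float:
    """Normalized entropy of the ROI-value histogram; in [0, 1].

    The final bin is right-closed (numpy histogram convention) so the
    maximum value is counted.  A degenerate map (max == min) is the
    delta-distribution limit and returns 0 by definition.
    """
    x = np.asarray(roi_values, dtype=float).ravel()
    if x.size < 2:
        raise InputError(f"SSE needs at least 2 ROI values (n={x.size})")
    if not np.all(np.isfinite(x)):
        raise InputError("ROI values must be finite")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return 0.0
    counts, _ = np.histogram(x, bins=config.n_bins, range=(lo, hi))
    p = counts / counts.sum()
    nz = p[p > 0]
    h = -np.sum(nz * np.log(nz))
    return float(h / np.log(config.n_bins))
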