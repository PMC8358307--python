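"""Non-linear local-activation parameters of a single epoch.

Three complementary measures are provided:

* **Lempel-Ziv complexity (LZC)** — the signal is binarized around its median
  and parsed with the LZ76 scheme; the parsing count ``c(n)`` is normalized
  as ``c(n) * log2(n) / n`` so that a random binary sequence tends to 1.
* **Sample entropy (SampEn)** — the negative log conditional probability that
  two sequences matching for ``m`` points (Chebyshev distance within
  ``r = r_factor * std``) also match for ``m + 1`` points; self-matches are
  excluded.  Defaults ``m = 1``, ``r = 0.25 * std``.
* **Central tendency measure (CTM)** — the fraction of points of the
  second-order difference diagram falling inside a circle of given radius
  (default 0.025).  The epoch is divided by its standard deviation before
  differencing so the radius is scale-free.

All three are invariant to amplitude scaling of the epoch: SampEn through
the std-proportional tolerance, CTM through the normalization, and LZC
through the median threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DegenerateSignalError, InputError

__all__ = [
    "NonlinearConfig",
    "lz76_complexity",
    "lempel_ziv_complexity",
    "sample_entropy",
    "central_tendency_measure",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NonlinearConfig:
    """Constants for the non-linear parameters.

    sampen_m:
        template length for sample entropy (sequences of ``m`` samples).
    sampen_r_factor:
        tolerance as a multiple of the epoch standard deviation.
    ctm_radius:
        radius of the central-tendency circle, on the std-normalized scale.
    lzc_threshold:
        binarization rule for LZC: ``"median"`` or ``"mean"``.
    """

    sampen_m: int = 1
    sampen_r_factor: float = 0.25
    ctm_radius: float = 0.025
    lzc_threshold: str = "median"

    def __post_init__(self) -> None:
        if self.sampen_m < 1:
            raise ConfigurationError("sampen_m must be >= 1")
        if self.sampen_r_factor <= 0:
            raise ConfigurationError("sampen_r_factor must be > 0")
        if self.ctm_radius <= 0:
            raise ConfigurationError("ctm_radius must be > 0")
        if self.lzc_threshold not in ("median", "mean"):
            raise ConfigurationError("lzc_threshold must be 'median' or 'mean'")


def lz76_complexity(bits) -> int:
    """LZ76 parsing count ``c(n)`` of a binary sequence.

    Scans left to right, extending the current phrase while it can be copied
    from the already-seen prefix, and starts a new phrase when it cannot
    (Lempel-Ziv 1976 exhaustive-history parsing).
    """
    s = "".join("1" if int(b) else "0" for b in bits)
    n = len(s)
    if n == 0:
        raise InputError("empty sequence")
    c = 1
    k = 1  # current extension length
    l = 1  # phrase start within the scan
    while l + k <= n:
        # does s[l : l+k] occur within s[i : l+k-1]?
        if s[l : l + k] in s[: l + k - 1]:
            k += 1
        else:
            c += 1
            l += k
            k = 1
    if k > 1:
        c += 1
    return c


def _binarize(x: np.ndarray, rule: str) -> np.ndarray:
    thr = np.median(x) if rule == "median" else np.mean(x)
    return (x > thr).astype(np.uint8)


def lempel_ziv_complexity(
    epoch: np.ndarray, config: NonlinearConfig = NonlinearConfig()
) -> float:
    """Normalized LZC ``c(n) * log2(n) / n`` of the binarized epoch."""
    x = np.asarray(epoch, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise InputError(f"LZC needs at least 2 samples (n={n})")
    bits = _binarize(x, config.lzc_threshold)
    c = lz76_complexity(bits)
    return float(c * np.log2(n) / n)


def _chebyshev_match_matrix(x: np.ndarray, r: float) -> np.ndarray:
    """Boolean matrix D[i, j] = |x_i - x_j| <= r, built in row blocks."""
    n = x.size
    out = np.empty((n, n), dtype=bool)
    block = max(1, int(4e6 // max(n, 1)))
    for start in range(0, n, block):
        stop = min(start + block, n)
        out[start:stop] = np.abs(x[start:stop, None] - x[None, :]) <= r
    return out


def sample_entropy(
    epoch: np.ndarray, config: NonlinearConfig = NonlinearConfig()
) -> float:
    """SampEn(m, r) of the epoch; ``nan`` when no (m+1)-template matches.

    Counts pairs of matching templates of lengths ``m`` and ``m + 1`` over
    the first ``n - m`` template positions (self-matches excluded) and
    returns ``-log(A / B)``.  A zero match count makes the entropy undefined;
    such epochs return ``nan`` and are reported with a logged warning so the
    caller can exclude them from epoch averaging.
    """
    x = np.asarray(epoch, dtype=float).ravel()
    m = config.sampen_m
    n = x.size
    if n < m + 2:
        raise InputError(f"SampEn needs at least m+2={m + 2} samples (n={n})")
    sd = float(np.std(x))
    if sd == 0:
        raise DegenerateSignalError("constant epoch: SampEn undefined")
    r = config.sampen_r_factor * sd

    d = _chebyshev_match_matrix(x, r)
    t = n - m  # number of (m+1)-templates; m-templates restricted to the same range
    match = d[:t, :t].copy()
    for offset in range(1, m):
        match &= d[offset : offset + t, offset : offset + t]
    b = (int(match.sum()) - t) // 2
    match &= d[m : m + t, m : m + t]
    a = (int(match.sum()) - t) // 2
    if a == 0 or b == 0:
        logger.warning(
            "SampEn undefined (A=%d, B=%d) for epoch of n=%d; returning nan", a, b, n
        )
        return float("nan")
    return float(-np.log(a / b))


def central_tendency_measure(
    epoch: np.ndarray, config: NonlinearConfig = NonlinearConfig()
) -> float:
    """Fraction of second-order difference points within ``ctm_radius``.

    Points are ``(x[i+1] - x[i], x[i+2] - x[i+1])`` for the std-normalized
    epoch; a constant epoch places every point at the origin and returns 1.
    """
    x = np.asarray(epoch, dtype=float).ravel()
    n = x.size
    if n < 3:
        raise InputError(f"CTM needs at least 3 samples (n={n})")
    sd = float(np.std(x))
    if sd > 0:
        x = x / sd
    d1 = np.diff(x)
    u, v = d1[:-1], d1[1:]
    inside = (u * u + v * v) < config.ctm_radius**2
    return float(np.mean(inside))
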