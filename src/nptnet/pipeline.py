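"""Per-epoch feature extraction and subject-level aggregation.

Order of operations, per subject and session:

1. zero-phase FIR filtering of every epoch (1-70 Hz band-pass and a
   49-51 Hz band-stop against line noise);
2. per epoch and ROI, the 13 local-activation parameters: six relative
   powers, MF, IAF, SE, SEF from the Blackman-Tukey PSDn, and LZC, SampEn,
   CTM from the time series;
3. epoch-averaging within each ROI (parameters are epoch statistics, so
   derived values — not PSDs — are averaged);
4. subject level: the mean over ROIs and the spatial Shannon entropy of the
   68 ROI values, for each parameter (13 means + 13 SSEs = 26 values).

Degenerate epochs (zero variance, or an undefined SampEn) are skipped with
a logged count, never imputed; an ROI whose epochs are all degenerate
raises naming the subject and ROI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .errors import ExtractionError
from .nonlinear import (
    NonlinearConfig,
    central_tendency_measure,
    lempel_ziv_complexity,
    sample_entropy,
)
from .spatial import SpatialEntropyConfig, spatial_shannon_entropy, sse_name
from .spectral import (
    CANONICAL_BANDS,
    blackman_tukey_psd,
    individual_alpha_frequency,
    median_frequency,
    relative_power,
    spectral_edge_frequency,
    spectral_entropy,
)
from .synthetic import RoiEpochArray
from .tables import PARAMETERS, ParameterTable, assemble_parameter_table  # noqa: F401

__all__ = [
    "FeatureConfig",
    "fir_preprocess",
    "extract_roi_features",
    "summarize_subject",
    "assemble_parameter_table",
    "ParameterTable",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureConfig:
    """Settings of the extraction stage.

    band_pass / band_stop:
        FIR passband limits and line-noise stopband, in Hz.
    n_taps:
        FIR length; the default (2001 at 1 kHz, scaled by sampling rate and
        capped below the epoch length) gives > 40 dB stopband attenuation
        after the forward-backward (zero-phase) pass.
    max_lag_fraction:
        Blackman-Tukey maximum lag as a fraction of the epoch length.
    """

    band_pass: tuple[float, float] = (1.0, 70.0)
    band_stop: tuple[float, float] = (49.0, 51.0)
    n_taps: int | None = None
    max_lag_fraction: float = 0.2
    nonlinear: NonlinearConfig = field(default_factory=NonlinearConfig)
    sse: SpatialEntropyConfig = field(default_factory=SpatialEntropyConfig)
    preprocess: bool = True


def _default_taps(fs: float, n_samples: int) -> int:
    taps = int(round(1001 * fs / 1000.0))
    taps = min(taps, max(n_samples // 3, 9))
    return taps if taps % 2 == 1 else taps + 1


def fir_preprocess(
    values: np.ndarray,
    sampling_rate: float,
    band_pass: tuple[float, float] = (1.0, 70.0),
    band_stop: tuple[float, float] = (49.0, 51.0),
    n_taps: int | None = None,
    edge_trim: bool = True,
) -> np.ndarray:
    """Zero-phase FIR band-pass + band-stop along the last axis.

    Hamming-window FIR filters applied with ``filtfilt`` (zero phase, which
    also squares the stopband attenuation).  The band-stop design edges are
    widened by the filter's transition width so the requested band is fully
    inside the realized stopband, not in its transition skirts.  With
    ``edge_trim`` (the default) half a filter length is discarded from each
    end of every epoch: a narrowband FIR rings for about its own length
    around the epoch boundaries, and no padding strategy removes that
    transient, so the standard remedy is to drop the affected samples.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[-1]
    taps = n_taps or _default_taps(sampling_rate, n)
    padlen = min(3 * taps, n - 1)
    bp = sp_signal.firwin(taps, band_pass, fs=sampling_rate, pass_zero=False)
    out = sp_signal.filtfilt(bp, [1.0], values, axis=-1, padlen=padlen)
    if band_stop is not None:
        trans = 3.3 * sampling_rate / taps
        lo = max(band_stop[0] - trans / 2, 0.1)
        hi = min(band_stop[1] + trans / 2, sampling_rate / 2 - 0.1)
        bs = sp_signal.firwin(taps, (lo, hi), fs=sampling_rate, pass_zero="bandstop")
        out = sp_signal.filtfilt(bs, [1.0], out, axis=-1, padlen=padlen)
    if edge_trim:
        trim = taps // 2
        if n - 2 * trim >= max(32, n // 2):
            out = out[..., trim : n - trim]
    return out


def _epoch_features(epoch: np.ndarray, fs: float, config: FeatureConfig) -> dict[str, float]:
    spectrum = blackman_tukey_psd(epoch, fs, max_lag_fraction=config.max_lag_fraction)
    feats = {f"RP({b.name})": relative_power(spectrum, b) for b in CANONICAL_BANDS}
    feats["MF"] = median_frequency(spectrum)
    feats["IAF"] = individual_alpha_frequency(spectrum)
    feats["SE"] = spectral_entropy(spectrum)
    feats["SEF"] = spectral_edge_frequency(spectrum)
    feats["LZC"] = lempel_ziv_complexity(epoch, config.nonlinear)
    feats["SampEn"] = sample_entropy(epoch, config.nonlinear)
    feats["CTM"] = central_tendency_measure(epoch, config.nonlinear)
    return feats


def extract_roi_features(
    signals: RoiEpochArray, config: FeatureConfig = FeatureConfig()
) -> pd.DataFrame:
    """ROIs x 13 parameters, epoch-averaged; index = ROI number.

    Parameters are computed per epoch per ROI and averaged over epochs.
    Zero-variance epochs are skipped (logged count); NaN parameter values
    (undefined SampEn) are excluded from that parameter's average only.
    """
    values = signals.values
    if config.preprocess:
        values = fir_preprocess(
            values, signals.sampling_rate, config.band_pass, config.band_stop,
            config.n_taps,
        )
    n_epochs, n_rois, _ = values.shape
    skipped = 0
    rows = []
    for roi in range(n_rois):
        per_epoch = []
        for epoch in range(n_epochs):
            x = values[epoch, roi]
            if np.ptp(x) == 0:
                skipped += 1
                continue
            per_epoch.append(_epoch_features(x, signals.sampling_rate, config))
        if not per_epoch:
            raise ExtractionError(
                f"all epochs degenerate for subject {signals.subject_id}, ROI {roi}"
            )
        frame = pd.DataFrame(per_epoch)
        rows.append(frame.mean(axis=0, skipna=True))
    if skipped:
        logger.warning(
            "skipped %d degenerate epochs for subject %s/%s",
            skipped, signals.subject_id, signals.session,
        )
    out = pd.DataFrame(rows, index=pd.RangeIndex(n_rois, name="roi"))
    return out[list(PARAMETERS)]


def summarize_subject(
    features: pd.DataFrame, sse_config: SpatialEntropyConfig = SpatialEntropyConfig()
) -> pd.Series:
    """Collapse the ROI dimension: per parameter, the ROI mean and the SSE."""
    out: dict[str, float] = {}
    for param in features.columns:
        roi_values = features[param].to_numpy(dtype=float)
        out[param] = float(np.mean(roi_values))
        out[sse_name(param)] = spatial_shannon_entropy(roi_values, sse_config)
    return pd.Series(out)
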