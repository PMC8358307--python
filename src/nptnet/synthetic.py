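"""Synthetic cohorts with the statistical structure the analysis assumes.

A single latent *severity* scalar per subject and session drives everything:

* clinical scores — MMSE decreases and DBD-13 increases with severity
  (monotone affine maps plus noise, rounded and clipped to their ranges);
* oscillatory signals — higher severity raises delta/theta band amplitudes,
  lowers beta amplitudes, and steepens the 1/f background (more regular,
  slower activity), mirroring the oscillatory slowing seen in dementia;
* the fast table path — draws the 26 subject-level neurophysiological
  variables directly from the same severity couplings, skipping signal
  synthesis, so network-level simulations run in milliseconds.

Treatment is modelled as a severity *improvement* between sessions whose
size correlates (negatively, by default) with baseline severity: milder
baseline alteration responds better, the regime the prediction network is
designed to detect.

Planted-structure helpers build tables in which one chosen pair of columns
carries an exact Spearman correlation via a Gaussian copula
(``r = 2 sin(pi * rho / 6)``); they are the ground truth for the recovery
and variability-detection simulations.

Determinism: every entity (subject, session, table) derives its own seed by
hashing ``(seed, subject_id, session)``, so cohorts, signals and tables are
bit-identical under a fixed configuration regardless of generation order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .spatial import sse_name
from .tables import ANALYSIS_VARIABLES, PARAMETERS, ParameterTable, session_column

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "RoiEpochArray",
    "DEFAULT_COUPLING",
    "sample_cohort",
    "synthesize_roi_signals",
    "emulate_parameter_table",
    "null_config",
    "planted_prediction_table",
    "planted_change_table",
]

_BAND_KEYS = ("delta", "theta", "alpha", "beta1", "beta2", "gamma")

#: signed effect of one standard deviation of severity on each signal
#: property (``amp_*``: band oscillation amplitudes, ``spectral_slope``: the
#: 1/f exponent) and on each subject-level variable of the fast table path.
DEFAULT_COUPLING: dict[str, float] = {
    # signal-model properties
    "amp_delta": 0.35,
    "amp_theta": 0.20,
    "amp_alpha": -0.10,
    "amp_beta1": -0.15,
    "amp_beta2": -0.12,
    "amp_gamma": -0.05,
    "spectral_slope": 0.30,
    # clinical scores (per severity sd, on the score scale)
    "MMSE": -5.4,
    "DBD-13": 3.0,
    # fast-path couplings of the 26 subject-level variables
    "RP(Delta)": 0.06,
    "RP(Theta)": 0.035,
    "RP(Alpha)": -0.025,
    "RP(Beta1)": -0.035,
    "RP(Beta2)": -0.03,
    "RP(Gamma)": -0.015,
    "MF": -1.8,
    "IAF": -0.7,
    "SE": -0.05,
    "SEF": -5.0,
    "LZC": -0.07,
    "SampEn": -0.18,
    "CTM": 0.10,
    **{sse_name(p): -0.04 for p in PARAMETERS},
}

#: baseline level and residual noise sd of each fast-path variable
_TABLE_MODEL: dict[str, tuple[float, float]] = {
    "RP(Delta)": (0.24, 0.04),
    "RP(Theta)": (0.18, 0.03),
    "RP(Alpha)": (0.20, 0.035),
    "RP(Beta1)": (0.13, 0.025),
    "RP(Beta2)": (0.11, 0.025),
    "RP(Gamma)": (0.14, 0.03),
    "MF": (8.0, 1.2),
    "IAF": (9.0, 0.6),
    "SE": (0.76, 0.04),
    "SEF": (24.0, 3.5),
    "LZC": (0.42, 0.05),
    "SampEn": (1.10, 0.12),
    "CTM": (0.50, 0.07),
    **{sse_name(p): (0.72, 0.05) for p in PARAMETERS},
}

_TABLE_CLIP: dict[str, tuple[float, float]] = {
    **{f"RP({b})": (1e-3, 1 - 1e-3) for b in ("Delta", "Theta", "Alpha", "Beta1", "Beta2", "Gamma")},
    "MF": (1.0, 70.0),
    "IAF": (4.0, 15.0),
    "SE": (0.0, 1.0),
    "SEF": (1.0, 70.0),
    "LZC": (0.0, np.inf),
    "SampEn": (0.0, np.inf),
    "CTM": (0.0, 1.0),
    **{sse_name(p): (0.0, 1.0) for p in PARAMETERS},
}

_BASE_AMP = {
    "delta": 1.0,
    "theta": 0.8,
    "alpha": 1.0,
    "beta1": 0.5,
    "beta2": 0.4,
    "gamma": 0.25,
}
_BAND_RANGES = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta1": (13.0, 19.0),
    "beta2": (19.0, 30.0),
    "gamma": (30.0, 70.0),
}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the clinical setting the pipeline targets: 19 subjects,
    68 cortical ROIs, 1 kHz sampling, 5-s epochs, and score distributions
    centred near MMSE 14.5 and DBD-13 10.5 with a mean treatment improvement
    of 0.35 severity standard deviations.  The epoch count per session is
    not dictated by the recording protocol; 12 is a configurable default.
    """

    n_subjects: int = 19
    n_rois: int = 68
    sampling_rate: float = 1000.0
    epoch_seconds: float = 5.0
    n_epochs: int = 12
    severity_mean: float = 0.0
    severity_sd: float = 1.0
    coupling: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COUPLING))
    treatment_effect_mean: float = 0.35
    treatment_effect_sd: float = 0.30
    response_coupling: float = -0.5
    spatial_heterogeneity: float = 0.5
    score_noise_sd: float = 2.0
    mmse_base: float = 14.5
    dbd_base: float = 10.5
    dbd_trait_sd: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_rois", "n_epochs"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        n_samples = self.epoch_seconds * self.sampling_rate
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise ConfigurationError("epoch_seconds * sampling_rate must be an integer")
        if not 0.0 <= self.spatial_heterogeneity <= 1.0:
            raise ConfigurationError("spatial_heterogeneity must be in [0, 1]")
        if self.severity_sd <= 0:
            raise ConfigurationError("severity_sd must be > 0")
        if not 0.0 <= self.mmse_base <= 30.0:
            raise ConfigurationError("mmse_base must lie in the MMSE range [0, 30]")
        if not 0.0 <= self.dbd_base <= 52.0:
            raise ConfigurationError("dbd_base must lie in the DBD-13 range [0, 52]")
        if not -1.0 <= self.response_coupling <= 1.0:
            raise ConfigurationError("response_coupling must be in [-1, 1]")
        if self.score_noise_sd < 0 or self.treatment_effect_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_seconds * self.sampling_rate))


@dataclass(frozen=True)
class SubjectRecord:
    """Latent severity, covariates and clinical scores for one subject."""

    subject_id: str
    age: float
    gender: str  # "M" or "F"
    severity_pre: float
    severity_post: float
    mmse_pre: int
    mmse_post: int
    dbd_pre: int
    dbd_post: int


@dataclass
class RoiEpochArray:
    """Per subject/session time series: epochs x ROIs x samples."""

    values: np.ndarray
    sampling_rate: float
    subject_id: str
    session: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ConfigurationError("values must be epochs x ROIs x samples")
        if not np.all(np.isfinite(v)):
            raise ConfigurationError("signal values must be finite")
        self.values = v


def _entity_seed(seed: int, *parts: object) -> int:
    """Deterministic sub-seed from (seed, parts), below 2**31."""
    key = "|".join([str(seed), *map(str, parts)]).encode()
    return int.from_bytes(hashlib.blake2b(key, digest_size=4).digest(), "big") % (2**31)


def _score(base: float, slope: float, severity_z: float, noise: float,
           lo: float, hi: float) -> int:
    return int(np.clip(np.round(base + slope * severity_z + noise), lo, hi))


def sample_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Draw the cohort: covariates, latent severities, and pre/post scores.

    Scores are monotone affine transforms of the session's severity plus
    noise, rounded to integers and clipped to the test range; DBD-13 carries
    an additional stable per-subject trait so its cross-sectional spread can
    exceed its treatment-related change.  Severity improves between sessions
    by a draw whose correlation with baseline severity is
    ``response_coupling``.
    """
    rng = np.random.default_rng(_entity_seed(config.seed, "cohort"))
    records = []
    rc = config.response_coupling
    for i in range(config.n_subjects):
        subject_id = f"S{i + 1:03d}"
        age = float(np.clip(rng.normal(86.0, 3.86), 65.0, 100.0))
        gender = "M" if rng.random() < 7 / 19 else "F"
        z = rng.standard_normal()  # standardized baseline severity
        sev_pre = config.severity_mean + config.severity_sd * z
        improvement = config.treatment_effect_mean + config.treatment_effect_sd * (
            rc * z + np.sqrt(max(0.0, 1 - rc**2)) * rng.standard_normal()
        )
        sev_post = sev_pre - improvement * config.severity_sd
        z_post = (sev_post - config.severity_mean) / config.severity_sd

        c = config.coupling
        noise = rng.normal(0.0, config.score_noise_sd, size=4)
        trait = rng.normal(0.0, config.dbd_trait_sd)
        records.append(
            SubjectRecord(
                subject_id=subject_id,
                age=age,
                gender=gender,
                severity_pre=float(sev_pre),
                severity_post=float(sev_post),
                mmse_pre=_score(config.mmse_base, c.get("MMSE", 0.0), z, noise[0], 0, 30),
                mmse_post=_score(config.mmse_base, c.get("MMSE", 0.0), z_post, noise[1], 0, 30),
                dbd_pre=_score(config.dbd_base + trait, c.get("DBD-13", 0.0), z, noise[2], 0, 52),
                dbd_post=_score(config.dbd_base + trait, c.get("DBD-13", 0.0), z_post, noise[3], 0, 52),
            )
        )
    return records


def _one_over_f_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-variance noise with amplitude spectrum proportional to f^(-chi/2)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    f[0] = f[1]  # avoid the DC singularity; DC is removed below anyway
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def synthesize_roi_signals(
    record: SubjectRecord, session: str, config: CohortConfig
) -> RoiEpochArray:
    """Band-limited oscillations on a 1/f background, coupled to severity.

    Each ROI trace is a sum over the six canonical bands of a sinusoid with
    a frequency drawn inside the band, plus unit-variance 1/f^chi noise.
    Severity shifts the band amplitudes (more delta/theta, less beta) and
    steepens chi (lower irregularity).  ROI-to-ROI dispersion of the band
    amplitudes is a log-normal factor scaled by ``spatial_heterogeneity``;
    at zero heterogeneity all ROIs share identical amplitudes.
    """
    if session not in ("pre", "post"):
        raise ConfigurationError(f"unknown session {session!r}")
    sev = record.severity_pre if session == "pre" else record.severity_post
    z = (sev - config.severity_mean) / config.severity_sd
    rng = np.random.default_rng(_entity_seed(config.seed, record.subject_id, session))
    n, fs = config.n_samples, config.sampling_rate
    t = np.arange(n) / fs
    c = config.coupling

    amps = {
        b: max(_BASE_AMP[b] + c.get(f"amp_{b}", 0.0) * z, 0.05) for b in _BAND_KEYS
    }
    chi = max(1.0 + c.get("spectral_slope", 0.0) * z, 0.1)
    # per-ROI log-normal amplitude dispersion, one factor per ROI and band
    roi_dev = rng.normal(0.0, 0.4, size=(config.n_rois, len(_BAND_KEYS)))
    roi_factor = np.exp(config.spatial_heterogeneity * roi_dev)

    out = np.empty((config.n_epochs, config.n_rois, n))
    for epoch in range(config.n_epochs):
        for roi in range(config.n_rois):
            trace = np.zeros(n)
            for bi, band in enumerate(_BAND_KEYS):
                lo, hi = _BAND_RANGES[band]
                freq = rng.uniform(lo, hi)
                phase = rng.uniform(0, 2 * np.pi)
                trace += amps[band] * roi_factor[roi, bi] * np.sin(
                    2 * np.pi * freq * t + phase
                )
            trace += _one_over_f_noise(rng, n, chi)
            out[epoch, roi] = trace
    return RoiEpochArray(out, fs, record.subject_id, session)


def emulate_parameter_table(config: CohortConfig) -> ParameterTable:
    """Fast path: draw the 26 subject-level variables straight from the model.

    Skips signal synthesis but keeps the same coupling signs, so network
    simulations remain statistically consistent with the signal path.  The
    six relative-power columns are drawn independently (no renormalization
    to unit sum): the fast path models the statistical structure of the
    table, not the physical sum constraint, which keeps zero-coupling tables
    exactly column-independent for null calibration.
    """
    records = sample_cohort(config)
    rng = np.random.default_rng(_entity_seed(config.seed, "table"))
    c = config.coupling
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "Subject": rec.subject_id,
            "Age": rec.age,
            "Gender": 1.0 if rec.gender == "M" else 0.0,
        }
        for session in ("pre", "post"):
            sev = rec.severity_pre if session == "pre" else rec.severity_post
            z = (sev - config.severity_mean) / config.severity_sd
            for var, (base, noise_sd) in _TABLE_MODEL.items():
                lo, hi = _TABLE_CLIP[var]
                value = base + c.get(var, 0.0) * z + rng.normal(0.0, noise_sd)
                row[session_column(var, session)] = float(np.clip(value, lo, hi))
            row[session_column("MMSE", session)] = float(
                rec.mmse_pre if session == "pre" else rec.mmse_post
            )
            row[session_column("DBD-13", session)] = float(
                rec.dbd_pre if session == "pre" else rec.dbd_post
            )
        rows.append(row)
    return ParameterTable(pd.DataFrame(rows))


def null_config(n_subjects: int = 19, seed: int = 0, **overrides) -> CohortConfig:
    """A configuration with every coupling set to zero (independent columns)."""
    coupling = {k: 0.0 for k in DEFAULT_COUPLING}
    return CohortConfig(
        n_subjects=n_subjects,
        coupling=coupling,
        treatment_effect_mean=0.0,
        treatment_effect_sd=0.0,
        response_coupling=0.0,
        dbd_trait_sd=0.0,
        seed=seed,
        **overrides,
    )


def _copula_pair(rng: np.random.Generator, n: int, rho_spearman: float) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate normal with Pearson r chosen so the Spearman rho is exact."""
    r = 2.0 * np.sin(np.pi * rho_spearman / 6.0)
    cov = np.array([[1.0, r], [r, 1.0]])
    g = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    return g[:, 0], g[:, 1]


def planted_prediction_table(
    n_subjects: int,
    rho: float,
    seed: int,
    predictor: str = "RP(Beta1)",
) -> ParameterTable:
    """Null table with one planted predictor -> MMSE-change association.

    The pre-treatment ``predictor`` column and the latent MMSE change share
    a Gaussian copula with Spearman correlation ``rho``; every other column
    is independent noise.  Score rounding attenuates the realized rank
    correlation slightly below the nominal value.
    """
    table = emulate_parameter_table(null_config(n_subjects=n_subjects, seed=seed))
    df = table.df.copy()
    rng = np.random.default_rng(_entity_seed(seed, "plant-prediction"))
    g_pred, g_change = _copula_pair(rng, n_subjects, rho)
    base, _ = _TABLE_MODEL[predictor]
    df[session_column(predictor, "pre")] = base + 0.03 * g_pred
    mmse_pre = df[session_column("MMSE", "pre")].to_numpy()
    delta = 2.0 + 1.5 * g_change
    df[session_column("MMSE", "post")] = np.clip(np.round(mmse_pre + delta), 0, 30)
    return ParameterTable(df)


def planted_change_table(
    n_subjects: int,
    rho_pre: float,
    rho_post: float,
    seed: int,
    var_x: str = "RP(Beta1)",
    var_y: str = "MF",
) -> ParameterTable:
    """Null table in which exactly one edge's correlation changes pre -> post.

    ``(var_x, var_y)`` carries Spearman ``rho_pre`` in the pre session and
    ``rho_post`` in the post session; all other pairs are independent in
    both sessions.  Used to probe the variability network's ability to flag
    a treatment-induced change in association structure.
    """
    table = emulate_parameter_table(null_config(n_subjects=n_subjects, seed=seed))
    df = table.df.copy()
    rng = np.random.default_rng(_entity_seed(seed, "plant-change"))
    for session, rho in (("pre", rho_pre), ("post", rho_post)):
        gx, gy = _copula_pair(rng, n_subjects, rho)
        for var, g in ((var_x, gx), (var_y, gy)):
            base, noise_sd = _TABLE_MODEL[var]
            lo, hi = _TABLE_CLIP[var]
            df[session_column(var, session)] = np.clip(base + noise_sd * g, lo, hi)
    return ParameterTable(df)
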