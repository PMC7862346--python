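"""Post-realignment signal conditioning of masked voxel time-series.

Fixed chain (each step optional via config, order never changes):

    motion regression -> spatial smoothing -> FIR band-pass ->
    quadratic detrend -> unit-variance normalization -> transient trim

Global-signal regression is intentionally not performed.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter

from .config import ConfigurationError, DegenerateInputError, PreprocessConfig
from .synthetic import SubjectRecording

log = logging.getLogger(__name__)

__all__ = [
    "regress_nuisance",
    "smooth_spatial",
    "bandpass_filter",
    "detrend_quadratic",
    "normalize_and_trim",
    "preprocess_recording",
]


def regress_nuisance(
    recording: SubjectRecording, regressors: Optional[np.ndarray] = None
) -> SubjectRecording:
    """Regress nuisance time-courses (e.g. the six motion parameters) out.

    Each voxel series is replaced by the residual of an ordinary
    least-squares fit on [intercept | regressors]; residuals are exactly
    orthogonal to every regressor column.  With no regressors the fit is
    intercept-only, i.e. mean-centering.
    """
    T = recording.n_frames
    if regressors is None:
        regressors = recording.motion_regressors
    if regressors is None:
        X = np.ones((T, 1))
    else:
        regressors = np.asarray(regressors, dtype=float)
        if regressors.shape[0] != T:
            raise ValueError(
                f"regressor table has {regressors.shape[0]} rows, expected {T}"
            )
        X = np.column_stack([np.ones(T), regressors])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DegenerateInputError("nuisance regressor matrix is rank-deficient")
    beta, *_ = np.linalg.lstsq(X, recording.frames, rcond=None)
    resid = recording.frames - X @ beta
    return recording.replace_frames(resid)


def smooth_spatial(
    recording: SubjectRecording,
    sigma_pixels: float,
    mask: Optional[np.ndarray] = None,
) -> SubjectRecording:
    """Per-frame 2D Gaussian smoothing restricted to in-mask voxels.

    Uses a mask-normalized kernel: smooth(x*m)/smooth(m) evaluated inside
    the mask, so spatially constant images are preserved and no off-mask
    zeros bleed in.  sigma 0 is the identity.
    """
    if sigma_pixels < 0:
        raise ConfigurationError("smoothing sigma must be >= 0")
    if sigma_pixels == 0:
        return recording.replace_frames(recording.frames.copy())
    mask = recording.mask if mask is None else mask
    m = mask.astype(float)
    msm = gaussian_filter(m, sigma_pixels, mode="constant")[mask]
    out = np.empty_like(recording.frames)
    img = np.zeros(mask.shape)
    for t in range(recording.n_frames):
        img[:] = 0.0
        img[mask] = recording.frames[t]
        sm = gaussian_filter(img, sigma_pixels, mode="constant")
        out[t] = sm[mask] / msm
    return recording.replace_frames(out)


def design_bandpass_fir(
    band_low_hz: float,
    band_high_hz: float,
    tr_seconds: float,
    n_frames: int,
    fir_order: Optional[int] = None,
) -> np.ndarray:
    """Windowed-sinc (Hamming) linear-phase band-pass taps.

    Default order is 4x the sample count of the slowest passband period,
    capped so that zero-phase (forward-backward) application remains
    valid for the series length; the number of taps is forced odd
    (type-I FIR) so the band-pass has no inherent delay ambiguity.
    """
    fs = 1.0 / tr_seconds
    if not (0.0 < band_low_hz < band_high_hz < fs / 2.0):
        raise ConfigurationError(
            f"band ({band_low_hz}, {band_high_hz}) Hz outside (0, Nyquist={fs/2})"
        )
    if fir_order is None:
        slowest_period_samples = int(round(fs / band_low_hz))
        numtaps = 4 * slowest_period_samples + 1
    else:
        numtaps = int(fir_order) + 1
    cap = (n_frames - 2) // 3  # filtfilt needs padlen < T
    numtaps = min(numtaps, cap)
    if numtaps % 2 == 0:
        numtaps -= 1
    if numtaps < 9:
        raise ConfigurationError("series too short for the requested FIR band-pass")
    return signal.firwin(
        numtaps, [band_low_hz, band_high_hz], pass_zero=False, fs=fs, window="hamming"
    )


def bandpass_filter(
    recording: SubjectRecording, config: PreprocessConfig
) -> SubjectRecording:
    """Zero-phase FIR band-pass of every voxel series."""
    config.validate_against_tr(recording.tr_seconds)
    taps = design_bandpass_fir(
        config.band_low_hz,
        config.band_high_hz,
        recording.tr_seconds,
        recording.n_frames,
        config.fir_order,
    )
    padlen = min(3 * len(taps), recording.n_frames - 2)
    out = signal.filtfilt(taps, [1.0], recording.frames, axis=0, padlen=padlen)
    return recording.replace_frames(out)


def detrend_quadratic(recording: SubjectRecording) -> SubjectRecording:
    """Subtract the per-voxel least-squares quadratic trend a + b t + c t^2."""
    T = recording.n_frames
    t = np.arange(T, dtype=float)
    t = (t - t.mean()) / max(t.std(), 1.0)  # conditioning only; same fit space
    X = np.column_stack([np.ones(T), t, t**2])
    beta, *_ = np.linalg.lstsq(X, recording.frames, rcond=None)
    return recording.replace_frames(recording.frames - X @ beta)


def normalize_and_trim(
    recording: SubjectRecording, config: PreprocessConfig
) -> SubjectRecording:
    """Trim transient frames and scale every voxel series to unit variance.

    Zero-variance voxels are left at zero (and counted in the log) rather
    than producing NaNs.  Variance here is the population variance
    (ddof 0) of the trimmed series.
    """
    lo, hi = int(config.n_trim_start), int(config.n_trim_end)
    T = recording.n_frames
    if T - lo - hi < 2:
        raise ConfigurationError(
            f"trimming {lo}+{hi} frames leaves nothing of a {T}-frame series"
        )
    frames = recording.frames[lo : T - hi]
    if config.zscore:
        frames = frames - frames.mean(axis=0)
        sd = frames.std(axis=0, ddof=0)
        flat = sd == 0
        if flat.any():
            log.warning("%d zero-variance voxels left at zero", int(flat.sum()))
        sd[flat] = 1.0
        frames = frames / sd
    return recording.replace_frames(frames, trim=(lo, hi))


def preprocess_recording(
    recording: SubjectRecording, config: Optional[PreprocessConfig] = None
) -> SubjectRecording:
    """Run the full conditioning chain in its fixed order."""
    config = config or PreprocessConfig()
    config.validate_against_tr(recording.tr_seconds)
    rec = recording
    if config.do_motion_regression and rec.motion_regressors is not None:
        rec = regress_nuisance(rec)
    rec = smooth_spatial(rec, config.smoothing_sigma_pixels)
    rec = bandpass_filter(rec, config)
    rec = detrend_quadratic(rec)
    rec = normalize_and_trim(rec, config)
    if not np.all(np.isfinite(rec.frames)):  # pragma: no cover - safety net
        raise FloatingPointError("preprocessing produced non-finite values")
    return rec
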