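"""Temporal cleaning of BOLD series.

The cleaning recipe follows the common resting-state convention: nuisance
regression with the 24-parameter motion expansion (6 rigid-body parameters,
their backward-difference derivatives, and the squares of both), optional
white-matter / CSF / global signals with their derivatives, followed by
band-pass filtering to 0.01-0.1 Hz. Frame-wise displacement uses the Power
formulation with rotations converted to arc length on a 50 mm sphere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import BoldSeries
from .errors import ParameterError, ShapeError

log = logging.getLogger(__name__)

#: Head radius (mm) used to convert rotations into displacements.
FD_HEAD_RADIUS_MM = 50.0


def _backward_diff(x: np.ndarray) -> np.ndarray:
    """Backward difference along axis 0 with the first element set to 0."""
    d = np.zeros_like(x)
    d[1:] = np.diff(x, axis=0)
    return d


@dataclass
class ConfoundMatrix:
    """Labelled nuisance regressors, one column per regressor."""

    columns: np.ndarray
    labels: list[str]
    rank_deficient: bool = False

    @property
    def n_frames(self) -> int:
        return self.columns.shape[0]


def build_confounds(motion: np.ndarray, wm: np.ndarray | None = None,
                    csf: np.ndarray | None = None,
                    global_sig: np.ndarray | None = None) -> ConfoundMatrix:
    """Assemble the nuisance design from motion and optional tissue signals.

    Six motion parameters expand to 24 columns: the parameters, their
    derivatives, and the squares of both. Each tissue/global signal
    contributes itself plus its derivative.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ShapeError(f"motion must be (frames, 6), got {motion.shape}")
    frames = motion.shape[0]
    dmotion = _backward_diff(motion)
    blocks = [motion, dmotion, motion ** 2, dmotion ** 2]
    labels = (
        [f"motion_{i}" for i in range(6)]
        + [f"motion_d{i}" for i in range(6)]
        + [f"motion_sq{i}" for i in range(6)]
        + [f"motion_dsq{i}" for i in range(6)]
    )
    for name, sig in (("wm", wm), ("csf", csf), ("global", global_sig)):
        if sig is None:
            continue
        sig = np.asarray(sig, dtype=float).reshape(-1)
        if sig.shape[0] != frames:
            raise ShapeError(f"{name} signal has {sig.shape[0]} frames, expected {frames}")
        blocks.append(np.column_stack([sig, _backward_diff(sig[:, None]).ravel()]))
        labels += [name, f"{name}_d"]
    columns = np.column_stack(blocks)
    design = np.column_stack([np.ones(frames), columns])
    deficient = np.linalg.matrix_rank(design) < design.shape[1]
    if deficient:
        log.warning("confound matrix is rank deficient (%d columns)", columns.shape[1])
    return ConfoundMatrix(columns=columns, labels=labels, rank_deficient=deficient)


def regress_confounds(bold: BoldSeries, conf: ConfoundMatrix) -> BoldSeries:
    """Project every voxel time course onto the orthogonal complement of the
    confounds (an intercept is always included)."""
    if conf.n_frames != bold.n_frames:
        raise ShapeError(
            f"confounds have {conf.n_frames} frames, series has {bold.n_frames}")
    X = np.column_stack([np.ones(bold.n_frames), conf.columns])
    Y = np.asarray(bold.data, dtype=float).T  # frames x voxels
    if conf.rank_deficient:
        log.warning("using pseudoinverse for rank-deficient confound design")
        beta = np.linalg.pinv(X) @ Y
    else:
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return bold.with_data(resid.T)


def bandpass(bold: BoldSeries, low_hz: float, high_hz: float,
             design: str = "butter") -> BoldSeries:
    """Zero-phase band-pass filter of every voxel time course.

    ``design='butter'`` applies an order-2 Butterworth forward-backward
    (filtfilt); ``design='fft'`` zeroes Fourier coefficients outside the band,
    which is the ideal-filter dialect used by the synthetic generator.
    """
    nyquist = 0.5 / bold.tr_s
    if not (0 < low_hz < high_hz < nyquist):
        raise ParameterError(
            f"band ({low_hz}, {high_hz}) Hz infeasible for tr={bold.tr_s}s "
            f"(Nyquist {nyquist:.4f} Hz)")
    data = np.asarray(bold.data, dtype=float)
    if design == "butter":
        sos = signal.butter(2, [low_hz, high_hz], btype="band", fs=1.0 / bold.tr_s,
                            output="sos")
        out = signal.sosfiltfilt(sos, data, axis=1)
    elif design == "fft":
        freqs = np.fft.rfftfreq(bold.n_frames, bold.tr_s)
        spec = np.fft.rfft(data, axis=1)
        spec[:, (freqs < low_hz) | (freqs > high_hz)] = 0.0
        out = np.fft.irfft(spec, n=bold.n_frames, axis=1)
    else:
        raise ParameterError(f"unknown filter design '{design}'")
    # a band filter excludes DC; remove the residual sample mean that
    # finite-length zero-phase filtering leaves at the edges
    out = out - out.mean(axis=1, keepdims=True)
    return bold.with_data(out)


def clean(bold: BoldSeries, conf: ConfoundMatrix, low_hz: float, high_hz: float,
          *, filter_design: str = "butter",
          order: str = "regress_then_filter") -> BoldSeries:
    """Full temporal cleaning.

    ``order='regress_then_filter'`` regresses the confounds and then band-pass
    filters (the conventional sequence); ``order='simultaneous'`` projects out
    the confounds and the out-of-band Fourier components in a single joint
    regression, which avoids re-introducing confound leakage through the
    filter.
    """
    if order == "regress_then_filter":
        return bandpass(regress_confounds(bold, conf), low_hz, high_hz,
                        design=filter_design)
    if order == "simultaneous":
        nyquist = 0.5 / bold.tr_s
        if not (0 < low_hz < high_hz < nyquist):
            raise ParameterError("band infeasible for tr")
        frames = bold.n_frames
        freqs = np.fft.rfftfreq(frames, bold.tr_s)
        t = np.arange(frames)
        basis = []
        for f_idx, f in enumerate(freqs):
            if f_idx == 0 or low_hz <= f <= high_hz:
                continue  # DC handled by the intercept; in-band kept
            basis.append(np.cos(2 * np.pi * f * t * bold.tr_s))
            basis.append(np.sin(2 * np.pi * f * t * bold.tr_s))
        extra = np.column_stack(basis) if basis else np.empty((frames, 0))
        joint = ConfoundMatrix(
            columns=np.column_stack([conf.columns, extra]),
            labels=conf.labels + [f"freq_{i}" for i in range(extra.shape[1])],
            rank_deficient=True,  # sine at exactly 0/Nyquist may be null; use pinv
        )
        return regress_confounds(bold, joint)
    raise ParameterError(f"unknown cleaning order '{order}'")


def mean_fd(motion: np.ndarray, head_radius_mm: float = FD_HEAD_RADIUS_MM) -> float:
    """Mean frame-wise displacement (Power): sum of absolute backward
    differences of the three translations (mm) and of the three rotations
    converted to arc length on a ``head_radius_mm`` sphere."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ShapeError(f"motion must be (frames, 6), got {motion.shape}")
    if motion.shape[0] < 2:
        raise ParameterError("mean FD needs at least 2 frames")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return float(fd.mean())
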