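"""Zero-phase signal conditioning used across the pipeline.

The reference pipeline low-pass filters measured force and COP signals with a
zero-phase (forward–backward) Butterworth filter; kinematic position signals
may optionally be smoothed the same way before numerical differentiation.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .errors import ValidationError


def lowpass(x: np.ndarray, cutoff_hz: float, fs: float, order: int = 2, axis: int = 0) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter.

    Parameters
    ----------
    x : array
        Signal, filtered along ``axis``.
    cutoff_hz : float
        Cutoff frequency in Hz; must be below the Nyquist frequency ``fs/2``.
    fs : float
        Sample rate in Hz.
    order : int
        Filter order per pass (the forward–backward application doubles the
        effective order and cancels phase lag).
    """
    if cutoff_hz <= 0:
        raise ValidationError(f"cutoff must be positive, got {cutoff_hz}")
    if cutoff_hz >= fs / 2:
        raise ValidationError(
            f"cutoff {cutoff_hz} Hz is not below the Nyquist frequency {fs / 2} Hz"
        )
    x = np.asarray(x, dtype=float)
    b, a = signal.butter(order, cutoff_hz, btype="low", fs=fs)
    # Gustafsson edge handling makes the forward-backward pass exactly
    # time-reversal symmetric (filtering a reversed signal and reversing
    # gives the same result), unlike signal-extension padding
    return signal.filtfilt(b, a, x, axis=axis, method="gust")


def median_smooth(x: np.ndarray, window: int, axis: int = 0) -> np.ndarray:
    """Running-median smoother with an odd window length.

    A generic utility for impulsive noise (e.g. mains hum spikes); not part of
    the reference prediction pipeline.
    """
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"window must be a positive odd integer, got {window}")
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return signal.medfilt(x, kernel_size=window)
    return np.apply_along_axis(signal.medfilt, axis, x, kernel_size=window)
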