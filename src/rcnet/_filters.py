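"""Zero-phase Butterworth filtering shared by the BOLD and EEG paths.

Band edges are treated as half-power (-3 dB) points of an order-4
Butterworth filter applied forward and backward (``sosfiltfilt``), so the
effective magnitude response is order 8 with zero phase distortion.
"""

from __future__ import annotations

import numpy as np
from scipy import signal


class InvalidBandError(ValueError):
    """Requested pass-band is not realizable at the given sampling rate."""


def butter_sos(low_hz: float, high_hz: float, fs: float, order: int = 4) -> np.ndarray:
    """Design a band-pass (or low-pass when ``low_hz <= 0``) Butterworth filter.

    Parameters
    ----------
    low_hz, high_hz
        Pass-band edges in Hz. ``high_hz`` must lie strictly below the
        Nyquist frequency ``fs / 2``.
    fs
        Sampling rate in Hz.
    order
        Filter order (applied twice by the zero-phase pass).
    """
    nyq = fs / 2.0
    if not np.isfinite(low_hz) or not np.isfinite(high_hz):
        raise InvalidBandError("band edges must be finite")
    if low_hz < 0 or high_hz <= low_hz:
        raise InvalidBandError(
            f"invalid band [{low_hz}, {high_hz}] Hz: need 0 <= low < high"
        )
    if high_hz >= nyq:
        raise InvalidBandError(
            f"upper band edge {high_hz} Hz is at or above Nyquist ({nyq} Hz)"
        )
    if low_hz <= 0:
        return signal.butter(order, high_hz, btype="lowpass", fs=fs, output="sos")
    return signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos"
    )


def min_samples(sos: np.ndarray) -> int:
    """Smallest series length accepted by :func:`apply_zero_phase`."""
    # mirrors scipy's default filtfilt padding requirement
    return 3 * (2 * sos.shape[0] + 1) + 1


def apply_zero_phase(sos: np.ndarray, data: np.ndarray, axis: int = 0) -> np.ndarray:
    """Forward-backward filter ``data`` along ``axis``.

    Raises
    ------
    ValueError
        If the series is too short for the filter's edge padding; short
        inputs are rejected rather than silently truncated.
    """
    n = data.shape[axis]
    need = min_samples(sos)
    if n < need:
        raise ValueError(
            f"series of length {n} is too short for zero-phase filtering "
            f"(needs at least {need} samples)"
        )
    return signal.sosfiltfilt(sos, data, axis=axis)
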