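"""Interhemispheric EEG synchronization in canonical frequency bands.

Two-channel (left/right somatosensory) EEG is band-pass filtered once per
band over the whole recording, then split into consecutive non-overlapping
30 s epochs; synchronization is the Pearson correlation between the two
band-filtered channels within each epoch.

Default bands: delta 1-5, theta 5-8, alpha 8-15, beta 15-30,
gamma 30-250, broad 1-255 Hz. Shared edges belong to both neighbouring
bands. The broad band's printed 255 Hz upper edge can exceed what the
sampling rate supports; it is clipped to 0.99 x Nyquist with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._filters import InvalidBandError, apply_zero_phase, butter_sos

__all__ = [
    "EEGRecording",
    "BandDefinition",
    "BandSyncSeries",
    "DEFAULT_BANDS",
    "band_filter",
    "epoch_sync",
    "sync_profile",
    "read_eeg_csv",
    "write_eeg_csv",
    "read_eeg_binary",
    "write_eeg_binary",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not self.low_hz < self.high_hz:
            raise ValueError(f"band {self.name}: low must be < high")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 5.0),
    BandDefinition("theta", 5.0, 8.0),
    BandDefinition("alpha", 8.0, 15.0),
    BandDefinition("beta", 15.0, 30.0),
    BandDefinition("gamma", 30.0, 250.0),
    BandDefinition("broad", 1.0, 255.0),
)


@dataclass
class EEGRecording:
    """Multi-channel EEG, channels x samples, in microvolts."""

    channels: np.ndarray
    sampling_rate: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if self.channels.shape[0] < 2:
            raise ValueError("need at least 2 channels")
        if len(self.channel_labels) != self.channels.shape[0]:
            raise ValueError("one label per channel required")
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("recording contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def pick_pair(self) -> tuple[int, int]:
        """Indices of the single contra and ipsi channel (in that order)."""
        contra = [i for i, l in enumerate(self.channel_labels) if l.startswith("contra")]
        ipsi = [i for i, l in enumerate(self.channel_labels) if l.startswith("ipsi")]
        if len(contra) != 1 or len(ipsi) != 1:
            raise ValueError(
                "need exactly one 'contra*' and one 'ipsi*' channel, got "
                f"{self.channel_labels}"
            )
        return contra[0], ipsi[0]


@dataclass
class BandSyncSeries:
    """Per-epoch interhemispheric correlation for one band."""

    band: BandDefinition
    epoch_length: float
    epoch_start_times: np.ndarray
    r_per_epoch: np.ndarray  # NaN marks an undefined (zero-variance) epoch


def band_filter(eeg: EEGRecording, band: BandDefinition) -> EEGRecording:
    """Zero-phase band-pass of every channel; clips the upper edge at Nyquist."""
    nyq = eeg.sampling_rate / 2.0
    if band.low_hz >= nyq:
        raise InvalidBandError(
            f"band {band.name} ({band.low_hz}-{band.high_hz} Hz) lies entirely "
            f"above Nyquist ({nyq} Hz)"
        )
    high = band.high_hz
    if high >= nyq:
        high = 0.99 * nyq
        warnings.warn(
            f"band {band.name}: upper edge {band.high_hz} Hz clipped to "
            f"{high:.1f} Hz (0.99 x Nyquist)",
            stacklevel=2,
        )
    sos = butter_sos(band.low_hz, high, fs=eeg.sampling_rate)
    return EEGRecording(
        channels=apply_zero_phase(sos, eeg.channels, axis=1),
        sampling_rate=eeg.sampling_rate,
        channel_labels=list(eeg.channel_labels),
    )


def epoch_sync(
    eeg: EEGRecording, band: BandDefinition, epoch_length: float = 30.0
) -> BandSyncSeries:
    """Pearson r between the two hemisphere channels in consecutive epochs.

    A partial trailing epoch is discarded; zero-variance epochs yield NaN.
    """
    if eeg.duration < epoch_length:
        raise ValueError(
            f"recording ({eeg.duration:.1f} s) shorter than one epoch "
            f"({epoch_length} s)"
        )
    c_idx, i_idx = eeg.pick_pair()
    filt = band_filter(eeg, band)
    x = filt.channels[c_idx]
    y = filt.channels[i_idx]
    n_per = int(round(epoch_length * eeg.sampling_rate))
    n_epochs = eeg.n_samples // n_per
    starts = np.arange(n_epochs) * epoch_length
    r = np.full(n_epochs, np.nan)
    for k in range(n_epochs):
        xe = x[k * n_per : (k + 1) * n_per]
        ye = y[k * n_per : (k + 1) * n_per]
        tol = 1e-12 * max(1.0, np.abs(xe).max(initial=0), np.abs(ye).max(initial=0))
        if xe.std() <= tol or ye.std() <= tol:
            continue  # undefined epoch stays NaN
        r[k] = np.corrcoef(xe, ye)[0, 1]
    return BandSyncSeries(
        band=band, epoch_length=epoch_length, epoch_start_times=starts, r_per_epoch=r
    )


def sync_profile(
    eeg: EEGRecording,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    epoch_length: float = 30.0,
) -> list[BandSyncSeries]:
    """One epoch-synchronization trace per band."""
    return [epoch_sync(eeg, band, epoch_length) for band in bands]


def sync_profile_frame(profile: list[BandSyncSeries]) -> pd.DataFrame:
    """Tidy table (band, epoch_start_s, r) for CSV emission."""
    rows = []
    for series in profile:
        for t, r in zip(series.epoch_start_times, series.r_per_epoch):
            rows.append({"band": series.band.name, "epoch_start_s": t, "r": r})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O

def write_eeg_csv(eeg: EEGRecording, path: str | Path) -> None:
    t = np.arange(eeg.n_samples) / eeg.sampling_rate
    df = pd.DataFrame({"time_s": t})
    for label, ch in zip(eeg.channel_labels, eeg.channels):
        df[label] = ch
    df.to_csv(path, index=False, float_format="%.6g")


def read_eeg_csv(path: str | Path) -> EEGRecording:
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    fs = 1.0 / float(np.median(np.diff(t)))
    return EEGRecording(
        channels=df.iloc[:, 1:].to_numpy(dtype=float).T,
        sampling_rate=fs,
        channel_labels=list(df.columns[1:]),
    )


def write_eeg_binary(eeg: EEGRecording, path: str | Path) -> None:
    """Raw float32 stream (channel-major) with a JSON sidecar."""
    path = Path(path)
    eeg.channels.astype(np.float32).tofile(path)
    sidecar = {
        "sampling_rate": eeg.sampling_rate,
        "channel_labels": eeg.channel_labels,
        "n_channels": eeg.channels.shape[0],
        "dtype": "float32",
        "order": "channel-major",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_eeg_binary(path: str | Path) -> EEGRecording:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    raw = np.fromfile(path, dtype=np.float32)
    n_ch = int(meta["n_channels"])
    return EEGRecording(
        channels=raw.reshape(n_ch, -1).astype(float),
        sampling_rate=float(meta["sampling_rate"]),
        channel_labels=list(meta["channel_labels"]),
    )
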