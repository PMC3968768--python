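"""Functional-connectivity networks from ROI time series.

This module turns per-animal BOLD-like ROI time series into pairwise
Pearson correlation (functional connectivity, FC) matrices, aggregates
them across animals, and derives positive-weight undirected networks,
including ipsilateral/contralateral hemispheric sub-networks.

Conventions
-----------
* ROI labels carry their hemisphere as a prefix, e.g. ``ipsi:S1BF``.
* FC aggregation across animals defaults to the plain arithmetic mean of
  ``r``; a Fisher-z mode (z-transform, mean, back-transform) is available.
* Negative and zero correlations are dropped when a weighted network is
  built, so edge weights are strictly positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from ._filters import InvalidBandError, apply_zero_phase, butter_sos

__all__ = [
    "ROITimeSeries",
    "FCMatrix",
    "FCSDMatrix",
    "WeightedNetwork",
    "EmptyNetworkError",
    "temporal_bandpass",
    "compute_fc",
    "average_fc",
    "fc_sd",
    "to_network",
    "extract_subnetwork",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_fc_csv",
    "write_fc_csv",
    "save_cohort_hdf5",
    "load_cohort_hdf5",
]

HEMISPHERES = ("ipsi", "contra")


class EmptyNetworkError(ValueError):
    """A derived network has no positive-weight edges."""


def _check_labels(labels, hemis) -> None:
    if len(hemis) != len(labels):
        raise ValueError("hemisphere tag required for every ROI")
    tagged = [f"{h}:{l}" for h, l in zip(hemis, labels)]
    if len(tagged) != len(set(tagged)):
        dupes = sorted({t for t in tagged if tagged.count(t) > 1})
        raise ValueError(f"duplicate ROI labels: {dupes}")
    bad = sorted({h for h in hemis if h not in HEMISPHERES})
    if bad:
        raise ValueError(f"unknown hemisphere tags {bad}; expected {HEMISPHERES}")


@dataclass
class ROITimeSeries:
    """One animal/condition's signals, time points x ROIs."""

    values: np.ndarray
    roi_labels: list[str]
    roi_hemisphere: list[str]
    sampling_interval: float = 0.5
    animal_id: str = ""
    condition: str = "pre"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (time x ROI) array")
        t, n = self.values.shape
        if t < 2 or n < 2:
            raise ValueError(f"need at least 2 time points and 2 ROIs, got {t}x{n}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        _check_labels(self.roi_labels, self.roi_hemisphere)
        if len(self.roi_labels) != n:
            raise ValueError("label count does not match number of columns")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.sampling_interval

    def window(self, start: int | None, stop: int | None) -> "ROITimeSeries":
        """Return a time-windowed copy (python slice semantics)."""
        return ROITimeSeries(
            values=self.values[start:stop].copy(),
            roi_labels=list(self.roi_labels),
            roi_hemisphere=list(self.roi_hemisphere),
            sampling_interval=self.sampling_interval,
            animal_id=self.animal_id,
            condition=self.condition,
        )


@dataclass
class FCMatrix:
    """Symmetric matrix of pairwise Pearson correlations."""

    r: np.ndarray
    roi_labels: list[str]
    roi_hemisphere: list[str]
    condition: str = "pre"

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.roi_labels)
        if self.r.shape != (n, n):
            raise ValueError("r must be square and match the label count")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("r must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("diagonal of r must be 1")
        off = self.r[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < -1 - 1e-9 or off.max() > 1 + 1e-9):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")
        _check_labels(self.roi_labels, self.roi_hemisphere)


@dataclass
class FCSDMatrix:
    """Element-wise across-animal standard deviation of FC values."""

    sd: np.ndarray
    n_animals: int
    roi_labels: list[str]
    roi_hemisphere: list[str]
    condition: str = "pre"

    def __post_init__(self) -> None:
        self.sd = np.asarray(self.sd, dtype=float)
        if np.any(self.sd < -1e-12):
            raise ValueError("standard deviations must be nonnegative")


@dataclass
class WeightedNetwork:
    """Positive-weight undirected graph stored as parallel edge arrays.

    ``edge_i < edge_j`` index into ``node_ids``; ``ranked_weights`` holds the
    edge weights sorted descending (ties broken by (i, j) order), which is
    the denominator ingredient of the weighted rich-club ratio.
    """

    node_ids: list[str]
    node_hemisphere: list[str]
    edge_i: np.ndarray
    edge_j: np.ndarray
    weights: np.ndarray
    ranked_weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.edge_i = np.asarray(self.edge_i, dtype=np.intp)
        self.edge_j = np.asarray(self.edge_j, dtype=np.intp)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (len(self.edge_i) == len(self.edge_j) == len(self.weights)):
            raise ValueError("edge arrays must have equal length")
        if np.any(self.edge_i >= self.edge_j):
            raise ValueError("edges must satisfy i < j (no self-loops)")
        if np.any(self.weights <= 0):
            raise ValueError("all edge weights must be strictly positive")
        order = np.lexsort((self.edge_j, self.edge_i, -self.weights))
        self.ranked_weights = self.weights[order]

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def E(self) -> int:
        return len(self.weights)

    @property
    def edges(self) -> list[tuple[int, int, float]]:
        return list(zip(self.edge_i.tolist(), self.edge_j.tolist(), self.weights.tolist()))

    def total_weight(self) -> float:
        return float(self.weights.sum())


# ---------------------------------------------------------------------------
# operations

def temporal_bandpass(ts: ROITimeSeries, low_hz: float, high_hz: float) -> ROITimeSeries:
    """Zero-phase band-pass filter every ROI channel.

    The slow-fluctuation band used for BOLD FC analysis is 0.01-0.1 Hz.
    """
    if high_hz >= ts.nyquist_hz:
        raise InvalidBandError(
            f"upper edge {high_hz} Hz >= Nyquist {ts.nyquist_hz} Hz "
            f"at sampling interval {ts.sampling_interval} s"
        )
    sos = butter_sos(low_hz, high_hz, fs=1.0 / ts.sampling_interval)
    filtered = apply_zero_phase(sos, ts.values, axis=0)
    if low_hz <= 0:  # lowpass keeps DC; remove it so channels are zero-mean
        filtered = filtered - filtered.mean(axis=0, keepdims=True)
    return ROITimeSeries(
        values=filtered,
        roi_labels=list(ts.roi_labels),
        roi_hemisphere=list(ts.roi_hemisphere),
        sampling_interval=ts.sampling_interval,
        animal_id=ts.animal_id,
        condition=ts.condition,
    )


def compute_fc(ts: ROITimeSeries) -> FCMatrix:
    """Pairwise Pearson correlation between all ROI channels."""
    sd = ts.values.std(axis=0)
    scale = np.maximum(1.0, np.abs(ts.values).max(axis=0))
    dead = np.flatnonzero(sd <= 1e-12 * scale)
    if dead.size:
        names = [ts.roi_labels[i] for i in dead]
        raise ValueError(f"zero-variance ROI(s): {names}")
    r = np.corrcoef(ts.values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(
        r=r,
        roi_labels=list(ts.roi_labels),
        roi_hemisphere=list(ts.roi_hemisphere),
        condition=ts.condition,
    )


def _check_group(mats: list[FCMatrix], same_condition: bool = True) -> None:
    if not mats:
        raise ValueError("need at least one FC matrix")
    ref = mats[0]
    for m in mats[1:]:
        if m.roi_labels != ref.roi_labels:
            extra = sorted(set(m.roi_labels) ^ set(ref.roi_labels))
            raise ValueError(f"ROI label mismatch across matrices: {extra or 'ordering differs'}")
        if same_condition and m.condition != ref.condition:
            raise ValueError(
                f"condition mismatch: {m.condition!r} vs {ref.condition!r}"
            )


def average_fc(
    mats: list[FCMatrix], mode: str = "mean", same_condition: bool = True
) -> FCMatrix:
    """Average FC matrices across animals.

    ``mode='mean'`` is the plain element-wise arithmetic mean of ``r``;
    ``mode='fisher'`` averages on the variance-stabilized atanh scale and
    transforms back. ``same_condition=False`` permits mixed-condition
    groups (used by label-permutation tests).
    """
    _check_group(mats, same_condition=same_condition)
    stack = np.stack([m.r for m in mats])
    if mode == "mean":
        avg = stack.mean(axis=0)
    elif mode == "fisher":
        z = np.arctanh(np.clip(stack, -1 + 1e-15, 1 - 1e-15))
        avg = np.tanh(z.mean(axis=0))
    else:
        raise ValueError(f"unknown averaging mode {mode!r}")
    avg = (avg + avg.T) / 2.0
    np.fill_diagonal(avg, 1.0)
    return FCMatrix(
        r=avg,
        roi_labels=list(mats[0].roi_labels),
        roi_hemisphere=list(mats[0].roi_hemisphere),
        condition=mats[0].condition,
    )


def fc_sd(mats: list[FCMatrix]) -> FCSDMatrix:
    """Element-wise sample SD (n-1 denominator) of FC across animals."""
    if len(mats) < 2:
        raise ValueError("need at least 2 FC matrices to compute an SD")
    _check_group(mats)
    stack = np.stack([m.r for m in mats])
    sd = stack.std(axis=0, ddof=1)
    np.fill_diagonal(sd, 0.0)
    return FCSDMatrix(
        sd=sd,
        n_animals=len(mats),
        roi_labels=list(mats[0].roi_labels),
        roi_hemisphere=list(mats[0].roi_hemisphere),
        condition=mats[0].condition,
    )


def to_network(fc: FCMatrix) -> WeightedNetwork:
    """Build the positive-weight undirected network from an FC matrix.

    Negative and exactly-zero correlations are excluded, so every retained
    edge has weight ``r > 0``; the diagonal is ignored.
    """
    n = len(fc.roi_labels)
    iu, ju = np.triu_indices(n, k=1)
    w = fc.r[iu, ju]
    keep = w > 0
    if not np.any(keep):
        raise EmptyNetworkError("no positive correlations: network has no edges")
    return WeightedNetwork(
        node_ids=[f"{h}:{l}" for h, l in zip(fc.roi_hemisphere, fc.roi_labels)],
        node_hemisphere=list(fc.roi_hemisphere),
        edge_i=iu[keep],
        edge_j=ju[keep],
        weights=w[keep],
    )


def extract_subnetwork(net: WeightedNetwork, hemisphere: str) -> WeightedNetwork:
    """Induced sub-network on one hemisphere's nodes."""
    if hemisphere not in HEMISPHERES:
        raise ValueError(f"hemisphere must be one of {HEMISPHERES}, got {hemisphere!r}")
    mask = np.array([h == hemisphere for h in net.node_hemisphere])
    if not mask.any():
        raise ValueError(f"no nodes tagged {hemisphere!r}")
    new_index = np.cumsum(mask) - 1  # old index -> new index where mask
    keep = mask[net.edge_i] & mask[net.edge_j]
    if not keep.any():
        raise EmptyNetworkError(
            f"{hemisphere} sub-network has no positive edges"
        )
    return WeightedNetwork(
        node_ids=[l for l, m in zip(net.node_ids, mask) if m],
        node_hemisphere=[hemisphere] * int(mask.sum()),
        edge_i=new_index[net.edge_i[keep]],
        edge_j=new_index[net.edge_j[keep]],
        weights=net.weights[keep].copy(),
    )


# ---------------------------------------------------------------------------
# I/O

def write_timeseries_csv(ts: ROITimeSeries, path: str | Path) -> None:
    """CSV dialect: first column time (s), remaining columns ``hemi:ROI``."""
    cols = [f"{h}:{l}" for h, l in zip(ts.roi_hemisphere, ts.roi_labels)]
    t = np.arange(ts.n_timepoints) * ts.sampling_interval
    df = pd.DataFrame(ts.values, columns=cols)
    df.insert(0, "time_s", t)
    df.to_csv(path, index=False, float_format="%.8g")


def read_timeseries_csv(
    path: str | Path, animal_id: str = "", condition: str = "pre"
) -> ROITimeSeries:
    df = pd.read_csv(path)
    time = df.iloc[:, 0].to_numpy(dtype=float)
    if len(time) < 2:
        raise ValueError(f"{path}: need at least 2 time points")
    dt = float(np.median(np.diff(time)))
    hemis, labels = [], []
    for col in df.columns[1:]:
        if ":" not in col:
            raise ValueError(f"{path}: column {col!r} lacks the 'hemi:ROI' prefix")
        h, l = col.split(":", 1)
        hemis.append(h)
        labels.append(l)
    return ROITimeSeries(
        values=df.iloc[:, 1:].to_numpy(dtype=float),
        roi_labels=labels,
        roi_hemisphere=hemis,
        sampling_interval=dt,
        animal_id=animal_id,
        condition=condition,
    )


def write_fc_csv(fc: FCMatrix | FCSDMatrix, path: str | Path) -> None:
    """Square matrix CSV with ``hemi:ROI`` labels as header row and column."""
    mat = fc.r if isinstance(fc, FCMatrix) else fc.sd
    cols = [f"{h}:{l}" for h, l in zip(fc.roi_hemisphere, fc.roi_labels)]
    pd.DataFrame(mat, index=cols, columns=cols).to_csv(path, float_format="%.8g")


def read_fc_csv(path: str | Path, condition: str = "pre") -> FCMatrix:
    df = pd.read_csv(path, index_col=0)
    hemis, labels = [], []
    for col in df.columns:
        h, l = col.split(":", 1)
        hemis.append(h)
        labels.append(l)
    return FCMatrix(
        r=df.to_numpy(dtype=float),
        roi_labels=labels,
        roi_hemisphere=hemis,
        condition=condition,
    )


def save_cohort_hdf5(cohort: dict[tuple[str, str], ROITimeSeries], path: str | Path) -> None:
    """Store a full cohort ({(animal_id, condition) -> series}) in one HDF5 file."""
    with h5py.File(path, "w") as f:
        for (animal, condition), ts in cohort.items():
            g = f.create_group(f"{animal}/{condition}")
            g.create_dataset("values", data=ts.values)
            g.attrs["sampling_interval"] = ts.sampling_interval
            g.attrs["roi_labels"] = json.dumps(ts.roi_labels)
            g.attrs["roi_hemisphere"] = json.dumps(ts.roi_hemisphere)


def load_cohort_hdf5(path: str | Path) -> dict[tuple[str, str], ROITimeSeries]:
    out: dict[tuple[str, str], ROITimeSeries] = {}
    with h5py.File(path, "r") as f:
        for animal in f:
            for condition in f[animal]:
                g = f[animal][condition]
                out[(animal, condition)] = ROITimeSeries(
                    values=g["values"][()],
                    roi_labels=json.loads(g.attrs["roi_labels"]),
                    roi_hemisphere=json.loads(g.attrs["roi_hemisphere"]),
                    sampling_interval=float(g.attrs["sampling_interval"]),
                    animal_id=animal,
                    condition=condition,
                )
    return out
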