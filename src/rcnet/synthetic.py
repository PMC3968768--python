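"""Synthetic cohorts with planted rich-club structure and a disruption effect.

The generator emulates a bilateral brain at rest observed through slow
band-limited signals: per hemisphere a block of ROIs with a common
intra-hemispheric correlation level, a weaker inter-hemispheric level, and
a planted "club" of hub ROIs whose mutual correlations are raised well
above background. The post-disruption condition lowers inter-hemispheric
coupling, raises intra-hemispheric coupling (more on the disrupted side),
and reassigns part of the club to previously non-club ROIs, mimicking a
transient unilateral silencing that reorganizes hub identity.

Signals are multivariate Gaussian with the target correlation as
cross-sectional covariance, AR(1)-smoothed in time, band-limited to the
slow-fluctuation band and re-standardized, with white sensor noise on top.
Only second-order structure matters downstream, so no hemodynamic forward
model is used.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal

from ._filters import apply_zero_phase, butter_sos
from .eeg_sync import EEGRecording
from .fc_network import ROITimeSeries, write_timeseries_csv

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "EEGSimConfig",
    "build_target_fc",
    "simulate_bold",
    "simulate_cohort",
    "simulate_eeg",
    "roi_names",
]

log = logging.getLogger(__name__)

# Fig-2-style cortical/subcortical ROI abbreviations, padded to 32 per hemisphere
_ROI_VOCAB = [
    "S1BF", "S1DZ", "S1FL", "S1HL", "S1J", "S1ULp", "S2", "M1", "M2", "Cg1",
    "Cg2", "GI", "AID", "AIP", "AIV", "Au1", "AuD", "AuV", "CPu", "DI",
    "Fr3", "PrL", "PtPD", "PtPR", "Rt", "TeA", "V1", "V2", "Hip", "Th",
    "Sep", "Amy",
]


def roi_names(n: int) -> list[str]:
    if n <= len(_ROI_VOCAB):
        return _ROI_VOCAB[:n]
    return _ROI_VOCAB + [f"R{k}" for k in range(len(_ROI_VOCAB), n)]


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Correlation levels are target Pearson r; deltas are the post-condition
    shifts (interhemispheric coupling decreases, both intra-hemispheric
    levels increase, more so ipsilaterally). Hub-club membership, per-node
    hub loadings and community assignments are structural cohort traits
    (shared across animals); ``animal_sd`` adds per-animal jitter on top.
    """

    n_animals: int = 3
    n_rois_per_hemisphere: int = 32
    n_timepoints: int = 1800
    sampling_interval: float = 0.5
    base_intra_r: float = 0.45
    base_inter_r: float = 0.35
    club_size: int = 8
    club_r: float = 0.8
    inter_delta: float = -0.20
    intra_ipsi_delta: float = 0.10
    intra_contra_delta: float = 0.05
    hub_reshuffle_fraction: float = 0.5
    hub_sd: float = 0.18
    core_loading_range: tuple[float, float] = (0.30, 0.75)
    peripheral_fraction: float = 0.25
    peripheral_loading_range: tuple[float, float] = (0.05, 0.25)
    n_communities: int = 3
    community_loading: float = 0.8
    noise_sd: float = 0.1
    animal_sd: float = 0.03
    ar_coef: float = 0.4
    bold_band: tuple[float, float] = (0.01, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.club_size > 2 * self.n_rois_per_hemisphere:
            raise ValueError("club_size cannot exceed the total ROI count")
        for name, r in (
            ("base_intra_r + intra_ipsi_delta", self.base_intra_r + self.intra_ipsi_delta),
            ("base_inter_r + inter_delta", self.base_inter_r + self.inter_delta),
            ("club_r", self.club_r),
        ):
            if not -1 < r < 1:
                raise ValueError(f"target correlation {name} = {r} outside (-1, 1)")
        if self.base_intra_r + self.intra_ipsi_delta <= self.base_inter_r + self.inter_delta:
            raise ValueError("intra-hemispheric coupling must stay above interhemispheric")

    @property
    def n_rois(self) -> int:
        return 2 * self.n_rois_per_hemisphere

    def labels(self) -> tuple[list[str], list[str]]:
        names = roi_names(self.n_rois_per_hemisphere)
        labels = names + names
        hemis = ["ipsi"] * self.n_rois_per_hemisphere + ["contra"] * self.n_rois_per_hemisphere
        return labels, hemis


@dataclass
class GroundTruth:
    """Targets and planted club identity persisted alongside generated data."""

    target_fc: dict = field(default_factory=dict)  # (animal_id, condition) -> ndarray
    club_nodes: dict = field(default_factory=dict)  # condition -> list of "hemi:ROI"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "club_nodes": self.club_nodes,
            "target_fc": {
                f"{a}|{c}": m.tolist() for (a, c), m in self.target_fc.items()
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        gt = cls(club_nodes=payload["club_nodes"])
        for key, m in payload["target_fc"].items():
            a, c = key.split("|")
            gt.target_fc[(a, c)] = np.asarray(m)
        return gt


def _club_indices(cfg: CohortConfig) -> dict[str, np.ndarray]:
    """Planted club node indices per condition, a pure function of the seed.

    The pre club is split as evenly as possible between hemispheres; the
    post condition reassigns ``hub_reshuffle_fraction`` of the slots to
    random non-club nodes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5C1]))
    half = cfg.n_rois_per_hemisphere
    n_ipsi = cfg.club_size // 2
    n_contra = cfg.club_size - n_ipsi
    pre = np.concatenate([
        rng.choice(half, size=n_ipsi, replace=False),
        half + rng.choice(half, size=n_contra, replace=False),
    ])
    n_swap = int(round(cfg.hub_reshuffle_fraction * cfg.club_size))
    keep = rng.choice(cfg.club_size, size=cfg.club_size - n_swap, replace=False)
    pool = np.setdiff1d(np.arange(cfg.n_rois), pre)
    newcomers = rng.choice(pool, size=n_swap, replace=False)
    post = np.concatenate([pre[keep], newcomers])
    return {"pre": np.sort(pre), "post": np.sort(post)}


def _nearest_psd_corr(mat: np.ndarray, floor: float = 1e-6) -> tuple[np.ndarray, float]:
    """Clip negative eigenvalues, renormalize to unit diagonal.

    Returns the repaired matrix and the largest absolute element change.
    """
    vals, vecs = np.linalg.eigh(mat)
    clipped = np.clip(vals, floor, None)
    repaired = (vecs * clipped) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    return repaired, float(np.max(np.abs(repaired - mat)))


def _structural_factors(cfg: CohortConfig) -> dict:
    """Cohort-level structural traits, a pure function of the config seed.

    ``lam`` are per-node loadings on the global integration factor. The
    distribution is bimodal: a ``peripheral_fraction`` of ROIs is weakly
    integrated (low loading, hence low strength and — through the signed
    community factors — many near-zero or negative pair correlations),
    while the rest form a graded core. Loadings are renormalized after
    clipping so the mean pair product equals ``base_inter_r``.

    ``comm``/``sign`` assign every node to one signed community; opposite
    signs within a community give anticorrelated resting-state-network-like
    blocks.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x57A]))
    n = cfg.n_rois
    lo, hi = cfg.core_loading_range
    peripheral = rng.random(n) < cfg.peripheral_fraction
    lam = np.where(
        peripheral,
        rng.uniform(*cfg.peripheral_loading_range, n),
        np.clip(rng.normal(np.sqrt(cfg.base_inter_r) + 0.03, cfg.hub_sd, n), lo, hi),
    )
    lam = lam * np.sqrt(cfg.base_inter_r) / lam.mean()
    lam = np.clip(lam, 0.03, hi)
    comm = rng.integers(0, max(cfg.n_communities, 1), n)
    sign = rng.choice([-1.0, 1.0], n)
    return {"lam": lam, "comm": comm, "sign": sign, "peripheral": peripheral}


def build_target_fc(
    cfg: CohortConfig,
    condition: str,
    animal_index: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Target correlation matrix for one animal/condition plus club indices.

    The matrix is a sum of factor contributions, so it is positive
    semi-definite by construction before jitter:

    * a global factor with heterogeneous hub loadings, scaled so the mean
      interhemispheric correlation matches the configured level (the
      post-condition scale-down realizes ``inter_delta``);
    * one factor per hemisphere realizing the intra-hemispheric surplus
      (larger post-condition, more so ipsilaterally);
    * signed community factors (background nodes only) that scatter
      individual pair correlations and drive weak pairs negative;
    * club members get the global loading ``sqrt(club_r)`` and no
      community/hemisphere loadings, so club x club entries equal
      ``club_r``; the post club is partially reassigned
      (``hub_reshuffle_fraction``).

    Per-animal symmetric jitter (``animal_sd``) is added afterwards and a
    nearest-PSD repair (eigenvalue clipping) handles the tiny violations
    it introduces.
    """
    if condition not in ("pre", "post"):
        raise ValueError(f"condition must be 'pre' or 'post', got {condition!r}")
    n = cfg.n_rois
    half = cfg.n_rois_per_hemisphere
    intra = {"ipsi": cfg.base_intra_r, "contra": cfg.base_intra_r}
    inter = cfg.base_inter_r
    if condition == "post":
        intra["ipsi"] += cfg.intra_ipsi_delta
        intra["contra"] += cfg.intra_contra_delta
        inter += cfg.inter_delta

    struct = _structural_factors(cfg)
    club = _club_indices(cfg)[condition]
    is_club = np.zeros(n, dtype=bool)
    is_club[club] = True

    # global factor: background loadings rescaled to the condition's inter
    # level; club members pinned at sqrt(club_r)
    g = struct["lam"] * np.sqrt(inter / cfg.base_inter_r)
    g[is_club] = np.sqrt(cfg.club_r)
    target = np.outer(g, g)

    # one factor per hemisphere carries the intra-hemispheric surplus
    # (background nodes only); separate factors keep the inter block clean
    hemi_mask = {"ipsi": np.arange(n) < half, "contra": np.arange(n) >= half}
    h_sq = np.zeros(n)
    for hemi, m in hemi_mask.items():
        hv = np.zeros(n)
        hv[m & ~is_club] = np.sqrt(max(intra[hemi] - inter, 0.0))
        target += np.outer(hv, hv)
        h_sq += hv**2

    # signed community factors; scatter is strongest for weakly integrated
    # nodes (their pairs are pushed to zero or below, so they also lose
    # edges and degree, as weak regions do in real FC networks); loadings
    # shrink to respect each node's unit variance budget
    used = g**2 + h_sq
    hi = cfg.core_loading_range[1]
    vmag = cfg.community_loading * np.clip((hi - struct["lam"]) / hi, 0.0, 1.0)
    v = np.where(is_club, 0.0, struct["sign"] * vmag)
    v = v * np.sqrt(np.clip((0.97 - used) / np.maximum(v**2, 1e-12), 0.0, 1.0))
    for c in range(cfg.n_communities):
        vc = np.where(struct["comm"] == c, v, 0.0)
        target += np.outer(vc, vc)
    np.fill_diagonal(target, 1.0)

    off = target[~np.eye(n, dtype=bool)]
    if np.any(np.abs(off) >= 1):
        raise ValueError("structural target correlation reached |r| >= 1")
    if cfg.animal_sd > 0:
        jit = rng.normal(0.0, cfg.animal_sd, size=(n, n))
        jit = (jit + jit.T) / np.sqrt(2.0)
        np.fill_diagonal(jit, 0.0)
        target = np.clip(target + jit, -0.985, 0.985)
        np.fill_diagonal(target, 1.0)
    target, delta = _nearest_psd_corr(target)
    log.debug(
        "PSD repair for animal %d/%s moved entries by at most %.4f",
        animal_index, condition, delta,
    )
    return target, club


def simulate_bold(
    target_fc: np.ndarray,
    cfg: CohortConfig,
    rng: np.random.Generator,
    n_timepoints: int | None = None,
    animal_id: str = "",
    condition: str = "pre",
) -> ROITimeSeries:
    """Gaussian series with the given cross-correlation target.

    White-in-time draws are mixed through the Cholesky factor of the
    target, AR(1)-smoothed, band-limited to the slow-fluctuation band, and
    re-standardized per channel (identical temporal filtering of every
    channel leaves the cross-channel correlation untouched); white sensor
    noise of SD ``noise_sd`` is then added.

    The band limit is asymmetric: a steep (order-4) high-pass at the low
    edge removes slow drift that would dominate short analysis windows,
    while a gentle (order-1) low-pass at the high edge leaves soft
    spectral skirts like real hemodynamic signals have.
    """
    target_fc = np.asarray(target_fc, dtype=float)
    n = target_fc.shape[0]
    t_total = cfg.n_timepoints if n_timepoints is None else n_timepoints
    min_eig = float(np.linalg.eigvalsh(target_fc).min())
    if min_eig < -1e-8:
        raise ValueError(f"target correlation is not PSD (min eigenvalue {min_eig:.2e})")
    L = np.linalg.cholesky(target_fc + 1e-9 * np.eye(n))

    burn = 200
    z = rng.standard_normal((t_total + burn, n))
    x = z @ L.T
    a = cfg.ar_coef
    if a > 0:  # unit-variance AR(1) smoothing, same kernel on all channels
        x = sp_signal.lfilter([np.sqrt(1 - a**2)], [1.0, -a], x, axis=0)
    x = x[burn:]
    fs = 1.0 / cfg.sampling_interval
    hp = sp_signal.butter(4, cfg.bold_band[0], btype="highpass", fs=fs, output="sos")
    lp = sp_signal.butter(1, cfg.bold_band[1], btype="lowpass", fs=fs, output="sos")
    x = apply_zero_phase(lp, apply_zero_phase(hp, x, axis=0), axis=0)
    x = x / x.std(axis=0, keepdims=True)
    if cfg.noise_sd > 0:
        x = x + cfg.noise_sd * rng.standard_normal(x.shape)

    labels, hemis = cfg.labels() if n == cfg.n_rois else (
        [f"R{k}" for k in range(n)], ["ipsi"] * n
    )
    return ROITimeSeries(
        values=x,
        roi_labels=labels,
        roi_hemisphere=hemis,
        sampling_interval=cfg.sampling_interval,
        animal_id=animal_id,
        condition=condition,
    )


def simulate_cohort(
    cfg: CohortConfig, out_dir: str | Path | None = None
) -> tuple[dict[tuple[str, str], ROITimeSeries], GroundTruth]:
    """Full cohort: every animal x {pre, post}, plus persisted ground truth.

    With ``out_dir`` set, each series is written in the ROI-CSV dialect and
    the ground truth as JSON.
    """
    labels, hemis = cfg.labels()
    ss = np.random.SeedSequence([cfg.seed, 0xB01D])
    streams = ss.spawn(cfg.n_animals * 2)
    gt = GroundTruth()
    club = _club_indices(cfg)
    for cond in ("pre", "post"):
        gt.club_nodes[cond] = [f"{hemis[i]}:{labels[i]}" for i in club[cond]]
    cohort: dict[tuple[str, str], ROITimeSeries] = {}
    k = 0
    for a in range(cfg.n_animals):
        animal_id = f"rat{a + 1:02d}"
        for cond in ("pre", "post"):
            rng = np.random.default_rng(streams[k])
            k += 1
            target, _ = build_target_fc(cfg, cond, a, rng)
            ts = simulate_bold(target, cfg, rng, animal_id=animal_id, condition=cond)
            cohort[(animal_id, cond)] = ts
            gt.target_fc[(animal_id, cond)] = target
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for (animal_id, cond), ts in cohort.items():
            write_timeseries_csv(ts, out_dir / f"{animal_id}_{cond}.csv")
        gt.to_json(out_dir / "ground_truth.json")
        (out_dir / "cohort_config.json").write_text(json.dumps(asdict(cfg), indent=1))
    return cohort, gt


# ---------------------------------------------------------------------------
# EEG generator

@dataclass
class EEGSimConfig:
    """Two-channel EEG with per-band shared sources and an injection effect.

    Each band contributes ``amplitude * (sqrt(r) * shared + noise_gain *
    sqrt(1-r) * private)`` per channel, so with ``noise_gain=1`` the
    within-band epoch correlation approximates ``r``. After
    ``injection_time`` the theta/alpha shared fractions drop, gamma rises
    transiently for ``gamma_transient_s``, and delta/beta are unchanged —
    the qualitative unilateral-silencing pattern; the broad-band
    correlation falls as a consequence of the theta/alpha drop.
    """

    duration: float = 900.0
    sampling_rate: float = 1000.0
    injection_time: float = 450.0
    gamma_transient_s: float = 120.0
    shared_pre: dict = field(
        default_factory=lambda: {
            "delta": 0.8, "theta": 0.8, "alpha": 0.8, "beta": 0.6, "gamma": 0.5
        }
    )
    shared_post: dict = field(
        default_factory=lambda: {
            "delta": 0.8, "theta": 0.3, "alpha": 0.3, "beta": 0.6, "gamma": 0.5
        }
    )
    gamma_transient_r: float = 0.85
    amplitude: dict = field(
        default_factory=lambda: {
            "delta": 1.0, "theta": 0.9, "alpha": 0.8, "beta": 0.5, "gamma": 0.6
        }
    )
    source_bands: dict = field(
        default_factory=lambda: {
            "delta": (1.0, 5.0), "theta": (5.0, 8.0), "alpha": (8.0, 15.0),
            "beta": (15.0, 30.0), "gamma": (30.0, 250.0),
        }
    )
    noise_gain: float = 1.0
    epoch_length: float = 30.0
    seed: int = 0


def _implied_broad_r(cfg: EEGSimConfig, shared: dict) -> float:
    num = sum(cfg.amplitude[b] ** 2 * shared[b] for b in shared)
    den = sum(
        cfg.amplitude[b] ** 2 * (shared[b] + cfg.noise_gain**2 * (1 - shared[b]))
        for b in shared
    )
    return num / den


def simulate_eeg(
    cfg: EEGSimConfig, rng: np.random.Generator | None = None
) -> tuple[EEGRecording, dict]:
    """Pre+post concatenated recording and its ground-truth correlations."""
    if cfg.duration < 2 * cfg.epoch_length:
        raise ValueError("recording must span at least 2 epochs")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xEE6]))
    n = int(round(cfg.duration * cfg.sampling_rate))
    t = np.arange(n) / cfg.sampling_rate
    post = t >= cfg.injection_time
    transient = post & (t < cfg.injection_time + cfg.gamma_transient_s)

    channels = np.zeros((2, n))
    truth: dict = {"bands": {}, "injection_time": cfg.injection_time}
    for band, (lo, hi) in cfg.source_bands.items():
        sos = butter_sos(lo, min(hi, 0.99 * cfg.sampling_rate / 2), fs=cfg.sampling_rate)

        def bandnoise() -> np.ndarray:
            sig = apply_zero_phase(sos, rng.standard_normal(n))
            return sig / sig.std()

        shared = bandnoise()
        r_t = np.where(post, cfg.shared_post[band], cfg.shared_pre[band])
        if band == "gamma":
            r_t = np.where(transient, cfg.gamma_transient_r, r_t)
        amp = cfg.amplitude[band]
        for c in range(2):
            private = bandnoise()
            channels[c] += amp * (
                np.sqrt(r_t) * shared + cfg.noise_gain * np.sqrt(1 - r_t) * private
            )
        truth["bands"][band] = {
            "pre_r": cfg.shared_pre[band],
            "post_r": cfg.shared_post[band],
            "transient_r": cfg.gamma_transient_r if band == "gamma" else None,
            "transient_end": (
                cfg.injection_time + cfg.gamma_transient_s if band == "gamma" else None
            ),
        }
    truth["bands"]["broad"] = {
        "pre_r": _implied_broad_r(cfg, cfg.shared_pre),
        "post_r": _implied_broad_r(cfg, cfg.shared_post),
    }
    rec = EEGRecording(
        channels=channels,
        sampling_rate=cfg.sampling_rate,
        channel_labels=["contra:S1", "ipsi:S1"],
    )
    return rec, truth
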