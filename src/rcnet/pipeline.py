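"""End-to-end orchestration: data -> FC -> networks -> rich-club -> report.

A run is fully determined by its configuration and a single mandatory
seed, which fans out into independent substreams for the generator, the
reshuffle null model and the permutation test. The report mirrors the
study's result surfaces: per-condition FC and SD matrices, prominence
rankings, whole-brain and hemispheric rho_w curves, permutation
comparisons per scope, and (optionally) the EEG synchronization profile.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .eeg_sync import BandSyncSeries, sync_profile, sync_profile_frame
from .fc_network import (
    FCMatrix,
    FCSDMatrix,
    ROITimeSeries,
    average_fc,
    compute_fc,
    fc_sd,
    extract_subnetwork,
    read_timeseries_csv,
    temporal_bandpass,
    to_network,
    write_fc_csv,
)
from .richclub import (
    CurveComparison,
    ProminenceRanking,
    RichClubCurve,
    compare_curves,
    prominence_ranking,
    rho_w,
    threshold_grid,
)
from .synthetic import CohortConfig, EEGSimConfig, simulate_cohort, simulate_eeg

__all__ = ["RunConfig", "RunReport", "run_study", "summarize_blocks", "write_report"]

log = logging.getLogger(__name__)

SCOPES = ("whole", "ipsi", "contra")
CONDITIONS = ("pre", "post")


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Either ``cohort`` (synthetic generation) or ``input_dir`` (CSV files
    named ``<animal>_<condition>.csv``) must be provided. The analysis
    window takes the first ``window_len`` time points of each pre series
    and the last ``window_len`` of each post series.
    """

    seed: int
    cohort: CohortConfig | None = None
    input_dir: str | None = None
    window_len: int = 500
    bandpass: tuple[float, float] | None = (0.01, 0.1)
    averaging: str = "mean"
    n_points: int = 20
    min_club_nodes: int = 3
    min_club_edges: int = 2
    n_null: int = 1000
    n_permutations: int = 999
    alpha: float = 0.01
    top_k: int = 10
    eeg: EEGSimConfig | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.cohort is None and self.input_dir is None:
            raise ValueError("provide either a synthetic cohort config or input_dir")


@dataclass
class RunReport:
    fc: dict[str, FCMatrix] = field(default_factory=dict)
    sd: dict[str, FCSDMatrix] = field(default_factory=dict)
    rankings: dict[str, ProminenceRanking] = field(default_factory=dict)
    curves: dict[tuple[str, str], RichClubCurve] = field(default_factory=dict)
    comparisons: dict[str, CurveComparison] = field(default_factory=dict)
    block_summaries: dict[str, dict[str, float]] = field(default_factory=dict)
    eeg_profile: list[BandSyncSeries] | None = None
    provenance: dict = field(default_factory=dict)


def summarize_blocks(fc: FCMatrix) -> dict[str, float]:
    """Mean FC in the intra-ipsi, intra-contra and interhemispheric blocks.

    Only off-diagonal entries contribute; intra-block means use each
    unordered pair once.
    """
    hemis = np.asarray(fc.roi_hemisphere)
    if not set(hemis) <= {"ipsi", "contra"}:
        raise ValueError("hemisphere tags required on every ROI")
    ipsi = hemis == "ipsi"
    contra = ~ipsi
    out = {}
    for name, mask in (("intra_ipsi", ipsi), ("intra_contra", contra)):
        sub = fc.r[np.ix_(mask, mask)]
        iu = np.triu_indices(sub.shape[0], k=1)
        out[name] = float(sub[iu].mean()) if iu[0].size else float("nan")
    out["inter"] = float(fc.r[np.ix_(ipsi, contra)].mean())
    return out


def _load_cohort(cfg: RunConfig) -> dict[tuple[str, str], ROITimeSeries]:
    if cfg.cohort is not None:
        cohort, _ = simulate_cohort(cfg.cohort)
        return cohort
    cohort = {}
    for path in sorted(Path(cfg.input_dir).glob("*_*.csv")):
        animal, cond = path.stem.rsplit("_", 1)
        if cond not in CONDITIONS:
            continue
        cohort[(animal, cond)] = read_timeseries_csv(path, animal_id=animal, condition=cond)
    if not cohort:
        raise FileNotFoundError(f"no '<animal>_<pre|post>.csv' files in {cfg.input_dir}")
    return cohort


def _analysis_window(ts: ROITimeSeries, window_len: int) -> ROITimeSeries:
    """First ``window_len`` points for pre, last ``window_len`` for post."""
    n = min(window_len, ts.n_timepoints)
    return ts.window(0, n) if ts.condition == "pre" else ts.window(-n, None)


def run_study(cfg: RunConfig) -> RunReport:
    """Execute the full analysis; deterministic given (inputs, seed)."""
    ss = np.random.SeedSequence(cfg.seed)
    seed_curves, seed_compare = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2)]

    report = RunReport()
    cohort = _load_cohort(cfg)
    animals = sorted({a for a, _ in cohort})
    for cond in CONDITIONS:
        missing = [a for a in animals if (a, cond) not in cohort]
        if missing:
            raise ValueError(f"animals {missing} lack a {cond!r} series")

    per_condition: dict[str, list[FCMatrix]] = {c: [] for c in CONDITIONS}
    for cond in CONDITIONS:
        for animal in animals:
            ts = _analysis_window(cohort[(animal, cond)], cfg.window_len)
            if cfg.bandpass is not None:
                ts = temporal_bandpass(ts, *cfg.bandpass)
            per_condition[cond].append(compute_fc(ts))

    grid_kw = dict(
        n_points=cfg.n_points,
        min_club_nodes=cfg.min_club_nodes,
        min_club_edges=cfg.min_club_edges,
    )
    for cond in CONDITIONS:
        avg = average_fc(per_condition[cond], mode=cfg.averaging)
        report.fc[cond] = avg
        report.block_summaries[cond] = summarize_blocks(avg)
        if len(animals) >= 2:
            report.sd[cond] = fc_sd(per_condition[cond])
        whole = to_network(avg)
        report.rankings[cond] = prominence_ranking(
            whole, k=min(cfg.top_k, whole.n_nodes)
        )
        for scope in SCOPES:
            net = whole if scope == "whole" else extract_subnetwork(whole, scope)
            thresholds = threshold_grid(net, **grid_kw)
            report.curves[(scope, cond)] = rho_w(
                net,
                thresholds=thresholds,
                n_null=cfg.n_null,
                seed=seed_curves,
            )
    for scope in SCOPES:
        log.info("permutation comparison, scope=%s", scope)
        report.comparisons[scope] = compare_curves(
            per_condition["pre"],
            per_condition["post"],
            n_permutations=cfg.n_permutations,
            seed=seed_compare,
            alpha=cfg.alpha,
            scope=scope,
            n_null=cfg.n_null,
            mode=cfg.averaging,
            **grid_kw,
        )

    if cfg.eeg is not None:
        rec, _ = simulate_eeg(cfg.eeg)
        report.eeg_profile = sync_profile(rec, epoch_length=cfg.eeg.epoch_length)

    cfg_json = json.dumps(_config_dict(cfg), sort_keys=True, default=str)
    report.provenance = {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "rcnet_version": __version__,
        "n_animals": len(animals),
    }
    if cfg.output_dir is not None:
        write_report(report, cfg.output_dir)
    return report


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def curve_frame(curve: RichClubCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "threshold": curve.thresholds,
            "phi": curve.phi,
            "phi_random_mean": curve.phi_random_mean,
            "rho": curve.rho,
        }
    )


def comparison_frame(comp: CurveComparison) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "threshold": comp.thresholds,
            "delta_rho": comp.delta_rho,
            "p": comp.p_values,
            "significant": comp.significant,
        }
    )


def write_report(report: RunReport, out_dir: str | Path) -> None:
    """Emit every report surface as plain CSV/JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cond, fc in report.fc.items():
        write_fc_csv(fc, out / f"fc_{cond}.csv")
    for cond, sd in report.sd.items():
        write_fc_csv(sd, out / f"fc_sd_{cond}.csv")
    for cond, ranking in report.rankings.items():
        pd.DataFrame(
            {
                "node": ranking.node_ids,
                "strength": ranking.strengths,
                "top_k": [i < ranking.k for i in range(len(ranking.node_ids))],
            }
        ).to_csv(out / f"prominence_{cond}.csv", index=False, float_format="%.8g")
    for (scope, cond), curve in report.curves.items():
        curve_frame(curve).to_csv(
            out / f"richclub_{scope}_{cond}.csv", index=False, float_format="%.8g"
        )
    for scope, comp in report.comparisons.items():
        comparison_frame(comp).to_csv(
            out / f"comparison_{scope}.csv", index=False, float_format="%.8g"
        )
    summary = {
        "block_summaries": report.block_summaries,
        "provenance": report.provenance,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    if report.eeg_profile is not None:
        sync_profile_frame(report.eeg_profile).to_csv(
            out / "eeg_sync.csv", index=False, float_format="%.8g"
        )


def plot_curves(report: RunReport, out_dir: str | Path) -> None:
    """Optional PNG panels of the rho_w curves per scope (pre vs post)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for scope in SCOPES:
        fig, ax = plt.subplots(figsize=(5, 4))
        for cond, color in (("pre", "tab:blue"), ("post", "tab:red")):
            curve = report.curves.get((scope, cond))
            if curve is None:
                continue
            ax.plot(curve.thresholds, curve.rho, color=color, label=cond)
        ax.axhline(1.0, color="gray", lw=0.8, ls="--")
        ax.set_xlabel("strength threshold s")
        ax.set_ylabel(r"$\rho^w(s)$")
        ax.set_title(f"weighted rich-club effect ({scope})")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / f"richclub_{scope}.png", dpi=120)
        plt.close(fig)
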