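"""End-to-end orchestration of the single-trial extraction chain.

One trial runs through: artifact gate -> EMD of the CI channel -> spatial
maps -> template matching -> 3-means selection -> reconstruction ->
trial-specific band -> zero-phase band-pass -> AM envelope -> beta
rebound.  Each per-trial branch (artifact, no detectable band, degenerate
selection) produces a QC flag instead of failing the run, so a session
summary always accounts for every trial.

The conventional baseline used in the paired comparison is computed on the
*same* trials (task band from trial-averaged spectra, cross-trial envelope
average, one BR from the channel with maximal reactive activity), which
keeps the single-trial-vs-averaged contrast internally valid.  The paired
test is a one-sample Wilcoxon signed-rank of the single-trial BRs against
the conventional BR constant (exact null distribution up to n = 25, normal
approximation above).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import template_builder
from .band_detect import bandpass, trial_band
from .emd import DEFAULT_EPS, DEFAULT_MAX_IMFS, DEFAULT_MAX_SIFT_ITERS, emd_decompose
from .envelope_br import am_envelope, beta_rebound, max_reactive_channel
from .errors import ConfigurationError, SelectionError
from .model import (
    BandSpec,
    EEGEpoch,
    SpatialTemplate,
    TimeWindow,
    TrialResult,
    reject_artifact_epoch,
)
from .spatial_select import reconstruct, select_imfs

__all__ = [
    "RunConfig",
    "SessionSummary",
    "extract_single_trial",
    "run_session",
    "averaging_attenuation_experiment",
    "results_table",
]

logger = logging.getLogger("betasift")


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one extraction run (windows, EMD, band rule, modes)."""

    ci_label: str = "C3"
    ref_window: TimeWindow = field(default_factory=lambda: TimeWindow(-3.5, -2.5))
    post_window: TimeWindow = field(default_factory=lambda: TimeWindow(0.5, 1.5))
    emd_eps: float = DEFAULT_EPS
    max_imfs: int = DEFAULT_MAX_IMFS
    max_sift_iters: int = DEFAULT_MAX_SIFT_ITERS
    band_rule: str = "two_sd"
    search_lo_hz: float = 13.0
    search_hi_hz: float = 30.0
    min_band_hz: float = 2.0
    filter_order: int = 4
    reconstruction: str = "ci"
    artifact_threshold_uv: float = 100.0
    eog_labels: tuple = ("VEOG", "HEOG")
    seed: int = 0

    @property
    def search_band(self) -> BandSpec:
        return BandSpec(self.search_lo_hz, self.search_hi_hz)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for key in ("ref_window", "post_window"):
            if key in kwargs and not isinstance(kwargs[key], TimeWindow):
                kwargs[key] = TimeWindow(*kwargs[key])
        if "eog_labels" in kwargs:
            kwargs["eog_labels"] = tuple(kwargs["eog_labels"])
        return cls(**kwargs)


@dataclass
class SessionSummary:
    """Per-trial results plus the paired single-trial-vs-conventional test."""

    results: List[TrialResult]
    counts: dict
    usable_fraction: float
    br_mean_uv: float
    br_sd_uv: float
    latency_mean_s: float
    latency_sd_s: float
    conventional_br_uv: float
    conventional_band: BandSpec
    conventional_channel: str
    wilcoxon_statistic: float
    wilcoxon_p: float

    @property
    def n_trials(self) -> int:
        return len(self.results)

    def table(self) -> pd.DataFrame:
        return results_table(self.results)


def results_table(results: Sequence[TrialResult]) -> pd.DataFrame:
    """Per-trial results as a delimited-text-ready table."""
    rows = []
    for r in results:
        rows.append(
            {
                "trial": r.trial_index,
                "qc": r.qc,
                "selected_imfs": ",".join(str(k) for k in r.selected_imfs),
                "band_lo_hz": r.band.f_lo if r.band else np.nan,
                "band_hi_hz": r.band.f_hi if r.band else np.nan,
                "br_uv": r.br_amplitude if r.br_amplitude is not None else np.nan,
                "br_latency_s": r.br_latency_s if r.br_latency_s is not None else np.nan,
                "br_channel": r.br_channel or "",
            }
        )
    return pd.DataFrame(rows)


def extract_single_trial(
    epoch: EEGEpoch,
    template: SpatialTemplate,
    cfg: RunConfig = RunConfig(),
    trial_index: int = 0,
) -> TrialResult:
    """Run the full single-trial chain on one epoch.

    Never raises for per-trial data problems: artifact trials, trials with
    no supra-threshold band and degenerate selections come back flagged via
    ``TrialResult.qc``.  Configuration mismatches (missing CI channel,
    template/montage disagreement) do raise.
    """
    if cfg.ci_label not in epoch.channel_labels:
        raise ConfigurationError(f"CI channel {cfg.ci_label!r} not in epoch montage")
    if epoch.channel_labels != template.channel_labels:
        raise ConfigurationError("epoch montage does not match template montage")

    if not reject_artifact_epoch(epoch, cfg.eog_labels, cfg.artifact_threshold_uv):
        logger.info("trial %d: rejected (EOG artifact)", trial_index)
        return TrialResult(trial_index=trial_index, qc="artifact")

    ci = epoch.channel_index(cfg.ci_label)
    imfset = emd_decompose(
        epoch.data[ci], eps=cfg.emd_eps, max_imfs=cfg.max_imfs,
        max_sift_iters=cfg.max_sift_iters,
    )
    try:
        s1, diag = select_imfs(imfset, epoch, template)
    except SelectionError as exc:
        logger.info("trial %d: degenerate selection (%s)", trial_index, exc)
        return TrialResult(trial_index=trial_index, qc="degenerate")
    logger.info(
        "trial %d: J=%d rho=%s selected=%s", trial_index, imfset.n_imfs,
        np.round(diag.correlations, 2).tolist(), [k + 1 for k in s1],
    )

    recon = reconstruct(imfset, s1, mode=cfg.reconstruction, epoch=epoch)
    ci_recon = recon[ci] if recon.ndim == 2 else recon

    from .model import window_indices

    r0, r1 = window_indices(cfg.ref_window, epoch.fs, epoch.t0_offset, epoch.n_samples)
    p0, p1 = window_indices(cfg.post_window, epoch.fs, epoch.t0_offset, epoch.n_samples)
    band = trial_band(
        ci_recon[r0:r1], ci_recon[p0:p1], epoch.fs,
        search=cfg.search_band, rule=cfg.band_rule, min_band_hz=cfg.min_band_hz,
    )
    if band is None:
        logger.info("trial %d: no supra-threshold band", trial_index)
        return TrialResult(
            trial_index=trial_index, qc="no-band",
            selected_imfs=tuple(k + 1 for k in s1), correlations=diag.correlations,
        )

    filtered = bandpass(recon, epoch.fs, band, order=cfg.filter_order)
    envelopes = am_envelope(filtered)
    if envelopes.ndim == 2:
        label, res = max_reactive_channel(
            envelopes, epoch.channel_labels, epoch.fs, epoch.t0_offset,
            cfg.post_window, cfg.ref_window,
        )
        ci_envelope = envelopes[ci]
    else:
        res = beta_rebound(envelopes, epoch.fs, epoch.t0_offset,
                           cfg.post_window, cfg.ref_window)
        label = cfg.ci_label
        ci_envelope = envelopes

    logger.info(
        "trial %d: band %.1f-%.1f Hz BR %.2f uV at %.2f s (%s)",
        trial_index, band.f_lo, band.f_hi, res.br_amplitude, res.br_latency_s, label,
    )
    return TrialResult(
        trial_index=trial_index,
        qc="ok",
        selected_imfs=tuple(k + 1 for k in s1),
        correlations=diag.correlations,
        band=band,
        reconstructed=ci_recon,
        envelope=ci_envelope,
        br_amplitude=res.br_amplitude,
        br_latency_s=res.br_latency_s,
        br_channel=label,
    )


def _conventional_baseline(epochs: Sequence[EEGEpoch], cfg: RunConfig):
    band = template_builder.task_band(
        list(epochs), cfg.ci_label, ref=cfg.ref_window, post=cfg.post_window,
        search=cfg.search_band, rule=cfg.band_rule, min_band_hz=cfg.min_band_hz,
    )
    ers = template_builder.conventional_ers(
        list(epochs), band, ref=cfg.ref_window, post=cfg.post_window,
        filter_order=cfg.filter_order,
    )
    label, res = max_reactive_channel(
        ers.avg_envelopes, ers.channel_labels, ers.fs, ers.t0_offset,
        cfg.post_window, cfg.ref_window,
    )
    return band, label, res.br_amplitude


def run_session(
    epochs: Sequence[EEGEpoch],
    template: SpatialTemplate,
    cfg: RunConfig = RunConfig(),
) -> SessionSummary:
    """Extract every trial, then compare against the conventional baseline.

    Raises :class:`SelectionError` when fewer than two trials survive QC
    (the paired test would be meaningless).
    """
    results = [
        extract_single_trial(e, template, cfg, trial_index=i)
        for i, e in enumerate(epochs)
    ]
    counts = {flag: 0 for flag in ("ok", "artifact", "no-band", "degenerate")}
    for r in results:
        counts[r.qc] += 1
    usable = [r for r in results if r.qc == "ok"]
    if len(usable) < 2:
        raise SelectionError(f"only {len(usable)} usable trials; need >= 2")

    clean_epochs = [
        e for e in epochs
        if reject_artifact_epoch(e, cfg.eog_labels, cfg.artifact_threshold_uv)
    ]
    conv_band, conv_label, conv_br = _conventional_baseline(clean_epochs, cfg)

    brs = np.array([r.br_amplitude for r in usable])
    lats = np.array([r.br_latency_s for r in usable])
    diffs = brs - conv_br
    if np.all(diffs == 0.0):
        stat, p = 0.0, 1.0
    else:
        method = "exact" if len(diffs) <= 25 else "approx"
        stat, p = stats.wilcoxon(diffs, alternative="greater", method=method)

    return SessionSummary(
        results=results,
        counts=counts,
        usable_fraction=len(usable) / len(results),
        br_mean_uv=float(brs.mean()),
        br_sd_uv=float(brs.std(ddof=1)) if brs.size > 1 else 0.0,
        latency_mean_s=float(lats.mean()),
        latency_sd_s=float(lats.std(ddof=1)) if lats.size > 1 else 0.0,
        conventional_br_uv=float(conv_br),
        conventional_band=conv_band,
        conventional_channel=conv_label,
        wilcoxon_statistic=float(stat),
        wilcoxon_p=float(p),
    )


def averaging_attenuation_experiment(
    epochs: Sequence[EEGEpoch],
    template: SpatialTemplate,
    cfg: RunConfig = RunConfig(),
    group_sizes: Sequence[int] = (1, 10, 25, 40),
    results: Optional[Sequence[TrialResult]] = None,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """BR of averaged envelopes as a function of how many trials are pooled.

    For each ``k`` the usable single-trial CI envelopes are split into
    disjoint consecutive groups of ``k`` trials; each group is averaged,
    one BR is read per group, and the mean over groups is reported (for
    ``k = 1`` this is exactly the mean single-trial BR).  Under latency
    jitter the averaged bump smears, so the BR shrinks with ``k``.  Also
    returns the latency-sorted raster of peak-normalized envelopes for
    plotting.
    """
    if results is None:
        results = [
            extract_single_trial(e, template, cfg, trial_index=i)
            for i, e in enumerate(epochs)
        ]
    usable = [r for r in results if r.qc == "ok"]
    group_sizes = [int(k) for k in group_sizes]
    if not group_sizes or min(group_sizes) < 1:
        raise ConfigurationError("group sizes must be positive")
    if len(usable) < max(group_sizes):
        raise ConfigurationError(
            f"need {max(group_sizes)} usable trials, have {len(usable)}"
        )
    fs = epochs[0].fs
    t0 = epochs[0].t0_offset
    envs = np.vstack([r.envelope for r in usable])
    rows = []
    for k in group_sizes:
        n_groups = len(usable) // k
        brs = []
        for g in range(n_groups):
            avg = envs[g * k:(g + 1) * k].mean(axis=0)
            res = beta_rebound(avg, fs, t0, cfg.post_window, cfg.ref_window)
            brs.append(res.br_amplitude)
        rows.append({"n_averaged": k, "n_groups": n_groups,
                     "br_uv": float(np.mean(brs))})

    order = np.argsort([r.br_latency_s for r in usable], kind="stable")
    peaks = envs.max(axis=1, keepdims=True)
    peaks[peaks == 0.0] = 1.0
    raster = (envs / peaks)[order]
    return pd.DataFrame(rows), raster
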