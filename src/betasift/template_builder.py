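"""Spatial-template construction via conventional ERS.

The conventional event-related-synchronization pipeline fixes one
*task-specific* beta band per subject (from trial-averaged reference vs
post-movement spectra at the channel of interest), band-pass filters every
trial on every channel, rectifies with the AM method, averages the
envelopes across trials, and reads one beta rebound per channel from the
averaged envelope (channel-wise maxima over the same post window, per
sensor site).  Averaging per-subject BR vectors across subjects yields the
common spatial template.  Templates are stored unnormalized (uV):
Pearson matching downstream is scale-invariant, so no normalization step
is introduced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .band_detect import (
    DEFAULT_FILTER_ORDER,
    DEFAULT_MIN_BAND_HZ,
    DEFAULT_SEARCH_BAND,
    DifferentialSpectrum,
    amplitude_spectrum,
    band_from_spectrum,
    bandpass,
)
from .envelope_br import am_envelope
from .errors import ConfigurationError, NoBandError
from .model import BandSpec, EEGEpoch, SpatialTemplate, TimeWindow, window_slice

__all__ = ["SubjectERS", "task_band", "conventional_ers", "build_template",
           "DEFAULT_REF_WINDOW", "DEFAULT_POST_WINDOW"]

DEFAULT_REF_WINDOW = TimeWindow(-3.5, -2.5)
DEFAULT_POST_WINDOW = TimeWindow(0.5, 1.5)

#: Below this many trials the "about 100 trials" guideline is clearly unmet.
MIN_RECOMMENDED_TRIALS = 20


@dataclass
class SubjectERS:
    """One subject's conventional-ERS summary."""

    channel_labels: tuple
    fs: float
    t0_offset: float
    avg_envelopes: np.ndarray  # M x N mean AM envelope, uV
    task_band: BandSpec
    br: np.ndarray  # per-channel beta rebound, uV
    n_trials: int


def _check_uniform(trials: Sequence[EEGEpoch]) -> None:
    first = trials[0]
    for t in trials[1:]:
        if t.channel_labels != first.channel_labels:
            raise ConfigurationError("trials have mismatched montages")
        if t.fs != first.fs or t.n_samples != first.n_samples or t.t0_offset != first.t0_offset:
            raise ConfigurationError("trials have mismatched sampling geometry")


def task_band(
    trials: Sequence[EEGEpoch],
    ci_label: str,
    ref: TimeWindow = DEFAULT_REF_WINDOW,
    post: TimeWindow = DEFAULT_POST_WINDOW,
    search: BandSpec = DEFAULT_SEARCH_BAND,
    rule: str = "two_sd",
    min_band_hz: float = DEFAULT_MIN_BAND_HZ,
) -> BandSpec:
    """Task-specific beta band from trial-averaged amplitude spectra at CI.

    Averages the reference-window and post-window amplitude spectra across
    trials, then applies the same supra-threshold rule as the single-trial
    band detector.  Raises :class:`NoBandError` when nothing passes — the
    template cannot be built from such data.
    """
    if len(trials) < 2:
        raise ConfigurationError("task band needs at least 2 trials")
    _check_uniform(trials)
    fs = trials[0].fs
    ci = trials[0].channel_index(ci_label)
    ref_acc = post_acc = None
    for t in trials:
        freqs, ra = amplitude_spectrum(window_slice(t, ref)[ci], fs)
        _, pa = amplitude_spectrum(window_slice(t, post)[ci], fs)
        ref_acc = ra if ref_acc is None else ref_acc + ra
        post_acc = pa if post_acc is None else post_acc + pa
    ref_amp = ref_acc / len(trials)
    post_amp = post_acc / len(trials)
    diff = post_amp - ref_amp
    scope = (freqs >= search.f_lo) & (freqs <= search.f_hi)
    sd = float(np.std(diff[scope]))
    threshold = 2.0 * sd if rule == "two_sd" else 3.09 * sd
    spec = DifferentialSpectrum(
        freqs=freqs, ref_amp=ref_amp, post_amp=post_amp,
        diff=diff, threshold=threshold, rule=rule, search=search,
    )
    band = band_from_spectrum(spec, min_band_hz=min_band_hz)
    if band is None:
        raise NoBandError("no supra-threshold task band in the averaged spectra")
    return band


def conventional_ers(
    trials: Sequence[EEGEpoch],
    band: BandSpec,
    ref: TimeWindow = DEFAULT_REF_WINDOW,
    post: TimeWindow = DEFAULT_POST_WINDOW,
    filter_order: int = DEFAULT_FILTER_ORDER,
) -> SubjectERS:
    """Band-pass, rectify and average each channel across trials.

    The per-channel BR is the difference between the maximum of the
    averaged envelope inside the post-movement window and its mean over the
    reference window, computed channel-wise ("for each sensor site").
    """
    if not trials:
        raise ConfigurationError("conventional ERS needs at least one trial")
    _check_uniform(trials)
    first = trials[0]
    acc = np.zeros_like(first.data)
    for t in trials:
        if np.ptp(t.data) == 0.0:
            env = np.zeros_like(t.data)  # all-zero trial: zero envelope
        else:
            env = am_envelope(bandpass(t.data, t.fs, band, order=filter_order))
        acc += env
    avg = acc / len(trials)
    from .model import window_indices

    p0, p1 = window_indices(post, first.fs, first.t0_offset, first.n_samples)
    r0, r1 = window_indices(ref, first.fs, first.t0_offset, first.n_samples)
    br = avg[:, p0:p1].max(axis=1) - avg[:, r0:r1].mean(axis=1)
    return SubjectERS(
        channel_labels=first.channel_labels,
        fs=first.fs,
        t0_offset=first.t0_offset,
        avg_envelopes=avg,
        task_band=band,
        br=br,
        n_trials=len(trials),
    )


def build_template(
    subject_ers: Sequence[SubjectERS], ci_label: str = "C3"
) -> SpatialTemplate:
    """Average per-subject BR vectors into a common spatial template."""
    if not subject_ers:
        raise ConfigurationError("need at least one subject's ERS")
    labels = subject_ers[0].channel_labels
    for s in subject_ers[1:]:
        if s.channel_labels != labels:
            raise ConfigurationError("subjects have mismatched montages")
    weights = np.mean([s.br for s in subject_ers], axis=0)
    return SpatialTemplate(weights=weights, channel_labels=labels, ci_label=ci_label)
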