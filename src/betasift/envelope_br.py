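"""Amplitude-modulation envelopes and beta-rebound quantification.

The band-passed activity ``M_BP(t)`` is rectified into its AM waveform

.. math:: m(t) = \\sqrt{M_{BP}(t)^2 + H(M_{BP}(t))^2}

with ``H`` the Hilbert transform, i.e. the analytic-signal magnitude.  The
beta rebound (BR) of a trial is the maximum of ``m(t)`` inside the
post-movement window minus the mean of ``m(t)`` over the reference window;
its latency is the time of that maximum.  The Hilbert transform is taken
over the full epoch so that window interiors are free of edge transients;
the outer 0.25 s of the envelope should be regarded as edge-unreliable.
BR may be negative — no rectification to zero — which preserves the
statistic's distribution for paired nonparametric tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.signal import hilbert

from .errors import ConfigurationError
from .model import TimeWindow, window_indices

__all__ = ["EnvelopeResult", "am_envelope", "beta_rebound", "max_reactive_channel"]

#: Width (s) of the envelope edge region affected by Hilbert transients.
EDGE_UNRELIABLE_S = 0.25


@dataclass
class EnvelopeResult:
    """Envelope plus the scalar beta-rebound read-out for one channel."""

    envelope: np.ndarray
    br_amplitude: float
    br_latency_s: float
    ref_mean: float
    channel_label: Optional[str] = None


def am_envelope(m_bp) -> np.ndarray:
    """Analytic-signal magnitude along the last axis.

    Satisfies ``m(t) >= |M_BP(t)|`` up to numerical tolerance at every
    sample and is exactly scale-equivariant: ``am_envelope(a*x) ==
    a*am_envelope(x)`` for ``a > 0``.
    """
    x = np.asarray(m_bp, dtype=float)
    return np.abs(hilbert(x, axis=-1))


def beta_rebound(
    envelope,
    fs: float,
    t0_offset: float,
    post: TimeWindow,
    ref: TimeWindow,
) -> EnvelopeResult:
    """BR amplitude and latency of one envelope.

    BR = max of the envelope over the post-movement window minus the mean
    over the reference window (may be negative).  Ties in the maximum break
    toward the earliest sample.
    """
    m = np.asarray(envelope, dtype=float)
    if m.ndim != 1:
        raise ConfigurationError("beta_rebound expects a single-channel envelope")
    p0, p1 = window_indices(post, fs, t0_offset, m.size)
    r0, r1 = window_indices(ref, fs, t0_offset, m.size)
    ref_mean = float(np.mean(m[r0:r1]))
    seg = m[p0:p1]
    peak = int(np.argmax(seg))  # first occurrence = earliest tie
    return EnvelopeResult(
        envelope=m,
        br_amplitude=float(seg[peak] - ref_mean),
        br_latency_s=t0_offset + (p0 + peak) / fs,
        ref_mean=ref_mean,
    )


def max_reactive_channel(
    envelopes,
    channel_labels: Sequence[str],
    fs: float,
    t0_offset: float,
    post: TimeWindow,
    ref: TimeWindow,
) -> Tuple[str, EnvelopeResult]:
    """Channel with the largest beta rebound and its result.

    Ties break deterministically toward the earlier channel in montage
    order.
    """
    env = np.atleast_2d(np.asarray(envelopes, dtype=float))
    labels = list(channel_labels)
    if env.shape[0] == 0:
        raise ConfigurationError("no envelopes supplied")
    if env.shape[0] != len(labels):
        raise ConfigurationError("one label per envelope row required")
    best: Tuple[str, EnvelopeResult] | None = None
    for label, row in zip(labels, env):
        res = beta_rebound(row, fs, t0_offset, post, ref)
        res.channel_label = label
        if best is None or res.br_amplitude > best[1].br_amplitude:
            best = (label, res)
    return best
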