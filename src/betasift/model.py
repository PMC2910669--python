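"""Core containers and epoch I/O.

Conventions used throughout the package:

* An epoch is an ``M x N`` matrix of channel signals in microvolts, with a
  time axis anchored to the task event: sample ``k`` sits at
  ``t = t0_offset + k / fs`` seconds, negative times preceding the event.
* Analysis windows are half-open ``[start, end)`` in event-relative seconds,
  so a 1-s window at 1000 Hz always covers exactly 1000 samples.
* The native on-disk epoch container is plain text: a commented header
  (sampling rate, event offset, channel labels) followed by one
  tab-separated row per channel, written with enough digits to round-trip
  float64 exactly.  EDF is supported read-only through :mod:`mne`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import (
    BoundsError,
    ConfigurationError,
    EpochValidationError,
    ParseError,
)

__all__ = [
    "EEGEpoch",
    "TimeWindow",
    "BandSpec",
    "IMFSet",
    "SpatialMap",
    "SpatialTemplate",
    "TrialResult",
    "read_epoch",
    "write_epoch",
    "window_indices",
    "window_slice",
    "reject_artifact_epoch",
]

_MAGIC = "betasift-epoch v1"


@dataclass(frozen=True)
class TimeWindow:
    """Half-open time interval ``[start_s, end_s)`` relative to the event."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ConfigurationError(
                f"window start ({self.start_s}) must precede end ({self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class BandSpec:
    """Contiguous frequency interval ``[f_lo, f_hi]`` in Hz."""

    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_lo < self.f_hi):
            raise ConfigurationError(
                f"band must satisfy 0 < f_lo < f_hi, got [{self.f_lo}, {self.f_hi}]"
            )

    @property
    def width_hz(self) -> float:
        return self.f_hi - self.f_lo

    @property
    def center_hz(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)


@dataclass
class EEGEpoch:
    """One event-locked multichannel EEG epoch.

    Parameters
    ----------
    data
        ``M x N`` array, microvolts; one row per channel.
    channel_labels
        ``M`` 10-20-style names (e.g. ``"C3"``), one per row.
    fs
        Sampling rate in Hz.
    t0_offset
        Time (s) of sample index 0 relative to the event; negative means the
        epoch starts before the event.
    """

    data: np.ndarray
    channel_labels: tuple
    fs: float
    t0_offset: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(str(c) for c in self.channel_labels)
        if self.data.ndim != 2:
            raise EpochValidationError("data must be a 2-D channels-by-samples array")
        m, n = self.data.shape
        if m < 2 or n < 2:
            raise EpochValidationError(f"need at least 2 channels and 2 samples, got {m}x{n}")
        if len(self.channel_labels) != m:
            raise EpochValidationError(
                f"{len(self.channel_labels)} labels for {m} channel rows"
            )
        if not self.fs > 0:
            raise EpochValidationError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise EpochValidationError("epoch contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def t_start(self) -> float:
        return self.t0_offset

    @property
    def t_end(self) -> float:
        """End of the epoch span (exclusive, half-open)."""
        return self.t0_offset + self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0_offset + np.arange(self.n_samples) / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ConfigurationError(
                f"channel {label!r} not in montage {self.channel_labels}"
            ) from None

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]


@dataclass
class IMFSet:
    """Result of one empirical mode decomposition.

    ``imfs`` are ordered as extracted (highest characteristic frequency
    first); ``residue`` is the final monotonic trend.  Completeness —
    ``sum(imfs) + residue == source_signal`` — is an algebraic identity of
    the sifting recursion and is verified on construction.
    """

    imfs: list
    residue: np.ndarray
    source_signal: np.ndarray
    stoppage_eps: float
    termination: str = "monotonic"
    sift_counts: tuple = ()

    def __post_init__(self) -> None:
        self.residue = np.asarray(self.residue, dtype=float)
        self.source_signal = np.asarray(self.source_signal, dtype=float)
        self.imfs = [np.asarray(c, dtype=float) for c in self.imfs]
        n = self.source_signal.size
        for k, c in enumerate(self.imfs):
            if c.size != n:
                raise EpochValidationError(f"IMF {k + 1} length {c.size} != source length {n}")
        if self.residue.size != n:
            raise EpochValidationError("residue length differs from source length")
        recon = self.residue + (np.sum(self.imfs, axis=0) if self.imfs else 0.0)
        denom = np.linalg.norm(self.source_signal)
        err = np.linalg.norm(recon - self.source_signal)
        if denom > 0 and err / denom > 1e-8:
            raise EpochValidationError(
                f"decomposition is not complete: relative L2 error {err / denom:.3g}"
            )

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def as_matrix(self) -> np.ndarray:
        """IMFs stacked into a J x N matrix (extraction order)."""
        if not self.imfs:
            return np.empty((0, self.source_signal.size))
        return np.vstack(self.imfs)


@dataclass
class SpatialMap:
    """Per-channel correlation weights of one IMF (its scalp distribution)."""

    weights: np.ndarray
    channel_labels: tuple

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.weights.ndim != 1 or self.weights.size != len(self.channel_labels):
            raise EpochValidationError("one weight per channel label required")
        if np.any(np.abs(self.weights) > 1.0 + 1e-9):
            raise EpochValidationError("spatial-map weights must lie in [-1, 1]")


@dataclass
class SpatialTemplate:
    """Per-channel template weights (conventional-ERS beta rebounds, uV)."""

    weights: np.ndarray
    channel_labels: tuple
    ci_label: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.channel_labels = tuple(str(c) for c in self.channel_labels)
        if self.weights.ndim != 1 or self.weights.size != len(self.channel_labels):
            raise EpochValidationError("one template weight per channel label required")
        if np.ptp(self.weights) == 0.0:
            raise EpochValidationError(
                "template is constant; template matching would be undefined"
            )
        if self.ci_label not in self.channel_labels:
            raise ConfigurationError(
                f"channel of interest {self.ci_label!r} missing from template montage"
            )


@dataclass
class TrialResult:
    """Everything the single-trial pipeline decided about one epoch.

    ``selected_imfs`` uses 1-based IMF numbering (IMF1 = first extracted).
    ``qc`` is one of ``"ok"``, ``"artifact"``, ``"no-band"``, ``"degenerate"``;
    quantitative fields are ``None`` for non-``"ok"`` trials.
    """

    trial_index: int
    qc: str
    selected_imfs: tuple = ()
    correlations: tuple = ()
    band: Optional[BandSpec] = None
    reconstructed: Optional[np.ndarray] = None
    envelope: Optional[np.ndarray] = None
    br_amplitude: Optional[float] = None
    br_latency_s: Optional[float] = None
    br_channel: Optional[str] = None


# ---------------------------------------------------------------------------
# Window arithmetic
# ---------------------------------------------------------------------------

def window_indices(win: TimeWindow, fs: float, t0_offset: float, n_samples: int):
    """Map a half-open time window to sample indices ``(i0, i1)``.

    Raises :class:`BoundsError` if the window is not fully inside the span.
    """
    i0 = int(round((win.start_s - t0_offset) * fs))
    i1 = i0 + int(round(win.duration_s * fs))
    if i0 < 0 or i1 > n_samples:
        raise BoundsError(
            f"window [{win.start_s}, {win.end_s}) s outside epoch span "
            f"[{t0_offset}, {t0_offset + n_samples / fs}) s"
        )
    return i0, i1


def window_slice(epoch: EEGEpoch, win: TimeWindow) -> np.ndarray:
    """Samples of ``epoch`` whose event-relative time lies in ``[start, end)``."""
    i0, i1 = window_indices(win, epoch.fs, epoch.t0_offset, epoch.n_samples)
    return epoch.data[:, i0:i1]


# ---------------------------------------------------------------------------
# Artifact gating
# ---------------------------------------------------------------------------

def reject_artifact_epoch(
    epoch: EEGEpoch,
    eog_labels: Sequence[str] = ("VEOG", "HEOG"),
    threshold_uv: float = 100.0,
) -> bool:
    """Return ``True`` (keep) iff every EOG channel stays below threshold.

    A trial is dropped when any EOG channel's peak absolute amplitude reaches
    ``threshold_uv`` (default 100 uV).
    """
    if not eog_labels:
        raise ConfigurationError("at least one EOG label is required")
    for label in eog_labels:
        if label not in epoch.channel_labels:
            raise ConfigurationError(f"EOG channel {label!r} not in montage")
        if np.max(np.abs(epoch.channel(label))) >= threshold_uv:
            return False
    return True


# ---------------------------------------------------------------------------
# Epoch I/O
# ---------------------------------------------------------------------------

def write_epoch(path, epoch: EEGEpoch) -> None:
    """Write an epoch in the native text container (exact float round-trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {_MAGIC}\n")
        fh.write(f"# fs_hz = {epoch.fs!r}\n")
        fh.write(f"# t0_offset_s = {epoch.t0_offset!r}\n")
        fh.write("# channels = " + ",".join(epoch.channel_labels) + "\n")
        np.savetxt(fh, epoch.data, fmt="%.17g", delimiter="\t")


def _read_native(path) -> EEGEpoch:
    header = {}
    n_header = 0
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if _MAGIC not in first:
            raise ParseError(f"{path}: missing container signature line '# {_MAGIC}'")
        n_header = 1
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                header[key.strip()] = value.strip()
    for key in ("fs_hz", "t0_offset_s", "channels"):
        if key not in header:
            raise ParseError(f"{path}: header field {key!r} is missing")
    try:
        fs = float(header["fs_hz"])
        t0 = float(header["t0_offset_s"])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric header field ({exc})") from None
    labels = [c for c in header["channels"].split(",") if c]
    try:
        data = np.loadtxt(path, delimiter="\t", skiprows=n_header, ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: malformed sample block ({exc})") from None
    return EEGEpoch(data=data, channel_labels=labels, fs=fs, t0_offset=t0)


def _read_edf(path, t0_offset: float) -> EEGEpoch:
    import mne  # deferred: import is slow and only EDF ingestion needs it

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return EEGEpoch(
        data=data_uv,
        channel_labels=list(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        t0_offset=t0_offset,
    )


def read_epoch(path, format: str = "matrix", t0_offset: float = 0.0) -> EEGEpoch:
    """Read an epoch from disk.

    Parameters
    ----------
    format
        ``"matrix"`` for the native text container (round-trips bit-exactly
        with :func:`write_epoch`), or ``"edf"`` for European Data Format.
        EDF carries no event anchor, so ``t0_offset`` must be supplied by the
        caller for EDF input; for the native container it is stored in the
        header and the argument is ignored.
    """
    if format == "matrix":
        return _read_native(path)
    if format == "edf":
        return _read_edf(path, t0_offset)
    raise ConfigurationError(f"unknown epoch format {format!r}")
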