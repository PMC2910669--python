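"""Spatial-template selection of task-relevant IMFs.

Every IMF extracted from the channel of interest (CI) is given a *spatial
map*: the vector of Pearson correlations between the IMF and each channel
of the epoch, i.e. its scalp weight distribution.  Maps are matched to a
spatial template (per-channel conventional-ERS beta rebounds) by Pearson
correlation; the resulting ``J`` correlation values are split into highly-,
middle- and lowly-correlated groups with an exact 1-D 3-means, and only
the high group is kept for reconstruction.

The 3-means is solved by exhaustive optimization over contiguous
partitions of the sorted values (optimal 1-D clusters are contiguous), so
the result is deterministic and globally optimal — no random restarts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, DegenerateInputError, SelectionError
from .model import EEGEpoch, IMFSet, SpatialMap, SpatialTemplate

__all__ = [
    "ClusterAssignment",
    "SelectionDiagnostics",
    "spatial_map",
    "template_correlation",
    "cluster_correlations",
    "select_imfs",
    "reconstruct",
    "read_template",
    "write_template",
    "FALLBACK_RHO_FLOOR",
]

#: Minimum template correlation accepted by the J < 3 fallback rule.
FALLBACK_RHO_FLOOR = 0.5

_TEMPLATE_MAGIC = "betasift-template v1"


@dataclass
class ClusterAssignment:
    """Exact 1-D 3-means result over the template correlations.

    ``labels[i]`` is ``"high"``, ``"middle"`` or ``"low"`` for the i-th
    input value; ``centroids`` maps each label to its cluster mean and
    ``objective`` is the minimized within-cluster sum of squares.
    """

    labels: tuple
    centroids: dict
    objective: float

    def indices(self, label: str) -> tuple:
        return tuple(i for i, lab in enumerate(self.labels) if lab == label)


@dataclass
class SelectionDiagnostics:
    """Audit trail of one IMF-selection decision."""

    correlations: tuple
    assignment: Optional[ClusterAssignment]
    fallback: bool


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise DegenerateInputError("zero-variance input to correlation")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def spatial_map(epoch: EEGEpoch, imf) -> SpatialMap:
    """Correlate one IMF against every channel of the epoch.

    Entry ``i`` is the Pearson correlation between channel row ``b_i`` and
    the IMF.  A constant channel or constant IMF makes the correlation
    undefined and raises :class:`DegenerateInputError` naming the culprit.
    """
    c = np.asarray(imf, dtype=float)
    if c.size != epoch.n_samples:
        raise ConfigurationError(
            f"IMF length {c.size} does not match epoch length {epoch.n_samples}"
        )
    c = c - c.mean()
    nc = np.linalg.norm(c)
    if nc == 0.0:
        raise DegenerateInputError("IMF has zero variance")
    X = epoch.data - epoch.data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    bad = np.flatnonzero(norms == 0.0)
    if bad.size:
        raise DegenerateInputError(
            f"zero-variance channel {epoch.channel_labels[bad[0]]!r}"
        )
    weights = np.clip(X @ c / (norms * nc), -1.0, 1.0)
    return SpatialMap(weights=weights, channel_labels=epoch.channel_labels)


def template_correlation(map_: SpatialMap, template: SpatialTemplate) -> float:
    """Pearson correlation between a spatial map and the template."""
    if map_.channel_labels != template.channel_labels:
        raise ConfigurationError("spatial map and template montages differ")
    return _pearson(map_.weights, template.weights)


def _contiguous_3means(values: np.ndarray):
    """Globally optimal contiguous 3-partition of sorted 1-D values.

    Returns ``(cuts, objective)`` where ``cuts = (i, j)`` split the sorted
    array into ``[0, i)``, ``[i, j)``, ``[j, J)``.
    """
    v = np.sort(values)
    j_total = v.size
    c1 = np.concatenate([[0.0], np.cumsum(v)])
    c2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def sse(a: int, b: int) -> float:
        s = c1[b] - c1[a]
        q = c2[b] - c2[a]
        return q - s * s / (b - a)

    best = (None, np.inf)
    for i in range(1, j_total - 1):
        left = sse(0, i)
        for j in range(i + 1, j_total):
            obj = left + sse(i, j) + sse(j, j_total)
            if obj < best[1] - 1e-15:
                best = ((i, j), obj)
    return best


def cluster_correlations(rhos: Sequence[float]) -> ClusterAssignment:
    """Split ``J >= 3`` correlation values into high/middle/low groups.

    Exact 1-D 3-means: the optimal partition is contiguous in sorted order,
    so all ``(i, j)`` cut pairs are scored by within-cluster sum of squares
    and the global minimum taken.  Labels are assigned by descending
    centroid.  All-identical values are degenerate (no meaningful grouping).
    """
    v = np.asarray(list(rhos), dtype=float)
    if v.size < 3:
        raise ConfigurationError(f"need at least 3 values to form 3 clusters, got {v.size}")
    if np.ptp(v) == 0.0:
        raise DegenerateInputError("all correlation values identical; clustering undefined")
    (cuts, objective) = _contiguous_3means(v)
    i, j = cuts
    order = np.argsort(v, kind="stable")
    sorted_labels = np.empty(v.size, dtype=object)
    sorted_labels[:i] = "low"
    sorted_labels[i:j] = "middle"
    sorted_labels[j:] = "high"
    labels = np.empty(v.size, dtype=object)
    labels[order] = sorted_labels
    sv = v[order]
    centroids = {
        "low": float(np.mean(sv[:i])),
        "middle": float(np.mean(sv[i:j])),
        "high": float(np.mean(sv[j:])),
    }
    return ClusterAssignment(
        labels=tuple(labels), centroids=centroids, objective=float(objective)
    )


def select_imfs(
    imfset: IMFSet, epoch: EEGEpoch, template: SpatialTemplate
) -> Tuple[tuple, SelectionDiagnostics]:
    """Pick the sensorimotor-related IMFs of one decomposed trial.

    Returns the 0-based indices of the IMFs in the highly-correlated group
    together with diagnostics (all correlations and the cluster assignment).
    With fewer than three IMFs the 3-means is impossible and a fallback
    applies: the single best IMF is taken provided its correlation reaches
    :data:`FALLBACK_RHO_FLOOR`, otherwise the trial is flagged unusable.

    Raises
    ------
    SelectionError
        When no usable selection exists (no IMFs, identical correlations,
        degenerate maps, or fallback below the floor).
    """
    if imfset.n_imfs == 0:
        raise SelectionError("decomposition produced no IMFs")
    if epoch.channel_labels != template.channel_labels:
        raise ConfigurationError("epoch montage does not match template montage")
    try:
        rhos = tuple(
            template_correlation(spatial_map(epoch, c), template) for c in imfset.imfs
        )
    except DegenerateInputError as exc:
        raise SelectionError(f"degenerate spatial map: {exc}") from exc

    if imfset.n_imfs >= 3:
        try:
            assignment = cluster_correlations(rhos)
        except DegenerateInputError as exc:
            raise SelectionError(str(exc)) from exc
        s1 = assignment.indices("high")
        return s1, SelectionDiagnostics(rhos, assignment, fallback=False)

    best = int(np.argmax(rhos))
    if rhos[best] < FALLBACK_RHO_FLOOR:
        raise SelectionError(
            f"only {imfset.n_imfs} IMFs and best correlation {rhos[best]:.2f} "
            f"below floor {FALLBACK_RHO_FLOOR}"
        )
    return (best,), SelectionDiagnostics(rhos, None, fallback=True)


def reconstruct(
    imfset: IMFSet,
    s1: Sequence[int],
    mode: str = "multichannel",
    epoch: Optional[EEGEpoch] = None,
) -> np.ndarray:
    """Rebuild noise-suppressed activity from the chosen IMFs.

    ``mode="ci"`` returns the plain sum of the chosen IMFs (the CI-channel
    reading).  ``mode="multichannel"`` projects every channel onto each
    chosen IMF by least squares — channel ``i`` becomes
    ``sum_k beta(i, k) * c_k`` with ``beta(i, k) = cov(b_i, c_k) / var(c_k)``
    — giving an ``M x N`` matrix whose CI row agrees with ``ci`` mode when
    the IMFs are mutually near-orthogonal.
    """
    s1 = tuple(int(k) for k in s1)
    if not s1:
        raise SelectionError("cannot reconstruct from an empty IMF selection")
    if any(k < 0 or k >= imfset.n_imfs for k in s1):
        raise ConfigurationError(f"IMF indices {s1} out of range 0..{imfset.n_imfs - 1}")
    C = np.vstack([imfset.imfs[k] for k in s1])
    if mode == "ci":
        return C.sum(axis=0)
    if mode != "multichannel":
        raise ConfigurationError(f"unknown reconstruction mode {mode!r}")
    if epoch is None:
        raise ConfigurationError("multichannel reconstruction requires the epoch")
    Cc = C - C.mean(axis=1, keepdims=True)
    var = np.sum(Cc * Cc, axis=1)
    if np.any(var == 0.0):
        raise DegenerateInputError("chosen IMF has zero variance")
    Bc = epoch.data - epoch.data.mean(axis=1, keepdims=True)
    beta = (Bc @ Cc.T) / var  # M x K
    return beta @ C


# ---------------------------------------------------------------------------
# Template file format: tab-separated (channel, weight) pairs + CI metadata
# ---------------------------------------------------------------------------

def write_template(path, template: SpatialTemplate) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {_TEMPLATE_MAGIC}\n")
        fh.write(f"# ci_label = {template.ci_label}\n")
        fh.write("channel\tweight\n")
        for label, w in zip(template.channel_labels, template.weights):
            fh.write(f"{label}\t{float(w)!r}\n")


def read_template(path) -> SpatialTemplate:
    from .errors import ParseError

    ci_label = None
    labels: list = []
    weights: list = []
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if _TEMPLATE_MAGIC not in first:
            raise ParseError(f"{path}: missing template signature '# {_TEMPLATE_MAGIC}'")
        for line in fh:
            line = line.strip()
            if not line or line == "channel\tweight":
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("ci_label"):
                    ci_label = body.partition("=")[2].strip()
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: malformed template row {line!r}")
            labels.append(parts[0])
            try:
                weights.append(float(parts[1]))
            except ValueError:
                raise ParseError(f"{path}: non-numeric weight in row {line!r}") from None
    if ci_label is None:
        raise ParseError(f"{path}: header field 'ci_label' is missing")
    return SpatialTemplate(weights=np.array(weights), channel_labels=labels, ci_label=ci_label)
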