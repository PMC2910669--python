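"""Shared fixtures: fast simulator configs and a minimal EDF writer."""

import struct

import numpy as np
import pytest

from betasift import SimConfig, SourceSpec, SpatialTemplate, forward_weights
from betasift.synthetic import MONTAGE_32


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def truth_template():
    """Template equal to the ground-truth forward pattern (ideal matching)."""
    return SpatialTemplate(
        weights=forward_weights(), channel_labels=MONTAGE_32, ci_label="C3"
    )


@pytest.fixture
def fast_cfg():
    """Low-rate simulator config for unit tests (windows still span [-4, 3))."""
    return SimConfig(fs=250.0, n_trials=6, seed=17)


def write_minimal_edf(path, data_uv, fs, labels):
    """Write a bare-bones EDF file (synthetic test fixture, 16-bit).

    Independent of the package's EDF reader: plain struct packing of the
    EDF header plus one data record per second.
    """
    data_uv = np.asarray(data_uv, dtype=float)
    ns, n = data_uv.shape
    spr = int(fs)  # samples per 1-s record
    assert n % spr == 0, "test fixture wants whole 1-s records"
    n_rec = n // spr
    pmin = data_uv.min(axis=1)
    pmax = data_uv.max(axis=1)
    pmax = np.where(pmax > pmin, pmax, pmin + 1.0)

    def pad(s, width):
        s = str(s)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X", 80), pad("X", 80),
        pad("01.01.20", 8), pad("10.00.00", 8),
        pad(256 * (ns + 1), 8), pad("", 44), pad(n_rec, 8), pad(1, 8), pad(ns, 4),
    ])
    header += b"".join(pad(lab, 16) for lab in labels)
    header += b"".join(pad("", 80) for _ in range(ns))
    header += b"".join(pad("uV", 8) for _ in range(ns))
    header += b"".join(pad(f"{v:.6g}", 8) for v in pmin)
    header += b"".join(pad(f"{v:.6g}", 8) for v in pmax)
    header += b"".join(pad(-32768, 8) for _ in range(ns))
    header += b"".join(pad(32767, 8) for _ in range(ns))
    header += b"".join(pad("", 80) for _ in range(ns))
    header += b"".join(pad(spr, 8) for _ in range(ns))
    header += b"".join(pad("", 32) for _ in range(ns))

    scale = (pmax - pmin) / 65535.0
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for i in range(ns):
                seg = data_uv[i, r * spr:(r + 1) * spr]
                dig = np.round((seg - pmin[i]) / scale[i]) - 32768
                fh.write(struct.pack(f"<{spr}h", *dig.astype(int)))
    return scale  # per-channel quantization step, for tolerance checks


@pytest.fixture
def edf_writer():
    return write_minimal_edf


def in_window_source(rebound_uv=2.0):
    """Source spec whose rebound peak always lies inside the scoring window."""
    return SourceSpec(
        rebound_uv=rebound_uv, latency_mean_s=1.0, latency_sd_s=0.2,
        latency_bounds_s=(0.6, 1.4),
    )
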