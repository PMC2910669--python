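"""Spatial maps, template matching, exact 1-D 3-means, reconstruction."""

import itertools

import numpy as np
import pytest
from scipy import signal as sps
from scipy.stats import spearmanr

from betasift import (
    EEGEpoch,
    IMFSet,
    SpatialTemplate,
    cluster_correlations,
    emd_decompose,
    reconstruct,
    select_imfs,
    spatial_map,
    template_correlation,
)
from betasift.errors import ConfigurationError, DegenerateInputError, SelectionError
from betasift.spatial_select import read_template, write_template
from betasift.synthetic import MONTAGE_32, forward_weights

#: The nine template correlations of the worked single-trial example.
WORKED_RHOS = [0.24, 0.35, 0.62, 0.81, 0.30, -0.03, 0.24, 0.33, 0.40]


def brute_force_3means(values):
    """Independent oracle: plain-Python search over contiguous 3-partitions."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    v = [values[i] for i in order]
    best = (None, float("inf"))
    for i in range(1, len(v) - 1):
        for j in range(i + 1, len(v)):
            parts = (v[:i], v[i:j], v[j:])
            sse = 0.0
            for p in parts:
                mu = sum(p) / len(p)
                sse += sum((x - mu) ** 2 for x in p)
            if sse < best[1] - 1e-15:
                best = ((i, j), sse)
    (i, j), sse = best
    return set(order[j:]), sse  # indices of the top cluster, objective


def exhaustive_any_partition(values):
    """All (not only contiguous) 3-labelings; returns the minimal objective."""
    best = float("inf")
    for labels in itertools.product(range(3), repeat=len(values)):
        if len(set(labels)) < 3:
            continue
        sse = 0.0
        for g in range(3):
            grp = [v for v, lab in zip(values, labels) if lab == g]
            mu = sum(grp) / len(grp)
            sse += sum((x - mu) ** 2 for x in grp)
        best = min(best, sse)
    return best


def _epoch_from(data):
    return EEGEpoch(data, MONTAGE_32[: data.shape[0]], 1000.0, 0.0)


class TestSpatialMap:
    def test_ci_row_identical_to_imf_correlates_perfectly(self, rng):
        imf = np.sin(2 * np.pi * 20 * np.arange(2000) / 1000.0)
        data = rng.standard_normal((4, 2000))
        data[2] = imf
        m = spatial_map(_epoch_from(data), imf)
        assert m.weights[2] == pytest.approx(1.0)
        assert np.all(np.abs(m.weights) <= 1.0)

    def test_forward_pattern_recovered_at_snr_10(self, rng):
        imf = np.sin(2 * np.pi * 20 * np.arange(4000) / 1000.0)
        w = rng.uniform(-1.0, 1.0, size=8)
        data = np.outer(w, imf)
        data += rng.standard_normal(data.shape) * (imf.std() * np.abs(w).mean() / np.sqrt(10))
        m = spatial_map(_epoch_from(data), imf)
        assert np.all(np.sign(m.weights) == np.sign(w))
        rho, _ = spearmanr(m.weights, w)
        assert rho > 0.9

    def test_constant_channel_is_named_in_error(self, rng):
        data = rng.standard_normal((4, 500))
        data[1] = 5.0
        with pytest.raises(DegenerateInputError, match=MONTAGE_32[1]):
            spatial_map(_epoch_from(data), data[0])


class TestTemplateCorrelation:
    def test_identity_and_antisymmetry(self, rng):
        from betasift.model import SpatialMap

        w = rng.uniform(0.1, 1.0, 8)
        tpl = SpatialTemplate(w, MONTAGE_32[:8], MONTAGE_32[0])
        m = SpatialMap(w / w.max(), MONTAGE_32[:8])
        assert template_correlation(m, tpl) == pytest.approx(1.0)
        m_neg = SpatialMap(-w / w.max(), MONTAGE_32[:8])
        assert template_correlation(m_neg, tpl) == pytest.approx(-1.0)

    def test_affine_invariance_of_matching(self, rng):
        from betasift.model import SpatialMap

        base = rng.standard_normal(12)
        tpl = SpatialTemplate(rng.standard_normal(12), MONTAGE_32[:12], MONTAGE_32[0])
        m1 = SpatialMap(np.clip(base, -1, 1), MONTAGE_32[:12])
        rho1 = template_correlation(m1, tpl)
        scaled = SpatialTemplate(3.7 * tpl.weights + 0.41, MONTAGE_32[:12], MONTAGE_32[0])
        assert template_correlation(m1, scaled) == pytest.approx(rho1)


class TestClusterCorrelations:
    def test_worked_example_high_cluster(self):
        a = cluster_correlations(WORKED_RHOS)
        assert set(a.indices("high")) == {2, 3}  # 0.62 and 0.81 (IMF3, IMF4)
        assert min(WORKED_RHOS[i] for i in a.indices("high")) == pytest.approx(0.62)
        assert a.centroids["high"] > a.centroids["middle"] > a.centroids["low"]

    def test_perfectly_separated_groups_have_zero_objective(self):
        a = cluster_correlations([1, 1, 1, 0, 0, 0, -1, -1, -1])
        assert a.objective == pytest.approx(0.0)
        assert set(a.indices("high")) == {0, 1, 2}
        assert set(a.indices("low")) == {6, 7, 8}

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(40):
            j = int(rng.integers(3, 13))
            v = rng.uniform(-1, 1, size=j)
            a = cluster_correlations(v)
            oracle_high, oracle_obj = brute_force_3means(list(v))
            assert set(a.indices("high")) == oracle_high
            assert a.objective == pytest.approx(oracle_obj)

    def test_contiguity_lemma_against_full_enumeration(self, rng):
        for _ in range(10):
            v = rng.uniform(-1, 1, size=6)
            a = cluster_correlations(v)
            assert a.objective == pytest.approx(exhaustive_any_partition(list(v)))

    def test_centroid_ordering_is_strict_for_distinct_values(self, rng):
        for _ in range(20):
            v = rng.uniform(-1, 1, size=int(rng.integers(3, 10)))
            a = cluster_correlations(v)
            assert a.centroids["high"] > a.centroids["middle"] > a.centroids["low"]

    def test_degenerate_and_undersized_inputs(self):
        with pytest.raises(DegenerateInputError):
            cluster_correlations([0.5, 0.5, 0.5])
        with pytest.raises(ConfigurationError):
            cluster_correlations([0.1, 0.2])


class TestSelectImfs:
    def _imfset(self, imfs, source=None):
        imfs = [np.asarray(c, float) for c in imfs]
        if source is None:
            source = np.sum(imfs, axis=0)
        return IMFSet(imfs=imfs, residue=source - np.sum(imfs, axis=0),
                      source_signal=source, stoppage_eps=0.2)

    def _template(self):
        return SpatialTemplate(forward_weights(), MONTAGE_32, "C3")

    def test_template_aligned_imf_selected(self, rng, truth_template):
        t = np.arange(4000) / 1000.0
        w = forward_weights()
        src = np.sin(2 * np.pi * 20 * t)
        others = [np.sin(2 * np.pi * f * t + rng.uniform(0, 6)) for f in (60.0, 7.0, 3.0)]
        data = np.outer(w, src) + rng.standard_normal((32, 4000)) * 0.3
        for o in others:
            data += np.outer(rng.uniform(0, 0.4, 32), o)
        epoch = EEGEpoch(data, MONTAGE_32, 1000.0, 0.0)
        imfset = self._imfset([src] + others)
        s1, diag = select_imfs(imfset, epoch, truth_template)
        assert 0 in s1
        assert diag.correlations[0] == max(diag.correlations)

    def test_two_imf_fallback_rules(self, rng, truth_template):
        t = np.arange(2000) / 1000.0
        src = np.sin(2 * np.pi * 20 * t)
        other = np.sin(2 * np.pi * 3 * t)
        data = np.outer(forward_weights(), src) + rng.standard_normal((32, 2000)) * 0.1
        epoch = EEGEpoch(data, MONTAGE_32, 1000.0, 0.0)
        s1, diag = select_imfs(self._imfset([src, other]), epoch, truth_template)
        assert s1 == (0,) and diag.fallback

    def test_fallback_below_floor_flags_trial(self, rng, truth_template):
        data = rng.standard_normal((32, 2000))
        epoch = EEGEpoch(data, MONTAGE_32, 1000.0, 0.0)
        imfs = [rng.standard_normal(2000), rng.standard_normal(2000)]
        with pytest.raises(SelectionError):
            select_imfs(self._imfset(imfs), epoch, truth_template)

    def test_identical_correlations_flag_trial(self, rng, truth_template):
        c = np.sin(2 * np.pi * 10 * np.arange(2000) / 1000.0)
        data = np.outer(forward_weights(), c) + rng.standard_normal((32, 2000)) * 0.05
        epoch = EEGEpoch(data, MONTAGE_32, 1000.0, 0.0)
        with pytest.raises(SelectionError):
            select_imfs(self._imfset([c, c, c], source=3 * c), epoch, truth_template)


class TestReconstruct:
    def test_all_imfs_plus_residue_restore_signal(self, rng):
        x = rng.standard_normal(3000)
        d = emd_decompose(x)
        recon = reconstruct(d, range(d.n_imfs), mode="ci") + d.residue
        assert np.linalg.norm(recon - x) <= 1e-8 * np.linalg.norm(x)

    def test_empty_selection_is_an_error(self, rng):
        d = emd_decompose(rng.standard_normal(1000))
        with pytest.raises(SelectionError):
            reconstruct(d, (), mode="ci")

    def test_noiseless_multichannel_projection_recovers_forward_weights(self):
        t = np.arange(4000) / 1000.0
        src = np.sin(2 * np.pi * 20 * t) * (1 + 0.5 * np.sin(2 * np.pi * 0.5 * t))
        w = forward_weights()
        keep = w > 1e-6
        data = np.outer(w, src)
        data[~keep] = np.sin(2 * np.pi * 3 * t) * 0.1  # EOG rows need variance
        epoch = EEGEpoch(data, MONTAGE_32, 1000.0, 0.0)
        d = IMFSet(imfs=[src], residue=np.zeros_like(src), source_signal=src,
                   stoppage_eps=0.2)
        recon = reconstruct(d, (0,), mode="multichannel", epoch=epoch)
        np.testing.assert_allclose(recon[keep], data[keep], atol=1e-9)

    def test_widespread_interference_suppressed_by_20_db(self, rng, truth_template):
        t = np.arange(7000) / 1000.0 - 4.0
        w = forward_weights()
        src = 2.0 * np.sin(2 * np.pi * 20 * t)
        line = 3.0 * np.sin(2 * np.pi * 60 * t)
        data = (np.outer(w, src)
                + np.outer(rng.uniform(0.7, 1.3, 32), line)
                + rng.standard_normal((32, 7000)) * 0.5)
        epoch = EEGEpoch(data, MONTAGE_32, 1000.0, -4.0)
        ci = epoch.channel_index("C3")
        d = emd_decompose(epoch.data[ci])
        s1, _ = select_imfs(d, epoch, truth_template)
        recon = reconstruct(d, s1, mode="ci")

        def p60(x):
            f, p = sps.periodogram(x, fs=1000.0)
            band = (f >= 58) & (f <= 62)
            return np.trapezoid(p[band], f[band])

        assert 10 * np.log10(p60(epoch.data[ci]) / p60(recon)) >= 20.0


class TestTemplateIO:
    def test_round_trip(self, tmp_path):
        tpl = SpatialTemplate(forward_weights(), MONTAGE_32, "C3")
        write_template(tmp_path / "tpl.tsv", tpl)
        back = read_template(tmp_path / "tpl.tsv")
        assert back.ci_label == "C3"
        assert back.channel_labels == tpl.channel_labels
        np.testing.assert_array_equal(back.weights, tpl.weights)
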