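"""Sifting primitives: extrema, envelopes, IMF extraction, decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from betasift import emd_decompose, extract_imf, find_extrema, is_imf, mean_envelope
from betasift.errors import ConfigurationError, InsufficientExtremaError

T1K = np.arange(0, 1, 0.001)


class TestFindExtrema:
    def test_sine_counts_match_closed_form(self):
        mx, mn = find_extrema(np.sin(2 * np.pi * 5 * T1K))
        assert len(mx) == 5 and len(mn) == 5
        assert np.all(np.diff(np.sort(np.concatenate([mx, mn]))) > 0)

    def test_monotone_ramp_has_no_interior_extrema(self):
        mx, mn = find_extrema(np.linspace(0, 1, 500))
        assert len(mx) == 0 and len(mn) == 0

    @pytest.mark.parametrize(
        "sig,expected_max",
        [([0, 1, 1, 0], 1), ([0, 1, 1, 1, 0], 2), ([0, 2, 2, 2, 2, 0], 2)],
    )
    def test_plateau_contributes_single_midpoint(self, sig, expected_max):
        mx, mn = find_extrema(np.asarray(sig, float))
        assert list(mx) == [expected_max]
        assert len(mn) == 0

    def test_endpoints_are_never_extrema(self):
        mx, mn = find_extrema(np.array([5.0, 1.0, 5.0]))
        assert list(mn) == [1] and len(mx) == 0


class TestMeanEnvelope:
    def test_pure_sine_envelope_is_near_zero_in_interior(self):
        a = 2.0
        x = a * np.sin(2 * np.pi * 10 * T1K)
        env = mean_envelope(x, *find_extrema(x))
        interior = slice(50, 950)  # away from the outer 5%
        assert np.max(np.abs(env[interior])) < 0.02 * a

    def test_offset_shifts_envelope_by_constant(self):
        c = 3.7
        x = np.sin(2 * np.pi * 10 * T1K) + c
        env = mean_envelope(x, *find_extrema(x))
        assert np.allclose(env[50:950], c, atol=0.05)

    def test_single_hump_signals_stop(self):
        x = np.exp(-0.5 * ((T1K - 0.5) / 0.1) ** 2)  # 1 max, 0 min
        with pytest.raises(InsufficientExtremaError):
            mean_envelope(x, *find_extrema(x))


class TestExtractImf:
    def test_existing_imf_is_a_fixed_point(self):
        x = np.sin(2 * np.pi * 10 * T1K)
        imf, n_iters = extract_imf(x)
        assert n_iters == 1
        interior = slice(50, 950)
        assert np.corrcoef(imf[interior], x[interior])[0, 1] > 0.9999

    def test_two_tone_first_imf_is_fast_tone(self):
        t = np.arange(0, 5, 0.001)
        x = np.sin(2 * np.pi * 20 * t) + np.sin(2 * np.pi * 2 * t)
        imf, _ = extract_imf(x)
        interior = slice(250, 4750)
        r = np.corrcoef(imf[interior], np.sin(2 * np.pi * 20 * t)[interior])[0, 1]
        assert r > 0.95

    def test_nonpositive_eps_rejected(self):
        with pytest.raises(ConfigurationError):
            extract_imf(np.sin(T1K), eps=0.0)

    def test_eps_terminated_imf_passes_definition(self, rng):
        imf, _ = extract_imf(rng.standard_normal(3000))
        assert is_imf(imf, tol=0.05)


class TestIsImf:
    def test_canonical_imf(self):
        assert is_imf(np.sin(2 * np.pi * 10 * T1K))

    def test_large_offset_breaks_zero_crossing_parity(self):
        assert not is_imf(np.sin(2 * np.pi * 10 * T1K) + 5.0)

    def test_constant_is_not_an_imf(self):
        assert not is_imf(np.ones(100))


class TestDecompose:
    def test_monotone_ramp_yields_no_imfs(self):
        x = np.linspace(0.0, 1.0, 100)
        d = emd_decompose(x)
        assert d.n_imfs == 0
        np.testing.assert_array_equal(d.residue, x)

    def test_constant_input_yields_no_imfs(self):
        d = emd_decompose(np.full(64, 2.5))
        assert d.n_imfs == 0

    def test_three_component_recovery(self):
        t = np.arange(0, 5, 0.001)
        fast, slow, trend = (
            np.sin(2 * np.pi * 20 * t), np.sin(2 * np.pi * 2 * t), 0.5 * t,
        )
        d = emd_decompose(fast + slow + trend)
        assert d.n_imfs >= 2
        interior = slice(250, 4750)
        assert np.corrcoef(d.imfs[0][interior], fast[interior])[0, 1] > 0.9
        assert np.corrcoef(d.imfs[1][interior], slow[interior])[0, 1] > 0.9
        trend_est = d.residue + sum(d.imfs[2:]) if d.n_imfs > 2 else d.residue
        assert np.corrcoef(trend_est[interior], trend[interior])[0, 1] > 0.99

    def test_decomposition_is_bit_deterministic(self, rng):
        x = rng.standard_normal(2000)
        d1, d2 = emd_decompose(x), emd_decompose(x)
        assert d1.n_imfs == d2.n_imfs
        for a, b in zip(d1.imfs, d2.imfs):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(d1.residue, d2.residue)

    def test_emitted_imfs_pass_definition_and_frequency_ordering(self, rng):
        for _ in range(3):
            x = rng.standard_normal(3000)
            d = emd_decompose(x)
            counts = []
            for c in d.imfs:
                assert is_imf(c, tol=0.05)
                mx, mn = find_extrema(c)
                counts.append(mx.size + mn.size)
            assert all(counts[i + 1] <= counts[i] + 1 for i in range(len(counts) - 1))

    def test_too_short_signal_rejected(self):
        with pytest.raises(ConfigurationError):
            emd_decompose(np.arange(4.0))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    hnp.arrays(
        np.float64,
        st.integers(min_value=64, max_value=256),
        elements=st.floats(-100.0, 100.0, allow_nan=False),
    )
)
def test_completeness_holds_for_arbitrary_finite_signals(x):
    """Sum of IMFs plus residue reproduces any input to ~machine precision."""
    d = emd_decompose(x)
    recon = d.residue + (np.sum(d.imfs, axis=0) if d.imfs else 0.0)
    norm = np.linalg.norm(x)
    err = np.linalg.norm(recon - x)
    assert err <= 1e-8 * max(norm, 1e-12)
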