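"""Clot-trace parameter extraction: examples, identities, oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ricotem import (
    InsufficientSpanError,
    InvalidParameterError,
    InvalidTraceError,
    RotemTrace,
    auc30,
    extract_all,
    extract_cft,
    extract_ct,
    extract_mcf,
    velocity_curve,
)
from ricotem.simulate import (
    PhenotypeParams,
    closed_form_amplitude,
    ground_truth_ct_s,
    simulate_trace,
)

from conftest import brute_force_crossing, random_monotone_trace


def make_trace(times, amps, channel="extem"):
    return RotemTrace(channel, np.asarray(times, float), np.asarray(amps, float))


FLAT_ZERO_30MIN = ([0.0, 900.0, 1800.0, 2100.0], [0.0, 0.0, 0.0, 0.0])


class TestTraceValidation:
    def test_too_short(self):
        with pytest.raises(InvalidTraceError):
            make_trace([0.0], [0.0])

    def test_duplicate_times_rejected(self):
        with pytest.raises(InvalidTraceError):
            make_trace([0.0, 10.0, 10.0], [0.0, 1.0, 2.0])

    def test_negative_amplitude_rejected(self):
        with pytest.raises(InvalidTraceError):
            make_trace([0.0, 10.0], [0.0, -1.0])

    def test_from_samples_dedups_exact_duplicates(self):
        tr = RotemTrace.from_samples("extem", [0, 10, 10, 20], [0, 1, 1, 2])
        assert tr.times_s.size == 3

    def test_from_samples_conflicting_duplicates(self):
        with pytest.raises(InvalidTraceError):
            RotemTrace.from_samples("extem", [0, 10, 10], [0, 1, 2])


class TestClotTimeExtraction:
    def test_flat_zero_never_clots(self):
        assert extract_ct(make_trace(*FLAT_ZERO_30MIN)) is None

    def test_linear_interpolated_crossing(self):
        # 0 mm at t=0, 4 mm at t=100: the 2-mm threshold is crossed at 50 s
        assert extract_ct(make_trace([0, 100], [0, 4])) == pytest.approx(50.0)

    def test_ct_on_noise_free_simulated_trace(self):
        params = PhenotypeParams(noise_cv=0.0)
        tr = simulate_trace(params, "extem")
        expected = ground_truth_ct_s(params, "extem")
        assert extract_ct(tr) == pytest.approx(expected, rel=1e-2)

    def test_cft_absent_for_weak_clot(self):
        # MCF 10 mm: the 20-mm band is never reached (typical after ristocetin)
        assert extract_cft(make_trace([0, 600, 2100], [0, 10, 10])) is None

    def test_cft_linear_ramp(self):
        # 0 -> 40 mm over 0 -> 400 s: crossings at 20 s and 200 s
        assert extract_cft(make_trace([0, 400, 2100], [0, 40, 40])) == pytest.approx(180.0)

    def test_cft_band_must_be_ordered(self):
        with pytest.raises(InvalidParameterError):
            extract_cft(make_trace([0, 100], [0, 30]), low_mm=20, high_mm=2)

    def test_type3_post_ristocetin_clot_barely_affected(self):
        # with no functional VWF, ristocetin removes nothing: CFT stays present
        params = PhenotypeParams(vwf_activity_pct=0.0, noise_cv=0.0)
        tr = simulate_trace(params, "rico")
        assert extract_cft(tr) is not None


class TestMcf:
    @pytest.mark.parametrize(
        "amps,expected",
        [([0, 0, 0, 0], 0.0), ([0, 12, 55, 54], 55.0)],
    )
    def test_examples(self, amps, expected):
        tr = make_trace([0, 600, 1200, 2100], amps)
        assert extract_mcf(tr) == expected

    def test_recovers_configured_plateau(self):
        params = PhenotypeParams(noise_cv=0.0)
        tr = simulate_trace(params, "extem")
        assert extract_mcf(tr) == pytest.approx(60.0, rel=1e-2)


class TestVelocityCurve:
    def test_constant_trace_zero_velocity(self):
        _, v = velocity_curve(make_trace([0, 60, 120], [5, 5, 5]))
        assert np.all(v == 0)

    def test_linear_ramp_constant_velocity(self):
        # slope 6 mm/min = 0.1 mm/s
        _, v = velocity_curve(make_trace([0, 60, 120, 180], [0, 6, 12, 18]))
        assert np.allclose(v, 6.0)

    def test_matches_analytic_derivative_of_exponential(self):
        tau, m = 300.0, 60.0
        t = np.arange(0.0, 2101.0, 1.0)
        tr = make_trace(t, m * (1 - np.exp(-t / tau)))
        mid, v = velocity_curve(tr)
        analytic = m / tau * np.exp(-mid / tau) * 60.0  # mm/min
        assert np.allclose(v, analytic, rtol=1e-4, atol=1e-4)


class TestAuc30:
    def test_flat_zero(self):
        assert auc30(make_trace(*FLAT_ZERO_30MIN)) == 0.0

    def test_fundamental_theorem_value(self):
        # reaches exactly 10 mm at 30 min from 0 mm; scale 100 -> 1000
        tr = make_trace([0, 1800, 2100], [0, 10, 10])
        assert auc30(tr, scale=100) == pytest.approx(1000.0, rel=1e-12)

    def test_short_trace_refused(self):
        with pytest.raises(InsufficientSpanError):
            auc30(make_trace([0, 1500], [0, 10]))  # 25 min

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_identity_on_random_zero_baseline_traces(self, seed):
        """auc30 == scale * amplitude(30 min) for any trace starting at 0 mm."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 80))
        t = np.sort(rng.uniform(0.0, 2400.0, size=n - 2))
        t = np.concatenate([[0.0], t, [2400.0]])
        t = np.unique(t)
        a = np.abs(rng.normal(0, 20, size=t.size))
        a[0] = 0.0
        tr = make_trace(t, a)
        expected = 100.0 * tr.amplitude_at(1800.0)
        assert auc30(tr) == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_invariant_under_collinear_refinement(self):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, 2400, 20))
        t = np.unique(np.concatenate([[0.0], t, [2400.0]]))
        a = np.cumsum(rng.uniform(0, 2, t.size))
        a -= a[0]
        tr = make_trace(t, a)
        # insert midpoints of every segment (collinear by construction)
        tm = (t[:-1] + t[1:]) / 2
        am = np.interp(tm, t, a)
        t2 = np.concatenate([t, tm])
        a2 = np.concatenate([a, am])
        order = np.argsort(t2)
        tr2 = make_trace(t2[order], a2[order])
        assert auc30(tr2) == pytest.approx(auc30(tr), rel=1e-9)


class TestOracleAgreement:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_crossings_match_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        tr = random_monotone_trace(rng)
        for threshold in (2.0, 20.0, 0.7 * tr.amplitudes_mm[-1] + 1e-6):
            expected = brute_force_crossing(tr, threshold)
            got = extract_ct(tr, threshold_mm=threshold)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=2e-3)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_mcf_bounds_every_sample(self, seed):
        rng = np.random.default_rng(seed)
        tr = random_monotone_trace(rng)
        assert extract_mcf(tr) >= np.max(tr.amplitudes_mm) - 1e-12


def test_extract_all_consistency():
    params = PhenotypeParams(noise_cv=0.0)
    tr = simulate_trace(params, "extem")
    p = extract_all(tr)
    assert p.mcf_mm == extract_mcf(tr)
    assert p.auc30 == pytest.approx(100.0 * closed_form_amplitude(params, "extem", 1800.0), rel=1e-6)
    assert p.ct_s is not None and p.cft_s is not None
    assert p.ct_s < p.ct_s + p.cft_s <= tr.times_s[-1]
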