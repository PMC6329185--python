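"""Mechanistic simulator: limits, parameter recovery, cohort construction."""

import dataclasses

import numpy as np
import pytest

from ricotem import (
    CohortSpec,
    InvalidParameterError,
    PhenotypeParams,
    VwdPhenotype,
    auc30,
    extract_ct,
    extract_mcf,
    ricotem_plus,
    simulate_cohort,
    simulate_patient,
    simulate_trace,
)
from ricotem.simulate import (
    agglutinated_fraction,
    closed_form_amplitude,
    ground_truth_ct_s,
    plateau_mm,
)

EXPECTED_PHENOTYPE = {
    "control": VwdPhenotype.NO_VWD,
    "type1": VwdPhenotype.TYPE1,
    "mild_type1": VwdPhenotype.MILD_TYPE1,
    "type2a": VwdPhenotype.TYPE2,
    "type3": VwdPhenotype.TYPE3,
    "possible": VwdPhenotype.POSSIBLE_VWD,
    "hemophilia_mild": VwdPhenotype.NO_VWD,
}


def noise_free(**kw):
    return PhenotypeParams(noise_cv=0.0, **kw)


class TestTraceModel:
    def test_absent_vwf_makes_ristocetin_inert(self):
        """g(0) = 0: with no functional VWF the rico trace equals the Extem trace."""
        p = noise_free(vwf_activity_pct=0.0)
        extem = simulate_trace(p, "extem")
        rico = simulate_trace(p, "rico")
        assert np.array_equal(extem.amplitudes_mm, rico.amplitudes_mm)

    def test_saturated_vwf_leaves_only_fibrinogen(self):
        """g(V) -> 1: the rico plateau approaches the fibrinogen fraction."""
        p = noise_free(vwf_activity_pct=1e9)
        assert plateau_mm(p, "rico") == pytest.approx(0.20 * 60.0, rel=1e-6)
        assert plateau_mm(p, "fibtem") == pytest.approx(0.20 * 60.0)

    def test_noisy_trace_recovers_plateau_within_tolerance(self):
        p = PhenotypeParams(vwf_activity_pct=100.0)  # default noise_cv 0.05
        tr = simulate_trace(p, "extem", seed=7)
        assert extract_mcf(tr) == pytest.approx(60.0, rel=0.25)

    def test_noise_free_closed_form_is_exact(self):
        p = noise_free()
        tr = simulate_trace(p, "extem")
        t = tr.times_s
        expected = np.where(
            t < p.lag_s, 0.0,
            60.0 * (1 - np.exp(-(np.clip(t - p.lag_s, 0, None)) / p.tau_s)),
        )
        assert np.allclose(tr.amplitudes_mm, expected, rtol=0, atol=1e-12)

    def test_deterministic_given_seed(self):
        p = PhenotypeParams()
        a = simulate_trace(p, "rico", seed=11)
        b = simulate_trace(p, "rico", seed=11)
        assert np.array_equal(a.amplitudes_mm, b.amplitudes_mm)

    @pytest.mark.parametrize("kw", [dict(dt_s=0.0), dict(duration_min=25.0)])
    def test_invalid_grid_rejected(self, kw):
        with pytest.raises(InvalidParameterError):
            simulate_trace(PhenotypeParams(), "extem", **kw)

    def test_unknown_condition_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_trace(PhenotypeParams(), "heptem")


class TestParameterRecovery:
    @pytest.mark.parametrize("vwf", [0.0, 20.0, 100.0, 200.0])
    @pytest.mark.parametrize("condition", ["extem", "rico"])
    def test_ct_and_mcf_match_closed_form(self, vwf, condition):
        p = noise_free(vwf_activity_pct=vwf)
        tr = simulate_trace(p, condition)
        expected_ct = ground_truth_ct_s(p, condition)
        assert extract_ct(tr) == pytest.approx(expected_ct, rel=1e-2)
        expected_mcf = closed_form_amplitude(p, condition, tr.times_s[-1])
        assert extract_mcf(tr) == pytest.approx(expected_mcf, rel=1e-2)

    def test_auc_matches_closed_form(self):
        p = noise_free()
        tr = simulate_trace(p, "extem")
        assert auc30(tr) == pytest.approx(
            100.0 * closed_form_amplitude(p, "extem", 1800.0), rel=1e-9
        )


class TestRicotemRegimes:
    @staticmethod
    def noise_free_plus(p: PhenotypeParams) -> float:
        aucs = {c: auc30(simulate_trace(p, c)) for c in ("extem", "rico", "rico_haemate")}
        return ricotem_plus(aucs["rico"], aucs["rico_haemate"], aucs["extem"])

    def test_monotone_decreasing_in_vwf_activity(self):
        values = [
            self.noise_free_plus(noise_free(vwf_activity_pct=v))
            for v in np.linspace(0.0, 200.0, 21)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_ceiling_at_fibrinogen_complement(self):
        """Full restoration of agglutination is bounded by the 80% non-fibrinogen share."""
        p = noise_free(vwf_activity_pct=0.0, haemate_increment_pct=1e7,
                       haemate_procoagulant_mm=0.0)
        value = self.noise_free_plus(p)
        assert value <= 80.0
        assert value == pytest.approx(80.0, abs=0.1)  # saturates toward the ceiling

    def test_healthy_defaults_little_effect(self):
        assert self.noise_free_plus(noise_free(vwf_activity_pct=100.0)) < 15.0

    def test_agglutination_half_saturation(self):
        assert agglutinated_fraction(30.0, 30.0) == pytest.approx(0.5)


class TestPatients:
    @pytest.mark.parametrize("cls_name", sorted(EXPECTED_PHENOTYPE))
    def test_lab_classification_recovers_class(self, cls_name):
        for seed in range(20):
            rec = simulate_patient(cls_name, seed=seed, with_traces=False)
            assert rec.phenotype is EXPECTED_PHENOTYPE[cls_name], (cls_name, seed)

    def test_mild_type1_draws_stay_in_band(self):
        for seed in range(100):
            rec = simulate_patient("mild_type1", seed=seed, with_traces=False)
            for v in rec.lab.vwf_values:
                assert 30.0 <= v < 50.0

    def test_unknown_class_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_patient("type4", seed=0)

    def test_traces_and_panel_attached(self):
        rec = simulate_patient("type3", seed=7)
        assert set(rec.traces) == {"extem", "rico", "rico_haemate", "fibtem"}
        assert rec.panel is not None and rec.responder in ("normal", "low", "high")
        # type 3: ristocetin nearly inert, supplementation restores agglutination
        assert rec.panel.ricotem_minus > 50.0
        assert rec.responder == "high"


class TestCohort:
    def test_default_composition(self, default_cohort):
        assert len(default_cohort) == 27
        counts = {}
        for rec in default_cohort:
            counts[rec.phenotype_class] = counts.get(rec.phenotype_class, 0) + 1
        assert counts == {"control": 7, "type1": 9, "type2a": 6, "type3": 2,
                          "possible": 2, "hemophilia_mild": 1}

    def test_single_control_cohort(self):
        spec = CohortSpec(controls=1, type1=0, type2a=0, type3=0, possible=0,
                          hemophilia_mild=0, seed=3)
        records = simulate_cohort(spec, with_traces=False)
        assert len(records) == 1
        assert records[0].phenotype is VwdPhenotype.NO_VWD

    def test_reproducible_for_fixed_seed(self):
        spec = CohortSpec(controls=2, type1=1, type2a=0, type3=1, possible=0,
                          hemophilia_mild=0, seed=9)
        a = simulate_cohort(spec)
        b = simulate_cohort(spec)
        for ra, rb in zip(a, b):
            assert ra.lab == rb.lab
            assert ra.panel == rb.panel
            for cond in ra.traces:
                assert np.array_equal(ra.traces[cond].amplitudes_mm,
                                      rb.traces[cond].amplitudes_mm)

    def test_empty_spec_rejected(self):
        with pytest.raises(InvalidParameterError):
            CohortSpec(controls=0, type1=0, type2a=0, type3=0, possible=0,
                       hemophilia_mild=0)
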