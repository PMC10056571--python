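"""Beat detection, r' location, limb fitting and triangle geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rprime.geometry import (
    CRITERIA,
    RPrimeGeometry,
    aggregate_patient,
    compute_geometry,
    detect_beats,
    extract_channel,
    fit_limbs,
    is_measurable,
    locate_rprime,
    Limb,
    PatientFeatures,
)
from rprime.io import Calibration, ECGRecord, ICLevel, Lead, LeadPlacement
from rprime.synth import WaveformParams, gen_waveform

V1_IV = LeadPlacement(Lead.V1, ICLevel.IV)


def _tan(deg):
    return math.tan(math.radians(deg))


class TestDetectBeats:
    def test_finds_all_beats_at_true_positions(self, clean_strip):
        record, truth = clean_strip
        beats = detect_beats(record, 0)
        assert len(beats) == 5
        found = np.array([b.r_peak for b in beats])
        assert np.all(np.abs(found - truth.r_peak_samples) <= 1)

    def test_all_zero_signal_gives_empty_list(self):
        rec = ECGRecord(500.0, [(V1_IV, np.zeros(5000))])
        assert detect_beats(rec, 0) == []

    def test_baseline_offset_recovered(self):
        record, _ = gen_waveform(WaveformParams(baseline_mv=0.2, n_beats=4))
        beats = detect_beats(record, 0)
        assert beats
        for b in beats:
            assert b.baseline_mv == pytest.approx(0.2, abs=0.005)

    def test_short_signal_rejected(self):
        rec = ECGRecord(500.0, [(V1_IV, np.zeros(600))])
        with pytest.raises(ValueError, match="2 s"):
            detect_beats(rec, 0)


class TestLocateRPrime:
    def test_apex_within_one_sample_of_truth(self, clean_strip):
        record, truth = clean_strip
        _, sig = record.channels[0]
        for beat, apex_true in zip(detect_beats(record, 0, post_ms=300),
                                   truth.rprime_apex_samples):
            apex = locate_rprime(sig, beat)
            assert apex is not None
            assert abs(apex - apex_true) <= 1

    def test_monophasic_r_beat_has_no_rprime(self):
        # tall R then a plain descent back to baseline: no terminal positive peak
        fs = 500.0
        t = np.arange(int(fs * 4)) / fs
        sig = np.zeros_like(t)
        for r_t in (1.0, 2.0, 3.0):
            sig += np.interp(t, [r_t - 0.03, r_t, r_t + 0.06], [0, 1.0, 0])
        rec = ECGRecord(fs, [(V1_IV, sig)])
        for beat in detect_beats(rec, 0):
            assert locate_rprime(sig, beat) is None

    def test_tiny_rprime_below_candidate_gate_ignored(self):
        # r' height 0.04 mV sits below the 0.05 mV candidate gate
        record, _ = gen_waveform(WaveformParams(h_mm=0.4, n_beats=4))
        _, sig = record.channels[0]
        for beat in detect_beats(record, 0):
            assert locate_rprime(sig, beat) is None


class TestMeasurability:
    @pytest.mark.parametrize(
        "height,descent,expected",
        [
            (0.15, 0.12, True),
            (0.10, 0.30, False),  # strict '>': 0.1 mV exactly fails
            (0.30, 0.10, False),
            (0.30, 0.08, False),
            (0.101, 0.101, True),
        ],
    )
    def test_strict_thresholds(self, height, descent, expected):
        assert is_measurable(height, descent) is expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            is_measurable(-0.1, 0.2)


class TestFitLimbs:
    def test_noiseless_angles_recovered_within_half_degree(self, calibration):
        record, _ = gen_waveform(WaveformParams(theta_up_deg=16, alpha_deg=24, h_mm=3))
        _, sig = record.channels[0]
        beat = detect_beats(record, 0, post_ms=300)[0]
        apex = locate_rprime(sig, beat)
        up, down = fit_limbs(sig, beat, apex, calibration, record.sampling_rate)
        assert up.angle_deg == pytest.approx(16.0, abs=0.5)
        assert down.angle_deg == pytest.approx(24.0, abs=0.5)

    def test_noisy_angles_within_three_degrees(self, calibration):
        record, _ = gen_waveform(
            WaveformParams(theta_up_deg=16, alpha_deg=24, h_mm=3,
                           noise_sd=0.02, n_beats=6, seed=77)
        )
        _, sig = record.channels[0]
        errs_up, errs_down = [], []
        for beat in detect_beats(record, 0, post_ms=300):
            apex = locate_rprime(sig, beat)
            if apex is None:
                continue
            limbs = fit_limbs(sig, beat, apex, calibration, record.sampling_rate)
            if limbs is None:
                continue
            errs_up.append(abs(limbs[0].angle_deg - 16.0))
            errs_down.append(abs(limbs[1].angle_deg - 24.0))
        assert errs_up and np.mean(errs_up) < 3.0
        assert errs_down and np.mean(errs_down) < 3.0

    def test_single_sample_descent_treated_as_vertical(self, calibration):
        # a 1-sample drop at 500 Hz: angle clipped to 0 deg with a warning
        fs = 500.0
        sig = np.zeros(int(fs * 3))
        r = int(fs * 1.5)
        sig[r - 10 : r] = np.linspace(0, 1.0, 10)
        sig[r : r + 20] = np.linspace(1.0, -0.2, 20)
        apex = r + 30
        sig[r + 20 : apex + 1] = np.linspace(-0.2, 0.4, 11)
        sig[apex + 1] = 0.0  # vertical downslope: one-sample drop
        rec = ECGRecord(fs, [(V1_IV, sig)])
        beat = detect_beats(rec, 0)[0]
        with pytest.warns(UserWarning, match="vertical"):
            limbs = fit_limbs(sig, beat, apex, calibration, fs)
        assert limbs is not None
        assert limbs[1].angle_deg == 0.0


class TestComputeGeometry:
    def _limb(self, angle_deg, apex=(10.0, 3.0), sign=1):
        slope = sign * _tan(angle_deg)
        return Limb(angle_deg=angle_deg, x0_mm=apex[0] - slope * apex[1], slope_xy=slope)

    @pytest.mark.parametrize(
        "theta,alpha,beta,dbt5",
        [
            (16.0, 24.0, 40.0, 200 * (_tan(16) + _tan(24))),  # 146.4 ms
            (18.43, 33.69, 52.12, 200 * (_tan(18.43) + _tan(33.69))),
        ],
    )
    def test_closed_form_angles_and_dbt5(self, calibration, theta, alpha, beta, dbt5):
        up = self._limb(theta, sign=1)
        down = self._limb(alpha, sign=-1)
        g = compute_geometry(up, down, baseline_mv=0.0, calibration=calibration)
        assert g.beta_deg == pytest.approx(beta, abs=0.01)
        assert g.dbt5_ms == pytest.approx(dbt5, abs=0.01)

    def test_vertical_upslope_tan45_case(self, calibration):
        # theta=0, alpha=45, h=3 mm: dbt5=200 ms, dbtiso=120 ms, ratio=1
        up = self._limb(0.0, sign=1)
        down = self._limb(45.0, sign=-1)
        g = compute_geometry(up, down, baseline_mv=0.0, calibration=calibration)
        assert g.h_mm == pytest.approx(3.0)
        assert g.dbt5_ms == pytest.approx(200.0)
        assert g.dbtiso_ms == pytest.approx(120.0)
        assert g.ratio == pytest.approx(1.0)

    def test_parallel_limbs_error(self, calibration):
        up = self._limb(20.0, sign=1)
        with pytest.raises(ValueError, match="parallel"):
            compute_geometry(up, up, 0.0, calibration)

    def test_apex_below_isoelectric_unmeasurable(self, calibration):
        up = self._limb(16.0, apex=(10.0, -1.0), sign=1)
        down = self._limb(24.0, apex=(10.0, -1.0), sign=-1)
        g = compute_geometry(up, down, baseline_mv=0.0, calibration=calibration)
        assert not g.measurable
        assert g.h_mm == 0.0

    @given(
        theta=st.floats(1.0, 45.0),
        alpha=st.floats(1.0, 70.0),
        h=st.floats(0.5, 8.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_identities_hold_exactly(self, theta, alpha, h):
        g = RPrimeGeometry(0.0, h, theta, alpha, h, True)
        tan_sum = _tan(theta) + _tan(alpha)
        assert abs(g.beta_deg - (theta + alpha)) < 1e-9
        assert abs(g.dbt5_ms - 200.0 * tan_sum) < 1e-9
        assert abs(g.dbtiso_ms - 40.0 * h * tan_sum) < 1e-9
        assert abs(g.ratio - tan_sum) < 1e-9

    def test_monotone_in_alpha_at_fixed_theta(self):
        alphas = np.linspace(5, 60, 25)
        geoms = [RPrimeGeometry(0.0, 3.0, 15.0, a, 3.0, True) for a in alphas]
        for c in ("beta_deg", "dbt5_ms", "dbtiso_ms", "ratio"):
            vals = [getattr(g, c) for g in geoms]
            assert np.all(np.diff(vals) > 0), c


class TestEndToEnd:
    def test_extraction_recovers_generator_geometry(self):
        record, truth = gen_waveform(WaveformParams(theta_up_deg=16, alpha_deg=24, h_mm=3))
        geoms = extract_channel(record, 0, post_ms=300)
        assert geoms
        g = geoms[0]
        t = truth.geometry
        assert g.beta_deg == pytest.approx(t.beta_deg, abs=1.0)
        assert g.alpha_deg == pytest.approx(t.alpha_deg, abs=1.0)
        assert g.dbt5_ms == pytest.approx(t.dbt5_ms, abs=2.0)
        assert g.dbtiso_ms == pytest.approx(t.dbtiso_ms, abs=2.0)
        assert g.ratio == pytest.approx(t.ratio, abs=0.05)


def _geom(beta=None, *, theta=10.0, alpha=None, h=3.0, measurable=True):
    if alpha is None:
        alpha = beta - theta
    return RPrimeGeometry(0.0, h, theta, alpha, h, measurable)


class TestAggregation:
    def test_lead_means_then_major(self):
        # V1-IV beats beta {40, 44} -> mean 42; other placements mean 50, 38
        groups = {
            LeadPlacement(Lead.V1, ICLevel.IV): [_geom(40.0), _geom(44.0)],
            LeadPlacement(Lead.V1, ICLevel.III): [_geom(50.0)],
            LeadPlacement(Lead.V2, ICLevel.II): [_geom(38.0)],
        }
        pf = aggregate_patient(groups)
        assert pf.any_measurable
        assert pf.beta_deg == pytest.approx(50.0)
        assert pf.measurable_by_ic == {
            ICLevel.II: True, ICLevel.III: True, ICLevel.IV: True
        }

    def test_single_beat_identity(self):
        g = _geom(45.0)
        pf = aggregate_patient({LeadPlacement(Lead.V2, ICLevel.III): [g]})
        for c in CRITERIA:
            assert getattr(pf, c) == pytest.approx(getattr(g, c))
        assert pf.measurable_by_ic[ICLevel.III]
        assert not pf.measurable_by_ic[ICLevel.II]

    def test_no_measurable_beats(self):
        groups = {
            LeadPlacement(Lead.V1, ICLevel.IV): [_geom(40.0, measurable=False)],
            LeadPlacement(Lead.V2, ICLevel.II): [],
        }
        pf = aggregate_patient(groups)
        assert not pf.any_measurable
        assert pf.beta_deg is None
        assert aggregate_patient({}).any_measurable is False

    def test_major_invariant_to_order_and_dominated_leads(self, rng):
        placements = [LeadPlacement(l, ic) for l in Lead for ic in ICLevel]
        groups = {
            p: [_geom(b) for b in rng.uniform(20, 60, rng.integers(1, 4))]
            for p in placements[:4]
        }
        pf = aggregate_patient(groups)
        shuffled = dict(reversed(list(groups.items())))
        pf2 = aggregate_patient(shuffled)
        for c in CRITERIA:
            assert getattr(pf, c) == pytest.approx(getattr(pf2, c))
        # adding a dominated placement leaves every major unchanged
        groups[placements[4]] = [_geom(11.0, theta=5.0, h=0.6)]
        pf3 = aggregate_patient(groups)
        for c in CRITERIA:
            assert getattr(pf3, c) == pytest.approx(getattr(pf, c))
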