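"""Steady-state GRE signal model: closed-form values and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from f19lung.signal_model import (
    AcquisitionProtocol,
    FixedNSA,
    GasSpecies,
    advantage_surface,
    ernst_angle,
    normalize_snr,
    nsa_from_scan_time,
    predicted_advantage,
    spoiled_gre_signal,
    steady_state_signal,
    tr_from_scan_time,
)


def make_protocol(tr, te, flip, nsa=1, **kw):
    return AcquisitionProtocol(name="t", tr_ms=tr, te_ms=te, flip_deg=flip, nsa=nsa, **kw)


class TestSteadyStateSignal:
    @pytest.mark.parametrize(
        "n_f,t1,t2s,tr,te,flip,expected",
        [
            # full-recovery limit at TE=0: 8·(1−e^(−100/17.77))
            (8, 17.77, 3.4, 100.0, 0.0, 90.0, 8 * (1 - math.exp(-100 / 17.77))),
            # direct evaluation at the continuous-breathing operating point
            (8, 17.77, 3.4, 20.07, 0.95, 70.0, 4.325687683725545),
        ],
    )
    def test_closed_form_values(self, n_f, t1, t2s, tr, te, flip, expected):
        assert spoiled_gre_signal(n_f, t1, t2s, tr, te, flip) == pytest.approx(
            expected, rel=1e-9
        )

    def test_full_recovery_value_matches_printed_magnitude(self):
        # sanity on the frozen number above: ~7.97 at TR/T1 = 5.63
        assert spoiled_gre_signal(8, 17.77, 3.4, 100.0, 0.0, 90.0) == pytest.approx(
            7.971, abs=5e-4
        )

    def test_zero_flip_angle_would_give_zero_signal(self):
        # flip=0 is outside the protocol domain; the raw formula limit is 0
        assert spoiled_gre_signal(8, 17.77, 3.4, 20.0, 0.95, 1e-9) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            spoiled_gre_signal(8, -1.0, 3.4, 20.0, 1.0, 70.0)
        with pytest.raises(ValueError):
            spoiled_gre_signal(8, 17.77, 3.4, 20.0, -0.1, 70.0)

    @settings(deadline=None, derandomize=True)
    @given(
        t2s=st.floats(1.0, 15.0),
        te1=st.floats(0.01, 5.0),  # at TE=0 the T2* dependence vanishes
        dte=st.floats(0.01, 5.0),
        dt2s=st.floats(0.01, 10.0),
    )
    def test_monotone_decreasing_in_te_increasing_in_t2star(self, t2s, te1, dte, dt2s):
        base = spoiled_gre_signal(8, 30.0, t2s, 20.0, te1, 70.0)
        assert spoiled_gre_signal(8, 30.0, t2s, 20.0, te1 + dte, 70.0) < base
        assert spoiled_gre_signal(8, 30.0, t2s + dt2s, 20.0, te1, 70.0) > base

    @pytest.mark.parametrize("tr,t1", [(20.0, 17.77), (100.0, 28.5), (12.5, 12.8)])
    def test_maximum_at_ernst_angle(self, tr, t1):
        angles = np.arange(0.05, 90.0, 0.05)
        sig = [spoiled_gre_signal(8, t1, 5.0, tr, 1.0, a) for a in angles]
        best = angles[int(np.argmax(sig))]
        assert best == pytest.approx(ernst_angle(tr, t1), abs=0.1)

    def test_long_tr_limit(self):
        # TR >> T1: signal → n_F · exp(−TE/T2*) · sin α
        limit = 8 * math.exp(-1.0 / 5.0) * math.sin(math.radians(70.0))
        val = spoiled_gre_signal(8, 10.0, 5.0, 500.0, 1.0, 70.0)
        assert val == pytest.approx(limit, rel=1e-6)

    def test_gas_protocol_interface(self, ofcb_invivo):
        proto = make_protocol(20.07, 0.95, 70.0)
        direct = spoiled_gre_signal(8, 17.77, 3.4, 20.07, 0.95, 70.0)
        assert steady_state_signal(ofcb_invivo, proto) == pytest.approx(direct)


class TestErnstAngle:
    def test_limits_and_closed_form(self):
        assert ernst_angle(1e6, 1.0) == pytest.approx(90.0, abs=1e-3)
        assert ernst_angle(17.0, 17.0) == pytest.approx(
            math.degrees(math.acos(1 / math.e)), rel=1e-12
        )
        assert math.degrees(math.acos(1 / math.e)) == pytest.approx(68.42, abs=0.01)

    def test_in_vivo_operating_point_rounds_to_70(self):
        assert ernst_angle(20.0, 17.77) == pytest.approx(71.07, abs=0.01)
        assert ernst_angle(20.0, 17.77, round_to=5) == 70.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ernst_angle(0.0, 17.0)


class TestScanTimeArithmetic:
    def test_tr_from_scan_time(self):
        assert tr_from_scan_time(11, 32, 16) == pytest.approx(21.48, abs=0.01)
        assert tr_from_scan_time(185, 64, 144) == pytest.approx(20.07, abs=0.01)

    def test_nsa_inverse_consistency(self):
        tr = tr_from_scan_time(185, 64, 144)
        assert nsa_from_scan_time(185, 64, tr) == 144
        # printed rounded TR also lands on the same NSA
        assert nsa_from_scan_time(185, 64, 20.07) == 144

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nsa_from_scan_time(-1, 32, 20)
        with pytest.raises(ValueError):
            tr_from_scan_time(11, 0, 16)


class TestNormalizeSnr:
    @pytest.mark.parametrize(
        "snr,nsa,expected", [(9.72, 16, 0.6075), (7.66, 24, 0.319167), (5.5, 1, 5.5)]
    )
    def test_values(self, snr, nsa, expected):
        assert normalize_snr(snr, nsa) == pytest.approx(expected, abs=1e-4)

    def test_nsa_below_one_rejected(self):
        with pytest.raises(ValueError):
            normalize_snr(1.0, 0)


class TestPredictedAdvantage:
    def test_breath_hold_prediction(self, ofcb_invivo, pfp_invivo, protocols):
        res = predicted_advantage(
            ofcb_invivo, pfp_invivo,
            protocols["breath-hold-ofcb"], protocols["breath-hold-pfp"],
        )
        assert res.advantage_pct == pytest.approx(86.196, abs=0.01)

    def test_full_recovery_prediction(self, ofcb_invivo, pfp_invivo, protocols):
        res = predicted_advantage(
            ofcb_invivo, pfp_invivo,
            protocols["full-recovery-ofcb"], protocols["full-recovery-pfp"],
        )
        assert res.advantage_pct == pytest.approx(85.324, abs=0.01)

    def test_identical_inputs_give_zero(self, ofcb_invivo, protocols):
        p = protocols["breath-hold-ofcb"]
        res = predicted_advantage(ofcb_invivo, ofcb_invivo, p, p)
        assert res.advantage_pct == pytest.approx(0.0, abs=1e-12)

    def test_reciprocity(self, ofcb_invivo, pfp_invivo, protocols):
        pa, pb = protocols["breath-hold-ofcb"], protocols["breath-hold-pfp"]
        ab = predicted_advantage(ofcb_invivo, pfp_invivo, pa, pb).advantage_pct
        ba = predicted_advantage(pfp_invivo, ofcb_invivo, pb, pa).advantage_pct
        assert (1 + ab / 100) * (1 + ba / 100) == pytest.approx(1.0, rel=1e-12)

    def test_doubling_nsa_scales_normalized_but_not_advantage(
        self, ofcb_invivo, pfp_invivo
    ):
        pa = make_protocol(21.48, 0.63, 70, nsa=16)
        pb = make_protocol(14.32, 0.63, 70, nsa=24)
        base = predicted_advantage(ofcb_invivo, pfp_invivo, pa, pb)
        pa2 = make_protocol(21.48, 0.63, 70, nsa=32)
        pb2 = make_protocol(14.32, 0.63, 70, nsa=48)
        doubled = predicted_advantage(ofcb_invivo, pfp_invivo, pa2, pb2)
        assert doubled.normalized_a == pytest.approx(base.normalized_a / math.sqrt(2))
        assert doubled.normalized_b == pytest.approx(base.normalized_b / math.sqrt(2))
        assert doubled.advantage_pct == pytest.approx(base.advantage_pct, rel=1e-12)


class TestAdvantageSurface:
    def test_scalar_consistency_at_protocol_point(self, ofcb_invivo, pfp_invivo, protocols):
        pa, pb = protocols["breath-hold-ofcb"], protocols["breath-hold-pfp"]
        # both gases on the surface share TR; compare at pa's operating point
        grid = advantage_surface(
            ofcb_invivo, pfp_invivo, [pa.tr_ms], [pa.te_ms], 70.0, FixedNSA(16, 24)
        )
        scalar = predicted_advantage(
            ofcb_invivo, pfp_invivo, pa,
            make_protocol(pa.tr_ms, pa.te_ms, 70.0, nsa=24),
        )
        assert grid[0, 0] == pytest.approx(scalar.ratio, rel=1e-12)

    def test_identical_gases_ratio_one_everywhere(self, ofcb_invivo):
        grid = advantage_surface(
            ofcb_invivo, ofcb_invivo, np.linspace(5, 40, 8), [0.63, 0.95], 70.0,
            FixedNSA(16, 16),
        )
        assert np.allclose(grid, 1.0)

    def test_crossover_region_is_at_short_tr(self, ofcb_invivo, pfp_invivo, protocols):
        # under fixed NSA 16/24 with PFP pinned at its breath-hold TR, PFP's
        # normalized SNR can only win when the OFCB TR is impractically short
        tr_grid = np.arange(1.0, 40.0, 0.1)
        grid = advantage_surface(
            ofcb_invivo, pfp_invivo, tr_grid, [0.63], 70.0, FixedNSA(16, 24),
            tr_b_ms=protocols["breath-hold-pfp"].tr_ms,
        )
        below = tr_grid[grid[:, 0] < 1.0]
        assert below.size > 0
        assert 4.0 < below.max() < 8.0  # crossover near the few-ms regime

    def test_shared_tr_surface_has_no_crossover(self, ofcb_invivo, pfp_invivo):
        # when both gases share TR, OFCB keeps the advantage over the whole
        # practical grid (its crossover claim requires the pinned-TR reading)
        grid = advantage_surface(
            ofcb_invivo, pfp_invivo, np.arange(1.0, 40.0, 0.5), [0.63], 70.0,
            FixedNSA(16, 24),
        )
        assert (grid > 1.0).all()

    def test_empty_grid_rejected(self, ofcb_invivo, pfp_invivo):
        with pytest.raises(ValueError):
            advantage_surface(ofcb_invivo, pfp_invivo, [], [1.0], 70.0, FixedNSA(1, 1))


class TestDomainTypes:
    def test_gas_invariants(self):
        with pytest.raises(ValueError):
            GasSpecies(name="bad", n_equivalent_f=8, t1_ms=5.0, t2star_ms=10.0)
        gas = GasSpecies(name="ok", n_equivalent_f=8, t1_ms=28.5, t2star_ms=10.5)
        assert gas.peaks == ((8, 0.0, 10.5),)
        assert gas.total_f == 8

    def test_protocol_scan_time_consistency(self):
        with pytest.raises(ValueError):
            make_protocol(30.0, 1.0, 70, nsa=16, n_lines=32, scan_time_s=11)
        ok = make_protocol(21.484375, 0.63, 70, nsa=16, n_lines=32, scan_time_s=11)
        assert ok.scan_time_s == 11

    def test_protocol_rejects_te_above_tr(self):
        with pytest.raises(ValueError):
            make_protocol(1.0, 2.0, 70)
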