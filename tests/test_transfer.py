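"""Transfer functions and the discrete lead-tip voltage line integral."""

import math

import numpy as np
import pytest

import leadheat as lh
from leadheat.geometry import LoopSegment, StraightSegment

K_REF = complex(6.7454, -0.6840)


def _loop_spec(turns=1, diameter=0.05, center_entry=(0.05, 0.0, 0.0)):
    return lh.WireSpec("loop", center_entry, (LoopSegment(turns, diameter),))


class TestTransferValue:
    @pytest.mark.parametrize("kind,gamma", [("unity", 0.0), ("sem", 0.0), ("tlm", 0.24)])
    def test_normalized_to_one_at_tip(self, kind, gamma):
        m = lh.TransferModel(kind, K_REF, 0.5, gamma)
        assert lh.transfer_value(m, 0.0) == pytest.approx(1.0)

    def test_tlm_reduces_to_sem_at_zero_gamma(self):
        rng = np.random.default_rng(5)
        ls = rng.uniform(0, 0.5, size=50)
        sem = lh.TransferModel("sem", K_REF, 0.5)
        tlm = lh.TransferModel("tlm", K_REF, 0.5, 0.0)
        np.testing.assert_allclose(
            lh.transfer_value(tlm, ls), lh.transfer_value(sem, ls), rtol=1e-14
        )

    def test_sem_matches_complex_exponential_oracle(self):
        m = lh.TransferModel("sem", K_REF, 0.5)
        l = 0.25
        expected = complex(
            math.exp(K_REF.imag * l) * math.cos(-K_REF.real * l),
            math.exp(K_REF.imag * l) * math.sin(-K_REF.real * l),
        )
        assert lh.transfer_value(m, l) == pytest.approx(expected, rel=1e-12)

    def test_sem_magnitude_monotone_nonincreasing(self):
        m = lh.TransferModel("sem", K_REF, 1.0)
        ls = np.linspace(0, 1.0, 200)
        mags = np.abs(lh.transfer_value(m, ls))
        assert np.all(np.diff(mags) <= 1e-15)

    def test_arc_length_outside_domain_rejected(self):
        m = lh.TransferModel("sem", K_REF, 0.5)
        with pytest.raises(ValueError):
            lh.transfer_value(m, 0.6)
        with pytest.raises(ValueError):
            lh.transfer_value(m, -0.1)

    def test_invalid_model_parameters_rejected(self):
        with pytest.raises(ValueError):
            lh.TransferModel("tlm", K_REF, 0.5, 1.0)
        with pytest.raises(ValueError):
            lh.TransferModel("sem", complex(6.7, +0.7), 0.5)
        with pytest.raises(ValueError):
            lh.TransferModel("huh", K_REF, 0.5)


class TestLeadTipVoltage:
    def test_closed_loop_matches_faraday_flux(self, analytic_field):
        """Discrete line integral around a coronal loop equals w*b1*A."""
        path = lh.build_wire_path(_loop_spec())
        V = lh.lead_tip_voltage(path, analytic_field, lh.TransferModel("unity"))
        A = math.pi * 0.025**2
        expected = analytic_field.angular_frequency * analytic_field.b1_amplitude * A
        assert abs(V) == pytest.approx(expected, rel=5e-4)

    def test_zero_field_gives_zero(self, zero_field):
        path = lh.build_wire_path(_loop_spec())
        assert lh.lead_tip_voltage(path, zero_field, lh.TransferModel("unity")) == 0

    def test_straight_vertical_wire_closed_form(self, analytic_field):
        x0, d = 0.1, 0.25
        spec = lh.WireSpec("s", (x0, 0, d / 2), (StraightSegment(d, (0, 0, -1)),))
        path = lh.build_wire_path(spec)
        V = lh.lead_tip_voltage(path, analytic_field, lh.TransferModel("unity"))
        expected = (
            analytic_field.angular_frequency * analytic_field.b1_amplitude * x0 * d
        )
        assert abs(V) == pytest.approx(expected, rel=5e-4)

    def test_one_over_n_turn_scaling_exact(self, analytic_field):
        """Fixed wire length wound into N coincident turns: |V| ~ 1/N.

        A coarse max_step keeps every loop at the common per-turn edge floor
        so the inscribed-polygon area correction cancels in the ratio exactly.
        """
        L = 0.4
        mags = []
        for N in range(1, 6):
            dia = L / (math.pi * N)
            spec = lh.WireSpec(
                f"N{N}", (dia / 2, 0.0, 0.0), (LoopSegment(N, dia),)
            )
            path = lh.build_wire_path(spec, max_step=0.01)
            mags.append(
                abs(lh.lead_tip_voltage(path, analytic_field, lh.TransferModel("unity")))
            )
        for N, m in enumerate(mags, start=1):
            assert N * m == pytest.approx(mags[0], rel=1e-12)

    def test_halving_step_changes_voltage_under_point1_percent(
        self, analytic_field, king_k
    ):
        spec = lh.table1_fixtures()[1]  # Bottom single
        p1 = lh.build_wire_path(spec, max_step=1e-3)
        p2 = lh.build_wire_path(spec, max_step=5e-4)
        m1 = lh.TransferModel("sem", king_k, p1.total_length)
        m2 = lh.TransferModel("sem", king_k, p2.total_length)
        v1 = abs(lh.lead_tip_voltage(p1, analytic_field, m1))
        v2 = abs(lh.lead_tip_voltage(p2, analytic_field, m2))
        assert abs(v1 - v2) / v2 < 1e-3

    def test_global_phase_invariance(
        self, analytic_field, phase_shifted_field_cls, king_k
    ):
        path = lh.build_wire_path(lh.table1_fixtures()[2])
        model = lh.TransferModel("sem", king_k, path.total_length)
        v0 = lh.lead_tip_voltage(path, analytic_field, model)
        shifted = phase_shifted_field_cls(analytic_field, 1.234)
        v1 = lh.lead_tip_voltage(path, shifted, model)
        assert abs(v1) == pytest.approx(abs(v0), rel=1e-12)
        assert v1 != pytest.approx(v0)  # the complex value does rotate

    def test_tip_end_convention_fixed_by_orientation(self, analytic_field, king_k):
        """Reversing the walk direction (l measured from the other end)
        changes the SEM voltage magnitude for an asymmetric wire."""
        spec = lh.table1_fixtures()[1]  # Bottom single (loop near IPG end)
        path = lh.build_wire_path(spec)
        rev = lh.WirePath(
            vertices=path.vertices[::-1].copy(),
            arc_lengths=(path.arc_lengths[-1] - path.arc_lengths[::-1]).copy(),
            name="reversed",
        )
        model = lh.TransferModel("sem", king_k, path.total_length)
        v_fwd = lh.lead_tip_voltage(path, analytic_field, model)
        v_rev = lh.lead_tip_voltage(rev, analytic_field, model)
        assert abs(v_fwd) != pytest.approx(abs(v_rev), rel=1e-3)

    def test_mismatched_model_length_rejected(self, analytic_field, king_k):
        path = lh.build_wire_path(lh.table1_fixtures()[0])
        with pytest.raises(ValueError):
            lh.lead_tip_voltage(
                path, analytic_field, lh.TransferModel("sem", king_k, 0.9)
            )

    def test_winding_sense_flips_loop_term(self, analytic_field, king_k):
        """'Middle single' vs 'Middle single flipped': the loop flux enters
        with opposite sign, so the SEM voltages differ."""
        by_name = {s.name: s for s in lh.table1_fixtures()}
        va, vb = (
            lh.lead_tip_voltage(
                lh.build_wire_path(by_name[n]),
                analytic_field,
                lh.TransferModel(
                    "sem", king_k, lh.arc_length(lh.build_wire_path(by_name[n]))
                ),
            )
            for n in ("Middle single", "Middle single flipped")
        )
        assert abs(va - vb) > 0.1 * max(abs(va), abs(vb))


class TestTemperatureRise:
    def test_zero_voltage(self):
        assert lh.temperature_rise(0j, 2.0) == 0.0

    def test_quadratic_in_voltage(self):
        assert lh.temperature_rise(2 + 0j, 1.5) * 4 == pytest.approx(
            lh.temperature_rise(4 + 0j, 1.5)
        )

    def test_pythagorean_example(self):
        assert lh.temperature_rise(3 + 4j, 1.0) == pytest.approx(25.0)

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            lh.temperature_rise(1 + 0j, -0.1)
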