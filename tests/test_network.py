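import dataclasses

import numpy as np
import pytest

from hnokinetics import (
    DEFAULT_CONDITIONS,
    DEFAULT_RATES,
    SPECIES,
    SteadyStateSolution,
    fluorescein_rates,
    flux_partition,
    hno_steady_state,
    inhibition_prediction,
    integrate_full_model,
    rhs_full_model,
)
from oracles import rk4_reference

IDX = {name: i for i, name in enumerate(SPECIES)}


class TestRhs:
    def test_fresh_donor_release_flux(self):
        # 20 uM donor at k_as = 8.0e-4 s^-1 releases HNO at 0.016 uM/s
        d = rhs_full_model({"AS": 20e-6}, DEFAULT_RATES, DEFAULT_CONDITIONS)
        assert d[IDX["AS"]] == pytest.approx(-1.6e-8, rel=1e-12)
        assert d[IDX["HNO"]] == pytest.approx(+1.6e-8, rel=1e-12)
        others = [d[i] for i in range(len(SPECIES)) if i not in (IDX["AS"], IDX["HNO"])]
        assert np.allclose(others, 0.0)

    def test_empty_system_is_static(self):
        d = rhs_full_model({"O2": 0.0}, DEFAULT_RATES, DEFAULT_CONDITIONS)
        assert np.allclose(d, 0.0)

    def test_dimerization_rate_law(self):
        # 1 uM HNO alone: HNO lost at 2*k_dim*[HNO]^2, N2O formed at half that
        cond = dataclasses.replace(DEFAULT_CONDITIONS, o2=0.0)
        d = rhs_full_model({"HNO": 1e-6}, DEFAULT_RATES, cond)
        assert d[IDX["HNO"]] == pytest.approx(-1.6e-5, rel=1e-12)
        assert d[IDX["N2O"]] == pytest.approx(+8.0e-6, rel=1e-12)

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            rhs_full_model({"AS": -1e-9}, DEFAULT_RATES, DEFAULT_CONDITIONS)
        with pytest.raises(ValueError, match="unknown"):
            rhs_full_model({"XYZ": 1e-9}, DEFAULT_RATES, DEFAULT_CONDITIONS)

    def test_o2_depletes_when_not_clamped(self):
        cond = dataclasses.replace(DEFAULT_CONDITIONS, o2_clamped=False)
        d = rhs_full_model({"HNO": 1e-9, "O2": 225e-6}, DEFAULT_RATES, cond)
        assert d[IDX["O2"]] == pytest.approx(-1.8e4 * 225e-6 * 1e-9, rel=1e-12)


class TestIntegration:
    def test_matches_rk4_oracle(self, control_trajectory):
        t_ref, ref = rk4_reference(
            k_as=8e-4, k_o2=1.8e4, k_probe=1e6, k_dim=8e6, k_nuc=0.0,
            as0=20e-6, probe0=25e-6, o2=225e-6, t_end=600.0, dt=0.01,
        )
        tr = control_trajectory
        assert np.allclose(tr.times, t_ref)
        assert tr["FlOH"][-1] == pytest.approx(ref["FlOH"][-1], rel=1e-5)
        assert tr["AS"][-1] == pytest.approx(ref["AS"][-1], rel=1e-6)
        # mid-trajectory HNO (a few nM) must also be resolved
        assert tr["HNO"][300] == pytest.approx(ref["HNO"][300], rel=1e-4)

    def test_product_follows_donor_decay(self, control_trajectory):
        # nearly all released HNO ends up as fluorescein in the control
        expected = 20e-6 * (1.0 - np.exp(-8e-4 * 600.0))
        assert control_trajectory["FlOH"][-1] == pytest.approx(expected, rel=0.02)

    def test_no_source_means_static(self):
        rates = dataclasses.replace(DEFAULT_RATES, k_as=0.0)
        tr = integrate_full_model(rates, DEFAULT_CONDITIONS)
        assert np.allclose(tr["AS"], 20e-6)
        assert np.allclose(tr["FlOH"], 0.0)
        assert np.allclose(tr["FlBA"], 25e-6)

    def test_equal_partition_halves_product(self, control_trajectory):
        # k_nuc*[nuc] == k_o2*[O2] splits HNO evenly between the channels
        rates = DEFAULT_RATES.with_nucleophile(1.8e4)
        cond = DEFAULT_CONDITIONS.with_nucleophile(225e-6)
        tr = integrate_full_model(rates, cond)
        ratio = tr["FlOH"][-1] / control_trajectory["FlOH"][-1]
        assert ratio == pytest.approx(0.5, rel=0.02)

    def test_conservation_invariants(self, control_trajectory):
        assert np.max(np.abs(control_trajectory.nitrogen_residual())) < 1e-10
        assert np.max(np.abs(control_trajectory.probe_residual())) < 1e-10

    def test_conservation_with_scavenger_and_free_o2(self):
        rates = DEFAULT_RATES.with_nucleophile(6.8e3)
        cond = dataclasses.replace(
            DEFAULT_CONDITIONS, nucleophile0=1e-3, o2_clamped=False
        )
        tr = integrate_full_model(rates, cond)
        assert np.max(np.abs(tr.nitrogen_residual())) < 1e-10
        assert np.max(np.abs(tr.probe_residual())) < 1e-10
        assert np.all(tr.data >= 0.0)

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            integrate_full_model(DEFAULT_RATES, DEFAULT_CONDITIONS, [0.0, 0.0, 1.0])
        with pytest.raises(ValueError):
            integrate_full_model(DEFAULT_RATES, DEFAULT_CONDITIONS, [1.0, 2.0])

    def test_tidy_frame_roundtrip(self, control_trajectory, tmp_path):
        frame = control_trajectory.to_frame()
        assert set(frame.columns) == {"time_s", "species", "concentration_M"}
        assert len(frame) == len(control_trajectory.times) * len(SPECIES)
        control_trajectory.to_csv(tmp_path / "traj.csv")
        assert (tmp_path / "traj.csv").exists()


class TestSteadyState:
    def test_reference_hno_level(self):
        expected = 8e-4 * 20e-6 / (1.8e4 * 225e-6)  # ~3.95 nM
        assert hno_steady_state(DEFAULT_RATES, DEFAULT_CONDITIONS) == pytest.approx(
            expected, rel=1e-12
        )

    def test_ode_plateau_matches_closed_form(self, control_trajectory):
        # full model relaxes onto the QSS level within a few lifetimes
        ss = hno_steady_state(DEFAULT_RATES, DEFAULT_CONDITIONS)
        assert control_trajectory["HNO"][10] == pytest.approx(ss, rel=0.03)

    def test_no_donor_no_hno(self):
        cond = dataclasses.replace(DEFAULT_CONDITIONS, as0=0.0)
        assert hno_steady_state(DEFAULT_RATES, cond) == 0.0

    def test_homogeneity_in_loss_rates(self):
        r1 = DEFAULT_RATES.with_nucleophile(1e3)
        c1 = DEFAULT_CONDITIONS.with_nucleophile(1e-3)
        r2 = dataclasses.replace(r1, k_nucleophile=2e3, k_o2=3.6e4)
        assert hno_steady_state(r2, c1) == pytest.approx(
            hno_steady_state(r1, c1) / 2.0, rel=1e-12
        )

    def test_zero_denominator_raises(self):
        rates = dataclasses.replace(DEFAULT_RATES, k_o2=0.0)
        with pytest.raises(ValueError, match="loss"):
            hno_steady_state(rates, DEFAULT_CONDITIONS)

    def test_fluorescein_rates_reference(self):
        ss = fluorescein_rates(DEFAULT_RATES, DEFAULT_CONDITIONS)
        assert isinstance(ss, SteadyStateSolution)
        assert ss.v0 == pytest.approx(1.6e-8, rel=1e-12)
        assert ss.vi == ss.v0  # no scavenger
        assert ss.onoo_ss == pytest.approx(
            1.8e4 * 225e-6 * ss.hno_ss / (1e6 * 25e-6), rel=1e-12
        )

    def test_equal_partition_halves_vi(self):
        rates = DEFAULT_RATES.with_nucleophile(1.8e4)
        cond = DEFAULT_CONDITIONS.with_nucleophile(225e-6)
        ss = fluorescein_rates(rates, cond)
        assert ss.vi == pytest.approx(ss.v0 / 2.0, rel=1e-12)

    def test_strong_scavenger_limit(self):
        rates = DEFAULT_RATES.with_nucleophile(1e12)
        cond = DEFAULT_CONDITIONS.with_nucleophile(1e-2)
        ss = fluorescein_rates(rates, cond)
        assert ss.vi < 1e-6 * ss.v0
        assert ss.vi <= ss.v0

    def test_zero_probe_raises(self):
        cond = dataclasses.replace(DEFAULT_CONDITIONS, probe0=0.0)
        with pytest.raises(ValueError, match="probe0"):
            fluorescein_rates(DEFAULT_RATES, cond)


class TestInhibitionLaw:
    def test_balanced_channels_give_unity(self):
        rates = DEFAULT_RATES.with_nucleophile(1.8e4)
        assert inhibition_prediction(rates, 225e-6, 225e-6) == pytest.approx(1.0)

    def test_printed_example_value(self):
        # k = 2.2e3, [nuc] = 1 mM, [O2] = 225 uM -> (2.2e3/1.8e4)*(1e-3/2.25e-4)
        rates = DEFAULT_RATES.with_nucleophile(2.2e3)
        assert inhibition_prediction(rates, 1e-3, 225e-6) == pytest.approx(
            0.54320987654, rel=1e-9
        )

    def test_no_scavenger_no_inhibition(self):
        assert inhibition_prediction(DEFAULT_RATES.with_nucleophile(5e3), 0.0, 225e-6) == 0.0

    @pytest.mark.parametrize("k_nuc,nuc", [(10.0, 1e-5), (2.2e3, 1e-3), (1e5, 1e-2)])
    def test_identity_with_rate_ratio(self, k_nuc, nuc):
        # v0/vi - 1 computed from the closed-form rates equals the law itself
        rates = DEFAULT_RATES.with_nucleophile(k_nuc)
        cond = DEFAULT_CONDITIONS.with_nucleophile(nuc)
        ss = fluorescein_rates(rates, cond)
        assert ss.inhibition() == pytest.approx(
            inhibition_prediction(rates, nuc, cond.o2), rel=1e-12
        )

    def test_zero_o2_rejected(self):
        with pytest.raises(ValueError):
            inhibition_prediction(DEFAULT_RATES, 1e-3, 0.0)


class TestFluxPartition:
    def test_fractions_sum_to_one(self, control_trajectory):
        parts = flux_partition(control_trajectory)
        assert sum(parts.values()) == pytest.approx(1.0, abs=1e-6)
        assert all(0.0 <= v <= 1.0 for v in parts.values())

    def test_no_dimerization_channel_when_disabled(self):
        rates = dataclasses.replace(DEFAULT_RATES, k_dim=0.0)
        tr = integrate_full_model(rates, DEFAULT_CONDITIONS)
        assert flux_partition(tr)["dimerization"] == 0.0

    def test_equal_partition_is_symmetric(self):
        rates = DEFAULT_RATES.with_nucleophile(1.8e4)
        cond = DEFAULT_CONDITIONS.with_nucleophile(225e-6)
        tr = integrate_full_model(rates, cond)
        parts = flux_partition(tr)
        assert parts["o2"] == pytest.approx(parts["nucleophile"], rel=0.01)

    def test_dimerization_fraction_matches_oracle(self, control_trajectory):
        # independent RK4 integration of the same channel fluxes
        t_ref, ref = rk4_reference(
            k_as=8e-4, k_o2=1.8e4, k_probe=1e6, k_dim=8e6, k_nuc=0.0,
            as0=20e-6, probe0=25e-6, o2=225e-6, t_end=600.0, dt=0.01,
        )
        h = ref["HNO"]
        dim = np.trapezoid(2 * 8e6 * h * h, t_ref)
        o2f = np.trapezoid(1.8e4 * 225e-6 * h, t_ref)
        expected = dim / (dim + o2f)
        parts = flux_partition(control_trajectory)
        assert parts["dimerization"] == pytest.approx(expected, rel=0.02)
        # small, consistent with treating dimerization as a minor channel
        assert parts["dimerization"] < 0.02

    def test_no_consumption_raises(self):
        rates = dataclasses.replace(DEFAULT_RATES, k_as=0.0)
        tr = integrate_full_model(rates, DEFAULT_CONDITIONS)
        with pytest.raises(ValueError, match="consumed"):
            flux_partition(tr)
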