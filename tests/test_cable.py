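"""Cable simulator: geometry identities, conservation laws, analytic oracles."""

import numpy as np
import pytest

from gdpflux import ionphys
from gdpflux.cable import (BuildError, ClampSpec, PassiveParams,
                           SynapseSpec, TransportParams, discretize,
                           gaba_current)
from gdpflux.morphology import Morphology, MorphologyError, Section


class TestDiscretize:
    def test_cylinder_membrane_area(self, ball_and_stick):
        m = discretize(ball_and_stick, nseg_rule=1)
        dend = m.seg_area[m.seg_is_dendrite]
        assert dend.sum() == pytest.approx(2 * np.pi * 1.0 * 100.0, rel=1e-12)

    def test_shell_volumes_partition_cytoplasm(self, small_surrogate):
        m = discretize(small_surrogate)
        assert m.zone_volume.sum() == pytest.approx(
            small_surrogate.total_volume, rel=1e-9)

    def test_dlambda_refinement_preserves_area(self, small_surrogate):
        coarse = discretize(small_surrogate, nseg_rule=0.1)
        fine = discretize(small_surrogate, nseg_rule=0.05)
        assert fine.n_seg > coarse.n_seg
        assert fine.seg_area.sum() == pytest.approx(coarse.seg_area.sum(),
                                                    rel=1e-12)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(MorphologyError):
            Morphology([Section(id=1, parent_id=-1, length=0.0,
                                diam_prox=10.0, diam_dist=10.0,
                                region="soma")])


class TestGabaCurrent:
    def test_zero_driving_force(self):
        assert gaba_current(-57.3, 1.0, -57.3, -57.3, 0.44) == (0.0, 0.0)

    def test_pure_chloride_limit(self):
        i_cl, i_hco3 = gaba_current(0.0, 2.0, -60.0, -10.0, p=0.0)
        assert i_hco3 == 0.0
        assert i_cl == pytest.approx(2.0 * 60.0)

    def test_branch_split_worked_example(self):
        i_cl, i_hco3 = gaba_current(0.0, 1.0, -57.3, -13.9, 0.44)
        assert i_cl == pytest.approx(57.3 / 1.44, abs=0.05)
        assert i_hco3 == pytest.approx(0.44 * 13.9 / 1.44, abs=0.01)

    def test_branches_sum_to_total(self):
        v, g, p = -40.0, 3.0, 0.44
        e_cl, e_h = -45.0, -14.0
        i_cl, i_h = gaba_current(v, g, e_cl, e_h, p)
        total = g / (1 + p) * (v - e_cl) + g * p / (1 + p) * (v - e_h)
        assert i_cl + i_h == pytest.approx(total, rel=1e-12)


class TestEquilibriumAndConservation:
    def test_resting_state_is_fixed_point(self, ball_and_stick):
        m = discretize(ball_and_stick)
        m.set_concentrations(30.0, 14.1)
        rec = m.advance(1000.0, dt=0.1, record_every=100.0)
        assert np.max(np.abs(rec["v_soma"] - m.passive.e_leak)) < 1e-9
        assert np.max(np.abs(rec["cl_dend"] - 30.0)) < 1e-9
        assert np.max(np.abs(rec["hco3_dend"] - 14.1)) < 1e-9

    def test_diffusion_conserves_mass(self, small_model):
        import copy
        m = copy.deepcopy(small_model)
        rng = np.random.default_rng(3)
        m.cl = rng.uniform(5.0, 60.0, m.cl.shape)
        m.hco3 = rng.uniform(5.0, 25.0, m.hco3.shape)
        cl0, h0 = m.total_moles("cl"), m.total_moles("hco3")
        m.advance(10_000.0, dt=1.0)
        assert m.total_moles("cl") == pytest.approx(cl0, rel=1e-6)
        assert m.total_moles("hco3") == pytest.approx(h0, rel=1e-6)

    def test_diffusion_equilibrates_to_uniform(self, ball_and_stick):
        m = discretize(ball_and_stick, nseg_rule=5)
        m.cl[:] = 10.0
        m.cl[-1, :] = 50.0  # distal load
        m.advance(60_000.0, dt=1.0)
        assert np.ptp(m.cl) < 0.5  # spatially uniform after a minute

    def test_synaptic_chloride_bookkeeping(self, single_compartment):
        """Total Cl gained equals the integral of the Cl branch current."""
        m = discretize(single_compartment, nseg_rule=1)
        m.set_concentrations(10.0, 14.1)
        m.add_synapse(SynapseSpec(section=1, position=0.5, kind="gaba",
                                  g_peak=1.0, onset=20.0))
        m.attach_clamp(ClampSpec(mode="sevc", rs=0.5, command=lambda t: 0.0))
        moles0 = m.total_moles("cl")
        dt = 0.01
        rec = m.advance(600.0, dt=dt)
        gained = m.total_moles("cl") - moles0          # mM*um^3 = 1e-18 mol
        integral = np.sum(rec["i_cl"]) * dt * 1e3 / ionphys.FARADAY
        assert gained == pytest.approx(integral, rel=5e-3)


class TestTransportRelaxation:
    @pytest.mark.parametrize("start,tau", [(20.0, 174.0), (40.0, 321.0)])
    def test_bimodal_e_fold_times(self, ball_and_stick, start, tau):
        """Uptake below rest relaxes with 174 s, extrusion above with 321 s."""
        m = discretize(ball_and_stick, nseg_rule=1)
        m.set_concentrations(start, 14.1)
        m.set_transport(TransportParams(cl_rest=30.0))
        m.diffusion_enabled = True
        dev0 = 30.0 - start
        m.advance(tau * 1e3, dt=50.0)
        dev = 30.0 - m.mean_dendritic_concentration("cl")
        # after exactly one nominal tau the deviation is dev0/e
        measured_tau = tau / -np.log(dev / dev0)
        assert measured_tau == pytest.approx(tau, rel=0.02)


class TestClamp:
    def test_low_rs_clamps_to_command(self, ball_and_stick):
        m = discretize(ball_and_stick)
        m.attach_clamp(ClampSpec(mode="sevc", rs=0.5, command=lambda t: -30.0))
        m.advance(100.0, dt=0.025)
        assert abs(m.v[m.soma_seg] - (-30.0)) < 0.1

    def test_high_rs_steady_state_error_is_voltage_divider(self,
                                                           ball_and_stick):
        m = discretize(ball_and_stick)
        r_in = m.input_resistance() * 1e3  # MOhm
        rs = 40.0
        step = 20.0
        cmd = m.passive.e_leak + step
        m.attach_clamp(ClampSpec(mode="sevc", rs=rs, command=lambda t: cmd))
        m.advance(200.0, dt=0.025)
        expected_err = step * rs / (rs + r_in)
        assert cmd - m.v[m.soma_seg] == pytest.approx(expected_err, rel=0.01)

    def test_zero_command_on_resting_cell_draws_no_current(self,
                                                           ball_and_stick):
        m = discretize(ball_and_stick)
        cmd = m.passive.e_leak
        m.attach_clamp(ClampSpec(mode="sevc", rs=5.0, command=lambda t: cmd))
        rec = m.advance(50.0, dt=0.025)
        assert np.max(np.abs(rec["i_clamp"])) < 1e-9

    def test_invalid_rs_rejected(self):
        with pytest.raises(BuildError):
            ClampSpec(mode="sevc", rs=0.0)

    def test_static_synaptic_reversal_recovered_at_soma(self,
                                                        ball_and_stick):
        """Somatic GABA reversal under good clamp matches the
        conductance-weighted mean of the two branch Nernst potentials."""
        from gdpflux.protocols import determine_egaba
        m = discretize(ball_and_stick)
        m.set_concentrations(30.0, 14.4)
        m.freeze_ions(True)
        e_cl = ionphys.nernst(30.0, 133.5)
        e_h = ionphys.nernst(14.4, 24.0)
        expected = (e_cl + 0.44 * e_h) / 1.44
        got = determine_egaba(m, rs=5.0, site=(1, 0.5))  # soma site
        assert got == pytest.approx(expected, abs=0.5)


class TestMeanDendriticConcentration:
    def test_uniform_state(self, small_model):
        import copy
        m = copy.deepcopy(small_model)
        m.set_concentrations(30.0, 14.1)
        assert m.mean_dendritic_concentration("cl") == pytest.approx(30.0)

    def test_two_equal_volume_pools_average(self):
        morph = Morphology([
            Section(id=1, parent_id=-1, length=10, diam_prox=10,
                    diam_dist=10, region="soma"),
            Section(id=2, parent_id=1, length=100, diam_prox=2, diam_dist=2),
            Section(id=3, parent_id=1, length=100, diam_prox=2, diam_dist=2),
        ])
        m = discretize(morph, nseg_rule=1)
        dend = np.nonzero(m.seg_is_dendrite)[0]
        m.cl[dend[0]] = 10.0
        m.cl[dend[1]] = 50.0
        assert m.mean_dendritic_concentration("cl") == pytest.approx(30.0)

    def test_matches_bruteforce_weighted_sum(self, small_model):
        import copy
        m = copy.deepcopy(small_model)
        rng = np.random.default_rng(9)
        m.cl = rng.uniform(1.0, 80.0, m.cl.shape)
        mask = m.seg_is_dendrite
        brute = (np.sum(m.cl[mask] * m.zone_volume[mask])
                 / np.sum(m.zone_volume[mask]))
        assert m.mean_dendritic_concentration("cl") == pytest.approx(
            brute, rel=1e-12)


class TestGridConvergence:
    def test_refining_time_step_and_shells_changes_delta_cl_little(
            self, ball_and_stick):
        """Halving dt and doubling the shell count moves the peak
        GABA-evoked chloride change by less than 2%."""
        def peak_delta(dt, n_shells):
            m = discretize(ball_and_stick, n_shells=n_shells)
            m.set_concentrations(10.0, 14.1)
            for onset in (10.0, 30.0, 60.0):
                m.add_synapse(SynapseSpec(section=2, position=0.5,
                                          kind="gaba", g_peak=2.0,
                                          onset=onset))
            m.attach_clamp(ClampSpec(mode="sevc", rs=5.0,
                                     command=lambda t: -30.0))
            rec = m.advance(600.0, dt=dt, record_every=5.0)
            return np.max(rec["cl_dend"]) - 10.0

        coarse = peak_delta(0.05, 4)
        fine = peak_delta(0.025, 8)
        assert abs(fine - coarse) / abs(fine) < 0.02


class TestStateSnapshots:
    def test_round_trip_restores_dynamics(self, ball_and_stick, tmp_path):
        m = discretize(ball_and_stick)
        m.set_concentrations(25.0, 12.0)
        m.add_synapse(SynapseSpec(section=2, position=0.5, kind="gaba",
                                  g_peak=2.0, onset=5.0))
        m.advance(50.0, dt=0.1)
        path = tmp_path / "state.npz"
        m.save_state(path)
        v, cl = m.v.copy(), m.cl.copy()
        m.advance(50.0, dt=0.1)
        m.load_state(path)
        assert np.array_equal(m.v, v)
        assert np.array_equal(m.cl, cl)

    def test_mismatched_discretization_rejected(self, ball_and_stick,
                                                single_compartment,
                                                tmp_path):
        from gdpflux.cable import SolverError
        a = discretize(ball_and_stick)
        b = discretize(single_compartment, nseg_rule=1)
        a.save_state(tmp_path / "a.npz")
        with pytest.raises(SolverError):
            b.load_state(tmp_path / "a.npz")


class TestPassiveSanity:
    def test_surrogate_matches_measured_input_resistance_and_tau(
            self, small_surrogate):
        """With the membrane resistivity implied by the measured membrane
        time constant (~100 ms at 1 uF/cm^2), a surrogate at the measured
        capacitance shows R_in and tau_m in the experimental ranges."""
        from gdpflux.synth import SurrogateMorphologySpec, \
            make_surrogate_morphology
        morph = make_surrogate_morphology(SurrogateMorphologySpec(seed=4))
        passive = PassiveParams(rm=100.0, e_leak=-50.0)
        m = discretize(morph, passive)
        r_in = m.input_resistance()
        assert 0.9 <= r_in <= 1.75  # GOhm
        # membrane time constant from a hyperpolarizing current step
        m.attach_clamp(ClampSpec(mode="current_clamp", rs=1.0,
                                 command=lambda t: -2.0))  # pA
        rec = m.advance(400.0, dt=0.25, record_every=0.25)
        v = rec["v_soma"] - m.passive.e_leak
        v_inf = v[-1]
        # time to reach 1 - 1/e of the steady deflection
        idx = np.argmax(v <= v_inf * (1 - 1 / np.e))
        tau = rec["t"][idx]
        assert 60.0 <= tau <= 130.0  # ms; experimental 86-106 ms range
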