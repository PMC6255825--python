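"""In-silico experiments: clamp-bias structure and GDP-driven ion shifts.

These run on a reduced surrogate cell (session fixture) so the whole file
stays within interactive runtimes; the full-size protocol is exercised by
the acceptance script.
"""

import numpy as np
import pytest

from gdpflux import ionphys
from gdpflux.protocols import (CalibrationError, GdpStimulus,
                               calibrate_gdp_charge, measure_clamp_charge,
                               proximal_to_distal_sites, run_gdp_simulation,
                               run_rs_experiment, run_spaceclamp_experiment)


@pytest.fixture(scope="module")
def sites(small_model):
    return proximal_to_distal_sites(small_model)


@pytest.fixture(scope="module")
def rs_table(small_model):
    return run_rs_experiment(small_model)


@pytest.fixture(scope="module")
def gdp_runs_by_cl(small_model):
    stim = GdpStimulus(seed=2)
    return {cl: run_gdp_simulation(small_model, stim, cl_init=cl,
                                   t_post=3000.0)
            for cl in (10.0, 30.0, 50.0)}


class TestRsExperiment:
    def test_egaba_span_below_half_millivolt(self, rs_table):
        assert rs_table.e_gaba.max() - rs_table.e_gaba.min() <= 0.5

    def test_close_to_analytic_two_branch_reversal(self, rs_table):
        e_cl = ionphys.nernst(30.0, 133.5)
        e_h = ionphys.nernst(14.4, 24.0)
        expected = ionphys.split_reversal(e_cl, e_h)
        assert rs_table.e_gaba.iloc[0] == pytest.approx(expected, abs=1.0)

    def test_single_rs_gives_single_row(self, small_model):
        df = run_rs_experiment(small_model, rs_list=(5.0,))
        assert len(df) == 1


class TestSpaceClampExperiment:
    def test_high_chloride_overestimated_distally(self, fine_model):
        sites = proximal_to_distal_sites(fine_model, distances=(5.0, 35.0,
                                                                60.0, 100.0))
        df = run_spaceclamp_experiment(fine_model, sites, cl_i=50.0)
        assert df.apparent_cl.is_monotonic_increasing
        assert df.apparent_cl.iloc[0] == pytest.approx(50.0, abs=2.0)
        assert df.apparent_cl.iloc[-1] > 50.0

    def test_low_chloride_underestimated_distally(self, fine_model):
        sites = proximal_to_distal_sites(fine_model, distances=(5.0, 35.0,
                                                                60.0, 100.0))
        df = run_spaceclamp_experiment(fine_model, sites, cl_i=10.0)
        assert df.apparent_cl.is_monotonic_decreasing
        assert df.apparent_cl.iloc[0] == pytest.approx(10.0, abs=2.0)
        assert df.apparent_cl.iloc[-1] < 10.0

    def test_soma_site_with_ideal_clamp_is_unbiased(self, small_model):
        soma_id = small_model.morph.root.id
        df = run_spaceclamp_experiment(small_model, [(soma_id, 0.5)],
                                       cl_i=30.0, rs=0.5)
        assert df.apparent_cl.iloc[0] == pytest.approx(30.0, abs=1.0)


class TestGdpSimulation:
    @pytest.fixture
    def runs(self, gdp_runs_by_cl):
        return gdp_runs_by_cl

    def test_low_chloride_cells_gain_chloride(self, runs):
        assert runs[10.0]["delta_cl"].max() > 0.1

    def test_high_chloride_cells_lose_chloride(self, runs):
        assert runs[50.0]["delta_cl"].min() < -0.1

    def test_intermediate_chloride_changes_least(self, runs):
        mag = {cl: np.max(np.abs(r["delta_cl"])) for cl, r in runs.items()}
        assert mag[30.0] < mag[10.0]
        assert mag[30.0] < mag[50.0]

    def test_peak_delta_monotone_in_initial_chloride(self, runs):
        def signed_peak(r):
            d = r["delta_cl"]
            return d[np.argmax(np.abs(d))]
        peaks = [signed_peak(runs[cl]) for cl in (10.0, 30.0, 50.0)]
        assert peaks[0] > peaks[1] > peaks[2]

    def test_bicarbonate_falls_in_all_scenarios(self, runs):
        for r in runs.values():
            assert r["delta_hco3"].min() < 0
            assert r["hco3_dend"].min() < r["baseline_hco3"]

    def test_bicarbonate_drop_ordering_follows_driving_force(self, runs):
        """The HCO3- efflux is largest where the barrage holds the
        membrane most negative, i.e. at low initial chloride (the GABA
        mixture reversal is most negative there)."""
        assert runs[10.0]["hco3_dend"].min() < runs[30.0]["hco3_dend"].min()
        assert runs[30.0]["hco3_dend"].min() < runs[50.0]["hco3_dend"].min()

    def test_delta_correlates_with_driving_force(self, runs):
        """Across cells the GDP-induced shift follows DF_Cl at the mean
        event potential (the in-silico analogue of the per-cell
        regression on recordings)."""
        dfs, deltas = [], []
        for cl, r in runs.items():
            active = r["t"] <= 1500.0
            e_m = float(np.mean(r["v_soma"][active]))
            e_gaba = ionphys.ghk_egaba(ionphys.IonState(cl_i=cl))
            dfs.append(ionphys.driving_force(e_m, e_gaba).df_cl)
            d = r["delta_cl"]
            deltas.append(d[np.argmax(np.abs(d))])
        order = np.argsort(dfs)
        assert np.all(np.diff(np.asarray(deltas)[order]) > 0)

    def test_no_synapses_leave_concentrations_flat(self, small_model):
        stim = GdpStimulus(n_gaba=0, n_ampa=0, seed=1)
        r = run_gdp_simulation(small_model, stim, cl_init=30.0,
                               t_post=500.0)
        assert np.max(np.abs(r["delta_cl"])) < 1e-9
        assert np.max(np.abs(r["delta_hco3"])) < 1e-9


class TestChargeCalibration:
    def test_zero_target_removes_gaba(self, small_model):
        stim, q = calibrate_gdp_charge(small_model, GdpStimulus(seed=1),
                                       target_charge=0.0)
        assert stim.n_gaba == 0 and q == 0.0

    def test_negative_target_rejected(self, small_model):
        with pytest.raises(CalibrationError):
            calibrate_gdp_charge(small_model, GdpStimulus(seed=1),
                                 target_charge=-5.0)

    def test_charge_grows_with_synapse_count(self, small_model):
        q_small = measure_clamp_charge(small_model,
                                       GdpStimulus(n_gaba=5, seed=3))
        q_large = measure_clamp_charge(small_model,
                                       GdpStimulus(n_gaba=50, seed=3))
        assert q_large > q_small > 0
        # sublinear growth: driving-force collapse in shared dendrites
        assert q_large < 10 * q_small * 1.05
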