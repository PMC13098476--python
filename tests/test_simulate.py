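import numpy as np
import pytest

import dissipycle as dc
from dissipycle.network import FirstOrder, Reaction, ReactionNetwork


class TestDoseEvent:
    @pytest.mark.parametrize("kwargs", [
        {"time": -1.0}, {"time": 0.0, "amount": -0.5},
        {"time": 0.0, "dilution": 0.0}, {"time": 0.0, "dilution": 1.5},
    ])
    def test_invalid_events_rejected(self, kwargs):
        with pytest.raises(ValueError):
            dc.DoseEvent(**kwargs)


class TestIntegrate:
    def test_without_dissipation_reporter_is_fully_cleaved(self, dz_condition):
        params = dc.default_params("dnazyme_exoIII")
        cond = dz_condition.replace(enzymes={"exoIII": 0.0})
        net = dc.build_network(params, cond)
        sched = (dc.DoseEvent(time=0.0, species="Fuel", amount=2.5),)
        tr = dc.integrate(net, net.initial_state(cond), sched, t_end=5000, dt_out=10.0)
        assert tr.species_series("RepCleaved")[-1] == pytest.approx(2.5, rel=0.01)

    def test_dissipative_reset_returns_protected_strand(self, dz_params, dz_condition,
                                                        dz_network):
        # long horizon: fuel duplex fully digested, S1 restored
        sched = (dc.DoseEvent(time=0.0, species="Fuel", amount=2.5),)
        tr = dc.integrate(dz_network, dz_network.initial_state(dz_condition),
                          sched, t_end=400, dt_out=1.0)
        assert tr.species_series("Dz")[-1] == pytest.approx(0.0, abs=1e-6)
        assert tr.species_series("S1")[-1] == pytest.approx(2.5, rel=1e-4)

    def test_repeated_doses_give_one_rise_plateau_cycle_each(self, dz_params):
        from dissipycle.synthetic import RECYCLABILITY_DOSES_DNAZYME as doses
        cond = dc.default_condition("dnazyme_exoIII", enzymes={"exoIII": 1.5})
        net = dc.build_network(dz_params, cond)
        sched = tuple(dc.DoseEvent(time=t, species="Fuel", amount=2.5) for t in doses)
        tr = dc.integrate(net, net.initial_state(cond), sched, t_end=300, dt_out=0.5)
        dz = tr.species_series("Dz")
        # the active duplex rises after each dose and decays back before the next
        for t_d in doses:
            i = np.searchsorted(tr.time, t_d)
            assert dz[i + 4] > 1.0  # shortly after the dose
            assert dz[i] < 0.2      # pre-dose sample: previous cycle decayed
        assert np.all(np.diff(tr.species_series("Waste")) >= -1e-9)

    def test_dose_time_sample_reports_pre_dose_state(self, dz_network, dz_condition):
        sched = (dc.DoseEvent(time=10.0, species="Fuel", amount=2.5),)
        tr = dc.integrate(dz_network, dz_network.initial_state(dz_condition),
                          sched, t_end=20, dt_out=0.5)
        i = int(np.searchsorted(tr.time, 10.0))
        assert tr.species_series("Fuel")[i] == pytest.approx(0.0, abs=1e-9)
        assert tr.species_series("Fuel")[i + 1] > 1.0

    def test_dilution_scales_all_species(self, dz_network, dz_condition):
        sched = (dc.DoseEvent(time=10.0, species="Fuel", amount=0.0, dilution=0.5),)
        tr = dc.integrate(dz_network, dz_network.initial_state(dz_condition),
                          sched, t_end=11, dt_out=0.5)
        rep = tr.species_series("Rep")
        i = int(np.searchsorted(tr.time, 10.0))
        assert rep[i + 1] == pytest.approx(rep[i] / 2, rel=1e-6)

    def test_unsorted_schedule_rejected(self, dz_network, dz_condition):
        sched = (dc.DoseEvent(time=20.0, amount=1.0), dc.DoseEvent(time=10.0, amount=1.0))
        with pytest.raises(ValueError):
            dc.integrate(dz_network, dz_network.initial_state(dz_condition),
                         sched, t_end=30)

    def test_conservation_and_non_negativity(self, dz_params, dz_condition, dz_network):
        sched = (dc.DoseEvent(time=15.0, species="Fuel", amount=5.0),)
        tr = dc.integrate(dz_network, dz_network.initial_state(dz_condition),
                          sched, t_end=200, dt_out=0.5)
        assert tr.conservation_residual(dz_network) <= 1e-8
        assert tr.states.min() >= -1e-10

    def test_refinement_changes_lifetime_under_half_percent(self, dz_params,
                                                            dz_condition, dz_network):
        sched = (dc.DoseEvent(time=15.0, species="Fuel", amount=2.5),)
        taus = []
        for dt, rtol, atol in ((0.5, 1e-10, 1e-12), (0.25, 1e-12, 1e-14)):
            tr = dc.integrate(dz_network, dz_network.initial_state(dz_condition),
                              sched, t_end=150, dt_out=dt, rtol=rtol, atol=atol)
            sig = dc.observables(tr, dz_params)
            taus.append(dc.transient_lifetime(sig, 15.0).lifetime)
        assert abs(taus[1] - taus[0]) / taus[0] < 0.005

    def test_zero_order_fuel_depletion_matches_closed_form(self):
        # saturated digestion + fast hybridization: depletion at Fuel0/(c*U*phi)
        params = dc.default_params("dnazyme_exoIII").replace(
            k_hyb_dz=200.0, Km_exo=2.5e-4 * 2.5)
        cond = dc.default_condition("dnazyme_exoIII", L_fuel=2)
        net = dc.build_network(params, cond)
        fuel0 = 25.0
        phi = dc.toehold_rate_factor(2, "exoIII", params)
        t_pred = fuel0 / (params.c_exo * 0.5 * phi)
        init = net.initial_state(cond)
        init[net.index("Fuel")] = fuel0
        tr = dc.integrate(net, init, (), t_end=1.2 * t_pred, dt_out=t_pred / 500)
        remaining = tr.species_series("Fuel") + tr.species_series("Dz")
        t_dep = tr.time[np.nonzero(remaining <= 0.01 * fuel0)[0][0]]
        assert t_dep == pytest.approx(t_pred, rel=0.05)


class TestObservables:
    def test_linear_map_and_delta(self, dz_params, dz_clean_cycle):
        clean, trace = dz_clean_cycle
        rep_cleaved = trace.species_series("RepCleaved")
        expected = dz_params.F0 + dz_params.alpha_F * rep_cleaved
        assert np.allclose(clean.values, expected)
        delta = dc.observables(trace, dz_params, normalization="delta")
        i = int(np.searchsorted(trace.time, 15.0))
        assert delta.values[i] == pytest.approx(0.0, abs=1e-12)

    def test_minmax_maps_monotone_rise_to_unit_interval(self, dz_params, dz_clean_cycle):
        _, trace = dz_clean_cycle
        sig = dc.observables(trace, dz_params, normalization="minmax")
        assert sig.values.min() == 0.0 and sig.values.max() == 1.0

    def test_unknown_channel_rejected(self, dz_params, dz_clean_cycle):
        with pytest.raises(ValueError):
            dc.observables(dz_clean_cycle[1], dz_params, channel="abs600")

    def test_absorbance_channel_needs_pna_species(self, dz_params, dz_clean_cycle):
        with pytest.raises(ValueError):
            dc.observables(dz_clean_cycle[1], dz_params, channel="abs405")


class TestCsvRoundTrip:
    def test_tidy_csv_round_trip_is_lossless(self, tmp_path, dz_clean_cycle):
        clean, _ = dz_clean_cycle
        sig = clean.replace(condition_id="c1")
        path = tmp_path / "trace.csv"
        dc.write_signals_csv(path, [sig])
        (back,) = dc.read_signals_csv(path)
        assert back.channel == sig.channel
        assert np.array_equal(back.time, sig.time)
        assert np.array_equal(back.values, sig.values)


def _decay_network(k=0.2):
    return ReactionNetwork(
        circuit_id="dnazyme_exoIII",
        species=("S1", "Fuel", "Dz", "Rep", "RepCleaved", "Waste"),
        reactions=(
            Reaction("decay", {"Rep": -1, "RepCleaved": +1}, FirstOrder(k, "Rep")),
        ),
        conserved=(("mass", {"Rep": 1, "RepCleaved": 1}),),
    )


class TestSSA:
    def test_same_seed_reproduces_trajectory(self, dz_network, dz_condition):
        init = dz_network.initial_state(dz_condition)
        init[dz_network.index("Fuel")] = 2.5
        runs = [dc.ssa_simulate(dz_network, init, t_end=10, dt_out=1.0,
                                volume_scale=500, n_runs=1, seed=42)[0]
                for _ in range(2)]
        assert np.array_equal(runs[0].states, runs[1].states)

    def test_first_order_decay_matches_exponential_closed_form(self):
        net = _decay_network(k=0.2)
        init = np.zeros(6)
        init[net.index("Rep")] = 10.0
        mean, _ = dc.ssa_simulate(net, init, t_end=20, dt_out=1.0,
                                  volume_scale=1000, n_runs=60, seed=7)
        expected = 10.0 * np.exp(-0.2 * mean.time)
        err = np.max(np.abs(mean.species_series("Rep") - expected)) / 10.0
        assert err < 0.02

    def test_zero_copy_required_species_rejected(self, dz_network, dz_condition):
        init = dz_network.initial_state(dz_condition)
        init[dz_network.index("Fuel")] = 1e-9  # rounds to zero copies
        with pytest.raises(ValueError, match="volume_scale"):
            dc.ssa_simulate(dz_network, init, t_end=10, dt_out=1.0,
                            volume_scale=100, n_runs=1, seed=0)

    def test_mean_field_agreement_with_ode_at_moderate_copy_number(
            self, dz_network, dz_condition):
        init = dz_network.initial_state(dz_condition)
        init[dz_network.index("Fuel")] = 2.5
        mean, _ = dc.ssa_simulate(dz_network, init, t_end=40, dt_out=2.0,
                                  volume_scale=2000, n_runs=30, seed=3)
        ode = dc.integrate(dz_network, init, (), t_end=40, dt_out=2.0)
        ref = ode.species_series("RepCleaved")
        err = np.max(np.abs(mean.species_series("RepCleaved") - ref)) / ref.max()
        assert err < 0.05
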