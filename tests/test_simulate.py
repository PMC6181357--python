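"""Engine-level behaviour: invariants of whole trajectories."""

import numpy as np
import pytest

import nestsim as ns

MOC = 10_000.0 / 300.0
ALL_SCENARIOS = ns.list_scenarios()


class TestBasicShape:
    def test_annual_sampling_inclusive(self, run_scenario):
        traj = run_scenario("burete_base")
        assert len(traj.frame) == 129  # 1890..2018 inclusive
        assert traj.years[0] == 1890 and traj.years[-1] == 2018

    def test_dt_must_divide_a_year(self):
        config = ns.build_unmanaged_2010().with_overrides(dt=0.3)
        with pytest.raises(ns.InvalidConfigError, match="divide one year"):
            ns.simulate(config)


class TestInvariants:
    @pytest.mark.parametrize("scenario_id", ALL_SCENARIOS)
    def test_stocks_never_negative(self, run_scenario, scenario_id):
        traj = run_scenario(scenario_id)
        assert (traj.on >= 0).all() and (traj.tn >= 0).all()

    def test_capacity_bound_in_unmanaged_runs(self, run_scenario):
        traj = run_scenario("burete_base")
        assert (traj.on <= MOC + 1e-9).all()

    def test_start_at_equilibrium_stays_constant(self, unmanaged_ref):
        assert np.ptp(unmanaged_ref.on) <= 1e-3 * MOC
        assert np.ptp(unmanaged_ref.tn) <= 1e-3 * unmanaged_ref.tn[0]

    def test_extinction_is_absorbing_and_nests_decay(self):
        config = ns.build_burete_base().with_overrides(
            initial_on=0.0, initial_tn=50.0, t0=2000, t1=2080
        )
        traj = ns.simulate(config)
        assert (traj.on == 0.0).all()
        assert traj.tn[-1] < 1.1  # 80 years of exp decay at 1/20.68 per yr
        assert (np.diff(traj.tn) < 0).all()

    def test_unmanaged_convergence_to_analytic_equilibrium(self):
        """From a moderate start the run settles on (moc, moc*nbr*nlf) to
        within 1 % after 120 years."""
        params = ns.ModelParams()
        tn_eq = ns.equilibrium_total_nests(MOC, params.nbr, params.nlf)
        config = ns.build_burete_base().with_overrides(
            t0=0, t1=120, initial_on=0.5 * MOC, initial_tn=0.5 * tn_eq
        )
        traj = ns.simulate(config)
        assert traj.on[-1] == pytest.approx(MOC, rel=0.01)
        assert traj.tn[-1] == pytest.approx(tn_eq, rel=0.01)

    def test_base_run_asymptote_matches_closed_form(self):
        """Extending the colonisation run far enough reaches the analytic
        total-nest equilibrium (the 2018 horizon itself is still ~5 % short
        because tn relaxes on a 20.7-yr time constant)."""
        params = ns.ModelParams()
        tn_eq = ns.equilibrium_total_nests(MOC, params.nbr, params.nlf)
        traj = ns.simulate(ns.build_burete_base().with_overrides(t1=2200))
        assert traj.tn[-1] == pytest.approx(tn_eq, rel=1e-3)
        assert traj.on[-1] == pytest.approx(MOC, rel=1e-6)

    @pytest.mark.parametrize("rotation", [40, 50, 60, 70])
    def test_protection_dominates_pointwise(self, run_scenario, rotation):
        prot = run_scenario(f"cut{rotation}_prot")
        noprot = run_scenario(f"cut{rotation}_noprot")
        assert (prot.on >= noprot.on - 1e-9).all()
        assert (prot.tn >= noprot.tn - 1e-9).all()

    def test_mean_occupancy_monotone_in_rotation_age(self, run_scenario):
        means = [run_scenario(f"cut{r}_noprot").on.mean() for r in (40, 50, 60, 70)]
        assert means == sorted(means)

    @pytest.mark.parametrize("scenario_id", ["burete_base", "cut40_prot",
                                             "cut70_noprot", "espuna"])
    def test_halving_dt_leaves_annual_values_unchanged(self, run_scenario, scenario_id):
        """Richardson check: at the default step, halving dt moves every
        annual value by < 0.1 % of the trajectory scale."""
        coarse = run_scenario(scenario_id)
        config = coarse.config
        fine = ns.simulate(config.with_overrides(dt=config.dt / 2.0))
        for attr in ("on", "tn"):
            a, b = getattr(coarse, attr), getattr(fine, attr)
            scale = max(np.max(np.abs(a)), 1e-12)
            assert np.max(np.abs(a - b)) < 1e-3 * scale

    def test_rerun_is_bit_identical(self, run_scenario):
        config = ns.get_scenario("cut50_prot")
        a = run_scenario("cut50_prot")
        b = ns.simulate(config)
        assert a.frame.equals(b.frame)


class TestPulseAccounting:
    def test_nest_discontinuities_equal_logged_pulses(self, run_scenario):
        traj = run_scenario("cut70_noprot")
        assert len(traj.events) == 4
        for event in traj.events:
            assert event.tn_before - event.nests_lost == pytest.approx(
                event.tn_after, abs=1e-12
            )
            row = traj.at(event.year)
            assert row["tn"] == pytest.approx(event.tn_after, abs=1e-12)
            assert row["nlfc_pulse"] == pytest.approx(event.nests_lost, abs=1e-12)

    def test_rotation70_pulse_fraction(self, run_scenario):
        # one of four even-aged mature blocks is removed per cut
        traj = run_scenario("cut70_noprot")
        assert traj.events[0].mfcr == pytest.approx(0.25)

    def test_protection_scales_pulse_loss_by_protection_factor(self, run_scenario):
        noprot = run_scenario("cut70_noprot").events[0]
        prot = run_scenario("cut70_prot").events[0]
        assert prot.mfcr == noprot.mfcr
        assert prot.nests_lost == pytest.approx(0.1 * noprot.nests_lost, rel=1e-9)

    def test_continuous_step_matches_engine_between_pulses(self, run_scenario):
        """The public step() reproduces the engine's annual samples in an
        unmanaged stretch (flow/stock bookkeeping is consistent)."""
        traj = run_scenario("burete_base")
        params = traj.config.params
        row = traj.at(1950)
        state = ns.NestState(t=1950.0, tn=row["tn"], on=row["on"])
        n = round(1.0 / traj.config.dt)
        for _ in range(n):
            state = ns.step(state, params, MOC, traj.config.dt)
        nxt = traj.at(1951)
        assert state.on == pytest.approx(nxt["on"], abs=1e-9)
        assert state.tn == pytest.approx(nxt["tn"], abs=1e-9)


class TestEspuna:
    def test_no_occupancy_before_first_mature_year(self, run_scenario):
        traj = run_scenario("espuna")
        frame = traj.frame
        before = frame[frame["year"] < 1943]
        assert (before["on"] == 0.0).all()
        assert (before["moc"] == 0.0).all()

    def test_seeded_then_strictly_increasing(self, run_scenario):
        traj = run_scenario("espuna")
        after = traj.frame[traj.frame["year"] >= 1943]
        assert after["on"].iloc[0] == pytest.approx(1.0)
        assert (np.diff(after["on"]) > 0).all()

    def test_still_in_transition_phase_at_end(self, run_scenario):
        traj = run_scenario("espuna")
        assert traj.on[-1] < traj.moc[-1]
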