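"""Network topology, canonical constants, ODE integration and equilibrium."""

import json

import numpy as np
import pytest

import gltkin as g
from gltkin.scheme import (
    COMPOSITION,
    RateConstants,
    RateSet,
    _kd3_from_affinity_anchor,
)


class TestTopology:
    def test_variant_topologies(self):
        asp = g.build_scheme("P11W_ASP")
        assert len(asp.reactions) == 6
        assert len(asp.complexes) == 6
        tboa = g.build_scheme("P11W_TBOA")
        assert [r.index for r in tboa.reactions] == [1, 2, 3, 4, 5]
        assert "TANa3" not in tboa.complexes
        fm = g.build_scheme("FM_ASP")
        assert fm.reactions == asp.reactions
        assert fm.complexes == asp.complexes

    def test_unknown_variant_names_valid_set(self):
        with pytest.raises(ValueError, match="P11W_ASP"):
            g.build_scheme("WT")

    def test_connectivity_matches_mechanism(self):
        sch = g.build_scheme("P11W_ASP")
        table = {r.index: (r.reactant, r.ligand, r.product) for r in sch.reactions}
        assert table[1] == ("T", "Na", "TNa")
        assert table[2] == ("TNa", "Na", "TNa2")
        assert table[3] == ("TNa", "A", "TANa")
        assert table[4] == ("TNa2", "A", "TANa2")
        assert table[5] == ("TANa", "Na", "TANa2")
        assert table[6] == ("TANa2", "Na", "TANa3")

    def test_single_closed_cycle_between_tna_and_tana2(self):
        # paths 2->4 and 3->5 both connect TNa to TANa2
        sch = g.build_scheme("P11W_ASP")
        table = {r.index: r for r in sch.reactions}
        assert (table[2].reactant, table[4].product) == ("TNa", "TANa2")
        assert (table[3].reactant, table[5].product) == ("TNa", "TANa2")


class TestCanonicalRates:
    def test_printed_constants(self, asp_rates):
        assert asp_rates.on(1) == 36.0
        assert asp_rates.kd(1) == pytest.approx(0.5)
        assert asp_rates.kd(2) == pytest.approx(0.08)
        assert asp_rates.kd(5) == pytest.approx(5e-4)
        assert asp_rates.kd(6) == pytest.approx(1e-5)
        assert asp_rates.off(3) == pytest.approx(0.2)
        for i in (2, 5, 6):
            assert asp_rates.on(i) == 1e7

    def test_cycle_closure(self, asp_rates, tboa_rates, fm_rates):
        for rs in (asp_rates, tboa_rates, fm_rates):
            assert g.check_detailed_balance(rs) < 1e-6

    def test_cycle_residual_arithmetic(self, asp_rates):
        doubled = asp_rates.updated(off4=asp_rates.off(4) * 2)
        assert g.check_detailed_balance(doubled) == pytest.approx(1.0)

    def test_kd3_anchor_solves_apparent_affinity(self):
        assert _kd3_from_affinity_anchor() == pytest.approx(4.05e-5, rel=1e-3)

    def test_variant_scalings(self, asp_rates, tboa_rates, fm_rates):
        assert tboa_rates.off(3) == pytest.approx(20 * asp_rates.off(3))
        assert tboa_rates.off(4) == pytest.approx(20 * asp_rates.off(4))
        assert tboa_rates.on(3) == asp_rates.on(3)
        assert fm_rates.on(1) == pytest.approx(4 * asp_rates.on(1))
        assert fm_rates.kd(1) == pytest.approx(0.125)
        assert fm_rates.off(3) == pytest.approx(1000 * asp_rates.off(3))
        assert fm_rates.off(4) == pytest.approx(1000 * asp_rates.off(4))

    def test_json_round_trip_bit_stable(self, asp_rates, tmp_path):
        path = tmp_path / "rates.json"
        asp_rates.to_json(path)
        back = RateSet.from_json(path)
        for i in range(1, 7):
            assert back.on(i) == asp_rates.on(i)
            assert back.off(i) == asp_rates.off(i)
            assert back.fixed(i) == asp_rates.fixed(i)
        # a second write is byte-identical
        path2 = tmp_path / "rates2.json"
        back.to_json(path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_rejects_nonpositive_rates(self):
        with pytest.raises(ValueError):
            RateSet("P11W_ASP", {1: RateConstants(-1.0, 2.0)})
        with pytest.raises(ValueError):
            RateSet("P11W_ASP", {1: RateConstants(1.0, float("inf"))})


class TestMassAction:
    def test_zero_state_zero_derivative(self, asp_scheme, asp_rates):
        dc = g.mass_action_rhs(asp_scheme, asp_rates, np.zeros(8))
        assert np.all(dc == 0)

    def test_hand_evaluated_first_binding_term(self, asp_scheme, asp_rates):
        state = {"T": 1e-6, "Na": 1e-3}
        dc = g.mass_action_rhs(asp_scheme, asp_rates, state)
        # only reaction 1 runs: d[TNa]/dt = 36 * 1e-3 * 1e-6
        assert dc[asp_scheme.species_index("TNa")] == pytest.approx(36e-9)

    def test_conserved_totals_have_zero_derivative(self, asp_scheme, asp_rates):
        rng = np.random.default_rng(3)
        for _ in range(10):
            state = rng.uniform(0, 1e-3, 8)
            dc = g.mass_action_rhs(asp_scheme, asp_rates, state)
            cols = [asp_scheme.species_index(c) for c in asp_scheme.complexes]
            assert abs(dc[cols].sum()) < 1e-16 * max(abs(dc).max(), 1)
            d_na = dc[asp_scheme.species_index("Na")] + sum(
                COMPOSITION[c][0] * dc[asp_scheme.species_index(c)]
                for c in asp_scheme.complexes
            )
            assert abs(d_na) < 1e-12 * max(abs(dc).max(), 1)

    def test_rejects_negative_concentrations(self, asp_scheme, asp_rates):
        state = np.zeros(8)
        state[0] = -1e-6
        with pytest.raises(ValueError):
            g.mass_action_rhs(asp_scheme, asp_rates, state)

    def test_zero_derivative_at_equilibrium(self, asp_scheme, asp_rates):
        eq = g.equilibrium_state(
            asp_scheme, asp_rates, {"T": 1e-6, "Na": 1e-3, "A": 1e-4}
        )
        dc = g.mass_action_rhs(asp_scheme, asp_rates, eq.as_vector())
        flux_scale = asp_rates.on(1) * 1e-6 * 1e-3
        assert np.max(np.abs(dc)) < 1e-9 * flux_scale


class TestSimulation:
    def test_conservation_along_trajectory(self, asp_scheme, asp_rates):
        traj = g.simulate_timecourse(
            asp_scheme,
            asp_rates,
            {"T": 1e-6, "Na": 1e-3, "A": 1e-4},
            np.linspace(0, 500, 120),
        )
        for total in traj.conserved_totals().values():
            assert np.max(np.abs(total - total[0])) <= 1e-6 * total[0]
        assert traj.concentrations.min() > -1e-12

    def test_irreversible_limit_accumulates_fully_bound(self, asp_scheme, asp_rates):
        # off-rates ~0 with excess ligands: monotone accumulation of TANa3
        rs = asp_rates
        tiny = {f"off{i}": rs.on(i) * 1e-30 for i in range(1, 7)}
        irr = rs.updated(**tiny)
        traj = g.simulate_timecourse(
            asp_scheme, irr, {"T": 1e-6, "Na": 0.1, "A": 1e-2},
            np.linspace(0, 5.0, 80),
        )
        tana3 = traj.series("TANa3")
        assert np.all(np.diff(tana3) >= -1e-15)
        assert tana3[-1] > 0.95e-6

    def test_long_time_state_matches_equilibrium_solver(self, asp_scheme, asp_rates):
        totals = {"T": 1e-6, "Na": 1e-3, "A": 1e-4}
        eq = g.equilibrium_state(asp_scheme, asp_rates, totals)
        traj = g.simulate_timecourse(
            asp_scheme, asp_rates, totals, np.geomspace(1e-3, 2e4, 60)
        )
        v, w = traj.final_state(), eq.as_vector()
        assert np.max(np.abs(v - w) / np.maximum(w, 1e-12)) < 1e-4

    def test_refinement_independence(self, asp_scheme, asp_rates):
        totals = {"T": 1e-6, "Na": 1e-3, "A": 1e-4}
        coarse = g.simulate_timecourse(
            asp_scheme, asp_rates, totals, np.linspace(0, 100, 11)
        )
        fine = g.simulate_timecourse(
            asp_scheme, asp_rates, totals, np.linspace(0, 100, 101)
        )
        a = coarse.concentrations[-1]
        b = fine.concentrations[-1]
        assert np.max(np.abs(a - b) / np.maximum(np.abs(b), 1e-15)) < 1e-6

    def test_bad_time_grid_rejected(self, asp_scheme, asp_rates):
        with pytest.raises(ValueError):
            g.simulate_timecourse(
                asp_scheme, asp_rates, {"T": 1e-6}, np.array([0.0, 1.0, 1.0])
            )


class TestEquilibrium:
    def test_no_ligands_all_apo(self, asp_scheme, asp_rates):
        eq = g.equilibrium_state(asp_scheme, asp_rates, {"T": 1e-6, "Na": 0, "A": 0})
        assert eq.concentrations["T"] == pytest.approx(1e-6)
        assert eq.bound_fraction == 0.0

    def test_saturation_fills_fully_bound(self, asp_scheme, asp_rates):
        eq = g.equilibrium_state(
            asp_scheme, asp_rates, {"T": 1e-6, "Na": 10.0, "A": 0.5}
        )
        assert eq.concentrations["TANa3"] / 1e-6 > 0.999

    def test_two_site_isotherm_oracle(self, asp_scheme, asp_rates):
        eq = g.equilibrium_state(asp_scheme, asp_rates, {"T": 1e-6, "Na": 0.2, "A": 0})
        x = eq.concentrations["Na"]
        k1, k2 = asp_rates.kd(1), asp_rates.kd(2)
        isotherm = x**2 / (x**2 + k2 * x + k1 * k2)
        assert eq.concentrations["TNa2"] / 1e-6 == pytest.approx(isotherm, rel=1e-9)

    def test_detailed_balance_residuals_vanish(self, asp_scheme, asp_rates):
        eq = g.equilibrium_state(
            asp_scheme, asp_rates, {"T": 1e-6, "Na": 2e-3, "A": 5e-5}
        )
        assert max(eq.reaction_flux_residuals(asp_rates).values()) < 1e-9

    def test_random_networks_ode_agrees_with_equilibrium(self, asp_scheme):
        # seeded sweep: the independent algebraic solve and the long-time
        # ODE limit must coincide for arbitrary cycle-closed rate sets
        rng = np.random.default_rng(42)
        for _ in range(20):
            rc = {
                i: RateConstants(10 ** rng.uniform(3, 7), 10 ** rng.uniform(-1, 5))
                for i in range(1, 7)
            }
            # close the thermodynamic cycle through reaction 4
            kd4 = rc[3].kd * rc[5].kd / rc[2].kd
            rc[4] = RateConstants(rc[4].on, rc[4].on * kd4)
            rs = RateSet("P11W_ASP", rc)
            totals = {
                "T": 1e-6,
                "Na": 10 ** rng.uniform(-4, -1),
                "A": 10 ** rng.uniform(-6, -3),
            }
            eq = g.equilibrium_state(asp_scheme, rs, totals)
            traj = g.simulate_timecourse(
                asp_scheme, rs, totals, np.geomspace(1e-6, 1e8, 60)
            )
            v, w = traj.final_state(), eq.as_vector()
            # relative agreement for populated species; trace species
            # (< 0.1% of the transporter pool) compared absolutely
            floor = 1e-3 * totals["T"]
            major = w >= floor
            if major.any():
                assert np.max(np.abs(v[major] - w[major]) / w[major]) < 1e-4
            if (~major).any():
                assert np.max(np.abs(v[~major] - w[~major])) < 1e-4 * totals["T"]

    def test_equilibrium_path_independence_under_cycle_closure(
        self, asp_scheme, asp_rates
    ):
        # weights accumulated through 2->4 equal those through 3->5
        from gltkin.scheme import _weight_coefficients

        coef = _weight_coefficients(asp_scheme, asp_rates)
        via_24 = 1.0 / (asp_rates.kd(1) * asp_rates.kd(2) * asp_rates.kd(4))
        via_35 = 1.0 / (asp_rates.kd(1) * asp_rates.kd(3) * asp_rates.kd(5))
        assert coef["TANa2"] == pytest.approx(via_24, rel=1e-9)
        assert coef["TANa2"] == pytest.approx(via_35, rel=1e-9)


class TestApparentAffinity:
    def test_anchor_value_at_1mM(self, asp_scheme, asp_rates):
        kd = g.apparent_kd_ligand(asp_scheme, asp_rates, 1e-3)
        assert kd == pytest.approx(1e-4, rel=1e-9)

    def test_strictly_decreasing_in_na(self, asp_scheme, asp_rates):
        nas = np.geomspace(1e-5, 1.0, 40)
        kds = [g.apparent_kd_ligand(asp_scheme, asp_rates, x) for x in nas]
        assert np.all(np.diff(kds) < 0)

    def test_log_log_slope_near_three(self, asp_scheme, asp_rates):
        k1 = g.apparent_kd_ligand(asp_scheme, asp_rates, 5e-4)
        k2 = g.apparent_kd_ligand(asp_scheme, asp_rates, 1e-3)
        slope = abs(np.log(k2 / k1) / np.log(2.0))
        assert 2.9 <= slope <= 3.0
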