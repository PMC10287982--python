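"""Whole-cell termination flow model: network, steady state, times, pathways."""

import json
import math
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

from termkin.cell_flow_model import (CODONS, CellParams, SteadyStateError,
                                     average_cycle_time, build_network,
                                     compute_times, pathway_flux_fractions,
                                     relax_to_steady_state, solve_steady_state,
                                     supply_demand_analysis, titrate)

GOLDEN = Path(__file__).parent / "data" / "network_manifest.json"


@pytest.fixture(scope="module")
def default_solution():
    return solve_steady_state(build_network(CellParams()))


@pytest.fixture(scope="module")
def no_rf3_solution():
    return solve_steady_state(build_network(CellParams(rf3_present=False)))


class TestBuildNetwork:
    def test_manifest_matches_golden_file(self):
        man = build_network(CellParams()).manifest()
        golden = json.loads(GOLDEN.read_text())
        assert man["n_species"] == golden["n_species"]
        assert man["n_reactions"] == golden["n_reactions"]
        assert man["species"] == golden["species"]

    def test_invalid_rate_names_offender(self):
        with pytest.raises(ValueError, match="k_release"):
            build_network(CellParams(k_release=-1.0))

    def test_stop_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CellParams(stop_fractions={"UAA": 0.5, "UGA": 0.5, "UAG": 0.5})

    def test_no_rf3_leaves_zero_flux_capacity(self, no_rf3_solution):
        sol = no_rf3_solution
        for c in CODONS:
            for name, conc in sol.concentrations[c].items():
                if "F3" in name or name == "R_PR3":
                    assert conc == pytest.approx(0.0, abs=1e-12)


class TestSteadyState:
    def test_flux_balance_and_conservation(self, default_solution):
        sol = default_solution
        assert sol.residual < 1e-8
        pools = sol.pool_totals()
        p = sol.params
        for c in CODONS:
            assert pools[f"ribosomes_{c}"] == pytest.approx(
                p.stop_fractions[c] * p.ribosome_total, rel=1e-6)
        totals = p.rf_totals
        assert pools["RF1"] == pytest.approx(totals["RF1"], rel=1e-6)
        assert pools["RF2"] == pytest.approx(totals["RF2"], rel=1e-6)
        assert pools["RF3"] == pytest.approx(p.F_tot3, rel=1e-6)

    def test_fixed_point_agrees_with_ode_relaxation_on_random_params(self):
        """Independent-route check: the fixed-point steady state matches
        long-time ODE integration to <0.1% on randomized parameter sets."""
        rng = np.random.default_rng(123)
        for trial in range(20):
            scale = lambda v: float(v * rng.uniform(0.5, 2.0))
            p = CellParams(
                F_tot=scale(1.8), F_tot3=scale(1.0),
                ribosome_total=scale(20.0),
                k_release=scale(10.0), k_split=scale(10.0),
                tau_IR=scale(0.3),
                k_C={"RF1": scale(0.1), "RF2": scale(1.0)},
                k_3on=scale(2.3), k_rot=scale(3.2), k_31D=scale(4.0),
                k_RD_plus={"RF1": scale(2.5), "RF2": scale(3.5)},
                q_S_3D=scale(0.03),
            )
            net = build_network(p)
            fp = solve_steady_state(net)
            ode = relax_to_steady_state(net)
            for c in CODONS:
                for name in fp.concentrations[c]:
                    a = fp.concentrations[c][name]
                    b = ode.concentrations[c][name]
                    if max(a, b) > 1e-9:
                        assert abs(a - b) / max(a, b) < 1e-3, (trial, c, name)

    def test_blocked_termination_accumulates_post_termination_complexes(self):
        # 1e-4/s = a ~3 h factor dwell: termination is blocked on every
        # relevant timescale while the system stays numerically solvable
        p = CellParams(rf3_present=False,
                       k_C={"RF1": 1e-4, "RF2": 1e-4})
        sol = solve_steady_state(build_network(p))
        times = compute_times(sol)
        held = sum(sol.concentrations[c][f"RP_F_{rf}"]
                   for c in CODONS
                   for rf in ("RF1", "RF2")
                   if f"RP_F_{rf}" in sol.concentrations[c])
        # every class-I factor ends up trapped in a post-termination complex
        # and the remaining ribosomes queue in the pre-termination state
        assert held == pytest.approx(p.F_tot, rel=1e-3)
        queued = sum(sol.concentrations[c]["R_A"] for c in CODONS)
        assert queued > 0.9 * (p.ribosome_total - p.F_tot)
        # throughput collapses to the residual leak k_C * [RP_F]
        assert all(j < 2e-4 for j in times.throughput.values())

    def test_rate_rescaling_rescales_fluxes(self):
        """Multiplying every rate constant by two doubles all fluxes and
        leaves steady-state concentrations unchanged (time-unit scaling)."""
        p = CellParams()
        s = 2.0
        p2 = replace(
            p, v_R=p.v_R * s, k_release=p.k_release * s,
            k_C={k: v * s for k, v in p.k_C.items()},
            k_ion={k: v * s for k, v in p.k_ion.items()},
            k_3on=p.k_3on * s, k_3off_GDP=p.k_3off_GDP * s,
            k_3off_GTP=p.k_3off_GTP * s, k_rot=p.k_rot * s,
            k_RD_plus={k: v * s for k, v in p.k_RD_plus.items()},
            k_31D=p.k_31D * s, k_exchange_rib=p.k_exchange_rib * s,
            k_GTP_on=p.k_GTP_on * s, q_S_3D=p.q_S_3D * s,
            tau_IR=p.tau_IR / s, k_split=p.k_split * s)
        a = solve_steady_state(build_network(p))
        b = solve_steady_state(build_network(p2))
        for c in CODONS:
            assert b.throughput(c) == pytest.approx(2 * a.throughput(c),
                                                    rel=1e-6)
            for name in a.concentrations[c]:
                va, vb = a.concentrations[c][name], b.concentrations[c][name]
                if max(va, vb) > 1e-12:
                    assert vb == pytest.approx(va, rel=1e-6)

    def test_nonconvergence_reports_residual(self):
        net = build_network(CellParams())
        with pytest.raises(SteadyStateError, match="residual"):
            solve_steady_state(net, max_iter=1, residual_tol=1e-16)


class TestComputeTimes:
    def test_average_cycle_time_arithmetic(self):
        tau = average_cycle_time({"X": 0.5, "Y": 0.5}, {"X": 10.0, "Y": 20.0})
        assert tau == pytest.approx(1.0 / (0.05 + 0.025))

    def test_reference_operating_point(self, default_solution):
        """The calibrated physiological state: ~17 s average cycle time,
        sub-second RF2 waiting."""
        times = compute_times(default_solution)
        assert 16.0 < times.tau_R < 18.5
        assert times.tau_W["UGA"] < 1.0
        assert times.tau_W["UAA"] < 1.0

    def test_no_rf3_termination_time_low_single_seconds(self, no_rf3_solution):
        times = compute_times(no_rf3_solution)
        assert 1.0 < times.tau_Term["UGA"] < 5.0

    def test_rf3_removal_raises_cycle_time_modestly(self, default_solution,
                                                    no_rf3_solution):
        with_rf3 = compute_times(default_solution).tau_R
        without = compute_times(no_rf3_solution).tau_R
        assert without > with_rf3
        assert 100 * (without - with_rf3) / with_rf3 < 10.0


class TestPathways:
    def test_fractions_sum_to_one(self, default_solution):
        fr = pathway_flux_fractions(default_solution)
        assert sum(fr.overall.values()) == pytest.approx(1.0, abs=1e-9)
        for c in CODONS:
            assert sum(fr.per_codon[c].values()) == pytest.approx(1.0, abs=1e-9)

    def test_no_rf3_routes_everything_through_pathway_c(self, no_rf3_solution):
        fr = pathway_flux_fractions(no_rf3_solution)
        assert fr.overall["C"] == pytest.approx(1.0, abs=1e-12)

    def test_ribosomal_exchange_dominates_at_physiology(self, default_solution):
        fr = pathway_flux_fractions(default_solution)
        assert fr.overall["A"] / (fr.overall["A"] + fr.overall["B"]) > 0.95

    def test_solution_exchange_alone_serves_few_terminations(self):
        """With on-ribosome exchange off, solution-regenerated RF3.GTP can
        catalyse at most ~2.5% of termination events (supply-capped)."""
        p = CellParams(ribosomal_exchange=False)
        fr = pathway_flux_fractions(solve_steady_state(build_network(p)))
        assert fr.overall["A"] == pytest.approx(0.0, abs=1e-12)
        assert fr.overall["B"] <= 0.025

    def test_exchange_rate_limit_is_continuous(self):
        """Sending the on-ribosome GDP release rate to zero reproduces the
        switched-off topology without discontinuity."""
        slow = CellParams(k_exchange_rib=1e-6)
        off = CellParams(ribosomal_exchange=False)
        fr_slow = pathway_flux_fractions(solve_steady_state(build_network(slow)))
        fr_off = pathway_flux_fractions(solve_steady_state(build_network(off)))
        assert fr_slow.overall["A"] < 1e-4
        assert fr_slow.overall["B"] == pytest.approx(fr_off.overall["B"],
                                                     rel=0.01)
        assert fr_slow.overall["C"] == pytest.approx(fr_off.overall["C"],
                                                     rel=0.01)


class TestTitrate:
    def test_single_point_matches_direct_solve(self, default_solution):
        pts = titrate(CellParams(), "F_tot", [1.8])
        direct = compute_times(default_solution)
        assert pts[0].times.tau_R == pytest.approx(direct.tau_R, rel=1e-9)

    def test_no_rf3_titration_phases(self):
        """Class-I RF titration without RF3: starvation at low factor
        levels (waiting dominates, ~100 s scale), then a termination-time
        minimum, then a slow rise from factor rebinding."""
        p = CellParams(rf3_present=False)
        grid = [0.1, 0.5, 1.8, 6.0, 12.0]
        pts = titrate(p, "F_tot", grid)
        tw = [pt.times.tau_W["UGA"] for pt in pts]
        assert tw[0] > 50.0
        assert tw[-1] < 1.0
        tterm = [pt.times.tau_Term["UGA"] for pt in pts]
        imin = int(np.argmin(tterm))
        assert 0 < imin < len(tterm) - 1
        assert tterm[-1] > tterm[imin]

    def test_rf3_titration_releases_rf2_codons(self):
        pts = titrate(CellParams(), "F_tot3", [0.05, 0.4, 0.8, 2.0])
        tw = [pt.times.tau_W["UGA"] for pt in pts]
        assert all(b <= a for a, b in zip(tw, tw[1:]))
        assert tw[-1] < 1.0

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            titrate(CellParams(), "F_tot", [2.0, 1.0])
        with pytest.raises(ValueError):
            titrate(CellParams(), "GTP_mM", [1.0])


class TestSupplyDemand:
    def test_published_flux_arithmetic(self):
        demand, supply, frac = supply_demand_analysis(CellParams())
        assert demand == pytest.approx(20 * 20 / 300, rel=1e-12)   # 1.333
        assert supply == pytest.approx(0.03, rel=1e-12)
        assert frac == pytest.approx(0.0225, rel=1e-3)
        assert frac <= 0.025

    def test_zero_protein_length_rejected(self):
        with pytest.raises(ValueError):
            supply_demand_analysis(replace(CellParams(), protein_length=0.0))
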