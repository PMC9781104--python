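import numpy as np
import pytest

import clomipk as ck
from clomipk.engine import DoseEvent
from clomipk.massbalance import InsufficientEliminationError, PathwayReport
from clomipk.network import ReactionSpec, UNDEFINED_METABOLITE

from conftest import make_compound, make_physiology


def run_toy(net, phys, dose_mg=40.0, horizon=600.0, cid="drug", **kwargs):
    grid = np.linspace(0.0, horizon, 201)
    return ck.simulate(phys, net, [DoseEvent(cid, dose_mg, 0.0)], grid=grid,
                       t_end=horizon, **kwargs)


class TestPathwayFractions:
    def test_single_route_fraction_one(self, toy_physiology):
        compound = make_compound()
        net = ck.NetworkSpec(
            [compound],
            [ReactionSpec("only", "drug", UNDEFINED_METABOLITE,
                          "unspecific_hepatic", clint=5.0)],
        )
        report = ck.pathway_fractions(run_toy(net, toy_physiology))
        assert report.route_fractions["drug"]["only"] == pytest.approx(1.0)

    def test_competing_first_order_routes_split_by_rate(self, toy_physiology):
        """Two first-order routes: cumulative split equals cl1/(cl1+cl2)."""
        compound = make_compound()
        cl1, cl2 = 3.0, 3.0
        net = ck.NetworkSpec(
            [compound],
            [
                ReactionSpec("r1", "drug", UNDEFINED_METABOLITE,
                             "unspecific_hepatic", clint=cl1),
                ReactionSpec("r2", "drug", UNDEFINED_METABOLITE,
                             "unspecific_hepatic", clint=cl2),
            ],
        )
        report = ck.pathway_fractions(run_toy(net, toy_physiology))
        assert report.route_fractions["drug"]["r1"] == pytest.approx(0.5, abs=1e-9)
        assert report.route_fractions["drug"]["r2"] == pytest.approx(0.5, abs=1e-9)

    def test_unequal_competing_routes(self, toy_physiology):
        compound = make_compound()
        cl1, cl2 = 2.0, 6.0
        net = ck.NetworkSpec(
            [compound],
            [
                ReactionSpec("r1", "drug", UNDEFINED_METABOLITE,
                             "unspecific_hepatic", clint=cl1),
                ReactionSpec("r2", "drug", UNDEFINED_METABOLITE,
                             "unspecific_hepatic", clint=cl2),
            ],
        )
        report = ck.pathway_fractions(run_toy(net, toy_physiology))
        assert report.route_fractions["drug"]["r1"] == pytest.approx(
            cl1 / (cl1 + cl2), abs=1e-9
        )

    def test_route_fractions_sum_to_one(self, nm_report):
        for cid, routes in nm_report.route_fractions.items():
            if routes:
                assert sum(routes.values()) == pytest.approx(1.0, abs=1e-6)

    def test_parent_cyp2d6_fraction_86_percent(self, nm_report):
        cyp2d6 = nm_report.enzyme_fractions["e_clomiphene"]["CYP2D6"]
        assert round(cyp2d6 * 100) == 86

    def test_insufficient_elimination_raises(self, bundle):
        regimen = ck.build_regimen("control")
        grid = np.linspace(0.0, 24.0, 25)  # far too short
        res = ck.simulate(bundle.reference, bundle.network, list(regimen.doses),
                          grid=grid, activity_score=ck.ActivityScore.from_value(2.0),
                          ivsf=bundle.ivsf, t_end=24.0)
        with pytest.raises(InsufficientEliminationError):
            ck.pathway_fractions(res)

    def test_terminal_sinks_sum_to_fraction_absorbed(self, nm_extended, nm_report):
        sinks = 0.0
        for rxn in nm_extended.network.reactions:
            if rxn.product == UNDEFINED_METABOLITE:
                sinks += nm_extended.reaction_flux[rxn.id][-1]
        for cid in nm_extended.compounds:
            sinks += nm_extended.amounts[cid]["urine"][-1]
        dose = nm_extended.dosed_umol["e_clomiphene"]
        assert sinks / dose == pytest.approx(nm_report.fraction_absorbed, abs=1e-4)


class TestCumulativeYield:
    def chain_report(self):
        # hand-built: a -> b (0.5), b -> c (0.5); unreachable compound d
        return PathwayReport(
            dosed_compound="a",
            dose_umol=100.0,
            fraction_absorbed=1.0,
            route_fractions={
                "a": {"a_to_b": 0.5, "a_sink": 0.5},
                "b": {"b_to_c": 0.5, "b_sink": 0.5},
                "c": {"c_sink": 1.0},
            },
            enzyme_fractions={},
            route_topology={
                "a_to_b": ("a", "b", "CYP3A4"),
                "a_sink": ("a", UNDEFINED_METABOLITE, "CYP2D6"),
                "b_to_c": ("b", "c", "CYP2D6"),
                "b_sink": ("b", UNDEFINED_METABOLITE, "CYP3A4"),
                "c_sink": ("c", UNDEFINED_METABOLITE, "unspecific_hepatic"),
            },
        )

    def test_chain_multiplication(self):
        assert ck.cumulative_yield(self.chain_report(), "a", "c") == pytest.approx(0.25)

    def test_unreachable_target_is_zero(self):
        assert ck.cumulative_yield(self.chain_report(), "c", "a") == 0.0

    def test_fig9_yield_and_path_shares(self, nm_report):
        total = ck.cumulative_yield(nm_report, "e_clomiphene", "e_4oh_de_clomiphene")
        assert total == pytest.approx(0.41 * 0.17 + 0.17 * 0.90, abs=2e-3)
        paths = ck.yield_decomposition(nm_report, "e_clomiphene", "e_4oh_de_clomiphene")
        via_de = sum(f for p, f in paths if "e_de_clomiphene" in p)
        via_4oh = sum(f for p, f in paths if "e_4oh_clomiphene" in p)
        assert via_de / total == pytest.approx(0.687, abs=0.01)
        assert via_4oh / total == pytest.approx(0.313, abs=0.01)

    def test_yield_invariant_to_time_scale(self, bundle):
        """Scaling every rate constant by the same factor changes kinetics
        but not fraction splits, hence not the yields."""
        from dataclasses import replace

        scaled = ck.NetworkSpec(
            compounds=bundle.network.compounds,
            reactions=[
                replace(r, clint=r.clint * 3.0) for r in bundle.network.reactions
            ],
        )
        regimen = ck.build_regimen("control")
        grid = np.linspace(0.0, 1500.0, 301)
        res = ck.simulate(bundle.reference, scaled, list(regimen.doses), grid=grid,
                          activity_score=ck.ActivityScore.from_value(2.0),
                          ivsf=bundle.ivsf, t_end=1500.0)
        report = ck.pathway_fractions(res)
        y = ck.cumulative_yield(report, "e_clomiphene", "e_4oh_de_clomiphene")
        assert y == pytest.approx(0.41 * 0.17 + 0.17 * 0.90, abs=2e-3)


class TestBioavailability:
    def test_no_metabolism_full_absorption_gives_one(self, toy_physiology):
        compound = make_compound(renal=True)
        net = ck.NetworkSpec([compound], [])
        res = run_toy(net, toy_physiology, horizon=2000.0)
        assert ck.bioavailability(res, "drug") == pytest.approx(1.0, abs=1e-4)

    def test_well_stirred_closed_form(self):
        """Single first-order hepatic route: F = Q_li / (Q_li + fu·CLint)."""
        phys = make_physiology(co=300.0)
        fu, clint = 0.5, 400.0
        compound = make_compound(fu=fu)
        net = ck.NetworkSpec(
            [compound],
            [ReactionSpec("hep", "drug", UNDEFINED_METABOLITE,
                          "unspecific_hepatic", clint=clint)],
        )
        res = run_toy(net, phys, horizon=400.0)
        q_li = phys.liver_total_flow
        expected = q_li / (q_li + fu * clint)
        assert ck.bioavailability(res, "drug") == pytest.approx(expected, rel=0.01)

    def test_phenotype_ordering(self, bundle):
        regimen = ck.build_regimen("control")
        grid = np.linspace(0.0, 400.0, 101)
        f = {}
        for score in (0.0, 0.5, 2.0, 3.0):
            res = ck.simulate(bundle.reference, bundle.network, list(regimen.doses),
                              grid=grid, activity_score=ck.ActivityScore.from_value(score),
                              ivsf=bundle.ivsf, t_end=400.0)
            f[score] = ck.bioavailability(res, "e_clomiphene")
        assert f[0.0] > f[0.5] > f[2.0] > f[3.0]

    def test_nm_bioavailability_near_target(self, nm_report):
        assert nm_report.bioavailability["e_clomiphene"] == pytest.approx(0.11, abs=0.002)


class TestUrinaryFraction:
    def test_renal_disabled_gives_zero(self, toy_physiology):
        compound = make_compound(renal=False)
        net = ck.NetworkSpec(
            [compound],
            [ReactionSpec("hep", "drug", UNDEFINED_METABOLITE,
                          "unspecific_hepatic", clint=5.0)],
        )
        res = run_toy(net, toy_physiology)
        assert ck.urinary_fraction(res, "drug") == 0.0

    def test_competing_clearance_ratio(self):
        """Slow renal vs slow hepatic route: urinary share matches
        CL_renal / (CL_renal + CL_hepatic) when extraction is negligible."""
        phys = make_physiology(co=300.0, gfr=6.0)
        fu, clint, fsf = 1.0, 0.5, 0.05
        compound = make_compound(fu=fu, renal=True, fsf=fsf)
        net = ck.NetworkSpec(
            [compound],
            [ReactionSpec("hep", "drug", UNDEFINED_METABOLITE,
                          "unspecific_hepatic", clint=clint)],
        )
        res = run_toy(net, phys, horizon=3000.0)
        cl_renal = phys.gfr * fu * fsf
        cl_hep = clint * fu
        expected = cl_renal / (cl_renal + cl_hep)
        assert ck.urinary_fraction(res, "drug") / 1000.0 == pytest.approx(
            expected, rel=0.01
        )

    def test_calibrated_nm_all_below_one_permille(self, nm_report):
        for cid, permille in nm_report.urinary_permille.items():
            assert permille < 1.0

    def test_calibrated_nm_matches_targets(self, nm_report):
        targets = dict(zip(
            ("e_clomiphene", "e_4oh_clomiphene", "e_de_clomiphene",
             "e_4oh_de_clomiphene"),
            (0.01, 0.09, 0.05, 0.23),
        ))
        for cid, expected in targets.items():
            assert nm_report.urinary_permille[cid] == pytest.approx(expected, rel=0.05)
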