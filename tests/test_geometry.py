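"""Mixture-triangle coordinates, balances, projections and ellipses."""

import numpy as np
import pytest

from nutrichoice import synth
from nutrichoice.datatypes import Stimulus
from nutrichoice.geometry import (
    MixturePoint,
    ReferencePoint,
    balance_ellipse,
    choice_balance,
    deviation_from_reference,
    ellipse_contains,
    mixture_coordinates,
    project_reference,
)

from conftest import build_session


class TestMixtureCoordinates:
    def test_protein_vertex(self):
        mp = mixture_coordinates(Stimulus(id="p", protein=3.0))
        assert (mp.pct_fat, mp.pct_sugar, mp.pct_protein) == (0.0, 0.0, 100.0)

    def test_equal_energy_thirds(self):
        # equal kcal from each source: fat 4 g (36 kcal), sugar/protein 9 g (36 kcal)
        mp = mixture_coordinates(Stimulus(id="e", fat=4.0, sugar=9.0, protein=9.0))
        assert mp.pct_fat == pytest.approx(100 / 3)
        assert mp.pct_sugar == pytest.approx(100 / 3)

    def test_hand_computed_composition(self):
        # fat 3.6, sugar 5, protein 3.4 -> 32.4 / 20 / 13.6 of 66 kcal
        mp = mixture_coordinates(Stimulus(id="h", fat=3.6, sugar=5.0, protein=3.4))
        assert mp.pct_fat == pytest.approx(100 * 32.4 / 66)
        assert mp.pct_sugar == pytest.approx(100 * 20 / 66)
        assert mp.pct_protein == pytest.approx(100 * 13.6 / 66)

    def test_zero_energy_rejected(self):
        with pytest.raises(ValueError, match="zero energy"):
            mixture_coordinates(Stimulus(id="w"))

    def test_dilution_invariance(self):
        a = mixture_coordinates(Stimulus(id="a", fat=2.0, sugar=6.0, protein=3.0))
        b = mixture_coordinates(Stimulus(id="b", fat=1.0, sugar=3.0, protein=1.5))
        assert a.pct_fat == pytest.approx(b.pct_fat)
        assert a.pct_sugar == pytest.approx(b.pct_sugar)


class TestChoiceBalance:
    def test_single_stimulus_balance_is_its_composition(self, factorial_stimuli, toy_hfls_session):
        bal = choice_balance(toy_hfls_session, factorial_stimuli)
        mp = mixture_coordinates(factorial_stimuli["HFLS"])
        assert bal.pct_fat == pytest.approx(mp.pct_fat)

    def test_even_energy_split_gives_midpoint(self, factorial_stimuli):
        # HFLS and LFHS are isocaloric: equal magnitudes -> equal energy intake
        sess = build_session(
            [("HFLS", "LFHS", 1.0, 1.0, "left"), ("HFLS", "LFHS", 1.0, 1.0, "right")]
        )
        bal = choice_balance(sess, factorial_stimuli)
        a = mixture_coordinates(factorial_stimuli["HFLS"])
        b = mixture_coordinates(factorial_stimuli["LFHS"])
        assert bal.pct_fat == pytest.approx((a.pct_fat + b.pct_fat) / 2)
        assert bal.pct_sugar == pytest.approx((a.pct_sugar + b.pct_sugar) / 2)

    def test_intake_and_convex_routes_agree(self, factorial_stimuli):
        agent = synth.NutrientValueFunction("a", w_sugar=0.12, temperature=1.5)
        sess = synth.simulate_session(
            agent, (factorial_stimuli["LFLS"], factorial_stimuli["HFHS"]), 150, seed=8
        )
        b1 = choice_balance(sess, factorial_stimuli, method="intake")
        b2 = choice_balance(sess, factorial_stimuli, method="convex")
        assert b1.pct_fat == pytest.approx(b2.pct_fat, abs=1e-12)
        assert b1.pct_sugar == pytest.approx(b2.pct_sugar, abs=1e-12)

    def test_balance_lies_on_offer_segment(self, factorial_stimuli):
        agent = synth.NutrientValueFunction("a", w_fat=0.1, temperature=1.5)
        sess = synth.simulate_session(
            agent, (factorial_stimuli["LFLS"], factorial_stimuli["HFLS"]), 200, seed=9
        )
        bal = choice_balance(sess, factorial_stimuli)
        res = project_reference(bal, factorial_stimuli["LFLS"], factorial_stimuli["HFLS"])
        assert res["distance"] < 1e-9


class TestProjectReference:
    def test_point_on_segment_projects_to_itself(self, factorial_stimuli):
        a = mixture_coordinates(factorial_stimuli["LFLS"])
        b = mixture_coordinates(factorial_stimuli["HFLS"])
        mid_xy = (a.xy + b.xy) / 2
        mid = MixturePoint(mid_xy[0], mid_xy[1], 100 - mid_xy.sum())
        res = project_reference(mid, factorial_stimuli["LFLS"], factorial_stimuli["HFLS"])
        assert res["distance"] == pytest.approx(0.0, abs=1e-12)
        assert res["t"] == pytest.approx(0.5)

    def test_point_beyond_endpoint_is_clamped(self, factorial_stimuli):
        a, b = factorial_stimuli["LFLS"], factorial_stimuli["HFHS"]
        pa, pb = mixture_coordinates(a).xy, mixture_coordinates(b).xy
        for frac, expected_t in ((-0.5, 0.0), (1.5, 1.0)):
            xy = pa + frac * (pb - pa)
            ref = MixturePoint(xy[0], xy[1], 100 - xy.sum())
            res = project_reference(ref, a, b)
            assert res["t"] == expected_t
            assert res["distance"] > 0

    def test_matches_brute_force_grid_search(self, factorial_stimuli):
        rng = np.random.default_rng(12)
        a, b = factorial_stimuli["LFLS"], factorial_stimuli["HFHS"]
        pa = mixture_coordinates(a).xy
        pb = mixture_coordinates(b).xy
        ts = np.linspace(0, 1, 10_001)
        grid = pa[None, :] + ts[:, None] * (pb - pa)[None, :]
        for _ in range(25):
            xy = rng.uniform(0, 50, size=2)
            ref = MixturePoint(xy[0], xy[1], 100 - xy.sum())
            res = project_reference(ref, a, b)
            dists = np.linalg.norm(grid - ref.xy, axis=1)
            assert res["t"] == pytest.approx(ts[np.argmin(dists)], abs=1e-4)
            assert res["distance"] == pytest.approx(dists.min(), abs=1e-4)

    def test_identical_endpoints_rejected(self, factorial_stimuli):
        ref = MixturePoint(30.0, 30.0, 40.0)
        with pytest.raises(ValueError, match="identical"):
            project_reference(ref, factorial_stimuli["LFLS"], factorial_stimuli["LFLS"])


class TestBalanceEllipse:
    def test_isotropic_scatter_yields_near_circle(self):
        rng = np.random.default_rng(3)
        pts = rng.normal([30, 45], 2.0, size=(200, 2))
        balances = [MixturePoint(x, y, 100 - x - y) for x, y in pts]
        e = balance_ellipse(balances)
        ratio = e["semi_axes"][1] / e["semi_axes"][0]
        assert 0.8 <= ratio <= 1.25
        assert not e["degenerate"]

    def test_identical_balances_are_degenerate(self):
        balances = [MixturePoint(30.0, 45.0, 25.0)] * 5
        e = balance_ellipse(balances)
        assert e["degenerate"]
        assert e["semi_axes"][0] == pytest.approx(0.0, abs=1e-9)

    def test_coverage_near_nominal(self):
        rng = np.random.default_rng(4)
        mean = np.array([30.0, 45.0])
        hits = 0
        n_sets = 400
        for _ in range(n_sets):
            pts = rng.normal(mean, 3.0, size=(80, 2))
            balances = [MixturePoint(x, y, 100 - x - y) for x, y in pts]
            hits += ellipse_contains(balance_ellipse(balances), mean)
        assert 0.90 <= hits / n_sets <= 0.985

    def test_too_few_balances_rejected(self):
        with pytest.raises(ValueError, match="3"):
            balance_ellipse([MixturePoint(30, 45, 25)] * 2)


class TestDeviationFromReference:
    def test_balance_at_projected_reference_deviates_zero(self, factorial_stimuli):
        a, b = factorial_stimuli["LFLS"], factorial_stimuli["HFLS"]
        ref = ReferencePoint("optimal", MixturePoint(15.0, 60.0, 25.0))
        proj = project_reference(ref, a, b)["projected"]
        res = deviation_from_reference(proj, ref, a, b)
        assert res["mean_deviation"] == pytest.approx(0.0, abs=1e-9)

    def test_high_nutrient_loyalist_deviates_positively(self, factorial_stimuli):
        sess = build_session([("HFHS", "LFLS", 1.0, 1.0, "left")] * 20)
        bal = choice_balance(sess, factorial_stimuli)
        ref = ReferencePoint("optimal", MixturePoint(15.0, 60.0, 25.0))
        res = deviation_from_reference(
            bal, ref, factorial_stimuli["LFLS"], factorial_stimuli["HFHS"]
        )
        assert res["mean_deviation"] > 0

    def test_toy_geometry_hand_computed(self):
        # segment from (10, 20) to (50, 20): composition varies along the fat axis only
        ref = MixturePoint(30.0, 20.0, 50.0)
        lo = Stimulus(id="l", fat=10.0 / 9.0, sugar=5.0, protein=17.5)  # -> (10, 20, 70)
        hi = Stimulus(id="h", fat=50.0 / 9.0, sugar=5.0, protein=7.5)  # -> (50, 20, 30)
        mp_lo = mixture_coordinates(lo)
        assert mp_lo.pct_fat == pytest.approx(10.0)
        assert mp_lo.pct_sugar == pytest.approx(20.0)
        mp_hi = mixture_coordinates(hi)
        assert mp_hi.pct_fat == pytest.approx(50.0)
        assert mp_hi.pct_sugar == pytest.approx(20.0)
        # balance at pct_fat = 40 -> t = 0.75; reference projects to t = 0.5
        bal = MixturePoint(40.0, 20.0, 40.0)
        res = deviation_from_reference(bal, ref, lo, hi)
        assert res["nutrient_axis"] == "fat"
        assert res["mean_deviation"] == pytest.approx((0.75 - 0.5) * 40.0)
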