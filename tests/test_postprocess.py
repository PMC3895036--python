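"""Level diagrams, restriction scenarios, densities, PCoA, re-simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fuelscape as fs
from fuelscape.objectives import OBJECTIVE_NAMES, ObjectiveVector
from fuelscape.postprocess import (
    Constraint,
    ParetoFrontier,
    PcoaResult,
    scenario_mask,
)


def frontier_from_display(rows):
    objs = [ObjectiveVector(*row) for row in rows]
    regime = fs.ManagementRegime((10.0,), (1.0,))
    return ParetoFrontier(regimes=[regime] * len(objs), objectives=objs)


BEST = (0.0, 100.0, 10.0, 2.0, 30.0, 30.0)  # best display value in each objective
WORST = (20.0, 900.0, 1.0, 0.1, 5.0, 5.0)  # worst display value in each objective


class TestStandardizeAndScore:
    def test_best_solution_distance_zero(self):
        score = fs.standardize_and_score(frontier_from_display([BEST, WORST]))
        assert score.distance[0] == pytest.approx(0.0)

    def test_worst_solution_distance_sqrt_66(self):
        # weights: 6 (cost), 2+2+2 (fire), 3+3 (biodiversity) -> sqrt(66)
        score = fs.standardize_and_score(frontier_from_display([BEST, WORST]))
        assert score.distance[1] == pytest.approx(np.sqrt(66.0))

    def test_worst_only_in_cost_distance_six(self):
        rows = [BEST, (20.0, *BEST[1:])]
        score = fs.standardize_and_score(frontier_from_display(rows))
        assert score.distance[1] == pytest.approx(6.0)

    def test_single_solution_degenerate(self):
        score = fs.standardize_and_score(frontier_from_display([BEST]))
        assert score.distance[0] == 0.0

    @given(scale=st.floats(0.5, 50), shift=st.floats(-10, 10))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_affine_rescaling_of_an_objective(self, scale, shift):
        rng = np.random.default_rng(0)
        raw = rng.random((6, 6)) * 10
        rows = [tuple(r) for r in raw]
        base = fs.standardize_and_score(frontier_from_display(rows)).distance
        scaled = raw.copy()
        scaled[:, 1] = scale * scaled[:, 1] + shift  # rescale fuel load
        out = fs.standardize_and_score(frontier_from_display([tuple(r) for r in scaled]))
        assert out.distance == pytest.approx(base, abs=1e-9)


class TestScenarios:
    def test_cost_band_keeps_and_drops(self):
        rows = [
            (5.375, *BEST[1:]),
            (5.5, *BEST[1:]),
        ]
        frontier = frontier_from_display(rows)
        sub = fs.apply_scenario(frontier, fs.standard_scenarios()["cost5"])
        assert len(sub) == 1
        assert sub.objectives[0].cost == 5.375

    def test_biodiversity_floor(self):
        rows = [
            (1.0, 100.0, 5.0, 1.0, 9.9, 9.9),
            (1.0, 100.0, 5.0, 1.0, 9.8, 20.0),
        ]
        frontier = frontier_from_display(rows)
        sub = fs.apply_scenario(frontier, fs.standard_scenarios()["biodiversity"])
        assert len(sub) == 1
        assert sub.objectives[0].mid_area == 9.9

    def test_empty_frontier_allowed(self):
        empty = frontier_from_display([])
        sub = fs.apply_scenario(empty, fs.standard_scenarios()["cost5"])
        assert len(sub) == 0

    def test_quantile_constraints_respect_direction(self, rng):
        rows = [tuple(r) for r in rng.random((40, 6)) * 100]
        frontier = frontier_from_display(rows)
        sub = fs.apply_scenario(frontier, fs.standard_scenarios()["fire"])
        D = frontier.display_matrix()
        fuel = D[:, OBJECTIVE_NAMES.index("fuel_load")]
        edge = D[:, OBJECTIVE_NAMES.index("edge_contrast")]
        for o in sub.objectives:
            assert o.fuel_load <= np.quantile(fuel, 0.25) + 1e-9
            assert o.edge_contrast >= np.quantile(edge, 0.75) - 1e-9

    def test_adding_constraints_never_enlarges(self, rng):
        rows = [tuple(r) for r in rng.random((30, 6)) * 100]
        frontier = frontier_from_display(rows)
        base = fs.Scenario("a", (Constraint("cost", "threshold", op="le", value=50.0),))
        tighter = fs.Scenario(
            "b",
            base.constraints
            + (Constraint("mid_area", "threshold", op="ge", value=50.0),),
        )
        m1 = scenario_mask(frontier, base)
        m2 = scenario_mask(frontier, tighter)
        assert np.all(m2 <= m1)

    def test_unknown_objective_rejected(self):
        with pytest.raises(ValueError):
            Constraint("not_an_objective", "threshold")


class TestSolutionDensity:
    def test_density_integrates_to_one(self):
        reg = fs.ManagementRegime((5.0, 75.0, 100.0), (0.55, 0.35, 0.10))
        d = fs.solution_density(reg)
        assert np.trapezoid(d.values, d.grid) == pytest.approx(1.0, abs=1e-3)

    def test_single_group_unimodal_peak_at_interval(self):
        d = fs.solution_density(fs.ManagementRegime((40.0,), (1.0,)))
        assert d.grid[np.argmax(d.values)] == pytest.approx(40.0, abs=0.1)
        peaks = np.flatnonzero(
            (np.diff(np.sign(np.diff(d.values))) < 0)
        )
        assert len(peaks) == 1

    def test_mirrored_regimes_give_mirrored_densities(self):
        # intervals reflected about the midpoint of [3, 100]
        a = fs.solution_density(fs.ManagementRegime((23.0,), (1.0,)))
        b = fs.solution_density(fs.ManagementRegime((80.0,), (1.0,)))
        assert a.values == pytest.approx(b.values[::-1], abs=1e-12)

    def test_identical_regimes_distance_near_zero(self):
        # kernels are not renormalized at the grid bounds, so a sliver of
        # tail mass (< 2e-3 even for intervals at the bounds) escapes the
        # grid and the self-distance is tiny but not exactly zero
        for intervals in [(30.0, 90.0), (3.0, 100.0)]:
            reg = fs.ManagementRegime(intervals, (0.5, 0.5))
            assert fs.density_distance(
                fs.solution_density(reg), fs.solution_density(reg)
            ) == pytest.approx(0.0, abs=2e-3)

    def test_distant_groups_nearly_disjoint(self):
        a = fs.solution_density(fs.ManagementRegime((3.0,), (1.0,)))
        b = fs.solution_density(fs.ManagementRegime((100.0,), (1.0,)))
        assert fs.density_distance(a, b) >= 0.99

    def test_symmetric_and_bounded(self, rng):
        regs = [
            fs.ManagementRegime((float(rng.uniform(3, 100)),), (1.0,)) for _ in range(4)
        ]
        ds = [fs.solution_density(r) for r in regs]
        for i in range(4):
            for j in range(4):
                dij = fs.density_distance(ds[i], ds[j])
                assert 0.0 <= dij <= 1.0
                assert dij == pytest.approx(fs.density_distance(ds[j], ds[i]))

    def test_mismatched_grids_rejected(self):
        a = fs.solution_density(fs.ManagementRegime((10.0,), (1.0,)))
        b = fs.solution_density(
            fs.ManagementRegime((10.0,), (1.0,)), grid=np.linspace(0, 100, 50)
        )
        with pytest.raises(ValueError):
            fs.density_distance(a, b)


class TestPcoa:
    def test_recovers_planar_configuration(self, rng):
        points = rng.random((5, 2)) * 10
        D = np.linalg.norm(points[:, None] - points[None, :], axis=2)
        result = fs.pcoa(D)
        rec = result.coordinates
        D2 = np.linalg.norm(rec[:, None] - rec[None, :], axis=2)
        assert D2 == pytest.approx(D, abs=1e-8)
        assert rec.shape[1] == 2  # planar input: exactly two positive axes

    def test_matches_hand_double_centering(self):
        D = np.array(
            [
                [0.0, 1.0, 2.0, 1.0],
                [1.0, 0.0, 1.0, 2.0],
                [2.0, 1.0, 0.0, 1.0],
                [1.0, 2.0, 1.0, 0.0],
            ]
        )
        n = 4
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D**2) @ J
        eigval = np.sort(np.linalg.eigvalsh(B))[::-1]
        result = fs.pcoa(D)
        assert result.eigenvalues == pytest.approx(eigval, abs=1e-10)
        # embedded coordinates reproduce B's positive part
        rec = result.coordinates @ result.coordinates.T
        eigval_pos = np.clip(eigval, 0, None)
        w, v = np.linalg.eigh(B)
        B_pos = (v * np.clip(w, 0, None)) @ v.T
        assert rec == pytest.approx(B_pos, abs=1e-8)

    def test_matches_scikit_bio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as skbio_pcoa

        points = rng.random((6, 3))
        D = np.linalg.norm(points[:, None] - points[None, :], axis=2)
        ours = fs.pcoa(D)
        theirs = skbio_pcoa(skbio.DistanceMatrix(D), number_of_dimensions=3)
        assert np.sort(ours.eigenvalues)[::-1][:3] == pytest.approx(
            theirs.eigvals.to_numpy()[:3], abs=1e-8
        )
        assert ours.proportion_explained[:2] == pytest.approx(
            theirs.proportion_explained.to_numpy()[:2], abs=1e-8
        )

    def test_negative_eigenvalues_dropped(self):
        # a non-Euclidean (but metric) distance matrix
        D = np.array(
            [
                [0.0, 1.0, 1.0, 1.0],
                [1.0, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 1.9],
                [1.0, 1.0, 1.9, 0.0],
            ]
        )
        result = fs.pcoa(D)
        assert np.any(result.eigenvalues < 0)
        assert result.proportion_explained.sum() == pytest.approx(1.0)
        assert result.coordinates.shape[1] == np.count_nonzero(
            result.eigenvalues > 1e-9
        )

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            fs.pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestCompromiseRescan:
    def test_single_simulation_has_zero_sd(self):
        reg = fs.ManagementRegime((10.0,), (1.0,))
        df = fs.compromise_rescan([reg], n_rows=8, n_cols=8, n_sims=1, seed=1)
        assert np.all(df["sd"] == 0.0)

    def test_no_management_regime_never_manages(self):
        reg = fs.ManagementRegime((100.0,), (1.0,))
        df = fs.compromise_rescan([reg], n_rows=8, n_cols=8, n_sims=2, seed=1)
        managed = df[df["variable"] == "pct_managed"]
        assert np.all(managed["mean"] == 0.0)

    def test_long_run_age_mix_matches_renewal_theory(self):
        """Mixed steady-state age composition: sum_g p_g min(a/m_g, 1)."""
        reg = fs.ManagementRegime((10.0, 50.0), (0.5, 0.5))
        cfg = fs.SimConfig(horizon=400, burn_in=20)
        df = fs.compromise_rescan(
            [reg], n_rows=20, n_cols=20, n_sims=8, sim_config=cfg, seed=4
        )
        young = df[(df["variable"] == "pct_young") & (df["year"] >= 200)]["mean"]
        # fraction with age < 10: group 1 always (<10 = full cycle), group 2 10/50
        expected = 100.0 * (0.5 * 1.0 + 0.5 * 10.0 / 50.0)
        assert young.mean() == pytest.approx(expected, abs=6.0)
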