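"""EPDFs, the Jeffreys divergence, and simplex-constrained weight estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glycopore as gp
from glycopore.mixture import _objective_and_grad, project_to_simplex, simplex_lattice


def two_bin_epdf(p0, eps=1e-12):
    """EPDF with two ratio bins and one dwell bin carrying masses (p0, 1-p0)."""
    grid = gp.GridSpec(ratio_edges=(0.0, 0.5, 1.0), logdwell_edges=(-1.0, 1.0), smoothing_eps=eps)
    mass = np.array([[p0], [1.0 - p0]])
    return gp.EPDF(grid=grid, mass=mass / mass.sum())


def table_from_arrays(ratios, dwells, label="t"):
    return gp.EventTable(label, pd.DataFrame({"ratio": ratios, "dwell_ms": dwells}))


class TestGridSpec:
    def test_default_grid_covers_data(self, table_6sl):
        grid = gp.GridSpec.from_tables([table_6sl])
        assert grid.shape == (50, 50)
        assert grid.ratio_edges[0] == 0.0 and grid.ratio_edges[-1] == 1.0
        logd = np.log10(table_6sl.dwell_ms)
        assert grid.logdwell_edges[0] < logd.min() and grid.logdwell_edges[-1] > logd.max()

    def test_invalid_edges_rejected(self):
        with pytest.raises(ValueError):
            gp.GridSpec(ratio_edges=(0.0, 0.5, 0.5), logdwell_edges=(-1.0, 1.0))
        with pytest.raises(ValueError):
            gp.GridSpec(ratio_edges=(0.0, 1.0), logdwell_edges=(-1.0, 1.0), smoothing_eps=0.0)


class TestBuildEpdf:
    def test_total_mass_one(self, table_6sl):
        grid = gp.GridSpec.from_tables([table_6sl])
        e = gp.build_epdf(table_6sl, grid)
        assert float(e.mass.sum()) == pytest.approx(1.0, abs=1e-12)
        assert (e.mass > 0).all()

    def test_single_bin_concentration_in_eps_limit(self):
        t = table_from_arrays([0.25] * 100, [1.0] * 100)
        grid = gp.GridSpec(
            ratio_edges=(0.0, 0.5, 1.0), logdwell_edges=(-1.0, 1.0), smoothing_eps=1e-15
        )
        e = gp.build_epdf(t, grid)
        assert e.mass[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_uniform_events_spread_evenly(self):
        rng = np.random.default_rng(3)
        n = 40_000
        t = table_from_arrays(rng.uniform(0, 1, n), 10.0 ** rng.uniform(-1, 1, n))
        grid = gp.GridSpec(
            ratio_edges=tuple(np.linspace(0, 1, 5)),
            logdwell_edges=tuple(np.linspace(-1, 1, 5)),
        )
        e = gp.build_epdf(t, grid)
        p = 1.0 / 16
        sd = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(e.mass - p) < 3 * sd + 1e-6)

    def test_empty_table_and_out_of_grid_rejected(self, table_6sl):
        grid = gp.GridSpec.from_tables([table_6sl])
        with pytest.raises(ValueError, match="empty"):
            gp.build_epdf(table_from_arrays([], []), grid)
        bad = table_from_arrays([0.5], [1e9])
        with pytest.raises(ValueError, match="outside"):
            gp.build_epdf(bad, grid)


class TestMixtureEpdf:
    def test_degenerate_weight_equals_component(self):
        f, g = two_bin_epdf(0.8), two_bin_epdf(0.2)
        out = gp.mixture_epdf([f, g], [1.0, 0.0])
        np.testing.assert_allclose(out.mass, f.mass)

    def test_equal_components_any_weights(self):
        f = two_bin_epdf(0.3)
        out = gp.mixture_epdf([f, two_bin_epdf(0.3)], [0.4, 0.6])
        np.testing.assert_allclose(out.mass, f.mass)

    def test_hand_arithmetic(self):
        # 0.25*(0.8, 0.2) + 0.75*(0.2, 0.8) = (0.35, 0.65)
        out = gp.mixture_epdf([two_bin_epdf(0.8), two_bin_epdf(0.2)], [0.25, 0.75])
        np.testing.assert_allclose(out.mass.ravel(), [0.35, 0.65], atol=1e-9)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            gp.mixture_epdf([two_bin_epdf(0.8), two_bin_epdf(0.2)], [0.5, 0.6])


class TestSymmetrizedDivergence:
    def test_identical_distributions_zero(self, table_6sl):
        grid = gp.GridSpec.from_tables([table_6sl])
        e = gp.build_epdf(table_6sl, grid)
        assert gp.symmetrized_divergence(e, e) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_bin_value(self):
        # (0.8-0.2)*ln(0.8/0.2) * 2 halves = 1.2 * ln 4
        f, g = two_bin_epdf(0.8), two_bin_epdf(0.2)
        assert gp.symmetrized_divergence(f, g) == pytest.approx(1.2 * np.log(4.0), rel=1e-9)

    @given(st.floats(0.05, 0.95), st.floats(0.05, 0.95))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_and_nonnegativity(self, a, b):
        f, g = two_bin_epdf(a), two_bin_epdf(b)
        d_fg, d_gf = gp.symmetrized_divergence(f, g), gp.symmetrized_divergence(g, f)
        assert d_fg == pytest.approx(d_gf, rel=1e-9, abs=1e-12)
        assert d_fg >= 0
        if abs(a - b) > 1e-6:
            assert d_fg > 0

    def test_grid_mismatch_rejected(self, table_6sl, table_3sl):
        g1 = gp.GridSpec.from_tables([table_6sl])
        g2 = gp.GridSpec.from_tables([table_3sl])
        with pytest.raises(ValueError, match="GridSpec"):
            gp.symmetrized_divergence(gp.build_epdf(table_6sl, g1), gp.build_epdf(table_3sl, g2))


class TestSimplexMachinery:
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_projection_lands_on_simplex(self, v):
        w = project_to_simplex(np.array(v))
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert (w >= 0).all()

    def test_lattice_count_two_components(self):
        pts = list(simplex_lattice(2, 0.01))
        assert len(pts) == 101

    def test_lattice_points_on_simplex(self):
        for w in simplex_lattice(3, 0.2):
            assert w.sum() == pytest.approx(1.0) and (w >= 0).all()


@pytest.fixture(scope="module")
def refs(table_3sl, table_6sl):
    grid = gp.GridSpec.from_tables([table_3sl, table_6sl])
    return grid, gp.build_epdf(table_3sl, grid), gp.build_epdf(table_6sl, grid)


class TestEstimateWeights:

    def test_pure_component_recovered(self, library, table_3sl, table_6sl):
        pure = gp.sample_events(library["3SL-MPB"], 10_000, seed=55, with_times=False)
        est = gp.estimate_weights(pure, [table_3sl, table_6sl])
        assert est.weights[0] > 0.95
        assert est.converged

    def test_titration_fraction_recovered(self, library, table_3sl, table_6sl):
        models = [library["3SL-MPB"], library["6SL-MPB"]]
        mix = gp.sample_mixture(models, [0.2, 0.8], 10_000, seed=56)
        est = gp.estimate_weights(mix, [table_3sl, table_6sl])
        assert abs(est.weights[0] - 0.2) < 0.03

    def test_simplex_constraints_hold(self, library, table_3sl, table_6sl):
        mix = gp.sample_mixture(
            [library["3SL-MPB"], library["6SL-MPB"]], [0.4, 0.6], 5_000, seed=57
        )
        est = gp.estimate_weights(mix, [table_3sl, table_6sl])
        assert float(est.weights.sum()) == pytest.approx(1.0, abs=1e-9)
        assert (est.weights >= 0).all()
        assert est.objective >= 0

    def test_matches_oracle_two_components(self, library, table_3sl, table_6sl, refs):
        grid, f3, f6 = refs
        mix = gp.sample_mixture(
            [library["3SL-MPB"], library["6SL-MPB"]], [0.35, 0.65], 10_000, seed=58
        )
        fmix = gp.build_epdf(mix, grid)
        pgd = gp.estimate_weights(fmix, [f3, f6])
        oracle = gp.grid_search_weights(fmix, [f3, f6], resolution=0.01)
        np.testing.assert_allclose(pgd.weights, oracle.weights, atol=0.01)

    def test_matches_oracle_three_components(self, library):
        names = ["3SL-MPB", "6SL-MPB", "6S2FL-MPB"]
        refs = [
            gp.sample_events(library[n], 20_000, seed=60 + i, with_times=False)
            for i, n in enumerate(names)
        ]
        mix = gp.sample_mixture([library[n] for n in names], [0.2, 0.5, 0.3], 10_000, seed=66)
        grid = gp.GridSpec.from_tables([mix, *refs])
        fmix = gp.build_epdf(mix, grid)
        fs = [gp.build_epdf(r, grid) for r in refs]
        pgd = gp.estimate_weights(fmix, fs)
        oracle = gp.grid_search_weights(fmix, fs, resolution=0.02)
        np.testing.assert_allclose(pgd.weights, oracle.weights, atol=0.02)

    def test_oracle_is_exhaustive_minimum(self, refs):
        grid, f3, f6 = refs
        mix = gp.mixture_epdf([f3, f6], [0.3, 0.7])
        oracle = gp.grid_search_weights(mix, [f3, f6], resolution=0.05)
        F = np.stack([f3.flat, f6.flat], axis=1)
        objs = [
            _objective_and_grad(w, mix.flat, F)[0] for w in simplex_lattice(2, 0.05)
        ]
        assert oracle.objective == pytest.approx(min(objs), rel=1e-12)

    def test_oracle_identifies_pure_second_component(self, refs):
        grid, f3, f6 = refs
        oracle = gp.grid_search_weights(f6, [f3, f6], resolution=0.05)
        np.testing.assert_allclose(oracle.weights, [0.0, 1.0])

    def test_objective_convex_along_simplex_segments(self, refs):
        grid, f3, f6 = refs
        rng = np.random.default_rng(1234)
        mix = gp.mixture_epdf([f3, f6], [0.4, 0.6])
        F = np.stack([f3.flat, f6.flat], axis=1)
        j = lambda w: _objective_and_grad(w, mix.flat, F)[0]
        for _ in range(50):
            w1 = rng.dirichlet([1.0, 1.0])
            w2 = rng.dirichlet([1.0, 1.0])
            mid = 0.5 * (w1 + w2)
            assert j(mid) <= 0.5 * (j(w1) + j(w2)) + 1e-12

    def test_fewer_than_two_components_rejected(self, table_3sl, table_6sl):
        with pytest.raises(ValueError):
            gp.estimate_weights(table_6sl, [table_3sl])

    def test_titration_linearity(self, library, table_3sl, table_6sl, refs):
        # estimated vs true 3SL fractions regress with slope ~1 (y = x)
        grid, f3, f6 = refs
        fractions = [0.2, 0.4, 0.5, 0.6, 0.8]
        estimates = []
        for i, frac in enumerate(fractions):
            mix = gp.sample_mixture(
                [library["3SL-MPB"], library["6SL-MPB"]], [frac, 1 - frac], 10_000, seed=70 + i
            )
            est = gp.estimate_weights(gp.build_epdf(mix, grid), [f3, f6])
            estimates.append(est.weights[0])
        slope = np.polyfit(fractions, estimates, 1)[0]
        assert abs(slope - 1.0) < 0.05
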