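"""Prediction surfaces, uncertainty and change maps, footprint summaries."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from wfdisp import displacement as disp
from wfdisp import inference, smooths
from wfdisp.displacement import (
    PredictionGrid,
    change_map,
    footprint_summary,
    make_grid,
    predict_surface,
    uncertainty_map,
)

X0, Y0 = 430_000.0, 6_050_000.0


def _zero_post(family="NB", n_draws=50, coords=None):
    """PosteriorSamples with every coefficient zero (link identity)."""
    rng = np.random.default_rng(0)
    if coords is None:
        coords = rng.uniform(0, 5000, size=(60, 2)) + [X0, Y0]
    basis = smooths.build_basis(coords, smooths.place_knots(coords, 8, seed=0))
    whitener = smooths.penalized_subspace(basis)
    q = whitener.shape[1]
    levels = ("preconstruction", "construction", "operation")
    c, d = 2, n_draws
    zeros = np.zeros((c, d))
    scalars = {
        "beta0": zeros.copy(),
        "phase_construction": zeros.copy(),
        "phase_operation": zeros.copy(),
        "gamma0": zeros.copy(),
        "gamma_cond": zeros.copy(),
    }
    return inference.PosteriorSamples(
        family=family,
        levels=levels,
        scalars=scalars,
        linear=np.zeros((c, d, 3, 2)),
        smooth_u=np.zeros((c, d, 3, q)),
        tau=np.full((c, d, 3), 1e-8),
        basis=basis,
        whitener=whitener,
        nominal_length=600.0,
        species="guillemot",
    )


def _grid_from_draws(draws, xy=None):
    """Summarise a (cells, draws) matrix into a PredictionGrid."""
    n = len(draws)
    if xy is None:
        xy = np.column_stack([np.arange(n) * 600.0 + X0, np.full(n, Y0)])
    lo, hi = np.quantile(draws, [0.025, 0.975], axis=1)
    cells = pd.DataFrame(
        {
            "x": xy[:, 0],
            "y": xy[:, 1],
            "mean": draws.mean(axis=1),
            "sd": draws.std(axis=1, ddof=1),
            "lo": lo,
            "hi": hi,
        }
    )
    return PredictionGrid("guillemot", "preconstruction", 600.0, cells, draws)


class TestPredictSurface:
    def test_zero_coefficients_give_unit_mean(self):
        post = _zero_post()
        grid = pd.DataFrame({"x": post.basis.knots[:, 0], "y": post.basis.knots[:, 1]})
        g = predict_surface(post, grid, "construction")
        np.testing.assert_allclose(g.cells["mean"], 1.0, atol=1e-9)
        np.testing.assert_allclose(g.cells["sd"], 0.0, atol=1e-9)

    def test_shifting_phase_effect_scales_means_exactly(self):
        post = _zero_post()
        grid = pd.DataFrame({"x": post.basis.knots[:, 0], "y": post.basis.knots[:, 1]})
        base = predict_surface(post, grid, "construction").cells["mean"].to_numpy()
        post.scalars["phase_construction"] += np.log(2.0)
        doubled = predict_surface(post, grid, "construction").cells["mean"].to_numpy()
        np.testing.assert_allclose(doubled, 2.0 * base, rtol=1e-12)

    def test_zip_expected_count_decreasing_in_zero_probability(self):
        post = _zero_post(family="ZIP")
        grid = pd.DataFrame({"x": post.basis.knots[:2, 0], "y": post.basis.knots[:2, 1]})
        at_half = predict_surface(post, grid, "construction").cells["mean"].to_numpy()
        post.scalars["gamma0"] += 2.0  # higher pi0
        at_high = predict_surface(post, grid, "construction").cells["mean"].to_numpy()
        assert (at_high < at_half).all()

    def test_unknown_phase_rejected(self):
        post = _zero_post()
        grid = pd.DataFrame({"x": [X0], "y": [Y0]})
        with pytest.raises(ValueError, match="phase"):
            predict_surface(post, grid, "decommissioning")

    def test_surface_shape_recovered_from_fit(self, tiny_fit, tiny_files):
        from scipy.stats import spearmanr

        post, _ = tiny_fit
        _, _, truth = tiny_files
        kn = post.basis.knots
        grid = pd.DataFrame({"x": kn[:, 0], "y": kn[:, 1]})
        g = predict_surface(post, grid, "preconstruction")
        true = np.exp(truth.log_intensity("guillemot", "preconstruction", kn))
        rho = spearmanr(g.cells["mean"], true).statistic
        assert rho > 0.3  # small fixture; the full-size bound is tested below

    def test_surface_shape_recovery_at_full_scenario(self, tmp_path):
        """A pronounced latent intensity field (log-SD 1) over 900 segments is
        recovered with rank correlation >= 0.9 between true and posterior-mean
        surfaces."""
        import dataclasses

        from scipy.stats import spearmanr

        from wfdisp import synthetic
        from wfdisp.cli import RunConfig, build_segments

        cfg = synthetic.recovery_scenario("guillemot", seed=1000)
        cfg = dataclasses.replace(
            cfg, guillemot=dataclasses.replace(cfg.guillemot, surface_sd=1.0)
        )
        truth = synthetic.simulate(cfg, tmp_path)
        rc = RunConfig(
            track=str(tmp_path / "track.csv"),
            sightings=str(tmp_path / "sightings.csv"),
            seastate=str(tmp_path / "seastate.csv"),
            phases=str(tmp_path / "phases.csv"),
            footprint=None,
            species="guillemot",
        )
        table = build_segments(rc)
        spec = inference.ModelSpec(
            family="NB", knots=15, chains=2, warmup=300, draws=300, seed=1000
        )
        post, _ = inference.fit(table, spec)
        coords = table.rows[["x", "y"]].drop_duplicates().reset_index(drop=True)
        g = predict_surface(post, coords, "preconstruction")
        true = np.exp(
            truth.log_intensity("guillemot", "preconstruction", coords.to_numpy())
        )
        assert spearmanr(g.cells["mean"], true).statistic >= 0.9


class TestUncertaintyMap:
    def test_ratio_arithmetic_and_degenerate_cases(self):
        draws = np.vstack(
            [
                np.full(200, 3.0),  # sd 0 -> ratio 0
                np.concatenate([np.full(100, 1.0), np.full(100, 3.0)]),  # mean 2
            ]
        )
        g = _grid_from_draws(draws)
        out = uncertainty_map(g)
        assert out["cv"].iloc[0] == 0.0
        assert out["cv"].iloc[1] == pytest.approx(
            draws[1].std(ddof=1) / 2.0
        )

    def test_zero_mean_flagged_undefined(self):
        g = _grid_from_draws(np.zeros((1, 100)))
        out = uncertainty_map(g)
        assert bool(out["undefined"].iloc[0])


class TestChangeMap:
    def test_self_comparison_is_null(self):
        g = _grid_from_draws(np.random.default_rng(0).gamma(2, 1, (5, 300)))
        cm = change_map(g, g)
        assert (cm.cells["diff"] == 0).all()
        assert not cm.cells["significant"].any()

    def test_disjoint_interval_rule(self):
        a = _grid_from_draws(np.random.default_rng(1).uniform(1, 2, (1, 1000)))
        b = _grid_from_draws(np.random.default_rng(2).uniform(3, 4, (1, 1000)))
        c = _grid_from_draws(np.random.default_rng(3).uniform(1.5, 2.5, (1, 1000)))
        assert change_map(a, b).cells["significant"].iloc[0]
        assert not change_map(a, c).cells["significant"].iloc[0]

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        a = _grid_from_draws(rng.gamma(2, 1, (8, 400)))
        b = _grid_from_draws(rng.gamma(3, 1, (8, 400)))
        ab, ba = change_map(a, b), change_map(b, a)
        np.testing.assert_allclose(ab.cells["diff"], -ba.cells["diff"])
        np.testing.assert_array_equal(ab.cells["significant"], ba.cells["significant"])

    def test_flags_invariant_under_monotone_rescaling(self):
        rng = np.random.default_rng(5)
        da = rng.gamma(2, 1, (6, 500))
        db = rng.gamma(4, 1, (6, 500))
        before = change_map(_grid_from_draws(da), _grid_from_draws(db)).cells[
            "significant"
        ]
        f = lambda x: np.log1p(x) ** 2  # strictly monotone on positives
        after = change_map(_grid_from_draws(f(da)), _grid_from_draws(f(db))).cells[
            "significant"
        ]
        np.testing.assert_array_equal(before, after)

    def test_geometry_mismatch_rejected(self):
        a = _grid_from_draws(np.ones((3, 100)))
        b = _grid_from_draws(np.ones((4, 100)))
        with pytest.raises(ValueError, match="geometry"):
            change_map(a, b)

    def test_difference_rule_available(self):
        rng = np.random.default_rng(6)
        a = _grid_from_draws(rng.normal(2, 0.1, (2, 800)) ** 2)
        b = _grid_from_draws(rng.normal(3, 0.1, (2, 800)) ** 2)
        cm = change_map(a, b, rule="difference")
        assert cm.cells["significant"].all()


class TestFootprintSummary:
    def test_single_cell_polygon_equals_cell(self):
        rng = np.random.default_rng(7)
        draws = rng.gamma(2, 1, (5, 400))
        g = _grid_from_draws(draws)
        x, y = g.cells[["x", "y"]].iloc[2]
        poly = box(x - 10, y - 10, x + 10, y + 10)
        s = footprint_summary(g, poly)
        assert s["n_cells"] == 1
        assert s["mean"] == pytest.approx(draws[2].mean())

    def test_uniform_surface_average(self):
        draws = np.tile(np.linspace(1, 2, 400), (5, 1))
        g = _grid_from_draws(draws)
        poly = box(X0 - 1e4, Y0 - 1e4, X0 + 1e5, Y0 + 1e5)
        s = footprint_summary(g, poly)
        assert s["n_cells"] == 5
        assert s["mean"] == pytest.approx(np.linspace(1, 2, 400).mean())

    def test_empty_polygon_rejected(self):
        g = _grid_from_draws(np.ones((3, 500)))
        with pytest.raises(ValueError, match="footprint"):
            footprint_summary(g, box(0, 0, 1, 1))


def test_make_grid_clips_to_hull():
    pts = np.array([[0, 0], [10_000, 0], [0, 10_000]]) + [X0, Y0]
    grid = make_grid(pts, 1000.0)
    # triangular hull: roughly half of the bounding box's cells
    assert 35 <= len(grid) <= 60
    assert (grid["x"] + grid["y"] <= X0 + Y0 + 10_600).all()
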