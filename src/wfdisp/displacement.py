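"""Posterior prediction surfaces and the credible-interval displacement test.

Per development phase, the fitted model predicts the expected count per
(full-effort) segment on a regular grid of cells — 0.36 km^2 cells for
guillemot, 1 km^2 for harbour porpoise — clipped to the convex hull of the
surveyed segment midpoints so the smooth is never extrapolated off-support.
Predictions are population level: random effects at zero, good sea state for
the zero-inflated model, full nominal effort.

A cell-wise change between two phases is flagged *significant* when the two
phases' marginal 95% credible intervals for the predicted value are disjoint.
This non-overlap rule is conservative relative to a credible interval on the
per-cell difference, which is available as an option.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, Polygon

from .inference import PosteriorSamples
from .utm import utm_to_lonlat

GRID_COLUMNS = ["x", "y", "mean", "sd", "lo", "hi"]


@dataclass
class PredictionGrid:
    """Per-cell posterior summaries of predicted count per segment."""

    species: str
    phase: str
    cell_size_m: float
    cells: pd.DataFrame = field(repr=False)  # x, y, mean, sd, lo, hi
    draws: np.ndarray | None = field(repr=False, default=None)  # (n_cells, n_draws)

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size_m / 1000.0) ** 2

    def to_csv(self, path) -> None:
        self.cells.loc[:, GRID_COLUMNS].to_csv(path, index=False)


@dataclass
class ChangeMap:
    """Pairwise phase difference of posterior mean predictions with flags."""

    species: str
    phase_a: str
    phase_b: str
    cells: pd.DataFrame = field(repr=False)  # x, y, diff, significant

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


def make_grid(coords: np.ndarray, spacing_m: float) -> pd.DataFrame:
    """Regular cell centres clipped to the convex hull of surveyed midpoints."""
    coords = np.asarray(coords, dtype=float)
    hull = MultiPoint(coords).convex_hull
    xmin, ymin, xmax, ymax = hull.bounds
    xs = np.arange(xmin + spacing_m / 2, xmax, spacing_m)
    ys = np.arange(ymin + spacing_m / 2, ymax, spacing_m)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    inside = np.array([hull.covers(Point(p)) for p in pts])
    return pd.DataFrame(pts[inside], columns=["x", "y"])


def predict_surface(
    post: PosteriorSamples,
    grid: pd.DataFrame,
    phase: str,
    condition: str = "good",
    cell_size_m: float | None = None,
) -> PredictionGrid:
    """Posterior predicted count per segment for one phase over the grid.

    Per draw and cell: ``mu = exp(beta_phase + f_phase(x, y))`` with random
    effects at zero and full nominal effort; for the ZIP family the expected
    count is ``(1 - pi0) * mu`` at the stated survey condition.
    """
    if phase not in post.levels:
        raise ValueError(f"phase {phase!r} was not in the fitted data")
    j = post.levels.index(phase)
    coords = grid[["x", "y"]].to_numpy()
    rows = post.basis.evaluate(coords)
    lin_cells = rows[:, : post.basis.n_linear]
    z_cells = rows[:, post.basis.n_linear :] @ post.whitener

    nc, nd = post.n_chains, post.n_draws
    beta0 = post.stacked("beta0")
    eta = np.broadcast_to(beta0, (len(coords), nc * nd)).copy()
    if phase != post.levels[0]:
        eta += post.stacked(f"phase_{phase}")
    lin_j = post.linear[:, :, j, :].reshape(nc * nd, -1)
    u_j = post.smooth_u[:, :, j, :].reshape(nc * nd, -1)
    tau_j = post.tau[:, :, j].reshape(nc * nd)
    eta += lin_cells @ lin_j.T + z_cells @ (tau_j[:, None] * u_j).T
    mu = np.exp(eta)
    if post.family == "ZIP":
        if condition not in ("good", "poor"):
            raise ValueError(f"unknown condition {condition!r}")
        zeta = post.stacked("gamma0")
        if condition == "poor":
            zeta = zeta + post.stacked("gamma_cond")
        mu = mu * (1.0 - 1.0 / (1.0 + np.exp(-zeta)))

    lo, hi = np.quantile(mu, [0.025, 0.975], axis=1)
    cells = grid.copy()
    cells["mean"] = mu.mean(axis=1)
    cells["sd"] = mu.std(axis=1, ddof=1)
    cells["lo"] = lo
    cells["hi"] = hi
    if cell_size_m is None:
        cell_size_m = post.nominal_length
    return PredictionGrid(
        species=post.species, phase=phase, cell_size_m=float(cell_size_m),
        cells=cells, draws=mu,
    )


def uncertainty_map(grid: PredictionGrid) -> pd.DataFrame:
    """Per-cell posterior SD as a proportion of the posterior mean.

    Degenerate cells (SD exactly 0) get ratio 0; zero-mean cells are flagged
    undefined (NaN ratio).
    """
    cells = grid.cells
    ratio = np.where(cells["sd"] == 0, 0.0, cells["sd"] / cells["mean"])
    undefined = cells["mean"].to_numpy() == 0
    ratio = np.where(undefined, np.nan, ratio)
    out = cells[["x", "y"]].copy()
    out["cv"] = ratio
    out["undefined"] = undefined
    return out


def change_map(
    grid_a: PredictionGrid, grid_b: PredictionGrid, rule: str = "overlap"
) -> ChangeMap:
    """Cell-wise difference of posterior means (B - A) with significance flags.

    ``rule='overlap'`` flags cells whose marginal 95% intervals are disjoint
    (the conservative mapping convention); ``rule='difference'`` instead flags
    cells whose 95% interval of the per-cell posterior difference excludes 0.
    """
    a, b = grid_a.cells, grid_b.cells
    if len(a) != len(b) or not np.allclose(a[["x", "y"]], b[["x", "y"]]):
        raise ValueError("grids have different cell geometry")
    out = a[["x", "y"]].copy()
    out["diff"] = b["mean"].to_numpy() - a["mean"].to_numpy()
    if rule == "overlap":
        sig = (a["lo"].to_numpy() > b["hi"].to_numpy()) | (
            b["lo"].to_numpy() > a["hi"].to_numpy()
        )
    elif rule == "difference":
        if grid_a.draws is None or grid_b.draws is None:
            raise ValueError("difference rule needs retained draws")
        d = grid_b.draws - grid_a.draws
        lo, hi = np.quantile(d, [0.025, 0.975], axis=1)
        sig = (lo > 0) | (hi < 0)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    out["significant"] = sig
    return ChangeMap(
        species=grid_a.species, phase_a=grid_a.phase, phase_b=grid_b.phase, cells=out
    )


def footprint_summary(grid: PredictionGrid, polygon: Polygon):
    """Posterior mean and 95% CrI of the average predicted count per segment
    over the cells whose centres fall inside the footprint polygon."""
    if grid.draws is None:
        raise ValueError("footprint summaries need retained draws")
    member = np.array(
        [polygon.covers(Point(x, y)) for x, y in grid.cells[["x", "y"]].to_numpy()]
    )
    if not member.any():
        raise ValueError("no grid cell centre falls inside the footprint polygon")
    per_draw = grid.draws[member].mean(axis=0)
    lo, hi = np.quantile(per_draw, [0.025, 0.975])
    return {
        "mean": float(per_draw.mean()),
        "lo": float(lo),
        "hi": float(hi),
        "n_cells": int(member.sum()),
        "per_draw": per_draw,
    }


def grid_to_geojson(grid: PredictionGrid, path, extra: pd.DataFrame | None = None) -> None:
    """Write the grid as a GeoJSON FeatureCollection of square cells (WGS84)."""
    h = grid.cell_size_m / 2.0
    feats = []
    cells = grid.cells if extra is None else grid.cells.join(
        extra.drop(columns=["x", "y"], errors="ignore")
    )
    for _, row in cells.iterrows():
        cx, cy = row["x"], row["y"]
        corners_x = np.array([cx - h, cx + h, cx + h, cx - h, cx - h])
        corners_y = np.array([cy - h, cy - h, cy + h, cy + h, cy - h])
        lon, lat = utm_to_lonlat(corners_x, corners_y)
        props = {
            k: (bool(v) if isinstance(v, (bool, np.bool_)) else float(v))
            for k, v in row.items()
            if k not in ("x", "y")
        }
        props.update({"phase": grid.phase, "species": grid.species})
        feats.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [
                        [[round(lo, 7), round(la, 7)] for lo, la in zip(lon, lat)]
                    ],
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
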