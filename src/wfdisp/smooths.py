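"""Low-rank penalized 2-D spline bases over UTM coordinates.

The spatial term of both count models is a two-dimensional smooth of position
allowed to differ between development phases.  It is built as a low-rank
thin-plate-type radial basis: knots are a space-filling (farthest-point)
subset of the observed segment midpoints, the radial columns are
``eta(r) = r^2 log r`` distances to the knots, and an unpenalized linear span
``(1, x, y)`` carries the polynomial part.  The penalty is the radial kernel
Gram matrix on the knots projected onto the complement of the knot-linear
span, which makes it positive semi-definite; the remaining null directions
are exactly the linear functions already carried by the unpenalized columns.

Coordinates are handled in kilometres internally so the kernel is numerically
well scaled, and the penalized columns are sum-to-zero centred over the
observed rows so the phase intercepts stay identifiable when the smooth is
expanded per phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_M_PER_KM = 1000.0


def _eta(r: np.ndarray) -> np.ndarray:
    """Thin-plate radial kernel r^2 log r with eta(0) = 0."""
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * np.log(r[nz])
    return out


def place_knots(coords: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Choose ``k`` space-filling knots among observed coordinates.

    Farthest-point (greedy cover) design: the start point is drawn with the
    seed, every later knot is the point maximising its distance to the chosen
    set (ties broken by index, so the result is deterministic given the seed).
    """
    pts = np.unique(np.asarray(coords, dtype=float), axis=0)
    if k < 4:
        raise ValueError("at least 4 knots are required")
    if k > len(pts):
        raise ValueError(f"requested {k} knots but only {len(pts)} distinct coordinates")
    if k == len(pts):
        return pts
    rng = np.random.default_rng(seed)
    chosen = [int(rng.integers(len(pts)))]
    d = np.linalg.norm(pts - pts[chosen[0]], axis=1)
    while len(chosen) < k:
        nxt = int(np.argmax(d))  # argmax takes the first maximiser: index tie-break
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(pts - pts[nxt], axis=1))
    return pts[chosen]


@dataclass
class SmoothBasis:
    """Constrained low-rank thin-plate design with its penalty.

    ``design`` holds the centred linear columns (x, y) followed by the centred
    radial columns; ``penalty`` acts on the radial block only and is PSD by
    construction.  ``centering`` stores the column means removed so new points
    are evaluated consistently.
    """

    knots: np.ndarray
    design: np.ndarray = field(repr=False)
    penalty: np.ndarray = field(repr=False)
    centering: np.ndarray
    origin: np.ndarray
    n_linear: int = 2

    @property
    def rank(self) -> int:
        return self.design.shape[1]

    @property
    def n_radial(self) -> int:
        return self.rank - self.n_linear

    def evaluate(self, coords: np.ndarray) -> np.ndarray:
        """Design rows for arbitrary coordinates (metres), same centring."""
        return _build_rows(np.asarray(coords, float), self.knots, self.origin) - self.centering


def _build_rows(coords_m: np.ndarray, knots_m: np.ndarray, origin: np.ndarray) -> np.ndarray:
    s = (coords_m - origin) / _M_PER_KM
    kn = (knots_m - origin) / _M_PER_KM
    r = np.linalg.norm(s[:, None, :] - kn[None, :, :], axis=2)
    return np.column_stack([s[:, 0], s[:, 1], _eta(r)])


def build_basis(coords: np.ndarray, knots: np.ndarray) -> SmoothBasis:
    """Build the constrained thin-plate radial basis at observed coordinates.

    Raises on coincident knots.  The penalty is the knot Gram matrix of the
    radial kernel projected off the knot-linear span (symmetrised, with
    negative round-off eigenvalues clipped at zero).
    """
    coords = np.asarray(coords, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if coords.ndim != 2 or len(coords) < 1:
        raise ValueError("coords must be a non-empty (n, 2) array")
    if len(knots) < 4:
        raise ValueError("at least 4 knots are required")
    if len(np.unique(knots, axis=0)) != len(knots):
        raise ValueError("coincident knots")

    origin = coords.mean(axis=0)
    raw = _build_rows(coords, knots, origin)
    centering = raw.mean(axis=0)
    design = raw - centering

    kn = (knots - origin) / _M_PER_KM
    rr = np.linalg.norm(kn[:, None, :] - kn[None, :, :], axis=2)
    gram = _eta(rr)
    # project off the span of (1, x, y) at the knots: the kernel is only
    # conditionally positive definite, the projection makes the penalty PSD
    t = np.column_stack([np.ones(len(kn)), kn])
    q, _ = np.linalg.qr(t)
    proj = np.eye(len(kn)) - q @ q.T
    pen = proj @ gram @ proj
    pen = 0.5 * (pen + pen.T)
    w, v = np.linalg.eigh(pen)
    pen = (v * np.clip(w, 0.0, None)) @ v.T

    return SmoothBasis(
        knots=knots, design=design, penalty=pen, centering=centering, origin=origin
    )


def penalized_subspace(basis: SmoothBasis, tol: float = 1e-10):
    """Whitened penalized columns for i.i.d.-coefficient sampling.

    Eigendecomposes the penalty and returns the transform ``T`` such that the
    radial block times ``T`` has an exchangeable N(0, tau^2) coefficient prior
    equivalent to the quadratic penalty.  Null directions of the projected
    penalty duplicate the unpenalized linear span and are dropped.
    """
    w, v = np.linalg.eigh(basis.penalty)
    keep = w > tol * w.max()
    return v[:, keep] / np.sqrt(w[keep])


@dataclass
class PhaseBasis:
    """Block-diagonal (factor-by) expansion of a smooth over phases."""

    basis: SmoothBasis
    levels: tuple[str, ...]
    design: np.ndarray = field(repr=False)
    block: np.ndarray  # column -> phase-level index

    @property
    def rank(self) -> int:
        return self.design.shape[1]


def expand_by_phase(basis: SmoothBasis, phases, levels=None) -> PhaseBasis:
    """Give each development phase its own copy of the smooth columns.

    A row has nonzero entries only in the block of its own phase, so the
    fitted surfaces are distinct per phase.
    """
    phases = np.asarray(phases)
    if levels is None:
        levels = tuple(dict.fromkeys(phases))  # first-appearance order
    unknown = set(phases) - set(levels)
    if unknown:
        raise ValueError(f"unknown phase label(s): {sorted(unknown)}")
    q = basis.rank
    design = np.zeros((len(phases), q * len(levels)))
    block = np.repeat(np.arange(len(levels)), q)
    for j, lev in enumerate(levels):
        rows = phases == lev
        design[np.ix_(rows, np.arange(j * q, (j + 1) * q))] = basis.design[rows]
    return PhaseBasis(basis=basis, levels=tuple(levels), design=design, block=block)
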