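"""Hierarchical Bayesian count models for segment-level abundance.

Two model families, mirroring the displacement analysis design:

* **NB GAMM** (guillemot): segment counts are negative binomial with
  ``log mu = beta_phase + f_phase(x, y) + b_survey + b_transect +
  log(effort/nominal)`` where ``f_phase`` is a phase-specific low-rank
  thin-plate smooth and the survey / transect-within-survey terms are nested
  Gaussian random effects.  The NB is mean-dispersion parameterized:
  ``Var = mu + mu^2/theta``.
* **ZIP GAMM** (harbour porpoise): the Poisson count part shares the same
  linear predictor; a binary part generates extra zeros with
  ``logit pi0 = gamma0 + gamma_cond * [condition == poor]`` so detectability
  can fall in poor sea states.

Priors are weakly informative and proper: N(0, 10^2) on intercept, phase
contrasts, per-phase linear trends and zero-part coefficients; half-N(0, 2^2)
on the random-effect and smoothing SDs; Gamma(0.01, 0.01) on the NB size.
The smooth penalty enters as a per-phase smoothing variance: whitened radial
columns carry i.i.d. N(0, tau_phase^2) coefficients.  Sampling uses the
non-centred parameterization throughout and the NUTS engine in
:mod:`wfdisp.mcmc`; convergence is summarised by split R-hat and bulk ESS.

Reported contrasts follow the conventional row labels: *pre vs con* is the
log-ratio construction/preconstruction, *con vs op* operation/construction,
*pre vs op* operation/preconstruction (the middle one is derived from draws).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import digamma, expit, gammaln, logsumexp

from . import smooths
from .mcmc import sample_nuts
from .survey_io import PHASES, SegmentTable

logger = logging.getLogger(__name__)

CONTRAST_ROWS = ("pre_vs_con", "con_vs_op", "pre_vs_op")


# ---------------------------------------------------------------------------
# probability mass functions


def nb_logpmf(y, mu, theta):
    """Negative binomial log-pmf, mean-dispersion form (Var = mu + mu^2/theta).

    Converges to the Poisson log-pmf as ``theta -> inf``.
    """
    y = np.asarray(y)
    if np.any(y < 0) or not np.issubdtype(np.asarray(y).dtype, np.integer):
        if np.any(np.asarray(y, float) % 1 != 0) or np.any(np.asarray(y, float) < 0):
            raise ValueError("y must be a non-negative integer")
        y = np.asarray(y, dtype=int)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(mu <= 0) or np.any(theta <= 0):
        raise ValueError("mu and theta must be positive")
    # large theta: gammaln cancellation loses ~1e-6 absolute, so switch to the
    # asymptotic expansion of log Gamma(theta+y) - log Gamma(theta)
    ratio = np.where(
        theta > 1e7,
        y * np.log(theta) + y * (y - 1) / (2.0 * theta),
        gammaln(y + theta) - gammaln(theta),
    )
    return (
        ratio
        - gammaln(y + 1)
        - theta * np.log1p(mu / theta)
        + y * (np.log(mu) - np.log(theta) - np.log1p(mu / theta))
    )


def zip_logpmf(y, mu, pi0):
    """Zero-inflated Poisson log-pmf.

    ``P(0) = pi0 + (1 - pi0) exp(-mu)``; positive counts come from the
    Poisson component scaled by ``1 - pi0``.
    """
    y = np.asarray(y)
    if np.any(np.asarray(y, float) % 1 != 0) or np.any(np.asarray(y, float) < 0):
        raise ValueError("y must be a non-negative integer")
    y = np.asarray(y, dtype=int)
    mu = np.asarray(mu, dtype=float)
    pi0 = np.asarray(pi0, dtype=float)
    if np.any((pi0 < 0) | (pi0 > 1)):
        raise ValueError("pi0 must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        log_pois = y * np.log(mu) - mu - gammaln(y + 1)
        shape = log_pois.shape
        zero = logsumexp(
            np.stack(
                [
                    np.broadcast_to(np.log(pi0), shape),
                    np.broadcast_to(np.log1p(-pi0) - mu, shape),
                ]
            ),
            axis=0,
        )
        pos = np.log1p(-pi0) + log_pois
    return np.where(y == 0, zero, pos)


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class PriorSpec:
    fixed_sd: float = 10.0  # intercept, contrasts, linear trends, zero part
    sd_scale: float = 2.0  # half-normal scale for random-effect/smoothing SDs
    theta_a: float = 0.01  # Gamma shape for NB size
    theta_b: float = 0.01  # Gamma rate


@dataclass(frozen=True)
class ModelSpec:
    family: str = "NB"  # "NB" or "ZIP"
    knots: int = 25
    chains: int = 3
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    target_accept: float = 0.8
    priors: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self):
        if self.family not in ("NB", "ZIP"):
            raise ValueError("family must be 'NB' or 'ZIP'")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")


@dataclass
class PosteriorSamples:
    """MCMC draws plus the design metadata needed to predict from them."""

    family: str
    levels: tuple[str, ...]
    scalars: dict[str, np.ndarray]  # name -> (chains, draws)
    linear: np.ndarray = field(repr=False)  # (chains, draws, n_phase, 2)
    smooth_u: np.ndarray = field(repr=False)  # (chains, draws, n_phase, q)
    tau: np.ndarray = field(repr=False)  # (chains, draws, n_phase)
    basis: smooths.SmoothBasis = field(repr=False, default=None)
    whitener: np.ndarray = field(repr=False, default=None)  # (n_radial, q)
    nominal_length: float = 600.0
    species: str = "guillemot"

    @property
    def n_chains(self):
        return next(iter(self.scalars.values())).shape[0]

    @property
    def n_draws(self):
        return next(iter(self.scalars.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        return self.scalars[name].reshape(-1)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format draw table (parameter, chain, iteration, value)."""
        recs = []
        for name, arr in self.scalars.items():
            c, d = arr.shape
            recs.append(
                pd.DataFrame(
                    {
                        "parameter": name,
                        "chain": np.repeat(np.arange(c), d),
                        "iteration": np.tile(np.arange(d), c),
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(recs, ignore_index=True)

    def save(self, outdir) -> None:
        """Write draws as a long text table plus a plain-text basis sidecar."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(outdir / "draws.csv", index=False)
        nc, nd = self.n_chains, self.n_draws
        import json as _json

        sidecar = {
            "family": self.family,
            "levels": list(self.levels),
            "species": self.species,
            "nominal_length": self.nominal_length,
            "knots": self.basis.knots.tolist(),
            "centering": self.basis.centering.tolist(),
            "origin": self.basis.origin.tolist(),
            "penalty": self.basis.penalty.tolist(),
            "whitener": self.whitener.tolist(),
            "shape": [nc, nd],
            "linear": self.linear.tolist(),
            "smooth_u": self.smooth_u.tolist(),
            "tau": self.tau.tolist(),
        }
        with open(outdir / "fit_state.json", "w") as fh:
            _json.dump(sidecar, fh)

    @classmethod
    def load(cls, outdir) -> "PosteriorSamples":
        import json as _json
        from pathlib import Path

        outdir = Path(outdir)
        long = pd.read_csv(outdir / "draws.csv")
        with open(outdir / "fit_state.json") as fh:
            sc = _json.load(fh)
        nc, nd = sc["shape"]
        scalars = {}
        for name, grp in long.groupby("parameter", sort=False):
            scalars[name] = (
                grp.sort_values(["chain", "iteration"])["value"].to_numpy().reshape(nc, nd)
            )
        knots = np.asarray(sc["knots"])
        basis = smooths.SmoothBasis(
            knots=knots,
            design=np.zeros((1, 2 + len(knots))),
            penalty=np.asarray(sc["penalty"]),
            centering=np.asarray(sc["centering"]),
            origin=np.asarray(sc["origin"]),
        )
        return cls(
            family=sc["family"],
            levels=tuple(sc["levels"]),
            scalars=scalars,
            linear=np.asarray(sc["linear"]),
            smooth_u=np.asarray(sc["smooth_u"]),
            tau=np.asarray(sc["tau"]),
            basis=basis,
            whitener=np.asarray(sc["whitener"]),
            nominal_length=sc["nominal_length"],
            species=sc["species"],
        )


@dataclass
class FitDiagnostics:
    rhat: pd.Series
    ess_bulk: pd.Series
    divergences: int
    converged: bool

    @property
    def max_rhat(self) -> float:
        return float(self.rhat.max())


# ---------------------------------------------------------------------------
# linear predictor (single segment; the vectorised version lives in _Model)


def linear_predictor(
    phase_effect: float,
    smooth_value: float,
    survey_effect: float,
    transect_effect: float,
    effort_m: float,
    nominal_m: float,
    gamma0: float | None = None,
    gamma_cond: float | None = None,
    condition: str = "good",
):
    """Segment-level linear predictor on the link scales.

    Returns ``(log_mu, logit_pi0)``; the second element is None unless the
    zero-part coefficients are supplied.
    """
    if condition not in ("good", "poor"):
        raise ValueError(f"unknown condition {condition!r}")
    log_mu = (
        phase_effect
        + smooth_value
        + survey_effect
        + transect_effect
        + np.log(effort_m / nominal_m)
    )
    logit_pi0 = None
    if gamma0 is not None:
        logit_pi0 = gamma0 + (gamma_cond or 0.0) * (condition == "poor")
    return log_mu, logit_pi0


# ---------------------------------------------------------------------------
# internal model: packed parameter vector, joint log density and gradient


class _Model:
    def __init__(self, table: SegmentTable, spec: ModelSpec):
        rows = table.rows.reset_index(drop=True)
        self.spec = spec
        self.y = rows["count"].to_numpy(dtype=int)
        self.n = len(rows)
        self.offset = np.log(rows["effort_m"].to_numpy() / table.nominal_length)

        self.levels = tuple(p for p in PHASES if (rows["phase"] == p).any())
        self.phase_idx = np.array([self.levels.index(p) for p in rows["phase"]])
        counts = rows.groupby("phase")["survey_id"].nunique()
        if (counts < 2).any():
            raise ValueError("each development phase needs at least 2 surveys")

        coords = rows[["x", "y"]].to_numpy()
        knots = smooths.place_knots(coords, k=min(spec.knots, len(np.unique(coords, axis=0))),
                                    seed=spec.seed)
        self.basis = smooths.build_basis(coords, knots)
        whitener = smooths.penalized_subspace(self.basis)
        Z = self.basis.design[:, self.basis.n_linear :] @ whitener
        # standardise the whitened columns over the observed rows so the
        # smoothing SD tau is scale-free (the penalty's absolute scale is
        # arbitrary); the rescale is folded into the stored whitener so
        # predictions at new locations are consistent
        col_scale = Z.std(axis=0)
        col_scale[col_scale == 0] = 1.0
        self.whitener = whitener / col_scale
        self.Xlin = self.basis.design[:, : self.basis.n_linear]  # (n, 2)
        self.Z = Z / col_scale
        self.q = self.Z.shape[1]
        self.n_phase = len(self.levels)

        # per-phase row masks
        self.masks = [self.phase_idx == j for j in range(self.n_phase)]

        surveys = sorted(rows["survey_id"].unique())
        transects = sorted(set(zip(rows["survey_id"], rows["transect_id"])))
        self.surveys, self.transects = surveys, transects
        self.survey_idx = rows["survey_id"].map({s: i for i, s in enumerate(surveys)}).to_numpy()
        tmap = {t: i for i, t in enumerate(transects)}
        self.transect_idx = np.array(
            [tmap[(s, t)] for s, t in zip(rows["survey_id"], rows["transect_id"])]
        )
        self.n_survey, self.n_transect = len(surveys), len(transects)

        if spec.family == "ZIP":
            if set(rows["condition"].unique()) != {"good", "poor"}:
                raise ValueError("ZIP fits require both good and poor conditions present")
        self.poor = (rows["condition"] == "poor").to_numpy(dtype=float)

        # packed layout
        sizes = {
            "beta0": 1,
            "contrasts": self.n_phase - 1,
            "linear": 2 * self.n_phase,
            "u": self.q * self.n_phase,
            "survey_raw": self.n_survey,
            "transect_raw": self.n_transect,
            "log_tau": self.n_phase,
            "log_sigma_s": 1,
            "log_sigma_t": 1,
        }
        if spec.family == "NB":
            sizes["log_theta"] = 1
        else:
            sizes["gamma"] = 2
        self.slices = {}
        pos = 0
        for k, s in sizes.items():
            self.slices[k] = slice(pos, pos + s)
            pos += s
        self.dim = pos
        self.P = self.slices["transect_raw"].stop  # coefficient block length

        # one dense design for the whole coefficient block, so each density
        # evaluation is two matrix-vector products
        X = np.zeros((self.n, self.P))
        X[:, 0] = 1.0
        for j in range(1, self.n_phase):
            X[self.masks[j], j] = 1.0
        l0 = self.slices["linear"].start
        u0 = self.slices["u"].start
        for j, m in enumerate(self.masks):
            X[m, l0 + 2 * j : l0 + 2 * j + 2] = self.Xlin[m]
            X[m, u0 + j * self.q : u0 + (j + 1) * self.q] = self.Z[m]
        s0 = self.slices["survey_raw"].start
        t0 = self.slices["transect_raw"].start
        X[np.arange(self.n), s0 + self.survey_idx] = 1.0
        X[np.arange(self.n), t0 + self.transect_idx] = 1.0
        self.X = np.ascontiguousarray(X)
        self.XT = np.ascontiguousarray(X.T)
        self._u_slices = [
            slice(u0 + j * self.q, u0 + (j + 1) * self.q) for j in range(self.n_phase)
        ]
        self._s_slice = self.slices["survey_raw"]
        self._t_slice = self.slices["transect_raw"]
        self._fixed_slice = slice(0, u0)  # intercept, contrasts, linear trends
        self._raw_slice = slice(u0, self.P)  # whitened smooth + random effects

        # counts take few unique values: evaluate special functions there only
        self._yf = self.y.astype(float)
        self._yu, self._y_inv = np.unique(self.y, return_inverse=True)
        self._yuf = self._yu.astype(float)
        self._gammaln_y1 = gammaln(self._yf + 1.0)
        self._zero_mask = self.y == 0
        self._pos_mask = ~self._zero_mask

    # -- densities ----------------------------------------------------------

    def _unpack(self, w):
        s = self.slices
        return {k: w[v] for k, v in s.items()}

    def logp_grad(self, w):
        pr = self.spec.priors
        s = self.slices
        wc = w[: self.P]
        tau = np.exp(w[s["log_tau"]])
        sig_s = np.exp(w[s["log_sigma_s"]][0])
        sig_t = np.exp(w[s["log_sigma_t"]][0])
        svec = np.ones(self.P)
        for j, usl in enumerate(self._u_slices):
            svec[usl] = tau[j]
        svec[self._s_slice] = sig_s
        svec[self._t_slice] = sig_t

        eta = self.X @ (wc * svec) + self.offset
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        y = self.y
        grad = np.zeros_like(w)

        if self.spec.family == "NB":
            theta = np.exp(w[s["log_theta"]][0])
            yf = self._yf
            tpm = theta + mu
            log_tpm = np.log(tpm)
            # special functions only at the few unique count values
            gl_ratio = (gammaln(self._yuf + theta) - gammaln(theta))[self._y_inv]
            ll = (
                gl_ratio.sum() - self._gammaln_y1.sum()
                + theta * (self.n * np.log(theta) - log_tpm.sum())
                + yf @ eta - yf @ log_tpm
            )
            g_eta = (yf - mu) * (theta / tpm)
            dg_ratio = (digamma(self._yuf + theta) - digamma(theta))[self._y_inv]
            dll_dlogtheta = theta * (
                dg_ratio.sum()
                + self.n * (np.log(theta) + 1.0) - log_tpm.sum()
                - ((yf + theta) / tpm).sum()
            )
            ll += pr.theta_a * w[s["log_theta"]][0] - pr.theta_b * theta
            grad[s["log_theta"]] = dll_dlogtheta + pr.theta_a - pr.theta_b * theta
        else:
            g0, gc = w[s["gamma"]]
            zeta = g0 + gc * self.poor
            pi0 = expit(zeta)
            zero = self._zero_mask
            pos = self._pos_mask
            yf = self._yf
            log_pois0 = -mu[zero]
            # log P(0) = log(pi0 + (1-pi0) e^{-mu}), stable via logaddexp
            la = np.logaddexp(np.log(pi0[zero]), np.log1p(-pi0[zero]) + log_pois0)
            ll = la.sum()
            ll += (
                np.log1p(-pi0[pos]).sum()
                + yf[pos] @ eta[pos] - mu[pos].sum()
                - self._gammaln_y1[pos].sum()
            )
            g_eta = np.empty(self.n)
            ez = np.exp(np.log1p(-pi0[zero]) + log_pois0 - la)  # (1-pi0)e^-mu / P(0)
            g_eta[zero] = -ez * mu[zero]
            g_eta[pos] = yf[pos] - mu[pos]
            g_zeta = np.empty(self.n)
            # d logP(0)/d zeta = pi0 (1 - pi0)(1 - e^{-mu}) / P(0)
            g_zeta[zero] = pi0[zero] * (1.0 - pi0[zero]) * (1.0 - np.exp(log_pois0)) * np.exp(-la)
            g_zeta[pos] = -pi0[pos]
            ll += -(g0**2 + gc**2) / (2 * pr.fixed_sd**2)
            grad[s["gamma"]] = np.array(
                [g_zeta.sum(), g_zeta @ self.poor]
            ) - np.array([g0, gc]) / pr.fixed_sd**2

        # priors: N(0, fixed_sd^2) on the fixed block, N(0,1) on raw coefficients
        wf = wc[self._fixed_slice]
        wr = wc[self._raw_slice]
        ll += -(wf**2).sum() / (2 * pr.fixed_sd**2) - 0.5 * (wr**2).sum()
        # half-normal on SD scales (with log-Jacobian from sampling the log)
        for key, val in (("log_tau", tau), ("log_sigma_s", np.array([sig_s])),
                         ("log_sigma_t", np.array([sig_t]))):
            ll += (-(val**2) / (2 * pr.sd_scale**2) + np.log(val)).sum()
            grad[s[key]] += -(val**2) / pr.sd_scale**2 + 1.0

        # chain rule through eta in one pass
        h = self.XT @ g_eta
        gc_ = h * svec
        gc_[self._fixed_slice] += -wf / pr.fixed_sd**2
        gc_[self._raw_slice] += -wr
        grad[: self.P] += gc_
        t = h * wc * svec  # d eta/d log-scale contributions
        for j, usl in enumerate(self._u_slices):
            grad[s["log_tau"]][j : j + 1] += t[usl].sum()
        grad[s["log_sigma_s"]] += t[self._s_slice].sum()
        grad[s["log_sigma_t"]] += t[self._t_slice].sum()
        return ll, grad

    def initial_point(self, rng) -> np.ndarray:
        w = 0.01 * rng.standard_normal(self.dim)
        rate = max(self.y.mean(), 0.05)
        w[self.slices["beta0"]] = np.log(rate)
        w[self.slices["log_tau"]] = np.log(0.5)
        w[self.slices["log_sigma_s"]] = np.log(0.3)
        w[self.slices["log_sigma_t"]] = np.log(0.3)
        if self.spec.family == "NB":
            w[self.slices["log_theta"]] = 0.0
        else:
            w[self.slices["gamma"]] = np.array([-0.5, 0.5])
        return w


# ---------------------------------------------------------------------------
# fitting


def fit(table: SegmentTable, spec: ModelSpec):
    """Fit the model by NUTS; returns posterior draws and diagnostics.

    A fit with max split R-hat above 1.1 is flagged non-converged; the result
    is still returned so artifacts can be inspected.
    """
    model = _Model(table, spec)
    chains = []
    for c in range(spec.chains):
        rng = np.random.default_rng([spec.seed, 7919, c])
        init = model.initial_point(rng)
        res = sample_nuts(
            model.logp_grad,
            init,
            n_warmup=spec.warmup,
            n_draws=spec.draws,
            seed=int(np.random.default_rng([spec.seed, 104729, c]).integers(2**31)),
            target_accept=spec.target_accept,
        )
        chains.append(res)
    draws = np.stack([c.draws for c in chains])  # (chains, draws, dim)
    divergences = sum(c.divergences for c in chains)

    s = model.slices
    n_phase = model.n_phase
    scalars: dict[str, np.ndarray] = {"beta0": draws[:, :, s["beta0"].start]}
    contrasts = draws[:, :, s["contrasts"]]
    # phase contrasts vs preconstruction baseline
    names = [f"phase_{lev}" for lev in model.levels[1:]]
    for i, nm in enumerate(names):
        scalars[nm] = contrasts[:, :, i]
    if n_phase == 3:
        scalars["pre_vs_con"] = contrasts[:, :, 0]
        scalars["con_vs_op"] = contrasts[:, :, 1] - contrasts[:, :, 0]
        scalars["pre_vs_op"] = contrasts[:, :, 1]
    tau = np.exp(draws[:, :, s["log_tau"]])
    for j, lev in enumerate(model.levels):
        scalars[f"tau_{lev}"] = tau[:, :, j]
    scalars["sigma_survey"] = np.exp(draws[:, :, s["log_sigma_s"].start])
    scalars["sigma_transect"] = np.exp(draws[:, :, s["log_sigma_t"].start])
    if spec.family == "NB":
        scalars["theta"] = np.exp(draws[:, :, s["log_theta"].start])
    else:
        scalars["gamma0"] = draws[:, :, s["gamma"].start]
        scalars["gamma_cond"] = draws[:, :, s["gamma"].start + 1]

    post = PosteriorSamples(
        family=spec.family,
        levels=model.levels,
        scalars=scalars,
        linear=draws[:, :, s["linear"]].reshape(spec.chains, spec.draws, n_phase, 2),
        smooth_u=draws[:, :, s["u"]].reshape(spec.chains, spec.draws, n_phase, model.q),
        tau=tau,
        basis=model.basis,
        whitener=model.whitener,
        nominal_length=table.nominal_length,
        species=table.species,
    )

    idata = az.from_dict(posterior={k: v for k, v in scalars.items()})
    rhat = pd.Series({k: float(v.values) for k, v in az.rhat(idata).items()})
    ess = pd.Series({k: float(v.values) for k, v in az.ess(idata).items()})
    converged = bool(rhat.max() <= 1.1)
    if not converged:
        logger.warning("fit flagged non-converged: max R-hat = %.3f", rhat.max())
    diag = FitDiagnostics(
        rhat=rhat, ess_bulk=ess, divergences=divergences, converged=converged
    )
    return post, diag


# ---------------------------------------------------------------------------
# raw -> response scale and the significance rule


def response_level(estimate, lower, upper, link: str):
    """Transform a raw estimate and CrI to the response scale.

    ``log`` link: elementwise exp (rate ratios); ``logit`` link: elementwise
    inverse-logit (probabilities).  Interval ordering is preserved because
    both inverse links are strictly increasing.
    """
    if not (lower <= estimate <= upper):
        raise ValueError("require lower <= estimate <= upper")
    if link == "log":
        f = np.exp
    elif link == "logit":
        f = expit
    else:
        raise ValueError(f"unknown link {link!r}")
    return float(f(estimate)), float(f(lower)), float(f(upper))


def credible_interval(draws, prob: float = 0.95):
    """Equal-tailed posterior interval from raw draws."""
    a = (1.0 - prob) / 2.0
    lo, hi = np.quantile(np.asarray(draws).reshape(-1), [a, 1.0 - a])
    return float(lo), float(hi)


def significance(draws, prob: float = 0.95) -> bool:
    """CrI-bounds-zero rule: significant iff the interval excludes zero."""
    flat = np.asarray(draws).reshape(-1)
    if flat.size < 400:
        raise ValueError("at least 400 draws are required for the 95% interval")
    lo, hi = credible_interval(flat, prob)
    return (lo > 0 and hi > 0) or (lo < 0 and hi < 0)
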