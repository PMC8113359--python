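"""Numerical inversion of the forward PRF model.

Given a gene's observed pN/pS and dN/dS (on the count-ratio scale of the
forward model), its mutation-rate ratio muN/muS and the sample size m, the
estimator finds the (Ne*s, alpha_m) pair whose forward predictions match the
observations.  By default the divergence observable is the
divergence-dominated limit of dN/dS, which needs no divergence time; the full
finite-t_div model is available through the options.

The key structural fact exploited here: at fixed Ne*s both expected ratios
are *linear* in alpha_m, so each observation defines alpha_m as an explicit
function of Ne*s and the two-parameter system collapses to a one-dimensional
root find.  A profile scan over log Ne*s locates sign changes, brentq
polishes each root, and any root with alpha_m inside [0, 1] is an exact
solution (residual ~ machine precision).  When no interior root exists
(observations outside the attainable set) a bounded multi-start least-squares
fit on the log scale reports the minimal-residual estimate with a
``no_solution`` flag.  All grids are gene-independent, so a fitter built once
serves a whole table.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize

from .errors import ConfigError, ValidationError
from . import prf_model
from .prf_model import harmonic_number

__all__ = [
    "InferenceOptions",
    "PRFEstimate",
    "PRFFitter",
    "estimate_mu_ratio",
    "estimate_gene",
    "estimate_table",
]

log = logging.getLogger(__name__)

NEUTRAL_THRESHOLD = 1e-4  # below this Ne*s, alpha_m is unidentifiable


@dataclass(frozen=True)
class InferenceOptions:
    """Tuning knobs for the per-gene inversion.

    ne_s_bounds : search interval for Ne*s (log-spaced scan).
    scan_points : grid size of the 1-D profile scan for exact roots.
    multistart : grid shape (Ne*s, alpha_m) of the least-squares fallback.
    residual_tol : log-residual norm below which the fit counts as converged.
    no_solution_tol : residual norm above which the observations are declared
        unattainable.
    t_div : when set, fit the full finite-divergence dN/dS instead of the
        divergence-dominated limit.
    """

    ne_s_bounds: tuple[float, float] = (1e-6, 100.0)
    scan_points: int = 48
    multistart: tuple[int, int] = (8, 8)
    residual_tol: float = 1e-6
    no_solution_tol: float = 1e-3
    t_div: float | None = None


DEFAULT_OPTIONS = InferenceOptions()


@dataclass(frozen=True)
class PRFEstimate:
    """Per-gene estimate with diagnostics.

    ``identifiability`` is one of ``ok``, ``neutral_alpha_unidentifiable``
    (Ne*s below 1e-4, where alpha_m has no leverage), ``boundary`` (an
    observation was floored away from zero), or ``no_solution``.
    """

    ne_s_hat: float
    alpha_m_hat: float
    converged: bool
    residual_norm: float
    identifiability: str


def estimate_mu_ratio(sites_N: float, sites_S: float) -> float:
    """muN/muS estimated as the ratio of nonsynonymous to synonymous site
    totals (equal per-site rates)."""
    if sites_S <= 0:
        raise ConfigError(f"sites_S must be > 0, got {sites_S}")
    if sites_N < 0:
        raise ConfigError(f"sites_N must be >= 0, got {sites_N}")
    if sites_N == 0:
        warnings.warn("sites_N = 0: gene carries no information about selection",
                      stacklevel=2)
        return 0.0
    return sites_N / sites_S


def _fixation_factors(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.atleast_1d(x)
    with np.errstate(over="ignore"):
        fb = np.where(np.abs(x) < prf_model.NEAR_NEUTRAL,
                      1.0 + 0.5 * x + x * x / 12.0,
                      x / (-np.expm1(-x)))
        fd = np.where(np.abs(x) < prf_model.NEAR_NEUTRAL,
                      1.0 - 0.5 * x + x * x / 12.0,
                      x / np.expm1(x))
    return fb, fd


class PRFFitter:
    """Inverts the forward model for genes sharing a sample size m.

    The profile-scan grid, the multi-start grid and their forward components
    depend only on (m, options), so they are computed once per fitter and
    reused for every gene.
    """

    def __init__(self, m: int, options: InferenceOptions = DEFAULT_OPTIONS):
        if int(m) != m or m < 2:
            raise ConfigError(f"m must be an integer >= 2, got {m}")
        self.m = int(m)
        self.options = options
        self.h = harmonic_number(self.m - 1)
        lo, hi = options.ne_s_bounds
        self._scan_x = np.geomspace(lo, hi, options.scan_points)
        self._scan = self._components(self._scan_x)
        n_x, n_a = options.multistart
        self._ms_x = np.geomspace(lo, hi, n_x)
        self._ms_a = np.linspace(0.0, 1.0, n_a)
        self._ms = self._components(self._ms_x)

    # alpha_m-linear decomposition:
    #   pn_ps/mu = a*pb + (1-a)*pd ;  dn_ds/mu = a*db + (1-a)*dd
    def _components(self, x: np.ndarray):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        pb = prf_model.segregating_integral_many(4.0 * x, self.m) / self.h
        pd_ = prf_model.segregating_integral_many(-4.0 * x, self.m) / self.h
        fb, fd = _fixation_factors(x)
        t = self.options.t_div
        if t is None:
            db, dd = fb, fd
        else:
            denom = t + 1.0 / self.m + 1.0
            gb = (prf_model.g_integral_many(x, self.m)
                  + prf_model.g_integral_many(x, 1))
            gd = (prf_model.g_integral_many(-x, self.m)
                  + prf_model.g_integral_many(-x, 1))
            db, dd = fb * (t + gb) / denom, fd * (t + gd) / denom
        return pb, pd_, db, dd

    def _ratios(self, x: float, alpha: float) -> tuple[float, float]:
        pb, pd_, db, dd = self._components(np.array([x]))
        return (alpha * pb[0] + (1 - alpha) * pd_[0],
                alpha * db[0] + (1 - alpha) * dd[0])

    def _residual(self, x: float, alpha: float, P: float, D: float) -> float:
        p, d = self._ratios(x, alpha)
        return math.hypot(math.log(p / P), math.log(d / D))

    def fit(
        self,
        pnps_obs: float,
        dnds_obs: float,
        mu_ratio: float,
        boundary: bool = False,
    ) -> PRFEstimate:
        for name, v in (("pnps_obs", pnps_obs), ("dnds_obs", dnds_obs)):
            if v is None or not math.isfinite(v):
                raise ValidationError(f"{name} must be finite, got {v}")
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        if pnps_obs == 0 or dnds_obs == 0:
            raise ValidationError(
                "zero observations must be floored before fitting "
                "(see estimate_table)"
            )
        if mu_ratio <= 0:
            raise ConfigError(f"mu_ratio must be > 0, got {mu_ratio}")
        P = pnps_obs / mu_ratio
        D = dnds_obs / mu_ratio
        opts = self.options
        lo, hi = opts.ne_s_bounds

        xs = self._scan_x
        pb, pd_, db, dd = self._scan
        with np.errstate(divide="ignore", invalid="ignore"):
            g = (D - dd) / (db - dd) - (P - pd_) / (pb - pd_)

        def g_scalar(logx: float) -> float:
            x = math.exp(logx)
            pbx, pdx, dbx, ddx = self._components(np.array([x]))
            return ((D - ddx[0]) / (dbx[0] - ddx[0])
                    - (P - pdx[0]) / (pbx[0] - pdx[0]))

        candidates: list[tuple[float, float, float]] = []
        finite = np.isfinite(g)
        for i in range(len(xs) - 1):
            if not (finite[i] and finite[i + 1]):
                continue
            if g[i] == 0.0 or g[i] * g[i + 1] < 0:
                try:
                    lx = brentq(g_scalar, math.log(xs[i]), math.log(xs[i + 1]),
                                xtol=1e-14, rtol=8.9e-16)
                except ValueError:
                    continue
                x_root = math.exp(lx)
                _, _, dbx, ddx = self._components(np.array([x_root]))
                alpha = (D - ddx[0]) / (dbx[0] - ddx[0])
                if -1e-9 <= alpha <= 1.0 + 1e-9:
                    alpha = min(max(alpha, 0.0), 1.0)
                    candidates.append(
                        (self._residual(x_root, alpha, P, D), x_root, alpha)
                    )

        if candidates:
            res, x_hat, a_hat = min(candidates, key=lambda c: (c[0], c[1]))
        else:
            pbg, pdg, dbg, ddg = self._ms
            ga = self._ms_a
            obj_grid = (
                np.log((ga[None, :] * pbg[:, None]
                        + (1 - ga[None, :]) * pdg[:, None]) / P) ** 2
                + np.log((ga[None, :] * dbg[:, None]
                          + (1 - ga[None, :]) * ddg[:, None]) / D) ** 2
            )
            order = np.dstack(
                np.unravel_index(np.argsort(obj_grid, axis=None), obj_grid.shape)
            )[0]

            def objective(v: np.ndarray) -> float:
                p, d = self._ratios(math.exp(v[0]), v[1])
                return math.log(p / P) ** 2 + math.log(d / D) ** 2

            # the grid already localises the optimum well; one bounded local
            # refinement from each of the two best cells suffices
            best = None
            for ix, ia in order[:2]:
                r = minimize(
                    objective,
                    x0=np.array([math.log(self._ms_x[ix]), ga[ia]]),
                    method="L-BFGS-B",
                    bounds=[(math.log(lo), math.log(hi)), (0.0, 1.0)],
                )
                if best is None or r.fun < best.fun:
                    best = r
            x_hat = math.exp(best.x[0])
            a_hat = float(min(max(best.x[1], 0.0), 1.0))
            res = math.sqrt(max(best.fun, 0.0))

        if x_hat < NEUTRAL_THRESHOLD:
            flag = "neutral_alpha_unidentifiable"
        elif boundary:
            flag = "boundary"
        elif res > opts.no_solution_tol:
            flag = "no_solution"
        else:
            flag = "ok"
        return PRFEstimate(
            ne_s_hat=float(x_hat),
            alpha_m_hat=float(a_hat),
            converged=res < opts.residual_tol,
            residual_norm=float(res),
            identifiability=flag,
        )


def estimate_gene(
    pnps_obs: float,
    dnds_obs: float,
    mu_ratio: float,
    m: int,
    options: InferenceOptions = DEFAULT_OPTIONS,
) -> PRFEstimate:
    """Invert the forward model for one gene (see :class:`PRFFitter`).

    Observations must be finite and > 0; zero observations are floored
    upstream (see :func:`estimate_table`).
    """
    return PRFFitter(m, options).fit(pnps_obs, dnds_obs, mu_ratio)


def estimate_table(
    genes: pd.DataFrame,
    m: int,
    options: InferenceOptions = DEFAULT_OPTIONS,
) -> pd.DataFrame:
    """Fit every usable gene in a table; returns a copy with estimate columns.

    Per-site ``pn_ps``/``dn_ds`` observations are rescaled by each gene's
    muN/muS (= sites_N/sites_S) onto the model's count-ratio scale.  Genes
    with undefined observations (NaN pn_ps from poly_S = 0, NaN dn_ds) are
    skipped with a logged reason; zero observations are floored at half the
    smallest positive observed value of their column and flagged ``boundary``.
    Output is deterministic given the input table.
    """
    table = genes.copy()
    for col in ("pn_ps", "dn_ds"):
        if col not in table.columns:
            raise ConfigError(f"gene table lacks required column {col!r}")
    mu = (table["sites_N"] / table["sites_S"]).to_numpy(dtype=float)
    pnps = table["pn_ps"].to_numpy(dtype=float) * mu
    dnds = table["dn_ds"].to_numpy(dtype=float) * mu

    def floor_of(values: np.ndarray) -> float:
        pos = values[np.isfinite(values) & (values > 0)]
        if pos.size == 0:
            raise ValidationError("no positive observations to derive a floor")
        return 0.5 * float(pos.min())

    usable = np.isfinite(pnps) & np.isfinite(dnds) & (mu > 0)
    if not usable.any():
        raise ValidationError("no genes with defined pn_ps and dn_ds observations")
    floor_p = floor_of(pnps[usable])
    floor_d = floor_of(dnds[usable])

    fitter = PRFFitter(m, options)
    n = len(table)
    out = {
        "ne_s_hat": np.full(n, np.nan),
        "alpha_m_hat": np.full(n, np.nan),
        "prf_converged": np.zeros(n, dtype=bool),
        "prf_residual": np.full(n, np.nan),
        "prf_flag": np.array(["skipped"] * n, dtype=object),
    }
    for i in range(n):
        if not usable[i]:
            log.info(
                "gene %s skipped: undefined pn_ps or dn_ds",
                table.iloc[i].get("gene_id", i),
            )
            continue
        p, d = pnps[i], dnds[i]
        boundary = False
        if p == 0:
            p, boundary = floor_p, True
        if d == 0:
            d, boundary = floor_d, True
        est = fitter.fit(p, d, mu[i], boundary=boundary)
        out["ne_s_hat"][i] = est.ne_s_hat
        out["alpha_m_hat"][i] = est.alpha_m_hat
        out["prf_converged"][i] = est.converged
        out["prf_residual"][i] = est.residual_norm
        out["prf_flag"][i] = est.identifiability
    for k, v in out.items():
        table[k] = v
    return table
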