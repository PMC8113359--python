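"""Forward Poisson random field (PRF) model of polymorphism and divergence.

The model assumes that sites within a gene evolve independently (no selective
interference), that a fraction ``alpha_m`` of new nonsynonymous mutations are
beneficial with scaled selection strength ``+Ne*s`` (homozygote effect, additive),
the remaining fraction deleterious with ``-Ne*s``, and that synonymous mutations
are neutral.  Under a Poisson random field, the numbers of polymorphic and fixed
sites of each class are independent Poisson variables whose means are diffusion
integrals over the allele-frequency sojourn density.  The module computes those
means and the derived pN/pS and dN/dS ratios, and provides a discrete
Wright-Fisher simulator as an independent oracle.

Scaling note (``gamma_convention``): the polymorphism integrals use the exponent
``4*Ne*s`` while the fixation factors and the divergence-dominated limit use
``Ne*s``.  Both forms are implemented exactly as stated, sharing the single
parameter ``ne_s`` on the fixation scale; the polymorphism sojourn density is
evaluated at ``gamma = 4*ne_s``.  See docs/methods.md for discussion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .errors import ConfigError, NumericalError

__all__ = [
    "PRFParams",
    "WFResult",
    "harmonic_number",
    "g_integral",
    "segregating_integral",
    "segregating_integral_many",
    "g_integral_many",
    "synonymous_sites_integral",
    "fixation_factor",
    "expected_poly_sites",
    "pn_ps_expected",
    "expected_fixed_sites",
    "dn_ds_expected",
    "dn_ds_limit",
    "pn_ps_ratio",
    "dn_ds_ratio",
    "dn_ds_ratio_limit",
    "wf_oracle",
]

# Below this magnitude of the scaled selection coefficient every sojourn and
# fixation factor is a 0/0 form; second-order series expansions take over.
NEAR_NEUTRAL = 1e-6


@dataclass(frozen=True)
class PRFParams:
    """Parameters of the two-effect PRF model.

    ne_s : scaled selection magnitude (>= 0); beneficial mutations have effect
        +s as homozygotes, deleterious mutations -s.
    alpha_m : fraction of new nonsynonymous mutations that are beneficial.
    mu_ratio : ratio of nonsynonymous to synonymous mutation rates (muN/muS).
    m : sample size in gene copies.
    t_div : species divergence time in units of 2*Ne generations (only needed
        for absolute fixed-site counts; the divergence-dominated limit does not
        use it).
    theta_S : synonymous population mutation scale 4*Ne*muS; cancels in both
        ratios and only sets absolute count scales.
    """

    ne_s: float
    alpha_m: float
    mu_ratio: float
    m: int
    t_div: float | None = None
    theta_S: float = 1.0

    def __post_init__(self) -> None:
        if not (self.ne_s >= 0 and math.isfinite(self.ne_s)):
            raise ConfigError(f"ne_s must be finite and >= 0, got {self.ne_s}")
        if not 0.0 <= self.alpha_m <= 1.0:
            raise ConfigError(f"alpha_m must lie in [0, 1], got {self.alpha_m}")
        if not self.mu_ratio > 0:
            raise ConfigError(f"mu_ratio must be > 0, got {self.mu_ratio}")
        if int(self.m) != self.m or self.m < 2:
            raise ConfigError(f"m must be an integer >= 2, got {self.m}")
        if self.t_div is not None and not self.t_div > 0:
            raise ConfigError(f"t_div must be > 0 where used, got {self.t_div}")
        if not self.theta_S > 0:
            raise ConfigError(f"theta_S must be > 0, got {self.theta_S}")


def harmonic_number(n: int) -> float:
    """H_n = sum_{k=1..n} 1/k (H_0 = 0)."""
    return float(np.sum(1.0 / np.arange(1, n + 1)))


# ---------------------------------------------------------------------------
# sojourn-density integrals
# ---------------------------------------------------------------------------

def _sojourn_ratio(p: np.ndarray, gamma: float) -> np.ndarray:
    """[1 - e^{-gamma(1-p)}] / [1 - e^{-gamma}], overflow-safe for gamma < 0.

    For gamma < 0 the naive form exponentiates +|gamma|; rewriting as
    e^{gamma p} * [1 - e^{gamma(1-p)}] / [1 - e^{gamma}] keeps every exponent
    non-positive.
    """
    if gamma > 0:
        return np.expm1(-gamma * (1.0 - p)) / np.expm1(-gamma)
    g = -gamma  # > 0
    return np.exp(-g * p) * np.expm1(-g * (1.0 - p)) / np.expm1(-g)


def _seg_integrand(p: float, gamma: float, m: int) -> float:
    # finite at both endpoints: -> m as p -> 0, -> 0 as p -> 1
    if p <= 0.0:
        return float(m)
    if p >= 1.0:
        return 0.0
    r = _sojourn_ratio(np.asarray(p), gamma)
    return float(r / (p * (1.0 - p)) * (1.0 - p**m - (1.0 - p) ** m))


def segregating_integral(gamma: float, m: int) -> float:
    """Expected segregating sites per unit mutation influx (theta = 1).

    I(gamma; m) = int_0^1 R(p; gamma)/(p(1-p)) * [1 - p^m - (1-p)^m] dp with
    R the selected sojourn ratio.  At gamma = 0 this is the neutral frequency
    spectrum integral and equals H_{m-1}; for |gamma| below the near-neutral
    threshold a first-order series in gamma is used:
    H_{m-1} + (gamma/2) * (m-1)/(m+1).
    """
    m = int(m)
    if m < 2:
        raise ConfigError(f"m must be >= 2, got {m}")
    if abs(gamma) < NEAR_NEUTRAL:
        return harmonic_number(m - 1) + 0.5 * gamma * (m - 1) / (m + 1)
    val, err = quad(
        _seg_integrand, 0.0, 1.0, args=(gamma, m),
        limit=400, epsabs=1e-13, epsrel=1e-11,
    )
    if not math.isfinite(val) or err > 1e-8 * max(1.0, abs(val)):
        raise NumericalError(
            f"segregating-site quadrature failed: gamma={gamma}, m={m}, "
            f"value={val}, error estimate={err}"
        )
    return val


def _g_integrand(x: float, ne_s: float, n: int) -> float:
    u = 1.0 - x
    arg = ne_s * u
    if abs(arg) < 1e-8:
        fac = 1.0 - 0.5 * arg
    else:
        fac = -math.expm1(-arg) / arg
    return x ** (n - 1) * fac


def g_integral(ne_s: float, n: int) -> float:
    """G(n) = int_0^1 x^{n-1} [1 - e^{-Ne*s(1-x)}]/(Ne*s(1-x)) dx.

    ``ne_s`` is signed: the beneficial integral takes +Ne*s, the deleterious
    one -Ne*s.  As ne_s -> 0 the bracket tends to 1 and G(n) -> 1/n; the
    series branch 1/n - ne_s/(2n(n+1)) is used for |ne_s| below the
    near-neutral threshold.
    """
    n = int(n)
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    if abs(ne_s) < NEAR_NEUTRAL:
        return 1.0 / n - ne_s / (2.0 * n * (n + 1))
    val, err = quad(
        _g_integrand, 0.0, 1.0, args=(ne_s, n),
        limit=400, epsabs=1e-13, epsrel=1e-11,
    )
    if not math.isfinite(val) or err > 1e-8 * max(1.0, abs(val)):
        raise NumericalError(
            f"G-integral quadrature failed: ne_s={ne_s}, n={n}, "
            f"value={val}, error estimate={err}"
        )
    return val


def synonymous_sites_integral(m: int) -> float:
    """Neutral spectrum integral int_0^1 [1 - p^m - (1-p)^m]/p dp.

    Evaluated by adaptive quadrature; analytically equal to H_{m-1}, which the
    test suite asserts.
    """
    m = int(m)

    def f(p: float) -> float:
        if p <= 0.0:
            return float(m)
        return (1.0 - p**m - (1.0 - p) ** m) / p

    val, _ = quad(f, 0.0, 1.0, limit=400, epsabs=1e-13, epsrel=1e-12)
    return val


# --- vectorised composite Gauss-Legendre evaluators ------------------------
# Panels dyadically refined toward both endpoints resolve the boundary layers
# of width ~1/|gamma| that the selected sojourn density develops; validated
# against adaptive quadrature to <1e-10 for |gamma| up to 400 in the tests.

def _panel_edges(levels: int = 12) -> np.ndarray:
    e = {0.0, 0.5, 1.0}
    for j in range(2, levels + 1):
        e.add(2.0**-j)
        e.add(1.0 - 2.0**-j)
    return np.array(sorted(e))

_EDGES = _panel_edges()
_GL_X, _GL_W = np.polynomial.legendre.leggauss(16)
_A, _B = _EDGES[:-1], _EDGES[1:]
_P_NODES = ((_A + _B) / 2)[:, None] + ((_B - _A) / 2)[:, None] * _GL_X[None, :]
_P_NODES = _P_NODES.ravel()
_W_NODES = (((_B - _A) / 2)[:, None] * _GL_W[None, :]).ravel()


def segregating_integral_many(gammas: np.ndarray, m: int) -> np.ndarray:
    """Vectorised I(gamma; m) over an array of gamma values."""
    g = np.atleast_1d(np.asarray(gammas, dtype=float))[:, None]
    p = _P_NODES[None, :]
    with np.errstate(over="ignore"):
        pos = np.expm1(-g * (1.0 - p)) / np.where(g > 0, np.expm1(-g), 1.0)
        ga = np.abs(g)
        neg = np.exp(-ga * p) * np.expm1(-ga * (1.0 - p)) / np.expm1(
            -np.where(g > 0, 1.0, ga)
        )
    r = np.where(g > 0, pos, neg)
    f = r / (p * (1.0 - p)) * (1.0 - p**m - (1.0 - p) ** m)
    out = f @ _W_NODES
    small = np.abs(np.ravel(gammas)) < NEAR_NEUTRAL
    if np.any(small):
        gg = np.atleast_1d(np.asarray(gammas, dtype=float))
        out[small] = harmonic_number(m - 1) + 0.5 * gg[small] * (m - 1) / (m + 1)
    return out


def g_integral_many(ne_s: np.ndarray, n: int) -> np.ndarray:
    """Vectorised G(n) over an array of signed Ne*s values."""
    s = np.atleast_1d(np.asarray(ne_s, dtype=float))[:, None]
    x = _P_NODES[None, :]
    arg = s * (1.0 - x)
    with np.errstate(divide="ignore", invalid="ignore"):
        fac = -np.expm1(-arg) / arg
    fac = np.where(np.abs(arg) < 1e-8, 1.0 - 0.5 * arg, fac)
    f = x ** (n - 1) * fac
    out = f @ _W_NODES
    ss = np.ravel(np.asarray(ne_s, dtype=float))
    small = np.abs(ss) < NEAR_NEUTRAL
    if np.any(small):
        out[small] = 1.0 / n - ss[small] / (2.0 * n * (n + 1))
    return out


# ---------------------------------------------------------------------------
# expected counts and ratios
# ---------------------------------------------------------------------------

def fixation_factor(x: float) -> float:
    """Relative fixation rate x / (1 - e^{-x}); 1 at x = 0, series for small x.

    Deleterious mutations take x < 0, for which this equals |x|/(e^{|x|}-1).
    """
    if abs(x) < NEAR_NEUTRAL:
        return 1.0 + 0.5 * x + x * x / 12.0
    return x / (-math.expm1(-x))


def expected_poly_sites(params: PRFParams) -> tuple[float, float, float]:
    """Expected polymorphic-site counts (n_B, n_D, n_S) in a sample of size m.

    n_S = theta_S * H_{m-1}; n_B and n_D are the beneficial and deleterious
    sojourn integrals at gamma = +/- 4*Ne*s scaled by the nonsynonymous influx
    theta_S * mu_ratio split by alpha_m.
    """
    gamma = 4.0 * params.ne_s
    theta_N = params.theta_S * params.mu_ratio
    n_b = theta_N * params.alpha_m * segregating_integral(gamma, params.m)
    n_d = theta_N * (1.0 - params.alpha_m) * segregating_integral(-gamma, params.m)
    n_s = params.theta_S * harmonic_number(params.m - 1)
    return n_b, n_d, n_s


def pn_ps_expected(params: PRFParams) -> float:
    """(n_B + n_D)/n_S: expected ratio of nonsynonymous to synonymous
    polymorphic-site counts.  theta_S cancels; depends only on alpha_m, Ne*s,
    mu_ratio and the sample size m."""
    n_b, n_d, n_s = expected_poly_sites(params)
    return (n_b + n_d) / n_s


def expected_fixed_sites(params: PRFParams) -> tuple[float, float, float]:
    """Expected fixed-site counts (F_B, F_D, F_S) between two species.

    F_S = theta_S*(t_div + 1/m + 1); the selected classes multiply the
    relative fixation factor at +/-Ne*s by [t_div + G(m) + G(1)].
    """
    if params.t_div is None:
        raise ConfigError("t_div is required for fixed-site expectations")
    x = params.ne_s
    t = params.t_div
    theta_N = params.theta_S * params.mu_ratio
    f_s = params.theta_S * (t + 1.0 / params.m + 1.0)
    f_b = (
        theta_N * params.alpha_m * fixation_factor(x)
        * (t + g_integral(x, params.m) + g_integral(x, 1))
    )
    f_d = (
        theta_N * (1.0 - params.alpha_m) * fixation_factor(-x)
        * (t + g_integral(-x, params.m) + g_integral(-x, 1))
    )
    return f_b, f_d, f_s


def dn_ds_expected(params: PRFParams) -> float:
    """(F_B + F_D)/F_S at finite divergence time; theta_S cancels."""
    f_b, f_d, f_s = expected_fixed_sites(params)
    return (f_b + f_d) / f_s


def pn_ps_ratio(ne_s: float, alpha_m: float, mu_ratio: float, m: int) -> float:
    """pN/pS as a function of a *signed* selection coefficient.

    The beneficial fraction alpha_m takes effect +ne_s, the rest -ne_s; a
    negative ne_s therefore swaps the roles of the two classes, which makes
    the mirror symmetry (alpha_m, s) <-> (1-alpha_m, -s) explicit.
    """
    gamma = 4.0 * ne_s
    num = alpha_m * segregating_integral(gamma, m) + (1.0 - alpha_m) * (
        segregating_integral(-gamma, m)
    )
    return mu_ratio * num / harmonic_number(m - 1)


def dn_ds_ratio_limit(ne_s: float, alpha_m: float, mu_ratio: float) -> float:
    """Divergence-dominated dN/dS for a signed selection coefficient."""
    return mu_ratio * (
        alpha_m * fixation_factor(ne_s) + (1.0 - alpha_m) * fixation_factor(-ne_s)
    )


def dn_ds_ratio(
    ne_s: float, alpha_m: float, mu_ratio: float, m: int, t_div: float
) -> float:
    """Finite-divergence dN/dS for a signed selection coefficient."""
    denom = t_div + 1.0 / m + 1.0
    fb = fixation_factor(ne_s) * (t_div + g_integral(ne_s, m) + g_integral(ne_s, 1))
    fd = fixation_factor(-ne_s) * (t_div + g_integral(-ne_s, m) + g_integral(-ne_s, 1))
    return mu_ratio * (alpha_m * fb + (1.0 - alpha_m) * fd) / denom


def dn_ds_limit(params: PRFParams) -> float:
    """Divergence-dominated limit of dN/dS (t_div >> 1):

    mu_ratio * [alpha_m * x/(1-e^{-x}) + (1-alpha_m) * (-x)/(1-e^{x})],
    x = Ne*s; continuous at x = 0 with value mu_ratio.
    """
    x = params.ne_s
    a = params.alpha_m
    return params.mu_ratio * (a * fixation_factor(x) + (1.0 - a) * fixation_factor(-x))


# ---------------------------------------------------------------------------
# Wright-Fisher oracle
# ---------------------------------------------------------------------------

@dataclass
class WFResult:
    """Time-averaged segregating-site counts in samples of size m plus
    cumulative fixation counts from a discrete Wright-Fisher simulation."""

    seg_NB_mean: float
    seg_ND_mean: float
    seg_S_mean: float
    seg_N_se: float
    seg_S_se: float
    ratio_NS: float
    ratio_NS_se: float
    fixations: dict = field(default_factory=dict)
    n_epochs: int = 0
    generations: int = 0

    @property
    def seg_N_mean(self) -> float:
        return self.seg_NB_mean + self.seg_ND_mean


def _wf_select(p: np.ndarray, s: float) -> np.ndarray:
    # additive selection: genotype fitnesses 1, 1+s/2, 1+s
    if s == 0.0:
        return p
    return p * (1.0 + s * p + 0.5 * s * (1.0 - p)) / (1.0 + s * p)


def wf_oracle(
    ne_s: float,
    alpha_m: float,
    mu_N_total: float,
    mu_S_total: float,
    pop_size: int,
    m: int,
    generations: int,
    seed: int,
    burn_in: int | None = None,
    sample_interval: int | None = None,
) -> WFResult:
    """Discrete Wright-Fisher simulation with independent sites.

    Each new mutation founds an independent biallelic site starting at one
    copy out of 2N; selected sites have additive fitness with homozygote
    effect ``s_wf = 2*ne_s/pop_size`` so that the sojourn-density exponent
    matches the polymorphism integrals (gamma = 4*Ne*s with Ne = pop_size).
    Mutation influx per generation is Poisson(2N*mu) per class, with the
    nonsynonymous rate split ``alpha_m : 1-alpha_m`` between beneficial and
    deleterious.  Samples of ``m`` copies are drawn without replacement at
    fixed intervals after burn-in; a site counts as segregating in the sample
    when both alleles appear.  Standard errors come from batch means over
    blocks of sampling epochs.
    """
    rng = np.random.default_rng(seed)
    if pop_size > 200:
        raise ConfigError(
            f"pop_size={pop_size} refused: the oracle is intended for small "
            "populations (<= 200) where diffusion assumptions can be checked "
            "cheaply"
        )
    if mu_N_total > 1.0 or mu_S_total > 1.0:
        raise ConfigError(
            "per-genome mutation rates above 1 per generation refused: "
            "the oracle targets the low-rate regime of the PRF model"
        )
    if not 0.0 <= alpha_m <= 1.0:
        raise ConfigError(f"alpha_m must lie in [0, 1], got {alpha_m}")
    two_n = 2 * pop_size
    s_wf = 2.0 * ne_s / pop_size
    if burn_in is None:
        burn_in = 10 * two_n
    if sample_interval is None:
        sample_interval = two_n

    classes = {
        "B": (s_wf, two_n * mu_N_total * alpha_m),
        "D": (-s_wf, two_n * mu_N_total * (1.0 - alpha_m)),
        "S": (0.0, two_n * mu_S_total),
    }
    counts = {c: np.empty(0, dtype=np.int64) for c in classes}
    fixations = {c: 0 for c in classes}
    epochs: dict[str, list[int]] = {c: [] for c in classes}

    for gen in range(generations):
        for c, (s, lam) in classes.items():
            arr = counts[c]
            n_new = rng.poisson(lam)
            if n_new:
                arr = np.concatenate([arr, np.ones(n_new, dtype=np.int64)])
            if arr.size:
                p = arr / two_n
                arr = rng.binomial(two_n, _wf_select(p, s))
                fixed = arr == two_n
                fixations[c] += int(fixed.sum())
                arr = arr[(arr > 0) & ~fixed]
            counts[c] = arr
        if gen >= burn_in and (gen - burn_in) % sample_interval == 0:
            for c in classes:
                arr = counts[c]
                if arr.size:
                    k = rng.hypergeometric(arr, two_n - arr, m)
                    epochs[c].append(int(np.sum((k > 0) & (k < m))))
                else:
                    epochs[c].append(0)

    n_epochs = len(epochs["S"])
    if n_epochs < 10:
        raise ConfigError(
            f"only {n_epochs} sampling epochs; increase generations "
            f"(burn_in={burn_in}, interval={sample_interval})"
        )
    nb = np.array(epochs["B"], dtype=float)
    nd = np.array(epochs["D"], dtype=float)
    ns = np.array(epochs["S"], dtype=float)
    ntot = nb + nd

    # batch means (blocks of 5 epochs) absorb residual autocorrelation
    block = 5
    nblk = n_epochs // block
    bn = ntot[: nblk * block].reshape(nblk, block).mean(axis=1)
    bs = ns[: nblk * block].reshape(nblk, block).mean(axis=1)
    se_n = float(bn.std(ddof=1) / math.sqrt(nblk))
    se_s = float(bs.std(ddof=1) / math.sqrt(nblk))
    mean_n, mean_s = float(ntot.mean()), float(ns.mean())
    ratio = mean_n / mean_s
    cov = float(np.cov(bn, bs)[0, 1] / nblk)
    var_r = ratio**2 * (
        (se_n / mean_n) ** 2 + (se_s / mean_s) ** 2 - 2.0 * cov / (mean_n * mean_s)
    )
    return WFResult(
        seg_NB_mean=float(nb.mean()),
        seg_ND_mean=float(nd.mean()),
        seg_S_mean=mean_s,
        seg_N_se=se_n,
        seg_S_se=se_s,
        ratio_NS=ratio,
        ratio_NS_se=math.sqrt(max(var_r, 0.0)),
        fixations=dict(fixations),
        n_epochs=n_epochs,
        generations=generations,
    )
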