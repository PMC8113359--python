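"""Synthetic cohorts with planted age-dependent selection.

The generator plants the statistical structure the downstream pipeline is
meant to recover: each gene gets a true REA slope; selection strength maps
log-linearly onto REA (Ne*s = exp(a0 + a1*REA)) and the beneficial fraction
logistically (alpha_m = logistic(c0 + c1*REA)); polymorphic and fixed site
counts are Poisson draws around the forward PRF expectations; and gene age is
an exponential waiting time whose mean follows the lifespan walk's expected
extinction time at the gene's fixation rates.  The default configuration
mirrors a whole-body expression study with three replicate pools at five
adult ages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix
from .errors import ConfigError
from . import prf_model
from .prf_model import harmonic_number

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "generate_paralog_pairs"]


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Expression design: ``ages`` (arbitrary time units) x
    ``n_replicates_per_age`` x ``n_tissues`` samples per gene; log expression
    is baseline + REA*age + noise.  REA slopes are Normal(rea_mean, rea_sd) on
    a standardised scale.  Selection maps: Ne*s = exp(a0 + a1*REA) (always
    positive), alpha_m = logistic(c0 + c1*REA) (always in (0, 1)).
    ``theta_S`` is the per-gene synonymous mutation scale 4*Ne*muS*sites_S;
    ``m`` the population-sample size in gene copies; ``t_div`` the divergence
    time in 2*Ne-generation units.  ``lifespan_k`` and ``age_scale`` control
    the exponential gene-age draw tied to the walk model's expected
    extinction time.
    """

    n_genes: int = 2000
    ages: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    n_replicates_per_age: int = 3
    n_tissues: int = 1
    rea_mean: float = 0.0
    rea_sd: float = 1.0
    rea_dist: str = "normal"  # or "uniform" (same mean/sd)
    expr_noise_sd: float = 1.0
    base_expr_mean: float = 5.0
    base_expr_sd: float = 1.5
    tissue_effect_sd: float = 0.0
    a0: float = 0.5
    a1: float = -0.5
    c0: float = -2.0
    c1: float = 1.0
    sites_N: int = 1000
    sites_S: int = 300
    mu_ratio_override: float | None = None
    theta_S: float = 20.0
    m: int = 40
    t_div: float = 10.0
    lifespan_k: int = 10
    fixation_rate_scale: float = 1.0
    age_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("n_genes", self.n_genes >= 1),
            ("ages", len(self.ages) >= 1 and all(a >= 0 for a in self.ages)),
            ("n_replicates_per_age", self.n_replicates_per_age >= 1),
            ("n_tissues", self.n_tissues >= 1),
            ("rea_sd", self.rea_sd >= 0),
            ("rea_dist", self.rea_dist in ("normal", "uniform")),
            ("expr_noise_sd", self.expr_noise_sd >= 0),
            ("sites_N", self.sites_N >= 1),
            ("sites_S", self.sites_S >= 1),
            ("theta_S", self.theta_S > 0),
            ("m", self.m >= 2),
            ("t_div", self.t_div > 0),
            ("lifespan_k", self.lifespan_k >= 1),
            ("fixation_rate_scale", self.fixation_rate_scale > 0),
            ("age_scale", self.age_scale > 0),
            ("mu_ratio_override",
             self.mu_ratio_override is None or self.mu_ratio_override > 0),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigError(f"invalid CohortConfig field: {name}")

    @property
    def mu_ratio(self) -> float:
        if self.mu_ratio_override is not None:
            return self.mu_ratio_override
        return self.sites_N / self.sites_S

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown CohortConfig fields: {sorted(unknown)}")
        if "ages" in d:
            d = {**d, "ages": tuple(d["ages"])}
        return cls(**d)


@dataclass
class SyntheticCohort:
    """Generator output: observables plus the planted truth (one row per
    gene, keyed by gene_id, columns prefixed ``truth_``)."""

    expression: ExpressionMatrix
    genes: pd.DataFrame
    truth: pd.DataFrame


def _draw_rea(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.rea_dist == "normal":
        return rng.normal(cfg.rea_mean, cfg.rea_sd, cfg.n_genes)
    half = cfg.rea_sd * math.sqrt(3.0)
    return rng.uniform(cfg.rea_mean - half, cfg.rea_mean + half, cfg.n_genes)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one cohort; identical config (including seed) gives identical
    output."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")

    rea = _draw_rea(config, rng)
    baseline = rng.normal(config.base_expr_mean, config.base_expr_sd, n)

    sample_ids, ages_col, tissue_col = [], [], []
    for t in range(config.n_tissues):
        for a in config.ages:
            for r in range(config.n_replicates_per_age):
                sample_ids.append(f"t{t}_a{a:g}_r{r}")
                ages_col.append(float(a))
                tissue_col.append(f"tissue{t}")
    n_samples = len(sample_ids)
    ages_arr = np.array(ages_col)
    tissue_idx = np.array([int(s.split("_")[0][1:]) for s in sample_ids])

    tissue_fx = rng.normal(0.0, config.tissue_effect_sd, (n, config.n_tissues)) \
        if config.tissue_effect_sd > 0 else np.zeros((n, config.n_tissues))
    noise = rng.normal(0.0, config.expr_noise_sd, (n, n_samples))
    values = (
        baseline[:, None]
        + rea[:, None] * ages_arr[None, :]
        + tissue_fx[:, tissue_idx]
        + noise
    )
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        samples=pd.DataFrame(
            {"age": ages_arr, "tissue": tissue_col},
            index=pd.Index(sample_ids, name="sample_id"),
        ),
    )

    # planted selection parameters (Ne*s > 0 and alpha_m in (0,1) by construction)
    ne_s = np.exp(config.a0 + config.a1 * rea)
    alpha_m = 1.0 / (1.0 + np.exp(-(config.c0 + config.c1 * rea)))
    mu_ratio = config.mu_ratio
    theta_n = config.theta_S * mu_ratio
    h = harmonic_number(config.m - 1)

    # polymorphism: Poisson counts around the PRF expectations
    seg_b = prf_model.segregating_integral_many(4.0 * ne_s, config.m)
    seg_d = prf_model.segregating_integral_many(-4.0 * ne_s, config.m)
    n_n_exp = theta_n * (alpha_m * seg_b + (1.0 - alpha_m) * seg_d)
    n_s_exp = config.theta_S * h
    poly_N = rng.poisson(n_n_exp)
    poly_S = rng.poisson(np.full(n, n_s_exp))

    # divergence: full finite-t_div model
    with np.errstate(over="ignore"):
        fb = np.where(ne_s < prf_model.NEAR_NEUTRAL,
                      1.0 + 0.5 * ne_s, ne_s / (-np.expm1(-ne_s)))
        fd = np.where(ne_s < prf_model.NEAR_NEUTRAL,
                      1.0 - 0.5 * ne_s, ne_s / np.expm1(ne_s))
    gb = prf_model.g_integral_many(ne_s, config.m) + prf_model.g_integral_many(ne_s, 1)
    gd = prf_model.g_integral_many(-ne_s, config.m) + prf_model.g_integral_many(-ne_s, 1)
    t = config.t_div
    f_n_exp = theta_n * (
        alpha_m * fb * (t + gb) + (1.0 - alpha_m) * fd * (t + gd)
    )
    f_s_exp = config.theta_S * (t + 1.0 / config.m + 1.0)
    fix_N = rng.poisson(f_n_exp)
    fix_S = rng.poisson(np.full(n, f_s_exp))
    with np.errstate(divide="ignore", invalid="ignore"):
        dn_ds = np.where(
            fix_S > 0,
            (fix_N / config.sites_N) / (fix_S / config.sites_S),
            np.nan,
        )

    # gene age: exponential waiting time around the walk model's expected
    # extinction time (small-alpha form, finite for every alpha < 1) at the
    # gene's beneficial/deleterious fixation rates
    r_b = config.fixation_rate_scale * mu_ratio * alpha_m * fb
    r_d = config.fixation_rate_scale * mu_ratio * (1.0 - alpha_m) * fd
    total = r_b + r_d
    alpha_walk = r_b / total
    t_bar = (config.lifespan_k / total) * (1.0 + 2.0 * alpha_walk)
    gene_age = rng.exponential(config.age_scale * t_bar)

    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "poly_N": poly_N,
            "poly_S": poly_S,
            "sites_N": config.sites_N,
            "sites_S": config.sites_S,
            "fix_N": fix_N,
            "fix_S": fix_S,
            "dn_ds": dn_ds,
            "gene_age": gene_age,
        }
    ).reset_index(drop=True)

    site_ratio = config.sites_N / config.sites_S
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "truth_rea": rea,
            "truth_ne_s": ne_s,
            "truth_alpha_m": alpha_m,
            # per-site scale, matching the downstream observable
            "truth_pnps_expected": (n_n_exp / n_s_exp) / site_ratio,
            "truth_dnds_expected": (f_n_exp / f_s_exp) / site_ratio,
            "truth_t_bar": t_bar,
            "truth_gene_age": gene_age,
        }
    ).reset_index(drop=True)
    return SyntheticCohort(expression=expr, genes=genes, truth=truth)


def generate_paralog_pairs(
    config: CohortConfig, n_pairs: int, cohort: SyntheticCohort | None = None
) -> pd.DataFrame:
    """Draw disjoint gene pairs with differing REA from a generated cohort.

    Each row carries both members' estimated REA, mean log expression, pn_ps,
    dn_ds and gene age (columns suffixed ``_a``/``_b``); downstream contrasts
    re-orient pairs by ascending gene id, so the draw order here is
    immaterial.
    """
    if n_pairs < 1:
        raise ConfigError(f"n_pairs must be >= 1, got {n_pairs}")
    if cohort is None:
        cohort = generate_cohort(config)
    n = config.n_genes
    if n_pairs > n // 2:
        raise ConfigError(
            f"n_pairs={n_pairs} exceeds the {n // 2} disjoint pairs available "
            f"from {n} genes"
        )
    from .gene_metrics import add_pnps_column, compute_rea_table

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    order = rng.permutation(n)
    genes = add_pnps_column(cohort.genes)
    rea = compute_rea_table(cohort.expression).to_numpy()
    mean_expr = cohort.expression.values.mean(axis=1).to_numpy()

    ia = order[0 : 2 * n_pairs : 2]
    ib = order[1 : 2 * n_pairs : 2]
    cols = {"gene_a": genes["gene_id"].to_numpy()[ia],
            "gene_b": genes["gene_id"].to_numpy()[ib]}
    stats = {
        "rea": rea,
        "mean_expr": mean_expr,
        "pn_ps": genes["pn_ps"].to_numpy(),
        "dn_ds": genes["dn_ds"].to_numpy(),
        "gene_age": genes["gene_age"].to_numpy(),
    }
    for name, arr in stats.items():
        cols[f"{name}_a"] = arr[ia]
        cols[f"{name}_b"] = arr[ib]
    return pd.DataFrame(cols)
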