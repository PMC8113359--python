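"""Per-gene expression-side statistics.

REA (regression of expression on age) is the ordinary least-squares slope of a
gene's log expression on sample age: positive means the gene is expressed most
strongly late in life.  The module also computes the age of maximum expression
(an alternative age-of-expression metric), the tissue-specificity index tau,
the observed pN/pS ratio from per-gene site counts, the early/late percentile
classes of REA, and the proportional early-vs-late contrast in dN/dS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix
from .errors import ConfigError, UndefinedStatisticError, ValidationError

__all__ = [
    "AgeClassLabels",
    "compute_rea",
    "compute_rea_table",
    "age_of_max_expression",
    "compute_tau",
    "compute_pnps",
    "add_pnps_column",
    "classify_age_groups",
    "delta_r_ns",
]


def compute_rea(matrix: ExpressionMatrix, gene_id: str) -> float:
    """OLS slope of log expression on age across the gene's samples.

    Every sample is one point (replicates are not averaged).  Requires
    observations at two or more distinct ages.
    """
    y = matrix.gene(gene_id)
    ages = matrix.ages
    ok = np.isfinite(y) & np.isfinite(ages)
    y, ages = y[ok], ages[ok]
    if np.unique(ages).size < 2:
        raise UndefinedStatisticError(
            f"REA undefined for {gene_id}: observations at fewer than 2 ages"
        )
    a = ages - ages.mean()
    return float(a @ (y - y.mean()) / (a @ a))


def compute_rea_table(matrix: ExpressionMatrix) -> pd.Series:
    """Vectorised REA for every gene (all samples must be complete)."""
    ages = matrix.ages
    if np.unique(ages).size < 2:
        raise UndefinedStatisticError("REA undefined: fewer than 2 distinct ages")
    a = ages - ages.mean()
    v = matrix.values.to_numpy(dtype=float)
    slopes = (v - v.mean(axis=1, keepdims=True)) @ a / (a @ a)
    return pd.Series(slopes, index=matrix.gene_ids, name="rea")


def age_of_max_expression(matrix: ExpressionMatrix, gene_id: str) -> float:
    """Age whose mean log expression is largest; ties go to the youngest age."""
    y = matrix.gene(gene_id)
    ages = matrix.ages
    by_age = pd.Series(y).groupby(ages).mean()
    best = by_age.max()
    return float(min(age for age, v in by_age.items() if v == best))


def compute_tau(per_tissue_means: np.ndarray) -> float:
    """Tissue-specificity index tau = sum_i (1 - x_i/x_max) / (N - 1).

    0 for uniform expression, 1 for single-tissue expression; input must be
    non-negative (linear-scale) per-tissue means over N >= 2 tissues.
    """
    x = np.asarray(per_tissue_means, dtype=float)
    if x.size < 2:
        raise ConfigError("tau requires at least 2 tissues")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValidationError("tau requires finite non-negative expression values")
    xmax = x.max()
    if xmax == 0:
        raise UndefinedStatisticError("tau undefined for an all-zero profile")
    return float(np.sum(1.0 - x / xmax) / (x.size - 1))


def compute_pnps(
    poly_N: float, sites_N: float, poly_S: float, sites_S: float
) -> float:
    """(poly_N/sites_N) / (poly_S/sites_S): per-site polymorphism ratio.

    Returns NaN (the undefined flag) when poly_S = 0; downstream analyses
    drop those genes listwise.
    """
    if min(poly_N, poly_S) < 0:
        raise ValidationError("negative polymorphism counts")
    if sites_N <= 0 or sites_S <= 0:
        raise ValidationError("site totals must be positive")
    if poly_S == 0:
        return math.nan
    return (poly_N / sites_N) / (poly_S / sites_S)


def add_pnps_column(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorised pn_ps column for a validated gene table (NaN where
    poly_S = 0)."""
    out = table.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        pnps = (out["poly_N"] / out["sites_N"]) / (out["poly_S"] / out["sites_S"])
    out["pn_ps"] = np.where(out["poly_S"] > 0, pnps, np.nan)
    return out


@dataclass(frozen=True)
class AgeClassLabels:
    """Early/middle/late class labels from the REA percentile rule.

    ``lower_cut`` is the inverse-ECDF (type-1) quantile of the lower
    percentile; ``upper_cut`` is the mirrored type-1 quantile taken from the
    top of the distribution, so the two tails are symmetric.  Ties at a cutoff
    fall in the extreme class.
    """

    labels: pd.Series
    lower_cut: float
    upper_cut: float
    lower_pct: float
    upper_pct: float


def classify_age_groups(
    rea: pd.Series | np.ndarray, lower_pct: float = 10.0, upper_pct: float = 90.0
) -> AgeClassLabels:
    """Label genes early (REA <= lower cutoff), late (>= upper cutoff) or
    middle."""
    if not lower_pct < upper_pct:
        raise ConfigError(
            f"lower percentile ({lower_pct}) must be below upper ({upper_pct})"
        )
    values = pd.Series(rea).astype(float)
    if values.size < 10:
        raise ConfigError(f"need at least 10 genes to form classes, got {values.size}")
    if values.nunique() == 1:
        raise UndefinedStatisticError("all REA values equal; no classes definable")
    x = np.sort(values.to_numpy())
    n = x.size
    lo_idx = max(math.ceil(n * lower_pct / 100.0), 1) - 1
    hi_idx = n - max(math.ceil(n * (100.0 - upper_pct) / 100.0), 1)
    lower_cut, upper_cut = float(x[lo_idx]), float(x[hi_idx])
    if lower_cut >= upper_cut:
        raise UndefinedStatisticError(
            "degenerate REA distribution: class cutoffs coincide"
        )
    labels = pd.Series("middle", index=values.index, name="age_class")
    labels[values <= lower_cut] = "early"
    labels[values >= upper_cut] = "late"
    return AgeClassLabels(
        labels=labels,
        lower_cut=lower_cut,
        upper_cut=upper_cut,
        lower_pct=lower_pct,
        upper_pct=upper_pct,
    )


def delta_r_ns(dn_ds: pd.Series | np.ndarray, classes: AgeClassLabels) -> float:
    """Proportional late-vs-early contrast in mean dN/dS:

    (late mean - early mean) / (half the sum of the class means), bounded in
    [-2, 2] and antisymmetric under swapping the classes.  NaN responses are
    dropped; both classes must remain non-empty with means not both zero.
    """
    values = pd.Series(dn_ds).astype(float)
    lab = classes.labels
    early = values[(lab == "early").to_numpy()].dropna()
    late = values[(lab == "late").to_numpy()].dropna()
    if early.empty or late.empty:
        raise UndefinedStatisticError("empty early or late class")
    e, l = early.mean(), late.mean()
    if e == 0 and l == 0:
        raise UndefinedStatisticError("both class means are zero")
    return float((l - e) / (0.5 * (l + e)))
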