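"""Statistical layer relating REA to molecular-evolution statistics.

Each evolutionary statistic y is regressed on REA with mean expression (and,
where available, tissue specificity tau) as covariates:

    y_i = b0 + b1*REA_i + b2*mean_expr_i + ... + e_i

The OLS coefficients are descriptive; significance follows the nonparametric
route: a two-sided Spearman rank correlation between the response and REA,
with no multiple-testing correction.  Tables with a ``tissue`` column get
fixed per-tissue intercepts (a fixed-effect stand-in for a tissue random
factor).  Paralog contrasts regress within-pair differences of a statistic on
the within-pair REA difference; binary annotations are tested with Spearman
on the 0/1 indicator and a two-sided Wilcoxon rank-sum on REA between
classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .errors import ConfigError, UndefinedStatisticError, ValidationError

__all__ = [
    "AssociationResult",
    "BinaryAssociation",
    "spearman_test",
    "fit_rea_regression",
    "paralog_contrasts",
    "binary_trait_association",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssociationResult:
    """One response's regression and rank-correlation summary.

    ``coefficients`` maps term names to OLS estimates (b0 = const, b1 = rea,
    b2 = mean_expr, further covariates and per-tissue intercepts by name);
    ``spearman_rho``/``p_value`` are the two-sided Spearman test between the
    response and REA on the rows actually used.
    """

    response: str
    coefficients: dict = field(default_factory=dict)
    spearman_rho: float = np.nan
    p_value: float = np.nan
    n_used: int = 0

    @property
    def b0(self) -> float:
        return self.coefficients.get("const", np.nan)

    @property
    def b1(self) -> float:
        return self.coefficients.get("rea", np.nan)

    @property
    def b2(self) -> float:
        return self.coefficients.get("mean_expr", np.nan)


def spearman_test(x, y) -> tuple[float, float]:
    """Two-sided Spearman rank correlation with midranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 5:
        raise ValidationError(f"need at least 5 paired values, got {x.size}")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise UndefinedStatisticError("Spearman rho undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _check_rank(design: pd.DataFrame) -> None:
    mat = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        guilty = []
        for col in design.columns:
            reduced = design.drop(columns=[col]).to_numpy(dtype=float)
            if np.linalg.matrix_rank(reduced) == rank:
                guilty.append(col)
        raise ValidationError(f"rank-deficient design; collinear columns: {guilty}")


def fit_rea_regression(
    table: pd.DataFrame,
    response: str,
    covariates: tuple[str, ...] | None = None,
) -> AssociationResult:
    """OLS of ``response`` on REA plus covariates, with Spearman significance.

    Default covariates are mean expression plus tau when present; a
    ``tissue`` column adds fixed per-tissue intercepts.  Rows with missing
    values are dropped listwise and the count used is reported.
    """
    if covariates is None:
        covariates = ("mean_expr",) + (("tau",) if "tau" in table.columns else ())
    needed = ["rea", response, *covariates]
    for col in needed:
        if col not in table.columns:
            raise ConfigError(f"column {col!r} not in table")
    use_tissue = "tissue" in table.columns
    cols = needed + (["tissue"] if use_tissue else [])
    data = table[cols].dropna()
    n_dropped = len(table) - len(data)
    if n_dropped:
        log.info("fit_rea_regression(%s): dropped %d rows with missing values",
                 response, n_dropped)
    if len(data) < 10:
        raise ValidationError(
            f"need >= 10 complete rows to fit, got {len(data)}"
        )

    design = pd.DataFrame({"const": 1.0, "rea": data["rea"]}, index=data.index)
    for cov in covariates:
        design[cov] = data[cov]
    if use_tissue:
        dummies = pd.get_dummies(data["tissue"], prefix="tissue", drop_first=True,
                                 dtype=float)
        design = pd.concat([design, dummies], axis=1)
    _check_rank(design)
    fit = sm.OLS(data[response].to_numpy(dtype=float), design).fit()
    rho, p = spearman_test(data[response], data["rea"])
    return AssociationResult(
        response=response,
        coefficients=dict(fit.params),
        spearman_rho=rho,
        p_value=p,
        n_used=len(data),
    )


def paralog_contrasts(
    pairs: pd.DataFrame,
    statistic: str,
    covariates: tuple[str, ...] = ("mean_expr",),
) -> AssociationResult:
    """Regress the within-pair difference of ``statistic`` on the REA
    difference.

    Pairs are re-oriented so gene_a < gene_b by id and differences taken as
    (b - a); the slope is invariant to any per-pair orientation because both
    differences negate together.  Covariates (differences of mean expression
    and, when present, tau) follow the same orientation.
    """
    needed = ["gene_a", "gene_b", "rea_a", "rea_b",
              f"{statistic}_a", f"{statistic}_b"]
    for col in needed:
        if col not in pairs.columns:
            raise ConfigError(f"paralog table lacks column {col!r}")
    covs = tuple(c for c in covariates if f"{c}_a" in pairs.columns) + (
        ("tau",) if "tau_a" in pairs.columns and "tau" not in covariates else ()
    )
    flip = (pairs["gene_a"].astype(str) > pairs["gene_b"].astype(str)).to_numpy()
    sign = np.where(flip, -1.0, 1.0)

    def delta(name: str) -> np.ndarray:
        return sign * (
            pairs[f"{name}_b"].to_numpy(dtype=float)
            - pairs[f"{name}_a"].to_numpy(dtype=float)
        )

    d = pd.DataFrame({"d_rea": delta("rea"), "d_stat": delta(statistic)})
    for c in covs:
        d[f"d_{c}"] = delta(c)
    d = d.dropna()
    if len(d) < 10:
        raise ValidationError(f"need >= 10 complete pairs, got {len(d)}")
    if np.allclose(d["d_rea"], 0.0):
        raise ValidationError("all REA differences are zero")

    design = pd.DataFrame({"const": 1.0, "rea": d["d_rea"]}, index=d.index)
    for c in covs:
        design[c] = d[f"d_{c}"]
    _check_rank(design)
    fit = sm.OLS(d["d_stat"].to_numpy(dtype=float), design).fit()
    rho, p = spearman_test(d["d_stat"], d["d_rea"])
    return AssociationResult(
        response=f"delta_{statistic}",
        coefficients=dict(fit.params),
        spearman_rho=rho,
        p_value=p,
        n_used=len(d),
    )


@dataclass(frozen=True)
class BinaryAssociation:
    """Association between REA and a binary gene annotation."""

    annotation: str
    spearman_rho: float
    spearman_p: float
    wilcoxon_p: float
    binned_fractions: pd.DataFrame
    n_annotated: int
    n_total: int


def binary_trait_association(
    table: pd.DataFrame, annotation: str, n_bins: int = 10
) -> BinaryAssociation:
    """Spearman of the 0/1 annotation indicator against REA, a two-sided
    Wilcoxon rank-sum on REA between classes, and per-bin annotated fractions
    over equal-count REA bins."""
    if annotation not in table.columns:
        raise ConfigError(f"annotation column {annotation!r} not in table")
    data = table[["rea", annotation]].dropna()
    flag = data[annotation].astype(bool).to_numpy()
    rea = data["rea"].to_numpy(dtype=float)
    if flag.all() or not flag.any():
        raise ValidationError(
            f"annotation {annotation!r} has a single class; association undefined"
        )
    rho, rho_p = spearman_test(flag.astype(float), rea)
    w = stats.mannwhitneyu(rea[flag], rea[~flag], alternative="two-sided")
    bins = pd.qcut(pd.Series(rea).rank(method="first"), n_bins, labels=False)
    binned = (
        pd.DataFrame({"bin": bins, "rea": rea, "flag": flag.astype(float)})
        .groupby("bin")
        .agg(rea_mean=("rea", "mean"), fraction=("flag", "mean"), n=("flag", "size"))
        .reset_index()
    )
    return BinaryAssociation(
        annotation=annotation,
        spearman_rho=rho,
        spearman_p=rho_p,
        wilcoxon_p=float(w.pvalue),
        binned_fractions=binned,
        n_annotated=int(flag.sum()),
        n_total=len(data),
    )
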