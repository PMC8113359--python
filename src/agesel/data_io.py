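"""Readers and writers for the tabular formats shared across the package.

All tables are UTF-8 TSV with a header row and ``NA`` for missing values:

``expression.tsv``
    genes x samples matrix of (log) expression; first column is the gene id.
``samples.tsv``
    one row per sample id with an ``age`` column and optional ``tissue`` and
    ``sex`` columns.
``genes.tsv``
    one row per gene: required columns ``gene_id``, ``poly_N``, ``poly_S``,
    ``sites_N``, ``sites_S``; any further columns (rea, dn_ds, gene_age,
    annotations, ...) are preserved untouched.
``paralogs.tsv``
    one row per pair: ``gene_a``, ``gene_b`` plus per-member statistic columns
    suffixed ``_a``/``_b``.
``annotation.txt``
    one gene id per line, ``#`` comments allowed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_table",
    "write_gene_table",
    "validate_gene_table",
    "read_paralog_table",
    "write_paralog_table",
    "read_annotation_list",
]

GENE_TABLE_REQUIRED = ("gene_id", "poly_N", "poly_S", "sites_N", "sites_S")
_FLOAT_FMT = "%.17g"  # full round-trip precision for the write->read identity


@dataclass
class ExpressionMatrix:
    """Log-expression values (genes x samples) with per-sample metadata.

    ``values`` is indexed by gene id with sample ids as columns; ``samples``
    is indexed by sample id and carries at least an ``age`` column.
    ``log_transformed`` records that values are on the (natural) log scale;
    ``pseudocount`` records the offset used if raw counts were transformed on
    load.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    log_transformed: bool = True
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.samples.index]
        if missing:
            raise SchemaError(
                f"samples missing from metadata: {', '.join(map(str, missing))}"
            )
        self.samples = self.samples.loc[list(self.values.columns)]
        if "age" not in self.samples.columns:
            raise SchemaError("sample metadata lacks required 'age' column")
        ages = pd.to_numeric(self.samples["age"], errors="coerce")
        bad = self.samples.index[~np.isfinite(ages) | (ages < 0)]
        if len(bad):
            raise SchemaError(
                f"non-finite or negative age for samples: {', '.join(map(str, bad))}"
            )
        self.samples["age"] = ages.astype(float)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def ages(self) -> np.ndarray:
        return self.samples["age"].to_numpy()

    def gene(self, gene_id: str) -> np.ndarray:
        if gene_id not in self.values.index:
            raise KeyError(f"unknown gene id: {gene_id}")
        return self.values.loc[gene_id].to_numpy(dtype=float)


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True, **kw)


def read_expression_matrix(
    path: str | Path,
    metadata_path: str | Path,
    raw_counts: bool = False,
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """Load an expression matrix and its sample metadata.

    With ``raw_counts=True`` the values are transformed to log(count +
    pseudocount) on load; otherwise they are taken to be log scale already.
    Non-numeric cells raise a parse error naming the row and column.
    """
    values = _read_tsv(path, index_col=0)
    for col in values.columns:
        coerced = pd.to_numeric(values[col], errors="coerce")
        bad = values.index[coerced.isna() & values[col].notna()]
        if len(bad):
            raise SchemaError(
                f"non-numeric expression value at gene {bad[0]!r}, sample {col!r}"
            )
        values[col] = coerced
    samples = _read_tsv(metadata_path, index_col=0)
    samples.index = samples.index.astype(str)
    values.columns = values.columns.astype(str)
    if raw_counts:
        values = np.log(values + pseudocount)
    return ExpressionMatrix(
        values=values, samples=samples, log_transformed=True, pseudocount=pseudocount
    )


def write_expression_matrix(
    em: ExpressionMatrix, path: str | Path, metadata_path: str | Path
) -> None:
    em.values.to_csv(path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT,
                     index_label="gene_id")
    em.samples.to_csv(metadata_path, sep="\t", na_rep="NA",
                      float_format=_FLOAT_FMT, index_label="sample_id")


def validate_gene_table(table: pd.DataFrame) -> pd.DataFrame:
    """Enforce the per-gene count invariants; raise listing offending genes."""
    missing = [c for c in GENE_TABLE_REQUIRED if c not in table.columns]
    if missing:
        raise SchemaError(f"gene table missing required columns: {', '.join(missing)}")
    for col in ("poly_N", "poly_S", "sites_N", "sites_S"):
        if (table[col] < 0).any():
            bad = table.loc[table[col] < 0, "gene_id"].tolist()
            raise ValidationError(f"negative {col} for genes: {', '.join(map(str, bad))}")
    for poly, sites in (("poly_N", "sites_N"), ("poly_S", "sites_S")):
        over = table[poly] > table[sites]
        if over.any():
            bad = table.loc[over, "gene_id"].tolist()
            raise ValidationError(
                f"{poly} exceeds {sites} for genes: {', '.join(map(str, bad))}"
            )
    if "tau" in table.columns:
        tau = table["tau"].dropna()
        if ((tau < 0) | (tau > 1)).any():
            raise ValidationError("tau values outside [0, 1]")
    for col in ("pn_ps", "dn_ds"):
        if col in table.columns and (table[col].dropna() < 0).any():
            raise ValidationError(f"negative {col} values")
    return table


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-gene table; unknown columns are preserved."""
    table = _read_tsv(path)
    table = validate_gene_table(table)
    table["gene_id"] = table["gene_id"].astype(str)
    return table


def write_gene_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_gene_table(table)
    table.to_csv(path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT, index=False)


def read_paralog_table(path: str | Path) -> pd.DataFrame:
    table = _read_tsv(path)
    for col in ("gene_a", "gene_b"):
        if col not in table.columns:
            raise SchemaError(f"paralog table missing required column {col!r}")
    same = table["gene_a"] == table["gene_b"]
    if same.any():
        raise ValidationError(
            f"self-paired rows in paralog table: {table.loc[same, 'gene_a'].tolist()}"
        )
    return table


def write_paralog_table(table: pd.DataFrame, path: str | Path) -> None:
    if (table["gene_a"] == table["gene_b"]).any():
        raise ValidationError("self-paired rows in paralog table")
    table.to_csv(path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT, index=False)


def read_annotation_list(path: str | Path) -> set[str]:
    """Read a one-id-per-line annotation list; de-duplicates, trims whitespace,
    allows ``#`` comments.  An empty result triggers a warning, not an error."""
    ids: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.add(line)
    if not ids:
        warnings.warn(f"annotation list {path} contains no gene ids", stacklevel=2)
    return ids
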