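"""Expression-side metrics for the reference cohort.

Estimates each gene's REA from the expression matrix, adds mean expression
and pN/pS, labels the early/late REA percentile classes, and reports the
early-vs-late dN/dS contrast (the proportional difference statistic).
Requires 01_simulate_cohort.py to have run.
"""

from pathlib import Path

from agesel import data_io
from agesel.gene_metrics import (
    add_pnps_column,
    classify_age_groups,
    compute_rea_table,
    delta_r_ns,
)

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    em = data_io.read_expression_matrix(
        BASE / "cohort" / "expression.tsv", BASE / "cohort" / "samples.tsv"
    )
    genes = data_io.read_gene_table(BASE / "cohort" / "genes.tsv")
    genes = genes.merge(
        compute_rea_table(em).rename("rea"), left_on="gene_id", right_index=True
    )
    genes = genes.merge(
        em.values.mean(axis=1).rename("mean_expr"),
        left_on="gene_id", right_index=True,
    )
    genes = add_pnps_column(genes)

    classes = classify_age_groups(genes.set_index("gene_id")["rea"])
    genes["age_class"] = classes.labels.to_numpy()
    contrast = delta_r_ns(genes.set_index("gene_id")["dn_ds"], classes)

    out = BASE / "genes_metrics.tsv"
    data_io.write_gene_table(genes, out)
    n_early = (genes["age_class"] == "early").sum()
    n_late = (genes["age_class"] == "late").sum()
    print(f"REA classes: {n_early} early (<= {classes.lower_cut:.3f}), "
          f"{n_late} late (>= {classes.upper_cut:.3f})")
    print(f"early/late dN/dS contrast (proportional difference): {contrast:+.4f}")
    print(f"genes with undefined pN/pS: {genes['pn_ps'].isna().sum()}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
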