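"""Generate the reference synthetic cohort.

Plants the study's assumed structure — selection strength declining with the
age of expression (a1 < 0) and the beneficial fraction rising (c1 > 0) — and
writes the expression matrix, gene table, truth table and a paralog-pair
table under results/cohort/.
"""

from pathlib import Path

from agesel import data_io
from agesel.synthetic import CohortConfig, generate_cohort, generate_paralog_pairs

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 42


def main() -> None:
    cfg = CohortConfig(seed=SEED)
    cohort = generate_cohort(cfg)
    OUTDIR.mkdir(parents=True, exist_ok=True)
    data_io.write_expression_matrix(
        cohort.expression, OUTDIR / "expression.tsv", OUTDIR / "samples.tsv"
    )
    data_io.write_gene_table(cohort.genes, OUTDIR / "genes.tsv")
    cohort.truth.to_csv(OUTDIR / "truth.tsv", sep="\t", na_rep="NA", index=False)
    pairs = generate_paralog_pairs(cfg, n_pairs=500, cohort=cohort)
    data_io.write_paralog_table(pairs, OUTDIR / "paralogs.tsv")

    print(f"cohort: {cfg.n_genes} genes, {cohort.expression.values.shape[1]} samples")
    print(f"planted maps: Ne*s = exp({cfg.a0} + {cfg.a1}*REA), "
          f"alpha_m = logistic({cfg.c0} + {cfg.c1}*REA)")
    print(f"Ne*s range: [{cohort.truth['truth_ne_s'].min():.3f}, "
          f"{cohort.truth['truth_ne_s'].max():.3f}]")
    print(f"wrote tables to {OUTDIR}")


if __name__ == "__main__":
    main()
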