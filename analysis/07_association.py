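"""Two-stage association mapping and the genome-size model.

Adjusts line means for Wolbachia and inversion karyotypes, runs the
single-variant mixed-model scan against the genomic relationship
matrix, compares inflation of adjusted vs unadjusted scans, runs
gene-based burden and SKAT tests with PC covariates, and regresses
genome size on inversion count.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from common import PANEL_DIR, load_world, out_path

from genarch import association as assoc
from genarch import io
from genarch import relatedness as rel


def main() -> None:
    matrix, panel, reference, outgroup, rec, chrom, lengths = \
        load_world()
    genes = io.read_gff(os.path.join(PANEL_DIR, "genes.gff"))
    y = panel.table["phenotype"]

    adj = assoc.adjust_phenotype(y, panel)
    if adj.dropped_columns:
        print("aliased covariates dropped:", adj.dropped_columns)
    grm = rel.compute_grm(matrix)

    scan = assoc.mixed_model_scan(adj, matrix, grm, maf_min=0.05)
    scan.to_csv(out_path("association", "single_variant.tsv"),
                sep="\t", index=False)
    lam_adj, qq = assoc.qq_inflation(scan.p.to_numpy())
    raw = assoc.AdjustedPhenotype(matrix.line_ids, y.to_numpy(),
                                  y.to_numpy(),
                                  pd.DataFrame(index=matrix.line_ids))
    lam_raw, _ = assoc.qq_inflation(
        assoc.mixed_model_scan(raw, matrix, grm,
                               maf_min=0.05).p.to_numpy())
    qq.to_csv(out_path("association", "qq_adjusted.tsv"), sep="\t",
              index=False)
    thr = assoc.bonferroni(scan.p.to_numpy())
    print(f"single-variant scan: {len(scan)} variants, "
          f"lambda adjusted {lam_adj:.2f} vs unadjusted {lam_raw:.2f}")
    print(f"Bonferroni 0.05 threshold {thr:.2e}; "
          f"{int((scan.p < thr).sum())} variants pass "
          f"(polygenic-only phenotype: expect ~0)")

    # PC covariates: the components with Tracy-Widom p < 0.01
    common = matrix.take_variants(matrix.minor_allele_freq() >= 0.05)
    pca = rel.pca(common, n_components=11)
    n_pc = max(1, rel.n_significant_components(pca, alpha=0.01))
    covs = np.column_stack([
        assoc.covariate_design(panel).to_numpy(float),
        pca.components[:, :n_pc]])
    print(f"gene tests with {n_pc} PC covariates "
          f"+ Wolbachia + inversions")
    rows = []
    for gene in genes:
        for stratum in ("all", "common", "rare"):
            b = assoc.burden_test(matrix, gene, y.to_numpy(), covs,
                                  stratum=stratum)
            s = assoc.skat_test(matrix, gene, y.to_numpy(), covs,
                                stratum=stratum)
            for r in (b, s):
                if r is not None:
                    rows.append((r.gene_id, r.test, r.stratum,
                                 r.n_variants, r.statistic, r.p))
    gene_df = pd.DataFrame(rows, columns=["gene_id", "test", "stratum",
                                          "n_variants", "statistic",
                                          "p"])
    gene_df.to_csv(out_path("association", "gene_tests.tsv"), sep="\t",
                   index=False)
    n_genes = gene_df.gene_id.nunique()
    gthr = 0.05 / n_genes
    hits = gene_df[gene_df.p < gthr]
    print(f"gene-based tests on {n_genes} genes x 3 strata: "
          f"{len(hits)} Bonferroni hits at {gthr:.1e}")

    gs = assoc.genome_size_model(
        panel.table["genome_size_mb"], panel.inversion_count(),
        pd.read_csv(os.path.join(PANEL_DIR,
                                 "genome_size_replicates.tsv"),
                    sep="\t"))
    print(f"genome size ~ inversion count: b = {gs['b']:.2f} Mb "
          f"(planted -0.5), F(1,{gs['df'][1]}) = {gs['F']:.2f}, "
          f"p = {gs['p']:.4f}; among-line ANOVA F = "
          f"{gs['anova_F']:.1f} (p = {gs['anova_p']:.2g})")
    with open(out_path("association", "genome_size_model.tsv"),
              "w") as fh:
        fh.write("b\tF\tp\tanova_F\tanova_p\n")
        fh.write(f"{gs['b']}\t{gs['F']}\t{gs['p']}\t{gs['anova_F']}\t"
                 f"{gs['anova_p']}\n")


if __name__ == "__main__":
    main()
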