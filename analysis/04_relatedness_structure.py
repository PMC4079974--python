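"""Genomic relatedness and population structure.

VanRaden relationship matrix from common variants, the pair-relatedness
histogram and threshold bookkeeping, LD pruning, and PCA with and
without the major-inversion regions, with Tracy-Widom significance of
the leading eigenvalues.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from common import load_world, out_path

from genarch import relatedness as rel

EXCLUDE = [("2L", 38_000, 162_000), ("2R", 88_000, 182_000),
           ("3R", 58_000, 242_000)]


def main() -> None:
    matrix, panel, reference, outgroup, rec, chrom, lengths = \
        load_world()

    grm = rel.compute_grm(matrix)
    grm.to_frame().to_csv(out_path("relatedness", "grm.tsv"), sep="\t")
    summary = rel.relatedness_summary(grm)
    summary.to_csv(out_path("relatedness", "pair_summary.tsv"),
                   sep="\t", index=False)
    hist = rel.pair_histogram(grm)
    hist.to_csv(out_path("relatedness", "pair_histogram.tsv"),
                sep="\t", index=False)
    print(f"GRM on {grm.n_lines} lines "
          f"({grm.source}); mean diagonal "
          f"{np.mean(np.diag(grm.values)):.3f}")
    print(summary.to_string(index=False))

    common = matrix.take_variants(matrix.minor_allele_freq() >= 0.05)
    kept = rel.ld_prune(common, window=500, r2_max=0.2)
    pruned = common.take_variants(kept)
    print(f"LD pruning: {common.n_variants} -> {pruned.n_variants} "
          f"variants (r2 < 0.2 in 500-variant windows)")

    kar = panel.karyotype("In(2L)t").to_numpy(float)
    res = rel.pca(pruned)
    res_x = rel.pca(pruned, exclude_regions=EXCLUDE)
    for label, r in (("all variants", res),
                     ("inversions excluded", res_x)):
        cors = [abs(np.corrcoef(r.components[:, k], kar)[0, 1])
                for k in range(3)]
        print(f"PCA ({label}): |corr(PC1..3, In(2L)t karyotype)| = "
              + ", ".join(f"{c:.2f}" for c in cors)
              + f"; TW p(1) = {r.pvalues[0]:.2g}")
    pd.DataFrame({
        "eigenvalue": res.eigenvalues,
        "tw_stat": res.twstats,
        "tw_p": res.pvalues,
    }).to_csv(out_path("relatedness", "tracy_widom.tsv"), sep="\t",
              index=False)
    comp = pd.DataFrame(res.components,
                        index=pd.Index(res.line_ids, name="line_id"),
                        columns=[f"PC{i+1}"
                                 for i in range(res.components.shape[1])])
    comp.to_csv(out_path("relatedness", "pcs.tsv"), sep="\t")
    n_sig = rel.n_significant_components(res, alpha=0.01)
    print(f"significant components at TW p < 0.01: {n_sig}")


if __name__ == "__main__":
    main()
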