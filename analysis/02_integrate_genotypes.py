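"""Cross-caller integration and freeze filtering.

Corrupts the truth panel through seven simulated callers, merges their
lists into a consensus with left-alignment, re-genotypes every line from
combined read counts, applies the freeze filters (site quality >= 500,
depth >= 1, genotype quality >= 20, biallelic non-overlapping), and
checks concordance of two independent noisy re-genotypings the way the
original validation compared sequencing technologies.
"""

from __future__ import annotations

import numpy as np

from common import load_world, out_path

from genarch import integrate as intg
from genarch import simulate as sim
from genarch.types import MISSING

SEED = 20130715


def main() -> None:
    matrix, panel, reference, outgroup, rec, chrom, lengths = \
        load_world()
    rng = np.random.default_rng(SEED + 1)
    profile = sim.CallerErrorProfile(fn_rate=0.05, fp_rate=0.01,
                                     mean_depth=25.0, seq_error=0.01,
                                     missing_rate=0.02)
    callers = sim.emit_caller_outputs(matrix, 7, profile, rng, reference)
    consensus = intg.consensus_variants(callers, matrix.n_lines,
                                        reference)
    print(f"consensus: {len(consensus.variants)} variants "
          f"({matrix.n_variants} true), "
          f"{len(consensus.flagged)} flagged ref conflicts")
    gm = intg.genotype_matrix_from_counts(consensus, matrix.line_ids)
    filtered, report = intg.apply_freeze_filters(gm)
    report.to_csv(out_path("integration", "filter_report.tsv"),
                  sep="\t", index=False)
    print(report.to_string(index=False))
    print(f"freeze: {filtered.n_variants} variants retained")

    # genotype accuracy on shared keys
    truth_keys = {v.key: j for j, v in enumerate(matrix.variants)}
    shared = [(j, truth_keys[v.key])
              for j, v in enumerate(filtered.variants)
              if v.key in truth_keys]
    agree = np.mean([
        np.mean((filtered.calls[:, a] == matrix.calls[:, b])
                | (filtered.calls[:, a] == MISSING))
        for a, b in shared])
    print(f"call agreement on {len(shared)} shared sites "
          f"(missing excluded): {100 * agree:.2f}%")

    # haplotype bins over the consensus non-SNP variants
    bins = intg.build_haplotype_bins(consensus.variants, flank=110)
    n_multi = sum(1 for b in bins if len(b.member_ids) > 1)
    print(f"haplotype bins: {len(bins)} ({n_multi} with >1 member)")

    # technology concordance: two independent noisy count draws per site
    rng2 = np.random.default_rng(SEED + 2)
    n_sites, depth = 2000, 25
    concordant = 0
    for _ in range(n_sites):
        hom_alt = rng2.random() < 0.5
        p_sup = 0.99 if hom_alt else 0.01
        a = rng2.binomial(depth, p_sup)
        b = rng2.binomial(depth, p_sup)
        _, conc = intg.concordance_test((a, depth - a), (b, depth - b))
        concordant += conc
    pct = intg.validation_summary(concordant, n_sites)
    print(f"simulated technology concordance: {concordant}/{n_sites} "
          f"= {pct}%")
    with open(out_path("integration", "concordance.tsv"), "w") as fh:
        fh.write("concordant\ttotal\tpercent\n")
        fh.write(f"{concordant}\t{n_sites}\t{pct}\n")


if __name__ == "__main__":
    main()
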