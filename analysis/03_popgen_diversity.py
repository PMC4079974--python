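"""Population genomics of the panel.

Per-line segregating-site profiles and their association with inversion
heterokaryotypy (the 9% rule); windowed pi, pi_indel and divergence k;
indel polarization against the outgroup with MAF/DAF spectra; variant
clustering around high-MAF focal variants; correlation of diversity with
the recombination map; chromatin-domain enrichment.
"""

from __future__ import annotations

import numpy as np

from common import load_world, out_path

from genarch import popgen

INVERSION_ARMS = {"In(2L)t": "2L", "In(2R)NS": "2R", "In(3R)Mo": "3R"}
INVERSION_REGIONS = {
    "In(2L)t": ("2L", 40_000, 160_000),
    "In(2R)NS": ("2R", 90_000, 180_000),
    "In(3R)Mo": ("3R", 60_000, 240_000),
}


def main() -> None:
    matrix, panel, reference, outgroup, rec, chrom, lengths = \
        load_world()

    prof = popgen.segregating_fraction(matrix)
    prof.to_csv(out_path("popgen", "segregating_profiles.tsv"),
                sep="\t", index=False)
    table, p = popgen.inversion_association(
        prof, panel, INVERSION_ARMS, threshold=9.0,
        autosomes=["2L", "2R", "3L", "3R"])
    print("inversion association (>=9% segregating x heterokaryotypic):")
    print(f"  table {table.tolist()}, Fisher p = {p:.3g}")

    div_snp = popgen.nucleotide_diversity(matrix, lengths, 100_000,
                                          "snp")
    div_indel = popgen.nucleotide_diversity(matrix, lengths, 100_000,
                                            "indel")
    k = popgen.divergence(matrix, outgroup, lengths, 100_000)
    div = div_snp.merge(
        div_indel[["contig", "start", "pi"]].rename(
            columns={"pi": "pi_indel"}), on=["contig", "start"])
    div = div.merge(k[["contig", "start", "k"]], on=["contig", "start"])
    div.to_csv(out_path("popgen", "diversity_windows.tsv"), sep="\t",
               index=False)
    auto = div[div.contig != "X"]
    print(f"pi (autosomes) = {auto.pi.mean():.5f}, "
          f"pi_X = {div[div.contig == 'X'].pi.mean():.5f}, "
          f"pi_indel = {auto.pi_indel.mean():.5f}, "
          f"k = {div.k.mean():.5f}")

    pol = popgen.polarize_variants(matrix, outgroup)
    dels = sum(1 for q in pol if q.derived_type == "deletion")
    ins = sum(1 for q in pol if q.derived_type == "insertion")
    unpol = sum(1 for q in pol if q.status == "unpolarized")
    print(f"polarization: {dels} derived deletions, {ins} insertions "
          f"(ratio {dels / max(ins, 1):.2f}:1), "
          f"{100 * unpol / len(pol):.0f}% unpolarizable")
    maf = popgen.frequency_spectrum(matrix, "minor")
    maf.to_csv(out_path("popgen", "maf_spectrum.tsv"), sep="\t")
    daf = popgen.frequency_spectrum(
        matrix, "derived", polarized=pol,
        classes={q.vid: q.derived_type for q in pol
                 if q.status == "polarized"})
    daf.to_csv(out_path("popgen", "daf_spectrum.tsv"), sep="\t")

    # within/between karyotype diversity per inversion
    rows = []
    for inv, region in INVERSION_REGIONS.items():
        ps, pv, pb = popgen.karyotype_diversity(matrix, panel, inv,
                                                region)
        rows.append((inv, ps, pv, pb))
        print(f"{inv}: pi_std {ps:.5f}, pi_inv {pv:.5f}, "
              f"pi_between {pb:.5f}")
    with open(out_path("popgen", "karyotype_diversity.tsv"), "w") as fh:
        fh.write("inversion\tpi_standard\tpi_inverted\tpi_between\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")

    clust = popgen.variant_clustering(matrix)
    clust.to_csv(out_path("popgen", "variant_clustering.tsv"),
                 sep="\t", index=False)
    carrier = clust[clust.stratum == "carrier"].mean_count.mean()
    noncar = clust[clust.stratum == "noncarrier"].mean_count.mean()
    print(f"clustering around MAF 40-50% focal variants: carrier "
          f"{carrier:.3f} vs non-carrier {noncar:.3f} SNPs/bp-class")

    div10 = popgen.nucleotide_diversity(matrix, lengths, 10_000, "snp")
    rho, prho = popgen.recombination_correlation(div10, rec)
    print(f"Spearman rho(pi, recombination) = {rho:.2f} (p = {prho:.2g})")

    enr = popgen.chromatin_enrichment(matrix, chrom, lengths)
    enr.to_csv(out_path("popgen", "chromatin_enrichment.tsv"),
               sep="\t", index=False)
    print("chromatin folds:",
          {r.domain: round(r.fold, 2) for r in enr.itertuples()})


if __name__ == "__main__":
    main()
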