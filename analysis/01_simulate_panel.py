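"""Simulate the inbred-line panel every later stage analyzes.

Builds the stated world: 205 lines derived by 20 generations of full-sib
inbreeding from a founder population carrying SNPs, deletion-biased
indels (derived deletions 69%), three diverged polymorphic inversions,
an outgroup for polarization, Wolbachia infection at 53% prevalence, and
genome sizes shifted -0.5 Mb per inverted arrangement. Writes the truth
VCF, reference/outgroup FASTA, line metadata, phenotypes, tracks and
gene models under results/panel/.
"""

from __future__ import annotations

import sys

import numpy as np

from common import PANEL_DIR, out_path

from genarch import io
from genarch import simulate as sim
from genarch.types import SEG

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20130715


def main() -> None:
    cfg = sim.SimulationConfig(seed=SEED)
    founders = sim.simulate_founders(cfg)
    matrix, panel = sim.simulate_inbreeding(founders, cfg)

    lengths = {c.name: c.length for c in cfg.contigs}
    io.write_vcf(out_path("panel", "truth.vcf"), matrix, lengths)
    io.write_fasta(out_path("panel", "reference.fa"), founders.reference)
    io.write_fasta(out_path("panel", "outgroup_aligned.fa"),
                   founders.outgroup.aligned)
    with open(out_path("panel", "outgroup_alleles.tsv"), "w") as fh:
        fh.write("vid\toutgroup_allele\n")
        for vid, allele in founders.outgroup.variant_alleles.items():
            fh.write(f"{vid}\t{allele}\n")
    io.write_bed(out_path("panel", "recombination.bed"),
                 founders.recombination_track, "cm_mb")
    io.write_bed(out_path("panel", "chromatin.bed"),
                 founders.chromatin_track, "domain")
    io.write_gff(out_path("panel", "genes.gff"), founders.genes)

    from genarch.relatedness import compute_grm
    grm = compute_grm(matrix)  # polygenic covariance for the phenotypes
    pheno = sim.simulate_phenotypes(panel, grm, cfg, matrix=matrix)
    panel.table["phenotype"] = pheno["phenotype"]
    panel.table["genome_size_mb"] = pheno["genome_size_mb"]
    io.write_panel(out_path("panel", "lines.tsv"), panel)
    reps = sim.genome_size_replicates(pheno, cfg)
    reps.to_csv(out_path("panel", "genome_size_replicates.tsv"),
                sep="\t", index=False)

    n_snp = sum(v.is_snp for v in matrix.variants)
    n_indel = sum(v.is_indel for v in matrix.variants)
    seg = (matrix.calls == SEG).mean(axis=1)
    print(f"panel: {matrix.n_lines} lines, {n_snp} SNPs, "
          f"{n_indel} indels on {len(lengths)} contigs")
    print(f"mean per-line segregating fraction: {seg.mean():.4f} "
          f"(median {np.median(seg):.4f})")
    print(f"Wolbachia prevalence: {panel.wolbachia.mean():.2f}")
    for inv in panel.inversions:
        counts = panel.karyotype(inv).value_counts().to_dict()
        print(f"{inv}: karyotype dosage counts {counts}")
    print(f"wrote panel files to {PANEL_DIR}")


if __name__ == "__main__":
    main()
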