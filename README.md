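# genarch

Genome architecture of an inbred-line reference panel, as a tested,
reusable pipeline on synthetic data.

Panels of fully inbred lines — hundreds of genomes derived from one
natural population by ~20 generations of full-sib mating — are the
workhorse of quantitative genetics: every line is a frozen, replicable
genotype. Analyzing one raises a connected chain of problems: merging
variant calls from many callers into one genotyped freeze; measuring
residual heterozygosity against the inbreeding expectation (full-sib
recurrence F_t = (1 + 2F_{t−1} + F_{t−2})/4 gives F₂₀ = 0.986, so 1.4%
of sites should still segregate); polarizing indels against an outgroup
to expose the deletion-biased mutation spectrum; quantifying how
polymorphic inversions suppress recombination, diverge from the
standard karyotype (π_between > π_within) and dominate relatedness and
principal components; mapping LD decay and the long-range LD of rare
alleles; translating each line's variants into protein-level damage
calls; and running mixed-model association, y = Xb + Zu + e with
Var(u) = Gσ², plus gene-level burden and SKAT tests, adjusted for
*Wolbachia* infection and inversion karyotypes.

`genarch` implements every step as a library (`src/genarch/`), with a
synthetic-panel generator that plants known truth so each estimator can
be tested by parameter recovery, and a sequence of analysis drivers
(`analysis/`) that run the whole arc on one simulated panel. It is for
people who want to study, teach, or stress-test these methods with full
control of the ground truth — not a caller for real BAM files.

## Layout

| Module | What it does |
| --- | --- |
| `genarch.simulate` | founder population, indels/inversions/outgroup, full-sib inbreeding, phenotypes, caller emulation |
| `genarch.integrate` | left-alignment, cross-caller consensus, genotype-from-read-counts, freeze filters, concordance tests |
| `genarch.popgen` | segregating-site profiles, Fisher's exact (log-space), π / π_indel / k in windows, polarization, spectra, clustering, chromatin enrichment |
| `genarch.relatedness` | VanRaden GRM, pair summaries, LD pruning, PCA with Tracy-Widom significance |
| `genarch.linkage` | r² / D′, decay curves, sliding-window LD, long-range high-LD counts |
| `genarch.annotation` | consequence classes, per-line protein reconstruction, global-alignment damage calls, compensatory pairs |
| `genarch.association` | two-stage covariate adjustment, mixed-model scan, burden/SKAT, inflation λ, genome-size model |

## Worked example

```python
import numpy as np
from genarch import simulate as sim, popgen, relatedness as rel

cfg = sim.SimulationConfig(
    n_lines=60,
    contigs=[sim.ContigSpec("2L", 120_000), sim.ContigSpec("2R", 120_000)],
    inversions=[sim.InversionSpec("In(2L)t", "2L", 20_000, 100_000,
                                  karyotype_frequency=0.25,
                                  divergence=0.01)],
    seed=7)
founders = sim.simulate_founders(cfg)
matrix, panel = sim.simulate_inbreeding(founders, cfg)

print(sim.expected_inbreeding(20).final_F)          # 0.9863...
pol = popgen.polarize_variants(matrix, founders.outgroup)
print(round(popgen.derived_deletion_share(pol), 2))  # ~0.69
ps, pv, pb = popgen.karyotype_diversity(
    matrix, panel, "In(2L)t", ("2L", 20_000, 100_000))
print(f"{ps:.4f} {pv:.4f} {pb:.4f}")  # e.g. 0.0033 0.0032 0.0143
```

F₂₀ = 0.986 is the analytic inbreeding coefficient after 20 full-sib
generations. The polarization pipeline recovers the configured derived-
deletion share (0.69, i.e. deletions outnumber insertions ~2.2:1)
because the outgroup carries the ancestral allele. Diversity between
karyotypes (0.0143/bp here) far exceeds diversity within either class —
the inversion is an island of divergence.

Run the full analysis arc (each driver prints its findings and writes
TSVs under `results/`):

```
cd analysis
python 01_simulate_panel.py     # 205-line panel -> results/panel/
python 02_integrate_genotypes.py
python 03_popgen_diversity.py
python 04_relatedness_structure.py
python 05_linkage.py
python 06_annotation_damage.py
python 07_association.py
```

On the default panel, driver 03 reports a derived deletion:insertion
ratio of 2.18:1 with 41% of indels unpolarizable, Spearman ρ = 0.73
between windowed π and the recombination map, and π_between above both
within-karyotype values for all three inversions; driver 07 recovers
the planted genome-size slope (b = −0.48 Mb per inversion against a
planted −0.5) and shows the two-stage adjustment deflating the scan's
inflation factor.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline from scratch at the given seed — simulation,
caller integration and freeze filtering, population-genomic statistics,
relatedness/PCA, LD, damage annotation, and the association stage — and
writes the result JSON to `--out`.
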