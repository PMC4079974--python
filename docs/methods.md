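# Methods

`genarch` re-implements, as a tested pipeline on synthetic data, the
analysis arc of a sequenced inbred-line reference panel: integrated
multi-caller genotyping with freeze-quality filtering, population
genomics of SNPs and indels, inversion karyotype structure, genomic
relatedness and principal components, linkage disequilibrium, protein-
level functional annotation, and two-stage association mapping. This
note records the models, the parameters that matter, and the places
where a design choice was genuinely open.

## The synthetic panel

The generator (`genarch.simulate`) produces the statistical world the
analyses assume, not sequence reads.

**Founder population.** Each contig gets a random reference sequence.
Segregating SNPs arise at `snp_rate` per bp (default 0.01) with founder
allele counts drawn from a neutral 1/i spectrum over
`n_founder_haplotypes` (default 40); the X chromosome uses
`x_effective_size_ratio` (default 3/4) times the autosomal rate, the
standard expectation when males carry one X. Variant placement
probability follows the simulated recombination map (a noisy mid-arm
bump, suppressed toward telomere/centromere ends), which plants the
positive diversity-recombination correlation the analyses then measure
— the generator encodes hitchhiking's *signature*, not its mechanism.

**Indels.** Indels arise at `indel_rate` per bp with a 1–2 bp modal
size distribution and a rare large tail. Each event first draws its
*derived* state: a deletion with probability `deletion_fraction`
(default 0.69, the derived-deletion share corresponding to the observed
~2.2:1 deletion:insertion bias). Because the reference genome is itself
a sample from the population, the reference carries the derived allele
with probability equal to its frequency; when it does, a derived
deletion surfaces in reference coordinates as an "insertion" — this is
what makes reference-based indel labels mislabel a predictable minority
and is why polarization is against the outgroup, not the reference.
Frame-shifting (non-3n) indels falling in coding sequence are retained
with probability `cds_frameshift_depletion` (default 0.2), emulating
purifying selection against frameshifts.

**Outgroup.** The outgroup carries the ancestral allele at every
polarizable site; with probability `unpolarizable_fraction` (default
0.41, matching the fraction of indels the protocol this emulates had to
discard) the outgroup allele matches neither panel allele and the site
is unpolarizable. Background fixed substitutions accumulate at
`outgroup_substitution_rate` (default 0.02) at non-variant positions;
the windowed divergence estimator recovers this rate.

**Inversions.** Each `InversionSpec` assigns founder haplotypes an
orientation at `karyotype_frequency` and plants excess differences
inside the interval at `divergence` per bp. Divergence sites are
strongly but not perfectly karyotype-correlated: each inverted founder
carries a given site with probability 1−U(0, `within_karyotype_
polymorphism`) (default 0.3), with low-rate leakage into standard
haplotypes. Inverted haplotypes are not clones of one another in nature
either; without this within-class polymorphism every divergence site is
in perfect mutual LD and LD pruning collapses the whole inversion to a
single tag, which destroys the PCA phenomenology the real data show.

**Inbreeding.** Each line is founded by two unrelated founder
individuals (four founder haplotypes) whose offspring form the base
full-sib pair; `generations_inbreeding` (default 20) sib matings
follow. This base is what makes the analytic recurrence
F_t = (1 + 2F_{t−1} + F_{t−2})/4, F_0 = F_{−1} = 0 apply, giving
F_20 = 0.986 and an expected 1.4% of initially heterozygous sites still
segregating. Meioses place Poisson(1) crossovers uniformly per contig,
fully suppressed inside an inversion interval when the parent is
heterokaryotypic — so heterokaryotypic lines stay polymorphic across
the whole inverted region, the mechanism behind the "9% segregating
sites" diagnostic. A fraction of lines
(`heterokaryotypic_line_fraction`, default 0.07 ≈ 62/820 observed
line-arm combinations) is conditioned to remain heterokaryotypic,
standing in for balanced inversions still segregating within lines.

**Phenotypes and genome size.** Line means are intercept + Wolbachia
effect + per-inversion dosage effects + a polygenic deviate with
covariance proportional to the genomic relationship matrix + residual
noise. Wolbachia infection is Bernoulli(0.53). Genome size (Mb) is a
base of 175 plus the line's net homozygous indel content, plus
`genome_size_inversion_effect_mb` (default −0.5, the scale of the
reported b = −0.52) per inverted arrangement carried, plus N(0, 1 Mb)
noise; replicate "flow-cytometry" measurements add within-line noise of
1 Mb.

**Caller emulation.** Each of (default) seven callers sees the truth
matrix through a false-negative rate (0.05/variant), adds spurious
variants (0.01 relative rate), and reports supporting/opposing read
counts: depth Poisson(25) per call, supporting reads Binomial with
success probability e, 1−e, or 1/2 for hom-ref, hom-alt and segregating
truth (e = 0.01).

All draws flow from one `numpy.random.Generator`; a seed fully
determines the panel, byte for byte.

## Integration and filtering

Caller lists are normalized by left-alignment against the reference
(trim shared affixes, shift left through repeat tracts) and merged by
(contig, pos, ref, alt); read counts are summed over reporting callers
— the stand-in for re-genotyping each line from combined data. Records
at one position with incompatible reference alleles are flagged, never
merged. Re-genotyping uses a binomial three-state posterior (success
probability e, 1/2, 1−e) with a uniform prior; the genotype call is the
posterior mode, genotype quality is the phred of 1 − max posterior, and
depth 0 is missing. The prior is a declared substitute: the population
genotyper this models does not publish one. Site quality is the summed
phred evidence against hom-ref across covered lines, capped at 9999.
Freeze filters drop sites below quality 500, multiallelic and
overlapping records, and censor calls with depth < 1 or genotype
quality < 20; filtering is idempotent. Technology concordance uses a
two-sided Fisher's exact test on the 2×2 allele-support table,
discordant at nominal p < 0.05.

Fisher's exact test is computed by summing hypergeometric
log-probabilities not exceeding the observed table's (relative slack
1e−7), with `logsumexp`; this stays exact at p ~ 1e−81 where factorial
products underflow.

## Population genomics

Inbred lines are read as single gametes; residual segregating calls are
missing for that line at that site (F ≈ 0.99 makes the haploid reading
the natural convention). Diversity uses the per-site unbiased form
π = Σ [n/(n−1)]·2p(1−p) / L in non-overlapping windows (default 100
kb); π_indel is identical over indel sites, each indel counting once
regardless of length. Whether the original analysis used the n/(n−1)
correction is not stated; it is used here and matters only at small n.
Divergence k counts fixed differences to the outgroup per bp: aligned
substitutions at non-variant positions plus variant sites fixed for the
non-outgroup allele. Polarization is by exact allele match to the
outgroup over the variant footprint — a declared stand-in for the
original's alignment-based protocol, consistent with its ~41% exclusion
rate. Frequency spectra conserve counts by class; DAF exists only for
polarized variants. Variant clustering profiles count SNPs at 1–100 bp
from MAF 40–50% focal variants, stratified by minor-allele-count class
and by presence among carrier vs non-carrier lines. Chromatin
enrichment is fold = density in domain / genome-wide density with a
two-sided binomial test. The 9%/2% segregating thresholds and the MAF
band are configuration defaults, not constants.

## Relatedness and structure

The GRM is VanRaden's G = ZZ′ / (2Σp(1−p)) with Z = M − 2P on 0/2
dosages from common variants (MAF ≥ 0.05, call rate > 0.8), mean-
imputed per variant (the source is silent on missing handling;
mean-imputation preserves the centering), then normalized by the mean
diagonal. Per-chromosome GRMs, weighted by their 2Σp(1−p), recombine to
the genome-wide matrix. LD pruning is greedy drop-the-later-variant
within moving windows of 500 variants at r² < 0.2, sliding over the
retained list and iterated to a fixed point so the constraint holds for
any window of survivors. PCA standardizes by √(2p(1−p)), eigendecomposes
the line covariance, and tests leading eigenvalues with the Tracy-Widom
statistic under the Patterson moments normalization; the TW1 law is
evaluated through Chiani's shifted-gamma approximation (absolute error
~1e−4), a declared approximation in place of tabulated quantiles.

## Linkage disequilibrium

r², D and D′ use the standard haploid definitions with pairwise-
complete lines; r² equals the squared Pearson correlation of the allele
vectors. Decay curves bin intra-arm pairs by distance (subsampled above
a 2×10⁶-pair cap, seeded); the sliding-window track averages r² over
pairs 50–150 bp apart by window midpoint; long-range counts sample up
to 1000 focal variants per minor-allele-count value and count partners
at r² > 0.95 genome-wide and within 1 kb, optionally stratified by
inversion membership. No MAF floor is stated for the decay analysis in
the source; 0.05 is the configurable default.

## Annotation

Toy gene models are transcripts with exons, CDS and strand; internal
exons have length ≡ 0 (mod 3) so exon-skipping isoforms keep frame.
Consequences: 2-bp intron-edge splice sites; non-3n CDS indels are
FRAME_SHIFT; 3n indels CODON_DELETION/INSERTION; SNPs are classified by
codon substitution (START_LOST, STOP_GAINED, STOP_LOST, MISSENSE,
SYNONYMOUS), with UTR/intron/intergenic fallbacks. Six classes are
"potentially damaging". Line-specific damage applies all homozygous-alt
variants right-to-left in the spliced CDS (minus strands reverse-
complemented after application), translates with the standard code to
the first stop, and globally aligns variant to reference protein with
BLOSUM62, gap open 12 / extend 2 (stretcher-like defaults; the source
names the tool, not parameters). Identity = matches / alignment length
including gaps — the gapped denominator is a documented choice, not
asserted authorial intent. A transcript is damaged when start or stop
is lost or identity < 90%; a gene is damaged only if every splice
variant is. Compensatory pairs: frame-restoring indel pairs (each
frameshifting alone, joint length change ≡ 0 mod 3, identical
homozygous carrier sets) and stop-rescuing SNP pairs within one codon
(stop carriers a subset of rescuer carriers); D′ is reported per pair.

## Association

Stage one regresses line means on Wolbachia and inversion dosages
(aliased columns dropped) and keeps residuals + grand mean. Stage two
fits y = Xb + Zu + e with Var(u) = Aσ²_g via the eigen-rotated
single-GRM trick: variance components by maximum likelihood on the null
model (ML chosen for determinism; the source names a program, not an
estimator), then per-variant GLS with a Wald t test (df = n − 2).
Mixed-model p-values on variants that are themselves inside the GRM
deflate (proximal contamination); calibration tests therefore draw the
polygenic term from a GRM built on other variants. Gene windows are the
gene span ± 1 kb (transcript vs gene span is unstated in the source;
gene span chosen). The burden statistic weights each variant by
1/√(p(1−p)/n) on the haploid line count and score-tests the weighted
sum; SKAT uses the unweighted linear kernel Q = r′GG′r with the null
mixture of chi-squares inverted exactly by Imhof's method (Liu
moment-matching as fallback for degenerate spectra). Binary traits use
a logistic null. λ = median(χ²)/0.4549 diagnoses inflation; Bonferroni
is the multiple-testing correction throughout. The genome-size model
regresses line-mean size on inversion count (0–4) and runs a one-way
among-line ANOVA on replicate measurements; the source's Methods
describe the ANOVA response as the within-line standard deviation while
its Results regress mean size — both readings are available
(`genome_size_model` takes any response series), and the regression on
means is what the reported slope refers to.

## What a green test does and does not establish

The generator reproduces the *statistical structure* the analyses
assume: inbreeding decay, deletion bias with frameshift depletion,
karyotype divergence with suppressed recombination, relatedness from
founder sharing, phenotype covariances. It does not simulate reads,
alignment error, transposable elements, demographic history, or real
linkage maps — so green tests establish that the estimators recover
planted truth under the stated model, not that the original study's
genomic counts would be reproduced. Desk scale also changes some
magnitudes: with tens of founder haplotypes, baseline relatedness among
lines is far above the near-zero of a large natural population, and a
kb-scale inversion cannot dominate post-pruning PCA the way a 14-Mb one
does (the structure tests therefore prune at r² < 0.5; the default
threshold remains 0.2).

## Numerical choices

Coordinates are 0-based half-open internally, 1-based in VCF/GFF.
Genotype codes: 0 hom-ref, 1 segregating, 2 hom-alt, −1 missing. Phred
values cap at 9999. Fisher two-sided comparisons use relative slack
1e−7 when testing "no more probable than observed". GRM symmetry is
enforced by averaging with its transpose; PSD is checked to −1e−8.
Degenerate inputs return flagged NaN (zero-callable windows,
monomorphic LD sites, constant regressors raise or flag rather than
silently producing numbers).
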