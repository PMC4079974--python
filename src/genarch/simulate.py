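"""Synthetic inbred-line panel generator.

Emulates a reference panel of ~200 lines derived from one natural
population by 20 generations of full-sib inbreeding: segregating SNPs and
deletion-biased indels (derived deletions outnumber insertions ~2.2:1),
frame-shift depletion inside coding sequence, polymorphic inversions
genetically diverged from the standard karyotype with recombination
suppressed in heterokaryotypes, an outgroup sequence for polarization,
binary Wolbachia infection status, genome sizes perturbed by indel
content and inversions, and line-mean phenotypes with
Wolbachia/inversion/polygenic components.

Every stochastic draw flows from one ``numpy.random.Generator`` seeded by
a single integer, so a seed fully determines the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genes import Gene, cds_intervals, make_toy_genes, patch_reference_for_gene
from .outgroup import OutgroupAlignment
from .types import (
    HOM_ALT,
    HOM_REF,
    MISSING,
    SEG,
    GenotypeMatrix,
    LinePanel,
    RelationshipMatrix,
    VariantRecord,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigError(ValueError):
    pass


# ----------------------------------------------------------------------
# Configuration
# ----------------------------------------------------------------------

@dataclass
class ContigSpec:
    name: str
    length: int
    is_x: bool = False


@dataclass
class InversionSpec:
    """A polymorphic inversion segregating among founder haplotypes.

    ``divergence`` is the per-bp rate of excess fixed differences between
    inverted and standard founder haplotypes inside [start, end);
    recombination in heterokaryotypes is fully suppressed there when
    ``recombination_suppressed``.
    """

    name: str
    arm: str
    start: int
    end: int
    karyotype_frequency: float = 0.15
    divergence: float = 0.008
    recombination_suppressed: bool = True
    # inverted haplotypes are not clones: a divergence site is carried by
    # each inverted founder with probability 1-U(0, wkp), and leaks into
    # standard founders at a low rate, so divergence sites are strongly
    # but not perfectly correlated with the karyotype
    within_karyotype_polymorphism: float = 0.3
    leakage: float = 0.02

    def validate(self, contigs: dict[str, "ContigSpec"]) -> None:
        if self.start >= self.end:
            raise ConfigError(f"{self.name}: start >= end")
        if self.divergence < 0:
            raise ConfigError(f"{self.name}: negative divergence")
        if not 0.0 <= self.karyotype_frequency <= 1.0:
            raise ConfigError(f"{self.name}: frequency outside [0,1]")
        if self.arm not in contigs:
            raise ConfigError(f"{self.name}: unknown arm {self.arm}")
        if self.end > contigs[self.arm].length:
            raise ConfigError(f"{self.name}: interval outside contig")


def _default_contigs() -> list[ContigSpec]:
    return [
        ContigSpec("2L", 300_000),
        ContigSpec("2R", 300_000),
        ContigSpec("3L", 300_000),
        ContigSpec("3R", 300_000),
        ContigSpec("X", 300_000, is_x=True),
    ]


def _default_inversions() -> list[InversionSpec]:
    return [
        InversionSpec("In(2L)t", "2L", 40_000, 160_000,
                      karyotype_frequency=0.15),
        InversionSpec("In(2R)NS", "2R", 90_000, 180_000,
                      karyotype_frequency=0.10),
        InversionSpec("In(3R)Mo", "3R", 60_000, 240_000,
                      karyotype_frequency=0.10),
    ]


def _default_indel_sizes() -> dict[int, float]:
    # 1-2 bp mode with a rare-large tail
    return {1: 0.40, 2: 0.24, 3: 0.12, 4: 0.07, 5: 0.05,
            6: 0.04, 8: 0.03, 10: 0.02, 15: 0.02, 30: 0.01}


@dataclass
class SimulationConfig:
    n_lines: int = 205
    n_founder_haplotypes: int = 40
    contigs: list[ContigSpec] = field(default_factory=_default_contigs)
    snp_rate: float = 0.01
    indel_rate: float = 0.002
    deletion_fraction: float = 0.69
    indel_size_distribution: dict[int, float] = field(
        default_factory=_default_indel_sizes)
    cds_frameshift_depletion: float = 0.2
    inversions: list[InversionSpec] = field(
        default_factory=_default_inversions)
    generations_inbreeding: int = 20
    wolbachia_prevalence: float = 0.53
    phenotype_effects: dict[str, float] = field(
        default_factory=lambda: {"wolbachia": 0.5, "In(2L)t": 0.4,
                                 "In(2R)NS": 0.3, "In(3R)Mo": 0.3})
    polygenic_variance: float = 0.3
    residual_variance: float = 0.5
    genome_size_base_mb: float = 175.0
    genome_size_inversion_effect_mb: float = -0.5
    genome_size_noise_mb: float = 1.0
    genome_size_within_line_sd_mb: float = 1.0
    genome_size_replicates: int = 3
    x_effective_size_ratio: float = 0.75
    unpolarizable_fraction: float = 0.41
    outgroup_substitution_rate: float = 0.02
    heterokaryotypic_line_fraction: float = 0.07
    genes_per_contig: int = 12
    seed: int = 0

    def validate(self) -> None:
        for name in ("snp_rate", "indel_rate", "deletion_fraction",
                     "cds_frameshift_depletion", "wolbachia_prevalence",
                     "unpolarizable_fraction", "outgroup_substitution_rate",
                     "heterokaryotypic_line_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0,1]")
        if self.generations_inbreeding < 0:
            raise ConfigError("negative generations_inbreeding")
        cmap = {c.name: c for c in self.contigs}
        for c in self.contigs:
            if c.length <= 0:
                raise ConfigError(f"contig {c.name}: non-positive length")
        for inv in self.inversions:
            inv.validate(cmap)
        total = sum(self.indel_size_distribution.values())
        if not np.isclose(total, 1.0):
            raise ConfigError("indel size distribution must sum to 1")

    def contig_map(self) -> dict[str, ContigSpec]:
        return {c.name: c for c in self.contigs}


# ----------------------------------------------------------------------
# Full-sib inbreeding expectation
# ----------------------------------------------------------------------

@dataclass
class InbreedingTrajectory:
    generations: int
    F_values: np.ndarray  # F_1 .. F_t

    @property
    def final_F(self) -> float:
        return float(self.F_values[-1]) if self.generations else 0.0

    @property
    def expected_segregating_fraction(self) -> float:
        """Expected fraction of initially heterozygous sites still
        segregating after ``generations`` of full-sib mating."""
        return 1.0 - self.final_F


def expected_inbreeding(generations: int) -> InbreedingTrajectory:
    """Inbreeding coefficient under repeated full-sib mating.

    Recurrence F_t = (1 + 2 F_{t-1} + F_{t-2}) / 4 with F_0 = F_{-1} = 0.
    F_1 = 0.25; F_20 = 0.986 to 3 decimals.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    f_prev2, f_prev1 = 0.0, 0.0
    out = []
    for _ in range(generations):
        f = (1.0 + 2.0 * f_prev1 + f_prev2) / 4.0
        out.append(f)
        f_prev2, f_prev1 = f_prev1, f
    return InbreedingTrajectory(generations, np.array(out))


def fullsib_heterozygosity_mc(
    generations: int, n_loci: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo oracle: fraction of unlinked loci at which an
    individual is still heterozygous after ``generations`` of full-sib
    mating, starting from two unrelated heterozygous founders (4 distinct
    alleles). Expectation: 1 - F_t."""
    a = np.zeros((n_loci, 2), dtype=np.int8)
    b = np.zeros((n_loci, 2), dtype=np.int8)
    a[:, 0], a[:, 1] = 0, 1
    b[:, 0], b[:, 1] = 2, 3
    idx = np.arange(n_loci)
    # founding cross: the base generation is a full-sib pair, so that
    # iteration t realizes the t-th sib mating (F_t recurrence)
    for _g in range(generations + 1):
        children = []
        for _k in range(2):
            ga = a[idx, rng.integers(0, 2, n_loci)]
            gb = b[idx, rng.integers(0, 2, n_loci)]
            children.append(np.stack([ga, gb], axis=1))
        a, b = children
    return float(np.mean(a[:, 0] != a[:, 1]))


# ----------------------------------------------------------------------
# Founder simulation
# ----------------------------------------------------------------------

@dataclass
class FounderSet:
    config: SimulationConfig
    reference: dict[str, str]
    variants_by_contig: dict[str, list[VariantRecord]]
    haplotypes: dict[str, np.ndarray]       # contig -> (n_founders, m) uint8
    inversion_states: dict[str, np.ndarray]  # inversion -> (n_founders,) bool
    outgroup: OutgroupAlignment
    genes: list[Gene]
    recombination_track: pd.DataFrame
    chromatin_track: pd.DataFrame

    @property
    def variants(self) -> list[VariantRecord]:
        out: list[VariantRecord] = []
        for c in self.config.contigs:
            out.extend(self.variants_by_contig[c.name])
        return out

    def truth_derived_type(self, v: VariantRecord) -> str | None:
        """From the recorded ancestral allele: what the derived allele is."""
        if v.ancestral is None:
            return None
        derived = v.alt if v.ancestral == v.ref else v.ref
        if len(derived) < len(v.ancestral):
            return "deletion"
        if len(derived) > len(v.ancestral):
            return "insertion"
        return "substitution"


CHROMATIN_CLASSES = ["YELLOW", "RED", "GREEN", "BLUE", "BLACK"]


def _sfs_counts(n_draws: int, n_hap: int, rng: np.random.Generator
                ) -> np.ndarray:
    """Founder minor/derived allele counts from a neutral 1/i spectrum."""
    i = np.arange(1, n_hap)
    p = (1.0 / i) / np.sum(1.0 / i)
    return rng.choice(i, size=n_draws, p=p)


def _recombination_profile(length: int, rng: np.random.Generator,
                           window: int = 10_000) -> np.ndarray:
    """cM/Mb per window: noisy mid-arm bump, suppressed near both ends
    (telomere/centromere)."""
    n_win = max(1, length // window)
    x = (np.arange(n_win) + 0.5) / n_win
    bump = 4.0 * x * (1.0 - x) + 0.1
    noise = rng.gamma(shape=3.0, scale=1.0, size=n_win)
    return bump * noise


def _weighted_positions(n: int, free: np.ndarray, weights: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Sample n distinct free positions, probability ~ weights."""
    w = np.where(free, weights, 0.0)
    tot = w.sum()
    if tot <= 0 or n == 0:
        return np.empty(0, dtype=np.int64)
    p = w / tot
    n = min(n, int(free.sum()))
    pos = rng.choice(len(free), size=min(len(free), int(n * 1.5) + 10),
                     replace=True, p=p)
    pos = pd.unique(pos)[:n]
    return np.asarray(pos, dtype=np.int64)


def _outgroup_mismatch_allele(ref: str, alt: str, ancestral: str,
                              rng: np.random.Generator) -> str:
    """An outgroup allele matching neither panel allele (unpolarizable)."""
    if len(ancestral) == 1 and len(ref) == 1 == len(alt):
        pool = [b for b in "ACGT" if b != ref and b != alt]
        return str(rng.choice(pool))
    cand = ancestral + str(rng.choice(list("ACGT")))
    if cand in (ref, alt):
        cand = cand + "A"
    return cand


def simulate_founders(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> FounderSet:
    """Generate the natural-population layer: reference and outgroup
    sequences, founder haplotypes carrying SNPs/indels/inversion
    divergence, toy gene models and recombination/chromatin tracks."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_hap = config.n_founder_haplotypes

    reference: dict[str, str] = {}
    aligned_outgroup: dict[str, str] = {}
    variants_by_contig: dict[str, list[VariantRecord]] = {}
    haplotypes: dict[str, np.ndarray] = {}
    inversion_states: dict[str, np.ndarray] = {}
    var_outgroup: dict[str, str] = {}
    var_positions: dict[str, set] = {}
    genes: list[Gene] = []
    rec_rows = []
    chrom_rows = []

    # inversion founder states (resample until both classes have >= 2
    # members so within/between-karyotype contrasts are defined)
    for inv in config.inversions:
        if inv.karyotype_frequency in (0.0, 1.0):
            states = np.full(n_hap, bool(inv.karyotype_frequency))
        else:
            for _ in range(200):
                states = rng.random(n_hap) < inv.karyotype_frequency
                if 2 <= states.sum() <= n_hap - 2:
                    break
        inversion_states[inv.name] = states

    for cs in config.contigs:
        L = cs.length
        seq = bytearray(rng.choice(BASES, size=L).tobytes())

        contig_genes = make_toy_genes(cs.name, L, config.genes_per_contig,
                                      rng)
        for g in contig_genes:
            patch_reference_for_gene(seq, g)
        genes.extend(contig_genes)
        cds = cds_intervals(contig_genes, cs.name)
        cds_mask = np.zeros(L, dtype=bool)
        for s, e in cds:
            cds_mask[s:e] = True

        rec = _recombination_profile(L, rng)
        win = 10_000
        for i, r in enumerate(rec):
            rec_rows.append((cs.name, i * win, min(L, (i + 1) * win),
                             float(r)))
        # per-bp variant placement weight follows local recombination
        rec_bp = np.repeat(rec, win)[:L]
        if len(rec_bp) < L:
            rec_bp = np.pad(rec_bp, (0, L - len(rec_bp)), mode="edge")
        weights = 0.5 + rec_bp / rec_bp.mean()

        # chromatin domains tile the contig
        p0 = 0
        while p0 < L:
            dlen = int(rng.exponential(15_000)) + 2_000
            chrom_rows.append((cs.name, p0, min(L, p0 + dlen),
                               str(rng.choice(CHROMATIN_CLASSES))))
            p0 += dlen

        free = np.ones(L, dtype=bool)
        free[:2] = False
        free[-40:] = False
        records: list[VariantRecord] = []
        carriers: list[np.ndarray] = []

        # ---- indels (placed first: they occupy reference footprints)
        sizes = np.array(sorted(config.indel_size_distribution))
        size_p = np.array([config.indel_size_distribution[s] for s in sizes],
                          dtype=float)
        n_indel = rng.binomial(L, config.indel_rate)
        pos_pool = _weighted_positions(int(n_indel * 1.4) + 20, free,
                                       weights, rng)
        counts = _sfs_counts(len(pos_pool), n_hap, rng)
        made = 0
        for pos, cnt in zip(pos_pool, counts):
            if made >= n_indel:
                break
            size = int(rng.choice(sizes, p=size_p))
            if pos + size + 2 >= L or not free[pos:pos + size + 2].all():
                continue
            in_cds = cds_mask[pos:pos + size + 1].any()
            if in_cds and size % 3 != 0:
                if rng.random() > config.cds_frameshift_depletion:
                    continue
            derived_is_deletion = rng.random() < config.deletion_fraction
            ref_is_derived = rng.random() < cnt / n_hap
            anchor = chr(seq[pos])
            present = bytes(seq[pos + 1: pos + 1 + size]).decode()
            absent_extra = "".join(rng.choice(list("ACGT"), size=size))
            if derived_is_deletion:
                if not ref_is_derived:
                    ref, alt = anchor + present, anchor  # deletion vs ref
                    ancestral, alt_n = ref, cnt
                else:
                    # reference lost the segment: shows as an insertion
                    ref, alt = anchor, anchor + absent_extra
                    ancestral, alt_n = alt, n_hap - cnt
            else:  # derived insertion
                if not ref_is_derived:
                    ref, alt = anchor, anchor + absent_extra
                    ancestral, alt_n = ref, cnt
                else:
                    ref, alt = anchor + present, anchor
                    ancestral, alt_n = alt, n_hap - cnt  # short = ancestral
            rec_v = VariantRecord(cs.name, int(pos), ref, alt,
                                  VariantRecord.classify(ref, alt),
                                  ancestral=ancestral)
            records.append(rec_v)
            car = np.zeros(n_hap, dtype=np.uint8)
            car[rng.choice(n_hap, size=alt_n, replace=False)] = 1
            carriers.append(car)
            free[pos: pos + len(ref) + 1] = False
            made += 1

        # ---- SNPs
        rate = config.snp_rate * (config.x_effective_size_ratio
                                  if cs.is_x else 1.0)
        n_snp = rng.binomial(L, rate)
        pos_snp = _weighted_positions(n_snp, free, weights, rng)
        cnt_snp = _sfs_counts(len(pos_snp), n_hap, rng)
        for pos, cnt in zip(pos_snp, cnt_snp):
            refb = chr(seq[pos])
            other = str(rng.choice([b for b in "ACGT" if b != refb]))
            ref_is_derived = rng.random() < cnt / n_hap
            if not ref_is_derived:
                ref, alt, ancestral, alt_n = refb, other, refb, cnt
            else:
                ref, alt, ancestral, alt_n = refb, other, other, n_hap - cnt
            records.append(VariantRecord(cs.name, int(pos), ref, alt,
                                         "snp", ancestral=ancestral))
            car = np.zeros(n_hap, dtype=np.uint8)
            car[rng.choice(n_hap, size=alt_n, replace=False)] = 1
            carriers.append(car)
            free[pos] = False

        # ---- inversion divergence: fixed differences between karyotypes
        for inv in config.inversions:
            if inv.arm != cs.name or inv.divergence == 0:
                continue
            states = inversion_states[inv.name]
            n_div = rng.binomial(inv.end - inv.start, inv.divergence)
            sub_free = free.copy()
            sub_free[:inv.start] = False
            sub_free[inv.end:] = False
            pos_div = _weighted_positions(n_div, sub_free,
                                          np.ones(L), rng)
            for pos in pos_div:
                refb = chr(seq[pos])
                alt = str(rng.choice([b for b in "ACGT" if b != refb]))
                records.append(VariantRecord(cs.name, int(pos), refb, alt,
                                             "snp", ancestral=refb))
                q = 1.0 - rng.uniform(
                    0.0, inv.within_karyotype_polymorphism)
                car = np.where(
                    states,
                    rng.random(n_hap) < q,
                    rng.random(n_hap) < inv.leakage,
                ).astype(np.uint8)
                if car[states].sum() == 0:  # keep the site informative
                    car[np.flatnonzero(states)[0]] = 1
                carriers.append(car)
                free[pos] = False

        order = np.argsort([r.pos for r in records], kind="stable")
        records = [records[i] for i in order]
        hap = (np.stack([carriers[i] for i in order], axis=1)
               if records else np.zeros((n_hap, 0), dtype=np.uint8))
        variants_by_contig[cs.name] = records
        haplotypes[cs.name] = hap.astype(np.uint8)

        # ---- outgroup: ancestral allele at polarizable variant sites,
        # a mismatching allele at unpolarizable ones, plus background
        # fixed substitutions at non-variant positions
        ref_str = seq.decode()
        out_seq = bytearray(seq)
        occupied = set()
        for r in records:
            occupied.update(range(r.pos, r.end))
            anc = r.ancestral
            if rng.random() < config.unpolarizable_fraction:
                og = _outgroup_mismatch_allele(r.ref, r.alt, anc, rng)
            else:
                og = anc
            var_outgroup[r.vid] = og
            # aligned view records only single-base differences
            if len(og) == 1 == len(r.ref) and og != r.ref:
                out_seq[r.pos] = ord(og)
        n_sub = rng.binomial(L, config.outgroup_substitution_rate)
        sub_pos = rng.choice(L, size=n_sub, replace=False)
        for p in sub_pos:
            if int(p) in occupied:
                continue
            cur = chr(out_seq[p])
            out_seq[p] = ord(str(rng.choice(
                [b for b in "ACGT" if b != cur])))
        reference[cs.name] = ref_str
        aligned_outgroup[cs.name] = out_seq.decode()
        var_positions[cs.name] = occupied

    outgroup = OutgroupAlignment(reference, aligned_outgroup,
                                 var_outgroup, var_positions)
    rec_df = pd.DataFrame(rec_rows,
                          columns=["contig", "start", "end", "cm_mb"])
    chrom_df = pd.DataFrame(chrom_rows,
                            columns=["contig", "start", "end", "domain"])
    return FounderSet(config, reference, variants_by_contig, haplotypes,
                      inversion_states, outgroup, genes, rec_df, chrom_df)


# ----------------------------------------------------------------------
# Inbreeding
# ----------------------------------------------------------------------

def _gamete(hapA: np.ndarray, hapB: np.ndarray,
            orientA: dict[str, bool], orientB: dict[str, bool],
            positions: np.ndarray, length: int,
            suppressed: list[tuple[str, int, int]],
            inv_starts: dict[str, int],
            rng: np.random.Generator
            ) -> tuple[np.ndarray, dict[str, bool]]:
    """One meiotic product: Poisson(1) crossovers at uniform positions,
    none inside intervals where the parent is heterokaryotypic."""
    k = rng.poisson(1.0)
    xs = np.sort(rng.uniform(0, length, size=k))
    if suppressed:
        keep = np.ones(len(xs), dtype=bool)
        for _name, s, e in suppressed:
            keep &= ~((xs >= s) & (xs < e))
        xs = xs[keep]
    start = int(rng.integers(0, 2))
    src = (np.searchsorted(xs, positions) + start) % 2
    allele = np.where(src == 0, hapA, hapB)
    orient: dict[str, bool] = {}
    for name in orientA:
        # interval inherited from the haplotype contributing at its start
        # (intact when suppression applies; same-orientation otherwise
        # except for rare discordant recombinants, resolved by the start)
        side = (int(np.searchsorted(xs, inv_starts[name])) + start) % 2
        orient[name] = orientA[name] if side == 0 else orientB[name]
    return allele.astype(np.uint8), orient


def simulate_inbreeding(
    founders: FounderSet,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, LinePanel]:
    """Derive inbred lines by full-sib mating from founder individuals.

    Each line starts from two unrelated founder individuals (4 founder
    haplotypes); a sib pair is propagated ``generations_inbreeding``
    times with on average one crossover per contig per meiosis, fully
    suppressed inside inversion intervals when the parent is
    heterokaryotypic. A designated fraction of lines is kept
    heterokaryotypic for one inversion throughout (mimicking lines in
    which an inversion still segregates).
    """
    config = config or founders.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n_hap = config.n_founder_haplotypes
    contigs = config.contigs
    inv_by_contig: dict[str, list[InversionSpec]] = {}
    inv_starts: dict[str, int] = {}
    for inv in config.inversions:
        inv_by_contig.setdefault(inv.arm, []).append(inv)
        inv_starts[inv.name] = inv.start

    pos_by_contig = {
        c.name: np.array([v.pos for v in founders.variants_by_contig[c.name]],
                         dtype=np.int64)
        for c in contigs
    }

    n_forced = int(round(config.heterokaryotypic_line_fraction
                         * config.n_lines))
    forced_targets = [config.inversions[i % len(config.inversions)].name
                      for i in range(n_forced)] if config.inversions else []

    calls_rows = []
    panel_rows = []
    founder_cols = []
    for li in range(config.n_lines):
        target = forced_targets[li] if li < len(forced_targets) else None
        # founder haplotypes for the two founding individuals
        for _attempt in range(200):
            hidx = rng.choice(n_hap, size=4, replace=False)
            if target is None:
                break
            st = founders.inversion_states[target][hidx]
            # both parents heterokaryotypic -> maintainable
            if st[0] != st[1] and st[2] != st[3]:
                break
        else:
            target = None

        # individuals: per contig (hapA, hapB) allele arrays + orientations
        def founder_ind(i0: int, i1: int):
            ind = {}
            for c in contigs:
                hA = founders.haplotypes[c.name][i0].copy()
                hB = founders.haplotypes[c.name][i1].copy()
                oA = {inv.name: bool(founders.inversion_states[inv.name][i0])
                      for inv in inv_by_contig.get(c.name, [])}
                oB = {inv.name: bool(founders.inversion_states[inv.name][i1])
                      for inv in inv_by_contig.get(c.name, [])}
                ind[c.name] = (hA, hB, oA, oB)
            return ind

        p1 = founder_ind(hidx[0], hidx[1])
        p2 = founder_ind(hidx[2], hidx[3])

        def child(pa, pb):
            kid = {}
            for c in contigs:
                hA, hB, oA, oB = pa[c.name]
                supA = [(i.name, i.start, i.end)
                        for i in inv_by_contig.get(c.name, [])
                        if i.recombination_suppressed
                        and oA[i.name] != oB[i.name]]
                gA, orA = _gamete(hA, hB, oA, oB, pos_by_contig[c.name],
                                  c.length, supA, inv_starts, rng)
                hA2, hB2, oA2, oB2 = pb[c.name]
                supB = [(i.name, i.start, i.end)
                        for i in inv_by_contig.get(c.name, [])
                        if i.recombination_suppressed
                        and oA2[i.name] != oB2[i.name]]
                gB, orB = _gamete(hA2, hB2, oA2, oB2,
                                  pos_by_contig[c.name], c.length, supB,
                                  inv_starts, rng)
                kid[c.name] = (gA, gB, orA, orB)
            return kid

        def is_het(ind, inv_name):
            for c in contigs:
                _, _, oA, oB = ind[c.name]
                if inv_name in oA:
                    return oA[inv_name] != oB[inv_name]
            return False

        # founding cross first (uncounted): the base generation is a
        # full-sib pair, so g sib matings realize the F_g recurrence
        for _g in range(config.generations_inbreeding + 1):
            for _try in range(60):
                k1, k2 = child(p1, p2), child(p1, p2)
                if target is None or (is_het(k1, target)
                                      and is_het(k2, target)):
                    break
            p1, p2 = k1, k2

        final = p1
        line_calls = []
        kar: dict[str, int] = {}
        for c in contigs:
            gA, gB, oA, oB = final[c.name]
            call = np.full(gA.shape, SEG, dtype=np.int8)
            call[(gA == 0) & (gB == 0)] = HOM_REF
            call[(gA == 1) & (gB == 1)] = HOM_ALT
            line_calls.append(call)
            for inv in inv_by_contig.get(c.name, []):
                kar[inv.name] = int(oA[inv.name]) + int(oB[inv.name])
        calls_rows.append(np.concatenate(line_calls))
        panel_rows.append(kar)
        founder_cols.append(",".join(str(int(h)) for h in hidx))

    calls = np.stack(calls_rows, axis=0)
    line_ids = [f"line_{i:03d}" for i in range(config.n_lines)]
    table = pd.DataFrame(index=pd.Index(line_ids, name="line_id"))
    for inv in config.inversions:
        table[f"kar_{inv.name}"] = [row.get(inv.name, 0)
                                    for row in panel_rows]
    table["wolbachia"] = (rng.random(config.n_lines)
                          < config.wolbachia_prevalence).astype(int)
    table["founders"] = founder_cols
    panel = LinePanel(table, [inv.name for inv in config.inversions])
    matrix = GenotypeMatrix(line_ids, founders.variants, calls)
    return matrix, panel


# ----------------------------------------------------------------------
# Phenotypes and genome size
# ----------------------------------------------------------------------

def simulate_phenotypes(
    panel: LinePanel,
    relationship: RelationshipMatrix | None,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    matrix: GenotypeMatrix | None = None,
) -> pd.DataFrame:
    """Line-mean phenotype and genome size.

    phenotype = intercept + Wolbachia effect + sum of inversion-dosage
    effects + polygenic deviate (covariance ~ relationship) + residual.

    genome size (Mb) = base + net homozygous indel content +
    per-inversion offset * inversion count + noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    ids = panel.line_ids
    n = len(ids)
    if relationship is not None and relationship.line_ids != ids:
        raise KeyError("relationship matrix lines do not match panel lines")

    eff = config.phenotype_effects
    y = np.full(n, eff.get("intercept", 0.0))
    y += eff.get("wolbachia", 0.0) * panel.wolbachia.to_numpy(float)
    for inv in panel.inversions:
        y += eff.get(inv, 0.0) * panel.karyotype(inv).to_numpy(float)
    if relationship is not None and config.polygenic_variance > 0:
        K = relationship.values + 1e-6 * np.eye(n)
        L = np.linalg.cholesky(K)
        y += np.sqrt(config.polygenic_variance) * (L @ rng.standard_normal(n))
    y += np.sqrt(config.residual_variance) * rng.standard_normal(n)

    net_mb = np.zeros(n)
    if matrix is not None:
        delta = np.array([v.length_change for v in matrix.variants],
                         dtype=float)
        hom_alt = (matrix.calls == HOM_ALT).astype(float)
        net_mb = hom_alt @ delta / 1e6
    inv_count = panel.inversion_count().to_numpy(float)
    gsize = (config.genome_size_base_mb + net_mb
             + config.genome_size_inversion_effect_mb * inv_count
             + config.genome_size_noise_mb * rng.standard_normal(n))
    return pd.DataFrame(
        {"phenotype": y, "genome_size_mb": gsize},
        index=pd.Index(ids, name="line_id"),
    )


def genome_size_replicates(
    pheno: pd.DataFrame, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Replicate flow-cytometry-style measurements around each line mean."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    rows = []
    for line_id, mean in pheno["genome_size_mb"].items():
        for r in range(config.genome_size_replicates):
            rows.append((line_id, r,
                         mean + config.genome_size_within_line_sd_mb
                         * rng.standard_normal()))
    return pd.DataFrame(rows, columns=["line_id", "replicate",
                                       "genome_size_mb"])


# ----------------------------------------------------------------------
# Caller emulation
# ----------------------------------------------------------------------

@dataclass
class CallerErrorProfile:
    fn_rate: float = 0.05
    fp_rate: float = 0.01
    mean_depth: float = 25.0
    seq_error: float = 0.01
    missing_rate: float = 0.02


@dataclass
class CallerCalls:
    """One caller's corrupted view of the truth: a variant list with
    per-line supporting/opposing read counts."""
    name: str
    variants: list[VariantRecord]
    support: np.ndarray  # (n_lines, k)
    oppose: np.ndarray


def emit_caller_outputs(
    truth: GenotypeMatrix,
    n_callers: int = 7,
    profile: CallerErrorProfile | None = None,
    rng: np.random.Generator | None = None,
    reference: dict[str, str] | None = None,
) -> list[CallerCalls]:
    """Simulate caller outputs: each caller misses a fraction of true
    variants, adds spurious ones, and reports binomial read support."""
    profile = profile or CallerErrorProfile()
    if rng is None:
        rng = np.random.default_rng(0)
    n_lines, n_var = truth.calls.shape
    p_support = {HOM_REF: profile.seq_error,
                 HOM_ALT: 1.0 - profile.seq_error,
                 SEG: 0.5, MISSING: profile.seq_error}
    out = []
    for c in range(n_callers):
        keep = rng.random(n_var) >= profile.fn_rate
        idx = np.flatnonzero(keep)
        variants = [truth.variants[i] for i in idx]
        calls = truth.calls[:, idx]
        if profile.mean_depth <= 0:
            depth = np.zeros(calls.shape, dtype=np.int64)
        else:
            depth = rng.poisson(profile.mean_depth, size=calls.shape)
        if profile.missing_rate > 0:
            depth[rng.random(calls.shape) < profile.missing_rate] = 0
        probs = np.empty(calls.shape)
        for code, p in p_support.items():
            probs[calls == code] = p
        support = rng.binomial(depth, probs)
        oppose = depth - support

        n_fp = rng.binomial(max(n_var, 1), profile.fp_rate)
        fp_records, fp_sup, fp_opp = [], [], []
        for _ in range(n_fp):
            vt = truth.variants[int(rng.integers(0, n_var))]
            pos = int(rng.integers(50, 10_000_000))
            if reference is not None:
                seq = reference[vt.contig]
                pos = int(rng.integers(2, len(seq) - 2))
                refb = seq[pos]
            else:
                refb = str(rng.choice(list("ACGT")))
            altb = str(rng.choice([b for b in "ACGT" if b != refb]))
            fp_records.append(VariantRecord(vt.contig, pos, refb, altb,
                                            "snp"))
            d = rng.poisson(profile.mean_depth, size=n_lines)
            s = rng.binomial(d, profile.seq_error)
            fp_sup.append(s)
            fp_opp.append(d - s)
        if fp_records:
            variants = variants + fp_records
            support = np.concatenate(
                [support, np.stack(fp_sup, axis=1)], axis=1)
            oppose = np.concatenate(
                [oppose, np.stack(fp_opp, axis=1)], axis=1)
        out.append(CallerCalls(f"caller_{c}", variants, support, oppose))
    return out
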