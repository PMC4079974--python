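"""Functional consequence annotation against toy gene models.

Classifies variants into the usual consequence classes (splice site,
start/stop disruption, frameshift, in-frame codon indels, missense,
synonymous, UTR, intron, intergenic); six classes are "potentially
damaging": SPLICE_SITE_ACCEPTOR, SPLICE_SITE_DONOR, START_LOST,
FRAME_SHIFT, STOP_GAINED, STOP_LOST.

Gene-level damage follows a protein-comparison rule: per line, all
homozygous-alt variants are applied to each transcript, the variant CDS
is translated, and the protein is globally aligned to the reference
protein; the transcript is damaged when the start or stop codon is lost
or the sequence identity falls below 90%. A gene is damaged for a line
only if *every* splice variant is damaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .genes import Gene, Transcript, revcomp
from .linkage import MonomorphicError, ld_pair_from_alleles
from .types import HOM_ALT, GenotypeMatrix, VariantRecord

DAMAGING_CLASSES = frozenset({
    "SPLICE_SITE_ACCEPTOR", "SPLICE_SITE_DONOR", "START_LOST",
    "FRAME_SHIFT", "STOP_GAINED", "STOP_LOST",
})

IDENTITY_THRESHOLD = 90.0


@dataclass
class ConsequenceCall:
    vid: str
    tx_id: str
    consequence: str

    @property
    def damaging(self) -> bool:
        return self.consequence in DAMAGING_CLASSES


# ----------------------------------------------------------------------
# Consequence classification
# ----------------------------------------------------------------------

def _overlaps(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def _codon_of(tx: Transcript, seq: str, genomic_pos: int
              ) -> tuple[int, int, str]:
    """(codon index, offset within codon, reference codon) for a CDS
    base at ``genomic_pos``."""
    cpos = tx.cds_positions()
    where = np.flatnonzero(cpos == genomic_pos)
    if where.size == 0:
        raise ValueError("position not in CDS")
    i = int(where[0])
    ci, off = divmod(i, 3)
    cds = tx.cds_sequence(seq)
    return ci, off, cds[3 * ci: 3 * ci + 3]


def _classify_for_transcript(
    v: VariantRecord, tx: Transcript, seq: str
) -> str | None:
    """Consequence of one variant on one transcript; None if the variant
    does not touch the transcript span."""
    span = tx.span
    if not _overlaps(v.pos, v.end, span[0], span[1]):
        return None
    for s, e, kind in tx.splice_sites():
        if _overlaps(v.pos, v.end, s, e):
            return ("SPLICE_SITE_DONOR" if kind == "donor"
                    else "SPLICE_SITE_ACCEPTOR")
    cds_iv = tx.cds_exon_intervals()
    in_cds = any(_overlaps(v.pos, v.end, s, e) for s, e in cds_iv)
    if in_cds:
        delta = v.length_change
        if delta != 0:
            if delta % 3 != 0:
                return "FRAME_SHIFT"
            return "CODON_DELETION" if delta < 0 else "CODON_INSERTION"
        if v.is_snp:
            ci, _off, codon = _codon_of(tx, seq, v.pos)
            new = _mutated_codon(tx, seq, v)
            n_codons = len(tx.cds_positions()) // 3
            old_is_stop = codon in ("TAA", "TAG", "TGA")
            new_is_stop = new in ("TAA", "TAG", "TGA")
            if ci == 0 and new != "ATG":
                return "START_LOST"
            if old_is_stop and ci == n_codons - 1 and not new_is_stop:
                return "STOP_LOST"
            if new_is_stop and not old_is_stop:
                return "STOP_GAINED"
            aa_old = str(Seq(codon).translate())
            aa_new = str(Seq(new).translate())
            return "MISSENSE" if aa_old != aa_new else "SYNONYMOUS"
        return "MISSENSE"  # MNP inside CDS, same length
    in_exon = any(_overlaps(v.pos, v.end, s, e) for s, e in tx.exons)
    if in_exon:
        cs, ce = tx.cds
        upstream = v.pos < cs
        if tx.strand == "+":
            return "UTR_5" if upstream else "UTR_3"
        return "UTR_3" if upstream else "UTR_5"
    return "INTRON"


def _mutated_codon(tx: Transcript, seq: str, v: VariantRecord) -> str:
    """Reference codon at a SNP position with the alt base substituted,
    in transcript orientation."""
    cpos = tx.cds_positions()
    i = int(np.flatnonzero(cpos == v.pos)[0])
    ci = i // 3
    codon_positions = cpos[3 * ci: 3 * ci + 3]  # transcript order
    out = []
    for p in codon_positions:
        if p == v.pos:
            out.append(v.alt if tx.strand == "+" else revcomp(v.alt))
        else:
            out.append(seq[p] if tx.strand == "+" else revcomp(seq[p]))
    return "".join(out)


def classify_consequence(
    v: VariantRecord, gene: Gene, seq: str
) -> list[ConsequenceCall]:
    """One call per transcript the variant touches; a single INTERGENIC
    call if it touches none."""
    if v.contig != gene.contig:
        raise ValueError(f"variant {v.vid} not on contig of "
                         f"{gene.gene_id}")
    calls = []
    for tx in gene.transcripts:
        c = _classify_for_transcript(v, tx, seq)
        if c is not None:
            calls.append(ConsequenceCall(v.vid, tx.tx_id, c))
    if not calls:
        calls.append(ConsequenceCall(v.vid, gene.gene_id, "INTERGENIC"))
    return calls


def annotate_matrix(
    matrix: GenotypeMatrix, genes: list[Gene],
    reference: dict[str, str],
) -> pd.DataFrame:
    """Consequence calls for every variant against every overlapping
    gene (long format)."""
    by_contig: dict[str, list[Gene]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    rows = []
    for v in matrix.variants:
        hit = False
        for g in by_contig.get(v.contig, []):
            s, e = g.span
            if not _overlaps(v.pos, v.end, s, e):
                continue
            for call in classify_consequence(v, g, reference[v.contig]):
                if call.consequence != "INTERGENIC":
                    hit = True
                    rows.append((v.vid, g.gene_id, call.tx_id,
                                 call.consequence, call.damaging))
        if not hit:
            rows.append((v.vid, "", "", "INTERGENIC", False))
    return pd.DataFrame(rows, columns=["vid", "gene_id", "tx_id",
                                       "consequence", "damaging"])


# ----------------------------------------------------------------------
# Per-line transcript reconstruction and translation
# ----------------------------------------------------------------------

def apply_variants_to_transcript(
    tx: Transcript, seq: str, variants: list[VariantRecord]
) -> str:
    """Variant CDS sequence after applying a line's homozygous variants.

    Variants are applied right-to-left in genomic coordinates inside the
    spliced CDS; minus-strand transcripts are reverse-complemented after
    application. Variants whose footprint crosses a CDS-exon boundary
    are ignored (they cannot be represented in the spliced sequence);
    overlapping variants raise with the conflict listed.
    """
    cds_iv = tx.cds_exon_intervals()
    pieces = [seq[s:e] for s, e in cds_iv]
    offsets = np.cumsum([0] + [len(p) for p in pieces[:-1]])
    spliced = "".join(pieces)

    applicable = []
    for v in variants:
        for (s, e), off in zip(cds_iv, offsets):
            if v.pos >= s and v.end <= e:
                applicable.append((v, int(off + v.pos - s)))
                break
    applicable.sort(key=lambda t: t[1])
    for (va, la), (vb, lb) in zip(applicable, applicable[1:]):
        if la + len(va.ref) > lb:
            raise ValueError(
                f"overlapping variants {va.vid} and {vb.vid}")
    out = spliced
    for v, loc in reversed(applicable):
        if out[loc: loc + len(v.ref)] != v.ref:
            raise ValueError(f"{v.vid}: reference allele mismatch")
        out = out[:loc] + v.alt + out[loc + len(v.ref):]
    return revcomp(out) if tx.strand == "-" else out


def translate(cds: str) -> str:
    """Standard-code translation to the first stop; trailing partial
    codon dropped."""
    if len(cds) < 3:
        raise ValueError("coding sequence shorter than one codon")
    usable = cds[: len(cds) - len(cds) % 3]
    return str(Seq(usable).translate(to_stop=True))


def _has_stop(cds: str) -> bool:
    usable = cds[: len(cds) - len(cds) % 3]
    prot = str(Seq(usable).translate())
    return "*" in prot


_ALIGNER: Align.PairwiseAligner | None = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -12.0
        a.extend_gap_score = -2.0
        _ALIGNER = a
    return _ALIGNER


def global_identity(protein_a: str, protein_b: str) -> float:
    """Percent identity from an end-to-end global alignment (BLOSUM62,
    gap open 12 / extend 2); denominator is the alignment length
    including gaps. Empty input yields 0."""
    if not protein_a or not protein_b:
        return 0.0
    if protein_a == protein_b:
        return 100.0
    aln = _aligner().align(protein_a, protein_b)[0]
    counts = aln.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    return 100.0 * counts.identities / length


# ----------------------------------------------------------------------
# Gene damage
# ----------------------------------------------------------------------

@dataclass
class TranscriptVerdict:
    tx_id: str
    start_lost: bool
    stop_lost: bool
    identity: float

    @property
    def damaged(self) -> bool:
        return (self.start_lost or self.stop_lost
                or self.identity < IDENTITY_THRESHOLD)


@dataclass
class DamageReport:
    line_id: str
    gene_id: str
    verdicts: list[TranscriptVerdict] = field(default_factory=list)

    @property
    def damaged(self) -> bool:
        """Damaged only when every splice variant is affected."""
        return bool(self.verdicts) and all(v.damaged for v in self.verdicts)

    @property
    def identity(self) -> float:
        return min((v.identity for v in self.verdicts), default=100.0)


def gene_damage(
    line_id: str, gene: Gene, matrix: GenotypeMatrix,
    reference: dict[str, str],
) -> DamageReport:
    """Protein-level damage verdict for one line at one gene."""
    li = matrix.line_ids.index(line_id)
    seq = reference[gene.contig]
    span = gene.span
    line_vars = [
        v for j, v in enumerate(matrix.variants)
        if matrix.calls[li, j] == HOM_ALT and v.contig == gene.contig
        and _overlaps(v.pos, v.end, span[0], span[1])
    ]
    report = DamageReport(line_id, gene.gene_id)
    for tx in gene.transcripts:
        ref_cds = tx.cds_sequence(seq)
        ref_prot = translate(ref_cds)
        var_cds = apply_variants_to_transcript(tx, seq, line_vars)
        start_lost = not var_cds.startswith("ATG")
        stop_lost = not _has_stop(var_cds)
        var_prot = translate(var_cds) if len(var_cds) >= 3 else ""
        ident = global_identity(ref_prot, var_prot)
        report.verdicts.append(
            TranscriptVerdict(tx.tx_id, start_lost, stop_lost, ident))
    return report


def damage_scan(
    matrix: GenotypeMatrix, genes: list[Gene],
    reference: dict[str, str],
    line_ids: list[str] | None = None,
) -> list[DamageReport]:
    reports = []
    for lid in line_ids or matrix.line_ids:
        for g in genes:
            reports.append(gene_damage(lid, g, matrix, reference))
    return reports


def damage_summary(reports: list[DamageReport]
                   ) -> tuple[pd.Series, pd.Series, dict]:
    """(lines-per-damaged-gene histogram, damaged-genes-per-line
    histogram, totals)."""
    df = pd.DataFrame(
        [(r.line_id, r.gene_id, r.damaged) for r in reports],
        columns=["line_id", "gene_id", "damaged"])
    per_gene = df[df.damaged].groupby("gene_id").size()
    per_line = df.groupby("line_id")["damaged"].sum()
    totals = {
        "n_damaged_genes": int((per_gene > 0).sum()),
        "mean_damaged_genes_per_line": float(per_line.mean()),
    }
    lines_per_gene = per_gene.value_counts().sort_index()
    genes_per_line = per_line.value_counts().sort_index()
    return lines_per_gene, genes_per_line, totals


# ----------------------------------------------------------------------
# Compensatory pairs
# ----------------------------------------------------------------------

@dataclass
class CompensatoryPair:
    gene_id: str
    vid_a: str
    vid_b: str
    mechanism: str  # frame_restoring_indels | stop_rescuing_snp
    distance: int
    D_prime: float


def _carriers(matrix: GenotypeMatrix, j: int) -> frozenset[str]:
    rows = np.flatnonzero(matrix.calls[:, j] == HOM_ALT)
    return frozenset(matrix.line_ids[i] for i in rows)


def _pair_dprime(matrix: GenotypeMatrix, i: int, j: int) -> float:
    h = matrix.haploid_alleles()
    try:
        _, dprime, _, _ = ld_pair_from_alleles(h[:, i], h[:, j])
        return dprime
    except MonomorphicError:
        return np.nan


def find_compensatory_pairs(
    matrix: GenotypeMatrix, genes: list[Gene],
    reference: dict[str, str],
) -> list[CompensatoryPair]:
    """Frame-restoring indel pairs and premature-stop rescuing SNP pairs.

    Frame pair: two indels in one transcript, each frameshifting alone,
    whose summed length change is a multiple of 3 and whose homozygous
    carrier sets coincide (no line carries one without the other).

    Rescue pair: two SNPs in one codon where one alone creates a
    premature stop but the joint codon does not, and every line carrying
    the stop allele also carries the rescuer.
    """
    vindex = {v.vid: j for j, v in enumerate(matrix.variants)}
    pairs: list[CompensatoryPair] = []
    for gene in genes:
        seq = reference[gene.contig]
        for tx in gene.transcripts:
            cds_iv = tx.cds_exon_intervals()
            in_cds = [
                (j, v) for j, v in enumerate(matrix.variants)
                if v.contig == gene.contig
                and any(v.pos >= s and v.end <= e for s, e in cds_iv)
            ]
            # ---- frame-restoring indels
            shifts = [(j, v) for j, v in in_cds
                      if v.length_change % 3 != 0]
            for a in range(len(shifts)):
                for b in range(a + 1, len(shifts)):
                    ja, va = shifts[a]
                    jb, vb = shifts[b]
                    if (va.length_change + vb.length_change) % 3 != 0:
                        continue
                    ca, cb = _carriers(matrix, ja), _carriers(matrix, jb)
                    if not ca or ca != cb:
                        continue
                    pairs.append(CompensatoryPair(
                        gene.gene_id, va.vid, vb.vid,
                        "frame_restoring_indels",
                        abs(va.pos - vb.pos),
                        _pair_dprime(matrix, ja, jb)))
            # ---- stop-rescuing SNP pairs within one codon
            snps = [(j, v) for j, v in in_cds if v.is_snp]
            cpos = tx.cds_positions()
            codon_of = {int(p): int(i // 3) for i, p in enumerate(cpos)}
            by_codon: dict[int, list[tuple[int, VariantRecord]]] = {}
            for j, v in snps:
                ci = codon_of.get(v.pos)
                if ci is not None:
                    by_codon.setdefault(ci, []).append((j, v))
            for ci, group in by_codon.items():
                if len(group) < 2:
                    continue
                codon_positions = cpos[3 * ci: 3 * ci + 3]
                ref_codon = _codon_string(tx, seq, codon_positions)
                for a in range(len(group)):
                    for b in range(len(group)):
                        if a == b:
                            continue
                        ja, va = group[a]
                        jb, vb = group[b]
                        alone = _codon_apply(tx, seq, codon_positions,
                                             [va])
                        joint = _codon_apply(tx, seq, codon_positions,
                                             [va, vb])
                        if (alone in ("TAA", "TAG", "TGA")
                                and ref_codon not in ("TAA", "TAG", "TGA")
                                and joint not in ("TAA", "TAG", "TGA")):
                            ca = _carriers(matrix, ja)
                            cb = _carriers(matrix, jb)
                            if ca and ca <= cb:
                                pairs.append(CompensatoryPair(
                                    gene.gene_id, va.vid, vb.vid,
                                    "stop_rescuing_snp",
                                    abs(va.pos - vb.pos),
                                    _pair_dprime(matrix, ja, jb)))
    # deduplicate (a gene's transcripts can nominate the same pair twice)
    seen = set()
    unique = []
    for p in pairs:
        key = (p.gene_id, tuple(sorted((p.vid_a, p.vid_b))), p.mechanism)
        if key not in seen:
            seen.add(key)
            unique.append(p)
    return unique


def _codon_string(tx: Transcript, seq: str, positions: np.ndarray) -> str:
    bases = "".join(seq[int(p)] for p in sorted(positions))
    return bases if tx.strand == "+" else revcomp(bases)


def _codon_apply(tx: Transcript, seq: str, positions: np.ndarray,
                 variants: list[VariantRecord]) -> str:
    sub = {v.pos: v.alt for v in variants}
    bases = "".join(sub.get(int(p), seq[int(p)])
                    for p in sorted(positions))
    return bases if tx.strand == "+" else revcomp(bases)
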