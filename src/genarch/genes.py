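"""Toy gene models: transcripts with exons, CDS and strand.

These are deliberately small structures — enough to support consequence
classification (splice sites, frameshifts, stop gain/loss), per-line
transcript reconstruction and protein-level damage calls, without any of
the bookkeeping a full genome annotation needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
STOP_CODONS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class Transcript:
    """One splice variant. Coordinates are 0-based half-open genomic.

    ``exons`` are sorted genomic intervals; ``cds`` is the genomic span of
    the coding region (its spliced length is a multiple of 3). For minus
    strand transcripts the coding sequence is the reverse complement of
    the spliced exonic sequence.
    """

    tx_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: tuple[int, int]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if e0 > s1:
                raise ValueError(f"{self.tx_id}: overlapping exons")

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    def cds_exon_intervals(self) -> list[tuple[int, int]]:
        """Exon pieces intersected with the CDS span, genomic order."""
        cs, ce = self.cds
        out = []
        for s, e in self.exons:
            a, b = max(s, cs), min(e, ce)
            if a < b:
                out.append((a, b))
        return out

    def cds_positions(self) -> np.ndarray:
        """Genomic positions of CDS bases in *transcript* (5'->3') order."""
        pos = np.concatenate(
            [np.arange(s, e) for s, e in self.cds_exon_intervals()]
        )
        return pos[::-1] if self.strand == "-" else pos

    def cds_sequence(self, seq: str) -> str:
        parts = "".join(seq[s:e] for s, e in self.cds_exon_intervals())
        return revcomp(parts) if self.strand == "-" else parts

    def splice_sites(self) -> list[tuple[int, int, str]]:
        """2-bp intron-edge intervals: (start, end, 'donor'|'acceptor').

        Donor = the intron side adjacent to the upstream exon in
        transcript orientation.
        """
        sites = []
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            left = (e0, e0 + 2)   # intron start, genomic
            right = (s1 - 2, s1)  # intron end, genomic
            if self.strand == "+":
                sites.append((*left, "donor"))
                sites.append((*right, "acceptor"))
            else:
                sites.append((*right, "donor"))
                sites.append((*left, "acceptor"))
        return sites


@dataclass
class Gene:
    gene_id: str
    contig: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> tuple[int, int]:
        starts = [t.span[0] for t in self.transcripts]
        ends = [t.span[1] for t in self.transcripts]
        return (min(starts), max(ends))


# ----------------------------------------------------------------------
# Toy gene construction on a random reference
# ----------------------------------------------------------------------

def _patch_codon(seq: bytearray, positions: np.ndarray, strand: str,
                 codon: str) -> None:
    """Write ``codon`` (transcript orientation) at 3 genomic positions."""
    bases = codon if strand == "+" else revcomp(codon)
    pos = positions if strand == "+" else positions[::-1]
    # pos is genomic-ascending order of the codon's bases
    for p, b in zip(sorted(pos), bases):
        seq[p] = ord(b)


def _read_codon(seq: bytearray, positions: np.ndarray, strand: str) -> str:
    bases = "".join(chr(seq[p]) for p in sorted(positions))
    return bases if strand == "+" else revcomp(bases)


def patch_reference_for_gene(seq: bytearray, gene: Gene) -> None:
    """Make the reference a clean ORF for every transcript of ``gene``:
    ATG start, single terminal stop, no internal stops."""
    for tx in gene.transcripts:
        pos = tx.cds_positions()
        n_codons = len(pos) // 3
        _patch_codon(seq, pos[0:3], tx.strand, "ATG")
        for c in range(1, n_codons - 1):
            trip = pos[3 * c: 3 * c + 3]
            codon = _read_codon(seq, trip, tx.strand)
            if codon in STOP_CODONS:
                # swap the wobble base to C: TAA/TAG->TAC, TGA->TGC
                _patch_codon(seq, trip, tx.strand, codon[:2] + "C")
        _patch_codon(seq, pos[-3:], tx.strand, "TAA")


def make_toy_genes(
    contig: str,
    length: int,
    n_genes: int,
    rng: np.random.Generator,
    start_id: int = 0,
) -> list[Gene]:
    """Place non-overlapping toy genes on a contig.

    Internal exons have length divisible by 3 so that an exon-skipping
    second splice variant keeps the reading frame and shares start/stop
    codons with the full transcript.
    """
    genes: list[Gene] = []
    cursor = 500
    for g in range(n_genes):
        n_exons = int(rng.integers(2, 5))
        exon_lens = []
        for i in range(n_exons):
            le = int(rng.integers(150, 600))
            if 0 < i < n_exons - 1:
                le -= le % 3
            exon_lens.append(le)
        intron_lens = [int(rng.integers(80, 400)) for _ in range(n_exons - 1)]
        span = sum(exon_lens) + sum(intron_lens)
        gap = int(rng.integers(400, 1500))
        start = cursor + gap
        if start + span + 500 > length:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        p = start
        for i, le in enumerate(exon_lens):
            exons.append((p, p + le))
            p += le
            if i < n_exons - 1:
                p += intron_lens[i]
        # CDS: inset UTRs inside terminal exons, spliced length % 3 == 0
        utr5 = int(rng.integers(30, min(90, exon_lens[0] - 60)))
        utr3 = int(rng.integers(30, min(90, exon_lens[-1] - 60)))
        cs = exons[0][0] + utr5
        ce = exons[-1][1] - utr3
        spliced = sum(min(e, ce) - max(s, cs)
                      for s, e in exons if max(s, cs) < min(e, ce))
        ce -= spliced % 3
        gid = f"gene_{contig}_{start_id + g:03d}"
        tx1 = Transcript(f"{gid}.t1", contig, strand, exons, (cs, ce))
        transcripts = [tx1]
        if n_exons >= 3 and rng.random() < 0.5:
            keep = list(range(n_exons))
            keep.remove(int(rng.integers(1, n_exons - 1)))
            tx2 = Transcript(
                f"{gid}.t2", contig, strand,
                [exons[i] for i in keep], (cs, ce),
            )
            transcripts.append(tx2)
        genes.append(Gene(gid, contig, transcripts))
        cursor = start + span
    return genes


def cds_intervals(genes: list[Gene], contig: str) -> list[tuple[int, int]]:
    """Merged CDS-exon intervals for one contig (for frameshift thinning)."""
    raw = []
    for g in genes:
        if g.contig != contig:
            continue
        for tx in g.transcripts:
            raw.extend(tx.cds_exon_intervals())
    raw.sort()
    merged: list[tuple[int, int]] = []
    for s, e in raw:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged
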