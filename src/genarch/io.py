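"""File interchange: VCF, FASTA, BED-like tracks, GFF gene models, TSV.

The internal coordinate convention is 0-based half-open; VCF and GFF are
written 1-based as those formats require. VCF genotypes are one sample
per line with GT:DP:GQ; residual segregating calls are emitted as
heterozygous genotypes (0/1).
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genes import Gene
from .types import (
    HOM_ALT,
    HOM_REF,
    MISSING,
    SEG,
    GenotypeMatrix,
    LinePanel,
    VariantRecord,
)

_GT = {HOM_REF: "0/0", HOM_ALT: "1/1", SEG: "0/1", MISSING: "./."}
_GT_INV = {v: k for k, v in _GT.items()}
_GT_INV.update({"0|0": HOM_REF, "1|1": HOM_ALT, "1/0": SEG,
                "0|1": SEG, "1|0": SEG})


def write_vcf(path: str, matrix: GenotypeMatrix,
              contig_lengths: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=genarch\n")
        for contig, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,'
                 'Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                 'Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.line_ids) + "\n")
        has_dp = matrix.depth is not None
        has_gq = matrix.gq is not None
        fmt = "GT" + (":DP" if has_dp else "") + (":GQ" if has_gq else "")
        for j, v in enumerate(matrix.variants):
            fields = []
            for i in range(matrix.n_lines):
                parts = [_GT[int(matrix.calls[i, j])]]
                if has_dp:
                    parts.append(str(int(matrix.depth[i, j])))
                if has_gq:
                    parts.append(str(int(round(float(matrix.gq[i, j])))))
                fields.append(":".join(parts))
            fh.write(
                f"{v.contig}\t{v.pos + 1}\t{v.vid}\t{v.ref}\t{v.alt}\t"
                f"{v.site_quality:.0f}\tPASS\t.\t{fmt}\t"
                + "\t".join(fields) + "\n")


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a one-sample-per-line VCF back into a GenotypeMatrix
    (cyvcf2 when available, plain-text fallback otherwise)."""
    try:
        from cyvcf2 import VCF
    except ImportError:
        VCF = None
    if VCF is not None and not path.endswith(".tsv"):
        vcf = VCF(path)
        line_ids = list(vcf.samples)
        variants, calls, depths, gqs = [], [], [], []
        for rec in vcf:
            variants.append(VariantRecord(
                rec.CHROM, rec.POS - 1, rec.REF, rec.ALT[0],
                VariantRecord.classify(rec.REF, rec.ALT[0]),
                site_quality=float(rec.QUAL or 0.0)))
            gt = rec.gt_types  # 0=hom_ref,1=het,2=unknown,3=hom_alt
            col = np.full(len(line_ids), MISSING, dtype=np.int8)
            col[gt == 0] = HOM_REF
            col[gt == 1] = SEG
            col[gt == 3] = HOM_ALT
            calls.append(col)
            depths.append(np.array(rec.format("DP")).ravel()
                          if rec.format("DP") is not None
                          else np.zeros(len(line_ids)))
            gqs.append(np.array(rec.format("GQ")).ravel()
                       if rec.format("GQ") is not None
                       else np.zeros(len(line_ids)))
        return GenotypeMatrix(
            line_ids, variants,
            np.stack(calls, axis=1) if calls
            else np.zeros((len(line_ids), 0), dtype=np.int8),
            np.stack(depths, axis=1) if depths else None,
            np.stack(gqs, axis=1) if gqs else None)
    # text fallback
    line_ids: list[str] = []
    variants, calls = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                line_ids = line.rstrip("\n").split("\t")[9:]
                continue
            f = line.rstrip("\n").split("\t")
            variants.append(VariantRecord(
                f[0], int(f[1]) - 1, f[3], f[4],
                VariantRecord.classify(f[3], f[4]),
                site_quality=float(f[5])))
            col = [
                _GT_INV.get(s.split(":")[0], MISSING) for s in f[9:]
            ]
            calls.append(np.array(col, dtype=np.int8))
    return GenotypeMatrix(
        line_ids, variants,
        np.stack(calls, axis=1) if calls
        else np.zeros((len(line_ids), 0), dtype=np.int8))


def write_fasta(path: str, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_bed(path: str, track: pd.DataFrame,
              value_col: str | None = None) -> None:
    cols = ["contig", "start", "end"]
    if value_col:
        cols.append(value_col)
    track[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str, value_col: str = "value") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    names = ["contig", "start", "end"] + (
        [value_col] if df.shape[1] > 3 else [])
    df.columns = names[: df.shape[1]]
    return df


def write_gff(path: str, genes: Iterable[Gene]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            fh.write(f"{g.contig}\tgenarch\tgene\t{s + 1}\t{e}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            for tx in g.transcripts:
                ts, te = tx.span
                fh.write(f"{g.contig}\tgenarch\tmRNA\t{ts + 1}\t{te}\t.\t"
                         f"{tx.strand}\t.\tID={tx.tx_id};"
                         f"Parent={g.gene_id}\n")
                for (xs, xe) in tx.exons:
                    fh.write(f"{g.contig}\tgenarch\texon\t{xs + 1}\t{xe}"
                             f"\t.\t{tx.strand}\t.\tParent={tx.tx_id}\n")
                for (cs, ce) in tx.cds_exon_intervals():
                    fh.write(f"{g.contig}\tgenarch\tCDS\t{cs + 1}\t{ce}"
                             f"\t.\t{tx.strand}\t.\tParent={tx.tx_id}\n")


def read_gff(path: str) -> list[Gene]:
    """Rebuild toy gene models from a GFF written by write_gff."""
    from .genes import Transcript

    tx_meta: dict[str, dict] = {}
    gene_of_tx: dict[str, str] = {}
    gene_contig: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            contig, kind, start, end = f[0], f[2], int(f[3]) - 1, int(f[4])
            attrs = dict(kv.split("=") for kv in f[8].split(";"))
            if kind == "gene":
                gene_contig[attrs["ID"]] = contig
                order.append(attrs["ID"])
            elif kind == "mRNA":
                gene_of_tx[attrs["ID"]] = attrs["Parent"]
                tx_meta[attrs["ID"]] = {"strand": f[6], "contig": contig,
                                        "exons": [], "cds": []}
            elif kind == "exon":
                tx_meta[attrs["Parent"]]["exons"].append((start, end))
            elif kind == "CDS":
                tx_meta[attrs["Parent"]]["cds"].append((start, end))
    genes: dict[str, Gene] = {
        gid: Gene(gid, gene_contig[gid]) for gid in order}
    for tx_id, meta in tx_meta.items():
        cds_span = (min(s for s, _ in meta["cds"]),
                    max(e for _, e in meta["cds"]))
        genes[gene_of_tx[tx_id]].transcripts.append(
            Transcript(tx_id, meta["contig"], meta["strand"],
                       meta["exons"], cds_span))
    return [genes[gid] for gid in order]


def write_panel(path: str, panel: LinePanel) -> None:
    panel.table.to_csv(path, sep="\t")


def read_panel(path: str) -> LinePanel:
    table = pd.read_csv(path, sep="\t", index_col=0)
    inversions = [c[len("kar_"):] for c in table.columns
                  if c.startswith("kar_")]
    return LinePanel(table, inversions)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
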