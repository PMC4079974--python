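"""Shared plumbing for the analysis drivers: canonical file locations
under results/panel and reconstruction of the in-memory world from the
files 01_simulate_panel.py writes."""

from __future__ import annotations

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from genarch import io  # noqa: E402
from genarch.outgroup import OutgroupAlignment  # noqa: E402

ROOT = os.path.abspath(os.path.join(os.path.dirname(__file__), ".."))
RESULTS = os.path.join(ROOT, "results")
PANEL_DIR = os.path.join(RESULTS, "panel")


def out_path(*parts: str) -> str:
    path = os.path.join(RESULTS, *parts)
    os.makedirs(os.path.dirname(path), exist_ok=True)
    return path


def load_world():
    """Matrix, panel, reference, outgroup alignment and tracks from the
    files written by 01_simulate_panel.py."""
    matrix = io.read_vcf(os.path.join(PANEL_DIR, "truth.vcf"))
    panel = io.read_panel(os.path.join(PANEL_DIR, "lines.tsv"))
    reference = io.read_fasta(os.path.join(PANEL_DIR, "reference.fa"))
    aligned = io.read_fasta(os.path.join(PANEL_DIR,
                                         "outgroup_aligned.fa"))
    og_alleles = pd.read_csv(
        os.path.join(PANEL_DIR, "outgroup_alleles.tsv"), sep="\t")
    variant_positions = {}
    for v in matrix.variants:
        variant_positions.setdefault(v.contig, set()).update(
            range(v.pos, v.end))
    outgroup = OutgroupAlignment(
        reference, aligned,
        dict(zip(og_alleles.vid, og_alleles.outgroup_allele)),
        variant_positions)
    rec = io.read_bed(os.path.join(PANEL_DIR, "recombination.bed"),
                      "cm_mb")
    chrom = io.read_bed(os.path.join(PANEL_DIR, "chromatin.bed"),
                        "domain")
    lengths = {
        name: len(seq) for name, seq in reference.items()
    }
    return matrix, panel, reference, outgroup, rec, chrom, lengths
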