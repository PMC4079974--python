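"""Core containers shared by every analysis stage.

The panel is a set of inbred lines, each sequenced as a single sample. A
line's call at a variant site is one of four states:

* ``HOM_REF`` / ``HOM_ALT`` — the line is fixed for one allele;
* ``SEG`` — residual heterozygosity: the line still segregates for both
  alleles despite 20 generations of full-sib inbreeding;
* ``MISSING`` — no call.

For allele-frequency work the panel is read haploid (a fixed line is one
gamete); residual segregating calls are treated as missing at that site for
that line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

HOM_REF: int = 0
SEG: int = 1
HOM_ALT: int = 2
MISSING: int = -1

_SNP = "snp"
_DEL = "del"
_INS = "ins"
_MNP = "mnp"


@dataclass
class VariantRecord:
    """One biallelic variant on the reference coordinate system.

    ``pos`` is 0-based; ``ref``/``alt`` follow VCF allele conventions
    (indels carry a left anchor base). ``ancestral`` is the allele carried
    by the outgroup lineage when known (simulated truth or inferred).
    """

    contig: str
    pos: int
    ref: str
    alt: str
    vtype: str = _SNP
    site_quality: float = 1000.0
    ancestral: str | None = None
    functional_class: str | None = None
    vid: str | None = None

    def __post_init__(self) -> None:
        if self.vid is None:
            self.vid = f"{self.contig}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def length_change(self) -> int:
        """alt length minus ref length (negative for deletions)."""
        return len(self.alt) - len(self.ref)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return self.vtype in (_DEL, _INS) or (
            len(self.ref) != len(self.alt)
        )

    @property
    def end(self) -> int:
        """End of the reference footprint (0-based, half-open)."""
        return self.pos + len(self.ref)

    @staticmethod
    def classify(ref: str, alt: str) -> str:
        if len(ref) == 1 and len(alt) == 1:
            return _SNP
        if len(ref) > len(alt):
            return _DEL
        if len(alt) > len(ref):
            return _INS
        return _MNP


class GenotypeMatrix:
    """lines x variants call matrix with optional per-call depth/quality.

    ``calls`` uses the codes above (int8). ``depth`` and ``gq`` are
    optional arrays of the same shape; ``depth`` is total reads at the
    call, ``gq`` a phred-scaled genotype quality.
    """

    def __init__(
        self,
        line_ids: Sequence[str],
        variants: Sequence[VariantRecord],
        calls: np.ndarray,
        depth: np.ndarray | None = None,
        gq: np.ndarray | None = None,
    ) -> None:
        self.line_ids = list(line_ids)
        self.variants = list(variants)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.line_ids), len(self.variants)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.variants)} variants"
            )
        self.calls = calls
        self.depth = None if depth is None else np.asarray(depth)
        self.gq = None if gq is None else np.asarray(gq)

    # ------------------------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def contigs(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.variants:
            seen.setdefault(v.contig, None)
        return list(seen)

    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def contig_index(self) -> np.ndarray:
        return np.array([v.contig for v in self.variants])

    # ------------------------------------------------------------------
    def haploid_alleles(self) -> np.ndarray:
        """Read lines as single gametes: 0/1 alleles, NaN where missing.

        Residual segregating calls are unresolvable haploid reads and are
        treated as missing for that line at that site.
        """
        out = np.full(self.calls.shape, np.nan)
        out[self.calls == HOM_REF] = 0.0
        out[self.calls == HOM_ALT] = 1.0
        return out

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing haploid
        calls; NaN where no line has a resolved call."""
        h = self.haploid_alleles()
        n = np.sum(~np.isnan(h), axis=0)
        s = np.nansum(h, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, s / np.maximum(n, 1), np.nan)

    def minor_allele_freq(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        """Fraction of lines with a resolved haploid call per variant."""
        h = self.haploid_alleles()
        return np.mean(~np.isnan(h), axis=0)

    # ------------------------------------------------------------------
    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.line_ids,
            [self.variants[i] for i in index],
            self.calls[:, index],
            None if self.depth is None else self.depth[:, index],
            None if self.gq is None else self.gq[:, index],
        )

    def take_lines(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            [self.line_ids[i] for i in index],
            self.variants,
            self.calls[index],
            None if self.depth is None else self.depth[index],
            None if self.gq is None else self.gq[index],
        )

    def subset_contig(self, contig: str) -> "GenotypeMatrix":
        mask = np.array([v.contig == contig for v in self.variants])
        return self.take_variants(mask)


@dataclass
class LinePanel:
    """Per-line metadata: inversion karyotypes, Wolbachia, genome size,
    phenotype means, and (synthetic panels only) the founder pedigree.

    ``table`` is indexed by line id; inversion columns (``kar_<name>``)
    store the dosage of the inverted arrangement (0/1/2; 1 =
    heterokaryotypic).
    """

    table: pd.DataFrame
    inversions: list[str] = field(default_factory=list)

    @property
    def line_ids(self) -> list[str]:
        return list(self.table.index)

    def karyotype(self, inversion: str) -> pd.Series:
        return self.table[f"kar_{inversion}"]

    def is_heterokaryotypic(self, inversion: str) -> pd.Series:
        return self.karyotype(inversion) == 1

    @property
    def wolbachia(self) -> pd.Series:
        return self.table["wolbachia"]

    def inversion_count(self) -> pd.Series:
        """Number of inverted arrangements carried per line (0..n_inv)."""
        cols = [f"kar_{i}" for i in self.inversions]
        if not cols:
            return pd.Series(0, index=self.table.index)
        return (self.table[cols] >= 1).sum(axis=1)


@dataclass
class RelationshipMatrix:
    """Symmetric line x line realized-relationship estimates."""

    line_ids: list[str]
    values: np.ndarray
    normalization: str = "raw"  # raw | mean_diagonal
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.line_ids, columns=self.line_ids
        )
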