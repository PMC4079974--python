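"""Outgroup alignment container used for polarization and divergence.

The outgroup stands in for a sister species aligned to the panel's
reference. Two views are kept:

* an *aligned* outgroup sequence in reference coordinates (substitutions
  only), used to count fixed differences at non-variant positions;
* a per-variant outgroup allele (the sequence the outgroup carries over
  the variant's reference footprint), used to polarize alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class OutgroupAlignment:
    reference: dict[str, str]
    aligned: dict[str, str]
    variant_alleles: dict[str, str] = field(default_factory=dict)
    variant_positions: dict[str, set] = field(default_factory=dict)

    def allele_at(self, vid: str) -> str | None:
        return self.variant_alleles.get(vid)

    def substitution_positions(self, contig: str,
                               start: int, end: int) -> list[int]:
        """Non-variant positions in [start, end) where the aligned
        outgroup differs from the reference."""
        ref = self.reference[contig]
        out = self.aligned[contig]
        skip = self.variant_positions.get(contig, set())
        return [
            i for i in range(start, min(end, len(ref)))
            if ref[i] != out[i] and i not in skip
        ]
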