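"""Population genomics: exact tests, diversity, polarization, spectra."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from genarch import popgen
from genarch import simulate as sim
from genarch.outgroup import OutgroupAlignment
from genarch.types import (
    HOM_ALT,
    HOM_REF,
    MISSING,
    SEG,
    GenotypeMatrix,
    LinePanel,
    VariantRecord,
)


def brute_force_fisher(table) -> float:
    """Enumerate every table with the observed margins; sum P(table) for
    tables no more probable than the observed one."""
    a, b, c, d = np.asarray(table).ravel()
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k):
        return (math.comb(r1, k) * math.comb(r2, c1 - k)
                / math.comb(n, c1))

    p_obs = prob(a)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


class TestFishersExact:
    def test_inversion_table(self):
        p = popgen.fishers_exact([[60, 2], [6, 752]])
        assert p == pytest.approx(1.91e-81, rel=5e-3)

    def test_uniform_table(self):
        assert popgen.fishers_exact([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_diagonal_table(self):
        assert popgen.fishers_exact([[5, 0], [0, 5]]) == pytest.approx(
            2 / 252, rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            popgen.fishers_exact([[1, -1], [1, 1]])

    @given(st.lists(st.integers(0, 15), min_size=4, max_size=4))
    @settings(deadline=None, max_examples=150)
    def test_matches_enumeration(self, cells):
        table = np.array(cells).reshape(2, 2)
        p = popgen.fishers_exact(table)
        assert p == pytest.approx(brute_force_fisher(table), rel=1e-7,
                                  abs=1e-12)
        # scipy as a second, independent implementation
        assert p == pytest.approx(scipy_fisher(table)[1], rel=1e-6,
                                  abs=1e-12)


class TestSegregatingProfiles:
    def test_simple_fractions(self):
        calls = np.full((1, 100), HOM_REF, dtype=np.int8)
        calls[0, :3] = SEG
        m = GenotypeMatrix(["a"], [VariantRecord("c", i, "A", "G")
                                   for i in range(100)], calls)
        prof = popgen.segregating_fraction(m)
        assert prof.percent_segregating.iloc[0] == pytest.approx(3.0)

    def test_all_homozygous_zero(self):
        calls = np.full((2, 10), HOM_ALT, dtype=np.int8)
        m = GenotypeMatrix(["a", "b"],
                           [VariantRecord("c", i, "A", "G")
                            for i in range(10)], calls)
        prof = popgen.segregating_fraction(m)
        assert (prof.percent_segregating == 0).all()

    def test_all_missing_flagged(self):
        calls = np.full((1, 5), MISSING, dtype=np.int8)
        m = GenotypeMatrix(["a"], [VariantRecord("c", i, "A", "G")
                                   for i in range(5)], calls)
        prof = popgen.segregating_fraction(m)
        assert not prof.defined.iloc[0]

    def test_heterokaryotype_exceeds_threshold(self, small_panel,
                                               small_config):
        matrix, panel = small_panel
        inv = small_config.inversions[0]
        prof = popgen.segregating_fraction(matrix)
        arm = prof[prof.contig == inv.arm].set_index("line_id")
        het = panel.table[f"kar_{inv.name}"] == 1
        assert (arm.loc[het[het].index, "percent_segregating"] > 9).all()
        assert (arm.loc[het[~het].index, "percent_segregating"]
                < 9).all()


class TestInversionAssociation:
    def test_synthetic_panel_association(self, small_panel, small_config):
        matrix, panel = small_panel
        prof = popgen.segregating_fraction(matrix)
        table, p = popgen.inversion_association(
            prof, panel, {"In(2L)t": "2L"}, autosomes=["2L", "2R"])
        assert table.sum() == 60  # one autosome arm with an inversion
        assert p < 1e-4

    def test_all_homokaryotypic_degenerate(self):
        calls = np.full((4, 10), HOM_REF, dtype=np.int8)
        m = GenotypeMatrix([f"l{i}" for i in range(4)],
                           [VariantRecord("2L", i * 5, "A", "G")
                            for i in range(10)], calls)
        table = pd.DataFrame({"kar_inv": [0, 0, 0, 0],
                              "wolbachia": [0, 1, 0, 1]},
                             index=pd.Index(m.line_ids, name="line_id"))
        panel = LinePanel(table, ["inv"])
        prof = popgen.segregating_fraction(m)
        tab, p = popgen.inversion_association(prof, panel, {"inv": "2L"})
        assert tab[:, 0].sum() == 0
        assert p == pytest.approx(1.0)


def brute_force_pi(h: np.ndarray, length: int) -> float:
    """Mean pairwise difference over all line pairs (pairwise-complete),
    with the n/(n-1) correction applied per site via pair counting."""
    n_sites = h.shape[1]
    total = 0.0
    for j in range(n_sites):
        col = h[:, j]
        called = col[~np.isnan(col)]
        n = len(called)
        if n < 2:
            continue
        diffs = sum(1 for x, y in itertools.combinations(called, 2)
                    if x != y)
        # mean pairwise difference == [n/(n-1)] 2p(1-p) exactly
        total += diffs / (n * (n - 1) / 2)
    return total / length


class TestDiversity:
    def test_hand_computed_window(self):
        # one SNP at p = 0.5 among 4 lines in a 100-bp window
        calls = np.array([[HOM_REF], [HOM_REF], [HOM_ALT], [HOM_ALT]],
                         dtype=np.int8)
        m = GenotypeMatrix(["a", "b", "c", "d"],
                           [VariantRecord("c", 50, "A", "G")], calls)
        div = popgen.nucleotide_diversity(m, {"c": 100}, window_size=100)
        assert div.pi.iloc[0] == pytest.approx((4 / 3) * 0.5 / 100)

    def test_monomorphic_window_zero(self):
        calls = np.full((4, 3), HOM_REF, dtype=np.int8)
        m = GenotypeMatrix(list("abcd"),
                           [VariantRecord("c", i * 10, "A", "G")
                            for i in range(3)], calls)
        div = popgen.nucleotide_diversity(m, {"c": 100}, window_size=100)
        assert div.pi.iloc[0] == 0.0

    def test_indel_diversity_length_blind(self):
        # a 10-bp deletion at p=0.5 contributes exactly like a SNP
        calls = np.array([[HOM_REF, HOM_REF], [HOM_ALT, HOM_ALT]],
                         dtype=np.int8)
        vs = [VariantRecord("c", 10, "ACGTACGTACG", "A", "del"),
              VariantRecord("c", 50, "A", "G", "snp")]
        m = GenotypeMatrix(["a", "b"], vs, calls)
        d_indel = popgen.nucleotide_diversity(m, {"c": 100}, 100, "indel")
        d_snp = popgen.nucleotide_diversity(m, {"c": 100}, 100, "snp")
        assert d_indel.pi.iloc[0] == pytest.approx(d_snp.pi.iloc[0])

    def test_matches_brute_force_pairwise(self, rng):
        """Windowed formula == direct mean pairwise difference over all
        line pairs, instances with <= 8 lines."""
        for _ in range(20):
            n = int(rng.integers(3, 9))
            m_sites = int(rng.integers(1, 30))
            calls = rng.choice(
                [HOM_REF, HOM_ALT, MISSING], p=[0.5, 0.4, 0.1],
                size=(n, m_sites)).astype(np.int8)
            vs = [VariantRecord("c", i * 3, "A", "G")
                  for i in range(m_sites)]
            m = GenotypeMatrix([f"l{i}" for i in range(n)], vs, calls)
            div = popgen.nucleotide_diversity(m, {"c": 100}, 100, "all")
            h = m.haploid_alleles()
            assert div.pi.iloc[0] == pytest.approx(
                brute_force_pi(h, 100), abs=1e-12)

    def test_x_less_diverse_than_autosomes(self, small_panel):
        """X at 3/4 the autosomal effective size shows lower pi."""
        matrix, _ = small_panel
        clens = {"2R": 120_000, "X": 120_000}
        div = popgen.nucleotide_diversity(matrix, clens,
                                          window_size=20_000)
        pi_a = div[div.contig == "2R"].pi.mean()
        pi_x = div[div.contig == "X"].pi.mean()
        assert pi_x < pi_a


class TestDivergence:
    def _setup(self, og_allele, panel_calls):
        ref = {"c": "A" * 100}
        aligned = {"c": "A" * 100}
        vs = [VariantRecord("c", 50, "A", "G")]
        out = OutgroupAlignment(ref, aligned, {vs[0].vid: og_allele},
                                {"c": {50}})
        calls = np.array(panel_calls, dtype=np.int8).reshape(-1, 1)
        m = GenotypeMatrix([f"l{i}" for i in range(len(panel_calls))],
                           vs, calls)
        return m, out

    def test_outgroup_matches_fixed_panel(self):
        m, out = self._setup("G", [HOM_ALT, HOM_ALT])
        k = popgen.divergence(m, out, {"c": 100}, 100)
        assert k.k.iloc[0] == 0.0

    def test_fixed_difference_counted(self):
        m, out = self._setup("A", [HOM_ALT, HOM_ALT])
        k = popgen.divergence(m, out, {"c": 100}, 100)
        assert k.n_fixed.iloc[0] == 1
        assert k.k.iloc[0] == pytest.approx(0.01)

    def test_background_rate_recovered(self, small_founders, small_panel):
        matrix, _ = small_panel
        clens = {c.name: c.length for c in
                 small_founders.config.contigs}
        k = popgen.divergence(matrix, small_founders.outgroup, clens,
                              window_size=60_000)
        assert k.k.mean() == pytest.approx(
            small_founders.config.outgroup_substitution_rate, rel=0.15)


class TestPolarization:
    def _one(self, ref, alt, og, calls):
        vs = [VariantRecord("c", 10, ref, alt,
                            VariantRecord.classify(ref, alt))]
        m = GenotypeMatrix([f"l{i}" for i in range(len(calls))], vs,
                           np.array(calls, dtype=np.int8).reshape(-1, 1))
        out = OutgroupAlignment({}, {}, {vs[0].vid: og}, {})
        return popgen.polarize_variants(m, out)[0]

    def test_outgroup_matches_long_allele(self):
        p = self._one("ACGT", "A", "ACGT", [HOM_REF, HOM_ALT])
        assert p.status == "polarized"
        assert p.derived_type == "deletion"
        assert p.derived_count == 1

    def test_outgroup_matches_neither(self):
        p = self._one("ACGT", "A", "AGGT", [HOM_REF, HOM_ALT])
        assert p.status == "unpolarized"

    def test_swap_invariance(self):
        """derived_type is invariant to swapping ref/alt labels."""
        a = self._one("ACGT", "A", "ACGT", [HOM_REF, HOM_ALT])
        b = self._one("A", "ACGT", "ACGT", [HOM_ALT, HOM_REF])
        assert a.derived_type == b.derived_type == "deletion"
        assert a.derived_count == b.derived_count

    def test_conservation(self, small_panel, small_founders):
        matrix, _ = small_panel
        pol = popgen.polarize_variants(matrix, small_founders.outgroup)
        n_indels = sum(1 for v in matrix.variants if v.is_indel)
        assert len(pol) == n_indels


class TestFrequencySpectrum:
    def test_counts_conserved(self, small_panel):
        matrix, _ = small_panel
        spec = popgen.frequency_spectrum(matrix, "minor")
        n_defined = int(np.sum(~np.isnan(matrix.minor_allele_freq())))
        assert spec.to_numpy().sum() == n_defined

    def test_derived_bin_placement(self):
        vs = [VariantRecord("c", 10, "AC", "A", "del")]
        calls = np.array([[HOM_ALT]] + [[HOM_REF]] * 9, dtype=np.int8)
        m = GenotypeMatrix([f"l{i}" for i in range(10)], vs, calls)
        out = OutgroupAlignment({}, {}, {vs[0].vid: "AC"}, {})
        pol = popgen.polarize_variants(m, out)
        spec = popgen.frequency_spectrum(m, "derived", polarized=pol)
        assert spec.iloc[1].sum() == 1  # DAF 0.1 lands in bin [0.1, 0.2)
        assert spec.to_numpy().sum() == 1

    def test_purifying_selection_left_shift(self, rng):
        """A class sampled with frequency down-weighting shows an excess
        of low-frequency variants (stochastic dominance of its MAF)."""
        n_lines, n_var = 40, 400
        freqs_neutral = rng.uniform(0.05, 0.5, n_var)
        freqs_selected = rng.beta(0.6, 3.0, n_var) * 0.5
        calls = np.zeros((n_lines, 2 * n_var), dtype=np.int8)
        for j, f in enumerate(np.r_[freqs_neutral, freqs_selected]):
            calls[:, j] = np.where(rng.random(n_lines) < f, HOM_ALT,
                                   HOM_REF)
        vs = ([VariantRecord("c", j, "A", "G") for j in range(n_var)]
              + [VariantRecord("c", n_var + j, "A", "G", "del")
                 for j in range(n_var)])
        m = GenotypeMatrix([f"l{i}" for i in range(n_lines)], vs, calls)
        maf = m.minor_allele_freq()
        from scipy.stats import mannwhitneyu
        stat = mannwhitneyu(maf[:n_var], maf[n_var:],
                            alternative="greater")
        assert stat.pvalue < 0.01


class TestKaryotypeDiversity:
    def test_between_exceeds_within_for_diverged_inversion(
            self, small_panel, small_config):
        matrix, panel = small_panel
        inv = small_config.inversions[0]
        ps, pv, pb = popgen.karyotype_diversity(
            matrix, panel, inv.name, (inv.arm, inv.start, inv.end))
        assert pb > max(ps, pv)

    def test_identical_lines_all_zero(self):
        calls = np.full((4, 5), HOM_REF, dtype=np.int8)
        m = GenotypeMatrix(list("abcd"),
                           [VariantRecord("c", i * 10, "A", "G")
                            for i in range(5)], calls)
        table = pd.DataFrame({"kar_inv": [0, 0, 2, 2],
                              "wolbachia": 0},
                             index=pd.Index(list("abcd"),
                                            name="line_id"))
        panel = LinePanel(table, ["inv"])
        ps, pv, pb = popgen.karyotype_diversity(m, panel, "inv",
                                                ("c", 0, 100))
        assert ps == pv == pb == 0.0

    def test_too_few_lines_undefined(self):
        calls = np.full((3, 5), HOM_REF, dtype=np.int8)
        m = GenotypeMatrix(list("abc"),
                           [VariantRecord("c", i * 10, "A", "G")
                            for i in range(5)], calls)
        table = pd.DataFrame({"kar_inv": [0, 0, 2], "wolbachia": 0},
                             index=pd.Index(list("abc"),
                                            name="line_id"))
        panel = LinePanel(table, ["inv"])
        ps, pv, _ = popgen.karyotype_diversity(m, panel, "inv",
                                               ("c", 0, 100))
        assert not np.isnan(ps)
        assert np.isnan(pv)


class TestVariantClustering:
    def test_planted_carrier_clustering(self):
        """SNPs planted within 20 bp of focal variants, only on carrier
        haplotypes, elevate the carrier profile at short range only."""
        n_lines = 20
        rng = np.random.default_rng(3)
        variants, cols = [], []
        pos = 0
        for _ in range(30):
            pos += 1000
            carriers = rng.choice(n_lines, size=9, replace=False)
            focal = np.zeros(n_lines, dtype=np.int8)
            focal[carriers] = HOM_ALT
            variants.append(VariantRecord("c", pos, "A", "G"))
            cols.append(focal)
            near = np.zeros(n_lines, dtype=np.int8)
            near[carriers[:5]] = HOM_ALT
            variants.append(VariantRecord("c", pos + 15, "T", "C"))
            cols.append(near)
        m = GenotypeMatrix([f"l{i}" for i in range(n_lines)], variants,
                           np.stack(cols, axis=1))
        prof = popgen.variant_clustering(m, maf_band=(0.40, 0.50),
                                         radius=100)
        carrier = prof[prof.stratum == "carrier"]
        short = carrier[carrier.distance <= 20].mean_count.sum()
        long = carrier[carrier.distance > 20].mean_count.sum()
        assert short > 0
        assert long == 0

    def test_no_focal_variants_raises(self):
        calls = np.full((4, 2), HOM_REF, dtype=np.int8)
        calls[0, :] = HOM_ALT  # MAF 0.25, outside the band
        m = GenotypeMatrix(list("abcd"),
                           [VariantRecord("c", i * 10, "A", "G")
                            for i in range(2)], calls)
        with pytest.raises(ValueError):
            popgen.variant_clustering(m)


class TestRecombinationCorrelation:
    def test_monotone_relation_rho_one(self):
        div = pd.DataFrame({"contig": "c", "start": range(0, 50, 10),
                            "pi": [0.1, 0.2, 0.3, 0.4, 0.5]})
        rec = pd.DataFrame({"contig": "c", "start": range(0, 50, 10),
                            "cm_mb": [1.0, 2.0, 4.0, 8.0, 16.0]})
        rho, _ = popgen.recombination_correlation(div, rec)
        assert rho == pytest.approx(1.0)

    def test_constant_track_undefined(self):
        div = pd.DataFrame({"contig": "c", "start": range(0, 30, 10),
                            "pi": [0.1, 0.1, 0.1]})
        rec = pd.DataFrame({"contig": "c", "start": range(0, 30, 10),
                            "cm_mb": [1.0, 2.0, 3.0]})
        rho, p = popgen.recombination_correlation(div, rec)
        assert np.isnan(rho)

    def test_coupled_simulation_positive(self, small_founders,
                                         small_panel):
        """Variant placement follows the recombination profile, so
        windowed diversity correlates positively with the map."""
        matrix, _ = small_panel
        clens = {c.name: c.length for c in small_founders.config.contigs}
        div = popgen.nucleotide_diversity(matrix, clens,
                                          window_size=10_000)
        rho, p = popgen.recombination_correlation(
            div, small_founders.recombination_track)
        assert rho > 0
        assert p < 0.05


class TestChromatinEnrichment:
    def test_uniform_variants_fold_one(self):
        rng = np.random.default_rng(4)
        pos = np.sort(rng.choice(100_000, 2000, replace=False))
        vs = [VariantRecord("c", int(p), "A", "G") for p in pos]
        m = GenotypeMatrix(["a"], vs,
                           np.zeros((1, len(vs)), dtype=np.int8))
        domains = pd.DataFrame({
            "contig": "c", "start": [0, 50_000],
            "end": [50_000, 100_000], "domain": ["RED", "BLUE"]})
        enr = popgen.chromatin_enrichment(m, domains, {"c": 100_000})
        assert enr.fold.min() > 0.9
        assert enr.fold.max() < 1.1

    def test_planted_double_density(self):
        rng = np.random.default_rng(5)
        pos = np.concatenate([
            np.sort(rng.choice(50_000, 2000, replace=False)),
            50_000 + np.sort(rng.choice(50_000, 1000, replace=False))])
        vs = [VariantRecord("c", int(p), "A", "G") for p in pos]
        m = GenotypeMatrix(["a"], vs,
                           np.zeros((1, len(vs)), dtype=np.int8))
        domains = pd.DataFrame({
            "contig": "c", "start": [0, 50_000],
            "end": [50_000, 100_000], "domain": ["RED", "BLUE"]})
        enr = popgen.chromatin_enrichment(m, domains, {"c": 100_000})
        red = enr[enr.domain == "RED"].iloc[0]
        assert red.fold == pytest.approx(2 * 2000 / 3000, rel=0.05)
        assert red.p < 1e-6
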