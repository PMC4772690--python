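"""NG86 site/difference counting, H_A/H_S, permutation and signed-rank tests."""

import math
from itertools import combinations, permutations, product

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, wilcoxon

import anemonepg as apg
from anemonepg.coding import (
    GENETIC_CODE,
    GeneModel,
    _codon_path_counts,
    ng86_site_counts,
    reference_cds,
)

from conftest import make_callset


class TestNG86Sites:
    def test_ttt_by_enumerating_all_nine_changes(self):
        syn = nonsyn = 0
        for j, b in product(range(3), "ACGT"):
            if b == "TTT"[j]:
                continue
            mut = "TTT"[:j] + b + "TTT"[j + 1:]
            if GENETIC_CODE[mut] == GENETIC_CODE["TTT"]:
                syn += 1
            else:
                nonsyn += 1
        assert (syn / 3, nonsyn / 3) == (1 / 3, 8 / 3)
        s, n, _ = ng86_site_counts("TTT")
        assert (s, n) == pytest.approx((1 / 3, 8 / 3))

    def test_tryptophan_has_no_synonymous_sites(self):
        s, n, _ = ng86_site_counts("TGG")
        assert s == 0.0 and n == 3.0

    def test_conservation_over_full_cds(self, rng):
        codons = [c for c in GENETIC_CODE if GENETIC_CODE[c] != "*"]
        cds = "ATG" + "".join(rng.choice(codons, 50)) + "TAA"
        s, n, skipped = ng86_site_counts(cds)
        assert skipped == 0
        assert s + n == pytest.approx(len(cds) - 3)  # terminal stop excluded

    def test_internal_stop_codon_skipped(self):
        s, n, skipped = ng86_site_counts("ATGTAAAAA")
        assert skipped == 1
        assert s + n == pytest.approx(6.0)


class TestPairwiseDifferences:
    def test_third_position_synonymous_change(self):
        pair = apg.AllelePairCDS("g", "s", "TTT", "TTC")
        assert apg.count_pairwise_differences(pair) == pytest.approx((1.0, 0.0))

    def test_two_difference_codon_averages_both_orderings(self):
        # explicit pathway enumeration for TTT -> GTC
        paths = []
        for order in permutations([0, 2]):
            cur, syn, nonsyn = "TTT", 0, 0
            for i in order:
                nxt = cur[:i] + "GTC"[i] + cur[i + 1:]
                syn += GENETIC_CODE[cur] == GENETIC_CODE[nxt]
                nonsyn += GENETIC_CODE[cur] != GENETIC_CODE[nxt]
                cur = nxt
            paths.append((syn, nonsyn))
        expected = tuple(sum(p[i] for p in paths) / 2 for i in (0, 1))
        pair = apg.AllelePairCDS("g", "s", "TTT", "GTC")
        assert apg.count_pairwise_differences(pair) == pytest.approx(expected)
        assert expected == (1.0, 1.0)

    def test_identity_and_symmetry(self, rng):
        codons = [c for c in GENETIC_CODE if GENETIC_CODE[c] != "*"]
        a = "".join(rng.choice(codons, 20))
        assert apg.count_pairwise_differences(
            apg.AllelePairCDS("g", "s", a, a)) == (0.0, 0.0)
        b = list(a)
        for i in rng.choice(len(a), 6, replace=False):
            b[i] = rng.choice([x for x in "ACGT" if x != a[i]])
        b = "".join(b)
        ab = apg.count_pairwise_differences(apg.AllelePairCDS("g", "s", a, b))
        ba = apg.count_pairwise_differences(apg.AllelePairCDS("g", "s", b, a))
        assert ab == pytest.approx(ba)

    def test_pathways_through_stops_downweighted(self):
        # TGT (Cys) -> TGG (Trp) direct is fine; check a pair whose one
        # ordering passes through TGA (stop): TGT -> AGG
        counts = _codon_path_counts("TGT", "AGG")
        # orderings: TGT->AGT->AGG (no stop) and TGT->TGG->AGG (no stop);
        # both avoid stops so both are averaged
        assert counts == pytest.approx((0.0, 2.0))
        # CGA -> TGG: CGA->TGA is a stop intermediate; only CGA->CGG->TGG used
        syn, nonsyn = _codon_path_counts("CGA", "TGG")
        assert (syn, nonsyn) == pytest.approx((1.0, 1.0))


class TestJukesCantor:
    def test_closed_form_value(self):
        assert apg.jukes_cantor(0.03) == pytest.approx(
            -0.75 * math.log(1 - 0.04), rel=1e-12)

    def test_identity_to_first_order_at_zero(self):
        for p in (1e-3, 1e-5, 1e-7):
            assert apg.jukes_cantor(p) == pytest.approx(p, rel=5e-3)

    def test_saturation_is_flagged(self):
        assert math.isnan(apg.jukes_cantor(0.75))


class TestAlleleCDS:
    def test_no_snps_gives_reference_identity(self, pipeline):
        ds = pipeline.dataset
        gene = ds.reference.genes[0]
        empty = pipeline.filtered.take_sites(
            np.zeros(pipeline.filtered.n_sites, dtype=bool))
        pair = apg.build_allele_cds(ds.reference.contigs, gene, empty,
                                    ds.callset.samples[0])
        assert pair.cds_a == pair.cds_b == reference_cds(
            gene, ds.reference.contigs)
        assert pair.n_het_cds == 0

    def test_het_snp_substitutes_one_allele_at_mapped_position(self):
        contig = {"c": "AAAAATGGCTGCAGCCGCGAAATAAAAAA"}
        gene = GeneModel("g1", "c", "+", [(5, 25, 0)])
        ref = reference_cds(gene, contig)
        assert ref.startswith("ATG") and ref.endswith("TAA")
        # het SNP at genomic pos 14 (CDS index 9): A>G
        cs = make_callset(np.array([[1]], dtype=np.int8), contig="c",
                          start=14, samples=["S1"],
                          ref=contig["c"][13], alt="T")
        pair = apg.build_allele_cds(contig, gene, cs, "S1")
        assert pair.cds_a == ref
        assert pair.cds_b == ref[:9] + "T" + ref[10:]
        assert pair.n_het_cds == 1

    def test_minus_strand_mapping_equals_brute_force(self, pipeline):
        ds = pipeline.dataset
        gene = next(g for g in ds.reference.genes if g.strand == "-")
        ref = reference_cds(gene, ds.reference.contigs)
        positions = gene.coding_positions()
        # brute-force coordinate map: genomic position of CDS index i
        idx = 40
        genomic = int(positions[idx])
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        ref_gen = ds.reference.contigs[gene.contig][genomic - 1]
        assert ref[idx] == comp[ref_gen]
        alt_gen = "A" if ref_gen != "A" else "C"
        cs = make_callset(np.array([[2]], dtype=np.int8), contig=gene.contig,
                          start=genomic, samples=["S1"],
                          ref=ref_gen, alt=alt_gen)
        pair = apg.build_allele_cds(ds.reference.contigs, gene, cs, "S1")
        assert pair.cds_a[idx] == comp[alt_gen]  # hom_alt hits both alleles
        assert pair.cds_b[idx] == comp[alt_gen]

    def test_reference_mismatch_raises(self, pipeline):
        ds = pipeline.dataset
        gene = ds.reference.genes[0]
        pos = int(gene.coding_positions()[10])
        base = ds.reference.contigs[gene.contig][pos - 1]
        wrong = "A" if base != "A" else "C"
        cs = make_callset(np.array([[1]], dtype=np.int8), contig=gene.contig,
                          start=pos, samples=["S1"], ref=wrong,
                          alt={"A": "G", "C": "T"}[wrong])
        with pytest.raises(Exception, match="mismatch"):
            apg.build_allele_cds(ds.reference.contigs, gene, cs, "S1")


class TestHaHsGene:
    def test_below_min_het_is_skipped(self):
        pair = apg.AllelePairCDS("g", "s", "ATGAAACCCGGGTTTTAA",
                                 "ATGAAACCCGGGTTCTAA")
        assert apg.ha_hs_gene(pair, min_het=5) is None

    def test_site_conservation_per_gene(self, pipeline):
        counts = pipeline.coding_counts
        genes = {g.gene_id: g for g in pipeline.dataset.reference.genes}
        sub = counts.drop_duplicates("gene_id").head(20)
        for row in sub.itertuples():
            length = genes[row.gene_id].spliced_length()
            assert row.syn_sites + row.nonsyn_sites == pytest.approx(
                length - 3, abs=1e-6)  # minus the terminal stop codon

    def test_planted_ratio_classes_recovered(self, pipeline):
        table = apg.ha_hs_table(pipeline.coding_counts, min_het=5)
        ratios = apg.gene_mean_ratios(table)
        classes = pipeline.dataset.truth.gene_classes
        med = {c: float(ratios[[g for g in ratios.index
                                if classes[g] == c]].median())
               for c in ("low", "background", "high")}
        assert med["low"] < med["background"] < med["high"]
        assert med["low"] == pytest.approx(0.07, abs=0.07)
        assert med["background"] == pytest.approx(0.22, abs=0.1)


class TestGenomewide:
    def test_identical_genes_give_zero_replicate_variance(self):
        rows = []
        for g in range(5):
            rows.append({"gene_id": f"g{g}", "sample": "S1",
                         "syn_sites": 100.0, "nonsyn_sites": 300.0,
                         "syn_diffs": 2.0, "nonsyn_diffs": 1.5,
                         "n_het_cds": 7})
        counts = pd.DataFrame(rows)
        out = apg.genomewide_ha_hs(counts, n_genes=3, reps=20, seed=0)
        assert out.loc["S1", "h_s"] == pytest.approx(
            apg.jukes_cantor(2.0 / 100.0))
        assert out.loc["S1", "h_a"] == pytest.approx(
            apg.jukes_cantor(1.5 / 300.0))

    def test_seeded_determinism(self, pipeline):
        a = apg.genomewide_ha_hs(pipeline.coding_counts, n_genes=50, reps=5,
                                 seed=9)
        b = apg.genomewide_ha_hs(pipeline.coding_counts, n_genes=50, reps=5,
                                 seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_genes_rejected(self, pipeline):
        with pytest.raises(ValueError, match="eligible genes"):
            apg.genomewide_ha_hs(pipeline.coding_counts, n_genes=10_000)

    def test_large_reps_converge_to_pooled_concatenation(self, pipeline):
        counts = pipeline.coding_counts
        n_genes = counts.gene_id.nunique()
        out = apg.genomewide_ha_hs(counts, n_genes=n_genes, reps=2, seed=1)
        pooled = counts.groupby("sample", sort=False).sum(numeric_only=True)
        s = pipeline.dataset.config.samples[0]
        assert out.loc[s, "h_s"] == pytest.approx(apg.jukes_cantor(
            pooled.loc[s, "syn_diffs"] / pooled.loc[s, "syn_sites"]))


class TestPermutationTest:
    def test_whole_universe_is_degenerate(self):
        ratios = pd.Series({"a": 0.1, "b": 0.2, "c": 0.3})
        res = apg.permutation_median_test(ratios, ["a", "b", "c"],
                                          n_perm=100, seed=0)
        assert res.p_ge == res.p_le == 1.0

    def test_matches_exhaustive_enumeration_on_tiny_universe(self):
        ratios = pd.Series({f"g{i}": v for i, v in
                            enumerate([0.1, 0.2, 0.3, 0.4, 0.5, 0.9])})
        gene_set = ["g3", "g4", "g5"]  # observed median is the unique max
        observed = float(ratios[gene_set].median())
        exact_ge = sum(
            float(np.median([ratios[f"g{i}"] for i in subset])) >= observed
            for subset in combinations(range(6), 3)) / 20
        res = apg.permutation_median_test(ratios, gene_set, n_perm=20_000,
                                          seed=3)
        se = math.sqrt(exact_ge * (1 - exact_ge) / 20_000)
        assert abs(res.p_ge - exact_ge) <= 4 * se + 1e-9

    def test_seed_stability_bound(self, pipeline):
        table = apg.ha_hs_table(pipeline.coding_counts)
        ratios = apg.gene_mean_ratios(table)
        classes = pipeline.dataset.truth.gene_classes
        low = [g for g in ratios.index if classes[g] == "low"]
        p1 = apg.permutation_median_test(ratios, low, 5000, seed=1).p_le
        p2 = apg.permutation_median_test(ratios, low, 5000, seed=2).p_le
        p = max(p1, p2, 1 / 5000)
        assert abs(p1 - p2) <= 3 * math.sqrt(p * (1 - p) / 5000) + 1e-9

    def test_unknown_gene_and_oversized_set_rejected(self):
        ratios = pd.Series({"a": 0.1, "b": 0.2})
        with pytest.raises(KeyError):
            apg.permutation_median_test(ratios, ["zz"], 10, seed=0)
        with pytest.raises(ValueError):
            apg.permutation_median_test(ratios, ["a", "b", "a"][:3] * 2,
                                        10, seed=0)


class TestWilcoxonExact:
    def test_all_positive_n8(self):
        pairs = [(i + 1.0, 0.0) for i in range(8)]
        assert apg.wilcoxon_signed_rank_exact(pairs) == pytest.approx(
            2 / 256)

    def test_single_pair_is_uninformative(self):
        assert apg.wilcoxon_signed_rank_exact([(3.0, 1.0)]) == 1.0

    def test_all_zero_differences_undefined(self):
        with pytest.raises(ValueError):
            apg.wilcoxon_signed_rank_exact([(1.0, 1.0), (2.0, 2.0)])

    def test_matches_sign_enumeration_oracle(self, rng):
        d = rng.normal(0.3, 1.0, 6).round(2)
        d = d[d != 0]
        ranks = rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = [sum(r for r, s in zip(ranks, signs) if s)
              for signs in product([True, False], repeat=len(d))]
        n = len(ws)
        p_le = sum(w <= w_obs for w in ws) / n
        p_ge = sum(w >= w_obs for w in ws) / n
        expected = min(1.0, 2 * min(p_le, p_ge))
        pairs = [(x, 0.0) for x in d]
        assert apg.wilcoxon_signed_rank_exact(pairs) == pytest.approx(expected)

    def test_agrees_with_scipy_exact_without_ties(self):
        x = [2.1, -0.7, 3.3, 1.2, -0.4, 0.9, 2.8, -1.6]
        pairs = [(v, 0.0) for v in x]
        ours = apg.wilcoxon_signed_rank_exact(pairs)
        ref = wilcoxon(x, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(ref, rel=1e-9)
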