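"""Hudson F_ST against the closed-form expression, gene-level aggregation,
locus/sweep detection on constructed scenarios, Jaccard allele profiles, and
the Mantel permutation test (cross-checked against scikit-bio)."""

import math

import numpy as np
import pandas as pd
import pytest

from strainpop import differentiation as df_
from strainpop.io import GeneModel, GenomeAnnotation


def hudson_formula(p1, n1, p2, n2):
    hw = (2 * p1 * (1 - p1) * n1 / (n1 - 1) + 2 * p2 * (1 - p2) * n2 / (n2 - 1)) / 2
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    return 1 - hw / hb


class TestSiteFst:
    def test_fixed_difference_is_one(self):
        assert df_.site_fst(1.0, 1e9, 0.0, 1e9) == pytest.approx(1.0)

    def test_equal_frequencies_near_zero(self):
        # small negative bias -1/(n-1) at finite coverage, exactly 0 as n->inf
        val = df_.site_fst(0.5, 20, 0.5, 20)
        assert val == pytest.approx(-1 / 19)
        assert df_.site_fst(0.5, 1e9, 0.5, 1e9) == pytest.approx(0.0, abs=1e-6)

    def test_hand_computed_large_n(self):
        # p1=0.9, p2=0.1: 1 - 0.18/0.82 = 0.7805
        assert df_.site_fst(0.9, 1e9, 0.1, 1e9) == pytest.approx(0.7805, abs=1e-4)

    def test_matches_formula_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p1, p2 = rng.random(2)
            n1, n2 = rng.integers(20, 200, size=2)
            expect = hudson_formula(p1, n1, p2, n2)
            got = df_.site_fst(p1, n1, p2, n2)
            if math.isnan(got):
                assert p1 + p2 in (0.0, 2.0)
            else:
                assert got == pytest.approx(expect)

    def test_symmetry_and_allele_relabeling(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p1, p2 = rng.random(2)
            n1, n2 = rng.integers(20, 100, size=2)
            a = df_.site_fst(p1, n1, p2, n2)
            assert df_.site_fst(p2, n2, p1, n1) == pytest.approx(a, nan_ok=True)
            assert df_.site_fst(1 - p1, n1, 1 - p2, n2) == pytest.approx(a, nan_ok=True)

    def test_coverage_gate(self):
        assert math.isnan(df_.site_fst(0.9, 19, 0.1, 100))


def snps_for_fst(entries):
    rows = []
    for pos, gene, p1, n1, p2, n2 in entries:
        rows.append(
            {
                "species": "s", "contig": "c1", "pos": pos, "ref": "A",
                "major": "A", "minor": "G", "gene_id": gene,
                "effect_class": "S",
                "freq_WW1": p1, "cov_WW1": n1, "freq_WW2": p2, "cov_WW2": n2,
            }
        )
    return pd.DataFrame(rows)


class TestGeneFst:
    def test_single_site_gene_reduces_to_site_fst(self):
        snps = snps_for_fst([(10, "g1", 0.9, 50, 0.2, 60)])
        sites = df_.site_fst_table(snps, "WW1", "WW2")
        genes = df_.gene_fst(sites)
        expect = min(max(hudson_formula(0.9, 50, 0.2, 60), 0.0), 1.0)
        assert genes.iloc[0]["fst"] == pytest.approx(expect)
        assert genes.iloc[0]["n_sites_used"] == 1

    def test_identical_frequencies_give_zero(self):
        snps = snps_for_fst([(i, "g1", 0.5, 100, 0.5, 100) for i in range(5)])
        genes = df_.gene_fst(df_.site_fst_table(snps, "WW1", "WW2"))
        assert genes.iloc[0]["fst"] == 0.0  # small negative bias clamped

    def test_ratio_of_averages_not_average_of_ratios(self):
        entries = [(1, "g1", 0.9, 40, 0.1, 40), (2, "g1", 0.55, 40, 0.45, 40)]
        snps = snps_for_fst(entries)
        sites = df_.site_fst_table(snps, "WW1", "WW2")
        genes = df_.gene_fst(sites)
        hw = sum(
            (2 * p1 * (1 - p1) * n1 / (n1 - 1) + 2 * p2 * (1 - p2) * n2 / (n2 - 1)) / 2
            for _, _, p1, n1, p2, n2 in entries
        )
        hb = sum(
            p1 * (1 - p2) + p2 * (1 - p1) for _, _, p1, n1, p2, n2 in entries
        )
        assert genes.iloc[0]["fst"] == pytest.approx(1 - hw / hb)

    def test_low_coverage_sites_skipped(self):
        snps = snps_for_fst(
            [(1, "g1", 0.9, 19, 0.1, 100), (2, "g1", 0.8, 50, 0.2, 50)]
        )
        genes = df_.gene_fst(df_.site_fst_table(snps, "WW1", "WW2"))
        assert genes.iloc[0]["n_sites_used"] == 1

    def test_clamped_into_unit_interval(self, community):
        snps = community["snps"]
        pops = community["truth"].populations
        sites = df_.site_fst_table(snps, pops[0], pops[1])
        genes = df_.gene_fst(sites)
        assert len(genes)
        assert genes["fst"].between(0, 1).all()


def make_gene_annotation(n_genes, gene_len=90, gap=10):
    genes, seqs = [], []
    pos = 1
    rng = np.random.default_rng(0)
    for i in range(n_genes):
        seqs.append("".join(rng.choice(list("ACGT"), size=gap)))
        start = pos + gap
        cds = "ATG" + "AAA" * (gene_len // 3 - 2) + "TAA"
        seqs.append(cds)
        genes.append(GeneModel(f"g{i}", "c1", start, start + gene_len - 1, "+"))
        pos = start + gene_len - 1 + 1 - 1 + 1
        pos = start + gene_len
    contig = "".join(seqs)
    return GenomeAnnotation("s", {"c1": contig}, genes)


class TestLoci:
    def _gene_table(self, fsts):
        return pd.DataFrame(
            {
                "species": "s",
                "pop_a": "WW1",
                "pop_b": "WW2",
                "gene_id": [f"g{i}" for i in range(len(fsts))],
                "fst": fsts,
                "n_sites_used": 5,
            }
        )

    def test_flat_background_yields_no_loci(self):
        ann = make_gene_annotation(40)
        rng = np.random.default_rng(2)
        loci = df_.high_fst_loci(
            self._gene_table(rng.normal(0.05, 0.02, 40)), ann, pd.DataFrame()
        )
        assert len(loci) == 0

    def test_constructed_run_detected(self):
        ann = make_gene_annotation(40)
        fsts = list(np.random.default_rng(3).normal(0.05, 0.02, 40))
        fsts[10:13] = [0.9, 0.9, 0.9]
        loci = df_.high_fst_loci(self._gene_table(fsts), ann, pd.DataFrame())
        assert len(loci) == 1
        assert loci.iloc[0]["gene_ids"] == "g10,g11,g12"
        assert loci.iloc[0]["mean_fst"] == pytest.approx(0.9)

    def test_short_run_not_reported(self):
        ann = make_gene_annotation(40)
        fsts = list(np.random.default_rng(3).normal(0.05, 0.02, 40))
        fsts[10:12] = [0.9, 0.9]
        loci = df_.high_fst_loci(self._gene_table(fsts), ann, pd.DataFrame())
        assert len(loci) == 0

    def test_too_few_genes_refused(self):
        ann = make_gene_annotation(10)
        with pytest.raises(ValueError, match="refused"):
            df_.high_fst_loci(
                self._gene_table([0.05] * 10), ann, pd.DataFrame()
            )

    def test_locus_tests_and_sweep_flag(self):
        """A locus with depressed diversity and elevated linkage relative to
        the genome background is flagged as a sweep; one with elevated
        diversity is not."""
        ann = make_gene_annotation(40)
        fsts = list(np.full(40, 0.05) + np.linspace(0, 0.01, 40))
        fsts[10:13] = [0.9, 0.9, 0.9]
        locus_lo, locus_hi = ann.genes[10].start, ann.genes[12].end
        rng = np.random.default_rng(4)
        pos = np.arange(1, ann.genome_length, 7)
        in_locus = (pos >= locus_lo) & (pos <= locus_hi)
        pi_vals = np.where(in_locus, 0.0005, 0.02) + rng.normal(0, 1e-4, len(pos))
        dp_vals = np.where(in_locus, 0.99, 0.5) + rng.normal(0, 1e-3, len(pos))
        site_pi = pd.DataFrame({"contig": "c1", "pos": pos, "pi": pi_vals})
        site_dp = pd.DataFrame({"contig": "c1", "pos": pos, "d_prime": dp_vals})
        loci = df_.high_fst_loci(
            self._gene_table(fsts), ann, pd.DataFrame(), site_pi, site_dp
        )
        flagged = df_.sweep_candidates(loci)
        assert len(flagged) == 1 and bool(flagged.iloc[0]["sweep_flag"])

        # same locus but with diversity ABOVE the genome mean: no sweep
        pi_up = np.where(in_locus, 0.05, 0.02) + rng.normal(0, 1e-4, len(pos))
        loci2 = df_.high_fst_loci(
            self._gene_table(fsts), ann, pd.DataFrame(),
            pd.DataFrame({"contig": "c1", "pos": pos, "pi": pi_up}), site_dp,
        )
        flagged2 = df_.sweep_candidates(loci2)
        assert not flagged2["sweep_flag"].any()

    def test_no_loci_no_flags(self):
        out = df_.sweep_candidates(pd.DataFrame())
        assert len(out) == 0


class TestDissimilarityAndMantel:
    def test_identical_columns_zero_dissimilarity(self):
        mat = pd.DataFrame({"WW1": [0.9, 0.2, 0.8], "WW2": [0.9, 0.2, 0.8]})
        d = df_.allele_profile_dissimilarity(mat)
        assert d.loc["WW1", "WW2"] == 0.0

    def test_disjoint_profiles_full_dissimilarity(self):
        mat = pd.DataFrame({"WW1": [0.9, 0.9], "WW2": [0.1, 0.1]})
        d = df_.allele_profile_dissimilarity(mat)
        assert d.loc["WW1", "WW2"] == 1.0

    def test_mantel_self_correlation(self):
        rng = np.random.default_rng(5)
        x = rng.random((6, 6))
        m = (x + x.T) / 2
        np.fill_diagonal(m, 0)
        r, p = df_.mantel(m, m, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_mantel_matches_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

        rng = np.random.default_rng(6)
        def sym(x):
            m = (x + x.T) / 2
            np.fill_diagonal(m, 0)
            return m
        a = sym(rng.random((8, 8)))
        b = sym(rng.random((8, 8)))
        r, p = df_.mantel(a, b, n_perm=999, seed=1)
        r_sk = skbio_mantel(
            DistanceMatrix(a), DistanceMatrix(b), method="pearson",
            permutations=999, alternative="two-sided",
        )[0]
        assert r == pytest.approx(float(r_sk), abs=1e-9)

    def test_mantel_shape_mismatch(self):
        with pytest.raises(ValueError):
            df_.mantel(np.zeros((3, 3)), np.zeros((4, 4)))

    def test_mean_gene_fst_reports_both_conventions(self):
        gt = pd.DataFrame(
            {
                "pop_a": ["WW1", "WW1", "WW1"],
                "pop_b": ["WW2", "WW2", "WW3"],
                "fst": [0.2, 0.4, 0.9],
            }
        )
        out = df_.mean_gene_fst(gt)
        assert out["mean_all_gene_pairs"] == pytest.approx(0.5)
        assert out["mean_of_pair_means"] == pytest.approx((0.3 + 0.9) / 2)
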