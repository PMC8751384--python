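"""S/N classification against brute-force translation, Nei-Gojobori site
counting, pN/pS arithmetic, the Fisher+BH outlier scan, and the
Kruskal-Wallis/Dunn gene-class comparison."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from strainpop import selection as sel
from strainpop._genetics import BASES, CODON_TO_AA
from strainpop.io import GeneModel


class TestClassifier:
    def test_synonymous_third_position(self):
        assert sel.classify_substitution("TTT", 2, "C") == "S"  # Phe/Phe

    def test_nonsynonymous_third_position(self):
        assert sel.classify_substitution("TTT", 2, "A") == "N"  # Phe -> Leu

    def test_exhaustive_against_biopython_translation(self):
        """All 64 codons x 9 substitutions (576 cases) against independent
        translation with Biopython (table 11)."""
        for codon in map("".join, itertools.product(BASES, repeat=3)):
            for pos in range(3):
                for alt in BASES:
                    if alt == codon[pos]:
                        continue
                    mutated = codon[:pos] + alt + codon[pos + 1 :]
                    aa_ref = str(Seq(codon).translate(table=11))
                    aa_alt = str(Seq(mutated).translate(table=11))
                    expect = "S" if aa_ref == aa_alt else "N"
                    assert sel.classify_substitution(codon, pos, alt) == expect

    def test_minus_strand_gene_classified_on_coding_strand(self, toy_annotation):
        # gene2 coding ATG TTT GGG TGA; genomic pos 36 = coding GGG position 1
        g2 = toy_annotation.genes[1]
        assert sel.classify_snp_effect(g2, 36, "C", "T") == "N"  # Gly -> Arg
        # genomic pos 34 = coding offset 8 = GGG position 3; C->T is coding
        # G->A: GGA, still Gly
        assert sel.classify_snp_effect(g2, 34, "C", "T") == "S"

    def test_stop_read_through_is_nonsynonymous(self):
        assert sel.classify_substitution("TAA", 0, "C") == "N"

    def test_reference_mismatch_detected(self, toy_annotation):
        with pytest.raises(ValueError, match="mismatch"):
            sel.classify_snp_effect(toy_annotation.genes[0], 4, "C", "G")


class TestPotentialSites:
    def test_atg_fully_nonsynonymous(self):
        assert sel.count_potential_sites("ATG") == (3.0, 0.0)

    def test_ttt_one_third_synonymous(self):
        n, s = sel.count_potential_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_conservation_over_random_cds(self):
        rng = np.random.default_rng(1)
        sense = [c for c, aa in CODON_TO_AA.items() if aa != "*"]
        for _ in range(20):
            cds = "".join(rng.choice(sense, size=int(rng.integers(5, 40))))
            n, s = sel.count_potential_sites(cds)
            assert n + s == pytest.approx(len(cds))

    def test_brute_force_enumeration_per_codon(self):
        """Potential-site fractions equal direct enumeration of the 9
        substitutions for every codon."""
        for codon in map("".join, itertools.product(BASES, repeat=3)):
            if CODON_TO_AA[codon] == "*":
                continue
            syn = 0
            for pos in range(3):
                for alt in BASES:
                    if alt == codon[pos]:
                        continue
                    mutated = codon[:pos] + alt + codon[pos + 1 :]
                    syn += CODON_TO_AA[codon] == CODON_TO_AA[mutated]
            n, s = sel.count_potential_sites(codon)
            assert s == pytest.approx(syn / 3)

    def test_internal_stop_error(self):
        with pytest.raises(ValueError, match="internal stop"):
            sel.count_potential_sites("ATGTAAAAATGA", "bad_gene")


class TestPnps:
    def test_hand_example(self):
        # (2/600) / (6/200) = 0.1111
        assert sel.pnps(2, 600, 6, 200) == pytest.approx(0.1111, abs=1e-4)

    def test_zero_nonsynonymous_is_zero(self):
        assert sel.pnps(0, 600, 5, 200) == 0.0

    def test_zero_synonymous_undefined(self):
        assert math.isnan(sel.pnps(3, 600, 0, 200))
        assert math.isnan(sel.pnps(0, 600, 0, 200))


def fisher_tail_by_enumeration(a, b, c, d):
    """One-sided (greater) Fisher p for table [[a,b],[c,d]] by hypergeometric
    enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = math.comb(n, col1)
    p = 0.0
    for x in range(a, min(row1, col1) + 1):
        if col1 - x > n - row1:
            continue
        p += math.comb(row1, x) * math.comb(n - row1, col1 - x) / denom
    return p


class TestPositiveSelectionScan:
    def _stats(self, special=(20, 0), n_genes=50):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(n_genes):
            if i == 0:
                nn, ns = special
            else:
                nn, ns = int(rng.integers(0, 4)), int(rng.integers(4, 10))
            rows.append(
                {
                    "species": "s", "population": "ALL", "gene_id": f"g{i}",
                    "n_nonsyn_snps": nn, "n_syn_snps": ns,
                    "nonsyn_sites": 600.0, "syn_sites": 200.0,
                    "pnps": sel.pnps(nn, 600.0, ns, 200.0),
                }
            )
        return pd.DataFrame(rows)

    def test_all_nonsynonymous_gene_flagged(self):
        out = sel.positive_selection_scan(self._stats())
        assert bool(out.iloc[0]["outlier"])
        assert not out.iloc[1:]["outlier"].any()

    def test_fisher_p_matches_enumeration(self):
        df = self._stats()
        out = sel.positive_selection_scan(df)
        a, b = int(df.iloc[0]["n_nonsyn_snps"]), int(df.iloc[0]["n_syn_snps"])
        c = int(df["n_nonsyn_snps"].sum()) - a
        d = int(df["n_syn_snps"].sum()) - b
        assert out.iloc[0]["p_raw"] == pytest.approx(
            fisher_tail_by_enumeration(a, b, c, d), rel=1e-9
        )

    def test_background_like_gene_not_flagged(self):
        out = sel.positive_selection_scan(self._stats(special=(2, 6)))
        assert not out.iloc[0]["outlier"]

    def test_too_few_genes_refused(self):
        with pytest.raises(ValueError):
            sel.positive_selection_scan(self._stats(n_genes=10))


def test_benjamini_hochberg_step_up_thresholds():
    """p = (0.01, 0.02, 0.04) with m = 3 at alpha 0.05: step-up thresholds
    0.0167/0.0333/0.05 reject all three."""
    from statsmodels.stats.multitest import multipletests

    reject, adj, *_ = multipletests([0.01, 0.02, 0.04], alpha=0.05, method="fdr_bh")
    assert reject.all()
    assert adj.max() <= 0.05


class TestGeneClassComparison:
    def test_identical_distributions_no_signal(self):
        rng = np.random.default_rng(2)
        base = rng.random(10)
        df = pd.DataFrame(
            {
                "gene_class": ["a"] * 10 + ["b"] * 10 + ["c"] * 10,
                "pnps": np.concatenate([base, base, base]),
            }
        )
        out = sel.compare_gene_classes(df, "pnps")
        assert out["p"] > 0.5
        assert (out["pairwise"]["p_adj"] > 0.05).all()
        # all classes share a letter
        letters = set(out["letters"].values())
        assert len(letters) == 1

    def test_disjoint_ranges_strongly_significant(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "gene_class": ["low"] * 10 + ["high"] * 10,
                "pnps": np.concatenate(
                    [rng.uniform(0, 0.1, 10), rng.uniform(10, 11, 10)]
                ),
            }
        )
        out = sel.compare_gene_classes(df, "pnps")
        assert (out["pairwise"]["p_adj"] < 0.01).all()
        assert out["letters"]["low"] != out["letters"]["high"]

    def test_letters_shared_iff_not_significant(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "gene_class": ["a"] * 12 + ["b"] * 12 + ["c"] * 12,
                "pnps": np.concatenate(
                    [
                        rng.uniform(0, 0.2, 12),
                        rng.uniform(0.1, 0.3, 12),   # overlaps a
                        rng.uniform(5, 6, 12),       # far from both
                    ]
                ),
            }
        )
        out = sel.compare_gene_classes(df, "pnps")
        letters = out["letters"]
        for _, row in out["pairwise"].iterrows():
            shared = set(letters[row["class_a"]]) & set(letters[row["class_b"]])
            if row["p_adj"] >= 0.05:
                assert shared
            else:
                assert not shared

    def test_small_class_excluded(self):
        df = pd.DataFrame(
            {
                "gene_class": ["a"] * 10 + ["b"] * 10 + ["tiny"] * 2,
                "pnps": list(range(22)),
            }
        )
        out = sel.compare_gene_classes(df, "pnps")
        assert "tiny" not in out["letters"]


class TestSimulatorRecovery:
    def test_ns_fraction_ordering(self):
        """Genome pN/pS tracks the simulated nonsynonymous fraction."""
        import strainpop as sp
        from strainpop import diversity as dv
        from strainpop import filtering as flt
        from strainpop import simulate as sim

        result = {}
        for nsf in (0.2, 0.8):
            vals = []
            for seed in (31, 32):
                cfg = sp.SimulationConfig(
                    seed=seed, genome_length=15_000, n_genes=15,
                    ns_fraction=nsf, error_rate=0.0, n_populations=2,
                )
                ann = sp.simulate_reference(cfg)
                truth = sp.simulate_haplotypes(ann, cfg)
                sp.assign_population_frequencies(truth, cfg)
                counts = sp.emit_site_counts(truth, cfg, 1)
                pooled = flt.pool_populations(
                    counts, sim.simulated_metadata(truth, 1)
                )
                snps = dv.call_snps(pooled, ann)
                table = sel.gene_selection_table(snps, ann, ["ALL"])
                vals.append(sel.genome_pnps(table))
            result[nsf] = np.mean(vals)
        assert result[0.2] < result[0.8]
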