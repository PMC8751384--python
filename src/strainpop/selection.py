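"""Codon-aware synonymous/nonsynonymous classification, Nei-Gojobori
potential-site counting, pN/pS, positive-selection outlier genes, and
gene-class comparisons.

Site counting is equal-weight Nei-Gojobori (no transition/transversion
bias).  Codons carrying several SNPs are classified per SNP against the
reference codon independently (polymorphism counting, not substitution
paths).  ``pN/pS = (nN/NN)/(nS/NS)``; at the genome level the raw counts are
summed over retained genes before taking the ratio.  A gene with pS = 0 and
pN > 0 gets an undefined marker (NaN with an "inf" flag) and is excluded
from population means, with the number of exclusions logged.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._genetics import BASES, codon_site_fractions, complement, is_synonymous, translate_codon
from .io import GeneModel, GenomeAnnotation

logger = logging.getLogger(__name__)


def classify_substitution(codon: str, pos_in_codon: int, alt_base: str) -> str:
    """'S' if the substituted codon encodes the same amino acid, else 'N'
    (read-through of a stop codon classifies as N)."""
    return "S" if is_synonymous(codon, pos_in_codon, alt_base) else "N"


def classify_snp_effect(
    gene: GeneModel, pos: int, ref_base: str, alt_base: str
) -> str:
    """Classify a SNP inside a CDS on the coding strand.

    ``pos`` is the genomic position; for minus-strand genes the substitution
    is complemented onto the coding strand before lookup.
    """
    off = gene.coding_offset(pos)
    codon = gene.cds[3 * (off // 3) : 3 * (off // 3) + 3]
    pos_in = off % 3
    if gene.strand == "-":
        ref_base, alt_base = complement(ref_base), complement(alt_base)
    if codon[pos_in] != ref_base:
        raise ValueError(
            f"gene {gene.gene_id}: reference base mismatch at {pos} "
            f"({codon[pos_in]} != {ref_base})"
        )
    return classify_substitution(codon, pos_in, alt_base)


def count_potential_sites(cds: str, gene_id: str = "?") -> tuple[float, float]:
    """Nei-Gojobori potential-site counts ``(nonsyn_sites, syn_sites)`` for a
    CDS; their sum is exactly 3 x n_codons.  An internal stop codon is an
    annotation error."""
    if len(cds) % 3 != 0:
        raise ValueError(f"gene {gene_id}: CDS length not multiple of 3")
    nonsyn = syn = 0.0
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if translate_codon(codon) == "*" and i < n_codons - 1:
            raise ValueError(f"gene {gene_id}: internal stop codon at codon {i + 1}")
        n, s = codon_site_fractions(codon)
        nonsyn += n
        syn += s
    return nonsyn, syn


def pnps(n_nonsyn: int, nonsyn_sites: float, n_syn: int, syn_sites: float) -> float:
    """(nN/NN)/(nS/NS).  Returns NaN when undefined: no polymorphisms at all,
    or pS = 0 with pN > 0 (the "infinity" case, flagged by callers)."""
    if nonsyn_sites <= 0 or syn_sites <= 0:
        return math.nan
    if n_syn == 0:
        # pN > 0 is the "infinity" case, pN = 0 the no-data case; both NaN here
        return math.nan
    return (n_nonsyn / nonsyn_sites) / (n_syn / syn_sites)


def gene_selection_table(
    snps: pd.DataFrame, annotation: GenomeAnnotation, populations: list[str]
) -> pd.DataFrame:
    """Per-gene, per-population S/N polymorphism counts and pN/pS.

    A SNP counts for a population when it is polymorphic in that population's
    pooled counts (the ``poly_<pop>`` columns of the SNP table).  Triallelic
    sites (effect_class 'multi') are excluded from the biallelic pN/pS
    machinery.
    """
    site_counts = {
        g.gene_id: count_potential_sites(g.cds, g.gene_id) for g in annotation.genes
    }
    coding = snps[snps["effect_class"].isin(["S", "N"])]
    rows = []
    n_inf = 0
    for g in annotation.genes:
        in_gene = coding[coding["gene_id"] == g.gene_id]
        nn_sites, s_sites = site_counts[g.gene_id]
        for pop in populations:
            col = f"poly_{pop}"
            sub = in_gene[in_gene[col]] if col in in_gene.columns else in_gene.iloc[0:0]
            n_n = int((sub["effect_class"] == "N").sum())
            n_s = int((sub["effect_class"] == "S").sum())
            ratio = pnps(n_n, nn_sites, n_s, s_sites)
            inf_flag = n_s == 0 and n_n > 0
            n_inf += inf_flag
            rows.append(
                {
                    "species": annotation.species_id,
                    "population": pop,
                    "gene_id": g.gene_id,
                    "contig": g.contig_id,
                    "start": g.start,
                    "end": g.end,
                    "gene_class": g.gene_class,
                    "n_nonsyn_snps": n_n,
                    "n_syn_snps": n_s,
                    "nonsyn_sites": nn_sites,
                    "syn_sites": s_sites,
                    "pnps": ratio,
                    "pnps_inf": inf_flag,
                }
            )
    if n_inf:
        logger.info(
            "gene_selection_table: %d gene/population pN/pS undefined (pS=0, "
            "pN>0); excluded from means", n_inf,
        )
    return pd.DataFrame(rows)


def genome_pnps(gene_stats: pd.DataFrame, retained_genes: set[str] | None = None) -> float:
    """Genome-level pN/pS: raw S/N counts and potential sites summed over
    retained genes before taking the ratio."""
    sub = gene_stats
    if retained_genes is not None:
        sub = sub[sub["gene_id"].isin(retained_genes)]
    if not len(sub):
        return math.nan
    n_n = sub["n_nonsyn_snps"].sum()
    n_s = sub["n_syn_snps"].sum()
    nn = sub["nonsyn_sites"].sum()
    ns = sub["syn_sites"].sum()
    if n_s == 0:
        return math.nan
    return (n_n / nn) / (n_s / ns)


def positive_selection_scan(
    gene_stats: pd.DataFrame, alpha: float = 0.05, min_genes: int = 20
) -> pd.DataFrame:
    """Outlier genes under positive selection for one population: Fisher's
    exact test of each gene's (nN, nS) against the rest of the genome,
    one-sided toward excess nonsynonymous polymorphism, Benjamini-Hochberg
    adjusted; outliers must also have gene pN/pS > 1."""
    df = gene_stats.copy()
    if len(df) < min_genes:
        raise ValueError(
            f"positive_selection_scan needs >= {min_genes} genes, got {len(df)}"
        )
    tot_n = df["n_nonsyn_snps"].sum()
    tot_s = df["n_syn_snps"].sum()
    if tot_n + tot_s == 0:
        logger.warning("positive_selection_scan: no polymorphisms; empty scan")
        df["outlier_p"] = np.nan
        df["outlier"] = False
        return df
    pvals = []
    for _, row in df.iterrows():
        table = [
            [row["n_nonsyn_snps"], row["n_syn_snps"]],
            [tot_n - row["n_nonsyn_snps"], tot_s - row["n_syn_snps"]],
        ]
        pvals.append(stats.fisher_exact(table, alternative="greater")[1])
    df["p_raw"] = pvals
    df["outlier_p"] = multipletests(pvals, method="fdr_bh")[1]
    # a gene with pS = 0 but pN > 0 has unbounded pN/pS and satisfies the
    # "above 1" condition even though the ratio itself is undefined
    above_one = (df["pnps"] > 1) | (
        (df["n_syn_snps"] == 0) & (df["n_nonsyn_snps"] > 0)
    )
    df["outlier"] = (df["outlier_p"] < alpha) & above_one
    return df


# ---------------------------------------------------------------------------
# gene-class comparisons (Kruskal-Wallis + Dunn with Holm)
# ---------------------------------------------------------------------------

def dunn_test(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Dunn z statistics on the joint ranks, Holm-adjusted
    two-sided p-values."""
    labels = list(groups)
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    sizes = {g: len(groups[g]) for g in labels}
    ranks = stats.rankdata(values)
    mean_rank = {}
    start = 0
    for g in labels:
        mean_rank[g] = ranks[start : start + sizes[g]].mean()
        start += sizes[g]
    n = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    rows = []
    for a, b in combinations(labels, 2):
        se = math.sqrt(
            (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"class_a": a, "class_b": b, "z": z, "p_raw": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p_raw"], method="holm")[1]
    return out


def _letter_groups(labels: list[str], nonsig_pairs: set[frozenset]) -> dict[str, str]:
    """Compact letter display: classes sharing no significant difference
    share a letter (maximal cliques of the not-significantly-different
    graph)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(labels)
    for pair in nonsig_pairs:
        a, b = tuple(pair)
        g.add_edge(a, b)
    cliques = sorted(
        (sorted(c, key=labels.index) for c in nx.find_cliques(g)),
        key=lambda c: labels.index(c[0]),
    )
    letters: dict[str, str] = {lab: "" for lab in labels}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for lab in clique:
            letters[lab] += letter
    return letters


def compare_gene_classes(
    values: pd.DataFrame,
    metric_col: str,
    class_col: str = "gene_class",
    alpha: float = 0.05,
    min_per_class: int = 3,
) -> dict:
    """Kruskal-Wallis across gene classes followed by Dunn's test with
    Holm correction; returns H, p, the pairwise table, and letter groups
    (classes sharing a letter are not significantly different)."""
    df = values.dropna(subset=[metric_col])
    groups = {
        str(c): grp[metric_col].to_numpy()
        for c, grp in df.groupby(class_col, sort=True)
        if len(grp) >= min_per_class
    }
    skipped = sorted(set(df[class_col].astype(str)) - set(groups))
    if skipped:
        logger.warning("compare_gene_classes: classes excluded (too few genes): %s", skipped)
    if len(groups) < 2:
        raise ValueError("need >= 2 classes with enough genes")
    h, p = stats.kruskal(*groups.values())
    pairwise = dunn_test(groups)
    labels = list(groups)
    nonsig = {
        frozenset((r["class_a"], r["class_b"]))
        for _, r in pairwise.iterrows()
        if r["p_adj"] >= alpha
    }
    return {
        "H": float(h),
        "p": float(p),
        "pairwise": pairwise,
        "letters": _letter_groups(labels, nonsig),
    }
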