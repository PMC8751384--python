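"""Population differentiation: per-site and per-gene F_ST, high-F_ST locus
detection, selective-sweep candidates, allele-profile dissimilarities, and
Mantel tests.

The site estimator is Hudson's, with the small-sample heterozygosity
correction: ``F_ST = 1 - H_w / H_b`` where
``H_w = [2 p1 (1-p1) n1/(n1-1) + 2 p2 (1-p2) n2/(n2-1)] / 2`` and
``H_b = p1 (1-p2) + p2 (1-p1)``.  Multi-site (gene) values are
ratio-of-averages, clamped to [0, 1] with clamp events logged.  Only sites
with coverage >= 20 in both populations enter the calculation.  A Nei G_ST
alternative is provided as a configurable estimator.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def _hudson_components(p1: float, n1: float, p2: float, n2: float) -> tuple[float, float]:
    hw = (
        2 * p1 * (1 - p1) * n1 / (n1 - 1)
        + 2 * p2 * (1 - p2) * n2 / (n2 - 1)
    ) / 2.0
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    return hw, hb


def site_fst(
    p1: float, n1: float, p2: float, n2: float,
    min_cov: int = 20, estimator: str = "hudson",
) -> float:
    """Hudson-style F_ST for one biallelic site from allele frequency and
    coverage in two populations.  Sites below ``min_cov`` coverage in either
    population, or with zero between-population heterozygosity, return NaN
    (skipped, logged by table-level callers)."""
    if n1 < min_cov or n2 < min_cov:
        return math.nan
    if estimator == "hudson":
        hw, hb = _hudson_components(p1, n1, p2, n2)
        if hb <= 0:
            return math.nan
        return 1.0 - hw / hb
    if estimator == "nei":
        hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2.0
        pbar = (p1 + p2) / 2.0
        ht = 2 * pbar * (1 - pbar)
        if ht <= 0:
            return math.nan
        return 1.0 - hs / ht
    raise ValueError(f"unknown estimator '{estimator}'")


def site_fst_table(
    snps: pd.DataFrame,
    pop_a: str,
    pop_b: str,
    min_cov: int = 20,
    estimator: str = "hudson",
) -> pd.DataFrame:
    """Per-site F_ST between two populations over the called SNPs, using the
    ALL-major allele frequency (``freq_*``) and coverage (``cov_*``) columns.
    Sites failing the 20x coverage rule in either population are skipped."""
    need = [f"freq_{pop_a}", f"cov_{pop_a}", f"freq_{pop_b}", f"cov_{pop_b}"]
    missing = [c for c in need if c not in snps.columns]
    if missing:
        raise ValueError(f"SNP table missing columns {missing}")
    p1 = snps[f"freq_{pop_a}"].to_numpy(dtype=float)
    p2 = snps[f"freq_{pop_b}"].to_numpy(dtype=float)
    n1 = snps[f"cov_{pop_a}"].to_numpy(dtype=float)
    n2 = snps[f"cov_{pop_b}"].to_numpy(dtype=float)
    ok = (n1 >= min_cov) & (n2 >= min_cov) & np.isfinite(p1) & np.isfinite(p2)
    n_skip = int((~ok).sum())
    if n_skip:
        logger.info(
            "site_fst_table %s-%s: %d sites below %dx coverage skipped",
            pop_a, pop_b, n_skip, min_cov,
        )
    hw, hb = _hudson_components(p1, np.maximum(n1, 2), p2, np.maximum(n2, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(hb > 0, 1.0 - hw / hb, np.nan)
    if estimator == "nei":
        hs = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2.0
        pbar = (p1 + p2) / 2.0
        ht = 2 * pbar * (1 - pbar)
        with np.errstate(divide="ignore", invalid="ignore"):
            fst = np.where(ht > 0, 1.0 - hs / ht, np.nan)
    out = snps[["species", "contig", "pos", "gene_id"]].copy()
    out["pop_a"], out["pop_b"] = pop_a, pop_b
    out["hw"], out["hb"] = hw, hb
    out["fst"] = np.where(ok, fst, np.nan)
    out.loc[~ok, ["hw", "hb"]] = np.nan
    return out


def gene_fst(site_records: pd.DataFrame) -> pd.DataFrame:
    """Ratio-of-averages gene F_ST: ``1 - sum(H_w)/sum(H_b)`` over a gene's
    qualifying sites, clamped to [0, 1] (clamps logged).  Genes with no
    qualifying site are absent from the output."""
    sub = site_records.dropna(subset=["hw", "hb"])
    sub = sub[(sub["gene_id"] != "") & (sub["hb"] > 0)]
    if not len(sub):
        return pd.DataFrame(
            columns=["species", "pop_a", "pop_b", "gene_id", "fst", "n_sites_used"]
        )
    agg = (
        sub.groupby(["species", "pop_a", "pop_b", "gene_id"], sort=True)
        .agg(hw=("hw", "sum"), hb=("hb", "sum"), n_sites_used=("fst", "size"))
        .reset_index()
    )
    raw = 1.0 - agg["hw"] / agg["hb"]
    clamped = raw.clip(0.0, 1.0)
    n_clamp = int((raw != clamped).sum())
    if n_clamp:
        logger.info("gene_fst: clamped %d gene values into [0, 1]", n_clamp)
    agg["fst"] = clamped
    return agg.drop(columns=["hw", "hb"])


def mean_gene_fst(gene_table: pd.DataFrame) -> dict:
    """Genome summaries of gene F_ST: the mean over all (gene x population
    pair) values and the mean of per-pair means.  Both are reported because
    the aggregation convention is ambiguous in the field."""
    if not len(gene_table):
        return {"mean_all_gene_pairs": math.nan, "mean_of_pair_means": math.nan}
    per_pair = gene_table.groupby(["pop_a", "pop_b"])["fst"].mean()
    return {
        "mean_all_gene_pairs": float(gene_table["fst"].mean()),
        "mean_of_pair_means": float(per_pair.mean()),
    }


# ---------------------------------------------------------------------------
# high-F_ST loci and sweeps
# ---------------------------------------------------------------------------

def high_fst_loci(
    gene_table: pd.DataFrame,
    annotation,
    site_fst_records: pd.DataFrame,
    site_pi: pd.DataFrame | None = None,
    site_dprime: pd.DataFrame | None = None,
    window: int = 3,
    z_thresh: float = 2.0,
    min_genes: int = 30,
) -> pd.DataFrame:
    """Loci of unusually high differentiation for one population pair: runs
    of >= ``window`` consecutive genes (genome order within a contig) whose
    gene F_ST z-score against the genome's gene-F_ST distribution is >=
    ``z_thresh``.  Per locus, a two-sample Wilcoxon (rank-sum) test compares
    locus site-D' with the genomic site-D' background and a two-sample t test
    compares locus site-pi with the genomic background; both families are
    Benjamini-Hochberg adjusted across loci.

    ``site_pi`` columns: contig, pos, pi (for the population pair's pooled
    scope); ``site_dprime`` columns: contig, pos, d_prime.  Missing linkage
    or diversity inputs leave the corresponding p-values NaN.
    """
    pairs = gene_table[["pop_a", "pop_b"]].drop_duplicates()
    if len(pairs) != 1:
        raise ValueError("high_fst_loci expects a single population pair")
    if len(gene_table) < min_genes:
        raise ValueError(
            f"scan refused: only {len(gene_table)} genes with F_ST "
            f"(needs >= {min_genes} for a background)"
        )
    pop_a, pop_b = pairs.iloc[0]
    order = {
        g.gene_id: (g.contig_id, g.start, g.end)
        for g in annotation.genes
    }
    gt = gene_table.copy()
    gt["contig"] = [order[g][0] for g in gt["gene_id"]]
    gt["start"] = [order[g][1] for g in gt["gene_id"]]
    gt["end"] = [order[g][2] for g in gt["gene_id"]]
    gt = gt.sort_values(["contig", "start"]).reset_index(drop=True)
    mu, sd = gt["fst"].mean(), gt["fst"].std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        gt["z"] = 0.0
    else:
        gt["z"] = (gt["fst"] - mu) / sd

    loci = []
    for contig, grp in gt.groupby("contig", sort=True):
        grp = grp.reset_index(drop=True)
        hot = (grp["z"] >= z_thresh).to_numpy()
        i = 0
        while i < len(grp):
            if not hot[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(grp) and hot[j + 1]:
                j += 1
            if j - i + 1 >= window:
                run = grp.iloc[i : j + 1]
                loci.append(
                    {
                        "species": run["species"].iloc[0],
                        "pop_a": pop_a,
                        "pop_b": pop_b,
                        "contig": contig,
                        "gene_ids": ",".join(run["gene_id"]),
                        "start": int(run["start"].min()),
                        "end": int(run["end"].max()),
                        "mean_fst": float(run["fst"].mean()),
                    }
                )
            i = j + 1

    df = pd.DataFrame(
        loci,
        columns=["species", "pop_a", "pop_b", "contig", "gene_ids", "start",
                 "end", "mean_fst"],
    )
    if not len(df):
        df["linkage_test_p"] = pd.Series(dtype=float)
        df["diversity_test_p"] = pd.Series(dtype=float)
        df["locus_pi"] = pd.Series(dtype=float)
        df["locus_dprime"] = pd.Series(dtype=float)
        df["genome_pi"] = pd.Series(dtype=float)
        df["genome_dprime"] = pd.Series(dtype=float)
        return df

    link_p, div_p = [], []
    locus_pi_mean, locus_dp_mean = [], []
    for _, locus in df.iterrows():
        in_locus = lambda t: (
            (t["contig"] == locus["contig"])
            & (t["pos"] >= locus["start"])
            & (t["pos"] <= locus["end"])
        )
        if site_dprime is not None and len(site_dprime):
            inside = site_dprime[in_locus(site_dprime)]["d_prime"].dropna()
            outside = site_dprime[~in_locus(site_dprime)]["d_prime"].dropna()
            if len(inside) >= 2 and len(outside) >= 2:
                link_p.append(
                    stats.mannwhitneyu(inside, outside, alternative="two-sided")[1]
                )
            else:
                link_p.append(np.nan)
            locus_dp_mean.append(inside.mean() if len(inside) else np.nan)
        else:
            link_p.append(np.nan)
            locus_dp_mean.append(np.nan)
        if site_pi is not None and len(site_pi):
            inside = site_pi[in_locus(site_pi)]["pi"].dropna()
            outside = site_pi[~in_locus(site_pi)]["pi"].dropna()
            if len(inside) >= 2 and len(outside) >= 2:
                div_p.append(stats.ttest_ind(inside, outside, equal_var=False)[1])
            else:
                div_p.append(np.nan)
            locus_pi_mean.append(inside.mean() if len(inside) else np.nan)
        else:
            div_p.append(np.nan)
            locus_pi_mean.append(np.nan)

    def bh(p):
        p = np.asarray(p, dtype=float)
        out = np.full_like(p, np.nan)
        ok = np.isfinite(p)
        if ok.sum():
            out[ok] = multipletests(p[ok], method="fdr_bh")[1]
        return out

    df["linkage_test_p"] = bh(link_p)
    df["diversity_test_p"] = bh(div_p)
    df["locus_pi"] = locus_pi_mean
    df["locus_dprime"] = locus_dp_mean
    df["genome_pi"] = (
        float(site_pi["pi"].mean()) if site_pi is not None and len(site_pi) else np.nan
    )
    df["genome_dprime"] = (
        float(site_dprime["d_prime"].mean())
        if site_dprime is not None and len(site_dprime)
        else np.nan
    )
    return df


def sweep_candidates(loci: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Flag loci consistent with a recent selective sweep: significantly low
    diversity (adjusted t-test p < alpha, locus pi below the genome mean) AND
    significantly high linkage (adjusted Wilcoxon p < alpha, locus D' above
    the genome mean)."""
    out = loci.copy()
    if not len(out):
        out["sweep_flag"] = pd.Series(dtype=bool)
        return out
    out["sweep_flag"] = (
        (out["diversity_test_p"] < alpha)
        & (out["locus_pi"] < out["genome_pi"])
        & (out["linkage_test_p"] < alpha)
        & (out["locus_dprime"] > out["genome_dprime"])
    )
    return out


# ---------------------------------------------------------------------------
# allele-profile dissimilarity and Mantel
# ---------------------------------------------------------------------------

def allele_profile_dissimilarity(matrix: pd.DataFrame) -> pd.DataFrame:
    """Jaccard dissimilarity between population columns of a common-SNP
    major-allele frequency matrix.  Entries are binarized as "population
    major allele equals the species-wide major allele" (frequency >= 0.5);
    0 means identical allele profiles."""
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 populations")
    binary = (matrix.to_numpy(dtype=float) >= 0.5).astype(int)
    pops = list(matrix.columns)
    n = len(pops)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = binary[:, i], binary[:, j]
            union = np.logical_or(a, b).sum()
            inter = np.logical_and(a, b).sum()
            d = 0.0 if union == 0 else 1.0 - inter / union
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=pops, columns=pops)


def mantel(
    matrix_a: pd.DataFrame | np.ndarray,
    matrix_b: pd.DataFrame | np.ndarray,
    n_perm: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel test: Pearson correlation of the off-diagonal entries of two
    square symmetric dissimilarity matrices, two-sided significance from
    ``n_perm`` row/column permutations with the observed value included in
    the null set (p >= 1/(n_perm+1))."""
    a = np.asarray(matrix_a, dtype=float)
    b = np.asarray(matrix_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("mantel needs two square matrices of the same shape")
    n = a.shape[0]
    av = squareform(a, checks=False)
    bv = squareform(b, checks=False)
    r_obs = float(np.corrcoef(av, bv)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = b[np.ix_(perm, perm)]
        r = np.corrcoef(av, squareform(bp, checks=False))[0, 1]
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return r_obs, p
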