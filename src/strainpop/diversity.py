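"""SNP calling from pooled counts and nucleotide-diversity statistics.

A site is a SNP when, in the pooled ``ALL`` population, coverage reaches
``min_cov`` and the second-most-common base reaches both ``min_minor_count``
reads and ``min_minor_freq`` frequency.  Those thresholds are not printed in
typical strain-metagenomics reports; they follow common practice and are
exposed as configuration.

Per-site diversity is the unbiased average pairwise difference among sampled
reads, ``pi = n/(n-1) * (1 - sum_b p_b^2)``.  Aggregates divide the summed
site values by the number of *all* gated positions (variant and invariant)
in scope — this denominator choice is what makes genome-scale magnitudes
comparable across populations and is deliberate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .filtering import ALL_POPULATION
from .io import COUNT_COLS, GenomeAnnotation
from .selection import classify_snp_effect

logger = logging.getLogger(__name__)


def pi_site(counts: np.ndarray | list[int]) -> float:
    """Unbiased per-site diversity from base counts (A, C, G, T):
    ``n/(n-1) * (1 - sum p^2)``; NaN when coverage < 2."""
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    if n < 2:
        return float("nan")
    p = c / n
    return float(n / (n - 1.0) * (1.0 - (p**2).sum()))


def site_pi_columns(df: pd.DataFrame) -> pd.Series:
    """Vectorized ``pi_site`` over the count columns of a table."""
    c = df[COUNT_COLS].to_numpy(dtype=float)
    n = c.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p2 = (c / n[:, None]) ** 2
        pi = n / (n - 1.0) * (1.0 - p2.sum(axis=1))
    pi[n < 2] = np.nan
    return pd.Series(pi, index=df.index)


def _gene_lookup(annotation: GenomeAnnotation):
    """(contig, pos) -> gene index map, built once."""
    maps = {}
    for cid, seq in annotation.contigs.items():
        maps[cid] = np.full(len(seq), -1, dtype=int)
    for gi, g in enumerate(annotation.genes):
        maps[g.contig_id][g.start - 1 : g.end] = gi
    return maps


def call_snps(
    pooled: pd.DataFrame,
    annotation: GenomeAnnotation,
    min_cov: int = 5,
    min_minor_count: int = 4,
    min_minor_freq: float = 0.05,
) -> pd.DataFrame:
    """Call biallelic SNPs on the pooled ``ALL`` population and annotate each
    with its gene, effect class, and per-population frequencies.

    Output columns: the ``snps`` schema plus, per population P,
    ``freq_P`` (frequency of the ALL-major allele among P's major+minor
    reads), ``cov_P`` (P's coverage), and ``poly_P`` (whether the site passes
    the same polymorphism thresholds inside P alone).  Sites with three
    alleles passing the minor thresholds keep the top-2 alleles and get
    effect_class ``multi``; reference-N sites are excluded.
    """
    allp = pooled[pooled["population"] == ALL_POPULATION]
    if not len(allp):
        raise ValueError("pooled table has no ALL population")
    counts = allp[COUNT_COLS].to_numpy(dtype=int)
    cov = counts.sum(axis=1)
    order = np.argsort(-counts, axis=1, kind="stable")
    top = np.take_along_axis(counts, order, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        minor_freq = np.where(cov > 0, top[:, 1] / cov, 0.0)
        third_freq = np.where(cov > 0, top[:, 2] / cov, 0.0)
    is_snp = (
        (cov >= min_cov)
        & (top[:, 1] >= min_minor_count)
        & (minor_freq >= min_minor_freq)
        & allp["ref"].isin(list("ACGT")).to_numpy()
    )
    multi = is_snp & (top[:, 2] >= min_minor_count) & (third_freq >= min_minor_freq)

    bases = np.array(list("ACGT"))
    snp = allp.loc[is_snp, ["species", "contig", "pos", "ref"]].reset_index(drop=True)
    snp["major"] = bases[order[is_snp, 0]]
    snp["minor"] = bases[order[is_snp, 1]]
    snp["_multi"] = multi[is_snp]

    lookup = _gene_lookup(annotation)
    gene_ids, effects = [], []
    for _, row in snp.iterrows():
        gi = lookup[row["contig"]][row["pos"] - 1]
        gene = annotation.genes[gi] if gi >= 0 else None
        gene_ids.append(gene.gene_id if gene else "")
        if row["_multi"]:
            effects.append("multi")
        elif gene is None:
            effects.append("intergenic")
        else:
            alt = row["major"] if row["major"] != row["ref"] else row["minor"]
            effects.append(
                classify_snp_effect(gene, int(row["pos"]), row["ref"], alt)
            )
    snp["gene_id"] = gene_ids
    snp["effect_class"] = effects
    snp = snp.drop(columns="_multi")

    # per-population profiles at the called sites
    key = ["species", "contig", "pos"]
    for pop, grp in pooled.groupby("population", sort=True):
        sub = snp[key].merge(grp, on=key, how="left")
        c = sub[COUNT_COLS].fillna(0).to_numpy(dtype=int)
        pcov = c.sum(axis=1)
        maj_idx = np.array([COUNT_COLS.index(b) for b in snp["major"]])
        min_idx = np.array([COUNT_COLS.index(b) for b in snp["minor"]])
        rows = np.arange(len(snp))
        nmaj = c[rows, maj_idx] if len(snp) else np.array([], dtype=int)
        nmin = c[rows, min_idx] if len(snp) else np.array([], dtype=int)
        denom = nmaj + nmin
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = np.where(denom > 0, nmaj / denom, np.nan)
        top2 = np.sort(c, axis=1)[:, ::-1] if len(snp) else c
        poly = (
            (pcov >= min_cov)
            & (top2[:, 1] >= min_minor_count)
            & np.where(pcov > 0, top2[:, 1] / np.maximum(pcov, 1) >= min_minor_freq, False)
        )
        snp[f"freq_{pop}"] = freq
        snp[f"cov_{pop}"] = pcov
        snp[f"poly_{pop}"] = poly
    return snp


def diversity_stats(
    pooled: pd.DataFrame,
    annotation: GenomeAnnotation,
    snps: pd.DataFrame | None = None,
    min_cov: int = 5,
) -> pd.DataFrame:
    """Genome-level diversity per population: pi (summed site pi over the
    number of gated positions, variant + invariant), SNP count and SNPs/Mbp
    against the same denominator, and mean coverage over gated sites."""
    rows = []
    for pop, grp in pooled.groupby("population", sort=True):
        grp = grp[grp["ref"].isin(list("ACGT"))]
        cov = grp[COUNT_COLS].sum(axis=1)
        gated = grp[cov >= max(min_cov, 2)]
        n_gated = len(gated)
        if n_gated == 0:
            rows.append(
                {"species": annotation.species_id, "population": pop, "pi": np.nan,
                 "n_sites": 0, "snp_count": 0, "snps_per_mbp": np.nan,
                 "mean_coverage": np.nan}
            )
            continue
        pi_sum = site_pi_columns(gated).sum()
        snp_count = 0
        if snps is not None and len(snps):
            col = f"poly_{pop}"
            snp_count = int(snps[col].sum()) if col in snps.columns else 0
        rows.append(
            {
                "species": annotation.species_id,
                "population": pop,
                "pi": pi_sum / n_gated,
                "n_sites": n_gated,
                "snp_count": snp_count,
                "snps_per_mbp": snp_count / (n_gated / 1e6),
                "mean_coverage": float(gated[COUNT_COLS].sum(axis=1).mean()),
            }
        )
    return pd.DataFrame(rows)


def gene_pi(
    pooled: pd.DataFrame, annotation: GenomeAnnotation, min_cov: int = 5
) -> pd.DataFrame:
    """Per-gene, per-population diversity and mean coverage (gated sites as
    denominator, as at genome level)."""
    lookup = _gene_lookup(annotation)
    rows = []
    for pop, grp in pooled.groupby("population", sort=True):
        grp = grp[grp["ref"].isin(list("ACGT"))].copy()
        gi = np.array(
            [lookup[c][p - 1] for c, p in zip(grp["contig"], grp["pos"])],
            dtype=int,
        ) if len(grp) else np.array([], dtype=int)
        grp["_gene"] = [annotation.genes[i].gene_id if i >= 0 else "" for i in gi]
        cov = grp[COUNT_COLS].sum(axis=1)
        grp = grp[(grp["_gene"] != "") & (cov >= max(min_cov, 2))]
        grp["_pi"] = site_pi_columns(grp)
        grp["_cov"] = grp[COUNT_COLS].sum(axis=1)
        for gene_id, gg in grp.groupby("_gene", sort=True):
            rows.append(
                {
                    "species": annotation.species_id,
                    "population": pop,
                    "gene_id": gene_id,
                    "pi": gg["_pi"].sum() / len(gg),
                    "coverage": float(gg["_cov"].mean()),
                    "n_sites": len(gg),
                }
            )
    return pd.DataFrame(rows)


def major_allele_matrix(
    snps: pd.DataFrame, min_cov: int = 5
) -> pd.DataFrame:
    """Common-SNP x population matrix of the frequency of the ALL-major
    allele; rows keep only SNPs covered strictly above ``min_cov`` in every
    population (populations other than ALL)."""
    pops = sorted(
        c[len("cov_"):] for c in snps.columns
        if c.startswith("cov_") and c != f"cov_{ALL_POPULATION}"
    )
    if not pops:
        return pd.DataFrame()
    keep = np.ones(len(snps), dtype=bool)
    for pop in pops:
        keep &= snps[f"cov_{pop}"].to_numpy() > min_cov
    sub = snps[keep]
    mat = pd.DataFrame(
        {pop: sub[f"freq_{pop}"].to_numpy() for pop in pops},
        index=pd.MultiIndex.from_arrays(
            [sub["contig"], sub["pos"]], names=["contig", "pos"]
        ),
    )
    return mat


def flag_clonal_expansion(
    stats: pd.DataFrame, pi_ratio: float = 0.1, min_cov: float = 10.0
) -> pd.DataFrame:
    """Flag local populations consistent with clonal expansion: mean coverage
    >= ``min_cov`` and local genome pi <= ``pi_ratio`` x the species-wide
    (ALL) pi."""
    out = stats.copy()
    allrow = out[out["population"] == ALL_POPULATION]
    if not len(allrow) or not np.isfinite(allrow["pi"].iloc[0]) or allrow["pi"].iloc[0] == 0:
        logger.warning("flag_clonal_expansion: species-wide pi is 0 or missing; no flags")
        out["clonal_expansion"] = False
        return out
    species_pi = float(allrow["pi"].iloc[0])
    out["clonal_expansion"] = (
        (out["population"] != ALL_POPULATION)
        & (out["mean_coverage"] >= min_cov)
        & (out["pi"] <= pi_ratio * species_pi)
    )
    return out
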