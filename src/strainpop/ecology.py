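"""Compositional ecology layer: count-zero-multiplicative replacement,
centered log-ratio transform, proportionality rho, permutation-FDR network
extraction, and richness summaries.

Abundance tables are species x sample; all associations are computed on CLR
coordinates, which makes them invariant to per-sample scaling (sequencing
depth).  Zero replacement uses the count-zero-multiplicative convention:
zeros become 0.65 x the sample's smallest nonzero proportion and the nonzero
parts are multiplicatively rescaled so each sample keeps its original total.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def czm_zero_replace(table: pd.DataFrame, delta_frac: float = 0.65) -> pd.DataFrame:
    """Replace zeros per sample (column) by ``delta_frac`` x the smallest
    nonzero proportion of that sample, rescaling the nonzero entries
    multiplicatively so the column total is preserved.  Samples with no
    nonzero entry are an error; tables without zeros pass through unchanged.
    """
    if (table.to_numpy() < 0).any():
        raise ValueError("abundances must be non-negative")
    out = table.astype(float).copy()
    for col in out.columns:
        x = out[col].to_numpy(dtype=float)
        total = x.sum()
        if total == 0:
            raise ValueError(f"sample '{col}' is entirely zero")
        zeros = x == 0
        if not zeros.any():
            continue
        delta = delta_frac * x[~zeros].min()
        replaced_mass = delta * zeros.sum()
        scale = (total - replaced_mass) / total
        x = x * scale
        x[zeros] = delta
        out[col] = x
    return out


def clr(table: pd.DataFrame) -> pd.DataFrame:
    """Centered log-ratio transform per sample (column): log x_i minus the
    mean log of the sample; each transformed sample sums to 0."""
    x = table.to_numpy(dtype=float)
    if (x <= 0).any():
        raise ValueError(
            "CLR needs strictly positive entries; run czm_zero_replace first"
        )
    logx = np.log(x)
    return pd.DataFrame(
        logx - logx.mean(axis=0, keepdims=True),
        index=table.index,
        columns=table.columns,
    )


def proportionality_rho(clr_table: pd.DataFrame) -> pd.DataFrame:
    """Proportionality rho between species pairs across samples:
    ``rho(i, j) = 1 - var(clr_i - clr_j) / (var(clr_i) + var(clr_j))``
    with sample variance (ddof=1).  Zero-variance species yield NaN for
    their pairs (logged)."""
    if clr_table.shape[1] < 3:
        raise ValueError("need >= 3 samples for proportionality")
    x = clr_table.to_numpy(dtype=float)
    var = x.var(axis=1, ddof=1)
    flat = np.where(var == 0)[0]
    if len(flat):
        logger.warning(
            "proportionality_rho: %d zero-variance species; their pairs are NaN",
            len(flat),
        )
    n = x.shape[0]
    xc = x - x.mean(axis=1, keepdims=True)
    cov = xc @ xc.T / (x.shape[1] - 1)
    denom = var[:, None] + var[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = 1.0 - (var[:, None] + var[None, :] - 2 * cov) / denom
    rho[denom == 0] = np.nan
    rho[flat, :] = np.nan
    rho[:, flat] = np.nan
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=clr_table.index, columns=clr_table.index)


def rho_pairs(rho: pd.DataFrame) -> pd.DataFrame:
    """Upper-triangle long form of a rho matrix."""
    species = list(rho.index)
    rows = []
    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            rows.append(
                {"source": species[i], "target": species[j],
                 "rho": float(rho.iloc[i, j])}
            )
    return pd.DataFrame(rows, columns=["source", "target", "rho"])


def network_edges(
    clr_table: pd.DataFrame,
    cutoff: float = 0.56,
    fdr_target: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Co-occurrence edges: species pairs with rho > ``cutoff``, plus a
    permutation estimate of the false-discovery rate at a grid of cutoffs.

    The FDR at a cutoff is the mean number of above-cutoff pairs after
    permuting each species' sample labels independently, divided by the
    observed number (NaN when nothing is observed above the cutoff).  Node
    sizes are mean CLR abundances.  The estimated FDR at the chosen cutoff is
    compared against ``fdr_target`` and a warning logged if it exceeds it.
    """
    rho = proportionality_rho(clr_table)
    pairs = rho_pairs(rho)
    edges = pairs[pairs["rho"] > cutoff].reset_index(drop=True)

    rng = np.random.default_rng(seed)
    x = clr_table.to_numpy(dtype=float)
    n_species, n_samples = x.shape
    cut_grid = sorted({round(c, 2) for c in np.arange(0.05, 1.0, 0.05)} | {cutoff})
    iu = np.triu_indices(n_species, k=1)
    obs_vals = rho.to_numpy()[iu]
    perm_counts = np.zeros(len(cut_grid))
    for _ in range(n_perm):
        xp = np.empty_like(x)
        for i in range(n_species):
            xp[i] = x[i, rng.permutation(n_samples)]
        rp = proportionality_rho(
            pd.DataFrame(xp, index=clr_table.index, columns=clr_table.columns)
        ).to_numpy()[iu]
        for k, c in enumerate(cut_grid):
            perm_counts[k] += np.nansum(rp > c)
    fdr_rows = []
    for k, c in enumerate(cut_grid):
        observed = int(np.nansum(obs_vals > c))
        mean_perm = perm_counts[k] / n_perm
        fdr = mean_perm / observed if observed > 0 else np.nan
        fdr_rows.append({"cutoff": c, "n_observed": observed,
                         "mean_permuted": mean_perm, "fdr": fdr})
    fdr_table = pd.DataFrame(fdr_rows)
    at_cut = fdr_table.loc[fdr_table["cutoff"] == round(cutoff, 2), "fdr"]
    fdr_at_cutoff = float(at_cut.iloc[0]) if len(at_cut) else np.nan
    if np.isfinite(fdr_at_cutoff) and fdr_at_cutoff > fdr_target:
        logger.warning(
            "network_edges: estimated FDR %.3f at cutoff %.2f exceeds target %.2f",
            fdr_at_cutoff, cutoff, fdr_target,
        )
    node_sizes = clr_table.mean(axis=1)
    return {
        "edges": edges,
        "fdr_table": fdr_table,
        "fdr_at_cutoff": fdr_at_cutoff,
        "node_sizes": node_sizes,
        "rho": rho,
    }


def richness(table: pd.DataFrame, threshold: float = 0.5) -> pd.Series:
    """Number of species strictly above ``threshold`` (percent relative
    abundance) per sample."""
    return (table > threshold).sum(axis=0)
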