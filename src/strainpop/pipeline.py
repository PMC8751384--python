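"""End-to-end orchestration: one config drives simulation (or input
loading), gating, pooling, SNP calling, diversity, linkage, selection,
differentiation and ecology, and writes every result table plus a manifest
(package version, thresholds, input checksums, stage status).

All randomness flows from the single root seed; each simulator stage derives
its own stream from it, so partial reruns are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import diversity as dv
from . import differentiation as df_
from . import ecology as eco
from . import filtering as flt
from . import io as sio
from . import linkage as lk
from . import selection as sel
from . import simulate as sim

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every stage threshold of the pipeline, with the documented defaults.

    When ``simulate`` is set (a mapping of SimulationConfig fields), inputs
    are generated; otherwise ``reference_fasta``/``reference_gff``/
    ``sitecounts``/``metadata`` must point to files, and read-level filters
    are assumed pre-applied to the sitecounts.
    """

    outdir: str = "strainpop_out"
    seed: int = 0
    reference_fasta: str | None = None
    reference_gff: str | None = None
    sitecounts: str | None = None
    metadata: str | None = None
    abundance: str | None = None
    simulate: dict | None = None
    samples_per_population: int = 2
    min_breadth: float = 0.5
    min_depth: int = 5
    snp_min_cov: int = 5
    snp_min_minor_count: int = 4
    snp_min_minor_freq: float = 0.05
    gene_gate_sd: float = 2.0
    fst_min_cov: int = 20
    fst_estimator: str = "hudson"
    locus_window: int = 3
    locus_z: float = 2.0
    locus_min_genes: int = 30
    linkage_max_dist: int = 500
    linkage_min_pair_cov: int = 10
    clonal_pi_ratio: float = 0.1
    clonal_min_cov: float = 10.0
    rho_cutoff: float = 0.56
    fdr_target: float = 0.05
    ecology_n_perm: int = 200
    run_linkage: bool = True
    run_selection: bool = True
    run_fst: bool = True
    run_ecology: bool = True

    def __post_init__(self):
        if not 0 <= self.min_breadth <= 1:
            raise ValueError("min_breadth must be in [0, 1]")
        if not 0 <= self.snp_min_minor_freq <= 1:
            raise ValueError("snp_min_minor_freq must be in [0, 1]")
        if self.fst_estimator not in ("hudson", "nei"):
            raise ValueError("fst_estimator must be 'hudson' or 'nei'")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run every enabled stage and write the artifact directory.  Any stage
    failure leaves partial outputs plus a manifest marking the failure point
    and re-raises."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "thresholds": dataclasses.asdict(config),
        "inputs": {},
        "stages": {},
        "entry_point": "simulated" if config.simulate is not None else
                       "sitecounts (read filters assumed pre-applied)",
    }
    stage = "init"
    try:
        # --- inputs -------------------------------------------------------
        stage = "inputs"
        truth = None
        reads = None
        if config.simulate is not None:
            simcfg = sim.SimulationConfig(seed=config.seed, **config.simulate)
            ann = sim.simulate_reference(simcfg)
            truth = sim.simulate_haplotypes(ann, simcfg)
            sim.assign_population_frequencies(truth, simcfg)
            counts = sim.emit_site_counts(truth, simcfg, config.samples_per_population)
            meta = sim.simulated_metadata(truth, config.samples_per_population)
            sio.write_annotation(ann, out / "reference.fasta", out / "reference.gff")
            sio.write_site_counts(counts, out / "sitecounts.tsv")
            meta.to_csv(out / "metadata.tsv", sep="\t", index=False)
            sio.write_table(truth.site_table(), out / "truth_sites.tsv", "truth")
            truth.frequency_table().to_csv(out / "truth_frequencies.tsv", sep="\t")
            if config.run_linkage:
                reads = sim.emit_reads(truth, simcfg, config.samples_per_population)
        else:
            for name in ("reference_fasta", "reference_gff", "sitecounts", "metadata"):
                p = getattr(config, name)
                if p is None:
                    raise ValueError(f"config.{name} is required without simulate")
                manifest["inputs"][name] = _sha256(Path(p))
            ann = sio.read_reference(config.reference_fasta, config.reference_gff)
            counts = sio.read_site_counts(config.sitecounts)
            meta = sio.read_metadata(config.metadata)
        manifest["stages"][stage] = "ok"

        # --- gating and pooling ------------------------------------------
        stage = "gate_pool"
        lengths = {ann.species_id: ann.genome_length}
        gate = flt.gate_report(counts, lengths, config.min_breadth, config.min_depth)
        gate.to_csv(out / "gate_report.tsv", sep="\t", index=False)
        pooled = flt.pool_populations(counts, meta, gate)
        manifest["stages"][stage] = "ok"

        # --- SNPs and diversity ------------------------------------------
        stage = "snps_diversity"
        snps = dv.call_snps(
            pooled, ann, config.snp_min_cov, config.snp_min_minor_count,
            config.snp_min_minor_freq,
        )
        sio.write_table(snps, out / "snps.tsv", "snps")
        gstats = dv.diversity_stats(pooled, ann, snps, config.snp_min_cov)
        gstats = dv.flag_clonal_expansion(
            gstats, config.clonal_pi_ratio, config.clonal_min_cov
        )
        gene_pi = dv.gene_pi(pooled, ann, config.snp_min_cov)
        matrix = dv.major_allele_matrix(snps, config.snp_min_cov)
        if len(matrix):
            matrix.to_csv(out / "major_allele_matrix.tsv", sep="\t")
        manifest["stages"][stage] = "ok"

        populations = sorted(pooled["population"].unique())
        real_pops = [p for p in populations if p != flt.ALL_POPULATION]

        # --- gene coverage gate ------------------------------------------
        stage = "gene_gate"
        gene_gate = flt.gate_gene_coverage(
            gene_pi[["population", "gene_id", "coverage"]], config.gene_gate_sd
        )
        retained = {
            pop: set(grp.loc[grp["retained"], "gene_id"])
            for pop, grp in gene_gate.groupby("population")
        }
        manifest["stages"][stage] = "ok"

        # --- linkage ------------------------------------------------------
        stage = "linkage"
        pairs = pd.DataFrame()
        dp_aggregate = pd.DataFrame(columns=["population", "d_prime", "n_pairs"])
        if config.run_linkage and reads is not None:
            pairs = lk.collect_pair_observations(
                reads, snps, config.linkage_max_dist, config.linkage_min_pair_cov
            )
            pairs.to_csv(out / "linkage_pairs.tsv", sep="\t", index=False)
            dp_aggregate = lk.d_prime_aggregate(pairs)
            dp_aggregate.to_csv(out / "dprime_aggregate.tsv", sep="\t", index=False)
        manifest["stages"][stage] = "ok" if config.run_linkage else "skipped"

        # --- selection ----------------------------------------------------
        stage = "selection"
        gene_sel = pd.DataFrame()
        pnps_by_pop: dict[str, float] = {}
        if config.run_selection:
            gene_sel = sel.gene_selection_table(snps, ann, populations)
            for pop in populations:
                sub = gene_sel[gene_sel["population"] == pop]
                pnps_by_pop[pop] = sel.genome_pnps(sub, retained.get(pop))
            try:
                scan = sel.positive_selection_scan(
                    gene_sel[gene_sel["population"] == flt.ALL_POPULATION]
                )
                scan.to_csv(out / "positive_selection.tsv", sep="\t", index=False)
            except ValueError as exc:
                logger.warning("positive_selection_scan skipped: %s", exc)
        manifest["stages"][stage] = "ok" if config.run_selection else "skipped"

        # --- gene_stats table ---------------------------------------------
        stage = "gene_stats"
        gene_dp = _per_gene_dprime(pairs, ann) if len(pairs) else {}
        gene_stats = _assemble_gene_stats(ann, gene_pi, gene_sel, gene_dp)
        sio.write_table(gene_stats, out / "gene_stats.tsv", "gene_stats")
        manifest["stages"][stage] = "ok"

        # --- differentiation ----------------------------------------------
        stage = "fst"
        if config.run_fst and len(real_pops) >= 2 and len(snps):
            fst_genes, loci_all = [], []
            for i, pa in enumerate(real_pops):
                for pb in real_pops[i + 1 :]:
                    site_tab = df_.site_fst_table(
                        snps, pa, pb, config.fst_min_cov, config.fst_estimator
                    )
                    gf = df_.gene_fst(site_tab)
                    keep = retained.get(pa, set()) & retained.get(pb, set())
                    gf = gf[gf["gene_id"].isin(keep)]
                    fst_genes.append(gf)
                    try:
                        site_pi_tab = _pair_site_pi(pooled, [pa, pb], config.snp_min_cov)
                        site_dp = (
                            lk.site_d_prime(pairs[pairs["population"] == "ALL"])
                            if len(pairs)
                            else None
                        )
                        loci = df_.high_fst_loci(
                            gf.assign(pop_a=pa, pop_b=pb), ann, site_tab,
                            site_pi_tab, site_dp, config.locus_window,
                            config.locus_z, config.locus_min_genes,
                        )
                        loci_all.append(df_.sweep_candidates(loci))
                    except ValueError as exc:
                        logger.warning("locus scan %s-%s skipped: %s", pa, pb, exc)
            fst_table = (
                pd.concat(fst_genes, ignore_index=True) if fst_genes else pd.DataFrame()
            )
            if len(fst_table):
                sio.write_table(fst_table, out / "fst_genes.tsv", "fst_pairs")
                manifest["mean_gene_fst"] = df_.mean_gene_fst(fst_table)
            if loci_all:
                loci_table = pd.concat(loci_all, ignore_index=True)
                sio.write_table(loci_table, out / "loci.tsv", "loci")
            if len(matrix) and matrix.shape[1] >= 2:
                diss = df_.allele_profile_dissimilarity(matrix)
                diss.to_csv(out / "allele_dissimilarity.tsv", sep="\t")
            manifest["stages"][stage] = "ok"
        else:
            manifest["stages"][stage] = "skipped"

        # --- ecology --------------------------------------------------------
        stage = "ecology"
        if config.run_ecology and config.abundance is not None:
            table = sio.read_abundance(config.abundance)
            manifest["inputs"]["abundance"] = _sha256(Path(config.abundance))
            comp = eco.czm_zero_replace(table)
            clr_tab = eco.clr(comp)
            net = eco.network_edges(
                clr_tab, config.rho_cutoff, config.fdr_target,
                config.ecology_n_perm, config.seed,
            )
            sio.write_table(net["edges"], out / "network_edges.tsv", "network_edges")
            net["fdr_table"].to_csv(out / "network_fdr.tsv", sep="\t", index=False)
            rel = table / table.sum(axis=0) * 100.0
            eco.richness(rel).rename("richness").to_csv(out / "richness.tsv", sep="\t")
            manifest["stages"][stage] = "ok"
        else:
            manifest["stages"][stage] = "skipped"

        # --- genome_stats + triplet ----------------------------------------
        stage = "report"
        gs = gstats.copy()
        dp_map = dict(zip(dp_aggregate["population"], dp_aggregate["d_prime"]))
        gs["dprime"] = gs["population"].map(dp_map).astype(float)
        gs["pnps"] = gs["population"].map(pnps_by_pop).astype(float)
        sio.write_table(gs, out / "genome_stats.tsv", "genome_stats")
        triplet_report(gs).to_csv(out / "triplet_report.tsv", sep="\t", index=False)
        manifest["stages"][stage] = "ok"
    except Exception:
        manifest["stages"][stage] = "FAILED"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _pair_site_pi(pooled: pd.DataFrame, pops: list[str], min_cov: int) -> pd.DataFrame:
    """Site-level diversity over the two populations' pooled counts (used as
    the diversity background for locus tests)."""
    sub = pooled[pooled["population"].isin(pops)]
    merged = (
        sub.groupby(["contig", "pos"], sort=True, as_index=False)[sio.COUNT_COLS].sum()
    )
    cov = merged[sio.COUNT_COLS].sum(axis=1)
    merged = merged[cov >= max(min_cov, 2)].reset_index(drop=True)
    merged["pi"] = dv.site_pi_columns(merged)
    return merged[["contig", "pos", "pi"]]


def _per_gene_dprime(pairs: pd.DataFrame, ann) -> dict[str, float]:
    """Mean D' (ALL population) over pairs whose both sites fall inside a
    gene."""
    out: dict[str, float] = {}
    sub = pairs[pairs["population"] == "ALL"]
    for g in ann.genes:
        in_gene = sub[
            (sub["contig"] == g.contig_id)
            & (sub["site_a"] >= g.start)
            & (sub["site_b"] <= g.end)
        ]
        if len(in_gene):
            out[g.gene_id] = float(in_gene["d_prime"].mean())
    return out


def _assemble_gene_stats(
    ann, gene_pi: pd.DataFrame, gene_sel: pd.DataFrame, gene_dp: dict[str, float]
) -> pd.DataFrame:
    meta = {
        g.gene_id: (g.contig_id, g.start, g.end, g.gene_class) for g in ann.genes
    }
    if len(gene_sel):
        base = gene_sel.copy()
    else:
        base = gene_pi.assign(
            n_nonsyn_snps=np.nan, n_syn_snps=np.nan,
            nonsyn_sites=np.nan, syn_sites=np.nan, pnps=np.nan,
        )[["species", "population", "gene_id", "n_nonsyn_snps", "n_syn_snps",
           "nonsyn_sites", "syn_sites", "pnps"]]
    pi_map = gene_pi.set_index(["population", "gene_id"])
    base["pi"] = [
        pi_map["pi"].get((r["population"], r["gene_id"]), np.nan)
        for _, r in base.iterrows()
    ]
    base["coverage"] = [
        pi_map["coverage"].get((r["population"], r["gene_id"]), np.nan)
        for _, r in base.iterrows()
    ]
    base["dprime"] = base["gene_id"].map(gene_dp).astype(float)
    base["contig"] = [meta[g][0] for g in base["gene_id"]]
    base["start"] = [meta[g][1] for g in base["gene_id"]]
    base["end"] = [meta[g][2] for g in base["gene_id"]]
    base["gene_class"] = [meta[g][3] for g in base["gene_id"]]
    cols = sio.SCHEMAS["gene_stats"]
    return base[[c for c in cols if c in base.columns]].reindex(columns=cols)


def triplet_report(genome_stats: pd.DataFrame) -> pd.DataFrame:
    """Long-format (species x population x metric) table of the headline
    triplet pi / D' / pN/pS; missing metrics stay as NaN rows rather than
    being dropped, so external comparison tables can be joined on."""
    rows = []
    for _, r in genome_stats.iterrows():
        for metric, col in (("pi", "pi"), ("dprime", "dprime"), ("pnps", "pnps")):
            rows.append(
                {
                    "species": r["species"],
                    "population": r["population"],
                    "metric": metric,
                    "value": r[col] if col in r else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["species", "population", "metric", "value"])
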