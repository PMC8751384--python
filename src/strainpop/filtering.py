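"""Read filters, coverage gating, and pooling of samples into populations.

Read-level filtering keeps alignments with mapping quality >= 30, percent
identity >= 96 over aligned columns (soft-clips excluded), and a uniquely
best mapping pair.  Sample x genome combinations enter the analysis only
when at least 50% of the genome is covered at >= 5x.  Retained samples are
pooled by population (waterworks), plus a synthetic ``ALL`` population
summing every retained sample.  When the pipeline starts from a sitecounts
table rather than alignments, read filters are assumed pre-applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import COUNT_COLS, SITECOUNT_COLUMNS, GenomeAnnotation

logger = logging.getLogger(__name__)

ALL_POPULATION = "ALL"


@dataclass
class AlignmentRecordSummary:
    """The fields of one aligned read that the filters consume."""

    read_id: str
    sample_id: str
    contig: str
    pos: int
    mapq: int
    percent_identity: float
    pair_uniquely_best: bool

    def __post_init__(self):
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity must be within [0, 100]")


def filter_alignment_record(
    rec: AlignmentRecordSummary, min_mapq: int = 30, min_identity: float = 96.0
) -> bool:
    """Keep a read iff mapq >= ``min_mapq``, percent identity >=
    ``min_identity`` (both boundaries inclusive), and its pair maps uniquely
    best."""
    return (
        rec.mapq >= min_mapq
        and rec.percent_identity >= min_identity
        and rec.pair_uniquely_best
    )


def percent_identity(aligned_length: int, edit_distance: int) -> float:
    """Identity over aligned columns: (aligned_length - NM) / aligned_length."""
    if aligned_length <= 0:
        raise ValueError("aligned_length must be positive")
    return 100.0 * (aligned_length - edit_distance) / aligned_length


def sitecounts_from_sam(
    sam_path: str,
    annotation: GenomeAnnotation,
    sample_id: str,
    min_mapq: int = 30,
    min_identity: float = 96.0,
) -> pd.DataFrame:
    """Collapse a coordinate-sorted SAM/BAM into a sitecounts table, applying
    the read filters.  Identity uses the NM tag over aligned (matched)
    columns; pair uniqueness is approximated as alignment score strictly
    above the suboptimal score (AS > XS; reads without XS count as unique).
    """
    import pysam

    counts: dict[str, np.ndarray] = {
        cid: np.zeros((len(seq), 4), dtype=int)
        for cid, seq in annotation.contigs.items()
    }
    base_idx = {b: i for i, b in enumerate("ACGT")}
    n_kept = n_seen = 0
    with pysam.AlignmentFile(sam_path) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            n_seen += 1
            stats = read.get_cigar_stats()[0]
            aligned = int(stats[0] + stats[7] + stats[8])  # M + = + X
            if aligned == 0:
                continue
            nm = read.get_tag("NM") if read.has_tag("NM") else 0
            ident = percent_identity(aligned, nm)
            unique = True
            if read.has_tag("AS") and read.has_tag("XS"):
                unique = read.get_tag("AS") > read.get_tag("XS")
            rec = AlignmentRecordSummary(
                read_id=read.query_name,
                sample_id=sample_id,
                contig=read.reference_name,
                pos=read.reference_start + 1,
                mapq=read.mapping_quality,
                percent_identity=ident,
                pair_uniquely_best=unique,
            )
            if not filter_alignment_record(rec, min_mapq, min_identity):
                continue
            n_kept += 1
            arr = counts.get(read.reference_name)
            if arr is None:
                continue
            seq = read.query_sequence
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                b = seq[qpos].upper()
                if b in base_idx:
                    arr[rpos, base_idx[b]] += 1
    logger.info("sitecounts_from_sam: kept %d / %d reads", n_kept, n_seen)
    rows = []
    for cid, seq in annotation.contigs.items():
        arr = counts[cid]
        covered = arr.sum(axis=1) > 0
        pos = np.where(covered)[0]
        rows.append(
            pd.DataFrame(
                {
                    "species": annotation.species_id,
                    "contig": cid,
                    "pos": pos + 1,
                    "ref": [seq[p] for p in pos],
                    "sample": sample_id,
                    "A": arr[pos, 0],
                    "C": arr[pos, 1],
                    "G": arr[pos, 2],
                    "T": arr[pos, 3],
                }
            )
        )
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=SITECOUNT_COLUMNS)
    return out[out["ref"].isin(list("ACGT"))].reset_index(drop=True)


# ---------------------------------------------------------------------------
# coverage gating
# ---------------------------------------------------------------------------

def gate_sample_genome(
    counts: pd.DataFrame,
    genome_length: int,
    species: str | None = None,
    sample: str | None = None,
    min_breadth: float = 0.5,
    min_depth: int = 5,
) -> dict:
    """One gate-report entry: the sample passes iff the fraction of genome
    positions covered at >= ``min_depth`` is >= ``min_breadth`` (both
    boundaries inclusive).  Positions absent from the table count as depth 0.
    """
    if genome_length <= 0:
        raise ValueError("unknown or invalid genome length")
    sub = counts
    if species is not None:
        sub = sub[sub["species"] == species]
    if sample is not None:
        sub = sub[sub["sample"] == sample]
    depth = sub[COUNT_COLS].sum(axis=1)
    n_ok = int((depth >= min_depth).sum())
    frac = n_ok / genome_length
    return {
        "species": species if species is not None else "-",
        "sample": sample if sample is not None else "-",
        "fraction_genome_ge_depth": frac,
        "passed": frac >= min_breadth,
    }


def gate_report(
    counts: pd.DataFrame,
    genome_lengths: dict[str, int],
    min_breadth: float = 0.5,
    min_depth: int = 5,
) -> pd.DataFrame:
    """Gate every (species, sample) combination present in the table."""
    rows = []
    for (species, sample), grp in counts.groupby(["species", "sample"], sort=True):
        if species not in genome_lengths:
            raise ValueError(f"unknown genome length for species '{species}'")
        rows.append(
            gate_sample_genome(
                grp, genome_lengths[species], species, sample, min_breadth, min_depth
            )
        )
    return pd.DataFrame(rows, columns=["species", "sample", "fraction_genome_ge_depth", "passed"])


def pool_populations(
    counts: pd.DataFrame, metadata: pd.DataFrame, gate: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Sum counts of retained samples per population, with the ``sample``
    column replaced by the population id; adds a synthetic ``ALL`` population
    summing every retained sample.  Populations with no retained sample are
    dropped with a log entry."""
    missing = set(counts["sample"]) - set(metadata["sample"])
    if missing:
        raise ValueError(f"samples absent from metadata: {sorted(missing)}")
    retained = counts
    if gate is not None:
        ok = gate[gate["passed"]][["species", "sample"]]
        retained = counts.merge(ok, on=["species", "sample"], how="inner")
        dropped_pops = set(
            metadata.loc[~metadata["sample"].isin(retained["sample"]), "population"]
        ) - set(
            metadata.loc[metadata["sample"].isin(retained["sample"]), "population"]
        )
        if dropped_pops:
            logger.info(
                "pool_populations: populations with zero retained samples "
                "dropped: %s", sorted(dropped_pops)
            )
    pop_of = metadata.set_index("sample")["population"]
    retained = retained.assign(population=retained["sample"].map(pop_of))
    key = ["species", "contig", "pos", "ref"]
    pooled = (
        retained.groupby(key + ["population"], sort=True, as_index=False)[COUNT_COLS]
        .sum()
    )
    allpop = retained.groupby(key, sort=True, as_index=False)[COUNT_COLS].sum()
    allpop["population"] = ALL_POPULATION
    out = pd.concat([pooled, allpop], ignore_index=True)
    return out[key + ["population"] + COUNT_COLS]


def gate_gene_coverage(
    gene_coverage: pd.DataFrame, sd_mult: float = 2.0
) -> pd.DataFrame:
    """Per-population exclusion of genes whose mean coverage lies outside
    ``sd_mult`` standard deviations of that population's per-gene coverage
    distribution.  Expects columns ``population``, ``gene_id``, ``coverage``;
    returns the input with a boolean ``retained`` column.  With fewer than 3
    genes no exclusion is applied (logged)."""
    out = []
    for pop, grp in gene_coverage.groupby("population", sort=True):
        grp = grp.copy()
        if len(grp) < 3:
            logger.warning(
                "gate_gene_coverage: population %s has %d genes; no exclusion",
                pop, len(grp),
            )
            grp["retained"] = True
        else:
            mean = grp["coverage"].mean()
            sd = grp["coverage"].std(ddof=1)
            if sd == 0 or np.isnan(sd):
                grp["retained"] = True
            else:
                grp["retained"] = (grp["coverage"] - mean).abs() <= sd_mult * sd
        out.append(grp)
    return pd.concat(out, ignore_index=True)
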