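"""Shared fixtures: a tiny hand-built annotation (with a minus-strand gene)
and a session-scoped simulated community reused by integration tests."""

import numpy as np
import pandas as pd
import pytest

import strainpop as sp
from strainpop import diversity as dv
from strainpop import filtering as flt
from strainpop import simulate as sim
from strainpop.io import GeneModel, GenomeAnnotation

# contig layout: filler(3) + gene1(+ strand, 4..15) + filler(15) +
# gene2(- strand, 31..42, coding ATGTTTGGGTGA) + filler(18)
GENE1_CODING = "ATGAAACCCTAA"
GENE2_CODING = "ATGTTTGGGTGA"
CONTIG = (
    "ACG" + GENE1_CODING + "ACGTACGTACGTACG" + "TCACCCAAACAT" + "ACGTACGTACGTACGTAC"
)


@pytest.fixture
def toy_annotation():
    genes = [
        GeneModel("g1", "c1", 4, 15, "+", gene_class="amoA"),
        GeneModel("g2", "c1", 31, 42, "-", gene_class="other"),
    ]
    return GenomeAnnotation("toy", {"c1": CONTIG}, genes)


@pytest.fixture(scope="session")
def community():
    """One simulated community taken through pooling and SNP calling."""
    cfg = sp.SimulationConfig(
        seed=11, genome_length=30_000, n_genes=30, coverage_mean=40,
        n_populations=3, error_rate=0.001,
    )
    ann = sp.simulate_reference(cfg)
    truth = sp.simulate_haplotypes(ann, cfg)
    sp.assign_population_frequencies(truth, cfg)
    counts = sp.emit_site_counts(truth, cfg, 2)
    meta = sim.simulated_metadata(truth, 2)
    pooled = flt.pool_populations(counts, meta)
    snps = dv.call_snps(pooled, ann)
    return {
        "config": cfg,
        "annotation": ann,
        "truth": truth,
        "counts": counts,
        "metadata": meta,
        "pooled": pooled,
        "snps": snps,
    }


def pooled_from_rows(rows):
    """Build a pooled-counts table from (population, contig, pos, ref, A, C,
    G, T) tuples."""
    return pd.DataFrame(
        rows, columns=["population", "contig", "pos", "ref", "A", "C", "G", "T"]
    ).assign(species="toy")[
        ["species", "contig", "pos", "ref", "population", "A", "C", "G", "T"]
    ]
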