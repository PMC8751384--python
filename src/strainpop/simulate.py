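"""Synthetic haplotype-community simulator with known ground truth.

The simulator stands in for raw metagenome read data.  It generates a random
coding reference genome, a pool of haplotypes diverged from it at a target
nucleotide diversity under an infinite-sites approximation (mutated sites are
resampled on collision, which keeps the mapping between mutation count and
expected pairwise diversity analytic), optional segment-reassortment
recombination, per-population haplotype frequency vectors drawn from a
symmetric Dirichlet (smaller concentration -> stronger between-population
differentiation), and finally per-sample per-site allele counts (Poisson
depth by default, negative-binomial with an overdispersion switch) and,
optionally, read-pair observations for linkage analysis.

Mutations attach to clades of a random bifurcating relatedness tree over the
haplotypes, so derived alleles are nested as in a clonal genealogy: without
recombination every biallelic site pair shows at most three of the four
haplotype combinations (complete linkage, D' = 1), and segment reassortment
is what erodes that signal.

Every stage draws from its own seed stream derived from the root seed, so
each stage is deterministic given the config.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._genetics import BASES, SENSE_CODONS, STOP_CODONS, complement, is_synonymous, revcomp
from .io import GeneModel, GenomeAnnotation, NITRIFICATION_CLASSES

logger = logging.getLogger(__name__)

_STAGE_REF, _STAGE_HAP, _STAGE_FREQ, _STAGE_COUNTS, _STAGE_READS = 11, 12, 13, 14, 15
_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass
class SimulationConfig:
    """Ground-truth parameters of one synthetic community.

    ``target_pi`` is the expected per-site pairwise diversity among the
    haplotypes under uniform weights; ``ns_fraction`` the probability that a
    coding mutation is placed as nonsynonymous where the codon admits one;
    ``recomb_rate`` the per-haplotype expected number of segment-reassortment
    events; ``dirichlet_alpha`` the symmetric Dirichlet concentration for the
    per-population haplotype frequency vectors (``inf`` -> identical uniform
    vectors, i.e. no differentiation).
    """

    seed: int = 0
    genome_length: int = 60_000
    n_genes: int = 50
    n_haplotypes: int = 20
    target_pi: float = 0.01
    ns_fraction: float = 0.2
    recomb_rate: float = 0.0
    n_populations: int = 4
    dirichlet_alpha: float = 0.5
    coverage_mean: float = 50.0
    error_rate: float = 0.001
    overdispersion: float | None = None
    species_id: str = "sim"
    min_gene_codons: int = 30
    coding_fraction: float = 0.70
    label_nitrification_genes: bool = True

    def __post_init__(self):
        if not 0.0 <= self.target_pi <= 0.1:
            raise ValueError("target_pi must be within [0, 0.1]")
        if not 0.0 <= self.ns_fraction <= 1.0:
            raise ValueError("ns_fraction must be within [0, 1]")
        for name in ("genome_length", "n_genes", "n_haplotypes", "n_populations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.coverage_mean <= 0 or not 0 <= self.error_rate < 1:
            raise ValueError("invalid coverage_mean / error_rate")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SimTruth:
    """Ground truth of one simulated community: haplotype alleles at mutated
    sites, per-population frequency vectors, and the realized statistics
    recomputable from them."""

    annotation: GenomeAnnotation
    config: SimulationConfig
    contig: np.ndarray          # contig id per mutated site
    pos: np.ndarray             # 1-based genomic position per mutated site
    ref: np.ndarray             # reference base per site
    alt: np.ndarray             # derived base per site
    mut_class: np.ndarray       # 'S' / 'N' / 'I' (intergenic)
    alleles: np.ndarray         # (n_haplotypes, n_sites) bool: carries alt
    populations: list[str] = field(default_factory=list)
    frequencies: np.ndarray | None = None   # (n_populations, n_haplotypes)
    realized_pi: dict[str, float] = field(default_factory=dict)
    true_fst: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    def haplotype_sequence(self, h: int, contig_id: str) -> str:
        """Full nucleotide sequence of haplotype ``h`` on one contig."""
        seq = list(self.annotation.contigs[contig_id])
        mask = (self.contig == contig_id) & self.alleles[h]
        for p, a in zip(self.pos[mask], self.alt[mask]):
            seq[p - 1] = a
        return "".join(seq)

    def pairwise_pi_uniform(self) -> float:
        """Mean per-site pairwise difference among haplotypes under uniform
        weights (the quantity ``target_pi`` calibrates)."""
        h = self.n_haplotypes
        if h < 2:
            return 0.0
        k = self.alleles.sum(axis=0)
        het = 2.0 * k * (h - k) / (h * (h - 1))
        return float(het.sum() / self.annotation.genome_length)

    def population_allele_freqs(self) -> np.ndarray:
        """(n_populations, n_sites) derived-allele frequencies from the stored
        frequency vectors and haplotype alleles."""
        if self.frequencies is None:
            raise ValueError("population frequencies not assigned yet")
        return self.frequencies @ self.alleles.astype(float)

    def recompute_realized_pi(self) -> dict[str, float]:
        p = self.population_allele_freqs()
        het = 2.0 * p * (1.0 - p)
        length = self.annotation.genome_length
        return {
            pop: float(het[i].sum() / length)
            for i, pop in enumerate(self.populations)
        }

    def recompute_true_fst(self) -> dict[tuple[str, str], np.ndarray]:
        """Per-site Hudson F_ST from the true (infinite-sample) allele
        frequencies, for every population pair."""
        p = self.population_allele_freqs()
        out: dict[tuple[str, str], np.ndarray] = {}
        for i in range(len(self.populations)):
            for j in range(i + 1, len(self.populations)):
                p1, p2 = p[i], p[j]
                hw = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2.0
                hb = p1 * (1 - p2) + p2 * (1 - p1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    fst = np.where(hb > 0, 1.0 - hw / hb, np.nan)
                out[(self.populations[i], self.populations[j])] = fst
        return out

    def site_table(self) -> pd.DataFrame:
        """Site-level truth in the ``truth`` writer schema (carriers encoded
        as a 0/1 string over haplotypes)."""
        carriers = ["".join("1" if c else "0" for c in col) for col in self.alleles.T]
        df = pd.DataFrame(
            {
                "species": self.config.species_id,
                "contig": self.contig,
                "pos": self.pos,
                "ref": self.ref,
                "alt": self.alt,
                "mut_class": self.mut_class,
                "carriers": carriers,
            }
        )
        if self.frequencies is not None:
            p = self.population_allele_freqs()
            for i, pop in enumerate(self.populations):
                df[f"freq_{pop}"] = p[i]
        return df

    def frequency_table(self) -> pd.DataFrame:
        if self.frequencies is None:
            raise ValueError("population frequencies not assigned yet")
        return pd.DataFrame(
            self.frequencies,
            index=pd.Index(self.populations, name="population"),
            columns=[f"hap_{h}" for h in range(self.n_haplotypes)],
        )


# ---------------------------------------------------------------------------
# stage 1: reference genome
# ---------------------------------------------------------------------------

def simulate_reference(config: SimulationConfig) -> GenomeAnnotation:
    """Random single-contig coding genome: ``n_genes`` non-overlapping CDS
    (ATG start, stop-free interior, stop codon, length a multiple of 3)
    covering at least 60% of ``genome_length``."""
    rng = np.random.default_rng([_STAGE_REF, config.seed])
    L, n_genes = config.genome_length, config.n_genes
    min_len = config.min_gene_codons * 3
    if n_genes * min_len > L:
        raise ValueError(
            f"genome too short: {n_genes} genes x {min_len} bp minimum "
            f"exceeds genome_length {L}"
        )
    base = int(config.coding_fraction * L / (3 * n_genes))
    low = max(config.min_gene_codons, int(base * 0.75))
    high = max(low + 1, int(base * 1.25))
    codons = rng.integers(low, high + 1, size=n_genes)
    # keep total coding within the genome and at least 60% of it
    def total(c):
        return int(c.sum()) * 3
    while total(codons) > L - (n_genes + 1):
        codons = np.maximum(config.min_gene_codons, codons - 1)
    while total(codons) < min(0.6 * L, L - (n_genes + 1) * 2):
        codons = codons + 1
    spare = L - total(codons)
    gaps = rng.multinomial(spare, np.full(n_genes + 1, 1.0 / (n_genes + 1)))

    sense = np.array(SENSE_CODONS)
    stops = np.array(STOP_CODONS)
    contig_id = f"{config.species_id}_c1"
    parts: list[str] = []
    genes: list[GeneModel] = []
    cursor = 0
    class_genes = {}
    if config.label_nitrification_genes and n_genes >= len(NITRIFICATION_CLASSES):
        chosen = rng.choice(n_genes, size=len(NITRIFICATION_CLASSES), replace=False)
        class_genes = {int(g): c for g, c in zip(chosen, NITRIFICATION_CLASSES)}

    for i in range(n_genes):
        gap = int(gaps[i])
        parts.append("".join(rng.choice(list(BASES), size=gap)))
        cursor += gap
        n_cod = int(codons[i])
        interior = "".join(rng.choice(sense, size=n_cod - 2))
        coding = "ATG" + interior + str(rng.choice(stops))
        strand = "+" if rng.random() < 0.5 else "-"
        genomic = coding if strand == "+" else revcomp(coding)
        start = cursor + 1
        end = cursor + len(coding)
        parts.append(genomic)
        cursor = end
        genes.append(
            GeneModel(
                gene_id=f"{config.species_id}_g{i + 1:04d}",
                contig_id=contig_id,
                start=start,
                end=end,
                strand=strand,
                gene_class=class_genes.get(i, "other"),
            )
        )
    parts.append("".join(rng.choice(list(BASES), size=int(gaps[n_genes]))))
    sequence = "".join(parts)
    assert len(sequence) == L
    return GenomeAnnotation(
        species_id=config.species_id, contigs={contig_id: sequence}, genes=genes
    )


# ---------------------------------------------------------------------------
# stage 2: haplotypes
# ---------------------------------------------------------------------------

def _random_clades(h: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Clades of a random bifurcating relatedness tree over ``h`` haplotypes
    (every group formed by successive random merges, root excluded).

    Mutations attach to a uniformly chosen clade, so derived alleles are
    shared along nested groups exactly as in a clonal genealogy: without
    recombination at most three of the four haplotype combinations exist at
    any site pair, the condition under which D' = 1.  This is a relatedness
    structure only, not a timed coalescent.
    """
    groups = [np.array([i]) for i in range(h)]
    clades = [g for g in groups]
    while len(groups) > 1:
        i, j = sorted(rng.choice(len(groups), size=2, replace=False))
        merged = np.concatenate([groups[i], groups[j]])
        groups = [g for k, g in enumerate(groups) if k not in (i, j)]
        groups.append(merged)
        if len(groups) > 1:          # exclude the root (all haplotypes)
            clades.append(merged)
    return clades


def _mean_het(clades: list[np.ndarray], h: int) -> float:
    """Exact expected per-mutation pairwise difference under a uniform choice
    of clade: E[2k(h-k)] / (h(h-1)) over the clade sizes k."""
    ks = np.array([len(c) for c in clades], dtype=float)
    return float((2.0 * ks * (h - ks)).mean() / (h * (h - 1)))


def simulate_haplotypes(annotation: GenomeAnnotation, config: SimulationConfig) -> SimTruth:
    """Place mutations on ``n_haplotypes`` copies of the reference so that the
    expected pairwise diversity under uniform haplotype weights matches
    ``target_pi``; each coding mutation is nonsynonymous with probability
    ``ns_fraction`` (realized by choosing an admissible substitution given the
    codon; sites with no admissible option are resampled).  Recombination is
    applied afterwards as allele-segment swaps between random haplotype pairs.
    """
    rng = np.random.default_rng([_STAGE_HAP, config.seed])
    h = config.n_haplotypes
    length = annotation.genome_length

    # flat coordinate space over contigs
    contig_ids = list(annotation.contigs)
    offsets, off = {}, 0
    for cid in contig_ids:
        offsets[cid] = off
        off += len(annotation.contigs[cid])
    bounds = np.array([offsets[c] for c in contig_ids] + [length])

    gene_of = np.full(length, -1, dtype=int)
    for gi, g in enumerate(annotation.genes):
        o = offsets[g.contig_id]
        gene_of[o + g.start - 1 : o + g.end] = gi

    if h < 2 or config.target_pi == 0:
        clades: list[np.ndarray] = []
        n_mut = 0
    else:
        clades = _random_clades(h, rng)
        n_mut = int(round(config.target_pi * length / _mean_het(clades, h)))
        if n_mut > 0.5 * length:
            raise ValueError(
                "target_pi too high for the infinite-sites approximation "
                f"(needs {n_mut} mutated sites on a {length} bp genome)"
            )

    used: set[int] = set()
    sites, refs, alts, classes, carriers = [], [], [], [], []
    n_resampled = 0
    attempts = 0
    while len(sites) < n_mut:
        attempts += 1
        if attempts > 50 * max(n_mut, 1):
            raise RuntimeError("mutation placement failed to converge")
        gpos = int(rng.integers(0, length))
        if gpos in used:
            continue
        ci = int(np.searchsorted(bounds, gpos, side="right") - 1)
        cid = contig_ids[ci]
        pos = gpos - offsets[cid] + 1
        ref_base = annotation.contigs[cid][pos - 1]
        if ref_base == "N":
            continue
        gi = gene_of[gpos]
        if gi >= 0:
            gene = annotation.genes[gi]
            cds_off = gene.coding_offset(pos)
            codon = gene.cds[3 * (cds_off // 3) : 3 * (cds_off // 3) + 3]
            pos_in = cds_off % 3
            want_nonsyn = rng.random() < config.ns_fraction
            cands = [
                b
                for b in BASES
                if b != codon[pos_in]
                and is_synonymous(codon, pos_in, b) != want_nonsyn
            ]
            if not cands:
                n_resampled += 1
                continue
            alt_coding = cands[int(rng.integers(len(cands)))]
            alt_base = alt_coding if gene.strand == "+" else complement(alt_coding)
            mclass = "N" if want_nonsyn else "S"
        else:
            others = [b for b in BASES if b != ref_base]
            alt_base = others[int(rng.integers(3))]
            mclass = "I"
        used.add(gpos)
        sites.append(gpos)
        refs.append(ref_base)
        alts.append(alt_base)
        classes.append(mclass)
        row = np.zeros(h, dtype=bool)
        row[clades[int(rng.integers(len(clades)))]] = True
        carriers.append(row)
    if n_resampled:
        logger.info(
            "simulate_haplotypes: resampled %d sites with no admissible "
            "substitution of the requested class",
            n_resampled,
        )

    order = np.argsort(sites) if sites else np.array([], dtype=int)
    gsites = np.array(sites, dtype=int)[order]
    alleles = (
        np.array(carriers, dtype=bool)[order].T
        if sites
        else np.zeros((h, 0), dtype=bool)
    )

    # recombination: segment swaps on the allele matrix
    n_events = rng.poisson(config.recomb_rate * h)
    for _ in range(int(n_events)):
        i, j = rng.choice(h, size=2, replace=False)
        a, b = sorted(rng.integers(0, length, size=2))
        seg = (gsites >= a) & (gsites < b)
        tmp = alleles[i, seg].copy()
        alleles[i, seg] = alleles[j, seg]
        alleles[j, seg] = tmp

    ci = np.searchsorted(bounds, gsites, side="right") - 1
    contig_arr = np.array([contig_ids[c] for c in ci], dtype=object)
    pos_arr = gsites - np.array([offsets[contig_ids[c]] for c in ci], dtype=int) + 1

    return SimTruth(
        annotation=annotation,
        config=config,
        contig=contig_arr,
        pos=pos_arr.astype(int),
        ref=np.array(refs, dtype=object)[order] if sites else np.array([], dtype=object),
        alt=np.array(alts, dtype=object)[order] if sites else np.array([], dtype=object),
        mut_class=np.array(classes, dtype=object)[order]
        if sites
        else np.array([], dtype=object),
        alleles=alleles,
    )


# ---------------------------------------------------------------------------
# stage 3: population structure
# ---------------------------------------------------------------------------

def assign_population_frequencies(truth: SimTruth, config: SimulationConfig) -> SimTruth:
    """Draw one haplotype frequency vector per population from a symmetric
    Dirichlet(``dirichlet_alpha``); store realized per-population diversity
    and per-site true F_ST for every population pair."""
    rng = np.random.default_rng([_STAGE_FREQ, config.seed])
    h, n_pop = truth.n_haplotypes, config.n_populations
    if math.isinf(config.dirichlet_alpha):
        freqs = np.full((n_pop, h), 1.0 / h)
    else:
        freqs = rng.dirichlet(np.full(h, config.dirichlet_alpha), size=n_pop)
    truth.populations = [f"WW{i + 1}" for i in range(n_pop)]
    truth.frequencies = freqs
    truth.realized_pi = truth.recompute_realized_pi()
    truth.true_fst = truth.recompute_true_fst()
    return truth


# ---------------------------------------------------------------------------
# stage 4: sitecounts
# ---------------------------------------------------------------------------

def _apply_errors(counts: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Miscall each base with probability ``error_rate``, uniformly to one of
    the three other bases."""
    if error_rate <= 0:
        return counts
    out = counts.copy()
    for b in range(4):
        m = rng.binomial(counts[:, b], error_rate)
        out[:, b] -= m
        m1 = rng.binomial(m, 1.0 / 3.0)
        m2 = rng.binomial(m - m1, 0.5)
        m3 = m - m1 - m2
        targets = [t for t in range(4) if t != b]
        out[:, targets[0]] += m1
        out[:, targets[1]] += m2
        out[:, targets[2]] += m3
    return out


def emit_site_counts(
    truth: SimTruth, config: SimulationConfig, samples_per_population: int = 2
) -> pd.DataFrame:
    """Collapse the community to a sitecounts table: per sample and site,
    depth ~ Poisson(``coverage_mean``) (negative binomial when
    ``overdispersion`` is set), each observation drawn from a haplotype by the
    population's frequency vector, then miscalled at ``error_rate``."""
    if truth.frequencies is None:
        raise ValueError("assign_population_frequencies must run first")
    rng = np.random.default_rng([_STAGE_COUNTS, config.seed])
    ann = truth.annotation
    p_pop = truth.population_allele_freqs()

    frames = []
    for pi_, pop in enumerate(truth.populations):
        for s in range(samples_per_population):
            sample_id = f"{pop}_s{s + 1}"
            for cid, seq in ann.contigs.items():
                L = len(seq)
                if config.overdispersion:
                    r = config.overdispersion
                    depth = rng.negative_binomial(
                        r, r / (r + config.coverage_mean), size=L
                    )
                else:
                    depth = rng.poisson(config.coverage_mean, size=L)
                refidx = np.frombuffer(seq.encode(), dtype=np.uint8)
                lut = np.zeros(256, dtype=int)
                for b, i in _BASE_IDX.items():
                    lut[ord(b)] = i
                refidx = lut[refidx]
                counts = np.zeros((L, 4), dtype=int)
                counts[np.arange(L), refidx] = depth
                mask = truth.contig == cid
                vpos = truth.pos[mask] - 1
                if len(vpos):
                    kalt = rng.binomial(depth[vpos], p_pop[pi_][mask])
                    altidx = np.array([_BASE_IDX[a] for a in truth.alt[mask]])
                    vref = refidx[vpos]
                    counts[vpos, vref] = depth[vpos] - kalt
                    counts[vpos, altidx] += kalt
                counts = _apply_errors(counts, config.error_rate, rng)
                frames.append(
                    pd.DataFrame(
                        {
                            "species": config.species_id,
                            "contig": cid,
                            "pos": np.arange(1, L + 1),
                            "ref": list(seq),
                            "sample": sample_id,
                            "A": counts[:, 0],
                            "C": counts[:, 1],
                            "G": counts[:, 2],
                            "T": counts[:, 3],
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)


def simulated_metadata(truth: SimTruth, samples_per_population: int = 2) -> pd.DataFrame:
    rows = [
        {"sample": f"{pop}_s{s + 1}", "population": pop}
        for pop in truth.populations
        for s in range(samples_per_population)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage 5: read-pair observations (for linkage)
# ---------------------------------------------------------------------------

@dataclass
class ReadObservation:
    """Alleles observed at variant sites covered by one sequenced fragment
    (a read pair from a single haplotype molecule)."""

    sample_id: str
    population: str
    contig: str
    positions: np.ndarray   # 1-based, ascending
    bases: np.ndarray


def emit_reads(
    truth: SimTruth,
    config: SimulationConfig,
    samples_per_population: int = 2,
    read_length: int = 150,
    insert_mean: float = 350.0,
    insert_sd: float = 50.0,
) -> list[ReadObservation]:
    """Sample paired-read fragments from haplotypes and report the alleles
    they carry at the truth's variant sites (with sequencing error).  This is
    the physical-linkage input the D' machinery consumes."""
    if truth.frequencies is None:
        raise ValueError("assign_population_frequencies must run first")
    rng = np.random.default_rng([_STAGE_READS, config.seed])
    out: list[ReadObservation] = []
    other = {b: [x for x in BASES if x != b] for b in BASES}
    for pi_, pop in enumerate(truth.populations):
        freqs = truth.frequencies[pi_]
        for s in range(samples_per_population):
            sample_id = f"{pop}_s{s + 1}"
            for cid, seq in truth.annotation.contigs.items():
                L = len(seq)
                mask = truth.contig == cid
                vpos = truth.pos[mask]          # ascending
                vref = truth.ref[mask]
                valt = truth.alt[mask]
                valle = truth.alleles[:, mask]
                n_frag = int(round(config.coverage_mean * L / (2 * read_length)))
                inserts = np.clip(
                    rng.normal(insert_mean, insert_sd, size=n_frag),
                    read_length,
                    min(600, L),
                ).astype(int)
                starts = rng.integers(1, np.maximum(2, L - inserts + 1))
                haps = rng.choice(truth.n_haplotypes, size=n_frag, p=freqs)
                for f in range(n_frag):
                    a = starts[f]
                    b = a + inserts[f] - 1
                    blocks = [(a, min(b, a + read_length - 1))]
                    r2 = (max(a, b - read_length + 1), b)
                    if r2[0] > blocks[0][1]:
                        blocks.append(r2)
                    else:
                        blocks = [(a, b)]
                    idx = []
                    for lo, hi in blocks:
                        i0 = np.searchsorted(vpos, lo, side="left")
                        i1 = np.searchsorted(vpos, hi, side="right")
                        idx.extend(range(i0, i1))
                    if len(idx) < 2:
                        continue
                    idx = np.array(idx)
                    bases = np.where(valle[haps[f]][idx], valt[idx], vref[idx])
                    if config.error_rate > 0:
                        errs = rng.random(len(idx)) < config.error_rate
                        for e in np.where(errs)[0]:
                            bases[e] = other[bases[e]][int(rng.integers(3))]
                    out.append(
                        ReadObservation(
                            sample_id=sample_id,
                            population=pop,
                            contig=cid,
                            positions=vpos[idx],
                            bases=bases,
                        )
                    )
    return out
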