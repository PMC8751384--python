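"""Readers and writers for references, annotations, sitecounts, metadata,
abundance tables, and every result-table schema.

Coordinates are 1-based inclusive throughout (GFF3 convention); sitecounts
positions are 1-based to match.  Only CDS features are consumed from GFF3;
other feature types are counted and logged.  Reference ambiguity characters
(N) are tracked so downstream statistics can exclude those sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO

from ._genetics import revcomp

logger = logging.getLogger(__name__)

NITRIFICATION_CLASSES = ("amoA", "amoB", "haoA", "haoB", "nxrA", "nxrB")


class AnnotationError(ValueError):
    """Raised when a reference/annotation violates a structural invariant."""


@dataclass
class GeneModel:
    """A single CDS gene model.

    ``start``/``end`` are 1-based inclusive genomic coordinates; ``cds`` is
    the coding-strand nucleotide sequence (reverse-complemented at load time
    for minus-strand genes), so codon extraction never needs to know the
    strand again.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    cds: str = ""
    product: str | None = None
    gene_class: str = "other"

    def __post_init__(self):
        if self.strand not in "+-":
            raise AnnotationError(f"gene {self.gene_id}: strand must be + or -")
        if self.start > self.end:
            raise AnnotationError(f"gene {self.gene_id}: start > end")
        if (self.end - self.start + 1) % 3 != 0:
            raise AnnotationError(
                f"gene {self.gene_id}: CDS length not multiple of 3"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def coding_offset(self, pos: int) -> int:
        """0-based offset of genomic position ``pos`` within the coding-strand
        CDS sequence."""
        if not self.start <= pos <= self.end:
            raise ValueError(f"position {pos} outside gene {self.gene_id}")
        return pos - self.start if self.strand == "+" else self.end - pos


@dataclass
class GenomeAnnotation:
    """Reference contigs plus CDS gene models for one species."""

    species_id: str
    contigs: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            if g.contig_id not in self.contigs:
                raise AnnotationError(
                    f"gene {g.gene_id}: unknown contig {g.contig_id}"
                )
            contig = self.contigs[g.contig_id]
            if g.end > len(contig) or g.start < 1:
                raise AnnotationError(
                    f"gene {g.gene_id}: coordinates out of contig bounds"
                )
            expected = contig[g.start - 1 : g.end]
            if g.strand == "-":
                expected = revcomp(expected)
            if not g.cds:
                g.cds = expected
            elif g.cds != expected:
                raise AnnotationError(
                    f"gene {g.gene_id}: stored CDS disagrees with contig sequence"
                )

    @property
    def genome_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    @property
    def n_ambiguous(self) -> int:
        return sum(s.count("N") for s in self.contigs.values())

    def gene_index(self) -> dict[str, list[GeneModel]]:
        """Genes grouped per contig, sorted by start coordinate."""
        idx: dict[str, list[GeneModel]] = {c: [] for c in self.contigs}
        for g in self.genes:
            idx[g.contig_id].append(g)
        for genes in idx.values():
            genes.sort(key=lambda g: g.start)
        return idx

    def gene_at(self, contig_id: str, pos: int) -> GeneModel | None:
        """The gene covering (contig, pos), or None when intergenic.
        Overlapping genes resolve to the first by start coordinate."""
        for g in self.gene_index().get(contig_id, []):
            if g.start <= pos <= g.end:
                return g
        return None


def read_reference(
    fasta_path: str | Path, gff_path: str | Path, species_id: str | None = None
) -> GenomeAnnotation:
    """Load a reference FASTA plus its GFF3 CDS annotations.

    Minus-strand genes are stored with their coding-strand sequence so that
    codon extraction downstream is strand-agnostic.  Non-CDS feature types
    are skipped with a logged count.
    """
    fasta_path, gff_path = Path(fasta_path), Path(gff_path)
    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    if not contigs:
        raise AnnotationError(f"no sequences in {fasta_path}")
    if species_id is None:
        species_id = fasta_path.stem

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    skipped = 0
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype != "CDS":
            skipped += 1
            continue
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        product = feat.attributes.get("product", [None])[0]
        gene_class = feat.attributes.get("gene_class", ["other"])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                contig_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                product=product,
                gene_class=gene_class,
            )
        )
    if skipped:
        logger.info("read_reference: ignored %d non-CDS features", skipped)
    ann = GenomeAnnotation(species_id=species_id, contigs=contigs, genes=genes)
    if ann.n_ambiguous:
        logger.info(
            "read_reference: %d ambiguous (N) reference positions will be "
            "excluded from statistics",
            ann.n_ambiguous,
        )
    return ann


# ---------------------------------------------------------------------------
# sitecounts / metadata / abundance tables
# ---------------------------------------------------------------------------

SITECOUNT_COLUMNS = ["species", "contig", "pos", "ref", "sample", "A", "C", "G", "T"]
COUNT_COLS = ["A", "C", "G", "T"]


def read_site_counts(path: str | Path) -> pd.DataFrame:
    """Read a sitecounts TSV (header: species contig pos ref sample nA nC nG nT
    or A C G T) into a typed table; positions are 1-based."""
    df = pd.read_csv(path, sep="\t", dtype={"species": str, "contig": str, "sample": str})
    df = df.rename(columns={"nA": "A", "nC": "C", "nG": "G", "nT": "T"})
    missing = [c for c in SITECOUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sitecounts file missing columns: {missing}")
    df = df[SITECOUNT_COLUMNS].copy()
    if len(df):
        df["pos"] = df["pos"].astype(int)
        df[COUNT_COLS] = df[COUNT_COLS].astype(int)
        if (df[COUNT_COLS].to_numpy() < 0).any():
            raise ValueError("negative counts in sitecounts table")
        if not df["ref"].isin(list("ACGT")).all():
            bad = df.loc[~df["ref"].isin(list("ACGT")), "ref"].unique()
            raise ValueError(f"non-ACGT reference base(s) in sitecounts: {bad}")
        key = ["species", "contig", "pos", "sample"]
        if df.duplicated(subset=key).any():
            raise ValueError("duplicate (species, contig, pos, sample) rows")
    return df


def write_site_counts(df: pd.DataFrame, path: str | Path) -> None:
    df[SITECOUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV: columns ``sample``, ``population`` plus optional
    numeric chemistry / coordinate columns."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "population": str})
    for col in ("sample", "population"):
        if col not in df.columns:
            raise ValueError(f"metadata missing required column '{col}'")
    if df["sample"].duplicated().any():
        raise ValueError("duplicate sample_ids in metadata")
    return df


def read_abundance(path: str | Path) -> pd.DataFrame:
    """Species x sample abundance TSV (first column = species id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("negative abundances")
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("abundance table needs >= 2 species and >= 2 samples")
    return df


# ---------------------------------------------------------------------------
# result-table schemas
# ---------------------------------------------------------------------------

SCHEMAS: dict[str, list[str]] = {
    "genome_stats": [
        "species", "population", "pi", "dprime", "pnps",
        "n_sites", "snp_count", "snps_per_mbp", "mean_coverage",
    ],
    "gene_stats": [
        "species", "population", "gene_id", "contig", "start", "end",
        "gene_class", "pi", "dprime", "n_nonsyn_snps", "n_syn_snps",
        "nonsyn_sites", "syn_sites", "pnps", "coverage",
    ],
    "snps": [
        "species", "contig", "pos", "ref", "major", "minor",
        "gene_id", "effect_class",
    ],
    "fst_pairs": [
        "species", "pop_a", "pop_b", "gene_id", "fst", "n_sites_used",
    ],
    "loci": [
        "species", "pop_a", "pop_b", "contig", "gene_ids", "start", "end",
        "mean_fst", "linkage_test_p", "diversity_test_p", "sweep_flag",
    ],
    "network_edges": ["source", "target", "rho"],
    "truth": [
        "species", "contig", "pos", "ref", "alt", "mut_class", "carriers",
    ],
}


def write_table(df: pd.DataFrame, path: str | Path, schema_name: str) -> None:
    """Write a result table under a named schema with a deterministic column
    order: the schema columns first, extra columns (e.g. per-population
    frequencies) sorted lexically after them."""
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema '{schema_name}'")
    required = SCHEMAS[schema_name]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"schema '{schema_name}' missing columns: {missing}")
    extras = sorted(c for c in df.columns if c not in required)
    df[required + extras].to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema '{schema_name}'")
    dtypes = {"carriers": str} if schema_name == "truth" else None
    df = pd.read_csv(path, sep="\t", dtype=dtypes)
    missing = [c for c in SCHEMAS[schema_name] if c not in df.columns]
    if missing:
        raise ValueError(f"schema '{schema_name}' missing columns: {missing}")
    return df


def write_annotation(
    ann: GenomeAnnotation, fasta_path: str | Path, gff_path: str | Path
) -> None:
    """Write a GenomeAnnotation back to FASTA + GFF3 (CDS features only)."""
    with open(fasta_path, "w") as fh:
        for cid, seq in ann.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(ann.genes, key=lambda g: (g.contig_id, g.start)):
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            attrs += f";gene_class={g.gene_class}"
            fh.write(
                f"{g.contig_id}\tstrainpop\tCDS\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t0\t{attrs}\n"
            )
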