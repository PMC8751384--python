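"""Codon-level helpers shared by the simulator and the selection scan.

All codon logic uses the bacterial/archaeal genetic code (NCBI translation
table 11).  Stop codons translate to ``"*"``; a substitution turning a stop
into a sense codon (read-through) therefore classifies as nonsynonymous, and
stop-to-stop exchanges as synonymous.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_TABLE = unambiguous_dna_by_id[11]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = tuple(sorted(_TABLE.stop_codons))
SENSE_CODONS = tuple(sorted(c for c, aa in CODON_TO_AA.items() if aa != "*"))


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (preserves N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def translate_codon(codon: str) -> str:
    return CODON_TO_AA[codon]


def is_synonymous(codon: str, pos_in_codon: int, alt_base: str) -> bool:
    """True iff replacing ``codon[pos_in_codon]`` with ``alt_base`` preserves
    the encoded amino acid (internal codons; table-11 start handling is not
    applied)."""
    if alt_base == codon[pos_in_codon]:
        raise ValueError("alt_base equals the reference base; not a substitution")
    mutated = codon[:pos_in_codon] + alt_base + codon[pos_in_codon + 1 :]
    return CODON_TO_AA[codon] == CODON_TO_AA[mutated]


def codon_site_fractions(codon: str) -> tuple[float, float]:
    """Nei–Gojobori potential-site counts ``(nonsyn_sites, syn_sites)`` for one
    codon, weighting the three possible substitutions at each position equally
    (no transition/transversion bias)."""
    syn = 0.0
    for pos in range(3):
        ref = codon[pos]
        n_syn = sum(
            1 for b in BASES if b != ref and is_synonymous(codon, pos, b)
        )
        syn += n_syn / 3.0
    return 3.0 - syn, syn
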