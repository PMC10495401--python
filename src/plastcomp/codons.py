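"""Genetic-code helpers shared by the variant-effect and codon-usage modules.

Chloroplast protein-coding genes are translated with the bacterial/plastid
code (NCBI translation table 11). The standard-table amino-acid assignments
are identical for all 64 codons; table 11 differs only in its wider set of
permitted initiation codons, which does not affect codon-by-codon
translation or synonymous-family structure.
"""

from __future__ import annotations

from Bio.Data import CodonTable

BASES = "ACGT"
COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_TABLE = CodonTable.unambiguous_dna_by_id[11]

#: codon -> one-letter amino acid, with '*' for stop codons
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_TABLE.stop_codons)

#: amino acid (or '*') -> sorted tuple of codons encoding it
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS[_aa] = AA_TO_CODONS[_aa] + (_codon,)

#: synonymous-family size r_a for each amino acid (stops form their own family)
FAMILY_SIZE: dict[str, int] = {aa: len(cs) for aa, cs in AA_TO_CODONS.items()}

ALL_CODONS = tuple(sorted(CODON_TO_AA))


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; '*' for stop, 'X' if ambiguous."""
    return CODON_TO_AA.get(codon.upper(), "X")


def translate_cds(cds: str) -> str:
    """Translate a strand-corrected CDS, codon by codon (no start-codon rules)."""
    return "".join(
        translate_codon(cds[i : i + 3]) for i in range(0, len(cds) - len(cds) % 3, 3)
    )


def is_synonymous(ref_codon: str, alt_codon: str) -> bool:
    return translate_codon(ref_codon) == translate_codon(alt_codon)
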