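"""Standard genetic code lookup tables shared by the simulator and the Ka/Ks machinery.

Everything here is derived once, at import time, from Biopython's standard
codon table, so the simulator and the NG86 counter agree on what counts as a
synonymous change by construction.
"""

from __future__ import annotations

import itertools

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

_standard = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid for the 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)

SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3)) if c not in STOP_CODONS)
)


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate_codon(codon: str) -> str:
    """One-letter amino acid of a sense codon; raises KeyError for stops."""
    return CODON_TO_AA[codon]


def single_nt_neighbors(codon: str) -> list[str]:
    """All 9 codons one nucleotide change away, in deterministic order."""
    out = []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                out.append(codon[:pos] + nt + codon[pos + 1 :])
    return out


def synonymous_site_fractions(codon: str) -> float:
    """NG86 count of synonymous sites in one sense codon.

    Each of the three positions contributes (number of synonymous
    single-nucleotide changes)/3; a change producing a stop codon counts as
    nonsynonymous, so the synonymous + nonsynonymous site counts always sum
    to 3 per codon.
    """
    aa = CODON_TO_AA[codon]
    syn = 0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
                syn += 1
    return syn / 3.0


def validate_cds(cds: str, name: str = "sequence") -> None:
    """Check frame, alphabet and absence of internal stop codons."""
    if len(cds) == 0 or len(cds) % 3 != 0:
        raise ValueError(f"{name}: coding sequence length {len(cds)} is not a positive multiple of 3")
    cds = cds.upper()
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if any(nt not in NUCLEOTIDES for nt in codon):
            raise ValueError(f"{name}: invalid nucleotide in codon {codon!r} at position {i}")
        if codon in STOP_CODONS and i < len(cds) - 3:
            raise ValueError(f"{name}: internal stop codon {codon} at position {i}")


def split_codons(cds: str, drop_trailing_stop: bool = True) -> list[str]:
    """Split an in-frame CDS into codons, optionally dropping a trailing stop."""
    cds = cds.upper()
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if drop_trailing_stop and codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    return codons
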