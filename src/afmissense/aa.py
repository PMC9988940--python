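"""Amino-acid code utilities shared across the package.

Wraps Biopython's IUPAC code tables; all residues are stored internally as
upper-case one-letter codes for the 20 standard amino acids.
"""

from __future__ import annotations

from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1

#: one-letter -> three-letter (e.g. "A" -> "ALA"), 20 standard residues
ONE_TO_THREE: dict[str, str] = {
    one: three.upper() for one, three in protein_letters_1to3.items()
}

#: three-letter -> one-letter (e.g. "ALA" -> "A")
THREE_TO_ONE: dict[str, str] = {
    three.upper(): one for three, one in protein_letters_3to1.items()
}

STANDARD_AA: frozenset[str] = frozenset(ONE_TO_THREE)


def to_one_letter(code: str) -> str:
    """Normalize a 1- or 3-letter amino-acid code to upper-case one-letter.

    Raises ``KeyError`` for non-standard residues.
    """
    code = code.strip()
    if len(code) == 1:
        one = code.upper()
        if one not in STANDARD_AA:
            raise KeyError(f"unknown amino acid code {code!r}")
        return one
    three = code.upper()
    if three not in THREE_TO_ONE:
        raise KeyError(f"unknown amino acid code {code!r}")
    return THREE_TO_ONE[three]


def to_three_letter(code: str) -> str:
    """Normalize a 1- or 3-letter amino-acid code to upper-case three-letter."""
    return ONE_TO_THREE[to_one_letter(code)]


def is_standard(code: str) -> bool:
    try:
        to_one_letter(code)
    except KeyError:
        return False
    return True
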