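"""Canonical residue alphabet and vector index conventions.

Every 20-dimensional and 400-dimensional feature vector produced by this
package is indexed in **alphabetical one-letter order**::

    A C D E F G H I K L M N P Q R S T V W Y

PSI-BLAST writes its ASCII PSSM columns in a different, historical order
(A R N D C Q E G H I L K M F P S T W Y V); profiles are remapped to the
alphabetical order at parse time so all encoders share one convention.

Dipeptide (ordered residue pair) vectors use first-residue-major order:
index(pair) = 20 * index(first) + index(second).
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
"""The 20 standard residues in canonical (alphabetical) vector order."""

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

PSIBLAST_ORDER: str = "ARNDCQEGHILKMFPSTWYV"
"""Native column order of PSI-BLAST ``-out_ascii_pssm`` files."""

#: column j of the canonical order found at this index of the native order
PSIBLAST_TO_CANONICAL: tuple[int, ...] = tuple(
    PSIBLAST_ORDER.index(aa) for aa in AMINO_ACIDS
)
CANONICAL_TO_PSIBLAST: tuple[int, ...] = tuple(
    AMINO_ACIDS.index(aa) for aa in PSIBLAST_ORDER
)

DIPEPTIDES: tuple[str, ...] = tuple(a + b for a in AMINO_ACIDS for b in AMINO_ACIDS)
"""All 400 ordered residue pairs, first residue major, canonical order."""

DIPEPTIDE_INDEX: dict[str, int] = {dp: i for i, dp in enumerate(DIPEPTIDES)}

#: letters that may legitimately appear in sequences but are not one of the
#: 20 standard residues (ambiguity codes, selenocysteine/pyrrolysine, stops)
NONSTANDARD_LETTERS: frozenset[str] = frozenset("BJOUXZ*")


def is_standard(letter: str) -> bool:
    """True if ``letter`` is one of the 20 standard one-letter residues."""
    return letter in AA_INDEX


def dipeptide_index(pair: str) -> int:
    """Index of an ordered residue pair in the canonical 400-vector.

    Raises
    ------
    KeyError
        If ``pair`` is not two standard residues.
    """
    return DIPEPTIDE_INDEX[pair]
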