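"""Amino-acid and dipeptide composition encoders.

Amino-acid composition (AAC) is the 20-vector of residue counts normalised
by the number of residues; dipeptide composition (DPC) is the 400-vector of
ordered adjacent-pair counts normalised by the number of pairs.  Both are
length-invariant descriptors of a protein sequence.

Non-standard letters (B, J, O, U, X, Z, ``*``) are excluded from both the
numerator and the denominator of AAC, and any dipeptide window overlapping
one is skipped for DPC.
"""

from __future__ import annotations

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS
from .errors import EmptyDatasetError, EncodingError
from .seqio import ProteinRecord


def aa_composition(record: ProteinRecord) -> np.ndarray:
    """20-dim amino-acid composition of a sequence, canonical residue order.

    Entries are fractions in [0, 1] and sum to 1 for any sequence with at
    least one standard residue.

    Raises
    ------
    EncodingError
        If the sequence contains no standard residues.
    """
    counts = np.zeros(20, dtype=np.int64)
    for ch in record.sequence:
        idx = AA_INDEX.get(ch)
        if idx is not None:
            counts[idx] += 1
    total = counts.sum()
    if total == 0:
        raise EncodingError(
            f"record {record.id!r}: no standard residues to encode"
        )
    return counts / total


def dipeptide_composition(record: ProteinRecord) -> np.ndarray:
    """400-dim dipeptide composition over overlapping adjacent pairs.

    Windows are positions (i, i+1) for i = 1..L-1; windows containing a
    non-standard letter are skipped.  Retained pair counts are divided by
    the number of retained windows, so entries sum to 1.

    Raises
    ------
    EncodingError
        If no valid window exists (length < 2 or every window touches a
        non-standard letter).
    """
    seq = record.sequence
    counts = np.zeros(400, dtype=np.int64)
    n_windows = 0
    for i in range(len(seq) - 1):
        a = AA_INDEX.get(seq[i])
        b = AA_INDEX.get(seq[i + 1])
        if a is None or b is None:
            continue
        counts[20 * a + b] += 1
        n_windows += 1
    if n_windows == 0:
        raise EncodingError(
            f"record {record.id!r}: no valid dipeptide window "
            f"(length {len(seq)})"
        )
    return counts / n_windows


def class_composition_profile(records: list[ProteinRecord]) -> np.ndarray:
    """Mean amino-acid composition over records, in percent.

    This is the per-class residue profile used to contrast splicing factors
    against non-splicing proteins (splicing factors are enriched in the
    charged residues R, K, D, E and in G, and depleted in L).

    Raises
    ------
    EmptyDatasetError
        On an empty record list.
    """
    if not records:
        raise EmptyDatasetError("cannot profile an empty record list")
    mat = np.stack([aa_composition(r) for r in records])
    return mat.mean(axis=0) * 100.0


PROFILE_RESIDUES = tuple(AMINO_ACIDS)
"""Residue order of :func:`class_composition_profile` output."""
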