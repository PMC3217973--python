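"""Evolutionary feature encoding from PSI-BLAST PSSM profiles.

A profile is an m x 20 matrix of per-position log-odds scores.  To obtain a
fixed-length descriptor regardless of m, scores are pooled by the residue
type occupying each position: for residue type r and profile column c,

    x(r, c) = sum of scores[i, c] over positions i where residue(i) == r

(an empty sum is 0).  Each x is divided by the sequence length m and mapped
through a squashing function — the logistic 1/(1 + e^-x) by default — giving
a 400-dimensional vector with entries strictly inside (0, 1), indexed
(sequence residue type major, profile column minor) in canonical alphabetical
order.  Residue types absent from the sequence therefore encode as
logistic(0) = 0.5; set ``absent_as_zero=True`` to zero them instead.
"""

from __future__ import annotations

import warnings
from typing import Callable

import numpy as np

from .alphabet import AA_INDEX
from .seqio import PSSMProfile


def logistic(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function 1/(1 + e^-x)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def pssm_to_vector(
    profile: PSSMProfile,
    scale: Callable[[np.ndarray], np.ndarray] = logistic,
    absent_as_zero: bool = False,
) -> np.ndarray:
    """Pool a PSSM profile into the 400-dim evolutionary feature vector.

    Positions whose residue letter is outside the 20-letter alphabet are
    excluded from every row sum (with a warning); the divisor stays the full
    profile length m, so duplicating a profile (m -> 2m with rows repeated)
    leaves the vector unchanged.

    Parameters
    ----------
    profile : PSSMProfile
        Parsed profile with canonical column order.
    scale : callable
        Squashing function applied to the length-normalised sums; the
        default logistic maps into (0, 1).
    absent_as_zero : bool
        If True, entries for residue types absent from the sequence are set
        to 0 instead of scale(0).
    """
    m = profile.length
    sums = np.zeros((20, 20), dtype=float)
    present = np.zeros(20, dtype=bool)
    skipped = 0
    for i, letter in enumerate(profile.residues):
        r = AA_INDEX.get(letter)
        if r is None:
            skipped += 1
            continue
        sums[r] += profile.scores[i]
        present[r] = True
    if skipped:
        warnings.warn(
            f"PSSM {profile.protein_id!r}: {skipped} position(s) with "
            "non-standard residues excluded from row sums",
            stacklevel=2,
        )
    vec = scale(sums / m)
    if absent_as_zero:
        vec[~present] = 0.0
    return vec.reshape(400)
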