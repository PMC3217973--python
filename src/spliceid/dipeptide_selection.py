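"""Hypergeometric selection of class-associated dipeptides.

Each of the 400 ordered residue pairs is scored by how over-represented it
is among the positive proteins.  With

* K — number of proteins in the background (positives + negatives),
* T — number of positive proteins,
* k — number of proteins *containing* the pair (presence, not frequency),
* t — number of positive proteins containing the pair,

the p-value is the hypergeometric upper tail P(X >= t) for
X ~ Hypergeometric(K, T, k): the chance that a random size-k subset of the
background holds at least t positives.  A pair is selected when
p < alpha (default 0.05) **and** its probability difference
t/T - (k-t)/(K-T) is strictly positive, i.e. it is genuinely more prevalent
in positives.  On the original splicing-factor data this dual filter keeps
64 of the 400 pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .alphabet import AA_INDEX, DIPEPTIDES
from .errors import EmptyDatasetError, EncodingError
from .composition import dipeptide_composition
from .seqio import ProteinRecord


@dataclass(frozen=True)
class DipeptideStat:
    """Presence counts and significance of one ordered residue pair."""

    pair: str
    K: int
    T: int
    k: int
    t: int
    p_value: float
    prob_pos: float
    prob_neg: float
    prob_diff: float


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of significance screening over all 400 dipeptides.

    ``selected`` holds exactly the pairs with p_value < alpha and
    prob_diff > 0, sorted ascending by p-value with lexicographic
    tie-breaking; ``stats`` holds all 400 per-pair statistics in canonical
    pair order.
    """

    selected: tuple[str, ...]
    alpha: float
    stats: tuple[DipeptideStat, ...]

    def stat(self, pair: str) -> DipeptideStat:
        return self.stats[20 * AA_INDEX[pair[0]] + AA_INDEX[pair[1]]]


def presence_matrix(records: list[ProteinRecord]) -> np.ndarray:
    """Boolean (n_records, 400) matrix of dipeptide presence.

    Entry (i, j) is True iff record i contains pair j as adjacent residues
    at least once; windows overlapping a non-standard letter never count.
    """
    out = np.zeros((len(records), 400), dtype=bool)
    for i, rec in enumerate(records):
        seq = rec.sequence
        for p in range(len(seq) - 1):
            a = AA_INDEX.get(seq[p])
            b = AA_INDEX.get(seq[p + 1])
            if a is not None and b is not None:
                out[i, 20 * a + b] = True
    return out


def count_presence(records: list[ProteinRecord], pair: str) -> int:
    """Number of records whose sequence contains ``pair`` at least once.

    Presence semantics: multiple occurrences in one sequence count once.
    """
    if len(pair) != 2 or pair[0] not in AA_INDEX or pair[1] not in AA_INDEX:
        raise ValueError(f"{pair!r} is not an ordered pair of standard residues")
    j = 20 * AA_INDEX[pair[0]] + AA_INDEX[pair[1]]
    return int(presence_matrix(records)[:, j].sum())


def _validate_counts(K: int, T: int, k: int, t: int) -> None:
    if K < 1:
        raise ValueError(f"background size K={K} must be >= 1")
    if not 0 <= T <= K:
        raise ValueError(f"positive count T={T} outside [0, K={K}]")
    if not 0 <= k <= K:
        raise ValueError(f"containing count k={k} outside [0, K={K}]")
    if not max(0, k + T - K) <= t <= min(T, k):
        raise ValueError(
            f"t={t} outside the hypergeometric support "
            f"[{max(0, k + T - K)}, {min(T, k)}] for K={K}, T={T}, k={k}"
        )


def hypergeometric_pvalues(
    K: int, T: int, k: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Vectorised upper-tail p-values P(X >= t), X ~ Hypergeom(K, T, k).

    ``k`` and ``t`` are broadcast together; each entry must satisfy the
    hypergeometric support constraints.
    """
    k = np.asarray(k, dtype=np.int64)
    t = np.asarray(t, dtype=np.int64)
    if K < 1 or not 0 <= T <= K:
        raise ValueError(f"invalid K={K}, T={T}")
    if np.any(k < 0) or np.any(k > K):
        raise ValueError("k outside [0, K]")
    lo = np.maximum(0, k + T - K)
    hi = np.minimum(T, k)
    if np.any(t < lo) or np.any(t > hi):
        raise ValueError("t outside the hypergeometric support")
    # sf(t-1) = P(X >= t); scipy parameterisation: M=K, n=T, N=k
    p = hypergeom.sf(t - 1, K, T, k)
    # the upper tail including the support minimum is exactly 1
    return np.clip(p, 0.0, 1.0)


def hypergeometric_pvalue(K: int, T: int, k: int, t: int) -> float:
    """Upper-tail p-value P(X >= t) for X ~ Hypergeometric(K, T, k).

    X counts positives in a uniformly random size-k subset of a K-element
    background containing T positives.  Returns a value in (0, 1]; t at the
    support minimum (e.g. t = 0) gives exactly 1.

    Raises
    ------
    ValueError
        If (K, T, k, t) violate the support constraints
        0 <= T <= K, 0 <= k <= K, max(0, k+T-K) <= t <= min(T, k).
    """
    _validate_counts(K, T, k, t)
    return float(
        hypergeometric_pvalues(K, T, np.asarray([k]), np.asarray([t]))[0]
    )


def select_significant(
    pos: list[ProteinRecord],
    neg: list[ProteinRecord],
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> SelectionResult:
    """Screen all 400 dipeptides for over-representation in positives.

    A pair is selected iff p_value < alpha and prob_diff > 0 (both strict).
    ``bonferroni=True`` divides alpha by 400 first; the default follows the
    original procedure of applying the raw threshold.

    Raises
    ------
    EmptyDatasetError
        If either class is empty.
    """
    if not pos or not neg:
        raise EmptyDatasetError("both positive and negative sets must be non-empty")
    threshold = alpha / 400.0 if bonferroni else alpha
    K = len(pos) + len(neg)
    T = len(pos)
    pos_presence = presence_matrix(pos)
    neg_presence = presence_matrix(neg)
    t_arr = pos_presence.sum(axis=0).astype(np.int64)
    k_arr = t_arr + neg_presence.sum(axis=0).astype(np.int64)
    p_arr = hypergeometric_pvalues(K, T, k_arr, t_arr)
    prob_pos = t_arr / T
    prob_neg = (k_arr - t_arr) / (K - T)
    prob_diff = prob_pos - prob_neg

    stats = tuple(
        DipeptideStat(
            pair=DIPEPTIDES[j],
            K=K,
            T=T,
            k=int(k_arr[j]),
            t=int(t_arr[j]),
            p_value=float(p_arr[j]),
            prob_pos=float(prob_pos[j]),
            prob_neg=float(prob_neg[j]),
            prob_diff=float(prob_diff[j]),
        )
        for j in range(400)
    )
    hits = [s for s in stats if s.p_value < threshold and s.prob_diff > 0.0]
    hits.sort(key=lambda s: (s.p_value, s.pair))
    return SelectionResult(
        selected=tuple(s.pair for s in hits), alpha=threshold, stats=stats
    )


def encode_selected(record: ProteinRecord, result: SelectionResult) -> np.ndarray:
    """Dipeptide-composition values restricted to the selected pairs.

    Values are taken from the full 400-dim composition and are *not*
    renormalised after restriction, so each entry remains the fraction of
    the sequence's dipeptide windows holding that pair.

    Raises
    ------
    EncodingError
        If the selection is empty or the record has no valid window.
    """
    if not result.selected:
        raise EncodingError(
            "empty dipeptide selection: nothing to encode (rerun selection "
            "with a larger dataset or higher alpha)"
        )
    full = dipeptide_composition(record)
    idx = [20 * AA_INDEX[p[0]] + AA_INDEX[p[1]] for p in result.selected]
    return full[idx]
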