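"""Binary InterPro-domain features from a positive-class vocabulary.

The vocabulary is built from the *positive* (splicing-factor) training
records only: an accession enters it when strictly more than
``min_support_exclusive`` distinct positives carry it (default: more than
five, the rule that yields the 15 hallmark domains — RRM, LSm, WD40
repeats... — on the original data).  Proteins are then encoded as binary
presence vectors over the vocabulary.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import EmptyDatasetError, EncodingError
from .seqio import ProteinRecord


@dataclass(frozen=True)
class DomainVocabulary:
    """Ordered list of (accession, positive-class support) pairs.

    Entries are sorted descending by support, ties broken by accession, and
    every support strictly exceeds ``min_support_exclusive``.
    """

    entries: tuple[tuple[str, int], ...]
    min_support_exclusive: int

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(acc for acc, _ in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def build_vocabulary(
    pos: list[ProteinRecord], min_support_exclusive: int = 5
) -> DomainVocabulary:
    """Count accessions over positive proteins and keep the well-supported.

    Support is the number of distinct positive proteins annotated with the
    accession; retention requires support > ``min_support_exclusive``
    (strict, so the default keeps accessions seen in six or more).

    Raises
    ------
    EmptyDatasetError
        On an empty positive list.
    """
    if not pos:
        raise EmptyDatasetError("cannot build a domain vocabulary from no positives")
    support: Counter[str] = Counter()
    for rec in pos:
        support.update(set(rec.domains))
    kept = [
        (acc, n) for acc, n in support.items() if n > min_support_exclusive
    ]
    kept.sort(key=lambda e: (-e[1], e[0]))
    return DomainVocabulary(tuple(kept), min_support_exclusive)


def encode_domains(record: ProteinRecord, vocab: DomainVocabulary) -> np.ndarray:
    """Binary vector: entry j = 1 iff vocabulary accession j annotates the record.

    Raises
    ------
    EncodingError
        If the vocabulary is empty.
    """
    if len(vocab) == 0:
        raise EncodingError(
            "empty domain vocabulary: no accession passed the support "
            "threshold, so domain features cannot be encoded"
        )
    return np.array(
        [1.0 if acc in record.domains else 0.0 for acc in vocab.accessions]
    )


def write_vocabulary(vocab: DomainVocabulary, path: str | Path) -> None:
    """Export the vocabulary as a two-column TSV (accession, support)."""
    with open(path, "w") as handle:
        for acc, n in vocab.entries:
            handle.write(f"{acc}\t{n}\n")
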