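"""Reading and validating protein sequences, domain tables and PSSM profiles.

The three input formats are:

* FASTA — protein sequences; the header token before the first whitespace
  becomes the record id.
* A headerless two-column TSV mapping protein ids to InterPro accessions
  (``protein_id<TAB>IPRxxxxxx``), one pair per line.
* PSI-BLAST ASCII PSSMs (the ``-out_ascii_pssm`` dialect): header lines,
  one row per sequence position holding the position index, the query
  residue, 20 log-odds integers and 20 weighted-percentage integers, then
  footer statistics.  Only the log-odds block is retained, and columns are
  remapped from PSI-BLAST's native residue order to the package-wide
  alphabetical order (see :mod:`spliceid.alphabet`).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import (
    AMINO_ACIDS,
    CANONICAL_TO_PSIBLAST,
    PSIBLAST_ORDER,
    PSIBLAST_TO_CANONICAL,
    is_standard,
)
from .errors import EmptyDatasetError, ParseError, ValidationError

LABELS = ("positive", "negative", "unknown")

_IPR_RE = re.compile(r"^IPR\d{6}$")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with class label and optional domain annotations.

    Parameters
    ----------
    id : str
        Non-empty identifier, unique within a dataset.
    sequence : str
        Upper-case residue string, length >= 1.  Letters outside the 20
        standard residues are permitted (they are excluded from feature
        numerators and denominators downstream).
    label : {"positive", "negative", "unknown"}
        Class membership; "positive" marks a splicing factor.
    domains : frozenset of str
        InterPro accessions annotated on the protein (possibly empty).
    """

    id: str
    sequence: str
    label: str = "unknown"
    domains: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"record {self.id!r}: sequence must be non-empty")
        if self.label not in LABELS:
            raise ValidationError(
                f"record {self.id!r}: label {self.label!r} not one of {LABELS}"
            )
        if not isinstance(self.domains, frozenset):
            object.__setattr__(self, "domains", frozenset(self.domains))

    @property
    def has_nonstandard(self) -> bool:
        """True if the sequence contains a letter outside the 20 residues."""
        return any(not is_standard(ch) for ch in self.sequence)

    def with_domains(self, domains: Iterable[str]) -> "ProteinRecord":
        """Copy of this record with the given domain annotation set."""
        return ProteinRecord(self.id, self.sequence, self.label, frozenset(domains))

    def with_label(self, label: str) -> "ProteinRecord":
        return ProteinRecord(self.id, self.sequence, label, self.domains)


@dataclass(frozen=True)
class PSSMProfile:
    """Position-specific scoring matrix for one protein.

    ``scores`` is an m x 20 integer array of log-odds scores with columns in
    the canonical alphabetical residue order; row i scores position i of
    ``residues``.
    """

    protein_id: str
    residues: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=np.int64)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValidationError(
                f"PSSM {self.protein_id!r}: scores must be m x 20, got {scores.shape}"
            )
        if scores.shape[0] != len(self.residues):
            raise ValidationError(
                f"PSSM {self.protein_id!r}: {scores.shape[0]} score rows for "
                f"{len(self.residues)} residues"
            )
        if len(self.residues) < 1:
            raise ValidationError(f"PSSM {self.protein_id!r}: empty profile")

    @property
    def length(self) -> int:
        return len(self.residues)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PSSMProfile):
            return NotImplemented
        return (
            self.protein_id == other.protein_id
            and self.residues == other.residues
            and np.array_equal(self.scores, other.scores)
        )

    __hash__ = None  # type: ignore[assignment]


def read_fasta(path: str | Path, label: str = "unknown") -> list[ProteinRecord]:
    """Read a FASTA file into labelled :class:`ProteinRecord` objects.

    Sequences are upper-cased; the header token before the first whitespace
    becomes the id.  Records containing letters outside the 20 standard
    residues are kept but a warning names them.

    Raises
    ------
    EmptyDatasetError
        If the file contains no FASTA entries.
    ValidationError
        If two entries share an id.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    flagged: list[str] = []
    with open(path) as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            rec = ProteinRecord(entry.id, str(entry.seq).upper(), label)
            if rec.id in seen:
                raise ValidationError(f"duplicate id {rec.id!r} in {path}")
            seen.add(rec.id)
            if rec.has_nonstandard:
                flagged.append(rec.id)
            records.append(rec)
    if not records:
        raise EmptyDatasetError(f"no FASTA entries in {path}")
    if flagged:
        warnings.warn(
            f"{path}: {len(flagged)} record(s) contain non-standard letters: "
            + ", ".join(flagged[:10]),
            stacklevel=2,
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA (id as header, 60-column wrapped sequence)."""
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(entries, handle, "fasta")


def read_domain_table(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a headerless TSV of (protein_id, InterPro accession) pairs.

    All accessions for a protein are aggregated into one set.  Accessions
    not matching ``IPR`` + 6 digits trigger a warning and are skipped.
    Proteins absent from the table simply map to nothing here; downstream
    they are treated as having an empty annotation set.

    Raises
    ------
    ParseError
        On a line that does not hold exactly two tab-separated fields.
    """
    path = Path(path)
    mapping: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0]:
                raise ParseError(
                    f"{path}:{lineno}: expected 'protein_id<TAB>IPRxxxxxx', "
                    f"got {line!r}"
                )
            pid, acc = fields
            if not _IPR_RE.match(acc):
                warnings.warn(
                    f"{path}:{lineno}: {acc!r} is not an InterPro accession "
                    "(IPR followed by 6 digits); pair skipped",
                    stacklevel=2,
                )
                continue
            mapping.setdefault(pid, set()).add(acc)
    return {pid: frozenset(accs) for pid, accs in mapping.items()}


def write_domain_table(
    mapping: Mapping[str, Iterable[str]], path: str | Path
) -> None:
    """Write a protein -> accession mapping as a headerless two-column TSV."""
    with open(path, "w") as handle:
        for pid in sorted(mapping):
            for acc in sorted(mapping[pid]):
                handle.write(f"{pid}\t{acc}\n")


def attach_domains(
    records: Iterable[ProteinRecord], mapping: Mapping[str, frozenset[str]]
) -> list[ProteinRecord]:
    """Return records with domain sets looked up from ``mapping``.

    Records absent from the mapping receive the empty set.
    """
    return [r.with_domains(mapping.get(r.id, frozenset())) for r in records]


def parse_psiblast_pssm(path: str | Path, protein_id: str) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM file into a :class:`PSSMProfile`.

    Only the first 20 integer columns (position-specific log-odds) are
    retained; the weighted-percentage block and the footer statistics
    (K/lambda lines) are ignored.  Columns are remapped from PSI-BLAST's
    native residue order to the canonical alphabetical order.

    Raises
    ------
    ParseError
        On a position row with fewer than 40 numeric fields, or if the file
        holds no position rows at all.
    """
    path = Path(path)
    residues: list[str] = []
    rows: list[list[int]] = []
    with open(path) as handle:
        for line in handle:
            tokens = line.split()
            if len(tokens) < 2 or not tokens[0].isdigit():
                continue  # header, blank or footer line
            if not (len(tokens[1]) == 1 and tokens[1].isalpha()):
                continue
            pos, letter = int(tokens[0]), tokens[1]
            numeric: list[float] = []
            for tok in tokens[2:]:
                try:
                    numeric.append(float(tok))
                except ValueError:
                    break
            if len(numeric) < 40:
                raise ParseError(
                    f"{path}: position {pos}: expected 40 numeric fields "
                    f"(20 log-odds + 20 percentages), found {len(numeric)}"
                )
            residues.append(letter)
            rows.append([int(v) for v in numeric[:20]])
    if not rows:
        raise ParseError(f"{path}: no PSSM position rows found")
    native = np.array(rows, dtype=np.int64)
    canonical = native[:, PSIBLAST_TO_CANONICAL]
    return PSSMProfile(protein_id, "".join(residues), canonical)


def write_psiblast_pssm(profile: PSSMProfile, path: str | Path) -> None:
    """Serialize a profile back to the PSI-BLAST ASCII dialect.

    Columns are emitted in PSI-BLAST's native residue order; the
    weighted-percentage block is written as zeros and a standard footer is
    appended, so the output re-parses to an identical profile.
    """
    native = profile.scores[:, CANONICAL_TO_PSIBLAST]
    cols = "  ".join(PSIBLAST_ORDER)
    with open(path, "w") as handle:
        handle.write("\n")
        handle.write(
            "Last position-specific scoring matrix computed, weighted "
            "observed percentages rounded down, information per position, "
            "and relative weight of gapless real matches to pseudocounts\n"
        )
        handle.write(f"            {cols}   {cols}\n")
        for i, (letter, row) in enumerate(zip(profile.residues, native), start=1):
            scores = " ".join(f"{v:3d}" for v in row)
            pcts = " ".join(f"{0:3d}" for _ in range(20))
            handle.write(f"{i:5d} {letter}  {scores}  {pcts}  0.00 0.00\n")
        handle.write("\n")
        handle.write("                      K         Lambda\n")
        handle.write("Standard Ungapped    0.1347     0.3179\n")
        handle.write("Standard Gapped      0.0410     0.2670\n")
        handle.write("PSI Ungapped         0.1347     0.3179\n")
        handle.write("PSI Gapped           0.0410     0.2670\n")


def validate_unique_ids(records: Iterable[ProteinRecord]) -> None:
    """Raise :class:`ValidationError` naming the first duplicated id."""
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValidationError(f"duplicate id {rec.id!r} in dataset")
        seen.add(rec.id)
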