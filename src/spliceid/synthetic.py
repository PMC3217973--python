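"""Synthetic labelled datasets with the class structure the method assumes.

The generator emulates the three signals the classifier exploits:

* **Compositional bias** — positives (synthetic "splicing factors") are
  drawn from a residue distribution enriched in the charged residues
  R, K, D, E and in G, and depleted in L and C, over a human-proteome-like
  background; the shifts are one to two percentage points, the scale seen
  when real splicing factors are profiled against non-splicing proteins.
* **Class-enriched dipeptides** — chosen pairs are inserted into a class-
  dependent fraction of sequences, giving the hypergeometric screen a
  planted truth to recover.
* **Class-enriched domains** — InterPro-style accessions assigned with
  class-dependent prevalence, mirroring the real support profile where two
  hallmark domains (RRM-like) cover a quarter of positives each and a tail
  of minor domains follows, on top of a sparse uninformative background
  pool shared by both classes.

Toy PSSM profiles score each position's own residue positively (+5) against
a noisy negative background, so profile pooling yields a signal correlated
with composition.  Everything is a pure function of the spec and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import AMINO_ACIDS
from .errors import ValidationError
from .seqio import (
    ProteinRecord,
    PSSMProfile,
    write_domain_table,
    write_fasta,
    write_psiblast_pssm,
)

#: approximate human proteome residue frequencies, canonical order
DEFAULT_NEG_FREQS: dict[str, float] = {
    "A": 0.072, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.036,
    "G": 0.066, "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100,
    "M": 0.021, "N": 0.036, "P": 0.063, "Q": 0.048, "R": 0.056,
    "S": 0.083, "T": 0.053, "V": 0.060, "W": 0.012, "Y": 0.027,
}

#: percentage-point shifts applied to the positive class
POSITIVE_SHIFTS: dict[str, float] = {
    "R": 0.020, "K": 0.020, "E": 0.020, "D": 0.015, "G": 0.010,
    "L": -0.020, "C": -0.010,
}

#: (pair, prevalence in positives, prevalence in negatives); tryptophan
#: pairs keep the background presence rate low
DEFAULT_PLANTED_DIPEPTIDES: tuple[tuple[str, float, float], ...] = (
    ("WC", 0.90, 0.05),
    ("WM", 0.85, 0.05),
)

#: (accession, prevalence in positives, prevalence in negatives), scaled
#: from the real hallmark-domain support profile
DEFAULT_PLANTED_DOMAINS: tuple[tuple[str, float, float], ...] = (
    ("IPR012677", 0.27, 0.010),
    ("IPR000504", 0.26, 0.010),
    ("IPR001163", 0.065, 0.005),
    ("IPR006649", 0.060, 0.005),
    ("IPR001680", 0.055, 0.010),
)

_BACKGROUND_POOL: tuple[str, ...] = tuple(f"IPR9{i:05d}" for i in range(40))
_BACKGROUND_PREVALENCE = 0.01


def _default_freq_vectors() -> tuple[np.ndarray, np.ndarray]:
    neg = np.array([DEFAULT_NEG_FREQS[a] for a in AMINO_ACIDS])
    neg = neg / neg.sum()
    pos = neg.copy()
    shifted = [i for i, a in enumerate(AMINO_ACIDS) if a in POSITIVE_SHIFTS]
    for i in shifted:
        pos[i] += POSITIVE_SHIFTS[AMINO_ACIDS[i]]
    # absorb the net shift proportionally over the untouched residues
    others = [i for i in range(20) if i not in shifted]
    deficit = 1.0 - pos.sum()
    pos[others] += neg[others] * deficit / neg[others].sum()
    return pos, neg


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterisation of a synthetic dataset.

    Defaults define the reference study conditions: 200 positives vs 800
    negatives, lengths uniform on [80, 600], the compositional shifts above,
    two planted dipeptides and five planted domains.
    """

    n_pos: int = 200
    n_neg: int = 800
    length_range: tuple[int, int] = (80, 600)
    pos_residue_freqs: np.ndarray = field(
        default_factory=lambda: _default_freq_vectors()[0]
    )
    neg_residue_freqs: np.ndarray = field(
        default_factory=lambda: _default_freq_vectors()[1]
    )
    planted_dipeptides: tuple[tuple[str, float, float], ...] = (
        DEFAULT_PLANTED_DIPEPTIDES
    )
    planted_domains: tuple[tuple[str, float, float], ...] = DEFAULT_PLANTED_DOMAINS
    pssm_noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pos_residue_freqs", "neg_residue_freqs"):
            freqs = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, freqs)
            if freqs.shape != (20,) or abs(freqs.sum() - 1.0) > 1e-9 or (
                freqs < 0
            ).any():
                raise ValidationError(f"{name} must be a 20-simplex vector")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValidationError("n_pos and n_neg must be >= 1")
        lo, hi = self.length_range
        if not (2 <= lo <= hi):
            raise ValidationError(f"invalid length range {self.length_range}")
        for pair, p_pos, p_neg in self.planted_dipeptides:
            if len(pair) != 2 or any(c not in AMINO_ACIDS for c in pair):
                raise ValidationError(f"planted dipeptide {pair!r} invalid")
            if not (0 <= p_pos <= 1 and 0 <= p_neg <= 1):
                raise ValidationError(f"prevalence for {pair!r} outside [0,1]")
        for acc, p_pos, p_neg in self.planted_domains:
            if not (0 <= p_pos <= 1 and 0 <= p_neg <= 1):
                raise ValidationError(f"prevalence for {acc!r} outside [0,1]")
        if self.pssm_noise < 0:
            raise ValidationError("pssm_noise must be non-negative")


def _generate_class(
    rng: np.random.Generator,
    n: int,
    freqs: np.ndarray,
    length_range: tuple[int, int],
    planted_dipeptides: list[tuple[str, float]],
    planted_domains: list[tuple[str, float]],
    prefix: str,
    label: str,
) -> list[ProteinRecord]:
    lo, hi = length_range
    records: list[ProteinRecord] = []
    aas = np.array(list(AMINO_ACIDS))
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(aas, size=length, p=freqs)
        for pair, prevalence in planted_dipeptides:
            if rng.random() < prevalence:
                pos = int(rng.integers(0, length - 1))
                seq[pos] = pair[0]
                seq[pos + 1] = pair[1]
        domains = {
            acc for acc, prevalence in planted_domains if rng.random() < prevalence
        }
        background = rng.random(len(_BACKGROUND_POOL)) < _BACKGROUND_PREVALENCE
        domains.update(
            acc for acc, hit in zip(_BACKGROUND_POOL, background) if hit
        )
        records.append(
            ProteinRecord(
                id=f"{prefix}{i + 1:05d}",
                sequence="".join(seq),
                label=label,
                domains=frozenset(domains),
            )
        )
    return records


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Draw (positives, negatives) fully determined by ``spec`` and its seed.

    Sequences are i.i.d. draws from the class residue frequencies; planted
    dipeptides overwrite a random adjacent position pair with their class
    prevalence; domains are assigned per class prevalence plus the shared
    background pool.
    """
    rng = np.random.default_rng(spec.seed)
    pos = _generate_class(
        rng,
        spec.n_pos,
        spec.pos_residue_freqs,
        spec.length_range,
        [(p, pp) for p, pp, _ in spec.planted_dipeptides],
        [(a, pp) for a, pp, _ in spec.planted_domains],
        prefix="sf",
        label="positive",
    )
    neg = _generate_class(
        rng,
        spec.n_neg,
        spec.neg_residue_freqs,
        spec.length_range,
        [(p, pn) for p, _, pn in spec.planted_dipeptides],
        [(a, pn) for a, _, pn in spec.planted_domains],
        prefix="ns",
        label="negative",
    )
    return pos, neg


def generate_pssm(record: ProteinRecord, noise: float, seed: int) -> PSSMProfile:
    """Toy PSSM for one record: +5 at each position's own residue column,
    -2 noisy background elsewhere, integer-rounded; deterministic in seed.
    """
    rng = np.random.default_rng(seed)
    m = len(record.sequence)
    scores = -2.0 + noise * rng.normal(size=(m, 20))
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for i, ch in enumerate(record.sequence):
        j = aa_index.get(ch)
        if j is not None:
            scores[i, j] += 7.0  # lifts the own-residue column to ~+5
    return PSSMProfile(
        protein_id=record.id,
        residues=record.sequence,
        scores=np.rint(scores).astype(np.int64),
    )


def generate_pssms(
    records: list[ProteinRecord], noise: float, seed: int
) -> dict[str, PSSMProfile]:
    """One toy profile per record, with per-record seeds derived stably."""
    child_seeds = np.random.SeedSequence(seed).generate_state(len(records))
    return {
        rec.id: generate_pssm(rec, noise, int(s) & 0x7FFFFFFF)
        for rec, s in zip(records, child_seeds)
    }


def write_dataset(
    spec: SyntheticSpec, out_dir: str | Path, with_pssm: bool = True
) -> dict[str, Path]:
    """Generate and write a dataset: pos.fa, neg.fa, domains.tsv, pssm/*.pssm.

    Returns the paths written (``pssm`` maps to the profile directory).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pos, neg = generate_dataset(spec)
    paths = {
        "pos": out_dir / "pos.fa",
        "neg": out_dir / "neg.fa",
        "domains": out_dir / "domains.tsv",
    }
    write_fasta(pos, paths["pos"])
    write_fasta(neg, paths["neg"])
    write_domain_table(
        {r.id: r.domains for r in pos + neg if r.domains}, paths["domains"]
    )
    if with_pssm:
        pssm_dir = out_dir / "pssm"
        pssm_dir.mkdir(exist_ok=True)
        profiles = generate_pssms(pos + neg, spec.pssm_noise, spec.seed)
        for pid, profile in profiles.items():
            write_psiblast_pssm(profile, pssm_dir / f"{pid}.pssm")
        paths["pssm"] = pssm_dir
    return paths
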