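"""Feature assembly, RBF-SVM training, cross-validation and evaluation.

Feature blocks are concatenated in a fixed canonical order

    aac (20) | dpc (400) | sig_dpc (|selected|) | pssm (400) | domain (|vocab|)

so column layout is reproducible for any active subset.  The classifier is
a binary soft-margin SVM with the radial-basis-function kernel
exp(-gamma * ||u - v||^2), regularisation C, trained with libsvm (via
scikit-learn's SVC).  C and gamma are tuned by exhaustive grid search that
maximises pooled k-fold cross-validation accuracy on seeded stratified
folds.  Performance is reported as

    sensitivity = TP / (TP + FN) * 100
    specificity = TN / (TN + FP) * 100
    accuracy    = (TP + TN) / (TP + TN + FP + FN) * 100

with the cross-validation headline computed from the confusion counts
pooled over the k validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .composition import aa_composition, dipeptide_composition
from .dipeptide_selection import SelectionResult, encode_selected
from .domain_features import DomainVocabulary, encode_domains
from .errors import EncodingError, SpliceIdError, ValidationError
from .pssm_features import pssm_to_vector
from .seqio import PSSMProfile, ProteinRecord, parse_psiblast_pssm

BLOCK_ORDER = ("aac", "dpc", "sig_dpc", "pssm", "domain")

#: libsvm practitioners' guide convention: C = 2^-5, 2^-3, ..., 2^15
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0 ** e for e in range(-5, 16, 2))
#: gamma = 2^-15, 2^-13, ..., 2^3
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0 ** e for e in range(-15, 4, 2))

BUNDLE_FORMAT = "spliceid-model/1"


class PssmSource:
    """Resolves protein ids to PSSM profiles, from a directory or a mapping.

    A directory source expects one file per record named ``<id>.pssm`` in
    the PSI-BLAST ASCII dialect.
    """

    def __init__(
        self,
        directory: str | Path | None = None,
        mapping: Mapping[str, PSSMProfile] | None = None,
    ) -> None:
        if (directory is None) == (mapping is None):
            raise ValueError("provide exactly one of directory or mapping")
        self._dir = Path(directory) if directory is not None else None
        self._map = dict(mapping) if mapping is not None else None

    @classmethod
    def from_dir(cls, directory: str | Path) -> "PssmSource":
        return cls(directory=directory)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, PSSMProfile]) -> "PssmSource":
        return cls(mapping=mapping)

    def get(self, protein_id: str) -> PSSMProfile:
        if self._map is not None:
            if protein_id not in self._map:
                raise EncodingError(f"no PSSM profile for record {protein_id!r}")
            return self._map[protein_id]
        path = self._dir / f"{protein_id}.pssm"  # type: ignore[operator]
        if not path.exists():
            raise EncodingError(
                f"no PSSM file for record {protein_id!r} (expected {path})"
            )
        return parse_psiblast_pssm(path, protein_id)


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature blocks are active and the frozen resources they need.

    ``blocks`` may be given in any order; it is canonicalised to the fixed
    block order so assembled matrices always have the same column layout.
    """

    blocks: tuple[str, ...]
    selection: SelectionResult | None = None
    vocabulary: DomainVocabulary | None = None
    pssms: PssmSource | None = None

    def __post_init__(self) -> None:
        unknown = set(self.blocks) - set(BLOCK_ORDER)
        if unknown:
            raise ValidationError(f"unknown feature blocks: {sorted(unknown)}")
        if not self.blocks:
            raise ValidationError("at least one feature block must be active")
        ordered = tuple(b for b in BLOCK_ORDER if b in self.blocks)
        object.__setattr__(self, "blocks", ordered)
        if "sig_dpc" in ordered and self.selection is None:
            raise ValidationError("block 'sig_dpc' requires a SelectionResult")
        if "domain" in ordered and self.vocabulary is None:
            raise ValidationError("block 'domain' requires a DomainVocabulary")
        if "pssm" in ordered and self.pssms is None:
            raise ValidationError("block 'pssm' requires a PssmSource")

    @property
    def width(self) -> int:
        widths = {
            "aac": 20,
            "dpc": 400,
            "sig_dpc": len(self.selection.selected) if self.selection else 0,
            "pssm": 400,
            "domain": len(self.vocabulary) if self.vocabulary else 0,
        }
        return sum(widths[b] for b in self.blocks)


def encode_record(record: ProteinRecord, config: FeatureConfig) -> np.ndarray:
    """Concatenated feature vector for one record, in canonical block order.

    Raises
    ------
    EncodingError
        Naming the record, if any active block cannot encode it (missing
        PSSM file, no valid dipeptide window, ...).
    """
    parts: list[np.ndarray] = []
    for block in config.blocks:
        if block == "aac":
            parts.append(aa_composition(record))
        elif block == "dpc":
            parts.append(dipeptide_composition(record))
        elif block == "sig_dpc":
            parts.append(encode_selected(record, config.selection))
        elif block == "pssm":
            profile = config.pssms.get(record.id)
            parts.append(pssm_to_vector(profile))
        elif block == "domain":
            parts.append(encode_domains(record, config.vocabulary))
    return np.concatenate(parts)


_LABEL_TO_INT = {"negative": 0, "positive": 1}


def assemble_features(
    records: Sequence[ProteinRecord],
    config: FeatureConfig,
    require_labels: bool = True,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Design matrix and 0/1 label vector for a record list.

    Returns ``(X, y)`` with X of shape (n_records, config.width) and y the
    integer labels (positive=1, negative=0), or ``y=None`` when
    ``require_labels=False`` and some record is unlabelled.

    Raises
    ------
    EncodingError
        Naming the first record that an active block cannot encode.
    ValidationError
        If ``require_labels`` and a record has label "unknown".
    """
    if not records:
        return np.empty((0, config.width)), np.empty(0, dtype=np.int64)
    rows = [encode_record(rec, config) for rec in records]
    X = np.stack(rows)
    if X.shape[1] != config.width:
        raise ValidationError(
            f"assembled width {X.shape[1]} != configured width {config.width}"
        )
    labels = [rec.label for rec in records]
    if any(lab == "unknown" for lab in labels):
        if require_labels:
            raise ValidationError("records must be labelled positive/negative")
        return X, None
    y = np.array([_LABEL_TO_INT[lab] for lab in labels], dtype=np.int64)
    return X, y


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion counts with sensitivity/specificity/accuracy percentages."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "EvalMetrics":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )

    def __add__(self, other: "EvalMetrics") -> "EvalMetrics":
        return EvalMetrics(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else 0.0

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return 100.0 * self.tn / denom if denom else 0.0

    @property
    def accuracy(self) -> float:
        denom = self.tp + self.tn + self.fp + self.fn
        return 100.0 * (self.tp + self.tn) / denom if denom else 0.0


@dataclass(frozen=True)
class CVResult:
    """Per-fold and pooled cross-validation metrics.

    ``pooled`` is computed from confusion counts summed over folds
    (micro-averaged); ``fold_assignment[i]`` is the validation fold of
    sample i.
    """

    folds: tuple[EvalMetrics, ...]
    pooled: EvalMetrics
    fold_assignment: np.ndarray
    best_params: tuple[float, float] | None = None


@dataclass(frozen=True)
class GridSearchResult:
    best_C: float
    best_gamma: float
    cv: CVResult
    table: tuple[tuple[float, float, float], ...]
    """(C, gamma, pooled accuracy) for every grid point evaluated."""


@dataclass
class ModelBundle:
    """A trained RBF-SVM with its frozen feature configuration.

    Freezing the selection result and domain vocabulary inside the bundle
    guarantees that independent-test encoding uses exactly the training-time
    feature definitions.
    """

    svc: SVC
    config: FeatureConfig | None
    C: float
    gamma: float
    seed: int
    metadata: dict = field(default_factory=dict)


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    gamma: float,
    seed: int = 0,
    config: FeatureConfig | None = None,
) -> ModelBundle:
    """Fit an RBF-kernel SVM on a labelled feature matrix.

    Raises
    ------
    ValidationError
        If X is empty, y is single-class, C <= 0 or gamma <= 0, or X's
        width disagrees with ``config``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.size == 0:
        raise ValidationError("empty feature matrix")
    if C <= 0 or gamma <= 0:
        raise ValidationError(f"C and gamma must be positive (got C={C}, gamma={gamma})")
    if len(np.unique(y)) < 2:
        raise ValidationError("training labels must contain both classes")
    if config is not None and X.shape[1] != config.width:
        raise ValidationError(
            f"feature width {X.shape[1]} inconsistent with config width "
            f"{config.width}"
        )
    svc = SVC(kernel="rbf", C=C, gamma=gamma)
    svc.fit(X, y)
    return ModelBundle(svc=svc, config=config, C=C, gamma=gamma, seed=seed)


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    gamma: float,
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation at fixed (C, gamma).

    Folds are a seeded stratified shuffle: every sample is validated exactly
    once and per-fold class counts differ by at most one from proportional.
    Metrics are computed per fold and pooled over the summed confusion.

    Raises
    ------
    ValidationError
        If k < 2 or either class has fewer than k members.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k < 2:
        raise ValidationError(f"k={k} must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if len(counts) < 2 or counts.min() < k:
        raise ValidationError(
            f"each class needs at least k={k} members (class sizes {counts.tolist()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics: list[EvalMetrics] = []
    assignment = np.full(len(y), -1, dtype=np.int64)
    for fold, (train_idx, val_idx) in enumerate(skf.split(X, y)):
        assignment[val_idx] = fold
        svc = SVC(kernel="rbf", C=C, gamma=gamma)
        svc.fit(X[train_idx], y[train_idx])
        fold_metrics.append(
            EvalMetrics.from_predictions(y[val_idx], svc.predict(X[val_idx]))
        )
    pooled = fold_metrics[0]
    for m in fold_metrics[1:]:
        pooled = pooled + m
    return CVResult(
        folds=tuple(fold_metrics), pooled=pooled, fold_assignment=assignment
    )


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    k: int = 5,
    seed: int = 0,
) -> GridSearchResult:
    """Exhaustive (C, gamma) search maximising pooled k-fold CV accuracy.

    Every grid point is evaluated on the *same* seeded folds.  Ties are
    broken toward smaller C, then smaller gamma.  Grids are deduplicated.

    Raises
    ------
    ValidationError
        On empty grids, or as :func:`kfold_cv`.
    """
    Cs = sorted(set(float(c) for c in C_grid))
    gammas = sorted(set(float(g) for g in gamma_grid))
    if not Cs or not gammas:
        raise ValidationError("C and gamma grids must be non-empty")
    best: tuple[float, float, CVResult] | None = None
    table: list[tuple[float, float, float]] = []
    for C in Cs:
        for gamma in gammas:
            cv = kfold_cv(X, y, C, gamma, k=k, seed=seed)
            acc = cv.pooled.accuracy
            table.append((C, gamma, acc))
            if best is None or acc > best[2].pooled.accuracy:
                best = (C, gamma, cv)
    best_C, best_gamma, best_cv = best
    best_cv = CVResult(
        folds=best_cv.folds,
        pooled=best_cv.pooled,
        fold_assignment=best_cv.fold_assignment,
        best_params=(best_C, best_gamma),
    )
    return GridSearchResult(best_C, best_gamma, best_cv, tuple(table))


def evaluate(model: ModelBundle, records: Sequence[ProteinRecord]) -> EvalMetrics:
    """Confusion counts and Sn/Sp/Acc of the model on labelled records.

    Raises
    ------
    ValidationError
        If any record is unlabelled or the bundle has no feature config.
    """
    if model.config is None:
        raise ValidationError("model bundle has no frozen feature config")
    X, y = assemble_features(records, model.config, require_labels=True)
    y_pred = model.svc.predict(X) if len(records) else np.empty(0)
    return EvalMetrics.from_predictions(y, y_pred)


@dataclass(frozen=True)
class Prediction:
    """Per-record prediction: label, decision score, or a failure message."""

    id: str
    label: str | None
    score: float | None
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None


def predict(model: ModelBundle, records: Sequence[ProteinRecord]) -> list[Prediction]:
    """Predict labels and decision scores for records, tolerating failures.

    A record that cannot be encoded under the frozen config (e.g. missing
    PSSM file) is reported as failed; the remaining records are still
    predicted.  Deterministic given the bundle.
    """
    if model.config is None:
        raise ValidationError("model bundle has no frozen feature config")
    out: list[Prediction] = []
    for rec in records:
        try:
            x = encode_record(rec, model.config).reshape(1, -1)
        except SpliceIdError as exc:
            out.append(Prediction(rec.id, None, None, error=str(exc)))
            continue
        score = float(model.svc.decision_function(x)[0])
        label = "positive" if int(model.svc.predict(x)[0]) == 1 else "negative"
        out.append(Prediction(rec.id, label, score))
    return out


def save_bundle(model: ModelBundle, path: str | Path) -> None:
    """Serialize a model bundle (versioned format tag) with joblib."""
    payload = {
        "format": BUNDLE_FORMAT,
        "svc": model.svc,
        "config": model.config,
        "C": model.C,
        "gamma": model.gamma,
        "seed": model.seed,
        "metadata": model.metadata,
    }
    joblib.dump(payload, path)


def load_bundle(path: str | Path) -> ModelBundle:
    """Load a bundle written by :func:`save_bundle`.

    Raises
    ------
    ValidationError
        If the file does not carry the expected format tag.
    """
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != BUNDLE_FORMAT:
        raise ValidationError(f"{path}: not a {BUNDLE_FORMAT} bundle")
    return ModelBundle(
        svc=payload["svc"],
        config=payload["config"],
        C=payload["C"],
        gamma=payload["gamma"],
        seed=payload["seed"],
        metadata=payload.get("metadata", {}),
    )
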