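"""MACCS-fingerprint MLP discriminator for active/nonactive classification.

Closes the design-test loop: ligands with measured binding affinity are
split at a Ki cutoff (default 100 nM, strict less-than) into actives and
inactives, mixed with drug-like decoys (always nonactive), fingerprinted
with the 166 MACCS structural keys, and fed to a multilayer perceptron
(three hidden layers, 166 ReLU units each, Adam).  Generated molecules are
then scored with the active-class probability.

Confusion-matrix metrics are implemented from their closed forms so the
zero-denominator conventions are explicit: any undefined ratio is reported
as 0 together with a ``degenerate`` flag (decoy-heavy designs can produce
folds with no predicted positives).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys

RDLogger.DisableLog("rdApp.*")


class DiscriminatorError(ValueError):
    pass


@dataclass(frozen=True)
class ActivityRecord:
    smiles: str
    ki_nm: float


@dataclass
class LabeledFingerprintSet:
    """166-bit MACCS fingerprints with binary labels and row provenance."""

    fingerprints: np.ndarray  # (N, 166) uint8
    labels: np.ndarray  # (N,) 1 = active, 0 = nonactive
    provenance: list[str]  # per row: active | inactive | decoy

    def __post_init__(self) -> None:
        if self.fingerprints.shape[1] != 166:
            raise DiscriminatorError("fingerprint width must be exactly 166")
        if not (len(self.labels) == len(self.fingerprints) == len(self.provenance)):
            raise DiscriminatorError("inconsistent row counts")
        for lab, prov in zip(self.labels, self.provenance):
            if prov != "active" and lab == 1:
                raise DiscriminatorError("nonactive provenance with active label")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class MLPConfig:
    hidden_layers: int = 3
    hidden_units: int = 166
    activation: str = "relu"
    seed: int = 0
    max_iter: int = 300

    def __post_init__(self) -> None:
        if self.hidden_layers < 1:
            raise DiscriminatorError("need at least one hidden layer")


def label_by_ki(
    records: list[ActivityRecord], cutoff_nm: float = 100.0
) -> tuple[list[ActivityRecord], list[ActivityRecord], list[tuple[ActivityRecord, str]]]:
    """Split by affinity: active iff Ki < cutoff (strict; boundary Ki equal
    to the cutoff is inactive).  Returns (actives, inactives, rejected)."""
    actives, inactives, rejected = [], [], []
    for rec in records:
        ki = rec.ki_nm
        if ki is None or (isinstance(ki, float) and math.isnan(ki)):
            rejected.append((rec, "missing Ki"))
        elif ki <= 0:
            rejected.append((rec, f"non-positive Ki {ki}"))
        elif ki < cutoff_nm:
            actives.append(rec)
        else:
            inactives.append(rec)
    return actives, inactives, rejected


def maccs_matrix(smiles: list[str]) -> tuple[np.ndarray, list[int], list[tuple[int, str]]]:
    """166-key MACCS matrix for parseable SMILES.

    RDKit emits a 167-bit vector whose bit 0 is a placeholder for the
    1-based key numbering; it is dropped here.  Returns (matrix, kept row
    indices, rejected (index, reason) pairs).
    """
    rows, kept, rejected = [], [], []
    for i, s in enumerate(smiles):
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            rejected.append((i, f"unparseable SMILES {s!r}"))
            continue
        arr = np.zeros(167, dtype=np.uint8)
        fp = MACCSkeys.GenMACCSKeys(mol)
        for b in fp.GetOnBits():
            arr[b] = 1
        rows.append(arr[1:])
        kept.append(i)
    mat = np.array(rows, dtype=np.uint8) if rows else np.zeros((0, 166), dtype=np.uint8)
    return mat, kept, rejected


def assemble_training_set(
    actives: list[str], inactives: list[str], decoys: list[str]
) -> LabeledFingerprintSet:
    """Fingerprint and label the three pools; decoys are always nonactive."""
    if not actives:
        raise DiscriminatorError("need at least one active molecule")
    if not inactives and not decoys:
        raise DiscriminatorError("need at least one nonactive molecule")
    fps, labels, prov = [], [], []
    for pool, label, tag in ((actives, 1, "active"), (inactives, 0, "inactive"),
                             (decoys, 0, "decoy")):
        mat, kept, rejected = maccs_matrix(pool)
        fps.append(mat)
        labels.extend([label] * len(kept))
        prov.extend([tag] * len(kept))
    return LabeledFingerprintSet(
        fingerprints=np.vstack(fps), labels=np.asarray(labels), provenance=prov
    )


def classification_metrics(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Standard binary metrics from a 2x2 confusion table.

    precision = tp/(tp+fp); recall = tp/(tp+fn); F1 their harmonic mean;
    accuracy = (tp+tn)/n; Cohen's kappa from observed vs chance agreement;
    MCC in its determinant form.  Any zero denominator yields 0 and sets the
    ``degenerate`` flag.
    """
    if min(tp, fp, tn, fn) < 0:
        raise DiscriminatorError("confusion counts must be >= 0")
    n = tp + fp + tn + fn
    if n == 0:
        raise DiscriminatorError("empty confusion table")
    degenerate = False

    def ratio(num: float, den: float) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    f1 = ratio(2 * precision * recall, precision + recall)
    accuracy = (tp + tn) / n
    p_yes = ((tp + fp) / n) * ((tp + fn) / n)
    p_no = ((tn + fn) / n) * ((tn + fp) / n)
    kappa = ratio(accuracy - (p_yes + p_no), 1.0 - (p_yes + p_no))
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = ratio(tp * tn - fp * fn, mcc_den)
    return {
        "precision": precision, "recall": recall, "f1": f1,
        "accuracy": accuracy, "kappa": kappa, "mcc": mcc,
        "degenerate": degenerate,
    }


def _build_mlp(config: MLPConfig):
    from sklearn.neural_network import MLPClassifier

    return MLPClassifier(
        hidden_layer_sizes=(config.hidden_units,) * config.hidden_layers,
        activation=config.activation,
        solver="adam",
        max_iter=config.max_iter,
        random_state=config.seed,
    )


@dataclass
class CVReport:
    fold_metrics: list[dict] = field(default_factory=list)
    fold_auc: list[float] = field(default_factory=list)
    roc_points: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    class_counts: dict = field(default_factory=dict)

    @property
    def mean_metrics(self) -> dict:
        keys = [k for k in self.fold_metrics[0] if k != "degenerate"]
        return {k: float(np.mean([m[k] for m in self.fold_metrics])) for k in keys}

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    def to_dict(self) -> dict:
        return {
            "folds": self.fold_metrics,
            "fold_auc": self.fold_auc,
            "mean": self.mean_metrics,
            "mean_auc": self.mean_auc,
            "class_counts": self.class_counts,
        }


def cross_validate(
    dataset: LabeledFingerprintSet,
    config: MLPConfig = MLPConfig(),
    k: int = 6,
    seed: int = 0,
    threshold: float = 0.5,
) -> CVReport:
    """Stratified k-fold cross-validation of the MLP discriminator.

    Per fold: fit on the training split, score the held-out split, derive
    the confusion table at the probability threshold, and the ROC/AUC from
    the held-out scores.  Class imbalance is reported, not corrected.
    """
    from sklearn.metrics import auc, roc_curve
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(dataset.labels)
    counts = {int(c): int((y == c).sum()) for c in np.unique(y)}
    if min(counts.values()) < k:
        raise DiscriminatorError(
            f"smallest class ({min(counts.values())}) cannot be split into {k} folds"
        )
    X = dataset.fingerprints.astype(np.float64)
    report = CVReport(class_counts=counts)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        clf = _build_mlp(config)
        clf.fit(X[train_idx], y[train_idx])
        scores = clf.predict_proba(X[test_idx])[:, 1]
        pred = (scores >= threshold).astype(int)
        yt = y[test_idx]
        tp = int(((pred == 1) & (yt == 1)).sum())
        fp = int(((pred == 1) & (yt == 0)).sum())
        tn = int(((pred == 0) & (yt == 0)).sum())
        fn = int(((pred == 0) & (yt == 1)).sum())
        report.fold_metrics.append(classification_metrics(tp, fp, tn, fn))
        fpr, tpr, _ = roc_curve(yt, scores)
        report.roc_points.append((fpr, tpr))
        report.fold_auc.append(float(auc(fpr, tpr)))
    return report


def train_discriminator(dataset: LabeledFingerprintSet, config: MLPConfig = MLPConfig()):
    """Fit the MLP on the full labelled set."""
    clf = _build_mlp(config)
    clf.fit(dataset.fingerprints.astype(np.float64), np.asarray(dataset.labels))
    return clf


def predict_likelihood(
    model, smiles: list[str], n_bins: int = 10
) -> tuple[np.ndarray, list[tuple[int, str]], np.ndarray]:
    """Active-class probability per molecule plus a decile histogram.

    Returns (scores aligned with parseable rows, rejected (index, reason)
    pairs, histogram counts over [0,1] in ``n_bins`` equal bins).
    """
    mat, kept, rejected = maccs_matrix(smiles)
    if len(kept) == 0:
        return np.zeros(0), rejected, np.zeros(n_bins, dtype=int)
    scores = model.predict_proba(mat.astype(np.float64))[:, 1]
    hist, _ = np.histogram(scores, bins=n_bins, range=(0.0, 1.0))
    return scores, rejected, hist
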