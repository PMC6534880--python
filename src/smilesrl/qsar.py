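"""Binary activity QSAR: dataset curation, ECFP6 fingerprints, and four
predictor algorithms (RF, SVM, NB, DNN) whose probability output is the RL
reward.

Curation rules: records with the same canonical SMILES are merged by
averaging their pChEMBL values; a merged record is negative when the mean
pChEMBL is < 6.5 or the annotation says "Not Active" (case-insensitive),
positive otherwise.

Fingerprints are hashed circular fingerprints of bond radius 3 folded to
4096 bits (ECFP6), represented as frozen sets of on-bit positions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import joblib
import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import matthews_corrcoef, roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import BernoulliNB
from sklearn.svm import SVC

from smilesrl.nn import MLPClassifier

logger = logging.getLogger(__name__)

N_BITS = 4096
RADIUS = 3
ACTIVITY_THRESHOLD = 6.5

_fp_generator = rdFingerprintGenerator.GetMorganGenerator(radius=RADIUS,
                                                          fpSize=N_BITS)

ALGORITHMS = ("RF", "SVM", "NB", "DNN")


@dataclass(frozen=True)
class ActivityRecord:
    """One activity measurement: SMILES plus pChEMBL value and/or annotation."""

    smiles: str
    pchembl: float | None = None
    annotation: str | None = None

    def __post_init__(self) -> None:
        if self.pchembl is None and self.annotation is None:
            raise ValueError("record needs a pchembl value or an annotation")


Fingerprint = frozenset  # bit positions in 0..N_BITS-1


def compute_ecfp6(smiles: str) -> Fingerprint:
    """ECFP6 on-bit set (radius 3, 4096 bits); invariant under SMILES
    rewriting of the same molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    fp = _fp_generator.GetFingerprint(mol)
    return frozenset(fp.GetOnBits())


def fingerprint_matrix(fps: list[Fingerprint]) -> np.ndarray:
    """Dense 0/1 matrix (n x 4096) from on-bit sets."""
    X = np.zeros((len(fps), N_BITS), dtype=np.float64)
    for i, fp in enumerate(fps):
        X[i, list(fp)] = 1.0
    return X


@dataclass
class QSARDataset:
    """Curated, deduplicated binary dataset."""

    smiles: list[str]          # canonical
    fingerprints: list[Fingerprint]
    labels: np.ndarray         # 0/1

    def __len__(self) -> int:
        return len(self.smiles)

    @property
    def X(self) -> np.ndarray:
        return fingerprint_matrix(self.fingerprints)

    @property
    def y(self) -> np.ndarray:
        return self.labels


def curate_activity_dataset(records: list[ActivityRecord]) -> QSARDataset:
    """Merge duplicates by canonical SMILES, average pChEMBL, assign labels.

    Unparseable SMILES are skipped with a warning.  A merged entry is
    labelled 0 when any annotation is "Not Active" (case-insensitive) or the
    averaged pChEMBL is < 6.5; otherwise 1.
    """
    merged: dict[str, dict] = {}
    order: list[str] = []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            logger.warning("skipping unparseable SMILES %r", rec.smiles)
            continue
        canon = Chem.MolToSmiles(mol)
        if canon not in merged:
            merged[canon] = {"pchembl": [], "not_active": False}
            order.append(canon)
        if rec.pchembl is not None:
            merged[canon]["pchembl"].append(float(rec.pchembl))
        if rec.annotation is not None and rec.annotation.strip().lower() == "not active":
            merged[canon]["not_active"] = True
    smiles, fps, labels = [], [], []
    for canon in order:
        info = merged[canon]
        if info["not_active"]:
            label = 0
        elif info["pchembl"]:
            label = 0 if float(np.mean(info["pchembl"])) < ACTIVITY_THRESHOLD else 1
        else:
            # annotation present but not "Not Active" and no measurement:
            # nothing marks it negative, treat as positive annotation
            label = 1
        smiles.append(canon)
        fps.append(compute_ecfp6(canon))
        labels.append(label)
    return QSARDataset(smiles, fps, np.array(labels, dtype=np.int64))


def zinc_like_filter(smiles_list: list[str], logp_range=(-2.0, 6.0),
                     mw_range=(200.0, 600.0)) -> list[str]:
    """Drug-likeness corpus pre-filter: keep molecules with
    -2 < logP < 6 and 200 < MW < 600 (open intervals)."""
    kept = []
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            continue
        logp = Crippen.MolLogP(mol)
        mw = Descriptors.MolWt(mol)
        if logp_range[0] < logp < logp_range[1] and mw_range[0] < mw < mw_range[1]:
            kept.append(s)
    return kept


class PredictorModel:
    """Fitted activity classifier; ``predict_q`` maps fingerprints to the
    activity probability used as the RL reward."""

    def __init__(self, algorithm: str, estimator):
        if algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {algorithm!r}")
        self.algorithm = algorithm
        self.estimator = estimator

    def predict_q(self, fps: list[Fingerprint]) -> np.ndarray:
        if not fps:
            return np.zeros(0)
        X = fingerprint_matrix(fps)
        q = self.estimator.predict_proba(X)[:, 1]
        return np.clip(q, 0.0, 1.0)

    def predict_q_smiles(self, smiles: str) -> float:
        return float(self.predict_q([compute_ecfp6(smiles)])[0])

    def save(self, path: str) -> None:
        joblib.dump({"algorithm": self.algorithm, "estimator": self.estimator},
                    path)

    @classmethod
    def load(cls, path: str) -> "PredictorModel":
        data = joblib.load(path)
        return cls(data["algorithm"], data["estimator"])


def _make_estimator(algorithm: str, seed: int, dnn_hidden=(8000, 4000, 2000),
                    dnn_epochs: int = 100, svm_grid_step: int = 2,
                    svm_inner_folds: int = 3):
    if algorithm == "RF":
        return RandomForestClassifier(n_estimators=1000, criterion="gini",
                                      random_state=seed, n_jobs=1)
    if algorithm == "NB":
        return BernoulliNB()
    if algorithm == "SVM":
        # C in [2^-5, 2^15], gamma in [2^-15, 2^5], log2 grid, inner-CV AUC
        grid = {
            "C": [2.0 ** e for e in range(-5, 16, svm_grid_step)],
            "gamma": [2.0 ** e for e in range(-15, 6, svm_grid_step)],
        }
        svc = SVC(kernel="rbf", probability=True, random_state=seed)
        return GridSearchCV(svc, grid, scoring="roc_auc", cv=svm_inner_folds,
                            n_jobs=1)
    if algorithm == "DNN":
        return MLPClassifier(N_BITS, hidden=dnn_hidden, dropout=0.2, lr=1e-3,
                             epochs=dnn_epochs, seed=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def train_predictor(dataset: QSARDataset, algorithm: str, seed: int = 0,
                    **kwargs) -> PredictorModel:
    """Fit one of RF / SVM / NB / DNN on the curated dataset.

    RF: 1000 trees, gini.  SVM: RBF kernel, C/gamma searched on a log2 grid
    over [2^-5, 2^15] x [2^-15, 2^5] by inner-CV AUC.  DNN: hidden layers
    8000/4000/2000 (configurable for desk-scale runs), ReLU, sigmoid output,
    20% dropout, Adam 1e-3, 100 epochs.  NB: Bernoulli on the bits.
    """
    y = dataset.y
    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both classes")
    est = _make_estimator(algorithm, seed, **kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(dataset.X, y)
    return PredictorModel(algorithm, est)


@dataclass(frozen=True)
class CVMetrics:
    auc: float
    mcc: float
    sensitivity: float
    specificity: float
    accuracy: float

    def to_tsv(self) -> str:
        rows = [("auc", self.auc), ("mcc", self.mcc),
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity), ("accuracy", self.accuracy)]
        return "metric\tvalue\n" + "\n".join(f"{k}\t{v:.4f}" for k, v in rows) + "\n"


def crossvalidate(dataset: QSARDataset, algorithm: str, k: int = 5,
                  seed: int = 0, threshold: float = 0.5,
                  return_probabilities: bool = False, **kwargs):
    """Stratified k-fold CV; metrics pooled over held-out predictions with a
    0.5 probability threshold for the confusion-matrix metrics.

    With ``return_probabilities=True`` returns ``(metrics, pooled_prob)``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = dataset.y
    if len(y) < k:
        raise ValueError("fewer samples than folds")
    X = dataset.X
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled_prob = np.zeros(len(y))
    for train_idx, test_idx in skf.split(X, y):
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError("a training fold contains one class")
        est = _make_estimator(algorithm, seed, **kwargs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X[train_idx], y[train_idx])
        pooled_prob[test_idx] = est.predict_proba(X[test_idx])[:, 1]
    pred = (pooled_prob > threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / len(y)
    metrics = CVMetrics(
        auc=float(roc_auc_score(y, pooled_prob)),
        mcc=float(matthews_corrcoef(y, pred)),
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
    )
    return (metrics, pooled_prob) if return_probabilities else metrics
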