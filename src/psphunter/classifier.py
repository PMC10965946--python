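"""Dataset assembly, random-forest training, feature selection, evaluation
and proteome screening.

The classifier is a 500-tree random forest trained on the directly
concatenated feature blocks.  Datasets pair each positive (phase-separating)
protein with a freshly sampled negative of equal count, split 70/30 into
train and held-out test; repeating the negative draw yields independent
repeat datasets whose evaluation metrics are averaged.  Feature selection
keeps the top-k columns by impurity importance (default k=60) and retrains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .embedding import EmbeddingModel
from .io import ProteinRecord

logger = logging.getLogger("psphunter")

DEFAULT_N_TREES = 500
DEFAULT_TOP_K = 60
DEFAULT_SCREEN_THRESHOLD = 0.82


# --------------------------------------------------------------------------
# dataset assembly


def kmer_set(seq: str, k: int = 5) -> frozenset[str]:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def jaccard_similarity_filter(records: list[ProteinRecord], k: int = 5,
                              cutoff: float = 0.5) -> list[ProteinRecord]:
    """Greedy redundancy filter: keep a record unless its k-mer Jaccard
    similarity to an already kept record exceeds ``cutoff``.

    This is a fast stand-in for clustering at ~30% pairwise identity; an
    adapter can substitute genuine cluster assignments when available.
    """
    kept: list[ProteinRecord] = []
    kept_sets: list[frozenset[str]] = []
    for rec in records:
        s = kmer_set(rec.sequence, k)
        redundant = False
        for other in kept_sets:
            union = len(s | other)
            if union and len(s & other) / union > cutoff:
                redundant = True
                break
        if redundant:
            logger.debug("similarity filter dropped %s", rec.id)
        else:
            kept.append(rec)
            kept_sets.append(s)
    return kept


@dataclass
class LabeledDataset:
    """Feature matrix with labels (1 = phase-separating) and a 70/30
    train/test split assignment."""

    X: np.ndarray
    y: np.ndarray
    ids: list[str]
    split: np.ndarray  # "train"/"test" per row
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.split = np.asarray(self.split)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate protein ids in dataset")

    def _part(self, name: str):
        m = self.split == name
        return self.X[m], self.y[m]

    @property
    def train(self):
        return self._part("train")

    @property
    def test(self):
        return self._part("test")


def _stratified_split(ids: list[str], rng: np.random.Generator,
                      test_fraction: float) -> np.ndarray:
    n = len(ids)
    n_test = int(round(n * test_fraction))
    order = rng.permutation(n)
    split = np.full(n, "train", dtype=object)
    split[order[:n_test]] = "test"
    return split


def assemble_splits(
    positives: list[ProteinRecord],
    negative_pool: list[ProteinRecord],
    features: dict[str, np.ndarray],
    repeats: int = 1,
    seed: int = 0,
    test_fraction: float = 0.3,
    similarity_filter=jaccard_similarity_filter,
    feature_names: list[str] | None = None,
) -> list[LabeledDataset]:
    """Build ``repeats`` balanced, redundancy-filtered, 70/30-split datasets.

    Each repeat draws a fresh equal-size negative sample (without
    replacement) from the pool; positives and negatives are split 70/30
    separately so both partitions stay balanced.  Per-repeat seeds are
    derived from the master seed by fixed increments.
    """
    if similarity_filter is not None:
        positives = similarity_filter(positives)
        negative_pool = similarity_filter(negative_pool)
    n_pos = len(positives)
    if len(negative_pool) < n_pos:
        raise ValueError(
            f"negative pool ({len(negative_pool)}) smaller than positive set "
            f"({n_pos}) after filtering")
    datasets = []
    for r in range(repeats):
        rng = np.random.default_rng(seed + r)
        neg_idx = rng.choice(len(negative_pool), size=n_pos, replace=False)
        negatives = [negative_pool[i] for i in neg_idx]
        split = np.concatenate([
            _stratified_split([p.id for p in positives], rng, test_fraction),
            _stratified_split([n.id for n in negatives], rng, test_fraction),
        ])
        recs = positives + negatives
        datasets.append(LabeledDataset(
            X=np.vstack([features[p.id] for p in recs]),
            y=np.array([1] * n_pos + [0] * n_pos),
            ids=[p.id for p in recs],
            split=split,
            feature_names=feature_names,
        ))
    return datasets


# --------------------------------------------------------------------------
# training and selection


@dataclass
class TrainedModel:
    """A fitted forest plus everything needed to apply it consistently."""

    forest: RandomForestClassifier
    selected: np.ndarray | None = None  # column indices into the full vector
    feature_names: list[str] | None = None
    embedding: EmbeddingModel | None = None
    seed: int = 0
    config: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return self.forest.n_estimators

    def _project(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.selected is not None:
            if X.shape[1] != self.config.get("n_input_features", X.shape[1]):
                raise ValueError(
                    f"expected {self.config['n_input_features']} feature "
                    f"columns, got {X.shape[1]}")
            X = X[:, self.selected]
        if X.shape[1] != self.forest.n_features_in_:
            raise ValueError(
                f"feature count {X.shape[1]} does not match model "
                f"({self.forest.n_features_in_})")
        return X


def train_model(dataset: LabeledDataset, n_trees: int = DEFAULT_N_TREES,
                seed: int = 0, embedding: EmbeddingModel | None = None,
                ) -> TrainedModel:
    """Fit the random forest on the dataset's training rows."""
    X, y = dataset.train
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                    n_jobs=1)
    forest.fit(X, y)
    return TrainedModel(
        forest=forest, feature_names=dataset.feature_names,
        embedding=embedding, seed=seed,
        config={"n_trees": n_trees, "n_input_features": X.shape[1]},
    )


def select_features(model: TrainedModel, dataset: LabeledDataset,
                    k: int = DEFAULT_TOP_K) -> TrainedModel:
    """Retrain on the k highest-importance columns (ties -> lower index)."""
    imp = model.forest.feature_importances_
    if k > imp.size:
        raise ValueError(f"k={k} exceeds feature count {imp.size}")
    order = np.argsort(-imp, kind="stable")  # stable: ties keep lower index
    selected = np.sort(order[:k])
    X, y = dataset.train
    forest = RandomForestClassifier(n_estimators=model.n_trees,
                                    random_state=model.seed, n_jobs=1)
    forest.fit(X[:, selected], y)
    config = dict(model.config, top_k=k, n_input_features=X.shape[1])
    return replace(model, forest=forest, selected=selected, config=config)


def predict_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Positive-class probability for each row — the PSPHunter score."""
    X = model._project(X)
    pos_col = int(np.flatnonzero(model.forest.classes_ == 1)[0])
    return model.forest.predict_proba(X)[:, pos_col]


def screen_proteome(scores: dict[str, float],
                    threshold: float = DEFAULT_SCREEN_THRESHOLD) -> set[str]:
    """Call phase-separating proteins at a score cutoff (default 0.82, the
    high-specificity operating point)."""
    return {pid for pid, s in scores.items() if s >= threshold}


# --------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvalReport:
    auc: float
    recall: float
    precision: float
    f1: float
    accuracy: float
    mcc: float
    counts: ConfusionCounts | None = None


def confusion_counts(y_true: np.ndarray, scores: np.ndarray,
                     threshold: float = 0.5) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y_true == 1))),
        tn=int(np.sum((pred == 0) & (y_true == 0))),
        fp=int(np.sum((pred == 1) & (y_true == 0))),
        fn=int(np.sum((pred == 0) & (y_true == 1))),
    )


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    """Recall, precision, F1, accuracy and MCC from a confusion matrix.

    Undefined ratios (zero denominators) are reported as 0.
    """
    tp, tn, fp, fn = (float(c.tp), float(c.tn), float(c.fp), float(c.fn))
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * recall * precision / (recall + precision)
          if recall + precision else 0.0)
    accuracy = (tp + tn) / c.total if c.total else 0.0
    denom = np.sqrt((tp + fn) * (tp + fp) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return {"recall": recall, "precision": precision, "f1": f1,
            "accuracy": accuracy, "mcc": mcc}


def evaluate(model: TrainedModel, X: np.ndarray, y: np.ndarray,
             threshold: float = 0.5) -> EvalReport:
    """Score a labeled test set: AUC from the ranked scores, the remaining
    metrics from the confusion matrix at ``threshold``."""
    y = np.asarray(y, dtype=int)
    if y.size == 0:
        raise ValueError("empty test set")
    scores = predict_scores(model, X)
    auc = (roc_auc_score(y, scores) if len(np.unique(y)) == 2 else float("nan"))
    counts = confusion_counts(y, scores, threshold)
    return EvalReport(auc=float(auc), counts=counts,
                      **metrics_from_counts(counts))


def evaluate_dataset(model: TrainedModel, dataset: LabeledDataset) -> EvalReport:
    X, y = dataset.test
    return evaluate(model, X, y)


def kfold_indices(n: int, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Shuffled k-fold partition: every index lands in exactly one fold."""
    rng = np.random.default_rng(seed)
    return np.array_split(rng.permutation(n), k)


def cross_validate(X: np.ndarray, y: np.ndarray, k: int = 5,
                   n_trees: int = DEFAULT_N_TREES, seed: int = 0
                   ) -> list[EvalReport]:
    """k-fold cross-validation; every row lands in exactly one test fold."""
    n = len(y)
    folds = kfold_indices(n, k, seed)
    order = np.concatenate(folds)
    reports = []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        ds = LabeledDataset(
            X=np.vstack([X[train_idx], X[test_idx]]),
            y=np.concatenate([y[train_idx], y[test_idx]]),
            ids=[f"r{j}" for j in np.concatenate([train_idx, test_idx])],
            split=np.array(["train"] * len(train_idx) + ["test"] * len(test_idx)),
        )
        model = train_model(ds, n_trees=n_trees, seed=seed + i)
        reports.append(evaluate_dataset(model, ds))
    return reports


# --------------------------------------------------------------------------
# persistence


def save_model(model: TrainedModel, path) -> None:
    joblib.dump(model, path)


def load_model(path) -> TrainedModel:
    model = joblib.load(path)
    if not isinstance(model, TrainedModel):
        raise TypeError(f"{path} does not contain a TrainedModel")
    return model
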