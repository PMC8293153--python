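"""The ideal-segmentation classifier: data augmentation, training, scoring.

The evolutionary optimizer needs a fitness function that tells good
segmentations from bad ones.  Training data are manufactured from any
map with ground-truth labels:

* "bad" samples are the feature vectors of independent random watershed
  segmentations (random sigma, s), which over-segment noisy maps;
* "good" samples are the ground truth with exactly one uniformly chosen
  subunit split in two (via a random watershed restricted to that
  subunit), i.e. near-ideal segmentations.

Four model families are available behind one interface -- logistic
regression, RBF support-vector machine, multilayer perceptron and random
forest -- each tuned by cross-validated grid search maximising the area
under the ROC curve.  The random forest is the default family; its grid
includes 1200 trees with sqrt(d) features per split.  The fitted model's
probability of the "good" class is the fitness used by the optimizer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import N_FEATURES, encode_features
from .phantom import PhantomPair
from .volume_io import LabelMap, canonicalize_labels
from .watershed_seg import (random_segmentation, random_watershed,
                            watershed_segment)

__all__ = [
    "TrainingSample",
    "FitnessModel",
    "augment_samples",
    "train_fitness_model",
    "score",
    "evaluate_roc",
    "DEFAULT_GRIDS",
]

GOOD, BAD = "good", "bad"

DEFAULT_GRIDS: dict[str, dict] = {
    "logreg": {"clf__C": [0.1, 1.0, 10.0], "clf__max_iter": [120]},
    "svm": {"clf__C": [0.1, 1.0], "clf__gamma": [1.0, "scale"]},
    "mlp": {"clf__hidden_layer_sizes": [(100,)], "clf__alpha": [1e-4]},
    "rf": {"clf__n_estimators": [300, 1200], "clf__max_features": ["sqrt"]},
}


@dataclass
class TrainingSample:
    features: np.ndarray
    label: str
    source_map: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.shape != (N_FEATURES,):
            raise ValueError(f"features must have length {N_FEATURES}")
        if self.label not in (GOOD, BAD):
            raise ValueError("label must be 'good' or 'bad'")


@dataclass
class FitnessModel:
    """A fitted segmentation-quality scorer.

    ``score_features`` maps a feature vector to the probability of the
    "good" class in [0, 1]; this probability is the GA fitness.
    """

    family: str
    estimator: object
    cv_auc: float
    grid: dict = field(default_factory=dict)
    seed: int | None = None

    def score_features(self, features: np.ndarray) -> float:
        features = np.asarray(features, dtype=np.float64).reshape(1, -1)
        proba = self.estimator.predict_proba(features)[0]
        good_idx = list(self.estimator.classes_).index(1)
        return float(proba[good_idx])

    def score_labels(self, labels: LabelMap) -> float:
        return self.score_features(encode_features(labels))

    def save(self, path) -> None:
        joblib.dump(self.estimator, str(path))
        sidecar = {"family": self.family, "cv_auc": self.cv_auc,
                   "grid": {k: [str(v) for v in vals] for k, vals in self.grid.items()},
                   "seed": self.seed}
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path) -> "FitnessModel":
        estimator = joblib.load(str(path))
        try:
            with open(str(path) + ".json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            meta = {"family": "unknown", "cv_auc": float("nan"), "seed": None}
        return cls(family=meta["family"], estimator=estimator,
                   cv_auc=meta["cv_auc"], seed=meta.get("seed"))


def split_one_segment(truth: LabelMap, dmap, rng: np.random.Generator,
                      max_retries: int = 20) -> LabelMap:
    """Split one uniformly chosen subunit of ``truth`` exactly in two.

    The split boundary comes from a random watershed restricted to the
    chosen subunit: one of its regions becomes a new segment, the rest
    keeps the old label.  Retries with fresh draws (possibly another
    subunit) when the watershed does not subdivide the subunit.
    """
    truth = canonicalize_labels(truth)
    ids = truth.label_ids()
    for attempt in range(max_retries + 1):
        if attempt < max_retries:
            ws = random_watershed(dmap, rng).labels
        else:
            # last resort: the unsmoothed watershed is as fine as it gets
            ws = watershed_segment(dmap).labels
        splittable = [int(k) for k in ids
                      if np.unique(ws[truth.labels == k][ws[truth.labels == k] > 0]).size >= 2]
        if not splittable:
            continue
        target = int(rng.choice(splittable))
        seg_mask = truth.labels == target
        pieces = np.unique(ws[seg_mask])
        pieces = pieces[pieces > 0]
        carved = int(rng.choice(pieces))
        out = truth.labels.copy()
        out[seg_mask & (ws == carved)] = int(truth.labels.max()) + 1
        return canonicalize_labels(LabelMap(out))
    raise RuntimeError("could not split any ground-truth segment")


def augment_samples(pair: PhantomPair, n_good: int = 10, n_bad: int = 10,
                    rng: np.random.Generator | None = None,
                    source: str = "") -> list[TrainingSample]:
    """Manufacture a balanced set of good/bad samples from one annotated map."""
    if rng is None:
        rng = np.random.default_rng()
    samples = []
    for _ in range(n_bad):
        ind = random_segmentation(pair.map, rng)
        samples.append(TrainingSample(encode_features(ind.labels), BAD, source))
    for _ in range(n_good):
        split = split_one_segment(pair.truth, pair.map, rng)
        samples.append(TrainingSample(encode_features(split), GOOD, source))
    return samples


def _make_pipeline(family: str, seed: int | None) -> Pipeline:
    if family == "logreg":
        clf = LogisticRegression(dual=False)
    elif family == "svm":
        clf = SVC(kernel="rbf", probability=True, random_state=seed)
    elif family == "mlp":
        clf = MLPClassifier(activation="relu", solver="adam",
                            learning_rate="constant", max_iter=500,
                            random_state=seed)
    elif family == "rf":
        clf = RandomForestClassifier(random_state=seed, n_jobs=1)
    else:
        raise ValueError(f"unknown model family {family!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _xy(samples: list[TrainingSample]):
    X = np.stack([s.features for s in samples])
    y = np.array([1 if s.label == GOOD else 0 for s in samples])
    return X, y


def train_fitness_model(samples: list[TrainingSample], family: str = "rf",
                        grid: dict | None = None, cv_folds: int = 5,
                        seed: int | None = None) -> FitnessModel:
    """Cross-validated grid search; returns the best model by ROC AUC."""
    X, y = _xy(samples)
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 samples of each class")
    if grid is None:
        grid = DEFAULT_GRIDS[family]
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(_make_pipeline(family, seed), grid,
                          scoring="roc_auc", cv=cv, refit=True, n_jobs=1)
    search.fit(X, y)
    assert search.best_score_ >= max(search.cv_results_["mean_test_score"]) - 1e-12
    return FitnessModel(family=family, estimator=search.best_estimator_,
                        cv_auc=float(search.best_score_), grid=grid, seed=seed)


def score(model: FitnessModel, features: np.ndarray) -> float:
    """Probability that a segmentation is "good"; the GA fitness."""
    return model.score_features(features)


def evaluate_roc(model: FitnessModel, samples: list[TrainingSample]):
    """ROC curve and AUC of a fitted model on labeled samples."""
    X, y = _xy(samples)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    scores = model.estimator.predict_proba(X)[:, list(model.estimator.classes_).index(1)]
    fpr, tpr, thr = roc_curve(y, scores)
    return {"fpr": fpr, "tpr": tpr, "thresholds": thr,
            "auc": float(sk_auc(fpr, tpr))}


def holdout_auc(model: FitnessModel, samples: list[TrainingSample]) -> float:
    """AUC of a fitted model on held-out labeled samples."""
    X, y = _xy(samples)
    scores = model.estimator.predict_proba(X)[:, list(model.estimator.classes_).index(1)]
    return float(roc_auc_score(y, scores))
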