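"""Classifier training, scoring and persistence.

The training pipeline is: encode fragments under the chosen scheme, fit a
min-max scaler on the training matrix, scale to [0, 1], fit relief-F and
retain the configured top-d features (combined schemes only), then fit the
classifier.  Everything fitted — scaler parameters, retained feature
indices, and for KNN-containing schemes the reference fragments — is frozen
into the :class:`TrainedPredictor` so prediction-time encoding sees only
training-derived state.

Scaling is applied uniformly to all classifier families; it is a strictly
monotone per-feature map, so the tree-based families are unaffected by it
while the RBF kernel and neighbor distances get comparable feature scales.

Decision scores are continuous with larger = more phosphosite-like: the
signed margin for the SVM, the positive-vote fraction for the random
forest, the positive-leaf proportion for the decision tree, and the
positive-neighbor fraction for the KNN classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import make_scorer, matthews_corrcoef
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from oryzaphos.dataset import Fragment
from oryzaphos.encodings import EncodingSpec, SimilarityMatrix, encode_fragments, normalize_blosum62
from oryzaphos.errors import ConfigError, DataError
from oryzaphos.featsel import SelectionSpec, relieff_weights, select_top

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

FAMILIES = ("SVM", "RF", "DT", "KNNC")


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier family and hyperparameters.

    ``gamma="1/d"`` resolves the RBF width to 1 over the retained feature
    dimension at fit time.  ``m_features="sqrt"`` gives the random forest
    floor(sqrt(d)) candidate features per split.
    """

    family: str = "SVM"
    C: float = 1.0
    gamma: float | str = "1/d"
    n_trees: int = 100
    m_features: int | str = "sqrt"
    knn_k: int = 5
    tune: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown classifier family {self.family!r}; expected {FAMILIES}")
        if self.family == "RF" and self.n_trees < 1:
            raise ConfigError("n_trees must be >= 1")
        if self.family == "SVM" and self.C <= 0:
            raise ConfigError("C must be positive")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "C": self.C,
            "gamma": self.gamma,
            "n_trees": self.n_trees,
            "m_features": self.m_features,
            "knn_k": self.knn_k,
            "tune": self.tune,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierSpec":
        return cls(**d)


def _make_estimator(spec: ClassifierSpec, dim: int):
    if spec.family == "SVM":
        gamma = 1.0 / dim if spec.gamma == "1/d" else float(spec.gamma)
        return SVC(kernel="rbf", C=spec.C, gamma=gamma, random_state=spec.seed)
    if spec.family == "RF":
        m = (
            max(1, int(np.sqrt(dim)))
            if spec.m_features == "sqrt"
            else int(spec.m_features)
        )
        return RandomForestClassifier(
            n_estimators=spec.n_trees, max_features=m, random_state=spec.seed
        )
    if spec.family == "DT":
        return DecisionTreeClassifier(criterion="gini", random_state=spec.seed)
    if spec.family == "KNNC":
        return KNeighborsClassifier(n_neighbors=spec.knn_k)
    raise ConfigError(f"unknown family {spec.family!r}")


def _tune_svm(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec):
    """Inner-CV hyperparameter search for the RBF SVM.

    Log grid C in {0.1, 1, 10, 100} and gamma in {4^j / d : j = -2..2},
    selected by stratified 3-fold inner cross-validation on MCC.
    """
    d = X.shape[1]
    grid = {
        "C": [0.1, 1.0, 10.0, 100.0],
        "gamma": [4.0**j / d for j in range(-2, 3)],
    }
    search = GridSearchCV(
        SVC(kernel="rbf", random_state=spec.seed),
        grid,
        scoring=make_scorer(matthews_corrcoef),
        cv=StratifiedKFold(n_splits=3, shuffle=True, random_state=spec.seed),
        n_jobs=1,
    )
    search.fit(X, y)
    logger.info("tuned SVM: C=%g gamma=%g (inner-CV MCC %.3f)",
                search.best_params_["C"], search.best_params_["gamma"],
                search.best_score_)
    return SVC(kernel="rbf", random_state=spec.seed, **search.best_params_)


@dataclass
class TrainedPredictor:
    """Everything needed to score new fragments.

    Holds the fitted classifier, the encoding/selection/classifier specs,
    training min/max for scaling, retained feature indices and identifiers,
    KNN reference fragments (when the scheme includes the KNN encoding),
    the training keys (for holdout-overlap guards) and a decision threshold.
    """

    estimator: object
    encoding_spec: EncodingSpec
    selection_spec: SelectionSpec
    classifier_spec: ClassifierSpec
    feature_layout: list[str]
    retained: np.ndarray
    scaler_min: np.ndarray
    scaler_range: np.ndarray
    positive_refs: list[Fragment] | None
    negative_refs: list[Fragment] | None
    train_keys: set
    threshold: float
    similarity: SimilarityMatrix | None = None
    schema_version: int = SCHEMA_VERSION

    @property
    def retained_ids(self) -> list[str]:
        return [self.feature_layout[i] for i in self.retained]


def default_threshold(family: str) -> float:
    """0 for the SVM margin score, 0.5 for the [0,1] vote/proportion scores."""
    return 0.0 if family == "SVM" else 0.5


def _encode_for_training(
    fragments: Sequence[Fragment],
    enc_spec: EncodingSpec,
    positives: list[Fragment],
    negatives: list[Fragment],
    sim: SimilarityMatrix | None,
    exclude_self: bool,
) -> np.ndarray:
    return encode_fragments(
        fragments,
        enc_spec,
        positive_refs=positives if enc_spec.uses_knn else None,
        negative_refs=negatives if enc_spec.uses_knn else None,
        sim=sim,
        exclude_self=exclude_self,
    )


def train(
    fragments: Sequence[Fragment],
    encoding_spec: EncodingSpec | None = None,
    selection_spec: SelectionSpec | None = None,
    classifier_spec: ClassifierSpec | None = None,
    exclude_self: bool = True,
) -> TrainedPredictor:
    """Fit the full pipeline on labeled fragments.

    ``exclude_self`` controls self-match removal in the KNN encoding of the
    training set itself (the training fragments are their own reference
    set); it should stay on except for diagnostic use.
    """
    encoding_spec = encoding_spec or EncodingSpec()
    selection_spec = selection_spec or SelectionSpec()
    classifier_spec = classifier_spec or ClassifierSpec()

    positives = [f for f in fragments if f.label == "positive"]
    negatives = [f for f in fragments if f.label == "negative"]
    if not positives or not negatives:
        raise DataError(
            f"training needs both classes; got {len(positives)} (+) / {len(negatives)} (-)"
        )

    sim = normalize_blosum62() if encoding_spec.uses_knn else None
    X = _encode_for_training(
        fragments, encoding_spec, positives, negatives, sim, exclude_self
    )
    bad = ~np.isfinite(X)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        frag = fragments[int(i)]
        raise DataError(
            f"non-finite feature {encoding_spec.feature_layout()[int(j)]} "
            f"for fragment {frag.protein_id}:{frag.position}"
        )
    y = np.array([1 if f.label == "positive" else 0 for f in fragments])

    scaler_min = X.min(axis=0)
    scaler_range = X.max(axis=0) - scaler_min
    safe_range = np.where(scaler_range == 0, 1.0, scaler_range)
    Xs = (X - scaler_min) / safe_range

    layout = encoding_spec.feature_layout()
    pre_dim = len(layout)
    target_dim = selection_spec.target_dim(encoding_spec.scheme, pre_dim)
    if target_dim < pre_dim:
        fw = relieff_weights(
            Xs,
            y,
            neighbors=selection_spec.neighbors,
            sample_size=selection_spec.sample_size,
            seed=classifier_spec.seed,
        )
        Xr, retained = select_top(Xs, fw, target_dim)
    else:
        Xr, retained = Xs, np.arange(pre_dim)

    if classifier_spec.family == "SVM" and classifier_spec.tune:
        estimator = _tune_svm(Xr, y, classifier_spec)
    else:
        estimator = _make_estimator(classifier_spec, Xr.shape[1])
    estimator.fit(Xr, y)

    return TrainedPredictor(
        estimator=estimator,
        encoding_spec=encoding_spec,
        selection_spec=selection_spec,
        classifier_spec=classifier_spec,
        feature_layout=layout,
        retained=retained,
        scaler_min=scaler_min,
        scaler_range=scaler_range,
        positive_refs=positives if encoding_spec.uses_knn else None,
        negative_refs=negatives if encoding_spec.uses_knn else None,
        train_keys={f.key for f in fragments},
        threshold=default_threshold(classifier_spec.family),
        similarity=sim,
    )


def _transform(predictor: TrainedPredictor, fragments: Sequence[Fragment],
               exclude_self: bool = False) -> np.ndarray:
    X = encode_fragments(
        fragments,
        predictor.encoding_spec,
        positive_refs=predictor.positive_refs,
        negative_refs=predictor.negative_refs,
        sim=predictor.similarity,
        exclude_self=exclude_self,
    )
    safe_range = np.where(predictor.scaler_range == 0, 1.0, predictor.scaler_range)
    Xs = (X - predictor.scaler_min) / safe_range
    return Xs[:, predictor.retained]


def decision_scores(
    predictor: TrainedPredictor,
    fragments: Sequence[Fragment],
    exclude_self: bool = False,
) -> np.ndarray:
    """Continuous per-fragment scores; larger = more phosphosite-like."""
    Xr = _transform(predictor, fragments, exclude_self=exclude_self)
    family = predictor.classifier_spec.family
    est = predictor.estimator
    if family == "SVM":
        return est.decision_function(Xr)
    if family == "RF":
        votes = np.stack([tree.predict(Xr) for tree in est.estimators_])
        return votes.mean(axis=0)
    # DT positive-leaf proportion; KNNC positive-neighbor fraction
    return est.predict_proba(Xr)[:, 1]


def predict_labels(
    predictor: TrainedPredictor,
    fragments: Sequence[Fragment],
    threshold: float | None = None,
    exclude_self: bool = False,
) -> list[str]:
    """Hard labels: positive iff score >= threshold (ties go positive)."""
    thr = predictor.threshold if threshold is None else threshold
    scores = decision_scores(predictor, fragments, exclude_self=exclude_self)
    return ["positive" if s >= thr else "negative" for s in scores]


def save_model(predictor: TrainedPredictor, path: str | Path) -> None:
    """Persist a predictor as a single archive (schema-versioned)."""
    payload = {
        "schema_version": predictor.schema_version,
        "estimator": predictor.estimator,
        "encoding_spec": predictor.encoding_spec.to_dict(),
        "selection_spec": {
            "target_dims": dict(predictor.selection_spec.target_dims),
            "neighbors": predictor.selection_spec.neighbors,
            "sample_size": predictor.selection_spec.sample_size,
        },
        "classifier_spec": predictor.classifier_spec.to_dict(),
        "feature_layout": predictor.feature_layout,
        "retained": predictor.retained,
        "scaler_min": predictor.scaler_min,
        "scaler_range": predictor.scaler_range,
        "positive_refs": predictor.positive_refs,
        "negative_refs": predictor.negative_refs,
        "train_keys": sorted(predictor.train_keys),
        "threshold": predictor.threshold,
        "similarity": None if predictor.similarity is None else predictor.similarity.values,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedPredictor:
    payload = joblib.load(path)
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ConfigError(
            f"incompatible model archive: schema version {version}, expected {SCHEMA_VERSION}"
        )
    return TrainedPredictor(
        estimator=payload["estimator"],
        encoding_spec=EncodingSpec.from_dict(payload["encoding_spec"]),
        selection_spec=SelectionSpec(
            target_dims=payload["selection_spec"]["target_dims"],
            neighbors=payload["selection_spec"]["neighbors"],
            sample_size=payload["selection_spec"]["sample_size"],
        ),
        classifier_spec=ClassifierSpec.from_dict(payload["classifier_spec"]),
        feature_layout=payload["feature_layout"],
        retained=payload["retained"],
        scaler_min=payload["scaler_min"],
        scaler_range=payload["scaler_range"],
        positive_refs=payload["positive_refs"],
        negative_refs=payload["negative_refs"],
        train_keys={tuple(k) for k in payload["train_keys"]},
        threshold=payload["threshold"],
        similarity=(
            None if payload["similarity"] is None else SimilarityMatrix(payload["similarity"])
        ),
        schema_version=version,
    )
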