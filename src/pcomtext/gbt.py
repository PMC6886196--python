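"""Gradient-boosted tree classifier over bag-of-n-grams plus volumes.

Unlike the rule engine, this model sees each whole report as one
document: counts of all 1-, 2- and 3-grams (no human term selection, no
laterality split) plus two numeric predictors, ``eval_left`` and
``eval_right`` — the per-side ovarian volumes extracted by the
contextualization/volumetry pipeline. Missing volumes stay missing
(XGBoost handles them natively); 0 ml would be a meaningful, impossible
value. The only tuned quantity is the number of boosting rounds,
selected by minimizing 5-fold cross-validated multiclass error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold

from .contextualizer import build_ovary_documents
from .rbc import LABELS, PCOMLabel
from .textprep import RawReport, default_stopwords, preprocess_report

__all__ = [
    "DEFAULT_PARAMS",
    "FeatureMatrix",
    "BoostedModel",
    "build_features",
    "select_rounds_cv",
    "train_gbt",
    "predict_gbt",
]

# Pinned "conventional defaults": library defaults drift across versions.
DEFAULT_PARAMS: dict = {
    "objective": "multi:softprob",
    "num_class": 3,
    "eta": 0.3,
    "max_depth": 6,
    "tree_method": "hist",
    "nthread": 1,
}

MAX_ROUNDS = 400
VOLUME_FEATURES = ("eval_left", "eval_right")


@dataclass
class FeatureMatrix:
    """Per-report features: n-gram counts then eval_left / eval_right."""

    report_ids: list[str]
    feature_names: list[str]  # vocabulary n-grams + VOLUME_FEATURES
    X: sp.csr_matrix  # missing volumes encoded as NaN

    @property
    def vocabulary(self) -> list[str]:
        return self.feature_names[: -len(VOLUME_FEATURES)]


def _report_grams(report: RawReport, stopwords) -> tuple[dict[str, int], float, float]:
    """N-gram counts over the whole report plus the two side volumes."""
    clean = preprocess_report(report, stopwords)
    grams: dict[str, int] = {}
    for tokens in clean.token_sentences:
        for n in (1, 2, 3):
            for i in range(len(tokens) - n + 1):
                g = " ".join(tokens[i : i + n])
                grams[g] = grams.get(g, 0) + 1
    docs = build_ovary_documents(report, stopwords)
    left = docs["left"].volume_ml
    right = docs["right"].volume_ml
    return grams, (np.nan if left is None else left), (np.nan if right is None else right)


def build_features(
    reports: list[RawReport],
    vocabulary: list[str] | None = None,
    min_df: int = 2,
) -> FeatureMatrix:
    """Bag-of-1-3-grams plus extracted volumes for every report.

    With ``vocabulary=None`` (training) the vocabulary is built from
    these reports, keeping n-grams seen in at least ``min_df`` of them;
    at prediction time pass the model's vocabulary and unseen n-grams
    are dropped.
    """
    stopwords = default_stopwords()
    per_report = [_report_grams(r, stopwords) for r in reports]
    if vocabulary is None:
        df: dict[str, int] = {}
        for grams, _, _ in per_report:
            for g in grams:
                df[g] = df.get(g, 0) + 1
        vocabulary = sorted(g for g, c in df.items() if c >= min_df)
    index = {g: j for j, g in enumerate(vocabulary)}
    n_vocab = len(vocabulary)
    rows, cols, vals = [], [], []
    for r, (grams, left, right) in enumerate(per_report):
        for g, c in grams.items():
            j = index.get(g)
            if j is not None:
                rows.append(r)
                cols.append(j)
                vals.append(float(c))
        for k, vol in enumerate((left, right)):
            if not np.isnan(vol):
                rows.append(r)
                cols.append(n_vocab + k)
                vals.append(vol)
            else:
                # explicit NaN entry so XGBoost routes it as missing
                rows.append(r)
                cols.append(n_vocab + k)
                vals.append(np.nan)
    X = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(reports), n_vocab + 2), dtype=np.float32
    )
    return FeatureMatrix(
        report_ids=[r.report_id for r in reports],
        feature_names=list(vocabulary) + list(VOLUME_FEATURES),
        X=X,
    )


def _encode_labels(labels) -> np.ndarray:
    index = {c: i for i, c in enumerate(LABELS)}
    try:
        return np.array([index[str(l)] for l in labels], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unknown label {exc.args[0]!r}") from exc


def _dmatrix(fm: FeatureMatrix, y: np.ndarray | None = None) -> xgb.DMatrix:
    return xgb.DMatrix(
        fm.X, label=y, feature_names=fm.feature_names, missing=np.nan
    )


def select_rounds_cv(
    features: FeatureMatrix,
    labels,
    k: int = 5,
    max_rounds: int = MAX_ROUNDS,
    seed: int = 0,
) -> int:
    """Boosting rounds minimizing mean k-fold multiclass error rate.

    Folds are stratified by class and seeded; ties break toward fewer
    rounds. Raises if any class has fewer than ``k`` examples.
    """
    y = _encode_labels(labels)
    if k > len(y):
        raise ValueError(f"k={k} exceeds the number of examples {len(y)}")
    for i, cls in enumerate(LABELS):
        if (y == i).sum() < k:
            raise ValueError(f"class {cls!r} has fewer than k={k} examples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(y)), y))
    params = dict(DEFAULT_PARAMS, seed=seed)
    cv = xgb.cv(
        params,
        _dmatrix(features, y),
        num_boost_round=max_rounds,
        folds=folds,
        metrics="merror",
        seed=seed,
    )
    mean_err = cv["test-merror-mean"].to_numpy()
    return int(np.argmin(mean_err)) + 1  # first minimum = fewest rounds


@dataclass
class BoostedModel:
    """Trained 3-class boosted-tree ensemble plus everything to reuse it."""

    booster: xgb.Booster
    feature_names: list[str]
    n_rounds: int
    seed: int
    params: dict

    def save(self, model_dir: str | Path) -> None:
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        self.booster.save_model(model_dir / "model.json")
        meta = {
            "feature_names": self.feature_names,
            "n_rounds": self.n_rounds,
            "seed": self.seed,
            "params": self.params,
            "classes": list(LABELS),
        }
        (model_dir / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, model_dir: str | Path) -> "BoostedModel":
        model_dir = Path(model_dir)
        meta = json.loads((model_dir / "meta.json").read_text())
        booster = xgb.Booster()
        booster.load_model(model_dir / "model.json")
        return cls(
            booster=booster,
            feature_names=meta["feature_names"],
            n_rounds=meta["n_rounds"],
            seed=meta["seed"],
            params=meta["params"],
        )

    @property
    def vocabulary(self) -> list[str]:
        return self.feature_names[: -len(VOLUME_FEATURES)]


def train_gbt(
    features: FeatureMatrix, labels, n_rounds: int, seed: int = 0
) -> BoostedModel:
    """Fit the boosted ensemble; same seed, same model."""
    y = _encode_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    params = dict(DEFAULT_PARAMS, seed=seed)
    booster = xgb.train(params, _dmatrix(features, y), num_boost_round=n_rounds)
    return BoostedModel(
        booster=booster,
        feature_names=features.feature_names,
        n_rounds=n_rounds,
        seed=seed,
        params=params,
    )


def predict_gbt(
    model: BoostedModel, features: FeatureMatrix
) -> tuple[list[PCOMLabel], np.ndarray]:
    """Labels (argmax) and per-class probability triples.

    Features must be built against the model's vocabulary.
    """
    if features.feature_names != model.feature_names:
        raise ValueError("feature names do not match the model's vocabulary")
    probs = model.booster.predict(_dmatrix(features))
    labels = [PCOMLabel(LABELS[i]) for i in np.argmax(probs, axis=1)]
    return labels, probs
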