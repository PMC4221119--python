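"""Score fusion: logistic combination of the gene variant score and the walk
score into the final ExomeWalker score.

A logistic model is trained on labeled (variant score, walk feature)
examples with k-fold cross validation; the fold models' coefficients are
averaged into the final model (prediction averaging is available as an
alternative).  The walk feature defaults to the gene's percentile among all
network genes' stationary probabilities, which is comparable across networks
of different size; the raw stationary probability can be used instead.

The shipped default model is a surrogate fit on this package's synthetic
labeled-variant generator with a documented seed.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

MODEL_SCHEMA_VERSION = 1

#: inverse L2 strength for the per-fold logistic fits; a small fixed penalty
#: keeps coefficients finite on separable data
LOGISTIC_C = 10.0


class WalkTransform(enum.Enum):
    RAW = "RAW"
    PERCENTILE = "PERCENTILE"


class Label(enum.Enum):
    BENIGN = 0
    DISEASE = 1


@dataclass(frozen=True)
class LabeledExample:
    variant_score: float
    walk_score: float
    label: Label


@dataclass
class CombinerModel:
    """Averaged logistic model sigma(intercept + w_variant*v + w_walk*t(walk))."""

    intercept: float
    w_variant: float
    w_walk: float
    walk_transform: WalkTransform = WalkTransform.PERCENTILE
    averaging: str = "coefficients"
    fold_models: list[tuple[float, float, float]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "intercept": self.intercept,
            "w_variant": self.w_variant,
            "w_walk": self.w_walk,
            "walk_transform": self.walk_transform.value,
            "averaging": self.averaging,
            "fold_models": self.fold_models,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CombinerModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported model schema version {payload.get('schema_version')}"
            )
        return cls(
            intercept=payload["intercept"],
            w_variant=payload["w_variant"],
            w_walk=payload["w_walk"],
            walk_transform=WalkTransform(payload["walk_transform"]),
            averaging=payload.get("averaging", "coefficients"),
            fold_models=[tuple(t) for t in payload.get("fold_models", [])],
            provenance=payload.get("provenance", {}),
        )


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def train_combiner(
    examples: list[LabeledExample],
    folds: int = 10,
    seed: int = 0,
    walk_transform: WalkTransform = WalkTransform.PERCENTILE,
    averaging: str = "coefficients",
) -> CombinerModel:
    """Cross-validated logistic fusion of variant and walk scores.

    One logistic model is fit per fold on the training portion; the final
    coefficients are the arithmetic mean over folds.  Held-out AUC per fold
    and its mean are recorded in ``provenance``.  Deterministic given
    (examples, folds, seed).

    Raises
    ------
    ValueError
        If only one class is present or folds < 2.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.array([[e.variant_score, e.walk_score] for e in examples])
    y = np.array([e.label.value for e in examples])
    if len(np.unique(y)) < 2:
        raise ValueError("both DISEASE and BENIGN examples are required")
    if averaging not in ("coefficients", "predictions"):
        raise ValueError(f"unknown averaging mode {averaging!r}")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_models: list[tuple[float, float, float]] = []
    fold_aucs: list[float] = []
    for train_idx, test_idx in skf.split(X, y):
        clf = LogisticRegression(C=LOGISTIC_C, solver="lbfgs", max_iter=1000)
        clf.fit(X[train_idx], y[train_idx])
        fold_models.append(
            (float(clf.intercept_[0]), float(clf.coef_[0, 0]), float(clf.coef_[0, 1]))
        )
        if len(np.unique(y[test_idx])) == 2:
            prob = clf.predict_proba(X[test_idx])[:, 1]
            fold_aucs.append(float(roc_auc_score(y[test_idx], prob)))

    arr = np.array(fold_models)
    intercept, w_v, w_w = arr.mean(axis=0)
    return CombinerModel(
        intercept=float(intercept),
        w_variant=float(w_v),
        w_walk=float(w_w),
        walk_transform=walk_transform,
        averaging=averaging,
        fold_models=fold_models,
        provenance={
            "n_pos": int((y == 1).sum()),
            "n_neg": int((y == 0).sum()),
            "folds": folds,
            "seed": seed,
            "fold_aucs": fold_aucs,
            "mean_auc": float(np.mean(fold_aucs)) if fold_aucs else None,
        },
    )


def combine(gene_variant_score: float, walk_feature: float, model: CombinerModel) -> float:
    """Final fused score in (0, 1).

    ``walk_feature`` must already be on the model's feature scale: the
    percentile in [0, 1] for a PERCENTILE model (see
    `exomewalker.walk.walk_percentiles`), the raw stationary probability for
    a RAW model.  Strictly increasing in each input with a positive weight.
    """
    if not (math.isfinite(model.intercept) and math.isfinite(model.w_variant)):
        raise ValueError("combiner model is not trained")
    if model.averaging == "predictions" and model.fold_models:
        preds = [
            _sigmoid(b0 + bv * gene_variant_score + bw * walk_feature)
            for b0, bv, bw in model.fold_models
        ]
        return float(np.mean(preds))
    return _sigmoid(
        model.intercept
        + model.w_variant * gene_variant_score
        + model.w_walk * walk_feature
    )


def default_model(seed: int = 20_001) -> CombinerModel:
    """Surrogate default model fit on the synthetic labeled-variant generator
    (20k disease + 20k benign examples scaled down to 2k/2k, documented seed).
    """
    from .simulate import generate_labeled_variants

    examples = generate_labeled_variants(
        n_pos=2000, n_neg=2000, effect_size=0.8, seed=seed
    )
    model = train_combiner(examples, folds=10, seed=seed)
    model.provenance["source"] = "synthetic-labeled-generator"
    return model
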