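"""The PPV model: L2 logistic regression under nested cross-validation.

The outer 5-fold loop produces out-of-fold probabilities used for all
reported performance numbers; the inner 4-fold loop selects the
regularization strength by validation AUC.  The 5 x 4 = 20 inner-fold
models (at each outer fold's selected strength) are retained so that the
spread of their coefficients can be inspected.  Folds are group-aware by
protein accession: every peptide variant of one precursor shares a fold,
preventing near-duplicate intervals from leaking between train and test.
Feature standardization (z-scoring) is always fit on the training rows of
the fold at hand, never on its held-out rows.

The optional positive upsampling (sampling positives with replacement up to
a target positive:negative ratio) is applied only to rows a model is fitted
on — never to validation or test rows — and exists for the assembly variant,
where synthetic peptides flood the negative class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .evaluation import roc_auc
from .features import FEATURE_NAMES

DEFAULT_REG_GRID = (0.01, 0.1, 1.0)

TIER_VERY_HIGH_THRESHOLD = 0.05
TIER_HIGH_THRESHOLD = 0.01


@dataclass
class InnerModel:
    outer_fold: int
    inner_fold: int
    C: float
    coef: np.ndarray
    intercept: float
    mean: np.ndarray
    sd: np.ndarray
    val_auc: float


@dataclass
class ModelBundle:
    feature_names: list[str]
    inner_models: list[InnerModel]
    outer_fold: np.ndarray  # per design row
    selected_C: dict[int, float]
    final_coef: np.ndarray
    final_intercept: float
    final_mean: np.ndarray
    final_sd: np.ndarray
    oof_scores: np.ndarray
    seed: int
    upsample_ratio: float | None = None
    outer_models: list[InnerModel] = field(default_factory=list)

    def coefficient_table(self) -> pd.DataFrame:
        """Inner-model coefficients, one row per (outer, inner) model."""
        rows = []
        for m in self.inner_models:
            row = dict(zip(self.feature_names, m.coef))
            row["outer_fold"] = m.outer_fold
            row["inner_fold"] = m.inner_fold
            row["C"] = m.C
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        def arr(a):
            return np.asarray(a).tolist()

        payload = {
            "format_version": 1,
            "feature_names": self.feature_names,
            "seed": self.seed,
            "upsample_ratio": self.upsample_ratio,
            "selected_C": {str(k): v for k, v in self.selected_C.items()},
            "outer_fold": arr(self.outer_fold),
            "oof_scores": arr(self.oof_scores),
            "final": {
                "coef": arr(self.final_coef),
                "intercept": self.final_intercept,
                "mean": arr(self.final_mean),
                "sd": arr(self.final_sd),
            },
            "inner_models": [
                {
                    "outer_fold": m.outer_fold,
                    "inner_fold": m.inner_fold,
                    "C": m.C,
                    "coef": arr(m.coef),
                    "intercept": m.intercept,
                    "mean": arr(m.mean),
                    "sd": arr(m.sd),
                    "val_auc": m.val_auc,
                }
                for m in self.inner_models
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelBundle":
        payload = json.loads(Path(path).read_text())
        inner = [
            InnerModel(
                outer_fold=m["outer_fold"],
                inner_fold=m["inner_fold"],
                C=m["C"],
                coef=np.asarray(m["coef"]),
                intercept=m["intercept"],
                mean=np.asarray(m["mean"]),
                sd=np.asarray(m["sd"]),
                val_auc=m["val_auc"],
            )
            for m in payload["inner_models"]
        ]
        final = payload["final"]
        return cls(
            feature_names=payload["feature_names"],
            inner_models=inner,
            outer_fold=np.asarray(payload["outer_fold"]),
            selected_C={int(k): v for k, v in payload["selected_C"].items()},
            final_coef=np.asarray(final["coef"]),
            final_intercept=final["intercept"],
            final_mean=np.asarray(final["mean"]),
            final_sd=np.asarray(final["sd"]),
            oof_scores=np.asarray(payload["oof_scores"]),
            seed=payload["seed"],
            upsample_ratio=payload["upsample_ratio"],
        )


def assign_group_folds(
    groups: Sequence[str],
    labels: Sequence[int],
    n_folds: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Group-aware fold assignment balancing positives across folds.

    Groups carrying positives are shuffled and dealt round-robin by
    descending positive count; negative-only groups then top up the
    currently smallest fold.  Deterministic given the generator state.
    """
    groups = np.asarray(groups)
    labels = np.asarray(labels)
    unique = sorted(set(groups))
    pos_count = {g: int(labels[groups == g].sum()) for g in unique}
    size = {g: int((groups == g).sum()) for g in unique}

    shuffled = list(unique)
    rng.shuffle(shuffled)
    pos_groups = sorted(
        [g for g in shuffled if pos_count[g] > 0],
        key=lambda g: -pos_count[g],
    )
    neg_groups = sorted(
        [g for g in shuffled if pos_count[g] == 0],
        key=lambda g: -size[g],
    )

    fold_of: dict[str, int] = {}
    fold_sizes = np.zeros(n_folds, dtype=int)
    for i, g in enumerate(pos_groups):
        fold = i % n_folds
        fold_of[g] = fold
        fold_sizes[fold] += size[g]
    for g in neg_groups:
        fold = int(np.argmin(fold_sizes))
        fold_of[g] = fold
        fold_sizes[fold] += size[g]
    return np.asarray([fold_of[g] for g in groups])


def _standardize_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def _upsample(
    X: np.ndarray, y: np.ndarray, ratio: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Resample positives with replacement up to ratio * n_negatives."""
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    target = int(round(ratio * len(neg)))
    if target <= len(pos):
        return X, y
    extra = rng.choice(pos, size=target - len(pos), replace=True)
    idx = np.concatenate([np.arange(len(y)), extra])
    return X[idx], y[idx]


def _fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    upsample_ratio: float | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Standardize on (X, y), optionally upsample positives, fit L2 logistic."""
    mean, sd = _standardize_params(X)
    Z = (X - mean) / sd
    if upsample_ratio is not None:
        Z, y = _upsample(Z, y, upsample_ratio, rng)
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)  # L2 penalty
    clf.fit(Z, y)
    return clf.coef_[0].copy(), float(clf.intercept_[0]), mean, sd


def _predict(
    X: np.ndarray, coef: np.ndarray, intercept: float, mean: np.ndarray, sd: np.ndarray
) -> np.ndarray:
    z = ((X - mean) / sd) @ coef + intercept
    return 1.0 / (1.0 + np.exp(-z))


def train_nested_cv(
    design: pd.DataFrame,
    n_outer: int = 5,
    n_inner: int = 4,
    reg_grid: Sequence[float] = DEFAULT_REG_GRID,
    upsample_ratio: float | None = None,
    seed: int = 0,
) -> ModelBundle:
    """Nested group-aware cross-validation of the logistic PPV model.

    Returns a bundle holding the n_outer x n_inner inner models (at each
    outer fold's selected strength), the per-row outer-fold assignment,
    out-of-fold probabilities, and a final model refit on all rows at the
    modal selected strength.
    """
    if n_outer < 2 or n_inner < 2:
        raise ValueError("need at least 2 outer and 2 inner folds")
    X = design[FEATURE_NAMES].to_numpy(dtype=float)
    y = design["label"].to_numpy(dtype=int)
    groups = design["group_key"].to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("training requires both positive and negative rows")

    rng = np.random.default_rng(seed)
    outer_fold = assign_group_folds(groups, y, n_outer, rng)
    for fold in range(n_outer):
        if y[outer_fold != fold].sum() < 2:
            raise ValueError(
                f"outer training split {fold} has fewer than 2 positives"
            )

    inner_models: list[InnerModel] = []
    outer_models: list[InnerModel] = []
    oof = np.full(len(y), np.nan)
    selected: dict[int, float] = {}

    for fold in range(n_outer):
        train_idx = np.flatnonzero(outer_fold != fold)
        test_idx = np.flatnonzero(outer_fold == fold)
        X_tr, y_tr, g_tr = X[train_idx], y[train_idx], groups[train_idx]

        inner_fold = assign_group_folds(g_tr, y_tr, n_inner, rng)
        fits: dict[float, list[InnerModel]] = {C: [] for C in reg_grid}
        for C in reg_grid:
            for j in range(n_inner):
                fit_idx = np.flatnonzero(inner_fold != j)
                val_idx = np.flatnonzero(inner_fold == j)
                coef, intercept, mean, sd = _fit_logistic(
                    X_tr[fit_idx], y_tr[fit_idx], C, upsample_ratio, rng
                )
                val_scores = _predict(X_tr[val_idx], coef, intercept, mean, sd)
                if 0 < y_tr[val_idx].sum() < len(val_idx):
                    auc = roc_auc(y_tr[val_idx], val_scores)
                else:
                    auc = 0.5  # degenerate validation split carries no signal
                fits[C].append(
                    InnerModel(fold, j, C, coef, intercept, mean, sd, auc)
                )
        mean_auc = {C: float(np.mean([m.val_auc for m in fits[C]])) for C in reg_grid}
        best_C = min(reg_grid, key=lambda C: (-mean_auc[C], C))
        selected[fold] = best_C
        inner_models.extend(fits[best_C])

        coef, intercept, mean, sd = _fit_logistic(
            X_tr, y_tr, best_C, upsample_ratio, rng
        )
        outer_models.append(
            InnerModel(fold, -1, best_C, coef, intercept, mean, sd, np.nan)
        )
        oof[test_idx] = _predict(X[test_idx], coef, intercept, mean, sd)

    counts = {C: sum(1 for v in selected.values() if v == C) for C in reg_grid}
    modal_C = min(reg_grid, key=lambda C: (-counts[C], C))
    final_coef, final_intercept, final_mean, final_sd = _fit_logistic(
        X, y, modal_C, upsample_ratio, rng
    )
    return ModelBundle(
        feature_names=list(FEATURE_NAMES),
        inner_models=inner_models,
        outer_fold=outer_fold,
        selected_C=selected,
        final_coef=final_coef,
        final_intercept=final_intercept,
        final_mean=final_mean,
        final_sd=final_sd,
        oof_scores=oof,
        seed=seed,
        upsample_ratio=upsample_ratio,
        outer_models=outer_models,
    )


def score_peptides(bundle: ModelBundle, features: pd.DataFrame) -> np.ndarray:
    """Probability per row from the final refit model."""
    missing = [c for c in bundle.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"feature columns missing from input: {missing}")
    X = features[bundle.feature_names].to_numpy(dtype=float)
    return _predict(
        X, bundle.final_coef, bundle.final_intercept, bundle.final_mean,
        bundle.final_sd,
    )


def classify_score_tier(p: float) -> str:
    """Tier a PPV probability: very_high (>0.05), high (>0.01), else low."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability outside [0, 1]: {p}")
    if p > TIER_VERY_HIGH_THRESHOLD:
        return "very_high"
    if p > TIER_HIGH_THRESHOLD:
        return "high"
    return "low"


def combine_tissue_scores(scores: Mapping[str, float]) -> float:
    """Noisy-OR consolidation of per-tissue probabilities."""
    if not scores:
        raise ValueError("at least one tissue score is required")
    keep = 1.0
    for tissue, p in scores.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability for {tissue!r} outside [0, 1]: {p}")
        keep *= 1.0 - p
    return 1.0 - keep


def rank_predictions(predictions: pd.DataFrame, score_column: str = "ppv_score") -> pd.DataFrame:
    """Deterministic ranking: score desc, abundance desc, accession asc, start asc."""
    ordered = predictions.sort_values(
        by=[score_column, "total_abundance", "protein_accession", "start"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    ordered["rank"] = np.arange(1, len(ordered) + 1)
    return ordered
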