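"""Phylogenetically blocked cross-validation for random-forest models.

Random splits overstate predictive performance when observations share
evolutionary history: related taxa resemble each other in both features and
labels, so a randomly held-out taxon has close relatives in the training
set.  Blocked cross-validation instead holds out whole monophyletic clades
(phyla, classes, or families), so each fold estimates genuinely
out-of-clade generalization.  Performance is summarized by Cohen's kappa
(chance-corrected agreement over a prevalence-only null) and the area under
the precision-recall curve for classification, and by RMSE, the
predicted-observed correlation, and adjusted R^2 for regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import precision_recall_curve
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "FoldSpec",
    "LearnConfig",
    "ClassificationMetrics",
    "RegressionMetrics",
    "make_clade_folds",
    "cohens_kappa",
    "precision_recall_auc",
    "mean_impute",
    "blocked_classify",
    "blocked_regress",
]


@dataclass(frozen=True)
class FoldSpec:
    """Clade-label folds: every fold is a label equivalence class."""

    folds: Mapping[str, tuple[str, ...]]  # fold_id -> unit ids
    level: str

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for members in self.folds.values():
            overlap = seen.intersection(members)
            if overlap:
                raise ValueError(f"units in multiple folds: {sorted(overlap)[:5]}")
            seen.update(members)

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def units(self) -> list[str]:
        return [u for members in self.folds.values() for u in members]


def make_clade_folds(
    units: Sequence[str],
    clade_labels: pd.DataFrame,
    level: str,
    fallback_levels: Sequence[str] = ("class", "family"),
) -> FoldSpec:
    """One fold per clade label at ``level``; descend when a level is degenerate.

    If all units share a single label at the requested level (as happens for
    phyla whose sampled members all belong to one class), the next finer
    level from ``fallback_levels`` is tried; a level at which everything is
    still one clade and nothing finer exists is an error.
    """
    candidates = [level] + [l for l in fallback_levels if l != level]
    for lev in candidates:
        if lev not in clade_labels.columns:
            continue
        labels = clade_labels.loc[list(units), lev]
        if labels.isna().any() or (labels == "").any():
            continue
        if labels.nunique() >= 2:
            folds = {
                str(lab): tuple(labels.index[labels == lab])
                for lab in sorted(labels.unique())
            }
            return FoldSpec(folds, lev)
    raise ValueError(
        f"no clade level among {candidates} splits the {len(units)} units "
        "into >= 2 folds"
    )


def cohens_kappa(observed: Sequence, predicted: Sequence) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    p_e is computed from the marginal label frequencies of both lists.
    Returns 0.0 in the degenerate case p_e = 1 (a single shared class),
    where the null already agrees perfectly.
    """
    obs = np.asarray(observed)
    pred = np.asarray(predicted)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size == 0:
        raise ValueError("observed and predicted must be equal-length 1-d, n >= 1")
    n = obs.size
    p_o = float((obs == pred).mean())
    labels = np.unique(np.concatenate([obs, pred]))
    p_e = float(
        sum((obs == lab).mean() * (pred == lab).mean() for lab in labels)
    )
    if p_e >= 1.0 - 1e-12:
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def precision_recall_auc(observed: Sequence, scores: Sequence[float],
                         positive_class=1) -> float:
    """Area under the precision-recall curve by step-wise interpolation.

    The curve is swept over unique score thresholds in descending order and
    integrated as sum over recall steps of (R_k - R_{k-1}) * P_k.  Constant
    scores give the positive-class prevalence.  Raises on single-class input.
    """
    y = (np.asarray(observed) == positive_class).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("precision-recall AUC undefined for single-class labels")
    precision, recall, _ = precision_recall_curve(y, s)
    # sklearn returns the curve from high threshold to low, reversed; step sum:
    return float(-np.sum(np.diff(recall) * np.array(precision)[:-1]))


def mean_impute(values: pd.DataFrame) -> pd.DataFrame:
    """Replace missing cells by the column mean over the whole matrix.

    Columns with no observed value cannot be imputed and are dropped with a
    warning.  Means are database-wide (not per training fold), matching the
    use of the full curated database as the imputation reference.
    """
    out = values.copy()
    all_missing = [c for c in out.columns if out[c].isna().all()]
    if all_missing:
        import logging

        logging.getLogger(__name__).warning(
            "dropping %d all-missing columns: %s", len(all_missing), all_missing[:5]
        )
        out = out.drop(columns=all_missing)
    return out.fillna(out.mean())


class BalancedRandomForestClassifier:
    """Random forest with stratified per-class bootstrap.

    Each tree is grown on a bootstrap sample in which every class is drawn
    with replacement down to the minority-class count, so class priors are
    equalized per tree and predicted probabilities are calibrated around the
    balanced prior.  This mirrors stratified sampling for uneven classes
    (randomForest's ``sampsize`` with equal per-class counts).
    """

    def __init__(self, n_estimators: int = 500, random_state: int = 0,
                 max_features: str = "sqrt"):
        self.n_estimators = n_estimators
        self.random_state = random_state
        self.max_features = max_features

    def fit(self, X, y) -> "BalancedRandomForestClassifier":
        Xv = np.asarray(X, dtype=float)
        yv = np.asarray(y)
        self.classes_ = np.unique(yv)
        rng = np.random.default_rng(self.random_state)
        idx_by_class = [np.where(yv == c)[0] for c in self.classes_]
        m = min(len(ix) for ix in idx_by_class)
        self.estimators_ = []
        self._boot_indices: list[np.ndarray] = []
        self._X_train = Xv
        self._y_train = yv
        for _ in range(self.n_estimators):
            boot = np.concatenate(
                [rng.choice(ix, size=m, replace=True) for ix in idx_by_class]
            )
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(Xv[boot], yv[boot])
            self.estimators_.append(tree)
            self._boot_indices.append(boot)
        return self

    def oob_mda_importance(self, n_repeats: int = 1, seed: int = 0) -> np.ndarray:
        """Per-tree out-of-bag mean decrease in accuracy.

        For each tree and feature, the tree's accuracy on its out-of-bag
        rows is compared with the accuracy after permuting that feature
        within the out-of-bag rows; drops are averaged over trees.
        Evaluating per tree (rather than on the ensemble) prevents
        correlated features from masking each other's importance.
        """
        rng = np.random.default_rng(seed)
        n, p = self._X_train.shape
        drops = np.zeros(p)
        counted = 0
        for tree, boot in zip(self.estimators_, self._boot_indices):
            oob = np.setdiff1d(np.arange(n), boot)
            if oob.size < 2:
                continue
            X_oob = self._X_train[oob]
            y_oob = self._y_train[oob]
            base = float((tree.predict(X_oob) == y_oob).mean())
            # one stacked predict per repeat: all features permuted side by side
            for _ in range(n_repeats):
                stacked = np.tile(X_oob, (p, 1))
                for j in range(p):
                    rows = slice(j * oob.size, (j + 1) * oob.size)
                    stacked[rows, j] = rng.permutation(X_oob[:, j])
                pred = tree.predict(stacked)
                acc = (
                    (pred == np.tile(y_oob, p))
                    .reshape(p, oob.size)
                    .mean(axis=1)
                )
                drops += base - acc
            counted += n_repeats
        return drops / max(counted, 1)

    def predict_proba(self, X) -> np.ndarray:
        Xv = np.asarray(X, dtype=float)
        proba = np.zeros((len(Xv), len(self.classes_)))
        class_pos = {c: k for k, c in enumerate(self.classes_)}
        for tree in self.estimators_:
            p = tree.predict_proba(Xv)
            cols = [class_pos[c] for c in tree.classes_]
            proba[:, cols] += p
        return proba / self.n_estimators

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


@dataclass
class LearnConfig:
    """Random-forest and fold-loop settings."""

    n_trees: int = 5000
    seed: int = 0
    stratify: bool = True  # balanced per-class bootstrap weighting
    importance_repeats: int = 5
    compute_importance: bool = True

    def fold_seed(self, fold_index: int) -> int:
        return int(
            np.random.default_rng([self.seed, fold_index]).integers(2**31 - 1)
        )


@dataclass
class ClassificationMetrics:
    per_fold: pd.DataFrame  # index fold; columns kappa, auprc, prevalence, n
    mean_kappa: float
    mean_auprc: float
    pooled_kappa: float
    skipped_folds: list[str] = field(default_factory=list)


@dataclass
class RegressionMetrics:
    per_fold: pd.DataFrame  # index fold; columns rmse, rho, rho_spearman, adj_r2, n
    mean_rmse: float
    mean_rho: float
    mean_adj_r2: float


def _fold_iter(folds: FoldSpec, features: pd.DataFrame):
    for fold_id, members in folds.folds.items():
        test_ix = [m for m in members if m in features.index]
        train_ix = [
            u for fid, mem in folds.folds.items() if fid != fold_id
            for u in mem if u in features.index
        ]
        yield fold_id, train_ix, test_ix


def blocked_classify(
    features: pd.DataFrame,
    labels: pd.Series,
    folds: FoldSpec,
    config: LearnConfig | None = None,
) -> tuple[pd.DataFrame, ClassificationMetrics, pd.DataFrame]:
    """Leave-one-clade-out random-forest classification.

    For each fold a forest is trained on all other folds and scored on the
    held-out clade.  Returns per-unit predictions (unit, fold, truth, score,
    prediction), fold-level and mean kappa / AUPRC, and per-training-
    configuration permutation importances (mean decrease in accuracy).
    Folds whose training partition is single-class are skipped and flagged.
    """
    config = config or LearnConfig()
    preds_rows = []
    fold_rows = {}
    importances = {}
    skipped = []
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    positive = classes[1]

    for k, (fold_id, train_ix, test_ix) in enumerate(_fold_iter(folds, features)):
        y_train = labels.loc[train_ix]
        if y_train.nunique() < 2 or not test_ix:
            skipped.append(fold_id)
            continue
        if config.stratify:
            clf = BalancedRandomForestClassifier(
                n_estimators=config.n_trees, random_state=config.fold_seed(k)
            )
        else:
            clf = RandomForestClassifier(
                n_estimators=config.n_trees,
                random_state=config.fold_seed(k), n_jobs=1,
            )
        clf.fit(features.loc[train_ix].to_numpy(dtype=float), y_train.to_numpy())
        pos_col = list(clf.classes_).index(positive)
        X_test = features.loc[test_ix].to_numpy(dtype=float)
        score = clf.predict_proba(X_test)[:, pos_col]
        pred = clf.predict(X_test)
        y_test = labels.loc[test_ix]
        for u, t, s, p in zip(test_ix, y_test, score, pred):
            preds_rows.append(
                {"unit": u, "fold": fold_id, "truth": t, "score": s, "prediction": p}
            )
        kappa = cohens_kappa(y_test.to_numpy(), pred)
        try:
            auprc = precision_recall_auc(
                y_test.to_numpy(), score, positive_class=positive
            )
        except ValueError:
            auprc = float("nan")
        fold_rows[fold_id] = {
            "kappa": kappa,
            "auprc": auprc,
            "prevalence": float((y_test == positive).mean()),
            "n": len(test_ix),
        }
        if config.compute_importance:
            if isinstance(clf, BalancedRandomForestClassifier):
                importances[fold_id] = pd.Series(
                    clf.oob_mda_importance(
                        config.importance_repeats, config.fold_seed(k) ^ 0x5F5F
                    ),
                    index=features.columns,
                )
            else:
                importances[fold_id] = _mda_importance(
                    clf, features.loc[train_ix], y_train,
                    config.importance_repeats, config.fold_seed(k) ^ 0x5F5F,
                )

    per_fold = pd.DataFrame.from_dict(fold_rows, orient="index")
    preds = pd.DataFrame(preds_rows)
    if per_fold.empty:
        metrics = ClassificationMetrics(per_fold, float("nan"), float("nan"),
                                        float("nan"), skipped)
        return preds, metrics, pd.DataFrame(index=features.columns)

    pooled = cohens_kappa(preds["truth"].to_numpy(), preds["prediction"].to_numpy())
    imp = pd.DataFrame(importances, index=features.columns)
    imp["mean"] = imp.mean(axis=1) if importances else np.nan
    imp["rank"] = imp["mean"].rank(ascending=False, method="first")
    metrics = ClassificationMetrics(
        per_fold,
        float(per_fold["kappa"].mean()),
        float(per_fold["auprc"].mean()),
        float(pooled),
        skipped,
    )
    return preds, metrics, imp


def _permuted_stacks(Xv: np.ndarray, n_repeats: int, rng: np.random.Generator,
                     max_rows: int = 200_000):
    """Yield (feature indices, stacked design with those features permuted)."""
    n, p = Xv.shape
    per_feature = n * n_repeats
    feats_per_chunk = max(1, max_rows // max(per_feature, 1))
    for start in range(0, p, feats_per_chunk):
        block = list(range(start, min(start + feats_per_chunk, p)))
        stacked = np.tile(Xv, (len(block) * n_repeats, 1))
        for b, j in enumerate(block):
            for r in range(n_repeats):
                rows = slice((b * n_repeats + r) * n, (b * n_repeats + r + 1) * n)
                stacked[rows, j] = rng.permutation(Xv[:, j])
        yield block, stacked


def _mda_importance(model, X: pd.DataFrame, y: pd.Series, n_repeats: int,
                    seed: int) -> pd.Series:
    """Mean decrease in accuracy under per-feature permutation."""
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy()
    n, p = Xv.shape
    base = float((model.predict(Xv) == yv).mean())
    scores = np.zeros(p)
    for block, stacked in _permuted_stacks(Xv, n_repeats, rng):
        pred = model.predict(stacked)
        acc = (
            (pred == np.tile(yv, len(block) * n_repeats))
            .reshape(len(block), n_repeats, n)
            .mean(axis=(1, 2))
        )
        scores[block] = base - acc
    return pd.Series(scores, index=X.columns)


def _mda_importance_regress(model, X: pd.DataFrame, y: pd.Series,
                            n_repeats: int, seed: int) -> pd.Series:
    """Mean increase in MSE under per-feature permutation."""
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    n, p = Xv.shape
    base = float(np.mean((model.predict(Xv) - yv) ** 2))
    scores = np.zeros(p)
    for block, stacked in _permuted_stacks(Xv, n_repeats, rng):
        pred = model.predict(stacked)
        mse = (
            ((pred - np.tile(yv, len(block) * n_repeats)) ** 2)
            .reshape(len(block), n_repeats, n)
            .mean(axis=(1, 2))
        )
        scores[block] = mse - base
    return pd.Series(scores, index=X.columns)


def blocked_regress(
    features: pd.DataFrame,
    response: pd.Series,
    folds: FoldSpec,
    config: LearnConfig | None = None,
) -> tuple[pd.DataFrame, RegressionMetrics, pd.DataFrame]:
    """Leave-one-clade-out random-forest regression.

    Per fold: RMSE, Pearson rho between predicted and observed (Spearman
    reported alongside), and the adjusted R^2 of the observed ~ predicted
    linear fit with n = fold test size and one predictor.  Folds with a
    constant observed response get NaN rho, flagged by omission.
    """
    config = config or LearnConfig()
    preds_rows = []
    fold_rows = {}
    importances = {}
    for k, (fold_id, train_ix, test_ix) in enumerate(_fold_iter(folds, features)):
        if not train_ix or not test_ix:
            continue
        reg = RandomForestRegressor(
            n_estimators=config.n_trees,
            random_state=config.fold_seed(k),
            n_jobs=1,
        )
        reg.fit(features.loc[train_ix].to_numpy(dtype=float),
                response.loc[train_ix].to_numpy(dtype=float))
        pred = reg.predict(features.loc[test_ix].to_numpy(dtype=float))
        obs = response.loc[test_ix].to_numpy(dtype=float)
        for u, t, p in zip(test_ix, obs, pred):
            preds_rows.append({"unit": u, "fold": fold_id, "truth": t,
                               "score": p, "prediction": p})
        rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
        n = len(obs)
        if np.std(obs) == 0 or np.std(pred) == 0 or n < 3:
            rho = rho_s = adj_r2 = float("nan")
        else:
            rho = float(stats.pearsonr(pred, obs)[0])
            rho_s = float(stats.spearmanr(pred, obs)[0])
            r2 = rho**2
            adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        fold_rows[fold_id] = {"rmse": rmse, "rho": rho, "rho_spearman": rho_s,
                              "adj_r2": adj_r2, "n": n}
        if config.compute_importance:
            importances[fold_id] = _mda_importance_regress(
                reg, features.loc[train_ix], response.loc[train_ix],
                config.importance_repeats, config.fold_seed(k) ^ 0x5F5F,
            )

    per_fold = pd.DataFrame.from_dict(fold_rows, orient="index")
    preds = pd.DataFrame(preds_rows)
    imp = pd.DataFrame(importances, index=features.columns)
    imp["mean"] = imp.mean(axis=1) if importances else np.nan
    imp["rank"] = imp["mean"].rank(ascending=False, method="first")
    metrics = RegressionMetrics(
        per_fold,
        float(per_fold["rmse"].mean()) if not per_fold.empty else float("nan"),
        float(per_fold["rho"].mean()) if not per_fold.empty else float("nan"),
        float(per_fold["adj_r2"].mean()) if not per_fold.empty else float("nan"),
    )
    return preds, metrics, imp
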