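"""Two-stage outcome prediction.

Stage 1 classifies lesion laterality from EEG features (slow-wave
lateralization carries the signal); bilateral subjects are then assigned
to the left or right group by the trained model. Stage 2, per group:
Pearson correlation filter (|r| > 0.3), tree-ensemble importance ranking
normalized to sum 1, top-k selection (k=20), and leave-one-out regression
(ridge, lasso, elasticnet, svr, adaboost) scored by R^2 = 1 - SS_res/SS_tot
on the pooled LOO predictions. A composite-subset sensitivity search over
"top pool + bottom pool" feature combinations is included.

By default feature selection runs once on the full group before LOO
("paper" mode); "strict" mode re-runs the correlation filter, ranking and
top-k selection inside every LOO fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import ElasticNet, Lasso, Ridge
from sklearn.svm import SVR

from .connectivity import parse_feature_name
from .synth import GROUP_COL, ID_COL, OUTCOME_COL

REGRESSOR_NAMES = ("ridge", "lasso", "elasticnet", "svr", "adaboost")


def _make_regressor(name: str, seed: int):
    if name == "ridge":
        return Ridge(alpha=1.0)
    if name == "lasso":
        return Lasso(alpha=0.1, max_iter=50_000)
    if name == "elasticnet":
        return ElasticNet(alpha=0.1, l1_ratio=0.5, max_iter=50_000)
    if name == "svr":
        return SVR(C=1.0, epsilon=0.1)
    if name == "adaboost":
        return AdaBoostRegressor(n_estimators=50, random_state=seed)
    raise ValueError(f"unknown model {name!r}; choose from {REGRESSOR_NAMES}")


def feature_columns(table: pd.DataFrame) -> list[str]:
    reserved = {ID_COL, GROUP_COL, OUTCOME_COL}
    return [c for c in table.columns if c not in reserved]


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> tuple[float, float, float]:
    """R^2 = 1 - SS_res/SS_tot; returns (r2, ss_res, ss_tot)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot, ss_res, ss_tot


@dataclass
class ModelEvaluation:
    model: str
    y: np.ndarray
    y_hat: np.ndarray
    ss_res: float
    ss_tot: float
    r2: float
    features: list[str] = field(default_factory=list)

    @classmethod
    def from_predictions(cls, model, y, y_hat, features=()):
        r2, ss_res, ss_tot = r_squared(y, y_hat)
        return cls(model=model, y=np.asarray(y, float), y_hat=np.asarray(y_hat, float),
                   ss_res=ss_res, ss_tot=ss_tot, r2=r2, features=list(features))


@dataclass
class FeatureRanking:
    features: list[str]  # ordered by normalized importance, descending
    raw_importance: np.ndarray
    normalized_importance: np.ndarray
    r_threshold: float | None = None
    correlations: dict[str, float] = field(default_factory=dict)


@dataclass
class LateralityModel:
    estimator: RandomForestClassifier
    feature_names: list[str]
    loo_accuracy: float
    loo_sensitivity: float  # recall on "left"
    loo_specificity: float  # recall on "right"
    confusion: dict[str, int] = field(default_factory=dict)

    def predict_side(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.feature_names].to_numpy(dtype=float)
        return self.estimator.predict(X)


def classify_laterality(
    table: pd.DataFrame, seed: int = 0, n_estimators: int = 200
) -> LateralityModel:
    """Train a seeded random-forest laterality classifier on unilateral
    subjects and report LOO accuracy/sensitivity/specificity."""
    uni = table[table[GROUP_COL].isin(["left", "right"])]
    labels = uni[GROUP_COL].to_numpy()
    classes = set(labels)
    if classes != {"left", "right"}:
        raise ValueError(
            f"need both 'left' and 'right' unilateral subjects, got {sorted(classes)}"
        )
    for side in ("left", "right"):
        if (labels == side).sum() < 2:
            raise ValueError(f"need >= 2 subjects with side {side!r}")
    cols = feature_columns(uni)
    X = uni[cols].to_numpy(dtype=float)
    n = len(uni)
    preds = np.empty(n, dtype=object)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
        clf.fit(X[mask], labels[mask])
        preds[i] = clf.predict(X[i : i + 1])[0]
    acc = float(np.mean(preds == labels))
    is_left = labels == "left"
    sens = float(np.mean(preds[is_left] == "left")) if is_left.any() else np.nan
    spec = float(np.mean(preds[~is_left] == "right")) if (~is_left).any() else np.nan
    confusion = {
        "left_as_left": int(np.sum((labels == "left") & (preds == "left"))),
        "left_as_right": int(np.sum((labels == "left") & (preds == "right"))),
        "right_as_right": int(np.sum((labels == "right") & (preds == "right"))),
        "right_as_left": int(np.sum((labels == "right") & (preds == "left"))),
    }
    final = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    final.fit(X, labels)
    return LateralityModel(
        estimator=final, feature_names=cols, loo_accuracy=acc,
        loo_sensitivity=sens, loo_specificity=spec, confusion=confusion,
    )


def assign_bilateral(model: LateralityModel, table: pd.DataFrame) -> pd.Series:
    """Group assignment: unilateral subjects keep their label; bilateral
    subjects get the model's predicted side."""
    sides = table[GROUP_COL].copy()
    bilateral = sides == "bilateral"
    if bilateral.any():
        sides.loc[bilateral] = model.predict_side(table.loc[bilateral])
    return sides


def correlation_filter(
    table: pd.DataFrame, r_min: float = 0.3
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Keep features whose |Pearson r| with the outcome exceeds ``r_min``.

    Zero-variance features are excluded (undefined correlation) and
    logged with r = NaN.
    """
    if len(table) < 3:
        raise ValueError("correlation filter needs >= 3 subjects")
    y = table[OUTCOME_COL].to_numpy(dtype=float)
    y_c = y - y.mean()
    sy = np.sqrt((y_c**2).sum())
    cols = feature_columns(table)
    X = table[cols].to_numpy(dtype=float)
    X_c = X - X.mean(axis=0, keepdims=True)
    sx = np.sqrt((X_c**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_all = np.where((sx > 0) & (sy > 0), (X_c.T @ y_c) / (sx * sy), np.nan)
    corr = {c: float(r) for c, r in zip(cols, r_all)}
    kept = [c for c, r in zip(cols, r_all) if np.isfinite(r) and abs(r) > r_min]
    reserved = [c for c in (ID_COL, GROUP_COL, OUTCOME_COL) if c in table.columns]
    return table[reserved + kept], corr


def rank_importance(
    table: pd.DataFrame, seed: int = 0, n_estimators: int = 500
) -> FeatureRanking:
    """Tree-ensemble importance, normalized so the importances sum to 1.

    Ties in normalized importance break by feature name for determinism.
    """
    cols = feature_columns(table)
    if not cols:
        raise ValueError("no features to rank")
    X = table[cols].to_numpy(dtype=float)
    y = table[OUTCOME_COL].to_numpy(dtype=float)
    forest = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
    forest.fit(X, y)
    raw = forest.feature_importances_.astype(float)
    total = raw.sum()
    norm = raw / total if total > 0 else np.full_like(raw, 1.0 / len(raw))
    order = sorted(range(len(cols)), key=lambda i: (-norm[i], cols[i]))
    return FeatureRanking(
        features=[cols[i] for i in order],
        raw_importance=raw[order],
        normalized_importance=norm[order],
    )


def select_top_k(ranking: FeatureRanking, k: int = 20) -> list[str]:
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(ranking.features) < k:
        warnings.warn(
            f"only {len(ranking.features)} features available for top-{k} selection",
            RuntimeWarning, stacklevel=2,
        )
    return ranking.features[:k]


@dataclass
class SelectionSummary:
    band_counts: dict[str, int]
    band_importance: dict[str, float]
    lobe_counts: dict[str, int]
    lobe_importance: dict[str, float]
    k: int

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for axis, counts, imps in (
            ("band", self.band_counts, self.band_importance),
            ("lobe", self.lobe_counts, self.lobe_importance),
        ):
            total_imp = sum(imps.values())
            for key in counts:
                rows.append(
                    {
                        "axis": axis,
                        "category": key,
                        "count": counts[key],
                        "count_pct": 100.0 * counts[key] / self.k,
                        "importance": imps[key],
                        "importance_pct": (
                            100.0 * imps[key] / total_imp if total_imp > 0 else 0.0
                        ),
                    }
                )
        return pd.DataFrame(rows)


def summarize_selection(
    selected: list[str], ranking: FeatureRanking
) -> SelectionSummary:
    """Per-band and per-lobe counts and summed normalized importance of
    the selected features. Graph-global features (no ROI) count toward
    the 'global' lobe bucket; unmapped ROIs fall into 'others'."""
    imp = dict(zip(ranking.features, ranking.normalized_importance))
    band_counts: dict[str, int] = {}
    band_imp: dict[str, float] = {}
    lobe_counts: dict[str, int] = {}
    lobe_imp: dict[str, float] = {}
    for name in selected:
        try:
            info = parse_feature_name(name)
            band, lobe = info.band, (info.lobe or "global")
        except ValueError:
            warnings.warn(f"feature {name!r} unparseable; bucketed as others",
                          RuntimeWarning, stacklevel=2)
            band, lobe = "others", "others"
        w = float(imp.get(name, 0.0))
        band_counts[band] = band_counts.get(band, 0) + 1
        band_imp[band] = band_imp.get(band, 0.0) + w
        lobe_counts[lobe] = lobe_counts.get(lobe, 0) + 1
        lobe_imp[lobe] = lobe_imp.get(lobe, 0.0) + w
    return SelectionSummary(
        band_counts=band_counts, band_importance=band_imp,
        lobe_counts=lobe_counts, lobe_importance=lobe_imp, k=len(selected),
    )


def _loo_predict(X: np.ndarray, y: np.ndarray, model_name: str, seed: int) -> np.ndarray:
    n = len(y)
    y_hat = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        est = _make_regressor(model_name, seed)
        est.fit(X[mask], y[mask])
        y_hat[i] = est.predict(X[i : i + 1])[0]
    return y_hat


def fit_regressors_loo(
    table: pd.DataFrame,
    features: list[str],
    models: tuple[str, ...] = REGRESSOR_NAMES,
    seed: int = 0,
) -> dict[str, ModelEvaluation]:
    """Leave-one-out regression per model; one pooled R^2 per model."""
    if len(table) < 3:
        raise ValueError("LOO regression needs >= 3 subjects")
    for m in models:
        if m not in REGRESSOR_NAMES:
            raise ValueError(f"unknown model {m!r}; choose from {REGRESSOR_NAMES}")
    X = table[list(features)].to_numpy(dtype=float)
    y = table[OUTCOME_COL].to_numpy(dtype=float)
    out = {}
    for m in models:
        y_hat = _loo_predict(X, y, m, seed)
        out[m] = ModelEvaluation.from_predictions(m, y, y_hat, features)
    return out


def fit_loo_strict(
    table: pd.DataFrame,
    r_min: float = 0.3,
    k: int = 20,
    models: tuple[str, ...] = ("ridge",),
    seed: int = 0,
    n_estimators: int = 100,
) -> dict[str, ModelEvaluation]:
    """Strict LOO: the correlation filter, importance ranking and top-k
    selection are re-run inside every fold (no selection leakage)."""
    n = len(table)
    if n < 4:
        raise ValueError("strict LOO needs >= 4 subjects")
    y = table[OUTCOME_COL].to_numpy(dtype=float)
    preds = {m: np.empty(n) for m in models}
    for i in range(n):
        train = table.drop(table.index[i])
        filtered, _ = correlation_filter(train, r_min)
        cols = feature_columns(filtered)
        if not cols:  # fall back to the grand mean when nothing passes
            for m in models:
                preds[m][i] = train[OUTCOME_COL].mean()
            continue
        ranking = rank_importance(filtered, seed=seed, n_estimators=n_estimators)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            selected = select_top_k(ranking, min(k, len(ranking.features)))
        X_tr = train[selected].to_numpy(dtype=float)
        X_te = table.iloc[[i]][selected].to_numpy(dtype=float)
        for m in models:
            est = _make_regressor(m, seed)
            est.fit(X_tr, train[OUTCOME_COL].to_numpy(dtype=float))
            preds[m][i] = est.predict(X_te)[0]
    return {
        m: ModelEvaluation.from_predictions(m, y, preds[m]) for m in models
    }


def count_composite_subsets(
    top_pool: int, bottom_pool: int, top_take: range, max_total: int
) -> int:
    total = 0
    for t in top_take:
        if t > top_pool:
            continue
        for b in range(0, min(bottom_pool, max_total - t) + 1):
            total += comb(top_pool, t) * comb(bottom_pool, b)
    return total


def composite_search(
    ranking: FeatureRanking,
    table: pd.DataFrame,
    top_pool: int = 5,
    bottom_pool: int = 15,
    top_take: range = range(3, 6),
    max_total: int = 10,
    max_models: int = 9000,
    model: str = "ridge",
    seed: int = 0,
) -> list[ModelEvaluation]:
    """Sensitivity search over composite feature subsets: take 3-5 of the
    top pool plus a complement from the bottom pool, total capped. If the
    subset count exceeds ``max_models``, a seeded subsample is evaluated.
    Returns evaluations sorted by LOO R^2, descending."""
    feats = ranking.features
    if len(feats) < top_pool + bottom_pool:
        raise ValueError(
            f"ranking has {len(feats)} features; need >= {top_pool + bottom_pool}"
        )
    top = feats[:top_pool]
    bottom = feats[top_pool : top_pool + bottom_pool]
    subsets: list[tuple[str, ...]] = []
    for t in top_take:
        if t > top_pool:
            continue
        for chosen_top in combinations(top, t):
            for b in range(0, min(bottom_pool, max_total - t) + 1):
                for chosen_bot in combinations(bottom, b):
                    subsets.append(chosen_top + chosen_bot)
    if not subsets:
        raise ValueError("composite-search constraints admit zero subsets")
    if len(subsets) > max_models:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(subsets), size=max_models, replace=False)
        subsets = [subsets[i] for i in sorted(idx)]
    evals = []
    for sub in subsets:
        ev = fit_regressors_loo(table, list(sub), models=(model,), seed=seed)[model]
        evals.append(ev)
    evals.sort(key=lambda e: -e.r2)
    return evals
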