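"""Balanced-draw ensemble classifier with F-max score thresholding.

Class imbalance (SM genes are a ~0.19 minority) is neutralized by training
one base learner per *balanced draw*: an equal-size random subsample of each
class drawn from the training set.  The ensemble's SM score for a gene is
the arithmetic mean, over base learners, of the learner's SM-class
probability.  A gene is called SM when its score reaches the threshold tau
that maximizes the F-measure on training genes.

Hyperparameters are chosen by an exhaustive grid search with stratified
k-fold cross-validation on a balanced draw; fold scoring uses the learner's
native argmax call (the F-max threshold is applied only to the final
ensemble's SM scores — thresholding inside CV folds would make even a
no-skill model look better than chance on balanced folds, because the
predict-everything-SM call has F = 2/3 there).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.svm import SVC

SM, GM = "SM", "GM"

DEFAULT_GRID: dict[str, list] = {
    # documented default search space; single point => no search
    "n_estimators": [100],
    "max_depth": [None],
    "max_features": ["sqrt"],
}

FULL_GRID: dict[str, list] = {
    "n_estimators": [100, 500],
    "max_depth": [None, 5, 10],
    "max_features": ["sqrt", 0.25, 0.5],
}

SVM_GRID: dict[str, list] = {
    "kernel": ["rbf", "linear"],
    "C": [0.1, 1.0, 10.0],
    "gamma": ["scale"],
}


@dataclass
class SplitSpec:
    """Stratified train/test split of annotated SM/GM genes."""

    train: pd.Index
    test: pd.Index
    test_fraction: float
    seed: int


@dataclass
class BalancedDraw:
    """One equal-size subsample of each class from the training set."""

    index: int
    sm: pd.Index
    gm: pd.Index

    @property
    def genes(self) -> pd.Index:
        return self.sm.append(self.gm)


@dataclass
class EnsembleModel:
    """Fitted balanced-draw ensemble.

    One base learner per draw, a frozen feature order, the SM-score
    threshold tau learned on training data, and signed feature importances.
    """

    algorithm: str
    hyperparameters: dict
    learners: list
    draws: list[BalancedDraw]
    feature_names: list[str]
    threshold: float | None = None
    threshold_f: float | None = None
    importances: pd.Series | None = None
    seed: int = 0
    n_folds: int | None = None
    trained_on_harmonized: bool = False
    sm_index: list[int] = field(default_factory=list)


def split_train_test(
    labels: pd.Series, test_fraction: float = 0.1, seed: int = 0
) -> SplitSpec:
    """Withhold a stratified test fraction of the annotated SM/GM genes.

    DF and unannotated genes are excluded from both sides.  Per class,
    round(fraction * class size) genes go to the test set; the split is
    deterministic given the seed.
    """
    ann = labels[labels.isin([SM, GM])]
    rng = np.random.default_rng(seed)
    test_parts, train_parts = [], []
    for cls in (SM, GM):
        members = ann.index[ann == cls].to_numpy()
        if len(members) < 10 and test_fraction > 0:
            raise ValueError(f"class {cls} has only {len(members)} genes; need >= 10 to split")
        n_test = int(round(test_fraction * len(members)))
        perm = rng.permutation(members)
        test_parts.append(perm[:n_test])
        train_parts.append(perm[n_test:])
    return SplitSpec(
        train=pd.Index(np.concatenate(train_parts)),
        test=pd.Index(np.concatenate(test_parts)),
        test_fraction=test_fraction,
        seed=seed,
    )


def make_balanced_draws(
    split: SplitSpec,
    labels: pd.Series,
    n_draws: int = 100,
    per_class: int = 500,
    seed: int = 0,
) -> list[BalancedDraw]:
    """Create n equal-size per-class subsamples of the training set.

    Each draw samples ``per_class`` genes per class without replacement,
    capped at the minority-class training size.  Draws are independent (and
    virtually always distinct in composition); sampling is deterministic
    given the seed.
    """
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    train_labels = labels.loc[split.train]
    sm = train_labels.index[train_labels == SM].to_numpy()
    gm = train_labels.index[train_labels == GM].to_numpy()
    if len(sm) == 0 or len(gm) == 0:
        raise ValueError("training set must contain both classes")
    size = min(per_class, len(sm), len(gm))
    rng = np.random.default_rng(seed)
    draws = []
    for i in range(n_draws):
        draws.append(
            BalancedDraw(
                index=i,
                sm=pd.Index(rng.choice(sm, size=size, replace=False)),
                gm=pd.Index(rng.choice(gm, size=size, replace=False)),
            )
        )
    return draws


def _base_learner(algorithm: str, hyperparameters: dict, seed: int):
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, **hyperparameters)
    if algorithm == "svm":
        # margin scores are not probabilities; calibrate with a
        # cross-validated sigmoid fit
        svc = SVC(random_state=seed, **hyperparameters)
        return CalibratedClassifierCV(svc, method="sigmoid", cv=3)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _xy(features: pd.DataFrame, labels: pd.Series, genes: pd.Index):
    x = features.loc[genes].to_numpy(float)
    y = (labels.loc[genes] == SM).to_numpy(int)
    return x, y


def precision_recall_f(calls: pd.Series | np.ndarray, truth: pd.Series | np.ndarray) -> dict:
    """Precision, recall and F-measure with SM as the positive class.

    F is the harmonic mean of precision (proportion of SM calls that are
    correct) and recall (proportion of true SM genes called SM); F = 0 when
    precision + recall = 0.  Also reports a class-balanced F in which
    precision is recomputed from the true/false positive *rates* — the F a
    model would attain on an evaluation set with equal class sizes.
    """
    calls = np.asarray(calls)
    truth = np.asarray(truth)
    if calls.shape != truth.shape:
        raise ValueError(f"length mismatch: {calls.shape} vs {truth.shape}")
    tp = int(np.sum((calls == SM) & (truth == SM)))
    fp = int(np.sum((calls == SM) & (truth != SM)))
    fn = int(np.sum((calls != SM) & (truth == SM)))
    tn = int(np.sum((calls != SM) & (truth != SM)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    tpr = recall
    fpr = fp / (fp + tn) if fp + tn else 0.0
    bal_precision = tpr / (tpr + fpr) if tpr + fpr else 0.0
    f_bal = (
        2 * bal_precision * tpr / (bal_precision + tpr) if bal_precision + tpr else 0.0
    )
    return {
        "precision": precision,
        "recall": recall,
        "f_measure": f,
        "f_balanced": f_bal,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
    }


def _f_measure_curve(scores: np.ndarray, is_sm: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """F-measure of the rule (score >= tau -> SM) for each candidate tau."""
    order = np.argsort(scores, kind="stable")
    s = scores[order]
    y = is_sm[order]
    n_sm = int(y.sum())
    # genes with score >= tau: suffix counts
    cum_sm = np.concatenate([[0], np.cumsum(y)])
    pos = np.searchsorted(s, candidates, side="left")
    n_called = len(s) - pos
    tp = n_sm - cum_sm[pos]
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(n_called > 0, tp / np.maximum(n_called, 1), 0.0)
        recall = tp / n_sm if n_sm else np.zeros_like(tp, dtype=float)
        f = np.where(precision + recall > 0, 2 * precision * recall / np.maximum(precision + recall, 1e-300), 0.0)
    return f


def select_threshold(scores: pd.Series, labels: pd.Series) -> tuple[float, float]:
    """Choose the SM-score threshold maximizing the F-measure.

    Candidates are the midpoints of adjacent sorted unique scores plus 0
    (call everything SM) and 1 + eps (call nothing SM); ties break toward
    the smallest tau.  Returns (tau, F at tau).
    """
    common = scores.index.intersection(labels.index)
    s = scores.loc[common].to_numpy(float)
    y = (labels.loc[common] == SM).to_numpy()
    if y.all() or not y.any():
        raise ValueError("threshold selection needs both classes present")
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.array([])
    candidates = np.concatenate([[0.0], mids, [1.0 + 1e-9]])
    f = _f_measure_curve(s, y.astype(int), candidates)
    best = int(np.argmax(f))  # argmax returns the first (smallest tau) maximizer
    return float(candidates[best]), float(f[best])


def grid_search_cv(
    features: pd.DataFrame,
    labels: pd.Series,
    draw: BalancedDraw,
    grid: dict[str, list] | list[dict] | None = None,
    algorithm: str = "random_forest",
    folds: int = 10,
    seed: int = 0,
) -> tuple[dict, float]:
    """Exhaustive grid search with stratified k-fold CV on one balanced draw.

    Every grid point is scored by the mean F-measure over folds (learner's
    argmax call, see module docstring); the argmax grid point is returned,
    ties resolved toward the earlier point in documented grid order.
    """
    if grid is None:
        grid = DEFAULT_GRID if algorithm == "random_forest" else SVM_GRID
    points = list(grid) if isinstance(grid, list) else list(ParameterGrid([grid]))
    if not points:
        raise ValueError("empty hyperparameter grid")
    x, y = _xy(features, labels, draw.genes)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best_params, best_f = None, -1.0
    for params in points:
        fold_f = []
        for k, (tr, va) in enumerate(skf.split(x, y)):
            learner = _base_learner(algorithm, params, seed=seed + k)
            learner.fit(x[tr], y[tr])
            pred = learner.predict(x[va])
            calls = np.where(pred == 1, SM, GM)
            truth = np.where(y[va] == 1, SM, GM)
            fold_f.append(precision_recall_f(calls, truth)["f_measure"])
        mean_f = float(np.mean(fold_f))
        if mean_f > best_f:
            best_params, best_f = copy.deepcopy(params), mean_f
    return best_params, best_f


def fit_ensemble(
    features: pd.DataFrame,
    labels: pd.Series,
    draws: list[BalancedDraw],
    hyperparameters: dict | None = None,
    algorithm: str = "random_forest",
    seed: int = 0,
) -> EnsembleModel:
    """Fit one base learner per balanced draw with the chosen hyperparameters.

    The model freezes the feature column order at fit time; refitting with
    the same seed reproduces identical SM scores.
    """
    if hyperparameters is None:
        hyperparameters = {k: v[0] for k, v in DEFAULT_GRID.items()}
    missing = labels.reindex(pd.Index(np.concatenate([d.genes for d in draws]))).isna()
    if missing.any():
        raise ValueError("draw genes missing labels")
    learners = []
    sm_index = []
    for draw in draws:
        x, y = _xy(features, labels, draw.genes)
        learner = _base_learner(algorithm, hyperparameters, seed=seed + draw.index)
        learner.fit(x, y)
        learners.append(learner)
        sm_index.append(int(np.where(learner.classes_ == 1)[0][0]))
    return EnsembleModel(
        algorithm=algorithm,
        hyperparameters=dict(hyperparameters),
        learners=learners,
        draws=list(draws),
        feature_names=list(features.columns),
        seed=seed,
        trained_on_harmonized=bool(features.attrs.get("harmonized", False)),
        sm_index=sm_index,
    )


def sm_score(
    model: EnsembleModel, features: pd.DataFrame, mode: str = "all"
) -> pd.DataFrame:
    """SM score per gene: mean SM-class probability across base learners.

    ``mode="all"`` averages every learner.  ``mode="out_of_draw"`` averages,
    for each gene, only the learners whose training draw did not contain it
    (an out-of-bag-style score for training genes; genes present in every
    draw fall back to the all-learner mean).  When the model carries a
    threshold, a thresholded SM/GM call is included (call = SM iff
    score >= tau).
    """
    missing = [f for f in model.feature_names if f not in features.columns]
    if missing:
        raise KeyError(f"missing feature columns: {missing}")
    x = features[model.feature_names].to_numpy(float)
    probs = np.column_stack(
        [learner.predict_proba(x)[:, j] for learner, j in zip(model.learners, model.sm_index)]
    )
    if mode == "all":
        scores = probs.mean(axis=1)
    elif mode == "out_of_draw":
        in_draw = np.zeros((len(features), len(model.draws)), dtype=bool)
        for k, draw in enumerate(model.draws):
            pos = features.index.get_indexer(draw.genes.intersection(features.index))
            in_draw[pos[pos >= 0], k] = True
        weights = (~in_draw).astype(float)
        rows_all_in = weights.sum(axis=1) == 0
        weights[rows_all_in] = 1.0
        scores = (probs * weights).sum(axis=1) / weights.sum(axis=1)
    else:
        raise ValueError(f"unknown scoring mode {mode!r}")
    out = pd.DataFrame({"sm_score": scores}, index=features.index)
    out.index.name = "gene_id"
    if model.threshold is not None:
        out["call"] = np.where(out["sm_score"] >= model.threshold, SM, GM)
    return out


def signed_importance(
    model: EnsembleModel, features: pd.DataFrame, labels: pd.Series
) -> pd.Series:
    """Signed, normalized feature importances.

    Magnitude: mean impurity-decrease importance across the forest base
    learners.  Sign: positive when the feature's mean value among SM
    training genes exceeds its mean among GM genes, negative otherwise.
    Magnitudes are rescaled so the top feature has |importance| = 1.
    """
    if model.algorithm != "random_forest":
        raise NotImplementedError("impurity importances are defined for random forests only")
    if not model.learners:
        raise ValueError("model has no fitted learners")
    mags = np.mean([lr.feature_importances_ for lr in model.learners], axis=0)
    ann = labels[labels.isin([SM, GM])]
    common = ann.index.intersection(features.index)
    sub = features.loc[common, model.feature_names]
    ann = ann.loc[common]
    diff = sub[ann == SM].mean(axis=0) - sub[ann == GM].mean(axis=0)
    sign = np.where(diff.to_numpy() >= 0, 1.0, -1.0)
    top = mags.max()
    scaled = mags / top if top > 0 else mags
    out = pd.Series(scaled * sign, index=model.feature_names, name="importance")
    return out


def cross_fit_scores(
    features: pd.DataFrame,
    labels: pd.Series,
    train_genes: pd.Index,
    hyperparameters: dict | None,
    algorithm: str = "random_forest",
    n_draws: int = 5,
    per_class: int = 500,
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Honest SM scores for training genes via cross-fitting.

    The training set is split into stratified folds; each fold is scored by
    a small balanced-draw ensemble fitted on the remaining folds only.  This
    matters for threshold selection: when the per-class draw size equals the
    minority-class size, every minority gene sits in every draw, so its
    out-of-draw score degenerates to an in-bag (memorized) probability and a
    threshold chosen on such scores drifts far above the score range the
    model produces on unseen genes.
    """
    train_genes = pd.Index(train_genes)
    y = (labels.loc[train_genes] == SM).to_numpy(int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = pd.Series(np.nan, index=train_genes)
    for k, (tr, va) in enumerate(skf.split(np.zeros(len(train_genes)), y)):
        fit_genes = train_genes[tr]
        split = SplitSpec(train=fit_genes, test=pd.Index([]), test_fraction=0.0, seed=seed)
        draws = make_balanced_draws(
            split, labels, n_draws=n_draws, per_class=per_class, seed=seed + 7919 * (k + 1)
        )
        sub = fit_ensemble(
            features, labels, draws, hyperparameters, algorithm=algorithm, seed=seed + k
        )
        scores.iloc[va] = sm_score(sub, features.loc[train_genes[va]])["sm_score"].to_numpy()
    out = pd.DataFrame({"sm_score": scores})
    out.index.name = "gene_id"
    return out


def train_model(
    features: pd.DataFrame,
    labels: pd.Series,
    train_genes: pd.Index,
    n_draws: int = 100,
    per_class: int = 500,
    algorithm: str = "random_forest",
    grid: dict[str, list] | list[dict] | None = None,
    folds: int = 10,
    seed: int = 0,
    do_grid_search: bool = False,
    score_mode: str = "out_of_draw",
    threshold_mode: str = "cv",
) -> tuple[EnsembleModel, pd.DataFrame]:
    """Convenience wrapper: draws -> (optional grid search) -> fit ->
    threshold on training genes.

    Returns the fitted model (with tau frozen from training data) and the
    training-gene score table (out-of-draw scores by default).  The
    threshold is selected on cross-fitted training scores
    (``threshold_mode="cv"``, see :func:`cross_fit_scores`); the
    alternatives ``"out_of_draw"`` and ``"all"`` (in-bag) select tau
    directly on the returned training-score table.
    """
    split = SplitSpec(train=pd.Index(train_genes), test=pd.Index([]), test_fraction=0.0, seed=seed)
    draws = make_balanced_draws(split, labels, n_draws=n_draws, per_class=per_class, seed=seed)
    if do_grid_search:
        params, _ = grid_search_cv(
            features, labels, draws[0], grid=grid, algorithm=algorithm, folds=folds, seed=seed
        )
    elif grid is not None:
        points = list(grid) if isinstance(grid, list) else list(ParameterGrid([grid]))
        params = points[0]
    else:
        params = None
    model = fit_ensemble(features, labels, draws, params, algorithm=algorithm, seed=seed)
    model.n_folds = folds
    train_scores = sm_score(model, features.loc[split.train], mode=score_mode)
    if threshold_mode == "cv":
        thr_scores = cross_fit_scores(
            features, labels, split.train, params, algorithm=algorithm,
            per_class=per_class, seed=seed,
        )["sm_score"]
    elif threshold_mode in ("out_of_draw", "all"):
        thr_scores = sm_score(model, features.loc[split.train], mode=threshold_mode)["sm_score"]
    else:
        raise ValueError(f"unknown threshold mode {threshold_mode!r}")
    tau, f_at_tau = select_threshold(thr_scores, labels.loc[split.train])
    model.threshold = tau
    model.threshold_f = f_at_tau
    train_scores["call"] = np.where(train_scores["sm_score"] >= tau, SM, GM)
    model.importances = (
        signed_importance(model, features, labels.loc[split.train])
        if algorithm == "random_forest"
        else None
    )
    return model, train_scores
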