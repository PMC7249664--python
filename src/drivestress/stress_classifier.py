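"""RBF-SVM stress classification with leave-one-subject-out evaluation.

Training balances the two classes by subsampling the majority class, scales
the five block features to [0, 1] on the training range, and selects the SVM
cost and kernel width by a seeded cross-validated search.  Evaluation uses
leave-one-subject-out (LOSO) folds: the scaler and the model for a fold see
only the remaining subjects' blocks, so no information from the held-out
subject leaks into training.

Predicted block sequences are post-processed by a relabeling step that
clears isolated positives: a short run of "stress" blocks surrounded by
"no-stress" neighbors is treated as a spurious detection and flipped to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .blocks_features import FEATURE_NAMES, apply_feature_scaler, fit_feature_scaler

__all__ = [
    "SearchSpec",
    "TrainedStressModel",
    "train_svm",
    "predict_blocks",
    "relabel_isolated",
    "predict_timeline",
    "loso_evaluate",
]


@dataclass(frozen=True)
class SearchSpec:
    """Seeded hyperparameter search: log-grid over cost and RBF width with
    internal stratified cross-validation."""

    costs: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gammas: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    cv_folds: int = 5
    seed: int = 0


@dataclass
class TrainedStressModel:
    svc: SVC
    scaler: tuple[np.ndarray, np.ndarray]
    cost: float
    gamma: float
    n_per_class: dict[int, int]
    seed: int


def _balance(X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Subsample the majority class to the minority count."""
    idx0, idx1 = np.flatnonzero(y == 0), np.flatnonzero(y == 1)
    m = min(idx0.size, idx1.size)
    keep = np.sort(np.concatenate([rng.choice(idx0, m, replace=False), rng.choice(idx1, m, replace=False)]))
    return X[keep], y[keep]


def train_svm(rows: pd.DataFrame, search: SearchSpec | None = None) -> TrainedStressModel:
    """Fit the RBF-SVM on a block-feature table.

    The feature scaler is fit on all training rows; the class balance is then
    restored by subsampling before the seeded grid search.  Deterministic for
    a fixed seed.
    """
    search = search if search is not None else SearchSpec()
    y = rows["truth_label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    X_raw = rows[FEATURE_NAMES].to_numpy(dtype=float)
    scaler = fit_feature_scaler(X_raw)
    X = apply_feature_scaler(X_raw, scaler)
    rng = np.random.default_rng(search.seed)
    Xb, yb = _balance(X, y, rng)
    cv = StratifiedKFold(n_splits=search.cv_folds, shuffle=True, random_state=search.seed)
    gs = GridSearchCV(
        SVC(kernel="rbf"),
        {"C": list(search.costs), "gamma": list(search.gammas)},
        cv=cv,
        n_jobs=1,
    )
    gs.fit(Xb, yb)
    svc = gs.best_estimator_
    return TrainedStressModel(
        svc=svc,
        scaler=scaler,
        cost=float(svc.C),
        gamma=float(svc.gamma),
        n_per_class={0: int(np.sum(yb == 0)), 1: int(np.sum(yb == 1))},
        seed=search.seed,
    )


def predict_blocks(model: TrainedStressModel, rows: pd.DataFrame) -> np.ndarray:
    """Raw per-block predictions (before relabeling)."""
    X = apply_feature_scaler(rows[FEATURE_NAMES].to_numpy(dtype=float), model.scaler)
    return model.svc.predict(X).astype(int)


def relabel_isolated(labels: np.ndarray, max_run: int = 1) -> np.ndarray:
    """Clear isolated positive runs.

    A run of consecutive 1s of length at most ``max_run``, whose neighbors in
    the *original* sequence are 0 (or the sequence boundary), is flipped to
    0.  Never flips a 0 to 1, and is idempotent.
    """
    x = np.asarray(labels, dtype=int).copy()
    n = x.size
    i = 0
    while i < n:
        if x[i] == 1:
            j = i
            while j + 1 < n and x[j + 1] == 1:
                j += 1
            if j - i + 1 <= max_run:
                x[i : j + 1] = 0
            i = j + 1
        else:
            i += 1
    return x


def predict_timeline(model: TrainedStressModel, rows: pd.DataFrame, max_run: int = 1) -> pd.DataFrame:
    """Per-block predictions with relabeling and confusion flags.

    Relabeling is applied within each (subject, scenario) sequence ordered by
    block start time.  The returned table adds ``predicted_label``,
    ``relabeled_label`` and a ``flag`` column in {TP, FP, TN, FN} comparing
    the relabeled prediction with the truth label.
    """
    out = rows.copy()
    out["predicted_label"] = predict_blocks(model, rows)
    out["relabeled_label"] = out["predicted_label"]
    for _, idx in out.groupby(["subject_id", "scenario"], sort=False).groups.items():
        seq = out.loc[idx].sort_values("t_start_s")
        out.loc[seq.index, "relabeled_label"] = relabel_isolated(
            seq["predicted_label"].to_numpy(), max_run=max_run
        )
    truth = out["truth_label"].to_numpy(dtype=int)
    pred = out["relabeled_label"].to_numpy(dtype=int)
    flags = np.where(pred == 1, np.where(truth == 1, "TP", "FP"), np.where(truth == 0, "TN", "FN"))
    out["flag"] = flags
    return out


def loso_evaluate(
    rows: pd.DataFrame, search: SearchSpec | None = None, max_run: int = 1
) -> tuple[dict[str, float], float, pd.DataFrame]:
    """Leave-one-subject-out evaluation.

    For each subject, the scaler and model are fit on all other subjects'
    blocks and applied to the held-out subject; accuracy is the fraction of
    held-out blocks whose post-relabel prediction matches the truth label.
    Returns per-subject accuracies, their mean, and the concatenated
    prediction timeline.
    """
    subjects = list(dict.fromkeys(rows["subject_id"]))
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    per_subject: dict[str, float] = {}
    timelines = []
    for subj in subjects:
        held = rows[rows["subject_id"] == subj]
        if held.empty:
            raise ValueError(f"subject {subj!r} has no blocks")
        train_rows = rows[rows["subject_id"] != subj]
        model = train_svm(train_rows, search)
        tl = predict_timeline(model, held, max_run=max_run)
        per_subject[subj] = float((tl["relabeled_label"] == tl["truth_label"]).mean())
        timelines.append(tl)
    mean_acc = float(np.mean(list(per_subject.values())))
    return per_subject, mean_acc, pd.concat(timelines, ignore_index=True)
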