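"""Repeated-holdout harness for microbiome-marker association strength.

The harness quantifies how strongly a target variable is associated with
the microbiome by training an injected learner on arcsine square-root
transformed relative abundances over many stratified 80:20 train/test
splits and summarizing per-repeat AUC (classification) or Spearman
correlation between truth and prediction (regression).

Continuous targets are binarized by quartile contrasts (first vs fourth
quartile, first three vs fourth, first vs last three).  Twin pairs (or
any grouping) are kept on the same side of every split so that
near-identical profiles cannot leak between train and test.

The learner is deliberately injected: the harness's identity is the
evaluation protocol, not the model.  ``default_model_factory`` provides
the documented reference configuration (1000-tree random forest with
sqrt-features).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .errors import ValidationError
from .profiles import AbundanceTable, arcsin_sqrt

__all__ = [
    "EvalResult",
    "quartile_labels",
    "repeated_holdout_eval",
    "default_model_factory",
]

CONTRASTS = ("1v4", "123v4", "1v234", "none")


@dataclass
class EvalResult:
    target: str
    task: str
    contrast: str
    values: np.ndarray
    mean: float
    sd: float
    n_repeats: int


def default_model_factory(task: str, seed: int = 0):
    """Reference learner: 1000-tree random forest, sqrt max-features."""
    from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

    if task == "classification":
        return RandomForestClassifier(
            n_estimators=1000, max_features="sqrt", random_state=seed, n_jobs=1
        )
    return RandomForestRegressor(
        n_estimators=1000, max_features="sqrt", random_state=seed, n_jobs=1
    )


def quartile_labels(y, contrast: str) -> tuple[np.ndarray, np.ndarray]:
    """Binary labels from quartile membership of a continuous target.

    Quartiles are assigned by average-tie fractional rank with stable
    index order breaking boundary ties.  ``1v4`` keeps only the first and
    fourth quartiles (middle half excluded); ``123v4`` and ``1v234`` use
    every sample.  Label 1 is always the "high" side.

    Returns
    -------
    (labels, included) : labels in {0, 1} (undefined where excluded) and
    a boolean inclusion mask.
    """
    if contrast not in CONTRASTS or contrast == "none":
        raise ValidationError(f"unknown contrast: {contrast!r}")
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    if keep.sum() < 8:
        raise ValidationError("need at least 8 non-missing values")
    if np.ptp(y[keep]) == 0:
        raise ValidationError("degenerate target: all values equal")
    idx = np.flatnonzero(keep)
    frac = stats.rankdata(y[idx], method="average")
    order = np.lexsort((idx, frac))  # fractional rank, then stable index
    n = len(idx)
    quart = np.empty(n, dtype=int)
    pos_pct = (np.arange(n) + 1) / n
    quart[order] = np.minimum(3, np.searchsorted([0.25, 0.5, 0.75], pos_pct, "left"))
    labels = np.zeros(len(y), dtype=int)
    included = np.zeros(len(y), dtype=bool)
    q = np.full(len(y), -1, dtype=int)
    q[idx] = quart
    if contrast == "1v4":
        included = (q == 0) | (q == 3)
        labels[q == 3] = 1
    elif contrast == "123v4":
        included = q >= 0
        labels[q == 3] = 1
    else:  # 1v234
        included = q >= 0
        labels[q >= 1] = 1
    return labels, included


def _canonical_class_blocks(labels: np.ndarray) -> list[np.ndarray]:
    """Index blocks per class, ordered by each block's smallest index.

    The ordering depends only on the *partition* of indices, not on the
    label values, so flipping 0/1 labels yields byte-identical splits —
    which makes per-repeat AUC exactly antisymmetric under label flips.
    """
    blocks = [np.flatnonzero(labels == c) for c in np.unique(labels)]
    return sorted(blocks, key=lambda b: int(b[0]))


def _stratified_split(
    labels: np.ndarray, test_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train, test = [], []
    for block in _canonical_class_blocks(labels):
        perm = block[rng.permutation(len(block))]
        n_test = max(1, int(round(test_frac * len(block))))
        test.append(perm[:n_test])
        train.append(perm[n_test:])
    return np.concatenate(train), np.concatenate(test)


def _group_units(groups) -> list[np.ndarray]:
    g = np.asarray(groups)
    units: dict = {}
    for i, key in enumerate(g):
        units.setdefault(key, []).append(i)
    return [np.array(v) for v in units.values()]


def repeated_holdout_eval(
    X,
    y,
    task: str,
    model_factory,
    n_repeats: int = 100,
    test_frac: float = 0.2,
    groups=None,
    seed: int = 0,
    target: str = "target",
    contrast: str = "none",
    transform: bool = True,
) -> EvalResult:
    """Stratified repeated 80:20 holdout evaluation.

    Parameters
    ----------
    X : AbundanceTable or array
        Features; an AbundanceTable (or raw fractions with ``transform``
        on) is arcsine square-root transformed.
    y : labels (classification) or continuous values (regression).
    model_factory : callable ``(task, seed) -> estimator`` with
        fit/predict_proba (classification) or fit/predict (regression).
    groups : optional per-sample grouping (e.g. twin pair ids); members
        of one group always land on the same side of a split.

    Classification splits are stratified to preserve the class ratio; a
    repeat whose training fold misses a class is redrawn (at most 10
    times, then it errors).  All randomness derives from ``seed``.
    """
    if task not in {"classification", "regression"}:
        raise ValidationError(f"unknown task: {task!r}")
    if isinstance(X, AbundanceTable):
        X = X.data.to_numpy()
        X = arcsin_sqrt(X)
    else:
        X = np.asarray(X, dtype=float)
        if transform:
            X = arcsin_sqrt(X)
    y = np.asarray(y)
    n = len(y)
    if X.shape[0] != n:
        raise ValidationError("X and y lengths differ")

    if groups is not None:
        units = _group_units(groups)
    else:
        units = [np.array([i]) for i in range(n)]
    if task == "classification":
        yf = y.astype(float)
        unit_labels = np.array([int(round(yf[u].mean())) for u in units])
    else:
        unit_labels = np.zeros(len(units), dtype=int)

    values = np.empty(n_repeats)
    for rep in range(n_repeats):
        for attempt in range(10):
            rng = np.random.default_rng([seed, rep, attempt])
            tr_units, te_units = _stratified_split(unit_labels, test_frac, rng)
            train = np.concatenate([units[i] for i in tr_units])
            test = np.concatenate([units[i] for i in te_units])
            if task == "classification" and len(np.unique(y[train])) < 2:
                continue
            break
        else:
            raise ValidationError("class missing from training fold after 10 redraws")
        model = model_factory(task, int(np.random.default_rng([seed, rep]).integers(2**31)))
        model.fit(X[train], y[train])
        if task == "classification":
            if hasattr(model, "predict_proba"):
                classes = list(model.classes_)
                score = model.predict_proba(X[test])[:, classes.index(max(classes))]
            else:
                score = model.decision_function(X[test])
            values[rep] = roc_auc_score(y[test], score)
        else:
            pred = model.predict(X[test])
            values[rep] = stats.spearmanr(y[test], pred).statistic
    return EvalResult(
        target=target,
        task=task,
        contrast=contrast,
        values=values,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if n_repeats > 1 else 0.0,
        n_repeats=n_repeats,
    )
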