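"""Repeated cross-validation and the model-quality gate.

A context (environmental factor) only yields a fingerprint when a random
forest can actually predict it from the attribute table. The harness
composes the two stated protocols: per repeat, the data are split 50/50
into train and test halves; 10-fold cross-validation runs inside the
training half (per-fold scores are reported), and the gate statistics —
root-mean-square error and variance explained — come from the held-out
half. The response is standardized to unit variance before scoring so one
RMSE threshold is comparable across factors with different units; the
gate passes when RMSE < 0.8 or variance explained >= 60% ("and/or" read
as OR, with AND available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import KFold

from .io import AttributeTable, EnvTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GatePolicy:
    """Thresholds deciding whether a context's model is usable."""

    max_rmse: float = 0.8
    min_variance_explained: float = 0.60
    combination: str = "OR"

    def __post_init__(self) -> None:
        if self.max_rmse <= 0 or self.min_variance_explained <= 0:
            raise ValueError("gate thresholds must be positive")
        if self.combination not in ("AND", "OR"):
            raise ValueError("combination must be 'AND' or 'OR'")


@dataclass
class CvResult:
    """Scores from repeated 50/50 splits with 10-fold CV inside training."""

    context: str
    rmse: float
    variance_explained: float
    folds: int
    repeats: int
    train_fraction: float
    per_fold: list[dict] = field(default_factory=list)
    per_repeat: list[dict] = field(default_factory=list)
    standardized_response: bool = True

    def to_dict(self) -> dict:
        return {
            "context": self.context,
            "rmse": self.rmse,
            "variance_explained": self.variance_explained,
            "folds": self.folds,
            "repeats": self.repeats,
            "train_fraction": self.train_fraction,
            "standardized_response": self.standardized_response,
            "per_fold": self.per_fold,
            "per_repeat": self.per_repeat,
        }


def cross_validate(
    table: AttributeTable,
    env: EnvTable,
    context: str,
    seed: int = 0,
    folds: int = 10,
    repeats: int = 5,
    train_fraction: float = 0.5,
    n_trees: int = 100,
) -> CvResult:
    """Repeated 50/50 evaluation of a forest predicting ``context``.

    ``per_fold`` holds folds x repeats entries (the within-training CV);
    ``rmse`` and ``variance_explained`` are means over the held-out
    halves. The response is z-scored before scoring.
    """
    y_all = env.factor(context).dropna()
    shared = [s for s in table.sample_ids if s in y_all.index]
    if len(shared) < 20:
        raise ValueError(
            f"context {context!r}: need >= 20 usable samples, have {len(shared)}"
        )
    y = y_all.loc[shared].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError(f"context {context!r}: response has zero variance")
    y = (y - y.mean()) / y.std()
    X = table.counts.loc[shared].to_numpy(dtype=float)
    n = len(y)
    n_train = int(round(train_fraction * n))

    rng = np.random.default_rng(seed)
    per_fold: list[dict] = []
    per_repeat: list[dict] = []
    for repeat in range(repeats):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        kf = KFold(n_splits=folds, shuffle=True,
                   random_state=int(rng.integers(2**31 - 1)))
        for fold, (fit_idx, val_idx) in enumerate(kf.split(train)):
            model = _forest(n_trees, int(rng.integers(2**31 - 1)))
            model.fit(X[train[fit_idx]], y[train[fit_idx]])
            pred = model.predict(X[train[val_idx]])
            per_fold.append({
                "repeat": repeat,
                "fold": fold,
                "rmse": float(np.sqrt(mean_squared_error(y[train[val_idx]], pred))),
                "variance_explained": float(r2_score(y[train[val_idx]], pred))
                if len(val_idx) > 1 else float("nan"),
            })
        model = _forest(n_trees, int(rng.integers(2**31 - 1)))
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        per_repeat.append({
            "repeat": repeat,
            "rmse": float(np.sqrt(mean_squared_error(y[test], pred))),
            "variance_explained": float(r2_score(y[test], pred)),
        })
    return CvResult(
        context=context,
        rmse=float(np.mean([r["rmse"] for r in per_repeat])),
        variance_explained=float(
            np.mean([r["variance_explained"] for r in per_repeat])
        ),
        folds=folds,
        repeats=repeats,
        train_fraction=train_fraction,
        per_fold=per_fold,
        per_repeat=per_repeat,
    )


def _forest(n_trees: int, seed: int) -> RandomForestRegressor:
    # max_features=1/3 is the long-standing regression-forest convention
    return RandomForestRegressor(
        n_estimators=n_trees, random_state=seed, n_jobs=1, max_features=1 / 3
    )


def passes_gate(result: CvResult, policy: GatePolicy | None = None) -> bool:
    """True when the context's model clears the quality gate."""
    policy = policy or GatePolicy()
    rmse_ok = result.rmse < policy.max_rmse
    varexpl_ok = result.variance_explained >= policy.min_variance_explained
    verdict = (rmse_ok or varexpl_ok) if policy.combination == "OR" \
        else (rmse_ok and varexpl_ok)
    logger.info(
        "gate %s: rmse=%.3f (<%.2f: %s), varexpl=%.3f (>=%.2f: %s) -> %s",
        result.context, result.rmse, policy.max_rmse, rmse_ok,
        result.variance_explained, policy.min_variance_explained, varexpl_ok,
        verdict,
    )
    return verdict


class RandomForestGate(BaseEstimator):
    """Estimator form of the CV harness plus gate decision.

    Fitted attributes: ``cv_result_`` and ``passes_``.
    """

    def __init__(
        self,
        context: str = "ph",
        folds: int = 10,
        repeats: int = 5,
        train_fraction: float = 0.5,
        n_trees: int = 100,
        max_rmse: float = 0.8,
        min_variance_explained: float = 0.60,
        combination: str = "OR",
        random_state: int = 0,
    ):
        self.context = context
        self.folds = folds
        self.repeats = repeats
        self.train_fraction = train_fraction
        self.n_trees = n_trees
        self.max_rmse = max_rmse
        self.min_variance_explained = min_variance_explained
        self.combination = combination
        self.random_state = random_state

    def fit(self, table: AttributeTable, env: EnvTable):
        self.cv_result_ = cross_validate(
            table, env, self.context,
            seed=self.random_state, folds=self.folds, repeats=self.repeats,
            train_fraction=self.train_fraction, n_trees=self.n_trees,
        )
        self.passes_ = passes_gate(
            self.cv_result_,
            GatePolicy(self.max_rmse, self.min_variance_explained,
                       self.combination),
        )
        return self
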