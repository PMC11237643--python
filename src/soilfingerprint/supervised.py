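"""Supervised genomic fingerprints across environmental gradients and biomes.

The pipeline for one context (a soil factor or a biome) is:

1. split samples into the lowest and highest decile of the factor (or
   label one-vs-rest by biome),
2. rank every attribute by random-forest out-of-bag permutation
   importance (mean accuracy decrease across trees divided by its
   standard error),
3. cut the head of the sorted importance curve with breakpoint analysis,
4. assign each head attribute to the "high" or "low" fingerprint by the
   sign of its ordinary least-squares slope against the factor over all
   samples, recording slope and Pearson correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier

from .breakpoint import cut_leading_segments, segment_series
from .io import AttributeTable, EnvTable, FingerprintReport, FACTORS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExtremeSplit:
    """Lowest/highest decile membership for one factor."""

    factor: str
    low_ids: tuple[str, ...]
    high_ids: tuple[str, ...]
    fraction: float = 0.10


@dataclass
class ImportanceProfile:
    """Attributes ordered by descending importance for one context."""

    context: str
    importance: pd.Series  # index: attribute_id, sorted descending

    @property
    def attribute_ids(self) -> list[str]:
        return list(self.importance.index)


@dataclass
class SignedFingerprint:
    """The high/low member pair for one factor or biome."""

    context: str
    high_members: list[dict] = field(default_factory=list)
    low_members: list[dict] = field(default_factory=list)
    selection_meta: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def member_ids(self, direction: str) -> list[str]:
        members = self.high_members if direction == "high" else self.low_members
        return [m["attribute_id"] for m in members]

    def to_reports(self) -> tuple[FingerprintReport, FingerprintReport]:
        params = {**self.parameters, "selection_meta": self.selection_meta}
        return (
            FingerprintReport(self.context, "high", self.high_members, params),
            FingerprintReport(self.context, "low", self.low_members, params),
        )


def split_extremes(
    env: EnvTable, factor: str, fraction: float = 0.10
) -> ExtremeSplit:
    """Deterministic lowest/highest ``fraction`` membership for a factor.

    Samples missing the factor are excluded before ranking; ties are broken
    by a stable sort on (value, sample id). Group size is
    ``floor(fraction * n)``.
    """
    values = env.factor(factor).dropna()
    n = len(values)
    if n < 20:
        raise ValueError(
            f"factor {factor!r}: need >= 20 samples with values, have {n}"
        )
    if values.nunique() == 1:
        raise ValueError(f"factor {factor!r} is constant; extremes are undefined")
    k = math.floor(fraction * n)
    if k < 1:
        raise ValueError(f"fraction {fraction} yields empty extreme groups")
    order = values.to_frame("value").reset_index(names="sample")
    order = order.sort_values(["value", "sample"], kind="stable")
    low = tuple(order["sample"].iloc[:k])
    high = tuple(order["sample"].iloc[-k:])
    if set(low) & set(high):
        raise ValueError(f"factor {factor!r}: extreme deciles overlap")
    return ExtremeSplit(factor=factor, low_ids=low, high_ids=high, fraction=fraction)


def _oob_permutation_importance(
    forest: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-tree out-of-bag permutation importance (mean, standard error).

    For every tree, prediction accuracy on its out-of-bag samples is
    compared with the accuracy after permuting one attribute's values
    among those samples. Attributes a tree never splits on are exact
    zeros for that tree. The statistic is the mean decrease across trees
    divided by its standard error — the scaled importance convention of
    permutation-based forest importances.
    """
    n_samples, n_features = X.shape
    rng = np.random.default_rng(seed)
    all_idx = np.arange(n_samples)
    # individual trees predict encoded class indices, not original labels
    class_codes = {label: code for code, label in enumerate(forest.classes_)}
    y = np.asarray([class_codes[label] for label in y], dtype=float)
    decreases = np.zeros((forest.n_estimators, n_features))
    n_valid = 0
    for t, (tree, sampled) in enumerate(
        zip(forest.estimators_, forest.estimators_samples_)
    ):
        oob = np.setdiff1d(all_idx, sampled)
        if len(oob) < 2:
            continue
        n_valid += 1
        X_oob = X[oob]
        y_oob = y[oob]
        base = np.mean(tree.predict(X_oob) == y_oob)
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        perm = rng.permutation(len(oob))
        for j in used:
            X_perm = X_oob.copy()
            X_perm[:, j] = X_oob[perm, j]
            permuted = np.mean(tree.predict(X_perm) == y_oob)
            decreases[t, j] = base - permuted
    if n_valid < 2:
        raise ValueError("too few trees with out-of-bag samples")
    mean = decreases.mean(axis=0)
    se = decreases.std(axis=0, ddof=1) / math.sqrt(forest.n_estimators)
    return mean, se


def rank_importance(
    table: AttributeTable,
    groups: ExtremeSplit | pd.Series,
    seed: int = 0,
    n_trees: int = 500,
) -> ImportanceProfile:
    """Rank attributes by scaled out-of-bag permutation importance.

    ``groups`` is either an :class:`ExtremeSplit` (two-group environmental
    contrast) or a pd.Series of class labels indexed by sample id (biome
    contrast, binary or multi-class). Deterministic given ``seed``; sorted
    descending with ties broken by attribute id.
    """
    if isinstance(groups, ExtremeSplit):
        sample_ids = [
            s for s in table.sample_ids
            if s in set(groups.low_ids) | set(groups.high_ids)
        ]
        labels = pd.Series(
            ["low" if s in set(groups.low_ids) else "high" for s in sample_ids],
            index=sample_ids,
        )
        context = groups.factor
    else:
        labels = groups.dropna()
        sample_ids = [s for s in table.sample_ids if s in labels.index]
        labels = labels.loc[sample_ids]
        context = str(groups.name or "labels")
    if labels.value_counts().min() < 2:
        raise ValueError("every group needs at least 2 samples")
    X = table.counts.loc[sample_ids].to_numpy(dtype=float)
    y = labels.to_numpy()
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1, bootstrap=True
    )
    forest.fit(X, y)
    mean, se = _oob_permutation_importance(forest, X, y, seed)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, mean / np.maximum(se, 1e-12), 0.0)
    profile = (
        pd.DataFrame({"attribute_id": table.attribute_ids, "importance": z})
        .sort_values(["importance", "attribute_id"],
                     ascending=[False, True], kind="stable")
        .set_index("attribute_id")["importance"]
    )
    return ImportanceProfile(context=context, importance=profile)


def _slope_stats(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue), float(res.pvalue)


def fingerprint_context(
    table: AttributeTable,
    env: EnvTable,
    context: str,
    seed: int = 0,
    fraction: float = 0.10,
    n_trees: int = 500,
    h: float = 0.01,
    min_segment: int = 2,
    max_breaks: int = 5,
    noise_z: float = 2.0,
) -> SignedFingerprint:
    """Signed genomic fingerprint for one factor or biome.

    ``context`` is a factor name (decile contrast) or a biome label
    (one-vs-rest contrast). The head of the importance curve is selected
    by breakpoint analysis and members are signed by their OLS slope
    against the factor value (or biome indicator) over all samples.
    """
    if not table.normalized:
        raise ValueError("fingerprinting expects a TMM-normalized table")
    if context in FACTORS:
        split = split_extremes(env, context, fraction=fraction)
        profile = rank_importance(table, split, seed=seed, n_trees=n_trees)
        x_all = env.factor(context)
    else:
        biomes = env.biome.dropna()
        if context not in set(biomes):
            raise ValueError(f"context {context!r} is neither a factor nor a biome")
        labels = pd.Series(
            np.where(biomes == context, context, "rest"), index=biomes.index,
            name=context,
        )
        profile = rank_importance(table, labels, seed=seed, n_trees=n_trees)
        x_all = pd.Series(
            np.where(biomes == context, 1.0, 0.0), index=biomes.index
        )

    curve = profile.importance
    seg = segment_series(
        curve.to_numpy(), h=h, min_segment=min_segment, max_breaks=max_breaks
    )
    # the scaled importance is a z-statistic: keep the leading segments
    # whose mean clears the two-standard-error noise band
    head = cut_leading_segments(
        curve.to_numpy(), profile.attribute_ids, seg, min_segment_mean=noise_z
    )
    if not head:
        logger.warning("context %s: empty fingerprint head", context)

    x_all = x_all.dropna()
    shared = [s for s in table.sample_ids if s in x_all.index]
    x = x_all.loc[shared].to_numpy(dtype=float)
    fingerprint = SignedFingerprint(
        context=context,
        selection_meta={
            "breakpoints": list(seg.breakpoints),
            "head_size": len(head),
            "head_importances": {a: float(curve[a]) for a in head},
        },
        parameters={
            "seed": seed, "fraction": fraction, "n_trees": n_trees,
            "h": h, "min_segment": min_segment, "max_breaks": max_breaks,
            "noise_z": noise_z,
        },
    )
    for attr in head:
        y = table.counts.loc[shared, attr].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            continue  # degenerate predictor: never a member
        slope, r, p = _slope_stats(x, y)
        member = {
            "attribute_id": attr,
            "importance": float(curve[attr]),
            "slope": slope,
            "correlation": r,
            "p_value": p,
        }
        if slope > 0:
            fingerprint.high_members.append(member)
        elif slope < 0:
            fingerprint.low_members.append(member)
    return fingerprint


class SupervisedFingerprinter(BaseEstimator):
    """Estimator form of the supervised fingerprint pipeline.

    ``fit(table, env)`` runs decile split -> importance ranking ->
    breakpoint head cut -> signed regression for the configured context.
    Fitted attributes: ``fingerprint_`` (the signed member pair) and
    ``segmentation_meta_`` (breakpoints and head importances).
    """

    def __init__(
        self,
        context: str = "ph",
        fraction: float = 0.10,
        n_trees: int = 500,
        h: float = 0.01,
        min_segment: int = 2,
        max_breaks: int = 5,
        noise_z: float = 2.0,
        random_state: int = 0,
    ):
        self.context = context
        self.fraction = fraction
        self.n_trees = n_trees
        self.h = h
        self.min_segment = min_segment
        self.max_breaks = max_breaks
        self.noise_z = noise_z
        self.random_state = random_state

    def fit(self, table: AttributeTable, env: EnvTable):
        fp = fingerprint_context(
            table,
            env,
            self.context,
            seed=self.random_state,
            fraction=self.fraction,
            n_trees=self.n_trees,
            h=self.h,
            min_segment=self.min_segment,
            max_breaks=self.max_breaks,
            noise_z=self.noise_z,
        )
        self.fingerprint_ = fp
        self.segmentation_meta_ = fp.selection_meta
        return self
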