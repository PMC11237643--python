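"""Unsupervised fingerprints: k-means clusters of samples, selected by
environmental correlation count, with abundant/variable head cuts.

Samples are clustered on standardized log1p-transformed normalized
abundances (raw counts-per-million would let a handful of attributes
dominate the Euclidean metric). For every candidate k the total
within-cluster sum of squares (elbow) and the mean silhouette are
recorded; k is chosen by the silhouette. Each cluster's per-sample total
normalized abundance is regressed on each of the six soil factors, and
the cluster with the most significant correlations (ties by mean R² over
the significant factors) is selected. Its fingerprint is the breakpoint
head of the attributes sorted by total abundance ("most abundant") and by
coefficient of variation ("most variable") within the cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler

from .breakpoint import cut_head, segment_series
from .io import AttributeTable, EnvTable, FACTORS, FingerprintReport

logger = logging.getLogger(__name__)


@dataclass
class ClusterSolution:
    """K-means assignment with per-k diagnostics.

    ``assignment`` maps sample id -> contiguous cluster id (1..k). The
    candidate-k diagnostics keep both the elbow curve and the silhouette
    so the automatic choice can be inspected.
    """

    chosen_k: int
    assignment: pd.Series
    total_within_ss: dict = field(default_factory=dict)
    silhouette: dict = field(default_factory=dict)
    seed: int = 0

    def cluster_samples_ids(self, cluster: int) -> list[str]:
        return list(self.assignment.index[self.assignment == cluster])


@dataclass
class ClusterEnvProfile:
    """Per-cluster regressions of total abundance on each factor."""

    cluster: int
    n_samples: int
    regressions: dict = field(default_factory=dict)  # factor -> stats dict
    usable: bool = True
    alpha: float = 0.05

    @property
    def n_significant(self) -> int:
        return sum(
            1 for r in self.regressions.values()
            if r["p_value"] is not None and r["p_value"] < self.alpha
        )

    def mean_r_squared_significant(self) -> float:
        vals = [
            r["r_squared"] for r in self.regressions.values()
            if r["p_value"] is not None and r["p_value"] < self.alpha
        ]
        return float(np.mean(vals)) if vals else 0.0


@dataclass
class ClusterFingerprint:
    """Most-abundant and most-variable attribute sets for one cluster."""

    cluster: int
    abundant_members: list[dict] = field(default_factory=list)
    variable_members: list[dict] = field(default_factory=list)
    selection_meta: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def member_ids(self, direction: str) -> list[str]:
        members = (self.abundant_members if direction == "abundant"
                   else self.variable_members)
        return [m["attribute_id"] for m in members]

    def to_reports(self) -> tuple[FingerprintReport, FingerprintReport]:
        params = {**self.parameters, "selection_meta": self.selection_meta}
        ctx = f"cluster_{self.cluster}"
        return (
            FingerprintReport(ctx, "abundant", self.abundant_members, params),
            FingerprintReport(ctx, "variable", self.variable_members, params),
        )


def cluster_samples(
    table: AttributeTable,
    k_range: range = range(2, 13),
    seed: int = 0,
    n_init: int = 10,
) -> ClusterSolution:
    """K-means over candidate k; k chosen by maximal mean silhouette.

    Samples are canonically sorted by id before fitting so the assignment
    is invariant to input row order; cluster ids are relabelled 1..k by
    first appearance in that canonical order.
    """
    if not table.normalized:
        raise ValueError("clustering expects a TMM-normalized table")
    order = sorted(table.sample_ids)
    X = np.log1p(table.counts.loc[order].to_numpy(dtype=float))
    if np.allclose(X, X[0]):
        raise ValueError("all samples identical; clustering is degenerate")
    X = StandardScaler().fit_transform(X)
    n = len(order)
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError(f"no feasible k in {k_range} for {n} samples")
    tss: dict[int, float] = {}
    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(X)
        tss[k] = float(km.inertia_)
        sil[k] = float(silhouette_score(X, labels))
        labels_by_k[k] = labels
    chosen_k = max(ks, key=lambda k: (sil[k], -k))
    labels = labels_by_k[chosen_k]
    # contiguous ids 1..k by first appearance in canonical sample order
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    relabelled = pd.Series([remap[lab] for lab in labels], index=order)
    assignment = relabelled.loc[table.sample_ids]
    logger.info("k-means: chose k=%d (silhouette %.3f)", chosen_k, sil[chosen_k])
    return ClusterSolution(
        chosen_k=chosen_k,
        assignment=assignment,
        total_within_ss=tss,
        silhouette=sil,
        seed=seed,
    )


def profile_clusters(
    solution: ClusterSolution,
    table: AttributeTable,
    env: EnvTable,
    alpha: float = 0.05,
) -> list[ClusterEnvProfile]:
    """Regress per-sample total normalized abundance on each factor,
    within each cluster. Clusters with fewer than 3 samples are unusable;
    constant factors are skipped (never significant)."""
    totals = table.counts.sum(axis=1)
    profiles = []
    for cluster in sorted(solution.assignment.unique()):
        ids = [s for s in solution.cluster_samples_ids(cluster)
               if s in env.data.index]
        profile = ClusterEnvProfile(cluster=int(cluster), n_samples=len(ids),
                                    alpha=alpha)
        if len(ids) < 3:
            profile.usable = False
            profiles.append(profile)
            continue
        for factor in FACTORS:
            x = env.factor(factor).loc[ids].dropna()
            y = totals.loc[x.index]
            if len(x) < 3 or x.nunique() == 1:
                profile.regressions[factor] = {
                    "slope": None, "r_squared": None, "p_value": None,
                    "n": int(len(x)),
                }
                continue
            res = stats.linregress(x.to_numpy(), y.to_numpy())
            profile.regressions[factor] = {
                "slope": float(res.slope),
                "r_squared": float(res.rvalue**2),
                "p_value": float(res.pvalue),
                "n": int(len(x)),
            }
        profiles.append(profile)
    return profiles


def select_cluster(profiles: list[ClusterEnvProfile]) -> int:
    """Cluster with most significant factor correlations; ties by the
    mean R² over its significant factors."""
    usable = [p for p in profiles if p.usable]
    if not usable:
        raise ValueError("no usable cluster profiles")
    best = max(
        usable,
        key=lambda p: (p.n_significant, p.mean_r_squared_significant(), -p.cluster),
    )
    logger.info(
        "selected cluster %d (n_significant=%d, mean R2 %.3f)",
        best.cluster, best.n_significant, best.mean_r_squared_significant(),
    )
    return best.cluster


def _log_curve(values: pd.Series) -> pd.Series:
    """Descending curve on log10 scale (decay curves are ~exponential)."""
    ordered = values.sort_values(ascending=False, kind="stable")
    floor = ordered[ordered > 0].min()
    return np.log10(ordered.clip(lower=floor))


def extract_cluster_fingerprint(
    table: AttributeTable,
    solution: ClusterSolution,
    cluster: int,
    h: float = 0.01,
    min_segment: int = 2,
    max_breaks: int = 5,
) -> ClusterFingerprint:
    """Abundant and variable head sets within one cluster's samples.

    Attributes are sorted by total normalized abundance and by coefficient
    of variation (sd/mean; zero-mean attributes excluded); each sorted
    curve is segmented on the log10 scale and the first segment retained.
    """
    ids = solution.cluster_samples_ids(cluster)
    sub = table.counts.loc[ids]

    abundance = sub.sum(axis=0).sort_index()
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    cv = (sd / mean)[mean > 0].sort_index()

    fingerprint = ClusterFingerprint(
        cluster=int(cluster),
        parameters={"h": h, "min_segment": min_segment, "max_breaks": max_breaks},
    )
    for direction, curve in (("abundant", abundance), ("variable", cv)):
        log_curve = _log_curve(curve)
        seg = segment_series(
            log_curve.to_numpy(), h=h, min_segment=min_segment,
            max_breaks=max_breaks,
        )
        head = cut_head(list(log_curve.index), seg)
        if not head:
            logger.warning("cluster %d: empty %s head", cluster, direction)
        members = [
            {
                "attribute_id": a,
                "total_abundance": float(abundance[a]),
                "cv": float(cv[a]) if a in cv.index else None,
            }
            for a in head
        ]
        fingerprint.selection_meta[direction] = {
            "breakpoints": list(seg.breakpoints),
            "curve_length": int(seg.n_points),
        }
        if direction == "abundant":
            fingerprint.abundant_members = members
        else:
            fingerprint.variable_members = members
    return fingerprint


class ClusterFingerprinter(BaseEstimator):
    """Estimator form of the unsupervised pipeline.

    ``fit(table, env)`` clusters samples, profiles every cluster against
    the six factors, selects the most environment-coupled cluster and
    extracts its abundant/variable fingerprints. Fitted attributes:
    ``solution_``, ``profiles_``, ``selected_cluster_``, ``fingerprint_``.
    """

    def __init__(
        self,
        k_min: int = 2,
        k_max: int = 12,
        alpha: float = 0.05,
        h: float = 0.01,
        min_segment: int = 2,
        max_breaks: int = 5,
        n_init: int = 10,
        random_state: int = 0,
    ):
        self.k_min = k_min
        self.k_max = k_max
        self.alpha = alpha
        self.h = h
        self.min_segment = min_segment
        self.max_breaks = max_breaks
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, table: AttributeTable, env: EnvTable):
        self.solution_ = cluster_samples(
            table, range(self.k_min, self.k_max + 1),
            seed=self.random_state, n_init=self.n_init,
        )
        self.profiles_ = profile_clusters(self.solution_, table, env,
                                          alpha=self.alpha)
        self.selected_cluster_ = select_cluster(self.profiles_)
        self.fingerprint_ = extract_cluster_fingerprint(
            table, self.solution_, self.selected_cluster_,
            h=self.h, min_segment=self.min_segment, max_breaks=self.max_breaks,
        )
        return self
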