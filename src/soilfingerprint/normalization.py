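"""Attribute-type-specific filtering and trimmed-mean-of-M-values scaling.

The filter policy mirrors the compilation-study conventions: a per-sample
total-read floor that depends on the annotation type (KO/Pfam 2,000;
TIGRFAM 500; genus 4,000, all strict ``>``), and an attribute retention
rule that keeps an attribute when it is non-zero in at least half of the
samples *or* its total count reaches 7,560 (an average of 5 reads per
sample over 1,512 samples; both comparisons inclusive).

TMM factors follow the canonical doubly-trimmed weighted log-ratio
procedure: a reference sample is chosen by the 75th-percentile count
fraction, per-attribute log2 ratios (M) and mean log2 abundances (A) are
trimmed by 30% and 5% respectively, and the factor is two to the
precision-weighted mean of the surviving M values, with weights from the
approximate binomial (delta-method) variances. Zeros are handled by
pairwise exclusion; no pseudocounts. Factors are rescaled to geometric
mean one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .io import AttributeTable, TableFormatError

logger = logging.getLogger(__name__)

DEFAULT_MIN_SAMPLE_READS = {"KO": 2000, "PFAM": 2000, "TIGRFAM": 500, "GENUS": 4000}

#: 5 reads/sample over the 1,512-sample compilation.
DEFAULT_MIN_TOTAL_COUNT = 7560


def derive_min_total_count(reads_per_sample: float, n_samples: int) -> int:
    """Total-count floor equivalent to an average of ``reads_per_sample``."""
    return int(round(reads_per_sample * n_samples))


@dataclass(frozen=True)
class FilterPolicy:
    """Sample and attribute retention thresholds.

    An attribute is retained if EITHER its prevalence or its total count
    passes (logical OR). ``min_total_count`` may be given directly (the
    compilation's printed 7,560) or derived via
    :func:`derive_min_total_count` for other data sizes.
    """

    min_sample_reads: dict = field(
        default_factory=lambda: dict(DEFAULT_MIN_SAMPLE_READS)
    )
    min_prevalence_fraction: float = 0.5
    min_total_count: int = DEFAULT_MIN_TOTAL_COUNT

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.min_sample_reads.values()):
            raise ValueError("sample-read thresholds must be positive")
        if not 0 < self.min_prevalence_fraction <= 1:
            raise ValueError("min_prevalence_fraction must be in (0, 1]")
        if self.min_total_count <= 0:
            raise ValueError("min_total_count must be positive")

    @classmethod
    def for_data_size(
        cls, n_samples: int, reads_per_sample: float = 5.0, **kwargs
    ) -> "FilterPolicy":
        return cls(
            min_total_count=derive_min_total_count(reads_per_sample, n_samples),
            **kwargs,
        )


@dataclass(frozen=True)
class TmmFactors:
    """Per-sample TMM scale factors, geometric mean one."""

    reference_sample: str
    factor: pd.Series
    trim_m: float = 0.30
    trim_a: float = 0.05

    def __post_init__(self) -> None:
        if (self.factor <= 0).any():
            raise ValueError("TMM factors must be strictly positive")


def filter_samples(table: AttributeTable, policy: FilterPolicy | None = None) -> AttributeTable:
    """Keep samples whose total count strictly exceeds the type threshold."""
    if table.normalized:
        raise ValueError("sample filter applies to raw counts only")
    policy = policy or FilterPolicy()
    threshold = policy.min_sample_reads[table.attribute_type]
    totals = table.counts.sum(axis=1)
    keep = totals > threshold
    if not keep.any():
        raise TableFormatError(
            f"no samples exceed {threshold} total reads "
            f"(max observed {totals.max():.0f} of {len(totals)} samples)"
        )
    logger.info(
        "sample filter (%s > %d): kept %d of %d",
        table.attribute_type, threshold, int(keep.sum()), len(keep),
    )
    return AttributeTable(
        counts=table.counts.loc[keep],
        attribute_type=table.attribute_type,
        normalized=False,
    )


def filter_attributes(table: AttributeTable, policy: FilterPolicy | None = None) -> AttributeTable:
    """Keep attributes passing prevalence OR total-count (both inclusive)."""
    policy = policy or FilterPolicy()
    n = table.n_samples
    min_prevalence = math.ceil(policy.min_prevalence_fraction * n)
    prevalence = (table.counts > 0).sum(axis=0)
    totals = table.counts.sum(axis=0)
    keep = (prevalence >= min_prevalence) | (totals >= policy.min_total_count)
    if not keep.any():
        raise TableFormatError(
            f"no attributes reach prevalence {min_prevalence}/{n} or total "
            f"count {policy.min_total_count}"
        )
    logger.info(
        "attribute filter (prevalence >= %d OR total >= %d): kept %d of %d",
        min_prevalence, policy.min_total_count, int(keep.sum()), len(keep),
    )
    return AttributeTable(
        counts=table.counts.loc[:, keep],
        attribute_type=table.attribute_type,
        normalized=table.normalized,
    )


def _quantile75_fractions(counts: np.ndarray, lib_sizes: np.ndarray) -> np.ndarray:
    # 75th percentile of each sample's counts, as a fraction of library size
    return np.quantile(counts, 0.75, axis=1) / lib_sizes


def _pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
    sample_id: str,
) -> float:
    """Single-pair TMM factor (doubly trimmed, precision-weighted)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log2((obs / n_obs) / (ref / n_ref))
        abs_expr = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
        variance = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(log_ratio) & np.isfinite(abs_expr)
    if not finite.any():
        raise TableFormatError(
            f"sample {sample_id!r} shares no positive attributes with the reference"
        )
    log_ratio, abs_expr, variance = log_ratio[finite], abs_expr[finite], variance[finite]
    if np.max(np.abs(log_ratio)) < 1e-6:
        return 1.0
    n = len(log_ratio)
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(log_ratio)
    rank_a = rankdata(abs_expr)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    weighted = np.nansum(log_ratio[keep] / variance[keep]) / np.nansum(1.0 / variance[keep])
    if not np.isfinite(weighted):
        return 1.0
    return float(2.0 ** weighted)


def compute_tmm_factors(
    table: AttributeTable, trim_m: float = 0.30, trim_a: float = 0.05
) -> TmmFactors:
    """TMM scale factors for every sample of a filtered count table."""
    counts = table.counts.to_numpy(dtype=float)
    lib_sizes = counts.sum(axis=1)
    if (lib_sizes <= 0).any():
        bad = table.sample_ids[int(np.argmax(lib_sizes <= 0))]
        raise TableFormatError(f"sample {bad!r} has zero total count")
    f75 = _quantile75_fractions(counts, lib_sizes)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = counts[ref_idx]
    n_ref = lib_sizes[ref_idx]
    raw = np.array(
        [
            _pair_factor(counts[i], ref, lib_sizes[i], n_ref, trim_m, trim_a,
                         table.sample_ids[i])
            for i in range(counts.shape[0])
        ]
    )
    # rescale so the factors multiply to one (log-mean zero)
    raw /= np.exp(np.mean(np.log(raw)))
    return TmmFactors(
        reference_sample=table.sample_ids[ref_idx],
        factor=pd.Series(raw, index=table.counts.index, name="tmm_factor"),
        trim_m=trim_m,
        trim_a=trim_a,
    )


def apply_normalization(table: AttributeTable, factors: TmmFactors) -> AttributeTable:
    """Scale counts to TMM-adjusted counts-per-million."""
    missing = [s for s in table.sample_ids if s not in factors.factor.index]
    if missing:
        raise TableFormatError(f"missing TMM factors for samples: {missing[:5]}")
    lib_sizes = table.counts.sum(axis=1)
    scale = lib_sizes * factors.factor.loc[table.counts.index]
    normalized = table.counts.div(scale, axis=0) * 1e6
    return AttributeTable(
        counts=normalized, attribute_type=table.attribute_type, normalized=True
    )


class TMMNormalizer(TransformerMixin, BaseEstimator):
    """Scikit-learn-style transformer: raw counts -> TMM counts-per-million.

    Operates on a samples-by-attributes DataFrame; ``fit`` learns per-sample
    scale factors, ``transform`` rescales. Fitted attributes:

    - ``factors_`` : pd.Series of per-sample factors (geometric mean 1)
    - ``reference_sample_`` : the chosen reference sample id
    """

    def __init__(self, trim_m: float = 0.30, trim_a: float = 0.05,
                 attribute_type: str = "KO"):
        self.trim_m = trim_m
        self.trim_a = trim_a
        self.attribute_type = attribute_type

    def _as_table(self, X) -> AttributeTable:
        if isinstance(X, AttributeTable):
            return X
        frame = pd.DataFrame(X)
        return AttributeTable(counts=frame, attribute_type=self.attribute_type)

    def fit(self, X, y=None):
        table = self._as_table(X)
        tmm = compute_tmm_factors(table, trim_m=self.trim_m, trim_a=self.trim_a)
        self.factors_ = tmm.factor
        self.reference_sample_ = tmm.reference_sample
        self._tmm_ = tmm
        return self

    def transform(self, X):
        table = self._as_table(X)
        out = apply_normalization(table, self._tmm_)
        return out.counts if not isinstance(X, AttributeTable) else out


def normalize_pipeline(
    table: AttributeTable,
    policy: FilterPolicy | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> tuple[AttributeTable, TmmFactors]:
    """Full preprocessing: sample filter -> attribute filter -> TMM CPM."""
    filtered = filter_attributes(filter_samples(table, policy), policy)
    factors = compute_tmm_factors(filtered, trim_m=trim_m, trim_a=trim_a)
    return apply_normalization(filtered, factors), factors
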