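"""Synthetic soil-metagenome tables with known planted structure.

The generator emulates the statistical features the analysis pipeline
assumes about real attribute tables: heterogeneous library sizes
(log-normal), overdispersed counts (negative binomial via gamma-Poisson
mixing), a sparse low-abundance background tail, attributes whose
relative abundance varies monotonically with one environmental factor,
and — in the "fertile" scenario — a sample subset with coordinated
environmental shifts (SOC, N and CEC up; bulk density and clay down)
carrying its own elevated attribute set. Every generated data set ships
with a :class:`SyntheticTruth` describing exactly what was planted, so
recovery can be scored.

Planted effects are parameterized as the natural-log fold change of an
attribute's expected relative abundance across a factor's full range:
``lambda = baseline * exp(effect_size * z)`` with ``z`` the factor scaled
to [-1/2, 1/2] over its declared range. Factor ranges default to the
global soil compilation's observed spans (bulk density 0.28-1.56 kg/dm3,
CEC 7.7-68.7 cmol/kg, N 0.25-22.4 g/kg, pH 4.4-8.3, SOC 2.4-510.9 g/kg,
clay 2.7-57.1%).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AttributeTable, EnvTable, FACTORS

FACTOR_RANGES = {
    "bulk_density": (0.28, 1.56),
    "cec": (7.7, 68.7),
    "nitrogen": (0.25, 22.4),
    "ph": (4.4, 8.3),
    "soc": (2.4, 510.9),
    "clay": (2.7, 57.1),
}

BIOMES = (
    "tundra",
    "boreal_forest",
    "temperate_broadleaf_forest",
    "montane_grassland",
)

#: Factors rising in fertile soils vs falling (bulk density, clay).
FERTILE_POSITIVE = ("soc", "nitrogen", "cec")
FERTILE_NEGATIVE = ("bulk_density", "clay")


@dataclass(frozen=True)
class FertileScheme:
    """Planted fertile-cluster definition.

    A ``fraction`` of samples gets coordinated environmental shifts driven
    by a latent fertility score f in [-1, 1]: SOC/N/CEC quantiles rise
    with f, bulk density/clay fall. ``n_moderate`` attributes are
    uniformly elevated in fertile samples (fold x exp(trend * f)) and
    carry the clustering and total-abundance signal; ``n_spike``
    attributes are switched on in a fixed fraction of fertile samples at
    a high level, making them simultaneously the most abundant and the
    most variable attributes within the cluster — the planted
    fingerprint.
    """

    fraction: float = 0.25
    n_moderate: int = 40
    moderate_baseline: float = 1.5
    moderate_fold: float = 3.0
    moderate_trend: float = 0.5
    n_spike: int = 6
    spike_level: float = 80.0
    spike_off_level: float = 0.01
    spike_on_fraction: float = 0.16
    background_sigma: float = 0.6
    background_dispersion_mu: float = math.log(0.2)
    background_dispersion_sigma: float = 0.4

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 0.5:
            raise ValueError("fertile fraction must be in (0, 0.5]")


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for the synthetic compilation.

    ``planted`` maps a factor name to ``(n_up, n_down)`` attribute counts
    whose abundance rises/falls across that factor's range with
    ``effect_size`` natural-log folds. Background attributes have zero
    effect; a ``sparse_fraction`` of them is scaled down so the
    prevalence/total-count filter is exercised.
    """

    n_samples: int = 300
    n_background: int = 500
    planted: dict = field(default_factory=lambda: {"ph": (20, 20)})
    effect_size: float = 2.0
    library_mu: float = math.log(3.0e4)
    library_sigma: float = 0.6
    dispersion: float = 0.3
    background_baseline_sigma: float = 1.0
    planted_baseline_sigma: float = 0.5
    sparse_fraction: float = 0.10
    sparse_scale: float = 0.02
    factor_ranges: dict = field(default_factory=lambda: dict(FACTOR_RANGES))
    n_biomes: int = 4
    biome_planted: dict = field(default_factory=dict)  # biome -> n attributes
    biome_effect: float = 1.5
    attribute_type: str = "KO"
    fertile: FertileScheme | None = None

    def __post_init__(self) -> None:
        for factor, (n_up, n_down) in self.planted.items():
            if factor not in self.factor_ranges:
                raise ValueError(f"planted factor {factor!r} has no range")
            if n_up < 0 or n_down < 0:
                raise ValueError("planted counts must be non-negative")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")


@dataclass
class SyntheticTruth:
    """The planted signal, written alongside every generated data set."""

    planted_up: dict = field(default_factory=dict)     # factor -> [ids]
    planted_down: dict = field(default_factory=dict)   # factor -> [ids]
    biome_planted: dict = field(default_factory=dict)  # biome -> [ids]
    fertile_cluster_samples: list = field(default_factory=list)
    fertile_fingerprint: list = field(default_factory=list)
    fertile_support: list = field(default_factory=list)

    def all_planted_ids(self) -> set:
        out: set = set()
        for ids in self.planted_up.values():
            out |= set(ids)
        for ids in self.planted_down.values():
            out |= set(ids)
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=2, sort_keys=True)
            handle.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as handle:
            return cls(**json.load(handle))


def _scaled_factor(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Factor scaled to [-1/2, 1/2] over its declared range."""
    return (values - lo) / (hi - lo) - 0.5


def _draw_counts(
    lam_rel: np.ndarray,
    libraries: np.ndarray,
    dispersion: np.ndarray | float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Negative-binomial counts via gamma-Poisson, per-sample library."""
    comp = lam_rel / lam_rel.sum(axis=1, keepdims=True)
    mean = comp * libraries[:, None]
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    out = np.empty_like(mean)
    positive = phi > 0
    if positive.any():
        shaped = rng.gamma(1.0 / phi[positive], phi[positive] * mean[positive])
        out[positive] = shaped
    out[~positive] = mean[~positive]
    return rng.poisson(out).astype(np.int64)


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:04d}" for i in range(n)]


def _attribute_ids(n: int, prefix: str = "K") -> list[str]:
    return [f"{prefix}{i + 1:05d}" for i in range(n)]


def generate(
    spec: GeneratorSpec | None = None, seed: int = 0
) -> tuple[AttributeTable, EnvTable, SyntheticTruth]:
    """Generate a table, metadata, and its ground truth.

    Factors are uniform within their declared ranges; planted attributes'
    expected relative abundance follows ``baseline * exp(effect * z)``
    with z the scaled factor; counts are negative binomial under a
    log-normal library size. Deterministic under ``seed``.
    """
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(seed)
    n = spec.n_samples
    samples = _sample_ids(n)

    env = pd.DataFrame(index=pd.Index(samples, name="sample"))
    for factor in FACTORS:
        lo, hi = spec.factor_ranges[factor]
        env[factor] = rng.uniform(lo, hi, n)
    env["biome"] = rng.choice(BIOMES[: spec.n_biomes], n)

    n_planted = sum(u + d for u, d in spec.planted.values())
    n_biome_planted = sum(spec.biome_planted.values())
    n_attrs = spec.n_background + n_planted + n_biome_planted
    attrs = _attribute_ids(n_attrs)

    baselines = np.empty(n_attrs)
    bg = slice(0, spec.n_background)
    baselines[bg] = rng.lognormal(0.0, spec.background_baseline_sigma,
                                  spec.n_background)
    n_sparse = int(spec.sparse_fraction * spec.n_background)
    sparse_idx = rng.choice(spec.n_background, n_sparse, replace=False)
    baselines[sparse_idx] *= spec.sparse_scale
    baselines[spec.n_background:] = rng.lognormal(
        0.0, spec.planted_baseline_sigma, n_planted + n_biome_planted
    )

    lam = np.tile(baselines, (n, 1))
    truth = SyntheticTruth()
    cursor = spec.n_background
    for factor in sorted(spec.planted):
        n_up, n_down = spec.planted[factor]
        lo, hi = spec.factor_ranges[factor]
        z = _scaled_factor(env[factor].to_numpy(), lo, hi)
        up = list(range(cursor, cursor + n_up))
        down = list(range(cursor + n_up, cursor + n_up + n_down))
        lam[:, up] *= np.exp(spec.effect_size * z)[:, None]
        lam[:, down] *= np.exp(-spec.effect_size * z)[:, None]
        truth.planted_up[factor] = [attrs[i] for i in up]
        truth.planted_down[factor] = [attrs[i] for i in down]
        cursor += n_up + n_down
    for biome in sorted(spec.biome_planted):
        count = spec.biome_planted[biome]
        idx = list(range(cursor, cursor + count))
        in_biome = (env["biome"] == biome).to_numpy()
        lam[np.ix_(in_biome, idx)] *= math.exp(spec.biome_effect)
        truth.biome_planted[biome] = [attrs[i] for i in idx]
        cursor += count

    libraries = rng.lognormal(spec.library_mu, spec.library_sigma, n)
    counts = _draw_counts(lam, libraries, spec.dispersion, rng)
    table = AttributeTable(
        counts=pd.DataFrame(counts, index=env.index, columns=attrs),
        attribute_type=spec.attribute_type,
    )
    return table, EnvTable(data=env), truth


def generate_fertile_scenario(
    spec: GeneratorSpec | None = None, seed: int = 0
) -> tuple[AttributeTable, EnvTable, SyntheticTruth]:
    """Generate the coordinated-fertility scenario.

    One sample subset receives jointly elevated SOC/N/CEC and lowered
    bulk density/clay plus an elevated attribute set; the truth records
    the subset and the planted fingerprint attributes.
    """
    spec = spec or GeneratorSpec(n_samples=200, n_background=300, planted={})
    scheme = spec.fertile or FertileScheme()
    rng = np.random.default_rng(seed)
    n = spec.n_samples
    samples = _sample_ids(n)
    n_fertile = round(scheme.fraction * n)
    fertile_idx = np.sort(rng.choice(n, n_fertile, replace=False))
    is_fertile = np.zeros(n, dtype=bool)
    is_fertile[fertile_idx] = True
    fertility = rng.uniform(-1.0, 1.0, n_fertile)

    env = pd.DataFrame(index=pd.Index(samples, name="sample"))
    for factor in FACTORS:
        lo, hi = spec.factor_ranges[factor]
        x = rng.uniform(lo, hi, n)
        if factor in FERTILE_POSITIVE:
            q = np.clip(0.68 + 0.22 * fertility + rng.normal(0, 0.05, n_fertile),
                        0.02, 0.98)
            x[fertile_idx] = lo + q * (hi - lo)
        elif factor in FERTILE_NEGATIVE:
            q = np.clip(0.32 - 0.22 * fertility + rng.normal(0, 0.05, n_fertile),
                        0.02, 0.98)
            x[fertile_idx] = lo + q * (hi - lo)
        env[factor] = x
    env["biome"] = rng.choice(BIOMES[: spec.n_biomes], n)

    n_attrs = spec.n_background + scheme.n_moderate + scheme.n_spike
    attrs = _attribute_ids(n_attrs)
    bg_end = spec.n_background
    mod_idx = list(range(bg_end, bg_end + scheme.n_moderate))
    spike_idx = list(range(bg_end + scheme.n_moderate, n_attrs))

    baselines = np.empty(n_attrs)
    baselines[:bg_end] = rng.lognormal(0.0, scheme.background_sigma, bg_end)
    baselines[mod_idx] = scheme.moderate_baseline
    baselines[spike_idx] = scheme.spike_off_level

    lam = np.tile(baselines, (n, 1))
    fold = scheme.moderate_fold * np.exp(scheme.moderate_trend * fertility)
    lam[np.ix_(fertile_idx, mod_idx)] *= fold[:, None]
    k_on = max(2, round(scheme.spike_on_fraction * n_fertile))
    for j in spike_idx:
        on = rng.choice(fertile_idx, k_on, replace=False)
        lam[on, j] = scheme.spike_level

    dispersion = np.empty(n_attrs)
    dispersion[:bg_end] = rng.lognormal(
        scheme.background_dispersion_mu, scheme.background_dispersion_sigma,
        bg_end,
    )
    dispersion[mod_idx] = 0.25
    dispersion[spike_idx] = 0.05

    libraries = rng.lognormal(spec.library_mu, spec.library_sigma, n)
    counts = _draw_counts(lam, libraries, dispersion[None, :], rng)
    table = AttributeTable(
        counts=pd.DataFrame(counts, index=env.index, columns=attrs),
        attribute_type=spec.attribute_type,
    )
    truth = SyntheticTruth(
        fertile_cluster_samples=[samples[i] for i in fertile_idx],
        fertile_fingerprint=[attrs[j] for j in spike_idx],
        fertile_support=[attrs[j] for j in mod_idx],
    )
    return table, EnvTable(data=env), truth
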