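"""Reading, writing and aligning attribute tables, metadata and reports.

The two on-disk table formats are deliberately narrow: tab-separated text
with a header row, samples in rows, and a first column named ``sample``.
A transposed table is rejected rather than auto-detected, because silent
transposition is a classic tabular-omics bug. Fingerprint reports are JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ATTRIBUTE_TYPES = ("KO", "PFAM", "TIGRFAM", "GENUS")

#: Continuous soil factors carried by an EnvTable, with their units.
FACTORS = ("bulk_density", "cec", "nitrogen", "ph", "soc", "clay")
FACTOR_UNITS = {
    "bulk_density": "kg/dm3",
    "cec": "cmol C/kg",
    "nitrogen": "g/kg",
    "ph": "unitless",
    "soc": "g/kg",
    "clay": "%",
}


class TableFormatError(ValueError):
    """A table violated the on-disk or in-memory contract."""


@dataclass
class AttributeTable:
    """A sample x attribute count matrix for one annotation type.

    Parameters
    ----------
    counts
        DataFrame with sample ids as index and attribute ids as columns.
        Values are non-negative, and integer-valued while ``normalized``
        is False.
    attribute_type
        One of ``KO``, ``PFAM``, ``TIGRFAM``, ``GENUS``. Determines which
        sample-filter threshold applies downstream.
    normalized
        True once TMM-scaled counts-per-million have replaced raw counts.
    """

    counts: pd.DataFrame
    attribute_type: str
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.attribute_type not in ATTRIBUTE_TYPES:
            raise TableFormatError(
                f"unknown attribute_type {self.attribute_type!r}; "
                f"expected one of {ATTRIBUTE_TYPES}"
            )
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise TableFormatError(f"duplicate sample ids: {dupes}")
        if self.counts.columns.has_duplicates:
            dupes = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise TableFormatError(f"duplicate attribute ids: {dupes}")
        values = self.counts.to_numpy()
        if not np.isfinite(values).all():
            raise TableFormatError("counts contain non-finite values")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise TableFormatError(
                f"negative count at sample {self.counts.index[i]!r}, "
                f"attribute {self.counts.columns[j]!r}"
            )
        if not self.normalized and not np.array_equal(values, np.round(values)):
            i, j = np.argwhere(values != np.round(values))[0]
            raise TableFormatError(
                f"non-integer count in unnormalized table at sample "
                f"{self.counts.index[i]!r}, attribute {self.counts.columns[j]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def attribute_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.counts.shape[1]


@dataclass
class EnvTable:
    """Per-sample environmental factors and an optional biome label.

    ``data`` holds one row per sample (index = sample id) with the six
    factor columns of :data:`FACTORS` and, optionally, a ``biome`` column.
    Missing values are NaN; samples missing the factor under study are
    dropped per-analysis, not globally.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [f for f in FACTORS if f not in self.data.columns]
        if missing:
            raise TableFormatError(f"metadata missing factor columns: {missing}")
        if self.data.index.has_duplicates:
            raise TableFormatError("duplicate sample ids in metadata")
        ph = self.data["ph"].dropna()
        if ((ph < 0) | (ph > 14)).any():
            raise TableFormatError("ph outside the physically plausible 0-14 range")
        clay = self.data["clay"].dropna()
        if ((clay < 0) | (clay > 100)).any():
            raise TableFormatError("clay content outside 0-100%")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def biome(self) -> pd.Series:
        if "biome" in self.data.columns:
            return self.data["biome"]
        return pd.Series(pd.NA, index=self.data.index, name="biome")

    def factor(self, name: str) -> pd.Series:
        if name not in FACTORS:
            raise KeyError(f"unknown factor {name!r}; expected one of {FACTORS}")
        return self.data[name]


@dataclass
class FingerprintReport:
    """One signed fingerprint for one context, ready for serialization.

    ``direction`` is ``high``/``low`` for supervised fingerprints and
    ``abundant``/``variable`` for cluster fingerprints. Every member row
    carries the statistics used to select it.
    """

    context: str
    direction: str
    members: list[dict] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def member_ids(self) -> list[str]:
        return [m["attribute_id"] for m in self.members]

    def to_dict(self) -> dict:
        return {
            "context": self.context,
            "direction": self.direction,
            "members": self.members,
            "parameters": self.parameters,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "FingerprintReport":
        return cls(
            context=payload["context"],
            direction=payload["direction"],
            members=list(payload["members"]),
            parameters=dict(payload["parameters"]),
        )


def _parse_numeric(frame: pd.DataFrame, path: Path) -> pd.DataFrame:
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise TableFormatError(
            f"{path}: non-numeric count {frame.iat[i, j]!r} at sample "
            f"{frame.index[i]!r}, attribute {frame.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise TableFormatError(
            f"{path}: empty count at sample {frame.index[i]!r}, "
            f"attribute {frame.columns[j]!r}"
        )
    return numeric


def read_attribute_table(
    path: str | Path, attribute_type: str, normalized: bool = False
) -> AttributeTable:
    """Read a TSV count table (samples in rows, first column ``sample``)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str, index_col=0)
    if frame.index.name != "sample":
        raise TableFormatError(
            f"{path}: first column must be named 'sample', got "
            f"{frame.index.name!r} (samples belong in rows, not columns)"
        )
    counts = _parse_numeric(frame, path)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return AttributeTable(counts=counts, attribute_type=attribute_type,
                          normalized=normalized)


def write_attribute_table(table: AttributeTable, path: str | Path) -> None:
    """Write a table as TSV; normalized tables get a provenance comment."""
    path = Path(path)
    frame = table.counts.copy()
    frame.index.name = "sample"
    with open(path, "w") as handle:
        if table.normalized:
            handle.write(
                f"# normalized=true attribute_type={table.attribute_type} "
                "units=TMM-scaled counts-per-million\n"
            )
        if not table.normalized:
            frame = frame.astype(np.int64)
        frame.to_csv(handle, sep="\t")


def read_env_table(path: str | Path) -> EnvTable:
    """Read per-sample metadata (factors + optional biome); blanks are NaN."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if frame.index.name != "sample":
        raise TableFormatError(
            f"{path}: first column must be named 'sample', got {frame.index.name!r}"
        )
    frame.index = frame.index.astype(str)
    for factor in FACTORS:
        if factor in frame.columns:
            frame[factor] = pd.to_numeric(frame[factor], errors="raise")
    return EnvTable(data=frame)


def write_env_table(env: EnvTable, path: str | Path) -> None:
    frame = env.data.copy()
    frame.index.name = "sample"
    frame.to_csv(path, sep="\t")


def align_samples(table: AttributeTable, env: EnvTable) -> tuple[AttributeTable, EnvTable]:
    """Restrict both inputs to their shared samples, in table order."""
    if table.n_samples == 0 or len(env.sample_ids) == 0:
        raise TableFormatError("cannot align empty inputs")
    shared = [s for s in table.sample_ids if s in set(env.sample_ids)]
    if not shared:
        raise TableFormatError("no samples shared between table and metadata")
    logger.info(
        "aligned samples: %d shared of %d (table) and %d (metadata)",
        len(shared), table.n_samples, len(env.sample_ids),
    )
    aligned_table = AttributeTable(
        counts=table.counts.loc[shared],
        attribute_type=table.attribute_type,
        normalized=table.normalized,
    )
    aligned_env = EnvTable(data=env.data.loc[shared])
    return aligned_table, aligned_env


def write_fingerprint_report(report: FingerprintReport, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(report.to_dict(), handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_fingerprint_report(path: str | Path) -> FingerprintReport:
    with open(path) as handle:
        return FingerprintReport.from_dict(json.load(handle))


def write_fingerprint_reports(
    reports: Iterable[FingerprintReport], path: str | Path
) -> None:
    """Write several reports (e.g. the high/low pair of one context) as one
    JSON array, keyed so that same-context directions never collide."""
    with open(path, "w") as handle:
        json.dump([r.to_dict() for r in reports], handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_fingerprint_reports(path: str | Path) -> list[FingerprintReport]:
    with open(path) as handle:
        return [FingerprintReport.from_dict(p) for p in json.load(handle)]
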