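"""Abundance tables, multi-modal bundles, and cluster labels.

A modality is one kingdom's feature-by-sample abundance table (bacterial 16S,
fungal ITS, viral contigs, ...) with non-negative entries. Two or three
modalities measured on the same samples form a :class:`MultiOmicsDataset`.
All downstream machinery assumes the modalities share an identical,
identically ordered sample list; :func:`align_modalities` establishes that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "MultiOmicsDataset",
    "ClusterLabels",
    "read_abundance_table",
    "write_abundance_table",
    "align_modalities",
    "read_labels",
    "write_labels",
]


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class AbundanceMatrix:
    """Non-negative feature-by-sample abundance table for one modality.

    Parameters
    ----------
    values
        ``(p, n)`` array of non-negative abundances (counts or relative).
    feature_ids, sample_ids
        Unique row / column identifiers.
    name
        Modality label (e.g. ``"bacteria"``).
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    name: str = "modality"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(x) for x in self.feature_ids]
        self.sample_ids = [str(x) for x in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D feature-by-sample matrix")
        p, n = self.values.shape
        if p != len(self.feature_ids):
            raise ValueError(f"{len(self.feature_ids)} feature ids for {p} rows")
        if n != len(self.sample_ids):
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} columns")
        if p < 2 or n < 3:
            raise ValueError(f"need at least 2 features and 3 samples, got {p}x{n}")
        if not np.isfinite(self.values).all():
            raise ValueError("abundance values must be finite")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative abundance at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str = "modality") -> "AbundanceMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns), name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def select_samples(self, sample_ids: list[str]) -> "AbundanceMatrix":
        """Reorder / subset columns to the given sample order."""
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return AbundanceMatrix(self.values[:, idx], list(self.feature_ids), list(sample_ids), self.name)

    def normalized(self, log_c: float | None = None) -> "AbundanceMatrix":
        """Relative abundance per sample (columns sum to 1), optional log(1 + c*x).

        Compositional convention for microbiome profiles: sequencing depth is
        arbitrary, so each sample column is scaled to total 1 before any
        kernel is computed. ``log_c`` applies a variance-stabilizing
        ``log1p(c * x)`` after closure (off by default).
        """
        tot = self.values.sum(axis=0)
        if (tot <= 0).any():
            j = int(np.argmax(tot <= 0))
            raise ValueError(f"sample {self.sample_ids[j]!r} has zero total abundance")
        vals = self.values / tot
        if log_c is not None:
            vals = np.log1p(log_c * vals)
        return AbundanceMatrix(vals, list(self.feature_ids), list(self.sample_ids), self.name)


@dataclass
class MultiOmicsDataset:
    """Two or three modalities over an identical, identically ordered sample set."""

    modalities: list[AbundanceMatrix]
    modality_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.modality_names:
            self.modality_names = [m.name for m in self.modalities]
        if len(self.modalities) not in (2, 3):
            raise ValueError("a dataset holds 2 or 3 modalities")
        if len(self.modality_names) != len(self.modalities):
            raise ValueError("one name per modality required")
        _check_unique(self.modality_names, "modality")
        ref = self.modalities[0].sample_ids
        for m in self.modalities[1:]:
            if m.sample_ids != ref:
                raise ValueError(
                    "modalities must share an identical, identically ordered sample list; "
                    "use align_modalities() first"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.modalities[0].sample_ids

    @property
    def n_samples(self) -> int:
        return self.modalities[0].n_samples

    @property
    def n_modalities(self) -> int:
        return len(self.modalities)

    def __getitem__(self, key: int | str) -> AbundanceMatrix:
        if isinstance(key, str):
            key = self.modality_names.index(key)
        return self.modalities[key]


@dataclass
class ClusterLabels:
    """Cluster assignment for each sample; labels are contiguous ints from 0."""

    labels: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.labels.ndim != 1 or len(self.labels) != len(self.sample_ids):
            raise ValueError("labels must be a vector matched to sample_ids")
        uniq = np.unique(self.labels)
        if uniq.min() != 0 or not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("labels must be contiguous non-negative integers starting at 0")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "cluster": self.labels})


def read_abundance_table(path, delimiter: str = "\t", name: str | None = None) -> AbundanceMatrix:
    """Read a delimited feature-by-sample table.

    First column holds feature IDs, header row holds sample IDs, body is
    numeric. Malformed cells and duplicate identifiers are rejected with the
    offending row/column named.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
    sample_ids = [h.strip() for h in header[1:]]
    _check_unique(sample_ids, "sample")

    raw = pd.read_csv(path, sep=delimiter, index_col=0, header=0, dtype=str)
    feature_ids = [str(x) for x in raw.index]
    _check_unique(feature_ids, "feature")

    vals = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw.iloc[:, j], errors="coerce")
        bad = converted.isna() & raw.iloc[:, j].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"malformed numeric value {raw.iloc[i, j]!r} at feature "
                f"{feature_ids[i]!r}, sample {sample_ids[j]!r} in {path}"
            )
        if converted.isna().any():
            i = int(np.argmax(converted.isna().to_numpy()))
            raise ValueError(f"missing value at feature {feature_ids[i]!r}, sample {sample_ids[j]!r}")
        vals[:, j] = converted.to_numpy(dtype=float)

    if name is None:
        import os

        name = os.path.splitext(os.path.basename(str(path)))[0]
    return AbundanceMatrix(vals, feature_ids, sample_ids, name)


def write_abundance_table(am: AbundanceMatrix, path, delimiter: str = "\t") -> None:
    am.to_frame().to_csv(path, sep=delimiter, index_label="feature_id")


def read_labels(path, delimiter: str = "\t") -> ClusterLabels:
    df = pd.read_csv(path, sep=delimiter)
    return ClusterLabels(df["cluster"].to_numpy(int), list(df["sample_id"].astype(str)))


def write_labels(labels: ClusterLabels, path, delimiter: str = "\t") -> None:
    labels.to_frame().to_csv(path, sep=delimiter, index=False)


def align_modalities(
    tables: list[AbundanceMatrix], modality_names: list[str] | None = None
) -> MultiOmicsDataset:
    """Restrict all modalities to their shared samples, in a common order.

    Sample order follows the first table. Samples absent from any modality
    are dropped with a warning; the model requires matched samples and does
    not impute. Fewer than 3 shared samples is an error.
    """
    if len(tables) not in (2, 3):
        raise ValueError("provide 2 or 3 modalities")
    shared = [s for s in tables[0].sample_ids if all(s in t.sample_ids for t in tables[1:])]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} samples shared across modalities; need >= 3")
    n_drop = sum(t.n_samples - len(shared) for t in tables)
    if n_drop:
        warnings.warn(
            f"dropping {n_drop} sample columns not shared by all modalities "
            f"({len(shared)} samples retained)",
            stacklevel=2,
        )
    aligned = [t.select_samples(shared) for t in tables]
    return MultiOmicsDataset(aligned, modality_names or [t.name for t in tables])
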