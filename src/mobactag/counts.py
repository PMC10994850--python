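"""Sample-by-feature count tables and their TSV dialect.

The table is a pandas DataFrame with samples as rows and features as
columns, a per-feature class label (the five reference classes plus
``unassigned``) and a per-sample read depth equal to the row sum
including unassigned reads.  Raw tables are integral; applying a
correction factor produces real-valued tag counts, tracked with
``allow_fractional``.

TSV convention: tab-separated, UTF-8, mandatory header, no quoting,
floats at 12 significant digits, ``#``-prefixed provenance lines before
the header.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .references import FEATURE_CLASSES

UNASSIGNED = "unassigned"
VALID_CLASSES = FEATURE_CLASSES + (UNASSIGNED,)
FLOAT_FORMAT = "%.12g"


class CountTableError(ValueError):
    pass


@dataclass
class CountTable:
    counts: pd.DataFrame
    feature_classes: pd.Series
    depth: pd.Series = None
    allow_fractional: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.counts.index.name = "sample_id"
        self.feature_classes = pd.Series(self.feature_classes, dtype=object)
        missing = [f for f in self.counts.columns if f not in self.feature_classes.index]
        if missing:
            raise CountTableError(f"features lack class labels: {missing}")
        self.feature_classes = self.feature_classes.reindex(self.counts.columns)
        bad_classes = sorted(set(self.feature_classes) - set(VALID_CLASSES))
        if bad_classes:
            raise CountTableError(f"unknown feature classes: {bad_classes}")
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise CountTableError("negative counts")
        if not self.allow_fractional:
            if not np.array_equal(values, np.round(values)):
                raise CountTableError("non-integral counts in a raw table")
            self.counts = self.counts.astype(np.int64)
        row_sums = self.counts.sum(axis=1)
        if self.depth is None:
            self.depth = row_sums
        else:
            self.depth = pd.Series(self.depth).reindex(self.counts.index)
            if not np.allclose(self.depth.to_numpy(dtype=float), row_sums.to_numpy(dtype=float)):
                raise CountTableError("recorded depth does not equal row sums")
        self.depth.name = "depth"

    # -- access helpers -------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def features(self) -> list[str]:
        return list(self.counts.columns)

    def features_of_class(self, *classes: str) -> list[str]:
        return [f for f in self.features if self.feature_classes[f] in classes]

    def bacterial_features(self) -> list[str]:
        """Features counted as bacteria: endogenous 16S plus barcode tags."""
        return self.features_of_class("endogenous_16S", "barcode_tag")

    # -- IO --------------------------------------------------------------
    def to_tsv(self, counts_path, classes_path=None) -> None:
        write_tsv(self.counts.reset_index(), counts_path, self.provenance)
        if classes_path is not None:
            classes = self.feature_classes.rename("feature_class").rename_axis("feature_id")
            write_tsv(classes.reset_index(), classes_path, self.provenance)

    @classmethod
    def from_tsv(cls, counts_path, classes_path, **kwargs) -> "CountTable":
        counts = read_tsv(counts_path).set_index("sample_id")
        classes = read_tsv(classes_path).set_index("feature_id")["feature_class"]
        return cls(counts=counts, feature_classes=classes, **kwargs)


def deplete_features(table: CountTable, feature_ids: Iterable[str]) -> CountTable:
    """Remove focal features from a table (in-silico depletion).

    All remaining entries are untouched; depth metadata is recomputed over
    the remaining features and the original per-sample depth is retained in
    the provenance for reporting.
    """
    feature_ids = list(feature_ids)
    unknown = [f for f in feature_ids if f not in table.features]
    if unknown:
        raise CountTableError(f"cannot deplete unknown features: {unknown}")
    kept = [f for f in table.features if f not in set(feature_ids)]
    provenance = dict(table.provenance)
    provenance["depleted_features"] = feature_ids
    provenance["original_depth"] = table.depth.to_dict()
    return CountTable(
        counts=table.counts[kept],
        feature_classes=table.feature_classes[kept],
        allow_fractional=table.allow_fractional,
        provenance=provenance,
    )


# -- TSV plumbing -------------------------------------------------------

def write_tsv(frame: pd.DataFrame, path, provenance: Mapping | None = None) -> None:
    """Write a TSV with ``#``-prefixed provenance header lines."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        for key, value in (provenance or {}).items():
            handle.write(f"# {key}: {value}\n")
        frame.to_csv(handle, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def file_digest(path) -> str:
    """Short SHA-256 digest used in provenance headers."""
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:12]
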