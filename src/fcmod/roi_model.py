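"""ROI atlas labels, sleep/pain subsets, and seed/target edge masks.

The analysis restricts which ROI-to-ROI connections are tested by choosing a
seed set and a target set from flags on the atlas table:

=========  =======================  =======================
config     seeds                    targets
=========  =======================  =======================
``S-SP``   sleep ROIs               sleep ∪ pain ROIs
``SP-SP``  sleep ∪ pain ROIs        sleep ∪ pain ROIs
``S-A``    sleep ROIs               all atlas ROIs
``SP-A``   sleep ∪ pain ROIs        all atlas ROIs
=========  =======================  =======================

An edge mask is the set of unordered ROI pairs with one endpoint in the seed
set and the other in the target set (self-pairs excluded, each pair counted
once).  Two counting conventions are exposed: exact enumeration of unique
pairs (used everywhere inference happens) and the halved seed×target product
``floor(n_seeds * n_targets / 2)`` sometimes used when reporting seed-to-target
matrix sizes; the latter is reporting-only and never drives inference.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "ROISet",
    "ROIConfiguration",
    "EdgeMask",
    "CONFIG_NAMES",
    "load_roi_table",
    "packaged_roi_table_path",
    "build_edge_mask",
    "halved_pair_count",
]

CONFIG_NAMES = ("S-SP", "SP-SP", "S-A", "SP-A")
_HEMISPHERES = {"left", "right", "midline"}


class ROITableError(ValueError):
    """Malformed ROI table (missing columns, duplicates, bad hemisphere codes)."""


@dataclass(frozen=True)
class ROISet:
    """Atlas ROI labels with sleep/pain membership flags.

    ``roi_id`` is implicit: the row order of ``table``, 0-based and contiguous.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"name", "hemisphere", "is_sleep", "is_pain"}
        missing = required - set(self.table.columns)
        if missing:
            raise ROITableError(f"ROI table missing columns: {sorted(missing)}")
        if len(self.table) == 0:
            raise ROITableError("ROI table is empty")
        dup = self.table["name"][self.table["name"].duplicated()]
        if len(dup):
            raise ROITableError(f"duplicate ROI names: {sorted(dup.unique())}")
        bad_hemi = ~self.table["hemisphere"].isin(_HEMISPHERES)
        if bad_hemi.any():
            rows = list(self.table.index[bad_hemi])
            raise ROITableError(f"unknown hemisphere codes at rows {rows}")
        if int(self.table["is_sleep"].sum()) == 0:
            raise ROITableError("no ROI carries the sleep flag")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def names(self) -> list[str]:
        return list(self.table["name"])

    @property
    def sleep_ids(self) -> list[int]:
        return list(self.table.index[self.table["is_sleep"].astype(bool)])

    @property
    def pain_ids(self) -> list[int]:
        return list(self.table.index[self.table["is_pain"].astype(bool)])

    @property
    def union_ids(self) -> list[int]:
        both = self.table["is_sleep"].astype(bool) | self.table["is_pain"].astype(bool)
        return list(self.table.index[both])

    @property
    def all_ids(self) -> list[int]:
        return list(range(len(self.table)))

    def counts(self) -> dict[str, int]:
        """Sizes of the flag-derived subsets (sleep, pain, union, atlas)."""
        return {
            "n_sleep": len(self.sleep_ids),
            "n_pain": len(self.pain_ids),
            "n_union": len(self.union_ids),
            "n_total": len(self),
        }

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ROIConfiguration:
    """A named seed/target restriction derived from ROISet flags."""

    name: str
    seed_ids: tuple[int, ...]
    target_ids: tuple[int, ...]


@dataclass(frozen=True)
class EdgeMask:
    """Unordered ROI pairs (i < j) tested under one configuration."""

    edges: tuple[tuple[int, int], ...]
    config: ROIConfiguration

    @property
    def n_tests(self) -> int:
        return len(self.edges)

    def to_frame(self, rois: ROISet) -> pd.DataFrame:
        names = rois.names
        return pd.DataFrame(
            {
                "roi_i_name": [names[i] for i, _ in self.edges],
                "roi_j_name": [names[j] for _, j in self.edges],
                "config": self.config.name,
            }
        )


def packaged_roi_table_path() -> Path:
    """Path of the ROI table shipped with the package (calibrated transcription)."""
    return Path(str(resources.files("fcmod") / "data" / "roi_table.tsv"))


def load_roi_table(path: str | Path | None = None) -> ROISet:
    """Read and validate an ROI table TSV.

    Expected columns: ``name``, ``hemisphere`` (left/right/midline),
    ``is_sleep`` (0/1), ``is_pain`` (0/1).  Lines starting with ``#`` are
    comments.  With no *path*, the packaged atlas table is loaded.
    """
    if path is None:
        path = packaged_roi_table_path()
    try:
        table = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ROITableError(f"ROI table {path} is empty") from exc
    table = table.reset_index(drop=True)
    return ROISet(table=table)


def _resolve_sets(config_name: str, rois: ROISet) -> ROIConfiguration:
    sleep, union, allids = rois.sleep_ids, rois.union_ids, rois.all_ids
    try:
        seeds, targets = {
            "S-SP": (sleep, union),
            "SP-SP": (union, union),
            "S-A": (sleep, allids),
            "SP-A": (union, allids),
        }[config_name]
    except KeyError:
        raise ValueError(
            f"unknown configuration {config_name!r}; expected one of {CONFIG_NAMES}"
        ) from None
    if not seeds:
        raise ValueError(f"configuration {config_name}: empty seed set")
    return ROIConfiguration(config_name, tuple(seeds), tuple(targets))


def build_edge_mask(config_name: str, rois: ROISet) -> EdgeMask:
    """Enumerate the unique unordered seed-target pairs for a configuration.

    An edge {i, j} is included when one endpoint is a seed and the other a
    target (in either role); each pair appears once with i < j.
    """
    cfg = _resolve_sets(config_name, rois)
    seeds, targets = set(cfg.seed_ids), set(cfg.target_ids)
    edges = set()
    for i, j in itertools.product(seeds, targets):
        if i != j:
            edges.add((min(i, j), max(i, j)))
    return EdgeMask(edges=tuple(sorted(edges)), config=cfg)


def halved_pair_count(n_seeds: int, n_targets: int) -> int:
    """Halved seed×target product, ``floor(n_seeds * n_targets / 2)``.

    A reporting convention for seed-to-target matrix sizes; it differs from the
    exact unique-pair enumeration whenever the seed set is a proper subset of
    the target set.  Provided for comparability only — inference always uses
    :func:`build_edge_mask`.
    """
    if n_seeds <= 0 or n_targets <= 0:
        raise ValueError("counts must be positive")
    return (n_seeds * n_targets) // 2
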