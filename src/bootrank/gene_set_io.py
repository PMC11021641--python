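"""Readers and writers for gene-set collections (GMT) and differential-expression tables.

Feature identifiers are matched by exact, case-sensitive string equality
throughout the package; identifier mapping or orthology translation is out
of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "DEResult",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "read_de_table",
    "write_de_table",
    "filter_collection",
    "DEFAULT_MIN_SIZE",
    "DEFAULT_MAX_SIZE",
]

#: Default gene-set size filters applied before enrichment scoring.
DEFAULT_MIN_SIZE = 5
DEFAULT_MAX_SIZE = 5000


class GmtParseError(ValueError):
    """Raised when a GMT file violates the tab-separated dialect."""


@dataclass(frozen=True)
class GeneSet:
    """A named, deduplicated, unordered collection of feature identifiers."""

    set_id: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """An ordered mapping of set_id -> :class:`GeneSet` with unique set ids."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, gs in self.sets.items():
            if set_id != gs.set_id:
                raise ValueError(f"key {set_id!r} does not match set id {gs.set_id!r}")

    @classmethod
    def from_sets(cls, sets: Iterable[GeneSet]) -> "GeneSetCollection":
        out: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.set_id in out:
                raise ValueError(f"duplicate set id {gs.set_id!r}")
            out[gs.set_id] = gs
        return cls(out)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    @property
    def set_ids(self) -> list[str]:
        return list(self.sets)


@dataclass
class DEResult:
    """Per-feature differential-expression statistics.

    Wraps a DataFrame with the columns ``feature_id``, ``p``, ``p_adj`` and
    ``logfc``. The feature list doubles as the gene universe for enrichment:
    every measured feature is a row, not only the significant ones.
    """

    table: pd.DataFrame

    REQUIRED_COLUMNS = ("feature_id", "p", "p_adj", "logfc")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"DE table lacks required columns: {missing}")
        tab = self.table.reset_index(drop=True)
        dupes = tab["feature_id"][tab["feature_id"].duplicated()]
        if len(dupes):
            raise ValueError(f"duplicate feature id(s): {sorted(set(dupes))[:5]}")
        if tab["p"].isna().any():
            raise ValueError("missing p-values are not allowed")
        for col in ("p", "p_adj"):
            vals = tab[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"column {col!r} contains values outside [0, 1]")
        self.table = tab

    def __len__(self) -> int:
        return len(self.table)

    @property
    def feature_ids(self) -> list[str]:
        return self.table["feature_id"].tolist()

    @property
    def universe(self) -> frozenset[str]:
        """All measured features — the sampling frame for the bootstrap."""
        return frozenset(self.table["feature_id"])


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (tab-separated: name, description, members...).

    Duplicate member ids within a line are collapsed; duplicate set names or
    lines with fewer than three fields raise :class:`GmtParseError` naming
    the offending line.
    """
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            set_id, description = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise GmtParseError(f"{path}:{lineno}: set {set_id!r} has no members")
            if set_id in sets:
                raise GmtParseError(f"{path}:{lineno}: duplicate set name {set_id!r}")
            sets[set_id] = GeneSet(set_id, description, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection in canonical GMT form (members sorted)."""
    path = Path(path)
    with path.open("w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.set_id, gs.description, *sorted(gs.members)]) + "\n")


def read_de_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> DEResult:
    """Read a delimited DE result table into a :class:`DEResult`.

    ``column_map`` maps the canonical names (feature_id, p, p_adj, logfc)
    onto the file's header names; identity by default. The delimiter is
    inferred from the extension (.csv -> comma, otherwise tab) unless given.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    column_map = dict(column_map or {})
    raw = pd.read_csv(path, sep=sep)
    rename = {}
    for canonical in DEResult.REQUIRED_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source not in raw.columns:
            raise ValueError(
                f"{path}: mapped column {source!r} (for {canonical!r}) not in header "
                f"{list(raw.columns)}"
            )
        rename[source] = canonical
    tab = raw.rename(columns=rename)[list(DEResult.REQUIRED_COLUMNS)].copy()
    tab["feature_id"] = tab["feature_id"].astype(str)
    for col in ("p", "p_adj", "logfc"):
        tab[col] = pd.to_numeric(tab[col], errors="raise")
    return DEResult(tab)


def write_de_table(de: DEResult, path: str | Path) -> None:
    de.table.to_csv(path, sep="\t", index=False)


def filter_collection(
    collection: GeneSetCollection,
    universe: Iterable[str],
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> GeneSetCollection:
    """Intersect every set with the measured universe and apply size filters.

    Sets whose post-intersection size falls outside [min_size, max_size] are
    dropped. Idempotent for a fixed universe and bounds.
    """
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    if max_size < min_size:
        raise ValueError(f"max_size ({max_size}) < min_size ({min_size})")
    uni = frozenset(universe)
    kept: dict[str, GeneSet] = {}
    for gs in collection:
        members = gs.members & uni
        if min_size <= len(members) <= max_size:
            kept[gs.set_id] = GeneSet(gs.set_id, gs.description, members)
    return GeneSetCollection(kept)
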