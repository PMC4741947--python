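"""Study-level ranked miRNA lists: reading, name standardization, reporting summaries.

Each eligible profiling study contributes up to two ordered lists of
significantly dysregulated miRNAs (one per direction of change); lists are
partial — every platform assays a different subset of the miRNA catalogue —
and rank 1 is the most significant entry. The aggregation unit is the *list*,
not the study: a study profiled on several platforms contributes several
lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "DROP",
    "StudyMeta",
    "RankedList",
    "StudyCollection",
    "ReportingSummary",
    "StandardizationReport",
    "read_ranklists",
    "write_ranklists",
    "standardize_names",
    "summarize_reporting",
]

#: Sentinel value in an alias table marking a raw name for removal
#: (viral miRNAs, non-miRNA probes).
DROP = "__DROP__"

DIRECTIONS = ("up", "down")
TISSUES = ("colon", "rectum", "colorectal")


@dataclass(frozen=True)
class StudyMeta:
    """Metadata for one profiling study."""

    study_id: str
    population: str = ""
    platform: str = ""
    tissue: str = "colorectal"
    n_tumor: int = 0
    n_normal: int = 0
    n_assayed: int = 1

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        if self.n_tumor < 0 or self.n_normal < 0:
            raise ValueError("sample counts must be nonnegative")
        if self.n_assayed < 1:
            raise ValueError("n_assayed must be >= 1")


@dataclass(frozen=True)
class RankedList:
    """One study x direction ordered list; ``items[0]`` has rank 1."""

    meta: StudyMeta
    direction: str
    items: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if len(set(self.items)) != len(self.items):
            dupes = sorted({x for x in self.items if self.items.count(x) > 1})
            raise ValueError(
                f"duplicate items in list {self.meta.study_id}/{self.direction}: {dupes}"
            )

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class StudyCollection:
    """A set of ranked lists over a shared miRNA universe.

    The universe defaults to the union of all list members; a fixed catalogue
    size (e.g. the 2588 mature human entries of a full miRNA registry
    release) may be imposed downstream through the aggregation model's
    ``universe_size`` argument instead.
    """

    lists: tuple[RankedList, ...]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            object.__setattr__(self, "universe", frozenset(self._union()))
        missing = self._union() - set(self.universe)
        if missing:
            raise ValueError(f"items outside universe: {sorted(missing)[:5]} ...")

    def _union(self) -> set[str]:
        out: set[str] = set()
        for rl in self.lists:
            out.update(rl.items)
        return out

    def lists_for(self, direction: str) -> tuple[RankedList, ...]:
        return tuple(rl for rl in self.lists if rl.direction == direction)

    def subset(self, tissue: str) -> "StudyCollection":
        """Lists whose study tissue matches; universe recomputed from the subset."""
        kept = tuple(rl for rl in self.lists if rl.meta.tissue == tissue)
        if not kept:
            raise ValueError(f"no lists with tissue {tissue!r}")
        return StudyCollection(lists=kept)

    @property
    def studies(self) -> tuple[StudyMeta, ...]:
        seen: dict[str, StudyMeta] = {}
        for rl in self.lists:
            seen.setdefault(rl.meta.study_id, rl.meta)
        return tuple(seen.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (rl.meta.study_id, rl.direction, rank, name)
            for rl in self.lists
            for rank, name in enumerate(rl.items, start=1)
        ]
        return pd.DataFrame(rows, columns=["study_id", "direction", "rank", "mirna"])


@dataclass(frozen=True)
class StandardizationReport:
    renamed: int
    dropped: int
    merged: int


@dataclass(frozen=True)
class ReportingSummary:
    """Tallies over a standardized collection (counts are per list, not per study)."""

    n_up_any: int
    n_down_any: int
    n_inconsistent: int
    datasets_per_mirna: dict[str, tuple[int, int]]
    sample_totals: tuple[int, int]
    median_samples: float
    mean_assayed: float


def read_ranklists(
    path,
    metadata_path=None,
    *,
    delimiter: str = "\t",
    universe: set[str] | None = None,
) -> StudyCollection:
    """Read a ranked-list table (columns study_id, direction, rank, mirna).

    Ranks must be contiguous from 1 within each (study, direction) group and
    no name may repeat within a group. An optional metadata table (columns
    study_id, population, platform, tissue, n_tumor, n_normal, n_assayed)
    attaches study annotations.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    required = {"study_id", "direction", "rank", "mirna"}
    if not required.issubset(df.columns):
        raise ValueError(f"missing columns: {sorted(required - set(df.columns))}")
    if df.empty:
        raise ValueError("no lists parsed: input file has no data rows")

    bad_dir = df.loc[~df["direction"].isin(DIRECTIONS)]
    if not bad_dir.empty:
        row = bad_dir.index[0]
        raise ValueError(
            f"unknown direction {bad_dir['direction'].iloc[0]!r} at row {row + 2}"
        )
    df["rank"] = df["rank"].astype(int)

    meta_by_id: dict[str, StudyMeta] = {}
    if metadata_path is not None:
        mdf = pd.read_csv(metadata_path, sep=delimiter)
        for rec in mdf.to_dict("records"):
            meta = StudyMeta(
                study_id=str(rec["study_id"]),
                population=str(rec.get("population", "")),
                platform=str(rec.get("platform", "")),
                tissue=str(rec.get("tissue", "colorectal")),
                n_tumor=int(rec.get("n_tumor", 0)),
                n_normal=int(rec.get("n_normal", 0)),
                n_assayed=int(rec.get("n_assayed", 1)),
            )
            meta_by_id[meta.study_id] = meta

    lists = []
    for (sid, direction), grp in df.groupby(["study_id", "direction"], sort=True):
        dup = grp["mirna"].duplicated()
        if dup.any():
            row = grp.index[dup][0]
            raise ValueError(
                f"duplicate ({sid}, {direction}, {grp.loc[row, 'mirna']}) at row {row + 2}"
            )
        grp = grp.sort_values("rank")
        ranks = grp["rank"].to_list()
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError(
                f"non-contiguous ranks for ({sid}, {direction}): got {ranks[:10]}"
            )
        meta = meta_by_id.get(str(sid), StudyMeta(study_id=str(sid)))
        lists.append(RankedList(meta=meta, direction=str(direction), items=tuple(grp["mirna"])))

    return StudyCollection(
        lists=tuple(lists),
        universe=frozenset(universe) if universe is not None else frozenset(),
    )


def write_ranklists(collection: StudyCollection, path, *, delimiter: str = "\t") -> None:
    collection.to_frame().to_csv(path, sep=delimiter, index=False)


def _standardize_one(rl: RankedList, alias: dict[str, str]) -> tuple[RankedList, int, int, int]:
    renamed = dropped = merged = 0
    seen: dict[str, int] = {}
    out: list[str] = []
    for name in rl.items:
        canon = alias.get(name, name)
        if canon == DROP:
            dropped += 1
            continue
        if canon != name:
            renamed += 1
        if canon in seen:
            merged += 1  # keep the better (earlier) rank
            continue
        seen[canon] = len(out)
        out.append(canon)
    return replace(rl, items=tuple(out)), renamed, dropped, merged


def standardize_names(
    collection: StudyCollection, alias_table: dict[str, str]
) -> tuple[StudyCollection, StandardizationReport]:
    """Apply a raw-name -> canonical-name alias table to every list.

    DROP-mapped entries are removed and ranks re-compacted; two raw names
    mapping onto one canonical name collapse to the better (smaller) rank.
    The table must be a single-step mapping: chains and aliases whose target
    is itself an alias key are rejected.
    """
    for raw, canon in alias_table.items():
        if canon == DROP:
            continue
        if canon in alias_table and alias_table[canon] != canon:
            raise ValueError(f"alias target {canon!r} is itself aliased (cycle or chain)")
        if raw == canon:
            raise ValueError(f"canonical name {raw!r} maps to itself in the alias table")

    new_lists = []
    renamed = dropped = merged = 0
    for rl in collection.lists:
        new_rl, r, d, m = _standardize_one(rl, alias_table)
        renamed += r
        dropped += d
        merged += m
        new_lists.append(new_rl)
    new = StudyCollection(lists=tuple(new_lists))
    return new, StandardizationReport(renamed=renamed, dropped=dropped, merged=merged)


def summarize_reporting(collection: StudyCollection) -> ReportingSummary:
    """Direction-wise reporting tallies over all lists of a collection."""
    per: dict[str, list[int]] = {}
    for rl in collection.lists:
        col = 0 if rl.direction == "up" else 1
        for name in rl.items:
            per.setdefault(name, [0, 0])[col] += 1

    up_any = {m for m, (u, d) in per.items() if u > 0}
    down_any = {m for m, (u, d) in per.items() if d > 0}
    studies = collection.studies
    per_study_samples = [s.n_tumor + s.n_normal for s in studies]
    return ReportingSummary(
        n_up_any=len(up_any),
        n_down_any=len(down_any),
        n_inconsistent=len(up_any & down_any),
        datasets_per_mirna={m: (u, d) for m, (u, d) in per.items()},
        sample_totals=(
            sum(s.n_tumor for s in studies),
            sum(s.n_normal for s in studies),
        ),
        median_samples=float(pd.Series(per_study_samples).median()) if studies else math.nan,
        mean_assayed=float(pd.Series([s.n_assayed for s in studies]).mean())
        if studies
        else math.nan,
    )
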