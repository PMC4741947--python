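"""Consensus target voting and hypergeometric gene-set enrichment.

Target genes of a miRNA are called by consensus across a roster of
prediction algorithms (a gene predicted by at least ``min_algorithms`` of
them) united with experimentally validated targets. The consensus set is
then tested for over-representation in pathway/GO gene sets with the
hypergeometric upper tail, Benjamini-Hochberg FDR across sets, an
overlap/set-size enrichment ratio, and a strict-threshold classifier for
disease-related pathways (ratio > 0.3 and p < 1e-5 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TargetPredictionTable",
    "GeneSetCollection",
    "ClusterResult",
    "read_gmt",
    "consensus_targets",
    "hypergeometric_enrichment",
    "bh_fdr",
    "classify_related",
    "cluster_enrichment_matrix",
    "volcano_frame",
]


@dataclass(frozen=True)
class TargetPredictionTable:
    """Gene x algorithm incidence grid plus a validated-gene set.

    ``incidence`` is a 0/1 DataFrame indexed by gene with one column per
    prediction algorithm (fixed roster, default five slots).
    """

    incidence: pd.DataFrame
    validated: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.incidence.empty and not self.incidence.isin([0, 1]).all().all():
            raise ValueError("incidence entries must be 0/1")

    @property
    def algorithms(self) -> tuple[str, ...]:
        return tuple(self.incidence.columns)


def consensus_targets(table: TargetPredictionTable, min_algorithms: int = 3) -> frozenset[str]:
    """Genes predicted by >= ``min_algorithms`` algorithms, united with the
    validated set."""
    if min_algorithms < 1:
        raise ValueError("min_algorithms must be >= 1")
    if not table.incidence.empty and len(table.algorithms) < min_algorithms:
        raise ValueError("algorithm roster smaller than min_algorithms")
    if table.incidence.empty:
        voted: set[str] = set()
    else:
        votes = table.incidence.sum(axis=1)
        voted = set(votes.index[votes >= min_algorithms].astype(str))
    return frozenset(voted | set(table.validated))


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets with a background universe (default: union of sets)."""

    sets: dict[str, tuple[str, frozenset[str]]]  # id -> (name, genes)
    background: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for sid, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {sid!r} is empty")
        if not self.background:
            union: set[str] = set()
            for _, genes in self.sets.values():
                union |= genes
            object.__setattr__(self, "background", frozenset(union))


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets from GMT (tab-delimited: id, description, genes...)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = (parts[1], frozenset(g for g in parts[2:] if g))
    return GeneSetCollection(sets=sets)


def hypergeometric_enrichment(
    query: set[str] | frozenset[str],
    collection: GeneSetCollection,
    *,
    ratio_mode: str = "set",
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query gene set in every set.

    For each set, p = P(X >= overlap) with X ~ Hypergeom(background_size,
    set_size, query_size). Query genes outside the background are dropped
    with a warning. The enrichment ratio is overlap/set_size
    (``ratio_mode="query"`` divides by the query size instead). Rows for all
    sets are returned, including zero overlaps, with BH q-values attached.
    """
    if ratio_mode not in ("set", "query"):
        raise ValueError(f"unknown ratio_mode {ratio_mode!r}")
    bg = set(collection.background)
    M = len(bg)
    outside = set(query) - bg
    if outside:
        warnings.warn(f"{len(outside)} query gene(s) outside background dropped")
    q = set(query) & bg
    n_query = len(q)

    rows = []
    for sid, (name, genes) in collection.sets.items():
        if len(genes) > M:
            raise ValueError(f"set {sid!r} larger than background")
        k = len(q & genes)
        p = float(stats.hypergeom.sf(k - 1, M, len(genes), n_query))
        denom = len(genes) if ratio_mode == "set" else max(n_query, 1)
        rows.append(
            {
                "set_id": sid,
                "set_name": name,
                "overlap": k,
                "set_size": len(genes),
                "query_size": n_query,
                "background_size": M,
                "p_value": min(p, 1.0),
                "enrichment_ratio": k / denom if denom else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    df["q_value"] = bh_fdr(df["p_value"].to_numpy()) if len(df) else []
    return df


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_related(
    rows: pd.DataFrame,
    *,
    ratio_threshold: float = 0.3,
    p_threshold: float = 1e-5,
) -> pd.DataFrame:
    """Flag rows with enrichment_ratio > ratio_threshold and p < p_threshold
    (both strict); adds the -log10 p column used for volcano export."""
    if ratio_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    out = rows.copy()
    out["related"] = (out["enrichment_ratio"] > ratio_threshold) & (
        out["p_value"] < p_threshold
    )
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p_value"])
    return out


def volcano_frame(rows: pd.DataFrame) -> pd.DataFrame:
    """(-log10 p, enrichment ratio, related) triples for volcano plotting."""
    need = {"neg_log10_p", "enrichment_ratio"}
    if not need.issubset(rows.columns):
        rows = classify_related(rows)
    return rows[["set_id", "enrichment_ratio", "neg_log10_p", "related"]].copy()


@dataclass(frozen=True)
class ClusterResult:
    row_order: tuple[str, ...]
    col_order: tuple[str, ...]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    excluded_rows: tuple[str, ...]


def _corr_linkage(frame: pd.DataFrame) -> np.ndarray:
    # distance = 1 - Pearson correlation, average linkage
    d = pdist(frame.to_numpy(dtype=float), metric="correlation")
    return hierarchy.linkage(d, method="average")


def cluster_enrichment_matrix(matrix: pd.DataFrame) -> ClusterResult:
    """Average-linkage clustering of an enrichment matrix (e.g. miRNA x
    pathway grid of -log10 q) with 1 - Pearson correlation distance, rows
    and columns independently. Zero-variance rows are excluded with a
    warning; an all-constant matrix is rejected."""
    var = matrix.std(axis=1, ddof=0)
    excluded = tuple(matrix.index[var == 0].astype(str))
    kept = matrix.loc[var > 0]
    if kept.shape[0] < 2:
        raise ValueError("need >= 2 non-constant rows to cluster")
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 columns to cluster")
    if excluded:
        warnings.warn(f"excluded {len(excluded)} zero-variance row(s)")

    row_link = _corr_linkage(kept)
    col_var = kept.std(axis=0, ddof=0)
    col_kept = kept.loc[:, col_var > 0]
    if col_kept.shape[1] < 2:
        raise ValueError("need >= 2 non-constant columns to cluster")
    col_link = _corr_linkage(col_kept.T)
    return ClusterResult(
        row_order=tuple(kept.index[hierarchy.leaves_list(row_link)].astype(str)),
        col_order=tuple(col_kept.columns[hierarchy.leaves_list(col_link)].astype(str)),
        row_linkage=row_link,
        col_linkage=col_link,
        excluded_rows=excluded,
    )
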