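"""Robust rank aggregation of partial ranked lists.

The statistic scores each item by comparing its positions across n ranked
lists with the null in which every list is an independent random shuffle of
the universe. An item's 1-based position p in a list becomes a normalized
rank r = p/N (N = universe size). Under the null the k-th smallest of the
item's observed normalized ranks behaves like the k-th order statistic of n
iid uniforms, whose distribution is Beta(k, n-k+1); the item's rho is the
minimum over k of these Beta tail probabilities. Taking a minimum over n
positions is corrected by a positional Bonferroni factor (x n, giving the
``score``), and item-level significance by a further universe-level factor
(x N, giving ``p_adjusted``).

Lists may be partial: items absent from a list are UNRANKED by default and
simply contribute no order statistic while n stays at the full list count.
``missing_as_worst`` instead imputes the worst possible rank r = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ranklists import StudyCollection

__all__ = [
    "UNRANKED",
    "RankVector",
    "normalize_ranks",
    "beta_scores",
    "rho_score",
    "RankAggregation",
    "AggregationResults",
    "aggregate",
    "mc_null_oracle",
]

#: Placeholder for an item missing from a list (NaN in rank vectors).
UNRANKED = np.nan


@dataclass(frozen=True)
class RankVector:
    """One item's normalized ranks across the lists of one direction."""

    item: str
    normalized_ranks: tuple[float, ...]  # NaN where unranked
    n_lists: int

    @property
    def n_observed(self) -> int:
        return int(np.sum(~np.isnan(self.normalized_ranks)))


def normalize_ranks(
    collection: StudyCollection,
    direction: str,
    universe_size: int | None = None,
) -> list[RankVector]:
    """Normalized-rank vectors for every item present in >=1 list of a direction."""
    lists = collection.lists_for(direction)
    if not lists:
        raise ValueError(f"no lists with direction {direction!r}")
    N = len(collection.universe) if universe_size is None else int(universe_size)
    longest = max(len(rl) for rl in lists)
    if N < longest:
        raise ValueError(f"universe size {N} smaller than longest list ({longest})")

    items = sorted({name for rl in lists for name in rl.items})
    idx = {name: i for i, name in enumerate(items)}
    R = np.full((len(items), len(lists)), np.nan)
    for j, rl in enumerate(lists):
        for pos, name in enumerate(rl.items, start=1):
            R[idx[name], j] = pos / N
    return [
        RankVector(item=name, normalized_ranks=tuple(R[i]), n_lists=len(lists))
        for name, i in idx.items()
    ]


def beta_scores(v: RankVector, *, missing_as_worst: bool = False) -> np.ndarray:
    """Beta order-statistic tail probabilities for one rank vector.

    The defined ranks sorted ascending r_(1) <= ... <= r_(k) give, at each
    position j, P(Beta(j, n-j+1) <= r_(j)) with n the full list count.
    """
    r = np.asarray(v.normalized_ranks, dtype=float)
    if missing_as_worst:
        r = np.where(np.isnan(r), 1.0, r)
    obs = np.sort(r[~np.isnan(r)])
    if obs.size == 0:
        raise ValueError(f"item {v.item!r} has no observed ranks")
    if np.any((obs <= 0) | (obs > 1)):
        raise ValueError("normalized ranks must lie in (0, 1]")
    j = np.arange(1, obs.size + 1)
    return stats.beta.cdf(obs, j, v.n_lists - j + 1)


def rho_score(v: RankVector, *, missing_as_worst: bool = False) -> tuple[float, float]:
    """(rho, positionally corrected score) for one rank vector."""
    rho = float(np.min(beta_scores(v, missing_as_worst=missing_as_worst)))
    return rho, min(1.0, rho * v.n_lists)


def _rho_matrix(R: np.ndarray, n_lists: int, missing_as_worst: bool) -> np.ndarray:
    """Vectorized rho over rows of a (items x lists) normalized-rank matrix."""
    if missing_as_worst:
        R = np.where(np.isnan(R), 1.0, R)
    S = np.sort(R, axis=1)  # NaN sort to the end
    j = np.arange(1, n_lists + 1)
    with np.errstate(invalid="ignore"):
        P = stats.beta.cdf(S, j, n_lists - j + 1)
    return np.nanmin(P, axis=1)


class RankAggregation:
    """Rank-aggregation model over the lists of one direction of a collection.

    Parameters
    ----------
    collection
        Standardized study collection.
    direction
        ``"up"`` or ``"down"``; each direction is aggregated independently.
    universe_size
        Overrides the collection-universe size N used both for rank
        normalization and for the universe-level Bonferroni multiplier.
    missing_as_worst
        Impute r = 1 for items absent from a list instead of leaving them
        unranked.
    """

    def __init__(
        self,
        collection: StudyCollection,
        direction: str,
        *,
        universe_size: int | None = None,
        missing_as_worst: bool = False,
    ):
        self.collection = collection
        self.direction = direction
        self.lists = collection.lists_for(direction)
        if not self.lists:
            raise ValueError(f"no lists with direction {direction!r}")
        self.n_lists = len(self.lists)
        self.universe_size = (
            len(collection.universe) if universe_size is None else int(universe_size)
        )
        longest = max(len(rl) for rl in self.lists)
        if self.universe_size < longest:
            raise ValueError(
                f"universe size {self.universe_size} smaller than longest list ({longest})"
            )
        self.missing_as_worst = missing_as_worst

    def _rank_matrix(self) -> tuple[list[str], np.ndarray]:
        items = sorted({name for rl in self.lists for name in rl.items})
        idx = {name: i for i, name in enumerate(items)}
        R = np.full((len(items), self.n_lists), np.nan)
        for j, rl in enumerate(self.lists):
            for pos, name in enumerate(rl.items, start=1):
                R[idx[name], j] = pos / self.universe_size
        return items, R

    def fit(self) -> "AggregationResults":
        items, R = self._rank_matrix()
        rho = _rho_matrix(R, self.n_lists, self.missing_as_worst)
        score = np.minimum(1.0, rho * self.n_lists)
        p_adj = np.minimum(1.0, score * self.universe_size)
        n_obs = np.sum(~np.isnan(R), axis=1).astype(int)
        frame = pd.DataFrame(
            {
                "mirna": items,
                "direction": self.direction,
                "rho": rho,
                "score": score,
                "p_adjusted": p_adj,
                "n_observed": n_obs,
            }
        ).sort_values(["p_adjusted", "mirna"], kind="mergesort", ignore_index=True)
        return AggregationResults(model=self, frame=frame)


@dataclass(frozen=True)
class AggregationResults:
    """Fitted aggregation: one row per item present in >=1 list, sorted by
    universe-adjusted p with a lexicographic name tie-break."""

    model: RankAggregation
    frame: pd.DataFrame

    @property
    def direction(self) -> str:
        return self.model.direction

    @property
    def n_lists(self) -> int:
        return self.model.n_lists

    @property
    def universe_size(self) -> int:
        return self.model.universe_size

    def p_adjusted(self) -> pd.Series:
        return self.frame.set_index("mirna")["p_adjusted"]

    def summary(self, top: int | None = 10) -> str:
        head = self.frame if top is None else self.frame.head(top)
        lines = [
            "Robust rank aggregation results",
            f"  direction: {self.direction}   lists: {self.n_lists}   "
            f"universe: {self.universe_size}   items scored: {len(self.frame)}",
            "",
            head.to_string(
                index=False,
                float_format=lambda x: f"{x:.4g}",
            ),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.10e")


def aggregate(
    collection: StudyCollection,
    direction: str,
    *,
    universe_size: int | None = None,
    missing_as_worst: bool = False,
) -> AggregationResults:
    """Convenience wrapper: fit :class:`RankAggregation` in one call."""
    return RankAggregation(
        collection,
        direction,
        universe_size=universe_size,
        missing_as_worst=missing_as_worst,
    ).fit()


def mc_null_oracle(
    n_lists: int,
    ranks: RankVector | tuple[float, ...],
    n_draws: int = 100_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Monte-Carlo estimate of the beta order-statistic tail probabilities.

    Draws ``n_lists`` iid uniforms ``n_draws`` times and estimates
    P(U_(j) <= r_(j)) for each observed sorted rank, with binomial standard
    errors. Serves as an independent simulation oracle for ``beta_scores``.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    r = np.asarray(
        ranks.normalized_ranks if isinstance(ranks, RankVector) else ranks, dtype=float
    )
    obs = np.sort(r[~np.isnan(r)])
    rng = np.random.default_rng(seed)
    U = np.sort(rng.random((n_draws, n_lists)), axis=1)
    est, se = [], []
    for j, rj in enumerate(obs):
        hit = U[:, j] <= rj
        p = hit.mean()
        est.append(p)
        se.append(np.sqrt(p * (1 - p) / n_draws))
    return pd.DataFrame({"position": np.arange(1, len(obs) + 1), "estimate": est, "se": se})
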