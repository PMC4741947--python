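"""Leave-one-out stability resampling and integrated-signature calling.

Aggregated p-values from a handful of heterogeneous lists can hinge on a
single input. The stability analysis repeats the aggregation many times with
one randomly chosen list of the direction removed each round and averages
each item's adjusted p over rounds; a signature member should stay
significant on average. Because only n distinct leave-one-out configurations
exist, an exhaustive mode (each list removed exactly once) gives the
seed-free expectation of the random average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ranklists import StudyCollection
from .rra import AggregationResults, RankAggregation, aggregate

__all__ = [
    "StabilityResult",
    "SignatureEntry",
    "SignatureCall",
    "jackknife_stability",
    "call_signature",
    "subset_analysis",
]


@dataclass(frozen=True)
class StabilityResult:
    item: str
    direction: str
    p_mean: float
    n_rounds: int
    seed: int | None


@dataclass(frozen=True)
class SignatureEntry:
    item: str
    direction: str
    p_adjusted: float
    p_stability: float | None
    n_datasets: int
    consistent: bool


@dataclass(frozen=True)
class SignatureCall:
    """Called signature plus the side report of significant-but-inconsistent items."""

    entries: tuple[SignatureEntry, ...]
    inconsistent_significant: tuple[SignatureEntry, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries])

    def summary(self) -> str:
        lines = [f"Integrated signature: {len(self.entries)} miRNAs"]
        for e in self.entries:
            stab = f"{e.p_stability:.3g}" if e.p_stability is not None else "-"
            lines.append(
                f"  {e.item:<18s} {e.direction:<5s} p_adj={e.p_adjusted:.3g} "
                f"p_stab={stab} datasets={e.n_datasets}"
            )
        if self.inconsistent_significant:
            lines.append(
                f"  ({len(self.inconsistent_significant)} significant item(s) excluded "
                "as direction-inconsistent)"
            )
        return "\n".join(lines)


def jackknife_stability(
    collection: StudyCollection,
    direction: str,
    *,
    n_rounds: int = 10_000,
    seed: int | None = None,
    mode: str = "random",
    universe_size: int | None = None,
    missing_as_worst: bool = False,
) -> list[StabilityResult]:
    """Average adjusted p over re-aggregations each omitting one list.

    ``mode="random"`` draws the removed list uniformly with replacement for
    ``n_rounds`` rounds (seeded); ``mode="exhaustive"`` removes each list
    exactly once. Items vanishing from every remaining list in a round
    contribute p = 1.0 (the most conservative value). The universe size of
    the full collection is retained in every round so per-round p-values are
    comparable with the full-collection ones.
    """
    lists = collection.lists_for(direction)
    n = len(lists)
    if n < 2:
        raise ValueError("cannot leave one out: need >= 2 lists of the direction")
    if mode not in ("random", "exhaustive"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "random" and n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")

    N = len(collection.universe) if universe_size is None else int(universe_size)
    items = sorted({name for rl in lists for name in rl.items})

    # Only n distinct leave-one-out configurations exist; compute each once
    # and weight by its draw count — identical to looping over rounds.
    if mode == "exhaustive":
        weights = np.ones(n)
        n_rounds = n
    else:
        rng = np.random.default_rng(seed)
        drawn = rng.integers(0, n, size=n_rounds)
        weights = np.bincount(drawn, minlength=n).astype(float)

    acc = np.zeros(len(items))
    idx = {name: i for i, name in enumerate(items)}
    others = collection.lists_for("up" if direction == "down" else "down")
    for k in range(n):
        if weights[k] == 0:
            continue
        remaining = tuple(rl for j, rl in enumerate(lists) if j != k)
        sub = StudyCollection(lists=remaining + others, universe=collection.universe)
        res = aggregate(
            sub, direction, universe_size=N, missing_as_worst=missing_as_worst
        )
        p = np.ones(len(items))
        for name, val in res.p_adjusted().items():
            p[idx[name]] = val
        acc += weights[k] * p
    p_mean = acc / float(n_rounds)

    return [
        StabilityResult(
            item=name,
            direction=direction,
            p_mean=float(p_mean[idx[name]]),
            n_rounds=int(n_rounds),
            seed=seed if mode == "random" else None,
        )
        for name in items
    ]


def call_signature(
    up: AggregationResults,
    down: AggregationResults,
    stability: list[StabilityResult] | None = None,
    *,
    alpha: float = 0.05,
    min_fraction_datasets: float | None = 0.5,
) -> SignatureCall:
    """Call integrated-signature miRNAs from the two direction-wise results.

    An item enters the signature iff its universe-adjusted p is below
    ``alpha``, it was never reported in the opposite direction, and (when the
    fraction filter is enabled) it was reported by at least
    ``ceil(min_fraction_datasets x n_lists)`` lists of its own direction.
    Items significant in one direction but reported in both are returned in
    the ``inconsistent_significant`` side report, never silently dropped.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    stab_map: dict[tuple[str, str], float] = {}
    for s in stability or []:
        stab_map[(s.item, s.direction)] = s.p_mean

    presence = {
        "up": set(up.frame["mirna"]),
        "down": set(down.frame["mirna"]),
    }
    entries: list[SignatureEntry] = []
    side: list[SignatureEntry] = []
    for res, other in ((up, "down"), (down, "up")):
        direction = res.direction
        n_lists = res.n_lists
        min_n = (
            math.ceil(min_fraction_datasets * n_lists)
            if min_fraction_datasets is not None
            else 0
        )
        sig = res.frame[res.frame["p_adjusted"] < alpha]
        for rec in sig.itertuples():
            consistent = rec.mirna not in presence[other]
            entry = SignatureEntry(
                item=rec.mirna,
                direction=direction,
                p_adjusted=float(rec.p_adjusted),
                p_stability=stab_map.get((rec.mirna, direction)),
                n_datasets=int(rec.n_observed),
                consistent=consistent,
            )
            if not consistent:
                side.append(entry)
            elif rec.n_observed >= min_n:
                entries.append(entry)
    entries.sort(key=lambda e: (e.direction, e.p_adjusted, e.item))
    side.sort(key=lambda e: (e.direction, e.p_adjusted, e.item))
    return SignatureCall(entries=tuple(entries), inconsistent_significant=tuple(side))


def subset_analysis(
    collection: StudyCollection,
    tissue: str,
    *,
    universe_size: int | None = None,
    missing_as_worst: bool = False,
) -> tuple[AggregationResults, AggregationResults]:
    """Re-run both direction-wise aggregations on the lists of one tissue.

    The universe is recomputed from the subset unless a fixed
    ``universe_size`` is imposed.
    """
    sub = collection.subset(tissue)
    return (
        aggregate(sub, "up", universe_size=universe_size, missing_as_worst=missing_as_worst),
        aggregate(sub, "down", universe_size=universe_size, missing_as_worst=missing_as_worst),
    )
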