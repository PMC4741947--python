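"""Leave-one-out stability resampling, signature calling, tissue subsets."""

import numpy as np
import pandas as pd
import pytest

from mirsig import (
    StudyCollection,
    aggregate,
    call_signature,
    jackknife_stability,
    simulate_ranked_studies,
    subset_analysis,
)
from mirsig.simulate import SimulationConfig

from conftest import build_collection


def _padded(lists, n_universe):
    names = sorted({x for items in lists.values() for x in items})
    universe = names + [f"pad{i}" for i in range(n_universe - len(names))]
    return build_collection(lists, meta={}, universe=universe)


class TestJackknife:
    def test_two_identical_lists_reduce_to_single_list(self):
        items = ["a", "b", "c"]
        coll = _padded({("A", "up"): items, ("B", "up"): items}, 50)
        stab = jackknife_stability(coll, "up", mode="exhaustive")
        single = aggregate(
            _padded({("A", "up"): items}, 50), "up", universe_size=50
        ).p_adjusted()
        for s in stab:
            assert s.p_mean == pytest.approx(single[s.item])

    def test_random_mode_deterministic_under_seed(self, small_collection):
        a = jackknife_stability(small_collection, "up", n_rounds=200, seed=11)
        b = jackknife_stability(small_collection, "up", n_rounds=200, seed=11)
        assert a == b
        c = jackknife_stability(small_collection, "up", n_rounds=200, seed=12)
        assert any(x.p_mean != y.p_mean for x, y in zip(a, c))

    def test_single_list_rejected(self):
        coll = build_collection({("S", "up"): ["a", "b"]}, meta={})
        with pytest.raises(ValueError, match="leave one out"):
            jackknife_stability(coll, "up")

    def test_random_mean_matches_exhaustive_expectation(self):
        """Random-mode p_mean at 10^4 rounds agrees with the exhaustive mean
        within 3 sample standard errors, item by item, on a 5-list fixture."""
        cfg = SimulationConfig(
            seed=5, n_studies=5, universe_size=60, coverage=1.0,
            list_length=(8, 12), n_planted_up=3, n_planted_down=3,
            signal_strength=1.5,
        )
        coll, _ = simulate_ranked_studies(cfg)
        n_rounds = 10_000
        exh = {s.item: s.p_mean for s in jackknife_stability(coll, "up", mode="exhaustive")}
        rnd = {
            s.item: s.p_mean
            for s in jackknife_stability(coll, "up", n_rounds=n_rounds, seed=3)
        }
        # per-configuration p-values, recomputed independently for the SE
        lists = coll.lists_for("up")
        configs = []
        for k in range(len(lists)):
            remaining = tuple(rl for j, rl in enumerate(lists) if j != k)
            sub = StudyCollection(
                lists=remaining + coll.lists_for("down"), universe=coll.universe
            )
            configs.append(aggregate(sub, "up", universe_size=len(coll.universe)).p_adjusted())
        per_config = pd.DataFrame(configs).fillna(1.0)
        for item, mean_rand in rnd.items():
            vals = per_config.get(item, pd.Series(1.0, index=per_config.index))
            se = vals.std(ddof=1) / np.sqrt(n_rounds)
            assert abs(mean_rand - exh[item]) <= 3 * se + 1e-12

    def test_item_lost_in_a_round_counts_as_one(self):
        # "x" appears only in list A; removing A must contribute p = 1.0
        coll = _padded({("A", "up"): ["x", "a"], ("B", "up"): ["a", "b"]}, 40)
        stab = {s.item: s.p_mean for s in jackknife_stability(coll, "up", mode="exhaustive")}
        single_b = aggregate(
            _padded({("B", "up"): ["a", "b"]}, 40), "up", universe_size=40
        ).p_adjusted()
        # round 1 removes A (x absent -> 1.0); round 2 removes B (x at rank 1 of A)
        single_a = aggregate(
            _padded({("A", "up"): ["x", "a"]}, 40), "up", universe_size=40
        ).p_adjusted()
        assert stab["x"] == pytest.approx((1.0 + single_a["x"]) / 2)
        assert stab["b"] == pytest.approx((single_b["b"] + 1.0) / 2)


def _signature_fixture():
    """3 up lists with X, Z leading; Z also shows up in one down list."""
    lists = {
        ("A", "up"): ["Z", "X", "f1"],
        ("B", "up"): ["Z", "X", "f2"],
        ("C", "up"): ["Z", "X", "f3"],
        ("A", "down"): ["Y", "g1"],
        ("B", "down"): ["Y", "Z"],
    }
    return _padded(lists, 100)


class TestCallSignature:
    def test_consistency_and_threshold_rules(self):
        coll = _signature_fixture()
        up = aggregate(coll, "up", universe_size=100)
        down = aggregate(coll, "down", universe_size=100)
        call = call_signature(up, down, alpha=0.05)
        called = {(e.item, e.direction) for e in call.entries}
        # X: p_adj = 3 * 0.02^3 * 100 = 2.4e-3 < 0.05, never reported down
        assert ("X", "up") in called
        x = next(e for e in call.entries if e.item == "X")
        assert x.n_datasets == 3 and x.consistent
        # Z: significant up but present in a down list -> side report only
        assert all(e.item != "Z" for e in call.entries)
        assert any(e.item == "Z" for e in call.inconsistent_significant)

    def test_nonsignificant_item_excluded(self):
        coll = _signature_fixture()
        up = aggregate(coll, "up", universe_size=100)
        down = aggregate(coll, "down", universe_size=100)
        call = call_signature(up, down, alpha=1e-4)
        assert all(e.p_adjusted < 1e-4 for e in call.entries)

    def test_min_fraction_filter(self):
        # W sits at rank 1 in 2 of 4 up lists: the >=1/2-datasets filter keeps
        # it (ceil(0.5 * 4) = 2) while a 0.75 fraction (ceil = 3) drops it.
        lists = {
            ("A", "up"): ["W", "f1"],
            ("B", "up"): ["W", "f2"],
            ("C", "up"): ["f3", "f4"],
            ("D", "up"): ["f5", "f6"],
            ("A", "down"): ["Y", "g1"],
            ("B", "down"): ["Y", "g2"],
        }
        coll = _padded(lists, 100)
        up = aggregate(coll, "up", universe_size=100)
        down = aggregate(coll, "down", universe_size=100)
        alpha = 0.5  # W's adjusted p is ~0.24: inside 0.5, handy for the filter check
        kept = call_signature(up, down, alpha=alpha, min_fraction_datasets=0.5)
        assert any(e.item == "W" and e.n_datasets == 2 for e in kept.entries)
        dropped = call_signature(up, down, alpha=alpha, min_fraction_datasets=0.75)
        assert all(e.item != "W" for e in dropped.entries)
        assert all(e.item != "W" for e in dropped.inconsistent_significant)

    def test_monotone_in_alpha(self):
        cfg = SimulationConfig(seed=9, n_studies=8, universe_size=120, signal_strength=2.0)
        coll, _ = simulate_ranked_studies(cfg)
        up = aggregate(coll, "up")
        down = aggregate(coll, "down")
        prev: set = set()
        for alpha in (1e-6, 1e-3, 0.05, 0.5):
            now = {
                (e.item, e.direction)
                for e in call_signature(up, down, alpha=alpha).entries
            }
            assert prev <= now
            prev = now

    def test_signature_and_side_report_disjoint(self):
        coll = _signature_fixture()
        up = aggregate(coll, "up", universe_size=100)
        down = aggregate(coll, "down", universe_size=100)
        call = call_signature(up, down)
        main = {(e.item, e.direction) for e in call.entries}
        side = {(e.item, e.direction) for e in call.inconsistent_significant}
        assert not main & side

    def test_stability_values_attached(self):
        coll = _signature_fixture()
        up = aggregate(coll, "up", universe_size=100)
        down = aggregate(coll, "down", universe_size=100)
        stab = jackknife_stability(coll, "up", mode="exhaustive", universe_size=100)
        call = call_signature(up, down, stab)
        x = next(e for e in call.entries if e.item == "X")
        assert x.p_stability is not None and 0 < x.p_stability <= 1


class TestSubsetAnalysis:
    def test_whole_collection_identity(self):
        lists = {
            ("A", "up"): ["a", "b"], ("B", "up"): ["a", "c"],
            ("A", "down"): ["d"], ("B", "down"): ["d"],
        }
        meta = {"A": dict(tissue="colon"), "B": dict(tissue="colon")}
        coll = build_collection(lists, meta=meta)
        up_sub, down_sub = subset_analysis(coll, "colon")
        assert up_sub.frame.equals(aggregate(coll, "up").frame)
        assert down_sub.frame.equals(aggregate(coll, "down").frame)

    def test_filter_counts(self):
        lists = {(f"S{i}", "up"): ["a", "b"] for i in range(4)}
        lists.update({(f"S{i}", "down"): ["c"] for i in range(4)})
        meta = {f"S{i}": dict(tissue="colon" if i < 2 else "rectum") for i in range(4)}
        coll = build_collection(lists, meta=meta)
        up_sub, _ = subset_analysis(coll, "colon")
        assert up_sub.n_lists == 2

    def test_empty_subset_rejected(self):
        coll = build_collection(
            {("A", "up"): ["a"]}, meta={"A": dict(tissue="colon")}
        )
        with pytest.raises(ValueError, match="rectum"):
            subset_analysis(coll, "rectum")

    def test_tissue_specific_signal(self):
        """A signal planted only in colon lists is significant only there."""
        rng = np.random.default_rng(2)
        universe = [f"m{i:03d}" for i in range(150)]
        lists, meta = {}, {}
        for i in range(8):
            tissue = "colon" if i < 4 else "rectum"
            fill = list(rng.choice(universe[1:], size=10, replace=False))
            if tissue == "colon":
                items = ["hit"] + fill
            elif i == 4:  # one rectum list reports it, at the bottom
                items = fill + ["hit"]
            else:
                items = fill
            lists[(f"S{i}", "up")] = items
            lists[(f"S{i}", "down")] = list(
                rng.choice(universe[60:], size=5, replace=False)
            )
            meta[f"S{i}"] = dict(tissue=tissue)
        coll = build_collection(lists, meta=meta, universe=universe + ["hit"])
        colon_up, _ = subset_analysis(coll, "colon", universe_size=151)
        rectum_up, _ = subset_analysis(coll, "rectum", universe_size=151)
        p_colon = colon_up.p_adjusted()["hit"]
        p_rectum = rectum_up.p_adjusted()["hit"]
        assert p_colon < 0.05 < p_rectum
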