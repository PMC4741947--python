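import pandas as pd
import pytest

from mirsig import RankedList, StudyCollection, StudyMeta

# 3 studies x 2 directions, 27 rows in the TSV fixture.
# Hand-counted facts used across tests:
#   distinct names: u1..u11 (11 up-reported) + d1..d8, and u2 also appears in
#   C's down list -> n_up_any = 11, n_down_any = 9, inconsistent = {u2}.
FIXTURE_LISTS = {
    ("A", "up"): ["u1", "u2", "u3", "u4", "u5"],
    ("A", "down"): ["d1", "d2", "d3", "d4"],
    ("B", "up"): ["u1", "u2", "u6", "u7", "u8"],
    ("B", "down"): ["d1", "d2", "d5", "d6"],
    ("C", "up"): ["u1", "u3", "u9", "u10", "u11"],
    ("C", "down"): ["d1", "d7", "d8", "u2"],
}

FIXTURE_META = {
    "A": dict(tissue="colon", n_tumor=30, n_normal=25, n_assayed=120),
    "B": dict(tissue="rectum", n_tumor=40, n_normal=40, n_assayed=150),
    "C": dict(tissue="colorectal", n_tumor=25, n_normal=20, n_assayed=100),
}


def build_collection(lists=FIXTURE_LISTS, meta=FIXTURE_META, universe=None) -> StudyCollection:
    rls = []
    for (sid, direction), items in lists.items():
        m = StudyMeta(study_id=sid, **meta.get(sid, {})) if meta else StudyMeta(study_id=sid)
        rls.append(RankedList(meta=m, direction=direction, items=tuple(items)))
    return StudyCollection(
        lists=tuple(rls), universe=frozenset(universe) if universe else frozenset()
    )


@pytest.fixture
def small_collection() -> StudyCollection:
    return build_collection()


@pytest.fixture
def ranklist_tsv(tmp_path):
    rows = [
        {"study_id": sid, "direction": direction, "rank": r, "mirna": name}
        for (sid, direction), items in FIXTURE_LISTS.items()
        for r, name in enumerate(items, start=1)
    ]
    path = tmp_path / "ranklists.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    meta_path = tmp_path / "metadata.tsv"
    pd.DataFrame(
        [{"study_id": sid, **m} for sid, m in FIXTURE_META.items()]
    ).to_csv(meta_path, sep="\t", index=False)
    return path, meta_path
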