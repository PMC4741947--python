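"""qPCR ΔΔCt fold-change analysis and expression-matrix group statistics.

Relative qPCR quantification follows the 2^-ΔΔCt convention: for each
patient the target miRNA's Ct is normalized to a reference small RNA
(default RNU6B) within tumor and within paired normal tissue, and the
tumor-normal difference of these ΔCt values is the patient's ΔΔCt. The
reported fold change is 2^-(mean ΔΔCt), i.e. the geometric mean of the
per-patient folds, and significance comes from a paired t-test of the
per-patient ΔΔCt values against zero.

Sequencing expression matrices (reads-per-million) are filtered for
missingness, log2-transformed with a pseudo-count, and compared between
clinical groups (tumor stage, lymphovascular invasion, microscopic vascular
invasion) with two-sample t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QPCR_COLUMNS",
    "FoldChangeResult",
    "ExpressionMatrix",
    "GroupComparison",
    "ddct_fold_change",
    "ddct_table",
    "filter_missingness",
    "log2_transform",
    "compare_groups",
]

QPCR_COLUMNS = (
    "patient_id",
    "mirna",
    "ct_target_tumor",
    "ct_ref_tumor",
    "ct_target_normal",
    "ct_ref_normal",
)


@dataclass(frozen=True)
class FoldChangeResult:
    mirna: str
    fold: float
    t_stat: float | None
    p_value: float | None
    n_pairs: int
    degenerate: bool = False

    def summary(self) -> str:
        p = f"{self.p_value:.4g}" if self.p_value is not None else "-"
        return (
            f"{self.mirna}: fold={self.fold:.4g} (2^-mean(ddCt), n={self.n_pairs} pairs), "
            f"paired t p={p}"
        )


def _ddct(records: pd.DataFrame) -> np.ndarray:
    d_t = records["ct_target_tumor"] - records["ct_ref_tumor"]
    d_n = records["ct_target_normal"] - records["ct_ref_normal"]
    return (d_t - d_n).to_numpy(dtype=float)


def ddct_fold_change(records: pd.DataFrame, mirna: str | None = None) -> FoldChangeResult:
    """2^-ΔΔCt fold change with a paired t-test for one miRNA.

    ``records`` holds one row per patient with the four Ct columns (see
    :data:`QPCR_COLUMNS`). With a single pair only the fold is returned; with
    zero ΔΔCt variance the test is flagged degenerate and p is undefined.
    """
    if mirna is not None:
        records = records[records["mirna"] == mirna]
    else:
        names = records["mirna"].unique() if "mirna" in records else ["?"]
        if len(names) > 1:
            raise ValueError("records span several miRNAs; pass mirna= or use ddct_table")
        mirna = str(names[0])
    records = records.dropna(subset=[c for c in QPCR_COLUMNS[2:]])
    if len(records) < 1:
        raise ValueError(f"no complete paired records for {mirna!r}")
    ct = records[list(QPCR_COLUMNS[2:])].to_numpy(dtype=float)
    if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
        raise ValueError("Ct values must be finite and positive")

    ddct = _ddct(records)
    fold = float(2.0 ** (-np.mean(ddct)))
    n = len(ddct)
    if n < 2:
        return FoldChangeResult(mirna, fold, None, None, n)
    if np.ptp(ddct) == 0:
        return FoldChangeResult(mirna, fold, None, None, n, degenerate=True)
    t, p = stats.ttest_1samp(ddct, 0.0)
    return FoldChangeResult(mirna, fold, float(t), float(p), n)


def ddct_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-miRNA fold-change table over a full qPCR cohort."""
    rows = [
        vars(ddct_fold_change(grp, str(name)))
        for name, grp in records.groupby("mirna", sort=True)
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ExpressionMatrix:
    """miRNA x sample expression grid with per-sample clinical annotations.

    ``values`` is indexed by miRNA with one column per sample (reads per
    million; NaN = missing); ``annotations`` is indexed by sample id with
    categorical columns such as ``group`` (tumor/normal), ``stage``
    (I/II vs III/IV), ``lvi`` and ``mvi`` (yes/no).
    """

    values: pd.DataFrame
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not self.annotations.empty:
            missing = set(self.values.columns) - set(self.annotations.index)
            if missing:
                raise ValueError(f"samples without annotation: {sorted(missing)[:5]}")


def filter_missingness(
    m: ExpressionMatrix, max_missing_fraction: float = 0.10
) -> tuple[ExpressionMatrix, pd.Series]:
    """Drop miRNAs whose missing fraction strictly exceeds the threshold.

    Returns the filtered matrix and the per-miRNA missing fractions of the
    removed rows.
    """
    if not (0 <= max_missing_fraction < 1):
        raise ValueError("max_missing_fraction must be in [0, 1)")
    frac = m.values.isna().mean(axis=1)
    removed = frac[frac > max_missing_fraction]
    kept = m.values.loc[frac <= max_missing_fraction]
    return ExpressionMatrix(values=kept, annotations=m.annotations), removed


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(x + offset) on every present value; missing values stay missing.

    Raw values must be nonnegative (reads-per-million); a negative entry is
    rejected with its coordinates.
    """
    if offset <= 0:
        raise ValueError("offset must be > 0")
    if (m.values < 0).any().any():
        bad = np.argwhere((m.values < 0).to_numpy())[0]
        raise ValueError(
            f"negative expression at ({m.values.index[bad[0]]}, "
            f"{m.values.columns[bad[1]]})"
        )
    return ExpressionMatrix(values=np.log2(m.values + offset), annotations=m.annotations)


@dataclass(frozen=True)
class GroupComparison:
    mirna: str
    annotation: str
    groups: tuple[str, str]
    group_sizes: tuple[int, int]
    mean_difference: float  # group2 - group1 under sorted label order
    t_stat: float | None
    p_value: float | None
    test: str
    degenerate: bool = False


def compare_groups(
    m: ExpressionMatrix,
    mirna: str,
    annotation: str,
    test: str = "welch",
) -> GroupComparison:
    """Two-sample t-test of one miRNA's expression between two annotation groups.

    Group labels are ordered lexicographically; the mean difference is
    group2 - group1 and the t statistic is signed as group1 - group2 (the
    usual two-sample convention with the first group first). ``test`` is
    ``"welch"`` (default, unequal variances) or ``"student"`` (pooled).
    """
    if test not in ("welch", "student"):
        raise ValueError(f"unknown test {test!r}")
    if mirna not in m.values.index:
        raise KeyError(mirna)
    labels = m.annotations[annotation].dropna()
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"annotation {annotation!r} has {len(uniq)} levels, need 2")
    g1 = m.values.loc[mirna, labels.index[labels == uniq[0]]].dropna().to_numpy(float)
    g2 = m.values.loc[mirna, labels.index[labels == uniq[1]]].dropna().to_numpy(float)
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both groups must be nonempty")

    base = dict(
        mirna=mirna,
        annotation=annotation,
        groups=(str(uniq[0]), str(uniq[1])),
        group_sizes=(len(g1), len(g2)),
        mean_difference=float(np.mean(g2) - np.mean(g1)),
        test=test,
    )
    if min(len(g1), len(g2)) < 2:
        return GroupComparison(**base, t_stat=None, p_value=None, degenerate=False)
    if np.ptp(g1) == 0 and np.ptp(g2) == 0:
        return GroupComparison(**base, t_stat=None, p_value=None, degenerate=True)
    t, p = stats.ttest_ind(g1, g2, equal_var=(test == "student"))
    return GroupComparison(**base, t_stat=float(t), p_value=float(p))
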