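"""Seeded generators for every input the pipeline consumes.

Each generator emulates the statistical structure of one real input with
planted, known truth so recovery can be verified end to end:

* ranked study lists — per study a latent differential-expression score per
  assayed miRNA (planted items shifted by ``signal_strength`` standard
  deviations, signed by direction) is ranked; the top of the ranking forms
  the up-regulated significant list and the bottom the down-regulated one.
  Coverage < 1 makes lists partial, as platform differences do in practice.
* survival cohorts — exponential event times under a proportional-hazards
  marker effect, with independent exponential right-censoring.
* paired qPCR cohorts — four Ct values per patient/miRNA constructed so the
  expected ΔΔCt equals a configured shift.
* expression matrices — log-normal reads-per-million with planted
  tumor/normal and clinical-group shifts and completely-at-random missing
  entries.
* target-prediction tables — latent true-target indicators observed by
  several algorithms whose sensitivity is driven by an agreement knob, with
  false positives at a base rate.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ranklists import RankedList, StudyCollection, StudyMeta, TISSUES
from .enrichment import TargetPredictionTable

__all__ = [
    "SurvivalConfig",
    "QpcrConfig",
    "TargetConfig",
    "SimulationConfig",
    "simulate_ranked_studies",
    "simulate_survival_cohort",
    "simulate_qpcr_cohort",
    "simulate_expression_cohort",
    "simulate_target_tables",
]


@dataclass(frozen=True)
class SurvivalConfig:
    n_subjects: int = 400
    true_hr: float = 1.875  # hazard ratio per unit of the standardized marker
    censoring_rate: float = 0.2
    baseline_rate: float = 0.1


@dataclass(frozen=True)
class QpcrConfig:
    n_patients: int = 11
    ddct_shifts: dict[str, float] = field(
        default_factory=lambda: {"miR-up": -1.0, "miR-down": 2.0, "miR-null": 0.0}
    )
    ct_noise_sd: float = 0.3


@dataclass(frozen=True)
class TargetConfig:
    n_genes: int = 500
    n_algorithms: int = 5
    base_rate: float = 0.05
    agreement: float = 0.8
    true_target_fraction: float = 0.2
    validated_fraction: float = 0.3


@dataclass(frozen=True)
class SimulationConfig:
    """Defaults reproduce the strong-signal benchmark condition: 20 studies
    over a 300-miRNA universe, 80% platform coverage, 10 up + 10 down
    planted miRNAs shifted by 3 noise standard deviations."""

    seed: int = 0
    n_studies: int = 20
    universe_size: int = 300
    coverage: float = 0.8
    list_length: tuple[int, int] = (20, 40)
    n_planted_up: int = 10
    n_planted_down: int = 10
    signal_strength: float = 3.0
    noise_sd: float = 1.0
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)
    targets: TargetConfig = field(default_factory=TargetConfig)

    def __post_init__(self) -> None:
        if not (0 < self.coverage <= 1):
            raise ValueError("coverage must be in (0, 1]")
        if self.n_planted_up + self.n_planted_down > self.universe_size:
            raise ValueError("planted items exceed universe")
        if self.survival.true_hr <= 0:
            raise ValueError("true_hr must be > 0")


def _mirna_names(n: int) -> list[str]:
    return [f"miR-{i:04d}" for i in range(n)]


def simulate_ranked_studies(
    config: SimulationConfig,
) -> tuple[StudyCollection, pd.DataFrame]:
    """Ranked significant lists for ``n_studies`` synthetic studies.

    Returns the collection and a truth table (mirna, status in
    {up, down, null}). Tissue labels rotate colon/rectum/colorectal so
    subset analyses have deterministic fixtures.
    """
    rng = np.random.default_rng(config.seed)
    names = np.array(_mirna_names(config.universe_size))
    planted_up = set(names[: config.n_planted_up])
    planted_down = set(names[config.n_planted_up : config.n_planted_up + config.n_planted_down])
    shift = np.zeros(config.universe_size)
    shift[: config.n_planted_up] = config.signal_strength
    shift[config.n_planted_up : config.n_planted_up + config.n_planted_down] = (
        -config.signal_strength
    )

    lists = []
    lo, hi = config.list_length
    for s in range(config.n_studies):
        n_assayed = int(round(config.coverage * config.universe_size))
        L = int(rng.integers(lo, hi + 1))
        if n_assayed < 2 * L:
            raise ValueError(
                f"coverage too low: study assays {n_assayed} items but needs {2 * L}"
            )
        assayed = rng.choice(config.universe_size, size=n_assayed, replace=False)
        study_noise = rng.uniform(0.8, 1.2)  # per-study noise heterogeneity
        score = shift[assayed] + rng.normal(0, config.noise_sd * study_noise, n_assayed)
        order = np.argsort(-score, kind="mergesort")
        meta = StudyMeta(
            study_id=f"S{s:02d}",
            platform=f"platform-{s % 5}",
            tissue=TISSUES[s % 3],
            n_tumor=int(rng.integers(15, 60)),
            n_normal=int(rng.integers(15, 60)),
            n_assayed=n_assayed,
        )
        up_items = tuple(names[assayed[order[:L]]])
        down_items = tuple(names[assayed[order[-L:]][::-1]])
        lists.append(RankedList(meta=meta, direction="up", items=up_items))
        lists.append(RankedList(meta=meta, direction="down", items=down_items))

    truth = pd.DataFrame(
        {
            "mirna": names,
            "status": [
                "up" if n in planted_up else "down" if n in planted_down else "null"
                for n in names
            ],
        }
    )
    collection = StudyCollection(lists=tuple(lists), universe=frozenset(names))
    return collection, truth


def simulate_survival_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Right-censored cohort with a standard-normal marker acting on the
    hazard with ratio ``true_hr`` per unit. Returns columns subject_id,
    time, event, marker."""
    sc = config.survival
    if sc.censoring_rate >= 1:
        raise ValueError("censoring_rate must be < 1")
    rng = np.random.default_rng(config.seed)
    marker = rng.normal(0, 1, sc.n_subjects)
    rate = sc.baseline_rate * np.exp(np.log(sc.true_hr) * marker)
    t_event = rng.exponential(1.0 / rate)
    if sc.censoring_rate > 0:
        # matches the target rate for a marker at the population centre
        c_rate = sc.baseline_rate * sc.censoring_rate / (1 - sc.censoring_rate)
        t_cens = rng.exponential(1.0 / c_rate, sc.n_subjects)
    else:
        t_cens = np.full(sc.n_subjects, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {
            "subject_id": [f"P{i:04d}" for i in range(sc.n_subjects)],
            "time": time,
            "event": event,
            "marker": marker,
        }
    )


def simulate_qpcr_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Paired Ct table whose expected per-patient ΔΔCt equals the configured
    shift for each miRNA (negative shift = up-regulated in tumor)."""
    qc = config.qpcr
    rng = np.random.default_rng(config.seed)
    rows = []
    for mirna, shift in qc.ddct_shifts.items():
        for i in range(qc.n_patients):
            ref_t = 20 + rng.normal(0, qc.ct_noise_sd)
            ref_n = 20 + rng.normal(0, qc.ct_noise_sd)
            tgt_n = ref_n + 5 + rng.normal(0, qc.ct_noise_sd)
            tgt_t = ref_t + 5 + shift + rng.normal(0, qc.ct_noise_sd)
            rows.append(
                {
                    "patient_id": f"CRC{i + 1:02d}",
                    "mirna": mirna,
                    "ct_target_tumor": tgt_t,
                    "ct_ref_tumor": ref_t,
                    "ct_target_normal": tgt_n,
                    "ct_ref_normal": ref_n,
                }
            )
    return pd.DataFrame(rows)


def simulate_expression_cohort(
    config: SimulationConfig,
    *,
    n_mirnas: int = 30,
    n_tumor: int = 60,
    n_normal: int = 30,
    tumor_shift_log2: float = 1.5,
    group_shift_log2: float = 0.8,
    missing_rates: tuple[float, ...] = (0.0, 0.05, 0.2),
):
    """Log-normal RPM matrix with planted tumor/normal and clinical-group
    shifts and MCAR missingness (per-miRNA rates cycling through
    ``missing_rates``, deliberately straddling the 10% filter)."""
    from .expression import ExpressionMatrix

    rng = np.random.default_rng(config.seed)
    mirnas = [f"miR-e{i:03d}" for i in range(n_mirnas)]
    samples = [f"T{i:03d}" for i in range(n_tumor)] + [f"N{i:03d}" for i in range(n_normal)]
    is_tumor = np.array([1] * n_tumor + [0] * n_normal)

    stage = np.where(rng.random(n_tumor + n_normal) < 0.5, "I/II", "III/IV")
    lvi = np.where(rng.random(n_tumor + n_normal) < 0.4, "yes", "no")
    mvi = np.where(rng.random(n_tumor + n_normal) < 0.3, "yes", "no")

    base = rng.uniform(3, 9, n_mirnas)  # log2 RPM baseline per miRNA
    log2x = base[:, None] + rng.normal(0, 1.0, (n_mirnas, len(samples)))
    # first third up in tumor, second third down, last third null
    third = n_mirnas // 3
    log2x[:third, :] += tumor_shift_log2 * is_tumor[None, :]
    log2x[third : 2 * third, :] -= tumor_shift_log2 * is_tumor[None, :]
    # plant a stage effect on the first miRNA, LVI on the second, MVI on the third
    log2x[0, :] += group_shift_log2 * (stage == "III/IV")
    log2x[1, :] += group_shift_log2 * (lvi == "yes")
    log2x[2, :] += group_shift_log2 * (mvi == "yes")

    values = pd.DataFrame(2.0 ** log2x, index=mirnas, columns=samples)
    for i in range(n_mirnas):
        rate = missing_rates[i % len(missing_rates)]
        if rate > 0:
            mask = rng.random(len(samples)) < rate
            values.iloc[i, mask] = np.nan

    annotations = pd.DataFrame(
        {
            "group": np.where(is_tumor == 1, "tumor", "normal"),
            "stage": stage,
            "lvi": lvi,
            "mvi": mvi,
            "survival_key": [f"P{i:04d}" for i in range(len(samples))],
        },
        index=samples,
    )
    return ExpressionMatrix(values=values, annotations=annotations)


def simulate_target_tables(
    config: SimulationConfig,
) -> tuple[TargetPredictionTable, frozenset[str]]:
    """Prediction table plus the latent true-target set.

    Each algorithm detects a true target with sensitivity
    ``agreement + (1 - agreement) * base_rate`` (so agreement 1 gives
    unanimous detection and agreement 0 makes true targets
    indistinguishable from the ``base_rate`` false-positive background) and
    predicts non-targets at ``base_rate``. The validated set is a random
    subset of the true targets.
    """
    tc = config.targets
    if tc.n_algorithms < 3:
        raise ValueError("need >= 3 algorithms")
    rng = np.random.default_rng(config.seed)
    genes = [f"GENE{i:04d}" for i in range(tc.n_genes)]
    true = rng.random(tc.n_genes) < tc.true_target_fraction
    sens = tc.agreement + (1 - tc.agreement) * tc.base_rate
    prob = np.where(true, sens, tc.base_rate)
    inc = (rng.random((tc.n_genes, tc.n_algorithms)) < prob[:, None]).astype(int)
    incidence = pd.DataFrame(
        inc, index=genes, columns=[f"algo{j + 1}" for j in range(tc.n_algorithms)]
    )
    true_set = frozenset(np.array(genes)[true])
    validated = frozenset(
        g for g in sorted(true_set) if rng.random() < tc.validated_fraction
    )
    return TargetPredictionTable(incidence=incidence, validated=validated), true_set
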