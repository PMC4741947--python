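"""Survival analysis: Kaplan-Meier curves, log-rank tests, maximally
selected cut-points with permutation correction, and univariate Cox fits.

The cut-point selector emulates the X-tile idea: scan every admissible
threshold of a continuous marker (midpoints between consecutive distinct
values whose low/high split keeps both groups above a minimum fraction of
the cohort) and keep the one maximizing the two-group log-rank χ². Because
the scan takes a maximum over many correlated tests, the raw minimum p is
anticonservative; a permutation p (marker values shuffled against the
survival outcomes, add-one corrected) restores finite-sample validity.

Ties between an event and a censoring at the same time are resolved events
first; tied event times use the Breslow convention in both the log-rank
variance and the Cox partial likelihood (Efron is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMCurve",
    "LogrankResult",
    "CutpointResult",
    "CoxPH",
    "CoxPHResults",
    "km_curve",
    "logrank",
    "optimal_cutpoint",
    "cox_fit",
]


def _as_arrays(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("time and event must be 1-d arrays of equal length")
    if np.any(t <= 0):
        raise ValueError("all times must be > 0")
    if not np.all(np.isin(e, (0, 1))):
        raise ValueError("event must be 0 (censored) or 1 (death)")
    return t, e


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    no_events: bool = False

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )

    def plot(self, ax=None, **kwargs):
        """Step plot of the survivor function."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.concatenate([[0.0], self.times])
        s = np.concatenate([[1.0], self.survival])
        ax.step(t, s, where="post", **kwargs)
        ax.set_xlabel("time")
        ax.set_ylabel("S(t)")
        ax.set_ylim(0, 1.05)
        return ax


def km_curve(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored subjects leave the risk set immediately after their time
    (events precede censoring at ties). With no events the curve is flat at
    1 and flagged.
    """
    t, e = _as_arrays(time, event)
    if t.size == 0:
        raise ValueError("need >= 1 record")
    ev_times = np.unique(t[e == 1])
    if ev_times.size == 0:
        return KMCurve(
            times=np.array([]),
            survival=np.array([]),
            at_risk=np.array([], dtype=int),
            n_events=np.array([], dtype=int),
            no_events=True,
        )
    at_risk = np.array([(t >= u).sum() for u in ev_times])
    d = np.array([((t == u) & (e == 1)).sum() for u in ev_times])
    surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(times=ev_times, survival=surv, at_risk=at_risk, n_events=d)


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p_value: float
    observed_a: float
    expected_a: float
    variance: float
    degenerate: bool = False


def logrank(time_a, event_a, time_b, event_b) -> LogrankResult:
    """Two-group log-rank test: χ² = (O_A - E_A)² / V with hypergeometric
    variance accumulated over the distinct event times (1 df)."""
    ta, ea = _as_arrays(time_a, event_a)
    tb, eb = _as_arrays(time_b, event_b)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("need >= 1 event overall")

    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros_like(ta), np.ones_like(tb)])  # 0 = A
    o_a = e_a = v = 0.0
    for u in np.unique(t[e == 1]):
        at = t >= u
        n = at.sum()
        n_a = (at & (g == 0)).sum()
        d = ((t == u) & (e == 1)).sum()
        d_a = ((t == u) & (e == 1) & (g == 0)).sum()
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            v += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if v == 0:
        return LogrankResult(0.0, 1.0, o_a, e_a, 0.0, degenerate=True)
    chi2 = (o_a - e_a) ** 2 / v
    return LogrankResult(
        chi2=float(chi2),
        p_value=float(stats.chi2.sf(chi2, df=1)),
        observed_a=float(o_a),
        expected_a=float(e_a),
        variance=float(v),
    )


def _logrank_chi2_all_cuts(t: np.ndarray, e: np.ndarray, high: np.ndarray) -> np.ndarray:
    """χ² for every candidate split at once.

    ``high`` is a (subjects x candidates) boolean matrix marking the
    high-marker group. Vectorizes the per-event-time accumulation across
    candidates.
    """
    chi2 = np.zeros(high.shape[1])
    o = np.zeros(high.shape[1])
    ex = np.zeros(high.shape[1])
    v = np.zeros(high.shape[1])
    for u in np.unique(t[e == 1]):
        at = t >= u
        n = at.sum()
        n_h = high[at].sum(axis=0).astype(float)
        mask = (t == u) & (e == 1)
        d = mask.sum()
        d_h = high[mask].sum(axis=0).astype(float)
        o += d_h
        ex += d * n_h / n
        if n > 1:
            v += d * (n_h / n) * (1 - n_h / n) * (n - d) / (n - 1)
    ok = v > 0
    chi2[ok] = (o[ok] - ex[ok]) ** 2 / v[ok]
    return chi2


@dataclass(frozen=True)
class CutpointResult:
    cutpoint: float
    chi2: float
    p_raw: float
    p_corrected: float | None
    group_sizes: tuple[int, int]  # (low, high)
    n_candidates: int

    def summary(self) -> str:
        pc = f"{self.p_corrected:.4g}" if self.p_corrected is not None else "-"
        return (
            f"optimal cut-point {self.cutpoint:.6g}: chi2={self.chi2:.4g}, "
            f"raw p={self.p_raw:.4g}, permutation-corrected p={pc}, "
            f"groups low/high = {self.group_sizes[0]}/{self.group_sizes[1]} "
            f"({self.n_candidates} candidates scanned)"
        )


def _candidates(marker: np.ndarray, min_group_fraction: float) -> np.ndarray:
    distinct = np.unique(marker)
    if distinct.size < 2:
        raise ValueError("marker is constant; no cut-point exists")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n = marker.size
    n_high = (marker[:, None] > mids[None, :]).sum(axis=0)
    n_low = n - n_high
    min_n = min_group_fraction * n
    ok = (n_low >= min_n) & (n_high >= min_n)
    if not ok.any():
        raise ValueError("no candidate cut-point satisfies the group-size constraint")
    return mids[ok]


def optimal_cutpoint(
    time,
    event,
    marker,
    *,
    min_group_fraction: float = 0.10,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> CutpointResult:
    """Maximally selected log-rank cut-point with permutation correction.

    Candidates are the midpoints between consecutive distinct marker values
    whose low/high split keeps both groups at or above
    ``min_group_fraction`` of the cohort. The selected cut-point maximizes
    the log-rank χ² (ties broken toward the smaller cut-point). The
    corrected p is the add-one permutation fraction of marker shuffles whose
    own maximal χ² reaches the observed maximum; ``n_permutations=0``
    skips the correction.
    """
    t, e = _as_arrays(time, event)
    m = np.asarray(marker, dtype=float)
    if m.shape != t.shape:
        raise ValueError("marker must align with time/event")
    if not (0 < min_group_fraction < 0.5):
        raise ValueError("min_group_fraction must be in (0, 0.5)")
    cand = _candidates(m, min_group_fraction)
    high = m[:, None] > cand[None, :]
    chi2 = _logrank_chi2_all_cuts(t, e, high)
    best = int(np.argmax(chi2))  # argmax takes the first = smallest cutpoint on ties
    obs = float(chi2[best])
    cut = float(cand[best])
    n_high = int(high[:, best].sum())

    p_corr = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(m.size)
            chi2_p = _logrank_chi2_all_cuts(t, e, high[perm])
            if chi2_p.max() >= obs:
                hits += 1
        p_corr = (hits + 1) / (n_permutations + 1)

    return CutpointResult(
        cutpoint=cut,
        chi2=obs,
        p_raw=float(stats.chi2.sf(obs, df=1)),
        p_corrected=p_corr,
        group_sizes=(m.size - n_high, n_high),
        n_candidates=cand.size,
    )


class CoxPH:
    """Univariate Cox proportional-hazards model.

    Maximizes the partial likelihood by Newton iteration from β = 0 with
    Breslow handling of tied event times (``ties="efron"`` available).
    """

    def __init__(self, time, event, covariate, *, ties: str = "breslow"):
        self.time, self.event = _as_arrays(time, event)
        self.covariate = np.asarray(covariate, dtype=float)
        if self.covariate.shape != self.time.shape:
            raise ValueError("covariate must align with time/event")
        if self.event.sum() < 2:
            raise ValueError("need >= 2 events")
        if np.ptp(self.covariate) == 0:
            raise ValueError("covariate is constant")
        if ties not in ("breslow", "efron"):
            raise ValueError(f"unknown tie method {ties!r}")
        self.ties = ties

    def loglik(self, beta: float) -> float:
        """Partial log-likelihood at a given β (used by brute-force checks)."""
        ll, _, _ = self._ll_score_info(beta)
        return ll

    def _ll_score_info(self, beta: float) -> tuple[float, float, float]:
        t, e, x = self.time, self.event, self.covariate
        order = np.argsort(-t, kind="mergesort")  # decreasing time
        ts, es, xs = t[order], e[order], x[order]
        w = np.exp(beta * xs)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * xs)
        s2 = np.cumsum(w * xs * xs)
        ll = score = info = 0.0
        i = 0
        n = ts.size
        while i < n:
            j = i
            while j < n and ts[j] == ts[i]:
                j += 1
            # risk set for this time = everything up to index j-1
            S0, S1, S2 = s0[j - 1], s1[j - 1], s2[j - 1]
            ev = np.arange(i, j)[es[i:j] == 1]
            d = ev.size
            if d:
                xd = xs[ev]
                if self.ties == "breslow":
                    ll += beta * xd.sum() - d * np.log(S0)
                    score += xd.sum() - d * S1 / S0
                    info += d * (S2 / S0 - (S1 / S0) ** 2)
                else:  # efron
                    wd = np.exp(beta * xd)
                    T0, T1, T2 = wd.sum(), (wd * xd).sum(), (wd * xd * xd).sum()
                    ll += beta * xd.sum()
                    score += xd.sum()
                    for k in range(d):
                        f = k / d
                        a0 = S0 - f * T0
                        a1 = S1 - f * T1
                        a2 = S2 - f * T2
                        ll -= np.log(a0)
                        score -= a1 / a0
                        info += a2 / a0 - (a1 / a0) ** 2
            i = j
        return float(ll), float(score), float(info)

    def fit(self, *, tol: float = 1e-8, maxiter: int = 50) -> "CoxPHResults":
        beta = 0.0
        converged = False
        flagged = False
        score = info = 0.0
        for _ in range(maxiter):
            _, score, info = self._ll_score_info(beta)
            if info <= 0:
                flagged = True
                break
            step = score / info
            beta += step
            if abs(beta) > 50 / max(np.std(self.covariate), 1e-12):
                flagged = True  # monotone likelihood / separation
                break
            if abs(score) < tol or abs(step) < tol:
                converged = True
                break
        _, _, info = self._ll_score_info(beta)
        se = float(np.sqrt(1.0 / info)) if info > 0 else np.inf
        return CoxPHResults(
            model=self,
            beta=float(beta),
            se=se,
            converged=converged,
            flagged=flagged or not converged,
        )


@dataclass(frozen=True)
class CoxPHResults:
    model: CoxPH
    beta: float
    se: float
    converged: bool
    flagged: bool

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.beta - 1.96 * self.se)),
            float(np.exp(self.beta + 1.96 * self.se)),
        )

    @property
    def p_value(self) -> float:
        z = self.beta / self.se
        return float(2 * stats.norm.sf(abs(z)))

    @property
    def n(self) -> int:
        return int(self.model.time.size)

    @property
    def n_events(self) -> int:
        return int(self.model.event.sum())

    def summary(self) -> str:
        lo, hi = self.ci95
        flag = "  [monotone likelihood / not converged]" if self.flagged else ""
        return (
            f"Cox PH ({self.model.ties} ties): n={self.n}, events={self.n_events}\n"
            f"  beta={self.beta:.4f}  se={self.se:.4f}  HR={self.hr:.3f} "
            f"(95% CI {lo:.3f}-{hi:.3f})  p={self.p_value:.4g}{flag}"
        )


def cox_fit(time, event, covariate, *, ties: str = "breslow") -> CoxPHResults:
    """Convenience wrapper: fit :class:`CoxPH` in one call."""
    return CoxPH(time, event, covariate, ties=ties).fit()
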