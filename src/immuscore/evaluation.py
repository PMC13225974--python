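"""Discrimination, reclassification, clinical-utility and power
statistics for benchmarking prognostic scores on censored outcomes.

Conventions: risk scores are oriented so that *higher risk implies
earlier death*; time is in months. The time-dependent AUC uses the
cumulative/dynamic definition with inverse-probability-of-censoring
weights (IPCW) from a Kaplan-Meier estimate of the censoring
distribution. The concordance index is Harrell's original pair-counting
estimator. Decision-curve net benefit under censoring replaces the
TP/FP counts by Kaplan-Meier event probabilities at the horizon within
the predicted-positive/negative strata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .survival import km_estimate

__all__ = [
    "ConcordanceResult",
    "TimeAUCResult",
    "ReclassificationResult",
    "harrell_c",
    "time_dependent_auc",
    "idi_nri",
    "decision_curve",
    "confusion_accuracy",
    "logrank_power",
]


# ---------------------------------------------------------------------------
# Harrell's C
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceResult:
    c_index: float
    usable_pairs: int
    concordant: int
    discordant: int
    tied_risk: int


def harrell_c(times, events, risk_scores) -> ConcordanceResult:
    """Harrell's concordance index.

    A pair is usable iff its ordering is determined under censoring: the
    member with the shorter time had an event (or, at a tied time,
    exactly one of the two had an event). A usable pair is concordant
    when the earlier death carries the higher risk score; tied risk
    scores contribute 1/2.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    r = np.asarray(risk_scores, dtype=float)
    if not (t.size == e.size == r.size):
        raise ValueError("input lengths differ")

    # usable pairs (i earlier-event, j later): t_i < t_j & e_i, or
    # t_i == t_j & e_i & not e_j
    ti, tj = t[:, None], t[None, :]
    ei, ej = e[:, None].astype(bool), e[None, :].astype(bool)
    ri, rj = r[:, None], r[None, :]
    usable = (ei & (ti < tj)) | (ei & ~ej & (ti == tj))
    concordant = int(np.sum(usable & (ri > rj)))
    discordant = int(np.sum(usable & (ri < rj)))
    tied = int(np.sum(usable & (ri == rj)))
    n_usable = concordant + discordant + tied
    if n_usable == 0:
        raise ValueError("no usable (orderable) pairs under censoring")
    c = (concordant + 0.5 * tied) / n_usable
    return ConcordanceResult(float(c), n_usable, concordant, discordant, tied)


# ---------------------------------------------------------------------------
# Time-dependent (cumulative/dynamic) AUC with IPCW
# ---------------------------------------------------------------------------


@dataclass
class TimeAUCResult:
    horizon: float
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    estimator: str = "ipcw-cumulative-dynamic"


def _censoring_km(times, events):
    """KM of the censoring distribution (event indicator flipped)."""
    return km_estimate(times, 1 - np.asarray(events).astype(int))


def time_dependent_auc(times, events, marker, horizon: float) -> TimeAUCResult:
    """Cumulative/dynamic AUC(t): discrimination of events by ``horizon``.

    Cases are subjects with an observed event at or before the horizon
    (IPCW weight 1/G(T_i-)); controls are subjects still under
    observation past the horizon (weight 1/G(t)). Without censoring all
    weights coincide and the estimate reduces to the empirical rank-sum
    AUC of event-by-horizon status. The AUC is computed as the
    trapezoidal area of its own ROC, so the two are consistent by
    construction.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    m = np.asarray(marker, dtype=float)
    if horizon <= 0 or horizon > t.max():
        raise ValueError("horizon must lie within the observed time range")
    cases = (t <= horizon) & (e == 1)
    controls = t > horizon
    if not cases.any():
        raise ValueError("no events observed before the horizon")
    if not controls.any():
        raise ValueError("no subjects under observation past the horizon")

    G = _censoring_km(t, e)
    w_case = 1.0 / np.maximum(G.evaluate_left(t[cases]), 1e-12)
    w_ctrl = np.full(controls.sum(), 1.0 / max(float(G.evaluate(horizon)), 1e-12))

    mc, wc = m[cases], np.atleast_1d(w_case)
    mn, wn = m[controls], w_ctrl

    # weighted ROC over descending marker thresholds
    thresholds = np.unique(np.concatenate([mc, mn]))[::-1]
    Wc, Wn = wc.sum(), wn.sum()
    tpr = [0.0]
    fpr = [0.0]
    for thr in thresholds:
        tpr.append(float(wc[mc >= thr].sum() / Wc))
        fpr.append(float(wn[mn >= thr].sum() / Wn))
    fpr = np.asarray(fpr)
    tpr = np.asarray(tpr)
    auc = float(np.trapezoid(tpr, fpr))
    return TimeAUCResult(float(horizon), auc, fpr, tpr)


# ---------------------------------------------------------------------------
# IDI / continuous NRI
# ---------------------------------------------------------------------------


@dataclass
class ReclassificationResult:
    idi: float
    nri: float
    nri_events: float
    nri_nonevents: float
    idi_ci: tuple
    nri_ci: tuple
    n_bootstrap: int


def _idi_nri_point(old, new, ev):
    events = ev == 1
    d = new - old
    idi = float(d[events].mean() - d[~events].mean())
    up = d > 0
    down = d < 0
    nri_e = float(up[events].mean() - down[events].mean())
    nri_ne = float(down[~events].mean() - up[~events].mean())
    return idi, nri_e + nri_ne, nri_e, nri_ne


def idi_nri(
    risk_old,
    risk_new,
    event_by_horizon,
    n_bootstrap: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ReclassificationResult:
    """Integrated discrimination improvement and continuous NRI.

    IDI = (mean risk gain | events) - (mean risk gain | non-events).
    Continuous (category-free) NRI sums the event and non-event net
    proportions of correctly directed risk moves. Percentile bootstrap
    CIs, seeded.
    """
    old = np.asarray(risk_old, dtype=float)
    new = np.asarray(risk_new, dtype=float)
    ev = np.asarray(event_by_horizon).astype(int)
    if not (old.size == new.size == ev.size):
        raise ValueError("input lengths differ")
    if old.min() < 0 or old.max() > 1 or new.min() < 0 or new.max() > 1:
        raise ValueError("risks must be probabilities in [0, 1]")
    if ev.sum() == 0 or ev.sum() == ev.size:
        raise ValueError("need at least one event and one non-event")

    idi, nri, nri_e, nri_ne = _idi_nri_point(old, new, ev)

    rng = np.random.default_rng(seed)
    boot = np.empty((n_bootstrap, 2))
    n = ev.size
    for b in range(n_bootstrap):
        while True:
            idx = rng.integers(0, n, n)
            if 0 < ev[idx].sum() < n:
                break
        bi, bn, *_ = _idi_nri_point(old[idx], new[idx], ev[idx])
        boot[b] = bi, bn
    qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
    idi_ci = tuple(np.percentile(boot[:, 0], qs))
    nri_ci = tuple(np.percentile(boot[:, 1], qs))
    return ReclassificationResult(
        idi, nri, nri_e, nri_ne, idi_ci, nri_ci, n_bootstrap
    )


# ---------------------------------------------------------------------------
# Decision-curve analysis
# ---------------------------------------------------------------------------


def decision_curve(
    risk_probs,
    times,
    events,
    horizon: float,
    thresholds=None,
) -> pd.DataFrame:
    """Net benefit NB(p_t) = TP/n - FP/n * p_t / (1 - p_t) across thresholds.

    Under censoring, TP/n and FP/n are estimated as
    P(risk >= p_t) * (1 - S_pos(horizon)) and P(risk >= p_t) * S_pos(horizon)
    with S_pos the Kaplan-Meier curve within the predicted-positive
    stratum; without censoring this reduces to direct counting.
    Treat-all and treat-none reference curves are included.
    """
    r = np.asarray(risk_probs, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("empty threshold grid")
    if thresholds.min() <= 0 or thresholds.max() >= 1:
        raise ValueError("thresholds must lie strictly inside (0, 1)")

    n = r.size

    def event_prob(mask):
        """KM event probability at the horizon within a stratum."""
        if not mask.any():
            return 0.0
        km = km_estimate(t[mask], e[mask])
        return 1.0 - float(km.evaluate(horizon))

    overall = event_prob(np.ones(n, dtype=bool))
    rows = []
    for pt in thresholds:
        odds = pt / (1 - pt)
        pos = r >= pt
        frac_pos = pos.mean()
        ev_pos = event_prob(pos)
        tp = frac_pos * ev_pos
        fp = frac_pos * (1 - ev_pos)
        rows.append(
            {
                "threshold": float(pt),
                "net_benefit": tp - fp * odds,
                "treat_all": overall - (1 - overall) * odds,
                "treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Confusion matrix / accuracy
# ---------------------------------------------------------------------------


@dataclass
class ConfusionResult:
    counts: pd.DataFrame
    accuracy_pct: float
    flow: pd.DataFrame


def confusion_accuracy(
    predicted_group,
    response_label,
    mapping: dict | None = None,
) -> ConfusionResult:
    """2x2 confusion of score group vs observed response.

    ``mapping`` states which response each predicted group is taken to
    forecast; the default {"High": "CR", "Low": "RR"} reflects CR cases
    clustering in the High-score group. Accuracy is the percent of
    correctly forecast patients; the flow table is the tabular form of
    an alluvial diagram.
    """
    pred = pd.Series(predicted_group).reset_index(drop=True)
    obs = pd.Series(response_label).reset_index(drop=True)
    if pred.empty or obs.empty:
        raise ValueError("empty input")
    if pred.size != obs.size:
        raise ValueError("input lengths differ")
    mapping = mapping or {"High": "CR", "Low": "RR"}
    unknown = set(pred.dropna()) - set(mapping)
    if unknown:
        raise ValueError(f"predicted groups without mapping: {sorted(unknown)}")
    if not set(obs.dropna()) & set(mapping.values()):
        raise ValueError(
            "observed labels share no values with the mapping targets "
            f"({sorted(set(mapping.values()))})"
        )
    keep = pred.notna() & obs.notna()
    pred, obs = pred[keep], obs[keep]
    counts = pd.crosstab(pred, obs).reindex(
        index=sorted(mapping), columns=sorted(set(mapping.values())), fill_value=0
    )
    correct = sum(
        counts.loc[g, mapping[g]] for g in counts.index if mapping[g] in counts
    )
    total = int(counts.to_numpy().sum())
    accuracy = 100.0 * correct / total
    flow = (
        pd.DataFrame({"group": pred.values, "response": obs.values})
        .value_counts()
        .rename("n")
        .reset_index()
        .sort_values(["group", "response"], kind="stable")
        .reset_index(drop=True)
    )
    return ConfusionResult(counts, float(accuracy), flow)


# ---------------------------------------------------------------------------
# Schoenfeld power / sample size
# ---------------------------------------------------------------------------


def logrank_power(
    hazard_ratio: float,
    alpha: float = 0.05,
    power: float = 0.80,
    allocation: float = 0.5,
    event_probability: float = 1.0,
) -> dict:
    """Schoenfeld events formula for a two-group log-rank comparison.

    d = (z_{1-a/2} + z_{1-b})^2 / (p (1-p) (log HR)^2), rounded up;
    n = ceil(d / overall event probability).
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard ratio must be positive")
    if hazard_ratio == 1.0:
        raise ValueError("hazard ratio of 1 requires infinite sample size")
    if not 0 < allocation < 1:
        raise ValueError("allocation fraction must lie in (0, 1)")
    if not 0 < event_probability <= 1:
        raise ValueError("event probability must lie in (0, 1]")
    za = stats.norm.ppf(1 - alpha / 2)
    zb = stats.norm.ppf(power)
    d = (za + zb) ** 2 / (
        allocation * (1 - allocation) * math.log(hazard_ratio) ** 2
    )
    events = int(math.ceil(d))
    n = int(math.ceil(events / event_probability))
    return {"required_events": events, "required_n": n}
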