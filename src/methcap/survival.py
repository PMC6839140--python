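"""Univariate survival analysis: Cox PH (Breslow ties), Kaplan-Meier, logrank,
per-site favorable/unfavorable direction calls and the averaged prognostic score.

The per-sample prognostic score is the fraction of signature sites at which
the sample occupies the survival-favorable dichotomized (median-split)
methylation state; it is used to stratify patients into two groups whose
10-year outcome is compared by logrank and a Cox hazard ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from methcap.methio import BetaMatrix, SurvivalTable, ValidationError

log = logging.getLogger(__name__)

_MAX_ABS_LOGHR = 15.0


@dataclass
class CoxResult:
    log_hr: float
    hr: float
    se: float
    wald_p: float
    logrank_p: float
    score_statistic: float
    converged: bool
    boundary: bool = False


def _breslow_quantities(beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Log-likelihood, score and information of the Breslow partial likelihood."""
    order = np.argsort(time, kind="mergesort")
    t, xs, ev = time[order], x[order], event[order]
    w = np.exp(beta * xs)
    # reverse cumulative sums => risk-set sums at each index (risk set = t_i >= t)
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w * xs)[::-1])[::-1]
    s2 = np.cumsum((w * xs * xs)[::-1])[::-1]
    # group tied event times: risk-set sums taken at the first index of each tie block
    loglik = score = info = 0.0
    i = 0
    n = t.size
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(ev[i:j].sum())
        if d > 0:
            xsum = float((xs[i:j] * ev[i:j]).sum())
            e1 = s1[i] / s0[i]
            loglik += beta * xsum - d * np.log(s0[i])
            score += xsum - d * e1
            info += d * (s2[i] / s0[i] - e1 * e1)
        i = j
    return loglik, score, info


def fit_cox_univariate(
    covariate: np.ndarray, clinical: SurvivalTable
) -> CoxResult:
    """Newton-Raphson fit of the univariate Cox model (Breslow ties).

    Also reports the score test at beta=0, which for a binary covariate with
    untied event times equals the classical logrank test.  Convergence is
    declared at |score| < 1e-8 or 50 iterations; a monotone likelihood is
    flagged and the estimate capped.
    """
    x = np.asarray(covariate, dtype=float)
    if x.shape != (len(clinical.sample_ids),):
        raise ValidationError("covariate length does not match clinical table")
    if not np.isfinite(x).all():
        raise ValidationError("covariate must be finite")
    n_events = int(clinical.event.sum())
    if n_events < 2:
        raise ValidationError(f"need >= 2 events, got {n_events}")

    time, event = clinical.time, clinical.event.astype(float)
    xc = x - x.mean()  # centering for numerical stability; beta unchanged

    _, u0, i0 = _breslow_quantities(0.0, xc, time, event)
    if i0 <= 0:
        # no covariate variation within risk sets
        return CoxResult(0.0, 1.0, np.inf, 1.0, 1.0, 0.0, True)
    score_stat = u0 * u0 / i0
    logrank_p = float(stats.chi2.sf(score_stat, df=1))

    beta = 0.0
    converged = False
    boundary = False
    for _ in range(50):
        _, u, info = _breslow_quantities(beta, xc, time, event)
        if abs(u) < 1e-8:
            converged = True
            break
        if info <= 0:
            boundary = True
            break
        step = u / info
        step = np.clip(step, -2.0, 2.0)  # damped to avoid overshoot
        beta += step
        if abs(beta) > _MAX_ABS_LOGHR:
            boundary = True
            beta = float(np.clip(beta, -_MAX_ABS_LOGHR, _MAX_ABS_LOGHR))
            log.warning("monotone partial likelihood; log-HR capped at %s", beta)
            break
    _, _, info = _breslow_quantities(beta, xc, time, event)
    se = float(1.0 / np.sqrt(info)) if info > 0 else np.inf
    wald_p = float(2.0 * stats.norm.sf(abs(beta) / se)) if np.isfinite(se) and se > 0 else 1.0
    return CoxResult(
        log_hr=float(beta),
        hr=float(np.exp(beta)),
        se=se,
        wald_p=wald_p,
        logrank_p=logrank_p,
        score_statistic=float(score_stat),
        converged=converged and not boundary,
        boundary=boundary,
    )


@dataclass
class KMCurve:
    """Product-limit estimate: right-continuous step function."""

    times: np.ndarray  # event times where S drops (prepended 0)
    survival: np.ndarray
    group: str | None = None

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def km_curve(
    clinical: SurvivalTable, group: dict[str, str] | None = None
) -> list[KMCurve]:
    """Kaplan-Meier curves, one per group (single curve when group is None)."""
    if group is None:
        members = {None: list(clinical.sample_ids)}
    else:
        members = {}
        for s in clinical.sample_ids:
            members.setdefault(group[s], []).append(s)
    curves = []
    for g, samples in sorted(members.items(), key=lambda kv: str(kv[0])):
        sub = clinical.subset(samples)
        if len(sub.sample_ids) < 1:
            raise ValidationError("empty group")
        order = np.argsort(sub.time, kind="mergesort")
        t, e = sub.time[order], sub.event[order]
        uniq = np.unique(t[e == 1])
        times = [0.0]
        surv = [1.0]
        s = 1.0
        for u in uniq:
            at_risk = int((t >= u).sum())
            d = int(((t == u) & (e == 1)).sum())
            s *= 1.0 - d / at_risk
            times.append(float(u))
            surv.append(s)
        curves.append(KMCurve(np.array(times), np.array(surv), None if g is None else str(g)))
    return curves


@dataclass
class SiteDirection:
    probe_id: str
    favorable_state: str  # 'high' | 'low'
    hr: float  # hazard of high vs low methylation
    p: float  # logrank p
    significant: bool


def site_directions(
    betas: BetaMatrix, clinical: SurvivalTable, alpha: float = 0.01
) -> list[SiteDirection]:
    """Per signature site: median-split the betas, Cox-fit high vs low, and
    call the lower-hazard state favorable (logrank p < alpha marks the site
    significant).  hr = 1 exactly ties to favorable_state='low' with a log.
    """
    if len(clinical.sample_ids) < 10 or int(clinical.event.sum()) < 2:
        raise ValidationError("need >= 10 samples with >= 2 events")
    sub = betas.select_samples(clinical.sample_ids)
    out: list[SiteDirection] = []
    for i, pid in enumerate(sub.probe_ids):
        row = sub.values[i]
        if np.nanstd(row) == 0:
            log.info("site %s skipped: zero variance", pid)
            continue
        high = (row > np.median(row)).astype(float)
        res = fit_cox_univariate(high, clinical)
        if res.hr == 1.0:
            log.info("site %s: hr exactly 1, favorable tie broken to 'low'", pid)
            favorable = "low"
        else:
            favorable = "low" if res.hr > 1.0 else "high"
        out.append(
            SiteDirection(
                probe_id=pid,
                favorable_state=favorable,
                hr=res.hr,
                p=res.logrank_p,
                significant=res.logrank_p < alpha,
            )
        )
    return out


@dataclass
class PrognosticScore:
    sample_id: str
    score: float
    n_sites_used: int


def prognostic_scores(
    betas: BetaMatrix,
    directions: list[SiteDirection],
    use_only_significant: bool = True,
) -> list[PrognosticScore]:
    """Average per-site favorable-state indicators (1/0) per sample."""
    used = [d for d in directions if d.significant] if use_only_significant else list(directions)
    if not used:
        raise ValidationError("no sites available for scoring")
    sub = betas.select_probes([d.probe_id for d in used])
    indicators = np.zeros((len(used), sub.n_samples))
    for i, d in enumerate(used):
        row = sub.values[i]
        high = row > np.median(row)
        indicators[i] = high if d.favorable_state == "high" else ~high
    scores = indicators.mean(axis=0)
    return [
        PrognosticScore(sample_id=s, score=float(v), n_sites_used=len(used))
        for s, v in zip(sub.sample_ids, scores)
    ]


def stratify_and_test(
    scores: list[PrognosticScore], clinical: SurvivalTable
) -> tuple[dict[str, str], float, float]:
    """Median-split the per-sample scores (ties to 'low') and compare groups.

    Returns (sample -> 'low'|'high', logrank p, Cox HR of the low-score
    group relative to the high-score group).
    """
    score_map = {s.sample_id: s.score for s in scores}
    vals = np.array([score_map[s] for s in clinical.sample_ids])
    if np.std(vals) == 0:
        raise ValidationError("all prognostic scores equal; cannot stratify")
    med = float(np.median(vals))
    group = {
        s: ("low" if score_map[s] <= med else "high") for s in clinical.sample_ids
    }
    if len(set(group.values())) < 2:
        # median equals the max: flip strict side
        group = {
            s: ("low" if score_map[s] < med else "high") for s in clinical.sample_ids
        }
    indicator = np.array([1.0 if group[s] == "low" else 0.0 for s in clinical.sample_ids])
    res = fit_cox_univariate(indicator, clinical)
    return group, res.logrank_p, res.hr
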