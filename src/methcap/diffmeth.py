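"""Moderated-t differential methylation, BH adjustment, signature derivation.

The per-probe two-sample statistic shrinks the pooled residual variance s^2
toward a prior (d0, s0^2) estimated across probes by moment-matching the
marginal distribution of log s^2 to a scaled log-F:

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)
    t_mod     = delta / (s_tilde * sqrt(1/n_a + 1/n_b))

with d = n_a + n_b - 2 residual degrees of freedom and two-sided p-values
from the t distribution on d0 + d degrees.  d0 = 0 recovers the ordinary
pooled t; d0 = inf fixes the variance at s0^2 (normal reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from methcap.methio import BetaMatrix, ProbeAnnotation, SubtypeLabels, ValidationError


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Moment-match log s^2 to a scaled log-F to get (d0, s0^2).

    Under s^2 ~ s0^2 * F(d, d0): E[log s^2] = log s0^2 + psi(d/2) - log(d/2)
    - psi(d0/2) + log(d0/2) and Var[log s^2] = psi'(d/2) + psi'(d0/2).
    Probes with s^2 = 0 are excluded from the moment fit.
    """
    s2 = np.asarray(s2, float)
    pos = s2[s2 > 0]
    if pos.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(pos)
    evar = float(np.var(z, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if evar <= 0:
        d0 = np.inf
        extra = 0.0
    else:
        d0 = 2.0 * trigamma_inverse(evar)
        extra = float(special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    log_s0sq = (
        float(np.mean(z))
        - float(special.digamma(d / 2.0))
        + np.log(d / 2.0)
        + extra
    )
    return d0, float(np.exp(log_s0sq))


def moderated_t_test(
    betas: BetaMatrix,
    group_a: list[str],
    group_b: list[str],
    d0_override: float | None = None,
    s0sq_override: float | None = None,
) -> pd.DataFrame:
    """Per-probe moderated t for group_a minus group_b.

    Returns a DataFrame indexed by probe_id with columns delta_beta, s2,
    t_mod, df_total, p, p_adj and direction ('hyper' iff delta_beta > 0,
    i.e. higher methylation in group_a).
    """
    if set(group_a) & set(group_b):
        raise ValidationError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("both groups need >= 2 samples")
    a = betas.select_samples(group_a).values
    b = betas.select_samples(group_b).values
    na, nb = a.shape[1], b.shape[1]
    d = na + nb - 2

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    delta = mean_a - mean_b
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / d

    if d0_override is not None:
        d0 = float(d0_override)
        s0sq = float(s0sq_override) if s0sq_override is not None else estimate_prior(s2, d)[1]
    else:
        d0, s0sq = estimate_prior(s2, d)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = float(d)
    else:
        s2_post = (d0 * s0sq + d * s2) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, delta / se, np.where(delta == 0, 0.0, np.inf * np.sign(delta)))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, 0.0, 1.0)

    res = pd.DataFrame(
        {
            "delta_beta": delta,
            "s2": s2,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "p_adj": bh_adjust(p),
            "direction": np.where(delta > 0, "hyper", "hypo"),
        },
        index=pd.Index(betas.probe_ids, name="probe_id"),
    )
    res.attrs["d0"] = d0
    res.attrs["s0sq"] = s0sq
    res.attrs["d_residual"] = d
    return res


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving with input."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0,1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass
class SignatureSet:
    """pCpGs concordantly significant in both TN contrasts, plus their genes.

    Direction convention: 'hyper' means higher methylation in the non-TN
    group relative to TN (both contrasts are oriented non-TN minus TN).
    """

    hyper_cpgs: set[str]
    hypo_cpgs: set[str]
    genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.hyper_cpgs & self.hypo_cpgs:
            raise ValidationError("hyper and hypo sets overlap")

    @property
    def probes(self) -> list[str]:
        return sorted(self.hyper_cpgs | self.hypo_cpgs)

    def __len__(self) -> int:
        return len(self.hyper_cpgs) + len(self.hypo_cpgs)


def derive_signature(
    luminal_vs_tn: pd.DataFrame,
    her2p_vs_tn: pd.DataFrame,
    alpha: float = 0.01,
    annot: ProbeAnnotation | None = None,
) -> SignatureSet:
    """Intersect the two TN contrasts at BH-adjusted p < alpha.

    A probe enters the signature when it is significant in BOTH contrasts
    with the SAME direction; discordant probes are excluded.  Gene symbols
    are mapped through the annotation when provided.
    """
    if list(luminal_vs_tn.index) != list(her2p_vs_tn.index):
        raise ValidationError("contrast probe universes differ")
    sig_a = luminal_vs_tn[luminal_vs_tn["p_adj"] < alpha]
    sig_b = her2p_vs_tn[her2p_vs_tn["p_adj"] < alpha]
    shared = sig_a.index.intersection(sig_b.index)
    dir_a = sig_a.loc[shared, "direction"]
    dir_b = sig_b.loc[shared, "direction"]
    concordant = shared[(dir_a == dir_b).to_numpy()]
    hyper = set(concordant[(dir_a.loc[concordant] == "hyper").to_numpy()])
    hypo = set(concordant) - hyper
    genes: set[str] = set()
    if annot is not None:
        for pid in hyper | hypo:
            g = annot.table.at[pid, "gene_symbol"]
            if g:
                genes.add(str(g))
    return SignatureSet(hyper_cpgs=hyper, hypo_cpgs=hypo, genes=genes)


def overall_profile_anova(
    betas: BetaMatrix, labels: SubtypeLabels
) -> tuple[pd.Series, float, float]:
    """Per-sample mean beta and one-way ANOVA of those means across subtypes.

    Returns (per-sample mean series, F, p).  With zero variance everywhere
    the statistic is undefined and returned as NaN.
    """
    labelled = [s for s in betas.sample_ids if s in labels.labels]
    sub = betas.select_samples(labelled)
    means = pd.Series(np.nanmean(sub.values, axis=0), index=labelled, name="mean_beta")
    groups = {}
    for s in labelled:
        groups.setdefault(labels.labels[s], []).append(means[s])
    if len(groups) < 2:
        raise ValidationError("ANOVA needs >= 2 subtype groups")
    if any(len(v) < 2 for v in groups.values()):
        raise ValidationError("ANOVA needs >= 2 samples per subtype")
    arrays = [np.asarray(v) for v in groups.values()]
    if all(np.ptp(np.concatenate(arrays)) == 0 for _ in (0,)):
        return means, float("nan"), float("nan")
    f, p = stats.f_oneway(*arrays)
    return means, float(f), float(p)
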