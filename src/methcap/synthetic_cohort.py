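"""Synthetic methylation/expression/clinical cohorts with planted structure.

Beta values are generated as logistic-transformed Gaussians on the M scale
(M = log2(beta/(1-beta))) so group effects compose additively there, while
the *targets* are specified on the beta scale: for each probe and group the
Gaussian mean is chosen (by quadrature-corrected inversion) so that the
expected back-transformed beta equals the requested group mean.  Planted
TN-differential probes are shifted by +/- effect_delta in the TN group only;
luminal-only probes are shifted in the luminal group only.  Expression for
genes of planted probes is negatively correlated with their promoter
methylation; survival follows an exponential model whose log hazard sums
per-site contributions of the unfavorable (above-median) methylation state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from methcap import methio
from methcap.methio import (
    HER2P,
    LUMINAL,
    SURVIVAL_CAP_MONTHS,
    TN,
    BetaMatrix,
    ProbeAnnotation,
    SubtypeLabels,
    SurvivalTable,
)


class ConfigError(ValueError):
    """A cohort configuration field violates its contract."""


@dataclass(frozen=True)
class CohortConfig:
    n_samples_per_subtype: tuple[int, int, int] = (40, 40, 40)  # TN, HER2p, luminal
    n_probes: int = 1000
    n_planted_tn: int = 50
    n_planted_luminal_only: int = 50
    effect_delta: float = 0.25
    noise_sd: float = 0.05
    meth_expr_rho: float = 0.7
    n_prognostic: int = 20
    hazard_log_hr: float = 0.0
    censor_rate: float = 0.3
    seed: int = 0
    #: seed for the planted structure (probe baselines, planted sets); defaults
    #: to ``seed``.  Two cohorts sharing structure_seed but differing in seed
    #: share planted probes/directions with independent noise — a discovery /
    #: validation pair.
    structure_seed: int | None = None

    def validate(self) -> None:
        counts = dict(
            n_probes=self.n_probes,
            n_planted_tn=self.n_planted_tn,
            n_planted_luminal_only=self.n_planted_luminal_only,
            n_prognostic=self.n_prognostic,
        )
        for name, v in counts.items():
            if v < 0:
                raise ConfigError(f"{name} must be >= 0, got {v}")
        if any(n < 0 for n in self.n_samples_per_subtype):
            raise ConfigError(
                f"n_samples_per_subtype must be >= 0, got {self.n_samples_per_subtype}"
            )
        if self.n_planted_tn + self.n_planted_luminal_only > self.n_probes:
            raise ConfigError(
                "n_planted_tn + n_planted_luminal_only exceeds n_probes"
            )
        if self.n_prognostic > self.n_probes:
            raise ConfigError("n_prognostic exceeds n_probes")
        if not (0 <= self.effect_delta < 1):
            raise ConfigError(f"effect_delta must be in [0,1), got {self.effect_delta}")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not (0 <= self.meth_expr_rho <= 1):
            raise ConfigError(f"meth_expr_rho must be in [0,1], got {self.meth_expr_rho}")
        if not (0 <= self.censor_rate < 1):
            raise ConfigError(f"censor_rate must be in [0,1), got {self.censor_rate}")


@dataclass
class PlantedTruth:
    tn_probes: list[str]
    tn_directions: dict[str, str]  # probe -> hyper|hypo (non-TN relative to TN)
    luminal_only_probes: list[str]
    prognostic_probes: list[str]
    prognostic_unfavorable: dict[str, str]  # probe -> high|low


@dataclass
class SyntheticCohort:
    betas: BetaMatrix
    expression: pd.DataFrame  # gene x sample
    annotation: ProbeAnnotation
    labels: SubtypeLabels
    receptor_status: dict[str, tuple[str, str, str]]
    clinical: SurvivalTable
    truth: PlantedTruth
    config: CohortConfig = field(repr=False, default=None)


_LN2 = np.log(2.0)
# Gauss-Hermite rule for E[logistic2(mu + sd*Z)], Z ~ N(0,1)
_GH_X, _GH_W = np.polynomial.hermite_e.hermegauss(31)
_GH_W = _GH_W / np.sqrt(2 * np.pi)


def beta_to_m(beta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    b = np.clip(beta, eps, 1 - eps)
    return np.log2(b / (1 - b))


def m_to_beta(m: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.power(2.0, -m))


def _expected_beta(mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """E[m_to_beta(N(mu, sd^2))] via Gauss-Hermite quadrature."""
    mu = np.asarray(mu, float)
    grid = mu[..., None] + np.asarray(sd, float)[..., None] * _GH_X
    return m_to_beta(grid) @ _GH_W


def _mu_for_target_beta(target: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Invert _expected_beta in mu so the beta-scale group mean hits *target*."""
    target = np.atleast_1d(np.asarray(target, float))
    sd = np.broadcast_to(np.asarray(sd, float), target.shape)
    out = np.empty_like(target)
    for i, (t, s) in enumerate(zip(target.ravel(), sd.ravel())):
        f = lambda mu: _expected_beta(np.array([mu]), np.array([s]))[0] - t
        out.ravel()[i] = brentq(f, -25.0, 25.0, xtol=1e-10)
    return out


def _m_scale_sd(target_beta: np.ndarray, noise_sd: float) -> np.ndarray:
    """M-scale sd giving approximately *noise_sd* dispersion on the beta scale."""
    b = np.clip(np.asarray(target_beta, float), 0.05, 0.95)
    slope = b * (1 - b) * _LN2  # d beta / d M
    return noise_sd / slope


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort deterministically from *config* (seed included)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    rng_structure = np.random.default_rng(
        config.seed if config.structure_seed is None else config.structure_seed
    )

    n_tn, n_her2p, n_lum = config.n_samples_per_subtype
    n = n_tn + n_her2p + n_lum
    p = config.n_probes

    sample_ids = [f"S{i:04d}" for i in range(n)]
    classes = [TN] * n_tn + [HER2P] * n_her2p + [LUMINAL] * n_lum
    receptor = {}
    for s, c in zip(sample_ids, classes):
        receptor[s] = {
            TN: ("-", "-", "-"),
            HER2P: ("-", "-", "+"),
            LUMINAL: ("+", "+", "-"),
        }[c]
    labels = methio.assign_subtypes(receptor)

    probe_ids = [f"cg{i:06d}" for i in range(p)]
    # two probes per gene so probe-to-gene collapse is exercised
    gene_ids = [f"G{i // 2:05d}" for i in range(p)]

    # baseline means: bimodal so peak normalization has two modes to anchor
    lo = rng_structure.uniform(0.10, 0.30, size=p)
    hi = rng_structure.uniform(0.70, 0.90, size=p)
    base = np.where(rng_structure.random(p) < 0.5, lo, hi)

    # planted sets
    order = rng_structure.permutation(p)
    tn_idx = order[: config.n_planted_tn]
    lum_idx = order[config.n_planted_tn : config.n_planted_tn + config.n_planted_luminal_only]

    # per-probe per-group target beta means; plants shift away from the boundary
    targets = np.tile(base[:, None], (1, 3))  # columns: TN, HER2p, luminal
    delta = config.effect_delta
    sign_tn = np.where(base[tn_idx] > 0.5, -1.0, 1.0)  # shift toward the open side
    targets[tn_idx, 0] = base[tn_idx]  # TN keeps base...
    targets[tn_idx, 1] = base[tn_idx] + sign_tn * delta  # non-TN groups shifted
    targets[tn_idx, 2] = base[tn_idx] + sign_tn * delta
    sign_lum = np.where(base[lum_idx] > 0.5, -1.0, 1.0)
    targets[lum_idx, 2] = base[lum_idx] + sign_lum * delta
    targets = np.clip(targets, 0.02, 0.98)

    tn_directions = {
        probe_ids[i]: ("hyper" if s > 0 else "hypo") for i, s in zip(tn_idx, sign_tn)
    }

    # Gaussian means on the M scale, corrected so beta-scale means hit targets
    sd_m = _m_scale_sd(targets, config.noise_sd)  # (p, 3)
    mu = np.empty_like(targets)
    for g in range(3):
        mu[:, g] = _mu_for_target_beta(targets[:, g], sd_m[:, g])

    group_of = np.array([0] * n_tn + [1] * n_her2p + [2] * n_lum)
    z = rng.standard_normal((p, n))
    m_vals = mu[:, group_of] + sd_m[:, group_of] * z
    betas_arr = m_to_beta(m_vals)
    betas = BetaMatrix(probe_ids, sample_ids, betas_arr)

    # expression: one row per gene; genes with a planted probe track it negatively
    genes = sorted(set(gene_ids))
    gene_rows = {g: [] for g in genes}
    for i, g in enumerate(gene_ids):
        gene_rows[g].append(i)
    planted = set(tn_idx.tolist()) | set(lum_idx.tolist())
    rho = config.meth_expr_rho
    expr = rng.standard_normal((len(genes), n))
    for gi, g in enumerate(genes):
        anchor = next((i for i in gene_rows[g] if i in planted), None)
        if anchor is None:
            continue
        mcol = m_vals[anchor]
        zstd = (mcol - mcol.mean()) / (mcol.std() or 1.0)
        expr[gi] = -rho * zstd + np.sqrt(max(0.0, 1 - rho**2)) * expr[gi]
    expression = pd.DataFrame(expr, index=genes, columns=sample_ids)
    expression.index.name = "gene_symbol"

    annotation = ProbeAnnotation(
        pd.DataFrame(
            {
                "gene_symbol": gene_ids,
                "chromosome": ["chr1"] * p,
                "snp_flag": [False] * p,
                "crossreactive_flag": [False] * p,
            },
            index=pd.Index(probe_ids, name="probe_id"),
        )
    )

    # survival: exponential hazard, log-hazard summed over planted prognostic
    # sites where the sample is in the unfavorable (above-median) state.
    # Prognostic sites are drawn from non-differential probes: subtype-shifted
    # probes have strongly dependent above-median indicators (hyper vs hypo
    # plants are anticorrelated), which would scramble marginal per-site
    # direction calls.
    prog_pool = [i for i in range(p) if i not in planted] + list(tn_idx)
    prog_idx = np.array(prog_pool[: config.n_prognostic], dtype=int)
    unfav = {probe_ids[i]: "high" for i in prog_idx}
    loghaz = np.zeros(n)
    for i in prog_idx:
        above = betas_arr[i] > np.median(betas_arr[i])
        loghaz += config.hazard_log_hr * above
    base_hazard = np.log(2.0) / 50.0  # median ~50 months at zero covariates
    lam = base_hazard * np.exp(loghaz)
    t_event = rng.exponential(1.0 / lam)

    if config.censor_rate > 0:
        c_max = _calibrate_censoring(lam, config.censor_rate)
        c_time = rng.uniform(0, c_max, size=n)
        event = (t_event <= c_time).astype(int)
        time = np.minimum(t_event, c_time)
    else:
        event = np.ones(n, dtype=int)
        time = t_event
    time = np.maximum(time, 1e-3)
    over = time > SURVIVAL_CAP_MONTHS
    event = np.where(over, 0, event)
    time = np.where(over, SURVIVAL_CAP_MONTHS, time)
    clinical = SurvivalTable(sample_ids, time, event)

    truth = PlantedTruth(
        tn_probes=[probe_ids[i] for i in tn_idx],
        tn_directions=tn_directions,
        luminal_only_probes=[probe_ids[i] for i in lum_idx],
        prognostic_probes=[probe_ids[i] for i in prog_idx],
        prognostic_unfavorable=unfav,
    )
    return SyntheticCohort(
        betas=betas,
        expression=expression,
        annotation=annotation,
        labels=labels,
        receptor_status=receptor,
        clinical=clinical,
        truth=truth,
        config=config,
    )


def _calibrate_censoring(lam: np.ndarray, rate: float) -> float:
    """Choose the U(0, c_max) censoring horizon hitting the requested rate.

    The realized censoring fraction includes the 120-month administrative
    cap: a subject is an observed event only when T <= min(C, cap).  For
    exponential event times P(event | lambda, c_max) has a closed form that
    is averaged over subjects and inverted by root finding.  Rates below the
    cap-only floor (everything that survives past 120 months is censored
    regardless) are unattainable; the horizon is then pushed out and the
    floor accepted.
    """
    cap = SURVIVAL_CAP_MONTHS

    def censored_frac(c: float) -> float:
        # P(censored | lam, c) = (1/c) * int_0^c exp(-lam * min(t, cap)) dt
        if c <= cap:
            inner = (1.0 - np.exp(-lam * c)) / lam
        else:
            inner = (1.0 - np.exp(-lam * cap)) / lam + (c - cap) * np.exp(-lam * cap)
        return float(np.mean(inner / c))

    floor = censored_frac(1e9)
    if rate <= floor + 1e-9:
        return 1e9
    return brentq(lambda c: censored_frac(c) - rate, 1e-6, 1e9, xtol=1e-6)


def write_fixture(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort in the TSV dialects the readers consume.

    Returns a manifest mapping artifact kind to path; the same mapping is
    written as a key=path listing in ``manifest.txt``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "betas": directory / "betas.tsv",
        "expression": directory / "expression.tsv",
        "annotation": directory / "annotation.tsv",
        "receptor_status": directory / "receptor_status.tsv",
        "clinical": directory / "clinical.tsv",
        "truth": directory / "truth.tsv",
    }
    methio.write_beta_matrix(cohort.betas, manifest["betas"])
    methio.write_matrix_tsv(cohort.expression, manifest["expression"])
    methio.write_annotation(cohort.annotation, manifest["annotation"])
    methio.write_receptor_status(cohort.receptor_status, manifest["receptor_status"])
    methio.write_clinical(cohort.clinical, manifest["clinical"])
    with open(manifest["truth"], "wt") as fh:
        fh.write("probe_id\tkind\tdetail\n")
        for pid in cohort.truth.tn_probes:
            fh.write(f"{pid}\tplanted_tn\t{cohort.truth.tn_directions[pid]}\n")
        for pid in cohort.truth.luminal_only_probes:
            fh.write(f"{pid}\tluminal_only\t.\n")
        for pid in cohort.truth.prognostic_probes:
            fh.write(f"{pid}\tprognostic\t{cohort.truth.prognostic_unfavorable[pid]}\n")
    with open(directory / "manifest.txt", "wt") as fh:
        for key, path in manifest.items():
            fh.write(f"{key}={path}\n")
    manifest["manifest"] = directory / "manifest.txt"
    return manifest
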