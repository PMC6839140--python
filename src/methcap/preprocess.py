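"""Probe QC filtering, peak-based normalization, and probe-to-gene collapse."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from methcap.methio import BetaMatrix, ProbeAnnotation, ValidationError
from methcap.synthetic_cohort import beta_to_m, m_to_beta

log = logging.getLogger(__name__)

SEX_CHROMOSOMES = {"chrX", "chrY", "X", "Y"}


@dataclass
class FilterReport:
    """Per-category removal tallies; each probe counted once, in listed order."""

    n_input_probes: int
    n_removed_detection: int
    n_removed_snp: int
    n_removed_crossreactive: int
    n_removed_sex_chromosome: int
    n_retained: int

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_detection
            + self.n_removed_snp
            + self.n_removed_crossreactive
            + self.n_removed_sex_chromosome
        )
        assert self.n_retained == self.n_input_probes - removed

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def filter_probes(
    betas: BetaMatrix,
    annot: ProbeAnnotation,
    detection_threshold: float = 0.01,
) -> tuple[BetaMatrix, FilterReport]:
    """Mask failed detections to null, then drop flagged / sex-chromosome /
    incomplete probes.

    Entries whose detection p exceeds *detection_threshold* are set to null;
    probes flagged SNP-associated or cross-reactive, probes on chrX/chrY, and
    probes left with any null entry (complete-case rule) are removed.  Each
    removed probe is tallied once, attributed to the first matching category
    in the order: detection/null, SNP, cross-reactive, sex chromosome.
    """
    missing = annot.covers(betas.probe_ids)
    if missing:
        raise ValidationError(
            f"{len(missing)} probes missing from annotation, e.g. {missing[:5]}"
        )
    values = betas.values.copy()
    if annot.detection_p is not None:
        det = annot.detection_p
        pidx = {p: i for i, p in enumerate(det.probe_ids)}
        sidx = {s: j for j, s in enumerate(det.sample_ids)}
        rows = [pidx[p] for p in betas.probe_ids]
        cols = [sidx[s] for s in betas.sample_ids]
        detv = det.values[np.ix_(rows, cols)]
        values[detv > detection_threshold] = np.nan

    tab = annot.table.loc[betas.probe_ids]
    has_null = np.isnan(values).any(axis=1)
    is_snp = tab["snp_flag"].to_numpy(bool)
    is_xr = tab["crossreactive_flag"].to_numpy(bool)
    is_sex = tab["chromosome"].isin(SEX_CHROMOSOMES).to_numpy()

    cat = np.full(len(betas.probe_ids), "", dtype=object)
    cat[is_sex] = "sex"
    cat[is_xr] = "crossreactive"
    cat[is_snp] = "snp"
    cat[has_null] = "detection"  # highest priority applied last

    keep = cat == ""
    report = FilterReport(
        n_input_probes=betas.n_probes,
        n_removed_detection=int((cat == "detection").sum()),
        n_removed_snp=int((cat == "snp").sum()),
        n_removed_crossreactive=int((cat == "crossreactive").sum()),
        n_removed_sex_chromosome=int((cat == "sex").sum()),
        n_retained=int(keep.sum()),
    )
    kept = BetaMatrix(
        [p for p, k in zip(betas.probe_ids, keep) if k],
        list(betas.sample_ids),
        values[keep],
    )
    return kept, report


MIN_PROBES_FOR_KDE = 30


def _two_peaks(m: np.ndarray, grid_size: int = 512) -> tuple[float, float] | None:
    """Locate the unmethylated (<0) and methylated (>0) modes of an M density.

    Returns None when the KDE does not show a local maximum on each side of
    zero (effectively unimodal for our purposes).
    """
    kde = gaussian_kde(m)
    lo, hi = m.min() - 1.0, m.max() + 1.0
    grid = np.linspace(lo, hi, grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = grid[1:-1][interior]
    pdens = dens[1:-1][interior]
    neg = peaks < 0
    pos = peaks > 0
    if not neg.any() or not pos.any():
        return None
    low = peaks[neg][np.argmax(pdens[neg])]
    high = peaks[pos][np.argmax(pdens[pos])]
    return float(low), float(high)


def peak_normalize(betas: BetaMatrix) -> BetaMatrix:
    """Align each sample's two M-value density modes to the cohort medians.

    Betas are mapped to M = log2(b/(1-b)); per sample the principal mode
    below 0 (unmethylated) and above 0 (methylated) are found by KDE; each
    sample's M values are affinely rescaled so its two peaks land on the
    cohort-median peak positions, then mapped back to betas.  Samples with
    an effectively unimodal density pass through unscaled with a warning.
    """
    if betas.n_probes < MIN_PROBES_FOR_KDE:
        raise ValidationError(
            f"peak normalization needs >= {MIN_PROBES_FOR_KDE} probes, "
            f"got {betas.n_probes}"
        )
    m = beta_to_m(betas.values)
    n = betas.n_samples
    peaks: list[tuple[float, float] | None] = []
    for j in range(n):
        col = m[:, j]
        col = col[~np.isnan(col)]
        peaks.append(_two_peaks(col))

    usable = [pk for pk in peaks if pk is not None]
    if not usable:
        log.warning("no sample shows two M-density modes; matrix passed through")
        return BetaMatrix(list(betas.probe_ids), list(betas.sample_ids), betas.values.copy())
    low_med = float(np.median([pk[0] for pk in usable]))
    high_med = float(np.median([pk[1] for pk in usable]))

    out = np.empty_like(m)
    for j in range(n):
        pk = peaks[j]
        if pk is None:
            log.warning(
                "sample %s: unimodal M density, passed through unscaled",
                betas.sample_ids[j],
            )
            out[:, j] = m[:, j]
            continue
        low, high = pk
        a = (high_med - low_med) / (high - low)
        b = low_med - a * low
        out[:, j] = a * m[:, j] + b
    vals = m_to_beta(out)
    nan_mask = np.isnan(betas.values)
    vals[nan_mask] = np.nan
    return BetaMatrix(list(betas.probe_ids), list(betas.sample_ids), vals)


@dataclass
class GeneMethMatrix:
    """Gene x sample betas with, per gene, the most negatively expression-
    correlated probe as provenance."""

    values: pd.DataFrame  # gene x sample
    chosen_probe: dict[str, str]
    chosen_r: dict[str, float]


def collapse_to_genes(
    betas: BetaMatrix,
    expression: pd.DataFrame,
    annot: ProbeAnnotation,
) -> GeneMethMatrix:
    """Keep, per gene, the probe whose beta correlates most negatively with
    that gene's expression over the shared samples."""
    shared = [s for s in betas.sample_ids if s in expression.columns]
    if len(shared) < 3:
        raise ValidationError(
            f"need >= 3 shared samples between betas and expression, got {len(shared)}"
        )
    bsub = betas.select_samples(shared)
    expr = expression[shared]

    tab = annot.table.loc[betas.probe_ids]
    gene_probes: dict[str, list[int]] = {}
    for i, (pid, gene) in enumerate(zip(betas.probe_ids, tab["gene_symbol"])):
        if not gene or gene not in expr.index:
            continue
        gene_probes.setdefault(str(gene), []).append(i)

    rows, chosen_probe, chosen_r = [], {}, {}
    for gene in sorted(gene_probes):
        y = expr.loc[gene].to_numpy(float)
        if np.std(y) == 0:
            log.info("gene %s skipped: zero-variance expression", gene)
            continue
        idxs = gene_probes[gene]
        rs = []
        for i in idxs:
            x = bsub.values[i]
            if np.std(x) == 0 or np.isnan(x).any():
                rs.append(np.nan)
            else:
                rs.append(float(np.corrcoef(x, y)[0, 1]))
        rs = np.array(rs)
        if np.isnan(rs).all():
            best = 0  # single/degenerate candidates: keep the first probe
        else:
            best = int(np.nanargmin(rs))
        i = idxs[best]
        rows.append((gene, bsub.values[i]))
        chosen_probe[gene] = betas.probe_ids[i]
        chosen_r[gene] = float(rs[best]) if not np.isnan(rs[best]) else np.nan
        if not np.isnan(rs[best]) and rs[best] > 0:
            log.info(
                "gene %s: no negatively correlated probe; kept %s (r=%.3f)",
                gene,
                chosen_probe[gene],
                rs[best],
            )
    values = pd.DataFrame(
        {g: v for g, v in rows}, index=shared
    ).T
    values.index.name = "gene_symbol"
    return GeneMethMatrix(values=values, chosen_probe=chosen_probe, chosen_r=chosen_r)
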