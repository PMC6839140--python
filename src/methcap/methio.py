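"""Matrix, annotation and clinical I/O plus receptor-status subtype assignment.

All on-disk formats are plain TSV with an explicit dialect: tab separator, no
quoting, ``#``-prefixed provenance/comment lines ignored.  Beta matrices are
probes x samples with the probe identifier in the first column and sample
identifiers in the header; missing values are written as ``null`` and read
back as NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TN = "TN"
HER2P = "HER2p"
LUMINAL = "luminal"
SUBTYPES = (TN, HER2P, LUMINAL)

#: months; survival beyond this horizon is administratively censored
SURVIVAL_CAP_MONTHS = 120.0

_MISSING_TOKENS = {"", "null", "NULL", "NA", "na", "NaN", "nan"}


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class ParseError(ValueError):
    """Raised for malformed on-disk inputs; carries the offending line number."""


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions in [0,1], NaN = missing."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("probe identifiers are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample identifiers are not unique")
        bad = np.where((self.values < 0) | (self.values > 1))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"beta value {self.values[i, j]} outside [0,1] at probe "
                f"{self.probe_ids[i]}, sample {self.sample_ids[j]}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    def select_probes(self, probes: Sequence[str]) -> "BetaMatrix":
        idx = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probes if p not in idx]
        if missing:
            raise ValidationError(f"probes not in matrix: {missing[:5]}")
        rows = [idx[p] for p in probes]
        return BetaMatrix(list(probes), list(self.sample_ids), self.values[rows])

    def select_samples(self, samples: Sequence[str]) -> "BetaMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing[:5]}")
        cols = [idx[s] for s in samples]
        return BetaMatrix(list(self.probe_ids), list(samples), self.values[:, cols])


@dataclass
class ProbeAnnotation:
    """Per-probe annotation; ``detection_p`` is an optional probes x samples matrix."""

    table: pd.DataFrame  # index=probe_id; columns gene_symbol, chromosome, snp_flag, crossreactive_flag
    detection_p: BetaMatrix | None = None

    REQUIRED = ("gene_symbol", "chromosome", "snp_flag", "crossreactive_flag")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValidationError(f"annotation missing column {col!r}")
        if self.table.index.has_duplicates:
            raise ValidationError("annotation probe_id not unique")

    def covers(self, probe_ids: Sequence[str]) -> list[str]:
        """Return probes from *probe_ids* absent from the annotation."""
        known = set(self.table.index)
        return [p for p in probe_ids if p not in known]


@dataclass
class SubtypeLabels:
    """sample_id -> subtype class; samples with unknown receptor status are excluded."""

    labels: dict[str, str]
    excluded: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {s: c for s, c in self.labels.items() if c not in SUBTYPES}
        if bad:
            raise ValidationError(f"unknown subtype classes: {bad}")

    def samples_of(self, subtype: str) -> list[str]:
        return [s for s, c in self.labels.items() if c == subtype]

    def binary_tn(self) -> dict[str, str]:
        """Collapse to the TN / non-TN framing."""
        return {s: (TN if c == TN else "nonTN") for s, c in self.labels.items()}


@dataclass
class SurvivalTable:
    """Per-sample time-to-event capped at 120 months with event indicator."""

    sample_ids: list[str]
    time: np.ndarray  # months, > 0, <= cap
    event: np.ndarray  # 1=death, 0=censored
    score: np.ndarray | None = None  # optional prognostic score in [0,1]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValidationError("time/event length does not match sample_ids")
        if np.any(self.time <= 0):
            bad = self.sample_ids[int(np.argmax(self.time <= 0))]
            raise ValidationError(f"non-positive survival time for sample {bad}")
        if not np.isin(self.event, (0, 1)).all():
            raise ValidationError("event indicator must be 0 or 1")
        if self.score is not None:
            self.score = np.asarray(self.score, dtype=float)
            if self.score.shape != (n,):
                raise ValidationError("score length does not match sample_ids")

    def subset(self, samples: Sequence[str]) -> "SurvivalTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in samples]
        return SurvivalTable(
            list(samples),
            self.time[rows],
            self.event[rows],
            None if self.score is None else self.score[rows],
        )


# ---------------------------------------------------------------------------
# readers / writers


def _data_lines(path: Path):
    with open(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#") or not line.strip():
                continue
            yield lineno, line


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    """Read a probes x samples beta TSV; empty/``null``/``NA`` cells become NaN."""
    path = Path(path)
    lines = _data_lines(path)
    try:
        _, header = next(lines)
    except StopIteration:
        raise ParseError(f"{path}: empty file") from None
    sample_ids = header.split("\t")[1:]
    ncol = len(sample_ids) + 1
    probe_ids: list[str] = []
    rows: list[np.ndarray] = []
    for lineno, line in lines:
        fields = line.split("\t")
        if len(fields) != ncol:
            raise ParseError(
                f"{path}:{lineno}: expected {ncol} fields, found {len(fields)}"
            )
        probe_ids.append(fields[0])
        row = np.array(
            [np.nan if f in _MISSING_TOKENS else float(f) for f in fields[1:]]
        )
        rows.append(row)
    values = (
        np.vstack(rows) if rows else np.empty((0, len(sample_ids)))
    )
    return BetaMatrix(probe_ids, sample_ids, values)


def write_beta_matrix(
    bm: BetaMatrix, path: str | Path, header_comment: str | None = None
) -> None:
    with open(path, "wt") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("probe_id\t" + "\t".join(bm.sample_ids) + "\n")
        for pid, row in zip(bm.probe_ids, bm.values):
            cells = ["null" if np.isnan(v) else format(v, ".17g") for v in row]
            fh.write(pid + "\t" + "\t".join(cells) + "\n")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Generic real-valued matrix TSV (e.g. expression, detection p), rows labelled."""
    return pd.read_csv(
        path, sep="\t", index_col=0, comment="#", float_precision="round_trip"
    )


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label=df.index.name or "id")


def read_annotation(
    path: str | Path, detection_path: str | Path | None = None
) -> ProbeAnnotation:
    table = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        comment="#",
        dtype={"gene_symbol": str, "chromosome": str},
        keep_default_na=False,
    )
    table["snp_flag"] = table["snp_flag"].astype(str).isin(("1", "True", "true"))
    table["crossreactive_flag"] = (
        table["crossreactive_flag"].astype(str).isin(("1", "True", "true"))
    )
    det = None
    if detection_path is not None:
        df = read_matrix_tsv(detection_path)
        det = BetaMatrix(list(df.index), list(df.columns), df.to_numpy(float))
    return ProbeAnnotation(table, det)


def write_annotation(annot: ProbeAnnotation, path: str | Path) -> None:
    out = annot.table.copy()
    out["snp_flag"] = out["snp_flag"].astype(int)
    out["crossreactive_flag"] = out["crossreactive_flag"].astype(int)
    out.to_csv(path, sep="\t", index_label="probe_id")


def assign_subtypes(
    receptor_status: Mapping[str, tuple[str, str, str]]
) -> SubtypeLabels:
    """Map per-sample (ER, PR, HER2) status in {'+','-','?'} to subtype labels.

    ER+ or PR+ (any HER2) -> luminal; ER-PR-HER2+ -> HER2p; ER-PR-HER2- -> TN.
    A sample whose deciding markers are unknown is excluded with a reason
    rather than guessed.
    """
    labels: dict[str, str] = {}
    excluded: dict[str, str] = {}
    for sample, (er, pr, her2) in receptor_status.items():
        for v in (er, pr, her2):
            if v not in ("+", "-", "?"):
                raise ValidationError(
                    f"sample {sample}: receptor status must be '+', '-' or '?', got {v!r}"
                )
        if er == "+" or pr == "+":
            labels[sample] = LUMINAL
        elif er == "?" or pr == "?":
            excluded[sample] = "ER or PR status unknown"
        elif her2 == "+":
            labels[sample] = HER2P
        elif her2 == "-":
            labels[sample] = TN
        else:
            excluded[sample] = "HER2 status unknown for ER-PR- sample"
    for sample, reason in excluded.items():
        log.info("excluding sample %s: %s", sample, reason)
    return SubtypeLabels(labels, excluded)


def read_receptor_status(path: str | Path) -> dict[str, tuple[str, str, str]]:
    """TSV with columns sample_id, er, pr, her2 (values '+', '-' or '?')."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return {
        row.sample_id: (row.er, row.pr, row.her2) for row in df.itertuples(index=False)
    }


def write_receptor_status(
    status: Mapping[str, tuple[str, str, str]], path: str | Path
) -> None:
    with open(path, "wt") as fh:
        fh.write("sample_id\ter\tpr\ther2\n")
        for sample, (er, pr, her2) in status.items():
            fh.write(f"{sample}\t{er}\t{pr}\t{her2}\n")


def read_clinical(path: str | Path) -> SurvivalTable:
    """Read sample_id / os_months / os_event TSV, capping follow-up at 120 months.

    Times above the cap are set to the cap with the event indicator cleared:
    a death after 10 years is not an event for 10-year overall survival.
    """
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    time = df["os_months"].to_numpy(float)
    event = df["os_event"].to_numpy(int)
    if np.any(time < 0):
        bad = df["sample_id"].iloc[int(np.argmax(time < 0))]
        raise ValidationError(f"negative survival time for sample {bad}")
    over = time > SURVIVAL_CAP_MONTHS
    event = np.where(over, 0, event)
    time = np.where(over, SURVIVAL_CAP_MONTHS, time)
    return SurvivalTable(list(df["sample_id"].astype(str)), time, event)


def write_clinical(table: SurvivalTable, path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("sample_id\tos_months\tos_event\n")
        for s, t, e in zip(table.sample_ids, table.time, table.event):
            fh.write(f"{s}\t{format(t, '.17g')}\t{int(e)}\n")
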