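"""End-to-end orchestration: preprocess -> differential methylation -> signature
-> clustering/PCA -> classification -> survival scoring -> enrichment."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from methcap import (
    classify_eval,
    cluster_purity,
    diffmeth,
    enrichment,
    methio,
    preprocess,
    survival,
)
from methcap.methio import HER2P, LUMINAL, TN, ValidationError

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; message carries stage name and cause."""


@dataclass
class PipelineConfig:
    discovery_betas: Path
    validation_betas: Path
    annotation: Path
    discovery_receptors: Path
    validation_receptors: Path
    discovery_clinical: Path
    gene_sets: Path | None = None
    detection_p: Path | None = None
    alpha_dm: float = 0.01
    alpha_surv: float = 0.01
    distance: str = "euclidean"
    max_k: int = 10
    n_trees: int = 200
    scan_trees: int | None = 50
    skip_peak_normalize: bool = False
    seed: int = 0
    raw: dict[str, str] = field(default_factory=dict, repr=False)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat key=value config file."""
        raw: dict[str, str] = {}
        base = Path(path).parent
        with open(path, "rt") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValidationError(f"config line without '=': {line!r}")
                key, _, val = line.partition("=")
                raw[key.strip()] = val.strip()

        def p(key, required=True):
            if key not in raw:
                if required:
                    raise ValidationError(f"config missing required key {key!r}")
                return None
            candidate = Path(raw[key])
            return candidate if candidate.is_absolute() else base / candidate

        cfg = cls(
            discovery_betas=p("discovery_betas"),
            validation_betas=p("validation_betas"),
            annotation=p("annotation"),
            discovery_receptors=p("discovery_receptors"),
            validation_receptors=p("validation_receptors"),
            discovery_clinical=p("discovery_clinical"),
            gene_sets=p("gene_sets", required=False),
            detection_p=p("detection_p", required=False),
            alpha_dm=float(raw.get("alpha_dm", 0.01)),
            alpha_surv=float(raw.get("alpha_surv", 0.01)),
            distance=raw.get("distance", "euclidean"),
            max_k=int(raw.get("max_k", 10)),
            n_trees=int(raw.get("n_trees", 200)),
            scan_trees=int(raw["scan_trees"]) if "scan_trees" in raw else 50,
            skip_peak_normalize=raw.get("skip_peak_normalize", "0") in ("1", "true", "True"),
            seed=int(raw.get("seed", 0)),
            raw=raw,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key in (
            "discovery_betas",
            "validation_betas",
            "annotation",
            "discovery_receptors",
            "validation_receptors",
            "discovery_clinical",
        ):
            path = getattr(self, key)
            if not Path(path).exists():
                raise ValidationError(f"config path {key}={path} does not exist")
        for key in ("alpha_dm", "alpha_surv"):
            v = getattr(self, key)
            if not (0 < v < 1):
                raise ValidationError(f"{key} must be in (0,1), got {v}")

    def content_hash(self) -> str:
        items = sorted(self.raw.items()) if self.raw else sorted(
            (k, str(v)) for k, v in self.__dict__.items() if k != "raw"
        )
        blob = "\n".join(f"{k}={v}" for k, v in items).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, stage: str, cfg_hash: str, index=True) -> None:
    with open(path, "wt") as fh:
        fh.write(f"# methcap stage={stage} config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, object]:
    """Execute every stage, writing TSV outputs plus ``summary.tsv`` to *outdir*.

    An empty signature downgrades the signature-dependent stages to a logged
    skip instead of an error so null cohorts complete cleanly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.content_hash()
    summary: dict[str, object] = {"config_hash": h}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # -- load ---------------------------------------------------------------
    def _load():
        disc = methio.read_beta_matrix(config.discovery_betas)
        val = methio.read_beta_matrix(config.validation_betas)
        annot = methio.read_annotation(config.annotation, config.detection_p)
        disc_labels = methio.assign_subtypes(
            methio.read_receptor_status(config.discovery_receptors)
        )
        val_labels = methio.assign_subtypes(
            methio.read_receptor_status(config.validation_receptors)
        )
        clinical = methio.read_clinical(config.discovery_clinical)
        return disc, val, annot, disc_labels, val_labels, clinical

    disc, val, annot, disc_labels, val_labels, clinical = stage("load")(_load)

    # -- preprocess ---------------------------------------------------------
    def _preprocess():
        filtered, report = preprocess.filter_probes(disc, annot)
        if not config.skip_peak_normalize:
            filtered = preprocess.peak_normalize(filtered)
        _write_tsv(report.to_frame(), outdir / "filter_report.tsv", "preprocess", h, index=False)
        return filtered, report

    filtered, filter_report = stage("preprocess")(_preprocess)
    summary["n_probes_retained"] = filter_report.n_retained
    log.info("preprocess: %d/%d probes retained", filter_report.n_retained, filter_report.n_input_probes)

    # -- differential methylation -------------------------------------------
    def _diffmeth():
        tn = disc_labels.samples_of(TN)
        lum = disc_labels.samples_of(LUMINAL)
        her2p = disc_labels.samples_of(HER2P)
        res_lum = diffmeth.moderated_t_test(filtered, lum, tn)
        res_her2 = diffmeth.moderated_t_test(filtered, her2p, tn)
        sig = diffmeth.derive_signature(res_lum, res_her2, config.alpha_dm, annot)
        _write_tsv(res_lum, outdir / "diffmeth_luminal_vs_tn.tsv", "diffmeth", h)
        _write_tsv(res_her2, outdir / "diffmeth_her2p_vs_tn.tsv", "diffmeth", h)
        sig_df = pd.DataFrame(
            sorted(
                [(p, "hyper") for p in sig.hyper_cpgs]
                + [(p, "hypo") for p in sig.hypo_cpgs]
            ),
            columns=["probe_id", "direction"],
        )
        _write_tsv(sig_df, outdir / "signature.tsv", "diffmeth", h, index=False)
        _write_tsv(
            pd.DataFrame(sorted(sig.genes), columns=["gene_symbol"]),
            outdir / "signature_genes.tsv",
            "diffmeth",
            h,
            index=False,
        )
        return sig

    signature = stage("diffmeth")(_diffmeth)
    summary["n_signature_cpgs"] = len(signature)
    summary["n_signature_genes"] = len(signature.genes)
    log.info("signature: %d CpGs (%d hyper / %d hypo), %d genes",
             len(signature), len(signature.hyper_cpgs), len(signature.hypo_cpgs),
             len(signature.genes))

    if len(signature) == 0:
        log.warning("empty signature; downstream stages skipped")
        summary["skipped"] = "signature empty"
        _write_summary(summary, outdir, h)
        return summary

    sig_disc = filtered.select_probes(signature.probes)

    # -- clustering / purity / PCA ------------------------------------------
    def _cluster():
        dendro = cluster_purity.hierarchical_cluster(sig_disc, config.distance)
        curve = cluster_purity.purity_curve(dendro, disc_labels.binary_tn(), config.max_k)
        _write_tsv(curve.to_frame(), outdir / "purity_curve.tsv", "cluster", h, index=False)
        (outdir / "dendrogram.newick").write_text(dendro.to_newick() + "\n")
        proj = cluster_purity.pca_project(sig_disc, k=3)
        _write_tsv(proj.component_scores, outdir / "pca_scores.tsv", "cluster", h)
        w, b, acc = cluster_purity.linear_separation(proj, disc_labels.binary_tn(), 2)
        return curve, acc

    curve, sep_acc = stage("cluster")(_cluster)
    summary["max_purity_at_k3"] = curve.max_cluster_purity.get(3)
    summary["linear_separation_accuracy"] = sep_acc

    # -- classification ------------------------------------------------------
    def _classify():
        feats_tr = sig_disc.to_frame().T  # samples x probes
        val_probes = [p for p in signature.probes if p in val.probe_ids]
        if len(val_probes) < len(signature.probes):
            log.warning("validation matrix missing %d signature probes",
                        len(signature.probes) - len(val_probes))
        feats_tr = feats_tr[val_probes]
        ens = classify_eval.train_tree_ensemble(
            feats_tr,
            disc_labels.binary_tn(),
            seed=config.seed,
            n_trees=config.n_trees,
            scan_trees=config.scan_trees,
        )
        feats_te = val.select_probes(val_probes).to_frame().T
        shared = [s for s in feats_te.index if s in val_labels.labels]
        feats_te = feats_te.loc[shared]
        scores = classify_eval.predict_scores(ens, feats_te)
        pred = classify_eval.predict_classes(ens, feats_te)
        cm = classify_eval.confusion_from_predictions(pred, val_labels.binary_tn())
        report = classify_eval.confusion_metrics(cm)
        points, auc = classify_eval.roc_auc(scores, val_labels.binary_tn())
        report.auc = auc
        rep_df = pd.DataFrame(
            [
                dict(
                    tp=cm.tp, fn=cm.fn, fp=cm.fp, tn=cm.tn,
                    f1_tn=classify_eval.round2(report.f1_tn),
                    f1_nontn=classify_eval.round2(report.f1_nontn),
                    mcc=classify_eval.round2(report.mcc),
                    auc=report.auc,
                    n_correct=report.n_correct,
                    node_count=ens.node_count,
                )
            ]
        )
        _write_tsv(rep_df, outdir / "classifier_report.tsv", "classify", h, index=False)
        _write_tsv(points, outdir / "roc_points.tsv", "classify", h, index=False)
        return report

    clf_report = stage("classify")(_classify)
    summary["classifier_auc"] = clf_report.auc
    summary["classifier_f1_tn"] = classify_eval.round2(clf_report.f1_tn)
    summary["classifier_mcc"] = classify_eval.round2(clf_report.mcc)

    # -- survival ------------------------------------------------------------
    def _survival():
        shared = [s for s in clinical.sample_ids if s in sig_disc.sample_ids]
        clin = clinical.subset(shared)
        dirs = survival.site_directions(sig_disc.select_samples(shared), clin, config.alpha_surv)
        n_sig = sum(d.significant for d in dirs)
        use_sig_only = n_sig > 0
        if not use_sig_only:
            log.warning("no site reached logrank p < %g; scoring over all sites",
                        config.alpha_surv)
        scores = survival.prognostic_scores(
            sig_disc.select_samples(shared), dirs, use_only_significant=use_sig_only
        )
        dirs_df = pd.DataFrame([d.__dict__ for d in dirs])
        _write_tsv(dirs_df, outdir / "site_directions.tsv", "survival", h, index=False)
        scores_df = pd.DataFrame([s.__dict__ for s in scores])
        _write_tsv(scores_df, outdir / "prognostic_scores.tsv", "survival", h, index=False)
        group, logrank_p, hr = survival.stratify_and_test(scores, clin)
        curves = survival.km_curve(clin, group)
        km_rows = []
        for c in curves:
            for t, s in zip(c.times, c.survival):
                km_rows.append(dict(group=c.group, time=t, survival=s))
        _write_tsv(pd.DataFrame(km_rows), outdir / "km_curves.tsv", "survival", h, index=False)
        return logrank_p, hr, n_sig

    logrank_p, strat_hr, n_sig_sites = stage("survival")(_survival)
    summary["n_significant_sites"] = n_sig_sites
    summary["stratification_logrank_p"] = logrank_p
    summary["stratification_hr"] = strat_hr

    # -- enrichment ----------------------------------------------------------
    if config.gene_sets is not None and signature.genes:
        def _enrich():
            universe = {
                str(g) for g in annot.table["gene_symbol"] if g
            }
            coll = enrichment.read_gmt(config.gene_sets, universe=universe)
            df = enrichment.fisher_enrich(signature.genes & coll.universe, coll)
            _write_tsv(df, outdir / "enrichment.tsv", "enrich", h, index=False)
            return df

        enr = stage("enrich")(_enrich)
        summary["top_enriched_set"] = enr.iloc[0]["set_id"] if len(enr) else None
        summary["n_enriched_significant"] = int(enr["significant"].sum())
    else:
        log.info("no gene sets supplied; enrichment skipped")

    _write_summary(summary, outdir, h)
    return summary


def _write_summary(summary: dict[str, object], outdir: Path, cfg_hash: str) -> None:
    rows = pd.DataFrame(
        [(k, v) for k, v in summary.items()], columns=["key", "value"]
    )
    _write_tsv(rows, outdir / "summary.tsv", "summary", cfg_hash, index=False)
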