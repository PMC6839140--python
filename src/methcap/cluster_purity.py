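"""Sample hierarchical clustering, dendrogram purity curves, PCA + linear separation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.svm import SVC

from methcap.methio import HER2P, LUMINAL, TN, BetaMatrix, SubtypeLabels, ValidationError

#: majority-vote tie-breaking priority for cluster labels
LABEL_PRIORITY = (TN, HER2P, LUMINAL, "nonTN")


@dataclass
class Dendrogram:
    """Agglomerative tree over samples (scipy linkage encoding)."""

    linkage: np.ndarray
    sample_ids: list[str]
    distance: str

    def cut(self, k: int) -> dict[str, int]:
        """Cut into k clusters; returns sample -> cluster id (1-based)."""
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.sample_ids, (int(c) for c in flat)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.sample_ids[node.id]
            left, right = rec(node.left), rec(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return rec(tree) + ";"


def hierarchical_cluster(
    betas: BetaMatrix, distance: str = "euclidean"
) -> Dendrogram:
    """Ward-linkage agglomerative clustering of samples.

    distance: 'euclidean' or 'one_minus_r' (1 - Pearson correlation between
    sample profiles).  A constant sample makes 1-r undefined and is an error.
    """
    if betas.n_samples < 2:
        raise ValidationError("clustering needs >= 2 samples")
    if betas.n_probes < 1:
        raise ValidationError("clustering needs >= 1 probe")
    x = betas.values.T  # samples x probes
    if distance == "euclidean":
        d = pdist(x, metric="euclidean")
    elif distance in ("one_minus_r", "correlation"):
        sd = x.std(axis=1)
        if np.any(sd == 0):
            bad = betas.sample_ids[int(np.argmax(sd == 0))]
            raise ValidationError(
                f"sample {bad} is constant; correlation distance undefined"
            )
        d = pdist(x, metric="correlation")
    else:
        raise ValidationError(f"unknown distance {distance!r}")
    linkage = hierarchy.linkage(d, method="ward")
    return Dendrogram(linkage=linkage, sample_ids=list(betas.sample_ids), distance=distance)


@dataclass
class PurityCurve:
    """Cluster purity summaries for dendrogram cuts k = 1..max_k."""

    cutoffs: list[int]
    per_cutoff: dict[int, list[tuple[int, int, str, float]]]
    overall_weighted_purity: dict[int, float]
    max_cluster_purity: dict[int, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in self.cutoffs:
            for cid, size, major, frac in self.per_cutoff[k]:
                rows.append(
                    dict(
                        k=k,
                        cluster=cid,
                        size=size,
                        majority_class=major,
                        purity=frac,
                        weighted_purity=self.overall_weighted_purity[k],
                        max_purity=self.max_cluster_purity[k],
                    )
                )
        return pd.DataFrame(rows)


def purity_curve(
    dendro: Dendrogram,
    labels: SubtypeLabels | dict[str, str],
    max_k: int = 10,
) -> PurityCurve:
    """Purity of each cluster at cuts k=1..max_k.

    Each cluster is assigned its most represented label (ties broken by the
    fixed priority TN > HER2p > luminal > nonTN); its purity is the fraction
    of member samples carrying that label.  Also reports the size-weighted
    overall purity and the maximum single-cluster purity per cut.
    """
    lab = labels.labels if isinstance(labels, SubtypeLabels) else dict(labels)
    missing = [s for s in dendro.sample_ids if s not in lab]
    if missing:
        raise ValidationError(f"unlabelled samples: {missing[:5]}")
    n = len(dendro.sample_ids)
    max_k = min(max_k, n)
    cutoffs = list(range(1, max_k + 1))
    per_cutoff: dict[int, list[tuple[int, int, str, float]]] = {}
    weighted: dict[int, float] = {}
    maxpur: dict[int, float] = {}
    prio = {c: i for i, c in enumerate(LABEL_PRIORITY)}
    for k in cutoffs:
        assign = dendro.cut(k)
        clusters: dict[int, list[str]] = {}
        for s, c in assign.items():
            clusters.setdefault(c, []).append(s)
        entries = []
        correct = 0
        best = 0.0
        for cid in sorted(clusters):
            members = clusters[cid]
            counts: dict[str, int] = {}
            for s in members:
                counts[lab[s]] = counts.get(lab[s], 0) + 1
            major = min(
                counts, key=lambda c: (-counts[c], prio.get(c, len(prio)), c)
            )
            frac = counts[major] / len(members)
            entries.append((cid, len(members), major, frac))
            correct += counts[major]
            best = max(best, frac)
        per_cutoff[k] = entries
        weighted[k] = correct / n
        maxpur[k] = best
    return PurityCurve(cutoffs, per_cutoff, weighted, maxpur)


@dataclass
class PCAProjection:
    """Sample scores on principal components of the probe-centered matrix."""

    component_scores: pd.DataFrame  # samples x components
    explained_variance_fraction: np.ndarray
    loadings: pd.DataFrame  # probes x components


def pca_project(betas: BetaMatrix, k: int = 3) -> PCAProjection:
    """Project samples onto the first k principal components via SVD.

    Probe-wise centered; signs fixed so each component's largest-magnitude
    loading is positive, making the output deterministic.
    """
    if betas.n_samples < 2:
        raise ValidationError("PCA needs >= 2 samples")
    x = betas.values.T  # samples x probes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if k > rank:
        k = rank
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # deterministic sign: largest-magnitude loading positive
    for i in range(k):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    scores = u * s
    total_var = float((x**2).sum())
    explained = (s**2) / total_var if total_var > 0 else np.zeros(k)
    cols = [f"PC{i+1}" for i in range(k)]
    return PCAProjection(
        component_scores=pd.DataFrame(scores, index=betas.sample_ids, columns=cols),
        explained_variance_fraction=explained,
        loadings=pd.DataFrame(vt.T, index=betas.probe_ids, columns=cols),
    )


def linear_separation(
    projection: PCAProjection,
    binary_labels: dict[str, str],
    n_components: int = 2,
) -> tuple[np.ndarray, float, float]:
    """Fit a maximum-margin linear boundary in the first components' scores.

    Returns (weight vector w, intercept b, training separation accuracy)
    where the decision rule is sign(w . scores + b).
    """
    samples = list(projection.component_scores.index)
    y = np.array([binary_labels[s] for s in samples])
    classes = np.unique(y)
    if classes.size != 2:
        raise ValidationError(f"need exactly 2 classes, got {list(classes)}")
    x = projection.component_scores.iloc[:, :n_components].to_numpy()
    svm = SVC(kernel="linear", C=1e6)
    svm.fit(x, y)
    acc = float((svm.predict(x) == y).mean())
    return svm.coef_[0].copy(), float(svm.intercept_[0]), acc
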