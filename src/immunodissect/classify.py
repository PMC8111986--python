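"""Immune-class discovery and projection.

Discovery: samples are consensus-clustered on the exemplar genes of the
immune NMF factor (resampled hierarchical clustering, average linkage on
1 - Pearson correlation); the cluster with the higher mean immune enrichment
score is the immune class. Within the immune class, a 1-D two-means split of
the activated-stroma enrichment score separates the exhausted subtype
(higher stroma — inflammatory stromal activation masking the response) from
the active immune subtype.

Projection: an external cohort is assigned by rank-normalizing each sample
over the shared exemplar genes and correlating against the class centroids
learned on the discovery cohort (an NNLS-onto-W mode is available as an
alternative), then re-splitting the projected immune class on its stroma
scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.optimize import nnls
from scipy.spatial.distance import squareform

from .factorization import FactorModel

LABELS = ("active_immune", "exhausted", "non_immune")


@dataclass
class ClassAssignment:
    """Per-sample class labels with clustering provenance."""

    labels: pd.Series  # sample -> label
    consensus: pd.DataFrame | None = None
    provenance: str = "discovered"  # or "projected"
    immune_scores: pd.Series | None = None
    stroma_scores: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"class": self.labels})
        if self.immune_scores is not None:
            out["immune_score"] = self.immune_scores.reindex(out.index)
        if self.stroma_scores is not None:
            out["stroma_score"] = self.stroma_scores.reindex(out.index)
        out["provenance"] = self.provenance
        out.index.name = "sample"
        return out


def consensus_cluster(
    expr: pd.DataFrame,
    k_clusters: int = 2,
    n_resamples: int = 100,
    sample_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Resampled hierarchical clustering of samples on a feature subset.

    Each resample draws ``sample_fraction`` of the samples without
    replacement, clusters them (average linkage, 1 - Pearson distance) and
    accumulates co-assignment counts; the consensus matrix is co-assignment
    frequency among co-sampled pairs. The final partition cuts the
    average-linkage tree of ``1 - consensus`` at ``k_clusters``.
    """
    if expr.shape[1] < 2 * k_clusters:
        raise ValueError("need at least 2*k_clusters samples")
    values = expr.to_numpy(dtype=float)
    keep = values.std(axis=1) > 0
    if not keep.any():
        raise ValueError("all feature rows are constant")
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant feature rows",
            RuntimeWarning,
            stacklevel=2,
        )
        values = values[keep]

    n = values.shape[1]
    size = max(2 * k_clusters, int(round(sample_fraction * n)))
    size = min(size, n)
    rng = np.random.default_rng(seed)
    co_count = np.zeros((n, n))
    together = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = (
            np.arange(n)
            if size == n
            else np.sort(rng.choice(n, size=size, replace=False))
        )
        sub = values[:, idx]
        labels = _hcluster_samples(sub, k_clusters)
        co_count[np.ix_(idx, idx)] += 1
        same = labels[:, None] == labels[None, :]
        together[np.ix_(idx, idx)] += same
    never = co_count == 0
    if never.any() and n_resamples > 1:
        warnings.warn(
            "some sample pairs were never co-sampled; their consensus is 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_count > 0, together / np.maximum(co_count, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2

    dist = squareform(1.0 - consensus, checks=False)
    Z = average(dist)
    part = fcluster(Z, t=k_clusters, criterion="maxclust")

    cons_df = pd.DataFrame(consensus, index=expr.columns, columns=expr.columns)
    return cons_df, pd.Series(part, index=expr.columns, name="cluster")


def _hcluster_samples(values: np.ndarray, k: int) -> np.ndarray:
    """Average-linkage clustering of columns under 1 - Pearson distance."""
    X = values.T
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Xc**2).sum(axis=1))
    norm[norm == 0] = 1.0
    corr = (Xc / norm[:, None]) @ (Xc / norm[:, None]).T
    np.clip(corr, -1.0, 1.0, out=corr)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    Z = average(squareform(d, checks=False))
    return fcluster(Z, t=k, criterion="maxclust")


def assign_immune_class(
    partition: pd.Series, immune_scores: pd.Series
) -> pd.Series:
    """Label a 2-cluster partition immune / non_immune by mean immune score."""
    clusters = partition.unique()
    if len(clusters) != 2:
        raise ValueError(f"expected exactly 2 clusters, got {len(clusters)}")
    scores = immune_scores.reindex(partition.index)
    if scores.isna().any():
        raise ValueError("immune scores missing for some samples")
    means = scores.groupby(partition).mean()
    if any((partition == c).sum() == 0 for c in clusters):
        raise ValueError("empty cluster")
    if abs(means.iloc[0] - means.iloc[1]) < 1e-9:
        raise ValueError("cluster immune-score means are indistinguishable")
    immune_cluster = means.idxmax()
    labels = partition.map(
        lambda c: "immune" if c == immune_cluster else "non_immune"
    )
    return labels.rename("class")


def two_means_split_1d(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact 1-D two-means: best split point by within-cluster sum of squares.

    Returns a boolean mask (True = upper cluster) and the threshold
    (midpoint between cluster means). Deterministic: scans all sorted split
    points. All-equal input is an error.
    """
    v = np.asarray(values, dtype=float)
    if np.ptp(v) == 0:
        raise ValueError("all values equal; no 2-means split exists")
    order = np.argsort(v, kind="stable")
    sv = v[order]
    n = len(sv)
    csum = np.cumsum(sv)
    css = np.cumsum(sv**2)
    best = (np.inf, 1)
    for i in range(1, n):  # lower cluster = sv[:i]
        lo = css[i - 1] - csum[i - 1] ** 2 / i
        hi = (css[-1] - css[i - 1]) - (csum[-1] - csum[i - 1]) ** 2 / (n - i)
        ss = lo + hi
        if ss < best[0] - 1e-12:
            best = (ss, i)
    i = best[1]
    lower_mean = csum[i - 1] / i
    upper_mean = (csum[-1] - csum[i - 1]) / (n - i)
    thr = (lower_mean + upper_mean) / 2
    mask = np.zeros(n, dtype=bool)
    mask[order[i:]] = True
    return mask, float(thr)


def split_immune_subtypes(
    labels: pd.Series,
    stroma_scores: pd.Series,
    consensus: pd.DataFrame | None = None,
    immune_scores: pd.Series | None = None,
    provenance: str = "discovered",
) -> ClassAssignment:
    """Split the immune class into active_immune / exhausted on stroma score.

    The higher-stroma cluster of a 1-D two-means split is the exhausted
    subtype. Requires at least 4 immune samples and non-constant scores.
    """
    immune_samples = labels.index[labels == "immune"]
    if len(immune_samples) < 4:
        raise ValueError("immune class has fewer than 4 samples; cannot split")
    scores = stroma_scores.reindex(immune_samples)
    if scores.isna().any():
        raise ValueError("stroma scores missing for some immune samples")
    upper, _thr = two_means_split_1d(scores.to_numpy())
    final = labels.copy().astype(object)
    final.loc[immune_samples] = np.where(upper, "exhausted", "active_immune")
    return ClassAssignment(
        labels=final.rename("class"),
        consensus=consensus,
        provenance=provenance,
        immune_scores=immune_scores,
        stroma_scores=stroma_scores,
    )


@dataclass
class ProjectionReference:
    """Frozen discovery-cohort state needed to classify external cohorts."""

    exemplar_genes: list[str]
    centroids: pd.DataFrame  # rank-normalized exemplar profile per class (immune / non_immune)
    W: pd.DataFrame | None = None  # basis on exemplar genes, for NNLS mode
    immune_factor: int | None = None
    metadata: dict = field(default_factory=dict)


def _rank_normalize_columns(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-sample fractional ranks in [0, 1] (average ranks on ties)."""
    r = expr.rank(axis=0, method="average")
    return (r - 1) / max(len(expr) - 1, 1)


def build_reference(
    expr: pd.DataFrame,
    labels: pd.Series,
    exemplars: list[str],
    model: FactorModel | None = None,
) -> ProjectionReference:
    """Class centroids of rank-normalized exemplar expression.

    ``labels`` may be the 2-level immune/non_immune labelling or the final
    3-level one (active_immune and exhausted collapse to immune).
    """
    coarse = labels.map(
        lambda c: "immune" if c in ("immune", "active_immune", "exhausted") else "non_immune"
    )
    shared = [g for g in exemplars if g in expr.index]
    if not shared:
        raise ValueError("no exemplar gene present in the expression matrix")
    ranked = _rank_normalize_columns(expr.loc[shared])
    centroids = ranked.T.groupby(coarse.reindex(ranked.columns)).mean().T
    W = None
    immune_factor = None
    if model is not None:
        W = model.W.loc[[g for g in shared if g in model.W.index]]
        immune_factor = model.immune_factor
    return ProjectionReference(
        exemplar_genes=shared,
        centroids=centroids,
        W=W,
        immune_factor=immune_factor,
    )


def project_cohort(
    reference: ProjectionReference,
    new_expr: pd.DataFrame,
    stroma_scores: pd.Series,
    immune_scores: pd.Series | None = None,
    mode: str = "centroid",
) -> ClassAssignment:
    """Assign an external cohort to the discovered classes.

    ``mode='centroid'`` (default): per-sample rank normalization over shared
    exemplar genes, nearest class centroid by Pearson correlation.
    ``mode='nnls'``: non-negative projection of each sample onto the reference
    basis W; a sample is immune when the immune factor takes the largest
    coefficient. Either way the projected immune class is then split on the
    cohort's own stroma scores.
    """
    if new_expr.shape[1] == 0:
        raise ValueError("empty cohort")
    shared = [g for g in reference.exemplar_genes if g in new_expr.index]
    frac = len(shared) / len(reference.exemplar_genes)
    if frac < 0.5:
        missing = sorted(set(reference.exemplar_genes) - set(new_expr.index))
        raise ValueError(
            f"only {frac:.0%} of exemplar genes present (<50%); missing: "
            + ", ".join(missing[:20])
            + ("..." if len(missing) > 20 else "")
        )

    if mode == "centroid":
        ranked = _rank_normalize_columns(new_expr.loc[shared])
        cent = reference.centroids.loc[shared]
        R = ranked.to_numpy()
        C = cent.to_numpy()
        Rc = R - R.mean(axis=0)
        Cc = C - C.mean(axis=0)
        num = Rc.T @ Cc
        den = np.outer(
            np.sqrt((Rc**2).sum(axis=0)), np.sqrt((Cc**2).sum(axis=0))
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(den > 0, num / den, -np.inf)
        # ties break to the first (lowest-index) class column, deterministic
        winner = corr.argmax(axis=1)
        labels = pd.Series(
            cent.columns.to_numpy(dtype=object)[winner],
            index=new_expr.columns,
            name="class",
        )
    elif mode == "nnls":
        if reference.W is None or reference.immune_factor is None:
            raise ValueError("reference lacks a basis; rebuild with model=")
        genesW = [g for g in shared if g in reference.W.index]
        A = reference.W.loc[genesW].to_numpy()
        X = new_expr.loc[genesW].to_numpy(dtype=float)
        col_mass = A.sum(axis=0)
        lab = []
        for j in range(X.shape[1]):
            h, _ = nnls(A, X[:, j])
            # each factor's share of the predicted expression on the shared
            # genes, so factors with differently scaled basis columns compare
            share = h * col_mass
            lab.append(
                "immune"
                if share.argmax() == reference.immune_factor
                else "non_immune"
            )
        labels = pd.Series(lab, index=new_expr.columns, name="class")
    else:
        raise ValueError(f"unknown projection mode {mode!r}")

    return split_immune_subtypes(
        labels,
        stroma_scores,
        immune_scores=immune_scores,
        provenance="projected",
    )
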