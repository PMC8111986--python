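"""Virtual microdissection by non-negative matrix factorization.

Bulk tumour expression mixes signals from malignant cells, stroma and
infiltrating immune cells. Factorizing the non-negative gene x sample matrix
``X ~ W H`` with a small number of factors (k = 3 by default: tumour, stroma,
immune) separates these compartments without microdissection. The
factorization minimises the generalised Kullback-Leibler divergence

    D(X || WH) = sum_ij [ X_ij log(X_ij / (WH)_ij) - X_ij + (WH)_ij ]

by the classical multiplicative updates, which never increase the objective.
The best of several random restarts is kept; W columns are rescaled to unit
L1 norm with compensating row scaling of H so factor weights are comparable
across genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform

_EPS = 1e-12  # denominator guard inside multiplicative updates


@dataclass
class FactorModel:
    """NMF decomposition with restart provenance.

    W: gene x k non-negative basis (columns unit L1 norm).
    H: k x sample non-negative coefficients.
    objective_trace: per-iteration KL divergence of the winning restart.
    restart_divergences: final divergence per restart seed.
    immune_factor: index of the factor identified as immune (set later).
    converged: whether the winning restart met the tolerance before max_iter.
    """

    W: pd.DataFrame
    H: pd.DataFrame
    k: int
    objective_trace: list[float]
    restart_divergences: dict[int, float]
    chosen_restart: int
    converged: bool
    immune_factor: int | None = None


@dataclass
class ExemplarGeneList:
    """Genes most specifically weighted on one factor, best first."""

    table: pd.DataFrame  # columns: gene, weight, specificity_ratio
    factor: int

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()


def kl_divergence(X: np.ndarray, WH: np.ndarray) -> float:
    """Generalised KL divergence D(X || WH); 0 log 0 terms contribute 0."""
    WH = np.maximum(WH, _EPS)
    pos = X > 0
    term = np.zeros_like(X)
    term[pos] = X[pos] * np.log(X[pos] / WH[pos])
    return float(term.sum() - X.sum() + WH.sum())


def _nmf_single(
    X: np.ndarray, k: int, max_iter: int, tol: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    n, m = X.shape
    scale = np.sqrt(X.mean() / k)
    W = rng.uniform(0.1, 1.0, size=(n, k)) * scale
    H = rng.uniform(0.1, 1.0, size=(k, m)) * scale
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        WH = W @ H
        H *= (W.T @ (X / np.maximum(WH, _EPS))) / np.maximum(
            W.sum(axis=0)[:, None], _EPS
        )
        WH = W @ H
        W *= ((X / np.maximum(WH, _EPS)) @ H.T) / np.maximum(
            H.sum(axis=1)[None, :], _EPS
        )
        d = kl_divergence(X, W @ H)
        trace.append(d)
        if len(trace) > 1:
            prev = trace[-2]
            if prev - d <= tol * max(abs(prev), 1.0):
                converged = True
                break
    return W, H, trace, converged


def nmf(
    expr: pd.DataFrame,
    k: int,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> FactorModel:
    """Best-of-restarts KL NMF of a non-negative gene x sample matrix.

    Raises on negative entries or all-zero gene rows (filter those first);
    non-convergence at ``max_iter`` only flags ``converged=False``.
    """
    X = expr.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("expression matrix has negative entries")
    if (X.sum(axis=1) == 0).any():
        raise ValueError("expression matrix has all-zero gene rows; filter them first")
    if not k < min(X.shape):
        raise ValueError("k must be smaller than both matrix dimensions")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    base = np.random.SeedSequence(seed)
    best = None
    divergences: dict[int, float] = {}
    for r, child in enumerate(base.spawn(n_restarts)):
        rng = np.random.default_rng(child)
        W, H, trace, conv = _nmf_single(X, k, max_iter, tol, rng)
        divergences[r] = trace[-1]
        if best is None or trace[-1] < best[3][-1]:
            best = (r, W, H, trace, conv)
    r, W, H, trace, conv = best
    if not conv:
        warnings.warn(
            f"NMF did not reach tol={tol} within {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )

    norms = np.maximum(W.sum(axis=0), _EPS)
    W = W / norms
    H = H * norms[:, None]

    return FactorModel(
        W=pd.DataFrame(W, index=expr.index, columns=range(k)),
        H=pd.DataFrame(H, index=range(k), columns=expr.columns),
        k=k,
        objective_trace=trace,
        restart_divergences=divergences,
        chosen_restart=r,
        converged=conv,
    )


def mad_filter(expr: pd.DataFrame, n_top: int = 1500) -> pd.DataFrame:
    """Restrict to the ``n_top`` genes with largest median absolute deviation.

    Ties at the cutoff resolve by gene identifier so the selection is
    deterministic.
    """
    med = expr.sub(expr.median(axis=1), axis=0).abs().median(axis=1)
    tab = pd.DataFrame(
        {"mad": med.to_numpy(), "gene": expr.index.to_numpy()}
    ).sort_values(["mad", "gene"], ascending=[False, True])
    keep = set(tab["gene"].head(min(n_top, len(expr))))
    return expr.loc[expr.index.isin(keep)]


def rank_diagnostics(
    expr: pd.DataFrame,
    k_range: list[int],
    n_runs: int = 10,
    max_iter: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Cophenetic correlation and reconstruction error across candidate ranks.

    For each k, ``n_runs`` factorizations from different starts yield sample
    connectivity matrices (samples co-assigned to their argmax factor); the
    cophenetic correlation of the average-linkage dendrogram on the consensus
    measures clustering stability. With ``n_runs = 1`` the consensus is a 0/1
    matrix and cophenetic correlation is 1 by construction; flagged degenerate.
    """
    if not k_range:
        raise ValueError("k_range is empty")
    rows = []
    m = expr.shape[1]
    for k in k_range:
        consensus = np.zeros((m, m))
        best_div = np.inf
        for run in range(n_runs):
            model = nmf(
                expr, k, n_restarts=1, max_iter=max_iter,
                seed=seed * 10_000 + 101 * k + run,
            )
            assign = model.H.to_numpy().argmax(axis=0)
            consensus += (assign[:, None] == assign[None, :]).astype(float)
            best_div = min(best_div, model.objective_trace[-1])
        consensus /= n_runs
        dist = squareform(1.0 - consensus, checks=False)
        if np.allclose(dist, dist.flat[0] if dist.size else 0.0):
            coph = 1.0  # degenerate: all runs agree (or n_runs == 1)
        else:
            Z = average(dist)
            coph = float(cophenet(Z, dist)[0])
        rows.append(
            {
                "k": k,
                "cophenetic": coph,
                "reconstruction_error": best_div,
                "degenerate": n_runs == 1,
            }
        )
    return pd.DataFrame(rows).set_index("k")


def identify_immune_factor(
    model: FactorModel, immune_scores: pd.Series
) -> tuple[int, pd.Series]:
    """Factor whose per-sample coefficients track the immune enrichment score.

    Returns the argmax over factors of the Pearson correlation between each
    row of H and the immune ssGSEA score, together with all correlations.
    A constant score vector, or two factors tied to within 1e-9, is an error.
    """
    aligned = immune_scores.reindex(model.H.columns)
    if aligned.isna().any():
        raise ValueError("immune scores do not cover all samples in the model")
    y = aligned.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("immune score is constant across samples; correlation undefined")
    if model.k == 1:
        return 0, pd.Series([1.0], index=[0], name="pearson_r")
    Hm = model.H.to_numpy()
    yc = y - y.mean()
    corrs = np.empty(model.k)
    for f in range(model.k):
        h = Hm[f] - Hm[f].mean()
        denom = np.sqrt((h * h).sum() * (yc * yc).sum())
        corrs[f] = (h * yc).sum() / denom if denom > 0 else np.nan
    series = pd.Series(corrs, index=range(model.k), name="pearson_r")
    order = np.argsort(-corrs)
    if abs(corrs[order[0]] - corrs[order[1]]) < 1e-9:
        raise ValueError("two factors correlate equally with the immune score")
    return int(order[0]), series


def exemplar_genes(
    model: FactorModel,
    factor: int,
    m: int = 150,
    min_ratio: float = 2.0,
) -> ExemplarGeneList:
    """Top-weighted, factor-specific genes of one basis column.

    A gene is retained if its weight on ``factor`` is at least ``min_ratio``
    times its largest weight on any other factor (ratio is +inf when the gene
    loads nowhere else); the retained genes are ranked by basis weight and
    the top ``m`` returned (all of them if fewer pass).
    """
    if not 0 <= factor < model.k:
        raise ValueError(f"factor must be in [0, {model.k})")
    if m < 1:
        raise ValueError("m must be >= 1")
    W = model.W.to_numpy()
    w = W[:, factor]
    if model.k == 1:
        ratio = np.full(len(w), np.inf)
    else:
        others = np.delete(W, factor, axis=1).max(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(others > 0, w / others, np.inf)
        ratio = np.where(w == 0, 0.0, ratio)
    tab = pd.DataFrame(
        {"gene": model.W.index, "weight": w, "specificity_ratio": ratio}
    )
    tab = tab[tab["specificity_ratio"] >= min_ratio]
    if tab.empty:
        raise ValueError(
            "no gene passes the specificity ratio; lower min_ratio"
        )
    tab = tab.sort_values(
        ["weight", "gene"], ascending=[False, True]
    ).head(m).reset_index(drop=True)
    return ExemplarGeneList(table=tab, factor=factor)
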