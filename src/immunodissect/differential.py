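"""Differential analysis per omics layer and preranked GSEA.

Differential expression uses a per-feature Welch t-test (or Wilcoxon
rank-sum) on log-scale values with Benjamini-Hochberg control of the false
discovery rate; a feature passes at adjusted p < fdr together with
|log fold-change| > lfc. The fold-change convention is
mean(group A) - mean(group B) on the log scale, group A being the first
level passed.

Preranked GSEA scores each gene set by the weighted Kolmogorov-Smirnov
maximum-deviation statistic on a ranked list; significance and FDR come from
gene-label permutations of the ranking (not phenotype permutation), with
normalized scores stratified by sign as in the standard procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import GeneSetCollection


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values: adj_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _welch_rows(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t statistic and two-sided p with zero-variance guards."""
    nA, nB = A.shape[1], B.shape[1]
    mA, mB = A.mean(axis=1), B.mean(axis=1)
    vA, vB = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    se2 = vA / nA + vB / nB
    zero = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mA - mB) / np.sqrt(se2)
        df = se2**2 / (
            (vA / nA) ** 2 / (nA - 1) + (vB / nB) ** 2 / (nB - 1)
        )
    # both groups constant: identical means -> p=1, different -> p=0
    t[zero] = np.where(mA[zero] == mB[zero], 0.0, np.inf * np.sign(mA - mB)[zero])
    df[zero] = nA + nB - 2
    p = 2 * stats.t.sf(np.abs(t), df)
    p[zero & (mA != mB)] = 0.0
    return t, p


def differential_expression(
    matrix: pd.DataFrame,
    groups: pd.Series,
    test: str = "welch_t",
    fdr: float = 0.05,
    lfc: float = 1.0,
) -> pd.DataFrame:
    """Feature-wise two-group differential table on a log-scale matrix.

    Returns one row per feature: log2 fold-change (first group level minus
    second), raw p, BH-adjusted p, direction, zero-variance flag and the
    pass flag (adjusted p < fdr and |logFC| > lfc, both strict).
    """
    g = groups.reindex(matrix.columns)
    if g.isna().any():
        raise ValueError("group labels missing for some samples")
    levels = list(pd.unique(g))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {levels}")
    A = matrix.loc[:, g == levels[0]].to_numpy(dtype=float)
    B = matrix.loc[:, g == levels[1]].to_numpy(dtype=float)
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")

    logfc = A.mean(axis=1) - B.mean(axis=1)
    zero_var = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
    if test == "welch_t":
        stat, p = _welch_rows(A, B)
    elif test == "wilcoxon":
        stat = np.empty(len(matrix))
        p = np.empty(len(matrix))
        for i in range(len(matrix)):
            res = stats.mannwhitneyu(A[i], B[i], alternative="two-sided")
            stat[i], p[i] = res.statistic, res.pvalue
    else:
        raise ValueError(f"unknown test {test!r}")

    q = benjamini_hochberg(p)
    out = pd.DataFrame(
        {
            "log2_fc": logfc,
            "statistic": stat,
            "p_value": p,
            "adj_p": q,
            "direction": np.where(logfc >= 0, "up", "down"),
            "zero_variance": zero_var,
        },
        index=matrix.index,
    )
    out["pass"] = (out["adj_p"] < fdr) & (out["log2_fc"].abs() > lfc)
    out.index.name = "feature"
    return out


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    fdr: float
    size: int
    leading_edge: list[str]


def _es_from_positions(
    abs_w: np.ndarray, positions: np.ndarray, n: int
) -> tuple[float, int]:
    """Weighted-KS enrichment score given in-set positions in a fixed ranking.

    ``abs_w`` are |stat|^weight along the sorted ranking. Returns the signed
    maximum deviation of the running sum and its position.
    """
    inset = np.zeros(n, dtype=bool)
    inset[positions] = True
    w = np.where(inset, abs_w, 0.0)
    denom = w.sum()
    if denom == 0:  # all in-set stats are exactly 0: fall back to unweighted
        w = inset.astype(float)
        denom = w.sum()
    p_in = np.cumsum(w) / denom
    p_out = np.cumsum(~inset) / (n - len(positions))
    dev = p_in - p_out
    i_max = int(np.argmax(np.abs(dev)))
    return float(dev[i_max]), i_max


def preranked_gsea(
    ranked_stats: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA with gene-label permutation FDR.

    ``ranked_stats`` maps features to a real ranking statistic (no duplicate
    feature names). NES divides ES by the mean |permutation ES| of the same
    sign; p and FDR are computed within the positive and negative strata.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    if ranked_stats.index.duplicated().any():
        raise ValueError("duplicate feature identifiers in ranking")
    stats_sorted = ranked_stats.sort_values(ascending=False, kind="stable")
    genes = stats_sorted.index.to_numpy(dtype=object)
    n = len(genes)
    abs_w = np.abs(stats_sorted.to_numpy(dtype=float)) ** weight
    pos_of = {g: i for i, g in enumerate(genes)}

    usable = []
    for name in sets:
        members = [g for g in sets[name] if g in pos_of]
        if not members or len(members) == n:
            continue
        usable.append((name, np.array([pos_of[g] for g in members])))
    if not usable:
        raise ValueError("no gene set overlaps the ranking")

    rng = np.random.default_rng(seed)
    obs = {}
    perm_es: dict[str, np.ndarray] = {}
    for name, positions in usable:
        es, i_max = _es_from_positions(abs_w, positions, n)
        lead_mask = positions <= i_max if es >= 0 else positions > i_max
        leading = [genes[p] for p in np.sort(positions[lead_mask])]
        obs[name] = (es, leading, len(positions))
        null = np.empty(n_perm)
        for b in range(n_perm):
            rand_pos = rng.choice(n, size=len(positions), replace=False)
            null[b], _ = _es_from_positions(abs_w, rand_pos, n)
        perm_es[name] = null

    # sign-stratified normalization: NES = ES / mean |null ES| of same sign
    rows = []
    all_nes_null: list[np.ndarray] = []
    nes_obs = {}
    for name, positions in usable:
        es, leading, size = obs[name]
        null = perm_es[name]
        pos_mean = null[null > 0].mean() if (null > 0).any() else np.nan
        neg_mean = -null[null < 0].mean() if (null < 0).any() else np.nan
        scale = pos_mean if es >= 0 else neg_mean
        nes = es / scale if scale and np.isfinite(scale) else np.nan
        null_nes = np.where(
            null >= 0,
            null / pos_mean if np.isfinite(pos_mean) else np.nan,
            null / neg_mean if np.isfinite(neg_mean) else np.nan,
        )
        if es >= 0:
            p = (1 + (null[null >= 0] >= es).sum()) / (1 + (null >= 0).sum())
        else:
            p = (1 + (null[null < 0] <= es).sum()) / (1 + (null < 0).sum())
        nes_obs[name] = nes
        all_nes_null.append(null_nes[np.isfinite(null_nes)])
        rows.append([name, es, nes, p, size, leading])

    pooled_null = np.concatenate(all_nes_null)
    obs_nes_arr = np.array([nes_obs[name] for name, _ in usable])
    fdrs = []
    for name, _ in usable:
        nes = nes_obs[name]
        if not np.isfinite(nes):
            fdrs.append(np.nan)
            continue
        if nes >= 0:
            num = (pooled_null >= nes).mean() / max(
                (pooled_null >= 0).mean(), 1e-12
            )
            den = (obs_nes_arr[np.isfinite(obs_nes_arr)] >= nes).mean() / max(
                (obs_nes_arr >= 0).mean(), 1e-12
            )
        else:
            num = (pooled_null <= nes).mean() / max(
                (pooled_null < 0).mean(), 1e-12
            )
            den = (obs_nes_arr[np.isfinite(obs_nes_arr)] <= nes).mean() / max(
                (obs_nes_arr < 0).mean(), 1e-12
            )
        fdrs.append(float(np.clip(num / max(den, 1e-12), 0.0, 1.0)))

    out = pd.DataFrame(
        rows, columns=["set_name", "es", "nes", "p_value", "size", "leading_edge"]
    )
    out["fdr"] = fdrs
    return out.set_index("set_name")
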