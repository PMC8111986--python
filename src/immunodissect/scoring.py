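"""Single-sample gene-set enrichment (ssGSEA) scores.

For one sample, genes are ranked by decreasing expression (ties broken by
gene-identifier lexicographic order, so scoring is bit-reproducible). Writing
``r_j`` for the descending-rank weight of the gene at ordered position ``j``
(the top gene has ``r = N``), the in-set and out-of-set empirical cumulative
distributions at position ``i`` are

    P_in(i)  = sum_{j<=i, j in S} r_j^alpha / sum_{j in S} r_j^alpha
    P_out(i) = sum_{j<=i, j not in S} 1 / (N - |S|)

and the enrichment score is the running-sum integral
``ES = sum_i (P_in(i) - P_out(i))``. With ``alpha = 0`` this reduces to an
unweighted rank statistic; the default ``alpha = 0.25`` up-weights highly
expressed genes. Scores are rank-based, hence invariant under any strictly
monotone transform of a sample's expression values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genesets import GeneSetCollection

NORMALIZATION_MODES = ("none", "global-range", "z-by-set")


@dataclass
class ScoringConfig:
    """ssGSEA parameters.

    alpha: rank-weight exponent (>= 0); 0 gives the unweighted statistic.
    normalization: 'none', 'global-range' (divide the whole matrix by its
        range, the customary cross-set normalization), or 'z-by-set'
        (per-set mean 0 / sd 1 across samples).
    """

    alpha: float = 0.25
    normalization: str = "none"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.normalization not in NORMALIZATION_MODES:
            raise ValueError(
                f"normalization must be one of {NORMALIZATION_MODES}"
            )


@dataclass
class EnrichmentScoreMatrix:
    """Set x sample enrichment scores plus per-set error records."""

    scores: pd.DataFrame
    normalization: str = "none"
    set_errors: dict[str, str] = field(default_factory=dict)

    def row(self, set_name: str) -> pd.Series:
        return self.scores.loc[set_name]


def ssgsea_scores(
    expr: pd.DataFrame,
    sets: GeneSetCollection,
    cfg: ScoringConfig | None = None,
) -> EnrichmentScoreMatrix:
    """Score every gene set in every sample of a gene x sample matrix.

    A set with no gene in the expression universe, or covering the whole
    universe (the out-of-set distribution is then undefined), is recorded in
    ``set_errors`` and omitted from the score matrix rather than failing the
    whole call.
    """
    if cfg is None:
        cfg = ScoringConfig()
    genes = expr.index.to_numpy(dtype=object)
    n_genes = len(genes)
    if n_genes == 0:
        raise ValueError("expression matrix has no genes")
    gene_pos = {g: i for i, g in enumerate(genes)}

    usable: list[tuple[str, np.ndarray]] = []
    errors: dict[str, str] = {}
    for name in sets:
        members = [g for g in sets[name] if g in gene_pos]
        if not members:
            errors[name] = "no overlap with expression gene universe"
            continue
        if len(members) == n_genes:
            errors[name] = "set covers the whole gene universe"
            continue
        mask = np.zeros(n_genes, dtype=bool)
        mask[[gene_pos[g] for g in members]] = True
        usable.append((name, mask))

    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")

    # lexicographic gene order for tie-breaking within equal expression
    lex_order = np.argsort(genes, kind="stable")

    out = np.empty((len(usable), expr.shape[1]), dtype=float)
    rank_weight = np.arange(n_genes, 0, -1, dtype=float) ** cfg.alpha
    for s in range(expr.shape[1]):
        col = values[:, s]
        # stable sort of the lexicographically pre-ordered genes by
        # decreasing expression: ties resolve to lexicographic order
        order = lex_order[np.argsort(-col[lex_order], kind="stable")]
        for k, (_, mask) in enumerate(usable):
            inset = mask[order]
            w = np.where(inset, rank_weight, 0.0)
            denom_in = w.sum()
            p_in = np.cumsum(w) / denom_in
            n_out = n_genes - int(mask.sum())
            p_out = np.cumsum(~inset) / n_out
            out[k, s] = float(np.sum(p_in - p_out))

    scores = pd.DataFrame(
        out, index=[name for name, _ in usable], columns=expr.columns
    )
    scores.index.name = "gene_set"

    if cfg.normalization == "global-range":
        rng = scores.to_numpy().max() - scores.to_numpy().min()
        if rng > 0:
            scores = scores / rng
    elif cfg.normalization == "z-by-set":
        mu = scores.mean(axis=1)
        sd = scores.std(axis=1, ddof=0)
        sd = sd.replace(0.0, 1.0)
        scores = scores.sub(mu, axis=0).div(sd, axis=0)

    return EnrichmentScoreMatrix(
        scores=scores, normalization=cfg.normalization, set_errors=errors
    )
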