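"""miRNA / lncRNA / multiomics integration networks.

All operations here are deterministic set and join algebra over input edge
tables: miRNA-target links supported by both experimentally validated and
database-predicted evidence, lncRNA -> miRNA -> mRNA tripartite assembly,
the >= 2-of-N multiomics gene integration, hypergeometric pathway
over-representation, and bipartite pathway-gene export.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .differential import benjamini_hochberg
from .genesets import GeneSetCollection

MIRNA_RULES = ("validated_and_both_predicted", "validated_and_either_predicted")


def mirna_target_links(
    defms: list[str],
    validated: pd.DataFrame,
    predicted: pd.DataFrame,
    degs: pd.DataFrame | None = None,
    rule: str = "validated_and_both_predicted",
) -> pd.DataFrame:
    """Targets of differential miRNAs supported by validation + prediction.

    ``validated`` and ``predicted`` have columns mirna / gene / db. Under the
    default rule a (miRNA, gene) pair is kept when it is experimentally
    validated and predicted by both prediction databases; the "either"
    variant requires just one. Targets are annotated as DEGs (with
    direction) when a differential table is supplied.
    """
    if rule not in MIRNA_RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {MIRNA_RULES}")
    if not defms:
        raise ValueError("empty differential-miRNA list")
    val = validated[validated["mirna"].isin(defms)][["mirna", "gene"]]
    val = val.drop_duplicates()
    pred = predicted[predicted["mirna"].isin(defms)]
    support = (
        pred.drop_duplicates(["mirna", "gene", "db"])
        .groupby(["mirna", "gene"])["db"]
        .nunique()
        .rename("n_predicted_dbs")
        .reset_index()
    )
    need = 2 if rule == "validated_and_both_predicted" else 1
    kept = support[support["n_predicted_dbs"] >= need]
    edges = val.merge(kept, on=["mirna", "gene"], how="inner")
    edges = edges.sort_values(["mirna", "gene"]).reset_index(drop=True)
    edges["rule"] = rule
    if degs is not None:
        edges["target_is_deg"] = edges["gene"].isin(degs.index[degs["pass"]])
        direction = degs["direction"].to_dict()
        edges["target_direction"] = [
            direction.get(g, "") if is_deg else ""
            for g, is_deg in zip(edges["gene"], edges["target_is_deg"])
        ]
    return edges


def lncrna_network(
    diff_lncrnas: list[str],
    lnc_mir_edges: pd.DataFrame,
    mir_gene_edges: pd.DataFrame,
    degs: list[str] | None = None,
) -> dict:
    """Tripartite lncRNA -> miRNA -> mRNA network around differential lncRNAs.

    lnc->miR edges are restricted to the differential lncRNAs; miR->gene
    edges to miRNAs reached in the first step. Genes are annotated as
    DEG / non-DEG; connected components of the combined graph are reported.
    """
    if lnc_mir_edges.empty or mir_gene_edges.empty:
        raise ValueError("edge tables must be non-empty")
    lnc_mir = lnc_mir_edges[lnc_mir_edges["lncrna"].isin(diff_lncrnas)][
        ["lncrna", "mirna"]
    ].drop_duplicates()
    reached = set(lnc_mir["mirna"])
    mir_gene = mir_gene_edges[mir_gene_edges["mirna"].isin(reached)][
        ["mirna", "gene"]
    ].drop_duplicates()
    deg_set = set(degs or [])
    mir_gene = mir_gene.assign(gene_is_deg=mir_gene["gene"].isin(deg_set))

    G = nx.Graph()
    for r in lnc_mir.itertuples(index=False):
        G.add_edge(("lnc", r.lncrna), ("mir", r.mirna))
    for r in mir_gene.itertuples(index=False):
        G.add_edge(("mir", r.mirna), ("gene", r.gene))
    mir_degree = mir_gene.groupby("mirna").size().to_dict()
    lnc_mir = lnc_mir.assign(
        mirna_target_degree=lnc_mir["mirna"].map(mir_degree).fillna(0).astype(int)
    )
    return {
        "lnc_mir": lnc_mir.sort_values(["lncrna", "mirna"]).reset_index(drop=True),
        "mir_gene": mir_gene.sort_values(["mirna", "gene"]).reset_index(drop=True),
        "n_components": nx.number_connected_components(G) if len(G) else 0,
    }


def multiomics_venn(
    hits: dict[str, set[str]], min_layers: int = 2
) -> tuple[list[str], pd.DataFrame]:
    """Genes recurrent across omics layers, with the membership matrix.

    ``hits`` maps layer name (DEG / CNV / SNP / miRNA-target / ...) to a
    gene set. Returns genes present in at least ``min_layers`` layers and a
    gene x layer boolean membership table (with an ``n_layers`` column).
    """
    if len(hits) < 2:
        raise ValueError("need >= 2 omics layers")
    if min_layers > len(hits):
        raise ValueError("min_layers exceeds the number of layers")
    universe = sorted(set().union(*hits.values()))
    members = pd.DataFrame(
        {layer: [g in s for g in universe] for layer, s in hits.items()},
        index=pd.Index(universe, name="gene"),
    )
    members["n_layers"] = members.sum(axis=1)
    integrated = sorted(members.index[members["n_layers"] >= min_layers])
    return integrated, members


def overrepresentation_test(
    gene_list: list[str],
    universe: list[str],
    pathways: GeneSetCollection,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per pathway, BH-adjusted.

    Pathways with no overlap with the universe are skipped. An empty gene
    list gives p = 1 everywhere.
    """
    uni = set(universe)
    query = set(gene_list)
    if not query <= uni:
        raise ValueError("gene_list must be a subset of the universe")
    N, n = len(uni), len(query)
    rows = []
    for name in pathways:
        members = set(pathways[name]) & uni
        if not members:
            continue
        k = len(members & query)
        # P(overlap >= k) with K pathway genes in a universe of N
        p = float(stats.hypergeom.sf(k - 1, N, len(members), n)) if n else 1.0
        rows.append(
            {"pathway": name, "overlap": k, "pathway_size": len(members),
             "p_value": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["adj_p"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out.set_index("pathway")


def pathway_gene_network(
    enrichment: pd.DataFrame,
    gene_list: list[str],
    pathways: GeneSetCollection,
    p_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bipartite (pathway, gene) edges for enriched pathways.

    Edges link each pathway with raw p < threshold to its member genes that
    appear in the gene list; genes in no enriched pathway are excluded. A
    node table carries the p-values.
    """
    query = set(gene_list)
    keep = enrichment[enrichment["p_value"] < p_threshold]
    edges = []
    for name in keep.index:
        for g in sorted(set(pathways[name]) & query):
            edges.append({"pathway": name, "gene": g})
    edges_df = pd.DataFrame(edges, columns=["pathway", "gene"])
    nodes = [
        {"node": name, "kind": "pathway", "p_value": keep.loc[name, "p_value"]}
        for name in keep.index
    ] + [
        {"node": g, "kind": "gene", "p_value": np.nan}
        for g in sorted(set(edges_df["gene"]))
    ]
    return edges_df, pd.DataFrame(nodes, columns=["node", "kind", "p_value"])
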