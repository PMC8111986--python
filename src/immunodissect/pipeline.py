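"""End-to-end orchestration of the immune-classification workflow.

Stages run in dependency order — enrichment scoring, NMF virtual
microdissection, immune-factor identification, exemplar extraction,
consensus clustering into immune / non-immune, the active/exhausted stroma
split, optional projection of a second cohort, differential expression and
preranked GSEA, copy-number and mutation scores, multiomics integration and
the clinical statistics — writing one TSV per stage plus a JSON manifest
recording parameters and seeds, sufficient to re-run any stage in isolation.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .classify import (
    assign_immune_class,
    build_reference,
    consensus_cluster,
    project_cohort,
    split_immune_subtypes,
)
from .cohort_stats import (
    chi_square_test,
    contingency_from_clinical,
    kaplan_meier,
    logrank_test,
    propensity_match,
)
from .contexts import synthetic_reference_signatures
from .differential import differential_expression, preranked_gsea
from .factorization import exemplar_genes, identify_immune_factor, mad_filter, nmf
from .genomics import (
    context_count_matrix,
    extract_mutational_signatures,
    fraction_genome_altered,
    aneuploidy_score,
    leukocyte_cnv_correlation,
    mutation_frequency_filter,
)
from .networks import mirna_target_links, multiomics_venn
from .scoring import ScoringConfig, ssgsea_scores
from .synthetic import CohortConfig, generate_cohort


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs; YAML-loadable."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    ssgsea_alpha: float = 0.25
    nmf_k: int = 3
    nmf_restarts: int = 5
    nmf_max_iter: int = 400
    nmf_tol: float = 1e-5
    n_top_genes: int = 1500
    exemplar_m: int = 150
    exemplar_min_ratio: float = 2.0
    consensus_resamples: int = 100
    consensus_fraction: float = 0.8
    de_fdr: float = 0.05
    de_lfc: float = 1.0
    gsea_permutations: int = 200
    mutsig_k: int = 3
    min_layers: int = 2
    project_validation: bool = True
    stages: list[str] = field(
        default_factory=lambda: [
            "simulate", "score", "nmf", "classify", "project",
            "de", "gsea", "cnv", "mutsig", "integrate", "stats", "survival",
        ]
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def class_proportions(labels: pd.Series) -> pd.DataFrame:
    """Count and percentage (2 decimals, round half-up) per class label."""
    if labels.empty:
        raise ValueError("empty assignment")
    counts = labels.value_counts()
    total = int(counts.sum())
    pct = [
        float(
            (Decimal(int(c)) * 100 / Decimal(total)).quantize(
                Decimal("0.01"), rounding=ROUND_HALF_UP
            )
        )
        for c in counts
    ]
    out = pd.DataFrame({"count": counts, "percent": pct})
    out.index.name = "class"
    return out


def run_pipeline(config: PipelineConfig | str | Path) -> dict:
    """Execute the configured stages; returns the manifest dictionary.

    A stage failure halts the run with the stage name and cause; outputs of
    completed stages remain on disk.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "parameters": asdict(config), "outputs": {}}
    state: dict = {}

    def record(stage: str, name: str, path: Path) -> None:
        manifest["outputs"].setdefault(stage, []).append(str(path))

    def log(msg: str) -> None:
        print(f"[immunodissect] {msg}", file=sys.stderr)

    for stage in config.stages:
        try:
            log(f"stage {stage} (seed={config.seed})")
            if stage == "simulate":
                cc = CohortConfig(seed=config.seed, **config.cohort)
                cohort = generate_cohort(cc)
                state["cohort"] = cohort
                pio.write_expression(cohort.expression, out / "expression.tsv")
                pio.write_clinical(cohort.clinical, out / "clinical.tsv")
                pio.write_segments(cohort.segments, out / "segments.seg")
                pio.write_maf(cohort.mutations, out / "mutations.maf")
                cohort.truth.to_json(out / "truth.json")
                for n in ["expression.tsv", "clinical.tsv", "segments.seg",
                          "mutations.maf", "truth.json"]:
                    record(stage, n, out / n)

            elif stage == "score":
                cohort = state["cohort"]
                scores = ssgsea_scores(
                    cohort.expression, cohort.gene_sets,
                    ScoringConfig(alpha=config.ssgsea_alpha),
                )
                state["scores"] = scores
                scores.scores.to_csv(out / "ssgsea_scores.tsv", sep="\t")
                record(stage, "scores", out / "ssgsea_scores.tsv")

            elif stage == "nmf":
                cohort = state["cohort"]
                filtered = mad_filter(cohort.expression, config.n_top_genes)
                model = nmf(
                    filtered, config.nmf_k, n_restarts=config.nmf_restarts,
                    max_iter=config.nmf_max_iter, tol=config.nmf_tol,
                    seed=config.seed,
                )
                immune_idx, corrs = identify_immune_factor(
                    model, state["scores"].row("immune_signature")
                )
                model.immune_factor = immune_idx
                state["model"] = model
                exem = exemplar_genes(
                    model, immune_idx, m=config.exemplar_m,
                    min_ratio=config.exemplar_min_ratio,
                )
                state["exemplars"] = exem
                model.W.to_csv(out / "nmf_W.tsv", sep="\t")
                model.H.to_csv(out / "nmf_H.tsv", sep="\t")
                exem.table.to_csv(out / "exemplar_genes.tsv", sep="\t", index=False)
                with open(out / "nmf_meta.json", "w") as fh:
                    json.dump(
                        {
                            "k": model.k, "immune_factor": immune_idx,
                            "factor_immune_correlations": corrs.to_dict(),
                            "chosen_restart": model.chosen_restart,
                            "restart_divergences": model.restart_divergences,
                            "converged": model.converged,
                            "seed": config.seed,
                        },
                        fh, indent=1,
                    )
                for n in ["nmf_W.tsv", "nmf_H.tsv", "exemplar_genes.tsv",
                          "nmf_meta.json"]:
                    record(stage, n, out / n)

            elif stage == "classify":
                cohort = state["cohort"]
                exem = state["exemplars"]
                consensus, partition = consensus_cluster(
                    cohort.expression.loc[exem.genes],
                    k_clusters=2,
                    n_resamples=config.consensus_resamples,
                    sample_fraction=config.consensus_fraction,
                    seed=config.seed,
                )
                labels2 = assign_immune_class(
                    partition, state["scores"].row("immune_signature")
                )
                assignment = split_immune_subtypes(
                    labels2,
                    state["scores"].row("activated_stroma"),
                    consensus=consensus,
                    immune_scores=state["scores"].row("immune_signature"),
                )
                state["assignment"] = assignment
                assignment.to_frame().to_csv(out / "class_labels.tsv", sep="\t")
                consensus.to_csv(out / "consensus_matrix.tsv", sep="\t")
                class_proportions(assignment.labels).to_csv(
                    out / "class_proportions.tsv", sep="\t"
                )
                for n in ["class_labels.tsv", "consensus_matrix.tsv",
                          "class_proportions.tsv"]:
                    record(stage, n, out / n)

            elif stage == "project":
                if not config.project_validation:
                    continue
                cohort = state["cohort"]
                reference = build_reference(
                    cohort.expression,
                    state["assignment"].labels,
                    state["exemplars"].genes,
                    model=state["model"],
                )
                state["reference"] = reference
                val_cfg = CohortConfig(seed=config.seed + 1, **config.cohort)
                validation = generate_cohort(val_cfg)
                state["validation"] = validation
                vscores = ssgsea_scores(
                    validation.expression, validation.gene_sets,
                    ScoringConfig(alpha=config.ssgsea_alpha),
                )
                projected = project_cohort(
                    reference,
                    validation.expression,
                    vscores.row("activated_stroma"),
                    immune_scores=vscores.row("immune_signature"),
                )
                state["projected"] = projected
                projected.to_frame().to_csv(out / "validation_labels.tsv", sep="\t")
                class_proportions(projected.labels).to_csv(
                    out / "validation_proportions.tsv", sep="\t"
                )
                for n in ["validation_labels.tsv", "validation_proportions.tsv"]:
                    record(stage, n, out / n)

            elif stage == "de":
                cohort = state["cohort"]
                labels = state["assignment"].labels
                imm = labels.map(
                    lambda c: "immune" if c != "non_immune" else "non_immune"
                )
                de = differential_expression(
                    np.log2(cohort.expression + 1.0), imm,
                    fdr=config.de_fdr, lfc=config.de_lfc,
                )
                state["de"] = de
                de.to_csv(out / "de_immune_vs_nonimmune.tsv", sep="\t")
                de_mir = differential_expression(cohort.mirna, imm, fdr=0.05, lfc=0.0)
                state["de_mirna"] = de_mir
                de_mir.to_csv(out / "de_mirna.tsv", sep="\t")
                de_lnc = differential_expression(cohort.lncrna, imm,
                                                 fdr=config.de_fdr, lfc=1.0)
                state["de_lncrna"] = de_lnc
                de_lnc.to_csv(out / "de_lncrna.tsv", sep="\t")
                de_prot = differential_expression(cohort.protein, imm,
                                                  fdr=1.0, lfc=0.0)
                # protein layer is conventionally filtered on the raw t-test p
                de_prot["pass"] = de_prot["p_value"] < 0.05
                state["de_protein"] = de_prot
                de_prot.to_csv(out / "de_protein.tsv", sep="\t")
                for n in ["de_immune_vs_nonimmune.tsv", "de_mirna.tsv",
                          "de_lncrna.tsv", "de_protein.tsv"]:
                    record(stage, n, out / n)

            elif stage == "gsea":
                ranked = state["de"]["statistic"].replace(
                    [np.inf, -np.inf], [1e6, -1e6]
                )
                res = preranked_gsea(
                    ranked, state["cohort"].gene_sets,
                    n_perm=config.gsea_permutations, seed=config.seed,
                )
                state["gsea"] = res
                res.drop(columns="leading_edge").to_csv(
                    out / "gsea_results.tsv", sep="\t"
                )
                record(stage, "gsea", out / "gsea_results.tsv")

            elif stage == "cnv":
                cohort = state["cohort"]
                fga = fraction_genome_altered(cohort.segments)
                state["fga"] = fga
                fga.to_csv(out / "fraction_genome_altered.tsv", sep="\t")
                aneu = aneuploidy_score(cohort.segments)
                state["aneuploidy"] = aneu
                aneu.to_csv(out / "aneuploidy_scores.tsv", sep="\t")
                lf = cohort.clinical["leukocyte_fraction"]
                corr = leukocyte_cnv_correlation(
                    lf, fga["n_segments"], groups=state["assignment"].labels
                )
                corr.to_csv(out / "leukocyte_cnv_correlation.tsv", sep="\t")
                for n in ["fraction_genome_altered.tsv", "aneuploidy_scores.tsv",
                          "leukocyte_cnv_correlation.tsv"]:
                    record(stage, n, out / n)

            elif stage == "mutsig":
                cohort = state["cohort"]
                counts = context_count_matrix(cohort.mutations)
                extraction = extract_mutational_signatures(
                    counts, k=config.mutsig_k, seed=config.seed,
                    reference=synthetic_reference_signatures(),
                )
                state["mutsig"] = extraction
                extraction["signatures"].to_csv(out / "signatures.tsv", sep="\t")
                extraction["exposures"].to_csv(out / "exposures.tsv", sep="\t")
                extraction["match"].to_csv(out / "signature_match.tsv", sep="\t")
                freq_genes = mutation_frequency_filter(
                    cohort.mutations, n_samples=cohort.expression.shape[1]
                )
                state["mut_genes"] = freq_genes
                pd.Series(freq_genes, name="gene").to_csv(
                    out / "frequently_mutated_genes.tsv", sep="\t", index=False
                )
                for n in ["signatures.tsv", "exposures.tsv", "signature_match.tsv",
                          "frequently_mutated_genes.tsv"]:
                    record(stage, n, out / n)

            elif stage == "integrate":
                cohort = state["cohort"]
                defms = list(
                    state["de_mirna"].index[state["de_mirna"]["adj_p"] <= 0.05]
                )
                links = mirna_target_links(
                    defms, cohort.edges_validated, cohort.edges_predicted,
                    degs=state["de"],
                )
                state["mirna_links"] = links
                links.to_csv(out / "mirna_target_links.tsv", sep="\t", index=False)
                hits = {
                    "DEG": set(state["de"].index[state["de"]["pass"]]),
                    "CNV": set(),
                    "SNP": set(state.get("mut_genes", [])),
                    "miRNA-target": set(links["gene"]),
                }
                # CNV layer: genes on arms recurrently altered is out of the
                # synthetic truth; use frequently high-burden samples' gene
                # calls when present, else leave empty
                integrated, members = multiomics_venn(hits, config.min_layers)
                state["integrated"] = integrated
                members.to_csv(out / "multiomics_membership.tsv", sep="\t")
                pd.Series(integrated, name="gene").to_csv(
                    out / "integrated_genes.tsv", sep="\t", index=False
                )
                for n in ["mirna_target_links.tsv", "multiomics_membership.tsv",
                          "integrated_genes.tsv"]:
                    record(stage, n, out / n)

            elif stage == "stats":
                cohort = state["cohort"]
                clin = cohort.clinical.copy()
                clin["class"] = state["assignment"].labels
                rows = []
                for cov in ["hpv_status", "stage", "histology"]:
                    tab = contingency_from_clinical(clin, cov)
                    chi2, df, p = chi_square_test(tab)
                    rows.append({"covariate": cov, "chi2": chi2, "df": df, "p": p})
                pd.DataFrame(rows).to_csv(
                    out / "clinical_association_tests.tsv", sep="\t", index=False
                )
                record(stage, "stats", out / "clinical_association_tests.tsv")

            elif stage == "survival":
                cohort = state["cohort"]
                clin = cohort.clinical
                labels = state["assignment"].labels
                km = kaplan_meier(clin["time"], clin["event"], labels)
                curves = pd.concat(
                    [c.assign(group=g) for g, c in km.curves.items()],
                    ignore_index=True,
                )
                curves.to_csv(out / "km_curves.tsv", sep="\t", index=False)
                chi2, df, p = logrank_test(clin["time"], clin["event"], labels)
                exhausted = (labels == "exhausted").astype(int)
                covs = clin[["age", "hpv_status", "stage", "histology"]]
                match = propensity_match(covs, exhausted, seed=config.seed)
                matched = pd.Index(
                    list(match.pairs["treated"]) + list(match.pairs["control"])
                )
                if len(matched) >= 4 and clin.loc[matched, "event"].sum() > 0:
                    chi2_adj, _, p_adj = logrank_test(
                        clin.loc[matched, "time"], clin.loc[matched, "event"],
                        exhausted.loc[matched],
                    )
                else:
                    chi2_adj, p_adj = float("nan"), float("nan")
                with open(out / "survival_tests.json", "w") as fh:
                    json.dump(
                        {
                            "logrank_3class": {"chi2": chi2, "df": df, "p": p},
                            "logrank_exhausted_after_psm": {
                                "chi2": chi2_adj, "p": p_adj,
                                "n_matched_pairs": int(match.n_matched),
                            },
                            "km_median_survival": km.medians,
                        },
                        fh, indent=1, allow_nan=True,
                    )
                for n in ["km_curves.tsv", "survival_tests.json"]:
                    record(stage, n, out / n)

            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:  # noqa: BLE001 - halt with stage provenance
            manifest["failed_stage"] = stage
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=1)
            raise StageError(stage, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
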