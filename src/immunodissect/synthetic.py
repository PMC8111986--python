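"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a bulk tumour expression cohort of the size and
composition the training data had (293 samples; roughly 52% active immune,
26% exhausted, 22% non-immune): expression is a non-negative 3-factor model
``W_true @ H_true`` (immune / activated-stroma / tumour factors) plus
Gaussian noise truncated at zero, so the NMF precondition holds exactly.
Active-immune samples load on the immune factor, exhausted samples on both
the immune and stroma factors, non-immune samples on the tumour factor.
Planted gene sets (immune, activated stroma, tumour/proliferation, plus a
few immune cell-type panels) live inside the corresponding factor's genes.

Clinical covariates (HPV status, stage, histology — each with an explicit
"Unknown" level), exponential survival with per-class hazards and uniform
censoring, per-class copy-number segment profiles, leukocyte fractions
anti-correlated with segment counts, mutation catalogues drawn from known
signature mixtures, and miRNA / lncRNA / protein layers with planted
immune-vs-non-immune shifts are generated alongside, with the full ground
truth recorded for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contexts import CONTEXTS_96, synthetic_reference_signatures
from .genesets import GeneSetCollection
from .genomics import autosomal_arm_table

CLASSES = ("active_immune", "exhausted", "non_immune")


def _default_proportions() -> dict[str, float]:
    return {"active_immune": 0.52, "exhausted": 0.26, "non_immune": 0.22}


def _default_hazards() -> dict[str, float]:
    # events per month; exhausted tumours carry the worst prognosis
    return {"active_immune": 0.010, "exhausted": 0.025, "non_immune": 0.016}


def _default_seg_profile() -> dict[str, dict[str, float]]:
    # exhausted: largest altered fraction; non-immune: most segments
    return {
        "active_immune": {"fraction_altered": 0.15, "n_segments": 60},
        "exhausted": {"fraction_altered": 0.35, "n_segments": 75},
        "non_immune": {"fraction_altered": 0.22, "n_segments": 110},
    }


def _default_signature_mixtures() -> dict[str, dict[str, float]]:
    # active immune: APOBEC C>T-flavoured; exhausted: APOBEC C>G-flavoured;
    # non-immune: clock-like + background
    return {
        "active_immune": {"apobec_tcw_ct": 0.55, "aging_cpg_ct": 0.25, "flat": 0.20},
        "exhausted": {"apobec_tcw_cg": 0.55, "aging_cpg_ct": 0.25, "flat": 0.20},
        "non_immune": {"aging_cpg_ct": 0.50, "smoking_ca": 0.30, "flat": 0.20},
    }


@dataclass
class CohortConfig:
    """Generator parameters; defaults emulate the training-cohort conditions."""

    n_samples: int = 293
    n_genes: int = 2000
    k_factors: int = 3
    class_proportions: dict[str, float] = field(default_factory=_default_proportions)
    factor_loading_scale: float = 3.0
    noise_sd: float = 0.25
    hazard_ratios: dict[str, float] = field(default_factory=_default_hazards)
    censor_t_max: float = 120.0  # months of follow-up
    seg_profile: dict[str, dict[str, float]] = field(default_factory=_default_seg_profile)
    signature_mixtures: dict[str, dict[str, float]] = field(
        default_factory=_default_signature_mixtures
    )
    mutations_per_sample: int = 120
    n_mirnas: int = 150
    n_lncrnas: int = 200
    n_proteins: int = 100
    seed: int = 0
    # gene -> factor loadings are a property of the genes, not of one cohort:
    # cohorts generated with the same biology_seed share W_true, so a
    # classifier learned on one cohort transfers to another
    biology_seed: int = 1618

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if set(self.class_proportions) != set(CLASSES):
            raise ValueError(f"class proportions must cover {CLASSES}")
        if self.k_factors < 2:
            raise ValueError("k_factors must be >= 2")
        if self.noise_sd < 0 or self.factor_loading_scale <= 0:
            raise ValueError("scales must be non-negative (loading scale positive)")
        if any(h <= 0 for h in self.hazard_ratios.values()):
            raise ValueError("hazards must be positive")


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort, for parameter-recovery tests."""

    labels: pd.Series  # sample -> class
    W_true: pd.DataFrame  # gene x factor loadings
    H_true: pd.DataFrame  # factor x sample weights
    exposures: pd.DataFrame  # signature x sample mixing proportions
    hazards: pd.Series  # sample -> true hazard rate
    factor_names: tuple[str, ...] = ("immune", "stroma", "tumour")

    def to_json(self, path) -> None:
        payload = {
            "labels": self.labels.to_dict(),
            "factor_names": list(self.factor_names),
            "hazards": self.hazards.to_dict(),
            "exposures": self.exposures.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class Cohort:
    """All generated tables of one synthetic cohort."""

    expression: pd.DataFrame
    clinical: pd.DataFrame
    segments: pd.DataFrame
    mutations: pd.DataFrame
    mirna: pd.DataFrame
    lncrna: pd.DataFrame
    protein: pd.DataFrame
    gene_sets: GeneSetCollection
    edges_validated: pd.DataFrame
    edges_predicted: pd.DataFrame
    edges_lnc_mir: pd.DataFrame
    truth: CohortTruth


def generate_mutation_catalog(
    exposures: pd.DataFrame,
    n_mutations: int | pd.Series,
    reference_signatures: pd.DataFrame | None = None,
    seed: int = 0,
    gene_pool: list[str] | None = None,
) -> pd.DataFrame:
    """Multinomial mutation catalogues from per-sample signature mixtures.

    ``exposures`` is a signature x sample matrix of simplex columns; each
    sample receives ``n_mutations`` substitutions whose 96-context counts are
    multinomial with probabilities equal to the mixture of the reference
    signature profiles. Records are minimal MAF rows with a ``context96``
    column. ``n_mutations = 0`` yields an empty catalogue.
    """
    if reference_signatures is None:
        reference_signatures = synthetic_reference_signatures()
    ref = reference_signatures
    col_sums = ref.sum(axis=0)
    if not np.allclose(col_sums, 1.0, atol=1e-9):
        raise ValueError("reference signatures must be column-stochastic")
    expo = exposures.reindex(ref.columns).fillna(0.0)
    sums = expo.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("per-sample exposures must lie on the simplex")

    rng = np.random.default_rng(seed)
    if gene_pool is None:
        gene_pool = [f"G{i:05d}" for i in range(500)]
    contexts = np.array(CONTEXTS_96, dtype=object)
    rows = []
    for sample in expo.columns:
        n_mut = int(
            n_mutations[sample] if isinstance(n_mutations, pd.Series) else n_mutations
        )
        if n_mut == 0:
            continue
        probs = (ref.to_numpy() @ expo[sample].to_numpy()).clip(min=0)
        probs = probs / probs.sum()
        counts = rng.multinomial(n_mut, probs)
        genes = rng.choice(gene_pool, size=n_mut)
        chroms = rng.choice(list("123456789"), size=n_mut)
        positions = rng.integers(1, 50_000_000, size=n_mut)
        ctx = np.repeat(contexts, counts)
        silent = rng.random(n_mut) < 0.25
        for i in range(n_mut):
            sub = ctx[i][2:5]  # e.g. C>T from A[C>T]G
            rows.append(
                {
                    "Hugo_Symbol": genes[i],
                    "Tumor_Sample_Barcode": sample,
                    "Chromosome": chroms[i],
                    "Start_Position": int(positions[i]),
                    "Reference_Allele": sub[0],
                    "Tumor_Seq_Allele2": sub[2],
                    "Variant_Classification": (
                        "Silent" if silent[i] else "Missense_Mutation"
                    ),
                    "context96": ctx[i],
                }
            )
    columns = [
        "Hugo_Symbol", "Tumor_Sample_Barcode", "Chromosome", "Start_Position",
        "Reference_Allele", "Tumor_Seq_Allele2", "Variant_Classification",
        "context96",
    ]
    return pd.DataFrame(rows, columns=columns)


def _class_vector(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    p = np.array([config.class_proportions[c] for c in CLASSES])
    return rng.choice(np.array(CLASSES, dtype=object), size=config.n_samples, p=p)


_CLINICAL_PROBS = {
    # covariate -> class -> level probabilities
    "hpv_status": {
        "levels": ("Positive", "Negative", "Unknown"),
        "active_immune": (0.92, 0.04, 0.04),
        "exhausted": (0.90, 0.05, 0.05),
        "non_immune": (0.76, 0.17, 0.07),
    },
    "stage": {
        "levels": ("I", "II", "III", "IV", "Unknown"),
        "active_immune": (0.54, 0.23, 0.15, 0.05, 0.03),
        "exhausted": (0.43, 0.24, 0.18, 0.12, 0.03),
        "non_immune": (0.66, 0.17, 0.08, 0.07, 0.02),
    },
    "histology": {
        "levels": ("Squamous", "Adenocarcinoma", "Adenosquamous", "Unknown"),
        "active_immune": (0.95, 0.02, 0.01, 0.02),
        "exhausted": (0.95, 0.01, 0.02, 0.02),
        "non_immune": (0.28, 0.64, 0.05, 0.03),
    },
}


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate one cohort; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    labels = pd.Series(_class_vector(config, rng), index=samples, name="class")

    # --- factor structure -------------------------------------------------
    # W_true comes from its own generator so that independently seeded
    # cohorts share the same gene biology (see CohortConfig.biology_seed)
    rng_bio = np.random.default_rng(config.biology_seed)
    k = config.k_factors
    scale = config.factor_loading_scale
    # compartment block sizes: the defaults suit n_genes >= ~1000 and shrink
    # proportionally for smaller gene universes
    n_immune = min(150, max(12, config.n_genes // 4))
    n_stroma = min(120, max(8, config.n_genes // 5))
    n_tumour = min(150, max(12, config.n_genes // 4))
    W = rng_bio.uniform(0.0, 0.05, size=(config.n_genes, k)) * scale / 3.0
    tumour_f = 2 % k
    half_i = n_immune // 2
    # canonical markers (first half of each block) are the compartment's
    # brightest genes and are expressed nowhere else
    W[:half_i, 0] += scale * rng_bio.uniform(1.0, 2.0, size=half_i)
    W[half_i:n_immune, 0] += scale * rng_bio.uniform(0.5, 1.5, size=n_immune - half_i)
    # the second half of each compartment block keeps a low-level
    # tumour-compartment expression, as most genes do in real bulk data
    # (it gives samples lacking the compartment correlated structure on
    # those genes); the pure markers anchor the factor's cone edge and keep
    # the factorization identifiable
    W[half_i:n_immune, tumour_f] += scale * rng_bio.uniform(
        0.04, 0.30, size=n_immune - half_i
    )
    half_s = n_stroma // 2
    W[n_immune : n_immune + half_s, 1] += scale * rng_bio.uniform(
        1.0, 2.0, size=half_s
    )
    W[n_immune + half_s : n_immune + n_stroma, 1] += scale * rng_bio.uniform(
        0.5, 1.5, size=n_stroma - half_s
    )
    W[n_immune + half_s : n_immune + n_stroma, tumour_f] += scale * rng_bio.uniform(
        0.04, 0.30, size=n_stroma - half_s
    )
    t0 = n_immune + n_stroma
    W[t0 : t0 + n_tumour, tumour_f] += scale * rng_bio.uniform(
        0.5, 1.5, size=n_tumour
    )
    # remaining genes: broadly expressed housekeeping-like background whose
    # compartment shares sit close to 1/k (nonspecific genes express in every
    # compartment at similar per-cell rates)
    n_hk = config.n_genes - t0 - n_tumour
    hk_total = scale * rng_bio.uniform(0.2, 0.9, size=n_hk)
    hk_shares = rng_bio.dirichlet(np.full(k, 25.0), size=n_hk)
    W[t0 + n_tumour :, :] += hk_total[:, None] * hk_shares

    h_means = {
        #            immune stroma tumour
        # every tumour carries some stroma; the exhausted class carries an
        # activated stromal response on top of that baseline
        "active_immune": (1.2, 0.30, 0.80),
        "exhausted": (1.0, 1.20, 0.70),
        "non_immune": (0.12, 0.35, 1.40),
    }
    H = np.empty((k, config.n_samples))
    for j, lab in enumerate(labels):
        means = np.array(h_means[lab][:k])
        H[:, j] = rng.gamma(shape=20.0, scale=means / 20.0)
    X = W @ H
    if config.noise_sd > 0:
        X = np.maximum(X + rng.normal(0.0, config.noise_sd, size=X.shape), 0.0)
    expression = pd.DataFrame(X, index=genes, columns=samples)
    expression.index.name = "gene"

    sets = GeneSetCollection()
    sets.add("immune_signature", genes[:n_immune], "planted immune factor genes")
    sets.add(
        "activated_stroma",
        genes[n_immune : n_immune + n_stroma],
        "planted activated-stroma factor genes",
    )
    sets.add("tumour_proliferation", genes[t0 : t0 + n_tumour],
             "planted tumour factor genes")
    # small cell-type panels inside the immune block, for per-cell scoring
    q = max(n_immune // 6, 2)
    for i, name in enumerate(
        ["cd8_t_cells", "b_cells", "macrophages", "dendritic_cells"]
    ):
        sets.add(name, genes[i * q : (i + 1) * q],
                 "planted immune cell-type panel")

    # --- clinical + survival ----------------------------------------------
    clinical = pd.DataFrame(index=pd.Index(samples, name="sample"))
    clinical["class"] = labels
    for cov, probs in _CLINICAL_PROBS.items():
        levels = np.array(probs["levels"], dtype=object)
        draws = np.empty(config.n_samples, dtype=object)
        for c in CLASSES:
            mask = labels.to_numpy() == c
            draws[mask] = rng.choice(levels, size=mask.sum(), p=probs[c])
        clinical[cov] = draws
    clinical["age"] = np.round(rng.normal(48.0, 13.0, config.n_samples), 1)

    hazard = labels.map(config.hazard_ratios).astype(float)
    event_time = rng.exponential(1.0 / hazard.to_numpy())
    censor_time = rng.uniform(0.0, config.censor_t_max, config.n_samples)
    observed = np.minimum(event_time, censor_time)
    clinical["time"] = np.maximum(observed, 1e-3)
    clinical["event"] = (event_time <= censor_time).astype(int)

    # --- copy-number segments ---------------------------------------------
    arms = autosomal_arm_table()
    seg_rows = []
    n_seg_actual = {}
    for j, s in enumerate(samples):
        prof = config.seg_profile[labels.iloc[j]]
        target_frac = prof["fraction_altered"]
        # per-sample dispersion so segment counts vary within a class
        target_segs = max(int(rng.poisson(prof["n_segments"])), 39)
        # split arms into segments until the target count is met
        per_arm = np.maximum(
            rng.multinomial(int(target_segs), np.full(len(arms), 1 / len(arms))), 1
        )
        count = 0
        for (arm, n_pieces) in zip(arms.itertuples(index=False), per_arm):
            cuts = np.sort(
                rng.integers(arm.start, arm.end, size=max(n_pieces - 1, 0))
            )
            bounds = [arm.start, *[int(c) for c in cuts], arm.end]
            for b0, b1 in zip(bounds[:-1], bounds[1:]):
                if b1 <= b0:
                    continue
                altered = rng.random() < target_frac
                mean = (
                    rng.uniform(0.2, 0.8) * rng.choice([-1.0, 1.0])
                    if altered
                    else rng.normal(0.0, 0.03)
                )
                seg_rows.append(
                    {"sample": s, "chromosome": arm.chromosome,
                     "start": int(b0), "end": int(b1),
                     "num_mark": int((b1 - b0) // 10_000) + 10,
                     "seg_mean": round(float(mean), 4)}
                )
                count += 1
        n_seg_actual[s] = count
    segments = pd.DataFrame(seg_rows)

    # leukocyte fraction: class-dependent level, anti-correlated with the
    # per-sample segment count within each class (the planted LF ~ CNV
    # association; coefficient sized for a rank correlation near -0.35)
    lf_mean = {"active_immune": 0.45, "exhausted": 0.35, "non_immune": 0.15}
    nseg = pd.Series(n_seg_actual).reindex(samples)
    z_within = nseg.copy().astype(float)
    for c in CLASSES:
        mask = labels == c
        sd = nseg[mask].std(ddof=0)
        z_within[mask] = (nseg[mask] - nseg[mask].mean()) / (sd if sd > 0 else 1.0)
    clinical["leukocyte_fraction"] = (
        labels.map(lf_mean) - 0.02 * z_within
        + rng.normal(0, 0.05, config.n_samples)
    ).clip(0.01, 0.95)

    # --- mutations ---------------------------------------------------------
    ref = synthetic_reference_signatures()
    expo = pd.DataFrame(0.0, index=ref.columns, columns=samples)
    for s, lab in labels.items():
        for sig, wgt in config.signature_mixtures[lab].items():
            expo.loc[sig, s] = wgt
    n_mut = pd.Series(
        rng.poisson(config.mutations_per_sample, config.n_samples), index=samples
    )
    # a few recurrently mutated genes with class-linked frequency
    mutations = generate_mutation_catalog(
        expo, n_mut, ref, seed=int(rng.integers(2**31 - 1)), gene_pool=genes[:800],
    )
    hot1, hot2, hot3 = genes[-3], genes[-2], genes[-1]
    recurrent = {hot1: 0.35, hot2: 0.20, hot3: 0.12}
    extra = []
    for g, base in recurrent.items():
        for s, lab in labels.items():
            freq = base * (1.6 if lab != "non_immune" and g == hot1 else 1.0)
            if rng.random() < freq:
                extra.append(
                    {"Hugo_Symbol": g, "Tumor_Sample_Barcode": s,
                     "Chromosome": "1", "Start_Position": 1_000_000,
                     "Reference_Allele": "C", "Tumor_Seq_Allele2": "T",
                     "Variant_Classification": "Missense_Mutation",
                     "context96": "A[C>T]G"}
                )
    if extra:
        mutations = pd.concat(
            [mutations, pd.DataFrame(extra)], ignore_index=True
        )

    # --- miRNA / lncRNA / protein layers ------------------------------------
    def _layer(prefix: str, n_feat: int, n_diff: int, shift: float) -> pd.DataFrame:
        ids = [f"{prefix}{i:04d}" for i in range(n_feat)]
        M = rng.normal(6.0, 1.0, size=(n_feat, config.n_samples))
        immune_mask = (labels != "non_immune").to_numpy()
        M[:n_diff, immune_mask] += shift
        return pd.DataFrame(M, index=ids, columns=samples)

    mirna = _layer("mir-", config.n_mirnas, 20, 1.6)
    lncrna = _layer("lnc-", config.n_lncrnas, 25, 1.8)
    protein = _layer("prot-", config.n_proteins, 15, 1.2)

    # interaction edge tables consistent with the differential features
    diff_mirs = list(mirna.index[:20])
    val_rows, pred_rows = [], []
    for i, mir in enumerate(mirna.index[:40]):
        targets = rng.choice(genes[:400], size=6, replace=False)
        for t in targets:
            val_rows.append({"mirna": mir, "gene": t, "db": "validated_db"})
            pred_rows.append({"mirna": mir, "gene": t, "db": "pred_db_a"})
            if rng.random() < 0.7:
                pred_rows.append({"mirna": mir, "gene": t, "db": "pred_db_b"})
    lnc_rows = []
    for lnc in lncrna.index[:30]:
        for mir in rng.choice(diff_mirs, size=3, replace=False):
            lnc_rows.append({"lncrna": lnc, "mirna": mir})

    truth = CohortTruth(
        labels=labels,
        W_true=pd.DataFrame(
            W, index=genes, columns=["immune", "stroma", "tumour"][:k]
        ),
        H_true=pd.DataFrame(
            H, index=["immune", "stroma", "tumour"][:k], columns=samples
        ),
        exposures=expo,
        hazards=hazard.rename("hazard"),
    )
    return Cohort(
        expression=expression,
        clinical=clinical,
        segments=segments,
        mutations=mutations,
        mirna=mirna,
        lncrna=lncrna,
        protein=protein,
        gene_sets=sets,
        edges_validated=pd.DataFrame(val_rows),
        edges_predicted=pd.DataFrame(pred_rows),
        edges_lnc_mir=pd.DataFrame(lnc_rows),
        truth=truth,
    )
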