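"""Copy-number and somatic-mutation scores.

Segment tables are SEG-style: per-sample genomic intervals with a
``seg_mean`` in log2 relative copy-number space. Burden is the fraction of
covered bases deviating from baseline ploidy (|seg_mean| > 0.1, strict);
gene-level gain/loss calls use the printed thresholds (> 0.3 gain,
< -0.3 loss, strict); the aneuploidy score counts chromosome arms whose
length-weighted mean seg_mean exceeds +/-0.1 in magnitude. Mutational
signatures are extracted from 96-context catalogues by the same KL NMF used
for expression, with column-stochastic signature profiles and non-negative
exposures.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .contexts import CONTEXTS_96
from .differential import benjamini_hochberg
from .factorization import nmf

SEG_COLUMNS = ["sample", "chromosome", "start", "end", "seg_mean"]

# Approximate hg38 chromosome lengths and centromere midpoints (Mb-rounded).
# A standard reference constant, embedded so arm-level scores need no
# external file; acrocentric short arms (13p, 14p, 15p, 21p, 22p) are
# excluded as usual, leaving 39 autosomal arms.
_HG38_CHROM = {
    # chrom: (length_bp, centromere_bp)
    "1": (248_956_422, 123_400_000), "2": (242_193_529, 93_900_000),
    "3": (198_295_559, 90_900_000), "4": (190_214_555, 50_000_000),
    "5": (181_538_259, 48_800_000), "6": (170_805_979, 59_800_000),
    "7": (159_345_973, 60_100_000), "8": (145_138_636, 45_200_000),
    "9": (138_394_717, 43_000_000), "10": (133_797_422, 39_800_000),
    "11": (135_086_622, 53_400_000), "12": (133_275_309, 35_500_000),
    "13": (114_364_328, 17_700_000), "14": (107_043_718, 17_200_000),
    "15": (101_991_189, 19_000_000), "16": (90_338_345, 36_800_000),
    "17": (83_257_441, 25_100_000), "18": (80_373_285, 18_500_000),
    "19": (58_617_616, 26_200_000), "20": (64_444_167, 28_100_000),
    "21": (46_709_983, 12_000_000), "22": (50_818_468, 15_000_000),
}
_ACROCENTRIC = {"13", "14", "15", "21", "22"}


def autosomal_arm_table() -> pd.DataFrame:
    """39 autosomal chromosome arms (approximate hg38 coordinates, 1-based)."""
    rows = []
    for chrom, (length, cen) in _HG38_CHROM.items():
        if chrom not in _ACROCENTRIC:
            rows.append({"arm": f"{chrom}p", "chromosome": chrom,
                         "start": 1, "end": cen})
        rows.append({"arm": f"{chrom}q", "chromosome": chrom,
                     "start": cen + 1, "end": length})
    return pd.DataFrame(rows)


def _check_segments(segments: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SEG_COLUMNS if c not in segments.columns]
    if missing:
        raise ValueError(f"segment table missing columns: {missing}")
    if (segments["end"] < segments["start"]).any():
        raise ValueError("segment with end < start")
    return segments


def _overlap_weighted_mean(
    seg: pd.DataFrame, chrom: str, start: int, end: int
) -> tuple[float, int]:
    """Length-weighted mean seg_mean over [start, end] and covered bases."""
    sub = seg[seg["chromosome"].astype(str) == str(chrom)]
    if sub.empty:
        return np.nan, 0
    ov_start = np.maximum(sub["start"].to_numpy(), start)
    ov_end = np.minimum(sub["end"].to_numpy(), end)
    lengths = np.maximum(ov_end - ov_start + 1, 0)
    covered = int(lengths.sum())
    if covered == 0:
        return np.nan, 0
    mean = float((lengths * sub["seg_mean"].to_numpy()).sum() / covered)
    return mean, covered


def call_gains_losses(
    segments: pd.DataFrame,
    gene_coords: pd.DataFrame,
    gain_thr: float = 0.3,
    loss_thr: float = -0.3,
) -> pd.DataFrame:
    """Per-sample per-gene copy-number calls from length-weighted means.

    ``gene_coords`` needs columns gene / chromosome / start / end (1-based
    inclusive, same build as the segments). A gene's call is gain when its
    weighted mean seg_mean is strictly above ``gain_thr``, loss when strictly
    below ``loss_thr``, otherwise neutral; genes with no overlapping segment
    are neutral with ``missing_data=True``.
    """
    _check_segments(segments)
    rows = []
    for sample, seg in segments.groupby("sample", sort=True):
        for g in gene_coords.itertuples(index=False):
            mean, covered = _overlap_weighted_mean(
                seg, g.chromosome, int(g.start), int(g.end)
            )
            if covered == 0:
                call, missing = "neutral", True
                mean = np.nan
            else:
                missing = False
                if mean > gain_thr:
                    call = "gain"
                elif mean < loss_thr:
                    call = "loss"
                else:
                    call = "neutral"
            rows.append(
                {"sample": sample, "gene": g.gene, "call": call,
                 "weighted_mean": mean, "missing_data": missing}
            )
    return pd.DataFrame(rows)


def fraction_genome_altered(
    segments: pd.DataFrame, thr: float = 0.1
) -> pd.DataFrame:
    """Per-sample fraction of covered bases with |seg_mean| > thr, and segment count."""
    _check_segments(segments)
    rows = []
    for sample, seg in segments.groupby("sample", sort=True):
        lengths = (seg["end"] - seg["start"] + 1).to_numpy(dtype=float)
        total = lengths.sum()
        if total <= 0:
            raise ValueError(f"sample {sample}: zero total segment length")
        altered = lengths[np.abs(seg["seg_mean"].to_numpy()) > thr].sum()
        rows.append(
            {"sample": sample, "fraction_altered": altered / total,
             "n_segments": len(seg)}
        )
    return pd.DataFrame(rows).set_index("sample")


def aneuploidy_score(
    segments: pd.DataFrame,
    arms: pd.DataFrame | None = None,
    arm_thr: float = 0.1,
) -> pd.DataFrame:
    """Per-sample count of amplified or deleted chromosome arms.

    An arm's value is the length-weighted mean seg_mean over the segments
    overlapping it; the arm counts toward the score when |value| > arm_thr.
    Arms with no covered bases in a sample are skipped and counted in
    ``n_arms_skipped``.
    """
    _check_segments(segments)
    if arms is None:
        arms = autosomal_arm_table()
    rows = []
    for sample, seg in segments.groupby("sample", sort=True):
        score = 0
        skipped = 0
        for a in arms.itertuples(index=False):
            mean, covered = _overlap_weighted_mean(
                seg, a.chromosome, int(a.start), int(a.end)
            )
            if covered == 0:
                skipped += 1
                continue
            if abs(mean) > arm_thr:
                score += 1
        rows.append(
            {"sample": sample, "aneuploidy_score": score,
             "n_arms_skipped": skipped}
        )
    return pd.DataFrame(rows).set_index("sample")


_SILENT_CLASSES = {"Silent", "silent", "Synonymous", "synonymous"}


def mutation_frequency_filter(
    catalog: pd.DataFrame, n_samples: int, min_freq: float = 0.05
) -> list[str]:
    """Genes non-silently mutated in strictly more than min_freq * n_samples samples.

    Multiple records of a gene in one sample count once. An empty catalogue
    yields an empty list.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if catalog.empty:
        return []
    nonsilent = catalog[
        ~catalog["Variant_Classification"].isin(_SILENT_CLASSES)
    ]
    counts = (
        nonsilent.drop_duplicates(["Hugo_Symbol", "Tumor_Sample_Barcode"])
        .groupby("Hugo_Symbol")
        .size()
    )
    keep = counts[counts > min_freq * n_samples]
    return sorted(keep.index)


def context_count_matrix(catalog: pd.DataFrame) -> pd.DataFrame:
    """96-context x sample mutation counts from a catalogue with context codes."""
    if catalog.empty:
        return pd.DataFrame(index=pd.Index(CONTEXTS_96, name="context"))
    bad = set(catalog["context96"].dropna()) - set(CONTEXTS_96)
    if bad:
        raise ValueError(f"non-canonical context codes: {sorted(bad)[:5]}")
    counts = (
        catalog.dropna(subset=["context96"])
        .groupby(["context96", "Tumor_Sample_Barcode"])
        .size()
        .unstack(fill_value=0)
    )
    return counts.reindex(CONTEXTS_96, fill_value=0).rename_axis("context")


def extract_mutational_signatures(
    context_counts: pd.DataFrame,
    k: int,
    n_restarts: int = 5,
    max_iter: int = 500,
    seed: int = 0,
    reference: pd.DataFrame | None = None,
) -> dict:
    """NMF decomposition of a 96 x sample catalogue into signatures and exposures.

    Returns ``signatures`` (96 x k, column-stochastic), ``exposures``
    (k x sample, scaled so signatures @ exposures reconstructs expected
    counts) and, when a reference table is given, a cosine-similarity
    ``match`` report of each extracted signature against the reference.
    All-zero sample columns are dropped with a warning.
    """
    counts = context_counts.copy()
    zero = counts.sum(axis=0) == 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} all-zero sample columns",
            RuntimeWarning,
            stacklevel=2,
        )
        counts = counts.loc[:, ~zero]
    if not k < counts.shape[1]:
        raise ValueError("k must be smaller than the number of samples")
    # KL NMF cannot have all-zero rows; add nothing, just drop and restore
    nonzero_rows = counts.sum(axis=1) > 0
    model = nmf(
        counts.loc[nonzero_rows], k, n_restarts=n_restarts,
        max_iter=max_iter, seed=seed,
    )
    # nmf() returns W with unit-L1 columns already; re-embed zero rows
    S = model.W.reindex(counts.index, fill_value=0.0)
    S.columns = [f"extracted_{i}" for i in range(k)]
    E = model.H.copy()
    E.index = S.columns

    out = {"signatures": S, "exposures": E, "model": model}
    if reference is not None:
        ref = reference.reindex(counts.index).fillna(0.0)
        sim = _cosine_table(S, ref)
        out["match"] = sim
    return out


def _cosine_table(A: pd.DataFrame, B: pd.DataFrame) -> pd.DataFrame:
    a = A.to_numpy(dtype=float)
    b = B.to_numpy(dtype=float)
    na = np.linalg.norm(a, axis=0, keepdims=True)
    nb = np.linalg.norm(b, axis=0, keepdims=True)
    sim = (a / np.maximum(na, 1e-12)).T @ (b / np.maximum(nb, 1e-12))
    return pd.DataFrame(sim, index=A.columns, columns=B.columns)


def differential_alteration_test(
    altered: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Per-feature chi-square (Fisher fallback) test of alteration vs group.

    ``altered`` is a feature x sample boolean matrix. For each feature a
    2 x g contingency (altered / not x group) is tested by Pearson
    chi-square without continuity correction; when any expected count is
    below 5 and there are two groups, Fisher's exact test is used instead
    (for more than two groups the chi-square is kept and flagged). Features
    altered in zero samples are skipped. BH adjustment across features.
    """
    g = groups.reindex(altered.columns)
    if g.isna().any():
        raise ValueError("group labels missing for some samples")
    levels = list(pd.unique(g))
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    for feat in altered.index:
        flags = altered.loc[feat].astype(bool)
        if not flags.any():
            continue
        table = np.array(
            [
                [(flags & (g == lv)).sum() for lv in levels],
                [(~flags & (g == lv)).sum() for lv in levels],
            ]
        )
        keep_cols = table.sum(axis=0) > 0
        table = table[:, keep_cols]
        if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
            continue
        expected = stats.contingency.expected_freq(table)
        low = (expected < 5).any()
        if low and table.shape == (2, 2):
            _, p = stats.fisher_exact(table)
            method = "fisher"
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            method = "chi2_low_expected" if low else "chi2"
        rows.append({"feature": feat, "p_value": p, "method": method})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["adj_p"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out.set_index("feature")


def leukocyte_cnv_correlation(
    leukocyte_fraction: pd.Series,
    n_segments: pd.Series,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Spearman correlation of leukocyte fraction with segment counts.

    Average ranks on ties. Returns one row per group plus a pooled row;
    requires >= 4 paired finite values per group and non-constant vectors.
    """
    lf = leukocyte_fraction
    ns = n_segments.reindex(lf.index)

    def one(name, x, y):
        x, y = np.asarray(x, float), np.asarray(y, float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 4:
            raise ValueError(f"group {name}: fewer than 4 paired values")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"group {name}: constant vector")
        rho, p = stats.spearmanr(x, y)
        return {"group": name, "spearman_rho": rho, "p_value": p, "n": len(x)}

    rows = [one("pooled", lf, ns)]
    if groups is not None:
        g = groups.reindex(lf.index)
        for lv in pd.unique(g.dropna()):
            sel = g == lv
            rows.append(one(lv, lf[sel], ns[sel]))
    return pd.DataFrame(rows).set_index("group")
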