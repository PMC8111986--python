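"""Consensus clustering, immune-class assignment, subtype split, projection."""

import numpy as np
import pandas as pd
import pytest

from immunodissect.classify import (
    assign_immune_class,
    build_reference,
    consensus_cluster,
    project_cohort,
    split_immune_subtypes,
    two_means_split_1d,
)


def _block_data(rng, n_a=20, n_b=20, n_genes=60):
    """Two well-separated sample blocks with distinct gene signatures."""
    X = rng.normal(0, 0.3, (n_genes, n_a + n_b))
    X[: n_genes // 2, :n_a] += 4.0
    X[n_genes // 2 :, n_a:] += 4.0
    return pd.DataFrame(
        X,
        index=[f"g{i:03d}" for i in range(n_genes)],
        columns=[f"s{j:03d}" for j in range(n_a + n_b)],
    )


class TestConsensusCluster:
    def test_planted_blocks_have_large_consensus_gap(self, rng):
        expr = _block_data(rng)
        cons, part = consensus_cluster(expr, n_resamples=50, seed=1)
        same = np.zeros((40, 40), dtype=bool)
        same[:20, :20] = True
        same[20:, 20:] = True
        np.fill_diagonal(same, False)
        within = cons.to_numpy()[same].mean()
        between = cons.to_numpy()[~same & ~np.eye(40, dtype=bool)].mean()
        assert within - between > 0.8
        assert part.nunique() == 2

    def test_full_fraction_gives_binary_consensus(self, rng):
        expr = _block_data(rng)
        cons, _ = consensus_cluster(
            expr, n_resamples=10, sample_fraction=1.0, seed=0
        )
        vals = np.unique(np.round(cons.to_numpy(), 12))
        assert set(vals) <= {0.0, 1.0}

    def test_consensus_matrix_is_valid(self, rng):
        expr = _block_data(rng)
        cons, _ = consensus_cluster(expr, n_resamples=30, seed=5)
        M = cons.to_numpy()
        assert ((M >= 0) & (M <= 1)).all()
        np.testing.assert_allclose(M, M.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(M), 1.0)

    def test_sample_permutation_gives_same_partition(self, rng):
        expr = _block_data(rng)
        _, part = consensus_cluster(expr, n_resamples=40, seed=2)
        perm = rng.permutation(expr.columns)
        _, part_p = consensus_cluster(expr[perm], n_resamples=40, seed=2)
        # identical up to relabeling: co-membership must agree
        a = part.reindex(expr.columns).to_numpy()
        b = part_p.reindex(expr.columns).to_numpy()
        assert (
            (a[:, None] == a[None, :]) == (b[:, None] == b[None, :])
        ).all()

    def test_all_constant_rows_error(self):
        expr = pd.DataFrame(np.ones((5, 10)))
        with pytest.raises(ValueError, match="constant"):
            consensus_cluster(expr)


class TestAssignImmuneClass:
    def test_cluster_id_swap_invariance(self):
        part = pd.Series([1, 1, 2, 2], index=list("abcd"))
        scores = pd.Series([5.0, 4.0, 1.0, 2.0], index=list("abcd"))
        lab1 = assign_immune_class(part, scores)
        lab2 = assign_immune_class(part.map({1: 2, 2: 1}), scores)
        assert (lab1 == lab2).all()
        assert lab1["a"] == "immune" and lab1["c"] == "non_immune"

    def test_indistinguishable_means_error(self):
        part = pd.Series([1, 1, 2, 2], index=list("abcd"))
        scores = pd.Series([1.0, 2.0, 2.0, 1.0], index=list("abcd"))
        with pytest.raises(ValueError, match="indistinguishable"):
            assign_immune_class(part, scores)

    def test_single_cluster_error(self):
        part = pd.Series([1, 1, 1], index=list("abc"))
        with pytest.raises(ValueError, match="2 clusters"):
            assign_immune_class(part, pd.Series([1.0, 2.0, 3.0], index=list("abc")))

    def test_planted_cohort_recovers_immune_class(
        self, small_cohort, small_assignment
    ):
        truth2 = small_cohort.truth.labels.map(
            lambda c: "non_immune" if c == "non_immune" else "immune"
        )
        pred2 = small_assignment.labels.map(
            lambda c: "non_immune" if c == "non_immune" else "immune"
        )
        agreement = (truth2 == pred2).mean()
        assert agreement >= 0.95


class TestTwoMeansSplit:
    def test_bimodal_split_and_shift_invariance(self, rng):
        vals = np.concatenate([rng.normal(0, 0.5, 30), rng.normal(5, 0.5, 20)])
        upper, thr = two_means_split_1d(vals)
        assert upper.sum() == 20
        upper_shift, thr_shift = two_means_split_1d(vals + 100.0)
        assert (upper == upper_shift).all()
        assert thr_shift == pytest.approx(thr + 100.0, abs=1e-9)

    def test_all_equal_error(self):
        with pytest.raises(ValueError, match="equal"):
            two_means_split_1d(np.ones(10))


class TestSplitImmuneSubtypes:
    def test_planted_exhausted_recovered(self, small_cohort, small_assignment):
        truth = small_cohort.truth.labels
        in_immune = truth != "non_immune"
        acc = (
            small_assignment.labels[in_immune] == truth[in_immune]
        ).mean()
        assert acc >= 0.95

    def test_small_immune_class_error(self):
        labels = pd.Series(
            ["immune", "immune", "non_immune", "non_immune"], index=list("abcd")
        )
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        with pytest.raises(ValueError, match="fewer than 4"):
            split_immune_subtypes(labels, scores)


class TestProjection:
    def test_self_consistency(
        self, small_cohort, small_assignment, small_exemplars, small_model,
        small_scores,
    ):
        ref = build_reference(
            small_cohort.expression,
            small_assignment.labels,
            small_exemplars.genes,
            model=small_model,
        )
        proj = project_cohort(
            ref,
            small_cohort.expression,
            small_scores.row("activated_stroma"),
        )
        assert proj.provenance == "projected"
        assert (proj.labels == small_assignment.labels).mean() >= 0.95

    def test_independent_cohort_truth_accuracy(
        self, small_config, small_cohort, small_assignment, small_exemplars,
        small_model,
    ):
        from dataclasses import replace

        from immunodissect import ssgsea_scores
        from immunodissect.synthetic import generate_cohort

        ref = build_reference(
            small_cohort.expression,
            small_assignment.labels,
            small_exemplars.genes,
            model=small_model,
        )
        fresh = generate_cohort(replace(small_config, seed=small_config.seed + 1))
        fresh_scores = ssgsea_scores(fresh.expression, fresh.gene_sets)
        proj = project_cohort(
            ref, fresh.expression, fresh_scores.row("activated_stroma")
        )
        assert (proj.labels == fresh.truth.labels).mean() >= 0.9

    def test_insufficient_overlap_lists_missing_genes(
        self, small_cohort, small_assignment, small_exemplars
    ):
        ref = build_reference(
            small_cohort.expression,
            small_assignment.labels,
            small_exemplars.genes,
        )
        tiny = small_cohort.expression.iloc[:5]
        with pytest.raises(ValueError, match="missing"):
            project_cohort(
                ref, tiny, pd.Series(1.0, index=tiny.columns)
            )

    def test_nnls_mode_agrees_with_truth_coarsely(
        self, small_cohort, small_assignment, small_exemplars, small_model,
        small_scores, small_immune_factor,
    ):
        small_model.immune_factor = small_immune_factor
        ref = build_reference(
            small_cohort.expression,
            small_assignment.labels,
            small_exemplars.genes,
            model=small_model,
        )
        proj = project_cohort(
            ref,
            small_cohort.expression,
            small_scores.row("activated_stroma"),
            mode="nnls",
        )
        truth2 = small_cohort.truth.labels.map(
            lambda c: False if c == "non_immune" else True
        )
        pred2 = proj.labels.map(lambda c: c != "non_immune")
        assert (truth2 == pred2).mean() >= 0.9
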