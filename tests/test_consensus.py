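import numpy as np
import pandas as pd
import pytest

from perturbsig import (
    GeneratorConfig,
    build_consensus,
    gene_seed_decomposition_scatter,
    generate_signature_dataset,
    leave_one_out_consensus,
    modz_weights,
    on_target_filter_crosscell,
    spearman_correlation,
    target_gene_rank,
    target_rank_table,
)
from perturbsig.errors import InvalidGroupingError, InvalidInputError


class TestModzWeights:
    def test_two_members_always_equal(self):
        for c in (-0.9, 0.0, 0.7):
            corr = np.array([[1.0, c], [c, 1.0]])
            assert modz_weights(corr) == pytest.approx([0.5, 0.5])

    def test_hand_computed_three_member_example(self):
        # zeroed-diagonal row sums [1.6, 1.0, 1.0] -> normalize by 3.6
        corr = np.array([
            [1.0, 0.8, 0.8],
            [0.8, 1.0, 0.2],
            [0.8, 0.2, 1.0],
        ])
        expect = np.array([1.6, 1.0, 1.0]) / 3.6
        assert modz_weights(corr) == pytest.approx(expect, abs=1e-12)

    def test_all_negative_rows_fall_back_to_equal(self):
        corr = np.array([
            [1.0, -0.5, -0.3],
            [-0.5, 1.0, -0.2],
            [-0.3, -0.2, 1.0],
        ])
        assert modz_weights(corr) == pytest.approx([1 / 3] * 3)

    def test_negative_row_clipped_to_zero(self):
        corr = np.array([
            [1.0, 0.9, -0.95],
            [0.9, 1.0, -0.1],
            [-0.95, -0.1, 1.0],
        ])
        w = modz_weights(corr)
        assert w[2] == 0.0
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_diagonal_is_ignored(self):
        base = np.array([[1.0, 0.4], [0.4, 1.0]])
        spiked = np.array([[5.0, 0.4], [0.4, -3.0]])
        assert modz_weights(base) == pytest.approx(modz_weights(spiked))

    def test_singleton_rejected(self):
        with pytest.raises(InvalidInputError):
            modz_weights(np.array([[1.0]]))


class TestBuildConsensus:
    def test_identical_signatures_returned_unchanged(self):
        s = np.array([1.0, -2.0, 3.0, 0.0])
        cs = build_consensus(np.column_stack([s, s, s]))
        assert np.allclose(cs.values, s)

    def test_two_signatures_arithmetic_mean(self, rng):
        vals = rng.normal(size=(20, 2))
        cs = build_consensus(vals)
        assert np.allclose(cs.values, vals.mean(axis=1))

    def test_composition_with_modz_weights(self, rng):
        from perturbsig import pairwise_correlation_matrix

        vals = rng.normal(size=(30, 3))
        cs = build_consensus(vals)
        w = modz_weights(pairwise_correlation_matrix(vals))
        assert np.allclose(cs.values, vals @ w)
        assert cs.weights == pytest.approx(w)

    def test_singleton_group_weight_one(self):
        s = np.array([[1.0], [2.0], [3.0]])
        cs = build_consensus(s, ["only"])
        assert cs.weights == pytest.approx([1.0])
        assert np.allclose(cs.values, s[:, 0])

    def test_mixed_cell_lines_rejected(self, rng):
        with pytest.raises(InvalidGroupingError):
            build_consensus(rng.normal(size=(10, 2)),
                            cell_lines=["A375", "MCF7"])


class TestLeaveOneOut:
    def test_group_of_two_returns_other_member(self, rng):
        vals = rng.normal(size=(15, 2))
        cs = leave_one_out_consensus(vals, held_out_index=0)
        assert np.allclose(cs.values, vals[:, 1])

    def test_out_of_range_index_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            leave_one_out_consensus(rng.normal(size=(10, 3)), held_out_index=3)

    def test_matches_explicit_remainder(self, rng):
        vals = rng.normal(size=(25, 4))
        cs = leave_one_out_consensus(vals, held_out_index=2)
        explicit = build_consensus(vals[:, [0, 1, 3]])
        assert np.allclose(cs.values, explicit.values)


class TestTargetGeneRank:
    def test_extremes(self):
        genes = ["G1", "G2", "G3", "G4"]
        vals = np.array([-5.0, 0.0, 1.0, 2.0])
        assert target_gene_rank(vals, genes, "G1") == 1
        assert target_gene_rank(vals, genes, "G4") == 4

    def test_tie_broken_by_gene_order(self):
        genes = ["GA", "GB", "GC"]
        vals = np.array([0.5, 0.5, 1.0])
        assert target_gene_rank(vals, genes, "GA") == 1
        assert target_gene_rank(vals, genes, "GB") == 2

    def test_non_landmark_target_rejected(self):
        with pytest.raises(InvalidInputError):
            target_gene_rank(np.zeros(3), ["G1", "G2", "G3"], "G9")

    def test_top_percent_cutoff_is_rank_nine_of_978(self):
        assert int(0.01 * 978) == 9

    def test_consensus_improves_target_rank_fraction(
        self, default_shrna_collapsed
    ):
        collapsed, _ = default_shrna_collapsed
        cgs_ranks = target_rank_table(collapsed, use_consensus=True)["rank"]
        ind_ranks = target_rank_table(collapsed, use_consensus=False)["rank"]
        assert (cgs_ranks <= 9).mean() > (ind_ranks <= 9).mean()


class TestDecompositionScatter:
    def test_no_seed_collisions_gives_empty_table(self):
        cfg = GeneratorConfig(n_genes_targeted=3, reagents_per_gene=2,
                              n_seed_pool=500, n_cell_lines=1,
                              n_landmarks=60, rng_seed=0)
        dataset, _ = generate_signature_dataset(cfg)
        scatter = gene_seed_decomposition_scatter(dataset)
        assert scatter.empty

    def test_on_target_reagents_score_high_cgs_low_css(self):
        cfg = GeneratorConfig(n_genes_targeted=8, reagents_per_gene=4,
                              n_seed_pool=6, n_cell_lines=1,
                              beta_seed=0.0, sigma_noise=0.2, rng_seed=4)
        dataset, _ = generate_signature_dataset(cfg)
        scatter = gene_seed_decomposition_scatter(dataset)
        assert len(scatter) > 0
        assert scatter["cgs_corr"].mean() > 0.5
        assert scatter["cgs_corr"].mean() > scatter["css_corr"].abs().mean()

    def test_off_target_reagents_score_high_css(self):
        cfg = GeneratorConfig(n_genes_targeted=8, reagents_per_gene=4,
                              n_seed_pool=6, n_cell_lines=1,
                              alpha_on=0.0, sigma_noise=0.2, rng_seed=4)
        dataset, _ = generate_signature_dataset(cfg)
        scatter = gene_seed_decomposition_scatter(dataset)
        assert scatter["css_corr"].mean() > scatter["cgs_corr"].mean()

    def test_loo_cgs_beats_random_other_reagent(self, default_shrna_collapsed):
        collapsed, _ = default_shrna_collapsed
        scatter = gene_seed_decomposition_scatter(collapsed)
        rng = np.random.default_rng(0)
        sub = scatter.sample(n=min(len(scatter), 100), random_state=1)
        rand_corrs = []
        ids = list(collapsed.meta.index)
        for row in sub.itertuples():
            focal = f"{row.reagent_id}:{row.cell_line}"
            other = ids[rng.integers(len(ids))]
            if other == focal:
                continue
            rand_corrs.append(spearman_correlation(
                collapsed.data[focal], collapsed.data[other]
            ))
        assert sub["cgs_corr"].mean() > np.mean(rand_corrs)


class TestCrossCellFilter:
    def _scatter(self):
        return pd.DataFrame([
            dict(reagent_id="r1", cell_line="A", cgs_corr=0.3, css_corr=0.1),
            dict(reagent_id="r1", cell_line="B", cgs_corr=0.4, css_corr=0.05),
            dict(reagent_id="r2", cell_line="A", cgs_corr=0.3, css_corr=-0.25),
            dict(reagent_id="r2", cell_line="B", cgs_corr=0.1, css_corr=0.1),
            dict(reagent_id="r3", cell_line="A", cgs_corr=0.05, css_corr=0.5),
            dict(reagent_id="r3", cell_line="B", cgs_corr=0.02, css_corr=0.4),
        ])

    def test_threshold_rules(self):
        flags, _ = on_target_filter_crosscell(self._scatter())
        by = flags.set_index(["reagent_id", "cell_line"])["on_target"]
        assert bool(by[("r1", "A")]) is True
        # |css| >= 0.2 fails the filter even at high cgs (absolute value rule)
        assert bool(by[("r2", "A")]) is False
        assert bool(by[("r3", "A")]) is False

    def test_hand_computed_odds_ratio(self):
        rows = []
        # 10 both-flagged, 2 A-only, 3 B-only, 15 neither
        for i, (fa, fb) in enumerate(
            [(True, True)] * 10 + [(True, False)] * 2
            + [(False, True)] * 3 + [(False, False)] * 15
        ):
            rows.append(dict(reagent_id=f"r{i}", cell_line="A",
                             cgs_corr=0.3 if fa else 0.0,
                             css_corr=0.0 if fa else 0.5))
            rows.append(dict(reagent_id=f"r{i}", cell_line="B",
                             cgs_corr=0.3 if fb else 0.0,
                             css_corr=0.0 if fb else 0.5))
        _, pairs = on_target_filter_crosscell(pd.DataFrame(rows))
        assert len(pairs) == 1
        assert pairs["odds_ratio"].iloc[0] == pytest.approx(25.0)

    def test_consistent_flags_give_large_odds_ratio(self, default_shrna_collapsed):
        collapsed, _ = default_shrna_collapsed
        scatter = gene_seed_decomposition_scatter(collapsed)
        _, pairs = on_target_filter_crosscell(scatter)
        assert len(pairs) == 3  # 3 cell-line pairs
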