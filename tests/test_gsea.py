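"""GSEA core: ranking metric, enrichment score, permutation null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parpibench.expression import ExpressionMatrix, PhenotypeLabels
from parpibench.genesets import GeneSet
from parpibench.gsea import (
    GSEAConfig,
    RankedList,
    enrichment_score,
    permutation_null,
    rank_by_signal_to_noise,
    score_gene_set,
)
from parpibench.simulate import CohortSpec, simulate_expression


def brute_force_es(metric, member, p):
    """Independent prefix-loop recomputation of the running-sum extremum."""
    metric = np.asarray(metric, dtype=float)
    member = np.asarray(member, dtype=bool)
    n, nh = len(metric), member.sum()
    weights = np.abs(metric) ** p
    denom_hit = weights[member].sum()
    p_hit = p_miss = 0.0
    best = 0.0
    for i in range(n):
        if member[i]:
            p_hit += weights[i]
        else:
            p_miss += 1.0
        cur = p_hit / denom_hit - p_miss / (n - nh)
        if abs(cur) > abs(best):
            best = cur
    return best


def small_cohort(n_per_class=5, n_genes=30, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(2 * n_per_class)]
    matrix = ExpressionMatrix(
        pd.DataFrame(rng.standard_normal((n_genes, 2 * n_per_class)), index=genes, columns=samples)
    )
    labels = PhenotypeLabels(
        samples, ["A"] * n_per_class + ["B"] * n_per_class, ("A", "B")
    )
    return matrix, labels


class TestSignalToNoise:
    def test_equal_class_means_give_zero(self):
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]],
            index=["g"],
            columns=[f"s{i}" for i in range(6)],
        )
        labels = PhenotypeLabels(list(df.columns), ["A"] * 3 + ["B"] * 3, ("A", "B"))
        ranked = rank_by_signal_to_noise(ExpressionMatrix(df), labels)
        assert ranked.metric_values[0] == 0.0

    def test_matches_hand_calculation_with_flooring(self):
        # gene "up": A = (10, 12, 14), B = (1, 2, 3)
        # means 12, 2; sds 2, 1 -> floors max(0.2*12,0.2)=2.4, max(0.2*2,0.2)=1
        # s2n = (12-2)/(2.4+1) = 2.9412
        df = pd.DataFrame(
            [[10.0, 12.0, 14.0, 1.0, 2.0, 3.0], [0.0] * 6],
            index=["up", "zero"],
            columns=[f"s{i}" for i in range(6)],
        )
        labels = PhenotypeLabels(list(df.columns), ["A"] * 3 + ["B"] * 3, ("A", "B"))
        ranked = rank_by_signal_to_noise(ExpressionMatrix(df), labels)
        assert ranked.gene_ids[0] == "up"
        assert ranked.metric_values[0] == pytest.approx(10 / 3.4, abs=1e-10)

    def test_invariant_to_sample_order_within_classes(self):
        matrix, labels = small_cohort(seed=3)
        ranked1 = rank_by_signal_to_noise(matrix, labels)
        perm = ["s3", "s1", "s0", "s4", "s2", "s8", "s6", "s9", "s5", "s7"]
        matrix2 = ExpressionMatrix(matrix.values[perm])
        labels2 = labels.subset_to(perm)
        ranked2 = rank_by_signal_to_noise(matrix2, labels2)
        assert ranked1.gene_ids == ranked2.gene_ids
        np.testing.assert_allclose(ranked1.metric_values, ranked2.metric_values)

    def test_small_class_rejected(self):
        matrix, _ = small_cohort()
        labels = PhenotypeLabels(
            matrix.sample_ids, ["A"] * 2 + ["B"] * 8, ("A", "B")
        )
        with pytest.raises(ValueError, match="gene_set permutation"):
            rank_by_signal_to_noise(matrix, labels)

    def test_tie_break_is_lexicographic(self):
        df = pd.DataFrame(
            np.zeros((3, 6)), index=["c", "a", "b"], columns=[f"s{i}" for i in range(6)]
        )
        labels = PhenotypeLabels(list(df.columns), ["A"] * 3 + ["B"] * 3, ("A", "B"))
        ranked = rank_by_signal_to_noise(ExpressionMatrix(df), labels)
        assert ranked.gene_ids == ["a", "b", "c"]


class TestEnrichmentScore:
    def test_whole_list_set_rejected(self):
        ranked = RankedList(["a", "b"], np.array([1.0, 0.5]))
        with pytest.raises(ValueError, match="entire ranked list"):
            enrichment_score(ranked, GeneSet("s", "", ["a", "b"]))

    def test_empty_intersection_rejected(self):
        ranked = RankedList(["a", "b"], np.array([1.0, 0.5]))
        with pytest.raises(ValueError, match="no genes"):
            enrichment_score(ranked, GeneSet("s", "", ["z"]))

    def test_all_zero_metric_with_weighting_rejected(self):
        ranked = RankedList(["a", "b", "c"], np.zeros(3))
        with pytest.raises(ValueError, match="zero"):
            enrichment_score(ranked, GeneSet("s", "", ["a"]))

    def test_unweighted_equals_classic_ks(self):
        # p = 0: running sum is the classic KS statistic, by enumeration
        rng = np.random.default_rng(7)
        metric = np.sort(rng.standard_normal(10))[::-1]
        genes = [f"g{i}" for i in range(10)]
        members = ["g1", "g4", "g9"]
        es, _, _ = enrichment_score(
            RankedList(genes, metric), GeneSet("s", "", members), weight_p=0.0
        )
        member = np.array([g in members for g in genes])
        assert es == pytest.approx(brute_force_es(metric, member, 0.0), abs=1e-14)

    def test_perfect_separation_reaches_one_unweighted(self):
        genes = [f"g{i}" for i in range(10)]
        metric = np.linspace(2, -2, 10)
        es, _, _ = enrichment_score(
            RankedList(genes, metric), GeneSet("s", "", genes[:3]), weight_p=0.0
        )
        assert es == pytest.approx(1.0)

    def test_mirrored_list_negates_score(self):
        rng = np.random.default_rng(8)
        metric = np.sort(rng.uniform(0.5, 2.0, 20))[::-1]
        genes = [f"g{i:02d}" for i in range(20)]
        members = list(rng.choice(genes, 5, replace=False))
        es_fwd, _, _ = enrichment_score(
            RankedList(genes, metric), GeneSet("s", "", members)
        )
        es_rev, _, _ = enrichment_score(
            RankedList(genes[::-1], -metric[::-1]), GeneSet("s", "", members)
        )
        assert es_rev == pytest.approx(-es_fwd, abs=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        n=st.integers(5, 200),
        frac=st.floats(0.05, 0.8),
        p=st.sampled_from([0.0, 1.0, 1.5]),
        seed=st.integers(0, 10_000),
    )
    def test_matches_brute_force_on_random_instances(self, n, frac, p, seed):
        rng = np.random.default_rng(seed)
        metric = np.sort(rng.standard_normal(n))[::-1]
        genes = [f"g{i:04d}" for i in range(n)]
        nh = max(1, min(n - 1, int(frac * n)))
        members = list(rng.choice(genes, nh, replace=False))
        es, running, hits = enrichment_score(
            RankedList(genes, metric), GeneSet("s", "", members), weight_p=p
        )
        member = np.array([g in set(members) for g in genes])
        assert es == pytest.approx(brute_force_es(metric, member, p), abs=1e-12)
        assert abs(es) <= 1.0 + 1e-12
        assert len(running) == n


class TestPermutationAndScoring:
    def test_same_seed_identical_null(self):
        matrix, labels = small_cohort(n_per_class=10, n_genes=50, seed=1)
        gs = GeneSet("s", "", matrix.gene_ids[:8])
        cfg = GSEAConfig(n_perm=50, seed=42)
        null1 = permutation_null(matrix, labels, gs, cfg)
        null2 = permutation_null(matrix, labels, gs, cfg)
        np.testing.assert_array_equal(null1, null2)

    def test_gene_set_null_centered_for_symmetric_metric(self):
        matrix, labels = small_cohort(n_per_class=20, n_genes=200, seed=2)
        gs = GeneSet("s", "", matrix.gene_ids[:20])
        cfg = GSEAConfig(n_perm=500, permutation_type="gene_set", seed=0)
        null = permutation_null(matrix, labels, gs, cfg)
        assert abs(np.mean(null)) < 0.1

    def test_n_perm_floor(self):
        with pytest.raises(ValueError, match="at least 10"):
            GSEAConfig(n_perm=5)

    def test_planted_signal_recovered(self):
        spec = CohortSpec(
            n_samples=120, n_genes=500, planted_gene_set_size=50,
            enrichment_shift=1.0, seed=9,
        )
        matrix, planted, labels = simulate_expression(spec)
        r = score_gene_set(matrix, labels, planted, GSEAConfig(n_perm=200, seed=9))
        assert r.es > 0
        assert r.fdr_q < 0.05
        assert r.fdr_q == r.nominal_p  # single-gene-set run

    def test_leading_edge_contained_in_set(self):
        matrix, labels = small_cohort(n_per_class=10, n_genes=100, seed=4)
        members = matrix.gene_ids[:15]
        r = score_gene_set(
            matrix, labels, GeneSet("s", "", members), GSEAConfig(n_perm=50, seed=0)
        )
        assert set(r.leading_edge) <= set(members)
        assert np.sign(r.nes) == np.sign(r.es)

    def test_degenerate_phenotype_rejected_for_phenotype_permutation(self):
        matrix, _ = small_cohort(n_per_class=5, seed=5)
        labels = PhenotypeLabels(matrix.sample_ids, ["A"] * 10, ("A", "B"))
        gs = GeneSet("s", "", matrix.gene_ids[:5])
        with pytest.raises(ValueError):
            score_gene_set(matrix, labels, gs, GSEAConfig(n_perm=20, seed=0))

    def test_bit_reproducible_given_seed_and_config(self):
        spec = CohortSpec(n_samples=40, n_genes=200, planted_gene_set_size=20, seed=6)
        matrix, planted, labels = simulate_expression(spec)
        cfg = GSEAConfig(n_perm=99, seed=123)
        r1 = score_gene_set(matrix, labels, planted, cfg)
        r2 = score_gene_set(matrix, labels, planted, cfg)
        assert (r1.es, r1.nes, r1.nominal_p) == (r2.es, r2.nes, r2.nominal_p)
        assert r1.leading_edge == r2.leading_edge
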