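from fractions import Fraction

import numpy as np
import pytest

from _oracles import oracle_cv_error_1nn
from conftest import random_instance

from methylselect.classifiers import ClassifierSpec
from methylselect.core import (
    DOWN,
    UP,
    LabelVector,
    MethylationMatrix,
    ProbeAnnotation,
)
from methylselect.selection import (
    GAConfig,
    balance_weights,
    control_random,
    control_top_two_correlated,
    cv_error,
    ga_fitness,
    ga_knn_select,
    make_cv_plan,
    relieff_step,
    relieff_weights,
    select_annotation_based,
    select_top_k,
    sfs_select,
    svm_rfe_rank,
)

KNN1 = ClassifierSpec(family="knn", k_neighbors=1)


def planted_fixture(n_noise=5, seed=0, n_samples=20, sep=(0.2, 0.8), sd=0.03):
    """One cleanly separating probe among label-independent noise probes."""
    rng = np.random.default_rng(seed)
    labels = np.array([DOWN] * (n_samples // 2) + [UP] * (n_samples - n_samples // 2),
                      dtype=object)
    rng.shuffle(labels)
    rows = []
    planted = np.where(
        labels == DOWN,
        rng.normal(sep[0], sd, n_samples),
        rng.normal(sep[1], sd, n_samples),
    ).clip(0, 1)
    rows.append(planted)
    for _ in range(n_noise):
        rows.append(rng.beta(2, 2, n_samples))
    order = rng.permutation(len(rows))
    probe_ids = [f"cg{i}" for i in range(len(rows))]
    sample_ids = [f"s{i:02d}" for i in range(n_samples)]
    meth = MethylationMatrix(
        [probe_ids[i] for i in order], sample_ids, np.asarray(rows)[order]
    )
    planted_id = meth.probe_ids[int(np.flatnonzero(order == 0)[0])]
    lv = LabelVector("G1", sample_ids, labels)
    return meth, lv, planted_id


class TestCVPlan:
    def test_even_folds(self):
        _, lv = random_instance(1, n_samples=20)
        plan = make_cv_plan(lv, n_folds=10, seed=3)
        sizes = np.bincount([plan.assignment[s] for s in lv.sample_ids])
        assert plan.n_folds == 10
        assert all(size == 2 for size in sizes)

    def test_fold_reduction_when_few_samples(self):
        _, lv = random_instance(2, n_samples=7)
        plan = make_cv_plan(lv, n_folds=10, seed=0)
        assert plan.n_folds == 7

    def test_same_seed_same_plan(self):
        _, lv = random_instance(3)
        a = make_cv_plan(lv, 10, seed=9)
        b = make_cv_plan(lv, 10, seed=9)
        assert a.assignment == b.assignment

    def test_stratification_within_one_sample(self):
        _, lv = random_instance(4, n_samples=23)
        plan = make_cv_plan(lv, 5, seed=1)
        for cls in (DOWN, UP):
            ids = [s for s, l in zip(lv.sample_ids, lv.labels) if l == cls]
            per_fold = np.bincount(
                [plan.assignment[s] for s in ids], minlength=plan.n_folds
            )
            assert per_fold.max() - per_fold.min() <= 1


class TestCVError:
    def test_separable_probe_zero_error(self):
        meth, lv, planted = planted_fixture(seed=1)
        plan = make_cv_plan(lv, 10, seed=1)
        assert cv_error(KNN1, [planted], meth, lv, plan) == 0.0

    def test_matches_enumeration_oracle(self):
        meth, lv = random_instance(7, n_probes=3, n_samples=10)
        plan = make_cv_plan(lv, 5, seed=2)
        fold_of = [plan.assignment[s] for s in lv.sample_ids]
        x = meth.values.T.tolist()
        for probe_idx in range(3):
            expected = oracle_cv_error_1nn(
                x, list(lv.labels), lv.sample_ids, fold_of, [probe_idx]
            )
            got = cv_error(KNN1, [meth.probe_ids[probe_idx]], meth, lv, plan)
            assert got == pytest.approx(expected)

    def test_identical_probe_columns_identical_error(self):
        values = np.vstack([np.linspace(0.1, 0.9, 10)] * 2)
        meth = MethylationMatrix(["a", "b"], [f"s{i}" for i in range(10)], values)
        lv = LabelVector(
            "G", meth.sample_ids,
            np.array([DOWN] * 5 + [UP] * 5, dtype=object),
        )
        plan = make_cv_plan(lv, 5, seed=0)
        assert cv_error(KNN1, ["a"], meth, lv, plan) == cv_error(
            KNN1, ["b"], meth, lv, plan
        )


class TestSFS:
    def test_single_candidate_always_selected(self):
        meth, lv = random_instance(5, n_probes=1)
        plan = make_cv_plan(lv, 10, seed=1)
        res = sfs_select(KNN1, "G1", meth.probe_ids, meth, lv, plan)
        assert res.selected_probe_ids == meth.probe_ids

    def test_perfect_probe_selected_alone(self):
        meth, lv, planted = planted_fixture(n_noise=5, seed=4)
        plan = make_cv_plan(lv, 10, seed=4)
        res = sfs_select(KNN1, "G1", meth.probe_ids, meth, lv, plan)
        assert res.selected_probe_ids == [planted]
        assert res.final_cv_error == 0.0

    def test_rotation_of_candidates_keeps_perfect_probe(self):
        meth, lv, planted = planted_fixture(n_noise=4, seed=6)
        plan = make_cv_plan(lv, 10, seed=6)
        rotated = meth.probe_ids[2:] + meth.probe_ids[:2]
        res = sfs_select(KNN1, "G1", rotated, meth, lv, plan)
        assert res.selected_probe_ids == [planted]

    def test_accepted_errors_strictly_decrease(self):
        for seed in range(5):
            meth, lv = random_instance(seed, n_probes=5, n_samples=20)
            plan = make_cv_plan(lv, 10, seed=seed)
            res = sfs_select(KNN1, "G1", meth.probe_ids, meth, lv, plan)
            accepted = [min(c for _, c in rnd) for rnd in res.trace[: len(res.selected_probe_ids)]]
            assert all(b < a for a, b in zip(accepted, accepted[1:]))
            assert len(res.selected_probe_ids) <= 5


class TestClassWeights:
    def test_minority_class_upweighted(self):
        lv = LabelVector(
            "G", [f"s{i}" for i in range(40)],
            np.array([DOWN] * 10 + [UP] * 30, dtype=object),
        )
        w = balance_weights(lv)
        assert w.w0 == Fraction(3) and w.w1 == 1
        assert w.n0 * w.w0 == w.n1 * w.w1

    def test_balanced_classes_unit_weights(self):
        lv = LabelVector(
            "G", ["a", "b"], np.array([DOWN, UP], dtype=object)
        )
        w = balance_weights(lv)
        assert w.w0 == w.w1 == 1

    def test_missing_class_rejected(self):
        lv = LabelVector("G", ["a", "b"], np.array([UP, UP], dtype=object))
        with pytest.raises(ValueError):
            balance_weights(lv)


class TestSVMRFE:
    def test_constant_probe_ranked_last(self):
        meth, lv, planted = planted_fixture(n_noise=0, seed=2)
        values = np.vstack([meth.values, np.full(len(lv), 0.5)])
        meth2 = MethylationMatrix(
            meth.probe_ids + ["const"], meth.sample_ids, values
        )
        ranking = svm_rfe_rank(meth2.probe_ids, meth2, lv)
        assert ranking[0] == planted
        assert ranking[-1] == "const"

    def test_ranking_is_permutation_of_candidates(self):
        meth, lv = random_instance(9, n_probes=6)
        ranking = svm_rfe_rank(meth.probe_ids, meth, lv)
        assert sorted(ranking) == sorted(meth.probe_ids)

    def test_duplicate_columns_adjacent_with_index_tiebreak(self):
        rng = np.random.default_rng(3)
        base = rng.random(16)
        sep = np.array([0.1] * 8 + [0.9] * 8)
        meth = MethylationMatrix(
            ["dup1", "dup2", "sig"],
            [f"s{i:02d}" for i in range(16)],
            np.vstack([base, base, sep]),
        )
        lv = LabelVector(
            "G", meth.sample_ids, np.array([DOWN] * 8 + [UP] * 8, dtype=object)
        )
        ranking = svm_rfe_rank(meth.probe_ids, meth, lv)
        i1, i2 = ranking.index("dup1"), ranking.index("dup2")
        assert abs(i1 - i2) == 1 and i1 < i2


class TestReliefF:
    def test_printed_formula_hand_value(self):
        got = relieff_step(np.array([0.0]), np.array([0.5]),
                           np.array([[0.4]]), np.array([[0.8]]))
        assert got[0] == pytest.approx(0.08)

    def test_equal_hit_miss_zero_update(self):
        got = relieff_step(np.array([0.0]), np.array([0.5]),
                           np.array([[0.5]]), np.array([[0.5]]))
        assert got[0] == 0.0

    def test_perfectly_separating_feature_gets_positive_weight(self):
        # 6-sample fixture: feature 0 equals the class structure, feature 1 noise
        values = np.array(
            [[0.1, 0.1, 0.1, 0.9, 0.9, 0.9],
             [0.5, 0.4, 0.6, 0.5, 0.4, 0.6]]
        )
        meth = MethylationMatrix(["sig", "noise"], [f"s{i}" for i in range(6)], values)
        lv = LabelVector(
            "G", meth.sample_ids, np.array([DOWN] * 3 + [UP] * 3, dtype=object)
        )
        state = relieff_weights(meth.probe_ids, meth, lv, k_neighbors=1, seed=0)
        assert state.weights[0] > 0
        assert state.weights[0] > state.weights[1]
        assert state.ranking()[0] == "sig"

    def test_weight_vector_length_and_determinism(self):
        meth, lv = random_instance(12, n_probes=4)
        a = relieff_weights(meth.probe_ids, meth, lv, seed=5)
        b = relieff_weights(meth.probe_ids, meth, lv, seed=5)
        assert len(a.weights) == 4
        np.testing.assert_array_equal(a.weights, b.weights)


class TestGA:
    def test_fitness_arithmetic(self):
        assert ga_fitness(0.2, 10, 2) == pytest.approx(0.025)

    def test_zero_loss_zero_fitness(self):
        assert ga_fitness(0.0, 10, 3) == 0.0

    def test_degenerate_masks_excluded(self):
        assert ga_fitness(0.1, 10, 10) == np.inf
        assert ga_fitness(0.1, 10, 0) == np.inf

    def test_select_is_deterministic_and_valid(self):
        meth, lv = random_instance(21, n_probes=6)
        cfg = GAConfig(population_size=10, n_generations=10, seed=7)
        a = ga_knn_select(meth.probe_ids, meth, lv, cfg)
        b = ga_knn_select(meth.probe_ids, meth, lv, cfg)
        assert a.selected_probe_ids == b.selected_probe_ids
        assert 0 < len(a.selected_probe_ids) < 6


class TestControls:
    def test_top_k(self):
        assert select_top_k(["a", "b", "c"], 2) == ["a", "b"]
        assert select_top_k(["a", "b", "c"], 3) == ["a", "b", "c"]
        assert select_top_k(["a", "b"], 5) == ["a", "b"]  # warned, returns all
        with pytest.raises(ValueError):
            select_top_k(["a"], 0)

    def test_random_full_draw_and_seeding(self):
        probes = ["a", "b", "c", "d"]
        assert sorted(control_random(probes, 4, seed=1)) == probes
        assert control_random(probes, 2, seed=5) == control_random(probes, 2, seed=5)

    def test_random_is_uniform(self):
        probes = ["a", "b", "c", "d"]
        counts = {p: 0 for p in probes}
        n = 10_000
        for i in range(n):
            counts[control_random(probes, 1, seed=i)[0]] += 1
        for p in probes:
            assert abs(counts[p] / n - 0.25) < 0.02

    def test_top_two_by_absolute_correlation(self):
        rng = np.random.default_rng(2)
        e = rng.normal(size=12)
        rows = [
            0.5 + 0.3 * (e - e.mean()) / e.std(),              # strong +
            0.5 - 0.25 * (e - e.mean()) / e.std(),             # strong -
            rng.random(12) * 0.05 + 0.4,                       # weak
        ]
        meth = MethylationMatrix(
            ["pos", "neg", "weak"], [f"s{i}" for i in range(12)],
            np.asarray(rows).clip(0, 1),
        )
        chosen = control_top_two_correlated(
            meth.probe_ids, meth, e, meth.sample_ids
        )
        assert set(chosen) == {"pos", "neg"}

    def test_probe_equal_to_expression_always_selected(self):
        rng = np.random.default_rng(4)
        e = rng.random(10)
        meth = MethylationMatrix(
            ["mirror", "n1", "n2"], [f"s{i}" for i in range(10)],
            np.vstack([e, rng.random(10), rng.random(10)]),
        )
        chosen = control_top_two_correlated(meth.probe_ids, meth, e, meth.sample_ids)
        assert "mirror" in chosen

    def test_fewer_than_three_candidates_returned_whole(self):
        meth = MethylationMatrix(
            ["a", "b"], ["s1", "s2", "s3"], np.random.default_rng(0).random((2, 3))
        )
        assert control_top_two_correlated(
            ["a", "b"], meth, np.array([1.0, 2.0, 3.0]), meth.sample_ids
        ) == ["a", "b"]


class TestAnnotationSelectors:
    @pytest.fixture
    def annotated(self):
        mk = lambda pid, region, island, tss: ProbeAnnotation(
            probe_id=pid, gene_symbols=["G"],
            region_group_per_gene={"G": region},
            cpg_island_relation=island, chromosome="chr1", position=1,
            tss_distance_per_gene={"G": tss},
        )
        anns = {
            "p1": mk("p1", "TSS200", "Island", -150),
            "p2": mk("p2", "Body", "Island", 3000),
            "p3": mk("p3", "1stExon", "Shore", -2500),
            "p4": mk("p4", "Body", "OpenSea", 2501),
        }
        values = np.array(
            [[0.5] * 6, np.linspace(0.1, 0.9, 6), [0.4, 0.45, 0.5, 0.55, 0.6, 0.65],
             [0.2] * 6]
        )
        meth = MethylationMatrix(list(anns), [f"s{i}" for i in range(6)], values)
        return anns, meth

    def test_all(self, annotated):
        anns, meth = annotated
        assert select_annotation_based("all", "G", list(anns), anns, meth) == list(anns)

    def test_upstream_island_excludes_body(self, annotated):
        anns, meth = annotated
        got = select_annotation_based("upstream_cpg_island", "G", list(anns), anns, meth)
        assert got == ["p1"]  # p2 is Island but Body; p3 upstream but Shore

    def test_tss_window_inclusive_boundary(self, annotated):
        anns, meth = annotated
        got = select_annotation_based("tss_window", "G", list(anns), anns, meth)
        assert got == ["p1", "p3"]  # |-2500| included, 2501 and 3000 excluded

    def test_top_sd_single_probe(self, annotated):
        anns, meth = annotated
        got = select_annotation_based("top_sd", "G", list(anns), anns, meth)
        assert got == ["p2"]

    def test_empty_result_returned_empty(self, annotated):
        anns, meth = annotated
        only_body = ["p2", "p4"]
        got = select_annotation_based("upstream_cpg_island", "G", only_body, anns, meth)
        assert got == []
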