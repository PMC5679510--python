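import dataclasses

import numpy as np
import pytest

from itess import (
    FEATURE_NAMES,
    FeatureVector,
    TaxonConfig,
    generate_organism,
    leave_one_species_out,
    monte_carlo_cv,
    pairwise_cross,
    pooled_cv,
    predict_scores,
    rank_features,
    roc_auc,
    select_top_k,
    taxon_eval,
    threshold_metrics,
    train_rf,
    under_sample,
)
from conftest import small_config

from oracles import auc_oracle, info_gain_oracle


def make_vectors(values_by_gene, labels):
    out = []
    for i, (vals, label) in enumerate(zip(values_by_gene, labels)):
        full = {n: 0.0 for n in FEATURE_NAMES}
        full.update(vals)
        out.append(FeatureVector(f"g{i}", "O", full, label))
    return out


class TestUnderSample:
    def vectors(self, n_pos, n_neg):
        return make_vectors(
            [{} for _ in range(n_pos + n_neg)],
            ["essential"] * n_pos + ["non_essential"] * n_neg,
        )

    def test_balances_majority_class(self):
        out = under_sample(self.vectors(30, 300), seed=0)
        assert sum(v.label == "essential" for v in out) == 30
        assert sum(v.label == "non_essential" for v in out) == 30

    def test_never_oversamples_minority_majority_flip(self):
        vecs = self.vectors(30, 20)
        assert under_sample(vecs, seed=0) == vecs

    def test_same_seed_same_subset(self):
        vecs = self.vectors(10, 100)
        a = under_sample(vecs, seed=5)
        b = under_sample(vecs, seed=5)
        assert [v.gene_id for v in a] == [v.gene_id for v in b]

    def test_missing_class_errors(self):
        with pytest.raises(ValueError):
            under_sample(self.vectors(5, 0), seed=0)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, pts = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)

    def test_tie_contributes_half(self):
        # pairs: 3 concordant + 1 tie -> (3 + 0.5)/4
        auc, _ = roc_auc([0.9, 0.8, 0.8, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(0.875, abs=1e-12)

    def test_all_tied_is_half(self):
        auc, _ = roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert auc == pytest.approx(0.5, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(auc_oracle(scores, labels), abs=1e-12)

    def test_roc_points_monotone(self):
        rng = np.random.default_rng(1)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        _, pts = roc_auc(scores, labels)
        arr = np.array(pts)
        assert (np.diff(arr, axis=0) >= 0).all()


class TestThresholdMetrics:
    def test_perfect_scores(self):
        acc, f = threshold_metrics([1.0, 1.0, 0.0, 0.0], [1, 1, 0, 0])
        assert acc == 1.0 and f == 1.0

    def test_all_predicted_essential_half_true(self):
        acc, f = threshold_metrics([0.9, 0.9, 0.9, 0.9], [1, 1, 0, 0])
        assert acc == pytest.approx(0.5)
        assert f == pytest.approx(2 / 3)

    def test_no_predicted_positives_f_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="itess.classifier_eval"):
            acc, f = threshold_metrics([0.1, 0.1], [0, 0])
        assert f == 0.0
        assert any("undefined" in r.message for r in caplog.records)


class TestRandomForest:
    def test_stump_on_perfect_feature(self):
        vecs = make_vectors(
            [{"MI_total": float(l == "essential")} for l in
             ["essential"] * 5 + ["non_essential"] * 5],
            ["essential"] * 5 + ["non_essential"] * 5,
        )
        model = train_rf(vecs, n_trees=1, max_depth=1, seed=0,
                         feature_subset=["MI_total"])
        scores = predict_scores(model, vecs)
        assert set(scores) <= {0.0, 1.0}
        assert [int(s) for s in scores] == [1] * 5 + [0] * 5

    def test_training_set_auc_on_separable_data(self, small_vectors):
        balanced = under_sample(small_vectors, seed=0)
        model = train_rf(balanced, seed=0)
        auc, _ = roc_auc(predict_scores(model, balanced),
                         [1 if v.label == "essential" else 0 for v in balanced])
        assert auc >= 0.99

    def test_label_permutation_null_auc(self, small_vectors):
        # permute labels, train on one half, test on the other, 20 reps
        aucs = []
        for rep in range(20):
            rng = np.random.default_rng(rep)
            labels = [v.label for v in small_vectors]
            permuted = rng.permutation(labels)
            vecs = [dataclasses.replace(v, label=l)
                    for v, l in zip(small_vectors, permuted)]
            balanced = under_sample(vecs, seed=rep)
            rng.shuffle(balanced)
            half = len(balanced) // 2
            train, test = balanced[:half], balanced[half:]
            y_test = [1 if v.label == "essential" else 0 for v in test]
            if len(set(y_test)) < 2 or len({v.label for v in train}) < 2:
                continue
            model = train_rf(train, seed=rep)
            aucs.append(roc_auc(predict_scores(model, test), y_test)[0])
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_unknown_feature_subset_errors(self, small_vectors):
        with pytest.raises(ValueError):
            train_rf(small_vectors, feature_subset=["NOT_A_FEATURE"])


class TestMonteCarloCV:
    def test_separable_folds_recorded_and_high_auc(self, small_separable):
        result = monte_carlo_cv(small_separable, n_folds=5, seed=1)
        assert len(result.fold_aucs) == 5
        assert result.mean_auc >= 0.9
        assert result.mean_auc == pytest.approx(np.mean(result.fold_aucs), abs=1e-12)

    def test_same_seed_bit_identical(self, small_separable):
        a = monte_carlo_cv(small_separable, n_folds=3, seed=9)
        b = monte_carlo_cv(small_separable, n_folds=3, seed=9)
        assert a.fold_aucs == b.fold_aucs
        assert a.roc_points == b.roc_points
        assert (a.accuracy, a.f_measure) == (b.accuracy, b.f_measure)

    def test_degenerate_train_frac_errors(self, small_separable):
        with pytest.raises(ValueError):
            monte_carlo_cv(small_separable, n_folds=1, train_frac=1.0)

    def test_fold_train_test_disjoint(self, small_separable):
        result = monte_carlo_cv(small_separable, n_folds=3, seed=2)
        for train_ids, test_ids in result.fold_memberships:
            assert not (train_ids & test_ids)

    def test_top_k_selection_runs(self, small_separable):
        result = monte_carlo_cv(small_separable, n_folds=2, seed=3, top_k=50)
        assert len(result.fold_aucs) == 2


class TestCrossOrganism:
    def test_same_source_pair_transfers(self):
        a, _ = generate_organism(small_config(1.0, seed=21, organism="A"))
        b, _ = generate_organism(small_config(1.0, seed=22, organism="B"))
        result = pairwise_cross(a, b, seed=0)
        assert result.mean_auc > 0.8
        assert result.mode == "pairwise"

    def test_identical_organism_refused(self, small_separable):
        with pytest.raises(ValueError):
            pairwise_cross(small_separable, small_separable)

    def test_relabeled_test_organism_gives_identical_auc(self):
        a, _ = generate_organism(small_config(1.0, seed=21, organism="A"))
        b, _ = generate_organism(small_config(1.0, seed=22, organism="B"))
        c_genes = [dataclasses.replace(g, organism="C") for g in b.genes]
        from itess.sequence_io import OrganismDataset

        c = OrganismDataset("C", c_genes, genome=b.genome)
        assert pairwise_cross(a, b, seed=0).mean_auc == pairwise_cross(a, c, seed=0).mean_auc


def three_organisms():
    return [
        generate_organism(small_config(1.0, seed=31 + i, organism=f"O{i}"))[0]
        for i in range(3)
    ]


class TestLeaveOneSpeciesOut:
    def test_held_out_never_in_training(self):
        orgs = three_organisms()
        for held in ("O0", "O1", "O2"):
            result = leave_one_species_out(orgs, held, seed=0)
            held_ids = {g.gene_id for o in orgs if o.organism == held for g in o.genes}
            for train_ids, test_ids in result.fold_memberships:
                assert not (train_ids & held_ids)
                assert test_ids <= held_ids

    def test_same_source_transfers(self):
        orgs = three_organisms()
        assert leave_one_species_out(orgs, "O1", seed=0).mean_auc > 0.8

    def test_unrelated_source_reports_without_error(self):
        orgs = three_organisms()
        null_org, _ = generate_organism(small_config(0.0, seed=40, organism="NULL"))
        result = leave_one_species_out(orgs + [null_org], "NULL", seed=0)
        assert 0.0 <= result.mean_auc <= 1.0

    def test_unknown_holdout_errors(self):
        with pytest.raises(ValueError, match="NOPE"):
            leave_one_species_out(three_organisms(), "NOPE")


class TestTaxonEval:
    def taxa(self):
        return TaxonConfig(groups={
            "T1": ["O0"], "T2": ["O1"], "T3": ["O2"], "T4": ["O3"],
        })

    def orgs(self):
        return [
            generate_organism(small_config(1.0, seed=51 + i, organism=f"O{i}"))[0]
            for i in range(4)
        ]

    def test_cross_taxon_yields_ordered_pairs(self):
        results = taxon_eval(self.orgs(), self.taxa(), "cross_taxon", seed=0)
        assert len(results) == 12
        assert {(r.train_id, r.test_id) for r in results} == {
            (a, b) for a in ("T1", "T2", "T3", "T4") for b in ("T1", "T2", "T3", "T4")
            if a != b
        }

    def test_leave_taxon_out_yields_one_per_taxon(self):
        results = taxon_eval(self.orgs(), self.taxa(), "leave_taxon_out", seed=0)
        assert len(results) == 4
        assert {r.test_id for r in results} == {"T1", "T2", "T3", "T4"}

    def test_shared_source_gives_high_auc(self):
        results = taxon_eval(self.orgs(), self.taxa(), "leave_taxon_out", seed=0)
        assert np.mean([r.mean_auc for r in results]) > 0.8

    def test_absent_organism_named_in_error(self):
        taxa = TaxonConfig(groups={"T1": ["O0"], "T2": ["MISSING"]})
        with pytest.raises(ValueError, match="MISSING"):
            taxon_eval(self.orgs(), taxa, "cross_taxon")

    def test_organism_in_two_taxa_rejected(self):
        with pytest.raises(ValueError):
            TaxonConfig(groups={"T1": ["O0"], "T2": ["O0"]})


class TestPooledCV:
    def test_folds_partition_and_report(self):
        orgs = three_organisms()
        result = pooled_cv(orgs, n_folds=3, seed=0)
        assert result.n_folds == 3
        all_test = set().union(*(t for _, t in result.fold_memberships))
        all_ids = {g.gene_id for o in orgs for g in o.labeled_genes}
        assert all_test == all_ids
        for train_ids, test_ids in result.fold_memberships:
            assert not (train_ids & test_ids)


class TestFeatureRanking:
    def test_perfect_binary_feature_ranks_first_with_one_bit(self):
        labels = ["essential"] * 6 + ["non_essential"] * 6
        vecs = make_vectors(
            [{"H2": float(l == "essential")} for l in labels], labels
        )
        ranking = rank_features(vecs)
        name, gain = ranking.entries[0]
        assert name == "H2"
        assert gain == pytest.approx(1.0, abs=1e-12)

    def test_constant_feature_has_zero_gain(self):
        labels = ["essential"] * 4 + ["non_essential"] * 4
        vecs = make_vectors([{} for _ in labels], labels)
        ranking = rank_features(vecs)
        assert all(g == 0.0 for _, g in ranking.entries)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_threshold_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = ["essential"] * 8 + ["non_essential"] * 8
        table = {n: rng.normal(size=16).round(1) for n in ("MI_total", "H2", "KLD1")}
        vecs = make_vectors(
            [{n: table[n][i] for n in table} for i in range(16)], labels
        )
        ranking = rank_features(vecs)
        gains = dict(ranking.entries)
        y = [1] * 8 + [0] * 8
        for n in table:
            assert gains[n] == pytest.approx(info_gain_oracle(table[n], y), abs=1e-12)

    def test_select_top_k_bounds(self, small_vectors):
        ranking = rank_features(small_vectors)
        assert len(select_top_k(ranking, 50)) == 50
        with pytest.raises(ValueError):
            select_top_k(ranking, 92)


class TestDivergenceMonotonicity:
    def test_auc_monotone_in_source_divergence(self):
        aucs = []
        for i, d in enumerate((0.0, 0.3, 1.0)):
            ds, _ = generate_organism(small_config(d, seed=61, organism=f"D{i}"))
            aucs.append(monte_carlo_cv(ds, n_folds=4, seed=7).mean_auc)
        assert aucs[0] <= aucs[1] + 0.1  # null is near chance
        assert aucs[1] <= aucs[2]
        assert aucs[2] >= 0.9
        assert 0.3 <= aucs[0] <= 0.7
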