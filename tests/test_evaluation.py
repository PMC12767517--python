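"""Clustering, group CV, test classes, AUC and blind-test evaluation."""

import numpy as np
import pandas as pd
import pytest

from edgetic.corpus import VariantPartnerPair
from edgetic.errors import DataError, PartitionError, UndefinedMetricError
from edgetic.evaluation import (
    CVResult,
    assign_test_class,
    blind_test,
    cluster_pairs,
    group_kfold,
    linear_trainer,
    mean_roc_curve,
    parse_clstr,
    roc_auc,
    run_cv,
)
from edgetic.features import MutationSpec
from edgetic.synthetic import PlantedRule, generate_ppi_dataset


def _pair(i, p, seq_i, seq_p, pos=1, label=1):
    wt = seq_i[pos - 1]
    mut = "W" if wt != "W" else "Y"
    return VariantPartnerPair(
        interactor_id=i, partner_id=p,
        mutation=MutationSpec(pos, wt, mut, protein_id=i),
        label=label, interactor_seq=seq_i, partner_seq=seq_p,
    )


def _mutated(seq, n, rng):
    chars = list(seq)
    for pos in rng.choice(len(seq), size=n, replace=False):
        alphabet = [a for a in "ACDEFGHIKLMNPQRSTVWY" if a != chars[pos]]
        chars[pos] = alphabet[rng.integers(len(alphabet))]
    return "".join(chars)


class TestClusterPairs:
    def test_identical_pairs_cluster_together(self):
        pairs = [_pair("A", "B", "ACDEF" * 8, "GHIKL" * 8) for _ in range(2)]
        clusters = cluster_pairs(pairs)
        assert len(clusters) == 1
        assert sorted(clusters[0].members) == [0, 1]

    def test_unrelated_sequences_split(self):
        rng = np.random.default_rng(0)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = ["".join(rng.choice(alphabet, size=40)) for _ in range(4)]
        pairs = [_pair("A", "B", seqs[0], seqs[1]),
                 _pair("C", "D", seqs[2], seqs[3])]
        assert len(cluster_pairs(pairs)) == 2

    def test_two_families_match_identity_oracle(self):
        rng = np.random.default_rng(1)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        pairs = []
        for fam in range(2):
            base_i = "".join(rng.choice(alphabet, size=30))
            base_p = "".join(rng.choice(alphabet, size=30))
            for copy in range(5):
                # ≥90% identity within a family
                pairs.append(_pair(f"I{fam}_{copy}", f"P{fam}_{copy}",
                                   _mutated(base_i, 2, rng),
                                   _mutated(base_p, 2, rng)))
        clusters = cluster_pairs(pairs, identity_threshold=0.5)
        assert len(clusters) == 2

        # exhaustive all-pairs identity: members of one cluster are mutually
        # >= 50% identical, members of different clusters are not
        def identity(a, b):
            return sum(x == y for x, y in zip(a, b)) / min(len(a), len(b))

        concat = [p.interactor_seq + p.partner_seq for p in pairs]
        member_of = {}
        for c in clusters:
            for m in c.members:
                member_of[m] = c.cluster_id
        for a in range(len(pairs)):
            for b in range(a + 1, len(pairs)):
                same = member_of[a] == member_of[b]
                assert same == (identity(concat[a], concat[b]) >= 0.5)

    def test_missing_sequence_rejected(self):
        pair = _pair("A", "B", "ACDEF", "GHIKL")
        pair.partner_seq = None
        with pytest.raises(DataError):
            cluster_pairs([pair])


def test_parse_clstr():
    text = (
        ">Cluster 0\n"
        "0\t100aa, >seqA... *\n"
        "1\t98aa, >seqB... at 95.00%\n"
        ">Cluster 1\n"
        "0\t80aa, >seqC... *\n"
    )
    assert parse_clstr(text) == [["seqA", "seqB"], ["seqC"]]


class TestGroupKfold:
    def _singletons(self, n):
        pairs = []
        rng = np.random.default_rng(0)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for i in range(n):
            pairs.append(_pair(f"I{i}", f"P{i}",
                               "".join(rng.choice(alphabet, size=30)),
                               "".join(rng.choice(alphabet, size=30))))
        return cluster_pairs(pairs)

    def test_one_cluster_per_fold(self):
        folds = group_kfold(self._singletons(10), k=10, seed=0)
        assert sorted(len(f) for f in folds) == [1] * 10

    def test_partition_law(self):
        clusters = self._singletons(23)
        folds = group_kfold(clusters, k=5, seed=3)
        everything = [i for fold in folds for i in fold]
        assert sorted(everything) == list(range(23))

    def test_clusters_never_split(self):
        rng = np.random.default_rng(5)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        pairs = []
        for fam in range(12):
            base_i = "".join(rng.choice(alphabet, size=30))
            base_p = "".join(rng.choice(alphabet, size=30))
            for copy in range(rng.integers(1, 5)):
                pairs.append(_pair(f"I{fam}_{copy}", f"P{fam}_{copy}",
                                   _mutated(base_i, 1, rng),
                                   _mutated(base_p, 1, rng)))
        clusters = cluster_pairs(pairs)
        folds = group_kfold(clusters, k=4, seed=1)
        fold_of = {}
        for f, members in enumerate(folds):
            for m in members:
                fold_of[m] = f
        for cluster in clusters:
            assert len({fold_of[m] for m in cluster.members}) == 1

    def test_too_few_clusters(self):
        with pytest.raises(PartitionError):
            group_kfold(self._singletons(4), k=10)


class TestAssignTestClass:
    def test_both_shared(self):
        pair = _pair("A", "B", "ACDEF", "GHIKL")
        assert assign_test_class(pair, {"A", "B", "X"}) == 1

    def test_one_shared(self):
        pair = _pair("A", "B", "ACDEF", "GHIKL")
        assert assign_test_class(pair, {"A", "X"}) == 2

    def test_neither_shared(self):
        pair = _pair("A", "B", "ACDEF", "GHIKL")
        assert assign_test_class(pair, {"X", "Y"}) == 3


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, size=4000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_hand_example_matches_pair_count_oracle(self):
        data = [(0.1, 0), (0.4, 0), (0.35, 1), (0.8, 1), (0.8, 0), (0.9, 1)]
        scores = [s for s, _ in data]
        labels = [l for _, l in data]
        concordant = tied = total = 0
        for sp, lp in data:
            if lp != 1:
                continue
            for sn, ln in data:
                if ln != 0:
                    continue
                total += 1
                if sp > sn:
                    concordant += 1
                elif sp == sn:
                    tied += 1
        expected = (concordant + 0.5 * tied) / total
        assert roc_auc(scores, labels) == pytest.approx(expected)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.2, 0.8], [1, 1])

    @pytest.mark.parametrize("transform", [
        lambda s: 2 * s + 1, np.exp, lambda s: s ** 3,
    ])
    def test_invariant_under_monotone_transform(self, transform):
        rng = np.random.default_rng(2)
        scores = rng.random(100)
        labels = rng.integers(0, 2, size=100)
        assert roc_auc(transform(np.asarray(scores)), labels) == pytest.approx(
            roc_auc(scores, labels)
        )


def test_weighted_aggregate_arithmetic():
    table = pd.DataFrame(
        [
            {"iteration": 0, "fold": 0, "cls": 1, "n": 10, "auc": 0.8},
            {"iteration": 0, "fold": 1, "cls": 1, "n": 30, "auc": 0.6},
        ]
    )
    result = CVResult(table=table, assignments=[])
    assert result.aggregate() == {1: pytest.approx(0.65)}


def test_mean_roc_curve_grid(tmp_path):
    from edgetic.evaluation import write_roc_tsv

    sets = [
        ([0.1, 0.9, 0.8, 0.3], [0, 1, 1, 0]),
        ([0.2, 0.7, 0.6, 0.4], [0, 1, 0, 1]),
    ]
    grid, mean_tpr, sem = mean_roc_curve(sets)
    assert len(grid) == len(mean_tpr) == len(sem) == 101
    assert mean_tpr[0] >= 0 and mean_tpr[-1] == 1.0
    out = tmp_path / "roc.tsv"
    write_roc_tsv(out, sets)
    frame = pd.read_csv(out, sep="\t")
    assert list(frame.columns) == ["fpr", "tpr_mean", "tpr_sem"]
    assert len(frame) == 101


@pytest.fixture(scope="module")
def cv_dataset(request):
    from edgetic.features import SyntheticEmbedder
    from edgetic.pipeline import featurize_pairs

    pairs, structures, _ = generate_ppi_dataset(
        n_pairs=16, variants_per_pair=8,
        rule=PlantedRule("interface-disrupts", noise=0.05, seed=21),
    )
    embedder = SyntheticEmbedder(dimension=32, seed=1)
    return featurize_pairs(pairs, structures, embedder)


class TestRunCV:
    def test_reproducible_under_seed(self, cv_dataset):
        kwargs = dict(iterations=1, k=4, min_class_n=5, seed=9)
        r1 = run_cv(cv_dataset, linear_trainer(), **kwargs)
        r2 = run_cv(cv_dataset, linear_trainer(), **kwargs)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_no_pair_or_cluster_leaks(self, cv_dataset):
        result = run_cv(cv_dataset, linear_trainer(), iterations=2, k=4,
                        min_class_n=5, seed=0)
        pairs = [ex.record for ex in cv_dataset]
        clusters = cluster_pairs(pairs)
        cluster_of = {}
        for c in clusters:
            for m in c.members:
                cluster_of[m] = c.cluster_id
        for fa in result.assignments:
            train, test = set(fa.train_indices), set(fa.test_indices)
            assert not train & test
            assert not ({cluster_of[i] for i in train}
                        & {cluster_of[i] for i in test})

    def test_class_bins_partition_test_folds(self, cv_dataset):
        result = run_cv(cv_dataset, linear_trainer(), iterations=1, k=4,
                        min_class_n=5, seed=0)
        for fa in result.assignments:
            assert set(fa.test_class) == set(fa.test_indices)
            assert set(fa.test_class.values()) <= {1, 2, 3}

    def test_planted_signal_class_ordering(self, cv_dataset):
        """Seen-protein (class 1) performance should not trail unseen-protein
        (class 3) performance on planted data, matching the published
        behavior of paired-input predictors."""
        aggregates = []
        for seed in (0, 1, 2):
            result = run_cv(cv_dataset, linear_trainer(), iterations=2, k=4,
                            min_class_n=5, seed=seed)
            aggregates.append(result.aggregate())
        class1 = [a[1] for a in aggregates if 1 in a]
        class3 = [a[3] for a in aggregates if 3 in a]
        if class1 and class3:
            assert np.mean(class1) >= np.mean(class3) - 0.05


class TestBlindTest:
    def test_training_copy_fully_excluded(self, cv_dataset):
        with pytest.raises(DataError):
            blind_test(cv_dataset, cv_dataset, linear_trainer(), k=4)

    def test_exclusion_matches_key_intersection(self, cv_dataset):
        benchmark = cv_dataset[:48]
        novel = cv_dataset[48:]
        train = novel
        train_keys = {ex.record.variant_key for ex in train}
        expected_excluded = sum(
            1 for ex in benchmark if ex.record.variant_key in train_keys
        )
        result = blind_test(train, benchmark, linear_trainer(), k=4,
                            min_class_n=5)
        assert result.excluded == expected_excluded

    def test_novel_proteins_are_class_three(self, cv_dataset):
        split = len(cv_dataset) // 2
        train, benchmark = cv_dataset[:split], cv_dataset[split:]
        train_proteins = {ex.record.interactor_id for ex in train} | {
            ex.record.partner_id for ex in train
        }
        benchmark = [
            ex for ex in benchmark
            if ex.record.interactor_id not in train_proteins
            and ex.record.partner_id not in train_proteins
        ]
        result = blind_test(train, benchmark, linear_trainer(), k=4,
                            min_class_n=5)
        assert (result.classes == 3).all()
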