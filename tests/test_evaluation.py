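"""Cross-validation harness, ranking metrics and report computations."""

import numpy as np
import pytest

from ricewalk import (
    CandidateRecord,
    DataError,
    FunctionalNetwork,
    column_normalize,
    confirmation_rate,
    cross_validate,
    go_term_counts,
    kfold_split,
    roc_auc,
    run_fold,
    select_r,
    topk_match_counts,
)
from ricewalk.evaluation import CVReport, FoldRecord

from conftest import random_weighted_network


class TestKFoldSplit:
    def test_exact_division(self):
        seeds = {f"s{i}" for i in range(10)}
        folds = kfold_split(seeds, 5, rng_seed=1).folds
        assert sorted(len(f) for f in folds) == [2] * 5
        assert set().union(*folds) == seeds

    def test_round_robin_remainder(self):
        """136 seeds into 5 folds: sizes {28, 27, 27, 27, 27}."""
        seeds = {f"s{i:03d}" for i in range(136)}
        folds = kfold_split(seeds, 5, rng_seed=0).folds
        assert sorted((len(f) for f in folds), reverse=True) == [28, 27, 27, 27, 27]
        assert set().union(*folds) == seeds

    def test_deterministic_and_disjoint(self):
        seeds = {f"s{i}" for i in range(17)}
        a = kfold_split(seeds, 4, rng_seed=9)
        b = kfold_split(seeds, 4, rng_seed=9)
        assert a.folds == b.folds
        assert sum(len(f) for f in a.folds) == len(seeds)

    def test_too_few_seeds(self):
        with pytest.raises(DataError, match="at least"):
            kfold_split({"a", "b"}, 5, rng_seed=0)


@pytest.fixture
def chain_matrix():
    """Path a-b-c-d, unweighted."""
    net = FunctionalNetwork(
        nodes=("a", "b", "c", "d"),
        edges={("a", "b"): 1.0, ("b", "c"): 1.0, ("c", "d"): 1.0},
    )
    return column_normalize(net, mode="unweighted")


class TestRunFold:
    def test_heldout_neighbor_ranks_first(self, chain_matrix):
        run = run_fold(chain_matrix, train_seeds={"a"}, test_seeds={"b"}, r=0.3)
        assert run.test_ranks["b"] == 1
        assert [g for _, g, _ in run.ranking][:1] == ["b"]

    def test_overlapping_sets_are_an_error(self, chain_matrix):
        with pytest.raises(DataError, match="disjoint"):
            run_fold(chain_matrix, {"a", "b"}, {"b"}, r=0.3)

    def test_missing_test_seed_reported(self, chain_matrix):
        run = run_fold(chain_matrix, {"a"}, {"b", "ghost"}, r=0.3)
        assert run.missing_test_seeds == ("ghost",)
        assert set(run.test_ranks) == {"b"}

    def test_r_one_is_degenerate(self, chain_matrix):
        run = run_fold(chain_matrix, {"a"}, {"b"}, r=1.0)
        assert run.degenerate
        # all candidate scores are 0; ranking falls back to lexicographic order
        assert [g for _, g, _ in run.ranking] == ["b", "c", "d"]


class TestTopkCounts:
    @pytest.mark.parametrize(
        "ranks, expected",
        [
            ([50, 150, 450], [1, 2, 2, 2, 3]),
            ([], [0, 0, 0, 0, 0]),
            ([501, 600], [0, 0, 0, 0, 0]),
        ],
    )
    def test_examples(self, ranks, expected):
        assert topk_match_counts(ranks) == expected

    def test_counts_monotone_in_cutoff(self):
        rng = np.random.default_rng(5)
        ranks = rng.integers(1, 600, size=30)
        counts = topk_match_counts(ranks)
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_cutoffs_must_ascend(self):
        with pytest.raises(DataError, match="ascending"):
            topk_match_counts([1], cutoffs=[200, 100])


def _ranking(scores):
    """RankedList from a gene -> score dict (descending, lexicographic ties)."""
    items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(i + 1, g, s) for i, (g, s) in enumerate(items)]


class TestRocAuc:
    @pytest.mark.parametrize(
        "scores, positives, expected",
        [
            ({"p": 3.0, "n1": 2.0, "n2": 1.0}, {"p"}, 1.0),
            ({"n1": 3.0, "p": 2.0, "n2": 1.0}, {"p"}, 0.5),
            ({"n1": 3.0, "n2": 2.0, "p": 1.0}, {"p"}, 0.0),
            ({"p": 1.0, "n1": 1.0}, {"p"}, 0.5),  # exact tie: half credit
        ],
    )
    def test_examples(self, scores, positives, expected):
        assert roc_auc(_ranking(scores), positives) == pytest.approx(expected)

    def test_degenerate_label_sets_are_errors(self):
        r = _ranking({"a": 1.0, "b": 0.5})
        with pytest.raises(DataError):
            roc_auc(r, {"zzz"})
        with pytest.raises(DataError):
            roc_auc(r, {"a", "b"})

    def test_matches_exhaustive_pairwise_and_sklearn(self):
        """Tie-aware AUC equals both the exhaustive positive-negative pair
        count and scikit-learn's roc_auc_score, exactly."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(10, 100))
            genes = [f"g{i}" for i in range(n)]
            scores = {g: float(rng.choice(rng.uniform(0, 1, size=max(2, n // 3)))) for g in genes}
            positives = set(rng.choice(genes, size=max(1, n // 5), replace=False))
            ranking = _ranking(scores)
            ours = roc_auc(ranking, positives)
            pairs = 0.0
            pos = [scores[g] for g in genes if g in positives]
            neg = [scores[g] for g in genes if g not in positives]
            for sp in pos:
                for sn in neg:
                    pairs += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
            assert ours == pytest.approx(pairs / (len(pos) * len(neg)), abs=1e-12)
            labels = [g in positives for g in genes]
            skl = roc_auc_score(labels, [scores[g] for g in genes])
            assert ours == pytest.approx(skl, abs=1e-12)


@pytest.fixture(scope="module")
def network():
    rng = np.random.default_rng(21)
    return random_weighted_network(rng, 60, p=0.15)


class TestCrossValidate:

    def test_bookkeeping_grid(self, network):
        seeds = list(network.nodes[:10])
        report = cross_validate(
            network, seeds, r_values=[0.1 * i for i in range(1, 10)],
            k=5, n_repeats=1, rng_seed=3,
        )
        assert len(report.records) == 9 * 5

    def test_deterministic_report(self, network):
        seeds = list(network.nodes[:10])
        kw = dict(r_values=[0.3, 0.6], k=5, n_repeats=2, rng_seed=11)
        a = cross_validate(network, seeds, **kw)
        b = cross_validate(network, seeds, **kw)
        assert a.to_json() == b.to_json()

    def test_paired_folds_across_r(self, network):
        """Within a repeat, every r sees the same fold assignment, so the
        number of held-out seeds per (repeat, fold) is r-independent."""
        seeds = list(network.nodes[:11])
        report = cross_validate(network, seeds, r_values=[0.2, 0.8], k=5,
                                n_repeats=2, rng_seed=5)
        by_cell = {}
        for rec in report.records:
            by_cell.setdefault((rec.repeat, rec.fold), set()).add(
                (len(rec.test_ranks), rec.test_ranks and max(rec.test_ranks) >= 1)
            )
        assert all(len(v) == 1 for v in by_cell.values())

    def test_leave_one_out_boundary(self, network):
        seeds = list(network.nodes[:6])
        report = cross_validate(network, seeds, r_values=[0.3], k=len(seeds),
                                n_repeats=1, rng_seed=1)
        assert len(report.records) == len(seeds)
        assert all(len(rec.test_ranks) == 1 for rec in report.records)

    def test_out_of_network_seeds_listed(self, network):
        seeds = list(network.nodes[:8]) + ["ghost1", "ghost2"]
        report = cross_validate(network, seeds, r_values=[0.3], k=4, rng_seed=2)
        assert report.missing_seeds == ("ghost1", "ghost2")


class TestSelectR:
    def _report(self, totals):
        records = tuple(
            FoldRecord(repeat=0, fold=0, r=r, counts=(t,), auc=0.5, test_ranks=())
            for r, t in totals.items()
        )
        return CVReport(r_values=tuple(totals), cutoffs=(100,), k=5,
                        n_repeats=1, rng_seed=0, records=records)

    def test_argmax(self):
        assert select_r(self._report({0.2: 40, 0.3: 55, 0.4: 51})) == 0.3

    def test_tie_breaks_toward_smaller_r(self):
        assert select_r(self._report({0.5: 55, 0.3: 55})) == 0.3

    def test_single_r(self):
        assert select_r(self._report({0.7: 1})) == 0.7

    def test_empty_report_is_an_error(self):
        with pytest.raises(DataError):
            select_r(CVReport(r_values=(), cutoffs=(), k=5, n_repeats=0,
                              rng_seed=0, records=()))


class TestConfirmationRate:
    def _records(self, confirmed_ranks, n=10):
        return [
            CandidateRecord(rank=i, gene=f"g{i}", score=1.0 / i,
                            pmids=("12345",) if i in confirmed_ranks else ())
            for i in range(1, n + 1)
        ]

    def test_count_and_rate(self):
        assert confirmation_rate(self._records({1, 3, 5}), 5) == (3, 0.6)

    def test_all_unconfirmed(self):
        assert confirmation_rate(self._records(set()), 10) == (0, 0.0)

    def test_n_beyond_available_ranks(self):
        with pytest.raises(DataError, match="ranks 1"):
            confirmation_rate(self._records({1}), 11)


class TestGoTermCounts:
    def test_counting_and_order(self, small_index):
        counts = go_term_counts(["g1", "g2", "g3"], small_index)
        assert counts == {"f2": 3, "f1": 2, "f3": 1}
        assert list(counts) == ["f2", "f1", "f3"]  # descending, then term id

    def test_unannotated_genes_empty(self, small_index):
        assert go_term_counts(["zz1", "zz2"], small_index) == {}

    def test_counts_bounded_by_gene_count(self, small_index):
        counts = go_term_counts(["g1", "g2"], small_index)
        assert all(c <= 2 for c in counts.values())
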