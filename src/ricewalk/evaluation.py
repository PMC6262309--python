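"""Cross-validation, ranking metrics, and reporting for RWR prioritization.

The validation protocol: seed genes are split evenly into k folds; each fold
in turn is held out, its genes re-enter the candidate pool, the walk restarts
from the remaining seeds, and the held-out seeds' ranks among all candidates
are recorded.  Performance is summarized as top-k matched-seed counts at
fixed rank cutoffs, tie-aware ROC AUC, and rank sums, over a grid of restart
probabilities and any number of repeated, re-randomized splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .annotations import AnnotationIndex
from .errors import DataError
from .netbuild import FunctionalNetwork
from .walker import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    RankedList,
    TransitionMatrix,
    column_normalize,
    make_seed_vector,
    rank_candidates,
    rwr,
)

__all__ = [
    "FoldAssignment",
    "FoldRun",
    "CVReport",
    "CandidateRecord",
    "kfold_split",
    "run_fold",
    "topk_match_counts",
    "roc_auc",
    "cross_validate",
    "select_r",
    "confirmation_rate",
    "go_term_counts",
    "DEFAULT_CUTOFFS",
    "DEFAULT_R_GRID",
]

DEFAULT_CUTOFFS = (100, 200, 300, 400, 500)
DEFAULT_R_GRID = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class FoldAssignment:
    """Disjoint folds covering the seed set; sizes differ by at most one."""

    folds: tuple[frozenset[str], ...]
    rng_seed: int


@dataclass(frozen=True)
class CandidateRecord:
    """One row of a ranked candidate table with literature evidence.

    ``pmids`` is empty when no supporting publication is recorded.
    """

    rank: int
    gene: str
    score: float
    pmids: tuple[str, ...] = ()
    reconstructed: bool = False

    @property
    def confirmed(self) -> bool:
        return len(self.pmids) > 0


@dataclass(frozen=True)
class FoldRun:
    """Result of ranking one held-out fold."""

    ranking: tuple[tuple[int, str, float], ...]
    test_ranks: Mapping[str, int]
    missing_test_seeds: tuple[str, ...]
    iterations: int
    final_delta: float
    degenerate: bool = False  # r = 1: scores carry no network information


@dataclass(frozen=True)
class FoldRecord:
    """Bookkeeping for one (repeat, fold, r) cell of a cross-validation."""

    repeat: int
    fold: int
    r: float
    counts: tuple[int, ...]
    auc: float
    test_ranks: tuple[int, ...]


@dataclass(frozen=True)
class CVReport:
    """Full cross-validation record with per-r aggregates."""

    r_values: tuple[float, ...]
    cutoffs: tuple[int, ...]
    k: int
    n_repeats: int
    rng_seed: int
    records: tuple[FoldRecord, ...]
    missing_seeds: tuple[str, ...] = ()

    def total_matched(self) -> dict[float, int]:
        """Per-r total matched-seed count summed over cutoffs, folds, repeats."""
        totals = {r: 0 for r in self.r_values}
        for rec in self.records:
            totals[rec.r] += sum(rec.counts)
        return totals

    def counts_by_cutoff(self) -> dict[float, tuple[int, ...]]:
        """Per-r matched counts at each cutoff, summed over folds and repeats."""
        out = {r: np.zeros(len(self.cutoffs), dtype=int) for r in self.r_values}
        for rec in self.records:
            out[rec.r] += np.asarray(rec.counts)
        return {r: tuple(int(c) for c in v) for r, v in out.items()}

    def rank_sums(self) -> dict[float, tuple[int, ...]]:
        """Per-r sum of held-out-seed ranks, one entry per repeat."""
        sums = {r: np.zeros(self.n_repeats, dtype=np.int64) for r in self.r_values}
        for rec in self.records:
            sums[rec.r][rec.repeat] += sum(rec.test_ranks)
        return {r: tuple(int(s) for s in v) for r, v in sums.items()}

    def mean_auc(self) -> dict[float, float]:
        accum: dict[float, list[float]] = {r: [] for r in self.r_values}
        for rec in self.records:
            if not np.isnan(rec.auc):
                accum[rec.r].append(rec.auc)
        return {r: float(np.mean(v)) if v else float("nan") for r, v in accum.items()}

    def to_dict(self) -> dict:
        return {
            "r_values": list(self.r_values),
            "cutoffs": list(self.cutoffs),
            "k": self.k,
            "n_repeats": self.n_repeats,
            "rng_seed": self.rng_seed,
            "missing_seeds": list(self.missing_seeds),
            "records": [
                {
                    "repeat": rec.repeat,
                    "fold": rec.fold,
                    "r": rec.r,
                    "counts": list(rec.counts),
                    "auc": rec.auc,
                    "test_ranks": list(rec.test_ranks),
                }
                for rec in self.records
            ],
            "total_matched": {str(r): v for r, v in self.total_matched().items()},
            "rank_sums": {str(r): list(v) for r, v in self.rank_sums().items()},
            "mean_auc": {str(r): v for r, v in self.mean_auc().items()},
            "selected_r": select_r(self),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def kfold_split(seeds: Iterable[str], k: int, rng_seed: int) -> FoldAssignment:
    """Shuffle the seeds with a seeded generator and deal them round-robin
    into k folds, so fold sizes differ by at most one."""
    seeds = sorted(set(seeds))
    if k < 2:
        raise DataError("k must be at least 2")
    if len(seeds) < k:
        raise DataError(f"need at least k={k} seeds, got {len(seeds)}")
    rng = np.random.default_rng(rng_seed)
    order = [seeds[i] for i in rng.permutation(len(seeds))]
    folds = tuple(frozenset(order[i::k]) for i in range(k))
    return FoldAssignment(folds=folds, rng_seed=rng_seed)


def run_fold(
    W: TransitionMatrix,
    train_seeds: Iterable[str],
    test_seeds: Iterable[str],
    r: float,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FoldRun:
    """Rank all non-training genes from a training-seed restart and locate
    the held-out seeds.

    The restart vector is built from the training seeds only; held-out
    seeds are candidates like any other gene.  Held-out seeds absent from
    the network cannot be ranked and are reported in
    ``missing_test_seeds``.
    """
    train = set(train_seeds)
    test = set(test_seeds)
    if train & test:
        raise DataError("training and test seed sets must be disjoint")
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        p0 = make_seed_vector(train, W.node_order)
    result = rwr(W, p0, r=r, tol=tol, max_iter=max_iter)
    ranking = rank_candidates(result.state, train)
    rank_of = {gene: rank for rank, gene, _ in ranking}
    test_ranks = {g: rank_of[g] for g in sorted(test) if g in rank_of}
    missing = tuple(sorted(g for g in test if g not in rank_of))
    return FoldRun(
        ranking=tuple(ranking),
        test_ranks=test_ranks,
        missing_test_seeds=missing,
        iterations=result.iterations,
        final_delta=result.final_delta,
        degenerate=(r == 1.0),
    )


def topk_match_counts(
    test_ranks: Iterable[int],
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
) -> list[int]:
    """Number of held-out seeds ranked at or above each cutoff."""
    cutoffs = list(cutoffs)
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise DataError("cutoffs must be strictly ascending")
    ranks = list(test_ranks)
    return [sum(1 for rk in ranks if rk <= c) for c in cutoffs]


def roc_auc(ranking: RankedList, positives: Iterable[str]) -> float:
    """Tie-aware ROC AUC of a ranking against a positive gene set.

    Computed as the Mann-Whitney probability that a random positive
    outscores a random negative, with half credit for exact score ties.
    Negatives are all ranked genes outside the positive set.
    """
    positives = set(positives)
    genes = [g for _, g, _ in ranking]
    scores = np.asarray([s for _, _, s in ranking])
    labels = np.asarray([g in positives for g in genes])
    n_pos = int(labels.sum())
    n_neg = len(genes) - n_pos
    if n_pos == 0:
        raise DataError("no positive gene appears in the ranking")
    if n_neg == 0:
        raise DataError("ranking contains no negatives")
    # average ranks of ascending scores: ties get half credit automatically
    asc_ranks = rankdata(scores, method="average")
    u = float(asc_ranks[labels].sum()) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def roc_curve_points(
    ranking: RankedList, positives: Iterable[str]
) -> list[tuple[float, float]]:
    """(FPR, TPR) points of the ROC curve, one per distinct score threshold."""
    positives = set(positives)
    labels = [g in positives for _, g, _ in ranking]
    scores = [s for _, _, s in ranking]
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError("ROC curve needs both positives and negatives")
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and scores[j] == scores[i]:
            tp += labels[j]
            fp += not labels[j]
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    return points


def cross_validate(
    network: FunctionalNetwork | TransitionMatrix,
    seeds: Iterable[str],
    r_values: Sequence[float] = DEFAULT_R_GRID,
    k: int = 5,
    n_repeats: int = 1,
    rng_seed: int = 0,
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
    mode: str = "weighted",
    dangling: str = "self_loop",
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CVReport:
    """Repeated k-fold cross-validation over a restart-probability grid.

    Fold assignments are re-randomized each repeat (seeded, reproducible)
    and shared across all r values within a repeat, so the r comparison is
    paired.  Seeds absent from the network are dropped up front and listed
    in the report.  Accepts either a built functional network (normalized
    here with ``mode``/``dangling``) or a ready transition matrix.
    """
    if isinstance(network, TransitionMatrix):
        W = network
    else:
        W = column_normalize(network, mode=mode, dangling=dangling)
    node_set = set(W.node_order)
    all_seeds = sorted(set(seeds))
    in_net = [s for s in all_seeds if s in node_set]
    missing = tuple(s for s in all_seeds if s not in node_set)
    if len(in_net) < k:
        raise DataError(
            f"only {len(in_net)} seed(s) are in the network; need at least k={k}"
        )
    master = np.random.default_rng(rng_seed)
    repeat_seeds = master.integers(0, 2**31 - 1, size=n_repeats)
    records: list[FoldRecord] = []
    for repeat in range(n_repeats):
        assignment = kfold_split(in_net, k, int(repeat_seeds[repeat]))
        for fold_idx, test in enumerate(assignment.folds):
            train = set(in_net) - test
            for r in r_values:
                run = run_fold(W, train, test, r, tol=tol, max_iter=max_iter)
                ranks = tuple(sorted(run.test_ranks.values()))
                counts = tuple(topk_match_counts(ranks, cutoffs))
                auc = (
                    roc_auc(list(run.ranking), set(run.test_ranks))
                    if run.test_ranks
                    else float("nan")
                )
                records.append(
                    FoldRecord(
                        repeat=repeat,
                        fold=fold_idx,
                        r=float(r),
                        counts=counts,
                        auc=auc,
                        test_ranks=ranks,
                    )
                )
    return CVReport(
        r_values=tuple(float(r) for r in r_values),
        cutoffs=tuple(int(c) for c in cutoffs),
        k=k,
        n_repeats=n_repeats,
        rng_seed=rng_seed,
        records=tuple(records),
        missing_seeds=missing,
    )


def select_r(report: CVReport) -> float:
    """Restart probability with the maximum total matched-seed count;
    ties break toward the smaller r."""
    if not report.records:
        raise DataError("empty cross-validation report")
    totals = report.total_matched()
    return min(sorted(totals), key=lambda r: (-totals[r], r))


def confirmation_rate(
    records: Sequence[CandidateRecord], n: int
) -> tuple[int, float]:
    """Count and fraction of the top-n candidates with literature support."""
    if n < 1:
        raise DataError("n must be a positive integer")
    available = {rec.rank for rec in records}
    if not set(range(1, n + 1)) <= available:
        raise DataError(f"records do not cover ranks 1..{n}")
    count = sum(1 for rec in records if rec.rank <= n and rec.confirmed)
    return count, count / n


def go_term_counts(
    top_genes: Iterable[str], index: AnnotationIndex
) -> dict[str, int]:
    """How many of the given genes are annotated to each function term,
    sorted by descending count then term ID."""
    counts: dict[str, int] = {}
    for gene in set(top_genes):
        for term in index.terms_of(gene):
            counts[term] = counts.get(term, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
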