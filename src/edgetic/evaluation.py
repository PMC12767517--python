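"""Leakage-aware evaluation: pair clustering, group CV, test classes, AUC.

Paired-protein inputs leak information in ordinary cross-validation both
through sequence similarity and through individual proteins shared between
train and test. Two mechanisms address this:

* variant-partner pairs are grouped by clustering the *concatenated*
  wild-type sequences of both proteins at 50% identity, and whole clusters
  are assigned to folds (group k-fold), so no cluster spans the split;
* each test pair is binned post hoc by how many of its two proteins appear
  anywhere in the training pairs — both (class 1), one (class 2) or
  neither (class 3) — and AUC is reported per class, size-weighted across
  folds and iterations.

Clustering uses a built-in greedy longest-first algorithm compatible with
CD-HIT's convention (identity = identical positions in an ungapped
comparison divided by the shorter length); a parser for CD-HIT ``.clstr``
output is provided for users who prefer the external tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import DataError, PartitionError, UndefinedMetricError
from .gat import TrainingExample, finetune

DEFAULT_IDENTITY_THRESHOLD = 0.5
DEFAULT_ITERATIONS = 30
DEFAULT_FOLDS = 10
MIN_CLASS_N = 30  # per-class curves with fewer test points are skipped


@dataclass
class SequenceCluster:
    cluster_id: int
    representative: str      # concatenated sequence of the founding pair
    members: list[int]       # indices into the input pair list


def _ungapped_identity(a: str, b: str) -> float:
    """Identical positions over the shorter length (ungapped, offset 0)."""
    shorter = min(len(a), len(b))
    if shorter == 0:
        return 0.0
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return matches / shorter


def _pair_concat_sequence(pair) -> str:
    if pair.interactor_seq is None or pair.partner_seq is None:
        raise DataError(
            f"pair {pair.interactor_id}/{pair.partner_id} lacks sequences"
        )
    return pair.interactor_seq + pair.partner_seq


def cluster_pairs(
    pairs, identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
) -> list[SequenceCluster]:
    """Greedy incremental clustering of concatenated pair sequences.

    Sequences are sorted by length descending (ties by sequence, then input
    order, for determinism); each joins the first existing cluster whose
    representative it matches at >= threshold identity, else founds a new
    cluster.
    """
    seqs = [_pair_concat_sequence(p) for p in pairs]
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), seqs[i], i))
    clusters: list[SequenceCluster] = []
    for idx in order:
        seq = seqs[idx]
        for cluster in clusters:
            if _ungapped_identity(seq, cluster.representative) >= identity_threshold:
                cluster.members.append(idx)
                break
        else:
            clusters.append(
                SequenceCluster(
                    cluster_id=len(clusters), representative=seq, members=[idx]
                )
            )
    return clusters


def parse_clstr(text: str) -> list[list[str]]:
    """Parse CD-HIT ``.clstr`` output into clusters of sequence names."""
    clusters: list[list[str]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">Cluster"):
            clusters.append([])
        else:
            name = line.split(">", 1)[1].split("...")[0]
            clusters[-1].append(name)
    return clusters


def group_kfold(
    clusters: list[SequenceCluster], k: int = DEFAULT_FOLDS, seed: int = 0
) -> list[list[int]]:
    """Assign whole clusters to k folds, balancing pair counts.

    Clusters are taken largest-first (ties shuffled by ``seed``) and each goes
    to the currently lightest fold, so every member of a cluster lands in the
    same fold and fold sizes stay balanced.
    """
    if len(clusters) < k:
        raise PartitionError(f"{len(clusters)} clusters cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    tie_break = rng.permutation(len(clusters))
    order = sorted(
        range(len(clusters)),
        key=lambda c: (-len(clusters[c].members), tie_break[c]),
    )
    folds: list[list[int]] = [[] for _ in range(k)]
    loads = np.zeros(k, dtype=int)
    for c in order:
        f = int(np.argmin(loads))  # lowest index wins ties
        folds[f].extend(clusters[c].members)
        loads[f] += len(clusters[c].members)
    return folds


def assign_test_class(pair, train_protein_ids: set) -> int:
    """Park–Marcotte class: both proteins seen → 1, one → 2, neither → 3."""
    shared = int(pair.interactor_id in train_protein_ids) + int(
        pair.partner_id in train_protein_ids
    )
    return {2: 1, 1: 2, 0: 3}[shared]


def roc_auc(scores, labels) -> float:
    """Rank-based (Mann–Whitney) ROC AUC; ties count one half."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise UndefinedMetricError("AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def mean_roc_curve(score_label_sets, n_grid: int = 101):
    """Vertically averaged ROC over a fixed FPR grid.

    Returns (fpr_grid, mean_tpr, sem_tpr) across the provided folds.
    """
    grid = np.linspace(0, 1, n_grid)
    tprs = []
    for scores, labels in score_label_sets:
        fpr, tpr, _ = roc_curve(labels, scores)
        tprs.append(np.interp(grid, fpr, tpr))
    tprs = np.asarray(tprs)
    sem = tprs.std(axis=0, ddof=1) / np.sqrt(len(tprs)) if len(tprs) > 1 else np.zeros(n_grid)
    return grid, tprs.mean(axis=0), sem


def write_roc_tsv(path, score_label_sets, n_grid: int = 101) -> None:
    """Export the vertically averaged ROC as (fpr, tpr_mean, tpr_sem) TSV."""
    grid, mean_tpr, sem = mean_roc_curve(score_label_sets, n_grid)
    pd.DataFrame(
        {"fpr": grid, "tpr_mean": mean_tpr, "tpr_sem": sem}
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# cross-validation driver

@dataclass
class FoldAssignment:
    iteration: int
    fold: int
    train_indices: list[int]
    test_indices: list[int]
    test_class: dict[int, int]   # example index -> class bin 1/2/3


@dataclass
class CVResult:
    table: pd.DataFrame          # iteration, fold, cls, n, auc
    assignments: list[FoldAssignment]
    skipped: list[dict] = field(default_factory=list)

    def aggregate(self) -> dict[int, float]:
        """Per-class AUC, weighted by test-class size over folds/iterations."""
        out = {}
        for cls, sub in self.table.groupby("cls"):
            out[int(cls)] = float(np.average(sub["auc"], weights=sub["n"]))
        return out

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def gat_trainer(config, pretrained=None):
    """Trainer factory for :func:`run_cv` backed by the GAT model.

    With ``pretrained`` given, each fold model starts from the stability-
    pretrained parameters; otherwise folds train from scratch.
    """

    def train(train_examples, seed):
        model, _ = finetune(
            pretrained, config, train_examples, seed=seed,
            from_scratch=pretrained is None,
        )
        return model

    return train


class _LinearModel:
    def __init__(self, clf):
        self.clf = clf

    def predict_many(self, examples):
        x = np.array([ex.raw_encoding for ex in examples])
        return self.clf.predict_proba(x)[:, 1]


def linear_trainer():
    """Fast logistic-regression baseline on raw mutation encodings.

    Useful for exercising the CV machinery (fold structure, class bins)
    without the cost of graph-model training.
    """

    def train(train_examples, seed):
        x = np.array([ex.raw_encoding for ex in train_examples])
        y = np.array([ex.label for ex in train_examples])
        clf = LogisticRegression(max_iter=500, random_state=seed)
        clf.fit(x, y)
        return _LinearModel(clf)

    return train


def run_cv(
    examples: list[TrainingExample],
    trainer,
    iterations: int = DEFAULT_ITERATIONS,
    k: int = DEFAULT_FOLDS,
    min_class_n: int = MIN_CLASS_N,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    seed: int = 0,
) -> CVResult:
    """Iterated group cross-validation with per-class AUC aggregation.

    Per iteration a fresh seed-derived fold partition is drawn; per fold the
    trainer fits on the training pairs only, test pairs are binned into
    classes 1/2/3 against that fold's training proteins, and AUC is computed
    per class wherever the class holds at least ``min_class_n`` pairs with
    both labels present.
    """
    if not examples:
        raise DataError("no examples")
    pairs = [ex.record for ex in examples]
    clusters = cluster_pairs(pairs, identity_threshold)
    rng = np.random.default_rng(seed)
    iter_seeds = rng.integers(0, 2**31, size=iterations)
    rows, assignments, skipped = [], [], []
    for it in range(iterations):
        folds = group_kfold(clusters, k=k, seed=int(iter_seeds[it]))
        for f, test_idx in enumerate(folds):
            test_set = set(test_idx)
            train_idx = [i for i in range(len(examples)) if i not in test_set]
            if not train_idx or not test_idx:
                continue
            train_examples = [examples[i] for i in train_idx]
            model_seed = int((iter_seeds[it] + f) % 2**31)
            model = trainer(train_examples, model_seed)
            scores = model.predict_many([examples[i] for i in test_idx])
            train_proteins = {pairs[i].interactor_id for i in train_idx} | {
                pairs[i].partner_id for i in train_idx
            }
            test_class = {
                i: assign_test_class(pairs[i], train_proteins) for i in test_idx
            }
            assignments.append(
                FoldAssignment(
                    iteration=it, fold=f, train_indices=train_idx,
                    test_indices=list(test_idx), test_class=test_class,
                )
            )
            for cls in (1, 2, 3):
                sel = [j for j, i in enumerate(test_idx) if test_class[i] == cls]
                n = len(sel)
                if n < min_class_n:
                    if n:
                        skipped.append({"iteration": it, "fold": f, "cls": cls,
                                        "n": n, "reason": "n<min_class_n"})
                    continue
                labels = [examples[test_idx[j]].label for j in sel]
                try:
                    auc = roc_auc([scores[j] for j in sel], labels)
                except UndefinedMetricError:
                    skipped.append({"iteration": it, "fold": f, "cls": cls,
                                    "n": n, "reason": "single-class"})
                    continue
                rows.append(
                    {"iteration": it, "fold": f, "cls": cls, "n": n, "auc": auc}
                )
    table = pd.DataFrame(rows, columns=["iteration", "fold", "cls", "n", "auc"])
    return CVResult(table=table, assignments=assignments, skipped=skipped)


@dataclass
class BlindTestResult:
    scores: np.ndarray
    classes: np.ndarray
    aucs: dict[int, float]
    class_sizes: dict[int, int]
    excluded: int


def blind_test(
    train_examples: list[TrainingExample],
    benchmark_examples: list[TrainingExample],
    trainer,
    k: int = DEFAULT_FOLDS,
    min_class_n: int = MIN_CLASS_N,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    seed: int = 0,
) -> BlindTestResult:
    """Benchmark evaluation with a k-fold ensemble and variant exclusion.

    Benchmark variants already present in training (same interactor and
    mutation, any partner) are excluded; remaining pairs are binned into
    classes against the full training protein set and scored with the mean
    over the k fold models.
    """
    train_variants = {ex.record.variant_key for ex in train_examples}
    kept = [ex for ex in benchmark_examples
            if ex.record.variant_key not in train_variants]
    excluded = len(benchmark_examples) - len(kept)
    if not kept:
        raise DataError("every benchmark pair overlaps the training variants")
    clusters = cluster_pairs([ex.record for ex in train_examples],
                             identity_threshold)
    folds = group_kfold(clusters, k=k, seed=seed)
    models = []
    for f, fold_idx in enumerate(folds):
        fold_set = set(fold_idx)
        subset = [ex for i, ex in enumerate(train_examples) if i not in fold_set]
        models.append(trainer(subset, int(seed + f)))
    member_scores = np.array([m.predict_many(kept) for m in models])
    scores = member_scores.mean(axis=0)
    train_proteins = {ex.record.interactor_id for ex in train_examples} | {
        ex.record.partner_id for ex in train_examples
    }
    classes = np.array(
        [assign_test_class(ex.record, train_proteins) for ex in kept]
    )
    aucs, sizes = {}, {}
    for cls in (1, 2, 3):
        sel = classes == cls
        sizes[cls] = int(sel.sum())
        if sizes[cls] < min_class_n:
            continue
        try:
            aucs[cls] = roc_auc(scores[sel], [ex.label for ex, s in
                                              zip(kept, sel) if s])
        except UndefinedMetricError:
            pass
    return BlindTestResult(scores=scores, classes=classes, aucs=aucs,
                           class_sizes=sizes, excluded=excluded)
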