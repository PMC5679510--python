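"""Random-Forest essentiality classification and the five evaluation regimes.

The classifier is a Random Forest with the information-gain (entropy) split
criterion. Because non-essential genes heavily outnumber essential ones,
every training set is first balanced by random under-sampling of the
non-essential class. Performance is summarized primarily by the AUC of the
ROC curve — the probability that a randomly chosen essential gene scores
above a randomly chosen non-essential one (ties count 1/2), computed by the
Mann-Whitney rank formulation — with threshold-dependent accuracy and
F-measure reported alongside.

Evaluation regimes:

* ``monte_carlo_cv`` — intra-organism: repeated stratified 80/20 splits
  (100 by default), with the Markov chains and the background distribution
  refitted inside each fold from the training side only.
* ``pairwise_cross`` — train on one organism, test on another.
* ``leave_one_species_out`` — train on all organisms but one pooled.
* ``pooled_cv`` — k-fold CV over all organisms pooled, folds stratified by
  organism and label.
* ``taxon_eval`` — the same protocols at the taxonomic-order level:
  every ordered taxon pair (cross-taxon) or leave-one-taxon-out.

Every regime records the train/test gene-ID sets per fold so the absence of
information leakage can be audited after the fact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve

from .feature_table import FEATURE_NAMES, FeatureVector, extract_features
from .info_features import EnergyTable
from .markov_model import DEFAULT_DELTA, DEFAULT_ORDER, estimate_order, fit_markov
from .sequence_io import (
    GeneRecord,
    LABEL_ESSENTIAL,
    LABEL_NON_ESSENTIAL,
    OrganismDataset,
    build_background,
)

logger = logging.getLogger("itess.classifier_eval")

DEFAULT_N_TREES = 100
DEFAULT_THRESHOLD = 0.5

MODES = ("intra_cv", "pooled_cv", "pairwise", "loso", "cross_taxon", "leave_taxon_out")


# ---------------------------------------------------------------------------
# result containers


@dataclass
class EvalResult:
    """Outcome of one evaluation run: per-fold AUCs, ROC, and summary metrics."""

    mode: str
    train_id: str
    test_id: str
    fold_aucs: list[float]
    mean_auc: float
    roc_points: list[tuple[float, float]]
    f_measure: float
    accuracy: float
    n_folds: int
    seed: int
    fold_memberships: list[tuple[frozenset, frozenset]] = field(
        default_factory=list, repr=False
    )

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if abs(self.mean_auc - float(np.mean(self.fold_aucs))) > 1e-12:
            raise ValueError("mean_auc is not the mean of fold_aucs")
        pts = self.roc_points
        if pts[0] != (0.0, 0.0) or pts[-1] != (1.0, 1.0):
            raise ValueError("ROC must start at (0,0) and end at (1,1)")
        arr = np.asarray(pts)
        if np.any(np.diff(arr, axis=0) < 0):
            raise ValueError("ROC points must be monotone nondecreasing")


@dataclass(frozen=True)
class TaxonConfig:
    """Grouping of organism tags into taxonomic orders."""

    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for taxon, orgs in self.groups.items():
            for tag in orgs:
                if tag in seen:
                    raise ValueError(f"organism {tag!r} appears in more than one taxon")
                seen.add(tag)


@dataclass(frozen=True)
class FeatureRanking:
    """All 91 features ordered by decreasing information gain (bits)."""

    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if len(self.entries) != len(FEATURE_NAMES):
            raise ValueError("ranking must cover all 91 features")
        gains = [g for _, g in self.entries]
        if any(gains[i] < gains[i + 1] for i in range(len(gains) - 1)):
            raise ValueError("ranking gains must be nonincreasing")


# ---------------------------------------------------------------------------
# balancing, model, metrics


def _binary_labels(items: Sequence[FeatureVector] | Sequence[GeneRecord]) -> np.ndarray:
    return np.array([1 if it.label == LABEL_ESSENTIAL else 0 for it in items])


def _undersample(items: list, rng: np.random.Generator) -> list:
    """Keep all essentials; keep a uniform random subset of non-essentials of
    equal size. Never over-samples: if essentials are the majority, the input
    is returned unchanged (logged)."""
    pos = [it for it in items if it.label == LABEL_ESSENTIAL]
    neg = [it for it in items if it.label == LABEL_NON_ESSENTIAL]
    if not pos or not neg:
        raise ValueError("both classes must be present for under-sampling")
    if len(neg) <= len(pos):
        logger.info(
            "non-essential class (%d) not larger than essential (%d); no balancing",
            len(neg), len(pos),
        )
        return list(items)
    chosen = rng.choice(len(neg), size=len(pos), replace=False)
    return pos + [neg[i] for i in sorted(chosen)]


def under_sample(vectors: Sequence[FeatureVector], seed: int) -> list[FeatureVector]:
    """Class-balance labeled feature vectors by random under-sampling (seeded)."""
    return _undersample(list(vectors), np.random.default_rng(seed))


@dataclass
class RFModel:
    """A fitted forest plus the feature-name contract it was trained under."""

    estimator: RandomForestClassifier
    feature_names: tuple[str, ...]


def _matrix(vectors: Sequence[FeatureVector], names: Sequence[str]) -> np.ndarray:
    return np.array([[v.values[n] for n in names] for v in vectors])


def train_rf(
    train: Sequence[FeatureVector],
    n_trees: int = DEFAULT_N_TREES,
    max_depth: int | None = None,
    seed: int = 0,
    feature_subset: Sequence[str] | None = None,
) -> RFModel:
    """Fit a Random Forest with the information-gain (entropy) criterion."""
    if not train:
        raise ValueError("empty training set")
    names = tuple(feature_subset) if feature_subset is not None else FEATURE_NAMES
    unknown = set(names) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown feature names: {sorted(unknown)}")
    y = _binary_labels(train)
    if len(set(y)) < 2:
        raise ValueError("training set must contain both classes")
    est = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="entropy",
        max_depth=max_depth,
        max_features="sqrt",
        random_state=seed,
    )
    est.fit(_matrix(train, names), y)
    return RFModel(estimator=est, feature_names=names)


def predict_scores(model: RFModel, test: Sequence[FeatureVector]) -> np.ndarray:
    """Per-gene essentiality score in [0, 1]: the fraction of trees voting essential."""
    if not test:
        raise ValueError("empty test set")
    proba = model.estimator.predict_proba(_matrix(test, model.feature_names))
    (pos_col,) = np.flatnonzero(model.estimator.classes_ == 1)
    return proba[:, pos_col]


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, list[tuple[float, float]]]:
    """AUC by the Mann-Whitney rank formulation, plus ROC curve points.

    Tied scores contribute 1/2 through midranks. The ROC starts at (0,0) and
    ends at (1,1).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes in the labels")
    # midranks: average rank within tied groups
    order = np.argsort(s, kind="stable")
    ranks = np.empty(len(s))
    sorted_s = s[order]
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1  # 1-based midrank
        i = j + 1
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(y, s)
    pts = [(float(a), float(b)) for a, b in zip(fpr, tpr)]
    if pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return float(auc), pts


def threshold_metrics(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[float, float]:
    """(accuracy, F-measure) at a score threshold (default 0.5).

    With no predicted or no true positives the F-measure is undefined and is
    reported as 0 with a warning.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    accuracy = float((pred == y).mean())
    if 2 * tp + fp + fn == 0:
        logger.warning("F-measure undefined (no true or predicted positives); reporting 0")
        return accuracy, 0.0
    f_measure = 2 * tp / (2 * tp + fp + fn)
    return accuracy, float(f_measure)


# ---------------------------------------------------------------------------
# shared train/test engine


def _resolve_order(
    pos_pool: list[str], neg_pool: list[str], markov_order, max_order: int, seed: int
) -> tuple[int, int]:
    if markov_order == "estimate":
        m_pos = estimate_order(pos_pool, max_order, seed=seed)
        m_neg = estimate_order(neg_pool, max_order, seed=seed + 1)
        logger.info("estimated Markov orders: MC+ m=%d, MC- m=%d", m_pos, m_neg)
        return m_pos, m_neg
    return int(markov_order), int(markov_order)


def _fit_and_score(
    train_genes: list[GeneRecord],
    test_genes: list[GeneRecord],
    genome: str | None,
    seed: int,
    n_trees: int = DEFAULT_N_TREES,
    max_depth: int | None = None,
    markov_order=DEFAULT_ORDER,
    max_order: int = 3,
    delta: float = DEFAULT_DELTA,
    energy_table: EnergyTable | None = None,
    top_k: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit chains/background/forest on the training side, score the test side.

    All training-derived objects (Markov chains, background distribution,
    feature ranking, the forest) come exclusively from ``train_genes`` and,
    for the background, the training ``genome``.
    """
    pos_pool = [g.sequence for g in train_genes if g.label == LABEL_ESSENTIAL]
    neg_pool = [g.sequence for g in train_genes if g.label == LABEL_NON_ESSENTIAL]
    if not pos_pool or not neg_pool:
        raise ValueError("training side must contain both classes")
    m_pos, m_neg = _resolve_order(pos_pool, neg_pool, markov_order, max_order, seed)
    pos_chain = fit_markov(pos_pool, m_pos, delta, class_tag="positive")
    neg_chain = fit_markov(neg_pool, m_neg, delta, class_tag="negative")
    background = build_background(
        organism="train",
        genome=genome,
        sequences=None if genome is not None else pos_pool + neg_pool,
    )
    train_vec = extract_features(
        train_genes, background, pos_chain, neg_chain, energy_table,
        train_pos=pos_pool, train_neg=neg_pool,
    )
    test_vec = extract_features(test_genes, background, pos_chain, neg_chain, energy_table)
    subset = None
    if top_k is not None:
        ranking = rank_features(train_vec)
        subset = select_top_k(ranking, top_k)
    model = train_rf(train_vec, n_trees=n_trees, max_depth=max_depth, seed=seed,
                     feature_subset=subset)
    scores = predict_scores(model, test_vec)
    return scores, _binary_labels(test_vec)


def _summarize(
    mode: str,
    train_id: str,
    test_id: str,
    fold_aucs: list[float],
    all_scores: np.ndarray,
    all_labels: np.ndarray,
    n_folds: int,
    seed: int,
    memberships: list[tuple[frozenset, frozenset]],
    threshold: float = DEFAULT_THRESHOLD,
) -> EvalResult:
    _, roc_points = roc_auc(all_scores, all_labels)
    accuracy, f_measure = threshold_metrics(all_scores, all_labels, threshold)
    return EvalResult(
        mode=mode, train_id=train_id, test_id=test_id,
        fold_aucs=fold_aucs, mean_auc=float(np.mean(fold_aucs)),
        roc_points=roc_points, f_measure=f_measure, accuracy=accuracy,
        n_folds=n_folds, seed=seed, fold_memberships=memberships,
    )


def _ids(genes: Iterable[GeneRecord]) -> frozenset:
    return frozenset(g.gene_id for g in genes)


# ---------------------------------------------------------------------------
# evaluation regimes


def monte_carlo_cv(
    dataset: OrganismDataset,
    n_folds: int = 100,
    train_frac: float = 0.8,
    seed: int = 0,
    **fit_kwargs,
) -> EvalResult:
    """Intra-organism Monte Carlo cross-validation.

    Each repetition balances the classes by under-sampling, splits the
    balanced set stratified ``train_frac``/(1−train_frac), refits the Markov
    chains (and, without a genome, the background) on the training side only,
    and records the held-out AUC.
    """
    labeled = dataset.labeled_genes
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    fold_aucs: list[float] = []
    memberships: list[tuple[frozenset, frozenset]] = []
    scores_all: list[np.ndarray] = []
    labels_all: list[np.ndarray] = []
    for fold in range(n_folds):
        balanced = _undersample(labeled, rng)
        train_genes: list[GeneRecord] = []
        test_genes: list[GeneRecord] = []
        for cls in (LABEL_ESSENTIAL, LABEL_NON_ESSENTIAL):
            members = [g for g in balanced if g.label == cls]
            perm = rng.permutation(len(members))
            n_train = int(round(train_frac * len(members)))
            if n_train == 0 or n_train == len(members):
                raise ValueError(
                    f"train_frac={train_frac} leaves an empty split for class {cls}"
                )
            train_genes += [members[i] for i in perm[:n_train]]
            test_genes += [members[i] for i in perm[n_train:]]
        fold_seed = int(rng.integers(2**31))
        scores, y = _fit_and_score(
            train_genes, test_genes, dataset.genome, fold_seed, **fit_kwargs
        )
        auc, _ = roc_auc(scores, y)
        fold_aucs.append(auc)
        memberships.append((_ids(train_genes), _ids(test_genes)))
        scores_all.append(scores)
        labels_all.append(y)
    return _summarize(
        "intra_cv", dataset.organism, dataset.organism, fold_aucs,
        np.concatenate(scores_all), np.concatenate(labels_all),
        n_folds, seed, memberships,
    )


def pairwise_cross(
    train_org: OrganismDataset,
    test_org: OrganismDataset,
    seed: int = 0,
    **fit_kwargs,
) -> EvalResult:
    """Train on one organism (balanced), test on all labeled genes of another.

    The KLD background is the training organism's.
    """
    if train_org.organism == test_org.organism:
        raise ValueError(
            "train and test organism are identical; use monte_carlo_cv instead"
        )
    rng = np.random.default_rng(seed)
    train_genes = _undersample(train_org.labeled_genes, rng)
    test_genes = test_org.labeled_genes
    model_seed = int(rng.integers(2**31))
    scores, y = _fit_and_score(train_genes, test_genes, train_org.genome, model_seed, **fit_kwargs)
    auc, _ = roc_auc(scores, y)
    return _summarize(
        "pairwise", train_org.organism, test_org.organism, [auc], scores, y,
        1, seed, [(_ids(train_genes), _ids(test_genes))],
    )


def _eval_pooled_train(
    mode: str,
    train_orgs: list[OrganismDataset],
    test_genes: list[GeneRecord],
    train_id: str,
    test_id: str,
    seed: int,
    **fit_kwargs,
) -> EvalResult:
    rng = np.random.default_rng(seed)
    pool = [g for o in train_orgs for g in o.labeled_genes]
    train_genes = _undersample(pool, rng)
    model_seed = int(rng.integers(2**31))
    genomes = (
        [o.genome for o in train_orgs]
        if all(o.genome is not None for o in train_orgs)
        else None
    )
    pos_pool = [g.sequence for g in train_genes if g.label == LABEL_ESSENTIAL]
    neg_pool = [g.sequence for g in train_genes if g.label == LABEL_NON_ESSENTIAL]
    if genomes is not None:
        # pooled-genome background: counts summed across genomes, no joins
        background = build_background(organism=train_id, sequences=genomes)
    else:
        background = build_background(organism=train_id, sequences=pos_pool + neg_pool)
    markov_order = fit_kwargs.pop("markov_order", DEFAULT_ORDER)
    max_order = fit_kwargs.pop("max_order", 3)
    delta = fit_kwargs.pop("delta", DEFAULT_DELTA)
    energy_table = fit_kwargs.pop("energy_table", None)
    top_k = fit_kwargs.pop("top_k", None)
    m_pos, m_neg = _resolve_order(pos_pool, neg_pool, markov_order, max_order, model_seed)
    pos_chain = fit_markov(pos_pool, m_pos, delta, class_tag="positive")
    neg_chain = fit_markov(neg_pool, m_neg, delta, class_tag="negative")
    train_vec = extract_features(
        train_genes, background, pos_chain, neg_chain, energy_table,
        train_pos=pos_pool, train_neg=neg_pool,
    )
    test_vec = extract_features(test_genes, background, pos_chain, neg_chain, energy_table)
    subset = None
    if top_k is not None:
        subset = select_top_k(rank_features(train_vec), top_k)
    model = train_rf(train_vec, seed=model_seed, feature_subset=subset, **fit_kwargs)
    scores = predict_scores(model, test_vec)
    y = _binary_labels(test_vec)
    auc, _ = roc_auc(scores, y)
    return _summarize(
        mode, train_id, test_id, [auc], scores, y, 1, seed,
        [(_ids(train_genes), _ids(test_genes))],
    )


def leave_one_species_out(
    all_orgs: Sequence[OrganismDataset],
    held_out: str,
    seed: int = 0,
    **fit_kwargs,
) -> EvalResult:
    """Train on all organisms but one pooled (balanced), test the held-out one."""
    if len(all_orgs) < 2:
        raise ValueError("leave-one-species-out requires at least 2 organisms")
    tags = [o.organism for o in all_orgs]
    if held_out not in tags:
        raise ValueError(f"held-out organism {held_out!r} not among {tags}")
    train_orgs = [o for o in all_orgs if o.organism != held_out]
    test_org = next(o for o in all_orgs if o.organism == held_out)
    result = _eval_pooled_train(
        "loso", train_orgs, test_org.labeled_genes,
        "+".join(o.organism for o in train_orgs), held_out, seed, **fit_kwargs,
    )
    return result


def pooled_cv(
    all_orgs: Sequence[OrganismDataset],
    n_folds: int = 5,
    seed: int = 0,
    **fit_kwargs,
) -> EvalResult:
    """k-fold CV over all organisms pooled, folds stratified by organism and label."""
    rng = np.random.default_rng(seed)
    folds: list[list[GeneRecord]] = [[] for _ in range(n_folds)]
    for org in all_orgs:
        for cls in (LABEL_ESSENTIAL, LABEL_NON_ESSENTIAL):
            members = [g for g in org.labeled_genes if g.label == cls]
            perm = rng.permutation(len(members))
            for pos, idx in enumerate(perm):
                folds[pos % n_folds].append(members[idx])
    fold_aucs: list[float] = []
    memberships = []
    scores_all, labels_all = [], []
    pooled_id = "+".join(o.organism for o in all_orgs)
    for f in range(n_folds):
        test_genes = folds[f]
        train_pool = [g for j in range(n_folds) if j != f for g in folds[j]]
        train_genes = _undersample(train_pool, rng)
        model_seed = int(rng.integers(2**31))
        scores, y = _fit_and_score(train_genes, test_genes, None, model_seed, **fit_kwargs)
        auc, _ = roc_auc(scores, y)
        fold_aucs.append(auc)
        memberships.append((_ids(train_genes), _ids(test_genes)))
        scores_all.append(scores)
        labels_all.append(y)
    return _summarize(
        "pooled_cv", pooled_id, pooled_id, fold_aucs,
        np.concatenate(scores_all), np.concatenate(labels_all),
        n_folds, seed, memberships,
    )


def taxon_eval(
    all_orgs: Sequence[OrganismDataset],
    taxa: TaxonConfig,
    mode: str,
    seed: int = 0,
    **fit_kwargs,
) -> list[EvalResult]:
    """Cross-taxon (every ordered taxon pair) or leave-one-taxon-out evaluation."""
    if mode not in ("cross_taxon", "leave_taxon_out"):
        raise ValueError(f"mode must be cross_taxon or leave_taxon_out, got {mode!r}")
    by_tag = {o.organism: o for o in all_orgs}
    for taxon, tags in taxa.groups.items():
        for tag in tags:
            if tag not in by_tag:
                raise ValueError(f"organism {tag!r} in taxon {taxon!r} absent from data")
    if len(taxa.groups) < 2:
        raise ValueError("need at least 2 taxa")
    taxon_orgs = {t: [by_tag[tag] for tag in tags] for t, tags in taxa.groups.items()}
    results: list[EvalResult] = []
    names = list(taxa.groups)
    rng = np.random.default_rng(seed)
    if mode == "cross_taxon":
        for train_t in names:
            for test_t in names:
                if train_t == test_t:
                    continue
                sub_seed = int(rng.integers(2**31))
                test_genes = [g for o in taxon_orgs[test_t] for g in o.labeled_genes]
                results.append(
                    _eval_pooled_train(
                        "cross_taxon", taxon_orgs[train_t], test_genes,
                        train_t, test_t, sub_seed, **fit_kwargs,
                    )
                )
    else:
        for test_t in names:
            sub_seed = int(rng.integers(2**31))
            train_orgs = [o for t in names if t != test_t for o in taxon_orgs[t]]
            test_genes = [g for o in taxon_orgs[test_t] for g in o.labeled_genes]
            results.append(
                _eval_pooled_train(
                    "leave_taxon_out", train_orgs, test_genes,
                    "+".join(o.organism for o in train_orgs), test_t, sub_seed,
                    **fit_kwargs,
                )
            )
    return results


# ---------------------------------------------------------------------------
# information-gain feature ranking


def _information_gain(x: np.ndarray, y: np.ndarray) -> float:
    """Label entropy minus conditional entropy at the best threshold on x (bits)."""

    def entropy(labels: np.ndarray) -> float:
        if len(labels) == 0:
            return 0.0
        p = np.bincount(labels, minlength=2) / len(labels)
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    base = entropy(y)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(xs)
    # candidate thresholds: midpoints between distinct consecutive values
    best_cond = base
    cum_pos = np.cumsum(ys)
    total_pos = cum_pos[-1]
    for i in range(n - 1):
        if xs[i + 1] == xs[i]:
            continue
        n_left = i + 1
        pos_left = cum_pos[i]
        n_right = n - n_left
        pos_right = total_pos - pos_left

        def h(pos: int, tot: int) -> float:
            if tot == 0 or pos == 0 or pos == tot:
                return 0.0
            p = pos / tot
            return -(p * np.log2(p) + (1 - p) * np.log2(1 - p))

        cond = (n_left / n) * h(int(pos_left), n_left) + (n_right / n) * h(
            int(pos_right), n_right
        )
        best_cond = min(best_cond, cond)
    return float(base - best_cond)


def rank_features(train: Sequence[FeatureVector]) -> FeatureRanking:
    """Rank all 91 features by information gain at the best single threshold."""
    y = _binary_labels(train)
    if len(set(y)) < 2:
        raise ValueError("both classes must be present to rank features")
    gains = []
    for name in FEATURE_NAMES:
        x = np.array([v.values[name] for v in train])
        gains.append((name, _information_gain(x, y)))
    gains.sort(key=lambda t: (-t[1], t[0]))
    return FeatureRanking(entries=tuple(gains))


def select_top_k(ranking: FeatureRanking, k: int) -> list[str]:
    """Names of the k highest-gain features."""
    if not (1 <= k <= len(ranking.entries)):
        raise ValueError(f"k must be in 1..{len(ranking.entries)}, got {k}")
    return [name for name, _ in ranking.entries[:k]]
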