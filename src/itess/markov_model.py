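"""Class-conditional Markov chains over gene sequences.

Two chains of order *m* are fitted — one on essential training genes
(MC+), one on non-essential training genes (MC−) — with Lidstone-smoothed
transition probabilities

.. math:: P_{v,a} = \\frac{N_x(va) + \\delta}{N_x(v) + 4\\delta},

where N_x(·) are word counts pooled over the training sequences (windows
never span sequence boundaries) and the pseudo-count δ (default 0.001)
keeps every probability positive. A gene is scored against a chain by the
cumulative weighted log-likelihood ratio of its transitions against the
marginal symbol distribution,

.. math:: \\mathrm{Score} = \\sum_{i=1}^{L-m} P(b_i\\ldots b_{i+m})\\,
    \\log_2 \\frac{P(b_{i+m}\\,|\\,b_i\\ldots b_{i+m-1})}{P(b_{i+m})},

with the unconditional word and symbol probabilities estimated from the
same training pool under the same Lidstone convention. The two scores
(on MC+ and MC−) are the gene's Markov features.

The chain order is fixed at m = 1 by default; an optional data-driven
order estimate is available via a permutation test on the conditional
mutual information between a symbol and its (m+1)-lagged predecessor
given the m intervening symbols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .sequence_io import count_kmers, sequence_to_indices

logger = logging.getLogger("itess.markov_model")

DEFAULT_DELTA = 0.001
DEFAULT_ORDER = 1


@dataclass
class MarkovChain:
    """Order-m Lidstone-smoothed chain with its empirical word distributions.

    Raw pooled counts are retained so that a training member's contribution
    can be subtracted exactly (the leakage guard in
    :func:`markov_feature_pair`) without refitting from scratch.
    """

    order_m: int
    delta: float
    word_counts: np.ndarray  # counts of (m+1)-words, length 4^(m+1)
    symbol_counts: np.ndarray  # counts of single bases, length 4
    class_tag: str = "positive"
    transitions: np.ndarray = field(init=False, repr=False)
    word_pmf: np.ndarray = field(init=False, repr=False)
    symbol_pmf: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.order_m < 0:
            raise ValueError("order_m must be >= 0")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.word_counts.shape != (4 ** (self.order_m + 1),):
            raise ValueError("word_counts has wrong length for the chain order")
        self._refresh()

    def _refresh(self) -> None:
        d = self.delta
        wc = self.word_counts.astype(float).reshape(-1, 4)  # rows = contexts v
        context_totals = wc.sum(axis=1, keepdims=True)
        self.transitions = (wc + d) / (context_totals + 4 * d)
        flat = self.word_counts.astype(float)
        self.word_pmf = (flat + d) / (flat.sum() + d * flat.size)
        sc = self.symbol_counts.astype(float)
        self.symbol_pmf = (sc + d) / (sc.sum() + d * 4)

    def without(self, seq: str) -> "MarkovChain":
        """A copy of this chain with one training sequence's counts removed."""
        wc = self.word_counts - count_kmers(seq, self.order_m + 1)
        sc = self.symbol_counts - count_kmers(seq, 1)
        if np.any(wc < 0) or np.any(sc < 0):
            raise ValueError("sequence was not part of this chain's training pool")
        return MarkovChain(
            order_m=self.order_m, delta=self.delta,
            word_counts=wc, symbol_counts=sc, class_tag=self.class_tag,
        )


def fit_markov(
    sequences: Iterable[str],
    m: int = DEFAULT_ORDER,
    delta: float = DEFAULT_DELTA,
    class_tag: str = "positive",
) -> MarkovChain:
    """Fit an order-m chain on a pool of sequences (Lidstone estimator).

    Counts are pooled over the sequences without cross-sequence windows.
    Sequences shorter than m+1 contribute no transition counts.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("cannot fit a Markov chain on an empty training pool")
    word_counts = np.zeros(4 ** (m + 1), dtype=np.int64)
    symbol_counts = np.zeros(4, dtype=np.int64)
    any_words = False
    for s in seqs:
        symbol_counts += count_kmers(s, 1)
        if len(s) >= m + 1:
            word_counts += count_kmers(s, m + 1)
            any_words = True
    if not any_words:
        raise ValueError(f"pooled sequences are all shorter than order+1 = {m + 1}")
    return MarkovChain(
        order_m=m, delta=delta,
        word_counts=word_counts, symbol_counts=symbol_counts, class_tag=class_tag,
    )


def score_sequence(chain: MarkovChain, seq: str) -> float:
    """Score a sequence against a fitted chain (bits).

    Positions holding the same (m+1)-word contribute identical summands, so
    the sum over positions collapses to a count-weighted sum over word types.
    """
    m = chain.order_m
    if len(seq) < m + 1:
        raise ValueError(f"sequence of length {len(seq)} shorter than order+1 = {m + 1}")
    counts = count_kmers(seq, m + 1).astype(float)
    # per-word summand: P(word) * log2( P(a|v) / P(a) ), word = va
    log_ratio = np.log2(chain.transitions.reshape(-1) / np.tile(chain.symbol_pmf, 4**m))
    return float((counts * chain.word_pmf * log_ratio).sum())


def markov_feature_pair(
    train_pos: Sequence[str],
    train_neg: Sequence[str],
    gene: str,
    m: int = DEFAULT_ORDER,
    delta: float = DEFAULT_DELTA,
    pos_chain: MarkovChain | None = None,
    neg_chain: MarkovChain | None = None,
) -> tuple[float, float]:
    """Score a gene on the essential (MC+) and non-essential (MC−) chains.

    If the gene is itself a member of a training pool, its counts are
    subtracted from that pool's chain before scoring (exactly equivalent to
    refitting without it), so a training gene never scores against a chain
    containing itself. Pre-fitted chains may be passed to avoid refitting
    per gene.
    """
    if pos_chain is None:
        pos_chain = fit_markov(train_pos, m, delta, class_tag="positive")
    if neg_chain is None:
        neg_chain = fit_markov(train_neg, m, delta, class_tag="negative")
    if gene in set(train_pos):
        pos_chain = pos_chain.without(gene)
    if gene in set(train_neg):
        neg_chain = neg_chain.without(gene)
    return score_sequence(pos_chain, gene), score_sequence(neg_chain, gene)


def _lagged_triples(sequences: Iterable[str], m: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(context, lag, current) code arrays for the order-(m+1) dependence test."""
    ctxs, lags, curs = [], [], []
    for s in sequences:
        codes = sequence_to_indices(s)
        L = len(codes)
        if L < m + 2:
            continue
        lag = codes[: L - m - 1]
        cur = codes[m + 1 :]
        ctx = np.zeros(L - m - 1, dtype=np.int64)
        for j in range(m):
            ctx = ctx * 4 + codes[1 + j : L - m + j]
        ctxs.append(ctx)
        lags.append(lag)
        curs.append(cur)
    if not ctxs:
        raise ValueError(f"pooled sequences too short for order test at m={m}")
    return np.concatenate(ctxs), np.concatenate(lags), np.concatenate(curs)


def _cmi_bits(ctx: np.ndarray, lag: np.ndarray, cur: np.ndarray, n_ctx: int) -> float:
    """I(lag; cur | ctx) in bits from code arrays."""
    n = len(ctx)
    joint = np.bincount(ctx * 16 + lag * 4 + cur, minlength=n_ctx * 16).astype(float)
    joint = joint.reshape(n_ctx, 4, 4) / n
    p_ctx = joint.sum(axis=(1, 2))
    p_cl = joint.sum(axis=2)
    p_cc = joint.sum(axis=1)
    mask = joint > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = p_ctx[:, None, None] * joint / (p_cl[:, :, None] * p_cc[:, None, :])
    return float((joint[mask] * np.log2(ratio[mask])).sum())


def estimate_order(
    sequences: Iterable[str],
    max_order: int,
    alpha: float = 0.05,
    n_permutations: int = 199,
    seed: int = 0,
) -> int:
    """Estimate the Markov order by successive permutation tests on CMI.

    For m = 0, 1, … the statistic I(X_t; X_{t−m−1} | X_{t−1..t−m}) is tested
    against a null built by permuting the lagged symbol within each context
    (which preserves all order-m structure). The smallest m whose test is
    non-significant at ``alpha`` is returned; ``max_order`` if all are
    significant.
    """
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    seqs = list(sequences)
    if not seqs:
        raise ValueError("empty sequence pool")
    rng = np.random.default_rng(seed)
    pooled = sum(len(s) for s in seqs)
    if pooled < 4 ** (max_order + 1):
        logger.warning(
            "pooled length %d < 4^(max_order+1) = %d; order estimate may be unstable",
            pooled, 4 ** (max_order + 1),
        )
    for m in range(max_order):
        ctx, lag, cur = _lagged_triples(seqs, m)
        n_ctx = 4**m
        observed = _cmi_bits(ctx, lag, cur, n_ctx)
        # permute lag within context groups to build the conditional null
        order = np.argsort(ctx, kind="stable")
        ctx_sorted, lag_sorted, cur_sorted = ctx[order], lag[order], cur[order]
        boundaries = np.flatnonzero(np.diff(ctx_sorted)) + 1
        groups = np.split(np.arange(len(ctx_sorted)), boundaries)
        exceed = 0
        for _ in range(n_permutations):
            perm_lag = lag_sorted.copy()
            for g in groups:
                perm_lag[g] = perm_lag[rng.permutation(g)]
            if _cmi_bits(ctx_sorted, perm_lag, cur_sorted, n_ctx) >= observed:
                exceed += 1
        p_value = (1 + exceed) / (n_permutations + 1)
        if p_value >= alpha:
            return m
    return max_order
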