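"""Independent brute-force oracles, written against the defining formulas.

These are deliberately naive dict-and-loop implementations, kept free of any
code from the package so they can serve as an independent second route for
the numerical tests.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

BASES = "ACGT"


def _window_counts(seq: str, k: int) -> Counter:
    return Counter(seq[i : i + k] for i in range(len(seq) - k + 1))


def mi_oracle(seq: str) -> tuple[float, dict[str, float]]:
    """Direct summation of pairwise MI: joint over overlapping pairs, marginals
    as row/column sums of the joint."""
    counts = _window_counts(seq, 2)
    total = sum(counts.values())
    joint = {p: c / total for p, c in counts.items()}
    px = {b: sum(v for p, v in joint.items() if p[0] == b) for b in BASES}
    py = {b: sum(v for p, v in joint.items() if p[1] == b) for b in BASES}
    terms = {}
    for x in BASES:
        for y in BASES:
            p = joint.get(x + y, 0.0)
            terms[x + y] = p * math.log2(p / (px[x] * py[y])) if p > 0 else 0.0
    return sum(terms.values()), terms


def cmi_oracle(seq: str) -> tuple[float, dict[str, float]]:
    """Direct summation of triplet CMI, term keys first+middle+last base."""
    counts = _window_counts(seq, 3)
    total = sum(counts.values())
    joint = {t: c / total for t, c in counts.items()}
    pz = {b: sum(v for t, v in joint.items() if t[1] == b) for b in BASES}
    pxz = {
        (x, z): sum(v for t, v in joint.items() if t[0] == x and t[1] == z)
        for x in BASES for z in BASES
    }
    pzy = {
        (z, y): sum(v for t, v in joint.items() if t[1] == z and t[2] == y)
        for z in BASES for y in BASES
    }
    terms = {}
    for x, z, y in itertools.product(BASES, repeat=3):
        trip = x + z + y
        p = joint.get(trip, 0.0)
        if p > 0:
            terms[trip] = p * math.log2(pz[z] * p / (pxz[(x, z)] * pzy[(z, y)]))
        else:
            terms[trip] = 0.0
    return sum(terms.values()), terms


def shannon_oracle(seq: str, N: int) -> float:
    counts = _window_counts(seq, N)
    total = sum(counts.values())
    return -sum((c / total) * math.log2(c / total) for c in counts.values())


def gibbs_oracle(seq: str, N: int, energies: dict[str, float],
                 temperature_K: float, kB: float = 1.38e-23) -> float:
    """Hand substitution of the Boltzmann-weighted entropy (energies kcal/mol)."""
    to_joules = 4184.0 / 6.02214076e23
    counts = _window_counts(seq, N)

    def energy(word: str) -> float:
        return sum(energies[word[i : i + 2]] for i in range(len(word) - 1)) * to_joules

    weights = {w: c * math.exp(-energy(w) / (kB * temperature_K)) for w, c in counts.items()}
    z = sum(weights.values())
    return -sum((v / z) * math.log(v / z) for v in weights.values() if v > 0)


def kld_oracle(seq: str, q: dict[str, float], k: int, eps: float = 1e-6) -> float:
    """Direct-summation KLD with the epsilon-floor-and-renormalize rule."""
    counts = _window_counts(seq, k)
    total = sum(counts.values())
    p = {w: c / total for w, c in counts.items()}
    kmers = ["".join(t) for t in itertools.product(BASES, repeat=k)]
    if any(p.get(w, 0) > 0 and q.get(w, 0.0) == 0 for w in kmers):
        q = {w: max(q.get(w, 0.0), eps) for w in kmers}
        z = sum(q.values())
        q = {w: v / z for w, v in q.items()}
    return sum(pv * math.log2(pv / q[w]) for w, pv in p.items() if pv > 0)


def background_oracle(genome: str, k: int) -> dict[str, float]:
    counts = _window_counts(genome, k)
    counts = Counter({w: c for w, c in counts.items() if set(w) <= set(BASES)})
    total = sum(counts.values())
    return {w: c / total for w, c in counts.items()}


def auc_oracle(scores, labels) -> float:
    """All-pairs concordance count; ties contribute 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def info_gain_oracle(x, y) -> float:
    """Exhaustive enumeration of every threshold between consecutive values."""

    def entropy(labels) -> float:
        n = len(labels)
        if n == 0:
            return 0.0
        out = 0.0
        for c in Counter(labels).values():
            out -= (c / n) * math.log2(c / n)
        return out

    base = entropy(y)
    pairs = sorted(zip(x, y))
    xs = sorted(set(x))
    best = base
    for lo, hi in zip(xs, xs[1:]):
        thr = (lo + hi) / 2
        left = [yy for xx, yy in pairs if xx <= thr]
        right = [yy for xx, yy in pairs if xx > thr]
        cond = (len(left) / len(y)) * entropy(left) + (len(right) / len(y)) * entropy(right)
        best = min(best, cond)
    return base - best
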