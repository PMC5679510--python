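"""Information-theoretic features of a single gene sequence.

Four feature families are computed from a gene's nucleotide sequence alone:

* **Mutual information (MI).** The MI between consecutive bases,

  .. math:: I(X,Y) = \\sum_{x,y \\in \\Omega} P(x,y)\\,
      \\log_2 \\frac{P(x,y)}{P(x)P(y)},

  estimated from the relative frequencies of all overlapping base pairs.
  Besides the total, each of the 16 per-pair summands is a feature (17 total).

* **Conditional mutual information (CMI).** For overlapping triplets, with
  the first, middle and last bases as X, Z and Y,

  .. math:: I(X;Y|Z) = \\sum_{x,z,y} P(x,z,y)\\,
      \\log_2 \\frac{P(z)\\,P(x,z,y)}{P(x,z)\\,P(z,y)},

  giving the total plus 64 per-triplet summands (65 total).

* **Entropy.** Shannon block entropies H_N for N = 2, 3 over overlapping
  N-mers, and Gibbs entropies for the same block sizes where the state
  probability is Boltzmann-weighted by nearest-neighbor dinucleotide free
  energies: P_G(i) ∝ n_i · exp(−E(i)/k_B T). Triplet energies are the sum of
  the two constituent dinucleotide energies. Gibbs entropies are reported in
  units of k_B (the physical constant is divided out so features are O(1);
  multiplying by k_B recovers J/K).

* **Kullback-Leibler divergence (KLD).** For k = 1, 2, 3, the divergence of
  the gene's overlapping k-mer distribution from the training organism's
  background distribution, in bits.

All probability estimates are plug-in relative frequencies; marginals are
always derived from the corresponding joint, which makes MI and CMI totals
nonnegative by construction. The convention 0·log(0/q) = 0 applies
throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .sequence_io import (
    ALPHABET,
    BackgroundDistribution,
    count_kmers,
    kmer_strings,
)

logger = logging.getLogger("itess.info_features")

#: Boltzmann constant, J/K.
BOLTZMANN_KB = 1.38e-23
#: Default temperature (37 °C), Kelvin.
DEFAULT_TEMPERATURE_K = 310.15
#: kcal/mol → J/molecule.
_KCAL_PER_MOL_TO_J = 4184.0 / 6.02214076e23
#: Floor applied to zero background-probability cells in the KLD (then renormalized).
KLD_EPSILON = 1e-6

_DINUCLEOTIDES = kmer_strings(2)
_TRINUCLEOTIDES = kmer_strings(3)


@dataclass(frozen=True)
class EnergyTable:
    """Nearest-neighbor dinucleotide free energies driving the Gibbs entropy.

    ``energies`` maps each of the 16 dinucleotides to a stacking free energy
    in kcal/mol (more negative = more stable). The bundled default is the
    unified nearest-neighbor set of SantaLucia (1998), ΔG°37.
    """

    energies: dict[str, float]
    temperature_K: float = DEFAULT_TEMPERATURE_K
    boltzmann_kB: float = BOLTZMANN_KB

    def __post_init__(self) -> None:
        missing = set(_DINUCLEOTIDES) - set(self.energies)
        if missing:
            raise ValueError(f"energy table missing dinucleotides: {sorted(missing)}")
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be positive")

    def energy_joules(self, word: str) -> float:
        """Energy of an N-mer in J/molecule: the sum of its overlapping dinucleotides."""
        total = 0.0
        for i in range(len(word) - 1):
            total += self.energies[word[i : i + 2]]
        return total * _KCAL_PER_MOL_TO_J


def load_energy_table(
    path: str | Path,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> EnergyTable:
    """Load a 16-line ``dinucleotide<TAB>energy_kcal_per_mol`` TSV."""
    energies: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            dinuc, value = line.split("\t")
            energies[dinuc] = float(value)
    return EnergyTable(energies=energies, temperature_K=temperature_K)


def default_energy_table(temperature_K: float = DEFAULT_TEMPERATURE_K) -> EnergyTable:
    """The bundled SantaLucia (1998) unified ΔG°37 table."""
    ref = resources.files("itess.data").joinpath("nn_free_energy.tsv")
    with resources.as_file(ref) as path:
        return load_energy_table(path, temperature_K=temperature_K)


@dataclass(frozen=True)
class PairTermSet:
    """Total pairwise MI plus its 16 per-pair summands, in bits."""

    total: float
    terms: dict[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.terms) != 16:
            raise ValueError(f"expected 16 pair terms, got {len(self.terms)}")
        if abs(self.total - sum(self.terms.values())) > 1e-9:
            raise ValueError("pair terms do not sum to the total")


@dataclass(frozen=True)
class TripletTermSet:
    """Total CMI plus its 64 per-triplet summands, in bits.

    Term keys are the triplets as they appear in the sequence
    (first base, middle base, last base).
    """

    total: float
    terms: dict[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.terms) != 64:
            raise ValueError(f"expected 64 triplet terms, got {len(self.terms)}")
        if abs(self.total - sum(self.terms.values())) > 1e-9:
            raise ValueError("triplet terms do not sum to the total")


def _pair_joint(seq: str) -> np.ndarray:
    counts = count_kmers(seq, 2).astype(float).reshape(4, 4)
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence has no valid base pairs")
    return counts / total


def mi_features(seq: str) -> PairTermSet:
    """Mutual information between consecutive bases and its 16 summands.

    The joint pmf P(x,y) is estimated from all overlapping consecutive pairs;
    the marginals P(x), P(y) are its row and column sums, so every occupied
    cell has a positive marginal product and the total is nonnegative.
    """
    if len(seq) < 2:
        raise ValueError("mi_features requires a sequence of length >= 2")
    joint = _pair_joint(seq)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    terms: dict[str, float] = {}
    for i, x in enumerate(ALPHABET):
        for j, y in enumerate(ALPHABET):
            p = joint[i, j]
            terms[x + y] = float(p * math.log2(p / (px[i] * py[j]))) if p > 0 else 0.0
    return PairTermSet(total=sum(terms.values()), terms=terms)


def cmi_features(seq: str) -> TripletTermSet:
    """CMI between the first and last base of a triplet given the middle base.

    The triplet joint P(x,z,y) is estimated from all overlapping triplets; all
    lower-order pmfs (P(z), P(x,z), P(z,y)) are its marginals.
    """
    if len(seq) < 3:
        raise ValueError("cmi_features requires a sequence of length >= 3")
    counts = count_kmers(seq, 3).astype(float).reshape(4, 4, 4)  # [x, z, y]
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence has no valid triplets")
    joint = counts / total
    pz = joint.sum(axis=(0, 2))
    pxz = joint.sum(axis=2)
    pzy = joint.sum(axis=0)
    terms: dict[str, float] = {}
    for i, x in enumerate(ALPHABET):
        for j, z in enumerate(ALPHABET):
            for k, y in enumerate(ALPHABET):
                p = joint[i, j, k]
                if p > 0:
                    val = float(p * math.log2(pz[j] * p / (pxz[i, j] * pzy[j, k])))
                else:
                    val = 0.0
                terms[x + z + y] = val
    return TripletTermSet(total=sum(terms.values()), terms=terms)


def shannon_entropy(seq: str, N: int) -> float:
    """Shannon block entropy H_N (bits) over overlapping N-mers, N in {2, 3}."""
    if N not in (2, 3):
        raise ValueError(f"block size must be 2 or 3, got {N}")
    if len(seq) < N:
        raise ValueError(f"sequence shorter than block size {N}")
    counts = count_kmers(seq, N).astype(float)
    p = counts / counts.sum()
    occupied = p > 0
    return float(-(p[occupied] * np.log2(p[occupied])).sum())


def gibbs_entropy(seq: str, N: int, table: EnergyTable | None = None) -> float:
    """Gibbs entropy (units of k_B) with Boltzmann-weighted state probabilities.

    States are the overlapping N-mers of the sequence. The probability of
    state i is P_G(i) = n_i·exp(−E(i)/k_B T) / Σ_j n_j·exp(−E(j)/k_B T) with
    n_i the N-mer count and E(i) its nearest-neighbor free energy (for N = 3,
    the sum of the two constituent dinucleotide energies). Returns
    −Σ P_G ln P_G; multiplying by k_B recovers the physical entropy in J/K.
    """
    if table is None:
        table = default_energy_table()
    if N not in (2, 3):
        raise ValueError(f"block size must be 2 or 3, got {N}")
    if len(seq) < N:
        raise ValueError(f"sequence shorter than block size {N}")
    counts = count_kmers(seq, N).astype(float)
    words = _DINUCLEOTIDES if N == 2 else _TRINUCLEOTIDES
    kBT = table.boltzmann_kB * table.temperature_K
    occupied = counts > 0
    # subtract the max exponent before exponentiating for numerical stability
    exponents = np.array(
        [-table.energy_joules(w) / kBT if occ else -np.inf for w, occ in zip(words, occupied)]
    )
    exponents -= exponents[occupied].max()
    weights = counts * np.exp(exponents, where=np.isfinite(exponents), out=np.zeros_like(counts))
    p = weights / weights.sum()
    occ = p > 0
    return float(-(p[occ] * np.log(p[occ])).sum())


def kld_features(
    seq: str,
    background: BackgroundDistribution,
    epsilon: float = KLD_EPSILON,
) -> tuple[float, float, float]:
    """KLD (bits) of the gene's k-mer pmfs from the background, k = 1, 2, 3.

    Zero-probability gene cells contribute 0. If the background assigns zero
    mass to a k-mer the gene contains, the background is floored at
    ``epsilon`` and renormalized (logged), keeping the divergence finite.
    """
    if len(seq) < 3:
        raise ValueError("kld_features requires a sequence of length >= 3")
    values = []
    for k in (1, 2, 3):
        if k not in background.pmf_k:
            raise ValueError(f"background distribution missing k={k}")
        counts = count_kmers(seq, k).astype(float)
        p = counts / counts.sum()
        q = background.pmf_k[k]
        if np.any((p > 0) & (q == 0)):
            logger.warning(
                "background for %s has zero mass on observed %d-mers; flooring at %g",
                background.organism, k, epsilon,
            )
            q = np.maximum(q, epsilon)
            q = q / q.sum()
        occupied = p > 0
        values.append(float((p[occupied] * np.log2(p[occupied] / q[occupied])).sum()))
    return tuple(values)  # type: ignore[return-value]
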