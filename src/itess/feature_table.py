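"""Assembly of the 91-feature vector per gene and feature-matrix I/O.

The canonical feature order is frozen so models and matrices are
interchangeable across runs: MI_total, the 16 per-pair MI terms
(lexicographic), CMI_total, the 64 per-triplet CMI terms (lexicographic),
the four entropies H2/H3/G2/G3, the three divergences KLD1/KLD2/KLD3, and
the two Markov scores MSCORE_POS/MSCORE_NEG — 91 features in total
(17 MI + 65 CMI + 4 entropy + 3 KLD + 2 Markov).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import info_features
from .info_features import EnergyTable
from .markov_model import MarkovChain, score_sequence
from .sequence_io import (
    BackgroundDistribution,
    EmptyDatasetError,
    FormatError,
    GeneRecord,
    LABEL_UNKNOWN,
    OrganismDataset,
    kmer_strings,
)

logger = logging.getLogger("itess.feature_table")

FEATURE_NAMES: tuple[str, ...] = (
    ("MI_total",)
    + tuple(f"MI_{p}" for p in kmer_strings(2))
    + ("CMI_total",)
    + tuple(f"CMI_{t}" for t in kmer_strings(3))
    + ("H2", "H3", "G2", "G3")
    + ("KLD1", "KLD2", "KLD3")
    + ("MSCORE_POS", "MSCORE_NEG")
)
assert len(FEATURE_NAMES) == 91

_META_COLUMNS = ("gene_id", "organism", "label")


@dataclass(frozen=True)
class FeatureVector:
    """The ordered 91 named features of one gene, plus its identity and label."""

    gene_id: str
    organism: str
    values: dict[str, float]
    label: str = LABEL_UNKNOWN

    def __post_init__(self) -> None:
        if tuple(self.values) != FEATURE_NAMES:
            raise ValueError(
                f"{self.gene_id}: feature names/order do not match the canonical 91"
            )
        for name, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"{self.gene_id}: non-finite value for {name}")


def compute_feature_vector(
    gene: GeneRecord,
    background: BackgroundDistribution,
    pos_chain: MarkovChain,
    neg_chain: MarkovChain,
    table: EnergyTable | None = None,
) -> FeatureVector:
    """All 91 features for one gene against fixed chains/background/energies."""
    seq = gene.sequence
    mi = info_features.mi_features(seq)
    cmi = info_features.cmi_features(seq)
    kld1, kld2, kld3 = info_features.kld_features(seq, background)
    values: dict[str, float] = {"MI_total": mi.total}
    for p in kmer_strings(2):
        values[f"MI_{p}"] = mi.terms[p]
    values["CMI_total"] = cmi.total
    for t in kmer_strings(3):
        values[f"CMI_{t}"] = cmi.terms[t]
    values["H2"] = info_features.shannon_entropy(seq, 2)
    values["H3"] = info_features.shannon_entropy(seq, 3)
    values["G2"] = info_features.gibbs_entropy(seq, 2, table)
    values["G3"] = info_features.gibbs_entropy(seq, 3, table)
    values["KLD1"] = kld1
    values["KLD2"] = kld2
    values["KLD3"] = kld3
    values["MSCORE_POS"] = score_sequence(pos_chain, seq)
    values["MSCORE_NEG"] = score_sequence(neg_chain, seq)
    return FeatureVector(
        gene_id=gene.gene_id, organism=gene.organism, values=values, label=gene.label
    )


def extract_features(
    dataset: OrganismDataset | Iterable[GeneRecord],
    background: BackgroundDistribution,
    pos_chain: MarkovChain,
    neg_chain: MarkovChain,
    table: EnergyTable | None = None,
    train_pos: Sequence[str] | None = None,
    train_neg: Sequence[str] | None = None,
) -> list[FeatureVector]:
    """One FeatureVector per gene; genes failing a precondition are dropped.

    When ``train_pos``/``train_neg`` (the chains' training pools) are given,
    a gene found in its own class's pool is scored against the chain with its
    counts subtracted — the Markov leakage guard for training-set members.
    """
    genes = dataset.genes if isinstance(dataset, OrganismDataset) else list(dataset)
    pos_pool = set(train_pos) if train_pos is not None else set()
    neg_pool = set(train_neg) if train_neg is not None else set()
    vectors: list[FeatureVector] = []
    for gene in genes:
        pc = pos_chain.without(gene.sequence) if gene.sequence in pos_pool else pos_chain
        nc = neg_chain.without(gene.sequence) if gene.sequence in neg_pool else neg_chain
        try:
            vectors.append(compute_feature_vector(gene, background, pc, nc, table))
        except ValueError as exc:
            logger.warning("dropping gene %s: %s", gene.gene_id, exc)
    if not vectors:
        raise EmptyDatasetError("no gene produced a feature vector")
    return vectors


def vectors_to_frame(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Feature vectors as a DataFrame: gene_id, organism, label + 91 columns."""
    if not vectors:
        raise EmptyDatasetError("empty feature-vector collection")
    rows = [
        {"gene_id": v.gene_id, "organism": v.organism, "label": v.label, **v.values}
        for v in vectors
    ]
    return pd.DataFrame(rows, columns=list(_META_COLUMNS) + list(FEATURE_NAMES))


def frame_to_vectors(frame: pd.DataFrame) -> list[FeatureVector]:
    expected = list(_META_COLUMNS) + list(FEATURE_NAMES)
    for col in expected:
        if col not in frame.columns:
            raise FormatError(f"feature matrix missing column {col!r}")
    extra = [c for c in frame.columns if c not in expected]
    if extra:
        raise FormatError(f"feature matrix has unexpected column {extra[0]!r}")
    return [
        FeatureVector(
            gene_id=str(row["gene_id"]),
            organism=str(row["organism"]),
            values={name: float(row[name]) for name in FEATURE_NAMES},
            label=str(row["label"]),
        )
        for _, row in frame.iterrows()
    ]


def write_feature_matrix(vectors: Sequence[FeatureVector], path: str | Path) -> None:
    """Write vectors as CSV (header: gene_id, organism, label, 91 names)."""
    frame = vectors_to_frame(vectors)  # raises before touching the file if empty
    frame.to_csv(path, index=False)


def read_feature_matrix(path: str | Path) -> list[FeatureVector]:
    """Read a CSV written by :func:`write_feature_matrix` (validates the header)."""
    return frame_to_vectors(pd.read_csv(path))
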