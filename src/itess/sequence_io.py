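"""Gene FASTA / label-table ingestion and background k-mer distributions.

Input conventions
-----------------
Gene sequences are coding-strand nucleotide sequences supplied as multi-FASTA
(one record per gene, gene ID = first whitespace-delimited header token).
Essentiality labels come as a headerless two-column TSV ``gene_id<TAB>label``
with label values ``E`` (essential) or ``NE`` (non-essential). Background
k-mer distributions for the Kullback-Leibler features are computed from the
organism's genome FASTA when available, otherwise from the concatenated
training gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("itess.sequence_io")

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

#: Maximum fraction of non-ACGT characters a raw sequence may lose in cleaning.
MAX_STRIP_FRACTION = 0.10
#: Minimum cleaned sequence length.
MIN_GENE_LENGTH = 3

LABEL_ESSENTIAL = "essential"
LABEL_NON_ESSENTIAL = "non_essential"
LABEL_UNKNOWN = "unknown"

_LABEL_CODES = {"E": LABEL_ESSENTIAL, "NE": LABEL_NON_ESSENTIAL}


class FormatError(ValueError):
    """Malformed input file (bad label value, duplicate ID, header mismatch)."""


class EmptyDatasetError(ValueError):
    """No usable records survive ingestion or filtering."""


class SequenceRejected(ValueError):
    """A raw sequence failed cleaning; ``reason`` says why."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class GeneRecord:
    """One gene: an ID, its coding-strand DNA sequence, and an essentiality label."""

    gene_id: str
    organism: str
    sequence: str
    label: str = LABEL_UNKNOWN

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if len(self.sequence) < MIN_GENE_LENGTH:
            raise ValueError(f"{self.gene_id}: sequence shorter than {MIN_GENE_LENGTH}")
        if set(self.sequence) - set(ALPHABET):
            raise ValueError(f"{self.gene_id}: sequence contains non-ACGT symbols")
        if self.label not in (LABEL_ESSENTIAL, LABEL_NON_ESSENTIAL, LABEL_UNKNOWN):
            raise ValueError(f"{self.gene_id}: bad label {self.label!r}")


@dataclass
class OrganismDataset:
    """An organism's gene set, with label bookkeeping and an optional genome."""

    organism: str
    genes: list[GeneRecord] = field(default_factory=list)
    genome: str | None = None

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise FormatError(f"duplicate gene_id {dup!r} in organism {self.organism!r}")

    @property
    def n_essential(self) -> int:
        return sum(g.label == LABEL_ESSENTIAL for g in self.genes)

    @property
    def n_non_essential(self) -> int:
        return sum(g.label == LABEL_NON_ESSENTIAL for g in self.genes)

    @property
    def labeled_genes(self) -> list[GeneRecord]:
        """Genes with a known label — the only ones used for training/testing."""
        return [g for g in self.genes if g.label != LABEL_UNKNOWN]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class BackgroundDistribution:
    """Per-k pmfs over the 4^k k-mers of a training organism (k = 1, 2, 3)."""

    organism: str
    pmf_k: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        for k, pmf in self.pmf_k.items():
            if pmf.shape != (4**k,):
                raise ValueError(f"k={k}: pmf has shape {pmf.shape}, expected ({4**k},)")
            if np.any(pmf < 0) or abs(pmf.sum() - 1.0) > 1e-12:
                raise ValueError(f"k={k}: background pmf is not a probability vector")


def kmer_strings(k: int) -> list[str]:
    """All 4^k k-mers in lexicographic order (A < C < G < T)."""
    return ["".join(p) for p in product(ALPHABET, repeat=k)]


def sequence_to_indices(seq: str) -> np.ndarray:
    """Map an ACGT string to integer codes 0..3; non-ACGT becomes -1."""
    table = np.full(256, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        table[ord(base)] = idx
        table[ord(base.lower())] = idx
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def count_kmers(seq: str, k: int) -> np.ndarray:
    """Overlapping (step-1) k-mer counts; windows containing non-ACGT are skipped."""
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} shorter than k={k}")
    codes = sequence_to_indices(seq)
    idx = np.zeros(len(codes) - k + 1, dtype=np.int64)
    valid = np.ones(len(idx), dtype=bool)
    for j in range(k):
        part = codes[j : j + len(idx)]
        valid &= part >= 0
        idx = idx * 4 + part
    return np.bincount(idx[valid], minlength=4**k)


def clean_sequence(raw: str) -> str:
    """Uppercase and strip non-ACGT symbols from a raw nucleotide string.

    Raises :class:`SequenceRejected` if more than 10% of characters had to be
    stripped or if fewer than 3 bases remain — genes that degraded are dropped
    rather than silently truncated.
    """
    upper = raw.upper()
    kept = "".join(c for c in upper if c in _BASE_INDEX)
    if not upper:
        raise SequenceRejected("empty sequence")
    stripped_frac = 1.0 - len(kept) / len(upper)
    if stripped_frac > MAX_STRIP_FRACTION:
        raise SequenceRejected(
            f"{stripped_frac:.1%} of characters are non-ACGT (limit {MAX_STRIP_FRACTION:.0%})"
        )
    if len(kept) < MIN_GENE_LENGTH:
        raise SequenceRejected(f"cleaned length {len(kept)} < {MIN_GENE_LENGTH}")
    return kept


def read_gene_fasta(path: str | Path, organism: str) -> OrganismDataset:
    """Read a multi-FASTA of gene sequences into an unlabeled dataset.

    Records whose sequences fail :func:`clean_sequence` are dropped and logged
    with the rejection reason. Duplicate gene IDs are an error.
    """
    path = Path(path)
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        if gene_id in seen:
            raise FormatError(f"duplicate gene_id {gene_id!r} in {path}")
        seen.add(gene_id)
        try:
            seq = clean_sequence(str(rec.seq))
        except SequenceRejected as exc:
            logger.warning("dropping %s: %s", gene_id, exc.reason)
            continue
        genes.append(GeneRecord(gene_id=gene_id, organism=organism, sequence=seq))
    if not genes:
        raise EmptyDatasetError(f"no usable records in {path}")
    return OrganismDataset(organism=organism, genes=genes)


def write_gene_fasta(dataset: OrganismDataset, path: str | Path) -> None:
    """Write a dataset back to multi-FASTA (inverse of :func:`read_gene_fasta`)."""
    records = [
        SeqRecord(Seq(g.sequence), id=g.gene_id, description="") for g in dataset.genes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_label_table(path: str | Path) -> dict[str, str]:
    """Read the two-column headerless TSV ``gene_id<TAB>{E,NE}``."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            gene_id, code = parts
            if code not in _LABEL_CODES:
                raise FormatError(
                    f"{path}:{lineno}: label {code!r} not in {sorted(_LABEL_CODES)}"
                )
            labels[gene_id] = _LABEL_CODES[code]
    return labels


def attach_labels(dataset: OrganismDataset, labels: Mapping[str, str]) -> OrganismDataset:
    """Attach essentiality labels to matching genes; unmatched IDs are logged.

    ``labels`` maps gene_id to ``essential``/``non_essential`` (as produced by
    :func:`read_label_table`). Genes without a label stay ``unknown`` and are
    excluded from training and testing downstream.
    """
    for value in labels.values():
        if value not in (LABEL_ESSENTIAL, LABEL_NON_ESSENTIAL):
            raise FormatError(f"label value {value!r} is not essential/non_essential")
    gene_ids = {g.gene_id for g in dataset.genes}
    labeled = []
    for g in dataset.genes:
        if g.gene_id in labels:
            labeled.append(replace(g, label=labels[g.gene_id]))
        else:
            logger.info("gene %s has no label entry; left unknown", g.gene_id)
            labeled.append(g)
    for gene_id in labels:
        if gene_id not in gene_ids:
            logger.info("label entry %s matches no gene; ignored", gene_id)
    return OrganismDataset(organism=dataset.organism, genes=labeled, genome=dataset.genome)


def save_dataset_json(dataset: OrganismDataset, path: str | Path) -> None:
    """Serialize a dataset (genes, labels, optional genome) to JSON."""
    import json

    payload = {
        "organism": dataset.organism,
        "genes": [
            {"gene_id": g.gene_id, "sequence": g.sequence, "label": g.label}
            for g in dataset.genes
        ],
        "genome": dataset.genome,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_dataset_json(path: str | Path) -> OrganismDataset:
    """Inverse of :func:`save_dataset_json`."""
    import json

    with open(path) as fh:
        payload = json.load(fh)
    genes = [
        GeneRecord(
            gene_id=g["gene_id"],
            organism=payload["organism"],
            sequence=g["sequence"],
            label=g.get("label", LABEL_UNKNOWN),
        )
        for g in payload["genes"]
    ]
    return OrganismDataset(
        organism=payload["organism"], genes=genes, genome=payload.get("genome")
    )


def compute_background(genome: str, k: int) -> np.ndarray:
    """Pmf over the 4^k k-mers of ``genome`` from overlapping window counts."""
    if k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    if len(genome) < k:
        raise ValueError(f"genome of length {len(genome)} shorter than k={k}")
    counts = count_kmers(genome, k)
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid k-mer windows in genome")
    return counts / total


def build_background(
    organism: str,
    genome: str | None = None,
    sequences: Iterable[str] | None = None,
) -> BackgroundDistribution:
    """Background distributions for k = 1, 2, 3 from a genome or a gene pool.

    The genome is used when provided; otherwise counts are pooled over the
    given sequences without crossing sequence boundaries. The active choice is
    logged so runs are auditable.
    """
    pmf_k: dict[int, np.ndarray] = {}
    if genome is not None:
        logger.info("background for %s computed from genome (%d nt)", organism, len(genome))
        for k in (1, 2, 3):
            pmf_k[k] = compute_background(genome, k)
    elif sequences is not None:
        seqs = list(sequences)
        if not seqs:
            raise EmptyDatasetError("no sequences provided for background")
        logger.info(
            "background for %s computed from %d pooled gene sequences", organism, len(seqs)
        )
        for k in (1, 2, 3):
            counts = np.zeros(4**k, dtype=np.int64)
            for s in seqs:
                if len(s) >= k:
                    counts += count_kmers(s, k)
            total = counts.sum()
            if total == 0:
                raise ValueError(f"no valid {k}-mer windows in gene pool")
            pmf_k[k] = counts / total
    else:
        raise ValueError("either genome or sequences must be provided")
    return BackgroundDistribution(organism=organism, pmf_k=pmf_k)
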