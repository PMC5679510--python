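"""Seeded synthetic organisms from class-conditional Markov sources.

The premise under test is that essential and non-essential genes are
generated by two different order-1 Markov sources. This module makes that
premise literal: it samples an organism's essential genes from a positive
source, its non-essential genes from a negative source obtained by linearly
mixing the positive transition matrix toward a distinct alternative matrix
(``divergence`` 0 = identical sources, 1 = fully distinct), and a genome
from the 50/50 average of the two class matrices. Every pipeline stage can
then be exercised end-to-end without any downloads, and the expected
outcome is known by construction: AUC near 0.5 at divergence 0, rising with
divergence.

Three frozen presets (``separable``, ``weak``, ``null``) share one matrix
pair, shipped as a data file, and differ only in divergence (1.0 / 0.3 / 0.0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .sequence_io import (
    ALPHABET,
    GeneRecord,
    LABEL_ESSENTIAL,
    LABEL_NON_ESSENTIAL,
    OrganismDataset,
    write_gene_fasta,
)

PRESET_NAMES = ("separable", "weak", "null")


@dataclass(frozen=True)
class SourceSpec:
    """An order-1 Markov source: transition matrix, start distribution, lengths."""

    transition_matrix: np.ndarray  # 4x4 row-stochastic
    initial_dist: np.ndarray  # pmf over ACGT
    length_dist: tuple[int, int]  # uniform integer bounds, nt

    def __post_init__(self) -> None:
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (4, 4) or np.any(tm < 0):
            raise ValueError("transition_matrix must be a nonnegative 4x4 matrix")
        if np.any(np.abs(tm.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition_matrix rows must sum to 1")
        init = np.asarray(self.initial_dist, dtype=float)
        if init.shape != (4,) or np.any(init < 0) or abs(init.sum() - 1.0) > 1e-12:
            raise ValueError("initial_dist must be a pmf over the 4 bases")
        lo, hi = self.length_dist
        if lo < 30 or hi < lo:
            raise ValueError("length bounds must satisfy 30 <= min <= max")
        object.__setattr__(self, "transition_matrix", tm)
        object.__setattr__(self, "initial_dist", init)


@dataclass(frozen=True)
class SynthConfig:
    """Full recipe for one synthetic organism; the seed fixes everything."""

    n_essential: int
    n_non_essential: int
    pos_source: SourceSpec
    neg_source: SourceSpec
    divergence: float
    genome_length: int
    seed: int
    organism: str = "SYN"

    def __post_init__(self) -> None:
        if self.n_essential < 5 or self.n_non_essential < 5:
            raise ValueError("class counts must be >= 5")
        if not (0.0 <= self.divergence <= 1.0):
            raise ValueError("divergence must lie in [0, 1]")
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")


def _sample_chain(
    rng: np.random.Generator,
    matrix: np.ndarray,
    initial: np.ndarray,
    length: int,
) -> str:
    cum = np.cumsum(matrix, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    out[0] = int(np.searchsorted(np.cumsum(initial), u[0], side="right"))
    state = out[0]
    for i in range(1, length):
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        out[i] = state
    return "".join(ALPHABET[i] for i in out)


def mixed_negative_matrix(config: SynthConfig) -> np.ndarray:
    """The non-essential source matrix: (1−d)·pos + d·alt."""
    d = config.divergence
    return (1 - d) * config.pos_source.transition_matrix + d * config.neg_source.transition_matrix


def generate_organism(config: SynthConfig) -> tuple[OrganismDataset, str]:
    """Sample a labeled organism and its genome, fully determined by the seed."""
    rng = np.random.default_rng(config.seed)
    neg_matrix = mixed_negative_matrix(config)
    genes: list[GeneRecord] = []
    for cls, n, source_matrix, spec in (
        (LABEL_ESSENTIAL, config.n_essential, config.pos_source.transition_matrix,
         config.pos_source),
        (LABEL_NON_ESSENTIAL, config.n_non_essential, neg_matrix, config.neg_source),
    ):
        lo, hi = spec.length_dist
        tag = "E" if cls == LABEL_ESSENTIAL else "NE"
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            seq = _sample_chain(rng, source_matrix, spec.initial_dist, length)
            genes.append(
                GeneRecord(
                    gene_id=f"{config.organism}_{tag}{i:04d}",
                    organism=config.organism,
                    sequence=seq,
                    label=cls,
                )
            )
    genome_matrix = 0.5 * config.pos_source.transition_matrix + 0.5 * neg_matrix
    genome = _sample_chain(
        rng, genome_matrix, config.pos_source.initial_dist, config.genome_length
    )
    dataset = OrganismDataset(organism=config.organism, genes=genes, genome=genome)
    return dataset, genome


def _load_preset_data() -> dict:
    ref = resources.files("itess.data").joinpath("presets.json")
    return json.loads(ref.read_text())


def preset(name: str, seed: int = 0, organism: str | None = None) -> SynthConfig:
    """One of the frozen configurations ``separable``, ``weak`` or ``null``."""
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; valid presets: {PRESET_NAMES}")
    data = _load_preset_data()
    lengths = tuple(data["length_range"])
    pos = SourceSpec(
        transition_matrix=np.array(data["pos_matrix"]),
        initial_dist=np.array(data["initial_dist"]),
        length_dist=lengths,
    )
    alt = SourceSpec(
        transition_matrix=np.array(data["alt_matrix"]),
        initial_dist=np.array(data["initial_dist"]),
        length_dist=lengths,
    )
    return SynthConfig(
        n_essential=data["n_essential"],
        n_non_essential=data["n_non_essential"],
        pos_source=pos,
        neg_source=alt,
        divergence=data["divergence"][name],
        genome_length=data["genome_length"],
        seed=seed,
        organism=organism or f"SYN_{name}",
    )


def write_synthetic_organism(
    dataset: OrganismDataset, genome: str, outdir: str | Path
) -> dict[str, Path]:
    """Emit genes.fasta, labels.tsv and genome.fasta in the formats ingestion reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "genes.fasta",
        "labels": outdir / "labels.tsv",
        "genome": outdir / "genome.fasta",
    }
    write_gene_fasta(dataset, paths["genes"])
    with open(paths["labels"], "w") as fh:
        for g in dataset.genes:
            if g.label in (LABEL_ESSENTIAL, LABEL_NON_ESSENTIAL):
                code = "E" if g.label == LABEL_ESSENTIAL else "NE"
                fh.write(f"{g.gene_id}\t{code}\n")
    with open(paths["genome"], "w") as fh:
        fh.write(f">{dataset.organism}_genome\n")
        for i in range(0, len(genome), 70):
            fh.write(genome[i : i + 70] + "\n")
    return paths
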