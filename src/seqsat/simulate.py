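"""Synthetic transcriptome and read-set simulation.

Generates an annotated transcriptome — gene identifiers, random
nucleotide sequences, exon-union lengths and true relative abundances —
and simulates single-end read sets from it with the statistical
structure the saturation analysis assumes: a heavy-tailed (log-normal)
abundance profile spanning all four expression quartiles, a configurable
fraction of silent genes so that even exhaustive sequencing detects well
under 100% of the annotation, and occasional defective reads (interspersed
Ns, sub-17 bp fragments) to exercise the pre-mapping filters.

Reads are drawn gene-first with probability proportional to
``true_abundance * (length - read_length + 1)`` — the number of distinct
fragment start positions — so that estimated RPKM is asymptotically
proportional to true molarity. Each read id carries a provenance tag
(``read0000042|gene00007``) naming its source gene, used only by the
oracle assigner in tests.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .io import PROVENANCE_DELIMITER, ReadSet, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASES_N = np.frombuffer(b"ACGTN", dtype=np.uint8)

#: placeholder Phred+33 quality character (Q40)
QUALITY_CHAR = "I"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic transcriptome and read simulator.

    Parameters
    ----------
    n_genes
        Number of annotated genes in the synthetic universe.
    silent_fraction
        Fraction of genes with true abundance exactly zero (never
        transcribed in this tissue), so full-depth detection saturates
        below 100%.
    abundance_sigma
        Scale of the log-normal molarity distribution over expressed
        genes; ~1.8 gives the heavy-tailed, quartile-spanning profile
        the correlation analysis stratifies on.
    abundance_mu
        Location of the log-normal (cancels under normalization; kept
        configurable for completeness).
    min_length_bp, max_length_bp
        Uniform integer range of transcript (exon-union) lengths.
    read_length
        Nominal read length in bp.
    n_reads
        Number of reads to simulate.
    n_injection_rate
        Per-read probability of carrying >=3 interspersed Ns.
    short_read_fraction
        Per-read probability of truncation to a length uniform in [5, 16].
    seed
        Seed fully determining all outputs.
    """

    n_genes: int = 15000
    silent_fraction: float = 0.1
    abundance_sigma: float = 1.8
    abundance_mu: float = 0.0
    min_length_bp: int = 300
    max_length_bp: int = 5000
    read_length: int = 75
    n_reads: int = 1_000_000
    n_injection_rate: float = 0.01
    short_read_fraction: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError(f"n_genes must be positive, got {self.n_genes}")
        for name in ("silent_fraction", "n_injection_rate", "short_read_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_length_bp < self.read_length:
            raise ValueError(
                f"min_length_bp ({self.min_length_bp}) must be >= "
                f"read_length ({self.read_length}): every transcript must "
                "accommodate at least one full read"
            )
        if self.max_length_bp < self.min_length_bp:
            raise ValueError("max_length_bp must be >= min_length_bp")
        if self.n_reads < 0:
            raise ValueError(f"n_reads must be >= 0, got {self.n_reads}")


@dataclass
class TranscriptomeModel:
    """Synthetic annotated transcriptome with known ground truth.

    ``true_abundance`` holds relative transcript molarities summing to 1
    over expressed genes; silent genes have abundance exactly 0.
    """

    gene_ids: list[str]
    lengths_bp: np.ndarray  # int64, one per gene
    sequences: list[str]
    true_abundance: np.ndarray  # float64, sums to 1 over expressed genes

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if not (len(self.sequences) == len(self.lengths_bp) == len(self.true_abundance) == n):
            raise ValueError("model fields must have one entry per gene")
        if len(set(self.gene_ids)) != n:
            raise ValueError("gene ids must be unique")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def expressed_mask(self) -> np.ndarray:
        return self.true_abundance > 0

    def write(self, out_dir: str | os.PathLike, prefix: str = "transcriptome") -> dict[str, str]:
        """Write FASTA, gene-length TSV and abundance truth table.

        Returns the mapping of artifact name to file path.
        """
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "fasta": os.path.join(out_dir, f"{prefix}.fasta"),
            "lengths": os.path.join(out_dir, f"{prefix}.lengths.tsv"),
            "truth": os.path.join(out_dir, f"{prefix}.truth.tsv"),
        }
        write_fasta(dict(zip(self.gene_ids, self.sequences)), paths["fasta"])
        with open(paths["lengths"], "w") as fh:
            for gid, L in zip(self.gene_ids, self.lengths_bp):
                fh.write(f"{gid}\t{int(L)}\n")
        with open(paths["truth"], "w") as fh:
            fh.write("gene_id\ttrue_abundance\n")
            for gid, a in zip(self.gene_ids, self.true_abundance):
                fh.write(f"{gid}\t{a:.10e}\n")
        return paths


def generate_transcriptome(config: SimulationConfig) -> TranscriptomeModel:
    """Draw a synthetic transcriptome from ``config``.

    Exactly ``round(silent_fraction * n_genes)`` genes (chosen at random)
    are silent; abundances of the rest are log-normal draws normalized to
    sum to 1. Sequences are i.i.d. uniform over {A, C, G, T}.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    width = max(5, len(str(n)))
    gene_ids = [f"gene{i:0{width}d}" for i in range(n)]
    lengths = rng.integers(config.min_length_bp, config.max_length_bp + 1, size=n)

    n_silent = round(config.silent_fraction * n)
    silent_idx = rng.choice(n, size=n_silent, replace=False)
    abundance = np.exp(rng.normal(config.abundance_mu, config.abundance_sigma, size=n))
    abundance[silent_idx] = 0.0
    total = abundance.sum()
    if total > 0:
        abundance /= total

    sequences = []
    for L in lengths:
        codes = rng.integers(0, 4, size=int(L), dtype=np.uint8)
        sequences.append(_BASES[codes].tobytes().decode("ascii"))

    return TranscriptomeModel(gene_ids, lengths.astype(np.int64), sequences, abundance)


def simulate_reads(model: TranscriptomeModel, config: SimulationConfig) -> ReadSet:
    """Simulate ``config.n_reads`` single-end reads from ``model``.

    Source genes are drawn with probability proportional to
    ``true_abundance * (length - read_length + 1)``; start positions are
    uniform over valid positions. Silent genes never emit reads.
    """
    config.validate()
    rl = config.read_length
    n = config.n_reads
    expressed = model.expressed_mask
    if n > 0 and not expressed.any():
        raise ValueError("cannot simulate reads: all genes are silent")
    if (model.lengths_bp < rl).any():
        bad = model.gene_ids[int(np.argmin(model.lengths_bp))]
        raise ValueError(f"gene {bad} is shorter than the read length ({rl} bp)")

    if n == 0:
        return ReadSet()

    rng = np.random.default_rng(config.seed + 1)
    weights = model.true_abundance * (model.lengths_bp - rl + 1)
    p = weights / weights.sum()

    gene_idx = rng.choice(model.n_genes, size=n, p=p)
    n_starts = model.lengths_bp[gene_idx] - rl + 1
    starts = rng.integers(0, n_starts)  # high is exclusive, broadcast per read

    # Concatenate the transcriptome once; reads are gathered as slices.
    concat = np.frombuffer("".join(model.sequences).encode("ascii"), dtype=np.uint8)
    offsets = np.concatenate([[0], np.cumsum(model.lengths_bp)])[:-1]
    abs_start = offsets[gene_idx] + starts
    mat = concat[abs_start[:, None] + np.arange(rl)[None, :]].copy()

    # map ASCII -> 0..4 codes for defect injection, back to ASCII at the end
    lut = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    codes = lut[mat]

    out_lengths = np.full(n, rl, dtype=np.int64)
    short_mask = rng.random(n) < config.short_read_fraction
    out_lengths[short_mask] = rng.integers(5, 17, size=int(short_mask.sum()))

    n_mask = rng.random(n) < config.n_injection_rate
    for i in np.flatnonzero(n_mask):
        L = int(out_lengths[i])
        k = min(int(rng.integers(3, 6)), L)
        pos = rng.choice(L, size=k, replace=False)
        codes[i, pos] = 4  # N

    ascii_mat = _BASES_N[codes]
    ids, seqs, quals = [], [], []
    id_width = max(7, len(str(n)))
    for i in range(n):
        L = int(out_lengths[i])
        ids.append(
            f"read{i:0{id_width}d}{PROVENANCE_DELIMITER}{model.gene_ids[gene_idx[i]]}"
        )
        seqs.append(ascii_mat[i, :L].tobytes().decode("ascii"))
        quals.append(QUALITY_CHAR * L)
    return ReadSet(ids, seqs, quals)
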