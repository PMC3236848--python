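"""Shared fixtures.

The ``study`` fixture builds the scaled synthetic depth-saturation
study once per session: a 15,000-gene transcriptome (10% silent,
log-normal abundance, sigma 1.8), 3 M simulated 75 bp reads, quality
filtering, the k-mer index and the full-depth reference expression
profile. The heavier analyses (replicated subsampling ladders) derive
from it inside the tests that need them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import seqsat


@dataclass
class Study:
    config: seqsat.SimulationConfig
    model: seqsat.TranscriptomeModel
    reads: seqsat.ReadSet  # filtered
    index: seqsat.KmerIndex
    lengths: seqsat.GeneLengthTable
    reference: seqsat.ExpressionProfile

    @property
    def n_reads(self) -> int:
        return len(self.reads)


@pytest.fixture(scope="session")
def study() -> Study:
    cfg = seqsat.SimulationConfig(
        n_genes=15000,
        silent_fraction=0.1,
        abundance_sigma=1.8,
        n_reads=3_000_000,
        read_length=75,
        seed=1,
    )
    model = seqsat.generate_transcriptome(cfg)
    raw = seqsat.simulate_reads(model, cfg)
    reads, _ = seqsat.filter_reads(raw)
    del raw
    index = seqsat.build_index(dict(zip(model.gene_ids, model.sequences)))
    lengths = seqsat.GeneLengthTable(
        dict(zip(model.gene_ids, (int(x) for x in model.lengths_bp)))
    )
    reference = seqsat.compute_rpkm(
        seqsat.assign_reads(reads, index),
        lengths,
        depth=len(reads),
        replicate="reference",
    )
    return Study(cfg, model, reads, index, lengths, reference)


@pytest.fixture(scope="session")
def replicate_sets(study: Study) -> dict[tuple[int, int], seqsat.ReadSet]:
    """Four independent 1 M-read draws from the filtered study reads."""
    plan = seqsat.SubsamplePlan(depths=[1_000_000], n_replicates=4, base_seed=1)
    return seqsat.make_replicates(study.reads, plan)


@pytest.fixture(scope="session")
def replicate_profiles(
    study: Study, replicate_sets
) -> list[seqsat.ExpressionProfile]:
    return [
        seqsat.compute_rpkm(
            seqsat.assign_reads(rs, study.index),
            study.lengths,
            depth=d,
            replicate=r,
        )
        for (d, r), rs in sorted(replicate_sets.items())
    ]


@pytest.fixture()
def tiny_model() -> seqsat.TranscriptomeModel:
    cfg = seqsat.SimulationConfig(
        n_genes=30, n_reads=0, silent_fraction=0.2, min_length_bp=200,
        max_length_bp=600, read_length=50, seed=11,
    )
    return seqsat.generate_transcriptome(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
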