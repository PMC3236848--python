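"""Replicated fixed-size random subsampling of reads without replacement.

This is the core experimental device of a depth-saturation study: from
one deep library, draw several independent read subsets of a fixed size,
each read equally likely, so that each subset behaves like a library
sequenced at the lower depth ("technical replicates" of that depth).

Draws use reservoir sampling (Algorithm L), so a stream larger than
memory can be subsampled in one pass holding only k records; each input
item ends up in the sample with probability exactly k/N. Output order is
the reservoir order — arbitrary but fully determined by the seed.

Per-cell seeds for a replicate plan are derived by a splitmix64-style
hash of (base_seed, depth, replicate), making every (depth, replicate)
cell an independent, reproducible draw with no dependence on the order
cells are computed in.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TypeVar

import numpy as np

from .io import ReadSet

T = TypeVar("T")


@dataclass(frozen=True)
class SubsamplePlan:
    """Target depths (read counts), replicate count and base seed."""

    depths: Sequence[int]
    n_replicates: int = 4
    base_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.depths) == 0:
            raise ValueError("plan needs at least one depth")
        if any(d <= 0 for d in self.depths):
            raise ValueError(f"depths must be strictly positive, got {list(self.depths)}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def cells(self) -> Iterator[tuple[int, int]]:
        for d in self.depths:
            for r in range(self.n_replicates):
                yield d, r


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return x ^ (x >> 31)


def derive_seed(base_seed: int, depth: int, replicate: int) -> int:
    """Deterministic, well-mixed per-cell seed (kept below 2**31)."""
    h = _splitmix64(_splitmix64(_splitmix64(base_seed) ^ depth) ^ replicate)
    return h % (2**31)


def reservoir_sample(items: Iterable[T], k: int, rng: np.random.Generator) -> list[T]:
    """Uniform sample of exactly k items without replacement (Algorithm L).

    Single pass; only k items are ever held. Raises if the stream has
    fewer than k items.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return []
    it = iter(items)
    reservoir: list[T] = []
    for item in it:
        reservoir.append(item)
        if len(reservoir) == k:
            break
    if len(reservoir) < k:
        raise ValueError(
            f"cannot draw {k} reads from an input of only {len(reservoir)}"
        )
    w = math.exp(math.log(rng.random()) / k)
    while True:
        skip = math.floor(math.log(rng.random()) / math.log1p(-w))
        item = None
        try:
            for _ in range(skip + 1):
                item = next(it)
        except StopIteration:
            return reservoir
        reservoir[int(rng.integers(k))] = item
        w *= math.exp(math.log(rng.random()) / k)


def subsample_reads(reads: ReadSet, k: int, seed: int) -> ReadSet:
    """Draw exactly k reads uniformly without replacement from ``reads``."""
    n = len(reads)
    if k > n:
        raise ValueError(f"cannot draw {k} reads from an input of only {n}")
    rng = np.random.default_rng(seed)
    # Sampling indices rather than records keeps the draw cheap for
    # in-memory sets; the stream path uses the same algorithm on records.
    idx = reservoir_sample(range(n), k, rng)
    return reads.select(idx)


def make_replicates(
    reads: ReadSet,
    plan: SubsamplePlan,
    out_dir: str | os.PathLike | None = None,
    sample: str = "sample",
) -> dict[tuple[int, int], ReadSet]:
    """Independent draws for every (depth, replicate) cell of ``plan``.

    Replicates at the same depth are independent draws from the full
    input, not nested subsets. If ``out_dir`` is given, each cell is also
    written as ``<sample>.depth<depth>.rep<r>.fastq``.
    """
    n = len(reads)
    worst = max(plan.depths)
    if worst > n:
        raise ValueError(f"cannot draw {worst} reads from an input of only {n}")
    out: dict[tuple[int, int], ReadSet] = {}
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
    for depth, rep in plan.cells():
        cell = subsample_reads(reads, depth, derive_seed(plan.base_seed, depth, rep))
        out[(depth, rep)] = cell
        if out_dir is not None:
            cell.to_fastq(os.path.join(out_dir, f"{sample}.depth{depth}.rep{rep}.fastq"))
    return out
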