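"""Pre-mapping read quality filters.

Two rules, applied in a fixed order: reads shorter than a minimum length
(default 17 bp) are removed, then reads with too many N calls (default:
more than 2) are removed. A read failing both rules is counted once,
under the length rule, so the accounting identity
``n_input = n_removed_short + n_removed_n + n_retained`` always holds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io import ReadRecord, ReadSet


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds for the pre-mapping filters.

    ``min_length_bp``: reads strictly shorter are removed (default 17,
    i.e. the "<17 bp" rule). ``max_n_count``: reads with more Ns than
    this are removed (default 2; "numerous interspersed Ns" has no
    standard definition, so the cutoff is explicit and configurable).
    """

    min_length_bp: int = 17
    max_n_count: int = 2

    def __post_init__(self) -> None:
        if self.min_length_bp < 1:
            raise ValueError("min_length_bp must be >= 1")
        if self.max_n_count < 0:
            raise ValueError("max_n_count must be >= 0")


@dataclass
class FilterStats:
    n_input: int = 0
    n_removed_short: int = 0
    n_removed_n: int = 0
    n_retained: int = 0

    def to_tsv(self) -> str:
        header = "n_input\tn_removed_short\tn_removed_n\tn_retained"
        row = f"{self.n_input}\t{self.n_removed_short}\t{self.n_removed_n}\t{self.n_retained}"
        return f"{header}\n{row}\n"


def filter_reads(
    reads: Iterable[ReadRecord], policy: FilterPolicy = FilterPolicy()
) -> tuple[ReadSet, FilterStats]:
    """Apply the length and N-count filters, preserving input order."""
    stats = FilterStats()
    kept = ReadSet()
    min_len = policy.min_length_bp
    max_n = policy.max_n_count
    for rec in reads:
        stats.n_input += 1
        if len(rec.seq) < min_len:
            stats.n_removed_short += 1
        elif rec.seq.count("N") > max_n:
            stats.n_removed_n += 1
        else:
            kept.ids.append(rec.id)
            kept.seqs.append(rec.seq)
            kept.quals.append(rec.qual)
    stats.n_retained = len(kept)
    return kept, stats
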