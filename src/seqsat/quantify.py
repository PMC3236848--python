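"""Read-to-gene assignment and RPKM expression quantification.

Assignment is a deterministic exact-match k-mer method: every 31-mer of
every transcript is indexed; a read is assigned to gene g iff the
intersection of the gene sets of its sampled k-mers is exactly {g}. An
empty intersection leaves the read unassigned; an intersection with more
than one gene marks it ambiguous, and ambiguous reads are excluded both
from per-gene counts and from the mapped-read total. K-mers are sampled
along the read at stride ceil(len/3) with the final position always
included, giving at least two seeds per read longer than k.

Expression is summarized as RPKM — reads per kilobase of exon per
million mapped reads:

    rpkm(g) = 1e9 * C_g / (N * L_g)

with C_g the reads assigned to gene g, N the total assigned reads and
L_g the gene's exon-union length in bp. log2(RPKM) is defined only where
RPKM > 0 (genes with no reads are "not detected", not "expression 2^-inf";
downstream correlation analyses exclude them explicitly).

The index stores integer-encoded k-mers in a sorted uint64 array and
answers queries by binary search, so million-read sets are assigned in
seconds without a mapper.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

from .io import ReadSet, read_fasta

DEFAULT_K = 31

# ASCII -> 2-bit base code; anything outside ACGT (case-insensitive) -> 4
_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i
    _CODE_LUT[_b + 32] = _i  # lowercase


class GeneLengthTable(dict):
    """Mapping gene_id -> exon-union length in bp (positive integers)."""

    def __init__(self, data: Mapping[str, int] = ()):
        super().__init__(data)
        for gid, L in self.items():
            if L < 1:
                raise ValueError(f"gene {gid} has non-positive length {L}")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "GeneLengthTable":
        """Read a two-column ``gene_id<TAB>length_bp`` table (no header)."""
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "length_bp"])
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene id in length table: {dup}")
        return cls(dict(zip(df["gene_id"], df["length_bp"].astype(int))))

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for gid, L in self.items():
                fh.write(f"{gid}\t{int(L)}\n")


def gene_lengths_from_gtf(path: str | os.PathLike) -> GeneLengthTable:
    """Exon-union gene lengths from a GTF/GFF annotation.

    For each gene, the length is the number of bases covered by the
    union of its exon intervals, overlaps merged, strand ignored.
    GTF coordinates are 1-based end-inclusive; pyranges converts them to
    half-open internally, so merged interval lengths are End - Start.
    """
    # validate exon coordinates first so errors carry a line number
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise ValueError(f"line {lineno}: not a GTF/GFF record")
            if parts[2] != "exon":
                continue
            start, end = int(parts[3]), int(parts[4])
            if end < start:
                raise ValueError(
                    f"line {lineno}: exon end < start ({end} < {start})"
                )
    gr = pr.read_gtf(os.fspath(path))
    exons = gr[gr.Feature == "exon"]
    if len(exons) == 0:
        return GeneLengthTable()
    merged = exons.merge(by="gene_id", strand=False)
    df = merged.df
    lengths = (df["End"] - df["Start"]).groupby(df["gene_id"], observed=True).sum()
    return GeneLengthTable({str(g): int(L) for g, L in lengths.items()})


@dataclass
class CountTable:
    """Per-gene assigned-read counts for one read set."""

    counts: pd.Series  # index gene_id, int64
    n_unassigned: int
    n_ambiguous: int

    @property
    def total_assigned(self) -> int:
        return int(self.counts.sum())

    @property
    def n_reads(self) -> int:
        return self.total_assigned + self.n_unassigned + self.n_ambiguous

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# total_assigned={self.total_assigned}"
                f"\tn_unassigned={self.n_unassigned}"
                f"\tn_ambiguous={self.n_ambiguous}\n"
            )
            fh.write("gene_id\tcount\n")
            for gid, c in self.counts.items():
                fh.write(f"{gid}\t{int(c)}\n")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "CountTable":
        with open(path) as fh:
            header = fh.readline()
        meta = dict(
            kv.split("=", 1) for kv in header.lstrip("# ").rstrip("\n").split("\t")
        )
        df = pd.read_csv(path, sep="\t", skiprows=1)
        counts = pd.Series(
            df["count"].to_numpy(np.int64),
            index=pd.Index(df["gene_id"], name="gene_id"),
            name="count",
        )
        return cls(
            counts=counts,
            n_unassigned=int(meta.get("n_unassigned", 0)),
            n_ambiguous=int(meta.get("n_ambiguous", 0)),
        )


@dataclass
class ExpressionProfile:
    """Per-gene RPKM for one (sample, depth, replicate) read set.

    ``rpkm`` is indexed by gene_id over the full annotated universe;
    zero means no read was assigned. ``log2_rpkm`` is NaN exactly where
    rpkm is zero.
    """

    rpkm: pd.Series
    sample: str = "sample"
    depth: int | float | None = None
    replicate: int | str | None = None

    @property
    def log2_rpkm(self) -> pd.Series:
        with np.errstate(divide="ignore"):
            vals = np.log2(self.rpkm.to_numpy(dtype=float))
        vals[~(self.rpkm.to_numpy() > 0)] = np.nan
        return pd.Series(vals, index=self.rpkm.index, name="log2_rpkm")

    @property
    def expressed(self) -> pd.Index:
        return self.rpkm.index[self.rpkm > 0]

    @property
    def label(self) -> tuple:
        return (self.sample, self.depth, self.replicate)

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f"# sample={self.sample}\tdepth={self.depth}\treplicate={self.replicate}\n")
            fh.write("gene_id\trpkm\tlog2_rpkm\n")
            l2 = self.log2_rpkm
            for gid in self.rpkm.index:
                r = self.rpkm[gid]
                l = l2[gid]
                fh.write(f"{gid}\t{r:.6e}\t{'' if np.isnan(l) else f'{l:.6f}'}\n")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "ExpressionProfile":
        with open(path) as fh:
            header = fh.readline()
        meta = dict(
            kv.split("=", 1) for kv in header.lstrip("# ").rstrip("\n").split("\t")
        )
        df = pd.read_csv(path, sep="\t", skiprows=1)
        rpkm = pd.Series(
            df["rpkm"].to_numpy(float),
            index=pd.Index(df["gene_id"], name="gene_id"),
            name="rpkm",
        )
        depth: int | float | None = None
        if meta.get("depth", "None") != "None":
            d = float(meta["depth"])
            depth = int(d) if d.is_integer() else d
        rep = meta.get("replicate", "None")
        replicate: int | str | None
        replicate = None if rep == "None" else (int(rep) if rep.isdigit() else rep)
        return cls(
            rpkm=rpkm, sample=meta.get("sample", "sample"), depth=depth, replicate=replicate
        )


class KmerIndex:
    """Exact k-mer -> gene lookup over a set of transcript sequences.

    K-mers containing non-ACGT characters are not indexed. Internally
    the 2-bit-encoded k-mers live in one sorted uint64 array parallel to
    a gene-index array, so a batch of queries is two vectorized binary
    searches.
    """

    def __init__(self, gene_ids: Sequence[str], sequences: Sequence[str], k: int = DEFAULT_K):
        if len(gene_ids) != len(sequences):
            raise ValueError("one sequence per gene id required")
        if k < 1 or k > 31:
            raise ValueError(f"k must be in [1, 31], got {k}")
        for gid, seq in zip(gene_ids, sequences):
            if len(seq) < k:
                raise ValueError(
                    f"transcript {gid} (length {len(seq)}) is shorter than k={k}"
                )
        self.k = k
        self.gene_ids = list(gene_ids)

        chunks_codes: list[np.ndarray] = []
        chunks_genes: list[np.ndarray] = []
        powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.uint64)
        for gi, seq in enumerate(sequences):
            base = _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
            win = np.lib.stride_tricks.sliding_window_view(base, k)
            valid = (win < 4).all(axis=1)
            codes = win.astype(np.uint64) @ powers
            chunks_codes.append(codes[valid])
            chunks_genes.append(np.full(int(valid.sum()), gi, dtype=np.int32))
        codes = np.concatenate(chunks_codes)
        genes = np.concatenate(chunks_genes)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._genes = genes[order]

    def __len__(self) -> int:
        return len(self._codes)

    def lookup(self, kmer: str) -> set[str]:
        """Gene ids whose transcripts contain ``kmer`` (exact match)."""
        base = _CODE_LUT[np.frombuffer(kmer.encode("ascii"), dtype=np.uint8)]
        if len(base) != self.k or (base >= 4).any():
            return set()
        powers = (4 ** np.arange(self.k - 1, -1, -1)).astype(np.uint64)
        code = np.uint64(base.astype(np.uint64) @ powers)
        lo = int(np.searchsorted(self._codes, code, side="left"))
        hi = int(np.searchsorted(self._codes, code, side="right"))
        return {self.gene_ids[g] for g in self._genes[lo:hi]}

    # -- batch machinery -------------------------------------------------

    def _query_codes(
        self, codes: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(count, left-offset, first-gene-index) per query; gene -1 where absent.

        Queries are binary-searched in sorted order for memory locality;
        the right-side search runs only for the (rare) k-mers shared by
        several genes, where count is capped at 2 — callers only need to
        distinguish 0 / 1 / many.
        """
        m = len(self._codes)
        qorder = np.argsort(codes, kind="stable")
        lo = np.empty(len(codes), dtype=np.int64)
        lo[qorder] = np.searchsorted(self._codes, codes[qorder], side="left")
        safe_lo = np.minimum(lo, m - 1)
        found = self._codes[safe_lo] == codes
        first = np.where(found, self._genes[safe_lo], -1)
        cnt = found.astype(np.int64)
        dup = found & (lo + 1 < m)
        dup[dup] = self._codes[lo[dup] + 1] == codes[dup]
        cnt[dup] = 2
        return cnt, lo, first


def build_index(
    fasta: str | os.PathLike | Mapping[str, str], k: int = DEFAULT_K
) -> KmerIndex:
    """Build a :class:`KmerIndex` from a FASTA path or id->sequence mapping."""
    seqs = read_fasta(fasta) if isinstance(fasta, (str, os.PathLike)) else dict(fasta)
    return KmerIndex(list(seqs.keys()), list(seqs.values()), k=k)


def _seed_positions(length: int, k: int) -> list[int]:
    """K-mer start positions sampled along a read: stride ceil(len/3),
    last valid position always included (>= 2 seeds when length > k)."""
    last = length - k
    stride = math.ceil(length / 3)
    pos = list(range(0, last + 1, stride))
    if pos[-1] != last:
        pos.append(last)
    return pos


def assign_reads_detail(reads: ReadSet, index: KmerIndex) -> np.ndarray:
    """Per-read assignment: gene index, or -1 unassigned, -2 ambiguous.

    A read is assigned to the single gene in the intersection of the
    gene sets of its valid sampled k-mers; reads shorter than k, reads
    whose k-mers are all invalid (e.g. all Ns), and reads whose k-mer
    gene sets have empty intersection are unassigned.
    """
    k = index.k
    n = len(reads)
    result = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return result

    lengths = np.fromiter((len(s) for s in reads.seqs), dtype=np.int64, count=n)
    concat = np.frombuffer("".join(reads.seqs).encode("ascii"), dtype=np.uint8)
    read_offset = np.concatenate([[0], np.cumsum(lengths)])[:-1]

    bad_char = (_CODE_LUT[concat] == 4) & (concat != ord("N"))
    if bad_char.any():
        pos = int(np.flatnonzero(bad_char)[0])
        ri = int(np.searchsorted(read_offset, pos, side="right") - 1)
        raise ValueError(
            f"read {reads.ids[ri]!r} contains a non-ACGTN character "
            f"({chr(int(concat[pos]))!r})"
        )

    # absolute k-mer start positions, vectorized per read-length group
    qstarts: list[np.ndarray] = []
    qreads: list[np.ndarray] = []
    for L in np.unique(lengths):
        if L < k:
            continue
        pos = np.asarray(_seed_positions(int(L), k), dtype=np.int64)
        ridx = np.flatnonzero(lengths == L)
        qstarts.append((read_offset[ridx][:, None] + pos[None, :]).ravel())
        qreads.append(np.repeat(ridx, len(pos)))
    if not qstarts:
        return result
    starts = np.concatenate(qstarts)
    read_idx = np.concatenate(qreads)
    order = np.argsort(read_idx, kind="stable")  # contiguous per-read segments
    starts = starts[order]
    read_idx = read_idx[order]

    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.uint64)
    codes = np.empty(len(starts), dtype=np.uint64)
    valid = np.empty(len(starts), dtype=bool)
    base_all = _CODE_LUT[concat]
    chunk = 500_000
    for c0 in range(0, len(starts), chunk):
        sl = slice(c0, min(c0 + chunk, len(starts)))
        win = base_all[starts[sl][:, None] + np.arange(k)[None, :]]
        valid[sl] = (win < 4).all(axis=1)
        codes[sl] = win.astype(np.uint64) @ powers

    read_idx = read_idx[valid]
    codes = codes[valid]
    if len(codes) == 0:
        return result
    cnt, lo, first = index._query_codes(codes)

    # fast path: every k-mer hits 0 or 1 genes; a read is assigned iff all
    # its k-mers agree on one present gene (min == max == gene >= 0)
    multi = cnt > 1
    seg_ids, seg_first = np.unique(read_idx, return_index=True)
    gmin = np.minimum.reduceat(np.where(cnt > 0, first, -1), seg_first)
    gmax = np.maximum.reduceat(np.where(cnt > 0, first, -1), seg_first)
    has_multi = np.zeros(len(seg_ids), dtype=bool)
    if multi.any():
        has_multi = np.maximum.reduceat(multi.astype(np.int8), seg_first).astype(bool)
    ok = (gmin == gmax) & (gmin >= 0) & ~has_multi
    result[seg_ids[ok]] = gmin[ok]

    # slow path: reads touching a k-mer shared by several genes
    if multi.any():
        for si in np.flatnonzero(has_multi):
            rows = slice(
                seg_first[si],
                seg_first[si + 1] if si + 1 < len(seg_first) else len(read_idx),
            )
            inter: set[int] | None = None
            for c, l, code in zip(cnt[rows], lo[rows], codes[rows]):
                if c == 0:
                    genes: set[int] = set()
                elif c == 1:
                    genes = {int(index._genes[l])}
                else:
                    hi = int(np.searchsorted(index._codes, code, side="right"))
                    genes = set(index._genes[l:hi].tolist())
                inter = genes if inter is None else inter & genes
            if inter is None or len(inter) == 0:
                continue  # unassigned
            if len(inter) == 1:
                result[seg_ids[si]] = inter.pop()
            else:
                result[seg_ids[si]] = -2
    return result


def assign_reads(reads: ReadSet, index: KmerIndex) -> CountTable:
    """Assign reads to genes and tabulate per-gene counts."""
    assignment = assign_reads_detail(reads, index)
    n_genes = len(index.gene_ids)
    counts = np.bincount(assignment[assignment >= 0], minlength=n_genes)
    return CountTable(
        counts=pd.Series(counts, index=pd.Index(index.gene_ids, name="gene_id"), name="count"),
        n_unassigned=int((assignment == -1).sum()),
        n_ambiguous=int((assignment == -2).sum()),
    )


def count_by_provenance(reads: ReadSet, gene_ids: Sequence[str]) -> CountTable:
    """Oracle assigner: count reads by the provenance tag in their ids.

    For testing only — ground truth on simulated reads whose ids encode
    their source gene.
    """
    tags = reads.provenance_tags()
    counts = pd.Series(0, index=pd.Index(gene_ids, name="gene_id"), name="count")
    vc = pd.Series(tags).value_counts()
    unknown = vc.index.difference(counts.index)
    if len(unknown) > 0:
        raise ValueError(f"provenance tag {unknown[0]!r} is not a known gene id")
    counts.loc[vc.index] = vc
    return CountTable(counts=counts.astype(np.int64), n_unassigned=0, n_ambiguous=0)


def compute_rpkm(
    counts: CountTable,
    lengths: GeneLengthTable,
    sample: str = "sample",
    depth: int | float | None = None,
    replicate: int | str | None = None,
) -> ExpressionProfile:
    """RPKM = 1e9 * C / (N * L) per gene, over the count table's universe."""
    N = counts.total_assigned
    if N == 0:
        raise ValueError("no assigned reads: RPKM denominator is zero")
    missing = [g for g, c in counts.counts.items() if c > 0 and g not in lengths]
    if missing:
        raise ValueError(f"gene {missing[0]} has counts but no length entry")
    L = pd.Series(
        [lengths.get(g, np.nan) for g in counts.counts.index],
        index=counts.counts.index,
        dtype=float,
    )
    rpkm = 1e9 * counts.counts.astype(float) / (N * L)
    rpkm = rpkm.fillna(0.0)  # genes absent from the length table have count 0
    rpkm.name = "rpkm"
    return ExpressionProfile(rpkm=rpkm, sample=sample, depth=depth, replicate=replicate)


def average_profiles(profiles: Sequence[ExpressionProfile]) -> ExpressionProfile:
    """Per-gene arithmetic mean of RPKM across replicates of one depth."""
    if len(profiles) == 0:
        raise ValueError("no profiles to average")
    first = profiles[0]
    for p in profiles[1:]:
        if not p.rpkm.index.equals(first.rpkm.index):
            raise ValueError("profiles cover different gene sets")
        if p.depth != first.depth or p.sample != first.sample:
            raise ValueError("profiles carry different sample/depth labels")
    mean = pd.concat([p.rpkm for p in profiles], axis=1).mean(axis=1)
    mean.name = "rpkm"
    return ExpressionProfile(
        rpkm=mean, sample=first.sample, depth=first.depth, replicate="mean"
    )
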