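"""YGS-style k-mer subtraction scan.

The statistic scores each reference window by the percentage of its
genome-wide single-copy k-mers that are absent from the opposite-sex read
k-mer database; windows retaining >= 50% unmatched single-copy k-mers are
candidate sex-determining-region (SDR) sequences. Defaults mirror the
original protocol: canonical 15-mers, phred >= 20 bases only, read k-mers
kept at count >= 5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import _encode
from .core_io import GenomicInterval, SequenceSet, Window, merge_adjacent
from .reads import ReadSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KmerConfig:
    k: int = 15
    canonical: bool = True
    min_count: int = 5
    min_base_quality: int | None = 20

    def __post_init__(self) -> None:
        if not (1 <= self.k <= _encode.MAX_K):
            raise ValueError(f"k must be in [1, {_encode.MAX_K}]")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


class KmerSet:
    """Canonical k-mer -> count mapping backed by sorted packed codes."""

    def __init__(self, codes: np.ndarray, counts: np.ndarray, k: int,
                 canonical: bool = True):
        codes = np.asarray(codes, dtype=_encode.dtype_for(k))
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.counts = np.asarray(counts, dtype=np.int64)[order]
        self.k = k
        self.canonical = canonical

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, kmer: str) -> bool:
        code = _encode.encode_kmer(kmer)
        if self.canonical:
            code = min(code, _encode.revcomp_code(code, self.k))
        return bool(self.contains_codes(
            np.array([code], dtype=self.codes.dtype))[0])

    def contains_codes(self, codes: np.ndarray) -> np.ndarray:
        """Vectorized membership for packed (already canonical) codes."""
        idx = np.searchsorted(self.codes, codes)
        idx_clipped = np.minimum(idx, len(self.codes) - 1) if len(self.codes) \
            else np.zeros_like(idx)
        if not len(self.codes):
            return np.zeros(len(codes), dtype=bool)
        return (idx < len(self.codes)) & (self.codes[idx_clipped] == codes)

    def to_dict(self) -> dict[str, int]:
        """Decode to a {k-mer string: count} dict (small sets only)."""
        return {
            _encode.decode_kmer(int(c), self.k): int(n)
            for c, n in zip(self.codes, self.counts)
        }


@dataclass(frozen=True)
class WindowKmerScore:
    """Per-window YGS score: ``pct_unmatched`` is NaN when the window has no
    single-copy k-mers (excluded from calling)."""

    window: GenomicInterval
    n_single_copy: int
    n_unmatched: int

    @property
    def pct_unmatched(self) -> float:
        if self.n_single_copy == 0:
            return math.nan
        return 100.0 * self.n_unmatched / self.n_single_copy


# ---------------------------------------------------------------------------

def count_read_kmers(reads, cfg: KmerConfig = KmerConfig(),
                     chunk_reads: int = 500_000) -> KmerSet:
    """Count canonical k-mers in a read set, mirroring jellyfish count/dump.

    ``reads`` may be a :class:`~uvsdr.reads.ReadSet`, a FASTQ path, or an
    iterable of sequence strings. K-mers containing an N or a base under
    ``min_base_quality`` are skipped; counts below ``min_count`` are dropped
    at the end.
    """
    if isinstance(reads, (str, Path)):
        reads = ReadSet.from_fastq(reads)
    if not isinstance(reads, ReadSet):
        reads = ReadSet.from_sequences(list(reads))

    dtype = _encode.dtype_for(cfg.k)
    if reads.n_reads == 0:
        return KmerSet(np.empty(0, dtype=dtype),
                       np.empty(0, dtype=np.int64), cfg.k, cfg.canonical)
    if cfg.k > reads.read_len:
        logger.warning("k=%d exceeds read length %d; empty k-mer set",
                       cfg.k, reads.read_len)
        return KmerSet(np.empty(0, dtype=dtype),
                       np.empty(0, dtype=np.int64), cfg.k, cfg.canonical)

    k, L = cfg.k, reads.read_len
    chunks: list[np.ndarray] = []
    for start in range(0, reads.n_reads, chunk_reads):
        block = reads.codes[start:start + chunk_reads]
        codes = block.reshape(-1).copy()
        if cfg.min_base_quality is not None and reads.quals is not None:
            low = reads.quals[start:start + chunk_reads].reshape(-1) \
                < cfg.min_base_quality
            codes[low] = 4
        kcodes, valid = _encode.canonical_rolling(codes, k, cfg.canonical)
        # mask windows spanning a read boundary in the flattened matrix
        pos_in_read = np.arange(len(kcodes)) % L
        keep = valid & (pos_in_read <= L - k)
        chunks.append(kcodes[keep])
    allcodes = np.concatenate(chunks) if chunks else np.empty(0, dtype)
    uniq, counts = np.unique(allcodes, return_counts=True)
    keep = counts >= cfg.min_count
    return KmerSet(uniq[keep], counts[keep], cfg.k, cfg.canonical)


class SingleCopyKmers:
    """Genome-wide single-copy canonical k-mers with their start positions,
    per reference sequence."""

    def __init__(self, k: int, canonical: bool,
                 positions: dict[str, np.ndarray],
                 codes: dict[str, np.ndarray]):
        self.k = k
        self.canonical = canonical
        self.positions = positions  # chrom -> int64 start positions
        self.codes = codes          # chrom -> uint64 canonical codes

    def total(self) -> int:
        return sum(len(v) for v in self.codes.values())

    def as_set(self) -> set[str]:
        """Decode to a set of k-mer strings (small genomes only)."""
        out: set[str] = set()
        for codes in self.codes.values():
            for c in codes:
                out.add(_encode.decode_kmer(int(c), self.k))
        return out


def genome_single_copy_kmers(assembly: SequenceSet,
                             cfg: KmerConfig = KmerConfig()
                             ) -> SingleCopyKmers:
    """Canonical k-mers with genome-wide count exactly 1, tagged with their
    start position (hence window of origin).

    A k-mer occurring twice anywhere — including once forward and once as its
    reverse complement — is excluded.
    """
    if len(assembly) == 0:
        raise ValueError("empty assembly")
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    allcodes: list[np.ndarray] = []
    for chrom, seq in assembly.records.items():
        codes = _encode.seq_to_codes(seq)
        kcodes, valid = _encode.canonical_rolling(codes, cfg.k, cfg.canonical)
        pos = np.nonzero(valid)[0].astype(np.int64)
        kcodes = kcodes[valid]
        per_chrom[chrom] = (pos, kcodes)
        allcodes.append(kcodes)
    cat = np.concatenate(allcodes) if allcodes else np.empty(0, _encode.dtype_for(cfg.k))
    uniq, counts = np.unique(cat, return_counts=True)
    single = uniq[counts == 1]
    positions: dict[str, np.ndarray] = {}
    codes_out: dict[str, np.ndarray] = {}
    for chrom, (pos, kcodes) in per_chrom.items():
        member = _sorted_member(single, kcodes)
        positions[chrom] = pos[member]
        codes_out[chrom] = kcodes[member]
    return SingleCopyKmers(cfg.k, cfg.canonical, positions, codes_out)


def _sorted_member(sorted_codes: np.ndarray, query: np.ndarray) -> np.ndarray:
    if len(sorted_codes) == 0:
        return np.zeros(len(query), dtype=bool)
    idx = np.searchsorted(sorted_codes, query)
    idxc = np.minimum(idx, len(sorted_codes) - 1)
    return (idx < len(sorted_codes)) & (sorted_codes[idxc] == query)


def ygs_score_windows(assembly: SequenceSet, windows: Sequence[Window],
                      opp: KmerSet, cfg: KmerConfig = KmerConfig(),
                      single_copy: SingleCopyKmers | None = None
                      ) -> list[WindowKmerScore]:
    """Score each window by the proportion of its single-copy k-mers absent
    from the opposite-sex k-mer database ``opp``.

    A k-mer belongs to the window containing its start position.
    """
    if opp.k != cfg.k or opp.canonical != cfg.canonical:
        raise ValueError("opposite-sex KmerSet configuration mismatch")
    for w in windows:
        if w.chrom not in assembly:
            raise ValueError(f"window on unknown sequence {w.chrom!r}")
    if single_copy is None:
        single_copy = genome_single_copy_kmers(assembly, cfg)

    win_by_chrom: dict[str, list[tuple[int, Window]]] = {}
    for i, w in enumerate(windows):
        win_by_chrom.setdefault(w.chrom, []).append((i, w))

    n_sc = np.zeros(len(windows), dtype=np.int64)
    n_un = np.zeros(len(windows), dtype=np.int64)
    for chrom, entries in win_by_chrom.items():
        pos = single_copy.positions.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        codes = single_copy.codes[chrom]
        unmatched = ~opp.contains_codes(codes)
        starts = np.array([w.start for _, w in entries])
        ends = np.array([w.end for _, w in entries])
        order = np.argsort(starts)
        idx = np.searchsorted(starts[order], pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[order][np.maximum(idx, 0)])
        widx = np.array([entries[j][0] for j in order])
        target = widx[idx[inside]]
        np.add.at(n_sc, target, 1)
        np.add.at(n_un, target, unmatched[inside])
    return [
        WindowKmerScore(w, int(n_sc[i]), int(n_un[i]))
        for i, w in enumerate(windows)
    ]


def call_candidate_windows(scores: Iterable[WindowKmerScore],
                           threshold_pct: float = 50.0
                           ) -> list[GenomicInterval]:
    """Retain windows with pct_unmatched >= threshold (inclusive; NA windows
    never retained) and merge adjacent retained windows."""
    retained = [
        s.window for s in scores
        if s.n_single_copy > 0 and s.pct_unmatched >= threshold_pct
    ]
    if not retained:
        return []
    return merge_adjacent(retained)
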