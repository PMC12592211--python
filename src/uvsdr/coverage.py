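"""Depth-based sex-linkage scan.

Per-window depth per sex is normalized by that sex's genome-wide mean; a
window is a V-SDR candidate when male coverage sits within 75-125% of the
male genome average while female coverage stays below 50% of the female
average (and conversely for U-SDR candidates). The log2 male:female fold
change is the companion scaffold-level statistic.

Read placement here is by unique exact match (desk-scale stand-in for a
mapper with a MAPQ filter): multi-mapping reads are discarded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _encode
from .core_io import GenomicInterval, SequenceSet, Window, read_bed
from .reads import ReadSet

logger = logging.getLogger(__name__)

V_CANDIDATE = "V_candidate"
U_CANDIDATE = "U_candidate"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class CoverageClassifierConfig:
    """Bounds are fractions of the per-sex genome-wide mean; the male band is
    inclusive, the female bound strict."""

    male_low: float = 0.75
    male_high: float = 1.25
    female_max: float = 0.50

    def __post_init__(self) -> None:
        if not (0 < self.male_low < self.male_high):
            raise ValueError("need 0 < male_low < male_high")
        if self.female_max <= 0:
            raise ValueError("female_max must be > 0")


class DepthTable:
    """Rows of (sample, window, mean depth) plus a sample -> sex mapping."""

    COLUMNS = ["sample", "chrom", "start", "end", "depth"]

    def __init__(self, df: pd.DataFrame, sample_sex: dict[str, str]):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"depth table missing columns {sorted(missing)}")
        if (df["depth"] < 0).any():
            raise ValueError("negative depth")
        dup = df.duplicated(subset=["sample", "chrom", "start", "end"])
        if dup.any():
            raise ValueError("duplicate sample x window rows")
        self.df = df.reset_index(drop=True)
        self.sample_sex = dict(sample_sex)

    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.df["sample"]))

    def for_sample(self, sample: str) -> pd.DataFrame:
        sub = self.df[self.df["sample"] == sample]
        return sub.sort_values(["chrom", "start"]).reset_index(drop=True)

    def sex_mean(self, sex: str) -> pd.DataFrame:
        """Mean depth per window across samples of one sex."""
        samples = [s for s in self.samples() if self.sample_sex.get(s) == sex]
        if not samples:
            raise ValueError(f"no samples with sex {sex!r}")
        sub = self.df[self.df["sample"].isin(samples)]
        out = (sub.groupby(["chrom", "start", "end"], as_index=False)["depth"]
               .mean())
        return out.sort_values(["chrom", "start"]).reset_index(drop=True)

    @staticmethod
    def concat(tables: Sequence["DepthTable"]) -> "DepthTable":
        df = pd.concat([t.df for t in tables], ignore_index=True)
        sex: dict[str, str] = {}
        for t in tables:
            sex.update(t.sample_sex)
        return DepthTable(df, sex)


# ---------------------------------------------------------------------------
# Exact-match read placement

class _GenomeIndex:
    """Anchor-code index over a concatenated genome for unique exact-match
    read placement."""

    def __init__(self, assembly: SequenceSet, anchor_k: int):
        self.anchor_k = anchor_k
        self.chroms = list(assembly.records)
        self.lengths = np.array([len(assembly[c]) for c in self.chroms])
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)])
        codes = np.concatenate([
            _encode.seq_to_codes(assembly[c]) for c in self.chroms
        ])
        self.codes = codes
        self.invalid = _encode.invalid_for(anchor_k)
        fwd, valid = _encode.rolling_codes(codes, anchor_k)
        # anchors must not span a chromosome boundary
        pos = np.arange(len(fwd))
        chrom_idx = np.searchsorted(self.offsets, pos, side="right") - 1
        in_chrom = pos + anchor_k <= self.offsets[chrom_idx + 1]
        fwd[~(valid & in_chrom)] = self.invalid
        # padded so candidate+offset lookups never run off the end
        self.anchors = np.concatenate(
            [fwd, np.full(anchor_k, self.invalid, dtype=fwd.dtype)]
        )
        ok = fwd != self.invalid
        searchable = fwd[ok]
        order = np.argsort(searchable, kind="stable")
        self.sorted_anchors = searchable[order]
        self.sorted_pos = np.nonzero(ok)[0][order]

    def to_chrom(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.searchsorted(self.offsets, gpos, side="right") - 1
        return idx, gpos - self.offsets[idx]


def _read_anchor_offsets(read_len: int, k: int) -> list[int]:
    """Anchor start offsets covering the whole read with adjacent or
    overlapping k-length anchors."""
    offsets = [0]
    while offsets[-1] + k < read_len:
        offsets.append(min(offsets[-1] + k, read_len - k))
    return offsets


def _candidate_positions(index: _GenomeIndex, first_codes: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Genome positions whose anchor equals each query's first-anchor code.

    Returns (read_index, genome_position) flat arrays.
    """
    lo = np.searchsorted(index.sorted_anchors, first_codes, side="left")
    hi = np.searchsorted(index.sorted_anchors, first_codes, side="right")
    cnt = hi - lo
    total = int(cnt.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    read_idx = np.repeat(np.arange(len(first_codes)), cnt)
    starts = np.repeat(lo, cnt)
    within = np.arange(total) - np.repeat(np.concatenate([[0], np.cumsum(cnt)[:-1]]), cnt)
    gpos = index.sorted_pos[starts + within]
    return read_idx, gpos


def _verify(index: _GenomeIndex, anchor_codes: np.ndarray,
            read_idx: np.ndarray, gpos: np.ndarray,
            offsets: list[int]) -> np.ndarray:
    """Exact full-read match check via covering anchors (O(1) per anchor)."""
    ok = np.ones(len(read_idx), dtype=bool)
    for j, off in enumerate(offsets):
        ok &= index.anchors[gpos + off] == anchor_codes[read_idx, j]
    return ok


def place_reads(assembly: SequenceSet, reads: ReadSet,
                chunk: int = 200_000
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Place each read at its unique exact match (either strand).

    Returns ``(placed_mask, chrom_index, position, n_multi)``; reads with no
    exact match are unplaced, reads with more than one are discarded and
    counted in ``n_multi``.
    """
    L = reads.read_len
    anchor_k = min(L, _encode.MAX_K)
    index = _GenomeIndex(assembly, anchor_k)
    offsets = _read_anchor_offsets(L, anchor_k)

    placed = np.zeros(reads.n_reads, dtype=bool)
    chrom_idx = np.full(reads.n_reads, -1, dtype=np.int64)
    position = np.full(reads.n_reads, -1, dtype=np.int64)
    n_multi = 0

    for start in range(0, reads.n_reads, chunk):
        block = reads.codes[start:start + chunk]
        n = block.shape[0]
        rc_block = (np.uint8(3) - block[:, ::-1]) % np.uint8(8)

        hits_count = np.zeros(n, dtype=np.int64)
        best_pos = np.full(n, -1, dtype=np.int64)
        for mat in (block, rc_block):
            dtype = _encode.dtype_for(anchor_k)
            anchor_codes = np.zeros((n, len(offsets)), dtype=dtype)
            invalid_read = (mat > 3).any(axis=1)
            for j, off in enumerate(offsets):
                seg = mat[:, off:off + anchor_k].astype(dtype)
                code = np.zeros(n, dtype=dtype)
                for b in range(anchor_k):
                    code <<= dtype(2)
                    code |= seg[:, b]
                anchor_codes[:, j] = code
            first = anchor_codes[:, 0].copy()
            first[invalid_read] = index.invalid
            ridx, gpos = _candidate_positions(index, first)
            if len(ridx):
                ok = _verify(index, anchor_codes, ridx, gpos, offsets)
                np.add.at(hits_count, ridx[ok], 1)
                best_pos[ridx[ok]] = gpos[ok]

        unique = hits_count == 1
        n_multi += int((hits_count > 1).sum())
        sel = np.nonzero(unique)[0]
        cidx, cpos = index.to_chrom(best_pos[sel])
        placed[start + sel] = True
        chrom_idx[start + sel] = cidx
        position[start + sel] = cpos

    if n_multi:
        logger.info("discarded %d multi-mapping reads", n_multi)
    return placed, chrom_idx, position, n_multi


def window_depth_from_reads(assembly: SequenceSet, reads: ReadSet,
                            windows: Sequence[Window],
                            sample: str = "sample",
                            sex: str = "none") -> DepthTable:
    """Per-window mean depth from uniquely exact-matching reads."""
    placed, chrom_idx, position, _ = place_reads(assembly, reads)
    chroms = list(assembly.records)
    per_base: dict[str, np.ndarray] = {
        c: np.zeros(len(assembly[c]) + 1, dtype=np.int64) for c in chroms
    }
    L = reads.read_len
    for ci, chrom in enumerate(chroms):
        sel = placed & (chrom_idx == ci)
        starts = position[sel]
        np.add.at(per_base[chrom], starts, 1)
        np.add.at(per_base[chrom], starts + L, -1)
    depth = {c: np.cumsum(arr[:-1]) for c, arr in per_base.items()}
    rows = []
    for w in windows:
        if w.chrom not in depth:
            raise ValueError(f"window on unknown sequence {w.chrom!r}")
        mean = float(depth[w.chrom][w.start:w.end].sum()) / len(w)
        rows.append((sample, w.chrom, w.start, w.end, mean))
    df = pd.DataFrame(rows, columns=DepthTable.COLUMNS)
    return DepthTable(df, {sample: sex} if sex in ("male", "female") else {})


def read_depth_bed(path, windows: Sequence[Window], sample: str = "sample",
                   sex: str = "none") -> DepthTable:
    """Ingest a per-window depth BED (chrom, start, end, depth), e.g. a
    mosdepth regions file, checking that every requested window is present."""
    bed = read_bed(path)
    if "value" not in bed.columns:
        raise ValueError(f"{path}: BED needs a 4th (depth) column")
    keyed = {(r.chrom, int(r.start), int(r.end)): float(r.value)
             for r in bed.itertuples()}
    missing = [w for w in windows if (w.chrom, w.start, w.end) not in keyed]
    if missing:
        names = ", ".join(f"{w.chrom}:{w.start}-{w.end}" for w in missing[:5])
        raise ValueError(f"depth BED missing {len(missing)} windows ({names} ...)")
    rows = [(sample, w.chrom, w.start, w.end, keyed[(w.chrom, w.start, w.end)])
            for w in windows]
    df = pd.DataFrame(rows, columns=DepthTable.COLUMNS)
    return DepthTable(df, {sample: sex} if sex in ("male", "female") else {})


def normalize_by_genome_mean(table: DepthTable) -> DepthTable:
    """Divide each sample's window depths by that sample's length-weighted
    genome-wide mean depth (so the weighted mean of normalized values is 1)."""
    parts = []
    for sample in table.samples():
        sub = table.for_sample(sample).copy()
        lengths = (sub["end"] - sub["start"]).to_numpy(dtype=float)
        mean = float((sub["depth"].to_numpy() * lengths).sum() / lengths.sum())
        if mean == 0:
            raise ValueError(f"sample {sample!r} has zero depth everywhere")
        sub["depth"] = sub["depth"] / mean
        sub["sample"] = sample
        parts.append(sub)
    return DepthTable(pd.concat(parts, ignore_index=True), table.sample_sex)


def classify_windows(norm_male: pd.DataFrame, norm_female: pd.DataFrame,
                     cfg: CoverageClassifierConfig = CoverageClassifierConfig()
                     ) -> pd.DataFrame:
    """Label each window V_candidate / U_candidate / unclassified from
    normalized male and female depths (DataFrames with chrom/start/end/depth
    over identical windows)."""
    m = norm_male.sort_values(["chrom", "start"]).reset_index(drop=True)
    f = norm_female.sort_values(["chrom", "start"]).reset_index(drop=True)
    if not (m[["chrom", "start", "end"]].equals(f[["chrom", "start", "end"]])):
        raise ValueError("male and female tables cover different windows")
    md = m["depth"].to_numpy()
    fd = f["depth"].to_numpy()
    labels = np.full(len(m), UNCLASSIFIED, dtype=object)
    v_mask = (cfg.male_low <= md) & (md <= cfg.male_high) & (fd < cfg.female_max)
    u_mask = (cfg.male_low <= fd) & (fd <= cfg.male_high) & (md < cfg.female_max)
    labels[v_mask] = V_CANDIDATE
    labels[u_mask] = U_CANDIDATE
    out = m[["chrom", "start", "end"]].copy()
    out["male_norm"] = md
    out["female_norm"] = fd
    out["label"] = labels
    return out


def candidate_intervals(classified: pd.DataFrame,
                        label: str = V_CANDIDATE) -> list[GenomicInterval]:
    """Merge adjacent windows carrying ``label`` into intervals."""
    from .core_io import merge_adjacent

    ivs = [GenomicInterval(r.chrom, int(r.start), int(r.end))
           for r in classified.itertuples() if r.label == label]
    return merge_adjacent(ivs) if ivs else []


def log2_fold_change(mean_male_cov: float, mean_female_cov: float,
                     pseudocount: float = 0.0) -> float:
    """log2(male) - log2(female) scaffold coverage fold change.

    With a zero denominator and no pseudocount the statistic is +/-inf; NaN
    when both are zero.
    """
    m = mean_male_cov + pseudocount
    f = mean_female_cov + pseudocount
    if m < 0 or f < 0:
        raise ValueError("coverage must be >= 0")
    if m == 0 and f == 0:
        return math.nan
    if f == 0:
        return math.inf
    if m == 0:
        return -math.inf
    return math.log2(m / f)
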