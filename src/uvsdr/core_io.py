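"""Readers/writers for the standard formats the pipeline touches, plus the
window/interval arithmetic every stage shares.

Coordinate convention: 0-based half-open internally everywhere; GFF3 and VCF
are 1-based on disk and converted at the boundary; BED is 0-based half-open.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")

#: genotype codes used throughout the genotype matrix
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

COMPARTMENTS = ("autosome", "PAR", "SDR", "UV_homologue", "none")


class ParseError(ValueError):
    """Raised when an input file violates its format."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class WindowSpec:
    """Tiling specification: window ``width`` and ``step`` in bp (step defaults
    to width, i.e. non-overlapping)."""

    width: int
    step: int | None = None

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be > 0")
        if self.step is None:
            object.__setattr__(self, "step", self.width)
        if self.step <= 0:
            raise ValueError("window step must be > 0")


@dataclass(frozen=True)
class Window(GenomicInterval):
    """A tiling window; ``partial`` flags a trailing window shorter than the
    nominal width (the borderline case statistics may wish to exclude)."""

    partial: bool = False


class SequenceSet:
    """Uppercase A/C/G/T/N sequences keyed by unique ids, with an optional
    sex tag (``male``/``female``/``None``)."""

    def __init__(self, records: Mapping[str, str], sex_tag: str | None = None):
        self.records: dict[str, str] = {}
        for name, seq in records.items():
            if name in self.records:
                raise ValueError(f"duplicate sequence id {name!r}")
            seq = seq.upper()
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(f"sequence {name!r} has invalid residues {bad}")
            self.records[name] = seq
        if sex_tag not in (None, "male", "female", "none"):
            raise ValueError(f"invalid sex_tag {sex_tag!r}")
        self.sex_tag = None if sex_tag == "none" else sex_tag

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, name: str) -> str:
        return self.records[name]

    def __contains__(self, name: str) -> bool:
        return name in self.records

    def __iter__(self):
        return iter(self.records)

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.records.items()}

    def total_length(self) -> int:
        return sum(len(s) for s in self.records.values())


@dataclass(frozen=True)
class Feature:
    feature_id: str
    interval: GenomicInterval
    strand: str = "."
    feature_type: str = "gene"
    compartment: str = "none"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"invalid compartment {self.compartment!r}")


class AnnotationSet:
    """Gene/repeat features with compartment labels (autosome/PAR/SDR/...)."""

    def __init__(self, features: Iterable[Feature],
                 sequence_lengths: Mapping[str, int] | None = None):
        self.features: list[Feature] = list(features)
        seen: set[str] = set()
        for f in self.features:
            if f.feature_id in seen:
                raise ValueError(f"duplicate feature id {f.feature_id!r}")
            seen.add(f.feature_id)
            if sequence_lengths is not None:
                if f.interval.chrom not in sequence_lengths:
                    raise ValueError(
                        f"feature {f.feature_id!r} on unknown sequence "
                        f"{f.interval.chrom!r}"
                    )
                if f.interval.end > sequence_lengths[f.interval.chrom]:
                    raise ValueError(
                        f"feature {f.feature_id!r} extends past the end of "
                        f"{f.interval.chrom!r}"
                    )

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def by_type(self, feature_type: str) -> list[Feature]:
        return [f for f in self.features if f.feature_type == feature_type]

    def by_compartment(self, compartment: str) -> list[Feature]:
        return [f for f in self.features if f.compartment == compartment]

    def get(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)


class GenotypeTable:
    """Population genotypes: a site x individual matrix of codes
    (0 hom_ref, 1 het, 2 hom_alt, -1 missing) plus per-individual sex labels."""

    def __init__(self, sites: pd.DataFrame, genotypes: np.ndarray,
                 individuals: Sequence[str],
                 individual_sex: Mapping[str, str]):
        required = {"chrom", "pos", "ref", "alt"}
        if not required.issubset(sites.columns):
            raise ValueError(f"sites table needs columns {sorted(required)}")
        genotypes = np.asarray(genotypes, dtype=np.int8)
        if genotypes.shape != (len(sites), len(individuals)):
            raise ValueError(
                f"genotype matrix shape {genotypes.shape} does not match "
                f"{len(sites)} sites x {len(individuals)} individuals"
            )
        for ind in individuals:
            if ind not in individual_sex:
                raise ValueError(f"individual {ind!r} has no sex label")
            if individual_sex[ind] not in ("male", "female"):
                raise ValueError(
                    f"invalid sex {individual_sex[ind]!r} for {ind!r}"
                )
        self.sites = sites.reset_index(drop=True)
        self.genotypes = genotypes
        self.individuals = list(individuals)
        self.individual_sex = dict(individual_sex)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def sex_columns(self, sex: str) -> np.ndarray:
        return np.array(
            [i for i, ind in enumerate(self.individuals)
             if self.individual_sex[ind] == sex],
            dtype=int,
        )


# ---------------------------------------------------------------------------
# FASTA

def read_sequences(path: str | Path, sex_tag: str | None = None) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet` (residues uppercased)."""
    path = Path(path)
    records: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise ParseError(f"{path}: empty file (line 1)")
        if not first.startswith(">"):
            raise ParseError(f"{path}: line 1 is not a FASTA header")
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return SequenceSet(records, sex_tag=sex_tag)


def write_sequences(seqs: SequenceSet, path: str | Path,
                    line_width: int = 80) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="")
            for name, seq in seqs.records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLS = 9


def read_annotations(path: str | Path,
                     sequence_lengths: Mapping[str, int] | None = None
                     ) -> AnnotationSet:
    """Read a GFF3 file (1-based inclusive on disk) into an
    :class:`AnnotationSet` with 0-based half-open intervals.

    The compartment label is taken from a ``compartment=`` attribute when
    present, else ``none``.
    """
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _GFF_COLS:
                raise ParseError(
                    f"{path}: line {lineno}: expected {_GFF_COLS} columns, "
                    f"got {len(parts)}"
                )
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs \
                = parts
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if end1 < start1:
                raise ParseError(
                    f"{path}: line {lineno}: end < start ({end1} < {start1})"
                )
            attr_map = _parse_gff_attributes(attrs)
            fid = attr_map.get("ID")
            if fid is None:
                raise ParseError(f"{path}: line {lineno}: missing ID attribute")
            features.append(Feature(
                feature_id=fid,
                interval=GenomicInterval(chrom, start1 - 1, end1),
                strand=strand if strand in "+-" else ".",
                feature_type=ftype,
                compartment=attr_map.get("compartment", "none"),
            ))
    return AnnotationSet(features, sequence_lengths=sequence_lengths)


def _parse_gff_attributes(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attrs.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            key, value = item.split("=", 1)
            out[key] = value
    return out


def write_annotations(ann: AnnotationSet, path: str | Path,
                      source: str = "uvsdr") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in ann.features:
            attrs = f"ID={f.feature_id}"
            if f.compartment != "none":
                attrs += f";compartment={f.compartment}"
            fh.write("\t".join([
                f.interval.chrom, source, f.feature_type,
                str(f.interval.start + 1), str(f.interval.end),
                ".", f.strand, ".", attrs,
            ]) + "\n")


# ---------------------------------------------------------------------------
# VCF

def read_genotypes(path: str | Path,
                   sex_map: Mapping[str, str]) -> GenotypeTable:
    """Read biallelic SNPs (GT field) from a VCF into a
    :class:`GenotypeTable`.

    Multiallelic records are skipped with a logged count; ``./.`` becomes
    missing. Every sample must appear in ``sex_map``.
    """
    vf = pysam.VariantFile(str(path))
    individuals = list(vf.header.samples)
    for ind in individuals:
        if ind not in sex_map:
            raise ValueError(f"individual {ind!r} absent from sex map")
    rows = []
    codes = []
    n_multi = 0
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1:
            n_multi += 1
            continue
        row_codes = []
        for ind in individuals:
            gt = rec.samples[ind].get("GT")
            if gt is None or any(a is None for a in gt):
                row_codes.append(MISSING)
            else:
                row_codes.append(int(sum(gt)))
        rows.append((rec.chrom, rec.pos - 1, rec.ref, alts[0]))
        codes.append(row_codes)
    if n_multi:
        logger.info("skipped %d multiallelic VCF records", n_multi)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    genotypes = (np.array(codes, dtype=np.int8)
                 if codes else np.zeros((0, len(individuals)), dtype=np.int8))
    return GenotypeTable(sites, genotypes, individuals, sex_map)


def write_genotypes(gt: GenotypeTable, path: str | Path) -> None:
    """Write a minimal GT-only VCF (1-based positions on disk)."""
    gt_strings = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    chroms = list(dict.fromkeys(gt.sites["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gt.individuals) + "\n")
        for i in range(gt.n_sites):
            site = gt.sites.iloc[i]
            calls = "\t".join(gt_strings[int(c)] for c in gt.genotypes[i])
            fh.write(f"{site.chrom}\t{site.pos + 1}\t.\t{site.ref}\t"
                     f"{site.alt}\t.\tPASS\t.\tGT\t{calls}\n")


# ---------------------------------------------------------------------------
# Trees

def read_tree(path_or_string: str | Path) -> dendropy.Tree:
    """Read a rooted newick tree with branch lengths.

    Accepts a path or a literal newick string. A trifurcating root is
    rejected with instructions to root the tree first.
    """
    text = None
    p = Path(str(path_or_string))
    if p.exists():
        text = p.read_text()
    else:
        text = str(path_or_string)
    tree = dendropy.Tree.get(data=text, schema="newick")
    root_children = tree.seed_node.child_nodes()
    if len(root_children) > 2:
        raise ValueError(
            "tree root is a trifurcation; root the tree (2 children at the "
            "root) before use"
        )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length in tree")
    names = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(names) != len(set(names)):
        raise ValueError("duplicate tip names in tree")
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True)
    )


# ---------------------------------------------------------------------------
# Windows

def make_windows(lengths: Mapping[str, int], spec: WindowSpec) -> list[Window]:
    """Tile each sequence left to right with ``spec`` windows.

    A trailing window shorter than ``spec.width`` is kept and flagged
    ``partial``. When ``step == width`` the tiling covers every base exactly
    once.
    """
    windows: list[Window] = []
    for chrom, length in lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom!r}")
        start = 0
        while start < length:
            end = min(start + spec.width, length)
            windows.append(Window(chrom, start, end,
                                  partial=(end - start) < spec.width))
            start += spec.step
    return windows


def merge_adjacent(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge book-ended or overlapping intervals on the same sequence."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in by_chrom:
        ivs = sorted(by_chrom[chrom], key=lambda x: x.start)
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


# ---------------------------------------------------------------------------
# BED / TSV helpers

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED-like file (chrom, start, end[, value...]), 0-based
    half-open."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ParseError(f"{path}: BED needs at least 3 columns")
    cols = ["chrom", "start", "end"] + [
        f"value{i}" if i else "value" for i in range(df.shape[1] - 3)
    ]
    df.columns = cols[: df.shape[1]]
    return df


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              values: Sequence | None = None) -> None:
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            row = [iv.chrom, str(iv.start), str(iv.end)]
            if values is not None:
                row.append(str(values[i]))
            fh.write("\t".join(row) + "\n")
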