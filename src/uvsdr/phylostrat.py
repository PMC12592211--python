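"""Phylostratigraphy: relative gene ages from a homology hit table over an
ordered taxonomy ladder, and taxonomically restricted gene (TRG) flagging.

A gene's age is the oldest (rank-1 = most inclusive) stratum containing a
homology hit at or below the e-value threshold (default 1e-5); genes with no
qualifying hit outside the focal species fall in the youngest stratum R.
Higher ranks are younger ages. TRGs are genes whose age rank is at or above
a configurable cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


class TaxonomyLadder:
    """Ordered phylostrata, rank 1 = oldest to rank R = youngest (the focal
    species); each stratum is a disjoint set of subject taxa."""

    def __init__(self, strata: list[tuple[str, set[str]]]):
        if not strata:
            raise ValueError("empty ladder")
        self.strata = [(name, frozenset(taxa)) for name, taxa in strata]
        self.rank_of_taxon: dict[str, int] = {}
        for rank, (name, taxa) in enumerate(self.strata, start=1):
            for taxon in taxa:
                if taxon in self.rank_of_taxon:
                    raise ValueError(
                        f"taxon {taxon!r} appears in more than one stratum"
                    )
                self.rank_of_taxon[taxon] = rank

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    def name(self, rank: int) -> str:
        return self.strata[rank - 1][0]

    def focal_taxa(self) -> frozenset[str]:
        """Taxa of the youngest stratum (the focal species itself)."""
        return self.strata[-1][1]


def assign_gene_ages(hits: pd.DataFrame, ladder: TaxonomyLadder,
                     evalue_threshold: float = 1e-5,
                     genes: list[str] | None = None) -> pd.DataFrame:
    """Assign each gene the rank of the oldest stratum holding a qualifying
    hit (e-value <= threshold).

    Self-hits (taxa in the focal stratum) are ignored; genes without any
    qualifying external hit get rank R. ``genes`` optionally supplies the
    full gene universe (genes absent from the hit table then also get R).
    """
    required = {"gene", "taxon", "evalue"}
    if not required.issubset(hits.columns):
        raise ValueError(f"hit table needs columns {sorted(required)}")
    unknown = set(hits["taxon"]) - set(ladder.rank_of_taxon)
    if unknown:
        raise ValueError(f"hit taxa not in ladder: {sorted(unknown)}")
    focal = ladder.focal_taxa()
    R = ladder.n_strata
    qualifying = hits[(hits["evalue"] <= evalue_threshold)
                      & ~hits["taxon"].isin(focal)]
    ranks = qualifying["taxon"].map(ladder.rank_of_taxon)
    oldest = ranks.groupby(qualifying["gene"]).min()
    universe = list(genes) if genes is not None \
        else list(dict.fromkeys(hits["gene"]))
    rows = [(g, int(oldest.get(g, R))) for g in universe]
    out = pd.DataFrame(rows, columns=["gene", "age_rank"])
    out["stratum"] = out["age_rank"].map(lambda r: ladder.name(r))
    return out


def flag_trg(ages: pd.DataFrame, cutoff_rank: int,
             n_strata: int | None = None) -> pd.DataFrame:
    """Flag taxonomically restricted genes: TRG iff age_rank >= cutoff_rank."""
    R = n_strata if n_strata is not None else int(ages["age_rank"].max())
    if not (1 <= cutoff_rank <= R):
        raise ValueError(f"cutoff_rank must be in [1, {R}]")
    out = ages.copy()
    out["trg"] = out["age_rank"] >= cutoff_rank
    return out


def read_ladder_tsv(path) -> TaxonomyLadder:
    """Read a two-column TSV (stratum name, comma-separated taxa), oldest
    first."""
    strata: list[tuple[str, set[str]]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name, taxa = line.split("\t")
            strata.append((name, set(t for t in taxa.split(",") if t)))
    return TaxonomyLadder(strata)


def write_ladder_tsv(ladder: TaxonomyLadder, path) -> None:
    with open(path, "w") as fh:
        for name, taxa in ladder.strata:
            fh.write(f"{name}\t{','.join(sorted(taxa))}\n")
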