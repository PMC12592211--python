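"""Population statistics for the sex-chromosome search: per-scaffold
heterozygosity, the log10 male:female heterozygosity ratio, and between-sex
FST.

Sex-biased heterozygosity is expected to be ~0 on autosomal scaffolds and
elevated on young sex-linked scaffolds where males carry excess
heterozygosity (young-XY signal). FST uses the Weir & Cockerham (1984)
two-allele, two-population variance-component estimator; negative per-site
values are reported as computed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import HET, MISSING, GenotypeTable

logger = logging.getLogger(__name__)


def heterozygosity_fraction(gt: GenotypeTable,
                            scaffold_of: dict | None = None) -> pd.DataFrame:
    """Fraction of non-missing sites called heterozygous, per individual and
    scaffold.

    ``scaffold_of`` optionally remaps site chroms to scaffold groups.
    Individuals with no called site on a scaffold get NaN with a warning.
    """
    chroms = gt.sites["chrom"].to_numpy()
    if scaffold_of is not None:
        chroms = np.array([scaffold_of.get(c, c) for c in chroms])
    rows = []
    for scaffold in dict.fromkeys(chroms):
        mask = chroms == scaffold
        sub = gt.genotypes[mask]
        for j, ind in enumerate(gt.individuals):
            called = sub[:, j] != MISSING
            n_called = int(called.sum())
            if n_called == 0:
                logger.warning("no called sites for %s on %s", ind, scaffold)
                frac = math.nan
            else:
                frac = float((sub[called, j] == HET).sum() / n_called)
            rows.append((ind, gt.individual_sex[ind], scaffold, frac, n_called))
    return pd.DataFrame(
        rows, columns=["individual", "sex", "scaffold", "het_fraction",
                       "n_called"]
    )


def group_mean_heterozygosity(het: pd.DataFrame) -> pd.DataFrame:
    """Mean het fraction per scaffold for each sex (H_m, H_f)."""
    out = (het.pivot_table(index="scaffold", columns="sex",
                           values="het_fraction", aggfunc="mean")
           .rename(columns={"male": "H_m", "female": "H_f"})
           .reset_index())
    return out


def sex_biased_heterozygosity(h_m: float, h_f: float) -> float:
    """log10(H_m / H_f); 0 expected for autosomal scaffolds.

    H_f = 0 -> NaN (undefined); H_m = 0 with H_f > 0 -> -inf.
    """
    if h_m < 0 or h_f < 0:
        raise ValueError("heterozygosities must be >= 0")
    if h_f == 0:
        return math.nan
    if h_m == 0:
        return -math.inf
    return math.log10(h_m / h_f)


@dataclass
class FstResult:
    """Weir-Cockerham variance components per site and windowed ratio-of-sums
    theta."""

    per_site: pd.DataFrame  # chrom, pos, a, b, c, theta
    theta_overall: float
    n_skipped: int

    def windowed(self, windows) -> pd.DataFrame:
        """Ratio-of-sums theta per window."""
        rows = []
        ps = self.per_site
        for w in windows:
            sub = ps[(ps["chrom"] == w.chrom) & (ps["pos"] >= w.start)
                     & (ps["pos"] < w.end)]
            denom = (sub["a"] + sub["b"] + sub["c"]).sum()
            theta = float(sub["a"].sum() / denom) if denom > 0 else math.nan
            rows.append((w.chrom, w.start, w.end, theta, len(sub)))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "theta",
                                           "n_sites"])


def _site_components(gts: np.ndarray, cols_by_group: list[np.ndarray]
                     ) -> tuple[float, float, float] | None:
    """Weir & Cockerham (1984) a, b, c for one biallelic site, two groups.

    Returns None for skipped sites (underpopulated group or monomorphic).
    """
    r = len(cols_by_group)
    n_i, p_i, h_i = [], [], []
    for cols in cols_by_group:
        g = gts[cols]
        g = g[g != MISSING]
        if len(g) < 2:
            return None
        n_i.append(len(g))
        p_i.append(float((g).sum()) / (2 * len(g)))  # alt allele freq
        h_i.append(float((g == HET).sum()) / len(g))
    n_i = np.array(n_i, dtype=float)
    p_i = np.array(p_i)
    h_i = np.array(h_i)
    n_total = n_i.sum()
    p_bar = float((n_i * p_i).sum() / n_total)
    if p_bar in (0.0, 1.0):
        return None  # monomorphic across called individuals
    n_bar = n_total / r
    nc = (n_total - (n_i ** 2).sum() / n_total) / (r - 1)
    s2 = float((n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar))
    h_bar = float((n_i * h_i).sum() / n_total)
    a = (n_bar / nc) * (
        s2 - (1.0 / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4
        )
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - s2 * (r - 1) / r
        - h_bar * (2 * n_bar - 1) / (4 * n_bar)
    )
    c = h_bar / 2
    return a, b, c


def weir_cockerham_fst(gt: GenotypeTable,
                       groups: dict[str, list[str]] | None = None
                       ) -> FstResult:
    """Weir-Cockerham theta between two groups (default: male vs female).

    Per-site theta = a/(a+b+c); the overall value is the ratio of sums.
    Sites where a group has < 2 called individuals, or that are monomorphic
    among called individuals, are skipped and counted.
    """
    if groups is None:
        groups = {
            "male": [i for i in gt.individuals
                     if gt.individual_sex[i] == "male"],
            "female": [i for i in gt.individuals
                       if gt.individual_sex[i] == "female"],
        }
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    col_of = {ind: j for j, ind in enumerate(gt.individuals)}
    cols_by_group = [np.array([col_of[i] for i in members], dtype=int)
                     for members in groups.values()]
    rows = []
    n_skipped = 0
    for s in range(gt.n_sites):
        comp = _site_components(gt.genotypes[s], cols_by_group)
        if comp is None:
            n_skipped += 1
            continue
        a, b, c = comp
        denom = a + b + c
        theta = a / denom if denom != 0 else math.nan
        rows.append((gt.sites.at[s, "chrom"], gt.sites.at[s, "pos"],
                     a, b, c, theta))
    per_site = pd.DataFrame(rows,
                            columns=["chrom", "pos", "a", "b", "c", "theta"])
    denom = (per_site["a"] + per_site["b"] + per_site["c"]).sum()
    overall = float(per_site["a"].sum() / denom) if denom > 0 else math.nan
    if n_skipped:
        logger.info("skipped %d sites (underpopulated or monomorphic)",
                    n_skipped)
    return FstResult(per_site, overall, n_skipped)


def scaffold_summary(gt: GenotypeTable) -> pd.DataFrame:
    """Per-scaffold H_m, H_f, sex-biased heterozygosity and W&C theta."""
    het = group_mean_heterozygosity(heterozygosity_fraction(gt))
    rows = []
    for rec in het.itertuples():
        scaffold = rec.scaffold
        mask = (gt.sites["chrom"] == scaffold).to_numpy()
        sub = GenotypeTable(gt.sites[mask], gt.genotypes[mask],
                            gt.individuals, gt.individual_sex)
        fst = weir_cockerham_fst(sub)
        rows.append((scaffold, rec.H_m, rec.H_f,
                     sex_biased_heterozygosity(rec.H_m, rec.H_f),
                     fst.theta_overall))
    return pd.DataFrame(rows, columns=["scaffold", "H_m", "H_f",
                                       "sex_biased_het", "theta"])
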