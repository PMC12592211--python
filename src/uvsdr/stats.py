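"""Window feature densities and the comparative statistical battery:
two-sided Wilcoxon rank-sum, Benjamini-Hochberg FDR, seeded permutation
tests, chi-square orthologue-depletion, Pearson standardized residuals,
OLS R-squared, PAR enrichment of sex-biased genes, and the transcriptional
activity threshold log2(TPM + 1) > 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core_io import AnnotationSet, Window


@dataclass(frozen=True)
class EnrichmentConfig:
    n_perm: int = 10_000
    fdr_alpha: float = 0.05
    residual_threshold: float = 2.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class TestResult:
    statistic: float
    p: float
    n_a: int
    n_b: int
    p_adj: float | None = None


# ---------------------------------------------------------------------------
# Window feature densities

def window_feature_density(ann: AnnotationSet, windows: list[Window],
                           feature_type: str) -> pd.DataFrame:
    """Fraction of each window covered by (unioned) features of one type."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in ann.by_type(feature_type):
        by_chrom.setdefault(f.interval.chrom, []).append(
            (f.interval.start, f.interval.end)
        )
    merged: dict[str, np.ndarray] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = []
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((cur_s, cur_e))
        merged[chrom] = np.array(out)
    rows = []
    for w in windows:
        ivs = merged.get(w.chrom)
        covered = 0
        if ivs is not None:
            starts = np.maximum(ivs[:, 0], w.start)
            ends = np.minimum(ivs[:, 1], w.end)
            covered = int(np.maximum(ends - starts, 0).sum())
        rows.append((w.chrom, w.start, w.end, covered / len(w)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "density"])


# ---------------------------------------------------------------------------
# Tests

def wilcoxon_rank_sum(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U): exact null when
    min(n) <= 8 without ties, else normal approximation with tie and
    continuity corrections."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult(float(res.statistic), float(res.pvalue), len(a), len(b))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept)."""
    pvals = np.asarray(pvals, dtype=float)
    if len(pvals) == 0:
        return pvals
    if ((pvals <= 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def permutation_test(values, labels, cfg: EnrichmentConfig = EnrichmentConfig(),
                     ) -> TestResult:
    """Two-sided label-permutation test on the difference of group means.

    p = (#{|stat*| >= |stat_obs|} + 1) / (n_perm + 1), never exactly zero.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two labels required")
    mask = labels == uniq[0]
    n_a, n_b = int(mask.sum()), int((~mask).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("one group is empty")
    obs = values[mask].mean() - values[~mask].mean()
    rng = np.random.default_rng(cfg.seed)
    n = len(values)
    count = 0
    chunk = max(1, min(cfg.n_perm, int(2e7) // max(n, 1)))
    done = 0
    while done < cfg.n_perm:
        m = min(chunk, cfg.n_perm - done)
        perm = rng.permuted(np.tile(values, (m, 1)), axis=1)
        stat = perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1)
        count += int((np.abs(stat) >= abs(obs) - 1e-12).sum())
        done += m
    p = (count + 1) / (cfg.n_perm + 1)
    return TestResult(float(obs), float(p), n_a, n_b)


def orthologue_depletion_test(observed: dict[str, int],
                              genes: dict[str, int]) -> pd.DataFrame:
    """Per-chromosome chi-square of observed vs expected one-to-one
    orthologue counts, expected proportional to gene content; BH-corrected
    across chromosomes."""
    chroms = list(observed)
    if set(chroms) != set(genes):
        raise ValueError("observed and gene tables cover different chromosomes")
    total_obs = sum(observed.values())
    total_genes = sum(genes.values())
    if total_obs <= 0 or total_genes <= 0:
        raise ValueError("totals must be positive")
    rows = []
    for chrom in chroms:
        expected = total_obs * genes[chrom] / total_genes
        other_obs = total_obs - observed[chrom]
        other_exp = total_obs - expected
        stat, p = sps.chisquare([observed[chrom], other_obs],
                                [expected, other_exp])
        rows.append((chrom, observed[chrom], expected, float(stat), float(p)))
    df = pd.DataFrame(rows, columns=["chrom", "observed", "expected",
                                     "chi2", "p"])
    df["p_adj"] = bh_fdr(df["p"].to_numpy())
    return df


def pearson_std_residuals(table: np.ndarray,
                          residual_threshold: float = 2.4
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Pearson standardized (adjusted) residuals of a contingency table and
    flags where |r| exceeds the threshold."""
    table = np.asarray(table, dtype=float)
    grand = table.sum()
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / grand
    if (expected <= 0).any():
        raise ValueError("all expected cells must be > 0")
    denom = np.sqrt(expected * (1 - row / grand) * (1 - col / grand))
    residuals = (table - expected) / denom
    return residuals, np.abs(residuals) > residual_threshold


def linreg_r2(x, y) -> float:
    """OLS R-squared; NaN (with no fit) when y is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.var(x) == 0:
        raise ValueError("x is constant")
    if np.var(y) == 0:
        import warnings

        warnings.warn("y is constant; R^2 undefined", stacklevel=2)
        return math.nan
    res = sps.linregress(x, y)
    return float(res.rvalue ** 2)


def sbg_compartment_enrichment(table: np.ndarray,
                               continuity: bool = False) -> TestResult:
    """Chi-square independence test on a 2x2 (male-biased vs other) x
    (PAR vs non-PAR) count table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    stat, p, _dof, _exp = sps.chi2_contingency(table, correction=continuity)
    return TestResult(float(stat), float(p),
                      int(table[0].sum()), int(table[1].sum()))


def expression_active(tpm: float) -> bool:
    """Transcriptionally active iff log2(TPM + 1) > 2 (strict)."""
    if tpm < 0:
        raise ValueError("TPM must be >= 0")
    return math.log2(tpm + 1.0) > 2.0


# ---------------------------------------------------------------------------
# Compartment / chromosome batteries

def autosome_vs_sex_chromosome(features: pd.DataFrame, value_col: str,
                               sex_chrom: str) -> pd.DataFrame:
    """Wilcoxon contrast of each autosome against the sex chromosome for one
    window feature, BH-corrected across autosomes."""
    sex_vals = features.loc[features["chrom"] == sex_chrom, value_col].dropna()
    rows = []
    for chrom in dict.fromkeys(features["chrom"]):
        if chrom == sex_chrom:
            continue
        vals = features.loc[features["chrom"] == chrom, value_col].dropna()
        res = wilcoxon_rank_sum(vals, sex_vals)
        rows.append((chrom, res.statistic, res.p, len(vals), len(sex_vals)))
    df = pd.DataFrame(rows, columns=["chrom", "U", "p", "n_autosome",
                                     "n_sex_chrom"])
    df["p_adj"] = bh_fdr(df["p"].to_numpy())
    return df


def compartment_permutation_tests(values: pd.Series, compartments: pd.Series,
                                  cfg: EnrichmentConfig = EnrichmentConfig()
                                  ) -> pd.DataFrame:
    """Pairwise permutation tests of a window/gene feature between genomic
    compartments (SDR, PAR, autosome), BH-corrected."""
    values = values.to_numpy(dtype=float)
    compartments = compartments.to_numpy()
    keep = ~np.isnan(values)
    values, compartments = values[keep], compartments[keep]
    names = list(dict.fromkeys(compartments))
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            mask = (compartments == a) | (compartments == b)
            res = permutation_test(values[mask],
                                   (compartments[mask] == a).astype(int), cfg)
            rows.append((a, b, res.statistic, res.p, res.n_a, res.n_b))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "p",
                                     "n_a", "n_b"])
    if len(df):
        df["p_adj"] = bh_fdr(df["p"].to_numpy())
    return df
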