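"""End-to-end orchestration: simulate a study system and run every analysis
stage against its ground truth.

``run_demo`` executes simulate -> k-mer scan -> coverage scan -> population
statistics -> gametologues -> ancestral reconstruction -> phylostratigraphy
-> compartment statistics and returns a report comparing calls to truth
(SDR recovery F1 at window resolution, k-mer/coverage agreement, Ks
recovery, rate recovery, age recovery, enrichment tests). All randomness
descends from the single config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestral, coverage, gametologs, kmer, phylostrat, popgen, \
    simulate, stats
from .core_io import (
    GenomicInterval,
    SequenceSet,
    Window,
    WindowSpec,
    make_windows,
    merge_adjacent,
    write_bed,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    simulation: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig
    )
    kmer: kmer.KmerConfig = field(default_factory=kmer.KmerConfig)
    coverage: coverage.CoverageClassifierConfig = field(
        default_factory=coverage.CoverageClassifierConfig
    )
    enrichment: stats.EnrichmentConfig = field(
        default_factory=stats.EnrichmentConfig
    )
    kmer_window: int = 500_000
    coverage_window: int = 10_000
    density_window: int = 100_000
    fit_restarts: int = 5

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(klass, block):
            valid = klass.__dataclass_fields__
            unknown = set(block) - set(valid)
            if unknown:
                raise ValueError(f"unknown {klass.__name__} fields "
                                 f"{sorted(unknown)}")
            return klass(**block)

        kwargs = {}
        for key, klass in (
            ("simulation", simulate.SimulationConfig),
            ("kmer", kmer.KmerConfig),
            ("coverage", coverage.CoverageClassifierConfig),
            ("enrichment", stats.EnrichmentConfig),
        ):
            if key in raw:
                kwargs[key] = build(klass, raw[key])
        for key in ("kmer_window", "coverage_window", "density_window",
                    "fit_restarts"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Interval comparison helpers

def _window_set(intervals: list[GenomicInterval],
                windows: list[Window]) -> set[int]:
    out = set()
    for i, w in enumerate(windows):
        for iv in intervals:
            if w.overlaps(iv):
                out.add(i)
                break
    return out


def window_f1(called: list[GenomicInterval], truth: list[GenomicInterval],
              windows: list[Window]) -> float:
    """F1 of called vs true intervals at window resolution."""
    called_set = _window_set(called, windows)
    truth_set = _window_set(truth, windows)
    tp = len(called_set & truth_set)
    if tp == 0:
        return 0.0
    precision = tp / len(called_set)
    recall = tp / len(truth_set)
    return 2 * precision * recall / (precision + recall)


def interval_jaccard(a: list[GenomicInterval],
                     b: list[GenomicInterval]) -> float:
    """Base-pair Jaccard index between two merged interval sets."""
    a = merge_adjacent(a) if a else []
    b = merge_adjacent(b) if b else []
    inter = 0
    for iv in a:
        for jv in b:
            if iv.overlaps(jv):
                inter += min(iv.end, jv.end) - max(iv.start, jv.start)
    union = sum(len(iv) for iv in a) + sum(len(jv) for jv in b) - inter
    return inter / union if union else 0.0


# ---------------------------------------------------------------------------

def run_demo(cfg: PipelineConfig | None = None,
             outdir: str | Path | None = None) -> dict:
    """Run the full synthetic demonstration and return the report."""
    cfg = cfg or PipelineConfig()
    sim = cfg.simulation
    report: dict = {"seed": sim.seed}

    logger.info("stage 1/8: simulating genome pair")
    male, female, ann_m, ann_f, truth = simulate.simulate_genome_pair(sim)
    logger.info("stage 1/8: simulating reads at %.0fx", sim.depth)
    male_reads, _ = simulate.simulate_reads(
        male, sim.depth, sim.read_len, sim.error_rate, sim.seed * 8 + 1)
    female_reads, _ = simulate.simulate_reads(
        female, sim.depth, sim.read_len, sim.error_rate, sim.seed * 8 + 2)

    # --- k-mer scan: male reference vs female read k-mers
    logger.info("stage 2/8: YGS k-mer scan")
    kwindows = make_windows(male.lengths(), WindowSpec(cfg.kmer_window))
    opp = kmer.count_read_kmers(female_reads, cfg.kmer)
    scores = kmer.ygs_score_windows(male, kwindows, opp, cfg.kmer)
    kmer_calls = kmer.call_candidate_windows(scores)
    report["kmer"] = {
        "n_candidate_intervals": len(kmer_calls),
        "sdr_f1": window_f1(kmer_calls, truth.sdr_bed["male"], kwindows),
        "min_sdr_window_pct": min(
            (s.pct_unmatched for s in scores
             if s.n_single_copy and any(s.window.overlaps(iv)
                                        for iv in truth.sdr_bed["male"])),
            default=float("nan"),
        ),
        "max_autosomal_pct": max(
            (s.pct_unmatched for s in scores
             if s.window.chrom != simulate.UV_CHROM and s.n_single_copy),
            default=0.0,
        ),
    }

    # --- coverage scan on the male assembly
    logger.info("stage 3/8: coverage scan")
    cwindows = make_windows(male.lengths(), WindowSpec(cfg.coverage_window))
    male_depth = coverage.window_depth_from_reads(
        male, male_reads, cwindows, sample="male_pool", sex="male")
    female_depth = coverage.window_depth_from_reads(
        male, female_reads, cwindows, sample="female_pool", sex="female")
    norm_m = coverage.normalize_by_genome_mean(male_depth)
    norm_f = coverage.normalize_by_genome_mean(female_depth)
    classified = coverage.classify_windows(
        norm_m.sex_mean("male"), norm_f.sex_mean("female"), cfg.coverage)
    cov_calls = coverage.candidate_intervals(classified)
    sdr_mask = classified.apply(
        lambda r: any(GenomicInterval(r.chrom, int(r.start), int(r.end))
                      .overlaps(iv) for iv in truth.sdr_bed["male"]),
        axis=1,
    ).to_numpy()
    report["coverage"] = {
        "sdr_f1": window_f1(cov_calls, truth.sdr_bed["male"], cwindows),
        "jaccard_with_kmer": interval_jaccard(kmer_calls, cov_calls),
        "female_norm_sdr_pct": 100.0 * float(
            classified.loc[sdr_mask, "female_norm"].mean()),
        "male_norm_sdr_pct": 100.0 * float(
            classified.loc[sdr_mask, "male_norm"].mean()),
        "log2_mf_sdr": coverage.log2_fold_change(
            float(classified.loc[sdr_mask, "male_norm"].mean()),
            float(classified.loc[sdr_mask, "female_norm"].mean()),
            pseudocount=1e-3,
        ),
        "n_false_positive_windows": int(
            (~sdr_mask & (classified["label"] != coverage.UNCLASSIFIED)).sum()
        ),
    }

    # --- population statistics
    logger.info("stage 4/8: population statistics")
    gt = simulate.simulate_population_genotypes(sim, seed=sim.seed * 8 + 3)
    summary = popgen.scaffold_summary(gt)
    sex_scaffold = f"scaffold_{sim.n_scaffolds}"
    auto = summary[summary["scaffold"] != sex_scaffold]
    sexrow = summary[summary["scaffold"] == sex_scaffold].iloc[0]
    report["popgen"] = {
        "autosomal_sex_biased_het_max_abs": float(
            auto["sex_biased_het"].abs().max()),
        "autosomal_theta_max_abs": float(auto["theta"].abs().max()),
        "sex_scaffold_sex_biased_het": float(sexrow["sex_biased_het"]),
        "sex_scaffold_theta": float(sexrow["theta"]),
    }

    # --- gametologues
    logger.info("stage 5/8: gametologue Ks")
    def cds_of(genome: SequenceSet, ann, compartment="SDR"):
        return {
            f.feature_id: genome[f.interval.chrom][f.interval.start:
                                                   f.interval.end]
            for f in ann.by_type("gene") if f.compartment == compartment
        }

    cds_m = cds_of(male, ann_m)
    cds_f = cds_of(female, ann_f)
    prot_m = {g: gametologs.translate_cds(c) for g, c in cds_m.items()}
    prot_f = {g: gametologs.translate_cds(c) for g, c in cds_f.items()}
    pairs = gametologs.reciprocal_best_hits(prot_m, prot_f)
    true_pairs = {(m, f) for m, f, _ in truth.true_pairs}
    found = {(m, f) for m, f, _ in pairs} & true_pairs
    ks_values = []
    for m, f, _score in pairs:
        if (m, f) in true_pairs:
            res = gametologs.kaks_for_cds_pair(cds_m[m], cds_f[f])
            ks_values.append(res.Ks)
    classes = gametologs.classify_sdr_genes(
        sorted(cds_m), sorted(cds_f), pairs)
    truth_class = {
        g: ("gametologue" if any(g in p[:2] for p in truth.true_pairs)
            else "sex_specific")
        for g in list(cds_m) + list(cds_f)
    }
    class_ok = all(truth_class[r.gene] == r._3 for r in
                   classes.itertuples())  # _3 = class column
    report["gametologs"] = {
        "n_true_pairs": len(true_pairs),
        "n_recovered_pairs": len(found),
        "mean_ks": float(np.nanmean(ks_values)) if ks_values else None,
        "target_ks": sim.target_ks,
        "classification_correct": bool(class_ok),
    }

    # --- ancestral reconstruction
    logger.info("stage 6/8: ancestral gain/loss reconstruction")
    tree = simulate.default_species_tree()
    index = ancestral.TreeIndex(tree)
    matrix, node_truth = simulate.simulate_family_evolution(
        index, sim.gain_rate, sim.loss_rate, sim.gamma_shape,
        sim.n_families, seed=sim.seed * 8 + 4,
        n_categories=sim.n_categories)
    model, loglik = ancestral.fit_gain_loss(
        index, matrix, n_categories=sim.n_categories,
        restarts=cfg.fit_restarts, seed=sim.seed * 8 + 5)
    posteriors = ancestral.ancestral_posteriors(index, matrix, model)
    expected = ancestral.expected_gene_count(posteriors)
    true_counts = {
        lab: sum(node_truth[(f"fam{f}", lab)] for f in range(sim.n_families))
        for lab in index.labels
    }
    internal = [lab for i, lab in enumerate(index.labels)
                if not index.is_tip[i]]
    rel_err = [
        abs(expected[lab] - true_counts[lab]) / max(true_counts[lab], 1)
        for lab in internal
    ]
    report["ancestral"] = {
        "gain_hat": model.gain, "loss_hat": model.loss,
        "alpha_hat": model.gamma_shape,
        "gain_rel_err": abs(model.gain - sim.gain_rate) / sim.gain_rate,
        "loss_rel_err": abs(model.loss - sim.loss_rate) / sim.loss_rate,
        "log_likelihood": loglik,
        "max_internal_count_rel_err": float(max(rel_err)),
    }

    # --- phylostratigraphy
    logger.info("stage 7/8: phylostratigraphy")
    hits, true_ages, ladder = simulate.simulate_homology_table(
        sim.n_genes, sim.n_strata, sim.stratum_proportions,
        seed=sim.seed * 8 + 6)
    ages = phylostrat.assign_gene_ages(hits, ladder)
    recovered = all(true_ages[r.gene] == r.age_rank
                    for r in ages.itertuples())
    report["phylostrat"] = {
        "n_genes": len(ages),
        "ages_recovered_exactly": bool(recovered),
    }

    # --- compartment statistics on the male assembly
    logger.info("stage 8/8: compartment statistics")
    dwindows = make_windows(male.lengths(), WindowSpec(cfg.density_window))
    cds_density = stats.window_feature_density(ann_m, dwindows, "gene")
    rep_density = stats.window_feature_density(ann_m, dwindows, "repeat")
    compartment = []
    sdr_iv = truth.sdr_bed["male"]
    for w in dwindows:
        if w.chrom != simulate.UV_CHROM:
            compartment.append("autosome")
        elif any(w.overlaps(iv) for iv in sdr_iv):
            compartment.append("SDR")
        else:
            compartment.append("PAR")
    rep_density["compartment"] = compartment
    perm = stats.compartment_permutation_tests(
        rep_density["density"], rep_density["compartment"], cfg.enrichment)
    wil = stats.autosome_vs_sex_chromosome(
        pd.concat([rep_density], axis=0), "density", simulate.UV_CHROM)
    sdr_vs_auto = perm[((perm["group_a"] == "SDR")
                        & (perm["group_b"] == "autosome"))
                       | ((perm["group_a"] == "autosome")
                          & (perm["group_b"] == "SDR"))]
    report["stats"] = {
        "sdr_vs_autosome_repeat_perm_p_adj": float(
            sdr_vs_auto["p_adj"].iloc[0]),
        "min_wilcoxon_p_adj_repeat": float(wil["p_adj"].min()),
        "mean_repeat_density_sdr": float(
            rep_density.loc[rep_density["compartment"] == "SDR",
                            "density"].mean()),
        "mean_repeat_density_autosome": float(
            rep_density.loc[rep_density["compartment"] == "autosome",
                            "density"].mean()),
        "mean_cds_density": float(cds_density["density"].mean()),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_bed(kmer_calls, outdir / "kmer_candidates.bed")
        write_bed(cov_calls, outdir / "coverage_candidates.bed")
        pd.DataFrame(
            [(s.window.chrom, s.window.start, s.window.end, s.n_single_copy,
              s.n_unmatched, s.pct_unmatched) for s in scores],
            columns=["chrom", "start", "end", "n_single_copy", "n_unmatched",
                     "pct_unmatched"],
        ).to_csv(outdir / "ygs_scores.tsv", sep="\t", index=False)
        classified.to_csv(outdir / "coverage_classified.tsv", sep="\t",
                          index=False)
        summary.to_csv(outdir / "popgen_scaffolds.tsv", sep="\t", index=False)
        posteriors.to_csv(outdir / "ancestral_posteriors.tsv", sep="\t")
        ages.to_csv(outdir / "gene_ages.tsv", sep="\t", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
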