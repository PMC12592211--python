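"""Find a sex-determining region with the k-mer and coverage scans.

Builds a small male/female genome pair (600 kb each, 100-kb V-SDR),
simulates 12x error-free reads, and runs both SDR detectors on the male
assembly: the YGS scan scores windows by the % of single-copy 15-mers
absent from female reads (>= 50% retained), and the coverage scan flags
windows where male depth is 75-125% of the male genome average while
female depth is below 50% of hers. Both should point at the same interval
as the simulated truth.
"""

from uvsdr import coverage, kmer, simulate
from uvsdr.core_io import WindowSpec, make_windows

cfg = simulate.SimulationConfig(
    seed=7, n_autosomes=2, autosome_len=200_000, uv_len=200_000,
    sdr_start=50_000, sdr_len=100_000, n_gametologues=4, n_sex_specific=2,
    n_autosomal_genes=16, n_par_genes=6, depth=12.0,
)
male, female, ann_m, ann_f, truth = simulate.simulate_genome_pair(cfg)
male_reads, _ = simulate.simulate_reads(male, cfg.depth, cfg.read_len, 0.0, 71)
female_reads, _ = simulate.simulate_reads(female, cfg.depth, cfg.read_len,
                                          0.0, 72)

print(f"true V-SDR: {truth.sdr_bed['male'][0]}")

# --- YGS k-mer subtraction: male windows vs female read k-mers
windows = make_windows(male.lengths(), WindowSpec(50_000))
opp = kmer.count_read_kmers(female_reads)
scores = kmer.ygs_score_windows(male, windows, opp)
print("\nYGS scan (% single-copy 15-mers unmatched in female reads):")
for s in scores:
    if s.window.chrom == "chrUV":
        print(f"  chrUV:{s.window.start:>7}-{s.window.end:<7}"
              f" {s.pct_unmatched:6.2f}%")
calls = kmer.call_candidate_windows(scores)
print(f"candidate SDR from k-mers: {calls}")

# --- coverage classification
cw = make_windows(male.lengths(), WindowSpec(10_000))
norm = {}
for sex, reads in (("male", male_reads), ("female", female_reads)):
    depth = coverage.window_depth_from_reads(male, reads, cw,
                                             sample=sex, sex=sex)
    norm[sex] = coverage.normalize_by_genome_mean(depth).sex_mean(sex)
classified = coverage.classify_windows(norm["male"], norm["female"])
v_calls = coverage.candidate_intervals(classified)
print(f"candidate SDR from coverage: {v_calls}")
print("\nWindows where female coverage collapses while male coverage is "
      "normal are V-SDR candidates; both detectors should match the truth "
      "interval above.")
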