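"""Synthetic study system: male/female genome pairs with a non-recombining
SDR, sexed read sets, population genotypes with young-XY signal, gene-family
presence/absence evolved on a species tree, and homology tables with known
phylostratum labels — each with the ground truth the downstream analyses are
judged against.

The default configuration is the package's study condition: 10-Mb haploid
genomes (four 2-Mb autosomes plus a 2-Mb U/V chromosome whose central
500-kb SDR haplotypes are mutually non-homologous random sequences flanked
by shared PARs), 15x error-free 100-bp reads per sex, gametologue CDS pairs
diverged at synonymous sites to a target Ks, 12 diploid individuals per sex
with fully heterozygous males at young sex-linked sites, and 500 families
evolved under gain 0.5 / loss 1.0 with gamma(1) rate variation on a 6-tip
dated tree. All randomness flows from one integer seed; identical config +
seed gives byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from ._encode import codes_to_seq, seq_to_codes
from .ancestral import GainLossModel, TreeIndex, discretize_gamma, \
    transition_matrix
from .core_io import (
    HET,
    HOM_ALT,
    HOM_REF,
    AnnotationSet,
    Feature,
    GenomicInterval,
    GenotypeTable,
    SequenceSet,
    read_tree,
)
from .gametologs import CODON_TABLE, SENSE_CODONS, STOP_CODONS
from .phylostrat import TaxonomyLadder
from .reads import ReadSet

UV_CHROM = "chrUV"

#: default dated species tree for family evolution (time in arbitrary units)
DEFAULT_TREE_NEWICK = (
    "(((sp1:0.3,sp2:0.3):0.4,(sp3:0.5,sp4:0.5):0.2):0.3,"
    "(sp5:0.6,sp6:0.6):0.4);"
)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_autosomes: int = 4
    autosome_len: int = 2_000_000
    uv_len: int = 2_000_000
    sdr_start: int = 500_000
    sdr_len: int = 500_000
    n_gametologues: int = 12
    target_ks: float = 0.75
    n_sex_specific: int = 8
    cds_len: int = 1_500
    n_autosomal_genes: int = 120
    n_par_genes: int = 30
    te_density: dict = field(default_factory=lambda: {
        "autosome": 0.08, "PAR": 0.08, "SDR": 0.20,
    })
    te_motif_len: int = 500
    n_te_motifs: int = 20
    read_len: int = 100
    depth: float = 15.0
    error_rate: float = 0.0
    n_individuals: int = 12          # per sex
    n_sites: int = 3_000
    n_scaffolds: int = 6
    autosomal_het: float = 0.3
    n_sexlinked_sites: int = 30
    gain_rate: float = 0.5
    loss_rate: float = 1.0
    gamma_shape: float = 1.0
    n_categories: int = 10
    n_families: int = 500
    n_genes: int = 300               # phylostratigraphy genes
    n_strata: int = 8
    stratum_proportions: tuple | None = None

    def __post_init__(self) -> None:
        if self.depth < 0 or self.error_rate < 0 or self.target_ks < 0:
            raise ValueError("rates and depths must be >= 0")
        if self.sdr_len > 0 and not (
            0 <= self.sdr_start
            and self.sdr_start + self.sdr_len <= self.uv_len
        ):
            raise ValueError("SDR interval outside the U/V chromosome")

    @property
    def sdr_interval(self) -> GenomicInterval | None:
        if self.sdr_len == 0:
            return None
        return GenomicInterval(UV_CHROM, self.sdr_start,
                               self.sdr_start + self.sdr_len)


@dataclass
class TruthSet:
    """Ground truth emitted alongside the synthetic data."""

    sdr_bed: dict[str, list[GenomicInterval]]
    gene_compartments: dict[str, str]
    true_pairs: list[tuple[str, str, float]]
    node_states: dict | None = None
    true_ages: dict | None = None
    per_base_depth: dict | None = None


# ---------------------------------------------------------------------------
# Genome pair

def _random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def _random_cds_codes(rng: np.random.Generator, n_codons: int) -> np.ndarray:
    codons = rng.choice(len(SENSE_CODONS), size=n_codons)
    seq = "".join(SENSE_CODONS[i] for i in codons)
    return seq_to_codes(seq)


_SYN_ALTS: dict[tuple[str, int], str] = {}
for _codon in SENSE_CODONS:
    for _pos in range(3):
        alts = [b for b in "ACGT"
                if b != _codon[_pos]
                and CODON_TABLE.get(_codon[:_pos] + b + _codon[_pos + 1:])
                == CODON_TABLE[_codon]]
        _SYN_ALTS[(_codon, _pos)] = "".join(alts)


def _diverge_synonymously(cds_codes: np.ndarray, target_ks: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Substitute synonymous sites so the expected NG86 ps equals the
    Jukes-Cantor probability for ``target_ks``.

    At every site a substitution is proposed with probability
    q = 3/4 (1 - e^{-4/3 Ks}) to a uniform alternative base and accepted only
    if the codon's amino acid is unchanged, so E[Sd] = q * S and the
    JC-corrected Ks recovers the target in expectation.
    """
    if target_ks == 0:
        return cds_codes.copy()
    q = 0.75 * (1.0 - math.exp(-4.0 / 3.0 * target_ks))
    seq = list(codes_to_seq(cds_codes))
    hit = rng.random(len(seq)) < q
    choice = rng.random(len(seq))
    for i in np.nonzero(hit)[0]:
        codon_start = 3 * (i // 3)
        codon = "".join(seq[codon_start:codon_start + 3])
        pos = i - codon_start
        alts = [b for b in "ACGT" if b != codon[pos]]
        base = alts[int(choice[i] * 3)]
        if base in _SYN_ALTS.get((codon, pos), ""):
            seq[i] = base
    return seq_to_codes("".join(seq))


def _place_nonoverlapping(rng: np.random.Generator, region_len: int,
                          sizes: list[int], max_tries: int = 2000
                          ) -> list[int]:
    """Greedy random non-overlapping placement of blocks in [0, region_len)."""
    placed: list[tuple[int, int]] = []
    out: list[int] = []
    for size in sizes:
        if size > region_len:
            raise ValueError("feature longer than its region")
        for _ in range(max_tries):
            start = int(rng.integers(0, region_len - size + 1))
            if all(start + size <= s or start >= e for s, e in placed):
                placed.append((start, start + size))
                out.append(start)
                break
        else:
            raise RuntimeError("could not place features without overlap; "
                               "reduce density")
    return out


def simulate_genome_pair(cfg: SimulationConfig
                         ) -> tuple[SequenceSet, SequenceSet, AnnotationSet,
                                    AnnotationSet, TruthSet]:
    """Generate a male and a female haploid genome sharing autosomes and
    PARs but carrying mutually non-homologous SDR haplotypes.

    Gametologue CDS pairs sit in both SDRs with synonymous divergence at
    ``target_ks``; sex-specific genes sit in one SDR only; TE motif copies
    are pasted at the per-compartment densities (identically between sexes
    outside the SDRs). Returns (male genome, female genome, male annotation,
    female annotation, truth).
    """
    rng = np.random.default_rng(cfg.seed)
    chroms: dict[str, np.ndarray] = {}
    for i in range(cfg.n_autosomes):
        chroms[f"chr{i + 1}"] = _random_codes(rng, cfg.autosome_len)
    uv_shared = _random_codes(rng, cfg.uv_len)
    sdr = cfg.sdr_interval

    motifs = [_random_codes(rng, cfg.te_motif_len)
              for _ in range(cfg.n_te_motifs)]

    male: dict[str, np.ndarray] = {}
    female: dict[str, np.ndarray] = {}
    feats_m: list[Feature] = []
    feats_f: list[Feature] = []
    gene_compartments: dict[str, str] = {}

    def paste_tes(seq: np.ndarray, lo: int, hi: int, density: float,
                  prefix: str, feats: list[list], rng_: np.random.Generator
                  ) -> None:
        span = hi - lo
        if span < cfg.te_motif_len:
            return
        n_copies = int(density * span / cfg.te_motif_len)
        if n_copies == 0:
            return
        starts = rng_.integers(lo, hi - cfg.te_motif_len + 1, size=n_copies)
        which = rng_.integers(0, cfg.n_te_motifs, size=n_copies)
        for j, (s, m) in enumerate(zip(starts, which)):
            seq[s:s + cfg.te_motif_len] = motifs[m]
            feats.append([f"{prefix}_te{j}", int(s), int(s) + cfg.te_motif_len])

    # --- autosomes: TEs then genes, shared between sexes
    shared_feats: list[tuple[str, str, int, int, str, str]] = []
    for i in range(cfg.n_autosomes):
        chrom = f"chr{i + 1}"
        te_rows: list[list] = []
        paste_tes(chroms[chrom], 0, cfg.autosome_len,
                  cfg.te_density.get("autosome", 0.0), chrom, te_rows, rng)
        for fid, s, e in te_rows:
            shared_feats.append((fid, chrom, s, e, "repeat", "autosome"))
    n_per_auto = cfg.n_autosomal_genes // max(cfg.n_autosomes, 1)
    for i in range(cfg.n_autosomes):
        chrom = f"chr{i + 1}"
        starts = _place_nonoverlapping(rng, cfg.autosome_len,
                                       [cfg.cds_len] * n_per_auto)
        for j, s in enumerate(starts):
            cds = _random_cds_codes(rng, cfg.cds_len // 3)
            chroms[chrom][s:s + len(cds)] = cds
            fid = f"{chrom}_gene{j}"
            shared_feats.append((fid, chrom, s, s + len(cds), "gene",
                                 "autosome"))
            gene_compartments[fid] = "autosome"

    # --- U/V chromosome: shared PARs, independent SDR haplotypes
    if sdr is not None:
        paste_tes(uv_shared, 0, sdr.start, cfg.te_density.get("PAR", 0.0),
                  "parL", par_rows := [], rng)
        paste_tes(uv_shared, sdr.end, cfg.uv_len,
                  cfg.te_density.get("PAR", 0.0), "parR", par_rows, rng)
        for fid, s, e in par_rows:
            shared_feats.append((fid, UV_CHROM, s, e, "repeat", "PAR"))
        par_spans = [(0, sdr.start), (sdr.end, cfg.uv_len)]
        par_spans = [sp for sp in par_spans if sp[1] - sp[0] >= cfg.cds_len]
        for j in range(cfg.n_par_genes):
            lo, hi = par_spans[j % len(par_spans)]
            s = lo + _place_nonoverlapping(
                rng, hi - lo, [cfg.cds_len])[0]
            cds = _random_cds_codes(rng, cfg.cds_len // 3)
            uv_shared[s:s + len(cds)] = cds
            fid = f"par_gene{j}"
            shared_feats.append((fid, UV_CHROM, s, s + len(cds), "gene",
                                 "PAR"))
            gene_compartments[fid] = "PAR"

    uv_male = uv_shared.copy()
    uv_female = uv_shared.copy()
    true_pairs: list[tuple[str, str, float]] = []
    if sdr is not None:
        uv_male[sdr.start:sdr.end] = _random_codes(rng, len(sdr))
        uv_female[sdr.start:sdr.end] = _random_codes(rng, len(sdr))
        for sex, uv, feats in (("male", uv_male, feats_m),
                               ("female", uv_female, feats_f)):
            te_rows = []
            rng_sdr = rng  # single stream keeps determinism simple
            paste_tes(uv, sdr.start, sdr.end, cfg.te_density.get("SDR", 0.0),
                      f"{sex}_sdr", te_rows, rng_sdr)
            for fid, s, e in te_rows:
                feats.append(Feature(fid, GenomicInterval(UV_CHROM, s, e),
                                     "+", "repeat", "SDR"))
        # gametologue pairs: male copy random, female copy diverged
        n_sdr_genes = cfg.n_gametologues + cfg.n_sex_specific
        starts_m = _place_nonoverlapping(rng, len(sdr),
                                         [cfg.cds_len] * n_sdr_genes)
        starts_f = _place_nonoverlapping(rng, len(sdr),
                                         [cfg.cds_len] * n_sdr_genes)
        for j in range(cfg.n_gametologues):
            cds_m = _random_cds_codes(rng, cfg.cds_len // 3)
            cds_f = _diverge_synonymously(cds_m, cfg.target_ks, rng)
            sm = sdr.start + starts_m[j]
            sf = sdr.start + starts_f[j]
            uv_male[sm:sm + len(cds_m)] = cds_m
            uv_female[sf:sf + len(cds_f)] = cds_f
            mid, fid_ = f"male_sdr_gene{j}", f"female_sdr_gene{j}"
            feats_m.append(Feature(mid, GenomicInterval(UV_CHROM, sm,
                                                        sm + len(cds_m)),
                                   "+", "gene", "SDR"))
            feats_f.append(Feature(fid_, GenomicInterval(UV_CHROM, sf,
                                                         sf + len(cds_f)),
                                   "+", "gene", "SDR"))
            gene_compartments[mid] = "SDR"
            gene_compartments[fid_] = "SDR"
            true_pairs.append((mid, fid_, cfg.target_ks))
        for j in range(cfg.n_sex_specific):
            idx = cfg.n_gametologues + j
            for sex, uv, feats, starts in (
                ("male", uv_male, feats_m, starts_m),
                ("female", uv_female, feats_f, starts_f),
            ):
                cds = _random_cds_codes(rng, cfg.cds_len // 3)
                s = sdr.start + starts[idx]
                uv[s:s + len(cds)] = cds
                fid = f"{sex}_specific_gene{j}"
                feats.append(Feature(fid, GenomicInterval(UV_CHROM, s,
                                                          s + len(cds)),
                                     "+", "gene", "SDR"))
                gene_compartments[fid] = "SDR"

    for name, arr in chroms.items():
        male[name] = arr
        female[name] = arr
    male[UV_CHROM] = uv_male
    female[UV_CHROM] = uv_female

    shared = [Feature(fid, GenomicInterval(chrom, s, e), "+", ftype, comp)
              for fid, chrom, s, e, ftype, comp in shared_feats]
    male_seq = SequenceSet({c: codes_to_seq(a) for c, a in male.items()},
                           sex_tag="male")
    female_seq = SequenceSet({c: codes_to_seq(a) for c, a in female.items()},
                             sex_tag="female")
    lengths = male_seq.lengths()
    ann_m = AnnotationSet(shared + feats_m, sequence_lengths=lengths)
    ann_f = AnnotationSet(shared + feats_f,
                          sequence_lengths=female_seq.lengths())
    truth = TruthSet(
        sdr_bed={
            "male": [sdr] if sdr is not None else [],
            "female": [sdr] if sdr is not None else [],
        },
        gene_compartments=gene_compartments,
        true_pairs=true_pairs,
    )
    return male_seq, female_seq, ann_m, ann_f, truth


# ---------------------------------------------------------------------------
# Reads

def simulate_reads(genome: SequenceSet, depth: float, read_len: int,
                   error_rate: float, seed: int
                   ) -> tuple[ReadSet, dict[str, np.ndarray]]:
    """Uniform error-prone reads from both strands at the requested fold
    coverage, plus the true per-base source depth.

    Total read bases land within one read of depth x genome length;
    substitution errors occur independently at ``error_rate``.
    """
    if len(genome) == 0:
        raise ValueError("empty genome")
    lengths = genome.lengths()
    if read_len > min(lengths.values()):
        raise ValueError("read_len exceeds the shortest sequence")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    total_len = genome.total_length()
    n_reads_total = int(round(depth * total_len / read_len))
    per_base: dict[str, np.ndarray] = {}
    blocks: list[np.ndarray] = []
    ids: list[str] = []
    chrom_names = list(genome.records)
    probs = np.array([lengths[c] for c in chrom_names], dtype=float)
    probs /= probs.sum()
    counts = rng.multinomial(n_reads_total, probs)
    for chrom, n_reads in zip(chrom_names, counts):
        codes = seq_to_codes(genome[chrom])
        cover = np.zeros(lengths[chrom] + 1, dtype=np.int64)
        if n_reads == 0:
            per_base[chrom] = np.cumsum(cover[:-1])
            continue
        starts = rng.integers(0, lengths[chrom] - read_len + 1, size=n_reads)
        strands = rng.integers(0, 2, size=n_reads)
        idx = starts[:, None] + np.arange(read_len)[None, :]
        block = codes[idx]
        rc = (np.uint8(3) - block[:, ::-1]) % np.uint8(8)
        block = np.where(strands[:, None] == 1, rc, block)
        if error_rate > 0:
            err = rng.random(block.shape) < error_rate
            shift = rng.integers(1, 4, size=block.shape, dtype=np.uint8)
            block = np.where(err & (block <= 3),
                             (block + shift) % np.uint8(4), block)
        np.add.at(cover, starts, 1)
        np.add.at(cover, starts + read_len, -1)
        per_base[chrom] = np.cumsum(cover[:-1])
        blocks.append(block.astype(np.uint8))
        ids.extend(f"{chrom}_read{i}" for i in range(n_reads))
    if blocks:
        codes_mat = np.vstack(blocks)
    else:
        codes_mat = np.empty((0, read_len), dtype=np.uint8)
    quals = np.full(codes_mat.shape, 40, dtype=np.uint8)
    return ReadSet(codes_mat, quals, ids), per_base


# ---------------------------------------------------------------------------
# Population genotypes

def simulate_population_genotypes(cfg: SimulationConfig,
                                  seed: int | None = None) -> GenotypeTable:
    """Diploid genotypes: Hardy-Weinberg autosomal sites identical in
    distribution between sexes, plus young sex-linked sites where every male
    is heterozygous and every female homozygous reference (all placed on the
    last scaffold)."""
    if cfg.n_individuals < 2:
        raise ValueError("need >= 2 individuals per sex")
    if cfg.autosomal_het > 0.5:
        raise ValueError("autosomal_het cannot exceed 0.5 under HW")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    males = [f"m{i + 1}" for i in range(cfg.n_individuals)]
    females = [f"f{i + 1}" for i in range(cfg.n_individuals)]
    individuals = males + females
    sex = {**{m: "male" for m in males}, **{f: "female" for f in females}}
    # allele frequency giving the requested expected heterozygosity under HW
    p = (1.0 - math.sqrt(1.0 - 2.0 * cfg.autosomal_het)) / 2.0
    n_auto = cfg.n_sites - cfg.n_sexlinked_sites
    geno = rng.binomial(2, p, size=(cfg.n_sites, len(individuals))) \
        .astype(np.int8)
    scaffold_of_site = np.array([
        f"scaffold_{1 + (i * cfg.n_scaffolds) // cfg.n_sites}"
        for i in range(cfg.n_sites)
    ])
    if cfg.n_sexlinked_sites > 0:
        sex_scaffold = f"scaffold_{cfg.n_scaffolds}"
        candidates = np.nonzero(scaffold_of_site == sex_scaffold)[0]
        if len(candidates) < cfg.n_sexlinked_sites:
            raise ValueError("not enough sites on the sex scaffold")
        linked = candidates[:cfg.n_sexlinked_sites]
        geno[np.ix_(linked, np.arange(len(males)))] = HET
        geno[np.ix_(linked, np.arange(len(males), len(individuals)))] = HOM_REF
    pos = np.arange(cfg.n_sites) * 100 + 1
    sites = pd.DataFrame({
        "chrom": scaffold_of_site,
        "pos": pos,
        "ref": "A",
        "alt": "T",
    })
    return GenotypeTable(sites, geno, individuals, sex)


# ---------------------------------------------------------------------------
# Family evolution on a tree

def default_species_tree() -> dendropy.Tree:
    return read_tree(DEFAULT_TREE_NEWICK)


def simulate_family_evolution(tree: dendropy.Tree | TreeIndex, gain: float,
                              loss: float, gamma_shape: float,
                              n_families: int, seed: int,
                              n_categories: int = 10,
                              joint_multiplier: bool = True
                              ) -> tuple[pd.DataFrame, dict]:
    """Evolve binary presence/absence down the tree under the gain/loss
    chain with per-family discretized-gamma rate multipliers (one shared
    multiplier for gain and loss by default; ``joint_multiplier=False``
    draws them independently).

    Root states are drawn from the stationary distribution. Returns the tip
    matrix (families x species) and the full node-state truth
    {(family, node label): state}.
    """
    if gain < 0 or loss < 0:
        raise ValueError("rates must be >= 0")
    if gain + loss == 0:
        raise ValueError("g = l = 0: stationary distribution undefined")
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    rng = np.random.default_rng(seed)
    cats = discretize_gamma(gamma_shape, n_categories) if gamma_shape \
        else np.ones(1)
    mult_g = cats[rng.integers(0, len(cats), size=n_families)]
    mult_l = mult_g if joint_multiplier \
        else cats[rng.integers(0, len(cats), size=n_families)]
    pi1 = gain / (gain + loss)
    states = np.zeros((index.n_nodes, n_families), dtype=np.int8)
    node_truth: dict = {}
    order = list(reversed(range(index.n_nodes)))  # preorder
    states[index.root] = (rng.random(n_families) < pi1).astype(np.int8)
    for i in order:
        if i != index.root:
            p = index.parent[i]
            t = index.blen[i]
            # per-family transition with its own rate multiplier
            g_eff = gain * mult_g
            l_eff = loss * mult_l
            rate = g_eff + l_eff
            decay = 1.0 - np.exp(-rate * t)
            p01 = (g_eff / rate) * decay
            p10 = (l_eff / rate) * decay
            u = rng.random(n_families)
            parent_states = states[p]
            flip_from0 = (parent_states == 0) & (u < p01)
            flip_from1 = (parent_states == 1) & (u < p10)
            states[i] = parent_states
            states[i, flip_from0] = 1
            states[i, flip_from1] = 0
        for f in range(n_families):
            node_truth[(f"fam{f}", index.labels[i])] = int(states[i, f])
    tip_cols = {index.labels[i]: states[i]
                for i in range(index.n_nodes) if index.is_tip[i]}
    matrix = pd.DataFrame(tip_cols,
                          index=[f"fam{f}" for f in range(n_families)])
    return matrix, node_truth


# ---------------------------------------------------------------------------
# Homology tables for phylostratigraphy

def default_ladder(n_strata: int) -> TaxonomyLadder:
    """A nested ladder of synthetic taxa: rank 1 oldest, rank R the focal
    species."""
    strata: list[tuple[str, set[str]]] = []
    for r in range(1, n_strata):
        strata.append((f"stratum{r}", {f"taxon_r{r}a", f"taxon_r{r}b"}))
    strata.append(("focal", {"focal_sp"}))
    return TaxonomyLadder(strata)


def simulate_homology_table(n_genes: int, n_strata: int,
                            stratum_proportions=None, seed: int = 0
                            ) -> tuple[pd.DataFrame, dict[str, int],
                                       TaxonomyLadder]:
    """Homology hits with known phylostratum labels.

    Each gene's oldest qualifying hit (e <= 1e-5) lies in its true stratum;
    younger strata may hold extra qualifying hits, and older strata may hold
    decoy hits above the e-value threshold to exercise the filter. Genes
    with true age R (focal) have no qualifying external hits.
    """
    rng = np.random.default_rng(seed)
    ladder = default_ladder(n_strata)
    if stratum_proportions is None:
        props = np.ones(n_strata) / n_strata
    else:
        props = np.asarray(stratum_proportions, dtype=float)
        if len(props) != n_strata or not math.isclose(props.sum(), 1.0):
            raise ValueError("proportions must sum to 1 over n_strata")
    ages = rng.choice(np.arange(1, n_strata + 1), size=n_genes, p=props)
    rows = []
    true_ages: dict[str, int] = {}
    for g in range(n_genes):
        gene = f"gene{g}"
        r = int(ages[g])
        true_ages[gene] = r
        if r < n_strata:
            # founding hit in the true (oldest) stratum
            taxon = f"taxon_r{r}{'ab'[rng.integers(0, 2)]}"
            rows.append((gene, taxon, 10.0 ** -rng.uniform(6, 40)))
            # extra qualifying hits in younger external strata
            for younger in range(r + 1, n_strata):
                if rng.random() < 0.5:
                    taxon = f"taxon_r{younger}{'ab'[rng.integers(0, 2)]}"
                    rows.append((gene, taxon, 10.0 ** -rng.uniform(6, 40)))
        # decoy non-qualifying hits, possibly in older strata
        n_decoys = int(rng.integers(0, 3))
        for _ in range(n_decoys):
            dr = int(rng.integers(1, n_strata))
            taxon = f"taxon_r{dr}{'ab'[rng.integers(0, 2)]}"
            rows.append((gene, taxon, 10.0 ** -rng.uniform(1, 4)))
        # a self-hit, always present and ignored for aging
        rows.append((gene, "focal_sp", 0.0))
    hits = pd.DataFrame(rows, columns=["gene", "taxon", "evalue"])
    return hits, true_ages, ladder
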