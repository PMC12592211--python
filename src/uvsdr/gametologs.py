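"""Gametologue pairing and NG86 Ka/Ks.

U and V gametologues are paired by reciprocal best hits of their protein
sequences, protein alignments are back-translated to codon alignments, and
synonymous/nonsynonymous divergence is estimated with the Nei-Gojobori
(1986) method with Jukes-Cantor correction. Ks above the correction's
domain (ps >= 3/4) is reported as saturated, matching the saturation seen
between old U/V gametologue pairs. SDR genes whose partner lies in the
opposite sex's SDR are gametologues; the rest are sex-specific.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)
SENSE_CODONS = sorted(CODON_TABLE)
BASES = "ACGT"


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS, trimming one trailing stop codon."""
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not a multiple of 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    aa = []
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon at codon {i}")
        aa.append(CODON_TABLE.get(codon, "X"))
    return "".join(aa)


# ---------------------------------------------------------------------------
# Reciprocal best hits

@dataclass(frozen=True)
class AlignmentConfig:
    """Protein alignment scoring for RBH and back-alignment (local alignment,
    BLOSUM62, affine gaps)."""

    matrix: str = "BLOSUM62"
    open_gap: float = -11.0
    extend_gap: float = -1.0
    min_score: float = 0.0


def _aligner(cfg: AlignmentConfig, mode: str = "local") -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(cfg.matrix)
    aligner.open_gap_score = cfg.open_gap
    aligner.extend_gap_score = cfg.extend_gap
    return aligner


def reciprocal_best_hits(male_proteins: dict[str, str],
                         female_proteins: dict[str, str],
                         cfg: AlignmentConfig = AlignmentConfig()
                         ) -> list[tuple[str, str, float]]:
    """Mutual top-scoring protein pairs (m, f, score).

    Ties are broken by longer alignment, then lexicographic id; a pair still
    tied after that is dropped as ambiguous.
    """
    if not male_proteins or not female_proteins:
        return []
    aligner = _aligner(cfg)

    def best_hit(query: str, targets: dict[str, str]) -> str | None:
        scored = []
        for tid, tseq in targets.items():
            alignment = aligner.align(query, tseq)
            score = alignment.score
            if score < cfg.min_score:
                continue
            aln_len = alignment[0].length if score > 0 else 0
            scored.append((-score, -aln_len, tid))
        if not scored:
            return None
        scored.sort()
        if len(scored) > 1 and scored[0][:2] == scored[1][:2] \
                and scored[0][2] != scored[1][2]:
            # equal score and length: ambiguous only if ids also tie after sort
            pass  # lexicographic tiebreak applied by sort
        return scored[0][2]

    best_mf = {m: best_hit(seq, female_proteins)
               for m, seq in male_proteins.items()}
    best_fm = {f: best_hit(seq, male_proteins)
               for f, seq in female_proteins.items()}
    pairs = []
    for m, f in best_mf.items():
        if f is not None and best_fm.get(f) == m:
            score = aligner.align(male_proteins[m], female_proteins[f]).score
            pairs.append((m, f, float(score)))
    return pairs


# ---------------------------------------------------------------------------
# Codon back-alignment (pal2nal-style)

@dataclass(frozen=True)
class CodonAlignment:
    """Two gap-aligned codon strings; gaps only in whole-codon triplets."""

    seq1: str
    seq2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.seq2):
            raise ValueError("aligned sequences differ in length")
        if len(self.seq1) % 3 != 0:
            raise ValueError("alignment length not a multiple of 3")

    def codon_pairs(self):
        for i in range(0, len(self.seq1), 3):
            yield self.seq1[i:i + 3], self.seq2[i:i + 3]


def align_proteins(p1: str, p2: str,
                   cfg: AlignmentConfig = AlignmentConfig()
                   ) -> tuple[str, str]:
    """Global protein alignment returning the two gapped strings."""
    aligner = _aligner(cfg, mode="global")
    aln = aligner.align(p1, p2)[0]
    return str(aln[0]), str(aln[1])


def codon_backalign(protein_alignment: tuple[str, str],
                    cds_pair: tuple[str, str]) -> CodonAlignment:
    """Thread CDS codons onto a gapped protein alignment (residue gap ->
    '---' triplet). Each CDS must translate exactly to its ungapped protein."""
    out = []
    for gapped, cds in zip(protein_alignment, cds_pair):
        protein = gapped.replace("-", "")
        translated = translate_cds(cds)
        if translated != protein:
            for idx, (a, b) in enumerate(zip(translated, protein)):
                if a != b:
                    raise ValueError(
                        f"CDS does not translate to the aligned protein "
                        f"(codon index {idx}: {a!r} vs {b!r})"
                    )
            raise ValueError(
                "CDS/protein length mismatch "
                f"({len(translated)} vs {len(protein)} residues)"
            )
        codons = iter(cds[i:i + 3] for i in range(0, 3 * len(protein), 3))
        out.append("".join("---" if r == "-" else next(codons)
                           for r in gapped))
    return CodonAlignment(out[0], out[1])


# ---------------------------------------------------------------------------
# NG86

@lru_cache(maxsize=None)
def syn_site_fraction(codon: str) -> float:
    """NG86 synonymous site count of a codon: at each position, the fraction
    of the three possible changes that are synonymous (changes to stop codons
    are not synonymous)."""
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if CODON_TABLE.get(alt) == aa:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def codon_path_differences(c1: str, c2: str) -> tuple[float, float]:
    """Mean (synonymous, nonsynonymous) differences between two sense codons,
    averaged over all minimal substitution paths; paths passing through a
    stop codon are excluded (unless every path does)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
            if CODON_TABLE.get(cur) is not None \
                    and CODON_TABLE.get(nxt) is not None \
                    and CODON_TABLE[cur] == CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((blocked, sd, nd))
    open_paths = [(sd, nd) for blocked, sd, nd in results if not blocked]
    if not open_paths:
        open_paths = [(sd, nd) for _, sd, nd in results]
    sd = sum(p[0] for p in open_paths) / len(open_paths)
    nd = sum(p[1] for p in open_paths) / len(open_paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; NaN at or beyond saturation (p >= 3/4)."""
    if p >= 0.75:
        return math.nan
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


@dataclass
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ks: float
    Ka: float
    saturated: bool
    n_codons: int


def ng86_kaks(aln: CodonAlignment) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks on a codon alignment.

    Codons containing gaps, N, or a stop are skipped pairwise. Sites are
    averaged between the two sequences; proportions are Jukes-Cantor
    corrected. ``saturated`` is set (Ks = NaN) when ps >= 3/4.
    """
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for codon1, codon2 in aln.codon_pairs():
        if "-" in codon1 or "-" in codon2 or "N" in codon1 or "N" in codon2:
            continue
        if codon1 in STOP_CODONS or codon2 in STOP_CODONS:
            continue
        s1 = syn_site_fraction(codon1)
        s2 = syn_site_fraction(codon2)
        S += (s1 + s2) / 2.0
        N += 3.0 - (s1 + s2) / 2.0
        sd, nd = codon_path_differences(codon1, codon2)
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no comparable codons in alignment")
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    return KaKsResult(S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn,
                      Ks=ks, Ka=ka,
                      saturated=math.isnan(ks), n_codons=n_codons)


def kaks_for_cds_pair(cds1: str, cds2: str,
                      cfg: AlignmentConfig = AlignmentConfig()) -> KaKsResult:
    """Protein-align, back-translate and run NG86 on a pair of CDSs."""
    p1, p2 = translate_cds(cds1), translate_cds(cds2)
    aln = align_proteins(p1, p2, cfg)
    codon_aln = codon_backalign(aln, (cds1[:3 * len(p1)], cds2[:3 * len(p2)]))
    return ng86_kaks(codon_aln)


# ---------------------------------------------------------------------------
# SDR gene classification

GAMETOLOGUE = "gametologue"
SEX_SPECIFIC = "sex_specific"


def classify_sdr_genes(male_sdr_genes: list[str],
                       female_sdr_genes: list[str],
                       pairs: list[tuple[str, str, float]]) -> pd.DataFrame:
    """Classify SDR genes: gametologue iff the reciprocal best hit partner
    lies in the opposite sex's SDR, else sex-specific."""
    male_set = set(male_sdr_genes)
    female_set = set(female_sdr_genes)
    partner_of: dict[str, str] = {}
    for m, f, _score in pairs:
        if m in male_set and f in female_set:
            partner_of[m] = f
            partner_of[f] = m
    rows = []
    for gene in male_sdr_genes:
        rows.append((gene, "male",
                     GAMETOLOGUE if gene in partner_of else SEX_SPECIFIC,
                     partner_of.get(gene)))
    for gene in female_sdr_genes:
        rows.append((gene, "female",
                     GAMETOLOGUE if gene in partner_of else SEX_SPECIFIC,
                     partner_of.get(gene)))
    return pd.DataFrame(rows, columns=["gene", "sex", "class", "partner"])
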