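"""Coding-sequence evolution: ORF finding, allele phasing, Nei–Gojobori
Ka/Ks with Jukes–Cantor correction, divergence dating, and an exact
rank-sum test for comparing gene classes.

The substitution-rate engine is the classic pathway-counting method: each
codon contributes synonymous (S) and non-synonymous (N) site counts from
the fraction of its possible single-base changes that preserve the encoded
amino acid, and each differing codon pair contributes synonymous and
non-synonymous difference counts averaged over all minimal mutational
pathways between the codons. Proportions of differences are corrected for
multiple hits with the one-parameter Jukes–Cantor formula. Divergence time
follows the molecular clock T = K / 2r for a pair of lineages separated
for T generations at neutral rate r per site per generation.

Standard nuclear genetic code only; changes to stop codons are excluded
from site denominators and pathways passing through a stop codon are
excluded from difference averaging (a pair whose every pathway is blocked
is skipped and counted).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from math import log, sqrt
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq
from scipy.stats import rankdata

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# ORF finding and phasing

@dataclass(frozen=True)
class OrfLocation:
    """Longest open reading frame: ATG through stop, inclusive.

    ``start``/``end`` are 0-based half-open on the strand the ORF lies on
    (i.e. on the reverse complement for strand '-'); ``frame`` is start % 3.
    """

    strand: str  # '+' or '-'
    frame: int
    start: int
    end: int

    def extract(self, seq: str) -> str:
        s = seq.upper()
        if self.strand == "-":
            s = str(Seq(s).reverse_complement())
        return s[self.start:self.end]


def _orfs_in_frame(seq: str, frame: int) -> Iterable[tuple[int, int]]:
    start = None
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        if codon in STOP_CODONS:
            if start is not None:
                yield start, i + 3
                start = None
        elif codon == "ATG" and start is None:
            start = i
    # open-ended runs (no stop) are not ORFs and are dropped


def find_orf(seq: str, min_len: int = 150) -> OrfLocation | None:
    """Longest ATG-to-stop ORF over all six frames, or None if the longest
    is shorter than ``min_len`` nt (length includes the stop codon).

    Ties break deterministically: forward strand first, lower frame, lower
    start.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    candidates: list[tuple[int, int, int, int, int]] = []
    for strand_rank, s in ((0, seq), (1, str(Seq(seq).reverse_complement()))):
        for frame in range(3):
            for start, end in _orfs_in_frame(s, frame):
                candidates.append((-(end - start), strand_rank, frame, start, end))
    if not candidates:
        return None
    neg_len, strand_rank, frame, start, end = min(candidates)
    if -neg_len < min_len:
        return None
    return OrfLocation("+" if strand_rank == 0 else "-", frame, start, end)


@dataclass(frozen=True)
class CodingAlignment:
    """A pair of in-frame, coordinate-phased allele sequences (no gaps —
    alleles differ only by substitutions, so no realignment is ever done)."""

    seq_x: str
    seq_y: str

    def __post_init__(self) -> None:
        if len(self.seq_x) != len(self.seq_y):
            raise ValueError("aligned sequences must have equal length")
        if len(self.seq_x) % 3:
            raise ValueError("alignment length must be a multiple of 3")

    def codon_pairs(self) -> Iterable[tuple[str, str]]:
        for i in range(0, len(self.seq_x), 3):
            yield self.seq_x[i:i + 3], self.seq_y[i:i + 3]


def phase_alleles(ref_cds: str,
                  snps: Sequence[tuple[int, str, str]]) -> CodingAlignment:
    """Build X and Y allele CDSs by substituting phased SNP bases into the
    reference CDS.

    ``snps`` holds (0-based CDS position, X base, Y base). For a pattern-1
    site the Y base is the allele absent from the female homozygotes and
    the X base is the female-homozygous allele. Two SNPs at one position
    must agree or it is an error.
    """
    ref_cds = ref_cds.upper()
    x = list(ref_cds)
    y = list(ref_cds)
    seen: dict[int, tuple[str, str]] = {}
    for pos, xb, yb in snps:
        if not 0 <= pos < len(ref_cds):
            raise ValueError(f"SNP position {pos} outside CDS")
        xb, yb = xb.upper(), yb.upper()
        if pos in seen and seen[pos] != (xb, yb):
            raise ValueError(f"conflicting bases at CDS position {pos}")
        seen[pos] = (xb, yb)
        x[pos] = xb
        y[pos] = yb
    return CodingAlignment("".join(x), "".join(y))


# ---------------------------------------------------------------------------
# Nei–Gojobori counting

@lru_cache(maxsize=None)
def ng_sites(codon: str) -> tuple[float, float]:
    """Synonymous and non-synonymous site counts (s, n) for one codon.

    Per position, the synonymous share is the fraction of the possible
    single-base changes that are synonymous, with changes to stop codons
    excluded from the denominator; s sums the shares and n = 3 - s.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError("stop codon has no site counts")
    if codon not in GENETIC_CODE:
        raise ValueError(f"ambiguous or invalid codon {codon!r}")
    aa = GENETIC_CODE[codon]
    s = 0.0
    for i in range(3):
        syn = non = 0
        for b in _BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1:]
            if mut in STOP_CODONS:
                continue
            if GENETIC_CODE[mut] == aa:
                syn += 1
            else:
                non += 1
        if syn + non:
            s += syn / (syn + non)
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng_differences(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """Synonymous/non-synonymous difference counts (sd, nd) between two
    codons, averaged over all minimal mutational pathways.

    Pathways passing through a stop codon are excluded; returns None when
    every pathway is blocked (the codon pair cannot be scored).
    """
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if c in STOP_CODONS:
            raise ValueError("stop codon in difference counting")
        if c not in GENETIC_CODE:
            raise ValueError(f"ambiguous or invalid codon {c!r}")
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diff):
        cur = a
        sd = nd = 0
        ok = True
        for i in order:
            nxt = cur[:i] + b[i] + cur[i + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:
        return None
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Multiple-hit corrected distance d = -(3/4) ln(1 - 4p/3).

    Valid for 0 <= p < 0.75; at p = 0.75 the correction diverges
    (saturation).
    """
    if p < 0:
        raise ValueError("proportion of differences cannot be negative")
    if p >= 0.75:
        raise ValueError(f"p = {p:.4f} is at or beyond Jukes-Cantor saturation")
    return -0.75 * log(1.0 - p * 4.0 / 3.0)


@dataclass
class KaKsResult:
    """Site counts, difference counts and corrected rates for one pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    codons_used: int
    codons_skipped: int = 0

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S else 0.0

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N else 0.0

    @property
    def Ks(self) -> float:
        return jukes_cantor(self.pS)

    @property
    def Ka(self) -> float:
        return jukes_cantor(self.pN)

    @property
    def ka_ks(self) -> float | None:
        return self.Ka / self.Ks if self.Ks > 0 else None


def ka_ks(aln: CodingAlignment) -> KaKsResult:
    """Pairwise Ka/Ks for a phased allele pair.

    Codons containing non-ACGT symbols are skipped and counted (pairwise
    deletion); a terminal stop codon pair is excluded before counting;
    internal stops and pathway-blocked pairs are likewise skipped and
    counted. Site counts S and N are the averages of the two sequences.
    """
    pairs = list(aln.codon_pairs())
    if pairs and (pairs[-1][0] in STOP_CODONS or pairs[-1][1] in STOP_CODONS):
        pairs = pairs[:-1]
    s_x = s_y = n_x = n_y = sd = nd = 0.0
    used = skipped = 0
    for ca, cb in pairs:
        if (set(ca) | set(cb)) - set(_BASES):
            skipped += 1
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            skipped += 1
            continue
        d = ng_differences(ca, cb)
        if d is None:
            skipped += 1
            continue
        sa, na = ng_sites(ca)
        sb, nb = ng_sites(cb)
        s_x += sa
        n_x += na
        s_y += sb
        n_y += nb
        sd += d[0]
        nd += d[1]
        used += 1
    if used == 0:
        raise ValueError("no analyzable codons in alignment")
    return KaKsResult(S=(s_x + s_y) / 2, N=(n_x + n_y) / 2,
                      Sd=sd, Nd=nd, codons_used=used, codons_skipped=skipped)


# ---------------------------------------------------------------------------
# Dating and class comparison

@dataclass(frozen=True)
class DivergenceEstimate:
    T: float                # years
    K: float                # substitution rate used (normally Ks)
    r: float                # neutral rate per site per generation
    generation_years: float = 1.0


def divergence_time(K: float, r: float = 6.5e-9,
                    generation_years: float = 1.0) -> DivergenceEstimate:
    """T = K / (2 r) generations, converted to years.

    The factor 2 counts both lineages since the split; r defaults to the
    plant neutral rate 6.5e-9 per nucleotide per generation with one
    generation per year.
    """
    if r <= 0:
        raise ValueError("neutral rate r must be positive")
    if K < 0:
        raise ValueError("substitution rate K cannot be negative")
    return DivergenceEstimate(T=K / (2.0 * r) * generation_years, K=K, r=r,
                              generation_years=generation_years)


def summarize_divergence(ks_values: Sequence[float], r: float = 6.5e-9,
                         generation_years: float = 1.0) -> dict[str, float]:
    """Mean +/- SE of per-gene Ks, with divergence time reported both ways:
    from the mean Ks and as the mean of per-gene times (identical scaling,
    but kept separate so either convention can be quoted)."""
    ks = np.asarray(ks_values, dtype=float)
    if ks.size == 0:
        raise ValueError("no Ks values to summarize")
    mean_ks = float(ks.mean())
    se_ks = float(ks.std(ddof=1) / sqrt(ks.size)) if ks.size > 1 else 0.0
    per_gene_t = np.array(
        [divergence_time(k, r, generation_years).T for k in ks])
    return {
        "n_genes": int(ks.size),
        "mean_ks": mean_ks,
        "se_ks": se_ks,
        "t_from_mean_ks": divergence_time(mean_ks, r, generation_years).T,
        "mean_per_gene_t": float(per_gene_t.mean()),
        "se_per_gene_t": float(per_gene_t.std(ddof=1) / sqrt(ks.size))
        if ks.size > 1 else 0.0,
    }


def rank_sum_exact(group_a: Sequence[float], group_b: Sequence[float],
                   ) -> tuple[float, float]:
    """Exact two-sided Wilcoxon rank-sum test with mid-ranks for ties.

    Returns (W, p) where W is the rank sum of the first group and p is the
    doubled smaller tail of the exact permutation distribution of W
    (capped at 1), computed by dynamic programming over rank assignments.
    Group sizes up to ~30 are practical.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(np.concatenate([a, b]))
    # doubled mid-ranks are integers, which keeps the DP exact
    r2 = np.rint(ranks * 2).astype(np.int64)
    w2 = int(r2[: a.size].sum())
    n, n1 = r2.size, int(a.size)
    max_sum = int(r2.sum())
    # count[k, s] = number of k-subsets of the ranks with doubled-sum s
    count = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    count[0, 0] = 1.0
    for r in r2:
        for k in range(n1, 0, -1):  # descend so each rank is used once
            count[k, r:] += count[k - 1, : max_sum + 1 - r]
    dist = count[n1]
    total = dist.sum()
    p_low = dist[: w2 + 1].sum() / total
    p_high = dist[w2:].sum() / total
    p = min(1.0, 2.0 * min(p_low, p_high))
    return float(w2) / 2.0, float(p)
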