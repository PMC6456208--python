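"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: amino acids come from
Bio.Seq translation, probabilities are exact rationals from math.comb, and
searches are plain enumerations.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

from Bio.Seq import Seq

_BASES = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_ng_sites(codon: str) -> tuple[float, float]:
    """Site counts by direct enumeration of all nine single-base mutants."""
    aa = _aa(codon)
    s = 0.0
    for i in range(3):
        outcomes = []
        for b in _BASES:
            if b == codon[i]:
                continue
            mut_aa = _aa(codon[:i] + b + codon[i + 1:])
            if mut_aa == "*":
                continue
            outcomes.append(mut_aa == aa)
        if outcomes:
            s += sum(outcomes) / len(outcomes)
    return s, 3.0 - s


def oracle_ng_differences(a: str, b: str) -> tuple[float, float] | None:
    """Pathway-averaged difference counts by permutation enumeration."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    acc = []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = a, 0, 0, True
        for i in order:
            nxt = cur[:i] + b[i] + cur[i + 1:]
            if _aa(nxt) == "*":
                ok = False
                break
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            acc.append((sd, nd))
    if not acc:
        return None
    return (sum(x[0] for x in acc) / len(acc),
            sum(x[1] for x in acc) / len(acc))


def oracle_pair_counts(seq_a: str, seq_b: str):
    """NG86 S, N, Sd, Nd for an in-frame pair, skipping stop/blocked codons
    the same way the method definition requires."""
    s_sum = n_sum = sd = nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if _aa(ca) == "*" or _aa(cb) == "*":
            continue
        d = oracle_ng_differences(ca, cb)
        if d is None:
            continue
        sa, na = oracle_ng_sites(ca)
        sb, nb = oracle_ng_sites(cb)
        s_sum += (sa + sb) / 2
        n_sum += (na + nb) / 2
        sd += d[0]
        nd += d[1]
    return s_sum, n_sum, sd, nd


def oracle_fisher_2xk(table) -> Fraction:
    """Two-sided exact p as an exact rational, by enumerating every table
    with the observed margins and summing point probabilities <= observed."""
    row1 = list(table[0])
    row2 = list(table[1])
    cols = [a + b for a, b in zip(row1, row2)]
    keep = [j for j, c in enumerate(cols) if c > 0]
    row1 = [row1[j] for j in keep]
    cols = [cols[j] for j in keep]
    n1 = sum(row1)
    total = sum(cols)
    denom = comb(total, n1)

    def weight(cells):
        w = 1
        for a, c in zip(cells, cols):
            w *= comb(c, a)
        return w

    obs = weight(row1)
    acc = 0
    for cells in itertools.product(*[range(c + 1) for c in cols[:-1]]):
        last = n1 - sum(cells)
        if not 0 <= last <= cols[-1]:
            continue
        w = weight((*cells, last))
        if w <= obs:
            acc += w
    return Fraction(acc, denom)


def oracle_rank_sum(group_a, group_b) -> tuple[float, float]:
    """Exact rank-sum p by full enumeration of subset assignments."""
    from scipy.stats import rankdata

    n1 = len(group_a)
    pooled = list(group_a) + list(group_b)
    ranks = rankdata(pooled)
    w_obs = ranks[:n1].sum()
    sums = [sum(ranks[i] for i in c)
            for c in itertools.combinations(range(len(pooled)), n1)]
    total = len(sums)
    eps = 1e-9
    p_low = sum(1 for s in sums if s <= w_obs + eps) / total
    p_high = sum(1 for s in sums if s >= w_obs - eps) / total
    return float(w_obs), min(1.0, 2.0 * min(p_low, p_high))


def oracle_orfs(seq: str, rc: str) -> list[tuple[int, int, int, int]]:
    """All ATG-to-stop ORFs over six frames by brute force: returns
    (length, strand_rank, start, end) per ORF on its own strand."""
    stops = {"TAA", "TAG", "TGA"}
    out = []
    for strand_rank, s in ((0, seq), (1, rc)):
        for start in range(len(s) - 2):
            if s[start:start + 3] != "ATG":
                continue
            for j in range(start, len(s) - 2, 3):
                if s[j:j + 3] in stops:
                    end = j + 3
                    out.append((end - start, strand_rank, start, end))
                    break
    return out
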