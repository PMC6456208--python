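"""Exact genotype-by-sex association and recombinant counting.

The sex-linkage test is Fisher's exact test on a 2xk table (rows: male;
female+monoecious — monoecious individuals are pooled with females;
columns: genotype classes aa/ab/bb). k=3 is handled by full enumeration
over the two free cells (the Freeman–Halton extension). All point
probabilities are computed in log space from lgamma, so p-values far below
the double underflow of naive factorial ratios (down past 1e-70) remain
exact; no asymptotic approximation is used anywhere.

Two-sidedness follows the point-probability convention of standard
statistical software: p is the sum over all tables with the observed
margins whose point probability does not exceed that of the observed table
(with a 1+1e-7 relative slack against float noise).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from math import lgamma, log1p
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .genotyping import GenotypeCall, GenotypeState

_REL_SLACK = log1p(1e-7)


def _log_choose(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def _log_table_prob(row1: Sequence[int], col_sums: Sequence[int],
                    n1: int, total: int) -> float:
    """log P(table | margins) = sum_j log C(c_j, a_j) - log C(N, n1)."""
    lp = -_log_choose(total, n1)
    for a, c in zip(row1, col_sums):
        lp += _log_choose(c, a)
    return lp


def fisher_exact_2xk(table: Sequence[Sequence[int]]) -> float:
    """Two-sided exact p for a 2xk contingency table, k in {2, 3}.

    Columns with zero total are dropped first (an unobserved genotype class
    carries no information and leaves the exact p unchanged).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("table must have exactly 2 rows")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    t = t[:, t.sum(axis=0) > 0]
    k = t.shape[1]
    if k == 0:
        raise ValueError("table has no observations")
    if k > 3:
        raise ValueError("only 2x2 and 2x3 tables are supported")
    if k == 1:
        return 1.0
    col_sums = t.sum(axis=0)
    n1 = int(t[0].sum())
    total = int(t.sum())
    obs = _log_table_prob(t[0], col_sums, n1, total)
    cutoff = obs + _REL_SLACK
    logs = []
    free_ranges = [range(int(c) + 1) for c in col_sums[:-1]]
    for cells in itertools.product(*free_ranges):
        last = n1 - sum(cells)
        if not 0 <= last <= col_sums[-1]:
            continue
        lp = _log_table_prob((*cells, last), col_sums, n1, total)
        if lp <= cutoff:
            logs.append(lp)
    return float(min(1.0, np.exp(logsumexp(logs))))


class LinkageCategory(str, Enum):
    MSY = "MSY"
    SEX_ASSOCIATED = "SEX_ASSOCIATED"
    RECOMBINING_OR_RECENT = "RECOMBINING_OR_RECENT"
    NO_ASSOCIATION = "NO_ASSOCIATION"


@dataclass(frozen=True)
class SexLinkageCall:
    marker_id: str
    p_value: float
    category: LinkageCategory


def classify_sex_linkage(p: float, marker_id: str = "",
                         msy_p: float = 1e-60, significant_p: float = 1e-10,
                         weak_p: float = 1e-5) -> SexLinkageCall:
    """Tier a raw exact p into MSY / associated / recombining / none.

    Full sex linkage across an unrelated panel (p below ``msy_p``) places a
    marker in the male-specific region; significant but weaker association
    indicates a region where X–Y recombination is ongoing or only recently
    suppressed. Thresholds act on raw p — no multiple-testing correction.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if p < msy_p:
        cat = LinkageCategory.MSY
    elif p < significant_p:
        cat = LinkageCategory.SEX_ASSOCIATED
    elif p <= weak_p:
        cat = LinkageCategory.RECOMBINING_OR_RECENT
    else:
        cat = LinkageCategory.NO_ASSOCIATION
    return SexLinkageCall(marker_id, p, cat)


@dataclass(frozen=True)
class RecombinantCount:
    marker_id: str
    population_id: str
    n_recombinants: int | None
    no_variant: bool = False


def count_recombinants(marker_genotypes: Sequence[GenotypeCall],
                       sexes: Sequence[str],
                       het_sex: str = "male",
                       marker_id: str = "", population_id: str = "",
                       ) -> RecombinantCount:
    """Count progeny whose genotype contradicts the sex–genotype coupling.

    ``het_sex`` states which sex is expected heterozygous (males, for a
    fixed X–Y difference in an XY system). A marker with no heterozygote
    and a single observed allele is monomorphic: reported as no-variant
    ("n.v."), with the recombinant count undefined.
    """
    if len(marker_genotypes) != len(sexes):
        raise ValueError("genotypes and sexes must align")
    usable = [(g, s) for g, s in zip(marker_genotypes, sexes) if g.usable]
    alleles = {a for g, _ in usable for a in g.alleles}
    if len(alleles) <= 1:
        return RecombinantCount(marker_id, population_id, None, no_variant=True)
    n_rec = 0
    for g, sex in usable:
        expected_het = sex == het_sex
        if g.is_het != expected_het:
            n_rec += 1
    return RecombinantCount(marker_id, population_id, n_rec)


def genotype_sex_table(genotypes: Sequence[GenotypeCall], sexes: Sequence[str],
                       ) -> list[list[int]]:
    """Build the 2x3 male vs female+monoecious genotype-class table.

    Genotype classes are aa (homozygous major-X), ab, bb — here realised as
    HOM_REF / HET / HOM_ALT. MISSING and ambiguous calls are dropped.
    """
    if len(genotypes) != len(sexes):
        raise ValueError("genotypes and sexes must align")
    idx = {GenotypeState.HOM_REF: 0, GenotypeState.HET: 1, GenotypeState.HOM_ALT: 2}
    table = [[0, 0, 0], [0, 0, 0]]
    for g, sex in zip(genotypes, sexes):
        if not g.usable:
            continue
        row = 0 if sex == "male" else 1
        table[row][idx[g.state]] += 1
    return table
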