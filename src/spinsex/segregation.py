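"""Sex-chromosomal segregation-pattern classification.

In an XY cross the male is heterogametic, so a site tied to the sex
chromosomes shows one of three diagnostic progeny configurations:

* pattern 1 — every female the same homozygote (X^aX^a), every male
  heterozygous for one shared allele pair (X^aY^b): a fixed X–Y difference.
  The Y allele is the one absent from the female homozygotes.
* pattern 2 — every female heterozygous (X^aX^b), every male the same
  homozygote (X^aY^a) or hemizygote (X^aY^null): the paternal X carries a
  variant the Y does not. Genotypes alone cannot distinguish Y^a from
  Y^null, so the call carries a hemizygosity-unknown flag.
* pattern 3 — females X^aX^b, males X^aY^c with a third allele c: only
  observable at a multiallelic site.

Classification uses progeny only; parents need not be sequenced. Monoecious
samples are never part of a cross progeny and are excluded upstream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .genotyping import GenotypeCall, SiteGenotypes
from .io import SampleSheet, log


class Pattern(str, Enum):
    P1 = "1"
    P2 = "2"
    P3 = "3"
    NONE = "none"


@dataclass(frozen=True)
class SegregationClassification:
    unigene_id: str
    pos: int
    pattern: Pattern
    x_allele: int | None = None   # allele on X in males
    y_allele: int | None = None   # allele carried by Y (pattern 2: male hom allele)
    hemizygosity_unknown: bool = False


def _uniform_hom(calls: Sequence[GenotypeCall]) -> int | None:
    """The shared homozygous allele if every call is the same homozygote."""
    alleles = set()
    for c in calls:
        if not c.is_hom:
            return None
        alleles.add(c.alleles[0])
    return alleles.pop() if len(alleles) == 1 else None


def _uniform_het(calls: Sequence[GenotypeCall]) -> tuple[int, int] | None:
    """The shared allele pair if every call is the same heterozygote."""
    pairs = {c.alleles if c.is_het else None for c in calls}
    if len(pairs) == 1 and None not in pairs:
        return pairs.pop()
    return None


def classify_site(female_calls: Sequence[GenotypeCall],
                  male_calls: Sequence[GenotypeCall],
                  unigene_id: str = "", pos: int = 0,
                  ) -> SegregationClassification:
    """Classify one complete site into pattern 1/2/3 or none.

    Any MISSING or ambiguous call makes the site unclassifiable (none): the
    patterns are defined by *all* samples of a sex agreeing.
    """
    if not female_calls or not male_calls:
        raise ValueError("need at least one call per sex")

    def none() -> SegregationClassification:
        return SegregationClassification(unigene_id, pos, Pattern.NONE)

    if not all(c.usable for c in (*female_calls, *male_calls)):
        return none()

    f_hom = _uniform_hom(female_calls)
    m_het = _uniform_het(male_calls)
    if f_hom is not None and m_het is not None and f_hom in m_het:
        y = m_het[0] if m_het[1] == f_hom else m_het[1]
        return SegregationClassification(unigene_id, pos, Pattern.P1,
                                         x_allele=f_hom, y_allele=y)

    f_het = _uniform_het(female_calls)
    m_hom = _uniform_hom(male_calls)
    if f_het is not None and m_hom is not None and m_hom in f_het:
        return SegregationClassification(unigene_id, pos, Pattern.P2,
                                         x_allele=m_hom, y_allele=m_hom,
                                         hemizygosity_unknown=True)

    if f_het is not None and m_het is not None:
        shared = set(f_het) & set(m_het)
        third = set(m_het) - set(f_het)
        if len(shared) == 1 and len(third) == 1:
            return SegregationClassification(unigene_id, pos, Pattern.P3,
                                             x_allele=shared.pop(),
                                             y_allele=third.pop())
    return none()


def classify_sites(matrix: Iterable[SiteGenotypes], samples: SampleSheet,
                   require_complete: bool = True, min_per_sex: int = 4,
                   ) -> list[SegregationClassification]:
    """Classify every site in a genotype matrix.

    With ``require_complete`` (default) a site must be callable in all
    progeny samples; otherwise sites keep their usable calls as long as each
    sex retains ``min_per_sex`` of them.
    """
    samples.require_both_sexes()
    females = samples.progeny_females
    males = samples.progeny_males
    out: list[SegregationClassification] = []
    n_skipped = 0
    for sg in matrix:
        f = [sg.calls[s] for s in females]
        m = [sg.calls[s] for s in males]
        if require_complete:
            if not sg.complete:
                n_skipped += 1
                out.append(SegregationClassification(
                    sg.site.unigene_id, sg.site.pos, Pattern.NONE))
                continue
        else:
            f = [c for c in f if c.usable]
            m = [c for c in m if c.usable]
            if len(f) < min_per_sex or len(m) < min_per_sex:
                n_skipped += 1
                out.append(SegregationClassification(
                    sg.site.unigene_id, sg.site.pos, Pattern.NONE))
                continue
        out.append(classify_site(f, m, sg.site.unigene_id, sg.site.pos))
    n_classified = sum(1 for c in out if c.pattern is not Pattern.NONE)
    log.info("classified %d sites: %d patterned, %d incomplete",
             len(out), n_classified, n_skipped)
    return out


@dataclass
class UnigeneSummary:
    unigene_id: str
    snp_count: dict[Pattern, int]

    @property
    def patterns(self) -> set[Pattern]:
        return set(self.snp_count)


@dataclass
class PatternTotals:
    """Aggregate counts mirroring the per-pattern summary table layout.

    ``total_distinct_unigenes`` counts a gene carrying SNPs of several
    patterns once (the union, not the per-pattern column sum).
    """

    snps: dict[Pattern, int]
    unigenes: dict[Pattern, int]
    total_snps: int
    total_distinct_unigenes: int


def aggregate_unigenes(classifications: Iterable[SegregationClassification],
                       ) -> tuple[list[UnigeneSummary], PatternTotals]:
    per_gene: dict[str, Counter] = {}
    for c in classifications:
        if c.pattern is Pattern.NONE:
            continue
        per_gene.setdefault(c.unigene_id, Counter())[c.pattern] += 1
    summaries = [
        UnigeneSummary(g, dict(cnt)) for g, cnt in sorted(per_gene.items())
    ]
    snps: Counter = Counter()
    genes: Counter = Counter()
    for s in summaries:
        for p, n in s.snp_count.items():
            snps[p] += n
            genes[p] += 1
    totals = PatternTotals(
        snps={p: snps.get(p, 0) for p in (Pattern.P1, Pattern.P2, Pattern.P3)},
        unigenes={p: genes.get(p, 0) for p in (Pattern.P1, Pattern.P2, Pattern.P3)},
        total_snps=sum(snps.values()),
        total_distinct_unigenes=len(summaries),
    )
    return summaries, totals


def classification_table(classifications: Iterable[SegregationClassification],
                         ) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "unigene": c.unigene_id,
            "pos": c.pos,
            "pattern": c.pattern.value,
            "x_allele": c.x_allele if c.x_allele is not None else ".",
            "y_allele": c.y_allele if c.y_allele is not None else ".",
            "hemizygosity_unknown": c.hemizygosity_unknown,
        }
        for c in classifications
    ])


def totals_table(totals: PatternTotals) -> pd.DataFrame:
    rows = [
        {"segregation_pattern": p.value,
         "n_snps": totals.snps[p], "n_unigenes": totals.unigenes[p]}
        for p in (Pattern.P1, Pattern.P2, Pattern.P3)
    ]
    rows.append({"segregation_pattern": "total",
                 "n_snps": totals.total_snps,
                 "n_unigenes": totals.total_distinct_unigenes})
    return pd.DataFrame(rows)
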