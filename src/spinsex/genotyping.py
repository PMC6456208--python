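"""Depth-rule genotype calling.

A sample's genotype at a site is called from raw allele read depths with the
10%-of-total rule: if the minor allele carries strictly less than
``hom_fraction`` (default 10%) of the total depth the call is homozygous for
the major allele, otherwise heterozygous for the two best-supported alleles.
Sites below ``min_total_depth`` reads are MISSING — the rule exists to avoid
genotyping errors caused by low read depth, so we refuse to call where depth
cannot support the fraction test at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING, Iterable

import pandas as pd

if TYPE_CHECKING:  # avoid a runtime io<->genotyping cycle
    from .io import SampleSheet, VariantTable, VariantSite


@dataclass(frozen=True)
class AlleleDepth:
    """Read depths per allele; index 0 is REF, then ALT alleles in order."""

    ref_depth: int
    alt_depths: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.ref_depth < 0 or any(d < 0 for d in self.alt_depths):
            raise ValueError("allele depths must be non-negative")

    @property
    def all(self) -> tuple[int, ...]:
        return (self.ref_depth, *self.alt_depths)

    @property
    def total(self) -> int:
        return sum(self.all)


class GenotypeState(str, Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    MISSING = "MISSING"


@dataclass(frozen=True)
class GenotypeCall:
    """state plus the ordered allele-index pair (0 = REF); MISSING has none.

    ``ambiguous`` marks multiallelic sites where a third allele exceeds the
    homozygosity fraction — the two-allele genotype model does not fit and
    downstream classification treats the call as unusable.
    """

    state: GenotypeState
    alleles: tuple[int, int] | None = None
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.state is GenotypeState.MISSING:
            if self.alleles is not None:
                raise ValueError("MISSING call carries no alleles")
        else:
            a, b = self.alleles
            if self.state is GenotypeState.HET and a == b:
                raise ValueError("HET needs two distinct alleles")
            if self.state is not GenotypeState.HET and a != b:
                raise ValueError("homozygous call needs identical alleles")

    @property
    def is_hom(self) -> bool:
        return self.state in (GenotypeState.HOM_REF, GenotypeState.HOM_ALT)

    @property
    def is_het(self) -> bool:
        return self.state is GenotypeState.HET

    @property
    def usable(self) -> bool:
        return self.state is not GenotypeState.MISSING and not self.ambiguous


MISSING_CALL = GenotypeCall(GenotypeState.MISSING)


def call_genotype(depths: AlleleDepth, min_total_depth: int = 10,
                  hom_fraction: float = 0.10) -> GenotypeCall:
    """Call one genotype from allele depths with the 10% rule.

    The boundary is strict: a minor fraction of exactly ``hom_fraction``
    (e.g. 2/20 at 10%) is *not* "less than" and stays heterozygous. Depth
    ties between candidate alleles break by allele index (REF first), so
    output is deterministic.
    """
    if not 0 < hom_fraction < 0.5:
        raise ValueError("hom_fraction must be in (0, 0.5)")
    d = depths.all
    total = depths.total
    if total < min_total_depth or total == 0:
        return MISSING_CALL
    order = sorted(range(len(d)), key=lambda i: (-d[i], i))
    major = order[0]
    minor = order[1] if len(order) > 1 else None
    ambiguous = any(d[i] / total >= hom_fraction for i in order[2:])
    if minor is None or d[minor] / total < hom_fraction:
        state = GenotypeState.HOM_REF if major == 0 else GenotypeState.HOM_ALT
        return GenotypeCall(state, (major, major), ambiguous)
    pair = tuple(sorted((major, minor)))
    return GenotypeCall(GenotypeState.HET, pair, ambiguous)


@dataclass
class SiteGenotypes:
    """All per-sample calls at one site, plus a completeness flag over the
    progeny samples actually used downstream."""

    site: "VariantSite"
    calls: dict[str, GenotypeCall]
    complete: bool


def genotype_matrix(variants: "VariantTable", samples: "SampleSheet",
                    min_total_depth: int = 10, hom_fraction: float = 0.10,
                    ) -> list[SiteGenotypes]:
    """Call every (site, sample); a site is flagged incomplete when any
    male/female progeny sample is MISSING or ambiguous."""
    progeny = set(samples.progeny_females) | set(samples.progeny_males)
    out = []
    for site in variants:
        calls = {
            s: call_genotype(site.depths[s], min_total_depth, hom_fraction)
            for s in variants.samples
        }
        complete = all(calls[s].usable for s in variants.samples if s in progeny)
        out.append(SiteGenotypes(site, calls, complete))
    return out


def genotype_table(matrix: Iterable[SiteGenotypes]) -> pd.DataFrame:
    """Flatten calls to a tidy TSV-ready frame."""
    rows = []
    for sg in matrix:
        for sample, call in sg.calls.items():
            d = sg.site.depths[sample]
            rows.append({
                "unigene": sg.site.unigene_id,
                "pos": sg.site.pos,
                "sample": sample,
                "state": call.state.value,
                "alleles": "/".join(map(str, call.alleles)) if call.alleles else ".",
                "ref_depth": d.ref_depth,
                "alt_depth": ",".join(map(str, d.alt_depths)),
            })
    return pd.DataFrame(rows)
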