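"""Expression quantification and allele-specific Y/X expression.

Per-unigene expression is RPKM (reads per kilobase of transcript per
million aligned reads). Sex-biased expression is a one-way two-group ANOVA
F-test on log2(RPKM + pseudocount); with four samples per sex the degrees
of freedom are (1, 6). The Y-to-X allele expression ratio of a sex-linked
gene is read directly from allele depths at pattern-1 SNPs heterozygous in
every male sample: total Y-allele read depth over those SNPs and samples,
divided by total X-allele depth ("pooled", not a mean of per-SNP ratios —
deep SNPs should weigh more).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist


def rpkm(mapped_reads: float, length_nt: float,
         total_mapped_in_sample: float) -> float:
    """reads / (length in kb) / (library size in millions)."""
    if length_nt <= 0:
        raise ValueError("length must be positive")
    if total_mapped_in_sample <= 0:
        raise ValueError("library size must be positive")
    return mapped_reads / (length_nt / 1e3) / (total_mapped_in_sample / 1e6)


def rpkm_matrix(counts: pd.DataFrame, lengths: Mapping[str, int]) -> pd.DataFrame:
    """RPKM for a unigene x sample count matrix; library size per sample is
    its column sum."""
    missing = set(counts.index) - set(lengths)
    if missing:
        raise ValueError(f"no length for unigenes: {sorted(missing)[:5]} ...")
    lens = np.array([lengths[u] for u in counts.index], dtype=float)
    totals = counts.sum(axis=0).to_numpy(dtype=float)
    if (totals <= 0).any():
        raise ValueError("a sample has zero mapped reads")
    return counts / (lens[:, None] / 1e3) / (totals[None, :] / 1e6)


def log2_rpkm(values: np.ndarray | pd.DataFrame, pseudocount: float = 0.01):
    return np.log2(np.asarray(values, dtype=float) + pseudocount)


@dataclass(frozen=True)
class DETestResult:
    unigene_id: str
    F: float
    df: tuple[int, int]
    p: float


def sex_de_test(female_log2rpkm: Sequence[float],
                male_log2rpkm: Sequence[float],
                unigene_id: str = "") -> DETestResult:
    """Two-group one-way ANOVA F-test on log2 expression.

    Equivalent to the squared equal-variance t statistic; df = (1, nf+nm-2).
    A pair of groups with zero between- and within-group variance (all
    values identical) is reported as F = 0, p = 1.
    """
    f = np.asarray(female_log2rpkm, dtype=float)
    m = np.asarray(male_log2rpkm, dtype=float)
    if f.size < 2 or m.size < 2:
        raise ValueError("need at least two samples per sex")
    n = f.size + m.size
    grand = np.concatenate([f, m]).mean()
    ss_between = f.size * (f.mean() - grand) ** 2 + m.size * (m.mean() - grand) ** 2
    ss_within = ((f - f.mean()) ** 2).sum() + ((m - m.mean()) ** 2).sum()
    df = (1, n - 2)
    if ss_between == 0:
        return DETestResult(unigene_id, 0.0, df, 1.0)
    if ss_within == 0:
        return DETestResult(unigene_id, float("inf"), df, 0.0)
    F = (ss_between / df[0]) / (ss_within / df[1])
    p = float(f_dist.sf(F, *df))
    return DETestResult(unigene_id, float(F), df, p)


@dataclass(frozen=True)
class AlleleExpressionRatio:
    unigene_id: str
    pooled_y_depth: int
    pooled_x_depth: int
    n_snps: int

    @property
    def undefined(self) -> bool:
        return self.pooled_x_depth == 0

    @property
    def ratio(self) -> float | None:
        if self.undefined:
            return None
        return self.pooled_y_depth / self.pooled_x_depth


@dataclass(frozen=True)
class SnpMaleDepths:
    """Per-male-sample X- and Y-allele depths at one qualifying SNP
    (pattern 1, heterozygous in every male sample)."""

    x_depths: tuple[int, ...]
    y_depths: tuple[int, ...]


def yx_ratio(snps: Sequence[SnpMaleDepths], unigene_id: str = "",
             min_snps: int = 2) -> AlleleExpressionRatio | None:
    """Pooled Y/X expression ratio for one gene, or None when fewer than
    ``min_snps`` SNPs qualify (a single SNP is too noisy to quote)."""
    if len(snps) < min_snps:
        return None
    y = sum(sum(s.y_depths) for s in snps)
    x = sum(sum(s.x_depths) for s in snps)
    return AlleleExpressionRatio(unigene_id, y, x, len(snps))


def per_snp_ratios(snps: Sequence[SnpMaleDepths]) -> list[float | None]:
    """Per-SNP pooled ratios, for diagnostics alongside the gene ratio."""
    out = []
    for s in snps:
        x = sum(s.x_depths)
        out.append(sum(s.y_depths) / x if x else None)
    return out


def de_fraction(results: pd.DataFrame, p_cutoff: float = 0.01,
                min_length_nt: int = 400) -> dict[str, float]:
    """Fraction of length-filtered unigenes significantly differentially
    expressed between sexes.

    ``results`` needs columns unigene, length, p.
    """
    kept = results[results["length"] > min_length_nt]
    n_total = len(kept)
    n_de = int((kept["p"] < p_cutoff).sum())
    return {
        "n_tested": n_total,
        "n_de": n_de,
        "fraction": n_de / n_total if n_total else 0.0,
    }
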