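"""End-to-end orchestration: variants -> genotypes -> segregation patterns
-> X/Y phasing -> Ka/Ks and dating -> expression and Y/X allele ratios.

Each stage is the corresponding library call; this module only wires them
together and writes the result tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import association, expression, genotyping, molevol, segregation
from .config import PipelineConfig
from .io import (SampleSheet, Sex, VariantTable, log, read_fasta,
                 read_variants, write_results)


@dataclass
class GeneKaKs:
    unigene_id: str
    n_snps: int
    result: molevol.KaKsResult


@dataclass
class PipelineResult:
    genotypes: list[genotyping.SiteGenotypes]
    classifications: list[segregation.SegregationClassification]
    totals: segregation.PatternTotals
    kaks: list[GeneKaKs]
    divergence: dict[str, float] | None
    yx_ratios: list[expression.AlleleExpressionRatio]
    recombinants: list[association.RecombinantCount]
    de_results: pd.DataFrame | None = None
    de_summary: dict[str, float] | None = None
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _p1_sites_by_gene(classifications, min_pattern=segregation.Pattern.P1):
    by_gene: dict[str, list] = {}
    for c in classifications:
        if c.pattern is segregation.Pattern.P1:
            by_gene.setdefault(c.unigene_id, []).append(c)
    return by_gene


def phase_and_rate_genes(classifications, variants: VariantTable,
                         reference: dict[str, str],
                         min_orf_len: int = 150) -> list[GeneKaKs]:
    """Phase X/Y allele CDSs for every gene with pattern-1 SNPs inside its
    ORF and compute Ka/Ks per gene.

    Genes whose longest ORF is on the reverse strand, or whose pattern-1
    SNPs all fall outside the ORF, are skipped with a log line (phasing is
    coordinate-based; no realignment is attempted).
    """
    sites_by_key = {(s.unigene_id, s.pos): s for s in variants}
    p1 = _p1_sites_by_gene(classifications)
    out: list[GeneKaKs] = []
    n_no_orf = n_rev = 0
    for gene_id, classed in sorted(p1.items()):
        seq = reference.get(gene_id)
        if seq is None:
            continue
        orf = molevol.find_orf(seq, min_len=min_orf_len)
        if orf is None:
            n_no_orf += 1
            continue
        if orf.strand == "-":
            n_rev += 1
            continue
        cds = orf.extract(seq)
        snps = []
        for c in classed:
            site = sites_by_key[(c.unigene_id, c.pos)]
            cds_pos = (c.pos - 1) - orf.start
            if not 0 <= cds_pos < len(cds):
                continue
            snps.append((cds_pos, site.alleles[c.x_allele],
                         site.alleles[c.y_allele]))
        if not snps:
            continue
        aln = molevol.phase_alleles(cds, snps)
        out.append(GeneKaKs(gene_id, len(snps), molevol.ka_ks(aln)))
    if n_no_orf or n_rev:
        log.info("phasing skipped %d genes without ORF, %d reverse-strand",
                 n_no_orf, n_rev)
    return out


def yx_ratios_from_depths(classifications, genotypes, samples: SampleSheet,
                          min_snps: int = 2,
                          ) -> list[expression.AlleleExpressionRatio]:
    """Pooled Y/X allele expression ratios from male allele depths at
    pattern-1 SNPs heterozygous in every male sample."""
    males = samples.progeny_males
    calls_by_key = {(sg.site.unigene_id, sg.site.pos): sg for sg in genotypes}
    by_gene: dict[str, list[expression.SnpMaleDepths]] = {}
    for c in classifications:
        if c.pattern is not segregation.Pattern.P1:
            continue
        sg = calls_by_key[(c.unigene_id, c.pos)]
        if not all(sg.calls[m].is_het for m in males):
            continue
        x_d, y_d = [], []
        for m in males:
            d = sg.site.depths[m].all
            x_d.append(d[c.x_allele])
            y_d.append(d[c.y_allele])
        by_gene.setdefault(c.unigene_id, []).append(
            expression.SnpMaleDepths(tuple(x_d), tuple(y_d)))
    out = []
    for gene_id, snps in sorted(by_gene.items()):
        r = expression.yx_ratio(snps, gene_id, min_snps=min_snps)
        if r is not None:
            out.append(r)
    return out


def cross_recombinants(classifications, genotypes, samples: SampleSheet,
                       ) -> list[association.RecombinantCount]:
    """Recombinant counts in the cross for every pattern-1 marker site
    (coupling: heterozygous in males)."""
    sex_of = {s.sample_id: s.sex.value for s in samples}
    progeny = samples.progeny_females + samples.progeny_males
    calls_by_key = {(sg.site.unigene_id, sg.site.pos): sg for sg in genotypes}
    out = []
    for c in classifications:
        if c.pattern is not segregation.Pattern.P1:
            continue
        sg = calls_by_key[(c.unigene_id, c.pos)]
        gts = [sg.calls[s] for s in progeny]
        sexes = [sex_of[s] for s in progeny]
        out.append(association.count_recombinants(
            gts, sexes, het_sex="male",
            marker_id=f"{c.unigene_id}:{c.pos}", population_id="cross"))
    return out


def run_expression(counts: pd.DataFrame, reference: dict[str, str],
                   samples: SampleSheet, config: PipelineConfig,
                   ) -> tuple[pd.DataFrame, dict[str, float]]:
    """RPKM -> log2 -> per-gene two-group F-test -> DE fraction."""
    mat = counts.pivot(index="unigene", columns="sample",
                       values="mapped_reads").fillna(0)
    lengths = {g: len(s) for g, s in reference.items()}
    rp = expression.rpkm_matrix(mat, lengths)
    lg = pd.DataFrame(expression.log2_rpkm(rp, config.rpkm_pseudocount),
                      index=rp.index, columns=rp.columns)
    females = [s for s in samples.progeny_females if s in lg.columns]
    males = [s for s in samples.progeny_males if s in lg.columns]
    rows = []
    for gene in lg.index:
        t = expression.sex_de_test(lg.loc[gene, females], lg.loc[gene, males],
                                   gene)
        rows.append({"unigene": gene, "length": lengths[gene], "F": t.F,
                     "df_between": t.df[0], "df_within": t.df[1], "p": t.p})
    results = pd.DataFrame(rows)
    summary = expression.de_fraction(results, config.de_p_cutoff,
                                     config.de_min_length)
    return results, summary


def run_pipeline(variants: VariantTable, samples: SampleSheet,
                 reference: dict[str, str],
                 counts: pd.DataFrame | None = None,
                 config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run every stage on in-memory inputs; optionally write all tables."""
    cfg = (config or PipelineConfig()).validate()
    samples.require_both_sexes()
    matrix = genotyping.genotype_matrix(variants, samples,
                                        cfg.min_total_depth, cfg.hom_fraction)
    classifications = segregation.classify_sites(
        matrix, samples, cfg.require_complete, cfg.min_per_sex)
    _, totals = segregation.aggregate_unigenes(classifications)
    kaks = phase_and_rate_genes(classifications, variants, reference,
                                cfg.min_orf_len)
    divergence = None
    ks_values = [g.result.Ks for g in kaks]
    if ks_values:
        divergence = molevol.summarize_divergence(
            ks_values, cfg.neutral_rate, cfg.generation_years)
    yx = yx_ratios_from_depths(classifications, matrix, samples,
                               cfg.min_yx_snps)
    recomb = cross_recombinants(classifications, matrix, samples)
    de_results = de_summary = None
    if counts is not None:
        de_results, de_summary = run_expression(counts, reference, samples, cfg)

    result = PipelineResult(matrix, classifications, totals, kaks, divergence,
                            yx, recomb, de_results, de_summary)
    result.tables = _result_tables(result)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in result.tables.items():
            write_results(df, out / f"{name}.tsv")
    return result


def _result_tables(res: PipelineResult) -> dict[str, pd.DataFrame]:
    tables = {
        "genotypes": genotyping.genotype_table(res.genotypes),
        "classification": segregation.classification_table(res.classifications),
        "pattern_totals": segregation.totals_table(res.totals),
        "kaks": pd.DataFrame([
            {"unigene": g.unigene_id, "n_snps": g.n_snps,
             "S": g.result.S, "N": g.result.N,
             "Sd": g.result.Sd, "Nd": g.result.Nd,
             "Ks": g.result.Ks, "Ka": g.result.Ka,
             "ka_ks": g.result.ka_ks}
            for g in res.kaks
        ]),
        "yx_ratios": pd.DataFrame([
            {"unigene": r.unigene_id, "n_snps": r.n_snps,
             "pooled_y_depth": r.pooled_y_depth,
             "pooled_x_depth": r.pooled_x_depth,
             "ratio": r.ratio}
            for r in res.yx_ratios
        ]),
        "recombinants": pd.DataFrame([
            {"marker": r.marker_id, "population": r.population_id,
             "n_recombinants": "n.v." if r.no_variant else r.n_recombinants}
            for r in res.recombinants
        ]),
    }
    if res.divergence is not None:
        tables["divergence"] = pd.DataFrame([res.divergence])
    if res.de_results is not None:
        tables["de_results"] = res.de_results
    return tables


def run_pipeline_from_dir(data_dir: str | Path,
                          config: PipelineConfig | None = None,
                          out_dir: str | Path | None = None) -> PipelineResult:
    """Run on a directory laid out like the synthetic generator's output."""
    data = Path(data_dir)
    samples = SampleSheet.from_tsv(data / "samples.tsv")
    reference = read_fasta(data / "reference.fasta")
    cfg = config or PipelineConfig()
    variants = read_variants(data / "variants.vcf", samples, cfg.min_qual)
    counts_path = data / "counts.tsv"
    counts = pd.read_csv(counts_path, sep="\t") if counts_path.exists() else None
    return run_pipeline(variants, samples, reference, counts, cfg, out_dir)
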