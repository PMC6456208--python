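"""Synthetic XY-cross data generator.

Generates datasets with the statistical structure the pipeline assumes: a
single dioecious cross (mother X1X2 x father X3Y) producing a balanced set
of female and male progeny, with genes in three genomic compartments:

* MSY — male-specific region of the Y: the X and Y copies stopped
  recombining ``xy_divergence_years`` ago and have accumulated fixed
  differences under neutral rate ``r`` per site per year, with
  non-synonymous changes accepted at probability ``ka_ks_target``.
  Following that structure, MSY genes carry only fixed X-Y differences.
* PAR — pseudoautosomal: still recombining with the X at frequency
  ``recomb_freq`` per meiosis, so it carries only segregating polymorphism
  (heterozygosity ``pi``), never fixed X-Y differences.
* autosome — segregating polymorphism, independent inheritance.

Read depths are sampled per site and sample (Poisson total, binomial
allele split with optional Y allelic bias in males, per-read miscall at
``error_rate``), expression counts are negative-binomial, and everything
derives from one seeded generator: the same seed reproduces the dataset
bit for bit. The generator also records full truth tables (true X/Y
sequences, every fixed difference with its site class, and the segregation
pattern each site shows in the noise-free genotypes), so every pipeline
stage can be scored against what was simulated.

The substitution model is Jukes-Cantor (uniform base exchange), matching
the analysis-side multiple-hit correction exactly; richer models are out
of scope by design.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotyping import AlleleDepth
from .io import (Role, Sample, SampleSheet, Sex, VariantSite, VariantTable,
                 write_fasta, write_variants_vcf)
from .molevol import GENETIC_CODE, STOP_CODONS
from .segregation import Pattern, classify_site
from .genotyping import GenotypeCall, GenotypeState

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}

MSY = "MSY"
PAR = "PAR"
AUTOSOME = "autosome"


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults are the conditions of the reference analysis: 8+8 progeny of a
    single cross, ~50x depth, X-Y divergence 0.4 My under r = 6.5e-9 per
    site per year (one generation per year), with 50 MSY, 100 PAR and 200
    autosomal genes of 1200 nt coding length (a typical plant CDS).
    """

    n_msy: int = 50
    n_par: int = 100
    n_autosome: int = 200
    gene_length: int = 1200                  # nt, multiple of 3, incl. ATG+stop
    xy_divergence_years: float = 4.0e5
    interspecific_divergence_years: float = 5.66e6
    n_orthologs: int = 100                   # interspecific ortholog pairs
    r: float = 6.5e-9                        # substitutions/site/year
    ka_ks_target: float = 0.25               # acceptance prob. of nonsyn changes
    n_progeny_per_sex: int = 8
    depth_mean: float = 50.0                 # reads per site per sample
    error_rate: float = 0.005                # per-read miscall probability
    pi: float = 0.003                        # segregating-site density (PAR/autosome)
    recomb_freq: float = 0.1                 # X3-Y crossover prob. per meiosis (PAR)
    allelic_bias: float = 1.0                # Y allele expression relative to X
    expression_mean: float = 400.0           # NB mean mapped reads per gene/sample
    expression_dispersion: float = 0.2       # NB dispersion (1/size)
    gc_content: float = 0.45
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.gene_length < 300 or self.gene_length % 3:
            raise ValueError("gene_length must be >= 300 and a multiple of 3")
        for name in ("ka_ks_target", "error_rate", "pi", "recomb_freq",
                     "gc_content"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if 2 * self.r * self.xy_divergence_years >= 0.75:
            raise ValueError("X-Y divergence is saturated under this rate")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw).validate()


@dataclass(frozen=True)
class FixedDifference:
    pos: int           # 0-based on the gene
    x_base: str
    y_base: str
    site_class: str    # "syn" | "nonsyn"


@dataclass
class GeneTruth:
    """Everything the generator knows about one gene.

    Haplotype keys: M1/M2 are the mother's two copies; P1 is the father's
    X (or first autosome copy), P2 his Y (or second autosome copy).
    """

    gene_id: str
    compartment: str
    haplotypes: dict[str, str]
    fixed_diffs: list[FixedDifference]
    divergence_years: float
    true_site_patterns: dict[int, Pattern] = field(default_factory=dict)

    @property
    def seq_x(self) -> str:
        return self.haplotypes["P1"]

    @property
    def seq_y(self) -> str:
        return self.haplotypes["P2"]

    @property
    def true_patterns(self) -> set[Pattern]:
        return {p for p in self.true_site_patterns.values()
                if p is not Pattern.NONE}


# ---------------------------------------------------------------------------
# reference sequences and lineage evolution

def _random_codon(rng: np.random.Generator, p: np.ndarray) -> str:
    while True:
        codon = "".join(_BASES[i] for i in rng.choice(4, size=3, p=p))
        if codon not in STOP_CODONS:
            return codon


def generate_reference(n_genes: int, gene_length: int, gc_content: float,
                       rng: np.random.Generator) -> dict[str, str]:
    """Random CDSs: ATG + random sense codons + one stop; no internal stop."""
    if gene_length < 9 or gene_length % 3:
        raise ValueError("gene_length must be a multiple of 3, >= 9")
    at = (1 - gc_content) / 2
    gc = gc_content / 2
    p = np.array([at, gc, gc, at])
    stops = sorted(STOP_CODONS)
    out = {}
    for i in range(n_genes):
        n_internal = gene_length // 3 - 2
        body = "".join(_random_codon(rng, p) for _ in range(n_internal))
        stop = stops[rng.integers(len(stops))]
        out[f"g{i + 1:04d}"] = "ATG" + body + stop
    return out


def _mutate_lineage(seq: str, years: float, r: float, ka_ks_target: float,
                    rng: np.random.Generator) -> str:
    """Place a Poisson number of substitutions on one lineage.

    Proposals land uniformly on the internal codons; a proposal creating a
    stop codon is rejected, a non-synonymous proposal is accepted with
    probability ``ka_ks_target``, a synonymous one always. The start and
    stop codons are never touched, so the ORF survives evolution.
    """
    L_mut = len(seq) - 6
    n = rng.poisson(L_mut * r * years)
    s = list(seq)
    for _ in range(n):
        pos = int(rng.integers(3, len(seq) - 3))
        old = s[pos]
        new = _BASES[(_BASE_IDX[old] + 1 + rng.integers(3)) % 4]
        c0 = pos - pos % 3
        codon_old = "".join(s[c0:c0 + 3])
        codon_new = codon_old[: pos - c0] + new + codon_old[pos - c0 + 1:]
        if codon_new in STOP_CODONS:
            continue
        if GENETIC_CODE[codon_old] != GENETIC_CODE[codon_new]:
            if rng.random() >= ka_ks_target:
                continue
        s[pos] = new
    return "".join(s)


def evolve_pair(cds: str, years: float, r: float, ka_ks_target: float,
                rng: np.random.Generator,
                ) -> tuple[str, str, list[FixedDifference]]:
    """Evolve two lineages independently from a common ancestor for
    ``years`` each; expected neutral divergence between them is 2*r*years.

    Returns (seq_a, seq_b, fixed differences classified syn/nonsyn by
    whether the two final codons encode the same amino acid).
    """
    if years < 0:
        raise ValueError("divergence age cannot be negative")
    if 2 * r * years >= 0.75:
        raise ValueError("expected divergence is saturated")
    a = _mutate_lineage(cds, years, r, ka_ks_target, rng)
    b = _mutate_lineage(cds, years, r, ka_ks_target, rng)
    diffs = []
    for pos, (ba, bb) in enumerate(zip(a, b)):
        if ba == bb:
            continue
        c0 = pos - pos % 3
        syn = GENETIC_CODE[a[c0:c0 + 3]] == GENETIC_CODE[b[c0:c0 + 3]]
        diffs.append(FixedDifference(pos, ba, bb, "syn" if syn else "nonsyn"))
    return a, b, diffs


def _segregating_sites(ref: str, pi: float, rng: np.random.Generator,
                       ) -> dict[str, str]:
    """Four haplotypes differing from ref by random biallelic segregating
    sites (density ``pi`` per internal site); derived alleles never create
    a stop codon on the reference background."""
    haps = {k: list(ref) for k in ("M1", "M2", "P1", "P2")}
    n = rng.poisson(pi * (len(ref) - 6))
    used: set[int] = set()
    for _ in range(n):
        for _try in range(50):
            pos = int(rng.integers(3, len(ref) - 3))
            if pos in used:
                continue
            old = ref[pos]
            new = _BASES[(_BASE_IDX[old] + 1 + rng.integers(3)) % 4]
            c0 = pos - pos % 3
            codon = ref[c0:c0 + 3]
            codon_new = codon[: pos - c0] + new + codon[pos - c0 + 1:]
            if codon_new in STOP_CODONS:
                continue
            carriers = rng.random(4) < 0.5
            if not carriers.any() or carriers.all():
                continue
            used.add(pos)
            for k, hit in zip(("M1", "M2", "P1", "P2"), carriers):
                if hit:
                    haps[k][pos] = new
            break
    return {k: "".join(v) for k, v in haps.items()}


def build_genes(config: SimConfig, rng: np.random.Generator,
                ) -> tuple[dict[str, str], list[GeneTruth]]:
    """Reference CDSs plus per-gene parental haplotypes and truth."""
    n_total = config.n_msy + config.n_par + config.n_autosome
    reference = generate_reference(n_total, config.gene_length,
                                   config.gc_content, rng)
    compartments = ([MSY] * config.n_msy + [PAR] * config.n_par
                    + [AUTOSOME] * config.n_autosome)
    genes = []
    for (gid, ref), comp in zip(reference.items(), compartments):
        if comp == MSY:
            x, y, diffs = evolve_pair(ref, config.xy_divergence_years,
                                      config.r, config.ka_ks_target, rng)
            haps = {"M1": x, "M2": x, "P1": x, "P2": y}
            genes.append(GeneTruth(gid, comp, haps, diffs,
                                   config.xy_divergence_years))
        else:
            haps = _segregating_sites(ref, config.pi, rng)
            genes.append(GeneTruth(gid, comp, haps, [], 0.0))
    return reference, genes


# ---------------------------------------------------------------------------
# the cross

def make_sample_sheet(n_per_sex: int) -> SampleSheet:
    samples = [Sample(f"F{i + 1:02d}", Sex.FEMALE, Role.PROGENY, "cross")
               for i in range(n_per_sex)]
    samples += [Sample(f"M{i + 1:02d}", Sex.MALE, Role.PROGENY, "cross")
                for i in range(n_per_sex)]
    return SampleSheet(samples)


def simulate_cross(genes: list[GeneTruth], config: SimConfig,
                   rng: np.random.Generator,
                   ) -> tuple[SampleSheet, dict[str, list[tuple[str, str]]]]:
    """Draw progeny haplotype inheritance, sex forced to n per sex.

    Each child receives one maternal copy (fair draw per gene) and a
    paternal copy set by its sex: daughters the paternal X, sons the Y.
    For PAR genes an X3-Y crossover at ``recomb_freq`` swaps the paternal
    copy; autosomal genes take either paternal copy at random. MSY genes
    never recombine.
    """
    sheet = make_sample_sheet(config.n_progeny_per_sex)
    sexes = [s.sex for s in sheet]
    inheritance: dict[str, list[tuple[str, str]]] = {}
    for gene in genes:
        draws = []
        for sex in sexes:
            mat = "M1" if rng.random() < 0.5 else "M2"
            if gene.compartment == AUTOSOME:
                pat = "P1" if rng.random() < 0.5 else "P2"
            else:
                pat = "P1" if sex is Sex.FEMALE else "P2"
                if gene.compartment == PAR and rng.random() < config.recomb_freq:
                    pat = "P2" if pat == "P1" else "P1"
            draws.append((mat, pat))
        inheritance[gene.gene_id] = draws
    return sheet, inheritance


def _variant_positions(gene: GeneTruth, ref: str) -> list[int]:
    pos = set()
    for hap in gene.haplotypes.values():
        pos.update(i for i, (a, b) in enumerate(zip(ref, hap)) if a != b)
    return sorted(pos)


def _true_call(base_pair: tuple[str, str], alleles: list[str]) -> GenotypeCall:
    i, j = sorted(alleles.index(b) for b in base_pair)
    if i == j:
        state = GenotypeState.HOM_REF if i == 0 else GenotypeState.HOM_ALT
        return GenotypeCall(state, (i, i))
    return GenotypeCall(GenotypeState.HET, (i, j))


def annotate_true_patterns(genes: list[GeneTruth], reference: dict[str, str],
                           sheet: SampleSheet,
                           inheritance: dict[str, list[tuple[str, str]]],
                           ) -> None:
    """Record, per variant site, the segregation pattern implied by the
    noise-free true genotypes — the oracle the noisy pipeline is scored
    against."""
    sex_of = [s.sex for s in sheet]
    for gene in genes:
        ref = reference[gene.gene_id]
        draws = inheritance[gene.gene_id]
        for pos in _variant_positions(gene, ref):
            bases = {ref[pos]} | {h[pos] for h in gene.haplotypes.values()}
            alleles = [ref[pos]] + sorted(bases - {ref[pos]})
            f_calls, m_calls = [], []
            for (mat, pat), sex in zip(draws, sex_of):
                pair = (gene.haplotypes[mat][pos], gene.haplotypes[pat][pos])
                call = _true_call(pair, alleles)
                (f_calls if sex is Sex.FEMALE else m_calls).append(call)
            cls = classify_site(f_calls, m_calls, gene.gene_id, pos + 1)
            gene.true_site_patterns[pos] = cls.pattern


# ---------------------------------------------------------------------------
# read-depth and expression sampling

def _sample_site_depth(base_pair: tuple[str, str], p_second: float,
                       depth_mean: float, error_rate: float,
                       rng: np.random.Generator) -> dict[str, int]:
    """Observed per-base read depths for one genotype at one site."""
    total = int(rng.poisson(depth_mean))
    b1, b2 = base_pair
    if b1 == b2:
        true_counts = {b1: total}
    else:
        n2 = int(rng.binomial(total, p_second))
        true_counts = {b1: total - n2, b2: n2}
    observed: dict[str, int] = defaultdict(int)
    for base, n in true_counts.items():
        n_err = int(rng.binomial(n, error_rate)) if error_rate > 0 else 0
        observed[base] += n - n_err
        if n_err:
            others = [b for b in _BASES if b != base]
            split = rng.multinomial(n_err, [1 / 3] * 3)
            for b, k in zip(others, split):
                if k:
                    observed[b] += int(k)
    return dict(observed)


def simulate_depths(genes: list[GeneTruth], reference: dict[str, str],
                    sheet: SampleSheet,
                    inheritance: dict[str, list[tuple[str, str]]],
                    config: SimConfig, rng: np.random.Generator,
                    ) -> VariantTable:
    """Sample a VCF-shaped variant table with AD depths for every site at
    which any parental haplotype differs from the reference.

    The Y allelic bias applies to the paternal allele of sex-linked genes
    in male samples: a Y allele expressed at ``allelic_bias`` relative to X
    contributes reads with probability bias/(1+bias) at a heterozygous
    site.
    """
    sample_ids = sheet.ids
    sex_of = {s.sample_id: s.sex for s in sheet}
    p_y = config.allelic_bias / (1.0 + config.allelic_bias)
    sites: list[VariantSite] = []
    for gene in genes:
        ref = reference[gene.gene_id]
        draws = inheritance[gene.gene_id]
        sex_linked = gene.compartment in (MSY, PAR)
        for pos in _variant_positions(gene, ref):
            per_sample_bases: dict[str, dict[str, int]] = {}
            for sid, (mat, pat) in zip(sample_ids, draws):
                pair = (gene.haplotypes[mat][pos], gene.haplotypes[pat][pos])
                is_y = (sex_of[sid] is Sex.MALE and sex_linked and pat == "P2")
                p_second = p_y if (is_y and pair[0] != pair[1]) else 0.5
                per_sample_bases[sid] = _sample_site_depth(
                    pair, p_second, config.depth_mean, config.error_rate, rng)
            true_alts = sorted(
                {h[pos] for h in gene.haplotypes.values()} - {ref[pos]})
            error_alts = sorted(
                {b for d in per_sample_bases.values() for b in d}
                - {ref[pos]} - set(true_alts))
            alts = tuple(true_alts + error_alts)
            if not alts:
                continue
            depths = {
                sid: AlleleDepth(bases.get(ref[pos], 0),
                                 tuple(bases.get(a, 0) for a in alts))
                for sid, bases in per_sample_bases.items()
            }
            sites.append(VariantSite(gene.gene_id, pos + 1, ref[pos], alts,
                                     depths))
    return VariantTable(sites, sample_ids)


def simulate_expression(genes: list[GeneTruth], sheet: SampleSheet,
                        config: SimConfig, rng: np.random.Generator,
                        ) -> pd.DataFrame:
    """Negative-binomial mapped-read counts per gene and sample (tidy)."""
    size = 1.0 / config.expression_dispersion
    rows = []
    for gene in genes:
        mu = config.expression_mean
        p = size / (size + mu)
        for s in sheet:
            reads = int(rng.negative_binomial(size, p))
            rows.append({"unigene": gene.gene_id, "sample": s.sample_id,
                         "mapped_reads": reads})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# unrelated association panel and ortholog pairs

def simulate_association_panel(gene: GeneTruth, pos: int, n_males: int,
                               n_females: int, rng: np.random.Generator,
                               ) -> tuple[list[GenotypeCall], list[str]]:
    """Marker genotypes for an unrelated panel at one site of a gene.

    Every male is X+Y with an independent X draw from the X pool; every
    female draws two X copies. For an MSY gene the Y never recombines away,
    which is what drives the association p far below any cross-scale value.
    """
    ref0 = gene.haplotypes["M1"][pos]
    x_pool = [gene.haplotypes[k][pos] for k in ("M1", "M2", "P1")]
    bases = sorted({h[pos] for h in gene.haplotypes.values()} | {ref0})
    alleles = [ref0] + [b for b in bases if b != ref0]
    calls, sexes = [], []
    y_base = gene.haplotypes["P2"][pos]
    for _ in range(n_males):
        x = x_pool[rng.integers(len(x_pool))]
        calls.append(_true_call((x, y_base), alleles))
        sexes.append("male")
    for _ in range(n_females):
        x1 = x_pool[rng.integers(len(x_pool))]
        x2 = x_pool[rng.integers(len(x_pool))]
        calls.append(_true_call((x1, x2), alleles))
        sexes.append("female")
    return calls, sexes


def generate_ortholog_pairs(config: SimConfig, rng: np.random.Generator,
                            ) -> list[tuple[str, str, str]]:
    """Interspecific ortholog pairs (gene_id, seq_a, seq_b) diverged for
    ``interspecific_divergence_years`` — the dating benchmark set."""
    ref = generate_reference(config.n_orthologs, config.gene_length,
                             config.gc_content, rng)
    out = []
    for gid, seq in ref.items():
        a, b, _ = evolve_pair(seq, config.interspecific_divergence_years,
                              config.r, config.ka_ks_target, rng)
        out.append((f"ortho_{gid}", a, b))
    return out


# ---------------------------------------------------------------------------
# dataset assembly

@dataclass
class SimDataset:
    config: SimConfig
    reference: dict[str, str]
    genes: list[GeneTruth]
    samples: SampleSheet
    inheritance: dict[str, list[tuple[str, str]]]
    variants: VariantTable
    counts: pd.DataFrame

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            rows.append({
                "unigene": g.gene_id,
                "compartment": g.compartment,
                "divergence_years": g.divergence_years,
                "n_fixed_diffs": len(g.fixed_diffs),
                "fixed_diff_pos": ",".join(str(d.pos + 1) for d in g.fixed_diffs),
                "fixed_diff_class": ",".join(d.site_class for d in g.fixed_diffs),
                "true_patterns": ",".join(
                    sorted(p.value for p in g.true_patterns)),
                "seq_x": g.seq_x,
                "seq_y": g.seq_y,
            })
        return pd.DataFrame(rows)


def generate_dataset(config: SimConfig, out_dir: str | Path | None = None,
                     ) -> SimDataset:
    """Build one self-consistent dataset; optionally write it to disk as
    reference.fasta, variants.vcf, counts.tsv, samples.tsv, truth.tsv."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    reference, genes = build_genes(config, rng)
    sheet, inheritance = simulate_cross(genes, config, rng)
    annotate_true_patterns(genes, reference, sheet, inheritance)
    variants = simulate_depths(genes, reference, sheet, inheritance, config, rng)
    counts = simulate_expression(genes, sheet, config, rng)
    ds = SimDataset(config, reference, genes, sheet, inheritance, variants,
                    counts)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(reference, out / "reference.fasta")
        write_variants_vcf(variants, out / "variants.vcf",
                           {g: len(s) for g, s in reference.items()})
        counts.to_csv(out / "counts.tsv", sep="\t", index=False)
        sheet.to_tsv(out / "samples.tsv")
        ds.truth_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
    return ds
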