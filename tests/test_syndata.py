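import numpy as np
import pytest

from spinsex import molevol as me
from spinsex import syndata as sd
from spinsex.io import Sex
from spinsex.segregation import Pattern


def test_reference_is_deterministic_and_stop_free(rng):
    rng2 = np.random.default_rng(1234)
    a = sd.generate_reference(20, 300, 0.45, rng)
    b = sd.generate_reference(20, 300, 0.45, rng2)
    assert a == b
    for seq in a.values():
        assert seq.startswith("ATG")
        assert seq[-3:] in me.STOP_CODONS
        for i in range(0, len(seq) - 3, 3):
            assert seq[i:i + 3] not in me.STOP_CODONS


def test_reference_gc_content_tracks_config(rng):
    seqs = sd.generate_reference(100, 600, 0.60, rng)
    gc = np.mean([(s.count("G") + s.count("C")) / len(s)
                  for s in seqs.values()])
    # stop-codon avoidance shifts composition slightly; band is generous
    assert 0.55 < gc < 0.65


def test_evolve_pair_zero_years_is_identity(rng):
    cds = sd.generate_reference(1, 300, 0.45, rng)["g0001"]
    a, b, diffs = sd.evolve_pair(cds, 0.0, 6.5e-9, 0.25, rng)
    assert a == b == cds
    assert diffs == []


def test_evolve_pair_zero_kaks_target_blocks_amino_acid_changes(rng):
    cds = sd.generate_reference(1, 900, 0.45, rng)["g0001"]
    a, b, diffs = sd.evolve_pair(cds, 5e6, 6.5e-9, 0.0, rng)
    assert all(d.site_class == "syn" for d in diffs)
    prot_a = me.GENETIC_CODE
    # translated proteins identical
    ta = [me.GENETIC_CODE[a[i:i+3]] for i in range(0, len(a) - 3, 3)]
    tb = [me.GENETIC_CODE[b[i:i+3]] for i in range(0, len(b) - 3, 3)]
    assert ta == tb


def test_evolve_pair_saturation_guard(rng):
    with pytest.raises(ValueError, match="saturat"):
        sd.evolve_pair("ATG" + "AAA" * 98 + "TAA", 1e9, 6.5e-9, 0.25, rng)


def test_realized_synonymous_divergence_matches_clock(rng):
    """Mean pipeline-measured Ks over many simulated pairs sits within two
    standard errors of the 2rT expectation."""
    years, r = 4e5, 6.5e-9
    ks = []
    refs = sd.generate_reference(200, 900, 0.45, rng)
    for cds in refs.values():
        a, b, _ = sd.evolve_pair(cds, years, r, 0.25, rng)
        ks.append(me.ka_ks(me.CodingAlignment(a, b)).Ks)
    ks = np.array(ks)
    se = ks.std(ddof=1) / np.sqrt(ks.size)
    assert abs(ks.mean() - 2 * r * years) < 2 * se


def test_msy_cross_sons_het_daughters_hom(rng):
    cfg = sd.SimConfig(n_msy=5, n_par=0, n_autosome=0, gene_length=600,
                       seed=3)
    ds = sd.generate_dataset(cfg)
    for gene in ds.genes:
        draws = ds.inheritance[gene.gene_id]
        sexes = [s.sex for s in ds.samples]
        for d in gene.fixed_diffs:
            for (mat, pat), sex in zip(draws, sexes):
                pair = {gene.haplotypes[mat][d.pos], gene.haplotypes[pat][d.pos]}
                if sex is Sex.MALE:
                    assert len(pair) == 2   # son carries X and Y alleles
                else:
                    assert len(pair) == 1   # daughter homozygous


def test_autosomal_maternal_het_segregates_one_to_one(rng):
    """A site heterozygous in the mother and absent from the father feeds
    each child one derived allele with probability 1/2, in both sexes."""
    cfg = sd.SimConfig(n_msy=0, n_par=0, n_autosome=300, gene_length=300,
                       pi=0.01, n_progeny_per_sex=8, seed=7)
    rng2 = np.random.default_rng(cfg.seed)
    _, genes = sd.build_genes(cfg, rng2)
    sheet, inheritance = sd.simulate_cross(genes, cfg, rng2)
    n_child = n_derived = 0
    for gene in genes:
        for pos in range(len(gene.haplotypes["M1"])):
            m1, m2 = gene.haplotypes["M1"][pos], gene.haplotypes["M2"][pos]
            p1, p2 = gene.haplotypes["P1"][pos], gene.haplotypes["P2"][pos]
            if m1 == m2 or p1 != p2:
                continue  # want: maternal het, paternal hom
            for mat, _pat in inheritance[gene.gene_id]:
                n_child += 1
                n_derived += gene.haplotypes[mat][pos] != m1
    frac = n_derived / n_child
    se = np.sqrt(0.25 / n_child)
    assert abs(frac - 0.5) < 3 * se


def test_depths_pure_at_zero_error(rng):
    cfg = sd.SimConfig(n_msy=3, n_par=3, n_autosome=3, gene_length=600,
                       error_rate=0.0, seed=13)
    ds = sd.generate_dataset(cfg)
    genes = {g.gene_id: g for g in ds.genes}
    for site in ds.variants:
        gene = genes[site.unigene_id]
        for sid, (mat, pat) in zip(ds.samples.ids,
                                   ds.inheritance[site.unigene_id]):
            true = {gene.haplotypes[mat][site.pos - 1],
                    gene.haplotypes[pat][site.pos - 1]}
            d = site.depths[sid]
            observed = {a for a, dp in zip(site.alleles, d.all) if dp > 0}
            assert observed <= true


def test_het_allele_fraction_is_balanced_without_bias(rng):
    fracs = []
    for _ in range(1000):
        obs = sd._sample_site_depth(("A", "G"), 0.5, 60, 0.0, rng)
        tot = sum(obs.values())
        if tot:
            fracs.append(obs.get("G", 0) / tot)
    m = np.mean(fracs)
    se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
    assert abs(m - 0.5) < 2 * se


def test_dataset_files_are_seed_deterministic(tmp_path):
    cfg = sd.SimConfig(n_msy=3, n_par=3, n_autosome=3, gene_length=300, seed=21)
    sd.generate_dataset(cfg, tmp_path / "a")
    sd.generate_dataset(cfg, tmp_path / "b")
    for name in ("reference.fasta", "variants.vcf", "counts.tsv",
                 "samples.tsv", "truth.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == \
            (tmp_path / "b" / name).read_bytes(), name


def test_different_seeds_give_different_variants(tmp_path):
    cfg_a = sd.SimConfig(n_msy=3, n_par=3, n_autosome=3, gene_length=300, seed=1)
    cfg_b = sd.SimConfig(n_msy=3, n_par=3, n_autosome=3, gene_length=300, seed=2)
    a = sd.generate_dataset(cfg_a)
    b = sd.generate_dataset(cfg_b)
    pos_a = {(s.unigene_id, s.pos) for s in a.variants}
    pos_b = {(s.unigene_id, s.pos) for s in b.variants}
    assert pos_a != pos_b


def test_truth_table_covers_all_genes(tiny_sim):
    truth = tiny_sim.truth_frame()
    cfg = tiny_sim.config
    assert len(truth) == cfg.n_msy + cfg.n_par + cfg.n_autosome
    assert set(truth["compartment"]) == {"MSY", "PAR", "autosome"}
    msy = truth[truth["compartment"] == "MSY"]
    assert (msy["divergence_years"] == cfg.xy_divergence_years).all()
    # only MSY genes carry fixed X-Y differences
    other = truth[truth["compartment"] != "MSY"]
    assert (other["n_fixed_diffs"] == 0).all()


def test_msy_fixed_differences_show_pattern1_in_true_genotypes(tiny_sim):
    for gene in tiny_sim.genes:
        if gene.compartment != "MSY":
            continue
        for d in gene.fixed_diffs:
            assert gene.true_site_patterns[d.pos] is Pattern.P1


def test_par_full_recombination_breaks_sex_association():
    """At 50% X-Y crossover a PAR gene segregates like an autosome: the
    cross progeny show no systematic sex-genotype coupling, so exact-test
    p-values stay unremarkable (the exact test is conservative under the
    null, so we check against extremes rather than exact uniformity)."""
    from spinsex.association import fisher_exact_2xk, genotype_sex_table

    cfg = sd.SimConfig(n_msy=0, n_par=60, n_autosome=0, gene_length=600,
                       recomb_freq=0.5, pi=0.01, seed=17)
    rng = np.random.default_rng(5)
    _, genes = sd.build_genes(cfg, rng)
    sheet, inheritance = sd.simulate_cross(genes, cfg, rng)
    sexes = [s.sex.value for s in sheet]
    ps = []
    for gene in genes:
        ref = gene.haplotypes["M1"]
        for pos in sd._variant_positions(gene, ref):
            bases = {ref[pos]} | {h[pos] for h in gene.haplotypes.values()}
            alleles = [ref[pos]] + sorted(bases - {ref[pos]})
            calls = [
                sd._true_call((gene.haplotypes[mat][pos],
                               gene.haplotypes[pat][pos]), alleles)
                for mat, pat in inheritance[gene.gene_id]
            ]
            ps.append(fisher_exact_2xk(genotype_sex_table(calls, sexes)))
    ps = np.array(ps)
    assert len(ps) > 50
    assert ps.min() > 1e-5   # nothing approaches the sex-linked extreme
    assert (ps > 0.05).mean() > 0.5
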