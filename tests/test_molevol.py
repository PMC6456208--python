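import math

import numpy as np
import pytest
from Bio.Seq import Seq

from spinsex import molevol as me
from oracles import (oracle_ng_differences, oracle_ng_sites,
                     oracle_orfs, oracle_pair_counts, oracle_rank_sum)


# ---------------------------------------------------------------------------
# ORF finding

def test_single_orf():
    orf = me.find_orf("ATGAAATAG", min_len=9)
    assert (orf.strand, orf.frame, orf.start, orf.end) == ("+", 0, 0, 9)
    assert orf.extract("ATGAAATAG") == "ATGAAATAG"


def test_no_atg_means_no_orf():
    assert me.find_orf("TTTTTTTTTTTT", min_len=9) is None


def test_min_length_filters_short_orfs():
    assert me.find_orf("ATGAAATAG", min_len=12) is None


def test_reverse_strand_orf_found():
    fwd = "ATGAAACCCGGGTTTACGTAG"          # 21 nt ORF
    seq = str(Seq(fwd).reverse_complement()) + "TT"
    orf = me.find_orf(seq, min_len=21)
    assert orf.strand == "-"
    assert orf.extract(seq) == fwd


def test_longest_orf_matches_six_frame_brute_force(rng):
    bases = np.array(list("ACGT"))
    for _ in range(25):
        seq = "".join(rng.choice(bases, size=200))
        rc = str(Seq(seq).reverse_complement())
        expected = oracle_orfs(seq, rc)
        got = me.find_orf(seq, min_len=1)
        if not expected:
            assert got is None
            continue
        best = min((-l, strand, start % 3, start) for l, strand, start, _ in expected)
        assert -best[0] == got.end - got.start
        assert got.strand == ("+" if best[1] == 0 else "-")
        assert got.start == best[3]


def test_empty_sequence_is_an_error():
    with pytest.raises(ValueError):
        me.find_orf("")


# ---------------------------------------------------------------------------
# phasing

def test_phase_single_substitution():
    aln = me.phase_alleles("ATGTTTTAA", [(5, "T", "A")])
    assert aln.seq_x == "ATGTTTTAA"
    assert aln.seq_y == "ATGTTATAA"


def test_phase_without_snps_is_identity():
    aln = me.phase_alleles("ATGTTTTAA", [])
    assert aln.seq_x == aln.seq_y == "ATGTTTTAA"


def test_phase_two_snps_in_one_codon():
    aln = me.phase_alleles("ATGTTTTAA", [(3, "T", "G"), (5, "T", "A")])
    assert aln.seq_y == "ATGGTATAA"


def test_phase_conflicting_duplicate_positions():
    with pytest.raises(ValueError, match="conflict"):
        me.phase_alleles("ATGTTTTAA", [(5, "T", "A"), (5, "T", "G")])
    # agreeing duplicates are fine
    me.phase_alleles("ATGTTTTAA", [(5, "T", "A"), (5, "T", "A")])


# ---------------------------------------------------------------------------
# Nei-Gojobori counting

@pytest.mark.parametrize("codon,s,n", [
    ("TTT", 1 / 3, 8 / 3),
    ("GGG", 1.0, 2.0),
    ("ATG", 0.0, 3.0),  # Met: no synonymous change exists
])
def test_site_counts_for_known_codons(codon, s, n):
    got = me.ng_sites(codon)
    assert got == pytest.approx((s, n), abs=1e-12)


def test_site_counts_reject_stops_and_ambiguity():
    with pytest.raises(ValueError):
        me.ng_sites("TAA")
    with pytest.raises(ValueError):
        me.ng_sites("ANA")


def test_sites_sum_to_three_over_all_sense_codons():
    total = 0.0
    for codon in me.SENSE_CODONS:
        s, n = me.ng_sites(codon)
        assert s + n == pytest.approx(3.0, abs=1e-12)
        total += s + n
    assert total == pytest.approx(183.0, abs=1e-9)
    assert len(me.SENSE_CODONS) == 61


@pytest.mark.parametrize("a,b,sd,nd", [
    ("TTT", "TTC", 1.0, 0.0),   # Phe -> Phe
    ("TTT", "TTA", 0.0, 1.0),   # Phe -> Leu
    ("TTT", "GTA", 0.5, 1.5),   # average over the two open pathways
    ("AAA", "AAA", 0.0, 0.0),
])
def test_difference_counts_for_known_pairs(a, b, sd, nd):
    assert me.ng_differences(a, b) == pytest.approx((sd, nd), abs=1e-12)


def test_differences_match_enumeration_oracle_over_all_pairs():
    for a in me.SENSE_CODONS:
        for b in me.SENSE_CODONS:
            ours = me.ng_differences(a, b)
            ref = oracle_ng_differences(a, b)
            if ref is None:
                assert ours is None
            else:
                assert ours == pytest.approx(ref, abs=1e-12), (a, b)


def test_sites_match_enumeration_oracle_over_all_codons():
    for codon in me.SENSE_CODONS:
        assert me.ng_sites(codon) == pytest.approx(
            oracle_ng_sites(codon), abs=1e-12), codon


# ---------------------------------------------------------------------------
# Jukes-Cantor and Ka/Ks composition

def test_jukes_cantor_values_and_domain():
    assert me.jukes_cantor(0.0) == 0.0
    assert me.jukes_cantor(0.10) == pytest.approx(0.10733, abs=5e-6)
    with pytest.raises(ValueError):
        me.jukes_cantor(0.75)
    with pytest.raises(ValueError):
        me.jukes_cantor(-0.01)


def test_jukes_cantor_never_shrinks_and_is_increasing():
    grid = np.linspace(0.0, 0.74, 200)
    d = np.array([me.jukes_cantor(p) for p in grid])
    assert (d >= grid - 1e-15).all()
    assert (np.diff(d) > 0).all()


def test_identical_sequences_have_zero_rates():
    res = me.ka_ks(me.CodingAlignment("ATGTTTGGG", "ATGTTTGGG"))
    assert res.Ks == res.Ka == 0.0
    assert res.ka_ks is None  # Ks = 0: ratio undefined


def test_single_codon_alignment_composes_sites_and_differences():
    # TTT vs TTC: one synonymous difference on ~1/3 synonymous site
    res = me.ka_ks(me.CodingAlignment("TTT", "TTC"))
    s_avg = (me.ng_sites("TTT")[0] + me.ng_sites("TTC")[0]) / 2
    assert res.S == pytest.approx(s_avg)
    assert res.Sd == 1.0 and res.Nd == 0.0
    assert res.pS == pytest.approx(1.0 / s_avg)
    # one difference on a third of a site saturates the correction
    with pytest.raises(ValueError, match="saturation"):
        res.Ks
    assert res.Ka == 0.0


def test_multi_codon_alignment_composes_counts_and_jc():
    # nine codons, one synonymous difference: Ks = jc(Sd / S)
    x = "TTTAAAGGGCCCATGTGGAAAGGGCCC"
    y = "TTCAAAGGGCCCATGTGGAAAGGGCCC"
    res = me.ka_ks(me.CodingAlignment(x, y))
    s_avg = sum(me.ng_sites(x[i:i + 3])[0] for i in range(0, len(x), 3))
    s_avg = (s_avg + sum(me.ng_sites(y[i:i + 3])[0]
                         for i in range(0, len(y), 3))) / 2
    assert res.S == pytest.approx(s_avg)
    assert res.Sd == 1.0 and res.Nd == 0.0
    assert res.Ks == pytest.approx(me.jukes_cantor(1.0 / s_avg), abs=1e-12)
    assert res.Ka == 0.0


def test_ka_ks_is_symmetric(rng):
    codons = [c for c in me.SENSE_CODONS]
    for _ in range(10):
        x = "".join(rng.choice(codons, size=60))
        y = "".join(rng.choice(codons, size=60))
        fwd = me.ka_ks(me.CodingAlignment(x, y))
        rev = me.ka_ks(me.CodingAlignment(y, x))
        assert (fwd.S, fwd.N, fwd.Sd, fwd.Nd) == pytest.approx(
            (rev.S, rev.N, rev.Sd, rev.Nd), abs=1e-12)


def test_ambiguous_codons_are_skipped_and_counted():
    res = me.ka_ks(me.CodingAlignment("ATGNNNTTT", "ATGAAATTC"))
    assert res.codons_used == 2
    assert res.codons_skipped == 1


def test_terminal_stop_pair_is_excluded():
    res = me.ka_ks(me.CodingAlignment("ATGTTTTAA", "ATGTTCTGA"))
    assert res.codons_used == 2  # ATG + TTT/TTC only


def test_random_pairs_match_brute_force_oracle(rng):
    codons = np.array(me.SENSE_CODONS)
    for _ in range(30):
        x = rng.choice(codons, size=50)
        y = x.copy()
        mask = rng.random(50) < 0.3
        y[mask] = rng.choice(codons, size=int(mask.sum()))
        sx, sy = "".join(x), "".join(y)
        res = me.ka_ks(me.CodingAlignment(sx, sy))
        S, N, Sd, Nd = oracle_pair_counts(sx, sy)
        assert (res.S, res.N, res.Sd, res.Nd) == pytest.approx(
            (S, N, Sd, Nd), abs=1e-12)


# ---------------------------------------------------------------------------
# dating

def test_divergence_time_known_values():
    assert me.divergence_time(0.0736).T == pytest.approx(5.66e6, rel=5e-3)
    assert me.divergence_time(0.0).T == 0.0
    assert me.divergence_time(0.0057).T == pytest.approx(4.38e5, rel=5e-3)


def test_divergence_time_contracts():
    with pytest.raises(ValueError):
        me.divergence_time(0.01, r=0.0)
    with pytest.raises(ValueError):
        me.divergence_time(-0.1)


def test_generation_time_scales_linearly():
    t1 = me.divergence_time(0.01, generation_years=1.0).T
    t3 = me.divergence_time(0.01, generation_years=3.0).T
    assert t3 == pytest.approx(3 * t1)


def test_summarize_divergence_reports_both_conventions():
    out = me.summarize_divergence([0.004, 0.006, 0.008])
    assert out["mean_ks"] == pytest.approx(0.006)
    assert out["t_from_mean_ks"] == pytest.approx(0.006 / (2 * 6.5e-9))
    assert out["mean_per_gene_t"] == pytest.approx(out["t_from_mean_ks"])
    assert out["n_genes"] == 3


# ---------------------------------------------------------------------------
# exact rank-sum

def test_rank_sum_small_case():
    w, p = me.rank_sum_exact([1, 2], [3, 4])
    assert w == 3.0
    assert p == pytest.approx(1 / 3)


def test_rank_sum_identical_groups():
    _, p = me.rank_sum_exact([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == 1.0


def test_rank_sum_empty_group_is_error():
    with pytest.raises(ValueError):
        me.rank_sum_exact([], [1.0])


def test_rank_sum_matches_permutation_oracle(rng):
    for _ in range(20):
        n1 = int(rng.integers(2, 5))
        n2 = int(rng.integers(2, 5))
        # integer values force ties, exercising the mid-rank path
        a = rng.integers(0, 5, size=n1).astype(float)
        b = rng.integers(0, 5, size=n2).astype(float)
        w_ref, p_ref = oracle_rank_sum(a, b)
        w, p = me.rank_sum_exact(a, b)
        assert w == pytest.approx(w_ref)
        assert p == pytest.approx(p_ref, rel=1e-9)
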