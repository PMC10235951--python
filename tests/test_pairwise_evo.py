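"""Alignment, identity and Nei-Gojobori dN/dS, checked against brute force."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from euplofs.pairwise_evo import (
    Alignment,
    NGCounts,
    align_sw,
    dnds_purifying_support,
    dnds_uniformity,
    ng_dnds,
    ng_site_counts,
    protein_identity,
)
from euplofs.seqcore import EUPLOTID, STANDARD

BASES = "ACGT"


# ---------------------------------------------------------------------------
# independent oracles


def sw_bruteforce_score(a, b, match=1.0, mismatch=-1.0, gap=-2.0):
    """Textbook Smith-Waterman DP with linear gap cost (oracle)."""
    best = 0.0
    H = [[0.0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, H[i - 1][j] + gap, H[i][j - 1] + gap)
            best = max(best, H[i][j])
    return best


def ng_bruteforce(cds_a, cds_b, code):
    """Independent Nei-Gojobori implementation (site + difference counts)."""
    syn_sites = nonsyn_sites = syn_d = nonsyn_d = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if code.is_stop(ca) or code.is_stop(cb):
            continue
        for codon in (ca, cb):
            s = 0.0
            for pos in range(3):
                muts = [
                    codon[:pos] + x + codon[pos + 1 :]
                    for x in BASES
                    if x != codon[pos]
                ]
                muts = [m for m in muts if not code.is_stop(m)]
                if muts:
                    s += sum(
                        code.codon_to_aa[m] == code.codon_to_aa[codon] for m in muts
                    ) / len(muts)
            syn_sites += s / 2
            nonsyn_sites += (3 - s) / 2
        diff = [p for p in range(3) if ca[p] != cb[p]]
        if not diff:
            continue
        paths = []
        blocked = []
        for order in itertools.permutations(diff):
            cur, sd, nd, hit = ca, 0, 0, False
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1 :]
                if code.is_stop(nxt):
                    hit = True
                if code.codon_to_aa.get(cur) == code.codon_to_aa.get(nxt):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            (blocked if hit else paths).append((sd, nd))
        pool = paths or blocked
        syn_d += sum(p[0] for p in pool) / len(pool)
        nonsyn_d += sum(p[1] for p in pool) / len(pool)
    return syn_sites, nonsyn_sites, syn_d, nonsyn_d


def random_cds(rng, n_codons, code):
    out = []
    while len(out) < n_codons:
        c = "".join(rng.choice(list(BASES), 3))
        if not code.is_stop(c):
            out.append(c)
    return "".join(out)


# ---------------------------------------------------------------------------


class TestAlignSW:
    def test_identical_full_length(self):
        aln = align_sw("MKVLW", "MKVLW", match=1, mismatch=-1, gap_open=-2, gap_extend=-2)
        assert aln.aligned_a == "MKVLW"
        assert aln.score == 5

    def test_kkkc_vs_kkkw(self):
        aln = align_sw("KKKC", "KKKW", match=1, mismatch=-1, gap_open=-2, gap_extend=-2)
        assert aln.score == sw_bruteforce_score("KKKC", "KKKW") == 3

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            align_sw("", "MK")

    @settings(deadline=None, max_examples=40)
    @given(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=25),
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=25),
    )
    def test_score_matches_bruteforce_and_is_symmetric(self, a, b):
        kw = dict(match=1, mismatch=-1, gap_open=-2, gap_extend=-2)
        assert align_sw(a, b, **kw).score == sw_bruteforce_score(a, b)
        assert align_sw(a, b, **kw).score == align_sw(b, a, **kw).score


class TestProteinIdentity:
    def test_identical(self):
        assert protein_identity(Alignment("MKV", "MKV", 0)) == 1.0

    def test_gap_columns_removed(self):
        assert protein_identity(Alignment("AC-D", "AW-D", 0)) == pytest.approx(2 / 3)

    def test_wholly_mismatched(self):
        assert protein_identity(Alignment("AAA", "WWW", 0)) == 0.0

    def test_no_nongap_columns_raises(self):
        with pytest.raises(ValueError):
            protein_identity(Alignment("A-", "-A", 0))


class TestNGSiteCounts:
    def test_ttt_euplotid(self):
        assert ng_site_counts("TTT", EUPLOTID) == pytest.approx((1 / 3, 8 / 3))

    def test_tgt_euplotid_counts_tga_as_synonymous(self):
        assert ng_site_counts("TGT", EUPLOTID) == pytest.approx((2 / 3, 7 / 3))

    def test_tgt_standard_excludes_stop_mutant(self):
        syn_std, _ = ng_site_counts("TGT", STANDARD)
        syn_eup, _ = ng_site_counts("TGT", EUPLOTID)
        assert syn_std < syn_eup
        assert syn_eup - syn_std == pytest.approx(1 / 6)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng_site_counts("TAA", EUPLOTID)

    @pytest.mark.parametrize("code", [EUPLOTID, STANDARD], ids=["euplotid", "standard"])
    def test_sites_sum_to_three_for_every_codon(self, code):
        for codon in map("".join, itertools.product(BASES, repeat=3)):
            if code.is_stop(codon):
                continue
            s, n = ng_site_counts(codon, code)
            assert s + n == pytest.approx(3.0)


class TestNGdNdS:
    def test_identical_pair_zero_distances(self):
        cds = "ATGAAATTTGGG"
        c = ng_dnds(cds, cds, EUPLOTID)
        assert c.dN == 0.0 and c.dS == 0.0
        assert c.dnds is None  # dS = 0 -> ratio undefined

    def test_single_synonymous_third_position_difference(self):
        rng = np.random.default_rng(7)
        rest = random_cds(rng, 99, EUPLOTID)
        a = "TTT" + rest
        b = "TTC" + rest  # Phe -> Phe, one synonymous change in 100 codons
        c = ng_dnds(a, b, EUPLOTID)
        assert c.nonsyn_diffs == 0
        assert c.syn_diffs == 1
        assert c.dN == 0.0 and c.dS > 0
        assert c.dnds == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = random_cds(rng, 30, EUPLOTID)
        b = random_cds(rng, 30, EUPLOTID)
        ca, cb = ng_dnds(a, b, EUPLOTID), ng_dnds(b, a, EUPLOTID)
        assert ca.syn_sites == pytest.approx(cb.syn_sites)
        assert ca.syn_diffs == pytest.approx(cb.syn_diffs)
        assert ca.nonsyn_diffs == pytest.approx(cb.nonsyn_diffs)

    def test_jukes_cantor_saturation_reported_undefined(self):
        # wholly dissimilar codons can push p >= 3/4; the correction must
        # then be reported as undefined rather than a complex number
        c = NGCounts(1.0, 2.0, 0.9, 0.2, 1)
        assert c.dS is None

    @pytest.mark.parametrize("code", [EUPLOTID, STANDARD], ids=["euplotid", "standard"])
    def test_matches_bruteforce_on_random_pairs(self, code):
        rng = np.random.default_rng(11)
        for _ in range(25):
            a = random_cds(rng, 30, code)
            b = random_cds(rng, 30, code)
            c = ng_dnds(a, b, code)
            s, n, sd, nd = ng_bruteforce(a, b, code)
            assert c.syn_sites == pytest.approx(s)
            assert c.nonsyn_sites == pytest.approx(n)
            assert c.syn_diffs == pytest.approx(sd)
            assert c.nonsyn_diffs == pytest.approx(nd)


class TestResampling:
    def test_uniformity_null_is_half(self):
        counts = NGCounts(100.0, 200.0, 20.0, 10.0, 100)
        rng = np.random.default_rng(0)
        m = dnds_uniformity(counts, counts, rounds=10_000, rng=rng)
        # identical means: metric ~ 0.5 within Monte-Carlo error
        assert abs(m - 0.5) < 3 * 0.005

    def test_elevated_adjacent_dn_pushes_metric_to_one(self):
        primary = NGCounts(100.0, 200.0, 20.0, 10.0, 100)
        adjacent = NGCounts(100.0, 200.0, 20.0, 100.0, 100)
        rng = np.random.default_rng(1)
        assert dnds_uniformity(primary, adjacent, rounds=10_000, rng=rng) > 0.99

    def test_deterministic_given_seed(self):
        primary = NGCounts(50.0, 100.0, 8.0, 4.0, 50)
        adjacent = NGCounts(30.0, 60.0, 5.0, 3.0, 30)
        m1 = dnds_uniformity(primary, adjacent, 5000, np.random.default_rng(42))
        m2 = dnds_uniformity(primary, adjacent, 5000, np.random.default_rng(42))
        assert m1 == m2

    def test_degenerate_counts_are_uninformative(self):
        zero_dn = NGCounts(50.0, 100.0, 8.0, 0.0, 50)
        healthy = NGCounts(50.0, 100.0, 8.0, 4.0, 50)
        assert dnds_uniformity(zero_dn, healthy, 1000, np.random.default_rng(0)) == 0.5

    def test_purifying_support_limits(self):
        rng = np.random.default_rng(5)
        assert dnds_purifying_support(NGCounts(50, 100, 5, 0, 50), 1000, rng) == 1.0
        assert dnds_purifying_support(NGCounts(50, 100, 0, 5, 50), 1000, rng) == 0.0
        strong = dnds_purifying_support(NGCounts(50, 100, 30, 2, 50), 2000, rng)
        assert strong > 0.99
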