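"""Molecular assays: digestion, snap-back, end-labeling, PCR, CN, reads."""

import collections

import numpy as np
import pytest
from Bio.Restriction import BglII, EcoRV, HindIII
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

import odirasim as od
from odirasim.assays import Duplex, junction_split_reads, snapback_assay
from odirasim.seqs import revcomp

from oracles import brute_coverage, brute_foldback


class TestDigest:
    def test_circular_single_site_linearizes(self):
        g = od.random_genome(4_600, 0.5, seed=2).bases
        g = g.replace("CTCGAG", "CTCGAA")  # scrub, then plant exactly one
        mol = Duplex("c", g[:1000] + "CTCGAG" + g[1000:], circular=True)
        frags = od.restriction_digest(mol, ["XhoI"])
        assert len(frags) == 1
        assert len(frags[0]) == len(mol.seq)

    def test_linear_k_sites_k_plus_one_fragments(self):
        s = "A" * 500 + "AGATCT" + "C" * 300 + "AGATCT" + "G" * 200
        frags = od.restriction_digest(Duplex("l", s), ["BglII"])
        assert len(frags) == 3
        assert "".join(f.seq for f in frags) == s

    def test_multiset_matches_biopython_oracle(self):
        g = od.random_genome(30_000, 0.42, seed=8)
        frags = od.restriction_digest(g, ["BglII", "EcoRV", "HindIII"])
        assert "".join(f.seq for f in frags) == g.bases
        cuts = sorted(
            c
            for enz in (BglII, EcoRV, HindIII)
            for c in enz.search(Seq(g.bases))
        )
        # Bio.Restriction reports 1-based first-base-after-cut positions
        oracle_sizes = sorted(
            b - a for a, b in zip([1] + cuts, cuts + [len(g) + 1])
        )
        assert sorted(len(f) for f in frags) == oracle_sizes

    def test_dog_bone_end_fragments_carry_loops(self, dogbone, fixture):
        frags = od.restriction_digest(dogbone, [fixture.snapback_site["enzyme"]])
        assert len(frags) == 2
        left, right_f = frags
        assert left.loop_left == dogbone.loop_left and left.loop_right == ""
        assert right_f.loop_right == dogbone.loop_right
        # hairpin caps add nucleotides -> slight gel up-shift vs bare duplex
        assert left.total_nt == 2 * len(left) + len(dogbone.loop_left)
        assert sum(len(f) for f in frags) == len(dogbone.unit)

    def test_uncut_dog_bone_is_covalently_closed(self, dogbone):
        frags = od.restriction_digest(dogbone, ["XhoI"])  # no site in unit
        assert len(frags) == 1 and frags[0].circular
        assert frags[0].loop_left and frags[0].loop_right

    def test_iupac_degenerate_site_both_strands(self):
        s = "ACGTA" + "CCTAATTGAGG" + "TTTTT"  # EcoNI CCTNNNNNAGG
        frags = od.restriction_digest(Duplex("d", s), ["EcoNI"])
        assert len(frags) == 2
        assert len(frags[0]) == 10  # cut at 5 into the 11 bp site

    def test_unknown_enzyme_lookup_error(self):
        with pytest.raises(LookupError, match="unknown enzyme"):
            od.restriction_digest(Duplex("d", "ACGT" * 100), ["NoSuchI"])

    def test_circular_reconstitution_is_rotation(self, plasmid):
        frags = od.restriction_digest(plasmid, ["EcoRV"])
        joined = "".join(f.seq for f in frags)
        doubled = plasmid.circle + plasmid.circle
        assert len(joined) == plasmid.circumference
        assert joined in doubled


class TestSnapback:
    def test_perfect_palindrome_halves(self):
        x = od.random_genome(1_350, 0.5, seed=3).bases
        res = snapback_assay(x + revcomp(x))
        assert res.is_foldback
        assert res.duplex_len_after_snapback == 1_350
        assert res.loop_len == 0
        assert res.s1_resistant_len == 1_350

    @pytest.mark.parametrize("loop_len", [2, 4, 17, 100])
    def test_central_loop_subtracted(self, loop_len):
        x = od.random_genome(600, 0.5, seed=loop_len).bases
        loop = "T" * loop_len if loop_len != 4 else "ACCA"
        res = snapback_assay(x + loop + revcomp(x))
        L = 1_200 + loop_len
        assert res.fragment_len == L
        assert res.duplex_len_after_snapback == (L - res.loop_len) // 2
        assert res.loop_len == loop_len
        assert res.s1_resistant_len == 600

    def test_non_palindromic_fragment_degraded(self):
        frag = od.random_genome(1_260, 0.5, seed=4).bases
        res = snapback_assay(frag)
        assert not res.is_foldback
        assert res.s1_resistant_len == 0

    def test_terminal_overhangs_trimmed(self):
        x = od.random_genome(400, 0.5, seed=5).bases
        tail = od.random_genome(150, 0.5, seed=6).bases
        res = snapback_assay(tail + x + "TTTT" + revcomp(x))
        assert res.is_foldback
        assert res.duplex_len_after_snapback == 400
        assert res.loop_len == 4
        assert res.left_overhang_len == 150 and res.right_overhang_len == 0

    def test_planted_large_deletion_loop_vs_oracle(self):
        arm = od.random_genome(800, 0.5, seed=7).bases
        loop = od.random_genome(4_000, 0.5, seed=8).bases
        frag = arm + loop + revcomp(arm)
        res = snapback_assay(frag)
        assert res.s1_resistant_len == (len(frag) - 4_000) // 2 == 800
        k, a, j = brute_foldback(frag[:2_000])  # oracle on a trimmed window
        impl = snapback_assay(frag[:2_000], min_duplex=1)
        assert impl.duplex_len_after_snapback == k

    @given(st.integers(10, 300), st.integers(0, 30), st.integers(0, 40),
           st.integers(0, 1_000))
    @settings(max_examples=40, deadline=None)
    def test_halving_invariant_on_constructed_palindromes(self, half, loop,
                                                          tail, seed):
        x = od.random_genome(half + 20, 0.5, seed=seed).bases[:half]
        lp = "TTTT" + od.random_genome(loop + 4, 0.5, seed=seed + 1).bases[:loop]
        frag = od.random_genome(tail + 4, 0.5, seed=seed + 2).bases[:tail] \
            + x + lp + revcomp(x)
        res = snapback_assay(frag, min_duplex=1)
        assert res.duplex_len_after_snapback >= half
        assert res.s1_resistant_len == res.duplex_len_after_snapback


class TestEndLabel:
    def test_ancestor_one_band_per_enzyme(self, fixture):
        anc = fixture.chrom
        probe = anc.bases[11_810 : 11_850]  # adjacent to the planted site
        bands = od.indirect_end_label(anc, "EcoRV", ["BglII", "HindIII"], probe)
        assert all(len(v) == 1 for v in bands.values())

    def test_rearranged_product_gains_second_band(self, fixture, triplication):
        pair = od.find_direct_repeat_pairs(triplication, 12)[0]
        after = od.apply_arm_deletion(triplication, pair)
        probe = fixture.chrom.bases[11_810 : 11_850]
        anc_bands = od.indirect_end_label(fixture.chrom, "EcoRV", ["HindIII"], probe)
        amp_bands = od.indirect_end_label(after, "EcoRV", ["HindIII"], probe)
        assert len(amp_bands["HindIII"]) > len(anc_bands["HindIII"])

    def test_sizes_equal_digest_and_filter_oracle(self, fixture):
        anc = fixture.chrom
        probe = anc.bases[11_810 : 11_850]
        bands = od.indirect_end_label(anc, "EcoRV", ["BglII"], probe)
        frags = od.restriction_digest(anc, ["EcoRV", "BglII"])
        oracle = sorted(
            {len(f) for f in frags if probe in f.seq or revcomp(probe) in f.seq},
            reverse=True,
        )
        assert bands["BglII"] == oracle

    def test_probe_absent_raises(self, fixture):
        with pytest.raises(LookupError, match="probe"):
            od.indirect_end_label(fixture.chrom, "EcoRV", ["BglII"], "T" * 40)


class TestPCR:
    def test_primer_pair_absent_gives_empty(self):
        g = od.random_genome(2_000, 0.5, seed=9)
        assert od.simulate_pcr([g], "A" * 20, "C" * 20) == []

    def test_product_between_convergent_primers(self):
        g = od.random_genome(2_000, 0.5, seed=10).bases
        pf = g[100:120]
        pr = revcomp(g[800:820])
        products = od.simulate_pcr([od.Sequence("t", g)], pf, pr)
        assert [len(p) for p in products] == [720]
        assert products[0].seq == g[100:820]

    def test_primers_swapped_same_duplex_product(self):
        g = od.random_genome(2_000, 0.5, seed=10).bases
        pf = g[100:120]
        pr = revcomp(g[800:820])
        a = od.simulate_pcr([od.Sequence("t", g)], pf, pr)
        b = od.simulate_pcr([od.Sequence("t", g)], pr, pf)
        assert {revcomp(p.seq) for p in b} == {p.seq for p in a}

    def test_max_product_enforced(self):
        g = od.random_genome(9_000, 0.5, seed=11).bases
        pf, pr = g[0:20], revcomp(g[8_000:8_020])
        assert od.simulate_pcr([od.Sequence("t", g)], pf, pr, max_product=5_000) == []

    def test_circular_template_wraps(self, plasmid):
        circle = plasmid.circle
        pf = circle[-50:-30]
        pr = revcomp((circle + circle)[len(circle) - 10 : len(circle) + 10])
        products = od.simulate_pcr([plasmid], pf, pr)
        assert products and all(len(p) <= 60 for p in products)

    def test_divergent_primers_no_product(self):
        g = od.random_genome(2_000, 0.5, seed=12).bases
        pf = g[800:820]
        pr = revcomp(g[100:120])  # points away from pf
        assert od.simulate_pcr([od.Sequence("t", g)], pf, pr, max_product=1_000) == []

    def test_short_primer_rejected(self):
        with pytest.raises(od.ParameterError, match="15"):
            od.simulate_pcr([od.Sequence("t", "ACGT" * 100)], "ACGTACGTACGT", "ACGT" * 5)

    def test_junction_pcr_distinguishes_integrant(self, fixture, triplication):
        # primers flanking the tail-to-tail junction: product only from the
        # integrated structure, never from the ancestor
        prod = triplication.rendered
        rec = triplication.junction_records[0]
        pf = prod[rec.position - 200 : rec.position - 180]
        pr = revcomp(prod[rec.position + 180 : rec.position + 200])
        got = od.simulate_pcr([od.Sequence("amp", prod)], pf, pr, max_product=1_000)
        # the quasi-palindromic junction also templates the mirror-image
        # product; the canonical one has the predicted size
        assert 400 in {len(p) for p in got}  # pos-200 .. pos+200, loop inside
        assert od.simulate_pcr([fixture.chrom], pf, pr, max_product=10_000) == []


class TestCNProfile:
    def test_ancestor_vs_itself_all_one(self, fixture):
        d = od.DerivedChromosome(
            fixture.chrom, [od.SegmentPiece(0, len(fixture.chrom), "+")]
        )
        prof = od.cn_profile(d, 500)
        assert np.all(prof.values == 1.0)

    def test_triplication_plateaus(self, fixture, triplication):
        prof = od.cn_profile(triplication, 50)  # unit bounds are multiples of 50
        assert prof.plateaus() == [1.0, 3.0, 1.0]

    def test_five_copy_plateau_for_two_insertions(self, fixture, plasmid):
        d = od.integrate_plasmid(fixture.chrom, plasmid, n_copies=2)
        prof = od.cn_profile(d, 50)
        assert prof.plateaus() == [1.0, 5.0, 1.0]

    def test_window_average_matches_per_base_oracle(self, triplication):
        prof = od.cn_profile(triplication, 333)
        cov = brute_coverage(triplication)
        for i, v in enumerate(prof.values):
            chunk = cov[i * 333 : (i + 1) * 333]
            assert v == pytest.approx(sum(chunk) / len(chunk))

    def test_oversized_window_rejected(self, triplication):
        with pytest.raises(od.ParameterError, match="window"):
            od.cn_profile(triplication, len(triplication.ancestor) + 1)


class TestSplitReads:
    def test_labels_and_mappability(self, fixture, triplication):
        reads = junction_split_reads(triplication, read_len=100, step=23)
        counts = collections.Counter(r.label for r in reads)
        assert counts["split"] >= 2 and counts["flank"] > 100
        anc = fixture.chrom.bases
        rc_anc = revcomp(anc)
        for r in reads:
            if r.label == "split":
                assert r.seq not in anc and r.seq not in rc_anc
            elif r.label == "flank":
                assert r.seq in anc or r.seq in rc_anc

    def test_split_coordinates_match_junction_records(self, triplication):
        reads = junction_split_reads(triplication, read_len=100, step=7)
        recorded = {r.position for r in triplication.junction_records}
        seen = {r.junction["position"] for r in reads if r.label == "split"}
        assert seen == recorded

    def test_read_length_must_anchor_junctions(self, triplication):
        widest = max(
            hi - lo for (lo, hi) in
            (r.novel_span for r in triplication.junction_records)
        )
        with pytest.raises(od.ParameterError, match="read_len"):
            junction_split_reads(triplication, read_len=widest, step=10)
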