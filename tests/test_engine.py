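"""Amplification engine: dog bone, dimer, integration, deletions, driver."""

import numpy as np
import pytest

import odirasim as od
from odirasim.seqs import revcomp

from oracles import brute_common_substrings, brute_coverage


def coverage_runs(d):
    cov = brute_coverage(d)
    runs = [cov[0]]
    for v in cov:
        if v != runs[-1]:
            runs.append(v)
    return runs


class TestExtrusion:
    def test_circuit_length_arithmetic(self, fixture, dogbone):
        sL = fixture.spec.loop_left_len
        sR = fixture.spec.loop_right_len
        assert len(dogbone.unit) == fixture.spec.unit_len
        assert dogbone.circuit_length == 2 * fixture.spec.unit_len + sL + sR

    def test_unit_bounded_by_ancestral_arms(self, fixture, dogbone):
        anc = fixture.chrom.bases
        left, right = fixture.iirs
        arm = left.arm_len
        assert dogbone.unit[:arm] == anc[left.right_arm_start : left.right_arm_start + arm]
        assert dogbone.unit[-arm:] == anc[right.left_arm_start : right.left_arm_start + arm]
        assert dogbone.unit == anc[left.right_arm_start : right.left_arm_end]

    def test_inactive_origin_refused(self, fixture):
        inactive = [
            od.Origin(o.seq_id, o.start, o.end, o.name, active=False)
            for o in fixture.origins
        ]
        with pytest.raises(od.LicensingError, match="origin"):
            od.extrude_dog_bone(fixture.chrom, *fixture.iirs, inactive)

    def test_no_origin_between_repeats_refused(self, fixture):
        outside = [od.Origin("fixture", 10, 60, "far", True)]
        with pytest.raises(od.LicensingError):
            od.extrude_dog_bone(fixture.chrom, *fixture.iirs, outside)


class TestReplication:
    def test_circumference_equals_circuit(self, dogbone, plasmid):
        assert plasmid.circumference == dogbone.circuit_length
        # 2.3 kb unit with short loops -> ~4.6 kb circle
        assert f"{plasmid.circumference / 1000:.1f}" == "4.6"

    def test_junction_centers_are_palindromic(self, plasmid):
        circle = plasmid.circle
        n = len(circle)
        for j in plasmid.junctions:
            a, b = j["loop_start"], j["loop_end"]
            for k in range(1, 200):
                left = circle[(a - k) % n]
                right = circle[(b + k - 1) % n]
                assert left == {"A": "T", "T": "A", "C": "G", "G": "C"}[right]

    def test_loop_removal_leaves_rotated_unit_palindrome(self, plasmid):
        circle = plasmid.circle
        u = len(plasmid.unit)
        stripped = circle[:u] + circle[u + len(plasmid.loop_right) : u + len(plasmid.loop_right) + u]
        target = plasmid.unit + revcomp(plasmid.unit)
        assert stripped == target  # a rotation with offset 0 by construction


class TestIntegration:
    def test_length_arithmetic_single_copy(self, fixture, dogbone, triplication):
        expected = (
            len(fixture.chrom) + 2 * len(dogbone.unit)
            + len(dogbone.loop_left) + len(dogbone.loop_right)
        )
        assert len(triplication) == expected
        assert len(triplication.rendered) == expected

    @pytest.mark.parametrize("n_copies,peak", [(1, 3), (2, 5), (3, 7)])
    def test_odd_copy_numbers(self, fixture, plasmid, n_copies, peak):
        d = od.integrate_plasmid(fixture.chrom, plasmid, n_copies=n_copies)
        us, ue = fixture.unit_interval
        cov = d.coverage()
        assert cov[us:ue].max() == cov[us:ue].min() == peak
        assert cov[:us - 20].max() == 1 and cov[ue + 20 :].max() == 1

    def test_crossover_position_does_not_change_product(self, fixture, plasmid):
        us, ue = fixture.unit_interval
        a = od.integrate_plasmid(fixture.chrom, plasmid, crossover=us + 1)
        b = od.integrate_plasmid(fixture.chrom, plasmid, crossover=ue - 1)
        assert a.rendered == b.rendered

    def test_distal_sequences_intact(self, fixture, triplication):
        anc = fixture.chrom.bases
        us, ue = fixture.unit_interval
        prod = triplication.rendered
        assert prod[: ue] == anc[: ue]           # prefix + first copy
        assert prod.endswith(anc[us:])           # last copy + suffix

    def test_junction_kmers_novel_flank_kmers_ancestral(self, fixture, triplication):
        anc = fixture.chrom.bases
        rc_anc = revcomp(anc)
        prod = triplication.rendered
        k = 60
        for rec in triplication.junction_records:
            # a window reaching 30 bp beyond the preserved arm-spacer-arm
            # triplet on both sides cannot match the ancestor (the fixture
            # carries no duplicate 15-mers outside planted features)
            w = prod[rec.position - 30 : rec.position + len(rec.loop) + 30]
            assert w not in anc and w not in rc_anc
            lo, hi = rec.novel_span
            assert prod[lo:hi] not in anc and prod[lo:hi] not in rc_anc
        for x in (0, 1_000, len(prod) - k):  # flanks map contiguously
            w = prod[x : x + k]
            assert w in anc or w in rc_anc

    def test_junction_fidelity_arm_spacer_arm(self, fixture, triplication):
        anc = fixture.chrom.bases
        prod = triplication.rendered
        for iir in fixture.iirs:
            triplet = anc[iir.start : iir.end]
            assert triplet in prod
        # and specifically across each junction
        for rec in triplication.junction_records:
            arm = fixture.spec.arm_len
            window = prod[rec.position - arm : rec.position + len(rec.loop) + arm]
            assert window in anc

    def test_no_homology_refused(self, fixture, plasmid):
        host = od.random_genome(5_000, 0.4, seed=123, seq_id="host")
        with pytest.raises(od.HomologyError, match="homology"):
            od.integrate_plasmid(host, plasmid)

    def test_rendering_roundtrip_through_json(self, fixture, triplication):
        d2 = od.DerivedChromosome.from_dict(triplication.to_dict(), fixture.chrom)
        assert d2.rendered == triplication.rendered
        assert [r.position for r in d2.junction_records] == [
            r.position for r in triplication.junction_records
        ]


class TestSingleFork:
    def _iir(self, fixture):
        return fixture.iirs[1]

    def test_isochromosome_length_and_palindrome(self, fixture):
        iir = self._iir(fixture)
        iso = od.single_fork_outcome(
            fixture.chrom, iir, "telomere-proximal",
            cen=(100, 200), tel=(len(fixture.chrom) - 100, len(fixture.chrom)),
        )
        x = iir.left_arm_end
        loop = iir.spacer_len
        assert len(iso) == 2 * x + loop
        prod = iso.rendered
        assert prod[:x] == revcomp(prod[x + loop :])
        assert not iso.is_acentric

    def test_isochromosome_copy_number_two_then_zero(self, fixture):
        iir = self._iir(fixture)
        iso = od.single_fork_outcome(
            fixture.chrom, iir, "telomere-proximal",
            cen=(100, 200), tel=(len(fixture.chrom) - 100, len(fixture.chrom)),
        )
        cov = iso.coverage()
        x = iir.left_arm_end
        assert cov[: x].min() == cov[: x].max() == 2
        assert cov[x + 10 :].max() == 0
        assert iso.centromere_copies((100, 200)) == 2

    def test_centromere_proximal_fork_yields_acentric_fragment(self, fixture):
        iir = self._iir(fixture)
        frag = od.single_fork_outcome(
            fixture.chrom, iir, "centromere-proximal",
            cen=(100, 200), tel=(len(fixture.chrom) - 100, len(fixture.chrom)),
        )
        assert frag.is_acentric
        assert frag.centromere_copies((100, 200)) == 0
        y = iir.right_arm_start
        prod = frag.rendered
        n = len(fixture.chrom) - y
        assert prod[:n] == revcomp(prod[n + iir.spacer_len :])


class TestArmDeletion:
    def test_planted_pair_found_and_verified_by_oracle(self, fixture, triplication):
        pairs = od.find_direct_repeat_pairs(triplication, 12)
        planted = fixture.repeat_pair
        assert any(
            p.left_start - 0 == planted["pos1"] and p.length >= planted["len"]
            for p in pairs
        )
        prod = triplication.rendered
        for p in pairs:
            assert prod[p.left_start : p.left_start + p.length] == \
                prod[p.right_start : p.right_start + p.length]
        # brute-force cross-matching around the first junction agrees
        rec = [r for r in triplication.junction_records if r.kind == "inverted"][0]
        us, ue = fixture.unit_interval
        arm_l = prod[us : rec.position]
        arm_r = prod[rec.position + len(rec.loop) : rec.position + len(rec.loop) + (rec.position - us)]
        oracle = brute_common_substrings(arm_l, arm_r, 12)
        got = {(p.left_start - us, p.right_start - (rec.position + len(rec.loop)), p.length)
               for p in pairs if p.junction_position == rec.position}
        assert got == set(oracle)

    def test_no_repeats_no_pairs(self):
        spec = od.FixtureSpec(seed=21, repeat_word_offsets=(400, 1_800))
        fx = od.make_sul1_like_fixture(spec)
        db = od.extrude_dog_bone(fx.chrom, *fx.iirs, fx.origins)
        d = od.integrate_plasmid(fx.chrom, od.replicate_dog_bone(db))
        pairs = od.find_direct_repeat_pairs(d, 15)  # longer than any planted word
        assert pairs == []

    def test_length_bookkeeping(self, triplication):
        pair = od.find_direct_repeat_pairs(triplication, 12)[0]
        after = od.apply_arm_deletion(triplication, pair)
        assert len(after) == len(triplication) - pair.separation

    def test_copy_number_staircase(self, fixture, triplication):
        pair = od.find_direct_repeat_pairs(triplication, 12)[0]
        after = od.apply_arm_deletion(triplication, pair)
        assert coverage_runs(after) == [1, 3, 2, 1]

    def test_wrong_pair_refused(self, triplication):
        bogus = od.RepeatPair(100, 5_000, 12, 0)
        with pytest.raises(od.PreconditionError):
            od.apply_arm_deletion(triplication, bogus)

    def test_retained_junction_snaps_back_with_large_loop(self, triplication):
        from oracles import brute_foldback

        pair = od.find_direct_repeat_pairs(triplication, 12)[0]
        after = od.apply_arm_deletion(triplication, pair)
        prod = after.rendered
        # a fragment spanning the retained junction folds back, but the
        # deleted arm leaves a large single-stranded (S1-sensitive) loop
        frag = prod[pair.left_start - 400 : pair.left_start + 2000]
        res = od.snapback_assay(frag, min_duplex=30)
        k, a, j = brute_foldback(frag)
        assert res.is_foldback
        assert res.duplex_len_after_snapback == k
        assert res.loop_len == j - a - k
        assert res.s1_resistant_len == res.duplex_len_after_snapback
        assert res.loop_len > res.fragment_len // 10  # large S1-sensitive loop


class TestSimulate:
    def test_same_seed_byte_identical(self, fixture):
        p = od.SimParams(max_span=4_000)
        a = od.simulate_odira(fixture.chrom, fixture.origins, p, seed=5)
        b = od.simulate_odira(fixture.chrom, fixture.origins, p, seed=5)
        assert a.product.rendered == b.product.rendered
        assert a.events == b.events

    def test_seed_sweep_products_pass_invariants(self, fixture):
        anc = fixture.chrom.bases
        for seed in range(4):
            out = od.simulate_odira(
                fixture.chrom, fixture.origins,
                od.SimParams(max_span=4_000, secondary_deletion="off"), seed=seed,
            )
            d = out.product
            assert d is not None
            assert brute_coverage(d) == list(d.coverage())
            for rec in d.junction_records:
                span = d.rendered[rec.position - 7 : rec.position + len(rec.loop) + 7]
                assert span in anc  # arm-spacer-arm fidelity
            us = min(p.start for p in d.pieces if hasattr(p, "strand"))
            assert d.rendered.startswith(anc[:us])

    def test_all_origins_inactive_no_products(self, fixture):
        inactive = [
            od.Origin(o.seq_id, o.start, o.end, o.name, active=False)
            for o in fixture.origins
        ]
        for seed in range(5):
            out = od.simulate_odira(fixture.chrom, inactive, seed=seed)
            assert out.no_substrate and out.product is None
            assert any(e["event"] == "no_odira_substrate" for e in out.events)

    def test_no_substrate_outcome_on_empty_scan(self):
        g = od.Sequence("bare", "A" * 2_000)
        out = od.simulate_odira(g, [od.Origin("bare", 900, 1_000, "o", True)], seed=0)
        assert out.no_substrate
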