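"""Pileup, permissive calling, the filtration cascade and heteroplasmy classes."""

import numpy as np
import pytest

from cfmito.reference import MtReference, find_homopolymers
from cfmito.simulate import AlignedFragment
from cfmito.variants import (
    DEL,
    HOMOPOLYMER,
    INS,
    LOW_ALT_SUPPORT,
    LOW_DEPTH,
    SNV,
    MtVariant,
    PileupSite,
    VariantKey,
    build_pileup,
    call_variants,
    classify_heteroplasmy,
    filter_alt_support,
    filter_depth,
    filter_homopolymer,
    hgvs_name,
    parse_hgvs,
    run_cascade,
)


def frag(start, length, alleles=(), sid="s"):
    return AlignedFragment(sid, start, length, tuple(alleles), "maternal_cf")


def mkvar(pos=100, ref="G", alt="A", vtype=SNV, depth=10, alt_reads=6, ref_reads=4):
    return MtVariant(VariantKey(pos, ref, alt, vtype), depth, alt_reads, ref_reads)


class TestHgvsNaming:
    @pytest.mark.parametrize(
        "key,name",
        [
            (VariantKey(15_326, "A", "G", SNV), "m.15326A>G"),
            (VariantKey(9_906, "G", "", DEL), "m.9906delG"),
            (VariantKey(9_808, "", "T", INS), "m.9808insT"),
        ],
    )
    def test_naming_and_roundtrip(self, key, name):
        assert hgvs_name(key) == name
        assert parse_hgvs(name) == key


class TestBuildPileup:
    def test_empty(self, ref):
        sites, depth = build_pileup([], ref)
        assert sites == [] and depth.sum() == 0

    def test_two_identical_alt_fragments(self, ref):
        a = VariantKey(100, ref.base(100), "A" if ref.base(100) != "A" else "C", SNV)
        sites, _ = build_pileup([frag(50, 170, [a]), frag(50, 170, [a])], ref)
        assert len(sites) == 1
        assert sites[0].pos == 100 and sites[0].alt_counts == {a: 2}
        assert sites[0].depth == 2

    def test_depth_equals_interval_stabbing_oracle(self, ref):
        rng = np.random.default_rng(3)
        frags = [
            frag(int(rng.integers(1, ref.length + 1)), int(rng.integers(60, 400)))
            for _ in range(300)
        ]
        _, depth = build_pileup(frags, ref)
        # brute-force: count fragments overlapping each probed position
        for pos in rng.integers(1, ref.length + 1, size=50):
            n = 0
            for f in frags:
                offset = (pos - f.start) % ref.length
                n += offset < f.length
            assert depth[pos - 1] == n


class TestCallVariants:
    def test_reference_only_site(self):
        sites = [PileupSite(pos=10, ref_base="G", depth=10, alt_counts={})]
        assert call_variants(sites) == []

    def test_simple_snv(self):
        a = VariantKey(10, "G", "A", SNV)
        sites = [PileupSite(pos=10, ref_base="G", depth=10, alt_counts={a: 6})]
        (v,) = call_variants(sites)
        assert (v.depth, v.alt_reads, v.ref_reads) == (10, 6, 4)

    def test_min_alt_call_threshold(self):
        a = VariantKey(10, "G", "A", SNV)
        sites = [PileupSite(pos=10, ref_base="G", depth=10, alt_counts={a: 1})]
        assert call_variants(sites, min_alt_call=2) == []


class TestFilters:
    @pytest.mark.parametrize("depth,flagged", [(4, True), (5, False)])
    def test_depth_boundary(self, depth, flagged):
        (v,) = filter_depth([mkvar(depth=depth)], min_depth=5)
        assert (LOW_DEPTH in v.filter_flags) is flagged

    def test_depth_empty_input(self):
        assert filter_depth([]) == []

    @pytest.mark.parametrize("alt,flagged", [(3, True), (4, False), (100, False)])
    def test_alt_support_boundary(self, alt, flagged):
        (v,) = filter_alt_support([mkvar(alt_reads=alt)], min_alt=4)
        assert (LOW_ALT_SUPPORT in v.filter_flags) is flagged

    def test_homopolymer_modes(self):
        # toy reference: TTTT at 4-7, CCC at 12-14
        ref = MtReference("t", "ACGTTTTACGACCCAGACGA", circular=False)
        track4 = find_homopolymers(ref, 4)
        track3 = find_homopolymers(ref, 3)
        snv_in_4run = mkvar(pos=5, ref="T", alt="A")
        indel_next_to_3run = mkvar(pos=11, ref="A", alt="", vtype=DEL)
        snv_in_3run = mkvar(pos=13, ref="C", alt="T")
        # cascade mode: >=4 for both classes
        out = filter_homopolymer(
            [snv_in_4run, indel_next_to_3run, snv_in_3run], track4, track4, length=20
        )
        assert HOMOPOLYMER in out[0].filter_flags
        assert HOMOPOLYMER not in out[1].filter_flags
        assert HOMOPOLYMER not in out[2].filter_flags
        # indel-strict mode: indels against the >=3 track
        out = filter_homopolymer(
            [snv_in_4run, indel_next_to_3run, snv_in_3run], track4, track3, length=20
        )
        assert HOMOPOLYMER in out[1].filter_flags
        assert HOMOPOLYMER not in out[2].filter_flags  # SNV still uses >=4


class TestHeteroplasmy:
    def test_pure_alt_is_homoplasmic(self):
        v = classify_heteroplasmy(mkvar(depth=20, alt_reads=20, ref_reads=0))
        assert v.heteroplasmy_class == "homoplasmic"
        assert v.heteroplasmy_fraction == pytest.approx(1.0)

    def test_approximate_rule_low_ref(self):
        strict = classify_heteroplasmy(mkvar(depth=33, alt_reads=30, ref_reads=3))
        assert strict.heteroplasmy_class == "heteroplasmic"
        approx = classify_heteroplasmy(
            mkvar(depth=33, alt_reads=30, ref_reads=3), approximate=True
        )
        assert approx.heteroplasmy_class == "homoplasmic"

    def test_balanced_site(self):
        v = classify_heteroplasmy(mkvar(depth=20, alt_reads=10, ref_reads=10))
        assert v.heteroplasmy_class == "heteroplasmic"
        assert v.heteroplasmy_fraction == pytest.approx(0.5)

    def test_zero_alt_is_error(self):
        with pytest.raises(ValueError):
            classify_heteroplasmy(mkvar(alt_reads=0))


class TestCascade:
    def test_clean_input_passes_untouched(self, snv_track, ref):
        from cfmito.reference import position_in_run

        clear = [
            p for p in range(1000, 1100)
            if not position_in_run(snv_track, p, DEL, length=ref.length)
        ][:5]
        variants = [
            mkvar(pos=p, depth=20, alt_reads=10, ref_reads=10) for p in clear
        ]
        kept, report = run_cascade(variants, snv_track, ref_length=ref.length)
        frame = report.to_frame()
        assert len(kept) == len(clear)
        assert (frame["total"] == len(clear)).all()
        assert (frame["total"] == frame["indels"] + frame["snvs"]).all()

    def test_stage_counts_non_increasing_and_additive(self, snv_track, ref):
        rng = np.random.default_rng(8)
        variants = [
            mkvar(
                pos=int(rng.integers(1, ref.length)),
                depth=int(rng.integers(1, 30)),
                alt_reads=int(rng.integers(1, 15)),
                ref_reads=int(rng.integers(0, 15)),
                vtype=SNV if rng.random() < 0.5 else DEL,
            )
            for _ in range(200)
        ]
        _, report = run_cascade(variants, snv_track, ref_length=ref.length)
        frame = report.to_frame()
        assert (frame["total"].diff().dropna() <= 0).all()
        assert (frame["total"] == frame["indels"] + frame["snvs"]).all()

    def test_final_set_is_order_invariant(self, snv_track, ref):
        rng = np.random.default_rng(9)

        def variants():
            return [
                mkvar(
                    pos=int(rng2.integers(1, ref.length)),
                    depth=int(rng2.integers(1, 30)),
                    alt_reads=int(rng2.integers(1, 15)),
                    ref_reads=int(rng2.integers(0, 15)),
                )
                for _ in range(100)
            ]

        rng2 = np.random.default_rng(10)
        a = variants()
        rng2 = np.random.default_rng(10)
        b = variants()
        kept_a, _ = run_cascade(a, snv_track, ref_length=ref.length)
        # apply the same predicates in a different order
        b = filter_alt_support(b, 4)
        b = filter_homopolymer(b, snv_track, length=ref.length)
        b = filter_depth(b, 5)
        kept_b = [v for v in b if v.passed]
        assert {v.key for v in kept_a} == {v.key for v in kept_b}
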