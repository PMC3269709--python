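"""Primer-set construction, backbone validation and cross-reactivity."""

import numpy as np
import pytest

from mirloop import (
    BACKBONES, GROUP1, GROUP2, REFERENCE_MATURES,
    DesignConfig, DesignError, NucSeq, StemLoopBackbone,
    design_assay, design_forward_primer, design_rt_primer,
    derive_reverse_primer, hexamer_cross_reactivity, melting_temp,
    reference_assay, validate_backbone,
)
from .conftest import random_rna


class TestBackbone:
    def test_terminal_complement_presets(self):
        # direct string check on the two published backbones
        assert validate_backbone(GROUP1).k_terminal_complement == 14
        assert validate_backbone(GROUP2).k_terminal_complement == 8
        assert validate_backbone(GROUP1).is_valid
        assert validate_backbone(GROUP2).is_valid

    def test_homopolymer_fails(self):
        b = StemLoopBackbone("flat", "AAAAAAAAAA", 1, 4)
        report = validate_backbone(b)
        assert report.k_terminal_complement == 0
        assert not report.is_valid

    def test_reverse_primer_substring(self):
        assert derive_reverse_primer(GROUP2) == "GCACTTCAGTGTCGTGGTCAGTGACGGCAATT"
        assert derive_reverse_primer(GROUP1) == "GTGCAGGGTCCGAGGT"
        with pytest.raises(DesignError):
            StemLoopBackbone("bad", "ACGTACGT", 7, 5)


class TestRtPrimer:
    @pytest.mark.parametrize("mirna_id,backbone_id,tail", [
        ("sli-miR-14", "group1", "GGATACGACTAGGAG"),
        ("sli-miR-2a", "group2", "TGAAGTGCGCTCAT"),
    ])
    def test_published_tails(self, mirna_id, backbone_id, tail):
        rt = design_rt_primer(REFERENCE_MATURES[mirna_id], BACKBONES[backbone_id])
        assert rt.endswith(tail)

    def test_length_is_backbone_plus_anchor(self, rng):
        mature = NucSeq("m", random_rna(rng, 22), "RNA")
        assert len(design_rt_primer(mature, GROUP2)) == 46
        assert len(design_rt_primer(mature, GROUP1)) == 50

    def test_too_short_mature(self):
        with pytest.raises(DesignError):
            design_rt_primer(NucSeq("m", "ACGUAC", "RNA"), GROUP2)


class TestForwardPrimer:
    def test_published_forward_primers(self):
        f14, cover, prefix = design_forward_primer(
            REFERENCE_MATURES["sli-miR-14"],
            DesignConfig(cover_len=13, prefix="CGGGGC"),
        )
        assert (f14, cover, prefix) == ("CGGGGCTCAGTCTTTTTCT", 13, "CGGGGC")
        f2a, _, _ = design_forward_primer(
            REFERENCE_MATURES["sli-miR-2a"],
            DesignConfig(cover_len=14, prefix="CGACACACACCATCAG"),
        )
        assert f2a == "CGACACACACCATCAGTATCACAGCCAGCT"

    def test_zero_gap_rejected(self):
        mature = REFERENCE_MATURES["sli-miR-14"]  # 21 nt
        with pytest.raises(DesignError):
            design_forward_primer(mature, DesignConfig(cover_len=15))  # gap 0

    def test_auto_prefix_reproducible_and_in_tm_window(self):
        mature = REFERENCE_MATURES["sli-miR-14"]
        cfg = DesignConfig(seed=42)
        out1 = design_forward_primer(mature, cfg, backbone=GROUP2)
        out2 = design_forward_primer(mature, cfg, backbone=GROUP2)
        assert out1 == out2
        forward, _, prefix = out1
        assert 4 <= len(prefix) <= 16
        assert cfg.tm_range[0] <= melting_temp(forward) <= cfg.tm_range[1]


class TestDesignAssay:
    @pytest.mark.parametrize("mirna_id,gap", [
        ("sli-miR-14", 2), ("sli-miR-2a", 3), ("sli-bantam", 4),
    ])
    def test_gap_lengths(self, mirna_id, gap):
        ps = reference_assay(mirna_id, "group2")
        assert ps.gap_len == gap
        assert ps.cover_len + ps.gap_len + ps.anchor_len == len(
            REFERENCE_MATURES[mirna_id]
        )

    def test_primer_set_invariants(self, rng):
        from mirloop.seqcore import as_dna_string, revcomp_str

        for i in range(30):
            n = int(rng.integers(18, 27))
            mature = NucSeq(f"m{i}", random_rna(rng, n), "RNA")
            ps = design_assay(mature, GROUP2, DesignConfig(seed=i))
            mdna = as_dna_string(mature)
            assert ps.rt_primer[-6:] == revcomp_str(mdna[-6:])
            assert ps.forward.endswith(mdna[:ps.cover_len])
            assert ps.cover_len + ps.gap_len + ps.anchor_len == n
            assert ps.gap_len >= 1

    def test_short_mature_warns(self):
        with pytest.warns(UserWarning, match="outside typical"):
            design_assay(NucSeq("tiny", "ACGUACGUACGUACGU", "RNA"),
                         GROUP2, DesignConfig(prefix="CGCACG", cover_len=8))


class TestMeltingTemp:
    def test_gc_raises_tm(self):
        assert melting_temp("A" * 12) < melting_temp("G" * 12)

    def test_monotone_in_concentration(self):
        p = "CGGGGCTCAGTCTTTTTCT"
        assert melting_temp(p, dnac_nM=500.0) > melting_temp(p, dnac_nM=250.0)

    def test_published_forward_in_sanity_window(self):
        assert 50.0 <= melting_temp("CGGGGCTCAGTCTTTTTCT") <= 65.0

    def test_too_short(self):
        with pytest.raises(DesignError):
            melting_temp("ACGT")


class TestCrossReactivity:
    def test_identical_pair_collides(self):
        a = NucSeq("a", "UGAUUGUCCAAACGCAAUUCUU", "RNA")
        b = NucSeq("b", "UGAUUGUCCAAACGCAAUUCUU", "RNA")
        report = hexamer_cross_reactivity([a, b])
        assert report.anchor_groups == {"ATTCTT": ("a", "b")}
        assert report.identical_pairs == (("a", "b"),)

    def test_five_prime_variant_flagged(self):
        # single 5' substitution: same 3' hexamer, invisible to the primers
        a = NucSeq("a", "UGAUUGUCCAAACGCAAUUCUU", "RNA")
        b = NucSeq("b", "CGAUUGUCCAAACGCAAUUCUU", "RNA")
        report = hexamer_cross_reactivity([a, b])
        assert report.five_prime_variant_pairs == (("a", "b"),)
        assert report.identical_pairs == ()
        assert report.gap_variant_pairs == ()

    def test_gap_variant_needs_cover(self):
        a = NucSeq("a", "UGAUUGUCCAAACGCAAUUCUU", "RNA")
        seq = list(a.seq)
        seq[14] = "G"  # inside the gap for cover 13, anchor 6 (positions 14-16)
        b = NucSeq("b", "".join(seq), "RNA")
        with_cover = hexamer_cross_reactivity([a, b], cover_len=13)
        assert with_cover.gap_variant_pairs == (("a", "b"),)
        without = hexamer_cross_reactivity([a, b])
        assert without.five_prime_variant_pairs == (("a", "b"),)

    def test_matches_all_pairs_oracle(self, rng):
        matures = []
        for i in range(50):
            n = int(rng.integers(18, 25))
            matures.append(NucSeq(f"m{i}", random_rna(rng, n), "RNA"))
        # force some collisions by reusing 3' hexamers
        for i in range(0, 20, 2):
            donor, recv = matures[i], matures[i + 1]
            matures[i + 1] = NucSeq(recv.id, recv.seq[:-6] + donor.seq[-6:], "RNA")
        report = hexamer_cross_reactivity(matures, anchor_len=6, cover_len=13)

        # independent quadratic oracle over plain DNA strings
        def oracle_category(sa: str, sb: str) -> str | None:
            if sa[-6:] != sb[-6:]:
                return None
            if sa == sb:
                return "identical"
            if len(sa) != len(sb):
                return "anchor_collision"
            diffs = [p + 1 for p in range(len(sa)) if sa[p] != sb[p]]
            if all(13 < d <= len(sa) - 6 for d in diffs):
                return "gap_variant"
            if all(d <= 13 for d in diffs):
                return "five_prime_variant"
            return "anchor_collision"

        expected = {"identical": [], "five_prime_variant": [],
                    "gap_variant": [], "anchor_collision": []}
        for i in range(len(matures)):
            for j in range(i + 1, len(matures)):
                sa = matures[i].seq.replace("U", "T")
                sb = matures[j].seq.replace("U", "T")
                cat = oracle_category(sa, sb)
                if cat:
                    expected[cat].append((matures[i].id, matures[j].id))
        assert list(report.identical_pairs) == expected["identical"]
        assert list(report.five_prime_variant_pairs) == expected["five_prime_variant"]
        assert list(report.gap_variant_pairs) == expected["gap_variant"]
        assert list(report.anchor_collision_pairs) == expected["anchor_collision"]

    def test_needs_two(self):
        with pytest.raises(DesignError):
            hexamer_cross_reactivity([NucSeq("a", "ACGUACGUACGUACGUACGU", "RNA")])
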