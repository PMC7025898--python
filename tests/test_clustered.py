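"""Kataegis, chromothripsis and chromoplexy detectors, their
categorisation rules and cross-sample recurrence scans."""

import numpy as np
import pytest

from pancankit import clustered as clu
from pancankit.io_formats import (
    GenomicInterval,
    JunctionRecord,
    SegmentRecord,
    VariantRecord,
)


def _snv(pos, chrom="1", ref="C", alt="T", context=None):
    rec = VariantRecord(chrom, pos, ref, alt, alt_count=5, depth=20)
    if context is not None:
        object.__setattr__(rec, "context", context)  # frozen dataclass
    return rec


def _run(start, n, gap=100, **kw):
    return [_snv(start + i * gap, **kw) for i in range(n)]


class TestDetectKataegis:
    def test_six_tight_substitutions_form_one_focus(self):
        foci = clu.detect_kataegis(_run(1000, 6, gap=90))
        assert len(foci) == 1 and foci[0].n_members == 6

    def test_five_clustered_snvs_are_not_enough(self):
        assert clu.detect_kataegis(_run(1000, 5)) == []

    def test_internal_gap_splits_run(self):
        # 12 SNVs with a 5-kb gap after the seventh: only the 7-member
        # run qualifies
        snvs = _run(1000, 7) + _run(1000 + 6 * 100 + 5000, 5)
        foci = clu.detect_kataegis(snvs)
        assert [f.n_members for f in foci] == [7]

    def test_gap_exactly_1kb_keeps_run_together(self):
        foci = clu.detect_kataegis(_run(1000, 6, gap=1000))
        assert len(foci) == 1

    def test_strand_coordination_fraction(self):
        mixed = _run(1000, 4, ref="C", alt="T") + \
            [_snv(1400 + i * 50, ref="G", alt="A") for i in range(2)]
        (focus,) = clu.detect_kataegis(mixed)
        assert focus.strand_coordination == pytest.approx(4 / 6)

    def test_invariant_to_distant_snvs(self):
        base = _run(10_000, 8)
        with_noise = base + [_snv(50_000), _snv(5_000), _snv(11_900)]
        a = clu.detect_kataegis(base)
        b = clu.detect_kataegis(with_noise)
        assert len(b) == len(a) == 1
        assert {m.pos for m in a[0].members} <= {m.pos for m in b[0].members}

    def test_closure_on_injected_foci(self, event_truth):
        foci = clu.detect_kataegis(event_truth.noiseless_variant_calls())
        truth_ids = [e for e in event_truth.events if e.kind == "kataegis"]
        assert len(foci) >= len(truth_ids)
        for e in truth_ids:
            iv = e.intervals[0]
            assert any(f.interval.overlaps(iv) for f in foci)


class TestClassifyKataegis:
    def _focus(self, members):
        return clu.KataegisFocus(
            interval=GenomicInterval("1", members[0].pos - 1, members[-1].pos),
            members=members, strand_coordination=1.0)

    def test_c_to_t_in_tpc_context_is_apobec(self):
        members = _run(1000, 6, ref="C", alt="T", context="TCA")
        assert clu.classify_kataegis(self._focus(members)) == "APOBEC-TpC"

    def test_t_to_g_in_cpt_context_is_error_prone_polymerase(self):
        members = _run(1000, 6, ref="T", alt="G", context="CTT")
        assert clu.classify_kataegis(self._focus(members)) == "TN-CpTpT"

    def test_c_mutations_in_gpc_context_are_alternative_deamination(self):
        members = _run(1000, 6, ref="C", alt="A", context="GCA")
        assert clu.classify_kataegis(self._focus(members)) == "alt-GpC/CpC"

    def test_purine_reference_is_reverse_complemented(self):
        # G>A on the reverse strand of a TpC context: complement G->C,
        # reversed context TGA -> TCA
        members = _run(1000, 6, ref="G", alt="A", context="TGA")
        assert clu.classify_kataegis(self._focus(members)) == "APOBEC-TpC"

    def test_even_mixture_is_other(self):
        members = (_run(1000, 3, ref="C", alt="T", context="TCA")
                   + _run(1400, 3, ref="T", alt="G", context="CTT"))
        assert clu.classify_kataegis(self._focus(members)) == "other"

    def test_all_contexts_missing_is_an_error(self):
        members = _run(1000, 6)
        with pytest.raises(ValueError, match="context"):
            clu.classify_kataegis(self._focus(members))


class TestJunctionAssociation:
    def _focus_at(self, start=10_000, end=10_500):
        members = [_snv(start + 1), _snv(end)]
        return clu.KataegisFocus(GenomicInterval("1", start, end),
                                 members, 1.0)

    @pytest.mark.parametrize("offset,window,expect", [
        (800, 1000, True),
        (5000, 1000, False),
        (5000, 10_000, True),
    ])
    def test_window_rules(self, offset, window, expect):
        focus = self._focus_at()
        j = JunctionRecord("1", focus.interval.end + offset, "+",
                           "2", 999_999, "-")
        assert clu.associate_with_junctions([focus], [j],
                                            window=window) == [expect]


class TestKataegisHotspots:
    def _focus(self, pos, sample):
        return clu.KataegisFocus(GenomicInterval("1", pos, pos + 400),
                                 [_snv(pos + 1)], 1.0, sample=sample)

    def test_three_foci_from_three_samples_make_a_hotspot(self):
        foci = [self._focus(10_000 + 200 * i, f"s{i}") for i in range(3)]
        assert len(clu.find_kataegis_hotspots(foci)) == 1

    def test_two_foci_are_not_enough(self):
        foci = [self._focus(10_000, "a"), self._focus(10_100, "b")]
        assert clu.find_kataegis_hotspots(foci) == []

    def test_three_foci_from_one_sample_are_not_a_hotspot(self):
        foci = [self._focus(10_000 + 200 * i, "same") for i in range(3)]
        assert clu.find_kataegis_hotspots(foci) == []


class TestChromothripsis:
    def test_injected_oscillating_region_detected(self, event_truth):
        regions = clu.detect_chromothripsis(event_truth.segments,
                                            event_truth.junctions)
        truth = [e for e in event_truth.events if e.kind == "chromothripsis"]
        assert len(regions) == len(truth) == 2
        for e in truth:
            assert any(r.intervals[0].overlaps(e.intervals[0])
                       for r in regions)
        for r in regions:
            assert r.breakend_count >= 10
            assert r.dominant_state_fraction >= 0.5
            assert r.junction_type_pvalue > 0.05
            assert set(r.characteristics) == {
                "multichromosomal", "amplification", "homozygous_deletion",
                "telomere_adjacent", "interbreakpoint_lt_10kb"}

    def test_monotonic_cn_staircase_rejected(self):
        # 12 breakends, copy number climbing 1..13: no two dominant states
        segs, junctions = [], []
        pos = 1_000_000
        for i in range(13):
            segs.append(SegmentRecord(
                GenomicInterval("1", pos, pos + 50_000), i + 1, 0))
            pos += 50_000
        bps = [s.interval.start for s in segs[1:]]
        for k in range(0, len(bps) - 1, 2):
            junctions.append(JunctionRecord("1", bps[k], "+",
                                            "1", bps[k + 1], "-"))
        assert clu.detect_chromothripsis(segs, junctions) == []

    def test_quiet_chromosome_yields_nothing(self):
        segs = [SegmentRecord(GenomicInterval("1", 0, 10_000_000), 1, 1)]
        assert clu.detect_chromothripsis(segs, []) == []

    def test_no_segments_is_an_error(self):
        with pytest.raises(ValueError):
            clu.detect_chromothripsis([], [])

    def test_skewed_junction_types_fail_random_stitching(self):
        # oscillating CN but all junctions deletion-type: not random
        segs = []
        pos = 1_000_000
        for i in range(13):
            segs.append(SegmentRecord(
                GenomicInterval("1", pos, pos + 50_000),
                1, 1 - i % 2))
            pos += 50_000
        bps = [s.interval.start for s in segs[1:]]
        junctions = [JunctionRecord("1", bps[k], "+", "1", bps[k + 1], "-")
                     for k in range(0, len(bps) - 1, 2)]
        assert clu.detect_chromothripsis(segs, junctions) == []


class TestChromoplexy:
    def _cycle(self, n=3, bridge=3000):
        chroms = [str(i + 1) for i in range(n)]
        foots = [(c, 1_000_000 * (i + 1)) for i, c in enumerate(chroms)]
        junctions = []
        for i in range(n):
            c1, p1 = foots[i]
            c2, p2 = foots[(i + 1) % n]
            junctions.append(JunctionRecord(c1, p1 + bridge, "+",
                                            c2, p2, "-"))
        return junctions

    def test_three_chromosome_cycle_is_one_chain(self):
        chains = clu.detect_chromoplexy(self._cycle())
        assert len(chains) == 1
        chain = chains[0]
        assert chain.kind == "chromoplexy" and chain.n_junctions == 3
        assert len(chain.footprints) == 3

    def test_reciprocal_pair_is_balanced_translocation_not_chromoplexy(self):
        a = JunctionRecord("1", 100_000, "+", "2", 500_000, "-")
        b = JunctionRecord("1", 100_040, "-", "2", 500_040, "+")
        (chain,) = clu.detect_chromoplexy([a, b])
        assert chain.kind == "balanced-translocation"

    def test_unrelated_distant_junction_excluded_from_chain(self):
        extra = JunctionRecord("1", 50_000_000, "+", "4", 70_000_000, "-")
        chains = clu.detect_chromoplexy(self._cycle() + [extra])
        assert len(chains) == 1
        keys = {j.key for j in chains[0].junctions}
        assert extra.key not in keys

    def test_chain_conservation_and_node_disjointness(self, event_truth):
        chains = [c for c in clu.detect_chromoplexy(event_truth.junctions)
                  if c.kind == "chromoplexy"]
        truth = [e for e in event_truth.events if e.kind == "chromoplexy"]
        assert len(chains) == len(truth) == 2
        seen_footprints = set()
        for c in chains:
            # each junction contributes exactly two breakends
            assert len(c.footprints) == c.n_junctions
            ids = {(fp.chrom, fp.start) for fp in c.footprints}
            assert not ids & seen_footprints
            seen_footprints |= ids


class TestChromoplexyHotspots:
    def _chain(self, sample, shift=0):
        juncs = [JunctionRecord("1", 100_000 + shift, "+",
                                "2", 500_000 + shift, "-")]
        return clu.ChromoplexyChain(
            junctions=juncs, chromosomes=["1", "2"],
            footprints=[GenomicInterval("1", 100_000 + shift, 100_100 + shift),
                        GenomicInterval("2", 500_000 + shift, 500_100 + shift)],
            sample=sample)

    def test_two_nearby_footprints_from_two_samples_recur(self):
        loci = clu.find_chromoplexy_hotspots(
            [self._chain("a"), self._chain("b", shift=8000)])
        assert len(loci) == 2  # both chromosome-1 and chromosome-2 loci

    def test_footprints_30kb_apart_do_not_recur(self):
        loci = clu.find_chromoplexy_hotspots(
            [self._chain("a"), self._chain("b", shift=30_000)])
        assert loci == []

    def test_four_clustered_footprints_collapse_to_one_locus(self):
        chains = [self._chain(f"s{i}", shift=2000 * i) for i in range(4)]
        loci = clu.find_chromoplexy_hotspots(chains)
        per_chrom = {l["chrom"]: l["n"] for l in loci}
        assert per_chrom == {"1": 4, "2": 4}
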