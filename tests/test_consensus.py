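"""Consensus merging rules, the indel stacker, SV clustering, consensus
copy number and accuracy evaluation."""

import numpy as np
import pandas as pd
import pytest

from pancankit import consensus as cns
from pancankit.io_formats import (
    GenomicInterval,
    JunctionRecord,
    SegmentRecord,
    VariantRecord,
)
from pancankit.simulate import (
    CallerProfile,
    TumourConfig,
    simulate_caller_outputs,
    simulate_tumour,
)


def _snv(chrom, pos, ref="A", alt="T", caller="x", **kw):
    kw.setdefault("alt_count", 5)
    kw.setdefault("depth", 20)
    return VariantRecord(chrom, pos, ref, alt, callers=(caller,), **kw)


class TestMergeSnvs:
    def test_two_of_three_agreement_rule(self):
        shared = [("1", 100), ("1", 200)]
        only_a = [("2", 50)]
        sets = {
            "a": [_snv(c, p, caller="a") for c, p in shared + only_a],
            "b": [_snv(c, p, caller="b") for c, p in shared],
            "c": [],
        }
        merged = cns.merge_snvs(sets)
        assert [(r.chrom, r.pos) for r in merged] == shared
        assert all(r.callers == {"a", "b"} for r in merged)

    def test_fewer_than_two_callsets_is_an_error(self):
        with pytest.raises(ValueError):
            cns.merge_snvs({"a": []})

    def test_mnv_recomposed_when_all_constituents_agree(self):
        mnv = VariantRecord("1", 100, "AC", "TG", 5, 20, ("a",))
        sets = {
            "a": [mnv],
            "b": [_snv("1", 100, "A", "T", caller="b"),
                  _snv("1", 101, "C", "G", caller="b")],
        }
        merged = cns.merge_snvs(sets)
        assert [(r.ref, r.alt) for r in merged] == [("AC", "TG")]

    def test_mnv_not_recomposed_when_constituent_missing(self):
        mnv = VariantRecord("1", 100, "AC", "TG", 5, 20, ("a",))
        sets = {
            "a": [mnv],
            "b": [_snv("1", 100, "A", "T", caller="b")],
        }
        merged = cns.merge_snvs(sets)
        assert [(r.ref, r.alt) for r in merged] == [("A", "T")]

    def test_monotone_adding_a_caller_never_removes_calls(self):
        sets = {
            "a": [_snv("1", 100, caller="a"), _snv("1", 300, caller="a")],
            "b": [_snv("1", 100, caller="b")],
        }
        before = {r.key for r in cns.merge_snvs(sets)}
        sets["c"] = [_snv("1", 300, caller="c")]
        after = {r.key for r in cns.merge_snvs(sets)}
        assert before <= after

    def test_output_is_subset_of_input_union(self, quiet_truth, three_callers):
        calls = simulate_caller_outputs(quiet_truth, three_callers, seed=2)
        sets = {n: calls[n]["snvs"] for n in calls}
        union = set().union(*({r.key for r in v} for v in sets.values()))
        assert {r.key for r in cns.merge_snvs(sets)} <= union


class TestTwoOfThreeClosedForm:
    def test_consensus_sensitivity_matches_binomial_closed_form(self):
        s = 0.85
        cfg = TumourConfig(seed=7, n_snvs=10_000, n_indels=0, n_svs=0,
                           subclonal_fraction=0.0, purity=1.0,
                           n_reciprocal_translocations=0)
        truth = simulate_tumour(cfg)
        profiles = [CallerProfile(name=n, sensitivity=s, fp_per_mb=0.1)
                    for n in "ABC"]
        calls = simulate_caller_outputs(truth, profiles, seed=11)
        merged = cns.merge_snvs({n: calls[n]["snvs"] for n in "ABC"})
        report = cns.evaluate_calls(merged, truth.noiseless_variant_calls())
        expected = 3 * s**2 * (1 - s) + s**3
        assert report.sensitivity == pytest.approx(expected, abs=0.01)
        # position-random false positives virtually never coincide
        assert report.precision > 0.999


class TestIndelStacker:
    def _table(self, n=200, seed=0, informative=True):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=n)
        x = y if informative else rng.integers(0, 2, size=n)
        return pd.DataFrame({
            "a": x, "b": x,
            "c": rng.integers(0, 2, size=n),
            "vaf": np.where(x, 0.35, 0.05) if informative
            else rng.uniform(0, 0.5, n),
            "depth": rng.poisson(38, n).astype(float),
            "homopolymer": rng.integers(0, 2, size=n),
            "label": y,
        })

    def test_perfectly_separable_training_accuracy_is_one(self):
        table = self._table(informative=True)
        model = cns.fit_indel_stacker(table, C=100.0)
        assert model.score(table) == 1.0

    def test_uninformative_features_give_chance_auc(self):
        from sklearn.metrics import roc_auc_score
        table = self._table(n=4000, seed=3, informative=False)
        model = cns.fit_indel_stacker(table)
        auc = roc_auc_score(table["label"],
                            model.predict_proba(table.drop(columns="label"))[:, 1])
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_refit_with_same_seed_is_deterministic(self):
        table = self._table()
        a = cns.fit_indel_stacker(table, seed=7)
        b = cns.fit_indel_stacker(table, seed=7)
        assert np.array_equal(a.coef_, b.coef_)

    def test_single_class_labels_rejected(self):
        table = self._table()
        table["label"] = 1
        with pytest.raises(ValueError, match="single class"):
            cns.fit_indel_stacker(table)

    def test_get_params_round_trip(self):
        model = cns.IndelStacker(C=2.0, seed=3)
        assert cns.IndelStacker(**model.get_params()).get_params() \
            == model.get_params()


@pytest.fixture(scope="module")
def fitted():
    cfg = TumourConfig(seed=31)
    truth = simulate_tumour(cfg)
    profiles = [CallerProfile(name=n, sensitivity=0.85,
                              indel_sensitivity=0.5, fp_per_mb=0.05,
                              indel_fp_per_mb=0.3) for n in "ABC"]
    calls = simulate_caller_outputs(truth, profiles, seed=13)
    sets = {n: calls[n]["indels"] for n in "ABC"}
    hp = calls["A"]["homopolymer"]
    table = cns.build_indel_features(
        sets, homopolymer=hp, truth_keys={v.key for v in truth.indels})
    return sets, hp, cns.fit_indel_stacker(table, seed=0)


class TestMergeIndels:
    def test_unanimous_clean_call_retained(self, fitted):
        sets, hp, model = fitted
        unanimous = [k for k in set(sets["A"] and
                     {r.key for r in sets["A"]})
                     & {r.key for r in sets["B"]} & {r.key for r in sets["C"]}
                     if not hp.get(k, False)]
        merged_keys = {r.key for r in cns.merge_indels(sets, model,
                                                       homopolymer=hp)}
        assert unanimous and set(unanimous) <= merged_keys

    def test_singleton_low_vaf_homopolymer_call_dropped(self, fitted):
        sets, hp, model = fitted
        lone = VariantRecord("1", 999_999, "A", "AT", alt_count=1, depth=40,
                             callers=("A",))
        test_sets = {"A": [lone], "B": [], "C": []}
        merged = cns.merge_indels(test_sets, model,
                                  homopolymer={lone.key: True})
        assert merged == []

    def test_threshold_zero_keeps_union(self, fitted):
        sets, hp, model = fitted
        union = set().union(*({r.key for r in v} for v in sets.values()))
        merged = cns.merge_indels(sets, model, threshold=0.0, homopolymer=hp)
        assert {r.key for r in merged} == union

    def test_unfitted_model_rejected(self, fitted):
        sets, hp, _ = fitted
        with pytest.raises(ValueError, match="fitted"):
            cns.merge_indels(sets, cns.IndelStacker())


def _brute_force_sv_clusters(items, tol):
    """Transitive closure over the both-breakends-within-tolerance
    relation, by repeated sweeps."""
    n = len(items)
    labels = list(range(n))
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(n):
                if labels[i] != labels[j] and \
                        cns._junctions_match(items[i][1], items[j][1], tol):
                    tgt = min(labels[i], labels[j])
                    src = max(labels[i], labels[j])
                    labels = [tgt if l == src else l for l in labels]
                    changed = True
    groups = {}
    for l, it in zip(labels, items):
        groups.setdefault(l, []).append(it)
    return list(groups.values())


class TestMergeSvs:
    def test_identical_junction_from_two_callers_merges(self):
        j = JunctionRecord("1", 1000, "+", "2", 5000, "-")
        merged = cns.merge_svs({"a": [j], "b": [j]})
        assert len(merged) == 1
        assert merged[0].key == j.key

    def test_breakends_beyond_tolerance_do_not_merge(self):
        a = JunctionRecord("1", 1000, "+", "2", 5000, "-")
        b = JunctionRecord("1", 1250, "+", "2", 5000, "-")
        assert cns.merge_svs({"a": [a], "b": [b]}, tolerance=100) == []

    def test_orientation_mismatch_blocks_merging(self):
        a = JunctionRecord("1", 1000, "+", "2", 5000, "-")
        b = JunctionRecord("1", 1000, "-", "2", 5000, "+")
        assert cns.merge_svs({"a": [a], "b": [b]}) == []

    def test_jittered_copies_merge_at_median_position(self):
        base = ("1", 10_000, "+", "2", 50_000, "-")
        jitters = [(-50, 30), (0, 0), (40, -45)]
        sets = {f"c{i}": [JunctionRecord(base[0], base[1] + da, base[2],
                                         base[3], base[4] + db, base[5])]
                for i, (da, db) in enumerate(jitters)}
        (merged,) = cns.merge_svs(sets, tolerance=100)
        # medians of (-50, 0, +40) and (+30, 0, -45) are both zero
        assert merged.pos_a == 10_000 and merged.pos_b == 50_000

    def test_clustering_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        items = []
        for caller in "abcd":
            for _ in range(15):
                p = int(rng.integers(0, 40) * 60)
                q = int(rng.integers(0, 40) * 60)
                items.append((caller, JunctionRecord(
                    "1", 100_000 + p, "+", "2", 200_000 + q, "-")))
        tol = 100
        oracle = _brute_force_sv_clusters(items, tol)
        expected = sorted(len({c for c, _ in grp}) >= 2 for grp in oracle)
        sets = {}
        for c, j in items:
            sets.setdefault(c, []).append(j)
        merged = cns.merge_svs(sets, tolerance=tol)
        assert len(merged) == sum(expected)


class TestConsensusCna:
    def test_boundary_snapped_to_junction_breakend(self):
        segs = [SegmentRecord(GenomicInterval("1", 0, 10_500), 1, 1),
                SegmentRecord(GenomicInterval("1", 10_500, 20_000), 2, 1)]
        j = JunctionRecord("1", 10_000, "+", "1", 30_000, "-")
        out = cns.consensus_cna({"a": segs}, [j], snap_tolerance=1000)
        assert any(s.interval.end == 10_000 or s.interval.start == 10_000
                   for s in out)

    def test_unanimous_callers_reproduce_input(self):
        segs = [SegmentRecord(GenomicInterval("1", 0, 10_000), 1, 1),
                SegmentRecord(GenomicInterval("1", 10_000, 20_000), 2, 1)]
        out = cns.consensus_cna({"a": segs, "b": segs, "c": segs}, [])
        assert out == segs

    def test_majority_wins_two_versus_one(self):
        base = [SegmentRecord(GenomicInterval("1", 0, 10_000), 1, 1)]
        other = [SegmentRecord(GenomicInterval("1", 0, 10_000), 2, 1)]
        out = cns.consensus_cna({"a": base, "b": base, "c": other}, [])
        assert out == base

    def test_tie_broken_toward_ploidy(self):
        a = [SegmentRecord(GenomicInterval("1", 0, 10_000), 3, 1)]
        b = [SegmentRecord(GenomicInterval("1", 0, 10_000), 1, 1)]
        out = cns.consensus_cna({"a": a, "b": b}, [], ploidy=2.0)
        assert (out[0].major, out[0].minor) == (1, 1)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            cns.consensus_cna({}, [])


class TestSvCnConsistency:
    def _segments(self, states):
        segs, start = [], 0
        for (major, minor), length in states:
            segs.append(SegmentRecord(
                GenomicInterval("1", start, start + length), major, minor))
            start += length
        return segs

    def test_deletion_with_cn_step_is_consistent(self):
        segs = self._segments([((1, 1), 100_000), ((1, 0), 50_000),
                               ((1, 1), 100_000)])
        j = JunctionRecord("1", 100_000, "+", "1", 150_000, "-")
        frac, flags = cns.sv_cn_consistency([j], segs)
        assert frac == 1.0 and flags == ["cn-change"]

    def test_lone_junction_on_flat_cn_is_inconsistent(self):
        segs = self._segments([((1, 1), 300_000)])
        j = JunctionRecord("1", 100_000, "+", "1", 200_000, "-")
        frac, flags = cns.sv_cn_consistency([j], segs)
        assert frac == 0.0 and flags == ["inconsistent"]

    def test_reciprocal_pair_on_flat_cn_is_balanced(self):
        segs = (self._segments([((1, 1), 300_000)])
                + [SegmentRecord(GenomicInterval("2", 0, 300_000), 1, 1)])
        a = JunctionRecord("1", 100_000, "+", "2", 100_000, "-")
        b = JunctionRecord("1", 100_050, "-", "2", 100_050, "+")
        frac, flags = cns.sv_cn_consistency([a, b], segs)
        assert frac == 1.0 and flags == ["balanced", "balanced"]

    def test_uncovered_junction_excluded_from_denominator(self):
        segs = self._segments([((1, 1), 300_000)])
        inside = JunctionRecord("1", 100_000, "+", "1", 200_000, "-")
        outside = JunctionRecord("3", 100_000, "+", "3", 200_000, "-")
        frac, flags = cns.sv_cn_consistency([inside, outside], segs)
        assert flags == ["inconsistent", "uncovered"]
        assert frac == 0.0

    def test_jointly_simulated_truth_is_fully_consistent(self, event_truth):
        frac, _ = cns.sv_cn_consistency(event_truth.junctions,
                                        event_truth.segments)
        assert frac == 1.0


class TestEvaluateCalls:
    def _truth(self, n=100):
        return [_snv("1", 10 * i + 10, caller="t") for i in range(n)]

    def test_perfect_calls_score_one(self):
        truth = self._truth()
        rep = cns.evaluate_calls(truth, truth)
        assert rep.sensitivity == rep.precision == rep.f1 == 1.0

    def test_symmetric_operating_point(self):
        assert cns.AccuracyReport.f1_score(0.95, 0.95) == pytest.approx(0.95)

    def test_printed_indel_operating_point(self):
        # sens 0.60, precision 0.91 -> F1 = 2*.6*.91/1.51
        assert cns.AccuracyReport.f1_score(0.60, 0.91) == pytest.approx(
            2 * 0.60 * 0.91 / (0.60 + 0.91))

    def test_zero_sensitivity_and_precision_give_zero_f1(self):
        assert cns.AccuracyReport.f1_score(0.0, 0.0) == 0.0

    def test_report_is_exchangeable_in_input_order(self):
        truth = self._truth(50)
        calls = truth[:30] + [_snv("2", 5, caller="x")]
        a = cns.evaluate_calls(calls, truth)
        b = cns.evaluate_calls(list(reversed(calls)), list(reversed(truth)))
        assert (a.sensitivity, a.precision, a.f1) == \
               (b.sensitivity, b.precision, b.f1)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            cns.evaluate_calls([], [])

    def test_per_bin_counts_partition_the_truth(self):
        truth = self._truth(60)
        rep = cns.evaluate_calls(truth[:40], truth,
                                 vaf_bins=[0, 0.1, 0.3, 1.0])
        assert rep.per_bin["n_truth"].sum() == 60


class TestContaminationFlag:
    @pytest.mark.parametrize("frac,expect", [
        (0.06, True),   # above the 5% threshold
        (0.05, False),  # boundary is strict
        (0.0, False),
    ])
    def test_threshold_rule(self, frac, expect):
        assert cns.flag_contaminated_normal(frac) is expect
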