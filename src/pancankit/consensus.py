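"""Multi-caller consensus merging and call-set accuracy evaluation.

SNVs use a simple agreement rule: a call enters the consensus when two
or more callers report the identical (chrom, pos, ref, alt). MNVs are
decomposed into their constituent SNVs before merging and re-composed
only when every constituent reaches consensus. Indels, where callers
agree far less, are integrated by a stacked logistic regression over
per-caller support flags, observed VAF, depth and a homopolymer-context
flag. SV junctions merge when two or more callers place both breakends
within a positional tolerance with matching orientations. Copy-number
segments are joined across callers with boundaries snapped to consensus
junction breakends, yielding base-pair-resolved consensus segments.

Because SV calls cannot be validated by re-sequencing a breakpoint
easily, the orthogonal check used here is copy-number consistency: a
genuine junction must either change total copy number at a breakend or
be balanced by a reciprocal partner.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.proportion import proportion_confint

from .io_formats import (
    GenomicInterval,
    JunctionRecord,
    SegmentRecord,
    VariantRecord,
)

__all__ = [
    "AccuracyReport",
    "merge_snvs",
    "decompose_mnv",
    "IndelStacker",
    "build_indel_features",
    "fit_indel_stacker",
    "merge_indels",
    "merge_svs",
    "consensus_cna",
    "sv_cn_consistency",
    "evaluate_calls",
    "flag_contaminated_normal",
]


# ---------------------------------------------------------------------------
# SNV consensus


def decompose_mnv(rec: VariantRecord) -> list[VariantRecord]:
    """Split an MNV into per-base SNVs (positions advance along ref)."""
    if rec.variant_class != "MNV":
        return [rec]
    out = []
    for i, (r, a) in enumerate(zip(rec.ref, rec.alt)):
        if r != a:
            out.append(VariantRecord(rec.chrom, rec.pos + i, r, a,
                                     alt_count=rec.alt_count, depth=rec.depth,
                                     callers=rec.callers,
                                     truth_label=rec.truth_label))
    return out


def merge_snvs(callsets: Mapping[str, Sequence[VariantRecord]],
               min_callers: int = 2) -> list[VariantRecord]:
    """Consensus SNVs/MNVs: keys reported by >= ``min_callers`` callers.

    Provenance is retained as the union of supporting callers. MNVs are
    decomposed before voting and re-composed when every constituent SNV
    reaches consensus.
    """
    if len(callsets) < 2:
        raise ValueError("need at least two call sets to form a consensus")
    support: dict[tuple, set] = {}
    best: dict[tuple, VariantRecord] = {}
    mnvs: dict[tuple, VariantRecord] = {}
    for caller, records in callsets.items():
        for rec in records:
            if rec.variant_class == "MNV":
                mnvs.setdefault(rec.key, rec)
            for sub in decompose_mnv(rec):
                support.setdefault(sub.key, set()).add(caller)
                prev = best.get(sub.key)
                if prev is None or sub.depth > prev.depth:
                    best[sub.key] = sub
    consensus_keys = {k for k, s in support.items() if len(s) >= min_callers}
    out = []
    recomposed: set = set()
    for key, rec in mnvs.items():
        parts = decompose_mnv(rec)
        if parts and all(p.key in consensus_keys for p in parts):
            callers = frozenset().union(*(support[p.key] for p in parts))
            out.append(VariantRecord(rec.chrom, rec.pos, rec.ref, rec.alt,
                                     alt_count=rec.alt_count, depth=rec.depth,
                                     callers=callers,
                                     truth_label=rec.truth_label))
            recomposed.update(p.key for p in parts)
    for key in consensus_keys - recomposed:
        rec = best[key]
        out.append(VariantRecord(rec.chrom, rec.pos, rec.ref, rec.alt,
                                 alt_count=rec.alt_count, depth=rec.depth,
                                 callers=frozenset(support[key]),
                                 truth_label=rec.truth_label))
    out.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    return out


# ---------------------------------------------------------------------------
# indel stacking


def build_indel_features(callsets: Mapping[str, Sequence[VariantRecord]],
                         homopolymer: Mapping[tuple, bool] | None = None,
                         truth_keys: set | None = None) -> pd.DataFrame:
    """Per-variant feature table over the union of indel calls.

    One row per distinct (chrom, pos, ref, alt): a 0/1 column per caller,
    mean observed VAF and depth across supporting callers, a homopolymer
    flag (from the supplied lookup), and ``label`` when truth is known.
    """
    callers = sorted(callsets)
    rows: dict[tuple, dict] = {}
    for caller, records in callsets.items():
        for rec in records:
            row = rows.setdefault(rec.key, {c: 0 for c in callers})
            row[caller] = 1
            row.setdefault("_vafs", []).append(rec.vaf)
            row.setdefault("_depths", []).append(rec.depth)
            if rec.truth_label is not None:
                row["label"] = int(rec.truth_label)
    data = []
    for key, row in rows.items():
        entry = {c: row[c] for c in callers}
        entry["vaf"] = float(np.mean(row["_vafs"]))
        entry["depth"] = float(np.mean(row["_depths"]))
        entry["homopolymer"] = int(bool(homopolymer.get(key, False))
                                   if homopolymer else 0)
        if truth_keys is not None:
            entry["label"] = int(key in truth_keys)
        elif "label" in row:
            entry["label"] = row["label"]
        entry["key"] = key
        data.append(entry)
    df = pd.DataFrame(data)
    if not df.empty:
        df = df.set_index("key")
    return df


class IndelStacker(BaseEstimator, ClassifierMixin):
    """Stacked logistic regression over per-caller indel evidence.

    Features: one 0/1 support flag per caller, mean observed VAF, depth
    and a homopolymer-context flag. Deterministic given ``seed``.

    Attributes (after :meth:`fit`)
    ------------------------------
    feature_names_ : list of str
    coef_ : ndarray, coefficient per feature
    intercept_ : float
    """

    def __init__(self, C: float = 1.0, seed: int = 0):
        self.C = C
        self.seed = seed

    def _matrix(self, table: pd.DataFrame) -> np.ndarray:
        return table[self.feature_names_].to_numpy(dtype=float)

    def fit(self, table: pd.DataFrame, y=None) -> "IndelStacker":
        if "label" in table.columns and y is None:
            y = table["label"].to_numpy()
        if y is None:
            raise ValueError("training labels required")
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        self.feature_names_ = [c for c in table.columns if c != "label"]
        self.model_ = LogisticRegression(
            C=self.C, max_iter=2000, random_state=self.seed)
        self.model_.fit(self._matrix(table), y)
        self.coef_ = self.model_.coef_[0].copy()
        self.intercept_ = float(self.model_.intercept_[0])
        return self

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise ValueError("IndelStacker is not fitted")
        return self.model_.predict_proba(self._matrix(table))

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(table)[:, 1] >= 0.5).astype(int)

    def score(self, table: pd.DataFrame, y=None) -> float:
        if y is None:
            y = table["label"].to_numpy()
        return float(np.mean(self.predict(table) == np.asarray(y)))


def fit_indel_stacker(labelled_table: pd.DataFrame, C: float = 1.0,
                      seed: int = 0) -> IndelStacker:
    """Fit the stacking model on a labelled feature table."""
    return IndelStacker(C=C, seed=seed).fit(labelled_table)


def merge_indels(callsets: Mapping[str, Sequence[VariantRecord]],
                 model: IndelStacker, threshold: float = 0.5,
                 homopolymer: Mapping[tuple, bool] | None = None
                 ) -> list[VariantRecord]:
    """Score the union of indel calls with the stacker; keep P >= threshold."""
    if not hasattr(model, "model_"):
        raise ValueError("stacking model must be fitted before merging")
    table = build_indel_features(callsets, homopolymer=homopolymer)
    if table.empty:
        return []
    feats = table[[c for c in table.columns if c != "label"]]
    probs = model.predict_proba(feats)[:, 1]
    callers = sorted(callsets)
    best: dict[tuple, VariantRecord] = {}
    support: dict[tuple, set] = {}
    for caller, records in callsets.items():
        for rec in records:
            support.setdefault(rec.key, set()).add(caller)
            prev = best.get(rec.key)
            if prev is None or rec.depth > prev.depth:
                best[rec.key] = rec
    out = []
    for key, p in zip(table.index, probs):
        if p >= threshold:
            rec = best[key]
            out.append(VariantRecord(rec.chrom, rec.pos, rec.ref, rec.alt,
                                     alt_count=rec.alt_count, depth=rec.depth,
                                     callers=frozenset(support[key]),
                                     truth_label=rec.truth_label))
    out.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    return out


# ---------------------------------------------------------------------------
# SV consensus


def _junctions_match(a: JunctionRecord, b: JunctionRecord,
                     tolerance: float) -> bool:
    (ca1, pa1, sa1), (ca2, pa2, sa2) = a.key
    (cb1, pb1, sb1), (cb2, pb2, sb2) = b.key
    return (ca1 == cb1 and ca2 == cb2 and sa1 == sb1 and sa2 == sb2
            and abs(pa1 - pb1) <= tolerance and abs(pa2 - pb2) <= tolerance)


def merge_svs(junction_callsets: Mapping[str, Sequence[JunctionRecord]],
              tolerance: float = 100.0, min_callers: int = 2
              ) -> list[JunctionRecord]:
    """Cluster junctions across callers; emit clusters seen by >= 2 callers.

    Two junctions cluster (single linkage) when both canonical breakends
    lie within ``tolerance`` bases with identical orientations. Each
    emitted consensus junction takes the median breakend positions of its
    cluster and the union of supporting callers.
    """
    items = []  # (caller, junction)
    for caller, recs in junction_callsets.items():
        for r in recs:
            items.append((caller, r))
    n = len(items)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # sort by first breakend to limit pair comparisons
    order = sorted(range(n), key=lambda i: items[i][1].key)
    for ii, i in enumerate(order):
        ji = items[i][1]
        for j in order[ii + 1:]:
            jj = items[j][1]
            if jj.key[0][0] != ji.key[0][0] or jj.key[0][1] - ji.key[0][1] > tolerance:
                break
            if _junctions_match(ji, jj, tolerance):
                union(i, j)
    clusters: dict[int, list] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(items[i])
    out = []
    for members in clusters.values():
        callers = {c for c, _ in members}
        if len(callers) < min_callers:
            continue
        keys = [j.key for _, j in members]
        pos1 = int(np.median([k[0][1] for k in keys]))
        pos2 = int(np.median([k[1][1] for k in keys]))
        (c1, _, s1), (c2, _, s2) = keys[0]
        cls = Counter(j.sv_class for _, j in members).most_common(1)[0][0]
        all_callers = frozenset().union(*(j.callers or {c} for c, j in members))
        out.append(JunctionRecord(c1, pos1, s1, c2, pos2, s2, sv_class=cls,
                                  callers=all_callers or frozenset(callers),
                                  name=members[0][1].name))
    out.sort(key=lambda j: j.key)
    return out


# ---------------------------------------------------------------------------
# consensus copy number


def _majority_cn(states: list[tuple[int, int]], ploidy: float) -> tuple[int, int]:
    counts = Counter(states)
    top = counts.most_common()
    best_count = top[0][1]
    tied = [s for s, c in top if c == best_count]
    if len(tied) == 1:
        return tied[0]
    # tie: prefer the state whose total is nearest the sample ploidy
    return min(tied, key=lambda s: (abs(s[0] + s[1] - ploidy), s))


def consensus_cna(segment_callsets: Mapping[str, Sequence[SegmentRecord]],
                  consensus_junctions: Sequence[JunctionRecord],
                  snap_tolerance: float = 1000.0,
                  ploidy: float = 2.0) -> list[SegmentRecord]:
    """Join per-caller segmentations into base-pair-resolved consensus.

    Segment boundaries within ``snap_tolerance`` of a consensus junction
    breakend are moved onto the breakend; copy-number states are decided
    per atomic interval by caller majority, ties resolved toward the
    sample ploidy.
    """
    if not segment_callsets or all(not v for v in segment_callsets.values()):
        raise ValueError("no segment call sets supplied")
    breakends: dict[str, list[int]] = {}
    for j in consensus_junctions:
        for chrom, pos, _ in j.breakends:
            breakends.setdefault(chrom, []).append(pos)
    for v in breakends.values():
        v.sort()

    def snap(chrom: str, pos: int) -> int:
        cands = breakends.get(chrom)
        if not cands:
            return pos
        i = int(np.searchsorted(cands, pos))
        best = min(
            (c for c in cands[max(0, i - 1):i + 1]),
            key=lambda c: abs(c - pos),
            default=pos,
        )
        return best if abs(best - pos) <= snap_tolerance else pos

    snapped: dict[str, list[SegmentRecord]] = {}
    bounds: dict[str, set] = {}
    for caller, segs in segment_callsets.items():
        fixed = []
        for s in segs:
            a = snap(s.chrom, s.interval.start)
            b = snap(s.chrom, s.interval.end)
            if a >= b:
                continue
            fixed.append(SegmentRecord(GenomicInterval(s.chrom, a, b),
                                       s.major, s.minor))
            bounds.setdefault(s.chrom, set()).update((a, b))
        snapped[caller] = fixed
    out = []
    for chrom, bset in bounds.items():
        cuts = sorted(bset)
        for a, b in zip(cuts, cuts[1:]):
            mid = (a + b) // 2
            states = []
            for segs in snapped.values():
                for s in segs:
                    if s.contains(chrom, mid):
                        states.append((s.major, s.minor))
                        break
            if not states:
                continue
            major, minor = _majority_cn(states, ploidy)
            out.append(SegmentRecord(GenomicInterval(chrom, a, b), major, minor))
    # merge adjacent intervals with identical state
    out.sort(key=lambda s: (s.chrom, s.interval.start))
    merged: list[SegmentRecord] = []
    for s in out:
        if (merged and merged[-1].chrom == s.chrom
                and merged[-1].interval.end == s.interval.start
                and (merged[-1].major, merged[-1].minor) == (s.major, s.minor)):
            merged[-1] = SegmentRecord(
                GenomicInterval(s.chrom, merged[-1].interval.start,
                                s.interval.end), s.major, s.minor)
        else:
            merged.append(s)
    return merged


# ---------------------------------------------------------------------------
# SV copy-number consistency


def _cn_change_near(segments_by_chrom: dict, chrom: str, pos: int,
                    tolerance: float) -> tuple[bool, bool]:
    """(covered, CN changes at a segment boundary within tolerance)."""
    segs = segments_by_chrom.get(chrom, [])
    covered = any(s.interval.start <= pos < s.interval.end for s in segs)
    if not covered:
        return False, False
    for left, right in zip(segs, segs[1:]):
        if left.interval.end != right.interval.start:
            continue
        boundary = left.interval.end
        if abs(boundary - pos) <= tolerance and left.total != right.total:
            return True, True
    return True, False


def _is_reciprocal(a: JunctionRecord, b: JunctionRecord,
                   tolerance: float) -> bool:
    (ca1, pa1, sa1), (ca2, pa2, sa2) = a.key
    (cb1, pb1, sb1), (cb2, pb2, sb2) = b.key
    return (ca1 == cb1 and ca2 == cb2
            and abs(pa1 - pb1) <= tolerance and abs(pa2 - pb2) <= tolerance
            and sa1 != sb1 and sa2 != sb2)


def sv_cn_consistency(junctions: Sequence[JunctionRecord],
                      segments: Sequence[SegmentRecord],
                      cn_tolerance: float = 10_000.0,
                      partner_tolerance: float = 1000.0
                      ) -> tuple[float, list[str]]:
    """Fraction of junctions that respect copy number, plus per-junction flags.

    A junction is consistent when total copy number steps at a segment
    boundary within ``cn_tolerance`` of either breakend, or when a
    reciprocal partner (same chromosome pair, breakends within
    ``partner_tolerance``, opposite orientations at both ends) makes it
    balanced. Junctions with an uncovered breakend are flagged
    ``uncovered`` and excluded from the denominator.
    """
    by_chrom: dict[str, list] = {}
    for s in sorted(segments, key=lambda s: (s.chrom, s.interval.start)):
        by_chrom.setdefault(s.chrom, []).append(s)
    flags = []
    n_considered = n_consistent = 0
    junctions = list(junctions)
    for i, j in enumerate(junctions):
        covered = True
        changed = False
        for chrom, pos, _ in j.breakends:
            cov, chg = _cn_change_near(by_chrom, chrom, pos, cn_tolerance)
            covered &= cov
            changed |= chg
        if not covered:
            flags.append("uncovered")
            continue
        if changed:
            flags.append("cn-change")
            n_considered += 1
            n_consistent += 1
            continue
        if any(_is_reciprocal(j, other, partner_tolerance)
               for k, other in enumerate(junctions) if k != i):
            flags.append("balanced")
            n_considered += 1
            n_consistent += 1
        else:
            flags.append("inconsistent")
            n_considered += 1
    fraction = n_consistent / n_considered if n_considered else float("nan")
    return fraction, flags


# ---------------------------------------------------------------------------
# accuracy evaluation


@dataclass
class AccuracyReport:
    """Sensitivity/precision/F1 with Clopper-Pearson intervals."""

    sensitivity: float
    precision: float
    f1: float
    n_truth: int
    n_calls: int
    n_tp: int
    ci_level: float
    sensitivity_ci: tuple
    precision_ci: tuple
    per_bin: pd.DataFrame | None = None

    @staticmethod
    def f1_score(sensitivity: float, precision: float) -> float:
        if sensitivity + precision == 0:
            return 0.0
        return 2 * sensitivity * precision / (sensitivity + precision)


def evaluate_calls(calls: Sequence[VariantRecord],
                   truth: Sequence, vaf_bins: Sequence[float] | None = None,
                   ci_level: float = 0.90) -> AccuracyReport:
    """Compare a call set with truth by exact (chrom,pos,ref,alt) keys.

    ``truth`` items need ``.key`` and, for per-bin reporting, ``.vaf``.
    ``vaf_bins`` are bin edges partitioning [0, 1].
    """
    truth = list(truth)
    if not truth:
        raise ValueError("empty truth set")
    truth_keys = {t.key for t in truth}
    call_keys = {c.key for c in calls}
    tp = len(call_keys & truth_keys)
    fp = len(call_keys - truth_keys)
    fn = len(truth_keys - call_keys)
    sens = tp / (tp + fn) if tp + fn else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    alpha = 1 - ci_level
    sens_ci = proportion_confint(tp, tp + fn, alpha=alpha, method="beta") \
        if tp + fn else (0.0, 1.0)
    prec_ci = proportion_confint(tp, tp + fp, alpha=alpha, method="beta") \
        if tp + fp else (0.0, 1.0)
    per_bin = None
    if vaf_bins is not None:
        edges = np.asarray(vaf_bins, dtype=float)
        rows = []
        call_vaf = {c.key: c.vaf for c in calls}
        truth_vaf = {t.key: getattr(t, "vaf", np.nan) for t in truth}
        for lo, hi in zip(edges, edges[1:]):
            t_in = [k for k, v in truth_vaf.items() if lo <= v < hi or
                    (hi == edges[-1] and v == hi)]
            c_in = [k for k, v in call_vaf.items() if lo <= v < hi or
                    (hi == edges[-1] and v == hi)]
            btp = len([k for k in t_in if k in call_keys])
            bfn = len(t_in) - btp
            ctp = len([k for k in c_in if k in truth_keys])
            cfp = len(c_in) - ctp
            bsens = btp / (btp + bfn) if btp + bfn else np.nan
            bprec = ctp / (ctp + cfp) if ctp + cfp else np.nan
            bf1 = (AccuracyReport.f1_score(bsens, bprec)
                   if not (np.isnan(bsens) or np.isnan(bprec)) else np.nan)
            rows.append({"vaf_lo": lo, "vaf_hi": hi, "n_truth": len(t_in),
                         "n_calls": len(c_in), "sensitivity": bsens,
                         "precision": bprec, "f1": bf1})
        per_bin = pd.DataFrame(rows)
    return AccuracyReport(
        sensitivity=sens, precision=prec,
        f1=AccuracyReport.f1_score(sens, prec),
        n_truth=len(truth_keys), n_calls=len(call_keys), n_tp=tp,
        ci_level=ci_level, sensitivity_ci=tuple(np.atleast_1d(sens_ci)),
        precision_ci=tuple(np.atleast_1d(prec_ci)), per_bin=per_bin)


def flag_contaminated_normal(contamination_fraction: float,
                             threshold: float = 0.05) -> bool:
    """Tumour-in-normal QC: flag when contamination strictly exceeds 5%."""
    if not 0 <= contamination_fraction <= 1:
        raise ValueError("contamination fraction must lie in [0,1]")
    return contamination_fraction > threshold
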