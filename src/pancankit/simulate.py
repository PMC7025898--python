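"""Synthetic tumour-genome cohorts with known truth.

The simulator emulates the observables a whole-genome tumour/normal pair
yields after variant calling: somatic SNVs/indels with read support shaped
by purity, local copy number and cancer-cell fraction; SV junctions; and
allele-specific copy-number segments. On top of a Poisson background it
injects the three clustered processes — kataegis foci (strand-coordinated
TpC C>N runs next to an SV breakend), chromothripsis regions (≥10
clustered breakends with copy number oscillating between two states) and
chromoplexy chains (closed cycles of ≥3 balanced translocations bridged by
short deletions) — so that every downstream detector can be validated
against construction-time truth.

Imperfect callers are modelled as sensitivity curves over VAF plus a
uniform false-positive rate per megabase and positional jitter on
junction breakends.

All randomness flows from the single integer seed in ``TumourConfig``
through one ``numpy`` generator; no global state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .io_formats import (
    GenomicInterval,
    JunctionRecord,
    SegmentRecord,
    VariantRecord,
)

__all__ = [
    "TumourConfig",
    "TruthVariant",
    "InjectedEvent",
    "TruthSet",
    "CallerProfile",
    "expected_vaf",
    "simulate_tumour",
    "simulate_caller_outputs",
    "simulate_cohort_burdens",
    "detection_power",
    "power_profile",
]

DEFAULT_CHROMS = {"1": 50_000_000, "2": 50_000_000,
                  "3": 50_000_000, "4": 50_000_000}

#: per-year background burden slopes used as defaults
SNVS_PER_YEAR = 190.0
INDELS_PER_YEAR = 22.0
SVS_PER_YEAR = 1.5

_BASES = np.array(list("ACGT"))


def expected_vaf(purity: float, multiplicity: int, tumour_total_cn: int,
                 normal_cn: int = 2) -> float:
    """Expected variant allele fraction of a clonal mutation.

    VAF = rho * m / (rho * n_t + (1 - rho) * n_normal), the fraction of
    all chromosome copies at the locus, across tumour and contaminating
    normal cells, that carry the mutation.
    """
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0,1], got {purity}")
    if multiplicity < 1:
        raise ValueError(f"multiplicity must be >= 1, got {multiplicity}")
    if tumour_total_cn < 1:
        raise ValueError(f"tumour total CN must be >= 1, got {tumour_total_cn}")
    if normal_cn not in (0, 1, 2):
        raise ValueError(f"normal CN must be 0, 1 or 2, got {normal_cn}")
    if multiplicity > tumour_total_cn:
        raise ValueError(
            f"multiplicity {multiplicity} exceeds tumour total CN {tumour_total_cn}")
    return purity * multiplicity / (
        purity * tumour_total_cn + (1 - purity) * normal_cn)


def detection_power(depth: int, vaf: float, min_alt_reads: int = 3) -> float:
    """P(Binomial(depth, vaf) >= min_alt_reads): the chance a clonal
    mutation at this locus yields enough alt reads to be callable."""
    if min_alt_reads < 1:
        raise ValueError("min_alt_reads must be >= 1")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not 0 <= vaf <= 1:
        raise ValueError("expected VAF must lie in [0,1]")
    if depth == 0:
        return 0.0
    return float(stats.binom.sf(min_alt_reads - 1, depth, vaf))


def power_profile(segments: Sequence[SegmentRecord], purity: float,
                  coverage: float, ploidy: float | None = None,
                  min_alt_reads: int = 3, normal_cn: int = 2) -> float:
    """Genome-wide average sensitivity for clonal single-copy mutations,
    weighting each copy-number segment by its length."""
    if not segments:
        raise ValueError("no segments supplied")
    if ploidy is None:
        tot = sum(s.total * s.interval.length for s in segments)
        ploidy = tot / sum(s.interval.length for s in segments)
    weights, powers = [], []
    for s in segments:
        vaf = expected_vaf(purity, 1, max(s.total, 1), normal_cn)
        depth = coverage * (purity * s.total + (1 - purity) * normal_cn) / (
            purity * ploidy + (1 - purity) * normal_cn)
        powers.append(detection_power(int(round(depth)), vaf, min_alt_reads))
        weights.append(s.interval.length)
    return float(np.average(powers, weights=weights))


# ---------------------------------------------------------------------------
# configuration and truth containers


@dataclass
class TumourConfig:
    """Parameters of one simulated tumour.

    Background burdens default to per-year slopes times age (about 190
    SNVs, 22 indels and 1.5 SVs per year of age at diagnosis). Counts of
    clustered events to inject are explicit.
    """

    seed: int
    purity: float = 0.7
    wgd: bool = False
    sex: str = "male"
    age: float = 56.0
    tumour_type: str = "simulated"
    coverage: float = 38.0
    chromosome_lengths: dict = field(default_factory=lambda: dict(DEFAULT_CHROMS))
    subclone_ccfs: tuple = (0.4,)
    subclonal_fraction: float = 0.2
    n_snvs: int | None = None
    n_indels: int | None = None
    n_svs: int | None = None
    n_kataegis: int = 0
    n_chromothripsis: int = 0
    n_chromoplexy: int = 0
    n_reciprocal_translocations: int = 1
    kataegis_size: int = 8
    chromothripsis_breakends: int = 30
    pre_gain_fraction: float = 0.5

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0,1]")
        for ccf in self.subclone_ccfs:
            if not 0 < ccf < 1:
                raise ValueError(f"subclone CCF must be in (0,1), got {ccf}")
        for name in ("n_snvs", "n_indels", "n_svs"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def genome_length(self) -> int:
        return sum(self.chromosome_lengths.values())

    def expected_burden(self) -> tuple[float, float, float]:
        return (
            self.n_snvs if self.n_snvs is not None else SNVS_PER_YEAR * self.age,
            self.n_indels if self.n_indels is not None else INDELS_PER_YEAR * self.age,
            self.n_svs if self.n_svs is not None else SVS_PER_YEAR * self.age,
        )


@dataclass
class TruthVariant:
    """A true somatic mutation with its clonal context."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ccf: float
    multiplicity: int
    major: int
    minor: int
    context: str  # trinucleotide around the (first) ref base
    homopolymer: bool = False
    event_id: str | None = None
    event_type: str | None = None  # kataegis | chromothripsis | chromoplexy
    timing: str | None = None  # pre-gain | post-gain | None

    @property
    def total_cn(self) -> int:
        return self.major + self.minor

    @property
    def variant_class(self) -> str:
        if len(self.ref) == len(self.alt):
            return "SNV" if len(self.ref) == 1 else "MNV"
        return "insertion" if len(self.ref) < len(self.alt) else "deletion"

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class InjectedEvent:
    """Truth descriptor of one injected clustered event."""

    kind: str  # kataegis | chromothripsis | chromoplexy
    event_id: str
    intervals: list
    variant_keys: list = field(default_factory=list)
    junction_keys: list = field(default_factory=list)
    n_oscillation_states: int | None = None


@dataclass
class TruthSet:
    """Everything the simulator knows about one tumour."""

    config: TumourConfig
    ploidy: float
    variants: list  # TruthVariant (SNVs/MNVs)
    indels: list  # TruthVariant
    junctions: list  # JunctionRecord
    segments: list  # SegmentRecord
    events: list  # InjectedEvent

    def tumour_vaf(self, v: TruthVariant) -> float:
        rho = self.config.purity
        return rho * v.multiplicity * v.ccf / (
            rho * v.total_cn + (1 - rho) * 2)

    def noiseless_variant_calls(self) -> list[VariantRecord]:
        """Perfect call set: every true SNV at its expected read support."""
        out = []
        depth0 = self.config.coverage
        for v in self.variants:
            depth = max(1, int(round(depth0 * (
                self.config.purity * v.total_cn
                + (1 - self.config.purity) * 2) / (
                self.config.purity * self.ploidy
                + (1 - self.config.purity) * 2))))
            alt = min(depth, max(1, int(round(self.tumour_vaf(v) * depth))))
            out.append(VariantRecord(v.chrom, v.pos, v.ref, v.alt,
                                     alt_count=alt, depth=depth,
                                     callers=("truth",), truth_label=True))
        return sorted(out, key=lambda r: (r.chrom, r.pos))

    def noiseless_junction_calls(self) -> list[JunctionRecord]:
        return list(self.junctions)


@dataclass
class CallerProfile:
    """An imperfect variant caller.

    ``sensitivity`` maps VAF -> detection probability (a callable or a
    constant); ``fp_per_mb`` false positives are sprinkled uniformly with
    low VAFs; junction breakends are jittered by a Gaussian of
    ``jitter_sd`` bases.
    """

    name: str
    sensitivity: Callable[[float], float] | float = 0.85
    indel_sensitivity: Callable[[float], float] | float | None = None
    fp_per_mb: float = 0.1
    indel_fp_per_mb: float = 0.2
    jitter_sd: float = 0.0
    junction_sensitivity: float = 0.9
    homopolymer_penalty: float = 0.4  # multiplicative sens loss in homopolymers

    def sens(self, vaf: float) -> float:
        s = self.sensitivity(vaf) if callable(self.sensitivity) else self.sensitivity
        if not 0 <= s <= 1:
            raise ValueError(f"sensitivity {s} outside [0,1]")
        return s

    def indel_sens(self, vaf: float, homopolymer: bool) -> float:
        base = self.indel_sensitivity
        if base is None:
            base = self.sensitivity
        s = base(vaf) if callable(base) else base
        if homopolymer:
            s *= 1 - self.homopolymer_penalty
        if not 0 <= s <= 1:
            raise ValueError(f"indel sensitivity {s} outside [0,1]")
        return s


# ---------------------------------------------------------------------------
# copy-number bookkeeping


def _split_segments(segments: list[SegmentRecord], chrom: str, start: int,
                    end: int) -> list[SegmentRecord]:
    """Split segments so that [start, end) boundaries coincide with
    segment boundaries."""
    out = []
    for s in segments:
        iv = s.interval
        if iv.chrom != chrom or iv.end <= start or iv.start >= end:
            out.append(s)
            continue
        cuts = sorted({iv.start, iv.end, max(iv.start, start), min(iv.end, end)})
        for a, b in zip(cuts, cuts[1:]):
            if a < b:
                out.append(SegmentRecord(GenomicInterval(chrom, a, b),
                                         s.major, s.minor))
    out.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    return out


def _apply_cn_delta(segments: list[SegmentRecord], chrom: str, start: int,
                    end: int, delta: int) -> list[SegmentRecord]:
    """Add ``delta`` to total copy number over [start, end): gains raise
    the major allele, losses delete the minor allele first."""
    segments = _split_segments(segments, chrom, start, end)
    out = []
    for s in segments:
        iv = s.interval
        if iv.chrom == chrom and iv.start >= start and iv.end <= end:
            major, minor = s.major, s.minor
            if delta >= 0:
                major += delta
            else:
                take = min(minor, -delta)
                minor -= take
                major -= (-delta - take)
                major = max(major, 0)
                minor = min(minor, major)
            out.append(SegmentRecord(iv, major, minor))
        else:
            out.append(s)
    return out


def _set_cn(segments: list[SegmentRecord], chrom: str, start: int, end: int,
            major: int, minor: int) -> list[SegmentRecord]:
    segments = _split_segments(segments, chrom, start, end)
    out = []
    for s in segments:
        iv = s.interval
        if iv.chrom == chrom and iv.start >= start and iv.end <= end:
            out.append(SegmentRecord(iv, major, minor))
        else:
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# tumour simulation


def _random_context(rng, ref: str) -> str:
    left, right = rng.choice(_BASES), rng.choice(_BASES)
    return f"{left}{ref}{right}"


def _sample_clone(rng, config: TumourConfig) -> float:
    """CCF of the clone a background mutation belongs to."""
    if config.subclone_ccfs and rng.random() < config.subclonal_fraction:
        return float(rng.choice(np.asarray(config.subclone_ccfs)))
    return 1.0


class _Placer:
    """Samples positions while keeping injected events apart."""

    def __init__(self, rng, chrom_lengths: dict):
        self.rng = rng
        self.lengths = chrom_lengths
        self.reserved: dict[str, list] = {c: [] for c in chrom_lengths}

    def reserve_window(self, span: int, margin: int = 1_000_000,
                       chrom: str | None = None) -> tuple[str, int]:
        chroms = list(self.lengths) if chrom is None else [chrom]
        for _ in range(200):
            c = chroms[int(self.rng.integers(len(chroms)))]
            length = self.lengths[c]
            if length <= span + 2 * margin:
                continue
            start = int(self.rng.integers(margin, length - span - margin))
            if all(start + span + margin < a or start > b + margin
                   for a, b in self.reserved[c]):
                self.reserved[c].append((start, start + span))
                return c, start
        raise ValueError("genome too short for the requested events")


def simulate_tumour(config: TumourConfig) -> TruthSet:
    """Generate the full truth for one tumour; deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    placer = _Placer(rng, config.chromosome_lengths)
    base_major, base_minor = (2, 2) if config.wgd else (1, 1)

    # baseline copy number: one whole-arm gain on a random chromosome so
    # that pre-/post-gain timing is exercised
    segments: list[SegmentRecord] = [
        SegmentRecord(GenomicInterval(c, 0, length), base_major, base_minor)
        for c, length in config.chromosome_lengths.items()
    ]
    gain_chrom = list(config.chromosome_lengths)[
        int(rng.integers(len(config.chromosome_lengths)))]
    gain_len = config.chromosome_lengths[gain_chrom] // 2
    segments = _apply_cn_delta(segments, gain_chrom, 0, gain_len, +1)

    junctions: list[JunctionRecord] = []
    events: list[InjectedEvent] = []
    variants: list[TruthVariant] = []
    indels: list[TruthVariant] = []

    # ---- chromothripsis regions -------------------------------------
    for i in range(config.n_chromothripsis):
        n_be = config.chromothripsis_breakends
        if n_be % 2:
            n_be += 1
        span = 2_000_000
        chrom, start = placer.reserve_window(span)
        # breakpoints with a minimum spacing so no junction is sub-SV-sized
        gaps = rng.integers(5_000, span // n_be, size=n_be)
        bps = start + np.cumsum(gaps)
        bps = np.sort(bps)
        # oscillating copy number: alternate (1,1) / (1,0) between breakpoints
        bounds = [start] + [int(b) for b in bps] + [start + span]
        state = 0
        for a, b in zip(bounds, bounds[1:]):
            major, minor = (1, 1) if state == 0 else (1, 0)
            segments = _set_cn(segments, chrom, a, b, major, minor)
            state ^= 1
        # near-random stitching with balanced junction-type proportions
        order = rng.permutation(n_be)
        strand_pairs = [("+", "-"), ("-", "+"), ("+", "+"), ("-", "-")]
        jkeys = []
        k = 0
        for j in range(0, n_be, 2):
            pa, pb = int(bps[order[j]]), int(bps[order[j + 1]])
            if abs(pa - pb) <= 200:
                pb += 5_000
            sa, sb = strand_pairs[k % 4]
            k += 1
            jn = JunctionRecord(chrom, min(pa, pb), sa, chrom, max(pa, pb), sb,
                                name=f"ct{i}_{j // 2}")
            junctions.append(jn)
            jkeys.append(jn.key)
        events.append(InjectedEvent(
            "chromothripsis", f"chromothripsis_{i}",
            [GenomicInterval(chrom, start, start + span)],
            junction_keys=jkeys, n_oscillation_states=2))

    # ---- chromoplexy chains ------------------------------------------
    chrom_names = list(config.chromosome_lengths)
    for i in range(config.n_chromoplexy):
        k = min(3, len(chrom_names))
        if k < 2:
            raise ValueError("chromoplexy needs >= 2 chromosomes")
        chosen = [str(c) for c in
                  rng.choice(np.asarray(chrom_names), size=k, replace=False)]
        foots = []
        for c in chosen:
            bridge = int(rng.integers(2_000, 8_000))
            cc, s = placer.reserve_window(bridge, chrom=c)
            foots.append((cc, s, s + bridge))
            # short deletion bridge between the two breakends
            segments = _apply_cn_delta(segments, cc, s, s + bridge, -1)
        jkeys = []
        for j in range(k):
            c1, _, b_end = foots[j]
            c2, b_start, _ = foots[(j + 1) % k]
            jn = JunctionRecord(c1, b_end, "+", c2, b_start, "-",
                                name=f"cp{i}_{j}")
            junctions.append(jn)
            jkeys.append(jn.key)
        events.append(InjectedEvent(
            "chromoplexy", f"chromoplexy_{i}",
            [GenomicInterval(c, s, e) for c, s, e in foots],
            junction_keys=jkeys))

    # ---- balanced reciprocal translocations --------------------------
    for i in range(config.n_reciprocal_translocations):
        if len(chrom_names) < 2:
            break
        ca, cb = rng.choice(np.asarray(chrom_names), size=2, replace=False)
        _, pa = placer.reserve_window(1000, chrom=str(ca))
        _, pb = placer.reserve_window(1000, chrom=str(cb))
        junctions.append(JunctionRecord(str(ca), pa, "+", str(cb), pb, "-",
                                        name=f"recip{i}_a"))
        junctions.append(JunctionRecord(str(ca), pa + 1, "-", str(cb), pb + 1, "+",
                                        name=f"recip{i}_b"))

    # ---- background SVs (deletions/duplications with CN effect) ------
    exp_snvs, exp_indels, exp_svs = config.expected_burden()
    n_bg_sv = int(rng.poisson(exp_svs))
    for i in range(n_bg_sv):
        span = int(rng.integers(50_000, 500_000))
        try:
            chrom, start = placer.reserve_window(span, margin=100_000)
        except ValueError:
            break
        if rng.random() < 0.6:  # deletion
            junctions.append(JunctionRecord(chrom, start, "+",
                                            chrom, start + span, "-",
                                            name=f"bgdel{i}"))
            segments = _apply_cn_delta(segments, chrom, start, start + span, -1)
        else:  # tandem duplication
            junctions.append(JunctionRecord(chrom, start, "-",
                                            chrom, start + span, "+",
                                            name=f"bgdup{i}"))
            segments = _apply_cn_delta(segments, chrom, start, start + span, +1)

    seg_sorted = sorted(segments, key=lambda s: (s.interval.chrom, s.interval.start))

    def seg_at(chrom: str, pos: int) -> SegmentRecord:
        for s in seg_sorted:
            if s.contains(chrom, pos):
                return s
        raise ValueError(f"position {chrom}:{pos} outside simulated segments")

    # ---- kataegis foci ------------------------------------------------
    katcontexts = ["TCA", "TCT", "TCC"]
    for i in range(config.n_kataegis):
        # anchor junction with a deletion so its CN footprint is consistent
        span = 20_000
        chrom, start = placer.reserve_window(span + 12_000, margin=50_000)
        anchor = JunctionRecord(chrom, start, "+", chrom, start + span, "-",
                                name=f"kat_anchor{i}")
        junctions.append(anchor)
        segments = _apply_cn_delta(segments, chrom, start, start + span, -1)
        seg_sorted = sorted(segments,
                            key=lambda s: (s.interval.chrom, s.interval.start))
        pos = start + span + int(rng.integers(100, 900))
        keys = []
        focus_start = pos
        for _ in range(config.kataegis_size):
            seg = seg_at(chrom, pos)
            alt = "T" if rng.random() < 0.7 else "G"
            v = TruthVariant(chrom, pos, "C", alt, ccf=1.0, multiplicity=1,
                             major=seg.major, minor=seg.minor,
                             context=katcontexts[int(rng.integers(3))],
                             event_id=f"kataegis_{i}", event_type="kataegis")
            variants.append(v)
            keys.append(v.key)
            pos += int(rng.integers(50, 900))
        events.append(InjectedEvent(
            "kataegis", f"kataegis_{i}",
            [GenomicInterval(chrom, focus_start, pos)],
            variant_keys=keys, junction_keys=[anchor.key]))

    # ---- background point mutations ----------------------------------
    chrom_arr = list(config.chromosome_lengths.items())
    probs = np.array([l for _, l in chrom_arr], dtype=float)
    probs /= probs.sum()

    def place_background(n: int, indel: bool):
        recs = []
        chrom_idx = rng.choice(len(chrom_arr), size=n, p=probs)
        for ci in chrom_idx:
            chrom, length = chrom_arr[ci]
            pos = int(rng.integers(1, length))
            try:
                seg = seg_at(chrom, pos)
            except ValueError:
                continue
            total = seg.total
            if total < 1:
                continue
            ccf = _sample_clone(rng, config)
            if ccf < 1.0 or seg.major < 2:
                mult, timing = 1, None
            elif rng.random() < config.pre_gain_fraction:
                mult, timing = seg.major, "pre-gain"
            else:
                mult, timing = 1, "post-gain"
            ref = str(rng.choice(_BASES))
            if indel:
                ins = rng.random() < 0.5
                unit = str(rng.choice(_BASES))
                alt = ref + unit if ins else ref
                if not ins:
                    ref = ref + unit
                homopolymer = rng.random() < 0.3
            else:
                alt = str(rng.choice(_BASES[_BASES != ref]))
                homopolymer = False
            recs.append(TruthVariant(chrom, pos, ref, alt, ccf=ccf,
                                     multiplicity=mult, major=seg.major,
                                     minor=seg.minor,
                                     context=_random_context(rng, ref[0]),
                                     homopolymer=homopolymer, timing=timing))
        return recs

    variants.extend(place_background(int(rng.poisson(exp_snvs)), indel=False))
    indels.extend(place_background(int(rng.poisson(exp_indels)), indel=True))

    variants.sort(key=lambda v: (v.chrom, v.pos))
    indels.sort(key=lambda v: (v.chrom, v.pos))
    seg_sorted = sorted(segments, key=lambda s: (s.interval.chrom, s.interval.start))
    ploidy = sum(s.total * s.interval.length for s in seg_sorted) / sum(
        s.interval.length for s in seg_sorted)
    return TruthSet(config=config, ploidy=ploidy, variants=variants,
                    indels=indels, junctions=junctions, segments=seg_sorted,
                    events=events)


# ---------------------------------------------------------------------------
# caller simulation


def _emit_variant(rng, truth: TruthSet, v: TruthVariant, sens: float,
                  caller: str) -> VariantRecord | None:
    if rng.random() >= sens:
        return None
    cfg = truth.config
    depth_mean = cfg.coverage * (cfg.purity * v.total_cn + (1 - cfg.purity) * 2) / (
        cfg.purity * truth.ploidy + (1 - cfg.purity) * 2)
    depth = int(rng.poisson(max(depth_mean, 1.0)))
    if depth == 0:
        depth = 1
    alt = int(rng.binomial(depth, min(truth.tumour_vaf(v), 1.0)))
    if alt == 0:
        alt = 1  # a caller never reports a variant with zero alt reads
    return VariantRecord(v.chrom, v.pos, v.ref, v.alt, alt_count=alt,
                         depth=depth, callers=(caller,), truth_label=True)


def _false_positives(rng, cfg: TumourConfig, rate_per_mb: float, caller: str,
                     indel: bool,
                     homopolymer_map: dict | None = None) -> list[VariantRecord]:
    n = int(rng.poisson(rate_per_mb * cfg.genome_length / 1e6))
    out = []
    chroms = list(cfg.chromosome_lengths.items())
    for _ in range(n):
        chrom, length = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1, length))
        vaf = rng.uniform(0.02, 0.15)
        depth = max(1, int(rng.poisson(cfg.coverage)))
        alt = min(depth, max(1, int(rng.binomial(depth, vaf))))
        ref = str(rng.choice(_BASES))
        if indel:
            unit = str(rng.choice(_BASES))
            if rng.random() < 0.5:
                alt_allele = ref + unit
            else:
                ref, alt_allele = ref + unit, ref
        else:
            alt_allele = str(rng.choice(_BASES[_BASES != ref]))
        rec = VariantRecord(chrom, pos, ref, alt_allele, alt_count=alt,
                            depth=depth, callers=(caller,),
                            truth_label=False)
        if indel and homopolymer_map is not None:
            # slippage artefacts concentrate in homopolymer runs
            homopolymer_map.setdefault(rec.key, rng.random() < 0.7)
        out.append(rec)
    return out


def simulate_caller_outputs(truth: TruthSet, profiles: Sequence[CallerProfile],
                            seed: int | None = None) -> dict:
    """Noisy per-caller call sets: dict name -> {snvs, indels, junctions}.

    Each caller detects a true variant independently with probability
    ``sens(expected VAF)``, reporting its own binomial read counts; false
    positives are added at the profile's rate with VAF ~ U(0.02, 0.15);
    junction breakends get Gaussian positional jitter.
    """
    if not profiles:
        raise ValueError("at least one caller profile required")
    rng = np.random.default_rng(
        truth.config.seed + 104729 if seed is None else seed)
    out = {}
    homopolymer_map = {v.key: v.homopolymer for v in truth.indels}
    for prof in profiles:
        snvs, inds, juncs = [], [], []
        for v in truth.variants:
            rec = _emit_variant(rng, truth, v,
                                prof.sens(truth.tumour_vaf(v)), prof.name)
            if rec is not None:
                snvs.append(rec)
        for v in truth.indels:
            s = prof.indel_sens(truth.tumour_vaf(v), v.homopolymer)
            rec = _emit_variant(rng, truth, v, s, prof.name)
            if rec is not None:
                inds.append(rec)
        snvs.extend(_false_positives(rng, truth.config, prof.fp_per_mb,
                                     prof.name, indel=False))
        inds.extend(_false_positives(rng, truth.config, prof.indel_fp_per_mb,
                                     prof.name, indel=True,
                                     homopolymer_map=homopolymer_map))
        for j in truth.junctions:
            if rng.random() >= prof.junction_sensitivity:
                continue
            if prof.jitter_sd > 0:
                da, db = rng.normal(0, prof.jitter_sd, size=2)
            else:
                da = db = 0.0
            try:
                juncs.append(JunctionRecord(
                    j.chrom_a, max(0, j.pos_a + int(round(da))), j.strand_a,
                    j.chrom_b, max(0, j.pos_b + int(round(db))), j.strand_b,
                    sv_class=j.sv_class, callers=(prof.name,), name=j.name))
            except ValueError:
                continue  # jitter collapsed the junction below SV size
        snvs.sort(key=lambda r: (r.chrom, r.pos))
        inds.sort(key=lambda r: (r.chrom, r.pos))
        out[prof.name] = {"snvs": snvs, "indels": inds, "junctions": juncs,
                          "homopolymer": homopolymer_map}
    return out


def simulate_cohort_burdens(ages: Sequence[float], seed: int,
                            snvs_per_year: float = SNVS_PER_YEAR
                            ) -> np.ndarray:
    """Poisson SNV burdens for a cohort with a linear age slope; used to
    exercise burden-vs-age regression without full genome simulation."""
    rng = np.random.default_rng(seed)
    lam = snvs_per_year * np.asarray(ages, dtype=float)
    return rng.poisson(lam).astype(float)
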