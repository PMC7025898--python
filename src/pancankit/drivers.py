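"""Rank-and-cut driver assignment and biallelic-inactivation calling.

Not every point mutation in a recurrently mutated element is a driver.
The rank-and-cut approach orders the mutations observed in an element by
a weighted score of recurrence, functional consequence and a positional
(hotspot) prior, estimates the excess of observed mutations over the
neutral background expectation, and labels exactly that many of the
top-ranked mutations as probable drivers; the rest are probable
passengers.

The element catalogue merges de novo discovered elements with previously
known cancer genes (which rescues real drivers that a cohort is
underpowered to rediscover). Biallelic inactivation of tumour
suppressors is classified from the combination of somatic point drivers,
allele-specific copy number, gene-disrupting junctions and germline
protein-truncating variants.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval, JunctionRecord, SegmentRecord

__all__ = [
    "DriverElement",
    "MutationRankEntry",
    "rank_mutations",
    "rank_and_cut",
    "compile_compendium",
    "classify_biallelic",
    "summarize_driver_panorama",
    "round_half_away",
]

ELEMENT_TYPES = ("coding", "promoter", "enhancer", "UTR")
BIALLELIC_STATUSES = ("none", "point+deletion", "point+point",
                      "germline+somatic", "SV-mediated", "unknown")


def round_half_away(x: float) -> int:
    """Round to nearest integer with halves away from zero (printed-ratio
    convention; Python's round() would go to even)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class DriverElement:
    """One element of the driver compendium."""

    identifier: str
    intervals: tuple
    element_type: str = "coding"
    known_cancer_gene: bool = False
    background_rate: float = 0.0  # expected neutral mutations per base per sample
    provenance: str = "discovery"  # discovery | known | both

    def __post_init__(self):
        if self.element_type not in ELEMENT_TYPES:
            raise ValueError(f"unknown element type {self.element_type!r}")
        if self.background_rate < 0:
            raise ValueError("background rate must be >= 0")
        ivs = sorted(self.intervals, key=lambda i: (i.chrom, i.start))
        for a, b in zip(ivs, ivs[1:]):
            if a.overlaps(b):
                raise ValueError(f"element intervals overlap: {a} / {b}")
        object.__setattr__(self, "intervals", tuple(ivs))

    @property
    def length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        return any(iv.chrom == chrom and iv.start <= pos < iv.end
                   for iv in self.intervals)

    def expected_mutations(self, cohort_size: int) -> float:
        """Background expectation: rate x element length x cohort size."""
        return self.background_rate * self.length * cohort_size


@dataclass
class MutationRankEntry:
    """One distinct mutation within an element, with its ranking score."""

    key: tuple  # (chrom, pos, ref, alt)
    recurrence: int
    functional_score: float
    positional_prior: float
    score: float
    rank: int


def rank_mutations(element: DriverElement, cohort_mutations: Sequence,
                   weights: tuple[float, float, float] = (1.0, 1.0, 0.5),
                   positional_prior: Mapping[tuple, float] | None = None
                   ) -> list[MutationRankEntry]:
    """Rank the distinct mutations observed in an element.

    ``cohort_mutations`` are records with ``.key`` and a
    ``functional_score`` attribute (or dict entries); recurrence is the
    number of cohort occurrences of the identical key. The score is
    ``w_r * log2(1 + recurrence) + w_f * functional + w_p * prior``;
    ties break deterministically by genomic position.
    """
    by_key: dict[tuple, list] = {}
    for m in cohort_mutations:
        key = m.key if hasattr(m, "key") else tuple(m["key"])
        chrom, pos = key[0], key[1]
        if not element.contains(chrom, pos - 1):
            raise ValueError(
                f"mutation {key} lies outside element {element.identifier}")
        by_key.setdefault(key, []).append(m)
    w_rec, w_fun, w_pos = weights
    entries = []
    for key, members in by_key.items():
        fscores = [getattr(m, "functional_score", None) if hasattr(m, "functional_score")
                   else m.get("functional_score") for m in members]
        fscores = [f for f in fscores if f is not None]
        fun = float(np.mean(fscores)) if fscores else 0.5
        if not 0 <= fun <= 1:
            raise ValueError(f"functional score {fun} outside [0,1]")
        prior = float(positional_prior.get(key, 0.0)) if positional_prior else 0.0
        score = (w_rec * math.log2(1 + len(members)) + w_fun * fun
                 + w_pos * prior)
        entries.append(MutationRankEntry(key=key, recurrence=len(members),
                                         functional_score=fun,
                                         positional_prior=prior,
                                         score=score, rank=0))
    entries.sort(key=lambda e: (-e.score, e.key))
    for i, e in enumerate(entries):
        e.rank = i + 1
    return entries


def rank_and_cut(element: DriverElement, ranked: Sequence[MutationRankEntry],
                 observed_count: int, expected: float | None = None,
                 cohort_size: int = 1) -> dict[tuple, str]:
    """Label mutations driver/passenger by excess over background.

    excess = max(0, round(observed - E)) with halves rounding up; the top
    ``excess`` ranked mutation keys become ``driver`` (recurrent keys count
    once but absorb all their occurrences), the rest ``passenger``.
    """
    E = element.expected_mutations(cohort_size) if expected is None else expected
    if E < 0:
        raise ValueError("background expectation must be >= 0")
    excess = max(0, round_half_away(observed_count - E))
    labels: dict[tuple, str] = {}
    assigned = 0
    for entry in sorted(ranked, key=lambda e: e.rank):
        if assigned < excess:
            labels[entry.key] = "driver"
            assigned += entry.recurrence
        else:
            labels[entry.key] = "passenger"
    return labels


def compile_compendium(discovered: Sequence[DriverElement],
                       known: Sequence[DriverElement]) -> list[DriverElement]:
    """Union of discovered and previously known elements.

    Duplicated identifiers merge, keeping the wider interval set and
    marking provenance ``both``; conflicting element types are an error.
    """
    merged: dict[str, DriverElement] = {}
    for el in discovered:
        merged[el.identifier] = DriverElement(
            el.identifier, el.intervals, el.element_type,
            el.known_cancer_gene, el.background_rate, "discovery")
    for el in known:
        if el.identifier in merged:
            prev = merged[el.identifier]
            if prev.element_type != el.element_type:
                raise ValueError(
                    f"conflicting element types for {el.identifier}: "
                    f"{prev.element_type} vs {el.element_type}")
            wider = prev.intervals if prev.length >= el.length else el.intervals
            merged[el.identifier] = DriverElement(
                el.identifier, wider, el.element_type, True,
                max(prev.background_rate, el.background_rate), "both")
        else:
            merged[el.identifier] = DriverElement(
                el.identifier, el.intervals, el.element_type, True,
                el.background_rate, "known")
    return sorted(merged.values(), key=lambda e: e.identifier)


def classify_biallelic(gene: DriverElement,
                       point_drivers: Sequence,
                       segments: Sequence[SegmentRecord],
                       junctions: Sequence[JunctionRecord] = (),
                       germline_ptvs: Sequence = ()) -> str:
    """Biallelic inactivation status of one gene in one tumour.

    Order of precedence: germline PTV plus any somatic hit; somatic point
    driver plus deletion of the other allele (minor CN = 0 over the
    gene); two somatic point drivers; gene-disrupting junction plus any
    other hit; otherwise none. Returns ``unknown`` when the gene is not
    covered by any segment.
    """
    points = list(point_drivers)
    covering = [s for s in segments
                if any(iv.overlaps(s.interval) for iv in gene.intervals)]
    if not covering:
        return "unknown"
    minor_zero = all(s.minor == 0 for s in covering) and bool(covering)
    disrupting = [
        j for j in junctions
        if any(gene.contains(chrom, pos) for chrom, pos, _ in j.breakends)
    ]
    n_points = len({(p.key if hasattr(p, "key") else tuple(p)) for p in points})
    somatic_hits = n_points + len(disrupting) + (1 if minor_zero else 0)
    if list(germline_ptvs) and somatic_hits >= 1:
        return "germline+somatic"
    if n_points >= 1 and minor_zero:
        return "point+deletion"
    if n_points >= 2:
        return "point+point"
    if disrupting and (n_points >= 1 or minor_zero):
        return "SV-mediated"
    return "none"


def summarize_driver_panorama(assignments: pd.DataFrame) -> dict:
    """Cohort-level driver summary.

    ``assignments`` has one row per (tumour, element, variant) with
    columns ``tumour``, ``variant_class`` in {coding point, non-coding
    point, CNA, SV, germline}, ``is_driver`` (bool) and optionally
    ``biallelic`` (status string) and ``gene``. Percentages use
    half-away-from-zero rounding, matching how cohort ratios are printed.
    """
    if assignments.empty:
        raise ValueError("no assignments supplied")
    df = assignments.copy()
    drivers = df[df["is_driver"]]
    tumours = df["tumour"].unique()
    n_tumours = len(tumours)
    with_driver = drivers["tumour"].nunique()
    per_tumour = drivers.groupby("tumour").size()
    per_class = {}
    for cls, grp in drivers.groupby("variant_class"):
        counts = grp.groupby("tumour").size()
        per_class[cls] = {"mean": float(counts.mean()),
                          "sd": float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
                          "n_tumours": int(len(counts))}
    point = drivers[drivers["variant_class"].isin(["coding point",
                                                   "non-coding point"])]
    n_point = len(point)
    n_noncoding = int((point["variant_class"] == "non-coding point").sum())
    summary = {
        "n_tumours": n_tumours,
        "fraction_with_driver_pct": round_half_away(
            100 * with_driver / n_tumours),
        "mean_drivers_per_tumour": float(per_tumour.mean()) if len(per_tumour)
        else 0.0,
        "per_class": per_class,
        "n_driver_points": n_point,
        "noncoding_point_pct": (round_half_away(100 * n_noncoding / n_point)
                                if n_point else None),
    }
    if "biallelic" in df.columns and "gene" in df.columns:
        biallelic = {}
        for gene, grp in df[df["biallelic"].notna()].groupby("gene"):
            tum = grp.drop_duplicates("tumour")
            n_with = int((tum["biallelic"] != "none").sum())
            n_tot = len(tum)
            sub = tum[tum["biallelic"] != "none"]
            n_pd = int((sub["biallelic"] == "point+deletion").sum())
            biallelic[gene] = {
                "n_mutated": n_tot,
                "n_biallelic": n_with,
                "biallelic_pct": round_half_away(100 * n_with / n_tot),
                "point_deletion_pct": (round_half_away(100 * n_pd / n_with)
                                       if n_with else None),
            }
        summary["biallelic_by_gene"] = biallelic
    return summary
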