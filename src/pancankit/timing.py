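"""Molecular timing: placing mutations and clustered events into epochs.

Two molecular clocks order events in a tumour's life history. The
clonal/subclonal transition separates mutations that predate the most
recent common ancestor of the tumour cell population (clonal, CCF ~ 1)
from later ones confined to a subclone. Inside copy-number gains, the
multiplicity of a clonal mutation splits clonal time further: a mutation
on >= 2 copies must have preceded the gain that duplicated it (early),
one on a single copy arose after (late).

The cancer cell fraction is estimated from the variant allele fraction
by inverting VAF = rho * m * CCF / (rho * n_t + 2 (1 - rho)), with the
binomial uncertainty on VAF propagated to a CCF interval.

Clustered events (kataegis, chromothripsis, chromoplexy) inherit the
majority epoch of their member mutations, and their enrichment toward an
epoch is summarised as relative odds against the genome-wide background
with a percentile bootstrap over events.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .io_formats import SegmentRecord

__all__ = [
    "TimingCall",
    "OddsSummary",
    "estimate_multiplicity",
    "classify_clonality",
    "classify_gain_timing",
    "clustered_event_odds",
    "time_amplification",
]


@dataclass
class TimingCall:
    """CCF/multiplicity estimate and epoch for one variant."""

    key: tuple
    ccf: float
    ccf_ci: tuple
    multiplicity: int
    major: int
    minor: int
    clipped: bool = False
    epoch: str = "clonal-unspecified"  # clonal-early | clonal-late |
    # clonal-unspecified | subclonal


@dataclass
class OddsSummary:
    """Relative odds of an event class being clonal vs subclonal."""

    event_class: str
    odds: float
    ci: tuple
    n_events: int
    n_boot: int
    corrected: bool = False

    def __post_init__(self):
        lo, hi = self.ci
        if not lo <= hi:
            raise ValueError("invalid bootstrap CI")


def estimate_multiplicity(variant, purity: float, segment: SegmentRecord,
                          ci_level: float = 0.95) -> TimingCall:
    """Integer multiplicity and CCF from read counts.

    m = clamp(round(VAF / rho * (rho * n_t + 2 (1 - rho))), 1, major);
    CCF = VAF * (rho * n_t + 2 (1 - rho)) / (rho * m). CCF > 1 (sampling
    noise) is clipped and flagged rather than rejected. The binomial
    Clopper-Pearson interval on VAF is propagated linearly to CCF.
    """
    if purity <= 0:
        raise ValueError("purity must be positive")
    if variant.depth <= 0:
        raise ValueError("variant depth must be positive")
    if not segment.contains(variant.chrom, variant.pos - 1) \
            and not segment.contains(variant.chrom, variant.pos):
        raise ValueError(f"segment does not cover {variant.chrom}:{variant.pos}")
    n_t = segment.total
    vaf = variant.alt_count / variant.depth
    denom = purity * n_t + 2 * (1 - purity)
    raw_m = vaf / purity * denom
    m = int(np.clip(round(raw_m), 1, max(segment.major, 1)))
    ccf = vaf * denom / (purity * m)
    lo, hi = proportion_confint(variant.alt_count, variant.depth,
                                alpha=1 - ci_level, method="beta")
    ccf_lo = lo * denom / (purity * m)
    ccf_hi = hi * denom / (purity * m)
    clipped = ccf > 1
    return TimingCall(key=variant.key, ccf=min(ccf, 1.0) if clipped else ccf,
                      ccf_ci=(ccf_lo, ccf_hi), multiplicity=m,
                      major=segment.major, minor=segment.minor,
                      clipped=clipped)


def classify_clonality(call: TimingCall, ccf_threshold: float = 0.9) -> str:
    """Clonal when the data cannot exclude CCF = 1 (interval upper bound
    reaches 1) or the point estimate is >= 0.9; otherwise subclonal."""
    clonal = call.ccf_ci[1] >= 1.0 or call.ccf >= ccf_threshold
    call.epoch = "clonal-unspecified" if clonal else "subclonal"
    return "clonal" if clonal else "subclonal"


def classify_gain_timing(call: TimingCall, segment: SegmentRecord) -> str:
    """Early/late placement of a clonal mutation relative to a gain.

    In gained regions (major >= 2) a duplicated mutation (m >= 2) must
    precede the gain; m = 1 means it followed. Without a gain the clock
    has no second hand: not-timeable.
    """
    if call.epoch == "subclonal":
        raise ValueError("gain timing is defined only for clonal mutations")
    if segment.major < 2:
        call.epoch = "clonal-unspecified"
        return "not-timeable"
    if call.multiplicity >= 2:
        call.epoch = "clonal-early"
        return "early"
    call.epoch = "clonal-late"
    return "late"


def _odds(a: float, b: float, c: float, d: float) -> tuple[float, bool]:
    """(a/b) / (c/d) with Haldane +0.5 correction when any cell is zero."""
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a / b) / (c / d), corrected


def clustered_event_odds(event_epochs: Sequence[str],
                         background_epochs: Sequence[str],
                         event_class: str = "clustered",
                         n_boot: int = 1000, seed: int = 0,
                         ci_level: float = 0.95) -> OddsSummary:
    """Relative odds that events of a class are clonal rather than subclonal.

    ``event_epochs`` holds one majority epoch per clustered event (any
    label starting with ``clonal`` counts as clonal);
    ``background_epochs`` the epochs of all mutations, defining the
    baseline. Odds = (clonal_e / subclonal_e) / (clonal_bg / subclonal_bg)
    with Haldane correction for empty cells; the CI is a seeded
    percentile bootstrap resampling events with replacement.
    """
    events = ["clonal" if e.startswith("clonal") else "subclonal"
              for e in event_epochs]
    if not events:
        raise ValueError("no events supplied")
    bg = ["clonal" if e.startswith("clonal") else "subclonal"
          for e in background_epochs]
    if not bg:
        raise ValueError("no background mutations supplied")
    c_bg = bg.count("clonal")
    s_bg = len(bg) - c_bg
    c_e = events.count("clonal")
    s_e = len(events) - c_e
    point, corrected = _odds(c_e, s_e, c_bg, s_bg)
    rng = np.random.default_rng(seed)
    is_clonal = np.array([e == "clonal" for e in events])
    boots = np.empty(n_boot)
    for i in range(n_boot):
        sample = rng.integers(0, len(events), size=len(events))
        ce = int(is_clonal[sample].sum())
        boots[i], _ = _odds(ce, len(events) - ce, c_bg, s_bg)
    alpha = 1 - ci_level
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return OddsSummary(event_class=event_class, odds=point,
                       ci=(float(lo), float(hi)), n_events=len(events),
                       n_boot=n_boot, corrected=corrected)


def time_amplification(segment: SegmentRecord, timing_calls: Sequence[TimingCall],
                       early_threshold_per_mb: float = 5.0,
                       noise_fraction: float = 0.05,
                       alpha: float = 0.05) -> dict:
    """Time a high-level amplification from mutation multiplicities.

    Mutations at the maximum copy number predate the amplification (they
    rode along on every doubling); single-copy mutations follow it. An
    amplification preceded by few mutations happened early in the
    tumour's life; one preceded by hundreds happened late. A surplus of
    mutations at intermediate copy numbers — beyond the ``noise_fraction``
    expected from multiplicity misassignment — indicates mutations that
    accumulated while the amplification was ongoing.
    """
    if segment.total < 4:
        raise ValueError(
            f"not an amplification: total CN {segment.total} < 4")
    max_m = segment.major
    n_pre = sum(1 for c in timing_calls if c.multiplicity >= max_m)
    n_post = sum(1 for c in timing_calls if c.multiplicity == 1)
    n_int = sum(1 for c in timing_calls if 1 < c.multiplicity < max_m)
    mb = segment.interval.length / 1e6
    verdict = "early" if n_pre / mb <= early_threshold_per_mb else "late"
    n_total = n_pre + n_post + n_int
    if n_int > 0 and n_total > 0:
        p_excess = float(stats.binom.sf(n_int - 1, n_total, noise_fraction))
        excess = p_excess < alpha
    else:
        p_excess, excess = 1.0, False
    return {
        "verdict": verdict,
        "n_pre_amplification": n_pre,
        "n_post_amplification": n_post,
        "n_intermediate": n_int,
        "intermediate_excess": excess,
        "intermediate_excess_p": p_excess,
        "pre_per_mb": n_pre / mb,
    }
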