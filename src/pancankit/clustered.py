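"""Detection and categorisation of clustered mutational processes.

Three catastrophic processes leave recognisable footprints in a tumour
genome:

* **kataegis** — focal, strand-coordinated hypermutation: runs of >= 6
  consecutive substitutions with successive gaps <= 1 kb, typically C>N
  in a TpC context (APOBEC deamination), often within a kilobase of an
  SV breakend;
* **chromothripsis** — a one-off shattering of one or a few chromosomes:
  >= 10 clustered breakends whose fragments are stitched back together
  in near-random order, with total copy number oscillating between two
  (or three) states;
* **chromoplexy** — chains of co-occurring balanced translocations
  across several chromosomes, joined through short deletion bridges,
  forming closed cycles of >= 3 junctions.

Each detector is paired with a cross-sample recurrence scan (hotspots of
kataegis foci, recurrent chromoplexy footprints).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .io_formats import GenomicInterval, JunctionRecord, SegmentRecord

__all__ = [
    "KataegisFocus",
    "ChromothripsisRegion",
    "ChromoplexyChain",
    "detect_kataegis",
    "classify_kataegis",
    "associate_with_junctions",
    "find_kataegis_hotspots",
    "detect_chromothripsis",
    "detect_chromoplexy",
    "find_chromoplexy_hotspots",
]

KATAEGIS_MIN_MEMBERS = 6
KATAEGIS_MAX_GAP = 1000
PYRIMIDINES = {"C", "T"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class KataegisFocus:
    """A maximal run of closely spaced substitutions in one sample."""

    interval: GenomicInterval
    members: list  # records with chrom/pos/ref/alt (1-based pos)
    strand_coordination: float
    kataegis_class: str = "other"
    nearest_junction_distance: float = float("inf")
    sample: str | None = None

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def midpoint(self) -> int:
        return (self.interval.start + self.interval.end) // 2


@dataclass
class ChromothripsisRegion:
    """A shattered region with its five-characteristic categorisation.

    The characteristics vector is this package's concrete rendering of a
    multi-feature categorisation: multichromosomal involvement,
    amplification, homozygous deletion, telomere adjacency and mean
    interbreakpoint distance below 10 kb.
    """

    intervals: list
    breakend_count: int
    oscillation_states: int
    dominant_state_fraction: float
    chromosomes: list
    characteristics: dict
    mean_interbreakpoint_distance: float
    junction_type_pvalue: float
    sample: str | None = None


@dataclass
class ChromoplexyChain:
    """A closed cycle of balanced rearrangements across chromosomes."""

    junctions: list
    chromosomes: list
    footprints: list  # GenomicInterval per breakend cluster
    balanced: bool = True
    kind: str = "chromoplexy"  # chromoplexy | balanced-translocation
    sample: str | None = None

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)


# ---------------------------------------------------------------------------
# kataegis


def detect_kataegis(snvs: Sequence, min_members: int = KATAEGIS_MIN_MEMBERS,
                    max_gap: int = KATAEGIS_MAX_GAP,
                    sample: str | None = None) -> list[KataegisFocus]:
    """Maximal runs of >= ``min_members`` SNVs with gaps <= ``max_gap``.

    ``snvs`` need ``chrom``, ``pos`` (1-based), ``ref``, ``alt``. Strand
    coordination is the fraction of members on the majority strand,
    orienting each substitution by its pyrimidine context (ref C or T =
    one strand, ref G or A = the other).
    """
    recs = sorted(snvs, key=lambda v: (v.chrom, v.pos))
    foci = []
    run: list = []

    def flush(run):
        if len(run) >= min_members:
            pyr = sum(1 for v in run if v.ref[0].upper() in PYRIMIDINES)
            coord = max(pyr, len(run) - pyr) / len(run)
            iv = GenomicInterval(run[0].chrom, run[0].pos - 1, run[-1].pos)
            foci.append(KataegisFocus(interval=iv, members=list(run),
                                      strand_coordination=coord,
                                      sample=sample))

    for v in recs:
        if len(v.ref) != 1 or len(v.alt) != 1:
            continue
        if run and (v.chrom != run[-1].chrom or v.pos - run[-1].pos > max_gap):
            flush(run)
            run = []
        run.append(v)
    flush(run)
    return foci


def _pyrimidine_view(ref: str, alt: str, context: str) -> tuple[str, str, str]:
    """Orient a substitution so the reference base is a pyrimidine."""
    if ref.upper() in PYRIMIDINES:
        return ref.upper(), alt.upper(), context.upper()
    return (ref.upper().translate(_COMPLEMENT),
            alt.upper().translate(_COMPLEMENT),
            context.upper().translate(_COMPLEMENT)[::-1])


def classify_kataegis(focus: KataegisFocus,
                      contexts: dict | None = None,
                      majority: float = 0.6) -> str:
    """Assign a mutational-process class to a focus by context majority.

    >= 60% of members C>N in TpC context -> ``APOBEC-TpC`` (cytidine
    deamination); >= 60% T>N at CpT/TpT -> ``TN-CpTpT`` (error-prone
    polymerases); >= 60% C>N at GpC/CpC -> ``alt-GpC/CpC``; otherwise
    ``other``. ``contexts`` optionally maps member key -> trinucleotide;
    members may instead carry a ``context`` attribute. Members without
    context are excluded; if none remain, an error is raised.
    """
    tallies = Counter()
    n_used = 0
    for m in focus.members:
        ctx = None
        if contexts is not None:
            ctx = contexts.get(getattr(m, "key", (m.chrom, m.pos, m.ref, m.alt)))
        if ctx is None:
            ctx = getattr(m, "context", None)
        if ctx is None or len(ctx) != 3:
            continue
        ref, _alt, ctx = _pyrimidine_view(m.ref[0], m.alt[0], ctx)
        n_used += 1
        five_prime = ctx[0]
        if ref == "C" and five_prime == "T":
            tallies["APOBEC-TpC"] += 1
        elif ref == "T" and five_prime in ("C", "T"):
            tallies["TN-CpTpT"] += 1
        elif ref == "C" and five_prime in ("G", "C"):
            tallies["alt-GpC/CpC"] += 1
    if n_used == 0:
        raise ValueError("no member has a usable trinucleotide context")
    for cls, count in tallies.most_common(1):
        if count / n_used >= majority:
            focus.kataegis_class = cls
            return cls
    focus.kataegis_class = "other"
    return "other"


def associate_with_junctions(foci: Sequence[KataegisFocus],
                             junctions: Sequence[JunctionRecord],
                             window: float = 1000.0) -> list[bool]:
    """Flag each focus that has an SV breakend within ``window`` bases."""
    flags = []
    for f in foci:
        near = float("inf")
        for j in junctions:
            for chrom, pos, _ in j.breakends:
                near = min(near, f.interval.distance_to(chrom, pos))
        f.nearest_junction_distance = near
        flags.append(near <= window)
    return flags


def _single_linkage_loci(points: list[tuple], max_distance: float,
                         min_count: int, distinct_samples: bool = True
                         ) -> list[dict]:
    """Cluster (chrom, pos, sample) points by single linkage along the
    genome; keep clusters with >= min_count points from distinct samples."""
    points = sorted(points)
    loci = []
    cluster: list = []

    def flush(cluster):
        if not cluster:
            return
        samples = {s for _, _, s in cluster}
        count = len(samples) if distinct_samples else len(cluster)
        if count >= min_count:
            loci.append({
                "chrom": cluster[0][0],
                "start": cluster[0][1],
                "end": cluster[-1][1],
                "n": len(cluster),
                "samples": sorted(samples),
            })

    for p in points:
        if cluster and (p[0] != cluster[-1][0]
                        or p[1] - cluster[-1][1] > max_distance):
            flush(cluster)
            cluster = []
        cluster.append(p)
    flush(cluster)
    return loci


def find_kataegis_hotspots(foci: Sequence[KataegisFocus],
                           max_distance: float = 1000.0,
                           min_foci: int = 3) -> list[dict]:
    """Loci where >= 3 foci from distinct samples fall within 1 kb."""
    points = [(f.interval.chrom, f.midpoint, f.sample) for f in foci]
    return _single_linkage_loci(points, max_distance, min_foci,
                                distinct_samples=True)


# ---------------------------------------------------------------------------
# chromothripsis


def _breakend_clusters(positions: list[int], max_gap: int) -> list[list[int]]:
    clusters, cur = [], []
    for p in sorted(positions):
        if cur and p - cur[-1] > max_gap:
            clusters.append(cur)
            cur = []
        cur.append(p)
    if cur:
        clusters.append(cur)
    return clusters


def detect_chromothripsis(segments: Sequence[SegmentRecord],
                          junctions: Sequence[JunctionRecord],
                          min_breakends: int = 10,
                          cluster_gap: int = 100_000,
                          min_dominant_fraction: float = 0.5,
                          uniformity_alpha: float = 0.05,
                          telomere_margin: int = 5_000_000,
                          chrom_lengths: dict | None = None,
                          sample: str | None = None
                          ) -> list[ChromothripsisRegion]:
    """Find shattered regions on each chromosome.

    A candidate region is a cluster of >= ``min_breakends`` junction
    breakends (single linkage, gap <= ``cluster_gap``). It is called
    chromothripsis when (a) total copy number over the region oscillates,
    with the two dominant CN states covering >= 50% of segments, and (b)
    the junction-type proportions are compatible with random stitching
    (chi-square goodness of fit against uniform, p > 0.05).
    """
    if not segments:
        raise ValueError("no copy-number segments supplied")
    by_chrom_be: dict[str, list] = {}
    for j in junctions:
        for chrom, pos, _ in j.breakends:
            by_chrom_be.setdefault(chrom, []).append(pos)
    regions = []
    for chrom, positions in by_chrom_be.items():
        for cluster in _breakend_clusters(positions, cluster_gap):
            if len(cluster) < min_breakends:
                continue
            lo, hi = cluster[0], cluster[-1] + 1
            region_iv = GenomicInterval(chrom, lo, hi)
            segs = [s for s in segments if s.interval.overlaps(region_iv)]
            if len(segs) < 3:
                continue
            totals = [s.total for s in segs]
            state_counts = Counter(totals)
            dominant = state_counts.most_common(2)
            dom_frac = sum(c for _, c in dominant) / len(totals)
            if dom_frac < min_dominant_fraction or len(state_counts) < 2:
                continue
            # random-stitching signature: junction classes ~ uniform
            region_juncs = [
                j for j in junctions
                if any(c == chrom and lo <= p < hi for c, p, _ in j.breakends)
            ]
            classes = [j.sv_class for j in region_juncs
                       if j.chrom_a == j.chrom_b]
            if classes:
                counts = Counter(classes)
                observed = [counts.get(c, 0) for c in (
                    "deletion", "duplication", "inversion-head-to-head",
                    "inversion-tail-to-tail")]
                chi2, p_uniform = stats.chisquare(observed)
            else:
                p_uniform = 1.0
            if p_uniform <= uniformity_alpha:
                continue
            gaps = np.diff(sorted(cluster))
            mean_ibd = float(np.mean(gaps)) if len(gaps) else float("inf")
            chroms_involved = sorted({c for j in region_juncs
                                      for c, _, _ in j.breakends})
            telomere_adjacent = lo <= telomere_margin
            if chrom_lengths and chrom in chrom_lengths:
                telomere_adjacent |= hi >= chrom_lengths[chrom] - telomere_margin
            characteristics = {
                "multichromosomal": len(chroms_involved) > 1,
                "amplification": any(s.total >= 5 for s in segs),
                "homozygous_deletion": any(s.total == 0 for s in segs),
                "telomere_adjacent": telomere_adjacent,
                "interbreakpoint_lt_10kb": mean_ibd < 10_000,
            }
            regions.append(ChromothripsisRegion(
                intervals=[region_iv], breakend_count=len(cluster),
                oscillation_states=len(state_counts),
                dominant_state_fraction=dom_frac,
                chromosomes=chroms_involved,
                characteristics=characteristics,
                mean_interbreakpoint_distance=mean_ibd,
                junction_type_pvalue=float(p_uniform), sample=sample))
    return regions


# ---------------------------------------------------------------------------
# chromoplexy


def detect_chromoplexy(junctions: Sequence[JunctionRecord],
                       bridge_limit: int = 10_000,
                       sample: str | None = None) -> list[ChromoplexyChain]:
    """Chains of rearrangements joined through short bridges.

    Breakends on one chromosome within ``bridge_limit`` of each other are
    clustered into footprints; junctions become edges between footprint
    nodes. Cycles of >= 3 junction edges spanning >= 2 chromosomes are
    chromoplexy chains; pairs of parallel edges between two footprints
    with opposite orientations at both ends are balanced translocations.
    """
    junctions = list(junctions)
    # footprint clustering per chromosome
    be_list = []  # (chrom, pos, junction index, end index)
    for i, j in enumerate(junctions):
        for e, (chrom, pos, _) in enumerate(j.breakends):
            be_list.append((chrom, pos, i, e))
    be_list.sort()
    node_of = {}
    footprints = {}  # node id -> (chrom, min pos, max pos)
    node = -1
    prev = None
    for chrom, pos, i, e in be_list:
        if prev is None or chrom != prev[0] or pos - prev[1] > bridge_limit:
            node += 1
            footprints[node] = [chrom, pos, pos]
        footprints[node][2] = pos
        node_of[(i, e)] = node
        prev = (chrom, pos)

    graph = nx.MultiGraph()
    graph.add_nodes_from(footprints)
    for i, j in enumerate(junctions):
        graph.add_edge(node_of[(i, 0)], node_of[(i, 1)], junction=i)

    chains = []
    used = set()

    def footprint_ivs(nodes):
        return [GenomicInterval(footprints[n][0], footprints[n][1],
                                footprints[n][2] + 1) for n in sorted(nodes)]

    # balanced translocation pairs: parallel interchromosomal edges with
    # opposite orientations at both ends
    pair_edges: dict[tuple, list] = {}
    for u, v, d in graph.edges(data=True):
        if u == v:
            continue
        pair_edges.setdefault(tuple(sorted((u, v))), []).append(d["junction"])
    for (u, v), idxs in pair_edges.items():
        if len(idxs) < 2:
            continue
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                ja, jb = junctions[idxs[a]], junctions[idxs[b]]
                if idxs[a] in used or idxs[b] in used:
                    continue
                if ja.chrom_a == ja.chrom_b:
                    continue
                (_, _, sa1), (_, _, sa2) = ja.key
                (_, _, sb1), (_, _, sb2) = jb.key
                if sa1 != sb1 and sa2 != sb2:
                    used.update((idxs[a], idxs[b]))
                    nodes = {u, v}
                    chains.append(ChromoplexyChain(
                        junctions=[ja, jb],
                        chromosomes=sorted({ja.chrom_a, ja.chrom_b}),
                        footprints=footprint_ivs(nodes),
                        balanced=True, kind="balanced-translocation",
                        sample=sample))

    # cycles of >= 3 junctions over >= 2 chromosomes
    simple = nx.Graph()
    simple.add_nodes_from(graph.nodes)
    for u, v, d in graph.edges(data=True):
        if u != v and d["junction"] not in used:
            if not simple.has_edge(u, v):
                simple.add_edge(u, v, junction=d["junction"])
    for cycle_nodes in nx.cycle_basis(simple):
        if len(cycle_nodes) < 3:
            continue
        cyc_junctions = []
        ok = True
        ring = list(cycle_nodes) + [cycle_nodes[0]]
        for u, v in zip(ring, ring[1:]):
            data = simple.get_edge_data(u, v)
            if data is None:
                ok = False
                break
            cyc_junctions.append(junctions[data["junction"]])
        if not ok:
            continue
        chroms = sorted({footprints[n][0] for n in cycle_nodes})
        if len(chroms) < 2:
            continue
        used.update(simple.get_edge_data(u, v)["junction"]
                    for u, v in zip(ring, ring[1:]))
        chains.append(ChromoplexyChain(
            junctions=cyc_junctions, chromosomes=chroms,
            footprints=footprint_ivs(cycle_nodes), balanced=True,
            kind="chromoplexy", sample=sample))
    return chains


def find_chromoplexy_hotspots(chains: Sequence[ChromoplexyChain],
                              max_distance: float = 10_000.0,
                              min_footprints: int = 2) -> list[dict]:
    """Loci where >= 2 chain footprints from distinct samples fall within
    10 kb of each other (single linkage)."""
    points = []
    for chain in chains:
        for fp in chain.footprints:
            points.append((fp.chrom, (fp.start + fp.end) // 2, chain.sample))
    return _single_linkage_loci(points, max_distance, min_footprints,
                                distinct_samples=True)
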