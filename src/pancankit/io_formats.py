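"""Readers and writers for the text dialects the pipeline exchanges.

Three tabular formats are supported:

* a minimal VCF-like dialect for SNVs/MNVs/indels (1-based positions,
  ``CHROM POS ID REF ALT QUAL FILTER INFO`` with INFO keys ``CALLERS``,
  ``TAL`` alt reads, ``TDP`` depth), plus an equivalent plain TSV;
* BEDPE for SV junctions (0-based half-open breakend intervals, strands
  in columns 9-10, optional class and caller columns);
* a five-column TSV for allele-specific copy-number segments.

Internally every coordinate is 0-based half-open; the VCF dialect is
converted on the way in and out. Chromosome names are normalised to the
bare hs37d5 style (no ``chr`` prefix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "VariantRecord",
    "JunctionRecord",
    "SegmentRecord",
    "ParseError",
    "normalize_chrom",
    "left_align_indel",
    "read_variants",
    "write_variants",
    "read_junctions",
    "write_junctions",
    "read_segments",
    "write_segments",
    "MIN_SV_SIZE",
]

#: Intrachromosomal junctions spanning no more than this many bases are
#: not structural variants and are rejected on input.
MIN_SV_SIZE = 100

VARIANT_CLASSES = ("SNV", "MNV", "insertion", "deletion")
JUNCTION_CLASSES = (
    "deletion",
    "duplication",
    "inversion-head-to-head",
    "inversion-tail-to-tail",
    "translocation",
)


class ParseError(ValueError):
    """Raised when an input line cannot be interpreted, naming the line."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


def normalize_chrom(chrom: str) -> str:
    """Strip a ``chr`` prefix; ``chrM`` becomes ``MT``."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if not c:
        raise ValueError(f"empty chromosome name {chrom!r}")
    return "MT" if c in ("M", "m") else c


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.start > self.end:
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to(self, chrom: str, pos: int) -> float:
        """Distance from a point to this interval; 0 if inside, inf off-chromosome."""
        if chrom != self.chrom:
            return float("inf")
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0.0


def _classify_alleles(ref: str, alt: str) -> str:
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNV"
    return "insertion" if len(ref) < len(alt) else "deletion"


@dataclass(frozen=True)
class VariantRecord:
    """One somatic SNV/MNV/indel with read support and caller provenance.

    ``pos`` is 1-based, matching the VCF convention in which the record
    is written; indel records include the padding base.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_count: int = 0
    depth: int = 0
    callers: frozenset = frozenset()
    truth_label: bool | None = None
    normalized: bool = True

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if not (0 <= self.alt_count <= self.depth):
            raise ValueError(
                f"alt count {self.alt_count} > depth {self.depth} "
                f"at {self.chrom}:{self.pos}"
            )
        object.__setattr__(self, "callers", frozenset(self.callers))

    @property
    def variant_class(self) -> str:
        return _classify_alleles(self.ref, self.alt)

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class JunctionRecord:
    """Two oriented breakends. Orientation ``+`` means the joined segment
    extends to lower coordinates (the breakend is a right end), ``-`` the
    opposite, matching BEDPE strand columns."""

    chrom_a: str
    pos_a: int
    strand_a: str
    chrom_b: str
    pos_b: int
    strand_b: str
    sv_class: str = ""
    callers: frozenset = frozenset()
    name: str = "."

    def __post_init__(self):
        for s in (self.strand_a, self.strand_b):
            if s not in "+-":
                raise ValueError(f"bad strand {s!r}")
        if (
            self.chrom_a == self.chrom_b
            and abs(self.pos_a - self.pos_b) <= MIN_SV_SIZE
        ):
            raise ValueError(
                f"intrachromosomal junction spans "
                f"{abs(self.pos_a - self.pos_b)} bp <= {MIN_SV_SIZE} bp"
            )
        object.__setattr__(self, "callers", frozenset(self.callers))
        if not self.sv_class:
            object.__setattr__(self, "sv_class", self.infer_class())

    def infer_class(self) -> str:
        if self.chrom_a != self.chrom_b:
            return "translocation"
        sa, sb = self.strand_a, self.strand_b
        if (sa, sb) == ("+", "-"):
            return "deletion"
        if (sa, sb) == ("-", "+"):
            return "duplication"
        if (sa, sb) == ("+", "+"):
            return "inversion-head-to-head"
        return "inversion-tail-to-tail"

    @property
    def breakends(self) -> tuple:
        return (
            (self.chrom_a, self.pos_a, self.strand_a),
            (self.chrom_b, self.pos_b, self.strand_b),
        )

    @property
    def key(self) -> tuple:
        return tuple(sorted(self.breakends))


@dataclass(frozen=True)
class SegmentRecord:
    """Allele-specific copy-number call over one interval."""

    interval: GenomicInterval
    major: int
    minor: int

    def __post_init__(self):
        if self.minor < 0 or self.major < self.minor:
            raise ValueError(
                f"require major >= minor >= 0, got ({self.major},{self.minor})"
            )

    @property
    def total(self) -> int:
        return self.major + self.minor

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    def contains(self, chrom: str, pos: int) -> bool:
        return (
            chrom == self.interval.chrom
            and self.interval.start <= pos < self.interval.end
        )


# ---------------------------------------------------------------------------
# indel left-normalisation


def left_align_indel(pos: int, ref: str, alt: str, ref_window: str,
                     window_start: int) -> tuple[int, str, str]:
    """Shift an indel to its leftmost equivalent placement.

    ``pos`` is the 1-based position of the padding base, ``ref_window`` a
    reference substring whose first base sits at 1-based ``window_start``.
    Standard VCF-style normalisation: while the final bases of ref and alt
    agree, drop them and prepend the preceding reference base.
    """
    if len(ref) == len(alt):
        return pos, ref, alt
    ref, alt = ref.upper(), alt.upper()
    window = ref_window.upper()
    while ref and alt and ref[-1] == alt[-1]:
        prev = pos - window_start - 1  # index of base preceding pos
        if (len(ref) == 1 or len(alt) == 1) and prev < 0:
            break  # window exhausted; cannot shift further left
        # trim shared trailing base, refilling from the reference on the left
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            base = window[prev]
            ref, alt = base + ref, base + alt
            pos -= 1
    # trim shared leading bases beyond the single padding base
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


# ---------------------------------------------------------------------------
# variants

_VCF_COLUMNS = ["CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]


def _split_callers(token: str) -> list[str]:
    """Caller provenance list: semicolon-separated in the TSV column,
    comma-separated inside VCF INFO (semicolons delimit INFO keys there);
    both separators are accepted on input."""
    return [c for c in token.replace(",", ";").split(";") if c and c != "."]


def _parse_info(info: str) -> dict:
    out = {}
    for token in info.split(";"):
        if not token or token == ".":
            continue
        if "=" in token:
            k, v = token.split("=", 1)
            out[k] = v
        else:
            out[token] = True
    return out


def read_variants(path, dialect: str = "vcf-like",
                  reference: dict[str, str] | None = None,
                  known_chroms: Iterable[str] | None = None
                  ) -> list[VariantRecord]:
    """Read variant records, returning them sorted by (chrom, pos).

    ``reference`` optionally maps chromosome -> sequence string (1-based
    origin); when given, indels are left-aligned against it, otherwise
    indel records are flagged ``normalized=False``.
    """
    if dialect not in ("vcf-like", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    known = {normalize_chrom(c) for c in known_chroms} if known_chroms else None
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "vcf-like":
                    if len(fields) < 8:
                        raise ValueError(f"expected 8 columns, got {len(fields)}")
                    chrom, pos, _id, ref, alt, _q, _f, info = fields[:8]
                    meta = _parse_info(info)
                    alt_count = int(meta.get("TAL", 0))
                    depth = int(meta.get("TDP", 0))
                    callers = [c for c in
                               _split_callers(str(meta.get("CALLERS", "")))]
                    truth = meta.get("TRUTH")
                else:
                    if len(fields) < 7:
                        raise ValueError(f"expected 7 columns, got {len(fields)}")
                    chrom, pos, ref, alt, alt_s, dp_s, callers_s = fields[:7]
                    alt_count, depth = int(alt_s), int(dp_s)
                    callers = _split_callers(callers_s)
                    truth = fields[7] if len(fields) > 7 else None
                chrom = normalize_chrom(chrom)
                if known is not None and chrom not in known:
                    raise ValueError(f"unknown chromosome {chrom!r}")
                pos_i, ref_u, alt_u = int(pos), ref.upper(), alt.upper()
                normalized = True
                if len(ref_u) != len(alt_u):
                    if reference is not None and chrom in reference:
                        seq = reference[chrom]
                        lo = max(1, pos_i - 200)
                        pos_i, ref_u, alt_u = left_align_indel(
                            pos_i, ref_u, alt_u, seq[lo - 1:pos_i + len(ref_u)], lo
                        )
                    else:
                        normalized = False
                rec = VariantRecord(
                    chrom=chrom, pos=pos_i, ref=ref_u, alt=alt_u,
                    alt_count=alt_count, depth=depth, callers=callers,
                    truth_label=(None if truth in (None, ".", "")
                                 else str(truth) in ("1", "True", "true")),
                    normalized=normalized,
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            records.append(rec)
    records.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    return records


def write_variants(path, records: Sequence[VariantRecord],
                   dialect: str = "vcf-like") -> None:
    with open(path, "w") as fh:
        if dialect == "vcf-like":
            fh.write("#" + "\t".join(_VCF_COLUMNS) + "\n")
            for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
                info = [f"CALLERS={','.join(sorted(r.callers))}",
                        f"TAL={r.alt_count}", f"TDP={r.depth}"]
                if r.truth_label is not None:
                    info.append(f"TRUTH={int(r.truth_label)}")
                fh.write("\t".join([r.chrom, str(r.pos), ".", r.ref, r.alt,
                                    ".", "PASS", ";".join(info)]) + "\n")
        elif dialect == "tsv":
            fh.write("#chrom\tpos\tref\talt\talt_count\tdepth\tcallers\ttruth\n")
            for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
                truth = "." if r.truth_label is None else str(int(r.truth_label))
                fh.write("\t".join([r.chrom, str(r.pos), r.ref, r.alt,
                                    str(r.alt_count), str(r.depth),
                                    ";".join(sorted(r.callers)) or ".",
                                    truth]) + "\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# junctions (BEDPE)


def read_junctions(path) -> list[JunctionRecord]:
    """Read a BEDPE-like file of SV junctions.

    Columns: chromA startA endA chromB startB endB name score strandA
    strandB [class] [callers]. Breakend position is taken as the start of
    each (typically 1-bp) interval. Intrachromosomal junctions spanning
    <= 100 bp are skipped with a warning: they are below the size at which
    a call counts as a structural variant.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ParseError(path, lineno,
                                 f"BEDPE needs >= 10 columns (strands missing), got {len(f)}")
            try:
                rec = JunctionRecord(
                    chrom_a=normalize_chrom(f[0]), pos_a=int(f[1]),
                    strand_a=f[8],
                    chrom_b=normalize_chrom(f[3]), pos_b=int(f[4]),
                    strand_b=f[9],
                    sv_class=f[10] if len(f) > 10 and f[10] != "." else "",
                    callers=[c for c in (f[11] if len(f) > 11 else "").split(";")
                             if c and c != "."],
                    name=f[6],
                )
            except ValueError as exc:
                if "intrachromosomal" in str(exc):
                    warnings.warn(f"{path}:{lineno}: skipping sub-{MIN_SV_SIZE}bp "
                                  f"junction ({exc})")
                    continue
                raise ParseError(path, lineno, str(exc)) from exc
            records.append(rec)
    return records


def write_junctions(path, records: Sequence[JunctionRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("#chromA\tstartA\tendA\tchromB\tstartB\tendB\t"
                 "name\tscore\tstrandA\tstrandB\tclass\tcallers\n")
        for r in records:
            fh.write("\t".join([
                r.chrom_a, str(r.pos_a), str(r.pos_a + 1),
                r.chrom_b, str(r.pos_b), str(r.pos_b + 1),
                r.name, ".", r.strand_a, r.strand_b,
                r.sv_class or ".", ";".join(sorted(r.callers)) or ".",
            ]) + "\n")


# ---------------------------------------------------------------------------
# copy-number segments


def read_segments(path) -> list[SegmentRecord]:
    """Read chrom/start/end/major/minor TSV; validate sorted, non-overlapping.

    A line with major < minor is accepted with a warning and the alleles
    swapped (major/minor is a naming convention, not phased information).
    """
    segs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise ParseError(path, lineno, f"expected 5 columns, got {len(f)}")
            try:
                chrom = normalize_chrom(f[0])
                start, end = int(f[1]), int(f[2])
                major, minor = int(f[3]), int(f[4])
                if major < minor:
                    warnings.warn(
                        f"{path}:{lineno}: major {major} < minor {minor}; swapping")
                    major, minor = minor, major
                segs.append(SegmentRecord(GenomicInterval(chrom, start, end),
                                          major, minor))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    segs.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    for a, b in zip(segs, segs[1:]):
        if a.interval.overlaps(b.interval):
            raise ValueError(f"overlapping segments {a.interval} and {b.interval}")
    return segs


def write_segments(path, records: Sequence[SegmentRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tmajor\tminor\n")
        for s in sorted(records, key=lambda s: (s.interval.chrom, s.interval.start)):
            fh.write("\t".join([s.interval.chrom, str(s.interval.start),
                                str(s.interval.end), str(s.major),
                                str(s.minor)]) + "\n")


def segment_at(segments: Sequence[SegmentRecord], chrom: str,
               pos: int) -> SegmentRecord | None:
    """The segment covering a position, or None."""
    for s in segments:
        if s.contains(chrom, pos):
            return s
    return None
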