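"""Genomic coordinate conventions and interval arithmetic.

Everything downstream (QC filtering, database-overlap classification, CNVR
clustering, aneuploidy detection) is built on the primitives in this module.

Conventions
-----------
* Internal representation is **0-based, half-open** ``[start, end)`` —
  the BED convention.
* Array-software exports and the bundled cohort tables print **1-based,
  inclusive** coordinates; conversion happens only at I/O boundaries via
  :func:`from_table_coords` / :meth:`GenomicInterval.to_table_coords`.
* Chromosome names are stored without a ``chr`` prefix ("7", "X"); parsing
  is case-insensitive and accepts either style.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence


class CoordinateError(ValueError):
    """Reversed or otherwise invalid coordinates."""


class UnknownContigError(KeyError):
    """Chromosome name absent from the active genome build."""


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name: strip 'chr' prefix, uppercase X/Y/M."""
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.upper() if s.lower() in ("x", "y", "m", "mt") else s


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (the tables' rounding; banker's rounding is not)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    covered_start: int
    covered_end: int

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: non-positive length")
        if not (0 <= self.covered_start < self.covered_end <= self.length):
            raise ValueError(
                f"chromosome {self.name}: covered span "
                f"[{self.covered_start}, {self.covered_end}) not within "
                f"[0, {self.length}]")

    @property
    def covered_span(self) -> int:
        return self.covered_end - self.covered_start


@dataclass(frozen=True)
class GenomeBuild:
    """A named set of chromosomes with declared probe-covered spans.

    The covered span is the territory the array interrogates; whole-chromosome
    (aneuploidy-scale) events are measured against it rather than the full
    sequence length, because acrocentric p-arms and heterochromatin carry no
    probes.
    """

    name: str
    chromosomes: tuple[Chromosome, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        idx = {}
        for c in self.chromosomes:
            if c.name in idx:
                raise ValueError(f"duplicate chromosome {c.name!r}")
            idx[c.name] = c
        object.__setattr__(self, "_index", idx)

    def __contains__(self, name: str) -> bool:
        return normalize_chrom(name) in self._index

    def chromosome(self, name: str) -> Chromosome:
        key = normalize_chrom(name)
        try:
            return self._index[key]
        except KeyError:
            raise UnknownContigError(
                f"chromosome {name!r} not in build {self.name!r}") from None


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.end <= self.start:
            raise CoordinateError(
                f"end ({self.end}) must exceed start ({self.start})")
        if self.start < 0:
            raise CoordinateError(f"negative start ({self.start})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_table_coords(self) -> tuple[str, int, int]:
        """Export as (chrom, 1-based start, inclusive end) — the table/array
        convention. Round-trips with :func:`from_table_coords`."""
        return self.chrom, self.start + 1, self.end


def from_table_coords(chrom: str, start_1based: int, end_1based: int,
                      build: GenomeBuild | None = None) -> GenomicInterval:
    """Build an interval from 1-based inclusive coordinates.

    The resulting length is ``end_1based - start_1based + 1`` bp (a printed
    single-base interval has length 1). When a build is supplied the
    chromosome must exist and the interval must fit on it.
    """
    if start_1based < 1:
        raise CoordinateError(f"1-based start must be >= 1, got {start_1based}")
    if end_1based < start_1based:
        raise CoordinateError(
            f"reversed coordinates: start {start_1based} > end {end_1based}")
    iv = GenomicInterval(chrom, start_1based - 1, end_1based)
    if build is not None:
        c = build.chromosome(iv.chrom)
        if iv.end > c.length:
            raise CoordinateError(
                f"interval end {iv.end} beyond {c.name} length {c.length}")
    return iv


def length_kb(iv: GenomicInterval) -> int:
    """Interval length in integer kb, round-half-up (table "size (Kb)")."""
    return int(round_half_up(iv.length / 1000))


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Base pairs shared by two intervals (0 if disjoint / different chrom)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted list of disjoint intervals (per chrom)."""
    out: list[GenomicInterval] = []
    for iv in sorted(ivs, key=lambda v: (v.chrom, v.start, v.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def union_coverage_fraction(query: GenomicInterval,
                            hits: Sequence[GenomicInterval]) -> float:
    """Fraction of `query` covered by the union of `hits`.

    Overlapping hits are counted once; hits on other chromosomes contribute
    nothing. This is the "fraction of the call covered by database records"
    statistic behind the non-causative classification.
    """
    covered = 0
    for m in merge_intervals(h for h in hits if h.chrom == query.chrom):
        covered += overlap_bp(query, m)
    return covered / query.length


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/len(a), overlap/len(b)) — the standard CNV matching
    criterion; 1.0 iff the intervals are identical."""
    ov = overlap_bp(a, b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)
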