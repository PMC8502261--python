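"""CNV classification, CNVR clustering and chromosome-level event detection.

The classification is a two-way split on population-database coverage:
calls whose territory is covered >= 70% by same-type population-database
records are *non-causative*; the rest are *potentially-causative*. Cohort
rarity splits at 1% carrier frequency (rare < 1% <= common). Recurrent
calls are grouped into CNV regions (CNVRs) by single-linkage clustering at
reciprocal overlap >= 0.5, so that heterogeneous whole-chromosome-arm
events (e.g. the trisomy-21-scale 21q duplications) count as one variant
with one cohort frequency.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .intervals import (GenomeBuild, GenomicInterval, merge_intervals,
                        reciprocal_overlap, round_half_up,
                        union_coverage_fraction)
from .io import CnvCall, ReferenceDb

COVERAGE_THRESHOLD = 0.70     # inclusive: coverage == 0.70 -> non-causative
RARE_THRESHOLD_PERCENT = 1.0  # rare < 1% <= common
CLUSTER_RECIPROCAL = 0.5
NOVELTY_PRESENCE = 0.10
ANEUPLOIDY_FRACTION = 0.80

NON_CAUSATIVE = "non_causative"
POTENTIALLY_CAUSATIVE = "potentially_causative"


class DbIndex:
    """Per-(chrom, type) interval index over reference-db records."""

    def __init__(self, db: ReferenceDb):
        self.db = db
        self._trees: dict[tuple[str, str], IntervalTree] = defaultdict(
            IntervalTree)
        for rec in db.records:
            iv = rec.interval
            self._trees[(iv.chrom, rec.cnv_type)].addi(iv.start, iv.end, rec)

    def query(self, region: GenomicInterval, cnv_type: str | None = None):
        """Records overlapping `region` (>=1 bp), optionally type-matched."""
        types = [cnv_type] if cnv_type else ["DUP", "DEL"]
        out = []
        for t in types:
            tree = self._trees.get((region.chrom, t))
            if tree:
                out.extend(hit.data for hit in
                           tree.overlap(region.start, region.end))
        return out


def _as_index(db) -> DbIndex:
    return db if isinstance(db, DbIndex) else DbIndex(db)


def db_coverage(region: GenomicInterval, db, cnv_type: str | None = None
                ) -> float:
    """Fraction of `region` covered by the union of (optionally same-type)
    database records."""
    idx = _as_index(db)
    hits = [r.interval for r in idx.query(region, cnv_type)]
    return union_coverage_fraction(region, hits) if hits else 0.0


def classify_causative(call: CnvCall, popdb,
                       threshold: float = COVERAGE_THRESHOLD,
                       type_matched: bool = True) -> tuple[str, float]:
    """(causative_status, db_coverage) for one call.

    Coverage is fraction-of-call by the union of population-db records
    (same-type by default); status is non-causative iff coverage >=
    threshold (boundary inclusive).
    """
    idx = _as_index(popdb)
    if idx.db.kind != "population":
        raise ValueError("classify_causative requires a population db")
    cov = db_coverage(call.interval, idx,
                      call.cnv_type if type_matched else None)
    status = NON_CAUSATIVE if cov >= threshold else POTENTIALLY_CAUSATIVE
    return status, cov


@dataclass(frozen=True)
class CnvRegion:
    """Cluster of same-type calls across samples (a recurrent CNV)."""

    region_id: str
    interval: GenomicInterval  # union span of members
    cnv_type: str
    calls: tuple[CnvCall, ...]
    carriers: frozenset[str]
    cohort_freq_percent: dict | None = None  # cohort label -> percent


def cluster_cnvrs(calls: Sequence[CnvCall],
                  min_reciprocal: float = CLUSTER_RECIPROCAL
                  ) -> list[CnvRegion]:
    """Single-linkage clustering of same-type, same-chromosome calls at
    reciprocal overlap >= `min_reciprocal`.

    Returns a partition (every call in exactly one CNVR), invariant to input
    order: members are sorted internally and regions by coordinate.
    """
    groups: dict[tuple[str, str], list[CnvCall]] = defaultdict(list)
    for c in calls:
        groups[(c.interval.chrom, c.cnv_type)].append(c)

    regions = []
    for (chrom, ctype), members in groups.items():
        members = sorted(members,
                         key=lambda c: (c.interval.start, c.interval.end,
                                        c.sample_id))
        parent = list(range(len(members)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i].interval, members[j].interval
                if b.start >= a.end:  # sorted by start; no overlap beyond
                    break
                if reciprocal_overlap(a, b) >= min_reciprocal:
                    parent[find(i)] = find(j)
        clusters: dict[int, list[CnvCall]] = defaultdict(list)
        for i, c in enumerate(members):
            clusters[find(i)].append(c)
        for cl in clusters.values():
            span = GenomicInterval(chrom,
                                   min(c.interval.start for c in cl),
                                   max(c.interval.end for c in cl))
            regions.append(CnvRegion(
                f"{ctype}_{chrom}_{span.start + 1}_{span.end}", span, ctype,
                tuple(sorted(cl, key=lambda c: (c.sample_id,
                                                c.interval.start))),
                frozenset(c.sample_id for c in cl)))
    return sorted(regions, key=lambda r: (r.interval.chrom, r.interval.start,
                                          r.interval.end, r.cnv_type))


def cohort_frequency(cnvr: CnvRegion, cohort_n: int, ndigits: int = 4
                     ) -> float:
    """Percent of the cohort carrying the CNVR (distinct carriers), rounded
    half-up; 4 decimals in table mode, pass ndigits=2 for summary text."""
    if cohort_n <= 0:
        raise ValueError("cohort_n must be positive")
    return round_half_up(100.0 * len(cnvr.carriers) / cohort_n, ndigits)


def classify_rarity(freq_percent: float,
                    threshold: float = RARE_THRESHOLD_PERCENT) -> str:
    """rare iff cohort frequency < 1%; the boundary itself is common."""
    return "rare" if freq_percent < threshold else "common"


def flag_novel(call: CnvCall, popdb, clindb,
               presence_threshold: float = NOVELTY_PRESENCE) -> bool:
    """Novel iff essentially absent (< `presence_threshold` coverage, any
    type) from both the population and the clinical database."""
    return (db_coverage(call.interval, popdb, None) < presence_threshold
            and db_coverage(call.interval, clindb, None) < presence_threshold)


@dataclass(frozen=True)
class AneuploidyFlag:
    sample_id: str
    chrom: str
    direction: str  # gain | loss
    covered_fraction: float


_DIRECTION = {"DUP": "gain", "DEL": "loss"}


def detect_chromosome_level_events(calls: Sequence[CnvCall],
                                   build: GenomeBuild,
                                   min_fraction: float = ANEUPLOIDY_FRACTION
                                   ) -> list[AneuploidyFlag]:
    """Flag trisomy-/monosomy-like events for one sample.

    Per (chromosome, direction), the union of same-type calls must cover
    >= `min_fraction` of the chromosome's declared probe-covered span (not
    its full sequence length — acrocentric p-arms carry no probes).
    """
    sample_ids = {c.sample_id for c in calls}
    if len(sample_ids) > 1:
        raise ValueError("detect_chromosome_level_events takes the calls of "
                         f"one sample, got {sorted(sample_ids)}")
    by_key: dict[tuple[str, str], list[GenomicInterval]] = defaultdict(list)
    for c in calls:
        by_key[(c.interval.chrom, c.cnv_type)].append(c.interval)
    flags = []
    for (chrom, ctype), ivs in sorted(by_key.items()):
        chromo = build.chromosome(chrom)  # raises UnknownContigError
        span = GenomicInterval(chrom, chromo.covered_start,
                               chromo.covered_end)
        covered = sum(max(0, min(m.end, span.end) - max(m.start, span.start))
                      for m in merge_intervals(ivs))
        frac = covered / span.length
        if frac >= min_fraction:
            flags.append(AneuploidyFlag(next(iter(sample_ids)), chrom,
                                        _DIRECTION[ctype], frac))
    return flags


@dataclass(frozen=True)
class ClassifiedCall:
    """A call with every classification label attached."""

    call: CnvCall
    causative_status: str
    db_coverage: float
    region_id: str
    cohort_freq_percent: float
    rarity: str
    novel: bool | None = None

    # convenience pass-throughs used by writers
    @property
    def sample_id(self):
        return self.call.sample_id

    @property
    def interval(self):
        return self.call.interval

    @property
    def cnv_type(self):
        return self.call.cnv_type


def classify_calls(calls: Sequence[CnvCall], popdb: ReferenceDb,
                   cohort_of: dict, cohort_n: dict,
                   clindb: ReferenceDb | None = None,
                   threshold: float = COVERAGE_THRESHOLD,
                   type_matched: bool = True,
                   min_reciprocal: float = CLUSTER_RECIPROCAL,
                   ) -> tuple[list[ClassifiedCall], list[CnvRegion]]:
    """Run the full per-call classification: causative status, CNVR
    clustering, per-cohort CNVR frequency and rarity, optional novelty.

    `cohort_of` maps sample_id -> cohort label; `cohort_n` maps cohort
    label -> denominator (QC-passing cohort size).
    """
    pop_idx = _as_index(popdb)
    clin_idx = _as_index(clindb) if clindb is not None else None
    cnvrs = cluster_cnvrs(calls, min_reciprocal)
    freq_of: dict[str, dict] = {}
    region_of: dict[int, CnvRegion] = {}
    annotated_cnvrs = []
    for r in cnvrs:
        freqs = {}
        for cohort, n in sorted(cohort_n.items()):
            k = sum(1 for s in r.carriers if cohort_of.get(s) == cohort)
            freqs[cohort] = round_half_up(100.0 * k / n, 4)
        r = replace(r, cohort_freq_percent=freqs)
        annotated_cnvrs.append(r)
        freq_of[r.region_id] = freqs
        for c in r.calls:
            region_of[id(c)] = r

    out = []
    for c in calls:
        status, cov = classify_causative(c, pop_idx, threshold, type_matched)
        region = region_of[id(c)]
        freq = freq_of[region.region_id].get(cohort_of.get(c.sample_id), 0.0)
        novel = (flag_novel(c, pop_idx, clin_idx)
                 if clin_idx is not None else None)
        out.append(ClassifiedCall(c, status, cov, region.region_id, freq,
                                  classify_rarity(freq), novel))
    return out, annotated_cnvrs
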