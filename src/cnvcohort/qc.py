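"""Sample-level QC exclusion and call-level size/probe filtering.

Defaults implement the study design: keep only calls strictly larger than
200 kb with at least 50 supporting probes. ``as_published=True`` disables
the size filter so that a published call set containing sub-200 kb rows can
be pushed through the pipeline unchanged.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import CnvCall, Sample

MIN_SIZE_BP = 200_000   # strict >
MIN_PROBES = 50         # >=


@dataclass(frozen=True)
class QcResult:
    passing: tuple[Sample, ...]
    failed: tuple[Sample, ...]
    cohort_n: dict  # cohort label -> n passing (the frequency denominators)


def apply_sample_qc(samples: Sequence[Sample]) -> QcResult:
    """Drop qc_pass=False samples and compute per-cohort denominators."""
    passing = tuple(s for s in samples if s.qc_pass)
    failed = tuple(s for s in samples if not s.qc_pass)
    return QcResult(passing, failed,
                    dict(Counter(s.cohort for s in passing)))


@dataclass(frozen=True)
class RejectedCall:
    call: CnvCall
    reason: str


def apply_call_filters(calls: Iterable[CnvCall],
                       min_size_bp: int = MIN_SIZE_BP,
                       min_probes: int = MIN_PROBES,
                       as_published: bool = False,
                       ) -> tuple[list[CnvCall], list[RejectedCall]]:
    """Partition calls into (kept, rejected-with-reason), preserving order.

    A call is kept iff ``length > min_size_bp`` (strict — "larger than") and
    ``marker_count >= min_probes``. ``as_published`` zeroes the size
    threshold only.
    """
    if min_size_bp < 0 or min_probes < 0:
        raise ValueError("filter thresholds must be non-negative")
    if as_published:
        min_size_bp = 0
    kept, rejected = [], []
    for c in calls:
        if min_size_bp and c.interval.length <= min_size_bp:
            rejected.append(RejectedCall(
                c, f"size {c.interval.length} bp <= {min_size_bp} bp"))
        elif c.marker_count < min_probes:
            rejected.append(RejectedCall(
                c, f"marker_count {c.marker_count} < {min_probes}"))
        else:
            kept.append(c)
    return kept, rejected
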