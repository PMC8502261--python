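"""Cohort-level statistics: detection rates, sex ratios, phenotype
co-occurrence and duplication/deletion counts.

All sample-level rates count DISTINCT samples (a sample carrying two
qualifying CNVs counts once) and all percentages are round-half-up at 2
decimals (4 decimals is the per-CNVR table convention, handled in
classify.cohort_frequency).
"""
from __future__ import annotations

from typing import Iterable, Sequence, Set

from .intervals import round_half_up
from .io import Sample


def detection_rate(samples_with_flag: Set[str], cohort_n: int
                   ) -> tuple[int, float]:
    """(distinct-sample count, percent at 2 dp) of flagged samples."""
    if cohort_n <= 0:
        raise ValueError("cohort_n must be positive")
    k = len(set(samples_with_flag))
    return k, round_half_up(100.0 * k / cohort_n, 2)


def sex_ratio(group: Sequence[Sample], order: str = "F_over_M"
              ) -> tuple[float | None, int, int]:
    """(ratio at 2 dp, numerator count, denominator count).

    order "F_over_M" -> females/males; "M_over_F" -> males/females. A zero
    denominator yields ratio None (counts still reported), not an exception.
    """
    n_f = sum(1 for s in group if s.sex == "F")
    n_m = sum(1 for s in group if s.sex == "M")
    if order == "F_over_M":
        num, den = n_f, n_m
    elif order == "M_over_F":
        num, den = n_m, n_f
    else:
        raise ValueError(f"unknown order {order!r}")
    ratio = round_half_up(num / den, 2) if den else None
    return ratio, num, den


def phenotype_cooccurrence(group: Sequence[Sample], code: str
                           ) -> tuple[int, float]:
    """(count, percent at 2 dp) of group members whose phenotype set
    contains `code`."""
    if not group:
        raise ValueError("phenotype co-occurrence undefined for empty group")
    code = code.strip().upper()
    k = sum(1 for s in group if code in s.phenotypes)
    return k, round_half_up(100.0 * k / len(group), 2)


def type_counts(items: Iterable) -> tuple[int, int]:
    """(n_dup, n_del) over calls or CNVRs (anything with .cnv_type)."""
    n_dup = n_del = 0
    for it in items:
        if it.cnv_type == "DUP":
            n_dup += 1
        elif it.cnv_type == "DEL":
            n_del += 1
    return n_dup, n_del
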