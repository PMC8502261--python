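"""Gene, cytoband, candidate-gene and clinical-database annotation."""
from __future__ import annotations

from typing import Sequence

import pandas as pd

from .intervals import GenomicInterval, round_half_up, union_coverage_fraction
from .classify import COVERAGE_THRESHOLD, DbIndex, _as_index
from .io import ReferenceDb, SchemaError


def db_frequency(region: GenomicInterval, cnv_type: str, clindb,
                 match_threshold: float = COVERAGE_THRESHOLD,
                 type_matched: bool = True) -> tuple[int, int, float]:
    """(count, denominator, percent) of clinical patient records matching a
    region.

    A record matches when it covers >= `match_threshold` of the region
    (same CNV type by default); `count` sums record multiplicities and the
    percent is 100 x count / n_total_records, round-half-up to 4 decimals —
    the fixed-denominator convention of clinical CNV databases.
    """
    idx = _as_index(clindb)
    if idx.db.kind != "clinical":
        raise ValueError("db_frequency requires a clinical db")
    denom = idx.db.n_total_records
    if not denom:
        raise SchemaError("clinical db lacks n_total_records denominator")
    count = 0
    for rec in idx.query(region, cnv_type if type_matched else None):
        cov = union_coverage_fraction(region, [rec.interval])
        if cov >= match_threshold:
            count += rec.n_records
    return count, denom, round_half_up(100.0 * count / denom, 4)


def genes_in_region(region: GenomicInterval, gene_model: pd.DataFrame,
                    candidates: Sequence[str] = ()) -> list[dict]:
    """Genes overlapping the region by >= 1 bp, in coordinate order.

    Returns [{gene, start, end, candidate}, ...]; `candidate` is True when
    the symbol is on the supplied candidate-gene list.
    """
    cand = {g.strip().upper() for g in candidates}
    if len(gene_model) == 0:
        return []
    g = gene_model[(gene_model["chrom"] == region.chrom)
                   & (gene_model["start"] < region.end)
                   & (gene_model["end"] > region.start)]
    return [{"gene": r.gene, "start": int(r.start), "end": int(r.end),
             "candidate": r.gene.upper() in cand}
            for r in g.sort_values("start").itertuples()]


def cytoband_label(region: GenomicInterval, cytobands: pd.DataFrame) -> str:
    """Cytogenetic label for a region, e.g. "7q11.23" within one band or
    "21q11.2-21q22.3" across several (band order by coordinate)."""
    b = cytobands[(cytobands["chrom"] == region.chrom)
                  & (cytobands["start"] < region.end)
                  & (cytobands["end"] > region.start)]
    if len(b) == 0:
        raise KeyError(f"region {region} outside the cytoband table")
    b = b.sort_values("start")
    first, last = b.iloc[0]["band"], b.iloc[-1]["band"]
    if first == last:
        return f"{region.chrom}{first}"
    return f"{region.chrom}{first}-{region.chrom}{last}"


def load_candidate_genes(path) -> list[str]:
    """Candidate-gene list: one symbol per line, '#' comments allowed."""
    out = []
    with open(path) as fh:
        for line in fh:
            sym = line.split("#")[0].strip()
            if sym:
                out.append(sym)
    return out
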