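"""Readers and writers for every file the pipeline touches.

Formats
-------
* CNV call tables: array-export-like TSV (1-based inclusive coordinates,
  ``chas_tsv`` dialect) or BED4+ (0-based half-open, ``bed`` dialect).
* Sample sheets: TSV with sample_id / sex / cohort / phenotypes / qc_pass.
* Reference CNV databases: TSV with ``#key=value`` header pragmas declaring
  the kind (population or clinical), the coordinate convention and — for
  clinical databases — the total patient-record denominator.
* Gene models: BED6. Cytobands: UCSC cytoBand.txt layout.

Readers reject malformed coordinates rather than coercing them; writers are
deterministic (fixed row order, no timestamps) so reruns are byte-identical.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .intervals import (CoordinateError, Chromosome, GenomeBuild,
                        GenomicInterval, from_table_coords, normalize_chrom)

DUP = "DUP"
DEL = "DEL"
_TYPE_ALIASES = {"dup": DUP, "duplication": DUP, "gain": DUP, "amp": DUP,
                 "del": DEL, "deletion": DEL, "loss": DEL}


class SchemaError(ValueError):
    """Missing mandatory column or malformed header."""


class RowError(ValueError):
    """Unparseable value in a data row (carries the 1-based line number)."""


def parse_cnv_type(token: str) -> str:
    try:
        return _TYPE_ALIASES[str(token).strip().lower()]
    except KeyError:
        raise RowError(f"unrecognized CNV type {token!r}") from None


@dataclass(frozen=True)
class CnvCall:
    """One per-sample segment call as emitted by array analysis software."""

    sample_id: str
    interval: GenomicInterval
    cnv_type: str  # DUP or DEL
    marker_count: int
    copy_number: int | None = None
    source_row: int = -1
    info: Mapping[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.cnv_type not in (DUP, DEL):
            raise ValueError(f"cnv_type must be DUP/DEL, got {self.cnv_type!r}")
        if self.marker_count < 0:
            raise ValueError("marker_count must be >= 0")


@dataclass(frozen=True)
class Sample:
    sample_id: str
    sex: str  # M / F / unknown
    cohort: str
    phenotypes: frozenset[str] = frozenset()
    qc_pass: bool = True


@dataclass(frozen=True)
class DbRecord:
    interval: GenomicInterval
    cnv_type: str
    frequency: float | None = None   # population kind
    n_records: int = 1               # clinical kind: patient-record multiplicity
    phenotypes: frozenset[str] = frozenset()


@dataclass(frozen=True)
class ReferenceDb:
    """Population (frequency-bearing) or clinical (record-count-bearing)
    collection of CNV intervals."""

    kind: str  # population | clinical
    records: tuple[DbRecord, ...]
    n_total_records: int | None = None

    def __post_init__(self):
        if self.kind not in ("population", "clinical"):
            raise ValueError(f"unknown db kind {self.kind!r}")
        if self.kind == "clinical":
            if not self.n_total_records or self.n_total_records <= 0:
                raise SchemaError(
                    "clinical reference db requires a positive "
                    "n_total_records denominator")
        for r in self.records:
            if r.frequency is not None and not (0.0 <= r.frequency <= 1.0):
                raise ValueError(f"frequency {r.frequency} outside [0,1]")


# --------------------------------------------------------------------- helpers

def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) "
                          + ", ".join(missing))


def _int_at(row, col, lineno: int) -> int:
    raw = row[col]
    try:
        return int(str(raw).replace(",", ""))
    except (TypeError, ValueError):
        raise RowError(f"line {lineno}: unparseable {col} value {raw!r}") from None


# --------------------------------------------------------------------- readers

def read_cnv_table(path, dialect: str = "chas_tsv",
                   build: GenomeBuild | None = None) -> list[CnvCall]:
    """Read per-sample CNV calls.

    ``chas_tsv``: TSV with at least sample_id, chrom, start, end, cnv_type,
    marker_count (1-based inclusive coordinates; extra columns preserved in
    ``call.info``).  ``bed``: BED4+ of ``chrom start end type`` with optional
    sample_id / marker_count columns (0-based half-open).
    """
    if dialect == "chas_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        _require_columns(
            df, ["sample_id", "chrom", "start", "end", "cnv_type",
                 "marker_count"], path)
        calls = []
        extras = [c for c in df.columns
                  if c not in ("sample_id", "chrom", "start", "end",
                               "cnv_type", "marker_count", "copy_number")]
        for i, row in df.iterrows():
            lineno = i + 2  # header is line 1
            try:
                iv = from_table_coords(row["chrom"],
                                       _int_at(row, "start", lineno),
                                       _int_at(row, "end", lineno), build)
            except CoordinateError as e:
                raise RowError(f"line {lineno}: {e}") from None
            cn = None
            if "copy_number" in df.columns and pd.notna(row["copy_number"]):
                cn = _int_at(row, "copy_number", lineno)
            info = {c: row[c] for c in extras if pd.notna(row[c])}
            calls.append(CnvCall(str(row["sample_id"]), iv,
                                 parse_cnv_type(row["cnv_type"]),
                                 _int_at(row, "marker_count", lineno),
                                 copy_number=cn, source_row=lineno,
                                 info=info))
        return calls
    if dialect == "bed":
        calls = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t") if "\t" in line else line.split()
                if len(f) < 4:
                    raise RowError(f"line {lineno}: BED needs >= 4 fields")
                try:
                    start, end = int(f[1]), int(f[2])
                except ValueError:
                    raise RowError(
                        f"line {lineno}: unparseable coordinates") from None
                if end <= start:
                    raise RowError(f"line {lineno}: end <= start")
                iv = GenomicInterval(f[0], start, end)
                sample = f[4] if len(f) > 4 else "NA"
                markers = int(f[5]) if len(f) > 5 else 0
                calls.append(CnvCall(sample, iv, parse_cnv_type(f[3]),
                                     markers, source_row=lineno))
        return calls
    raise ValueError(f"unknown dialect {dialect!r}")


def load_vocabulary(path=None) -> dict[str, str]:
    """Phenotype vocabulary: {token (canonical or synonym) -> canonical code}."""
    if path is None:
        path = bundled_path("phenotype_vocabulary.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str)
    vocab: dict[str, str] = {}
    for _, row in df.iterrows():
        code = row["code"].strip().upper()
        vocab[code] = code
        if pd.notna(row.get("synonyms")) and str(row["synonyms"]).strip():
            for syn in str(row["synonyms"]).split(","):
                vocab[syn.strip().upper()] = code
    return vocab


def parse_phenotypes(text, vocab: Mapping[str, str] | None = None
                     ) -> frozenset[str]:
    """Split a semicolon-separated phenotype string into canonical codes.

    Unknown codes are preserved (uppercased) but flagged with a warning when
    a vocabulary is supplied.
    """
    if text is None or (isinstance(text, float) and pd.isna(text)):
        return frozenset()
    out = set()
    for tok in str(text).replace(",", ";").split(";"):
        tok = tok.strip().upper()
        if not tok:
            continue
        if vocab is not None:
            if tok in vocab:
                tok = vocab[tok]
            else:
                warnings.warn(f"phenotype code {tok!r} not in vocabulary",
                              stacklevel=2)
        out.add(tok)
    return frozenset(out)


def read_sample_sheet(path, vocab: Mapping[str, str] | None = None
                      ) -> list[Sample]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    _require_columns(df, ["sample_id", "sex", "cohort", "phenotypes",
                          "qc_pass"], path)
    dupes = df["sample_id"][df["sample_id"].duplicated()]
    if len(dupes):
        raise SchemaError(f"{path}: duplicated sample_id(s): "
                          + ", ".join(sorted(set(dupes))))
    samples = []
    for _, row in df.iterrows():
        sex = str(row["sex"]).strip().upper()
        if sex not in ("M", "F"):
            if sex not in ("UNKNOWN", "U", "NA", "NAN"):
                warnings.warn(f"unknown sex code {row['sex']!r} for "
                              f"{row['sample_id']}; recorded as unknown",
                              stacklevel=2)
            sex = "unknown"
        qc = str(row["qc_pass"]).strip().lower() in ("true", "1", "yes", "pass")
        samples.append(Sample(str(row["sample_id"]), sex,
                              str(row["cohort"]).strip(),
                              parse_phenotypes(row["phenotypes"], vocab), qc))
    return samples


def read_pragmas(path) -> dict[str, str]:
    pragmas = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line[1:].strip().split("=", 1)
                pragmas[k.strip()] = v.strip()
    return pragmas


def read_reference_db(path, kind: str | None = None) -> ReferenceDb:
    """Read a population or clinical CNV database TSV.

    Header pragmas: ``#kind=``, ``#coords=`` (``1-based`` default, or
    ``0-based``), and for clinical DBs ``#n_total_records=`` (the fixed
    patient-record denominator all clinical frequencies are computed
    against). Clinical rows may carry an ``n_records`` multiplicity column:
    one row standing for N patient records sharing that CNV.
    """
    pragmas = read_pragmas(path)
    kind = kind or pragmas.get("kind")
    if kind not in ("population", "clinical"):
        raise SchemaError(f"{path}: reference db kind not declared")
    one_based = pragmas.get("coords", "1-based") == "1-based"
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    _require_columns(df, ["chrom", "start", "end", "cnv_type"], path)
    records = []
    for i, row in df.iterrows():
        lineno = i + 2
        s, e = _int_at(row, "start", lineno), _int_at(row, "end", lineno)
        iv = (from_table_coords(row["chrom"], s, e) if one_based
              else GenomicInterval(row["chrom"], s, e))
        freq = None
        if "frequency" in df.columns and pd.notna(row["frequency"]):
            freq = float(row["frequency"])
        n = 1
        if "n_records" in df.columns and pd.notna(row.get("n_records")):
            n = _int_at(row, "n_records", lineno)
        phen = parse_phenotypes(row.get("phenotypes")) \
            if "phenotypes" in df.columns else frozenset()
        records.append(DbRecord(iv, parse_cnv_type(row["cnv_type"]),
                                frequency=freq, n_records=n, phenotypes=phen))
    n_total = pragmas.get("n_total_records")
    return ReferenceDb(kind, tuple(records),
                       int(n_total) if n_total else None)


def read_genome_build(path) -> GenomeBuild:
    pragmas = read_pragmas(path)
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"chrom": str})
    _require_columns(df, ["chrom", "length", "covered_start", "covered_end"],
                     path)
    chroms = tuple(Chromosome(normalize_chrom(r.chrom), int(r.length),
                              int(r.covered_start), int(r.covered_end))
                   for r in df.itertuples())
    return GenomeBuild(pragmas.get("name", Path(path).stem), chroms)


def read_genes_bed(path) -> pd.DataFrame:
    """Gene model BED6 -> DataFrame(chrom, start, end, gene, strand),
    0-based half-open, sorted by (chrom, start)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "gene", "score",
                            "strand"],
                     usecols=[0, 1, 2, 3, 4, 5], dtype={0: str})
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return (df[["chrom", "start", "end", "gene", "strand"]]
            .sort_values(["chrom", "start"]).reset_index(drop=True))


def read_cytobands(path) -> pd.DataFrame:
    """UCSC cytoBand.txt -> DataFrame(chrom, start, end, band, stain)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "band", "stain"],
                     dtype={0: str})
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


# --------------------------------------------------------------------- writers

def calls_to_frame(calls: Iterable) -> pd.DataFrame:
    """Classified (or raw) calls -> tidy DataFrame in 1-based table coords,
    deterministically ordered by (sample_id, chrom, start)."""
    rows = []
    for c in calls:
        call = getattr(c, "call", c)  # ClassifiedCall or bare CnvCall
        chrom, s1, e1 = call.interval.to_table_coords()
        row = {"sample_id": call.sample_id, "chrom": chrom, "start": s1,
               "end": e1, "cnv_type": call.cnv_type,
               "marker_count": call.marker_count}
        for attr in ("causative_status", "db_coverage", "rarity",
                     "cohort_freq_percent", "novel", "region_id",
                     "cytoband", "genes"):
            if hasattr(c, attr):
                row[attr] = getattr(c, attr)
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["sample_id", "chrom", "start"]).reset_index(
            drop=True)
    return df


def cnvrs_to_frame(cnvrs: Iterable) -> pd.DataFrame:
    rows = []
    for r in cnvrs:
        chrom, s1, e1 = r.interval.to_table_coords()
        rows.append({"region_id": r.region_id, "chrom": chrom, "start": s1,
                     "end": e1, "cnv_type": r.cnv_type,
                     "n_calls": len(r.calls), "n_carriers": len(r.carriers),
                     "carriers": ";".join(sorted(r.carriers))})
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["chrom", "start", "cnv_type"]).reset_index(
            drop=True)
    return df


def write_outputs(outdir, classified=None, cnvrs=None, summary=None,
                  bed_causative=None) -> dict[str, Path]:
    """Write the pipeline products; returns {name: path}.

    Outputs are deterministic: fixed sort order, no timestamps. ``summary``
    is any JSON-serializable mapping.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    if classified is not None:
        p = outdir / "classified_calls.tsv"
        calls_to_frame(classified).to_csv(p, sep="\t", index=False)
        written["classified_calls"] = p
    if cnvrs is not None:
        p = outdir / "cnv_regions.tsv"
        cnvrs_to_frame(cnvrs).to_csv(p, sep="\t", index=False)
        written["cnv_regions"] = p
    if summary is not None:
        p = outdir / "summary.json"
        p.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        written["summary"] = p
    if bed_causative is not None:
        p = outdir / "potentially_causative.bed"
        with open(p, "w") as fh:
            for c in bed_causative:
                call = getattr(c, "call", c)
                iv = call.interval
                fh.write(f"chr{iv.chrom}\t{iv.start}\t{iv.end}\t"
                         f"{call.cnv_type}\t{call.sample_id}\n")
        written["bed"] = p
    return written


# ----------------------------------------------------------- bundled fixtures

def bundled_path(name: str) -> Path:
    """Path of a packaged data file (bundled cohort tables and synthetic
    reference files)."""
    return Path(resources.files("cnvcohort") / "data" / name)


SUMMARY_SCHEMA_NAME = "summary_schema.json"


def validate_summary(summary: Mapping, schema: Mapping | None = None) -> None:
    """Structural check of a cohort-summary mapping against the packaged
    schema (required keys and primitive types); raises ValueError on the
    first violation."""
    if schema is None:
        schema = json.loads(bundled_path(SUMMARY_SCHEMA_NAME).read_text())
    _check_node(summary, schema, "summary")


_TYPES = {"object": dict, "number": (int, float), "integer": int,
          "string": str, "boolean": bool, "array": list}


def _check_node(value, schema, where):
    expected = _TYPES[schema.get("type", "object")]
    if expected is int and isinstance(value, bool):
        raise ValueError(f"{where}: expected integer, got bool")
    if not isinstance(value, expected):
        raise ValueError(f"{where}: expected {schema.get('type')}, "
                         f"got {type(value).__name__}")
    for key, sub in schema.get("properties", {}).items():
        if key in schema.get("required", []) and key not in value:
            raise ValueError(f"{where}: missing required key {key!r}")
        if isinstance(value, dict) and key in value:
            _check_node(value[key], sub, f"{where}.{key}")
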