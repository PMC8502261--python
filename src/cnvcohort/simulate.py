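"""Synthetic SNP-array cohort simulator.

Generates reference files (genome build, population and clinical CNV
databases, gene model, cytobands) and a cohort (sample sheet, CNV call
table, truth table) with the statistical structure the analysis assumes:

* polymorphic background CNVs segregating at known population frequencies
  (their carriers should classify non-causative);
* rare potentially-causative CNVs at configured per-cohort frequencies;
* a recurrent whole-covered-span duplication of one chromosome in a
  configurable fraction of one sub-cohort (an aneuploidy-scale event),
  with a sex-odds multiplier among carriers and a phenotype code whose
  probability depends on carrier status;
* per-call marker counts drawn from a Poisson at the array's probe density
  and Gaussian breakpoint jitter.

Everything is driven by one integer seed; identical (config, seed) pairs
produce identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .intervals import Chromosome, GenomeBuild, GenomicInterval
from .io import CnvCall, DbRecord, ReferenceDb, Sample
import pandas as pd


@dataclass(frozen=True)
class SimRegion:
    """A spiked CNV: polymorphic (population) or causative (per-cohort)."""

    chrom: str
    start: int
    end: int
    cnv_type: str                      # DUP | DEL
    frequency: float                   # population or per-cohort carrier freq
    name: str = ""
    cohorts: tuple[str, ...] = ()      # causative: restrict to these cohorts
    phenotype: str | None = None       # optional effect code
    p_phenotype_carrier: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.frequency <= 1.0):
            raise ValueError(f"frequency {self.frequency} outside [0,1]")


@dataclass(frozen=True)
class AneuploidySpec:
    chrom: str
    carrier_fraction: float
    cohort: str
    sex_odds: float = 1.0              # female:male odds among carriers
    phenotype: str | None = None
    p_phenotype_carrier: float = 0.0
    p_phenotype_background: float = 0.0
    end_jitter_sd: int = 1_200_000     # variable distal breakpoints

    def __post_init__(self):
        if not (0.0 <= self.carrier_fraction <= 1.0):
            raise ValueError("carrier_fraction outside [0,1]")


@dataclass
class SimConfig:
    """Simulation parameters. The defaults emulate a two-arm CHD cohort:
    262 + 259 samples, a trisomy-like duplication in 14.9% of the first
    arm with 1.6:1 female:male odds and a 41% pulmonary-hypertension rate
    among carriers (10% background), polymorphic CNVs at realistic
    population frequencies, and 0.10 probes/kb — the density implied by
    ~3,400 markers over a ~33.6 Mb call."""

    seed: int = 0
    genome: tuple = (
        ("1", 50_000_000, 500_000, 49_500_000),
        ("2", 50_000_000, 500_000, 49_500_000),
        ("3", 50_000_000, 500_000, 49_500_000),
        ("4", 50_000_000, 500_000, 49_500_000),
        ("21", 35_000_000, 10_500_000, 35_000_000),
        ("X", 30_000_000, 500_000, 29_500_000),
        ("Y", 10_000_000, 1_000_000, 9_000_000),
    )
    probe_density: float = 0.10        # probes per kb
    n_samples: dict = field(default_factory=lambda: {"CAVC": 262, "SV": 259})
    polymorphic: tuple = (
        SimRegion("1", 10_000_000, 10_800_000, "DEL", 0.05, "poly_1"),
        SimRegion("2", 20_000_000, 21_000_000, "DUP", 0.12, "poly_2"),
        SimRegion("3", 5_000_000, 5_900_000, "DEL", 0.02, "poly_3"),
        SimRegion("4", 30_000_000, 31_200_000, "DUP", 0.30, "poly_4"),
    )
    causative: tuple = (
        SimRegion("2", 40_000_000, 41_500_000, "DEL", 0.004, "causal_del",
                  cohorts=("CAVC",)),
        SimRegion("3", 25_000_000, 26_000_000, "DUP", 0.004, "causal_dup",
                  cohorts=("SV",)),
    )
    aneuploidy: AneuploidySpec | None = AneuploidySpec(
        "21", 0.149, "CAVC", sex_odds=1.6, phenotype="PH",
        p_phenotype_carrier=0.41, p_phenotype_background=0.10)
    jitter_sd: int = 20_000            # bp, both breakpoints
    clindb_n_total: int = 38_367
    clindb_records_per_event: int = 20

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory (no implicit randomness)")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")

    def build(self) -> GenomeBuild:
        return GenomeBuild("synthetic-v1", tuple(
            Chromosome(c, ln, cs, ce) for c, ln, cs, ce in self.genome))


@dataclass(frozen=True)
class TruthRecord:
    sample_id: str
    category: str          # polymorphic | causative | aneuploidy
    event: str
    interval: GenomicInterval
    cnv_type: str


# ------------------------------------------------------------------ reference

def generate_reference(config: SimConfig):
    """(build, popdb, clindb, gene_model, cytobands) matching the config.

    The population db contains each polymorphic region (so their carriers
    classify non-causative); the clinical db contains each causative region
    and the aneuploidy span with a configurable record multiplicity.
    Deterministic: no randomness is consumed here.
    """
    build = config.build()
    pop = tuple(DbRecord(GenomicInterval(r.chrom, r.start, r.end),
                         r.cnv_type, frequency=r.frequency)
                for r in config.polymorphic)
    clin = [DbRecord(GenomicInterval(r.chrom, r.start, r.end), r.cnv_type,
                     n_records=config.clindb_records_per_event,
                     phenotypes=frozenset({"VSD"}))
            for r in config.causative]
    if config.aneuploidy is not None:
        c = build.chromosome(config.aneuploidy.chrom)
        clin.append(DbRecord(
            GenomicInterval(c.name, c.covered_start, c.covered_end), "DUP",
            n_records=config.clindb_records_per_event,
            phenotypes=frozenset({"CAVC"})))
    popdb = ReferenceDb("population", pop)
    clindb = ReferenceDb("clinical", tuple(clin), config.clindb_n_total)

    genes = []
    for i, r in enumerate(tuple(config.polymorphic) + tuple(config.causative)):
        mid = (r.start + r.end) // 2
        genes.append({"chrom": r.chrom, "start": mid - 10_000,
                      "end": mid + 10_000, "gene": f"GENE{i + 1}",
                      "strand": "+"})
    gene_model = pd.DataFrame(genes).sort_values(
        ["chrom", "start"]).reset_index(drop=True)

    bands = []
    for c in build.chromosomes:
        half = c.length // 2
        bands.append({"chrom": c.name, "start": 0, "end": half,
                      "band": "p11", "stain": "gneg"})
        bands.append({"chrom": c.name, "start": half, "end": c.length,
                      "band": "q11", "stain": "gneg"})
    cytobands = pd.DataFrame(bands)
    return build, popdb, clindb, gene_model, cytobands


# --------------------------------------------------------------------- cohort

def _jitter_interval(rng, chrom: Chromosome, start: int, end: int,
                     sd: int) -> tuple[int, int]:
    """Gaussian breakpoint jitter, rounded to bp, truncated at +/-3 sd and
    clipped so the interval stays valid and on the chromosome."""
    if sd == 0:
        return start, end
    ds = int(np.clip(round(rng.normal(0, sd)), -3 * sd, 3 * sd))
    de = int(np.clip(round(rng.normal(0, sd)), -3 * sd, 3 * sd))
    s = max(0, min(start + ds, end - 1))
    e = min(chrom.length, max(end + de, s + 1))
    return s, e


def _markers(rng, length_bp: int, density: float) -> int:
    return int(rng.poisson(density * length_bp / 1000))


def generate_cohort(config: SimConfig
                    ) -> tuple[list[Sample], list[CnvCall], list[TruthRecord]]:
    """Draw one synthetic cohort: samples (sex, cohort, phenotypes, QC),
    their CNV calls, and the truth table linking every call to the event
    that generated it."""
    rng = np.random.default_rng(config.seed)
    build = config.build()
    an = config.aneuploidy

    samples: list[Sample] = []
    calls: list[CnvCall] = []
    truth: list[TruthRecord] = []

    for cohort, n in sorted(config.n_samples.items()):
        if an is not None and an.cohort == cohort:
            carrier_mask = rng.random(n) < an.carrier_fraction
        else:
            carrier_mask = np.zeros(n, dtype=bool)
        for i in range(n):
            sid = f"{cohort}{i + 1:03d}"
            is_an = bool(carrier_mask[i])
            # sex: Bernoulli(0.5) baseline; carriers use the odds multiplier
            p_f = an.sex_odds / (1 + an.sex_odds) if (an and is_an) else 0.5
            sex = "F" if rng.random() < p_f else "M"
            phen = {cohort}

            if is_an:
                c21 = build.chromosome(an.chrom)
                end = c21.covered_end - abs(int(rng.normal(0,
                                                           an.end_jitter_sd)))
                end = max(end, c21.covered_start
                          + int(0.85 * (c21.covered_end - c21.covered_start)))
                iv = GenomicInterval(c21.name, c21.covered_start, end)
                calls.append(CnvCall(sid, iv, "DUP",
                                     _markers(rng, iv.length,
                                              config.probe_density)))
                truth.append(TruthRecord(sid, "aneuploidy",
                                         f"aneuploidy_{an.chrom}", iv, "DUP"))
                if an.phenotype and rng.random() < an.p_phenotype_carrier:
                    phen.add(an.phenotype)
            elif an is not None and an.cohort == cohort and an.phenotype:
                if rng.random() < an.p_phenotype_background:
                    phen.add(an.phenotype)

            for reg in config.polymorphic:
                if rng.random() < reg.frequency:
                    chrom = build.chromosome(reg.chrom)
                    s, e = _jitter_interval(rng, chrom, reg.start, reg.end,
                                            config.jitter_sd)
                    iv = GenomicInterval(reg.chrom, s, e)
                    calls.append(CnvCall(sid, iv, reg.cnv_type,
                                         _markers(rng, iv.length,
                                                  config.probe_density)))
                    truth.append(TruthRecord(sid, "polymorphic", reg.name,
                                             iv, reg.cnv_type))

            for reg in config.causative:
                if reg.cohorts and cohort not in reg.cohorts:
                    continue
                if rng.random() < reg.frequency:
                    chrom = build.chromosome(reg.chrom)
                    s, e = _jitter_interval(rng, chrom, reg.start, reg.end,
                                            config.jitter_sd)
                    iv = GenomicInterval(reg.chrom, s, e)
                    calls.append(CnvCall(sid, iv, reg.cnv_type,
                                         _markers(rng, iv.length,
                                                  config.probe_density)))
                    truth.append(TruthRecord(sid, "causative", reg.name, iv,
                                             reg.cnv_type))
                    if reg.phenotype and rng.random() < reg.p_phenotype_carrier:
                        phen.add(reg.phenotype)

            samples.append(Sample(sid, sex, cohort, frozenset(phen), True))
    return samples, calls, truth


# ----------------------------------------------------------------- evaluation

def evaluate_against_truth(classified, truth: Sequence[TruthRecord]) -> dict:
    """Confusion summary of pipeline output against the generating truth.

    Polymorphic events should come back non-causative, causative and
    aneuploidy events potentially-causative. Calls are matched to truth
    records by (sample, chromosome, type, >=1 bp overlap). Also reports the
    estimated vs generating carrier frequency per named event.
    """
    from .intervals import overlap_bp

    by_sample: dict[tuple, list[TruthRecord]] = {}
    for t in truth:
        by_sample.setdefault((t.sample_id, t.interval.chrom, t.cnv_type),
                             []).append(t)

    cats = {"polymorphic": {"n": 0, "recovered": 0},
            "causative": {"n": 0, "recovered": 0},
            "aneuploidy": {"n": 0, "recovered": 0}}
    unmatched = 0
    for cc in classified:
        key = (cc.sample_id, cc.interval.chrom, cc.cnv_type)
        match = None
        for t in by_sample.get(key, []):
            if overlap_bp(t.interval, cc.interval) > 0:
                match = t
                break
        if match is None:
            unmatched += 1
            continue
        want = ("non_causative" if match.category == "polymorphic"
                else "potentially_causative")
        cats[match.category]["n"] += 1
        if cc.causative_status == want:
            cats[match.category]["recovered"] += 1
    for v in cats.values():
        v["rate"] = v["recovered"] / v["n"] if v["n"] else None
    return {"by_category": cats, "n_unmatched_calls": unmatched,
            "n_truth_events": len(truth)}


def observed_event_frequency(truth: Sequence[TruthRecord], event: str,
                             cohort_samples: Sequence[Sample]) -> float:
    """Fraction of `cohort_samples` carrying `event` in the truth table."""
    ids = {s.sample_id for s in cohort_samples}
    carriers = {t.sample_id for t in truth
                if t.event == event and t.sample_id in ids}
    return len(carriers) / len(ids)


# ------------------------------------------------------------------ config IO

def load_config(path) -> SimConfig:
    """Load a SimConfig from YAML (keys mirror the dataclass fields)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "genome" in raw:
        raw["genome"] = tuple(tuple(x) for x in raw["genome"])
    for key in ("polymorphic", "causative"):
        if key in raw:
            raw[key] = tuple(SimRegion(**d) for d in raw[key])
    if raw.get("aneuploidy") is not None and "aneuploidy" in raw:
        raw["aneuploidy"] = AneuploidySpec(**raw["aneuploidy"])
    return SimConfig(**raw)


def write_simulated(config: SimConfig, outdir) -> dict[str, Path]:
    """Run the simulator and write every output in the formats the readers
    consume (TSV/BED/cytoband text). Deterministic given (config, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    build, popdb, clindb, genes, bands = generate_reference(config)
    samples, calls, truth = generate_cohort(config)
    paths = {}

    p = outdir / "genome_build.tsv"
    with open(p, "w") as fh:
        fh.write(f"#name={build.name}\n")
        fh.write("chrom\tlength\tcovered_start\tcovered_end\n")
        for c in build.chromosomes:
            fh.write(f"{c.name}\t{c.length}\t{c.covered_start}\t"
                     f"{c.covered_end}\n")
    paths["genome_build"] = p

    p = outdir / "popdb.tsv"
    with open(p, "w") as fh:
        fh.write("#kind=population\n#coords=0-based\n")
        fh.write("chrom\tstart\tend\tcnv_type\tfrequency\n")
        for r in popdb.records:
            fh.write(f"{r.interval.chrom}\t{r.interval.start}\t"
                     f"{r.interval.end}\t{r.cnv_type}\t{r.frequency}\n")
    paths["popdb"] = p

    p = outdir / "clindb.tsv"
    with open(p, "w") as fh:
        fh.write("#kind=clinical\n#coords=0-based\n"
                 f"#n_total_records={clindb.n_total_records}\n")
        fh.write("chrom\tstart\tend\tcnv_type\tn_records\tphenotypes\n")
        for r in clindb.records:
            fh.write(f"{r.interval.chrom}\t{r.interval.start}\t"
                     f"{r.interval.end}\t{r.cnv_type}\t{r.n_records}\t"
                     f"{';'.join(sorted(r.phenotypes))}\n")
    paths["clindb"] = p

    p = outdir / "genes.bed"
    with open(p, "w") as fh:
        for r in genes.itertuples():
            fh.write(f"chr{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\t0\t"
                     f"{r.strand}\n")
    paths["genes"] = p

    p = outdir / "cytobands.txt"
    with open(p, "w") as fh:
        for r in bands.itertuples():
            fh.write(f"chr{r.chrom}\t{r.start}\t{r.end}\t{r.band}\t"
                     f"{r.stain}\n")
    paths["cytobands"] = p

    p = outdir / "sample_sheet.tsv"
    with open(p, "w") as fh:
        fh.write("sample_id\tsex\tcohort\tphenotypes\tqc_pass\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.sex}\t{s.cohort}\t"
                     f"{';'.join(sorted(s.phenotypes))}\t"
                     f"{'true' if s.qc_pass else 'false'}\n")
    paths["sample_sheet"] = p

    p = outdir / "cnv_calls.tsv"
    with open(p, "w") as fh:
        fh.write("sample_id\tchrom\tstart\tend\tcnv_type\tmarker_count\n")
        for c in calls:
            chrom, s1, e1 = c.interval.to_table_coords()
            fh.write(f"{c.sample_id}\t{chrom}\t{s1}\t{e1}\t{c.cnv_type}\t"
                     f"{c.marker_count}\n")
    paths["cnv_calls"] = p

    p = outdir / "truth.tsv"
    with open(p, "w") as fh:
        fh.write("sample_id\tcategory\tevent\tchrom\tstart\tend\tcnv_type\n")
        for t in truth:
            fh.write(f"{t.sample_id}\t{t.category}\t{t.event}\t"
                     f"{t.interval.chrom}\t{t.interval.start}\t"
                     f"{t.interval.end}\t{t.cnv_type}\n")
    paths["truth"] = p
    return paths
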