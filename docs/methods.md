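# Methods

## Scope and model

`cnvcohort` operates strictly downstream of CNV calling: its inputs are
per-sample segment calls (interval, gain/loss, supporting marker count) as
exported by array analysis software, a sample sheet, and reference CNV
collections. It does not model probe intensities, segmentation or calling
noise beyond breakpoint jitter.

The analysis chain is: sample QC → call filtering → population-database
classification → CNVR clustering and cohort frequencies → aneuploidy
detection → annotation → cohort summary. Each stage is a pure function of
its inputs; the whole pipeline is deterministic, and output files are
byte-identical across reruns.

## Coordinate conventions

Internally every interval is 0-based half-open. Array-export tables and
the bundled cohort tables are 1-based inclusive; conversion happens only
in the readers/writers, so a printed pair (start, end) has length
`end − start + 1`. This is the common vendor convention and is consistent
with every printed kb size in the bundled tables (all 65 rows reproduce
exactly under round-half-up integer kb). Chromosome names are stored
without the `chr` prefix; both styles parse.

Rounding is decimal round-half-up everywhere a value is displayed:
integer kb for sizes, 2 decimals for summary percentages and ratios,
4 decimals for per-CNVR table frequencies. Python's default banker's
rounding would differ on exact halves.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_size_bp` | 200,000 | call kept iff length strictly greater (bp) |
| `min_probes` | 50 | call kept iff marker count ≥ this |
| `coverage_threshold` | 0.70 | non-causative iff db coverage ≥ this (inclusive) |
| `rare_threshold` | 1.0 % | rare iff cohort frequency < this |
| `cluster_ro` | 0.5 | single-linkage reciprocal-overlap threshold |
| `aneuploidy_fraction` | 0.80 | of the chromosome's covered span |
| `type_matched` | on | DUP matches gains, DEL matches losses |
| novelty presence | 0.10 | novel iff < this coverage in both databases |

Design choices where the underlying convention is genuinely open:

* **Coverage statistic.** "≥ 70% overlap with the population database" is
  implemented as fraction of the *query call* covered by the *union* of
  same-type records — the most permissive reading consistent with overlap
  against a database of many records. Single-record and reciprocal modes
  are deliberately not the default but the machinery (`db_coverage`,
  `reciprocal_overlap`) supports building them; type matching is a flag.
* **CNVR clustering at reciprocal 0.5, single linkage.** The bundled
  cohort's 39 chromosome-21 duplications differ in their distal
  breakpoints (42.7–46.7 Mb around a shared proximal end); their minimum
  pairwise reciprocal overlap is ≈ 0.881, so 0.5 merges them into one
  CNVR while keeping every distinct locus in the fixtures separate.
  Clustering is order-invariant: members are sorted before union-find and
  region ids derive from the union span.
* **Aneuploidy against the covered span, not chromosome length.** An
  acrocentric chromosome's p-arm carries no probes, so a complete trisomy
  present in the data covers only the declared probe territory; the
  genome-build file therefore declares a covered span per chromosome
  (e.g. chr21: 13.0–46.7 Mb) and the 0.80 threshold applies to it.
* **Novelty at 0.10 coverage** is a package convention for "essentially
  absent from both databases", not a claim about any published operational
  rule.
* **Clinical-db frequency** divides matching record counts by one fixed
  total-record denominator declared as a file pragma (all frequencies in a
  study are computed against the same database freeze), with the same
  0.70-coverage, type-matched match rule as classification. Clinical rows
  may carry an `n_records` multiplicity so one row stands for N patient
  records.
* **Filter boundaries.** "Larger than 200 kb" is strict `>`; "at least 50
  probes" is `≥`. The bundled SV table contains four sub-200 kb rows;
  since published tables sometimes retain calls the stated filter would
  drop, an `as_published` mode disables the size filter (marker filter
  still applies) so both behaviours are reproducible. The bundled
  reproduction uses that mode.

## Bundled cohort and synthetic reference files

The package ships a transcribed two-arm CHD cohort: per-CNV tables for
264 CAVC and 264 SV children (65 calls; 7 samples fail QC leaving
262 + 259), a 528-row sample sheet, and reference files. The population
and clinical databases, the gene model and the cytoband table are
*synthetic stand-ins* (so named in their filenames): their record
intervals are placed at the cohort's CNV coordinates such that the
pipeline's classification reproduces the tables' printed labels, clinical
record multiplicities match the printed per-region counts against the
38,367-record denominator, and band boundaries are placed so every call
resolves to its printed cytogenetic label. Chromosome lengths in the
genome-build file are real GRCh38 values; covered spans are the package's
declaration. These files exercise the machinery faithfully but are not
excerpts of DGV, DECIPHER, RefSeq or the UCSC cytoband track, and gene
content is a small curated subset — whole-genome gene counts are out of
scope.

## Synthetic cohort simulator

`simulate.SimConfig` defaults define the emulated study conditions:
two cohorts of 262 and 259 samples; four polymorphic CNVs of 0.8–1.2 Mb
at population frequencies 0.02–0.30; two rare causative CNVs at 0.4%
carrier frequency; a whole-covered-span chromosome-21 duplication in
14.9% of the first cohort with female:male odds 1.6 among carriers and a
phenotype code (PH) at probability 0.41 in carriers vs 0.10 in
non-carrier cohort members; probe density 0.10 probes/kb (the density
implied by ~3,400 markers on a ~33.6 Mb call); Gaussian breakpoint jitter
(sd 20 kb, truncated at ±3 sd, clipped to the chromosome) and a larger
distal-breakpoint jitter (sd 1.2 Mb, floored at 85% of the covered span)
for the aneuploidy calls, mimicking the variable distal ends of recurrent
whole-arm duplications. The scaled genome (four 50 Mb autosomes, X, Y,
and a 35 Mb acrocentric "21") keeps a full simulated cohort under a
second.

All randomness flows from one mandatory integer seed through a single
`numpy` generator; (config, seed) → byte-identical output files. The
truth table links every emitted call to its generating event, and
`evaluate_against_truth` reports per-category recovery plus frequency
errors.

What the simulator does **not** model: probe-level intensities, false or
split calls (beyond jitter), mosaicism, LOH, sex-chromosome dosage
effects, relatedness, or batch effects. Passing recovery tests therefore
demonstrates the correctness of the post-calling logic under clean calls
with realistic sampling noise — not robustness to caller artefacts.

## Verification strategy

* Interval primitives are property-tested against a base-by-base set
  oracle on small random instances (derandomised hypothesis), including
  symmetry, bounds and monotonicity.
* Every printed per-row and cohort-level statistic of the bundled tables
  is recomputed through the pipeline and asserted exactly: sizes for all
  65 rows, classification labels for all rows (driven purely by database
  coverage, labels hidden), CNVR counts, the 14.8855% recurrent-CNVR
  frequency, detection rates, sex ratios and phenotype co-occurrence.
* Calibration: over 20 seeds at study scale, every spiked event's
  estimated frequency lies within 3 binomial standard errors of its
  generating value, and the carrier/background phenotype rates recover
  0.41 / 0.10, in at least 19 of 20 seeds.

## Problem sizes

The bundled analysis is 65 calls over 521 samples and runs in well under
a second; the calibration suites simulate 20 cohorts of 521 samples each
and complete in a few seconds. These sizes were chosen as comfortably
sufficient for the binomial tolerances used.

## Known limitations

* Overlap semantics other than query-fraction-by-union (e.g. mutual-best
  reciprocal matching against the population database) are not the
  default anywhere; studies differ and results near the 0.70 boundary can
  depend on the choice.
* Single-linkage CNVR clustering can chain partially overlapping calls at
  a locus with gradually shifting breakpoints into one region.
* No liftover: all inputs must share one build.
* No inheritance (de novo vs transmitted) analysis and no ACMG-style
  pathogenicity scoring; "potentially causative" is a database-overlap
  statement only.
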