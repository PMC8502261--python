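"""Synthetic cohort simulator: determinism, calibration, truth recovery."""
import math

import pytest

import cnvcohort as cc
from cnvcohort.simulate import AneuploidySpec, SimConfig, SimRegion


def small_config(seed=0, **kw):
    base = dict(
        seed=seed,
        n_samples={"CAVC": 60, "SV": 50},
        polymorphic=(SimRegion("1", 10_000_000, 10_800_000, "DEL", 0.2,
                               "poly_1"),),
        causative=(SimRegion("2", 40_000_000, 41_500_000, "DEL", 0.05,
                             "causal_del", cohorts=("CAVC",)),),
    )
    base.update(kw)
    return SimConfig(**base)


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        a = cc.write_simulated(small_config(seed=3), tmp_path / "a")
        b = cc.write_simulated(small_config(seed=3), tmp_path / "b")
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes(), key

    def test_different_seeds_differ(self, tmp_path):
        a = cc.write_simulated(small_config(seed=3), tmp_path / "a")
        b = cc.write_simulated(small_config(seed=4), tmp_path / "b")
        assert a["cnv_calls"].read_bytes() != b["cnv_calls"].read_bytes()

    def test_reference_has_no_randomness(self):
        cfg = small_config(seed=1)
        _, pop1, clin1, *_ = cc.generate_reference(cfg)
        _, pop2, clin2, *_ = cc.generate_reference(small_config(seed=99))
        assert pop1.records == pop2.records
        assert clin1.records == clin2.records

    def test_popdb_frequencies_equal_config(self):
        cfg = small_config()
        _, popdb, *_ = cc.generate_reference(cfg)
        assert [r.frequency for r in popdb.records] \
            == [r.frequency for r in cfg.polymorphic]


class TestGeneration:
    def test_zero_jitter_shares_breakpoints(self):
        cfg = small_config(seed=5, jitter_sd=0, aneuploidy=None)
        _, calls, truth = cc.generate_cohort(cfg)
        poly = [c.interval for c in calls if c.interval.chrom == "1"]
        assert len(set(poly)) == 1

    def test_jitter_varies_breakpoints(self):
        cfg = small_config(seed=5, aneuploidy=None,
                           n_samples={"CAVC": 200, "SV": 0})
        _, calls, _ = cc.generate_cohort(cfg)
        poly = [c.interval for c in calls if c.interval.chrom == "1"]
        assert len(set(poly)) > 1

    def test_zero_polymorphic_regions(self):
        cfg = small_config(polymorphic=())
        _, calls, truth = cc.generate_cohort(cfg)
        assert all(t.category in ("causative", "aneuploidy") for t in truth)
        assert len(calls) == len(truth)

    def test_every_call_traces_to_truth(self):
        _, calls, truth = cc.generate_cohort(small_config(seed=2))
        assert len(calls) == len(truth)
        for c, t in zip(calls, truth):
            assert c.sample_id == t.sample_id and c.interval == t.interval

    def test_frequency_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SimRegion("1", 0, 100, "DUP", 1.5)

    def test_aneuploidy_carrier_count_in_binomial_bounds(self):
        cfg = SimConfig(seed=7)
        _, _, truth = cc.generate_cohort(cfg)
        k = len({t.sample_id for t in truth if t.category == "aneuploidy"})
        n, p = 262, 0.149
        sd = math.sqrt(n * p * (1 - p))
        # central 99.9% binomial interval (normal approximation, z=3.29)
        assert abs(k - n * p) <= 3.29 * sd

    def test_aneuploidy_calls_cover_declared_span(self):
        cfg = SimConfig(seed=7)
        build = cfg.build()
        _, calls, truth = cc.generate_cohort(cfg)
        c21 = build.chromosome("21")
        for t in truth:
            if t.category == "aneuploidy":
                frac = (t.interval.end - t.interval.start) / c21.covered_span
                assert frac >= 0.85


class TestTruthEvaluation:
    def run_pipeline(self, cfg):
        build, popdb, clindb, genes, bands = cc.generate_reference(cfg)
        samples, calls, truth = cc.generate_cohort(cfg)
        res = cc.run_pipeline(calls, samples, popdb, build, clindb=clindb)
        return res, truth

    def test_perfectly_separable_config(self):
        """Polymorphic regions fully in the popdb, causative absent:
        classification recovers every truth category."""
        cfg = small_config(seed=11, jitter_sd=0)
        res, truth = self.run_pipeline(cfg)
        ev = cc.evaluate_against_truth(res.classified, truth)
        assert ev["n_unmatched_calls"] == 0
        for cat in ("polymorphic", "causative", "aneuploidy"):
            if ev["by_category"][cat]["n"]:
                assert ev["by_category"][cat]["rate"] == 1.0

    def test_069_coverage_stays_potentially_causative(self):
        """A causative region 69%-covered by the popdb must not flip."""
        cfg = small_config(seed=11, jitter_sd=0)
        reg = cfg.causative[0]
        build, popdb, clindb, *_ = cc.generate_reference(cfg)
        span = reg.end - reg.start
        decoy = cc.DbRecord(
            cc.GenomicInterval(reg.chrom, reg.start,
                               reg.start + int(0.69 * span)),
            reg.cnv_type, frequency=0.01)
        popdb = cc.ReferenceDb("population", popdb.records + (decoy,))
        samples, calls, truth = cc.generate_cohort(cfg)
        res = cc.run_pipeline(calls, samples, popdb, build)
        ev = cc.evaluate_against_truth(res.classified, truth)
        assert ev["by_category"]["causative"]["rate"] in (1.0, None)

    def test_empty_cohort(self):
        ev = cc.evaluate_against_truth([], [])
        assert ev["n_truth_events"] == 0
        assert all(v["n"] == 0 for v in ev["by_category"].values())


N_CALIBRATION_SEEDS = 20


@pytest.fixture(scope="module")
def calibration_runs():
    out = []
    for seed in range(N_CALIBRATION_SEEDS):
        cfg = SimConfig(seed=seed)
        build, popdb, clindb, *_ = cc.generate_reference(cfg)
        samples, calls, truth = cc.generate_cohort(cfg)
        res = cc.run_pipeline(calls, samples, popdb, build)
        out.append((cfg, samples, res, truth))
    return out


class TestCalibrationRecovery:
    """Defaults emulate the study cohort: the pipeline's estimates must
    recover the generating parameters across seeds."""

    N_SEEDS = N_CALIBRATION_SEEDS

    def test_aneuploidy_frequency_recovery(self, calibration_runs):
        """|estimated - 0.149| <= 3 binomial SE in >= 19 of 20 seeds."""
        p = 0.149
        tol = 3 * math.sqrt(p * (1 - p) / 262)
        ok = 0
        for cfg, samples, res, truth in calibration_runs:
            flagged = {f.sample_id for f in res.aneuploidy_flags
                       if f.chrom == "21" and f.direction == "gain"}
            est = len(flagged) / 262
            ok += abs(est - p) <= tol
        assert ok >= self.N_SEEDS - 1

    def test_polymorphic_frequency_recovery(self, calibration_runs):
        """Per spiked region, CNVR carrier frequency recovers the
        generating population frequency within 3 binomial SE."""
        ok = 0
        for cfg, samples, res, truth in calibration_runs:
            n = sum(cfg.n_samples.values())
            good = True
            for reg in cfg.polymorphic:
                carriers = set()
                for r in res.cnvrs:
                    if (r.interval.chrom == reg.chrom
                            and r.cnv_type == reg.cnv_type
                            and r.interval.start < reg.end
                            and r.interval.end > reg.start):
                        carriers |= r.carriers
                est = len(carriers) / n
                tol = 3 * math.sqrt(reg.frequency * (1 - reg.frequency) / n)
                good &= abs(est - reg.frequency) <= tol
            ok += good
        assert ok >= self.N_SEEDS - 1

    def test_phenotype_effect_recovery(self, calibration_runs):
        """PH rate: ~0.41 among trisomy-like carriers vs ~0.10 background;
        both point estimates within 3 SE, and the difference visible, in
        >= 19 of 20 seeds."""
        ok = 0
        for cfg, samples, res, truth in calibration_runs:
            an = cfg.aneuploidy
            carriers = {f.sample_id for f in res.aneuploidy_flags}
            cohort = [s for s in samples if s.cohort == an.cohort]
            grp_c = [s for s in cohort if s.sample_id in carriers]
            grp_b = [s for s in cohort if s.sample_id not in carriers]
            _, pct_c = cc.phenotype_cooccurrence(grp_c, "PH")
            _, pct_b = cc.phenotype_cooccurrence(grp_b, "PH")
            se_c = math.sqrt(0.41 * 0.59 / len(grp_c))
            se_b = math.sqrt(0.10 * 0.90 / len(grp_b))
            good = (abs(pct_c / 100 - 0.41) <= 3 * se_c
                    and abs(pct_b / 100 - 0.10) <= 3 * se_b
                    and pct_c > pct_b)
            ok += good
        assert ok >= self.N_SEEDS - 1
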