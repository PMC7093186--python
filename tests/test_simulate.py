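"""Cohort drawing, methylation drift model, and bisulfite read simulation."""

import numpy as np
import pandas as pd
import pytest

from nmrclock.panel import make_panel
from nmrclock.simulate import (
    DriftModel,
    draw_cohort,
    read_fastq,
    read_sample_sheet,
    simulate_reads,
    true_methylation,
    write_fastq,
    write_sample_sheet,
)


def flat_model(panel, m0, slope=0.0, **kw):
    m = len(panel.site_ids)
    return DriftModel(
        site_ids=list(panel.site_ids),
        m0=np.full(m, m0),
        slope=np.full(m, slope),
        **kw,
    )


class TestCohort:
    def test_ages_in_range_and_sorted(self):
        cohort = draw_cohort(24, 39, 1144, "liver", "set1", seed=7)
        ages = [s.age_weeks for s in cohort]
        assert len(cohort) == 24
        assert all(39 <= a <= 1144 for a in ages)
        assert ages == sorted(ages)
        assert all(s.tissue == "liver" and s.batch == "set1" for s in cohort)

    def test_degenerate_range(self):
        cohort = draw_cohort(2, 100, 100.0001, seed=0)
        assert all(abs(s.age_weeks - 100) < 0.001 for s in cohort)

    def test_determinism(self):
        assert draw_cohort(10, 39, 1144, seed=3) == draw_cohort(10, 39, 1144, seed=3)
        assert draw_cohort(10, 39, 1144, seed=3) != draw_cohort(10, 39, 1144, seed=4)

    def test_sample_sheet_round_trip(self, tmp_path):
        cohort = draw_cohort(5, 50, 900, "skin", "set2", seed=1)
        write_sample_sheet(cohort, tmp_path / "s.tsv")
        assert read_sample_sheet(tmp_path / "s.tsv") == cohort

    def test_sheet_non_numeric_age_names_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "sample_id\tage_weeks\ttissue\tbatch\n"
            "a\t100\tliver\tset1\n"
            "b\told\tliver\tset1\n"
        )
        with pytest.raises(ValueError, match="row 3.*'b'"):
            read_sample_sheet(path)


class TestTrueMethylation:
    def test_no_drift_no_noise_is_constant(self, small_panel):
        model = flat_model(small_panel, 0.4, sigma_b=0.0)
        cohort = draw_cohort(6, 39, 1144, seed=0)
        probs = true_methylation(small_panel, cohort, model, seed=0)
        assert np.allclose(probs.to_numpy(), 0.4)

    def test_linear_drift_arithmetic(self, small_panel):
        # m0=0.1, s=5e-4/week, r_liver=1, age=1000 -> p = 0.6
        model = flat_model(small_panel, 0.1, slope=5e-4, sigma_b=0.0)
        cohort = [s for s in draw_cohort(2, 999.9999, 1000.0001, seed=0)]
        probs = true_methylation(small_panel, cohort, model, seed=0)
        assert np.allclose(probs.to_numpy(), 0.6, atol=1e-4)

    def test_skin_drift_exactly_half_at_half_rate(self, small_panel):
        model = flat_model(
            small_panel, 0.1, slope=5e-4, sigma_b=0.0,
            tissue_rates={"liver": 1.0, "skin": 0.5},
        )
        age = 800.0
        from nmrclock.simulate import SampleMeta

        liver = [SampleMeta("L", age, "liver", "set1")]
        skin = [SampleMeta("S", age, "skin", "set1")]
        p_liver = true_methylation(small_panel, liver, model, seed=0).to_numpy()
        p_skin = true_methylation(small_panel, skin, model, seed=0).to_numpy()
        # oracle: direct formula evaluation
        assert np.allclose(p_liver - 0.1, 5e-4 * age)
        assert np.allclose(p_skin - 0.1, (p_liver - 0.1) / 2)

    def test_probabilities_clamped(self, small_panel):
        model = flat_model(small_panel, 0.9, slope=5e-4, sigma_b=0.0)
        cohort = draw_cohort(4, 39, 1144, seed=0)
        probs = true_methylation(small_panel, cohort, model, seed=0).to_numpy()
        assert probs.max() <= 1.0 and probs.min() >= 0.0


@pytest.fixture(scope="module")
def mini():
    panel = make_panel(2, 4, 80, seed=3)
    cohort = draw_cohort(2, 100, 900, seed=5)
    return panel, cohort


class TestReads:
    def _reads(self, panel, cohort, p, ce=1.0, err=0.0, coverage=30, seed=0):
        model = flat_model(
            panel, p, sigma_b=0.0, conversion_efficiency=ce,
            sequencing_error_rate=err, target_coverage=coverage,
        )
        probs = true_methylation(panel, cohort, model, seed=0)
        return simulate_reads(panel, cohort, probs, model, seed=seed), model

    def test_fully_methylated_keeps_all_cpg_c(self, mini):
        panel, cohort = mini
        (reads, truth), _ = self._reads(panel, cohort, p=1.0)
        for sample_reads in reads.values():
            for name, seq in sample_reads:
                rid = name.split("|")[1]
                for site in panel.sites_in_region(rid):
                    assert seq[site.offset] == "C"
        assert (truth["n_meth_drawn"] == truth["n_reads"]).all()

    def test_fully_unmethylated_reads_t_at_cpg(self, mini):
        panel, cohort = mini
        (reads, truth), _ = self._reads(panel, cohort, p=0.0)
        for sample_reads in reads.values():
            for name, seq in sample_reads:
                rid = name.split("|")[1]
                for site in panel.sites_in_region(rid):
                    assert seq[site.offset] == "T"
        assert (truth["n_meth_drawn"] == 0).all()

    def test_no_c_outside_cpg_when_fully_converted(self, mini):
        panel, cohort = mini
        (reads, _), _ = self._reads(panel, cohort, p=1.0)
        for sample_reads in reads.values():
            for name, seq in sample_reads:
                rid = name.split("|")[1]
                cpg = {s.offset for s in panel.sites_in_region(rid)}
                for i, base in enumerate(seq):
                    if base == "C":
                        assert i in cpg

    def test_binomial_convergence_at_high_coverage(self):
        # p=0.3, coverage 10,000: C fraction within 3 binomial SE of 0.3
        panel = make_panel(1, 1, 50, seed=1)
        cohort = draw_cohort(2, 100, 900, seed=2)[:1]
        model = flat_model(
            panel, 0.3, sigma_b=0.0, conversion_efficiency=1.0,
            sequencing_error_rate=0.0, target_coverage=10_000,
        )
        probs = true_methylation(panel, cohort, model, seed=0)
        reads, truth = simulate_reads(panel, cohort, probs, model, seed=9)
        offset = panel.cpg_sites[0].offset
        frac_c = np.mean([seq[offset] == "C" for _, seq in reads[cohort[0].sample_id]])
        se = np.sqrt(0.3 * 0.7 / 10_000)
        assert abs(frac_c - 0.3) <= 3 * se
        # the simulator's own ledger agrees with the emitted reads exactly
        assert truth.loc[0, "n_meth_drawn"] == sum(
            seq[offset] == "C" for _, seq in reads[cohort[0].sample_id]
        )

    def test_seed_determinism_and_sensitivity(self, mini, tmp_path):
        panel, cohort = mini
        (ra, _), _ = self._reads(panel, cohort, p=0.5, err=0.001, seed=5)
        (rb, _), _ = self._reads(panel, cohort, p=0.5, err=0.001, seed=5)
        (rc, _), _ = self._reads(panel, cohort, p=0.5, err=0.001, seed=6)
        assert ra == rb
        assert ra != rc

    def test_fastq_round_trip(self, mini, tmp_path):
        panel, cohort = mini
        (reads, _), _ = self._reads(panel, cohort, p=0.5)
        sample = cohort[0].sample_id
        path = tmp_path / f"{sample}.fastq"
        write_fastq(reads[sample], path)
        assert read_fastq(path) == reads[sample]


def test_plant_marks_requested_number_of_admps(study_panel):
    model = DriftModel.plant(study_panel, n_admp=23, seed=2)
    assert int(model.is_admp.sum()) == 23
    assert np.all(np.abs(model.slope[model.is_admp]) >= 3e-4)
    truth = model.truth_table()
    assert list(truth.columns) == ["site_id", "m0", "slope", "is_admp"]
    assert truth["is_admp"].sum() == 23
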