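"""Read assignment, methylation counting, coverage filtering, matrix assembly."""

import math

import numpy as np
import pandas as pd
import pytest

from nmrclock.extract import (
    MethFileError,
    MethMatrix,
    _collapsed_reference,
    assign_reads,
    bisulfite_distance,
    build_matrix,
    count_methylation,
    extract_sample,
    filter_coverage,
    read_coverage_file,
    write_coverage_file,
)
from nmrclock.panel import make_panel
from nmrclock.simulate import DriftModel, SampleMeta, draw_cohort, simulate_reads, true_methylation


@pytest.fixture(scope="module")
def panel():
    return make_panel(4, 12, 120, seed=11)


def clean_model(panel, coverage=60):
    m = len(panel.site_ids)
    return DriftModel(
        site_ids=list(panel.site_ids),
        m0=np.full(m, 0.5),
        slope=np.zeros(m),
        sigma_b=0.0,
        conversion_efficiency=1.0,
        sequencing_error_rate=0.0,
        target_coverage=coverage,
    )


@pytest.fixture(scope="module")
def clean_reads(panel):
    model = clean_model(panel)
    cohort = draw_cohort(3, 100, 900, seed=4)
    probs = true_methylation(panel, cohort, model, seed=1)
    reads, truth = simulate_reads(panel, cohort, probs, model, seed=8)
    return cohort, reads, truth, model


class TestAssignment:
    def test_exact_provenance(self, panel, clean_reads):
        cohort, reads, _, _ = clean_reads
        result = assign_reads(reads[cohort[0].sample_id], panel)
        assert result.n_discarded == 0
        for rid, group in result.groups.items():
            for name, _ in group:
                assert name.split("|")[1] == rid

    def test_conservation(self, panel, clean_reads):
        cohort, reads, _, _ = clean_reads
        result = assign_reads(reads[cohort[0].sample_id], panel)
        assert result.n_assigned + result.n_discarded == len(reads[cohort[0].sample_id])

    def test_random_sequence_discarded(self, panel):
        # oracle: explicit Hamming distance against every collapsed reference
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=120))
        refs = [
            _collapsed_reference(r.sequence, [s.offset for s in panel.sites_in_region(r.region_id)])
            for r in panel.regions
        ]
        dists = [bisulfite_distance(seq, ref, wc) for ref, wc in refs]
        assert min(dists) > math.ceil(0.1 * len(seq))  # sanity of the oracle itself
        result = assign_reads([("rand", seq)], panel)
        assert result.n_discarded == 1 and result.n_assigned == 0

    def test_empty_input_is_not_an_error(self, panel):
        result = assign_reads([], panel)
        assert result.n_total == 0
        assert all(len(g) == 0 for g in result.groups.values())


class TestCounting:
    def test_all_c_and_mixed_fractions(self, panel):
        region = panel.regions[0]
        site = panel.sites_in_region(region.region_id)[0]
        base = list(region.sequence)

        def read_with(b):
            s = base.copy()
            s[site.offset] = b
            return "".join(s)

        groups = {region.region_id: [(f"r{i}", read_with("C")) for i in range(10)]}
        recs = count_methylation(groups, panel, "s1").set_index("site_id")
        assert recs.loc[site.site_id, "count_methylated"] == 10
        assert recs.loc[site.site_id, "count_unmethylated"] == 0

        groups = {
            region.region_id: [(f"r{i}", read_with("C")) for i in range(7)]
            + [(f"t{i}", read_with("T")) for i in range(3)]
        }
        recs = count_methylation(groups, panel, "s1").set_index("site_id")
        assert recs.loc[site.site_id, "count_methylated"] == 7
        assert recs.loc[site.site_id, "count_unmethylated"] == 3

    def test_ambiguous_base_excluded_from_both_counts(self, panel):
        region = panel.regions[0]
        site = panel.sites_in_region(region.region_id)[0]
        s = list(region.sequence)
        s[site.offset] = "N"
        recs = count_methylation({region.region_id: [("r0", "".join(s))]}, panel, "s1")
        recs = recs.set_index("site_id")
        assert recs.loc[site.site_id, "count_methylated"] == 0
        assert recs.loc[site.site_id, "count_unmethylated"] == 0

    def test_short_read_does_not_reach_late_sites(self, panel):
        region = panel.regions[0]
        sites = sorted(panel.sites_in_region(region.region_id), key=lambda s: s.offset)
        short = region.sequence[: sites[-1].offset]  # stops before the last CpG
        recs = count_methylation({region.region_id: [("r0", short)]}, panel, "s1")
        recs = recs.set_index("site_id")
        cov = recs["count_methylated"] + recs["count_unmethylated"]
        assert cov.loc[sites[-1].site_id] == 0

    def test_count_conservation_against_simulator_ledger(self, panel, clean_reads):
        """error=0, conversion=1: extracted counts equal the per-read draws exactly."""
        cohort, reads, truth, model = clean_reads
        for sample in cohort:
            recs, assignment = extract_sample(reads[sample.sample_id], panel, sample.sample_id)
            assert assignment.n_discarded == 0
            merged = recs.merge(
                truth[truth.sample_id == sample.sample_id], on=["sample_id", "site_id"]
            )
            assert (merged.count_methylated == merged.n_meth_drawn).all()
            assert (
                merged.count_methylated + merged.count_unmethylated == merged.n_reads
            ).all()


class TestCoverageFilter:
    def records(self, covs):
        return pd.DataFrame(
            {
                "sample_id": ["s"] * len(covs),
                "site_id": [f"x:{i}" for i in range(len(covs))],
                "count_methylated": [c // 2 for c in covs],
                "count_unmethylated": [c - c // 2 for c in covs],
            }
        )

    def test_boundary_49_dropped_50_kept(self):
        out = filter_coverage(self.records([49, 50, 51]), min_coverage=50)
        assert list(out["missing"]) == [True, False, False]

    def test_identity_at_min_one(self):
        out = filter_coverage(self.records([1, 5, 10]), min_coverage=1)
        assert not out["missing"].any()

    def test_idempotent_and_monotone(self):
        recs = self.records(list(range(40, 70)))
        once = filter_coverage(recs, 50)
        twice = filter_coverage(once, 50)
        pd.testing.assert_frame_equal(once, twice)
        stricter = filter_coverage(recs, 60)
        # raising the threshold never un-hides a cell
        assert (stricter["missing"] | ~once["missing"]).all() or (
            stricter["missing"][once["missing"]].all()
        )
        assert stricter["missing"][once["missing"]].all()


class TestMatrix:
    def test_complete_records(self):
        cohort = [SampleMeta("a", 100, "liver", "set1"), SampleMeta("b", 200, "liver", "set1")]
        recs = pd.DataFrame(
            [
                ("a", "x:1", 60, 40), ("a", "x:2", 30, 70), ("a", "x:3", 55, 55),
                ("b", "x:1", 80, 20), ("b", "x:2", 10, 90), ("b", "x:3", 20, 30),
            ],
            columns=["sample_id", "site_id", "count_methylated", "count_unmethylated"],
        )
        m = build_matrix(recs, cohort, ["x:1", "x:2", "x:3"], min_coverage=50)
        assert m.fraction.shape == (2, 3)
        # independently recomputed ratios
        assert m.fraction.loc["a", "x:1"] == pytest.approx(60 / 100)
        assert m.fraction.loc["b", "x:2"] == pytest.approx(10 / 100)
        # (b, x:3) has coverage 50 -> kept at exactly the cut-off
        assert m.fraction.loc["b", "x:3"] == pytest.approx(20 / 50)
        assert m.fraction.notna().all().all()

    def test_low_coverage_cell_missing(self):
        cohort = [SampleMeta("a", 100, "liver", "set1")]
        recs = pd.DataFrame(
            [("a", "x:1", 60, 40), ("a", "x:2", 20, 29)],
            columns=["sample_id", "site_id", "count_methylated", "count_unmethylated"],
        )
        m = build_matrix(recs, cohort, ["x:1", "x:2"], min_coverage=50)
        assert m.fraction["x:2"].isna().all()
        assert m.coverage.loc["a", "x:2"] == 49  # raw coverage retained

    def test_duplicate_record_raises(self):
        cohort = [SampleMeta("a", 100, "liver", "set1")]
        recs = pd.DataFrame(
            [("a", "x:1", 60, 40), ("a", "x:1", 61, 39)],
            columns=["sample_id", "site_id", "count_methylated", "count_unmethylated"],
        )
        with pytest.raises(ValueError, match="duplicate"):
            build_matrix(recs, cohort, ["x:1"])

    def test_matrix_tsv_round_trip(self, tmp_path):
        frac = pd.DataFrame(
            [[0.5, np.nan], [0.25, 0.75]], index=["a", "b"], columns=["x:1", "x:2"]
        )
        m = MethMatrix(frac)
        m.to_tsv(tmp_path / "m.tsv")
        back = MethMatrix.from_tsv(tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(back.fraction, frac)


class TestCoverageFiles:
    def test_round_trip(self, tmp_path):
        recs = pd.DataFrame(
            [("s1", "JH602136:8746439", 88, 12), ("s1", "JH602136:8746500", 0, 55)],
            columns=["sample_id", "site_id", "count_methylated", "count_unmethylated"],
        )
        path = tmp_path / "s1.cov"
        write_coverage_file(recs, path)
        back = read_coverage_file(path, "s1")
        pd.testing.assert_frame_equal(back, recs)

    def test_parse_known_line(self, tmp_path):
        path = tmp_path / "x.cov"
        path.write_text("JH602136\t8746439\t8746439\t88.0\t88\t12\n")
        recs = read_coverage_file(path, "s")
        assert recs.loc[0, "site_id"] == "JH602136:8746439"
        assert recs.loc[0, "count_methylated"] == 88
        assert recs.loc[0, "count_unmethylated"] == 12

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.cov"
        path.write_text("JH1\t10\t10\t50.0\t5\t5\nJH1\t20\t20\t50.0\n")
        with pytest.raises(MethFileError, match="line 2"):
            read_coverage_file(path, "s")

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "neg.cov"
        path.write_text("JH1\t10\t10\t50.0\t-5\t5\n")
        with pytest.raises(MethFileError, match="negative"):
            read_coverage_file(path, "s")

    def test_inconsistent_percent_warns(self, tmp_path):
        path = tmp_path / "warn.cov"
        path.write_text("JH1\t10\t10\t90.0\t5\t5\n")
        with pytest.warns(UserWarning, match="inconsistent"):
            read_coverage_file(path, "s")


def test_extraction_recovers_probabilities_within_binomial_error(panel):
    """sigma_b=0: extracted fractions within 3*sqrt(p(1-p)/cov) for >=99% of cells."""
    model = clean_model(panel, coverage=200)
    model.m0[:] = np.linspace(0.2, 0.8, len(panel.site_ids))
    cohort = draw_cohort(10, 100, 1100, seed=5)
    probs = true_methylation(panel, cohort, model, seed=1)
    reads, _ = simulate_reads(panel, cohort, probs, model, seed=2)
    recs = pd.concat(
        [extract_sample(reads[s.sample_id], panel, s.sample_id)[0] for s in cohort],
        ignore_index=True,
    )
    m = build_matrix(recs, cohort, panel.site_ids, min_coverage=50)
    p = probs.to_numpy()
    f = m.fraction.to_numpy()
    se = np.sqrt(p * (1 - p) / 200)
    ok = np.abs(f - p) <= 3 * se
    assert ok.mean() >= 0.99
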