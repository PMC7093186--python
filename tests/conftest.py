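import numpy as np
import pytest

from nmrclock.panel import make_panel
from nmrclock.simulate import DriftModel, draw_cohort, true_methylation


@pytest.fixture(scope="session")
def small_panel():
    """Four regions, twelve CpGs: big enough to exercise round-robin placement."""
    return make_panel(n_regions=4, total_cpgs=12, region_length=120, seed=11)


@pytest.fixture(scope="session")
def study_panel():
    """The study geometry: 12 amplicons, 51 CpGs."""
    return make_panel(n_regions=12, total_cpgs=51, region_length=300, seed=1)


@pytest.fixture(scope="session")
def drift_model(study_panel):
    return DriftModel.plant(study_panel, n_admp=23, seed=2)


@pytest.fixture(scope="session")
def liver_cohort():
    return draw_cohort(24, 39, 1144, "liver", "set1", seed=7)


@pytest.fixture(scope="session")
def liver_probs(study_panel, liver_cohort, drift_model):
    return true_methylation(study_panel, liver_cohort, drift_model, seed=3)


def study_instance(seed, n_liver=24, n_skin=0, coverage=200, sigma_b=0.03,
                   skin_rate=0.6, n_admp=23):
    """One synthetic study replicate: panel, drift model, cohorts, fractions.

    Returns a dict with liver (and optionally skin) fraction DataFrames from
    binomial count sampling at the given coverage, plus the planted truth.
    """
    from nmrclock.simulate import binomial_counts

    ss = np.random.SeedSequence(seed).generate_state(8) % (2**31)
    panel = make_panel(12, 51, 300, seed=int(ss[0]))
    model = DriftModel.plant(
        panel, n_admp=n_admp, seed=int(ss[1]), sigma_b=sigma_b,
        tissue_rates={"liver": 1.0, "skin": skin_rate}, target_coverage=coverage,
    )
    liver = draw_cohort(n_liver, 39, 1144, "liver", "set1", seed=int(ss[2]))
    p_liver = true_methylation(panel, liver, model, seed=int(ss[3]))
    frac_liver = binomial_counts(p_liver, coverage, seed=int(ss[4]))[0] / coverage
    out = {
        "panel": panel,
        "model": model,
        "liver": liver,
        "liver_ages": np.array([s.age_weeks for s in liver]),
        "liver_frac": frac_liver,
    }
    if n_skin:
        skin = draw_cohort(n_skin, 43, 1196, "skin", "set2", seed=int(ss[5]))
        p_skin = true_methylation(panel, skin, model, seed=int(ss[6]))
        out["skin"] = skin
        out["skin_ages"] = np.array([s.age_weeks for s in skin])
        out["skin_frac"] = binomial_counts(p_skin, coverage, seed=int(ss[7]))[0] / coverage
    return out
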