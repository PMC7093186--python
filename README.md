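# nmrclock

Epigenetic-clock analysis for targeted bisulfite amplicon sequencing in the
naked mole-rat (*Heterocephalus glaber*), the longest-lived rodent. The
package covers the full analysis path: simulating age-structured bisulfite
amplicon data, quantifying per-CpG methylation from reads, screening CpGs for
age association (aDMPs — ageing-associated differentially methylated
positions), fitting and cross-validating an elastic-net chronological-age
predictor, and comparing epigenetic ageing rates between tissues.

It is written for researchers who need an age estimate for animals of unknown
provenance — wild-caught or unpedigreed captive naked mole-rats — from a small
targeted panel (12 amplicons, 51 CpGs), and for anyone who wants a fully
seeded, testable re-implementation of that style of clock analysis.

## The model

Methylation at an ageing-associated CpG *j* drifts linearly with age:

```
m_ij = m0_j + s_j · r_t(i) · age_i + ε_ij,      ε_ij ~ N(0, σ_b²)
```

where `m0_j` is the baseline fraction, `s_j` the drift slope
(fraction/week), `r_t` a tissue rate multiplier (liver = 1 by convention) and
`σ_b` biological noise. Reads sampled from a sample's methylation state give
binomial counts per CpG; sites with coverage < 50× are discarded.

Per-CpG screening regresses methylation on age (two-sided t-test on the
slope, *n* − 2 df); sites with p < 0.05 (no multiple-testing correction) are
the aDMPs. The clock is then the elastic net

```
min_β  (1/2n) Σ_i (age_i − β₀ − x_iᵀβ)²  +  λ (α‖β‖₁ + (1−α)/2 ‖β‖₂²)
```

solved by cyclic coordinate descent (α = 0.5 by default, λ by the one-SE rule
over a log grid with leave-one-out folds). Accuracy is reported as Pearson R,
RMSE, MAD (mean absolute deviation) and MAE (median absolute error), all in
weeks. The ageing rate of a second tissue relative to the training tissue is
the OLS slope of predicted on actual age: a slope below 1 with a 95% CI
excluding 1 means that tissue's methylation drifts more slowly.

## Worked example

```python
import numpy as np
from nmrclock import (
    make_panel, DriftModel, draw_cohort, true_methylation, binomial_counts,
    screen_sites, select_admps, MethylationClock, estimate_tissue_rate,
)

# a 12-amplicon, 51-CpG panel with 23 age-drifting sites planted
panel = make_panel(n_regions=12, total_cpgs=51, region_length=300, seed=1)
drift = DriftModel.plant(panel, n_admp=23, seed=2)

# 24 livers spanning 39-1,144 weeks; methylation fractions at 200x coverage
liver = draw_cohort(24, 39, 1144, "liver", "set1", seed=3)
ages = np.array([s.age_weeks for s in liver])
probs = true_methylation(panel, liver, drift, seed=4)
fractions = binomial_counts(probs, coverage=200, seed=5)[0] / 200

# aDMP screening and clock fitting with leave-one-out cross-validation
admps = select_admps(screen_sites(fractions, ages), alpha=0.05)
print(f"{len(admps)} of 51 CpGs associated with age (p < 0.05)")

clock = MethylationClock(fractions[admps], ages, alpha_mix=0.5)
m = clock.loocv().metrics
print(f"LOOCV: R = {m.pearson_r:.3f}, RMSE = {m.rmse_weeks:.1f} wk, "
      f"MAD = {m.mad_weeks:.1f} wk, MAE = {m.mae_weeks:.1f} wk")

# apply the liver-trained clock to skin simulated at 0.6x the liver drift rate
skin = draw_cohort(20, 43, 1196, "skin", "set2", seed=6)
skin_frac = binomial_counts(
    true_methylation(panel, skin, drift, seed=7), 200, seed=8)[0] / 200
rate = estimate_tissue_rate(
    clock.fit().predict(skin_frac).to_numpy(),
    np.array([s.age_weeks for s in skin]))
print(f"skin ageing rate vs liver: {rate.slope:.2f} "
      f"(95% CI {rate.ci_low:.2f}-{rate.ci_high:.2f})")
```

Output:

```
25 of 51 CpGs associated with age (p < 0.05)
LOOCV: R = 0.995, RMSE = 32.8 wk, MAD = 25.8 wk, MAE = 23.3 wk
skin ageing rate vs liver: 0.56 (95% CI 0.53-0.58)
```

25 sites pass the screen: the 23 planted drifting CpGs plus two false
positives, consistent with the 5% per-site null rate over 28 null sites. The
leave-one-out error of ~33 weeks is small against the ~1,100-week age span,
and the skin slope recovers the simulated 0.6 rate multiplier with a CI that
excludes 1 — the signature of a tissue ageing more slowly than the one the
clock was trained on.

The same analysis runs from the shell: `nmrclock simulate / extract / select /
fit / predict / evaluate / rate`, or end to end with a manifest via
`nmrclock run --outdir DIR [--config cfg.yaml] [--seed N]`. Real data enter
as per-CpG count tables (Bismark-coverage-dialect TSV) or a fraction-matrix
TSV plus a sample sheet; see `nmrclock.load_study_tables`.

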