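"""Per-CpG age association and aDMP selection.

Each CpG is tested for a linear association between its methylation fraction
and chronological age: ordinary least squares of methylation on age gives the
drift slope, and the p-value is the two-sided t-test on that slope with
``n - 2`` degrees of freedom.  Because single-site prediction errors are
reported on the age scale (weeks), the inverse regression — age on
methylation — supplies in-sample residuals from which RMSE (root mean
squared), MAD (mean absolute) and MAE (median absolute) are computed.

Sites with p < alpha (strict, no multiple-testing correction) are selected as
ageing-associated differentially methylated positions (aDMPs), ordered by
ascending p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .extract import MethMatrix

__all__ = ["ADMPStat", "fit_site", "screen_sites", "select_admps"]


@dataclass(frozen=True)
class ADMPStat:
    """Association of one CpG's methylation with age.

    ``slope_meth_per_week``/``intercept`` are from the methylation-on-age OLS;
    ``age_rmse_weeks``/``age_mad_weeks``/``age_mae_weeks`` are in-sample
    errors of the inverse (age-on-methylation) regression, in weeks.  MAD is
    the mean absolute error and MAE the median absolute error, following the
    field's reporting convention for clock errors.
    """

    site_id: str
    n_used: int
    slope_meth_per_week: float
    intercept: float
    pearson_r: float
    p_value: float
    age_rmse_weeks: float
    age_mad_weeks: float
    age_mae_weeks: float
    usable: bool = True


def fit_site(fractions: np.ndarray, ages: np.ndarray, site_id: str = "") -> ADMPStat:
    """Test one site; missing fractions (NaN) are dropped pairwise."""
    fractions = np.asarray(fractions, dtype=float)
    ages = np.asarray(ages, dtype=float)
    keep = ~np.isnan(fractions) & ~np.isnan(ages)
    f, a = fractions[keep], ages[keep]
    n = f.size
    nan = float("nan")
    if n < 3 or np.ptp(a) == 0:
        return ADMPStat(site_id, n, nan, nan, nan, nan, nan, nan, nan, usable=False)
    if np.ptp(f) == 0:
        # flat methylation: no age signal by definition
        return ADMPStat(site_id, n, 0.0, float(f[0]), 0.0, 1.0, nan, nan, nan)
    fwd = stats.linregress(a, f)
    inv = stats.linregress(f, a)
    resid = a - (inv.intercept + inv.slope * f)
    return ADMPStat(
        site_id=site_id,
        n_used=n,
        slope_meth_per_week=float(fwd.slope),
        intercept=float(fwd.intercept),
        pearson_r=float(fwd.rvalue),
        p_value=float(fwd.pvalue),
        age_rmse_weeks=float(np.sqrt(np.mean(resid**2))),
        age_mad_weeks=float(np.mean(np.abs(resid))),
        age_mae_weeks=float(np.median(np.abs(resid))),
    )


def screen_sites(matrix: MethMatrix | pd.DataFrame, ages: np.ndarray) -> pd.DataFrame:
    """Run :func:`fit_site` for every column; one row per site."""
    frac = matrix.fraction if isinstance(matrix, MethMatrix) else matrix
    ages = np.asarray(ages, dtype=float)
    if len(ages) != len(frac.index):
        raise ValueError("ages must align with matrix rows")
    stats_rows = [
        asdict(fit_site(frac[sid].to_numpy(), ages, site_id=sid)) for sid in frac.columns
    ]
    return pd.DataFrame(stats_rows)


def select_admps(stats_df: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Sites with p-value strictly below ``alpha``, ordered by ascending p.

    No multiple-testing correction is applied; the raw per-site threshold is
    the published selection rule.  An empty selection is allowed (warned).
    """
    if stats_df.empty:
        raise ValueError("no site statistics supplied")
    ok = stats_df[stats_df.get("usable", True) & (stats_df["p_value"] < alpha)]
    ok = ok.sort_values(["p_value", "site_id"], kind="mergesort")
    selected = list(ok["site_id"])
    if not selected:
        warnings.warn(f"no site passed p < {alpha}", stacklevel=2)
    return selected
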