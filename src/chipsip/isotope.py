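"""Isotope-ratio conversion and hybridization-corrected enrichment (HCE).

delta notation: delta = [(R_meas / R_standard) - 1] * 1000, with R the
15N/14N ratio measured as 12C15N-/12C14N- ion counts and R_standard the
ratio in unhybridized regions of the array.

The HCE of a taxon under one treatment is the ordinary-least-squares slope
of spot delta (permil) on spot fluorescence over that taxon's probe set,
in permil per fluorescence unit. Because probe hybridization efficiency
scales both fluorescence and isotope signal, the slope corrects the raw
enrichment for hybridization strength; it is the per-taxon measure of
substrate incorporation compared across taxa and treatments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateDesignError, InsufficientDataError, ParameterError


def compute_delta(count_15N, count_14N, r_standard: float):
    """Convert raw ion counts to a delta value (permil).

    delta = (r_meas / r_standard - 1) * 1000 with r_meas = 15N / 14N.
    Accepts scalars or arrays; counts may be float (pre-aggregated).

    Raises
    ------
    ParameterError
        If ``r_standard`` is not positive or any 14N count is zero/negative
        (the ratio is undefined) or any count is negative.
    """
    if r_standard <= 0:
        raise ParameterError(f"r_standard must be positive, got {r_standard}")
    c15 = np.asarray(count_15N, dtype=float)
    c14 = np.asarray(count_14N, dtype=float)
    if np.any(c14 <= 0):
        raise ParameterError("count_14N must be positive: 15N/14N ratio undefined")
    if np.any(c15 < 0):
        raise ParameterError("count_15N must be nonnegative")
    r_meas = c15 / c14
    delta = (r_meas / r_standard - 1.0) * 1000.0
    if np.ndim(count_15N) == 0 and np.ndim(count_14N) == 0:
        return float(delta)
    return delta


def pooled_delta(counts_15N: Sequence[float], counts_14N: Sequence[float],
                 r_standard: float) -> float:
    """Delta of pooled replicate measurements: ratio of summed counts.

    Summing counts before taking the ratio (rather than averaging per-spot
    ratios) is the Poisson-stable aggregation for ion-counting data.
    """
    c15 = float(np.sum(np.asarray(counts_15N, dtype=float)))
    c14 = float(np.sum(np.asarray(counts_14N, dtype=float)))
    return compute_delta(c15, c14, r_standard)


@dataclass
class HceEstimate:
    """Per-taxon, per-treatment HCE regression result.

    ``slope`` is the HCE in permil per fluorescence unit; ``slope_se`` its
    OLS standard error (error bars in plots span two standard errors);
    ``enriched`` is set by :func:`flag_enrichment`.
    """

    taxon_id: str
    treatment: str
    slope: float
    slope_se: float
    intercept: float
    n_spots: int
    r_squared: float
    enriched: Optional[bool] = None
    mean_delta: float = float("nan")

    @property
    def two_se_halfwidth(self) -> float:
        return 2.0 * self.slope_se


def fit_hce(fluorescence, delta, taxon_id: str = "", treatment: str = "",
            min_spots: int = 3) -> HceEstimate:
    """OLS regression of spot delta on spot fluorescence for one probe set.

    Parameters
    ----------
    fluorescence, delta
        Spot-level arrays for a single taxon under a single treatment.
    min_spots
        Minimum number of spots (default 3; the slope SE needs df >= 1).

    Raises
    ------
    InsufficientDataError
        Fewer than ``min_spots`` spots.
    DegenerateDesignError
        All fluorescence values identical (slope undefined).
    """
    x = np.asarray(fluorescence, dtype=float)
    y = np.asarray(delta, dtype=float)
    if x.size != y.size:
        raise ParameterError("fluorescence and delta must have equal length")
    if x.size < min_spots:
        raise InsufficientDataError(
            f"{taxon_id}/{treatment}: {x.size} spots < minimum {min_spots}"
        )
    if np.ptp(x) == 0.0:
        raise DegenerateDesignError(
            f"{taxon_id}/{treatment}: all fluorescence values equal ({x[0]})"
        )

    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    intercept, slope = fit.params
    se = float(fit.bse[1])
    # rsquared is nan for a constant response; report 1.0 for the exact fit
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = float(fit.rsquared)
    if not np.isfinite(r2):
        r2 = 1.0 if np.allclose(fit.resid, 0.0) else 0.0
    r2 = min(max(r2, 0.0), 1.0)
    return HceEstimate(
        taxon_id=taxon_id,
        treatment=treatment,
        slope=float(slope),
        slope_se=se,
        intercept=float(intercept),
        n_spots=int(x.size),
        r_squared=r2,
        mean_delta=float(np.mean(y)),
    )


def flag_enrichment(est: HceEstimate, alpha: float = 0.05,
                    require_positive_mean: bool = True) -> bool:
    """Decide whether a probe set is significantly isotopically enriched.

    Default rule: one-sided t-test of slope > 0 at ``alpha``
    (t = slope / slope_se, df = n_spots - 2), and, when
    ``require_positive_mean``, mean delta > 0. A degenerate exact fit
    (slope_se = 0) with positive slope counts as enriched.
    """
    df = est.n_spots - 2
    if est.slope_se == 0.0:
        significant = est.slope > 0.0
    else:
        t = est.slope / est.slope_se
        significant = stats.t.sf(t, df) < alpha
    if require_positive_mean:
        significant = significant and est.mean_delta > 0.0
    return bool(significant)


def fit_taxon_hces(spots: pd.DataFrame, min_spots: int = 3,
                   enrichment_alpha: float = 0.05,
                   require_positive_mean: bool = True) -> list[HceEstimate]:
    """Fit HCE for every treatment present for one taxon's spots.

    ``spots`` must carry internal columns (taxon_id, treatment,
    fluorescence, delta_permil). Treatments with too few spots are skipped;
    a degenerate design still raises.
    """
    taxon = str(spots["taxon_id"].iloc[0]) if len(spots) else ""
    out: list[HceEstimate] = []
    for treatment, grp in spots.groupby("treatment", observed=True):
        if len(grp) < min_spots:
            continue
        est = fit_hce(grp["fluorescence"], grp["delta_permil"],
                      taxon_id=taxon, treatment=str(treatment),
                      min_spots=min_spots)
        est.enriched = flag_enrichment(est, alpha=enrichment_alpha,
                                       require_positive_mean=require_positive_mean)
        out.append(est)
    return out
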