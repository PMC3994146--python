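"""Activity classes and trophic-guild classification.

Two orthogonal groupings of taxa:

* **Activity** — ranked by HCE at one reference concentration; taxa at or
  above ``cutoff_fraction`` times the maximum (default 50%) are HIGH, the
  rest LOW.
* **Trophic guild** — the shape of the incorporation response across the
  three substrate concentrations H > M > L, decided by an analysis of
  covariance (delta on fluorescence with treatment terms) followed by
  directional pairwise post-hoc tests:

  ========================  =============================================
  label                     incorporation pattern
  ========================  =============================================
  NULL_HML   ("H≈M≈L")      saturated at the lowest tested concentration
                            (oligotroph-like) or activity below detection
  INTERMEDIATE ("H≈M>L")    saturated only at the highest concentration
  COPIOTROPH ("H>M>L")      unsaturated at every tested concentration
  OTHER                     patterns outside this taxonomy
  ========================  =============================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import TREATMENTS
from .errors import InsufficientDataError
from .isotope import HceEstimate, fit_hce

GUILD_NULL = "NULL_HML"
GUILD_INTERMEDIATE = "INTERMEDIATE"
GUILD_COPIOTROPH = "COPIOTROPH"
GUILD_OTHER = "OTHER"
GUILDS = (GUILD_NULL, GUILD_INTERMEDIATE, GUILD_COPIOTROPH, GUILD_OTHER)

#: Human-readable pattern for each guild label.
GUILD_PATTERNS = {
    GUILD_NULL: "H≈M≈L",
    GUILD_INTERMEDIATE: "H≈M>L",
    GUILD_COPIOTROPH: "H>M>L",
    GUILD_OTHER: "other",
}

# relative tolerance deciding when a residual-sum-of-squares difference is
# numerically zero (exact-fit synthetic data produces SSR == 0 designs)
_SSR_RTOL = 1e-10


@dataclass
class ActivityClass:
    taxon_id: str
    hce_reference: float
    activity: str  # "HIGH" or "LOW"


@dataclass
class AncovaResult:
    """Joint concentration-effect test for one taxon."""

    taxon_id: str
    p_value: float
    f_stat: float
    df_num: int
    df_den: int
    levels: tuple
    partial: bool  # True when a treatment level was missing/unusable


@dataclass
class GuildAssignment:
    taxon_id: str
    guild: str
    ancova_p: float
    posthoc: frozenset = frozenset()  # significant ordered (higher, lower) pairs
    partial: bool = False


def rank_activity(hces: Sequence[HceEstimate], cutoff_fraction: float = 0.5
                  ) -> tuple[list[ActivityClass], pd.DataFrame]:
    """Rank enriched taxa by reference-treatment HCE and split HIGH/LOW.

    HCE values at a single concentration are lognormal-like: a few high
    values, mostly low. The split is at ``cutoff_fraction`` times the
    maximum; the report also carries the percent change between successive
    ranked values (the diagnostic used to place the cutoff at a local high
    of that series).

    Returns ``(classes, report)`` where ``report`` is a DataFrame ranked
    high-to-low with columns taxon_id, hce, pct_change, activity.
    """
    if not hces:
        return [], pd.DataFrame(columns=["taxon_id", "hce", "pct_change", "activity"])
    rows = sorted(((e.taxon_id, e.slope) for e in hces), key=lambda r: -r[1])
    values = np.array([v for _, v in rows], dtype=float)
    cutoff = cutoff_fraction * values[0]
    pct = np.full(values.size, np.nan)
    prev = values[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct[1:] = 100.0 * (prev - values[1:]) / np.abs(prev)
    classes = [
        ActivityClass(taxon_id=t, hce_reference=v,
                      activity="HIGH" if v >= cutoff else "LOW")
        for (t, v) in rows
    ]
    report = pd.DataFrame({
        "taxon_id": [t for t, _ in rows],
        "hce": values,
        "pct_change": pct,
        "activity": [c.activity for c in classes],
    })
    report.attrs["cutoff"] = float(cutoff)
    return classes, report


def _ancova_design(fluor: np.ndarray, treat: np.ndarray, levels: Sequence[str],
                   interaction: bool) -> np.ndarray:
    """Design matrix [1, fluor, level dummies, (fluor x dummies)].

    First level in ``levels`` is the reference.
    """
    cols = [np.ones_like(fluor), fluor]
    for lev in levels[1:]:
        d = (treat == lev).astype(float)
        cols.append(d)
    if interaction:
        for lev in levels[1:]:
            d = (treat == lev).astype(float)
            cols.append(fluor * d)
    return np.column_stack(cols)


def _nested_f(y: np.ndarray, X_full: np.ndarray, X_red: np.ndarray
              ) -> tuple[float, float, int, int]:
    """F-test of the full vs reduced OLS model, robust to exact fits.

    Returns (F, p, df_num, df_den). When the residual improvement is
    numerically zero the effect is absent (F=0, p=1); when the full model
    fits exactly but the reduced does not, the effect is overwhelming
    (p=0).
    """
    fit_full = sm.OLS(y, X_full).fit()
    fit_red = sm.OLS(y, X_red).fit()
    df_num = int(round(fit_full.df_model - fit_red.df_model))
    df_den = int(round(fit_full.df_resid))
    scale = float(np.sum((y - y.mean()) ** 2)) or 1.0
    diff = float(fit_red.ssr - fit_full.ssr)
    if df_num <= 0 or df_den <= 0:
        raise InsufficientDataError("no residual degrees of freedom for the F-test")
    if diff <= _SSR_RTOL * scale:
        return 0.0, 1.0, df_num, df_den
    if fit_full.ssr <= _SSR_RTOL * scale:
        return float("inf"), 0.0, df_num, df_den
    f = (diff / df_num) / (fit_full.ssr / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    return float(f), p, df_num, df_den


def ancova_concentration_effect(spots: pd.DataFrame, min_spots: int = 3,
                                model: str = "interaction") -> AncovaResult:
    """Joint F-test for a concentration effect on isotopic enrichment.

    Fits delta ~ fluorescence + treatment + treatment:fluorescence by least
    squares over all usable treatment levels of one taxon and tests all
    treatment terms together against delta ~ fluorescence, so a shift in
    either the HCE slope or the intercept registers as a concentration
    effect. With ``model="intercept"`` the interaction terms are dropped
    (classical common-slope ANCOVA).

    Levels with fewer than ``min_spots`` spots are excluded; the result is
    flagged ``partial`` when any level of H/M/L is missing.

    Raises
    ------
    InsufficientDataError
        Fewer than two usable treatment levels.
    """
    taxon = str(spots["taxon_id"].iloc[0]) if len(spots) else ""
    counts = spots.groupby("treatment", observed=True).size()
    levels = [t for t in TREATMENTS if counts.get(t, 0) >= min_spots]
    if len(levels) < 2:
        raise InsufficientDataError(
            f"{taxon}: only {len(levels)} treatment level(s) with >= {min_spots} spots"
        )
    sub = spots[spots["treatment"].isin(levels)]
    y = sub["delta_permil"].to_numpy(dtype=float)
    fluor = sub["fluorescence"].to_numpy(dtype=float)
    treat = sub["treatment"].astype(str).to_numpy()
    X_full = _ancova_design(fluor, treat, levels, interaction=(model == "interaction"))
    X_red = _ancova_design(fluor, treat, levels[:1], interaction=False)
    f, p, dfn, dfd = _nested_f(y, X_full, X_red)
    return AncovaResult(taxon_id=taxon, p_value=p, f_stat=f, df_num=dfn,
                        df_den=dfd, levels=tuple(levels),
                        partial=len(levels) < len(TREATMENTS))


def posthoc_pairs(spots: pd.DataFrame, overall_p: float, alpha: float = 0.05,
                  min_spots: int = 3, model: str = "interaction",
                  correction: str = "none") -> frozenset:
    """Directional pairwise concentration comparisons after a significant ANCOVA.

    For each ordered pair (higher, lower) among (H,M), (H,L), (M,L) with
    both levels usable, runs the two-level ANCOVA; the pair is significant
    iff its p-value is below ``alpha`` (after optional Holm correction) AND
    the higher concentration's fitted HCE exceeds the lower's — lower
    substrate availability should not drive higher incorporation, so
    reversed contrasts are never counted.

    Gate: returns the empty set when ``overall_p >= alpha``.
    """
    if not (overall_p < alpha):
        return frozenset()
    counts = spots.groupby("treatment", observed=True).size()
    usable = [t for t in TREATMENTS if counts.get(t, 0) >= min_spots]

    slopes: dict[str, float] = {}
    for t in usable:
        grp = spots[spots["treatment"] == t]
        slopes[t] = fit_hce(grp["fluorescence"], grp["delta_permil"],
                            taxon_id="", treatment=t, min_spots=min_spots).slope

    ordered_pairs = [("H", "M"), ("H", "L"), ("M", "L")]
    pvals: dict[tuple, float] = {}
    for hi, lo in ordered_pairs:
        if hi not in usable or lo not in usable:
            continue
        sub = spots[spots["treatment"].isin([hi, lo])]
        try:
            res = ancova_concentration_effect(sub, min_spots=min_spots, model=model)
        except InsufficientDataError:
            continue
        pvals[(hi, lo)] = res.p_value

    if correction == "holm" and pvals:
        keys = sorted(pvals, key=pvals.get)
        m = len(keys)
        adj_prev = 0.0
        for rank, k in enumerate(keys):
            adj = min(1.0, max(adj_prev, (m - rank) * pvals[k]))
            pvals[k] = adj
            adj_prev = adj

    significant = {
        pair for pair, p in pvals.items()
        if p < alpha and slopes[pair[0]] > slopes[pair[1]]
    }
    return frozenset(significant)


def classify_guild(taxon_id: str, overall_p: float, pairs: frozenset,
                   alpha: float = 0.05, partial: bool = False) -> GuildAssignment:
    """Map (ANCOVA p, significant directional pairs) to a trophic guild.

    Decision table (total and deterministic):

    * overall p >= alpha                      -> NULL_HML  (H≈M≈L)
    * (H,M) and (M,L) significant             -> COPIOTROPH (H>M>L)
    * (M,L) or (H,L) significant, (H,M) not   -> INTERMEDIATE (H≈M>L)
    * anything else (e.g. H>M≈L, or a significant ANCOVA whose only
      pairwise contrasts violate the concentration direction)
                                              -> OTHER
    """
    hm = ("H", "M") in pairs
    hl = ("H", "L") in pairs
    ml = ("M", "L") in pairs
    if not (overall_p < alpha):
        guild = GUILD_NULL
    elif hm and ml:
        guild = GUILD_COPIOTROPH
    elif (ml or hl) and not hm:
        guild = GUILD_INTERMEDIATE
    else:
        guild = GUILD_OTHER
    return GuildAssignment(taxon_id=taxon_id, guild=guild, ancova_p=overall_p,
                           posthoc=frozenset(pairs), partial=partial)


def assign_guild(spots: pd.DataFrame, alpha: float = 0.05, min_spots: int = 3,
                 model: str = "interaction", correction: str = "none"
                 ) -> GuildAssignment:
    """Full per-taxon procedure: ANCOVA, post-hoc pairs, decision table."""
    res = ancova_concentration_effect(spots, min_spots=min_spots, model=model)
    pairs = posthoc_pairs(spots, res.p_value, alpha=alpha, min_spots=min_spots,
                          model=model, correction=correction)
    return classify_guild(res.taxon_id, res.p_value, pairs, alpha=alpha,
                          partial=res.partial)
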