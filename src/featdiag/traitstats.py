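"""Trait-level statistics: reliance-on-detail slopes, per-item trait
effects, clinical diagnosticity log-odds, robust regression across the 50
AQ items, and the subscale ANOVA with Bonferroni post-hocs.

Reliance-on-detail is each participant's OLS slope of mean FDi on the
ascending spatial-frequency bin index (1-5).  A trait's effect is the mean
reliance difference between endorsers and non-endorsers; its clinical
diagnosticity is ln(prevalence in diagnosed ASD / prevalence in
neurotypical controls).  The headline fit regresses the 50 trait effects
on their diagnosticities with a bisquare IRLS robust regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import N_ITEMS, SUBSCALES, ParticipantProfile

logger = logging.getLogger(__name__)

__all__ = [
    "RobustFit",
    "reliance_on_detail",
    "log_diagnosticity",
    "trait_effects",
    "robust_regress",
    "subscale_anova",
    "validate_trait_table",
]


def reliance_on_detail(bin_values: np.ndarray) -> float:
    """OLS slope of a participant's mean bin FDi on bin index 1..n."""
    y = np.asarray(bin_values, dtype=float)
    if y.ndim != 1 or np.isnan(y).any():
        raise ValueError("bin_values must be a 1-D array of finite values")
    x = np.arange(1, y.size + 1, dtype=float)
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def log_diagnosticity(prevalence_asd: float,
                      prevalence_control: float | None = None) -> float:
    """Natural log of the trait-prevalence ratio (ASD over control).

    Call with a precomputed ratio, or with two prevalences in (0, 1].
    Zero or negative inputs are domain errors (no smoothing).
    """
    if prevalence_control is None:
        ratio = prevalence_asd
    else:
        if not (0 < prevalence_asd <= 1 and 0 < prevalence_control <= 1):
            raise ValueError("prevalences must be in (0, 1]")
        ratio = prevalence_asd / prevalence_control
    if ratio <= 0:
        raise ValueError(f"prevalence ratio must be positive, got {ratio}")
    return float(np.log(ratio))


def trait_effects(reliance: np.ndarray,
                  profiles: list[ParticipantProfile]) -> np.ndarray:
    """Per-item effect: mean reliance-on-detail of endorsers minus
    non-endorsers.  Items endorsed by everyone or no one are undefined and
    returned as NaN (logged)."""
    reliance = np.asarray(reliance, dtype=float)
    items = np.vstack([p.aq_items for p in profiles])  # (P, 50)
    if items.shape[0] != reliance.size:
        raise ValueError("reliance and profiles lengths differ")
    effects = np.full(N_ITEMS, np.nan)
    for i in range(N_ITEMS):
        on = items[:, i] == 1
        if on.all() or not on.any():
            continue
        effects[i] = reliance[on].mean() - reliance[~on].mean()
    n_missing = int(np.isnan(effects).sum())
    if n_missing:
        logger.warning("trait_effects: %d items with all-or-none endorsement "
                       "have undefined effects", n_missing)
    return effects


@dataclass
class RobustFit:
    slope: float
    intercept: float
    t_stat: float
    df: int
    p: float
    method: str = "IRLS-bisquare"


def robust_regress(effects: np.ndarray, diagnosticity: np.ndarray,
                   max_iter: int = 100) -> RobustFit:
    """Bisquare IRLS robust regression of trait effects on clinical
    diagnosticity.

    Pairs with a NaN effect are dropped.  t = slope / robust SE with
    df = n_complete - 2; on clean linear data the fit coincides with OLS.
    """
    import statsmodels.api as sm

    effects = np.asarray(effects, dtype=float)
    diagnosticity = np.asarray(diagnosticity, dtype=float)
    ok = np.isfinite(effects) & np.isfinite(diagnosticity)
    if ok.sum() < 3:
        raise ValueError("robust regression needs >= 3 complete pairs")
    y, x = effects[ok], diagnosticity[ok]
    X = sm.add_constant(x)
    model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight())
    fit = model.fit(maxiter=max_iter)
    if fit.fit_history["iteration"] >= max_iter:
        raise RuntimeError(
            f"robust regression did not converge in {max_iter} iterations "
            f"(last params {fit.params})")
    slope, intercept = float(fit.params[1]), float(fit.params[0])
    se = float(fit.bse[1])
    dof = int(ok.sum() - 2)
    t = slope / se if se > 0 else 0.0
    p = 2.0 * stats.t.sf(abs(t), dof)
    return RobustFit(slope=slope, intercept=intercept, t_stat=float(t),
                     df=dof, p=float(p))


def subscale_anova(effects: np.ndarray, subscale_labels: list[str]):
    """One-way ANOVA of the 50 trait effects across the five subscales,
    plus per-subscale each-vs-rest t contrasts with Bonferroni correction.

    Returns (F, df1, df2, p, contrasts) where contrasts maps subscale name
    to {"t", "df", "p_uncorrected", "p_bonferroni"}.
    """
    effects = np.asarray(effects, dtype=float)
    labels = np.asarray(subscale_labels)
    if effects.size != labels.size:
        raise ValueError("effects and labels lengths differ")
    names = sorted(SUBSCALES)
    groups = [effects[labels == name] for name in names]
    sizes = {name: g.size for name, g in zip(names, groups)}
    if len(set(sizes.values())) != 1 or sum(sizes.values()) != effects.size:
        raise ValueError(f"unbalanced subscale labels: {sizes}")
    if any(np.isnan(g).any() for g in groups):
        raise ValueError("NaN effects; resolve undefined items first")
    F, p = stats.f_oneway(*groups)
    if not np.isfinite(F):  # all effects identical
        F, p = 0.0, 1.0
    df1 = len(names) - 1
    df2 = effects.size - len(names)
    n_tests = len(names)
    contrasts = {}
    for name in names:
        a = effects[labels == name]
        b = effects[labels != name]
        res = stats.ttest_ind(a, b, equal_var=True)
        t = float(res.statistic) if np.isfinite(res.statistic) else 0.0
        p_unc = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
        contrasts[name] = {
            "t": t,
            "df": a.size + b.size - 2,
            "p_uncorrected": p_unc,
            "p_bonferroni": min(1.0, n_tests * p_unc),
        }
    return float(F), df1, df2, float(p), contrasts


def validate_trait_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a trait table: 50 items, 10 per subscale, consistent
    log-diagnosticity.  Fills log_diagnosticity from prevalences or a
    ratio column when absent."""
    df = table.copy()
    if set(df["item_id"]) != set(range(1, N_ITEMS + 1)):
        raise ValueError("trait table must cover item_id 1..50")
    counts = df["subscale"].value_counts()
    if set(counts.index) != set(SUBSCALES) or (counts != 10).any():
        raise ValueError("trait table must have 10 items per subscale")
    if "log_diagnosticity" not in df.columns:
        if "prevalence_ratio" in df.columns:
            df["log_diagnosticity"] = np.log(df["prevalence_ratio"])
        else:
            df["log_diagnosticity"] = np.log(
                df["prevalence_asd"] / df["prevalence_control"])
    if {"prevalence_asd", "prevalence_control"} <= set(df.columns):
        expected = np.log(df["prevalence_asd"] / df["prevalence_control"])
        if not np.allclose(df["log_diagnosticity"], expected, atol=1e-12):
            raise ValueError("log_diagnosticity inconsistent with prevalences")
    return df.sort_values("item_id").reset_index(drop=True)
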