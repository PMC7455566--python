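"""Feature binning and the group-by-bin ANOVAs.

Features (pooled over all images) are sorted by a criterion — spatial
frequency, distance from the nearest eye, or distance from the image
centre — and split into five equally sized ascending bins (2,000 features
each at the standard 10 x 1,000 scale).  Per-participant mean FDi within
each bin feeds a 5 x 2 (bin x AQ-group) ANOVA; the headline contrast
compares the groups in the highest bin with a pooled-variance t-test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .fdi import FDiTensor
from .geometry import FeatureBank

__all__ = [
    "BinSpec",
    "Landmarks",
    "AnovaResult",
    "assign_bins",
    "feature_distances",
    "participant_bin_means",
    "two_way_anova",
    "highest_bin_contrast",
]


@dataclass
class Landmarks:
    """Per-image landmark annotations (eye points; the centre is implied
    by the geometry: ((side-1)/2, (side-1)/2))."""

    eye_points: dict[str, list[tuple[float, float]]]

    @classmethod
    def from_json(cls, path: str | Path) -> "Landmarks":
        data = json.loads(Path(path).read_text())
        return cls({img: [tuple(p) for p in entry["eyes"]]
                    for img, entry in data.items()})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {img: {"eyes": [list(p) for p in pts]}
             for img, pts in self.eye_points.items()}))


@dataclass
class BinSpec:
    """Assignment of every (image, feature) pair to one of ``n_bins``
    ascending, equally sized bins."""

    criterion: str
    n_bins: int
    bin_index: np.ndarray          # (images, features) int array
    boundaries: list[tuple[float, float]]  # per-bin [min, max] of the values
    images: list[str]

    def counts(self) -> np.ndarray:
        return np.bincount(self.bin_index.ravel(), minlength=self.n_bins)


def assign_bins(values: np.ndarray, images: list[str], n_bins: int = 5,
                criterion: str = "sf") -> BinSpec:
    """Stable-sort features by value and split into equally sized
    contiguous bins (any remainder goes to the lowest bins).

    ``values`` is (n_images, n_features); ties are broken by ascending
    (image, feature) index, so the assignment is deterministic.
    """
    values = np.asarray(values, dtype=float)
    n_total = values.size
    if n_bins > n_total:
        raise ValueError(f"n_bins={n_bins} exceeds {n_total} features")
    flat = values.ravel()
    order = np.argsort(flat, kind="stable")
    base, rem = divmod(n_total, n_bins)
    sizes = np.full(n_bins, base)
    sizes[:rem] += 1
    bin_of_rank = np.repeat(np.arange(n_bins), sizes)
    bin_flat = np.empty(n_total, dtype=int)
    bin_flat[order] = bin_of_rank
    boundaries = []
    stops = np.concatenate([[0], np.cumsum(sizes)])
    for b in range(n_bins):
        chunk = flat[order[stops[b]:stops[b + 1]]]
        boundaries.append((float(chunk.min()), float(chunk.max())))
    return BinSpec(criterion=criterion, n_bins=n_bins,
                   bin_index=bin_flat.reshape(values.shape),
                   boundaries=boundaries, images=list(images))


def feature_distances(banks: dict[str, FeatureBank],
                      criterion: str,
                      landmarks: Landmarks | None = None) -> np.ndarray:
    """Per-feature distances in degrees visual angle.

    criterion "eye_distance": Euclidean distance to the nearest eye point;
    "center_distance": distance to the image centre; "sf": the features'
    spatial frequencies (cpd) for uniformity.
    Returns an (n_images, n_features) array ordered by sorted image id.
    """
    images = sorted(banks)
    out = []
    for img in images:
        bank = banks[img]
        geom = bank.geometry
        pos = bank.positions_px
        if criterion == "sf":
            out.append(bank.sf_cpd)
            continue
        if criterion == "center_distance":
            c = (geom.side_px - 1) / 2.0
            d = np.hypot(pos[:, 0] - c, pos[:, 1] - c)
        elif criterion == "eye_distance":
            if landmarks is None or img not in landmarks.eye_points:
                missing = [i for i in images
                           if landmarks is None
                           or i not in landmarks.eye_points]
                raise ValueError(
                    f"eye-distance binning requested but landmarks are "
                    f"missing for images {missing}")
            pts = np.asarray(landmarks.eye_points[img], dtype=float)
            d = np.min(
                np.hypot(pos[:, 0, None] - pts[None, :, 0],
                         pos[:, 1, None] - pts[None, :, 1]), axis=1)
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        out.append(d / geom.px_per_dva)
    return np.vstack(out)


def participant_bin_means(fdi: FDiTensor, spec: BinSpec) -> pd.DataFrame:
    """Mean FDi per participant and bin (pooling all images' features).

    Returns a long DataFrame with columns participant_id, bin (1-based),
    value.
    """
    if list(spec.images) != list(fdi.images):
        raise ValueError("bin spec and FDi tensor image sets differ")
    P = len(fdi.participants)
    flat_bins = spec.bin_index.ravel()
    flat_vals = fdi.flat()  # (P, images*features)
    rows = []
    for b in range(spec.n_bins):
        sel = flat_bins == b
        means = flat_vals[:, sel].mean(axis=1)
        rows.append(pd.DataFrame({
            "participant_id": fdi.participants,
            "bin": b + 1,
            "value": means,
        }))
    return pd.concat(rows, ignore_index=True)


@dataclass
class AnovaResult:
    """F-test table for a two-factor design plus cell means."""

    effects: dict[str, dict]   # name -> {F, df1, df2, p}
    cell_means: pd.DataFrame
    model: str

    def to_dict(self) -> dict:
        return {"model": self.model, "effects": self.effects,
                "cell_means": self.cell_means.to_dict(orient="records")}


def two_way_anova(table: pd.DataFrame, dv: str = "value",
                  within: str = "bin", between: str = "group",
                  subject: str = "participant_id",
                  model: str = "flat") -> AnovaResult:
    """Bin-by-group ANOVA on participant-level cell means.

    model="flat": fixed-effects two-way ANOVA with Type II sums of squares,
    treating every (participant, bin) value as one observation.  Its error
    degrees of freedom follow the N*b - b*g pattern (e.g. 52 participants,
    5 bins, 2 groups -> interaction df (4, 250)).

    model="rm": mixed repeated-measures ANOVA (within-subject bin factor,
    between-subject group), whose interaction test is exact at its nominal
    level when each subject's bin profile sums to a constant — as z-scored
    FDi bin means do.  See the methods note for why the two disagree.
    """
    import statsmodels.api as sm  # noqa: F401
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = table.rename(columns={dv: "value"}).copy()
    for col in (within, between):
        if df.groupby([within, between])["value"].count().min() == 0:
            raise ValueError("empty design cells")
    cell_means = (df.groupby([within, between])["value"]
                  .mean().reset_index())
    n_within = df[within].nunique()
    n_between = df[between].nunique()
    if np.ptp(df["value"].to_numpy()) == 0:
        # all observations identical: every sum of squares is zero
        zero = {"F": 0.0, "df1": float(n_within - 1), "df2": float(
            len(df) - n_within * n_between), "p": 1.0}
        effects = {within: dict(zero), between: dict(zero),
                   "interaction": dict(zero)}
        return AnovaResult(effects=effects, cell_means=cell_means,
                           model=model)
    if model == "flat":
        if n_within == 1 or n_between == 1:
            # degenerate factor: collapse to a one-way layout
            factor = within if n_within > 1 else between
            fit = smf.ols(f"value ~ C({factor})", data=df).fit()
            aov = anova_lm(fit, typ=2)
            resid_df = float(aov.loc["Residual", "df"])
            absent = {"F": 0.0, "df1": 0.0, "df2": resid_df, "p": 1.0}
            effects = {within: dict(absent), between: dict(absent),
                       "interaction": dict(absent)}
            effects[factor] = {
                "F": float(aov.loc[f"C({factor})", "F"]),
                "df1": float(aov.loc[f"C({factor})", "df"]),
                "df2": resid_df,
                "p": float(aov.loc[f"C({factor})", "PR(>F)"]),
            }
            return AnovaResult(effects=effects, cell_means=cell_means,
                               model=model)
        fit = smf.ols(f"value ~ C({within}) * C({between})", data=df).fit()
        aov = anova_lm(fit, typ=2)
        resid_df = float(aov.loc["Residual", "df"])
        effects = {}
        name_map = {f"C({within})": within, f"C({between})": between,
                    f"C({within}):C({between})": "interaction"}
        for row_name, eff in name_map.items():
            F = float(aov.loc[row_name, "F"])
            if not np.isfinite(F):  # zero residual SS (e.g. constant data)
                F = 0.0
            effects[eff] = {
                "F": F,
                "df1": float(aov.loc[row_name, "df"]),
                "df2": resid_df,
                "p": float(aov.loc[row_name, "PR(>F)"]),
            }
    elif model == "rm":
        import warnings

        import pingouin as pg

        with warnings.catch_warnings():
            # z-scored bin profiles have zero between-subject variance, which
            # makes pingouin's (unused here) between-effect F divide by zero
            warnings.simplefilter("ignore", RuntimeWarning)
            aov = pg.mixed_anova(data=df, dv="value", within=within,
                                 between=between, subject=subject)
        effects = {}
        key = {within: within, between: between, "Interaction": "interaction"}
        for _, r in aov.iterrows():
            eff = key.get(r["Source"], r["Source"])
            effects[eff] = {"F": float(r["F"]), "df1": float(r["DF1"]),
                            "df2": float(r["DF2"]), "p": float(r["p_unc"])}
    else:
        raise ValueError(f"unknown model {model!r}")
    for eff in effects.values():
        if not np.isfinite(eff["p"]):
            eff["p"] = 1.0
    return AnovaResult(effects=effects, cell_means=cell_means, model=model)


def highest_bin_contrast(bin_means: pd.DataFrame, groups: dict[str, str],
                         equal_var: bool = True):
    """Two-sample t-test on the highest bin's per-participant means.

    ``groups`` maps participant_id -> group label.  Pooled-variance by
    default (df = n1 + n2 - 2, reproducing t(50) for 25 vs 27); Welch via
    ``equal_var=False``.  Returns (t, df, p).
    """
    top = bin_means["bin"].max()
    sub = bin_means[bin_means["bin"] == top]
    labels = sub["participant_id"].map(groups)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    a = sub.loc[labels == uniq[0], "value"].to_numpy()
    b = sub.loc[labels == uniq[1], "value"].to_numpy()
    if min(len(a), len(b)) < 2:
        raise ValueError("each group needs >= 2 participants")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        dof = len(a) + len(b) - 2
    else:
        dof = float(res.df)
    t = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(t):  # identical constant groups
        t, p = 0.0, 1.0
    return t, dof, p
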