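"""Feature diagnosticity estimation.

The Feature Diagnosticity index (FDi) of a feature is the mean recognition
accuracy over the trials that contained it, z-scored within each
(participant, image) slice across that image's features.  The z-scoring
removes image-recognizability and participant-performance variance, so FDi
is invariant to affine transforms of a participant's raw accuracies.

Replicability of the cohort's FDi pattern is the mean Pearson correlation,
over random participant splits, between the two halves' mean FDi vectors
(images x features flattened); its significance comes from a permutation
null that shuffles one half's feature labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .stimulus import TrialTable

logger = logging.getLogger(__name__)

__all__ = [
    "FDiTensor",
    "ReplicabilityResult",
    "correctness",
    "per_feature_accuracy",
    "zscore_fdi",
    "split_half_replicability",
    "permutation_p",
    "rt_fdi",
    "FDiMapper",
]


@dataclass
class FDiTensor:
    """participants x images x features array with axis labels.

    ``values`` holds raw per-feature statistics (NaN = never-shown cell)
    before z-scoring, and z-scores (NaN-free, missing cells imputed to 0)
    after.  ``counts`` records per-cell observation counts.
    """

    values: np.ndarray
    participants: list[str]
    images: list[str]
    counts: np.ndarray | None = None
    source: str = "accuracy"
    zscored: bool = False

    @property
    def n_features(self) -> int:
        return self.values.shape[2]

    def flat(self) -> np.ndarray:
        """(participants, images*features) view used by replicability."""
        return self.values.reshape(self.values.shape[0], -1)

    def to_csv(self, path: str | Path) -> None:
        p, i, f = self.values.shape
        df = pd.DataFrame({
            "participant_id": np.repeat(self.participants, i * f),
            "image_id": np.tile(np.repeat(self.images, f), p),
            "feature_id": np.tile(np.arange(f), p * i),
            "fdi": self.values.ravel(),
        })
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, source: str = "accuracy",
                 zscored: bool = True) -> "FDiTensor":
        df = pd.read_csv(path)
        participants = sorted(df["participant_id"].unique())
        images = sorted(df["image_id"].unique())
        f = int(df["feature_id"].max()) + 1
        df = df.sort_values(["participant_id", "image_id", "feature_id"])
        vals = df["fdi"].to_numpy().reshape(len(participants), len(images), f)
        return cls(values=vals, participants=participants, images=images,
                   source=source, zscored=zscored)


def correctness(trials: TrialTable) -> np.ndarray:
    """1.0 where the reported category matches the true one, else 0.0
    ('unsure' and wrong-animal responses both count as not recognized)."""
    if not trials.has_responses:
        raise ValueError("trial table has no response column")
    return (trials.df["response"].to_numpy()
            == trials.df["true_category"].to_numpy()).astype(float)


def _per_feature_stat(trials: TrialTable, stat: np.ndarray,
                      n_features: int | None, source: str) -> FDiTensor:
    if len(trials) == 0:
        raise ValueError("empty trial table")
    df = trials.df
    participants = sorted(df["participant_id"].unique())
    images = sorted(df["image_id"].unique())
    p_code = df["participant_id"].map({p: k for k, p in enumerate(participants)})
    i_code = df["image_id"].map({m: k for k, m in enumerate(images)})
    F = int(n_features if n_features is not None else trials.features.max() + 1)
    if trials.features.max() >= F or trials.features.min() < 0:
        raise ValueError("feature ids outside 0..n_features-1")
    P, I = len(participants), len(images)
    k = trials.features.shape[1]
    cell = (p_code.to_numpy() * I + i_code.to_numpy())
    idx = (cell[:, None] * F + trials.features).ravel()
    sums = np.bincount(idx, weights=np.repeat(stat, k), minlength=P * I * F)
    counts = np.bincount(idx, minlength=P * I * F)
    with np.errstate(invalid="ignore"):
        vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return FDiTensor(values=vals.reshape(P, I, F), participants=participants,
                     images=images, counts=counts.reshape(P, I, F),
                     source=source)


def per_feature_accuracy(trials: TrialTable,
                         n_features: int | None = None) -> FDiTensor:
    """Raw reverse-correlation tensor: cell (p, i, f) is the mean
    correctness over participant p's trials of image i that contained
    feature f; never-shown cells are NaN."""
    return _per_feature_stat(trials, correctness(trials), n_features,
                             source="accuracy")


def zscore_fdi(raw: FDiTensor, ddof: int = 1) -> FDiTensor:
    """Z-score each (participant, image) slice across features.

    Missing cells are imputed as 0 after standardization (logged); a
    constant slice is uninformative and becomes all zeros with a warning.
    """
    vals = raw.values.astype(float).copy()
    P, I, F = vals.shape
    n_missing = int(np.isnan(vals).sum())
    out = np.empty_like(vals)
    n_constant = 0
    for p in range(P):
        for i in range(I):
            slc = vals[p, i]
            obs = ~np.isnan(slc)
            if obs.sum() >= 2 and np.nanmax(slc) > np.nanmin(slc):
                sd = np.nanstd(slc, ddof=ddof)
            else:
                sd = 0.0  # constant or single-valued slice: uninformative
            if sd == 0.0 or not np.isfinite(sd):
                out[p, i] = 0.0
                n_constant += 1
                continue
            out[p, i] = (slc - np.nanmean(slc)) / sd
            out[p, i][~obs] = 0.0
    if n_missing:
        logger.info("zscore_fdi: imputed %d never-shown cells (%.2f%%) as 0",
                    n_missing, 100.0 * n_missing / vals.size)
    if n_constant:
        logger.warning("zscore_fdi: %d constant participant-image slices set "
                       "to zeros", n_constant)
    return FDiTensor(values=out, participants=raw.participants,
                     images=raw.images, counts=raw.counts, source=raw.source,
                     zscored=True)


def rt_fdi(trials: TrialTable, n_features: int | None = None,
           correct_only: bool = False) -> FDiTensor:
    """RT-based variant: per-feature mean reaction time (all trials by
    default; ``correct_only`` restricts to recognized trials), z-scored the
    same way as accuracy-based FDi."""
    if "rt_ms" not in trials.df.columns:
        raise ValueError("trial table has no rt_ms column")
    if correct_only:
        keep = correctness(trials) == 1.0
        sub = TrialTable(trials.df[keep], trials.features[keep])
        return rt_fdi(sub, n_features=n_features, correct_only=False)
    raw = _per_feature_stat(trials, trials.df["rt_ms"].to_numpy(dtype=float),
                            n_features, source="rt")
    return zscore_fdi(raw)


# ---------------------------------------------------------------------------
# split-half replicability and the permutation null


def _split_half_means(fdi: FDiTensor, n_splits: int,
                      rng: np.random.Generator):
    """Per-split half-mean matrices A, B of shape (n_splits, images*features).

    Participants are partitioned into halves of sizes ceil(n/2), floor(n/2)
    uniformly at random per split.
    """
    flat = fdi.flat()
    n = flat.shape[0]
    if n < 4:
        raise ValueError("split-half replicability needs >= 4 participants")
    h = (n + 1) // 2
    A = np.empty((n_splits, flat.shape[1]))
    B = np.empty_like(A)
    for s in range(n_splits):
        perm = rng.permutation(n)
        A[s] = flat[perm[:h]].mean(axis=0)
        B[s] = flat[perm[h:]].mean(axis=0)
    return A, B


def _row_standardize(M: np.ndarray) -> np.ndarray:
    """Center rows and scale to unit norm so r = a . b."""
    M = M - M.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return M / norms


def split_half_replicability(fdi: FDiTensor, n_splits: int = 100,
                             rng: np.random.Generator | None = None) -> float:
    """Mean Pearson correlation between half-cohort mean FDi vectors over
    ``n_splits`` random participant splits."""
    rng = rng if rng is not None else np.random.default_rng()
    A, B = _split_half_means(fdi, n_splits, rng)
    An, Bn = _row_standardize(A), _row_standardize(B)
    return float(np.einsum("sf,sf->s", An, Bn).mean())


@dataclass
class ReplicabilityResult:
    observed_r: float
    n_splits: int
    n_perm: int
    p_value: float
    null_mean: float
    null_sd: float
    null_q95: float

    def to_dict(self) -> dict:
        return {
            "observed_r": self.observed_r, "n_splits": self.n_splits,
            "n_perm": self.n_perm, "p_value": self.p_value,
            "null_mean": self.null_mean, "null_sd": self.null_sd,
            "null_q95": self.null_q95,
        }


def permutation_p(fdi: FDiTensor, n_splits: int = 100, n_perm: int = 10000,
                  rng: np.random.Generator | None = None
                  ) -> ReplicabilityResult:
    """Permutation test of split-half replicability.

    The observed statistic is the mean split-half correlation; each null
    iteration recomputes it on the same splits with one half's flattened
    feature vector label-permuted (a fresh permutation per iteration).  The
    p-value uses the add-one estimator (1 + #{null >= obs}) / (1 + n_perm),
    so it is never zero.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if n_perm < 100:
        logger.warning("n_perm=%d is very small; p-value resolution is coarse",
                       n_perm)
    A, B = _split_half_means(fdi, n_splits, rng)
    An, Bn = _row_standardize(A), _row_standardize(B)
    observed = float(np.einsum("sf,sf->s", An, Bn).mean())
    F = An.shape[1]
    # cross-split Gram matrix M[f, g] = sum_s A[s,f] B[s,g]: each null value
    # is then a single fancy-indexed trace, making 10,000 permutations cheap
    dtype = np.float32 if F > 3000 else np.float64
    M = (An.astype(dtype).T @ Bn.astype(dtype))
    fidx = np.arange(F)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(F)
        null[k] = M[fidx, perm].sum() / n_splits
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return ReplicabilityResult(
        observed_r=observed, n_splits=n_splits, n_perm=n_perm, p_value=float(p),
        null_mean=float(null.mean()), null_sd=float(null.std()),
        null_q95=float(np.quantile(null, 0.95)),
    )


class FDiMapper(BaseEstimator):
    """Estimator-style wrapper: fit a trial table, get the z-scored FDi
    tensor (``fdi_``) and optionally its replicability (``replicability_``).
    """

    def __init__(self, source: str = "accuracy", n_splits: int = 100,
                 n_perm: int = 10000, compute_replicability: bool = True,
                 random_state: int = 0):
        self.source = source
        self.n_splits = n_splits
        self.n_perm = n_perm
        self.compute_replicability = compute_replicability
        self.random_state = random_state

    def fit(self, X: TrialTable, y=None, n_features: int | None = None):
        rng = np.random.default_rng(self.random_state)
        if self.source == "accuracy":
            raw = per_feature_accuracy(X, n_features)
            self.fdi_ = zscore_fdi(raw)
        elif self.source == "rt":
            self.fdi_ = rt_fdi(X, n_features)
        else:
            raise ValueError(f"unknown source {self.source!r}")
        if self.compute_replicability:
            self.replicability_ = permutation_p(
                self.fdi_, self.n_splits, self.n_perm, rng)
        return self
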