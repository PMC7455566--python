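"""Synthetic observers: AQ-profiled cohorts, planted feature weightings and
simulated recognition responses.

The generator emulates the study conditions end to end so every downstream
stage (FDi estimation, bin ANOVAs, trait statistics) can be exercised and
validated by parameter recovery:

* a cohort (default 52 participants) with AQ totals drawn from a truncated
  normal (mean 14.3, SD 5.9, clipped to 5-30), item endorsements sampled to
  match each total, and a high/low group split at the cohort median;
* per-feature "ground-truth" diagnosticity weights for each participant,
  with a planted coupling that adds weight to high-spatial-frequency
  features in proportion to group membership and to endorsement of
  clinically diagnostic items;
* a threshold observer: trial evidence is the mean weight of the 90
  presented features plus Gaussian noise, mapped to correct / wrong /
  unsure by two ordered thresholds calibrated so cohort marginals sit near
  50 / 21 / 29 %.

Reaction times carry no feature information by default; an optional
coupling plants RT structure for testing the RT-based pipeline positively.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    FeatureBank,
    GaborWavelet,
    ImageGeometry,
    LadderConfig,
    default_sigma_px,
)
from .stimulus import SessionPlan, TrialTable, build_experiment

logger = logging.getLogger(__name__)

__all__ = [
    "SUBSCALES",
    "ParticipantProfile",
    "ObserverModel",
    "CohortConfig",
    "simulate_cohort",
    "ground_truth_weights",
    "simulate_response",
    "simulate_experiment",
    "random_feature_bank",
    "synthetic_portrait",
    "default_trait_table",
    "cohort_to_csv",
    "cohort_from_csv",
]

#: AQ subscale membership (1-based item ids), the standard 5 x 10 partition.
SUBSCALES: dict[str, tuple[int, ...]] = {
    "social skill": (1, 11, 13, 15, 22, 36, 44, 45, 47, 48),
    "attention switching": (2, 4, 10, 16, 25, 32, 34, 37, 43, 46),
    "attention to detail": (5, 6, 9, 12, 19, 23, 28, 29, 30, 49),
    "communication": (7, 17, 18, 26, 27, 31, 33, 35, 38, 39),
    "imagination": (3, 8, 14, 20, 21, 24, 40, 41, 42, 50),
}

N_ITEMS = 50


def subscale_of_items() -> list[str]:
    """Subscale label for each item, indexed by item_id - 1."""
    labels = [""] * N_ITEMS
    for name, items in SUBSCALES.items():
        for i in items:
            labels[i - 1] = name
    return labels


@dataclass
class ParticipantProfile:
    participant_id: str
    aq_items: np.ndarray  # 50 binary endorsements
    group: str = "low"  # high/low vs cohort median, filled by simulate_cohort
    rt_base_ms: float = 895.0
    rt_sd_ms: float = 250.0
    n_sessions: int = 4

    @property
    def aq_total(self) -> int:
        return int(self.aq_items.sum())

    @property
    def subscale_scores(self) -> dict[str, int]:
        return {name: int(self.aq_items[np.array(items) - 1].sum())
                for name, items in SUBSCALES.items()}


@dataclass(frozen=True)
class ObserverModel:
    """Threshold observer: evidence = mean presented-feature weight + noise;
    response is correct above ``theta_correct``, wrong below ``theta_wrong``
    and unsure in between.  The defaults put the marginals near the
    50/21/29 % (correct/wrong/unsure) operating point for zero-mean weights
    and unit noise."""

    theta_correct: float = 0.0
    theta_wrong: float = -0.8
    noise_sd: float = 1.0
    rt_floor_ms: float = 150.0
    rt_evidence_coupling_ms: float = 0.0  # planted RT structure when nonzero

    def __post_init__(self) -> None:
        if self.theta_wrong > self.theta_correct:
            raise ValueError("theta_wrong must not exceed theta_correct")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition and planted effect sizes.

    ``sessions_counts`` maps a session count to how many participants
    complete it (the default reproduces the 6/5/4/3/2-session split of
    2/14/25/10/1 participants); when its totals do not match
    ``n_participants`` the distribution is used proportionally.
    ``sf_coupling_high/low`` add weight to high-sf features per AQ group;
    ``item_coupling_scale`` scales the per-item couplings, proportional to
    clinical diagnosticity for the planted (social-skill) items.
    """

    n_participants: int = 52
    aq_mean: float = 14.3
    aq_sd: float = 5.9
    aq_min: int = 5
    aq_max: int = 30
    sessions_counts: tuple[tuple[int, int], ...] = (
        (6, 2), (5, 14), (4, 25), (3, 10), (2, 1))
    fixed_sessions: int | None = None
    base_scale: float = 2.0
    sf_coupling_high: float = 0.2
    sf_coupling_low: float = 0.0
    item_coupling_scale: float = 0.3
    item_couplings: tuple[float, ...] | None = None  # default: diagnosticity-planted
    rt_group_shift_ms: float = 95.0
    observer: ObserverModel = field(default_factory=ObserverModel)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 4:
            raise ValueError("n_participants must be >= 4")
        for v in (self.base_scale, self.sf_coupling_high, self.sf_coupling_low,
                  self.item_coupling_scale):
            if not math.isfinite(v):
                raise ValueError("planted effect sizes must be finite")

    @classmethod
    def null(cls, **overrides) -> "CohortConfig":
        """A fully null observer: no feature-dependent signal at all
        (flat base weights, zero sf and item couplings), so FDi is pure
        noise and every downstream test sees its null distribution."""
        defaults = dict(base_scale=0.0, sf_coupling_high=0.0,
                        sf_coupling_low=0.0, item_coupling_scale=0.0)
        defaults.update(overrides)
        return cls(**defaults)


def default_trait_table(rng_seed: int = 12345) -> pd.DataFrame:
    """Synthetic clinical-diagnosticity table for the 50 AQ items.

    This is a stand-in for published prevalence data (which the pipeline
    accepts as a user CSV): each item gets ASD and control endorsement
    prevalences whose log ratio is largest for the social-skill items —
    topping out at ln(7.7) ~ 2.04 — and smallest for attention-to-detail
    items, a pattern matching how clinical diagnosticity orders the
    subscales in the AQ validation literature.
    """
    rng = np.random.default_rng(rng_seed)
    labels = subscale_of_items()
    subscale_center = {
        "social skill": 1.5,
        "communication": 1.1,
        "attention switching": 0.9,
        "imagination": 0.7,
        "attention to detail": 0.2,
    }
    log_ratio = np.array([subscale_center[s] for s in labels])
    log_ratio = log_ratio + rng.normal(0.0, 0.25, N_ITEMS)
    # pin the best social-skill item at the canonical ln(7.7) top value
    social = np.array([s == "social skill" for s in labels])
    log_ratio[np.flatnonzero(social)[0]] = math.log(7.7)
    log_ratio = np.clip(log_ratio, -0.5, math.log(7.7))
    prev_control = rng.uniform(0.05, 0.25, N_ITEMS)
    prev_asd = np.clip(prev_control * np.exp(log_ratio), None, 0.98)
    log_ratio = np.log(prev_asd / prev_control)
    return pd.DataFrame({
        "item_id": np.arange(1, N_ITEMS + 1),
        "subscale": labels,
        "prevalence_asd": prev_asd,
        "prevalence_control": prev_control,
        "log_diagnosticity": log_ratio,
    })


def _default_item_couplings() -> np.ndarray:
    """Planted per-item couplings: proportional to clinical diagnosticity
    for social-skill items, zero elsewhere; normalized to unit sum."""
    table = default_trait_table()
    d = table["log_diagnosticity"].to_numpy().copy()
    social = table["subscale"].to_numpy() == "social skill"
    d[~social] = 0.0
    d[d < 0] = 0.0
    return d / d.sum()


def simulate_cohort(cfg: CohortConfig,
                    rng: np.random.Generator | None = None
                    ) -> list[ParticipantProfile]:
    """Draw a cohort: AQ totals, item endorsements, groups and session
    counts.

    Item endorsements are sampled without replacement to match each
    participant's total, with planted items biased toward high-AQ profiles
    (weighted sampling via Gumbel top-k), so trait/total consistency holds
    exactly.  Group = high iff AQ > cohort median.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    n = cfg.n_participants
    totals = np.rint(rng.normal(cfg.aq_mean, cfg.aq_sd, n)).astype(int)
    totals = np.clip(totals, cfg.aq_min, cfg.aq_max)

    couplings = (np.asarray(cfg.item_couplings, dtype=float)
                 if cfg.item_couplings is not None
                 else _default_item_couplings())
    loadings = 3.0 * couplings / max(couplings.max(), 1e-12)

    profiles = []
    for j in range(n):
        z = (totals[j] - cfg.aq_mean) / cfg.aq_sd
        keys = loadings * z + rng.gumbel(size=N_ITEMS)
        endorsed = np.argsort(-keys)[: totals[j]]
        items = np.zeros(N_ITEMS, dtype=int)
        items[endorsed] = 1
        profiles.append(ParticipantProfile(
            participant_id=f"p{j:02d}", aq_items=items))

    median = float(np.median(totals))
    if np.all(totals == totals[0]):
        logger.warning("degenerate cohort: all AQ totals identical; "
                       "everyone assigned to the low group")
    for prof, t in zip(profiles, totals):
        prof.group = "high" if t > median else "low"

    # session counts: exact multiset when it matches n, else proportional draw
    counts = dict(cfg.sessions_counts)
    if cfg.fixed_sessions is not None:
        sessions = np.full(n, cfg.fixed_sessions)
    elif sum(counts.values()) == n:
        sessions = np.repeat(list(counts.keys()), list(counts.values()))
        rng.shuffle(sessions)
    else:
        ks = np.array(list(counts.keys()))
        ps = np.array(list(counts.values()), dtype=float)
        sessions = rng.choice(ks, size=n, p=ps / ps.sum())
    rt_shift = {"high": cfg.rt_group_shift_ms, "low": -cfg.rt_group_shift_ms}
    for prof, s in zip(profiles, sessions):
        prof.n_sessions = int(s)
        prof.rt_base_ms = 895.0 + rt_shift[prof.group] + float(rng.normal(0, 80))
    return profiles


def ground_truth_weights(bank: FeatureBank, profile: ParticipantProfile,
                         cfg: CohortConfig) -> np.ndarray:
    """Planted per-feature diagnosticity weights for one participant/image.

    weight_f = base_f + coupling(profile) * zscore(sf_f), where base_f is
    the feature's covariance rank (normalized to zero mean and
    SD = base_scale) and the coupling grows with group membership and with
    endorsement of the planted items.
    """
    n = bank.n_features
    if bank.covariances is not None:
        order = np.argsort(-bank.covariances, kind="stable")
        rank = np.empty(n)
        rank[order] = np.arange(n)
    else:
        rank = np.arange(n, dtype=float)
    u = 1.0 - (rank + 0.5) / n  # high covariance -> high base weight
    base = cfg.base_scale * (u - u.mean()) / max(u.std(), 1e-12)

    sf = bank.sf_cpd
    sf_z = (sf - sf.mean()) / max(sf.std(), 1e-12)

    coupling = (cfg.sf_coupling_high if profile.group == "high"
                else cfg.sf_coupling_low)
    if cfg.item_coupling_scale != 0.0:
        couplings = (np.asarray(cfg.item_couplings, dtype=float)
                     if cfg.item_couplings is not None
                     else _default_item_couplings())
        coupling += cfg.item_coupling_scale * float(
            profile.aq_items @ couplings)
    return base + coupling * sf_z


def simulate_response(trial_weights: np.ndarray, model: ObserverModel,
                      rng: np.random.Generator,
                      rt_base_ms: float = 895.0, rt_sd_ms: float = 250.0):
    """Response and RT for trials given the presented features' weights.

    ``trial_weights`` is (n_trials, k): the planted weights of each trial's
    presented features.  Returns (outcome, rt_ms) arrays where outcome is
    in {"correct", "wrong", "unsure"}.
    """
    trial_weights = np.atleast_2d(trial_weights)
    evidence = trial_weights.mean(axis=1)
    if model.noise_sd > 0:
        evidence = evidence + rng.normal(0.0, model.noise_sd, evidence.shape)
    outcome = np.where(evidence > model.theta_correct, "correct",
                       np.where(evidence < model.theta_wrong, "wrong",
                                "unsure"))
    rt = rt_base_ms + rng.normal(0.0, rt_sd_ms, evidence.shape)
    if model.rt_evidence_coupling_ms != 0.0:
        rt = rt - model.rt_evidence_coupling_ms * trial_weights.mean(axis=1)
    rt = np.maximum(model.rt_floor_ms, rt)
    return outcome, rt


def simulate_experiment(cfg: CohortConfig, banks: dict[str, FeatureBank],
                        rng: np.random.Generator | None = None,
                        plan: SessionPlan | None = None,
                        profiles: list[ParticipantProfile] | None = None,
                        ) -> tuple[TrialTable, list[ParticipantProfile],
                                   dict[str, dict[str, np.ndarray]]]:
    """Full simulated experiment: cohort, trials, responses and RTs.

    Returns the trial table (with ``response`` holding the reported category
    label or "unsure", and ``rt_ms``), the cohort profiles, and the planted
    weights as {participant_id: {image_id: weights}} for recovery checks.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    plan = plan or SessionPlan()
    if profiles is None:
        profiles = simulate_cohort(cfg, rng)
    categories = sorted({_cat(i) for i in banks})
    tables = []
    weights_out: dict[str, dict[str, np.ndarray]] = {}
    for prof in profiles:
        trials = build_experiment(banks, prof.n_sessions, plan, rng,
                                  participant_id=prof.participant_id)
        w_by_img = {img: ground_truth_weights(bank, prof, cfg)
                    for img, bank in banks.items()}
        weights_out[prof.participant_id] = w_by_img
        tw = np.empty(trials.features.shape)
        img_col = trials.df["image_id"].to_numpy()
        for img in banks:
            sel = img_col == img
            tw[sel] = w_by_img[img][trials.features[sel]]
        outcome, rt = simulate_response(tw, cfg.observer, rng,
                                        prof.rt_base_ms, prof.rt_sd_ms)
        true_cat = trials.df["true_category"].to_numpy()
        response = np.where(
            outcome == "correct", true_cat,
            np.where(outcome == "unsure", "unsure",
                     [_other_category(c, categories, rng) for c in true_cat]))
        trials.df["response"] = response
        trials.df["rt_ms"] = np.round(rt, 1)
        tables.append(trials)
    df = pd.concat([t.df for t in tables], ignore_index=True)
    df["trial_id"] = np.arange(len(df))
    feats = np.vstack([t.features for t in tables])
    return TrialTable(df, feats), profiles, weights_out


def _cat(image_id: str) -> str:
    from .stimulus import category_of

    return category_of(image_id)


def _other_category(true_cat: str, categories: list[str],
                    rng: np.random.Generator) -> str:
    others = [c for c in categories if c != true_cat]
    if not others:
        return true_cat  # single-category experiment: "wrong" is unobservable
    return others[int(rng.integers(len(others)))]


# ---------------------------------------------------------------------------
# synthetic inputs: feature banks and portrait images


def random_feature_bank(image_id: str, geom: ImageGeometry | None = None,
                        ladder: LadderConfig | None = None,
                        n_features: int = 1000,
                        rng: np.random.Generator | None = None) -> FeatureBank:
    """A simulated feature bank: wavelets drawn from the ladder with
    per-frequency probabilities following the nw = 272 * sf**1.8 rule,
    uniform positions and orientations from the 18-step grid.

    Pseudo-covariances (sorted descending, as a decomposition would rank
    them) are attached so downstream weight planting behaves as with a real
    bank.  Synthetic: no image is decomposed.
    """
    geom = geom or ImageGeometry()
    ladder = ladder or LadderConfig()
    rng = rng if rng is not None else np.random.default_rng()
    sf_vals = ladder.sf_values
    probs = ladder.nw_scale * sf_vals**ladder.nw_exponent
    probs = probs / probs.sum()
    levels = rng.choice(ladder.n_levels, size=n_features, p=probs)
    oris = ladder.orientations_deg
    wavelets = []
    for lev in levels:
        sf = float(sf_vals[lev])
        wavelets.append(GaborWavelet(
            x_px=float(rng.integers(geom.side_px)),
            y_px=float(rng.integers(geom.side_px)),
            sf_cpd=sf,
            orientation_deg=float(oris[rng.integers(len(oris))]),
            phase_rad=float(rng.uniform(0, 2 * np.pi)),
            sigma_px=default_sigma_px(sf, geom),
            amplitude=1.0,
        ))
    cov = np.sort(np.abs(rng.normal(0.0, 1.0, n_features)))[::-1]
    return FeatureBank(image_id=image_id, geometry=geom, wavelets=wavelets,
                       covariances=cov)


def synthetic_portrait(image_id: str, geom: ImageGeometry | None = None,
                       rng: np.random.Generator | None = None
                       ) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Synthetic animal-portrait stand-in: 1/f noise plus a head blob and
    two darker eye blobs.  Returns (float image spanning 0-255, eye points
    in pixel coordinates).  Broadband by construction so the decomposition
    finds candidates at every ladder level.
    """
    geom = geom or ImageGeometry()
    rng = rng if rng is not None else np.random.default_rng()
    n = geom.side_px
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.rfftfreq(n)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0
    spectrum = (rng.normal(size=(n, f.shape[1]))
                + 1j * rng.normal(size=(n, f.shape[1]))) / f**1.2
    noise = np.fft.irfft2(spectrum, s=(n, n))
    noise = (noise - noise.mean()) / noise.std()

    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    cx = cy = (n - 1) / 2.0
    head = 1.6 * np.exp(-(((xx - cx) / (0.32 * n)) ** 2
                          + ((yy - cy) / (0.38 * n)) ** 2))
    eye_dx = 0.14 * n * rng.uniform(0.85, 1.15)
    eye_y = cy - 0.10 * n * rng.uniform(0.8, 1.2)
    eyes = [(cx - eye_dx, eye_y), (cx + eye_dx, eye_y)]
    img = noise + head
    for ex, ey in eyes:
        img = img - 2.2 * np.exp(-(((xx - ex) ** 2 + (yy - ey) ** 2)
                                   / (2 * (0.02 * n) ** 2)))
    img = img - img.min()
    img = img * (255.0 / img.max())
    return img, eyes


# ---------------------------------------------------------------------------
# AQ CSV round trip


def cohort_to_csv(profiles: list[ParticipantProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        row = {"participant_id": p.participant_id}
        row.update({f"item_{i + 1:02d}": int(v)
                    for i, v in enumerate(p.aq_items)})
        row["aq_total"] = p.aq_total
        row["group"] = p.group
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def cohort_from_csv(path: str | Path) -> list[ParticipantProfile]:
    df = pd.read_csv(path)
    item_cols = [f"item_{i:02d}" for i in range(1, N_ITEMS + 1)]
    profiles = []
    for row in df.itertuples():
        items = np.array([getattr(row, c) for c in item_cols], dtype=int)
        if int(row.aq_total) != int(items.sum()):
            raise ValueError(
                f"participant {row.participant_id}: aq_total != item sum")
        profiles.append(ParticipantProfile(
            participant_id=str(row.participant_id), aq_items=items,
            group=str(row.group)))
    return profiles
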