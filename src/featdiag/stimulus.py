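"""Trial construction: random 90-feature subsets, session plans and the
long-format trial table with CSV round-tripping.

Each trial presents a partial reconstruction of one image: the sum of a
random subset (default 90) of that image's 1,000-wavelet bank, rescaled to
the full 0-255 display range.  A session shows every image a fixed number
of times (default 50) in randomized order; participants complete a variable
number of sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import FeatureBank, rescale_to_display, sum_features

__all__ = [
    "TrialSpec",
    "SessionPlan",
    "TrialTable",
    "sample_subset",
    "build_experiment",
    "render_trial",
]

DEFAULT_SUBSET_SIZE = 90

#: CSV schema of the long-format trial table (feature ids semicolon-joined)
TRIAL_COLUMNS = [
    "trial_id", "participant_id", "session", "image_id", "true_category",
    "feature_ids",
]


@dataclass(frozen=True)
class TrialSpec:
    trial_id: int
    participant_id: str
    session: int
    image_id: str
    feature_ids: tuple[int, ...]
    true_category: str


@dataclass(frozen=True)
class SessionPlan:
    """One session: every image appears exactly ``trials_per_image`` times,
    in randomized order."""

    trials_per_image: int = 50
    subset_size: int = DEFAULT_SUBSET_SIZE


def sample_subset(bank: FeatureBank, k: int = DEFAULT_SUBSET_SIZE,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Uniform sample of ``k`` feature ids without replacement."""
    rng = rng if rng is not None else np.random.default_rng()
    if k > bank.n_features:
        raise ValueError(f"k={k} exceeds bank size {bank.n_features}")
    return np.sort(rng.choice(bank.n_features, size=k, replace=False))


def category_of(image_id: str) -> str:
    """Image category from its id prefix (e.g. 'cat3' -> 'cat')."""
    return "".join(ch for ch in image_id if not ch.isdigit()) or image_id


class TrialTable:
    """Long-format behavioral records.

    ``df`` holds the per-trial metadata (and, once simulated or ingested,
    ``response`` in {correct, wrong, unsure} and ``rt_ms``); ``features`` is
    the aligned (n_trials, subset_size) integer array of presented feature
    ids, kept separate for fast vectorized reverse correlation.
    """

    def __init__(self, df: pd.DataFrame, features: np.ndarray):
        if len(df) != len(features):
            raise ValueError("df and features row counts differ")
        self.df = df.reset_index(drop=True)
        self.features = np.asarray(features, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_responses(self) -> bool:
        return "response" in self.df.columns

    def validate_against(self, banks: dict[str, FeatureBank]) -> None:
        """Check feature ids and image ids against the banks; raises with
        offending row numbers."""
        for image_id, sub in self.df.groupby("image_id", sort=False):
            if image_id not in banks:
                raise ValueError(f"trials reference unknown image {image_id!r}")
            n = banks[image_id].n_features
            feats = self.features[sub.index.to_numpy()]
            bad = (feats < 0) | (feats >= n)
            if bad.any():
                rows = sub.index.to_numpy()[bad.any(axis=1)]
                raise ValueError(
                    f"rows {rows.tolist()[:10]}: feature ids outside "
                    f"0..{n - 1} for image {image_id!r}")

    # ---- CSV round trip ----

    def to_csv(self, path: str | Path) -> None:
        out = self.df.copy()
        out["feature_ids"] = [";".join(map(str, row)) for row in self.features]
        cols = TRIAL_COLUMNS + [c for c in out.columns if c not in TRIAL_COLUMNS]
        out[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialTable":
        df = pd.read_csv(path)
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trial CSV missing columns {missing}")
        try:
            features = np.array(
                [[int(t) for t in s.split(";")] for s in df.pop("feature_ids")],
                dtype=np.int64)
        except ValueError as e:
            raise ValueError(f"malformed feature_ids column: {e}") from None
        return cls(df, features)


def build_experiment(banks: dict[str, FeatureBank],
                     n_sessions: int,
                     plan: SessionPlan,
                     rng: np.random.Generator,
                     participant_id: str = "p00",
                     shared_subsets: list[np.ndarray] | None = None,
                     ) -> TrialTable:
    """Concatenated shuffled sessions for one participant.

    Per-image trial count is ``n_sessions * plan.trials_per_image``.  Subsets
    are sampled independently per trial unless ``shared_subsets`` supplies a
    pre-drawn pool (one array of ids per trial, recycled in order).
    """
    if not banks:
        raise ValueError("no feature banks supplied")
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    rows, feats = [], []
    trial_id = 0
    for session in range(1, n_sessions + 1):
        image_seq = np.repeat(list(banks.keys()), plan.trials_per_image)
        rng.shuffle(image_seq)
        for image_id in image_seq:
            if shared_subsets is not None:
                subset = np.asarray(shared_subsets[trial_id % len(shared_subsets)])
            else:
                subset = sample_subset(banks[image_id], plan.subset_size, rng)
            rows.append((trial_id, participant_id, session, image_id,
                         category_of(image_id)))
            feats.append(subset)
            trial_id += 1
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS[:-1])
    return TrialTable(df, np.vstack(feats))


def render_trial(spec: TrialSpec | tuple, banks: dict[str, FeatureBank]
                 ) -> np.ndarray:
    """8-bit stimulus image for one trial: sum the subset, rescale to 0-255."""
    if isinstance(spec, TrialSpec):
        image_id, feature_ids = spec.image_id, spec.feature_ids
    else:
        image_id, feature_ids = spec
    bank = banks[image_id]
    return rescale_to_display(sum_features(bank, feature_ids))
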