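"""End-to-end runner: decomposition/banks -> stimuli -> simulation or
ingest -> FDi -> bin ANOVAs -> trait statistics, with JSON/CSV outputs.

Every output embeds the global seed and a hash of the configuration, so a
run is reproducible byte-for-byte given the same config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binstats, traitstats
from .cohort import (
    CohortConfig,
    default_trait_table,
    random_feature_bank,
    simulate_experiment,
    synthetic_portrait,
)
from .decompose import DecompositionConfig, decompose
from .fdi import per_feature_accuracy, permutation_p, zscore_fdi
from .geometry import FeatureBank, ImageGeometry
from .stimulus import SessionPlan, TrialTable

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "ingest_trials"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "featdiag_out"
    seed: int = 0
    # inputs: synthetic by default; or point at real artifacts
    n_images: int = 10
    side_px: int = 250
    extent_dva: float = 22.5
    bank_mode: str = "random"  # random | decompose | load
    bank_paths: dict[str, str] = field(default_factory=dict)
    image_paths: dict[str, str] = field(default_factory=dict)
    landmarks_path: str | None = None
    trials_path: str | None = None
    trait_table_path: str | None = None
    n_features: int = 1000
    # analysis switches
    bin_criteria: tuple[str, ...] = ("sf",)
    n_bins: int = 5
    n_splits: int = 100
    n_perm: int = 10000
    anova_model: str = "flat"
    # nested stage configs
    cohort: CohortConfig = field(default_factory=CohortConfig)
    decomposition: DecompositionConfig = field(default_factory=DecompositionConfig)
    trials_per_image_session: int = 50

    def config_hash(self) -> str:
        d = _as_jsonable(self)
        d.pop("out_dir", None)  # where outputs land does not change them
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        decomp = DecompositionConfig(**raw.pop("decomposition", {}))
        return cls(cohort=cohort, decomposition=decomp, **raw)


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (np.ndarray, tuple, list)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def ingest_trials(path: str | Path, banks: dict[str, FeatureBank]
                  ) -> TrialTable:
    """Load and validate a behavioral trials CSV against the feature banks.

    Feature ids are checked per image; the response column must be present
    (reported category label or 'unsure'); correctness is recomputed
    downstream from response vs true_category, with 'unsure' counting as
    not recognized.
    """
    trials = TrialTable.from_csv(path)
    if "response" not in trials.df.columns:
        raise ValueError("trials CSV has no response column")
    trials.validate_against(banks)
    return trials


def _build_banks(cfg: RunConfig, rng: np.random.Generator):
    geom = ImageGeometry(side_px=cfg.side_px, extent_dva=cfg.extent_dva)
    image_ids = ([f"cat{i}" for i in range(1, cfg.n_images // 2 + 1)]
                 + [f"dog{i}" for i in range(1, cfg.n_images
                                             - cfg.n_images // 2 + 1)])
    banks: dict[str, FeatureBank] = {}
    eye_points: dict[str, list[tuple[float, float]]] = {}
    if cfg.bank_mode == "load":
        for img, p in cfg.bank_paths.items():
            banks[img] = FeatureBank.from_csv(p)
    elif cfg.bank_mode == "decompose":
        for img in image_ids:
            if img in cfg.image_paths:
                from PIL import Image

                arr = np.asarray(
                    Image.open(cfg.image_paths[img]).convert("L"), dtype=float)
                eyes = None
            else:
                arr, eyes = synthetic_portrait(img, geom, rng)
            banks[img] = decompose(
                arr, cfg.decomposition, geom, rng, image_id=img)
            if eyes is not None:
                eye_points[img] = eyes
    elif cfg.bank_mode == "random":
        for img in image_ids:
            _, eyes = synthetic_portrait(img, geom, rng)
            banks[img] = random_feature_bank(
                img, geom, cfg.decomposition.ladder, cfg.n_features, rng)
            eye_points[img] = eyes
    else:
        raise ValueError(f"unknown bank_mode {cfg.bank_mode!r}")
    landmarks = None
    if cfg.landmarks_path:
        landmarks = binstats.Landmarks.from_json(cfg.landmarks_path)
    elif eye_points:
        landmarks = binstats.Landmarks(eye_points)
    return banks, landmarks


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write the report bundle to ``cfg.out_dir``.

    Returns the summary dictionary.  Stage failures surface as exceptions
    tagged with the stage name.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    meta = {"seed": cfg.seed, "config_hash": cfg.config_hash()}
    summary: dict = dict(meta)

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("banks")
        banks, landmarks = _build_banks(cfg, rng)
        summary["n_images"] = len(banks)

        _stage("trials")
        plan = SessionPlan(trials_per_image=cfg.trials_per_image_session)
        if cfg.trials_path:
            trials = ingest_trials(cfg.trials_path, banks)
            profiles = None
        else:
            trials, profiles, _ = simulate_experiment(
                cfg.cohort, banks, rng, plan=plan)
            trials.to_csv(out / "trials.csv")
        summary["n_trials"] = len(trials)

        _stage("fdi")
        n_feat = max(b.n_features for b in banks.values())
        raw = per_feature_accuracy(trials, n_features=n_feat)
        fdi = zscore_fdi(raw)
        fdi.to_csv(out / "fdi.csv")
        rep = permutation_p(fdi, cfg.n_splits, cfg.n_perm, rng)
        (out / "replicability.json").write_text(
            json.dumps({**meta, **rep.to_dict()}, indent=2))
        summary["replicability_r"] = rep.observed_r
        summary["replicability_p"] = rep.p_value

        _stage("bins")
        if profiles is not None:
            groups = {p.participant_id: p.group for p in profiles}
        else:
            med = None
            groups = {}
        anova_out: dict = dict(meta)
        for criterion in cfg.bin_criteria:
            values = binstats.feature_distances(banks, criterion, landmarks)
            spec = binstats.assign_bins(values, sorted(banks), cfg.n_bins,
                                        criterion)
            means = binstats.participant_bin_means(fdi, spec)
            entry = {"boundaries": spec.boundaries}
            if groups:
                means["group"] = means["participant_id"].map(groups)
                aov = binstats.two_way_anova(means, model=cfg.anova_model)
                t, dof, p = binstats.highest_bin_contrast(means, groups)
                entry["anova"] = aov.to_dict()
                entry["highest_bin_contrast"] = {"t": t, "df": dof, "p": p}
                if criterion == "sf":
                    summary["sf_interaction_p"] = (
                        aov.effects["interaction"]["p"])
            anova_out[criterion] = entry
            means.to_csv(out / f"bin_means_{criterion}.csv", index=False)
            if criterion == "sf":
                sf_means = means
        (out / "anova.json").write_text(
            json.dumps(_as_jsonable(anova_out), indent=2))

        _stage("traits")
        traits_out: dict = dict(meta)
        if profiles is not None and "sf" in cfg.bin_criteria:
            wide = sf_means.pivot(index="participant_id", columns="bin",
                                  values="value")
            reliance = np.array([
                traitstats.reliance_on_detail(wide.loc[p.participant_id].values)
                for p in profiles])
            if cfg.trait_table_path:
                table = traitstats.validate_trait_table(
                    pd.read_csv(cfg.trait_table_path))
            else:
                table = default_trait_table()
            effects = traitstats.trait_effects(reliance, profiles)
            fitres = traitstats.robust_regress(
                effects, table["log_diagnosticity"].to_numpy())
            traits_out.update({
                "robust_fit": dataclasses.asdict(fitres),
                "mean_reliance": float(reliance.mean()),
            })
            if np.isfinite(effects).all():
                F, df1, df2, p, contrasts = traitstats.subscale_anova(
                    effects, list(table["subscale"]))
                traits_out["subscale_anova"] = {
                    "F": F, "df1": df1, "df2": df2, "p": p}
                traits_out["contrasts"] = contrasts
            else:
                n_und = int(np.isnan(effects).sum())
                traits_out["subscale_anova"] = None
                traits_out["subscale_anova_skipped"] = (
                    f"{n_und} items with all-or-none endorsement")
            summary["robust_slope"] = fitres.slope
        (out / "traits.json").write_text(
            json.dumps(_as_jsonable(traits_out), indent=2))

        (out / "summary.json").write_text(
            json.dumps(_as_jsonable(summary), indent=2))
        lines = [f"{k}: {v}" for k, v in summary.items()]
        (out / "summary.txt").write_text("\n".join(lines) + "\n")
        return summary
    except Exception as e:
        raise RuntimeError(f"pipeline stage failed: {e}") from e
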