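"""Gabor-wavelet geometry: the spatial-frequency ladder, feature-count rule,
wavelet rendering, summation and display rescaling.

An image is modelled as a sparse sum of Gabor wavelets — sinusoidal gratings
windowed by an isotropic Gaussian envelope.  Spatial frequencies live on an
exponential ladder of 29 levels,

    sf(n) = (10/45) * 1.08**n,   n = 1..29,

covering 0.24 to 2.07 cycles per degree of visual angle (cpd) for the default
geometry (250 px spanning 22.5 deg).  The number of wavelets sampled at a
given frequency follows the power law  nw = 272 * sf**1.8, so fine detail is
represented by many small wavelets and coarse structure by few large ones.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ImageGeometry",
    "LadderConfig",
    "GaborWavelet",
    "FeatureBank",
    "ladder_sf",
    "features_per_sf",
    "render_wavelet",
    "sum_features",
    "rescale_to_display",
]


@dataclass(frozen=True)
class ImageGeometry:
    """Square image geometry: pixel count and angular extent.

    Pixel coordinates are 0-based (column = x, row = y) and wavelet centres
    sit on pixel centres.
    """

    side_px: int = 250
    extent_dva: float = 22.5

    def __post_init__(self) -> None:
        if self.side_px <= 0:
            raise ValueError(f"side_px must be positive, got {self.side_px}")
        if self.extent_dva <= 0:
            raise ValueError(f"extent_dva must be positive, got {self.extent_dva}")

    @property
    def px_per_dva(self) -> float:
        """Pixels per degree of visual angle (default 250/22.5 ~ 11.111)."""
        return self.side_px / self.extent_dva

    def to_dict(self) -> dict:
        return {"side_px": self.side_px, "extent_dva": self.extent_dva}

    @classmethod
    def from_dict(cls, d: dict) -> "ImageGeometry":
        return cls(side_px=int(d["side_px"]), extent_dva=float(d["extent_dva"]))


@dataclass(frozen=True)
class LadderConfig:
    """Parameters of the exponential spatial-frequency ladder and the
    per-frequency feature-count rule."""

    n_levels: int = 29
    base: float = 10.0 / 45.0
    growth: float = 1.08
    nw_scale: float = 272.0
    nw_exponent: float = 1.8
    n_orientations: int = 18

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.growth <= 1:
            raise ValueError("growth must be > 1")
        if self.n_orientations < 1:
            raise ValueError("n_orientations must be >= 1")

    @property
    def orientations_deg(self) -> np.ndarray:
        """Equidistant grating orientations covering [0, 180), default
        0..170 in steps of 10."""
        return np.arange(self.n_orientations) * (180.0 / self.n_orientations)

    @property
    def sf_values(self) -> np.ndarray:
        return np.array([ladder_sf(n, self) for n in range(1, self.n_levels + 1)])


def ladder_sf(n: int, cfg: LadderConfig | None = None) -> float:
    """Spatial frequency (cpd) at ladder level ``n`` (1-based).

    sf = base * growth**n; with the defaults this is (10/45) * 1.08**n,
    giving exactly 0.24 cpd at n=1 and 2.07 cpd (2 dp) at n=29.
    """
    cfg = cfg or LadderConfig()
    if not 1 <= n <= cfg.n_levels:
        raise ValueError(f"ladder level n={n} outside 1..{cfg.n_levels}")
    return cfg.base * cfg.growth**n


def features_per_sf(sf_cpd: float, cfg: LadderConfig | None = None) -> int:
    """Number of wavelets sampled at frequency ``sf_cpd``:
    round(272 * sf**1.8) with the default rule (21 at 0.24 cpd, 1008 at
    2.07 cpd)."""
    cfg = cfg or LadderConfig()
    if sf_cpd <= 0:
        raise ValueError(f"sf_cpd must be positive, got {sf_cpd}")
    return int(round(cfg.nw_scale * sf_cpd**cfg.nw_exponent))


@dataclass(frozen=True)
class GaborWavelet:
    """One image feature: a Gabor wavelet.

    x_px, y_px      centre position (column, row), 0-based pixel indices
    sf_cpd          spatial frequency in cycles / degree visual angle
    orientation_deg grating orientation in [0, 180)
    phase_rad       phase in [0, 2*pi)
    sigma_px        Gaussian envelope standard deviation in pixels
    amplitude       unitless scale
    """

    x_px: float
    y_px: float
    sf_cpd: float
    orientation_deg: float
    phase_rad: float
    sigma_px: float
    amplitude: float = 1.0


#: envelope width as a fraction of the grating wavelength (~1-octave bandwidth)
SIGMA_PER_WAVELENGTH = 0.5


def wavelength_px(sf_cpd: float, geom: ImageGeometry) -> float:
    """Grating period in pixels for a frequency in cpd."""
    return geom.px_per_dva / sf_cpd


def default_sigma_px(sf_cpd: float, geom: ImageGeometry,
                     sigma_factor: float = SIGMA_PER_WAVELENGTH) -> float:
    return sigma_factor * wavelength_px(sf_cpd, geom)


def _patch_slices(w: GaborWavelet, geom: ImageGeometry, n_sigma: float = 4.0):
    """Bounding box (row slice, col slice) of the wavelet's support,
    truncated at ``n_sigma`` envelope widths and clipped to the image."""
    r = int(math.ceil(n_sigma * w.sigma_px))
    x0, y0 = int(round(w.x_px)), int(round(w.y_px))
    c0, c1 = max(0, x0 - r), min(geom.side_px, x0 + r + 1)
    r0, r1 = max(0, y0 - r), min(geom.side_px, y0 + r + 1)
    return slice(r0, r1), slice(c0, c1)


def _render_patch(w: GaborWavelet, geom: ImageGeometry, rows: slice, cols: slice
                  ) -> np.ndarray:
    yy, xx = np.mgrid[rows, cols]
    dx = xx - w.x_px
    dy = yy - w.y_px
    th = math.radians(w.orientation_deg)
    xr = dx * math.cos(th) + dy * math.sin(th)
    f_cpp = w.sf_cpd / geom.px_per_dva  # cycles per pixel
    env = np.exp(-(dx * dx + dy * dy) / (2.0 * w.sigma_px**2))
    return w.amplitude * env * np.cos(2.0 * np.pi * f_cpp * xr + w.phase_rad)


def render_wavelet(w: GaborWavelet, geom: ImageGeometry) -> np.ndarray:
    """Render one wavelet into a full (side_px, side_px) float image.

    Value at the centre pixel with phase 0 equals ``amplitude``; the kernel
    decays to ~0 beyond a few envelope widths.
    """
    if not (0 <= w.x_px < geom.side_px and 0 <= w.y_px < geom.side_px):
        raise ValueError(
            f"wavelet centre ({w.x_px}, {w.y_px}) outside {geom.side_px}px image")
    img = np.zeros((geom.side_px, geom.side_px))
    rows, cols = _patch_slices(w, geom)
    img[rows, cols] = _render_patch(w, geom, rows, cols)
    return img


@dataclass
class FeatureBank:
    """The selected wavelets for one image, with dense integer feature ids.

    ``covariances`` optionally records each feature's covariance with the
    original grayscale image (filled by the decomposition; used to rank
    features and as a default base for simulated observer weights).
    """

    image_id: str
    geometry: ImageGeometry
    wavelets: list[GaborWavelet]
    covariances: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.covariances is not None:
            self.covariances = np.asarray(self.covariances, dtype=float)
            if len(self.covariances) != len(self.wavelets):
                raise ValueError("covariances length != number of wavelets")

    @property
    def n_features(self) -> int:
        return len(self.wavelets)

    @property
    def feature_ids(self) -> np.ndarray:
        return np.arange(self.n_features)

    @property
    def sf_cpd(self) -> np.ndarray:
        """Per-feature spatial frequencies (cpd), indexed by feature_id."""
        return np.array([w.sf_cpd for w in self.wavelets])

    @property
    def positions_px(self) -> np.ndarray:
        """(n_features, 2) array of (x_px, y_px) centres."""
        return np.array([[w.x_px, w.y_px] for w in self.wavelets])

    # ---- serialization: CSV of wavelets + JSON sidecar for geometry ----

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        df = pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "x_px": [w.x_px for w in self.wavelets],
                "y_px": [w.y_px for w in self.wavelets],
                "sf_cpd": [w.sf_cpd for w in self.wavelets],
                "orientation_deg": [w.orientation_deg for w in self.wavelets],
                "phase_rad": [w.phase_rad for w in self.wavelets],
                "sigma_px": [w.sigma_px for w in self.wavelets],
                "amplitude": [w.amplitude for w in self.wavelets],
            }
        )
        if self.covariances is not None:
            df["covariance"] = self.covariances
        df.to_csv(path, index=False)
        sidecar = {"image_id": self.image_id, "geometry": self.geometry.to_dict()}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureBank":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        if not (df["feature_id"].values == np.arange(len(df))).all():
            raise ValueError("feature_id column must be dense 0..N-1 and sorted")
        wavelets = [
            GaborWavelet(
                x_px=row.x_px, y_px=row.y_px, sf_cpd=row.sf_cpd,
                orientation_deg=row.orientation_deg, phase_rad=row.phase_rad,
                sigma_px=row.sigma_px, amplitude=row.amplitude,
            )
            for row in df.itertuples()
        ]
        cov = df["covariance"].to_numpy() if "covariance" in df.columns else None
        return cls(
            image_id=sidecar["image_id"],
            geometry=ImageGeometry.from_dict(sidecar["geometry"]),
            wavelets=wavelets,
            covariances=cov,
        )


def sum_features(bank: FeatureBank, ids, geom: ImageGeometry | None = None
                 ) -> np.ndarray:
    """Pixel-wise sum of the rendered wavelets with the given feature ids.

    Additive over disjoint id sets; the empty set gives a zero image.
    """
    geom = geom or bank.geometry
    img = np.zeros((geom.side_px, geom.side_px))
    n = bank.n_features
    for fid in ids:
        fid = int(fid)
        if not 0 <= fid < n:
            raise KeyError(f"unknown feature_id {fid} (bank has {n} features)")
        w = bank.wavelets[fid]
        rows, cols = _patch_slices(w, geom)
        img[rows, cols] += _render_patch(w, geom, rows, cols)
    return img


def rescale_to_display(img: np.ndarray) -> np.ndarray:
    """Affine-map a real image so min -> 0 and max -> 255, as uint8.

    Rounding is round-half-to-even (numpy's default), so the mapping is
    deterministic across platforms.  A constant image has no valid display
    mapping and raises.
    """
    img = np.asarray(img, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        raise ValueError("cannot rescale a constant image to the 0-255 range")
    out = (img - lo) * (255.0 / (hi - lo))
    return np.rint(out).astype(np.uint8)
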