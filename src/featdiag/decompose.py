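"""Iterative coarse-to-fine sparse Gabor decomposition.

A grayscale image is reduced to a fixed number of equal-amplitude Gabor
wavelets.  Frequencies are visited from the lowest to the highest ladder
level; at each level a quadrature Gabor filter bank (18 orientations)
yields, per pixel, the best-fitting orientation, phase and response
amplitude.  The top 25% of pixels by amplitude are candidates; ``nw``
of them (nw = 272 * sf**1.8) are sampled uniformly, candidates whose
covariance with the current input falls below one fifth of the maximum
observed covariance are discarded, and the survivors become regressors:
the next level's input is the least-squares residual of the current input
on them.  Finally the pooled survivors from all levels are ranked by
covariance with the *original* image and the top ``n_final`` (default
1000) are kept, amplitudes set equal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve
from sklearn.base import BaseEstimator

from .geometry import (
    FeatureBank,
    GaborWavelet,
    ImageGeometry,
    LadderConfig,
    SIGMA_PER_WAVELENGTH,
    _patch_slices,
    _render_patch,
    default_sigma_px,
    ladder_sf,
    features_per_sf,
    wavelength_px,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DecompositionConfig",
    "CandidateSet",
    "best_local_gabor",
    "iteration_select",
    "residual_update",
    "feature_covariance",
    "decompose",
    "SparseGaborDecomposer",
]


@dataclass(frozen=True)
class DecompositionConfig:
    """Tunables of the iterative selection.

    amplitude_quantile     fraction of pixels kept by the amplitude screen
    covariance_floor_ratio candidates below this fraction of the maximum
                           observed covariance are discarded
    n_final                size of the final bank
    sigma_factor           envelope SD as a fraction of the wavelength
    """

    ladder: LadderConfig = field(default_factory=LadderConfig)
    amplitude_quantile: float = 0.25
    covariance_floor_ratio: float = 0.2
    n_final: int = 1000
    sigma_factor: float = SIGMA_PER_WAVELENGTH
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.amplitude_quantile <= 1:
            raise ValueError("amplitude_quantile must be in (0, 1]")
        if not 0 <= self.covariance_floor_ratio < 1:
            raise ValueError("covariance_floor_ratio must be in [0, 1)")
        if self.n_final < 1:
            raise ValueError("n_final must be >= 1")


@dataclass
class CandidateSet:
    """Surviving wavelet candidates of one ladder iteration."""

    iteration: int
    wavelets: list[GaborWavelet]
    covariances: np.ndarray  # covariance with the iteration's input image

    def __len__(self) -> int:
        return len(self.wavelets)


def _gabor_kernel(sf_cpd: float, orientation_deg: float, geom: ImageGeometry,
                  sigma_factor: float, n_sigma: float = 4.0) -> np.ndarray:
    """Complex quadrature Gabor kernel (even = real part, odd = -imag of
    the conjugate used for correlation).  The even part is DC-corrected so
    responses to a constant image are zero."""
    sigma = default_sigma_px(sf_cpd, geom, sigma_factor)
    r = int(math.ceil(n_sigma * sigma))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    th = math.radians(orientation_deg)
    xr = xx * math.cos(th) + yy * math.sin(th)
    f_cpp = sf_cpd / geom.px_per_dva
    env = np.exp(-(xx * xx + yy * yy) / (2.0 * sigma**2))
    carrier = np.exp(1j * 2.0 * np.pi * f_cpp * xr)
    kern = env * carrier
    # remove the even part's DC leakage (odd part is zero-mean by symmetry)
    kern = kern - env * (kern.real.sum() / env.sum())
    return kern


def best_local_gabor(input_img: np.ndarray, sf_cpd: float,
                     geom: ImageGeometry,
                     ladder: LadderConfig | None = None,
                     sigma_factor: float = SIGMA_PER_WAVELENGTH):
    """Per-pixel best orientation, phase and response amplitude at one
    spatial frequency.

    The image is correlated with a quadrature pair of Gabor kernels at each
    of the 18 orientations (reflective boundary padding).  Per pixel, the
    orientation maximising quadrature energy wins; the phase is the argument
    of the complex response and the amplitude its magnitude.

    Returns (orientation_deg, phase_rad, amplitude) maps of the image shape.
    """
    ladder = ladder or LadderConfig()
    input_img = np.asarray(input_img, dtype=float)
    if wavelength_px(sf_cpd, geom) < 2.0:
        raise ValueError(
            f"sf {sf_cpd:.3f} cpd has wavelength < 2 px at this geometry")
    best_amp = np.full(input_img.shape, -np.inf)
    best_phase = np.zeros(input_img.shape)
    best_ori = np.zeros(input_img.shape)
    for ori in ladder.orientations_deg:
        kern = _gabor_kernel(sf_cpd, ori, geom, sigma_factor)
        r = kern.shape[0] // 2
        padded = np.pad(input_img, r, mode="reflect")
        # correlation with the conjugate kernel: angle(resp) is the
        # best-fitting phase, |resp| the response amplitude
        resp = fftconvolve(padded, np.conj(kern)[::-1, ::-1], mode="same")
        resp = resp[r:r + input_img.shape[0], r:r + input_img.shape[1]]
        amp = np.abs(resp)
        take = amp > best_amp
        best_amp[take] = amp[take]
        best_phase[take] = np.angle(resp)[take]
        best_ori[take] = ori
    return best_ori, np.mod(best_phase, 2.0 * np.pi), best_amp


def feature_covariance(w: GaborWavelet, img: np.ndarray,
                       geom: ImageGeometry | None = None) -> float:
    """Sample covariance over pixels between the rendered wavelet and the
    image (both mean-centered over all pixels)."""
    img = np.asarray(img, dtype=float)
    geom = geom or ImageGeometry(side_px=img.shape[0])
    return _patch_covariance(w, img - img.mean(), geom)


def _patch_covariance(w: GaborWavelet, img_centered: np.ndarray,
                      geom: ImageGeometry) -> float:
    """Covariance with a (pre-centered) image using only the wavelet's
    support patch; exact because the wavelet is zero outside the patch."""
    n = img_centered.size
    rows, cols = _patch_slices(w, geom)
    patch = _render_patch(w, geom, rows, cols)
    # cov = sum((w - wbar)(img - ibar)) / (n-1); with img centered the
    # cross term with wbar vanishes
    return float(np.sum(patch * img_centered[rows, cols]) / (n - 1))


def iteration_select(input_img: np.ndarray, sf_cpd: float,
                     cfg: DecompositionConfig, geom: ImageGeometry,
                     rng: np.random.Generator, iteration: int = 0
                     ) -> CandidateSet:
    """One ladder iteration: amplitude screen, nw-sample, covariance floor.

    Keeps the top ``amplitude_quantile`` of per-pixel candidates, samples
    min(nw, available) of them uniformly without replacement, computes each
    sampled wavelet's covariance with ``input_img`` and discards those below
    ``covariance_floor_ratio`` times the maximum observed covariance.
    """
    input_img = np.asarray(input_img, dtype=float)
    ori_map, phase_map, amp_map = best_local_gabor(
        input_img, sf_cpd, geom, cfg.ladder, cfg.sigma_factor)
    flat_amp = amp_map.ravel()
    n_keep = max(1, int(round(cfg.amplitude_quantile * flat_amp.size)))
    keep_idx = np.argpartition(flat_amp, -n_keep)[-n_keep:]
    nw = features_per_sf(sf_cpd, cfg.ladder)
    if nw > keep_idx.size:
        logger.info("iteration %d: nw=%d exceeds %d candidates, taking all",
                    iteration, nw, keep_idx.size)
        sampled = keep_idx
    else:
        sampled = rng.choice(keep_idx, size=nw, replace=False)
    sigma = default_sigma_px(sf_cpd, geom, cfg.sigma_factor)
    img_c = input_img - input_img.mean()
    wavelets = []
    covs = np.empty(sampled.size)
    side = geom.side_px
    for j, pix in enumerate(np.sort(sampled)):
        y, x = divmod(int(pix), side)
        w = GaborWavelet(
            x_px=float(x), y_px=float(y), sf_cpd=sf_cpd,
            orientation_deg=float(ori_map[y, x]),
            phase_rad=float(phase_map[y, x]),
            sigma_px=sigma, amplitude=1.0,
        )
        wavelets.append(w)
        covs[j] = _patch_covariance(w, img_c, geom)
    if covs.size:
        floor = cfg.covariance_floor_ratio * covs.max()
        survive = covs >= floor
    else:
        survive = np.zeros(0, dtype=bool)
    if not survive.any():
        logger.warning("iteration %d: no candidates survived the covariance "
                       "floor", iteration)
        return CandidateSet(iteration, [], np.empty(0))
    return CandidateSet(
        iteration,
        [w for w, s in zip(wavelets, survive) if s],
        covs[survive],
    )


def residual_update(prev_input: np.ndarray, selected: list[GaborWavelet],
                    geom: ImageGeometry) -> np.ndarray:
    """Residual of ``prev_input`` after least-squares regression on the
    rendered ``selected`` wavelets plus an intercept.

    The residual is orthogonal to each regressor.  A rank-deficient
    regressor matrix is handled by the minimum-norm solution.
    """
    if not selected:
        raise ValueError("residual_update requires at least one wavelet")
    prev_input = np.asarray(prev_input, dtype=float)
    n = prev_input.size
    X = np.empty((n, len(selected) + 1))
    X[:, 0] = 1.0
    for j, w in enumerate(selected, start=1):
        img = np.zeros((geom.side_px, geom.side_px))
        rows, cols = _patch_slices(w, geom)
        img[rows, cols] = _render_patch(w, geom, rows, cols)
        X[:, j] = img.ravel()
    y = prev_input.ravel()
    beta, residues, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        logger.warning("rank-deficient regressor matrix (rank %d of %d); "
                       "minimum-norm solution used", rank, X.shape[1])
    return (y - X @ beta).reshape(prev_input.shape)


def decompose(image: np.ndarray, cfg: DecompositionConfig | None = None,
              geom: ImageGeometry | None = None,
              rng: np.random.Generator | None = None,
              image_id: str = "image") -> FeatureBank:
    """Full coarse-to-fine decomposition of one grayscale image.

    Runs the ladder iterations with residual updates, pools the surviving
    candidates, ranks them by (signed) covariance with the original image
    and returns the top ``n_final`` with equal amplitudes.  Deterministic
    given the seed.
    """
    cfg = cfg or DecompositionConfig()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be a square 2-D array")
    geom = geom or ImageGeometry(side_px=image.shape[0])
    if geom.side_px != image.shape[0]:
        raise ValueError("geometry side_px does not match the image")
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)

    orig_c = image - image.mean()
    current = image.copy()
    pooled: list[GaborWavelet] = []
    for n in range(1, cfg.ladder.n_levels + 1):
        sf = ladder_sf(n, cfg.ladder)
        if wavelength_px(sf, geom) < 2.0:
            raise ValueError(
                f"ladder level {n} (sf={sf:.3f} cpd) is not representable at "
                f"{geom.side_px}px / {geom.extent_dva} dva")
        cand = iteration_select(current, sf, cfg, geom, rng, iteration=n)
        logger.info("iteration %d (sf=%.3f): %d survivors", n, sf, len(cand))
        pooled.extend(cand.wavelets)
        if cand.wavelets:
            current = residual_update(current, cand.wavelets, geom)

    if len(pooled) < cfg.n_final:
        raise RuntimeError(
            f"decomposition pooled only {len(pooled)} candidates but "
            f"n_final={cfg.n_final} (shortfall {cfg.n_final - len(pooled)})")
    final_cov = np.array([_patch_covariance(w, orig_c, geom) for w in pooled])
    order = np.argsort(-final_cov, kind="stable")[: cfg.n_final]
    wavelets = [replace(pooled[i], amplitude=1.0) for i in order]
    return FeatureBank(image_id=image_id, geometry=geom, wavelets=wavelets,
                       covariances=final_cov[order])


class SparseGaborDecomposer(BaseEstimator):
    """Estimator-style wrapper around :func:`decompose`.

    Parameters mirror :class:`DecompositionConfig`; ``fit(image)`` stores the
    selected features as ``bank_``.
    """

    def __init__(self, n_final: int = 1000, amplitude_quantile: float = 0.25,
                 covariance_floor_ratio: float = 0.2,
                 sigma_factor: float = SIGMA_PER_WAVELENGTH,
                 extent_dva: float = 22.5, random_state: int = 0):
        self.n_final = n_final
        self.amplitude_quantile = amplitude_quantile
        self.covariance_floor_ratio = covariance_floor_ratio
        self.sigma_factor = sigma_factor
        self.extent_dva = extent_dva
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None, image_id: str = "image"):
        X = np.asarray(X, dtype=float)
        cfg = DecompositionConfig(
            amplitude_quantile=self.amplitude_quantile,
            covariance_floor_ratio=self.covariance_floor_ratio,
            n_final=self.n_final, sigma_factor=self.sigma_factor,
            rng_seed=self.random_state,
        )
        geom = ImageGeometry(side_px=X.shape[0], extent_dva=self.extent_dva)
        self.bank_ = decompose(X, cfg, geom,
                               np.random.default_rng(self.random_state),
                               image_id=image_id)
        return self

    def transform(self, ids) -> np.ndarray:
        """Render the partial reconstruction of a feature-id subset."""
        from .geometry import sum_features

        return sum_features(self.bank_, ids)
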