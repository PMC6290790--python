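"""Decombing methods for single-band images.

Five corrections, four of them parameterised by a single characteristic
filter size ``r`` (pixels):

- ``gaussian``: 2-D Gaussian convolution with sigma = r;
- ``median``: sliding median over a 2r-by-2r window;
- ``fourier``: low-pass in the Fourier domain with cut-off f0 = 1/(2r)
  cycles/pixel (the smallest resolvable feature at Nyquist is then 2r);
- ``interpolation``: piecewise-linear (Delaunay) interpolation of the pixel
  values read at the fibre centres — r is not well defined for it;
- ``physical``: optical defocus applied at capture time, so the in-software
  correction is the identity (r maps to the axial displacement via
  r = |displacement / 0.5 um|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, cKDTree
from sklearn.base import BaseEstimator, TransformerMixin

from .centres import CentreFinderConfig, CentreMap, find_centres

__all__ = [
    "R_MIN",
    "R_MAX",
    "CorrectionConfig",
    "ScatteredInterpolator",
    "gaussian_decomb",
    "median_decomb",
    "fourier_decomb",
    "interpolation_decomb",
    "correct",
    "GaussianDecomber",
    "MedianDecomber",
    "FourierDecomber",
    "InterpolationDecomber",
    "PhysicalDecomber",
]

R_MIN, R_MAX = 1.0, 50.0

FILTER_METHODS = ("gaussian", "median", "fourier")
ALL_METHODS = ("interpolation", "fourier", "gaussian", "median", "physical")


def _check_r(r: float) -> float:
    r = float(r)
    if not (R_MIN <= r <= R_MAX):
        raise ValueError(f"characteristic filter size r={r} outside [{R_MIN}, {R_MAX}]")
    return r


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D single-band image")
    return image


def gaussian_decomb(image: np.ndarray, r: float) -> np.ndarray:
    """Gaussian smoothing with standard deviation r (mirror boundary)."""
    return ndimage.gaussian_filter(_check_image(image), _check_r(r), mode="reflect")


def median_decomb(image: np.ndarray, r: float) -> np.ndarray:
    """Sliding-window median over a 2r-by-2r region.

    The window side is 2r (not 2r+1); for even windows, which have no
    centre pixel, the window is anchored so the output pixel falls in its
    top-left quadrant, and the median of the even-sized sample is the upper
    order statistic (rank filtering, no averaging of the middle pair).
    """
    image = _check_image(image)
    w = max(2, int(round(2 * _check_r(r))))
    origin = -1 if w % 2 == 0 else 0
    return ndimage.median_filter(image, size=w, mode="reflect", origin=origin)


def fourier_decomb(image: np.ndarray, r: float, shape: str = "circular") -> np.ndarray:
    """Fourier low-pass: zero all spatial frequencies above f0 = 1/(2r).

    ``shape`` selects the pass-band support in the 2-D spectrum:
    ``circular`` (radial cut, isotropic; default) or ``square``
    (independent per-axis cut).  The DC component is always retained, so a
    constant image is unchanged.
    """
    image = _check_image(image)
    f0 = 1.0 / (2.0 * _check_r(r))
    fy = np.fft.fftfreq(image.shape[0])[:, None]
    fx = np.fft.fftfreq(image.shape[1])[None, :]
    if shape == "circular":
        keep = np.hypot(fy, fx) <= f0
    elif shape == "square":
        keep = (np.abs(fy) <= f0) & (np.abs(fx) <= f0)
    else:
        raise ValueError(f"unknown pass-band shape {shape!r}")
    return np.fft.ifft2(np.fft.fft2(image) * keep).real


class ScatteredInterpolator:
    """Piecewise-linear interpolation from scattered centres to a pixel grid.

    The Delaunay triangulation, the simplex lookup and the barycentric
    weights are precomputed once for a centre set and grid shape, so the
    same lookup table applies to any number of value vectors (e.g. all
    spectral bands).  Grid points outside the convex hull are filled with
    the nearest centre's value and flagged False in ``valid_mask``.
    """

    def __init__(self, points: np.ndarray, grid_shape: tuple[int, int]):
        points = np.asarray(points, dtype=float).reshape(-1, 2)
        if len(points) < 3:
            raise ValueError("need at least 3 centres to triangulate")
        try:
            tri = Delaunay(points)
        except Exception as exc:  # qhull degenerate input
            raise ValueError(f"cannot triangulate centres: {exc}") from exc
        if tri.simplices.size == 0:
            raise ValueError("cannot triangulate centres: all collinear")
        h, w = grid_shape
        yy, xx = np.mgrid[0:h, 0:w]
        q = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        simplex = tri.find_simplex(q)
        inside = simplex >= 0
        # barycentric coordinates for interior points
        t = tri.transform[simplex[inside]]
        bary2 = np.einsum("nij,nj->ni", t[:, :2, :], q[inside] - t[:, 2, :])
        bary = np.hstack([bary2, 1.0 - bary2.sum(axis=1, keepdims=True)])
        self.grid_shape = (h, w)
        self.points = points
        self._inside = inside
        self._vertices = tri.simplices[simplex[inside]]
        self._weights = bary
        self._outside_nearest = cKDTree(points).query(q[~inside])[1] if (~inside).any() else None
        self.valid_mask = inside.reshape(h, w)

    def __call__(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float).reshape(-1)
        if len(values) != len(self.points):
            raise ValueError("one value per centre required")
        flat = np.empty(self.grid_shape[0] * self.grid_shape[1], dtype=float)
        flat[self._inside] = (values[self._vertices] * self._weights).sum(axis=1)
        if self._outside_nearest is not None:
            flat[~self._inside] = values[self._outside_nearest]
        return flat.reshape(self.grid_shape)


def sample_at_centres(
    image: np.ndarray, centres: np.ndarray, sampling: str = "pixel"
) -> np.ndarray:
    """Read per-centre values: the nearest pixel (default, matching the
    single-pixel-per-fibrelet readout) or a small-disc (radius 1) mean."""
    image = _check_image(image)
    centres = np.asarray(centres, dtype=float).reshape(-1, 2)
    xs = np.clip(np.rint(centres[:, 0]).astype(int), 0, image.shape[1] - 1)
    ys = np.clip(np.rint(centres[:, 1]).astype(int), 0, image.shape[0] - 1)
    if sampling == "pixel":
        return image[ys, xs]
    if sampling == "disc":
        vals = np.empty(len(centres))
        for i, (x, y) in enumerate(zip(xs, ys)):
            y0, y1 = max(0, y - 1), min(image.shape[0], y + 2)
            x0, x1 = max(0, x - 1), min(image.shape[1], x + 2)
            vals[i] = image[y0:y1, x0:x1].mean()
        return vals
    raise ValueError(f"unknown sampling {sampling!r}")


def interpolation_decomb(
    image: np.ndarray,
    centre_map: CentreMap | np.ndarray,
    interpolator: ScatteredInterpolator | None = None,
    sampling: str = "pixel",
) -> np.ndarray:
    """Decomb by bilinear interpolation of the values at fibre centres."""
    image = _check_image(image)
    centres = getattr(centre_map, "centres", centre_map)
    if interpolator is None:
        interpolator = ScatteredInterpolator(centres, image.shape)
    return interpolator(sample_at_centres(image, centres, sampling=sampling))


@dataclass
class CorrectionConfig:
    """Method selection for :func:`correct`.

    ``r`` is required for the filter methods and meaningless for
    ``interpolation`` (spatially variant filter) and ``physical`` (the blur
    happened in hardware; the software step is the identity).
    """

    method: str
    r: float | None = None
    centre_map: CentreMap | None = None
    fourier_shape: str = "circular"

    def __post_init__(self) -> None:
        if self.method not in ALL_METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.method in FILTER_METHODS:
            if self.r is None:
                raise ValueError(f"method {self.method!r} requires r")
            _check_r(self.r)
        if self.method == "interpolation" and self.centre_map is None:
            raise ValueError("interpolation requires a centre_map")


def correct(image: np.ndarray, config: CorrectionConfig) -> np.ndarray:
    """Dispatch a correction according to ``config``."""
    if config.method == "gaussian":
        return gaussian_decomb(image, config.r)
    if config.method == "median":
        return median_decomb(image, config.r)
    if config.method == "fourier":
        return fourier_decomb(image, config.r, shape=config.fourier_shape)
    if config.method == "interpolation":
        return interpolation_decomb(image, config.centre_map)
    # physical: blur was applied optically at capture time
    return _check_image(image).copy()


class _Decomber(TransformerMixin, BaseEstimator):
    """Base for stateless image-to-image corrections."""

    def fit(self, X: np.ndarray, y=None):
        _check_image(X)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class GaussianDecomber(_Decomber):
    def __init__(self, r: float = 4.0):
        self.r = r

    def transform(self, X: np.ndarray) -> np.ndarray:
        return gaussian_decomb(X, self.r)


class MedianDecomber(_Decomber):
    def __init__(self, r: float = 4.0):
        self.r = r

    def transform(self, X: np.ndarray) -> np.ndarray:
        return median_decomb(X, self.r)


class FourierDecomber(_Decomber):
    def __init__(self, r: float = 4.0, shape: str = "circular"):
        self.r = r
        self.shape = shape

    def transform(self, X: np.ndarray) -> np.ndarray:
        return fourier_decomb(X, self.r, shape=self.shape)


class PhysicalDecomber(_Decomber):
    """Identity transform: the defocus blur happened at the point of imaging."""

    def transform(self, X: np.ndarray) -> np.ndarray:
        return _check_image(X).copy()


class InterpolationDecomber(TransformerMixin, BaseEstimator):
    """Centre-based decombing fitted on a bright-field calibration frame.

    ``fit`` locates the fibre centres (or accepts a precomputed
    ``centre_map``) and builds the interpolation lookup table once;
    ``transform`` then corrects any frame of the same shape by sampling it
    at the centres and interpolating.
    """

    def __init__(
        self,
        D: int = 9,
        I_min: float = 20.0,
        pre_blur_sigma: float = 0.0,
        centre_map: CentreMap | None = None,
        sampling: str = "pixel",
    ):
        self.D = D
        self.I_min = I_min
        self.pre_blur_sigma = pre_blur_sigma
        self.centre_map = centre_map
        self.sampling = sampling

    def fit(self, X: np.ndarray, y=None) -> "InterpolationDecomber":
        X = _check_image(X)
        if self.centre_map is not None:
            self.centre_map_ = self.centre_map
        else:
            cfg = CentreFinderConfig(
                D=self.D, I_min=self.I_min, pre_blur_sigma=self.pre_blur_sigma
            )
            self.centre_map_ = find_centres(X, cfg)
        if len(self.centre_map_) < 3:
            raise ValueError("too few centres found to triangulate")
        self.interpolator_ = ScatteredInterpolator(self.centre_map_.centres, X.shape)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "interpolator_"):
            raise RuntimeError("InterpolationDecomber is not fitted")
        X = _check_image(X)
        if X.shape != self.interpolator_.grid_shape:
            raise ValueError("frame shape differs from the fitted calibration frame")
        return self.interpolator_(
            sample_at_centres(X, self.centre_map_.centres, sampling=self.sampling)
        )
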