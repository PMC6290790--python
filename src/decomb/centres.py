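"""Fibre-centre detection from a bright-field calibration image.

The detector follows the classic local-neighbourhood scheme used in
fibre-bundle calibration: every pixel whose (2d+1)^2 neighbourhood spans an intensity range
above ``I_min`` is a candidate; each candidate is scored by how well a 2-D
quasi-Gaussian surface

    G(x, y) = H * exp(-l^4 / (2 D^2)),   H = I(x_c, y_c),

fits its neighbourhood (sum of squared residuals, lower is better); and
candidates are greedily accepted in ascending-score order subject to a
strict exclusion radius of one fibre diameter D around every accepted
centre.  The resulting centre map is built once from a calibration frame
and reused for all subsequent frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

__all__ = [
    "CentreFinderConfig",
    "CentreMap",
    "find_candidates",
    "score_candidate",
    "score_candidates",
    "build_centre_map",
    "find_centres",
    "FibreCentreFinder",
]


@dataclass(frozen=True)
class CentreFinderConfig:
    """Detector parameters.

    D is the neighbourhood side 2d+1, roughly one fibrelet diameter, and
    must be odd; ``I_min`` is the user's expected minimum intensity
    difference between fibrelet cores and cladding.  ``pre_blur_sigma``
    smooths the calibration frame first — 0 for monochrome frames, >0 for
    raw mosaic frames where it suppresses the CFA pattern (default there:
    half the super-pixel side).
    """

    D: int = 9
    I_min: float = 20.0
    pre_blur_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.D < 3 or self.D % 2 == 0:
            raise ValueError("D must be odd and >= 3")
        if self.I_min <= 0:
            raise ValueError("I_min must be positive")
        if self.pre_blur_sigma < 0:
            raise ValueError("pre_blur_sigma must be >= 0")

    @property
    def d(self) -> int:
        return (self.D - 1) // 2


@dataclass
class CentreMap:
    """Accepted fibre centres in acceptance (ascending-score) order."""

    centres: np.ndarray  # (m, 2) pixel (x, y)
    scores: np.ndarray  # (m,), ascending
    D: int

    def __post_init__(self) -> None:
        self.centres = np.asarray(self.centres, dtype=float).reshape(-1, 2)
        self.scores = np.asarray(self.scores, dtype=float).reshape(-1)
        if len(self.centres) != len(self.scores):
            raise ValueError("centres and scores must align")
        if np.any(np.diff(self.scores) < 0):
            raise ValueError("scores must ascend in acceptance order")

    def __len__(self) -> int:
        return len(self.centres)

    def min_pairwise_distance(self) -> float:
        if len(self) < 2:
            return np.inf
        from scipy.spatial.distance import pdist

        return float(pdist(self.centres).min())

    def assert_exclusion(self) -> None:
        """Raise if any two centres violate the strict > D exclusion."""
        if self.min_pairwise_distance() <= self.D:
            raise AssertionError("exclusion invariant violated: centres <= D apart")


def _neighbourhood_range(image: np.ndarray, D: int) -> np.ndarray:
    return ndimage.maximum_filter(image, size=D, mode="nearest") - ndimage.minimum_filter(
        image, size=D, mode="nearest"
    )


def find_candidates(image: np.ndarray, config: CentreFinderConfig) -> np.ndarray:
    """Candidate centre pixels (x, y), raster (row-major) order.

    A pixel is a candidate iff max(N) - min(N) > I_min over its full
    (2d+1)^2 neighbourhood N.  Pixels whose neighbourhood exits the image
    are discarded (partial neighbourhoods would bias the score).
    """
    image = np.asarray(image, dtype=float)
    d = config.d
    if min(image.shape) < config.D:
        raise ValueError("image smaller than the candidate neighbourhood")
    rng_map = _neighbourhood_range(image, config.D)
    mask = rng_map > config.I_min
    mask[:d, :] = mask[-d:, :] = False
    mask[:, :d] = mask[:, -d:] = False
    ys, xs = np.nonzero(mask)
    return np.column_stack([xs, ys])


def _quasi_gaussian_kernel(D: int) -> np.ndarray:
    d = (D - 1) // 2
    dy, dx = np.mgrid[-d : d + 1, -d : d + 1]
    l2 = dx.astype(float) ** 2 + dy.astype(float) ** 2
    return np.exp(-(l2**2) / (2.0 * D**2))


def score_candidate(
    image: np.ndarray, candidate, config: CentreFinderConfig
) -> float:
    """Quasi-Gaussian fit score s_c = sum_N (G - I)^2 for one candidate."""
    image = np.asarray(image, dtype=float)
    x, y = int(candidate[0]), int(candidate[1])
    d = config.d
    if not (d <= x < image.shape[1] - d and d <= y < image.shape[0] - d):
        raise ValueError("candidate neighbourhood exits the image")
    patch = image[y - d : y + d + 1, x - d : x + d + 1]
    g = image[y, x] * _quasi_gaussian_kernel(config.D)
    return float(((g - patch) ** 2).sum())


def score_candidates(
    image: np.ndarray, candidates: np.ndarray, config: CentreFinderConfig
) -> np.ndarray:
    """Vectorised scores for many candidates.

    Expands s_c = H^2 * sum(g^2) - 2 H * (g (x) I) + (1 (x) I^2) with
    H = I(x_c, y_c) so the whole score map costs two correlations.
    """
    image = np.asarray(image, dtype=float)
    g = _quasi_gaussian_kernel(config.D)
    cross = ndimage.correlate(image, g, mode="constant")
    sq = ndimage.correlate(image**2, np.ones_like(g), mode="constant")
    xs, ys = candidates[:, 0], candidates[:, 1]
    h = image[ys, xs]
    return h**2 * float((g**2).sum()) - 2.0 * h * cross[ys, xs] + sq[ys, xs]


def build_centre_map(
    candidates: np.ndarray, scores: np.ndarray, config: CentreFinderConfig
) -> CentreMap:
    """Greedy acceptance in ascending-score order with strict > D exclusion.

    Score ties are broken by raster order of the candidate coordinates.  A
    candidate is accepted iff its Euclidean distance to every already
    accepted centre exceeds D; the scan continues until all candidates are
    accepted or rejected.
    """
    candidates = np.asarray(candidates, dtype=int).reshape(-1, 2)
    scores = np.asarray(scores, dtype=float).reshape(-1)
    if len(candidates) != len(scores):
        raise ValueError("candidates and scores must align")
    if len(candidates) == 0:
        return CentreMap(centres=np.empty((0, 2)), scores=np.empty(0), D=config.D)

    order = np.lexsort((candidates[:, 0], candidates[:, 1], scores))
    D = float(config.D)
    cell = config.D  # accepted centres within distance D lie in the 3x3 cell patch
    grid: dict[tuple[int, int], list[int]] = {}
    accepted: list[int] = []
    pts = candidates.astype(float)
    for idx in order:
        x, y = pts[idx]
        cx, cy = int(x // cell), int(y // cell)
        ok = True
        for gx in range(cx - 1, cx + 2):
            for gy in range(cy - 1, cy + 2):
                for j in grid.get((gx, gy), ()):
                    dx, dy = x - pts[j, 0], y - pts[j, 1]
                    if dx * dx + dy * dy <= D * D:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            accepted.append(idx)
            grid.setdefault((cx, cy), []).append(idx)
    return CentreMap(
        centres=pts[accepted], scores=scores[accepted], D=config.D
    )


def build_centre_map_bruteforce(
    candidates: np.ndarray, scores: np.ndarray, config: CentreFinderConfig
) -> CentreMap:
    """O(n^2) reference implementation of the greedy acceptance."""
    candidates = np.asarray(candidates, dtype=int).reshape(-1, 2)
    scores = np.asarray(scores, dtype=float).reshape(-1)
    order = np.lexsort((candidates[:, 0], candidates[:, 1], scores))
    accepted: list[int] = []
    D = float(config.D)
    for idx in order:
        c = candidates[idx].astype(float)
        if all(np.hypot(*(c - candidates[j])) > D for j in accepted):
            accepted.append(idx)
    return CentreMap(
        centres=candidates[accepted].astype(float),
        scores=scores[accepted],
        D=config.D,
    )


def find_centres(image: np.ndarray, config: CentreFinderConfig) -> CentreMap:
    """Full pipeline: optional pre-blur, candidates, scores, greedy map."""
    image = np.asarray(image, dtype=float)
    if config.pre_blur_sigma > 0:
        image = ndimage.gaussian_filter(image, config.pre_blur_sigma, mode="reflect")
    candidates = find_candidates(image, config)
    if len(candidates) == 0:
        warnings.warn(
            "no candidate centres found: check I_min against the fibrelet/"
            "cladding contrast and D against the fibrelet diameter",
            stacklevel=2,
        )
        return CentreMap(centres=np.empty((0, 2)), scores=np.empty(0), D=config.D)
    scores = score_candidates(image, candidates, config)
    return build_centre_map(candidates, scores, config)


class FibreCentreFinder(BaseEstimator):
    """Estimator wrapper: fit on a calibration frame, keep the centre map.

    Parameters mirror :class:`CentreFinderConfig`.  After ``fit`` the
    detected map is available as ``centre_map_`` and the centre count as
    ``n_centres_``; the same map is meant to be reused for every subsequent
    frame of the session.
    """

    def __init__(self, D: int = 9, I_min: float = 20.0, pre_blur_sigma: float = 0.0):
        self.D = D
        self.I_min = I_min
        self.pre_blur_sigma = pre_blur_sigma

    def _config(self) -> CentreFinderConfig:
        return CentreFinderConfig(
            D=self.D, I_min=self.I_min, pre_blur_sigma=self.pre_blur_sigma
        )

    def fit(self, X: np.ndarray, y=None) -> "FibreCentreFinder":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a single 2-D calibration image")
        self.centre_map_ = find_centres(X, self._config())
        self.n_centres_ = len(self.centre_map_)
        return self

    def predict(self, X=None) -> np.ndarray:
        """Return the fitted centre coordinates (x, y)."""
        if not hasattr(self, "centre_map_"):
            raise RuntimeError("FibreCentreFinder is not fitted")
        return self.centre_map_.centres
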