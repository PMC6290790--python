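"""Performance metrics for comb correction and their score normalisation.

Five metrics characterise a corrected frame or cube:

- resolution R: the bar spacing at which the Michelson contrast of a
  multi-element bar target drops below 5%, read off a smoothing spline fit
  of contrast against spacing (5% rather than 1% keeps the threshold above
  the noise floor);
- smoothness sigma: spatial standard deviation over a flat-field region
  (band-averaged for cubes);
- signal S: mean intensity over a region of interest (averaged over the
  bands overlapping the fluorophore emission for cubes);
- speed t: median wall-clock correction time per frame;
- accuracy of spectral reconstruction Q: squared distance between the
  AUC-normalised spatially averaged cube spectrum and the AUC-normalised
  predicted spectrum E_k (cubes only).

Raw metrics are turned into [0, 1] scores by min-max normalisation across
the full comparison set of one benchmark run (1 = best, 0 = worst; for
signal larger raw values are better, for the others smaller).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

from .mosaic import SpectralCube
from .spectra import SIGNAL_BAND_SUBSET
from .synthetic import BarElement

__all__ = [
    "CONTRAST_THRESHOLD",
    "VALIDITY_THRESHOLD",
    "michelson_contrast",
    "contrast_curve",
    "resolution",
    "resolution_from_image",
    "smoothness",
    "signal",
    "speed",
    "asr",
    "normalise_scores",
]

#: Michelson-contrast threshold defining the resolution limit
CONTRAST_THRESHOLD = 0.05

#: contrast a spacing must exceed (at > MIN_VALID_SPACINGS distinct
#: spacings) for the spline fit to be attempted
VALIDITY_THRESHOLD = 0.01
MIN_VALID_SPACINGS = 3


def michelson_contrast(image: np.ndarray, element: BarElement) -> float:
    """Michelson contrast (Imax - Imin)/(Imax + Imin) of one bar element.

    The image rows of the element are averaged along the bar direction into
    a 1-D profile; Imax and Imin are the profile means over the central
    thirds of the ideal bar and space positions, which keeps the estimate
    unbiased under residual comb modulation and noise.
    """
    image = np.asarray(image, dtype=float)
    r0, r1 = element.rows
    profile = image[r0:r1, :].mean(axis=0)
    x = np.arange(profile.size, dtype=float)
    phase = ((x - element.phase) % element.spacing) / element.spacing
    # central third of the bar ([0, 0.5)) and of the space ([0.5, 1))
    bar_sel = np.abs(phase - 0.25) < 1.0 / 12.0
    space_sel = np.abs(phase - 0.75) < 1.0 / 12.0
    if not bar_sel.any() or not space_sel.any():
        raise ValueError("element too narrow to sample bar and space centres")
    i_max = profile[bar_sel].mean()
    i_min = profile[space_sel].mean()
    denom = i_max + i_min
    if denom <= 0:
        return 0.0
    return float((i_max - i_min) / denom)


def contrast_curve(
    image: np.ndarray, elements: list[BarElement]
) -> tuple[np.ndarray, np.ndarray]:
    """Mean signed contrast per distinct spacing, sorted by spacing.

    Elements sharing a spacing (phase-staggered chart elements) are
    averaged with their sign, so the aliasing beat between the bars and
    the fibre lattice — positive at some phases, negative at others —
    cancels, while genuinely resolved contrast is phase-independent and
    survives.
    """
    per_spacing: dict[float, list[float]] = {}
    for el in elements:
        per_spacing.setdefault(float(el.spacing), []).append(
            michelson_contrast(image, el)
        )
    spacings = np.array(sorted(per_spacing))
    contrasts = np.array([np.mean(per_spacing[s]) for s in spacings])
    return spacings, contrasts


def _loo_spline_smoothing(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """Leave-one-out choice of the smoothing factor; fixed fallback."""
    n = len(x)
    fallback = n * max(np.var(y), 1e-6) * 0.01
    if n < k + 3:
        return fallback
    grid = [0.0] + [n * np.var(y) * f for f in (1e-4, 1e-3, 1e-2, 1e-1)]
    best_s, best_err = fallback, np.inf
    for s in grid:
        errs = []
        for i in range(n):
            sel = np.arange(n) != i
            if sel.sum() < k + 1:
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sp = UnivariateSpline(x[sel], y[sel], k=k, s=s)
                errs.append((float(sp(x[i])) - y[i]) ** 2)
            except Exception:
                errs = None
                break
        if errs:
            err = float(np.mean(errs))
            if err < best_err:
                best_err, best_s = err, s
    return best_s


def resolution(
    spacings: np.ndarray, contrasts: np.ndarray
) -> float:
    """Resolution R: the spacing at the 5% Michelson-contrast crossing.

    A smoothing spline is fitted to contrast versus spacing and evaluated
    densely; R is the largest spacing below which the contrast stays under
    5%.  If the contrast never drops below 5% the target limits the
    measurement and R equals the smallest printed spacing.  If fewer than
    4 distinct spacings show contrast above 1%, no spline is fitted and R
    is undefined (returned as NaN).
    """
    spacings = np.asarray(spacings, dtype=float)
    contrasts = np.asarray(contrasts, dtype=float)
    order = np.argsort(spacings)
    spacings, contrasts = spacings[order], contrasts[order]
    valid = np.unique(spacings[contrasts > VALIDITY_THRESHOLD])
    if valid.size <= MIN_VALID_SPACINGS:
        return float("nan")
    k = min(3, len(spacings) - 1)
    s = _loo_spline_smoothing(spacings, contrasts, k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spline = UnivariateSpline(spacings, contrasts, k=k, s=s)
    dense = np.linspace(spacings[0], spacings[-1], 2048)
    fit = spline(dense)
    below = fit < CONTRAST_THRESHOLD
    if not below.any():
        return float(spacings[0])  # resolution limited by the target
    if below.all():
        return float("nan")
    last_below = np.nonzero(below)[0][-1]
    if last_below == len(dense) - 1:
        return float(dense[-1])
    # linear refinement of the crossing between the two dense samples
    x0, x1 = dense[last_below], dense[last_below + 1]
    y0, y1 = fit[last_below], fit[last_below + 1]
    if y1 == y0:
        return float(x1)
    return float(x0 + (CONTRAST_THRESHOLD - y0) * (x1 - x0) / (y1 - y0))


def resolution_from_image(
    image: np.ndarray | SpectralCube, elements: list[BarElement]
) -> float:
    """Resolution of a corrected frame, or the band-average for a cube."""
    if isinstance(image, SpectralCube):
        per_band = [
            resolution(*contrast_curve(image[k], elements))
            for k in range(image.n_bands)
        ]
        per_band = np.asarray(per_band, dtype=float)
        if np.isnan(per_band).all():
            return float("nan")
        return float(np.nanmean(per_band))
    return resolution(*contrast_curve(np.asarray(image, float), elements))


def _region_view(image: np.ndarray, region) -> np.ndarray:
    if region is None:
        return image
    x0, y0, x1, y1 = region
    return image[y0:y1, x0:x1]


def smoothness(
    image: np.ndarray | SpectralCube, region: tuple[int, int, int, int] | None = None
) -> float:
    """Spatial (population) standard deviation over a flat-field region;
    band-averaged for spectral cubes."""
    if isinstance(image, SpectralCube):
        return float(
            np.mean([_region_view(image[k], region).std() for k in range(image.n_bands)])
        )
    return float(_region_view(np.asarray(image, float), region).std())


def signal(
    image: np.ndarray | SpectralCube,
    roi: tuple[int, int, int, int] | None = None,
    band_subset: tuple[int, ...] = SIGNAL_BAND_SUBSET,
) -> float:
    """Mean intensity over the ROI; for cubes, averaged over the bands that
    overlap the fluorophore emission (default: the 665 nm and 714 nm narrow
    bands plus the broadband)."""
    if isinstance(image, SpectralCube):
        return float(
            np.mean([_region_view(image[k], roi).mean() for k in band_subset])
        )
    return float(_region_view(np.asarray(image, float), roi).mean())


def speed(correction, frame: np.ndarray, repeats: int = 5) -> float:
    """Median wall-clock seconds per corrected frame over >= 5 repeats.

    Reported alongside the other metrics but never entered into the overall
    performance score, since speed can be optimised independently.
    """
    repeats = max(5, int(repeats))
    times = []
    for _ in range(repeats):
        t0 = time.perf_counter()
        correction(frame)
        times.append(time.perf_counter() - t0)
    return float(np.median(times))


def asr(cube: SpectralCube | np.ndarray, expected: np.ndarray) -> float:
    """Accuracy-of-spectral-reconstruction distance Q.

    Each band is spatially averaged over all pixels *first*; the resulting
    measured spectrum and the predicted spectrum E_k are both normalised to
    unit area, and Q is the sum over bands of the squared differences.
    Averaging before normalisation keeps non-smoothness (already captured
    by the smoothness metric) out of Q.
    """
    measured = (
        cube.band_means() if isinstance(cube, SpectralCube) else np.asarray(cube, float)
    )
    if measured.ndim == 3:
        measured = measured.mean(axis=(1, 2))
    expected = np.asarray(expected, dtype=float)
    if measured.shape != expected.shape:
        raise ValueError("cube and calibration must share the band count")
    ms, es = measured.sum(), expected.sum()
    if ms <= 0 or es <= 0:
        warnings.warn("zero-sum spectrum: Q undefined", stacklevel=2)
        return float("nan")
    diff = measured / ms - expected / es
    return float((diff**2).sum())


@dataclass
class NormalisationRefs:
    """Min/max reference values used for the score normalisation."""

    R_min: float
    R_max: float
    sigma_min: float
    sigma_max: float
    S_min: float
    S_max: float
    Q_min: float | None = None
    Q_max: float | None = None


def _minmax_score(values: np.ndarray, larger_is_better: bool) -> np.ndarray:
    vmin, vmax = np.min(values), np.max(values)
    if vmax == vmin:
        warnings.warn(
            "degenerate comparison set (max == min): scores set to 1", stacklevel=2
        )
        return np.ones_like(values)
    frac = (values - vmin) / (vmax - vmin)
    return frac if larger_is_better else 1.0 - frac


def normalise_scores(raw: pd.DataFrame) -> tuple[pd.DataFrame, NormalisationRefs]:
    """Min-max scores across one comparison set of correction variants.

    ``raw`` must carry columns ``R``, ``sigma``, ``S`` and optionally ``Q``
    (one row per method x r entry).  Undefined resolutions (NaN) take the
    set's R_max so their resolution score is 0.  Returns the score table
    (columns ``S_res``, ``S_smooth``, ``S_signal`` and, when Q is present,
    ``S_ASR``) and the reference values used.
    """
    required = {"R", "sigma", "S"}
    if not required.issubset(raw.columns):
        raise ValueError(f"raw metrics must include columns {sorted(required)}")
    if len(raw) < 2:
        raise ValueError("comparison set needs at least 2 entries")
    R = raw["R"].to_numpy(dtype=float).copy()
    if np.isnan(R).all():
        raise ValueError("resolution undefined for every entry")
    r_max_defined = np.nanmax(R)
    undefined = np.isnan(R)
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} entry(ies) with undefined resolution "
            "assigned the comparison set's R_max",
            stacklevel=2,
        )
        R[undefined] = r_max_defined
    sig = raw["sigma"].to_numpy(dtype=float)
    S = raw["S"].to_numpy(dtype=float)
    scores = pd.DataFrame(index=raw.index)
    scores["S_res"] = _minmax_score(R, larger_is_better=False)
    scores["S_smooth"] = _minmax_score(sig, larger_is_better=False)
    scores["S_signal"] = _minmax_score(S, larger_is_better=True)
    refs = NormalisationRefs(
        R_min=float(np.min(R)),
        R_max=float(np.max(R)),
        sigma_min=float(np.min(sig)),
        sigma_max=float(np.max(sig)),
        S_min=float(np.min(S)),
        S_max=float(np.max(S)),
    )
    if "Q" in raw.columns:
        Q = raw["Q"].to_numpy(dtype=float)
        scores["S_ASR"] = _minmax_score(Q, larger_is_better=False)
        refs.Q_min = float(np.min(Q))
        refs.Q_max = float(np.max(Q))
    return scores, refs
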