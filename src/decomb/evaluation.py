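"""Overall-performance scoring, weight-simplex sweeps and the benchmark.

Each correction variant's four scores are combined into a single overall
performance value

    OP = w_res*S_res + w_smooth*S_smooth + w_signal*S_signal + w_ASR*S_ASR

with application-dependent weights on the simplex (summing to one; for
monochrome imaging w_ASR = 0).  Because the best weighting depends on the
application, OP is evaluated over the whole weight simplex and the winning
(method, r) pair is recorded at every grid point, producing the winner map
from which a user reads off the preferred correction for their own
priorities.  Speed is reported but never enters OP.

``run_benchmark`` is the end-to-end driver: it generates a synthetic comb
and test targets, builds the fibre-centre map once from a calibration
frame, applies every correction variant, computes the metrics, normalises
them across the whole comparison set and sweeps the weights.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .centres import CentreFinderConfig, CentreMap, find_centres
from .correct import (
    CorrectionConfig,
    ScatteredInterpolator,
    correct,
    interpolation_decomb,
)
from .metrics import (
    normalise_scores,
    resolution_from_image,
    signal,
    smoothness,
    asr,
)
from .mosaic import (
    CFAPattern,
    centre_based_demosaick,
    demosaick_then_filter,
    interpolate_centre_spectra,
    simple_demosaick,
)
from .spectra import default_calibration
from .synthetic import (
    DEFAULT_DARK_LEVEL,
    DEFAULT_NOISE_SIGMA,
    CombSpec,
    SceneSpectrum,
    apply_comb,
    generate_comb,
    make_target,
    simulate_defocus,
    simulate_ms_capture,
)

__all__ = [
    "WeightVector",
    "PerformanceMap",
    "BenchmarkConfig",
    "BenchmarkResult",
    "overall_performance",
    "simplex_grid",
    "sweep_weights",
    "run_benchmark",
]

logger = logging.getLogger(__name__)

#: fixed tie-break order over methods (then ascending r)
TIE_BREAK_ORDER = ("interpolation", "fourier", "gaussian", "median", "physical")

SCORE_COLUMNS = ("S_res", "S_smooth", "S_signal", "S_ASR")


@dataclass(frozen=True)
class WeightVector:
    """Application weights on the simplex (w_ASR = 0 for monochrome)."""

    w_res: float = 0.25
    w_smooth: float = 0.25
    w_signal: float = 0.25
    w_asr: float = 0.25

    def __post_init__(self) -> None:
        vals = self.as_array()
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("weights must lie in [0, 1]")
        if not np.isclose(vals.sum(), 1.0, atol=1e-9):
            raise ValueError("weights must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_res, self.w_smooth, self.w_signal, self.w_asr])


def overall_performance(scores, w: WeightVector | np.ndarray) -> float:
    """Weighted sum of the four scores (speed excluded by construction).

    ``scores`` may be a mapping with keys S_res/S_smooth/S_signal/S_ASR
    (S_ASR optional, treated as 0-weighted absent) or a length-4 vector.
    """
    wv = w.as_array() if isinstance(w, WeightVector) else np.asarray(w, float)
    if hasattr(scores, "get"):
        s = np.array([float(scores.get(c, 0.0)) for c in SCORE_COLUMNS])
    else:
        s = np.asarray(scores, dtype=float)
    return float(wv @ s)


def simplex_grid(active: tuple[str, ...], step: float) -> np.ndarray:
    """All weight vectors (w_res, w_smooth, w_signal, w_ASR) whose support
    lies in ``active`` and whose entries are multiples of ``step`` summing
    to one."""
    names = ("res", "smooth", "signal", "asr")
    idx = [names.index(a) for a in active]
    n = int(round(1.0 / step))
    if not np.isclose(n * step, 1.0):
        raise ValueError("1/step must be an integer")
    out = []
    if len(idx) == 3:
        for i in range(n + 1):
            for j in range(n + 1 - i):
                k = n - i - j
                w = np.zeros(4)
                w[idx[0]], w[idx[1]], w[idx[2]] = i / n, j / n, k / n
                out.append(w)
    elif len(idx) == 4:
        for i in range(n + 1):
            for j in range(n + 1 - i):
                for k in range(n + 1 - i - j):
                    l = n - i - j - k
                    w = np.zeros(4)
                    w[idx[0]], w[idx[1]], w[idx[2]], w[idx[3]] = (
                        i / n, j / n, k / n, l / n,
                    )
                    out.append(w)
    else:
        raise ValueError("active must name 3 or 4 weights")
    return np.asarray(out)


@dataclass
class PerformanceMap:
    """Winner per weight-grid point: method, its r, and the attained OP."""

    weights: np.ndarray  # (G, 4)
    winner_method: np.ndarray  # (G,) str
    winner_r: np.ndarray  # (G,) float (NaN where r is undefined)
    op: np.ndarray  # (G,)
    grid_step: float

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.weights, columns=["w_res", "w_smooth", "w_signal", "w_ASR"]
        )
        df["method"] = self.winner_method
        df["r"] = self.winner_r
        df["OP"] = self.op
        return df

    def winner_at(self, w: WeightVector) -> tuple[str, float]:
        """Winner at the grid point nearest to ``w``."""
        d = np.abs(self.weights - w.as_array()).sum(axis=1)
        i = int(np.argmin(d))
        return str(self.winner_method[i]), float(self.winner_r[i])


def _entry_sort_key(method: str, r: float) -> tuple[int, float]:
    rank = TIE_BREAK_ORDER.index(method) if method in TIE_BREAK_ORDER else 99
    return rank, -np.inf if np.isnan(r) else r


def sweep_weights(
    scores: pd.DataFrame,
    grid_step: float | None = None,
    active: tuple[str, ...] | None = None,
) -> PerformanceMap:
    """Evaluate OP over the weight simplex and record the winner everywhere.

    ``scores`` needs ``method`` and ``r`` columns plus the score columns;
    when ``S_ASR`` is absent the sweep runs over the three monochrome
    weights.  Default grid step: 0.01 for 3 active weights, 0.05 for 4.
    Ties are broken by the fixed method order (interpolation, fourier,
    gaussian, median, physical), then by smaller r.
    """
    if len(scores) == 0:
        raise ValueError("empty score table")
    has_asr = "S_ASR" in scores.columns
    if active is None:
        active = ("res", "smooth", "signal", "asr") if has_asr else (
            "res", "smooth", "signal",
        )
    if grid_step is None:
        grid_step = 0.01 if len(active) == 3 else 0.05
    weights = simplex_grid(active, grid_step)

    order = sorted(
        range(len(scores)),
        key=lambda i: _entry_sort_key(
            scores["method"].iloc[i], float(scores["r"].iloc[i])
        ),
    )
    tbl = scores.iloc[order]
    smat = np.zeros((len(tbl), 4))
    for j, col in enumerate(SCORE_COLUMNS):
        if col in tbl.columns:
            smat[:, j] = tbl[col].to_numpy(dtype=float)
    op = weights @ smat.T  # (G, E)
    best = op.max(axis=1, keepdims=True)
    winner = np.argmax(op >= best - 1e-12, axis=1)  # first max in tie-break order
    return PerformanceMap(
        weights=weights,
        winner_method=tbl["method"].to_numpy()[winner],
        winner_r=tbl["r"].to_numpy(dtype=float)[winner],
        op=op[np.arange(len(weights)), winner],
        grid_step=grid_step,
    )


@dataclass
class BenchmarkConfig:
    """Study conditions for one benchmark run.

    Defaults reproduce the reference conditions: a ~10 px pitch comb on a
    512 px square sensor, 1% dynamic-range noise, bar/flat/bright-region
    targets, and the full monochrome r sweep (the multispectral sweep uses
    the sparser grid over which the spectral comparison is made).
    """

    mode: str = "mono"  # "mono" or "ms"
    image_side: int = 512
    comb: CombSpec = field(default_factory=CombSpec)
    methods: tuple[str, ...] = ("interpolation", "gaussian", "median", "fourier", "physical")
    r_grid: tuple[float, ...] | None = None
    defocus_displacements_um: tuple[float, ...] = (1.0, 2.5, 5.0, 10.0)
    defocus_blur_per_um: float = 1.0
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    dark_level: float = DEFAULT_DARK_LEVEL
    bar_spacings: tuple[float, ...] | None = None
    I_min: float = 20.0
    weight_step: float | None = None
    measure_speed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("mono", "ms"):
            raise ValueError("mode must be 'mono' or 'ms'")
        if self.r_grid is None:
            self.r_grid = (
                (2, 3, 5, 8, 12, 16, 20, 25) if self.mode == "mono" else (1, 5, 10, 25)
            )

    def resolved_comb(self) -> CombSpec:
        if self.comb.image_side != self.image_side:
            return replace(self.comb, image_side=self.image_side)
        return self.comb

    def centre_finder_config(self, pre_blur: float = 0.0) -> CentreFinderConfig:
        d = self.resolved_comb().scaled_diameter
        D = int(round(d))
        if D % 2 == 0:
            D += 1
        return CentreFinderConfig(D=max(D, 3), I_min=self.I_min, pre_blur_sigma=pre_blur)


@dataclass
class BenchmarkResult:
    raw_metrics: pd.DataFrame
    scores: pd.DataFrame
    refs: object
    performance_map: PerformanceMap
    centre_map: CentreMap
    manifest: dict


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _add_noise(image: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    if sigma <= 0:
        return image
    rng = np.random.default_rng(seed)
    return image + rng.normal(0.0, sigma, size=image.shape)


def _timeit(fn, repeats: int) -> tuple[object, float]:
    times, out = [], None
    for _ in range(max(1, repeats)):
        t0 = time.perf_counter()
        out = fn()
        times.append(time.perf_counter() - t0)
    return out, float(np.median(times))


def _mono_entries(config: BenchmarkConfig):
    for method in config.methods:
        if method in ("gaussian", "median", "fourier"):
            for r in config.r_grid:
                yield method, float(r), None
        elif method == "interpolation":
            yield method, float("nan"), None
        elif method == "physical":
            for d in config.defocus_displacements_um:
                yield method, abs(d / 0.5), float(d)
        else:
            raise ValueError(f"unknown method {method!r}")


def run_benchmark(config: BenchmarkConfig) -> BenchmarkResult:
    """Run the full method-by-r comparison on synthetic fixtures.

    Generates the comb and the three test scenes, builds the centre map
    once from a bright-field calibration frame, corrects every fixture
    with every (method, r) variant, computes the metrics, normalises them
    over the whole comparison set and sweeps the weight simplex.
    """
    t_start = time.perf_counter()
    side = config.image_side
    shape = (side, side)
    seeds = _child_seeds(config.seed, 8)
    comb_spec = replace(config.resolved_comb(), seed=seeds[0])
    logger.info("stage comb: generating %s", comb_spec)
    comb = generate_comb(comb_spec)

    margin = side // 8
    flat_region = (margin, margin, side - margin, side - margin)
    bar_kw = {} if config.bar_spacings is None else {"spacings": list(config.bar_spacings)}
    bar = make_target("bar_target", bar_kw, blur_sigma=1.0, shape=shape)
    uni = make_target("uniform", {"value": 150.0}, blur_sigma=1.0, shape=shape)
    bright = make_target("bright_region", None, blur_sigma=1.0, shape=shape)
    x0, y0, x1, y1 = bright.geometry["region"]
    inset = max(4, side // 16)
    roi = (x0 + inset, y0 + inset, x1 - inset, y1 - inset)
    elements = bar.elements

    if config.mode == "mono":
        result = _run_mono(config, comb, bar, uni, bright, flat_region, roi, seeds)
    else:
        result = _run_ms(config, comb, bar, uni, bright, flat_region, roi, seeds)
    raw, centre_map = result

    logger.info("stage normalise: %d entries", len(raw))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores, refs = normalise_scores(raw)
    scores = pd.concat([raw[["method", "r"]], scores], axis=1)
    pmap = sweep_weights(scores, grid_step=config.weight_step)
    manifest = {
        "mode": config.mode,
        "image_side": side,
        "n_fibrelets": comb.n_fibrelets,
        "fill_factor": comb.fill_factor(),
        "n_centres": len(centre_map),
        "seed": config.seed,
        "noise_sigma": config.noise_sigma,
        "r_grid": list(config.r_grid),
        "elements": [
            {"rows": el.rows, "spacing": el.spacing} for el in elements
        ],
        "flat_region": flat_region,
        "roi": roi,
        "runtime_s": time.perf_counter() - t_start,
    }
    return BenchmarkResult(
        raw_metrics=raw,
        scores=scores,
        refs=refs,
        performance_map=pmap,
        centre_map=centre_map,
        manifest=manifest,
    )


def _run_mono(config, comb, bar, uni, bright, flat_region, roi, seeds):
    shape = comb.shape
    cal = apply_comb(
        make_target("uniform", {"value": 255.0}, blur_sigma=0.0, shape=shape),
        comb, noise_sigma=config.noise_sigma, seed=seeds[1],
    )
    cfg = config.centre_finder_config()
    logger.info("stage centres: D=%d I_min=%g", cfg.D, cfg.I_min)
    centre_map = find_centres(cal, cfg)
    if len(centre_map) < 3:
        raise RuntimeError("centre finding failed on the calibration frame")
    lut = ScatteredInterpolator(centre_map.centres, shape)

    captures = {
        "bar": apply_comb(bar, comb, config.noise_sigma, seeds[2]),
        "uniform": apply_comb(uni, comb, config.noise_sigma, seeds[3]),
        "bright": apply_comb(bright, comb, config.noise_sigma, seeds[4]),
    }
    clean = {
        "bar": apply_comb(bar, comb, 0.0),
        "uniform": apply_comb(uni, comb, 0.0),
        "bright": apply_comb(bright, comb, 0.0),
    }

    rows = []
    for method, r, displacement in _mono_entries(config):
        logger.info("stage correct: %s r=%.3g", method, r)
        if method == "physical":
            frames = {
                key: _add_noise(
                    simulate_defocus(clean[key], displacement, config.defocus_blur_per_um)[0],
                    config.noise_sigma, seeds[5],
                )
                for key in captures
            }
            corrected = frames
            t = 0.0
            if config.measure_speed:
                _, t = _timeit(lambda: frames["bar"].copy(), 5)
        else:
            if method == "interpolation":
                fn = lambda img: interpolation_decomb(img, centre_map, interpolator=lut)
            else:
                cc = CorrectionConfig(method=method, r=r)
                fn = lambda img: correct(img, cc)
            if config.measure_speed:
                out, t = _timeit(lambda: fn(captures["bar"]), 5)
            else:
                out, t = fn(captures["bar"]), 0.0
            corrected = {
                "bar": out,
                "uniform": fn(captures["uniform"]),
                "bright": fn(captures["bright"]),
            }
        rows.append(
            {
                "method": method,
                "r": r,
                "R": resolution_from_image(corrected["bar"], bar.elements),
                "sigma": smoothness(corrected["uniform"], flat_region),
                "S": signal(corrected["bright"], roi),
                "t": t,
            }
        )
    return pd.DataFrame(rows), centre_map


def _run_ms(config, comb, bar, uni, bright, flat_region, roi, seeds):
    shape = comb.shape
    pattern = CFAPattern.standard(3)
    led = default_calibration("led")
    flat = default_calibration("flat")
    fluor = default_calibration("fluorophore")
    spectra = {
        "bar": SceneSpectrum(flat.predicted_spectrum()),
        "uniform": SceneSpectrum(led.predicted_spectrum()),
        "bright": SceneSpectrum(fluor.predicted_spectrum()),
    }
    e_led = led.predicted_spectrum()

    cal_raw, _ = simulate_ms_capture(
        make_target("uniform", {"value": 255.0}, blur_sigma=0.0, shape=shape),
        comb, spectra["bar"], pattern,
        noise_sigma=config.noise_sigma, seed=seeds[1], dark_level=config.dark_level,
    )
    cfg = config.centre_finder_config(pre_blur=pattern.L / 2.0)
    logger.info("stage centres (mosaic): D=%d I_min=%g", cfg.D, cfg.I_min)
    centre_map = find_centres(cal_raw, cfg)
    if len(centre_map) < 3:
        raise RuntimeError("centre finding failed on the mosaic calibration frame")
    lut = ScatteredInterpolator(centre_map.centres, shape)

    targets = {"bar": bar, "uniform": uni, "bright": bright}
    raws = {
        key: simulate_ms_capture(
            targets[key], comb, spectra[key], pattern,
            noise_sigma=config.noise_sigma, seed=seeds[2 + i],
            dark_level=config.dark_level,
        )[0]
        for i, key in enumerate(targets)
    }

    def interp_cube(raw):
        cs = centre_based_demosaick(raw, pattern, centre_map)
        return interpolate_centre_spectra(cs, shape, interpolator=lut)

    rows = []
    for method, r, displacement in _mono_entries(config):
        logger.info("stage correct (ms): %s r=%.3g", method, r)
        if method == "physical":
            cubes = {}
            for i, (key, target) in enumerate(targets.items()):
                raw_d, _ = simulate_ms_capture(
                    target, comb, spectra[key], pattern,
                    noise_sigma=config.noise_sigma, seed=seeds[2 + i],
                    dark_level=config.dark_level,
                    defocus_um=displacement,
                    blur_per_um=config.defocus_blur_per_um,
                )
                cubes[key] = simple_demosaick(raw_d, pattern)
            t = 0.0
            if config.measure_speed:
                _, t = _timeit(lambda: simple_demosaick(raws["bar"], pattern), 5)
        else:
            if method == "interpolation":
                fn = interp_cube
            else:
                fn = lambda raw: demosaick_then_filter(raw, pattern, method, r)
            if config.measure_speed:
                out, t = _timeit(lambda: fn(raws["bar"]), 5)
            else:
                out, t = fn(raws["bar"]), 0.0
            cubes = {"bar": out, "uniform": fn(raws["uniform"]), "bright": fn(raws["bright"])}
        rows.append(
            {
                "method": method,
                "r": r,
                "R": resolution_from_image(cubes["bar"], bar.elements),
                "sigma": smoothness(cubes["uniform"], flat_region),
                "S": signal(cubes["bright"], roi),
                "Q": asr(cubes["uniform"], e_led),
                "t": t,
            }
        )
    return pd.DataFrame(rows), centre_map
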