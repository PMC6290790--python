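"""Synthetic fibre-bundle scenes with known ground truth.

A fibre bundle relays an image through ~10**3 - 10**4 individual fibrelets
separated by opaque cladding, imprinting an irregular dark lattice (the
"comb" artifact) on every frame.  This module builds that world from
scratch: a comb transmission mask decomposed into per-fibrelet masks, ideal
test targets (bar charts, flat fields, bright regions), the fibre-sampled
monochrome capture, the mosaic capture of a spectrally resolved detector
array (SRDA), and a defocus blur emulating "physical" comb correction.

Everything is deterministic given a seed, and every generator records the
ground truth (true centres, scene spectrum, element geometry) that the
metrics need later.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "CombSpec",
    "FibreletMask",
    "CombMask",
    "BarElement",
    "TestTarget",
    "SceneSpectrum",
    "generate_comb",
    "make_target",
    "apply_comb",
    "apply_cfa",
    "simulate_defocus",
    "simulate_ms_capture",
]

#: default additive-noise level: 1% of an 8-bit dynamic range
DEFAULT_NOISE_SIGMA = 2.55

#: default sensor dark level (counts) added in the CFA sampling step; makes
#: cladding pixels carry a small spectrally flat signal, as real sensors do
DEFAULT_DARK_LEVEL = 2.0

#: fibrelet-mask binarisation threshold used when sampling a scene
BINARISE_THRESHOLD = 0.1


@dataclass(frozen=True)
class CombSpec:
    """Geometry of a synthetic comb.

    Fibrelets sit on a jittered hexagonal lattice.  ``magnification`` scales
    both fibrelet diameter and lattice pitch (i.e. cores and cladding scale
    together) while the sensor size stays fixed.
    """

    image_side: int = 512
    n_fibrelets: int | None = None  # None: fill the image
    mean_diameter: float = 8.0
    diameter_jitter: float = 0.08
    position_jitter: float = 0.12
    cladding_gap: float = 2.0
    mask_blur_sigma: float = 1.0
    magnification: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_side < 4:
            raise ValueError("image_side must be at least 4 pixels")
        if self.n_fibrelets is not None and self.n_fibrelets < 1:
            raise ValueError("n_fibrelets must be >= 1")
        if self.mean_diameter <= 0:
            raise ValueError("mean_diameter must be positive")
        for name in ("diameter_jitter", "position_jitter"):
            v = getattr(self, name)
            if not 0 <= v < 0.5:
                raise ValueError(f"{name} must be in [0, 0.5)")
        if self.cladding_gap < 0:
            raise ValueError("cladding_gap must be >= 0")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")
        if self.pitch <= 0:
            raise ValueError("infeasible geometry: lattice pitch <= 0")

    @property
    def scaled_diameter(self) -> float:
        return self.mean_diameter * self.magnification

    @property
    def pitch(self) -> float:
        """Centre-to-centre distance of adjacent fibrelets."""
        return (self.mean_diameter + self.cladding_gap) * self.magnification


@dataclass
class FibreletMask:
    """One fibrelet's graded transmission patch, stored on its bounding box."""

    slices: tuple[slice, slice]
    patch: np.ndarray  # float in [0, 1]

    def dense(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=self.patch.dtype)
        out[self.slices] = self.patch
        return out

    def support(self, threshold: float = BINARISE_THRESHOLD) -> np.ndarray:
        """Binarised support (strict ``> threshold``) on the bounding box."""
        return self.patch > threshold


@dataclass
class CombMask:
    """Comb transmission map plus its per-fibrelet decomposition."""

    transmission: np.ndarray  # C(x, y), in [0, 1]
    fibrelets: list[FibreletMask]
    true_centres: np.ndarray  # (n, 2) subpixel (x, y)
    spec: CombSpec | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.transmission.shape

    @property
    def n_fibrelets(self) -> int:
        return len(self.fibrelets)

    def fibrelet_dense(self, i: int) -> np.ndarray:
        return self.fibrelets[i].dense(self.shape)

    def fill_factor(self) -> float:
        return float(self.transmission.mean())


def _hex_lattice(side: int, pitch: float, margin: float) -> np.ndarray:
    """Hexagonal lattice sites (x, y) inside ``[margin, side - margin]``."""
    row_step = pitch * np.sqrt(3.0) / 2.0
    sites = []
    y = margin
    row = 0
    while y <= side - margin:
        x0 = margin + (pitch / 2.0 if row % 2 else 0.0)
        x = x0
        while x <= side - margin:
            sites.append((x, y))
            x += pitch
        y += row_step
        row += 1
    return np.asarray(sites, dtype=float).reshape(-1, 2)


def generate_comb(spec: CombSpec) -> CombMask:
    """Build a comb mask on a jittered hexagonal lattice.

    Each fibrelet is a disc of jittered radius, Gaussian-blurred to emulate
    soft fibrelet edges, and clipped to its Voronoi cell so that fibrelet
    supports stay disjoint even under position jitter (this is also what
    gives the fibrelets their irregular outlines).
    """
    rng = np.random.default_rng(spec.seed)
    side = spec.image_side
    pitch = spec.pitch
    d_eff = spec.scaled_diameter
    margin = d_eff / 2.0 + 1.0

    sites = _hex_lattice(side, pitch, margin)
    if sites.size == 0:
        raise ValueError("infeasible geometry: no lattice site fits the image")
    if spec.n_fibrelets is not None:
        if spec.n_fibrelets > len(sites):
            raise ValueError(
                f"infeasible geometry: {spec.n_fibrelets} fibrelets requested "
                f"but only {len(sites)} lattice sites fit"
            )
        # deterministic choice: sites closest to the image centre
        c = np.array([side / 2.0, side / 2.0])
        order = np.argsort(((sites - c) ** 2).sum(axis=1), kind="stable")
        sites = sites[order[: spec.n_fibrelets]]

    n = len(sites)
    offsets_r = spec.position_jitter * pitch * np.sqrt(rng.uniform(0.0, 1.0, n))
    offsets_t = rng.uniform(0.0, 2.0 * np.pi, n)
    centres = sites + np.column_stack(
        [offsets_r * np.cos(offsets_t), offsets_r * np.sin(offsets_t)]
    )
    centres[:, 0] = np.clip(centres[:, 0], margin, side - margin)
    centres[:, 1] = np.clip(centres[:, 1], margin, side - margin)
    radii = d_eff / 2.0 * (1.0 + spec.diameter_jitter * rng.uniform(-1.0, 1.0, n))

    # Voronoi assignment of every pixel to its nearest centre
    yy, xx = np.mgrid[0:side, 0:side]
    tree = cKDTree(centres)
    dist, label = tree.query(np.column_stack([xx.ravel(), yy.ravel()]), k=1)
    dist = dist.reshape(side, side)
    label = label.reshape(side, side)

    pad = int(np.ceil(3.0 * spec.mask_blur_sigma)) + 1
    transmission = np.zeros((side, side), dtype=np.float64)
    fibrelets: list[FibreletMask] = []
    for i in range(n):
        cx, cy = centres[i]
        r = radii[i]
        half = int(np.ceil(r)) + pad
        y0, y1 = max(0, int(np.floor(cy)) - half), min(side, int(np.ceil(cy)) + half + 1)
        x0, x1 = max(0, int(np.floor(cx)) - half), min(side, int(np.ceil(cx)) + half + 1)
        ly, lx = np.mgrid[y0:y1, x0:x1]
        disc = ((lx - cx) ** 2 + (ly - cy) ** 2 <= r**2).astype(np.float64)
        if spec.mask_blur_sigma > 0:
            disc = ndimage.gaussian_filter(disc, spec.mask_blur_sigma, mode="constant")
        disc *= label[y0:y1, x0:x1] == i
        sl = (slice(y0, y1), slice(x0, x1))
        fibrelets.append(FibreletMask(slices=sl, patch=disc))
        transmission[sl] += disc

    np.clip(transmission, 0.0, 1.0, out=transmission)
    # keep patches consistent with the clipped sum (clipping is a no-op in
    # practice because Voronoi cells are disjoint)
    return CombMask(
        transmission=transmission,
        fibrelets=fibrelets,
        true_centres=centres,
        spec=spec,
    )


@dataclass(frozen=True)
class BarElement:
    """One bar-chart element: vertical bars of a single spacing (period)."""

    rows: tuple[int, int]  # [row0, row1) band of the image
    spacing: float  # full period in pixels (bar + space)
    phase: float = 0.0  # x of a bar's leading edge

    def bar_profile(self, width: int) -> np.ndarray:
        """Ideal binary profile across ``width`` columns (1 = bar)."""
        x = np.arange(width, dtype=float)
        return (((x - self.phase) % self.spacing) < self.spacing / 2.0).astype(float)


@dataclass
class TestTarget:
    """Ideal scene with generation metadata.

    kind is one of ``bar_target``, ``uniform``, ``bright_region``.
    """

    image: np.ndarray
    kind: str
    geometry: dict = field(default_factory=dict)
    blur_sigma: float = 0.0
    noise_sigma: float = 0.0

    @property
    def elements(self) -> list[BarElement]:
        return self.geometry.get("elements", [])


def make_target(
    kind: str,
    geometry: dict | None = None,
    blur_sigma: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
) -> TestTarget:
    """Build an ideal test image, blur it, and add Gaussian noise.

    Geometry keys by kind:

    - ``uniform``: ``value`` (default 150)
    - ``bar_target``: ``spacings`` (full periods, px; >= 3 distinct values
      required), ``phases`` elements per spacing with staggered bar phase
      (default 3; phase staggering lets the contrast metric cancel the
      aliasing beat between the bars and the fibre lattice, as averaging
      over a chart's repeated elements does), ``low``/``high`` levels
      (default 0/200)
    - ``bright_region``: ``background`` (default 117), ``value`` (default
      156), ``region`` as (x0, y0, x1, y1) (default centred square of half
      the image side)
    """
    geometry = dict(geometry or {})
    h, w = shape
    if kind == "uniform":
        value = float(geometry.setdefault("value", 150.0))
        img = np.full(shape, value, dtype=np.float64)
    elif kind == "bar_target":
        spacings = geometry.get("spacings")
        if spacings is None:
            # geometric series spanning ~0.8-6.4x the fibre Nyquist spacing
            # of the reference comb (2 x 10 px pitch)
            spacings = [16, 22, 32, 45, 64, 90, 128]
            geometry["spacings"] = spacings
        if len(set(spacings)) < 3:
            raise ValueError("bar_target needs >= 3 distinct line spacings")
        phases = int(geometry.setdefault("phases", 3))
        low = float(geometry.setdefault("low", 0.0))
        high = float(geometry.setdefault("high", 200.0))
        n_el = len(spacings) * phases
        bounds = np.linspace(0, h, n_el + 1).astype(int)
        img = np.full(shape, low, dtype=np.float64)
        elements = []
        i = 0
        for spacing in spacings:
            for p in range(phases):
                r0, r1 = bounds[i], bounds[i + 1]
                el = BarElement(
                    rows=(int(r0), int(r1)),
                    spacing=float(spacing),
                    phase=spacing * p / phases,
                )
                img[r0:r1, :] = low + (high - low) * el.bar_profile(w)[None, :]
                elements.append(el)
                i += 1
        geometry["elements"] = elements
    elif kind == "bright_region":
        background = float(geometry.setdefault("background", 117.0))
        value = float(geometry.setdefault("value", 156.0))
        region = geometry.get("region")
        if region is None:
            region = (w // 4, h // 4, 3 * w // 4, 3 * h // 4)
            geometry["region"] = region
        x0, y0, x1, y1 = region
        img = np.full(shape, background, dtype=np.float64)
        img[y0:y1, x0:x1] = value
    else:
        raise ValueError(f"unknown target kind: {kind!r}")

    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, blur_sigma, mode="reflect")
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return TestTarget(
        image=img, kind=kind, geometry=geometry,
        blur_sigma=blur_sigma, noise_sigma=noise_sigma,
    )


def apply_comb(
    target: TestTarget | np.ndarray,
    comb: CombMask,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Sample a scene through the fibre bundle.

    For every fibrelet the scene mean over the binarised support
    (``C_i > 0.1``, strict) is taken and painted back through the graded
    mask; the per-fibrelet contributions are summed and Gaussian noise is
    added.  Fibrelets whose binarised support is empty are skipped with a
    warning (degenerate fibrelet).
    """
    scene = target.image if isinstance(target, TestTarget) else np.asarray(target, float)
    if scene.shape != comb.shape:
        raise ValueError(
            f"target shape {scene.shape} does not match comb shape {comb.shape}"
        )
    out = np.zeros_like(scene, dtype=np.float64)
    degenerate = 0
    for fm in comb.fibrelets:
        support = fm.support()
        n_px = int(support.sum())
        if n_px == 0:
            degenerate += 1
            continue
        m_i = float(scene[fm.slices][support].sum() / n_px)
        out[fm.slices] += fm.patch * m_i
    if degenerate:
        warnings.warn(
            f"{degenerate} fibrelet(s) had an empty binarised support and were skipped",
            stacklevel=2,
        )
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sigma, size=out.shape)
    return out


def fibrelet_means(
    target: TestTarget | np.ndarray, comb: CombMask
) -> np.ndarray:
    """Per-fibrelet scene means ``M_i`` over the binarised supports."""
    scene = target.image if isinstance(target, TestTarget) else np.asarray(target, float)
    means = np.full(comb.n_fibrelets, np.nan)
    for i, fm in enumerate(comb.fibrelets):
        support = fm.support()
        if support.any():
            means[i] = scene[fm.slices][support].mean()
    return means


@dataclass
class SceneSpectrum:
    """Ideal per-band scene intensities for an L*L-band mosaic sensor."""

    band_intensities: np.ndarray

    def __post_init__(self) -> None:
        self.band_intensities = np.asarray(self.band_intensities, dtype=float)
        if np.any(self.band_intensities < 0):
            raise ValueError("band intensities must be >= 0")

    @property
    def n_bands(self) -> int:
        return len(self.band_intensities)

    def normalised(self) -> np.ndarray:
        s = self.band_intensities.sum()
        if s <= 0:
            raise ValueError("zero-sum spectrum cannot be normalised")
        return self.band_intensities / s

    @classmethod
    def from_tables(cls, source: np.ndarray, responses: np.ndarray) -> "SceneSpectrum":
        """Predict recorded band intensities from a source spectrum G(lambda)
        and per-band responses R_k(lambda) sampled on a shared wavelength
        grid: intensity_k = sum_lambda G * R_k."""
        source = np.asarray(source, dtype=float)
        responses = np.asarray(responses, dtype=float)
        if responses.shape[1] != source.shape[0]:
            raise ValueError("responses and source must share the wavelength grid")
        return cls(band_intensities=responses @ source)


def apply_cfa(
    band_images,
    pattern,
    noise_sigma: float = 0.0,
    seed: int = 0,
    dark_level: float = DEFAULT_DARK_LEVEL,
) -> np.ndarray:
    """Sample a per-band image stack through the colour-filter array.

    ``raw(x, y) = band_images[P(x, y)](x, y) + dark_level + noise``.  The
    dark level models the sensor's spectrally flat dark/stray-light floor.
    ``band_images`` may be a ``(K, H, W)`` array, a list of images, or a
    :class:`~decomb.mosaic.SpectralCube`.
    """
    data = getattr(band_images, "data", band_images)
    stack = np.asarray(data, dtype=float)
    if stack.ndim != 3:
        raise ValueError("band_images must stack to (n_bands, H, W)")
    shape = stack.shape[1:]
    p = pattern.band_index_map(shape)
    if int(p.max()) >= stack.shape[0]:
        raise ValueError("pattern refers to bands missing from the stack")
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    raw = stack[p, yy, xx] + dark_level
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        raw = raw + rng.normal(0.0, noise_sigma, size=raw.shape)
    return raw


def simulate_ms_capture(
    target: TestTarget | np.ndarray,
    comb: CombMask,
    spectrum: SceneSpectrum,
    pattern,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
    dark_level: float = DEFAULT_DARK_LEVEL,
    defocus_um: float = 0.0,
    blur_per_um: float = 1.0,
):
    """End-to-end SRDA capture: comb sampling, optional defocus, CFA mosaic.

    The scene is ``target`` scaled per band by the (max-normalised) scene
    spectrum; the comb acts identically on every band up to that scale, so
    the fibre-sampled image is computed once and scaled.  Returns
    ``(raw, band_truth)`` where ``band_truth`` is the noiseless pre-CFA band
    stack (the demosaicking ground truth).
    """
    comb_img = apply_comb(target, comb, noise_sigma=0.0)
    if defocus_um:
        comb_img, _ = simulate_defocus(comb_img, defocus_um, blur_per_um=blur_per_um)
    scale = spectrum.band_intensities / spectrum.band_intensities.max()
    band_truth = comb_img[None, :, :] * scale[:, None, None]
    raw = apply_cfa(
        band_truth, pattern, noise_sigma=noise_sigma, seed=seed, dark_level=dark_level
    )
    return raw, band_truth


def simulate_defocus(
    comb_image: np.ndarray,
    displacement_um: float,
    blur_per_um: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Defocus the image of the fibre face ("physical" comb correction).

    The point-spread function is modelled as a Gaussian whose sigma grows
    linearly with the axial displacement (``blur_per_um`` px/um).  Returns
    the blurred image and the dimensionless characteristic filter size
    ``r = |displacement / 0.5 um|``; displacement 0 is the identity.
    """
    r = abs(displacement_um / 0.5)
    if displacement_um == 0:
        return np.asarray(comb_image, dtype=float).copy(), 0.0
    sigma = blur_per_um * abs(displacement_um)
    return ndimage.gaussian_filter(np.asarray(comb_image, float), sigma, mode="reflect"), r
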