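"""Spectral calibration for the nine-band mosaic sensor.

The reference sensor carries a 3x3 super-pixel of 8 narrow bands (centre
wavelengths 553-829 nm, ~30 nm FWHM) plus one broad band (500-850 nm).
This module holds wavelength-resolved source spectra G(lambda) and band
responses R_k(lambda), and folds them into the predicted recorded spectrum

    E_k = sum_lambda G(lambda) R_k(lambda),   k = 1..9,

the ground truth that the accuracy-of-spectral-reconstruction metric
compares against.  Synthetic calibration tables (Gaussian band responses, a
narrow-band LED source, a flat broadband source) are provided so the whole
pipeline runs without measured hardware curves; measured curves can be
loaded from CSV wavelength-value tables instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectralCalibration",
    "default_calibration",
    "NARROW_BAND_CENTRES",
    "SIGNAL_BAND_SUBSET",
]

#: centre wavelengths (nm) of the 8 narrow bands of the reference SRDA
NARROW_BAND_CENTRES = (553.0, 587.0, 629.0, 665.0, 714.0, 749.0, 791.0, 829.0)

#: broadband band passband (nm)
BROADBAND_RANGE = (500.0, 850.0)

#: 0-based indices of the bands overlapping a far-red fluorophore emission
#: (665 nm, 714 nm narrow bands plus the broadband): the signal-metric bands
SIGNAL_BAND_SUBSET = (3, 4, 8)


def _gaussian(wl: np.ndarray, centre: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((wl - centre) / sigma) ** 2)


@dataclass
class SpectralCalibration:
    """Source spectrum and per-band responses on a shared wavelength grid."""

    wavelengths: np.ndarray
    source: np.ndarray  # G(lambda)
    responses: np.ndarray  # (n_bands, n_wavelengths)
    band_centres: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.source = np.asarray(self.source, dtype=float)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if self.source.shape != self.wavelengths.shape:
            raise ValueError("source must be sampled on the wavelength grid")
        if self.responses.shape[1] != self.wavelengths.size:
            raise ValueError("responses must be sampled on the wavelength grid")

    @property
    def n_bands(self) -> int:
        return self.responses.shape[0]

    def predicted_spectrum(self) -> np.ndarray:
        """E_k = sum_lambda G(lambda) R_k(lambda)."""
        return self.responses @ self.source

    def predicted_spectrum_normalised(self) -> np.ndarray:
        e = self.predicted_spectrum()
        total = e.sum()
        if total <= 0:
            raise ValueError("predicted spectrum sums to zero")
        return e / total

    def with_source(self, source: np.ndarray) -> "SpectralCalibration":
        return SpectralCalibration(
            wavelengths=self.wavelengths,
            source=np.asarray(source, dtype=float),
            responses=self.responses,
            band_centres=self.band_centres,
        )

    @classmethod
    def from_csv(cls, source_path, response_paths) -> "SpectralCalibration":
        """Load wavelength-value tables (CSV, two columns, no header
        required) and resample the responses onto the source grid."""
        src = np.loadtxt(source_path, delimiter=",")
        wl = src[:, 0]
        responses = []
        for path in response_paths:
            tab = np.loadtxt(path, delimiter=",")
            responses.append(np.interp(wl, tab[:, 0], tab[:, 1], left=0.0, right=0.0))
        return cls(wavelengths=wl, source=src[:, 1], responses=np.array(responses))


def synthetic_band_responses(wavelengths: np.ndarray) -> np.ndarray:
    """Gaussian narrow-band responses plus a smooth-edged broadband."""
    wl = np.asarray(wavelengths, dtype=float)
    rows = [0.6 * _gaussian(wl, c, 30.0) for c in NARROW_BAND_CENTRES]
    lo, hi = BROADBAND_RANGE
    edge = 10.0
    broad = 0.8 / (1.0 + np.exp(-(wl - lo) / edge)) / (1.0 + np.exp((wl - hi) / edge))
    rows.append(broad)
    return np.vstack(rows)


def led_source(wavelengths: np.ndarray, centre: float = 630.0, fwhm: float = 20.0) -> np.ndarray:
    """Narrow-band LED emission profile."""
    return _gaussian(np.asarray(wavelengths, float), centre, fwhm)


def flat_source(wavelengths: np.ndarray) -> np.ndarray:
    """Spectrally flat (white) source, used for calibration frames."""
    return np.ones_like(np.asarray(wavelengths, float))


def fluorophore_source(wavelengths: np.ndarray) -> np.ndarray:
    """Far-red fluorophore emission profile (AF647-like, peak ~670 nm)."""
    return _gaussian(np.asarray(wavelengths, float), 670.0, 45.0)


def default_calibration(source: str = "led") -> SpectralCalibration:
    """Synthetic nine-band calibration with a chosen source.

    ``source`` is one of ``led`` (narrow-band 630 nm), ``flat`` (white) or
    ``fluorophore`` (far-red emission).
    """
    wl = np.arange(450.0, 901.0, 1.0)
    sources = {"led": led_source, "flat": flat_source, "fluorophore": fluorophore_source}
    try:
        g = sources[source](wl)
    except KeyError:
        raise ValueError(f"unknown source {source!r}") from None
    return SpectralCalibration(
        wavelengths=wl,
        source=g,
        responses=synthetic_band_responses(wl),
        band_centres=NARROW_BAND_CENTRES + (sum(BROADBAND_RANGE) / 2.0,),
    )
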