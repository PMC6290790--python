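"""Reading and writing the toolkit's on-disk formats.

Images travel as single-channel TIFF (16-bit by default), spectral cubes
as multi-page TIFF with one page per band, ground truth and run manifests
as JSON sidecars, centre spectra and score tables as CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .centres import CentreMap
from .mosaic import CFAPattern, CentreSpectra, SpectralCube

__all__ = [
    "write_image",
    "read_image",
    "write_cube",
    "read_cube",
    "write_sidecar",
    "read_sidecar",
    "write_centre_spectra",
    "write_pattern",
    "read_pattern",
    "write_benchmark",
]


def _to_uint16(image: np.ndarray, scale: float | None) -> tuple[np.ndarray, float]:
    image = np.asarray(image, dtype=float)
    if scale is None:
        peak = float(np.max(np.abs(image))) or 1.0
        scale = 65535.0 / peak
    return np.clip(image * scale, 0, 65535).astype(np.uint16), scale


def write_image(path, image: np.ndarray, scale: float | None = 1.0) -> None:
    """Write a 2-D image as 16-bit single-channel TIFF.

    ``scale=1.0`` stores rounded raw counts; ``scale=None`` stretches to
    the full 16-bit range.
    """
    data, _ = _to_uint16(image, scale)
    tifffile.imwrite(str(path), data)


def read_image(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def write_cube(path, cube: SpectralCube, scale: float | None = 1.0) -> None:
    """Write a spectral cube as multi-page TIFF (one page per band) with
    band metadata in the TIFF description."""
    data, _ = _to_uint16(cube.data, scale)
    tifffile.imwrite(
        str(path), data, metadata={"band_meta": list(cube.band_meta)}
    )


def read_cube(path) -> SpectralCube:
    return SpectralCube(data=tifffile.imread(str(path)).astype(float))


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def write_sidecar(path, payload: dict) -> None:
    """JSON sidecar with ground truth / run metadata."""
    Path(path).write_text(json.dumps(payload, cls=_Encoder, indent=2))


def read_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())


def write_centre_spectra(path, spectra: CentreSpectra) -> None:
    """CSV with columns x, y, band1..bandK (1-based band naming)."""
    cols = {"x": spectra.centre_map.centres[:, 0], "y": spectra.centre_map.centres[:, 1]}
    for k in range(spectra.n_bands):
        cols[f"band{k + 1}"] = spectra.values[:, k]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_pattern(path, pattern: CFAPattern) -> None:
    """CFA pattern as JSON; band indices serialised 1-based."""
    write_sidecar(
        path,
        {
            "L": pattern.L,
            "tile": (pattern.tile + 1).tolist(),
            "offset": list(pattern.offset),
            "band_meta": list(pattern.band_meta),
        },
    )


def read_pattern(path) -> CFAPattern:
    doc = read_sidecar(path)
    return CFAPattern(
        tile=np.asarray(doc["tile"], dtype=int) - 1,
        band_meta=doc.get("band_meta", []),
        offset=tuple(doc.get("offset", (0, 0))),
    )


def write_centre_map(path, centre_map: CentreMap) -> None:
    pd.DataFrame(
        {
            "x": centre_map.centres[:, 0],
            "y": centre_map.centres[:, 1],
            "score": centre_map.scores,
        }
    ).to_csv(path, index=False)


def read_centre_map(path, D: int) -> CentreMap:
    df = pd.read_csv(path)
    return CentreMap(
        centres=df[["x", "y"]].to_numpy(), scores=df["score"].to_numpy(), D=D
    )


def _ternary_coords(weights: np.ndarray) -> np.ndarray:
    """Map 3 active weights (rows summing to 1) to 2-D ternary-plot x, y."""
    a, b, c = weights[:, 0], weights[:, 1], weights[:, 2]
    x = 0.5 * (2 * b + c) / (a + b + c)
    y = (np.sqrt(3) / 2) * c / (a + b + c)
    return np.column_stack([x, y])


def write_winner_map_figure(path, performance_map, title: str = "") -> None:
    """Ternary scatter of the winning method over the weight simplex.

    For 4 active weights the w_ASR = 0 face is drawn.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    weights = performance_map.weights
    methods = performance_map.winner_method
    active_cols = [i for i in range(4) if np.any(weights[:, i] > 0)]
    if len(active_cols) == 4:
        face = weights[:, 3] == 0
        weights, methods = weights[face], methods[face]
        active_cols = [0, 1, 2]
    tri = _ternary_coords(weights[:, active_cols])
    palette = {
        "gaussian": "#56B4E9",
        "median": "#009E73",
        "fourier": "#E69F00",
        "physical": "#D55E00",
        "interpolation": "#0072B2",
    }
    fig, ax = plt.subplots(figsize=(5, 4.5))
    for name, colour in palette.items():
        sel = methods == name
        if sel.any():
            ax.scatter(tri[sel, 0], tri[sel, 1], s=6, c=colour, label=name)
    labels = ["w_res", "w_smooth", "w_signal", "w_ASR"]
    corner_names = [labels[i] for i in active_cols]
    for (cx, cy), name in zip([(0, 0), (1, 0), (0.5, np.sqrt(3) / 2)], corner_names):
        ax.annotate(name, (cx, cy), ha="center", va="bottom" if cy else "top")
    ax.set_title(title)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_benchmark(outdir, result) -> None:
    """Persist a benchmark run: CSV tables, JSON manifest, winner-map PNG."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.raw_metrics.to_csv(outdir / "raw_metrics.csv", index=False)
    result.scores.to_csv(outdir / "scores.csv", index=False)
    result.performance_map.to_dataframe().to_csv(outdir / "winner_map.csv", index=False)
    manifest = dict(result.manifest)
    manifest["normalisation_refs"] = dataclasses.asdict(result.refs)
    manifest["note"] = (
        "scores are min-max normalised within this run's comparison set; "
        "they are not comparable across runs"
    )
    write_sidecar(outdir / "manifest.json", manifest)
    write_centre_map(outdir / "centre_map.csv", result.centre_map)
    write_winner_map_figure(outdir / "winner_map.png", result.performance_map)
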