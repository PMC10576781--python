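"""Proteoform ion images from multi-line scans.

Ions within ±10 ppm of a feature's major isotope masses are located on the
tissue (row = line index, column = along-track pixel) and accumulated into a
2-D count heatmap.  Counts are kept raw by default so images stay auditable;
hot-spot clipping is available but off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .geometry import ScanGeometry
from .spectrum import ProteoformFeature


@dataclass
class ProteoformImage:
    """2-D ion-count image of one proteoform."""

    feature_id: str
    grid: np.ndarray  # rows = lines, cols = along-track pixels
    pixel_along: float  # µm
    pixel_across: float  # µm (= strip step)

    @property
    def total_ions(self) -> int:
        return int(self.grid.sum())


def build_image(
    ions: pd.DataFrame,
    feature: ProteoformFeature,
    geometry: ScanGeometry,
    pixel_along: float = 20.0,
    ppm_tol: float = 10.0,
) -> ProteoformImage:
    """Accumulate a feature's matched ions into a count image.

    A pixel spans ``pixel_along`` µm along the track and one strip step
    across; ions outside every isotope window are ignored.
    """
    if pixel_along <= 0:
        raise InvalidInputError("pixel_along must be positive")
    n_cols = max(1, int(np.ceil(geometry.line_length / pixel_along)))
    grid = np.zeros((geometry.n_lines, n_cols), dtype=int)

    mass = ions["neutral_mass"].to_numpy(dtype=float) if "neutral_mass" in ions else np.full(len(ions), np.nan)
    matched = np.zeros(len(ions), dtype=bool)
    ok = np.isfinite(mass)
    for w in feature.isotope_masses:
        tol = ppm_tol * 1e-6 * w
        matched |= ok & (np.abs(mass - w) <= tol)

    rows = ions["line_index"].to_numpy()[matched]
    coord = geometry.scan_coordinate(ions["scan_index"].to_numpy()[matched])
    cols = np.clip((coord / pixel_along).astype(int), 0, n_cols - 1)
    np.add.at(grid, (rows, cols), 1)
    return ProteoformImage(
        feature_id=feature.feature_id,
        grid=grid,
        pixel_along=pixel_along,
        pixel_across=geometry.strip_step,
    )


def merge_images(a: ProteoformImage, b: ProteoformImage) -> np.ndarray:
    """Channelwise max-normalized two-channel overlay of two images.

    Returns an array of shape ``(rows, cols, 2)``; each channel is divided
    by its own maximum (an all-zero channel stays zero) with no
    cross-channel mixing of counts.
    """
    if a.grid.shape != b.grid.shape or not np.isclose(a.pixel_along, b.pixel_along):
        raise InvalidInputError("images must share geometry to be merged")
    out = np.zeros(a.grid.shape + (2,), dtype=float)
    for ch, img in enumerate((a, b)):
        peak = img.grid.max()
        if peak > 0:
            out[..., ch] = img.grid / peak
    return out


def clip_hotspots(image: ProteoformImage, percentile: float = 99.0) -> np.ndarray:
    """Counts clipped at a high percentile, for display only."""
    cap = np.percentile(image.grid, percentile)
    return np.minimum(image.grid, cap)


def write_image_tsv(image: ProteoformImage, path) -> None:
    pd.DataFrame(image.grid).to_csv(path, sep="\t", index=False, header=False)


def plot_image(image: ProteoformImage, path, cmap: str = "viridis") -> None:
    """Save a PNG heatmap (pixels drawn at their physical aspect ratio)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.imshow(
        image.grid,
        cmap=cmap,
        aspect=image.pixel_across / image.pixel_along,
        interpolation="nearest",
    )
    ax.set_xlabel(f"along-track pixel ({image.pixel_along:g} µm)")
    ax.set_ylabel(f"line ({image.pixel_across:g} µm strip)")
    ax.set_title(image.feature_id)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
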