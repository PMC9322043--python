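"""Pixel-wise chemical maps of predicted S-ovalbumin content.

A fitted calibration model (trained on SNV-corrected mean ROI spectra over
the effective wavelength range) is applied to every ROI pixel of a
calibrated cube: the pixel spectrum is cropped to the effective range, SNV
is applied to the full cropped spectrum, the feature-wavelength subset is
taken, and the model predicts the content.  SNV always sees the full
effective range, never only the feature subset — a model fit on SNV spectra
is meaningless on spectra standardized over a different band set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .hsi_io import HyperCube

logger = logging.getLogger(__name__)

__all__ = ["ChemicalMap", "predict_pixelwise", "render_map"]


@dataclass
class ChemicalMap:
    """Per-pixel predicted content (percent); background pixels are NaN."""

    values: np.ndarray
    mask: np.ndarray
    color_range: tuple = (0.0, 100.0)

    def roi_values(self) -> np.ndarray:
        v = self.values[self.mask]
        return v[np.isfinite(v)]


def predict_pixelwise(
    cube: HyperCube,
    mask: np.ndarray,
    model,
    feature_indices=None,
    clip=(0.0, 100.0),
    min_nm: float = 435.0,
    color_range=(0.0, 100.0),
) -> ChemicalMap:
    """Predict content for every ROI pixel of a calibrated cube.

    ``feature_indices`` index into the cropped (>= ``min_nm``) grid; ``None``
    means the model uses the full effective range.  Degenerate (constant)
    pixel spectra cannot be SNV-scaled and are set to NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask spatial shape must match cube")
    keep = cube.wavelengths_nm >= min_nm
    if not keep.any():
        raise ValueError("cube wavelength grid has no bands in the effective range")

    values = np.full(mask.shape, np.nan)
    if mask.any():
        pix = cube.data[mask][:, keep].astype(float)
        mean = pix.mean(axis=1, keepdims=True)
        sd = pix.std(axis=1, ddof=1, keepdims=True)
        good = sd[:, 0] > 1e-12 * np.maximum(1.0, np.abs(mean[:, 0]))
        n_bad = int((~good).sum())
        if n_bad:
            logger.warning("predict_pixelwise: %d degenerate pixel spectra set to NaN", n_bad)
        snv_pix = np.full_like(pix, np.nan)
        snv_pix[good] = (pix[good] - mean[good]) / sd[good]
        feats = snv_pix if feature_indices is None else snv_pix[:, np.asarray(feature_indices, dtype=int)]
        pred = np.full(pix.shape[0], np.nan)
        if good.any():
            pred[good] = np.clip(model.predict(feats[good]), *clip)
        values[mask] = pred
    return ChemicalMap(values=values, mask=mask, color_range=tuple(color_range))


def render_map(cmap: ChemicalMap, out_path, colormap: str = "jet", title: str | None = None):
    """Write a raster image of the map with a linear color bar.

    Low content renders blue, high content red; the background is neutral
    gray.  The color scale spans ``color_range`` so maps of different eggs
    are directly comparable.
    """
    lo, hi = cmap.color_range
    masked = np.ma.masked_invalid(np.where(cmap.mask, cmap.values, np.nan))
    fig, ax = plt.subplots(figsize=(4, 4))
    palette = plt.get_cmap(colormap).copy()
    palette.set_bad("0.85")
    im = ax.imshow(masked, cmap=palette, vmin=lo, vmax=hi, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="S-ovalbumin content (%)")
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path
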