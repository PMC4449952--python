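"""Comparison method variants, including the vesselness-masked PCA.

Besides the vessel-removal method, three variants are implemented for
benchmarking:

* ``downsampled``    -- PCA on downsampled frames without closing;
* ``with_mask``      -- PCA restricted to pixels selected by a
  Hessian-based (Frangi) vesselness mask, i.e. the vessel-centric
  masked-PCA approach adapted to emit the raw first-component projection;
* ``inverted_mask``  -- PCA restricted to the complement of that mask.

The mask is built on downsampled, *unclosed* frames (closing would erase
the very structures the mask selects): per-frame multiscale vesselness
for dark tubular structures, aggregated by per-pixel maximum over the
training frames, then binarized at an intensity quantile.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.filters import frangi

from .io import SurrogateSignal, XASequence
from .pca import PCAModel, fit
from .preprocess import PreprocessConfig, downsample

METHODS = ("vessel_removed", "downsampled", "with_mask", "inverted_mask")

DEFAULT_SCALES = (1.0, 2.0, 3.0)
DEFAULT_QUANTILE = 0.9


@dataclass
class PixelMask:
    """Boolean pixel selection on the downsampled grid (flattened).

    ``grid_shape`` (rows, cols of the downsampled grid) is kept when
    known so the mask can be exported as a PNG image.
    """

    mask: np.ndarray
    scales_px: tuple
    threshold_quantile: float
    grid_shape: tuple | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool).ravel()
        if self.mask.sum() < 2:
            raise ValueError("empty mask: fewer than 2 selected pixels")
        if not 0.0 < self.coverage < 1.0:
            raise ValueError("mask must select a strict subset of pixels")

    @property
    def coverage(self) -> float:
        return float(self.mask.mean())

    def to_png(self, path: str | Path) -> None:
        """Export as a binary PNG (selected pixels white)."""
        if self.grid_shape is None:
            raise ValueError("mask has no grid shape; cannot rasterize")
        img = self.mask.reshape(self.grid_shape).astype(np.uint8) * 255
        iio.imwrite(Path(path), img)

    @classmethod
    def from_png(
        cls, path: str | Path, scales_px: tuple = (),
        threshold_quantile: float = 0.0,
    ) -> "PixelMask":
        img = np.asarray(iio.imread(Path(path)))
        if img.ndim == 3:
            img = img.mean(axis=-1)
        return cls(
            mask=(img > 127).ravel(),
            scales_px=tuple(scales_px),
            threshold_quantile=threshold_quantile,
            grid_shape=img.shape,
        )


def vesselness_mask(
    seq: XASequence,
    factor: int,
    scales_px: tuple = DEFAULT_SCALES,
    threshold_quantile: float = DEFAULT_QUANTILE,
    frames: slice | None = None,
) -> PixelMask:
    """Build a dark-tubular-structure mask on the downsampled grid.

    Frangi vesselness (black ridges) is computed per frame at the given
    scales, the per-pixel maximum over frames is taken, and pixels above
    the given quantile of that aggregate are selected.  ``frames``
    restricts the aggregation to the training range.
    """
    if min(scales_px) < 1:
        raise ValueError("vesselness scales must be >= 1 px")
    if not 0.0 < threshold_quantile < 1.0:
        raise ValueError("threshold_quantile must lie in (0, 1)")
    stack = seq.frames if frames is None else seq.frames[frames]
    agg = None
    for frame in stack:
        small = downsample(frame, factor)
        v = frangi(small, sigmas=scales_px, black_ridges=True)
        agg = v if agg is None else np.maximum(agg, v)
    threshold = np.quantile(agg, threshold_quantile)
    mask = agg > threshold
    if mask.sum() < 2:
        raise ValueError(
            "empty mask: vesselness is (near-)constant, cannot threshold"
        )
    return PixelMask(
        mask=mask.ravel(),
        scales_px=tuple(scales_px),
        threshold_quantile=threshold_quantile,
        grid_shape=agg.shape,
    )


def invert(mask: PixelMask) -> PixelMask:
    """Logical complement of a pixel mask (coverage maps to 1 - coverage)."""
    comp = ~mask.mask
    if comp.sum() < 2:
        raise ValueError("empty complement: mask selects (nearly) all pixels")
    return PixelMask(
        mask=comp,
        scales_px=mask.scales_px,
        threshold_quantile=mask.threshold_quantile,
        grid_shape=mask.grid_shape,
    )


def run_method(
    seqs,
    method: str,
    cfg: PreprocessConfig | None = None,
    frames: slice | None = None,
    scales_px: tuple = DEFAULT_SCALES,
    threshold_quantile: float = DEFAULT_QUANTILE,
) -> tuple[PCAModel, SurrogateSignal]:
    """Fit one of the four comparison methods on mono or biplane input.

    All methods share the center -> Gram-eigendecomposition -> lift ->
    project pipeline and emit the raw first-component projection without
    any filtering; they differ only in which pixels enter the data matrix:

    * ``vessel_removed``: downsampled + morphological closing (all pixels);
    * ``downsampled``: downsampled only (all pixels);
    * ``with_mask`` / ``inverted_mask``: downsampled only, rows outside
      (inside) the vesselness mask dropped.  Masks are built per plane
      from the training frames.
    """
    if method not in METHODS:
        raise ValueError(
            f"unknown method {method!r}; valid methods: {', '.join(METHODS)}"
        )
    if cfg is None:
        cfg = PreprocessConfig()
    planes = [seqs] if isinstance(seqs, XASequence) else list(seqs)

    if method == "vessel_removed":
        use_cfg = PreprocessConfig(
            downsample_factor=cfg.downsample_factor,
            struct_radius=cfg.struct_radius,
            vessel_diameter_mm=cfg.vessel_diameter_mm,
            apply_closing=True,
        )
        return fit(planes, use_cfg, frames=frames, method=method)

    use_cfg = PreprocessConfig(
        downsample_factor=cfg.downsample_factor,
        struct_radius=cfg.struct_radius,
        vessel_diameter_mm=cfg.vessel_diameter_mm,
        apply_closing=False,
    )
    if method == "downsampled":
        return fit(planes, use_cfg, frames=frames, method=method)

    pixel_masks = []
    for plane in planes:
        resolved = use_cfg.resolve(plane)
        m = vesselness_mask(
            plane,
            resolved.factor,
            scales_px=scales_px,
            threshold_quantile=threshold_quantile,
            frames=frames,
        )
        if method == "inverted_mask":
            m = invert(m)
        pixel_masks.append(m.mask)
    return fit(
        planes, use_cfg, frames=frames, pixel_masks=pixel_masks, method=method
    )
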