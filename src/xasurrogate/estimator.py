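"""scikit-learn style estimator wrapping the surrogate extraction pipeline.

:class:`SurrogateExtractor` is a transformer over frame stacks: ``fit``
learns the preprocessing geometry, the per-pixel training mean and the
first principal component from an ``(N, H, W)`` array of frames;
``transform`` / ``predict`` score new frames of the same geometry into a
per-frame scalar surrogate.  It composes with sklearn pipelines and
model selection (``get_params`` / ``set_params`` come from
``BaseEstimator``).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import masks as _masks
from . import pca as _pca
from .io import XASequence
from .preprocess import PreprocessConfig


class SurrogateExtractor(TransformerMixin, BaseEstimator):
    """Respiratory motion surrogate extraction from XA frame stacks.

    Parameters
    ----------
    method : {"vessel_removed", "downsampled", "with_mask", "inverted_mask"}
        Which pixel selection/preprocessing variant to run.  The default
        removes dark curvilinear structures by grayscale closing before
        PCA.
    downsample_factor : int or "auto"
        Block-mean downsampling factor; "auto" derives it from the frame
        side (512/600 -> 4, 1024 -> 8).
    struct_radius : int or "auto"
        Closing-disk radius in downsampled pixels; "auto" derives it from
        ``vessel_diameter_mm`` and the effective pixel spacing.
    vessel_diameter_mm : float
        Maximal projected vessel/catheter diameter the closing must cover.
    pixel_spacing_mm : float
        Detector pixel spacing of the input frames.
    frame_rate_hz : float
        Acquisition frame rate (metadata only; kept for provenance).
    mask_scales_px, mask_quantile
        Vesselness scales and binarization quantile for the masked
        variants.

    Attributes
    ----------
    model_ : PCAModel
        The fitted model (training mean, unit-norm first component,
        eigenvalue spectrum, frozen preprocessing).
    components_ : ndarray of shape (1, D)
        The first principal component.
    mean_ : ndarray of shape (D,)
        Per-pixel temporal mean of the training frames.
    explained_variance_ : ndarray
        Training eigenvalue spectrum, descending.
    """

    def __init__(
        self,
        method: str = "vessel_removed",
        downsample_factor="auto",
        struct_radius="auto",
        vessel_diameter_mm: float = 11.0,
        pixel_spacing_mm: float = 0.216,
        frame_rate_hz: float = 15.0,
        mask_scales_px: tuple = _masks.DEFAULT_SCALES,
        mask_quantile: float = _masks.DEFAULT_QUANTILE,
    ):
        self.method = method
        self.downsample_factor = downsample_factor
        self.struct_radius = struct_radius
        self.vessel_diameter_mm = vessel_diameter_mm
        self.pixel_spacing_mm = pixel_spacing_mm
        self.frame_rate_hz = frame_rate_hz
        self.mask_scales_px = mask_scales_px
        self.mask_quantile = mask_quantile

    def _as_sequence(self, X) -> XASequence:
        if isinstance(X, XASequence):
            return X
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError(
                f"expected an (N, H, W) frame stack, got shape {X.shape}"
            )
        return XASequence(
            frames=X,
            pixel_spacing_mm=self.pixel_spacing_mm,
            frame_rate_hz=self.frame_rate_hz,
        )

    def fit(self, X, y=None):
        """Fit on an (N, H, W) frame stack (or XASequence); y is ignored."""
        seq = self._as_sequence(X)
        cfg = PreprocessConfig(
            downsample_factor=self.downsample_factor,
            struct_radius=self.struct_radius,
            vessel_diameter_mm=self.vessel_diameter_mm,
            apply_closing=self.method == "vessel_removed",
        )
        model, signal = _masks.run_method(
            seq,
            self.method,
            cfg,
            scales_px=self.mask_scales_px,
            threshold_quantile=self.mask_quantile,
        )
        self.model_ = model
        self.components_ = model.e1[None, :]
        self.mean_ = model.mean_vector
        self.explained_variance_ = model.eigenvalues
        self.training_signal_ = signal.values
        self.n_features_in_ = int(np.prod(seq.frame_shape))
        return self

    def transform(self, X) -> np.ndarray:
        """Project frames onto the first component; returns shape (M, 1)."""
        check_is_fitted(self, "model_")
        frames = X.frames if isinstance(X, XASequence) else np.asarray(X)
        signal = _pca.predict(self.model_, frames)
        return signal.values[:, None]

    def predict(self, X) -> np.ndarray:
        """Per-frame surrogate values as a flat (M,) vector."""
        return self.transform(X)[:, 0]

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Retrospective surrogate of the training frames themselves."""
        self.fit(X)
        return self.training_signal_.copy()
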