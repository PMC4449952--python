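"""PCA of pixel-intensity time series via the Gram-matrix trick.

A preprocessed XA sequence is a D x N matrix ``X`` whose columns are
flattened frames (D pixels, N frames, D >> N).  After centering each pixel
over time, the principal components are the eigenvectors of the D x D
pixel covariance ``X X^T``.  Because D >> N we instead diagonalize the
small N x N Gram matrix ``X^T X`` and lift its leading eigenvector back to
pixel space:

    e1  =  X v1 / ||X v1||,        p  =  X^T e1,

where ``v1`` is the leading Gram eigenvector and ``p`` holds one scalar
per frame -- the respiratory motion surrogate.  In sequences whose
cardiac-moving structures have been removed, respiration dominates the
intensity variance, so ``p`` tracks breathing.

``e1`` is normalized to unit length rather than scaled by the inverse
eigenvalue: the two conventions differ by a positive scalar on ``p``,
which is irrelevant for a correlation-based surrogate, and unit
normalization avoids dividing by the structurally zero smallest
eigenvalue introduced by centering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import SurrogateSignal, XASequence
from .preprocess import (
    PreprocessConfig,
    ResolvedPreprocess,
    preprocess_frames,
    preprocess_sequence,
)

#: Relative eigenvalue-gap threshold under which the first component is
#: ill-determined and a warning is emitted.
DEGENERATE_GAP = 1e-6


def center_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the per-pixel temporal mean from every column.

    Pixels are the variables and frames the observations: the mean is the
    average *image* of the sequence.  Each row of the result sums to zero.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be a D x N matrix with N >= 2")
    mean = X.mean(axis=1)
    return X - mean[:, None], mean


def gram_eig(Xc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the N x N Gram matrix ``Xc^T Xc``.

    Returns unit-norm eigenvectors (columns) and eigenvalues sorted in
    descending order; tiny negative eigenvalues from round-off are clipped
    to zero.  Centering makes the all-ones vector a null vector, so the
    smallest eigenvalue is numerically zero.
    """
    Xc = np.asarray(Xc, dtype=np.float64)
    if not np.all(np.isfinite(Xc)):
        raise ValueError("input matrix contains non-finite values")
    gram = Xc.T @ Xc
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    return evecs[:, order], evals


def lift_first_component(
    Xc: np.ndarray, evecs: np.ndarray, evals: np.ndarray
) -> np.ndarray:
    """Lift the leading Gram eigenvector to pixel space.

    Returns the unit-norm first principal component ``e1`` of the pixel
    covariance.  The sign is fixed so that the entry of ``e1`` with the
    largest magnitude is positive (PCA sign is otherwise arbitrary).
    Raises on (numerically) constant sequences, which carry no variance
    to decompose.
    """
    evals = np.asarray(evals, dtype=np.float64)
    trace = float(evals.sum())
    if trace <= 0 or evals[0] <= 1e-12 * trace:
        raise ValueError("no variance: the sequence is (numerically) constant")
    if evals.size > 1 and (evals[0] - evals[1]) / evals[0] < DEGENERATE_GAP:
        warnings.warn(
            "near-degenerate leading eigenvalues: the first principal "
            "component is ill-determined",
            RuntimeWarning,
            stacklevel=2,
        )
    e1 = Xc @ evecs[:, 0]
    e1 /= np.linalg.norm(e1)
    if e1[np.argmax(np.abs(e1))] < 0:
        e1 = -e1
    return e1


def project(Xc: np.ndarray, e1: np.ndarray) -> np.ndarray:
    """Project (already centered) columns onto the first component:
    ``p[j] = <column j, e1>``."""
    Xc = np.asarray(Xc, dtype=np.float64)
    e1 = np.asarray(e1, dtype=np.float64)
    if Xc.shape[0] != e1.shape[0]:
        raise ValueError(
            f"dimension mismatch: matrix has {Xc.shape[0]} rows, "
            f"component has {e1.shape[0]}"
        )
    return Xc.T @ e1


# ---------------------------------------------------------------------------
# fitted model
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """A trained surrogate extractor.

    Holds everything needed to score new frames: the frozen preprocessing
    per plane, the per-pixel training mean, the unit-norm first principal
    component and the training eigenvalue spectrum (kept for diagnostics).
    ``pixel_masks`` restricts each plane's pixel vector to a subset of
    rows (used by the masked comparison variants); ``None`` entries mean
    no restriction.
    """

    mean_vector: np.ndarray
    e1: np.ndarray
    eigenvalues: np.ndarray
    preprocess: list[ResolvedPreprocess]
    n_train: int
    plane_scope: str = "mono"
    plane_dims: list[int] = field(default_factory=list)
    method: str = "vessel_removed"
    pixel_masks: list | None = None

    def __post_init__(self) -> None:
        self.mean_vector = np.asarray(self.mean_vector, dtype=np.float64)
        self.e1 = np.asarray(self.e1, dtype=np.float64)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64)
        if self.mean_vector.shape != self.e1.shape:
            raise ValueError("mean_vector and e1 must have equal length")
        if abs(np.linalg.norm(self.e1) - 1.0) > 1e-9:
            raise ValueError("e1 must be unit norm")
        if np.any(np.diff(self.eigenvalues) > 1e-9 * max(self.eigenvalues[0], 1)):
            raise ValueError("eigenvalues must be sorted descending")

    def eigenimage(self, plane: int = 0) -> np.ndarray:
        """Reshape the plane's block of ``e1`` to the downsampled grid
        (only for unmasked models, where the block is a full image)."""
        if self.pixel_masks is not None and self.pixel_masks[plane] is not None:
            raise ValueError("masked models have no dense eigenimage")
        start = sum(self.plane_dims[:plane])
        block = self.e1[start : start + self.plane_dims[plane]]
        return block.reshape(self.preprocess[plane].grid_shape)

    def save(self, path: str | Path) -> None:
        """Serialize to a single ``.npz`` archive (arrays + JSON metadata)."""
        meta = {
            "n_train": self.n_train,
            "plane_scope": self.plane_scope,
            "plane_dims": list(self.plane_dims),
            "method": self.method,
            "preprocess": [r.to_dict() for r in self.preprocess],
            "has_masks": self.pixel_masks is not None,
        }
        arrays = {
            "mean_vector": self.mean_vector,
            "e1": self.e1,
            "eigenvalues": self.eigenvalues,
            "meta_json": np.frombuffer(
                json.dumps(meta).encode(), dtype=np.uint8
            ),
        }
        if self.pixel_masks is not None:
            for i, m in enumerate(self.pixel_masks):
                arrays[f"mask_{i}"] = (
                    np.zeros(0, dtype=bool) if m is None else np.asarray(m)
                )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "PCAModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta_json"]).decode())
            masks = None
            if meta["has_masks"]:
                masks = []
                for i in range(len(meta["plane_dims"])):
                    m = data[f"mask_{i}"]
                    masks.append(None if m.size == 0 else m.astype(bool))
            return cls(
                mean_vector=data["mean_vector"],
                e1=data["e1"],
                eigenvalues=data["eigenvalues"],
                preprocess=[
                    ResolvedPreprocess.from_dict(d) for d in meta["preprocess"]
                ],
                n_train=int(meta["n_train"]),
                plane_scope=meta["plane_scope"],
                plane_dims=[int(d) for d in meta["plane_dims"]],
                method=meta["method"],
                pixel_masks=masks,
            )


# ---------------------------------------------------------------------------
# fit / predict
# ---------------------------------------------------------------------------

def fit_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Center -> Gram eigendecomposition -> lift -> project.

    Returns ``(mean, e1, eigenvalues, p)`` for a D x N training matrix.
    This is the computational core shared by every method variant.
    """
    Xc, mean = center_columns(X)
    evecs, evals = gram_eig(Xc)
    e1 = lift_first_component(Xc, evecs, evals)
    p = project(Xc, e1)
    return mean, e1, evals, p


def _as_plane_list(seqs) -> list[XASequence]:
    if isinstance(seqs, XASequence):
        return [seqs]
    planes = list(seqs)
    if len(planes) not in (1, 2):
        raise ValueError("expected one sequence or a biplane pair")
    return planes


def fit(
    seqs,
    cfg: PreprocessConfig | None = None,
    frames: slice | None = None,
    pixel_masks: list | None = None,
    method: str | None = None,
) -> tuple[PCAModel, SurrogateSignal]:
    """Fit the surrogate extractor on one sequence or a biplane pair.

    Each plane is preprocessed independently; for a biplane pair the two
    pixel-vector blocks of every frame are stacked into one column
    (``X = (X_A; X_B)``), so a single projection vector describes both
    views.  ``frames`` restricts training to an index range.  Returns the
    model and the retrospective surrogate over the training frames.
    """
    planes = _as_plane_list(seqs)
    if cfg is None:
        cfg = PreprocessConfig()
    if len(planes) == 2 and planes[0].n_frames != planes[1].n_frames:
        raise ValueError(
            "biplane sequences must be time-synchronized with equal frame "
            f"counts, got {planes[0].n_frames} and {planes[1].n_frames}"
        )

    blocks: list[np.ndarray] = []
    resolved_list: list[ResolvedPreprocess] = []
    for i, plane in enumerate(planes):
        Xp, resolved = preprocess_sequence(plane, cfg)
        if frames is not None:
            Xp = Xp[:, frames]
        if pixel_masks is not None and pixel_masks[i] is not None:
            Xp = Xp[np.asarray(pixel_masks[i], dtype=bool)]
        blocks.append(Xp)
        resolved_list.append(resolved)

    X = np.vstack(blocks)
    mean, e1, evals, p = fit_matrix(X)

    scope = "biplane" if len(planes) == 2 else "mono"
    method_name = method or (
        "vessel_removed" if cfg.apply_closing else "downsampled"
    )
    model = PCAModel(
        mean_vector=mean,
        e1=e1,
        eigenvalues=evals,
        preprocess=resolved_list,
        n_train=X.shape[1],
        plane_scope=scope,
        plane_dims=[b.shape[0] for b in blocks],
        method=method_name,
        pixel_masks=pixel_masks,
    )
    signal = SurrogateSignal(
        values=p, method=method_name, mode="retrospective", plane_scope=scope
    )
    return model, signal


def predict(model: PCAModel, seqs) -> SurrogateSignal:
    """Score new frames with a fitted model (prospective mode).

    Each frame is preprocessed with the parameters frozen at fit time,
    centered with the *training* mean (never its own -- streaming
    prediction must not peek ahead) and projected onto ``e1``.  Accepts
    an ``XASequence``, a raw (M, H, W) array, or a biplane pair thereof.
    """
    if isinstance(seqs, (XASequence, np.ndarray)):
        planes = [seqs]
    else:
        planes = list(seqs)
    if len(planes) != len(model.plane_dims):
        raise ValueError(
            f"model was trained on {len(model.plane_dims)} plane(s), "
            f"got {len(planes)}"
        )
    blocks = []
    for i, plane in enumerate(planes):
        frames = plane.frames if isinstance(plane, XASequence) else plane
        Xp = preprocess_frames(frames, model.preprocess[i])
        if model.pixel_masks is not None and model.pixel_masks[i] is not None:
            Xp = Xp[np.asarray(model.pixel_masks[i], dtype=bool)]
        if Xp.shape[0] != model.plane_dims[i]:
            raise ValueError(
                f"plane {i}: expected {model.plane_dims[i]} pixels, "
                f"got {Xp.shape[0]}"
            )
        blocks.append(Xp)
    X = np.vstack(blocks)
    p = project(X - model.mean_vector[:, None], model.e1)
    return SurrogateSignal(
        values=p,
        method=model.method,
        mode="prospective",
        plane_scope=model.plane_scope,
    )
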