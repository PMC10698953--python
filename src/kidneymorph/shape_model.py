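"""Statistical shape analysis: PCA modes of variation and per-subject scores.

The shape representation can be flattened vertex coordinates (d = 3 n_v), the
S2S scalar field (d = n_v), or their concatenation; the decomposition is a
centred, full-SVD PCA with a deterministic sign convention (each mode's
largest-magnitude loading is positive).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "ShapeModel",
    "fit_shape_model",
    "mode_reconstruction",
    "project",
    "variance_explained",
]


@dataclass
class ShapeModel:
    mean: np.ndarray  # (d,)
    modes: np.ndarray  # (k, d), orthonormal rows
    eigenvalues: np.ndarray  # (k,) variances, non-increasing
    total_variance: float  # over all d directions, not just the k kept
    data_kind: str = "s2s"  # {"coordinates", "s2s", "coordinates+s2s"}
    degenerate: bool = False

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def variance_explained_pct(self) -> np.ndarray:
        if self.total_variance <= 0:
            return np.zeros(self.n_modes)
        return 100.0 * self.eigenvalues / self.total_variance

    def save(self, directory: str | Path) -> Path:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savetxt(d / "mean.txt", self.mean)
        np.savetxt(d / "modes.txt", self.modes)
        np.savetxt(d / "eigenvalues.txt", self.eigenvalues)
        (d / "model.json").write_text(
            json.dumps(
                {
                    "data_kind": self.data_kind,
                    "n_modes": self.n_modes,
                    "total_variance": self.total_variance,
                    "degenerate": self.degenerate,
                },
                indent=2,
            )
        )
        return d

    @classmethod
    def load(cls, directory: str | Path) -> "ShapeModel":
        d = Path(directory)
        meta = json.loads((d / "model.json").read_text())
        return cls(
            mean=np.loadtxt(d / "mean.txt"),
            modes=np.atleast_2d(np.loadtxt(d / "modes.txt")),
            eigenvalues=np.atleast_1d(np.loadtxt(d / "eigenvalues.txt")),
            total_variance=meta["total_variance"],
            data_kind=meta["data_kind"],
            degenerate=meta["degenerate"],
        )


def fit_shape_model(
    data: np.ndarray, n_modes: int | None = None, data_kind: str = "s2s"
) -> ShapeModel:
    """Centred PCA of an (n_s, d) shape-representation matrix.

    Modes are unit-norm eigenvectors of the sample covariance (denominator
    n_s - 1), ordered by decreasing variance.  ``n_modes`` beyond the data
    rank is clipped with a warning; an all-identical cohort yields a model
    flagged degenerate with zero eigenvalues.
    """
    data = np.asarray(data, float)
    if data.ndim != 2:
        raise ValueError("data must be (n_s, d)")
    n_s, d = data.shape
    if n_s < 2:
        raise ValueError("need at least 2 subjects")
    max_modes = min(n_s - 1, d)
    if n_modes is None:
        n_modes = max_modes
    if n_modes > max_modes:
        warnings.warn(f"n_modes={n_modes} clipped to {max_modes}")
        n_modes = max_modes
    pca = PCA(n_components=max_modes, svd_solver="full")
    with np.errstate(divide="ignore", invalid="ignore"):
        pca.fit(data)
    modes = pca.components_[:n_modes]
    eigenvalues = pca.explained_variance_[:n_modes].copy()
    total_var = float(data.var(axis=0, ddof=1).sum())
    degenerate = total_var <= 1e-30
    if degenerate:
        eigenvalues[:] = 0.0
    # deterministic sign: orient each mode along the mean shape where that
    # projection is meaningful (a size mode then grows with +SD), otherwise
    # make the largest-|loading| entry positive
    mean_norm = np.linalg.norm(pca.mean_)
    for k in range(len(modes)):
        proj = float(modes[k] @ pca.mean_)
        if abs(proj) > 1e-8 * max(mean_norm, 1e-30):
            if proj < 0:
                modes[k] *= -1.0
        else:
            j = int(np.argmax(np.abs(modes[k])))
            if modes[k, j] < 0:
                modes[k] *= -1.0
    return ShapeModel(
        mean=pca.mean_,
        modes=modes,
        eigenvalues=eigenvalues,
        total_variance=total_var,
        data_kind=data_kind,
        degenerate=degenerate,
    )


def mode_reconstruction(model: ShapeModel, mode_index: int, c: float) -> np.ndarray:
    """Shape at ``c`` SD along one mode: mean + c * sqrt(lambda_k) * e_k."""
    if not 0 <= mode_index < model.n_modes:
        raise IndexError(f"mode {mode_index} outside fitted range")
    return model.mean + c * np.sqrt(model.eigenvalues[mode_index]) * model.modes[mode_index]


def project(model: ShapeModel, x: np.ndarray) -> np.ndarray:
    """PC scores of one subject vector or an (n, d) stack: modes . (x - mean)."""
    x = np.asarray(x, float)
    if x.shape[-1] != model.mean.shape[0]:
        raise ValueError("dimension mismatch with shape model")
    return (x - model.mean) @ model.modes.T


def reconstruct(model: ShapeModel, scores: np.ndarray) -> np.ndarray:
    return model.mean + np.asarray(scores, float) @ model.modes


def variance_explained(model: ShapeModel, first_k: int | None = None) -> float:
    """Percentage of total variance captured by the first ``first_k`` modes."""
    if first_k is None:
        first_k = model.n_modes
    first_k = min(first_k, model.n_modes)
    if model.total_variance <= 0:
        return 0.0
    return float(100.0 * model.eigenvalues[:first_k].sum() / model.total_variance)
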