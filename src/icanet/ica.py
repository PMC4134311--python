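"""Per-subject spatial ICA.

Spatial orientation: time points are the observed mixtures, voxels are the
samples, so the recovered sources are spatial maps and the mixing columns
are component time courses. Decomposition = temporal PCA whitening followed
by FastICA with deflation and the tanh contrast, one component at a time
with Gram-Schmidt orthogonalisation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volume import Grid, Volume4D

__all__ = [
    "WhiteningRecord",
    "ICDecomposition",
    "whiten",
    "fastica_deflation",
    "orient_components",
    "decompose_subject",
]


@dataclass
class WhiteningRecord:
    """Retained principal subspace of the temporal covariance."""

    eigenvalues: np.ndarray  # (k,) retained eigenvalues, descending
    projection: np.ndarray  # (k, t): maps demeaned data rows to whitened rows
    explained_variance: np.ndarray  # (k,) fractions of total variance
    n_requested: int
    n_retained: int


@dataclass
class ICDecomposition:
    """Z-scaled spatial maps plus matching time courses for one subject.

    ``spatial_maps`` is components x in-mask voxels with each row
    standardised to zero mean and unit variance; ``time_courses`` is scaled
    so that sum_i time_courses[:, i] (outer) spatial_maps[i] reconstructs the
    whitened-subspace part of the data.
    """

    spatial_maps: np.ndarray  # (k, v)
    time_courses: np.ndarray  # (t, k)
    unmixing: np.ndarray  # (k, k) orthonormal rows in whitened space
    whitening: WhiteningRecord
    convergence: np.ndarray  # (k,) iteration counts; -1 marks non-convergence
    seed: int

    @property
    def n_components(self) -> int:
        return self.spatial_maps.shape[0]

    def maps_in_grid(self, mask: np.ndarray, grid: Grid) -> np.ndarray:
        """Embed the masked maps back into the 3-D grid (k, x, y, z)."""
        out = np.zeros((self.n_components,) + tuple(grid.shape), dtype=np.float32)
        out[:, mask] = self.spatial_maps
        return out

    def save(self, directory, mask: np.ndarray, grid: Grid) -> None:
        import nibabel as nib

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        stack = np.moveaxis(self.maps_in_grid(mask, grid), 0, -1)
        nib.save(nib.Nifti1Image(stack, grid.affine), str(d / "ic_maps.nii"))
        pd.DataFrame(
            self.time_courses,
            columns=[f"IC{i + 1}" for i in range(self.n_components)],
        ).to_csv(d / "ic_timecourses.tsv", sep="\t", index=False)
        sidecar = {
            "seed": int(self.seed),
            "n_components": int(self.n_components),
            "convergence_iterations": [int(c) for c in self.convergence],
            "explained_variance": [float(v) for v in self.whitening.explained_variance],
        }
        with open(d / "ica.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


def whiten(data: np.ndarray, n_components: int = 30) -> tuple[np.ndarray, WhiteningRecord]:
    """PCA-whiten a (time x voxel) matrix over its temporal dimension.

    Rows (time points) are demeaned across voxels; the retained principal
    subspace is scaled to identity covariance over voxels. If the data rank
    is below the request, fewer components are retained with a warning.
    """
    X = np.asarray(data, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("expected a 2-D (time x voxel) matrix")
    nt, nv = X.shape
    X = X - X.mean(axis=1, keepdims=True)
    cov = (X @ X.T) / nv
    total_var = float(np.trace(cov))
    if total_var <= 0:
        raise ValueError("degenerate (constant) data: zero variance")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(nt, nv) * np.finfo(float).eps * max(evals.max(), 0.0)
    rank = int((evals > tol).sum())
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(
            f"requested {n_components} components but data rank is {rank}; "
            f"retaining {k}"
        )
    evals_k = evals[:k]
    proj = evecs[:, :k].T / np.sqrt(evals_k)[:, None]
    Xw = proj @ X
    record = WhiteningRecord(
        eigenvalues=evals_k,
        projection=proj,
        explained_variance=evals_k / total_var,
        n_requested=n_components,
        n_retained=k,
    )
    return Xw, record


def _one_unit(
    Xw32: np.ndarray,
    W_prev: np.ndarray,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    max_restarts: int = 5,
) -> tuple[np.ndarray, int]:
    """Extract one unmixing vector by the tanh fixed-point iteration.

    The two large matrix-vector passes over the voxel axis run in single
    precision: they are memory-bandwidth bound and their ~1e-7 rounding sits
    two orders of magnitude below the convergence tolerance. Everything that
    accumulates across iterations (orthogonalisation, normalisation, the
    convergence test) stays in double precision.
    """
    k, nv = Xw32.shape

    def deflate(w):
        if W_prev.shape[0]:
            w = w - W_prev.T @ (W_prev @ w)
        n = np.linalg.norm(w)
        return w / n if n > 0 else w

    for restart in range(max_restarts):
        w = deflate(rng.standard_normal(k))
        for it in range(1, max_iter + 1):
            g = np.tanh(w.astype(np.float32) @ Xw32)
            g64 = g.astype(np.float64)
            # E[g'] = 1 - E[g^2] for g = tanh.
            w_new = (Xw32 @ g).astype(np.float64) / nv - (1.0 - (g64 @ g64) / nv) * w
            w_new = deflate(w_new)
            if np.linalg.norm(w_new) == 0:
                break
            if abs(w_new @ w) > 1.0 - tol:
                return w_new, it
            w = w_new
    return w, -1


def fastica_deflation(
    whitened: np.ndarray,
    n_components: int | None = None,
    tol: float = 1e-5,
    max_iter: int = 1000,
    seed: int = 0,
    whitening: WhiteningRecord | None = None,
) -> ICDecomposition:
    """FastICA by deflation with the tanh contrast on whitened data.

    Components are extracted one at a time with the fixed-point update
    w <- E[x g(w'x)] - E[g'(w'x)] w (g = tanh), Gram-Schmidt deflation
    against previously found vectors, and renormalisation every iteration.
    Convergence is declared when |<w_new, w_old>| > 1 - tol; a component
    that fails to converge after restarts is flagged with -1, not dropped.
    """
    Xw = np.asarray(whitened, dtype=np.float64)
    k_dim, nv = Xw.shape
    if n_components is None:
        n_components = k_dim
    if n_components > k_dim:
        raise ValueError("cannot extract more components than whitened dimensions")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5]))
    Xw32 = Xw.astype(np.float32)
    W = np.zeros((0, k_dim))
    iters = []
    for _ in range(n_components):
        w, it = _one_unit(Xw32, W, rng, tol, max_iter)
        if it < 0:
            warnings.warn("FastICA component failed to converge; flagged")
        W = np.vstack([W, w])
        iters.append(it)

    sources = W @ Xw  # (k, v), zero mean over voxels by construction
    sd = sources.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    maps = sources / sd[:, None]

    if whitening is not None:
        # Mixing in original time space: A = U sqrt(D) W' (t x k); absorb the
        # map standardisation so time_course x map reconstructs the data.
        dewhiten = np.linalg.pinv(whitening.projection)  # (t, k)
        tcs = dewhiten @ W.T * sd[None, :]
        record = whitening
    else:
        tcs = W.T * sd[None, :]
        record = WhiteningRecord(
            eigenvalues=np.ones(k_dim),
            projection=np.eye(k_dim),
            explained_variance=np.full(k_dim, 1.0 / k_dim),
            n_requested=k_dim,
            n_retained=k_dim,
        )
    return ICDecomposition(
        spatial_maps=maps,
        time_courses=tcs,
        unmixing=W,
        whitening=record,
        convergence=np.asarray(iters),
        seed=int(seed),
    )


def orient_components(decomp: ICDecomposition) -> ICDecomposition:
    """Resolve the ICA sign ambiguity: flip each map to positive skewness.

    The time course flips with the map so their product is unchanged. Maps
    with exactly zero skewness are left as-is.
    """
    maps = decomp.spatial_maps
    m3 = (maps**3).mean(axis=1)  # maps are standardised, so this is the skewness
    flip = np.where(m3 < 0, -1.0, 1.0)
    decomp.spatial_maps = maps * flip[:, None]
    decomp.time_courses = decomp.time_courses * flip[None, :]
    decomp.unmixing = decomp.unmixing * flip[:, None]
    return decomp


def decompose_subject(
    vol: Volume4D,
    mask: np.ndarray,
    n_components: int = 30,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 1000,
) -> ICDecomposition:
    """Whiten + FastICA + orientation for one preprocessed subject."""
    data = vol.data[mask].T  # (t, v)
    Xw, record = whiten(data, n_components)
    decomp = fastica_deflation(
        Xw, record.n_retained, tol=tol, max_iter=max_iter, seed=seed, whitening=record
    )
    return orient_components(decomp)
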