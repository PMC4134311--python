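"""Per-subject preparation of 4D series for ICA.

Stage order: discard initial scans (T1 saturation) -> motion QC ->
voxel-wise linear detrending -> isotropic Gaussian smoothing (FWHM 6 mm) ->
nuisance regression against white-matter and CSF mean signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import Volume4D

__all__ = [
    "MotionParams",
    "MotionCheck",
    "discard_initial",
    "motion_check",
    "detrend_voxelwise",
    "smooth_gaussian",
    "nuisance_regression",
    "preprocess_subject",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# Worst-case head radius (mm) used to convert rotations to surface displacement.
HEAD_RADIUS_MM = 65.0


@dataclass
class MotionParams:
    """Per-volume rigid-body parameters: 3 translations (mm), 3 rotations (deg)."""

    translations_mm: np.ndarray  # (t, 3)
    rotations_deg: np.ndarray  # (t, 3)

    def __post_init__(self) -> None:
        self.translations_mm = np.atleast_2d(np.asarray(self.translations_mm, float))
        self.rotations_deg = np.atleast_2d(np.asarray(self.rotations_deg, float))
        if self.translations_mm.shape != self.rotations_deg.shape:
            raise ValueError("translations and rotations must have matching shapes")
        if self.translations_mm.shape[1] != 3:
            raise ValueError("expected 3 translation and 3 rotation columns")

    @classmethod
    def from_tsv(cls, path) -> "MotionParams":
        df = pd.read_csv(path, sep="\t")
        arr = df.to_numpy(dtype=float)
        if arr.shape[1] != 6:
            raise ValueError("motion TSV must have 6 columns (3 trans, 3 rot)")
        return cls(arr[:, :3], arr[:, 3:])

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            np.hstack([self.translations_mm, self.rotations_deg]),
            columns=["tx_mm", "ty_mm", "tz_mm", "rx_deg", "ry_deg", "rz_deg"],
        )
        df.to_csv(path, sep="\t", index=False)


@dataclass
class MotionCheck:
    passed: bool
    max_excursion_mm: float
    threshold_mm: float


def discard_initial(vol: Volume4D, n_discard: int = 2) -> Volume4D:
    """Drop the first ``n_discard`` volumes (T1 saturation transients)."""
    if n_discard < 0:
        raise ValueError("n_discard must be nonnegative")
    if vol.n_volumes <= n_discard:
        raise ValueError(
            f"cannot discard {n_discard} of {vol.n_volumes} volumes (empty result)"
        )
    if n_discard == 0:
        return vol
    return vol.copy_with(vol.data[..., n_discard:])


def motion_check(params: MotionParams, voxel_mm: float) -> MotionCheck:
    """Half-a-voxel movement rule.

    Fails if any translation exceeds voxel/2 mm, or any rotation moves the
    head surface (at a 65-mm radius) by more than voxel/2 mm.
    """
    if params.translations_mm.size == 0:
        raise ValueError("motion parameters are empty")
    threshold = voxel_mm / 2.0
    trans_exc = np.abs(params.translations_mm).max()
    rot_disp = HEAD_RADIUS_MM * np.deg2rad(np.abs(params.rotations_deg))
    rot_exc = rot_disp.max() if rot_disp.size else 0.0
    excursion = float(max(trans_exc, rot_exc))
    return MotionCheck(passed=excursion <= threshold, max_excursion_mm=excursion,
                       threshold_mm=threshold)


def detrend_voxelwise(vol: Volume4D) -> Volume4D:
    """Remove each voxel's least-squares linear trend, keeping its mean."""
    nt = vol.n_volumes
    if nt < 3:
        raise ValueError("need at least 3 time points to detrend")
    t = np.arange(nt, dtype=np.float64)
    tc = t - t.mean()
    denom = float(tc @ tc)
    data = vol.data.astype(np.float32, copy=False)
    slope = (data @ tc.astype(np.float32)) / denom
    out = data - slope[..., None] * tc.astype(np.float32)
    return vol.copy_with(out)


def smooth_gaussian(vol: Volume4D, fwhm_mm: float = 6.0) -> Volume4D:
    """Convolve each volume with an isotropic Gaussian (reflective borders)."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return vol
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vol.grid.voxel_mm
    out = ndimage.gaussian_filter(
        vol.data, sigma=(sigma_vox, sigma_vox, sigma_vox, 0.0), mode="reflect"
    )
    return vol.copy_with(out)


def nuisance_regression(
    vol: Volume4D, wm_mask: np.ndarray, csf_mask: np.ndarray
) -> tuple[Volume4D, pd.DataFrame]:
    """Regress out mean WM and CSF signals (plus intercept) from every voxel.

    Returns the residual volume and the nuisance series actually used. If the
    two covariates are (near-)collinear the CSF column is dropped with a
    warning.
    """
    for name, mask in (("WM", wm_mask), ("CSF", csf_mask)):
        if mask.sum() == 0:
            raise ValueError(f"{name} mask is empty")
        if tuple(mask.shape) != tuple(vol.grid.shape):
            raise ValueError(f"{name} mask is not aligned with the volume grid")
    data = vol.data
    nt = vol.n_volumes
    wm_ts = data[wm_mask].mean(axis=0).astype(np.float64)
    csf_ts = data[csf_mask].mean(axis=0).astype(np.float64)

    cols = {"WM": wm_ts, "CSF": csf_ts}
    wm_c = wm_ts - wm_ts.mean()
    csf_c = csf_ts - csf_ts.mean()
    denom = np.linalg.norm(wm_c) * np.linalg.norm(csf_c)
    corr = float(wm_c @ csf_c / denom) if denom > 0 else 1.0
    if abs(corr) > 0.999 or denom == 0:
        warnings.warn("WM and CSF covariates are collinear; dropping CSF")
        cols.pop("CSF")

    design = np.column_stack([np.ones(nt)] + list(cols.values()))
    # Residual-forming projection applied to the flattened data.
    pinv = np.linalg.pinv(design)
    flat = data.reshape(-1, nt).astype(np.float64)
    beta = flat @ pinv.T
    resid = flat - beta @ design.T
    out = resid.reshape(data.shape).astype(np.float32)
    series = pd.DataFrame(cols)
    return vol.copy_with(out), series


def preprocess_subject(
    vol: Volume4D,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    n_discard: int = 2,
    fwhm_mm: float = 6.0,
    motion: MotionParams | None = None,
    regress_nuisance: bool = True,
) -> Volume4D:
    """Full per-subject preprocessing chain."""
    vol = discard_initial(vol, n_discard)
    if motion is not None:
        check = motion_check(motion, vol.grid.voxel_mm)
        if not check.passed:
            raise ValueError(
                f"motion QC failed: excursion {check.max_excursion_mm:.2f} mm "
                f"> {check.threshold_mm:.2f} mm"
            )
    vol = detrend_voxelwise(vol)
    vol = smooth_gaussian(vol, fwhm_mm)
    if regress_nuisance:
        vol, _ = nuisance_regression(vol, wm_mask, csf_mask)
    return vol
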