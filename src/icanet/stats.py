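"""Group inference on network Z maps.

Voxel-wise one-way ANOVA between two groups (equivalently a pooled t, with
F = t^2), familywise-error control by Monte Carlo cluster-size thresholding,
ROI summaries, behavioural group t-tests, and brain-behaviour Pearson
correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .physio import pooled_ttest_from_summaries
from .volume import Grid

__all__ = [
    "StatsConfig",
    "StatMap",
    "ClusterTable",
    "MonteCarloResult",
    "voxelwise_group_anova",
    "montecarlo_min_cluster",
    "threshold_and_label",
    "roi_group_ttest",
    "behavioral_group_tests",
    "roi_behavior_correlation",
]


@dataclass
class StatsConfig:
    """Cluster-correction settings.

    Defaults: voxel-level p < 0.005 (two-sided), familywise alpha 0.05,
    null-field smoothness FWHM 1.842 voxels, 5000 Monte Carlo iterations,
    26-connectivity.
    """

    voxel_p: float = 0.005
    alpha: float = 0.05
    sim_fwhm_vox: float = 1.842
    n_iterations: int = 5000
    connectivity: int = 26
    sim_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.voxel_p < self.alpha < 1):
            raise ValueError("require 0 < voxel_p < alpha < 1")
        if self.n_iterations < 100:
            raise ValueError("n_iterations must be >= 100")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class StatMap:
    """Voxel-wise statistic volumes with degrees of freedom."""

    t: np.ndarray  # signed (EDp - HC) t, 3-D
    f: np.ndarray  # F = t^2
    df: tuple[int, int]
    grid: Grid
    mask: np.ndarray
    zero_variance: np.ndarray  # voxels where the statistic was forced to 0


def voxelwise_group_anova(
    zmaps_edp: np.ndarray, zmaps_hc: np.ndarray, mask: np.ndarray, grid: Grid
) -> StatMap:
    """Per-voxel one-way ANOVA between groups on in-mask Z values.

    Inputs are (subjects x in-mask voxels) arrays. Returns the signed
    companion t map (EDp - HC) with F = t^2 and df = (1, n1 + n2 - 2).
    Voxels with zero within-group variance get statistic 0 and a flag.
    """
    a = np.asarray(zmaps_edp, dtype=np.float64)
    b = np.asarray(zmaps_hc, dtype=np.float64)
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    df = n1 + n2 - 2
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    ss1 = ((a - m1) ** 2).sum(axis=0)
    ss2 = ((b - m2) ** 2).sum(axis=0)
    sp2 = (ss1 + ss2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    zero_var = se == 0
    t_flat = np.zeros(a.shape[1])
    np.divide(m1 - m2, se, out=t_flat, where=~zero_var)
    if zero_var.any() and np.any((m1 != m2) & zero_var):
        warnings.warn("zero within-group variance at voxels with unequal means; set to 0")

    t_vol = np.zeros(grid.shape)
    t_vol[mask] = t_flat
    zv_vol = np.zeros(grid.shape, dtype=bool)
    zv_vol[mask] = zero_var
    return StatMap(t=t_vol, f=t_vol**2, df=(1, df), grid=grid, mask=mask,
                   zero_variance=zv_vol)


@dataclass
class MonteCarloResult:
    min_cluster_size: int
    attained_alpha: float
    mask_voxels: int
    max_cluster_sizes: np.ndarray

    def __int__(self) -> int:
        return self.min_cluster_size


def montecarlo_min_cluster(mask: np.ndarray, cfg: StatsConfig) -> MonteCarloResult:
    """Minimum cluster extent controlling the familywise error at alpha.

    Each iteration fills the mask's embedding box with unit Gaussian noise,
    smooths it with an isotropic Gaussian of FWHM ``sim_fwhm_vox`` voxels,
    re-standardises within the mask, thresholds so that the suprathreshold
    class has total probability ``voxel_p`` (the F-map exceedance
    convention: on an ANOVA map the sign of a difference does not split
    clusters), and records the largest suprathreshold cluster under the
    configured connectivity. The returned extent is the smallest k with
    P(max cluster >= k) <= alpha. Deterministic given ``sim_seed``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("mask is empty")
    sigma = cfg.sim_fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    z_crit = sps.norm.isf(cfg.voxel_p)
    structure = _STRUCTURES[cfg.connectivity]
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.sim_seed), 7]))

    max_sizes = np.zeros(cfg.n_iterations, dtype=np.int64)
    for i in range(cfg.n_iterations):
        field3d = rng.standard_normal(mask.shape)
        if sigma > 0:
            field3d = ndimage.gaussian_filter(field3d, sigma=sigma, mode="reflect")
        vals = field3d[mask]
        z = (field3d - vals.mean()) / vals.std()
        supra = (np.abs(z) > z_crit) & mask
        if not supra.any():
            continue
        labels, n_lab = ndimage.label(supra, structure=structure)
        if n_lab:
            sizes = np.bincount(labels[supra])
            max_sizes[i] = sizes.max()

    # Smallest k whose familywise exceedance rate is within alpha.
    for k in range(1, int(max_sizes.max()) + 2):
        tail = float((max_sizes >= k).mean())
        if tail <= cfg.alpha:
            return MonteCarloResult(
                min_cluster_size=k,
                attained_alpha=tail,
                mask_voxels=int(mask.sum()),
                max_cluster_sizes=max_sizes,
            )
    raise RuntimeError("alpha unattainable at any cluster size")  # pragma: no cover


@dataclass
class ClusterTable:
    """Suprathreshold clusters surviving the extent threshold."""

    clusters: pd.DataFrame  # label, size, peak mm, peak stat, sign
    voxel_threshold: float
    min_cluster_size: int
    label_volume: np.ndarray

    def __len__(self) -> int:
        return len(self.clusters)

    def cluster_mask(self, label: int) -> np.ndarray:
        return self.label_volume == label


def threshold_and_label(
    statmap: StatMap,
    voxel_p: float,
    min_cluster: int,
    connectivity: int = 26,
) -> ClusterTable:
    """Two-sided voxel thresholding plus connected-component extent filtering.

    Positive and negative suprathreshold voxels are labelled separately so a
    cluster has a definite sign of group difference.
    """
    df = statmap.df[1]
    t_crit = sps.t.isf(voxel_p / 2.0, df)
    structure = _STRUCTURES[connectivity]
    rows = []
    label_vol = np.zeros(statmap.t.shape, dtype=np.int32)
    next_label = 1
    for sign in (1, -1):
        supra = (sign * statmap.t > t_crit) & statmap.mask
        labels, n_lab = ndimage.label(supra, structure=structure)
        for lab in range(1, n_lab + 1):
            member = labels == lab
            size = int(member.sum())
            if size < min_cluster:
                continue
            tvals = statmap.t[member]
            peak_flat = np.argmax(sign * tvals)
            idx = np.argwhere(member)[peak_flat]
            peak_mm = statmap.grid.voxel_to_mm(idx)
            label_vol[member] = next_label
            rows.append(
                {
                    "label": next_label,
                    "size_voxels": size,
                    "peak_x_mm": peak_mm[0],
                    "peak_y_mm": peak_mm[1],
                    "peak_z_mm": peak_mm[2],
                    "peak_t": float(tvals[peak_flat]),
                    "sign": sign,
                }
            )
            next_label += 1
    table = pd.DataFrame(
        rows,
        columns=["label", "size_voxels", "peak_x_mm", "peak_y_mm", "peak_z_mm",
                 "peak_t", "sign"],
    )
    return ClusterTable(
        clusters=table,
        voxel_threshold=float(t_crit),
        min_cluster_size=int(min_cluster),
        label_volume=label_vol,
    )


def roi_group_ttest(
    zmaps_edp: np.ndarray,
    zmaps_hc: np.ndarray,
    roi_flat: np.ndarray,
) -> dict:
    """Two-sample t on per-subject mean Z within an ROI.

    ``roi_flat`` is a boolean selector over the same in-mask voxel axis as
    the Z-map rows. Reports group means, SEMs, t (EDp - HC) and two-tailed p.
    """
    roi_flat = np.asarray(roi_flat, dtype=bool)
    if roi_flat.sum() == 0:
        raise ValueError("ROI is empty")
    a = np.asarray(zmaps_edp)[:, roi_flat].mean(axis=1)
    b = np.asarray(zmaps_hc)[:, roi_flat].mean(axis=1)
    t, p = pooled_ttest_from_summaries(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )
    return {
        "mean_EDp": float(a.mean()),
        "sem_EDp": float(a.std(ddof=1) / np.sqrt(a.size)),
        "mean_HC": float(b.mean()),
        "sem_HC": float(b.std(ddof=1) / np.sqrt(b.size)),
        "t": t,
        "p": p,
        "n_EDp": int(a.size),
        "n_HC": int(b.size),
    }


def behavioral_group_tests(subjects: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Pooled-variance two-tailed t per behavioural/physiological column."""
    if "group" not in subjects.columns:
        raise ValueError("subjects table needs a 'group' column")
    groups = set(subjects["group"])
    if not {"EDp", "HC"} <= groups:
        raise ValueError("both EDp and HC groups must be present")
    if columns is None:
        columns = [
            c for c in subjects.columns
            if c not in ("subject_id", "group")
            and pd.api.types.is_numeric_dtype(subjects[c])
        ]
    rows = []
    for col in columns:
        if col not in subjects.columns:
            warnings.warn(f"column {col!r} missing from subjects table; skipped")
            continue
        a = subjects.loc[subjects["group"] == "EDp", col].dropna().to_numpy(float)
        b = subjects.loc[subjects["group"] == "HC", col].dropna().to_numpy(float)
        t, p = pooled_ttest_from_summaries(
            a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
        )
        rows.append({"score": col, "mean_EDp": a.mean(), "sd_EDp": a.std(ddof=1),
                     "mean_HC": b.mean(), "sd_HC": b.std(ddof=1), "t": t, "p": p})
    return pd.DataFrame(rows)


def roi_behavior_correlation(roi_z: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """Pearson r between per-subject ROI Z values and a behavioural score.

    Two-tailed p from the t transform, uncorrected for multiplicity.
    """
    x = np.asarray(roi_z, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
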