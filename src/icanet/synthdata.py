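"""Synthetic two-group cohort generator.

Emulates the data model of a free-viewing fMRI group study: each subject is a
4D volume built from planted spatial networks (Gaussian node bumps times
smooth band-limited time courses), white-matter and CSF nuisance signals
confined to their masks, a linear drift, and i.i.d. Gaussian noise — plus
100-Hz physiological traces and behavioural scores drawn from the study's
group summary statistics. All randomness fans out deterministically from a
single master seed, and every planted quantity is recorded as ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .networks import (
    GroupEffectSpec,
    NetworkSpec,
    NodeSpec,
    default_group_effects,
    default_networks,
)
from .physio import PhysioTrace
from .volume import Grid, Volume4D, brain_mask, default_grid, save_mask

__all__ = [
    "CohortConfig",
    "PhysioGroupParams",
    "NetworkAtlas",
    "GroundTruth",
    "SubjectRecord",
    "Cohort",
    "make_network_atlas",
    "simulate_subject",
    "simulate_cohort",
    "simulate_physio",
    "default_wm_csf_masks",
    "BEHAVIORAL_SCORES",
    "DEFAULT_PHYSIO_PARAMS",
]

GROUPS = ("EDp", "HC")


@dataclass(frozen=True)
class PhysioGroupParams:
    """Group-level physiological parameters (means and between-subject SDs)."""

    tumescence_pct_mean: float
    tumescence_pct_sd: float
    cardiac_rate_bpm_mean: float
    cardiac_rate_bpm_sd: float
    resp_rate_hz_mean: float
    resp_rate_hz_sd: float


# Group physiological summaries: tumescence percent change, heart rate in
# beats/min, respiratory rate (stored explicitly in Hz; the corresponding
# printed study unit is ambiguous).
DEFAULT_PHYSIO_PARAMS: dict[str, PhysioGroupParams] = {
    "EDp": PhysioGroupParams(0.81, 7.1, 74.0, 12.5, 0.68, 0.10),
    "HC": PhysioGroupParams(10.32, 16.4, 75.4, 11.2, 0.69, 0.17),
}

# Behavioural score distributions: column -> (EDp mean, EDp sd, HC mean, HC sd).
BEHAVIORAL_SCORES: dict[str, tuple[float, float, float, float]] = {
    "age": (33.87, 11.2, 33.57, 11.4),
    "education": (14.5, 2.3, 14.5, 2.7),
    "IIEF5": (14.5, 5.5, 24.0, 0.93),
    "BIS": (20.8, 3.4, 21.26, 3.7),
    "BAS_reward": (19.0, 2.4, 19.6, 2.5),
    "BAS_drive": (12.0, 3.7, 12.8, 2.7),
    "BAS_fun": (11.2, 2.8, 13.0, 2.3),
    "STAI_Y1": (38.1, 8.9, 35.4, 7.3),
    "STAI_Y2": (43.2, 9.2, 39.0, 8.5),
    "SAI_E": (74.0, 26.7, 106.0, 28.1),
    "SAI_anx": (76.0, 17.4, 98.0, 14.8),
    "SAI_tot": (2.06, 15.5, -7.84, 15.3),
}


@dataclass
class CohortConfig:
    """Study-level simulation parameters.

    Defaults reproduce the study conditions: 16 patients vs 19 controls,
    210 volumes at TR = 2 s on a 3-mm grid.
    """

    n_EDp: int = 16
    n_HC: int = 19
    n_volumes: int = 210
    tr_s: float = 2.0
    voxel_mm: float = 3.0
    noise_sd: float = 0.5
    drift_amplitude: float = 1.0
    nuisance_amplitude: float = 1.0
    loading_sd: float = 0.2
    node_radius_mm: float | None = None  # None: per-node radii from the atlas
    timecourse_cutoff_hz: float = 0.1
    ipl_sai_coupling: float = 0.6
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes < 10:
            raise ValueError("n_volumes must be >= 10")
        if self.tr_s <= 0 or self.voxel_mm <= 0:
            raise ValueError("tr_s and voxel_mm must be positive")
        for name in ("noise_sd", "drift_amplitude", "nuisance_amplitude", "loading_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative")

    def grid(self) -> Grid:
        return default_grid(self.voxel_mm)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class NetworkAtlas:
    """Labelled spatial maps on the analysis grid, one per network.

    Each map is the sum of isotropic Gaussian bumps (SD = node radius / 2)
    centred at the node peaks, max-normalised to 1. Per-node bumps and the
    node peak voxel indices are kept so subject simulation can weight nodes
    individually and tests can locate peaks.
    """

    grid: Grid
    networks: tuple[NetworkSpec, ...]
    maps: dict[str, np.ndarray]
    node_bumps: dict[str, dict[str, np.ndarray]]
    node_voxels: dict[str, dict[str, tuple[int, int, int]]]

    def network(self, name: str) -> NetworkSpec:
        for net in self.networks:
            if net.name == name:
                return net
        raise KeyError(name)


def make_network_atlas(
    networks: list[NetworkSpec] | None = None,
    grid: Grid | None = None,
    radius_mm: float | None = None,
) -> NetworkAtlas:
    """Render network node tables into spatial maps on ``grid``."""
    if grid is None:
        grid = default_grid()
    if radius_mm is not None and radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    override = radius_mm if (networks is not None and radius_mm is not None) else None
    if networks is None:
        networks = default_networks(radius_mm if radius_mm is not None else 8.0)
    X, Y, Z = grid.coords()
    maps: dict[str, np.ndarray] = {}
    node_bumps: dict[str, dict[str, np.ndarray]] = {}
    node_voxels: dict[str, dict[str, tuple[int, int, int]]] = {}
    for net in networks:
        bumps: dict[str, np.ndarray] = {}
        voxels: dict[str, tuple[int, int, int]] = {}
        total = np.zeros(grid.shape, dtype=np.float64)
        for node in net.nodes:
            if not grid.contains_mm(node.peak_mm):
                raise ValueError(
                    f"node {net.name}/{node.name} peak {node.peak_mm} "
                    "lies outside the grid bounding box"
                )
            r = override if override is not None else node.radius_mm
            sigma = r / 2.0
            d2 = (
                (X - node.peak_mm[0]) ** 2
                + (Y - node.peak_mm[1]) ** 2
                + (Z - node.peak_mm[2]) ** 2
            )
            bump = np.exp(-d2 / (2.0 * sigma**2)).astype(np.float32)
            bumps[node.name] = bump
            voxels[node.name] = grid.nearest_voxel(node.peak_mm)
            total += bump
        peak = total.max()
        if peak > 0:
            total = total / peak
        maps[net.name] = total.astype(np.float32)
        node_bumps[net.name] = bumps
        node_voxels[net.name] = voxels
    return NetworkAtlas(
        grid=grid,
        networks=tuple(networks),
        maps=maps,
        node_bumps=node_bumps,
        node_voxels=node_voxels,
    )


@dataclass
class GroundTruth:
    """Everything planted into one subject's data."""

    subject_id: str
    group: str
    seed: int
    loadings: dict[str, dict[str, float]]
    network_timecourses: dict[str, np.ndarray]
    nuisance_timecourses: dict[str, np.ndarray]
    drift_timecourse: np.ndarray
    tumescence_pct: float
    cardiac_rate_bpm: float
    resp_rate_hz: float


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    volume: Volume4D
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    physio: dict[str, PhysioTrace]
    scores: dict[str, float]
    truth: GroundTruth


@dataclass
class Cohort:
    config: CohortConfig
    atlas: NetworkAtlas
    effects: list[GroupEffectSpec]
    subjects: list[SubjectRecord]
    brain: np.ndarray

    def subjects_table(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {"subject_id": s.subject_id, "group": s.group}
            row.update(s.scores)
            rows.append(row)
        return pd.DataFrame(rows)

    def by_group(self) -> dict[str, list[SubjectRecord]]:
        return {g: [s for s in self.subjects if s.group == g] for g in GROUPS}


def rng_for(master_seed: int, *keys: int) -> np.random.Generator:
    """Deterministic per-stage generator fan-out from a single master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, keys)]))


_STAGE_SUBJECT = 1
_STAGE_PHYSIO = 2
_STAGE_SCORES = 3


def lowpass_timecourse(n: int, tr_s: float, cutoff_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian time course low-pass filtered below ``cutoff_hz``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=tr_s)
    spec[freqs > cutoff_hz] = 0.0
    tc = np.fft.irfft(spec, n)
    tc -= tc.mean()
    sd = tc.std()
    return tc / sd if sd > 0 else tc


def default_wm_csf_masks(grid: Grid) -> tuple[np.ndarray, np.ndarray]:
    """Deep white-matter (bilateral) and third-ventricle CSF masks."""
    X, Y, Z = grid.coords()

    def sphere(center, radius):
        return (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 <= radius**2

    wm = sphere((26.0, -16.0, 24.0), 10.0) | sphere((-26.0, -16.0, 24.0), 10.0)
    csf = sphere((0.0, -10.0, 10.0), 5.0)
    brain = brain_mask(grid)
    return wm & brain, csf & brain


def _effect_multiplier(effects: list[GroupEffectSpec], network: str, node: str, group: str) -> float:
    m = 1.0
    for e in effects:
        if e.network == network and e.node == node:
            m *= e.multiplier(group)
    return m


def simulate_physio(
    group: str,
    cfg: CohortConfig,
    seed: int,
    tumescence_pct: float | None = None,
    cardiac_rate_bpm: float | None = None,
    resp_rate_hz: float | None = None,
    params: dict[str, PhysioGroupParams] | None = None,
) -> dict[str, PhysioTrace]:
    """100-Hz physiological traces for one subject.

    Tumescence: cuff pressure around 80 mmHg with a logistic rise (midpoint
    20 s, time constant 3 s) whose plateau is ``tumescence_pct`` percent of
    the baseline. Cardiac: R-peak event train with 3% inter-beat jitter.
    Respiration: belt sinusoid at ``resp_rate_hz`` with additive noise.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    p = (params or DEFAULT_PHYSIO_PARAMS)[group]
    if tumescence_pct is None:
        tumescence_pct = p.tumescence_pct_mean
    if cardiac_rate_bpm is None:
        cardiac_rate_bpm = p.cardiac_rate_bpm_mean
    if resp_rate_hz is None:
        resp_rate_hz = p.resp_rate_hz_mean
    if cardiac_rate_bpm <= 0 or resp_rate_hz <= 0:
        raise ValueError("cardiac and respiratory rates must be positive")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 97]))
    duration = cfg.n_volumes * cfg.tr_s
    fs = 100.0
    t = np.arange(int(round(duration * fs))) / fs

    baseline_mmhg = 80.0
    rise = 1.0 / (1.0 + np.exp(-(t - 20.0) / 3.0))
    tum = baseline_mmhg * (1.0 + tumescence_pct / 100.0 * rise)
    tum = tum + 0.3 * rng.standard_normal(t.size)

    ibi_nominal = 60.0 / cardiac_rate_bpm
    n_beats = int(np.ceil(duration / ibi_nominal)) + 8
    ibis = ibi_nominal * (1.0 + 0.03 * rng.standard_normal(n_beats))
    ibis = np.clip(ibis, 0.2 * ibi_nominal, 3.0 * ibi_nominal)
    events = np.cumsum(ibis)
    events = events[events <= duration]

    phase = rng.uniform(0, 2 * np.pi)
    resp = np.sin(2 * np.pi * resp_rate_hz * t + phase)
    resp = resp + 0.05 * rng.standard_normal(t.size)

    return {
        "tumescence": PhysioTrace("tumescence", tum, fs, units="mmHg"),
        "cardiac_events": PhysioTrace("cardiac_events", events, units="events"),
        "respiratory": PhysioTrace("respiratory", resp, fs, units="a.u."),
    }


def simulate_subject(
    atlas: NetworkAtlas,
    effects: list[GroupEffectSpec],
    group: str,
    cfg: CohortConfig,
    seed: int,
    subject_id: str = "sub",
    planted_networks: tuple[str, ...] | None = None,
) -> tuple[Volume4D, np.ndarray, np.ndarray, GroundTruth]:
    """One subject's 4D volume plus WM/CSF masks and the planted truth.

    The voxel time series is the sum over planted networks of
    (node-weighted map) x (band-limited unit-variance time course), where the
    node weight is the group multiplier plus N(0, loading_sd) between-subject
    variation, plus nuisance signals confined to the WM/CSF masks, a rank-1
    linear drift over the brain, and i.i.d. Gaussian noise. The group label
    enters only through the effect multipliers.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    grid = atlas.grid
    if abs(grid.voxel_mm - cfg.voxel_mm) > 1e-9:
        raise ValueError("atlas grid does not match cohort config voxel size")
    if planted_networks is None:
        planted_networks = tuple(
            n.name for n in atlas.networks if n.name in ("DMN", "FPN", "SN", "VN")
        )

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE_SUBJECT]))
    nt = cfg.n_volumes
    data = np.zeros(grid.shape + (nt,), dtype=np.float32)

    loadings: dict[str, dict[str, float]] = {}
    network_tcs: dict[str, np.ndarray] = {}
    for name in planted_networks:
        net = atlas.network(name)
        tc = lowpass_timecourse(nt, cfg.tr_s, cfg.timecourse_cutoff_hz, rng)
        network_tcs[name] = tc
        weighted = np.zeros(grid.shape, dtype=np.float32)
        loadings[name] = {}
        for node in net.nodes:
            base = _effect_multiplier(effects, name, node.name, group)
            loading = base + cfg.loading_sd * rng.standard_normal()
            loading = max(loading, 0.0)
            loadings[name][node.name] = float(loading)
            weighted += loading * atlas.node_bumps[name][node.name]
        data += weighted[..., None] * tc.astype(np.float32)

    wm, csf = default_wm_csf_masks(grid)
    nuis_tcs: dict[str, np.ndarray] = {}
    for label, mask in (("WM", wm), ("CSF", csf)):
        tc = lowpass_timecourse(nt, cfg.tr_s, cfg.timecourse_cutoff_hz, rng)
        nuis_tcs[label] = tc
        if cfg.nuisance_amplitude > 0:
            data[mask] += cfg.nuisance_amplitude * tc.astype(np.float32)

    brain = brain_mask(grid)
    drift_tc = np.linspace(-1.0, 1.0, nt)
    if cfg.drift_amplitude > 0:
        data[brain] += cfg.drift_amplitude * drift_tc.astype(np.float32)

    if cfg.noise_sd > 0:
        data += cfg.noise_sd * rng.standard_normal(data.shape).astype(np.float32)

    physio_rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE_PHYSIO]))
    p = DEFAULT_PHYSIO_PARAMS[group]
    tum_pct = p.tumescence_pct_mean + p.tumescence_pct_sd * physio_rng.standard_normal()
    card = p.cardiac_rate_bpm_mean + p.cardiac_rate_bpm_sd * physio_rng.standard_normal()
    card = max(card, 30.0)
    resp = p.resp_rate_hz_mean + p.resp_rate_hz_sd * physio_rng.standard_normal()
    resp = max(resp, 0.05)

    truth = GroundTruth(
        subject_id=subject_id,
        group=group,
        seed=int(seed),
        loadings=loadings,
        network_timecourses=network_tcs,
        nuisance_timecourses=nuis_tcs,
        drift_timecourse=drift_tc,
        tumescence_pct=float(tum_pct),
        cardiac_rate_bpm=float(card),
        resp_rate_hz=float(resp),
    )
    vol = Volume4D(data=data, grid=grid, tr_s=cfg.tr_s)
    return vol, wm, csf, truth


def _subject_scores(
    group: str, truth: GroundTruth, cfg: CohortConfig, rng: np.random.Generator
) -> dict[str, float]:
    col = 0 if group == "EDp" else 2
    scores: dict[str, float] = {}
    for name, row in BEHAVIORAL_SCORES.items():
        mean, sd = row[col], row[col + 1]
        if name == "SAI_E" and group == "EDp" and cfg.ipl_sai_coupling != 0:
            # Couple sexual-arousability score to the planted left-IPL loading.
            rho = cfg.ipl_sai_coupling
            loading = truth.loadings.get("DMN", {}).get("IPL_L")
            if loading is not None and cfg.loading_sd > 0:
                mult = _effect_multiplier(
                    default_group_effects(), "DMN", "IPL_L", group
                )
                z_load = (loading - mult) / cfg.loading_sd
                z = rho * z_load + np.sqrt(1 - rho**2) * rng.standard_normal()
                scores[name] = float(mean + sd * z)
                continue
        scores[name] = float(mean + sd * rng.standard_normal())
    scores["tumescence_pct"] = truth.tumescence_pct
    scores["cardiac_rate_bpm"] = truth.cardiac_rate_bpm
    scores["resp_rate_hz"] = truth.resp_rate_hz
    return scores


def simulate_cohort(
    cfg: CohortConfig | None = None,
    networks: list[NetworkSpec] | None = None,
    effects: list[GroupEffectSpec] | None = None,
    out_dir: str | Path | None = None,
    with_physio_traces: bool = True,
) -> Cohort:
    """Simulate the full two-group cohort; optionally write it to disk.

    On disk the layout is one NIfTI 4D file plus WM/CSF masks per subject,
    TSV physiological traces, a TSV subjects table, and a JSON manifest
    recording every seed.
    """
    if cfg is None:
        cfg = CohortConfig()
    if effects is None:
        effects = default_group_effects()
    grid = cfg.grid()
    atlas = make_network_atlas(networks, grid, radius_mm=cfg.node_radius_mm)
    brain = brain_mask(grid)

    subjects: list[SubjectRecord] = []
    manifest: dict = {"config": cfg.to_dict(), "subjects": []}
    labels = [("EDp", i) for i in range(cfg.n_EDp)] + [("HC", i) for i in range(cfg.n_HC)]
    for k, (group, i) in enumerate(labels):
        sid = f"{group}{i + 1:02d}"
        seed = int(
            np.random.SeedSequence([cfg.master_seed, 1000 + k]).generate_state(1)[0] % (2**31)
        )
        vol, wm, csf, truth = simulate_subject(
            atlas, effects, group, cfg, seed, subject_id=sid
        )
        physio = (
            simulate_physio(
                group, cfg, seed,
                tumescence_pct=truth.tumescence_pct,
                cardiac_rate_bpm=truth.cardiac_rate_bpm,
                resp_rate_hz=truth.resp_rate_hz,
            )
            if with_physio_traces
            else {}
        )
        score_rng = np.random.default_rng(np.random.SeedSequence([seed, _STAGE_SCORES]))
        scores = _subject_scores(group, truth, cfg, score_rng)
        subjects.append(
            SubjectRecord(sid, group, vol, wm, csf, physio, scores, truth)
        )
        manifest["subjects"].append({"subject_id": sid, "group": group, "seed": seed})

    cohort = Cohort(config=cfg, atlas=atlas, effects=list(effects), subjects=subjects, brain=brain)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for s in subjects:
            sdir = out / s.subject_id
            if sdir.exists():
                raise FileExistsError(f"output path collision: {sdir}")
            sdir.mkdir(parents=True)
            s.volume.save(sdir / "bold.nii")
            save_mask(s.wm_mask, grid, sdir / "wm_mask.nii")
            save_mask(s.csf_mask, grid, sdir / "csf_mask.nii")
            for kind, trace in s.physio.items():
                trace.save_tsv(sdir / f"{kind}.tsv")
        cohort.subjects_table().to_csv(out / "subjects.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return cohort
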