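"""Physiological signal reduction and group comparison.

Continuous traces (penile tumescence pressure, respiratory belt) arrive at
100 Hz; cardiac activity arrives as R-peak event times. Each is reduced to a
TR-locked series and a per-subject summary, then summaries are compared
between groups with a pooled-variance two-tailed t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PhysioTrace",
    "PhysioSummary",
    "tumescence_percent_change",
    "cardiac_rate",
    "respiratory_rate",
    "physio_group_test",
    "pooled_ttest_from_summaries",
]

CONTINUOUS_KINDS = {"tumescence", "respiratory"}
EVENT_KINDS = {"cardiac_events"}


@dataclass
class PhysioTrace:
    """One physiological recording.

    For continuous kinds, ``samples`` holds values at ``sampling_rate`` Hz
    starting at t = 0. For event kinds, ``samples`` holds strictly increasing
    event times in seconds.
    """

    kind: str
    samples: np.ndarray
    sampling_rate: float = 100.0
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.kind not in CONTINUOUS_KINDS | EVENT_KINDS:
            raise ValueError(f"unknown trace kind {self.kind!r}")
        if self.kind in CONTINUOUS_KINDS and self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.kind in EVENT_KINDS and np.any(np.diff(self.samples) <= 0):
            raise ValueError("event times must be strictly increasing")

    @property
    def duration_s(self) -> float:
        if self.kind in EVENT_KINDS:
            return float(self.samples[-1]) if self.samples.size else 0.0
        return self.samples.size / self.sampling_rate

    def to_frame(self) -> pd.DataFrame:
        if self.kind in EVENT_KINDS:
            return pd.DataFrame({"time_s": self.samples})
        t = np.arange(self.samples.size) / self.sampling_rate
        return pd.DataFrame({"time_s": t, "value": self.samples})

    def save_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def load_tsv(cls, path, kind: str, sampling_rate: float = 100.0,
                 units: str = "a.u.") -> "PhysioTrace":
        df = pd.read_csv(path, sep="\t")
        if kind in EVENT_KINDS:
            return cls(kind=kind, samples=df["time_s"].to_numpy(), units="events")
        return cls(kind=kind, samples=df["value"].to_numpy(),
                   sampling_rate=sampling_rate, units=units)


@dataclass
class PhysioSummary:
    subject_id: str
    tumescence_pct_mean: float
    cardiac_rate_bpm: float
    respiratory_rate_cpm: float


def _block_mean_downsample(x: np.ndarray, fs: float, tr_s: float, n_volumes: int) -> np.ndarray:
    """Average within consecutive TR-long blocks (anti-aliasing by block mean)."""
    per_tr = int(round(fs * tr_s))
    needed = per_tr * n_volumes
    if x.size < needed:
        raise ValueError(
            f"trace too short: {x.size} samples, need {needed} for "
            f"{n_volumes} volumes at TR={tr_s}s"
        )
    return x[:needed].reshape(n_volumes, per_tr).mean(axis=1)


def _remove_slope(y: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend while preserving the mean."""
    t = np.arange(y.size, dtype=float)
    tc = t - t.mean()
    slope = (y @ tc) / (tc @ tc)
    return y - slope * tc


def tumescence_percent_change(
    trace: PhysioTrace, tr_s: float, n_volumes: int, baseline_window_s: float = 10.0
) -> tuple[np.ndarray, float]:
    """TR-locked percent-change tumescence series and its run mean.

    The 100-Hz pressure trace is block-averaged to one value per TR, its
    linear trend removed (mean-preserving), and expressed as percent change
    relative to a baseline taken as the mean of the first ``baseline_window_s``
    seconds of the down-sampled raw trace (the cuff is inflated to a known
    pressure before acquisition, so the initial window is a stable reference).
    """
    if trace.kind != "tumescence":
        raise ValueError("expected a tumescence trace")
    ds = _block_mean_downsample(trace.samples, trace.sampling_rate, tr_s, n_volumes)
    n_base = max(1, int(round(baseline_window_s / tr_s)))
    baseline = float(ds[:n_base].mean())
    if baseline <= 0:
        raise ValueError(f"non-positive baseline pressure ({baseline:.3g})")
    detr = _remove_slope(ds)
    pct = 100.0 * (detr - baseline) / baseline
    return pct, float(pct.mean())


def _interp_to_tr(t_src: np.ndarray, v_src: np.ndarray, tr_s: float, n_volumes: int) -> np.ndarray:
    t_tr = (np.arange(n_volumes) + 0.5) * tr_s
    return np.interp(t_tr, t_src, v_src)


def cardiac_rate(trace: PhysioTrace, tr_s: float, n_volumes: int) -> tuple[np.ndarray, float]:
    """Instantaneous heart rate (beats/min) interpolated to the TR grid."""
    if trace.kind != "cardiac_events":
        raise ValueError("expected a cardiac event trace")
    ev = trace.samples
    if ev.size < 2:
        raise ValueError("need at least 2 R-peak events")
    ibi = np.diff(ev)
    rate = 60.0 / ibi
    mid = 0.5 * (ev[:-1] + ev[1:])
    series = _interp_to_tr(mid, rate, tr_s, n_volumes)
    return series, float(series.mean())


def respiratory_rate(
    trace: PhysioTrace, tr_s: float, n_volumes: int, smooth_s: float = 0.15
) -> tuple[np.ndarray, float]:
    """Respiratory cycle rate (cycles/min) from rising zero crossings.

    The belt trace is low-pass smoothed (zero-phase Gaussian, SD ``smooth_s``
    seconds, well below any plausible respiratory period) before crossing
    detection so that sensor noise near the zero line does not create
    spurious cycles.
    """
    if trace.kind != "respiratory":
        raise ValueError("expected a respiratory trace")
    x = trace.samples
    if smooth_s > 0:
        from scipy import ndimage

        x = ndimage.gaussian_filter1d(x, sigma=smooth_s * trace.sampling_rate)
    x = x - x.mean()
    rising = np.nonzero((x[:-1] < 0) & (x[1:] >= 0))[0]
    if rising.size < 2:
        raise ValueError("no complete respiratory cycle in trace")
    # Sub-sample linear interpolation of each crossing time.
    frac = -x[rising] / (x[rising + 1] - x[rising])
    t_cross = (rising + frac) / trace.sampling_rate
    periods = np.diff(t_cross)
    rate = 60.0 / periods
    mid = 0.5 * (t_cross[:-1] + t_cross[1:])
    series = _interp_to_tr(mid, rate, tr_s, n_volumes)
    return series, float(series.mean())


def pooled_ttest_from_summaries(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Classical two-sample pooled-variance t from printed summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        if mean1 == mean2:
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t = (mean1 - mean2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def physio_group_test(values_edp, values_hc) -> tuple[float, float]:
    """Two-tailed pooled-variance t-test comparing EDp against HC."""
    a = np.asarray(values_edp, dtype=float)
    b = np.asarray(values_hc, dtype=float)
    return pooled_ttest_from_summaries(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )
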