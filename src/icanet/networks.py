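"""Canonical intrinsic connectivity network (ICN) node tables.

Four networks (DMN, FPN, SN, VN) carry the node peaks observed for this
paradigm; the remaining three (AN, CEN, SMN) use conventional literature
coordinates and serve as negative controls for template matching.
Coordinates are stereotaxic mm (x: left-right, y: anterior-posterior,
z: dorsal-ventral).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "NodeSpec",
    "NetworkSpec",
    "GroupEffectSpec",
    "default_networks",
    "default_group_effects",
    "PLANTED_NETWORKS",
    "ALL_NETWORK_NAMES",
]

VALID_NETWORK_NAMES = {"DMN", "SN", "FPN", "VN", "AN", "CEN", "SMN"}


@dataclass(frozen=True)
class NodeSpec:
    """A single network node: a named peak with an isotropic extent."""

    name: str
    hemisphere: str  # {"L", "R", "midline"}
    peak_mm: tuple[float, float, float]
    radius_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"node {self.name}: radius_mm must be positive")
        if self.hemisphere not in {"L", "R", "midline"}:
            raise ValueError(f"node {self.name}: bad hemisphere {self.hemisphere!r}")


@dataclass(frozen=True)
class NetworkSpec:
    name: str
    nodes: tuple[NodeSpec, ...]
    timecourse_seed: int = 0

    def __post_init__(self) -> None:
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError(f"network {self.name}: duplicate node names")

    def node(self, name: str) -> NodeSpec:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(f"network {self.name} has no node {name!r}")


@dataclass(frozen=True)
class GroupEffectSpec:
    """Group-specific multiplier on one node's loading (default 1 = no effect)."""

    network: str
    node: str
    loading_multiplier_EDp: float = 1.0
    loading_multiplier_HC: float = 1.0

    def __post_init__(self) -> None:
        for m in (self.loading_multiplier_EDp, self.loading_multiplier_HC):
            if not (m >= 0 and m == m and m != float("inf")):
                raise ValueError("loading multipliers must be finite and nonnegative")

    def multiplier(self, group: str) -> float:
        if group == "EDp":
            return self.loading_multiplier_EDp
        if group == "HC":
            return self.loading_multiplier_HC
        raise ValueError(f"unknown group {group!r}")


def _n(name, hemi, x, y, z, r=8.0):
    return NodeSpec(name=name, hemisphere=hemi, peak_mm=(float(x), float(y), float(z)), radius_mm=r)


def default_networks(radius_mm: float = 8.0) -> list[NetworkSpec]:
    """The seven ICNs used for template matching and simulation."""
    r = radius_mm
    return [
        NetworkSpec("DMN", (
            _n("IPL_SMG_R", "R", 50, -59, 24, r),
            _n("mPFC", "L", -4, 49, 21, r),
            _n("PCC", "L", -1, -53, 21, r),
            _n("IPL_L", "L", -49, -62, 27, r),
            _n("IFG_L", "L", -43, 19, -6, r),
        ), timecourse_seed=11),
        NetworkSpec("FPN", (
            _n("SPL_IPS_R", "R", 38, -62, 48, r),
            _n("MFG_R", "R", 44, 7, 42, r),
            _n("PCUN_R", "R", 2, -65, 36, r),
            _n("AFC_R", "R", 32, 52, 9, r),
            _n("ITG_R", "R", 59, -35, -3, r),
            _n("ATP_L", "L", -46, -13, -15, r),
            _n("MFG_L", "L", -28, 10, 51, r),
            _n("SPL_L", "L", -43, -59, 39, r),
        ), timecourse_seed=12),
        NetworkSpec("SN", (
            _n("AI_IFG_R", "R", 44, 13, 0, r),
            _n("AI_L", "L", -43, 10, 0, r),
            _n("SFG_R", "R", 29, 49, 27, r),
            _n("dACC", "R", 2, 31, 30, r),
            _n("MPCC_L", "L", 1, -23, 27, r),
            _n("SFG_L", "L", -7, 19, 57, r),
            _n("MFG_L", "L", -31, 46, 30, r),
        ), timecourse_seed=13),
        NetworkSpec("VN", (
            # The visual cortex node spans BA 17/18/19, hence the larger extent.
            _n("VC", "R", 2, -71, 3, 1.5 * r),
        ), timecourse_seed=14),
        # Conventional coordinates; not planted by the default cohort.
        NetworkSpec("AN", (
            _n("STG_R", "R", 52, -20, 8, r),
            _n("STG_L", "L", -50, -22, 8, r),
        ), timecourse_seed=15),
        NetworkSpec("CEN", (
            _n("dlPFC_R", "R", 42, 32, 28, r),
            _n("dlPFC_L", "L", -42, 30, 28, r),
            _n("PAR_R", "R", 44, -40, 44, r),
            _n("PAR_L", "L", -44, -38, 44, r),
        ), timecourse_seed=16),
        NetworkSpec("SMN", (
            _n("PreCG_R", "R", 38, -24, 54, r),
            _n("PreCG_L", "L", -38, -26, 52, r),
            _n("SMA", "midline", 0, -14, 52, r),
        ), timecourse_seed=17),
    ]


# The four networks the default synthetic cohort plants in the data.
PLANTED_NETWORKS = ("DMN", "FPN", "SN", "VN")
ALL_NETWORK_NAMES = ("DMN", "FPN", "SN", "VN", "AN", "CEN", "SMN")


def default_group_effects() -> list[GroupEffectSpec]:
    """Planted group differences: patient deficits at three default-mode
    nodes and the right anterior insula, and a patient excess at the dorsal
    anterior cingulate."""
    return [
        GroupEffectSpec("DMN", "mPFC", loading_multiplier_EDp=0.6),
        GroupEffectSpec("DMN", "PCC", loading_multiplier_EDp=0.6),
        GroupEffectSpec("DMN", "IPL_L", loading_multiplier_EDp=0.6),
        GroupEffectSpec("SN", "AI_IFG_R", loading_multiplier_EDp=0.6),
        GroupEffectSpec("SN", "dACC", loading_multiplier_EDp=1.4),
    ]
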