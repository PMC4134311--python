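"""Template matching and cross-subject component clustering.

Subjects' independent components are identified against network templates by
spatial cross-correlation, and aggregated across subjects by a
self-organising clustering of mutual spatial similarities: average-linkage
agglomeration on distance 1 - |r| under the constraint that no cluster holds
two components of the same subject. The procedure is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ica import ICDecomposition
from .synthdata import NetworkAtlas
from .volume import Grid

__all__ = [
    "NetworkTemplate",
    "ICCluster",
    "TemplateMatch",
    "spatial_correlation",
    "match_templates",
    "sogica_cluster",
    "subject_network_zmaps",
    "templates_from_atlas",
]


@dataclass
class NetworkTemplate:
    name: str
    map: np.ndarray  # flattened over in-mask voxels
    provenance: str = ""

    def __post_init__(self) -> None:
        self.map = np.asarray(self.map, dtype=np.float64)
        if not np.any(self.map):
            raise ValueError(f"template {self.name} is all-zero")


def templates_from_atlas(atlas: NetworkAtlas, mask: np.ndarray) -> list[NetworkTemplate]:
    """Synthesise network templates from the atlas node tables."""
    return [
        NetworkTemplate(
            name=net.name,
            map=atlas.maps[net.name][mask],
            provenance="synthesised from node peak table (Gaussian bumps)",
        )
        for net in atlas.networks
    ]


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("zero-variance map in spatial correlation")
    return x / sd


def spatial_correlation(map_a: np.ndarray, map_b: np.ndarray,
                        mask: np.ndarray | None = None) -> float:
    """Pearson correlation of two maps over in-mask voxels."""
    a, b = np.asarray(map_a), np.asarray(map_b)
    if mask is not None:
        a, b = a[mask], b[mask]
    if a.shape != b.shape:
        raise ValueError("maps do not share a grid")
    a, b = _standardize(a), _standardize(b)
    return float((a * b).mean())


@dataclass
class TemplateMatch:
    template: str
    component: int | None  # index into the candidate maps; None = absent
    r: float  # signed correlation of the (possibly flipped) best candidate
    sign: int = 1


def match_templates(
    candidate_maps: np.ndarray | ICDecomposition,
    templates: list[NetworkTemplate],
    r_min: float = 0.25,
) -> dict[str, TemplateMatch]:
    """Assign each template its best-matching candidate map by |r|.

    Greedy one-to-one assignment in descending |r| order (ties broken by
    lower component index); candidates are sign-aligned so the reported r is
    positive. Templates whose best remaining |r| falls below ``r_min`` are
    reported absent.
    """
    if isinstance(candidate_maps, ICDecomposition):
        candidate_maps = candidate_maps.spatial_maps
    M = np.asarray(candidate_maps, dtype=np.float64)
    if M.ndim != 2:
        raise ValueError("candidate_maps must be (components x voxels)")
    Mz = M - M.mean(axis=1, keepdims=True)
    sd = Mz.std(axis=1)
    sd[sd == 0] = np.inf  # zero-variance candidates can never match
    Mz = Mz / sd[:, None]
    T = np.vstack([_standardize(t.map) for t in templates])
    R = (T @ Mz.T) / M.shape[1]  # (templates, components)

    order = sorted(
        ((abs(R[ti, ci]), -ti, -ci) for ti in range(len(templates)) for ci in range(M.shape[0])),
        reverse=True,
    )
    taken_t: set[int] = set()
    taken_c: set[int] = set()
    result = {
        t.name: TemplateMatch(template=t.name, component=None, r=0.0)
        for t in templates
    }
    for absr, neg_ti, neg_ci in order:
        ti, ci = -neg_ti, -neg_ci
        if absr < r_min:
            break
        if ti in taken_t or ci in taken_c:
            continue
        taken_t.add(ti)
        taken_c.add(ci)
        sign = 1 if R[ti, ci] >= 0 else -1
        result[templates[ti].name] = TemplateMatch(
            template=templates[ti].name, component=ci, r=float(absr), sign=sign
        )
    return result


@dataclass
class ICCluster:
    """One cross-subject cluster of components."""

    members: list[tuple[str, int, int]]  # (subject_id, component index, sign)
    mean_map: np.ndarray
    mean_similarity: float  # mean pairwise |r| among members
    matched_template: str | None = None
    template_r: float = 0.0

    @property
    def subjects(self) -> set[str]:
        return {m[0] for m in self.members}


def _pairwise_abs_corr(M: np.ndarray) -> np.ndarray:
    Mz = M - M.mean(axis=1, keepdims=True)
    sd = Mz.std(axis=1)
    sd[sd == 0] = np.inf
    Mz = (Mz / sd[:, None]).astype(np.float32)
    R = (Mz @ Mz.T) / np.float32(M.shape[1])
    return np.abs(np.clip(R, -1.0, 1.0)).astype(np.float64)


def sogica_cluster(
    subject_ics: list[tuple[str, ICDecomposition]],
    n_clusters: int | None = None,
) -> list[ICCluster]:
    """Cluster all subjects' component maps by mutual spatial similarity.

    Average-linkage agglomeration on distance 1 - |r|, skipping any merge
    that would put two components of the same subject in one cluster, until
    ``n_clusters`` remain (default: the per-subject component count) or no
    allowed merge is left. Members are sign-aligned to the cluster mean and
    the cluster map is the voxel-wise mean of the aligned Z maps.
    """
    if len(subject_ics) < 1:
        raise ValueError("need at least one subject")
    per_subject = subject_ics[0][1].n_components
    if n_clusters is None:
        n_clusters = per_subject
    if n_clusters > sum(d.n_components for _, d in subject_ics):
        raise ValueError("n_clusters exceeds the number of components")

    items: list[tuple[str, int]] = []
    maps: list[np.ndarray] = []
    for sid, decomp in sorted(subject_ics, key=lambda x: x[0]):
        for ci in range(decomp.n_components):
            items.append((sid, ci))
            maps.append(decomp.spatial_maps[ci])
    M = np.asarray(maps)
    n = len(items)
    if len(subject_ics) == 1:
        # Degenerate case: each component is its own singleton cluster.
        return [
            ICCluster(members=[(sid, ci, 1)], mean_map=M[i].copy(), mean_similarity=1.0)
            for i, (sid, ci) in enumerate(items)
        ]

    absR = _pairwise_abs_corr(M)
    D = 1.0 - absR
    np.fill_diagonal(D, np.inf)

    clusters: list[list[int] | None] = [[i] for i in range(n)]
    subj_sets: list[set[str] | None] = [{items[i][0]} for i in range(n)]
    sizes = np.ones(n)
    active = np.ones(n, dtype=bool)
    n_active = n
    while n_active > n_clusters:
        i, j = np.unravel_index(np.argmin(D), D.shape)
        if not np.isfinite(D[i, j]):
            warnings.warn(
                f"no allowed merges left at {n_active} clusters "
                f"(requested {n_clusters})"
            )
            break
        if subj_sets[i] & subj_sets[j]:
            D[i, j] = D[j, i] = np.inf  # constrained out, try next-closest pair
            continue
        i, j = (i, j) if i < j else (j, i)
        # Weighted average linkage: distances to the merged cluster.
        new_row = (sizes[i] * D[i] + sizes[j] * D[j]) / (sizes[i] + sizes[j])
        # Preserve constraint marks against the union of subjects.
        D[i] = new_row
        D[:, i] = new_row
        D[i, i] = np.inf
        D[j, :] = np.inf
        D[:, j] = np.inf
        clusters[i] = clusters[i] + clusters[j]
        subj_sets[i] = subj_sets[i] | subj_sets[j]
        sizes[i] += sizes[j]
        clusters[j] = None
        subj_sets[j] = None
        active[j] = False
        n_active -= 1

    out: list[ICCluster] = []
    for idx in range(n):
        if clusters[idx] is None:
            continue
        member_idx = sorted(clusters[idx])
        sub = M[member_idx]
        # Sign-align to the first (lexicographically lowest) member, then to
        # the running mean, which is deterministic.
        ref = sub[0]
        signs = []
        for row in sub:
            c = float((row - row.mean()) @ (ref - ref.mean()))
            signs.append(1 if c >= 0 else -1)
        aligned = sub * np.asarray(signs)[:, None]
        mean_map = aligned.mean(axis=0)
        if len(member_idx) > 1:
            block = absR[np.ix_(member_idx, member_idx)]
            msim = float(block[np.triu_indices(len(member_idx), k=1)].mean())
        else:
            msim = 1.0
        out.append(
            ICCluster(
                members=[
                    (items[k][0], items[k][1], s)
                    for k, s in zip(member_idx, signs)
                ],
                mean_map=mean_map,
                mean_similarity=msim,
            )
        )
    # Stable order: largest first, ties by first member.
    out.sort(key=lambda c: (-len(c.members), c.members[0][:2]))
    return out


def subject_network_zmaps(
    clusters: list[ICCluster],
    templates: list[NetworkTemplate],
    subject_ics: list[tuple[str, ICDecomposition]],
    r_min: float = 0.25,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-network, per-subject sign-aligned Z maps (input to group stats).

    Cluster mean maps are matched one-to-one against the templates; for each
    matched cluster every member subject contributes its sign-aligned map.
    Subjects missing from a matched cluster are recorded absent with a
    warning and excluded from that network's statistics.
    """
    if not clusters:
        return {}
    cluster_maps = np.vstack([c.mean_map for c in clusters])
    matches = match_templates(cluster_maps, templates, r_min=r_min)
    decomp_by_sid = dict(subject_ics)
    all_sids = sorted(decomp_by_sid)

    out: dict[str, dict[str, np.ndarray]] = {}
    for tname, m in matches.items():
        if m.component is None:
            continue
        cl = clusters[m.component]
        cl.matched_template = tname
        cl.template_r = m.r
        per_subject: dict[str, np.ndarray] = {}
        for sid, ci, sign in cl.members:
            zmap = decomp_by_sid[sid].spatial_maps[ci] * (sign * m.sign)
            per_subject[sid] = zmap
        missing = set(all_sids) - set(per_subject)
        if missing:
            warnings.warn(
                f"network {tname}: no component for subject(s) "
                f"{sorted(missing)}; excluded from group statistics"
            )
        out[tname] = per_subject
    return out
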