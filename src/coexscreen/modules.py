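"""Module detection: clustering, dynamic tree cut, hub proteins, traits, stability.

Proteins are clustered hierarchically on the TOM dissimilarity (average
linkage by default) and the dendrogram is trimmed into modules with a dynamic
hybrid tree cut: branches are accepted as modules when they are large enough,
internally tight, and separated from their surroundings by a visible height
gap, and leftover objects are then assigned to the nearest module if they fit
within it.  Each module is summarized by its hub ("eigen") protein — the
member with the highest intramodular connectivity — whose profile is
correlated with binary clinical traits.  Module reproducibility is scored by
bootstrap resampling of samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform

from .io import AbundanceMatrix, TraitDesign
from .network import Adjacency, adjacency, pearson_matrix, tom, tom_dissimilarity

logger = logging.getLogger(__name__)

#: Branch-acceptance constants per deep-split level 0..4.  Higher levels relax
#: the core-scatter ceiling (standard hybrid-cut defaults, interpolated over
#: the dendrogram height range) and the normalized-gap floor, producing more
#: and smaller modules.
MAX_CORE_SCATTER = (0.64, 0.73, 0.82, 0.91, 0.95)
#: Minimum normalized separation (join height minus core scatter, as a
#: fraction of the dendrogram height span) for a branch to count as distinct
#: from its sibling.
MIN_NORM_GAP = (0.80, 0.75, 0.70, 0.65, 0.60)


@dataclass
class Dendrogram:
    """Agglomerative clustering tree in scipy linkage form."""

    leaf_ids: list[str]
    merges: np.ndarray  # (n-1, 4) scipy linkage matrix, heights non-decreasing
    linkage: str

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass
class ModulePartition:
    """Protein -> module assignment; label 0 means unassigned.

    Modules are numbered by decreasing size and named WM1..WMn.  The eigen
    protein of a module is its top hub (filled by
    :func:`assign_eigen_proteins`).
    """

    protein_ids: list[str]
    labels: np.ndarray
    min_module_size: int
    deep_split: int
    eigen_proteins: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.protein_ids):
            raise ValueError("labels length mismatch")

    @property
    def module_labels(self) -> list[int]:
        """Non-zero labels ordered by decreasing module size (1, 2, ...)."""
        return sorted(set(self.labels) - {0})

    @property
    def module_names(self) -> dict[int, str]:
        return {lab: f"WM{lab}" for lab in self.module_labels}

    def members(self, label: int) -> list[str]:
        return [p for p, l in zip(self.protein_ids, self.labels) if l == label]

    def sizes(self) -> dict[int, int]:
        return {lab: int((self.labels == lab).sum()) for lab in self.module_labels}

    def to_frame(self) -> pd.DataFrame:
        names = self.module_names
        return pd.DataFrame(
            {
                "protein_id": self.protein_ids,
                "module_label": self.labels,
                "module_name": [names.get(l, "") for l in self.labels],
                "is_eigen": [
                    self.eigen_proteins.get(l) == p
                    for p, l in zip(self.protein_ids, self.labels)
                ],
            }
        )


@dataclass
class StabilityReport:
    module_labels: list[int]
    scores: dict[int, float]
    n_resamples: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "module_label": self.module_labels,
                "stability": [self.scores[l] for l in self.module_labels],
            }
        )


def hierarchical_cluster(
    d: np.ndarray, leaf_ids: list[str], linkage: str = "complete"
) -> Dendrogram:
    """Agglomerative clustering of a square symmetric dissimilarity matrix."""
    d = np.asarray(d, dtype=float)
    if np.isnan(d).any():
        raise ValueError("NaN in dissimilarity matrix")
    if d.shape[0] != d.shape[1] or d.shape[0] != len(leaf_ids):
        raise ValueError("dissimilarity shape does not match leaf ids")
    if linkage not in ("complete", "average"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    condensed = squareform(np.clip((d + d.T) / 2.0, 0.0, None), checks=False)
    Z = scipy_linkage(condensed, method=linkage)
    return Dendrogram(list(leaf_ids), Z, linkage)


def cluster_samples(m: AbundanceMatrix, linkage: str = "complete") -> Dendrogram:
    """Cluster samples by Euclidean distance between their abundance profiles."""
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = squareform(pdist(m.values.T, metric="euclidean"))
    return hierarchical_cluster(d, m.sample_ids, linkage)


class _Branch:
    __slots__ = ("members", "attach", "composite")

    def __init__(self, members, attach, composite=False):
        self.members = members  # leaf indices
        self.attach = attach  # height at which each member attached
        self.composite = composite

    @property
    def size(self) -> int:
        return len(self.members)


def _core_size(n: int, min_module_size: int) -> int:
    base = min_module_size / 2.0 + 1.0
    if base >= n:
        return n
    return int(base + math.sqrt(n - base))


def _core_scatter(br: _Branch, min_module_size: int) -> float:
    """Mean attachment height of the branch core (its earliest joiners)."""
    if not br.attach:
        return 0.0
    cs = _core_size(br.size, min_module_size)
    return float(np.mean(sorted(br.attach)[:cs]))


def dynamic_tree_cut(
    dend: Dendrogram,
    d: np.ndarray,
    min_module_size: int = 5,
    deep_split: int = 4,
    cut_height: float | None = None,
) -> ModulePartition:
    """Dynamic hybrid cut of a dendrogram into modules.

    Stage 1 walks the merges bottom-up.  When two branches join at height h,
    each is accepted as a module if it has at least ``min_module_size``
    members, its core scatter (mean attachment height of its earliest
    joiners) is below a ceiling interpolated between the 5th-percentile
    merge height and ``cut_height``, and it is separated from the join by a
    minimum *normalized* gap: (h - scatter) as a fraction of the dendrogram
    height span, i.e. the join must sit well above the branch core on the
    scale of the whole tree.
    Both criteria are indexed by ``deep_split`` (0-4); higher values accept
    looser, less separated branches, so modules become more numerous and
    smaller.  When a join is rejected the larger branch absorbs the smaller
    (whose members attach at h) and keeps growing; members attached above
    the scatter ceiling are trimmed from accepted modules; branches still
    open at the top are accepted on size and scatter alone.

    Stage 2 assigns each leftover object to the module with the smallest
    average dissimilarity to its members, provided that distance is within
    the module's assignment radius: halfway between the module's internal
    level (mean member-to-module dissimilarity) and the matrix-wide mean
    dissimilarity.  Remaining objects keep label 0.  Labels are renumbered
    by decreasing module size.
    """
    n = len(dend.leaf_ids)
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be in 0..4")
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    if min_module_size > n:
        raise ValueError(f"min_module_size {min_module_size} exceeds {n} leaves")
    d = np.asarray(d, dtype=float)

    Z = dend.merges
    heights = Z[:, 2]
    if cut_height is None:
        cut_height = float(heights.max())
    ref = float(np.quantile(heights, 0.05))
    span = max(cut_height - ref, 0.0)
    max_abs_scatter = ref + MAX_CORE_SCATTER[deep_split] * span
    min_norm_gap = MIN_NORM_GAP[deep_split]

    def qualifies(br: _Branch, join_height: float | None) -> bool:
        if br.composite or br.size < min_module_size:
            return False
        scatter = _core_scatter(br, min_module_size)
        if scatter > max_abs_scatter:
            return False
        if join_height is not None:
            if span <= 0:
                return False
            if (join_height - scatter) / span < min_norm_gap:
                return False
        return True

    def freeze(br: _Branch) -> None:
        kept = [m for m, a in zip(br.members, br.attach) if a <= max_abs_scatter]
        if len(kept) >= min_module_size:
            frozen.append(kept)

    node: dict[int, _Branch] = {i: _Branch([i], [0.0]) for i in range(n)}
    frozen: list[list[int]] = []

    for step in range(n - 1):
        left, right, h = int(Z[step, 0]), int(Z[step, 1]), float(heights[step])
        a, b = node.pop(left), node.pop(right)
        if h > cut_height:
            # join above the cut: close both sides separately
            for br in (a, b):
                if qualifies(br, None):
                    freeze(br)
            node[n + step] = _Branch([], [], composite=True)
            continue
        qa, qb = qualifies(a, h), qualifies(b, h)
        if a.composite or b.composite or (qa and qb):
            for br, q in ((a, qa), (b, qb)):
                if q:
                    freeze(br)
            node[n + step] = _Branch([], [], composite=True)
        elif qa != qb:
            # one side is a distinct module, the other is not: emit the
            # module and let the other branch keep growing on its own
            freeze(a if qa else b)
            node[n + step] = b if qa else a
        else:
            big, small = (a, b) if a.size >= b.size else (b, a)
            # singleton pairs attach at their joint height; an absorbed
            # branch attaches wholesale at h
            if big.size == 1:
                node[n + step] = _Branch(big.members + small.members, [h, h])
            else:
                node[n + step] = _Branch(
                    big.members + small.members,
                    big.attach + [h] * small.size,
                )

    for br in node.values():
        if qualifies(br, None):
            freeze(br)

    labels = np.zeros(n, dtype=int)
    for lab, members in enumerate(frozen, start=1):
        labels[members] = lab

    # stage 2: nearest-module assignment of leftover objects, iterated so a
    # module's radius grows as genuine members are recovered.  The radius
    # sits three quarters of the way from the module's internal
    # dissimilarity level to the matrix-wide mean, so joiners must look
    # clearly more like the module than like an arbitrary object.
    if frozen:
        d_bar = float(d.sum() / (n * (n - 1))) if n > 1 else 0.0
        module_labels = sorted(set(labels) - {0})
        for _ in range(5):
            changed = 0
            member_idx = [np.flatnonzero(labels == lab) for lab in module_labels]
            mean_to_module = np.stack(
                [d[:, mem].mean(axis=1) for mem in member_idx], axis=1
            )
            radii = []
            for mem in member_idx:
                sub = d[np.ix_(mem, mem)]
                level = float((sub.sum(axis=1) / max(len(mem) - 1, 1)).mean())
                radii.append(level + 0.75 * max(d_bar - level, 0.0))
            radii = np.asarray(radii)
            for i in np.flatnonzero(labels == 0):
                k = int(np.argmin(mean_to_module[i]))
                if mean_to_module[i, k] <= radii[k]:
                    labels[i] = module_labels[k]
                    changed += 1
            if changed == 0:
                break

    # renumber by decreasing size (ties by previous label for determinism)
    sizes = [(lab, int((labels == lab).sum())) for lab in sorted(set(labels) - {0})]
    sizes.sort(key=lambda t: (-t[1], t[0]))
    remap = {old: new for new, (old, _) in enumerate(sizes, start=1)}
    labels = np.array([remap.get(l, 0) for l in labels], dtype=int)

    return ModulePartition(list(dend.leaf_ids), labels, min_module_size, deep_split)


def assign_eigen_proteins(p: ModulePartition, a: Adjacency) -> ModulePartition:
    """Pick each module's eigen protein: the hub with top intramodular connectivity.

    Ties are broken by the lexicographically smallest protein id.
    """
    idx = {pid: i for i, pid in enumerate(a.protein_ids)}
    for lab in p.module_labels:
        members = p.members(lab)
        rows = [idx[m] for m in members]
        sub = a.a[np.ix_(rows, rows)]
        k_in = sub.sum(axis=1)
        top = k_in.max()
        p.eigen_proteins[lab] = min(m for m, k in zip(members, k_in) if k == top)
    return p


def module_trait_correlation(
    p: ModulePartition, m: AbundanceMatrix, t: TraitDesign
) -> pd.DataFrame:
    """Pearson correlation of each eigen protein's profile with binary traits.

    Returns a long-format table (module, trait, r, p); p-values come from the
    t distribution with n_samples - 2 degrees of freedom, two-sided.  Modules
    whose eigen profile is constant get NaN with a warning.
    """
    if not p.eigen_proteins:
        raise ValueError("eigen proteins not assigned; run assign_eigen_proteins first")
    tm = t.trait_matrix.loc[m.sample_ids]
    ridx = {pid: i for i, pid in enumerate(m.protein_ids)}
    rows = []
    names = p.module_names
    for lab in p.module_labels:
        profile = m.values[ridx[p.eigen_proteins[lab]]]
        for trait in tm.columns:
            y = tm[trait].to_numpy(dtype=float)
            if profile.std() == 0 or y.std() == 0:
                logger.warning("constant profile/trait for module %s", names[lab])
                r_val, p_val = float("nan"), float("nan")
            else:
                res = stats.pearsonr(profile, y)
                r_val, p_val = float(res.statistic), float(res.pvalue)
            rows.append(
                {"module": names[lab], "trait": trait, "r": r_val, "p": p_val}
            )
    return pd.DataFrame(rows)


def grow_modules_by_membership(
    p: ModulePartition,
    m: AbundanceMatrix,
    threshold: float = 0.5,
    max_iter: int = 8,
) -> ModulePartition:
    """Grow modules by module-membership correlation (kME).

    Each unassigned protein joins the module whose summary profile (the
    normalized mean of its members' standardized profiles) it correlates
    with most strongly, provided |kME| >= ``threshold`` (0.5 is the
    customary module-membership cutoff).  Iterated until no protein moves,
    since memberships sharpen as modules grow.  Assigned labels from the
    tree cut are never revoked.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    idx = {pid: i for i, pid in enumerate(m.protein_ids)}
    rows = np.array([idx[pid] for pid in p.protein_ids])
    X = m.values[rows]
    sd = X.std(axis=1)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    mods = p.module_labels
    if not mods:
        return p
    labels = p.labels
    for _ in range(max_iter):
        kme = np.empty((len(labels), len(mods)))
        for k, lab in enumerate(mods):
            mem = np.flatnonzero(labels == lab)
            prof = Xs[mem].mean(axis=0)
            norm = np.sqrt((prof**2).mean())
            prof = prof / norm if norm > 0 else prof
            kme[:, k] = (Xs * prof).mean(axis=1)
        ak = np.abs(kme)
        changed = 0
        for i in np.flatnonzero(labels == 0):
            k = int(np.argmax(ak[i]))
            if ak[i, k] >= threshold:
                labels[i] = mods[k]
                changed += 1
        if changed == 0:
            break
    # renumber by decreasing size after growth
    sizes = [(lab, int((labels == lab).sum())) for lab in sorted(set(labels) - {0})]
    sizes.sort(key=lambda t: (-t[1], t[0]))
    remap = {old: new for new, (old, _) in enumerate(sizes, start=1)}
    p.labels = np.array([remap.get(l, 0) for l in labels], dtype=int)
    p.eigen_proteins = {}
    return p


def detect_modules(
    m: AbundanceMatrix,
    power: int = 10,
    network_type: str = "unsigned",
    min_module_size: int = 5,
    deep_split: int = 4,
    linkage: str = "average",
    kme_threshold: float | None = 0.5,
) -> tuple[ModulePartition, Adjacency]:
    """Full module-detection chain.

    Correlation -> soft-threshold adjacency -> TOM -> hierarchical
    clustering -> dynamic hybrid cut -> kME membership growth (skipped when
    ``kme_threshold`` is None) -> hub (eigen) protein assignment.
    """
    c = pearson_matrix(m)
    a = adjacency(c, power, network_type)
    dis = tom_dissimilarity(tom(a))
    dend = hierarchical_cluster(dis, a.protein_ids, linkage)
    part = dynamic_tree_cut(dend, dis, min_module_size, deep_split)
    if kme_threshold is not None:
        grow_modules_by_membership(part, m.subset_proteins(a.protein_ids), kme_threshold)
    assign_eigen_proteins(part, a)
    return part, a


def _jaccard(s1: set, s2: set) -> float:
    inter = len(s1 & s2)
    return inter / (len(s1) + len(s2) - inter) if (s1 or s2) else 0.0


def module_stability(
    m: AbundanceMatrix,
    power: int = 10,
    network_type: str = "unsigned",
    min_module_size: int = 5,
    deep_split: int = 4,
    linkage: str = "average",
    n_resamples: int = 10,
    seed: int = 0,
    reference: ModulePartition | None = None,
) -> StabilityReport:
    """Bootstrap stability of detected modules.

    Samples are drawn with replacement (same n) and the whole network +
    tree-cut chain is rerun; each reference module scores its best Jaccard
    overlap against any resample module, averaged over resamples.  Fully
    deterministic for a fixed seed.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if reference is None:
        reference, _ = detect_modules(
            m, power, network_type, min_module_size, deep_split, linkage
        )
    ref_sets = {lab: set(reference.members(lab)) for lab in reference.module_labels}
    rng = np.random.default_rng(seed)
    totals = {lab: 0.0 for lab in ref_sets}
    for _ in range(n_resamples):
        take = rng.integers(0, m.n_samples, size=m.n_samples)
        boot = AbundanceMatrix(
            m.protein_ids,
            [f"b{j}" for j in range(m.n_samples)],
            m.values[:, take],
            m.value_kind,
        )
        part, _ = detect_modules(
            boot, power, network_type, min_module_size, deep_split, linkage
        )
        boot_sets = [set(part.members(lab)) for lab in part.module_labels]
        for lab, ref in ref_sets.items():
            best = max((_jaccard(ref, bs) for bs in boot_sets), default=0.0)
            totals[lab] += best
    scores = {lab: totals[lab] / n_resamples for lab in ref_sets}
    return StabilityReport(list(ref_sets), scores, n_resamples, seed)
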