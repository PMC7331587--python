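"""Weighted co-expression network construction.

The network is built in the usual WGCNA way: pairwise Pearson correlation of
protein profiles across samples, soft-thresholded into a weighted adjacency
a_ij = |r_ij|**beta (unsigned; a signed variant ((1+r)/2)**beta is available),
with beta chosen so node connectivity approximately follows a power law
("scale-free topology").  The topological overlap matrix (TOM) then measures
how much two proteins share network neighbours, which is far more robust to
single noisy edges than the raw adjacency; 1 - TOM is the clustering
dissimilarity used downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import AbundanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    protein_ids: list[str]
    r: np.ndarray  # symmetric, diag 1, entries in [-1, 1]


@dataclass
class Adjacency:
    protein_ids: list[str]
    a: np.ndarray  # symmetric, diag 0, entries in [0, 1]
    power: int
    network_type: str = "unsigned"

    @property
    def connectivity(self) -> np.ndarray:
        """Node connectivity k_i = sum_j a_ij (diagonal is zero)."""
        return self.a.sum(axis=1)


@dataclass
class TOMatrix:
    protein_ids: list[str]
    t: np.ndarray  # symmetric, diag 1, entries in [0, 1]


@dataclass
class SoftThresholdScan:
    powers: list[int]
    fit_index: list[float]
    mean_connectivity: list[float]
    selected_power: int
    r2_threshold: float = 0.90
    threshold_met: bool = True

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "power": self.powers,
                "fit_index": self.fit_index,
                "mean_connectivity": self.mean_connectivity,
            }
        )


def pearson_matrix(m: AbundanceMatrix) -> CorrelationMatrix:
    """Pairwise Pearson correlation of protein profiles across samples.

    Proteins with zero variance across samples carry no correlation
    information and are excluded (with a logged warning naming them).
    """
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples for correlation")
    sd = m.values.std(axis=1)
    keep = sd > 0
    dropped = [p for p, k in zip(m.protein_ids, keep) if not k]
    if dropped:
        logger.warning("excluding %d zero-variance proteins: %s", len(dropped), dropped[:10])
    vals = m.values[keep]
    ids = [p for p, k in zip(m.protein_ids, keep) if k]
    r = np.corrcoef(vals)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(ids, r)


def adjacency(c: CorrelationMatrix, power: int, network_type: str = "unsigned") -> Adjacency:
    """Soft-threshold the correlation into a weighted adjacency.

    unsigned: a_ij = |r_ij|**power;  signed: a_ij = ((1 + r_ij)/2)**power.
    The diagonal is set to 0 so connectivity sums exclude self-edges.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    if network_type == "unsigned":
        a = np.abs(c.r) ** power
    elif network_type == "signed":
        a = ((1.0 + c.r) / 2.0) ** power
    else:
        raise ValueError(f"unknown network_type {network_type!r}")
    np.fill_diagonal(a, 0.0)
    return Adjacency(c.protein_ids, a, int(power), network_type)


def scale_free_fit_index(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit of a connectivity sequence.

    Connectivities are grouped into ``n_bins`` equal-occupancy bins; the
    log10 empirical density per bin (bin count / (n * bin width)) is
    regressed on the log10 mean connectivity per bin.  Returns
    R**2 * -sign(slope), so a decaying power law scores near +1.  Degenerate
    sequences (fewer than 3 usable bins) score 0.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size == 0:
        raise ValueError("all connectivities are zero")
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < 4:
        return 0.0
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, edges.size - 2)
    xs, ys = [], []
    for b in range(edges.size - 1):
        mask = idx == b
        width = edges[b + 1] - edges[b]
        if not mask.any() or width <= 0:
            continue
        dens = mask.sum() / (k.size * width)
        mk = k[mask].mean()
        if dens > 0 and mk > 0:
            xs.append(np.log10(mk))
            ys.append(np.log10(dens))
    if len(xs) < 3:
        return 0.0
    x, y = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    r2 = 1.0 - (resid**2).sum() / ss_tot
    return float(r2 * -np.sign(slope))


def scan_soft_threshold(
    m: AbundanceMatrix,
    powers: list[int] | None = None,
    r2_threshold: float = 0.90,
    network_type: str = "unsigned",
) -> SoftThresholdScan:
    """Scan candidate soft-threshold powers for scale-free topology.

    For each power the adjacency is built, node connectivities computed, and
    the scale-free fit index evaluated.  The selected power is the smallest
    one whose fit index reaches ``r2_threshold``; if none does, the power
    maximizing the fit index is returned with a warning.
    """
    if powers is None:
        powers = list(range(1, 31))
    if not powers:
        raise ValueError("powers must be non-empty")
    c = pearson_matrix(m)
    fits, means = [], []
    for p in powers:
        a = adjacency(c, p, network_type)
        k = a.connectivity
        if np.all(k == 0):
            raise ValueError(f"all connectivities zero at power {p}")
        fits.append(scale_free_fit_index(k))
        means.append(float(k.mean()))
    ok = [p for p, f in zip(powers, fits) if f >= r2_threshold]
    if ok:
        selected, met = ok[0], True
    else:
        selected, met = powers[int(np.argmax(fits))], False
        logger.warning(
            "no power reached fit index %.2f; using argmax power %d (fit %.3f)",
            r2_threshold, selected, max(fits),
        )
    return SoftThresholdScan(list(powers), fits, means, int(selected), r2_threshold, met)


def tom(a: Adjacency) -> TOMatrix:
    """Topological overlap matrix (unsigned Ravasz/Zhang-Horvath form).

    t_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j, where
    l_ij = sum_u a_iu a_uj and k_i = sum_u a_iu; t_ii = 1.  Pairs of fully
    isolated nodes (zero denominator) get t_ij = 0 by convention.
    """
    A = a.a
    L = A @ A
    k = A.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (L + A) / denom
    zero = denom <= 0
    if zero.any():
        logger.warning("zero TOM denominator for %d pairs; set to 0", int(zero.sum()) // 2)
        t[zero] = 0.0
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(t, 1.0)
    return TOMatrix(a.protein_ids, t)


def tom_dissimilarity(t: TOMatrix) -> np.ndarray:
    """d_ij = 1 - t_ij with a zero diagonal."""
    d = 1.0 - t.t
    np.fill_diagonal(d, 0.0)
    return d


def plot_soft_threshold_scan(scan: SoftThresholdScan, path: str) -> None:
    """Diagnostic plot: fit index and mean connectivity against power."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].plot(scan.powers, scan.fit_index, "o-")
    axes[0].axhline(scan.r2_threshold, color="red", ls="--")
    axes[0].axvline(scan.selected_power, color="grey", ls=":")
    axes[0].set_xlabel("soft threshold power")
    axes[0].set_ylabel("scale-free fit index")
    axes[1].plot(scan.powers, scan.mean_connectivity, "o-")
    axes[1].set_xlabel("soft threshold power")
    axes[1].set_ylabel("mean connectivity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
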