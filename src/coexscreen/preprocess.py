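"""Normalization, filtering and detection-overlap summaries.

Spectral counts are heteroskedastic and column sums vary with run depth, so
the default pipeline transform ahead of any correlation or ANOVA stage is
total-count normalization followed by log2(x + 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AbundanceMatrix, TraitDesign

logger = logging.getLogger(__name__)


def normalize(m: AbundanceMatrix, method: str = "total_count") -> AbundanceMatrix:
    """Normalize sample columns.

    total_count
        Scale each column so its sum equals the mean column sum of the
        input (library-size correction for run depth); requires counts.
    quantile
        Classical quantile normalization: each column's order statistics are
        replaced by the across-column means of order statistics, restoring
        ranks; ties receive the mean of their tied positions.
    none
        Pass through, relabelled as normalized.
    """
    if method == "none":
        return AbundanceMatrix(m.protein_ids, m.sample_ids, m.values.copy(), "normalized")
    if method == "total_count":
        if m.value_kind != "counts":
            raise ValueError("total_count normalization expects raw counts")
        sums = m.values.sum(axis=0)
        zero = np.flatnonzero(sums == 0)
        if zero.size:
            raise ValueError(
                f"sample column sums to 0: {[m.sample_ids[j] for j in zero]}"
            )
        scaled = m.values * (sums.mean() / sums)
        return AbundanceMatrix(m.protein_ids, m.sample_ids, scaled, "normalized")
    if method == "quantile":
        vals = np.sort(m.values, axis=0)
        ref = vals.mean(axis=1)
        csum = np.concatenate([[0.0], np.cumsum(ref)])
        out = np.empty_like(m.values)
        for j in range(m.n_samples):
            col = m.values[:, j]
            order = np.argsort(col, kind="mergesort")
            sorted_col = col[order]
            # tied counts get the mean of the reference values over their rank block
            uniq, starts, counts = np.unique(
                sorted_col, return_index=True, return_counts=True
            )
            block_mean = (csum[starts + counts] - csum[starts]) / counts
            out[:, j] = block_mean[np.searchsorted(uniq, col)]
        return AbundanceMatrix(m.protein_ids, m.sample_ids, out, "normalized")
    raise ValueError(f"unknown normalization method {method!r}")


def log_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """Elementwise log2(x + 1)."""
    return AbundanceMatrix(
        m.protein_ids, m.sample_ids, np.log2(m.values + 1.0), "normalized"
    )


def filter_low_detection(m: AbundanceMatrix, min_detect_fraction: float) -> AbundanceMatrix:
    """Keep proteins nonzero in >= ceil(fraction * n_samples) samples."""
    if not 0.0 <= min_detect_fraction <= 1.0:
        raise ValueError("min_detect_fraction must be in [0, 1]")
    need = math.ceil(min_detect_fraction * m.n_samples)
    n_detected = (m.values != 0).sum(axis=1)
    keep = [p for p, k in zip(m.protein_ids, n_detected) if k >= need]
    if not keep:
        raise ValueError(
            "no protein passes the detection filter; lower min_detect_fraction"
        )
    return m.subset_proteins(keep)


@dataclass
class DetectionPartition:
    """Three-set Venn partition of detected proteins across mutation groups.

    ``region_counts`` is keyed by frozensets of group names; ``fraction_common``
    is the share of proteins (among those detected in >= 1 group) detected in
    all three groups, and ``fraction_unique`` the per-group share detected in
    that group only.
    """

    detected: dict[str, set[str]]
    region_counts: dict[frozenset, int]
    fraction_common: float
    fraction_unique: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"groups": "+".join(sorted(k)), "n_proteins": v}
            for k, v in sorted(self.region_counts.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows)


def detection_partition(
    m: AbundanceMatrix, d: TraitDesign, min_samples_detected: int = 1
) -> DetectionPartition:
    """Partition detected proteins by which mutation groups they appear in.

    A protein counts as detected in a group when it is nonzero in at least
    ``min_samples_detected`` samples of that group.
    """
    if min_samples_detected < 1:
        raise ValueError("min_samples_detected must be >= 1")
    groups = d.groups()
    for g, sids in groups.items():
        if not sids:
            raise ValueError(f"group {g} has no samples")
    col = {s: j for j, s in enumerate(m.sample_ids)}
    missing = [s for s in d.sample_ids if s not in col]
    if missing:
        raise ValueError(f"trait samples not in matrix: {missing}")
    detected: dict[str, set[str]] = {}
    for g, sids in groups.items():
        block = m.values[:, [col[s] for s in sids]] != 0
        hits = block.sum(axis=1) >= min_samples_detected
        detected[g] = {p for p, h in zip(m.protein_ids, hits) if h}

    names = list(groups)
    any_detected = set().union(*detected.values())
    region_counts: dict[frozenset, int] = {}
    for p in any_detected:
        key = frozenset(g for g in names if p in detected[g])
        region_counts[key] = region_counts.get(key, 0) + 1
    for r in range(1, 4):
        from itertools import combinations

        for combo in combinations(names, r):
            region_counts.setdefault(frozenset(combo), 0)

    n_any = len(any_detected)
    common = region_counts[frozenset(names)]
    fraction_common = common / n_any if n_any else 0.0
    fraction_unique = {
        g: (region_counts[frozenset([g])] / n_any if n_any else 0.0) for g in names
    }
    return DetectionPartition(detected, region_counts, fraction_common, fraction_unique)
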