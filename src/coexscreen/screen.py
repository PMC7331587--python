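"""Per-protein ANOVA screening and module over-representation.

Each protein is tested by one-way fixed-effects ANOVA across the three
mutation groups (Ex19del / L858R / none), followed by post-hoc pairwise t
tests using the pooled within-group SD.  Significant proteins are classified
into eight expression-pattern groups by the direction of their change in
each mutation group relative to the no-mutation group.  Co-expression
modules are then screened for over-representation of each pattern group with
a one-sided Fisher exact (hypergeometric) test, Benjamini-Hochberg corrected.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceMatrix, TraitDesign
from .modules import ModulePartition

logger = logging.getLogger(__name__)

GROUPS = ("EX19DEL", "L858R", "NONE")
PAIRS = (("EX19DEL", "NONE"), ("L858R", "NONE"), ("EX19DEL", "L858R"))

#: Pattern ids for (direction under Ex19del, direction under L858R); the
#: directions are always defined against the no-mutation group.
PATTERN_IDS = {
    ("up", "ns"): 1,
    ("down", "ns"): 2,
    ("ns", "up"): 3,
    ("ns", "down"): 4,
    ("up", "up"): 5,
    ("down", "down"): 6,
    ("up", "down"): 7,
    ("down", "up"): 8,
}


def _group_columns(m: AbundanceMatrix, d: TraitDesign) -> dict[str, np.ndarray]:
    col = {s: j for j, s in enumerate(m.sample_ids)}
    out = {}
    for g, sids in d.groups().items():
        if len(sids) < 2:
            raise ValueError(f"group {g} needs >= 2 samples, has {len(sids)}")
        out[g] = np.array([col[s] for s in sids])
    return out


def _anova_components(m: AbundanceMatrix, d: TraitDesign):
    """Per-protein group means, within/between sums of squares and dfs."""
    gcols = _group_columns(m, d)
    n_total = sum(len(c) for c in gcols.values())
    means = {g: m.values[:, c].mean(axis=1) for g, c in gcols.items()}
    ns = {g: len(c) for g, c in gcols.items()}
    grand = sum(means[g] * ns[g] for g in GROUPS) / n_total
    ssb = sum(ns[g] * (means[g] - grand) ** 2 for g in GROUPS)
    ssw = sum(
        ((m.values[:, gcols[g]] - means[g][:, None]) ** 2).sum(axis=1) for g in GROUPS
    )
    return means, ns, ssb, ssw, n_total


def anova_per_protein(m: AbundanceMatrix, d: TraitDesign) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per protein; F with df (2, n - 3).

    Proteins with zero total variance get NaN p-values (with a warning) and
    are excluded downstream.
    """
    means, ns, ssb, ssw, n = _anova_components(m, d)
    df_b, df_w = len(GROUPS) - 1, n - len(GROUPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_b) / (ssw / df_w)
    p = np.where(np.isfinite(F), stats.f.sf(np.where(np.isfinite(F), F, 0.0), df_b, df_w), 0.0)
    degenerate = (ssb + ssw) == 0
    if degenerate.any():
        logger.warning("%d proteins have zero total variance; ANOVA p set NaN",
                       int(degenerate.sum()))
        F = np.where(degenerate, np.nan, F)
        p = np.where(degenerate, np.nan, p)
    return pd.DataFrame({"F": F, "anova_p": p}, index=m.protein_ids)


def _adjust_rows(praw: np.ndarray, method: str) -> np.ndarray:
    """Adjust each row's p-values (small m per row) by holm or bh."""
    k = praw.shape[1]
    order = np.argsort(praw, axis=1, kind="mergesort")
    sorted_p = np.take_along_axis(praw, order, axis=1)
    if method == "holm":
        mult = np.arange(k, 0, -1)
        stepped = np.minimum(np.maximum.accumulate(sorted_p * mult, axis=1), 1.0)
    elif method == "bh":
        mult = k / np.arange(1, k + 1)
        stepped = np.minimum(
            np.minimum.accumulate((sorted_p * mult)[:, ::-1], axis=1)[:, ::-1], 1.0
        )
    else:
        raise ValueError(f"unknown adjustment {method!r}")
    out = np.empty_like(praw)
    np.put_along_axis(out, order, stepped, axis=1)
    return out


def pairwise_posthoc(
    m: AbundanceMatrix, d: TraitDesign, adjust: str = "holm"
) -> pd.DataFrame:
    """Post-hoc pairwise t tests with the pooled within-group SD.

    All three pairwise contrasts share the pooled SD estimated from the full
    three-group within-group sum of squares (df = n - 3); the three raw
    p-values are adjusted per protein (Holm by default, BH by option).
    Mean-difference signs are recorded per contrast.
    """
    means, ns, ssb, ssw, n = _anova_components(m, d)
    df_w = n - len(GROUPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = ssw / df_w
        praw = np.empty((m.n_proteins, len(PAIRS)))
        signs = np.empty((m.n_proteins, len(PAIRS)))
        for j, (ga, gb) in enumerate(PAIRS):
            diff = means[ga] - means[gb]
            se = np.sqrt(s2 * (1.0 / ns[ga] + 1.0 / ns[gb]))
            t = diff / se
            praw[:, j] = 2.0 * stats.t.sf(np.abs(t), df_w)
            signs[:, j] = np.sign(diff)
    praw = np.where(np.isfinite(praw), praw, np.nan)
    valid = ~np.isnan(praw).any(axis=1)
    padj = np.full_like(praw, np.nan)
    if valid.any():
        padj[valid] = _adjust_rows(praw[valid], adjust)
    cols = {}
    for j, (ga, gb) in enumerate(PAIRS):
        tag = f"{ga.lower()}_vs_{gb.lower()}"
        cols[f"p_{tag}"] = padj[:, j]
        cols[f"sign_{tag}"] = signs[:, j]
    return pd.DataFrame(cols, index=m.protein_ids)


def differential_result(
    m: AbundanceMatrix, d: TraitDesign, adjust: str = "holm"
) -> pd.DataFrame:
    """ANOVA and post-hoc columns combined into one per-protein table."""
    return anova_per_protein(m, d).join(pairwise_posthoc(m, d, adjust))


def classify_patterns(r: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Classify proteins into the eight expression-pattern groups.

    A protein is a candidate iff its ANOVA p < alpha.  Its direction under a
    mutation is up/down iff the adjusted post-hoc p for that mutation vs the
    no-mutation group is < alpha, with the sign of the mean difference;
    otherwise ns.  The (Ex19del, L858R) direction pair indexes patterns 1-8;
    proteins with both directions ns (including candidates significant only
    in the Ex19del-vs-L858R contrast) get pattern 0.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    out = pd.DataFrame(index=r.index)

    def direction(tag: str) -> list[str]:
        p = r[f"p_{tag}"].to_numpy()
        s = r[f"sign_{tag}"].to_numpy()
        cand = (r["anova_p"].to_numpy() < alpha) & (p < alpha)
        return [
            ("up" if sg > 0 else "down") if c and sg != 0 else "ns"
            for c, sg in zip(cand, s)
        ]

    out["direction_ex19del"] = direction("ex19del_vs_none")
    out["direction_l858r"] = direction("l858r_vs_none")
    out["pattern"] = [
        PATTERN_IDS.get((a, b), 0)
        for a, b in zip(out["direction_ex19del"], out["direction_l858r"])
    ]
    return out


def pattern_members(patterns: pd.DataFrame) -> dict[int, list[str]]:
    """Protein lists for each non-empty pattern group."""
    out: dict[int, list[str]] = {}
    for pid in sorted(set(patterns["pattern"]) - {0}):
        out[pid] = list(patterns.index[patterns["pattern"] == pid])
    return out


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for a hypergeometric draw of n from N with K successes."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def overlap_screen(
    p: ModulePartition,
    patterns: pd.DataFrame,
    universe: set[str] | None = None,
    alpha: float = 0.05,
    bh_family: str = "all_cells",
) -> pd.DataFrame:
    """Screen modules for over-representation of the pattern groups.

    For each (module, pattern group) cell a one-sided Fisher exact p-value is
    the hypergeometric upper tail of the observed overlap given the universe.
    BH correction runs across all tested cells as one family by default
    (``bh_family='per_group'`` corrects within each pattern group instead).
    A module is selected when its best (minimum) q across groups is < alpha.
    """
    if universe is None:
        universe = set(p.protein_ids)
    if not universe:
        raise ValueError("empty universe")
    members = pattern_members(patterns)
    N = len(universe)
    names = p.module_names
    rows = []
    for lab in p.module_labels:
        mod = set(p.members(lab)) & universe
        for pid, prots in members.items():
            grp = set(prots) & universe
            if not grp:
                continue
            k = len(mod & grp)
            pval = hypergeom_upper_tail(k, N, len(grp), len(mod))
            rows.append(
                {
                    "module": names[lab],
                    "group": pid,
                    "overlap": k,
                    "module_size": len(mod),
                    "group_size": len(grp),
                    "universe": N,
                    "p": pval,
                }
            )
    tab = pd.DataFrame(rows)
    if tab.empty:
        tab["q"] = tab["best_q"] = tab["selected"] = []
        return tab
    if bh_family == "all_cells":
        tab["q"] = benjamini_hochberg(tab["p"].to_numpy())
    elif bh_family == "per_group":
        tab["q"] = np.nan
        for pid in tab["group"].unique():
            mask = tab["group"] == pid
            tab.loc[mask, "q"] = benjamini_hochberg(tab.loc[mask, "p"].to_numpy())
    else:
        raise ValueError(f"unknown bh_family {bh_family!r}")
    tab["best_q"] = tab.groupby("module")["q"].transform("min")
    tab["selected"] = tab["best_q"] < alpha
    return tab


def covariate_group_comparison(t: TraitDesign) -> pd.DataFrame:
    """Descriptive statistics and one-way ANOVA p per numeric covariate.

    Per covariate and mutation group: mean, SD (denominator n, the population
    form customarily printed as "mean +/- SD" in clinical tables) and n; plus
    the one-way ANOVA p-value across the three groups.  Missing values are
    excluded per covariate with a warning.
    """
    if t.covariates.empty:
        raise ValueError("trait design has no covariates")
    groups = t.groups()
    sid_to_status = dict(zip(t.sample_ids, t.status))
    rows = []
    for cov in t.covariates.columns:
        series = t.covariates[cov]
        if series.isna().any():
            logger.warning("covariate %s: %d missing values excluded",
                           cov, int(series.isna().sum()))
        by_group = {}
        for g in GROUPS:
            vals = series[[s for s in groups[g]]].dropna().to_numpy(dtype=float)
            if len(vals) < 2:
                raise ValueError(f"group {g} has < 2 values for covariate {cov}")
            by_group[g] = vals
        pooled = np.concatenate(list(by_group.values()))
        if pooled.std() == 0:
            pval = float("nan")
        else:
            pval = float(stats.f_oneway(*by_group.values()).pvalue)
        for g in GROUPS:
            v = by_group[g]
            rows.append(
                {
                    "covariate": cov,
                    "group": g,
                    "mean": float(v.mean()),
                    "sd": float(v.std()),  # denominator n
                    "n": len(v),
                    "anova_p": pval,
                }
            )
    return pd.DataFrame(rows)
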