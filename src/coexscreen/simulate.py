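"""Synthetic spectral-count datasets with planted modules and group effects.

The generator emulates the study design every stage of the pipeline is
tested against: 36 samples in three mutation groups (Ex19del 9, L858R 9,
none 18), ~1,000 proteins, a handful of planted co-expressed modules, and
planted group-specific up/down effects on designated proteins.

The generative model is a single latent factor per module.  For sample s and
protein i in module m with per-protein baseline b_i (log2 scale) and
within-group SD sigma_i:

    mu_i(s) = b_i + lambda * sigma_i * f_m(s) + delta_i * sigma_i * c_i(s)
              + eps,   eps ~ N(0, sigma_i * sqrt(1 - lambda**2))

where f_m(s) ~ N(0, 1) is the module factor, c_i(s) is +1/-1/0 according to
the protein's planted pattern and the sample's group, and lambda controls the
within-module correlation (~lambda**2 in the Gaussian layer).  Counts are
then drawn with mean 2**mu_i(s) from a negative binomial (overdispersed, the
realistic choice for spectral counts) or Poisson model.  Everything is a
pure function of the spec and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AbundanceMatrix, TraitDesign
from .screen import PATTERN_IDS

#: direction pair for each pattern id (inverse of PATTERN_IDS)
PATTERN_DIRECTIONS = {v: k for k, v in PATTERN_IDS.items()}


def default_effect_table(module_sizes: tuple[int, ...], delta: float = 2.0) -> list[tuple[int, int, float]]:
    """Default planted effects: 60 DE proteins spread over the 8 patterns.

    Pattern g is planted on the first few members of module g, so that
    differential proteins concentrate inside specific modules (patterns 1-4
    get 8 proteins each, patterns 5-8 get 7).
    """
    counts = (8, 8, 8, 8, 7, 7, 7, 7)
    offsets = np.concatenate([[0], np.cumsum(module_sizes)])
    table = []
    for pattern, n_de in zip(range(1, 9), counts):
        if pattern > len(module_sizes):
            break
        start = int(offsets[pattern - 1])
        for i in range(min(n_de, module_sizes[pattern - 1])):
            table.append((start + i, pattern, delta))
    return table


def scaled_module_sizes(n_proteins: int) -> tuple[int, ...]:
    """Eight planted modules covering ~30% of the proteome, sizes 20-60 at
    the default 1,000 proteins and scaled proportionally otherwise."""
    fractions = (0.06, 0.05, 0.045, 0.04, 0.035, 0.03, 0.025, 0.02)
    sizes = tuple(max(5, round(f * n_proteins)) for f in fractions)
    if sum(sizes) > n_proteins:
        raise ValueError(f"n_proteins={n_proteins} too small for 8 planted modules")
    return sizes


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic dataset; defaults mirror the study shape."""

    group_sizes: tuple[int, int, int] = (9, 9, 18)  # EX19DEL, L858R, NONE
    n_proteins: int = 1000
    module_sizes: tuple[int, ...] = (60, 50, 45, 40, 35, 30, 25, 20)
    loading: float = 0.8  # lambda, within-module factor loading
    effects: list[tuple[int, int, float]] | None = None  # (protein, pattern, delta)
    baseline_mean: float = 6.0  # log2 counts
    baseline_sd: float = 1.2
    sigma: float = 1.5  # within-group SD, log2 scale
    count_model: str = "negative_binomial"
    dispersion: float = 0.1
    seed: int = 42

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_proteins:
            raise ValueError("module sizes exceed n_proteins")
        if not 0.0 <= self.loading <= 1.0:
            raise ValueError("loading must be in [0, 1]")
        if any(g < 2 for g in self.group_sizes):
            raise ValueError("each group needs >= 2 samples")
        if self.count_model not in ("negative_binomial", "poisson"):
            raise ValueError(f"unknown count model {self.count_model!r}")
        if self.effects is None:
            self.effects = default_effect_table(self.module_sizes)
        for prot, pattern, _ in self.effects:
            if not 0 <= prot < self.n_proteins:
                raise ValueError(f"effect protein index {prot} out of range")
            if pattern not in PATTERN_DIRECTIONS:
                raise ValueError(f"unknown pattern id {pattern}")


@dataclass
class SyntheticTruth:
    """Planted ground truth: module labels, patterns, effect sizes, factors."""

    protein_ids: list[str]
    module: np.ndarray  # planted module label per protein, 0 = none
    pattern: np.ndarray  # planted pattern id per protein, 0 = none
    delta: np.ndarray  # planted effect size per protein (SD units)
    factors: pd.DataFrame = field(default_factory=pd.DataFrame)  # modules x samples

    def coexpression_labels(self, min_size: int = 5) -> np.ndarray:
        """The planted co-expression partition.

        A planted group effect adds a second, mutation-group-driven
        component to a protein's latent profile, so proteins sharing both a
        module and a pattern form their own co-expression cluster distinct
        from the rest of their module.  Each (module, pattern) cell with at
        least ``min_size`` members becomes its own cluster; smaller cells
        stay with their factor module.  Label 0 is background.
        """
        pairs = list(zip(self.module, self.pattern))
        counts: dict[tuple[int, int], int] = {}
        for pr in pairs:
            counts[pr] = counts.get(pr, 0) + 1
        next_label = int(self.module.max()) + 1
        cell_label: dict[tuple[int, int], int] = {}
        labels = np.array(self.module, dtype=int)
        for i, (mod, pat) in enumerate(pairs):
            if pat == 0 or counts[(mod, pat)] < min_size:
                continue
            if (mod, pat) not in cell_label:
                cell_label[(mod, pat)] = next_label
                next_label += 1
            labels[i] = cell_label[(mod, pat)]
        return labels


def _sample_layout(group_sizes: tuple[int, int, int]) -> tuple[list[str], list[str]]:
    statuses = (
        ["EX19DEL"] * group_sizes[0]
        + ["L858R"] * group_sizes[1]
        + ["NONE"] * group_sizes[2]
    )
    ids = [f"S{i + 1:02d}" for i in range(len(statuses))]
    return ids, statuses


def _effect_sign(pattern: int, status: str) -> float:
    if pattern == 0:
        return 0.0
    d_ex, d_l8 = PATTERN_DIRECTIONS[pattern]
    d = {"EX19DEL": d_ex, "L858R": d_l8, "NONE": "ns"}[status]
    return {"up": 1.0, "down": -1.0, "ns": 0.0}[d]


def generate_dataset(spec: SyntheticSpec) -> tuple[AbundanceMatrix, TraitDesign, SyntheticTruth]:
    """Draw a spectral-count dataset with planted modules and effects."""
    rng = np.random.default_rng(spec.seed)
    sample_ids, statuses = _sample_layout(spec.group_sizes)
    n_s = len(sample_ids)
    n_p = spec.n_proteins

    module = np.zeros(n_p, dtype=int)
    pos = 0
    for lab, size in enumerate(spec.module_sizes, start=1):
        module[pos : pos + size] = lab
        pos += size

    pattern = np.zeros(n_p, dtype=int)
    delta = np.zeros(n_p)
    for prot, pat, d in spec.effects:
        pattern[prot] = pat
        delta[prot] = d

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n_p)
    n_mod = len(spec.module_sizes)
    factors = rng.standard_normal((n_mod, n_s))

    lam = spec.loading
    noise_sd = spec.sigma * np.sqrt(1.0 - lam**2)
    signs = np.array(
        [[_effect_sign(pattern[i], st) for st in statuses] for i in range(n_p)]
    )
    mu = baseline[:, None] + delta[:, None] * spec.sigma * signs
    in_mod = module > 0
    mu[in_mod] += lam * spec.sigma * factors[module[in_mod] - 1]
    mu[in_mod] += rng.normal(0.0, noise_sd, size=(int(in_mod.sum()), n_s))
    mu[~in_mod] += rng.normal(0.0, spec.sigma, size=(int((~in_mod).sum()), n_s))

    mean_counts = np.exp2(mu)
    if spec.count_model == "poisson":
        counts = rng.poisson(mean_counts).astype(float)
    else:
        r = 1.0 / spec.dispersion
        p = r / (r + mean_counts)
        counts = rng.negative_binomial(r, p).astype(float)

    protein_ids = [f"P{i + 1:04d}" for i in range(n_p)]
    m = AbundanceMatrix(protein_ids, sample_ids, counts, "counts")
    design = TraitDesign(sample_ids, statuses)
    truth = SyntheticTruth(
        protein_ids,
        module,
        pattern,
        delta,
        pd.DataFrame(factors, index=[f"M{k + 1}" for k in range(n_mod)], columns=sample_ids),
    )
    return m, design, truth


def generate_null_dataset(
    n_proteins: int = 200,
    group_sizes: tuple[int, int, int] = (9, 9, 18),
    seed: int = 0,
    **kwargs,
) -> tuple[AbundanceMatrix, TraitDesign, SyntheticTruth]:
    """Dataset with no planted modules and no planted effects (type-I suites)."""
    spec = SyntheticSpec(
        group_sizes=group_sizes,
        n_proteins=n_proteins,
        module_sizes=(),
        loading=0.0,
        effects=[],
        seed=seed,
        **kwargs,
    )
    return generate_dataset(spec)


def generate_scale_free_connectivity(
    n: int, exponent: float = 2.5, seed: int = 0, noise_sd: float = 0.0
) -> np.ndarray:
    """Connectivity sequence following a discrete power law p(k) ~ k**-exponent.

    Built as k_i proportional to i**(-1/(exponent-1)) for ranks i = 1..n,
    optionally with multiplicative lognormal noise.  Used to validate the
    scale-free fit index.
    """
    if n < 50:
        raise ValueError("n must be >= 50")
    if exponent <= 1.0:
        raise ValueError("exponent must be > 1")
    ranks = np.arange(1, n + 1, dtype=float)
    k = 100.0 * ranks ** (-1.0 / (exponent - 1.0))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        k = k * np.exp(rng.normal(0.0, noise_sd, size=n))
    return k


def default_dataset(seed: int = 42) -> tuple[AbundanceMatrix, TraitDesign, SyntheticTruth]:
    """The default synthetic study: ~1,000 proteins x 36 samples, 8 modules."""
    return generate_dataset(SyntheticSpec(seed=seed))
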