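# Methods

This note documents the statistical procedures implemented in `coexscreen`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter for
reproducing results.

## Input model and preprocessing

The primary input is a proteins × samples matrix of label-free spectral
counts (number of MS/MS spectra assigned to a protein) together with a
per-sample mutation status in {Ex19del, L858R, none}, one-hot encoded as
traits M1 (L858R), M2 (Ex19del), NM (neither). Missing cells are read as
zero, matching spectral-count semantics where "not observed" is a zero
count rather than missing data. Technical replicate runs are aggregated by
the arithmetic mean per sample (sum available); with a single run per
sample aggregation is the identity.

Spectral counts are heteroskedastic and scale with run depth, so every
correlation and ANOVA stage operates by default on **total-count-normalized,
log2(x+1)-transformed** values: each sample column is scaled so its sum
equals the mean column sum, then log-transformed. Pearson correlation on
raw counts would be dominated by the most abundant proteins. Quantile
normalization (classical form: order statistics replaced by across-column
means, ties receiving the mean of their tied rank block) is available as an
alternative. A detection-overlap summary partitions proteins by the groups
in which they are detected (nonzero in ≥ 1 sample of the group by default)
into the seven three-set Venn regions, with the common fraction computed
over proteins detected in at least one group.

## Co-expression network

Pairwise Pearson correlation is computed across samples; zero-variance
proteins are excluded with a warning. The default network is **unsigned**:
a_ij = |r_ij|^β (signed variant ((1+r)/2)^β by option), with the diagonal
set to zero so connectivity sums exclude self-edges.

β is chosen by the scale-free topology criterion: for each candidate power
(1–30 by default; the range is configurable) connectivities k_i = Σ_j a_ij
are binned into 10 equal-occupancy bins, the log10 empirical density per
bin is regressed on the log10 mean connectivity per bin, and the fit index
is R² × −sign(slope). The **smallest power reaching fit ≥ 0.90** is
selected; if none reaches it, the argmax is used with a warning. The
pipeline runs this scan by default — the selection *procedure*, rather than
any particular power, is the portable part of the workflow; a fixed power
of 10 is the documented default wherever the scan is disabled. Degenerate
connectivity sequences (fewer than three usable bins, e.g. constant k)
score 0 by convention.

Topological overlap uses the standard unsigned form
t_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij) with t_ii = 1 and t_ij = 0
when the denominator vanishes (two fully isolated nodes). The clustering
dissimilarity is 1 − TOM.

## Module detection

Proteins are clustered agglomeratively on the TOM dissimilarity. The
default linkage for the protein tree is **average**, the standard choice
for TOM dendrograms; sample dendrograms (Euclidean distance between sample
profiles) default to complete linkage. Both linkages are available for
both clusterings.

The dendrogram is trimmed by a **dynamic hybrid tree cut** with two
stages. Stage 1 walks the merge list bottom-up, maintaining branches with
per-member attachment heights. When two branches join at height h, each is
accepted as a module if (i) it has ≥ `min_module_size` members (default 5),
(ii) its *core scatter* — the mean attachment height of its earliest
joiners, with the usual core-size rule m/2 + 1 + √(n − m/2 − 1) — is below
a ceiling interpolated between the 5th-percentile merge height and the cut
height using the published per-deep-split constants (0.64 … 0.95 for
deep-split 0 … 4), and (iii) its *normalized gap* (h − scatter)/span, where
span is the cut height minus the 5th-percentile height, reaches a floor of
0.80 … 0.60 for deep-split 0 … 4. The normalized form of the gap criterion
is this implementation's own choice: on TOM dendrograms the joining
heights compress into a narrow band near 1, and an absolute gap threshold
cannot distinguish a genuine module boundary (whose join sits near the top
of the height range) from incidental sub-structure; the span-relative form
behaves consistently on both compressed and well-spread trees. Higher
deep-split values therefore accept looser, less separated branches —
more, smaller modules — and module counts are monotone in deep-split on
the synthetic suite. When a join is rejected the larger branch absorbs the
smaller (whose members attach at h); when exactly one side qualifies it is
emitted and the other continues growing; members attached above the
scatter ceiling are trimmed; branches still open at the top are accepted
on size and scatter alone.

Stage 2 assigns leftover objects to the module with the smallest average
TOM dissimilarity to its members, accepting when that distance is within
an assignment radius set three quarters of the way from the module's
internal dissimilarity level to the matrix-wide mean, iterated to a fixed
point. The full detection chain adds a **membership-growth** step on the
expression profiles: unassigned proteins join the module whose summary
profile they correlate with most strongly when |kME| ≥ 0.5, the customary
module-membership cutoff; this recovers weak module members whose TOM
distances are compressed against the background. Labels are renumbered by
decreasing module size and named WM1, WM2, ….

Each module is summarized by its **eigen protein**, the member with the
highest intramodular connectivity Σ_{j∈module} a_ij (ties broken by
smallest id). This hub-protein summary — not the classical
first-principal-component eigengene — is the module profile correlated
with the binary traits; p-values come from the t transform of r with
n − 2 degrees of freedom, two-sided. Module stability is the mean, over
bootstrap resamples of samples (with replacement, same n), of each
reference module's best Jaccard overlap with any re-detected module; it is
a pure function of the seed.

## Differential screen

Per protein, a one-way fixed-effects ANOVA across the three groups gives
F = MSB/MSW with df (2, n − 3); zero-total-variance proteins get NaN and
are excluded downstream. Post-hoc pairwise t tests use the pooled
within-group SD from all three groups (df = n − 3), matching R's
`pairwise.t.test(..., pool.sd = TRUE)`; the three raw p-values are adjusted
per protein by Holm (BH by option), and mean-difference signs are kept.

A protein is classified into a pattern when its ANOVA p < α (0.05) and an
adjusted contrast against the **no-mutation group** is < α; the
(Ex19del-direction, L858R-direction) pair indexes patterns 1–8 (1 = up
under Ex19del only, 2 = down under Ex19del only, 3/4 = the L858R
equivalents, 5/6 = same direction under both, 7/8 = opposite directions).
The Ex19del-vs-L858R contrast never sets a direction, so proteins
significant only in that contrast carry no pattern.

The module × pattern-group screen computes, for each cell, the one-sided
Fisher exact p (hypergeometric upper tail of the observed overlap given
the analysis universe — the proteins that entered the network). BH runs
over all tested cells as one family by default (per-group by option); the
per-module summary `best_q` is the minimum q across groups and a module is
selected when best_q < α. The clinical covariate comparison reports
per-group mean, SD and n with the **population SD (denominator n)** — the
convention that reproduces printed "mean ± SD" clinical tables — while the
ANOVA itself uses the standard unbiased mean squares.

## Synthetic data

The generator emulates the study shape: 36 samples in groups of 9 (Ex19del),
9 (L858R) and 18 (neither); 1,000 proteins; eight planted modules of 60–20
proteins (~30% of the proteome). Each module has a single latent factor
f_m(s) ~ N(0,1); protein i in module m has log2 mean
b_i + λσ f_m(s) + δ_i σ c_i(s) + ε with ε ~ N(0, σ√(1−λ²)), so the
within-module correlation is λ² in the Gaussian layer (λ = 0.8 by
default). δ_i is the planted effect in within-group SD units (default
δ = 2 on 60 proteins spread over the eight patterns, placed at the start
of modules 1–8 so differential proteins concentrate inside specific
modules); c_i(s) is ±1/0 per the pattern and the sample's group. Counts
are negative binomial with mean 2^μ and dispersion 0.1 (Poisson by
option), reflecting spectral-count overdispersion.

Baselines are b ~ N(6, 1.2²) log2 counts and σ = 1.5. These were set so
that the counting layer attenuates rather than destroys the designed
Gaussian-layer correlation: at dispersion 0.1 the count noise contributes
roughly 0.5 log2 units regardless of abundance, so small σ would leave
realized correlations far below λ². With these values the realized
within-module correlation is ≈ 0.45–0.5 at λ = 0.8 and ≈ 0.65–0.7 at
λ = 0.9 — strong-but-noisy co-expression typical of clinical tissue
proteomes.

A planted group effect is itself a co-expression signal: proteins sharing
a pattern covary through the group indicator with magnitude comparable to
the factor loading (indicator variance × δ² ≈ λ² for the default δ).
`SyntheticTruth.coexpression_labels()` therefore exposes the refined
planted partition in which each (module, pattern) cell of at least the
minimum module size is its own cluster; detections that split these cells
from their host module are correct behaviour, not errors. The recovery
tests score the adjusted Rand index against the factor-module truth (with
unassigned and background each acting as a cluster); on the default
dataset it is ≈ 0.8–0.93 across seeds, limited by genuinely undetectable
weak members (low-baseline proteins whose count noise swamps the factor).

What the generator does **not** emulate: peptide-level identification and
protein inference, missingness mechanisms other than sampling zeros, batch
or run-order structure, and correlated module factors. Passing tests on
synthetic data therefore demonstrate correctness of the statistics and the
recovery machinery under the stated model, not robustness to those
real-data phenomena.

## Numerical conventions and edge cases

- All randomness flows through `numpy.random.default_rng` seeded per run;
  identical config + inputs give byte-identical output tables.
- Correlation matrices are symmetrized and clipped to [−1, 1]; TOM is
  symmetrized and clipped to [0, 1] before use.
- Hierarchical clustering uses scipy's linkage; merge heights are
  validated against a naive O(n³) agglomerative reference in the tests.
- Holm and BH adjustments are implemented directly (step-down with
  cumulative max / step-up with cumulative min) and cross-checked against
  statsmodels and R in the tests.
- Fisher tails use `hypergeom.sf(k − 1, N, K, n)`, exact against
  combinatorial sums.
- Status tokens are matched case-insensitively with aliases
  {EX19DEL, 19DEL}, {L858R}, {NONE, NEGATIVE, WT}.
- An empty pattern group is never tested in the screen; an empty screen
  table is returned when no group has members.

## Known limitations

- The tree cut's branch criteria are threshold rules; on data where module
  boundaries sit exactly at the criterion values, small perturbations
  (e.g. bootstrap resampling) can drop or merge a marginal module. The
  stability score is the intended diagnostic for this.
- Dense matrices throughout: the implementation targets proteome-scale
  inputs (10³–10⁴ features), not 50k+ transcriptomes.
- No merging of similar modules by summary-profile correlation, no
  blockwise decomposition, no imputation and no batch correction.
- Identifier matching in the annotation layer is exact-string; supply an
  alias map externally if needed.
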