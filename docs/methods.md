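# Methods

## Retention model

Each (compound, system) series is modelled as y = A + B·φ + ε with
y = R_M (planar) or log k (column), φ the organic-modifier volume fraction
stored as a dimensionless number in (0, 1), and ε i.i.d. Gaussian. The fit
is closed-form simple OLS; the extrapolated intercept A (R_Mw / log k_w) is
the lipophilicity descriptor and B < 0 in reversed phase. Decimal
logarithms are used throughout — the chromatographic convention in which
R_M = log₁₀(1/R_F − 1) and k = (t_R − t₀)/t₀ are defined — never natural
logarithms.

Diagnostics follow the standard identities for simple regression:
R² = 1 − SSE/SYY, adjusted R² = 1 − (1 − R²)(n−1)/(n−2),
F = (n−2)R²/(1−R²) with p from F(1, n−2), s = √(SSE/(n−2)), and the
coefficient standard errors from s and the design moments. R is reported
unsigned (√R²), as chromatographic reports print it; the slope sign carries
the direction. A perfectly collinear series yields s = 0, R² = 1, F = ∞,
p = 0. The minimum series length is 3 points — the smallest n that leaves a
residual degree of freedom — with at least two distinct φ levels; shorter
series are excluded and recorded rather than fitted. Missing
(compound, system) fits propagate as NaN cells in the coefficient matrix,
never as zeros.

## Chemometric layer

All comparisons operate on the compounds × descriptors matrix whose columns
are `<system>-R` (intercepts) and `<system>-S` (slopes), optionally joined
with computed log P / log D columns.

- **Descriptive statistics** use the sample (n−1) standard deviation and
  ignore missing cells (≥2 values required per column).
- **Correlation** is Pearson over pairwise-complete observations (rank
  statistics are not offered); pairs with fewer than 3 complete
  observations are left undefined with a warning. Pairwise-complete
  handling matters because computed tables legitimately carry missing
  entries for some compounds.
- **Pairwise regression** reuses the OLS core on complete pairs; its r
  equals the corresponding correlation-matrix entry by construction.
- **PCA** autoscales every column to zero mean and unit sample variance and
  takes the SVD of the scaled matrix, retaining min(n−1, p) components.
  Sign indeterminacy is fixed deterministically: the largest-magnitude
  loading of each component is made positive (first index on ties).
  Explained-variance proportions sum to 1 over the retained components.
  Missing cells are a policy decision the caller must make explicitly —
  `drop` affected columns (default in the CLI report) or `impute` column
  means; the report records which was used. Zero-variance columns are
  dropped with a warning.
- **Hierarchical clustering** of descriptor columns uses the signed
  correlation dissimilarity d = 1 − r (not 1 − |r|: anti-correlated
  descriptors should be maximally distant, d ≤ 2), with complete linkage by
  default and average/single configurable. Complete linkage is the default
  of the R `hclust` toolchain this kind of analysis is usually run in.
  Dendrograms export to Newick (merge heights as branch lengths, via
  scikit-bio) and to a JSON merge list.

## Drug-likeness screens

Four per-compound flags: Clog P < 5 (strict inequality, per the usual
phrasing of the Lipinski limit), −2.0 ≤ Mlog P ≤ 4 (Oprea; inclusive),
0 ≤ log P ≤ 3 and 1 ≤ log D₇.₄ ≤ 3 (inclusive "in the range of" windows).
A missing descriptor yields an indeterminate (`<NA>`) flag, never a pass.
Computed tables are loaded verbatim; no deduplication of algorithmically
identical columns is attempted. Compound alignment between chromatographic
and computed tables is an inner join on compound id with dropped ids
reported.

## Synthetic-data generator

The generator emulates an 18-compound × 13-system study: eight planar
systems (C18/C8 plates × MeOH, ACN, acetone, dioxane) and five column
systems (buffered C18/MeOH, C8/MeOH, C8/ACN, buffered IAM/ACN and
cholesterol/MeOH). Each compound has one latent lipophilicity L ~ N(0, 1);
system s maps it to the true intercept A = offset_s + gain_s·L. Default
offsets and gains are the per-system means and standard deviations of the
13-system design (e.g. planar C18/MeOH 4.34 ± 1.06, column C8/MeOH
5.01 ± 0.97), so the simulated descriptor scale matches the conditions the
pipeline targets. The true slope is coupled to the intercept as
B = −(0.5 + 0.9·A): more lipophilic solutes respond more steeply to
modifier. The coupling coefficients are configuration, not doctrine.
Measurement noise is N(0, 0.05²) log-units by default, a typical
plate/column reading error.

φ grids: column-system grids use the printed experimental designs (e.g.
C8/ACN 0.35–0.90 in 0.05 steps, IAM 0.05–0.40 in 0.05 steps; cholesterol
uses the coarser 0.1 option of its stated design). Planar ranges are the
stated ones (e.g. C18: MeOH 0.60–0.90, dioxane 0.40–0.80) with a 0.05 step,
chosen so that every compound on the design's intercept scale keeps at
least three measurable points (see censoring below).

Planar systems emit R_F = 1/(1 + 10^y), the exact inverse of the R_M
transform; points whose R_F falls outside the measurable window
[0.03, 0.97] are censored — dropped from the emitted table and written to a
sidecar log, so tests can separate censoring effects from noise. Highly
lipophilic compounds therefore lose their low-φ points, exactly as spots
that stay near the origin do on a real plate; occasionally a series drops
below 3 usable points and is excluded with a warning. Column systems emit
t_R = t₀(1 + 10^y) at fixed t₀ = 1.5 min with no censoring. Computed
descriptors are affine-plus-noise images of the same latent factor.

One seed sequence drives a `generate()` call; per-(compound, system) noise
streams are derived deterministically from it, so output is reproducible
bit for bit.

What the generator does **not** emulate: solvation/LSER-level physics,
tautomeric or pH-dependent retention, non-linear (quadratic-in-φ)
retention, inter-system error correlation, or realistic run-time limits on
column retention at low φ. Passing tests on synthetic data therefore
demonstrate the statistical machinery (recovery, redundancy detection,
censoring bookkeeping), not chromatographic realism.

## Numerical choices

- Exact-fit guard: R² ≥ 1 − 10⁻¹⁴ reports F = ∞, p = 0; SSE is clamped at 0
  against floating-point cancellation.
- A constant-response series fits exactly but has undefined correlation;
  r, R², F and p are NaN there.
- Correlation-distance matrices are symmetrised and clipped at 0 before
  linkage to absorb floating-point asymmetry.
- Report rendering rounds statistics tables to 4 decimals and correlation
  matrices to 2; full precision is kept internally and in `fits.csv`.

## Problem sizes

The default study is 18 compounds × 13 systems (≈ 1 500 measurements,
234 series); Monte-Carlo properties (latent-factor dominance, recovery
versus noise) average 5–20 replicate studies, which keeps the whole suite
under a minute on one CPU while the averaged shares are stable to ~1 %.

## Known limitations

- Reproduction of a published study's numeric tables requires that study's
  per-compound series; only the summary statistics, regression reports and
  screening outcomes printed in an article are available as frozen
  expectations without them (`tests/test_acceptance.py` documents the
  expected drop-in location).
- PCA requires a complete block; both offered policies (column drop, mean
  imputation) bias the variance shares when many cells are missing.
- The per-compound φ grids of real measurable-window designs are emulated
  only through censoring of a fixed grid.
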