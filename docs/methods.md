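# Methods notes

This note records the models behind `floodmeadow`, the defaults and why,
the numerical choices, and what the synthetic-data generators do and do
not emulate.

## Ordinal cover and community statistics

Cover is ordinal on the 5-degree Hult-Sernander-Du Rietz (HSD) scale.
Scores map to the midpoints of the geometrically halving classes:
1 → 3.125, 2 → 9.375, 3 → 18.75, 4 → 37.5, 5 → 75 %. Score 0 means
absent and maps to 0. Two abundance scales circulate in this literature
and both are supported: raw ordinal scores (used as weights in the
community-weighted indicator means and as the default input to
Bray–Curtis/clustering/NMDS) and midpoint percent cover (the default for
dominance statements such as "x % of total abundance"). Inverse Simpson
diversity D = 1/Σp²ᵢ is computed on midpoint-percent relative abundances
p, so that D is an effective species number on a cover basis.

Ward clustering uses the Ward.D2 criterion: the Lance–Williams recursion
on squared dissimilarities with merge heights reported on the
dissimilarity scale. The implementation delegates to
`scipy.cluster.hierarchy.linkage(method="ward")` on the Bray–Curtis
condensed matrix, which applies exactly that recursion; the tests verify
it against a hand-written exhaustive agglomeration for n ≤ 8. Cut
clusters are relabelled driest-first by mean plot elevation so cluster
ids are stable across runs.

The colonisation/extinction test is the exact binomial test of gains vs
losses at p = ½ with the two-sided p-value defined as the doubled smaller
tail, capped at 1 (for p = ½ this coincides with the minimum-likelihood
convention, which the tests confirm against enumeration and
`scipy.stats.binomtest`).

## NMDS

`ordination.nmds` minimises Kruskal stress-1,
√(Σ(d̂−d*)²/Σd̂²), where d̂ are configuration distances and d* their
least-squares monotone (isotonic) regression on the input dissimilarity
order. Ties receive the primary treatment: pairs tied in the input are
ordered by their current configuration distance, so they impose no
constraint on one another. Each restart alternates the isotonic fit with
a Guttman-transform update; iteration stops when stress improves by less
than 1e-6 (max 500 iterations), keeping the best configuration seen.
Defaults: k = 2, 20 restarts (restart 0 starts from the
principal-coordinates solution, the rest from seeded random
configurations), no prior standardisation of the dissimilarities. Scores
are centred, rotated to principal axes and sign-fixed so output is
reproducible. Stress on an exactly embeddable configuration is ~0; on
field-like ordinal data values around 0.03–0.1 are typical. Environmental
vectors are least-squares regressions of a per-plot variable on the score
columns (unit coefficient vector + r²), with an optional seeded
permutation p-value; a constant variable returns r² = 0 and a zero
vector.

## Poisson GLMM

The flowering model is log E[N_py] = β₀ + β₁ clim_y + β₂ elev_p +
β₃ clim_y elev_p + θ_p, θ_p ~ N(0, σ²_θ), N Poisson. Predictors are
centred and scaled (sample s.d., n−1) over the observation rows before
fitting, and the stored transform makes predictions on the original
scales invertible. Because the random effect is a scalar per plot, the
plot-level integrand depends on the data only through ΣY and Σe^η; the
marginal likelihood is computed by adaptive Gauss–Hermite quadrature
around each plot's conditional mode (Newton, vectorised across plots),
with Laplace as the 1-node special case. Default 15 nodes; the fit is
stable from ~9 nodes for counts of this magnitude (tested: 15 vs 25
nodes agree to 1e-4). Optimisation is L-BFGS-B on (β, log σ_θ) with
log σ_θ bounded in [−8, 3], started from the Poisson GLM fit (own
Newton–Raphson) and log σ_θ = log 0.5; standard errors come from the
central-difference observed-information matrix, with σ̂_θ's by the delta
method. `fix_sigma=0` short-circuits to the plain GLM, which the tests
compare against statsmodels IRLS; the full fit is cross-checked against
lme4::glmer (adaptive quadrature, 25 nodes) through Rscript.

Marginal/conditional R² follow the Nakagawa–Schielzeth decomposition for
log-link Poisson: R²m = σ²_f/(σ²_f+σ²_θ+σ²_d) and R²c adds σ²_θ to the
numerator, with σ²_f the variance of the fixed linear predictor over the
observations and the observation-level variance σ²_d computed by the
trigamma method ψ₁(λ̄) at λ̄ = exp(β₀ + ½(σ²_f+σ²_θ)); lognormal
(ln(1+1/λ̄)) and delta (1/λ̄) variants are switchable because published
analyses differ in which they use.

The previous-year model replaces the climate predictor with
log(N_{p,y−1} + 1), standardized; the +1 offset admits zero counts.
Census years without a preceding census are dropped automatically (for
the study's census calendar — 1938, 1981–1988, 2016–2021 — this leaves
the 12 usable years 1982–1988 and 2017–2021). March–April climate is the
mean of the two monthly temperatures and the two-month precipitation
sum; each (period, variable) pair is fitted as a separate model.

## Matrix model with cryptic dormancy

Fate classification operationalises dormancy as non-detection: an
unobserved year flanked by observations is dormant (multi-year gaps are
dormant throughout — the same logic extended beyond the original 3-year
window); a plant never seen again is dead from the first missing year; a
newly discovered plant was dormant in the preceding year, with earlier
years treated as pre-appearance and excluded. Every individual-year in
the window is thus exactly one of observed/dormant/dead/pre-appearance
(a tested conservation property). Transition matrices are column-wise
fate frequencies a_ij = n(j→i)/n(j→·), death included in the
denominator; columns are sub-stochastic and there is no fecundity row,
so λ ≤ 1 by construction. When a year-pair has no observable exits from
dormancy (always true for the final pair of a window), the dormant
column can be reused from a pair where exits are observable — the
assumption being that a similar share of the population is dormant each
year — and the reuse is flagged on the result.

λ is the Perron root from a dense eigendecomposition, cross-checked by
power iteration to 1e-10 (skipped for imprimitive matrices where power
iteration oscillates). w and v are the dominant right/left eigenvectors
normalised to Σw = 1 and v·w = 1; sensitivities v_i w_j/(v·w) are
verified against finite-difference perturbation of λ (h = 1e-6, 1e-4
relative) and elasticities sum to 1.

## Synthetic generators: what they emulate, and what not

*Community*: expected percent cover follows a Gaussian niche in elevation
(optimum, width, maximum per species), shifted per survey year by a
drift term, multiplied by log-normal noise (default s.d. 0.35 — keeps
covers positive and gives realistic zero-inflation after discretising),
then discretised by the HSD class bounds with a 0.5 % detection
threshold. Defaults: 76 plots on a 1.2–2.2 m gradient, 40 species,
surveys 1940/1982/1995/2016. The matched indicator table ties the
moisture indicator to the niche optimum (lower = wetter) so vector
fitting has signal; the other indicators are noise. Not emulated:
spatial autocorrelation between neighbouring plots, species
interactions, observer effects — so passing tests demonstrate the
statistical machinery, not robustness to those field realities.

*Flowering*: the exact generative inverse of the GLMM, with predictors
standardized over observation rows exactly as the fit does (anything
else biases tightly-estimated coefficients by the ddof mismatch).
Defaults follow the study conditions: six plots at 1.30–1.85 m, the 15
census years, β = (4, 0.3, −0.2, −0.4), σ_θ = 0.5; weather is
independent Normal temperature and zero-truncated Normal precipitation
per period with hemiboreal-lowland means (temperature–precipitation
independence is the observed situation). Morph counts are binomial
splits (white 3.7 %, pink 2 %).

*Demography*: individuals walk the true 5×5 matrix; dormant years are
emitted as "not seen", dead individuals never reappear, and individuals
never seen above ground are absent from the emitted histories. The
default truth matrix sends dormancy entries mostly from the smallest
class and most dormant exits back to it, with λ ≈ 0.91. Dormant
mortality defaults to 0 on identifiability grounds: with perfect
above-ground detection, a plant that dies while dormant is
indistinguishable from one that died the year after its last sighting,
so census data of this design cannot estimate that rate; the config
accepts nonzero values, but then the classification necessarily
mislabels dormant-then-dead individuals as earlier deaths. Truth-matrix
recovery is tested at an interior year-pair of an 8-year window so
dormancy gaps are resolvable on both sides; the test bound is a 99 %
familywise (Bonferroni-style, z = 3.54) binomial region over the 25
matrix entries, since 25 simultaneous per-entry 99 % intervals would
fail by chance alone about a quarter of the time.

## Problem sizes and tolerances

The parameter-recovery study uses 200 replicates of 50 plots × 40 years
(a deliberately information-rich design in which all four coefficients
are well identified); the demographic recovery uses 10,000 individuals
over 8 years; ordination property checks use 15–20 entities. Numerical
tolerances: GLMM optimiser ftol 1e-12, quadrature-node stability 1e-4,
eigen cross-check 1e-8, NMDS convergence 1e-6, Ward-oracle agreement
1e-9 relative. Ties in Ward merging are broken by scipy's
nearest-neighbour-chain order; with continuous dissimilarities exact
ties have probability zero, and the oracle comparison uses such inputs.

## Known limitations

Detection below 1 (missed above-ground plants) is not modelled anywhere;
dormancy estimates are therefore upper bounds on true dormancy only
under perfect detection. The GLMM fits one climate variable at a time
(six period × variable models), matching how the flowering analyses are
usually reported; a joint multi-predictor model would need a richer
design than six plots can support. Repeated-measures ANOVA of indicator
values, GAM elevation surfaces on ordinations and any GIS handling of
elevation rasters are intentionally out of scope.
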