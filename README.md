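# floodmeadow

Analysis pipeline for long-term studies of wet–mesic flood-meadow
vegetation and the population dynamics of the bulbous geophyte
*Fritillaria meleagris*. It is aimed at plant population and community
ecologists who resurvey permanent plots on ordinal cover scales, census
flowering over decades, and follow marked individuals through a stage
model that includes prolonged (below-ground, unobservable) dormancy.

The package has three analysis strands, plus a synthetic-data module that
generates inputs with exactly the statistical structure the analyses
assume, so the whole pipeline runs end-to-end with no external data.

## What it computes

**Community structure** (`floodmeadow.community`, `floodmeadow.ordination`).
Cover is recorded on the 5-degree Hult-Sernander-Du Rietz scale whose
classes halve geometrically (≤6.25, 6.25–12.5, 12.5–25, 25–50, ≥50 %);
class midpoints (3.125, 9.375, 18.75, 37.5, 75 %) convert scores to
percent cover. On top of that sit species richness *S*, inverse Simpson
diversity *D* = 1/Σp²ᵢ, relative and rank abundance, Bray–Curtis
dissimilarity Σ|x−y|/Σ(x+y), Ward.D2 hierarchical clustering with cluster
cutting, non-metric multidimensional scaling minimising Kruskal stress-1
(isotonic regression by pool-adjacent-violators), least-squares
environmental vectors with permutation tests, and an exact two-sided
binomial test of colonisations versus extinctions.

**Community-weighted indicator values** (`floodmeadow.indicators`).
Per plot, the abundance-weighted mean Σ(rᵢⱼ·xᵢ)/Σrᵢⱼ of species indicator
values xᵢ (moisture, light, nitrogen, grazing/mowing, soil disturbance,
soil reaction) with ordinal covers rᵢⱼ as weights, aggregated into group
trajectories (mean ± s.e.) over surveys.

**Flowering** (`floodmeadow.flowering`). A Poisson GLMM
log E[N_py] = β₀ + β₁·clim_y + β₂·elev_p + β₃·clim_y·elev_p + θ_p with
plot random intercepts θ_p ~ N(0, σ²_θ), standardized predictors, and the
random effects integrated out by adaptive Gauss–Hermite quadrature
(Laplace = 1 node). Includes Nakagawa–Schielzeth marginal/conditional R²
(trigamma method), a previous-year-flowering model on
log(N_{p,y−1} + 1), population- and plot-level predictions, and a
temperature–precipitation independence check.

**Demography** (`floodmeadow.demography`). Five stages — small, medium,
large vegetative, reproductive, dormant — where dormancy is inferred from
detection gaps: missed between two sightings → dormant; never relocated →
dead; newly discovered → dormant the year before. Transition matrices are
column-wise fate frequencies with mortality as the column deficit (no
fecundity row; seed recruitment is out of scope), from which the package
computes λ (dominant eigenvalue, cross-checked by power iteration), the
stable stage distribution w, reproductive values v, sensitivities
s_ij = v_i w_j/(v·w) and elasticities e_ij = (a_ij/λ)·s_ij.

## Worked example

```python
from floodmeadow import simulate, community, ordination, demography, flowering

cfg = simulate.CommunityGenConfig(n_plots=30, n_species=25, seed=11)
cover, plots = simulate.gen_meadow_surveys(cfg)
cm = cover[1982]
print("richness:", community.species_richness(cm))
print("inverse Simpson D: %.2f" % community.inverse_simpson(community.abundance_profile(cm)))
d = community.dissimilarity_matrix(cm)
res = ordination.nmds(d, k=2, n_restarts=10, seed=1)
print("NMDS stress: %.3f" % res.stress)

fcfg = simulate.FloweringGenConfig(seed=5)
cens, weather, truth = simulate.gen_flowering_counts(fcfg)
fit = flowering.fit_poisson_glmm(cens, weather, "mar_apr", "temperature",
                                 fcfg.elevations, n_quad=15)
print(fit.beta.round(3).to_dict(), "sigma_theta=%.3f" % fit.sigma_theta)

dcfg = simulate.DemographyGenConfig(n_individuals=5000, n_years=6, seed=3)
obs, _, truth_matrix = simulate.gen_individual_fates(dcfg)
fates = demography.classify_fates(obs, (1981, 1986))
pm = demography.build_projection_matrix(fates, (1983, 1984))
print("lambda = %.3f (truth %.3f)" % (demography.growth_rate(pm),
                                      demography.growth_rate(truth_matrix.to_numpy())))
```

prints

```
richness: 25
inverse Simpson D: 17.35
NMDS stress: 0.030
{'intercept': 4.12, 'clim': 0.3, 'elev': 0.034, 'clim_elev': -0.397} sigma_theta=0.399
lambda = 0.914 (truth 0.913)
```

The GLMM recovers the generating coefficients (truth β = 4, 0.3, −0.2,
−0.4; the elevation effect is estimated from only six plot-level values,
hence its wide uncertainty), the ordination embeds the simulated
elevation gradient at low stress, and the matrix model rebuilt from
census-style observations — dormant years emitted as "not seen" —
reproduces the generating λ.

There is also a CLI: `floodmeadow run-all --seed 1 --out results/`, with
`simulate`, `community`, `indicators`, `flowering` and `demography`
subcommands and a YAML config (flags override the config; every output
directory carries a manifest with the seed and config hash).

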