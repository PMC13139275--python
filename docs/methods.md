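# Methods

## Scope and data model

`sedrisk` assesses heavy-metal contamination of river sediment from
replicate concentration tables in long format: one row per (site, season,
metal, replicate), concentrations in mg/kg dry weight. Site order along the
river is explicit metadata supplied with the table, never inferred from
labels, so longitudinal summaries stay correct for arbitrary site names.
Below-detection cells are *censored* observations written `<LOD` (e.g.
`<0.001`); they are parsed into a flag plus the detection limit and are
never silently replaced by a surrogate number. The censoring policy for
summaries is explicit:

- `omit` (default) — censored replicates are excluded; a group whose
  replicates are all censored yields a below-LOD summary with no mean, and
  every index for that cell is emitted blank. This mirrors how published
  index tables leave below-detection cells empty.
- `half_lod` / `full_lod` — the two conventional single-value imputations
  (LOD/2 or LOD), available where a complete matrix is required (e.g. the
  biomass coupling score, PCA input).

Site–season summaries report the arithmetic mean and the standard error of
the mean (sample SD / √n) of the contributing replicates. The dispersion
printed in the bundled survey table is interpreted as a standard error over
the five 1 m² replicate plots; the source table does not name its
dispersion statistic, and this interpretation is used only to calibrate the
synthetic generator's noise, not in any index.

## Indices and classification

CF, EF, Igeo, PLI, CD, Er and RI are implemented exactly as defined in the
README. Numerical notes:

- PLI is computed in log space (`exp(mean(log CF))`); a property test keeps
  it within 1e−12 (relative) of the direct product-root on random inputs.
- EF is the ratio of the two CFs formed from the same site–season *means*
  (ratio of means, not mean of ratios); the reference metal's EF is then
  exactly 1 by construction, a useful internal consistency check.
- Igeo satisfies `Igeo = log2(CF) − log2(1.5)` identically; Igeo at zero
  concentration is undefined and reported as not computable.
- Indices are computed from site–season mean concentrations (one value per
  cell of a published-style table). A per-replicate mode
  (`indices.replicate_indices`) computes each index per replicate and
  reports mean ± SE; it is off the main path.
- Reported tables round half-to-even at two decimals; internal values keep
  full precision.

Classification schemes are ordered interval sets treated as data. All
intervals are left-closed/right-open (a value exactly at a cut point takes
the higher class); for Igeo the older convention places 0 itself in
"unpolluted" — the difference is a measure-zero boundary and the uniform
convention is kept for predictability. The CD scheme scales its cut points
with the number of metals assessed (< n low, [n, 2n) moderate, [2n, 4n)
considerable, ≥ 4n very high), since the classical class bounds assume
eight metals. Guideline screening uses ≥ TEL as "exceeds TEL" and > PEL as
"exceeds PEL": the TEL is the last concentration at which adverse effects
are improbable, so sitting exactly on it counts as reaching the threshold,
while effects are "probable" only beyond the PEL.

Two background presets ship with the package. `tw1961_shale` is the
classical average-shale set (As 13, Cr 90, Cu 45, Fe 47200, Zn 95 mg/kg).
`back_calculated` recovers, at call time, the backgrounds implied by the
bundled survey as the per-metal median of (printed mean ÷ printed CF):
As ≈ 9.29, Cr ≈ 21.61, Cu ≈ 40.02, Fe ≈ 47404, Zn ≈ 55.93. Fe agrees with
average shale to 0.5%; the other metals clearly do not, so the two sets are
kept as separate, explicitly named presets and `back_calculated` is the
default because it reproduces the bundled index table. Known
inconsistencies in that published table are documented rather than chased:
its stated CF minimum (0.11) contradicts its own Fe entries (0.02–0.05);
its printed EF values are not exact CF ratios (the inputs behind them are
unrecoverable, so only the Fe ≡ 1.00 column and the printed range are
meaningful targets); and its narrative PLI ≥ 1 at two sites is not
reproducible from its printed CFs (geometric mean ≈ 0.91 at the closest
site–season).

## Survey statistics

Spatial variation: one-way ANOVA of replicate-level concentrations across
sites, seasons pooled as replicates (a per-metal F across sites, matching
how such surveys are usually reported). Assumption checks accompany every
fit: Kolmogorov–Smirnov on standardised residuals and Levene's test across
groups. Post-hoc is Tukey HSD, condensed to a compact letter display via
the insert-and-absorb algorithm (groups sharing a letter are not
significantly different). Sites with fewer than two uncensored replicates
are dropped and listed; fewer than two usable sites raises instead of
returning NaN. The degenerate all-identical-constants input is defined as
F = 0, p = 1.

Seasonal contrasts: two-sided independent-samples t-test per (site, metal),
pooled variance by default, switching to Welch when Levene rejects equal
variances at α. Correlations are Pearson r with the two-sided t-based test
over pairwise-complete observations (constant vectors are flagged, not
silently NaN). PCA standardises columns (correlation-matrix PCA) and
reports orthonormal loadings, scores and variance proportions; rows with
missing cells are dropped and listed, zero-variance columns are an error
naming the column. α defaults to 0.05 and no multiple-testing correction is
applied by default, matching common practice for these surveys; a
Benjamini–Hochberg flag exists for the pairwise families.

## Macrobenthos biomass

Drying to constant mass: the stopping rule returns the first weighing whose
relative change from the previous one is within `rel_tol` (default 0.5%,
since "no change between days" is never quantified); series that never
stabilise return their last mass with a flag. Site–season biomass is the
mean over plots of summed per-taxon plot masses, in g dry mass per m²
(1 m² plots); the unit string travels with every output. Association with
metals and composite indices is plain Pearson correlation over pooled
site–season observations. Family-level tolerance labels (Oligochaeta,
Hirudinea, Chironomidae, Simulidae, Corbiculidae tolerant; Leptophlebiidae,
Trichoptera intolerant) ship as an editable table and drive only the
generator's taxon composition, never an index.

## Synthetic generator

The generator encodes the longitudinal structure the analysis assumes. The
deterministic expectation per (site, season, metal) is

    E = baseline × urban_step(site) × season_multiplier × (1 − retention)
        + Σ pulses × exp(−decay × steps_downstream)

with one inter-site step as the distance unit (true inter-site distances
are not modelled). Replicates are mean-preserving lognormal draws,
`E · exp(σZ − σ²/2)` with σ = 0.18 (log-scale), chosen so the implied
relative SEs of 5-replicate means match the ~5–15% seen in the bundled
survey; lognormal noise guarantees positivity and right skew. Draws below
the 0.001 mg/kg detection limit are emitted censored.

Default structure (all values mg/kg): headwater baselines As 0.0005,
Cr 0.0005, Cu 13, Fe 1200, Zn 15; urban step at site C multiplying As
×2000, Cu ×2.2, Fe ×11, Zn ×3.8; diffuse town Cr inputs of 17 at B and 12
at C; wastewater pulses at D (As 1.5, Cr 60, Cu 20, Fe 8000, Zn 12, decay
0.25), G (Cr 45, Cu 22, decay 0.4) and J (Cr 10, Cu 30, Fe 4000, Zn 5); an
impoundment at F retaining 35% of Fe and 30% of Zn baseline load;
dry-season baseline multipliers As 0.7, Cr 1.15, Cu 1.05, Fe 1.05, Zn 1.35.
These defaults place site–season magnitudes inside the bundled survey's
printed ranges and reproduce its qualitative fingerprint: headwater As/Cr
censored, Cu below its TEL upstream of the urban step and above it from
site D downstream, Cr peaks at the wastewater sites D and G, Zn under its
TEL everywhere. The town Cr input is set slightly below the printed site-B
magnitude (17 vs ~21) so headwater CF sits near 0.8 with clear margin below
1 under replicate noise — the published table itself has a site-B CF of
1.04, which would make "pristine headwaters" a coin flip at this noise
level. Because seasonal multipliers act on the baseline term only,
event-driven metals (Cr) carry no seasonal signal by default; seasonal
tests are exercised through Zn, whose dry-season excess at the headwater
sites is baseline-driven.

Biomass coupling: the site–season contamination score is
s = (z(Cr) + z(Cu))/2 over realised site–season means (censored groups
enter at LOD/2 so the score is complete). Biomass is
`b₀ + c·s + ε`, b₀ = 10 g/m², |c| = 2 g/m² per score SD, sign from the
target correlation, and the noise SD is solved in closed form from the
plug-in identity `r² = cov(s, Cr)² / ((var s + sd²/c²)·var Cr)` so the
model-implied correlation with the realised Cr means equals the configured
target (default −0.57). A target whose magnitude exceeds the zero-noise
correlation achievable for that survey is a configuration error. Biomass is
floored at 1 mg/m² (negative draws are vanishingly rare at these defaults);
plot masses are drawn to average exactly to the site–season biomass, the
tolerant-taxon share follows a logistic function of the score, and each
(plot, taxon) mass gets a synthetic drying series that stabilises exactly
at it.

Because the noise is solved per realised survey, the sample correlation at
n = 20 site–seasons scatters around the target with the usual ≈(1−r²)/√n
spread and a small negative-bias of order r(1−r²)/2n; the mean over 500
seeds lands within a few hundredths of the target (the acceptance script
recomputes this). Problem sizes throughout (10 sites × 2 seasons × 5
replicates; 500 generator draws for Monte-Carlo summaries; 200 seeds for
the power check) are chosen to keep the whole validation suite at desk
scale — about a minute end to end.

## What the synthetic data does and does not show

The generator reproduces the *structure* of a point-source survey —
gradients, censoring, seasonality, replicate noise, biomass coupling — so
green tests demonstrate that the pipeline recovers known truth under that
structure. It does not emulate inter-metal source correlations beyond the
shared longitudinal profile, multi-year trends, sediment grain-size or
organic-carbon effects, hydrodynamic transport, or abundance-based biotic
indices; conclusions about real rivers still require real data. Published
point statistics that depend on unavailable raw replicates (exact F values,
exact inter-metal correlations) are computed as quantities by the pipeline
but are not point targets.

## Known limitations

- The EF cells of the bundled published table cannot be reproduced exactly
  (see above); the implementation computes the literal double ratio.
- Compact letter displays are not guaranteed minimal in pathological
  significance patterns, only correct (letters shared iff not separated).
- The censoring model is a single shared detection limit per survey;
  per-metal or time-varying LODs would need per-row limits (the data model
  already stores the limit per row).
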