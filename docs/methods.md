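# Methods

## Scope and model

`lakesip` analyses closed-bottle stable-isotope-probing incubations: lake
water (150 ml in a 240 ml bottle) receives 2 mg of ¹³C-substrate carbon at
99 atom% and incubates in darkness for 28 days at the season's field
temperature (21 / 8 / 2 / 15 °C for summer / autumn / winter / spring).
The full design is 3 lakes × 4 seasons × 4 treatments (polyethylene,
polystyrene, plant litter, unamended control) × 4 replicates = 192
bottles. The analysis is end-point: rates are inferred from the final
state of each product pool, not from time-resolved curves.

### Gas budget

A 5 ml headspace aliquot in a He-flushed 12 ml Exetainer gives a TCD ppm
reading. The chain to carbon mass is n(gas) = (V_tube + V_sample)/V_m;
n(CO₂) = ppm/10⁶ × n(gas) × CF with CF = (V_tube + V_sample)/V_sample;
m(C) = n(CO₂) × M_CO₂ × (M_C/M_CO₂); c(C) = m(C) per sample volume scaled
to mg C per litre. Because bottles incubate away from lab temperature, the
sample volume is first corrected isobarically (Charles's law,
V × T_lab/T_incubation). V_m defaults to 22.414 L/mol and the Exetainer
volume to 12 ml; both are configurable (`GasConstants`), since reference
conditions for the molar volume and the tube geometry are lab choices.
The headspace pool mass uses the gas-phase volume (0.090 L). DIC is
measured by acidifying a water aliquot and reading the liberated CO₂
through the identical chain; its c(C) is interpreted as mg C per litre of
*water* and multiplied by the 0.150 L water volume. CH₄ readings are
carried through the concentration chain but excluded from the carbon-fate
arithmetic, which is defined on CO₂ and DIC only. Henry's-law speciation
of the carbonate system is deliberately out of scope.

### Isotope mass balance

δ¹³C → atom percent uses the exact VPDB form with R = 0.01118; ΔAP
subtracts the mean AP of the n = 4 control bottles of the same lake and
season. Negative ΔAP values are retained — clamping would bias slow
treatments (polyethylene) upward — and cells whose mean decomposition
rate is negative are reported with a warning. The biomass pool mass is
total PLFA carbon × 25 with bulk-PLFA δ¹³C as the pool's isotope value;
the per-g-carbon normalisation of PLFA concentrations cancels exactly in
this product, so the assimilation rate does not depend on the filter
carbon estimate. BGE is assimilation over decomposition × 100.

Annual budgets assume equal seasons: annual rate = Σ over the four
seasons of (daily × days_per_month × 3), days_per_month = 30.44
(365.25/12, configurable). Turnover time is 100/rate. Because reciprocals
and means do not commute for variable slow substrates, `annualize`
reports both aggregation orders — the mean of per-lake turnover times and
the turnover time of the mean rate — with the across-lake SD as the
uncertainty; neither order is privileged.

### PLFA pipeline

Calibration curves are ordinary least squares from instrument response to
concentration over the four standard levels (15/50/100/250 ng/µl); a
curve is accepted only if its Pearson r exceeds 0.99, otherwise that FAME
is excluded from quantification with a warning. Extraction losses are
corrected by one pooled recovery factor per bottle from the C19:0
internal standard, with C12:0 and C23:0 as fallbacks in that order (a
single-standard rule; combining all three would need a weighting model
there is no basis for). Biomass = total PLFA × 25, the standard 4%-PLFA
assumption. Compound-specific enrichment Δδ¹³C is the treatment mean
minus the matched-control mean per PLFA and (lake, season) cell;
chromatographic peaks at or below 0.015 nA are discarded as sub-detection,
and PLFAs absent from controls yield missing values, never zero. The
shipped biomarker map (i15:0/a15:0 gram-positive & Verrucomicrobia,
16:1ω7/18:1ω7 gram-negative Proteobacteria/Acidobacteria, 18:2ω6/18:3ω3
fungi) flags 18:1ω9 as ambiguous (fungi vs Planctomycetes) with a runtime
warning.

### Community screen

Counts are rarefied to exactly 4000 reads per bottle by multivariate
hypergeometric subsampling (bottles below depth are dropped with a
warning); genera at or below 0.5% of all reads are removed and the rest
expressed as percent of each bottle's reads. Bray–Curtis dissimilarities
are computed on square-root-transformed contributions. PERMANOVA is the
one-way pseudo-F on among/within sums of squared dissimilarities with a
seeded permutation p-value (#{F* ≥ F} + 1)/(n_perm + 1) — the +1
correction keeps small-replicate p-values conservative; on Euclidean
distances of a single variable the statistic equals the classical ANOVA
F, which the tests assert against both scipy and scikit-bio. SIMPER
averages each taxon's share |xᵢ − yᵢ| / Σ(x + y) over all between-group
bottle pairs, so contributions sum exactly to the mean between-group
dissimilarity. The decomposer screen correlates each genus's abundance
with the per-lake mean decomposition rate within a season (Spearman,
average ranks for ties); a genus passes at ρ > 0.6 with > 2% abundance in
at least one lake. The Pearson R² against the per-bottle rate is an
annotation only: R² < 0.3 marks a genus "unlikely" without removing it,
since no numeric exclusion cut-off is defensible. An external per-bottle
score (e.g. an nMDS axis) can replace the rate via the `target` argument.

## Synthetic experiments

The generator defines the study conditions and the ground truth the
pipeline must recover.

**Tracer propagation.** A cell's true decomposition rate r (%/day) is
defined as the quantity the rate formula estimates: the measurable ¹³C
excess placed into CO₂ + DIC + biomass equals r/100 × t × m_added
exactly (asserted to 1e-9). The split is governed by the mineralized
fraction and a CO₂:DIC partition (0.75 at day 28). Each pool's δ¹³C comes
from exact linear atom-percent mixing of baseline pool carbon with
99 atom% tracer carbon — delta-scale mixing is a low-enrichment
approximation that would be badly wrong here. Noise-free datasets are
therefore recovered exactly (the oracle-equivalence test asserts 1e-6).

**Default truth calibration.** Seasonal ratios are fixed at 5 : 1.7 : 1 : 2
(polystyrene) and 4 : 1.9 : 1 : 2.6 (plant litter) for
summer : autumn : winter : spring, anchored so the across-season mean
monthly litter rate is 12.6 %/month and the polystyrene annual rate is
0.11 %/yr; polyethylene is flat at 2×10⁻⁵ %/day (effectively inert).
Per-lake multipliers — litter (1.04, 1.00, 0.96), PS (1.18, 1.00, 0.82),
PE (1.5, 1.0, 0.5) — give realistic between-lake spread, largest for the
slowest substrate. Mineralized fractions are 0.89 (PS), 0.95 (litter),
0.89 (PE, but 0.45 in spring, when the tiny PE uptake leans toward
biomass).

**Baselines and noise.** Baseline community respiration follows a Q10 = 2
curve anchored at 0.03 mg C/L/d at 2 °C; DIC 3 mg C/L; biomass 0.5 mg
C/L; ambient headspace CO₂ 420 ppm; baseline δ¹³C −20‰ (CO₂, DIC) and
−30‰ (PLFA) — conventional natural-abundance values, not measured ones.
Instrument noise defaults: TCD 2% relative; δ¹³C 0.5‰ (CO₂/DIC) and 1.5‰
(PLFA); FAME responses 2 ng/µl at the 100 ng/µl calibration level,
scaling proportionally with signal. The proportional form matters: an
absolute noise floor of that size would put ~50% noise on the ~4 ng/µl
internal-standard peak, and dividing by such a noisy recovery estimate
inflates E[1/recovery] enough to more than double recovered assimilation
rates — a pathology no working GC-MS exhibits. Extraction recovery itself
varies per bottle (0.85 ± 0.05, clipped to [0.5, 1]) and is corrected
exactly by the internal standard in the noise-free limit.

**PLFA routing.** Assimilated tracer is routed to biomarker producers:
polystyrene mostly to 16:1ω7/18:1ω7 (with a smaller 17:0 share), plant
litter more broadly including the branched i15:0/a15:0. Peak heights are
proportional to concentration (0.04 nA per ng/µl), so trace FAMEs such as
18:3ω3 fall below the 0.015 nA detection cut in low-biomass bottles, as
in real chromatograms.

**Community model.** Genus counts are log-normal relative abundances
(SD 0.4 log units) times a multinomial of 4000 reads over a 29-genus
background spanning 9 classes typical of humic lakes. Designated
decomposer genera are shifted by slope × log(rate / seasonal mean rate)
in bottles of their substrate — the default slope of 8 makes the
across-lake rank signal reliably detectable through the lognormal and
multinomial noise (screen sensitivity ≥ 0.9 with a null pass-rate near
zero) — plus a flat ×2.5 abundance boost representing growth on the added
substrate, which is what makes treatment-vs-control PERMANOVA/SIMPER
comparisons respond. No sequence-level simulation is attempted: read
trimming, OTU clustering and chimera modelling are out of scope, so the
generator speaks genus-level counts directly.

**What passing tests do and do not show.** The generator reproduces the
statistical structure the analysis assumes — mass-conserving tracer
transfer, compositional counts, instrument-scale noise. It does not
emulate isotope fractionation, time-varying rates, succession, carbonate
chemistry, photo- or thermo-oxidation of plastics, or taxa whose
abundance responds to anything but the decomposition rate. Recovery on
synthetic data therefore validates the arithmetic and the statistical
power of the design, not the field accuracy of any real-lake estimate.

## Numerical choices and edge cases

- δ ≤ −1000‰ and AP outside (0, 100) raise; the AP↔δ round-trip is exact
  to 1e-9 over the full working range.
- BGE is reported missing (NaN) when decomposition is zero.
- Turnover time of a non-positive rate is reported as unbounded (inf).
- Rarefaction, PERMANOVA and the generator take explicit seeds; identical
  seeds give byte-identical outputs end to end.
- Spearman ties (lake-mean rates repeat within a season) use average
  ranks; a constant abundance vector skips that genus with a warning.
- Problem sizes in the test suite and acceptance script: 20-seed
  Monte-Carlo for rate-ratio recovery (240 bottles per substrate-season),
  100 seeds × 15 curves for calibration QC, 500 null simulations at 199
  permutations for PERMANOVA calibration, 200 seeds for the rarefaction
  expectation check. These sizes give Monte-Carlo standard errors well
  inside the asserted tolerances.

## Known limitations

- The rate formula scales ΔAP by the *measured* pool mass;
  for very slow substrates (PE) the per-bottle estimates sit at the
  δ-noise detection limit and per-cell means can be negative — they are
  reported as such, with a warning, rather than truncated.
- The c(C) step generalises the printed 5 ml hard-coding to arbitrary
  sample volumes; behaviour for non-5-ml samples follows the chain's
  algebra, with no independent reference to compare against.
- One pooled recovery factor per bottle assumes congruent losses across
  FAMEs; compound-specific recovery would need per-FAME standards.
- The screen correlates abundance with the rate itself; correlating with
  ordination scores instead is exposed via `target` but not the default.
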