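# lakesip

¹³C stable-isotope-probing (SIP) carbon-fate analysis for decomposition
assays in lake water.

Boreal humic lakes receive both terrestrial plant litter and microplastic
particles. To ask *how fast* the microbiome degrades such substrates and
*where the carbon ends up*, a SIP incubation adds a ¹³C-labelled substrate
(polyethylene, polystyrene, or plant litter at 99 atom% ¹³C) to bottles of
lake water across seasons, then traces the label into three product pools:
headspace CO₂, dissolved inorganic carbon (DIC), and microbial biomass
(via phospholipid fatty acids, PLFAs). `lakesip` implements the complete
analysis from raw instrument tables to annual decomposition budgets,
together with a synthetic-experiment generator with known ground truth so
every stage is testable without any field data.

## The mass balance

δ¹³C values (‰ vs VPDB, R = 0.01118) convert to atom percent

    AP = (δ¹³C + 1000) / (δ¹³C + 1000 + 1000/R) × 100,

the matched-control mean is subtracted (ΔAP, as a fraction), and each
pool's uptake rate in % of added substrate carbon per day is

    rate = (ΔAP × m_pool / m_added¹³C × 100) / t.

Total mineralization = CO₂ + DIC rates; decomposition = mineralization +
assimilation; bacterial growth efficiency BGE = assimilation/decomposition
× 100. Seasonal daily rates extrapolate to an annual budget (3 months per
season), and 100/rate gives the time to complete substrate turnover.
Pool masses come from a GC-TCD headspace chain (ideal-gas moles,
He-dilution concentration factor, Charles's-law volume correction) and
from PLFA totals × 25 (PLFAs are ~4% of biomass). Decomposer taxa are
screened by correlating genus abundance (rarefied to 4000 reads, >0.5%
filter) with the decomposition rate across lakes (Spearman ρ > 0.6, >2%
abundance in ≥1 lake), backed by PERMANOVA and SIMPER.

## Worked example

```sh
python examples/simulate_and_recover.py
```

```
recovered vs true decomposition rate, 24 cells:
  median |error| 1.4%  worst 5.1%
(polyethylene is near-inert; its tiny rates sit at the detection limit)

          PE: annual   0.0066 +- 0.0031 %/yr | full turnover  221086.0 months (18,424 yr)
          PS: annual   0.1072 +- 0.0189 %/yr | full turnover   11432.5 months (953 yr)
plant_litter: annual 149.9161 +- 6.0172 %/yr | full turnover       8.0 months (1 yr)
```

The generator plants known seasonal rates (polystyrene five-fold and plant
litter four-fold faster in summer than winter); the pipeline recovers each
lake-season cell within a few percent at default instrument noise, and the
annual budgets show the three regimes: plant litter turns over in months,
polystyrene in centuries, polyethylene in tens of millennia. Further
examples: `gas_chain.py` (the TCD chain step by step),
`carbon_fate_partition.py` (respired vs assimilated shares and BGE),
`plfa_biomarkers.py` (calibration QC and ¹³C-enriched biomarkers),
`decomposer_screen.py` (the correlation screen plus PERMANOVA/SIMPER).

A thin CLI wraps the same pipeline:

```sh
lakesip run-all --seed 1 --out-dir run1     # simulate + analyse + report
lakesip simulate --seed 1 --out-dir tables  # just the synthetic tables
```

`run-all` writes every intermediate table as TSV, a `summary.md` with the
annual budget / carbon partition / screened genera, and a `manifest.json`
with parameter values and SHA-256 hashes of all inputs and outputs.

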