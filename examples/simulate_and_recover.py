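"""Generate a synthetic seasonal SIP experiment and recover its ground truth.

Builds the full 3-lake x 4-season x 4-treatment x 4-replicate bottle grid
with known decomposition rates, runs the complete analysis (gas budget ->
PLFA biomass -> delta13C mass balance -> annual extrapolation), and
compares recovered rates against the truth table.
"""

import warnings

from lakesip import analyze_dataset, generate_dataset

warnings.filterwarnings("ignore", message="negative mean decomposition")

ds = generate_dataset(seed=1)
result = analyze_dataset(ds, seed=1)

merged = result.cells.merge(ds.truth.cells, on=["lake", "season", "substrate"])
measurable = merged[merged["substrate"].isin(["PS", "plant_litter"])]
err = (measurable["decomposition"] / measurable["decomposition_rate"] - 1) * 100
print(f"recovered vs true decomposition rate, {len(measurable)} cells:")
print(f"  median |error| {err.abs().median():.1f}%  worst {err.abs().max():.1f}%")
print("(polyethylene is near-inert; its tiny rates sit at the detection limit)\n")

for substrate, est in result.annual.items():
    years = est.total_years
    months = est.total_months
    print(
        f"{substrate:>12}: annual {est.annual_rate:8.4f} +- {est.annual_sd:.4f} %/yr"
        f" | full turnover {months:9.1f} months ({years:,.0f} yr)"
    )
print("\nannual rate = sum over the four seasons of (daily rate x 30.44 x 3);")
print("turnover time = 100 / rate, averaged over the per-lake estimates.")
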