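"""Headspace gas budget: TCD ppm readings to CO2-carbon masses.

A 5 ml headspace aliquot is injected into a He-flushed Exetainer tube and
the CO2 mixing ratio of the resulting gas mixture is read by a GC with a
thermal-conductivity detector (TCD).  The conversion back to carbon mass
runs through an ideal-gas mole count of the tube contents, a concentration
factor CF undoing the He dilution, and molar-mass conversions:

    n(gas)  = (V_tube + V_sample) / V_m
    n(CO2)  = TCD/1e6 x n(gas) x CF,   CF = (V_tube + V_sample) / V_sample
    m(CO2)  = n(CO2) x M_CO2
    m(C)    = m(CO2) x M_C / M_CO2
    c(C)    = m(C) per sample volume, scaled to mg C per litre of gas

Because bottles are incubated colder or warmer than the GC lab, the nominal
sample volume is first corrected to the measurement temperature with
Charles's law (isobaric V ~ T).

Dissolved inorganic carbon (DIC) is measured by acidifying a water aliquot
and reading the liberated CO2 through the same chain; its c(C) is taken as
mg C per litre of *water* and converted to a pool mass with the water
volume, whereas headspace readings use the gas-phase volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "M_CO2",
    "M_C",
    "GasConstants",
    "CarbonConcentration",
    "standardize_volume",
    "headspace_carbon",
    "ppm_from_concentration",
    "bottle_pool_mass",
    "process_gas_table",
]

M_CO2 = 44.009  # g/mol
M_C = 12.011  # g/mol


@dataclass(frozen=True)
class GasConstants:
    """Physical constants of the gas measurement.

    v_m
        Molar volume of an ideal gas, L/mol (22.414 at STP).
    v_tube
        Exetainer tube volume, L (12 ml tube).
    v_sample
        Nominal gas sample volume, L (5 ml).
    t_measurement_k
        GC lab temperature, K (21 degC).
    """

    v_m: float = 22.414
    v_tube: float = 0.012
    v_sample: float = 0.005
    t_measurement_k: float = 294.15

    def __post_init__(self) -> None:
        if self.v_m <= 0 or self.v_tube < 0 or self.v_sample <= 0:
            raise ValueError("gas volumes must be positive (v_tube may be 0)")
        if self.t_measurement_k <= 0:
            raise ValueError("temperature must be positive kelvin")


@dataclass(frozen=True)
class CarbonConcentration:
    """Derived quantities of one headspace reading."""

    n_gas: float  # mol of gas in the tube (sample + He)
    cf: float  # concentration factor (V_tube+V_sample)/V_sample
    n_co2: float  # mol CO2 in the sample
    m_co2_g: float  # g CO2 in the sample
    m_c_g: float  # g CO2-carbon in the sample
    c_c_mg_per_l: float  # mg C per litre of sampled gas phase


def standardize_volume(v_raw: float, t_incubation_k: float, t_measurement_k: float) -> float:
    """Charles's-law (isobaric) volume correction to the measurement temperature."""
    if t_incubation_k <= 0 or t_measurement_k <= 0:
        raise ValueError("temperatures must be positive kelvin")
    return v_raw * t_measurement_k / t_incubation_k


def headspace_carbon(
    tcd_ppm: float,
    constants: GasConstants = GasConstants(),
    v_sample: float | None = None,
) -> CarbonConcentration:
    """Run the TCD -> carbon chain for one reading.

    ``v_sample`` overrides the nominal sample volume with the
    Charles's-law-standardised one; pass the output of
    :func:`standardize_volume` when incubation and lab temperatures differ.
    """
    if tcd_ppm < 0:
        raise ValueError("TCD ppm must be >= 0")
    vs = constants.v_sample if v_sample is None else v_sample
    if vs <= 0:
        raise ValueError("sample volume must be positive (CF undefined at 0)")
    n_gas = (constants.v_tube + vs) / constants.v_m
    cf = (constants.v_tube + vs) / vs
    n_co2 = tcd_ppm / 1e6 * n_gas * cf
    m_co2 = n_co2 * M_CO2
    m_c = m_co2 * (M_C / M_CO2)
    # grams per sample volume -> g/L -> mg/L
    c_c = m_c * (1000.0 / (vs * 1000.0)) * 1000.0
    return CarbonConcentration(n_gas, cf, n_co2, m_co2, m_c, c_c)


def ppm_from_concentration(
    c_c_mg_per_l: float,
    constants: GasConstants = GasConstants(),
    v_sample: float | None = None,
) -> float:
    """Invert :func:`headspace_carbon`: the TCD ppm that yields ``c_c``."""
    vs = constants.v_sample if v_sample is None else v_sample
    if vs <= 0:
        raise ValueError("sample volume must be positive")
    m_c = c_c_mg_per_l * vs / 1e3  # grams per sample volume
    n_co2 = m_c / M_C
    n_gas = (constants.v_tube + vs) / constants.v_m
    cf = (constants.v_tube + vs) / vs
    return n_co2 / (n_gas * cf) * 1e6


def bottle_pool_mass(c_c_mg_per_l: float, compartment_volume_l: float) -> float:
    """Carbon mass (mg) of a bottle compartment from its concentration."""
    if compartment_volume_l < 0:
        raise ValueError("compartment volume must be >= 0")
    return c_c_mg_per_l * compartment_volume_l


def process_gas_table(
    gas: pd.DataFrame,
    metadata: pd.DataFrame,
    constants: GasConstants = GasConstants(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert a long gas table to concentration series and end pool masses.

    ``gas`` columns: bottle, day, gas (one of ``CO2``, ``DIC``, ``CH4``),
    ppm.  ``metadata`` supplies per-bottle temperature and volumes.  CH4
    rows are carried through the same chain into the time series but take
    no part in the carbon-fate pool masses.

    Returns ``(series, pools)``: per-reading concentrations, and one row
    per bottle with the end-of-incubation ``m_co2_mg`` (headspace) and
    ``m_dic_mg`` (water) carbon masses.
    """
    required = {"bottle", "day", "gas", "ppm"}
    if not required <= set(gas.columns):
        raise ValueError(f"gas table must have columns {sorted(required)}")
    meta = metadata.set_index("bottle")
    out = []
    for row in gas.itertuples(index=False):
        m = meta.loc[row.bottle]
        t_inc = m["temperature_c"] + 273.15
        vs = standardize_volume(constants.v_sample, t_inc, constants.t_measurement_k)
        cc = headspace_carbon(row.ppm, constants, v_sample=vs)
        out.append(
            {
                "bottle": row.bottle,
                "day": row.day,
                "gas": row.gas,
                "ppm": row.ppm,
                "c_c_mg_per_l": cc.c_c_mg_per_l,
            }
        )
    series = pd.DataFrame(out)

    pools = []
    for bottle, grp in series.groupby("bottle", sort=False):
        m = meta.loc[bottle]
        headspace = m["bottle_volume_l"] - m["water_volume_l"]
        co2 = grp[grp["gas"] == "CO2"]
        dic = grp[grp["gas"] == "DIC"]
        if co2.empty or dic.empty:
            raise ValueError(f"bottle {bottle!r} lacks CO2 or DIC readings")
        c_end = co2.loc[co2["day"].idxmax(), "c_c_mg_per_l"]
        c_dic = dic.loc[dic["day"].idxmax(), "c_c_mg_per_l"]
        pools.append(
            {
                "bottle": bottle,
                "m_co2_mg": bottle_pool_mass(c_end, headspace),
                "m_dic_mg": bottle_pool_mass(c_dic, m["water_volume_l"]),
            }
        )
    return series, pd.DataFrame(pools)
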