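"""Experimental design and ground-truth description of a SIP incubation.

A :class:`DesignSpec` describes the bottle grid of a seasonal
stable-isotope-probing (SIP) experiment: lake waters incubated in closed
bottles with a single pulse of ¹³C-labelled substrate (microplastic or plant
litter) plus unamended controls.  A :class:`TruthTable` holds the quantities
the analysis is meant to recover — per-cell decomposition rates and how the
taken-up carbon partitions between respiration (CO₂ and DIC) and biomass —
together with baseline pool sizes, baseline isotope values and measurement
noise.  :func:`default_truth` builds the default seasonal calibration used
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Season",
    "DesignSpec",
    "NoiseModel",
    "TruthTable",
    "default_truth",
    "DEFAULT_SEASONS",
    "DEFAULT_LAKES",
    "DEFAULT_SUBSTRATES",
]

DEFAULT_LAKES = ("Haukijarvi", "Majajarvi", "Nimeton")
DEFAULT_SUBSTRATES = ("PE", "PS", "plant_litter", "control")

DAYS_PER_YEAR = 365.28  # 12 x 30.44


@dataclass(frozen=True)
class Season:
    """Season name plus the incubation temperature used for its waters."""

    name: str
    temperature_c: float


DEFAULT_SEASONS = (
    Season("summer", 21.0),
    Season("autumn", 8.0),
    Season("winter", 2.0),
    Season("spring", 15.0),
)


@dataclass(frozen=True)
class DesignSpec:
    """Bottle grid and physical constants of one seasonal SIP experiment.

    Defaults describe the full design: 3 lakes x 4 seasons x 4 treatments x
    4 replicates, 150 ml of water in a 240 ml bottle, 2 mg of ¹³C-substrate
    carbon at 99 atom%, incubated for 28 days with headspace gas sampled
    three times per week.
    """

    lakes: tuple[str, ...] = DEFAULT_LAKES
    seasons: tuple[Season, ...] = DEFAULT_SEASONS
    substrates: tuple[str, ...] = DEFAULT_SUBSTRATES
    control: str = "control"
    replicates: int = 4
    water_volume_l: float = 0.150
    bottle_volume_l: float = 0.240
    added_c_mg: float = 2.0
    tracer_atom_percent: float = 99.0
    incubation_days: float = 28.0
    gas_sampling_per_week: int = 3
    filtered_volume_ml: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bottle_volume_l <= self.water_volume_l:
            raise ValueError("bottle_volume must exceed water_volume")
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")
        if self.added_c_mg <= 0:
            raise ValueError("added_c_mg must be positive for labelled treatments")
        if not 0 < self.tracer_atom_percent <= 100:
            raise ValueError("tracer_atom_percent must be in (0, 100]")
        if self.control not in self.substrates:
            raise ValueError(f"control treatment {self.control!r} not in substrates")
        if self.filtered_volume_ml > self.water_volume_l * 1000:
            raise ValueError("cannot filter more water than the bottle holds")

    @property
    def headspace_volume_l(self) -> float:
        return self.bottle_volume_l - self.water_volume_l

    @property
    def season_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.seasons)

    @property
    def treatments(self) -> tuple[str, ...]:
        """Labelled substrates, i.e. everything except the control."""
        return tuple(s for s in self.substrates if s != self.control)

    def temperature_k(self, season: str) -> float:
        for s in self.seasons:
            if s.name == season:
                return s.temperature_c + 273.15
        raise KeyError(f"unknown season {season!r}")

    def sampling_days(self) -> np.ndarray:
        """Evenly spaced headspace sampling days ending on the final day."""
        n = int(round(self.gas_sampling_per_week * self.incubation_days / 7))
        return np.linspace(self.incubation_days / n, self.incubation_days, n)

    def bottle_id(self, season: str, lake: str, substrate: str, replicate: int) -> str:
        return f"{season}-{lake}-{substrate}-{replicate}"

    def bottles(self) -> pd.DataFrame:
        """Metadata table with one row per bottle of the full design."""
        rows = []
        for season in self.seasons:
            for lake in self.lakes:
                for substrate in self.substrates:
                    labelled = substrate != self.control
                    for rep in range(1, self.replicates + 1):
                        rows.append(
                            {
                                "bottle": self.bottle_id(season.name, lake, substrate, rep),
                                "lake": lake,
                                "season": season.name,
                                "substrate": substrate,
                                "replicate": rep,
                                "temperature_c": season.temperature_c,
                                "incubation_days": self.incubation_days,
                                "added_13c_mg": self.added_c_mg if labelled else 0.0,
                                "water_volume_l": self.water_volume_l,
                                "bottle_volume_l": self.bottle_volume_l,
                                "filtered_volume_ml": self.filtered_volume_ml,
                            }
                        )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise of the simulated instruments.

    tcd_rel
        Relative SD of the gas-chromatograph TCD ppm reading.
    delta_gas_permil
        SD (per mil) of IRMS δ¹³C for CO₂ and DIC.
    delta_plfa_permil
        SD (per mil) of compound-specific and bulk PLFA δ¹³C.
    fame_ng_ul
        SD of the GC-MS FAME response in concentration units at the
        100 ng/µl calibration level; the noise scales proportionally with
        the signal, as GC-MS peak-area noise does at these levels.
    """

    tcd_rel: float = 0.02
    delta_gas_permil: float = 0.5
    delta_plfa_permil: float = 1.5
    fame_ng_ul: float = 2.0

    def __post_init__(self) -> None:
        for name in ("tcd_rel", "delta_gas_permil", "delta_plfa_permil", "fame_ng_ul"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def silent(self) -> "NoiseModel":
        """A copy with every noise source switched off."""
        return NoiseModel(0.0, 0.0, 0.0, 0.0)


@dataclass
class TruthTable:
    """Ground truth of a synthetic experiment.

    ``cells`` has one row per (lake, season, substrate) treatment cell with
    columns:

    decomposition_rate
        True decomposition rate, % of added substrate carbon per day.
    mineralized_fraction
        Fraction of taken-up carbon that is respired (the rest is
        assimilated into biomass).
    co2_fraction
        Fraction of the respired carbon residing in the headspace CO₂ pool
        at the end of the incubation (the rest stays dissolved as DIC).
    baseline_respiration
        Unlabelled community respiration, mg C per litre of water per day.
    """

    cells: pd.DataFrame
    dic_mg_per_l: float = 3.0
    biomass_mg_per_l: float = 0.5
    detritus_mg_per_l: float = 2.0
    ambient_co2_ppm: float = 420.0
    baseline_delta: dict = field(
        default_factory=lambda: {"CO2": -20.0, "DIC": -20.0, "PLFA": -30.0}
    )
    noise: NoiseModel = field(default_factory=NoiseModel)

    REQUIRED = (
        "lake",
        "season",
        "substrate",
        "decomposition_rate",
        "mineralized_fraction",
        "co2_fraction",
        "baseline_respiration",
    )

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.cells.columns)
        if missing:
            raise ValueError(f"truth table missing columns: {sorted(missing)}")
        c = self.cells
        if (c["decomposition_rate"] < 0).any():
            raise ValueError("decomposition rates must be >= 0")
        for col in ("mineralized_fraction", "co2_fraction"):
            if ((c[col] < 0) | (c[col] > 1)).any():
                raise ValueError(f"{col} must lie in [0, 1]")
        if (c["baseline_respiration"] < 0).any():
            raise ValueError("baseline respiration must be >= 0")

    def validate_against(self, design: DesignSpec) -> None:
        """Reject truth rows that reference cells absent from the design."""
        valid = {
            (lake, season.name, sub)
            for lake in design.lakes
            for season in design.seasons
            for sub in design.treatments
        }
        got = set(map(tuple, self.cells[["lake", "season", "substrate"]].values))
        unknown = got - valid
        if unknown:
            raise ValueError(f"truth rows reference undefined design cells: {sorted(unknown)}")
        absent = valid - got
        if absent:
            raise ValueError(f"truth table missing design cells: {sorted(absent)}")

    def cell(self, lake: str, season: str, substrate: str) -> pd.Series:
        m = self.cells[
            (self.cells["lake"] == lake)
            & (self.cells["season"] == season)
            & (self.cells["substrate"] == substrate)
        ]
        if len(m) != 1:
            raise KeyError(f"no unique truth row for ({lake}, {season}, {substrate})")
        return m.iloc[0]

    def without_noise(self) -> "TruthTable":
        return replace(self, noise=self.noise.silent())


# Seasonal ratios (summer : autumn : winter : spring) of the default truth,
# anchored so that the pipeline's seasonal aggregates reproduce realistic
# headline numbers: plant litter averages 12.6 %/month across seasons, PS
# reaches 0.11 %/yr annually, and PE is effectively inert (2e-5 %/day).
_SEASON_RATIOS = {
    "PS": {"summer": 5.0, "autumn": 1.7, "winter": 1.0, "spring": 2.0},
    "plant_litter": {"summer": 4.0, "autumn": 1.9, "winter": 1.0, "spring": 2.6},
}
_LITTER_MONTHLY_MEAN = 12.6  # % of added C per month, mean over seasons
_PS_ANNUAL = 0.11  # % of added C per year
_PE_DAILY = 2.0e-5  # % of added C per day, all seasons

# Across-lake multipliers, in design.lakes order; chosen to give realistic
# between-lake spread (PE is the most variable, litter the least).
_LAKE_FACTORS = {
    "PS": (1.18, 1.00, 0.82),
    "plant_litter": (1.04, 1.00, 0.96),
    "PE": (1.5, 1.0, 0.5),
}

_MINERALIZED_FRACTION = {"PS": 0.89, "plant_litter": 0.95, "PE": 0.89}
# In spring the (tiny) PE uptake leans toward biomass rather than CO2.
_PE_SPRING_MINERALIZED = 0.45
_CO2_FRACTION = 0.75  # share of respired C in headspace vs DIC at day 28

_DAYS_PER_MONTH = 30.44


def _baseline_respiration(temperature_c: float) -> float:
    """Community respiration, mg C/L/d, Q10 = 2 anchored at 0.03 @ 2 degC."""
    return 0.03 * 2.0 ** ((temperature_c - 2.0) / 10.0)


def _mean_daily_rate(substrate: str) -> float:
    if substrate == "plant_litter":
        return _LITTER_MONTHLY_MEAN / _DAYS_PER_MONTH
    if substrate == "PS":
        return _PS_ANNUAL / DAYS_PER_YEAR
    return _PE_DAILY


def default_truth(design: DesignSpec | None = None, noise: NoiseModel | None = None) -> TruthTable:
    """Default ground truth for ``design`` (default: the full design).

    Seasonal rate ratios are fixed per substrate (PS 5:1.7:1:2, plant litter
    4:1.9:1:2.6, PE flat) and scaled so the across-season means hit the
    calibration anchors above; per-lake multipliers add realistic
    between-lake variation.  Requires the default season names.
    """
    design = design or DesignSpec()
    rows = []
    for substrate in design.treatments:
        ratios = _SEASON_RATIOS.get(substrate)
        if ratios is None:  # PE and any unknown substrate: season-flat
            ratios = {s.name: 1.0 for s in design.seasons}
        missing = [s.name for s in design.seasons if s.name not in ratios]
        if missing:
            raise KeyError(
                f"no default seasonal ratio for {substrate!r} in season(s) {missing}; "
                "supply a custom TruthTable"
            )
        mean_ratio = np.mean([ratios[s.name] for s in design.seasons])
        base = _mean_daily_rate(substrate) / mean_ratio
        factors = _LAKE_FACTORS.get(substrate, (1.0,) * len(design.lakes))
        if len(factors) < len(design.lakes):
            raise ValueError("more lakes than default lake factors; supply a custom TruthTable")
        for lake, factor in zip(design.lakes, factors):
            for season in design.seasons:
                fmin = _MINERALIZED_FRACTION.get(substrate, 0.89)
                if substrate == "PE" and season.name == "spring":
                    fmin = _PE_SPRING_MINERALIZED
                rows.append(
                    {
                        "lake": lake,
                        "season": season.name,
                        "substrate": substrate,
                        "decomposition_rate": base * ratios[season.name] * factor,
                        "mineralized_fraction": fmin,
                        "co2_fraction": _CO2_FRACTION,
                        "baseline_respiration": _baseline_respiration(season.temperature_c),
                    }
                )
    truth = TruthTable(cells=pd.DataFrame(rows), noise=noise or NoiseModel())
    truth.validate_against(design)
    return truth
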