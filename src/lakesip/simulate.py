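"""Synthetic SIP experiment generator with known ground truth.

Builds complete synthetic measurement tables — headspace TCD readings,
IRMS δ¹³C records, GC-MS FAME peaks with calibration standards, and
genus-level 16S community tables — for the full bottle grid of a
:class:`~lakesip.design.DesignSpec`, from a
:class:`~lakesip.design.TruthTable` of known decomposition rates.

Tracer propagation is exact and mass-conserving: the ¹³C excess placed
into the CO₂, DIC and biomass pools of a bottle sums to
``rate/100 x days x added ¹³C mass``, and each pool's δ¹³C comes from
linear atom-percent mixing of baseline pool carbon with 99 atom% tracer
carbon (delta-scale mixing would be wrong at this enrichment).  Running
the analysis pipeline on a noise-free dataset therefore recovers the truth
table exactly; at default noise it recovers it to within instrument
precision.  Identical seeds yield byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import gas as gasmod
from .design import DesignSpec, NoiseModel, TruthTable, default_truth
from .fate import ap_to_delta, delta_to_ap

__all__ = [
    "SyntheticDataset",
    "generate_dataset",
    "generate_community",
    "simulate_calibration",
    "pool_excesses",
    "DEFAULT_GENERA",
    "DEFAULT_DECOMPOSERS",
    "FAME_COMPOSITION",
    "TRACER_ROUTING",
]

# Baseline PLFA composition of the lake-water microbial community
# (mass fractions of total PLFA; sum to 1).
FAME_COMPOSITION = {
    "14:0": 0.05,
    "i15:0": 0.08,
    "a15:0": 0.08,
    "15:0": 0.04,
    "16:0": 0.25,
    "16:1w7": 0.15,
    "17:0": 0.03,
    "18:0": 0.05,
    "18:1w7": 0.12,
    "18:1w9": 0.08,
    "18:2w6": 0.05,
    "18:3w3": 0.02,
}

# Where assimilated tracer carbon lands, per substrate: PS carbon flows to
# gram-negative Proteobacteria/Acidobacteria markers (16:1w7, 18:1w7),
# plant litter to a wider spread including branched gram-positive markers.
TRACER_ROUTING = {
    "PS": {
        "16:1w7": 0.45,
        "18:1w7": 0.36,
        "17:0": 0.05,
        "i15:0": 0.06,
        "16:0": 0.04,
        "a15:0": 0.04,
    },
    "plant_litter": {
        "16:1w7": 0.28,
        "18:1w7": 0.22,
        "i15:0": 0.14,
        "a15:0": 0.13,
        "16:0": 0.08,
        "18:1w9": 0.07,
        "15:0": 0.06,
        "18:0": 0.02,
    },
}
TRACER_ROUTING["PE"] = TRACER_ROUTING["PS"]  # negligible flux either way

# GC-MS response per ng/ul, varying by FAME as real detectors do.
_SLOPES = {
    fame: 900.0 + 25.0 * i
    for i, fame in enumerate(list(FAME_COMPOSITION) + ["C12:0", "C19:0", "C23:0"])
}
_CAL_LEVELS = (15.0, 50.0, 100.0, 250.0)
_IS_AMOUNT_UG = 0.5
_EXTRACT_VOLUME_UL = 100.0
_HEIGHT_NA_PER_NG_UL = 0.04
_RECOVERY_MEAN, _RECOVERY_SD = 0.85, 0.05

# Background freshwater community: (genus, class, phylum, baseline weight %).
DEFAULT_GENERA = [
    ("hgcI_clade", "Actinobacteria", "Actinobacteria", 12.0),
    ("CL500-29", "Actinobacteria", "Actinobacteria", 5.0),
    ("Polynucleobacter", "Gammaproteobacteria", "Proteobacteria", 8.0),
    ("Limnohabitans", "Gammaproteobacteria", "Proteobacteria", 4.0),
    ("Pseudomonas", "Gammaproteobacteria", "Proteobacteria", 3.5),
    ("Porticoccus", "Gammaproteobacteria", "Proteobacteria", 3.0),
    ("Aquabacterium", "Gammaproteobacteria", "Proteobacteria", 3.0),
    ("Herminiimonas", "Gammaproteobacteria", "Proteobacteria", 2.5),
    ("Pelomonas", "Gammaproteobacteria", "Proteobacteria", 2.5),
    ("Cellvibrio", "Gammaproteobacteria", "Proteobacteria", 2.5),
    ("Rhodovastum", "Alphaproteobacteria", "Proteobacteria", 3.0),
    ("Sphingomonas", "Alphaproteobacteria", "Proteobacteria", 4.0),
    ("Novosphingobium", "Alphaproteobacteria", "Proteobacteria", 3.0),
    ("uncultured_Beijerinckiaceae", "Alphaproteobacteria", "Proteobacteria", 2.5),
    ("Peredibacter", "Deltaproteobacteria", "Proteobacteria", 2.5),
    ("Haliangium", "Deltaproteobacteria", "Proteobacteria", 2.5),
    ("uncultured_Blrii41", "Deltaproteobacteria", "Proteobacteria", 2.0),
    ("Opitutus", "Verrucomicrobiae", "Verrucomicrobia", 4.0),
    ("Lacunisphaera", "Verrucomicrobiae", "Verrucomicrobia", 3.0),
    ("Luteolibacter", "Verrucomicrobiae", "Verrucomicrobia", 2.5),
    ("uncultured_Pedosphaeraceae", "Verrucomicrobiae", "Verrucomicrobia", 2.5),
    ("Candidatus_Solibacter", "Acidobacteriia", "Acidobacteria", 3.0),
    ("Occallatibacter", "Acidobacteriia", "Acidobacteria", 2.0),
    ("Planctomyces", "Planctomycetacia", "Planctomycetes", 3.0),
    ("Gemmata", "Planctomycetacia", "Planctomycetes", 2.0),
    ("Flavobacterium", "Bacteroidia", "Bacteroidetes", 4.0),
    ("Mucilaginibacter", "Bacteroidia", "Bacteroidetes", 2.5),
    ("Sediminibacterium", "Bacteroidia", "Bacteroidetes", 2.5),
]

#: genus -> (baseline weight %, enrichment slope vs log rate, substrate).
DEFAULT_DECOMPOSERS = {
    "Limnohabitans": (4.0, 8.0, "PS"),
    "Rhodovastum": (3.0, 8.0, "PS"),
    "Porticoccus": (3.0, 8.0, "PS"),
    "Pseudomonas": (3.5, 8.0, "PS"),
    "Aquabacterium": (3.0, 8.0, "PS"),
    "Herminiimonas": (2.5, 8.0, "PS"),
    "uncultured_Beijerinckiaceae": (2.5, 8.0, "PS"),
    "Candidatus_Solibacter": (3.0, 8.0, "PS"),
    "Opitutus": (4.0, 8.0, "plant_litter"),
    "Lacunisphaera": (3.0, 8.0, "plant_litter"),
    "Luteolibacter": (2.5, 8.0, "plant_litter"),
    "Peredibacter": (2.5, 8.0, "plant_litter"),
    "Haliangium": (2.5, 8.0, "plant_litter"),
    "Pelomonas": (2.5, 8.0, "plant_litter"),
    "Cellvibrio": (2.5, 8.0, "plant_litter"),
    "Flavobacterium": (4.0, 8.0, "plant_litter"),
    "Mucilaginibacter": (2.5, 8.0, "plant_litter"),
}

_LOG_ABUNDANCE_SD = 0.4
#: log-abundance boost of a decomposer genus in bottles of its substrate
#: (growth on the added carbon source), on top of the rate coupling.
DEFAULT_TREATMENT_BOOST = float(np.log(2.5))


@dataclass
class SyntheticDataset:
    """All measurement tables of one synthetic experiment plus its truth."""

    design: DesignSpec
    truth: TruthTable
    metadata: pd.DataFrame
    gas: pd.DataFrame
    isotopes: pd.DataFrame
    fame_peaks: pd.DataFrame
    calibration: pd.DataFrame
    otu: pd.DataFrame
    taxonomy: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        """Write every table as TSV into ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
        self.gas.to_csv(out / "gas.tsv", sep="\t", index=False)
        self.isotopes.to_csv(out / "isotopes.tsv", sep="\t", index=False)
        self.fame_peaks.to_csv(out / "fame_peaks.tsv", sep="\t", index=False)
        self.calibration.to_csv(out / "calibration.tsv", sep="\t", index=False)
        self.otu.to_csv(out / "otu.tsv", sep="\t")
        self.taxonomy.to_csv(out / "taxonomy.tsv", sep="\t", index=False)
        self.truth.cells.to_csv(out / "truth.tsv", sep="\t", index=False)


def pool_excesses(rate: float, mineralized_fraction: float, co2_fraction: float,
                  days: float, added_13c_mg: float) -> dict[str, float]:
    """¹³C excess mass (mg) routed to each pool over the incubation.

    The three entries sum to ``rate/100 x days x added_13c_mg`` exactly —
    the mass-conservation contract the generator is built on.
    """
    total = rate / 100.0 * days * added_13c_mg
    resp = total * mineralized_fraction
    return {
        "CO2": resp * co2_fraction,
        "DIC": resp * (1.0 - co2_fraction),
        "biomass": total - resp,
    }


def _mix_ap(m_base: float, ap_base: float, m_tracer: float, ap_tracer: float) -> float:
    """Exact two-source atom-percent mixing."""
    if m_base + m_tracer <= 0:
        raise ValueError("mixing requires positive total mass")
    return (m_base * ap_base + m_tracer * ap_tracer) / (m_base + m_tracer)


def generate_dataset(
    design: DesignSpec | None = None,
    truth: TruthTable | None = None,
    seed: int | None = None,
    constants: gasmod.GasConstants = gasmod.GasConstants(),
    decomposer_spec: dict | None = None,
) -> SyntheticDataset:
    """Generate a full synthetic dataset for ``design`` under ``truth``.

    ``seed`` overrides ``design.seed``.  Control bottles receive zero
    tracer.  See the module docstring for the propagation model.
    """
    design = design or DesignSpec()
    truth = truth if truth is not None else default_truth(design)
    truth.validate_against(design)
    rng = np.random.default_rng(design.seed if seed is None else seed)
    noise = truth.noise
    ap_tracer = design.tracer_atom_percent
    ap_base = {pool: delta_to_ap(d) for pool, d in truth.baseline_delta.items()}

    metadata = design.bottles()
    metadata["extract_volume_ul"] = _EXTRACT_VOLUME_UL
    metadata["is_amount_ug"] = _IS_AMOUNT_UG

    days = design.sampling_days()
    headspace_l = design.headspace_volume_l
    gas_rows, iso_rows, peak_rows, filter_c = [], [], [], []
    for row in metadata.itertuples(index=False):
        t_inc_k = row.temperature_c + 273.15
        v_std = gasmod.standardize_volume(
            constants.v_sample, t_inc_k, constants.t_measurement_k
        )
        labelled = row.substrate != design.control
        if labelled:
            cell = truth.cell(row.lake, row.season, row.substrate)
            excess = pool_excesses(
                cell["decomposition_rate"],
                cell["mineralized_fraction"],
                cell["co2_fraction"],
                row.incubation_days,
                row.added_13c_mg,
            )
            resp = cell["baseline_respiration"]
        else:
            cell_rows = truth.cells[
                (truth.cells["lake"] == row.lake) & (truth.cells["season"] == row.season)
            ]
            resp = float(cell_rows["baseline_respiration"].iloc[0])
            excess = {"CO2": 0.0, "DIC": 0.0, "biomass": 0.0}
        # tracer carbon mass that produces the target measurable excess
        m_tracer = {
            pool: excess[pool] / ((ap_tracer - ap_base[_BASE[pool]]) / 100.0)
            for pool in excess
        }

        # --- headspace CO2 time series -------------------------------------
        ambient = (
            gasmod.headspace_carbon(truth.ambient_co2_ppm, constants, v_sample=v_std).c_c_mg_per_l
            * headspace_l
        )
        for day in days:
            m_co2 = (
                ambient
                + resp * row.water_volume_l * day
                + m_tracer["CO2"] * day / row.incubation_days
            )
            ppm = gasmod.ppm_from_concentration(m_co2 / headspace_l, constants, v_sample=v_std)
            ppm *= 1.0 + noise.tcd_rel * rng.standard_normal()
            gas_rows.append({"bottle": row.bottle, "day": day, "gas": "CO2", "ppm": max(ppm, 0.0)})

        # --- DIC (end of incubation) ---------------------------------------
        m_dic_base = truth.dic_mg_per_l * row.water_volume_l
        m_dic = m_dic_base + m_tracer["DIC"]
        ppm_dic = gasmod.ppm_from_concentration(m_dic / row.water_volume_l, constants, v_sample=v_std)
        ppm_dic *= 1.0 + noise.tcd_rel * rng.standard_normal()
        gas_rows.append(
            {"bottle": row.bottle, "day": row.incubation_days, "gas": "DIC", "ppm": max(ppm_dic, 0.0)}
        )

        # --- pool delta13C --------------------------------------------------
        m_co2_base_end = ambient + resp * row.water_volume_l * row.incubation_days
        m_bio_base = truth.biomass_mg_per_l * row.water_volume_l
        for pool, m_base in (
            ("CO2", m_co2_base_end),
            ("DIC", m_dic_base),
            ("biomass", m_bio_base),
        ):
            ap = _mix_ap(m_base, ap_base[_BASE[pool]], m_tracer[pool], ap_tracer)
            sd = noise.delta_plfa_permil if pool == "biomass" else noise.delta_gas_permil
            iso_rows.append(
                {
                    "bottle": row.bottle,
                    "pool": pool,
                    "delta13c": ap_to_delta(ap) + sd * rng.standard_normal(),
                }
            )

        # --- per-FAME delta13C and GC-MS peaks ------------------------------
        routing = TRACER_ROUTING.get(row.substrate, TRACER_ROUTING["PS"])
        aliquot = row.filtered_volume_ml / (row.water_volume_l * 1000.0)
        recovery = float(np.clip(rng.normal(_RECOVERY_MEAN, _RECOVERY_SD), 0.5, 1.0))
        m_bio_filter = 0.0
        for fame, frac in FAME_COMPOSITION.items():
            b_i = m_bio_base * frac
            tr_i = m_tracer["biomass"] * routing.get(fame, 0.0)
            ap_i = _mix_ap(b_i, ap_base["PLFA"], tr_i, ap_tracer)
            iso_rows.append(
                {
                    "bottle": row.bottle,
                    "pool": f"PLFA:{fame}",
                    "delta13c": ap_to_delta(ap_i) + noise.delta_plfa_permil * rng.standard_normal(),
                }
            )
            fame_c_filter = (b_i + tr_i) * aliquot
            m_bio_filter += fame_c_filter
            plfa_ug = fame_c_filter / 25.0 * 1000.0
            conc = plfa_ug * 1000.0 / _EXTRACT_VOLUME_UL * recovery  # ng/ul as measured
            sd = noise.fame_ng_ul * conc / 100.0  # proportional instrument noise
            response = _SLOPES[fame] * (conc + sd * rng.standard_normal())
            peak_rows.append(
                {
                    "bottle": row.bottle,
                    "fame": fame,
                    "response": max(response, 0.0),
                    "height_na": _HEIGHT_NA_PER_NG_UL * conc,
                }
            )
        for std in ("C12:0", "C19:0", "C23:0"):
            conc = _IS_AMOUNT_UG * 1000.0 / _EXTRACT_VOLUME_UL * recovery
            sd = noise.fame_ng_ul * conc / 100.0
            response = _SLOPES[std] * (conc + sd * rng.standard_normal())
            peak_rows.append(
                {
                    "bottle": row.bottle,
                    "fame": std,
                    "response": max(response, 0.0),
                    "height_na": _HEIGHT_NA_PER_NG_UL * conc,
                }
            )
        filter_c.append(
            truth.detritus_mg_per_l * row.filtered_volume_ml / 1000.0 + m_bio_filter
        )
    metadata["filter_carbon_mg"] = filter_c

    calibration = simulate_calibration(noise, rng=rng)

    otu, taxonomy = generate_community(
        design,
        decomposer_spec if decomposer_spec is not None else DEFAULT_DECOMPOSERS,
        truth=truth,
        rng=rng,
    )
    return SyntheticDataset(
        design=design,
        truth=truth,
        metadata=metadata,
        gas=pd.DataFrame(gas_rows),
        isotopes=pd.DataFrame(iso_rows),
        fame_peaks=pd.DataFrame(peak_rows),
        calibration=calibration,
        otu=otu,
        taxonomy=taxonomy,
    )


_BASE = {"CO2": "CO2", "DIC": "DIC", "biomass": "PLFA"}


def simulate_calibration(
    noise: "NoiseModel | None" = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Four-point FAME calibration standards with instrument noise.

    One run of the standard mixture at 15, 50, 100 and 250 ng/µl for every
    FAME (internal standards included); the detector response carries the
    noise model's FAME noise, expressed in concentration units.
    """
    noise = noise if noise is not None else NoiseModel()
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for fame, slope in _SLOPES.items():
        for level in _CAL_LEVELS:
            sd = noise.fame_ng_ul * level / 100.0
            response = slope * (level + sd * rng.standard_normal())
            rows.append({"fame": fame, "conc_ng_ul": level, "response": max(response, 0.0)})
    return pd.DataFrame(rows)


def generate_community(
    design: DesignSpec | None = None,
    decomposer_spec: dict | None = None,
    truth: TruthTable | None = None,
    background: list[tuple] | None = None,
    depth: int = 4000,
    treatment_boost: float = DEFAULT_TREATMENT_BOOST,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genus-level count table (genera x bottles) plus taxonomy sidecar.

    Counts follow a compositional model: log-normal relative abundances
    drawn per bottle, then a multinomial of ``depth`` reads (default 4000,
    so every bottle's counts sum exactly to the rarefaction depth used in
    the analysis).  Genera in ``decomposer_spec`` — mapping genus to
    ``(baseline weight, slope)`` or ``(baseline weight, slope, substrate)``
    — have their log abundance shifted by ``slope x log(rate / seasonal
    mean rate)`` in bottles of their substrate, coupling them positively
    to that bottle's true decomposition rate, plus a flat
    ``treatment_boost`` (log units) representing growth on the added
    substrate relative to unamended controls.
    """
    design = design or DesignSpec()
    truth = truth if truth is not None else default_truth(design)
    if rng is None:
        rng = np.random.default_rng(design.seed if seed is None else seed)
    background = background if background is not None else DEFAULT_GENERA
    decomposer_spec = decomposer_spec or {}

    genera: dict[str, dict] = {}
    for genus, cls, phylum, weight in background:
        genera[genus] = {"class": cls, "phylum": phylum, "weight": weight, "slope": 0.0, "substrate": None}
    for genus, spec in decomposer_spec.items():
        if len(spec) == 2:
            weight, slope = spec
            substrate = None
        else:
            weight, slope, substrate = spec
        entry = genera.setdefault(
            genus, {"class": "unknown", "phylum": "unknown", "weight": weight, "slope": 0.0, "substrate": None}
        )
        entry.update(weight=weight, slope=slope, substrate=substrate)

    names = list(genera)
    weights = np.array([genera[g]["weight"] for g in names], dtype=float)
    if np.any(weights <= 0):
        raise ValueError("baseline abundances must be positive")
    if len(names) < 10 or len({genera[g]["class"] for g in names}) < 3:
        raise ValueError("community model needs >= 10 genera spanning >= 3 classes")
    if depth < len(names):
        raise ValueError(f"depth {depth} is below the number of genera ({len(names)})")

    season_mean = truth.cells.groupby(["season", "substrate"])["decomposition_rate"].mean()
    slopes = np.array([genera[g]["slope"] for g in names])
    substrates = [genera[g]["substrate"] for g in names]

    counts = {}
    for row in design.bottles().itertuples(index=False):
        mu = np.log(weights).copy()
        if row.substrate != design.control:
            cell = truth.cell(row.lake, row.season, row.substrate)
            rate = cell["decomposition_rate"]
            ref = season_mean.loc[(row.season, row.substrate)]
            shift = np.log(rate / ref) if (rate > 0 and ref > 0) else 0.0
            for i, sub in enumerate(substrates):
                if slopes[i] != 0.0 and sub in (None, row.substrate):
                    mu[i] += slopes[i] * shift + treatment_boost
        log_abund = mu + _LOG_ABUNDANCE_SD * rng.standard_normal(len(names))
        p = np.exp(log_abund - log_abund.max())
        counts[row.bottle] = rng.multinomial(depth, p / p.sum())

    otu = pd.DataFrame(counts, index=pd.Index(names, name="genus"))
    taxonomy = pd.DataFrame(
        {
            "genus": names,
            "class": [genera[g]["class"] for g in names],
            "phylum": [genera[g]["phylum"] for g in names],
        }
    )
    return otu, taxonomy
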