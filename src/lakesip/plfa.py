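"""PLFA quantification: calibration, recovery, biomass and ¹³C enrichment.

Phospholipid-derived fatty acids (PLFAs) are a viable-biomass biomarker;
their methyl esters (FAMEs) are quantified by GC-MS against four-point
calibration curves (15, 50, 100, 250 ng/µl) which must show a Pearson
correlation above 0.99 to be accepted.  Extraction losses are corrected
with internal standards (C19:0 primary, C12:0/C23:0 fallbacks).  Because
PLFAs make up about 4% of bacterial biomass, total PLFA carbon x 25 gives
total microbial biomass.  Compound-specific isotope analysis (CSIA)
compares per-PLFA δ¹³C between substrate treatments and unamended
controls; chromatographic peaks below 0.015 nA are excluded as
sub-detection.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BIOMASS_FACTOR",
    "CALIBRATION_LEVELS_NG_UL",
    "MIN_CALIBRATION_R",
    "MIN_PEAK_HEIGHT_NA",
    "INTERNAL_STANDARDS",
    "CalibrationCurve",
    "fit_calibration",
    "fit_calibration_table",
    "quantify_profiles",
    "csia_enrichment",
    "enrichment_matrix",
    "load_biomarkers",
]

#: PLFAs are ~4% of bacterial biomass, hence biomass = total PLFA x 25.
BIOMASS_FACTOR = 25.0
CALIBRATION_LEVELS_NG_UL = (15.0, 50.0, 100.0, 250.0)
MIN_CALIBRATION_R = 0.99
MIN_PEAK_HEIGHT_NA = 0.015
#: Internal standards in priority order for the recovery correction.
INTERNAL_STANDARDS = ("C19:0", "C12:0", "C23:0")


@dataclass(frozen=True)
class CalibrationCurve:
    """Least-squares line mapping instrument response to ng/µl."""

    fame: str
    slope: float
    intercept: float
    pearson_r: float
    n_points: int

    @property
    def ok(self) -> bool:
        """Quantification is blocked unless r exceeds 0.99."""
        return self.pearson_r > MIN_CALIBRATION_R

    def concentration(self, response) -> np.ndarray:
        return self.slope * np.asarray(response, dtype=float) + self.intercept


def fit_calibration(conc_ng_ul, response, fame: str = "") -> CalibrationCurve:
    """Fit a calibration line (response -> concentration) by OLS."""
    x = np.asarray(response, dtype=float)
    y = np.asarray(conc_ng_ul, dtype=float)
    if x.size < 2 or y.size != x.size:
        raise ValueError("need at least two (concentration, response) points")
    if np.unique(x).size < 2:
        raise ValueError(f"calibration for {fame!r} has identical responses")
    fit = stats.linregress(x, y)
    return CalibrationCurve(
        fame=fame,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        n_points=int(x.size),
    )


def fit_calibration_table(calibration: pd.DataFrame) -> dict[str, CalibrationCurve]:
    """Fit one curve per FAME from a long (fame, conc_ng_ul, response) table."""
    required = {"fame", "conc_ng_ul", "response"}
    if not required <= set(calibration.columns):
        raise ValueError(f"calibration table must have columns {sorted(required)}")
    curves = {}
    for fame, grp in calibration.groupby("fame", sort=False):
        curves[fame] = fit_calibration(grp["conc_ng_ul"], grp["response"], fame=fame)
    return curves


def quantify_profiles(
    peaks: pd.DataFrame,
    curves: dict[str, CalibrationCurve],
    metadata: pd.DataFrame,
    is_amount_ug: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify per-bottle PLFA profiles and derive microbial biomass.

    Parameters
    ----------
    peaks
        Long table ``bottle``, ``fame``, ``response`` (``height_na``
        optional, carried through for the CSIA detection filter).
    curves
        Calibration curves per FAME; curves failing the r > 0.99 gate are
        excluded from quantification with a warning.
    metadata
        Must carry ``filter_carbon_mg`` (particulate carbon on the PLFA
        filter), ``extract_volume_ul``, ``filtered_volume_ml`` and
        ``water_volume_l`` per bottle.
    is_amount_ug
        Amount of each internal standard added per sample.

    Returns ``(profile, summary)``: the per-bottle per-FAME concentrations
    (mg per g of filter carbon, recovery-corrected) and a per-bottle
    summary with the recovery factor, total PLFA, biomass (total x 25) and
    the whole-bottle biomass carbon mass ``m_biomass_mg`` used by the
    assimilation mass balance.
    """
    required = {"bottle", "fame", "response"}
    if not required <= set(peaks.columns):
        raise ValueError(f"peaks table must have columns {sorted(required)}")
    bad = sorted(f for f, c in curves.items() if not c.ok)
    if bad:
        warnings.warn(
            f"calibration r <= {MIN_CALIBRATION_R} for {bad}; excluded from quantification",
            stacklevel=2,
        )
    meta = metadata.set_index("bottle")

    profile_rows = []
    summary_rows = []
    for bottle, grp in peaks.groupby("bottle", sort=False):
        m = meta.loc[bottle]
        grp = grp.set_index("fame")
        measured_ug = {}
        for fame, row in grp.iterrows():
            curve = curves.get(fame)
            if curve is None or not curve.ok:
                continue
            conc = float(curve.concentration(row["response"]))
            measured_ug[fame] = max(conc, 0.0) * m["extract_volume_ul"] / 1000.0

        recovery = np.nan
        used_standard = None
        for std in INTERNAL_STANDARDS:
            if std in measured_ug and measured_ug[std] > 0:
                recovery = measured_ug[std] / is_amount_ug
                used_standard = std
                break
        if used_standard is None:
            raise ValueError(f"bottle {bottle!r}: no internal standard detected")

        filter_c_g = m["filter_carbon_mg"] / 1000.0
        total_ug = 0.0
        for fame, ug in measured_ug.items():
            if fame in INTERNAL_STANDARDS:
                continue
            corrected_ug = ug / recovery
            total_ug += corrected_ug
            profile_rows.append(
                {
                    "bottle": bottle,
                    "fame": fame,
                    "amount_ug": corrected_ug,
                    "conc_mg_per_g_c": corrected_ug / 1000.0 / filter_c_g,
                    "height_na": float(grp.loc[fame].get("height_na", np.nan)),
                }
            )
        total_mg_per_g_c = total_ug / 1000.0 / filter_c_g
        # scale the filtered aliquot back to the whole bottle
        aliquot = m["water_volume_l"] * 1000.0 / m["filtered_volume_ml"]
        summary_rows.append(
            {
                "bottle": bottle,
                "recovery": recovery,
                "internal_standard": used_standard,
                "total_plfa_mg_per_g_c": total_mg_per_g_c,
                "biomass_mg_per_g_c": total_mg_per_g_c * BIOMASS_FACTOR,
                "m_biomass_mg": total_ug / 1000.0 * BIOMASS_FACTOR * aliquot,
            }
        )
    return pd.DataFrame(profile_rows), pd.DataFrame(summary_rows)


def csia_enrichment(
    isotopes: pd.DataFrame,
    peaks: pd.DataFrame,
    metadata: pd.DataFrame,
    control: str = "control",
    min_height_na: float = MIN_PEAK_HEIGHT_NA,
) -> pd.DataFrame:
    """Per-PLFA ¹³C enrichment of each treatment over matched controls.

    Δδ¹³C = mean(treatment δ¹³C) − mean(control δ¹³C) per PLFA within a
    (lake, season) cell.  δ values whose chromatographic peak height is at
    or below ``min_height_na`` are dropped before averaging; PLFAs absent
    from the matched controls are reported with a missing (NaN) value, not
    zero.
    """
    iso = isotopes[isotopes["pool"].str.startswith("PLFA:")].copy()
    if iso.empty:
        raise ValueError("no per-PLFA isotope records (pool 'PLFA:<name>')")
    iso["fame"] = iso["pool"].str.removeprefix("PLFA:")
    if "height_na" in peaks.columns:
        iso = iso.merge(peaks[["bottle", "fame", "height_na"]], on=["bottle", "fame"], how="left")
        iso = iso[iso["height_na"].isna() | (iso["height_na"] > min_height_na)]
    iso = iso.merge(metadata[["bottle", "lake", "season", "substrate"]], on="bottle")

    means = (
        iso.groupby(["lake", "season", "substrate", "fame"])["delta13c"].mean().reset_index()
    )
    ctl = means[means["substrate"] == control].set_index(["lake", "season", "fame"])["delta13c"]
    trt = means[means["substrate"] != control].copy()
    key = pd.MultiIndex.from_frame(trt[["lake", "season", "fame"]])
    trt["delta_enrichment"] = trt["delta13c"].to_numpy() - ctl.reindex(key).to_numpy()
    return trt[["lake", "season", "substrate", "fame", "delta_enrichment"]].reset_index(drop=True)


def enrichment_matrix(enrichment: pd.DataFrame) -> pd.DataFrame:
    """Pivot enrichment to a PLFA x (substrate, season) heatmap matrix."""
    return enrichment.pivot_table(
        index="fame", columns=["substrate", "season"], values="delta_enrichment", aggfunc="mean"
    )


def load_biomarkers() -> pd.DataFrame:
    """PLFA -> taxon-group biomarker map shipped with the package.

    Warns about 18:1w9, which is characteristic of both fungi and
    Planctomycetes and should be interpreted with caution.
    """
    path = importlib.resources.files("lakesip").joinpath("data/biomarkers.tsv")
    with importlib.resources.as_file(path) as p:
        table = pd.read_csv(p, sep="\t", comment="#")
    ambiguous = table[table["ambiguous"]]
    if not ambiguous.empty:
        warnings.warn(
            "ambiguous biomarker(s) "
            + ", ".join(ambiguous["fame"])
            + ": assignable to more than one taxon group",
            stacklevel=2,
        )
    return table
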