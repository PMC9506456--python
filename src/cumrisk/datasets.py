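"""Bundled scallion field-study tables.

These loaders return the published input data of a supervised residue study
of the co-formulated fungicides metalaxyl-M and azoxystrobin on scallion:
final-residue measurements at two pre-harvest intervals across four Chinese
trial sites, liver-toxicity NOAELs, multi-crop residue screening values per
food category, and the applicable maximum residue limits.  They are the
reference inputs for the worked examples and the acceptance checks.

Site half-life metadata (reported, not recomputable from the bundled
final-residue table alone) is exposed via :data:`REPORTED_HALF_LIVES`.
"""

from __future__ import annotations

from .residues import MrlRecord, ResidueObservation
from .rpf import CategoryResidue, ToxProfile

__all__ = [
    "load_scallion_residues",
    "load_tox_profiles",
    "load_category_residues",
    "load_mrl_table",
    "load_calibration_curves",
    "REPORTED_HALF_LIVES",
    "LOQ_MG_KG",
]

#: analytical limit of quantification for both compounds in scallion (mg/kg)
LOQ_MG_KG = 0.001

#: reported first-order half-lives (days) per analyte × site — reference
#: metadata only; the underlying dissipation time-series is not bundled.
REPORTED_HALF_LIVES = {
    ("metalaxyl-M", "Shandong"): 1.15,
    ("metalaxyl-M", "Guizhou"): 1.06,
    ("azoxystrobin", "Shandong"): 2.28,
    ("azoxystrobin", "Guizhou"): 3.89,
}

# (site, interval_days, replicate-1, replicate-2); "<" marks below-LOQ
_FINAL_RESIDUES = {
    "metalaxyl-M": [
        ("Beijing", 7, 0.003, 0.003),
        ("Beijing", 10, 0.005, 0.004),
        ("Shandong", 7, 0.002, 0.002),
        ("Shandong", 10, 0.003, 0.002),
        ("Guizhou", 7, "<", "<"),
        ("Guizhou", 10, "<", "<"),
        ("Hunan", 7, 0.082, 0.088),
        ("Hunan", 10, 0.049, 0.049),
    ],
    "azoxystrobin": [
        ("Beijing", 7, 0.363, 0.190),
        ("Beijing", 10, 0.377, 0.492),
        ("Shandong", 7, 1.420, 1.360),
        ("Shandong", 10, 0.071, 0.043),
        ("Guizhou", 7, 0.314, 0.326),
        ("Guizhou", 10, 0.350, 0.334),
        ("Hunan", 7, 4.687, 4.687),
        ("Hunan", 10, 4.368, 4.203),
    ],
}


def load_scallion_residues() -> list[ResidueObservation]:
    """Final scallion residues: 2 analytes × 4 sites × {7, 10} d × 2 replicates.

    Below-LOQ entries are returned censored with the LOQ (0.001 mg/kg) as
    the concentration surrogate.
    """
    out: list[ResidueObservation] = []
    for analyte, rows in _FINAL_RESIDUES.items():
        for site, interval, *reps in rows:
            for value in reps:
                censored = value == "<"
                out.append(
                    ResidueObservation(
                        analyte=analyte,
                        site=site,
                        interval_days=interval,
                        concentration=LOQ_MG_KG if censored else float(value),
                        below_loq=censored,
                        loq=LOQ_MG_KG,
                    )
                )
    return out


def load_tox_profiles() -> list[ToxProfile]:
    """Liver-toxicity NOAELs (mg/kg bw/day) with azoxystrobin as index compound.

    Azoxystrobin is the index despite being the less toxic compound: it has
    far more residue data and higher residues across crops, which minimizes
    the uncertainty of the cumulation.
    """
    return [
        ToxProfile(compound="metalaxyl-M", noael=8.0, is_index=False),
        ToxProfile(compound="azoxystrobin", noael=18.2, is_index=True),
    ]


def load_category_residues() -> list[CategoryResidue]:
    """Per-food-category screening residues (STMR and HR, mg/kg).

    Each category carries the residue of the crop with the largest residues
    in that category (risk-maximizing extrapolation).  Compounds without
    data in a category are simply absent (structural zero).  Scallion enters
    under the condiments/soy-sauce category.
    """
    rows = [
        # (category, compound, crop, stmr, hr)
        ("Rice and products", "azoxystrobin", "Rice", 0.160, 0.230),
        ("Flour and products", "azoxystrobin", "Wheat", 0.023, 0.180),
        ("Other cereals", "metalaxyl-M", "Corn", 0.020, 0.020),
        ("Other cereals", "azoxystrobin", "Corn", 0.005, 0.005),
        ("Potatoes and products", "metalaxyl-M", "Potato", 0.011, 0.039),
        ("Potatoes and products", "azoxystrobin", "Potato", 0.020, 0.020),
        ("Legumes and products", "metalaxyl-M", "Soybean", 0.020, 0.020),
        ("Legumes and products", "azoxystrobin", "Soybean", 0.200, 0.265),
        ("Dark vegetables", "metalaxyl-M", "Tomato", 0.034, 0.051),
        ("Dark vegetables", "azoxystrobin", "Water spinach", 0.920, 4.000),
        ("Light vegetables", "metalaxyl-M", "Cauliflower", 0.109, 0.454),
        ("Light vegetables", "azoxystrobin", "Loofah", 0.240, 0.540),
        ("Fruits", "metalaxyl-M", "Watermelon", 0.010, 0.010),
        ("Fruits", "azoxystrobin", "Grape", 0.700, 3.220),
        ("Vegetable oil", "azoxystrobin", "Peanut", 0.050, 0.160),
        ("Soy sauce", "metalaxyl-M", "Scallion", 0.0025, 0.088),
        ("Soy sauce", "azoxystrobin", "Scallion", 0.861, 4.687),
    ]
    return [
        CategoryResidue(category=c, compound=p, stmr=s, hr=h, source_crop=crop)
        for c, p, crop, s, h in rows
    ]


def load_mrl_table() -> list[MrlRecord]:
    """Maximum residue limits applicable to scallion/green-onion commodities."""
    rows = [
        ("azoxystrobin", "China", "scallion", 7.0),
        ("azoxystrobin", "EU", "Welsh onion", 10.0),
        ("azoxystrobin", "US", "onion, green, subgroup 3-07B", 7.5),
        ("metalaxyl-M", "EU", "Welsh onion", 0.3),
        ("metalaxyl-M", "US", "onion, green, subgroup 3-07B", 10.0),
    ]
    return [
        MrlRecord(analyte=a, jurisdiction=j, commodity=c, mrl=m)
        for a, j, c, m in rows
    ]


def load_calibration_curves() -> dict[tuple[str, str], "CalibrationCurve"]:
    """Solvent and scallion-matrix calibration curves for both compounds.

    Keyed by (analyte, medium); the matrix-vs-solvent slope ratios quantify
    the strong ionization suppression the scallion matrix causes.
    """
    from .validation import CalibrationCurve

    specs = [
        ("metalaxyl-M", "solvent", 175194.0, 4646.8, 0.9919),
        ("metalaxyl-M", "matrix", 71002.0, 149.65, 0.9996),
        ("azoxystrobin", "solvent", 505999.0, 9186.5, 0.9946),
        ("azoxystrobin", "matrix", 237639.0, 1759.7, 0.9983),
    ]
    return {
        (a, m): CalibrationCurve(analyte=a, medium=m, slope=s, intercept=i, r_squared=r)
        for a, m, s, i, r in specs
    }
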