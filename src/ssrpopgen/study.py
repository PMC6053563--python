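"""Reference values for the motivating study system.

The package was built around a survey of two *Prosopis* species
(*P. rubriflora* and *P. ruscifolia*) genotyped at 10–11 SSR loci across 11
chaquenian (stepic savanna) sampling areas each. The raw genotypes are not
public, but the published per-area summary tables, global F-statistics and
sampling coordinates are, and they serve as worked-example inputs: table
arithmetic (column means, effective-allele percentages, island-model gene
flow from the global FST) can be recomputed and checked against the printed
values without the genotypes.

Coordinates are the published DMS strings; distances derive from them via
:func:`ssrpopgen.core.great_circle_km`.
"""

from __future__ import annotations

import pandas as pd

from .core import AreaMetadata, parse_dms

__all__ = [
    "RUBRIFLORA_AREAS",
    "RUSCIFOLIA_AREAS",
    "RUBRIFLORA_SUMMARY",
    "RUSCIFOLIA_SUMMARY",
    "GLOBAL_FSTATS",
    "area_metadata",
]

# label -> (preservation, lon DMS, lat DMS)
RUBRIFLORA_AREAS: dict[str, tuple[str, str, str]] = {
    "AAL": ("conserved-intermediate", "55°44′17″W", "20°48′05″S"),
    "FPT1": ("intermediate", "57°42′11″W", "21°42′09″S"),
    "FPT2": ("conserved", "57°43′16″W", "21°41′21″S"),
    "FSC": ("disturbed-conserved", "57°48′36″W", "21°34′35″S"),
    "RMS": ("disturbed-intermediate", "57°33′44″W", "21°44′57″S"),
    "FTR1": ("conserved-intermediate", "57°46′43″W", "21°24′42″S"),
    "FTR2": ("disturbed-conserved", "57°49′59″W", "21°28′40″S"),
    "FRC1": ("disturbed-intermediate", "57°45′49″W", "21°42′08″S"),
    "FRC2": ("conserved", "57°46′43″W", "21°41′05″S"),
    "FSM": ("intermediate", "57°39′34″W", "21°47′50″S"),
    "FSV": ("conserved-intermediate", "57°50′01″W", "21°06′42″S"),
}

RUSCIFOLIA_AREAS: dict[str, tuple[str, str, str]] = {
    "EPM": ("intermediate", "57°53′10″W", "21°42′31″S"),
    "FQB": ("disturbed", "57°54′11″W", "21°51′06″S"),
    "ROE": ("intermediate", "57°50′14″W", "21°54′34″S"),
    "FFL": ("conserved-intermediate", "57°53′53″W", "20°42′52″S"),
    "CJR": ("intermediate", "57°49′54″W", "21°39′17″S"),
    "NSA": ("intermediate", "57°49′51″W", "21°39′16″S"),
    "FSC": ("disturbed-conserved", "57°48′36″W", "21°34′35″S"),
    "ECD": ("disturbed", "57°10′14″W", "19°48′34″S"),
    "FRC1": ("disturbed-intermediate", "57°45′49″W", "21°42′08″S"),
    "FTR1": ("conserved-intermediate", "57°46′43″W", "21°24′42″S"),
    "FTR2": ("disturbed-conserved", "57°49′59″W", "21°28′40″S"),
}


def area_metadata(species: str = "rubriflora") -> list[AreaMetadata]:
    """Published sampling areas as :class:`AreaMetadata` records."""
    table = RUBRIFLORA_AREAS if species == "rubriflora" else RUSCIFOLIA_AREAS
    return [
        AreaMetadata(
            label=label,
            preservation=pres,
            latitude=parse_dms(lat),
            longitude=parse_dms(lon),
        )
        for label, (pres, lon, lat) in table.items()
    ]


def _summary(records) -> pd.DataFrame:
    cols = ["N", "k", "A_ri", "A_e", "A_e_pct", "A_p", "A_r", "Ho", "He", "FIS", "t_a", "Ne", "Ne_over_N"]
    return pd.DataFrame.from_dict(records, orient="index", columns=cols)


#: Published per-area diversity table, P. rubriflora (10 SSR loci, 11 areas).
RUBRIFLORA_SUMMARY = _summary(
    {
        "AAL": (20, 41, 3.9, 23.35, 57, 1, 11, 0.40, 0.49, 0.17, 0.74, 8.91, 0.45),
        "FPT1": (20, 57, 5.5, 31.14, 55, 1, 14, 0.57, 0.59, 0.02, 0.87, 11.79, 0.59),
        "FPT2": (20, 56, 5.4, 33.54, 60, 0, 15, 0.59, 0.61, 0.03, 0.92, 11.65, 0.58),
        "FSC": (25, 60, 5.4, 34.88, 58, 0, 17, 0.64, 0.61, -0.08, 0.96, 14.28, 0.57),
        "RMS": (27, 71, 6.1, 36.13, 51, 6, 23, 0.62, 0.64, 0.05, 0.90, 13.12, 0.49),
        "FTR1": (30, 66, 5.6, 31.33, 47, 1, 23, 0.61, 0.60, -0.03, 0.92, 15.10, 0.50),
        "FTR2": (16, 53, 5.3, 34.29, 65, 0, 12, 0.57, 0.60, 0.10, 0.78, 9.19, 0.57),
        "FRC1": (22, 61, 5.6, 30.53, 50, 0, 19, 0.53, 0.57, 0.05, 0.86, 11.64, 0.53),
        "FRC2": (22, 53, 5.0, 29.08, 55, 0, 12, 0.52, 0.55, 0.09, 0.80, 11.21, 0.51),
        "FSM": (19, 58, 5.5, 32.20, 55, 1, 15, 0.55, 0.58, 0.06, 0.87, 11.17, 0.59),
        "FSV": (20, 64, 6.0, 35.80, 56, 2, 20, 0.58, 0.61, 0.08, 0.84, 11.12, 0.56),
    }
)

#: Published per-area diversity table, P. ruscifolia (11 SSR loci, 11 areas).
RUSCIFOLIA_SUMMARY = _summary(
    {
        "EPM": (20, 50, 4.4, 30.51, 61, 1, 8, 0.46, 0.54, 0.16, 0.76, 8.81, 0.44),
        "FQB": (30, 80, 6.6, 46.86, 59, 7, 25, 0.56, 0.64, 0.17, 0.70, 11.84, 0.39),
        "ROE": (30, 67, 5.4, 36.37, 54, 2, 21, 0.60, 0.63, 0.01, 0.86, 14.22, 0.47),
        "FFL": (30, 87, 6.8, 46.99, 54, 8, 32, 0.53, 0.64, 0.17, 0.71, 13.74, 0.46),
        "CJR": (30, 69, 5.5, 40.19, 58, 2, 19, 0.49, 0.59, 0.17, 0.73, 11.80, 0.40),
        "NSA": (30, 68, 5.4, 35.26, 52, 0, 24, 0.56, 0.59, 0.04, 0.86, 12.72, 0.44),
        "FSC": (30, 62, 5.0, 34.30, 55, 1, 16, 0.56, 0.58, 0.01, 0.89, 14.28, 0.49),
        "ECD": (23, 72, 6.2, 44.19, 61, 5, 25, 0.48, 0.67, 0.28, 0.57, 7.06, 0.31),
        "FRC1": (25, 59, 5.1, 36.67, 62, 0, 13, 0.46, 0.55, 0.16, 0.75, 11.10, 0.44),
        "FTR1": (30, 66, 5.4, 42.06, 64, 3, 17, 0.51, 0.59, 0.10, 0.79, 13.28, 0.46),
        "FTR2": (30, 61, 5.2, 38.70, 63, 2, 14, 0.54, 0.60, 0.06, 0.84, 13.08, 0.44),
    }
)

#: Published global Weir–Cockerham estimates per species.
GLOBAL_FSTATS = pd.DataFrame(
    {
        "rubriflora": {"FIS": 0.042, "FST": 0.057, "FIT": 0.097},
        "ruscifolia": {"FIS": 0.138, "FST": 0.042, "FIT": 0.174},
    }
)

#: Number of sampled areas per species in the study design.
N_AREAS = 11
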