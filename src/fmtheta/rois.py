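"""Canonical region-of-interest vocabulary for the morphometry tables.

Gray-matter regions are the putative frontal-midline theta generators
(midcingulate cortex plus superior/middle/inferior frontal cortices from the
AAL atlas); white-matter regions are the tracts thought to carry the signal
(cingulate bundle, superior longitudinal fascicle II, anterior and superior
corona radiata, from the JHU tractography atlas).  Each region appears for
both hemispheres and with two measures: ``vol`` (modulated tissue volume,
arbitrary units, > 0) and ``conc`` (tissue concentration / probability, in
[0, 1]) -- 40 columns in total.

Canonical column names follow ``{tissue}_{measure}_{region}_{hemisphere}``,
e.g. ``gm_vol_mcc_r``.
"""

from __future__ import annotations

GM_REGIONS = ("mcc", "sfg", "mfg", "ifg_tri", "ifg_orb", "ifg_oper")
WM_REGIONS = ("cb", "slf2", "acr", "scr")
HEMISPHERES = ("l", "r")
MEASURES = ("vol", "conc")

# Typical regional means (arbitrary volume units; concentrations near 0.5).
# Only the relative scale matters: correlations and z-scored regressions are
# invariant to it.
_VOLUME_MEANS = {
    "mcc": 9.5, "sfg": 28.0, "mfg": 25.0,
    "ifg_tri": 7.5, "ifg_orb": 6.0, "ifg_oper": 5.0,
    "cb": 4.5, "slf2": 3.8, "acr": 12.0, "scr": 10.0,
}


def canonical_roi_columns() -> list[str]:
    """Return the 40 canonical column names in their documented order."""
    cols = []
    for tissue, regions in (("gm", GM_REGIONS), ("wm", WM_REGIONS)):
        for region in regions:
            for hemi in HEMISPHERES:
                for measure in MEASURES:
                    cols.append(f"{tissue}_{measure}_{region}_{hemi}")
    return cols


def gm_columns() -> list[str]:
    return [c for c in canonical_roi_columns() if c.startswith("gm_")]


def wm_columns() -> list[str]:
    return [c for c in canonical_roi_columns() if c.startswith("wm_")]


def volume_mean(column: str) -> float:
    region = column.split("_", 2)[2].rsplit("_", 1)[0]
    return _VOLUME_MEANS[region]


# Atlas-style aliases accepted by the TSV reader.  AAL labels for gray
# matter, JHU tractography labels for white matter; suffix encodes tissue
# and measure as written by common ROI-extraction scripts.
_ATLAS_BASE = {
    "mcc": "Cingulum_Mid",
    "sfg": "Frontal_Sup",
    "mfg": "Frontal_Mid",
    "ifg_tri": "Frontal_Inf_Tri",
    "ifg_orb": "Frontal_Inf_Orb",
    "ifg_oper": "Frontal_Inf_Oper",
    "cb": "Cingulum_Cingulate_Gyrus",
    "slf2": "SLF_II",
    "acr": "Anterior_Corona_Radiata",
    "scr": "Superior_Corona_Radiata",
}


def roi_alias_map() -> dict[str, str]:
    """Map atlas-style column aliases to canonical names."""
    aliases: dict[str, str] = {}
    for canonical in canonical_roi_columns():
        tissue, measure, rest = canonical.split("_", 2)
        region, hemi = rest.rsplit("_", 1)
        alias = f"{_ATLAS_BASE[region]}_{hemi.upper()}_{tissue}{measure}"
        aliases[alias] = canonical
    return aliases
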