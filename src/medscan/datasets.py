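"""Packaged reference tables for the Mediterranean bread-wheat landrace panel.

Three small published tables travel with the package so that the worked
examples and regression tests run offline:

* long-term (15-year) climate normals per country of origin, averaged over
  the sowing-to-anthesis (SA) and anthesis-to-maturity (AM) windows;
* the selected QTL hotspots (confidence interval <= 20 Mb) with flanking
  markers and physical positions;
* subpopulation allele frequencies at markers inside differentiation
  hotspots.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

CLIMATE_VARIABLES = ["Tmax", "Tmin", "Tmean", "Rh", "Sunshine", "Rad", "ET0", "Rain"]
CLIMATE_PERIODS = ["SA", "AM"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("medscan.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_reference_climate() -> pd.DataFrame:
    """Country climate normals as a long ClimateTable.

    Returns a frame with columns (country, variable, period, value); one
    row per country x variable x period, 23 countries x 8 variables x 2
    periods.  Units: temperatures degC, Rh %, Sunshine h/day, Rad
    MJ m-2 day-1, ET0 mm per window, Rain mm total per window.
    """
    wide = _read("climate_countries.tsv")
    rows = []
    for _, r in wide.iterrows():
        for period in CLIMATE_PERIODS:
            for var in CLIMATE_VARIABLES:
                rows.append((r["country"], var, period, float(r[f"{period}_{var}"])))
    return pd.DataFrame(rows, columns=["country", "variable", "period", "value"])


def load_reference_hotspots() -> pd.DataFrame:
    """The 33 selected QTL hotspots (CI <= 20 Mb) of the landrace panel.

    Columns: hotspot, chrom, cm_start, cm_end, trait_classes (subset of
    C/E/P, comma separated), left/right flanking marker ids and bp,
    ci_mb (printed physical width), n_gene_models.
    """
    return _read("selected_hotspots.tsv")


def load_reference_diff_frequencies() -> pd.DataFrame:
    """Subpopulation allele frequencies at differentiation-hotspot markers.

    Long frame (hotspot, marker, cm, bp, subpop, allele, frequency) as
    published; frequencies are fractions and, at a few markers, do not sum
    exactly to 1 within a subpopulation (rare third alleles/missing data
    in the original panel).
    """
    return _read("diff_frequencies.tsv")
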