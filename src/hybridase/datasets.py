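"""Bundled demonstration data.

Genotype trait means from a replicated two-location (Kinston and
Clayton, NC) soybean trial comparing the cultivar N7103, the wild-derived
breeding line NMS4-44-329 and their F1 and F2 progeny. Traits: seed
yield (kg/ha), seed protein (g/100 g, zero-moisture), harvestable
protein (kg/ha), oil (g/100 g), maturity (days after Oct 1), lodging
(1 erect – 5 prostrate), height (cm) and 100-seed weight (g).

These published genotype means feed :func:`hybridase.heterosis_report`
as a degenerate one-plot-per-mean table, reproducing the mid-parent
difference arithmetic of the original contrast table (differences of
means; p-values need the plot-level data and are reported as missing).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["soybean_trial_means", "means_as_plot_table"]

_COLUMNS = [
    "yield",
    "protein",
    "harvestable_protein",
    "oil",
    "maturity",
    "lodging",
    "height",
    "seed_weight",
]

_MEANS = {
    "Kinston": {
        "F1": [2204, 46.0, 941, 20.3, 38, 3.3, 66, 10.1],
        "F2": [2045, 46.1, 873, 20.1, 38, 3.4, 65, 9.7],
        "NMS4-44-329": [1934, 44.1, 791, 20.6, 38, 4.1, 57, 10.7],
        "N7103": [2096, 45.7, 889, 20.2, 36, 2.5, 81, 8.2],
    },
    "Clayton": {
        "F1": [2618, 44.1, 1057, 19.7, 32, 2.3, 85, 10.3],
        "F2": [2529, 44.1, 1053, 19.8, 33, 2.3, 84, 9.6],
        "NMS4-44-329": [2479, 42.2, 971, 20.5, 31, 3.1, 75, 10.9],
        "N7103": [2311, 43.7, 943, 19.8, 31, 1.6, 76, 7.8],
    },
}

_ENTRY_CLASS = {
    "N7103": "parent1",
    "NMS4-44-329": "parent2",
    "F1": "F1",
    "F2": "F2",
}


def soybean_trial_means() -> pd.DataFrame:
    """Tidy frame of the published genotype means (one row per
    genotype × location)."""
    rows = []
    for location, genos in _MEANS.items():
        for genotype, vals in genos.items():
            row = {"location": location, "genotype": genotype, "entry_class": _ENTRY_CLASS[genotype]}
            row.update(dict(zip(_COLUMNS, vals)))
            rows.append(row)
    return pd.DataFrame(rows)


def means_as_plot_table() -> pd.DataFrame:
    """The means as a degenerate plot table (one plot per genotype mean).

    Suitable for :func:`hybridase.heterosis_report`: contrast estimates
    equal differences of the published means; standard errors and
    p-values are undefined at one plot per genotype and reported NaN.
    """
    df = soybean_trial_means().copy()
    df.insert(1, "block", 1)
    df.insert(2, "row", df.groupby("location").cumcount() + 1)
    df.insert(3, "column", 1)
    return df
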