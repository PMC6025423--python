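"""Benchmark tables from a published nine-site urban biomonitoring survey.

A survey of one pleurocarpous moss (*Haplocladium angustifolium*), two
evergreen tree species (*Cinnamomum bodinieri*, *Osmanthus fragrans*) and
surface soil across nine land-use sites in Wuhan, China, printed per-medium
summary statistics, moss/leaf accumulation ratios and per-site moss
contamination factors for twelve trace metals.  Those printed numbers are
frozen here as desk-scale validation inputs: they let the index and
classification code be exercised against published values without any raw
per-site concentration data (which the survey did not publish).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "ELEMENTS",
    "SITES",
    "MEAN_CONCENTRATIONS",
    "RATIO_SURVEY",
    "CF_SURVEY",
    "CF_PUBLISHED_CATEGORY",
    "CF_NONREPRODUCIBLE",
]

ELEMENTS = ["Ag", "As", "Cd", "Co", "Cr", "Cu", "Mn", "Mo", "Ni", "Pb", "V", "Zn"]

#: Site codes; HZ is the designated clean background (university campus),
#: TR/GS are roadside, WS/WB industrial.
SITES = ["HZ", "HX", "JX", "LY", "MA", "TR", "GS", "WS", "WB"]

#: Published mean concentrations (µg g⁻¹ dry weight) per medium.
MEAN_CONCENTRATIONS = pd.DataFrame(
    {
        "moss":   [0.127, 4.20, 0.660, 4.14, 13.3, 25.6, 300.0, 338.0, 4.97, 28.0, 24.8, 114.0],
        "leaf_a": [0.008, 0.317, 0.050, 0.108, 0.579, 5.23, 120.0, 41.1, 0.549, 2.361, 0.735, 13.4],
        "leaf_b": [0.009, 0.196, 0.182, 0.224, 0.538, 5.14, 107.0, 144.0, 0.562, 3.59, 0.575, 27.1],
        "soil":   [0.107, 22.7, 0.185, 16.4, 49.3, 28.0, 667.0, 387.0, 18.4, 32.7, 124.0, 67.8],
    },
    index=pd.Index(ELEMENTS, name="element"),
)

#: Published moss/leaf accumulation ratios (mean ± SD of per-site ratios).
RATIO_SURVEY = pd.DataFrame(
    {
        ("moss", "leaf_a", "mean_ratio"): [19.8, 17.4, 15.3, 51.3, 29.9, 5.17, 4.08, 10.4, 10.3, 13.6, 48.5, 9.38],
        ("moss", "leaf_a", "sd_ratio"):   [9.79, 9.89, 7.76, 25.2, 21.3, 1.97, 2.18, 6.62, 4.75, 8.58, 28.1, 4.94],
        ("moss", "leaf_b", "mean_ratio"): [46.0, 25.0, 5.05, 20.0, 27.8, 5.27, 6.54, 3.30, 10.7, 12.3, 48.3, 4.78],
        ("moss", "leaf_b", "sd_ratio"):   [18.6, 11.8, 3.57, 7.25, 14.8, 1.18, 5.92, 2.20, 4.05, 10.4, 19.9, 1.35],
    },
    index=pd.Index(ELEMENTS, name="element"),
)
RATIO_SURVEY.columns = pd.MultiIndex.from_tuples(
    RATIO_SURVEY.columns, names=["numerator_medium", "denominator_medium", "stat"]
)

#: Published per-site moss contamination factors (site × element).
#: The background row (HZ) is 1.00 for every element except Mo (2.47),
#: which implies an unstated different Mo background — see
#: :data:`CF_NONREPRODUCIBLE`.
CF_SURVEY = pd.DataFrame(
    [
        # Ag    As    Cd    Co    Cr    Cu    Mn    Mo    Ni    Pb    V     Zn
        [1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 2.47, 1.00, 1.00, 1.00, 1.00],  # HZ
        [1.58, 1.43, 0.85, 3.54, 2.00, 1.31, 2.49, 2.35, 1.66, 1.44, 1.80, 1.17],  # HX
        [1.40, 1.14, 0.81, 1.89, 2.22, 0.95, 1.74, 2.41, 1.64, 1.38, 1.21, 1.32],  # JX
        [1.20, 1.02, 0.62, 2.13, 1.55, 1.05, 2.09, 2.18, 1.52, 1.26, 1.39, 1.19],  # LY
        [1.15, 1.28, 0.58, 2.21, 1.64, 1.00, 2.29, 2.29, 1.61, 1.13, 1.98, 1.01],  # MA
        [1.33, 1.65, 0.74, 2.17, 2.10, 1.19, 1.62, 2.58, 1.96, 1.13, 2.11, 1.95],  # TR
        [3.47, 2.20, 1.58, 2.83, 2.05, 2.14, 5.51, 3.86, 1.90, 3.55, 1.64, 1.70],  # GS
        [3.19, 1.04, 1.08, 2.79, 1.96, 1.31, 2.13, 2.41, 1.58, 2.66, 1.37, 1.54],  # WS
        [1.11, 1.67, 0.57, 2.71, 4.24, 1.03, 2.33, 3.40, 2.06, 1.04, 2.11, 1.00],  # WB
    ],
    index=pd.Index(SITES, name="site"),
    columns=pd.Index(ELEMENTS, name="element"),
)

#: Published per-element contamination category (tracks the column mean).
CF_PUBLISHED_CATEGORY = {
    "Ag": "C2", "As": "C2", "Cd": "C1", "Co": "C3", "Cr": "C3", "Cu": "C2",
    "Mn": "C3", "Mo": "C2", "Ni": "C2", "Pb": "C2", "V": "C2", "Zn": "C2",
}

#: Elements whose published CF entries are internally inconsistent and are
#: therefore excluded from reproduction checks: the Mo background-site CF is
#: printed as 2.47 (not 1), implying an unstated separate Mo background, and
#: the printed Mo category disagrees with both the column-mean and
#: column-max conventions.
CF_NONREPRODUCIBLE = ("Mo",)


def cf_survey_index():
    """The published CF table as a :class:`~mossmetal.indices.IndexTable`.

    Lets the per-element summary/categorization logic run directly on the
    printed values.
    """
    from .indices import IndexTable, classify_contamination

    long = CF_SURVEY.stack().rename("value").reset_index()
    long.insert(1, "medium", "moss")
    long["category"] = classify_contamination(long["value"].to_numpy())
    return IndexTable(kind="CF", df=long, metadata={"background_site": "HZ", "medium": "moss"})
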