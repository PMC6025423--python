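"""Bioaccumulation index mathematics.

Implements the standard biomonitoring indices for a moss/leaf/soil survey:

* per-medium descriptive summaries (min, max, mean, sample SD),
* cross-species accumulation ratios (mean of per-site ratios, not ratio of
  means — the two diverge whenever sites are heterogeneous),
* enrichment factors EF = (M/R)_plant ÷ (M/R)_soil with a crust-conservative
  reference element R (Al by default) and site-matched soil,
* contamination factors CF = C_site / C_background against a designated
  clean background site, with the ordinal C1–C6 contamination scale.

The EF and CF computations are exposed both as scikit-learn style
transformers (:class:`EnrichmentFactor`, :class:`ContaminationFactor`) and
as plain functions wrapping them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import AGGREGATED, ConcentrationTable, aggregate_replicates, canonical_element

__all__ = [
    "CATEGORY_BINS",
    "CATEGORY_LABELS",
    "CATEGORY_DESCRIPTIONS",
    "IndexTable",
    "summarize",
    "accumulation_ratios",
    "ratio_extremes",
    "EnrichmentFactor",
    "ContaminationFactor",
    "enrichment_factor",
    "contamination_factor",
    "classify_contamination",
    "cf_site_summary",
]

# Left-closed / right-open contamination bins partitioning [0, inf).
CATEGORY_BINS = np.array([0.0, 1.0, 2.0, 3.5, 8.0, 27.0])
CATEGORY_LABELS = ["C1", "C2", "C3", "C4", "C5", "C6"]
CATEGORY_DESCRIPTIONS = {
    "C1": "none contaminated",
    "C2": "suspected",
    "C3": "slightly contaminated",
    "C4": "moderately contaminated",
    "C5": "seriously contaminated",
    "C6": "extremely contaminated",
}


@dataclass(frozen=True)
class IndexTable:
    """EF or CF values keyed by (site, medium, element).

    ``df`` columns: site, medium, element, value (and ``category`` for CF).
    ``metadata`` records the reference element (EF) or background site (CF).
    """

    kind: str  # "EF" | "CF"
    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("EF", "CF"):
            raise ValueError(f"kind must be 'EF' or 'CF', got {self.kind!r}")
        if (self.df["value"] < 0).any():
            raise ValueError(f"{self.kind} values must be non-negative")


def summarize(table: ConcentrationTable, medium: str) -> pd.DataFrame:
    """Per-element descriptive statistics over all sites × replicates of a medium.

    Returns a frame with columns element, n, minimum, maximum, mean, sd; the
    SD is the sample standard deviation (n−1 denominator, 0 for n=1).
    """
    sub = table.subset(medium)

    def _stats(v: pd.Series) -> pd.Series:
        x = v.to_numpy(dtype=float)
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        return pd.Series(
            {
                "n": x.size,
                "minimum": float(x.min()),
                "maximum": float(x.max()),
                "mean": float(x.mean()),
                "sd": sd,
            }
        )

    out = (
        sub.groupby("element", sort=True)["concentration_ug_per_g"]
        .apply(_stats)
        .unstack()
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    out.insert(0, "medium", medium)
    return out


def accumulation_ratios(
    table: ConcentrationTable, numerator: str, denominator: str
) -> pd.DataFrame:
    """Per-element mean ± SD of per-site concentration ratios between two media.

    The per-site ratio numerator/denominator is formed first on replicate
    site means, then averaged across sites (mean-of-ratios).  With skewed
    surveys this deliberately differs from the ratio of across-site means.
    """
    agg = aggregate_replicates(table)
    num = agg.subset(numerator)
    den = agg.subset(denominator)
    merged = num.merge(den, on=["site", "element"], suffixes=("_num", "_den"))
    if merged.empty:
        raise KeyError(f"media {numerator!r} and {denominator!r} share no site")
    merged["ratio"] = (
        merged["concentration_ug_per_g_num"] / merged["concentration_ug_per_g_den"]
    )

    def _stats(v: pd.Series) -> pd.Series:
        x = v.to_numpy(dtype=float)
        return pd.Series(
            {
                "mean_ratio": float(x.mean()),
                "sd_ratio": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
                "n_sites": x.size,
            }
        )

    out = merged.groupby("element", sort=True)["ratio"].apply(_stats).unstack().reset_index()
    out["n_sites"] = out["n_sites"].astype(int)
    out.insert(1, "numerator_medium", numerator)
    out.insert(2, "denominator_medium", denominator)
    return out


def ratio_extremes(ratios: pd.DataFrame) -> pd.DataFrame:
    """Largest and smallest mean accumulation ratio per medium pair.

    Input is the output of :func:`accumulation_ratios` (possibly several
    concatenated pairs); output has one max and one min row per pair.
    """
    rows = []
    for (num, den), grp in ratios.groupby(["numerator_medium", "denominator_medium"]):
        hi = grp.loc[grp["mean_ratio"].idxmax()]
        lo = grp.loc[grp["mean_ratio"].idxmin()]
        rows.append((num, den, "max", hi["element"], float(hi["mean_ratio"])))
        rows.append((num, den, "min", lo["element"], float(lo["mean_ratio"])))
    return pd.DataFrame(
        rows,
        columns=["numerator_medium", "denominator_medium", "which", "element", "mean_ratio"],
    )


class EnrichmentFactor(BaseEstimator):
    """Enrichment factor transformer.

    For each site and each element M other than the reference element R,

        EF = (C_M / C_R)_plant ÷ (C_M / C_R)_soil

    computed on replicate site means with site-matched soil.  EF > 1 flags
    accumulation from sources other than local soil; the double ratio
    cancels any common rescaling of one medium at one site, so EF is
    unit-change robust.  The reference element itself is excluded from the
    output (its EF is identically 1).

    Parameters
    ----------
    plant_medium : str
        Medium whose enrichment is assessed.
    reference_element : str
        Crust-conservative normalizing element, default ``"Al"``.
    """

    def __init__(self, plant_medium: str = "moss", reference_element: str = "Al"):
        self.plant_medium = plant_medium
        self.reference_element = reference_element

    def fit(self, X: ConcentrationTable | None = None, y=None):  # noqa: N803
        """Stateless; present for scikit-learn API compatibility."""
        return self

    def transform(self, X: ConcentrationTable) -> IndexTable:  # noqa: N803
        ref = canonical_element(self.reference_element)
        agg = aggregate_replicates(X)
        plant = agg.site_element_matrix(self.plant_medium)
        soil = agg.site_element_matrix("soil")
        for name, mat in (("plant medium", plant), ("soil", soil)):
            if ref not in mat.columns or mat[ref].isna().any():
                missing = (
                    list(mat.index)
                    if ref not in mat.columns
                    else list(mat.index[mat[ref].isna()])
                )
                raise ValueError(
                    f"reference element {ref!r} missing in {name} at site(s): "
                    f"{', '.join(map(str, missing))}"
                )
        missing_soil = sorted(set(plant.index) - set(soil.index))
        if missing_soil:
            raise ValueError(f"soil missing at site(s): {', '.join(missing_soil)}")
        soil = soil.loc[plant.index]
        plant_norm = plant.div(plant[ref], axis=0)
        soil_norm = soil.div(soil[ref], axis=0)
        ef = (plant_norm / soil_norm).drop(columns=[ref])
        out = (
            ef.stack()
            .rename("value")
            .reset_index()
            .rename(columns={"level_1": "element"})
            .dropna(subset=["value"])
        )
        out.insert(1, "medium", self.plant_medium)
        return IndexTable(
            kind="EF",
            df=out.sort_values(["site", "element"]).reset_index(drop=True),
            metadata={"reference_element": ref, "plant_medium": self.plant_medium},
        )

    def fit_transform(self, X: ConcentrationTable, y=None) -> IndexTable:  # noqa: N803
        return self.fit(X).transform(X)


class ContaminationFactor(BaseEstimator):
    """Contamination factor transformer: CF = C_site / C_background.

    The background concentration of each element is that element's replicate
    site mean at the configured clean background site, in the same medium.
    Every CF entry carries its C1–C6 category.  At the background site
    itself CF is identically 1.
    """

    def __init__(self, medium: str = "moss", background_site: str = "HZ"):
        self.medium = medium
        self.background_site = background_site

    def fit(self, X: ConcentrationTable | None = None, y=None):  # noqa: N803
        return self

    def transform(self, X: ConcentrationTable) -> IndexTable:  # noqa: N803
        agg = aggregate_replicates(X)
        mat = agg.site_element_matrix(self.medium)
        if self.background_site not in mat.index:
            raise ValueError(
                f"background site {self.background_site!r} has no {self.medium!r} records"
            )
        background = mat.loc[self.background_site]
        missing = sorted(background.index[background.isna()])
        if missing:
            raise ValueError(
                f"background site {self.background_site!r} lacks element(s): "
                f"{', '.join(missing)}"
            )
        cf = mat.div(background, axis=1)
        out = (
            cf.stack()
            .rename("value")
            .reset_index()
            .rename(columns={"level_1": "element"})
            .dropna(subset=["value"])
        )
        out.insert(1, "medium", self.medium)
        out["category"] = classify_contamination(out["value"].to_numpy())
        return IndexTable(
            kind="CF",
            df=out.sort_values(["site", "element"]).reset_index(drop=True),
            metadata={"background_site": self.background_site, "medium": self.medium},
        )

    def fit_transform(self, X: ConcentrationTable, y=None) -> IndexTable:  # noqa: N803
        return self.fit(X).transform(X)


def enrichment_factor(
    table: ConcentrationTable, plant_medium: str, reference_element: str = "Al"
) -> IndexTable:
    """Functional wrapper over :class:`EnrichmentFactor`."""
    return EnrichmentFactor(plant_medium, reference_element).fit_transform(table)


def contamination_factor(
    table: ConcentrationTable, medium: str, background_site: str
) -> IndexTable:
    """Functional wrapper over :class:`ContaminationFactor`."""
    return ContaminationFactor(medium, background_site).fit_transform(table)


def classify_contamination(cf):
    """Map CF value(s) to the ordinal C1–C6 contamination category.

    Bins are left-closed/right-open: [0,1) C1, [1,2) C2, [2,3.5) C3,
    [3.5,8) C4, [8,27) C5, [27,∞) C6.  Scalar in → scalar out; array in →
    object array of labels.
    """
    x = np.asarray(cf, dtype=float)
    if np.any(x < 0):
        raise ValueError("contamination factor must be non-negative")
    idx = np.digitize(x, CATEGORY_BINS[1:], right=False)
    labels = np.array(CATEGORY_LABELS, dtype=object)[idx]
    return labels if x.ndim else str(labels)


def cf_site_summary(cf_table: IndexTable) -> pd.DataFrame:
    """Per-element summary of a CF table: mean over sites, max over sites,
    and the category of the mean.

    Both the mean and the max are reported because survey reports commonly
    conflate the two; the category is tied to the mean, which is the
    study-area-level statement the C1–C6 scale is meant to make.
    """
    if cf_table.kind != "CF":
        raise ValueError("cf_site_summary requires a CF IndexTable")
    g = cf_table.df.groupby("element", sort=True)["value"]
    out = pd.DataFrame(
        {"mean_cf": g.mean(), "max_cf": g.max(), "n_sites": g.size().astype(int)}
    ).reset_index()
    out["category_of_mean"] = classify_contamination(out["mean_cf"].to_numpy())
    return out
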