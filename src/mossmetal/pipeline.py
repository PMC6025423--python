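"""End-to-end survey analysis: read → aggregate → indices → inference → report.

The pipeline runs the stages in the canonical reporting order — descriptive
summaries with letter groups, cross-species accumulation ratios, enrichment
factors (with boxplot-style distribution summaries), contamination factors
with categories, soil–plant coupling correlations, the metal × metal
correlation matrix, and eigenvalue factoring — and renders every table as
CSV.  Any stage failure aborts with a stage-named error and no partial
output directory is left behind.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
import tempfile
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (
    ConcentrationTable,
    aggregate_replicates,
    read_concentrations,
    read_sites,
)
from .indices import (
    IndexTable,
    accumulation_ratios,
    cf_site_summary,
    contamination_factor,
    enrichment_factor,
    ratio_extremes,
    summarize,
)
from .stats import (
    CorrelationResult,
    EigenFactorAnalysis,
    FactorModel,
    anova_letter_groups,
    metal_metal_matrix,
    significance_stars,
    soil_plant_coupling,
)

__all__ = ["RunConfig", "ReportBundle", "PipelineError", "run_pipeline", "render_report"]

log = logging.getLogger("mossmetal")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    Paths may be None when the table is passed in memory.  ``schema`` maps
    canonical column names to the input file's column names.
    """

    input_concentrations: str | None = None
    input_sites: str | None = None
    schema: dict = field(default_factory=dict)
    background_site: str = "HZ"
    cf_medium: str = "moss"
    plant_media: tuple = ("moss", "leaf_a", "leaf_b")
    reference_element: str = "Al"
    transform: str = "log10"
    alpha: float = 0.05
    posthoc: str = "tukey"
    rotation: str | None = None
    output_dir: str = "out"
    seed: int | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if "plant_media" in raw:
            raw["plant_media"] = tuple(raw["plant_media"])
        return cls(**raw)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for path in (self.input_concentrations, self.input_sites):
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(path)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All result tables of one run plus provenance metadata."""

    summary: pd.DataFrame
    ratios: pd.DataFrame
    ratio_extremes: pd.DataFrame
    ef: dict[str, IndexTable]
    ef_boxstats: pd.DataFrame
    cf: IndexTable
    cf_summary: pd.DataFrame
    coupling: CorrelationResult
    metal_matrix: CorrelationResult
    factors: FactorModel | None
    metadata: dict
    warnings: list[str] = field(default_factory=list)


def _boxplot_stats(index_table: IndexTable) -> pd.DataFrame:
    """Five-number summaries plus 1.5·IQR outliers, one row per element."""
    rows = []
    for (medium, element), grp in index_table.df.groupby(["medium", "element"]):
        v = np.sort(grp["value"].to_numpy(dtype=float))
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        outliers = v[(v < lo) | (v > hi)]
        rows.append(
            {
                "medium": medium,
                "element": element,
                "min": v.min(),
                "q1": q1,
                "median": med,
                "q3": q3,
                "max": v.max(),
                "n_outliers": len(outliers),
                "outliers": ";".join(f"{o:.6g}" for o in outliers),
            }
        )
    return pd.DataFrame(rows)


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig, table: ConcentrationTable | None = None) -> ReportBundle:
    """Execute the full analysis under ``config``.

    ``table`` may be supplied directly (e.g. a synthetic survey); otherwise
    ``config.input_concentrations`` is read.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    captured: list[str] = []
    meta: dict = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }

    def stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                out = fn(*args, **kwargs)
            for w in caught:
                captured.append(f"{name}: {w.message}")
                log.warning("%s: %s", name, w.message)
        except Exception as err:  # noqa: BLE001
            raise PipelineError(name, err) from err
        log.info("stage %-12s %.3fs", name, time.perf_counter() - t0)
        return out

    if table is None:
        table = stage("read", read_concentrations, config.input_concentrations, config.schema)
        meta["input_checksum"] = _checksum(config.input_concentrations)
    else:
        meta["input_checksum"] = hashlib.sha256(
            table.df.to_csv(index=False).encode()
        ).hexdigest()[:16]
    background = config.background_site
    if config.input_sites:
        sites = stage("read", read_sites, config.input_sites)
        background = sites.background_site or background
    meta["background_site"] = background

    def _validate(t: ConcentrationTable):
        for m in config.plant_media:
            t.require_soil_for(m)
        t.require_reference_element(config.reference_element)
        return t

    stage("validate", _validate, table)
    agg = stage("aggregate", aggregate_replicates, table)

    def _summaries():
        letters = {
            e: anova_letter_groups(table, e, alpha=config.alpha, transform=config.transform)
            for e in table.elements
        }
        parts = []
        for m in table.media:
            s = summarize(table, m)
            s["letter_group"] = s["element"].map(lambda e, m=m: letters[e].letters[m])
            parts.append(s)
        return pd.concat(parts, ignore_index=True)

    summary = stage("summarize", _summaries)

    def _ratios():
        parts = [
            accumulation_ratios(agg, "moss", m)
            for m in config.plant_media
            if m != "moss" and m in agg.media
        ]
        return (
            pd.concat(parts, ignore_index=True)
            if parts
            else pd.DataFrame(
                columns=[
                    "element", "numerator_medium", "denominator_medium",
                    "mean_ratio", "sd_ratio", "n_sites",
                ]
            )
        )

    ratios = stage("ratios", _ratios)
    extremes = stage("ratios", ratio_extremes, ratios) if len(ratios) else pd.DataFrame()

    ef = {
        m: stage("ef", enrichment_factor, agg, m, config.reference_element)
        for m in config.plant_media
        if m in agg.media
    }
    ef_box = stage(
        "ef",
        lambda: pd.concat([_boxplot_stats(t) for t in ef.values()], ignore_index=True)
        if ef
        else pd.DataFrame(),
    )

    cf = stage("cf", contamination_factor, agg, config.cf_medium, background)
    cf_sum = stage("cf", cf_site_summary, cf)

    # correlation and factoring stages target the pollutant metals; the
    # crust-conservative reference element is a normalizer, not an analyte
    ref = table.df["element"].eq(config.reference_element)
    stats_table = ConcentrationTable(table.df[~ref]) if ref.any() else table
    coupling = stage(
        "correlate", soil_plant_coupling, stats_table, config.cf_medium, config.transform
    )
    matrix = stage(
        "correlate", metal_metal_matrix, stats_table, config.cf_medium, config.transform
    )

    def _factors():
        r = matrix.r
        if r.isna().any().any():
            warnings.warn(
                "correlation matrix contains NaN (constant elements); no factor retained",
                UserWarning,
                stacklevel=2,
            )
            return None
        est = EigenFactorAnalysis(rotation=config.rotation)
        est.fit_correlation(r)
        return est.to_model()

    factors = stage("factors", _factors)

    return ReportBundle(
        summary=summary,
        ratios=ratios,
        ratio_extremes=extremes,
        ef=ef,
        ef_boxstats=ef_box,
        cf=cf,
        cf_summary=cf_sum,
        coupling=coupling,
        metal_matrix=matrix,
        factors=factors,
        metadata=meta,
        warnings=captured,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _fmt_sig3(x) -> str:
    return f"{x:.3g}" if pd.notna(x) else ""


def _fmt_3dec(x) -> str:
    return f"{x:.3f}" if pd.notna(x) else ""


def _bundle_files(bundle: ReportBundle) -> dict[str, pd.DataFrame]:
    files: dict[str, pd.DataFrame] = {}

    s = bundle.summary.copy()
    for c in ("minimum", "maximum", "mean", "sd"):
        s[c] = s[c].map(_fmt_sig3)
    files["summary.csv"] = s

    r = bundle.ratios.copy()
    if len(r):
        r["mean_ratio"] = r["mean_ratio"].map(_fmt_sig3)
        r["sd_ratio"] = r["sd_ratio"].map(_fmt_sig3)
    files["ratios.csv"] = r
    files["ratio_extremes.csv"] = bundle.ratio_extremes.copy()

    for medium, tab in bundle.ef.items():
        e = tab.df.copy()
        e["value"] = e["value"].map(_fmt_3dec)
        files[f"ef_{medium}.csv"] = e
    files["ef_boxstats.csv"] = bundle.ef_boxstats.copy()

    c = bundle.cf.df.copy()
    c["value"] = c["value"].map(_fmt_3dec)
    files["cf.csv"] = c
    cs = bundle.cf_summary.copy()
    cs["mean_cf"] = cs["mean_cf"].map(_fmt_3dec)
    cs["max_cf"] = cs["max_cf"].map(_fmt_3dec)
    files["cf_summary.csv"] = cs

    cp = pd.concat(
        [
            bundle.coupling.r.rename(columns={"r": "r"}),
            bundle.coupling.p.rename(columns={"p": "p"}),
            bundle.coupling.n.rename(columns={"n": "n"}),
        ],
        axis=1,
    ).reset_index(names="element")
    cp["r"] = cp["r"].map(_fmt_3dec)
    cp["p"] = cp["p"].map(_fmt_3dec)  # "0.000" floor display
    files["coupling.csv"] = cp

    files["metal_matrix_r.csv"] = bundle.metal_matrix.r.map(_fmt_3dec).reset_index()
    files["metal_matrix_p.csv"] = bundle.metal_matrix.p.map(_fmt_3dec).reset_index()
    files["metal_matrix_stars.csv"] = significance_stars(bundle.metal_matrix.p).reset_index()

    if bundle.factors is not None and bundle.factors.n_factors > 0:
        fm = bundle.factors
        tab = fm.loadings.map(_fmt_3dec).reset_index(names="element")
        var_row = {"element": "variance_pct"}
        cum_row = {"element": "cumulative_pct"}
        for j, col in enumerate(fm.loadings.columns):
            var_row[col] = _fmt_3dec(fm.variance_pct[j])
            cum_row[col] = _fmt_3dec(fm.cumulative_pct[j])
        tab = pd.concat([tab, pd.DataFrame([var_row, cum_row])], ignore_index=True)
        files["factors.csv"] = tab
    else:
        files["factors.csv"] = pd.DataFrame({"note": ["no factor retained"]})
    return files


def render_report(bundle: ReportBundle, output_dir: str, fmt: str = "csv-dir") -> list[str]:
    """Render the bundle deterministically.

    ``csv-dir`` writes one CSV per table plus ``run_metadata.yaml``;
    ``single-html`` writes one ``report.html``.  Files are staged in a
    temporary directory and moved into place, so a failed render leaves no
    partial output.
    """
    if fmt not in ("csv-dir", "single-html"):
        raise ValueError(f"unknown report format {fmt!r}")
    files = _bundle_files(bundle)
    meta = dict(bundle.metadata)
    meta["warnings"] = list(bundle.warnings)
    os.makedirs(output_dir, exist_ok=True)
    written: list[str] = []
    with tempfile.TemporaryDirectory(dir=output_dir) as tmp:
        if fmt == "csv-dir":
            for name, df in files.items():
                df.to_csv(os.path.join(tmp, name), index=False)
            with open(os.path.join(tmp, "run_metadata.yaml"), "w", encoding="utf-8") as fh:
                yaml.safe_dump(meta, fh, sort_keys=True)
            names = [*files, "run_metadata.yaml"]
        else:
            parts = ["<html><body>"]
            for name, df in files.items():
                parts.append(f"<h2>{name.removesuffix('.csv')}</h2>")
                parts.append(df.to_html(index=False))
            parts.append("</body></html>")
            with open(os.path.join(tmp, "report.html"), "w", encoding="utf-8") as fh:
                fh.write("\n".join(parts))
            names = ["report.html"]
        for name in names:
            dest = os.path.join(output_dir, name)
            os.replace(os.path.join(tmp, name), dest)
            written.append(dest)
    return written
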