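"""Survey data structures: long-format concentration tables and site metadata.

A survey is a long table with one row per (site, medium, replicate, element)
holding a strictly positive concentration in µg g⁻¹ dry weight.  Media are
free-form strings; the conventional labels are ``moss``, ``leaf_a``,
``leaf_b`` and ``soil``, with the biological species recorded separately in
the ``species`` column.  All downstream stages (indices, correlations,
factoring) consume this single currency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AGGREGATED",
    "COLUMNS",
    "SchemaError",
    "TableValidationError",
    "ConcentrationTable",
    "SiteTable",
    "canonical_element",
    "read_concentrations",
    "write_concentrations",
    "read_sites",
    "aggregate_replicates",
]

#: Replicate sentinel marking rows that are site means over replicates.
AGGREGATED = 0

#: Canonical column order of the interchange CSV.
COLUMNS = ["site", "medium", "species", "replicate", "element", "concentration_ug_per_g"]

KEY = ["site", "medium", "replicate", "element"]


class SchemaError(ValueError):
    """A required column cannot be resolved in an input file."""


class TableValidationError(ValueError):
    """A concentration table violates a structural invariant."""


def canonical_element(symbol: str) -> str:
    """Normalize an element symbol to canonical capitalization (``"AL"`` → ``"Al"``)."""
    s = str(symbol).strip()
    if not s:
        raise TableValidationError("empty element symbol")
    return s[0].upper() + s[1:].lower()


@dataclass(frozen=True)
class ConcentrationTable:
    """Validated long-format concentration table.

    Parameters
    ----------
    df : pandas.DataFrame
        Must contain the columns in :data:`COLUMNS` (``species`` is filled
        with an empty string when absent).  Validation enforces unique
        (site, medium, replicate, element) keys and strictly positive
        concentrations.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in COLUMNS if c not in df.columns and c != "species"]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = df.copy()
        if "species" not in df.columns:
            df["species"] = ""
        df = df[COLUMNS]
        df["site"] = df["site"].astype(str)
        df["medium"] = df["medium"].astype(str)
        df["element"] = df["element"].map(canonical_element)
        conc = pd.to_numeric(df["concentration_ug_per_g"], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(conc.to_numpy(dtype=float, na_value=np.nan)))
        if bad.size:
            raise TableValidationError(
                f"non-numeric concentration at row {int(bad[0])}"
            )
        nonpos = np.flatnonzero(conc.to_numpy() <= 0)
        if nonpos.size:
            raise TableValidationError(
                f"non-positive concentration at row {int(nonpos[0])}: "
                f"{conc.iloc[int(nonpos[0])]!r}"
            )
        df["concentration_ug_per_g"] = conc.astype(float)
        rep = pd.to_numeric(df["replicate"], errors="coerce")
        if rep.isna().any() or (rep.astype(int) != rep).any() or (rep < 0).any():
            raise TableValidationError("replicate must be a non-negative integer")
        df["replicate"] = rep.astype(int)
        dup = df.duplicated(KEY)
        if dup.any():
            key = tuple(df.loc[dup.idxmax(), KEY])
            raise TableValidationError(f"duplicate (site, medium, replicate, element) key: {key}")
        object.__setattr__(self, "df", df.reset_index(drop=True))

    # -- convenience views ------------------------------------------------

    @property
    def sites(self) -> list[str]:
        return sorted(self.df["site"].unique())

    @property
    def media(self) -> list[str]:
        return sorted(self.df["medium"].unique())

    @property
    def elements(self) -> list[str]:
        return sorted(self.df["element"].unique())

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, medium: str) -> pd.DataFrame:
        """Rows of one medium; raises ``KeyError`` if the medium is absent."""
        if medium not in set(self.df["medium"]):
            raise KeyError(f"medium {medium!r} not present in table")
        return self.df[self.df["medium"] == medium]

    def site_element_matrix(self, medium: str) -> pd.DataFrame:
        """Site × element matrix of replicate-mean concentrations for a medium."""
        sub = aggregate_replicates(self).subset(medium)
        return sub.pivot(index="site", columns="element", values="concentration_ug_per_g")

    def require_reference_element(self, reference: str = "Al") -> None:
        ref = canonical_element(reference)
        if ref not in set(self.df["element"]):
            raise TableValidationError(
                f"reference element {ref!r} absent from table; required for enrichment factors"
            )

    def require_soil_for(self, plant_medium: str) -> None:
        """Every site present for ``plant_medium`` must also carry soil."""
        plant_sites = set(self.subset(plant_medium)["site"])
        soil_sites = set(self.df.loc[self.df["medium"] == "soil", "site"])
        orphan = sorted(plant_sites - soil_sites)
        if orphan:
            raise TableValidationError(
                f"site(s) {', '.join(orphan)} have {plant_medium!r} but no soil"
            )


@dataclass(frozen=True)
class SiteTable:
    """Site metadata: identifier, role (``background`` or ``ordinary``), free-text label."""

    df: pd.DataFrame
    max_background: int = field(default=1)

    def __post_init__(self) -> None:
        df = self.df
        for col in ("site", "role"):
            if col not in df.columns:
                raise SchemaError(f"missing required column(s): {col}")
        df = df.copy()
        if "label" not in df.columns:
            df["label"] = ""
        df["site"] = df["site"].astype(str)
        bad = ~df["role"].isin(["background", "ordinary"])
        if bad.any():
            raise TableValidationError(
                f"unknown site role {df.loc[bad, 'role'].iloc[0]!r}"
            )
        if df["site"].duplicated().any():
            raise TableValidationError("duplicate site identifier in site table")
        n_bg = int((df["role"] == "background").sum())
        if n_bg > self.max_background:
            raise TableValidationError(
                f"{n_bg} sites flagged background; at most {self.max_background} allowed"
            )
        object.__setattr__(self, "df", df[["site", "role", "label"]].reset_index(drop=True))

    @property
    def background_site(self) -> str | None:
        bg = self.df.loc[self.df["role"] == "background", "site"]
        return None if bg.empty else str(bg.iloc[0])


def read_concentrations(path, schema: dict[str, str] | None = None) -> ConcentrationTable:
    """Read a concentrations CSV into a validated :class:`ConcentrationTable`.

    Parameters
    ----------
    path : path-like
    schema : dict, optional
        Mapping from canonical column names (:data:`COLUMNS`) to the column
        names used in the file, absorbing dialect differences.

    Row order is preserved and element symbols are canonicalized.
    """
    raw = pd.read_csv(path)
    schema = schema or {}
    rename = {}
    for canon in COLUMNS:
        src = schema.get(canon, canon)
        if src not in raw.columns:
            if canon == "species":
                continue
            raise SchemaError(f"column {src!r} (for {canon!r}) not found in {path}")
        rename[src] = canon
    return ConcentrationTable(raw.rename(columns=rename))


def write_concentrations(table: ConcentrationTable, path) -> None:
    """Write the canonical CSV dialect (UTF-8, header row, '.' decimal)."""
    table.df.to_csv(path, index=False)


def read_sites(path, max_background: int = 1) -> SiteTable:
    return SiteTable(pd.read_csv(path), max_background=max_background)


def aggregate_replicates(table: ConcentrationTable) -> ConcentrationTable:
    """Collapse replicates to the arithmetic site mean on the raw scale.

    One output record per (site, medium, element); the replicate field is
    set to the sentinel :data:`AGGREGATED`.  Idempotent, and never changes
    the set of (site, medium, element) keys.
    """
    df = table.df
    if (df["replicate"] == AGGREGATED).all():
        return table
    agg = (
        df.groupby(["site", "medium", "species", "element"], as_index=False, sort=True)[
            "concentration_ug_per_g"
        ]
        .mean()
    )
    agg["replicate"] = AGGREGATED
    return ConcentrationTable(agg[COLUMNS])
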