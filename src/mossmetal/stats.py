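"""Inferential statistics for biomonitoring surveys.

Three stages sit here:

* one-way ANOVA across media with a Tukey-HSD compact letter display (media
  sharing a letter are not significantly different at alpha),
* Pearson correlation with exact two-sided p-values — per-element soil–plant
  coupling and the full metal × metal matrix within one medium,
* eigenvalue-based principal-component factoring of the correlation matrix
  (Kaiser retention, eigenvalue > 1), with an optional varimax rotation.

Concentrations are log-transformed before parametric analysis by default:
trace-metal concentrations are strictly positive and right-skewed, and the
log10 transform makes them approximately normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from statsmodels.multivariate.factor_rotation import rotate_factors

from .data import ConcentrationTable, aggregate_replicates

__all__ = [
    "TRANSFORMS",
    "transform_to_normal",
    "LetterGroups",
    "anova_letter_groups",
    "compact_letter_display",
    "PearsonResult",
    "pearson",
    "CorrelationResult",
    "soil_plant_coupling",
    "metal_metal_matrix",
    "significance_stars",
    "FactorModel",
    "EigenFactorAnalysis",
    "factor_analysis",
]

TRANSFORMS = {
    "log10": np.log10,
    "ln": np.log,
    "identity": np.asarray,
}


def transform_to_normal(values, method: str = "log10") -> np.ndarray:
    """Elementwise normalizing transform (default log10) for positive data.

    Raises ``ValueError`` on non-positive input for the log transforms and
    on an unknown method name.
    """
    if method not in TRANSFORMS:
        raise ValueError(f"unknown transform {method!r}; choose from {sorted(TRANSFORMS)}")
    x = np.asarray(values, dtype=float)
    if method != "identity" and np.any(x <= 0):
        raise ValueError("log transform requires strictly positive values")
    return TRANSFORMS[method](x)


# ---------------------------------------------------------------------------
# ANOVA + compact letter display
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LetterGroups:
    """Compact letter display for one element across media.

    Two media share a letter iff their Tukey-HSD comparison is
    non-significant at ``alpha``.  Letters are assigned in descending order
    of the (transformed) group mean.
    """

    element: str
    letters: dict[str, str]
    alpha: float
    means: dict[str, float]
    f_statistic: float
    p_value: float
    p_matrix: pd.DataFrame = field(repr=False, default=None)


def compact_letter_display(
    groups: list[str], significant: np.ndarray, order: list[str] | None = None
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Parameters
    ----------
    groups : list of group names.
    significant : boolean matrix aligned with ``groups``; ``significant[i, j]``
        is True when groups i and j differ significantly.
    order : optional group ordering (best first) used to assign letters.

    Guarantees: significantly different groups never share a letter;
    non-different groups share at least one letter; every group gets at
    least one letter.
    """
    k = len(groups)
    sig = np.asarray(significant, dtype=bool)
    columns: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i, j]:
                continue
            new_cols: list[set[int]] = []
            for col in columns:
                if i in col and j in col:
                    new_cols.extend([col - {i}, col - {j}])
                else:
                    new_cols.append(col)
            # absorb: drop columns contained in another
            columns = [
                c
                for n, c in enumerate(new_cols)
                if c and not any(c < d or (c == d and m < n) for m, d in enumerate(new_cols))
            ]
    rank = {g: r for r, g in enumerate(order or groups)}
    # letter order follows the best member of each column
    columns.sort(key=lambda col: min(rank[groups[i]] for i in col))
    letters = {g: "" for g in groups}
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", columns):
        for i in col:
            letters[groups[i]] += letter
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def anova_letter_groups(
    table: ConcentrationTable,
    element: str,
    alpha: float = 0.05,
    transform: str = "log10",
) -> LetterGroups:
    """One-way ANOVA across media for one element, with Tukey-HSD letters.

    Values (all sites × replicates per medium) are transformed before the
    parametric tests.  Requires at least two media with at least two
    observations each.
    """
    sub = table.df[table.df["element"] == element]
    if sub.empty:
        raise KeyError(f"element {element!r} not present in table")
    media = sorted(sub["medium"].unique())
    samples = [
        transform_to_normal(
            sub.loc[sub["medium"] == m, "concentration_ug_per_g"].to_numpy(), transform
        )
        for m in media
    ]
    if len(media) < 2:
        raise ValueError("ANOVA requires at least two media")
    if any(len(s) < 2 for s in samples):
        raise ValueError("each medium needs at least two observations")
    means = {m: float(s.mean()) for m, s in zip(media, samples)}
    k = len(media)

    pooled_within = np.concatenate([s - s.mean() for s in samples])
    if np.allclose(pooled_within, 0):
        # degenerate: no within-group variance; separate iff means differ
        distinct = ~np.isclose(
            np.subtract.outer(list(means.values()), list(means.values())), 0
        )
        pmat = np.where(distinct, 0.0, 1.0)
        f_stat, p_val = (np.inf, 0.0) if distinct.any() else (0.0, 1.0)
    else:
        f_stat, p_val = sps.f_oneway(*samples)
        pmat = sps.tukey_hsd(*samples).pvalue
    p_df = pd.DataFrame(pmat, index=media, columns=media)
    order = sorted(media, key=lambda m: -means[m])
    letters = compact_letter_display(media, p_df.to_numpy() < alpha, order=order)
    return LetterGroups(
        element=element,
        letters=letters,
        alpha=alpha,
        means=means,
        f_statistic=float(f_stat),
        p_value=float(p_val),
        p_matrix=p_df,
    )


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------


class PearsonResult(NamedTuple):
    r: float
    p: float
    n: int


def pearson(x, y) -> PearsonResult:
    """Sample Pearson r with the exact two-sided p-value.

    p is computed from t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom.
    Requires n ≥ 3 and non-zero variance in both inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("Pearson correlation requires n >= 3")
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise ValueError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return PearsonResult(float(r), float(p), int(n))


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a given sample r at sample size n.

    Uses t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom; handy for
    consistency-checking published (r, p) table cells.
    """
    if not -1 <= r <= 1:
        raise ValueError("r must lie in [-1, 1]")
    if n < 3:
        raise ValueError("requires n >= 3")
    if abs(r) == 1:
        return 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * sps.t.sf(abs(t), n - 2))


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r and p matrices with per-cell sample sizes."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    @property
    def labels(self):
        return list(self.r.index)


def soil_plant_coupling(
    table: ConcentrationTable, plant_medium: str, transform: str = "log10"
) -> CorrelationResult:
    """Per-element correlation between site-matched plant and soil levels.

    A strong positive r says the biomonitor tracks its substrate for that
    element; near-zero r across the board is the signature of atmospheric
    (rather than soil) origin.  Elements with zero variance in either
    compartment are reported as NaN with a warning.
    """
    agg = aggregate_replicates(table)
    plant = agg.site_element_matrix(plant_medium)
    soil = agg.site_element_matrix("soil")
    shared = plant.index.intersection(soil.index)
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared sites between {plant_medium!r} and soil, have {len(shared)}"
        )
    elements = plant.columns.intersection(soil.columns)
    rows = {}
    for e in elements:
        xy = pd.concat([plant.loc[shared, e], soil.loc[shared, e]], axis=1).dropna()
        try:
            res = pearson(
                transform_to_normal(xy.iloc[:, 0], transform),
                transform_to_normal(xy.iloc[:, 1], transform),
            )
        except ValueError as err:
            warnings.warn(f"{e}: {err}; reporting NaN", RuntimeWarning, stacklevel=2)
            res = PearsonResult(np.nan, np.nan, len(xy))
        rows[e] = res
    out = pd.DataFrame(rows, index=["r", "p", "n"]).T.sort_index()
    return CorrelationResult(
        r=out[["r"]].astype(float),
        p=out[["p"]].astype(float),
        n=out[["n"]].astype(int),
    )


def metal_metal_matrix(
    table: ConcentrationTable, medium: str, transform: str = "log10"
) -> CorrelationResult:
    """Full symmetric element × element correlation matrix within one medium.

    Computed on transformed replicate site means; the diagonal is exactly 1.
    Constant elements yield NaN rows/columns with a warning.
    """
    mat = table.site_element_matrix(medium)
    if len(mat) < 3:
        raise ValueError(f"need >= 3 sites for a correlation matrix, have {len(mat)}")
    elements = list(mat.columns)
    p_count = len(elements)
    r = np.eye(p_count)
    p = np.zeros((p_count, p_count))
    n = np.full((p_count, p_count), len(mat), dtype=int)
    for i in range(p_count):
        for j in range(i + 1, p_count):
            xy = mat[[elements[i], elements[j]]].dropna()
            try:
                res = pearson(
                    transform_to_normal(xy.iloc[:, 0], transform),
                    transform_to_normal(xy.iloc[:, 1], transform),
                )
            except ValueError as err:
                warnings.warn(
                    f"{elements[i]}–{elements[j]}: {err}; reporting NaN",
                    RuntimeWarning,
                    stacklevel=2,
                )
                res = PearsonResult(np.nan, np.nan, len(xy))
            r[i, j] = r[j, i] = res.r
            p[i, j] = p[j, i] = res.p
            n[i, j] = n[j, i] = res.n
    idx = pd.Index(elements, name="element")
    return CorrelationResult(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
    )


def significance_stars(p: pd.DataFrame) -> pd.DataFrame:
    """Annotate a p matrix: '**' for p < 0.01, '*' for p < 0.05, else ''."""
    return p.map(lambda v: "**" if v < 0.01 else ("*" if v < 0.05 else ""))


# ---------------------------------------------------------------------------
# Eigenvalue-based principal-component factoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FactorModel:
    """Retained factors from a principal-component factoring.

    ``loadings`` holds the retained (optionally rotated) columns;
    ``loadings_all`` holds every component unrotated, so that
    ``loadings_all @ loadings_all.T`` reconstructs the correlation matrix.
    ``variance_pct`` is 100·eigenvalue/p for every component and sums to 100.
    """

    loadings: pd.DataFrame
    loadings_all: pd.DataFrame = field(repr=False)
    eigenvalues: np.ndarray
    variance_pct: np.ndarray
    cumulative_pct: np.ndarray
    retention_rule: dict
    rotation: str | None

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]


def _fix_sign(load: np.ndarray) -> np.ndarray:
    """Make the largest-|loading| entry of each column positive (deterministic
    across linear-algebra backends)."""
    out = load.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            out[:, j] = -col
    return out


class EigenFactorAnalysis(BaseEstimator):
    """Principal-component factoring of a correlation matrix by eigenvalue.

    ``fit`` accepts an observations × variables matrix (e.g. sites ×
    elements of transformed concentrations), forms the Pearson correlation
    matrix, eigendecomposes it, and retains components under the Kaiser
    rule (eigenvalue strictly > 1; ties at exactly 1 are not retained).
    Loading column j is eigenvector j scaled by √eigenvalue j, sign-fixed
    so the largest-magnitude loading is positive.  Unrotated by default;
    ``rotation="varimax"`` rotates the retained columns for simple
    structure.

    Fitted attributes
    -----------------
    correlation_ : DataFrame — the analyzed correlation matrix.
    eigenvalues_ : ndarray, descending; sums to the number of variables.
    variance_pct_, cumulative_pct_ : per-component explained variance (%).
    n_factors_ : number of retained components (may be 0; warns).
    loadings_ : DataFrame, retained (rotated if requested) columns.
    loadings_all_ : DataFrame, all components, unrotated.
    """

    def __init__(self, rotation: str | None = None, transform: str = "log10"):
        self.rotation = rotation
        self.transform = transform

    def fit(self, X, y=None):  # noqa: N803
        X = pd.DataFrame(X)
        if X.shape[0] < 3:
            raise ValueError("need at least 3 observations")
        Z = transform_to_normal(X.to_numpy(dtype=float), self.transform)
        corr = pd.DataFrame(np.corrcoef(Z, rowvar=False), index=X.columns, columns=X.columns)
        return self.fit_correlation(corr)

    def fit_correlation(self, corr: pd.DataFrame):
        """Fit directly from a precomputed correlation matrix."""
        corr = pd.DataFrame(corr)
        A = corr.to_numpy(dtype=float)
        if A.shape[0] != A.shape[1]:
            raise ValueError("correlation matrix must be square")
        if np.isnan(A).any():
            raise ValueError("correlation matrix contains NaN")
        if not np.allclose(A, A.T, atol=1e-8):
            raise ValueError("correlation matrix must be symmetric")
        eigval, eigvec = np.linalg.eigh(A)
        if eigval.min() < -1e-8:
            raise ValueError("correlation matrix must be positive semidefinite")
        order = np.argsort(eigval)[::-1]
        eigval = np.clip(eigval[order], 0.0, None)
        eigvec = eigvec[:, order]
        p = A.shape[0]
        loadings_all = _fix_sign(eigvec * np.sqrt(eigval))
        n_ret = int(np.sum(eigval > 1.0))
        if n_ret == 0:
            warnings.warn(
                "no eigenvalue exceeds 1; no factor retained", UserWarning, stacklevel=2
            )
        retained = loadings_all[:, :n_ret]
        rotation = self.rotation
        if rotation is not None and n_ret >= 2:
            if rotation != "varimax":
                raise ValueError(f"unknown rotation {rotation!r}")
            retained, _ = rotate_factors(retained, "varimax")
            retained = _fix_sign(retained)

        self.correlation_ = corr
        self.eigenvalues_ = eigval
        self.variance_pct_ = 100.0 * eigval / p
        self.cumulative_pct_ = np.cumsum(self.variance_pct_)
        self.n_factors_ = n_ret
        self.feature_names_in_ = np.asarray(corr.index)
        cols = [f"factor_{j + 1}" for j in range(p)]
        self.loadings_all_ = pd.DataFrame(loadings_all, index=corr.index, columns=cols)
        self.loadings_ = pd.DataFrame(retained, index=corr.index, columns=cols[:n_ret])
        return self

    def to_model(self) -> FactorModel:
        return FactorModel(
            loadings=self.loadings_,
            loadings_all=self.loadings_all_,
            eigenvalues=self.eigenvalues_,
            variance_pct=self.variance_pct_,
            cumulative_pct=self.cumulative_pct_,
            retention_rule={"rule": "kaiser", "threshold": 1.0, "strict": True},
            rotation=self.rotation if self.n_factors_ >= 2 else None,
        )


def factor_analysis(
    corr: CorrelationResult | pd.DataFrame, rotation: str | None = None
) -> FactorModel:
    """Principal-component factoring of a correlation matrix (Kaiser retention).

    Accepts a :class:`CorrelationResult` (its r matrix is used) or a plain
    square DataFrame.
    """
    r = corr.r if isinstance(corr, CorrelationResult) else corr
    est = EigenFactorAnalysis(rotation=rotation)
    est.fit_correlation(r)
    return est.to_model()
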