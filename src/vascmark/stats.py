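"""Cohort association analysis.

Implements the statistical layer of the pipeline: normality testing,
Pearson/Spearman correlation with cell-wise outlier handling and
pairwise-complete Ns, multiple linear regression with standardized
coefficients, and a pairwise interaction scan.

Correlation pairs follow the published layout: Pearson for all-continuous
pairs, Spearman whenever the ordinal Max SC is involved.  Outlier removal
invalidates individual cells, never whole records, so different pairs may
have different N.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors

from .errors import DataError, StatsError

#: marker columns carrying per-cell validity flags
MARKER_COLUMNS = ("mean_sc", "max_sc", "nwi", "pwv_proximal", "pwv_distal")

#: (row, column) pairs of the association matrix, in published order
ASSOCIATION_PAIRS = (
    ("pwv_proximal", "mean_sc"),
    ("pwv_proximal", "max_sc"),
    ("pwv_proximal", "nwi"),
    ("pwv_distal", "mean_sc"),
    ("pwv_distal", "max_sc"),
    ("pwv_distal", "nwi"),
    ("nwi", "mean_sc"),
    ("nwi", "max_sc"),
)

ORDINAL_MARKERS = ("max_sc",)


class CohortTable:
    """Per-patient marker table with per-cell validity flags.

    ``data`` holds one row per patient with columns id, age, gender and the
    marker columns; ``valid`` is a boolean frame over the marker columns
    (all cells valid by default).
    """

    def __init__(self, data: pd.DataFrame, valid: pd.DataFrame | None = None):
        required = {"id", "age", "gender", *MARKER_COLUMNS}
        missing = required - set(data.columns)
        if missing:
            raise DataError(f"cohort table missing columns: {sorted(missing)}")
        if data["id"].duplicated().any():
            raise DataError("duplicate patient ids in cohort table")
        self.data = data.reset_index(drop=True)
        if valid is None:
            valid = pd.DataFrame(
                True, index=self.data.index, columns=list(MARKER_COLUMNS)
            )
        self.valid = valid.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), self.valid.copy())

    def invalidate(self, patient_id, variable: str) -> None:
        if variable not in MARKER_COLUMNS:
            raise DataError(f"unknown marker variable {variable!r}")
        rows = self.data.index[self.data["id"] == patient_id]
        if len(rows) == 0:
            raise DataError(f"unknown patient id {patient_id!r}")
        self.valid.loc[rows, variable] = False

    def pair_values(self, x: str, y: str) -> tuple:
        """Pairwise-complete values for two variables (cell-valid rows only)."""
        ok = self._valid_for(x) & self._valid_for(y)
        return (
            self.data.loc[ok, x].to_numpy(dtype=float),
            self.data.loc[ok, y].to_numpy(dtype=float),
        )

    def _valid_for(self, var: str) -> pd.Series:
        base = self.data[var].notna()
        if var in MARKER_COLUMNS:
            return base & self.valid[var]
        return base

    def to_csv(self, path) -> None:
        out = self.data.copy()
        for col in MARKER_COLUMNS:
            out.loc[~self.valid[col], col] = np.nan
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        data = pd.read_csv(path)
        table = cls(data)
        for col in MARKER_COLUMNS:
            table.valid[col] = data[col].notna()
        return table


@dataclass(frozen=True)
class PairAssociation:
    x: str
    y: str
    method: str  # 'pearson' | 'spearman'
    estimate: float
    p: float
    n_pairs: int
    error: str | None = None


@dataclass(frozen=True)
class AssociationReport:
    full: tuple
    outlier_removed: tuple | None = None

    def entry(self, x: str, y: str, dataset: str = "full") -> PairAssociation:
        entries = self.full if dataset == "full" else self.outlier_removed
        for e in entries:
            if {e.x, e.y} == {x, y}:
                return e
        raise KeyError((x, y, dataset))

    def to_records(self) -> list:
        recs = []
        for name, entries in (("full", self.full), ("outlier_removed", self.outlier_removed)):
            if entries is None:
                continue
            for e in entries:
                recs.append(
                    {
                        "dataset": name, "x": e.x, "y": e.y, "method": e.method,
                        "estimate": e.estimate, "p": e.p, "n_pairs": e.n_pairs,
                        "error": e.error,
                    }
                )
        return recs


@dataclass(frozen=True)
class CoefficientRow:
    name: str
    b: float
    se: float
    beta: float  # standardized; NaN for the intercept
    p: float


@dataclass(frozen=True)
class RegressionFit:
    outcome: str
    predictors: tuple
    coefficients: tuple  # CoefficientRow, intercept first
    r_squared: float
    n_obs: int

    def coefficient(self, name: str) -> CoefficientRow:
        for row in self.coefficients:
            if row.name == name:
                return row
        raise KeyError(name)


def ks_normality(
    values, method: str = "lilliefors", n_sims: int = 10000, seed: int | None = None
) -> tuple:
    """One-sample KS test of normality with plug-in mean/SD.

    ``method='lilliefors'`` calibrates the p-value for the estimated
    parameters (Monte-Carlo / table hybrid as implemented in statsmodels);
    ``method='plugin'`` returns the classic KS p-value with the fitted normal
    treated as fully specified, which is conservative (the SPSS-style
    default one-sample KS behaves this way).
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 5:
        raise StatsError(f"need >= 5 observations, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise StatsError("constant vector: normality test undefined")
    if method == "lilliefors":
        stat, p = lilliefors(x, dist="norm", pvalmethod="table")
        return float(stat), float(p)
    if method == "plugin":
        res = scipy.stats.kstest(x, "norm", args=(x.mean(), sd))
        return float(res.statistic), float(res.pvalue)
    raise StatsError(f"unknown KS method {method!r}")


def _check_pair(x, y) -> tuple:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise StatsError(f"need >= 3 complete pairs, got {x.size}")
    if x.std() == 0 or y.std() == 0:
        raise StatsError("zero variance in one of the variables")
    return x, y


def pearson(x, y) -> tuple:
    """Product-moment correlation with a two-sided t-based p-value."""
    x, y = _check_pair(x, y)
    res = scipy.stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple:
    """Rank correlation (midranks for ties) with a two-sided t-approximation p."""
    x, y = _check_pair(x, y)
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rs = float(scipy.stats.pearsonr(rx, ry).statistic)
    n = x.size
    if abs(rs) >= 1.0:
        return rs, 0.0
    tstat = rs * np.sqrt((n - 2) / (1 - rs**2))
    p = 2 * scipy.stats.t.sf(abs(tstat), df=n - 2)
    return rs, float(p)


def remove_outlier_cells(cohort: CohortTable, flags) -> CohortTable:
    """Invalidate individual (patient, variable) cells; records stay in place.

    Only the flagged cells drop out, so each correlation keeps every record
    whose two involved cells are still valid (pairwise-complete deletion).
    """
    out = cohort.copy()
    for patient_id, variable in flags:
        out.invalidate(patient_id, variable)
    return out


def _pair_association(cohort: CohortTable, x: str, y: str) -> PairAssociation:
    method = "spearman" if (x in ORDINAL_MARKERS or y in ORDINAL_MARKERS) else "pearson"
    xv, yv = cohort.pair_values(x, y)
    try:
        est, p = (spearman if method == "spearman" else pearson)(xv, yv)
        return PairAssociation(x, y, method, est, p, int(xv.size))
    except StatsError as exc:
        return PairAssociation(x, y, method, np.nan, np.nan, int(xv.size), error=str(exc))


def association_matrix(cohort: CohortTable, outlier_flags=None) -> AssociationReport:
    """The eight-pair association report, full and (optionally) outlier-removed."""
    full = tuple(_pair_association(cohort, x, y) for x, y in ASSOCIATION_PAIRS)
    removed = None
    if outlier_flags:
        reduced = remove_outlier_cells(cohort, outlier_flags)
        removed = tuple(_pair_association(reduced, x, y) for x, y in ASSOCIATION_PAIRS)
    return AssociationReport(full=full, outlier_removed=removed)


def _design(df: pd.DataFrame, predictors) -> np.ndarray:
    X = df[list(predictors)].to_numpy(dtype=float)
    return sm.add_constant(X, has_constant="add")


def fit_linear_model(df: pd.DataFrame, outcome: str, predictors) -> RegressionFit:
    """OLS of ``outcome`` on ``predictors`` with standardized coefficients.

    Rows with any missing value among the involved columns are dropped.
    The standardized coefficient is beta_j = B_j * SD(x_j) / SD(y).
    """
    predictors = tuple(predictors)
    cols = [outcome, *predictors]
    sub = df[cols].dropna()
    n = len(sub)
    if n <= len(predictors) + 1:
        raise StatsError(f"n={n} too small for {len(predictors)} predictors")
    y = sub[outcome].to_numpy(dtype=float)
    X = _design(sub, predictors)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise StatsError("rank-deficient design matrix (collinear predictors)")
    if np.linalg.cond(X) > 1e10:
        raise StatsError("ill-conditioned design matrix")
    res = sm.OLS(y, X).fit()
    sd_y = y.std(ddof=1)
    rows = [CoefficientRow("const", float(res.params[0]), float(res.bse[0]),
                           np.nan, float(res.pvalues[0]))]
    for j, name in enumerate(predictors, start=1):
        sd_x = sub[name].to_numpy(dtype=float).std(ddof=1)
        rows.append(
            CoefficientRow(
                name,
                b=float(res.params[j]),
                se=float(res.bse[j]),
                beta=float(res.params[j] * sd_x / sd_y),
                p=float(res.pvalues[j]),
            )
        )
    return RegressionFit(
        outcome=outcome,
        predictors=predictors,
        coefficients=tuple(rows),
        r_squared=float(res.rsquared),
        n_obs=n,
    )


def interaction_scan(df: pd.DataFrame, outcome: str, predictors) -> dict:
    """p-value of each pairwise product term added to the main-effects model.

    Continuous variables are mean-centered before multiplication, so the
    main effects keep their interpretation.  Returns
    {(pred_a, pred_b): p_product_term}.
    """
    predictors = tuple(predictors)
    out = {}
    for a, b in combinations(predictors, 2):
        sub = df[[outcome, *predictors]].dropna().copy()
        prod = (sub[a] - sub[a].mean()) * (sub[b] - sub[b].mean())
        sub["_interaction"] = prod
        fit = fit_linear_model(sub, outcome, predictors + ("_interaction",))
        out[(a, b)] = fit.coefficient("_interaction").p
    return out
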