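"""Cross-scale integration statistics.

Assembles the product x parameter feature table (replicate means) and
runs the comparison statistics: min-max normalization, parameter
variance ranking against a threshold, pairwise-complete Pearson
correlation matrices (combined and per product set), and univariate
F-statistic feature selection (top-k, k = 3 by default) against a chosen
target parameter.  Correlations are computed on product-level averages;
no multiple-testing correction is applied (p-values are informational).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.feature_selection import f_regression

PRODUCT_SET_COLUMN = "product_set"
VARIANCE_THRESHOLD_COMBINED = 0.10
VARIANCE_THRESHOLD_PER_SET = 0.15
DEFAULT_TOP_K = 3


@dataclass
class VarianceReport:
    """Per-parameter variance of min-max-normalized values with a flagged set."""

    variances: pd.Series
    threshold: float
    flagged: list[str]


@dataclass
class CorrelationMatrix:
    """Pairwise-complete Pearson correlations with per-pair sample counts."""

    r: pd.DataFrame
    n: pd.DataFrame

    def p_values(self) -> pd.DataFrame:
        """Two-sided p-values of each correlation (informational; uncorrected)."""
        r = self.r.to_numpy(dtype=float)
        n = self.n.to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / (1.0 - r**2))
            p = 2.0 * sps.t.sf(np.abs(t), df=np.maximum(n - 2, 1))
        p[~np.isfinite(r)] = np.nan
        np.fill_diagonal(p, np.nan)
        return pd.DataFrame(p, index=self.r.index, columns=self.r.columns)


@dataclass
class SelectionResult:
    """Univariate F-statistic ranking of features against one target."""

    target: str
    ranking: pd.DataFrame  # columns: feature, F, n; descending F
    selected: list[str]


def _numeric(table: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in table.columns if c != PRODUCT_SET_COLUMN]
    return table[cols].apply(pd.to_numeric, errors="coerce")


def build_feature_table(
    modalities: dict[str, pd.DataFrame],
    metadata: pd.DataFrame,
    product_column: str = "product",
) -> pd.DataFrame:
    """Replicate-mean product x parameter table.

    ``modalities`` maps a modality name to a replicate-level frame with a
    ``product`` column and numeric parameter columns; replicates are
    averaged per product.  ``metadata`` carries one row per product with
    the ``product_set`` label and any externally supplied columns (fibre
    score, process variables).  Products absent from a modality get NA in
    that modality's columns.
    """
    if metadata[product_column].duplicated().any():
        raise ValueError("duplicate product IDs in metadata")
    out = metadata.set_index(product_column).copy()
    seen = set(out.columns)
    for name, frame in modalities.items():
        if frame is None or frame.empty:
            continue
        if product_column not in frame.columns:
            raise ValueError(f"modality {name!r} lacks a {product_column!r} column")
        numeric_cols = [
            c for c in frame.columns
            if c != product_column and pd.api.types.is_numeric_dtype(frame[c])
        ]
        means = frame.groupby(product_column)[numeric_cols].mean()
        clash = seen & set(means.columns)
        if clash:
            raise ValueError(f"duplicate parameter columns: {sorted(clash)}")
        seen |= set(means.columns)
        out = out.join(means, how="left")
    out.index.name = product_column
    return out


def minmax_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-column (x - min)/(max - min) scaling of the numeric columns.

    Constant columns map to 0 with a warning; NA values are preserved;
    the ``product_set`` label column passes through untouched.
    """
    out = table.copy()
    for col in _numeric(table).columns:
        x = pd.to_numeric(table[col], errors="coerce")
        lo, hi = x.min(), x.max()
        if pd.isna(lo):
            continue
        if hi == lo:
            warnings.warn(f"constant column {col!r} normalized to 0", stacklevel=2)
            out[col] = x * 0.0
        else:
            out[col] = (x - lo) / (hi - lo)
    return out


def parameter_variance(
    normalized: pd.DataFrame, threshold: float = VARIANCE_THRESHOLD_COMBINED
) -> VarianceReport:
    """Sample variance (ddof=1) per normalized column, flagged above threshold.

    Rows with NA are dropped per column; columns with fewer than two
    observations report NA and are never flagged.
    """
    num = _numeric(normalized)
    variances = num.var(ddof=1, skipna=True)
    variances[num.notna().sum() < 2] = np.nan
    flagged = [c for c in variances.index if pd.notna(variances[c]) and variances[c] > threshold]
    return VarianceReport(variances=variances, threshold=threshold, flagged=flagged)


def pearson_matrix(
    table: pd.DataFrame,
    subset: list[str] | None = None,
    min_periods: int = 3,
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation matrix over product averages.

    Cells with fewer than ``min_periods`` complete pairs are NA.
    """
    num = _numeric(table)
    if subset is not None:
        num = num[subset]
    r = num.corr(method="pearson", min_periods=min_periods)
    present = num.notna().astype(int)
    n = pd.DataFrame(
        present.T.to_numpy() @ present.to_numpy(),
        index=num.columns,
        columns=num.columns,
    )
    return CorrelationMatrix(r=r, n=n)


def univariate_select(
    table: pd.DataFrame,
    target: str,
    k: int = DEFAULT_TOP_K,
    candidates: list[str] | None = None,
) -> SelectionResult:
    """Rank features by the univariate regression F-statistic against a target.

    Per feature, F = r^2 (n - 2) / (1 - r^2) on the pairwise-complete
    rows; the target itself is excluded from the candidate set; ties are
    broken by column order.  If fewer than ``k`` features are available,
    all are returned with a warning.
    """
    num = _numeric(table)
    if target not in num.columns:
        raise KeyError(f"target column {target!r} not present")
    y_all = num[target]
    if candidates is None:
        candidates = [c for c in num.columns if c != target]
    else:
        candidates = [c for c in candidates if c != target]
    rows = []
    for col in candidates:
        pair = pd.concat([num[col], y_all], axis=1).dropna()
        n = len(pair)
        if n < 3 or pair.iloc[:, 0].nunique() < 2 or pair.iloc[:, 1].nunique() < 2:
            rows.append({"feature": col, "F": np.nan, "n": n})
            continue
        F, _ = f_regression(pair.iloc[:, [0]].to_numpy(), pair.iloc[:, 1].to_numpy())
        rows.append({"feature": col, "F": float(F[0]), "n": n})
    ranking = pd.DataFrame(rows, columns=["feature", "F", "n"])
    order = np.argsort(-ranking["F"].fillna(-np.inf).to_numpy(), kind="stable")
    ranking = ranking.iloc[order].reset_index(drop=True)
    avail = int(ranking["F"].notna().sum())
    if k > avail:
        warnings.warn(
            f"only {avail} usable features available for k={k}", stacklevel=2
        )
    selected = ranking.loc[ranking["F"].notna(), "feature"].head(k).tolist()
    return SelectionResult(target=target, ranking=ranking, selected=selected)


def per_set_tables(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split the feature table by its product-set label."""
    if PRODUCT_SET_COLUMN not in table.columns:
        raise KeyError(f"table lacks a {PRODUCT_SET_COLUMN!r} column")
    return {
        str(label): sub for label, sub in table.groupby(PRODUCT_SET_COLUMN, sort=True)
    }
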