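"""Collinearity-based covariate selection.

Climate covariates such as the bioclim set are strongly intercorrelated,
which destabilises model weights and muddies interpretation.  Selection
here is the standard two-stage screen: a pairwise Pearson prefilter
(drop one member of every pair with |r| above a threshold, default 0.7)
followed by iterative elimination of variables whose variance inflation
factor VIF_j = 1 / (1 - R^2_j) exceeds a threshold (default 10), where
R^2_j comes from regressing variable j on all other remaining variables.

Both stages are deterministic: within an offending pair the variable
with the larger mean absolute correlation against the remaining
variables is dropped, ties broken by later input order.  Zero-variance
variables are removed up front (their correlation is undefined).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SelectionError(ValueError):
    pass


@dataclass
class SelectionReport:
    """Outcome of a selection stage: what survived, what fell, and why."""

    kept: list[str]
    dropped: list[tuple[str, str, float]] = field(default_factory=list)  # (name, reason, stat)
    correlation: pd.DataFrame | None = None
    vif: pd.Series | None = None

    def merge(self, later: "SelectionReport") -> "SelectionReport":
        return SelectionReport(
            kept=later.kept,
            dropped=self.dropped + later.dropped,
            correlation=self.correlation if later.correlation is None else later.correlation,
            vif=later.vif,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [{"variable": v, "status": "kept", "reason": "", "statistic": np.nan} for v in self.kept]
        rows += [
            {"variable": v, "status": "dropped", "reason": why, "statistic": stat}
            for v, why, stat in self.dropped
        ]
        return pd.DataFrame(rows, columns=["variable", "status", "reason", "statistic"])


def _as_frame(matrix, names=None) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix
    matrix = np.asarray(matrix, dtype=float)
    if names is None:
        names = [f"v{j}" for j in range(matrix.shape[1])]
    return pd.DataFrame(matrix, columns=list(names))


def pearson_prefilter(matrix, threshold: float = 0.7, names=None) -> SelectionReport:
    """Iteratively drop one variable from each |r| > threshold pair.

    Drops are strict (> threshold).  The correlation matrix of the
    original non-constant variables is attached to the report.
    """
    df = _as_frame(matrix, names)
    if df.shape[1] < 2:
        raise SelectionError("need at least 2 variables")
    if df.shape[0] < 3:
        raise SelectionError("need at least 3 complete rows")

    dropped: list[tuple[str, str, float]] = []
    stds = df.std(ddof=0)
    constant = [c for c in df.columns if not stds[c] > 0]
    for c in constant:
        dropped.append((c, "constant", 0.0))
    remaining = [c for c in df.columns if c not in constant]

    corr_full = df[remaining].corr() if remaining else None
    order = {c: i for i, c in enumerate(df.columns)}

    while len(remaining) >= 2:
        corr = corr_full.loc[remaining, remaining].abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = float(corr.values.max())
        if worst <= threshold:
            break
        i, j = np.unravel_index(int(corr.values.argmax()), corr.shape)
        a, b = corr.index[i], corr.columns[j]
        # mean |r| of each candidate against all other remaining variables
        mean_a = corr.loc[a].drop(a).mean()
        mean_b = corr.loc[b].drop(b).mean()
        if np.isclose(mean_a, mean_b):
            victim = a if order[a] > order[b] else b  # later input order falls
        else:
            victim = a if mean_a > mean_b else b
        dropped.append((victim, "pearson", worst))
        remaining = [c for c in remaining if c != victim]

    return SelectionReport(kept=remaining, dropped=dropped, correlation=corr_full)


def compute_vif(df: pd.DataFrame) -> pd.Series:
    """VIF_j = 1/(1 - R^2_j) from least squares of column j on the others.

    Perfect collinearity yields inf rather than an exception.
    """
    names = list(df.columns)
    X = df.to_numpy(dtype=float)
    n = X.shape[0]
    out = {}
    for j, name in enumerate(names):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot <= 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def vif_filter(matrix, threshold: float = 10.0, names=None) -> SelectionReport:
    """Iteratively drop the variable with the largest VIF until all
    remaining VIFs are at or below the threshold."""
    df = _as_frame(matrix, names)
    dropped: list[tuple[str, str, float]] = []
    stds = df.std(ddof=0)
    for c in df.columns:
        if not stds[c] > 0:
            dropped.append((c, "constant", 0.0))
    remaining = [c for c in df.columns if not any(d[0] == c for d in dropped)]

    vifs = pd.Series(dtype=float)
    while len(remaining) >= 2:
        vifs = compute_vif(df[remaining])
        worst = vifs.max()
        if not worst > threshold:
            break
        victim = vifs.idxmax()
        dropped.append((victim, "vif", float(worst)))
        remaining = [c for c in remaining if c != victim]
        vifs = vifs.drop(victim)
    if len(remaining) == 1:
        vifs = pd.Series({remaining[0]: 1.0}, name="VIF")

    return SelectionReport(kept=remaining, dropped=dropped, vif=vifs)


def select_variables(
    matrix,
    pearson_threshold: float = 0.7,
    vif_threshold: float = 10.0,
    names=None,
) -> SelectionReport:
    """Sequential Pearson prefilter then VIF elimination (the usual order)."""
    df = _as_frame(matrix, names)
    stage1 = pearson_prefilter(df, threshold=pearson_threshold)
    if len(stage1.kept) < 2:
        return stage1
    stage2 = vif_filter(df[stage1.kept], threshold=vif_threshold)
    return stage1.merge(stage2)
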