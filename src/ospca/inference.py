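"""Loading statistics: correlations, t-tests and FDR-adjusted selection.

What makes OS-PCA loadings testable is the identity linking the weight
vector to correlations: on autoscaled data the correlation between the
auxiliary score ``s = X w_y`` and metabolite p,

    corr(s, x_p) = 2 lambda_x w_x,p / var(s),

is elementwise proportional to ``w_x`` with a single positive constant.
Defining the loading ``r = corr(s, x_p)`` allows the classical
correlation t-test, ``t = r sqrt(n-2) / sqrt(1-r^2)`` with n-2 degrees
of freedom, followed by Benjamini–Hochberg adjustment across
metabolites.  For repeated measurements the correlation is between the
averaged score ``M s`` and averaged metabolite levels ``M x_p``, with u
(number of replicate sets) paired observations, hence u-2 degrees of
freedom.  Smoothed PCA exposes no such identity, so loading tests are
refused for it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .decomp import ComponentModel
from .preprocess import DataMatrix

__all__ = [
    "LoadingTestResult",
    "UnsupportedMethodError",
    "compute_loadings",
    "loading_t_test",
    "adjust_fdr",
    "loading_test_table",
    "select_metabolites",
]


class UnsupportedMethodError(ValueError):
    """Raised when loadings are requested for a model that has none."""


@dataclass(frozen=True)
class LoadingTestResult:
    """Per-metabolite loading test for one component."""

    metabolite_name: str
    loading: float
    t_statistic: float
    df: int
    p_value: float
    q_value: float


def _corr_with_columns(y: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Pearson correlation of vector y with every column of A."""
    yc = y - y.mean()
    Ac = A - A.mean(axis=0)
    denom = np.linalg.norm(yc) * np.linalg.norm(Ac, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ Ac) / denom
    return np.clip(r, -1.0, 1.0)


def compute_loadings(model: ComponentModel, X: DataMatrix, component: int = 1) -> np.ndarray:
    """Loadings of one component as correlations with metabolite levels.

    ``component`` is 1-based (component 2 is "OS-PC2").  For pca the
    loading is corr(t, x_p); for ospca corr(s, x_p); for ospca_rep
    corr(M s, M x_p) computed on the averaged data.  spca is refused:
    its generalized eigenvectors admit no correlation interpretation.
    """
    if model.method == "spca":
        raise UnsupportedMethodError(
            "smoothed PCA eigenvectors have no correlation interpretation; "
            "loading tests are available for pca, ospca and ospca_rep only"
        )
    if not (1 <= component <= model.k):
        raise ValueError(f"component must be in 1..{model.k}, got {component}")
    if tuple(X.metabolite_names) != tuple(model.metabolite_names):
        raise ValueError("data matrix columns do not match the fitted model")
    j = component - 1
    if model.method == "pca":
        return _corr_with_columns(model.scores_t[:, j], X.values)
    if model.method == "ospca":
        return _corr_with_columns(model.scores_s[:, j], X.values)
    # ospca_rep: averaged score against averaged data
    if model.averaged_data is None:
        raise ValueError("repeated-measurement model lacks averaged data")
    return _corr_with_columns(model.scores_avg[:, j], model.averaged_data)


def loading_t_test(r, n_eff: int):
    """t-statistic and two-sided p-value for a loading (correlation) r.

    ``n_eff`` is the number of paired observations entering the
    correlation: n samples for pca/ospca, u replicate sets for
    ospca_rep.  ``t = r sqrt(n_eff - 2) / sqrt(1 - r^2)`` referred to a
    t-distribution with ``n_eff - 2`` degrees of freedom.  |r| = 1 maps
    to infinite t and p = 0.
    """
    if n_eff < 3:
        raise ValueError(f"the correlation t-test needs n_eff >= 3, got {n_eff}")
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    df = n_eff - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
        t = np.where(np.abs(r) == 1.0, np.sign(r) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    if t.ndim == 0:
        return float(t), float(p)
    return t, p


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def loading_test_table(
    model: ComponentModel, X: DataMatrix, component: int = 1
) -> pd.DataFrame:
    """Full loading-test table for one component.

    Columns: metabolite, component, r, t, df, p, q.  The degrees of
    freedom use the number of rows entering the correlation (replicate
    sets for the repeated-measurement model).
    """
    r = compute_loadings(model, X, component)
    n_eff = model.averaged_data.shape[0] if model.method == "ospca_rep" else model.n_samples
    t, p = loading_t_test(r, n_eff)
    q = adjust_fdr(p)
    return pd.DataFrame(
        {
            "metabolite": list(model.metabolite_names),
            "component": component,
            "r": r,
            "t": t,
            "df": n_eff - 2,
            "p": p,
            "q": q,
        }
    )


def select_metabolites(results: pd.DataFrame, q_threshold: float) -> pd.DataFrame:
    """Rows with q below the threshold, strongest |loading| first.

    The sign of r is the direction of association with the component
    score and is preserved in the output.
    """
    hits = results[results["q"] < q_threshold].copy()
    return hits.reindex(hits["r"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )
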