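"""Data-matrix container and the scaling conventions of the decompositions.

All decompositions expect autoscaled data: every metabolite column shifted
to mean zero and scaled to unit variance, with variance computed with
divisor ``n`` (matching the ``var(t) = (1/n) t't`` convention used
throughout the eigenproblems).  With repeated measurements the averaged
matrix ``M X`` is the object that must be autoscaled, so
:func:`autoscale_by_average` standardizes the columns of ``X`` by the
column statistics of ``M X``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import AveragingOperator

logger = logging.getLogger(__name__)

__all__ = ["DataMatrix", "autoscale", "autoscale_by_average"]

_ZERO_VAR_TOL = 1e-12


@dataclass(frozen=True)
class DataMatrix:
    """Samples x metabolites values with row/column labels.

    ``scaling_state`` tracks what has been applied:
    ``raw | centered | autoscaled | autoscaled_by_average``.
    """

    values: np.ndarray
    sample_ids: tuple
    metabolite_names: tuple
    scaling_state: str = "raw"

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "metabolite_names", tuple(self.metabolite_names))
        if vals.ndim != 2:
            raise ValueError("values must be 2-D (samples x metabolites)")
        if vals.shape != (len(self.sample_ids), len(self.metabolite_names)):
            raise ValueError(
                f"shape {vals.shape} does not match {len(self.sample_ids)} sample ids "
                f"x {len(self.metabolite_names)} metabolite names"
            )
        if np.isnan(vals).any():
            rows, cols = np.nonzero(np.isnan(vals))
            coords = [
                (self.sample_ids[r], self.metabolite_names[c])
                for r, c in list(zip(rows, cols))[:5]
            ]
            raise ValueError(
                f"data contains missing values, e.g. at {coords}; impute or drop before use"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.metabolite_names)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, scaling_state: str = "raw") -> "DataMatrix":
        return cls(
            frame.to_numpy(dtype=float),
            tuple(map(str, frame.index)),
            tuple(map(str, frame.columns)),
            scaling_state,
        )

    def take_rows(self, perm: np.ndarray) -> "DataMatrix":
        return replace(
            self,
            values=self.values[perm],
            sample_ids=tuple(self.sample_ids[i] for i in perm),
        )


def _drop_constant(values: np.ndarray, names: tuple, sd: np.ndarray):
    keep = sd > _ZERO_VAR_TOL
    if not keep.all():
        dropped = [names[j] for j in np.nonzero(~keep)[0]]
        logger.warning("dropping %d zero-variance column(s): %s", len(dropped), dropped)
    return keep


def autoscale(X: DataMatrix) -> DataMatrix:
    """Standardize each column to mean 0, variance 1 (divisor n).

    Constant columns carry no information and would divide by zero; they
    are removed with a warning.  Idempotent on already-autoscaled data.
    """
    if X.n < 2:
        raise ValueError("autoscaling needs at least 2 samples")
    mean = X.values.mean(axis=0)
    sd = X.values.std(axis=0)  # divisor n
    keep = _drop_constant(X.values, X.metabolite_names, sd)
    vals = (X.values[:, keep] - mean[keep]) / sd[keep]
    return DataMatrix(
        vals,
        X.sample_ids,
        tuple(X.metabolite_names[j] for j in np.nonzero(keep)[0]),
        "autoscaled",
    )


def autoscale_by_average(X: DataMatrix, M: AveragingOperator) -> DataMatrix:
    """Standardize columns of X by the statistics of the averaged matrix M X.

    After the transform the averaged matrix ``M X`` has column mean 0 and
    variance 1 exactly (divisor u, the number of replicate sets); the raw
    rows of ``X`` generally retain small residual column means.  With all
    replicate sets singletons (M = I) this reduces to :func:`autoscale`.
    """
    if M.matrix.shape[1] != X.n:
        raise ValueError(
            f"averaging operator expects {M.matrix.shape[1]} rows, data has {X.n}"
        )
    avg = M.matrix @ X.values
    mean = avg.mean(axis=0)
    sd = avg.std(axis=0)  # divisor u
    keep = _drop_constant(avg, X.metabolite_names, sd)
    vals = (X.values[:, keep] - mean[keep]) / sd[keep]
    return DataMatrix(
        vals,
        X.sample_ids,
        tuple(X.metabolite_names[j] for j in np.nonzero(keep)[0]),
        "autoscaled_by_average",
    )
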