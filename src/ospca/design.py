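"""Sample-structure descriptors and the matrices that encode them.

The decompositions in :mod:`ospca.decomp` assume the rows of the data
matrix carry structure: samples belong to groups, are ordered within each
group by a covariate (incubation time, taste rank, ...), and may be
repeated measurements of the same underlying sample.  This module
represents that structure (:class:`SampleDesign`) and builds the three
operators derived from it:

* the difference matrix ``D`` (first or second differences of consecutive
  ordered samples within each group) whose quadratic form ``(Ds)'(Ds)``
  penalizes rough score sequences,
* the averaging matrix ``M`` mapping repeated measurements to their
  per-sample means, and
* the penalty matrix ``P = (1-kappa) I + kappa X'D'DX`` (or its averaged
  variant ``Q = (1-kappa) I + kappa X'M'D'DMX``) that enters the
  smoothed/orthogonal-smoothed eigenproblems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SampleDesign",
    "DifferentialOperator",
    "AveragingOperator",
    "PenaltyMatrix",
    "make_difference_matrix",
    "make_averaging_matrix",
    "make_penalty_matrix",
]


def _first_appearance_rank(labels: Sequence) -> dict:
    ranks: dict = {}
    for lab in labels:
        if lab not in ranks:
            ranks[lab] = len(ranks)
    return ranks


@dataclass(frozen=True)
class SampleDesign:
    """Group, order and replicate structure of the measurement rows.

    Parameters
    ----------
    sample_ids
        One identifier per measurement row.
    group
        Categorical group label per row.  Groups are ordered by first
        appearance in the input.
    order
        Real-valued ordering covariate per row (time, rank, ...); used
        only for sorting, never as a numeric weight.
    replicate_set
        Identifier naming which distinct sample a measurement repeats.
        ``None`` means every measurement is its own singleton set.
    """

    sample_ids: tuple
    group: tuple
    order: tuple
    replicate_set: tuple = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "group", tuple(self.group))
        object.__setattr__(self, "order", tuple(float(o) for o in self.order))
        if self.replicate_set is None:
            object.__setattr__(self, "replicate_set", tuple(self.sample_ids))
        else:
            object.__setattr__(self, "replicate_set", tuple(self.replicate_set))
        n = len(self.sample_ids)
        if n < 2:
            raise ValueError("a design needs at least 2 measurements")
        if not (len(self.group) == len(self.order) == len(self.replicate_set) == n):
            raise ValueError("sample_ids, group, order, replicate_set must have equal length")
        if len(set(self.sample_ids)) != n:
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        # group and order must be constant within a replicate set
        seen: dict = {}
        for g, o, r in zip(self.group, self.order, self.replicate_set):
            if r in seen and seen[r] != (g, o):
                raise ValueError(
                    f"replicate set {r!r} mixes (group, order) {seen[r]} and {(g, o)}"
                )
            seen[r] = (g, o)

    # -- basic structure -------------------------------------------------
    @property
    def n(self) -> int:
        """Total number of measurement rows."""
        return len(self.sample_ids)

    @property
    def groups(self) -> tuple:
        """Distinct group labels in first-appearance order."""
        return tuple(_first_appearance_rank(self.group))

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def replicate_sets(self) -> tuple:
        """Distinct replicate-set ids in first-appearance order."""
        return tuple(_first_appearance_rank(self.replicate_set))

    @property
    def replicate_sizes(self) -> tuple:
        counts = {r: 0 for r in self.replicate_sets}
        for r in self.replicate_set:
            counts[r] += 1
        return tuple(counts[r] for r in self.replicate_sets)

    # -- sorting ---------------------------------------------------------
    def sort_key(self) -> list:
        grank = _first_appearance_rank(self.group)
        rrank = _first_appearance_rank(self.replicate_set)
        return [
            (grank[g], o, rrank[r], i)
            for i, (g, o, r) in enumerate(zip(self.group, self.order, self.replicate_set))
        ]

    def sorted(self) -> tuple["SampleDesign", np.ndarray]:
        """Return the canonically sorted design and the row permutation.

        Primary key: group (first-appearance order); secondary: order
        ascending; then replicate set (first appearance) so replicate
        members end up adjacent; ties broken by input position (stable).
        """
        perm = np.array(sorted(range(self.n), key=lambda i: self.sort_key()[i]))
        for g in self.groups:
            orders = [self.order[i] for i in perm if self.group[i] == g]
            if len(set(orders)) < len(orders):
                logger.info("ties in order within group %r broken by input position", g)
            break
        take = lambda xs: tuple(xs[i] for i in perm)  # noqa: E731
        return (
            SampleDesign(
                take(self.sample_ids), take(self.group), take(self.order), take(self.replicate_set)
            ),
            perm,
        )

    def is_sorted(self) -> bool:
        key = self.sort_key()
        return all(key[i][:3] <= key[i + 1][:3] for i in range(self.n - 1))

    def collapsed(self) -> "SampleDesign":
        """Design at replicate-set resolution (one row per distinct sample)."""
        if not self.is_sorted():
            raise ValueError("collapse requires a sorted design; call .sorted() first")
        idx = {}
        for i, r in enumerate(self.replicate_set):
            idx.setdefault(r, i)
        rows = [idx[r] for r in self.replicate_sets]
        return SampleDesign(
            tuple(str(self.replicate_set[i]) for i in rows),
            tuple(self.group[i] for i in rows),
            tuple(self.order[i] for i in rows),
        )


@dataclass(frozen=True)
class DifferentialOperator:
    """Banded difference operator D acting on order-sorted samples."""

    matrix: np.ndarray
    diff_order: int
    row_group_map: tuple

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class AveragingOperator:
    """Row-stochastic operator M mapping measurements to replicate-set means."""

    matrix: np.ndarray
    replicate_sizes: tuple

    @property
    def n_sets(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class PenaltyMatrix:
    """Constraint matrix P (plain) or Q (averaged) of the smoothing penalty.

    ``P = (1-kappa) I + kappa X'D'DX``; with repeated measurements
    ``Q = (1-kappa) I + kappa X'M'D'DMX``.  Positive definite for
    ``kappa`` in [0, 1): its spectrum is bounded below by ``1-kappa``.
    """

    matrix: np.ndarray
    kappa: float
    flavor: str  # "plain" | "averaged"


_STENCILS = {1: np.array([1.0, -1.0]), 2: np.array([1.0, -2.0, 1.0])}


def make_difference_matrix(design: SampleDesign, diff_order: int = 1) -> DifferentialOperator:
    """Build the first or second difference matrix for a sorted design.

    The single-group stencil ([1, -1] or [1, -2, 1]) slides along
    consecutive ordered samples; groups contribute independent blocks, so
    no row straddles a group boundary.  With every group of size at least
    ``diff_order + 1`` the row count is ``n - g`` (order 1) or ``n - 2g``
    (order 2); smaller groups contribute no rows and are logged.
    """
    if diff_order not in _STENCILS:
        raise ValueError(f"diff_order must be 1 or 2, got {diff_order}")
    if not design.is_sorted():
        raise ValueError(
            "design rows are not in canonical order (group, then order); "
            "sort the design (and the data rows) with SampleDesign.sorted() first"
        )
    stencil = _STENCILS[diff_order]
    n = design.n
    blocks = []
    row_groups: list = []
    start = 0
    for g in design.groups:
        size = sum(1 for lab in design.group if lab == g)
        n_rows = size - diff_order
        if n_rows < 1:
            logger.warning(
                "group %r has %d samples, too few for diff_order=%d; contributes no rows",
                g, size, diff_order,
            )
        else:
            block = np.zeros((n_rows, n))
            for i in range(n_rows):
                block[i, start + i : start + i + diff_order + 1] = stencil
            blocks.append(block)
            row_groups.extend([g] * n_rows)
        start += size
    D = np.vstack(blocks) if blocks else np.zeros((0, n))
    return DifferentialOperator(D, diff_order, tuple(row_groups))


def make_averaging_matrix(design: SampleDesign) -> AveragingOperator:
    """Build M, one row per replicate set, entries 1/n_i on the set's columns.

    ``M @ X`` yields per-set column means.  Requires a sorted design so
    that replicate members occupy contiguous rows.
    """
    if not design.is_sorted():
        raise ValueError("design must be sorted before building the averaging matrix")
    sets = design.replicate_sets
    sizes = design.replicate_sizes
    # a replicate set may not span two groups
    for r in sets:
        gs = {design.group[i] for i, lab in enumerate(design.replicate_set) if lab == r}
        if len(gs) > 1:
            raise ValueError(f"replicate set {r!r} spans groups {sorted(map(str, gs))}")
    M = np.zeros((len(sets), design.n))
    col = 0
    for row, (r, ni) in enumerate(zip(sets, sizes)):
        members = [i for i, lab in enumerate(design.replicate_set) if lab == r]
        if members != list(range(col, col + ni)):
            raise ValueError(f"replicate set {r!r} is not contiguous after sorting")
        M[row, col : col + ni] = 1.0 / ni
        col += ni
    return AveragingOperator(M, tuple(sizes))


def make_penalty_matrix(
    X: np.ndarray,
    D: DifferentialOperator,
    kappa: float,
    M: AveragingOperator | None = None,
) -> PenaltyMatrix:
    """Assemble P (or Q when an averaging operator is supplied).

    ``X`` is the n x p (or, via M, averaged u x p) data array the
    decomposition will run on; ``kappa`` in [0, 1) mixes the identity and
    the roughness quadratic form.  ``kappa`` very close to 1 (the 0.999
    used for strongly smoothed fits) is admissible: the identity share
    keeps the matrix positive definite.
    """
    if not (0.0 <= kappa < 1.0):
        raise ValueError(f"kappa must lie in [0, 1), got {kappa}")
    values = np.asarray(X, dtype=float)
    if M is not None:
        values = M.matrix @ values
    if D.matrix.shape[1] != values.shape[0]:
        raise ValueError(
            f"difference matrix has {D.matrix.shape[1]} columns but the "
            f"{'averaged ' if M is not None else ''}data has {values.shape[0]} rows"
        )
    B = D.matrix @ values
    p = values.shape[1]
    mat = (1.0 - kappa) * np.eye(p) + kappa * (B.T @ B)
    mat = 0.5 * (mat + mat.T)
    return PenaltyMatrix(mat, float(kappa), "averaged" if M is not None else "plain")
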