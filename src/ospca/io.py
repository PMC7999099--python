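"""CSV interchange and the end-to-end pipeline.

Data CSV: first column sample_id, one column per metabolite, header row
of metabolite names.  Design CSV: columns sample_id, group, order and
optionally replicate_set.  Rows are re-sorted into the canonical
analysis order (group, then order) on ingestion; every output file
starts with comment lines naming the method and its parameters so
results are self-describing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .decomp import (
    ComponentModel,
    fit_ospca,
    fit_ospca_repeated,
    fit_pca,
    fit_smoothed_pca,
)
from .design import SampleDesign, make_averaging_matrix, make_difference_matrix
from .inference import select_metabolites, loading_test_table
from .preprocess import DataMatrix, autoscale, autoscale_by_average

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "read_dataset", "run_pipeline"]

_FLOAT_FMT = "%.10g"
_METHODS = ("pca", "spca", "ospca", "ospca-rep")


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    data_path: str
    design_path: str
    out_dir: str
    method: str = "ospca"
    kappa: float | None = None
    diff_order: int = 2
    n_components: int | None = None
    test_component: int = 1
    q_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")
        if self.method in ("spca", "ospca", "ospca-rep") and self.kappa is None:
            raise ValueError(
                f"method {self.method!r} requires an explicit kappa (no default: "
                "the smoothing strength is a per-dataset modelling choice)"
            )
        if self.diff_order not in (1, 2):
            raise ValueError("diff_order must be 1 or 2")


def read_dataset(data_path, design_path) -> tuple[DataMatrix, SampleDesign]:
    """Read and cross-validate the data and design CSVs, sorted canonically."""
    data = pd.read_csv(data_path, index_col=0)
    data.index = data.index.map(str)
    if data.shape[0] == 0 or data.shape[1] == 0:
        raise ValueError(f"{data_path}: empty data matrix")
    if data.index.duplicated().any():
        raise ValueError(
            f"{data_path}: duplicate sample ids {sorted(set(data.index[data.index.duplicated()]))}"
        )
    bad = []
    for col in data.columns:
        coerced = pd.to_numeric(data[col], errors="coerce")
        for rid in data.index[coerced.isna() & data[col].notna()]:
            bad.append((rid, col, data.loc[rid, col]))
        data[col] = coerced
    if bad:
        raise ValueError(f"{data_path}: non-numeric cells at (row, column, value): {bad[:10]}")

    des = pd.read_csv(design_path, dtype={"sample_id": str, "group": str})
    required = {"sample_id", "group", "order"}
    if missing := required - set(des.columns):
        raise ValueError(f"{design_path}: missing columns {sorted(missing)}")
    des["order"] = pd.to_numeric(
        des["order"].astype(str).str.strip(), errors="raise"
    )
    data_ids, design_ids = set(data.index), set(des["sample_id"])
    if data_ids != design_ids:
        raise ValueError(
            f"sample ids differ between data and design; only in data: "
            f"{sorted(data_ids - design_ids)}; only in design: {sorted(design_ids - data_ids)}"
        )
    rep = (
        tuple(des["replicate_set"].astype(str))
        if "replicate_set" in des.columns
        else None
    )
    design = SampleDesign(
        tuple(des["sample_id"]), tuple(des["group"]), tuple(des["order"]), rep
    )
    design, perm = design.sorted()
    matrix = DataMatrix.from_frame(data.loc[list(design.sample_ids)])
    return matrix, design


def _write_csv(path: Path, frame: pd.DataFrame, header_lines: list[str], index: bool = True):
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, float_format=_FLOAT_FMT, index=index)


def _fit(config: RunConfig, scaled: DataMatrix, design: SampleDesign):
    k = config.n_components
    if config.method == "pca":
        return fit_pca(scaled, k), None
    if config.method == "ospca-rep":
        M = make_averaging_matrix(design)
        D = make_difference_matrix(design.collapsed(), config.diff_order)
        return fit_ospca_repeated(scaled, M, D, config.kappa, k), M
    D = make_difference_matrix(design, config.diff_order)
    fit = fit_smoothed_pca if config.method == "spca" else fit_ospca
    return fit(scaled, D, config.kappa, k), None


def run_pipeline(config: RunConfig) -> dict:
    """Run read -> scale -> decompose -> loading tests -> write results.

    Writes scores/weights/eigenvalue CSVs, a loadings table with p and q
    values (except for spca, which has no testable loadings), the
    selected metabolites at the configured q threshold, and a JSON run
    manifest.  Returns the manifest as a dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, design = read_dataset(config.data_path, config.design_path)
    p_in = matrix.p

    if config.method == "ospca-rep":
        M = make_averaging_matrix(design)
        scaled = autoscale_by_average(matrix, M)
    else:
        scaled = autoscale(matrix)
    model, _ = _fit(config, scaled, design)

    hdr = [
        f"ospca {__version__}",
        f"method={config.method} kappa={config.kappa} diff_order={config.diff_order}",
    ]
    comps = [f"PC{j + 1}" for j in range(model.k)]
    _write_csv(
        out / "scores_t.csv",
        pd.DataFrame(model.scores_t, index=list(scaled.sample_ids), columns=comps),
        hdr,
    )
    _write_csv(
        out / "weights_x.csv",
        pd.DataFrame(model.weights_x, index=list(scaled.metabolite_names), columns=comps),
        hdr,
    )
    if model.scores_s is not None:
        _write_csv(
            out / "scores_s.csv",
            pd.DataFrame(model.scores_s, index=list(scaled.sample_ids), columns=comps),
            hdr,
        )
        _write_csv(
            out / "weights_y.csv",
            pd.DataFrame(model.weights_y, index=list(scaled.metabolite_names), columns=comps),
            hdr,
        )
    if model.scores_avg is not None:
        _write_csv(
            out / "scores_avg.csv",
            pd.DataFrame(model.scores_avg, index=list(design.replicate_sets), columns=comps),
            hdr,
        )
    eig = pd.DataFrame(
        {
            "component": comps,
            "eigenvalue": model.eigenvalues,
            "contribution": model.contribution,
            "basis": model.contribution_basis,
        }
    )
    _write_csv(out / "eigenvalues.csv", eig, hdr, index=False)

    n_selected = None
    if model.method != "spca":
        table = loading_test_table(model, scaled, config.test_component)
        flag = f"significant_at_{config.q_threshold:g}"
        table[flag] = table["q"] < config.q_threshold
        _write_csv(out / "loadings.csv", table, hdr, index=False)
        hits = select_metabolites(table, config.q_threshold)
        _write_csv(out / "selected_metabolites.csv", hits.drop(columns=[flag]), hdr, index=False)
        n_selected = int(len(hits))

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "n_samples": matrix.n,
        "n_metabolites_input": p_in,
        "n_metabolites_used": scaled.p,
        "dropped_columns": sorted(set(matrix.metabolite_names) - set(scaled.metabolite_names)),
        "n_components": model.k,
        "contribution_basis": model.contribution_basis,
        "n_selected": n_selected,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
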