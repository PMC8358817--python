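"""End-to-end computational experiments.

Each function wires together the tree generators, the hemodynamic solver
and the fractal estimators into one of the package's standard experiments
and returns tidy pandas DataFrames (plus small summary dicts), ready to be
written as CSV/JSON by the CLI or by scripts. Every experiment is exactly
reproducible from its configuration and seed; result tables carry the seed,
the q grid and a configuration hash alongside the numbers.
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .construction import ConstructionConfig, construct_tree
from .errors import ConfigurationError
from .fractal import (
    DEFAULT_Q_GRID,
    analytic_dimension,
    fractal_dimension,
    multifractal_spectrum,
)
from .hemodynamics import MMHG_TO_PA, RheologyParams, solve_network
from .tree import (
    SplitRatioConfig,
    VascularTree,
    carry_forward_table,
    coefficient_of_variation,
    make_perfect_binary_tree,
    read_tree_table,
)

#: Default structure-sweep grids: asymmetry sweep at k = 2.7 and
#: bifurcation-exponent sweep at lambda = 0.80.
LAMBDA_GRID = tuple(np.round(np.arange(0.60, 1.0001, 0.05), 2))
K_GRID = tuple(np.round(np.arange(2.3, 3.0001, 0.1), 1))

try:
    _VERSION = version("hemofractal")
except PackageNotFoundError:  # pragma: no cover
    _VERSION = "unknown"

__all__ = [
    "LAMBDA_GRID",
    "K_GRID",
    "structure_cells",
    "run_split_ratio_sweep",
    "run_depth_sweep",
    "run_structure_sweep",
    "run_flow_diameter_regression",
    "analyze_tree",
    "simulate_cell",
]


def _config_hash(payload: dict) -> str:
    return hashlib.md5(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def structure_cells(kind: str) -> list[tuple[float, float]]:
    """(k_mean, lambda_mean) cells for a structure sweep.

    ``"lambda"``: lambda 0.60..1.00 step 0.05 at k 2.7; ``"k"``: k 2.3..3.0
    step 0.1 at lambda 0.80; ``"full_grid"``: the union of both sweeps (the
    shared (2.7, 0.80) cell appears once).
    """
    lam_cells = [(2.7, float(lam)) for lam in LAMBDA_GRID]
    k_cells = [(float(k), 0.8) for k in K_GRID]
    if kind == "lambda":
        return lam_cells
    if kind == "k":
        return k_cells
    if kind == "full_grid":
        return sorted(set(lam_cells + k_cells))
    raise ConfigurationError(f"unknown sweep kind {kind!r}")


# -- perfect-binary experiments -----------------------------------------


def run_split_ratio_sweep(
    r_grid=None,
    max_generation: int = 9,
    q_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fractal parameters and CV of perfect binary trees across split ratios.

    For each r the tree is built explicitly, the dimension is both estimated
    by regression and evaluated in closed form, and the multifractal
    spectrum summarised by its width and height.
    """
    if r_grid is None:
        r_grid = np.round(np.arange(0.05, 1.0001, 0.05), 2)
    r_grid = np.atleast_1d(np.asarray(r_grid, dtype=float))
    if r_grid.size == 0:
        raise ConfigurationError("r grid must be non-empty")
    q = DEFAULT_Q_GRID if q_grid is None else np.asarray(q_grid, dtype=float)
    chash = _config_hash(
        {"experiment": "split_ratio_sweep", "G": max_generation, "r": list(r_grid)}
    )
    rows = []
    for r in r_grid:
        tree = make_perfect_binary_tree(SplitRatioConfig(max_generation, float(r)))
        table = carry_forward_table(tree)
        scaling = fractal_dimension(table)
        spec = multifractal_spectrum(table, q)
        rows.append(
            {
                "r": r,
                "max_generation": max_generation,
                "d_q_estimated": scaling.dimension,
                "d_q_analytic": analytic_dimension(float(r)),
                "r_squared": scaling.r_squared,
                "cv": coefficient_of_variation(tree),
                "delta_alpha": spec.delta_alpha,
                "f_max": spec.f_max,
                "q_min": q.min(),
                "q_max": q.max(),
                "config_hash": chash,
                "version": _VERSION,
            }
        )
    return pd.DataFrame(rows)


def run_depth_sweep(
    generations=range(6, 13), split_ratios=(0.25, 0.5, 0.75, 1.0)
) -> pd.DataFrame:
    """D_Q and CV of perfect trees across maximal generations.

    Exposes the contrast between the depth-invariant fractal dimension and
    the depth-dependent CV.
    """
    generations = list(generations)
    split_ratios = list(split_ratios)
    if not generations or not split_ratios:
        raise ConfigurationError("generation and split-ratio grids must be non-empty")
    chash = _config_hash(
        {"experiment": "depth_sweep", "G": generations, "r": split_ratios}
    )
    rows = []
    for r in split_ratios:
        for G in generations:
            tree = make_perfect_binary_tree(SplitRatioConfig(int(G), float(r)))
            scaling = fractal_dimension(carry_forward_table(tree))
            rows.append(
                {
                    "r": r,
                    "max_generation": G,
                    "d_q": scaling.dimension,
                    "cv": coefficient_of_variation(tree),
                    "config_hash": chash,
                    "version": _VERSION,
                }
            )
    return pd.DataFrame(rows)


# -- constructed-tree experiments ---------------------------------------


def simulate_cell(
    k_mean: float,
    lambda_mean: float,
    n_trees: int,
    seed,
    k_sd: float = 0.1,
    lambda_sd: float = 0.05,
    q_grid: np.ndarray | None = None,
    params: RheologyParams | None = None,
    inlet_pressure: float = MMHG_TO_PA,
    outlet_pressure: float = 0.0,
    collect_loglog: bool = False,
    compute_spectrum: bool = True,
):
    """Construct, solve and analyse ``n_trees`` trees for one (k, lambda) cell.

    Returns ``(per_tree_dataframe, loglog_points)`` where ``loglog_points``
    is the pooled (log10 d, log10 Q) array when requested, else ``None``.
    Trees themselves are discarded after analysis to bound memory.
    """
    q = DEFAULT_Q_GRID if q_grid is None else np.asarray(q_grid, dtype=float)
    cfg = ConstructionConfig(
        k_mean=float(k_mean),
        lambda_mean=float(lambda_mean),
        k_sd=k_sd,
        lambda_sd=lambda_sd,
    )
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    seeds = seed.spawn(n_trees)
    rows = []
    points = [] if collect_loglog else None
    for i, ss in enumerate(seeds):
        tree = construct_tree(cfg, np.random.default_rng(ss))
        solve_network(tree, inlet_pressure, outlet_pressure, params)
        table = carry_forward_table(tree)
        scaling = fractal_dimension(table)
        row = {
            "k_mean": k_mean,
            "lambda_mean": lambda_mean,
            "tree_index": i,
            "vessel_number": tree.n_segments,
            "max_generation": tree.max_generation,
            "d_q": scaling.dimension,
            "r_squared": scaling.r_squared,
            "cv": coefficient_of_variation(tree),
        }
        if compute_spectrum:
            spec = multifractal_spectrum(table, q)
            row["delta_alpha"] = spec.delta_alpha
            row["f_max"] = spec.f_max
        rows.append(row)
        if collect_loglog:
            points.append(
                np.column_stack(
                    [np.log10(tree.diameters()), np.log10(tree.flows())]
                )
            )
    df = pd.DataFrame(rows)
    return df, (np.vstack(points) if collect_loglog else None)


def run_structure_sweep(
    kind: str = "lambda",
    n_trees: int = 10,
    seed: int | None = 0,
    k_sd: float = 0.1,
    lambda_sd: float = 0.05,
    q_grid: np.ndarray | None = None,
    params: RheologyParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ensemble sweep over tree-structure parameters.

    For every (k_mean, lambda_mean) cell of the requested grid, ``n_trees``
    stochastic trees are constructed, their hemodynamics solved, and the
    per-tree fractal parameters computed. Returns ``(per_tree, summary)``
    DataFrames; the summary holds mean and SD per cell of vessel number,
    maximal generation, D_Q, delta_alpha and f_max.
    """
    if n_trees < 1:
        raise ConfigurationError("n_trees must be >= 1")
    cells = structure_cells(kind)
    q = DEFAULT_Q_GRID if q_grid is None else np.asarray(q_grid, dtype=float)
    seed_seq = (
        seed if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    chash = _config_hash(
        {
            "experiment": f"{kind}_sweep",
            "cells": cells,
            "n_trees": n_trees,
            "seed": seed,
            "k_sd": k_sd,
            "lambda_sd": lambda_sd,
            "q": [float(q.min()), float(q.max()), int(q.size)],
        }
    )
    cell_seeds = seed_seq.spawn(len(cells))
    per_tree = []
    for (k_mean, lam_mean), cseed in zip(cells, cell_seeds):
        df, _ = simulate_cell(
            k_mean, lam_mean, n_trees, cseed, k_sd, lambda_sd, q, params
        )
        per_tree.append(df)
    per_tree = pd.concat(per_tree, ignore_index=True)
    per_tree["seed"] = seed
    per_tree["config_hash"] = chash
    per_tree["version"] = _VERSION

    metrics = ["vessel_number", "max_generation", "d_q", "delta_alpha", "f_max"]
    summary = (
        per_tree.groupby(["k_mean", "lambda_mean"])[metrics]
        .agg(["mean", "std"])
        .reset_index()
    )
    summary.columns = [
        "_".join(c).rstrip("_") if isinstance(c, tuple) else c
        for c in summary.columns
    ]
    summary = summary.fillna({f"{m}_std": 0.0 for m in metrics})
    summary["n_trees"] = n_trees
    summary["seed"] = seed
    summary["config_hash"] = chash
    summary["version"] = _VERSION
    return per_tree, summary


def run_flow_diameter_regression(
    n_trees: int = 10,
    seed: int | None = 0,
    cells: list[tuple[float, float]] | None = None,
    k_sd: float = 0.1,
    lambda_sd: float = 0.05,
    params: RheologyParams | None = None,
) -> dict:
    """Pooled log-log regression of flow on diameter over a tree ensemble.

    Constructs and solves ``n_trees`` trees per (k, lambda) cell (default:
    the full structure-table grid), pools (log10 d, log10 Q) over all
    segments of all trees, and fits an ordinary least-squares line. The
    slope is the empirical flow-diameter scaling exponent.
    """
    if cells is None:
        cells = structure_cells("full_grid")
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    cell_seeds = seed.spawn(len(cells))
    chunks = []
    for (k_mean, lam_mean), cseed in zip(cells, cell_seeds):
        _, pts = simulate_cell(
            k_mean,
            lam_mean,
            n_trees,
            cseed,
            k_sd,
            lambda_sd,
            params=params,
            collect_loglog=True,
            compute_spectrum=False,
        )
        chunks.append(pts)
    pooled = np.vstack(chunks)
    fit = linregress(pooled[:, 0], pooled[:, 1])
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "n_points": int(pooled.shape[0]),
        "n_trees": n_trees * len(cells),
        "seed": seed,
        "config_hash": _config_hash(
            {
                "experiment": "flow_diameter_regression",
                "cells": cells,
                "n_trees": n_trees,
                "seed": seed,
            }
        ),
        "version": _VERSION,
    }


def analyze_tree(
    tree_or_path, q_grid: np.ndarray | None = None
) -> dict:
    """Full fractal/multifractal report of a single flow-carrying tree.

    Accepts a :class:`VascularTree` or a path to a tree table in the CSV
    dialect. Returns a dict with D_Q, its fit R^2, CV, delta_alpha, f_max,
    the q grid bounds and the underlying scaling and spectrum tables
    (as DataFrames under ``"scaling"`` and ``"spectrum"``). This is the
    pathway for analysing measured vascular trees, e.g. arterial trees
    under normal vs ischemic perfusion.
    """
    if isinstance(tree_or_path, VascularTree):
        tree = tree_or_path
    else:
        tree = read_tree_table(Path(tree_or_path))
    q = DEFAULT_Q_GRID if q_grid is None else np.asarray(q_grid, dtype=float)
    table = carry_forward_table(tree)
    scaling = fractal_dimension(table)
    spec = multifractal_spectrum(table, q)
    return {
        "n_segments": tree.n_segments,
        "max_generation": tree.max_generation,
        "d_q": scaling.dimension,
        "r_squared": scaling.r_squared,
        "cv": coefficient_of_variation(tree),
        "delta_alpha": spec.delta_alpha,
        "f_max": spec.f_max,
        "q_min": float(q.min()),
        "q_max": float(q.max()),
        "scaling": scaling.to_frame(),
        "spectrum": spec.to_frame(),
        "version": _VERSION,
    }
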