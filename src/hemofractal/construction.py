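"""Stochastic construction of vascular trees via Murray's bifurcation law.

Starting from a root segment of prescribed diameter, each segment bifurcates
into two daughters whose diameters follow the power-law bifurcation rule

    d0**k = d1**k + d2**k,    lambda = d2 / d1  (<= 1),

so ``d1 = d0 * (1 + lambda**k)**(-1/k)`` and ``d2 = lambda * d1``. The
bifurcation exponent ``k`` (reported range roughly 2.33-3.0; k = 3 is
Murray's classical cube law) and the asymmetry ratio ``lambda`` are drawn
independently at every bifurcation from truncated normal distributions, so
each constructed tree is a random realisation of a heterogeneous vasculature.
Segment length follows the empirical relation ``l = 7.4 * (d/2)**1.15``
(micrometres).

Growth proceeds breadth-first from the root and a segment bifurcates if and
only if BOTH sampled daughter diameters are at or above the capillary cutoff;
otherwise it becomes a terminal. Flows are left unset — they are assigned by
the hemodynamic solver.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ResourceLimitError
from .tree import VascularTree, VesselSegment

#: Truncation window for the bifurcation exponent, spanning the
#: physiologically reported range (area-preserving ~2 up to beyond cube law).
K_WINDOW = (2.0, 3.5)

_MAX_REJECTION_DRAWS = 10_000

__all__ = [
    "K_WINDOW",
    "ConstructionConfig",
    "daughter_diameters",
    "segment_length",
    "sample_bifurcation",
    "construct_tree",
    "construct_ensemble",
    "ensemble_summary",
]


@dataclass(slots=True)
class ConstructionConfig:
    """Parameters of the stochastic tree constructor.

    Defaults place the root at an arteriole-scale 300 um and terminate at
    the 10 um capillary scale. ``k_sd``/``lambda_sd`` control bifurcation-
    to-bifurcation heterogeneity; zero SDs give a deterministic tree.
    """

    root_diameter: float = 300.0
    cutoff_diameter: float = 10.0
    k_mean: float = 2.7
    k_sd: float = 0.1
    lambda_mean: float = 0.8
    lambda_sd: float = 0.05
    seed: int | None = None
    max_segments: int = 1_000_000

    def __post_init__(self) -> None:
        if not (self.root_diameter > 0 and self.cutoff_diameter > 0):
            raise ConfigurationError(
                "diameters must be > 0, got root "
                f"{self.root_diameter} / cutoff {self.cutoff_diameter}"
            )
        if not (0.0 < self.lambda_mean <= 1.0):
            raise ConfigurationError(
                f"lambda_mean must lie in (0, 1], got {self.lambda_mean}"
            )
        if not self.k_mean > 0:
            raise ConfigurationError(f"k_mean must be > 0, got {self.k_mean}")
        if self.k_sd < 0 or self.lambda_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if self.k_sd == 0 and not (K_WINDOW[0] <= self.k_mean <= K_WINDOW[1]):
            raise ConfigurationError(
                f"k_mean {self.k_mean} outside window {K_WINDOW} with k_sd = 0"
            )
        if self.max_segments < 1:
            raise ConfigurationError("max_segments must be >= 1")


def daughter_diameters(d0: float, k: float, lam: float) -> tuple[float, float]:
    """Daughter diameters of a Murray-law bifurcation.

    Returns ``(d1, d2)`` with ``d1 >= d2``, satisfying ``d0**k = d1**k +
    d2**k`` and ``d2 = lam * d1`` exactly (up to rounding).
    """
    if not d0 > 0:
        raise ConfigurationError(f"parent diameter must be > 0, got {d0}")
    if not k > 0:
        raise ConfigurationError(f"bifurcation exponent must be > 0, got {k}")
    if not (0.0 < lam <= 1.0):
        raise ConfigurationError(f"asymmetry ratio must lie in (0, 1], got {lam}")
    d1 = d0 * (1.0 + lam**k) ** (-1.0 / k)
    return d1, lam * d1


def segment_length(d: float) -> float:
    """Empirical segment length (um) from diameter (um): l = 7.4*(d/2)**1.15."""
    if not d > 0:
        raise ConfigurationError("diameter must be > 0")
    return 7.4 * (d / 2.0) ** 1.15


def sample_bifurcation(
    rng: np.random.Generator, config: ConstructionConfig
) -> tuple[float, float]:
    """Draw one (k, lambda) pair from the configured truncated normals.

    Rejection sampling (not clipping) keeps the distribution shape near the
    bounds: k is redrawn until it falls in ``K_WINDOW``, lambda until it
    falls in (0, 1]. Zero-SD parameters return their mean without drawing.
    """
    if config.k_sd == 0.0:
        k = config.k_mean
    else:
        for _ in range(_MAX_REJECTION_DRAWS):
            k = rng.normal(config.k_mean, config.k_sd)
            if K_WINDOW[0] <= k <= K_WINDOW[1]:
                break
        else:
            raise ConfigurationError(
                f"k window {K_WINDOW} rejects ~all draws of "
                f"Normal({config.k_mean}, {config.k_sd})"
            )
    if config.lambda_sd == 0.0:
        lam = config.lambda_mean
    else:
        for _ in range(_MAX_REJECTION_DRAWS):
            lam = rng.normal(config.lambda_mean, config.lambda_sd)
            if 0.0 < lam <= 1.0:
                break
        else:
            raise ConfigurationError(
                "lambda window (0, 1] rejects ~all draws of "
                f"Normal({config.lambda_mean}, {config.lambda_sd})"
            )
    return k, lam


def construct_tree(
    config: ConstructionConfig, rng: np.random.Generator | None = None
) -> VascularTree:
    """Grow one vascular tree breadth-first from the root diameter.

    At each segment a (k, lambda) pair is sampled, the would-be daughter
    diameters computed, and the segment bifurcates iff both daughters are at
    or above ``cutoff_diameter``; otherwise it terminates. The larger
    daughter is always created first, and the sampling order (parent before
    children, first child first) is fixed, so a seed fully determines the
    tree. Flows are left unset.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    segments: dict[int, VesselSegment] = {
        0: VesselSegment(
            0, None, 0, config.root_diameter, segment_length(config.root_diameter)
        )
    }
    queue: deque[int] = deque([0])
    next_id = 1
    cutoff = config.cutoff_diameter
    while queue:
        sid = queue.popleft()
        seg = segments[sid]
        k, lam = sample_bifurcation(rng, config)
        d1, d2 = daughter_diameters(seg.diameter, k, lam)
        if d1 < cutoff or d2 < cutoff:
            continue  # terminal: a daughter would fall below capillary size
        if next_id + 2 > config.max_segments:
            raise ResourceLimitError(
                f"max_segments={config.max_segments} exceeded while growing "
                f"tree (root {config.root_diameter} um, cutoff {cutoff} um, "
                f"k_mean {config.k_mean}, lambda_mean {config.lambda_mean})"
            )
        for d in (d1, d2):
            cid = next_id
            next_id += 1
            segments[cid] = VesselSegment(
                cid, sid, seg.generation + 1, d, segment_length(d)
            )
            seg.child_ids.append(cid)
            queue.append(cid)
    return VascularTree(segments, root_id=0)


def construct_ensemble(
    config: ConstructionConfig, n_trees: int, seed: int | None = None
) -> list[VascularTree]:
    """Construct ``n_trees`` independent trees with per-tree derived seeds.

    The ensemble seed (``seed``, falling back to ``config.seed``) is spawned
    into independent per-tree streams, so the ensemble is reproducible and
    any single tree can be rebuilt in isolation.
    """
    if n_trees < 1:
        raise ConfigurationError("n_trees must be >= 1")
    root_seed = config.seed if seed is None else seed
    children = np.random.SeedSequence(root_seed).spawn(n_trees)
    return [construct_tree(config, np.random.default_rng(ss)) for ss in children]


def ensemble_summary(
    trees: list[VascularTree], config: ConstructionConfig
) -> pd.DataFrame:
    """One-row summary (mean +/- SD of vessel number and max generation)."""
    counts = np.array([t.n_segments for t in trees], dtype=float)
    gens = np.array([t.max_generation for t in trees], dtype=float)
    return pd.DataFrame(
        [
            {
                "k": config.k_mean,
                "lambda": config.lambda_mean,
                "n_trees": len(trees),
                "vessel_number_mean": counts.mean(),
                "vessel_number_sd": counts.std(ddof=1) if len(trees) > 1 else 0.0,
                "max_gen_mean": gens.mean(),
                "max_gen_sd": gens.std(ddof=1) if len(trees) > 1 else 0.0,
            }
        ]
    )
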