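"""Rooted binary vascular trees and flow-distribution bookkeeping.

A vascular tree arises from successive dichotomous division: every internal
vessel segment splits into exactly two daughters, so a segment has either 0
or 2 children. The root is generation 0 and a daughter's generation is its
parent's plus one. Volumetric flow obeys conservation at every bifurcation
(``Q_parent = Q_left + Q_right``), which implies that the total flow crossing
any generation level equals the root flow.

Real trees are not *perfect* binary trees: branches may stop bifurcating
before the maximal generation is reached. The *carry-forward* convention
restores per-generation conservation on such trees: a segment that terminates
at generation ``n`` is counted, with its full flow, in every generation
cross-section beyond ``n``. The nominal cell count of the cross-section at
generation ``n`` is always ``2**n`` — the number of cells a perfect tree
would have — regardless of how many actual segments are included.

This module holds the tree data model, the perfect-binary generator with a
prescribed flow split ratio, the carry-forward flow tables consumed by the
fractal estimators, the coefficient of variation, and CSV tree I/O.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DataError,
    DegenerateInputError,
    TopologyError,
    TreeFormatError,
)

#: Relative tolerance for parent-vs-daughters flow conservation checks.
FLOW_CONSERVATION_RTOL = 1e-9

__all__ = [
    "FLOW_CONSERVATION_RTOL",
    "VesselSegment",
    "VascularTree",
    "GenerationFlowTable",
    "SplitRatioConfig",
    "make_perfect_binary_tree",
    "carry_forward_table",
    "coefficient_of_variation",
    "perfect_tree_cv",
    "read_tree_table",
    "write_tree_table",
]


@dataclass(slots=True)
class VesselSegment:
    """One vessel segment of a binary vascular tree.

    Parameters
    ----------
    id : int
        Integer identifier, unique within a tree.
    parent_id : int or None
        Identifier of the parent segment; ``None`` for the root.
    child_ids : list of int
        Identifiers of the daughter segments; length 0 (terminal) or 2.
    generation : int
        Depth in the tree; the root is generation 0.
    diameter : float
        Lumen diameter in micrometres, > 0.
    length : float
        Segment length in micrometres, > 0.
    flow : float
        Volumetric flow in cubic micrometres per second, >= 0. ``nan``
        while unset (e.g. before a hemodynamic solve).
    """

    id: int
    parent_id: int | None
    generation: int
    diameter: float
    length: float
    flow: float = math.nan
    child_ids: list[int] = field(default_factory=list)

    @property
    def is_terminal(self) -> bool:
        return len(self.child_ids) == 0

    @property
    def has_flow(self) -> bool:
        return not math.isnan(self.flow)


class VascularTree:
    """A rooted binary tree of :class:`VesselSegment` records.

    Invariants enforced on construction: exactly one root, every non-root
    segment reachable from the root, no cycles, 0-or-2 children everywhere,
    and each child's generation equal to its parent's plus one. When flows
    are populated, conservation at every bifurcation can additionally be
    checked with :meth:`check_flow_conservation`.
    """

    def __init__(
        self,
        segments: dict[int, VesselSegment],
        root_id: int,
        validate: bool = True,
    ):
        self.segments = segments
        self.root_id = root_id
        if validate:
            self.validate()

    # -- basic accessors -------------------------------------------------

    @property
    def root(self) -> VesselSegment:
        return self.segments[self.root_id]

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def max_generation(self) -> int:
        return max(s.generation for s in self.segments.values())

    @property
    def flows_populated(self) -> bool:
        return all(s.has_flow for s in self.segments.values())

    def terminals(self) -> list[VesselSegment]:
        return [s for s in self.segments.values() if s.is_terminal]

    def segments_at_generation(self, n: int) -> list[VesselSegment]:
        return [s for s in self.segments.values() if s.generation == n]

    def flows(self) -> np.ndarray:
        """All segment flows, ordered by segment id."""
        return np.array(
            [self.segments[i].flow for i in sorted(self.segments)], dtype=float
        )

    def diameters(self) -> np.ndarray:
        return np.array(
            [self.segments[i].diameter for i in sorted(self.segments)], dtype=float
        )

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if self.root_id not in self.segments:
            raise TopologyError(f"root id {self.root_id} not among segments")
        root = self.segments[self.root_id]
        if root.parent_id is not None:
            raise TopologyError("root segment must have parent_id None")
        roots = [s.id for s in self.segments.values() if s.parent_id is None]
        if roots != [self.root_id]:
            raise TopologyError(f"expected exactly one root, found {roots}")
        if root.generation != 0:
            raise TopologyError("root generation must be 0")

        seen: set[int] = set()
        queue: deque[int] = deque([self.root_id])
        while queue:
            sid = queue.popleft()
            if sid in seen:
                raise TopologyError(f"cycle detected at segment {sid}")
            seen.add(sid)
            seg = self.segments[sid]
            if len(seg.child_ids) not in (0, 2):
                raise TopologyError(
                    f"segment {sid} has {len(seg.child_ids)} children; "
                    "dichotomous division requires 0 or 2"
                )
            for cid in seg.child_ids:
                if cid not in self.segments:
                    raise TopologyError(f"segment {sid} references missing child {cid}")
                child = self.segments[cid]
                if child.parent_id != sid:
                    raise TopologyError(
                        f"segment {cid} parent_id {child.parent_id} != {sid}"
                    )
                if child.generation != seg.generation + 1:
                    raise TopologyError(
                        f"segment {cid} generation {child.generation} is not "
                        f"parent generation {seg.generation} + 1"
                    )
                queue.append(cid)
        if seen != set(self.segments):
            orphans = sorted(set(self.segments) - seen)
            raise TopologyError(f"segments not reachable from root: {orphans[:10]}")
        for seg in self.segments.values():
            if not seg.diameter > 0:
                raise DataError(f"segment {seg.id} has non-positive diameter")
            if not seg.length > 0:
                raise DataError(f"segment {seg.id} has non-positive length")
            if seg.has_flow and seg.flow < 0:
                raise DataError(f"segment {seg.id} has negative flow")

    def check_flow_conservation(self, rtol: float = FLOW_CONSERVATION_RTOL) -> float:
        """Verify ``Q_parent = Q_left + Q_right`` at every bifurcation.

        Returns the maximum relative residual; raises :class:`DataError` if
        it exceeds ``rtol``.
        """
        if not self.flows_populated:
            raise DataError("flows are not populated on every segment")
        worst = 0.0
        for seg in self.segments.values():
            if seg.is_terminal:
                continue
            qsum = sum(self.segments[c].flow for c in seg.child_ids)
            scale = max(abs(seg.flow), abs(qsum), 1e-300)
            worst = max(worst, abs(seg.flow - qsum) / scale)
        if worst > rtol:
            raise DataError(
                f"flow conservation violated: max relative residual {worst:.3e} "
                f"> {rtol:.1e}"
            )
        return worst


# -- perfect binary generator -------------------------------------------


@dataclass(slots=True)
class SplitRatioConfig:
    """Configuration for a perfect binary tree with a constant flow split.

    ``split_ratio`` (r) is the smaller daughter flow divided by the larger,
    r in (0, 1]; r = 1 is an even split, r -> 0 routes all flow down one
    daughter. ``root_flow`` sets the absolute scale (probabilities, and
    hence all fractal measures, are scale-free).
    """

    max_generation: int
    split_ratio: float
    root_flow: float = 1.0

    def __post_init__(self) -> None:
        if not (isinstance(self.max_generation, int) and self.max_generation >= 1):
            raise ConfigurationError(
                f"max_generation must be an integer >= 1, got {self.max_generation}"
            )
        if not (0.0 < self.split_ratio <= 1.0):
            raise ConfigurationError(
                f"split_ratio must lie in (0, 1], got {self.split_ratio}"
            )
        if not self.root_flow > 0:
            raise ConfigurationError(f"root_flow must be > 0, got {self.root_flow}")


def make_perfect_binary_tree(config: SplitRatioConfig) -> VascularTree:
    """Build a perfect binary tree of depth G with constant flow split ratio.

    Every internal segment splits its flow into fractions ``1/(1+r)`` (first
    daughter) and ``r/(1+r)`` (second daughter). The tree has ``2**(G+1)-1``
    segments. Diameters and lengths are filled with plausible placeholder
    values (symmetric cube-law halving); the fractal and CV analyses use
    flows only.
    """
    r = config.split_ratio
    big, small = 1.0 / (1.0 + r), r / (1.0 + r)
    segments: dict[int, VesselSegment] = {}
    next_id = 0

    def placeholder_geometry(gen: int) -> tuple[float, float]:
        d = 100.0 * 2.0 ** (-gen / 3.0)
        return d, 7.4 * (d / 2.0) ** 1.15

    d0, l0 = placeholder_geometry(0)
    segments[0] = VesselSegment(0, None, 0, d0, l0, config.root_flow)
    next_id = 1
    frontier = [0]
    for gen in range(1, config.max_generation + 1):
        d, l = placeholder_geometry(gen)
        new_frontier = []
        for pid in frontier:
            parent = segments[pid]
            for frac in (big, small):
                sid = next_id
                next_id += 1
                segments[sid] = VesselSegment(
                    sid, pid, gen, d, l, parent.flow * frac
                )
                parent.child_ids.append(sid)
                new_frontier.append(sid)
        frontier = new_frontier
    return VascularTree(segments, root_id=0)


# -- carry-forward flow tables ------------------------------------------


@dataclass
class GenerationFlowTable:
    """Per-generation flow-probability vectors under the carry-forward rule.

    ``probabilities[n]`` holds the flow probabilities ``p_i = Q_i / Q_root``
    of every segment included at generation ``n``: the segments whose
    generation is exactly ``n`` plus every terminal segment of generation
    < n, each carried forward with its full flow. By flow conservation each
    vector sums to 1. The nominal cell count at generation ``n`` is
    ``2**n``, not the number of included segments.

    ``active_flow_fraction[n]`` is the share of total flow passing through
    still-bifurcating (non-terminal) segments at generation ``n``. While it
    is high the measure is still being refined by further bisections; once
    most flow rests in carried-forward terminals the cross-sections stop
    changing, entropy saturates, and deeper generations carry no scaling
    information. The fractal estimators use it to bound their fit range
    (see :func:`hemofractal.fractal.fractal_dimension`). ``None`` for
    tables assembled without topology information, in which case the full
    generation range is fitted.
    """

    probabilities: list[np.ndarray]
    counts_included: list[int]
    max_generation: int
    active_flow_fraction: np.ndarray | None = None

    def n_cells(self, n: int) -> int:
        """Nominal number of cells at generation ``n`` (always ``2**n``)."""
        return 2**n

    def scaling_generations(self, threshold: float = 0.5) -> int:
        """Last generation of the scale-invariant range (at least 2).

        The largest generation at which at least ``threshold`` of the flow
        still passes through bifurcating segments; generations beyond it
        are saturated and excluded from scaling fits. Falls back to the
        full range when no active-flow information is available.
        """
        if self.active_flow_fraction is None:
            return self.max_generation
        frac = self.active_flow_fraction
        eligible = [
            n for n in range(1, self.max_generation + 1) if frac[n] >= threshold
        ]
        return max(2, eligible[-1] if eligible else 2)


def carry_forward_table(
    tree: VascularTree, rtol: float = FLOW_CONSERVATION_RTOL
) -> GenerationFlowTable:
    """Build the carry-forward generation flow table of a tree.

    Requires every flow populated and finite with positive root flow, and
    verifies bifurcation-level flow conservation to ``rtol`` before
    normalising. Raises :class:`DegenerateInputError` on zero root flow and
    :class:`DataError` on a conservation violation.
    """
    if not tree.flows_populated:
        raise DataError("flows must be populated on every segment")
    if not all(math.isfinite(s.flow) for s in tree.segments.values()):
        raise DataError("flows must be finite")
    root_flow = tree.root.flow
    if root_flow <= 0:
        raise DegenerateInputError(f"root flow must be > 0, got {root_flow}")
    tree.check_flow_conservation(rtol)

    G = tree.max_generation
    by_gen: list[list[float]] = [[] for _ in range(G + 1)]
    terminals_by_gen: list[list[float]] = [[] for _ in range(G + 1)]
    active = np.zeros(G + 1)
    for seg in tree.segments.values():
        by_gen[seg.generation].append(seg.flow)
        if seg.is_terminal:
            terminals_by_gen[seg.generation].append(seg.flow)
        else:
            active[seg.generation] += seg.flow

    probabilities: list[np.ndarray] = []
    counts: list[int] = []
    carried: list[float] = []
    for n in range(G + 1):
        included = by_gen[n] + carried
        p = np.asarray(included, dtype=float) / root_flow
        probabilities.append(p)
        counts.append(len(included))
        carried = carried + terminals_by_gen[n]
    return GenerationFlowTable(probabilities, counts, G, active / root_flow)


# -- whole-tree statistics ----------------------------------------------


def coefficient_of_variation(tree: VascularTree) -> float:
    """Population standard deviation over mean of all segment flows.

    The root segment is included. CV treats segments as independent samples
    and is therefore sensitive to tree depth, unlike the fractal dimension.
    """
    if tree.n_segments < 2:
        raise DegenerateInputError("CV requires at least 2 segments")
    flows = tree.flows()
    if np.isnan(flows).any():
        raise DataError("flows must be populated on every segment")
    mean = flows.mean()
    if mean == 0:
        raise DegenerateInputError("mean flow is zero; CV undefined")
    return float(flows.std(ddof=0) / mean)


def perfect_tree_cv(r: float, max_generation: int) -> float:
    """Closed-form CV of a constant-split perfect binary tree.

    With flow fractions p = 1/(1+r) and q = r/(1+r), the sum of squared
    flows at generation g is (p^2+q^2)^g (root flow 1), every generation
    carries total flow 1, and there are 2^(G+1)-1 segments, giving

        CV^2 = (2^(G+1) - 1) * sum_g (p^2+q^2)^g / (G+1)^2 - 1.

    Defined for r in [0, 1]; r = 0 is the single-path limit.
    """
    if not (0.0 <= r <= 1.0):
        raise ConfigurationError(f"split ratio must lie in [0, 1], got {r}")
    if max_generation < 1:
        raise ConfigurationError("max_generation must be >= 1")
    G = max_generation
    p, q = 1.0 / (1.0 + r), r / (1.0 + r)
    s = sum((p * p + q * q) ** g for g in range(G + 1))
    cv2 = (2.0 ** (G + 1) - 1.0) * s / (G + 1) ** 2 - 1.0
    return math.sqrt(cv2)


# -- tree table I/O ------------------------------------------------------

_COLUMNS = ["id", "parent_id", "generation", "diameter_um", "length_um", "flow"]


def write_tree_table(tree: VascularTree, path) -> None:
    """Write a tree as a CSV edge list.

    Dialect: header ``id,parent_id,generation,diameter_um,length_um,flow``;
    0-based integer ids; the root row has ``parent_id`` -1; unset flows are
    written as empty cells.
    """
    rows = []
    for sid in sorted(tree.segments):
        s = tree.segments[sid]
        rows.append(
            {
                "id": s.id,
                "parent_id": -1 if s.parent_id is None else s.parent_id,
                "generation": s.generation,
                "diameter_um": s.diameter,
                "length_um": s.length,
                "flow": s.flow if s.has_flow else np.nan,
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_tree_table(path) -> VascularTree:
    """Read a tree from the CSV edge-list dialect of :func:`write_tree_table`.

    The ``generation`` column is optional; generations are recomputed from
    the topology and cross-validated against the column when present.
    Violations (missing parents, non-binary branching, negative diameters or
    flows, generation mismatches) raise :class:`TreeFormatError` naming the
    offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns and c != "generation"]
    if missing:
        raise TreeFormatError(f"missing required columns: {missing}")

    segments: dict[int, VesselSegment] = {}
    root_id: int | None = None
    for idx, row in df.iterrows():
        try:
            sid = int(row["id"])
            pid = int(row["parent_id"])
        except (ValueError, TypeError) as exc:
            raise TreeFormatError(f"row {idx}: non-integer id/parent_id") from exc
        if sid in segments:
            raise TreeFormatError(f"row {idx}: duplicate id {sid}")
        d = float(row["diameter_um"])
        l = float(row["length_um"])
        if not d > 0:
            raise TreeFormatError(f"row {idx}: non-positive diameter {d}")
        if not l > 0:
            raise TreeFormatError(f"row {idx}: non-positive length {l}")
        flow = float(row["flow"]) if "flow" in df.columns else math.nan
        if not math.isnan(flow) and flow < 0:
            raise TreeFormatError(f"row {idx}: negative flow {flow}")
        if pid == -1:
            if root_id is not None:
                raise TreeFormatError(f"row {idx}: second root (parent_id -1)")
            root_id = sid
            parent: int | None = None
        else:
            parent = pid
        segments[sid] = VesselSegment(sid, parent, 0, d, l, flow)
    if root_id is None:
        raise TreeFormatError("no root row (parent_id -1) found")

    for sid, seg in segments.items():
        if seg.parent_id is not None:
            if seg.parent_id not in segments:
                raise TreeFormatError(
                    f"segment {sid} references missing parent {seg.parent_id}"
                )
            segments[seg.parent_id].child_ids.append(sid)
    for sid, seg in segments.items():
        if len(seg.child_ids) not in (0, 2):
            raise TreeFormatError(
                f"segment {sid} has {len(seg.child_ids)} children; must be 0 or 2"
            )
        seg.child_ids.sort()

    # recompute generations breadth-first from the root
    queue: deque[int] = deque([root_id])
    reached: set[int] = set()
    while queue:
        sid = queue.popleft()
        reached.add(sid)
        seg = segments[sid]
        for cid in seg.child_ids:
            segments[cid].generation = seg.generation + 1
            queue.append(cid)
    if reached != set(segments):
        orphans = sorted(set(segments) - reached)
        raise TreeFormatError(f"rows not reachable from root: {orphans[:10]}")

    if "generation" in df.columns and not df["generation"].isna().all():
        for idx, row in df.iterrows():
            stated = row["generation"]
            if pd.isna(stated):
                continue
            sid = int(row["id"])
            if int(stated) != segments[sid].generation:
                raise TreeFormatError(
                    f"row {idx}: stated generation {int(stated)} != "
                    f"recomputed {segments[sid].generation}"
                )
    return VascularTree(segments, root_id=root_id)
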