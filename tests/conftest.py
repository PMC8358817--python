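"""Shared fixtures: small hand-built trees and random pruned-tree generators."""

from __future__ import annotations

import numpy as np
import pytest

from hemofractal.tree import VascularTree, VesselSegment


def build_tree(rows):
    """Build a tree from (id, parent, gen, diameter, length, flow) tuples."""
    segments = {}
    root_id = None
    for sid, pid, gen, d, l, q in rows:
        segments[sid] = VesselSegment(sid, pid, gen, d, l, q)
        if pid is None:
            root_id = sid
    for sid, seg in segments.items():
        if seg.parent_id is not None:
            segments[seg.parent_id].child_ids.append(sid)
    return VascularTree(segments, root_id=root_id)


@pytest.fixture
def irregular_tree():
    """Depth-3 tree with early terminals (one branch stops at each level).

    Root splits 0.75/0.25; the 0.25 branch is terminal at generation 1; of
    the 0.75, 0.25 terminates at generation 2 and 0.5 splits once more into
    0.3/0.2 at generation 3.
    """
    return build_tree(
        [
            (0, None, 0, 40.0, 100.0, 1.0),
            (1, 0, 1, 30.0, 80.0, 0.75),
            (2, 0, 1, 20.0, 60.0, 0.25),
            (3, 1, 2, 22.0, 50.0, 0.25),
            (4, 1, 2, 25.0, 55.0, 0.50),
            (5, 4, 3, 18.0, 40.0, 0.30),
            (6, 4, 3, 15.0, 35.0, 0.20),
        ]
    )


def random_pruned_tree(rng: np.random.Generator, max_depth: int = 6):
    """Random binary tree with conserved positive flows and early terminals."""
    segments = {0: VesselSegment(0, None, 0, 50.0, 120.0, 1.0)}
    next_id = [1]

    def grow(sid: int) -> None:
        seg = segments[sid]
        if seg.generation >= max_depth:
            return
        # root always bifurcates so max_generation >= 2 is guaranteed below
        if seg.generation > 0 and rng.random() < 0.3:
            return
        frac = rng.uniform(0.2, 0.8)
        for share in (frac, 1.0 - frac):
            cid = next_id[0]
            next_id[0] += 1
            segments[cid] = VesselSegment(
                cid,
                sid,
                seg.generation + 1,
                seg.diameter * 0.8,
                seg.length * 0.9,
                seg.flow * share,
            )
            seg.child_ids.append(cid)
        for cid in seg.child_ids:
            grow(cid)

    grow(0)
    if segments[1].is_terminal and segments[2].is_terminal:
        # force depth >= 2 for estimator preconditions
        for cid in (1, 2):
            grow_seed = segments[cid]
            for share in (0.5, 0.5):
                nid = next_id[0]
                next_id[0] += 1
                segments[nid] = VesselSegment(
                    nid, cid, 2, grow_seed.diameter * 0.8,
                    grow_seed.length * 0.9, grow_seed.flow * share,
                )
                grow_seed.child_ids.append(nid)
    return VascularTree(segments, root_id=0)
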