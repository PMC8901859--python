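"""Dendritic morphometrics from SWC reconstructions.

Metrics follow the conventions of tree-tracing software for traced
pyramidal/stellate neurons: primary dendrites are the dendritic stems
leaving the soma, nodes are branch points (≥2 dendritic children), ends
are terminal tips, and branch order is centrifugal — the primary segment
has order 1 and the order increases by one at every branch point.  The
dendritic-complexity score combines topology and size:

    DC = (Σ terminal orders + number of terminals)
         × (total dendritic length / number of primary dendrites)

so a neuron with more, deeper branching and longer arbors scores higher.
Only dendrite-typed SWC nodes (types 3 and 4, basal and apical) enter
the metrics; the axon is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SOMA_TYPE = 1
DENDRITE_TYPES = (3, 4)

METRIC_COLUMNS = (
    "n_primary",
    "n_nodes",
    "n_ends",
    "total_length",
    "mean_length",
    "dc",
)


@dataclass
class MorphologyTree:
    """A reconstructed neuron as parallel SWC column arrays.

    ``parent`` holds SWC ids (−1 for the root); node order is arbitrary
    but ids are unique and every non-root parent id exists.
    """

    ids: np.ndarray
    types: np.ndarray
    xyz: np.ndarray
    radius: np.ndarray
    parent: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.types = np.asarray(self.types, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.radius = np.asarray(self.radius, dtype=float)
        self.parent = np.asarray(self.parent, dtype=int)
        self._validate()

    def _validate(self) -> None:
        if len(set(self.ids.tolist())) != len(self.ids):
            raise ValueError("duplicate SWC ids")
        idset = set(self.ids.tolist())
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        for pid in self.parent:
            if pid != -1 and pid not in idset:
                raise ValueError(f"orphan parent id {pid}")
        # cycle check: walk each node to the root
        index = self.index
        for start in self.ids:
            seen = set()
            node = int(start)
            while node != -1:
                if node in seen:
                    raise ValueError(f"cycle detected at id {node}")
                seen.add(node)
                node = int(self.parent[index[node]])

    @property
    def index(self) -> dict[int, int]:
        """Map SWC id → row position."""
        return {int(i): k for k, i in enumerate(self.ids)}

    @property
    def root_id(self) -> int:
        return int(self.ids[np.flatnonzero(self.parent == -1)[0]])

    @property
    def n_nodes_total(self) -> int:
        return len(self.ids)

    def children(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {int(i): [] for i in self.ids}
        for i, p in zip(self.ids, self.parent):
            if p != -1:
                out[int(p)].append(int(i))
        return out

    def edge_length(self, child_id: int) -> float:
        idx = self.index
        pid = int(self.parent[idx[child_id]])
        return float(
            np.linalg.norm(self.xyz[idx[child_id]] - self.xyz[idx[pid]])
        )


@dataclass
class MorphoMetrics:
    """Branch counts, lengths and the dendritic-complexity score."""

    n_primary: int
    n_nodes: int
    n_ends: int
    total_length: float
    mean_length: float
    terminal_orders: np.ndarray = field(default_factory=lambda: np.array([]))
    mean_segment_length: float = float("nan")
    dc: float = float("nan")

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "n_primary": self.n_primary,
                "n_nodes": self.n_nodes,
                "n_ends": self.n_ends,
                "total_length": self.total_length,
                "mean_length": self.mean_length,
                "dc": self.dc,
            }
        )


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path) -> MorphologyTree:
    """Parse an SWC file, validating ids, parents and acyclicity.

    Lines may appear in any order (forward references allowed); parse
    errors carry the offending line number.
    """
    ids, types, xyz, radius, parent = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 fields, got {len(parts)}")
            try:
                ids.append(int(parts[0]))
                types.append(int(parts[1]))
                xyz.append([float(parts[2]), float(parts[3]), float(parts[4])])
                radius.append(float(parts[5]))
                parent.append(int(parts[6]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    if not ids:
        raise ValueError(f"{path}: empty SWC file")
    return MorphologyTree(
        ids=np.array(ids),
        types=np.array(types),
        xyz=np.array(xyz),
        radius=np.array(radius),
        parent=np.array(parent),
    )


def write_swc(tree: MorphologyTree, path) -> None:
    """Write SWC with fixed 4-decimal formatting (byte-stable)."""
    with open(path, "w") as fh:
        for i in range(tree.n_nodes_total):
            x, y, z = tree.xyz[i]
            fh.write(
                f"{tree.ids[i]} {tree.types[i]} {x:.4f} {y:.4f} {z:.4f} "
                f"{tree.radius[i]:.4f} {tree.parent[i]}\n"
            )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def branch_metrics(
    tree: MorphologyTree,
    dendrite_types: tuple[int, ...] = DENDRITE_TYPES,
    mean_length_per: str = "primary",
) -> MorphoMetrics:
    """Count primaries, branch points and terminals; sum dendritic length.

    Branch order is centrifugal: a stem leaving the soma starts at order
    1 and the order increments at every branch point (a node with ≥2
    dendritic children).  ``mean_length_per`` selects the denominator of
    the mean dendrite length: ``"primary"`` (total length / number of
    primary dendrites, the default) or ``"segment"`` (per inter-branch
    segment).
    """
    idx = tree.index
    children = tree.children()
    is_dend = {int(i): int(t) in dendrite_types for i, t in zip(tree.ids, tree.types)}
    root = tree.root_id

    def dend_children(nid: int) -> list[int]:
        return [c for c in children[nid] if is_dend[c]]

    primaries = dend_children(root)
    # soma may be represented by several soma-typed nodes; stems can hang
    # off any of them
    for i, t in zip(tree.ids, tree.types):
        nid = int(i)
        if nid != root and int(t) == SOMA_TYPE:
            primaries.extend(dend_children(nid))
    if not primaries:
        raise ValueError("tree contains no dendrites")

    total_length = 0.0
    n_branch = 0
    terminal_orders: list[int] = []
    n_segments = 0
    # BFS over dendritic nodes carrying the centrifugal order
    stack: list[tuple[int, int]] = [(p, 1) for p in primaries]
    seg_starts = set(primaries)
    while stack:
        nid, order = stack.pop()
        total_length += tree.edge_length(nid)
        kids = dend_children(nid)
        if len(kids) == 0:
            terminal_orders.append(order)
        elif len(kids) == 1:
            stack.append((kids[0], order))
        else:
            n_branch += 1
            for c in kids:
                stack.append((c, order + 1))
                seg_starts.add(c)
    n_segments = len(seg_starts)

    n_primary = len(primaries)
    n_ends = len(terminal_orders)
    if mean_length_per == "primary":
        mean_length = total_length / n_primary
    elif mean_length_per == "segment":
        mean_length = total_length / n_segments
    else:
        raise ValueError(f"unknown mean_length_per {mean_length_per!r}")
    return MorphoMetrics(
        n_primary=n_primary,
        n_nodes=n_branch,
        n_ends=n_ends,
        total_length=total_length,
        mean_length=mean_length,
        terminal_orders=np.sort(np.asarray(terminal_orders)),
        mean_segment_length=total_length / n_segments,
    )


def dendritic_complexity(metrics: MorphoMetrics) -> float:
    """DC = (Σ terminal orders + #terminals) × (total length / #primaries)."""
    if metrics.n_primary < 1:
        raise ValueError("DC requires at least one primary dendrite")
    dc = (float(np.sum(metrics.terminal_orders)) + metrics.n_ends) * (
        metrics.total_length / metrics.n_primary
    )
    metrics.dc = dc
    return dc


def analyze_tree(tree: MorphologyTree, **kwargs) -> MorphoMetrics:
    """Branch metrics plus DC in one call."""
    m = branch_metrics(tree, **kwargs)
    dendritic_complexity(m)
    return m


def metrics_table(trees, **kwargs) -> pd.DataFrame:
    """Metrics for a collection of trees as one row per neuron."""
    rows = [analyze_tree(t, **kwargs).as_series() for t in trees]
    return pd.DataFrame(rows).reset_index(drop=True)


def normalize_to_reference(
    metrics: pd.DataFrame,
    reference_mean: pd.Series | None = None,
    groups: pd.Series | np.ndarray | None = None,
    reference_group=None,
) -> pd.DataFrame:
    """Express each metric relative to a reference-group mean.

    Either pass ``reference_mean`` directly, or ``groups`` +
    ``reference_group`` to compute it from the rows of ``metrics``
    belonging to the reference group (which then normalizes to 1.00 on
    average).
    """
    if reference_mean is None:
        if groups is None or reference_group is None:
            raise ValueError("need reference_mean, or groups and reference_group")
        mask = np.asarray(groups) == reference_group
        if not mask.any():
            raise ValueError(f"reference group {reference_group!r} is empty")
        reference_mean = metrics.loc[mask].mean()
    reference_mean = reference_mean[metrics.columns]
    if (reference_mean <= 0).any():
        bad = list(reference_mean.index[reference_mean <= 0])
        raise ValueError(f"non-positive reference mean for {bad}")
    return metrics / reference_mean
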