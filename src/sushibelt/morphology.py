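"""Neuron morphologies as compartment trees.

Reads and writes SWC, splits branches into compartments of bounded length,
and maps experimental imaging windows ("subregions") onto compartments by
their distance from the soma.  Compartments are indexed 0..N-1 with the soma
as the single root (index 0); SWC sample ids are kept as metadata only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CompartmentTree",
    "load_swc",
    "write_swc",
    "discretize",
    "map_subregions",
    "read_subregion_table",
    "write_subregion_table",
]

SOMA_LABEL = "soma"

#: SWC structure identifiers (standard 7-column dialect).
SWC_SOMA = 1
SWC_AXON = 2

TABLE_COLUMNS = ["name", "axial_distance", "day0", "day7", "day7_sd"]


class MorphologyError(ValueError):
    """Structural or parse error in a morphology file."""


@dataclass
class CompartmentTree:
    """Soma-rooted tree of cylindrical compartments.

    Attributes
    ----------
    parent : (N,) int array; ``-1`` marks the root (soma).
    length : (N,) float array, compartment length in µm (all > 0).
    tip : (N, 3) float array, distal end of each compartment in µm.  For the
        root this is the soma position.
    subregion : list of window labels (or ``None`` before mapping); the root
        carries the fixed label ``"soma"``.
    swc_id : (N,) int array of original SWC sample ids (-1 when synthetic).
    """

    parent: np.ndarray
    length: np.ndarray
    tip: np.ndarray
    subregion: list = field(default_factory=list)
    swc_id: np.ndarray | None = None

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=int)
        self.length = np.asarray(self.length, dtype=float)
        self.tip = np.asarray(self.tip, dtype=float)
        n = self.parent.size
        if not self.subregion:
            self.subregion = [SOMA_LABEL] + [None] * (n - 1)
        if self.swc_id is None:
            self.swc_id = np.full(n, -1, dtype=int)
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n(self) -> int:
        return self.parent.size

    def validate(self) -> None:
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1 or roots[0] != 0:
            raise MorphologyError(
                f"expected exactly one root at index 0, found {roots.tolist()}"
            )
        if np.any(self.parent[1:] >= np.arange(1, self.n)):
            raise MorphologyError("parents must precede children (topological order)")
        if np.any(self.length <= 0):
            raise MorphologyError("all compartment lengths must be > 0")

    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n)]
        for i in range(1, self.n):
            out[self.parent[i]].append(i)
        return out

    def edges(self) -> np.ndarray:
        """(N-1, 2) array of (parent, child) index pairs."""
        idx = np.arange(1, self.n)
        return np.column_stack([self.parent[idx], idx])

    @property
    def total_length(self) -> float:
        """Total cable length: sum of non-root compartment lengths, µm."""
        return float(self.length[1:].sum())

    # -- geometry ----------------------------------------------------------

    def midpoint(self) -> np.ndarray:
        """(N, 3) compartment midpoints; the root midpoint is the soma tip."""
        mid = self.tip.copy()
        mid[1:] = 0.5 * (self.tip[self.parent[1:]] + self.tip[1:])
        return mid

    def axial_distance(self, axis=(0.0, 0.0, 1.0)) -> np.ndarray:
        """Signed distance of each midpoint from the soma along ``axis``."""
        u = np.asarray(axis, dtype=float)
        u = u / np.linalg.norm(u)
        return (self.midpoint() - self.tip[0]) @ u

    def path_distance(self) -> np.ndarray:
        """Path length from the soma to each compartment midpoint, µm."""
        d = np.zeros(self.n)
        to_tip = np.zeros(self.n)  # root tip -> compartment tip
        for i in range(1, self.n):
            to_tip[i] = to_tip[self.parent[i]] + self.length[i]
            d[i] = to_tip[i] - 0.5 * self.length[i]
        return d

    def copy(self) -> "CompartmentTree":
        return CompartmentTree(
            self.parent.copy(),
            self.length.copy(),
            self.tip.copy(),
            list(self.subregion),
            self.swc_id.copy(),
        )


# ---------------------------------------------------------------------------
# SWC I/O

def load_swc(path) -> CompartmentTree:
    """Read a standard 7-column SWC file into a :class:`CompartmentTree`.

    All soma samples are collapsed into a single root compartment positioned
    at the first soma sample; axon subtrees are dropped (the model concerns
    dendritic cargo only).  Each remaining sample becomes one compartment
    whose length is the Euclidean distance to its parent sample.
    """
    ids, types, xyz, radius, parents = [], [], [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise MorphologyError(f"{path}:{ln}: expected 7 fields, got {len(parts)}")
            try:
                ids.append(int(parts[0]))
                types.append(int(parts[1]))
                xyz.append([float(parts[2]), float(parts[3]), float(parts[4])])
                radius.append(float(parts[5]))
                parents.append(int(parts[6]))
            except ValueError as exc:
                raise MorphologyError(f"{path}:{ln}: non-numeric field ({exc})") from None
    if not ids:
        raise MorphologyError(f"{path}: no samples")

    id_set = set(ids)
    for sid, pid in zip(ids, parents):
        if pid != -1 and pid not in id_set:
            raise MorphologyError(f"sample {sid} references unknown parent {pid}")

    soma_ids = {sid for sid, t in zip(ids, types) if t == SWC_SOMA}
    root_ids = [sid for sid, pid in zip(ids, parents) if pid == -1]
    if len(root_ids) != 1:
        raise MorphologyError(f"expected one root sample, found {len(root_ids)}")
    if not soma_ids:
        soma_ids = set(root_ids)  # single-point root of non-soma type
    if root_ids[0] not in soma_ids:
        raise MorphologyError("root sample is not a soma sample")

    by_id = {sid: k for k, sid in enumerate(ids)}
    # Drop axon subtrees: a sample is kept if neither it nor any ancestor is axon.
    drop = set()
    for sid, t in zip(ids, types):
        if t == SWC_AXON:
            drop.add(sid)
    changed = True
    while changed:
        changed = False
        for sid, pid in zip(ids, parents):
            if sid not in drop and pid in drop:
                drop.add(sid)
                changed = True

    root_xyz = np.array(xyz[by_id[root_ids[0]]])
    root_radius = radius[by_id[root_ids[0]]]

    order: list[int] = []          # kept sample ids, parents before children
    remaining = {
        sid for sid in ids if sid not in drop and sid not in soma_ids
    }
    placed = set(soma_ids)
    while remaining:
        progressed = False
        for sid in sorted(remaining):
            if parents[by_id[sid]] in placed:
                order.append(sid)
                placed.add(sid)
                remaining.discard(sid)
                progressed = True
        if not progressed:
            raise MorphologyError("cycle or disconnected component in SWC graph")

    n = len(order) + 1
    parent = np.full(n, -1, dtype=int)
    tip = np.zeros((n, 3))
    length = np.zeros(n)
    swc_id = np.full(n, -1, dtype=int)
    tip[0] = root_xyz
    length[0] = max(2.0 * root_radius, 1e-3)  # nominal soma extent, µm
    swc_id[0] = root_ids[0]

    index_of = {sid: 0 for sid in soma_ids}
    for k, sid in enumerate(order, start=1):
        i = by_id[sid]
        pid = parents[i]
        parent[k] = index_of[pid]
        tip[k] = xyz[i]
        length[k] = float(np.linalg.norm(tip[k] - tip[parent[k]]))
        if length[k] <= 0:
            # coincident samples: keep a degenerate-but-positive stub
            length[k] = 1e-6
        swc_id[k] = sid
        index_of[sid] = k

    return CompartmentTree(parent, length, tip, swc_id=swc_id)


def write_swc(tree: CompartmentTree, path) -> None:
    """Write the tree in the package's SWC dialect (round-trips bit-wise).

    The root is emitted as a type-1 sample whose radius encodes half the
    nominal soma length; every other compartment becomes a type-3 (dendrite)
    sample at the compartment tip.
    """
    with open(path, "w") as fh:
        fh.write("# generated by sushibelt\n")
        x, y, z = (float(v) for v in tree.tip[0])
        fh.write(f"1 {SWC_SOMA} {x!r} {y!r} {z!r} "
                 f"{float(tree.length[0]) / 2.0!r} -1\n")
        for i in range(1, tree.n):
            x, y, z = (float(v) for v in tree.tip[i])
            fh.write(f"{i + 1} 3 {x!r} {y!r} {z!r} 0.5 {tree.parent[i] + 1}\n")


# ---------------------------------------------------------------------------
# Discretization

def _branch_chains(tree: CompartmentTree) -> list[list[int]]:
    """Maximal unbranched chains of non-root compartments.

    A chain starts at a child of the root or of a branch point and runs to
    the next leaf or branch point.
    """
    kids = tree.children()
    chains = []
    starts = list(kids[0])
    for i in range(1, tree.n):
        if len(kids[i]) > 1:
            starts.extend(kids[i])
    for s in starts:
        chain = [s]
        while len(kids[chain[-1]]) == 1:
            chain.append(kids[chain[-1]][0])
        chains.append(chain)
    return chains


def discretize(tree: CompartmentTree, max_len: float) -> CompartmentTree:
    """Re-split every topological branch into equal pieces of length ≤ max_len.

    Each branch of length L becomes ⌈L/max_len⌉ compartments of length
    L/⌈L/max_len⌉, so total cable length is conserved exactly.  Compartment
    tips are interpolated along the branch's polyline; the soma root is left
    untouched.  Subregion labels are discarded (re-map afterwards).
    """
    if max_len <= 0:
        raise ValueError("max_len must be > 0")
    chains = _branch_chains(tree)
    parent = [-1]
    length = [tree.length[0]]
    tip = [tree.tip[0]]

    new_index_of_old_end = {0: 0}
    # process chains in an order where the chain's attachment is already built
    pending = list(chains)
    while pending:
        progressed = False
        for chain in list(pending):
            attach_old = tree.parent[chain[0]]
            if attach_old not in new_index_of_old_end:
                continue
            pending.remove(chain)
            progressed = True
            pts = [tree.tip[attach_old]] + [tree.tip[i] for i in chain]
            seg = np.array([tree.length[i] for i in chain])
            L = float(seg.sum())
            k = max(1, math.ceil(L / max_len - 1e-12))
            piece = L / k
            cum = np.concatenate([[0.0], np.cumsum(seg)])
            prev_new = new_index_of_old_end[attach_old]
            for j in range(1, k + 1):
                s = j * piece if j < k else L  # land exactly on the branch end
                seg_i = int(np.searchsorted(cum, s, side="left"))
                seg_i = min(max(seg_i, 1), len(chain))
                f = (s - cum[seg_i - 1]) / seg[seg_i - 1]
                p = (1 - f) * np.asarray(pts[seg_i - 1]) + f * np.asarray(pts[seg_i])
                parent.append(prev_new)
                length.append(piece)
                tip.append(p)
                prev_new = len(parent) - 1
            new_index_of_old_end[chain[-1]] = prev_new
        if not progressed:  # pragma: no cover - tree invariant guarantees progress
            raise MorphologyError("disconnected branch during discretization")

    return CompartmentTree(np.array(parent), np.array(length), np.array(tip))


# ---------------------------------------------------------------------------
# Subregion tables and window mapping

def read_subregion_table(path) -> pd.DataFrame:
    """Read a subregion window table (CSV: name,axial_distance,day0,day7,day7_sd)."""
    df = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subregion table missing columns {missing}")
    validate_table(df)
    return df


def write_subregion_table(df: pd.DataFrame, path) -> None:
    cols = TABLE_COLUMNS + [c for c in df.columns if c not in TABLE_COLUMNS]
    df.to_csv(path, index=False, columns=cols)


def validate_table(df: pd.DataFrame) -> None:
    if len(df) == 0:
        raise ValueError("empty subregion table")
    if df["name"].duplicated().any():
        raise ValueError("subregion names must be unique")
    if (df[["day0", "day7", "day7_sd"]] < 0).any().any():
        raise ValueError("abundances and SDs must be >= 0")
    if df["day0"].sum() <= 0:
        raise ValueError("sum of Day-0 values must be > 0")


def map_subregions(
    tree: CompartmentTree,
    table: pd.DataFrame,
    mode: str = "axis",
    axis=(0.0, 0.0, 1.0),
) -> CompartmentTree:
    """Label each compartment with the window nearest its distance from soma.

    mode="axis" uses signed distance along ``axis`` (apical positive, basal
    negative — the CA1 layer convention); mode="path" uses path distance
    along the dendrite (the DG convention).  Ties between two equally near
    windows go to the more distal one (larger |distance|).  The member count
    of each window is written back into the table as ``n_compartments``.

    Compartments beyond the outermost window distance are clamped to the
    nearest terminal window.
    """
    validate_table(table)
    if mode == "axis":
        dist = tree.axial_distance(axis)
    elif mode == "path":
        dist = tree.path_distance()
    else:
        raise ValueError(f"unknown mode {mode!r}")

    w = table["axial_distance"].to_numpy(dtype=float)
    names = table["name"].tolist()
    out = tree.copy()
    counts = np.zeros(len(table), dtype=int)
    for i in range(1, tree.n):
        diff = np.abs(w - dist[i])
        best = diff.min()
        cand = np.flatnonzero(diff <= best + 1e-12)
        j = cand[np.argmax(np.abs(w[cand]))]  # tie-break: more distal window
        out.subregion[i] = names[j]
        counts[j] += 1
    out.subregion[0] = SOMA_LABEL
    table["n_compartments"] = counts
    return out


def subregion_index(tree: CompartmentTree, table: pd.DataFrame) -> np.ndarray:
    """(N,) array mapping compartment -> row index in ``table`` (-1 = soma)."""
    row = {name: k for k, name in enumerate(table["name"])}
    idx = np.empty(tree.n, dtype=int)
    for i in range(tree.n):
        lbl = tree.subregion[i]
        if lbl is None:
            raise ValueError(f"compartment {i} is unlabelled; run map_subregions")
        idx[i] = row.get(lbl, -1)
    return idx
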