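"""Structure I/O and carbon-skeleton perception.

Reads and writes XYZ files, perceives covalent bonds by distance windows,
builds a smallest-ring basis of the carbon skeleton, aligns structures to
their best-fit plane, and counts highly connected rings.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import networkx as nx
import numpy as np

__all__ = [
    "Structure",
    "MolecularGraph",
    "RingSet",
    "XYZParseError",
    "GeometryError",
    "PlaneDegeneracyError",
    "DisconnectedSkeletonError",
    "UnsupportedElementError",
    "read_xyz",
    "write_xyz",
    "perceive_bonds",
    "perceive_rings",
    "align_to_plane",
    "count_highly_connected_rings",
]

# All IUPAC element symbols (Z = 1..118).
ELEMENT_SYMBOLS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No
    Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)

DEFAULT_CC_CUTOFF = 1.75  # Å, upper bound for a C-C bond
DEFAULT_CH_CUTOFF = 1.30  # Å, upper bound for a C-H bond
_CC_LOWER = 0.9  # Å, below this two carbons are a clash, not a bond
_CH_LOWER = 0.7


class XYZParseError(ValueError):
    """Malformed XYZ content; message carries the offending line number."""


class GeometryError(ValueError):
    """A structure fails a geometric sanity check."""


class PlaneDegeneracyError(GeometryError):
    """Selected atoms are collinear; no unique best-fit plane exists."""


class DisconnectedSkeletonError(GeometryError):
    """Carbon skeleton has more than one connected component."""


class UnsupportedElementError(GeometryError):
    """Structure contains elements other than C and H."""


@dataclass(frozen=True)
class Structure:
    """One molecule: element symbols plus Cartesian coordinates in Å."""

    symbols: tuple
    coords: np.ndarray
    comment: str = ""

    def __post_init__(self):
        symbols = tuple(self.symbols)
        object.__setattr__(self, "symbols", symbols)
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(symbols), 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match {len(symbols)} atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        for s in symbols:
            if s not in ELEMENT_SYMBOLS:
                raise ValueError(f"unknown element symbol {s!r}")
        coords = coords.copy()
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def carbon_indices(self) -> tuple:
        return tuple(i for i, s in enumerate(self.symbols) if s == "C")

    def transformed(self, rotation: np.ndarray = None, translation=None) -> "Structure":
        """Return a rigidly moved copy (rotation applied before translation)."""
        xyz = np.asarray(self.coords)
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, dtype=float)
        return Structure(self.symbols, xyz, self.comment)


@dataclass(frozen=True)
class MolecularGraph:
    """Covalent connectivity over atoms with the carbon skeleton marked out."""

    n_atoms: int
    bonds: frozenset  # of (i, j) tuples, i < j
    bond_lengths: dict  # (i, j) -> Å
    carbon_indices: tuple

    def __post_init__(self):
        for i, j in self.bonds:
            if i == j:
                raise ValueError("self-bond")
            if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
                raise ValueError(f"bond ({i},{j}) out of range")

    def neighbors(self, i: int) -> tuple:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return tuple(sorted(out))

    def carbon_graph(self) -> nx.Graph:
        """The C-C bond subgraph as a networkx Graph."""
        carbons = set(self.carbon_indices)
        g = nx.Graph()
        g.add_nodes_from(sorted(carbons))
        for i, j in self.bonds:
            if i in carbons and j in carbons:
                g.add_edge(i, j)
        return g

    @property
    def cc_bonds(self) -> frozenset:
        carbons = set(self.carbon_indices)
        return frozenset(b for b in self.bonds if b[0] in carbons and b[1] in carbons)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_atoms": self.n_atoms,
                "bonds": sorted(list(b) for b in self.bonds),
                "bond_lengths": {f"{i}-{j}": L for (i, j), L in sorted(self.bond_lengths.items())},
                "carbon_indices": list(self.carbon_indices),
            }
        )


@dataclass(frozen=True)
class RingSet:
    """Smallest-ring basis plus fused/perimeter bond classification."""

    rings: tuple  # of tuples of atom indices, each in cyclic order
    fused_bonds: frozenset  # bonds shared by >= 2 rings
    perimeter_bonds: frozenset  # bonds in exactly 1 ring
    ring_adjacency: dict  # ring index -> frozenset of fused-neighbor ring indices

    @property
    def n_rings(self) -> int:
        return len(self.rings)

    def ring_bonds(self, k: int) -> tuple:
        ring = self.rings[k]
        n = len(ring)
        return tuple(
            tuple(sorted((ring[i], ring[(i + 1) % n]))) for i in range(n)
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "rings": [list(r) for r in self.rings],
                "fused_bonds": sorted(list(b) for b in self.fused_bonds),
                "perimeter_bonds": sorted(list(b) for b in self.perimeter_bonds),
                "ring_adjacency": {str(k): sorted(v) for k, v in self.ring_adjacency.items()},
            }
        )


# ---------------------------------------------------------------------------
# XYZ I/O
# ---------------------------------------------------------------------------

def _open_maybe(source, mode):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode), True


def read_xyz(source) -> list:
    """Parse an XYZ file (single- or multi-frame) into Structures.

    Parameters
    ----------
    source : path-like or text stream
        Standard XYZ dialect: atom-count line, comment line, then one
        ``symbol x y z`` row per atom; frames may be concatenated.
    """
    stream, should_close = _open_maybe(source, "r")
    try:
        lines = stream.read().splitlines()
    finally:
        if should_close:
            stream.close()

    structures = []
    ln = 0
    n_lines = len(lines)
    while ln < n_lines:
        # tolerate blank lines between frames
        if lines[ln].strip() == "":
            ln += 1
            continue
        count_line = ln + 1  # 1-based for messages
        try:
            natoms = int(lines[ln].strip())
        except ValueError:
            raise XYZParseError(
                f"line {count_line}: expected an atom count, got {lines[ln]!r}"
            ) from None
        if natoms < 0:
            raise XYZParseError(f"line {count_line}: negative atom count")
        if ln + 1 >= n_lines:
            raise XYZParseError(f"line {count_line + 1}: missing comment line")
        comment = lines[ln + 1]
        body_start = ln + 2
        if body_start + natoms > n_lines:
            raise XYZParseError(
                f"line {body_start + 1}: frame truncated, expected {natoms} atom rows"
            )
        symbols = []
        coords = np.empty((natoms, 3))
        for k in range(natoms):
            row = lines[body_start + k]
            parts = row.split()
            if len(parts) < 4:
                raise XYZParseError(
                    f"line {body_start + k + 1}: expected 'symbol x y z', got {row!r}"
                )
            sym = parts[0]
            if sym not in ELEMENT_SYMBOLS:
                raise XYZParseError(
                    f"line {body_start + k + 1}: unknown element symbol {sym!r}"
                )
            try:
                coords[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise XYZParseError(
                    f"line {body_start + k + 1}: non-numeric coordinate in {row!r}"
                ) from None
            symbols.append(sym)
        structures.append(Structure(tuple(symbols), coords, comment))
        ln = body_start + natoms
    return structures


def write_xyz(structures: Iterable[Structure], target) -> None:
    """Write Structures as concatenated XYZ frames (coordinates to 6 dp)."""
    stream, should_close = _open_maybe(target, "w")
    try:
        for s in structures:
            stream.write(f"{s.n_atoms}\n{s.comment}\n")
            for sym, (x, y, z) in zip(s.symbols, s.coords):
                stream.write(f"{sym} {x:.6f} {y:.6f} {z:.6f}\n")
    finally:
        if should_close:
            stream.close()


# ---------------------------------------------------------------------------
# Bond perception
# ---------------------------------------------------------------------------

def perceive_bonds(
    structure: Structure,
    cc_cutoff: float = DEFAULT_CC_CUTOFF,
    ch_cutoff: float = DEFAULT_CH_CUTOFF,
) -> MolecularGraph:
    """Perceive covalent bonds by element-pair distance windows.

    C-C pairs with distance in (0.9, cc_cutoff] Å and C-H pairs in
    (0.7, ch_cutoff] Å are bonded; H-H pairs never are. Only C and H are
    accepted.
    """
    if cc_cutoff <= 0 or ch_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    bad = sorted({s for s in structure.symbols if s not in ("C", "H")})
    if bad:
        raise UnsupportedElementError(
            f"only C/H structures are supported, found: {', '.join(bad)}"
        )
    xyz = np.asarray(structure.coords)
    n = structure.n_atoms
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    is_c = np.array([s == "C" for s in structure.symbols])

    bonds = set()
    lengths = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = dist[i, j]
            if is_c[i] and is_c[j]:
                lo, hi = _CC_LOWER, cc_cutoff
            elif is_c[i] or is_c[j]:
                lo, hi = _CH_LOWER, ch_cutoff
            else:
                continue  # no H-H bonds
            if lo < d <= hi:
                bonds.add((i, j))
                lengths[(i, j)] = float(d)

    degree = np.zeros(n, dtype=int)
    for i, j in bonds:
        degree[i] += 1
        degree[j] += 1
    for i in range(n):
        if is_c[i] and not (1 <= degree[i] <= 4):
            raise GeometryError(
                f"atom {i} (C) has {degree[i]} bonds; expected 1-4 — "
                "check coordinates or cutoffs"
            )
    return MolecularGraph(
        n_atoms=n,
        bonds=frozenset(bonds),
        bond_lengths=lengths,
        carbon_indices=tuple(np.nonzero(is_c)[0].tolist()),
    )


# ---------------------------------------------------------------------------
# Ring perception
# ---------------------------------------------------------------------------

def _order_cycle(g: nx.Graph, nodes) -> tuple:
    """Order a basis cycle's node set into a closed walk.

    The induced subgraph of an SSSR ring in a benzenoid is chordless, so a
    degree-2 walk suffices; a backtracking Hamiltonian-cycle search covers
    rings whose induced subgraph picks up chords.
    """
    nodes = set(nodes)
    h = g.subgraph(nodes)
    if all(h.degree(v) == 2 for v in nodes):
        start = min(nodes)
        walk = [start]
        prev = None
        cur = start
        while len(walk) < len(nodes):
            nbrs = [v for v in h.neighbors(cur) if v != prev]
            nxt = min(nbrs)
            walk.append(nxt)
            prev, cur = cur, nxt
        return _canonical_rotation(walk)

    # fallback: Hamiltonian cycle on the induced subgraph by backtracking
    start = min(nodes)
    target_len = len(nodes)

    def extend(path, seen):
        if len(path) == target_len:
            return path if h.has_edge(path[-1], start) else None
        for v in sorted(h.neighbors(path[-1])):
            if v not in seen:
                out = extend(path + [v], seen | {v})
                if out is not None:
                    return out
        return None

    walk = extend([start], {start})
    if walk is None:
        raise GeometryError(f"cannot order ring over atoms {sorted(nodes)}")
    return _canonical_rotation(walk)


def _canonical_rotation(walk) -> tuple:
    """Rotate/reflect a cyclic walk so it starts at its minimum node and
    proceeds toward the smaller of that node's two ring neighbors."""
    n = len(walk)
    i0 = walk.index(min(walk))
    walk = walk[i0:] + walk[:i0]
    if walk[-1] < walk[1]:
        walk = [walk[0]] + walk[:0:-1]
    return tuple(walk)


def perceive_rings(graph: MolecularGraph) -> RingSet:
    """Perceive a smallest-ring basis of the carbon skeleton and classify
    each in-ring C-C bond as fused (shared by >= 2 rings) or perimeter."""
    g = graph.carbon_graph()
    if g.number_of_nodes() == 0:
        raise DisconnectedSkeletonError("structure has no carbon atoms")
    if not nx.is_connected(g):
        parts = [sorted(c) for c in nx.connected_components(g)]
        raise DisconnectedSkeletonError(
            f"carbon skeleton splits into {len(parts)} components; "
            "expected a single fused system"
        )
    basis = nx.minimum_cycle_basis(g)
    rings = sorted((_order_cycle(g, cyc) for cyc in basis), key=lambda r: tuple(sorted(r)))

    bond_ring_count = {}
    ring_bond_sets = []
    for ring in rings:
        bonds = set()
        n = len(ring)
        for i in range(n):
            b = tuple(sorted((ring[i], ring[(i + 1) % n])))
            bonds.add(b)
            bond_ring_count[b] = bond_ring_count.get(b, 0) + 1
        ring_bond_sets.append(bonds)

    fused = frozenset(b for b, c in bond_ring_count.items() if c >= 2)
    perimeter = frozenset(b for b, c in bond_ring_count.items() if c == 1)

    adjacency = {k: set() for k in range(len(rings))}
    for a, b in itertools.combinations(range(len(rings)), 2):
        if ring_bond_sets[a] & ring_bond_sets[b]:
            adjacency[a].add(b)
            adjacency[b].add(a)
    adjacency = {k: frozenset(v) for k, v in adjacency.items()}

    return RingSet(tuple(rings), fused, perimeter, adjacency)


def count_highly_connected_rings(rings: RingSet) -> int:
    """Number of rings fused to three or more neighboring rings."""
    return sum(1 for k in range(rings.n_rings) if len(rings.ring_adjacency[k]) >= 3)


# ---------------------------------------------------------------------------
# Plane alignment
# ---------------------------------------------------------------------------

def _signed_axis(axis: np.ndarray, projections: np.ndarray, tol: float = 1e-9):
    """Fix an axis sign: first selected atom with a non-negligible projection
    gets a positive one; fully degenerate case falls back to making the
    axis component of largest magnitude positive."""
    for p in projections:
        if abs(p) > tol:
            return axis if p > 0 else -axis
    k = int(np.argmax(np.abs(axis)))
    return axis if axis[k] > 0 else -axis


def align_to_plane(structure: Structure, atom_selection: str = "carbons") -> Structure:
    """Translate to the selected-atom centroid and rotate so the selected
    atoms' least-squares plane is z = 0.

    The covariance eigenvector of smallest variance maps to +z with its sign
    chosen so the first selected atom has z >= 0 (deterministic fallback when
    the selection is exactly planar).
    """
    if atom_selection not in ("carbons", "all"):
        raise ValueError("atom_selection must be 'carbons' or 'all'")
    if atom_selection == "carbons":
        sel = list(structure.carbon_indices)
    else:
        sel = list(range(structure.n_atoms))
    if len(sel) < 3:
        raise PlaneDegeneracyError("need at least 3 selected atoms to define a plane")

    xyz = np.asarray(structure.coords)
    centroid = xyz[sel].mean(axis=0)
    centered_sel = xyz[sel] - centroid
    cov = centered_sel.T @ centered_sel / len(sel)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[1] <= 1e-10 * max(evals[2], 1.0):
        raise PlaneDegeneracyError("selected atoms are collinear")

    z_axis = _signed_axis(evecs[:, 0], centered_sel @ evecs[:, 0])
    x_axis = _signed_axis(evecs[:, 2], centered_sel @ evecs[:, 2])
    y_axis = np.cross(z_axis, x_axis)
    rot = np.column_stack([x_axis, y_axis, z_axis])
    new_xyz = (xyz - centroid) @ rot
    return Structure(structure.symbols, new_xyz, structure.comment)
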