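"""Synthetic benzenoid structures and descriptor/energy tables.

Generates idealized fused-hexagon carbon skeletons on a honeycomb lattice,
applies controlled distortions (helical twist, hinge bend, coordinate noise,
alternating bond stretch), and samples seeded descriptor tables with
energies linear in the descriptors plus Laplace noise — so every fitting and
descriptor routine is testable without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .structio import Structure, perceive_bonds, perceive_rings

__all__ = [
    "DistortionSpec",
    "make_benzenoid",
    "apply_distortion",
    "synth_isomer_table",
    "ACENE",
]

#: hexagonal-lattice axial displacements of adjacent cells
_CELL_NEIGHBORS = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1))

DEFAULT_CC = 1.40  # Å
DEFAULT_CH = 1.09  # Å


def ACENE(n: int):
    """Axial cell coordinates of an n-ring linear acene."""
    if n < 1:
        raise ValueError("need at least one ring")
    return [(i, 0) for i in range(n)]


@dataclass(frozen=True)
class DistortionSpec:
    """A reproducible structural distortion.

    mode: 'twist' (progressive rotation about the long axis, degrees),
    'bend' (rigid rotation of a fragment about a fused bond, degrees),
    'noise' (i.i.d. Gaussian displacement, Å), or 'kekule' (alternating
    in-plane bond stretch/compress, Å). ``locus`` selects the fused bond for
    'bend' (index into the sorted fused-bond list).
    """

    mode: str
    magnitude: float
    locus: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("twist", "bend", "noise", "kekule"):
            raise ValueError(f"unknown distortion mode {self.mode!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")


def _cells_connected(cells) -> bool:
    cells = set(cells)
    seen = {next(iter(cells))}
    stack = list(seen)
    while stack:
        q, r = stack.pop()
        for dq, dr in _CELL_NEIGHBORS:
            nb = (q + dq, r + dr)
            if nb in cells and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen == cells


def make_benzenoid(
    spec: Union[int, Iterable[Tuple[int, int]]],
    bond_length: float = DEFAULT_CC,
    ch_length: float = DEFAULT_CH,
    hydrogens: bool = True,
) -> Structure:
    """Build a planar fused-hexagon structure from lattice cells.

    ``spec`` is an acene length n or an iterable of axial (q, r) hexagon
    coordinates on the triangular lattice; cells must be edge-connected.
    All C-C bonds equal ``bond_length``, all angles are 120°, and hydrogens
    sit in-plane on two-coordinate carbons at ``ch_length``.
    """
    cells = ACENE(spec) if isinstance(spec, int) else list(spec)
    if not cells:
        raise ValueError("empty cell set")
    if len(set(cells)) != len(cells):
        raise ValueError("duplicate cells")
    if not _cells_connected(cells):
        raise ValueError("cells are not edge-connected")

    L = float(bond_length)
    a1 = np.array([math.sqrt(3.0) * L, 0.0])
    a2 = np.array([math.sqrt(3.0) / 2.0 * L, 1.5 * L])

    verts = {}
    for q, r in cells:
        center = q * a1 + r * a2
        for k in range(6):
            ang = math.radians(30.0 + 60.0 * k)
            p = center + L * np.array([math.cos(ang), math.sin(ang)])
            key = (round(p[0], 6), round(p[1], 6))
            verts.setdefault(key, p)
    keys = sorted(verts)
    carbons = np.array([[verts[k][0], verts[k][1], 0.0] for k in keys])

    symbols = ["C"] * len(carbons)
    coords = [carbons]
    if hydrogens:
        # neighbors among carbons at exactly the lattice bond length
        d = np.linalg.norm(carbons[:, None, :] - carbons[None, :, :], axis=-1)
        adj = (d > 0.1) & (d < 1.05 * L)
        h_rows = []
        for i in range(len(carbons)):
            nbrs = np.nonzero(adj[i])[0]
            if len(nbrs) == 2:
                u = 2 * carbons[i] - carbons[nbrs[0]] - carbons[nbrs[1]]
                u /= np.linalg.norm(u)
                h_rows.append(carbons[i] + ch_length * u)
        if h_rows:
            coords.append(np.array(h_rows))
            symbols += ["H"] * len(h_rows)
    xyz = np.vstack(coords)
    comment = f"benzenoid cells={sorted(set(cells))} L={L:g}"
    return Structure(tuple(symbols), xyz, comment)


# ---------------------------------------------------------------------------
# distortions
# ---------------------------------------------------------------------------

def _rodrigues(points: np.ndarray, origin: np.ndarray, axis: np.ndarray,
               angles_deg) -> np.ndarray:
    """Rotate points about the line (origin, axis) by per-point angles."""
    u = axis / np.linalg.norm(axis)
    t = np.radians(np.atleast_1d(np.asarray(angles_deg, dtype=float)))
    p = points - origin
    cos_t = np.cos(t)[:, None]
    sin_t = np.sin(t)[:, None]
    cross = np.cross(np.broadcast_to(u, p.shape), p)
    dot = (p @ u)[:, None]
    rotated = p * cos_t + cross * sin_t + u * dot * (1 - cos_t)
    return rotated + origin


def _deterministic_sign(v: np.ndarray) -> np.ndarray:
    k = int(np.argmax(np.abs(v)))
    return v if v[k] > 0 else -v


def _twist(structure: Structure, magnitude: float) -> Structure:
    xyz = np.asarray(structure.coords)
    carbons = xyz[list(structure.carbon_indices)]
    centroid = carbons.mean(axis=0)
    cen = carbons - centroid
    _, vecs = np.linalg.eigh(cen.T @ cen)
    axis = _deterministic_sign(vecs[:, -1])  # largest-variance direction
    proj = (xyz - centroid) @ axis
    lo, hi = proj.min(), proj.max()
    if hi - lo < 1e-12:
        return structure
    frac = (proj - lo) / (hi - lo)
    new = _rodrigues(xyz, centroid, axis, magnitude * frac)
    return Structure(structure.symbols, new, structure.comment)


def _attached_hydrogens(structure: Structure, graph, carbon_set) -> set:
    hs = set()
    for i, j in graph.bonds:
        si, sj = structure.symbols[i], structure.symbols[j]
        if si == "H" and j in carbon_set:
            hs.add(i)
        elif sj == "H" and i in carbon_set:
            hs.add(j)
    return hs


def _bend(structure: Structure, magnitude: float, locus: int) -> Structure:
    import networkx as nx

    graph = perceive_bonds(structure)
    rings = perceive_rings(graph)
    fused = sorted(rings.fused_bonds)
    if not fused:
        raise ValueError("bend requires a fused bond")
    if not (0 <= locus < len(fused)):
        raise ValueError(f"locus {locus} out of range for {len(fused)} fused bonds")
    i, j = fused[locus]
    g = graph.carbon_graph()
    g.remove_nodes_from([i, j])
    comps = sorted(nx.connected_components(g), key=lambda c: (len(c), min(c)))
    moving = set(comps[0])
    moving |= _attached_hydrogens(structure, graph, moving)
    xyz = np.asarray(structure.coords).copy()
    idx = sorted(moving)
    axis = xyz[j] - xyz[i]
    xyz[idx] = _rodrigues(xyz[idx], xyz[i], axis, np.full(len(idx), magnitude))
    return Structure(structure.symbols, xyz, structure.comment)


def _noise(structure: Structure, magnitude: float, seed: int) -> Structure:
    rng = np.random.default_rng(seed)
    disp = rng.normal(0.0, magnitude, size=(structure.n_atoms, 3)) if magnitude > 0 \
        else np.zeros((structure.n_atoms, 3))
    return Structure(structure.symbols, np.asarray(structure.coords) + disp,
                     structure.comment)


def _kekule(structure: Structure, amplitude: float) -> Structure:
    graph = perceive_bonds(structure)
    rings = perceive_rings(graph)
    if rings.n_rings != 1:
        raise ValueError("kekule alternation is defined for single-ring structures")
    ring = rings.rings[0]
    if len(ring) % 2 != 0:
        raise ValueError("alternation requires an even-membered ring")
    xyz = np.asarray(structure.coords).copy()
    old = xyz.copy()
    pos = xyz[ring[0]].copy()
    for k in range(len(ring) - 1):
        a, b = ring[k], ring[k + 1]
        direction = old[b] - old[a]
        length = np.linalg.norm(direction)
        direction /= length
        new_len = length + amplitude * (1 if k % 2 == 0 else -1)
        pos = pos + new_len * direction
        xyz[b] = pos
    # carry hydrogens along with their carbon
    carbon_set = set(ring)
    for i, j in graph.bonds:
        if structure.symbols[i] == "H" and j in carbon_set:
            xyz[i] = old[i] + (xyz[j] - old[j])
        elif structure.symbols[j] == "H" and i in carbon_set:
            xyz[j] = old[j] + (xyz[i] - old[i])
    return Structure(structure.symbols, xyz, structure.comment)


def apply_distortion(structure: Structure, spec: DistortionSpec) -> Structure:
    """Apply a seeded, deterministic distortion; magnitude 0 is the identity."""
    if spec.magnitude == 0 and spec.mode != "noise":
        return structure
    if spec.mode == "twist":
        return _twist(structure, spec.magnitude)
    if spec.mode == "bend":
        return _bend(structure, spec.magnitude, spec.locus)
    if spec.mode == "noise":
        return _noise(structure, spec.magnitude, spec.seed)
    return _kekule(structure, spec.magnitude)


# ---------------------------------------------------------------------------
# synthetic descriptor/energy tables
# ---------------------------------------------------------------------------

#: seeded sampling ranges spanning the observed descriptor spectrum
#: (dihedral sums up to 1912°, out-of-plane extents up to 8.78 Å, so both
#: planar and nonplanar regimes are populated)
DESCRIPTOR_RANGES = {
    "sum_dihedral": (0.0, 1912.0),
    "homa": (0.4, 1.0),
    "theta_rmsd": (0.0, 8.0),
    "delta_z": (0.0, 8.78),
}


def synth_isomer_table(
    n_per_formula: int,
    formulas: Sequence[str],
    true_coefficients: Mapping[str, float],
    noise_scale: float,
    seed: int,
    intercept: float = 0.0,
    xtb_spec: Optional[Tuple[float, float, float]] = None,
) -> pd.DataFrame:
    """Sample a reproducible isomer table with energies linear in the
    descriptors plus Laplace noise.

    e_ref = intercept + sum(coef * descriptor) + Laplace(noise_scale); the
    optional ``xtb_spec=(offset, slope, noise)`` adds a systematically
    distorted e_xtb column. Identical seeds give identical tables.
    """
    if n_per_formula < 2:
        raise ValueError("need n_per_formula >= 2")
    unknown = set(true_coefficients) - set(DESCRIPTOR_RANGES)
    if unknown:
        raise ValueError(f"no sampling range for descriptors: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows = {"id": [], "formula": []}
    cols = list(DESCRIPTOR_RANGES)
    for c in cols:
        rows[c] = []
    n_total = n_per_formula * len(formulas)
    for formula in formulas:
        for i in range(n_per_formula):
            rows["id"].append(f"{formula}_{i}")
            rows["formula"].append(formula)
    for c in cols:
        lo, hi = DESCRIPTOR_RANGES[c]
        rows[c] = rng.uniform(lo, hi, size=n_total)
    df = pd.DataFrame(rows)
    e = np.full(n_total, float(intercept))
    for c, coef in true_coefficients.items():
        e = e + coef * df[c].to_numpy()
    if noise_scale > 0:
        e = e + rng.laplace(0.0, noise_scale, size=n_total)
    df["e_ref"] = e
    if xtb_spec is not None:
        offset, slope, xtb_noise = xtb_spec
        ex = offset + slope * df["e_ref"].to_numpy()
        if xtb_noise > 0:
            ex = ex + rng.laplace(0.0, xtb_noise, size=n_total)
        df["e_xtb"] = ex
    return df
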