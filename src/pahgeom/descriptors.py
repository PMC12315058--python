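"""Geometric descriptors of fused aromatic carbon skeletons.

All descriptors operate on the carbon skeleton only (hydrogens are ignored),
angles are reported in degrees and lengths in Å.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Callable, Optional

import numpy as np

from .structio import (
    MolecularGraph,
    RingSet,
    Structure,
    align_to_plane,
    count_highly_connected_rings,
    perceive_bonds,
    perceive_rings,
)

__all__ = [
    "HomaParams",
    "DescriptorSet",
    "DescriptorUndefinedError",
    "DESCRIPTOR_COLUMNS",
    "homa",
    "bla",
    "bond_angle_metrics",
    "sum_dihedral",
    "pyramidalization_rmsd",
    "delta_z",
    "ring_bond_lengths",
    "compute_all",
]

DEFAULT_R_OPT = 1.388  # Å, optimal aromatic C-C bond length
DEFAULT_ALPHA = 257.7  # normalization constant for C-C

IDEAL_ANGLE = 120.0  # degrees, ideal sp2 C-C-C angle


class DescriptorUndefinedError(ValueError):
    """The requested descriptor is undefined for this structure."""


@dataclass(frozen=True)
class HomaParams:
    """Parameters of the harmonic-oscillator aromaticity index.

    variant: 'all-ring' averages per-ring values over rings; 'fused' and
    'edge' evaluate the index once over the pooled fused / perimeter bonds.
    """

    r_opt: float = DEFAULT_R_OPT
    alpha: float = DEFAULT_ALPHA
    variant: str = "all-ring"

    def __post_init__(self):
        if self.r_opt <= 0:
            raise ValueError("r_opt must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.variant not in ("all-ring", "fused", "edge"):
            raise ValueError(f"unknown variant {self.variant!r}")


# Fixed CSV column order for descriptor rows.
DESCRIPTOR_COLUMNS = (
    "homa",
    "homa_fused",
    "homa_edge",
    "bla",
    "l_avg",
    "baa",
    "sum_theta",
    "theta_rmsd",
    "sum_dihedral",
    "theta_pyr_rmsd",
    "delta_z",
    "n_highly_connected_rings",
)


@dataclass(frozen=True)
class DescriptorSet:
    """The full geometric descriptor vector of one structure.

    Fields that are undefined for a structure (e.g. no fused bonds) are NaN.
    """

    homa: float
    homa_fused: float
    homa_edge: float
    bla: float
    l_avg: float
    baa: float
    sum_theta: float
    theta_rmsd: float
    sum_dihedral: float
    theta_pyr_rmsd: float
    delta_z: float
    n_highly_connected_rings: int

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def is_defined(self, name: str) -> bool:
        v = getattr(self, name)
        return not (isinstance(v, float) and math.isnan(v))


# ---------------------------------------------------------------------------
# bond-length descriptors
# ---------------------------------------------------------------------------

def _dist(xyz: np.ndarray, i: int, j: int) -> float:
    return float(np.linalg.norm(xyz[i] - xyz[j]))


def ring_bond_lengths(structure: Structure, rings: RingSet) -> list:
    """Per-ring lists of consecutive bond lengths (cyclic order)."""
    xyz = np.asarray(structure.coords)
    out = []
    for ring in rings.rings:
        n = len(ring)
        out.append([_dist(xyz, ring[i], ring[(i + 1) % n]) for i in range(n)])
    return out


def _homa_over_pool(lengths, r_opt: float, alpha: float) -> float:
    n = len(lengths)
    dev = sum((L - r_opt) ** 2 for L in lengths)
    return 1.0 - alpha / n * dev


def homa(structure: Structure, rings: RingSet, params: HomaParams = None) -> float:
    """Harmonic-oscillator aromaticity index.

    all-ring: mean over rings of ``1 - alpha/n * sum (R_k - r_opt)^2`` with
    n the bond count of that ring; fused/edge: one evaluation over the
    pooled fused / perimeter bond lengths.
    """
    params = params or HomaParams()
    xyz = np.asarray(structure.coords)
    if params.variant == "all-ring":
        if rings.n_rings == 0:
            raise DescriptorUndefinedError("no rings: aromaticity index undefined")
        per_ring = [
            _homa_over_pool(lengths, params.r_opt, params.alpha)
            for lengths in ring_bond_lengths(structure, rings)
        ]
        return float(np.mean(per_ring))
    pool = rings.fused_bonds if params.variant == "fused" else rings.perimeter_bonds
    if not pool:
        raise DescriptorUndefinedError(
            f"no {params.variant} bonds: variant undefined for this structure"
        )
    lengths = [_dist(xyz, i, j) for i, j in sorted(pool)]
    return _homa_over_pool(lengths, params.r_opt, params.alpha)


def bla(structure: Structure, rings: RingSet) -> float:
    """Bond-length alternation: per ring the mean cyclic |R_k - R_{k+1}|,
    averaged over rings."""
    if rings.n_rings == 0:
        raise DescriptorUndefinedError("no rings: bond-length alternation undefined")
    per_ring = []
    for lengths in ring_bond_lengths(structure, rings):
        n = len(lengths)
        per_ring.append(
            sum(abs(lengths[i] - lengths[(i + 1) % n]) for i in range(n)) / n
        )
    return float(np.mean(per_ring))


# ---------------------------------------------------------------------------
# bond-angle descriptors
# ---------------------------------------------------------------------------

def _angle_deg(xyz: np.ndarray, i: int, j: int, k: int) -> float:
    """Angle i-j-k in degrees."""
    u = xyz[i] - xyz[j]
    v = xyz[k] - xyz[j]
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, float(cosang)))))


def _carbon_neighbor_map(graph: MolecularGraph) -> dict:
    carbons = set(graph.carbon_indices)
    nbrs = {c: [] for c in carbons}
    for i, j in graph.bonds:
        if i in carbons and j in carbons:
            nbrs[i].append(j)
            nbrs[j].append(i)
    return {c: sorted(v) for c, v in nbrs.items()}


def bond_angle_metrics(structure: Structure, graph: MolecularGraph, rings: RingSet):
    """C-C-C angle statistics and the mean C-C bond length.

    Returns (sum_theta, theta_rmsd, baa, l_avg): the summed and RMS
    deviations of all carbon-centered C-C-C angles from 120 degrees, the
    ring-wise bond-angle alternation, and the mean C-C bond length.
    """
    xyz = np.asarray(structure.coords)
    nbrs = _carbon_neighbor_map(graph)
    devs = []
    for c, neigh in sorted(nbrs.items()):
        for a_i in range(len(neigh)):
            for a_k in range(a_i + 1, len(neigh)):
                devs.append(_angle_deg(xyz, neigh[a_i], c, neigh[a_k]) - IDEAL_ANGLE)
    if not devs:
        raise DescriptorUndefinedError("no C-C-C angles in structure")
    devs = np.array(devs)
    sum_theta = float(np.sum(np.abs(devs)))
    theta_rmsd = float(np.sqrt(np.mean(devs**2)))

    # bond-angle alternation: mean cyclic |θ_i − θ_{i+1}| of in-ring angles
    per_ring = []
    for ring in rings.rings:
        n = len(ring)
        ring_angles = [
            _angle_deg(xyz, ring[(i - 1) % n], ring[i], ring[(i + 1) % n])
            for i in range(n)
        ]
        per_ring.append(
            sum(abs(ring_angles[i] - ring_angles[(i + 1) % n]) for i in range(n)) / n
        )
    baa = float(np.mean(per_ring)) if per_ring else float("nan")

    cc = sorted(graph.cc_bonds)
    l_avg = float(np.mean([graph.bond_lengths[b] for b in cc]))
    return sum_theta, theta_rmsd, baa, l_avg


# ---------------------------------------------------------------------------
# nonplanarity descriptors
# ---------------------------------------------------------------------------

def _torsion_deg(p0, p1, p2, p3) -> float:
    """Dihedral angle of the chain p0-p1-p2-p3 in (-180, 180] degrees."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    phi = math.degrees(math.atan2(y, x))
    if phi <= -180.0:
        phi += 360.0
    return phi


def torsion_deviation(phi_deg: float) -> float:
    """Angular distance of a torsion to the nearest planar value (0 or 180)."""
    a = abs(phi_deg)
    return min(a, 180.0 - a) if a <= 180.0 else min(360.0 - a, a - 180.0)


def sum_dihedral(
    structure: Structure,
    graph: MolecularGraph,
    central_bond_filter: Optional[Callable] = None,
) -> float:
    """Sum of torsion deviations from planarity over all distinct bonded
    4-carbon simple paths, in degrees.

    Each unordered path a-b-c-d is counted once. ``central_bond_filter``
    optionally restricts which central bonds (b, c) are enumerated — pass a
    predicate over sorted bond tuples to match alternative conventions.
    """
    xyz = np.asarray(structure.coords)
    nbrs = _carbon_neighbor_map(graph)
    if len(nbrs) < 4:
        raise DescriptorUndefinedError("fewer than 4 carbons: no torsions")
    total = 0.0
    n_paths = 0
    for b, c in sorted({tuple(sorted(e)) for e in _cc_edges(nbrs)}):
        if central_bond_filter is not None and not central_bond_filter((b, c)):
            continue
        for a in nbrs[b]:
            if a == c:
                continue
            for d in nbrs[c]:
                if d == b or d == a:
                    continue
                phi = _torsion_deg(xyz[a], xyz[b], xyz[c], xyz[d])
                total += torsion_deviation(phi)
                n_paths += 1
    if n_paths == 0:
        raise DescriptorUndefinedError("no bonded 4-carbon paths")
    return total


def _cc_edges(nbrs: dict):
    for c, neigh in nbrs.items():
        for v in neigh:
            if c < v:
                yield (c, v)


def pyramidalization_rmsd(structure: Structure, graph: MolecularGraph) -> float:
    """RMS pyramidalization angle over carbons with three carbon neighbors.

    For each such carbon the angle is arcsin(h / l_mean) with h its distance
    from the plane of its three neighbors and l_mean the mean length of the
    three bonds; exactly 0 for a planar center.
    """
    xyz = np.asarray(structure.coords)
    nbrs = _carbon_neighbor_map(graph)
    angles = []
    for c, neigh in sorted(nbrs.items()):
        if len(neigh) != 3:
            continue
        p1, p2, p3 = (xyz[v] for v in neigh)
        normal = np.cross(p2 - p1, p3 - p1)
        nn = np.linalg.norm(normal)
        if nn < 1e-12:
            raise DescriptorUndefinedError(f"neighbors of atom {c} are collinear")
        h = abs(float(np.dot(xyz[c] - p1, normal / nn)))
        l_mean = float(np.mean([np.linalg.norm(xyz[c] - xyz[v]) for v in neigh]))
        ratio = min(1.0, h / l_mean)
        angles.append(math.degrees(math.asin(ratio)))
    if not angles:
        raise DescriptorUndefinedError("no carbon with exactly 3 carbon neighbors")
    return float(np.sqrt(np.mean(np.square(angles))))


def delta_z(structure: Structure, atom_selection: str = "carbons") -> float:
    """Out-of-plane extent: max(z) - min(z) of the selected atoms after
    aligning their best-fit plane to z = 0."""
    aligned = align_to_plane(structure, atom_selection)
    if atom_selection == "carbons":
        sel = list(aligned.carbon_indices)
    else:
        sel = list(range(aligned.n_atoms))
    z = np.asarray(aligned.coords)[sel, 2]
    return float(z.max() - z.min())


# ---------------------------------------------------------------------------
# one-shot panel
# ---------------------------------------------------------------------------

def compute_all(
    structure: Structure,
    cc_cutoff: float = 1.75,
    ch_cutoff: float = 1.30,
    homa_params: HomaParams = None,
    plane_selection: str = "carbons",
) -> DescriptorSet:
    """Chain perception and every descriptor into one DescriptorSet.

    Descriptors undefined for the structure (e.g. the fused-bond aromaticity
    variant of a single ring) come back as NaN rather than raising.
    """
    base = homa_params or HomaParams()
    graph = perceive_bonds(structure, cc_cutoff, ch_cutoff)
    rings = perceive_rings(graph)

    def guarded(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except DescriptorUndefinedError:
            return float("nan")

    homa_all = guarded(
        homa, structure, rings,
        HomaParams(base.r_opt, base.alpha, "all-ring"),
    )
    homa_f = guarded(
        homa, structure, rings, HomaParams(base.r_opt, base.alpha, "fused")
    )
    homa_e = guarded(
        homa, structure, rings, HomaParams(base.r_opt, base.alpha, "edge")
    )
    bla_v = guarded(bla, structure, rings)
    try:
        sum_theta, theta_rmsd, baa, l_avg = bond_angle_metrics(structure, graph, rings)
    except DescriptorUndefinedError:
        sum_theta = theta_rmsd = baa = l_avg = float("nan")
    sd = guarded(sum_dihedral, structure, graph)
    pyr = guarded(pyramidalization_rmsd, structure, graph)
    dz = guarded(delta_z, structure, plane_selection)
    return DescriptorSet(
        homa=homa_all,
        homa_fused=homa_f,
        homa_edge=homa_e,
        bla=bla_v,
        l_avg=l_avg,
        baa=baa,
        sum_theta=sum_theta,
        theta_rmsd=theta_rmsd,
        sum_dihedral=sd,
        theta_pyr_rmsd=pyr,
        delta_z=dz,
        n_highly_connected_rings=count_highly_connected_rings(rings),
    )
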