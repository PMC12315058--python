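"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the library's own code paths: plane fits via a
covariance eigen-decomposition, torsions via explicit plane normals,
descriptor sums via naive loops, and LAD fits via exhaustive search.
"""

import itertools
import math

import numpy as np


def plane_dz_oracle(points: np.ndarray) -> float:
    """max-min extent along the smallest-variance covariance eigenvector."""
    points = np.asarray(points, dtype=float)
    c = points.mean(axis=0)
    m = points - c
    evals, evecs = np.linalg.eigh(m.T @ m)
    normal = evecs[:, 0]
    proj = m @ normal
    return float(proj.max() - proj.min())


def torsion_oracle_deg(p0, p1, p2, p3) -> float:
    """Dihedral via plane normals (atan2 form, well conditioned near 0/180)."""
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.degrees(math.atan2(np.dot(m, n2), np.dot(n1, n2)))


def sum_dihedral_oracle(xyz: np.ndarray, cc_bonds) -> float:
    """Enumerate every ordered 4-carbon bonded chain, halve the double count."""
    adj = {}
    for i, j in cc_bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    total = 0.0
    for b in adj:
        for c in adj[b]:
            for a in adj[b] - {c}:
                for d in adj[c] - {b, a}:
                    phi = abs(torsion_oracle_deg(xyz[a], xyz[b], xyz[c], xyz[d]))
                    total += min(phi, 180.0 - phi)
    return total / 2.0


def angle_stats_oracle(xyz: np.ndarray, cc_bonds):
    """(sum|θ-120|, rms(θ-120)) over all carbon-centered C-C-C triples."""
    adj = {}
    for i, j in cc_bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    devs = []
    for center, nbrs in adj.items():
        for a, b in itertools.combinations(sorted(nbrs), 2):
            u = xyz[a] - xyz[center]
            v = xyz[b] - xyz[center]
            cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            theta = math.degrees(math.acos(max(-1.0, min(1.0, float(cosang)))))
            devs.append(theta - 120.0)
    devs = np.asarray(devs)
    return float(np.sum(np.abs(devs))), float(np.sqrt(np.mean(devs**2)))


def homa_oracle(bond_lengths, r_opt: float, alpha: float) -> float:
    """Direct summation of the aromaticity index over one bond pool."""
    s = 0.0
    for L in bond_lengths:
        s += (L - r_opt) ** 2
    return 1.0 - alpha / len(bond_lengths) * s


def pyramidalization_oracle(xyz: np.ndarray, cc_bonds) -> float:
    """RMS arcsin(plane distance / mean bond length) over 3-coordinate carbons."""
    adj = {}
    for i, j in cc_bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    angles = []
    for center, nbrs in sorted(adj.items()):
        if len(nbrs) != 3:
            continue
        a, b, c = (xyz[v] for v in sorted(nbrs))
        n = np.cross(b - a, c - a)
        n = n / np.linalg.norm(n)
        h = abs(float(np.dot(xyz[center] - a, n)))
        lmean = np.mean([np.linalg.norm(xyz[center] - xyz[v]) for v in sorted(nbrs)])
        angles.append(math.degrees(math.asin(min(1.0, h / lmean))))
    return float(np.sqrt(np.mean(np.square(angles))))


def bla_oracle(xyz: np.ndarray, rings) -> float:
    per_ring = []
    for ring in rings:
        n = len(ring)
        lengths = [np.linalg.norm(xyz[ring[i]] - xyz[ring[(i + 1) % n]]) for i in range(n)]
        per_ring.append(np.mean([abs(lengths[i] - lengths[(i + 1) % n]) for i in range(n)]))
    return float(np.mean(per_ring))


def lad_grid_oracle(X: np.ndarray, y: np.ndarray, grids):
    """Exhaustive grid search for the LAD optimum.

    grids: one 1-D candidate array per parameter, intercept first.
    Returns (best parameter vector, best MAD).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    X1 = np.column_stack([np.ones(len(y)), X])
    best = (None, np.inf)
    for combo in itertools.product(*grids):
        beta = np.asarray(combo, dtype=float)
        mad = float(np.mean(np.abs(y - X1 @ beta)))
        if mad < best[1]:
            best = (beta, mad)
    return best


def lad_subset_oracle(X: np.ndarray, y: np.ndarray):
    """Exact small-problem LAD: some optimum interpolates k+1 points, so
    enumerate all interpolating hyperplanes and keep the best MAD."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    X1 = np.column_stack([np.ones(len(y)), X])
    n, p = X1.shape
    best = (None, np.inf)
    for rows in itertools.combinations(range(n), p):
        A = X1[list(rows)]
        if abs(np.linalg.det(A)) < 1e-12:
            continue
        beta = np.linalg.solve(A, y[list(rows)])
        mad = float(np.mean(np.abs(y - X1 @ beta)))
        if mad < best[1]:
            best = (beta, mad)
    return best
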