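"""Small 3-D geometry primitives shared by the analyzers and generators."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed torsion p0-p1-p2-p3 mapped to [0, 360) degrees.

    Uses the standard atan2 formulation; the result is invariant under
    rigid rotation/translation and maps to 360 - x under mirror reflection.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, unit(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = np.degrees(np.arctan2(y, x))
    return float(ang % 360.0)


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares plane through points: returns (unit normal, RMS distance)."""
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    dists = centered @ normal
    return normal, float(np.sqrt(np.mean(dists**2)))


def superpose_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD of b onto a after optimal rigid (Kabsch) superposition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have identical shapes")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(ac, bc)
    return float(rssd / np.sqrt(len(a)))


def place_atom(a, b, c, bond: float, angle_deg: float,
               torsion_deg: float) -> np.ndarray:
    """Place atom d with given internal coordinates relative to chain a-b-c.

    ``bond`` = |d-c|, ``angle_deg`` = angle(d,c,b), ``torsion_deg`` =
    dihedral(d,c,b,a).  The natural-extension reference frame construction.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            -bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
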