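"""Backbone geometry primitives: dihedrals, internal-coordinate atom
placement (NeRF), ideal Cbeta reconstruction and Kabsch superposition.

All coordinates are in Angstroms, all angles in degrees at the interfaces.
"""
from __future__ import annotations

import numpy as np

# Ideal backbone internal coordinates (trans peptide).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.229
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
ANGLE_C_CA_CB = 110.1
TORSION_N_C_CA_CB = -122.6  # improper placing CB from N, C, CA
OMEGA_TRANS = 180.0


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(-y, x)))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D given A, B, C with |CD| = bond, angle(B,C,D) = angle and
    dihedral(A,B,C,D) = torsion (NeRF construction)."""
    ang = np.radians(angle)
    tor = np.radians(torsion)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal Cbeta position from backbone N, CA, C (tetrahedral, 1.521 A)."""
    return place_atom(n, c, ca, BOND_CA_CB, ANGLE_C_CA_CB, TORSION_N_C_CA_CB)


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Optimal rotation/translation superposing `mobile` onto `target`
    (least-squares, proper rotation). Returns (R, t) with
    transformed = mobile @ R.T + t."""
    mob_c = mobile.mean(axis=0)
    tgt_c = target.mean(axis=0)
    p = mobile - mob_c
    q = target - tgt_c
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    r = vt.T @ diag @ u.T
    t = tgt_c - r @ mob_c
    return r, t


def apply_transform(coords: np.ndarray, r: np.ndarray,
                    t: np.ndarray) -> np.ndarray:
    return coords @ r.T + t


def rmsd_superposed(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between coordinate sets after optimal superposition."""
    r, t = kabsch(a, b)
    diff = apply_transform(a, r, t) - b
    return float(np.sqrt((diff ** 2).sum() / len(a)))


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random proper rotation plus a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    r = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.normal(scale=20.0, size=3)
    return r, t
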