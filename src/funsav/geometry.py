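"""Low-level 3D geometry: angles, dihedrals, internal-coordinate chain building.

These primitives back both the synthetic structure generator and the
backbone-geometry features.  All angles are in degrees; all lengths in Å.
"""

from __future__ import annotations

import numpy as np

# Ideal backbone internal coordinates (Engh & Huber averages).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.4
# torsion C(i)-N(i)-CA(i)-CB(i) for an L-amino acid
TORSION_N_CA_CB = -122.6


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero-length vector")
    return v / n


def bond_angle(a, b, c) -> float:
    """Angle at vertex b, in degrees, within [0, 180]."""
    u = unit(np.asarray(a, float) - np.asarray(b, float))
    w = unit(np.asarray(c, float) - np.asarray(b, float))
    cosang = np.clip(np.dot(u, w), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(a, b, c, d) -> float:
    """Signed torsion a-b-c-d in degrees, in (-180, 180]."""
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    b0 = a - b
    b1 = c - b
    b2 = d - c
    b1u = unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang


def place_atom(a, b, c, length: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d such that |c-d| = length, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (NeRF construction)."""
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    theta = np.radians(angle)
    chi = np.radians(torsion)
    d_local = length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def pseudo_cbeta(n, ca, c) -> np.ndarray:
    """Ideal Cβ position from backbone N/CA/C (used for glycine and for
    synthetic structures)."""
    return place_atom(c, n, ca, BOND_CA_CB, ANGLE_N_CA_CB, TORSION_N_CA_CB)


def build_backbone(n_residues: int, phi, psi, omega=180.0):
    """Build backbone coordinates for a poly-peptide from torsions.

    phi/psi/omega may be scalars or per-residue sequences.  Returns a list of
    dicts with keys N, CA, C, O, CB (CB always built; callers drop it for Gly
    when a real glycine is wanted).
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    phi = np.broadcast_to(np.asarray(phi, float), (n_residues,))
    psi = np.broadcast_to(np.asarray(psi, float), (n_residues,))
    omega = np.broadcast_to(np.asarray(omega, float), (n_residues,))

    # seed the first three backbone atoms in the xy-plane
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    d = np.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * (
        np.cos(d) * unit(n0 - ca0) + np.sin(d) * np.array([0.0, 1.0, 0.0])
    )

    residues = [{"N": n0, "CA": ca0, "C": c0}]
    for i in range(1, n_residues):
        prev = residues[-1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        ca_i = place_atom(prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, omega[i - 1])
        c_i = place_atom(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi[i])
        residues.append({"N": n_i, "CA": ca_i, "C": c_i})

    # carbonyl oxygens: O(i) trans to N(i+1) about the CA(i)-C(i) axis
    for i, res in enumerate(residues):
        if i + 1 < n_residues:
            tors = dihedral(res["N"], res["CA"], res["C"], residues[i + 1]["N"]) + 180.0
        else:
            tors = psi[i] + 180.0
        res["O"] = place_atom(res["N"], res["CA"], res["C"], BOND_C_O, ANGLE_CA_C_O, tors)
        res["CB"] = pseudo_cbeta(res["N"], res["CA"], res["C"])
    return residues


# canonical torsion sets
HELIX_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (-180.0, 180.0)
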