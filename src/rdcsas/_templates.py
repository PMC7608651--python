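"""Idealized ribonucleotide templates.

Builds free-standing A/C/G/U nucleotides (heavy atoms plus the protons
needed for dipolar-coupling bond vectors) from internal coordinates.  The
ribose ring is generated from a pseudorotation-parameterized out-of-plane
displacement model and calibrated numerically so the Altona-Sundaralingam
phase computed from the resulting ring torsions hits the requested value.
Bases are planar rings with standard bond lengths.  These templates are
idealized scaffolds: bond lengths and angles are textbook values, not a
refined force-field geometry.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from ._geometry import dihedral, nerf_place

# ring atom order used throughout: O4', C1', C2', C3', C4'
RING_ATOMS = ("O4'", "C1'", "C2'", "C3'", "C4'")

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U"}

# default glycosidic / backbone torsions for the A-form-like template (deg).
# chi sits at the high-anti edge: with rigid residues on an ideal screw the
# calibration (backbone closure + WC H-bonds + stacking) prefers it there.
CHI_ANTI = -92.0
GAMMA = 54.0
BETA = 178.0
DELTA_TARGET = 82.0  # emerges from C3'-endo ring + O3' placement

CH_BOND = 1.09
NH_BOND = 1.03


def pseudorotation_phase(ring: dict[str, np.ndarray]) -> tuple[float, float]:
    """Altona-Sundaralingam (P, nu_max) in degrees from ring coordinates."""
    o4, c1, c2, c3, c4 = (ring[a] for a in RING_ATOMS)
    nu = np.array([
        dihedral(c4, o4, c1, c2),
        dihedral(o4, c1, c2, c3),
        dihedral(c1, c2, c3, c4),
        dihedral(c2, c3, c4, o4),
        dihedral(c3, c4, o4, c1),
    ])
    # least-squares fit of nu_j = nu_max * cos(P + 144 deg * (j - 2)),
    # which is exact for an ideal pseudorotation path and well conditioned
    # at every phase (the classic nu2 / cos P form diverges near P = 90).
    ang = np.radians(144.0 * (np.arange(5) - 2))
    a, b = np.linalg.lstsq(np.column_stack([np.cos(ang), -np.sin(ang)]), nu,
                           rcond=None)[0]
    P = float(np.degrees(np.arctan2(b, a)) % 360.0)
    nu_max = float(np.hypot(a, b))
    return P, nu_max


def _ring_coords(phase: float, q: float = 0.38, bond: float = 1.53) -> dict[str, np.ndarray]:
    """Five-membered ring with out-of-plane displacements z_j ~ q cos(phase + 4 pi j / 5)."""
    n = 5
    radius = bond / (2.0 * np.sin(np.pi / n))
    coords = {}
    for j, name in enumerate(RING_ATOMS):
        theta = 2.0 * np.pi * j / n
        z = np.sqrt(2.0 / n) * q * np.cos(np.radians(phase) + 2.0 * theta)
        coords[name] = np.array([radius * np.cos(theta), radius * np.sin(theta), z])
    return coords


@lru_cache(maxsize=64)
def _phase_for_pucker(p_target: float) -> float:
    """Displacement phase whose ring realizes Altona-Sundaralingam P = p_target."""

    def f(phase):
        P, _ = pseudorotation_phase(_ring_coords(phase))
        # signed circular difference
        d = (P - p_target + 180.0) % 360.0 - 180.0
        return d

    # scan for a bracketing interval
    grid = np.linspace(0.0, 360.0, 181)
    vals = [f(g) for g in grid]
    for k in range(len(grid) - 1):
        if vals[k] == 0.0:
            return float(grid[k])
        if vals[k] * vals[k + 1] < 0 and abs(vals[k] - vals[k + 1]) < 180.0:
            return float(brentq(f, grid[k], grid[k + 1], xtol=1e-10))
    raise RuntimeError(f"could not calibrate ring phase for P={p_target}")


def _tetrahedral_h(center: np.ndarray, neighbors: list[np.ndarray],
                   bond: float = CH_BOND) -> np.ndarray:
    """Proton opposite the vector sum of bonds to the known heavy neighbors."""
    direction = np.zeros(3)
    for nb in neighbors:
        u = nb - center
        direction += u / np.linalg.norm(u)
    nrm = np.linalg.norm(direction)
    if nrm < 1e-8:
        raise ValueError("degenerate neighbor geometry for proton placement")
    return center - bond * direction / nrm


def _build_purine(atoms: dict[str, np.ndarray], base: str) -> None:
    """Attach a planar purine (A/G) to C1' via N9; chi = O4'-C1'-N9-C4."""
    o4, c1 = atoms["O4'"], atoms["C1'"]
    c2s = atoms["C2'"]
    atoms["N9"] = nerf_place(c2s, o4, c1, 1.475, 108.0, 121.0)
    n9 = atoms["N9"]
    atoms["C4"] = nerf_place(o4, c1, n9, 1.37, 126.0, CHI_ANTI)
    c4 = atoms["C4"]
    # six-membered ring, planar (all ring torsions 0/180)
    atoms["N3"] = nerf_place(c1, n9, c4, 1.35, 127.0, 0.0)
    atoms["C2"] = nerf_place(n9, c4, atoms["N3"], 1.33, 112.0, 180.0)
    atoms["N1"] = nerf_place(c4, atoms["N3"], atoms["C2"], 1.34, 128.0, 0.0)
    atoms["C6"] = nerf_place(atoms["N3"], atoms["C2"], atoms["N1"], 1.39, 118.0, 0.0)
    atoms["C5"] = nerf_place(atoms["C2"], atoms["N1"], atoms["C6"], 1.41, 117.0, 0.0)
    # five-membered ring closure
    atoms["N7"] = nerf_place(atoms["N1"], atoms["C6"], atoms["C5"], 1.39, 132.0, 180.0)
    atoms["C8"] = nerf_place(atoms["C6"], atoms["C5"], atoms["N7"], 1.33, 104.5, 180.0)
    atoms["H8"] = _tetrahedral_h(atoms["C8"], [atoms["N7"], n9])
    if base == "A":
        atoms["N6"] = nerf_place(atoms["C2"], atoms["N1"], atoms["C6"], 1.34, 120.0, 180.0)
        atoms["H2"] = _tetrahedral_h(atoms["C2"], [atoms["N1"], atoms["N3"]])
    else:  # G
        atoms["O6"] = nerf_place(atoms["C2"], atoms["N1"], atoms["C6"], 1.23, 120.0, 180.0)
        atoms["N2"] = nerf_place(c4, atoms["N3"], atoms["C2"], 1.34, 120.0, 180.0)
        atoms["H1"] = _tetrahedral_h(atoms["N1"], [atoms["C2"], atoms["C6"]], NH_BOND)


def _build_pyrimidine(atoms: dict[str, np.ndarray], base: str) -> None:
    """Attach a planar pyrimidine (C/U) to C1' via N1; chi = O4'-C1'-N1-C2."""
    o4, c1 = atoms["O4'"], atoms["C1'"]
    c2s = atoms["C2'"]
    atoms["N1"] = nerf_place(c2s, o4, c1, 1.475, 108.0, 121.0)
    n1 = atoms["N1"]
    atoms["C2"] = nerf_place(o4, c1, n1, 1.38, 118.0, CHI_ANTI)
    atoms["O2"] = nerf_place(c1, n1, atoms["C2"], 1.22, 119.0, 0.0)
    atoms["N3"] = nerf_place(c1, n1, atoms["C2"], 1.37, 119.0, 180.0)
    atoms["C4"] = nerf_place(n1, atoms["C2"], atoms["N3"], 1.38, 125.5, 0.0)
    atoms["C5"] = nerf_place(atoms["C2"], atoms["N3"], atoms["C4"], 1.44, 116.0, 0.0)
    atoms["C6"] = nerf_place(atoms["N3"], atoms["C4"], atoms["C5"], 1.34, 121.0, 0.0)
    atoms["H6"] = _tetrahedral_h(atoms["C6"], [atoms["C5"], n1])
    atoms["H5"] = _tetrahedral_h(atoms["C5"], [atoms["C4"], atoms["C6"]])
    if base == "C":
        atoms["N4"] = nerf_place(atoms["C2"], atoms["N3"], atoms["C4"], 1.34, 118.0, 180.0)
    else:  # U
        atoms["O4"] = nerf_place(atoms["C2"], atoms["N3"], atoms["C4"], 1.23, 120.0, 180.0)
        atoms["H3"] = _tetrahedral_h(atoms["N3"], [atoms["C2"], atoms["C4"]], NH_BOND)


def build_nucleotide(base: str, pucker_p: float = 18.0) -> dict[str, np.ndarray]:
    """Free-standing nucleotide with ribose at pseudorotation phase ``pucker_p``.

    Returns a dict atom-name -> 3-vector in a local frame.  Includes the
    full heavy-atom complement of a 5'-phosphorylated residue plus the
    protons used as dipolar bond-vector partners.
    """
    base = base.upper()
    if base not in PURINES | PYRIMIDINES:
        raise ValueError(f"unsupported base {base!r}")
    phase = _phase_for_pucker(pucker_p % 360.0)
    atoms = dict(_ring_coords(phase))
    o4, c1, c2, c3, c4 = (atoms[a] for a in RING_ATOMS)

    # exocyclic sugar substituents
    atoms["C5'"] = nerf_place(c2, c3, c4, 1.51, 115.5, 118.0)
    atoms["O3'"] = nerf_place(atoms["C5'"], c4, c3, 1.42, 110.5, DELTA_TARGET)
    atoms["O2'"] = nerf_place(c4, c3, c2, 1.41, 110.0, 122.0)
    atoms["O5'"] = nerf_place(c3, c4, atoms["C5'"], 1.44, 109.5, GAMMA)
    atoms["P"] = nerf_place(c4, atoms["C5'"], atoms["O5'"], 1.59, 120.5, BETA)
    atoms["OP1"] = nerf_place(atoms["C5'"], atoms["O5'"], atoms["P"], 1.48, 108.0, -60.0)
    atoms["OP2"] = nerf_place(atoms["C5'"], atoms["O5'"], atoms["P"], 1.48, 108.0, 60.0)

    if base in PURINES:
        _build_purine(atoms, base)
    else:
        _build_pyrimidine(atoms, base)

    glyc = atoms["N9"] if base in PURINES else atoms["N1"]
    atoms["H1'"] = _tetrahedral_h(c1, [o4, c2, glyc])
    atoms["H2'"] = _tetrahedral_h(c2, [c1, c3, atoms["O2'"]])
    atoms["H3'"] = _tetrahedral_h(c3, [c2, c4, atoms["O3'"]])
    atoms["H4'"] = _tetrahedral_h(c4, [c3, o4, atoms["C5'"]])
    return atoms


def glycosidic_atom(base: str) -> str:
    return "N9" if base.upper() in PURINES else "N1"


def base_ring_atoms(base: str) -> tuple[str, ...]:
    if base.upper() in PURINES:
        return ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
    return ("N1", "C2", "N3", "C4", "C5", "C6")
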