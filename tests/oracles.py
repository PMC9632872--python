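"""Independent reference implementations used only by the tests.

Each oracle deliberately takes a different mathematical route from the code
it checks: torsions via the cross-product-of-normals formulation, optimal
superposition via the Horn quaternion eigenvalue method, peptide masses via
elemental composition arithmetic, and pairing counts by brute-force set
partitioning.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# monoisotopic element masses (u)
EL = {"C": 12.0, "H": 1.00782503207, "N": 14.0030740048,
      "O": 15.9949146196, "S": 31.97207100}

# residue elemental compositions (as residues, i.e. minus one water)
RESIDUE_FORMULA = {
    "G": "C2H3NO", "A": "C3H5NO", "S": "C3H5NO2", "P": "C5H7NO",
    "V": "C5H9NO", "T": "C4H7NO2", "C": "C3H5NOS", "L": "C6H11NO",
    "I": "C6H11NO", "N": "C4H6N2O2", "D": "C4H5NO3", "Q": "C5H8N2O2",
    "K": "C6H12N2O", "E": "C5H7NO3", "M": "C5H9NOS", "H": "C6H7N3O",
    "F": "C9H9NO", "R": "C6H12N4O", "Y": "C9H9NO2", "W": "C11H10N2O",
}


def formula_mass(formula: str) -> float:
    total = 0.0
    import re

    for el, count in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if el:
            total += EL[el] * (int(count) if count else 1)
    return total


def peptide_mass(seq: str) -> float:
    """Monoisotopic peptide mass from elemental compositions + one water."""
    return sum(formula_mass(RESIDUE_FORMULA[c]) for c in seq) + formula_mass("H2O")


def torsion_normals(p1, p2, p3, p4) -> float:
    """Signed torsion (deg) via the atan2-of-plane-normals formulation."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2u = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2u))
    return math.degrees(math.atan2(y, x))


def horn_superpose_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Optimal-superposition RMSD via Horn's quaternion eigenvalue method."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    m = b0.T @ a0  # correlation of mobile against target
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    e2 = np.sum(a0**2) + np.sum(b0**2) - 2.0 * lam
    return math.sqrt(max(e2, 0.0) / len(a))


def count_perfect_matchings(n: int) -> int:
    """Brute-force count of perfect matchings on n labelled points."""
    if n % 2:
        return 0
    items = tuple(range(n))
    seen = set()

    def rec(rest, acc):
        if not rest:
            seen.add(frozenset(acc))
            return
        first = rest[0]
        for other in rest[1:]:
            remaining = tuple(x for x in rest if x not in (first, other))
            rec(remaining, acc + [frozenset((first, other))])

    rec(items, [])
    return len(seen)


def katz_chi3_term_min(step: float = 0.1) -> float:
    """1-D grid minimum of the χ3 terms 14.64(1+cos2χ)+2.51(1+cos3χ).

    The four χ1/χ2 terms vanish independently at staggered angles, so the
    global minimum of the full series equals this 1-D minimum.
    """
    x = np.radians(np.arange(-180.0, 180.0, step))
    f = 14.64 * (1 + np.cos(2 * x)) + 2.51 * (1 + np.cos(3 * x))
    return float(f.min())
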