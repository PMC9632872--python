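"""Backbone model validation: Ramachandran classification and superposition.

Two standard checks for a refined peptide model:

* φ/ψ torsions per residue, classified on a Procheck-style region grid
  (10°×10° cells; classes core / additional / generous / disallowed, with the
  summary computed over non-Gly, non-Pro, non-terminal residues as Procheck
  does).  The region masks are built programmatically from polygonal
  approximations of the Morris et al. data-derived map; "generous" is the
  allowed envelope dilated by 20°.
* Least-squares rigid superposition (Kabsch, SVD with reflection correction)
  and segment-mapped backbone RMSD, pairing residues positionally across
  stated ranges — the convention used when two homologous helix-hairpin
  models are compared over explicit residue windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .disulfide import dihedral, GeometryError
from .structure_io import Atom, Residue, StructureEnsemble

__all__ = [
    "PhiPsi",
    "RamaSummary",
    "SuperpositionResult",
    "phi_psi",
    "classify_rama",
    "rama_summary",
    "kabsch_superpose",
    "segment_rmsd",
    "transform_ensemble",
]


@dataclass
class PhiPsi:
    residue: tuple[str, int, str]  # (chain, seq_id, res_name)
    phi: float | None
    psi: float | None


@dataclass
class RamaSummary:
    n_counted: int
    counts: dict[str, int]
    pct_core: float
    pct_additional: float
    pct_generous: float
    pct_disallowed: float


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # 3-vector
    rmsd: float
    n_atoms: int
    mapping: list[tuple[tuple, tuple]] | None = None


# ---------------------------------------------------------------------------
# Ramachandran region grid (10° x 10°, phi major).  Cell [i, j] covers
# phi in [-180 + 10i, -170 + 10i), psi in [-180 + 10j, -170 + 10j).
# Regions are axis-aligned polygon pieces approximating the Procheck map.
# ---------------------------------------------------------------------------

_CELL = 10
_N = 360 // _CELL

# (phi_lo, phi_hi, psi_lo, psi_hi) half-open boxes, degrees
_CORE_BOXES = [
    (-160, -40, -70, -10),    # A: right-handed alpha
    (-180, -45, 90, 180),     # B: beta
    (-180, -100, -180, -170),  # B wraps across psi = ±180
    (40, 70, 10, 60),         # L: left-handed alpha (tight)
]
_ALLOWED_BOXES = _CORE_BOXES + [
    (-180, -20, -110, 30),    # a: around/below alpha
    (-180, -45, 30, 90),      # bridge between alpha and beta
    (-180, -20, 60, 180),     # b: around beta
    (-180, -90, -180, -150),  # b wrap
    (20, 90, -20, 90),        # l: around left-handed alpha
    (40, 100, 150, 180),      # p/epsilon
    (40, 100, -180, -150),    # p wrap
]


def _paint(boxes) -> np.ndarray:
    mask = np.zeros((_N, _N), dtype=bool)
    for plo, phi_, slo, shi in boxes:
        i0 = (plo + 180) // _CELL
        i1 = (phi_ + 180) // _CELL
        j0 = (slo + 180) // _CELL
        j1 = (shi + 180) // _CELL
        mask[i0:i1, j0:j1] = True
    return mask


def _dilate_wrap(mask: np.ndarray, cells: int) -> np.ndarray:
    out = mask.copy()
    for _ in range(cells):
        grown = out.copy()
        grown |= np.roll(out, 1, axis=0) | np.roll(out, -1, axis=0)
        grown |= np.roll(out, 1, axis=1) | np.roll(out, -1, axis=1)
        out = grown
    return out


_CORE_MASK = _paint(_CORE_BOXES)
_ALLOWED_MASK = _paint(_ALLOWED_BOXES) | _CORE_MASK
_GENEROUS_MASK = _dilate_wrap(_ALLOWED_MASK, 2)  # 20° in each direction


def classify_rama(phi: float, psi: float) -> str:
    """Region class of a (φ, ψ) pair: core, additional, generous or disallowed."""
    # map each angle into [-180, 180) and then onto its 10° cell index
    i = int(((phi + 180.0) % 360.0) // _CELL)
    j = int(((psi + 180.0) % 360.0) // _CELL)
    if _CORE_MASK[i, j]:
        return "core"
    if _ALLOWED_MASK[i, j]:
        return "additional"
    if _GENEROUS_MASK[i, j]:
        return "generous"
    return "disallowed"


def phi_psi(ensemble: StructureEnsemble, model_index: int, chain: str) -> list[PhiPsi]:
    """Backbone φ/ψ per residue; termini carry None on their missing side."""
    residues = ensemble.residues(model_index, chain)
    out: list[PhiPsi] = []
    for k, res in enumerate(residues):
        phi = psi = None
        try:
            n, ca, c = (res.atoms[x].pos for x in ("N", "CA", "C"))
        except KeyError:
            warnings.warn(
                f"residue {chain}:{res.seq_id} lacks backbone atoms; φ/ψ undefined",
                stacklevel=2,
            )
            out.append(PhiPsi((chain, res.seq_id, res.res_name), None, None))
            continue
        if k > 0 and "C" in residues[k - 1].atoms:
            phi = dihedral(residues[k - 1].atoms["C"].pos, n, ca, c)
        if k < len(residues) - 1 and "N" in residues[k + 1].atoms:
            psi = dihedral(n, ca, c, residues[k + 1].atoms["N"].pos)
        out.append(PhiPsi((chain, res.seq_id, res.res_name), phi, psi))
    return out


def rama_summary(ensemble: StructureEnsemble, model_index: int = 0) -> RamaSummary:
    """Procheck-convention region percentages over one model.

    Glycine, proline and chain-terminal residues are excluded from the counts;
    percentages are reported to one decimal.
    """
    counts = {"core": 0, "additional": 0, "generous": 0, "disallowed": 0}
    n = 0
    for chain in ensemble.chains(model_index):
        angles = phi_psi(ensemble, model_index, chain)
        for k, pp in enumerate(angles):
            res_name = pp.residue[2]
            if res_name in ("GLY", "PRO"):
                continue
            if k == 0 or k == len(angles) - 1:
                continue
            if pp.phi is None or pp.psi is None:
                continue
            counts[classify_rama(pp.phi, pp.psi)] += 1
            n += 1
    if n == 0:
        raise ValueError("no countable residues (all Gly/Pro/terminal/undefined)")
    pct = {k: round(100.0 * v / n, 1) for k, v in counts.items()}
    return RamaSummary(
        n_counted=n,
        counts=counts,
        pct_core=pct["core"],
        pct_additional=pct["additional"],
        pct_generous=pct["generous"],
        pct_disallowed=pct["disallowed"],
    )


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(points_a, points_b) -> SuperpositionResult:
    """Optimal proper rotation + translation taking ``points_b`` onto ``points_a``.

    SVD-based least squares with reflection correction; RMSD is over the
    transformed pairs.
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point sets must be equal-length (n, 3) arrays")
    if len(a) < 3:
        raise ValueError("need at least 3 paired points")
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    a0 = a - ca
    b0 = b - cb
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ca - rot @ cb
    moved = (rot @ b0.T).T
    rmsd = float(np.sqrt(np.mean(np.sum((a0 - moved) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd, n_atoms=len(a))


def _range_coords(
    ensemble: StructureEnsemble,
    model_index: int,
    chain: str,
    ranges: list[tuple[int, int]],
    atom_names,
):
    coords, keys = [], []
    for start, end in ranges:
        for seq_id in range(start, end + 1):
            res = ensemble.residue(model_index, chain, seq_id)
            for name in atom_names:
                if name not in res.atoms:
                    raise GeometryError(
                        f"backbone atom {name} missing in {chain}:{seq_id}"
                    )
                coords.append(res.atoms[name].pos)
                keys.append((chain, seq_id, name))
    return np.array(coords), keys


def segment_rmsd(
    ensemble_a: StructureEnsemble,
    ranges_a: list[tuple[int, int]],
    ensemble_b: StructureEnsemble,
    ranges_b: list[tuple[int, int]],
    atom_names=("N", "CA", "C", "O"),
    chain_a: str | None = None,
    chain_b: str | None = None,
    model_a: int = 0,
    model_b: int = 0,
) -> SuperpositionResult:
    """Joint backbone superposition over residue-range segments.

    Segments pair off positionally (first range with first range, residue by
    residue); the superposition is computed once over all mapped atoms and the
    single global RMSD is returned.
    """
    chain_a = chain_a or ensemble_a.chains(model_a)[0]
    chain_b = chain_b or ensemble_b.chains(model_b)[0]
    len_a = sum(e - s + 1 for s, e in ranges_a)
    len_b = sum(e - s + 1 for s, e in ranges_b)
    if len(ranges_a) != len(ranges_b) or len_a != len_b or any(
        (ea - sa) != (eb - sb)
        for (sa, ea), (sb, eb) in zip(ranges_a, ranges_b)
    ):
        raise ValueError(
            f"segment mapping mismatch: ranges {ranges_a} vs {ranges_b} "
            "must pair off residue-by-residue with equal lengths"
        )
    pts_a, keys_a = _range_coords(ensemble_a, model_a, chain_a, ranges_a, atom_names)
    pts_b, keys_b = _range_coords(ensemble_b, model_b, chain_b, ranges_b, atom_names)
    result = kabsch_superpose(pts_a, pts_b)
    result.mapping = list(zip(keys_a, keys_b))
    return result


def transform_ensemble(ensemble: StructureEnsemble, result: SuperpositionResult) -> StructureEnsemble:
    """Apply a superposition transform to every atom (returns a new ensemble)."""
    models = []
    for model in ensemble.models:
        new_model = {}
        for chain, residues in model.items():
            new_residues = []
            for res in residues:
                atoms = {
                    name: Atom(
                        name=a.name,
                        element=a.element,
                        pos=result.rotation @ a.pos + result.translation,
                        occupancy=a.occupancy,
                        altloc=a.altloc,
                    )
                    for name, a in res.atoms.items()
                }
                new_residues.append(
                    Residue(res.chain_id, res.seq_id, res.res_name, atoms, res.icode)
                )
            new_model[chain] = new_residues
        models.append(new_model)
    return StructureEnsemble(models=models, source_id=ensemble.source_id + "_superposed")
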