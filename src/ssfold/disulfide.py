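"""Disulfide-bridge geometry and dihedral strain energetics.

A cystine bridge is described by five side-chain torsions: χ1 (N–CA–CB–SG)
and χ2 (CA–CB–SG–SG′) on each half-cystine, plus the central χ3
(CB–SG–SG′–CB′) about the S–S bond.  The strain estimate is the empirical
cosine series of Katz & Kossiakoff,

    E(kJ/mol) = 8.37(1+cos 3χ1) + 8.37(1+cos 3χ1′)
              + 4.18(1+cos 3χ2) + 4.18(1+cos 3χ2′)
              + 14.64(1+cos 2χ3) + 2.51(1+cos 3χ3),

which is bounded by [0, 84.50]; the two χ3 terms cannot vanish simultaneously,
so the attainable minimum sits near 2.04 kJ/mol at |χ3| ≈ 83°.  Ensemble
summaries (mean ± sample SD over the first models of an NMR deposition)
reproduce the per-deposition strain tables used to compare Saposin-fold
structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure_io import StructureEnsemble, SelectionError

__all__ = [
    "DisulfideBond",
    "EnsembleDisulfideStats",
    "GeometryError",
    "dihedral",
    "katz_energy",
    "KATZ_MAX_ENERGY",
    "find_disulfides",
    "disulfide_geometry",
    "ensemble_stats",
    "strain_table",
]

#: Upper bound of the Katz cosine series: 2 * (8.37+8.37+4.18+4.18+14.64+2.51)
KATZ_MAX_ENERGY = 84.50

CysKey = tuple[str, int]  # (chain, author seq_id)


class GeometryError(ValueError):
    """Degenerate or incomplete geometry for a torsion or bridge."""


@dataclass
class DisulfideBond:
    """One Cys–Cys bridge: five χ torsions (deg), S–S distance (Å), E (kJ/mol)."""

    cys_a: CysKey
    cys_b: CysKey
    chi1: float
    chi1p: float
    chi2: float
    chi2p: float
    chi3: float
    ss_distance: float
    energy: float


@dataclass
class EnsembleDisulfideStats:
    pair: tuple[CysKey, CysKey]
    n_models: int
    mean_distance: float
    sd_distance: float
    mean_energy: float
    sd_energy: float


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1–p2–p3–p4 in degrees, IUPAC convention, (−180, 180].

    Uses the projection formulation: b2 is the central bond; the angle is
    measured between b1 and b3 in the plane perpendicular to b2, with the sign
    given by the handedness about b2.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p1 - p2  # points back toward p1 so that eclipsed (cis) reads 0°
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(b1) < 1e-10 or nb2 < 1e-10 or np.linalg.norm(b3) < 1e-10:
        raise GeometryError("coincident consecutive points in torsion")
    b2u = b2 / nb2
    # components of b1, b3 perpendicular to the central bond
    v = b1 - np.dot(b1, b2u) * b2u
    w = b3 - np.dot(b3, b2u) * b2u
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        raise GeometryError("collinear consecutive points in torsion")
    x = np.dot(v, w)
    y = np.dot(np.cross(b2u, v), w)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def katz_energy(chi1: float, chi1p: float, chi2: float, chi2p: float, chi3: float) -> float:
    """Katz–Kossiakoff dihedral strain energy (kJ/mol) of a cystine bridge."""
    c = np.cos
    r = np.radians
    e = (
        8.37 * (1 + c(3 * r(chi1)))
        + 8.37 * (1 + c(3 * r(chi1p)))
        + 4.18 * (1 + c(3 * r(chi2)))
        + 4.18 * (1 + c(3 * r(chi2p)))
        + 14.64 * (1 + c(2 * r(chi3)))
        + 2.51 * (1 + c(3 * r(chi3)))
    )
    return float(e)


def _sg_atoms(ensemble: StructureEnsemble, model_index: int) -> list[tuple[CysKey, np.ndarray]]:
    out = []
    model = ensemble.models[model_index]
    for chain, residues in model.items():
        for res in residues:
            if res.res_name != "CYS":
                continue
            if "SG" not in res.atoms:
                import warnings

                warnings.warn(
                    f"CYS {chain}:{res.seq_id} lacks an SG atom; skipped",
                    stacklevel=2,
                )
                continue
            out.append(((chain, res.seq_id), res.atoms["SG"].pos))
    return out


def find_disulfides(
    ensemble: StructureEnsemble, model_index: int = 0, cutoff: float = 2.3
) -> list[tuple[CysKey, CysKey]]:
    """All SG–SG pairs within ``cutoff`` Å, each SG used once (greedy by distance)."""
    sgs = _sg_atoms(ensemble, model_index)
    candidates = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = float(np.linalg.norm(sgs[i][1] - sgs[j][1]))
            if d <= cutoff:
                candidates.append((d, sgs[i][0], sgs[j][0]))
    candidates.sort(key=lambda t: t[0])
    used: set[CysKey] = set()
    pairs: list[tuple[CysKey, CysKey]] = []
    for _, a, b in candidates:
        if a in used or b in used:
            continue
        used.update((a, b))
        pairs.append((a, b))
    return pairs


def disulfide_geometry(
    ensemble: StructureEnsemble, model_index: int, pair: tuple[CysKey, CysKey]
) -> DisulfideBond:
    """Measure the five χ torsions, S–S distance, and strain energy of a bridge."""
    (chain_a, seq_a), (chain_b, seq_b) = pair
    res_a = ensemble.residue(model_index, chain_a, seq_a)
    res_b = ensemble.residue(model_index, chain_b, seq_b)
    coords = {}
    for tag, res in (("a", res_a), ("b", res_b)):
        for name in ("N", "CA", "CB", "SG"):
            if name not in res.atoms:
                raise GeometryError(
                    f"atom {name} missing in CYS {res.chain_id}:{res.seq_id}"
                )
            coords[f"{name}_{tag}"] = res.atoms[name].pos
    chi1 = dihedral(coords["N_a"], coords["CA_a"], coords["CB_a"], coords["SG_a"])
    chi1p = dihedral(coords["N_b"], coords["CA_b"], coords["CB_b"], coords["SG_b"])
    chi2 = dihedral(coords["CA_a"], coords["CB_a"], coords["SG_a"], coords["SG_b"])
    chi2p = dihedral(coords["CA_b"], coords["CB_b"], coords["SG_b"], coords["SG_a"])
    chi3 = dihedral(coords["CB_a"], coords["SG_a"], coords["SG_b"], coords["CB_b"])
    ss = float(np.linalg.norm(coords["SG_a"] - coords["SG_b"]))
    return DisulfideBond(
        cys_a=(chain_a, seq_a),
        cys_b=(chain_b, seq_b),
        chi1=chi1,
        chi1p=chi1p,
        chi2=chi2,
        chi2p=chi2p,
        chi3=chi3,
        ss_distance=ss,
        energy=katz_energy(chi1, chi1p, chi2, chi2p, chi3),
    )


def ensemble_stats(
    ensemble: StructureEnsemble,
    pair: tuple[CysKey, CysKey],
    n_lowest: int = 10,
) -> EnsembleDisulfideStats:
    """Mean ± sample SD of distance and energy over the first ``n_lowest`` models.

    NMR depositions conventionally deposit conformers best-first, so the first
    models stand in for the lowest-energy set.  SD is the n−1 sample standard
    deviation and 0 for a single model.
    """
    n = min(n_lowest, ensemble.n_models)
    dists, energies = [], []
    for m in range(n):
        try:
            bond = disulfide_geometry(ensemble, m, pair)
        except (SelectionError, GeometryError) as exc:
            raise GeometryError(f"pair unresolvable in model {m + 1}: {exc}") from exc
        dists.append(bond.ss_distance)
        energies.append(bond.energy)
    dists = np.asarray(dists)
    energies = np.asarray(energies)

    def _sample_sd(values: np.ndarray) -> float:
        # exactly 0 for degenerate (all-identical) ensembles
        if n == 1 or values.max() == values.min():
            return 0.0
        return float(np.std(values, ddof=1))

    sd_d = _sample_sd(dists)
    sd_e = _sample_sd(energies)
    return EnsembleDisulfideStats(
        pair=pair,
        n_models=n,
        mean_distance=float(dists.mean()),
        sd_distance=sd_d,
        mean_energy=float(energies.mean()),
        sd_energy=sd_e,
    )


def strain_table(
    inputs: list[tuple[StructureEnsemble, list[tuple[CysKey, CysKey]]]],
    n_lowest: int = 10,
) -> pd.DataFrame:
    """One row per (structure, bridge): distance ± SD and strain energy ± SD.

    Columns mirror the per-deposition comparison table: structure id, implied
    method tag (ensemble vs single model), residue pair label, and the two
    measured quantities with their ensemble spreads (empty for single-model
    files).
    """
    rows = []
    for ensemble, pairs in inputs:
        method = "ensemble" if ensemble.n_models > 1 else "single"
        for pair in pairs:
            stats = ensemble_stats(ensemble, pair, n_lowest=n_lowest)
            (ca, sa), (cb, sb) = pair
            label = f"Cys-{sa} Cys-{sb}"
            if stats.n_models > 1:
                dist = f"{stats.mean_distance:.3f} ± {stats.sd_distance:.4f}"
                energy = f"{stats.mean_energy:.6f} ± {stats.sd_energy:.6f}"
            else:
                dist = f"{stats.mean_distance:.2f}"
                energy = f"{stats.mean_energy:.6f}"
            rows.append(
                {
                    "structure": ensemble.source_id,
                    "method": method,
                    "pair": label,
                    "n_models": stats.n_models,
                    "ss_distance_A": dist,
                    "strain_energy_kJ_mol": energy,
                    "mean_distance": stats.mean_distance,
                    "sd_distance": stats.sd_distance,
                    "mean_energy": stats.mean_energy,
                    "sd_energy": stats.sd_energy,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "structure", "method", "pair", "n_models",
            "ss_distance_A", "strain_energy_kJ_mol",
            "mean_distance", "sd_distance", "mean_energy", "sd_energy",
        ],
    )
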