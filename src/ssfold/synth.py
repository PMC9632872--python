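"""Seeded synthetic-data generators for every pipeline input.

All builders are pure functions of their spec and seed: identical inputs give
bit-identical outputs.  Geometry is produced by a single internal-coordinate
(Z-matrix / NeRF) primitive, which guarantees that specified torsions are
realized exactly — the fixture-inversion identities (build then measure) are
the backbone of the test suite.

Nothing here imitates real experimental noise structure beyond simple
Gaussian/uniform perturbations; the generators exist to give the analysis
code inputs with exactly known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import Atom, Residue, StructureEnsemble
from .spectro import Spectrum
from .massspec import (
    ConnectivityHypothesis,
    PeptideSequence,
    pepsin_digest,
    theoretical_species,
)

__all__ = [
    "HelixSpec",
    "DisulfideFixtureSpec",
    "SMB_SEQUENCE",
    "place_atom",
    "build_ideal_helix",
    "build_chain_from_torsions",
    "build_hairpin",
    "build_disulfide_fixture",
    "gaussian_spectrum",
    "synth_digest_observations",
]

#: 41-residue Super Mini-B construct: N-terminal insertion sequence,
#: N-terminal helix, bend, C-terminal helix; cysteines at 8, 11, 34, 40.
SMB_SEQUENCE = "FPIPLPYCWLCRALIKRIQAMIPKGGRMLPQLVCRLVLRCS"

# standard backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O, _A_N_CA_CB = 111.2, 116.2, 121.7, 120.8, 110.5


@dataclass
class HelixSpec:
    """An ideal α-helix: rise/twist for the Cα spiral, φ/ψ for full backbone."""

    n_res: int = 12
    rise: float = 1.5
    twist: float = 100.0
    phi: float = -57.0
    psi: float = -47.0
    radius: float = 2.3
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.n_res < 4:
            raise ValueError("a helix needs at least 4 residues")
        if self.rise <= 0 or not (0 < self.twist < 180):
            raise ValueError("rise must be positive and twist in (0, 180)")


@dataclass
class DisulfideFixtureSpec:
    """Two cystines built to realize the five χ torsions exactly."""

    chi1: float = -60.0
    chi1p: float = -60.0
    chi2: float = 80.0
    chi2p: float = 80.0
    chi3: float = 95.0
    ss_len: float = 2.05
    cb_sg_len: float = 1.81
    ang_ca_cb_sg: float = 114.0
    ang_cb_sg_sg: float = 104.0

    def __post_init__(self) -> None:
        if self.ss_len <= 0 or self.cb_sg_len <= 0:
            raise ValueError("bond lengths must be positive")
        if not (0 < self.ang_ca_cb_sg < 180 and 0 < self.ang_cb_sg_sg < 180):
            raise ValueError("bond angles must lie in (0, 180)")


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position D with |CD| = bond, ∠BCD = angle, ∠ABCD = torsion."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _make_residue(chain: str, seq_id: int, res_name: str, atoms: dict[str, np.ndarray]) -> Residue:
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "SG": "S"}
    return Residue(
        chain_id=chain,
        seq_id=seq_id,
        res_name=res_name,
        atoms={
            name: Atom(name=name, element=elements.get(name, name[0]), pos=pos)
            for name, pos in atoms.items()
        },
    )


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rodrigues rotation taking unit vector u onto unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # pick any axis perpendicular to u
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return -np.eye(3) + 2 * np.outer(perp, perp)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    axis = axis / s
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * k + (1 - c) * (k @ k)


def _names_for(spec_seq: str | None, n: int) -> list[str]:
    if spec_seq is None:
        return ["ALA"] * n
    if len(spec_seq) != n:
        raise ValueError("sequence length does not match n_res")
    return [_ONE_TO_THREE[c] for c in spec_seq]


def build_ideal_helix(
    spec: HelixSpec, full_backbone: bool = False, chain: str = "A", start_seq: int = 1
) -> StructureEnsemble:
    """One-model ensemble of an ideal helix.

    Cα-only mode places Cα atoms on a spiral of the stated rise, twist and
    radius; full-backbone mode chains standard bond geometry at the stated
    φ/ψ (ω = 180°), then orients the result so its measured global axis lies
    along ``spec.axis`` with the first Cα at ``spec.origin``.
    """
    names = _names_for(spec.sequence, spec.n_res)
    if full_backbone:
        ens = build_chain_from_torsions(
            [spec.phi] * spec.n_res, [spec.psi] * spec.n_res,
            sequence=spec.sequence, chain=chain, start_seq=start_seq,
        )
        coords = np.array(
            [r.atoms["CA"].pos for r in ens.residues(0, chain)]
        )
    else:
        i = np.arange(spec.n_res)
        theta = np.radians(spec.twist) * i
        coords = np.column_stack(
            [spec.radius * np.cos(theta), spec.radius * np.sin(theta), spec.rise * i]
        )
        ens = StructureEnsemble(
            models=[{
                chain: [
                    _make_residue(chain, start_seq + k, names[k], {"CA": coords[k]})
                    for k in range(spec.n_res)
                ]
            }],
            source_id="ideal_helix",
        )

    # orient: measured axis -> requested axis, first CA -> origin
    from .helix import local_axes, global_axis  # local import avoids a cycle

    current = global_axis(local_axes(coords))
    rot = _rotation_between(current, np.asarray(spec.axis, dtype=float))
    first_ca = coords[0]
    origin = np.asarray(spec.origin, dtype=float)
    for res in ens.residues(0, chain):
        for atom in res.atoms.values():
            atom.pos = rot @ (atom.pos - first_ca) + origin
    return ens


def build_chain_from_torsions(
    phi: list[float],
    psi: list[float],
    omega: float = 180.0,
    sequence: str | None = None,
    chain: str = "A",
    start_seq: int = 1,
) -> StructureEnsemble:
    """Full-backbone chain (N, CA, C, O) realizing per-residue φ/ψ exactly.

    φ of the first residue and ψ of the last are unconstrained by construction
    (they have no flanking peptide bond) and are ignored.
    """
    n = len(phi)
    if n != len(psi) or n < 1:
        raise ValueError("phi and psi lists must be equal-length and nonempty")
    names = _names_for(sequence, n)

    bb: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    bb.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n):
        prev = bb[-1]
        ni = place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi[i - 1])
        cai = place_atom(prev["CA"], prev["C"], ni, _B_N_CA, _A_C_N_CA, omega)
        ci = place_atom(prev["C"], ni, cai, _B_CA_C, _A_N_CA_C, phi[i])
        bb.append({"N": ni, "CA": cai, "C": ci})
    # carbonyl oxygens: anti to the next amide nitrogen (torsion ψ+180)
    for i, atoms in enumerate(bb):
        psi_i = psi[i] if i < n - 1 else -47.0
        atoms["O"] = place_atom(
            atoms["N"], atoms["CA"], atoms["C"], _B_C_O, _A_CA_C_O, psi_i + 180.0
        )

    residues = [
        _make_residue(chain, start_seq + i, names[i], bb[i]) for i in range(n)
    ]
    return StructureEnsemble(models=[{chain: residues}], source_id="torsion_chain")


def build_hairpin(
    spec_a: HelixSpec,
    spec_b: HelixSpec,
    angle: float,
    linker_res: int = 4,
    seed: int = 0,
) -> StructureEnsemble:
    """Two Cα helices at a set undirected axis angle, joined by a coil linker.

    Helix A runs along +z; helix B runs antiparallel (as in a helix hairpin),
    tilted so the undirected angle between the two global axes equals
    ``angle``.  Linker Cα positions interpolate between the helix ends with
    seeded jitter.
    """
    if not (0 <= angle <= 90):
        raise ValueError("angle must lie in [0, 90] degrees")
    rng = np.random.default_rng(seed)
    chain = "A"
    ens_a = build_ideal_helix(
        HelixSpec(n_res=spec_a.n_res, rise=spec_a.rise, twist=spec_a.twist,
                  radius=spec_a.radius, axis=(0, 0, 1), origin=(0, 0, 0),
                  sequence=spec_a.sequence),
        chain=chain, start_seq=1,
    )
    # antiparallel: B's axis near -z, tilted by the requested angle
    tilt = np.radians(angle)
    axis_b = np.array([np.sin(tilt), 0.0, -np.cos(tilt)])
    res_a = ens_a.residues(0, chain)
    end_a = res_a[-1].atoms["CA"].pos
    origin_b = end_a + np.array([8.0, 0.0, 2.0])  # offset to B's first residue
    ens_b = build_ideal_helix(
        HelixSpec(n_res=spec_b.n_res, rise=spec_b.rise, twist=spec_b.twist,
                  radius=spec_b.radius, axis=tuple(axis_b), origin=tuple(origin_b),
                  sequence=spec_b.sequence),
        chain=chain, start_seq=spec_a.n_res + linker_res + 1,
    )
    res_b = ens_b.residues(0, chain)
    start_b = res_b[0].atoms["CA"].pos

    linker = []
    for k in range(linker_res):
        t = (k + 1) / (linker_res + 1)
        pos = (1 - t) * end_a + t * start_b + rng.normal(0, 0.3, 3)
        linker.append(
            _make_residue(chain, spec_a.n_res + k + 1, "GLY", {"CA": pos})
        )
    residues = res_a + linker + res_b
    return StructureEnsemble(models=[{chain: residues}], source_id="hairpin")


def build_disulfide_fixture(spec: DisulfideFixtureSpec, chain: str = "A") -> StructureEnsemble:
    """Two CYS residues realizing the five χ torsions of one bridge exactly.

    Atoms are chained N_a–CA_a–CB_a–SG_a–SG_b–CB_b–CA_b–N_b by internal
    coordinates, so measuring the bridge recovers every specified torsion to
    numerical precision and the S–S distance equals ``ss_len``.
    """
    n_a = np.array([0.0, 0.0, 0.0])
    ca_a = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(_A_N_CA_CB)
    cb_a = ca_a + _B_CA_CB * np.array([-np.cos(ang), np.sin(ang), 0.0])
    sg_a = place_atom(n_a, ca_a, cb_a, spec.cb_sg_len, spec.ang_ca_cb_sg, spec.chi1)
    sg_b = place_atom(ca_a, cb_a, sg_a, spec.ss_len, spec.ang_cb_sg_sg, spec.chi2)
    cb_b = place_atom(cb_a, sg_a, sg_b, spec.cb_sg_len, spec.ang_cb_sg_sg, spec.chi3)
    # reversal invariance of torsions lets χ2′/χ1′ be applied directly
    ca_b = place_atom(sg_a, sg_b, cb_b, _B_CA_CB, spec.ang_ca_cb_sg, spec.chi2p)
    n_b = place_atom(sg_b, cb_b, ca_b, _B_N_CA, _A_N_CA_CB, spec.chi1p)
    res1 = _make_residue(chain, 1, "CYS", {"N": n_a, "CA": ca_a, "CB": cb_a, "SG": sg_a})
    res2 = _make_residue(chain, 2, "CYS", {"N": n_b, "CA": ca_b, "CB": cb_b, "SG": sg_b})
    return StructureEnsemble(models=[{chain: [res1, res2]}], source_id="ss_fixture")


def gaussian_spectrum(
    centers,
    widths,
    amps,
    x_range: tuple[float, float] = (1580.0, 1720.0),
    step: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    kind: str = "ftir",
) -> Spectrum:
    """Sum of Gaussian bands plus seeded Gaussian noise on a uniform grid."""
    centers = np.atleast_1d(np.asarray(centers, dtype=float))
    widths = np.atleast_1d(np.asarray(widths, dtype=float))
    amps = np.atleast_1d(np.asarray(amps, dtype=float))
    if not (len(centers) == len(widths) == len(amps)):
        raise ValueError("centers, widths and amps must be equal-length")
    if step <= 0:
        raise ValueError("step must be positive")
    x = np.arange(x_range[0], x_range[1] + step / 2, step)
    y = np.zeros_like(x)
    for c, w, a in zip(centers, widths, amps):
        y += a * np.exp(-0.5 * ((x - c) / w) ** 2)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, x.shape)
    return Spectrum(x, y, kind)


def synth_digest_observations(
    seq: str | PeptideSequence,
    hypothesis: ConnectivityHypothesis,
    ppm_jitter: float = 0.0,
    dropout_frac: float = 0.0,
    seed: int = 0,
    max_missed: int = 2,
) -> list[float]:
    """Observed-mass list for a digest under a known connectivity.

    Theoretical crosslinked-species masses, each perturbed by a seeded uniform
    relative jitter bounded by ``ppm_jitter``, with a seeded fraction dropped.
    """
    pep = seq if isinstance(seq, PeptideSequence) else PeptideSequence(seq)
    all_cys = {p for pair in hypothesis.pairs for p in pair}
    if all_cys - set(pep.cys_positions):
        raise ValueError("hypothesis names cysteines absent from the sequence")
    fragments = pepsin_digest(pep, max_missed=max_missed)
    species = theoretical_species(fragments, hypothesis)
    rng = np.random.default_rng(seed)
    masses = np.array([sp.mono_mass for sp in species])
    if ppm_jitter > 0:
        masses = masses * (1 + rng.uniform(-ppm_jitter, ppm_jitter, masses.size) * 1e-6)
    n_drop = int(dropout_frac * masses.size)
    if n_drop > 0:
        drop = rng.choice(masses.size, size=n_drop, replace=False)
        keep = np.setdiff1d(np.arange(masses.size), drop)
        masses = masses[keep]
    return [float(m) for m in masses]
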