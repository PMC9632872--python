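"""Reading, writing and selecting from multi-model PDB coordinate files.

The in-memory containers are deliberately small: an ordered list of models,
each a mapping ``chain id -> ordered residue list``.  They carry exactly what
the downstream geometry needs (author residue numbers, atom coordinates) and
nothing else.  Parsing is delegated to :mod:`gemmi`; writing produces plain
fixed-width ATOM/MODEL records so fixtures round-trip through any PDB reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureEnsemble",
    "PDBParseError",
    "EnsembleConsistencyError",
    "SelectionError",
    "read_pdb",
    "write_pdb",
    "select_atoms",
    "extract_sequence",
]

# 3-letter -> 1-letter code for the 20 standard amino acids
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class PDBParseError(ValueError):
    """Raised for unreadable or empty coordinate files."""


class EnsembleConsistencyError(ValueError):
    """Raised when models of one file disagree on their residue content."""


class SelectionError(KeyError):
    """Raised when a requested chain, residue or atom is absent."""

    def __str__(self) -> str:  # KeyError quotes its payload; keep it readable
        return self.args[0] if self.args else ""


@dataclass
class Atom:
    """One heavy atom: label, element, position (Å), occupancy, altloc."""

    name: str
    element: str
    pos: np.ndarray
    occupancy: float | None = 1.0
    altloc: str | None = None

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if not np.all(np.isfinite(self.pos)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    """A residue addressed by author numbering, holding a name->Atom map."""

    chain_id: str
    seq_id: int
    res_name: str
    atoms: dict[str, Atom] = field(default_factory=dict)
    icode: str | None = None

    @property
    def is_standard(self) -> bool:
        return self.res_name in THREE_TO_ONE

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")


# one model = {chain_id: [Residue, ...]} in file order
Model = dict[str, list[Residue]]


@dataclass
class StructureEnsemble:
    """Ordered coordinate models parsed from one PDB file."""

    models: list[Model]
    source_id: str = ""

    @property
    def n_models(self) -> int:
        return len(self.models)

    def residue(self, model_index: int, chain: str, seq_id: int) -> Residue:
        model = self.models[model_index]
        if chain not in model:
            raise SelectionError(f"chain {chain!r} not in model {model_index}")
        for res in model[chain]:
            if res.seq_id == seq_id:
                return res
        raise SelectionError(f"residue {chain}:{seq_id} not found")

    def residues(self, model_index: int, chain: str) -> list[Residue]:
        model = self.models[model_index]
        if chain not in model:
            raise SelectionError(f"chain {chain!r} not in model {model_index}")
        return model[chain]

    def chains(self, model_index: int = 0) -> list[str]:
        return list(self.models[model_index].keys())


def _residue_key_set(model: Model) -> set[tuple[str, int, str]]:
    return {
        (res.chain_id, res.seq_id, res.res_name)
        for residues in model.values()
        for res in residues
    }


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; alphabetically first altloc breaks ties
    return min(atoms, key=lambda a: (-(a.occ if a.occ else 0.0), a.altloc or ""))


def read_pdb(path, source_id: str | None = None) -> StructureEnsemble:
    """Parse a PDB file into a :class:`StructureEnsemble`.

    One model per MODEL record (a single implicit model if there are none).
    Alternate locations are resolved to the highest-occupancy conformer
    (alphabetical tie-break), hydrogens are dropped, and HETATM records are
    kept only for nonstandard amino acids inside a polymer chain.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    st.remove_hydrogens()
    st.remove_waters()

    models: list[Model] = []
    for gmodel in st:
        model: Model = {}
        for gchain in gmodel:
            residues: list[Residue] = []
            for gres in gchain:
                if gres.is_water():
                    continue
                het = gres.het_flag == "H"
                standard = gres.name in THREE_TO_ONE
                # HETATM ignored unless it is a nonstandard amino acid in a
                # chain (gemmi flags those as amino-acid-like residues)
                if het and not gres.is_amino_acid():
                    continue
                by_name: dict[str, list[gemmi.Atom]] = {}
                for gatom in gres:
                    by_name.setdefault(gatom.name, []).append(gatom)
                atoms: dict[str, Atom] = {}
                for name, variants in by_name.items():
                    chosen = _pick_altloc(variants)
                    atoms[name] = Atom(
                        name=name,
                        element=chosen.element.name,
                        pos=np.array([chosen.pos.x, chosen.pos.y, chosen.pos.z]),
                        occupancy=chosen.occ,
                        altloc=chosen.altloc or None,
                    )
                if not atoms:
                    continue
                icode = gres.seqid.icode.strip() or None
                residues.append(
                    Residue(
                        chain_id=gchain.name,
                        seq_id=gres.seqid.num,
                        res_name=gres.name,
                        atoms=atoms,
                        icode=icode,
                    )
                )
                _ = standard  # residues outside the 20 codes flag via is_standard
            if residues:
                model.setdefault(gchain.name, []).extend(residues)
        if model:
            models.append(model)

    if not models:
        raise PDBParseError(f"{path}: no ATOM records found (line 1)")

    ref = _residue_key_set(models[0])
    for i, model in enumerate(models[1:], start=2):
        if _residue_key_set(model) != ref:
            raise EnsembleConsistencyError(
                f"{path}: model {i} has a different residue set than model 1"
            )
    return StructureEnsemble(models=models, source_id=source_id or str(path))


def write_pdb(ensemble: StructureEnsemble, path) -> None:
    """Write the ensemble as plain PDB ATOM records (MODEL/ENDMDL when >1)."""
    multi = ensemble.n_models > 1
    lines: list[str] = []
    for i, model in enumerate(ensemble.models, start=1):
        if multi:
            lines.append(f"MODEL     {i:4d}")
        serial = 1
        for chain_id, residues in model.items():
            for res in residues:
                for atom in res.atoms.values():
                    name = atom.name
                    # column-13 convention: 1-letter elements start in col 14
                    padded = f" {name:<3s}" if len(name) < 4 else name
                    x, y, z = atom.pos
                    occ = atom.occupancy if atom.occupancy is not None else 1.0
                    lines.append(
                        f"ATOM  {serial:5d} {padded:<4s}{'':1s}{res.res_name:>3s} "
                        f"{chain_id:1s}{res.seq_id:4d}{res.icode or '':1s}   "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
                        f"          {atom.element:>2s}"
                    )
                    serial += 1
            lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def select_atoms(
    ensemble: StructureEnsemble,
    model_index: int,
    chain: str,
    seq_ids: list[int],
    names: list[str],
) -> np.ndarray:
    """Coordinates for the requested (residue, atom) grid.

    Returns an ``(len(seq_ids) * len(names), 3)`` array ordered residue-major,
    atoms in the order given.  Missing atoms raise :class:`SelectionError`
    naming the residue and atom.
    """
    coords: list[np.ndarray] = []
    for seq_id in seq_ids:
        res = ensemble.residue(model_index, chain, seq_id)
        for name in names:
            if name not in res.atoms:
                raise SelectionError(
                    f"atom {name!r} missing in {res.res_name} {chain}:{seq_id}"
                )
            coords.append(res.atoms[name].pos)
    return np.array(coords)


def extract_sequence(ensemble: StructureEnsemble, chain: str, model_index: int = 0) -> str:
    """Single-letter sequence of a chain in seq_id order; nonstandard -> 'X'."""
    residues = ensemble.residues(model_index, chain)
    return "".join(r.one_letter for r in sorted(residues, key=lambda r: r.seq_id))
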