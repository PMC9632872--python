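"""Disulfide-connectivity mapping from proteolytic digest masses.

The intact mass of an oxidized 4-cysteine peptide proves that two disulfides
formed but not which of the three possible pairings they follow.  Pepsin at
pH ≈ 1.4 cleaves almost exclusively C-terminal to Phe and Leu while leaving
disulfides intact, so the crosslinked fragment masses discriminate the
pairings: each candidate pairing predicts a distinct set of crosslinked
species, and the hypothesis whose theoretical masses explain the observed
deconvoluted monoisotopic masses best (most matches, then smallest mean ppm
error) wins.

Masses are neutral monoisotopic Da throughout: residue masses from the
standard table plus one water (18.010565) per peptide, minus 2 H
(2.015650 Da) per disulfide bond.
"""

from __future__ import annotations

from dataclasses import dataclass

from pyteomics import mass as _pmass

__all__ = [
    "PeptideSequence",
    "Fragment",
    "ConnectivityHypothesis",
    "CrosslinkedSpecies",
    "MatchReport",
    "WATER_MONO",
    "SS_BOND_DELTA",
    "monoisotopic_mass",
    "oxidized_mass",
    "pepsin_digest",
    "enumerate_pairings",
    "theoretical_species",
    "infer_connectivity",
]

WATER_MONO = 18.010565
SS_BOND_DELTA = 2.015650  # two hydrogens lost per disulfide

#: standard monoisotopic residue masses (pyteomics table)
RESIDUE_MASS = {aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"}


@dataclass
class PeptideSequence:
    """A single-letter peptide sequence with derived cysteine positions."""

    residues: str

    def __post_init__(self) -> None:
        bad = [
            (i + 1, c) for i, c in enumerate(self.residues) if c not in RESIDUE_MASS
        ]
        if bad:
            pos, c = bad[0]
            raise ValueError(f"unknown residue letter {c!r} at position {pos}")

    @property
    def cys_positions(self) -> list[int]:
        return [i + 1 for i, c in enumerate(self.residues) if c == "C"]

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Fragment:
    """A digest product: 1-based inclusive span, sequence and reduced mass."""

    span: tuple[int, int]
    sequence: str
    mono_mass: float

    def cys_positions(self) -> list[int]:
        start = self.span[0]
        return [start + i for i, c in enumerate(self.sequence) if c == "C"]


@dataclass(frozen=True)
class ConnectivityHypothesis:
    """A perfect matching over cysteine positions."""

    pairs: frozenset[frozenset[int]]

    @classmethod
    def of(cls, *pairs: tuple[int, int]) -> "ConnectivityHypothesis":
        return cls(frozenset(frozenset(p) for p in pairs))

    def label(self) -> str:
        parts = sorted(tuple(sorted(p)) for p in self.pairs)
        return " / ".join(f"Cys-{a}–Cys-{b}" for a, b in parts)


@dataclass(frozen=True)
class CrosslinkedSpecies:
    fragments: tuple[Fragment, ...]
    n_ss: int
    mono_mass: float

    def label(self) -> str:
        spans = "+".join(f"{s}-{e}" for s, e in (f.span for f in self.fragments))
        return f"{spans} ({self.n_ss} S-S)" if self.n_ss else spans


@dataclass
class MatchReport:
    hypothesis: ConnectivityHypothesis
    matched: list[tuple[float, float, float, CrosslinkedSpecies]]
    n_matched: int
    score: float
    mean_abs_ppm: float
    ambiguous: bool = False


def monoisotopic_mass(seq: str | PeptideSequence) -> float:
    """Neutral monoisotopic mass of a reduced peptide (residues + one water)."""
    s = seq.residues if isinstance(seq, PeptideSequence) else seq
    if not s:
        raise ValueError("empty sequence has no mass")
    PeptideSequence(s)  # validates the alphabet, naming the offending position
    return sum(RESIDUE_MASS[c] for c in s) + WATER_MONO


def oxidized_mass(seq: str | PeptideSequence, n_ss: int) -> float:
    """Monoisotopic mass after forming ``n_ss`` intramolecular disulfides."""
    s = seq.residues if isinstance(seq, PeptideSequence) else seq
    n_cys = s.count("C")
    if 2 * n_ss > n_cys:
        raise ValueError(f"{n_ss} disulfides need {2 * n_ss} Cys; sequence has {n_cys}")
    return monoisotopic_mass(s) - SS_BOND_DELTA * n_ss


def pepsin_digest(
    seq: str | PeptideSequence,
    max_missed: int = 2,
    block_before_proline: bool = False,
) -> list[Fragment]:
    """In-silico pepsin digest: cleavage C-terminal to every Phe and Leu.

    With ``block_before_proline`` the site is suppressed when the next residue
    is proline.  All products with at most ``max_missed`` missed cleavages are
    returned, deduplicated by span and ordered by position.
    """
    s = seq.residues if isinstance(seq, PeptideSequence) else seq
    if not s:
        raise ValueError("empty sequence")
    sites = [
        i + 1  # cleavage between i and i+1 (0-based string index of the cut)
        for i, c in enumerate(s[:-1])
        if c in "FL" and not (block_before_proline and s[i + 1] == "P")
    ]
    bounds = [0] + sites + [len(s)]
    fragments: dict[tuple[int, int], Fragment] = {}
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            start, end = bounds[i], bounds[j]
            span = (start + 1, end)  # 1-based inclusive
            if span not in fragments:
                sub = s[start:end]
                fragments[span] = Fragment(span, sub, monoisotopic_mass(sub))
    return sorted(fragments.values(), key=lambda f: f.span)


def enumerate_pairings(cys_positions: list[int]) -> list[ConnectivityHypothesis]:
    """All perfect matchings of the cysteines; (2k)!/(k!·2^k) of them."""
    positions = sorted(cys_positions)
    if len(positions) % 2 != 0:
        raise ValueError(f"odd cysteine count ({len(positions)}) cannot pair fully")

    def _match(rest: tuple[int, ...]):
        if not rest:
            yield []
            return
        first, tail = rest[0], rest[1:]
        for k, partner in enumerate(tail):
            remaining = tail[:k] + tail[k + 1:]
            for sub in _match(remaining):
                yield [(first, partner)] + sub

    return [ConnectivityHypothesis.of(*m) for m in _match(tuple(positions))]


def theoretical_species(
    fragments: list[Fragment], hypothesis: ConnectivityHypothesis
) -> list[CrosslinkedSpecies]:
    """Crosslinked species a pairing predicts over a set of digest fragments.

    Disulfide pairs whose cysteines fall in two distinct fragments join those
    fragments into a two-fragment species (both bonds counted when two pairs
    join the same two fragments); intra-fragment pairs decrement that
    fragment's own mass.  Species are deduplicated.
    """
    pos_to_frag: dict[int, list[Fragment]] = {}
    for frag in fragments:
        for p in frag.cys_positions():
            pos_to_frag.setdefault(p, []).append(frag)
    all_cys = {p for pair in hypothesis.pairs for p in pair}
    missing = [p for p in all_cys if p not in pos_to_frag]
    if missing:
        raise ValueError(f"cysteine position(s) {missing} outside all fragments")

    species: set[CrosslinkedSpecies] = set()
    pairs = [tuple(sorted(p)) for p in hypothesis.pairs]
    # enumerate fragment assignments: each Cys may sit in several overlapping
    # fragments (missed cleavages), every combination yields a candidate species
    for a, b in pairs:
        for fa in pos_to_frag[a]:
            for fb in pos_to_frag[b]:
                if fa.span == fb.span:
                    frags = (fa,)
                else:
                    frags = tuple(sorted((fa, fb), key=lambda f: f.span))
                # count every hypothesis bond linking cysteines within this
                # fragment union (aggregates double-linked fragment pairs)
                covered = set()
                for f in frags:
                    covered.update(f.cys_positions())
                n_ss = sum(1 for x, y in pairs if x in covered and y in covered)
                mass = sum(f.mono_mass for f in frags) - SS_BOND_DELTA * n_ss
                species.add(CrosslinkedSpecies(frags, n_ss, mass))
    return sorted(species, key=lambda sp: (sp.fragments[0].span, sp.mono_mass))


def _match_masses(
    observed: list[float], species: list[CrosslinkedSpecies], tol_ppm: float
):
    """Greedy unique matching, best ppm first; each observation consumed once."""
    candidates = []
    for oi, obs in enumerate(observed):
        for sp in species:
            ppm = (obs - sp.mono_mass) / sp.mono_mass * 1e6
            if abs(ppm) <= tol_ppm:
                candidates.append((abs(ppm), oi, obs, ppm, sp))
    candidates.sort(key=lambda t: (t[0], t[1], t[4].mono_mass))
    used_obs: set[int] = set()
    used_sp: set[CrosslinkedSpecies] = set()
    matched = []
    for _, oi, obs, ppm, sp in candidates:
        if oi in used_obs or sp in used_sp:
            continue
        used_obs.add(oi)
        used_sp.add(sp)
        matched.append((obs, sp.mono_mass, ppm, sp))
    return matched


def infer_connectivity(
    seq: str | PeptideSequence,
    observed_masses: list[float],
    tol_ppm: float = 10.0,
    max_missed: int = 2,
    block_before_proline: bool = False,
) -> list[MatchReport]:
    """Rank all connectivity hypotheses against observed digest masses.

    Each hypothesis is scored by how many observations its theoretical
    crosslinked species explain within ``tol_ppm`` (greedy unique matching);
    reports are sorted by matches descending, then mean |ppm| ascending.
    A tie on both keys marks the tied reports ambiguous — as does an
    all-zero outcome (inconclusive data).
    """
    if not observed_masses:
        raise ValueError("need at least one observed mass")
    pep = seq if isinstance(seq, PeptideSequence) else PeptideSequence(seq)
    fragments = pepsin_digest(pep, max_missed=max_missed,
                              block_before_proline=block_before_proline)
    reports = []
    for hyp in enumerate_pairings(pep.cys_positions):
        species = theoretical_species(fragments, hyp)
        matched = _match_masses(list(observed_masses), species, tol_ppm)
        mean_ppm = (
            sum(abs(m[2]) for m in matched) / len(matched) if matched else float("inf")
        )
        reports.append(
            MatchReport(
                hypothesis=hyp,
                matched=matched,
                n_matched=len(matched),
                score=len(matched) / len(observed_masses),
                mean_abs_ppm=mean_ppm,
            )
        )
    reports.sort(key=lambda r: (-r.n_matched, r.mean_abs_ppm))
    if reports:
        top = reports[0]
        for r in reports:
            tied = (
                r is not top
                and r.n_matched == top.n_matched
                and abs(r.mean_abs_ppm - top.mean_abs_ppm) < 1e-9
            )
            if tied:
                r.ambiguous = True
                top.ambiguous = True
        if top.n_matched == 0:
            for r in reports:
                r.ambiguous = True  # nothing matched anywhere: inconclusive
    return reports
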