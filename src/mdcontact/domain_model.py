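"""Protein structures and named-domain partitions.

A :class:`StructureModel` is a flat, order-preserving list of atoms read from
PDB ``ATOM``/``HETATM`` records.  A :class:`DomainMap` partitions residues of
each chain into named domains given as inclusive 1-based residue-id intervals
(e.g. an integrin fragment's N, α1, Hyb and β1 domains).  Every downstream
metric — per-domain RMSD, RMSF box statistics, domain contact numbers — is
resolved through these two objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger("mdcontact")

# Standard atomic masses (amu) for elements that occur in proteins and small
# organic ligands.  Unknown elements fall back to carbon (see resolve_mass).
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
    "NA": 22.990,
    "K": 39.098,
    "MG": 24.305,
    "CA": 40.078,
    "MN": 54.938,
    "FE": 55.845,
    "ZN": 65.38,
    "SE": 78.971,
}


class StructureError(ValueError):
    """Raised for malformed or empty structure input."""


class DomainMapError(ValueError):
    """Raised for invalid domain specifications (e.g. overlapping ranges)."""


def resolve_mass(element: str) -> float:
    """Mass in amu for *element*; unknown symbols default to carbon."""
    m = ATOMIC_MASSES.get(element.strip().upper())
    if m is None:
        logger.warning("unknown element %r: defaulting to carbon mass", element)
        return ATOMIC_MASSES["C"]
    return m


@dataclass(frozen=True)
class Atom:
    atom_id: int
    name: str
    element: str
    mass: float
    chain: str
    residue_id: int
    residue_name: str
    coords: tuple[float, float, float]
    bfactor: float


@dataclass
class StructureModel:
    """An ordered set of atoms plus an optional orthorhombic box (Å)."""

    atoms: list[Atom]
    box: Optional[tuple[float, float, float]] = None

    _residue_index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError("structure contains no atoms")
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise StructureError("duplicate atom ids in structure")
        coords = self.coords
        if not np.all(np.isfinite(coords)):
            raise StructureError("non-finite coordinates in structure")
        if any(a.mass <= 0 for a in self.atoms):
            raise StructureError("non-positive atom mass")
        self._residue_index = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float array of coordinates in Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def residues(self) -> list[tuple[str, int]]:
        """Ordered unique (chain, residue_id) pairs."""
        return list(self.residue_index())

    def residue_index(self) -> dict[tuple[str, int], np.ndarray]:
        """Mapping (chain, residue_id) -> atom index array, in file order."""
        if self._residue_index is None:
            idx: dict[tuple[str, int], list[int]] = {}
            for i, a in enumerate(self.atoms):
                idx.setdefault((a.chain, a.residue_id), []).append(i)
            self._residue_index = {
                key: np.asarray(v, dtype=int) for key, v in idx.items()
            }
        return self._residue_index

    def residue_name(self, chain: str, residue_id: int) -> str:
        idx = self.residue_index().get((chain, residue_id))
        if idx is None:
            raise StructureError(f"no residue {residue_id} in chain {chain!r}")
        return self.atoms[int(idx[0])].residue_name

    def chains(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain not in seen:
                seen.append(a.chain)
        return seen


# ---------------------------------------------------------------------------
# PDB I/O (fixed columns; ATOM/HETATM + CRYST1 only)
# ---------------------------------------------------------------------------


def parse_structure(pdb_text: str) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Only ``ATOM``/``HETATM`` records (and ``CRYST1`` for the box) are read.
    Alternate locations are reduced to the highest-occupancy conformer;
    insertion codes are rejected.  Raises :class:`StructureError` naming the
    offending line for malformed fixed-width records, and for zero atoms.
    """
    raw: list[tuple[Atom, str, float]] = []  # (atom, altloc, occupancy)
    box: Optional[tuple[float, float, float]] = None
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec == "CRYST1":
            try:
                box = (float(line[6:15]), float(line[15:24]), float(line[24:33]))
            except ValueError as exc:
                raise StructureError(f"malformed CRYST1 record at line {lineno}") from exc
            continue
        if rec not in ("ATOM  ", "HETATM"):
            continue
        try:
            atom_id = int(line[6:11])
            name = line[12:16].strip()
            altloc = line[16].strip() if len(line) > 16 else ""
            residue_name = line[17:20].strip()
            chain = line[21].strip() if len(line) > 21 else ""
            residue_id = int(line[22:26])
            icode = line[26].strip() if len(line) > 26 else ""
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ_field = line[54:60].strip()
            occupancy = float(occ_field) if occ_field else 1.0
            bf_field = line[60:66].strip()
            bfactor = float(bf_field) if bf_field else 0.0
            element = line[76:78].strip() if len(line) > 76 else ""
        except (ValueError, IndexError) as exc:
            raise StructureError(
                f"malformed fixed-width record at line {lineno}: {line!r}"
            ) from exc
        if icode:
            raise StructureError(
                f"insertion code {icode!r} at line {lineno} is not supported"
            )
        if not element:
            # Derive from the atom name: first alphabetic character.
            alpha = [c for c in name if c.isalpha()]
            element = alpha[0].upper() if alpha else "C"
        atom = Atom(
            atom_id=atom_id,
            name=name,
            element=element,
            mass=resolve_mass(element),
            chain=chain,
            residue_id=residue_id,
            residue_name=residue_name,
            coords=(x, y, z),
            bfactor=bfactor,
        )
        raw.append((atom, altloc, occupancy))
    if not raw:
        raise StructureError("no ATOM/HETATM records found (empty structure)")
    atoms = _collapse_altlocs(raw)
    return StructureModel(atoms=atoms, box=box)


def _collapse_altlocs(raw: list[tuple[Atom, str, float]]) -> list[Atom]:
    """Keep only the highest-occupancy alternate conformer of each atom."""
    if all(alt == "" for _, alt, _ in raw):
        return [a for a, _, _ in raw]
    best: dict[tuple[str, int, str], tuple[int, float]] = {}
    for i, (atom, alt, occ) in enumerate(raw):
        key = (atom.chain, atom.residue_id, atom.name)
        if alt == "":
            best[key] = (i, float("inf"))
        elif key not in best or occ > best[key][1]:
            best[key] = (i, occ)
    keep = sorted(i for i, _ in best.values())
    return [raw[i][0] for i in keep]


def write_pdb(structure: StructureModel, bfactors: Optional[np.ndarray] = None) -> str:
    """Render a :class:`StructureModel` as PDB text.

    B-factors are taken from *bfactors* (per atom) when given, else from the
    atoms themselves; values outside the 6.2F column are clipped with a
    warning.
    """
    lines: list[str] = []
    if structure.box is not None:
        a, b, c = structure.box
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
        )
    if bfactors is not None and len(bfactors) != structure.n_atoms:
        raise ValueError("bfactors length must equal atom count")
    for i, atom in enumerate(structure.atoms):
        bf = float(bfactors[i]) if bfactors is not None else atom.bfactor
        if bf > 999.99:
            logger.warning("B-factor %.3f exceeds PDB column width: clipped", bf)
            bf = 999.99
        if bf < -99.99:
            logger.warning("B-factor %.3f below PDB column range: clipped", bf)
            bf = -99.99
        name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3}"
        x, y, z = atom.coords
        lines.append(
            f"ATOM  {atom.atom_id:>5d} {name:<4s} {atom.residue_name:>3s} "
            f"{atom.chain:1s}{atom.residue_id:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{bf:6.2f}          "
            f"{atom.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Domain maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainEntry:
    domain: str
    chain: str
    ranges: tuple[tuple[int, int], ...]

    @property
    def n_residues(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self.ranges)

    def residue_ids(self) -> list[int]:
        out: list[int] = []
        for lo, hi in self.ranges:
            out.extend(range(lo, hi + 1))
        return out


@dataclass(frozen=True)
class DomainMap:
    """Chain-scoped partition of residue ids into named domains."""

    entries: tuple[DomainEntry, ...]

    def domains(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.domain not in seen:
                seen.append(e.domain)
        return seen

    def residues_in(self, domain: str) -> list[tuple[str, int]]:
        out: list[tuple[str, int]] = []
        for e in self.entries:
            if e.domain == domain:
                out.extend((e.chain, rid) for rid in e.residue_ids())
        return out

    def n_residues(self, domain: str) -> int:
        return sum(e.n_residues for e in self.entries if e.domain == domain)


def build_domain_map(
    spec: Iterable[tuple[str, str, Sequence[Sequence[int]]]],
) -> DomainMap:
    """Build a validated :class:`DomainMap` from (domain, chain, intervals).

    Intervals are 1-based inclusive ``[low, high]`` pairs.  Overlapping
    intervals within one chain raise :class:`DomainMapError` listing the
    colliding residue ids.
    """
    entries: list[DomainEntry] = []
    for domain, chain, intervals in spec:
        ranges: list[tuple[int, int]] = []
        for iv in intervals:
            lo, hi = int(iv[0]), int(iv[1])
            if lo > hi:
                raise DomainMapError(
                    f"interval [{lo}, {hi}] in domain {domain!r} has low > high"
                )
            ranges.append((lo, hi))
        entries.append(DomainEntry(domain=domain, chain=chain, ranges=tuple(ranges)))
    # Overlap check per chain.
    claimed: dict[str, dict[int, str]] = {}
    for e in entries:
        chain_claims = claimed.setdefault(e.chain, {})
        for rid in e.residue_ids():
            if rid in chain_claims:
                collisions = sorted(
                    r
                    for r in e.residue_ids()
                    if r in chain_claims and chain_claims[r] != e.domain
                )
                raise DomainMapError(
                    f"chain {e.chain!r}: residues {collisions} claimed by both "
                    f"{chain_claims[rid]!r} and {e.domain!r}"
                )
            chain_claims[rid] = e.domain
    return DomainMap(entries=tuple(entries))


def assign_residue_domain(
    domain_map: DomainMap, chain: str, residue_id: int
) -> Optional[str]:
    """Domain label owning (chain, residue_id), or ``None`` if unassigned."""
    for e in domain_map.entries:
        if e.chain != chain:
            continue
        for lo, hi in e.ranges:
            if lo <= residue_id <= hi:
                return e.domain
    return None


#: The integrin fragment domain map used throughout: chain A N-domain
#: (1:126 and 328:597) and α1 (127:327); chain B Hyb (58:101 and 343:423)
#: and β1 (102:342).
INTEGRIN_DOMAIN_SPEC: list[tuple[str, str, list[list[int]]]] = [
    ("N", "A", [[1, 126], [328, 597]]),
    ("alpha1", "A", [[127, 327]]),
    ("Hyb", "B", [[58, 101], [343, 423]]),
    ("beta1", "B", [[102, 342]]),
]


def integrin_domain_map() -> DomainMap:
    """The four-domain integrin fragment map (N, α1, Hyb, β1)."""
    return build_domain_map(INTEGRIN_DOMAIN_SPEC)
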