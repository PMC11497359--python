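"""Protein–ligand contact-occupancy analysis.

The central statistic is the transient contact number C_i(t): how many ligand
copies of a species have their center of mass strictly within a cutoff
(default 0.7 nm) of the center of mass of amino acid i at grid time t.  Its
time average ⟨C_i⟩ over the post-equilibration sampling grid measures how
often a residue is visited; summing ⟨C_i⟩ over a domain's residues gives the
domain contact number C_domain, which may exceed the number of ligand copies
because one copy can touch several residues simultaneously.  Comparing
C_domain for a compound alone (diagonal) versus in a binary mixture
(off-diagonal) yields the competition matrix that reveals displacement or
relocation between compounds.

Distances use the minimum-image convention in orthorhombic boxes; the
neighbor search is a k-d tree over ligand centers of mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .domain_model import DomainMap, StructureModel, write_pdb
from .stability import TrajectoryWindow

logger = logging.getLogger("mdcontact")

DEFAULT_CUTOFF_NM = 0.7
DEFAULT_INTERVAL_PS = 100.0
DEFAULT_EQUILIBRATION_PS = 3000.0
ANGSTROM_PER_NM = 10.0


# ---------------------------------------------------------------------------
# Ligand definitions
# ---------------------------------------------------------------------------


@dataclass
class LigandSet:
    """All copies of one ligand species, as atom-index groups.

    ``copies`` indexes into the structure/trajectory atom order; copies must
    be disjoint and non-empty.
    """

    species: str
    copies: list[np.ndarray]
    masses: np.ndarray  # per structure atom, used for copy COMs

    def __post_init__(self) -> None:
        if not self.copies:
            raise ValueError(f"ligand set {self.species!r} has no copies")
        seen: set[int] = set()
        for c in self.copies:
            c = np.asarray(c, dtype=int)
            if len(c) == 0:
                raise ValueError(f"empty ligand copy in species {self.species!r}")
            if seen.intersection(c.tolist()):
                raise ValueError(f"overlapping ligand copies in species {self.species!r}")
            seen.update(c.tolist())
        self.copies = [np.asarray(c, dtype=int) for c in self.copies]
        self.masses = np.asarray(self.masses, dtype=float)

    @property
    def n_copies(self) -> int:
        return len(self.copies)

    def copy_coms(self, frame: np.ndarray) -> np.ndarray:
        """(n_copies, 3) mass-weighted centers of mass for one frame."""
        out = np.empty((self.n_copies, 3))
        for k, idx in enumerate(self.copies):
            m = self.masses[idx]
            out[k] = m @ frame[idx] / m.sum()
        return out


def ligand_set_from_structure(
    structure: StructureModel,
    species: str,
    chain: Optional[str] = None,
    residue_name: Optional[str] = None,
) -> LigandSet:
    """Build a :class:`LigandSet` by grouping matching atoms per residue.

    Each residue (one molecule) that matches the chain and/or residue-name
    filter becomes one copy.
    """
    groups: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(structure.atoms):
        if chain is not None and a.chain != chain:
            continue
        if residue_name is not None and a.residue_name != residue_name:
            continue
        groups.setdefault((a.chain, a.residue_id), []).append(i)
    if not groups:
        raise ValueError(
            f"no atoms match species {species!r} (chain={chain!r}, "
            f"residue_name={residue_name!r})"
        )
    return LigandSet(
        species=species,
        copies=[np.asarray(v, dtype=int) for v in groups.values()],
        masses=structure.masses,
    )


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def minimum_image_distance(
    a: np.ndarray, b: np.ndarray, box: Optional[np.ndarray]
) -> np.ndarray:
    """Pairwise Euclidean distance with minimum-image wrap (orthorhombic)."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if box is not None:
        box = np.asarray(box, dtype=float)
        d = d - box * np.round(d / box)
    return np.sqrt(np.sum(d * d, axis=-1))


def residue_com(
    frame: np.ndarray, structure: StructureModel, chain: str, residue_id: int
) -> np.ndarray:
    """Mass-weighted center of mass of one residue in one frame (Å)."""
    idx = structure.residue_index().get((chain, residue_id))
    if idx is None:
        raise ValueError(f"no residue {residue_id} in chain {chain!r}")
    m = structure.masses[idx]
    return m @ np.asarray(frame, dtype=float)[idx] / m.sum()


def _residue_com_matrix(
    frame: np.ndarray,
    structure: StructureModel,
    residues: Sequence[tuple[str, int]],
) -> np.ndarray:
    out = np.empty((len(residues), 3))
    for j, (chain, rid) in enumerate(residues):
        out[j] = residue_com(frame, structure, chain, rid)
    return out


# ---------------------------------------------------------------------------
# Transient contact counting
# ---------------------------------------------------------------------------


def transient_contact_count(
    frame: np.ndarray,
    structure: StructureModel,
    chain: str,
    residue_id: int,
    ligands: LigandSet,
    cutoff_nm: float = DEFAULT_CUTOFF_NM,
    box: Optional[np.ndarray] = None,
) -> int:
    """C_i(t) for one residue and one species in one frame.

    Counts ligand copies whose COM lies strictly within the cutoff of the
    residue COM; the minimum-image convention applies when a box is given.
    """
    if cutoff_nm <= 0:
        raise ValueError("cutoff must be positive")
    rc = residue_com(frame, structure, chain, residue_id)
    lc = ligands.copy_coms(frame)
    dist = minimum_image_distance(lc, rc[None, :], box)
    return int(np.sum(dist < cutoff_nm * ANGSTROM_PER_NM))


def _frame_counts(
    res_coms: np.ndarray,
    lig_coms: np.ndarray,
    cutoff_A: float,
    box: Optional[np.ndarray],
) -> np.ndarray:
    """Counts per residue via k-d tree neighbor search (strict < cutoff)."""
    if len(lig_coms) == 0:
        return np.zeros(len(res_coms), dtype=int)
    if box is not None:
        box = np.asarray(box, dtype=float)
        tree = cKDTree(np.mod(lig_coms, box), boxsize=box)
        query_pts = np.mod(res_coms, box)
    else:
        tree = cKDTree(lig_coms)
        query_pts = res_coms
    counts = np.zeros(len(res_coms), dtype=int)
    # query_ball_point is inclusive at r; re-check candidates strictly.
    neighbor_lists = tree.query_ball_point(query_pts, r=cutoff_A)
    for j, neigh in enumerate(neighbor_lists):
        if not neigh:
            continue
        d = minimum_image_distance(lig_coms[neigh], res_coms[j][None, :], box)
        counts[j] = int(np.sum(d < cutoff_A))
    return counts


# ---------------------------------------------------------------------------
# Contact series on the sampling grid
# ---------------------------------------------------------------------------


@dataclass
class ContactSeries:
    """Per-residue, per-species transient contact counts on a fixed grid."""

    grid_times: np.ndarray
    residues: list[tuple[str, int]]
    counts: dict[str, np.ndarray]  # species -> (n_grid, n_residues) int
    cutoff_nm: float
    interval_ps: float
    equilibration_ps: float
    residue_names: dict[tuple[str, int], str] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return list(self.counts)

    def averages(self, species: str) -> np.ndarray:
        """⟨C_i⟩ per residue for one species (mean over the grid)."""
        return self.counts[species].mean(axis=0)

    def average_map(self, species: str) -> dict[tuple[str, int], float]:
        return dict(zip(self.residues, self.averages(species)))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sp in self.species:
            avg = self.averages(sp)
            for (chain, rid), v in zip(self.residues, avg):
                rows.append(
                    {
                        "species": sp,
                        "chain": chain,
                        "residue": rid,
                        "residue_name": self.residue_names.get((chain, rid), ""),
                        "avg_contacts": v,
                    }
                )
        return pd.DataFrame(rows)


def grid_frame_indices(
    times: np.ndarray, interval_ps: float, equilibration_ps: float
) -> tuple[np.ndarray, np.ndarray]:
    """Map grid times t = equilibration + k·interval to nearest stored frames.

    Ties between two stored frames resolve to the earlier one.  Returns
    (grid_times, frame_indices).
    """
    if interval_ps <= 0:
        raise ValueError("interval must be positive")
    times = np.asarray(times, dtype=float)
    t_end = times[-1]
    if t_end < equilibration_ps:
        raise ValueError("trajectory does not extend past the equilibration period")
    n_grid = int(np.floor((t_end - equilibration_ps) / interval_ps)) + 1
    grid = equilibration_ps + interval_ps * np.arange(n_grid)
    # Only post-equilibration frames may contribute, so results are identical
    # whether the discarded segment is present or pre-trimmed.
    (valid,) = np.nonzero(times >= equilibration_ps)
    vt = times[valid]
    # Nearest eligible frame; ties -> earlier frame.
    pos = np.searchsorted(vt, grid)
    pos = np.clip(pos, 0, len(vt) - 1)
    left = np.clip(pos - 1, 0, len(vt) - 1)
    d_left = np.abs(grid - vt[left])
    d_right = np.abs(vt[pos] - grid)
    idx = valid[np.where(d_left <= d_right, left, pos)]
    return grid, idx


def contact_series(
    traj: TrajectoryWindow,
    structure: StructureModel,
    residues: Sequence[tuple[str, int]],
    ligands: Sequence[LigandSet],
    interval_ps: float = DEFAULT_INTERVAL_PS,
    equilibration_ps: float = DEFAULT_EQUILIBRATION_PS,
    cutoff_nm: float = DEFAULT_CUTOFF_NM,
    periodic: Optional[bool] = None,
) -> ContactSeries:
    """Evaluate C_i(t) for all residues/species on the sampling grid.

    Counts are taken at grid times t = equilibration + k·interval (mapped to
    the nearest stored frame, ties to the earlier frame) and averaged over
    the grid to give ⟨C_i⟩.  ``periodic`` defaults to True when the
    trajectory has a box.
    """
    traj.check_structure(structure)
    if periodic is None:
        periodic = traj.box is not None
    if periodic and traj.box is None:
        raise ValueError("periodic contact counting requires box vectors")
    grid, idx = grid_frame_indices(traj.times, interval_ps, equilibration_ps)
    if len(idx) == 0:
        raise ValueError("no grid points inside the trajectory")
    residues = list(residues)
    cutoff_A = cutoff_nm * ANGSTROM_PER_NM
    counts = {
        lig.species: np.zeros((len(idx), len(residues)), dtype=int) for lig in ligands
    }
    for g, fi in enumerate(idx):
        frame = traj.frames[fi]
        box = traj.box[fi] if periodic else None
        res_coms = _residue_com_matrix(frame, structure, residues)
        for lig in ligands:
            counts[lig.species][g] = _frame_counts(
                res_coms, lig.copy_coms(frame), cutoff_A, box
            )
    names = {
        (c, r): structure.residue_name(c, r)
        for (c, r) in residues
        if (c, r) in structure.residue_index()
    }
    return ContactSeries(
        grid_times=grid,
        residues=residues,
        counts=counts,
        cutoff_nm=cutoff_nm,
        interval_ps=interval_ps,
        equilibration_ps=equilibration_ps,
        residue_names=names,
    )


# ---------------------------------------------------------------------------
# Domain aggregation and competition matrices
# ---------------------------------------------------------------------------


def domain_contact_number(
    series: ContactSeries, domain_map: DomainMap, domain: str, species: str
) -> float:
    """C_domain = Σ_{i ∈ domain} ⟨C_i⟩ for one species.

    May exceed the copy count: one copy can contact several residues at
    once.
    """
    if domain not in domain_map.domains():
        raise ValueError(f"domain {domain!r} not in map")
    members = set(domain_map.residues_in(domain))
    avg = series.averages(species)
    return float(sum(v for (res, v) in zip(series.residues, avg) if res in members))


@dataclass
class DomainContactMatrix:
    """Focal-compound × co-compound table of C_domain for one domain."""

    domain: str
    values: pd.DataFrame  # rows focal, cols co-compound
    annotations: pd.DataFrame  # "diagonal" | "increase" | "decrease" | ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for focal in self.values.index:
            for co in self.values.columns:
                v = self.values.loc[focal, co]
                if np.isnan(v):
                    continue
                rows.append(
                    {
                        "domain": self.domain,
                        "focal": focal,
                        "co_compound": co,
                        "c_domain": v,
                        "annotation": self.annotations.loc[focal, co],
                    }
                )
        return pd.DataFrame(rows)


def competition_matrix(
    systems: Sequence[tuple[str, Optional[str], ContactSeries]],
    domain_map: DomainMap,
    domain: str,
) -> DomainContactMatrix:
    """Assemble the per-domain competition matrix from system contact series.

    Diagonal cells come from single-species systems; off-diagonal cells from
    binary mixtures, annotated "increase"/"decrease" versus the focal
    compound's diagonal value.  A row with off-diagonal entries but no
    diagonal gets a warning and no annotations.
    """
    cells: dict[tuple[str, str], float] = {}
    for focal, co, series in systems:
        col = focal if co is None else co
        key = (focal, col)
        if key in cells:
            raise ValueError(f"duplicate competition cell {key}")
        cells[key] = domain_contact_number(series, domain_map, domain, focal)
    rows = sorted({r for r, _ in cells})
    cols = sorted({c for _, c in cells})
    values = pd.DataFrame(np.nan, index=rows, columns=cols)
    ann = pd.DataFrame("", index=rows, columns=cols)
    for (r, c), v in cells.items():
        values.loc[r, c] = v
    for r in rows:
        diag = cells.get((r, r))
        if diag is None and any(c != r for (rr, c) in cells if rr == r):
            logger.warning(
                "no single-compound (diagonal) system for %r: annotations suppressed", r
            )
            continue
        for c in cols:
            v = cells.get((r, c))
            if v is None:
                continue
            if c == r:
                ann.loc[r, c] = "diagonal"
            elif v > diag:
                ann.loc[r, c] = "increase"
            elif v < diag:
                ann.loc[r, c] = "decrease"
            else:
                ann.loc[r, c] = "unchanged"
    values.index.name = ann.index.name = "focal"
    values.columns.name = ann.columns.name = "co_compound"
    return DomainContactMatrix(domain=domain, values=values, annotations=ann)


# ---------------------------------------------------------------------------
# Residue-type profiles and hotspots
# ---------------------------------------------------------------------------


def amino_acid_type_profile(
    series: ContactSeries, structure: StructureModel
) -> pd.DataFrame:
    """Mean ⟨C_i⟩ per 3-letter residue type, per species, vs the global mean.

    Reveals residue-type preferences (e.g. above-average contacts with
    arginine/glutamine/alanine/leucine-type residues).
    """
    rows = []
    for sp in series.species:
        avg = series.averages(sp)
        types: dict[str, list[float]] = {}
        for (chain, rid), v in zip(series.residues, avg):
            types.setdefault(structure.residue_name(chain, rid), []).append(float(v))
        global_mean = float(np.mean(avg)) if len(avg) else 0.0
        for rtype, vals in sorted(types.items()):
            rows.append(
                {
                    "species": sp,
                    "residue_type": rtype,
                    "n_residues": len(vals),
                    "mean_avg_contacts": float(np.mean(vals)),
                    "global_mean": global_mean,
                }
            )
    return pd.DataFrame(rows)


def hotspot_residues(
    series: ContactSeries, k: float = 1.0, species: Optional[str] = None
) -> set[tuple[str, int]]:
    """Residues with ⟨C_i⟩ > mean(⟨C⟩) + k·sd(⟨C⟩) (population sd)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if species is None:
        if len(series.species) != 1:
            raise ValueError("species must be given for multi-species series")
        species = series.species[0]
    avg = series.averages(species)
    thresh = float(np.mean(avg)) + k * float(np.std(avg))
    return {res for res, v in zip(series.residues, avg) if v > thresh}


# ---------------------------------------------------------------------------
# B-factor annotated structures
# ---------------------------------------------------------------------------


def write_bfactor_pdb(
    structure: StructureModel, series: ContactSeries, species: str
) -> str:
    """PDB text with every atom's B-factor replaced by its residue's ⟨C_i⟩.

    Visualizes the most frequently visited surface spots; residues without a
    contact average get 0 so the written structure is always complete.
    """
    avg = series.average_map(species)
    bf = np.array(
        [avg.get((a.chain, a.residue_id), 0.0) for a in structure.atoms], dtype=float
    )
    return write_pdb(structure, bfactors=bf)
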