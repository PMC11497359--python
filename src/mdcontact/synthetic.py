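"""Synthetic structures, trajectories and tracks with known ground truth.

Every analysis stage is exercised against generated data whose answer is
analytic: ligand particles diffusing in a periodic box with a known contact
occupancy, harmonic per-residue fluctuations with RMSF A/√2, rigid-body
displaced frames with known RMSD, and persistent random walks with a tunable
directional-persistence parameter.  No solvent is generated: the contact
statistic depends only on ligand and residue centers of mass.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .contacts import LigandSet
from .domain_model import Atom, DomainMap, StructureModel, build_domain_map, resolve_mass
from .kinematics import CellTrack
from .stability import TrajectoryWindow

#: chains offered to ligand species, skipping any used by the protein
_LIGAND_CHAINS = "LMNOPQRSTUV"


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------


def make_lattice_protein(
    n_residues: int,
    spacing_A: float = 10.0,
    domain_splits: Optional[dict[str, Sequence[Sequence[int]]]] = None,
    chain: str = "A",
    residue_types: Union[str, Sequence[str]] = "ALA",
    center: Optional[Sequence[float]] = None,
    box: Optional[Sequence[float]] = None,
) -> tuple[StructureModel, DomainMap]:
    """One-atom-per-residue pseudo-protein on a cubic grid.

    Residues are Cα pseudo-atoms placed on a 3-D grid with the given spacing
    (grid placement keeps the geometry non-collinear for superposition).
    ``domain_splits`` maps domain label -> list of inclusive [low, high]
    residue-id intervals; default is one domain covering everything.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    side = int(np.ceil(n_residues ** (1.0 / 3.0)))
    pos = np.array(
        [
            (i % side, (i // side) % side, i // (side * side))
            for i in range(n_residues)
        ],
        dtype=float,
    ) * spacing_A
    pos -= pos.mean(axis=0)
    if center is not None:
        pos += np.asarray(center, dtype=float)
    if isinstance(residue_types, str):
        residue_types = [residue_types] * n_residues
    if len(residue_types) != n_residues:
        raise ValueError("residue_types length must equal n_residues")
    atoms = [
        Atom(
            atom_id=i + 1,
            name="CA",
            element="C",
            mass=resolve_mass("C"),
            chain=chain,
            residue_id=i + 1,
            residue_name=residue_types[i],
            coords=tuple(pos[i]),
            bfactor=0.0,
        )
        for i in range(n_residues)
    ]
    structure = StructureModel(atoms=atoms, box=None if box is None else tuple(box))
    if domain_splits is None:
        domain_splits = {"D1": [[1, n_residues]]}
    for label, intervals in domain_splits.items():
        for lo, hi in intervals:
            if lo < 1 or hi > n_residues:
                raise ValueError(
                    f"domain {label!r} interval [{lo}, {hi}] outside 1..{n_residues}"
                )
    domain_map = build_domain_map(
        [(label, chain, list(iv)) for label, iv in domain_splits.items()]
    )
    return structure, domain_map


_GLYCINE_ATOMS = [
    # name, element, offset (Å) — idealized glycine geometry
    ("N", "N", (-0.97, 0.59, 0.0)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (1.24, 0.86, 0.0)),
    ("O", "O", (1.27, 2.09, 0.0)),
    ("HA1", "H", (-0.25, -0.65, 0.84)),
    ("HA2", "H", (-0.25, -0.65, -0.84)),
]


def make_glycine(origin: Sequence[float] = (0.0, 0.0, 0.0), chain: str = "A") -> StructureModel:
    """A single multi-atom glycine residue, for center-of-mass tests."""
    o = np.asarray(origin, dtype=float)
    atoms = [
        Atom(
            atom_id=i + 1,
            name=name,
            element=elem,
            mass=resolve_mass(elem),
            chain=chain,
            residue_id=1,
            residue_name="GLY",
            coords=tuple(o + np.asarray(off)),
            bfactor=0.0,
        )
        for i, (name, elem, off) in enumerate(_GLYCINE_ATOMS)
    ]
    return StructureModel(atoms=atoms)


# ---------------------------------------------------------------------------
# Ligand diffusion with controlled occupancy
# ---------------------------------------------------------------------------


def _ligand_atoms(
    structure: StructureModel, species_order: Sequence[tuple[str, int]]
) -> tuple[StructureModel, dict[str, list[np.ndarray]]]:
    """Append one single-atom residue per ligand copy; return index groups."""
    used = set(structure.chains())
    avail = [c for c in _LIGAND_CHAINS if c not in used]
    atoms = list(structure.atoms)
    next_id = max(a.atom_id for a in atoms) + 1
    offset = len(atoms)
    groups: dict[str, list[np.ndarray]] = {}
    for si, (species, n_copies) in enumerate(species_order):
        lig_chain = avail[si]
        resname = (species[:3].upper() or "LIG").ljust(3, "X")
        idx_groups = []
        for c in range(n_copies):
            atoms.append(
                Atom(
                    atom_id=next_id,
                    name="C1",
                    element="C",
                    mass=100.0,
                    chain=lig_chain,
                    residue_id=c + 1,
                    residue_name=resname,
                    coords=(0.0, 0.0, 0.0),
                    bfactor=0.0,
                )
            )
            idx_groups.append(np.array([offset], dtype=int))
            next_id += 1
            offset += 1
        groups[species] = idx_groups
    combined = StructureModel(atoms=atoms, box=structure.box)
    return combined, groups


@dataclass
class SpeciesParams:
    """Diffusion parameters for one ligand species.

    mode "uniform": all copies i.i.d. uniform in the box each frame.
    mode "tethered": copy 0 sits within ``bind_radius_A`` of
    ``tether_residue`` for a deterministic fraction ``bound_fraction`` of
    frames (Bresenham schedule) and otherwise uniform but kept outside the
    contact cutoff of the tether residue; remaining copies are uniform.
    """

    n_copies: int = 10
    mode: str = "uniform"
    tether_residue: Optional[tuple[str, int]] = None
    bound_fraction: float = 1.0
    bind_radius_A: float = 3.0
    cutoff_A: float = 7.0


def simulate_ligand_mixture(
    structure: StructureModel,
    box_A: Union[float, Sequence[float]],
    species_params: dict[str, SpeciesParams],
    n_frames: int,
    dt_ps: float = 100.0,
    seed: int = 0,
    protein_wobble_A: float = 0.0,
) -> tuple[StructureModel, TrajectoryWindow, list[LigandSet]]:
    """Simulate 1+ ligand species diffusing around a (near-)static protein.

    ``protein_wobble_A`` adds isotropic Gaussian jitter of that standard
    deviation to every protein atom per frame, giving non-zero RMSD/RMSF.
    """
    box = np.broadcast_to(np.asarray(box_A, dtype=float), (3,)).copy()
    rng = np.random.default_rng(seed)
    order = [(sp, p.n_copies) for sp, p in species_params.items()]
    combined, groups = _ligand_atoms(structure, order)
    n_atoms = combined.n_atoms
    base = combined.coords
    frames = np.tile(base, (n_frames, 1, 1))
    from .contacts import residue_com  # local import avoids cycle at module load

    for species, params in species_params.items():
        idx = np.array([g[0] for g in groups[species]])
        if params.mode not in ("uniform", "tethered"):
            raise ValueError(f"unknown diffusion mode {params.mode!r}")
        positions = rng.uniform(0.0, 1.0, size=(n_frames, len(idx), 3)) * box
        if params.mode == "tethered":
            if params.tether_residue is None:
                raise ValueError("tethered mode requires tether_residue")
            chain, rid = params.tether_residue
            anchor = residue_com(base, combined, chain, rid)
            f = float(params.bound_fraction)
            if not 0.0 <= f <= 1.0:
                raise ValueError("bound_fraction must be in [0, 1]")
            bound = np.floor((np.arange(n_frames) + 1) * f) > np.floor(
                np.arange(n_frames) * f
            )
            for k in range(n_frames):
                if bound[k]:
                    direction = rng.normal(size=3)
                    direction /= np.linalg.norm(direction)
                    r = rng.uniform(0.0, params.bind_radius_A)
                    positions[k, 0] = anchor + r * direction
                else:
                    # Keep the unbound copy out of the tether residue's cutoff
                    # so the bound fraction equals the contact occupancy.
                    while True:
                        cand = rng.uniform(0.0, 1.0, size=3) * box
                        d = cand - anchor
                        d -= box * np.round(d / box)
                        if np.linalg.norm(d) >= params.cutoff_A + 1.0:
                            positions[k, 0] = cand
                            break
        frames[:, idx, 0:3] = positions
    if protein_wobble_A > 0.0:
        n_prot = structure.n_atoms
        frames[:, :n_prot, :] += rng.normal(
            scale=protein_wobble_A, size=(n_frames, n_prot, 3)
        )
    traj = TrajectoryWindow(
        times=np.arange(n_frames) * dt_ps,
        frames=frames,
        box=np.tile(box, (n_frames, 1)),
    )
    ligand_sets = [
        LigandSet(species=sp, copies=groups[sp], masses=combined.masses)
        for sp in species_params
    ]
    assert traj.n_atoms == n_atoms
    return combined, traj, ligand_sets


def simulate_ligand_diffusion(
    structure: StructureModel,
    box_A: Union[float, Sequence[float]],
    n_copies: int = 10,
    n_frames: int = 1000,
    dt_ps: float = 100.0,
    seed: int = 0,
    mode: str = "uniform",
    species: str = "LIG",
    tether_residue: Optional[tuple[str, int]] = None,
    bound_fraction: float = 1.0,
    bind_radius_A: float = 3.0,
) -> tuple[StructureModel, TrajectoryWindow, LigandSet]:
    """Single-species convenience wrapper around :func:`simulate_ligand_mixture`."""
    params = SpeciesParams(
        n_copies=n_copies,
        mode=mode,
        tether_residue=tether_residue,
        bound_fraction=bound_fraction,
        bind_radius_A=bind_radius_A,
    )
    combined, traj, sets = simulate_ligand_mixture(
        structure, box_A, {species: params}, n_frames, dt_ps, seed
    )
    return combined, traj, sets[0]


def uniform_occupancy_expectation(
    n_copies: int, cutoff_A: float, box_A: Union[float, Sequence[float]]
) -> float:
    """E[⟨C_i⟩] for uniform copies: M · (4/3)π r³ / V."""
    box = np.broadcast_to(np.asarray(box_A, dtype=float), (3,))
    return n_copies * (4.0 / 3.0) * np.pi * cutoff_A**3 / float(np.prod(box))


# ---------------------------------------------------------------------------
# Harmonic fluctuations (RMSF ground truth A/√2)
# ---------------------------------------------------------------------------


def simulate_harmonic_fluctuations(
    structure: StructureModel,
    amplitudes_A: Union[float, Sequence[float], dict[tuple[str, int], float]],
    n_frames: int,
    seed: int = 0,
    dt_ps: float = 10.0,
    period_frames: int = 100,
) -> TrajectoryWindow:
    """Each residue oscillates sinusoidally about its rest position.

    Residue i moves along a fixed random unit direction with amplitude A_i
    and random phase; its RMSF ground truth is A_i/√2.  When n_frames is a
    multiple of period_frames the sampled sin² averages to 1/2 exactly.
    """
    residues = structure.residues()
    if isinstance(amplitudes_A, dict):
        amps = np.array([amplitudes_A.get(r, 0.0) for r in residues], dtype=float)
    else:
        amps = np.broadcast_to(
            np.asarray(amplitudes_A, dtype=float), (len(residues),)
        ).copy()
    if np.any(amps < 0):
        raise ValueError("amplitudes must be non-negative")
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(len(residues), 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(residues))
    base = structure.coords
    res_index = structure.residue_index()
    frames = np.tile(base, (n_frames, 1, 1))
    t = np.arange(n_frames)
    for j, res in enumerate(residues):
        if amps[j] == 0.0:
            continue
        disp = amps[j] * np.sin(2.0 * np.pi * t / period_frames + phases[j])
        frames[:, res_index[res], :] += disp[:, None, None] * dirs[j]
    return TrajectoryWindow(times=t * dt_ps, frames=frames, box=None)


# ---------------------------------------------------------------------------
# Rigid-body motion (RMSD ground truth)
# ---------------------------------------------------------------------------


def random_rotations(n: int, seed: int = 0) -> np.ndarray:
    """(n, 3, 3) proper rotation matrices drawn uniformly (QR method)."""
    rng = np.random.default_rng(seed)
    out = np.empty((n, 3, 3))
    for k in range(n):
        m = rng.normal(size=(3, 3))
        q, r = np.linalg.qr(m)
        q = q @ np.diag(np.sign(np.diag(r)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        out[k] = q
    return out


def simulate_rigid_motion(
    structure: StructureModel,
    translations_A: np.ndarray,
    rotations: Optional[np.ndarray] = None,
    dt_ps: float = 10.0,
) -> TrajectoryWindow:
    """Frames are rigid transforms of the reference structure.

    Frame k = (x0 − centroid) @ R_kᵀ + centroid + t_k.  Superposed RMSD is
    0 by construction; unsuperposed RMSD equals |t_k| for pure translations.
    """
    trans = np.atleast_2d(np.asarray(translations_A, dtype=float))
    n_frames = len(trans)
    base = structure.coords
    centroid = base.mean(axis=0)
    centered = base - centroid
    frames = np.empty((n_frames, structure.n_atoms, 3))
    for k in range(n_frames):
        rot = np.eye(3) if rotations is None else rotations[k]
        frames[k] = centered @ rot.T + centroid + trans[k]
    return TrajectoryWindow(times=np.arange(n_frames) * dt_ps, frames=frames, box=None)


# ---------------------------------------------------------------------------
# Persistent random walks (migration ground truth)
# ---------------------------------------------------------------------------


def simulate_persistent_random_walk(
    n_tracks: int,
    n_steps: int,
    dt_min: float = 25.0,
    speed_um_per_min: float = 0.5,
    persistence: float = 0.5,
    seed: int = 0,
    condition: str = "sim",
) -> list[CellTrack]:
    """Constant-speed 2-D walks with tunable directional persistence.

    Turning angles are uniform on [−π(1−p), π(1−p)]: p = 0 is the unbiased
    random walk, p = 1 perfectly straight motion.  Every track's velocity is
    exactly the step speed.
    """
    p = float(persistence)
    if not 0.0 <= p <= 1.0:
        raise ValueError("persistence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    step = speed_um_per_min * dt_min
    half_width = np.pi * (1.0 - p)
    tracks: list[CellTrack] = []
    for i in range(n_tracks):
        theta0 = rng.uniform(0.0, 2.0 * np.pi)
        turns = rng.uniform(-half_width, half_width, size=n_steps - 1) if n_steps > 1 else np.array([])
        headings = theta0 + np.concatenate([[0.0], np.cumsum(turns)])
        dx = step * np.cos(headings)
        dy = step * np.sin(headings)
        x = np.concatenate([[0.0], np.cumsum(dx)])
        y = np.concatenate([[0.0], np.cumsum(dy)])
        t = np.arange(n_steps + 1) * dt_min
        tracks.append(CellTrack(cell_id=f"{condition}_{i:03d}", t=t, x=x, y=y))
    return tracks


# ---------------------------------------------------------------------------
# FixtureSpec dispatch
# ---------------------------------------------------------------------------


@dataclass
class FixtureSpec:
    """Declarative fixture request: kind + kind-specific parameters + seed."""

    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0


def generate(spec: FixtureSpec):
    """Dispatch a :class:`FixtureSpec` to its generator (deterministic)."""
    kinds = {
        "lattice_protein": lambda p: make_lattice_protein(**p),
        "ligand_diffusion": lambda p: simulate_ligand_diffusion(seed=spec.seed, **p),
        "harmonic": lambda p: simulate_harmonic_fluctuations(seed=spec.seed, **p),
        "rigid_motion": lambda p: simulate_rigid_motion(**p),
        "prw_tracks": lambda p: simulate_persistent_random_walk(seed=spec.seed, **p),
    }
    if spec.kind not in kinds:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    return kinds[spec.kind](dict(spec.parameters))
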