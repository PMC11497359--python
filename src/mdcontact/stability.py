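"""Domain-resolved trajectory stability metrics.

RMSD time series per named domain (each frame optimally superposed onto a
reference using the domain's selected atoms), per-residue RMSF about the
iteratively aligned mean structure, Tukey box statistics of RMSF per domain,
and the focal-by-co-compound matrix of time-averaged RMSD used to compare
systems.  Frames before the equilibration period (default 3 ns) are discarded
from every statistic.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .domain_model import DomainMap, StructureModel, assign_residue_domain

logger = logging.getLogger("mdcontact")

DEFAULT_EQUILIBRATION_PS = 3000.0


# ---------------------------------------------------------------------------
# Trajectory container and plain-text frame tables
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryWindow:
    """Time-ordered coordinate frames aligned to a structure's atom order.

    times are in ps (strictly increasing), frames an (n_frames, n_atoms, 3)
    array in Å, box per-frame orthorhombic lengths in Å (or None).
    """

    times: np.ndarray
    frames: np.ndarray
    box: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.ndim == 1:
                self.box = np.tile(self.box, (len(self.times), 1))
            if self.box.shape != (len(self.times), 3):
                raise ValueError("box must have shape (n_frames, 3)")
            if np.any(self.box <= 0):
                raise ValueError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def check_structure(self, structure: StructureModel) -> None:
        if self.n_atoms != structure.n_atoms:
            raise ValueError(
                f"trajectory has {self.n_atoms} atoms but structure has "
                f"{structure.n_atoms}"
            )

    def after(self, equilibration_ps: float) -> "TrajectoryWindow":
        """Sub-window of frames with time >= equilibration_ps."""
        mask = self.times >= equilibration_ps
        if not np.any(mask):
            raise ValueError(
                f"no frames at or after equilibration time {equilibration_ps} ps"
            )
        return TrajectoryWindow(
            times=self.times[mask],
            frames=self.frames[mask],
            box=None if self.box is None else self.box[mask],
        )


def write_frame_table(traj: TrajectoryWindow, structure: StructureModel) -> str:
    """Serialize a trajectory as a tidy CSV frame table.

    Columns: frame, time_ps, atom_id, x, y, z (Å) plus box_x/y/z when
    periodic.  Intended for small fixtures, not production trajectories.
    """
    traj.check_structure(structure)
    atom_ids = np.array([a.atom_id for a in structure.atoms])
    rows = []
    for k in range(traj.n_frames):
        df = pd.DataFrame(
            {
                "frame": k,
                "time_ps": traj.times[k],
                "atom_id": atom_ids,
                "x": traj.frames[k, :, 0],
                "y": traj.frames[k, :, 1],
                "z": traj.frames[k, :, 2],
            }
        )
        if traj.box is not None:
            df["box_x"], df["box_y"], df["box_z"] = traj.box[k]
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    buf = io.StringIO()
    out.to_csv(buf, index=False, float_format="%.6f")
    return buf.getvalue()


def read_frame_table(text_or_path, structure: StructureModel) -> TrajectoryWindow:
    """Read a frame table written by :func:`write_frame_table`.

    Atom rows are matched to the structure's atom order via atom_id.
    """
    if isinstance(text_or_path, str) and "\n" in text_or_path:
        df = pd.read_csv(io.StringIO(text_or_path))
    else:
        df = pd.read_csv(text_or_path)
    order = {a.atom_id: i for i, a in enumerate(structure.atoms)}
    times = []
    frames = []
    boxes = [] if "box_x" in df.columns else None
    for _, grp in df.groupby("frame", sort=True):
        times.append(float(grp["time_ps"].iloc[0]))
        coords = np.empty((structure.n_atoms, 3), dtype=float)
        idx = grp["atom_id"].map(order)
        if idx.isna().any():
            raise ValueError("frame table contains atom_ids absent from structure")
        coords[idx.to_numpy(dtype=int)] = grp[["x", "y", "z"]].to_numpy(dtype=float)
        frames.append(coords)
        if boxes is not None:
            boxes.append(grp[["box_x", "box_y", "box_z"]].iloc[0].to_numpy(dtype=float))
    return TrajectoryWindow(
        times=np.array(times),
        frames=np.array(frames),
        box=None if boxes is None else np.array(boxes),
    )


# ---------------------------------------------------------------------------
# Atom selections
# ---------------------------------------------------------------------------

SELECTIONS = ("ca", "backbone", "heavy", "all")
_BACKBONE_NAMES = {"N", "CA", "C", "O"}


def select_atoms(
    structure: StructureModel,
    selection: str = "ca",
    residues: Optional[Sequence[tuple[str, int]]] = None,
) -> np.ndarray:
    """Atom indices for a named selection, optionally restricted to residues.

    Selections: "ca" (Cα only), "backbone" (N/CA/C/O), "heavy" (non-H),
    "all".
    """
    if selection not in SELECTIONS:
        raise ValueError(f"unknown selection {selection!r}; choose from {SELECTIONS}")
    residue_set = None if residues is None else set(residues)
    idx = []
    for i, a in enumerate(structure.atoms):
        if residue_set is not None and (a.chain, a.residue_id) not in residue_set:
            continue
        if selection == "ca" and a.name != "CA":
            continue
        if selection == "backbone" and a.name not in _BACKBONE_NAMES:
            continue
        if selection == "heavy" and a.element.upper() in ("H", "D"):
            continue
        idx.append(i)
    return np.asarray(idx, dtype=int)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of *mobile* onto *reference* (SVD Kabsch).

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` minimizes the weighted RMSD to the
    reference; the rotation is proper (det = +1).  Requires at least three
    non-collinear reference points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 atoms")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    com_m = w @ mobile
    com_r = w @ reference
    pm = mobile - com_m
    pr = reference - com_r

    # Degenerate (collinear) reference leaves the rotation underdetermined.
    s_ref = np.linalg.svd(pr * np.sqrt(w)[:, None], compute_uv=False)
    if s_ref[1] <= 1e-10 * max(s_ref[0], 1.0):
        raise ValueError("degenerate (collinear) reference geometry")

    h = (pm * w[:, None]).T @ pr
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = com_r - rot @ com_m

    moved = pm @ rot.T
    msd = float(np.sum(w * np.sum((moved - pr) ** 2, axis=1)))
    return rot, trans, float(np.sqrt(max(msd, 0.0)))


def weighted_rmsd(a: np.ndarray, b: np.ndarray, weights: Optional[np.ndarray] = None) -> float:
    """Plain (unsuperposed) weighted RMSD between two coordinate sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.shape[0]
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights) / np.sum(weights)
    return float(np.sqrt(np.sum(w * np.sum((a - b) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# RMSD series per domain
# ---------------------------------------------------------------------------


@dataclass
class RMSDSeries:
    domain: str
    times: np.ndarray
    values: np.ndarray
    reference_time: float

    def mean(self) -> float:
        return float(np.mean(self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"domain": self.domain, "time_ps": self.times, "rmsd_A": self.values}
        )


def domain_rmsd_series(
    traj: TrajectoryWindow,
    structure: StructureModel,
    domain_map: DomainMap,
    domain: str,
    atom_selection: str = "ca",
    equilibration_ps: float = DEFAULT_EQUILIBRATION_PS,
    reference: Union[str, np.ndarray] = "first",
    superpose: bool = True,
) -> RMSDSeries:
    """RMSD time series of one domain after per-domain superposition.

    Each post-equilibration frame is superposed onto the reference using only
    the domain's selected atoms.  ``reference`` is "first" (the first
    post-equilibration frame) or an explicit (n_atoms, 3) coordinate array;
    ``superpose=False`` reports the raw (unfitted) RMSD instead.
    """
    traj.check_structure(structure)
    if domain not in domain_map.domains():
        raise ValueError(f"domain {domain!r} not in map")
    sel = select_atoms(structure, atom_selection, residues=domain_map.residues_in(domain))
    if len(sel) == 0:
        raise ValueError(f"empty atom selection for domain {domain!r}")
    window = traj.after(equilibration_ps)
    if isinstance(reference, str):
        if reference != "first":
            raise ValueError("reference must be 'first' or a coordinate array")
        ref = window.frames[0][sel]
        ref_time = float(window.times[0])
    else:
        reference = np.asarray(reference, dtype=float)
        ref = reference[sel] if reference.shape[0] == structure.n_atoms else reference
        ref_time = float("nan")
    values = np.empty(window.n_frames)
    for k in range(window.n_frames):
        mob = window.frames[k][sel]
        if superpose:
            _, _, values[k] = kabsch_superpose(mob, ref)
        else:
            values[k] = weighted_rmsd(mob, ref)
    return RMSDSeries(domain=domain, times=window.times, values=values, reference_time=ref_time)


# ---------------------------------------------------------------------------
# RMSF per residue
# ---------------------------------------------------------------------------


@dataclass
class RMSFProfile:
    """Per-residue root-mean-square fluctuation (Å)."""

    entries: list[tuple[str, int, float]]  # (chain, residue_id, rmsf)
    alignment: str

    def as_dict(self) -> dict[tuple[str, int], float]:
        return {(c, r): v for c, r, v in self.entries}

    def values(self) -> np.ndarray:
        return np.array([v for _, _, v in self.entries])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["chain", "residue", "rmsf_A"])


def residue_rmsf(
    traj: TrajectoryWindow,
    structure: StructureModel,
    atom_selection: str = "ca",
    equilibration_ps: float = DEFAULT_EQUILIBRATION_PS,
    align: bool = True,
    n_align_passes: int = 2,
) -> RMSFProfile:
    """Per-residue RMSF about the (optionally aligned) mean structure.

    With ``align=True`` frames are superposed onto a running-mean structure
    (two passes) before fluctuations are measured — the standard treatment
    when frames carry global rigid-body motion.  With ``align=False`` raw
    lab-frame fluctuations are used, appropriate when the input has no net
    translation/rotation by construction.  RMSF of a residue is the square
    root of the atom-averaged mean squared fluctuation over its selected
    atoms.
    """
    traj.check_structure(structure)
    sel = select_atoms(structure, atom_selection)
    if len(sel) == 0:
        raise ValueError("empty atom selection")
    window = traj.after(equilibration_ps)
    if window.n_frames < 2:
        raise ValueError("RMSF requires at least 2 post-equilibration frames")
    coords = window.frames[:, sel, :]  # (F, n_sel, 3)

    if align:
        ref = coords[0]
        aligned = coords
        for _ in range(n_align_passes):
            aligned = np.empty_like(coords)
            for k in range(coords.shape[0]):
                rot, trans, _ = kabsch_superpose(coords[k], ref)
                aligned[k] = coords[k] @ rot.T + trans
            ref = aligned.mean(axis=0)
        coords = aligned
        mean = ref
        descriptor = f"mean-structure ({n_align_passes}-pass), {atom_selection}"
    else:
        mean = coords.mean(axis=0)
        descriptor = f"unaligned, {atom_selection}"

    msf_atom = np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0)  # per sel atom

    # Aggregate selected atoms per residue: mean squared fluctuation, then sqrt.
    entries: list[tuple[str, int, float]] = []
    sel_atoms = [structure.atoms[i] for i in sel]
    by_res: dict[tuple[str, int], list[int]] = {}
    for j, a in enumerate(sel_atoms):
        by_res.setdefault((a.chain, a.residue_id), []).append(j)
    for (chain, rid), js in by_res.items():
        entries.append((chain, rid, float(np.sqrt(np.mean(msf_atom[js])))))
    return RMSFProfile(entries=entries, alignment=descriptor)


# ---------------------------------------------------------------------------
# Tukey box statistics per domain
# ---------------------------------------------------------------------------


@dataclass
class DomainBoxStats:
    domain: str
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[tuple[tuple[str, int], float]]
    n: int


def tukey_hinges(values: np.ndarray) -> tuple[float, float, float]:
    """(Q1, median, Q3) using Tukey's hinges (halves include the median when
    n is odd)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    med = float(np.median(x))
    half = (n + 1) // 2
    lower = x[:half]
    upper = x[n - half:]
    return float(np.median(lower)), med, float(np.median(upper))


def domain_rmsf_distribution(
    profile: RMSFProfile, domain_map: DomainMap
) -> list[DomainBoxStats]:
    """Tukey box statistics (whiskers at 1.5×IQR) of RMSF per domain.

    Residues outside every domain are excluded; a domain with no residues in
    the profile is omitted with a warning.
    """
    if not profile.entries:
        raise ValueError("empty RMSF profile")
    grouped: dict[str, list[tuple[tuple[str, int], float]]] = {
        d: [] for d in domain_map.domains()
    }
    for chain, rid, val in profile.entries:
        dom = assign_residue_domain(domain_map, chain, rid)
        if dom is not None:
            grouped[dom].append(((chain, rid), val))
    stats: list[DomainBoxStats] = []
    for dom in domain_map.domains():
        members = grouped[dom]
        if not members:
            logger.warning("domain %r has no residues in the RMSF profile: omitted", dom)
            continue
        vals = np.array([v for _, v in members])
        q1, med, q3 = tukey_hinges(vals)
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        whisk_lo = float(inside.min()) if len(inside) else q1
        whisk_hi = float(inside.max()) if len(inside) else q3
        outliers = [(res, float(v)) for res, v in members if v < lo_fence or v > hi_fence]
        stats.append(
            DomainBoxStats(
                domain=dom,
                median=med,
                q1=q1,
                q3=q3,
                whisker_low=whisk_lo,
                whisker_high=whisk_hi,
                outliers=outliers,
                n=len(vals),
            )
        )
    return stats


def box_stats_frame(stats: list[DomainBoxStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "domain": s.domain,
                "n": s.n,
                "median_A": s.median,
                "q1_A": s.q1,
                "q3_A": s.q3,
                "whisker_low_A": s.whisker_low,
                "whisker_high_A": s.whisker_high,
                "n_outliers": len(s.outliers),
            }
            for s in stats
        ]
    )


# ---------------------------------------------------------------------------
# Cross-system summary matrix
# ---------------------------------------------------------------------------


def rmsd_summary_matrix(
    systems: Sequence[tuple[str, Optional[str], RMSDSeries]],
) -> pd.DataFrame:
    """Time-averaged RMSD per (focal compound, co-compound) system.

    Diagonal cells hold single-compound systems (co-compound None or equal to
    the focal compound); duplicate cells are an error.  Missing cells are
    NaN.
    """
    cells: dict[tuple[str, str], float] = {}
    for focal, co, series in systems:
        col = focal if co is None else co
        key = (focal, col)
        if key in cells:
            raise ValueError(f"duplicate matrix cell {key}")
        cells[key] = series.mean()
    rows = sorted({r for r, _ in cells})
    cols = sorted({c for _, c in cells})
    mat = pd.DataFrame(np.nan, index=rows, columns=cols)
    for (r, c), v in cells.items():
        mat.loc[r, c] = v
    mat.index.name = "focal"
    mat.columns.name = "co_compound"
    return mat
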