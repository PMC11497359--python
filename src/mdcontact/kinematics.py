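"""Single-cell migration kinematics.

Tracks are planar (t, x, y) samples per cell, as exported by image-tracking
tools (e.g. 25-min phase-contrast frames over an 8 h window).  Per-track
statistics: velocity (accumulated path length over elapsed time, μm/min),
accumulated and Euclidean distance (μm), and directional persistence — the
directionality ratio Euclidean/accumulated, 1 for perfectly straight motion,
0 for a net return to the origin.  Two-group comparisons use the
Mann–Whitney U test (exact enumeration for small tie-free samples, normal
approximation with tie and continuity corrections otherwise).
"""

from __future__ import annotations

import io
import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger("mdcontact")


@dataclass
class CellTrack:
    """Ordered positions of one cell: t in minutes, x/y in μm."""

    cell_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) < 2:
            raise ValueError("a track needs at least 2 samples")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("track times must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class TrackStats:
    cell_id: str
    velocity: float  # μm/min
    accumulated: float  # μm
    euclidean: float  # μm
    persistence: Optional[float]  # euclidean/accumulated; None if undefined


def read_tracks(source) -> list[CellTrack]:
    """Read cell tracks from a delimited table with columns cell_id, t, x, y.

    Accepts a path, file-like object, or the table text itself; the delimiter
    (comma/tab/semicolon) is sniffed.  Rows are grouped by cell and sorted by
    time.  Non-numeric coordinates raise an error naming the data line;
    duplicate timestamps within a cell are rejected; cells with fewer than
    two samples are skipped with a warning.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}

    def pick(*names: str) -> str:
        for n in names:
            if n in cols:
                return cols[n]
        raise ValueError(f"missing required column (one of {names})")

    c_id = pick("cell_id", "cell", "track_id", "id")
    c_t = pick("t", "t_min", "time", "time_min")
    c_x = pick("x", "x_um")
    c_y = pick("y", "y_um")

    for col in (c_t, c_x, c_y):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad):
            # +2: one for the header line, one for 0-based indexing.
            raise ValueError(
                f"non-numeric value {df.loc[bad[0], col]!r} in column {col!r} "
                f"at line {int(bad[0]) + 2}"
            )
        df[col] = numeric

    tracks: list[CellTrack] = []
    for cid, grp in df.groupby(c_id, sort=False):
        grp = grp.sort_values(c_t)
        t = grp[c_t].to_numpy(dtype=float)
        if np.any(np.diff(t) == 0):
            raise ValueError(f"duplicate timestamps in cell {cid!r}")
        if len(grp) < 2:
            logger.warning("cell %r has fewer than 2 samples: skipped", cid)
            continue
        tracks.append(
            CellTrack(
                cell_id=str(cid),
                t=t,
                x=grp[c_x].to_numpy(dtype=float),
                y=grp[c_y].to_numpy(dtype=float),
            )
        )
    return tracks


def accumulated_distance(track: CellTrack) -> float:
    """Total path length: sum of consecutive planar step lengths (μm)."""
    steps = np.hypot(np.diff(track.x), np.diff(track.y))
    return float(np.sum(steps))


def euclidean_distance(track: CellTrack) -> float:
    """Straight-line distance between the first and last sample (μm)."""
    return float(np.hypot(track.x[-1] - track.x[0], track.y[-1] - track.y[0]))


def track_velocity(track: CellTrack) -> float:
    """Accumulated distance divided by elapsed time (μm/min)."""
    if track.duration <= 0:
        raise ValueError("track has zero duration")
    return accumulated_distance(track) / track.duration


def directional_persistence(track: CellTrack) -> Optional[float]:
    """Directionality ratio Euclidean/accumulated in [0, 1].

    Undefined (None) for a stationary track (accumulated distance 0).
    """
    acc = accumulated_distance(track)
    if acc == 0:
        return None
    return euclidean_distance(track) / acc


def track_stats(track: CellTrack) -> TrackStats:
    acc = accumulated_distance(track)
    euc = euclidean_distance(track)
    return TrackStats(
        cell_id=track.cell_id,
        velocity=track_velocity(track),
        accumulated=acc,
        euclidean=euc,
        persistence=None if acc == 0 else euc / acc,
    )


def stats_frame(tracks: Sequence[CellTrack], condition: Optional[str] = None) -> pd.DataFrame:
    """Tidy per-cell statistics table for a set of tracks."""
    rows = []
    for tr in tracks:
        s = track_stats(tr)
        row = {
            "cell_id": s.cell_id,
            "velocity_um_min": s.velocity,
            "accumulated_um": s.accumulated,
            "euclidean_um": s.euclidean,
            "persistence": np.nan if s.persistence is None else s.persistence,
        }
        if condition is not None:
            row = {"condition": condition, **row}
        rows.append(row)
    return pd.DataFrame(rows)


def condition_summary(stats: pd.DataFrame) -> pd.DataFrame:
    """Per-condition median velocity and mean persistence."""
    return (
        stats.groupby("condition")
        .agg(
            n_cells=("cell_id", "count"),
            median_velocity_um_min=("velocity_um_min", "median"),
            mean_persistence=("persistence", "mean"),
        )
        .reset_index()
    )


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------

EXACT_ENUMERATION_LIMIT = 12


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: pairwise wins, ties counting one half."""
    a = a[:, None]
    return float(np.sum(a > b) + 0.5 * np.sum(a == b))


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Mann–Whitney U test; returns (U of sample a, two-sided p).

    The p-value is exact (permutation enumeration over all label
    assignments) when n_a + n_b ≤ 12 and the pooled sample is tie-free;
    otherwise the normal approximation with tie correction and continuity
    correction is used.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = len(a), len(b)
    u_a = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)

    if na + nb <= EXACT_ENUMERATION_LIMIT and not has_ties:
        p = _exact_p(pooled, na, u_a)
    else:
        p = _normal_p(pooled, na, nb, u_a)
    return u_a, p


def _exact_p(pooled: np.ndarray, na: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating all C(n, na) label assignments."""
    n = len(pooled)
    idx = range(n)
    us = []
    for comb in itertools.combinations(idx, na):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        us.append(_u_statistic(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    nb = n - na
    u_other = na * nb - u_obs
    u_min = min(u_obs, u_other)
    p = 2.0 * np.mean(us <= u_min + 1e-12)
    return float(min(p, 1.0))


def _normal_p(pooled: np.ndarray, na: int, nb: int, u_obs: float) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n = na + nb
    mu = na * nb / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    # Continuity correction shrinks |U - mu| by 0.5.
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * norm.sf(z)))


def pairwise_tests(stats: pd.DataFrame, metric: str = "velocity_um_min") -> pd.DataFrame:
    """Mann–Whitney comparison of a metric between every pair of conditions."""
    conds = list(stats["condition"].unique())
    rows = []
    for i, ca in enumerate(conds):
        for cb in conds[i + 1 :]:
            va = stats.loc[stats["condition"] == ca, metric].dropna().to_numpy()
            vb = stats.loc[stats["condition"] == cb, metric].dropna().to_numpy()
            u, p = mann_whitney_u(va, vb)
            rows.append(
                {
                    "metric": metric,
                    "condition_a": ca,
                    "condition_b": cb,
                    "n_a": len(va),
                    "n_b": len(vb),
                    "U": u,
                    "p_two_sided": p,
                }
            )
    return pd.DataFrame(rows)
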