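"""End-to-end orchestration: config, report bundle, demo fixture bundle.

A run is described by a YAML config (paths to structures/trajectories per
system, a domain specification, analysis parameters, track tables) and
produces a directory of tidy CSVs — per-domain RMSD series, RMSF profiles
and box statistics, contact averages, competition matrices with
increase/decrease annotations, hotspot lists, B-factor annotated PDBs,
track statistics with pairwise Mann–Whitney tests — plus a manifest with a
checksum of every output.  Reruns on unchanged inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contacts import (
    amino_acid_type_profile,
    competition_matrix,
    contact_series,
    hotspot_residues,
    ligand_set_from_structure,
    write_bfactor_pdb,
)
from .domain_model import DomainMap, build_domain_map, parse_structure, write_pdb
from .kinematics import condition_summary, pairwise_tests, read_tracks, stats_frame
from .stability import (
    box_stats_frame,
    domain_rmsd_series,
    domain_rmsf_distribution,
    read_frame_table,
    residue_rmsf,
    rmsd_summary_matrix,
    write_frame_table,
)

logger = logging.getLogger("mdcontact")


@dataclass
class AnalysisParams:
    cutoff_nm: float = 0.7
    interval_ps: float = 100.0
    equilibration_ps: float = 3000.0
    atom_selection: str = "ca"
    hotspot_k: float = 1.0

    def validate(self) -> None:
        if self.cutoff_nm <= 0 or self.interval_ps <= 0:
            raise ValueError("cutoff and interval must be positive")
        if self.equilibration_ps < 0 or self.hotspot_k < 0:
            raise ValueError("equilibration and hotspot k must be non-negative")


@dataclass
class SystemConfig:
    name: str
    focal: str
    co: Optional[str]
    structure: str
    trajectory: str
    ligands: dict  # species -> {chain: ..., residue_name: ...}


@dataclass
class RunConfig:
    output_dir: str
    domains: list = field(default_factory=list)
    systems: list = field(default_factory=list)  # list[SystemConfig]
    tracks: list = field(default_factory=list)  # list[{condition, path}]
    params: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0
    base_dir: Path = field(default_factory=Path)


def load_config(path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    params = AnalysisParams(**raw.get("parameters", {}))
    params.validate()
    systems = [
        SystemConfig(
            name=s["name"],
            focal=s["focal"],
            co=s.get("co"),
            structure=s["structure"],
            trajectory=s["trajectory"],
            ligands=s.get("ligands", {}),
        )
        for s in raw.get("systems", [])
    ]
    return RunConfig(
        output_dir=raw["output_dir"],
        domains=raw.get("domains", []),
        systems=systems,
        tracks=raw.get("tracks", []),
        params=params,
        seed=int(raw.get("seed", 0)),
        base_dir=path.parent,
    )


def _domain_map(config: RunConfig) -> Optional[DomainMap]:
    if not config.domains:
        return None
    return build_domain_map(
        [(d["domain"], d["chain"], d["ranges"]) for d in config.domains]
    )


def _resolve(config: RunConfig, rel: str) -> Path:
    p = Path(rel)
    if not p.is_absolute():
        p = config.base_dir / p
    if not p.exists():
        raise FileNotFoundError(f"missing input: {p}")
    return p


def _param_header(params: AnalysisParams) -> str:
    return (
        f"# mdcontact {__version__}; cutoff_nm={params.cutoff_nm}; "
        f"interval_ps={params.interval_ps}; "
        f"equilibration_ps={params.equilibration_ps}; "
        f"selection={params.atom_selection}; hotspot_k={params.hotspot_k}\n"
    )


def _write_csv(path: Path, df: pd.DataFrame, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.6f")


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage and write the report bundle + manifest."""
    config.params.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = _param_header(config.params)
    written: list[Path] = []
    domain_map = _domain_map(config)
    p = config.params

    if config.systems:
        if domain_map is None:
            raise ValueError("systems configured but no domain specification given")
        rmsd_rows, rmsf_rows, box_rows = [], [], []
        rmsd_by_domain: dict[str, list] = {d: [] for d in domain_map.domains()}
        contact_frames = []
        profile_frames = []
        hotspot_rows = []
        system_series = []
        for sys_cfg in config.systems:
            structure = parse_structure(_resolve(config, sys_cfg.structure).read_text())
            traj = read_frame_table(str(_resolve(config, sys_cfg.trajectory)), structure)
            # Stability per domain
            for dom in domain_map.domains():
                series = domain_rmsd_series(
                    traj,
                    structure,
                    domain_map,
                    dom,
                    atom_selection=p.atom_selection,
                    equilibration_ps=p.equilibration_ps,
                )
                df = series.to_frame()
                df.insert(0, "system", sys_cfg.name)
                rmsd_rows.append(df)
                rmsd_by_domain[dom].append((sys_cfg.focal, sys_cfg.co, series))
            profile = residue_rmsf(
                traj,
                structure,
                atom_selection=p.atom_selection,
                equilibration_ps=p.equilibration_ps,
            )
            df = profile.to_frame()
            df.insert(0, "system", sys_cfg.name)
            rmsf_rows.append(df)
            bs = box_stats_frame(domain_rmsf_distribution(profile, domain_map))
            bs.insert(0, "system", sys_cfg.name)
            box_rows.append(bs)
            # Contacts
            ligands = [
                ligand_set_from_structure(
                    structure,
                    species,
                    chain=lg.get("chain"),
                    residue_name=lg.get("residue_name"),
                )
                for species, lg in sys_cfg.ligands.items()
            ]
            if ligands:
                residues = [
                    r
                    for d in domain_map.domains()
                    for r in domain_map.residues_in(d)
                    if r in structure.residue_index()
                ]
                series = contact_series(
                    traj,
                    structure,
                    residues,
                    ligands,
                    interval_ps=p.interval_ps,
                    equilibration_ps=p.equilibration_ps,
                    cutoff_nm=p.cutoff_nm,
                )
                system_series.append((sys_cfg, series))
                df = series.to_frame()
                df.insert(0, "system", sys_cfg.name)
                contact_frames.append(df)
                prof = amino_acid_type_profile(series, structure)
                prof.insert(0, "system", sys_cfg.name)
                profile_frames.append(prof)
                hot = hotspot_residues(series, k=p.hotspot_k, species=sys_cfg.focal)
                for chain, rid in sorted(hot):
                    hotspot_rows.append(
                        {
                            "system": sys_cfg.name,
                            "species": sys_cfg.focal,
                            "chain": chain,
                            "residue": rid,
                        }
                    )
                pdb_path = outdir / f"bfactor_{sys_cfg.name}_{sys_cfg.focal}.pdb"
                pdb_path.write_text(write_bfactor_pdb(structure, series, sys_cfg.focal))
                written.append(pdb_path)

        for name, frames in (
            ("rmsd_series.csv", rmsd_rows),
            ("rmsf_profile.csv", rmsf_rows),
            ("rmsf_box_stats.csv", box_rows),
            ("contact_averages.csv", contact_frames),
            ("residue_type_profile.csv", profile_frames),
        ):
            if frames:
                path = outdir / name
                _write_csv(path, pd.concat(frames, ignore_index=True), header)
                written.append(path)
        if hotspot_rows:
            path = outdir / "hotspots.csv"
            _write_csv(path, pd.DataFrame(hotspot_rows), header)
            written.append(path)
        # Cross-system matrices
        for dom in domain_map.domains():
            mat = rmsd_summary_matrix(rmsd_by_domain[dom])
            path = outdir / f"rmsd_matrix_{dom}.csv"
            with open(path, "w") as fh:
                fh.write(header)
                mat.to_csv(fh, float_format="%.6f")
            written.append(path)
        if system_series:
            systems_for_matrix = [
                (s.focal, s.co, series) for s, series in system_series
            ]
            for dom in domain_map.domains():
                dcm = competition_matrix(systems_for_matrix, domain_map, dom)
                path = outdir / f"competition_{dom}.csv"
                _write_csv(path, dcm.to_frame(), header)
                written.append(path)

    if config.tracks:
        all_stats = []
        for tr in config.tracks:
            tracks = read_tracks(str(_resolve(config, tr["path"])))
            all_stats.append(stats_frame(tracks, condition=tr["condition"]))
        stats = pd.concat(all_stats, ignore_index=True)
        path = outdir / "track_stats.csv"
        _write_csv(path, stats, header)
        written.append(path)
        path = outdir / "track_summary.csv"
        _write_csv(path, condition_summary(stats), header)
        written.append(path)
        if stats["condition"].nunique() > 1:
            tests = pd.concat(
                [
                    pairwise_tests(stats, metric="velocity_um_min"),
                    pairwise_tests(stats, metric="persistence"),
                ],
                ignore_index=True,
            )
            path = outdir / "track_tests.csv"
            _write_csv(path, tests, header)
            written.append(path)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "cutoff_nm": p.cutoff_nm,
            "interval_ps": p.interval_ps,
            "equilibration_ps": p.equilibration_ps,
            "atom_selection": p.atom_selection,
            "hotspot_k": p.hotspot_k,
        },
        "outputs": {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in sorted(written)
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def render_tables(outdir) -> str:
    """Human-readable summary of a report bundle's main tables."""
    outdir = Path(outdir)
    if not outdir.exists():
        raise FileNotFoundError(f"no report bundle at {outdir}")
    chunks: list[str] = []
    for comp in sorted(outdir.glob("competition_*.csv")):
        df = pd.read_csv(comp, comment="#")
        chunks.append(f"== {comp.stem} ==")
        for _, row in df.iterrows():
            flag = f" [{row['annotation']}]" if isinstance(row.get("annotation"), str) and row["annotation"] else ""
            chunks.append(
                f"  {row['focal']:>10s} with {row['co_compound']:<10s} "
                f"C_domain = {row['c_domain']:.3f}{flag}"
            )
    box = outdir / "rmsf_box_stats.csv"
    if box.exists():
        df = pd.read_csv(box, comment="#")
        chunks.append("== RMSF box statistics (Å) ==")
        for _, row in df.iterrows():
            chunks.append(
                f"  {row['system']:>12s} {row['domain']:<8s} median {row['median_A']:.3f} "
                f"IQR [{row['q1_A']:.3f}, {row['q3_A']:.3f}] outliers {int(row['n_outliers'])}"
            )
    summ = outdir / "track_summary.csv"
    if summ.exists():
        df = pd.read_csv(summ, comment="#")
        chunks.append("== Migration summary ==")
        for _, row in df.iterrows():
            chunks.append(
                f"  {row['condition']:>12s} n={int(row['n_cells'])} "
                f"median v = {row['median_velocity_um_min']:.3f} um/min, "
                f"mean persistence = {row['mean_persistence']:.3f}"
            )
    return "\n".join(chunks) + ("\n" if chunks else "")


# ---------------------------------------------------------------------------
# Demo fixture bundle
# ---------------------------------------------------------------------------


def write_demo_bundle(outdir, seed: int = 0, n_frames: int = 201) -> Path:
    """Write a self-contained synthetic input bundle plus a ready config.

    Three ligand systems around a 60-residue lattice protein with two
    domains (one species tethered to each domain, plus their binary
    mixture) and two migration conditions of 40 persistent-random-walk
    tracks each.  Returns the config path.
    """
    from .synthetic import (
        SpeciesParams,
        make_lattice_protein,
        simulate_ligand_mixture,
        simulate_persistent_random_walk,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    box = 80.0
    protein, _ = make_lattice_protein(
        60,
        spacing_A=8.0,
        domain_splits={"D1": [[1, 30]], "D2": [[31, 60]]},
        center=(box / 2, box / 2, box / 2),
    )
    spec_a = SpeciesParams(
        n_copies=5, mode="tethered", tether_residue=("A", 5), bound_fraction=0.9
    )
    spec_b = SpeciesParams(
        n_copies=5, mode="tethered", tether_residue=("A", 45), bound_fraction=0.5
    )
    systems_cfg = []
    compositions = [
        ("cmpA_alone", {"cmpA": spec_a}, "cmpA", None),
        ("cmpB_alone", {"cmpB": spec_b}, "cmpB", None),
        ("cmpA_with_cmpB", {"cmpA": spec_a, "cmpB": spec_b}, "cmpA", "cmpB"),
        ("cmpB_with_cmpA", {"cmpB": spec_b, "cmpA": spec_a}, "cmpB", "cmpA"),
    ]
    for name, params, focal, co in compositions:
        sys_seed = int(rng.integers(0, 2**31 - 1))
        combined, traj, sets = simulate_ligand_mixture(
            protein, box, params, n_frames=n_frames, dt_ps=100.0, seed=sys_seed,
            protein_wobble_A=0.3,
        )
        struct_path = outdir / f"{name}.pdb"
        struct_path.write_text(write_pdb(combined))
        traj_path = outdir / f"{name}_traj.csv"
        traj_path.write_text(write_frame_table(traj, combined))
        lig_cfg = {
            ls.species: {"chain": combined.atoms[int(ls.copies[0][0])].chain}
            for ls in sets
        }
        systems_cfg.append(
            {
                "name": name,
                "focal": focal,
                "co": co,
                "structure": struct_path.name,
                "trajectory": traj_path.name,
                "ligands": lig_cfg,
            }
        )

    track_cfg = []
    for cond, p_persist, speed in (("control", 0.7, 0.6), ("treated", 0.3, 0.3)):
        tracks = simulate_persistent_random_walk(
            n_tracks=40,
            n_steps=19,
            dt_min=25.0,
            speed_um_per_min=speed,
            persistence=p_persist,
            seed=int(rng.integers(0, 2**31 - 1)),
            condition=cond,
        )
        rows = []
        for tr in tracks:
            for t, x, y in zip(tr.t, tr.x, tr.y):
                rows.append({"cell_id": tr.cell_id, "t": t, "x": x, "y": y})
        path = outdir / f"tracks_{cond}.csv"
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")
        track_cfg.append({"condition": cond, "path": path.name})

    config = {
        "output_dir": str(outdir / "report"),
        "seed": seed,
        "domains": [
            {"domain": "D1", "chain": "A", "ranges": [[1, 30]]},
            {"domain": "D2", "chain": "A", "ranges": [[31, 60]]},
        ],
        "parameters": {
            "cutoff_nm": 0.7,
            "interval_ps": 100.0,
            "equilibration_ps": 3000.0,
            "atom_selection": "ca",
            "hotspot_k": 1.0,
        },
        "systems": systems_cfg,
        "tracks": track_cfg,
    }
    config_path = outdir / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return config_path
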