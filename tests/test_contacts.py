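"""Contact counting, domain aggregation, competition matrices, hotspots."""

import numpy as np
import pytest

from mdcontact import (
    Atom,
    ContactSeries,
    StructureModel,
    TrajectoryWindow,
    amino_acid_type_profile,
    build_domain_map,
    competition_matrix,
    contact_series,
    domain_contact_number,
    hotspot_residues,
    ligand_set_from_structure,
    make_glycine,
    make_lattice_protein,
    parse_structure,
    residue_com,
    simulate_ligand_diffusion,
    transient_contact_count,
    write_bfactor_pdb,
)
from mdcontact.contacts import LigandSet, minimum_image_distance
from mdcontact.domain_model import resolve_mass


def _atom(i, coords, chain="A", rid=1, name="CA", element="C", resname="ALA", mass=None):
    return Atom(
        atom_id=i,
        name=name,
        element=element,
        mass=resolve_mass(element) if mass is None else mass,
        chain=chain,
        residue_id=rid,
        residue_name=resname,
        coords=tuple(coords),
        bfactor=0.0,
    )


def _protein_with_ligands(n_residues, ligand_positions, spacing=8.0, center=None):
    """Lattice protein plus one single-atom ligand copy per given position."""
    protein, dmap = make_lattice_protein(n_residues, spacing_A=spacing, center=center)
    atoms = list(protein.atoms)
    nxt = n_residues + 1
    for k, pos in enumerate(ligand_positions):
        atoms.append(
            _atom(nxt, pos, chain="L", rid=k + 1, name="C1", resname="LIG", mass=100.0)
        )
        nxt += 1
    combined = StructureModel(atoms=atoms)
    lig = LigandSet(
        species="LIG",
        copies=[np.array([n_residues + k]) for k in range(len(ligand_positions))],
        masses=combined.masses,
    )
    return combined, dmap, lig


def brute_force_counts(frame, structure, residues, ligand, cutoff_A, box):
    """Independent all-pairs O(N*M) contact scan with explicit direct sums."""
    out = []
    res_index = structure.residue_index()
    masses = structure.masses
    for chain, rid in residues:
        idx = res_index[(chain, rid)]
        num = np.zeros(3)
        den = 0.0
        for i in idx:
            num += masses[i] * frame[i]
            den += masses[i]
        rcom = num / den
        count = 0
        for copy in ligand.copies:
            cnum = np.zeros(3)
            cden = 0.0
            for i in copy:
                cnum += masses[i] * frame[i]
                cden += masses[i]
            d = cnum / cden - rcom
            if box is not None:
                d = d - box * np.round(d / box)
            if np.sqrt(np.sum(d * d)) < cutoff_A:
                count += 1
        out.append(count)
    return np.array(out)


class TestResidueCOM:
    def test_equal_masses(self):
        s = StructureModel(
            atoms=[_atom(1, (0, 0, 0)), _atom(2, (2, 0, 0))]
        )
        assert residue_com(s.coords, s, "A", 1) == pytest.approx([1.0, 0.0, 0.0])

    def test_weighted_mean(self):
        s = StructureModel(
            atoms=[
                _atom(1, (0, 0, 0), mass=12.0),
                _atom(2, (13, 0, 0), name="H", element="H", mass=1.0),
            ]
        )
        assert residue_com(s.coords, s, "A", 1)[0] == pytest.approx(1.0)

    def test_glycine_matches_direct_sum(self):
        s = make_glycine(origin=(3.0, -1.0, 2.0))
        com = residue_com(s.coords, s, "A", 1)
        direct = np.zeros(3)
        total = 0.0
        for a in s.atoms:
            direct += a.mass * np.asarray(a.coords)
            total += a.mass
        assert np.abs(com - direct / total).max() < 1e-10

    def test_missing_residue(self):
        s = make_glycine()
        with pytest.raises(ValueError, match="no residue"):
            residue_com(s.coords, s, "A", 99)


class TestTransientContactCount:
    def test_coincident_com_counts_one(self):
        combined, _, lig = _protein_with_ligands(4, [(0.0, 0.0, 0.0)])
        # put the ligand exactly on residue 1's position
        frame = combined.coords
        frame[4] = frame[0]
        assert transient_contact_count(frame, combined, "A", 1, lig) == 1

    def test_exact_cutoff_excluded(self):
        combined, _, lig = _protein_with_ligands(4, [(0.0, 0.0, 0.0)])
        frame = combined.coords
        frame[4] = frame[0] + np.array([7.0, 0.0, 0.0])  # exactly 0.7 nm
        assert transient_contact_count(frame, combined, "A", 1, lig) == 0
        frame[4] = frame[0] + np.array([6.999, 0.0, 0.0])
        assert transient_contact_count(frame, combined, "A", 1, lig) == 1

    def test_empty_ligand_distance_shortcut(self):
        combined, _, lig = _protein_with_ligands(4, [(100.0, 100.0, 100.0)])
        assert transient_contact_count(combined.coords, combined, "A", 1, lig) == 0

    def test_cutoff_monotonicity(self, rng):
        combined, _, lig = _protein_with_ligands(
            8, rng.uniform(0, 40, size=(6, 3)), spacing=6.0
        )
        frame = combined.coords
        counts = [
            transient_contact_count(frame, combined, "A", 1, lig, cutoff_nm=c)
            for c in (0.3, 0.5, 0.7, 1.0, 2.0, 5.0)
        ]
        assert counts == sorted(counts)

    def test_matches_brute_force_on_random_frames(self, rng):
        """k-d tree counts equal the all-pairs scan exactly, 100 frames."""
        box = np.array([137.0, 137.0, 137.0])
        protein, _ = make_lattice_protein(50, spacing_A=8.0, center=box / 2)
        comb, traj, lig = simulate_ligand_diffusion(
            protein, 137.0, n_copies=10, n_frames=100, dt_ps=100.0, seed=17
        )
        residues = protein.residues()
        series = contact_series(
            traj, comb, residues, [lig], interval_ps=100.0, equilibration_ps=0.0
        )
        for g in range(traj.n_frames):
            expected = brute_force_counts(
                traj.frames[g], comb, residues, lig, 7.0, box
            )
            assert np.array_equal(series.counts["LIG"][g], expected)

    def test_pbc_full_box_translation_invariance(self):
        box = np.array([50.0, 50.0, 50.0])
        protein, _ = make_lattice_protein(8, spacing_A=6.0, center=box / 2)
        comb, traj, lig = simulate_ligand_diffusion(
            protein, 50.0, n_copies=5, n_frames=20, dt_ps=100.0, seed=3
        )
        series = contact_series(
            traj, comb, protein.residues(), [lig], equilibration_ps=0.0
        )
        shifted_frames = traj.frames.copy()
        lig_idx = np.concatenate(lig.copies)
        shifted_frames[:, lig_idx, :] += box  # one full box vector
        shifted = TrajectoryWindow(times=traj.times, frames=shifted_frames, box=traj.box)
        series2 = contact_series(
            shifted, comb, protein.residues(), [lig], equilibration_ps=0.0
        )
        assert np.array_equal(series.counts["LIG"], series2.counts["LIG"])

    def test_minimum_image_distance(self):
        box = np.array([10.0, 10.0, 10.0])
        d = minimum_image_distance(np.array([9.5, 0, 0]), np.array([0.5, 0, 0]), box)
        assert d == pytest.approx(1.0)


class TestContactSeries:
    def test_permanent_contact_average_one(self):
        protein, _ = make_lattice_protein(4, center=(40, 40, 40))
        comb, traj, lig = simulate_ligand_diffusion(
            protein,
            80.0,
            n_copies=1,
            n_frames=30,
            seed=1,
            mode="tethered",
            tether_residue=("A", 2),
            bound_fraction=1.0,
        )
        series = contact_series(traj, comb, protein.residues(), [lig], equilibration_ps=0)
        assert series.average_map("LIG")[("A", 2)] == pytest.approx(1.0)

    def test_half_occupancy_alternating(self):
        protein, _ = make_lattice_protein(4, center=(40, 40, 40))
        comb, traj, lig = simulate_ligand_diffusion(
            protein,
            80.0,
            n_copies=1,
            n_frames=30,
            seed=2,
            mode="tethered",
            tether_residue=("A", 2),
            bound_fraction=0.5,
        )
        series = contact_series(traj, comb, protein.residues(), [lig], equilibration_ps=0)
        avg = series.average_map("LIG")[("A", 2)]
        # Direct mean over the deterministic alternating schedule.
        direct = np.mean(
            [
                transient_contact_count(traj.frames[k], comb, "A", 2, lig)
                for k in range(traj.n_frames)
            ]
        )
        assert avg == pytest.approx(direct) == pytest.approx(0.5)

    def test_no_grid_time_before_equilibration(self):
        protein, _ = make_lattice_protein(4)
        comb, traj, lig = simulate_ligand_diffusion(
            protein, 60.0, n_copies=2, n_frames=60, dt_ps=100.0, seed=4
        )
        series = contact_series(
            traj, comb, protein.residues(), [lig], equilibration_ps=3000.0
        )
        assert series.grid_times.min() >= 3000.0

    def test_equilibration_discard_matches_pretrim(self):
        protein, _ = make_lattice_protein(6, center=(30, 30, 30))
        comb, traj, lig = simulate_ligand_diffusion(
            protein, 60.0, n_copies=4, n_frames=60, dt_ps=100.0, seed=5
        )
        full = contact_series(
            traj, comb, protein.residues(), [lig], equilibration_ps=3000.0
        )
        trimmed = contact_series(
            traj.after(3000.0), comb, protein.residues(), [lig], equilibration_ps=3000.0
        )
        assert np.array_equal(full.counts["LIG"], trimmed.counts["LIG"])

    def test_grid_tie_resolves_to_earlier_frame(self):
        from mdcontact.contacts import grid_frame_indices

        times = np.array([0.0, 50.0, 100.0, 150.0, 200.0])
        grid, idx = grid_frame_indices(times, interval_ps=100.0, equilibration_ps=50.0)
        assert np.array_equal(grid, [50.0, 150.0])
        assert np.array_equal(times[idx], [50.0, 150.0])
        # Midpoint tie between stored frames resolves to the earlier frame.
        times2 = np.array([0.0, 100.0, 200.0])
        grid2, idx2 = grid_frame_indices(times2, interval_ps=50.0, equilibration_ps=0.0)
        assert np.array_equal(grid2, [0.0, 50.0, 100.0, 150.0, 200.0])
        assert np.array_equal(times2[idx2], [0.0, 0.0, 100.0, 100.0, 200.0])
        # Frames before equilibration never contribute, even on a tie.
        grid3, idx3 = grid_frame_indices(times2, interval_ps=50.0, equilibration_ps=50.0)
        assert times2[idx3[0]] == 100.0

    def test_bad_interval(self):
        protein, _ = make_lattice_protein(4)
        comb, traj, lig = simulate_ligand_diffusion(protein, 60.0, n_copies=1, n_frames=5)
        with pytest.raises(ValueError, match="interval"):
            contact_series(traj, comb, protein.residues(), [lig], interval_ps=0.0,
                           equilibration_ps=0.0)


def _series_from_counts(residues, counts, species="X"):
    counts = np.asarray(counts)
    return ContactSeries(
        grid_times=np.arange(counts.shape[0]) * 100.0,
        residues=list(residues),
        counts={species: counts},
        cutoff_nm=0.7,
        interval_ps=100.0,
        equilibration_ps=0.0,
    )


class TestDomainContactNumber:
    def test_single_residue_domain(self):
        dmap = build_domain_map([("D", "A", [(1, 1)])])
        series = _series_from_counts([("A", 1)], [[1], [0]])
        assert domain_contact_number(series, dmap, "D", "X") == pytest.approx(0.5)

    def test_sum_of_averages(self):
        dmap = build_domain_map([("D", "A", [(1, 3)])])
        series = _series_from_counts(
            [("A", 1), ("A", 2), ("A", 3)],
            [[1, 2, 0], [0, 1, 0], [0, 1, 0], [1, 1, 0]],
        )
        # averages: 0.5, 1.25, 0
        assert domain_contact_number(series, dmap, "D", "X") == pytest.approx(1.75)

    def test_additivity_over_partitions(self, rng):
        residues = [("A", i) for i in range(1, 13)]
        counts = rng.integers(0, 4, size=(25, 12))
        whole = build_domain_map([("all", "A", [(1, 12)])])
        parts = build_domain_map(
            [("p1", "A", [(1, 4)]), ("p2", "A", [(5, 9)]), ("p3", "A", [(10, 12)])]
        )
        series = _series_from_counts(residues, counts)
        total = domain_contact_number(series, whole, "all", "X")
        split = sum(
            domain_contact_number(series, parts, d, "X") for d in ("p1", "p2", "p3")
        )
        assert total == pytest.approx(split, abs=1e-12)

    def test_exceeds_copy_count_with_multi_contacts(self):
        """One ligand copy simultaneously inside the cutoff of 4 residues."""
        protein, dmap = make_lattice_protein(4, spacing_A=8.0)
        # Residues form an 8x8 square; its center is 5.66 A from each corner.
        center = protein.coords.mean(axis=0)
        atoms = list(protein.atoms) + [
            _atom(5, center, chain="L", rid=1, name="C1", resname="LIG", mass=100.0)
        ]
        comb = StructureModel(atoms=atoms)
        lig = LigandSet(species="LIG", copies=[np.array([4])], masses=comb.masses)
        traj = TrajectoryWindow(
            times=np.array([0.0, 100.0]), frames=np.array([comb.coords, comb.coords])
        )
        series = contact_series(traj, comb, protein.residues(), [lig], equilibration_ps=0)
        c_dom = domain_contact_number(series, dmap, "D1", "LIG")
        assert c_dom == pytest.approx(4.0)
        assert c_dom > lig.n_copies


class TestCompetitionMatrix:
    def test_decrease_annotation(self):
        dmap = build_domain_map([("D", "A", [(1, 1)])])
        alone = _series_from_counts([("A", 1)], [[2], [2]], species="X")
        mixed = _series_from_counts([("A", 1)], [[1], [1]], species="X")
        mixed.counts["Y"] = np.array([[0], [0]])
        dcm = competition_matrix([("X", None, alone), ("X", "Y", mixed)], dmap, "D")
        assert dcm.values.loc["X", "X"] == pytest.approx(2.0)
        assert dcm.values.loc["X", "Y"] == pytest.approx(1.0)
        assert dcm.annotations.loc["X", "Y"] == "decrease"
        assert dcm.annotations.loc["X", "X"] == "diagonal"

    def test_full_cross_layout(self):
        dmap = build_domain_map([("D", "A", [(1, 1)])])
        species = ["a", "b", "c", "d", "e"]
        systems = []
        for i, f in enumerate(species):
            for j, c in enumerate(species):
                s = _series_from_counts([("A", 1)], [[i + j]], species=f)
                systems.append((f, None if f == c else c, s))
        dcm = competition_matrix(systems, dmap, "D")
        assert dcm.values.shape == (5, 5)
        for sp in species:
            assert dcm.annotations.loc[sp, sp] == "diagonal"

    def test_single_system(self):
        dmap = build_domain_map([("D", "A", [(1, 1)])])
        s = _series_from_counts([("A", 1)], [[1]], species="X")
        dcm = competition_matrix([("X", None, s)], dmap, "D")
        assert dcm.values.shape == (1, 1)

    def test_duplicate_cell_rejected(self):
        dmap = build_domain_map([("D", "A", [(1, 1)])])
        s = _series_from_counts([("A", 1)], [[1]], species="X")
        with pytest.raises(ValueError, match="duplicate"):
            competition_matrix([("X", "Y", s), ("X", "Y", s)], dmap, "D")

    def test_missing_diagonal_suppresses_annotations(self, caplog):
        dmap = build_domain_map([("D", "A", [(1, 1)])])
        s = _series_from_counts([("A", 1)], [[1]], species="X")
        with caplog.at_level("WARNING", logger="mdcontact"):
            dcm = competition_matrix([("X", "Y", s)], dmap, "D")
        assert dcm.annotations.loc["X", "Y"] == ""
        assert any("diagonal" in r.message for r in caplog.records)


class TestResidueTypeProfile:
    def test_uniform_type_equals_global(self):
        protein, _ = make_lattice_protein(5)
        series = _series_from_counts(protein.residues(), [[1, 0, 2, 0, 1]])
        prof = amino_acid_type_profile(series, protein)
        assert len(prof) == 1
        row = prof.iloc[0]
        assert row["mean_avg_contacts"] == pytest.approx(row["global_mean"])

    def test_enriched_type_above_global(self):
        types = ["ALA", "GLY", "ALA", "GLY", "ALA"]
        protein, _ = make_lattice_protein(5, residue_types=types)
        series = _series_from_counts(protein.residues(), [[3, 0, 3, 0, 3]])
        prof = amino_acid_type_profile(series, protein).set_index("residue_type")
        assert prof.loc["ALA", "mean_avg_contacts"] > prof.loc["ALA", "global_mean"]
        assert prof.loc["GLY", "mean_avg_contacts"] == 0.0
        # Verified against direct averaging.
        assert prof.loc["ALA", "mean_avg_contacts"] == pytest.approx(3.0)

    def test_no_contacts_all_zero(self):
        protein, _ = make_lattice_protein(4)
        series = _series_from_counts(protein.residues(), np.zeros((3, 4), dtype=int))
        prof = amino_acid_type_profile(series, protein)
        assert (prof["mean_avg_contacts"] == 0.0).all()


class TestHotspots:
    def test_uniform_empty(self):
        residues = [("A", i) for i in range(1, 6)]
        series = _series_from_counts(residues, np.ones((4, 5), dtype=int))
        assert hotspot_residues(series, k=1.0) == set()

    def test_dominant_residue_only(self):
        residues = [("A", i) for i in range(1, 11)]
        counts = np.ones((10, 10), dtype=int)
        counts[:, 4] = 10
        series = _series_from_counts(residues, counts)
        avg = series.averages("X")
        assert avg[4] > avg.mean() + np.std(avg)  # direct mean/sd check
        assert hotspot_residues(series, k=1.0) == {("A", 5)}

    def test_k_zero_above_mean(self):
        residues = [("A", i) for i in range(1, 5)]
        series = _series_from_counts(residues, [[0, 1, 2, 3]])
        assert hotspot_residues(series, k=0.0) == {("A", 3), ("A", 4)}

    def test_negative_k_rejected(self):
        series = _series_from_counts([("A", 1)], [[1]])
        with pytest.raises(ValueError):
            hotspot_residues(series, k=-1.0)


class TestBFactorPDB:
    def test_zero_contacts_zero_bfactors(self):
        protein, _ = make_lattice_protein(3)
        series = _series_from_counts(protein.residues(), np.zeros((2, 3), dtype=int))
        text = write_bfactor_pdb(protein, series, "X")
        for line in text.splitlines():
            if line.startswith("ATOM"):
                assert line[60:66] == "  0.00"

    def test_half_contact_formatting(self):
        protein, _ = make_lattice_protein(2)
        series = _series_from_counts(protein.residues(), [[1, 0], [0, 0]])
        text = write_bfactor_pdb(protein, series, "X")
        lines = [l for l in text.splitlines() if l.startswith("ATOM")]
        assert lines[0][60:66] == "  0.50"

    def test_roundtrip_recovers_averages(self, rng):
        protein, _ = make_lattice_protein(20)
        counts = rng.integers(0, 5, size=(7, 20))
        series = _series_from_counts(protein.residues(), counts)
        text = write_bfactor_pdb(protein, series, "X")
        reread = parse_structure(text)
        avg = series.average_map("X")
        for a in reread.atoms:
            assert a.bfactor == pytest.approx(avg[(a.chain, a.residue_id)], abs=0.01)

    def test_missing_residue_defaults_zero(self):
        protein, _ = make_lattice_protein(3)
        series = _series_from_counts([("A", 1)], [[2]])
        reread = parse_structure(write_bfactor_pdb(protein, series, "X"))
        assert reread.atoms[1].bfactor == 0.0
        assert reread.atoms[0].bfactor == pytest.approx(2.0)

    def test_clipping_warns(self, caplog):
        protein, _ = make_lattice_protein(1)
        series = _series_from_counts([("A", 1)], [[5000]])
        with caplog.at_level("WARNING", logger="mdcontact"):
            text = write_bfactor_pdb(protein, series, "X")
        assert "999.99" in text
        assert any("clipped" in r.message for r in caplog.records)


class TestLigandSetConstruction:
    def test_from_structure_groups_by_residue(self):
        protein, _ = make_lattice_protein(3)
        atoms = list(protein.atoms)
        for k in range(2):
            atoms.append(
                _atom(10 + k, (50 + k, 0, 0), chain="L", rid=k + 1, name="C1",
                      resname="LIG", mass=100.0)
            )
        comb = StructureModel(atoms=atoms)
        lig = ligand_set_from_structure(comb, "LIG", chain="L")
        assert lig.n_copies == 2

    def test_no_match_rejected(self):
        protein, _ = make_lattice_protein(3)
        with pytest.raises(ValueError, match="no atoms match"):
            ligand_set_from_structure(protein, "LIG", chain="Z")

    def test_overlapping_copies_rejected(self):
        protein, _ = make_lattice_protein(3)
        with pytest.raises(ValueError, match="overlapping"):
            LigandSet(
                species="X",
                copies=[np.array([0, 1]), np.array([1, 2])],
                masses=protein.masses,
            )
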