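"""Voronoi area per lipid, environment splits, and P2 bond order."""

import numpy as np
import pytest

import memshape as ms
from conftest import handmade_system, make_species, simple_lipid_positions


def one_bead_chain_species(name="LIPA", cardiolipin=False):
    return make_species(name, n_chain_beads=1, cardiolipin=cardiolipin)


def lattice_bilayer(nx=8, ny=4):
    """Two-chain lipids whose C1 sites tile a square lattice exactly."""
    sp = one_bead_chain_species()
    comp = ms.SystemComposition([sp], {"LIPA": nx * ny // 2})
    entries = []
    for leaflet, (z_head, z_c1) in (("u", (7.0, 6.6)), ("l", (3.0, 3.4))):
        k = 0
        sites = [(x + 0.5, y + 0.5) for y in range(ny) for x in range(nx)]
        for i in range(0, len(sites), 2):
            (x1, y1), (x2, y2) = sites[i], sites[i + 1]
            pos = [[x1, y1, z_head], [x1, y1, z_c1], [x2, y2, z_c1]]
            entries.append(("lipid", "LIPA", np.asarray(pos, float)))
            k += 1
    return handmade_system(comp, entries, box=[float(nx), float(ny), 10.0])


def test_square_lattice_cells_have_unit_area():
    frame, top = lattice_bilayer()
    lf = ms.assign_leaflets(frame, top)
    fa = ms.voronoi_apl(frame, top, lf)
    for area in fa.per_lipid_area.values():
        assert area == pytest.approx(2.0, abs=1e-9)
    traj = ms.Trajectory(top, [frame])
    table = ms.species_apl(traj, lf, n_boot=10)
    assert table.per_species["LIPA"].mean == pytest.approx(2.0, abs=1e-9)


def test_cardiolipin_apl_is_half_its_per_lipid_area():
    cl = one_bead_chain_species("CDL", cardiolipin=True)
    la = one_bead_chain_species("LIPA")
    comp = ms.SystemComposition([cl, la], {"CDL": 1, "LIPA": 12})
    rng = np.random.default_rng(2)
    entries = []
    for leaflet, (z_head, z_c1, down) in (("u", (7.0, 6.6, True)),
                                          ("l", (3.0, 3.4, False))):
        x, y = rng.uniform(0, 8, 2)
        cl_pos = [[x, y, z_head], [x + 0.3, y, z_head]]
        for dx, dy in ((0, 0), (0.4, 0), (0, 0.4), (0.4, 0.4)):
            cl_pos.append([x + dx, y + dy, z_c1])
        entries.append(("lipid", "CDL", np.asarray(cl_pos, float)))
        for _ in range(12):
            lx, ly = rng.uniform(0, 8, 2)
            entries.append(("lipid", "LIPA", np.asarray(
                [[lx, ly, z_head], [lx, ly, z_c1], [lx + 0.4, ly, z_c1]],
                float)))
    frame, top = handmade_system(comp, entries, box=[8, 8, 10])
    lf = ms.assign_leaflets(frame, top)
    fa = ms.voronoi_apl(frame, top, lf)
    traj = ms.Trajectory(top, [frame])
    table = ms.species_apl(traj, lf, n_boot=10)
    cl_mols = top.mols_of_species("CDL")
    per_lipid = np.mean([fa.per_lipid_area[int(m)] for m in cl_mols])
    assert table.per_species["CDL"].mean == pytest.approx(per_lipid / 2.0)
    la_mols = top.mols_of_species("LIPA")
    per_la = np.mean([fa.per_lipid_area[int(m)] for m in la_mols])
    assert table.per_species["LIPA"].mean == pytest.approx(per_la)


def test_total_cell_area_equals_box_area_on_random_frames():
    sp = one_bead_chain_species()
    rng = np.random.default_rng(0)
    for _ in range(5):
        n = int(rng.integers(50, 150))
        comp = ms.SystemComposition([sp], {"LIPA": n})
        spec = ms.SyntheticSpec(composition=comp, n_frames=1, min_spacing=0.0,
                                seed=int(rng.integers(2**31)))
        frame, top = ms.build_frame(spec)
        lf = ms.assign_leaflets(frame, top)
        fa = ms.voronoi_apl(frame, top, lf)
        for total in fa.leaflet_total.values():
            assert total == pytest.approx(fa.box_area, rel=1e-9)


def test_apl_invariant_to_in_plane_translation():
    frame, top = lattice_bilayer()
    lf = ms.assign_leaflets(frame, top)
    a0 = ms.voronoi_apl(frame, top, lf).per_lipid_area
    shifted = ms.Frame(0.0, frame.box, np.mod(
        frame.positions + np.array([0.37, 1.23, 0.0]), frame.box))
    a1 = ms.voronoi_apl(shifted, top, lf).per_lipid_area
    for m in a0:
        assert a1[m] == pytest.approx(a0[m], abs=1e-9)


def test_fewer_than_three_sites_raises():
    sp = one_bead_chain_species()
    comp = ms.SystemComposition([sp], {"LIPA": 1})
    entries = [("lipid", "LIPA",
                np.array([[1.0, 1, 7], [1, 1, 6.6], [1.4, 1, 6.6]])),
               ("lipid", "LIPA",
                np.array([[2.0, 2, 3], [2, 2, 3.4], [2.4, 2, 3.4]]))]
    frame, top = handmade_system(comp, entries, box=[8, 8, 10])
    lf = ms.assign_leaflets(frame, top)
    with pytest.raises(ValueError, match="at least 3"):
        ms.voronoi_apl(frame, top, lf)


def test_duplicate_sites_jittered_with_warning():
    sp = one_bead_chain_species()
    comp = ms.SystemComposition([sp], {"LIPA": 3})
    entries = []
    for z_head, z_c1 in ((7.0, 6.6), (3.0, 3.4)):
        for x in (1.0, 1.0, 4.0):  # two coincident C1 pairs
            entries.append(("lipid", "LIPA", np.array(
                [[x, 2.0, z_head], [x, 2.0, z_c1], [x, 2.0, z_c1]])))
    frame, top = handmade_system(comp, entries, box=[8, 8, 10])
    lf = ms.assign_leaflets(frame, top)
    with pytest.warns(UserWarning, match="duplicate"):
        fa = ms.voronoi_apl(frame, top, lf)
    for total in fa.leaflet_total.values():
        assert total == pytest.approx(fa.box_area, rel=1e-6)


# --------------------------------------------------------------------------
# Annular / bulk split
# --------------------------------------------------------------------------

def annular_fixture(lipid_x):
    comp = ms.SystemComposition([one_bead_chain_species()], {"LIPA": 2},
                                peptide_count_per_leaflet=1)
    bb = np.column_stack([np.linspace(2, 8.3, 19), np.full(19, 5.0),
                          np.full(19, 6.3)])
    entries = [
        ("lipid", "LIPA", np.array([[lipid_x, 5.0, 6.3],
                                    [lipid_x, 5.0, 6.0],
                                    [lipid_x, 5.0, 5.7]])),
        ("lipid", "LIPA", np.array([[2.0, 2.0, 3.0], [2.0, 2.0, 3.3],
                                    [2.0, 2.0, 3.6]])),
        ("peptide", None, bb),
    ]
    return handmade_system(comp, entries, box=[12, 12, 10])


def test_lipid_within_one_nm_is_annular():
    frame, top = annular_fixture(lipid_x=2.0 - 0.9)  # 0.9 nm from bead at x=2
    labels = ms.annular_bulk_split(frame, top, cutoff=1.0)
    lipid = int(top.lipid_mols[0])
    assert labels[lipid] == "annular"


def test_lipid_beyond_cutoff_is_bulk():
    frame, top = annular_fixture(lipid_x=2.0 - 1.1)
    labels = ms.annular_bulk_split(frame, top, cutoff=1.0)
    lipid = int(top.lipid_mols[0])
    assert labels[lipid] == "bulk"


def test_no_peptides_means_all_bulk():
    comp = ms.SystemComposition([make_species("POPE")], {"POPE": 10})
    spec = ms.SyntheticSpec(composition=comp, n_frames=1, seed=0)
    frame, top = ms.build_frame(spec)
    labels = ms.annular_bulk_split(frame, top)
    assert set(labels.values()) == {"bulk"}


def test_peptide_state_refines_annular_labels():
    frame, top = annular_fixture(lipid_x=2.0 - 0.5)
    pep = int(top.peptide_mols[0])
    labels = ms.annular_bulk_split(frame, top, cutoff=1.0,
                                   peptide_state={pep: "dimer"})
    lipid = int(top.lipid_mols[0])
    assert labels[lipid] == "dimer-annular"


# --------------------------------------------------------------------------
# Bond order
# --------------------------------------------------------------------------

def p2_traj(p2_target, n=60, seed=1):
    comp = ms.SystemComposition([make_species("POPE")], {"POPE": n})
    spec = ms.SyntheticSpec(composition=comp, p2_target=p2_target,
                            n_frames=1, min_spacing=0.0, seed=seed)
    frame, top = ms.build_frame(spec)
    return ms.Trajectory(top, [frame], comp)


def test_p2_limits_are_exact():
    for target, expected in ((1.0, 1.0), (-0.5, -0.5)):
        prof = ms.bond_order_p2(p2_traj(target))
        np.testing.assert_allclose(prof.data["p2"], expected, atol=1e-12)


def test_p2_bounds_hold_for_any_target():
    for target in (-0.5, -0.2, 0.0, 0.3, 0.7, 1.0):
        prof = ms.bond_order_p2(p2_traj(target, n=30))
        assert (prof.data["p2"] >= -0.5 - 1e-12).all()
        assert (prof.data["p2"] <= 1.0 + 1e-12).all()
        np.testing.assert_allclose(prof.data["p2"], target, atol=1e-12)


def test_isotropic_orientations_give_zero_p2():
    prof = ms.bond_order_p2(p2_traj("isotropic", n=2000, seed=3))
    chain_avg = prof.data["p2"].mean()
    assert abs(chain_avg) < 0.02


def test_bond_indexing_starts_at_c1_c2():
    prof = ms.bond_order_p2(p2_traj(0.5, n=10))
    assert sorted(prof.data["bond"].unique()) == [1, 2, 3]


def test_annular_and_bulk_environments_reported():
    comp = ms.SystemComposition([make_species("POPE")], {"POPE": 150},
                                peptide_count_per_leaflet=1)
    spec = ms.SyntheticSpec(composition=comp, p2_target=0.5, n_frames=1,
                            seed=2)
    frame, top = ms.build_frame(spec)
    traj = ms.Trajectory(top, [frame], comp)
    labels = [ms.annular_bulk_split(frame, top, cutoff=1.5)]
    prof = ms.bond_order_p2(traj, environment_labels=labels)
    envs = set(prof.data["environment"])
    assert {"all", "annular", "bulk"} <= envs


def test_removing_peptide_sites_grows_lipid_cells():
    comp = ms.SystemComposition([make_species("POPE")], {"POPE": 150},
                                peptide_count_per_leaflet=2)
    spec = ms.SyntheticSpec(composition=comp, n_frames=1, seed=6)
    frame, top = ms.build_frame(spec)
    lf = ms.assign_leaflets(frame, top)
    with_pep = ms.voronoi_apl(frame, top, lf, include_peptide_sites=True)
    without = ms.voronoi_apl(frame, top, lf, include_peptide_sites=False)
    mean_with = np.mean(list(with_pep.per_lipid_area.values()))
    mean_without = np.mean(list(without.per_lipid_area.values()))
    assert mean_without > mean_with
    assert with_pep.peptide_area  # peptides own some area
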