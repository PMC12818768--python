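"""Contact observables vs exhaustive brute-force oracles and fixed fixtures."""

import numpy as np
import pytest

import memshape as ms
from conftest import handmade_system, make_species, simple_lipid_positions


def straight_peptide(x0, y, z, direction=(1.0, 0.0), spacing=0.35, n=19):
    u = np.asarray(direction, float) / np.linalg.norm(direction)
    return np.array([[x0 + spacing * i * u[0], y + spacing * i * u[1], z]
                     for i in range(n)])


def random_membrane(seed, n_lipids=12, n_peptides=2, box=(14.0, 14.0, 10.0)):
    """Random lipid + peptide placements (no generator machinery)."""
    rng = np.random.default_rng(seed)
    sp = make_species("LIPA", n_chain_beads=2)
    sg = make_species("LIPB", n_chain_beads=2, charge=-1)
    comp = ms.SystemComposition([sp, sg],
                                {"LIPA": n_lipids, "LIPB": n_lipids // 2},
                                peptide_count_per_leaflet=n_peptides)
    entries = []
    for sign, z in ((1, 7.0), (-1, 3.0)):
        for sname, count in (("LIPA", n_lipids), ("LIPB", n_lipids // 2)):
            spec = comp.spec(sname)
            for _ in range(count):
                x, y = rng.uniform(0, box[0], 2)
                entries.append(("lipid", sname, simple_lipid_positions(
                    spec, x, y, z, down=(sign > 0))))
        for _ in range(n_peptides):
            phi = rng.uniform(0, 2 * np.pi)
            x, y = rng.uniform(0, box[0], 2)
            entries.append(("peptide", None, straight_peptide(
                x, y, z - sign * 0.2, (np.cos(phi), np.sin(phi)))))
    frame, top = handmade_system(comp, entries, box)
    return ms.Trajectory(top, [frame], comp), top


# --------------------------------------------------------------------------
# Brute-force oracles (explicit loops, no shared code with the package)
# --------------------------------------------------------------------------

def dist(p, q, box):
    d = np.abs(np.asarray(p) - np.asarray(q))
    d = np.minimum(d, box - d)
    return float(np.sqrt((d ** 2).sum()))


def brute_contact_map_full(traj, top, lf, threshold):
    n_res = len(top.composition.peptide_residues)
    peps = [int(p) for p in top.peptide_mols]
    total = np.zeros((n_res, n_res))
    samples = 0
    for frame in traj.frames:
        for ai, a in enumerate(peps):
            for b in peps[ai + 1:]:
                if lf[a] != lf[b]:
                    continue
                samples += 1
                hit = np.zeros((n_res, n_res), bool)
                for i in range(n_res):
                    beads_ai = [k for k in top.beads_of(a)
                                if top.residue[k] == i]
                    for j in range(n_res):
                        beads_bj = [k for k in top.beads_of(b)
                                    if top.residue[k] == j]
                        hit[i, j] = any(
                            dist(frame.positions[p], frame.positions[q],
                                 frame.box) < threshold
                            for p in beads_ai for q in beads_bj)
                total += (hit | hit.T)
    return 100.0 * total / max(samples, 1), samples


def brute_fc(frame, top, cutoff):
    out = {}
    pep_beads = [k for k in range(top.n_beads) if top.is_peptide[k]]
    for sname in top.composition.species_names:
        mols = top.mols_of_species(sname)
        touched = 0
        for m in mols:
            beads = top.beads_of(int(m))
            if any(dist(frame.positions[p], frame.positions[q], frame.box)
                   < cutoff for p in beads for q in pep_beads):
                touched += 1
        out[sname] = touched / len(mols)
    return out


def brute_lpp(frame, top, cutoff):
    counts = {s: 0.0 for s in top.composition.species_names}
    peps = [int(p) for p in top.peptide_mols]
    for pep in peps:
        pbeads = top.beads_of(pep)
        for m in top.lipid_mols:
            beads = top.beads_of(int(m))
            if any(dist(frame.positions[p], frame.positions[q], frame.box)
                   < cutoff for p in beads for q in pbeads):
                counts[top.mol_species[m]] += 1
    return {s: v / len(peps) for s, v in counts.items()}


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_contact_map_matches_brute_force(seed):
    traj, top = random_membrane(seed, n_lipids=6, n_peptides=2)
    lf = ms.assign_leaflets(traj.frames[0], top)
    got = ms.residue_contact_map(traj, lf, threshold=0.8)
    want, samples = brute_contact_map_full(traj, top, lf, 0.8)
    assert got.n_samples == samples
    np.testing.assert_array_equal(got.matrix.to_numpy(), want)


@pytest.mark.parametrize("seed", [3, 4, 5])
def test_contact_fraction_matches_brute_force(seed):
    traj, top = random_membrane(seed)
    fc = ms.contact_fraction(traj, cutoff=0.9)
    want = brute_fc(traj.frames[0], top, 0.9)
    for s, v in want.items():
        assert fc.f_c[s].iloc[0] == pytest.approx(v, abs=1e-12)


@pytest.mark.parametrize("seed", [6, 7, 8])
def test_lipids_per_peptide_matches_brute_force(seed):
    traj, top = random_membrane(seed)
    lpp = ms.lipids_per_peptide(traj, cutoff=0.9)
    want = brute_lpp(traj.frames[0], top, 0.9)
    for s, v in want.items():
        assert lpp.lpp_observed[s] == pytest.approx(v, abs=1e-12)
    # conservation: Σ species observed = total LpP
    assert sum(lpp.lpp_observed.values()) == pytest.approx(lpp.total_lpp)


def test_cutoff_monotonicity_of_contact_counts():
    traj, top = random_membrane(11)
    lf = ms.assign_leaflets(traj.frames[0], top)
    small = ms.residue_contact_map(traj, lf, threshold=0.5).matrix.to_numpy()
    large = ms.residue_contact_map(traj, lf, threshold=1.0).matrix.to_numpy()
    assert (large >= small).all()
    fc_small = ms.contact_fraction(traj, cutoff=0.5).f_c.iloc[0]
    fc_large = ms.contact_fraction(traj, cutoff=1.0).f_c.iloc[0]
    assert (fc_large >= fc_small).all()


# --------------------------------------------------------------------------
# Dimer detection fixtures
# --------------------------------------------------------------------------

def dimer_fixture(offset, antiparallel=True, n_lipids=6):
    comp = ms.SystemComposition([make_species("LIPA", n_chain_beads=1)],
                                {"LIPA": n_lipids},
                                peptide_count_per_leaflet=2)
    rng = np.random.default_rng(0)
    entries = []
    spec = comp.spec("LIPA")
    for sign, z in ((1, 7.0), (-1, 3.0)):
        for _ in range(n_lipids):
            x, y = rng.uniform(0, 14, 2)
            entries.append(("lipid", "LIPA", simple_lipid_positions(
                spec, x, y, z, down=(sign > 0))))
    a = straight_peptide(3.0, 7.0, 6.8)
    direction = (-1.0, 0.0) if antiparallel else (1.0, 0.0)
    if antiparallel:
        b = straight_peptide(3.0 + 18 * 0.35, 7.0 + offset, 6.8, direction)
    else:
        b = straight_peptide(3.0, 7.0 + offset, 6.8, direction)
    c = straight_peptide(2.0, 3.0, 3.2)
    d = straight_peptide(2.0, 10.0, 3.2)
    entries += [("peptide", None, p) for p in (a, b, c, d)]
    comp2 = ms.SystemComposition([make_species("LIPA", n_chain_beads=1)],
                                 {"LIPA": n_lipids},
                                 peptide_count_per_leaflet=2)
    frame, top = handmade_system(comp2, entries, box=[14, 14, 10])
    return ms.Trajectory(top, [frame], comp2), top


def test_two_residue_contacts_make_a_dimer():
    traj, top = dimer_fixture(offset=0.5)
    lf = ms.assign_leaflets(traj.frames[0], top)
    events = ms.detect_dimers(traj, threshold=0.6, leaflets=lf)
    assert len(events) == 1
    assert events[0].duration > 0


def test_single_residue_contact_is_not_a_dimer():
    # peptides perpendicular, touching only at one crossing point
    comp = ms.SystemComposition([make_species("LIPA", n_chain_beads=1)],
                                {"LIPA": 4}, peptide_count_per_leaflet=2)
    rng = np.random.default_rng(1)
    entries = []
    for sign, z in ((1, 7.0), (-1, 3.0)):
        for _ in range(4):
            x, y = rng.uniform(0, 14, 2)
            entries.append(("lipid", "LIPA", simple_lipid_positions(
                comp.spec("LIPA"), x, y, z, down=(sign > 0))))
    # end-to-end T geometry: only a's last bead and b's first bead touch
    a = straight_peptide(2.0, 7.0, 6.8)                      # ends at x=8.3
    b = straight_peptide(8.8, 7.0, 6.8, (0, 1))              # along +y
    entries += [("peptide", None, a), ("peptide", None, b),
                ("peptide", None, straight_peptide(2.0, 2.0, 3.2)),
                ("peptide", None, straight_peptide(2.0, 11.0, 3.2))]
    frame, top = handmade_system(comp, entries, box=[14, 14, 10])
    traj = ms.Trajectory(top, [frame], comp)
    lf = ms.assign_leaflets(frame, top)
    # each peptide has ≥1 residue in contact but only one residue each side
    events = ms.detect_dimers(traj, threshold=0.6, leaflets=lf,
                              min_residues=2)
    assert events == []


def test_reporter_requires_mutual_lys4_trp19_contact():
    traj, top = dimer_fixture(offset=0.5, antiparallel=True)
    lf = ms.assign_leaflets(traj.frames[0], top)
    ev_all = ms.detect_dimers(traj, leaflets=lf, criterion="residues")
    ev_rep = ms.detect_dimers(traj, leaflets=lf, criterion="reporter")
    # perfectly aligned antiparallel pair: Trp19 faces Pro1, not Lys4
    assert len(ev_all) == 1 and not ev_all[0].reporter
    assert ev_rep == []


def test_reporter_events_are_subset_of_residue_events():
    comp = ms.SystemComposition([make_species("POPE")], {"POPE": 160},
                                peptide_count_per_leaflet=3)
    spec = ms.SyntheticSpec(composition=comp,
                            diffusion_map={"POPE": 5e-7, "PEP": 3e-7},
                            dimer_kon=2.0, dimer_koff=0.1, n_frames=300,
                            dt=0.5, seed=6)
    traj, _ = ms.simulate(spec)
    lf = ms.assign_leaflets(traj.frames[0], traj.topology)
    by_res = ms.detect_dimers(traj, leaflets=lf, criterion="residues")
    by_rep = ms.detect_dimers(traj, leaflets=lf, criterion="reporter")
    res_frames = {(e.pair, t) for e in by_res
                  for t in np.arange(e.start, e.end, traj.dt)}
    rep_frames = {(e.pair, t) for e in by_rep
                  for t in np.arange(e.start, e.end, traj.dt)}
    assert rep_frames <= res_frames


def test_gap_tolerance_merges_interrupted_episodes():
    comp = ms.SystemComposition([make_species("LIPA", n_chain_beads=1)],
                                {"LIPA": 6}, peptide_count_per_leaflet=2)
    traj0, top = dimer_fixture(offset=0.5)
    frame_on = traj0.frames[0]
    apart = frame_on.positions.copy()
    pep_b = top.peptide_mols[1]
    sl = top.mol_slice(int(pep_b))
    apart[sl, 1] += 3.0
    frame_off = ms.Frame(1.0, frame_on.box, np.mod(apart, frame_on.box))
    frames = [ms.Frame(float(t), frame_on.box,
                       frame_on.positions if on else frame_off.positions)
              for t, on in enumerate([1, 1, 0, 1, 1])]
    traj = ms.Trajectory(top, frames, traj0.composition)
    lf = ms.assign_leaflets(frames[0], top)
    strict = ms.detect_dimers(traj, leaflets=lf, gap_tolerance=0)
    merged = ms.detect_dimers(traj, leaflets=lf, gap_tolerance=1)
    assert len(strict) == 2
    assert len(merged) == 1
    assert merged[0].duration == pytest.approx(5.0)


# --------------------------------------------------------------------------
# Survival histogram
# --------------------------------------------------------------------------

def make_event(start, end, pair=(0, 1), reporter=False):
    return ms.DimerEvent(start=start, end=end, pair=pair, reporter=reporter)


def test_survival_histogram_sums_episode_durations():
    events = [make_event(0, 3), make_event(10, 13), make_event(20, 30)]
    hist = ms.dimer_survival(events, bins=np.array([0, 5, 15]))
    assert hist.summed_time.tolist() == [6.0, 10.0]
    assert hist.total_time == pytest.approx(16.0)


def test_single_long_episode_is_all_long_lived():
    hist = ms.dimer_survival([make_event(0, 500)])
    assert hist.long_fraction == pytest.approx(1.0)
    assert hist.short_fraction == 0.0


def test_empty_events_give_empty_histogram():
    hist = ms.dimer_survival([])
    assert hist.total_time == 0.0


def test_planted_exponential_lifetimes_recovered():
    comp = ms.SystemComposition([make_species("POPE")], {"POPE": 160},
                                peptide_count_per_leaflet=3)
    durations = []
    for seed in (10, 11):
        spec = ms.SyntheticSpec(
            composition=comp, diffusion_map={"POPE": 5e-7, "PEP": 3e-7},
            dimer_kon=2.0, dimer_koff=0.1, n_frames=600, dt=0.5, seed=seed)
        traj, truth = ms.simulate(spec)
        lf = ms.assign_leaflets(traj.frames[0], traj.topology)
        events = ms.detect_dimers(traj, leaflets=lf)
        durations += [e.duration for e in events]
    durations = np.asarray(durations)
    assert durations.size >= 40
    expected = 0.5 / (1 - np.exp(-0.1 * 0.5))
    se = durations.std(ddof=1) / np.sqrt(durations.size)
    assert abs(durations.mean() - expected) < 3 * se


# --------------------------------------------------------------------------
# Transmembrane / pore labels
# --------------------------------------------------------------------------

def transmembrane_traj(n_contact_frames, n_total, dt=1.0):
    comp = ms.SystemComposition([make_species("LIPA", n_chain_beads=1)],
                                {"LIPA": 6}, peptide_count_per_leaflet=1)
    rng = np.random.default_rng(2)
    entries = []
    for sign, z in ((1, 7.0), (-1, 3.0)):
        for _ in range(6):
            x, y = rng.uniform(0, 14, 2)
            entries.append(("lipid", "LIPA", simple_lipid_positions(
                comp.spec("LIPA"), x, y, z, down=(sign > 0))))
    up = straight_peptide(3.0, 7.0, 6.0)
    down_touch = straight_peptide(3.0, 7.0, 5.6)   # within 0.6 of upper
    down_far = straight_peptide(3.0, 7.0, 3.2)
    entries += [("peptide", None, up), ("peptide", None, down_far)]
    frame_far, top = handmade_system(comp, entries, box=[14, 14, 10])
    pep_low = int(top.peptide_mols[1])
    sl = top.mol_slice(pep_low)
    touch_pos = frame_far.positions.copy()
    touch_pos[sl] = down_touch
    frames = []
    for i in range(n_total):
        on = i < n_contact_frames
        frames.append(ms.Frame(i * dt, frame_far.box,
                               touch_pos if on else frame_far.positions))
    lf_frame = ms.Frame(0.0, frame_far.box, frame_far.positions)
    lf = ms.assign_leaflets(lf_frame, top)
    return ms.Trajectory(top, frames, comp), lf


def test_opposite_leaflet_contact_is_transmembrane():
    traj, lf = transmembrane_traj(1, 3)
    labels = ms.transmembrane_pore_frames(traj, lf, persistence=1000.0)
    assert labels.labels[0] == "transmembrane-contact"
    assert labels.labels[1] == "none"


def test_same_leaflet_contact_is_not_transmembrane():
    traj, top = dimer_fixture(offset=0.5)
    lf = ms.assign_leaflets(traj.frames[0], top)
    labels = ms.transmembrane_pore_frames(traj, lf)
    assert labels.labels == ["none"]


def test_persistent_run_labelled_pore():
    traj, lf = transmembrane_traj(8, 10, dt=200.0)  # 1.6 µs run
    labels = ms.transmembrane_pore_frames(traj, lf, persistence=1000.0)
    assert labels.labels[:8] == ["pore"] * 8
    assert labels.labels[8:] == ["none", "none"]
    assert labels.pore_frames() == list(range(8))
    assert all(len(p) == 2 for p in labels.participants[:8])


# --------------------------------------------------------------------------
# LpP arithmetic and residue profiles
# --------------------------------------------------------------------------

def test_lpp_expected_follows_mole_fractions():
    """12 contacting lipids in a 2:1 system split 6/6 → ratios 0.75 and 1.5."""
    sp = make_species("LIPA", n_chain_beads=1)
    sg = make_species("LIPB", n_chain_beads=1, charge=-1)
    comp = ms.SystemComposition([sp, sg], {"LIPA": 8, "LIPB": 4},
                                peptide_count_per_leaflet=1)
    pep = straight_peptide(4.0, 7.0, 6.8)
    # 6 of each species touching the peptide, the rest far away
    placements = []
    for i in range(6):
        placements.append(("LIPA", 4.0 + 0.5 * i, 7.4))
        placements.append(("LIPB", 4.0 + 0.5 * i, 6.6))
    for i in range(2):
        placements.append(("LIPA", 1.0 + 0.5 * i, 12.0))
    # LIPB upper count is 4 but 6 touch: use lower-leaflet spares instead
    entries = []
    for sname, x, y in placements:
        entries.append(("lipid", sname, simple_lipid_positions(
            comp.spec(sname), x, y, 7.0)))
    # pad remaining molecules in the lower leaflet, far from any peptide
    entries.append(("lipid", "LIPB", simple_lipid_positions(
        comp.spec("LIPB"), 1.0, 1.0, 3.0, down=False)))
    entries.append(("peptide", None, pep))
    frame, top = handmade_system(comp, entries, box=[16, 16, 10])
    traj = ms.Trajectory(top, [frame], comp)
    lpp = ms.lipids_per_peptide(traj, cutoff=0.7)
    assert lpp.lpp_observed["LIPA"] == 6
    assert lpp.lpp_observed["LIPB"] == 6
    assert lpp.lpp_expected["LIPA"] == pytest.approx(8.0)
    assert lpp.lpp_expected["LIPB"] == pytest.approx(4.0)
    assert lpp.ratio["LIPA"] == pytest.approx(0.75)
    assert lpp.ratio["LIPB"] == pytest.approx(1.5)


def test_single_species_ratio_is_one():
    comp = ms.SystemComposition([make_species("POPE")], {"POPE": 150},
                                peptide_count_per_leaflet=1)
    spec = ms.SyntheticSpec(composition=comp, n_frames=1, seed=4)
    frame, top = ms.build_frame(spec)
    traj = ms.Trajectory(top, [frame], comp)
    lpp = ms.lipids_per_peptide(traj, cutoff=1.5)
    assert lpp.ratio["POPE"] == pytest.approx(1.0)


def test_residue_profile_full_occupancy_cell():
    sp = make_species("LIPA", n_chain_beads=1)
    comp = ms.SystemComposition([sp], {"LIPA": 3},
                                peptide_count_per_leaflet=1)
    pep = straight_peptide(4.0, 7.0, 6.8)
    entries = [("lipid", "LIPA", simple_lipid_positions(sp, 4.0, 7.3, 7.0))]
    entries += [("lipid", "LIPA", simple_lipid_positions(sp, 12.0, 12.0, 7.0)),
                ("lipid", "LIPA",
                 simple_lipid_positions(sp, 1.0, 1.0, 3.0, down=False))]
    entries.append(("peptide", None, pep))
    frame, top = handmade_system(comp, entries, box=[16, 16, 10])
    traj = ms.Trajectory(top, [frame], comp)
    prof = ms.residue_lipid_profile(traj, cutoff=0.7)
    # residue 1 sits 0.3+ nm from the only nearby phosphate: contact every frame
    assert prof.raw_counts.iloc[0, 0] == 1
    assert prof.matrix.max().max() == pytest.approx(1.0)


def test_profile_clustering_identical_profiles_merge_first():
    a = np.array([1.0, 0.5, 0.2, 0.9])
    profiles = {"A": a, "B": a.copy(), "C": np.array([0.1, 0.9, 0.8, 0.05])}
    labels, Z, newick = ms.cluster_profiles(profiles)
    # first merge joins the two identical profiles at zero distance
    first = sorted(int(i) for i in Z[0, :2])
    assert [labels[i] for i in first] == ["A", "B"]
    assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
    assert newick.endswith(";") and "A" in newick and "C" in newick
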