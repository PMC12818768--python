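"""Synthetic coarse-grained bilayer + peptide trajectories with planted truth.

The generator emulates the geometry and kinematics that the analysis stages
measure, without any physical forces:

* a planar two-leaflet bilayer: phosphates at ``center ± leaflet_z_offset``
  (optionally Gaussian-jittered), acyl-chain beads hanging toward the bilayer
  core with a prescribed bond orientational order ``p2_target``;
* lipids placed uniformly in-plane (minimum-spacing rejection sampling) or as
  planted Gaussian blobs for clustering tests;
* peptides as straight in-plane backbone-bead chains adsorbed just below the
  phosphate plane of each leaflet;
* lateral dynamics: independent 2D Brownian steps per molecule with
  per-species diffusion coefficients (step std = sqrt(2·D·dt) per axis);
  z and internal geometry stay rigid;
* peptide dimerization: a two-state Markov process (bind at rate ``k_on``
  while within ``capture_radius``, unbind at rate ``k_off``).  A bound pair is
  held in a shifted antiparallel arrangement whose Lys4–Trp19 interface sits
  within 0.5 nm, and moves as one unit.  Unbound pairs are softly excluded so
  that backbone-contact detection (0.6 nm) fires only while a pair is planted
  as bound.

Every planted property is recorded in :class:`GroundTruth`, so analyses can be
scored against construction rather than against themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import (
    Frame,
    SystemComposition,
    Topology,
    Trajectory,
    build_topology,
    min_image_displacement,
    min_image_distance,
    wrap_positions,
    PEPTIDE_SPECIES,
)

__all__ = ["SyntheticSpec", "GroundTruth", "build_frame", "simulate",
           "plant_spatial_clusters", "CM2_PER_S_TO_NM2_PER_NS"]

#: 1 cm²/s = 1e14 nm²/s = 1e5 nm²/ns
CM2_PER_S_TO_NM2_PER_NS = 1.0e5


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic bilayer trajectory.

    ``apl_target`` (nm² per chain pair) sets the in-plane box when ``box_xy``
    is None; ``diffusion_map`` maps species names (and ``"PEP"``) to lateral
    diffusion coefficients in cm²/s; ``p2_target`` is either a number in
    [−0.5, 1] (every bond drawn at the exact polar angle realising it) or
    ``"isotropic"`` (uniform orientations, expected P2 = 0).
    """

    composition: SystemComposition
    box_xy: float | None = None
    leaflet_z_offset: float = 2.0
    z_jitter: float = 0.0
    apl_target: float = 0.65
    diffusion_map: dict[str, float] = field(default_factory=dict)
    p2_target: float | str = 0.5
    dimer_kon: float = 0.0      # per ns, while within capture radius
    dimer_koff: float = 0.0     # per ns
    capture_radius: float = 1.2
    exclusion_distance: float = 0.75  # unbound pairs pushed beyond this
    cluster_plant: dict | None = None  # {species, n_clusters, cluster_radius}
    n_frames: int = 100
    dt: float = 1.0             # ns
    seed: int = 0
    min_spacing: float = 0.3    # nm, build-time rejection sampling (0 disables)
    bond_length: float = 0.47   # nm, acyl-chain bond
    head_link: float = 0.30     # nm, phosphate → C1 vertical drop
    peptide_depth: float = 0.15  # nm below the phosphate plane
    peptide_spacing: float = 0.35  # nm between backbone beads
    dimer_offset: float = 0.45  # nm lateral gap inside a bound dimer
    box_z: float | None = None

    def __post_init__(self) -> None:
        if self.dimer_kon < 0 or self.dimer_koff < 0:
            raise ValueError("rates must be >= 0")
        if not isinstance(self.p2_target, str):
            if not -0.5 <= float(self.p2_target) <= 1.0:
                raise ValueError("p2_target must lie in [-0.5, 1]")
        if self.capture_radius <= 0.6:
            raise ValueError("capture radius must exceed the 0.6 nm detection cutoff")

    # -- derived geometry --------------------------------------------------
    def required_area(self) -> float:
        comp = self.composition
        return sum(comp.counts_per_leaflet[s.name] * self.apl_target
                   * s.n_chain_pairs for s in comp.species
                   if s.name in comp.counts_per_leaflet)

    def resolved_box(self) -> np.ndarray:
        area = self.required_area()
        if self.box_xy is None:
            lxy = float(np.sqrt(area))
        else:
            lxy = float(self.box_xy)
            if area > lxy * lxy * (1 + 1e-9):
                raise ValueError(
                    f"packing infeasible: need {area:.2f} nm² per leaflet, "
                    f"box offers {lxy * lxy:.2f} nm²")
        if self.composition.peptide_count_per_leaflet > 0:
            extent = (len(self.composition.peptide_residues) - 1) \
                * self.peptide_spacing
            if lxy < extent + 1.0:
                raise ValueError(
                    f"box {lxy:.2f} nm too small for a {extent:.2f} nm peptide "
                    "(rods would span the periodic cell); add lipids or set "
                    "box_xy")
        lz = self.box_z if self.box_z is not None else \
            2.0 * (self.leaflet_z_offset + 2.5)
        return np.array([lxy, lxy, lz])


@dataclass
class GroundTruth:
    """Everything the generator planted, for scoring analyses against."""

    seed: int
    d_per_molecule: dict[int, float]          # cm²/s
    dimer_episodes: list[tuple[int, int, float, float]]  # (a, b, start, end) ns
    cluster_members: dict[str, list[list[int]]] = field(default_factory=dict)
    leaflet_of: dict[int, str] = field(default_factory=dict)
    half_thickness: float = 0.0
    peptide_depth: float = 0.0
    p2_target: float | str = 0.0

    def episode_durations(self) -> np.ndarray:
        return np.array([e - s for _, _, s, e in self.dimer_episodes])

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "seed": int(self.seed),
            "half_thickness_nm": float(self.half_thickness),
            "peptide_depth_nm": float(self.peptide_depth),
            "p2_target": self.p2_target,
            "d_per_molecule_cm2_s": {int(k): float(v)
                                     for k, v in self.d_per_molecule.items()},
            "dimer_episodes": [[int(a), int(b), float(s), float(e)]
                               for a, b, s, e in self.dimer_episodes],
            "cluster_members": {k: [[int(m) for m in grp] for grp in v]
                                for k, v in self.cluster_members.items()},
            "leaflet_of": {int(k): str(v) for k, v in self.leaflet_of.items()},
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


# --------------------------------------------------------------------------
# Placement helpers
# --------------------------------------------------------------------------

def _sample_xy(rng, n: int, box: np.ndarray, existing: np.ndarray,
               min_spacing: float) -> np.ndarray:
    """Uniform in-plane points keeping ``min_spacing`` from each other and
    from ``existing`` (min-image).  Rejection-sampled in batches."""
    if min_spacing <= 0:
        return rng.uniform(0, box[:2], size=(n, 2))
    pts: list[np.ndarray] = []
    pool = existing.copy() if len(existing) else np.empty((0, 2))
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > 200 * n + 1000:
            raise ValueError("packing infeasible: rejection sampling stalled "
                             f"(placed {len(pts)}/{n})")
        cand = rng.uniform(0, box[:2], size=2)
        if len(pool):
            d = min_image_distance(pool, cand[None, :], box[:2], xy_only=True)
            if np.min(d) < min_spacing:
                continue
        pts.append(cand)
        pool = np.vstack([pool, cand[None, :]])
    return np.asarray(pts)


def _bond_direction(rng, p2_target, down: bool) -> np.ndarray:
    """Unit bond vector realising the target order parameter.

    Numeric target: polar angle fixed at cosθ = sqrt((2·P2+1)/3) so that
    (3cos²θ−1)/2 equals the target exactly; azimuth uniform.  ``"isotropic"``:
    uniform on the sphere.
    """
    if isinstance(p2_target, str):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        if down and v[2] > 0:
            v[2] = -v[2]
        elif not down and v[2] < 0:
            v[2] = -v[2]
        return v
    cos_t = float(np.sqrt((2.0 * float(p2_target) + 1.0) / 3.0))
    sin_t = float(np.sqrt(max(0.0, 1.0 - cos_t ** 2)))
    phi = rng.uniform(0, 2 * np.pi)
    dz = -cos_t if down else cos_t
    return np.array([sin_t * np.cos(phi), sin_t * np.sin(phi), dz])


class _Builder:
    """Build one frame plus its topology and placement bookkeeping."""

    def __init__(self, spec: SyntheticSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.box = spec.resolved_box()
        self.records: list[tuple[str, str, list[tuple[str, str | int]]]] = []
        self.positions: list[np.ndarray] = []
        self.leaflet_of: dict[int, str] = {}
        self.cluster_members: dict[str, list[list[int]]] = {}
        self.peptide_axes: dict[int, np.ndarray] = {}

    # -- lipids ------------------------------------------------------------
    def _place_lipid(self, sname: str, xy: np.ndarray, leaflet: str) -> None:
        spec, comp = self.spec, self.spec.composition
        sp = comp.spec(sname)
        center_z = self.box[2] / 2.0
        sign = 1.0 if leaflet == "upper" else -1.0
        z_head = center_z + sign * spec.leaflet_z_offset
        if spec.z_jitter > 0:
            z_head += self.rng.normal(0, spec.z_jitter)
        beads: list[tuple[str, str]] = []
        pos: list[np.ndarray] = []
        for k, hb in enumerate(sp.headgroup_beads):
            beads.append((hb, sname))
            pos.append(np.array([xy[0] + 0.3 * k, xy[1], z_head]))
        for eb in sp.extra_beads:
            beads.append((eb, sname))
            pos.append(np.array([xy[0], xy[1], z_head - sign * 0.5 * spec.head_link]))
        for ci, chain in enumerate(sp.chain_beads):
            dx = 0.25 * (ci - (len(sp.chain_beads) - 1) / 2.0)
            p = np.array([xy[0] + dx, xy[1], z_head - sign * spec.head_link])
            beads.append((chain[0], sname))
            pos.append(p.copy())
            for bead in chain[1:]:
                p = p + spec.bond_length * _bond_direction(
                    self.rng, spec.p2_target, down=(leaflet == "upper"))
                beads.append((bead, sname))
                pos.append(p.copy())
        mid = len(self.records)
        self.records.append(("lipid", sname, beads))
        self.positions.append(np.asarray(pos))
        self.leaflet_of[mid] = leaflet

    def _place_leaflet_lipids(self, leaflet: str) -> None:
        spec, comp = self.spec, self.spec.composition
        plant = spec.cluster_plant
        placed = np.empty((0, 2))
        for sp in comp.species:
            n = comp.counts_per_leaflet.get(sp.name, 0)
            if n == 0:
                continue
            if plant and plant["species"] == sp.name:
                xy, groups_local = self._clustered_xy(n, plant)
                start_mid = len(self.records)
                groups = [[start_mid + i for i in grp] for grp in groups_local]
                self.cluster_members.setdefault(sp.name, []).extend(groups)
            else:
                xy = _sample_xy(self.rng, n, self.box, placed, spec.min_spacing)
            placed = np.vstack([placed, xy]) if len(placed) else xy
            for row in xy:
                self._place_lipid(sp.name, row, leaflet)

    def _clustered_xy(self, n: int, plant: dict) -> tuple[np.ndarray, list[list[int]]]:
        k = int(plant["n_clusters"])
        radius = float(plant["cluster_radius"])
        if 2 * radius > min(self.box[0], self.box[1]):
            raise ValueError("cluster blobs exceed the box")
        # well-separated blob centres on a jittered ring/grid
        centers = _sample_xy(self.rng, k, self.box, np.empty((0, 2)),
                             min_spacing=min(4.0 * radius,
                                             0.45 * min(self.box[0], self.box[1])))
        sizes = np.full(k, n // k)
        sizes[: n % k] += 1
        xy, groups = [], []
        i = 0
        for c, sz in zip(centers, sizes):
            pts = c[None, :] + self.rng.normal(0, radius / 2.0, size=(sz, 2))
            pts = np.mod(pts, self.box[:2])
            xy.append(pts)
            groups.append(list(range(i, i + sz)))
            i += sz
        return np.vstack(xy), groups

    # -- peptides ----------------------------------------------------------
    def _place_peptides(self, leaflet: str) -> None:
        spec, comp = self.spec, self.spec.composition
        n_res = len(comp.peptide_residues)
        center_z = self.box[2] / 2.0
        sign = 1.0 if leaflet == "upper" else -1.0
        z = center_z + sign * (spec.leaflet_z_offset - spec.peptide_depth)
        existing_beads = [self.positions[m] for m, lf in self.leaflet_of.items()
                          if lf == leaflet and self.records[m][0] == "peptide"]
        offsets = (np.arange(n_res) - (n_res - 1) / 2.0) * spec.peptide_spacing
        for _ in range(comp.peptide_count_per_leaflet):
            for attempt in range(500):
                com = self.rng.uniform(0, self.box[:2], size=2)
                phi = self.rng.uniform(0, 2 * np.pi)
                u = np.array([np.cos(phi), np.sin(phi), 0.0])
                pos = np.array([com[0], com[1], z])[None, :] \
                    + offsets[:, None] * u[None, :]
                if all(float(np.min(min_image_distance(
                        pos[:, None, :], other[None, :, :], self.box))) >
                        spec.exclusion_distance + 0.1
                       for other in existing_beads):
                    break
            else:
                raise ValueError("could not place peptides without overlap; "
                                 "box too crowded")
            beads = [(comp.backbone_bead, r) for r in range(n_res)]
            mid = len(self.records)
            self.records.append(("peptide", PEPTIDE_SPECIES, beads))
            self.positions.append(pos)
            self.leaflet_of[mid] = leaflet
            self.peptide_axes[mid] = u
            existing_beads.append(pos)

    # -- assembly ----------------------------------------------------------
    def build(self) -> tuple[Frame, Topology]:
        for leaflet in ("upper", "lower"):
            self._place_leaflet_lipids(leaflet)
        for leaflet in ("upper", "lower"):
            self._place_peptides(leaflet)
        topology = build_topology(self.records, self.spec.composition)
        self.raw_positions = np.vstack(self.positions)  # unwrapped
        frame = Frame(time=0.0, box=self.box.copy(),
                      positions=wrap_positions(self.raw_positions, self.box))
        return frame, topology


def build_frame(spec: SyntheticSpec) -> tuple[Frame, Topology]:
    """Build the t=0 frame (and its topology) for a synthetic system."""
    return _Builder(spec).build()


def plant_spatial_clusters(spec: SyntheticSpec
                           ) -> tuple[Frame, Topology, dict[str, list[list[int]]]]:
    """Build a frame whose chosen species forms Gaussian blobs; returns the
    frame, topology and the planted blob memberships (molecule ids)."""
    if not spec.cluster_plant:
        raise ValueError("cluster_plant not set")
    builder = _Builder(spec)
    frame, topology = builder.build()
    return frame, topology, builder.cluster_members


# --------------------------------------------------------------------------
# Dynamics
# --------------------------------------------------------------------------

def _pep_com_xy(pos: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return pos[idx, :2].mean(axis=0)


def simulate(spec: SyntheticSpec) -> tuple[Trajectory, GroundTruth]:
    """Evolve the built frame: Brownian in-plane diffusion plus two-state
    peptide dimer kinetics.  Bit-reproducible for a fixed seed."""
    builder = _Builder(spec)
    frame0, topology = builder.build()
    rng = builder.rng
    box = frame0.box
    comp = spec.composition
    dt = spec.dt

    # per-molecule diffusion coefficients (cm²/s → nm²/ns step widths)
    d_mol = np.zeros(topology.n_mols)
    for mol in range(topology.n_mols):
        key = PEPTIDE_SPECIES if topology.mol_is_peptide[mol] \
            else str(topology.mol_species[mol])
        d_mol[mol] = float(spec.diffusion_map.get(key, 0.0))
    step_std = np.sqrt(2.0 * d_mol * CM2_PER_S_TO_NM2_PER_NS * dt)

    peptides = list(topology.peptide_mols)
    bb_idx = {m: topology.backbone_indices(m) for m in peptides}
    same_leaflet_pairs = [
        (a, b) for i, a in enumerate(peptides) for b in peptides[i + 1:]
        if builder.leaflet_of[a] == builder.leaflet_of[b]]
    p_on = 1.0 - np.exp(-spec.dimer_kon * dt)
    p_off = 1.0 - np.exp(-spec.dimer_koff * dt)

    # Work on unwrapped coordinates so rigid-molecule geometry survives the
    # periodic boundary; wrap only when a frame is stored.
    pos = builder.raw_positions.copy()
    frames = [frame0]
    bound_partner: dict[int, int] = {}
    open_since: dict[tuple[int, int], float] = {}
    episodes: list[tuple[int, int, float, float]] = []

    n_res = len(comp.peptide_residues)

    def dock(a: int, b: int) -> None:
        """Place peptide b antiparallel alongside a, shifted so the
        Lys4–Trp19 interface (residues 4 and 19) is within 0.5 nm."""
        ia, ib = bb_idx[a], bb_idx[b]
        pa = pos[ia]
        u = pa[-1] - pa[0]
        nrm = np.linalg.norm(u[:2])
        u = u / np.linalg.norm(u)
        perp = np.array([-u[1], u[0], 0.0])
        if nrm > 0:
            perp /= np.linalg.norm(perp)
        s = spec.peptide_spacing
        # shifted antiparallel: residue j of b lies beside residue (21-j) of a
        shift = (n_res + 2)
        target = pa[0][None, :] + \
            np.outer((shift - np.arange(n_res)) * s, u)
        target = target + spec.dimer_offset * perp[None, :]
        target[:, 2] = pos[ib, 2].mean()
        pos[ib] = target

    def push_apart(ref: int, other: int, movers: list[int]) -> bool:
        """Shift ``movers`` away from ``ref`` until the ref/other backbone
        minimum distance clears the exclusion shell.  ``other`` is the peptide
        whose distance to ``ref`` is checked (it is in, or rides with, movers).
        Returns True if anything moved."""
        ia, ib = bb_idx[ref], bb_idx[other]
        d = min_image_distance(pos[ia][:, None, :], pos[ib][None, :, :], box)
        m = float(np.min(d))
        if m >= spec.exclusion_distance:
            return False
        # push along the closest-bead-pair axis (efficient even for crossing
        # rods); fall back to the COM axis, then to a random direction
        i_min, j_min = np.unravel_index(int(np.argmin(d)), d.shape)
        axis = min_image_displacement(pos[ia[i_min], :2], pos[ib[j_min], :2],
                                      box[:2], xy_only=True)
        if np.linalg.norm(axis) < 1e-6:
            axis = min_image_displacement(_pep_com_xy(pos, ia),
                                          _pep_com_xy(pos, ib), box[:2],
                                          xy_only=True)
        nrm = np.linalg.norm(axis)
        if nrm < 1e-9:
            phi = rng.uniform(0, 2 * np.pi)
            axis = np.array([np.cos(phi), np.sin(phi)])
        else:
            axis = axis / nrm
        shift = (spec.exclusion_distance - m) + 0.1
        for mv in movers:
            sl = topology.mol_slice(mv)
            pos[sl, 0] += shift * axis[0]
            pos[sl, 1] += shift * axis[1]
        return True

    for fi in range(1, spec.n_frames):
        t = fi * dt
        # Brownian step per molecule; bound partners copy their anchor's step
        steps = rng.normal(size=(topology.n_mols, 2)) * step_std[:, None]
        for b, a in bound_partner.items():
            if a < b:
                steps[b] = steps[a]
        for mol in range(topology.n_mols):
            sl = topology.mol_slice(mol)
            pos[sl, 0] += steps[mol, 0]
            pos[sl, 1] += steps[mol, 1]

        # kinetics
        for a, b in same_leaflet_pairs:
            key = (a, b)
            if bound_partner.get(a) == b:
                if rng.uniform() < p_off:
                    episodes.append((a, b, open_since.pop(key), t))
                    del bound_partner[a], bound_partner[b]
                    push_apart(a, b, [b])  # break contact immediately
            elif a not in bound_partner and b not in bound_partner:
                d_min = float(np.min(min_image_distance(
                    pos[bb_idx[a]][:, None, :], pos[bb_idx[b]][None, :, :],
                    box)))
                if d_min < spec.capture_radius and rng.uniform() < p_on:
                    bound_partner[a] = b
                    bound_partner[b] = a
                    dock(a, b)
                    open_since[key] = t

        # soft exclusion: keep every non-bound pair outside detection range;
        # multiple passes, since resolving one pair can crowd another
        for _pass in range(6):
            any_moved = False
            for a, b in same_leaflet_pairs:
                if bound_partner.get(a) == b:
                    continue
                if b not in bound_partner:
                    ref, other, movers = a, b, [b]
                elif a not in bound_partner:
                    ref, other, movers = b, a, [a]
                else:  # two distinct dimers colliding: move b's dimer as a unit
                    ref, other, movers = a, b, [b, bound_partner[b]]
                for _ in range(5):
                    if not push_apart(ref, other, movers):
                        break
                    any_moved = True
            if not any_moved:
                break

        frames.append(Frame(time=t, box=box.copy(),
                            positions=wrap_positions(pos, box)))

    # close episodes still open at the end
    t_end = spec.n_frames * dt
    for (a, b), s in open_since.items():
        if bound_partner.get(a) == b:
            episodes.append((a, b, s, t_end))

    truth = GroundTruth(
        seed=spec.seed,
        d_per_molecule={m: float(d_mol[m]) for m in range(topology.n_mols)},
        dimer_episodes=sorted(episodes, key=lambda e: (e[2], e[0], e[1])),
        cluster_members=builder.cluster_members,
        leaflet_of=dict(builder.leaflet_of),
        half_thickness=spec.leaflet_z_offset,
        peptide_depth=spec.peptide_depth,
        p2_target=spec.p2_target,
    )
    return Trajectory(topology, frames, comp), truth
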