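"""In-plane packing (Voronoi area per lipid) and acyl-chain bond order.

Area per lipid (ApL): each leaflet is tessellated independently from the xy
projections of the first tail bead (C1) of every acyl chain — one seed per
chain, so a cardiolipin contributes four cells while an ordinary phospholipid
contributes two.  A lipid's area is the sum of its chain-cell areas, and the
species ApL is reported per *pair* of acyl chains (per-lipid area divided by
n_chains/2) so that four-chain and two-chain species are comparable.
Periodicity is handled exactly for bilayer-scale boxes by tiling the seeds
into the 8 neighbouring images, tessellating the 3×3 supercell, and keeping
the central-copy cells; their areas sum to the box area to numerical
precision.  For pore analyses, selected peptide sites (the Trp19 backbone
beads) can join the tessellation.

Bond order: P2 = ⟨(3 cos²θ − 1)/2⟩ per bond of the acyl chain, θ measured
against the bilayer normal (z).  1 = aligned with the normal, −0.5 = in
plane, 0 = isotropic.  Profiles are split by environment (annular lipids
within 1 nm of a peptide vs bulk).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi, cKDTree

from .core import (
    Frame,
    LeafletMap,
    Topology,
    Trajectory,
    min_image_displacement,
)
from .stats import BootstrapEstimate, bootstrap_ci, point_or_bootstrap, propagate_ratio

__all__ = ["FrameApL", "ApLTable", "OrderProfile", "voronoi_apl",
           "species_apl", "apl_ratio", "annular_bulk_split", "bond_order_p2",
           "TRP19_RESIDUE_INDEX"]

#: 0-based residue index of the C-terminal tryptophan used as pore site.
TRP19_RESIDUE_INDEX = 18

_TILE = np.array([(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1)
                  if (i, j) != (0, 0)])


def _polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a convex polygon given in arbitrary vertex order."""
    c = vertices.mean(axis=0)
    d = vertices - c
    order = np.argsort(np.arctan2(d[:, 1], d[:, 0]))
    v = vertices[order]
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _periodic_voronoi_areas(sites: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    """Cell area of each site in a periodic 2D box (3×3 image tiling)."""
    n = len(sites)
    if n < 3:
        raise ValueError(f"need at least 3 Voronoi sites per leaflet, got {n}")
    # de-duplicate coincident seeds with a tiny deterministic jitter
    _, inverse, counts = np.unique(np.round(sites / 1e-9).astype(np.int64),
                                   axis=0, return_inverse=True,
                                   return_counts=True)
    if np.any(counts > 1):
        warnings.warn("duplicate Voronoi sites; jittering by 1e-6 nm")
        sites = sites.copy()
        for g in np.nonzero(counts > 1)[0]:
            dup = np.nonzero(inverse == g)[0]
            for k, i in enumerate(dup[1:], start=1):
                sites[i] += 1e-6 * np.array([k, -k])
    tiled = np.concatenate(
        [sites] + [sites + _TILE[k] * box_xy for k in range(len(_TILE))])
    vor = Voronoi(tiled)
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region:  # pragma: no cover - cannot happen with full tiling
            raise RuntimeError("unbounded central Voronoi cell")
        areas[i] = _polygon_area(vor.vertices[region])
    return areas


@dataclass
class FrameApL:
    """Single-frame tessellation result."""

    per_lipid_area: dict[int, float]          # mol id → nm² (sum of chain cells)
    peptide_area: dict[int, float]            # peptide mol id → nm²
    leaflet_total: dict[str, float]           # leaflet → summed cell area
    box_area: float


@dataclass
class ApLTable:
    """Time-averaged chain-pair-weighted ApL per species and environment."""

    per_species: dict[str, BootstrapEstimate]  # nm² per chain pair
    environment: str = "all"

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"species": s, "environment": self.environment,
              "apl_nm2": e.mean, "ci_low": e.ci_low, "ci_high": e.ci_high,
              "n_eff": e.n_eff} for s, e in self.per_species.items()])


def voronoi_apl(frame: Frame, topology: Topology, leaflets: LeafletMap,
                include_peptide_sites: bool = False) -> FrameApL:
    """Tessellate one frame, per leaflet, from C1 chain beads (+ optional
    Trp19 peptide sites); returns per-lipid summed chain-cell areas."""
    box_xy = frame.box[:2]
    per_lipid: dict[int, float] = {}
    per_pep: dict[int, float] = {}
    totals: dict[str, float] = {}
    is_c1 = (topology.chain >= 0) & (topology.chain_pos == 0)
    for lf in ("upper", "lower"):
        lipid_mols = leaflets.mols(lf, topology, lipids_only=True)
        keep = np.zeros(topology.n_mols, dtype=bool)
        keep[lipid_mols] = True
        c1_idx = np.nonzero(is_c1 & keep[topology.mol_id])[0]
        owners = topology.mol_id[c1_idx]
        sites = frame.positions[c1_idx, :2]
        pep_owners = np.empty(0, dtype=int)
        if include_peptide_sites:
            pep_mols = [m for m in topology.peptide_mols if leaflets[m] == lf]
            pep_idx = [i for m in pep_mols
                       for i in topology.beads_of(m, topology.is_backbone)
                       if topology.residue[i] == TRP19_RESIDUE_INDEX]
            if pep_idx:
                pep_idx = np.asarray(pep_idx)
                sites = np.vstack([sites, frame.positions[pep_idx, :2]])
                pep_owners = topology.mol_id[pep_idx]
        areas = _periodic_voronoi_areas(np.mod(sites, box_xy), box_xy)
        totals[lf] = float(areas.sum())
        n_lip = len(owners)
        for mol in lipid_mols:
            per_lipid[int(mol)] = float(areas[:n_lip][owners == mol].sum())
        for k, mol in enumerate(pep_owners):
            per_pep[int(mol)] = per_pep.get(int(mol), 0.0) + float(areas[n_lip + k])
    return FrameApL(per_lipid_area=per_lipid, peptide_area=per_pep,
                    leaflet_total=totals, box_area=float(box_xy[0] * box_xy[1]))


def species_apl(traj: Trajectory, leaflets: LeafletMap,
                window: tuple[float, float] | None = None,
                environment_labels: list[dict[int, str]] | None = None,
                environment: str = "all",
                include_peptide_sites: bool = False,
                n_boot: int = 1000, seed: int = 0) -> ApLTable:
    """Chain-pair-weighted ApL per species, averaged over a frame window.

    ``environment_labels`` (one dict per frame, mol id → label from
    :func:`annular_bulk_split`) restricts the average to lipids whose label
    matches ``environment`` (exact, or prefix before "-annular" for the
    aggregate "annular").
    """
    if window is not None:
        traj = traj.window(*window)
    comp = traj.composition
    top = traj.topology
    series: dict[str, list[float]] = {s: [] for s in comp.species_names
                                      if top.mols_of_species(s).size}

    def match(label: str) -> bool:
        if environment == "all":
            return True
        if environment == "annular":
            return label.endswith("annular")
        return label == environment

    for fi, frame in enumerate(traj.frames):
        fa = voronoi_apl(frame, top, leaflets,
                         include_peptide_sites=include_peptide_sites)
        labels = environment_labels[fi] if environment_labels else None
        for sname in series:
            spec = comp.spec(sname)
            vals = [fa.per_lipid_area[int(m)] / spec.n_chain_pairs
                    for m in top.mols_of_species(sname)
                    if labels is None or match(labels.get(int(m), "bulk"))]
            if vals:
                series[sname].append(float(np.mean(vals)))
    rng = np.random.default_rng(seed)
    return ApLTable(
        per_species={s: point_or_bootstrap(np.asarray(v), n_boot=n_boot,
                                           rng=rng)
                     for s, v in series.items() if v},
        environment=environment)


def apl_ratio(with_pep: ApLTable, without_pep: ApLTable
              ) -> dict[str, tuple[float, float]]:
    """ApL_PEP+/ApL_PEP− per species with propagated uncertainty."""
    out = {}
    for s in with_pep.per_species:
        if s not in without_pep.per_species:
            raise ValueError(f"species {s} missing from the peptide-free table")
        a, b = with_pep.per_species[s], without_pep.per_species[s]
        out[s] = propagate_ratio(a.mean, a.se, b.mean, b.se)
    return out


def annular_bulk_split(frame: Frame, topology: Topology, cutoff: float = 1.0,
                       peptide_state: dict[int, str] | None = None
                       ) -> dict[int, str]:
    """Label each lipid annular (any bead within ``cutoff`` of any peptide
    bead, 3D min-image) or bulk.

    With ``peptide_state`` (peptide mol id → "monomer"/"dimer"/"pore") the
    annular label is refined to "<state>-annular" using the highest-priority
    contacting peptide (pore > dimer > monomer).
    """
    labels: dict[int, str] = {}
    pep_beads = np.nonzero(topology.is_peptide)[0]
    lipid_mols = topology.lipid_mols
    if pep_beads.size == 0:
        return {int(m): "bulk" for m in lipid_mols}
    tree = cKDTree(np.mod(frame.positions[pep_beads], frame.box),
                   boxsize=frame.box)
    priority = {"pore": 2, "dimer": 1, "monomer": 0}
    for mol in lipid_mols:
        sl = topology.mol_slice(int(mol))
        pts = np.mod(frame.positions[sl], frame.box)
        neighbours = tree.query_ball_point(pts, cutoff)
        contacting = {int(topology.mol_id[pep_beads[j]])
                      for hits in neighbours for j in hits}
        if not contacting:
            labels[int(mol)] = "bulk"
        elif peptide_state is None:
            labels[int(mol)] = "annular"
        else:
            best = max(contacting,
                       key=lambda p: priority[peptide_state.get(p, "monomer")])
            labels[int(mol)] = f"{peptide_state.get(best, 'monomer')}-annular"
    return labels


@dataclass
class OrderProfile:
    """P2 per (species, bond index, environment); bond 1 = C1–C2."""

    data: pd.DataFrame  # columns: species, bond, environment, p2, se, n

    def profile(self, species: str, environment: str = "all") -> pd.Series:
        sel = self.data[(self.data.species == species)
                        & (self.data.environment == environment)]
        return sel.set_index("bond")["p2"]

    def chain_average(self, species: str, environment: str = "all") -> float:
        """Mean P2 over all bonds of the chain (the C1–C4/C1–C5 average)."""
        return float(self.profile(species, environment).mean())


def bond_order_p2(traj: Trajectory,
                  window: tuple[float, float] | None = None,
                  environment_labels: list[dict[int, str]] | None = None,
                  n_boot: int = 1000, seed: int = 0) -> OrderProfile:
    """Second-rank order parameter of every acyl-chain bond vs the z axis.

    Bonds link consecutive chain beads (bond 1 = C1–C2; the headgroup–C1 link
    is excluded).  With ``environment_labels`` the profile is additionally
    split into aggregate "annular" and "bulk" classes; otherwise a single
    "all" class is emitted.  The standard error is a bootstrap over per-frame
    means.
    """
    if window is not None:
        traj = traj.window(*window)
    top = traj.topology
    comp = traj.composition
    envs = ["all"] if environment_labels is None else ["all", "annular", "bulk"]
    per_frame: dict[tuple[str, int, str], list[float]] = {}
    # bond bead-index pairs, robust to arbitrary bead order within a molecule
    chain_beads = np.nonzero(top.chain >= 0)[0]
    order = chain_beads[np.lexsort((top.chain_pos[chain_beads],
                                    top.chain[chain_beads],
                                    top.mol_id[chain_beads]))]
    a, b = order[:-1], order[1:]
    bonded = ((top.mol_id[a] == top.mol_id[b])
              & (top.chain[a] == top.chain[b])
              & (top.chain_pos[b] == top.chain_pos[a] + 1))
    bond_i, bond_j = a[bonded], b[bonded]
    bond_no_all = top.chain_pos[bond_j]  # 1-based: C1–C2 → 1
    mols_all = top.mol_id[bond_i]
    species_all = top.species[bond_i]
    skipped = 0
    for fi, frame in enumerate(traj.frames):
        labels = environment_labels[fi] if environment_labels else None
        vec = min_image_displacement(frame.positions[bond_i],
                                     frame.positions[bond_j], frame.box)
        norms = np.linalg.norm(vec, axis=1)
        ok = norms > 0
        if not np.all(ok):
            skipped += int((~ok).sum())
        cos2 = np.zeros(len(norms))
        cos2[ok] = (vec[ok, 2] / norms[ok]) ** 2
        p2 = (1.5 * cos2 - 0.5)[ok]
        bond_no = bond_no_all[ok]
        mols = mols_all[ok]
        species = species_all[ok]
        for sname in comp.species_names:
            s_sel = species == sname
            if not s_sel.any():
                continue
            for env in envs:
                if env == "all":
                    e_sel = s_sel
                else:
                    lab = np.array([
                        (labels.get(int(m), "bulk") if labels else "bulk")
                        for m in mols])
                    in_env = (np.char.endswith(lab.astype(str), "annular")
                              if env == "annular" else lab == "bulk")
                    e_sel = s_sel & in_env
                if not e_sel.any():
                    continue
                for b in np.unique(bond_no[e_sel]):
                    key = (sname, int(b), env)
                    per_frame.setdefault(key, []).append(
                        float(p2[e_sel & (bond_no == b)].mean()))
    if skipped:
        warnings.warn(f"skipped {skipped} zero-length bond vectors")
    rng = np.random.default_rng(seed)
    rows = []
    for (sname, b, env), vals in sorted(per_frame.items()):
        arr = np.asarray(vals)
        if arr.size >= 10:
            est = point_or_bootstrap(arr, n_boot=n_boot, rng=rng)
            se = est.se
        else:
            se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
        rows.append({"species": sname, "bond": b, "environment": env,
                     "p2": float(arr.mean()), "se": se, "n": arr.size})
    return OrderProfile(data=pd.DataFrame(rows))
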