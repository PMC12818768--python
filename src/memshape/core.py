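"""System description, trajectory ingestion and periodic-boundary geometry.

Everything downstream (thickness, packing, diffusion, contacts, clustering)
consumes the containers defined here:

* :class:`SpeciesSpec` / :class:`SystemComposition` — declarative bead topology
  of each lipid species (chains, phosphates, charge, intrinsic-curvature sign)
  and of the adsorbed peptides.
* :class:`Topology` — flat per-bead arrays (molecule id, species, bead name,
  chain index, peptide residue index) shared by all frames of a trajectory.
* :class:`Frame` / :class:`Trajectory` — wrapped coordinates in nm with an
  orthorhombic periodic box, times in ns.
* :class:`LeafletMap` — frozen upper/lower assignment of every lipid and
  peptide, taken at a single reference frame.

Units follow GROMACS file conventions throughout: lengths in nm, times in ns,
areas in nm².  Ångström appears only in reporting helpers (×10).

File formats: GRO coordinate files and XTC/TRR trajectories are read through
MDAnalysis; a plain columnar text format (one row per bead per frame) is
supported as a fixture-friendly fallback and for round-tripping synthetic
trajectories.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CompositionError",
    "FormatError",
    "EmptySelectionError",
    "LeafletAssignmentError",
    "UnwrapError",
    "UndefinedRatioError",
    "SpeciesSpec",
    "SystemComposition",
    "Topology",
    "Frame",
    "Trajectory",
    "LeafletMap",
    "load_composition",
    "load_system",
    "write_gro",
    "write_columnar",
    "read_columnar",
    "bilayer_center",
    "assign_leaflets",
    "min_image_displacement",
    "min_image_distance",
    "wrap_positions",
    "make_whole",
    "residues_from_sequence",
    "ECDBS1R4_SEQUENCE",
]


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------

class CompositionError(ValueError):
    """A bead/residue in the input cannot be resolved against the composition."""


class FormatError(ValueError):
    """A coordinate or trajectory file violates the expected format."""


class EmptySelectionError(ValueError):
    """An operation's selection (e.g. phosphate beads) matched nothing."""


class LeafletAssignmentError(ValueError):
    """A molecule sits ambiguously close to the bilayer midplane."""


class UnwrapError(ValueError):
    """Frame-to-frame displacement too large to unwrap unambiguously."""


class UndefinedRatioError(ValueError):
    """A ratio whose denominator is statistically indistinguishable from 0."""


# --------------------------------------------------------------------------
# Composition
# --------------------------------------------------------------------------

#: EcDBS1R4, the designed antimicrobial peptide studied throughout.
ECDBS1R4_SEQUENCE = "PMKKKLAARILAKIVAPVW"

_AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def residues_from_sequence(sequence: str) -> list[str]:
    """Expand a one-letter amino-acid sequence into three-letter residue names."""
    try:
        return [_AA_1TO3[c] for c in sequence.upper()]
    except KeyError as exc:  # pragma: no cover - defensive
        raise CompositionError(f"unknown amino acid code {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class SpeciesSpec:
    """Bead topology of one lipid species.

    Parameters
    ----------
    name:
        Residue name as it appears in coordinate files (e.g. ``POPE``).
    charge:
        Net charge in elementary charges.
    n_acyl_chains:
        2 for ordinary phospholipids, 4 for cardiolipin.
    chain_beads:
        Ordered bead names per acyl chain, e.g. ``[["C1A","C2A","C3A","C4A"],
        ["C1B","C2B","C3B","C4B"]]``.  The first bead of each chain (C1) seeds
        the Voronoi tessellation.
    headgroup_beads:
        Phosphate bead name(s); cardiolipin carries two.
    extra_beads:
        Linker/headgroup beads that are neither phosphate nor chain (glycerols,
        amine, choline...), accepted on input but not used by any metric.
    curvature_sign:
        ``"negative"`` for cone-shaped lipids (PE, CL), ``"zero"`` for
        cylinder-shaped ones (PC, PG).  Metadata only.
    anionic_equivalents:
        How many anionic lipids this species counts as when balancing charge
        density; 2 for cardiolipin, otherwise 1 if anionic else 0.
    """

    name: str
    charge: int
    n_acyl_chains: int
    chain_beads: tuple[tuple[str, ...], ...]
    headgroup_beads: tuple[str, ...]
    extra_beads: tuple[str, ...] = ()
    curvature_sign: str = "zero"
    anionic_equivalents: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "chain_beads",
                           tuple(tuple(c) for c in self.chain_beads))
        object.__setattr__(self, "headgroup_beads", tuple(self.headgroup_beads))
        object.__setattr__(self, "extra_beads", tuple(self.extra_beads))
        if self.n_acyl_chains not in (2, 4):
            raise CompositionError(
                f"{self.name}: n_acyl_chains must be 2 or 4, got {self.n_acyl_chains}")
        if len(self.chain_beads) != self.n_acyl_chains:
            raise CompositionError(
                f"{self.name}: {len(self.chain_beads)} chains declared but "
                f"n_acyl_chains={self.n_acyl_chains}")
        all_beads = [b for c in self.chain_beads for b in c]
        all_beads += list(self.headgroup_beads) + list(self.extra_beads)
        if len(set(all_beads)) != len(all_beads):
            raise CompositionError(f"{self.name}: duplicate bead names")
        if self.curvature_sign not in ("negative", "zero"):
            raise CompositionError(
                f"{self.name}: curvature_sign must be 'negative' or 'zero'")
        cardiolipin_like = self.n_acyl_chains == 4 and len(self.headgroup_beads) == 2
        if (self.anionic_equivalents == 2) != cardiolipin_like:
            raise CompositionError(
                f"{self.name}: anionic_equivalents=2 is reserved for "
                "cardiolipin-like species (4 chains, 2 phosphates)")

    @property
    def n_chain_pairs(self) -> float:
        return self.n_acyl_chains / 2.0

    @property
    def beads(self) -> tuple[str, ...]:
        return (tuple(self.headgroup_beads) + tuple(self.extra_beads)
                + tuple(b for c in self.chain_beads for b in c))


@dataclass
class SystemComposition:
    """Lipid species, per-leaflet molecule counts, and the peptide complement."""

    species: list[SpeciesSpec]
    counts_per_leaflet: dict[str, int]
    peptide_count_per_leaflet: int = 0
    peptide_residues: list[str] = field(
        default_factory=lambda: residues_from_sequence(ECDBS1R4_SEQUENCE))
    backbone_bead: str = "BB"
    sidechain_beads: tuple[str, ...] = ("SC1", "SC2", "SC3", "SC4")

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise CompositionError("duplicate species names")
        for name, n in self.counts_per_leaflet.items():
            if name not in names:
                raise CompositionError(f"count given for unknown species {name!r}")
            if n <= 0:
                raise CompositionError(f"{name}: count must be strictly positive")
        if self.peptide_count_per_leaflet < 0:
            raise CompositionError("peptide count must be >= 0")

    def spec(self, name: str) -> SpeciesSpec:
        for s in self.species:
            if s.name == name:
                return s
        raise CompositionError(f"unknown species {name!r}")

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def n_lipids(self) -> int:
        return 2 * sum(self.counts_per_leaflet.get(s.name, 0) for s in self.species)

    @property
    def n_peptides(self) -> int:
        return 2 * self.peptide_count_per_leaflet

    @property
    def pl_ratio(self) -> float:
        """Peptide-to-lipid mole ratio (e.g. 1:12 → 0.0833)."""
        if self.n_lipids == 0:
            raise CompositionError("no lipids in composition")
        return self.n_peptides / self.n_lipids

    def mole_fractions(self) -> dict[str, float]:
        total = sum(self.counts_per_leaflet.values())
        return {k: v / total for k, v in self.counts_per_leaflet.items()}


def load_composition(path: str | Path) -> SystemComposition:
    """Read a YAML composition file (species topologies + counts + peptide)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    species = []
    counts = {}
    for entry in raw.get("species", []):
        entry = dict(entry)
        counts[entry["name"]] = int(entry.pop("count_per_leaflet", 0) or 0)
        species.append(SpeciesSpec(
            name=entry["name"],
            charge=int(entry.get("charge", 0)),
            n_acyl_chains=int(entry["n_acyl_chains"]),
            chain_beads=tuple(tuple(c) for c in entry["chain_beads"]),
            headgroup_beads=tuple(entry["headgroup_beads"]),
            extra_beads=tuple(entry.get("extra_beads", ())),
            curvature_sign=entry.get("curvature_sign", "zero"),
            anionic_equivalents=int(entry.get("anionic_equivalents", 0)),
        ))
    counts = {k: v for k, v in counts.items() if v > 0}
    pep = raw.get("peptide") or {}
    if "sequence" in pep:
        residues = residues_from_sequence(pep["sequence"])
    else:
        residues = list(pep.get("residues",
                                residues_from_sequence(ECDBS1R4_SEQUENCE)))
    return SystemComposition(
        species=species,
        counts_per_leaflet=counts,
        peptide_count_per_leaflet=int(pep.get("count_per_leaflet", 0)),
        peptide_residues=residues,
        backbone_bead=pep.get("backbone_bead", "BB"),
        sidechain_beads=tuple(pep.get("sidechain_beads", ("SC1", "SC2", "SC3", "SC4"))),
    )


# --------------------------------------------------------------------------
# Topology / frames
# --------------------------------------------------------------------------

PEPTIDE_SPECIES = "PEP"


class Topology:
    """Per-bead arrays shared by every frame of a trajectory.

    Beads of one molecule are contiguous and molecule ids run 0..n_mols-1 in
    order of appearance.  ``chain``/``chain_pos`` index acyl-chain beads
    (-1 elsewhere); ``residue`` indexes peptide residues 0-based (-1 for
    lipids).
    """

    def __init__(self, mol_id, species, bead, chain, chain_pos, residue,
                 is_phosphate, is_backbone, composition: SystemComposition):
        self.mol_id = np.asarray(mol_id, dtype=np.int64)
        self.species = np.asarray(species, dtype=object)
        self.bead = np.asarray(bead, dtype=object)
        self.chain = np.asarray(chain, dtype=np.int64)
        self.chain_pos = np.asarray(chain_pos, dtype=np.int64)
        self.residue = np.asarray(residue, dtype=np.int64)
        self.is_phosphate = np.asarray(is_phosphate, dtype=bool)
        self.is_backbone = np.asarray(is_backbone, dtype=bool)
        self.composition = composition
        self.is_peptide = self.species == PEPTIDE_SPECIES
        self.is_lipid = ~self.is_peptide
        if np.any(np.diff(self.mol_id) < 0):
            raise CompositionError("molecule ids must be non-decreasing")
        self.n_beads = len(self.mol_id)
        self.n_mols = int(self.mol_id.max()) + 1 if self.n_beads else 0
        # per-molecule lookup tables
        first = np.searchsorted(self.mol_id, np.arange(self.n_mols))
        last = np.searchsorted(self.mol_id, np.arange(self.n_mols), side="right")
        self._mol_start, self._mol_stop = first, last
        self.mol_species = self.species[first]
        self.mol_is_peptide = self.mol_species == PEPTIDE_SPECIES

    # -- selections --------------------------------------------------------
    def mol_slice(self, mol: int) -> slice:
        return slice(int(self._mol_start[mol]), int(self._mol_stop[mol]))

    @property
    def lipid_mols(self) -> np.ndarray:
        return np.nonzero(~self.mol_is_peptide)[0]

    @property
    def peptide_mols(self) -> np.ndarray:
        return np.nonzero(self.mol_is_peptide)[0]

    def mols_of_species(self, name: str) -> np.ndarray:
        return np.nonzero(self.mol_species == name)[0]

    def beads_of(self, mol: int, mask: np.ndarray | None = None) -> np.ndarray:
        idx = np.arange(self._mol_start[mol], self._mol_stop[mol])
        if mask is not None:
            idx = idx[mask[idx]]
        return idx

    def phosphate_indices(self, mols: Iterable[int] | None = None) -> np.ndarray:
        if mols is None:
            return np.nonzero(self.is_phosphate)[0]
        keep = np.zeros(self.n_mols, dtype=bool)
        keep[np.asarray(list(mols), dtype=int)] = True
        return np.nonzero(self.is_phosphate & keep[self.mol_id])[0]

    def backbone_indices(self, mol: int) -> np.ndarray:
        """Backbone beads of one peptide, ordered by residue index."""
        idx = self.beads_of(mol, self.is_backbone)
        return idx[np.argsort(self.residue[idx], kind="stable")]


@dataclass
class Frame:
    """One snapshot: time (ns), orthorhombic box lengths (nm), wrapped positions (nm)."""

    time: float
    box: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise FormatError("box must be three positive lengths")


@dataclass
class Trajectory:
    """Time-ordered frames over a fixed topology."""

    topology: Topology
    frames: list[Frame]
    composition: SystemComposition = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.composition is None:
            self.composition = self.topology.composition
        times = self.times
        if len(times) > 1:
            steps = np.diff(times)
            if np.any(steps <= 0):
                raise FormatError("frame times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise FormatError("frame spacing must be uniform")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def dt(self) -> float:
        if len(self.frames) < 2:
            return 0.0
        return float(self.frames[1].time - self.frames[0].time)

    def window(self, start: float | None = None, stop: float | None = None) -> "Trajectory":
        """Sub-trajectory with start <= time < stop (ns)."""
        frames = [f for f in self.frames
                  if (start is None or f.time >= start)
                  and (stop is None or f.time < stop)]
        return Trajectory(self.topology, frames, self.composition)


@dataclass
class LeafletMap:
    """Frozen per-molecule upper/lower labels, assigned at one reference frame."""

    labels: np.ndarray  # shape (n_mols,), values "upper"/"lower"
    assignment_time: float

    def __getitem__(self, mol: int) -> str:
        return str(self.labels[mol])

    def mols(self, leaflet: str, topology: Topology,
             lipids_only: bool = False) -> np.ndarray:
        sel = self.labels == leaflet
        if lipids_only:
            sel &= ~topology.mol_is_peptide
        return np.nonzero(sel)[0]


# --------------------------------------------------------------------------
# Periodic geometry
# --------------------------------------------------------------------------

def min_image_displacement(a: np.ndarray, b: np.ndarray, box: np.ndarray,
                           xy_only: bool = False) -> np.ndarray:
    """Displacement b−a under the nearest-periodic-image convention.

    Broadcasts over leading dimensions.  With ``xy_only`` the z component is
    dropped (in-plane displacement for a bilayer normal along z).
    """
    box = np.asarray(box, dtype=float)
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    ndim = 2 if xy_only else min(d.shape[-1], 3)
    d = d[..., :ndim].copy()
    d -= box[:ndim] * np.round(d / box[:ndim])
    return d


def min_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray,
                       xy_only: bool = False) -> np.ndarray:
    """Euclidean distance under the nearest-image convention (optionally in-plane)."""
    d = min_image_displacement(a, b, box, xy_only=xy_only)
    return np.sqrt(np.sum(d * d, axis=-1))


def wrap_positions(pos: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into [0, box)."""
    box = np.asarray(box, dtype=float)
    return np.mod(pos, box)


def pairwise_min_image(a: np.ndarray, b: np.ndarray, box: np.ndarray,
                       xy_only: bool = False) -> np.ndarray:
    """(len(a), len(b)) matrix of min-image distances."""
    return min_image_distance(a[:, None, :], b[None, :, :], box, xy_only=xy_only)


def make_whole(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Undo periodic wrapping along an ordered bead chain.

    Consecutive rows are assumed bonded with bond lengths < box/2 (true for
    all bead chains here), so chaining min-image displacements from the first
    bead reconstructs the contiguous molecule.
    """
    pos = np.asarray(positions, dtype=float)
    steps = min_image_displacement(pos[:-1], pos[1:], box)
    out = np.empty_like(pos)
    out[0] = pos[0]
    out[1:] = pos[0] + np.cumsum(steps, axis=0)
    return out


# --------------------------------------------------------------------------
# Bilayer center & leaflets
# --------------------------------------------------------------------------

def bilayer_center(frame: Frame, topology: Topology) -> float:
    """Mean z of all phosphate beads (both leaflets), in nm."""
    idx = np.nonzero(topology.is_phosphate)[0]
    if idx.size == 0:
        raise EmptySelectionError("no phosphate beads in topology")
    return float(frame.positions[idx, 2].mean())


def assign_leaflets(frame: Frame, topology: Topology,
                    tolerance: float = 0.05) -> LeafletMap:
    """Assign every lipid and peptide to the upper or lower leaflet.

    A lipid follows the sign of (mean phosphate z − bilayer center); a peptide
    follows its backbone center of mass.  Molecules within ``tolerance`` nm of
    the midplane raise :class:`LeafletAssignmentError` — labels are meant to be
    frozen at a frame where the geometry is unambiguous.
    """
    center = bilayer_center(frame, topology)
    labels = np.empty(topology.n_mols, dtype=object)
    for mol in range(topology.n_mols):
        if topology.mol_is_peptide[mol]:
            idx = topology.beads_of(mol, topology.is_backbone)
        else:
            idx = topology.beads_of(mol, topology.is_phosphate)
        if idx.size == 0:
            raise EmptySelectionError(f"molecule {mol} has no reference beads")
        dz = float(frame.positions[idx, 2].mean()) - center
        if abs(dz) < tolerance or dz == 0.0:
            raise LeafletAssignmentError(
                f"molecule {mol} within {tolerance} nm of the bilayer center "
                f"(dz={dz:.4f} nm)")
        labels[mol] = "upper" if dz > 0 else "lower"
    return LeafletMap(labels=labels, assignment_time=frame.time)


# --------------------------------------------------------------------------
# Topology construction from residue records
# --------------------------------------------------------------------------

def _classify_lipid_bead(spec: SpeciesSpec, bead: str) -> tuple[int, int, bool]:
    """Return (chain, chain_pos, is_phosphate) for a bead of a lipid species."""
    if bead in spec.headgroup_beads:
        return -1, -1, True
    for ci, chain in enumerate(spec.chain_beads):
        if bead in chain:
            return ci, chain.index(bead), False
    if bead in spec.extra_beads:
        return -1, -1, False
    raise CompositionError(
        f"bead {bead!r} not declared for species {spec.name!r}")


def build_topology(records: Sequence[tuple[str, str, list[tuple[str, str]]]],
                   composition: SystemComposition) -> Topology:
    """Build a Topology from per-molecule records.

    ``records`` is a sequence of (kind, species, beads) with kind "lipid" or
    "peptide"; ``beads`` is an ordered list of (bead_name, residue_name) —
    residue_name is ignored for lipids.
    """
    mol_id, species_a, bead_a = [], [], []
    chain_a, cpos_a, res_a = [], [], []
    phos_a, bb_a = [], []
    for mid, (kind, sname, beads) in enumerate(records):
        if kind == "lipid":
            spec = composition.spec(sname)
            for bead, _res in beads:
                ci, cp, isp = _classify_lipid_bead(spec, bead)
                mol_id.append(mid); species_a.append(sname); bead_a.append(bead)
                chain_a.append(ci); cpos_a.append(cp); res_a.append(-1)
                phos_a.append(isp); bb_a.append(False)
        else:
            for bead, res_idx in beads:
                if bead != composition.backbone_bead and \
                        bead not in composition.sidechain_beads:
                    raise CompositionError(
                        f"bead {bead!r} not declared for the peptide")
                mol_id.append(mid); species_a.append(PEPTIDE_SPECIES)
                bead_a.append(bead)
                chain_a.append(-1); cpos_a.append(-1); res_a.append(int(res_idx))
                phos_a.append(False)
                bb_a.append(bead == composition.backbone_bead)
    return Topology(mol_id, species_a, bead_a, chain_a, cpos_a, res_a,
                    phos_a, bb_a, composition)


def _records_from_universe(universe, composition: SystemComposition):
    """Group an MDAnalysis Universe's residues into molecule records."""
    species_names = set(composition.species_names)
    pep_res = composition.peptide_residues
    residues = list(universe.residues)
    records = []
    atom_order = []  # MDAnalysis atom indices in record order
    i = 0
    while i < len(residues):
        res = residues[i]
        rname = str(res.resname).strip()
        if rname in species_names:
            beads = [(str(a.name).strip(), rname) for a in res.atoms]
            # validate now so the error names the offending bead
            spec = composition.spec(rname)
            for bead, _ in beads:
                _classify_lipid_bead(spec, bead)
            records.append(("lipid", rname, beads))
            atom_order.extend(a.index for a in res.atoms)
            i += 1
        elif rname == pep_res[0] and i + len(pep_res) <= len(residues) and \
                all(str(residues[i + k].resname).strip() == pep_res[k]
                    for k in range(len(pep_res))):
            beads = []
            for k in range(len(pep_res)):
                for a in residues[i + k].atoms:
                    beads.append((str(a.name).strip(), k))
                    atom_order.append(a.index)
            records.append(("peptide", PEPTIDE_SPECIES, beads))
            i += len(pep_res)
        else:
            raise CompositionError(
                f"residue {rname!r} (index {i}) cannot be resolved against the "
                "composition (unknown species and not the start of the peptide "
                "sequence)")
    return records, np.array(atom_order, dtype=int)


def _box_from_dimensions(dims) -> np.ndarray:
    if dims is None or not np.all(np.asarray(dims)[:3] > 0):
        raise FormatError("coordinate file carries no periodic box")
    dims = np.asarray(dims, dtype=float)
    if not np.allclose(dims[3:6], 90.0, atol=1e-3):
        raise FormatError("only orthorhombic boxes are supported")
    return dims[:3] / 10.0  # Å → nm


def load_system(coordinate_file: str | Path,
                trajectory_file: str | Path | None = None,
                composition_file: str | Path | SystemComposition = None,
                ) -> Trajectory:
    """Load a GRO coordinate file (plus optional XTC/TRR or columnar trajectory).

    Coordinates come back in nm, times in ns, wrapped into the box.  Without a
    trajectory file the result holds the single coordinate frame.  Every bead
    and residue must resolve against the composition, else
    :class:`CompositionError` names the offender.
    """
    if composition_file is None:
        raise CompositionError("a composition (file or object) is required")
    if isinstance(composition_file, SystemComposition):
        composition = composition_file
    else:
        composition = load_composition(composition_file)

    traj_path = Path(trajectory_file) if trajectory_file is not None else None
    if traj_path is not None and traj_path.suffix.lower() in {".csv", ".tsv", ".dat"}:
        return read_columnar(traj_path, composition)

    import MDAnalysis as mda

    if traj_path is None:
        universe = mda.Universe(str(coordinate_file))
    else:
        universe = mda.Universe(str(coordinate_file), str(traj_path))
    records, atom_order = _records_from_universe(universe, composition)
    topology = build_topology(records, composition)

    frames = []
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.filterwarnings("ignore",
                                 message="Reader has no dt information.*")
        for ts in universe.trajectory:
            box = _box_from_dimensions(ts.dimensions)
            pos = np.asarray(ts.positions, dtype=float)[atom_order] / 10.0
            frames.append(Frame(time=float(ts.time) / 1000.0,  # ps → ns
                                box=box, positions=wrap_positions(pos, box)))
    return Trajectory(topology, frames, composition)


# --------------------------------------------------------------------------
# Writers / columnar fallback
# --------------------------------------------------------------------------

def write_gro(frame: Frame, topology: Topology, path: str | Path,
              title: str = "memshape frame") -> None:
    """Write one frame in fixed-column GRO format (nm, %8.3f precision)."""
    comp = topology.composition
    lines = [title, f"{topology.n_beads:5d}"]
    atom = 0
    resid = 0
    for mol in range(topology.n_mols):
        sl = topology.mol_slice(mol)
        if topology.mol_is_peptide[mol]:
            res_of_bead = topology.residue[sl]
            base = resid
            for j, bi in enumerate(range(sl.start, sl.stop)):
                r = base + int(res_of_bead[j])
                rname = comp.peptide_residues[int(res_of_bead[j])]
                atom += 1
                x, y, z = frame.positions[bi]
                lines.append(f"{(r % 100000) + 1:5d}{rname:<5s}"
                             f"{str(topology.bead[bi]):>5s}{atom % 100000:5d}"
                             f"{x:8.3f}{y:8.3f}{z:8.3f}")
            resid = base + len(comp.peptide_residues)
        else:
            resid += 1
            rname = str(topology.mol_species[mol])
            for bi in range(sl.start, sl.stop):
                atom += 1
                x, y, z = frame.positions[bi]
                lines.append(f"{resid % 100000:5d}{rname:<5s}"
                             f"{str(topology.bead[bi]):>5s}{atom % 100000:5d}"
                             f"{x:8.3f}{y:8.3f}{z:8.3f}")
    bx, by, bz = frame.box
    lines.append(f"{bx:10.5f}{by:10.5f}{bz:10.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


_COLUMNAR_COLS = ["frame", "time", "mol", "species", "residue", "bead",
                  "x", "y", "z", "box_x", "box_y", "box_z"]


def write_columnar(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as plain columnar text (one row per bead per frame)."""
    top = traj.topology
    rows = []
    for fi, frame in enumerate(traj.frames):
        n = top.n_beads
        rows.append(pd.DataFrame({
            "frame": np.full(n, fi), "time": np.full(n, frame.time),
            "mol": top.mol_id, "species": top.species,
            "residue": top.residue, "bead": top.bead,
            "x": frame.positions[:, 0], "y": frame.positions[:, 1],
            "z": frame.positions[:, 2],
            "box_x": np.full(n, frame.box[0]), "box_y": np.full(n, frame.box[1]),
            "box_z": np.full(n, frame.box[2]),
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False,
                                              float_format="%.6f")


def read_columnar(path: str | Path,
                  composition: SystemComposition) -> Trajectory:
    """Read the columnar fallback trajectory format."""
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNAR_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"columnar trajectory missing columns {missing}")
    first = df[df["frame"] == df["frame"].iloc[0]]
    records = []
    for mol, grp in first.groupby("mol", sort=True):
        sname = str(grp["species"].iloc[0])
        if sname == PEPTIDE_SPECIES:
            beads = list(zip(grp["bead"].astype(str), grp["residue"].astype(int)))
            records.append(("peptide", PEPTIDE_SPECIES, beads))
        else:
            beads = [(str(b), sname) for b in grp["bead"]]
            records.append(("lipid", sname, beads))
    topology = build_topology(records, composition)
    frames = []
    for fi, grp in df.groupby("frame", sort=True):
        box = grp[["box_x", "box_y", "box_z"]].iloc[0].to_numpy(dtype=float)
        pos = grp[["x", "y", "z"]].to_numpy(dtype=float)
        frames.append(Frame(time=float(grp["time"].iloc[0]), box=box,
                            positions=wrap_positions(pos, box)))
    return Trajectory(topology, frames, composition)
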