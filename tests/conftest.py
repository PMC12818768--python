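"""Shared fixtures: minimal species/compositions and hand-built frames."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import memshape as ms
from memshape.core import build_topology

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


def make_species(name: str, n_chain_beads: int = 4, charge: int = 0,
                 curvature: str = "zero",
                 cardiolipin: bool = False) -> ms.SpeciesSpec:
    """A minimal lipid species with one phosphate (two for cardiolipin)."""
    if cardiolipin:
        chains = tuple(tuple(f"C{i}{c}" for i in range(1, n_chain_beads + 1))
                       for c in "ABCD")
        return ms.SpeciesSpec(name, -2, 4, chains, ("PO41", "PO42"), (),
                              "negative", 2)
    chains = tuple(tuple(f"C{i}{c}" for i in range(1, n_chain_beads + 1))
                   for c in "AB")
    return ms.SpeciesSpec(name, charge, 2, chains, ("PO4",), (), curvature,
                          1 if charge < 0 else 0)


@pytest.fixture
def pope():
    return make_species("POPE", curvature="negative")


@pytest.fixture
def two_species_comp():
    return ms.SystemComposition(
        [make_species("POPE", curvature="negative"),
         make_species("POPG", charge=-1)],
        {"POPE": 30, "POPG": 15})


@pytest.fixture
def peptide_comp():
    return ms.SystemComposition(
        [make_species("POPE", curvature="negative")],
        {"POPE": 120}, peptide_count_per_leaflet=2)


def lipid_record(species: ms.SpeciesSpec):
    return ("lipid", species.name,
            [(b, species.name) for b in species.beads])


def peptide_record(comp: ms.SystemComposition):
    return ("peptide", "PEP",
            [(comp.backbone_bead, r)
             for r in range(len(comp.peptide_residues))])


def handmade_system(comp: ms.SystemComposition, positions_by_mol, box,
                    time=0.0):
    """Build (Frame, Topology) from explicit per-molecule bead positions.

    ``positions_by_mol`` is a list of ("lipid", species_name, array) or
    ("peptide", None, array) entries; arrays are (n_beads, 3) in nm and must
    match the species' bead count / peptide length.
    """
    records, pos = [], []
    for kind, sname, arr in positions_by_mol:
        if kind == "lipid":
            records.append(lipid_record(comp.spec(sname)))
        else:
            records.append(peptide_record(comp))
        pos.append(np.asarray(arr, dtype=float))
    top = build_topology(records, comp)
    frame = ms.Frame(time=time, box=np.asarray(box, dtype=float),
                     positions=np.mod(np.vstack(pos), box))
    return frame, top


def simple_lipid_positions(spec: ms.SpeciesSpec, x, y, z_head, down=True):
    """Beads stacked vertically below (or above) the phosphate."""
    sgn = -1.0 if down else 1.0
    pos = [[x, y, z_head]] * len(spec.headgroup_beads)
    pos += [[x, y, z_head + sgn * 0.3]] * len(spec.extra_beads)
    for ci, chain in enumerate(spec.chain_beads):
        for k in range(len(chain)):
            pos.append([x + 0.05 * ci, y, z_head + sgn * (0.4 + 0.3 * k)])
    return np.asarray(pos)
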