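"""In-plane lipid self-organisation: cis-RDF and graph-community clustering.

The cis-RDF is the two-dimensional, same-leaflet radial distribution of a
species' phosphate beads around the same species, normalised by the
ideal-gas shell density so that g(r) → 1 for uniform placements.

Clustering follows a community-structure approach: a graph per species and
leaflet whose nodes are lipids and whose edges link phosphates closer
(in-plane, minimum-image) than 2.25 × the species' occupancy radius — the
disk-equivalent radius sqrt(ApL/π) measured in the peptide-free system
(≈ 0.44 nm for an ApL of 0.62 nm², giving the ≈ 1 nm cutoff).  Communities
are found by greedy modularity maximisation (the fast-greedy algorithm);
isolated lipids are size-1 communities.  The cluster-size distribution
reports the fraction of trajectory time whose largest community falls in
each size class (% of the species total).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core import Frame, LeafletMap, Topology, Trajectory, min_image_distance

__all__ = ["RDFCurve", "CommunityPartition", "ClusterSizeDistribution",
           "cis_rdf", "occupancy_radius", "lipid_communities",
           "cluster_size_distribution"]


@dataclass
class RDFCurve:
    """2D same-leaflet radial distribution function of a species."""

    r: np.ndarray   # bin centres (nm)
    g: np.ndarray
    species: str

    def first_peak(self) -> float:
        return float(self.r[int(np.argmax(self.g))])


@dataclass
class CommunityPartition:
    """Community label per lipid of one species in one leaflet/frame."""

    labels: dict[int, int]   # mol id → community id
    modularity: float
    species: str
    leaflet: str

    def sizes(self) -> np.ndarray:
        _, counts = np.unique(list(self.labels.values()), return_counts=True)
        return np.sort(counts)[::-1]

    def communities(self) -> list[set[int]]:
        out: dict[int, set[int]] = {}
        for mol, c in self.labels.items():
            out.setdefault(c, set()).add(mol)
        return [out[k] for k in sorted(out)]


@dataclass
class ClusterSizeDistribution:
    """% of analysed frames whose largest community occupies each size class."""

    class_edges: np.ndarray  # % of species total
    occupancy: np.ndarray    # % of frames per class
    species: str

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class_low_pct": self.class_edges[:-1],
            "class_high_pct": self.class_edges[1:],
            "occupancy_pct": self.occupancy})


# --------------------------------------------------------------------------

def cis_rdf(traj: Trajectory, species: str, leaflets: LeafletMap,
            window: tuple[float, float] | None = None,
            bin_width: float = 0.05, r_max: float | None = None) -> RDFCurve:
    """In-plane same-leaflet RDF of a species' phosphates around themselves.

    Normalised by the ideal-gas expectation N(N−1)/2 · 2πr·dr / A per
    leaflet, averaged over leaflets and the frame window.
    """
    if window is not None:
        traj = traj.window(*window)
    top = traj.topology
    if top.mols_of_species(species).size == 0:
        raise ValueError(f"species {species!r} absent from the system")
    box_xy = traj.frames[0].box[:2]
    if r_max is None:
        r_max = float(min(box_xy) / 2.0)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    norm = np.zeros(len(edges) - 1)
    area = float(box_xy[0] * box_xy[1])
    shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    for frame in traj.frames:
        for lf in ("upper", "lower"):
            mols = [m for m in leaflets.mols(lf, top, lipids_only=True)
                    if top.mol_species[m] == species]
            if len(mols) < 2:
                continue
            idx = np.array([top.beads_of(m, top.is_phosphate)[0] for m in mols])
            xy = frame.positions[idx, :2]
            n = len(xy)
            d = min_image_distance(xy[:, None, :], xy[None, :, :],
                                   frame.box, xy_only=True)
            iu = np.triu_indices(n, k=1)
            hist += np.histogram(d[iu], bins=edges)[0]
            norm += n * (n - 1) / 2.0 * shell / area
    g = np.divide(hist, norm, out=np.zeros_like(hist), where=norm > 0)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return RDFCurve(r=centres, g=g, species=species)


def occupancy_radius(apl: float) -> float:
    """Disk-equivalent radius of one lipid from its area per lipid:
    r = sqrt(ApL/π).  2.25 × this radius is the community-graph cutoff."""
    if apl <= 0:
        raise ValueError("ApL must be positive")
    return float(np.sqrt(apl / np.pi))


def lipid_communities(frame: Frame, topology: Topology, species: str,
                      leaflets: LeafletMap, cutoff: float,
                      leaflet: str = "upper") -> CommunityPartition:
    """Greedy-modularity communities of one species' contact graph.

    Nodes are the species' lipids of one leaflet; edges join phosphates
    within ``cutoff`` (in-plane minimum-image).  Connected components that
    the greedy algorithm does not split further — including isolated
    lipids — come back as their own communities.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    top = topology
    mols = [int(m) for m in leaflets.mols(leaflet, top, lipids_only=True)
            if top.mol_species[m] == species]
    if not mols:
        raise ValueError(f"no {species} lipids in the {leaflet} leaflet")
    idx = np.array([top.beads_of(m, top.is_phosphate)[0] for m in mols])
    xy = frame.positions[idx, :2]
    d = min_image_distance(xy[:, None, :], xy[None, :, :], frame.box,
                           xy_only=True)
    g = nx.Graph()
    g.add_nodes_from(mols)
    ii, jj = np.nonzero(np.triu(d < cutoff, k=1))
    g.add_edges_from((mols[i], mols[j]) for i, j in zip(ii, jj))
    if g.number_of_edges() == 0:
        communities = [{m} for m in mols]
    else:
        communities = [set(c) for c in
                       nx.community.greedy_modularity_communities(g)]
    # deterministic community ids: by lowest member id
    communities.sort(key=lambda c: min(c))
    labels = {m: ci for ci, c in enumerate(communities) for m in c}
    mod = nx.community.modularity(g, communities) if g.number_of_edges() else 0.0
    return CommunityPartition(labels=labels, modularity=float(mod),
                              species=species, leaflet=leaflet)


def cluster_size_distribution(partitions: list[CommunityPartition],
                              species_count: int,
                              class_width: float = 5.0,
                              mode: str = "largest"
                              ) -> ClusterSizeDistribution:
    """Occupancy (% of frames) of community sizes per size class.

    Size classes are ``class_width``-% wide bins of the species' total
    molecule count, covering 0–100%.  ``mode="largest"`` (default) classes
    each frame by its largest community; ``mode="all"`` histograms every
    community of every frame, weighting each frame equally.
    """
    if not partitions:
        raise ValueError("need at least one partition")
    edges = np.arange(0.0, 100.0 + class_width, class_width)
    if mode == "largest":
        pct = 100.0 * np.array([p.sizes()[0] for p in partitions],
                               dtype=float) / species_count
        hist, _ = np.histogram(np.clip(pct, 0, 100 - 1e-9), bins=edges)
        occupancy = 100.0 * hist / len(partitions)
    elif mode == "all":
        hist = np.zeros(len(edges) - 1)
        for p in partitions:
            pct = 100.0 * p.sizes().astype(float) / species_count
            h, _ = np.histogram(np.clip(pct, 0, 100 - 1e-9), bins=edges)
            hist += h / h.sum()
        occupancy = 100.0 * hist / len(partitions)
    else:
        raise ValueError("mode must be 'largest' or 'all'")
    return ClusterSizeDistribution(class_edges=edges, occupancy=occupancy,
                                   species=partitions[0].species)
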