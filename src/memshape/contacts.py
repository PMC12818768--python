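"""Contact-based observables for peptide–peptide and peptide–lipid analysis.

Distance criteria (all minimum-image, bead-to-bead):

* residue–residue contact maps: 0.6 nm (6 Å) over any bead of the residue;
* dimer detection: 0.6 nm over *backbone* beads, a pair counting as a dimer
  only when at least two residues of each peptide contact the partner;
  the Lys4–Trp19 reporter flags the antiparallel interface;
* transmembrane contacts: backbone contact between peptides assigned to
  opposite leaflets; contiguous runs longer than a persistence threshold
  (1 µs by default) are labelled pore frames;
* lipid contact fraction f_c and lipids-per-peptide (LpP): 0.7 nm over any
  bead; LpP is compared to the composition-proportional expectation
  LpP_expected to yield a relative-affinity ratio per species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .core import LeafletMap, Trajectory, pairwise_min_image

__all__ = [
    "ContactMatrix", "DimerEvent", "SurvivalHistogram",
    "ContactFractionSeries", "SolvationStats", "ResidueLipidProfile",
    "PoreLabels", "residue_contact_map", "detect_dimers", "dimer_survival",
    "transmembrane_pore_frames", "contact_fraction", "lipids_per_peptide",
    "residue_lipid_profile", "cluster_profiles", "linkage_to_newick",
    "LYS4_RESIDUE_INDEX", "TRP19_RESIDUE_INDEX",
]

LYS4_RESIDUE_INDEX = 3    # 0-based
TRP19_RESIDUE_INDEX = 18


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class ContactMatrix:
    """Residue × residue contact prevalence (%) over analysed frame/pair samples."""

    matrix: pd.DataFrame
    mode: str
    n_samples: int


@dataclass(frozen=True, order=True)
class DimerEvent:
    """One maximal run of consecutive dimerised frames for a peptide pair."""

    start: float  # ns
    end: float    # ns (exclusive; single-frame episode spans one frame period)
    pair: tuple[int, int]
    reporter: bool

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("episode must have start < end")
        object.__setattr__(self, "pair", tuple(sorted(self.pair)))

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class SurvivalHistogram:
    """Summed dimer time per survival-time class."""

    bin_edges: np.ndarray    # ns
    summed_time: np.ndarray  # ns per bin
    short_fraction: float    # share of summed time in episodes < 50 ns
    long_fraction: float     # share of summed time in episodes > 400 ns

    @property
    def total_time(self) -> float:
        return float(self.summed_time.sum())


@dataclass
class ContactFractionSeries:
    """f_c per species per frame: fraction of lipids touching any peptide."""

    f_c: pd.DataFrame  # index: time (ns), columns: species
    cutoff: float


@dataclass
class SolvationStats:
    """Lipids-per-peptide counts vs the composition-proportional expectation."""

    lpp_observed: dict[str, float]
    lpp_expected: dict[str, float]
    ratio: dict[str, float]
    total_lpp: float
    split: dict[str, dict[str, float]] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"species": s, "lpp_observed": self.lpp_observed[s],
              "lpp_expected": self.lpp_expected[s], "ratio": self.ratio[s]}
             for s in self.lpp_observed])


@dataclass
class ResidueLipidProfile:
    """Residue × species normalised phosphate-contact frequencies."""

    matrix: pd.DataFrame   # rows: residue labels, columns: species
    raw_counts: pd.DataFrame


@dataclass
class PoreLabels:
    """Per-frame labels {none, transmembrane-contact, pore} + participants."""

    times: np.ndarray
    labels: list[str]
    participants: list[set[int]]

    def pore_frames(self) -> list[int]:
        return [i for i, l in enumerate(self.labels) if l == "pore"]

    def exclusion_map(self) -> dict[int, set[int]]:
        """frame index → pore-participant peptide ids (for depth exclusion)."""
        return {i: self.participants[i] for i in self.pore_frames()}


# --------------------------------------------------------------------------
# Internals
# --------------------------------------------------------------------------

def _peptide_bead_groups(top, beads: str):
    """Per peptide: list of per-residue bead-index arrays (ordered by residue)."""
    groups = {}
    for pep in top.peptide_mols:
        sel = top.is_backbone if beads == "backbone" else None
        idx = top.beads_of(pep, sel)
        n_res = len(top.composition.peptide_residues)
        groups[int(pep)] = [idx[top.residue[idx] == r] for r in range(n_res)]
    return groups


def _residue_min_dist(frame, ga, gb, box) -> np.ndarray:
    """(n_res, n_res) matrix of minimum bead distances between residue groups."""
    ia = np.concatenate(ga)
    ib = np.concatenate(gb)
    if len(ia) == len(ga) and len(ib) == len(gb):  # one bead per residue
        return pairwise_min_image(frame.positions[ia], frame.positions[ib], box)
    la = np.repeat(np.arange(len(ga)), [len(g) for g in ga])
    lb = np.repeat(np.arange(len(gb)), [len(g) for g in gb])
    D = pairwise_min_image(frame.positions[ia], frame.positions[ib], box)
    out = np.full((len(ga), len(gb)), np.inf)
    for i in range(len(ga)):
        rows = D[la == i]
        if rows.size == 0:
            continue
        mins = rows.min(axis=0)
        for j in range(len(gb)):
            m = mins[lb == j]
            if m.size:
                out[i, j] = m.min()
    return out


def _pairs(top, leaflets: LeafletMap | None, mode: str) -> list[tuple[int, int]]:
    peps = [int(p) for p in top.peptide_mols]
    pairs = []
    for i, a in enumerate(peps):
        for b in peps[i + 1:]:
            if mode == "all" or leaflets is None:
                pairs.append((a, b))
            elif mode == "same-leaflet" and leaflets[a] == leaflets[b]:
                pairs.append((a, b))
            elif mode == "trans-leaflet" and leaflets[a] != leaflets[b]:
                pairs.append((a, b))
    return pairs


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------

def residue_contact_map(traj: Trajectory, leaflets: LeafletMap | None = None,
                        mode: str = "same-leaflet", threshold: float = 0.6,
                        window: tuple[float, float] | None = None,
                        frame_indices: list[int] | None = None,
                        beads: str = "all") -> ContactMatrix:
    """Time-averaged residue–residue contact prevalence between peptide pairs.

    A cell (i, j) counts the fraction of analysed (frame, pair) samples in
    which residue i of one peptide touches residue j of the other (any bead
    within ``threshold``); the matrix is symmetrised over the pair order.
    ``frame_indices`` restricts the analysis (e.g. to pore frames for
    trans-leaflet pore maps).
    """
    if window is not None:
        traj = traj.window(*window)
    top = traj.topology
    pairs = _pairs(top, leaflets, mode)
    if not pairs:
        raise ValueError("need at least one peptide pair for a contact map")
    groups = _peptide_bead_groups(top, beads)
    n_res = len(top.composition.peptide_residues)
    count = np.zeros((n_res, n_res))
    samples = 0
    frames = traj.frames if frame_indices is None \
        else [traj.frames[i] for i in frame_indices]
    for frame in frames:
        for a, b in pairs:
            D = _residue_min_dist(frame, groups[a], groups[b], frame.box)
            hit = D < threshold
            count += (hit | hit.T)
            samples += 1
    labels = [f"{r}{i + 1}" for i, r in
              enumerate(top.composition.peptide_residues)]
    pct = 100.0 * count / max(samples, 1)
    return ContactMatrix(matrix=pd.DataFrame(pct, index=labels, columns=labels),
                         mode=mode, n_samples=samples)


def _frame_dimer_state(frame, groups, pairs, threshold, min_residues):
    """Per pair: (is_dimer_by_residues, reporter_criterion)."""
    out = {}
    for a, b in pairs:
        D = _residue_min_dist(frame, groups[a], groups[b], frame.box)
        hit = D < threshold
        n_a = int(np.count_nonzero(hit.any(axis=1)))
        n_b = int(np.count_nonzero(hit.any(axis=0)))
        reporter = bool(hit[LYS4_RESIDUE_INDEX, TRP19_RESIDUE_INDEX]
                        and hit[TRP19_RESIDUE_INDEX, LYS4_RESIDUE_INDEX])
        out[(a, b)] = (n_a >= min_residues and n_b >= min_residues, reporter)
    return out


def detect_dimers(traj: Trajectory, threshold: float = 0.6,
                  min_residues: int = 2, gap_tolerance: int = 0,
                  window: tuple[float, float] | None = None,
                  criterion: str = "residues",
                  leaflets: LeafletMap | None = None) -> list[DimerEvent]:
    """Detect dimer episodes from backbone–backbone contacts.

    Per frame a pair is dimerised iff at least ``min_residues`` residues of
    *each* peptide have a backbone bead within ``threshold`` of the partner's
    backbone (``criterion="residues"``), or iff the mutual Lys4–Trp19
    contacts are present (``criterion="reporter"``).  Episodes are maximal
    consecutive runs, tolerating up to ``gap_tolerance`` undimerised frames.
    The event's reporter flag records whether the Lys4–Trp19 interface was
    present in at least half of its frames.
    """
    if window is not None:
        traj = traj.window(*window)
    top = traj.topology
    pairs = _pairs(top, leaflets, "same-leaflet" if leaflets else "all")
    if not pairs:
        raise ValueError("need at least two peptides")
    groups = _peptide_bead_groups(top, "backbone")
    times = traj.times
    dt = traj.dt if traj.dt > 0 else 1.0
    state = {p: [] for p in pairs}
    rep = {p: [] for p in pairs}
    for frame in traj.frames:
        fs = _frame_dimer_state(frame, groups, pairs, threshold, min_residues)
        for p, (dim, reporter) in fs.items():
            on = reporter if criterion == "reporter" else dim
            state[p].append(on)
            rep[p].append(reporter)
    events: list[DimerEvent] = []
    for p in pairs:
        on = np.asarray(state[p])
        idx = np.nonzero(on)[0]
        if idx.size == 0:
            continue
        runs = [[idx[0], idx[0]]]
        for i in idx[1:]:
            if i - runs[-1][1] <= gap_tolerance + 1:
                runs[-1][1] = i
            else:
                runs.append([i, i])
        for s, e in runs:
            rep_frac = float(np.mean(rep[p][s:e + 1]))
            events.append(DimerEvent(start=float(times[s]),
                                     end=float(times[e]) + dt,
                                     pair=p, reporter=rep_frac >= 0.5))
    return sorted(events)


def dimer_survival(events: list[DimerEvent], bins: np.ndarray | None = None,
                   short_cutoff: float = 50.0, long_cutoff: float = 400.0
                   ) -> SurvivalHistogram:
    """Histogram of summed dimer time vs episode survival time.

    Each episode contributes its full duration to the bin of its duration, so
    the histogram integrates to the total time spent in dimers.  The
    short/long fractions summarise the bimodality (< 50 ns vs > 400 ns).
    """
    durations = np.array([e.duration for e in events])
    if durations.size == 0:
        edges = np.array([0.0, 1.0]) if bins is None else np.asarray(bins)
        return SurvivalHistogram(edges, np.zeros(len(edges) - 1), 0.0, 0.0)
    if bins is None:
        bins = np.linspace(0, durations.max() * (1 + 1e-9), 21)
    summed, edges = np.histogram(durations, bins=bins, weights=durations)
    total = durations.sum()
    return SurvivalHistogram(
        bin_edges=edges, summed_time=summed,
        short_fraction=float(durations[durations < short_cutoff].sum() / total),
        long_fraction=float(durations[durations > long_cutoff].sum() / total))


def transmembrane_pore_frames(traj: Trajectory, leaflets: LeafletMap,
                              threshold: float = 0.6,
                              persistence: float = 1000.0,
                              window: tuple[float, float] | None = None
                              ) -> PoreLabels:
    """Label frames with backbone contact between opposite-leaflet peptides.

    A frame is ``transmembrane-contact`` when any backbone bead of an
    upper-leaflet peptide is within ``threshold`` of a lower-leaflet
    peptide's backbone.  Contiguous transmembrane runs longer than
    ``persistence`` ns are relabelled ``pore``, and the contacting peptide
    ids are recorded per frame.
    """
    if window is not None:
        traj = traj.window(*window)
    top = traj.topology
    pairs = _pairs(top, leaflets, "trans-leaflet")
    bb = {int(p): top.backbone_indices(int(p)) for p in top.peptide_mols}
    labels, participants = [], []
    for frame in traj.frames:
        touching: set[int] = set()
        for a, b in pairs:
            D = pairwise_min_image(frame.positions[bb[a]],
                                   frame.positions[bb[b]], frame.box)
            if np.min(D) < threshold:
                touching |= {a, b}
        labels.append("transmembrane-contact" if touching else "none")
        participants.append(touching)
    dt = traj.dt if traj.dt > 0 else 0.0
    i = 0
    while i < len(labels):
        if labels[i] == "transmembrane-contact":
            j = i
            while j < len(labels) and labels[j] == "transmembrane-contact":
                j += 1
            if (j - i) * dt > persistence:
                for k in range(i, j):
                    labels[k] = "pore"
            i = j
        else:
            i += 1
    return PoreLabels(times=traj.times, labels=labels, participants=participants)


def _lipid_contact_sets(frame, top, cutoff):
    """Per peptide: set of lipid mol ids with any bead within cutoff."""
    lipid_beads = np.nonzero(top.is_lipid)[0]
    tree = cKDTree(np.mod(frame.positions[lipid_beads], frame.box),
                   boxsize=frame.box)
    out = {}
    for pep in top.peptide_mols:
        idx = top.beads_of(int(pep))
        hits = tree.query_ball_point(np.mod(frame.positions[idx], frame.box),
                                     cutoff)
        out[int(pep)] = {int(top.mol_id[lipid_beads[j]])
                         for h in hits for j in h}
    return out


def contact_fraction(traj: Trajectory, cutoff: float = 0.7,
                     window: tuple[float, float] | None = None
                     ) -> ContactFractionSeries:
    """Per-species fraction of lipids in contact with any peptide, per frame."""
    if window is not None:
        traj = traj.window(*window)
    top = traj.topology
    comp = traj.composition
    names = [s for s in comp.species_names if top.mols_of_species(s).size]
    counts = {s: top.mols_of_species(s).size for s in names}
    rows = []
    for frame in traj.frames:
        if top.peptide_mols.size == 0:
            rows.append({s: 0.0 for s in names})
            continue
        sets = _lipid_contact_sets(frame, top, cutoff)
        touched = set().union(*sets.values()) if sets else set()
        species_of = top.mol_species
        rows.append({s: sum(1 for m in touched if species_of[m] == s) / counts[s]
                     for s in names})
    return ContactFractionSeries(
        f_c=pd.DataFrame(rows, index=traj.times), cutoff=cutoff)


def lipids_per_peptide(traj: Trajectory, cutoff: float = 0.7,
                       window: tuple[float, float] | None = None,
                       dimer_events: list[DimerEvent] | None = None
                       ) -> SolvationStats:
    """Mean lipids of each species solvating a peptide (within ``cutoff``).

    The expectation assumes a composition-proportional random distribution:
    LpP_expected(species) = total LpP × mole fraction.  With ``dimer_events``
    the observed counts are additionally split by the peptide's
    monomer/dimer state at each frame.
    """
    if window is not None:
        traj = traj.window(*window)
    top = traj.topology
    comp = traj.composition
    if top.peptide_mols.size == 0:
        raise ValueError("no peptides in the system")
    names = [s for s in comp.species_names if top.mols_of_species(s).size]
    species_of = top.mol_species

    def in_dimer(pep: int, t: float) -> bool:
        return any(pep in e.pair and e.start <= t < e.end
                   for e in dimer_events or [])

    sums = {s: 0.0 for s in names}
    split_sums = {"monomer": {s: 0.0 for s in names},
                  "dimer": {s: 0.0 for s in names}}
    split_n = {"monomer": 0, "dimer": 0}
    n_samples = 0
    for frame in traj.frames:
        sets = _lipid_contact_sets(frame, top, cutoff)
        for pep, lipids in sets.items():
            n_samples += 1
            state = "dimer" if in_dimer(pep, frame.time) else "monomer"
            split_n[state] += 1
            for m in lipids:
                s = species_of[m]
                sums[s] += 1
                split_sums[state][s] += 1
    observed = {s: sums[s] / n_samples for s in names}
    total = float(sum(observed.values()))
    fractions = comp.mole_fractions()
    expected = {s: total * fractions[s] for s in names}
    ratio = {s: observed[s] / expected[s] if expected[s] > 0 else np.inf
             for s in names}
    split = {state: {s: (v[s] / split_n[state] if split_n[state] else np.nan)
                     for s in names}
             for state, v in split_sums.items()}
    return SolvationStats(lpp_observed=observed, lpp_expected=expected,
                          ratio=ratio, total_lpp=total, split=split)


def residue_lipid_profile(traj: Trajectory, cutoff: float = 0.7,
                          window: tuple[float, float] | None = None
                          ) -> ResidueLipidProfile:
    """Residue × species contact frequencies against phosphate beads.

    Counts, per (frame, peptide), whether each residue has any bead within
    ``cutoff`` of a phosphate of each species; counts are divided by the
    species' molecule count and each species column is scaled to unit
    maximum.
    """
    if window is not None:
        traj = traj.window(*window)
    top = traj.topology
    comp = traj.composition
    names = [s for s in comp.species_names if top.mols_of_species(s).size]
    n_res = len(comp.peptide_residues)
    groups = _peptide_bead_groups(top, "all")
    counts = np.zeros((n_res, len(names)))
    for frame in traj.frames:
        for sj, sname in enumerate(names):
            phos = top.phosphate_indices(top.mols_of_species(sname))
            for pep in top.peptide_mols:
                for ri, ridx in enumerate(groups[int(pep)]):
                    D = pairwise_min_image(frame.positions[ridx],
                                           frame.positions[phos], frame.box)
                    if np.min(D) < cutoff:
                        counts[ri, sj] += 1
    labels = [f"{r}{i + 1}" for i, r in enumerate(comp.peptide_residues)]
    raw = pd.DataFrame(counts, index=labels, columns=names)
    norm = counts / np.array([top.mols_of_species(s).size for s in names])
    col_max = norm.max(axis=0)
    col_max[col_max == 0] = 1.0
    norm = norm / col_max
    return ResidueLipidProfile(
        matrix=pd.DataFrame(norm, index=labels, columns=names), raw_counts=raw)


# --------------------------------------------------------------------------
# Profile clustering
# --------------------------------------------------------------------------

def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick tree string."""
    n = len(labels)

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, dist, _ = Z[i - n]
        return f"({node(int(a))},{node(int(b))}):{dist:.6g}"

    return node(2 * n - 2) + ";"


def cluster_profiles(profiles: dict[str, np.ndarray]
                     ) -> tuple[list[str], np.ndarray, str]:
    """Average-linkage hierarchical clustering of contact-profile vectors
    under correlation distance; returns (labels, linkage matrix, newick)."""
    labels = list(profiles)
    X = np.vstack([np.asarray(profiles[k], dtype=float).ravel()
                   for k in labels])
    if len(labels) < 2:
        raise ValueError("need at least two profiles to cluster")
    D = pdist(X, metric="correlation")
    D = np.nan_to_num(D, nan=0.0)
    Z = linkage(D, method="average")
    return labels, Z, linkage_to_newick(Z, labels)
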