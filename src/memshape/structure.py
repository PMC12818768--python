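"""Transversal structure: leaflet thickness, peptide insertion depth, tilt.

Thickness is the time-averaged |z − bilayer center| of a species' phosphate
beads — one value per species, pooled over both leaflets.  Insertion depth is
the signed distance between a peptide's backbone and the mean z of the
phosphates surrounding it (within 10 Å by default); positive means the peptide
sits deeper than the local phosphate plane, in either leaflet.  Tilt is the
angle between the backbone principal axis and the membrane plane, negative
when the C-terminus rides shallower than the N-terminus.

Internally everything is nm; reporting tables multiply by 10 (Å), following
the convention of the literature these observables come from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import (
    EmptySelectionError,
    LeafletMap,
    Trajectory,
    bilayer_center,
    make_whole,
    min_image_distance,
)
from .stats import BootstrapEstimate, bootstrap_ci, point_or_bootstrap, propagate_ratio

__all__ = ["ThicknessProfile", "DepthProfile", "TiltDistribution",
           "leaflet_thickness", "thinning_ratio", "peptide_depth",
           "peptide_tilt"]

NM_TO_ANGSTROM = 10.0


@dataclass
class ThicknessProfile:
    """Per-species mean |z − center| of phosphates (nm) with bootstrap CIs."""

    z_abs: dict[str, BootstrapEstimate]

    def table(self) -> pd.DataFrame:
        rows = [{"species": s, "z_abs_A": e.mean * NM_TO_ANGSTROM,
                 "ci_low_A": e.ci_low * NM_TO_ANGSTROM,
                 "ci_high_A": e.ci_high * NM_TO_ANGSTROM, "n_eff": e.n_eff}
                for s, e in self.z_abs.items()]
        return pd.DataFrame(rows)


@dataclass
class DepthProfile:
    """Signed peptide depth below the local phosphate plane (nm)."""

    per_peptide: dict[int, float]
    system: BootstrapEstimate
    neighborhood_cutoff: float
    low_coverage: list[int] = field(default_factory=list)
    skipped_frames: dict[int, int] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = [{"peptide": p, "depth_A": d * NM_TO_ANGSTROM,
                 "flagged_low_coverage": p in self.low_coverage}
                for p, d in self.per_peptide.items()]
        return pd.DataFrame(rows)


@dataclass
class TiltDistribution:
    """Helix tilt per peptide per frame, degrees in [−90, 90]; negative =
    C-terminus shallower than N-terminus."""

    angles: pd.DataFrame  # index: frame time, columns: peptide mol id

    def mean(self) -> float:
        return float(self.angles.to_numpy().mean())


# --------------------------------------------------------------------------

def leaflet_thickness(traj: Trajectory, leaflets: LeafletMap,
                      window: tuple[float, float] | None = None,
                      n_boot: int = 1000, seed: int = 0,
                      resample: str = "frames") -> ThicknessProfile:
    """Time-averaged |z − bilayer center| of each species' phosphate beads.

    Species without molecules are omitted with a warning.  The CI is a
    bootstrap over per-frame species means (``resample="frames"``, corrected
    for autocorrelation) or over per-phosphate time averages
    (``resample="molecules"``, appropriate for single frames or when the
    transversal structure is static).
    """
    if window is not None:
        traj = traj.window(*window)
    if traj.n_frames == 0:
        raise ValueError("empty analysis window")
    if resample not in ("frames", "molecules"):
        raise ValueError("resample must be 'frames' or 'molecules'")
    top = traj.topology
    series: dict[str, list] = {}
    for sname in traj.composition.species_names:
        mols = top.mols_of_species(sname)
        if mols.size == 0:
            warnings.warn(f"species {sname} has no molecules; omitted")
            continue
        series[sname] = []
    for frame in traj.frames:
        center = bilayer_center(frame, top)
        for sname in series:
            idx = top.phosphate_indices(top.mols_of_species(sname))
            dz = np.abs(frame.positions[idx, 2] - center)
            series[sname].append(dz if resample == "molecules"
                                 else float(dz.mean()))
    rng = np.random.default_rng(seed)
    if resample == "molecules":
        series = {s: np.mean(v, axis=0) for s, v in series.items()}
    return ThicknessProfile(z_abs={
        s: point_or_bootstrap(np.asarray(v), n_boot=n_boot, rng=rng)
        for s, v in series.items()})


def thinning_ratio(with_pep: ThicknessProfile, without_pep: ThicknessProfile
                   ) -> dict[str, tuple[float, float]]:
    """Per-species Z_PEP+/Z_PEP− with first-order propagated uncertainty."""
    if set(with_pep.z_abs) != set(without_pep.z_abs):
        raise ValueError("species sets differ between the two profiles")
    out = {}
    for s in with_pep.z_abs:
        a, b = with_pep.z_abs[s], without_pep.z_abs[s]
        out[s] = propagate_ratio(a.mean, a.se, b.mean, b.se)
    return out


def peptide_depth(traj: Trajectory, leaflets: LeafletMap,
                  window: tuple[float, float] | None = None,
                  cutoff: float = 1.0,
                  exclude: Mapping[int, Iterable[int]] | None = None,
                  n_boot: int = 1000, seed: int = 0,
                  resample: str = "frames") -> DepthProfile:
    """Signed depth of each peptide below its local phosphate plane.

    For every frame and peptide, the reference plane is the mean z of the
    same-leaflet phosphates within ``cutoff`` nm (3D min-image) of any
    backbone bead.  Depth is positive when the peptide backbone sits deeper
    than that plane, for either leaflet.  ``exclude`` maps frame index →
    peptide mol ids to skip (e.g. pore participants).  Peptides with local
    phosphates in fewer than half their frames are flagged.
    """
    if window is not None:
        traj = traj.window(*window)
    top = traj.topology
    peptides = list(top.peptide_mols)
    if not peptides:
        raise EmptySelectionError("no peptides in the system")
    phos_mols = {lf: top.phosphate_indices(leaflets.mols(lf, top, lipids_only=True))
                 for lf in ("upper", "lower")}
    per_pep: dict[int, list[float]] = {p: [] for p in peptides}
    skipped: dict[int, int] = {p: 0 for p in peptides}
    frame_means: list[float] = []
    for fi, frame in enumerate(traj.frames):
        banned = set(exclude.get(fi, ())) if exclude else set()
        vals = []
        for pep in peptides:
            if pep in banned:
                continue
            lf = leaflets[pep]
            sign = 1.0 if lf == "upper" else -1.0
            bb = top.backbone_indices(pep)
            phos = phos_mols[lf]
            if phos.size == 0:
                raise EmptySelectionError(f"no phosphates in {lf} leaflet")
            d = min_image_distance(frame.positions[bb][:, None, :],
                                   frame.positions[phos][None, :, :], frame.box)
            near = phos[np.any(d < cutoff, axis=0)]
            if near.size == 0:
                skipped[pep] += 1
                continue
            depth = sign * (float(frame.positions[near, 2].mean())
                            - float(frame.positions[bb, 2].mean()))
            per_pep[pep].append(depth)
            vals.append(depth)
        if vals:
            frame_means.append(float(np.mean(vals)))
    low = [p for p in peptides
           if len(per_pep[p]) < 0.5 * traj.n_frames]
    if resample == "molecules":
        values = np.asarray([np.mean(v) for v in per_pep.values() if v])
    else:
        values = np.asarray(frame_means)
    est = point_or_bootstrap(values, n_boot=n_boot,
                             rng=np.random.default_rng(seed))
    return DepthProfile(
        per_peptide={p: float(np.mean(v)) if v else np.nan
                     for p, v in per_pep.items()},
        system=est, neighborhood_cutoff=cutoff, low_coverage=low,
        skipped_frames={p: k for p, k in skipped.items() if k},
    )


def _tilt_one(bb_pos: np.ndarray, box: np.ndarray, deeper_sign: float) -> float:
    """Tilt angle (deg) of one backbone chain vs the membrane plane."""
    pos = make_whole(bb_pos, box)
    centered = pos - pos.mean(axis=0)
    if np.allclose(centered, 0):
        raise ValueError("degenerate peptide: all backbone beads coincide")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, pos[-1] - pos[0]) < 0:  # orient N → C
        axis = -axis
    # positive when the C-terminus is deeper than the N-terminus
    return float(np.degrees(np.arcsin(np.clip(deeper_sign * axis[2], -1, 1))))


def peptide_tilt(traj: Trajectory, leaflets: LeafletMap | None = None,
                 window: tuple[float, float] | None = None) -> TiltDistribution:
    """Backbone principal-axis tilt vs the membrane plane, per peptide per frame.

    The axis is the first principal component of the backbone beads.  Sign
    convention: positive = C-terminal half deeper (toward the bilayer core)
    than the N-terminal half; "deeper" is leaflet-aware when ``leaflets`` is
    given (upper-leaflet default otherwise).
    """
    if window is not None:
        traj = traj.window(*window)
    top = traj.topology
    peptides = list(top.peptide_mols)
    if not peptides:
        raise EmptySelectionError("no peptides in the system")
    for pep in peptides:
        if top.backbone_indices(pep).size < 4:
            raise ValueError(f"peptide {pep} has fewer than 4 backbone beads")
    data = {}
    for pep in peptides:
        lf = leaflets[pep] if leaflets is not None else "upper"
        deeper = -1.0 if lf == "upper" else 1.0
        bb = top.backbone_indices(pep)
        data[pep] = [_tilt_one(f.positions[bb], f.box, deeper)
                     for f in traj.frames]
    df = pd.DataFrame(data, index=traj.times)
    return TiltDistribution(angles=df)
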