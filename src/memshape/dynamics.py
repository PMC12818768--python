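"""Lateral diffusion from mean-squared displacement.

Molecules are tracked by a single reference point — the (first) phosphate
bead for lipids, the backbone centre of mass for peptides — unwrapped across
periodic boundaries by chaining frame-to-frame minimum-image displacements.
Per-frame lateral drift of each leaflet's lipid centre of mass is removed
before computing MSD(τ) = ⟨|r(t+τ) − r(t)|²⟩ over molecules and time
origins.  D follows from the 2D Einstein relation MSD = 4·D·τ via weighted
least squares over a lag window that skips the short-time regime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    LeafletMap,
    Trajectory,
    UnwrapError,
    make_whole,
    min_image_displacement,
)
from .stats import propagate_ratio

__all__ = ["MSDCurve", "DiffusionEstimate", "unwrapped_tracks", "msd_lateral",
           "fit_diffusion", "diffusion_ratio", "NM2_PER_NS_TO_CM2_PER_S"]

#: 1 nm²/ns = 1e-14/1e-9 cm²/s = 1e-5 cm²/s
NM2_PER_NS_TO_CM2_PER_S = 1.0e-5


@dataclass
class MSDCurve:
    """Ensemble- and time-averaged lateral MSD per lag."""

    lag_times: np.ndarray   # ns
    msd: np.ndarray         # nm²
    n_pairs: np.ndarray     # samples per lag

    def __post_init__(self) -> None:
        if self.msd[0] != 0:
            raise ValueError("MSD(0) must be 0")


@dataclass
class DiffusionEstimate:
    """Lateral diffusion coefficient in cm²/s with fit standard error."""

    D: float
    se: float
    fit_window: tuple[float, float]
    negative_slope: bool = False


def _reference_xy(traj: Trajectory, mols: Sequence[int]) -> np.ndarray:
    """(n_frames, n_mols, 2) wrapped reference positions."""
    top = traj.topology
    out = np.empty((traj.n_frames, len(mols), 2))
    ref_idx = []
    for m in mols:
        if top.mol_is_peptide[m]:
            ref_idx.append(top.backbone_indices(m))
        else:
            idx = top.beads_of(m, top.is_phosphate)
            ref_idx.append(idx[:1])
    for fi, frame in enumerate(traj.frames):
        for k, idx in enumerate(ref_idx):
            if len(idx) == 1:
                out[fi, k] = frame.positions[idx[0], :2]
            else:
                whole = make_whole(frame.positions[idx], frame.box)
                out[fi, k] = np.mod(whole.mean(axis=0)[:2], frame.box[:2])
    return out


def unwrapped_tracks(traj: Trajectory, mols: Sequence[int]) -> np.ndarray:
    """Unwrap reference xy positions across frames (min-image chaining).

    Raises :class:`UnwrapError` when a frame-to-frame displacement reaches
    half the box — the stride is then too coarse to unwrap unambiguously.
    """
    wrapped = _reference_xy(traj, mols)
    box_xy = traj.frames[0].box[:2]
    steps = min_image_displacement(wrapped[:-1], wrapped[1:], box_xy,
                                   xy_only=True)
    if np.any(np.abs(steps) >= box_xy / 2 - 1e-9):
        raise UnwrapError("frame-to-frame displacement ≥ box/2; "
                          "use a smaller trajectory stride")
    out = np.empty_like(wrapped)
    out[0] = wrapped[0]
    out[1:] = wrapped[0] + np.cumsum(steps, axis=0)
    return out


def _select_group(traj: Trajectory, group) -> list[int]:
    top = traj.topology
    if isinstance(group, str):
        mols = list(top.mols_of_species(group)) if group != "PEP" \
            else list(top.peptide_mols)
    else:
        mols = [int(m) for m in group]
    if not mols:
        raise ValueError(f"empty selection for group {group!r}")
    return mols


def msd_lateral(traj: Trajectory, group, leaflets: LeafletMap | None = None,
                window: tuple[float, float] | None = None,
                max_lag: float | None = None) -> MSDCurve:
    """Lateral MSD of a species (name), the peptides (``"PEP"``) or explicit
    molecule ids, averaged over molecules and all time origins.

    With ``leaflets`` given, the per-frame lateral drift of each leaflet's
    lipid centre of mass is subtracted from its members before the MSD.
    """
    if window is not None:
        traj = traj.window(*window)
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for an MSD")
    mols = _select_group(traj, group)
    tracks = unwrapped_tracks(traj, mols)  # (F, M, 2)

    if leaflets is not None:
        for lf in ("upper", "lower"):
            members = [k for k, m in enumerate(mols) if leaflets[m] == lf]
            if not members:
                continue
            ref_mols = list(leaflets.mols(lf, traj.topology, lipids_only=True))
            drift_tracks = unwrapped_tracks(traj, ref_mols)
            drift = drift_tracks.mean(axis=1, keepdims=True)
            tracks[:, members, :] -= drift - drift[0]

    F = tracks.shape[0]
    dt = traj.dt
    n_lags = F if max_lag is None else min(F, int(round(max_lag / dt)) + 1)
    msd = np.zeros(n_lags)
    n_pairs = np.zeros(n_lags, dtype=int)
    n_pairs[0] = tracks.shape[1] * F
    for lag in range(1, n_lags):
        d = tracks[lag:] - tracks[:-lag]
        msd[lag] = float(np.mean(np.sum(d * d, axis=-1)))
        n_pairs[lag] = d.shape[0] * d.shape[1]
    return MSDCurve(lag_times=np.arange(n_lags) * dt, msd=msd, n_pairs=n_pairs)


def fit_diffusion(msd: MSDCurve,
                  fit_window: tuple[float, float] = (10.0, 100.0)
                  ) -> DiffusionEstimate:
    """Weighted least-squares slope of MSD vs lag over ``fit_window`` (ns);
    D = slope/4, converted to cm²/s.  A negative fitted slope is reported as
    D with a warning flag rather than clipped."""
    lo, hi = fit_window
    sel = (msd.lag_times >= lo) & (msd.lag_times <= hi)
    if int(sel.sum()) < 5:
        raise ValueError("fewer than 5 lag points in the fit window")
    t = msd.lag_times[sel]
    y = msd.msd[sel]
    w = msd.n_pairs[sel].astype(float)
    W = np.sum(w)
    tbar = np.sum(w * t) / W
    ybar = np.sum(w * y) / W
    sxx = np.sum(w * (t - tbar) ** 2)
    slope = np.sum(w * (t - tbar) * (y - ybar)) / sxx
    resid = y - (ybar + slope * (t - tbar))
    dof = max(1, len(t) - 2)
    s2 = np.sum(w * resid ** 2) / dof / (W / len(t))
    slope_se = float(np.sqrt(s2 / sxx))
    negative = slope < 0
    if negative:
        warnings.warn("negative MSD slope; reporting D as fitted")
    return DiffusionEstimate(
        D=float(slope / 4.0 * NM2_PER_NS_TO_CM2_PER_S),
        se=slope_se / 4.0 * NM2_PER_NS_TO_CM2_PER_S,
        fit_window=(float(lo), float(hi)),
        negative_slope=bool(negative))


def estimate_diffusion(traj: Trajectory, group,
                       fit_window: tuple[float, float] = (10.0, 100.0),
                       leaflets: LeafletMap | None = None,
                       window: tuple[float, float] | None = None,
                       n_blocks: int = 10) -> DiffusionEstimate:
    """Diffusion coefficient with a replicate-spread standard error.

    MSD points at different lags share the same underlying trajectories, so
    the least-squares fit error badly understates the statistical uncertainty
    of D.  Here the molecules are split into ``n_blocks`` disjoint blocks,
    D is fitted per block, and the reported value/SE are the mean and
    standard error of the block estimates.  Falls back to the plain fit when
    there are too few molecules to block.
    """
    if window is not None:
        traj = traj.window(*window)
    mols = _select_group(traj, group)
    k = min(n_blocks, len(mols) // 2)
    if k < 2:
        return fit_diffusion(msd_lateral(traj, mols, leaflets=leaflets),
                             fit_window)
    blocks = [mols[i::k] for i in range(k)]
    ds = [fit_diffusion(msd_lateral(traj, blk, leaflets=leaflets),
                        fit_window).D for blk in blocks]
    ds = np.asarray(ds)
    return DiffusionEstimate(
        D=float(ds.mean()),
        se=float(ds.std(ddof=1) / np.sqrt(k)),
        fit_window=(float(fit_window[0]), float(fit_window[1])),
        negative_slope=bool(ds.mean() < 0))


def diffusion_ratio(with_pep: DiffusionEstimate,
                    without_pep: DiffusionEstimate) -> tuple[float, float]:
    """D_PEP+/D_PEP− with first-order propagated uncertainty."""
    return propagate_ratio(with_pep.D, with_pep.se,
                           without_pep.D, without_pep.se)
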