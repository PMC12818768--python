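"""Configuration-driven orchestration of all analysis stages.

A :class:`PipelineConfig` bundles the input paths, the burn-in / analysis
window (ns) and every distance cutoff, all defaulting to the values the
analyses are defined with (6 Å contact maps, 0.6 nm dimer detection, 0.7 nm
lipid contacts, 1.0 nm annular shell, 2.25× occupancy-radius clustering
cutoff, 10 Å depth neighbourhood, 5 µs burn-in, last 15 µs analysed, 1000
bootstrap resamples).  :func:`run_pipeline` applies the window, runs the
requested stages and writes one tabular file per stage plus a
machine-readable JSON summary; outputs are a pure function of (inputs,
config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import contacts as ct
from . import dynamics as dyn
from . import organization as org
from . import packing as pk
from . import structure as st
from .core import Trajectory, assign_leaflets, load_system

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("thickness", "apl", "order", "diffusion", "contacts",
              "dimers", "clustering", "rdf")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All pipeline inputs and parameters (lengths nm, times ns)."""

    coordinate_file: str | None = None
    trajectory_file: str | None = None
    composition_file: str | None = None
    out_dir: str = "memshape_out"
    stages: tuple[str, ...] = ALL_STAGES
    burn_in: float = 5000.0            # ns ignored at the start
    analysis_window: float | None = 15000.0  # ns analysed at the end
    contact_map_threshold: float = 0.6  # nm (6 Å)
    dimer_cutoff: float = 0.6           # nm, backbone–backbone
    dimer_min_residues: int = 2
    lipid_contact_cutoff: float = 0.7   # nm, f_c and LpP
    annular_cutoff: float = 1.0         # nm
    clustering_factor: float = 2.25     # × occupancy radius
    depth_cutoff: float = 1.0           # nm (10 Å)
    pore_persistence: float = 1000.0    # ns (1 µs)
    diffusion_fit_window: tuple[float, float] = (10.0, 100.0)
    rdf_bin_width: float = 0.05
    occupancy_apl: float | None = None  # nm², peptide-free ApL override
    n_boot: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "diffusion_fit_window" in raw:
            raw["diffusion_fit_window"] = tuple(raw["diffusion_fit_window"])
        return cls(**raw)


def _round(obj):
    if isinstance(obj, dict):
        return {k: _round(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_round(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return float(np.format_float_scientific(obj, precision=10))
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def run_pipeline(config: PipelineConfig,
                 traj: Trajectory | None = None) -> dict:
    """Run the configured stages and write per-stage tables + summary.json.

    ``traj`` may be passed directly (e.g. a synthetic trajectory); otherwise
    the input files from the config are loaded.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if traj is None:
        has_input = config.composition_file and (
            config.coordinate_file or config.trajectory_file)
        if not has_input:
            raise PipelineError(
                "config: composition_file plus a coordinate or trajectory "
                "file are required when no trajectory is passed")
        traj = load_system(config.coordinate_file, config.trajectory_file,
                           config.composition_file)

    t0, t_last = traj.frames[0].time, traj.frames[-1].time
    if config.burn_in >= t_last + max(traj.dt, 1e-12) - t0:
        raise PipelineError(
            f"config: burn_in {config.burn_in} ns >= trajectory length")
    start = t0 + config.burn_in
    if config.analysis_window is not None:
        start = max(start, t_last - config.analysis_window)
    work = traj.window(start, None)
    top = work.topology
    comp = work.composition
    leaflets = assign_leaflets(work.frames[0], top)
    has_peptides = top.peptide_mols.size > 0

    summary: dict = {
        "parameters": _round({k: v for k, v in dataclasses.asdict(config).items()
                              if not isinstance(v, (list, tuple)) or True}),
        "seed": config.seed,
        "n_frames_analyzed": work.n_frames,
        "analysis_start_ns": float(start),
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            if name in config.stages:
                try:
                    summary["stages"][name] = _round(fn())
                except PipelineError:
                    raise
                except Exception as exc:
                    raise PipelineError(f"stage {name}: {exc}") from exc
            return fn
        return deco

    env_labels = None

    def environment_labels():
        nonlocal env_labels
        if env_labels is None:
            env_labels = [pk.annular_bulk_split(f, top, config.annular_cutoff)
                          for f in work.frames]
        return env_labels

    @stage("thickness")
    def _thickness():
        prof = st.leaflet_thickness(work, leaflets, n_boot=config.n_boot,
                                    seed=config.seed)
        prof.table().to_csv(out / "thickness.csv", index=False)
        res = {s: {"z_abs_A": e.mean * 10, "ci_low_A": e.ci_low * 10,
                   "ci_high_A": e.ci_high * 10}
               for s, e in prof.z_abs.items()}
        if has_peptides:
            depth = st.peptide_depth(work, leaflets, cutoff=config.depth_cutoff,
                                     n_boot=config.n_boot, seed=config.seed)
            depth.table().to_csv(out / "depth.csv", index=False)
            res["peptide_depth_A"] = depth.system.mean * 10
            tilt = st.peptide_tilt(work, leaflets)
            res["peptide_tilt_deg"] = tilt.mean()
        return res

    @stage("apl")
    def _apl():
        res = {}
        tables = [pk.species_apl(work, leaflets, n_boot=config.n_boot,
                                 seed=config.seed)]
        if has_peptides:
            labels = environment_labels()
            for env in ("annular", "bulk"):
                tables.append(pk.species_apl(
                    work, leaflets, environment_labels=labels,
                    environment=env, n_boot=config.n_boot, seed=config.seed))
        import pandas as pd
        for t in tables:
            res[t.environment] = {s: e.mean for s, e in t.per_species.items()}
        pd.concat([t.table() for t in tables]).to_csv(out / "apl.csv",
                                                      index=False)
        return res

    @stage("order")
    def _order():
        labels = environment_labels() if has_peptides else None
        prof = pk.bond_order_p2(work, environment_labels=labels,
                                n_boot=config.n_boot, seed=config.seed)
        prof.data.to_csv(out / "order.csv", index=False)
        return {s: prof.chain_average(s)
                for s in comp.species_names if top.mols_of_species(s).size}

    @stage("diffusion")
    def _diffusion():
        res = {}
        rows = []
        groups = [s for s in comp.species_names if top.mols_of_species(s).size]
        if has_peptides:
            groups.append("PEP")
        for g in groups:
            est = dyn.estimate_diffusion(work, g,
                                         config.diffusion_fit_window,
                                         leaflets=leaflets)
            rows.append({"group": g, "D_cm2_s": est.D, "se": est.se})
            res[g] = {"D_cm2_s": est.D, "se": est.se}
        import pandas as pd
        pd.DataFrame(rows).to_csv(out / "diffusion.csv", index=False)
        return res

    @stage("contacts")
    def _contacts():
        res = {}
        fc = ct.contact_fraction(work, cutoff=config.lipid_contact_cutoff)
        fc.f_c.to_csv(out / "contact_fraction.csv")
        res["f_c_mean"] = {s: float(fc.f_c[s].mean()) for s in fc.f_c.columns}
        if has_peptides:
            lpp = ct.lipids_per_peptide(work, cutoff=config.lipid_contact_cutoff)
            lpp.table().to_csv(out / "lpp.csv", index=False)
            res["lpp_ratio"] = lpp.ratio
            prof = ct.residue_lipid_profile(
                work, cutoff=config.lipid_contact_cutoff)
            prof.matrix.to_csv(out / "residue_lipid_profile.csv")
            pore = ct.transmembrane_pore_frames(
                work, leaflets, threshold=config.dimer_cutoff,
                persistence=config.pore_persistence)
            res["n_pore_frames"] = len(pore.pore_frames())
        return res

    @stage("dimers")
    def _dimers():
        if not has_peptides or top.peptide_mols.size < 2:
            return {"n_events": 0}
        events = ct.detect_dimers(work, threshold=config.dimer_cutoff,
                                  min_residues=config.dimer_min_residues,
                                  leaflets=leaflets)
        import pandas as pd
        pd.DataFrame([{"peptide_a": e.pair[0], "peptide_b": e.pair[1],
                       "start_ns": e.start, "end_ns": e.end,
                       "reporter": e.reporter} for e in events]
                     ).to_csv(out / "dimer_events.csv", index=False)
        surv = ct.dimer_survival(events)
        pd.DataFrame({"bin_low_ns": surv.bin_edges[:-1],
                      "bin_high_ns": surv.bin_edges[1:],
                      "summed_time_ns": surv.summed_time}
                     ).to_csv(out / "dimer_survival.csv", index=False)
        return {"n_events": len(events),
                "total_dimer_time_ns": surv.total_time,
                "short_fraction": surv.short_fraction,
                "long_fraction": surv.long_fraction}

    @stage("clustering")
    def _clustering():
        main = max(comp.counts_per_leaflet, key=comp.counts_per_leaflet.get)
        if config.occupancy_apl is not None:
            apl = config.occupancy_apl
        else:
            apl = pk.species_apl(work, leaflets, n_boot=50,
                                 seed=config.seed).per_species[main].mean
        cutoff = config.clustering_factor * org.occupancy_radius(apl)
        parts = [org.lipid_communities(f, top, main, leaflets, cutoff,
                                       leaflet=lf)
                 for f in work.frames for lf in ("upper", "lower")]
        dist = org.cluster_size_distribution(
            parts, comp.counts_per_leaflet[main])
        dist.table().to_csv(out / "cluster_sizes.csv", index=False)
        return {"species": main, "cutoff_nm": cutoff,
                "largest_mean_pct": float(np.mean(
                    [100 * p.sizes()[0] / comp.counts_per_leaflet[main]
                     for p in parts]))}

    @stage("rdf")
    def _rdf():
        main = max(comp.counts_per_leaflet, key=comp.counts_per_leaflet.get)
        curve = org.cis_rdf(work, main, leaflets,
                            bin_width=config.rdf_bin_width)
        import pandas as pd
        pd.DataFrame({"r_nm": curve.r, "g": curve.g}
                     ).to_csv(out / f"rdf_{main}.csv", index=False)
        return {"species": main, "first_peak_nm": curve.first_peak()}

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
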