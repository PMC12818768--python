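# Methods

This note documents the models, estimators and numerical choices behind
`memshape`, and what the synthetic test bed does and does not establish
about real trajectories.

## Scope and data model

The package analyses planar, two-leaflet coarse-grained bilayers in
orthorhombic periodic boxes, with the bilayer normal along z.  Coordinates
are stored in nm and times in ns (GRO/XTC conventions); thickness and depth
tables multiply by 10 for Å reporting.  Triclinic boxes, vesicles and
atomistic systems are out of scope, as is running or setting up the
simulations themselves.

A `SystemComposition` declares each lipid species' bead topology: phosphate
bead(s), optional linker/head beads, and the ordered beads of each acyl
chain.  Cardiolipin-like species carry four chains and two phosphates and
count as two anionic equivalents.  Peptides are bead chains with one
backbone bead per residue (side-chain beads are accepted and used by the
"any-bead" contact criteria).  All distance computations use the
minimum-image convention; molecules straddling the boundary are made whole
by chaining min-image displacements along the bead chain, which is exact
whenever bond lengths are below half the box — always true here.

Leaflet labels are assigned once, at the first analysed frame, from the sign
of (phosphate z − bilayer centre) for lipids and the backbone centre of mass
for peptides, and are frozen thereafter; transmembrane behaviour is defined
relative to this original placement, and flip-flop is not tracked.
Molecules within a tolerance (default 0.05 nm) of the midplane raise an
error rather than being assigned arbitrarily.

## Estimators

**Thickness and thinning.**  Per species, the time-averaged |z − centre| of
all phosphate beads, pooled over leaflets.  The with/without-peptide ratio
uses first-order error propagation, σ_ratio = |r|·√((σa/a)² + (σb/b)²), and
refuses denominators whose 95% interval spans zero.

**Peptide depth.**  Per frame and peptide, the reference plane is the mean z
of same-leaflet phosphates within 1.0 nm (3D min-image) of any backbone
bead; depth is the signed offset of the backbone mean below that plane,
mirrored for the lower leaflet so "deeper" is positive in both.  Frames with
no local phosphate are skipped and counted; peptides covered in fewer than
half their frames are flagged.  Pore participants can be excluded via a
frame → peptide map.  The distance convention (3D, any backbone bead) is a
design choice; only the 10 Å cutoff is inherited from the observable's
definition.

**Tilt.**  The backbone principal axis (first singular vector), oriented
N→C; tilt is arcsin of its projection on the depth direction of the
peptide's leaflet, so positive means the C-terminus rides deeper.  The
estimator is parameter-free; a rigid rotated rod is recovered within 1°.

**Area per lipid.**  Each leaflet is tessellated independently from the xy
positions of the first tail bead (C1) of every chain.  Periodicity is exact:
sites are tiled into the 8 neighbouring images, scipy's Voronoi runs on the
3×3 supercell, and the central cells are kept; their areas (shoelace over
angle-sorted vertices) sum to the box area to ~1e-14 relative error.
Coincident sites are jittered by 1e-6 nm with a warning.  A lipid's area
sums its chain cells; the species ApL divides by n_chains/2 so cardiolipin
is weighted per chain pair.  Peptide Trp19 backbone sites join the
tessellation only for pore analyses; the default is lipid-only.  Annular
lipids are those with any bead within 1.0 nm of any peptide bead, with
dimer/monomer/pore sublabels by the contacting peptide's state
(pore > dimer > monomer priority when several peptides touch).

**Bond order.**  P2 per bond of consecutive chain beads (bond 1 = C1–C2;
the headgroup–C1 link is excluded), with θ against z.  Both the per-bond
profile and the chain average are available; environments split the profile
into annular/bulk.  Zero-length bonds are skipped and counted.

**Lateral diffusion.**  Molecules are tracked by one reference point —
first phosphate for lipids, backbone COM for peptides — unwrapped across
frames; a frame-to-frame displacement reaching box/2 is an unwrap error.
Per-leaflet lipid COM drift is removed before MSD; drift removal subtracts a
1/N random-walk component, a ≤0.5% bias at the molecule counts used here.
MSD averages over molecules and all time origins; D = slope/4 by weighted
least squares over a lag window that defaults to 10–100 ns, skipping the
short-time regime.  Because MSD values at different lags share the same
trajectories, the fit SE understates the real uncertainty by orders of
magnitude; `estimate_diffusion` therefore splits molecules into 10 disjoint
blocks, fits D per block, and reports the mean ± spread-based SE.  The
pipeline and all ratio computations use the blocked estimator.

**Contacts, dimers, pores.**  Residue contact maps count, per analysed
(frame, pair) sample, residue pairs with any beads within 6 Å, symmetrised
over the pair order and reported as a percentage of samples; trans-leaflet
maps can be restricted to pore frames.  Dimer detection uses backbone beads
at 0.6 nm and requires at least two contacting residues on *each* side;
episodes are maximal runs with configurable gap tolerance (default 0).  The
Lys4–Trp19 reporter demands both directed cross-contacts (Lys4 of each
peptide against Trp19 of the other), the signature of the shifted
antiparallel interface; an episode's reporter flag records whether that held
in at least half its frames.  Survival histograms weight each episode by its
duration ("summed dimer time") and summarise bimodality as the shares below
50 ns and above 400 ns.  A frame is transmembrane when backbone beads of
opposite-leaflet peptides touch at 0.6 nm; contiguous runs longer than 1 µs
become pore frames, with participants recorded.

**Affinity.**  f_c is the per-species fraction of lipids with any bead
within 0.7 nm of any peptide bead.  Lipids-per-peptide counts contacting
lipids per peptide per frame; the null expectation distributes the total
LpP by composition mole fractions, and the observed/expected ratio measures
relative affinity.  Monomer/dimer splits classify each peptide-frame by the
detected dimer state.  The residue × species profile counts contacts of each
residue with each species' phosphates, normalises by the species' molecule
count, scales each species column to unit maximum (the normalisation is a
package choice — the observable is conventionally reported only as
"normalized"), and clusters profile vectors by average linkage under
correlation distance, exporting Newick.

**Lateral organisation.**  The cis-RDF is the in-plane, same-leaflet pair
distribution of a species' phosphates, normalised by ideal-gas shells.
Community detection builds one graph per species and leaflet, edges between
phosphates within 2.25 × the occupancy radius √(ApL/π) (an ApL of 0.62 nm²
gives the ≈1.0 nm cutoff), and runs greedy modularity maximisation
(fast-greedy); isolated lipids are singleton communities, and community ids
are ordered by lowest member for determinism.  Cluster-size distributions
report the % of frames whose largest community falls in 5%-wide size
classes; an all-communities variant weights every community of each frame
equally.

**Uncertainty.**  95% percentile bootstrap with 1000 resamples.  Serial
correlation is corrected by resampling only n_eff = n/(1 + 2τ_int) points,
with τ_int the sum of the autocorrelation up to its first non-positive lag.
On AR(1) data with φ = 0.9 this recovers the closed form n(1−φ)/(1+φ)
within ~10% on average; single series fluctuate by ±25%, so calibration
checks average several realisations.  Measured coverage on iid normal data
is ≈94%, the usual mild undercoverage of percentile intervals.  For
single-frame or transversally static data the per-frame series is constant
and frame resampling degenerates to a point estimate; `resample="molecules"`
bootstraps over per-molecule values instead.

**Partition arithmetic.**  `estimate_pl_ratio` implements the printed
relation P/L = MIC·Kp·γ_L.  With Kp = 20×10⁴, MIC = 11 µM and
γ_L = 0.8 L/mol it evaluates to 1.76, which does not match the 1:12 ratio
quoted alongside those inputs in the source literature; the units or
exponent of Kp there are ambiguous.  The function computes the formula as
printed and leaves the reconciliation to the user.

## The synthetic generator

The generator emulates geometry and kinematics, not physics: no forces, no
membrane undulations, no excluded volume after build time (placement uses
0.3 nm minimum-spacing rejection sampling).  Phosphates sit at
centre ± `leaflet_z_offset` with optional Gaussian jitter; chain bonds are
drawn at the exact polar angle realising the target P2 (or isotropically),
so planted order is recovered without sampling error.  Lateral dynamics are
independent per-molecule 2D Brownian steps (std √(2·D·dt) per axis,
1 cm²/s = 10⁵ nm²/ns); z and internal geometry are rigid, so transversal
observables have no time variance by construction.

Dimerisation is a two-state Markov process: while two free same-leaflet
peptides' backbones come within the 1.2 nm capture radius they bind at rate
k_on, unbind at k_off, and while bound are held in the shifted antiparallel
arrangement whose Lys4–Trp19 interface sits at 0.45 nm, moving as one unit
with a single peptide's step.  Capture is gated on minimum backbone-bead
distance because the exclusion machinery (below) controls exactly that
quantity.  Discrete-time episode durations are geometric with mean
dt/(1−exp(−k_off·dt)) ≈ 1/k_off + dt/2; tests compare at this resolution.

So that contact detection is a strict readout of planted state, unbound
pairs are softly excluded: any non-bound pair drifting inside 0.75 nm is
pushed apart along the closest-bead axis (dimers move as units), in several
passes per frame since resolving one pair can crowd another.  The capture
radius therefore exceeds the 0.6 nm detection cutoff by construction.  The
in-plane box must exceed the peptide rod length (6.3 nm at 0.35 nm spacing)
plus a margin, else wrapped rods span the torus and cannot be disentangled;
the builder enforces this.

Because of these simplifications, passing tests establish the correctness
of the estimators (geometry, bookkeeping, statistics, detection logic) under
known truth — not the physical fidelity of any simulation.  Real
trajectories add undulations, protrusions, z-fluctuations, flip-flop and
correlated motion that the generator deliberately omits.

## Validation problem sizes

The acceptance computations run at desk scale, chosen to give comfortable
statistical resolution per check: 50 random frames of 100–400 lipids for
area conservation; 102 000 isotropic bonds for the P2 null; 200 molecules ×
1000 frames × 3 seeds per diffusion coefficient; two 750 ns dimer runs with
8 peptides each (≈250 episodes); 2- and 3-blob cluster plants over 3 seeds
and both leaflets; 500–1000 bootstrap coverage trials at series length 1000;
20 random fixtures for exhaustive contact cross-checks.  The full suite runs
in about a minute and `scripts/acceptance.py` in under one minute on a
single CPU.

## Known limitations

* Leaflet assignment is frozen; systems with significant peptide
  translocation or lipid flip-flop need per-frame reassignment, which is not
  provided.
* The periodic Voronoi implementation assumes the cell structure is
  determined within one image shell — valid for bilayer-scale boxes, not for
  boxes a few lipid diameters wide.
* Greedy modularity has the usual resolution limit; very diffuse or nested
  cluster structure may be merged or split relative to other community
  methods.
* The contact-map normalisation caps at the analysed-sample count; systems
  where a residue pair touches through multiple simultaneous partners are
  reported at prevalence, not multiplicity.
* `fit_diffusion`'s fit-based SE is only meaningful for genuinely
  independent MSD points; use `estimate_diffusion` for real uncertainty.
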