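# Methods

transcytokit models and quantifies receptor-mediated transcytosis of
multivalent nanoparticles across a brain-endothelial cell (BEC) layer, with
LRP1-targeted polymersomes as the motivating system.  Four computational
pieces share one theme — avidity controls both entry and release — and a
synthetic-data layer provides ground-truth inputs for every analysis stage.

## 1. Multivalent-avidity binding model (`avidity`)

A particle of radius R carrying L ligands meets a membrane presenting
receptors at surface density R_D (µm⁻²).  Enumerating bound states by the
number of closed bonds b gives the super-selectivity partition function

    W(b) = C(L, b) · C(n_r, b) · b! · x^b,   b = 0 … min(L, n_r),
    q    = Σ_{b≥1} W(b),

with x = c_eff / K_d the single-bond statistical weight.  The per-encounter
binding probability is p_bind = q / (1 + q) and the effective detachment
rate is k_off,eff = k_off,single / q (mean-field residence scaling).  All
combinatorics are evaluated in log space; L in the hundreds is safe.

**Receptor availability.**  A literal geometric contact patch (spherical cap
of height ~5 nm) holds `round(R_D · area) = 0` receptors at the study
densities of 15–30 µm⁻², which would disable binding entirely.  Receptors
are laterally mobile and are recruited into the adhesion zone during an
encounter, so the model instead counts receptors in a *capture zone* of
radius R + l_c with l_c = 0.3 µm by default:

    n_r = round(R_D · π (R + l_c)²)  →  12 at R_D = 30 µm⁻², R = 50 nm
                                         6 at R_D = 15 µm⁻².

l_c is configurable; the capture closure preserves the two monotonicities
that matter (more receptors with larger particles and denser membranes).

**Effective contact concentration.**  c_eff absorbs tether entropy and
orientational penalties of forming one bond; its default (3.6 nM, i.e.
x ≈ 0.012 at K_d = 300 nM) was fixed once, by design rather than fitting
runs: the monovalent bound weight q(L=1) = n_r·x ≈ 0.14 must be well below 1
(a single ligand binds weakly, which is why multivalency matters), while
q(L=22) ≈ 13 makes the L = 22 design bind nearly every encounter yet detach
basally on the ~10² s scale.  The strong combinatorial growth of q then
separates the tested valencies by orders of magnitude in release rate, which
is the entire Goldilocks mechanism.

## 2. Agent-based transwell simulator (`transwell`)

Particles are independent agents in the apical compartment of a transwell
whose bottom is a uniform 2-µm cell layer.  The state machine is

    free_apical → bound → endocytosed → trafficking → exocytosing → free_basal

with unbinding allowed from `bound`.  Per time step: free agents take
Gaussian Brownian displacements (D from Stokes–Einstein: 6.5 µm²/s for
R = 50 nm at 310 K in 0.7 mPa·s medium) with reflecting walls; an agent
within one step length of the layer is an encounter and binds with p_bind;
bound agents unbind at k_off,eff or endocytose; the internal stages are
exponential dwells (defaults 0.05 s⁻¹ each, putting the median apical→basal
transit at minutes); exocytosing agents release basally at the same
avidity-controlled k_off,eff.  Released mass Q(t) feeds the apparent
permeability P = (dQ/dt)/(C0·A), computed through the assay module, so the
simulated heatmaps and the experimental reduction share one code path.

Numerical choices:

- Time step from the layer-resolution rule √(6 D dt) ≤ (cell layer)/5,
  giving dt ≈ 4 ms for 50-nm particles.
- **Well-mixed unbinding.**  An agent that unbinds returns to a uniformly
  random apical position.  If it instead stayed adjacent to the layer, it
  would re-attempt binding every step at zero cost and even the weakest
  binder would eventually be endocytosed, erasing the low-avidity penalty;
  with the remix each binding episode costs one diffusive return (~10² s at
  the default 40 µm apical depth), which is what makes L = 1 cross far less
  than L = 22 within the simulated hour.  This is the mean-field reading of
  the huge real apical reservoir.
- Receptor pool unlimited (R_D enters only through the avidity model);
  agents are independent, so P is intensive — independent of the simulated
  concentration and lateral area, which the tests verify.
- Desk-scale geometry: 10 × 10 µm lateral box, 40 µm apical depth, 600 s
  runs with 500 agents; a sweep point is an average over ≥3 seeded
  replicates, each reproducible in isolation from its grid-derived seed.
- The ablation switch `l_independent_unbinding` pins the release rate to the
  monovalent value; the interior optimum in L then vanishes, confirming that
  the Goldilocks effect comes from avidity-controlled release, not binding
  saturation.

## 3. Coarse-grained membrane simulator (`membrane`)

The membrane is a one-particle-thick, solvent-free fluid sheet: each bead
carries a director and interacts via an orientation-dependent pair potential
(repulsive core with minimum at 2^{1/6} σ; attraction −ε_mm cos^{2ζ} scaled
by φ = 1 + µ(a − 1), a = n_i·n_j − (n_i·r̂)(n_j·r̂); ε_mm = 4.34 k_BT,
µ = 3, ζ = 4, cutoff 2.6 σ — the parameter regime in which this model class
is a self-assembled fluid bilayer with ~20 k_BT-scale bending rigidity).  A
Fibonacci-sphere vesicle relaxes to a stable fluid sphere within ~1500 MC
sweeps (default equilibration); the mean radius then fluctuates by ~1%.

Nanoparticles (diameter 2 σ) feel a truncated-and-shifted 12-6 attraction of
depth exactly ε (k_BT) to receptor beads — a random fraction f_r of beads —
and WCA repulsion to everything else.  Dynamics are seeded Metropolis Monte
Carlo (displacement + director rotation, Verlet neighbor lists, numba
kernel); MC samples the same equilibrium as overdamped Langevin and is the
declared evolution scheme.

Outcome classification is geometric: bound particles (within 0.4 σ of
contact) form a cluster graph; elongation via the gyration tensor
(λ1 > 3(λ2+λ3), clusters ≥ 3); "interior" via the sign of the displacement
along the smoothed normal of the *ambient* membrane (nearest beads beyond
the wrapping envelope, so a fully wrapped particle is referenced against the
surrounding sheet); "wrapped" via the receptor-bead count in the envelope.
Labels: unbound (window-averaged bound fraction < 0.3), adsorbed_isolated,
linear_aggregate (elongated, weakly wrapped), membrane_bound_tubule /
internalized_tubule (elongated, wrapped; ties resolve toward
membrane-bound), discrete_endocytosis (single wrapped interior particle).
Tubule width is the maximal particle count in any axial slab one particle
diameter thick.

Desk scale: phase diagrams use ~400-bead vesicles, ~10 particles and ≲10³
sweeps per cell, which resolves the unbound→adsorbed boundary and its
monotone shift with receptor fraction; populating the full tubulation and
discrete-endocytosis regimes needs the documented long-running options
(thousands of beads, ~10⁵–10⁶ sweeps, 105–200 particles).

## 4. PLA puncta quantification (`pla`)

Per optical slice: Gaussian denoise (σ = 1 px) against short-wavelength
detector noise; subtraction of a rolling-average low-pass (window 15 px,
reflected edges) against large-scale cross-talk; strict local maxima above a
robust threshold with greedy minimum-separation suppression (brightest wins,
ties to the lowest index).  Maxima of one physical punctum recur across
slices, so they are grouped by single-linkage (nearest-point) hierarchical
clustering on lateral position (z-weighted metric optional), cut at 0.3 µm.
Summaries: N_E = puncta/cell and PLA_C = Σ (intensity / voxel volume)/cell;
treated-vs-control deviations within ±5 events/cell count as physiological
fluctuation; marker ratios are ratios of N_E.

The detection threshold is median + 8·MAD of the processed slice.  The
noise of the filtered residual is spatially correlated, and at the
conventional 5·MAD the extreme-value tail of smoothed noise floods the
detector with false maxima; 8·MAD gives recall and precision ≈ 1.0 on the
default scenes while sitting ~4× below the dimmest puncta.  Cell counts are
supplied externally (nucleus segmentation is out of scope).

Intensity across resolutions: the generator models constant photon dose per
unit volume (a voxel collects counts in proportion to its volume), under
which the *integrated* punctum intensity is resolution-invariant and the
volume normalization is the declared unit convention (a.u./µm³), not an
additional correction.

## 5. Event kinetics in 4D movies (`kinetics`)

Per frame, voxels above a robust threshold (median + 10·MAD of the first
frame) are 26-connected components; components link frame-to-frame by
nearest lateral centroid within 2 µm (births/deaths otherwise).  Per event
and frame: footprint radius r_e (equivalent circle of the z-projection) and
axial extent h_e (occupied z-span, one-plane events measuring one z-step).
Stages follow the width-vs-height criterion in physical units: clustering
while r_e ≥ h_e, tubulation while r_e < h_e until the event leaves the
apical face, fission time = their sum (an exact identity per event),
crossing time = from the last frame touching the apical face to the first
frame reaching the basal face.  Complete events traverse the layer and then
vanish within the movie.  MSD profiles are per-track squared displacements
(3D by default, lateral-only optional) on normalized time τ* = t/τ_crossing,
averaged, max-normalized, with log-log exponents fit below and above
τ* = 0.5 (both choices configurable); slope 1 marks diffusive, slope 2
ballistic transport.  Tubule diameters are FWHMs of the through-axis
cross-sectional profile of a super-resolution stack (brightest z-plane,
axis-averaged, baseline-subtracted, interpolated half-crossings).

## 6. Assay reductions (`assay`)

Apparent permeability P = (dQ/dt)/(C0·A) with the transport rate from an
ordinary least-squares slope of the full Q(t) series (no window, matching a
plain mass-over-time gradient); reported in nm/s (1 cm/s = 10⁷ nm/s);
optional subtraction of a pristine-carrier baseline to remove passive
diffusion.  Crossing efficiency is 100·Q_basal(t)/Q_apical(0) (mass-based).
Biodistribution: mass = normalized fluorescence / spike-calibration slope;
%ID/g = 100·mass/(dose·tissue mass).

## 7. Synthetic data (`synth`) — what it emulates and what it does not

- **Puncta stacks**: anisotropic Gaussian PSF (lateral σ 0.15 µm, axial
  0.45 µm — confocal-like; smaller for STED-like scenes), flat background
  (100 counts), Poisson shot noise + Gaussian read noise (σ = 3), optional
  smooth cross-talk field, puncta placed with a minimum lateral separation.
  The acquisition-noise levels and PSF widths are not experimentally
  prescribed anywhere; these defaults are the package's documented fixture.
- **Event movies**: disks on the apical plane growing to a scripted final
  radius, then fixed-footprint tubules growing into the cell to a scripted
  end-of-tubulation aspect ratio h/r = 1.8, then detached carriers
  traversing the 8-µm layer before vanishing.  Defaults script 250 complete
  events over a 40-min movie at 8.2-s frames; stage durations are
  1 + Poisson in frames with means 13.5 s (clustering), 96.5 s (tubulation,
  hence 110 s fission) and 15 s (crossing).  Stage transitions are aligned
  to acquisition frames: time-lapse imaging cannot localize a transition
  inside a frame interval, and scripting sub-frame times would bias any
  estimator's recovered means by ~half a frame (~30% of the clustering
  time).  Footprint radii are moment-matched scaled-Beta draws on
  [0.7, 4.7] µm reproducing both the mean radius (2.52 µm) and the mean
  area (25 µm², range up to ~70 µm²).  Events occupy a site grid
  (12 µm spacing) with re-use after a guard gap, so concurrent events never
  overlap laterally while the same spot hosts many events over the movie.
  Footprints render at detector resolution without an extra PSF blur —
  optics are treated as folded into the footprint — keeping the r_e/h_e
  round trip unbiased; an axial structure of scripted extent h lights
  round(h/Δz) planes so the measured extent is an unbiased reading.
- **Tubule stacks**: filled cylinders, anti-aliased over one voxel, 20-nm
  voxels, isotropic 25-nm PSF σ; the through-axis slice shows a top-hat
  profile whose FWHM is the diameter (+2–4 nm PSF broadening, −3 nm axial
  mixing).
- **Timecourses**: Q(t) = P·C0·A·t + Gaussian noise — the ideal linear
  regime.

Not emulated: vectorial/depth-dependent PSFs, photobleaching, cell-shape
heterogeneity, nuclear exclusion zones, antibody chemistry of the PLA
reaction, membrane-stain channels.  Passing round trips therefore
demonstrate estimator correctness under the declared acquisition model, not
robustness to every real-microscope artifact.

## Known limitations

- The avidity model's c_eff and the ABM stage rates are declared package
  defaults (calibrated by the design argument above), not measured
  constants; absolute P values are order-of-magnitude realistic (tens of
  nm/s) but only the shape of P(L, K_d) is meaningful.
- ABM encounters are step-resolution events, so the effective on-rate
  depends (weakly) on dt; dt is pinned by the layer-resolution rule.
- The CG membrane is not mapped quantitatively to K_d or to real nm; ε is
  in k_BT and lengths in bead diameters, and desk-scale phase diagrams are
  validated on qualitative regime ordering only.
- Event detection assumes laterally separated concurrent events (as the
  generator guarantees); heavily overlapping events would need splitting
  logic that is out of scope.
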