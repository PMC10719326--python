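# Methods

## The problem

When a small molecule (here: an anthracycline-class drug) approaches a
lipid bilayer, the strength of its *anchorage* to the membrane surface
is a useful proxy for its potential to cross into, or be stored within,
the membrane.  `memanchor` quantifies anchorage from a trajectory with
four metrics and combines them through a threshold rubric into a
relative, anchorage-based toxicity-potential ranking.  The package
operates on coarse or atomistic coordinates alike: all it needs is a
topology (masses, charges, residues, leaflet labels, hydrogen-bond
roles) and a time-ordered set of positions in an orthorhombic box.

Conventions: lengths in nm, times in ps, masses in amu, charges in e.
The z axis is the membrane normal; the bilayer mid-plane is the
mass-weighted mean z of all lipid atoms, and the upper leaflet has
z > z₀.  Leaflet assignment is static (taken from the topology), since
lipids do not flip-flop on the timescales considered.

## The four anchorage metrics

**Residence time.**  Per frame, the molecule–surface distance is the
shortest minimum-image distance between any drug atom and any atom of
the leaflet selection ("any atom of a lipid assigned to that leaflet";
the selection is configurable).  The metric is the percentage of
analysed frames with that distance ≤ 0.3 nm — the length of a typical
biological salt bridge.  The cutoff comparison is inclusive.

**Hydrogen bonds.**  A geometric criterion: a donor Do carrying a polar
hydrogen and an acceptor A (O or N) bond when r(Do,A) ≤ 0.35 nm and the
angle at the donor between Do→H and Do→A is ≤ 30°.  Both bounds are
inclusive.  The donor-centred angle is the default because the
criterion is worded as a hydrogen–donor–acceptor angle; a
`angle_at="hydrogen"` switch selects the more common Do–H···A
deviation-from-linearity convention instead.  A (Do, A) pair counts
once per frame if any of the donor's hydrogens satisfies the angle
condition; both group directions are counted, and each bond is
attributed to the residue name of its membrane-side partner, yielding
the per-phospholipid attribution table.

**Diffusivity reduction.**  The Einstein relation: D = slope/(2·dim)
of a least-squares line through the mean square displacement MSD(τ),
where the MSD averages over all time origins of the drug's centre of
mass.  Lateral coordinates are unwrapped by minimum image before the
displacement sums; z is required to be stored unwrapped.  The default
fit window spans 10–50 % of the maximum lag, a standard bias/variance
compromise; R² of the fit is reported.  A negative fitted slope is
clamped to D = 0 with a warning.  Surface immobilisation is reported as
the percentage ratio 100·D_membrane/D_bulk from paired runs.

**Mid-plane proximity.**  Frames are partitioned by the sign of the
drug's centre-of-mass z relative to the per-frame mid-plane (z = 0
counts as upper; there is no third category for molecules inside the
bilayer, which simply show small |z|).  The metric is the mean |z| per
side; a side never visited reports an absent (NaN) value.

Two supporting profiles: a 1-D mass density ρ(z) in kg/m³ (per-group
mass histograms over z relative to the mid-plane, divided by the slab
volume; amu/nm³ → kg/m³ via 1.66053906660), and a free-energy profile
by Boltzmann inversion, F(z) = −ln p(z)/max p(z) in kT, with empty bins
reported as NaN rather than ±∞.  Boltzmann inversion is the only
reading compatible with unbiased occupancy data, which is why it is the
implemented route for free-energy profiles.

**Uncertainties.**  Every scalar metric carries a block standard
deviation: the first third of the trajectory is discarded as
equilibration, the remainder is split into 4 equal blocks, the metric
is evaluated per block, and the sample standard deviation (ddof = 1)
across blocks is reported.  This generalises the convention of
splitting the last two thirds of a production run into four blocks.

## The ranking rubric

| criterion | first category | second category |
|---|---|---|
| residence time (%) | > 20 | 12–20 |
| membrane H-bonds (/frame) | > 0.1 | 0.05–0.1 |
| distance from mid-plane (nm) | < 2.6 | 2.6–4.16 |
| D_membrane/D_bulk (%) | < 25 | 25–35 |

Leaflet-resolved criteria take the best category over the leaflets and
tag it U/L/B (upper/lower/both).  Boundary inclusivity is configurable
because prose thresholds are ambiguous at exact boundaries; the
defaults read "more than x" as strict and "between a and b" as closed.
Ranking sorts by number of firsts, then seconds, then residence layer
breadth (B beats single), then which criteria hold the marks in column
order (residence > hbonds > midplane > diffusion).  The last two keys
are artifact conventions chosen to make the ordering deterministic, not
rules with physical content; drugs still tied are reported as an
explicit tie group in alphabetical order.  A Spearman coefficient
(tie-adjusted, via `scipy.stats.spearmanr`) tests whether molecular
dipole moments — computed as |Σqᵢrᵢ| with 1 e·nm = 48.0321 D, about the
centre of mass with a warning for non-neutral species — carry any
information about the ranking.

## The synthetic generator

Real drug–membrane trajectories are rarely shareable, so the package
ships a generator with *known* statistical structure against which
every estimator is validated.

*Membrane.*  One bead per lipid head group on jittered square lattices
at z₀ ± `z_surface`, with per-leaflet head-group counts of the
asymmetric myocardial model (upper: 40 PC + 17 PE + 7 SM; lower:
35 PC + 21 PE + 8 PS; 64 per leaflet).  Head identities are assigned by
a seeded shuffle.  Beads are H-bond acceptors; PS carries −1 e.

*Drug.*  A single dynamic bead (≈543 amu, the anthracycline scale)
rigidly carrying a polar hydrogen and an acceptor oxygen as satellites,
so hydrogen-bond and dipole analyses have multi-site input without
complicating the integrator.

*Dynamics.*  Overdamped Langevin motion of the bead.  x, y are free
diffusion (variance 2·D_bulk·dt per step), wrapped periodically.  z
moves in a square-well potential of depth `well_depth` (specified
directly in kT, sidestepping any force-field energy scale) spanning
[z_surface − well_width, z_surface] and its mirror image, with
reflective walls at |z| = `core_halfwidth` (the tail core) and at the
box z faces.  Reflective z boundaries preserve the above/below-membrane
distinction that the mid-plane analysis needs, and mirror the
observation that unbiased trajectories do not cross the bilayer.  For a
piecewise-constant potential the deterministic drift −D·∂(U/kT)/∂z
vanishes almost everywhere, so the well edges are handled by a
Metropolis acceptance of the proposed Gaussian move; with a symmetric
proposal this preserves the Boltzmann distribution exp(−U/kT) exactly,
which is what makes closed-form validation possible.  At depth 0 every
move is accepted and the update is the literal free-diffusion step.  A
`StabilityError` rejects time steps whose RMS displacement
√(2·D_bulk·dt) exceeds the well width, since such steps straddle the
well.

The closed-form one-sided equilibrium occupancy of the well band,

    p_well = w·e^ε / (w·e^ε + L_free),    ε = well_depth in kT,

(w the well width, L_free the accessible width outside it) is exposed
as `SyntheticParams.equilibrium_well_fraction` and anchors the
stochastic tests.

*Defaults* (the study conditions): D_bulk = 4×10⁻⁴ nm²/ps
(4×10⁻⁶ cm²/s, typical of a ~550 Da solute in water), well_depth = 4 kT,
well_width = 0.5 nm, z_surface = 2.2 nm (half of a ~4.4 nm saturated-
chain bilayer), core_halfwidth = 1 nm, box 6.4 × 6.4 × 10 nm (64 lipids
per leaflet at ≈0.64 nm² each; ~3 nm of water per side), dt = 1 ps,
1.2×10⁶ steps (1.2 µs) sampled every 200 ps, T = 310 K.

*What the generator does and does not emulate.*  It reproduces the
composition bookkeeping, reversible surface adsorption with tunable
strength, Boltzmann z statistics, and free lateral diffusion.  It does
**not** model lateral friction near the surface (so apparent
D_membrane/D_bulk bottoms out near 2/3 — z immobilises, x and y do
not — far from the ~8–12-fold drops seen in all-atom data), explicit
water or ions (drug–water H-bond machinery is exercised with static
site-cloud fixtures), membrane undulations or lipid motion (beads are
frozen), drug orientation (satellites co-move rigidly), or membrane
crossing (reflective core).  Passing tests therefore certify the
*estimators* — that residence, H-bond, diffusion, density and
free-energy code recover known inputs — not that the generator
reproduces any particular drug's measured values, which would require
the original atomistic trajectories.

*Fixtures.*  `make_hbond_fixture` places donor–hydrogen–acceptor triads
with exact geometry (bonded; distance near-miss at r = 0.36 nm, angle
0°; angle near-miss at r = 0.30 nm, 35°) on a ≥1.5 nm grid so no
cross-triad pair can bond, making detected counts exactly predictable.
`make_residence_fixture` pins the drug at 0.25 nm or 1.5 nm beneath a
lower-leaflet bead so the within-cutoff fraction is exact by
construction.

## Numerical choices

- Minimum image per axis (exact for orthorhombic cells); triclinic
  boxes are rejected explicitly.
- MSD by the FFT autocorrelation decomposition over all time origins;
  MSD(0) ≡ 0 by construction.
- Reflection implemented as the triangle-wave fold, valid for
  arbitrarily large proposals.
- Equilibrium sampling for validation uses many independent walkers,
  optionally initialised from the exact piecewise Boltzmann law by
  inverse-CDF sampling (no burn-in bias).
- Density histograms guarantee Σ_bins ρ·V_bin = group mass (relative
  error ≤ 1e-9) when the z range covers the group.
- Block splitting uses `np.array_split` (consecutive, near-equal,
  non-empty); mid-plane block values skip blocks with no frames on the
  relevant side and report NaN if fewer than two remain.
- Ties, boundaries and degenerate inputs: inclusive ≤ at the residence
  cutoff and both H-bond bounds; z = 0 assigned to the upper side;
  empty drug lists produce a manifest-only pipeline run with a warning;
  per-drug analysis failures are isolated and reported, not fatal.

## Problem sizes used for validation

Desk-scale runs are deliberate: the demo pipeline simulates three drugs
(well depths 0.5, 2.5, 8 kT) for 1.2 µs each in an 18 nm-tall box — the
taller water slab separates the desorbed state cleanly, and the run
length gives the occupancy estimates roughly 15 decorrelated samples,
enough to keep each drug's expected category ≥2σ from the rubric
boundaries.  Diffusivity recovery uses 24 seeds × 150 ns of free
diffusion (lateral MSD, fit window 0.5–3 ns); well-depth recovery uses
512 walkers × 30 ns after 20 ns of equilibration.

## Known limitations

Single-bead drug dynamics cannot show orientation-dependent anchorage;
the static membrane suppresses density-profile broadening; the rubric's
tie-break chain beyond first/second counts is a reproducibility
convention, not physics; H-bond lifetimes/kinetics, umbrella-sampling
free energies and surface-tension analyses are out of scope.  Outputs
are an anchorage-based *potential* ranking — no clinical inference.
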