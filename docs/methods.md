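# Methods

This note documents the models and estimators implemented in
`densephase`, the parameters that matter, what the synthetic generators
do and do not emulate, and the numerical choices made where the design
was genuinely open. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model and geometry

Coordinates are stored in nm (PDB I/O converts Å↔nm at the boundary),
times in ps, masses in Da. Boxes are cubic only; triclinic inputs are
rejected (`UnsupportedGeometryError`) since every system this package
targets is cubic. Frames hold wrapped coordinates in [0, L); analyses
that need continuous paths (MSD, R_g, BAT) unwrap internally by
accumulating minimum-image displacements, which is valid while no atom
moves ≥ L/2 between frames (violations raise `SamplingTooCoarseError`
rather than aliasing silently). Hydrogens are flagged by element
inference from PDB-v3 atom names; every contact and SASA computation
uses heavy atoms only. Residue numbering is 1-based within each chain in
all inputs and reports.

Uncertainty propagation is first-order Gaussian:
ε_prop = sqrt(Σ (∂f/∂xᵢ · εᵢ)²), exposed as `core.propagate_error`.

## Contacts, valency, clusters

A residue pair is in contact when any heavy-atom pair sits within
0.35 nm (inclusive — the boundary is measure-zero and inclusivity fixes
determinism) under the minimum image. Intramolecular pairs with
|i−j| < 2 are excluded: nearest neighbors are bonded and always
"in contact", so counting them would only add a constant. Detection is
a chunked O(N²) pass verified against an explicit 27-image enumeration
oracle in the tests; no cell-list shortcut is used at the system sizes
this package targets.

Valency is the number of distinct partner chains per chain per frame.
Its autocorrelation is computed per chain on mean-removed series with
unbiased (per-origin-count) normalization, averaged over chains,
normalized at lag zero, and fit by A·exp(−t/τ) with unweighted least
squares on lags up to the first zero crossing (beyond it the ACF is
noise). Cluster series are connected components of the chain graph
(single-linkage at the contact cutoff is exactly component finding).
Percolation is geometric: a BFS tree anchors each chain at an unwrapped
position; any non-tree contact edge inconsistent with those positions
closes a cycle with nonzero net image displacement, i.e. the cluster
winds around the torus.

Contact lifetimes are maximal runs of consecutive presence of a specific
(chain,res)–(chain,res) contact; a single absent frame ends a run (no
gap tolerance — "uninterrupted" is read literally). Durations are
run-length × frame stride and are aggregated by unordered residue-type
pair or by sticker/spacer category.

Composition-expected contact fractions are n_A·n_B/N² (like pairs) and
2·n_A·n_B/N² (unlike pairs); enrichment is observed/expected, ranked
descending with alphabetical tie-break. With a valency filter, a contact
counts toward pair-type statistics only when **both** chains have the
filtered valency (a valency-1 contact is a 1:1 encounter); in
interactivity profiles the filter applies per side, since the profile
attributes contacts to residues of a specific chain.

## Motif (sticker) calling

Interactivity is the per-residue contact count over all chains and
frames, normalized to max 1. Smoothing and second derivatives use
quadratic Savitzky–Golay convolution (scipy `savgol_coeffs`) at windows
5, 7, 9; polynomial order 2 matches the classical coefficient tables for
these windows. Ends where the window does not fit carry NaN rather than
padded values — padding would fabricate curvature exactly where motif
boundaries matter; the consequence is that motifs cannot begin within
(w−1)/2 of a terminus at window w.

Candidate motif centers are positions whose second derivative lies
strictly below mean − 1·SD (strict for determinism). A Shapiro–Wilk
p-value for the second-derivative distribution is reported; p < 0.05
logs a warning but does not reject the call. Each candidate at window w
marks a w-wide interval; maximal sequence runs covered by intervals from
≥ 2 window sizes become motif calls, at full certainty when some
position is covered by all three. Because the threshold mean − 1·SD is
scale-equivariant and the normalization is a positive scaling, calls are
invariant to profile rescaling (tested).

## Rheology

Green–Kubo viscosity: per tensor element (P_xy, P_xz, P_yz and the three
half-differences), the ACF over all time origins (FFT) is integrated
numerically (trapezoid) on [0, 1 ps] and analytically beyond, using a
biexponential fitted on [1, 4 ps]; the tail contribution is
Σ a_k τ_k e^(−t_num/τ_k). Units: with C in bar², V in nm³, t in ps,
η[mPa·s] = 1e−26 · V ∫C dt / (k_B T), k_B = 1.380649e−23 J/K exact,
T = 310 K default. The six element estimates are averaged unweighted
(mean ± SD); elements whose fit fails to converge or leaves a large
relative residual are dropped with a log message.

Fit specifics, chosen after examining estimator behavior on series with
known viscosity: amplitudes are free in sign and τ is bounded by
5 × t_fit_end, with initialization from a log-linear single-exponential
fit split 70/30 between components. A 1–4 ps window cannot constrain
components much slower than itself; if τ is unbounded and amplitudes are
clamped non-negative, the slow component fits the (positively
correlated) ACF noise floor and systematically inflates the analytic
tail. With the bounded, sign-free fit the recovery error on 10⁴-ps
synthetic series is at the percent level (asserted at 5%/10% in the
acceptance suite).

Diffusion: MSD over all origins and particles (FFT decomposition), lags
to half the series; linear fit MSD = c + 6·D^PBC·τ on a configured
window. For real dense-phase trajectories the documented default window
is 10–30 ns (0–5 ns for dilute single chains, where no long linear
regime exists); for the pure-Brownian validation data the tests fit the
first 2% of the lag range — synthetic tracers have no short-time
ballistic or caging artifact, and the early lags are where the
origin-averaged MSD has the smallest variance, giving ≤ ~2% recovery
error where long-lag windows fluctuate by several percent. The
finite-size correction k_B·T·ξ/(6π·η_sim·L) with ξ = 2.837297 (cubic
lattice) is exact arithmetic; the experimental-viscosity rescaling uses
η_expt = 0.694 mPa·s by default.

## Conformational statistics

Fragment ensembles: overlapping w-mers (5 or 10, single-residue shift);
every (replica, chain, sampled frame) contributes one backbone (N, CA,
C) conformation per position; chains are made whole across the boundary
first. Backbone is N/CA/C without O for pairwise-fitting stability; for
bead polymers the backbone selection can be set to ("CA",).

Gromos clustering: pairwise RMSD after optimal (Kabsch) superposition;
iteratively the member with the most neighbors within the cutoff
(ties → lowest index, via argmax) is removed together with its neighbors
as a cluster. Cutoffs 0.05 nm (pentamers) and 0.1 nm (decamers) are the
defaults. The output is a partition; the implementation is checked
against an independently written neighbor-count oracle that uses scipy's
`Rotation.align_vectors` for the superposition.

RMSF: members of each fragment ensemble are superposed onto their mean
(two passes), per-atom RMSF is backbone-averaged at the fragment's
middle residue (3rd of 5, 5th of 10) and assigned to that sequence
position; unassigned terminal positions take the nearest assigned value.
The middle-residue choice avoids the fitting-edge inflation at fragment
ends.

R_g is mass-weighted per chain per frame (chains made whole first).
SASA uses Shrake–Rupley with a golden-spiral lattice of 960 points,
Bondi radii and a 0.14 nm probe; the quadrature error on a lone sphere
is < 0.5%. The dense-phase variant treats all chains as one occluding
body under the minimum image and reports the total divided by the chain
count.

## Solvation

The water RDF is *proximal*: each water oxygen is binned by its distance
to the nearest protein heavy atom (capped at 5 nm). N(r) is exact by
counting; g(r) divides by the ideal-gas expectation ρ·V_shell(r), where
the proximal shell volume — which has no closed form for an irregular
solute — is estimated by seeded Monte Carlo integration of the box
(10⁵ samples by default; the estimate uses the first frame's solute
configuration). Per-chain dense-phase counts assign a water to every
chain whose shell contains it; overlapping shells therefore double-count
by construction, and per-chain counts are reported independently.

The bound-shell radius r\* is the inflection point of the SD across
runs of N(r) (Savitzky–Golay second derivative at window 9, first sign
change, linearly interpolated). If the SD curve is flat or
inflection-free the caller falls back to the declared 1.25 nm with
provenance "declared". The solvent-entropy bound charges each released
water 7 cal mol⁻¹ K⁻¹ and neglects correlations between released waters,
which makes it an upper bound; the SASA route converts at 0.15 nm² per
bound water.

## Configurational entropy (MIST)

Chains are converted to internal coordinates along a linear z-matrix
tree (atom i: bond to i−1, angle with i−2, torsion with i−3), giving
3N−6 coordinates; the NeRF reconstruction reproduces Cartesian input to
machine precision up to rigid-body placement, and the forward transform
is cross-checked against MDAnalysis' BAT analysis in the tests.

Marginal entropies are histogram estimates with Jacobian corrections
(r² for bonds, sin θ for angles, supports (0, π) and (−π, π] for angles
and torsions) plus the Miller–Madow occupancy correction; pairwise MI
comes from 2-D histograms with the corresponding first-order bias
correction, clamped at zero. S_MIST = Σ h_i − Σ_tree MI with the maximum
spanning tree built by Kruskal (ties broken by coordinate index), so
S_MIST ≤ Σ h_i always. Defaults: 50 bins, ≥ 100 frames enforced. The
Miller–Madow choice matters: the plain plug-in MI at 50 bins and 10⁵
samples carries a bias of order (K−1)²/2n ≈ +8%, which the correction
removes (the Gaussian closed-form check in the acceptance suite then
agrees to well under 10%). One known estimator artifact is documented by
test: duplicating a coordinate changes S_MIST by exactly the
discretization offset ln(range/bins) rather than zero, because the
histogram MI of an exact copy saturates at the discrete entropy.

Units are nats throughout; ΔS (dense copy − single run, all
combinations) converts to energy as T·ΔS·R with R = 1.98720 cal/(mol K),
reported in kcal/mol at 310 K.

## Fractal model

φ = κ·M_w/((4/3)π R_g³) with κ = 1.21 Å³/Da (converted as
V_mol[nm³] = 1.21·M_w·10⁻³). φ is computed per frame and averaged —
averaging R_g first and then computing φ is not equivalent (Jensen), and
the per-frame convention is the default with the alternative exposed.
φ > 1 is physically possible for very compact conformers and is returned
as-is; the fractal formula d_F = 3/(1 − log φ/log(n+1)) itself requires
0 < φ < 1 and n > 0 and raises `DomainError` otherwise. Natural logs are
used internally; the ratio makes the base irrelevant.

Scaling curves iterate the aggregation: generation k has mass
(n+1)^k·M_w and radius R_g·((n+1)^k)^(1/d_F); the log–log regression
slope is 1/d_F by construction (asserted to 1e−10).

The explicit cluster generator is a hierarchical cluster–cluster
aggregation scheme (a deliberately simple, documented construction —
not a re-implementation of any published aggregation code): monomer
pairs, then cluster pairs, are merged by placing the partners at the
center separation Γ that makes the merged point-mass gyration radius
satisfy N = k_f·(R_g/a)^d_F exactly
(Γ² = N²/(N₁N₂)·(R_target² − (N₁R₁² + N₂R₂²)/N)), clamped at contact,
with random orientations redrawn (bounded retries) until no two
particles of different subclusters approach closer than one monomer
diameter. With the default k_f = 1 every merge level satisfies the
mass–radius law exactly, so the regression over the merge hierarchy
recovers the target exponent; k_f = 2 makes the two-particle cluster a
contact dimer with R_g = a.

## Synthetic-data generators: what they emulate, and what not

`generate_chain_trajectory` evolves bead-per-residue chains (bond length
0.38 nm, bead radius 0.26 nm) by single-bead Metropolis Monte Carlo:
harmonic bonds (200 kT/nm²), soft-core quadratic repulsion (6 kT at full
overlap), and a square well of depth ε_s (kT) and range 1.5× bead
diameter between sticker beads of *different* chains. Moves are uniform
with half-width sqrt(mobility); "mobility" is the nm² proposal scale per
sweep and the sweep→ps mapping is a declared configuration constant
(1 ps/sweep by default) — MC time is not physical time. The soft (not
hard) repulsion is deliberate: it lets bead centers approach within the
0.35 nm contact cutoff with Boltzmann-suppressed probability, so the
heavy-atom contact rule produces statistics, and sticker wells enrich
sub-cutoff approaches between planted positions. Default residue labels
cycle Gly/Arg/Tyr/Asp so composition-normalized enrichment is exercised.
The generator reproduces: planted interactivity peaks (recovered by the
motif caller), sticker-lifetime vs spacer-lifetime ordering, valency
fluctuations, and connectivity-preserving dynamics. It does **not**
reproduce: atomistic contact geometry, realistic kinetics or
hydrodynamics, secondary structure, sequence-specific physics beyond the
planted wells, or solvent. Passing tests therefore validate the
*estimators*, not force-field realism.

`generate_pressure_series` builds each tensor element as an independent
sum of exactly discretized Ornstein–Uhlenbeck components with
autocovariance Σ a_k e^(−t/τ_k), so the Green–Kubo integral is
Σ a_k τ_k in closed form. `generate_brownian_tracks` draws Gaussian
displacements with per-axis variance 2·D·dt and stores both wrapped and
unwrapped paths, so unwrapping and MSD code can be checked exactly. All
generators are bit-deterministic under a fixed seed.

`build_multicopy_box` reproduces the dense-phase construction: copies
drawn with replacement from a monomer pool, uniformly random rotations,
centered on a ⌈n^(1/3)⌉³ grid in randomized order, rejected and
re-rotated while any inter-copy heavy-atom pair is closer than the
minimum separation. It reports molar and mass concentration from the box
volume and chain mass; 24 copies of a 7558-Da chain in a 15 nm box give
11.8 mM ≈ 89.2 g/l, the dense-phase regime the defaults target.

## Pipeline

`run_pipeline` executes the stages in dependency order on a synthetic
dense system plus a single-chain reference, writing CSV artifacts and a
`summary.json` whose fields mirror the standard observable table, with
provenance (config hash, seed, package version). A single global seed
fans out to per-stage seeds by stable SHA-256 hashing, so stages remain
reproducible independently; identical config + seed gives byte-identical
summaries (tested). Demo problem sizes (12 chains × 60 residues,
150 frames; 2×10⁵-step pressure series; 32 tracers) are chosen so the
full demo completes in minutes on one CPU while every stage has enough
data to be statistically meaningful; the entropy stage requires at least
100 frames (histogram undersampling guard).

## Known limitations

- The contact kernel is O(N² ) per frame; adequate for bead systems and
  tens of thousands of atoms, not for production all-atom dense boxes at
  high frame counts.
- MIST is pairwise-truncated; higher-order correlations are ignored by
  construction, and absolute entropies depend weakly on the (documented)
  torsion-tree choice. Only entropy *differences* between like systems
  are meaningful.
- The solvent-entropy number is an upper bound with water–water
  correlations neglected; rigorous solvent-entropy methods are out of
  scope.
- The proximal-RDF shell volume uses the first frame's solute
  configuration; for strongly fluctuating solutes increase `mc_samples`
  or average externally.
- Percolation detection uses chain anchor atoms; chains longer than
  ~L/2 could in principle confound the image bookkeeping (not the case
  for the systems targeted here).
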