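# densephase

Analysis toolkit for the *dense phase* of intrinsically disordered
protein (IDP) condensates, built around all-atom or bead-resolution
multi-chain trajectories of a disordered chain (the reference system is
the 73-residue arginine/glycine-rich RGG3 fragment of FUS, simulated as
24 copies in a 15 nm periodic box).

Biomolecular condensates are protein-rich liquid phases whose interiors
are highly dynamic: chains exchange binding partners on nanosecond
timescales, yet the phase as a whole shows reproducible, statistically
well-defined organization. This package implements the full chain of
analyses needed to quantify that organization and to connect chain-level
observables to condensate architecture:

- **Contacts & valency** — residue–residue contacts under the 3.5 Å
  heavy-atom minimum-image rule; instantaneous valency *n* (number of
  distinct partner chains); valency autocorrelation with exponential
  relaxation times; cumulative pair coverage (of the n(n−1)/2 possible
  chain pairs); single-linkage cluster series with geometric percolation
  detection; uninterrupted contact lifetimes by residue-type or
  sticker/spacer category; contact-type enrichment against the
  composition-only expectation (n_A n_B/N², doubled for unlike pairs).
- **Interaction motifs (stickers)** — per-residue interactivity
  profiles, quadratic Savitzky–Golay smoothing and second derivatives at
  windows 5/7/9, minima picking at mean − 1 SD (with a Shapiro–Wilk
  normality report), and consensus motif calls supported by at least two
  window sizes.
- **In silico rheology** — Green–Kubo shear viscosity
  η = V/(k_B T) ∫ C(t) dt from the six pressure-tensor elements
  (numeric integral to 1 ps, analytic biexponential tail fitted on
  1–4 ps), and translational diffusion from MSD = c + 6 D τ with the
  cubic-lattice Yeh–Hummer finite-size correction
  D_t = D^PBC + k_B T ξ/(6πηL), ξ = 2.837297, plus viscosity rescaling
  D^pred = D_t · η_sim/η_expt (η_expt = 0.694 mPa·s at 310 K).
- **Conformational statistics** — sliding pentamer/decamer fragment
  ensembles, gromos-style neighbor-count RMSD clustering, RMSF profile
  reconstruction from fragment middle residues, radius of gyration, and
  Shrake–Rupley SASA (960 sphere points), including the dense-phase
  "all copies as one body" variant.
- **Solvation** — proximal water RDF (distance to the nearest protein
  heavy atom, Monte-Carlo shell-volume normalization), bound-shell
  boundary detection from inter-run N(r) variability (default 1.25 nm),
  and the solvent-entropy upper bound: each released water contributes
  ≈ 7 cal mol⁻¹ K⁻¹, with a SASA-based cross-estimate at 0.15 nm² per
  water.
- **Configurational entropy** — bond–angle–torsion transform (with
  exact Cartesian reconstruction) and the maximum information spanning
  tree (MIST) approximation S_MIST = Σᵢ h(xᵢ) − Σ_tree MI, in nats, with
  dilute→dense differences averaged over all run/copy combinations.
- **Fractal architecture** — the chain-level link between valency *n*
  and compactness φ = κM_w/((4/3)πR_g³) (κ = 1.21 Å³/Da) and the cluster
  fractal dimension

      d_F = 3 / (1 − log φ / log(n + 1)),

  mass–size scaling curves M ∝ R^d_F across aggregation generations, and
  a hierarchical cluster–cluster aggregation generator producing explicit
  particle clusters with a prescribed d_F.
- **Synthetic data** — every stage is validated without MD input:
  a seeded Metropolis Monte Carlo sticker-polymer generator (planted
  high-affinity residues with square-well attraction), Ornstein–Uhlenbeck
  pressure-tensor series with closed-form Green–Kubo viscosity, Brownian
  tracers with known D, and the multi-copy grid construction procedure
  (randomized identity and orientation, clash-free placement) with its
  concentration report.

## Worked example

Chain-level observables of a dense-phase run (mean valency n = 3.45,
radius of gyration R_g = 1.91 nm, chain mass 7558 Da) determine the
condensate architecture:

```python
>>> from densephase.fractal import fractal_dimension, volume_fraction
>>> round(volume_fraction(M_w=7558.0, R_g=1.91), 4)   # compactness of that frame
0.3133
>>> round(fractal_dimension(n=3.45, phi=0.38), 4)     # run-mean compactness 0.38
1.8203
```

A fractal dimension below 2 means a loose, low-dimensional cluster
topology: each 4.45-fold increase in cluster mass only multiplies its
radius by 4.45^(1/1.82) ≈ 2.3.

Finite-size-corrected diffusion for a particle with fitted
D^PBC = 1.0×10⁻⁶ cm²/s in a 15 nm box at 310 K and η_sim = 1.04 mPa·s:

```python
>>> import numpy as np
>>> from densephase.rheology import fit_diffusion
>>> lags = np.arange(50.0)                       # ps
>>> est = fit_diffusion(lags, 6e-4 * lags, (0, 49), L=15.0, T=310.0, eta_sim=1.04)
>>> round(est.D_t * 1e6, 3)                      # 1e-6 cm^2/s units
1.413
```

The correction adds 0.413×10⁻⁶ cm²/s — finite-size effects at this box
size are a ~40% correction, which is why they cannot be skipped.

The solvent-entropy bound for a measured depletion of 65 bound waters
per chain at 310 K:

```python
>>> from densephase.solvation import bound_water_change
>>> bound_water_change(dn_direct=-65.0, T=310.0).TdS_kcal
141.05
```

An end-to-end synthetic demonstration (generation → contacts → motifs →
rheology → conformers → solvation bound → entropy → fractal model) runs
with:

```bash
densephase run --outdir out/ --seed 1
```

and writes per-stage CSV artifacts plus a `summary.json` whose fields
mirror the standard dense-phase observable table (SASA, relative
exposure change, diffusion, R_g, valency, φ, d_F, ΔS_conf).

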