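# Methods

`dimerpmf` re-implements, at desk scale, the computational protocol used to
rank membrane-protein dimer interfaces by their interaction free energy:
umbrella sampling with window exchange along the protein–protein
separation, restraint-aware WHAM unbiasing with block-bootstrap errors and
time-windowed convergence diagnostics, plus the interface census
(RMSD clustering, contact statistics, orientation angles) and
distance-conditioned lipid occupancy maps. Because the production
simulations behind such studies are cluster-scale (tens of microseconds of
coarse-grained MD per umbrella window), the package substitutes an
analytic two-coordinate model with a Brownian-dynamics engine. The model
is exactly solvable, so every estimator in the package can be validated
against ground truth rather than against another simulation.

## The toy association landscape

Two degrees of freedom: the center-of-mass separation `d` (nm) of two
membrane proteins, and a dimensionless collective coordinate `l` for
interfacial lipids (`l0 = 0`: lipids away; `l1 = 2`: a lipid wedged at the
interface). The energy, in units of kT,

```
U(d, l) = U_d(d) + U_l(l) + c s(d) g1(l) + r c t(d) gm(l)
```

- `U_d`: a Morse well (depth `eps_bind = 16 kT` at `d0 = 5.4` nm, range
  0.25 nm), a Gaussian association barrier (`h_barrier = 10.5 kT` at
  5.9 nm, width 0.25 nm), and an exponential short-range repulsion
  (scale `a_rep = 0.04` nm) at the inner wall. The resulting marginal
  well depth is ~29.5 kJ/mol — inside the 20–55 kJ/mol range typical of
  transmembrane dimer interfaces.
- `U_l`: a quartic double well with a barrier `eps_trap = 2 kT` above the
  `l0` minimum, tilted by a Gaussian of depth `delta_trap = 2.5 kT` so the
  lipid-at-interface state is favoured whenever the proteins do not
  exclude it (free protein surfaces are wetted by lipid). The escape
  barrier out of the trap state is therefore 4.5 kT.
- Steric coupling: `c = c_couple = 8 kT` times a logistic switch `s(d)`
  (midpoint 5.9 nm, width 0.18 nm) times a Gaussian `g1` centered on
  `l1` — a lipid at the interface is heavily penalized once the proteins
  close below ~5.9 nm.
- Trapping coupling: amplitude `r c = 16 kT` times a sharp switch `t(d)`
  (midpoint 6.4 nm, width 0.06 nm) times a Gaussian `gm` on the double-well
  midpoint — at separations below ~6.4 nm the flip barrier between the two
  lipid states is raised so high that the lipid coordinate is kinetically
  frozen, while it equilibrates in a few hundred ps at larger separations.

With `c_couple = 0` the energy separates exactly, which gives the trivial
limit used by several tests. Reflecting walls bound the domain
(`d in [5.3, 7.5]` nm, `l in [-2, 4]`); the quadrature oracle integrates
`l` over the same interval, so dynamics and oracle describe the identical
finite system and agree to quadrature accuracy, not merely asymptotically.

These parameters were chosen to reproduce, at a 2×10⁵-step budget, the
sampling phenomenology seen in the cluster-scale studies: an unbound
start almost never binds (the lipid blocks association; 1–3 of 32
unbiased runs reach the well), conventional umbrella runs inherit their
start's lipid state and mis-estimate the profile by 1.5–4.5 kT, and
window exchange repairs both. The trap-switch sharpness and the modest
flip barrier set how fast the replica pool renews its lipid states;
they were chosen so renewal takes a few hundred ps — slow enough to
create hysteresis in exchange-free runs, fast enough that the exchange
sampler converges within the budget.

## Brownian dynamics

Overdamped dynamics with one step of the Leimkuhler–Matthews scheme:

```
x <- x - (D/kT) grad(U + bias) dt + sqrt(2 D dt) (xi_n + xi_{n+1})/2
```

with `D = 0.1 nm²/ps` per coordinate and `dt = 0.01 ps`. The averaged
noise costs nothing but removes the O(dt) stationary bias of the plain
Euler–Maruyama step; this matters because the umbrella force constants
put `D dt U''/kT` near one, where the plain scheme inflates window
variances by tens of percent and visibly biases the unbiased profile
(~0.5 kT in the well). For harmonic potentials the scheme samples the
exact variance `kT/k` at any stable step size.

Numerical guards: a setup check requires `D dt |grad U| / kT < 0.2` over
the thermally accessible domain (within 20 kT of the global minimum —
the repulsive wall corners of the rectangular domain are never visited
and would otherwise dominate); at run time, ten consecutive steps with
displacement above `5 sqrt(2 D dt)` abort with an instability error.
Deliberate far-from-center starts (a bound-state start in a far window)
are handled by a 500-step displacement-capped relaxation phase that is
not recorded.

Randomness: one counter-based Philox stream per replica, keyed by
`(master seed, replica id)`; the Metropolis uniforms for swaps come from
a dedicated stream. A replica carries its stream (and its previous noise
increment) wherever exchange takes it, so runs are bit-reproducible and
an exchange-free run is identical, sample for sample, to independent
window runs with the same seeds.

## Umbrella ladder and window exchange

Windows sit every 0.1 nm (21 windows over 5.4–7.4 nm by default). The
force constant follows an overlap rule: `k = 4 kT / spacing²`, i.e. the
Boltzmann width of a window is half the spacing, predicting ~32% overlap
between neighbouring window distributions. Measured exchange acceptance
is 0.15–0.40 across most of the ladder and a few percent for the two
pairs straddling the association barrier, where the landscape slope
displaces the window distributions apart. An optional single refinement
round runs a short pilot and inserts a midpoint window into any adjacent
pair whose acceptance falls below 10%.

Exchange attempts alternate even/odd adjacent pairs every `tau_ex` ps
(default 0.2 ps = 20 steps; the attempt interval must be a multiple of
dt). A swap exchanges the two configurations between their fixed windows
with probability `min(1, exp(-dU/kT))`, where `dU` involves only the two
bias energies. Every attempt is logged (time, pair, dU, uniform draw,
outcome) and the log is validated against the recorded draws on input;
replica identity is tracked per sample, and the replica-walk diagnostic
replays the log to verify the bookkeeping is a permutation at all times.

Initial states: `bound` places every window's walker at `(d0, l0)`;
`unbound` at the window center clipped to the plateau side of the barrier
with the lipid at the interface `(max(center, d_barrier + 0.3), l1)`;
`mixed` alternates the two by window parity.

## WHAM, convergence slices, bootstrap

Histograms use bins of spacing/5 = 0.02 nm. The standard self-consistent
WHAM iteration runs to `max |df_i| < 1e-8 kT` (at most 1e5 iterations),
with an over-relaxation boost (factor 1.7) engaged once the iteration is
steadily contracting and dropped on any non-monotone step. Disconnected
histogram support raises an error naming the empty gap. The profile is
zeroed so the mean over the outermost 0.3 nm of the sampled range is zero
(plateau anchoring is robust where single-bin anchoring is not), and
`d_int = d - argmin F` of a reference curve. A binless multistate
reweighting estimator (`mbar_pmf`) is kept as an independent cross-check;
it shares no code path with the WHAM solver.

Geometric corrections (`jacobian_correction`) are explicit: `none` for
the intrinsically 1D toy; `radial_3d` adds `2 kT ln d` for a freely
rotating 3D separation; `custom` applies a user-supplied log-Jacobian
table — the hook for orientation-restraint (virtual-bond) partition
terms, whose exact form depends on the restraint geometry and is left to
the caller.

Time-windowed profiles solve WHAM independently on consecutive slices
(default a tenth of the budget); slices with an empty window histogram
are returned flagged, not dropped. The convergence diagnostic is the
first slice whose RMS to the oracle drops below 0.5 kT.

Errors come from a block bootstrap in which every umbrella window is
rebuilt from two contiguous half-length blocks drawn with replacement,
each of 100 replicates is re-solved (warm-started) and re-zeroed, and
the error bar is the replicate standard deviation multiplied by
`sqrt(B/(B-1)) = sqrt(2)`: the plug-in variance of a B-block bootstrap
is biased low by `(B-1)/B`, which for two blocks halves the variance;
the correction makes the bars estimate the true sampling error
(verified on synthetic data with known error).

Known limitation: with half-run blocks the variance estimate has few
effective degrees of freedom, so pointwise `estimate ± 2 stderr` bands
behave like Student-t, not Gaussian, intervals; and error modes slower
than the half-run (the lipid-composition turnover of the replica pool)
are partially invisible to any within-run resampling. Measured over 20
independent runs at the default budget, the exact profile lies within
±2 stderr at ~72–81% of interior grid points rather than the ~95% a
Gaussian reading would suggest. Aggregate (RMS-level) error statements
are reliable; pointwise bands should be read as indicative. This is a
property of half-window resampling at finite budget, not of the WHAM
solution itself.

## Scalar extraction

`well_depth` reports `mean F over the plateau region - min F` as a
positive depth, flags curves without an interior minimum deeper than
0.5 kT as having no bound state, and lists local maxima between the
minimum and the plateau (with d_int positions and prominences) as
barriers. `residual_range_kt` quantifies the hysteresis shoulder as the
range of the estimate-minus-oracle residual across the boundary zone
(5.9–6.6 nm): a converged run is flat there (≲0.3 kT), a bound-start
exchange-free run shows a 1.5–2 kT ramp.

## Interface census

Dimers are harvested as all monomer pairs with minimum-image
center-of-mass separation below 5.3 nm, each shifted to a common image.
The dissimilarity is the mass-unweighted RMSD after least-squares
superposition of all dimer beads (Kabsch via quaternion-free
`Rotation.align_vectors`, residual computed explicitly to avoid the
cancellation noise of the rssd shortcut), optionally minimized over the
A/B label swap for homodimers. Clustering follows the greedy
neighbour-count rule at 0.4 nm: the conformation with the most
neighbours within the cutoff seeds a cluster, members are removed,
repeat; ties break to the lowest conformation index, making the result
deterministic and permutation-stable. Contacts: two monomers touch if
any inter-monomer bead pair is closer than 0.6 nm (a typical
coarse-grained bead contact distance); the census reports per-monomer
contact counts and their mean.

Orientation is described by two in-plane angles: each monomer's internal
axis is the membrane-plane projection of (reference bead − COM); `phi1`
is the signed angle at monomer A from its axis to the A→B COM vector,
`phi3` the same at B with the B→A vector, both in [−180, 180). The
convention is self-contained (the originating restraint scheme's exact
bead choices are not public) and is invariant under in-plane rigid
motion of the whole dimer. The weak harmonic restraint
`E = k/2 [(dphi1)² + (dphi3)²]` (differences wrapped across ±180) has
analytic per-bead forces validated against finite differences.

## Occupancy maps

Frames are rigidly superposed onto a reference via the anchor-protein
beads; selected species positions are binned into 0.1 nm voxels; counts
accumulate over frames, with out-of-grid molecules tallied in an
overflow counter rather than dropped. One grid per requested interfacial
separation is built from the frames of the matching umbrella window.
Counts (plus frame and molecule metadata) are stored rather than
normalized densities, so number density or occupancy probability can be
derived either way; grids export to OpenDX for molecular viewers.

## Synthetic-data generators and what they do not show

`generate_assembly_snapshot` places rigid bead-cloud monomers in the
membrane plane with prescribed aggregation topologies (isolated, chain,
grid, clustered) and seeded in-plane orientations — enough to exercise
harvesting, contact and clustering arithmetic exactly, but with none of
the conformational variety of real self-assembly trajectories: real
cluster populations, interface diversity, and bead-level packing are out
of reach, so passing census tests demonstrates the correctness of the
bookkeeping, not biological realism. `generate_lipid_frames` plants an
interfacial particle only at wide separations on top of a uniform
background — the appear/disappear-with-distance pattern in its cleanest
form. The Brownian engine has no explicit lipids, no membrane
embedding, and no force field; it emulates only the *kinetics* that make
dimer PMFs hard (a slow orthogonal coordinate coupled to the reaction
coordinate), which is exactly the regime the estimators must survive.

## Problem sizes

Defaults throughout — 21 windows, 2×10⁵ steps per window, exchange every
20 steps, 100 bootstrap replicates, 20 seeds for the calibration study,
32 runs for the binding census — complete in a few minutes on one CPU
core, with the integrator inner loop JIT-compiled. The same sizes are
used by the test suite and the acceptance script.
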