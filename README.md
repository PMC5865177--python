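# dimerpmf

Umbrella-exchange free-energy toolkit for membrane-protein dimerization,
with an exactly solvable toy engine for estimator validation.

## The problem

How strongly do two copies of a membrane protein — a neurotransmitter
transporter, say — bind each other, and through which interface? The
standard computational answer is a potential of mean force (PMF): the
free energy F(d) along the protein–protein separation d, obtained from
umbrella sampling (a ladder of harmonic windows
`B_i(d) = k/2 (d - d_i)^2` along d), unbiased and combined with WHAM,

    p_b = sum_i c_ib / sum_i N_i exp[(f_i - u_ib)/kT],
    exp(-f_i/kT) = sum_b p_b exp(-u_ib/kT),

with the well depth of F(d) ranking candidate interfaces. The catch is
convergence: lipids trapped between the approaching proteins are a slow
degree of freedom that umbrella windows cannot relax on their own, so
independent-window runs inherit their starting state for microseconds
(bound starts and unbound starts give different PMFs — hysteresis).
Window-exchange umbrella sampling (US-REMD) attacks this by letting
neighbouring windows swap configurations with Metropolis probability
`min(1, exp(-dU/kT))` every few tens of ps, shuttling configurations —
and their slow lipid states — across the ladder.

`dimerpmf` implements this whole workflow as a reusable library:

- **toy engine** (`landscape`, `dynamics`): an analytic two-coordinate
  "dimer association + lipid trapping" energy surface with a
  Brownian-dynamics integrator and an exact quadrature oracle for the
  marginal PMF — ground truth for every estimator here;
- **sampling** (`sampling`): umbrella ladders (0.1 nm spacing,
  overlap-rule force constants, optional low-exchange refinement),
  conventional US-MD, window-exchange US-REMD with full exchange logs and
  replica-walk diagnostics;
- **unbiasing** (`pmf`): WHAM, a binless multistate cross-check
  estimator, Jacobian corrections, time-windowed convergence profiles,
  half-window block-bootstrap error bars, well-depth/barrier extraction;
- **interface census** (`census`, `snapshots`): dimer harvesting at a
  5.3 nm center-of-mass cutoff, RMSD-based greedy (neighbour-count)
  clustering at 0.4 nm, contact statistics, virtual-bond orientation
  angles and their harmonic restraints;
- **occupancy maps** (`density`): 3D lipid density grids in the protein
  frame, conditioned on the interfacial separation;
- **I/O and workflow** (`io`, `pipeline`, `cli`): XVG-style series, TSV
  tables, OpenDX grids, a config-driven bit-reproducible pipeline, and a
  thin `dimerpmf` command-line tool.

## A worked example

`examples/03_hysteresis.py` reproduces the bound/unbound hysteresis of
conventional umbrella sampling and its repair by window exchange, all
against the exact profile (21 windows, 2e5 steps each, one CPU, ~20 s):

```
exact well depth: 11.8 kT
unbound-start US-MD    depth   7.5 kT | boundary distortion 1.46 kT | well+barrier RMS 1.43 kT
bound-start US-MD      depth  13.8 kT | boundary distortion 1.78 kT | well+barrier RMS 0.39 kT
bound-start US-REMD    depth  12.0 kT | boundary distortion 0.33 kT | well+barrier RMS 0.06 kT
```

Started unbound, the trapped interfacial lipid blocks association and
over 4 kT of well depth is missed; started bound, the profile is
distorted by ~1.8 kT across the bound/unbound boundary zone (the
"shoulder" of exchange-free umbrella runs); with exchanges the estimate
lands on the exact curve to 0.06 kT RMS. The other examples cover the
oracle itself, the full US-REMD + WHAM + bootstrap stack, the interface
census, and the distance-conditioned density maps — each prints the
numbers it computes and one line on what they mean.

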