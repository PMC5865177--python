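# File formats

All outputs are plain text; every writer adds `#` header lines carrying
provenance (bias parameters, config hash, master seed where available).

## Window series (`.xvg`)

Whitespace-separated columns; `#` comments and `@` legend lines ignored.

| column | meaning |
| --- | --- |
| 1 | time (ps), strictly increasing per window |
| 2 | separation d (nm), full double precision |
| 3 | lipid coordinate l (dimensionless) |
| 4 | window id (0-based) |
| 5 | replica id occupying this window at this sample |

Header keys: `bias_center_nm`, `bias_k_kjmol_nm2`.

## Umbrella ladder (`ladder.tsv`)

Two columns: `center_nm`, `k_kjmol_nm2`; header records `init_mode`.

## Exchange log (`exchange.tsv`)

Columns: `time_ps`, `i`, `j` (= i+1), `dU_kT`, `accepted` (0/1),
`uniform_draw`. Header: `tau_ex_ps`, `n_windows`, `pair_scheme`. The
reader re-checks every outcome against the recorded draw.

## PMF (`pmf.tsv`)

Columns: `d_nm`, `d_int_nm`, `F_kJmol`, `stderr_kJmol` (NaN when not
applicable). Header records the zero convention, kT, the estimator, the
convergence residual and, for bootstrap output, the replicate count and
resampling unit.

## Config (INI)

Flat key–value text with sections `[landscape]`, `[ladder]`,
`[sampler]`, `[analysis]`; see `examples/` and
`dimerpmf.pipeline.run_pipeline`. A run is reproducible from its config
plus master seed alone; `manifest.json` in a run directory stores the
config hash, seed, package version and completed stages.

## Coordinates

Snapshots read/write GRO or PDB (via MDAnalysis); one residue per
monomer carries the monomer partitioning. Density grids export to
OpenDX (`.dx`).

Conventions: nm and ps everywhere; indices 0-based internally, residue
ids 1-based in coordinate files.
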