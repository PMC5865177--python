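"""Bound/unbound-start hysteresis of conventional umbrella sampling.

At equal budget, independent-window umbrella runs inherit the memory of
their starting state: started unbound with a lipid at the interface,
they cannot reach the bound minimum and underestimate the well depth;
started bound, they develop a distortion (shoulder) across the
bound/unbound boundary zone.  Window exchange removes both artifacts.
"""

import numpy as np

from dimerpmf import (
    BrownianParams,
    ToyLandscape,
    build_ladder,
    make_histograms,
    marginal_pmf_oracle,
    residual_range_kt,
    rms_kt,
    run_us_md,
    run_us_remd,
    well_depth,
    wham_solve,
)

ls = ToyLandscape.default()
ladder = build_ladder(ls, d_range=(5.4, 7.4))
params = BrownianParams(n_steps=200_000, seed=1)
oracle = marginal_pmf_oracle(
    ls, np.arange(ls.d_range[0] + 0.01, ls.d_range[1], 0.02))
depth_true = well_depth(oracle).depth_kjmol


def unbias(series):
    return wham_solve(make_histograms(series, ladder.centers,
                                      ladder.ks_kjmol, ls.kT))


print(f"exact well depth: {depth_true / ls.kT:.1f} kT")
for label, series in (
    ("unbound-start US-MD",
     run_us_md(ls, ladder, params, init_mode="unbound")),
    ("bound-start US-MD",
     run_us_md(ls, ladder, params, init_mode="bound")),
    ("bound-start US-REMD",
     run_us_remd(ls, ladder, params, tau_ex=0.2, init_mode="bound")[0]),
):
    curve = unbias(series)
    depth = well_depth(curve).depth_kjmol / ls.kT
    dist = residual_range_kt(curve, oracle, (5.9, 6.6))
    rms = rms_kt(curve, oracle, (5.35, 6.2))
    print(f"{label:22s} depth {depth:5.1f} kT | boundary distortion "
          f"{dist:4.2f} kT | well+barrier RMS {rms:4.2f} kT")
print()
print("The unbound start misses several kT of well depth (the trapped")
print("lipid blocks association); the bound start is distorted across the")
print("boundary zone where the lipid coordinate stays frozen; exchanging")
print("configurations between windows recovers the exact profile.")
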