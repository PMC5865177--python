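"""Umbrella-exchange sampling + WHAM, with bootstrap error bars.

Runs a 21-window ladder (centers every 0.1 nm, overlap-rule force
constants) with configuration swaps attempted between neighbouring
windows every 20 integrator steps, unbiases the window histograms with
WHAM, and attaches half-window block-bootstrap errors.  Prints the
estimated well depth, the exchange acceptance, and the deviation from
the exact profile.
"""

import numpy as np

from dimerpmf import (
    BootstrapSpec,
    BrownianParams,
    ToyLandscape,
    bootstrap_pmf,
    build_ladder,
    exchange_rates,
    make_histograms,
    marginal_pmf_oracle,
    rms_kt,
    run_us_remd,
    well_depth,
    wham_solve,
)

ls = ToyLandscape.default()
ladder = build_ladder(ls, d_range=(5.4, 7.4), spacing=0.1)
params = BrownianParams(n_steps=200_000, seed=1)

print(f"{len(ladder)} windows, k = {ladder.ks_kjmol[0]:.0f} kJ/mol/nm^2, "
      f"predicted neighbour overlap {ladder.predicted_overlap(ls.kT)[0]:.2f}")
series, log = run_us_remd(ls, ladder, params, tau_ex=0.2, init_mode="bound")
rates = exchange_rates(log)
vals = [v for v in rates.per_pair.values() if v is not None]
print(f"exchange acceptance: overall {rates.overall:.2f}, "
      f"per-pair range [{min(vals):.2f}, {max(vals):.2f}]")

curve = wham_solve(make_histograms(series, ladder.centers, ladder.ks_kjmol,
                                   ls.kT))
boot = bootstrap_pmf(series, ladder.centers, ladder.ks_kjmol, ls.kT,
                     spec=BootstrapSpec(n_boot=100, seed=1))
wd = well_depth(curve)
i_min = np.nanargmin(boot.f_kjmol)
print(f"well depth: {wd.depth_kjmol:.1f} +/- "
      f"{boot.stderr_kjmol[i_min]:.1f} kJ/mol at d = {wd.d_min:.2f} nm")

oracle = marginal_pmf_oracle(ls, curve.d[curve.sampled()].clip(*ls.d_range))
print(f"RMS deviation from the exact profile over the well-and-barrier "
      f"region: {rms_kt(curve, oracle, (5.35, 6.2)):.3f} kT")
print()
print("An RMS well below the ~0.1-0.2 kT statistical floor of a single run")
print("means the exchange sampler has equilibrated the slow lipid")
print("coordinate across the ladder within the 2e5-step budget.")
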