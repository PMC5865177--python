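"""The analytic association landscape and its exact free-energy profile.

Builds the default two-coordinate landscape (protein-protein separation d
plus a slow interfacial-lipid coordinate), integrates the lipid
coordinate out by quadrature, and prints the exact potential of mean
force along d -- the ground truth every estimator in this package is
judged against.
"""

import numpy as np

from dimerpmf import ToyLandscape, marginal_pmf_oracle, well_depth

ls = ToyLandscape.default()
grid = np.arange(ls.d_range[0] + 0.01, ls.d_range[1], 0.02)
pmf = marginal_pmf_oracle(ls, grid)
wd = well_depth(pmf)

print(f"domain: d in [{ls.d_range[0]}, {ls.d_range[1]}] nm, kT = {ls.kT} kJ/mol")
print(f"bound minimum: {wd.d_min:.2f} nm, depth {wd.depth_kjmol:.1f} kJ/mol "
      f"({wd.depth_kjmol / ls.kT:.1f} kT)")
for b in wd.barriers:
    print(f"association barrier: {b.f_kjmol:.1f} kJ/mol at d = {b.d:.2f} nm "
          f"(d_int = {b.d_int:.2f} nm)")
print()
print("  d/nm   F/(kJ/mol)")
for d, f in zip(pmf.d[::10], pmf.f_kjmol[::10]):
    print(f"  {d:5.2f}  {f:8.2f}")
print()
print("The deep well at ~5.4 nm is the dimer; the profile climbs over the")
print("association barrier near 5.9 nm and flattens to the zero plateau at")
print("full separation, where the two proteins no longer interact.")
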