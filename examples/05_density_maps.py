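"""Distance-conditioned lipid occupancy maps around a protein pair.

Generates toy umbrella ensembles at a bound (d_int = 0) and a wide
(d_int = 1 nm) separation in which a lipid particle sits between the
proteins only when the gap is open, builds 3D occupancy grids in the
protein-fixed frame, and shows the interfacial density appearing with
distance -- the signature by which interface-bound lipids are identified.
"""

import numpy as np

from dimerpmf import density_by_distance, generate_lipid_frames

separations = {0: 5.4, 1: 6.4}            # window -> COM separation (nm)
d_int = {0: 0.0, 1: 1.0}                  # window -> interfacial separation
frames, reference = generate_lipid_frames(separations, n_frames=50, seed=2)

grids = density_by_distance(
    frames, d_int, [0.0, 1.0], reference=reference,
    origin=np.zeros(3), shape=(120, 120, 120), voxel=0.1,
)

box = 12.0
for grid, (w, sep) in zip(grids, separations.items()):
    mid = np.array([box / 2 + sep / 2, box / 2, box / 2])
    ijk = np.floor((mid - grid.origin) / grid.voxel).astype(int)
    occ = grid.counts[ijk[0] - 1:ijk[0] + 2, ijk[1] - 1:ijk[1] + 2,
                      ijk[2] - 1:ijk[2] + 2].sum() / grid.n_frames
    print(f"d_int = {grid.conditioning:.2f} nm: {grid.total} positions "
          f"binned over {grid.n_frames} frames "
          f"(overflow {grid.overflow}); midpoint occupancy {occ:.2f}")
    # grid.write_dx(f"density_dint_{grid.conditioning:.2f}.dx") for VMD/PyMOL

print()
print("At the wide separation the inter-protein midpoint voxels hold ~1")
print("molecule per frame (the wedged lipid); at contact the same voxels")
print("show only background -- the lipid is expelled when the interface")
print("closes, which is how interface-mediating lipids are spotted.")
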