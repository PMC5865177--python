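"""Interface census: contacts, dimer harvesting, GROMOS clustering, angles.

Generates a 16-copy membrane-plane snapshot with a clustered aggregation
topology, counts monomer-monomer contacts, harvests all dimer pairs
below the 5.3 nm center-of-mass cutoff, clusters them with the greedy
neighbour-count rule at 0.4 nm, and reports the virtual-bond orientation
angles of the top cluster's centroid.
"""

import numpy as np

from dimerpmf import (
    contact_census,
    generate_assembly_snapshot,
    gromos_cluster,
    harvest_dimers,
    vba_angles,
)

snap = generate_assembly_snapshot(16, topology="clustered", box=40.0, seed=3)
cc = contact_census(snap)
print(f"16 monomers, clustered: mean contacts per monomer {cc.mean:.2f} "
      f"(counts {np.bincount(cc.counts).tolist()} by degree)")

dimers = harvest_dimers(snap, com_cutoff=5.3)
print(f"harvested {len(dimers)} dimer conformations below 5.3 nm COM "
      f"separation")

result = gromos_cluster(dimers, cutoff=0.4, symmetry=True)
print(f"{result.n_clusters} clusters at 0.4 nm similarity cutoff; "
      f"populations: {[round(float(p), 2) for p in result.populations[:5]]} ...")

centroid = dimers[result.centroid_indices[0]]
ang = vba_angles(centroid, reference_beads=(0, 0))
print(f"top-cluster centroid: COM separation {centroid.com_separation:.2f} "
      f"nm, orientation phi1 = {ang.phi1:.1f} deg, phi3 = {ang.phi3:.1f} deg")
print()
print("In a tight aggregate each monomer touches on the order of 2-4")
print("neighbours; the clustering groups the harvested pairs by interface")
print("geometry and the two angles pin down the relative orientation that")
print("an umbrella run would restrain to probe one interface at a time.")
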