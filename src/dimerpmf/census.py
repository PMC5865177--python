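"""Dimer harvesting, GROMOS clustering, contacts and orientation angles.

The census pipeline mirrors how self-assembly trajectories are mined for
dimer interfaces: every monomer pair closer than a center-of-mass cutoff
(default 5.3 nm, minimum image) is collected as a two-monomer
conformation; pairwise dissimilarity is the mass-unweighted RMSD after
least-squares superposition of the whole dimer (optionally minimised
over the A/B label swap for homodimers); conformations are grouped with
the greedy neighbour-count (GROMOS) algorithm at a 0.4 nm cutoff.
Contact statistics (mean number of touching neighbours per monomer) and
the two virtual-bond orientation angles phi1/phi3, with their weak
harmonic restraints, complete the census.

Angle convention (the defining supplementary material of the original
restraint scheme is not public, so the convention here is self-contained
and documented): each monomer's internal axis is the membrane-plane
projection of (reference bead - COM); phi1 is the signed in-plane angle
at monomer A from its axis to the A->B COM vector, phi3 the same at
monomer B with the B->A vector.  Both lie in [-180, 180) degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GeometryError, MetricError
from .snapshots import AssemblySnapshot

COM_HARVEST_CUTOFF = 5.3   # nm
GROMOS_CUTOFF = 0.4        # nm
CONTACT_CUTOFF = 0.6       # nm between any inter-monomer beads


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class DimerConformation:
    """Two monomer bead sets (nm), already shifted to the same image."""

    coords_a: np.ndarray
    coords_b: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.coords_a = np.asarray(self.coords_a, float)
        self.coords_b = np.asarray(self.coords_b, float)

    @property
    def com_separation(self) -> float:
        return float(np.linalg.norm(
            self.coords_b.mean(axis=0) - self.coords_a.mean(axis=0)
        ))

    def all_beads(self) -> np.ndarray:
        return np.vstack([self.coords_a, self.coords_b])

    def swapped(self) -> "DimerConformation":
        return DimerConformation(self.coords_b, self.coords_a, self.source_id)


@dataclass
class ClusterResult:
    membership: np.ndarray          # conformation -> cluster id (0 = largest)
    centroid_indices: tuple         # conformation index of each centroid
    populations: np.ndarray         # fraction per cluster, decreasing
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.centroid_indices)


@dataclass(frozen=True)
class OrientationAngles:
    phi1: float   # degrees in [-180, 180)
    phi3: float


@dataclass(frozen=True)
class ContactCensus:
    counts: np.ndarray       # contacts per monomer
    mean: float
    pairs: tuple             # contacting (i, j) pairs, i < j


# ---------------------------------------------------------------------------
# harvesting
# ---------------------------------------------------------------------------
def _min_image(vec: np.ndarray, box: np.ndarray) -> np.ndarray:
    return vec - box * np.round(vec / box)


def harvest_dimers(
    snapshots: AssemblySnapshot | Sequence[AssemblySnapshot],
    com_cutoff: float = COM_HARVEST_CUTOFF,
) -> list[DimerConformation]:
    """All monomer pairs with minimum-image COM separation < cutoff.

    Each pair appears once; monomer B is shifted to the periodic image
    closest to A so downstream geometry is image-free.
    """
    if isinstance(snapshots, AssemblySnapshot):
        snapshots = [snapshots]
    out: list[DimerConformation] = []
    for s_idx, snap in enumerate(snapshots):
        coms = snap.coms()
        n = snap.n_monomers
        for i in range(n):
            for j in range(i + 1, n):
                raw = coms[j] - coms[i]
                wrapped = _min_image(raw, snap.box)
                if np.linalg.norm(wrapped) < com_cutoff:
                    shift = wrapped - raw
                    out.append(DimerConformation(
                        coords_a=snap.monomer(i).copy(),
                        coords_b=snap.monomer(j) + shift,
                        source_id=f"snap{s_idx}:{i}-{j}",
                    ))
    return out


# ---------------------------------------------------------------------------
# RMSD and clustering
# ---------------------------------------------------------------------------
def dimer_rmsd(a: DimerConformation, b: DimerConformation,
               symmetry: bool = False) -> float:
    """Least-squares superposition RMSD over all dimer beads (nm).

    With ``symmetry`` the A/B monomer labels of ``b`` may be swapped and
    the smaller RMSD is returned (homodimer interfaces are unordered).
    """
    pa = a.all_beads()
    pb = b.all_beads()
    if pa.shape != pb.shape or a.coords_a.shape != b.coords_a.shape:
        raise MetricError(
            f"bead-count mismatch: {pa.shape} vs {pb.shape}"
        )
    r = _fit_rmsd(pa, pb)
    if symmetry:
        r = min(r, _fit_rmsd(pa, b.swapped().all_beads()))
    return r


def _fit_rmsd(pa: np.ndarray, pb: np.ndarray) -> float:
    pa_c = pa - pa.mean(axis=0)
    pb_c = pb - pb.mean(axis=0)
    rot, _ = Rotation.align_vectors(pa_c, pb_c)
    # explicit residual: the rssd shortcut loses precision to cancellation
    diff = pa_c - rot.apply(pb_c)
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def pairwise_rmsd(conformations: Sequence[DimerConformation],
                  symmetry: bool = True) -> np.ndarray:
    n = len(conformations)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = dimer_rmsd(
                conformations[i], conformations[j], symmetry=symmetry
            )
    return m


def gromos_cluster(
    conformations: Sequence[DimerConformation],
    cutoff: float = GROMOS_CUTOFF,
    symmetry: bool = True,
    rmsd_matrix: Optional[np.ndarray] = None,
) -> ClusterResult:
    """Greedy neighbour-count clustering.

    Iteratively, the conformation with the most neighbours within
    ``cutoff`` becomes a centroid; it and its neighbours form a cluster
    and are removed.  Ties break to the lowest conformation index, which
    makes the procedure deterministic.  Clusters are numbered by
    decreasing population.
    """
    n = len(conformations)
    if n == 0:
        raise MetricError("no conformations to cluster")
    m = pairwise_rmsd(conformations, symmetry) if rmsd_matrix is None else rmsd_matrix
    neighbor = m < cutoff
    np.fill_diagonal(neighbor, True)
    alive = np.ones(n, bool)
    membership = np.full(n, -1)
    clusters: list[tuple[int, np.ndarray]] = []
    while alive.any():
        counts = (neighbor & alive[None, :]).sum(axis=1)
        counts[~alive] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbor[center] & alive)
        clusters.append((center, members))
        alive[members] = False
    clusters.sort(key=lambda c: (-len(c[1]), c[0]))
    pops = np.array([len(mem) for _, mem in clusters], float) / n
    for cid, (_, mem) in enumerate(clusters):
        membership[mem] = cid
    return ClusterResult(
        membership=membership,
        centroid_indices=tuple(c for c, _ in clusters),
        populations=pops,
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------
def contact_census(snapshot: AssemblySnapshot,
                   bead_cutoff: float = CONTACT_CUTOFF) -> ContactCensus:
    """Contacts per monomer: any inter-monomer bead pair < cutoff (min image)."""
    n = snapshot.n_monomers
    counts = np.zeros(n, int)
    pairs = []
    monomers = [snapshot.monomer(i) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            diff = monomers[i][:, None, :] - monomers[j][None, :, :]
            diff = _min_image(diff, snapshot.box)
            if (np.einsum("ijk,ijk->ij", diff, diff).min()
                    < bead_cutoff * bead_cutoff):
                counts[i] += 1
                counts[j] += 1
                pairs.append((i, j))
    return ContactCensus(counts=counts, mean=float(counts.mean()),
                         pairs=tuple(pairs))


# ---------------------------------------------------------------------------
# orientation angles and restraints
# ---------------------------------------------------------------------------
def wrap_angle(a) -> np.ndarray:
    """Wrap degrees to [-180, 180)."""
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


def _plane_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Signed in-plane (xy) angle from u to v, degrees."""
    ux, uy = u[0], u[1]
    vx, vy = v[0], v[1]
    if ux * ux + uy * uy < 1e-20 or vx * vx + vy * vy < 1e-20:
        raise GeometryError("degenerate (zero-length) in-plane vector")
    ang = np.degrees(np.arctan2(ux * vy - uy * vx, ux * vx + uy * vy))
    return float(wrap_angle(ang))


def vba_angles(dimer: DimerConformation,
               reference_beads: tuple[int, int] = (0, 0)) -> OrientationAngles:
    """Virtual-bond orientation angles (phi1, phi3) in degrees.

    ``reference_beads`` are per-monomer bead indices defining the internal
    axes (COM -> reference bead, projected into the membrane plane).
    """
    ra, rb = reference_beads
    com_a = dimer.coords_a.mean(axis=0)
    com_b = dimer.coords_b.mean(axis=0)
    axis_a = dimer.coords_a[ra] - com_a
    axis_b = dimer.coords_b[rb] - com_b
    phi1 = _plane_angle(axis_a, com_b - com_a)
    phi3 = _plane_angle(axis_b, com_a - com_b)
    return OrientationAngles(phi1=phi1, phi3=phi3)


def _perp(w: np.ndarray) -> np.ndarray:
    return np.array([-w[1], w[0]])


def _angle_gradients(dimer: DimerConformation, ref: int, which: str):
    """d(phi)/d(bead xy-coordinates) in degrees/nm for phi1 or phi3.

    Returns (grad_a, grad_b): arrays (n_beads, 3); z components are zero
    because the angles live in the membrane plane.
    """
    na, nb = len(dimer.coords_a), len(dimer.coords_b)
    com_a = dimer.coords_a.mean(axis=0)
    com_b = dimer.coords_b.mean(axis=0)
    if which == "phi1":
        u = (dimer.coords_a[ref] - com_a)[:2]
        v = (com_b - com_a)[:2]
    else:
        u = (dimer.coords_b[ref] - com_b)[:2]
        v = (com_a - com_b)[:2]
    if np.dot(u, u) < 1e-20 or np.dot(v, v) < 1e-20:
        raise GeometryError("degenerate reference axis")
    du = -_perp(u) / np.dot(u, u)     # d phi / d u (radians)
    dv = _perp(v) / np.dot(v, v)      # d phi / d v
    ga = np.zeros((na, 3))
    gb = np.zeros((nb, 3))
    if which == "phi1":
        # u depends on A beads (ref bead + COM); v on both COMs
        ga[:, :2] += -du / na                 # -dCOM_A contribution to u
        ga[ref, :2] += du
        ga[:, :2] += -dv / na                 # v = COM_B - COM_A
        gb[:, :2] += dv / nb
    else:
        gb[:, :2] += -du / nb
        gb[ref, :2] += du
        gb[:, :2] += -dv / nb                 # v = COM_A - COM_B
        ga[:, :2] += dv / na
    deg = 180.0 / np.pi
    return ga * deg, gb * deg


def orientation_restraint(
    dimer: DimerConformation,
    targets: tuple[float, float],
    k_ang: float,
    reference_beads: tuple[int, int] = (0, 0),
):
    """Weak harmonic restraint pinning the dimer orientation.

    E = 1/2 k [(dphi1)^2 + (dphi3)^2] with angle differences wrapped to
    (-180, 180]; ``k_ang`` in kJ/mol/deg^2.  Returns
    (energy kJ/mol, forces_a (n,3), forces_b (n,3)) with analytic forces
    -dE/dx by the chain rule.
    """
    if k_ang < 0:
        raise ValueError("k_ang must be non-negative")
    ang = vba_angles(dimer, reference_beads)
    d1 = float(wrap_angle(ang.phi1 - targets[0]))
    d3 = float(wrap_angle(ang.phi3 - targets[1]))
    energy = 0.5 * k_ang * (d1 * d1 + d3 * d3)
    g1a, g1b = _angle_gradients(dimer, reference_beads[0], "phi1")
    g3a, g3b = _angle_gradients(dimer, reference_beads[1], "phi3")
    forces_a = -k_ang * (d1 * g1a + d3 * g3a)
    forces_b = -k_ang * (d1 * g1b + d3 * g3b)
    return energy, forces_a, forces_b
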