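"""Multi-copy membrane-plane snapshots for the interface census.

A snapshot is a set of coarse-grained monomers (rigid bead clouds) placed
in the membrane plane of a periodic box, mimicking self-assembly frames
of a multi-copy transporter system.  Aggregation topologies:

``isolated``
    monomers farther apart than any contact or harvesting cutoff;
``chain``
    a linear string with adjacent centers ``contact_spacing`` apart --
    adjacent pairs touch, second neighbours exceed the 5.3 nm
    center-of-mass harvest cutoff by construction;
``grid``
    a square lattice at contact spacing (the initial condition of the
    multi-copy self-assembly setup);
``clustered``
    one hexagonally packed aggregate.

Files are written/read as GRO or PDB through MDAnalysis; each monomer is
one residue, which is how the monomer partitioning survives a round
trip.  Coordinates are in nm internally (MDAnalysis converts to/from A).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, PackingError

DEFAULT_CONTACT_SPACING = 2.8   # nm between adjacent monomer centers
DEFAULT_ISOLATED_SPACING = 6.0  # nm; beyond contact and COM-harvest cutoffs
MONOMER_RING_RADIUS = 1.2       # nm; outer bead ring of the template


@dataclass
class AssemblySnapshot:
    """Bead coordinates of a multi-monomer snapshot with periodic box."""

    positions: np.ndarray      # (N, 3) nm
    monomer_index: np.ndarray  # (N,) int, 0-based
    box: np.ndarray            # (3,) nm, orthorhombic

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.monomer_index = np.asarray(self.monomer_index, int)
        self.box = np.asarray(self.box, float)
        if self.positions.shape[0] != self.monomer_index.shape[0]:
            raise ValueError("positions and monomer_index lengths differ")

    @property
    def n_monomers(self) -> int:
        return int(self.monomer_index.max()) + 1 if self.monomer_index.size else 0

    def monomer(self, i: int) -> np.ndarray:
        return self.positions[self.monomer_index == i]

    def coms(self) -> np.ndarray:
        return np.stack([self.monomer(i).mean(axis=0) for i in range(self.n_monomers)])

    # -- file I/O ---------------------------------------------------------
    def write(self, path) -> None:
        """Write as GRO or PDB (by suffix); one residue per monomer."""
        import MDAnalysis as mda

        n = self.positions.shape[0]
        resindex = self.monomer_index
        u = mda.Universe.empty(
            n_atoms=n, n_residues=self.n_monomers, n_segments=1,
            atom_resindex=resindex,
            residue_segindex=np.zeros(self.n_monomers, int),
            trajectory=True,
        )
        u.add_TopologyAttr("names", ["BB"] * n)
        u.add_TopologyAttr("resnames", ["MON"] * self.n_monomers)
        u.add_TopologyAttr("resids", np.arange(1, self.n_monomers + 1))
        u.atoms.positions = self.positions * 10.0  # nm -> A
        u.dimensions = [*(self.box * 10.0), 90.0, 90.0, 90.0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.atoms.write(str(path))

    @classmethod
    def read(cls, path) -> "AssemblySnapshot":
        """Read GRO/PDB; monomers identified by residue."""
        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
        resindices = u.atoms.resindices
        if u.dimensions is None or not np.all(u.dimensions[:3] > 0):
            raise ConfigError(f"{path}: no box information")
        return cls(
            positions=u.atoms.positions / 10.0,
            monomer_index=resindices - resindices.min(),
            box=np.asarray(u.dimensions[:3], float) / 10.0,
        )


def monomer_template(beads_per_monomer: int = 16,
                     radius: float = MONOMER_RING_RADIUS) -> np.ndarray:
    """Rigid bead cloud of one monomer, COM at the origin.

    Bead 0 sits on the outer ring at angle 0 and serves as the default
    orientation-reference bead.  The outer ring carries alternating z
    offsets so the cloud is not exactly planar.
    """
    if beads_per_monomer < 4:
        raise ConfigError("need at least 4 beads per monomer")
    n_outer = max(beads_per_monomer * 3 // 4, 3)
    n_inner = beads_per_monomer - n_outer
    ang = 2 * np.pi * np.arange(n_outer) / n_outer
    outer = np.stack(
        [radius * np.cos(ang), radius * np.sin(ang),
         0.05 * (-1.0) ** np.arange(n_outer)], axis=1
    )
    if n_inner:
        ang_i = 2 * np.pi * np.arange(n_inner) / n_inner + 0.3
        inner = np.stack(
            [0.45 * radius * np.cos(ang_i), 0.45 * radius * np.sin(ang_i),
             np.zeros(n_inner)], axis=1
        )
        beads = np.vstack([outer, inner])
    else:
        beads = outer
    return beads - beads.mean(axis=0)


def _rot_z(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _com_layout(topology: str, n: int, spacing: float,
                rng: np.random.Generator) -> np.ndarray:
    if topology == "isolated":
        side = int(np.ceil(np.sqrt(n)))
        pts = [(i % side, i // side) for i in range(n)]
        return np.array([[x * DEFAULT_ISOLATED_SPACING,
                          y * DEFAULT_ISOLATED_SPACING] for x, y in pts])
    if topology == "chain":
        return np.array([[i * spacing, 0.0] for i in range(n)])
    if topology == "grid":
        side = int(np.ceil(np.sqrt(n)))
        return np.array([[(i % side) * spacing, (i // side) * spacing]
                         for i in range(n)])
    if topology == "clustered":
        # hexagonal packing spiralling out from the center
        pts = [(0.0, 0.0)]
        shell = 1
        while len(pts) < n:
            for k in range(6 * shell):
                a = 2 * np.pi * k / (6 * shell)
                pts.append((shell * spacing * np.cos(a),
                            shell * spacing * np.sin(a)))
                if len(pts) >= n:
                    break
            shell += 1
        return np.array(pts[:n])
    raise ConfigError(f"unknown topology {topology!r}")


def generate_assembly_snapshot(
    n_monomers: int,
    beads_per_monomer: int = 16,
    box: float | tuple[float, float, float] = 40.0,
    topology: str = "isolated",
    seed: int = 0,
    contact_spacing: float = DEFAULT_CONTACT_SPACING,
) -> AssemblySnapshot:
    """Seeded multi-copy snapshot with a prescribed aggregation topology.

    Monomers are copies of :func:`monomer_template` with seeded in-plane
    rotations, centered in the box.  Raises :class:`PackingError` when
    the requested layout does not fit the box with a margin.
    """
    if n_monomers < 1:
        raise ConfigError("n_monomers must be >= 1")
    box = np.array([box] * 3, float) if np.isscalar(box) else np.asarray(box, float)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5A9]))
    layout = _com_layout(topology, n_monomers, contact_spacing, rng)
    layout = layout - layout.mean(axis=0)
    margin = MONOMER_RING_RADIUS + 0.2
    extent = layout.max(axis=0) - layout.min(axis=0) + 2 * margin
    if extent[0] > box[0] or extent[1] > box[1]:
        raise PackingError(
            f"{topology} layout of {n_monomers} monomers needs "
            f"{extent[0]:.1f} x {extent[1]:.1f} nm; box is {box[0]} x {box[1]} nm"
        )
    template = monomer_template(beads_per_monomer)
    pos, idx = [], []
    for i, (x, y) in enumerate(layout):
        theta = rng.uniform(0, 2 * np.pi)
        beads = template @ _rot_z(theta).T
        beads = beads + np.array([x + box[0] / 2, y + box[1] / 2, box[2] / 2])
        pos.append(beads)
        idx.append(np.full(len(beads), i))
    return AssemblySnapshot(
        positions=np.vstack(pos),
        monomer_index=np.concatenate(idx),
        box=box,
    )


def generate_lipid_frames(
    separations: dict[int, float],
    n_frames: int = 20,
    n_background: int = 30,
    plant_above: float = 5.9,
    box: float = 12.0,
    beads_per_monomer: int = 16,
    seed: int = 0,
):
    """Toy umbrella ensembles with lipids around a two-monomer system.

    For each umbrella window (``separations`` maps window id -> COM
    separation d, nm) generates ``n_frames`` frames: monomer A centered,
    monomer B displaced by d along x, background "lipid" particles
    uniform in the box, and one particle planted at the inter-protein
    midpoint whenever d exceeds ``plant_above`` -- lipids sit between
    the proteins at wide separations and are expelled at contact, the
    appear/disappear-with-distance occupancy pattern.

    Returns (frames_by_window, reference_coords): frames are
    :class:`dimerpmf.density.Frame` objects whose reference selection is
    monomer A's beads; each frame carries a random rigid in-plane motion
    of the whole system so the reference fit is actually exercised.
    """
    from .density import Frame

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x11D]))
    template = monomer_template(beads_per_monomer)
    reference = template + np.array([box / 2, box / 2, box / 2])
    frames_by_window: dict[int, list] = {}
    for w, d in separations.items():
        frames = []
        for _ in range(n_frames):
            a = template + np.array([box / 2, box / 2, box / 2])
            lipids = rng.uniform(0, box, size=(n_background, 3))
            lipids[:, 2] = box / 2 + rng.normal(0, 0.1, n_background)
            if d > plant_above:
                mid = np.array([box / 2 + d / 2, box / 2, box / 2])
                lipids = np.vstack([lipids, mid + rng.normal(0, 0.05, 3)])
            # random rigid motion of everything (fit must undo it)
            theta = rng.uniform(0, 2 * np.pi)
            shift = rng.uniform(-1, 1, 3)
            R = _rot_z(theta)
            a_m = a @ R.T + shift
            lip_m = lipids @ R.T + shift
            frames.append(Frame(species=lip_m, reference=a_m, window_id=w))
        frames_by_window[w] = frames
    return frames_by_window, reference
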