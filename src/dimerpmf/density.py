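"""Distance-conditioned 3D occupancy maps in a protein-fixed frame.

Each frame carries the positions of a selected species (e.g. a lipid
type) plus reference coordinates of the anchor protein.  Frames are
rigidly superposed onto a common reference (least-squares fit of the
anchor selection), the species positions are binned into voxels, and
counts accumulate over frames -- occupancy maps like the lipid-density
analysis of umbrella ensembles, one grid per interfacial separation.

Counts, not normalized densities, are stored (with n_frames and the
per-frame molecule count in the metadata) so either a number density or
an occupancy probability can be derived afterwards.  Molecules falling
outside the grid are tallied in ``overflow``, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import EmptySelectionError, LookupError_

DEFAULT_VOXEL = 0.1  # nm


@dataclass
class Frame:
    """One trajectory frame: species positions + anchor reference beads."""

    species: np.ndarray     # (M, 3) nm
    reference: np.ndarray   # (R, 3) nm
    window_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.species = np.asarray(self.species, float).reshape(-1, 3)
        self.reference = np.asarray(self.reference, float).reshape(-1, 3)


@dataclass
class DensityGrid:
    """Voxelized occupancy counts in the reference frame."""

    origin: np.ndarray       # (3,) nm, corner of voxel (0,0,0)
    voxel: float             # nm
    counts: np.ndarray       # (nx, ny, nz)
    n_frames: int
    overflow: int = 0
    conditioning: Optional[float] = None   # d_int or window label
    reference_fit: str = "anchor-bead least-squares superposition"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float)
        self.counts = np.asarray(self.counts)
        if self.voxel <= 0:
            raise ValueError("voxel size must be positive")
        if np.any(self.counts < 0):
            raise ValueError("negative voxel counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "DensityGrid") -> "DensityGrid":
        if (self.voxel != other.voxel
                or not np.allclose(self.origin, other.origin)
                or self.counts.shape != other.counts.shape):
            raise ValueError("grids are not commensurate")
        return DensityGrid(
            origin=self.origin, voxel=self.voxel,
            counts=self.counts + other.counts,
            n_frames=self.n_frames + other.n_frames,
            overflow=self.overflow + other.overflow,
            conditioning=self.conditioning,
            reference_fit=self.reference_fit,
        )

    def max_voxel_position(self) -> np.ndarray:
        """Center of the highest-count voxel (nm)."""
        idx = np.unravel_index(int(np.argmax(self.counts)), self.counts.shape)
        return self.origin + (np.array(idx) + 0.5) * self.voxel

    def write_dx(self, path) -> None:
        """OpenDX scalar grid export."""
        from gridData import Grid

        edges = [
            self.origin[i] + self.voxel * np.arange(self.counts.shape[i] + 1)
            for i in range(3)
        ]
        Grid(self.counts.astype(float), edges=edges).export(str(path), "dx")


def _rigid_fit(mobile: np.ndarray, target: np.ndarray):
    """Rotation + translation superposing ``mobile`` onto ``target``."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    return rot, mc, tc


def accumulate_density(
    frames: Sequence[Frame],
    reference: np.ndarray,
    origin: np.ndarray,
    shape: tuple[int, int, int],
    voxel: float = DEFAULT_VOXEL,
    conditioning: Optional[float] = None,
) -> DensityGrid:
    """Superpose every frame onto ``reference`` and bin species into voxels.

    Raises :class:`EmptySelectionError` if no frame carries any species
    position (an empty selection is an input mistake, not a zero map).
    """
    reference = np.asarray(reference, float)
    origin = np.asarray(origin, float)
    counts = np.zeros(shape, int)
    overflow = 0
    if not frames or all(f.species.shape[0] == 0 for f in frames):
        raise EmptySelectionError("species selection matched no positions")
    for f in frames:
        rot, mc, tc = _rigid_fit(f.reference, reference)
        pos = rot.apply(f.species - mc) + tc
        ijk = np.floor((pos - origin) / voxel).astype(int)
        ok = np.all((ijk >= 0) & (ijk < np.array(shape)), axis=1)
        overflow += int((~ok).sum())
        np.add.at(counts, tuple(ijk[ok].T), 1)
    return DensityGrid(
        origin=origin, voxel=voxel, counts=counts,
        n_frames=len(frames), overflow=overflow, conditioning=conditioning,
    )


def density_by_distance(
    frames_by_window: dict[int, Sequence[Frame]],
    window_d_int: dict[int, float],
    d_int_targets: Sequence[float],
    reference: np.ndarray,
    origin: np.ndarray,
    shape: tuple[int, int, int],
    voxel: float = DEFAULT_VOXEL,
    tol: float = 1e-6,
) -> list[DensityGrid]:
    """One occupancy grid per requested interfacial separation.

    Each target d_int is matched (within ``tol``) to the umbrella window
    whose reference distance maps to it; a target without a matching
    window raises :class:`LookupError_` listing the available values.
    """
    grids = []
    for target in d_int_targets:
        match = [w for w, v in window_d_int.items() if abs(v - target) <= tol]
        if not match or match[0] not in frames_by_window:
            avail = sorted(round(v, 6) for v in window_d_int.values()
                           if window_d_int and v is not None)
            raise LookupError_(
                f"no umbrella window at d_int={target}; available: {avail}"
            )
        w = match[0]
        grids.append(accumulate_density(
            frames_by_window[w], reference, origin, shape, voxel,
            conditioning=window_d_int[w],
        ))
    return grids
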