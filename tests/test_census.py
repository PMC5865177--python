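"""Dimer harvesting, RMSD metric, GROMOS clustering, contacts, angles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from dimerpmf import (
    AssemblySnapshot,
    DimerConformation,
    contact_census,
    dimer_rmsd,
    generate_assembly_snapshot,
    gromos_cluster,
    harvest_dimers,
    monomer_template,
    orientation_restraint,
    vba_angles,
)
from dimerpmf.census import wrap_angle
from dimerpmf.errors import GeometryError, MetricError, PackingError


def _pair_snapshot(sep, box=40.0):
    t = monomer_template(12)
    a = t + np.array([box / 2 - sep / 2, box / 2, box / 2])
    b = t + np.array([box / 2 + sep / 2, box / 2, box / 2])
    return AssemblySnapshot(
        positions=np.vstack([a, b]),
        monomer_index=np.repeat([0, 1], len(t)),
        box=np.array([box] * 3),
    )


def _ring_snapshot(n, spacing=2.6, box=60.0):
    r = spacing / (2 * np.sin(np.pi / n))
    t = monomer_template(12)
    pos, idx = [], []
    for i in range(n):
        a = 2 * np.pi * i / n
        c = np.array([box / 2 + r * np.cos(a), box / 2 + r * np.sin(a),
                      box / 2])
        pos.append(t + c)
        idx.append(np.full(len(t), i))
    return AssemblySnapshot(np.vstack(pos), np.concatenate(idx),
                            np.array([box] * 3))


def _random_dimer(rng, n_beads=8, spread=1.0):
    a = rng.normal(0, spread, (n_beads, 3))
    b = rng.normal(0, spread, (n_beads, 3)) + np.array([3.0, 0, 0])
    return DimerConformation(a, b)


# ---------------------------------------------------------------------------
# harvesting and contacts
# ---------------------------------------------------------------------------
def test_com_cutoff_boundary():
    assert len(harvest_dimers(_pair_snapshot(5.2))) == 1
    assert len(harvest_dimers(_pair_snapshot(5.4))) == 0


def test_single_monomer_harvests_nothing():
    snap = generate_assembly_snapshot(1, topology="isolated", box=20.0)
    assert harvest_dimers(snap) == []


def test_chain_of_three_harvests_adjacent_pairs_only():
    snap = generate_assembly_snapshot(3, topology="chain", box=40.0, seed=1)
    dimers = harvest_dimers(snap)
    assert sorted(d.source_id for d in dimers) == ["snap0:0-1", "snap0:1-2"]


def test_minimum_image_harvest_across_boundary():
    box = 12.0
    t = monomer_template(12)
    a = t + np.array([0.5, box / 2, box / 2])
    b = t + np.array([box - 0.5, box / 2, box / 2])  # 1 nm via the image
    snap = AssemblySnapshot(np.vstack([a, b]), np.repeat([0, 1], len(t)),
                            np.array([box] * 3))
    dimers = harvest_dimers(snap)
    assert len(dimers) == 1
    assert dimers[0].com_separation == pytest.approx(1.0, abs=1e-9)


def test_contact_census_topologies():
    iso = generate_assembly_snapshot(5, topology="isolated", box=40.0)
    assert contact_census(iso).mean == 0.0
    chain = generate_assembly_snapshot(3, topology="chain", box=40.0, seed=2)
    cc = contact_census(chain)
    assert sorted(cc.counts.tolist()) == [1, 1, 2]
    assert cc.mean == pytest.approx(4 / 3)
    # contact-graph identity: mean degree = 2 E / N
    assert cc.mean == pytest.approx(2 * len(cc.pairs) / 3)


@pytest.mark.parametrize("n", [4, 6, 8])
def test_ring_has_exactly_two_contacts_each(n):
    cc = contact_census(_ring_snapshot(n))
    assert np.all(cc.counts == 2)
    assert cc.mean == 2.0


def test_packing_error_when_box_too_small():
    with pytest.raises(PackingError):
        generate_assembly_snapshot(16, topology="isolated", box=10.0)


def test_clustered_snapshot_is_seed_deterministic():
    a = generate_assembly_snapshot(16, topology="clustered", box=40.0, seed=5)
    b = generate_assembly_snapshot(16, topology="clustered", box=40.0, seed=5)
    np.testing.assert_array_equal(a.positions, b.positions)


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------
def test_rmsd_identity_and_rigid_invariance():
    rng = np.random.default_rng(0)
    a = _random_dimer(rng)
    assert dimer_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)
    rot = Rotation.random(random_state=3)
    moved = DimerConformation(rot.apply(a.coords_a) + 5.0,
                              rot.apply(a.coords_b) + 5.0)
    assert dimer_rmsd(a, moved) < 1e-9


def test_rmsd_against_quaternion_oracle():
    """MDAnalysis' quaternion (QCP) superposition as independent oracle."""
    from MDAnalysis.analysis.rms import rmsd as mda_rmsd

    rng = np.random.default_rng(1)
    for _ in range(10):
        a = _random_dimer(rng)
        b = _random_dimer(rng)
        ours = dimer_rmsd(a, b)
        ref = mda_rmsd(b.all_beads(), a.all_beads(), center=True,
                       superposition=True)
        assert ours == pytest.approx(ref, abs=1e-9)


def test_rmsd_single_displaced_bead():
    """4-bead monomers, one bead displaced by delta; vs quaternion oracle."""
    from MDAnalysis.analysis.rms import rmsd as mda_rmsd

    t = monomer_template(4)
    a = DimerConformation(t, t + np.array([3.0, 0, 0]))
    delta = 0.2
    cb = a.coords_b.copy()
    cb[1, 2] += delta
    b = DimerConformation(a.coords_a, cb)
    got = dimer_rmsd(a, b)
    ref = mda_rmsd(b.all_beads(), a.all_beads(), center=True,
                   superposition=True)
    assert got == pytest.approx(ref, abs=1e-9)
    # the fit cannot be worse than no fit at all
    assert got <= delta / np.sqrt(8) + 1e-12


def test_rmsd_symmetry_option_and_mismatch():
    rng = np.random.default_rng(2)
    a = _random_dimer(rng)
    sw = a.swapped()
    assert dimer_rmsd(a, sw, symmetry=True) < 1e-9
    assert dimer_rmsd(a, sw, symmetry=False) > 0.1
    with pytest.raises(MetricError):
        dimer_rmsd(a, _random_dimer(rng, n_beads=5))


def test_rmsd_pseudometric_properties():
    rng = np.random.default_rng(3)
    tri = [_random_dimer(rng) for _ in range(3)]
    dab = dimer_rmsd(tri[0], tri[1])
    assert dab == pytest.approx(dimer_rmsd(tri[1], tri[0]), abs=1e-9)
    dac = dimer_rmsd(tri[0], tri[2])
    dbc = dimer_rmsd(tri[1], tri[2])
    assert dac <= dab + dbc + 1e-9


# ---------------------------------------------------------------------------
# GROMOS clustering
# ---------------------------------------------------------------------------
def _bruteforce_gromos(confs, cutoff):
    """Independent literal re-execution of the neighbour-count rule."""
    n = len(confs)
    m = np.array([[dimer_rmsd(confs[i], confs[j], symmetry=True)
                   for j in range(n)] for i in range(n)])
    neigh = m < cutoff
    np.fill_diagonal(neigh, True)
    alive = set(range(n))
    clusters = []
    while alive:
        best, best_count = None, -1
        for i in sorted(alive):
            cnt = sum(1 for j in alive if neigh[i, j])
            if cnt > best_count:
                best, best_count = i, cnt
        members = frozenset(j for j in alive if neigh[best, j])
        clusters.append(members)
        alive -= members
    return clusters


def _noisy_family(rng, base, n, sigma):
    out = []
    for _ in range(n):
        out.append(DimerConformation(
            base.coords_a + rng.normal(0, sigma, base.coords_a.shape),
            base.coords_b + rng.normal(0, sigma, base.coords_b.shape),
        ))
    return out


def test_all_identical_form_one_cluster():
    rng = np.random.default_rng(4)
    a = _random_dimer(rng)
    res = gromos_cluster([a] * 7, cutoff=0.4)
    assert res.n_clusters == 1
    assert res.populations.tolist() == [1.0]


def test_two_groups_and_bruteforce_agreement():
    rng = np.random.default_rng(5)
    g1 = _noisy_family(rng, _random_dimer(rng), 7, 0.02)
    g2 = _noisy_family(rng, _random_dimer(rng), 3, 0.02)
    confs = g1 + g2
    res = gromos_cluster(confs, cutoff=0.4)
    assert res.populations.tolist() == [0.7, 0.3]
    bf = _bruteforce_gromos(confs, 0.4)
    ours = [frozenset(np.flatnonzero(res.membership == c))
            for c in range(res.n_clusters)]
    assert set(ours) == set(bf)


def test_singleton_cluster():
    rng = np.random.default_rng(6)
    family = _noisy_family(rng, _random_dimer(rng), 5, 0.02)
    outlier = _random_dimer(rng)
    res = gromos_cluster(family + [outlier], cutoff=0.4)
    assert res.membership[-1] != res.membership[0]
    assert res.populations[-1] == pytest.approx(1 / 6)


@given(st.randoms(use_true_random=False))
def test_cluster_partition_invariant_under_permutation(pyrandom):
    rng = np.random.default_rng(7)
    confs = (_noisy_family(rng, _random_dimer(rng), 6, 0.02)
             + _noisy_family(rng, _random_dimer(rng), 4, 0.02))
    perm = list(range(len(confs)))
    pyrandom.shuffle(perm)
    base = gromos_cluster(confs, cutoff=0.4)
    shuf = gromos_cluster([confs[p] for p in perm], cutoff=0.4)
    part_a = {frozenset(np.flatnonzero(base.membership == c))
              for c in range(base.n_clusters)}
    part_b = {frozenset(perm[i] for i in np.flatnonzero(shuf.membership == c))
              for c in range(shuf.n_clusters)}
    assert part_a == part_b


# ---------------------------------------------------------------------------
# orientation angles and restraints
# ---------------------------------------------------------------------------
def _c2_dimer(sep=3.0):
    """B is A rotated 180 degrees about the z-axis through the midpoint."""
    t = monomer_template(12)
    a = t + np.array([-sep / 2, 0, 0])
    Rz = np.array([[-1, 0, 0], [0, -1, 0], [0, 0, 1.0]])
    b = a @ Rz.T
    return DimerConformation(a, b)


def test_c2_symmetric_dimer_has_equal_angles():
    ang = vba_angles(_c2_dimer())
    assert ang.phi1 == pytest.approx(ang.phi3, abs=1e-9)


def test_rotating_monomer_b_shifts_phi3_only():
    d = _c2_dimer()
    ang0 = vba_angles(d)
    alpha = 37.0
    Rz = Rotation.from_euler("z", alpha, degrees=True)
    com_b = d.coords_b.mean(axis=0)
    b_rot = Rz.apply(d.coords_b - com_b) + com_b
    ang1 = vba_angles(DimerConformation(d.coords_a, b_rot))
    assert ang1.phi1 == pytest.approx(ang0.phi1, abs=1e-9)
    assert float(wrap_angle(ang1.phi3 - (ang0.phi3 - alpha))) == \
        pytest.approx(0.0, abs=1e-9)


def test_angles_invariant_under_in_plane_rigid_motion():
    rng = np.random.default_rng(8)
    d = _c2_dimer()
    ang0 = vba_angles(d)
    worst = 0.0
    for _ in range(1000):
        Rz = Rotation.from_euler("z", rng.uniform(0, 360), degrees=True)
        shift = rng.uniform(-5, 5, 3)
        moved = DimerConformation(Rz.apply(d.coords_a) + shift,
                                  Rz.apply(d.coords_b) + shift)
        ang = vba_angles(moved)
        worst = max(worst,
                    abs(float(wrap_angle(ang.phi1 - ang0.phi1))),
                    abs(float(wrap_angle(ang.phi3 - ang0.phi3))))
    assert worst < 1e-9


def test_label_swap_swaps_angles():
    rng = np.random.default_rng(9)
    d = _random_dimer(rng, n_beads=12)
    ang = vba_angles(d, reference_beads=(0, 2))
    sw = vba_angles(d.swapped(), reference_beads=(2, 0))
    assert sw.phi1 == pytest.approx(ang.phi3, abs=1e-9)
    assert sw.phi3 == pytest.approx(ang.phi1, abs=1e-9)


def test_degenerate_axis_raises():
    # reference bead 0 sits exactly above the COM: zero in-plane axis
    a = np.array([[0.0, 0.0, 0.5], [1.0, 0.0, 0.0],
                  [-1.0, 0.0, 0.0], [0.0, 0.0, -0.5]])
    d = DimerConformation(a, a + np.array([3.0, 0, 0]))
    with pytest.raises(GeometryError):
        vba_angles(d, reference_beads=(0, 0))


def test_restraint_zero_at_target_and_wrap_continuity():
    d = _c2_dimer()
    ang = vba_angles(d)
    e0, fa, fb = orientation_restraint(d, (ang.phi1, ang.phi3), 0.05)
    assert e0 == 0.0
    assert np.allclose(fa, 0) and np.allclose(fb, 0)
    # energy is continuous across the wrap: targets on either side of the
    # 180-degree seam give nearly identical energies
    eps = 1e-6
    e_plus, *_ = orientation_restraint(
        d, (ang.phi1 + 180 + eps, ang.phi3), 0.05)
    e_minus, *_ = orientation_restraint(
        d, (ang.phi1 + 180 - eps, ang.phi3), 0.05)
    assert e_plus == pytest.approx(e_minus, rel=1e-4)


def test_restraint_forces_match_finite_differences():
    rng = np.random.default_rng(10)
    d = _random_dimer(rng, n_beads=10)
    ang = vba_angles(d)
    targets = (ang.phi1 + 40.0, ang.phi3 - 25.0)
    k = 0.02
    _, fa, fb = orientation_restraint(d, targets, k)
    h = 1e-6
    scale = max(np.abs(fa).max(), np.abs(fb).max())
    for which in ("a", "b"):
        coords = d.coords_a if which == "a" else d.coords_b
        for bead in range(0, 10, 3):
            for axis in range(3):
                ca, cb = d.coords_a.copy(), d.coords_b.copy()
                arr = ca if which == "a" else cb
                arr[bead, axis] += h
                ep, *_ = orientation_restraint(
                    DimerConformation(ca, cb), targets, k)
                arr[bead, axis] -= 2 * h
                em, *_ = orientation_restraint(
                    DimerConformation(ca, cb), targets, k)
                num = -(ep - em) / (2 * h)
                ana = (fa if which == "a" else fb)[bead, axis]
                assert num == pytest.approx(ana, abs=1e-6 * max(scale, 1.0))
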