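"""WHAM correctness, corrections, convergence slices and bootstrap errors."""

import numpy as np
import pytest

from dimerpmf import (
    BootstrapSpec,
    BrownianParams,
    HistogramSet,
    ToyLandscape,
    bootstrap_pmf,
    build_ladder,
    jacobian_correction,
    make_histograms,
    marginal_pmf_oracle,
    mbar_pmf,
    rms_kt,
    run_us_remd,
    timewindow_pmfs,
    well_depth,
    wham_solve,
)
from dimerpmf.errors import (
    ConnectivityError,
    DimerPMFError,
    NonConvergenceError,
    ResamplingError,
)
from dimerpmf.pmf import PMFCurve

KT = 2.494


class _FakeSeries:
    """Synthetic per-window samples (no dynamics) for estimator tests."""

    def __init__(self, d_values, window_id=0):
        self.d_values = np.asarray(d_values, float)
        self.times = np.arange(1.0, self.d_values.size + 1.0)
        self.window_id = window_id


def _boltzmann_series(centers, k_kjmol, n, seed, kT=KT):
    """i.i.d. draws from each window's harmonic-bias Boltzmann density."""
    rng = np.random.default_rng(seed)
    sig = np.sqrt(kT / k_kjmol)
    return [
        _FakeSeries(rng.normal(c, sig, n), w)
        for w, c in enumerate(centers)
    ]


# ---------------------------------------------------------------------------
# wham_solve
# ---------------------------------------------------------------------------
def test_single_unbiased_window_inverts_to_harmonic():
    """One unbiased window sampling exp(-1/2 k d^2 / kT) -> F = harmonic."""
    rng = np.random.default_rng(0)
    k = 300.0
    d0 = 6.0
    samples = rng.normal(d0, np.sqrt(KT / k), 2_000_000)
    hists = make_histograms([_FakeSeries(samples)], centers=[d0],
                            ks_kjmol=[0.0], kT=KT, bin_width=0.02)
    curve = wham_solve(hists)
    ok = curve.sampled() & (np.abs(curve.d - d0) < 2 * np.sqrt(KT / k))
    expected = 0.5 * k * (curve.d[ok] - d0) ** 2
    diff = (curve.f_kjmol[ok] - expected) / KT
    assert np.max(np.abs(diff - diff.mean())) < 0.05


def test_flat_landscape_pmf_is_flat():
    centers = 5.4 + 0.1 * np.arange(21)
    k = 997.6
    series = _boltzmann_series(centers, k, 20_000, seed=1)
    curve = wham_solve(make_histograms(series, centers, [k] * 21, KT))
    ok = curve.sampled() & (curve.d >= 5.4) & (curve.d <= 7.4)
    assert np.ptp(curve.f_kt[ok]) < 0.2


def test_bias_shift_invariance():
    """Adding per-window constants to the bias leaves the PMF unchanged."""
    centers = 6.0 + 0.1 * np.arange(5)
    k = 997.6
    series = _boltzmann_series(centers, k, 5_000, seed=2)
    hists = make_histograms(series, centers, [k] * 5, KT)

    class Shifted(HistogramSet):
        def bias_kt(self):
            u = super().bias_kt()
            return u + np.arange(len(self.centers))[:, None] * 3.7

    shifted = Shifted(**{f: getattr(hists, f) for f in
                         ("bin_edges", "counts", "n_samples", "centers",
                          "ks_kjmol", "kT")})
    a = wham_solve(hists)
    b = wham_solve(shifted)
    ok = a.sampled()
    np.testing.assert_allclose(a.f_kjmol[ok], b.f_kjmol[ok], atol=1e-6)


def test_wham_connectivity_error_names_gap():
    centers = [5.5, 5.6, 7.0, 7.1]
    series = _boltzmann_series(centers, 997.6, 2_000, seed=3)
    hists = make_histograms(series, centers, [997.6] * 4, KT)
    with pytest.raises(ConnectivityError, match=r"gap.*\(.*nm"):
        wham_solve(hists)


def test_wham_nonconvergence_reports_residual():
    centers = 6.0 + 0.1 * np.arange(4)
    series = _boltzmann_series(centers, 997.6, 2_000, seed=4)
    hists = make_histograms(series, centers, [997.6] * 4, KT)
    with pytest.raises(NonConvergenceError, match="residual"):
        wham_solve(hists, max_iter=2)


def test_wham_self_consistency_reweighting(remd_run, landscape, ladder):
    """Reweighting the unbiased density by each bias reproduces histograms."""
    series, _ = remd_run
    hists = make_histograms(series, ladder.centers, ladder.ks_kjmol,
                            landscape.kT)
    curve = wham_solve(hists)
    p = np.exp(-np.nan_to_num(curve.f_kt, nan=np.inf))
    p /= p.sum()
    u = hists.bias_kt()
    for i in range(0, len(ladder), 5):
        pred = p * np.exp(-u[i])
        pred = pred / pred.sum() * hists.n_samples[i]
        obs = hists.counts[i]
        sel = pred > 20
        chi2_per_bin = np.sum((obs[sel] - pred[sel]) ** 2 / pred[sel]) / sel.sum()
        assert chi2_per_bin < 5.0


def test_wham_agrees_with_binless_mbar():
    centers = 5.9 + 0.1 * np.arange(9)
    k = 997.6
    series = _boltzmann_series(centers, k, 4_000, seed=5)
    hists = make_histograms(series, centers, [k] * 9, KT)
    wham = wham_solve(hists)
    mbar = mbar_pmf(series, centers, [k] * 9, KT, bin_edges=hists.bin_edges)
    assert rms_kt(wham, mbar, (5.95, 6.65)) < 0.1


# ---------------------------------------------------------------------------
# jacobian correction
# ---------------------------------------------------------------------------
def _flat_curve(d_lo=1.0, d_hi=2.0, n=101):
    d = np.linspace(d_lo, d_hi, n)
    return PMFCurve(d=d, f_kjmol=np.zeros(n), kT=KT)


def test_jacobian_none_is_identity():
    c = _flat_curve()
    out = jacobian_correction(c, "none")
    np.testing.assert_array_equal(out.f_kjmol, c.f_kjmol)


def test_jacobian_radial_closed_form():
    c = _flat_curve()
    out = jacobian_correction(c, "radial_3d")
    # plateau-zeroed: F(d) = 2 kT ln d - mean over the outer strip
    raw = 2 * KT * np.log(c.d)
    strip = c.d >= c.d.max() - 0.3
    np.testing.assert_allclose(out.f_kjmol, raw - raw[strip].mean(),
                               atol=1e-10)


def test_jacobian_not_idempotent_and_tagged():
    c = _flat_curve()
    once = jacobian_correction(c, "radial_3d")
    twice = jacobian_correction(once, "radial_3d")
    assert not np.allclose(once.f_kjmol, twice.f_kjmol)
    assert twice.provenance["jacobian"] == ["radial_3d", "radial_3d"]


def test_jacobian_custom_coverage_error():
    c = _flat_curve()
    with pytest.raises(DimerPMFError, match="cover"):
        jacobian_correction(c, "custom",
                            log_jacobian=(np.array([1.2, 1.5]),
                                          np.array([0.0, 1.0])))


# ---------------------------------------------------------------------------
# time-windowed convergence
# ---------------------------------------------------------------------------
def test_timewindow_reduction_to_full_solve():
    centers = 6.0 + 0.1 * np.arange(5)
    series = _boltzmann_series(centers, 997.6, 3_000, seed=6)
    full = wham_solve(make_histograms(series, centers, [997.6] * 5, KT))
    slices = timewindow_pmfs(series, centers, [997.6] * 5, KT,
                             window_length=3_000.0)
    assert len(slices) == 1
    ok = full.sampled()
    np.testing.assert_allclose(slices[0].f_kjmol[ok], full.f_kjmol[ok],
                               atol=1e-9)


def test_timewindow_stationary_slices_agree():
    centers = 6.0 + 0.1 * np.arange(5)
    series = _boltzmann_series(centers, 997.6, 20_000, seed=7)
    boot = bootstrap_pmf(series, centers, [997.6] * 5, KT,
                         spec=BootstrapSpec(n_boot=50, seed=7))
    slices = timewindow_pmfs(series, centers, [997.6] * 5, KT,
                             window_length=10_000.0)
    assert len(slices) == 2
    ok = (slices[0].sampled() & slices[1].sampled()
          & np.isfinite(boot.stderr_kjmol) & (boot.stderr_kjmol > 0))
    diff = slices[0].f_kjmol[ok] - slices[1].f_kjmol[ok]
    # two half-budget slices differ by ~2x the full-budget error scale;
    # aggregate (RMS) comparison is stable where pointwise ratios are not
    rms_diff = np.sqrt(np.mean(diff**2))
    rms_err = np.sqrt(np.mean(boot.stderr_kjmol[ok] ** 2))
    assert rms_diff < 3.0 * rms_err


def test_timewindow_flags_empty_windows():
    centers = 6.0 + 0.1 * np.arange(3)
    series = _boltzmann_series(centers, 997.6, 2_000, seed=8)
    # last window stops producing samples half way through
    series[2].d_values = series[2].d_values[:1_000]
    series[2].times = series[2].times[:1_000]
    slices = timewindow_pmfs(series, centers, [997.6] * 3, KT,
                             window_length=1_000.0)
    assert len(slices) == 2
    assert "empty_windows" not in slices[0].provenance
    assert slices[1].provenance["empty_windows"] == [2]


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------
def test_bootstrap_defaults_and_zero_variance():
    assert BootstrapSpec().n_boot == 100
    centers = 6.0 + 0.1 * np.arange(4)
    half = _boltzmann_series(centers, 997.6, 2_000, seed=9)
    series = [_FakeSeries(np.concatenate([s.d_values, s.d_values]), s.window_id)
              for s in half]
    boot = bootstrap_pmf(series, centers, [997.6] * 4, KT,
                         spec=BootstrapSpec(n_boot=20, seed=0))
    ok = np.isfinite(boot.stderr_kjmol)
    assert np.allclose(boot.stderr_kjmol[ok], 0.0, atol=1e-12)


def test_bootstrap_rejects_too_short_window():
    series = [_FakeSeries([6.0])]
    with pytest.raises(ResamplingError):
        bootstrap_pmf(series, [6.0], [997.6], KT)


def test_sample_size_consistency():
    """Doubling the sampling moves the PMF by less than ~stderr at >90% bins."""
    centers = 6.0 + 0.1 * np.arange(7)
    small = _boltzmann_series(centers, 997.6, 10_000, seed=10)
    big = _boltzmann_series(centers, 997.6, 20_000, seed=11)
    boot = bootstrap_pmf(small, centers, [997.6] * 7, KT,
                         spec=BootstrapSpec(n_boot=60, seed=1))
    curve_big = wham_solve(make_histograms(big, centers, [997.6] * 7, KT,
                                           bin_edges=None))
    ok = (boot.sampled() & np.isfinite(boot.stderr_kjmol)
          & (boot.stderr_kjmol > 0) & (boot.d >= 6.0) & (boot.d <= 6.6))
    diff = boot.f_kjmol[ok] - curve_big.interp(boot.d[ok])
    # aggregate check: the RMS movement under doubled sampling is bounded
    # by ~2x the bootstrap's own error scale (both runs contribute noise)
    rms_move = np.sqrt(np.mean(diff**2))
    assert rms_move < 2.0 * np.sqrt(np.mean(boot.stderr_kjmol[ok] ** 2))


# ---------------------------------------------------------------------------
# well depth extraction
# ---------------------------------------------------------------------------
def test_well_depth_flat_curve_has_no_bound_state():
    c = _flat_curve(5.4, 7.4, 101)
    wd = well_depth(c)
    assert wd.depth_kjmol == pytest.approx(0.0, abs=1e-12)
    assert not wd.has_bound_state


def test_well_depth_reporting_convention():
    """A -55 kJ/mol minimum against a zero plateau reports +55 kJ/mol."""
    d = np.linspace(5.0, 7.0, 201)
    f = -55.0 * np.exp(-((d - 5.4) ** 2) / (2 * 0.05**2))
    wd = well_depth(PMFCurve(d=d, f_kjmol=f, kT=KT))
    assert wd.depth_kjmol == pytest.approx(55.0, rel=1e-3)
    assert wd.d_min == pytest.approx(5.4, abs=0.011)
    assert wd.has_bound_state


def test_well_depth_of_oracle_matches_dense_scan(landscape, oracle):
    wd = well_depth(oracle)
    dense = np.linspace(landscape.d_range[0] + 0.01,
                        landscape.d_range[1], 20_000)
    curve = marginal_pmf_oracle(landscape, dense)
    i_min = np.argmin(curve.f_kjmol)
    plateau = curve.f_kjmol[dense >= dense.max() - 0.3].mean()
    assert wd.depth_kjmol == pytest.approx(
        plateau - curve.f_kjmol[i_min], abs=0.02 * landscape.kT
    )
    assert wd.d_min == pytest.approx(dense[i_min], abs=0.011)
    seg = (dense > dense[i_min]) & (dense < 6.6)
    i_bar = np.argmax(curve.f_kjmol[seg])
    assert wd.barriers[0].d == pytest.approx(dense[seg][i_bar], abs=0.011)
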