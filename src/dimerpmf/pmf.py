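"""Unbiasing of umbrella series: WHAM, bootstrap errors, convergence slices.

The central estimator is :func:`wham_solve`, the standard self-consistent
weighted-histogram iteration

.. math::

    p_b = \\frac{\\sum_i c_{ib}}{\\sum_i N_i e^{f_i - u_{ib}}},
    \\qquad
    e^{-f_i} = \\sum_b p_b e^{-u_{ib}},

with :math:`u_{ib}` the window-i bias evaluated at bin b (in kT) and
:math:`c_{ib}` the biased counts.  Statistical errors follow the
half-window block bootstrap: each of the (default 100) replicates
reassembles every umbrella window from two contiguous half-length blocks
drawn with replacement, and the reported error bar is the standard
deviation of the replicate profiles.  :func:`timewindow_pmfs` solves WHAM
independently on consecutive time slices to expose slow drift (memory of
the starting state), and :func:`mbar_pmf` is an independent binless
estimator kept as a cross-check.

Free energies are reported in kJ/mol; the zero convention sets the mean
over the outermost 0.3 nm of the sampled range to zero (plateau
anchoring, robust against single-bin noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.sparse.csgraph import connected_components

from .errors import (
    ConnectivityError,
    DimerPMFError,
    NonConvergenceError,
    ResamplingError,
)

PLATEAU_WIDTH = 0.3  # nm; outer strip anchoring F = 0
DEFAULT_BIN_WIDTH = 0.02  # nm; spacing/5 at the default 0.1 nm ladder spacing


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class PMFCurve:
    """Gridded free energy versus separation.

    ``d`` are bin centers (nm); ``f_kjmol`` the free energy (kJ/mol, NaN on
    unsampled bins); ``stderr_kjmol`` optional bootstrap errors;
    ``d_int`` the interfacial separation (zero at the bound minimum of a
    reference curve), populated by :meth:`with_d_int`.
    """

    d: np.ndarray
    f_kjmol: np.ndarray
    kT: float
    zero_convention: str = f"mean over outermost {PLATEAU_WIDTH} nm = 0"
    stderr_kjmol: Optional[np.ndarray] = None
    d_int: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.f_kjmol = np.asarray(self.f_kjmol, dtype=float)
        if self.d.shape != self.f_kjmol.shape:
            raise ValueError("d and f_kjmol shapes differ")

    @property
    def f_kt(self) -> np.ndarray:
        return self.f_kjmol / self.kT

    def sampled(self) -> np.ndarray:
        return np.isfinite(self.f_kjmol)

    def rezero(self, plateau_width: float = PLATEAU_WIDTH) -> "PMFCurve":
        """Shift so the mean over the outermost ``plateau_width`` nm is 0."""
        ok = self.sampled()
        if not ok.any():
            return replace(self)
        d_hi = self.d[ok].max()
        ref = ok & (self.d >= d_hi - plateau_width)
        shift = float(np.mean(self.f_kjmol[ref]))
        out = replace(self, f_kjmol=self.f_kjmol - shift)
        out.zero_convention = f"mean over outermost {plateau_width} nm = 0"
        return out

    def with_d_int(self, reference: Optional["PMFCurve"] = None) -> "PMFCurve":
        """Attach d_int = d - argmin(F of reference curve)."""
        ref = reference if reference is not None else self
        ok = ref.sampled()
        d_min = float(ref.d[ok][np.argmin(ref.f_kjmol[ok])])
        return replace(self, d_int=self.d - d_min)

    def interp(self, d_new: np.ndarray) -> np.ndarray:
        """Linear interpolation of F (kJ/mol) onto ``d_new``."""
        ok = self.sampled()
        return np.interp(np.asarray(d_new, float), self.d[ok], self.f_kjmol[ok])


@dataclass
class HistogramSet:
    """Per-window biased histograms sharing one set of bin edges."""

    bin_edges: np.ndarray
    counts: np.ndarray        # (n_windows, n_bins)
    n_samples: np.ndarray     # (n_windows,)
    centers: np.ndarray       # bias centers d_i (nm)
    ks_kjmol: np.ndarray      # force constants (kJ/mol/nm^2)
    kT: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("negative histogram counts")
        if not np.allclose(self.counts.sum(axis=1), self.n_samples):
            raise ValueError("counts do not sum to the recorded sample sizes")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def bias_kt(self) -> np.ndarray:
        """Bias energy matrix u_{ib} (kT), windows x bins."""
        x = self.bin_centers[None, :]
        return 0.5 * self.ks_kjmol[:, None] * (x - self.centers[:, None]) ** 2 / self.kT


@dataclass(frozen=True)
class BootstrapSpec:
    """Half-window block-bootstrap specification (default 100 replicates)."""

    n_boot: int = 100
    seed: int = 0
    resampling_unit: str = "contiguous half-window blocks, with replacement"

    def __post_init__(self) -> None:
        if self.n_boot < 2:
            raise ValueError("n_boot must be at least 2")


# ---------------------------------------------------------------------------
# histogram assembly
# ---------------------------------------------------------------------------
def make_histograms(
    series: Sequence,
    centers: Sequence[float],
    ks_kjmol: Sequence[float],
    kT: float,
    bin_width: float = DEFAULT_BIN_WIDTH,
    bin_edges: Optional[np.ndarray] = None,
    time_slice: Optional[tuple[float, float]] = None,
) -> HistogramSet:
    """Bin per-window separation samples onto a common grid.

    ``series`` is any sequence of objects with ``d_values`` and ``times``
    arrays (one per window, same order as ``centers``).  ``time_slice``
    restricts to samples with t0 <= t < t1.
    """
    centers = np.asarray(centers, float)
    ks = np.asarray(ks_kjmol, float)
    if len(series) != len(centers):
        raise ValueError("one series per window required")
    d_all = []
    for s in series:
        d = np.asarray(s.d_values, float)
        if time_slice is not None:
            t = np.asarray(s.times, float)
            d = d[(t >= time_slice[0]) & (t < time_slice[1])]
        d_all.append(d)
    if bin_edges is None:
        pooled = np.concatenate([d for d in d_all if d.size]) if any(
            d.size for d in d_all
        ) else np.array([0.0, 1.0])
        lo = np.floor(pooled.min() / bin_width) * bin_width
        hi = np.ceil(pooled.max() / bin_width) * bin_width
        bin_edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts = np.stack([np.histogram(d, bins=bin_edges)[0] for d in d_all])
    # samples outside the fixed edges are dropped from that window's count
    n = counts.sum(axis=1)
    return HistogramSet(
        bin_edges=np.asarray(bin_edges, float),
        counts=counts.astype(float),
        n_samples=n,
        centers=centers,
        ks_kjmol=ks,
        kT=kT,
    )


def _check_connectivity(hists: HistogramSet) -> None:
    """Require the window supports to chain-overlap; name the gap if not."""
    occ = hists.counts > 0
    live = np.flatnonzero(occ.any(axis=1))
    if live.size == 0:
        raise ConnectivityError("no window has any samples")
    overlap = (occ[live] @ occ[live].T) > 0
    n_comp, labels = connected_components(overlap, directed=False)
    if n_comp > 1:
        cen = hists.bin_centers
        spans = []
        for c in range(n_comp):
            sup = occ[live[labels == c]].any(axis=0)
            spans.append((cen[sup].min(), cen[sup].max()))
        spans.sort()
        gaps = [
            f"({spans[i][1]:.3f}, {spans[i + 1][0]:.3f}) nm"
            for i in range(len(spans) - 1)
        ]
        raise ConnectivityError(
            "histogram support is disconnected; empty gap(s) at "
            + ", ".join(gaps)
        )


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------
def wham_solve(
    hists: HistogramSet,
    tol: float = 1e-8,
    max_iter: int = 100_000,
    f0: Optional[np.ndarray] = None,
    plateau_width: float = PLATEAU_WIDTH,
    return_f: bool = False,
):
    """Self-consistent WHAM solution of a histogram set.

    Iterates the window free energies f_i (kT) until max |df_i| < ``tol``,
    with an adaptive over-relaxation boost once the iteration is safely
    contracting.  Returns a plateau-zeroed :class:`PMFCurve` (and the
    converged ``f`` when ``return_f``).
    """
    _check_connectivity(hists)
    u = hists.bias_kt()                       # (W, B)
    c_b = hists.counts.sum(axis=0)            # (B,)
    n_i = hists.n_samples.astype(float)       # (W,)
    support = c_b > 0
    f = np.zeros(len(n_i)) if f0 is None else np.array(f0, float)

    with np.errstate(under="ignore"):
        e_minus_u = np.exp(-u[:, support])
        cs = c_b[support]
        omega = 1.0
        last_delta = np.inf
        streak = 0
        for it in range(max_iter):
            denom = (n_i * np.exp(f)) @ e_minus_u   # (Bs,)
            p = cs / denom
            f_new = -np.log(e_minus_u @ p)
            f_new -= f_new[0]
            delta = float(np.max(np.abs(f_new - f)))
            if delta < tol:
                f = f_new
                break
            # successive over-relaxation once steadily contracting
            if delta < last_delta:
                streak += 1
                if streak >= 25:
                    omega = 1.7
            else:
                streak, omega = 0, 1.0
            f = f + omega * (f_new - f)
            f -= f[0]
            last_delta = delta
        else:
            raise NonConvergenceError(
                f"WHAM did not converge in {max_iter} iterations "
                f"(residual {delta:.3e} kT, tol {tol:.1e})"
            )
        denom = (n_i * np.exp(f)) @ e_minus_u
        p = cs / denom
        p = p / p.sum()

    f_kt = np.full(c_b.shape, np.nan)
    f_kt[support] = -np.log(p)
    curve = PMFCurve(
        d=hists.bin_centers,
        f_kjmol=f_kt * hists.kT,
        kT=hists.kT,
        provenance={
            "estimator": "wham",
            "iterations": it + 1,
            "residual_kt": delta,
            "tol_kt": tol,
        },
    ).rezero(plateau_width=plateau_width)
    if return_f:
        return curve, f
    return curve


def mbar_pmf(
    series: Sequence,
    centers: Sequence[float],
    ks_kjmol: Sequence[float],
    kT: float,
    bin_edges: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 20_000,
    decimate: int = 1,
    plateau_width: float = PLATEAU_WIDTH,
) -> PMFCurve:
    """Binless multistate reweighting estimator (cross-check for WHAM).

    Solves the sample-based self-consistent equations
    exp(-f_i) = sum_n exp(-u_i(x_n)) / sum_k N_k exp(f_k - u_k(x_n))
    on the pooled samples, then histograms the per-sample weights.
    Deliberately shares no code path with :func:`wham_solve`.
    """
    centers = np.asarray(centers, float)
    ks = np.asarray(ks_kjmol, float)
    xs = [np.asarray(s.d_values, float)[::decimate] for s in series]
    n_k = np.array([x.size for x in xs], float)
    x = np.concatenate(xs)
    u_kn = 0.5 * ks[:, None] * (x[None, :] - centers[:, None]) ** 2 / kT
    f = np.zeros(len(centers))
    with np.errstate(under="ignore"):
        e_mu = np.exp(-u_kn)
        for it in range(max_iter):
            denom = (n_k * np.exp(f)) @ e_mu        # (N,)
            f_new = -np.log(e_mu @ (1.0 / denom))
            f_new -= f_new[0]
            delta = float(np.max(np.abs(f_new - f)))
            f = f_new
            if delta < tol:
                break
        else:
            raise NonConvergenceError(
                f"MBAR iteration residual {delta:.3e} after {max_iter} steps"
            )
        w = 1.0 / ((n_k * np.exp(f)) @ e_mu)
    p, _ = np.histogram(x, bins=bin_edges, weights=w)
    f_kt = np.where(p > 0, -np.log(np.where(p > 0, p, 1.0)), np.nan)
    return PMFCurve(
        d=0.5 * (bin_edges[:-1] + bin_edges[1:]),
        f_kjmol=f_kt * kT,
        kT=kT,
        provenance={"estimator": "mbar", "iterations": it + 1},
    ).rezero(plateau_width=plateau_width)


# ---------------------------------------------------------------------------
# Jacobian / restraint corrections
# ---------------------------------------------------------------------------
def jacobian_correction(
    curve: PMFCurve,
    mode: str = "none",
    log_jacobian: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> PMFCurve:
    """Geometric correction of a distance PMF.

    ``none``
        identity (the intrinsically 1D toy case).
    ``radial_3d``
        free 3D separation entropy: F <- F + 2 kT ln d, then re-zeroed.
    ``custom``
        user-supplied table ``(d, ln J(d))``; F <- F + kT ln J, re-zeroed.
        Covers e.g. the partition-function terms of an orientation-restraint
        (virtual-bond) scheme, which depend on the specific restraint
        geometry and are therefore left to the caller.

    Applying ``radial_3d`` twice double-corrects; results are tagged in
    ``provenance['jacobian']`` so pipelines can guard against it.
    """
    if mode == "none":
        return replace(curve)
    if mode == "radial_3d":
        f = curve.f_kjmol + 2.0 * curve.kT * np.log(curve.d)
        out = replace(curve, f_kjmol=f).rezero()
    elif mode == "custom":
        if log_jacobian is None:
            raise ValueError("custom mode requires a (d, lnJ) table")
        dj, lj = (np.asarray(a, float) for a in log_jacobian)
        ok = curve.sampled()
        if curve.d[ok].min() < dj.min() - 1e-9 or curve.d[ok].max() > dj.max() + 1e-9:
            raise DimerPMFError(
                "custom log-Jacobian table does not cover the PMF grid "
                f"[{curve.d[ok].min():.3f}, {curve.d[ok].max():.3f}] nm"
            )
        f = curve.f_kjmol + curve.kT * np.interp(curve.d, dj, lj)
        out = replace(curve, f_kjmol=f).rezero()
    else:
        raise ValueError(f"unknown jacobian mode {mode!r}")
    out.provenance = dict(curve.provenance)
    out.provenance["jacobian"] = out.provenance.get("jacobian", []) + [mode]
    return out


# ---------------------------------------------------------------------------
# convergence slices and bootstrap
# ---------------------------------------------------------------------------
def timewindow_pmfs(
    series: Sequence,
    centers: Sequence[float],
    ks_kjmol: Sequence[float],
    kT: float,
    window_length: float,
    stride: Optional[float] = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    bin_edges: Optional[np.ndarray] = None,
    **wham_kwargs,
) -> list[PMFCurve]:
    """Independent WHAM solutions on consecutive time slices.

    ``window_length`` and ``stride`` are in the time unit of the series
    (ps).  All slices share one grid and the plateau zero convention.  A
    slice in which some umbrella window has no samples is still returned,
    flagged in ``provenance`` (``empty_windows``; ``error`` if WHAM could
    not run at all) rather than silently dropped.
    """
    stride = window_length if stride is None else stride
    t0 = min(float(np.min(s.times)) for s in series)
    t1 = max(float(np.max(s.times)) for s in series)
    # tolerance of one sampling interval so an N-sample series of duration
    # exactly window_length yields exactly one slice
    dt_s = min(
        float(np.median(np.diff(np.asarray(s.times))))
        if np.asarray(s.times).size > 1 else np.inf
        for s in series
    )
    if window_length > (t1 - t0) + dt_s:
        raise ValueError("window_length exceeds the series duration")
    if bin_edges is None:
        full = make_histograms(series, centers, ks_kjmol, kT, bin_width=bin_width)
        bin_edges = full.bin_edges
    out: list[PMFCurve] = []
    start = t0
    while start + window_length <= t1 + dt_s:
        hists = make_histograms(
            series, centers, ks_kjmol, kT,
            bin_edges=bin_edges, time_slice=(start, start + window_length),
        )
        empty = np.flatnonzero(hists.n_samples == 0).tolist()
        try:
            curve = wham_solve(hists, **wham_kwargs)
        except DimerPMFError as exc:
            curve = PMFCurve(
                d=hists.bin_centers,
                f_kjmol=np.full(hists.bin_centers.shape, np.nan),
                kT=kT,
            )
            curve.provenance["error"] = str(exc)
        curve.provenance["time_window"] = (start, start + window_length)
        if empty:
            curve.provenance["empty_windows"] = empty
        out.append(curve)
        start += stride
    return out


def bootstrap_pmf(
    series: Sequence,
    centers: Sequence[float],
    ks_kjmol: Sequence[float],
    kT: float,
    spec: BootstrapSpec = BootstrapSpec(),
    bin_width: float = DEFAULT_BIN_WIDTH,
    plateau_width: float = PLATEAU_WIDTH,
    **wham_kwargs,
) -> PMFCurve:
    """Half-window block bootstrap of the WHAM profile.

    Each replicate rebuilds every umbrella window from two contiguous
    half-length blocks drawn with replacement (preserving within-block
    autocorrelation), solves WHAM warm-started from the full-data solution,
    and re-zeros.  F is the replicate mean and ``stderr_kjmol`` the
    replicate standard deviation times sqrt(B/(B-1)) = sqrt(2): the
    plug-in variance of a B-block bootstrap is biased low by (B-1)/B,
    which for two blocks halves the variance, so the correction is what
    makes the reported bars estimate the true sampling error.
    """
    halves = []
    for s in series:
        d = np.asarray(s.d_values, float)
        if d.size < 2:
            raise ResamplingError(
                f"window {getattr(s, 'window_id', '?')} has {d.size} sample(s); "
                "cannot split into two half blocks"
            )
        m = d.size // 2
        halves.append((d[:m], d[m:]))

    base = make_histograms(series, centers, ks_kjmol, kT, bin_width=bin_width)
    base_curve, f_warm = wham_solve(
        base, plateau_width=plateau_width, return_f=True, **wham_kwargs
    )
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xB007]))

    reps = np.full((spec.n_boot, base.bin_centers.size), np.nan)
    for r in range(spec.n_boot):
        counts = np.zeros_like(base.counts)
        n = np.zeros(len(series))
        for i, (h1, h2) in enumerate(halves):
            pick = rng.integers(0, 2, size=2)
            d = np.concatenate([(h1, h2)[j] for j in pick])
            counts[i], _ = np.histogram(d, bins=base.bin_edges)
            n[i] = counts[i].sum()
        hists = HistogramSet(
            bin_edges=base.bin_edges, counts=counts, n_samples=n,
            centers=base.centers, ks_kjmol=base.ks_kjmol, kT=kT,
        )
        curve = wham_solve(
            hists, f0=f_warm, plateau_width=plateau_width, **wham_kwargs
        )
        reps[r] = curve.f_kjmol

    n_ok = np.sum(np.isfinite(reps), axis=0)
    good = n_ok >= max(2, int(0.8 * spec.n_boot))
    mean = np.full(reps.shape[1], np.nan)
    std = np.full(reps.shape[1], np.nan)
    mean[good] = np.nanmean(reps[:, good], axis=0)
    # sqrt(B/(B-1)) with B = 2 half-blocks: small-block bias correction
    std[good] = np.sqrt(2.0) * np.nanstd(reps[:, good], axis=0, ddof=1)
    return PMFCurve(
        d=base.bin_centers,
        f_kjmol=mean,
        stderr_kjmol=std,
        kT=kT,
        provenance={
            "estimator": "wham + half-window block bootstrap",
            "n_boot": spec.n_boot,
            "seed": spec.seed,
            "resampling_unit": spec.resampling_unit,
            "full_data_curve": base_curve.f_kjmol,
        },
    )


# ---------------------------------------------------------------------------
# scalar extraction and curve comparison
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class Barrier:
    d: float
    d_int: float
    f_kjmol: float
    prominence_kjmol: float


@dataclass(frozen=True)
class WellDepth:
    depth_kjmol: float
    d_min: float
    has_bound_state: bool
    barriers: tuple[Barrier, ...] = ()


def well_depth(
    curve: PMFCurve,
    plateau_region: Optional[tuple[float, float]] = None,
    min_depth_kt: float = 0.5,
    min_prominence_kt: float = 0.1,
) -> WellDepth:
    """Well depth (reported positive) and barrier positions of a PMF.

    depth = mean F over the plateau region minus the minimum of F.  A
    curve whose minimum is shallower than ``min_depth_kt`` or lies inside
    the plateau region is flagged as having no bound state.  Local maxima
    between the minimum and the plateau with prominence above
    ``min_prominence_kt`` are reported as barriers, with positions also in
    d_int (relative to the minimum).
    """
    ok = curve.sampled()
    d, f = curve.d[ok], curve.f_kjmol[ok]
    if plateau_region is None:
        plateau_region = (d.max() - PLATEAU_WIDTH, d.max())
    lo, hi = plateau_region
    if lo < d.min() - 1e-9 or hi > d.max() + 1e-9:
        raise ValueError("plateau_region outside the sampled range")
    plat = (d >= lo) & (d <= hi)
    f_plat = float(np.mean(f[plat]))
    i_min = int(np.argmin(f))
    d_min = float(d[i_min])
    depth = f_plat - float(f[i_min])
    bound = bool(depth > min_depth_kt * curve.kT and d_min < lo)

    barriers: list[Barrier] = []
    if bound:
        seg = slice(i_min, int(np.searchsorted(d, lo)) + 1)
        peaks, props = find_peaks(
            f[seg], prominence=min_prominence_kt * curve.kT
        )
        for p, prom in zip(peaks, props["prominences"]):
            dp = float(d[seg][p])
            barriers.append(
                Barrier(
                    d=dp,
                    d_int=dp - d_min,
                    f_kjmol=float(f[seg][p]),
                    prominence_kjmol=float(prom),
                )
            )
    return WellDepth(
        depth_kjmol=max(depth, 0.0) if not bound else depth,
        d_min=d_min,
        has_bound_state=bound,
        barriers=tuple(barriers),
    )


def local_maxima(
    curve: PMFCurve,
    region: Optional[tuple[float, float]] = None,
    min_prominence_kt: float = 0.0,
) -> list[Barrier]:
    """Interior local maxima of F within ``region``, with prominences."""
    ok = curve.sampled()
    d, f = curve.d[ok], curve.f_kjmol[ok]
    if region is not None:
        sel = (d >= region[0]) & (d <= region[1])
        d, f = d[sel], f[sel]
    peaks, props = find_peaks(f, prominence=max(min_prominence_kt * curve.kT, 0.0) or None)
    proms = props.get("prominences", np.zeros(len(peaks)))
    return [
        Barrier(d=float(d[p]), d_int=np.nan, f_kjmol=float(f[p]),
                prominence_kjmol=float(pr))
        for p, pr in zip(peaks, proms)
    ]


def residual_range_kt(
    curve: PMFCurve,
    reference: PMFCurve,
    region: tuple[float, float],
) -> float:
    """Range (max - min, kT) of the curve-minus-reference residual.

    A converged estimate has a flat residual (range ~ statistical noise);
    a hysteresis shoulder -- the boundary-region distortion a bound-start
    conventional umbrella run develops when slow interfacial degrees of
    freedom stay frozen -- shows up as a residual ramp of order kT across
    the bound/unbound boundary zone.
    """
    ok = curve.sampled()
    d = curve.d[ok]
    sel = (d >= region[0]) & (d <= region[1])
    if not sel.any():
        raise ValueError("no sampled bins in the region")
    diff = (curve.f_kjmol[ok][sel] - reference.interp(d[sel])) / curve.kT
    return float(diff.max() - diff.min())


def rms_kt(
    curve: PMFCurve,
    reference: PMFCurve,
    region: Optional[tuple[float, float]] = None,
    align: bool = True,
) -> float:
    """RMS deviation (kT) between two curves over ``region``.

    The reference is interpolated onto the curve grid.  With ``align`` the
    mean offset over the region is removed first, so the comparison is
    insensitive to the (arbitrary) zero convention.
    """
    ok = curve.sampled()
    d = curve.d[ok]
    if region is not None:
        sel = (d >= region[0]) & (d <= region[1])
    else:
        sel = np.ones(d.shape, bool)
    if not sel.any():
        raise ValueError("no sampled bins in the comparison region")
    diff = (curve.f_kjmol[ok][sel] - reference.interp(d[sel])) / curve.kT
    if align:
        diff = diff - diff.mean()
    return float(np.sqrt(np.mean(diff**2)))
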