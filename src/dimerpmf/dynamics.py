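"""Overdamped Langevin (Brownian) integrator for the toy landscape.

One Euler--Maruyama-type step on (d, l):

    x <- x - (D/kT) grad(U + bias) dt
           + sqrt(2 D dt) (xi_n + xi_{n+1}) / 2,   xi ~ N(0, 1)

i.e. the Leimkuhler--Matthews variant in which successive Gaussian
increments are averaged.  The averaging costs nothing but removes the
O(dt) stationary-distribution bias of the plain scheme -- for a harmonic
potential the sampled variance is exactly kT/k at any stable step size --
which matters here because the umbrella force constants make D dt U''/kT
of order one and a plain Euler--Maruyama run would visibly broaden every
window histogram and bias the unbiased profile.  Reflecting walls at the
domain edges make the stationary law the Boltzmann distribution truncated
to the domain, the same finite system the quadrature oracle integrates.
Energies are in kT internally, so the mobility is simply D.

Randomness: one counter-based Philox stream per replica, keyed by
(master seed, replica id).  A replica carries its stream wherever window
exchange takes it, which makes umbrella-exchange runs bit-reproducible
and makes an exchange-free run identical to independent window runs with
the same seeds.

The inner loop is JIT-compiled with numba; the per-step displacement is
monitored and a run aborts with :class:`InstabilityError` when the drift
repeatedly exceeds five noise standard deviations.  Drivers may request a
short displacement-capped equilibration phase for starts placed far from
a window's bias center (deliberate, e.g. bound starts in far windows).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .errors import ConfigError, DomainError, InstabilityError
from .landscape import ToyLandscape

#: consecutive oversized steps tolerated before aborting
_MAX_CONSECUTIVE_UNSTABLE = 10


@dataclass(frozen=True)
class BrownianParams:
    """Integrator parameters (per-coordinate diffusion constant D)."""

    D: float = 0.1          # nm^2/ps
    dt: float = 0.01        # ps
    n_steps: int = 200_000
    seed: int = 0
    position_restraint_k: Optional[float] = None  # kJ/mol/nm^2 tether on d

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.D <= 0:
            raise ConfigError("D and dt must be positive")
        if self.n_steps < 1:
            raise ConfigError("n_steps must be at least 1")

    def validate_for(self, landscape: ToyLandscape) -> None:
        """Setup-time stability check: D dt |grad U| / kT < 0.2 everywhere."""
        g = landscape.max_gradient_norm()
        crit = self.D * self.dt * g
        if crit >= 0.2:
            raise ConfigError(
                f"time step too large: D*dt*|gradU|/kT = {crit:.3f} >= 0.2 "
                f"(max gradient {g:.1f} kT/nm)"
            )


@dataclass
class WindowSeries:
    """Per-window time series of the reaction coordinate.

    ``replica_id_at_t`` records which replica occupied this window at each
    sample (exchange bookkeeping).  ``bias_center``/``bias_k_kjmol`` make
    every sample's generating bias recoverable from the series itself.
    """

    window_id: int
    times: np.ndarray          # ps
    d_values: np.ndarray       # nm
    l_values: np.ndarray       # dimensionless
    replica_id_at_t: np.ndarray
    bias_center: Optional[float] = None
    bias_k_kjmol: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.d_values = np.asarray(self.d_values, float)
        self.l_values = np.asarray(self.l_values, float)
        self.replica_id_at_t = np.asarray(self.replica_id_at_t, int)
        n = {a.size for a in (self.times, self.d_values, self.l_values,
                              self.replica_id_at_t)}
        if len(n) != 1:
            raise ValueError("series arrays must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def replica_streams(seed: int, n: int) -> list[np.random.Generator]:
    """Counter-based Philox streams keyed by (master seed, replica id)."""
    return [
        np.random.Generator(np.random.Philox(np.random.SeedSequence([int(seed), r])))
        for r in range(n)
    ]


def exchange_stream(seed: int, n_replicas: int) -> np.random.Generator:
    """Dedicated stream for the Metropolis uniform draws."""
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence([int(seed), int(n_replicas)]))
    )


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------
@njit(cache=False)
def _grad_kernel(d, l, p):  # pragma: no cover - exercised via dynamics tests
    """Analytic gradient of the landscape; mirrors ToyLandscape.gradient."""
    (d0, eps_bind, a_bind, d_barrier, h_barrier, sig_b, e_rep, a_rep,
     d_lo, d_hi, eps_trap, l0, l1, c, sig_l, sig_m, trap_ratio,
     d_couple, w_couple, d_trap, w_trap, l_lo, l_hi, delta_trap) = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8], p[9], p[10],
        p[11], p[12], p[13], p[14], p[15], p[16], p[17], p[18], p[19],
        p[20], p[21], p[22], p[23])
    e = np.exp(-(d - d0) / a_bind)
    gd = 2.0 * eps_bind * (1.0 - e) * e / a_bind
    gd += (-h_barrier * (d - d_barrier) / (sig_b * sig_b)
           * np.exp(-((d - d_barrier) ** 2) / (2.0 * sig_b * sig_b)))
    gd += -(e_rep / a_rep) * np.exp(-(d - d_lo) / a_rep)
    s = 1.0 / (1.0 + np.exp((d - d_couple) / w_couple))
    t = 1.0 / (1.0 + np.exp((d - d_trap) / w_trap))
    lm = 0.5 * (l0 + l1)
    w = 0.5 * (l1 - l0)
    g1 = np.exp(-((l - l1) ** 2) / (2.0 * sig_l * sig_l))
    gm = np.exp(-((l - lm) ** 2) / (2.0 * sig_m * sig_m))
    rc = trap_ratio * c
    gd += c * (-s * (1.0 - s) / w_couple) * g1
    gd += rc * (-t * (1.0 - t) / w_trap) * gm
    x = l - lm
    dg1 = -(l - l1) / (sig_l * sig_l) * g1
    gl = 4.0 * eps_trap * x * (x * x - w * w) / (w ** 4)
    gl += -delta_trap * dg1
    gl += c * s * dg1
    gl += rc * t * (-x / (sig_m * sig_m)) * gm
    return gd, gl


@njit(cache=False)
def _propagate(d, l, bias_c, bias_k_kt, p, D, dt, step0, record_every,
               noise, cap_mult, out_d, out_l, rec0, consec, last_xi):
    """Advance all walkers by noise.shape[0] steps; record periodically.

    ``last_xi`` carries each walker's previous Gaussian increment across
    calls (the Leimkuhler--Matthews noise average) and is updated in
    place.  Returns (status, n_records): status 0 ok, -1 instability.
    Reflecting walls at p[8]/p[9] in d and p[21]/p[22] in l.
    """
    n_steps = noise.shape[0]
    n_w = d.shape[0]
    sigma = np.sqrt(2.0 * D * dt)
    lim = 5.0 * sigma
    cap = cap_mult * sigma
    d_lo, d_hi = p[8], p[9]
    l_lo, l_hi = p[21], p[22]
    rec = rec0
    for s in range(n_steps):
        for w in range(n_w):
            gd, gl = _grad_kernel(d[w], l[w], p)
            fd = gd + bias_k_kt[w] * (d[w] - bias_c[w])
            drift_d = -D * dt * fd
            drift_l = -D * dt * gl
            if cap_mult > 0.0:
                if drift_d > cap:
                    drift_d = cap
                elif drift_d < -cap:
                    drift_d = -cap
                if drift_l > cap:
                    drift_l = cap
                elif drift_l < -cap:
                    drift_l = -cap
            dx = drift_d + 0.5 * sigma * (last_xi[w, 0] + noise[s, w, 0])
            dy = drift_l + 0.5 * sigma * (last_xi[w, 1] + noise[s, w, 1])
            last_xi[w, 0] = noise[s, w, 0]
            last_xi[w, 1] = noise[s, w, 1]
            if cap_mult <= 0.0 and (abs(dx) > lim or abs(dy) > lim):
                consec[w] += 1
                if consec[w] >= _MAX_CONSECUTIVE_UNSTABLE:
                    return -1, rec
            else:
                consec[w] = 0
            xn = d[w] + dx
            while xn < d_lo or xn > d_hi:
                if xn < d_lo:
                    xn = 2.0 * d_lo - xn
                if xn > d_hi:
                    xn = 2.0 * d_hi - xn
            d[w] = xn
            yn = l[w] + dy
            while yn < l_lo or yn > l_hi:
                if yn < l_lo:
                    yn = 2.0 * l_lo - yn
                if yn > l_hi:
                    yn = 2.0 * l_hi - yn
            l[w] = yn
        if record_every > 0 and (step0 + s + 1) % record_every == 0:
            for w in range(n_w):
                out_d[rec, w] = d[w]
                out_l[rec, w] = l[w]
            rec += 1
    return 0, rec


def gradient_via_kernel(landscape: ToyLandscape, d: float, l: float):
    """Kernel gradient exposed for consistency checks against the closed form."""
    return _grad_kernel(float(d), float(l), landscape.kernel_params())


# ---------------------------------------------------------------------------
# single-walker driver
# ---------------------------------------------------------------------------
def simulate(
    landscape: ToyLandscape,
    params: BrownianParams,
    bias: Optional[tuple[float, float]] = None,
    init: Optional[tuple[float, float]] = None,
    record_every: int = 10,
    cap_steps: int = 0,
    replica_id: int = 0,
    _noise_block: int = 65_536,
) -> WindowSeries:
    """Single biased/unbiased Brownian trajectory on the landscape.

    ``bias`` is an optional harmonic (center nm, k kJ/mol/nm^2); an
    additional position-restraint tether (``params.position_restraint_k``)
    is combined analytically with the bias.  ``init`` defaults to the
    bound state (d0, l0).  Samples are recorded every ``record_every``
    steps, after an optional displacement-capped relaxation phase of
    ``cap_steps`` (not recorded).
    """
    params.validate_for(landscape)
    if init is None:
        init = (landscape.d0, landscape.l0)
    d_init, l_init = float(init[0]), float(init[1])
    lo, hi = landscape.d_range
    if not (lo <= d_init <= hi):
        raise DomainError(f"init d={d_init} outside domain [{lo}, {hi}]")
    l_lo, l_hi = landscape.l_range
    if not (l_lo <= l_init <= l_hi):
        raise DomainError(f"init l={l_init} outside domain [{l_lo}, {l_hi}]")

    c, k_kjmol = (bias if bias is not None else (0.0, 0.0))
    k_kt = k_kjmol / landscape.kT
    if params.position_restraint_k:
        # combine tether (centered on the start) with the bias harmonic
        kr = params.position_restraint_k / landscape.kT
        k_tot = k_kt + kr
        c = (k_kt * c + kr * d_init) / k_tot if k_tot > 0 else c
        k_kt = k_tot

    p = landscape.kernel_params()
    d = np.array([d_init])
    l = np.array([l_init])
    bias_c = np.array([c])
    bias_k = np.array([k_kt])
    stream = replica_streams(params.seed, replica_id + 1)[replica_id]
    consec = np.zeros(1, np.int64)
    last_xi = stream.standard_normal((1, 2))

    if cap_steps > 0:
        noise = stream.standard_normal((cap_steps, 1, 2))
        _propagate(d, l, bias_c, bias_k, p, params.D, params.dt, 0, 0,
                   noise, 2.0, np.empty((0, 1)), np.empty((0, 1)), 0, consec,
                   last_xi)

    n_rec = params.n_steps // record_every
    out_d = np.empty((n_rec, 1))
    out_l = np.empty((n_rec, 1))
    rec = 0
    step = 0
    while step < params.n_steps:
        n = min(_noise_block, params.n_steps - step)
        noise = stream.standard_normal((n, 1, 2))
        status, rec = _propagate(
            d, l, bias_c, bias_k, p, params.D, params.dt, step,
            record_every, noise, 0.0, out_d, out_l, rec, consec, last_xi,
        )
        if status != 0:
            raise InstabilityError(
                f"repeated per-step displacements above 5*sqrt(2 D dt) "
                f"near step {step}; reduce dt or cap the relaxation"
            )
        step += n

    times = (np.arange(rec) + 1) * record_every * params.dt
    return WindowSeries(
        window_id=0,
        times=times,
        d_values=out_d[:rec, 0],
        l_values=out_l[:rec, 0],
        replica_id_at_t=np.full(rec, replica_id),
        bias_center=bias[0] if bias is not None else None,
        bias_k_kjmol=bias[1] if bias is not None else None,
    )
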