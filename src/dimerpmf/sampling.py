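"""Umbrella ladders and the US-MD / US-REMD drivers.

A ladder places harmonic windows every ``spacing`` (default 0.1 nm) along
the separation coordinate.  The default force constant follows an overlap
rule: k such that sqrt(kT/k) = spacing/2, i.e. the Boltzmann width of
each window is half the spacing, which predicts ~32% overlap between
neighbouring window distributions and lands the observed exchange
acceptance in the 0.15-0.40 band.  An optional one-round refinement runs
a short pilot and inserts midpoint windows wherever the estimated
neighbour exchange falls below 10%.

The umbrella-exchange driver attempts configuration swaps between
adjacent windows every ``tau_ex`` ps, alternating even/odd pairs, with
Metropolis acceptance min(1, exp(-dU/kT)) on the bias-energy difference

    dU = B_i(x_j) + B_j(x_i) - B_i(x_i) - B_j(x_j).

Configurations move between fixed windows; replica identity travels with
the configuration and is tracked in the series and the exchange log.
With exchanges disabled the driver reduces exactly (same seeds, same
noise) to independent umbrella runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .dynamics import (
    BrownianParams,
    WindowSeries,
    _propagate,
    exchange_stream,
    replica_streams,
)
from .errors import ConfigError, InstabilityError, IntegrityError
from .landscape import ToyLandscape

EXCHANGE_REFINE_THRESHOLD = 0.10  # insert midpoints below this acceptance
DEFAULT_SPACING = 0.1             # nm between umbrella centers


# ---------------------------------------------------------------------------
# ladder
# ---------------------------------------------------------------------------
def overlap_rule_k(spacing: float, kT: float) -> float:
    """Force constant (kJ/mol/nm^2) with Boltzmann width = spacing/2."""
    return 4.0 * kT / spacing**2


@dataclass(frozen=True)
class UmbrellaWindow:
    center: float           # nm
    k_kjmol: float          # kJ/mol/nm^2

    def __post_init__(self) -> None:
        if self.k_kjmol <= 0:
            raise ConfigError("force constant must be positive")

    def bias(self, d) -> np.ndarray:
        """Harmonic bias energy (kJ/mol)."""
        return 0.5 * self.k_kjmol * (np.asarray(d, float) - self.center) ** 2


@dataclass
class UmbrellaLadder:
    windows: list[UmbrellaWindow]
    init_mode: str = "bound"            # bound | unbound | mixed
    spacing_history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        c = self.centers
        if len(c) == 0:
            raise ConfigError("empty ladder")
        if np.any(np.diff(c) <= 0):
            raise ConfigError("window centers must be strictly increasing")
        if self.init_mode not in ("bound", "unbound", "mixed"):
            raise ConfigError(f"unknown init_mode {self.init_mode!r}")

    @property
    def centers(self) -> np.ndarray:
        return np.array([w.center for w in self.windows])

    @property
    def ks_kjmol(self) -> np.ndarray:
        return np.array([w.k_kjmol for w in self.windows])

    def __len__(self) -> int:
        return len(self.windows)

    def predicted_overlap(self, kT: float) -> np.ndarray:
        """Overlap coefficient of adjacent Boltzmann-predicted histograms.

        For harmonic windows on a locally flat landscape each window
        samples N(center, kT/k); the overlap coefficient of two such
        Gaussians with pooled width sig is 2*Phi(-delta/(2*sig)).
        """
        c, k = self.centers, self.ks_kjmol
        sig = np.sqrt(kT / k)
        sig_pair = np.sqrt(0.5 * (sig[:-1] ** 2 + sig[1:] ** 2))
        delta = np.diff(c)
        return 2.0 * norm.cdf(-delta / (2.0 * sig_pair))


def build_ladder(
    landscape: ToyLandscape,
    d_range: Optional[tuple[float, float]] = None,
    spacing: float = DEFAULT_SPACING,
    k_kjmol: Optional[float] = None,
    init_mode: str = "bound",
    refine: bool = False,
    pilot_steps: int = 10_000,
    pilot_tau_ex: float = 0.2,
    params: Optional[BrownianParams] = None,
    seed: int = 0,
) -> UmbrellaLadder:
    """Evenly spaced umbrella ladder, optionally refined once.

    Centers run d_min, d_min+spacing, ..., d_max (inclusive).  With
    ``refine``, a short pilot umbrella-exchange run estimates neighbour
    acceptance and a midpoint window is inserted in every pair below 10%;
    a single refinement round only.
    """
    if d_range is None:
        d_range = (landscape.d_range[0] + spacing, landscape.d_range[1] - spacing)
    lo, hi = d_range
    if spacing <= 0:
        raise ConfigError("spacing must be positive")
    if spacing > hi - lo:
        raise ConfigError(
            f"spacing {spacing} exceeds the requested range extent {hi - lo}"
        )
    if lo < landscape.d_range[0] - 1e-9 or hi > landscape.d_range[1] + 1e-9:
        raise ConfigError("ladder range outside the landscape domain")
    n = int(round((hi - lo) / spacing)) + 1
    centers = lo + spacing * np.arange(n)
    centers = centers[centers <= hi + 1e-9]
    if k_kjmol is None:
        k_kjmol = overlap_rule_k(spacing, landscape.kT)
    ladder = UmbrellaLadder(
        windows=[UmbrellaWindow(float(c), float(k_kjmol)) for c in centers],
        init_mode=init_mode,
        spacing_history=[{
            "stage": "initial", "spacing": spacing, "k_kjmol": k_kjmol,
            "n_windows": len(centers),
        }],
    )
    if refine:
        p = params or BrownianParams(n_steps=pilot_steps, seed=seed)
        p = replace(p, n_steps=pilot_steps)
        _, log = run_us_remd(landscape, ladder, p, tau_ex=pilot_tau_ex,
                             init_mode=init_mode)
        rates = exchange_rates(log)
        ladder = refine_ladder(ladder, rates.per_pair, kT=landscape.kT)
    return ladder


def refine_ladder(
    ladder: UmbrellaLadder,
    pair_rates: dict[tuple[int, int], Optional[float]],
    kT: float,
    threshold: float = EXCHANGE_REFINE_THRESHOLD,
) -> UmbrellaLadder:
    """Insert a midpoint window in every adjacent pair exchanging < 10%.

    Pure function of the measured rates, so refinement is idempotent when
    all pairs are at or above the threshold.  Inserted windows get the
    overlap-rule force constant for their (halved) local spacing.
    """
    inserts = []
    for (i, j), rate in sorted(pair_rates.items()):
        if j != i + 1:
            raise ConfigError("refinement expects adjacent-pair rates")
        if rate is not None and rate < threshold:
            lo, hi = ladder.windows[i].center, ladder.windows[j].center
            mid = 0.5 * (lo + hi)
            inserts.append(UmbrellaWindow(mid, overlap_rule_k((hi - lo) / 2, kT)))
    if not inserts:
        return ladder
    windows = sorted(ladder.windows + inserts, key=lambda w: w.center)
    history = ladder.spacing_history + [{
        "stage": "refined",
        "inserted_centers": [w.center for w in inserts],
        "threshold": threshold,
    }]
    return UmbrellaLadder(windows=windows, init_mode=ladder.init_mode,
                          spacing_history=history)


# ---------------------------------------------------------------------------
# exchange log
# ---------------------------------------------------------------------------
@dataclass
class ExchangeLog:
    """Record of all swap attempts between adjacent windows."""

    times: np.ndarray          # ps
    pair_i: np.ndarray         # lower window of each attempted pair
    pair_j: np.ndarray         # = pair_i + 1
    du_kt: np.ndarray          # bias-energy difference of the swap (kT)
    accepted: np.ndarray       # bool
    uniform_draw: np.ndarray   # the Metropolis uniform in [0, 1)
    tau_ex: float              # attempt interval (ps)
    n_windows: int
    pair_scheme: str = "alternating even/odd phases"

    def __post_init__(self) -> None:
        if np.any(self.pair_j != self.pair_i + 1):
            raise IntegrityError("exchange attempts must pair adjacent windows")
        should = self.uniform_draw < np.exp(np.minimum(-self.du_kt, 0.0))
        if np.any(should != self.accepted.astype(bool)):
            raise IntegrityError(
                "acceptance flags inconsistent with recorded dU and draws"
            )

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ExchangeRates:
    per_pair: dict          # (i, i+1) -> acceptance fraction (None if no attempts)
    attempts: dict          # (i, i+1) -> number of attempts
    missing: tuple          # pairs with zero attempts
    overall: Optional[float]


def exchange_rates(log: ExchangeLog) -> ExchangeRates:
    """Accepted/attempted fraction per adjacent pair, plus overall."""
    if len(log) == 0:
        raise ConfigError("empty exchange log")
    per_pair: dict = {}
    attempts: dict = {}
    missing = []
    for i in range(log.n_windows - 1):
        sel = log.pair_i == i
        n = int(sel.sum())
        attempts[(i, i + 1)] = n
        if n == 0:
            per_pair[(i, i + 1)] = None
            missing.append((i, i + 1))
        else:
            per_pair[(i, i + 1)] = float(log.accepted[sel].mean())
    overall = float(log.accepted.mean()) if len(log) else None
    return ExchangeRates(per_pair=per_pair, attempts=attempts,
                         missing=tuple(missing), overall=overall)


def metropolis_acceptance(
    du_kt: float, n_attempts: int, seed: int = 0
) -> tuple[float, np.ndarray]:
    """Empirical acceptance of forced swaps at a fixed dU (kT).

    Draws ``n_attempts`` uniforms from the dedicated exchange stream and
    applies min(1, exp(-dU)).  Returns (fraction accepted, accept mask).
    """
    u = exchange_stream(seed, 0).random(n_attempts)
    acc = u < math.exp(min(-du_kt, 0.0))
    return float(acc.mean()), acc


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------
def _initial_states(
    landscape: ToyLandscape, ladder: UmbrellaLadder, init_mode: str
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = landscape.d_range
    d = np.empty(len(ladder))
    l = np.empty(len(ladder))
    d_unbound_floor = landscape.d_barrier + 0.3  # plateau side of the barrier
    for w, win in enumerate(ladder.windows):
        mode = init_mode
        if init_mode == "mixed":
            mode = "bound" if w % 2 == 0 else "unbound"
        if mode == "bound":
            d[w] = min(max(landscape.d0, lo), hi)
            l[w] = landscape.l0
        elif mode == "unbound":
            d[w] = min(max(win.center, d_unbound_floor), hi)
            l[w] = landscape.l1
        else:
            raise ConfigError(f"unknown init mode {mode!r}")
    return d, l


def run_us_remd(
    landscape: ToyLandscape,
    ladder: UmbrellaLadder,
    params: BrownianParams,
    tau_ex: Optional[float] = 0.2,
    init_mode: Optional[str] = None,
    record_every: int = 10,
    cap_steps: int = 500,
) -> tuple[list[WindowSeries], ExchangeLog]:
    """Window-exchange umbrella sampling run.

    ``tau_ex`` is the attempt interval in ps and must be a multiple of the
    time step; ``None`` disables exchange entirely (conventional US-MD).
    Returns one series per window plus the exchange log.
    """
    params.validate_for(landscape)
    W = len(ladder)
    dt = params.dt
    if tau_ex is not None:
        seg = int(round(tau_ex / dt))
        if seg < 1 or abs(seg * dt - tau_ex) > 1e-9:
            raise ConfigError(
                f"tau_ex={tau_ex} ps is not a positive multiple of dt={dt} ps"
            )
    else:
        seg = 4096  # chunk size only; no exchanges

    init_mode = init_mode or ladder.init_mode
    d, l = _initial_states(landscape, ladder, init_mode)
    p = landscape.kernel_params()
    bias_c = ladder.centers.copy()
    bias_k_kt = ladder.ks_kjmol / landscape.kT
    streams = replica_streams(params.seed, W)
    ex_stream = exchange_stream(params.seed, W)
    replica_of_window = np.arange(W)
    consec = np.zeros(W, np.int64)
    # previous Gaussian increment (noise-average scheme) travels with the
    # replica, like its stream
    last_xi_rep = np.stack([streams[r].standard_normal(2) for r in range(W)])

    def _draw(n: int) -> np.ndarray:
        noise = np.empty((n, W, 2))
        for w in range(W):
            noise[:, w, :] = streams[replica_of_window[w]].standard_normal((n, 2))
        return noise

    def _run_segment(n: int, step0: int, record_every_: int, cap: float,
                     rec_: int) -> tuple[int, int]:
        xi = last_xi_rep[replica_of_window].copy()
        status, rec_new = _propagate(
            d, l, bias_c, bias_k_kt, p, params.D, dt, step0, record_every_,
            _draw(n), cap, out_d, out_l, rec_, consec, xi,
        )
        last_xi_rep[replica_of_window] = xi
        return status, rec_new

    if cap_steps > 0:
        out_d = np.empty((0, W))
        out_l = np.empty((0, W))
        _run_segment(cap_steps, 0, 0, 2.0, 0)

    n_rec = params.n_steps // record_every
    out_d = np.empty((n_rec, W))
    out_l = np.empty((n_rec, W))
    rep_at = np.empty((n_rec, W), int)
    ex_records: list[tuple] = []
    rec = 0
    step = 0
    attempt_phase = 0
    while step < params.n_steps:
        n = min(seg, params.n_steps - step)
        rec_before = rec
        status, rec = _run_segment(n, step, record_every, 0.0, rec)
        rep_at[rec_before:rec] = replica_of_window
        if status != 0:
            raise InstabilityError(
                f"integrator instability in window "
                f"{int(np.argmax(consec))} near step {step}"
            )
        step += n
        if tau_ex is not None and step < params.n_steps:
            t_now = step * dt
            for i in range(attempt_phase % 2, W - 1, 2):
                j = i + 1
                du_kjmol = (
                    ladder.windows[i].bias(d[j]) + ladder.windows[j].bias(d[i])
                    - ladder.windows[i].bias(d[i]) - ladder.windows[j].bias(d[j])
                )
                du = float(du_kjmol) / landscape.kT
                u = float(ex_stream.random())
                acc = u < math.exp(min(-du, 0.0))
                if acc:
                    d[i], d[j] = d[j], d[i]
                    l[i], l[j] = l[j], l[i]
                    replica_of_window[[i, j]] = replica_of_window[[j, i]]
                ex_records.append((t_now, i, j, du, acc, u))
            attempt_phase += 1

    times = (np.arange(rec) + 1) * record_every * dt
    series = [
        WindowSeries(
            window_id=w,
            times=times,
            d_values=out_d[:rec, w],
            l_values=out_l[:rec, w],
            replica_id_at_t=rep_at[:rec, w],
            bias_center=float(bias_c[w]),
            bias_k_kjmol=float(ladder.ks_kjmol[w]),
        )
        for w in range(W)
    ]
    if ex_records:
        t_a, i_a, j_a, du_a, acc_a, u_a = map(np.array, zip(*ex_records))
    else:
        t_a = du_a = u_a = np.empty(0)
        i_a = j_a = np.empty(0, int)
        acc_a = np.empty(0, bool)
    log = ExchangeLog(
        times=t_a, pair_i=i_a.astype(int), pair_j=j_a.astype(int),
        du_kt=du_a.astype(float), accepted=acc_a.astype(bool),
        uniform_draw=u_a.astype(float),
        tau_ex=tau_ex if tau_ex is not None else math.inf,
        n_windows=W,
    )
    return series, log


def run_us_md(
    landscape: ToyLandscape,
    ladder: UmbrellaLadder,
    params: BrownianParams,
    init_mode: Optional[str] = None,
    record_every: int = 10,
    cap_steps: int = 500,
) -> list[WindowSeries]:
    """Conventional umbrella sampling: independent windows, no exchange."""
    series, _ = run_us_remd(
        landscape, ladder, params, tau_ex=None, init_mode=init_mode,
        record_every=record_every, cap_steps=cap_steps,
    )
    return series


# ---------------------------------------------------------------------------
# replica-walk diagnostics
# ---------------------------------------------------------------------------
def replica_walk(
    log: ExchangeLog, series: Sequence[WindowSeries]
) -> tuple[np.ndarray, np.ndarray]:
    """Window index of every replica over time: matrix (replica, sample).

    Built from the per-window replica records and cross-validated by
    replaying the exchange log; any disagreement or non-permutation
    column raises :class:`IntegrityError`.
    """
    W = len(series)
    times = series[0].times
    occ = np.stack([s.replica_id_at_t for s in series], axis=1)  # (T, W)
    walk = np.empty((W, times.size), int)
    for t in range(times.size):
        row = occ[t]
        if sorted(row) != list(range(W)):
            raise IntegrityError(f"window occupancy at sample {t} is not a permutation")
        walk[row, t] = np.arange(W)

    # independent replay of the log
    replica_of_window = np.arange(W)
    k = 0
    order = np.argsort(log.times, kind="stable")
    for t_idx, t in enumerate(times):
        # an exchange logged at exactly a sample time happened after that
        # sample was recorded, so only strictly earlier entries are applied
        while k < len(log) and log.times[order[k]] < t - 1e-9:
            a = order[k]
            if log.accepted[a]:
                i, j = int(log.pair_i[a]), int(log.pair_j[a])
                replica_of_window[[i, j]] = replica_of_window[[j, i]]
            k += 1
        expect = np.empty(W, int)
        expect[replica_of_window] = np.arange(W)
        if not np.array_equal(expect, walk[:, t_idx]):
            raise IntegrityError(
                f"replica walk disagrees with exchange-log replay at t={t}"
            )
    return walk, times
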