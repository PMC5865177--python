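"""Analytic dimer-association landscape with a slow lipid-trap coordinate.

The toy system has two degrees of freedom: ``d``, the center-of-mass
separation of two membrane proteins (nm), and ``l``, a dimensionless
collective coordinate for interfacial lipids (``l0`` = lipids away from the
interface, ``l1`` = a lipid wedged between the proteins).  The energy
(in units of kT) is

.. math::

    U(d, l) = U_d(d) + U_l(l)
              + c\\,s(d)\\,g_1(l) + r c\\,t(d)\\,g_m(l)

with

* ``U_d`` -- a Morse well of depth ``eps_bind`` at ``d0``, a Gaussian
  association barrier of height ``h_barrier`` at ``d_barrier``, and an
  exponential short-range repulsion of scale ``a_rep`` at the inner wall;
* ``U_l`` -- a quartic double well with minima at ``l0``/``l1`` separated
  by a barrier of height ``eps_trap`` above the ``l0`` well, tilted by a
  Gaussian term of depth ``delta_trap`` so the lipid-at-interface state is
  the favoured one when the proteins do not sterically exclude it (free
  protein surfaces are wetted by lipid);
* a steric coupling: ``c = c_couple`` times the logistic switch ``s(d)``
  (on at small separation) times a Gaussian ``g_1`` centered on ``l1`` --
  a lipid at the interface is penalized when the proteins are close;
* a trapping coupling: ``r c = trap_ratio * c_couple`` times the switch
  ``t(d)`` times a Gaussian ``g_m`` centered on the double-well midpoint --
  at small and intermediate separations the barrier between the two lipid
  states is raised, so the lipid coordinate is kinetically frozen there
  while it equilibrates freely at large separation.

With ``c_couple = 0`` the energy separates exactly into
``U_d(d) + U_l(l)``.  Reflecting walls bound the domain
(``d_range`` x ``[l0-2, l1+2]``); the marginal-PMF oracle integrates the
lipid coordinate over the same interval, so dynamics and oracle describe
the identical finite system.

Energies are handled in kT internally; ``kT`` (kJ/mol) converts to the
external unit system.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import quad

from .errors import DomainError, QuadratureError
from .pmf import PMFCurve

KT_300K_KJMOL = 2.494
"""kT in kJ/mol at 300 K, the coarse-grained simulation temperature."""

#: width (nm) of the outer plateau strip used for the PMF zero convention
PLATEAU_WIDTH = 0.3


@dataclass(frozen=True)
class ToyLandscape:
    """Parameters of the two-coordinate association landscape.

    All energy parameters are in kT.  Distances in nm; the lipid
    coordinate is dimensionless.
    """

    d0: float = 5.4              # bound-state separation (nm)
    eps_bind: float = 16.0       # bound-well depth (kT)
    a_rep: float = 0.04          # short-range repulsion scale (nm)
    d_barrier: float = 5.9      # association-barrier position (nm)
    h_barrier: float = 10.5      # association-barrier height (kT)
    eps_trap: float = 2.0        # lipid flip barrier above the l0 well (kT)
    delta_trap: float = 2.5      # extra depth of the lipid-trap well (kT)
    l0: float = 0.0              # lipid-away position
    l1: float = 2.0              # lipid-at-interface position
    c_couple: float = 8.0        # steric-penalty amplitude (kT)
    d_range: tuple[float, float] = (5.3, 7.5)
    kT: float = KT_300K_KJMOL    # thermal energy (kJ/mol)

    # shape constants of the documented closed form
    a_bind: float = 0.25         # Morse range (nm)
    sigma_barrier: float = 0.25  # association-barrier width (nm)
    e_rep: float = 2.0           # repulsion amplitude at the inner wall (kT)
    sigma_l: float = 0.4         # width of the steric Gaussian in l
    sigma_m: float = 0.3         # width of the trap Gaussian in l
    trap_ratio: float = 2.0      # trap amplitude as a multiple of c_couple
    d_couple: float = 5.9        # steric switch midpoint (nm)
    w_couple: float = 0.18       # steric switch width (nm)
    d_trap: float = 6.4          # trap switch midpoint (nm)
    w_trap: float = 0.06         # trap switch width (nm)

    def __post_init__(self) -> None:
        if self.d_range[1] <= self.d_range[0]:
            raise DomainError(f"empty d_range {self.d_range}")
        if self.l1 <= self.l0:
            raise DomainError("l1 must exceed l0")

    # -- derived geometry -------------------------------------------------
    @property
    def l_mid(self) -> float:
        return 0.5 * (self.l0 + self.l1)

    @property
    def l_halfwidth(self) -> float:
        return 0.5 * (self.l1 - self.l0)

    @property
    def l_range(self) -> tuple[float, float]:
        """Domain of the lipid coordinate (reflecting walls)."""
        return (self.l0 - 2.0, self.l1 + 2.0)

    # -- closed-form terms ------------------------------------------------
    def switch_steric(self, d):
        """Logistic switch s(d): ~1 below ``d_couple``, ~0 above."""
        return 1.0 / (1.0 + np.exp((np.asarray(d) - self.d_couple) / self.w_couple))

    def switch_trap(self, d):
        """Logistic switch t(d) gating the lipid-barrier raise."""
        return 1.0 / (1.0 + np.exp((np.asarray(d) - self.d_trap) / self.w_trap))

    def u_d(self, d):
        """Separation-only part of the energy (kT)."""
        d = np.asarray(d, dtype=float)
        e = np.exp(-(d - self.d0) / self.a_bind)
        morse = self.eps_bind * ((1.0 - e) ** 2 - 1.0)
        barrier = self.h_barrier * np.exp(
            -((d - self.d_barrier) ** 2) / (2.0 * self.sigma_barrier**2)
        )
        rep = self.e_rep * np.exp(-(d - self.d_range[0]) / self.a_rep)
        return morse + barrier + rep

    def u_l(self, l):
        """Lipid-only part: tilted quartic double well (kT).

        The quartic has both minima at zero energy and a barrier
        ``eps_trap`` at the midpoint; the Gaussian tilt lowers the
        lipid-at-interface well by ``delta_trap``, so the escape barrier
        out of the trap state is ``eps_trap + delta_trap``.
        """
        l = np.asarray(l, dtype=float)
        x = l - self.l_mid
        w = self.l_halfwidth
        return (
            self.eps_trap * (x**2 - w**2) ** 2 / w**4
            - self.delta_trap * self._g1(l)
        )

    def _g1(self, l):
        return np.exp(-((np.asarray(l) - self.l1) ** 2) / (2.0 * self.sigma_l**2))

    def _gm(self, l):
        return np.exp(-((np.asarray(l) - self.l_mid) ** 2) / (2.0 * self.sigma_m**2))

    def u_couple(self, d, l):
        """Coupling terms; identically zero when ``c_couple`` is zero."""
        steric = self.c_couple * self.switch_steric(d) * self._g1(l)
        trap = self.trap_ratio * self.c_couple * self.switch_trap(d) * self._gm(l)
        return steric + trap

    # -- public surface ---------------------------------------------------
    def potential(self, d, l, check_domain: bool = True):
        """Total energy U(d, l) in kT.

        Raises :class:`DomainError` if ``d`` lies outside ``d_range``.
        """
        d = np.asarray(d, dtype=float)
        if check_domain:
            lo, hi = self.d_range
            if np.any(d < lo - 1e-12) or np.any(d > hi + 1e-12):
                raise DomainError(
                    f"d outside domain [{lo}, {hi}]: "
                    f"min={np.min(d):.4f} max={np.max(d):.4f}"
                )
        return self.u_d(d) + self.u_l(l) + self.u_couple(d, l)

    def gradient(self, d, l):
        """Analytic (dU/dd, dU/dl) in kT/nm and kT."""
        d = np.asarray(d, dtype=float)
        l = np.asarray(l, dtype=float)
        e = np.exp(-(d - self.d0) / self.a_bind)
        dmorse = 2.0 * self.eps_bind * (1.0 - e) * e / self.a_bind
        dbarr = (
            -self.h_barrier
            * (d - self.d_barrier)
            / self.sigma_barrier**2
            * np.exp(-((d - self.d_barrier) ** 2) / (2.0 * self.sigma_barrier**2))
        )
        drep = -(self.e_rep / self.a_rep) * np.exp(
            -(d - self.d_range[0]) / self.a_rep
        )
        s = self.switch_steric(d)
        t = self.switch_trap(d)
        ds = -s * (1.0 - s) / self.w_couple
        dt = -t * (1.0 - t) / self.w_trap
        g1 = self._g1(l)
        gm = self._gm(l)
        rc = self.trap_ratio * self.c_couple
        dU_dd = dmorse + dbarr + drep + self.c_couple * ds * g1 + rc * dt * gm

        x = l - self.l_mid
        w = self.l_halfwidth
        ddwell = 4.0 * self.eps_trap * x * (x**2 - w**2) / w**4
        dg1 = -(l - self.l1) / self.sigma_l**2 * g1
        dgm = -x / self.sigma_m**2 * gm
        dU_dl = (
            ddwell - self.delta_trap * dg1
            + self.c_couple * s * dg1 + rc * t * dgm
        )
        return dU_dd, dU_dl

    def max_gradient_norm(self, n: int = 400, accessible_within_kt: float = 20.0) -> float:
        """Largest |dU/dd| + |dU/dl| over the thermally accessible domain.

        The steepest *sampled* point is what matters for step-size
        stability, so points more than ``accessible_within_kt`` above the
        global minimum (Boltzmann weight < e^-20, never visited on the
        budgets used here) are excluded; the repulsive wall corners of the
        domain would otherwise dominate without ever being reached.
        """
        d = np.linspace(*self.d_range, n)
        l = np.linspace(*self.l_range, n)
        dd, ll = np.meshgrid(d, l, indexing="ij")
        u = self.u_d(dd) + self.u_l(ll) + self.u_couple(dd, ll)
        gd, gl = self.gradient(dd, ll)
        g = np.abs(gd) + np.abs(gl)
        mask = u <= u.min() + accessible_within_kt
        return float(np.max(g[mask]))

    def kernel_params(self) -> np.ndarray:
        """Flat parameter vector consumed by the numba integrator kernel."""
        return np.array(
            [
                self.d0, self.eps_bind, self.a_bind,
                self.d_barrier, self.h_barrier, self.sigma_barrier,
                self.e_rep, self.a_rep, self.d_range[0], self.d_range[1],
                self.eps_trap, self.l0, self.l1,
                self.c_couple, self.sigma_l, self.sigma_m, self.trap_ratio,
                self.d_couple, self.w_couple, self.d_trap, self.w_trap,
                self.l_range[0], self.l_range[1], self.delta_trap,
            ],
            dtype=np.float64,
        )

    # -- factories --------------------------------------------------------
    @classmethod
    def default(cls) -> "ToyLandscape":
        return cls()

    @classmethod
    def flat(cls, d_range: tuple[float, float] = (5.3, 7.5)) -> "ToyLandscape":
        """Zero-energy landscape (null case for estimator tests)."""
        return cls(
            eps_bind=0.0, h_barrier=0.0, e_rep=0.0, eps_trap=0.0,
            delta_trap=0.0, c_couple=0.0, d_range=d_range,
        )

    @classmethod
    def separable(cls, **overrides) -> "ToyLandscape":
        """Default geometry with the lipid coupling switched off."""
        return replace(cls(), c_couple=0.0, **overrides)


def marginal_pmf_oracle(
    landscape: ToyLandscape,
    d_grid: Sequence[float],
    plateau_width: float = PLATEAU_WIDTH,
    epsabs: float = 1e-10,
    epsrel: float = 1e-10,
) -> PMFCurve:
    """Exact marginal PMF along the separation coordinate.

    F(d) = -kT ln \\int exp(-U(d, l)/kT) dl, by adaptive quadrature over
    the (reflecting-wall) lipid domain, shifted so the mean over the
    outermost ``plateau_width`` nm of the grid is zero.

    Returns a :class:`~dimerpmf.pmf.PMFCurve` in kJ/mol.
    """
    d_grid = np.asarray(d_grid, dtype=float)
    lo, hi = landscape.d_range
    if np.any(d_grid < lo - 1e-12) or np.any(d_grid > hi + 1e-12):
        raise DomainError("d_grid extends outside the landscape domain")
    l_lo, l_hi = landscape.l_range
    special = [landscape.l0, landscape.l_mid, landscape.l1]

    f_kt = np.empty_like(d_grid)
    for i, d in enumerate(d_grid):
        u_min = min(
            float(landscape.potential(d, l, check_domain=False))
            for l in np.linspace(l_lo, l_hi, 201)
        )

        def integrand(l, d=d, u_min=u_min):
            return np.exp(-(landscape.potential(d, l, check_domain=False) - u_min))

        val, err = quad(
            integrand, l_lo, l_hi, points=special,
            epsabs=epsabs, epsrel=epsrel, limit=200,
        )
        if not np.isfinite(val) or val <= 0 or err > max(epsabs, 1e-6 * val):
            raise QuadratureError(
                f"marginalization failed at d={d:.4f}: value={val!r} err={err!r}"
            )
        f_kt[i] = u_min - np.log(val)

    curve = PMFCurve(
        d=d_grid,
        f_kjmol=f_kt * landscape.kT,
        kT=landscape.kT,
        zero_convention=f"mean over outermost {plateau_width} nm = 0",
        provenance={"source": "quadrature oracle"},
    )
    return curve.rezero(plateau_width=plateau_width)
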