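"""Wave-frame stream function, radial velocity, stagnation points and
bolus-trapping metrics.

The stream function is obtained by exact radial integration of the
piecewise (plug + sheared Casson) axial-velocity profile,

    ``psi(r, z) = int_0^r r' w(r', z) dr'``,

normalised to ``psi = 0`` on the axis; mass conservation in the wave
frame then fixes ``psi(h(z), z) = q/2`` for every ``z``.  The radial
velocity follows analytically from ``u = -(1/r) d(psi)/dz`` by chain
rule through ``h(z)``, ``w(h)(z)`` and ``dp/dz(z)``.

Trapping: in the wave frame, closed streamlines enclose a bolus of
fluid that is carried bodily at the metachronal wave speed.  Boluses are
detected as closed level sets of ``psi`` (marching squares) that touch
neither the axis, nor the wall, nor wrap the periodic boundary; because
a bolus straddles the widest section at ``z = 0 (mod 1)``, contouring is
done on a two-period extension and boluses are counted in a one-period
window interior to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .casson import axial_velocity, casson_resistance, plug_velocity
from .errors import ParameterDomainError, ResolutionError
from .geometry import boundary_axial_velocity, tube_radius
from .params import CiliaParams, PumpState

__all__ = [
    "FlowField",
    "TrappingMetrics",
    "stream_function",
    "radial_velocity",
    "compute_field",
    "stagnation_points",
    "trapping_metrics",
]

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------- station data

def _station(z, q: float, p: CiliaParams):
    """Wall state, pressure gradient and their z-derivatives at station(s) z."""
    z = np.asarray(z, dtype=float)
    e, hp = p.epsilon, p.hp
    k = TWO_PI * e * p.alpha * p.beta
    c, s = np.cos(TWO_PI * z), np.sin(TWO_PI * z)
    h = 1.0 + e * c
    hz = -TWO_PI * e * s
    ww = -1.0 - k * c
    wwz = TWO_PI * k * s
    d = casson_resistance(h, hp)
    # dD/dh for D = h^4/8 + h^3 Hp/6 - (2/7) h^{7/2} sqrt(Hp) - Hp^4/168
    dddh = h**3 / 2.0 + h * h * hp / 2.0 - np.sqrt(hp) * h**2.5
    num = h * h * ww - q
    dpdz = num / d
    numz = 2.0 * h * hz * ww + h * h * wwz
    dpdzz = (numz * d - num * dddh * hz) / (d * d)
    return h, hz, ww, wwz, dpdz, dpdzz


def _antiderivative(r, h, hp):
    """Indefinite integral of ``r * [shear bracket]`` in the sheared region:
    ``A(r) = r^4/4 - h^2 r^2/2 + 2 Hp (r^3/3 - h r^2/2)
             - (16/21) sqrt(Hp) r^{7/2} + (4/3) sqrt(Hp) h^{3/2} r^2``."""
    return (r**4 / 4.0 - h * h * r * r / 2.0
            + 2.0 * hp * (r**3 / 3.0 - h * r * r / 2.0)
            - (16.0 / 21.0) * np.sqrt(hp) * r**3.5
            + (4.0 / 3.0) * np.sqrt(hp) * h**1.5 * r * r)


def _shear_bracket(r, h, hp):
    return (r - h) * (r + h + 2.0 * hp) \
        - (8.0 / 3.0) * np.sqrt(hp) * (r**1.5 - h**1.5)


def stream_function(r, z, pump: PumpState, p: CiliaParams):
    """Stream function ``psi(r, z)``; closed-form radial integral of the
    piecewise profile.  ``psi(0, z) = 0`` and ``psi(h(z), z) = q/2``.

    Vectorized over broadcastable ``r`` and ``z``.
    """
    r = np.asarray(r, dtype=float)
    z = np.asarray(z, dtype=float)
    h, _, ww, _, dpdz, _ = _station(z, pump.q, p)
    if np.any(r < -1e-15) or np.any(r > h + 1e-12):
        raise ParameterDomainError("r must lie in [0, h(z)]")
    hp = p.hp
    gp = _shear_bracket(hp, h, hp)  # bracket at the yield surface
    # sheared region (r >= Hp):  ww r^2/2 + (dpdz/4) [G(Hp) Hp^2/2 + A(r) - A(Hp)]
    r_out = np.maximum(r, hp)
    psi_out = ww * r_out**2 / 2.0 + 0.25 * dpdz * (
        gp * hp * hp / 2.0 + _antiderivative(r_out, h, hp)
        - _antiderivative(hp, h, hp)
    )
    # plug region: psi = wp r^2 / 2 with uniform wp
    wp = ww + 0.25 * dpdz * gp
    psi_in = wp * r * r / 2.0
    psi = np.where(r < hp, psi_in, psi_out)
    return psi if psi.ndim else float(psi)


def radial_velocity(r, z, pump: PumpState, p: CiliaParams):
    """Radial velocity ``u = -(1/r) d(psi)/dz``, analytic chain rule.

    The axis value is the limit ``u -> 0`` as ``r -> 0`` (axisymmetry).
    """
    r = np.asarray(r, dtype=float)
    z = np.asarray(z, dtype=float)
    h, hz, ww, wwz, dpdz, dpdzz = _station(z, pump.q, p)
    if np.any(r < -1e-15) or np.any(r > h + 1e-12):
        raise ParameterDomainError("r must lie in [0, h(z)]")
    hp = p.hp
    sq = (np.sqrt(h) - np.sqrt(hp)) ** 2  # d(bracket)/dh common factor
    gp = _shear_bracket(hp, h, hp)
    # sheared region: dpsi/dz = ww' r^2/2 + (dpdz'/4) B(r) - (dpdz/4) h' r^2 S
    r_out = np.maximum(r, hp)
    b = gp * hp * hp / 2.0 + _antiderivative(r_out, h, hp) \
        - _antiderivative(hp, h, hp)
    dpsi_out = wwz * r_out**2 / 2.0 + 0.25 * dpdzz * b \
        - 0.25 * dpdz * hz * r_out**2 * sq
    # plug region: psi = wp r^2/2, wp' = ww' + (dpdz'/4) G(Hp) - (dpdz/2) S h'
    wpz = wwz + 0.25 * dpdzz * gp - 0.5 * dpdz * sq * hz
    dpsi_in = wpz * r * r / 2.0
    dpsi = np.where(r < hp, dpsi_in, dpsi_out)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(r > 0, -dpsi / np.where(r > 0, r, 1.0), 0.0)
    return u if u.ndim else float(u)


# ------------------------------------------------------------------ the field

@dataclass
class FlowField:
    """Gridded wave-frame field over one (or more) wavelengths.

    ``w``, ``u``, ``psi`` have shape ``(len(z_grid), len(r_grid))``;
    ``mask`` is True inside the tube (``r <= h(z)``).  Outside the tube
    the arrays hold the wall values (``psi = q/2``) so contouring never
    leaks through the wall.
    """

    r_grid: np.ndarray
    z_grid: np.ndarray
    w: np.ndarray
    u: np.ndarray
    psi: np.ndarray
    mask: np.ndarray
    params: CiliaParams
    pump: PumpState

    def to_frame(self) -> "pandas.DataFrame":
        """Long-format table (r, z, w, u, psi) of in-tube samples."""
        import pandas as pd

        zz, rr = np.meshgrid(self.z_grid, self.r_grid, indexing="ij")
        m = self.mask
        return pd.DataFrame({
            "r": rr[m], "z": zz[m],
            "w": self.w[m], "u": self.u[m], "psi": self.psi[m],
        })


def compute_field(pump: PumpState, p: CiliaParams, *, n_r: int = 401,
                  n_z: int = 401, z_span: tuple = (0.0, 1.0)) -> FlowField:
    """Evaluate ``w``, ``u`` and ``psi`` on a rectangular (z, r) grid."""
    z = np.linspace(z_span[0], z_span[1], n_z)
    r = np.linspace(0.0, p.h_max, n_r)
    zz, rr = np.meshgrid(z, r, indexing="ij")
    h = tube_radius(zz, p)
    mask = rr <= h
    r_in = np.minimum(rr, h)
    h_, _, ww, _, dpdz, _ = _station(zz, pump.q, p)
    w = axial_velocity(r_in.ravel(), zz.ravel(), dpdz.ravel(), p).reshape(zz.shape)
    u = radial_velocity(r_in, zz, pump, p)
    psi = stream_function(r_in, zz, pump, p)
    w = np.where(mask, w, ww)
    u = np.where(mask, u, 0.0)
    psi = np.where(mask, psi, pump.q / 2.0)
    return FlowField(r_grid=r, z_grid=z, w=w, u=u, psi=psi, mask=mask,
                     params=p, pump=pump)


# ------------------------------------------------------------- stagnation

def stagnation_points(pump: PumpState, p: CiliaParams, *, n_z: int = 241,
                      n_r: int = 121, tol: float = 1e-9):
    """All wave-frame stagnation locations ``(r, z)`` with ``w = u = 0``.

    Interior points are found by scanning grid cells where both velocity
    components change sign, then polishing with a 2-D Newton solve; axis
    points (``u = 0`` by symmetry) come from 1-D root finding on
    ``w(0, z)``.  Deterministic ordering by z then r; an empty list means
    no trapping centre exists at this operating point.
    """
    from scipy.optimize import brentq, root

    found: list[tuple[float, float]] = []

    # axis: w(0, z) = 0
    z_line = np.linspace(0.0, 1.0, 4 * n_z + 1)
    w_line = np.array([
        plug_velocity(z, _station(z, pump.q, p)[4], p) if p.hp > 0
        else axial_velocity(0.0, z, _station(z, pump.q, p)[4], p)
        for z in z_line
    ])
    for i in range(len(z_line) - 1):
        if w_line[i] == 0.0:
            found.append((0.0, float(z_line[i] % 1.0)))
        elif w_line[i] * w_line[i + 1] < 0:
            f = lambda z: (plug_velocity(z, _station(z, pump.q, p)[4], p)
                           if p.hp > 0 else
                           axial_velocity(0.0, z, _station(z, pump.q, p)[4], p))
            zr = brentq(f, z_line[i], z_line[i + 1], xtol=tol)
            found.append((0.0, float(zr % 1.0)))

    # interior: cells where both w and u straddle zero
    z = np.linspace(0.0, 1.0, n_z)
    r = np.linspace(0.0, p.h_max, n_r)
    zz, rr = np.meshgrid(z, r, indexing="ij")
    h = tube_radius(zz, p)
    inside = rr < h
    r_in = np.minimum(rr, h)
    dpdz = _station(zz, pump.q, p)[4]
    w = axial_velocity(r_in.ravel(), zz.ravel(), dpdz.ravel(), p).reshape(zz.shape)
    u = radial_velocity(r_in, zz, pump, p)

    def fun(x):
        rr_, zz_ = x
        d = _station(zz_, pump.q, p)[4]
        return [axial_velocity(rr_, zz_, d, p),
                radial_velocity(rr_, zz_, pump, p)]

    for i in range(n_z - 1):
        for j in range(1, n_r - 1):
            cell_w = w[i:i + 2, j:j + 2]
            cell_u = u[i:i + 2, j:j + 2]
            if not np.all(inside[i:i + 2, j:j + 2]):
                continue
            if cell_w.min() < 0 < cell_w.max() and cell_u.min() < 0 < cell_u.max():
                x0 = [0.5 * (r[j] + r[j + 1]), 0.5 * (z[i] + z[i + 1])]
                sol = root(fun, x0, tol=1e-12)
                if not sol.success:
                    continue
                r_s, z_s = float(sol.x[0]), float(sol.x[1]) % 1.0
                if not (0 < r_s < tube_radius(z_s, p)):
                    continue
                if max(abs(v) for v in fun([r_s, z_s])) > 1e-8:
                    continue
                found.append((r_s, z_s))

    # dedupe and order by z then r
    out: list[tuple[float, float]] = []
    for r_s, z_s in found:
        if not any(abs(r_s - r0) < 1e-5 and
                   min(abs(z_s - z0), 1 - abs(z_s - z0)) < 1e-5
                   for r0, z0 in out):
            out.append((r_s, z_s))
    return sorted(((r_s, z_s) for r_s, z_s in out), key=lambda t: (t[1], t[0]))


# --------------------------------------------------------------- trapping

@dataclass
class TrappingMetrics:
    """Bolus census over one wavelength."""

    n_boluses: int
    total_area: float
    areas: list = field(default_factory=list)
    n_levels: int = 30
    grid_shape: tuple = (0, 0)


def trapping_metrics(pump: PumpState, p: CiliaParams, *, n_r: int = 401,
                     n_z: int = 401, n_levels: int = 30) -> TrappingMetrics:
    """Count and measure trapped boluses: closed psi-contours that touch
    neither the axis nor the wall.

    The field is contoured on a two-period extension so that a bolus
    straddling ``z = 0 (mod 1)`` appears as an ordinary closed contour;
    boluses are then counted in the window ``0.5 <= z_centroid < 1.5``
    (one full wavelength).  Nested closed contours belong to one bolus:
    only outermost polygons are counted, and the reported area is the sum
    of their areas (marching-squares extraction at ``n_levels`` evenly
    spaced levels between the field extrema).
    """
    from shapely.geometry import Point, Polygon
    from skimage import measure

    if n_r < 64 or n_z < 64:
        raise ResolutionError(
            "grid too coarse for contour extraction; use n_r, n_z >= 64"
        )
    if p.epsilon == 0.0:
        # uniform tube: all streamlines are periodic lines, no trapping
        return TrappingMetrics(n_boluses=0, total_area=0.0,
                               n_levels=n_levels, grid_shape=(n_z, n_r))

    field_ = compute_field(pump, p, n_r=n_r, n_z=2 * n_z - 1,
                           z_span=(0.0, 2.0))
    psi, mask = field_.psi, field_.mask
    r_grid, z_grid = field_.r_grid, field_.z_grid
    dr = r_grid[1] - r_grid[0]
    psi_in = psi[mask]
    lo, hi = float(psi_in.min()), float(psi_in.max())
    if hi - lo < 1e-14:
        return TrappingMetrics(n_boluses=0, total_area=0.0,
                               n_levels=n_levels, grid_shape=(n_z, n_r))
    levels = np.linspace(lo, hi, n_levels + 2)[1:-1]

    polys = []
    for level in levels:
        for contour in measure.find_contours(psi, level):
            if not np.allclose(contour[0], contour[-1]):
                continue
            z_c = np.interp(contour[:, 0], np.arange(len(z_grid)), z_grid)
            r_c = np.interp(contour[:, 1], np.arange(len(r_grid)), r_grid)
            if r_c.min() < 2.0 * dr:          # touches the axis
                continue
            h_c = tube_radius(z_c, p)
            if np.any(r_c > h_c - 2.0 * dr):  # touches the wall
                continue
            zc = float(z_c.mean())
            if not (0.5 <= zc < 1.5):         # one-period census window
                continue
            poly = Polygon(np.column_stack([z_c, r_c]))
            if poly.is_valid and poly.area > 0:
                polys.append(poly)

    # keep outermost polygons only (nested contours are the same bolus)
    polys.sort(key=lambda q: q.area, reverse=True)
    outer: list = []
    for poly in polys:
        rep = poly.representative_point()
        if not any(kept.contains(rep) for kept in outer):
            outer.append(poly)
    areas = [float(q.area) for q in outer]
    return TrappingMetrics(n_boluses=len(outer), total_area=float(sum(areas)),
                           areas=areas, n_levels=n_levels,
                           grid_shape=(n_z, n_r))
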