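"""Radial heat conduction in an infinite cylinder with a convective boundary.

A green-bean pod is approximated as an infinite cylinder of radius ``R``
heated by immersion in a stirred water bath.  The temperature field obeys
the Fourier equation in cylindrical coordinates,

    rho_eff * cp_eff * dT/dt = lambda_eff / r * d/dr ( r * dT/dr ),

with zero flux at the axis and a convective flux

    -lambda_eff * dT/dr |_{r=R} = h_ext * ( T_surface - T_bath )

at the outer face.  Thermophysical properties are computed once from the
proximate composition (Choi–Okos component correlations) and held
temperature-independent, which makes the problem linear: heating curves at
different bath temperatures collapse onto one curve in the reduced
temperature theta = (T - T0) / (Te - T0).

The solver is a cell-centered finite-volume scheme on control volumes of
equal radial width, advanced with explicit Euler steps chosen automatically
inside the stability bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CompositionError, StabilityError, ValidationError

__all__ = [
    "Composition",
    "ThermalProperties",
    "CylinderGeometry",
    "BathSegment",
    "BathProgram",
    "TemperatureField",
    "effective_properties",
    "solve_heat_transfer",
    "average_temperature",
    "reduced_temperature",
]


# ---------------------------------------------------------------------------
# Composition and Choi–Okos thermophysical properties
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Composition:
    """Proximate composition as mass fractions.

    If ``fat`` is omitted it closes the balance to 1.  Fractions must be
    non-negative and sum to 1 within 1e-6.
    """

    water: float
    carbohydrate: float = 0.0
    protein: float = 0.0
    ash: float = 0.0
    fat: float | None = None

    def __post_init__(self) -> None:
        partial = self.water + self.carbohydrate + self.protein + self.ash
        if self.fat is None:
            fat = 1.0 - partial
            if fat < -1e-6:
                raise CompositionError(
                    f"fractions sum to {partial:.6f} > 1; cannot close with fat"
                )
            object.__setattr__(self, "fat", max(fat, 0.0))
        fractions = self.as_dict()
        if any(x < 0 for x in fractions.values()):
            raise CompositionError(f"negative mass fraction in {fractions}")
        total = sum(fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise CompositionError(f"mass fractions sum to {total:.6f}, not 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "water": self.water,
            "carbohydrate": self.carbohydrate,
            "protein": self.protein,
            "ash": self.ash,
            "fat": self.fat,  # type: ignore[dict-item]
        }


#: Default green-bean proximate composition (USDA-style): 90 % water,
#: 7 % carbohydrate, 2 % protein, 0.6 % ash, remainder fat.
GREEN_BEAN = Composition(water=0.90, carbohydrate=0.07, protein=0.02, ash=0.006)


@dataclass(frozen=True)
class ThermalProperties:
    """Effective properties of the food matrix (temperature-independent)."""

    volumetric_heat_capacity: float  # J m^-3 K^-1  (rho_eff * cp_eff)
    thermal_conductivity: float      # W m^-1 K^-1  (lambda_eff)

    def __post_init__(self) -> None:
        if self.volumetric_heat_capacity <= 0 or self.thermal_conductivity <= 0:
            raise ValidationError("thermal properties must be strictly positive")

    @property
    def diffusivity(self) -> float:
        """Thermal diffusivity alpha = lambda / (rho*cp), m^2 s^-1."""
        return self.thermal_conductivity / self.volumetric_heat_capacity


# Choi–Okos component polynomials, T in deg C (valid -40..150 C).
# thermal conductivity W m^-1 K^-1; cp kJ kg^-1 K^-1; density kg m^-3
_CHOI_OKOS = {
    "water": {
        "k": (0.57109, 1.7625e-3, -6.7036e-6),
        "cp": (4.1762, -9.0864e-5, 5.4731e-6),
        "rho": (997.18, 3.1439e-3, -3.7574e-3),
    },
    "protein": {
        "k": (0.17881, 1.1958e-3, -2.7178e-6),
        "cp": (2.0082, 1.2089e-3, -1.3129e-6),
        "rho": (1329.9, -0.5184, 0.0),
    },
    "fat": {
        "k": (0.18071, -2.7604e-3, -1.7749e-7),
        "cp": (1.9842, 1.4733e-3, -4.8008e-6),
        "rho": (925.59, -0.41757, 0.0),
    },
    "carbohydrate": {
        "k": (0.20141, 1.3874e-3, -4.3312e-6),
        "cp": (1.5488, 1.9625e-3, -5.9399e-6),
        "rho": (1599.1, -0.31046, 0.0),
    },
    "ash": {
        "k": (0.32962, 1.4011e-3, -2.9069e-6),
        "cp": (1.0926, 1.8896e-3, -3.6817e-6),
        "rho": (2423.8, -0.28063, 0.0),
    },
}


def _poly(coeffs: tuple[float, float, float], t_c: float) -> float:
    a, b, c = coeffs
    return a + b * t_c + c * t_c * t_c


def effective_properties(
    composition: Composition, evaluation_temperature: float = 25.0
) -> ThermalProperties:
    """Effective volumetric heat capacity and conductivity from composition.

    Choi–Okos component correlations evaluated at ``evaluation_temperature``
    (deg C); components are combined mass-fraction-wise for cp, through the
    reciprocal mixture rule for density, and volume-fraction-wise (parallel
    model) for conductivity.
    """
    t = evaluation_temperature
    x = composition.as_dict()
    inv_rho = sum(x[c] / _poly(_CHOI_OKOS[c]["rho"], t) for c in x if x[c] > 0)
    rho = 1.0 / inv_rho
    cp = sum(x[c] * _poly(_CHOI_OKOS[c]["cp"], t) for c in x) * 1e3  # J/kg/K
    # volume fractions for the parallel conductivity model
    lam = 0.0
    for c, xc in x.items():
        if xc <= 0:
            continue
        phi = (xc / _poly(_CHOI_OKOS[c]["rho"], t)) * rho
        lam += phi * _poly(_CHOI_OKOS[c]["k"], t)
    return ThermalProperties(volumetric_heat_capacity=rho * cp, thermal_conductivity=lam)


# ---------------------------------------------------------------------------
# Geometry and bath program
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CylinderGeometry:
    """Infinite cylinder with ``n_cells`` control volumes of equal width."""

    radius: float
    n_cells: int = 5

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError("radius must be > 0")
        if self.n_cells < 2:
            raise ValidationError("n_cells must be >= 2")

    @property
    def dr(self) -> float:
        return self.radius / self.n_cells

    @property
    def cell_centers(self) -> np.ndarray:
        return (np.arange(self.n_cells) + 0.5) * self.dr

    @property
    def cell_edges(self) -> np.ndarray:
        return np.arange(self.n_cells + 1) * self.dr

    @property
    def cell_volumes(self) -> np.ndarray:
        """Annulus cross-section areas (volume per unit length), m^2."""
        edges = self.cell_edges
        return np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)


@dataclass(frozen=True)
class BathSegment:
    """One stage of the bath temperature program.

    With ``ramp=True`` the bath temperature moves linearly from its value at
    the end of the previous segment (or the product's initial temperature for
    the first segment) to ``temperature_c``; otherwise it is constant.
    """

    duration_s: float
    temperature_c: float
    ramp: bool = False

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("segment duration must be > 0")


@dataclass(frozen=True)
class BathProgram:
    """Initial product temperature, bath segments, and film coefficient."""

    initial_temperature_c: float
    segments: tuple[BathSegment, ...]
    heat_transfer_coefficient: float  # W m^-2 K^-1

    def __post_init__(self) -> None:
        if self.heat_transfer_coefficient <= 0:
            raise ValidationError("heat transfer coefficient must be > 0")
        if not self.segments:
            raise ValidationError("bath program needs at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))

    @classmethod
    def constant(
        cls, t0_c: float, bath_c: float, duration_s: float, hext: float
    ) -> "BathProgram":
        return cls(t0_c, (BathSegment(duration_s, bath_c),), hext)

    @property
    def duration(self) -> float:
        return sum(s.duration_s for s in self.segments)

    def bath_temperature(self, t: np.ndarray | float) -> np.ndarray:
        """Bath temperature (deg C) at time(s) ``t``; clamped at the ends."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty_like(t)
        start = 0.0
        prev = self.initial_temperature_c
        for i, seg in enumerate(self.segments):
            end = start + seg.duration_s
            mask = (t >= start) & (t <= end) if i == len(self.segments) - 1 else (
                (t >= start) & (t < end)
            )
            if seg.ramp:
                frac = np.clip((t[mask] - start) / seg.duration_s, 0.0, 1.0)
                out[mask] = prev + frac * (seg.temperature_c - prev)
            else:
                out[mask] = seg.temperature_c
            prev = seg.temperature_c
            start = end
        out[t > start] = prev
        out[t < 0] = self.initial_temperature_c
        return out

    def temperature_bounds(self) -> tuple[float, float]:
        temps = [self.initial_temperature_c] + [s.temperature_c for s in self.segments]
        return min(temps), max(temps)


# ---------------------------------------------------------------------------
# Temperature field
# ---------------------------------------------------------------------------

@dataclass
class TemperatureField:
    """Solution of the conduction problem on the cell-centered grid.

    ``temperatures`` has shape (n_times, n_cells), in deg C.
    """

    times: np.ndarray
    temperatures: np.ndarray
    cell_centers: np.ndarray
    cell_volumes: np.ndarray
    bath: BathProgram | None = None
    _weights: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValidationError("time grid must be 1-D and strictly increasing")
        if self.temperatures.shape != (self.times.size, self.cell_centers.size):
            raise ValidationError("temperature array shape mismatch")
        self._weights = self.cell_volumes / self.cell_volumes.sum()

    @property
    def n_cells(self) -> int:
        return self.cell_centers.size

    def cell_history(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(times, T_C) trajectory of cell ``i``."""
        return self.times, self.temperatures[:, i]

    def average(self) -> np.ndarray:
        """Volume-weighted mean temperature at each time, deg C."""
        return self.temperatures @ self._weights


def average_temperature(fld: TemperatureField) -> tuple[np.ndarray, np.ndarray]:
    """Volume-weighted average temperature series ``(time_s, T_C)``."""
    return fld.times, fld.average()


def reduced_temperature(t, t0: float, te: float):
    """Dimensionless temperature theta = (T - T0) / (Te - T0)."""
    if te == t0:
        raise ValidationError("Te must differ from T0 for reduced temperature")
    return (np.asarray(t, dtype=float) - t0) / (te - t0)


# ---------------------------------------------------------------------------
# Finite-volume solver
# ---------------------------------------------------------------------------

def _conductances(geometry: CylinderGeometry, props: ThermalProperties, hext: float):
    """Face conductances per unit length, W m^-1 K^-1.

    Interior face between cells i and i+1: G = lambda * 2*pi*r_face / dr.
    Outer face: convection in series with the half-cell conduction
    resistance so the flux is driven by the bath-to-node difference.
    """
    lam = props.thermal_conductivity
    dr = geometry.dr
    r_faces = geometry.cell_edges[1:-1]
    g_int = lam * 2.0 * np.pi * r_faces / dr
    r_out = geometry.radius
    u = 1.0 / (1.0 / hext + 0.5 * dr / lam)
    g_out = u * 2.0 * np.pi * r_out
    return g_int, g_out


def stable_dt(
    geometry: CylinderGeometry, props: ThermalProperties, hext: float
) -> float:
    """Largest explicit-Euler step keeping every update coefficient positive."""
    g_int, g_out = _conductances(geometry, props, hext)
    cap = props.volumetric_heat_capacity * geometry.cell_volumes
    g_sum = np.zeros(geometry.n_cells)
    g_sum[:-1] += g_int
    g_sum[1:] += g_int
    g_sum[-1] += g_out
    return float(np.min(cap / g_sum))


def solve_heat_transfer(
    geometry: CylinderGeometry,
    props: ThermalProperties,
    bath: BathProgram,
    t_end: float | None = None,
    dt: float | None = None,
    safety: float = 0.2,
) -> TemperatureField:
    """Integrate the conduction problem with explicit Euler steps.

    ``dt`` defaults to ``safety`` times the stability bound; a user-supplied
    ``dt`` is validated against the bound.  ``t_end`` defaults to the bath
    program duration.
    """
    if t_end is None:
        t_end = bath.duration
    if t_end <= 0:
        raise ValidationError("t_end must be > 0")
    hext = bath.heat_transfer_coefficient
    dt_max = stable_dt(geometry, props, hext)
    if dt is None:
        dt = safety * dt_max
    elif dt > dt_max:
        raise StabilityError(
            f"dt={dt:g} s exceeds the explicit stability bound {dt_max:g} s"
        )
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    n_steps = max(1, int(np.ceil(t_end / dt)))
    dt = t_end / n_steps
    times = np.linspace(0.0, t_end, n_steps + 1)

    g_int, g_out = _conductances(geometry, props, hext)
    cap = props.volumetric_heat_capacity * geometry.cell_volumes
    te = bath.bath_temperature(times)

    n = geometry.n_cells
    temps = np.empty((n_steps + 1, n))
    temps[0] = bath.initial_temperature_c
    t_now = temps[0].copy()
    for k in range(n_steps):
        flux = np.zeros(n)
        dT = np.diff(t_now)
        f_int = g_int * dT           # + means heat flows inward (i+1 -> i)
        flux[:-1] += f_int
        flux[1:] -= f_int
        flux[-1] += g_out * (te[k] - t_now[-1])
        t_now = t_now + dt * flux / cap
        temps[k + 1] = t_now
    return TemperatureField(
        times=times,
        temperatures=temps,
        cell_centers=geometry.cell_centers,
        cell_volumes=geometry.cell_volumes,
        bath=bath,
    )


def energy_balance_residual(
    fld: TemperatureField, geometry: CylinderGeometry, props: ThermalProperties
) -> float:
    """Relative mismatch between stored-enthalpy change and boundary inflow.

    Recomputes the time-integrated boundary flux with the same discrete
    operators as the solver; for the explicit scheme the two agree to
    round-off.
    """
    if fld.bath is None:
        raise ValidationError("field carries no bath program")
    hext = fld.bath.heat_transfer_coefficient
    _, g_out = _conductances(geometry, props, hext)
    cap = props.volumetric_heat_capacity * geometry.cell_volumes
    te = fld.bath.bath_temperature(fld.times)
    # explicit scheme: flux of step k uses the state at t_k
    steps_in = g_out * (te[:-1] - fld.temperatures[:-1, -1]) * np.diff(fld.times)
    inflow = steps_in.sum()
    stored = float(cap @ (fld.temperatures[-1] - fld.temperatures[0]))
    scale = max(abs(inflow), abs(stored), 1e-30)
    return abs(stored - inflow) / scale
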