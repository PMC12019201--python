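"""Exact 2D photoacoustic fields of fluid disks.

A uniformly illuminated circular absorber (an erythrocyte cross-section,
acoustically a fluid disk) embedded in an unbounded fluid emits a
monochromatic pressure wave.  Separating variables in polar coordinates and
matching pressure and normal particle velocity at the rim gives a closed-form
solution: the interior field is built from ``J0(ks r)`` and the exterior from
the outgoing Hankel function ``H0^(1)(kf r)``, both sharing the boundary
determinant

    D = J1(ks a) H0^(1)(kf a) - rho_hat*c_hat * J0(ks a) H1^(1)(kf a)

with ``rho_hat = rho_s/rho_f`` and ``c_hat = vs/vf``.  For a dilute
collection of disks the total field is approximated by linear superposition
of single-disk exterior fields (the discrete particle approach, DPA), which
deliberately ignores multiple scattering between the absorbers.

These closed forms are the reference oracle against which the iterative
Born-series solver is validated.

Units at the public surface: positions and radii in micrometres, frequencies
in MHz, sound speeds in m/s, densities in kg/m^3.  All physics is evaluated
in SI internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import hankel1, j0, j1

__all__ = [
    "AcousticMedium",
    "OpticalThermalParams",
    "Disk",
    "FrequencyGrid",
    "Spectrum",
    "FieldComputationError",
    "disk_field",
    "dpa_field",
    "analytic_spectrum",
]

UM = 1e-6  # micrometre in metres
MHZ = 1e6  # megahertz in hertz


class FieldComputationError(ValueError):
    """Raised when a field evaluation cannot produce a finite value."""


@dataclass(frozen=True)
class AcousticMedium:
    """Sound speeds and densities of the ambient fluid and the source interior.

    Parameters
    ----------
    vf, vs : float
        Speed of sound (m/s) in the surrounding fluid and inside the source.
    rho_f, rho_s : float
        Mass density (kg/m^3) of the surrounding fluid and the source.
    """

    vf: float = 1500.0
    vs: float = 1500.0
    rho_f: float = 1000.0
    rho_s: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("vf", "vs", "rho_f", "rho_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"AcousticMedium.{name} must be > 0")

    @property
    def rho_hat(self) -> float:
        """Density contrast rho_s / rho_f."""
        return self.rho_s / self.rho_f

    @property
    def c_hat(self) -> float:
        """Sound-speed contrast vs / vf."""
        return self.vs / self.vf

    def kf(self, f_mhz):
        """Ambient wavenumber 2*pi*f/vf in rad/m for ``f_mhz`` in MHz."""
        return 2.0 * np.pi * np.asarray(f_mhz, dtype=float) * MHZ / self.vf

    def ks(self, f_mhz):
        """Source-interior wavenumber 2*pi*f/vs in rad/m."""
        return 2.0 * np.pi * np.asarray(f_mhz, dtype=float) * MHZ / self.vs


@dataclass(frozen=True)
class OpticalThermalParams:
    """Optical and thermodynamic coefficients of the absorber.

    All default to one (dimensionless working units): ``I0`` light intensity,
    ``mu`` optical absorption coefficient, ``beta`` isobaric thermal
    expansion coefficient, ``Cp`` specific heat.
    """

    I0: float = 1.0
    mu: float = 1.0
    beta: float = 1.0
    Cp: float = 1.0

    def __post_init__(self) -> None:
        for name in ("I0", "mu", "beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"OpticalThermalParams.{name} must be >= 0")
        if not self.Cp > 0:
            raise ValueError("OpticalThermalParams.Cp must be > 0")

    def amplitude(self, vs: float) -> complex:
        """Analytic source amplitude A = i*mu*beta*I0*vs/Cp (purely imaginary
        for real inputs); ``vs`` in m/s."""
        return 1j * self.mu * self.beta * self.I0 * vs / self.Cp


@dataclass(frozen=True)
class Disk:
    """A circular absorber: ``center`` (x, y) in micrometres, ``radius`` in
    micrometres."""

    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 2.75

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("Disk.radius must be > 0")


@dataclass(frozen=True)
class FrequencyGrid:
    """Equally spaced, strictly increasing frequency lattice in MHz.

    The default band is 300 points f_k = k * (2197/300) MHz, k = 1..300,
    i.e. from 7.3233 to 2197 MHz in steps of about 7.32 MHz.
    """

    values: np.ndarray = field(
        default_factory=lambda: np.arange(1, 301) * (2197.0 / 300.0)
    )

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("FrequencyGrid.values must be a 1D array")
        if v.size > 1:
            d = np.diff(v)
            if not np.all(d > 0):
                raise ValueError("frequencies must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-9):
                raise ValueError("frequencies must be equally spaced")

    @classmethod
    def from_band(cls, f_min: float, f_max: float, n_points: int) -> "FrequencyGrid":
        return cls(np.linspace(f_min, f_max, n_points))

    @property
    def f_min(self) -> float:
        return float(self.values[0])

    @property
    def f_max(self) -> float:
        return float(self.values[-1])

    @property
    def n_points(self) -> int:
        return int(self.values.size)


@dataclass
class Spectrum:
    """Complex pressure versus frequency for one or more detectors.

    ``values`` has shape (n_detectors, n_frequencies).  ``converged`` is an
    optional per-frequency boolean record for iterative solves.
    """

    freqs: FrequencyGrid
    values: np.ndarray
    converged: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim == 1:
            v = v[None, :]
        if v.shape[1] != self.freqs.n_points:
            raise ValueError("values second axis must match the frequency grid")
        self.values = v

    @property
    def n_detectors(self) -> int:
        return int(self.values.shape[0])

    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    def to_csv(self, path, detector: int = 0, config_hash: str | None = None) -> None:
        """Write one detector's spectrum as CSV with columns
        frequency_MHz, real, imag, magnitude."""
        import pandas as pd

        row = self.values[detector]
        df = pd.DataFrame(
            {
                "frequency_MHz": self.freqs.values,
                "real": row.real,
                "imag": row.imag,
                "magnitude": np.abs(row),
            }
        )
        with open(path, "w") as fh:
            if config_hash is not None:
                fh.write(f"# config_hash: {config_hash}\n")
            df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Field evaluation


def _denominator(ks_a: float, kf_a: float, rho_hat: float, c_hat: float) -> complex:
    return j1(ks_a) * hankel1(0, kf_a) - rho_hat * c_hat * j0(ks_a) * hankel1(1, kf_a)


def _field_at_radius(r_m, f_mhz, radius_um, medium, optical):
    """Vectorized interior/exterior solution at radial distance ``r_m`` (metres)
    from the disk center."""
    a = radius_um * UM
    kf = float(medium.kf(f_mhz))
    ks = float(medium.ks(f_mhz))
    A = optical.amplitude(medium.vs)
    D = _denominator(ks * a, kf * a, medium.rho_hat, medium.c_hat)
    r = np.asarray(r_m, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    out = np.empty(r.shape, dtype=complex)
    inside = r <= a
    if inside.any():
        out[inside] = (A / ks) * (
            1.0
            + medium.rho_hat * medium.c_hat * j0(ks * r[inside]) * hankel1(1, kf * a) / D
        )
    if (~inside).any():
        out[~inside] = (A / ks) * j1(ks * a) * hankel1(0, kf * r[~inside]) / D
    if not np.all(np.isfinite(out)):
        raise FieldComputationError(
            f"non-finite disk field (boundary determinant D={D!r} at f={f_mhz} MHz)"
        )
    return complex(out[0]) if scalar else out


def disk_field(
    point,
    f_mhz: float,
    disk: Disk,
    medium: AcousticMedium,
    optical: OpticalThermalParams = OpticalThermalParams(),
) -> complex:
    """Exact monochromatic pressure of a single disk at ``point`` (x, y) in
    micrometres.

    Uses the interior branch when the point lies in the disk (r <= a) and the
    outgoing exterior branch otherwise; the two agree at the rim (pressure
    continuity).
    """
    if not f_mhz > 0:
        raise ValueError("frequency must be positive")
    dx = point[0] - disk.center[0]
    dy = point[1] - disk.center[1]
    r_m = math.hypot(dx, dy) * UM
    return _field_at_radius(r_m, f_mhz, disk.radius, medium, optical)


def dpa_field(
    point,
    disks: list[Disk],
    f_mhz: float,
    medium: AcousticMedium,
    optical: OpticalThermalParams = OpticalThermalParams(),
) -> complex:
    """Discrete-particle superposition: sum of single-disk exterior fields.

    Valid only at points exterior to every disk; raises ``ValueError`` when
    the point lies inside any absorber, because the superposition has no
    interior branch.
    """
    if not f_mhz > 0:
        raise ValueError("frequency must be positive")
    total = 0.0 + 0.0j
    for n, disk in enumerate(disks):
        dx = point[0] - disk.center[0]
        dy = point[1] - disk.center[1]
        r_um = math.hypot(dx, dy)
        if r_um <= disk.radius:
            raise ValueError(
                f"dpa_field point {point} lies inside disk {n} "
                "(the superposition is exterior-only)"
            )
        total += _field_at_radius(r_um * UM, f_mhz, disk.radius, medium, optical)
    return total


def analytic_spectrum(
    detector,
    freqs: FrequencyGrid,
    source,
    medium: AcousticMedium,
    optical: OpticalThermalParams = OpticalThermalParams(),
) -> Spectrum:
    """Closed-form spectrum at a detector position over a frequency grid.

    ``source`` is a single :class:`Disk` or a list of disks (DPA
    superposition).  No smoothing is applied; element ``k`` is exactly the
    pointwise field at ``freqs.values[k]``.
    """
    disks = [source] if isinstance(source, Disk) else list(source)
    values = np.empty(freqs.n_points, dtype=complex)
    for k, f in enumerate(freqs.values):
        values[k] = dpa_field(detector, disks, float(f), medium, optical)
    return Spectrum(freqs=freqs, values=values)
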