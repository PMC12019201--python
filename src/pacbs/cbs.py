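"""Convergent Born series (CBS) solver for the photoacoustic Helmholtz equation.

The monochromatic photoacoustic pressure psi satisfies a Helmholtz equation
with a heat-deposition source.  Adding a small imaginary part ``i*eps`` to
the background wavenumber and moving the compensating term into the
scattering potential yields

    (lap + kf^2 + i*eps) psi = -S - V psi,

with, inside an absorber of interior wavenumber ks,

    S = -i * mu*beta*I0*omega / Cp,     V = ks^2 - kf^2 - i*eps,

and S = 0, V = -i*eps outside.  The damped background Green's function is
diagonal in Fourier space, g(p) = 1 / (|p|^2 - kf^2 - i*eps), so the formal
solution psi = G (V psi + S) can be iterated with FFTs.  The plain Neumann
iteration (the traditional Born series, TBS) diverges for large or strong
scatterers; preconditioning with gamma = (i/eps) V gives the convergent
Born series update

    psi <- psi - gamma * ( psi - IFFT[ g * FFT[ V psi + S ] ] ),

which converges for arbitrary contrast provided eps >= max|ks^2 - kf^2|.
The i*eps damping cancels identically at the fixed point, so the converged
field solves the undamped equation.

Because the FFT imposes periodic boundaries, a sigmoid absorbing boundary
layer (ABL) frame multiplies the field after every update so that outgoing
waves die out before wrapping around.

Convergence is monitored on the center row of the lattice: the iteration
stops when sum|psi_new - psi_old| / sum|psi_old| over that row falls below a
threshold (1e-4 by default).

Units at the public surface: micrometres / MHz / (m/s); lattices and
wavenumbers are SI internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft

from .analytic import MHZ, UM, AcousticMedium, Disk, OpticalThermalParams

__all__ = [
    "SimGrid",
    "CBSConfig",
    "CBSWorkspace",
    "FieldSolution",
    "ConvergenceWarning",
    "NP_TO_DB",
    "source_map",
    "potential_map",
    "greens_ft",
    "abl_window",
    "build_workspace",
    "initial_field",
    "cbs_step",
    "total_error",
    "solve_cbs",
    "solve_tbs",
    "attenuation_coefficient",
    "save_field",
    "load_field",
]

#: decibels per neper, 20/ln(10)
NP_TO_DB = 20.0 / np.log(10.0)


class ConvergenceWarning(UserWarning):
    """Issued when an iterative solve stops without reaching the threshold."""


@dataclass(frozen=True)
class SimGrid:
    """Square pixel lattice with physical pitch.

    ``n`` pixels per axis (even, >= 32), pitch ``h_um`` in micrometres.
    Pixel ``i`` sits at physical coordinate ``(i - n/2) * h``, so the domain
    center coincides with lattice point ``(n/2, n/2)``.  The conjugate
    Fourier lattice is ``p = 2*pi*m/(n*h)`` in FFT ordering, max |p| = pi/h.
    """

    n: int = 2048
    h_um: float = 0.1

    def __post_init__(self) -> None:
        if self.n < 32 or self.n % 2:
            raise ValueError("SimGrid.n must be even and >= 32")
        if not self.h_um > 0:
            raise ValueError("SimGrid.h_um must be > 0")

    @property
    def h_m(self) -> float:
        return self.h_um * UM

    @property
    def extent_um(self) -> float:
        return self.n * self.h_um

    def coords_um(self) -> np.ndarray:
        """Per-axis pixel coordinates (i - n/2)*h in micrometres."""
        return (np.arange(self.n) - self.n // 2) * self.h_um

    def fourier_coords(self) -> np.ndarray:
        """Per-axis Fourier coordinates 2*pi*m/(n*h) in rad/m, FFT ordering."""
        return 2.0 * np.pi * sfft.fftfreq(self.n, d=self.h_m)

    @property
    def center_row(self) -> int:
        """0-based index of the convergence-monitor row (n/2 in 1-based
        counting, i.e. row 1024 on a 2048 lattice)."""
        return self.n // 2 - 1


@dataclass(frozen=True)
class CBSConfig:
    """Solver configuration.

    ``c_eps`` sets the damping through eps = c_eps * kf^2 (0.8 keeps
    eps >= max|ks^2 - kf^2| for all sound speeds between 1200 and 1950 m/s
    in a 1500 m/s ambient).  ``abl_thickness`` is the ABL frame depth in
    pixels and ``abl_kappa_np_cm`` the sigmoid steepness in Np/cm.
    """

    c_eps: float = 0.8
    error_threshold: float = 1e-4
    max_iter: int = 2000
    abl_thickness: int = 500
    abl_kappa_np_cm: float = 61.36e2

    def __post_init__(self) -> None:
        if not self.c_eps > 0:
            raise ValueError("CBSConfig.c_eps must be > 0")
        if not self.error_threshold > 0:
            raise ValueError("CBSConfig.error_threshold must be > 0")
        if self.max_iter < 1:
            raise ValueError("CBSConfig.max_iter must be >= 1")
        if self.abl_thickness < 0:
            raise ValueError("CBSConfig.abl_thickness must be >= 0")

    def epsilon(self, kf: float) -> float:
        """Damping parameter eps = c_eps * kf^2 (kf in rad/m)."""
        return self.c_eps * kf * kf

    def validate_for_grid(self, grid: SimGrid) -> None:
        if self.abl_thickness >= grid.n // 2:
            raise ValueError(
                f"ABL thickness d={self.abl_thickness} must be < n/2 = {grid.n // 2}"
            )


@dataclass
class CBSWorkspace:
    """Precomputed per-frequency operator maps.

    ``S_map`` source term, ``V_map`` scattering potential, ``greens_ft``
    Fourier-domain Green's function on the FFT-ordered p lattice,
    ``gamma_map`` = (i/eps) V, ``abl_window`` real taper in [0, 1].
    """

    grid: SimGrid
    f_mhz: float
    epsilon: float
    kf: float
    S_map: np.ndarray
    V_map: np.ndarray
    greens_ft: np.ndarray
    gamma_map: np.ndarray
    abl_window: np.ndarray


@dataclass
class FieldSolution:
    """Converged (or abandoned) complex pressure field with its error trace."""

    psi: np.ndarray
    iterations: int
    error_trace: np.ndarray
    converged: bool
    f_mhz: float
    grid: SimGrid
    medium: AcousticMedium
    epsilon: float
    method: str = "cbs"

    def center_line(self) -> np.ndarray:
        return self.psi[self.grid.center_row, :]


# ---------------------------------------------------------------------------
# Operator maps


def _disk_mask(grid: SimGrid, disks: list[Disk]) -> np.ndarray:
    """Boolean lattice: pixel center within some disk radius (no
    anti-aliasing; boundary-pixel ambiguity is O(h/a))."""
    n, h = grid.n, grid.h_um
    mask = np.zeros((n, n), dtype=bool)
    x = grid.coords_um()
    for disk in disks:
        cx, cy = disk.center
        a = disk.radius
        # bounding-box slice keeps many-disk rasterization O(N * (a/h)^2)
        i0 = max(0, int(np.floor((cx - a) / h)) + n // 2 - 1)
        i1 = min(n, int(np.ceil((cx + a) / h)) + n // 2 + 2)
        j0 = max(0, int(np.floor((cy - a) / h)) + n // 2 - 1)
        j1 = min(n, int(np.ceil((cy + a) / h)) + n // 2 + 2)
        if i0 >= i1 or j0 >= j1:
            continue
        dx = x[i0:i1, None] - cx
        dy = x[None, j0:j1] - cy
        mask[i0:i1, j0:j1] |= dx * dx + dy * dy <= a * a
    return mask


def _check_disks_in_interior(grid: SimGrid, disks: list[Disk], d: int) -> None:
    half = grid.extent_um / 2.0
    lim = half - d * grid.h_um
    for k, disk in enumerate(disks):
        if max(abs(disk.center[0]), abs(disk.center[1])) + disk.radius > lim:
            warnings.warn(
                f"disk {k} extends into the ABL frame; fields there are "
                "deliberately damped",
                stacklevel=3,
            )


def source_map(
    grid: SimGrid,
    disks: list[Disk],
    optical: OpticalThermalParams,
    f_mhz: float,
) -> np.ndarray:
    """Heat-deposition source lattice: -i*mu*beta*I0*omega/Cp inside the
    absorbers, zero elsewhere (omega = 2*pi*f in rad/s)."""
    omega = 2.0 * np.pi * f_mhz * MHZ
    value = -1j * optical.mu * optical.beta * optical.I0 * omega / optical.Cp
    S = np.zeros((grid.n, grid.n), dtype=complex)
    if disks:
        S[_disk_mask(grid, disks)] = value
    return S


def potential_map(
    grid: SimGrid,
    disks: list[Disk],
    medium: AcousticMedium,
    f_mhz: float,
    epsilon: float,
) -> np.ndarray:
    """Scattering potential lattice: ks^2 - kf^2 - i*eps inside the absorbers,
    -i*eps outside.  Raises when eps violates the convergence guarantee
    eps >= max|ks^2 - kf^2|."""
    if not epsilon > 0:
        raise ValueError("epsilon must be > 0")
    kf = float(medium.kf(f_mhz))
    ks = float(medium.ks(f_mhz))
    contrast = ks * ks - kf * kf
    if abs(contrast) > epsilon:
        raise ValueError(
            f"epsilon={epsilon:.4g} < |ks^2-kf^2|={abs(contrast):.4g}: "
            "convergence guarantee violated"
        )
    V = np.full((grid.n, grid.n), -1j * epsilon, dtype=complex)
    if disks:
        V[_disk_mask(grid, disks)] = contrast - 1j * epsilon
    return V


def greens_ft(grid: SimGrid, kf: float, epsilon: float) -> np.ndarray:
    """Fourier-domain Green's function 1/(|p|^2 - kf^2 - i*eps) on the grid's
    p lattice in FFT-native ordering (kf in rad/m)."""
    if not epsilon > 0:
        raise ValueError("epsilon must be > 0")
    p = grid.fourier_coords()
    p2 = p[:, None] ** 2 + p[None, :] ** 2
    return 1.0 / (p2 - kf * kf - 1j * epsilon)


def abl_window(grid: SimGrid, d: int, kappa_np_cm: float) -> np.ndarray:
    """Separable sigmoid absorbing-boundary window.

    Exactly 1 on the interior (n-2d)^2 region; within the d-pixel frame each
    axis tapers as 1/(1 + exp(-kappa*(x - d*h/2))) where x is the physical
    distance from the outer boundary and kappa is in Np/cm.  The 2D window
    is the product of the two per-axis profiles.
    """
    if d >= grid.n // 2:
        raise ValueError("ABL thickness must be < n/2")
    prof = np.ones(grid.n)
    if d > 0:
        kappa_per_m = kappa_np_cm * 100.0
        x = np.arange(d) * grid.h_m  # distance of pixel i from outer boundary
        half = 0.5 * d * grid.h_m
        sig = 1.0 / (1.0 + np.exp(-kappa_per_m * (x - half)))
        prof[:d] = sig
        prof[grid.n - d :] = sig[::-1]
    return prof[:, None] * prof[None, :]


def build_workspace(
    grid: SimGrid,
    disks: list[Disk],
    medium: AcousticMedium,
    optical: OpticalThermalParams,
    f_mhz: float,
    config: CBSConfig,
) -> CBSWorkspace:
    """Assemble all per-frequency operator maps (eps = c_eps * kf^2 is
    frequency dependent, so every map is rebuilt per frequency)."""
    config.validate_for_grid(grid)
    _check_disks_in_interior(grid, disks, config.abl_thickness)
    kf = float(medium.kf(f_mhz))
    eps = config.epsilon(kf)
    V = potential_map(grid, disks, medium, f_mhz, eps)
    return CBSWorkspace(
        grid=grid,
        f_mhz=f_mhz,
        epsilon=eps,
        kf=kf,
        S_map=source_map(grid, disks, optical, f_mhz),
        V_map=V,
        greens_ft=greens_ft(grid, kf, eps),
        gamma_map=(1j / eps) * V,
        abl_window=abl_window(grid, config.abl_thickness, config.abl_kappa_np_cm),
    )


# ---------------------------------------------------------------------------
# Iteration


def initial_field(ws: CBSWorkspace) -> np.ndarray:
    """Starting field psi0 = gamma * IFFT[ g * FFT[S] ] (all element-wise)."""
    return ws.gamma_map * sfft.ifft2(ws.greens_ft * sfft.fft2(ws.S_map))


def cbs_step(psi: np.ndarray, ws: CBSWorkspace) -> np.ndarray:
    """One preconditioned update, followed by the ABL window.

    psi <- ABL * [ psi - gamma * ( psi - IFFT[ g * FFT[ V psi + S ] ] ) ]
    """
    work = ws.V_map * psi + ws.S_map
    work = sfft.ifft2(ws.greens_ft * sfft.fft2(work))
    if not np.all(np.isfinite(work)):
        raise FloatingPointError("non-finite value after Green's-function convolution")
    out = ws.abl_window * (psi - ws.gamma_map * (psi - work))
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite value after preconditioned update")
    return out


def total_error(psi_new: np.ndarray, psi_old: np.ndarray, grid: SimGrid) -> float:
    """Relative center-row change sum|new - old| / sum|old| used as the
    convergence metric."""
    if psi_new.shape != psi_old.shape:
        raise ValueError("field lattices must have the same shape")
    c = grid.center_row
    denom = float(np.abs(psi_old[c, :]).sum())
    if denom == 0.0:
        raise ZeroDivisionError("total_error undefined for an all-zero old field")
    return float(np.abs(psi_new[c, :] - psi_old[c, :]).sum()) / denom


def _row_error(psi_new: np.ndarray, psi_old: np.ndarray, grid: SimGrid) -> float:
    """total_error with the zero-source special case (0 -> 0 counts as
    converged rather than undefined)."""
    c = grid.center_row
    denom = float(np.abs(psi_old[c, :]).sum())
    num = float(np.abs(psi_new[c, :] - psi_old[c, :]).sum())
    if denom == 0.0:
        return 0.0 if num == 0.0 else np.inf
    return num / denom


def solve_cbs(
    disks: list[Disk],
    medium: AcousticMedium,
    optical: OpticalThermalParams,
    f_mhz: float,
    grid: SimGrid,
    config: CBSConfig = CBSConfig(),
) -> FieldSolution:
    """Iterate the convergent Born series to steady state.

    Starts from the preconditioned first term, applies :func:`cbs_step`
    until the center-row error drops below ``config.error_threshold`` or
    ``config.max_iter`` is reached.  Non-convergence sets
    ``converged=False`` with a warning; it never raises.
    """
    ws = build_workspace(grid, disks, medium, optical, f_mhz, config)
    psi = ws.abl_window * initial_field(ws)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        new = cbs_step(psi, ws)
        err = _row_error(new, psi, grid)
        trace.append(err)
        psi = new
        if err < config.error_threshold:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"CBS did not reach threshold {config.error_threshold} within "
            f"{config.max_iter} iterations (last error {trace[-1]:.3e})",
            ConvergenceWarning,
            stacklevel=2,
        )
    return FieldSolution(
        psi=psi,
        iterations=it,
        error_trace=np.asarray(trace),
        converged=converged,
        f_mhz=f_mhz,
        grid=grid,
        medium=medium,
        epsilon=ws.epsilon,
        method="cbs",
    )


def solve_tbs(
    disks: list[Disk],
    medium: AcousticMedium,
    optical: OpticalThermalParams,
    f_mhz: float,
    grid: SimGrid,
    config: CBSConfig = CBSConfig(),
) -> FieldSolution:
    """Partial sums of the traditional (unpreconditioned) Born series,
    psi <- IFFT[ g * FFT[ V psi + S ] ], for divergence demonstration.

    Divergence is flagged (``converged=False``) when the center-row error
    grows for 10 consecutive iterations or overflows; convergence uses the
    same threshold as the CBS solve.
    """
    ws = build_workspace(grid, disks, medium, optical, f_mhz, config)
    psi = ws.abl_window * sfft.ifft2(ws.greens_ft * sfft.fft2(ws.S_map))
    trace: list[float] = []
    converged = False
    diverged = False
    growth = 0
    it = 0
    for it in range(1, config.max_iter + 1):
        work = sfft.ifft2(ws.greens_ft * sfft.fft2(ws.V_map * psi + ws.S_map))
        new = ws.abl_window * work
        if not np.all(np.isfinite(new)):
            diverged = True
            trace.append(np.inf)
            break
        err = _row_error(new, psi, grid)
        trace.append(err)
        psi = new
        if err < config.error_threshold:
            converged = True
            break
        growth = growth + 1 if len(trace) > 1 and err > trace[-2] else 0
        if growth >= 10 or err > 1e6:
            diverged = True
            break
    if not converged:
        reason = "diverged" if diverged else "did not converge"
        warnings.warn(
            f"TBS {reason} after {it} iterations (last error {trace[-1]:.3e})",
            ConvergenceWarning,
            stacklevel=2,
        )
    return FieldSolution(
        psi=psi,
        iterations=it,
        error_trace=np.asarray(trace),
        converged=converged,
        f_mhz=f_mhz,
        grid=grid,
        medium=medium,
        epsilon=ws.epsilon,
        method="tbs",
    )


def attenuation_coefficient(epsilon: float, kf: float) -> float:
    """Effective background attenuation alpha = eps/(2*kf) in Np/m implied by
    the i*eps damping (kf in rad/m)."""
    if not kf > 0:
        raise ValueError("kf must be > 0")
    return epsilon / (2.0 * kf)


# ---------------------------------------------------------------------------
# Field I/O (HDF5)


def save_field(solution: FieldSolution, path, config_hash: str | None = None) -> None:
    """Write a solution as HDF5: /psi_real, /psi_imag, /error_trace plus
    scalar attributes describing the run."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("psi_real", data=solution.psi.real, compression="gzip")
        fh.create_dataset("psi_imag", data=solution.psi.imag, compression="gzip")
        fh.create_dataset("error_trace", data=solution.error_trace)
        fh.attrs.update(
            {
                "f": solution.f_mhz,
                "vs": solution.medium.vs,
                "vf": solution.medium.vf,
                "n": solution.grid.n,
                "h": solution.grid.h_um,
                "epsilon": solution.epsilon,
                "iterations": solution.iterations,
                "converged": solution.converged,
                "method": solution.method,
            }
        )
        if config_hash is not None:
            fh.attrs["config_hash"] = config_hash


def load_field(path) -> FieldSolution:
    """Read a solution written by :func:`save_field`."""
    import h5py

    with h5py.File(path, "r") as fh:
        psi = fh["psi_real"][...] + 1j * fh["psi_imag"][...]
        trace = fh["error_trace"][...]
        at = dict(fh.attrs)
    return FieldSolution(
        psi=psi,
        iterations=int(at["iterations"]),
        error_trace=trace,
        converged=bool(at["converged"]),
        f_mhz=float(at["f"]),
        grid=SimGrid(n=int(at["n"]), h_um=float(at["h"])),
        medium=AcousticMedium(vf=float(at["vf"]), vs=float(at["vs"])),
        epsilon=float(at["epsilon"]),
        method=str(at.get("method", "cbs")),
    )
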