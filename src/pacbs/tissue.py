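"""Metropolis hard-disk packing of blood-smear phantoms.

A smear is modelled as N equal-radius, non-overlapping disks (erythrocyte
cross-sections) placed in a square or circular region of interest (ROI) at a
target area fraction (the 2D analogue of hematocrit; 40% is typical).

Disks are first thrown down uniformly at random with overlaps allowed.  Each
overlapping pair contributes a fixed energy V_ij (1000 in units of kB*T, so
overlap creation is effectively forbidden while overlap removal is always
accepted).  Single-disk teleport moves — pick a disk, propose a fresh
uniform position — are accepted by the Metropolis rule on the energy change,
and the chain runs until the total energy is exactly zero, i.e. no pair of
disk interiors intersects.  Tangency is legal: overlap means center distance
strictly below the sum of radii.

Disks are kept fully inside the ROI (centers sampled from the
radius-eroded region), matching the packing arithmetic used for the
133-disk, 50-micron circular phantom.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .analytic import Disk

__all__ = [
    "ROISpec",
    "PackingConfig",
    "TissueRealization",
    "PackingError",
    "n_disks_for_fraction",
    "overlap_energy",
    "metropolis_accept",
    "pack_disks",
    "write_phantom",
    "read_phantom",
]


class PackingError(RuntimeError):
    """Raised when the proposal budget runs out before reaching zero energy."""


@dataclass(frozen=True)
class ROISpec:
    """Region of interest: ``shape`` is 'square' (``size`` = side length, um)
    or 'circle' (``size`` = radius, um); ``origin`` is its center in the
    simulation domain."""

    shape: str = "circle"
    size: float = 50.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.shape not in ("square", "circle"):
            raise ValueError("ROISpec.shape must be 'square' or 'circle'")
        if not self.size > 0:
            raise ValueError("ROISpec.size must be > 0")

    def area(self) -> float:
        """ROI area in um^2."""
        if self.shape == "square":
            return self.size * self.size
        return math.pi * self.size * self.size

    def contains_disk(self, center: tuple[float, float], radius: float) -> bool:
        """Whether a disk of given center/radius lies fully inside the ROI."""
        dx = center[0] - self.origin[0]
        dy = center[1] - self.origin[1]
        if self.shape == "square":
            half = self.size / 2.0 - radius
            return abs(dx) <= half and abs(dy) <= half
        return math.hypot(dx, dy) <= self.size - radius

    def sample_center(self, radius: float, rng: np.random.Generator) -> np.ndarray:
        """Uniform random disk center in the radius-eroded ROI."""
        if self.shape == "square":
            half = self.size / 2.0 - radius
            if half <= 0:
                raise ValueError("disk does not fit in the square ROI")
            return np.asarray(self.origin) + rng.uniform(-half, half, size=2)
        rmax = self.size - radius
        if rmax <= 0:
            raise ValueError("disk does not fit in the circular ROI")
        # uniform over the disk of radius rmax
        r = rmax * math.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * math.pi)
        return np.asarray(self.origin) + r * np.array(
            [math.cos(theta), math.sin(theta)]
        )


@dataclass(frozen=True)
class PackingConfig:
    """Chain parameters: disk count and radius (um), pair energy in kB*T,
    proposal budget (sweeps of ``n_disks`` proposals each) and RNG seed."""

    n_disks: int = 133
    radius: float = 2.75
    overlap_energy_unit: float = 1000.0
    max_sweeps: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_disks < 1:
            raise ValueError("PackingConfig.n_disks must be >= 1")
        if not self.radius > 0:
            raise ValueError("PackingConfig.radius must be > 0")
        if not self.overlap_energy_unit > 0:
            raise ValueError("PackingConfig.overlap_energy_unit must be > 0")


@dataclass
class TissueRealization:
    """A packed, overlap-free arrangement of equal disks inside an ROI."""

    disks: list[Disk]
    roi: ROISpec
    seed: int
    final_energy: float

    @property
    def n_disks(self) -> int:
        return len(self.disks)

    def area_fraction(self) -> float:
        return sum(math.pi * d.radius**2 for d in self.disks) / self.roi.area()


def n_disks_for_fraction(roi: ROISpec, radius: float, fraction: float) -> int:
    """Smallest N with N*pi*radius^2 >= fraction*area(roi).

    Warns above 55% achieved coverage, where random sequential hard-disk
    packing may fail to terminate.
    """
    if not 0.0 < fraction < 0.9:
        raise ValueError("fraction must be in (0, 0.9)")
    disk_area = math.pi * radius * radius
    n = math.ceil(fraction * roi.area() / disk_area - 1e-12)
    if n * disk_area / roi.area() > 0.55:
        warnings.warn(
            f"target area fraction {n * disk_area / roi.area():.2f} > 0.55: "
            "packing may not terminate",
            stacklevel=2,
        )
    return n


def _overlap_pairs(centers: np.ndarray, radii: np.ndarray) -> int:
    """Number of unordered overlapping pairs (strict inequality)."""
    d2 = np.sum((centers[:, None, :] - centers[None, :, :]) ** 2, axis=-1)
    lim = (radii[:, None] + radii[None, :]) ** 2
    over = d2 < lim
    np.fill_diagonal(over, False)
    return int(over.sum()) // 2


def overlap_energy(disks: list[Disk], config: PackingConfig) -> float:
    """Total interaction energy in kB*T: pair energy times the number of
    unordered overlapping pairs.  Tangent disks do not overlap."""
    if len(disks) < 2:
        return 0.0
    centers = np.array([d.center for d in disks], dtype=float)
    radii = np.array([d.radius for d in disks], dtype=float)
    return config.overlap_energy_unit * _overlap_pairs(centers, radii)


def metropolis_accept(delta_E: float, rng_draw: float) -> bool:
    """Metropolis rule in kB*T units: always accept energy decreases,
    otherwise accept when the uniform draw is <= exp(-delta_E)."""
    if delta_E < 0.0:
        return True
    return rng_draw <= math.exp(-min(delta_E, 700.0))


def pack_disks(roi: ROISpec, config: PackingConfig) -> TissueRealization:
    """Run the Metropolis chain until the configuration is overlap-free.

    Initial positions are uniform in the (eroded) ROI with overlaps allowed;
    proposals teleport one randomly chosen disk to a fresh uniform position.
    The chain is fully deterministic given ``config.seed``.  Raises
    :class:`PackingError` with the remaining energy and acceptance counts if
    the proposal budget is exhausted first.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_disks
    a = config.radius
    centers = np.array([roi.sample_center(a, rng) for _ in range(n)])
    radii = np.full(n, a)

    def overlaps_of(i: int, pos: np.ndarray) -> int:
        d2 = np.sum((centers - pos) ** 2, axis=1)
        d2[i] = np.inf
        return int(np.count_nonzero(d2 < (radii + a) ** 2))

    pair_count = _overlap_pairs(centers, radii) if n > 1 else 0
    proposals = accepted = 0
    budget = config.max_sweeps * n
    while pair_count > 0:
        if proposals >= budget:
            raise PackingError(
                f"packing budget exhausted after {proposals} proposals "
                f"({accepted} accepted); remaining energy "
                f"{pair_count * config.overlap_energy_unit:.0f} kB*T"
            )
        i = int(rng.integers(n))
        new_pos = roi.sample_center(a, rng)
        delta_pairs = overlaps_of(i, new_pos) - overlaps_of(i, centers[i])
        delta_E = config.overlap_energy_unit * delta_pairs
        proposals += 1
        if metropolis_accept(delta_E, float(rng.uniform())):
            centers[i] = new_pos
            pair_count += delta_pairs
            accepted += 1

    disks = [Disk(center=(float(c[0]), float(c[1])), radius=a) for c in centers]
    return TissueRealization(
        disks=disks, roi=roi, seed=config.seed, final_energy=0.0
    )


# ---------------------------------------------------------------------------
# Phantom exchange format: CSV of disk geometry + JSON sidecar of metadata


def write_phantom(realization: TissueRealization, csv_path) -> None:
    """Write disks as CSV (x_um, y_um, radius_um) with a JSON sidecar holding
    ROI shape/size/origin, seed and achieved area fraction."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "x_um": [d.center[0] for d in realization.disks],
            "y_um": [d.center[1] for d in realization.disks],
            "radius_um": [d.radius for d in realization.disks],
        }
    )
    df.to_csv(csv_path, index=False)
    meta = {
        "roi_shape": realization.roi.shape,
        "roi_size_um": realization.roi.size,
        "roi_origin_um": list(realization.roi.origin),
        "seed": realization.seed,
        "n_disks": realization.n_disks,
        "area_fraction": realization.area_fraction(),
        "final_energy": realization.final_energy,
    }
    with open(_sidecar_path(csv_path), "w") as fh:
        json.dump(meta, fh, indent=2)


def read_phantom(csv_path) -> TissueRealization:
    """Read a phantom written by :func:`write_phantom`."""
    import pandas as pd

    df = pd.read_csv(csv_path, comment="#")
    disks = [
        Disk(center=(float(r.x_um), float(r.y_um)), radius=float(r.radius_um))
        for r in df.itertuples()
    ]
    with open(_sidecar_path(csv_path)) as fh:
        meta = json.load(fh)
    roi = ROISpec(
        shape=meta["roi_shape"],
        size=float(meta["roi_size_um"]),
        origin=tuple(meta["roi_origin_um"]),
    )
    return TissueRealization(
        disks=disks,
        roi=roi,
        seed=int(meta["seed"]),
        final_energy=float(meta["final_energy"]),
    )


def _sidecar_path(csv_path) -> str:
    s = str(csv_path)
    return (s[: -len(".csv")] if s.endswith(".csv") else s) + ".json"
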