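"""Simulation world: physical constants, toroidal lattice, PSD regions, obstacle fields.

Units are fixed package-wide: time in ms, length in µm, binding energy in
units of k_B·T.  The membrane is a square mesh with toroidal (periodic)
boundary conditions; lattice site ``(i, j)`` covers the physical area
``[i·dx, (i+1)·dx) × [j·dx, (j+1)·dx)``.  The lattice spacing ``dx`` is tied
to the time step and free diffusion coefficient through the expected
displacement of a normally diffusing molecule, ``dx = sqrt(4·D_free·dt)``,
so a free walker taking one lattice step per ``dt`` has MSD = 4·D_free·t.
"""

from __future__ import annotations

import hashlib
import io as _io
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DEFAULT_DT",
    "DEFAULT_D_FREE",
    "DEFAULT_RECORD_INTERVAL",
    "SimulationConfig",
    "PSDRegion",
    "ObstacleField",
    "make_config",
    "make_obstacle_field",
    "assign_binding",
]

#: Default Monte Carlo time step, ms (1 µs).
DEFAULT_DT = 1.0e-3
#: Default unobstructed diffusion coefficient of the receptor, µm²/ms.
DEFAULT_D_FREE = 0.200e-3
#: Default position-recording interval, ms.
DEFAULT_RECORD_INTERVAL = 1.0

# Site states used by the engine kernels.
FREE, OBSTACLE, BINDABLE = 0, 1, 2


class ValidationError(ValueError):
    """Raised when a configuration or field argument is out of range."""


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValidationError(f"{name}: {msg}")


@dataclass(frozen=True)
class SimulationConfig:
    """Global physical constants and run geometry.

    Parameters
    ----------
    width, height
        Membrane size in µm.
    duration
        Total simulated time in ms.
    n_walkers
        Ensemble size (walkers are strictly non-interacting).
    dt
        Monte Carlo time step in ms.
    D_free
        Free diffusion coefficient in µm²/ms.
    record_interval
        Interval between recorded positions in ms; must be an integer
        multiple of ``dt``.
    seed
        Master RNG seed; per-walker streams are derived from it.
    """

    width: float
    height: float
    duration: float
    n_walkers: int = 400
    dt: float = DEFAULT_DT
    D_free: float = DEFAULT_D_FREE
    record_interval: float = DEFAULT_RECORD_INTERVAL
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("width", "height", "duration", "dt", "D_free", "record_interval"):
            _require(getattr(self, name) > 0, name, "must be positive")
        _require(self.n_walkers >= 1, "n_walkers", "must be >= 1")
        ratio = self.record_interval / self.dt
        _require(
            abs(ratio - round(ratio)) < 1e-9 * max(1.0, ratio),
            "record_interval",
            f"must be an integer multiple of dt (got ratio {ratio})",
        )
        _require(self.nx >= 2 and self.ny >= 2, "width", "grid must be at least 2x2 sites")

    @property
    def dx(self) -> float:
        """Lattice spacing in µm: expected per-step displacement sqrt(4·D_free·dt)."""
        return float(np.sqrt(4.0 * self.D_free * self.dt))

    @property
    def nx(self) -> int:
        return int(round(self.width / self.dx))

    @property
    def ny(self) -> int:
        return int(round(self.height / self.dx))

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def record_every(self) -> int:
        return int(round(self.record_interval / self.dt))

    @property
    def n_records(self) -> int:
        """Number of recorded instants after t=0."""
        return self.n_steps // self.record_every

    @property
    def times(self) -> np.ndarray:
        """Recorded instants in ms, starting at 0."""
        return np.arange(self.n_records + 1) * self.record_interval


def make_config(
    width: float,
    height: float,
    duration: float,
    n_walkers: int = 400,
    dt: float = DEFAULT_DT,
    D_free: float = DEFAULT_D_FREE,
    record_interval: float = DEFAULT_RECORD_INTERVAL,
    seed: int = 0,
) -> SimulationConfig:
    """Build and validate a :class:`SimulationConfig` (functional alias)."""
    return SimulationConfig(
        width=width,
        height=height,
        duration=duration,
        n_walkers=n_walkers,
        dt=dt,
        D_free=D_free,
        record_interval=record_interval,
        seed=seed,
    )


@dataclass(frozen=True)
class PSDRegion:
    """Axis-aligned rectangular region in µm, half-open on both axes."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        _require(0 <= self.x0 < self.x1, "x0", "requires 0 <= x0 < x1")
        _require(0 <= self.y0 < self.y1, "y0", "requires 0 <= y0 < y1")

    @classmethod
    def centered(cls, config: SimulationConfig, width: float, height: float | None = None) -> "PSDRegion":
        """A width × height rectangle centered on the membrane."""
        height = width if height is None else height
        return cls(
            (config.width - width) / 2.0,
            (config.height - height) / 2.0,
            (config.width + width) / 2.0,
            (config.height + height) / 2.0,
        )

    def site_bounds(self, config: SimulationConfig) -> tuple[int, int, int, int]:
        """Half-open site-index bounds (i0, i1, j0, j1) covering the region."""
        dx = config.dx
        i0, i1 = int(round(self.x0 / dx)), int(round(self.x1 / dx))
        j0, j1 = int(round(self.y0 / dx)), int(round(self.y1 / dx))
        _require(i1 <= config.nx and j1 <= config.ny, "x1", "region extends beyond the membrane")
        return i0, i1, j0, j1

    def contains_sites(self, i: np.ndarray, j: np.ndarray, config: SimulationConfig) -> np.ndarray:
        """Half-open membership test for wrapped site indices."""
        i0, i1, j0, j1 = self.site_bounds(config)
        return (i >= i0) & (i < i1) & (j >= j0) & (j < j1)

    def n_sites(self, config: SimulationConfig) -> int:
        i0, i1, j0, j1 = self.site_bounds(config)
        return (i1 - i0) * (j1 - j0)


@dataclass(frozen=True)
class ObstacleField:
    """Static obstacle / binding-site grids realizing a crowding fraction C.

    ``occupied`` marks sites holding an immobile PSD molecule; a subset of
    these may be ``bindable`` with a per-site binding energy in k_B·T.
    Bindable sites are still excluded volume for unbound walkers unless the
    walker binds on contact.
    """

    config: SimulationConfig
    occupied: np.ndarray
    bindable: np.ndarray
    energy: np.ndarray
    C_target: float
    P_target: float = 0.0
    arrangement: str = "random"
    region: PSDRegion | None = None

    def __post_init__(self) -> None:
        _require(self.occupied.shape == (self.config.nx, self.config.ny), "occupied", "grid shape mismatch")
        _require(bool(np.all(self.occupied[self.bindable])), "bindable", "bindable sites must be occupied")
        _require(bool(np.all(self.energy >= 0)), "energy", "binding energies must be >= 0")

    @property
    def n_occupied(self) -> int:
        return int(self.occupied.sum())

    @property
    def n_bindable(self) -> int:
        return int(self.bindable.sum())

    def site_state(self) -> np.ndarray:
        """int8 grid for the engine: 0 free, 1 obstacle, 2 bindable."""
        state = np.zeros(self.occupied.shape, dtype=np.int8)
        state[self.occupied] = OBSTACLE
        state[self.bindable] = BINDABLE
        return state

    def free_site_indices(self, region: PSDRegion | None = None) -> np.ndarray:
        """Flat indices (i*ny + j) of unoccupied sites, optionally within a region."""
        free = ~self.occupied
        if region is not None:
            i0, i1, j0, j1 = region.site_bounds(self.config)
            mask = np.zeros_like(free)
            mask[i0:i1, j0:j1] = True
            free = free & mask
        return np.flatnonzero(free.ravel())

    def site_table(self) -> np.ndarray:
        """Occupied sites as rows (i, j, bindable, energy) sorted by (i, j)."""
        i, j = np.nonzero(self.occupied)
        return np.column_stack([i, j, self.bindable[i, j].astype(int), self.energy[i, j]])

    def digest(self) -> str:
        """SHA-256 digest of the occupied-site list (reproducibility check)."""
        buf = _io.BytesIO()
        np.save(buf, self.site_table())
        return hashlib.sha256(buf.getvalue()).hexdigest()


def _region_box(config: SimulationConfig, region: PSDRegion | None) -> tuple[int, int, int, int]:
    if region is None:
        return 0, config.nx, 0, config.ny
    return region.site_bounds(config)


def make_obstacle_field(
    config: SimulationConfig,
    C: float,
    region: PSDRegion | None = None,
    arrangement: str = "random",
    seed: int | None = None,
) -> ObstacleField:
    """Populate a fraction C of the region's lattice sites with static obstacles.

    ``random`` places exactly ``round(C · n_region_sites)`` obstacles chosen
    uniformly without replacement (occupancy is exact, not Bernoulli, so
    realized crowding does not fluctuate between seeds).  ``regular`` places
    obstacles on the square sublattice whose occupancy ``1/s²`` is closest
    to C; it is deterministic and serves as the tortuosity control.
    """
    _require(0.0 <= C <= 1.0, "C", "crowding fraction must lie in [0, 1]")
    if arrangement not in ("random", "regular"):
        raise ValidationError(f"arrangement: unknown arrangement {arrangement!r}")
    i0, i1, j0, j1 = _region_box(config, region)
    n_sites = (i1 - i0) * (j1 - j0)
    occupied = np.zeros((config.nx, config.ny), dtype=bool)
    if arrangement == "random":
        n_occ = int(round(C * n_sites))
        rng = np.random.default_rng(config.seed if seed is None else seed)
        flat = rng.choice(n_sites, size=n_occ, replace=False)
        sub = np.zeros(n_sites, dtype=bool)
        sub[flat] = True
        occupied[i0:i1, j0:j1] = sub.reshape(i1 - i0, j1 - j0)
    else:
        if C > 0:
            # occupancy of spacing-s sublattice is 1/s^2; pick the closest,
            # preferring the empty field when C is closer to 0 than to any 1/s^2
            spacings = np.arange(1, max(2, min(i1 - i0, j1 - j0)) + 1)
            occ_fracs = 1.0 / spacings**2
            best = int(spacings[np.argmin(np.abs(occ_fracs - C))])
            if abs(C - 0.0) < abs(C - 1.0 / best**2):
                best = 0
            if best:
                sub = np.zeros((i1 - i0, j1 - j0), dtype=bool)
                sub[::best, ::best] = True
                occupied[i0:i1, j0:j1] = sub
    return ObstacleField(
        config=config,
        occupied=occupied,
        bindable=np.zeros_like(occupied),
        energy=np.zeros(occupied.shape, dtype=np.float64),
        C_target=C,
        arrangement=arrangement,
        region=region,
    )


def assign_binding(
    field_in: ObstacleField,
    P: float,
    energy_spec: float | tuple,
    seed: int = 0,
) -> ObstacleField:
    """Mark a fraction P of the obstacles as binding sites and assign energies.

    ``energy_spec`` is either a scalar E (every binding site gets energy E,
    in k_B·T) or a tuple ``("uniform", lo, hi)`` drawing one i.i.d. energy
    per site from U[lo, hi].  Exactly ``round(P · n_occupied)`` sites are
    chosen uniformly without replacement.
    """
    _require(0.0 <= P <= 1.0, "P", "bindable fraction must lie in [0, 1]")
    if isinstance(energy_spec, (int, float)):
        spec = ("fixed", float(energy_spec))
    else:
        spec = tuple(energy_spec)
    if spec[0] == "fixed":
        _require(spec[1] >= 0, "energy", "binding energy must be >= 0")
    elif spec[0] == "uniform":
        _require(0 <= spec[1] <= spec[2], "energy", "requires 0 <= lo <= hi")
    else:
        raise ValidationError(f"energy: unknown energy spec {spec[0]!r}")

    rng = np.random.default_rng(seed)
    occ_i, occ_j = np.nonzero(field_in.occupied)
    n_bind = int(round(P * occ_i.size))
    pick = rng.choice(occ_i.size, size=n_bind, replace=False) if n_bind else np.empty(0, dtype=int)
    bindable = np.zeros_like(field_in.occupied)
    energy = np.zeros(field_in.occupied.shape, dtype=np.float64)
    bi, bj = occ_i[pick], occ_j[pick]
    bindable[bi, bj] = True
    if spec[0] == "fixed":
        energy[bi, bj] = spec[1]
    else:
        energy[bi, bj] = rng.uniform(spec[1], spec[2], size=n_bind)
    return replace(field_in, bindable=bindable, energy=energy, P_target=P)
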