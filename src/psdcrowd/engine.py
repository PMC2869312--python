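"""Per-step Monte Carlo dynamics of lattice walkers.

Each time step ``dt`` an unbound walker draws one uniform number to pick the
axis of movement and a second to pick the direction along it.  If the target
site is free the walker moves one lattice spacing; if it holds a plain
obstacle the collision is elastic and the walker returns to (stays at) its
original site; if it holds a binding site the walker binds on contact and
remains fixed there.  A bound walker unbinds each step with probability
``exp(-E)`` (E in k_B·T; binding attempts occur once per dt = 1 µs, making
the attempt rate 1/µs) and is then released isotropically to a uniformly
chosen unoccupied 4-neighbor of the binding site, staying put for that step
if all four neighbors are occupied.  Positions wrap toroidally; integer
winding numbers track torus crossings so unwrapped displacements are exact.

RNG draws are consumed in a fixed order (axis, direction, unbind, release)
so trajectories are bit-reproducible for a given walker seed.  Walkers are
strictly non-interacting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .lattice import (
    FREE,
    BINDABLE,
    ObstacleField,
    PSDRegion,
    SimulationConfig,
    ValidationError,
)

__all__ = [
    "WalkerState",
    "Trajectory",
    "EnsembleResult",
    "step",
    "simulate_walker",
    "simulate_ensemble",
    "walker_seeds",
]


@dataclass
class WalkerState:
    """Wrapped lattice position, winding counts, and bound-state flag."""

    i: int
    j: int
    wind_x: int = 0
    wind_y: int = 0
    bound: bool = False

    def unwrapped(self, config: SimulationConfig) -> tuple[float, float]:
        """Position in µm including torus crossings."""
        return (
            (self.i + self.wind_x * config.nx) * config.dx,
            (self.j + self.wind_y * config.ny) * config.dx,
        )


@dataclass
class Trajectory:
    """One walker's recorded path.

    ``positions_unwrapped`` are µm coordinates including torus crossings
    (the quantity entering the MSD); ``positions_wrapped`` are lattice site
    indices on the torus (the quantity entering region membership).
    """

    times: np.ndarray
    positions_unwrapped: np.ndarray
    positions_wrapped: np.ndarray
    bound_flags: np.ndarray

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class EnsembleResult:
    """A set of independent walker trajectories over one obstacle field."""

    config: SimulationConfig
    trajectories: list[Trajectory]
    seed: int
    field_digest: str = ""

    @property
    def times(self) -> np.ndarray:
        return self.trajectories[0].times

    @property
    def n_walkers(self) -> int:
        return len(self.trajectories)

    def unwrapped(self) -> np.ndarray:
        """(N, T, 2) array of unwrapped positions in µm."""
        return np.stack([t.positions_unwrapped for t in self.trajectories])

    def wrapped(self) -> np.ndarray:
        """(N, T, 2) array of wrapped lattice site indices."""
        return np.stack([t.positions_wrapped for t in self.trajectories])


# ---------------------------------------------------------------------------
# Hot loop


@njit(cache=True)
def _run_walker(
    site_state,
    energy,
    n_records,
    record_every,
    i0,
    j0,
    seed,
    stim_on,
    stim_off,
    out_wi,
    out_wj,
    out_ui,
    out_uj,
    out_bound,
):  # pragma: no cover - exercised through simulate_walker
    """Simulate one walker for n_records*record_every steps, recording each interval.

    Binding sites act as plain obstacles outside step window [stim_on,
    stim_off); at step == stim_off a still-bound walker is force-released
    isotropically (that step consumes only the release draw).
    """
    nx, ny = site_state.shape
    np.random.seed(seed)
    i, j = i0, j0
    wx, wy = 0, 0
    bound = False
    out_wi[0] = i
    out_wj[0] = j
    out_ui[0] = i
    out_uj[0] = j
    out_bound[0] = False
    step_no = 0
    for rec in range(1, n_records + 1):
        for _ in range(record_every):
            release = False
            if bound and step_no == stim_off:
                bound = False
                release = True
            elif bound:
                if np.random.random() < np.exp(-energy[i, j]):
                    bound = False
                    release = True
            if release:
                # isotropic release: uniform over unoccupied 4-neighbors
                n_free = 0
                ti0 = i - 1 if i > 0 else nx - 1
                ti1 = i + 1 if i < nx - 1 else 0
                tj0 = j - 1 if j > 0 else ny - 1
                tj1 = j + 1 if j < ny - 1 else 0
                if site_state[ti0, j] == FREE:
                    n_free += 1
                if site_state[ti1, j] == FREE:
                    n_free += 1
                if site_state[i, tj0] == FREE:
                    n_free += 1
                if site_state[i, tj1] == FREE:
                    n_free += 1
                if n_free > 0:
                    k = int(np.random.random() * n_free)
                    if site_state[ti0, j] == FREE:
                        if k == 0:
                            if i == 0:
                                wx -= 1
                            i = ti0
                            step_no += 1
                            continue
                        k -= 1
                    if site_state[ti1, j] == FREE:
                        if k == 0:
                            if i == nx - 1:
                                wx += 1
                            i = ti1
                            step_no += 1
                            continue
                        k -= 1
                    if site_state[i, tj0] == FREE:
                        if k == 0:
                            if j == 0:
                                wy -= 1
                            j = tj0
                            step_no += 1
                            continue
                        k -= 1
                    if j == ny - 1:
                        wy += 1
                    j = tj1
            elif not bound:
                u_axis = np.random.random()
                u_dir = np.random.random()
                di = 0
                dj = 0
                if u_axis < 0.5:
                    di = -1 if u_dir < 0.5 else 1
                else:
                    dj = -1 if u_dir < 0.5 else 1
                ti = i + di
                tj = j + dj
                dwx = 0
                dwy = 0
                if ti < 0:
                    ti += nx
                    dwx = -1
                elif ti >= nx:
                    ti -= nx
                    dwx = 1
                if tj < 0:
                    tj += ny
                    dwy = -1
                elif tj >= ny:
                    tj -= ny
                    dwy = 1
                s = site_state[ti, tj]
                if s == FREE:
                    i = ti
                    j = tj
                    wx += dwx
                    wy += dwy
                elif s == BINDABLE and stim_on <= step_no < stim_off:
                    i = ti
                    j = tj
                    wx += dwx
                    wy += dwy
                    bound = True
                # plain obstacle (or inactive binding site): elastic
                # collision, walker stays at its original position
            step_no += 1
        out_wi[rec] = i
        out_wj[rec] = j
        out_ui[rec] = i + wx * nx
        out_uj[rec] = j + wy * ny
        out_bound[rec] = bound


# ---------------------------------------------------------------------------
# Reference single-step semantics (pure Python, used for unit-level checks
# and documentation; the numba kernel above implements the same rules)


def step(
    state: WalkerState,
    field: ObstacleField,
    config: SimulationConfig,
    rng: np.random.Generator,
    binding_active: bool = True,
) -> WalkerState:
    """Advance one walker by a single time step dt (total function).

    Consumes draws in the fixed order axis, direction (unbound) or
    unbind, release (bound).
    """
    nx, ny = config.nx, config.ny
    s = WalkerState(state.i, state.j, state.wind_x, state.wind_y, state.bound)
    if s.bound:
        if rng.random() < np.exp(-field.energy[s.i, s.j]):
            s.bound = False
            neighbors = []
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ti, tj = (s.i + di) % nx, (s.j + dj) % ny
                if not field.occupied[ti, tj]:
                    neighbors.append((di, dj))
            if neighbors:
                di, dj = neighbors[int(rng.random() * len(neighbors))]
                _move(s, di, dj, nx, ny)
        return s
    u_axis, u_dir = rng.random(), rng.random()
    if u_axis < 0.5:
        di, dj = (-1 if u_dir < 0.5 else 1), 0
    else:
        di, dj = 0, (-1 if u_dir < 0.5 else 1)
    ti, tj = (s.i + di) % nx, (s.j + dj) % ny
    if not field.occupied[ti, tj]:
        _move(s, di, dj, nx, ny)
    elif binding_active and field.bindable[ti, tj]:
        _move(s, di, dj, nx, ny)
        s.bound = True
    return s


def _move(s: WalkerState, di: int, dj: int, nx: int, ny: int) -> None:
    i, j = s.i + di, s.j + dj
    if i < 0:
        i += nx
        s.wind_x -= 1
    elif i >= nx:
        i -= nx
        s.wind_x += 1
    if j < 0:
        j += ny
        s.wind_y -= 1
    elif j >= ny:
        j -= ny
        s.wind_y += 1
    s.i, s.j = i, j


# ---------------------------------------------------------------------------
# Walker / ensemble drivers


def _binding_window_steps(config: SimulationConfig, binding_window) -> tuple[int, int]:
    if binding_window is None:
        # binding active for the whole run; stim_off beyond the last step so
        # no forced release ever triggers
        return 0, config.n_steps + 1
    t_on, t_off = binding_window
    return int(round(t_on / config.dt)), int(round(t_off / config.dt))


def simulate_walker(
    config: SimulationConfig,
    field: ObstacleField,
    start_site: tuple[int, int],
    walker_seed: int,
    binding_window: tuple[float, float] | None = None,
) -> Trajectory:
    """Run one walker for config.duration, recording every record_interval.

    ``binding_window`` (ms) optionally restricts when binding sites are
    active; outside it they behave as plain obstacles and a walker still
    bound at the window end is released isotropically.
    """
    i0, j0 = int(start_site[0]), int(start_site[1])
    if field.occupied[i0, j0]:
        raise ValidationError(f"start_site: site {(i0, j0)} is occupied")
    n_rec = config.n_records
    out_wi = np.empty(n_rec + 1, dtype=np.int64)
    out_wj = np.empty(n_rec + 1, dtype=np.int64)
    out_ui = np.empty(n_rec + 1, dtype=np.int64)
    out_uj = np.empty(n_rec + 1, dtype=np.int64)
    out_bound = np.empty(n_rec + 1, dtype=np.bool_)
    stim_on, stim_off = _binding_window_steps(config, binding_window)
    _run_walker(
        field.site_state(),
        field.energy,
        n_rec,
        config.record_every,
        i0,
        j0,
        int(walker_seed) & 0x7FFFFFFF,
        stim_on,
        stim_off,
        out_wi,
        out_wj,
        out_ui,
        out_uj,
        out_bound,
    )
    return _pack_trajectory(config, out_wi, out_wj, out_ui, out_uj, out_bound)


def _pack_trajectory(config, wi, wj, ui, uj, bound) -> Trajectory:
    return Trajectory(
        times=config.times,
        positions_unwrapped=np.column_stack([ui, uj]).astype(np.float64) * config.dx,
        positions_wrapped=np.column_stack([wi, wj]),
        bound_flags=bound.copy(),
    )


def walker_seeds(master_seed: int, n_walkers: int) -> np.ndarray:
    """Per-walker RNG seeds derived from the master seed (31-bit)."""
    return np.random.SeedSequence(master_seed).generate_state(n_walkers) & 0x7FFFFFFF


def _draw_starts(
    field: ObstacleField, start_policy, n_walkers: int, master_seed: int
) -> np.ndarray:
    """Start sites per policy: 'uniform-free', ('uniform-in-region', R), ('fixed', (i, j))."""
    ny = field.config.ny
    if start_policy == "uniform-free":
        candidates = field.free_site_indices()
    elif isinstance(start_policy, tuple) and start_policy[0] == "uniform-in-region":
        candidates = field.free_site_indices(start_policy[1])
    elif isinstance(start_policy, tuple) and start_policy[0] == "fixed":
        i, j = start_policy[1]
        if field.occupied[i, j]:
            raise ValidationError(f"start_policy: fixed site {(i, j)} is occupied")
        return np.full(n_walkers, i * ny + j, dtype=np.int64)
    else:
        raise ValidationError(f"start_policy: unknown policy {start_policy!r}")
    if candidates.size == 0:
        raise ValidationError("start_policy: no free start sites in the designated region")
    rng = np.random.default_rng(np.random.SeedSequence([int(master_seed), 1]))
    return rng.choice(candidates, size=n_walkers, replace=True)


def simulate_ensemble(
    config: SimulationConfig,
    field: ObstacleField,
    start_policy="uniform-free",
    binding_window: tuple[float, float] | None = None,
) -> EnsembleResult:
    """Run config.n_walkers independent walkers over one shared obstacle field.

    Per-walker seeds derive from config.seed via numpy's SeedSequence; start
    sites are drawn from a separate stream of the same master seed, so the
    whole ensemble is reproducible from (config, field) alone.
    """
    n = config.n_walkers
    seeds = walker_seeds(config.seed, n)
    starts = _draw_starts(field, start_policy, n, config.seed)
    site_state = field.site_state()
    stim_on, stim_off = _binding_window_steps(config, binding_window)
    n_rec = config.n_records
    ny = config.ny
    trajectories = []
    out = [np.empty(n_rec + 1, dtype=np.int64) for _ in range(4)]
    out_bound = np.empty(n_rec + 1, dtype=np.bool_)
    for w in range(n):
        i0, j0 = divmod(int(starts[w]), ny)
        _run_walker(
            site_state,
            field.energy,
            n_rec,
            config.record_every,
            i0,
            j0,
            int(seeds[w]),
            stim_on,
            stim_off,
            out[0],
            out[1],
            out[2],
            out[3],
            out_bound,
        )
        trajectories.append(
            _pack_trajectory(config, out[0], out[1], out[2], out[3], out_bound)
        )
    return EnsembleResult(
        config=config,
        trajectories=trajectories,
        seed=config.seed,
        field_digest=field.digest(),
    )
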