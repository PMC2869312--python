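"""Synthetic test fixtures with analytically known answers.

These generators sit deliberately outside the lattice engine so the
analysis operators can be validated against closed forms that do not share
code with the path being tested: an off-lattice Gaussian random walk whose
MSD is exactly 4·D·t (and whose median D_app is ln(2)·D, since the squared
displacement of an isotropic 2-D Gaussian is exponentially distributed),
and a noise-free power-law MSD curve 4·D·t^α.
"""

from __future__ import annotations

import numpy as np

from .analysis import MSDCurve
from .engine import EnsembleResult, Trajectory
from .lattice import SimulationConfig, ValidationError, make_config

__all__ = ["make_gaussian_walk_fixture", "make_powerlaw_msd_fixture"]


def make_gaussian_walk_fixture(
    D: float,
    n_walkers: int,
    duration: float,
    seed: int = 0,
    record_interval: float = 1.0,
) -> EnsembleResult:
    """Off-lattice Gaussian random walk ensemble with known diffusion coefficient.

    Displacements between recorded instants are i.i.d. normal with variance
    2·D·record_interval per axis (the increments of 2-D Brownian motion are
    Gaussian at any step size, so sampling at the recording resolution is
    distributionally exact).  Wrapped positions are not meaningful for this
    off-lattice fixture and are stored as zeros.
    """
    if D < 0:
        raise ValidationError("D: must be >= 0")
    config = make_config(
        width=max(duration * 4 * max(D, 1e-6), 1.0) ** 0.5 * 10,
        height=max(duration * 4 * max(D, 1e-6), 1.0) ** 0.5 * 10,
        duration=duration,
        n_walkers=n_walkers,
        record_interval=record_interval,
        dt=record_interval,
        D_free=D if D > 0 else 1e-12,
        seed=seed,
    )
    n_rec = config.n_records
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(2.0 * D * record_interval), size=(n_walkers, n_rec, 2))
    pos = np.concatenate(
        [np.zeros((n_walkers, 1, 2)), np.cumsum(steps, axis=1)], axis=1
    )
    times = config.times
    wrapped = np.zeros((n_rec + 1, 2), dtype=np.int64)
    bound = np.zeros(n_rec + 1, dtype=bool)
    trajectories = [
        Trajectory(
            times=times,
            positions_unwrapped=pos[w],
            positions_wrapped=wrapped,
            bound_flags=bound,
        )
        for w in range(n_walkers)
    ]
    return EnsembleResult(config=config, trajectories=trajectories, seed=seed, field_digest="gaussian-fixture")


def make_powerlaw_msd_fixture(D: float, alpha: float, t_grid) -> MSDCurve:
    """Noise-free anomalous-diffusion MSD curve: msd = 4·D·t^α."""
    if D <= 0:
        raise ValidationError("D: must be positive")
    if not 0 < alpha <= 1:
        raise ValidationError("alpha: must lie in (0, 1]")
    t = np.asarray(t_grid, dtype=float)
    msd = np.zeros_like(t)
    pos = t > 0
    msd[pos] = 4.0 * D * np.power(t[pos], alpha)
    return MSDCurve(t=t, msd=msd, n=0)
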