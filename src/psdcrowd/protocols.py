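"""The five in-silico experiments, orchestrated as reproducible runs.

Each protocol assembles its own geometry and obstacle fields, runs walker
ensembles through the engine, and reduces them to a one-row-per-parameter
summary.  Conventions shared by all protocols:

* Crowding sweeps over the whole membrane (α(C), D_app(C), binding sweeps)
  use a 2×2 µm torus fully covered by the random obstacle field; trapping
  and stimulation experiments place obstacles only inside a centered
  0.5×0.5 µm PSD, leaving the extra-synaptic membrane free.
* One obstacle field is drawn per parameter value and shared by the whole
  ensemble; field and ensemble seeds derive deterministically from the
  protocol's master seed and the parameter index.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

from . import analysis
from .engine import EnsembleResult, simulate_ensemble
from .lattice import (
    ObstacleField,
    PSDRegion,
    SimulationConfig,
    ValidationError,
    assign_binding,
    make_config,
    make_obstacle_field,
)

__all__ = [
    "SweepResult",
    "StimulationResult",
    "run_alpha_sweep",
    "run_dapp_sweep",
    "run_trapping_experiment",
    "run_binding_fraction_sweep",
    "run_uniform_binding_sweep",
    "run_stimulation_experiment",
    "run_regular_obstacle_control",
    "default_sweep_config",
    "default_trap_config",
    "default_stimulation_config",
]

PSD_WIDTH_UM = 0.5
STIM_PRE_MS, STIM_MS, STIM_POST_MS = 500.0, 100.0, 700.0
STIM_WINDOW_MS = 400.0
STIM_ACTIVE_FRACTION = 0.10


@dataclass
class SweepResult:
    """One summary row per swept parameter value."""

    parameter: str
    values: np.ndarray
    statistic: str
    stats: np.ndarray
    n_walkers: int
    seed: int
    msd_curves: list = dc_field(default_factory=list, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.parameter: self.values, self.statistic: self.stats})


@dataclass
class StimulationResult:
    """Percent change of PSD-resident receptors across one stimulation run."""

    C: float
    E: float
    percent_change: float
    pre_mean: float
    post_mean: float
    n_walkers: int
    counts: np.ndarray | None = None

    @staticmethod
    def table(results: list["StimulationResult"]) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "C": r.C,
                    "E": r.E,
                    "percent_change": r.percent_change,
                    "pre_mean": r.pre_mean,
                    "post_mean": r.post_mean,
                    "n_walkers": r.n_walkers,
                }
                for r in results
            ]
        )


def default_sweep_config(seed: int = 0, n_walkers: int = 400, duration: float = 2000.0) -> SimulationConfig:
    """Whole-membrane sweep geometry: 2×2 µm torus, 2 s, 400 walkers."""
    return make_config(width=2.0, height=2.0, duration=duration, n_walkers=n_walkers, seed=seed)


def default_trap_config(seed: int = 0, n_walkers: int = 400, duration: float = 1000.0) -> SimulationConfig:
    """Trapping geometry: 1×1 µm torus with a centered 0.5×0.5 µm PSD, 1 s."""
    return make_config(width=1.0, height=1.0, duration=duration, n_walkers=n_walkers, seed=seed)


def default_stimulation_config(seed: int = 0, n_walkers: int = 500) -> SimulationConfig:
    """Stimulation geometry: 2×2 µm torus, 500/100/700 ms timeline."""
    return make_config(
        width=2.0,
        height=2.0,
        duration=STIM_PRE_MS + STIM_MS + STIM_POST_MS,
        n_walkers=n_walkers,
        seed=seed,
    )


def _sub_seeds(master: int, index: int, n: int = 3) -> list[int]:
    """Deterministic child seeds for (field, ensemble, extras) at one grid point."""
    state = np.random.SeedSequence([int(master), int(index)]).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


def _sweep_ensemble(config, C, index, arrangement="random") -> tuple[EnsembleResult, ObstacleField]:
    field_seed, ens_seed, _ = _sub_seeds(config.seed, index)
    fld = make_obstacle_field(config, C=C, arrangement=arrangement, seed=field_seed)
    ens = simulate_ensemble(replace(config, seed=ens_seed), fld, start_policy="uniform-free")
    return ens, fld


def run_alpha_sweep(
    C_values,
    config: SimulationConfig | None = None,
    window=analysis.DEFAULT_ALPHA_WINDOW,
    arrangement: str = "random",
) -> SweepResult:
    """Anomalous exponent α versus whole-membrane crowding C.

    For each C: random field over the full 2×2 µm torus, ensemble released
    uniformly on free sites, MSD over the run, α from the log-log fit.  The
    α(C) curve is sigmoidal: α ≈ 1 below C ≈ 0.3, a steep drop through
    0.3 < C < 0.5, and α ≈ 0 above.
    """
    config = config or default_sweep_config()
    C_values = np.asarray(C_values, dtype=float)
    alphas, curves = [], []
    for k, C in enumerate(C_values):
        ens, _ = _sweep_ensemble(config, C, k, arrangement=arrangement)
        msd = analysis.compute_msd(ens)
        curves.append(msd)
        alphas.append(analysis.fit_alpha(msd, window=window).alpha)
    return SweepResult(
        parameter="C",
        values=C_values,
        statistic="alpha",
        stats=np.array(alphas),
        n_walkers=config.n_walkers,
        seed=config.seed,
        msd_curves=curves,
    )


def run_dapp_sweep(
    C_values,
    config: SimulationConfig | None = None,
    t_obs: float = 1000.0,
) -> SweepResult:
    """Median apparent diffusion coefficient versus crowding C."""
    config = config or default_sweep_config()
    C_values = np.asarray(C_values, dtype=float)
    meds = []
    for k, C in enumerate(C_values):
        ens, _ = _sweep_ensemble(config, C, k)
        meds.append(analysis.compute_dapp(ens, t_obs=t_obs).median)
    return SweepResult(
        parameter="C",
        values=C_values,
        statistic="median_dapp",
        stats=np.array(meds),
        n_walkers=config.n_walkers,
        seed=config.seed,
    )


def run_trapping_experiment(
    C_values,
    config: SimulationConfig | None = None,
    t_query: float | None = None,
) -> SweepResult:
    """Retention of walkers released inside a crowded PSD after one second.

    1×1 µm torus, centered 0.5×0.5 µm PSD with obstacles only inside it;
    each walker starts at a uniform random free site inside the PSD and its
    wrapped position is queried at t = 1000 ms.  At C = 0 the retention
    equals the PSD's area fraction of the membrane (0.25); above C ≈ 0.6
    the walkers stay confined.
    """
    config = config or default_trap_config()
    t_query = config.duration if t_query is None else t_query
    psd = PSDRegion.centered(config, PSD_WIDTH_UM)
    C_values = np.asarray(C_values, dtype=float)
    fractions = []
    for k, C in enumerate(C_values):
        field_seed, ens_seed, _ = _sub_seeds(config.seed, k)
        fld = make_obstacle_field(config, C=C, region=psd, seed=field_seed)
        ens = simulate_ensemble(
            replace(config, seed=ens_seed), fld, start_policy=("uniform-in-region", psd)
        )
        fractions.append(analysis.retention_fraction(ens, psd, t_query))
    return SweepResult(
        parameter="C",
        values=C_values,
        statistic="retention",
        stats=np.array(fractions),
        n_walkers=config.n_walkers,
        seed=config.seed,
    )


def run_binding_fraction_sweep(
    P_values,
    config: SimulationConfig | None = None,
    C: float = 0.45,
    energy_spec=("uniform", 4.0, 8.0),
    window=analysis.DEFAULT_ALPHA_WINDOW,
) -> SweepResult:
    """α versus the fraction P of PSD molecules able to bind the receptor.

    Whole membrane at C = 0.45 with per-site binding energies drawn from
    U[4, 8] k_B·T.  At P = 0 the receptors are trapped by crowding; already
    for P > 0.2 binding lets the membrane become well-mixed and diffusion is
    almost normal.
    """
    config = config or default_sweep_config()
    P_values = np.asarray(P_values, dtype=float)
    alphas, curves = [], []
    for k, P in enumerate(P_values):
        field_seed, ens_seed, bind_seed = _sub_seeds(config.seed, k)
        fld = make_obstacle_field(config, C=C, seed=field_seed)
        fld = assign_binding(fld, P=P, energy_spec=energy_spec, seed=bind_seed)
        ens = simulate_ensemble(replace(config, seed=ens_seed), fld, start_policy="uniform-free")
        msd = analysis.compute_msd(ens)
        curves.append(msd)
        alphas.append(analysis.fit_alpha(msd, window=window).alpha)
    return SweepResult(
        parameter="P",
        values=P_values,
        statistic="alpha",
        stats=np.array(alphas),
        n_walkers=config.n_walkers,
        seed=config.seed,
        msd_curves=curves,
    )


def run_uniform_binding_sweep(
    E_values,
    config: SimulationConfig | None = None,
    C: float = 0.45,
    window=None,
) -> SweepResult:
    """Late-window α versus binding energy when every obstacle binds (P = 1).

    Diffusion is transiently anomalous, then crosses over to slow normal
    diffusion (tortuosity); α is fitted on the late linear part of the
    log-log curve and stays close to 1 for all physiological energies,
    with the crossover time growing with E.
    """
    config = config or default_sweep_config()
    if window is None:
        # late linear part: final three quarters of the run (500 ms at the
        # standard 2 s duration)
        window = (config.duration / 4.0, None)
    E_values = np.asarray(E_values, dtype=float)
    alphas, curves = [], []
    for k, E in enumerate(E_values):
        field_seed, ens_seed, bind_seed = _sub_seeds(config.seed, k)
        fld = make_obstacle_field(config, C=C, seed=field_seed)
        fld = assign_binding(fld, P=1.0, energy_spec=float(E), seed=bind_seed)
        ens = simulate_ensemble(replace(config, seed=ens_seed), fld, start_policy="uniform-free")
        msd = analysis.compute_msd(ens)
        curves.append(msd)
        alphas.append(analysis.fit_alpha(msd, window=window).alpha)
    return SweepResult(
        parameter="E",
        values=E_values,
        statistic="alpha_late",
        stats=np.array(alphas),
        n_walkers=config.n_walkers,
        seed=config.seed,
        msd_curves=curves,
    )


def run_regular_obstacle_control(
    C: float,
    config: SimulationConfig | None = None,
    window=analysis.DEFAULT_ALPHA_WINDOW,
) -> SweepResult:
    """Evenly spaced obstacles: tortuosity without anomalous diffusion.

    Same pipeline as the α sweep but with obstacles on a regular sublattice.
    Expected outcome: α ≈ 1 with an MSD prefactor below free diffusion —
    the randomness of the obstacle field, not exclusion per se, is what
    produces anomalous transport.
    """
    return run_alpha_sweep([C], config=config, window=window, arrangement="regular")


def psd_resident_counts(ensemble: EnsembleResult, region: PSDRegion) -> np.ndarray:
    """Number of walkers inside the region at each recorded instant."""
    wrapped = ensemble.wrapped()
    inside = region.contains_sites(wrapped[..., 0], wrapped[..., 1], ensemble.config)
    return inside.sum(axis=0)


def run_stimulation_experiment(
    C_values,
    E_values,
    config: SimulationConfig | None = None,
    keep_counts: bool = False,
) -> list[StimulationResult]:
    """Transient binding stimulus over a crowded PSD: accumulation vs loss.

    2×2 µm torus with a centered 0.5×0.5 µm PSD holding obstacles at
    crowding C; walkers start uniformly over all free membrane sites.  The
    timeline is 500 ms of diffusion, 100 ms of stimulation during which a
    random 10% of the PSD molecules become binding sites with one shared
    energy E, then 700 ms of relaxation (activated molecules revert to
    plain obstacles; still-bound walkers are released isotropically).  The
    reported statistic is the percent change of the mean PSD-resident count
    between the first and last 400 ms.
    """
    config = config or default_stimulation_config()
    psd = PSDRegion.centered(config, PSD_WIDTH_UM)
    results = []
    C_values = np.atleast_1d(np.asarray(C_values, dtype=float))
    E_values = np.atleast_1d(np.asarray(E_values, dtype=float))
    for ci, C in enumerate(C_values):
        if not 0 <= C <= 1:
            raise ValidationError(f"C: {C} outside [0, 1]")
        # field, activated subset, start sites and walker streams depend on
        # C only, so the E axis is a paired comparison on identical runs
        field_seed, ens_seed, bind_seed = _sub_seeds(config.seed, ci)
        base = make_obstacle_field(config, C=C, region=psd, seed=field_seed)
        for E in E_values:
            if E < 0:
                raise ValidationError(f"E: {E} must be >= 0")
            fld = assign_binding(base, P=STIM_ACTIVE_FRACTION, energy_spec=float(E), seed=bind_seed)
            ens = simulate_ensemble(
                replace(config, seed=ens_seed),
                fld,
                start_policy="uniform-free",
                binding_window=(STIM_PRE_MS, STIM_PRE_MS + STIM_MS),
            )
            counts = psd_resident_counts(ens, psd)
            t = ens.times
            pre = counts[t < STIM_WINDOW_MS].mean()
            post = counts[t > config.duration - STIM_WINDOW_MS].mean()
            results.append(
                StimulationResult(
                    C=float(C),
                    E=float(E),
                    percent_change=float(100.0 * (post - pre) / pre) if pre > 0 else float("nan"),
                    pre_mean=float(pre),
                    post_mean=float(post),
                    n_walkers=config.n_walkers,
                    counts=counts if keep_counts else None,
                )
            )
    return results
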