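"""Trajectory-ensemble statistics and closed-form calculators.

Covers the quantities a single-particle-tracking study would report for the
simulated receptors: the origin-referenced ensemble MSD, the anomalous
exponent α from a log-log fit (MSD = 4·D·t^α), the per-walker apparent
diffusion coefficient D_app = Δr²/(4·t_obs), the Kusumi confined-diffusion
fit MSD = (L²/3)(1 − exp(−10·D·t/L²)) with D held fixed, PSD residence-time
predictions, and the back-of-envelope crowding calculators (PSD mass
fraction, occupied volume, K_d → k_BT conversion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .engine import EnsembleResult
from .lattice import PSDRegion, ValidationError

__all__ = [
    "MSDCurve",
    "AlphaFit",
    "DappDistribution",
    "KusumiFit",
    "compute_msd",
    "fit_alpha",
    "compute_dapp",
    "fit_kusumi",
    "residence_time",
    "retention_fraction",
    "kd_to_kbt",
    "expected_unbind_time",
    "psd_mass_fraction",
    "occupied_volume_fraction",
]

#: Gas constant times temperature at 298 K, kJ/mol.
RT_KJ_PER_MOL = 2.479
#: Conversion factor from kJ/mol to k_B·T units at physiological temperature.
KJ_PER_MOL_PER_KBT = 2.5
#: Average macro-protein density, g/nm^3.
PROTEIN_DENSITY_G_PER_NM3 = 1.4e-21
AVOGADRO = 6.02214076e23

#: Default α-fit window in ms: excludes the early transient of the first
#: ~10 ms that precedes the asymptotic power-law regime.
DEFAULT_ALPHA_WINDOW = (10.0, None)
#: Late window used when diffusion crosses over from anomalous to normal
#: (uniform-binding sweeps); the exponent is read off the final linear part.
LATE_ALPHA_WINDOW = (500.0, None)


@dataclass
class MSDCurve:
    """Ensemble mean squared displacement: t (ms), msd (µm²), ensemble size n."""

    t: np.ndarray
    msd: np.ndarray
    n: int


@dataclass
class AlphaFit:
    """Anomalous exponent from a linear fit of log(MSD) against log(t)."""

    alpha: float
    log_prefactor: float
    window: tuple[float, float]
    r2: float

    @property
    def D(self) -> float:
        """Generalized diffusion coefficient from MSD = 4·D·t^α, µm²/ms^α."""
        return float(np.exp(self.log_prefactor) / 4.0)


@dataclass
class DappDistribution:
    """Per-walker apparent diffusion coefficients at observation time t_obs."""

    values: np.ndarray
    t_obs: float

    @property
    def median(self) -> float:
        return float(np.median(self.values))


@dataclass
class KusumiFit:
    """Confinement length L (µm) from the corral model with D fixed."""

    L: float
    D_input: float
    residual: float

    def predict(self, t: np.ndarray) -> np.ndarray:
        return kusumi_msd(t, self.L, self.D_input)


def kusumi_msd(t: np.ndarray, L: float, D: float) -> np.ndarray:
    """Corral-model MSD: (L²/3)(1 − exp(−10·D·t/L²))."""
    return (L**2 / 3.0) * (1.0 - np.exp(-10.0 * D * t / L**2))


def compute_msd(ensemble: EnsembleResult) -> MSDCurve:
    """Origin-referenced ensemble MSD from unwrapped positions.

    msd(t) = (1/N) Σ_i |r_i(t) − r_i(0)|², averaging over walkers at each
    recorded instant (not a sliding-window time average: the statistic
    tracks the spread of the ensemble from its release points).
    """
    if not ensemble.trajectories:
        raise ValidationError("ensemble: needs at least one trajectory")
    pos = ensemble.unwrapped()
    disp = pos - pos[:, :1, :]
    msd = np.einsum("ntk,ntk->t", disp, disp) / pos.shape[0]
    return MSDCurve(t=ensemble.times.copy(), msd=msd, n=pos.shape[0])


def _window_mask(t, msd, window):
    t_lo, t_hi = window
    t_hi = np.inf if t_hi is None else t_hi
    return (t >= t_lo) & (t <= t_hi) & (t > 0) & (msd > 0)


def fit_alpha(msd: MSDCurve, window: tuple[float, float | None] = DEFAULT_ALPHA_WINDOW) -> AlphaFit:
    """Least-squares slope of log(msd) vs log(t) over the window.

    Equivalent to 1 + slope of log(msd/t) vs log(t).  Requires at least 5
    usable points.  Exponents outside [0, 1.2] are physically suspect for
    obstructed diffusion and trigger a warning.
    """
    mask = _window_mask(msd.t, msd.msd, window)
    if mask.sum() < 5:
        raise ValidationError("window: fewer than 5 positive MSD points in the fit window")
    res = stats.linregress(np.log(msd.t[mask]), np.log(msd.msd[mask]))
    alpha = float(res.slope)
    if not 0.0 <= alpha <= 1.2:
        warnings.warn(f"fitted anomalous exponent {alpha:.3f} outside [0, 1.2]", stacklevel=2)
    t_lo, t_hi = window
    return AlphaFit(
        alpha=alpha,
        log_prefactor=float(res.intercept),
        window=(t_lo, float(msd.t[mask].max()) if t_hi is None else t_hi),
        r2=float(res.rvalue**2),
    )


def compute_dapp(ensemble: EnsembleResult, t_obs: float = 1000.0) -> DappDistribution:
    """Per-walker D_app = |r(t_obs) − r(0)|² / (4·t_obs) from unwrapped positions."""
    t = ensemble.times
    idx = np.flatnonzero(np.isclose(t, t_obs, rtol=1e-9, atol=1e-9))
    if idx.size == 0:
        raise ValidationError(f"t_obs: {t_obs} ms is not on the recorded time grid")
    k = int(idx[0])
    if k == 0:
        raise ValidationError("t_obs: must be positive")
    pos = ensemble.unwrapped()
    sq = ((pos[:, k, :] - pos[:, 0, :]) ** 2).sum(axis=1)
    return DappDistribution(values=sq / (4.0 * t_obs), t_obs=float(t_obs))


def fit_kusumi(msd: MSDCurve, D_input: float) -> KusumiFit:
    """Fit the corral model for L only, with the diffusion coefficient fixed.

    The confined-diffusion analysis assumes the free coefficient applies
    inside the corral, so D is held at ``D_input`` (normally D_free) and
    only L is estimated.  L is initialized at sqrt(3·max(msd)), the exact
    inversion of the model's plateau.
    """
    if D_input <= 0:
        raise ValidationError("D_input: must be positive")
    mask = (msd.t > 0) & (msd.msd > 0)
    if mask.sum() < 5:
        raise ValidationError("msd: needs at least 5 positive points")
    t, y = msd.t[mask], msd.msd[mask]
    L0 = float(np.sqrt(3.0 * y.max()))
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, L: kusumi_msd(tt, L, D_input), t, y, p0=[L0], maxfev=10000
        )
    except RuntimeError as exc:
        raise ValidationError(f"fit_kusumi: did not converge (last L0={L0:.4g}): {exc}") from exc
    L = float(abs(popt[0]))
    resid = float(np.sqrt(np.mean((kusumi_msd(t, L, D_input) - y) ** 2)))
    return KusumiFit(L=L, D_input=float(D_input), residual=resid)


def residence_time(distance_um: float, alpha: float, D_free: float = 0.200e-3) -> float:
    """Time (ms) for an anomalously diffusing receptor to spread a given distance.

    Inverts distance = sqrt(4·D_free·t^α), i.e. t = (d²/(4·D_free))^(1/α).
    With α = 1 this is the normal-diffusion first-spread time d²/(4·D).
    Used to map PSD size and anomalous exponent onto predicted synaptic
    residence times.
    """
    if distance_um <= 0:
        raise ValidationError("distance_um: must be positive")
    if not 0 < alpha <= 1:
        raise ValidationError("alpha: must lie in (0, 1]")
    if D_free <= 0:
        raise ValidationError("D_free: must be positive")
    return float((distance_um**2 / (4.0 * D_free)) ** (1.0 / alpha))


def retention_fraction(ensemble: EnsembleResult, region: PSDRegion, t_query: float) -> float:
    """Fraction of walkers whose wrapped position lies in region at t_query."""
    t = ensemble.times
    idx = np.flatnonzero(np.isclose(t, t_query, rtol=1e-9, atol=1e-9))
    if idx.size == 0:
        raise ValidationError(f"t_query: {t_query} ms is not on the recorded time grid")
    k = int(idx[0])
    wrapped = ensemble.wrapped()[:, k, :]
    inside = region.contains_sites(wrapped[:, 0], wrapped[:, 1], ensemble.config)
    return float(inside.mean())


def kd_to_kbt(Kd_molar: float) -> float:
    """Convert a dissociation constant (M) to a binding energy in k_B·T.

    E = R·T·ln(1/K_d) / 2.5 with R·T = 2.479 kJ/mol (298 K) and 2.5
    converting kJ/mol to k_B·T units.  K_d ≥ 1 M is treated as non-binding.
    """
    if not 0 < Kd_molar < 1:
        raise ValidationError("Kd_molar: must lie in (0, 1) M")
    return float(RT_KJ_PER_MOL * np.log(1.0 / Kd_molar) / KJ_PER_MOL_PER_KBT)


def expected_unbind_time(energy_kbt: float, attempt_interval: float = 1e-6) -> float:
    """Mean time to escape a non-covalent bond of the given depth.

    Unbinding attempts succeed with probability exp(-E) at a characteristic
    attempt interval of 1 µs (the simulation time step), so the expected
    escape time is attempt_interval·exp(E).  For the strongest PSD
    protein-protein bonds (≈13 k_B·T) this gives 1×10⁻⁶/e⁻¹³ ≈ 0.44.
    """
    if energy_kbt < 0:
        raise ValidationError("energy_kbt: must be >= 0")
    if attempt_interval <= 0:
        raise ValidationError("attempt_interval: must be positive")
    return float(attempt_interval * np.exp(energy_kbt))


def psd_mass_fraction(
    psd_mass_g: float = 1.83e-15,
    psd_volume_nm3: float = 3.06e6,
    protein_density_g_per_nm3: float = PROTEIN_DENSITY_G_PER_NM3,
) -> float:
    """Percent of the PSD volume occupied by macromolecules, by mass.

    100 · m_PSD / (V_PSD · ρ_protein); the defaults (360 nm × 30 nm PSD of
    1.83 fg against a solid-protein density of 1.4×10⁻²¹ g/nm³) give ≈43%.
    """
    for name, v in (
        ("psd_mass_g", psd_mass_g),
        ("psd_volume_nm3", psd_volume_nm3),
        ("protein_density_g_per_nm3", protein_density_g_per_nm3),
    ):
        if v <= 0:
            raise ValidationError(f"{name}: must be positive")
    return 100.0 * psd_mass_g / (psd_volume_nm3 * protein_density_g_per_nm3)


def molecule_radius_nm(mw_daltons: float, density_g_per_nm3: float = PROTEIN_DENSITY_G_PER_NM3) -> float:
    """Radius (nm) of a globular protein of given molecular weight.

    r = [(0.75/π) · MW / (ρ · N_A)]^(1/3), i.e. the radius of a sphere whose
    volume holds one molecule at solid-protein density.
    """
    if mw_daltons <= 0:
        raise ValidationError("mw_daltons: must be positive")
    return float(((0.75 / np.pi) * mw_daltons / (density_g_per_nm3 * AVOGADRO)) ** (1.0 / 3.0))


def occupied_volume_fraction(
    n_molecules: float,
    mw_daltons: float,
    psd_volume_nm3: float,
    density_g_per_nm3: float = PROTEIN_DENSITY_G_PER_NM3,
) -> float:
    """Fraction of the PSD volume excluded by n globular molecules of given MW."""
    if n_molecules < 0:
        raise ValidationError("n_molecules: must be >= 0")
    if psd_volume_nm3 <= 0:
        raise ValidationError("psd_volume_nm3: must be positive")
    if n_molecules == 0:
        return 0.0
    r = molecule_radius_nm(mw_daltons, density_g_per_nm3)
    v_mol = (4.0 / 3.0) * np.pi * r**3
    return float(n_molecules * v_mol / psd_volume_nm3)
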