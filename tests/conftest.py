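"""Shared fixtures and the exact Markov-chain oracle for binding equilibrium."""

from dataclasses import replace

import numpy as np
import pytest

import psdcrowd as pc


@pytest.fixture(scope="session")
def tiny_config():
    """Small torus (11x11 sites) for cheap engine-level tests."""
    return pc.make_config(width=0.01, height=0.01, duration=10.0, n_walkers=4, seed=1)


def single_binding_site_field(config, site=(2, 2), energy=1.0):
    """Empty field with one bindable obstacle at the given site."""
    fld = pc.make_obstacle_field(config, C=0.0, seed=0)
    occ = fld.occupied.copy()
    occ[site] = True
    bnd = np.zeros_like(occ)
    bnd[site] = True
    en = np.zeros(occ.shape)
    en[site] = energy
    return replace(fld, occupied=occ, bindable=bnd, energy=en)


def markov_stationary_bound_fraction(nx, ny, site, energy):
    """Exact stationary bound-state probability on a small torus.

    Enumerates the walker's Markov chain (one state per free site plus one
    bound state) exactly as the step rules define it: from a free site each
    of the four neighbor moves has probability 1/4, moves into the binding
    site enter the bound state, moves into the torus wrap normally; from the
    bound state the walker unbinds with probability exp(-E) and is released
    uniformly onto the binding site's free neighbors.  Returns the
    stationary probability of the bound state.
    """
    sites = [(i, j) for i in range(nx) for j in range(ny) if (i, j) != site]
    index = {s: k for k, s in enumerate(sites)}
    bound_idx = len(sites)
    n = len(sites) + 1
    T = np.zeros((n, n))
    for (i, j), k in index.items():
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ti, tj = (i + di) % nx, (j + dj) % ny
            if (ti, tj) == site:
                T[k, bound_idx] += 0.25
            else:
                T[k, index[(ti, tj)]] += 0.25
    q = np.exp(-energy)
    free_neighbors = []
    for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        ti, tj = (site[0] + di) % nx, (site[1] + dj) % ny
        if (ti, tj) != site:
            free_neighbors.append((ti, tj))
    T[bound_idx, bound_idx] = 1.0 - q
    for s in free_neighbors:
        T[bound_idx, index[s]] += q / len(free_neighbors)
    evals, evecs = np.linalg.eig(T.T)
    k = int(np.argmin(np.abs(evals - 1.0)))
    pi = np.real(evecs[:, k])
    pi = pi / pi.sum()
    return float(pi[bound_idx])


def simulated_bound_fraction(energy, n_walkers=60, duration_ms=30.0, burn_in=0.3, seed=5):
    """Long-run fraction of time bound on a 5x5 torus with one binding site.

    Records every dt; returns per-walker bound fractions after discarding
    the initial burn-in portion of each record series.
    """
    dt = 1.0e-3
    config = pc.make_config(
        width=5 * np.sqrt(4 * pc.DEFAULT_D_FREE * dt),
        height=5 * np.sqrt(4 * pc.DEFAULT_D_FREE * dt),
        duration=duration_ms,
        n_walkers=n_walkers,
        record_interval=dt,
        seed=seed,
    )
    assert config.nx == config.ny == 5
    fld = single_binding_site_field(config, site=(2, 2), energy=energy)
    ens = pc.simulate_ensemble(config, fld)
    skip = int(burn_in * (config.n_records + 1))
    return np.array([t.bound_flags[skip:].mean() for t in ens.trajectories])
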