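# Methods

## Model

A single AMPA receptor is a random walker on a square lattice with
toroidal boundary conditions.  The membrane patch of size
`width × height` (µm) is discretized at spacing `dx = sqrt(4·D_free·dt)`,
the expected per-step displacement of a normally diffusing molecule, so an
unobstructed walker taking one step of length `dx` per time step `dt`
reproduces MSD = 4·D_free·t exactly in the ensemble mean.  With the default
`D_free = 0.200×10⁻³ µm²/ms` and `dt = 10⁻³ ms` this gives
`dx ≈ 8.9×10⁻⁴ µm`, i.e. a 2×2 µm membrane is a 2236×2236 grid.  Because
the dynamics are scale-free, multiplying `D_free` by any factor only
rescales `dx`; lattice paths are unchanged (this is covered by a test).

PSD molecules are immobile point obstacles occupying single lattice sites.
A crowding fraction `C` of the sites in a target region (the whole
membrane, or a rectangular PSD) is occupied; placement is uniform without
replacement with an *exact* count `round(C·n_sites)`, so realized crowding
does not fluctuate between seeds and α(C) curves are comparable across
replicates.  A `regular` arrangement places obstacles on the square
sublattice whose occupancy 1/s² is closest to `C`; it serves as the
tortuosity control (obstruction without disorder produces slower but still
normal diffusion).

Per step, an unbound walker draws one uniform number for the axis and one
for the direction.  The move outcomes are:

* target free → move one lattice step (winding numbers track torus
  crossings so unwrapped displacements are exact integers times `dx`);
* target an obstacle → elastic collision, walker stays at its site;
* target a binding site (while binding is active) → the walker moves onto
  the site and binds.

A bound walker unbinds each step with probability `exp(−E)`, `E` in k_BT.
Binding attempts therefore occur at a 1/µs attempt rate, and the mean bond
lifetime is `dt·e^E` (0.44 s for the strongest ≈13 k_BT scaffold bonds —
`analysis.expected_unbind_time`).  On unbinding the walker is released
*isotropically*: it moves to a uniformly chosen unoccupied 4-neighbor of
the binding site, or stays put for that step if all four are occupied.
Isotropic release is the rotational-diffusion argument: receptor–scaffold
complexes reorient on a 10–100 µs timescale, so the unbinding direction is
uncorrelated with the binding approach, and a receptor can continue past a
site that excluded it while unbound.  Walkers are strictly
non-interacting; any number may traverse the same site.

### Binding on contact (p_bounce)

A contact with a binding site could in principle bounce with some
probability before binding.  This package takes the simplest
detailed-balance-consistent convention: binding succeeds on first contact
(`p_bounce = 0`) and the bound state persists with per-step escape
probability `exp(−E)`.  Each active binding site then carries equilibrium
statistical weight `e^E` relative to a free site (verified against the
exact Markov-chain stationary distribution on a 5×5 torus in the tests).
Note the consequence for transient-activation experiments: at `E = 2` an
activated site already attracts 7.4× the occupancy of a free site, so weak
activation *loads* the PSD; with a large constant bounce probability the
loading would instead begin only at higher energies.  The crossover energy
between net receptor loss and net gain in the stimulation protocol is
therefore a direct function of this convention, and measured crossovers
are the right observable to calibrate `p_bounce` against, should data
become available.

### RNG discipline

Draws are consumed in a fixed order (axis, direction; or unbind, release)
so a trajectory is a pure function of (field, start site, walker seed).
Per-walker seeds are `SeedSequence(master).generate_state(n) & 0x7fffffff`;
start sites come from an independent stream of the same master seed.  Every
protocol derives per-condition field/ensemble seeds from
`SeedSequence([master, index])`.  Re-running any ensemble or protocol with
the same master seed is bit-identical, which the suite asserts.

## Analysis conventions

* **MSD** is origin-referenced — the ensemble mean of |r(t) − r(0)|² over
  walkers from their release points — not a sliding-window time average,
  because the quantity of interest is the spread of a released population.
  Unwrapped coordinates are used throughout; region membership uses
  wrapped lattice sites with half-open rectangles.
* **α** is the least-squares slope of log MSD vs log t.  The default fit
  window is t ∈ [10 ms, end of run]: the first ~10 ms contain a transient
  (walkers equilibrating into the local obstacle structure) that is not
  part of the asymptotic exponent.  For uniform-binding runs, where
  diffusion crosses over from anomalous to slow-normal, the exponent is
  read off a late window (the final three quarters of the run; 500–2000 ms
  at the standard duration).  Both windows are arguments.  Fits outside
  α ∈ [0, 1.2] trigger a warning rather than an error — deep-trapping runs
  legitimately fit marginally negative slopes.
* **D_app** = Δr²/(4·t_obs) per walker, with t_obs = 1000 ms by default
  (the trapping protocol's measurement horizon); t_obs is an argument and
  must lie on the recorded grid.  For free 2-D diffusion Δr² is
  exponentially distributed, so the median D_app is ln 2 · D_free — the
  closed form used as the estimator's oracle.
* **Kusumi fit**: MSD = (L²/3)(1 − exp(−10·D·t/L²)) with D *fixed* at the
  free coefficient (the corral model's assumption) and only L estimated by
  Levenberg–Marquardt, initialized at √(3·max MSD), the exact inversion of
  the model plateau.  t = 0 is excluded.
* **Residence time** inverts distance = √(4·D·t^α) to
  t = (d²/4D)^(1/α); it is strictly increasing in d and decreasing in α.
* Calculators: K_d → k_BT uses E = RT·ln(1/K_d)/2.5 with RT = 2.479 kJ/mol
  (298 K); the PSD mass-fraction and occupied-volume calculators implement
  100·m/(V·ρ) and the globular-protein radius
  [(0.75/π)·MW/(ρ·N_A)]^(1/3) with ρ = 1.4×10⁻²¹ g/nm³.

## Protocols and study conditions

| protocol | geometry | obstacles | walkers | duration |
|---|---|---|---|---|
| α(C), D_app(C), binding sweeps | 2×2 µm torus | whole membrane | 400 | 2000 ms |
| trapping | 1×1 µm torus, centered 0.5×0.5 µm PSD | PSD only | 400 | 1000 ms |
| stimulation | 2×2 µm torus, centered 0.5×0.5 µm PSD | PSD only | 500 | 500+100+700 ms |

Binding sweeps run at C = 0.45 with per-site energies U[4, 8] k_BT
(fraction sweep) or one shared energy (uniform sweep).  The stimulation
protocol activates a random 10% of the PSD molecules as binding sites with
one shared energy E for 100 ms; afterwards they revert to plain obstacles
and any still-bound walker is released isotropically at the window end.
The reported statistic is the percent change of the mean PSD-resident
count between the first and last 400 ms.  Within one crowding level the
field, the activated subset, the start sites, and the walker RNG streams
are shared across energies, so the E-axis is a paired comparison.

One obstacle field is drawn per parameter value and shared by its whole
ensemble (replicate ensembles redraw the field).  Walkers start uniformly
on free sites — which is the stationary distribution of this walk, so
pre-stimulus baselines have no drift in expectation.

## Synthetic fixtures

`make_gaussian_walk_fixture` generates off-lattice Gaussian walks with
per-interval displacement variance 2·D·Δ per axis — distributionally exact
Brownian sampling at the recording resolution — and
`make_powerlaw_msd_fixture` evaluates 4·D·t^α noise-free.  They validate
the analysis operators independently of the lattice engine: they share no
code with it, and they emulate only the ideal limits (no obstacles, no
binding, no lattice discreteness).  Passing those tests shows the
estimators are correct, not that the engine's physics is; the engine is
checked separately against closed forms (free-diffusion MSD, binding
equilibrium vs the exact transition matrix) and regime properties.

## Numerical choices and degenerate inputs

* Obstacle counts and bindable counts round to the nearest integer; C = 0
  and C = 1, P = 0 and P = 1 are exact.
* A walker walled in on all four sides simply never moves; a bound walker
  whose four neighbors are occupied stays on the binding site one more
  step after unbinding.
* `record_interval` must be an integer multiple of `dt`; trajectories
  store t = 0 plus one record per interval.
* Validation failures raise `ValidationError` naming the offending field.
* The trapping membership test is half-open ([x0,x1) × [y0,y1)) so region
  areas tile the torus without double counting.

## Known limitations

* Crowding values near C ≈ 0.40 sit at the square lattice's site
  percolation threshold (free-site fraction 0.5927).  Long-time transport
  observables there — D_app medians, fitted confinement lengths — are
  hypersensitive to the exact crowding convention, the fit window, and the
  field realization; confinement lengths from 2-second runs at C = 0.38
  versus 0.40 differ severalfold.  Comparisons against other
  implementations of the same model can disagree substantially in this
  regime while agreeing everywhere else; the anchors away from threshold
  (free-diffusion statistics, regime endpoints, trapping baselines) are
  the robust quantities.
* The stimulation loss/gain crossover energy depends directly on the
  binding-on-contact convention (see p_bounce above).
* PSD molecules are static point obstacles on single sites; mobile
  scaffolds, multi-site molecules, non-rectangular PSDs, receptor
  recycling, and receptor–receptor interactions are out of scope.
* The engine is exact per-step Monte Carlo, not an approximation — but it
  is serial per walker; very large ensembles parallelize only across
  processes.
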