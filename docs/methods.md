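# Methods

`senoclust` simulates how a senescent breast-cancer cell — a giant,
immobile "fried egg" with a bulged nuclear core and a thin spread body —
gathers neighboring proliferating tumor cells into a three-dimensional
cluster on top of its core, and provides the track statistics used to
quantify tumor-cell motility (anomalous MSD exponent, two-tiered directional
persistence, radial approach speed). This note documents the model, its
numerical choices, the parameters that matter, and what the synthetic-data
generators do and do not emulate.

## The lattice model

The simulator is a 3D cellular Potts model (Glazier–Graner–Hogeweg type).
Each site of an `(Lx, Ly, Lz)` grid holds a cell id; a cell is the domain of
sites sharing an id. Five types exist: culture **medium** (id 0), the
senescent **core**, the 48-wedge senescent **body** sheet, proliferating
**tumor** cells, and the frozen substrate (**matrix**). One lattice unit is
1 µm, so the printed target volumes (1800 / 600 / 400 µm³) map directly to
site counts; the full-scale grid is 200 × 200 × 50 µm with periodic x/y
boundaries, a one-site matrix floor and a pinned-medium ceiling.

Dynamics are Metropolis copy attempts: one Monte Carlo step (MCS) performs
as many attempts as there are lattice sites and equals one second of
physical time. An attempt picks a random site and a random neighbor within
the order-2 neighborhood (18 neighbors, all weighted equally), and proposes
copying the neighbor's id onto the site. The move is accepted with
probability 1 if it lowers the energy and `exp(-ΔH/T)` otherwise, at
temperature `T = 100`. Moves that would overwrite the substrate, copy the
substrate, modify the pinned ceiling, or erase a cell's last site are
rejected outright. The energy is

```
H = Σ_cells [ λ_V (v_σ − V_t)² + λ_P (P_σ − P_t)² ]
  + Σ_unlike-pairs J(τ_i, τ_j)
  + (per move, tumor cells only)  μ · (ω(target) − ω(source))
```

with the interface sum running over unlike-cell site pairs in the order-2
neighborhood. The chemotaxis term is a move bias, not a configuration
functional: with `μ < 0` an extension up the chemoattractant gradient is
favorable. Negative J values are used exactly as configured (contact lowers
energy); the 11 printed type pairs are defaults in `config.py`. The pair
body–matrix is not part of the printed set although the body rests on the
substrate; it defaults to the core–matrix value (−70) so the sheet stays
adherent. Cell surfaces are counted as exposed faces (6-connectivity,
spacing² each); the target surface is `asperity × area of the equal-volume
sphere`, reading the dimensionless asperity (0.8 core/body, 1.4 tumor) as a
sphere-normalized shape factor.

`ΔH` is evaluated incrementally from the local stencil; a brute-force
two-evaluation oracle (`total_hamiltonian`, an independent vectorized
implementation) verifies the incremental kernel to 1e−9 on randomized
lattices in the test suite. At zero temperature the energy is
non-increasing; per-cell volume/surface caches are updated in place and
checked against from-scratch recounts. Cell-domain connectivity is **not**
enforced (no constraint term exists in the model); fragmentation is
monitored in the tests and does occur for strongly chemotactic cells, mostly
as single-site debris.

## The chemoattractant field

The core continuously releases a single diffusible attractant ω (a stand-in
for the SASP species) obeying `∂ω/∂t = p − dω + D∇²ω` with `p = 2 µm⁻³s⁻¹`
applied at core sites only, `d = 0.02 s⁻¹`, `D = 2 µm²s⁻¹`. The PDE is
integrated by explicit forward Euler with a 7-point Laplacian; the number of
substeps per MCS is chosen automatically from the 3D stability bound
`D·dt/h² ≤ 1/6` (12 substeps at the defaults). ω diffuses through all
non-matrix sites (cells included); matrix sites and the z faces are no-flux.
One field update per MCS is interleaved after the copy sweep. The field
starts at zero and is pre-equilibrated for 300 s (six decay times 1/d = 50 s
would be ~99.8 % of steady state; the spatial profile equilibrates on the
same scale since √(D/d) ≈ 10 µm) so chemotaxis acts on a developed gradient
from the first division onward. With these rates the steady state obeys the
global balance `p·V_core = d·Σω` (verified to 1 % in the tests) and decays
radially with length √(D/d) ≈ 10 µm.

## Cell cycle and mitotic rounding

Tumor cells divide on a clock: cycle lengths are normal with mean 5000 s and
sd 1000 s, redrawn if non-positive. Division splits the cell by a vertical
plane through its centroid with uniformly random horizontal azimuth (the
division axis is co-planar with the substrate); one half keeps the id, the
other becomes a new cell; both receive fresh clocks, generation + 1, and a
rounding onset `t0`. Cells present at t = 0 start at a uniformly random
phase of a drawn cycle — an asynchronous population; with synchronized
fresh clocks essentially no divisions would occur within the first ~4000 s,
contradicting the observed early divisions. Division is purely clock-driven
(no volume checkpoint); daughters start below the 400 µm³ target and are
re-inflated by the volume elasticity.

During mitotic rounding the dividing cell's adhesion becomes
time-dependent:

```
J_tumor,tumor(t)  = −6  ∓ 110·exp(−(t − t0)/100)
J_tumor,matrix(t) = −20 ∓ 110·exp(−(t − t0)/500)
```

Both schedules relax to the resting values; beyond ten times the slower
time constant the resting J is used exactly. The sign is configurable
(`rounding_sign`): the *as-printed* form (−, default of the low-level API)
makes contacts transiently stronger; the *weakening* form (+) makes them
transiently repulsive. The simulation scenarios default to **weakening**:
mitotic rounding is, biophysically, a loss of substrate adhesion, and it is
the substrate release (J_tumor,matrix jumping to +90 before relaxing) that
lets newly divided cells leave the floor and climb the senescent body —
with the as-printed sign daughters are glued harder to the floor and no
cluster can form. When two rounding cells touch, the more recent onset
governs their pair energy. A per-cell sensitivity multiplier for rounding
cells exists (`mu_rounding_boost`) but the default keeps μ constant for all
tumor cells: selectivity — only newly divided cells climb — emerges from
the adhesion schedule alone, because resting cells stay anchored by
J_tumor,matrix = −20.

## Calibrated parameters

Three Hamiltonian parameters have no published value and were calibrated
in-repo on the reduced scenario so that (a) cell volumes track their
targets within a few percent, (b) only rounding-phase cells climb, and (c)
the scaled-down scenario reproduces cluster formation:

| parameter | default | role |
| --- | --- | --- |
| λ_V | 2.0 | volume elasticity; thermal volume fluctuation sd = √(T/2λ_V) = 5 sites |
| λ_P | 0.1 | surface elasticity against the sphere-normalized targets |
| μ | −350 | chemotactic sensitivity; strong enough for a daughter cell to cross the ~20 µm from the tumor ring to the core within its ~1000-s substrate-release window |

Both were calibrated empirically on the reduced scenario. λ_P turned out to
matter qualitatively: at λ_P ≈ 0.1 the core relaxes into a wide, low dome —
the fried-egg footprint — and climbing daughters pile on it reliably,
whereas with the surface term nearly off (λ_P ≤ 0.01) cells barely mount
the body at all, and μ alone cannot compensate. The tumor target surface
(asperity 1.4, i.e. ~12 % above a compact ball's face count) keeps tumor
cells mildly protrusive, which assists migration. μ is deliberately large
relative to T: the printed field rates put the tumor ring ~2.5 decay
lengths from the core, where the per-site gradient is only ~0.1–0.2 µm⁻³.
At these defaults selectivity holds — resting cells remain anchored by the
substrate adhesion while every climber in the end states is a
generation ≥ 1 daughter. Strongly chemotactic cells shed occasional
single-site fragments — the known CPM artifact of large per-move biases
without a connectivity constraint.

## Scenarios and cluster metric

* **Full scale** (`SimConfig()`): 200×200×50, 48 body wedges, 20 tumor
  cells, 8800 MCS. This is the published-figure scale; it is documented and
  runnable but not exercised by the test suite (hours of CPU).
* **Reduced** (`SimConfig.reduced()`): 60×60×20, 12 body wedges, 6 tumor
  cells, 3000 MCS, same physical parameters. The initial-layout builder
  digitizes a hemispherical core (1800 µm³) on the floor, tiles an annular
  body sheet around it (auto-selected thinnest sheet whose tumor ring still
  fits the grid), and seeds near-cubic tumor cells in a ring outside the
  body.
* **Plate** (`SimConfig.plate()`): tumor cells only (64 on a 96×96×12
  grid), field off — used to accumulate division statistics quickly. The
  population roughly doubles per cycle and the late phase is deliberately
  crowded (the jammed-then-multilayered regime); crowding compresses cell
  volumes but cannot perturb the clock-driven division intervals.
  Inter-division statistics are taken from *matured cohorts only*: a cycle
  clock started at time b contributes its interval only if the run extends
  past b + 8000 s (mean + 3 sd), so the sample contains no right-censored
  cycles — stopping at the Nth logged event would otherwise
  over-represent short cycles and bias the mean low by several standard
  errors.

`cluster_metrics` counts tumor cells whose centroid column lies in the
core's x–y footprint and whose centroid height exceeds the body's median
top surface; `cluster_formed` requires at least two such cells, the
"pair of daughter cells at the core" configuration of the experiment.

## Track statistics

The analysis operates on tidy track tables (`cell_id, time, x, y, z`),
whether simulated centroids or synthetic walkers, in 2D (x, y) by default to
match phase-contrast imaging.

* **MSD**: time-and-ensemble average over all overlapping pairs per lag;
  per-track means are averaged across tracks with equal weight. The
  anomalous exponent α is the OLS slope of log MSD vs log lag, fitted from
  two frames up to a quarter of the track length (short lags are
  noise-dominated, long lags statistics-starved).
* **Directional persistence**: the heading at time s is the unit
  displacement over one frame interval; the curve ⟨cos θ⟩(t) is fitted to
  `A e^(−t/τ) + B e^(−t/τ₀)` by bounded nonlinear least squares with
  multi-start initialization over a (τ, τ₀) grid, the identifiability
  constraint τ ≥ 2τ₀, and A, B ≥ 0. The lag-0 point (≡ 1) is excluded: the
  model describes decorrelation for t > 0 and any instantaneous component
  appears as A + B < 1. Parameter uncertainties come from the Gauss–Newton
  covariance; fits with singular covariance or relative τ uncertainty above
  1 are flagged.
* **Radial velocity**: per track, the least-squares slope of
  distance-to-center vs time, sign-flipped so inward motion is positive;
  the ensemble value is the unweighted track mean.

## Synthetic data

The generators replace the unavailable live-imaging tracks; their ground
truth is known by construction.

* `gen_persistent_tracks`: constant-speed 2D walkers whose heading diffuses
  with per-frame Gaussian increments of variance `2·dt/τ_i`. Two
  populations (fractions A/(A+B) slow, B/(A+B) fast) plus independent
  per-frame heading jitter of variance `−ln(A+B)` give ensemble
  autocorrelation exactly `A e^(−t/τ) + B e^(−t/τ₀)` for t > 0 — the jitter
  realizes the instantaneous decorrelated component implied by A + B < 1.
  Defaults: speed 30 µm/hr and dt = 0.25 hr, resembling aggregated
  15–30 s-frame imaging cadence.
* `gen_fbm_tracks`: independent fractional Brownian motion per axis, exact
  fractional-Gaussian-noise sampling by circulant embedding of the fGn
  autocovariance (verified in-tests against the covariance implied by the
  fBm definition). The MSD exponent is 2H by construction.

What the generators deliberately do **not** emulate: cell–cell collisions
and volume exclusion, confluency effects (jamming), heterogeneous
per-cell speeds, measurement pixelation noise, and finite-cell-size
centroid wobble. Passing recovery tests therefore shows the estimators are
unbiased and correctly implemented at realistic sampling and noise levels —
not that the biological tracks satisfy the generating models.

## Numerical and degenerate-input choices

* Copy-candidate ordering: independent uniform site draws per MCS (not a
  permutation); all randomness flows from one recorded seed, and identical
  (config, seed) reproduce byte-identical outputs.
* z boundaries: an out-of-range z neighbor contributes neither interface
  energy nor exposed surface; in simulation scenarios the floor/ceiling
  layers make this convention unobservable.
* ΔH = 0 moves are accepted (e⁰ = 1), exactly as the acceptance rule
  evaluates.
* Division of a cell with < 2 sites is deferred one MCS; a degenerate
  split plane (all sites on one side) falls back to a median split.
* Inter-division intervals are only logged for cells born during the run;
  initial cells start mid-cycle and their first division is not a full
  cycle.
* Zero-length displacements leave headings undefined and are skipped;
  non-positive MSD values are excluded from the log-log fit with a warning.
* Track sampling must be uniform within a track; non-uniform tables are
  rejected rather than silently resampled.

## Problem sizes used by the checks

The automated checks run the reduced scenario (10 seeds × 3000 MCS at
60×60×20) for cluster formation, the 96×96×12 plate until ≥ 205 matured
division intervals (~14–16 × 10³ MCS) for the cycle statistics,
5 × 500 tracks × 500 frames for the persistence recovery, and
200 × 1000-frame fBm tracks for the MSD exponent — sizes at which the
estimator standard errors are comfortably inside the tolerances being
checked.

## Known limitations

* No connectivity constraint: strongly biased cells shed site-scale debris.
* The reduced grid forces a body sheet several sites thick (the annulus
  must fit inside the periodic box), so the "thin body" is thinner at full
  scale than in the reduced tests.
* The chemoattractant diffuses through cell interiors; whether it should be
  excluded from cells is not determinable from the model description.
* The as-printed rounding sign is preserved verbatim in the API but is not
  usable for cluster formation (see above); the ambiguity is inherent to
  the source description.
* Haptotactic guidance along the body rim and membrane-ruffle dynamics are
  outside the model; tangential motion around the body arises only from the
  adhesion/chemotaxis balance.
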