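# senoclust

**3D cellular Potts simulation of senescent-cell-driven tumor cluster
formation, with cell-track motility statistics.**

Senescent cells in a confluent breast-cancer monolayer spread into huge,
flat "fried eggs" — a bulged nuclear core surrounded by a thin adherent
body. Far from being inert, such a cell can act as an aggregation center:
neighboring tumor cells that undergo mitotic cell-rounding lose their grip
on the substrate, climb over the senescent body, and migrate to its core,
where successive arrivals pile into a three-dimensional cluster on top of
an otherwise two-dimensional colony.

`senoclust` is for computational cell biologists who want to simulate and
analyze this process. It provides:

* a 3D **cellular Potts model** (Metropolis copy kinetics, one Monte Carlo
  step = 1 s) with five compartment types — medium, senescent core,
  senescent body, tumor cells, substrate — and the Hamiltonian

  ```
  H = Σ_σ [λ_V (v_σ − V_t)² + λ_P (P_σ − P_t)²]  +  Σ_⟨i,j⟩ J(τ_i, τ_j)
  ```

  plus a per-move chemotactic bias `ΔH_chemo = μ·(ω(x′) − ω(x))` for tumor
  cells;
* a coupled **reaction–diffusion chemoattractant field**
  `∂ω/∂t = p − dω + D∇²ω` released by the senescent core
  (p = 2 µm⁻³s⁻¹, d = 0.02 s⁻¹, D = 2 µm²s⁻¹);
* **mitotic cell-rounding** as time-dependent adhesion: at each division
  onset t₀ the tumor–tumor and tumor–substrate interaction energies jump by
  110 energy units and relax exponentially back to their resting values
  (−6 and −20) with time constants 100 s and 500 s;
* **track statistics**: ensemble MSD and its anomalous exponent α
  (⟨δ²⟩ ~ t^α), heading autocorrelation with the two-tiered exponential fit
  `⟨cos θ(t)⟩ = A e^(−t/τ) + B e^(−t/τ₀)`, mean radial approach speed, and a
  geometric cluster-formation metric;
* **synthetic track generators** (two-population persistent walkers,
  exact fractional Brownian motion) whose ground truth is known by
  construction, so the whole analysis chain is testable without imaging
  data.

See [docs/methods.md](docs/methods.md) for the model details, parameter
table and limitations.

## Worked example

Run the scaled-down cluster scenario (60×60×20 µm grid, 12 body wedges, 6
tumor cells, 3000 s):

```bash
senoclust simulate --reduced --seed 2 --out runs/demo
```

which prints

```
run complete: 5 division events
cluster_formed=True n_cells_on_core=6 max_stack_height=13
```

Reading the output: five divisions occurred during the 3000-s run; at the
end six tumor cells sit atop the senescent core (centroid inside the core's
x–y footprint, above the body's median top surface), with up to 13 µm of
contiguous tumor occupancy stacked over the core — a formed 3D cluster.
The run directory holds the centroid track table, the division-event log,
the cluster-metric time series and the exact resolved configuration.

The analysis chain is demonstrated on synthetic "experimental" tracks
generated at the published persistence parameters (A = 0.14, τ = 4.56 hr,
B = 0.64, τ₀ = 0.38 hr, 500 tracks):

```bash
senoclust synth walk --seed 0 --n-tracks 500 --out walk.csv
senoclust analyze walk.csv
```

```
alpha = 1.317 +/- 0.006
<cos theta> fit: A=0.154 tau=4.039 B=0.647 tau0=0.356
```

The two-tiered exponential fit recovers the generator's parameters (a
single seed lands within ~10 % of the slow time constant; the acceptance
script averages five seeds). The apparent MSD exponent α ≈ 1.3 of these
walkers is genuinely super-diffusive: over the fitted lag window a
persistent random walk sits in the crossover between short-lag ballistic
and long-lag diffusive scaling — the same reason confluent cells with
multi-hour directional persistence show 1 < α < 2.

Library use mirrors the CLI:

```python
from senoclust import SimConfig, run_simulation, analyze

cfg = SimConfig.reduced(seed=2)
result = run_simulation(cfg, out_dir="runs/demo")
print(result.cluster)                 # ClusterMetrics(n_cells_on_core=..., ...)
report = analyze(result.tracks)       # alpha, (A, tau, B, tau0), ...
```

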