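# multicargo

Stochastic and mean-field models of **multivalent cargo motion on
substrates** — bodies that stay attached through several transient "leg"
linkages and move because individual legs repeatedly unbind and rebind at
new positions.  Examples span multivalent ligands diffusing on
receptor-coated surfaces, crosslinker-coupled cytoskeletal filaments, and
cargo that track growing microtubule ends through end-binding (EB)
proteins.  The package is written for biophysicists who want to go from
*leg-level* binding/unbinding rate profiles to *cargo-level* transport
quantities — drift, diffusivity, dwell times, stationary densities,
tip-tracking ability — without fitting any free parameters.

## The model

A cargo of half-width `L` carries `N` legs, `n` of which are bound at
positions `{x_l}`; its centre is their mean, `x_a = (1/n) Σ x_l`.  Three
event types drive the dynamics:

* **binding** (m = 1): a free leg attaches at `y` with rate
  `κ₁(y) S_H(y | x_a)`, where `S_H` is the uniform shape factor `1/(2L)`
  on `[x_a − L, x_a + L]` (a disk of radius `L` in 2D);
* **unbinding** (m = 2): a bound leg detaches from `x_l` with rate
  `κ₂(x_l)`; unbinding of the last leg ends the run;
* **collective displacement** (m = 3): all bound legs shift by `Δx` at
  rate `k̄₃`, encoding substrate motion (e.g. the co-moving frame of a
  microtubule tip, `−k̄₃Δx = v_MT`).

Each event moves the centre by `(y − x_a)/(n ± 1)`.  Averaging the event
displacements over the leg-count distribution `P_n(x)` and the bound-leg
distribution `P_b` gives the coarse-grained drift and noise intensity

    S₁(x) = Σₙ Pₙ(x) Σₘ k̄ₘ λₘ⁽¹⁾ + k̄₃Δx ,
    S₂(x) = Σₙ Pₙ(x) Σₘ k̄ₘ λₘ⁽²⁾ + k̄₃Δx² ,

with `D_eff = S₂/2` and `v_eff = S₁ − ∂ₓD_eff`, which parameterize an Itô
Langevin equation `dx = S₁ dt + √S₂ dW` and the Fokker–Planck equation for
the cargo density.  Zeros of `S₁` with negative slope are stable fixed
points — the positions where cargo accumulate, e.g. just behind a
polymerizing microtubule tip.

Lengths are in units of `L` and times in units of `t_c = 1/κ₂` unless a
physical unit system is used (the tip-tracking application works in nm
and s).

## Layout

| module | contents |
| --- | --- |
| `multicargo.profiles` | rate profiles κ₁/κ₂ (uniform, flat-topped bump, tabulated, comet), characteristic lengths |
| `multicargo.model` | shape factors, domains, `CargoModel`, unit conventions |
| `multicargo.meanfield` | displacement moments, event rates, leg-count chain (dwell times, `P_n`), `S₁/S₂/v_eff/D_eff` tables, small-cargo and substrate-edge drift approximations, fixed points |
| `multicargo.gillespie` | exact event-driven simulation of individual cargo (1D) |
| `multicargo.twod` | 2D disk-cargo simulation and empirical vector velocity fields |
| `multicargo.langevin` / `multicargo.fokker_planck` | coarse-grained dynamics driven by the mean-field tables |
| `multicargo.analysis` | MSD and short/long-time diffusivities, empirical `P_b`/`P_n`, drift/noise fields, stationary densities |
| `multicargo.tiptrack` | EB-mediated microtubule plus-end tracking: comet rate profiles, (N, size) scans, force estimates |
| `multicargo.cli` | `multicargo simulate | simulate2d | meanfield | langevin | fp | analyze | scan-tip | fixture` |

## Worked example

Cargo with four legs on a substrate with a central region of enhanced
binding rate (`κ₁(0) = 3κ₂`, decaying to `κ₂` over `l_c ≈ 2.5 L`):

```python
import numpy as np
import multicargo as mc
from multicargo import meanfield as mf
from multicargo.gillespie import simulate_ensemble
from multicargo.analysis import stationary_density

bump = mc.logistic_bump_profile()          # kappa1: 1 + 4/(1 + exp((x/2)^6))
model = mc.CargoModel(N=4, kappa1=bump, kappa2=mc.uniform_profile(1.0))
pb = mf.uniform_bound_legs(1.0)

print(mc.characteristic_length(bump, 1.1))   # 2.483212655623275 (~2.5 L)
print(mf.mean_dwell_time(0.0, model, pb))    # 21.218208392678292 t_c

tables = mf.effective_tables(np.linspace(-10, 10, 201), model, pb)
print(mf.find_fixed_points(tables))   # [FixedPoint(x=8.88e-16, stable=True)]

ens = simulate_ensemble(model, 4000, 200.0, master_seed=11, x0_mode="uniform")
x, dens, se = stationary_density(ens, np.linspace(-10, 10, 101))
print(round(dens[np.argmin(abs(x))], 2), round(dens[np.argmin(abs(x - 5))], 3))
# 0.16 0.025  -> the cargo density peaks at the bump centre, ~6x the tails
```

The numbers mean: the binding-rate bump decays to 1.1×κ₂ at 2.48 L from
the centre; a 4-legged cargo at the bump centre stays bound for 21.2 t_c
on average (vs 3.75 t_c on the uniform tails); the drift field has a
single stable fixed point at the origin; and the time-averaged cargo
density from 4000 simulated cargo is peaked there.

The same pipeline from the shell:

```bash
multicargo simulate --scenario bump_N4 --n-cargo 4000 --t-max 200 --out run/
multicargo analyze --events run/events.csv --out run/analysis/
```

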