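# reflexgait

Reflex-driven planar gait simulation and speed modulation.

Human locomotion is flexible: we change speed continuously and switch
between walking and running.  How much of that flexibility could spinal
reflexes provide *on their own*, without rhythm generators or high-level
state machines?  `reflexgait` is a simulation toolkit for that question.
It implements a planar neuromusculoskeletal model (seven segments, 18
Hill-type muscles) driven entirely by delayed proprioceptive feedback, and
the analysis pipeline that turns the reflex network into a continuous speed
controller.  It is aimed at motor-control and biorobotics researchers who
want a self-contained, fully inspectable Python implementation.

## The model in brief

Each muscle *i* receives a stimulation

```
u_i(t) = clip( c_i + Σ_{j∈R_i} [ κL_ij · L̃_j(t−Δt) + κF_ij · F̃_j(t−Δt) ] )
```

from delayed, normalized muscle-fiber lengths `L̃` and tendon forces `F̃` of
itself (homonymous pathway) and its antagonists.  With nine muscles per leg
the network has 31 connections, hence 71 free parameters (31 length gains
κL, 31 force gains κF, 9 offsets c); both legs share one parameter set.

The speed pipeline:

1. **Speed optimization** — CMA-ES minimizes
   `J = 100·J_vel + 100·J_fall`, `J_vel = ±d_sim/t_max`,
   `J_fall = 1 − t_sim/t_max`, searching locally around a stable gait for
   its slowest and fastest neighbors.
2. **Harvesting** — every stable intermediate solution becomes a record
   `(p, v_act)` in a speed dataset Ω.
3. **Key parameters** — PCA on the standardized dataset; the parameters
   with the largest first-component loadings are the key reflexes, and a
   restricted optimization varies only those.
4. **Speed-modulation function (SMF)** — per key parameter, a polynomial
   `SMF_k(v) = β₀ + β₁v + β₂v² + β₃v³` in speed; `assemble(v_tgt)` builds a
   full 71-vector for any target speed (frozen baseline values elsewhere).
5. **Offline / online modulation** — sweep the target-speed grid for
   stability, then track step and triangle-ramp schedules at run time by
   re-assembling the vector once per second.
6. **Gait transitions** — abrupt whole-vector switches at 10 s boundaries,
   jointly re-optimized (2·71 or 4·71 dimensions) for survival.

A desk-scale **toy hopper** (point mass on a telescoping muscle-driven leg,
10 parameters through the identical controller machinery) runs the entire
pipeline in about two minutes and backs most of the test suite.  See
`docs/methods.md` for model details and design rationale.

## Worked example

```python
from reflexgait import run_episode
from reflexgait.toybench import make_toy_plant, toy_episode_config

plant, baseline = make_toy_plant()
cfg = toy_episode_config(t_max=20.0, transient=5.0)

result = run_episode(plant, baseline, cfg)
print(f"stable={result.stable}  t_sim={result.t_sim:.1f} s  "
      f"v_act={result.v_act:.3f} m/s  gait={result.gait}")

fast = baseline.copy()
fast.kappa_F[0] += 0.5   # stronger extensor force feedback
result = run_episode(plant, fast, cfg)
print(f"stable={result.stable}  t_sim={result.t_sim:.1f} s  "
      f"v_act={result.v_act:.3f} m/s  gait={result.gait}")
```

prints

```
stable=True  t_sim=20.0 s  v_act=2.264 m/s  gait=run
stable=True  t_sim=20.0 s  v_act=2.554 m/s  gait=run
```

The baseline reflex set hops stably for the full episode at 2.26 m/s and is
classified as running (periodic flight phases).  Raising the extensor's
homonymous force gain by 0.5 strengthens the stance push and the same
controller settles 0.29 m/s faster — the speed sensitivity that the
pipeline's PCA stage detects and the modulation function exploits.

The same stages are scriptable from the shell.  Library defaults follow the
full-model study protocol (50 s episodes, 20 CMA-ES seeds, σ₀ = 0.01); for
a desk-scale run on the toy, put reduced budgets in a config file:

```yaml
# toy.yaml
plant: toy
episode: {t_max: 10.0, transient: 3.0}
cma: {sigma0: 0.05, n_seeds: 2, max_generations: 12, popsize: 6}
smf: {n_key: 4, degree: 2, grid_min: 1.8, grid_max: 3.0, grid_step: 0.1}
```

```
reflexgait optimize --config toy.yaml --direction both --seed 1 --out runs/omega
reflexgait select-keys --config toy.yaml --omega runs/omega/omega.csv --out runs/keys
reflexgait fit-smf --config toy.yaml --omega runs/omega/omega.csv \
    --keys runs/keys/keys.json --out runs/smf
reflexgait sweep --config toy.yaml --model runs/smf/smf.json --out runs/sweep
reflexgait online --model runs/sweep/smf.json --kind ramp --out runs/online
reflexgait toybench --smoke --seed 1
```

On one CPU the `optimize` stage takes ~40 s and reports 14 harvested stable
records spanning 5.36 m/s; the sweep reports 13/13 stable targets with zero
monotonicity violations, and the ramp-tracking run survives its full
episode.  Each command writes its outputs (CSV/JSON) plus a manifest
recording seeds and input hashes.

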