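# shearwalk

Shear-induced platelet transport from heavy-tailed velocity statistics.

In a sheared red-blood-cell suspension, platelets wander across the flow far
faster than classical shear-induced-diffusion theory (Zydney–Colton)
predicts. The cross-flow velocity magnitude of a platelet is well described
by an exponential bulk joined to a power-law tail,

```
P(v) = p0 exp(-λ v)                                v ≤ v_min
P(v) = p0 exp(-λ v_min) (v / v_min)^-(1+α)         v ≥ v_min
```

with tail exponent α, threshold v_min and mean speed v_moy; the constants
(p0, λ) follow from requiring unit mass and mean v_moy. Because the
velocity decorrelates over a memory time Δt ≈ 0.5 ms, platelet motion at
device scales is an iid-step random walk, `y ← y + v Δt` with v drawn
fresh from ±P(v) each step, whose diffusion coefficient is exactly
`D = ⟨v²⟩ Δt / 2`.

`shearwalk` is for researchers in computational hemodynamics and blood-cell
biophysics who want to go from platelet trajectory data (or synthetic
stand-ins) to transport predictions. It provides:

- **velocity_model** — solve the (p0, λ) normalization constraints, evaluate
  the density/CDF in closed form, invert the CDF exactly, draw
  sign-symmetric samples, closed-form moments;
- **trajectory_analysis** — finite-difference velocities, near-wall
  exclusion, log-binned densities, Clauset-style power-law tail fits
  (KS-minimizing threshold + continuous MLE), velocity autocorrelation,
  power-law VACF fits, decorrelation time, wall profiles;
- **stochastic_sim** — the memory-time random walk between
  absorbing/reflecting walls, deposition experiments, parameter sweeps;
- **transport_metrics** — MSD with "in"/"in & out" censoring, slope/ratio
  diffusion estimators, finite-size scans, the Zydney–Colton reference value;
- **synthetic_data** — renewal-process trajectory ensembles with exactly
  known statistics, for validating every analysis stage;
- a `shearwalk` CLI (`solve-norm`, `fit-dist`, `sample`, `simulate`,
  `deposit`, `msd`, `vacf`, `zc`, `synth-traj`, `synth-vacf`, `run`).

## Worked example

```python
from shearwalk import VelocityDistribution, deposition_experiment

dist = VelocityDistribution.from_constraints(alpha=3.8, v_min=5e-3, v_moy=1e-3)
print(f"p0 = {dist.p0:.2f} s/m, lambda = {dist.lam:.2f} s/m")
print(f"<v^2> = {dist.moment(2):.3e} m^2/s^2")
print(f"iid-step D = <v^2> dt/2 = {dist.moment(2) * 0.5e-3 / 2:.3e} m^2/s")

curve, exponent = deposition_experiment(dist, seed=1)
print(f"deposited after 20 s: {int(curve.cumulative_absorbed[-1])} of 4800")
print(f"log-log growth exponent of N(t): {exponent:.3f}")
```

prints

```
p0 = 1015.24 s/m, lambda = 1017.36 s/m
<v^2> = 2.137e-06 m^2/s^2
iid-step D = <v^2> dt/2 = 5.343e-10 m^2/s
deposited after 20 s: 674 of 4800
log-log growth exponent of N(t): 0.516
```

The solved constants make the piecewise law a proper density with mean
1e-3 m/s. The implied diffusion coefficient, 5.3e-10 m²/s, is an order of
magnitude above the Zydney–Colton value for the same conditions
(`shearwalk zc` → D_ZC = 4.9e-11 m²/s at hematocrit 0.35 and shear rate
100 s⁻¹). In the deposition experiment — 4800 platelets seeded uniformly in
a 0.82 mm column with an absorbing floor — about 680 platelets deposit in
20 s, and the cumulative count grows as √t, the signature of a 1D
diffusion-absorption process.

The same sequence runs from the shell:

```
shearwalk solve-norm --alpha 3.8 --v-min 5e-3 --v-moy 1e-3
shearwalk deposit --alpha 3.8 --v-min 5e-3 --v-moy 1e-3 --seed 1 --out deposition.csv
```

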