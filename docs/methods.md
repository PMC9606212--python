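# Methods

## Model

Platelet motion perpendicular to a shear flow is modelled through the
marginal distribution of the cross-flow velocity magnitude,

    P(v) = p0 exp(-λ v)                                 v ≤ v_min
    P(v) = p0 exp(-λ v_min) (v / v_min)^-(1+α)          v ≥ v_min

a continuous exponential-bulk / Pareto-tail law. Signs are symmetric
(± with probability 1/2, independent of the magnitude), reflecting the
symmetry of a plane shear between parallel walls. The velocity decorrelates
over a memory time Δt, so on coarser time scales a platelet performs an
iid-step random walk `y(t+Δt) = y(t) + v Δt`. For that walk the diffusion
coefficient is exact: `D = ⟨v²⟩ Δt / 2`, which serves as the analytic
oracle throughout the test suite.

Assumptions worth keeping in mind: the velocity field is homogeneous in y
away from the walls (valid for plane shear, not for tube flow), there is no
drift/margination term, no platelet–platelet interaction, and the
distribution parameters do not depend on position.

### Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| α | tail exponent (density ∝ v^−(1+α)) | 3.8 | — |
| v_min | bulk/tail threshold | 5×10⁻³ | m/s |
| v_moy | mean velocity magnitude | 1×10⁻³ | m/s |
| Δt (`dt_step`) | velocity memory / walk step | 5×10⁻⁴ | s |
| δt (`fine_dt`) | trajectory sampling interval | 1×10⁻⁵ | s |
| L | domain height | 50 µm (analysis), 0.82 mm (deposition) | m |

The defaults are the study conditions of the shear-rate-100 s⁻¹,
hematocrit-0.35 setting the package addresses; all are overridable.
α must exceed 1 (finite tail mean); α ≤ 2 is the Lévy-flight regime with
infinite velocity variance, where transport becomes cutoff-sensitive (see
below).

## Normalization constants

(p0, λ) solve the exact integrals of the piecewise law:

    1     = (p0/λ)(1 − e^{−λ v_min}) + p0 e^{−λ v_min} v_min / α
    v_moy = p0 e^{−λ v_min} [v_min²/(α−1) − v_min/λ − 1/λ²] + p0/λ²

Note the mean constraint includes the bulk term p0/λ²; dropping it does not
reproduce the solved constants (1015.24, 1017.36 s/m at the defaults). The
2×2 system is solved with a hybrid Newton method in log-parameters
(positivity by construction), initialized at the pure-exponential limit
p0 = λ = 1/v_moy — exact when λ·v_min ≫ 1 and within a few percent at the
defaults. Solutions are accepted only if both relative residuals are
≤ 10⁻¹²; otherwise the solver raises, reporting the residuals.

## Sampling

Magnitudes are drawn by exact CDF inversion: for uniform r, the bulk branch
v = −ln(1 − λ r / p0)/λ applies below r_c = (p0/λ)(1 − e^{−λ v_min}) and the
Pareto branch above; the two branches join continuously at v_min. Uniforms
are consumed in (magnitude, sign) pairs per velocity — the draw order is
part of the reproducibility contract. r ≥ 1 − 10⁻¹² is clamped before
inversion so the tail bracket cannot underflow; with α = 3.8 this truncates
only astronomically rare draws and does not affect any statistic at the
sample sizes used. An optional speed cap redraws magnitudes above it; no
cap is applied by default for α > 2, while Lévy-regime runs (α ≤ 2) should
set one explicitly (tests and sweeps use 0.3 m/s, the top of the velocity
range the analysis plots, and record it).

## Trajectory statistics

**Velocities** are forward differences over `stride` samples,
v(t) = (y(t + stride·δt) − y(t))/(stride·δt); the mean speed is averaged
over time per record first, then over records, so records of unequal length
carry equal weight.

**Near-wall exclusion** removes samples within a margin (default 10 µm,
about one red-cell diameter) of either wall, where margination traps
platelets and the statistics are not representative. Each contiguous
in-band run becomes an independent record; autocorrelation pairs never
straddle a gap.

**Tail fitting** follows the standard threshold-selection recipe for
power laws: for each candidate threshold, the exponent is the continuous
MLE `â = 1 + n [Σ ln(v/v_min)]⁻¹` (density convention) and the fit quality
is the KS distance between the tail sample and the fitted Pareto; the
selected threshold minimizes KS, and the reported exponent is â − 1 (the
convention in which the tail decays as v^−(1+α)). Candidates are the unique
observed values between the 50th and 99.9th percentiles, thinned to ≤ 200
log-spaced values; tails smaller than 50 points are skipped. For tails
larger than 2000 points the KS distance is evaluated on 2000 evenly spaced
order statistics — a negligible approximation that bounds the cost of the
scan. A fit is flagged degenerate when the optimum sits at a grid extreme
or when even the best candidate is rejected by a KS test at the 1% level
(critical value 1.63/√n_tail) — both typical of data without a power-law
tail (an exponential sample triggers the flag).

**VACF** uses signed velocities: VACF(τ) = ⟨v(t+τ) v(t)⟩ averaged over all
records and admissible origins. A magnitude autocorrelation would plateau
at v_moy² instead of decaying into the noise floor, which would make the
memory-time criterion ill-posed. The power-law fit regresses ln VACF on
ln(τ/1 ms) by least squares over a stated window, using only strictly
positive values; the amplitude `a` is therefore the VACF value at τ = 1 ms
(the printed amplitude's units are ambiguous in the source analysis; this
convention is what the fitter recovers). The decorrelation time is the
smallest lag at which the VACF falls to the noise floor σ, with σ the
standard deviation of the VACF inside a tail window — by default the last
quarter of the lag range, and always reported alongside the result.

## Stochastic walk and deposition

Per step and per surviving walker: draw a signed velocity, move
ballistically for one step, then apply wall rules. Absorption (y ≤ 0 at an
absorbing floor) is tested before reflection; specular reflection maps
y → 2L − y, and a walker reflected across the whole domain in one step is
re-tested at the opposite wall (absorbed there if it absorbs, otherwise
clamped just inside). Walker conservation (absorbed + surviving = N) holds
at every step. One RNG stream per run, platelet-major draw order per step,
seed recorded in every output.

The reference deposition experiment seeds 4800 walkers uniformly on a
0.82 mm column with absorbing floor and reflecting ceiling and runs 20 s at
0.5 ms steps. For uniform initial data the 1D continuum solution gives the
absorbed fraction √(4Dt/π)/L, i.e. ≈ 683 platelets at D = ⟨v²⟩Δt/2 =
5.34×10⁻¹⁰ m²/s; the simulation reproduces this closed form (and the √t
growth of the count) rather than any particular larger figure.

## MSD and diffusion estimation

MSD(t) = ⟨(y(t) − y(0))²⟩ from the record origin, with two censoring modes:
"in" keeps only records that never leave the observation domain; "in & out"
lets each record contribute until its first exit. Both are computed and
reported; no ordering between the two D estimates is assumed. D comes
either from the mean of MSD/(2t) over a window ("ratio") or from the
zero-intercept least-squares slope over a window divided by 2 ("slope",
the default, over [t_end/10, t_end/2] unless stated — the late half is
excluded only when boxes saturate). Small reflecting boxes saturate the
MSD and underestimate D; the finite-size scan quantifies this against the
unbounded ⟨v²⟩Δt/2 limit.

The Zydney–Colton reference is
D_ZC = D_PRP(1−H) + 0.15 (d_RBC²/4) H γ̇ (1−H)^1.8 with defaults
D_PRP = 10⁻¹³ m²/s and d_RBC = 9 µm (a physiological red-cell diameter that
reproduces the commonly quoted 5×10⁻¹¹ m²/s at H = 0.35, γ̇ = 100 s⁻¹);
the (d_RBC²/4)·H grouping is the one consistent with that value.

## Synthetic data

The generator emulates the recording protocol of a fully resolved
suspension simulation — per-platelet vertical positions at δt = 10 µs over
~1 s in a 50 µm channel — with a renewal velocity process: each platelet
redraws a signed velocity every memory time (0.5 ms), aligned to the fine
grid and phase-randomized per platelet (the first renewal falls at a
uniform offset, so a window of one memory time may contain one renewal).
This construction makes the fine-grained velocity marginal equal the
generating law *exactly* and the VACF triangular with support equal to the
memory time — so mean-speed, tail, decorrelation and diffusion estimates
can all be checked against known truth. What it does **not** emulate: the
power-law (rather than triangular) VACF of real trajectories — the VACF
power-law fitter is instead validated on directly synthesized power-law
curves — nor margination, near-wall velocity suppression, sub-δt velocity
structure (so the dependence of the measured mean speed on sampling
resolution appears only qualitatively, via stride coarsening), or any
hematocrit dependence. Passing tests therefore validate the estimators and
the walk, not the physiological fidelity of the renewal process.

Deterministic fixtures: "small" (10 platelets × 0.05 s) and "medium"
(200 × 1 s). The medium set is ~2×10⁷ rows when written to disk, so the
test suite generates it in memory and writes only the small fixture.

## Numerical and design choices

- Uniform-spacing validation of trajectories at 1 ns tolerance; forward
  differences only (the last sample of each segment yields no velocity).
- Log-binned densities: counts/(n × linear bin width) on 8 bins per decade
  over [10⁻⁵, 0.3] m/s by default, so Σ density·width equals the in-range
  fraction.
- The k²-scaling property (jointly scaling v_min and v_moy by k multiplies
  D by k²) is verified with common random numbers: the scaled and base runs
  share a seed, and the sampler's exact scaling covariance then isolates
  the systematic effect without Monte-Carlo noise.
- α-sweep: for α strictly above 2, D and the deposited count stay within
  15% of their α = 3.8 reference values (the exact moments give
  +11%/−1%/−5% at α = 3/4/5); at and below α = 2 the variance is (log-)
  divergent and both quantities rise — with a 0.3 m/s cap, D roughly
  doubles at α = 2. Sweep cells with α ≤ 2 are labelled as
  infinite-variance and their D is cutoff-sensitive by nature.
- Problem sizes in the test suite (10³–10⁴ walkers, 1–20 s of walk time,
  10⁶-sample fits) are chosen so that statistical error bands sit well
  below the asserted tolerances while the full suite stays fast.
- Statistical assertions use empirical standard errors where the heavy
  tail makes Gaussian formulas optimistic (the fourth velocity moment
  diverges for α ≤ 4, so MSD ordinates converge slowly).

## Known limitations

- The walk has no drift term: deposition counts reflect pure
  diffusion-absorption and are expected to undershoot device observations
  where margination or other drifts act.
- D for α ≤ 2 depends on the chosen speed cap; the package surfaces the
  cap rather than fixing a policy.
- The tail fitter assumes an iid sample; applied to finely sampled renewal
  trajectories the KS statistic is inflated by within-segment repetition
  (the exponent estimate remains consistent, but the degeneracy flag can
  trip on strongly correlated input).
- Trajectory ingestion expects uniform sampling; irregularly sampled data
  must be resampled upstream.
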