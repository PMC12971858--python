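# Methods

## The model

`phagedyn` simulates lytic bacteriophage–bacteria population dynamics with
three state variables: uninfected bacteria U(t), infected bacteria I(t) and
free phage P(t) (all per mL). The building blocks are

* **logistic growth** of bacteria, per-capita rate
  `r(t) = r_max (1 − (U+I)/K_C)` with ceiling concentration `K_C`;
* **saturable adsorption**, `phi(t) = phi_max P_50 / (P_50 + P)`: phage bind
  uninfected and infected cells alike, but the per-cell infection pressure
  saturates at high phage titer;
* **lysis after a latent period** tau: a cell infected at time s lyses at
  s + tau, surviving until then with probability `exp(−delta_I tau)`, and
  releases a burst of progeny;
* first-order **decay** of each population (`delta_U`, `delta_I`, `delta_P`).

Single-cell experiments show the latent period is not one number but a
distribution across cells, and that the burst size grows with the time the
phage spends replicating inside the cell. `phagedyn` therefore treats tau as
a random variable with density `f_tau` (mean `tau_0`, relative SD `rsd_tau`,
hard minimum `tau_min`) and the conditional mean burst size as a saturating
sigmoid

    beta_0(tau) = beta_max (e^{r_beta (tau−D)} − 1) /
                  (e^{r_beta (btau_50−D)} + e^{r_beta (tau−D)} − 2),

zero for tau ≤ D (no virions assembled yet), half-maximal at tau = btau_50.
Only the *conditional means* of the burst size and the adsorption rate enter
the population equations — mixtures over beta and phi collapse onto their
means, which the test suite verifies numerically against an explicitly
mixture-expanded solver. `beta_max` is not a free input: it is computed by
adaptive quadrature so that the population mean burst
`E[beta_0(tau)] = beta_0_mean`, the quantity a single-step growth experiment
actually estimates. If essentially all latent mass lies below D the
normalization is singular and the parameter set is rejected as invalid.

Three model structures share these kinetics:

1. **Fixed-delay (DDE)** — the classical model: one latent period, constant
   burst `beta_0_mean`.
2. **Distributed-delay (DDDE)** — the delayed lysis terms become
   convolutions of the infection history `H(s) = phi(s) U(s) P(s)` with the
   latent density: survival-weighted mass `exp(−delta_I tau) f_tau(tau)` for
   the infected-pool outflow, additionally burst-weighted
   `beta_0(tau) exp(−delta_I tau) f_tau(tau)` for the phage source. History
   is zero before t = 0 (phage are administered at t = 0).
3. **Transit compartments (TC)** — an Erlang chain of
   `N = round(1/rsd_tau²)` infected stages with transit rate `k_tr = N/tau_0`,
   the standard ODE stand-in for a distributed delay. It cannot represent
   `tau_min > 0` or a tau-dependent burst; it uses the constant mean burst.

## Latent-period distributions

Truncated normal, lognormal and gamma families are supported, plus the
degenerate point mass (`rsd_tau = 0`). All are moment-matched so the
realized mean and SD are exactly `tau_0` and `rsd_tau·tau_0`:

* lognormal and gamma are shifted by `tau_min` and matched in closed form on
  the shifted variable — this preserves the exact moment targets and a hard
  zero below `tau_min`;
* the truncated normal solves for parent (mu, sigma) by damped
  Newton–Raphson on the truncated-moment equations (Mills ratio evaluated in
  log space), starting from (tau_0, sd), at most 100 iterations, relative
  tolerance 1e-10. One-sided truncation bounds the attainable width:
  sd < tau_0 − tau_min (the exponential-tail limit); wider targets raise an
  infeasibility error rather than silently missing the moments. This corner
  is real in the Monte Carlo: at rsd_tau = 0.5 with tau_min near tau_0/2 the
  truncated normal cannot exist, and such draws are resampled.

For the solvers the density is discretized onto the simulation grid: node
tau_k = k·dt receives the CDF difference over [tau_k − dt/2, tau_k + dt/2],
the support runs to the 1−1e−6 quantile, and weights are renormalized to sum
to one. CDF-difference binning conserves probability exactly and keeps the
first moment correct to well below the grid-step contract (|mean − tau_0| <
2dt; in practice the residual is the fixed tail clip, ~1e−6·tau).

## Numerical integration

The workhorse stepper is forward Euler with the delay integrals evaluated as
discrete convolutions of the stored history — compiled (numba) with the
convolution expressed as BLAS dot products, because the DDDE cost is
O(n_steps × kernel length). States are floored at zero after each step (the
scheme is explicit; undershoot events are counted on the trajectory), and a
non-finite state aborts the run with the offending step reported. An RK4
stepper with linear history interpolation at half-steps is available as a
cross-check; it agrees with Euler within the convergence criterion and shows
no practical benefit for this system, so Euler remains the default.

**Step control.** A run starts at dt = 0.01 h and halves the step until the
normalized area-between-curves error (below) between successive solutions is
< 1% for both the bacterial load (U + I) and the viral load (P), with at
most 8 halvings. Non-convergence is a reported outcome, not an exception:
the Monte Carlo layer replaces such parameter sets with a fresh draw. A cost
guard additionally skips any halving whose estimated work exceeds 4e10
node-updates (a pathological stiff corner: phi_max·P_50 can reach 10³/h,
beyond what an explicit method can resolve in 8 halvings anyway); guard
stops are reported as non-convergence. The guard is sized so that it is not
the binding constraint for ordinary draws — in diagnostics, typical runs
converge within 1–3 halvings.

**Horizon.** The area metric notionally integrates to infinity; runs use a
default 48 h horizon that doubles (at most twice, to 192 h) while either
load still changes by more than 0.1% relative over the final 10% of the run.
The horizon is chosen once per parameter set from the reference scenario, so
every compared trajectory shares the same window; when two converged runs
have different final steps, the finer one is downsampled (halvings nest) and
the longer one truncated.

## The error metric

Two profiles A and B are compared as
`Error(%) = 100 · 2 ∫|X_A − X_B| dt / (∫X_A dt + ∫X_B dt)` with trapezoidal
integrals on the simulation grid. The metric is symmetric, scale-invariant
and bounded by 200% (one curve identically zero); two identically-zero
curves define error 0. "Bacterial load" defaults to U + I (what a CFU count
sees) and "viral load" to free phage P (PFU); a `component="U"` switch
exists because the observable is a modeling choice, not a law.

## Comparison scenarios

For a given kinetic parameter set and rsd level, the reference is the
lognormal-kernel distributed model with the tau-dependent burst. The
approximations are:

* **Fixed-Mean / Fixed-Median** — fixed-delay model with tau set to the
  distribution mean / median;
* **Fixed-Early** — tau set to the time of first observed lysis, defined as
  the instant the number of infective centers (free phage + infected cells,
  i.e. plaque-forming units) doubles in a simulated single-step growth
  experiment. The experiment is realized as a synchronized infection: all
  inoculated phage are adsorbed at t = 0 (I(0) = P_init, U(0) = P(0) = 0)
  and adsorption is switched off, so exactly one round of lysis is observed;
  the infected cohort lyses along the latent kernel with the scenario's
  burst profile and decays are retained. Because the earliest-lysing cells
  double the count before the average cell lyses, this classically reported
  value underestimates tau_0 — the bias the comparison quantifies. If the
  population-mean burst (net of decay) cannot double the centers, the
  doubling time is undefined and the scenario fails explicitly.
* **TC** — the Erlang chain matched by `N = round(1/rsd²)`, `k_tr = N/tau_0`.

## Monte Carlo design

Kinetic parameter sets are drawn from literature-informed ranges: `r_max`
U(0.5, 2.5)/h; `K_C` log-U(1e8, 1e10)/mL; `phi_max` log-U(1e-9, 1e-7)
mL/cell/h; `P_50` log-U(r_max/phi_max, 1e10)/mL (adsorption can at least
offset growth); `tau_0` U(0.25, 3) h; `tau_min` U(0, tau_0/2);
`beta_0_mean` log-U(10, 500); `r_beta` U(1, 10)/h; `D` U(0, tau_0);
`btau_50` U(D, 3) h; decays `delta_U`, `delta_I` U(0.1, 0.25)/h, `delta_P`
U(0.05, 0.15)/h; `U_init` log-U(1e3, K_C(1 − delta_U/r_max));
`P_init` log-U(1e3, 1e9). Dependent bounds are resolved against the
already-drawn values in that order. The width `rsd_tau` is a controlled grid
variable (0.1–0.5), not a sampled one. An option exists to treat `beta_max`
rather than `beta_0_mean` as the sampled burst quantity.

Each Monte Carlo cell (scenario pair × rsd level) fills exactly `n_sets`
converged rows; a draw is replaced — from the same deterministic substream —
whenever any scenario in the cell is infeasible (truncated-normal width,
burst normalization) or fails the 1% convergence criterion, with a resample
budget of 10 per set. Substream j derives from (master_seed, cell_key, j),
so a study is bit-reproducible given its master seed. Summaries are medians
with IQRs per (pair, rsd, load); at reduced n the medians carry bootstrap
95% confidence intervals.

**Problem sizes.** The published comparison uses 500 sets per cell. The
bundled acceptance script defaults to 40 sets per cell and the test suite
uses 12, which keeps a full run at desk scale; medians of the error
distribution are stable enough at these sizes that the bootstrap CI is the
honest way to read them, and both sizes are parameters, not constants.

## What the generator does and does not emulate

The synthetic experiments cover the stated kinetic ranges with independent
(log-)uniform draws, which deliberately includes aggressive corners (e.g.
near-ceiling inoculums with strong adsorption) that real phage–host pairs
may never realize jointly. Cell-level variability enters only through the
latent period and its induced burst dependence — bimodal or empirical
single-cell distributions, experimental noise, plating error and
readsorption during the single-step assay are not modeled. Conclusions from
passing tests therefore speak to the model structures' mutual consistency
over these ranges, not to any particular organism.

## Known limitations

* Explicit Euler cannot resolve the stiffest sampled corners
  (phi_max·P_50 ~ 10³/h) within the halving budget; those sets are resampled,
  exactly as genuine convergence failures are, which slightly biases the
  sampled population toward non-stiff kinetics.
* The area metric on a finite horizon under-weights never-settling
  predator–prey oscillations; the horizon-extension rule caps at 192 h.
* The delay is grid-aligned (rounded to the nearest node), consistent with
  the convolution-sum scheme; sub-grid delay effects are controlled by the
  1% step-halving criterion rather than resolved exactly.
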