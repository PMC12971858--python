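# phagedyn

Bacteriophage–bacteria population dynamics with cell-level heterogeneity in
the latent period.

Classical phage pharmacodynamic models describe uninfected bacteria U,
infected bacteria I and free phage P with three key parameters: the
adsorption rate φ, a single latent period τ between infection and lysis, and
a burst size β of progeny per lysed cell. Single-cell experiments show that
τ varies substantially between cells and that β grows with τ. `phagedyn` is
a simulator suite for asking when that heterogeneity matters at the
population level, aimed at pharmacometric and viral-dynamics modelers
choosing a model structure for phage therapy.

It implements three structures over shared kinetics (logistic growth with
ceiling K_C, saturable adsorption φ(t) = φ_max P₅₀/(P₅₀+P), first-order
decays δ_U, δ_I, δ_P):

* **DDE** — the classical fixed-delay model, one τ and the population mean
  burst β₀,mean;
* **DDDE** — the distributed-delay model: lysis terms are convolutions of
  the infection history φ(s)U(s)P(s) with the latent-period density f_τ
  (truncated-normal, lognormal or gamma; mean τ₀, relative SD rsd_τ, minimum
  τ_min), with survival weight e^(−δ_I τ) and a τ-dependent mean burst
  β₀(τ) normalized so that E[β₀(τ)] = β₀,mean;
* **TC** — the transit-compartment (Erlang) chain, N = round(1/rsd_τ²)
  stages at rate k_tr = N/τ₀, constant burst.

Model discrepancies are scored with the normalized area between curves,

    Error(%) = 100 · 2∫|X_A − X_B| dt / (∫X_A dt + ∫X_B dt)  ∈ [0, 200],

on bacterial (U+I) and viral (P) load profiles, and a Monte Carlo layer
samples kinetic parameter sets from literature-informed ranges to compile
median errors of each approximation (fixed mean / median / first-observed
lysis, TC) against the distributed reference. See `docs/methods.md` for the
full model description and numerical choices.

## Worked example

With `example.yaml`:

```yaml
kinetics:
  r_max: 1.0        # /h
  K_C: 1.0e9        # bacteria/mL
  phi_max: 1.0e-8   # mL/cell/h
  P_50: 1.0e8       # phage/mL
  delta_U: 0.1
  delta_I: 0.1
  delta_P: 0.1      # /h
  beta_0_mean: 100.0
  r_beta: 2.0       # /h
  D: 0.2            # h
  beta_tau50: 0.8   # h
  U_init: 1.0e5
  P_init: 1.0e6
distribution:
  family: lognormal
  tau_0: 1.0
  rsd_tau: 0.3
  tau_min: 0.0
```

the single-step growth experiment (synchronized infection, one round of
lysis) shows the classical read-off bias:

```
$ phagedyn single-step --config example.yaml
first observed lysis (infective-center doubling): 0.5443 h
distribution mean: 1.0000 h, median: 0.9578 h
```

The infective centers double at 0.54 h — the earliest-lysing cells are
counted long before the average cell (τ₀ = 1 h) has lysed, so fixing the
latent period to the classically reported "first lysis" value understates τ
by almost half here.

Simulating the full distributed model writes a trajectory CSV
(`time_h, U, I, P`), with the step chosen by halving until both load
profiles change by less than 1%:

```
$ phagedyn simulate --config example.yaml --model ddde --out traj.csv
wrote traj.csv (dt=0.005 h, converged=True)
```

Comparing this reference against the fixed-delay model with τ set to the
distribution mean (library call, same parameter set) gives bacterial and
viral load errors of 0.53% and 0.37% over the settled 192 h window — at
rsd_τ = 30% with these mid-range kinetics the classical model is still an
excellent approximation; the Monte Carlo layer quantifies how quickly that
degrades across parameter space and at larger rsd_τ:

```
$ phagedyn montecarlo --pair fixed-mean --rsd 0.1,0.3,0.5 --n 100 \
      --seed 120659 --out records.csv
```

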