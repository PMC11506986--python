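# epime

Master-equation toolkit for stochastic SIS/SIR epidemic dynamics: exact
probabilistic evolution of outbreaks, branching-process extinction
probabilities, stochastic simulation, and entropy-based quantification of
forecast uncertainty.

## The problem

Deterministic compartmental models track the expected occupation of each
disease compartment, but a single expected trajectory hides the ensemble of
futures a stochastic epidemic can actually take: early extinction of a
supercritical pathogen, the spread of outcomes around the epidemic peak, the
bimodal split between minor and major outbreaks.  `epime` treats SIS and SIR
dynamics in a closed, well-mixed population of N individuals as a
continuous-time Markov chain over population configurations and evolves the
full probability distribution, for researchers and modellers who need the
distribution — not just its mean.

The state is a probability vector P over configurations (the infected count
I for SIS; the pair (S, I) for SIR).  It obeys the master equation

    dP/dt = H P,

where the generator H — the occupation-number (Doi–Peliti) representation of
the process Hamiltonian — encodes the two reactions

    contagion:  S + I -> 2I   at rate beta * S * I / N
    recovery:   I -> S (SIS)  or  I -> R (SIR)   at rate gamma * I

with basic reproduction number R0 = beta/gamma.  The state is propagated by
repeated application of the single-step propagator expm(H dt).  On top of
this core the package provides:

* deterministic ODE baselines, the endemic SIS prevalence 1 − 1/R0, the SIR
  final-size relation rho = 1 − s0·exp(−R0·rho) − r0, and peak location;
* compartment marginals P(I), P(R), their Shannon entropy H = −Σ P log P,
  and the no-outbreak mass of the stationary recovered marginal;
* the branching-process (Whittle) extinction law — probability 1 for
  R0 ≤ 1 and (1/R0)^I0 above threshold — as a closed form, as a truncated
  linear recursion, and cross-checked against the generator's own rates;
* tau-leap and exact event-driven simulators with minor-outbreak
  classification;
* the forecast-conditioning experiment: collapse the state onto a reference
  trajectory at time t0 and measure how uncertain the epidemic peak remains.

See `docs/methods.md` for assumptions, conventions and numerical policies.

## Worked example

Evolve an SIR outbreak seeded by one infectious individual in a population
of 100, with beta=0.6, gamma=0.1 (R0 = 6):

```python
import epime as e

params = e.EpidemicParams(beta=0.6, gamma=0.1, N=100, model=e.Model.SIR)
space = e.build_state_space(params)          # 5151 configurations (S, I)
gen = e.build_generator(params, space)       # sparse master-equation generator
series = e.evolve(gen, e.delta_state(space, (99, 1)),
                  e.PropagationConfig(dt=0.1, t_max=30.0, record_stride=100))
for pv in series:
    marg = e.marginal_infected(pv, space)
    print(f"t={pv.time:5.1f}  E[I]={marg.mean():6.2f}  "
          f"H={e.entropy(marg):.3f}  P(I=0)={marg.probabilities[0]:.3f}")
```

```
t=  0.0  E[I]=  1.00  H=0.000  P(I=0)=0.000
t= 10.0  E[I]= 32.37  H=3.866  P(I=0)=0.168
t= 20.0  E[I]= 30.57  H=3.376  P(I=0)=0.169
t= 30.0  E[I]= 12.73  H=3.002  P(I=0)=0.169
```

The mean infected count rises and falls like the deterministic wave, but the
distribution tells more: by t = 10 the extinction atom P(I = 0) has locked
in at ≈ 0.17 — almost exactly the branching-process prediction
1/R0 ≈ 0.167 for an outbreak seeded by one case — and the entropy stays
high around the peak, where forecasts are intrinsically most uncertain.

The same computations run from the shell.  An ensemble of 500 tau-leap
outbreaks at R0 = 2 in a population of 10,000:

```
$ epime simulate --beta 0.2 --gamma 0.1 --N 10000 --model SIR \
        --n-runs 500 --seed 7 --out demo-sim
no-outbreak fraction 0.5180 (95% CI 0.4742-0.5615); branching closed form 0.5000
```

Each subcommand (`propagate`, `deterministic`, `extinction`, `simulate`,
`forecast`, `cloud`, `fixtures`) writes CSV/JSON/MTX outputs at full double
precision plus a `manifest.json` recording the config hash, seed and
version; runs can equally be driven by a YAML config file (`--config`,
flags take precedence):

```yaml
params: {beta: 0.6, gamma: 0.1, N: 100, model: SIR}
propagation: {dt: 0.1, t_max: 60.0}
seed: 7
outdir: out
```

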